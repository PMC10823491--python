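"""End-to-end study designs built from the library pieces.

These functions wire the simulator, feature extraction, topology
weighting and networks into the experiments the package exists for:
training sets for topology classification, single-window
recombination-aware parameter regression, the gene-flow/recombination
topology-weight experiment, and selection-class-stratified estimation
on a labelled synthetic landscape.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .inference import featurize, locus_stats
from .matrix import GenotypeMatrix
from .simulate import (
    INGROUPS,
    OUTGROUP,
    POPS,
    DemographicModel,
    LandscapeConfig,
    PriorSet,
    generate_landscape,
    sample_prior,
    simulate_dataset,
    simulate_locus,
)
from .twisst import groups_from_matrix, nj_tree, weights_exact


def classifier_training_set(
    n_per_model: int,
    n_loci: int,
    seed: int,
    n_hap: int = 20,
    L: int = 10_000,
    priors: PriorSet | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Feature vectors + topology labels for genome-wide model selection.

    Each training example is one prior draw simulated as ``n_loci``
    independent loci and summarised by :func:`genarch.inference.featurize`.
    """
    rng = np.random.default_rng(seed)
    priors = priors or PriorSet()
    n_pp = {p: n_hap for p in INGROUPS}
    X, y = [], []
    for topo in (1, 2, 3):
        for _ in range(n_per_model):
            model = sample_prior(priors, topo, rng)
            loci, _ = simulate_dataset(
                model, n_loci, L, n_pp, seed=int(rng.integers(1, 2**31 - 1))
            )
            vec, _, _ = featurize(loci)
            X.append(vec)
            y.append(topo)
    return np.asarray(X), np.asarray(y)


def single_window_training_set(
    n_sims: int,
    seed: int,
    topology: int = 1,
    L: int = 100_000,
    n_hap: int = 20,
    r_max: float = 3.021e-9,
    priors: PriorSet | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Per-window statistics + true parameters for single-window regression.

    Windows are simulated with an intralocus recombination rate drawn
    uniformly on [0, r_max]; the feature vector is the window's own
    statistics (the single-locus limit of the dataset features).
    """
    rng = np.random.default_rng(seed)
    priors = priors or PriorSet()
    n_pp = {p: n_hap for p in INGROUPS}
    X, rows = [], []
    for _ in range(n_sims):
        r = rng.uniform(0, r_max)
        model = sample_prior(priors, topology, rng, r=r)
        gm = simulate_locus(
            model, n_pp, L, with_recombination=True,
            seed=int(rng.integers(1, 2**31 - 1)),
        )
        X.append(locus_stats(gm))
        rows.append(
            {
                "ne_Tapajos": model.ne["Tapajos"],
                "t_recent": model.t_recent,
                "t_deep": model.t_deep,
                "mig_Tapajos_Xingu": model.mig[("Tapajos", "Xingu")],
                "mig_Xingu_Belem": model.mig[("Xingu", "Belem")],
                "r": r,
            }
        )
    return np.asarray(X), pd.DataFrame(rows)


def topology_weight_experiment(
    n_windows: int,
    seed: int,
    mig_xb: float = 0.0,
    with_recombination: bool = False,
    L: int = 10_000,
    n_hap: int = 4,
    ne: float = 2e5,
    t_recent: float = 2e5,
    t_deep: float = 6e5,
) -> np.ndarray:
    """Topology weights for windows simulated under topology 1.

    Returns an (n_windows, 3) weight array from NJ trees of each window.
    ``mig_xb`` sets Xingu<->Belem gene flow in migrants/generation; with
    topology 1 this is flow between non-sister populations, which erodes
    the weight of the generating topology.
    """
    rng = np.random.default_rng(seed)
    model = DemographicModel(
        topology=1,
        ne={p: ne for p in POPS + ("anc_recent", "anc_deep")},
        t_recent=t_recent,
        t_deep=t_deep,
        t_outgroup=9.6e6,
        mig={("Xingu", "Belem"): mig_xb} if mig_xb > 0 else {},
        r=1e-8 if with_recombination else 0.0,
    )
    n_pp = {p: n_hap for p in INGROUPS}
    n_pp[OUTGROUP] = 2
    out = np.empty((n_windows, 3))
    for i in range(n_windows):
        gm = simulate_locus(
            model, n_pp, L, with_recombination,
            seed=int(rng.integers(1, 2**31 - 1)),
        )
        if gm.n_sites < 4:
            out[i] = 1 / 3
            continue
        tree = nj_tree(gm)
        out[i] = weights_exact(tree, groups_from_matrix(gm)).weights
    return out


def stratified_landscape(
    n_per_class: int,
    seed: int,
    window_length: int = 100_000,
    n_hap: int = 20,
    ne: float = 1.5e6,
    hard_suppression: float = 0.1,
    r: float = 2.1e-9,
) -> tuple[np.ndarray, pd.DataFrame, list[GenotypeMatrix]]:
    """Neutral + hard-sweep landscape, featurized per window.

    Returns (per-window statistic vectors, class table with truth labels
    and probability columns, the windows themselves).  The default base
    size is chosen so that suppressed windows keep their local size
    inside the default prior support — estimators trained on prior
    simulations are only meaningful where the training prior has mass.
    """
    base = DemographicModel(
        topology=1,
        ne={p: ne for p in POPS + ("anc_recent", "anc_deep")},
        t_recent=2e5,
        t_deep=6e5,
        t_outgroup=9.6e6,
        r=r,
    )
    classes = ["neutral"] * n_per_class + ["hard"] * n_per_class
    cfg = LandscapeConfig(
        base=base,
        n_windows=2 * n_per_class,
        window_length=window_length,
        class_of_window=classes,
        suppression={"neutral": 1.0, "hard": hard_suppression},
        n_per_pop={p: n_hap for p in INGROUPS},
        recomb_map=np.full(2 * n_per_class, r),
    )
    windows, _, table = generate_landscape(cfg, seed=seed)
    # rebase each window to local coordinates so per-bp statistics use the
    # window length, matching the single-window training features
    local = [
        GenotypeMatrix(
            w.alleles,
            w.positions - int(s),
            window_length,
            list(w.pops),
            w.chrom,
            w.phased,
        )
        for w, s in zip(windows, table["start"])
    ]
    feats = np.stack([locus_stats(w) for w in local])
    return feats, table, windows
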