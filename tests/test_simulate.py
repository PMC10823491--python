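"""Coalescent engine: analytic expectations, structure and determinism."""

import numpy as np
import pytest
from scipy import stats as sstats

from genarch.io import read_track, write_track
from genarch.matrix import GenotypeMatrix
from genarch.simulate import (
    INGROUPS,
    POPS,
    DemographicModel,
    LandscapeConfig,
    PriorSet,
    drop_mutations,
    generate_landscape,
    model_record,
    sample_prior,
    simulate_dataset,
    simulate_genealogy,
    simulate_locus,
)
from genarch.stats import diversity, pair_stats


def base_model(topology=1, ne=1e4, mig=None, t_recent=5e8, t_deep=6e8, **kw):
    return DemographicModel(
        topology=topology,
        ne={p: ne for p in POPS + ("anc_recent", "anc_deep")},
        t_recent=t_recent,
        t_deep=t_deep,
        t_outgroup=7e8,
        mig=mig or {},
        **kw,
    )


# ---------------------------------------------------------------------------
# priors
# ---------------------------------------------------------------------------
def test_prior_degenerate_and_deterministic():
    priors = PriorSet(ne=(2e5, 2e5), t_recent=(1e5, 1e5), t_deep=(9e5, 9e5), mig=(1, 1))
    m = sample_prior(priors, 2, seed=3)
    assert m.ne["Tapajos"] == 2e5 and m.t_recent == 1e5 and m.t_deep == 9e5
    assert all(v == 1 for v in m.mig.values())
    m2 = sample_prior(priors, 2, seed=3)
    assert model_record(m) == model_record(m2)


def test_prior_uniform_moments():
    """1,000 Ne draws from U(1e4, 1e6): bounds respected, mean within 3 SE."""
    priors = PriorSet(ne=(1e4, 1e6))
    draws = np.array(
        [sample_prior(priors, 1, seed=s).ne["Tapajos"] for s in range(1000)]
    )
    assert draws.min() >= 1e4 and draws.max() <= 1e6
    se = (1e6 - 1e4) / np.sqrt(12) / np.sqrt(1000)
    assert abs(draws.mean() - 5.05e5) < 3 * se


def test_prior_validation():
    with pytest.raises(ValueError):
        PriorSet(ne=(2e6, 5e4))
    with pytest.raises(ValueError):
        DemographicModel(
            topology=1,
            ne={p: 1e4 for p in POPS + ("anc_recent", "anc_deep")},
            t_recent=2e5,
            t_deep=1e5,  # out of order
            t_outgroup=1e6,
        )
    with pytest.raises(ValueError):
        base_model(mig={("Tapajos", "Belem"): 1.0})


# ---------------------------------------------------------------------------
# genealogies
# ---------------------------------------------------------------------------
def test_tmrca_expectation_single_population():
    """E[TMRCA] for n=2 in one deme of diploid size N is 2N generations."""
    model = base_model(ne=1e4)
    times = []
    for s in range(2000):
        ts = simulate_genealogy(model, {"Tapajos": 2}, seed=s + 1)
        t = ts.first()
        times.append(t.time(t.root))
    mean = np.mean(times)
    se = np.std(times, ddof=1) / np.sqrt(len(times))
    assert abs(mean - 2e4) < 3 * se


def test_cross_population_coalescence_respects_split():
    """With no migration, T and X lineages coalesce only above t_recent."""
    model = base_model(t_recent=5e4, t_deep=2e5, ne=1e5)
    for s in range(200):
        ts = simulate_genealogy(model, {"Tapajos": 1, "Xingu": 1}, seed=s + 1)
        t = ts.first()
        assert t.time(t.root) > 5e4


def test_migration_allows_early_coalescence():
    model = base_model(
        t_recent=5e5, t_deep=6e5, ne=2e4, mig={("Tapajos", "Xingu"): 1.0}
    )
    early = 0
    for s in range(200):
        ts = simulate_genealogy(model, {"Tapajos": 1, "Xingu": 1}, seed=s + 1)
        t = ts.first()
        if t.time(t.root) < 5e5:
            early += 1
    assert early > 0


def test_zero_ne_errors():
    with pytest.raises(ValueError):
        base_model(ne=0)


# ---------------------------------------------------------------------------
# mutations
# ---------------------------------------------------------------------------
def test_drop_mutations_zero_rate_and_unique_positions():
    model = base_model(ne=1e4)
    ts = simulate_genealogy(model, {"Tapajos": 4}, seed=7)
    gm0 = drop_mutations(ts, mu=0.0, L=10_000, seed=1)
    assert gm0.n_sites == 0
    for s in range(50):
        gm = drop_mutations(ts, mu=1e-6, L=10_000, seed=s + 1)
        assert len(np.unique(gm.positions)) == gm.n_sites  # infinite sites


def test_pairwise_differences_match_theta():
    """n=2: E[pairwise diffs] = 4 Ne mu L over 2,000 independent loci."""
    ne, mu, L = 1e4, 1e-7, 10_000
    model = base_model(ne=ne, mu=mu)
    loci, _ = simulate_dataset(model, 2000, L, {"Tapajos": 2}, seed=11)
    diffs = np.array(
        [np.sum(gm.alleles[0] != gm.alleles[1]) for gm in loci], float
    )
    theta = 4 * ne * mu * L
    se = diffs.std(ddof=1) / np.sqrt(len(diffs))
    assert abs(diffs.mean() - theta) < 3 * se


# ---------------------------------------------------------------------------
# loci with/without recombination
# ---------------------------------------------------------------------------
def _four_gamete_ok(gm, max_pairs=2000):
    a = gm.alleles
    n = min(gm.n_sites, 60)
    for i in range(n):
        for j in range(i + 1, n):
            pats = {(int(x), int(y)) for x, y in zip(a[:, i], a[:, j])}
            if len(pats) == 4:
                return False
    return True


def test_no_recombination_passes_four_gamete():
    model = base_model(ne=1e4, mu=5e-7)
    for s in range(5):
        gm = simulate_locus(model, {"Tapajos": 8}, 10_000, False, seed=s + 1)
        assert _four_gamete_ok(gm)


def test_same_seed_identical_output():
    model = base_model(ne=1e4, mu=1e-7, r=1e-8)
    a = simulate_locus(model, {"Tapajos": 6}, 10_000, True, seed=9)
    b = simulate_locus(model, {"Tapajos": 6}, 10_000, True, seed=9)
    assert a == b
    la, _ = simulate_dataset(model, 5, 10_000, {"Tapajos": 4}, seed=21)
    lb, _ = simulate_dataset(model, 5, 10_000, {"Tapajos": 4}, seed=21)
    assert all(x == y for x, y in zip(la, lb))


def test_ld_decays_with_distance_under_recombination():
    """Mean r^2 for pairs >10 kb apart < pairs <1 kb apart (200 loci)."""
    model = base_model(ne=2.5e4, mu=4e-8, r=1e-8)
    near, far = [], []
    for s in range(200):
        gm = simulate_locus(model, {"Tapajos": 20}, 20_000, True, seed=s + 1)
        a = gm.alleles.astype(float)
        freqs = a.mean(axis=0)
        ok = (freqs > 0.1) & (freqs < 0.9)
        idx = np.flatnonzero(ok)[:40]
        for u in range(len(idx)):
            for v in range(u + 1, len(idx)):
                i, j = idx[u], idx[v]
                d = gm.positions[j] - gm.positions[i]
                if d >= 1000 and d <= 10_000:
                    continue
                r = np.corrcoef(a[:, i], a[:, j])[0, 1] ** 2
                (near if d < 1000 else far).append(r)
    assert np.mean(far) < np.mean(near)


# ---------------------------------------------------------------------------
# datasets and topology signal
# ---------------------------------------------------------------------------
def test_dataset_labels_and_truth_record():
    model = base_model(ne=1e4, t_recent=1e5, t_deep=2e5)
    loci, rec = simulate_dataset(model, 3, 5_000, {p: 4 for p in POPS}, seed=2)
    assert len(loci) == 3
    for gm in loci:
        assert gm.populations == list(POPS)
    assert rec["topology"] == 1 and rec["ne_Tapajos"] == 1e4


@pytest.mark.parametrize("topology", [1, 2])
def test_dxy_ordering_matches_generating_topology(topology):
    """The most recently diverged pair has the smallest cross-pair D_XY."""
    model = base_model(
        topology=topology, ne=2e4, t_recent=1e5, t_deep=1e6, mu=1e-7
    )
    sums = {("Tapajos", "Xingu"): 0.0, ("Xingu", "Belem"): 0.0, ("Tapajos", "Belem"): 0.0}
    loci, _ = simulate_dataset(model, 100, 5_000, {p: 4 for p in INGROUPS}, seed=5)
    for gm in loci:
        for pair in sums:
            sums[pair] += pair_stats(gm, *pair).dxy
    recent = {1: ("Tapajos", "Xingu"), 2: ("Xingu", "Belem")}[topology]
    others = [p for p in sums if p != recent]
    assert sums[recent] < min(sums[o] for o in others)


# ---------------------------------------------------------------------------
# landscape generator
# ---------------------------------------------------------------------------
def test_landscape_suppression_lowers_diversity(tmp_path):
    base = base_model(ne=1e5, t_recent=1e5, t_deep=2e5, mu=1e-8)
    classes = ["neutral"] * 50 + ["hard"] * 50
    cfg = LandscapeConfig(
        base=base,
        n_windows=100,
        window_length=10_000,
        class_of_window=classes,
        suppression={"neutral": 1.0, "hard": 0.1},
        n_per_pop={"Tapajos": 8},
    )
    windows, r_track, table = generate_landscape(cfg, seed=4)
    pis = np.array(
        [diversity(w, "Tapajos", l_eff=10_000).pi for w in windows]
    )
    neutral, hard = pis[:50], pis[50:]
    stat = sstats.mannwhitneyu(hard, neutral, alternative="less")
    assert hard.mean() < neutral.mean()
    assert stat.pvalue < 0.01
    # truth labels and probability columns round-trip via the track io
    assert (table["true_class"] == classes).all()
    p = tmp_path / "cls.tsv"
    lab = table.rename(columns={"p_hard": "value"})[
        ["chrom", "start", "end", "value"]
    ].assign(n_sites=0)
    write_track(lab, p)
    back = read_track(p)
    np.testing.assert_allclose(back["value"], table["p_hard"])


def test_landscape_validation():
    base = base_model(ne=1e4)
    with pytest.raises(ValueError):
        LandscapeConfig(
            base=base,
            n_windows=2,
            window_length=1000,
            class_of_window=["neutral", "hard"],
            suppression={"neutral": 0.5},
        )
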