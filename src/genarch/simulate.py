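"""Structured-coalescent synthetic-data engine.

Simulates three 4-population isolation-with-migration histories for three
areas of endemism (Tapajos, Xingu, Belem) plus an outgroup:

* topology 1 — (outgroup, (Belem, (Xingu, Tapajos)))
* topology 2 — (outgroup, (Tapajos, (Xingu, Belem)))
* topology 3 — (outgroup, (Xingu, (Tapajos, Belem)))

Constant symmetric migration is allowed between the geographically
adjacent pairs Tapajos<->Xingu and Xingu<->Belem only; the disjunct
Tapajos<->Belem pair never exchanges migrants.  Migration is user-facing
in units of 2Nm migrants per generation and converted internally to the
per-lineage backwards rate m = 2Nm / (2 N_receiver).

Mutations follow an infinite-sites model at a default rate of
2.42e-9 /bp/generation; intralocus recombination is optional.  The
genome-landscape generator emulates sweep-like local diversity
suppression by scaling the local effective size of every deme, emitting
truth labels alongside the genotype data.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import msprime
import numpy as np
import pandas as pd
import tskit

from .io import new_track
from .matrix import GenotypeMatrix

INGROUPS = ("Tapajos", "Xingu", "Belem")
OUTGROUP = "Outgroup"
POPS = INGROUPS + (OUTGROUP,)
ADJACENT_PAIRS = (("Tapajos", "Xingu"), ("Xingu", "Belem"))
FORBIDDEN_PAIR = frozenset(("Tapajos", "Belem"))

#: sweep classes used by the landscape generator, mirroring the five
#: selection regimes a sweep classifier distinguishes
SWEEP_CLASSES = ("hard", "linked_hard", "soft", "linked_soft", "neutral")

MU_DEFAULT = 2.42e-9  # per bp per generation
T_OUTGROUP_DEFAULT = 9.6e6  # generations; deep outgroup split at 1-yr generations


@dataclass
class DemographicModel:
    """One isolation-with-migration history: the unit of simulation.

    ``ne`` maps each deme (the four sampled populations plus
    ``anc_recent``, ``anc_deep`` and ``root``) to a *diploid* effective
    size.  ``mig`` maps the adjacent pairs to 2Nm migrants/generation.
    Times are in generations, with t_recent < t_deep < t_outgroup.
    """

    topology: int
    ne: dict[str, float]
    t_recent: float
    t_deep: float
    t_outgroup: float = T_OUTGROUP_DEFAULT
    mig: dict[tuple[str, str], float] = field(default_factory=dict)
    mu: float = MU_DEFAULT
    r: float = 0.0
    gen_time: float = 1.0

    def __post_init__(self) -> None:
        if self.topology not in (1, 2, 3):
            raise ValueError("topology must be 1, 2 or 3")
        for name in POPS + ("anc_recent", "anc_deep"):
            if self.ne.get(name, 0) <= 0:
                raise ValueError(f"effective size for {name!r} must be > 0")
        self.ne.setdefault("root", self.ne["anc_deep"])
        if not (0 < self.t_recent < self.t_deep < self.t_outgroup):
            raise ValueError("need 0 < t_recent < t_deep < t_outgroup")
        for pair in self.mig:
            if frozenset(pair) == FORBIDDEN_PAIR:
                raise ValueError("no gene flow allowed between Tapajos and Belem")
            if tuple(pair) not in ADJACENT_PAIRS:
                raise ValueError(f"unknown migration pair {pair!r}")
            if self.mig[pair] < 0:
                raise ValueError("migration rate must be >= 0")

    # -- topology bookkeeping -------------------------------------------
    @property
    def recent_pair(self) -> tuple[str, str]:
        return {
            1: ("Xingu", "Tapajos"),
            2: ("Xingu", "Belem"),
            3: ("Tapajos", "Belem"),
        }[self.topology]

    @property
    def deep_single(self) -> str:
        return {1: "Belem", 2: "Tapajos", 3: "Xingu"}[self.topology]

    def replace(self, **kw) -> "DemographicModel":
        return dataclasses.replace(
            self, ne=dict(self.ne), mig=dict(self.mig), **kw
        )

    def scale_ne(self, factor: float) -> "DemographicModel":
        """All deme sizes multiplied by ``factor`` (local-Ne suppression)."""
        m = self.replace()
        m.ne = {k: v * factor for k, v in self.ne.items()}
        return m

    def to_demography(self) -> msprime.Demography:
        dem = msprime.Demography()
        for p in POPS:
            dem.add_population(name=p, initial_size=self.ne[p])
        dem.add_population(name="anc_recent", initial_size=self.ne["anc_recent"])
        dem.add_population(name="anc_deep", initial_size=self.ne["anc_deep"])
        dem.add_population(name="root", initial_size=self.ne["root"])
        for (a, b), mn in self.mig.items():
            if mn > 0:
                # backwards per-lineage rates; symmetric in migrants/generation
                dem.set_migration_rate(a, b, mn / (2 * self.ne[a]))
                dem.set_migration_rate(b, a, mn / (2 * self.ne[b]))
        dem.add_population_split(
            time=self.t_recent, derived=list(self.recent_pair), ancestral="anc_recent"
        )
        dem.add_population_split(
            time=self.t_deep,
            derived=["anc_recent", self.deep_single],
            ancestral="anc_deep",
        )
        dem.add_population_split(
            time=self.t_outgroup, derived=["anc_deep", OUTGROUP], ancestral="root"
        )
        dem.sort_events()
        return dem


@dataclass
class PriorSet:
    """Uniform prior bounds per parameter.

    Keys: ``ne`` (every deme, drawn independently), ``t_recent``,
    ``t_deep`` (lower bound is the drawn t_recent when below it) and
    ``mig`` (each adjacent pair).  Wide defaults bracket the magnitudes
    typical for Amazonian forest birds.
    """

    ne: tuple[float, float] = (5e4, 2e6)
    t_recent: tuple[float, float] = (5e4, 5e5)
    t_deep: tuple[float, float] = (5e4, 2e6)
    mig: tuple[float, float] = (0.0, 4.0)

    def __post_init__(self) -> None:
        for name in ("ne", "t_recent", "t_deep", "mig"):
            lo, hi = getattr(self, name)
            if not (np.isfinite(lo) and np.isfinite(hi)):
                raise ValueError(f"{name}: bounds must be finite")
            if lo > hi:
                raise ValueError(f"{name}: lower bound exceeds upper bound")


def sample_prior(
    priors: PriorSet,
    topology: int,
    seed: int | np.random.Generator,
    mu: float = MU_DEFAULT,
    r: float = 0.0,
    t_outgroup: float = T_OUTGROUP_DEFAULT,
) -> DemographicModel:
    """Draw one model from uniform priors (reproducible under ``seed``)."""
    rng = np.random.default_rng(seed)
    ne = {
        name: rng.uniform(*priors.ne)
        for name in POPS + ("anc_recent", "anc_deep")
    }
    t_recent = rng.uniform(*priors.t_recent)
    lo = max(priors.t_deep[0], t_recent)
    hi = max(priors.t_deep[1], lo)
    t_deep = rng.uniform(lo, hi)
    if t_deep <= t_recent:  # degenerate priors collapse the interval
        t_deep = t_recent * (1 + 1e-9) + 1e-6
    mig = {pair: rng.uniform(*priors.mig) for pair in ADJACENT_PAIRS}
    return DemographicModel(
        topology=topology,
        ne=ne,
        t_recent=t_recent,
        t_deep=t_deep,
        t_outgroup=max(t_outgroup, t_deep * (1 + 1e-9) + 1e-6),
        mig=mig,
        mu=mu,
        r=r,
    )


def model_record(model: DemographicModel) -> dict[str, float]:
    """Flat parameter record for training labels / truth tables."""
    rec: dict[str, float] = {"topology": model.topology}
    for k, v in model.ne.items():
        rec[f"ne_{k}"] = v
    rec["t_recent"] = model.t_recent
    rec["t_deep"] = model.t_deep
    rec["t_outgroup"] = model.t_outgroup
    for (a, b), v in model.mig.items():
        rec[f"mig_{a}_{b}"] = v
    rec["mu"] = model.mu
    rec["r"] = model.r
    return rec


# ---------------------------------------------------------------------------
# simulation proper
# ---------------------------------------------------------------------------
def _sample_sets(n_per_pop: dict[str, int]) -> list[msprime.SampleSet]:
    sets = []
    for pop, n in n_per_pop.items():
        if n < 1:
            raise ValueError(f"sample size for {pop!r} must be >= 1")
        sets.append(msprime.SampleSet(int(n), population=pop, ploidy=1))
    return sets


def _pop_labels(ts: tskit.TreeSequence) -> list[str]:
    names = {p.id: p.metadata.get("name", str(p.id)) for p in ts.populations()}
    return [names[ts.node(u).population] for u in ts.samples()]


def simulate_genealogy(
    model: DemographicModel, n_per_pop: dict[str, int], seed: int
) -> tskit.TreeSequence:
    """One non-recombining genealogy (a single-tree tree sequence).

    Leaves are haploid samples labelled by population; node times are in
    generations.  Under a split at time t, lineages sampled in different
    demes can only coalesce above t unless migration moves them earlier.
    """
    return msprime.sim_ancestry(
        samples=_sample_sets(n_per_pop),
        demography=model.to_demography(),
        sequence_length=1,
        ploidy=2,
        random_seed=_msp_seed(seed),
    )


def _msp_seed(seed: int | np.random.Generator) -> int:
    if isinstance(seed, np.random.Generator):
        return int(seed.integers(1, 2**31 - 1))
    return int(seed) % (2**31 - 2) + 1


def _ts_to_matrix(
    ts: tskit.TreeSequence, L: int, chrom: str = "chr1"
) -> GenotypeMatrix:
    """Genotype matrix with integer 1-based positions on [1, L]."""
    G = ts.genotype_matrix()  # sites x samples
    pos, keep = _int_positions(ts.tables.sites.position, L)
    G = np.clip(G[keep], 0, 1).astype(np.int8)
    return GenotypeMatrix(G.T, pos, L, _pop_labels(ts), chrom)


def _int_positions(raw: np.ndarray, L: int) -> tuple[np.ndarray, np.ndarray]:
    """Continuous [0, L) positions -> strictly increasing 1-based ints.

    Returns (positions, keep-mask); rounding collisions are bumped right
    and the rare site pushed past L is dropped.
    """
    pos = np.floor(raw).astype(np.int64) + 1
    for k in range(1, pos.size):
        if pos[k] <= pos[k - 1]:
            pos[k] = pos[k - 1] + 1
    keep = pos <= L
    return pos[keep], keep


def drop_mutations(
    ts: tskit.TreeSequence,
    mu: float,
    L: int,
    seed: int | np.random.Generator,
    pops: list[str] | None = None,
    chrom: str = "chr1",
) -> GenotypeMatrix:
    """Poisson infinite-sites mutations on a genealogy -> genotypes.

    Each branch receives Poisson(branch_length * mu * L) mutations; each
    mutation falls at a unique uniform position on [0, L) and the derived
    allele (1) labels every leaf below the mutated branch.  Requires a
    single-tree (non-recombining) genealogy.
    """
    if L < 1:
        raise ValueError("locus length must be >= 1")
    if ts.num_trees != 1:
        raise ValueError("drop_mutations needs a single-tree genealogy")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    tree = ts.first()
    samples = ts.samples()
    sample_index = {int(u): i for i, u in enumerate(samples)}
    n = samples.size
    below = np.zeros((ts.num_nodes, n), dtype=bool)
    branch_nodes, branch_len = [], []
    for u in tree.nodes(order="postorder"):
        if tree.is_leaf(u):
            below[u, sample_index[int(u)]] = True
        else:
            for c in tree.children(u):
                below[u] |= below[c]
        if tree.parent(u) != tskit.NULL:
            branch_nodes.append(u)
            branch_len.append(tree.branch_length(u))
    branch_nodes = np.asarray(branch_nodes)
    counts = rng.poisson(np.asarray(branch_len) * mu * L)
    nodes = np.repeat(branch_nodes, counts)
    raw = rng.uniform(0, L, size=nodes.size)
    order = np.argsort(raw, kind="stable")
    nodes, raw = nodes[order], raw[order]
    pos, keep = _int_positions(raw, L)
    alleles = below[nodes[keep]].T.astype(np.int8)
    return GenotypeMatrix(
        alleles, pos, L, pops if pops is not None else _pop_labels(ts), chrom
    )


def simulate_locus(
    model: DemographicModel,
    n_per_pop: dict[str, int],
    L: int,
    with_recombination: bool = False,
    seed: int = 1,
    chrom: str = "chr1",
) -> GenotypeMatrix:
    """Simulate one locus of ``L`` bp (optionally with recombination)."""
    if L < 1:
        raise ValueError("locus length must be >= 1")
    rng = np.random.default_rng(seed)
    ts = msprime.sim_ancestry(
        samples=_sample_sets(n_per_pop),
        demography=model.to_demography(),
        sequence_length=L,
        recombination_rate=model.r if with_recombination else 0.0,
        ploidy=2,
        random_seed=_msp_seed(rng),
    )
    if not with_recombination or model.r == 0:
        return drop_mutations(ts, model.mu, L, rng, chrom=chrom)
    mts = msprime.sim_mutations(
        ts,
        rate=model.mu,
        model=msprime.BinaryMutationModel(),
        discrete_genome=False,
        random_seed=_msp_seed(rng),
    )
    return _ts_to_matrix(mts, L, chrom)


def simulate_dataset(
    model: DemographicModel,
    n_loci: int,
    L: int,
    n_per_pop: dict[str, int],
    seed: int = 1,
    with_recombination: bool = False,
) -> tuple[list[GenotypeMatrix], dict[str, float]]:
    """Independent loci under one model + the truth record that made them."""
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    rng = np.random.default_rng(seed)
    reps = msprime.sim_ancestry(
        samples=_sample_sets(n_per_pop),
        demography=model.to_demography(),
        sequence_length=L,
        recombination_rate=model.r if with_recombination else 0.0,
        ploidy=2,
        num_replicates=n_loci,
        random_seed=_msp_seed(rng),
    )
    fast = not with_recombination or model.r == 0
    mut_seeds = rng.integers(1, 2**31 - 1, size=n_loci)
    out = []
    pops = None
    for i, ts in enumerate(reps):
        if fast:
            if pops is None:
                pops = _pop_labels(ts)
            out.append(
                drop_mutations(
                    ts, model.mu, L, int(mut_seeds[i]), pops=pops, chrom=f"locus{i}"
                )
            )
        else:
            mts = msprime.sim_mutations(
                ts,
                rate=model.mu,
                model=msprime.BinaryMutationModel(),
                discrete_genome=False,
                random_seed=int(mut_seeds[i]),
            )
            out.append(_ts_to_matrix(mts, L, chrom=f"locus{i}"))
    return out, model_record(model)


# ---------------------------------------------------------------------------
# genome landscape with truth labels
# ---------------------------------------------------------------------------
@dataclass
class LandscapeConfig:
    """Recipe for a heterogeneous synthetic genome.

    ``class_of_window`` assigns each window one sweep class;
    ``suppression`` maps classes to local-Ne multipliers in (0, 1] (the
    neutral class must be 1).  ``recomb_map`` optionally sets a
    per-window recombination rate; ``noise`` blurs the emitted class
    probabilities away from the 0/1 truth.
    """

    base: DemographicModel
    n_windows: int
    window_length: int
    class_of_window: list[str]
    suppression: dict[str, float]
    recomb_map: np.ndarray | None = None
    n_per_pop: dict[str, int] | None = None
    noise: float = 0.0

    def __post_init__(self) -> None:
        if len(self.class_of_window) != self.n_windows:
            raise ValueError("one class per window required")
        for c in self.class_of_window:
            if c not in SWEEP_CLASSES:
                raise ValueError(f"unknown sweep class {c!r}")
        for c, m in self.suppression.items():
            if not (0 < m <= 1):
                raise ValueError("suppression multipliers must be in (0, 1]")
        if self.suppression.get("neutral", 1.0) != 1.0:
            raise ValueError("neutral class must have multiplier 1")


def generate_landscape(
    cfg: LandscapeConfig, seed: int = 1
) -> tuple[list[GenotypeMatrix], pd.DataFrame, pd.DataFrame]:
    """Simulate a labelled genome landscape.

    Returns (windows, recombination track, class table).  The class table
    carries one probability column per sweep class (probability 1 for the
    true class, optionally blurred by ``cfg.noise``) plus the truth label.
    """
    rng = np.random.default_rng(seed)
    n_pp = cfg.n_per_pop or {p: 10 for p in POPS}
    wl = cfg.window_length
    windows, rates = [], []
    for i in range(cfg.n_windows):
        klass = cfg.class_of_window[i]
        mult = cfg.suppression.get(klass, 1.0)
        r_i = (
            float(cfg.recomb_map[i]) if cfg.recomb_map is not None else cfg.base.r
        )
        model = cfg.base.scale_ne(mult).replace(r=r_i)
        gm = simulate_locus(
            model,
            n_pp,
            wl,
            with_recombination=r_i > 0,
            seed=int(rng.integers(1, 2**31 - 1)),
            chrom="chr1",
        )
        # shift window onto the chromosome grid
        gm = GenotypeMatrix(
            gm.alleles,
            gm.positions + i * wl,
            cfg.n_windows * wl,
            gm.pops,
            "chr1",
            gm.phased,
        )
        windows.append(gm)
        rates.append(r_i)
    starts = np.arange(cfg.n_windows) * wl
    r_track = new_track("chr1", starts, starts + wl, rates)
    probs = np.zeros((cfg.n_windows, len(SWEEP_CLASSES)))
    for i, klass in enumerate(cfg.class_of_window):
        probs[i, SWEEP_CLASSES.index(klass)] = 1.0
    if cfg.noise > 0:
        probs += rng.uniform(0, cfg.noise, size=probs.shape)
        probs /= probs.sum(axis=1, keepdims=True)
    classes = pd.DataFrame(
        {"chrom": "chr1", "start": starts, "end": starts + wl}
    )
    classes["true_class"] = cfg.class_of_window
    for j, c in enumerate(SWEEP_CLASSES):
        classes[f"p_{c}"] = probs[:, j]
    return windows, r_track, classes
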