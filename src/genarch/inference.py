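"""Simulation-trained model selection and parameter estimation.

Simulated datasets (or single genomic windows) are summarised into fixed-
order feature vectors — means and variances across loci of standard
summary statistics — and fed to small dense neural networks: a softmax
classifier over the three divergence topologies and rectified regressors
for individual demographic parameters.  Networks are 3 x 32 relu layers
(scikit-learn multilayer perceptrons).  Regressors are trained as 10
seeded replicates whose predictions are averaged.

Also here: goodness-of-fit of the simulations to an observation, window
thinning to limit linkage between windows, and selection-class-stratified
parameter estimation with bootstrap standard errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.metrics import accuracy_score, log_loss, mean_absolute_error, r2_score
from sklearn.neural_network import MLPClassifier, MLPRegressor

from .matrix import MISSING, GenotypeMatrix
from .simulate import INGROUPS, SWEEP_CLASSES

# ---------------------------------------------------------------------------
# feature vectors
# ---------------------------------------------------------------------------
_PAIRS = [(0, 1), (1, 2), (0, 2)]  # (T,X), (X,B), (T,B)


def feature_names(pops: tuple[str, ...] = INGROUPS) -> list[str]:
    """Fixed per-locus statistic order underlying every feature vector."""
    names = []
    for stat in ("S", "pi", "theta_w"):
        names += [f"{stat}_{p}" for p in pops] + [f"{stat}_all"]
    pair_tags = [f"{pops[a]}_{pops[b]}" for a, b in _PAIRS]
    names += [f"fst_{t}" for t in pair_tags]
    names += [f"shared_{t}" for t in pair_tags]
    names += [f"private_{p}" for p in pops]
    for (a, b), t in zip(_PAIRS, pair_tags):
        names += [f"private_{t}_{pops[a]}", f"private_{t}_{pops[b]}"]
    names += [f"fixed_{p}" for p in pops]
    names += [f"fixed_{t}" for t in pair_tags]
    return names


_A1_CACHE = np.concatenate([[np.nan], np.cumsum(1.0 / np.arange(1, 4096))])


def _a1(n: np.ndarray) -> np.ndarray:
    return _A1_CACHE[np.clip(n - 1, 0, 4095)]


def locus_stats(gm: GenotypeMatrix, pops: tuple[str, ...] = INGROUPS) -> np.ndarray:
    """Per-locus statistic vector in :func:`feature_names` order."""
    L = gm.seq_length
    der, cal = [], []
    for p in pops:
        a = gm.alleles[gm.haplotype_indices(p)]
        der.append((a == 1).sum(axis=0).astype(float))
        cal.append((a != MISSING).sum(axis=0).astype(float))
    der_all = np.sum(der, axis=0)
    cal_all = np.sum(cal, axis=0)
    out: list[float] = []

    def _seg(d, n):
        return (d > 0) & (d < n) & (n >= 2)

    # S per pop + summed over all haplotypes pooled
    segs = [_seg(d, n) for d, n in zip(der, cal)]
    out += [float(s.sum()) for s in segs]
    seg_all = _seg(der_all, cal_all)
    out.append(float(seg_all.sum()))
    # pi
    for d, n in list(zip(der, cal)) + [(der_all, cal_all)]:
        ok = n >= 2
        with np.errstate(invalid="ignore", divide="ignore"):
            pi = 2.0 * d[ok] * (n[ok] - d[ok]) / (n[ok] * (n[ok] - 1.0))
        out.append(float(pi.sum() / L))
    # Watterson's theta
    for d, n in list(zip(der, cal)) + [(der_all, cal_all)]:
        seg = _seg(d, n)
        out.append(float(np.sum(1.0 / _a1(n[seg].astype(int))) / L) if seg.any() else 0.0)
    # Hudson F_ST per pair (ratio of sums)
    polys = [_seg(d, n) for d, n in zip(der, cal)]
    for a, b in _PAIRS:
        da, na, db, nb = der[a], cal[a], der[b], cal[b]
        ok = (na >= 2) & (nb >= 2)
        pa, pb = da[ok] / na[ok], db[ok] / nb[ok]
        between = pa * (1 - pb) + pb * (1 - pa)
        wa = 2 * da[ok] * (na[ok] - da[ok]) / (na[ok] * (na[ok] - 1))
        wb = 2 * db[ok] * (nb[ok] - db[ok]) / (nb[ok] * (nb[ok] - 1))
        sb = between.sum()
        out.append(float(1 - 0.5 * (wa + wb).sum() / sb) if sb > 0 else 0.0)
    # shared per pair
    for a, b in _PAIRS:
        out.append(float((polys[a] & polys[b]).sum()))
    # private per population (polymorphic only there, among the ingroups)
    for i in range(len(pops)):
        others = np.zeros(gm.n_sites, dtype=bool)
        for j in range(len(pops)):
            if j != i:
                others |= polys[j]
        out.append(float((polys[i] & ~others).sum()))
    # private per pair member
    for a, b in _PAIRS:
        out.append(float((polys[a] & ~polys[b]).sum()))
        out.append(float((polys[b] & ~polys[a]).sum()))
    # fixed derived per population (absent elsewhere)
    for i in range(len(pops)):
        fixed_i = (cal[i] >= 1) & (der[i] == cal[i])
        absent = np.ones(gm.n_sites, dtype=bool)
        for j in range(len(pops)):
            if j != i:
                absent &= (der[j] == 0) & (cal[j] >= 1)
        out.append(float((fixed_i & absent).sum()))
    # oppositely fixed per pair
    for a, b in _PAIRS:
        fa = (cal[a] >= 1) & ((der[a] == 0) | (der[a] == cal[a]))
        fb = (cal[b] >= 1) & ((der[b] == 0) | (der[b] == cal[b]))
        opp = fa & fb & ((der[a] == cal[a]) != (der[b] == cal[b]))
        out.append(float(opp.sum()))
    return np.asarray(out)


def called_individuals(gm: GenotypeMatrix, pop: str, min_called: float = 0.5) -> int:
    """Individuals of ``pop`` with at least ``min_called`` of sites called."""
    idx = gm.haplotype_indices(pop)
    if gm.n_sites == 0:
        return idx.size // 2
    a = gm.alleles[idx]
    frac = (a != MISSING).mean(axis=1)
    ind = frac.reshape(-1, 2).mean(axis=1)
    return int((ind >= min_called).sum())


def featurize(
    loci: list[GenotypeMatrix],
    pops: tuple[str, ...] = INGROUPS,
    min_individuals: int = 3,
) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Mean + variance of per-locus statistics across qualifying loci.

    Loci where any population has fewer than ``min_individuals`` called
    individuals are excluded (their indices are returned, not silently
    dropped).  A single-locus input yields zero variances: the vector is
    then the per-window statistics themselves.
    """
    base = feature_names(pops)
    excluded = []
    rows = []
    for i, gm in enumerate(loci):
        if any(called_individuals(gm, p) < min_individuals for p in pops):
            excluded.append(i)
            continue
        rows.append(locus_stats(gm, pops))
    if not rows:
        raise ValueError("no qualifying loci")
    arr = np.stack(rows)
    vec = np.concatenate([arr.mean(axis=0), arr.var(axis=0)])
    names = [f"mean_{n}" for n in base] + [f"var_{n}" for n in base]
    return vec, names, np.asarray(excluded, dtype=int)


def thin_windows(grid: pd.DataFrame, step: int) -> pd.DataFrame:
    """First window per ``step``-bp interval (limits linkage between
    windows); requires windows shorter than the step."""
    if (grid["end"] - grid["start"]).max() >= step:
        raise ValueError("step must exceed the window length")
    g = grid.sort_values(["chrom", "start"]).copy()
    g["_interval"] = g["start"] // step
    out = g.groupby(["chrom", "_interval"], as_index=False).first()
    return out.drop(columns="_interval").sort_values(["chrom", "start"]).reset_index(
        drop=True
    )


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------
@dataclass
class NetConfig:
    hidden: tuple[int, ...] = (32, 32, 32)
    epochs: int = 1000
    batch_size: int | str = "auto"
    test_fraction: float = 0.25
    validation_fraction: float = 0.05
    learning_rate: float = 3e-3
    tol: float = 1e-7
    patience: int = 50  # epochs without improvement before stopping
    seed: int = 0


@dataclass
class _Standardizer:
    mean: np.ndarray
    std: np.ndarray
    mask: np.ndarray  # features with nonzero training variance

    def __call__(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return (X[:, self.mask] - self.mean[self.mask]) / self.std[self.mask]


def _fit_standardizer(X: np.ndarray) -> _Standardizer:
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    mask = std > 0
    return _Standardizer(mean, np.where(mask, std, 1.0), mask)


def _split(n: int, frac: float, rng: np.random.Generator):
    idx = rng.permutation(n)
    n_test = max(int(round(frac * n)), 1)
    return idx[n_test:], idx[:n_test]


@dataclass
class TrainedClassifier:
    model: MLPClassifier
    standardizer: _Standardizer
    classes: np.ndarray
    n_features: int
    metrics: dict = field(default_factory=dict)
    config: NetConfig = field(default_factory=NetConfig)


def train_classifier(
    X: np.ndarray, y: np.ndarray, cfg: NetConfig | None = None
) -> TrainedClassifier:
    """Softmax topology classifier with a held-out test split.

    Features are standardized from the training split only; zero-variance
    features are dropped from both splits.  Reports held-out accuracy and
    categorical cross-entropy.
    """
    cfg = cfg or NetConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    rng = np.random.default_rng(cfg.seed)
    train, test = _split(len(y), cfg.test_fraction, rng)
    if len(np.unique(y[train])) < len(np.unique(y)):
        raise ValueError("a class is absent from the training split")
    std = _fit_standardizer(X[train])
    clf = MLPClassifier(
        hidden_layer_sizes=cfg.hidden,
        activation="relu",
        solver="adam",
        batch_size=cfg.batch_size,
        max_iter=cfg.epochs,
        learning_rate_init=cfg.learning_rate,
        tol=cfg.tol,
        n_iter_no_change=cfg.patience,
        random_state=cfg.seed,
        validation_fraction=cfg.validation_fraction,
    )
    clf.fit(std(X[train]), y[train])
    proba = clf.predict_proba(std(X[test]))
    metrics = {
        "accuracy": float(accuracy_score(y[test], clf.classes_[proba.argmax(1)])),
        "cross_entropy": float(log_loss(y[test], proba, labels=clf.classes_)),
        "n_train": int(len(train)),
        "n_test": int(len(test)),
    }
    return TrainedClassifier(clf, std, clf.classes_, X.shape[1], metrics, cfg)


def classify(model: TrainedClassifier, obs: np.ndarray) -> np.ndarray:
    """Probability simplex over topologies for one or more observations."""
    obs = np.atleast_2d(np.asarray(obs, dtype=float))
    if obs.shape[1] != model.n_features:
        raise ValueError(
            f"expected {model.n_features} features, got {obs.shape[1]}"
        )
    return model.model.predict_proba(model.standardizer(obs))


@dataclass
class TrainedRegressor:
    models: list[MLPRegressor]
    standardizer: _Standardizer
    n_features: int
    y_scale: float = 1.0
    metrics: dict = field(default_factory=dict)
    config: NetConfig = field(default_factory=NetConfig)

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features:
            raise ValueError(f"expected {self.n_features} features")
        Z = self.standardizer(X)
        preds = np.stack([m.predict(Z) for m in self.models]) * self.y_scale
        return np.clip(preds.mean(axis=0), 0.0, None)


def train_regressor(
    X: np.ndarray,
    y: np.ndarray,
    cfg: NetConfig | None = None,
    n_replicates: int = 10,
) -> TrainedRegressor:
    """Rectified-output parameter regressor, averaged over replicates.

    Targets must be positive (the output is rectified at zero).  Each of
    the ``n_replicates`` networks differs only in its seed; the reported
    prediction is the replicate mean.  Held-out R^2, MAE and the mean
    absolute percentage error are all recorded.
    """
    cfg = cfg or NetConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if (y <= 0).any():
        raise ValueError(
            "non-positive targets with a rectified output; transform first"
        )
    rng = np.random.default_rng(cfg.seed)
    train, test = _split(len(y), cfg.test_fraction, rng)
    std = _fit_standardizer(X[train])
    # scale targets to O(1) for stable optimisation; undo on predict
    y_scale = float(np.mean(y[train]))
    models = []
    for rep in range(n_replicates):
        reg = MLPRegressor(
            hidden_layer_sizes=cfg.hidden,
            activation="relu",
            solver="adam",
            batch_size=cfg.batch_size,
            max_iter=cfg.epochs,
            learning_rate_init=cfg.learning_rate,
            tol=cfg.tol,
            n_iter_no_change=cfg.patience,
            random_state=cfg.seed + 1000 * rep + 1,
        )
        reg.fit(std(X[train]), y[train] / y_scale)
        models.append(reg)
    tr = TrainedRegressor(models, std, X.shape[1], y_scale, {}, cfg)
    pred = tr.predict(X[test])
    mape = float(np.mean(np.abs(pred - y[test]) / y[test]))
    tr.metrics = {
        "r2": float(r2_score(y[test], pred)),
        "mae": float(mean_absolute_error(y[test], pred)),
        "mape": mape,
        "n_train": int(len(train)),
        "n_test": int(len(test)),
    }
    return tr


# ---------------------------------------------------------------------------
# goodness of fit
# ---------------------------------------------------------------------------
def goodness_of_fit(
    sims: np.ndarray,
    obs: np.ndarray,
    n_null: int = 200,
    k: int = 10,
    seed: int = 1,
) -> dict:
    """How well the simulations cover an observed feature vector.

    The statistic is the median distance from the observation to its k
    nearest simulated vectors in standardized feature space; the null
    distribution repeats this for held-out simulated vectors.  Returns the
    p-value (fraction of null >= observed) and 4-component PCA overlay
    coordinates of simulations and observation.
    """
    sims = np.asarray(sims, dtype=float)
    if sims.shape[0] < 100:
        raise ValueError("need at least 100 simulations")
    rng = np.random.default_rng(seed)
    std = _fit_standardizer(sims)
    Z = std(sims)
    z_obs = std(obs)[0]

    def stat(point: np.ndarray, pool: np.ndarray) -> float:
        d = np.linalg.norm(pool - point, axis=1)
        return float(np.median(np.sort(d)[:k]))

    obs_stat = stat(z_obs, Z)
    held = rng.choice(len(Z), size=min(n_null, len(Z)), replace=False)
    null = np.empty(held.size)
    mask = np.ones(len(Z), dtype=bool)
    for i, h in enumerate(held):
        mask[h] = False
        null[i] = stat(Z[h], Z[mask])
        mask[h] = True
    p = float(np.mean(null >= obs_stat))
    pca = PCA(n_components=min(4, Z.shape[1]), random_state=seed)
    sim_pcs = pca.fit_transform(Z)
    obs_pcs = pca.transform(z_obs[None, :])[0]
    return {
        "p_value": p,
        "statistic": obs_stat,
        "null": null,
        "sim_pcs": sim_pcs,
        "obs_pcs": obs_pcs,
    }


# ---------------------------------------------------------------------------
# selection-class-stratified estimates
# ---------------------------------------------------------------------------
def stratified_estimates(
    window_features: np.ndarray,
    class_table: pd.DataFrame,
    regressor: TrainedRegressor,
    threshold: float = 0.7,
    cap: int = 1000,
    seed: int = 1,
    n_boot: int = 500,
) -> pd.DataFrame:
    """Per-selection-class parameter estimates with bootstrap SEs.

    Windows are stratified by their confidently assigned sweep class
    (max probability strictly above ``threshold``); at most ``cap``
    windows per class are used (seeded subsample).  The estimate is the
    mean per-window regressor prediction; the SE is the bootstrap SE of
    that mean.  Empty classes are reported as missing.
    """
    from .windows import assign_classes

    rng = np.random.default_rng(seed)
    assigned = assign_classes(class_table, threshold)
    rows = []
    for klass in SWEEP_CLASSES:
        idx = np.flatnonzero((assigned == klass).values)
        if idx.size == 0:
            rows.append(
                {"class": klass, "n_windows": 0, "estimate": np.nan, "se": np.nan}
            )
            continue
        if idx.size > cap:
            idx = rng.choice(idx, size=cap, replace=False)
        preds = regressor.predict(window_features[idx])
        boots = np.empty(n_boot)
        for bi in range(n_boot):
            take = rng.integers(0, preds.size, size=preds.size)
            boots[bi] = preds[take].mean()
        rows.append(
            {
                "class": klass,
                "n_windows": int(idx.size),
                "estimate": float(preds.mean()),
                "se": float(boots.std(ddof=1)),
            }
        )
    return pd.DataFrame(rows)
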