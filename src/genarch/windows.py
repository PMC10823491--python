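"""Windowing, grid aggregation, quantile subsetting and track joins.

Windows are pandas tables with 0-based half-open ``start``/``end``
coordinates.  Fixed-SNP windows carry their physical span; fixed-length
windows sit on a regular grid.  ``regrid_weighted`` joins variable-width
tracks onto the common analysis grid with overlap-weighted means.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .io import new_track
from .matrix import MISSING, GenotypeMatrix
from .simulate import SWEEP_CLASSES


def snp_windows(
    gm: GenotypeMatrix, n_snps: int, max_missing: float = 0.3
) -> pd.DataFrame:
    """Consecutive non-overlapping windows of exactly ``n_snps`` SNPs.

    A SNP qualifies when its missing-genotype fraction is at most
    ``max_missing``.  The trailing remainder of qualifying SNPs that does
    not fill a window is dropped.  ``first_idx``/``last_idx`` are column
    indices into ``gm``; the physical span is [first SNP - 1, last SNP).
    """
    if n_snps < 2:
        raise ValueError("n_snps must be >= 2")
    miss_frac = (gm.alleles == MISSING).mean(axis=0)
    qual = np.flatnonzero(miss_frac <= max_missing)
    n_win = qual.size // n_snps
    rows = []
    for w in range(n_win):
        idx = qual[w * n_snps : (w + 1) * n_snps]
        rows.append(
            {
                "chrom": gm.chrom,
                "start": int(gm.positions[idx[0]]) - 1,
                "end": int(gm.positions[idx[-1]]),
                "n_sites": n_snps,
                "first_idx": int(idx[0]),
                "last_idx": int(idx[-1]),
            }
        )
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "n_sites", "first_idx", "last_idx"]
    )


def fixed_windows(
    gm: GenotypeMatrix, size: int, min_sites: int = 0
) -> pd.DataFrame:
    """Non-overlapping fixed-size grid over [0, seq_length).

    ``n_sites`` counts SNP columns with at least one called haplotype;
    windows below ``min_sites`` are flagged ``missing``.
    """
    if size <= 0:
        raise ValueError("window size must be > 0")
    starts = np.arange(0, gm.seq_length, size)
    called = (gm.alleles != MISSING).any(axis=0)
    rows = []
    for s in starts:
        e = min(s + size, gm.seq_length)
        in_w = (gm.positions > s) & (gm.positions <= e)
        n = int(np.count_nonzero(called & in_w))
        rows.append(
            {
                "chrom": gm.chrom,
                "start": int(s),
                "end": int(e),
                "n_sites": n,
                "missing": n < min_sites,
            }
        )
    return pd.DataFrame(rows)


def regrid_weighted(track: pd.DataFrame, grid_size: int) -> pd.DataFrame:
    """Overlap-weighted mean of a variable-window track on a fixed grid.

    Each grid cell gets sum(value * overlap_bp) / sum(overlap_bp) over
    input windows with non-missing values; cells without any overlap are
    missing.  Overlapping input windows are rejected (weights would be
    ambiguous).
    """
    if track["chrom"].nunique() > 1:
        raise ValueError("regrid one chromosome at a time")
    t = track.sort_values("start").reset_index(drop=True)
    if (t["start"].values[1:] < t["end"].values[:-1]).any():
        raise ValueError("overlapping input windows")
    chrom = t["chrom"].iloc[0] if len(t) else "chr1"
    n_cells = int(np.ceil(t["end"].max() / grid_size)) if len(t) else 0
    num = np.zeros(n_cells)
    den = np.zeros(n_cells)
    for s, e, v in zip(t["start"], t["end"], t["value"]):
        if not np.isfinite(v):
            continue
        c0, c1 = s // grid_size, (e - 1) // grid_size
        for c in range(c0, c1 + 1):
            ov = min(e, (c + 1) * grid_size) - max(s, c * grid_size)
            num[c] += v * ov
            den[c] += ov
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.where(den > 0, num / np.maximum(den, 1), np.nan)
    starts = np.arange(n_cells) * grid_size
    return new_track(chrom, starts, starts + grid_size, vals, den.astype(int))


def quantile_subset(
    track: pd.DataFrame, fraction: float, tail: str = "upper"
) -> pd.DataFrame:
    """The ceil(fraction * n_valid) windows with the most extreme values.

    Ties are broken by genomic order (chrom, then start), so an all-equal
    track yields the first windows along the genome.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    if tail not in ("upper", "lower"):
        raise ValueError("tail must be 'upper' or 'lower'")
    valid = track[np.isfinite(track["value"].values)].copy()
    if len(valid) == 0:
        raise ValueError("track has no valid values")
    k = int(np.ceil(fraction * len(valid)))
    asc = tail == "lower"
    valid = valid.sort_values(
        ["value", "chrom", "start"], ascending=[asc, True, True]
    )
    return valid.head(k).sort_values(["chrom", "start"]).reset_index(drop=True)


def assign_classes(class_table: pd.DataFrame, threshold: float = 0.7) -> pd.Series:
    """Assigned class per window: argmax class when max prob > threshold
    (strict), else ``low_probability``."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    probs = class_table[[f"p_{c}" for c in SWEEP_CLASSES]].values
    arg = probs.argmax(axis=1)
    conf = probs.max(axis=1) > threshold
    out = np.where(conf, np.array(SWEEP_CLASSES)[arg], "low_probability")
    return pd.Series(out, index=class_table.index, name="assigned_class")


def selection_summary(
    tracks: dict[str, pd.DataFrame],
    threshold: float = 0.7,
    fpr: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Per-species selection-class proportions plus cross-species mean.

    For each species: fraction of windows confidently classified
    (max probability strictly above ``threshold``) and, among those, the
    percentage assigned to nonneutral classes.  The adjusted percentage
    applies the documented heuristic nonneutral * (1 - FPR), treating all
    potential false positives as neutral windows mislabelled as selected.
    The final row is the arithmetic mean across species.
    """
    fpr = fpr or {}
    rows = []
    for species, table in tracks.items():
        assigned = assign_classes(table, threshold)
        confident = assigned != "low_probability"
        n_conf = int(confident.sum())
        nonneutral = confident & (assigned != "neutral")
        pct = 100.0 * nonneutral.sum() / n_conf if n_conf else float("nan")
        f = fpr.get(species, 0.0)
        rows.append(
            {
                "species": species,
                "n_windows": len(table),
                "frac_confident": n_conf / len(table) if len(table) else np.nan,
                "pct_nonneutral": pct,
                "pct_nonneutral_adj": pct * (1 - f),
            }
        )
    df = pd.DataFrame(rows)
    mean_row = {
        "species": "mean",
        "n_windows": df["n_windows"].sum(),
        "frac_confident": df["frac_confident"].mean(),
        "pct_nonneutral": df["pct_nonneutral"].mean(),
        "pct_nonneutral_adj": df["pct_nonneutral_adj"].mean(),
    }
    return pd.concat([df, pd.DataFrame([mean_row])], ignore_index=True)


def track_correlation(a: pd.DataFrame, b: pd.DataFrame) -> dict[str, float]:
    """Pearson correlation between two tracks joined on the same grid."""
    merged = a.merge(b, on=["chrom", "start", "end"], suffixes=("_a", "_b"))
    ok = np.isfinite(merged["value_a"]) & np.isfinite(merged["value_b"])
    x = merged.loc[ok, "value_a"].values
    y = merged.loc[ok, "value_b"].values
    if x.size < 3:
        raise ValueError("fewer than 3 complete pairs")
    r, p = sstats.pearsonr(x, y)
    return {"pearson_r": float(r), "n": int(x.size), "p": float(p)}
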