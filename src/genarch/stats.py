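"""Per-window population-genetic summary statistics.

All statistics tolerate missing data through per-site sample sizes:
frequencies and pairwise comparisons are computed over called haplotypes
only, and sites with fewer than two called haplotypes in a required group
are skipped (and counted).  The effective number of sites ``l_eff``
defaults to the matrix ``seq_length`` — appropriate for simulated loci
where every position without a SNP column is callable and monomorphic —
and can be overridden with the callable-site count for real data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .matrix import MISSING, GenotypeMatrix


@dataclass
class DiversityStats:
    S: int
    pi: float
    theta_w: float
    tajimas_d: float  # NaN when undefined (S == 0 or n < 4)
    n_eff_sites: int


@dataclass
class PairStats:
    dxy: float
    fst: float        # Hudson ratio-of-sums, clamped to [0, 1]
    fst_raw: float    # unclamped (can be <= 0)
    shared: int
    private_a: int
    private_b: int
    fixed: int


@dataclass
class IntrogressionStats:
    abba: float
    baba: float
    d_stat: float  # NaN when abba + baba == 0
    f_dm: float
    n_sites_used: int


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------
def _counts(alleles: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-site (derived count, called count) over the given haplotypes."""
    called = (alleles != MISSING).sum(axis=0)
    derived = (alleles == 1).sum(axis=0)
    return derived.astype(np.int64), called.astype(np.int64)


def _harmonic(n: int) -> float:
    return float(np.sum(1.0 / np.arange(1, n))) if n >= 2 else np.nan


# ---------------------------------------------------------------------------
# within-population diversity
# ---------------------------------------------------------------------------
def diversity(
    gm: GenotypeMatrix, pop: str | None = None, l_eff: int | None = None
) -> DiversityStats:
    """Nucleotide diversity, Watterson's theta and Tajima's D for one pop.

    pi sums the per-site unbiased heterozygosity 2c(n_s - c)/(n_s(n_s-1));
    theta_w applies the harmonic correction a1(n_s) per segregating site;
    Tajima's D uses the standard constants evaluated at the mean called
    sample size over segregating sites (a documented approximation under
    missingness).
    """
    idx = gm.haplotype_indices(pop) if pop is not None else np.arange(gm.n_haplotypes)
    a = gm.alleles[idx]
    L = l_eff if l_eff is not None else gm.seq_length
    der, called = _counts(a)
    ok = called >= 2
    der, called = der[ok], called[ok]
    seg = (der > 0) & (der < called)
    S = int(seg.sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        pi_site = 2.0 * der * (called - der) / (called * (called - 1.0))
    pi = float(pi_site.sum() / L) if L else 0.0
    a1_site = np.array([_harmonic(int(n)) for n in called[seg]])
    theta_w = float(np.sum(1.0 / a1_site) / L) if S and L else 0.0
    n_bar = float(called[seg].mean()) if S else float(called.mean()) if called.size else 0
    d = _tajimas_d(S, pi * L, n_bar)
    return DiversityStats(S, pi, theta_w, d, int(L))


def _tajimas_d(S: int, pi_sum: float, n: float) -> float:
    """Standard Tajima's D from S, the summed pairwise diversity and n."""
    if S == 0 or n < 4:
        return float("nan")
    nn = int(round(n))
    a1 = _harmonic(nn)
    a2 = float(np.sum(1.0 / np.arange(1, nn) ** 2))
    b1 = (nn + 1) / (3.0 * (nn - 1))
    b2 = 2.0 * (nn**2 + nn + 3) / (9.0 * nn * (nn - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (nn + 2) / (a1 * nn) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    if var <= 0:
        return float("nan")
    return float((pi_sum - S / a1) / np.sqrt(var))


# ---------------------------------------------------------------------------
# between-population statistics
# ---------------------------------------------------------------------------
def pair_stats(
    gm: GenotypeMatrix, pop_a: str, pop_b: str, l_eff: int | None = None
) -> PairStats:
    """D_XY, Hudson's F_ST and shared/private/fixed site counts.

    F_ST is the window-level ratio of sums 1 - sum(pi_within)/sum(pi_between)
    with pi_within the average of the two per-site within-population
    diversities — the standard Hudson estimator for windows.
    """
    ia, ib = gm.haplotype_indices(pop_a), gm.haplotype_indices(pop_b)
    a, b = gm.alleles[ia], gm.alleles[ib]
    da, na = _counts(a)
    db, nb = _counts(b)
    ok = (na >= 2) & (nb >= 2)
    if not ok.any() and gm.n_sites:
        if (na >= 1).sum() == 0 or (nb >= 1).sum() == 0:
            raise ValueError("a population has no called haplotypes")
    da, na, db, nb = da[ok], na[ok], db[ok], nb[ok]
    L = l_eff if l_eff is not None else gm.seq_length
    pa, pb = da / na, db / nb
    dxy_site = pa * (1 - pb) + pb * (1 - pa)
    with np.errstate(invalid="ignore"):
        piw_a = 2.0 * da * (na - da) / (na * (na - 1.0))
        piw_b = 2.0 * db * (nb - db) / (nb * (nb - 1.0))
    within = 0.5 * (piw_a + piw_b)
    sum_between = float(dxy_site.sum())
    fst_raw = (
        1.0 - float(within.sum()) / sum_between if sum_between > 0 else float("nan")
    )
    fst = float(np.clip(fst_raw, 0.0, 1.0)) if np.isfinite(fst_raw) else float("nan")
    poly_a = (da > 0) & (da < na)
    poly_b = (db > 0) & (db < nb)
    shared = int((poly_a & poly_b).sum())
    mono_b = ~poly_b
    mono_a = ~poly_a
    private_a = int((poly_a & mono_b).sum())
    private_b = int((poly_b & mono_a).sum())
    fixed = int((mono_a & mono_b & ((da == na) != (db == nb))).sum())
    dxy = sum_between / L if L else 0.0
    return PairStats(dxy, fst, fst_raw, shared, private_a, private_b, fixed)


# ---------------------------------------------------------------------------
# introgression statistics
# ---------------------------------------------------------------------------
def patterson_d(
    gm: GenotypeMatrix, p1: str, p2: str, p3: str, outgroup: str
) -> IntrogressionStats:
    """Frequency-based ABBA-BABA D and the dynamic-donor f_dM.

    The derived allele is polarized so that the outgroup frequency counts
    the '1' allele as ancestral-reference; per-site sample frequencies are
    used without small-sample correction.  Sites where any of the four
    groups has no called haplotype are skipped and counted.
    """
    freqs, used = [], None
    for pop in (p1, p2, p3, outgroup):
        d, n = _counts(gm.alleles[gm.haplotype_indices(pop)])
        ok = n >= 1
        used = ok if used is None else (used & ok)
        with np.errstate(invalid="ignore", divide="ignore"):
            freqs.append(np.where(n > 0, d / np.maximum(n, 1), np.nan))
    f1, f2, f3, f4 = (f[used] for f in freqs)
    abba_site = (1 - f1) * f2 * f3 * (1 - f4)
    baba_site = f1 * (1 - f2) * f3 * (1 - f4)
    abba, baba = float(abba_site.sum()), float(baba_site.sum())
    d_stat = (abba - baba) / (abba + baba) if (abba + baba) > 0 else float("nan")
    num = abba_site - baba_site
    # dynamic-donor denominator: the putative donor replaces both of its
    # copies; P3 donates into P2 when the site term is non-negative and
    # into P1 otherwise (which makes f_dM negative for P1<-P3 flow)
    pd23 = np.maximum(f2, f3)
    den_pos = (1 - f1) * pd23 * pd23 * (1 - f4) - f1 * (1 - pd23) * pd23 * (1 - f4)
    pd13 = np.maximum(f1, f3)
    den_neg = -((1 - pd13) * f2 * pd13 * (1 - f4) - pd13 * (1 - f2) * pd13 * (1 - f4))
    den_site = np.where(num >= 0, den_pos, den_neg)
    den = float(den_site.sum())
    f_dm = float(num.sum() / den) if den != 0 else float("nan")
    return IntrogressionStats(abba, baba, d_stat, f_dm, int(used.sum()))


# ---------------------------------------------------------------------------
# H-scan haplotype-homozygosity statistic
# ---------------------------------------------------------------------------
def hscan_h(gm: GenotypeMatrix, focal_index: int, max_gap: int = 100_000) -> float:
    """Mean pairwise identity-tract length (bp) around one focal SNP.

    For each haplotype pair the tract containing the focal position is
    bounded by the nearest flanking mismatch positions (or the window
    edges, taken as the first and last SNP positions) and truncated at any
    inter-SNP gap larger than ``max_gap``.  Pairs mismatching at the focal
    site contribute 0; pairs with a missing call at the focal site are
    skipped.  Requires phased input.
    """
    if not gm.phased:
        raise ValueError("H-scan requires phased haplotypes")
    if gm.n_sites == 0:
        raise ValueError("no SNPs in window")
    if not 0 <= focal_index < gm.n_sites:
        raise IndexError("focal index out of range")
    pos = gm.positions
    left_edge, right_edge = int(pos[0]), int(pos[-1])
    # truncation points from inter-SNP gaps
    gaps = np.diff(pos)
    total = 0.0
    n_pairs = 0
    a = gm.alleles
    for i in range(gm.n_haplotypes):
        for j in range(i + 1, gm.n_haplotypes):
            hi, hj = a[i], a[j]
            if hi[focal_index] == MISSING or hj[focal_index] == MISSING:
                continue
            n_pairs += 1
            if hi[focal_index] != hj[focal_index]:
                continue
            both = (hi != MISSING) & (hj != MISSING)
            mism = both & (hi != hj)
            mism_idx = np.flatnonzero(mism)
            left_m = mism_idx[mism_idx < focal_index]
            right_m = mism_idx[mism_idx > focal_index]
            lo = int(pos[left_m[-1]]) if left_m.size else left_edge
            hi_b = int(pos[right_m[0]]) if right_m.size else right_edge
            # truncate at oversized gaps between neighbouring SNPs
            for k in range(focal_index - 1, -1, -1):
                if pos[k] < lo:
                    break
                if gaps[k] > max_gap:
                    lo = max(lo, int(pos[k + 1]))
                    break
            for k in range(focal_index, gm.n_sites - 1):
                if pos[k + 1] > hi_b:
                    break
                if gaps[k] > max_gap:
                    hi_b = min(hi_b, int(pos[k]))
                    break
            total += max(hi_b - lo, 0)
    if n_pairs == 0:
        return float("nan")
    return total / n_pairs


# ---------------------------------------------------------------------------
# GC content
# ---------------------------------------------------------------------------
def gc_content(sequence: str) -> float:
    """(G+C)/(A+C+G+T); ambiguity codes excluded from the denominator."""
    s = sequence.upper()
    gc = s.count("G") + s.count("C")
    denom = gc + s.count("A") + s.count("T")
    if denom == 0:
        return float("nan")
    return gc / denom
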