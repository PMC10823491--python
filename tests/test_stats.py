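"""Summary statistics against brute-force oracles and hand computations."""

import numpy as np
import pytest

from genarch.matrix import MISSING, GenotypeMatrix
from genarch.stats import (
    diversity,
    gc_content,
    hscan_h,
    pair_stats,
    patterson_d,
)
from genarch.localpca import ibs_matrix

from conftest import random_matrix


# ---------------------------------------------------------------------------
# brute-force oracles: explicit loops over haplotype pairs / sites
# ---------------------------------------------------------------------------
def oracle_pi(a, L):
    """Mean pairwise differences per bp, looping over all pairs."""
    n = a.shape[0]
    total = 0.0
    for j in range(a.shape[1]):
        col = a[:, j]
        called = col[col != MISSING]
        m = len(called)
        if m < 2:
            continue
        diffs = sum(
            1
            for x in range(m)
            for y in range(x + 1, m)
            if called[x] != called[y]
        )
        total += diffs / (m * (m - 1) / 2)
    return total / L


def oracle_theta_w(a, L):
    total = 0.0
    for j in range(a.shape[1]):
        col = a[:, j]
        called = col[col != MISSING]
        m = len(called)
        if m < 2:
            continue
        k = (called == 1).sum()
        if 0 < k < m:
            total += 1.0 / sum(1.0 / i for i in range(1, m))
    return total / L


def oracle_dxy(a, b, L):
    total = 0.0
    for j in range(a.shape[1]):
        ca = a[:, j][a[:, j] != MISSING]
        cb = b[:, j][b[:, j] != MISSING]
        if len(ca) < 2 or len(cb) < 2:
            continue
        total += sum(int(x != y) for x in ca for y in cb) / (len(ca) * len(cb))
    return total / L


def oracle_hudson_fst(a, b):
    sw, sb = 0.0, 0.0
    for j in range(a.shape[1]):
        ca = a[:, j][a[:, j] != MISSING]
        cb = b[:, j][b[:, j] != MISSING]
        if len(ca) < 2 or len(cb) < 2:
            continue
        pw_a = sum(
            int(ca[x] != ca[y])
            for x in range(len(ca))
            for y in range(x + 1, len(ca))
        ) / (len(ca) * (len(ca) - 1) / 2)
        pw_b = sum(
            int(cb[x] != cb[y])
            for x in range(len(cb))
            for y in range(x + 1, len(cb))
        ) / (len(cb) * (len(cb) - 1) / 2)
        sw += 0.5 * (pw_a + pw_b)
        sb += sum(int(x != y) for x in ca for y in cb) / (len(ca) * len(cb))
    return 1 - sw / sb if sb > 0 else np.nan


def oracle_d_and_fdm(freqs):
    """Site-wise ABBA-BABA and dynamic-donor f_dM on frequency rows."""
    abba = baba = num = den = 0.0
    for p1, p2, p3, p4 in freqs:
        ab = (1 - p1) * p2 * p3 * (1 - p4)
        ba = p1 * (1 - p2) * p3 * (1 - p4)
        abba += ab
        baba += ba
        n = ab - ba
        num += n
        if n >= 0:
            pd = max(p2, p3)
            den += (1 - p1) * pd * pd * (1 - p4) - p1 * (1 - pd) * pd * (1 - p4)
        else:
            pd = max(p1, p3)
            den += -((1 - pd) * p2 * pd * (1 - p4) - pd * (1 - p2) * pd * (1 - p4))
    d = (abba - baba) / (abba + baba) if abba + baba > 0 else np.nan
    return d, (num / den if den != 0 else np.nan)


def oracle_ibs(dos):
    n = dos.shape[0]
    out = np.full((n, n), np.nan)
    for i in range(n):
        out[i, i] = 1.0
        for j in range(i + 1, n):
            vals = [
                1 - abs(dos[i, s] - dos[j, s]) / 2
                for s in range(dos.shape[1])
                if dos[i, s] != MISSING and dos[j, s] != MISSING
            ]
            if vals:
                out[i, j] = out[j, i] = float(np.mean(vals))
    return out


def group_freqs(gm, pops):
    freqs = []
    for j in range(gm.n_sites):
        row = []
        for p in pops:
            col = gm.alleles[gm.haplotype_indices(p), j]
            called = col[col != MISSING]
            row.append((called == 1).mean() if len(called) else np.nan)
        freqs.append(row)
    return [r for r in freqs if not any(np.isnan(v) for v in r)]


@pytest.mark.parametrize("missing_frac", [0.0, 0.2])
def test_statistics_match_bruteforce_on_random_matrices(rng, missing_frac):
    """pi, thetaW, Dxy, Fst, D, f_dM and IBS equal explicit-loop oracles
    on 50 randomized 20-site matrices."""
    pops4 = ["p1"] * 4 + ["p2"] * 4 + ["p3"] * 4 + ["p4"] * 4
    for _ in range(50):
        gm = random_matrix(
            rng, n_hap=16, n_sites=20, missing_frac=missing_frac, pops=pops4
        )
        L = gm.seq_length
        a1 = gm.alleles[gm.haplotype_indices("p1")]
        a2 = gm.alleles[gm.haplotype_indices("p2")]
        d = diversity(gm, "p1")
        assert d.pi == pytest.approx(oracle_pi(a1, L), abs=1e-12)
        assert d.theta_w == pytest.approx(oracle_theta_w(a1, L), abs=1e-12)
        ps = pair_stats(gm, "p1", "p2")
        assert ps.dxy == pytest.approx(oracle_dxy(a1, a2, L), abs=1e-12)
        of = oracle_hudson_fst(a1, a2)
        if np.isfinite(of):
            assert ps.fst_raw == pytest.approx(of, abs=1e-12)
        ist = patterson_d(gm, "p1", "p2", "p3", "p4")
        od, ofdm = oracle_d_and_fdm(group_freqs(gm, ["p1", "p2", "p3", "p4"]))
        if np.isfinite(od):
            assert ist.d_stat == pytest.approx(od, abs=1e-12)
        if np.isfinite(ofdm):
            assert ist.f_dm == pytest.approx(ofdm, abs=1e-12)
        np.testing.assert_allclose(
            ibs_matrix(gm), oracle_ibs(gm.dosages()), atol=1e-12
        )


# ---------------------------------------------------------------------------
# hand-worked examples
# ---------------------------------------------------------------------------
def test_diversity_hand_examples():
    # all identical -> S=0, pi=0, D undefined
    gm = GenotypeMatrix(np.zeros((4, 3), np.int8), [2, 5, 9], 10, ["p"] * 4)
    d = diversity(gm, "p")
    assert d.S == 0 and d.pi == 0 and np.isnan(d.tajimas_d)
    # n=4, one SNP at derived count 2, L=10: pi = (2*2*2/(4*3))/10
    a = np.zeros((4, 1), np.int8)
    a[:2, 0] = 1
    gm = GenotypeMatrix(a, [5], 10, ["p"] * 4)
    assert diversity(gm, "p").pi == pytest.approx(2 * 2 * 2 / (4 * 3) / 10)


def test_pair_stats_hand_examples():
    # reciprocally fixed single site, L=1
    a = np.array([[1], [1], [0], [0]], np.int8)
    gm = GenotypeMatrix(a, [1], 1, ["a", "a", "b", "b"])
    ps = pair_stats(gm, "a", "b")
    assert ps.dxy == 1.0 and ps.fst == 1.0 and ps.fixed == 1
    # 3 sites: both-polymorphic, A-only, opposite-fixed
    a = np.array(
        [[0, 0, 1], [1, 1, 1], [0, 0, 0], [1, 0, 0]], np.int8
    )
    gm = GenotypeMatrix(a, [1, 2, 3], 3, ["a", "a", "b", "b"])
    ps = pair_stats(gm, "a", "b")
    assert (ps.shared, ps.private_a, ps.fixed) == (1, 1, 1)


def test_site_classes_partition_segregating_sites(rng):
    """shared/private/fixed plus residual classes partition all counted
    segregating sites."""
    for _ in range(20):
        gm = random_matrix(rng, n_hap=12, n_sites=30, missing_frac=0.1)
        ps = pair_stats(gm, "popA", "popB")
        a = gm.alleles[gm.haplotype_indices("popA")]
        b = gm.alleles[gm.haplotype_indices("popB")]
        seg_either = 0
        residual = 0
        for j in range(gm.n_sites):
            ca = a[:, j][a[:, j] != MISSING]
            cb = b[:, j][b[:, j] != MISSING]
            if len(ca) < 2 or len(cb) < 2:
                continue
            pa, pb = (ca == 1).mean(), (cb == 1).mean()
            poly_a, poly_b = 0 < pa < 1, 0 < pb < 1
            if poly_a or poly_b:
                seg_either += 1
            elif (pa == 1) != (pb == 1):
                seg_either += 1
            if (poly_a or poly_b) and not (
                (poly_a and poly_b) or (poly_a and not poly_b) or (poly_b and not poly_a)
            ):
                residual += 1
        assert residual == 0
        assert ps.shared + ps.private_a + ps.private_b + ps.fixed == seg_either


def test_patterson_d_symmetry_and_hand_cases():
    # single ABBA site
    a = np.array([[0], [1], [1], [0]], np.int8)
    gm = GenotypeMatrix(a, [1], 1, ["p1", "p2", "p3", "p4"])
    ist = patterson_d(gm, "p1", "p2", "p3", "p4")
    assert (ist.abba, ist.baba, ist.d_stat) == (1.0, 0.0, 1.0)
    # frequencies symmetric in p1 and p2 -> D = 0
    a = np.array([[0, 1], [1, 0], [1, 1], [0, 0]], np.int8)
    gm = GenotypeMatrix(a, [1, 2], 2, ["p1", "p2", "p3", "p4"])
    assert patterson_d(gm, "p1", "p2", "p3", "p4").d_stat == pytest.approx(0.0)


def test_patterson_d_antisymmetric_under_p1_p2_swap(rng):
    pops4 = ["p1"] * 3 + ["p2"] * 3 + ["p3"] * 3 + ["p4"] * 3
    for _ in range(10):
        gm = random_matrix(rng, n_hap=12, n_sites=25, pops=pops4)
        d12 = patterson_d(gm, "p1", "p2", "p3", "p4").d_stat
        d21 = patterson_d(gm, "p2", "p1", "p3", "p4").d_stat
        if np.isfinite(d12):
            assert d12 == pytest.approx(-d21, abs=1e-12)


# ---------------------------------------------------------------------------
# H-scan
# ---------------------------------------------------------------------------
def test_hscan_identical_and_all_different():
    a = np.zeros((4, 5), np.int8)
    gm = GenotypeMatrix(a, [10, 20, 30, 40, 50], 60, ["p"] * 4)
    # identical haplotypes: tract = full window span at any focal site
    for f in range(5):
        assert hscan_h(gm, f) == 50 - 10
    b = np.array([[0, 0, 0], [1, 1, 1]], np.int8)
    gm = GenotypeMatrix(b, [5, 10, 15], 20, ["p"] * 2)
    for f in range(3):
        assert hscan_h(gm, f) == 0.0


def test_hscan_hand_tract_bounds():
    """Pair mismatching only at position 300: focal-200 tract spans the
    window start to 300."""
    a = np.array([[0, 0, 0], [0, 0, 1]], np.int8)
    gm = GenotypeMatrix(a, [100, 200, 300], 400, ["p"] * 2)
    assert hscan_h(gm, 1) == 300 - 100


def test_hscan_gap_truncation_and_unphased_error():
    a = np.zeros((2, 3), np.int8)
    gm = GenotypeMatrix(a, [100, 200, 100_000 + 300], 200_000, ["p"] * 2)
    # gap of 99,900+200 bp > max_gap truncates the right side at pos 200
    assert hscan_h(gm, 1, max_gap=50_000) == 200 - 100
    gm_unphased = GenotypeMatrix(a, [100, 200, 100_300], 200_000, ["p"] * 2, phased=False)
    with pytest.raises(ValueError):
        hscan_h(gm_unphased, 1)


def test_gc_content():
    assert gc_content("GGCC") == 1.0
    assert gc_content("ATAT") == 0.0
    assert gc_content("ANGC") == pytest.approx(2 / 3)
    assert np.isnan(gc_content(""))
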