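import numpy as np
import pytest

from genarch.matrix import MISSING, GenotypeMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20240117)


def random_matrix(
    rng,
    n_hap=10,
    n_sites=20,
    missing_frac=0.0,
    pops=None,
    seq_length=None,
    phased=True,
):
    """Random biallelic matrix with optional missingness; sites guaranteed
    to have at least 2 called haplotypes."""
    a = rng.integers(0, 2, size=(n_hap, n_sites)).astype(np.int8)
    if missing_frac > 0:
        mask = rng.random((n_hap, n_sites)) < missing_frac
        # keep >= 2 called per column
        for j in range(n_sites):
            if mask[:, j].sum() > n_hap - 2:
                mask[rng.choice(n_hap, 2, replace=False), j] = False
        a[mask] = MISSING
    positions = np.sort(rng.choice(np.arange(1, 10 * n_sites + 1), n_sites, replace=False))
    L = seq_length or 10 * n_sites
    pops = pops or ["popA"] * (n_hap // 2) + ["popB"] * (n_hap - n_hap // 2)
    return GenotypeMatrix(a, positions, L, pops, "chr1", phased)


@pytest.fixture
def toy_vcf(tmp_path):
    """20 records: 16 biallelic SNPs, 4 multiallelic; one SNP with 2/3
    samples missing."""
    lines = [
        "##fileformat=VCFv4.2",
        '##FILTER=<ID=PASS,Description="ok">',
        "##contig=<ID=chr1,length=100000>",
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3",
    ]
    pos = 100
    n_bi = 0
    for i in range(20):
        pos += 137
        if i % 5 == 4:  # 4 multiallelic records
            lines.append(
                f"chr1\t{pos}\t.\tA\tC,G\t50\tPASS\t.\tGT\t0/1\t0/2\t1/2"
            )
            continue
        n_bi += 1
        if n_bi == 3:  # heavy missingness site
            gt = "./.\t./.\t0/1"
        else:
            gt = "0/0\t0/1\t1/1"
        lines.append(f"chr1\t{pos}\t.\tA\tT\t50\tPASS\t.\tGT\t{gt}")
    p = tmp_path / "toy.vcf"
    p.write_text("\n".join(lines) + "\n")
    return p
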