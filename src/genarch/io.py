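"""Readers and writers for the standard formats the pipeline touches.

Conventions
-----------
* VCF positions are 1-based; internal window coordinates are 0-based
  half-open; ``GenotypeMatrix.positions`` are 1-based.
* Diploid genotypes are split into two pseudo-haplotypes in VCF sample
  order.  Genuinely phased records keep their phase; unphased records are
  split in the order written and the matrix is flagged ``phased=False``.
* The geno dialect is tab-separated ``chrom  pos  sample1 ...`` with
  diploid calls like ``0|1`` (phased) or ``0/1`` (unphased) and missing
  data written as ``N/N``.
* Window tracks are TSV tables with header
  ``chrom  start  end  value  n_sites`` and 0-based half-open coordinates.
"""

from __future__ import annotations

import io as _io
import logging
import re
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .matrix import MISSING, GenotypeMatrix

logger = logging.getLogger("genarch")

TRACK_COLUMNS = ["chrom", "start", "end", "value", "n_sites"]


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------
def read_vcf(
    path: str | Path,
    region: tuple[str, int, int] | None = None,
    min_presence: float = 0.5,
    pop_of_sample: dict[str, str] | None = None,
) -> GenotypeMatrix:
    """Read biallelic SNPs from a VCF into a :class:`GenotypeMatrix`.

    Multiallelic and non-SNP records are skipped (counted and logged).
    Sites where the fraction of called genotypes is below ``min_presence``
    are dropped.  ``region`` is ``(chrom, start, end)`` with 0-based
    half-open coordinates; a region absent from the file yields an empty
    matrix.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    n_hap = 2 * len(samples)
    cols: list[np.ndarray] = []
    positions: list[int] = []
    skipped = 0
    dropped = 0
    phased = True
    chrom_seen: str | None = None
    max_pos = 0
    for var in vcf:
        if region is not None:
            rc, rs, re_ = region
            if var.CHROM != rc or not (rs < var.POS <= re_):
                continue
        if not var.is_snp or len(var.ALT) != 1:
            skipped += 1
            continue
        if chrom_seen is None:
            chrom_seen = var.CHROM
        gts = var.genotypes  # [[a0, a1, phased], ...]
        col = np.full(n_hap, MISSING, dtype=np.int8)
        for i, g in enumerate(gts):
            a0, a1 = g[0], g[1]
            if not g[2] and (a0 >= 0 or a1 >= 0):
                phased = False
            if a0 >= 0:
                col[2 * i] = a0
            if a1 >= 0:
                col[2 * i + 1] = a1
        called = np.count_nonzero(col != MISSING)
        if called / n_hap < min_presence:
            dropped += 1
            continue
        cols.append(col)
        positions.append(var.POS)
        max_pos = max(max_pos, var.POS)
    if skipped:
        logger.info("read_vcf: skipped %d non-biallelic-SNP records", skipped)
    if dropped:
        logger.info(
            "read_vcf: dropped %d sites below presence %.2f", dropped, min_presence
        )
    alleles = (
        np.stack(cols, axis=1) if cols else np.zeros((n_hap, 0), dtype=np.int8)
    )
    pops = ["pop0"] * n_hap
    if pop_of_sample is not None:
        pops = []
        for s in samples:
            pops.extend([pop_of_sample.get(s, "pop0")] * 2)
    seq_length = region[2] if region is not None else max(max_pos, 1)
    return GenotypeMatrix(
        alleles,
        np.asarray(positions, dtype=np.int64),
        seq_length,
        pops,
        chrom_seen or (region[0] if region else "chr1"),
        phased,
    )


def read_pop_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV ``sample<TAB>population`` -> mapping."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            sample, pop = line.split("\t")[:2]
            out[sample] = pop
    return out


# ---------------------------------------------------------------------------
# geno dialect
# ---------------------------------------------------------------------------
def write_geno(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write diploid genotypes as tab-separated geno text."""
    if gm.n_haplotypes % 2:
        raise ValueError("odd haplotype count: geno format is diploid")
    sep = "|" if gm.phased else "/"
    n_ind = gm.n_haplotypes // 2
    names = [f"ind{i}" for i in range(n_ind)]
    with open(path, "w") as fh:
        fh.write("#CHROM\tPOS\t" + "\t".join(names) + "\n")
        fh.write(
            "##pops="
            + ",".join(gm.pops[::2])
            + f"\tseq_length={gm.seq_length}\tphased={int(gm.phased)}\n"
        )
        for j in range(gm.n_sites):
            calls = []
            for i in range(n_ind):
                a0, a1 = gm.alleles[2 * i, j], gm.alleles[2 * i + 1, j]
                if a0 == MISSING or a1 == MISSING:
                    calls.append("N/N")
                else:
                    calls.append(f"{a0}{sep}{a1}")
            fh.write(f"{gm.chrom}\t{gm.positions[j]}\t" + "\t".join(calls) + "\n")


def read_geno(path: str | Path) -> GenotypeMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        meta = fh.readline().rstrip("\n")
        m = re.match(r"##pops=([^\t]*)\tseq_length=(\d+)\tphased=([01])", meta)
        if m is None:
            raise ValueError("malformed geno metadata line")
        ind_pops = m.group(1).split(",") if m.group(1) else []
        seq_length = int(m.group(2))
        phased = bool(int(m.group(3)))
        n_ind = len(header) - 2
        cols, positions = [], []
        chrom = "chr1"
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            chrom = parts[0]
            positions.append(int(parts[1]))
            col = np.full(2 * n_ind, MISSING, dtype=np.int8)
            for i, call in enumerate(parts[2:]):
                if call == "N/N":
                    continue
                col[2 * i] = int(call[0])
                col[2 * i + 1] = int(call[2])
            cols.append(col)
    alleles = (
        np.stack(cols, axis=1) if cols else np.zeros((2 * n_ind, 0), dtype=np.int8)
    )
    pops = [p for ip in ind_pops for p in (ip, ip)]
    return GenotypeMatrix(
        alleles, np.asarray(positions, np.int64), seq_length, pops, chrom, phased
    )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------
_SYMBOL = {0: "A", 1: "T", MISSING: "N"}
REF_SYMBOL = "A"


def geno_to_fasta(
    gm: GenotypeMatrix, include_monomorphic: bool = True
) -> str:
    """Render haplotypes as a FASTA alignment.

    With ``include_monomorphic`` the alignment spans the full
    ``seq_length`` and positions without a SNP column are filled with a
    fixed reference symbol; otherwise the alignment holds SNP columns only.
    """
    if gm.positions.size and gm.positions[-1] > gm.seq_length:
        raise ValueError("positions exceed seq_length")
    out = _io.StringIO()
    for h in range(gm.n_haplotypes):
        pop = gm.pops[h] if gm.pops else "pop0"
        out.write(f">{pop}:{h}\n")
        if include_monomorphic:
            seq = np.full(gm.seq_length, REF_SYMBOL, dtype="U1")
            for j, pos in enumerate(gm.positions):
                seq[pos - 1] = _SYMBOL[int(gm.alleles[h, j])]
        else:
            seq = np.array(
                [_SYMBOL[int(a)] for a in gm.alleles[h]], dtype="U1"
            )
        out.write("".join(seq) + "\n")
    return out.getvalue()


def write_fasta(gm: GenotypeMatrix, path: str | Path, **kw) -> None:
    Path(path).write_text(geno_to_fasta(gm, **kw))


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------
def read_newick(path_or_text: str | Path) -> list[dendropy.Tree]:
    """Parse one or more Newick trees (branch lengths and polytomies ok)."""
    text = str(path_or_text)
    if "(" not in text:
        text = Path(path_or_text).read_text()
    trees = dendropy.TreeList.get(data=text, schema="newick")
    return list(trees)


def write_newick(trees, path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in trees:
            fh.write(t.as_string(schema="newick").strip() + "\n")


# ---------------------------------------------------------------------------
# ms format
# ---------------------------------------------------------------------------
def write_ms(dataset: list[GenotypeMatrix], path: str | Path, command: str = "genarch") -> None:
    """Write loci in Hudson's ms output format (positions scaled to [0,1))."""
    with open(path, "w") as fh:
        n = dataset[0].n_haplotypes if dataset else 0
        fh.write(f"{command} {n} {len(dataset)}\n0 0 0\n")
        for gm in dataset:
            fh.write("\n//\n")
            fh.write(f"segsites: {gm.n_sites}\n")
            pos = (gm.positions - 1) / max(gm.seq_length, 1)
            fh.write("positions: " + " ".join(f"{p:.6f}" for p in pos) + "\n")
            for h in range(gm.n_haplotypes):
                row = np.where(gm.alleles[h] == MISSING, 0, gm.alleles[h])
                fh.write("".join(str(int(a)) for a in row) + "\n")


def read_ms(path: str | Path, seq_length: int = 1) -> list[GenotypeMatrix]:
    text = Path(path).read_text().splitlines()
    out: list[GenotypeMatrix] = []
    i = 0
    while i < len(text):
        if text[i].strip() == "//":
            i += 1
            seg = int(text[i].split(":")[1])
            i += 1
            if seg > 0:
                rel = np.asarray(
                    [float(x) for x in text[i].split(":")[1].split()]
                )
                i += 1
            else:
                rel = np.zeros(0)
                if i < len(text) and text[i].startswith("positions"):
                    i += 1
            rows = []
            while i < len(text) and re.fullmatch(r"[01]+", text[i].strip()):
                rows.append([int(c) for c in text[i].strip()])
                i += 1
            alleles = (
                np.asarray(rows, dtype=np.int8)
                if rows
                else np.zeros((0, seg), dtype=np.int8)
            )
            pos = np.floor(rel * seq_length).astype(np.int64) + 1
            # enforce strict increase after integer rounding
            for k in range(1, pos.size):
                if pos[k] <= pos[k - 1]:
                    pos[k] = pos[k - 1] + 1
            L = max(seq_length, int(pos[-1]) if pos.size else 1)
            out.append(
                GenotypeMatrix(alleles, pos, L, ["pop0"] * alleles.shape[0])
            )
        else:
            i += 1
    return out


# ---------------------------------------------------------------------------
# Window tracks
# ---------------------------------------------------------------------------
def new_track(chrom, start, end, value, n_sites=None) -> pd.DataFrame:
    """Assemble a WindowTrack table from columns."""
    df = pd.DataFrame(
        {
            "chrom": chrom,
            "start": np.asarray(start, dtype=np.int64),
            "end": np.asarray(end, dtype=np.int64),
            "value": np.asarray(value, dtype=float),
        }
    )
    df["n_sites"] = 0 if n_sites is None else np.asarray(n_sites, dtype=np.int64)
    if (df["start"] >= df["end"]).any():
        raise ValueError("window start must be < end")
    return df[TRACK_COLUMNS]


def write_track(track: pd.DataFrame, path: str | Path) -> None:
    track.loc[:, TRACK_COLUMNS].to_csv(path, sep="\t", index=False, na_rep="NA")


def read_track(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    missing = set(TRACK_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"track file lacks columns {sorted(missing)}")
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    if (df["start"] >= df["end"]).any():
        raise ValueError("window start must be < end")
    return df[TRACK_COLUMNS]
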