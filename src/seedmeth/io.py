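"""Readers and writers for every on-disk format the pipeline touches.

All genomic intervals are 0-based half-open internally.  The single
exception on disk is the per-cytosine report, whose positions stay
1-based (the dialect written by Bismark's cytosine extractor); they are
converted to 0-based on read and back on write.

Formats
-------
- genome: FASTA
- cytosine report: headerless 7-column TSV
  (chrom, pos 1-based, strand, count_methylated, count_unmethylated,
  context, trinucleotide)
- genes: GFF3 (``ID=`` attribute); TEs: BED6 (name column carries the
  class token); small RNA: BED6
- expression: TSV with header ``gene_id`` plus one column per sample
- differential expression: TSV ``gene_id, log2fc, qvalue``
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator, Literal, Sequence

import numpy as np
import pandas as pd

CONTEXTS = ("CG", "CHG", "CHH")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FormatError(ValueError):
    """A file does not conform to its declared dialect."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CytosineRecord:
    """One reference cytosine with its bisulphite read counts.

    ``pos`` is the 0-based position of the C on the forward reference;
    for strand '-' the cytosine is the complement of the reference G at
    that position.  ``trinucleotide`` is read 5'->3' on the C's strand.
    """

    chrom: str
    pos: int
    strand: str
    context: str
    n_meth: int
    n_unmeth: int
    trinucleotide: str = ""

    @property
    def coverage(self) -> int:
        return self.n_meth + self.n_unmeth


@dataclass(frozen=True)
class GenomicFeature:
    """A gene or transposable element with 0-based half-open body."""

    id: str
    ftype: Literal["gene", "TE"]
    chrom: str
    start: int
    end: int
    strand: str = "."
    te_class: str = "n/a"

    def __post_init__(self):
        if self.start >= self.end:
            raise FormatError(
                f"feature {self.id}: start {self.start} >= end {self.end}")
        if (self.te_class == "n/a") != (self.ftype == "gene"):
            raise ValueError("te_class is n/a iff ftype is gene")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GenomeAssembly:
    """Chromosome sequences plus the name of the naturally unmethylated
    chloroplast chromosome used to estimate bisulphite conversion error."""

    chromosomes: dict[str, str]
    chloroplast_name: str

    def __post_init__(self):
        if self.chloroplast_name not in self.chromosomes:
            raise ValueError(
                f"chloroplast {self.chloroplast_name!r} not in assembly")
        for name, seq in self.chromosomes.items():
            if len(seq) < 1:
                raise ValueError(f"chromosome {name} is empty")

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.chromosomes.items()}


# ---------------------------------------------------------------------------
# context classification
# ---------------------------------------------------------------------------

def classify_context(genome: GenomeAssembly, chrom: str, pos: int,
                     strand: str) -> str:
    """Classify the cytosine context at a 1-based position.

    Returns "CG", "CHG", "CHH" or "not-a-C".  H is any base but G; N is
    treated as H (it cannot be called G), and bases missing beyond the
    3' chromosome end are likewise treated as H, so a terminal cytosine
    classifies as CHH unless its immediate neighbour is a G.
    """
    seq = genome.chromosomes.get(chrom)
    if seq is None:
        raise KeyError(f"unknown chromosome {chrom!r}")
    if not 1 <= pos <= len(seq):
        raise IndexError(f"position {pos} outside {chrom} (1..{len(seq)})")
    i = pos - 1
    if strand == "+":
        tri = seq[i:i + 3]
    elif strand == "-":
        tri = reverse_complement(seq[max(0, i - 2):i + 1])
    else:
        raise ValueError(f"bad strand {strand!r}")
    if tri[0] != "C":
        return "not-a-C"
    nxt = tri[1] if len(tri) > 1 else "N"
    nxt2 = tri[2] if len(tri) > 2 else "N"
    if nxt == "G":
        return "CG"
    if nxt2 == "G":
        return "CHG"
    return "CHH"


def trinucleotide_at(genome: GenomeAssembly, chrom: str, pos: int,
                     strand: str) -> str:
    """3-mer starting at the cytosine, on its strand, padded with N."""
    seq = genome.chromosomes[chrom]
    i = pos - 1
    if strand == "+":
        tri = seq[i:i + 3]
    else:
        tri = reverse_complement(seq[max(0, i - 2):i + 1])
    return tri + "N" * (3 - len(tri))


def genome_cytosines(genome: GenomeAssembly, chrom: str) -> pd.DataFrame:
    """All cytosine sites of one chromosome (both strands), 0-based.

    Returns columns pos, strand, context, trinucleotide, sorted by pos
    then strand.  Vectorised equivalent of calling ``classify_context``
    at every C (+) and G (-) of the reference.
    """
    seq = genome.chromosomes[chrom]
    arr = np.frombuffer(seq.encode("ascii"), dtype="S1")
    n = len(arr)
    is_g_code = arr == b"G"

    frames = []
    for strand in "+-":
        if strand == "+":
            pos = np.flatnonzero(arr == b"C")
            nxt = np.full(pos.size, False)
            nxt2 = np.full(pos.size, False)
            m1 = pos + 1 < n
            nxt[m1] = is_g_code[pos[m1] + 1]
            m2 = pos + 2 < n
            nxt2[m2] = is_g_code[pos[m2] + 2]
        else:
            pos = np.flatnonzero(is_g_code)
            # next base 3'->5' on minus strand = previous reference base,
            # complemented: reference C complements to G
            is_c = arr == b"C"
            nxt = np.full(pos.size, False)
            nxt2 = np.full(pos.size, False)
            m1 = pos - 1 >= 0
            nxt[m1] = is_c[pos[m1] - 1]
            m2 = pos - 2 >= 0
            nxt2[m2] = is_c[pos[m2] - 2]
        context = np.where(nxt, "CG", np.where(nxt2, "CHG", "CHH"))
        frames.append(pd.DataFrame({
            "pos": pos, "strand": strand, "context": context}))
    out = pd.concat(frames, ignore_index=True)
    out = out.sort_values(["pos", "strand"], kind="mergesort",
                          ignore_index=True)
    return out


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    chroms: dict[str, list[str]] = {}
    name = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                name = line[1:].split()[0]
                if name in chroms:
                    raise FormatError(f"duplicate sequence {name!r}")
                chroms[name] = []
            elif name is None:
                raise FormatError("sequence data before first FASTA header")
            else:
                chroms[name].append(line.upper())
    return {k: "".join(v) for k, v in chroms.items()}


def write_fasta(path, chromosomes: dict[str, str], width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in chromosomes.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# cytosine reports
# ---------------------------------------------------------------------------

_REPORT_COLS = ["chrom", "pos", "strand", "n_meth", "n_unmeth",
                "context", "trinucleotide"]


def read_cytosine_report(path) -> Iterator[CytosineRecord]:
    """Stream records from a 7-column cytosine report (1-based on disk)."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 7:
                raise FormatError(
                    f"{path}: line {lineno}: expected 7 columns, "
                    f"got {len(fields)}")
            chrom, pos, strand, n_meth, n_unmeth, context, tri = fields
            try:
                pos_i, m_i, u_i = int(pos), int(n_meth), int(n_unmeth)
            except ValueError as exc:
                raise FormatError(
                    f"{path}: line {lineno}: non-integer field: {exc}")
            if context not in CONTEXTS:
                raise FormatError(
                    f"{path}: line {lineno}: bad context {context!r}")
            if strand not in "+-":
                raise FormatError(
                    f"{path}: line {lineno}: bad strand {strand!r}")
            if m_i < 0 or u_i < 0:
                raise FormatError(
                    f"{path}: line {lineno}: negative count")
            yield CytosineRecord(chrom, pos_i - 1, strand, context,
                                 m_i, u_i, tri)


def read_cytosine_table(path) -> pd.DataFrame:
    """Whole cytosine report as a DataFrame (pos converted to 0-based)."""
    df = pd.read_csv(path, sep="\t", header=None, names=_REPORT_COLS,
                     dtype={"chrom": str, "strand": str, "context": str,
                            "trinucleotide": str})
    if df[["pos", "n_meth", "n_unmeth"]].dtypes.apply(
            lambda t: t.kind != "i").any():
        raise FormatError(f"{path}: non-integer pos/count column")
    bad = ~df["context"].isin(CONTEXTS)
    if bad.any():
        raise FormatError(
            f"{path}: line {bad.idxmax() + 1}: bad context "
            f"{df.loc[bad.idxmax(), 'context']!r}")
    df["pos"] -= 1
    return df


def write_cytosine_report(path, table: pd.DataFrame) -> None:
    out = table[_REPORT_COLS].copy()
    out["pos"] += 1
    out.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# features: GFF3 (genes) and BED6 (TEs)
# ---------------------------------------------------------------------------

_TE_CLASS_MAP = {
    "ltr": "LTR", "gypsy": "LTR", "copia": "LTR",
    "line": "LINE",
    "dna": "DNA", "tir": "DNA", "helitron": "DNA", "mite": "DNA",
}


def te_class_from_token(token: str) -> str:
    """Map an annotation class token to {LTR, LINE, DNA, other}."""
    for key, cls in _TE_CLASS_MAP.items():
        if key in token.lower():
            return cls
    return "other"


_ID_RE = re.compile(r"(?:^|;)\s*ID=([^;]+)")


def read_gff3_genes(path) -> list[GenomicFeature]:
    """Genes from GFF3; 1-based inclusive coordinates normalised to
    0-based half-open."""
    feats = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise FormatError(
                    f"{path}: line {lineno}: expected 9 GFF3 columns")
            chrom, _src, ftype, start, end, _score, strand, _frame, attrs = \
                fields
            if ftype != "gene":
                continue
            m = _ID_RE.search(attrs)
            fid = m.group(1) if m else f"gene_{lineno}"
            s, e = int(start) - 1, int(end)
            if s >= e:
                raise FormatError(f"{path}: line {lineno}: empty interval")
            feats.append(GenomicFeature(fid, "gene", chrom, s, e, strand))
    return feats


def write_gff3_genes(path, genes: Sequence[GenomicFeature]) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(f"{g.chrom}\tseedmeth\tgene\t{g.start + 1}\t{g.end}\t"
                     f".\t{g.strand}\t.\tID={g.id}\n")


def read_bed_tes(path) -> list[GenomicFeature]:
    """TEs from BED6 (already 0-based half-open); name column carries the
    class token, mapped case-insensitively to {LTR, LINE, DNA, other}."""
    feats = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 4:
                raise FormatError(
                    f"{path}: line {lineno}: expected >=4 BED columns")
            chrom, start, end, name = fields[:4]
            strand = fields[5] if len(fields) >= 6 else "."
            s, e = int(start), int(end)
            if s >= e:
                raise FormatError(f"{path}: line {lineno}: empty interval")
            feats.append(GenomicFeature(
                name, "TE", chrom, s, e, strand,
                te_class=te_class_from_token(name)))
    return feats


def write_bed_tes(path, tes: Sequence[GenomicFeature]) -> None:
    with open(path, "w") as fh:
        for t in tes:
            fh.write(f"{t.chrom}\t{t.start}\t{t.end}\t{t.id}\t0\t"
                     f"{t.strand}\n")


# ---------------------------------------------------------------------------
# expression / differential expression
# ---------------------------------------------------------------------------

def read_expression(path) -> pd.DataFrame:
    """FPKM table: header ``gene_id`` plus one column per sample."""
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "gene_id":
        raise FormatError(f"{path}: first column must be gene_id")
    samples = df.columns[1:]
    vals = df[samples].to_numpy(dtype=float)
    if not np.isfinite(vals).all() or (vals < 0).any():
        raise FormatError(f"{path}: FPKM must be finite and non-negative")
    return df


def read_de_table(path, min_abs_log2fc: float = 1.0,
                  max_q: float = 0.05) -> pd.DataFrame:
    """Differential-expression table with the two-fold / q<=0.05 filter.

    Adds a ``status`` column: up if log2fc >= 1 and q <= 0.05, down if
    log2fc <= -1 and q <= 0.05, else ns.
    """
    df = pd.read_csv(path, sep="\t")
    missing = {"gene_id", "log2fc", "qvalue"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    df["status"] = "ns"
    sig = df["qvalue"] <= max_q
    df.loc[sig & (df["log2fc"] >= min_abs_log2fc), "status"] = "up"
    df.loc[sig & (df["log2fc"] <= -min_abs_log2fc), "status"] = "down"
    return df


# ---------------------------------------------------------------------------
# small RNA
# ---------------------------------------------------------------------------

def read_smallrna_bed(path, lengths: tuple[int, ...] = (21, 24)
                      ) -> pd.DataFrame:
    """Small-RNA alignments from BED6; read length = interval length.

    Reads whose length is not in ``lengths`` are dropped (structural-RNA
    and size filtering happen upstream of this pipeline).
    """
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "name", "score",
                            "strand"],
                     dtype={"chrom": str, "strand": str})
    df["length"] = df["end"] - df["start"]
    return df[df["length"].isin(lengths)].reset_index(drop=True)


def write_smallrna_bed(path, df: pd.DataFrame) -> None:
    out = df.copy()
    if "name" not in out:
        out["name"] = [f"sr{i}" for i in range(len(out))]
    if "score" not in out:
        out["score"] = 0
    out[["chrom", "start", "end", "name", "score", "strand"]].to_csv(
        path, sep="\t", header=False, index=False)
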