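"""Gene models built from constitutive regions.

Every annotated isoform of a gene is collapsed into three region classes:

* **CERs** (constitutive exonic regions): genomic positions that are exonic
  in *every* isoform of the gene.
* **CIRs** (constitutive intronic regions): positions that are intronic
  (between two exons, inside the transcript span) in every isoform.
* **CJs** (constitutive junctions): boundaries where a CER directly abuts
  a CIR. Positions that are exonic in some isoforms and intronic in others
  belong to neither class, and a CIR edge that touches such ambiguous
  sequence is not a junction.

All coordinates are 0-based half-open (BED convention); GTF input is
converted on read.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "GenomicInterval",
    "GeneModel",
    "consolidate_gene",
    "read_annotation",
    "write_gene_models",
    "EXON_UPSTREAM",
    "INTRON_UPSTREAM",
]

# junction sides, in genomic (left-to-right) orientation
EXON_UPSTREAM = "exon_upstream_of_intron"
INTRON_UPSTREAM = "intron_upstream_of_exon"


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on a strand."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, start: int, end: int) -> bool:
        return self.start < end and start < self.end


@dataclass
class GeneModel:
    """Consolidated constitutive structure of one gene."""

    gene_id: str
    chrom: str
    strand: str
    cers: list[GenomicInterval] = field(default_factory=list)
    cirs: list[GenomicInterval] = field(default_factory=list)
    #: (position, side) pairs; side in {EXON_UPSTREAM, INTRON_UPSTREAM}
    cjs: list[tuple[int, str]] = field(default_factory=list)

    @property
    def cer_total_len(self) -> int:
        return sum(len(iv) for iv in self.cers)

    @property
    def cir_total_len(self) -> int:
        return sum(len(iv) for iv in self.cirs)

    @property
    def usable(self) -> bool:
        """A gene with no constitutive exonic sequence cannot be quantified."""
        return self.cer_total_len > 0

    @property
    def has_cirs(self) -> bool:
        return self.cir_total_len > 0

    @property
    def span(self) -> tuple[int, int]:
        starts = [iv.start for iv in self.cers + self.cirs]
        ends = [iv.end for iv in self.cers + self.cirs]
        if not starts:
            return (0, 0)
        return (min(starts), max(ends))


def _merge(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping/adjacent (start, end) pairs into a sorted disjoint list."""
    ivs = sorted(intervals)
    out: list[tuple[int, int]] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _intersect(a: list[tuple[int, int]], b: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Intersection of two sorted disjoint interval lists."""
    out: list[tuple[int, int]] = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            out.append((s, e))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def _introns(exons: list[tuple[int, int]]) -> list[tuple[int, int]]:
    return [
        (exons[k][1], exons[k + 1][0])
        for k in range(len(exons) - 1)
        if exons[k][1] < exons[k + 1][0]
    ]


def consolidate_gene(
    isoforms: Sequence[Sequence[tuple[int, int]]],
    gene_id: str,
    chrom: str = "chr1",
    strand: str = "+",
) -> GeneModel:
    """Collapse a gene's isoforms into CERs, CIRs and CJs.

    Parameters
    ----------
    isoforms
        One exon list per isoform; each exon is a (start, end) pair in
        0-based half-open coordinates. Exons within an isoform must be
        non-overlapping.
    gene_id, chrom, strand
        Identity of the gene; all isoforms are assumed to share them.

    Returns
    -------
    GeneModel
        CER = positions exonic in every isoform; CIR = positions intronic
        in every isoform; CJ = each boundary where a CER abuts a CIR.
    """
    if not isoforms:
        raise ValueError(f"gene {gene_id}: no isoforms")

    exon_sets = [_merge(iso) for iso in isoforms]
    for iso in exon_sets:
        if not iso:
            raise ValueError(f"gene {gene_id}: isoform with no exons")

    cer = exon_sets[0]
    cir = _introns(exon_sets[0])
    for iso in exon_sets[1:]:
        cer = _intersect(cer, iso)
        cir = _intersect(cir, _introns(iso))

    cer_starts = {s for s, _ in cer}
    cer_ends = {e for _, e in cer}
    cjs: list[tuple[int, str]] = []
    for s, e in cir:
        if s in cer_ends:
            cjs.append((s, EXON_UPSTREAM))
        if e in cer_starts:
            cjs.append((e, INTRON_UPSTREAM))
    cjs.sort()

    return GeneModel(
        gene_id=gene_id,
        chrom=chrom,
        strand=strand,
        cers=[GenomicInterval(chrom, s, e, strand) for s, e in cer],
        cirs=[GenomicInterval(chrom, s, e, strand) for s, e in cir],
        cjs=cjs,
    )


# ---------------------------------------------------------------------------
# annotation readers


def _read_gtf(path: str) -> dict[str, list[list[tuple[int, int]]]]:
    import pyranges as pr

    gr = pr.read_gtf(path)
    df = gr.df
    df = df[df["Feature"] == "exon"]
    if df.empty:
        raise ValueError(f"{path}: no exon features found")
    if "gene_id" not in df.columns or "transcript_id" not in df.columns:
        raise ValueError(f"{path}: exon lines lack gene_id/transcript_id attributes")

    genes: dict[str, dict[str, list[tuple[int, int]]]] = {}
    meta: dict[str, tuple[str, str]] = {}
    for row in df.itertuples(index=False):
        gid, tid = row.gene_id, row.transcript_id
        genes.setdefault(gid, {}).setdefault(tid, []).append((int(row.Start), int(row.End)))
        meta[gid] = (str(row.Chromosome), str(row.Strand))
    out = {}
    for gid, txs in genes.items():
        out[gid] = (meta[gid], [sorted(ex) for ex in txs.values()])
    return out


def _read_bed12(path: str) -> dict:
    """BED12: one line per isoform, name column carries the gene identifier."""
    genes: dict[str, tuple[tuple[str, str], list]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"{path}:{lineno}: expected 12 BED columns, got {len(f)}")
            try:
                chrom, start = f[0], int(f[1])
                name, strand = f[3], f[5]
                nblocks = int(f[9])
                sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: unparseable BED12 line ({exc})") from None
            if len(sizes) != nblocks or len(offsets) != nblocks:
                raise ValueError(f"{path}:{lineno}: blockCount inconsistent with block lists")
            exons = [(start + o, start + o + sz) for o, sz in zip(offsets, sizes)]
            if name not in genes:
                genes[name] = ((chrom, strand), [])
            genes[name][1].append(exons)
    return genes


def read_annotation(path: str) -> dict[str, GeneModel]:
    """Read a GTF or BED12 annotation into per-gene models.

    Genes whose isoforms share no common exonic base are kept but carry
    ``usable = False`` (a warning is emitted). The returned mapping is
    ordered by (chrom, span start, gene_id).
    """
    lower = str(path).lower()
    if lower.endswith((".gtf", ".gff", ".gtf.gz")):
        raw = _read_gtf(path)
    elif lower.endswith(".bed"):
        raw = _read_bed12(path)
    else:
        raise ValueError(f"unrecognised annotation format: {path}")

    models = {}
    for gid, ((chrom, strand), isoforms) in raw.items():
        m = consolidate_gene(isoforms, gid, chrom=chrom, strand=strand)
        if not m.usable:
            warnings.warn(f"gene {gid}: isoforms share no constitutive exonic base")
        models[gid] = m
    ordered = sorted(models.values(), key=lambda m: (m.chrom, m.span[0], m.gene_id))
    return {m.gene_id: m for m in ordered}


def write_gene_models(models: dict[str, GeneModel], prefix: str) -> None:
    """Serialize models to ``<prefix>.cer.bed``, ``.cir.bed`` and ``.cj.bed``."""
    with open(f"{prefix}.cer.bed", "w") as cer_fh, open(
        f"{prefix}.cir.bed", "w"
    ) as cir_fh, open(f"{prefix}.cj.bed", "w") as cj_fh:
        for m in models.values():
            for iv in m.cers:
                cer_fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{m.gene_id}\t0\t{iv.strand}\n")
            for iv in m.cirs:
                cir_fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{m.gene_id}\t0\t{iv.strand}\n")
            for pos, side in m.cjs:
                cj_fh.write(f"{m.chrom}\t{pos}\t{pos + 1}\t{m.gene_id};{side}\t0\t{m.strand}\n")
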