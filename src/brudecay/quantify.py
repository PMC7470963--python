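"""Read counting over constitutive regions and intron-retention indices.

The intron retention index (IRI) of a gene is the ratio of the read
density over its constitutive intronic regions (CIRs) to the read density
over its constitutive exonic regions (CERs):

    IRI = (cir_reads / cir_len) / (cer_reads / cer_len)

Because an intron-retained transcript contributes reads to both region
classes while a spliced transcript contributes only to exons, the gene
IRI estimates the fraction of intron-retained transcripts in the labeled
pool. Junction reads provide an orthogonal view: exon–exon (EE) reads are
spliced-only evidence, exon–intron (EI) reads retained-only evidence; a
read qualifies only if it overlaps each side of the junction by at least
``min_overlap`` aligned bases (default 8).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Literal

from intervaltree import IntervalTree

from .gene_models import GeneModel

__all__ = [
    "ReadAlignment",
    "RegionQuant",
    "IRIValue",
    "count_regions",
    "classify_junction_read",
    "gene_iri",
    "genome_wide_iri",
    "rpkm",
    "polii_level",
    "read_bed_reads",
    "read_bam_reads",
    "quants_to_frame",
]

Strandedness = Literal["forward", "reverse", "unstranded"]


@dataclass(frozen=True)
class ReadAlignment:
    """One (possibly gapped) aligned read: sorted, non-overlapping blocks."""

    chrom: str
    blocks: tuple[tuple[int, int], ...]
    strand: str = "+"
    unique: bool = True

    @property
    def start(self) -> int:
        return self.blocks[0][0]

    @property
    def end(self) -> int:
        return self.blocks[-1][1]


@dataclass
class RegionQuant:
    """Per-gene, per-library counts over constitutive regions."""

    gene_id: str
    cer_reads: int = 0
    cir_reads: int = 0
    x_ee: int = 0
    x_ei: int = 0
    cer_len: int = 0
    cir_len: int = 0
    library_size: int = 0


@dataclass(frozen=True)
class IRIValue:
    gene_id: str
    iri: float
    defined: bool


def _strand_match(read_strand: str, gene_strand: str, mode: Strandedness) -> bool:
    if mode == "unstranded":
        return True
    if mode == "forward":
        return read_strand == gene_strand
    return read_strand != gene_strand  # reverse (dUTP-style)


def classify_junction_read(
    read: ReadAlignment, model: GeneModel, min_overlap: int = 8
) -> tuple[str, int | None]:
    """Classify a read against a gene's constitutive junctions.

    Returns ``("EI", pos)`` if one contiguous block spans a CJ at ``pos``
    with >= ``min_overlap`` aligned bases on each side; ``("EE", start)``
    if two consecutive blocks exactly bridge one CIR (gap edges matching
    the CIR edges) with >= ``min_overlap`` bases in each flanking CER;
    otherwise ``("none", None)``. EE and EI are mutually exclusive for a
    single read: a contiguous block cannot also leave a gap.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    if read.chrom != model.chrom:
        return ("none", None)

    # EI: contiguous block covering a junction point with flanks on both sides
    for pos, _side in model.cjs:
        for bs, be in read.blocks:
            if bs <= pos - min_overlap and be >= pos + min_overlap:
                return ("EI", pos)

    # EE: gap between consecutive blocks exactly spans one CIR
    cer_starts = {iv.start: iv for iv in model.cers}
    cer_ends = {iv.end: iv for iv in model.cers}
    for k in range(len(read.blocks) - 1):
        (ls, le), (rs, re) = read.blocks[k], read.blocks[k + 1]
        for cir in model.cirs:
            if le == cir.start and rs == cir.end:
                left = cer_ends.get(cir.start)
                right = cer_starts.get(cir.end)
                if left is None or right is None:
                    continue
                left_ov = le - max(ls, left.start)
                right_ov = min(re, right.end) - rs
                if left_ov >= min_overlap and right_ov >= min_overlap:
                    return ("EE", cir.start)
    return ("none", None)


def _region_tree(models: dict[str, GeneModel]) -> dict[str, IntervalTree]:
    """chrom -> tree of (start, end) -> (gene_id, region_class)."""
    trees: dict[str, IntervalTree] = {}
    for m in models.values():
        tree = trees.setdefault(m.chrom, IntervalTree())
        for iv in m.cers:
            tree[iv.start: iv.end] = (m.gene_id, "cer")
        for iv in m.cirs:
            tree[iv.start: iv.end] = (m.gene_id, "cir")
    return trees


def count_regions(
    reads: Iterable[ReadAlignment],
    models: dict[str, GeneModel],
    strandedness: Strandedness = "reverse",
    min_overlap: int = 8,
) -> dict[str, RegionQuant]:
    """Count reads over CERs/CIRs and classify junction reads.

    A read contributes to a gene's CER (CIR) count if any block overlaps
    that region set by >= 1 base on the selected strand; it is counted at
    most once per region class per gene, so a read overlapping both region
    classes increments both. Only uniquely mapped reads are counted.
    ``library_size`` is the total number of unique reads seen.
    """
    quants = {
        gid: RegionQuant(
            gene_id=gid,
            cer_len=m.cer_total_len,
            cir_len=m.cir_total_len,
        )
        for gid, m in models.items()
    }
    trees = _region_tree(models)
    library_size = 0
    sense = antisense = 0

    for read in reads:
        if not read.unique:
            continue
        library_size += 1
        tree = trees.get(read.chrom)
        if tree is None:
            continue
        hits: set[tuple[str, str]] = set()
        for bs, be in read.blocks:
            for hit in tree.overlap(bs, be):
                hits.add(hit.data)
        genes_hit = {gid for gid, _ in hits}
        for gid in genes_hit:
            gene = models[gid]
            if read.strand == gene.strand:
                sense += 1
            else:
                antisense += 1
            if not _strand_match(read.strand, gene.strand, strandedness):
                continue
            q = quants[gid]
            if (gid, "cer") in hits:
                q.cer_reads += 1
            if (gid, "cir") in hits:
                q.cir_reads += 1
            kind, _ = classify_junction_read(read, gene, min_overlap=min_overlap)
            if kind == "EE":
                q.x_ee += 1
            elif kind == "EI":
                q.x_ei += 1

    total = sense + antisense
    if total > 0:
        antisense_frac = antisense / total
        expect_antisense = strandedness == "reverse"
        if not expect_antisense and antisense_frac > 0.9:
            warnings.warn(
                f"{antisense_frac:.0%} of overlapping reads are antisense to "
                "annotation; strandedness may be misconfigured"
            )
        if expect_antisense and antisense_frac < 0.1 and strandedness != "unstranded":
            warnings.warn(
                f"only {antisense_frac:.0%} of overlapping reads are antisense; "
                "library may be forward-stranded"
            )

    for q in quants.values():
        q.library_size = library_size
    return quants


def gene_iri(q: RegionQuant) -> IRIValue | None:
    """Gene-level IRI: CIR read density over CER read density.

    Returns ``None`` for genes without CIRs (IRI not applicable, as
    distinct from undefined). ``defined`` is False when the exonic
    density is zero.
    """
    if q.cir_len == 0:
        return None
    if q.cer_len == 0:
        raise ValueError(f"gene {q.gene_id}: CER length is zero")
    if q.cer_reads == 0:
        return IRIValue(q.gene_id, float("nan"), defined=False)
    iri = (q.cir_reads / q.cir_len) / (q.cer_reads / q.cer_len)
    return IRIValue(q.gene_id, iri, defined=True)


def genome_wide_iri(quants: Iterable[RegionQuant]) -> float:
    """Pooled IRI over all genes having both CERs and CIRs.

    Ratio of the genome-wide intronic read density (total CIR reads over
    total CIR length) to the genome-wide exonic read density.
    """
    cir_reads = cer_reads = cir_len = cer_len = 0
    for q in quants:
        if q.cer_len == 0 or q.cir_len == 0:
            continue
        cir_reads += q.cir_reads
        cer_reads += q.cer_reads
        cir_len += q.cir_len
        cer_len += q.cer_len
    if cir_len == 0:
        raise ValueError("no gene with both CERs and CIRs")
    if cer_reads == 0:
        raise ValueError("zero total exonic reads; genome-wide IRI undefined")
    return (cir_reads / cir_len) / (cer_reads / cer_len)


def rpkm(count: float, region_len: int, library_size: int) -> float:
    """Reads per kilobase of region per million library reads."""
    if region_len <= 0:
        raise ValueError("region length must be positive")
    if library_size <= 0:
        raise ValueError("library size must be positive")
    return count / (region_len / 1000.0) / (library_size / 1e6)


def polii_level(
    reads: Iterable[ReadAlignment],
    enriched: list[tuple[str, int, int]],
    model: GeneModel,
) -> float:
    """Pol II occupancy of a gene body, restricted to ChIP-enriched regions.

    Counts reads whose blocks overlap the intersection of the gene body
    with pre-called enriched regions, expressed as RPKM over the gene-body
    length with the library size taken as the total number of reads inside
    enriched regions (anywhere in the genome).
    """
    if not enriched:
        warnings.warn("empty enriched-region set; all Pol II levels are 0")
        return 0.0
    tree_all: dict[str, IntervalTree] = {}
    for chrom, s, e in enriched:
        tree_all.setdefault(chrom, IntervalTree())[s:e] = True

    span_s, span_e = model.span
    gene_len = span_e - span_s
    if gene_len <= 0:
        return 0.0

    in_gene = 0
    in_enriched_total = 0
    for read in reads:
        if not read.unique:
            continue
        tree = tree_all.get(read.chrom)
        if tree is None:
            continue
        hit = any(tree.overlap(bs, be) for bs, be in read.blocks)
        if not hit:
            continue
        in_enriched_total += 1
        if read.chrom == model.chrom and any(
            bs < span_e and span_s < be for bs, be in read.blocks
        ):
            in_gene += 1
    if in_enriched_total == 0:
        return 0.0
    return rpkm(in_gene, gene_len, in_enriched_total)


# ---------------------------------------------------------------------------
# read-alignment input


def read_bed_reads(path: str) -> Iterator[ReadAlignment]:
    """Read alignments from 6-column BED; lines sharing a name are one
    read's blocks (gapped alignment)."""
    pending_name: str | None = None
    pending: list[tuple[str, int, int, str]] = []

    def flush() -> ReadAlignment | None:
        if not pending:
            return None
        chrom = pending[0][0]
        strand = pending[0][3]
        blocks = tuple(sorted((s, e) for _, s, e, _ in pending))
        return ReadAlignment(chrom=chrom, blocks=blocks, strand=strand)

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            chrom, s, e, name = f[0], int(f[1]), int(f[2]), f[3]
            strand = f[5] if len(f) > 5 else "+"
            if name != pending_name and pending:
                out = flush()
                pending.clear()
                if out:
                    yield out
            pending_name = name
            pending.append((chrom, s, e, strand))
    out = flush()
    if out:
        yield out


def read_bam_reads(path: str, min_mapq: int = 1) -> Iterator[ReadAlignment]:
    """Read alignments from a coordinate-sorted BAM (uniquely mapped only)."""
    import pysam

    with pysam.AlignmentFile(path, "rb") as bam:
        for aln in bam:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            unique = aln.mapping_quality >= min_mapq
            if aln.has_tag("NH") and aln.get_tag("NH") > 1:
                unique = False
            blocks = tuple(aln.get_blocks())
            if not blocks:
                continue
            yield ReadAlignment(
                chrom=aln.reference_name,
                blocks=blocks,
                strand="-" if aln.is_reverse else "+",
                unique=unique,
            )


def quants_to_frame(quants: dict[str, RegionQuant]):
    """Tabulate per-gene quantifications with IRI and CER RPKM columns."""
    import pandas as pd

    rows = []
    for gid, q in quants.items():
        iri = gene_iri(q) if q.cir_len > 0 else None
        rows.append(
            {
                "gene_id": gid,
                "cer_reads": q.cer_reads,
                "cir_reads": q.cir_reads,
                "x_ee": q.x_ee,
                "x_ei": q.x_ei,
                "cer_len": q.cer_len,
                "cir_len": q.cir_len,
                "iri": iri.iri if iri is not None else float("nan"),
                "rpkm": rpkm(q.cer_reads, q.cer_len, q.library_size)
                if q.cer_len > 0 and q.library_size > 0
                else float("nan"),
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")
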