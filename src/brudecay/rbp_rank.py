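"""Ranking RNA-binding proteins by differential 3'UTR binding.

Genes whose spliced-transcript decay rate drops most on activation are
candidates for protection by a stabilizing RBP. Upregulated genes are
ranked by the relative stability change (beta_S,act - beta_S,rest) /
beta_S,rest; the k most-stabilized and k least-stabilized genes form two
sets, each gene receives a per-RBP binding score (sum of eCLIP peak
signal values falling in its 3'UTR), and a one-sided Wilcoxon rank-sum
test asks whether binding is higher among the stabilized set. RBPs are
ranked by ascending p-value.

A polyA-proximal metaprofile summarizes where a given RBP binds relative
to the polyA cleavage site, as binding events per kilobase per million
binding events.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .compare import distribution_test

__all__ = [
    "BindingProfile",
    "read_narrowpeak",
    "select_gene_sets",
    "score_rbp",
    "rank_rbps",
    "replicate_consensus",
    "polya_profile",
]

NARROWPEAK_COLUMNS = [
    "chrom", "start", "end", "name", "score", "strand",
    "signalValue", "pValue", "qValue", "peak",
]


@dataclass
class BindingProfile:
    """Binding density around polyA sites.

    ``edges`` are bp offsets relative to the cleavage site (negative =
    upstream); ``density`` is events per kilobase per million total
    binding events, one value per bin.
    """

    edges: np.ndarray
    density: np.ndarray
    n_events_total: int
    n_events_in_window: int


def read_narrowpeak(path: str) -> pd.DataFrame:
    """Load an ENCODE narrowPeak (BED6+4) file."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=NARROWPEAK_COLUMNS, usecols=range(10),
    )
    return df


def select_gene_sets(
    rel_change: dict[str, float] | pd.Series, k: int = 1000
) -> tuple[list[str], list[str]]:
    """Split genes into the k most- and k least-stabilized.

    ``rel_change`` maps gene id to the relative stability change;
    the most negative values are the most stabilized (largest decay-rate
    decrease). Ties break by gene id so the split is deterministic. If
    fewer than 2k genes are available, k shrinks symmetrically with a
    warning.
    """
    s = pd.Series(rel_change).dropna()
    if len(s) < 2 * k:
        k = len(s) // 2
        warnings.warn(f"fewer than 2k genes with defined stability change; using k={k}")
    if k == 0:
        raise ValueError("no genes with defined relative stability change")
    order = sorted(s.index, key=lambda g: (s[g], g))
    most_stabilized = order[:k]
    least_stabilized = order[-k:]
    return most_stabilized, least_stabilized


def _utr_tree(utr3: dict[str, list[tuple[str, int, int]]]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for gid, ivs in utr3.items():
        for chrom, s, e in ivs:
            trees.setdefault(chrom, IntervalTree())[s:e] = gid
    return trees


def score_rbp(
    peaks: pd.DataFrame,
    utr3: dict[str, list[tuple[str, int, int]]],
    most_stabilized: list[str],
    least_stabilized: list[str],
) -> tuple[pd.Series, float]:
    """Per-gene 3'UTR binding scores for one RBP and the rank-sum p-value.

    The binding score of a gene is the sum of narrowPeak ``signalValue``
    over all peaks overlapping the gene's 3'UTR (union over isoforms);
    genes without peaks score 0. The returned p-value is one-sided for
    binding in the most-stabilized set exceeding the least-stabilized set.
    An RBP with no 3'UTR peaks at all gets p = 1.
    """
    genes = list(most_stabilized) + list(least_stabilized)
    scores = pd.Series(0.0, index=genes)
    trees = _utr_tree({g: utr3[g] for g in genes if g in utr3})
    for row in peaks.itertuples(index=False):
        tree = trees.get(row.chrom)
        if tree is None:
            continue
        for hit in tree.overlap(row.start, row.end):
            scores[hit.data] += float(row.signalValue)
    a = scores[list(most_stabilized)].to_numpy()
    b = scores[list(least_stabilized)].to_numpy()
    if scores.sum() == 0:
        return scores, 1.0
    p = distribution_test(a, b, alternative="greater")
    return scores, p


def rank_rbps(
    rbp_peaks: dict[str, pd.DataFrame],
    utr3: dict[str, list[tuple[str, int, int]]],
    most_stabilized: list[str],
    least_stabilized: list[str],
) -> pd.DataFrame:
    """Rank RBPs by ascending differential-binding p-value.

    Returns a table ``rbp_id, n_genes_scored, p, rank`` (rank 1 = most
    significant; ties by p break by rbp_id)."""
    rows = []
    for rbp_id, peaks in rbp_peaks.items():
        scores, p = score_rbp(peaks, utr3, most_stabilized, least_stabilized)
        rows.append(
            {"rbp_id": rbp_id, "n_genes_scored": int((scores > 0).sum()), "p": p}
        )
    df = pd.DataFrame(rows).sort_values(["p", "rbp_id"]).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def replicate_consensus(
    peaks_rep1: pd.DataFrame, peaks_rep2: pd.DataFrame, min_overlap: int = 1
) -> pd.DataFrame:
    """Peaks of replicate 1 overlapping any replicate-2 peak by
    >= ``min_overlap`` bp (the shared/consensus peak set)."""
    if len(peaks_rep1) == 0 or len(peaks_rep2) == 0:
        warnings.warn("empty replicate peak set; consensus is empty")
        return peaks_rep1.iloc[0:0]
    trees: dict[str, IntervalTree] = {}
    for row in peaks_rep2.itertuples(index=False):
        trees.setdefault(row.chrom, IntervalTree())[row.start: row.end] = True
    keep = []
    for i, row in enumerate(peaks_rep1.itertuples(index=False)):
        tree = trees.get(row.chrom)
        if tree is None:
            continue
        ovs = tree.overlap(row.start, row.end)
        if any(min(row.end, ov.end) - max(row.start, ov.begin) >= min_overlap for ov in ovs):
            keep.append(i)
    return peaks_rep1.iloc[keep].reset_index(drop=True)


def polya_profile(
    peaks: pd.DataFrame,
    polya_sites: list[tuple[str, int, str]],
    window: int = 1000,
    bin_size: int = 50,
) -> BindingProfile:
    """Metaprofile of peak midpoints around polyA cleavage sites.

    Each peak is assigned (by midpoint) to its nearest same-strand polyA
    site; the signed offset is measured 5'->3' along the transcript, so
    negative offsets lie inside the 3'UTR. Density is events per kilobase
    per million total binding events (total = all peaks supplied, whether
    or not they fall inside the window).
    """
    if window % bin_size != 0:
        raise ValueError("window must be a multiple of bin_size")
    edges = np.arange(-window, window + bin_size, bin_size)
    counts = np.zeros(len(edges) - 1)
    by_chrom: dict[str, list[tuple[int, str]]] = {}
    for chrom, pos, strand in polya_sites:
        by_chrom.setdefault(chrom, []).append((pos, strand))
    for chrom in by_chrom:
        by_chrom[chrom].sort()

    n_total = len(peaks)
    n_in = 0
    for row in peaks.itertuples(index=False):
        mid = (row.start + row.end) // 2
        peak_strand = getattr(row, "strand", ".")
        sites = by_chrom.get(row.chrom, [])
        if peak_strand in ("+", "-"):  # unstranded peaks match either strand
            sites = [s for s in sites if s[1] == peak_strand]
        if not sites:
            continue
        pos, site_strand = min(sites, key=lambda s: abs(mid - s[0]))
        # signed offset measured 5'->3' along the transcript
        offset = mid - pos if site_strand == "+" else pos - mid
        if offset < -window or offset >= window:
            continue
        counts[int((offset + window) // bin_size)] += 1
        n_in += 1

    if n_total == 0:
        density = counts
    else:
        density = counts / (bin_size / 1000.0) / (n_total / 1e6)
    return BindingProfile(
        edges=edges, density=density,
        n_events_total=n_total, n_events_in_window=n_in,
    )
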