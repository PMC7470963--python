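"""Condition contrasts: stability, splicing-efficiency and transcription
changes, regulatory-mode categorization, and the associated global tests.

A gene upregulated on activation can get there by transcribing more
(Pol II occupancy / nascent Bru-seq RPKM up), splicing more efficiently
(PST up), or degrading more slowly (beta_S down). Default cutoffs:
|delta beta_S| >= 0.2 /h for (de)stabilization, delta PST >= 0.05,
fold change > 1.5 for transcription measures, and upregulation requires
steady-state fold > 1.5 with RPKM > 1 in at least one condition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "Thresholds",
    "GeneComparison",
    "compare_fits",
    "categorize",
    "overlap_summary",
    "distribution_test",
    "enrichment_test",
]


@dataclass(frozen=True)
class Thresholds:
    """Categorization cutoffs; defaults follow the analysis conventions above."""

    delta_beta_s: float = 0.2  # /h, absolute difference
    delta_pst: float = 0.05  # absolute difference in fraction
    fold: float = 1.5  # strict > for transcription measures
    min_rpkm: float = 1.0  # expression floor for "upregulated"


@dataclass
class GeneComparison:
    """Per-gene quantities contrasted between resting and activated states."""

    gene_id: str
    beta_s_rest: float | None = None
    beta_s_act: float | None = None
    pst_rest: float | None = None
    pst_act: float | None = None
    polii_rest: float | None = None
    polii_act: float | None = None
    brurpkm_rest: float | None = None
    brurpkm_act: float | None = None
    rpkm_rest: float | None = None  # steady-state expression
    rpkm_act: float | None = None
    categories: set[str] = field(default_factory=set)

    @property
    def delta_beta_s(self) -> float | None:
        if self.beta_s_rest is None or self.beta_s_act is None:
            return None
        return self.beta_s_act - self.beta_s_rest

    @property
    def rel_stability_change(self) -> float | None:
        """(beta_S,act - beta_S,rest) / beta_S,rest; negative = stabilized."""
        if self.beta_s_rest is None or self.beta_s_act is None:
            return None
        if self.beta_s_rest == 0:
            return None
        return (self.beta_s_act - self.beta_s_rest) / self.beta_s_rest


def _fold(a: float | None, b: float | None) -> float | None:
    """Fold change b/a on normalized values; zero denominators excluded."""
    if a is None or b is None or a <= 0:
        return None
    return b / a


def categorize(cmp: GeneComparison, thresholds: Thresholds = Thresholds()) -> set[str]:
    """Assign regulatory-mode categories; missing inputs leave a category
    undetermined (absent) rather than false."""
    cats: set[str] = set()
    d = cmp.delta_beta_s
    if d is not None:
        if d <= -thresholds.delta_beta_s:
            cats.add("stabilized")
        if d >= thresholds.delta_beta_s:
            cats.add("destabilized")
    if cmp.pst_rest is not None and cmp.pst_act is not None:
        if cmp.pst_act - cmp.pst_rest >= thresholds.delta_pst:
            cats.add("pst_up")
    pf = _fold(cmp.polii_rest, cmp.polii_act)
    if pf is not None and pf > thresholds.fold:
        cats.add("polii_up")
    bf = _fold(cmp.brurpkm_rest, cmp.brurpkm_act)
    if bf is not None and bf > thresholds.fold:
        cats.add("transcription_up")
    sf = _fold(cmp.rpkm_rest, cmp.rpkm_act)
    if sf is not None and sf > thresholds.fold:
        if max(cmp.rpkm_rest or 0.0, cmp.rpkm_act or 0.0) > thresholds.min_rpkm:
            cats.add("upregulated")
    cmp.categories = cats
    return cats


def compare_fits(
    fits_rest: dict,
    fits_act: dict,
    pst_rest: dict[str, float] | None = None,
    pst_act: dict[str, float] | None = None,
    thresholds: Thresholds = Thresholds(),
) -> dict[str, GeneComparison]:
    """Build per-gene comparisons from two conditions' mixture DecayFits."""
    pst_rest = pst_rest or {}
    pst_act = pst_act or {}
    out: dict[str, GeneComparison] = {}
    for gid in sorted(set(fits_rest) & set(fits_act)):
        fr, fa = fits_rest[gid], fits_act[gid]
        cmp = GeneComparison(
            gene_id=gid,
            beta_s_rest=fr.beta_s,
            beta_s_act=fa.beta_s,
            pst_rest=pst_rest.get(gid),
            pst_act=pst_act.get(gid),
        )
        categorize(cmp, thresholds)
        out[gid] = cmp
    return out


def overlap_summary(sets: dict[str, set[str]]) -> dict:
    """Three-way Venn cell counts over a common gene universe.

    ``sets`` maps three category names (e.g. stability / pst / polii) to
    gene-id sets. Returns the 7 intersection cells plus the exclusive
    members of the first-listed set (the "stability-only" genes when the
    stability set is given first).
    """
    if len(sets) != 3:
        raise ValueError("overlap_summary expects exactly 3 sets")
    (na, a), (nb, b), (nc, c) = sets.items()
    cells = {
        f"{na}_only": a - b - c,
        f"{nb}_only": b - a - c,
        f"{nc}_only": c - a - b,
        f"{na}&{nb}": (a & b) - c,
        f"{na}&{nc}": (a & c) - b,
        f"{nb}&{nc}": (b & c) - a,
        f"{na}&{nb}&{nc}": a & b & c,
    }
    return {
        "counts": {k: len(v) for k, v in cells.items()},
        "cells": cells,
        "first_set_exclusive": sorted(a - b - c),
        "union_size": len(a | b | c),
    }


def distribution_test(
    values_a,
    values_b,
    alternative: str = "less",
) -> float:
    """One-sided Mann–Whitney U p-value.

    ``alternative="less"`` tests whether A is stochastically smaller than
    B. Exact null distribution for combined n <= 20 without ties; normal
    approximation with tie correction otherwise. Two identical constant
    samples are degenerate and return p = 1.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValueError("each sample needs n >= 1")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0
    has_ties = len(np.unique(pooled)) < pooled.size
    if a.size + b.size <= 20 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative=alternative, method=method)
    return float(res.pvalue)


def enrichment_test(
    set_hits: int, set_size: int, background_hits: int, background_size: int
) -> float:
    """One-sided Fisher exact test (hypergeometric upper tail) for
    over-representation of hits in the set relative to the background."""
    for v in (set_hits, set_size, background_hits, background_size):
        if v < 0 or not isinstance(v, (int, np.integer)):
            raise ValueError("counts must be non-negative integers")
    if set_hits > set_size or background_hits > background_size:
        raise ValueError("hits exceed set sizes")
    table = [
        [set_hits, set_size - set_hits],
        [background_hits, background_size - background_hits],
    ]
    _, p = stats.fisher_exact(table, alternative="greater")
    return float(p)
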