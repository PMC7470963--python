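"""Housekeeping-gene normalization across chase-time libraries.

In a pulse-chase experiment the labeled RNA pool shrinks over the chase,
but each library is sequenced to an arbitrary depth, so raw RPKM values
are not comparable across time points. Genes with half-lives much longer
than the chase window are effectively stable over it; rescaling each
library so that the summed CER read count of such a housekeeping set is
constant puts all time points on one axis:

    factor = 1,000,000 / (total CER read counts of housekeeping genes)

Normalized expression is reads-per-kilobase times the factor,

    X(t) = [cer_reads / (cer_len/1000)] x factor(t),

i.e. RPKM in which the per-million scaling is anchored to housekeeping
reads rather than to the library total. This makes X invariant under a
uniform depth inflation of one library (counts and housekeeping counts
inflate together and cancel), which per-library-total RPKM x factor is
not; when all libraries have equal depth the two definitions differ
only by a global constant that the decay fit's free intercept absorbs.
The IRI is a ratio of densities within one library and passes through
unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "HOUSEKEEPING_GENES",
    "NormalizationFactor",
    "TimeCourse",
    "normalization_factor",
    "build_timecourse",
]

#: Default housekeeping set: transcripts validated as stable in both
#: resting and activated T cells. Overridable wherever it is consumed.
HOUSEKEEPING_GENES = (
    "B2M",
    "GAPDH",
    "HPRT1",
    "ACTB",
    "SDHA",
    "HSP90AB1",
    "YWHAB",
    "YWHAQ",
    "PTMA",
)


@dataclass(frozen=True)
class NormalizationFactor:
    library_id: str
    hk_cer_total: float
    factor: float
    missing: tuple[str, ...] = ()


@dataclass
class TimeCourse:
    """Per-gene normalized expression and IRI across ordered chase times."""

    gene_id: str
    condition: str
    times: np.ndarray  # hours, strictly increasing
    x: np.ndarray  # normalized CER RPKM
    iri: np.ndarray  # dimensionless; NaN where undefined/not applicable
    x_ee: np.ndarray = field(default_factory=lambda: np.array([]))
    x_ei: np.ndarray = field(default_factory=lambda: np.array([]))
    flags: set[str] = field(default_factory=set)


def normalization_factor(
    quants: pd.DataFrame,
    hk_genes=HOUSEKEEPING_GENES,
    library_id: str = "",
) -> NormalizationFactor:
    """Compute a library's normalization factor from housekeeping CER counts.

    ``quants`` is a per-gene table indexed by gene id with a ``cer_reads``
    column. Missing housekeeping genes are tolerated up to one third of
    the set and reported by id.
    """
    hk_genes = list(hk_genes)
    present = [g for g in hk_genes if g in quants.index]
    missing = tuple(g for g in hk_genes if g not in quants.index)
    if len(missing) > len(hk_genes) / 3:
        raise ValueError(
            f"library {library_id!r}: {len(missing)}/{len(hk_genes)} "
            f"housekeeping genes missing: {', '.join(missing)}"
        )
    total = float(quants.loc[present, "cer_reads"].sum())
    if total <= 0:
        raise ValueError(
            f"library {library_id!r}: zero housekeeping CER reads; cannot normalize"
        )
    return NormalizationFactor(
        library_id=library_id, hk_cer_total=total, factor=1_000_000.0 / total,
        missing=missing,
    )


def build_timecourse(
    libraries: dict[str, pd.DataFrame],
    manifest: list[dict],
    factors: dict[str, NormalizationFactor] | None = None,
    hk_genes=HOUSEKEEPING_GENES,
    condition: str | None = None,
    include_t0: bool = False,
) -> dict[str, TimeCourse]:
    """Assemble per-gene time courses from per-library quantification tables.

    Parameters
    ----------
    libraries
        library_id -> per-gene table (index gene_id; columns ``cer_reads``,
        ``cer_len``, ``iri``, and optionally ``x_ee``/``x_ei``).
    manifest
        One dict per library with keys ``library_id``, ``condition``,
        ``time`` (hours).
    factors
        Precomputed normalization factors; computed from ``hk_genes``
        when omitted.
    condition
        Restrict to one condition (required if the manifest mixes several).
    include_t0
        Keep the 0 h library. By default decay is measured from the 0.5 h
        and 2 h points only, so 0 h libraries are normalized but dropped.
    """
    entries = [e for e in manifest if condition is None or e["condition"] == condition]
    if not entries:
        raise ValueError(f"no libraries for condition {condition!r}")
    conds = {e["condition"] for e in entries}
    if len(conds) > 1:
        raise ValueError(f"manifest mixes conditions {sorted(conds)}; pass condition=")
    cond = conds.pop()

    if not include_t0:
        entries = [e for e in entries if float(e["time"]) > 0.0]
    entries = sorted(entries, key=lambda e: float(e["time"]))
    times = np.array([float(e["time"]) for e in entries])
    if len(set(times)) != len(times):
        raise ValueError("duplicate chase times in manifest")

    if factors is None:
        factors = {
            e["library_id"]: normalization_factor(
                libraries[e["library_id"]], hk_genes, library_id=e["library_id"]
            )
            for e in entries
        }

    universe: set[str] = set()
    for e in entries:
        universe |= set(libraries[e["library_id"]].index)

    out: dict[str, TimeCourse] = {}
    for gid in sorted(universe):
        x = np.zeros(len(entries))
        iri = np.full(len(entries), np.nan)
        x_ee = np.zeros(len(entries))
        x_ei = np.zeros(len(entries))
        flags: set[str] = set()
        for i, e in enumerate(entries):
            lib = libraries[e["library_id"]]
            f = factors[e["library_id"]].factor
            if gid not in lib.index:
                flags.add("missing_library")
                continue
            row = lib.loc[gid]
            if row["cer_len"] > 0:
                x[i] = float(row["cer_reads"]) / (float(row["cer_len"]) / 1000.0) * f
            iri[i] = float(row["iri"])
            if "x_ee" in lib.columns:
                x_ee[i] = float(row["x_ee"]) * f
                x_ei[i] = float(row["x_ei"]) * f
        out[gid] = TimeCourse(
            gene_id=gid, condition=cond, times=times, x=x, iri=iri,
            x_ee=x_ee, x_ei=x_ei, flags=flags,
        )
    return out
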