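"""End-to-end orchestration: libraries -> normalization -> decay fits.

These helpers tie the per-module operations together for the common case
of a two-condition, multi-time-point BruChase-seq experiment, whether
the per-library tables come from the synthetic generator, from read-level
quantification, or from files on disk.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
import yaml

from . import decay, normalize
from .compare import GeneComparison, Thresholds, categorize
from .gene_models import read_annotation
from .normalize import HOUSEKEEPING_GENES, TimeCourse, build_timecourse
from .quantify import count_regions, quants_to_frame, read_bed_reads

__all__ = [
    "ConditionResult",
    "analyze_condition",
    "fits_to_frame",
    "compare_conditions",
    "load_fixture",
]


class ConditionResult:
    """Per-condition decay analysis: time courses, fits and derived stats."""

    def __init__(
        self,
        condition: str,
        timecourses: dict[str, TimeCourse],
        fits_mixture: dict[str, decay.DecayFit],
        fits_one: dict[str, decay.DecayFit],
        fits_junction: dict[str, decay.DecayFit],
        pst: dict[str, float | None],
        expressed: set[str],
    ):
        self.condition = condition
        self.timecourses = timecourses
        self.fits_mixture = fits_mixture
        self.fits_one = fits_one
        self.fits_junction = fits_junction
        self.pst = pst
        self.expressed = expressed


def analyze_condition(
    libraries: dict[str, pd.DataFrame],
    manifest: list[dict],
    condition: str,
    hk_genes=HOUSEKEEPING_GENES,
    include_t0: bool = False,
) -> ConditionResult:
    """Normalize one condition's libraries and fit all three decay models."""
    tcs = build_timecourse(
        libraries, manifest, hk_genes=hk_genes, condition=condition,
        include_t0=include_t0,
    )
    fits_mixture = {g: decay.fit_mixture(tc) for g, tc in tcs.items()}
    fits_one = {g: decay.fit_one_component(tc) for g, tc in tcs.items()}
    fits_junction = {g: decay.fit_mixture_junction(tc) for g, tc in tcs.items()}
    pst = {g: decay.pst(tc) for g, tc in tcs.items()}
    expressed = decay.expressed_gene_filter(tcs, fits_mixture)
    return ConditionResult(
        condition, tcs, fits_mixture, fits_one, fits_junction, pst, expressed
    )


def fits_to_frame(result: ConditionResult) -> pd.DataFrame:
    """One row per gene: mixture rates, one-component rate, intercepts,
    spliced-component half-life, PST and flags."""
    rows = []
    for gid in sorted(result.fits_mixture):
        fm = result.fits_mixture[gid]
        fo = result.fits_one[gid]
        fj = result.fits_junction[gid]
        rows.append(
            {
                "gene_id": gid,
                "beta_s": fm.beta_s,
                "beta_ir": fm.beta_ir,
                "beta_onecomp": fo.beta,
                "beta_s_junction": fj.beta_s,
                "beta_ir_junction": fj.beta_ir,
                "x0_s": fm.x0_s,
                "x0_ir": fm.x0_ir,
                "halflife_s": fm.half_life,
                "pst": result.pst.get(gid),
                "expressed": gid in result.expressed,
                "flags": ",".join(sorted(fm.flags)),
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")


def compare_conditions(
    rest: ConditionResult,
    act: ConditionResult,
    thresholds: Thresholds = Thresholds(),
    expressed_only: bool = True,
) -> dict[str, GeneComparison]:
    """Per-gene condition contrast over genes measurable in both states."""
    genes = set(rest.fits_mixture) & set(act.fits_mixture)
    if expressed_only:
        genes &= rest.expressed & act.expressed
    out: dict[str, GeneComparison] = {}
    for gid in sorted(genes):
        cmp = GeneComparison(
            gene_id=gid,
            beta_s_rest=rest.fits_mixture[gid].beta_s,
            beta_s_act=act.fits_mixture[gid].beta_s,
            pst_rest=rest.pst.get(gid),
            pst_act=act.pst.get(gid),
        )
        categorize(cmp, thresholds)
        out[gid] = cmp
    return out


def load_fixture(fixture_dir: str) -> tuple[dict[str, pd.DataFrame], list[dict]]:
    """Load a written fixture (manifest.yaml + per-library tables).

    Libraries with a ``reads`` entry are re-quantified from the read BED
    against the fixture annotation; otherwise the stored count tables are
    used directly.
    """
    with open(os.path.join(fixture_dir, "manifest.yaml")) as fh:
        meta = yaml.safe_load(fh)
    manifest = meta["libraries"]
    models = None
    libraries: dict[str, pd.DataFrame] = {}
    for entry in manifest:
        if "reads" in entry:
            if models is None:
                models = read_annotation(os.path.join(fixture_dir, "annotation.gtf"))
            reads = read_bed_reads(os.path.join(fixture_dir, entry["reads"]))
            quants = count_regions(
                reads, models, strandedness=entry.get("strandedness", "reverse")
            )
            libraries[entry["library_id"]] = quants_to_frame(quants)
        else:
            df = pd.read_csv(
                os.path.join(fixture_dir, entry["counts"]), sep="\t", index_col=0
            )
            libraries[entry["library_id"]] = df
    return libraries, manifest
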