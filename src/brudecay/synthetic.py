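"""Synthetic pulse-chase cohorts with known decay kinetics.

Each simulated gene carries a labeled transcript pool that is a mixture
of spliced and intron-retained species. With the chase starting at
t0 = 0.5 h, the pools evolve as

    N_S(t)  = alpha * (1 - p_ir) * exp(-beta_s  * (t - t0))
    N_IR(t) = alpha * p_ir       * exp(-beta_ir * (t - t0))

where alpha is the transcription rate (arbitrary expression units) and
p_ir the intron-retained fraction of labeled transcripts at t0. Reads
land on constitutive exons in proportion to (N_S + N_IR) x CER length,
on constitutive introns in proportion to N_IR x CIR length, and on
junction footprints (exon–exon from N_S, exon–intron from N_IR), with
Poisson counting noise; each library is scaled to its sequencing depth,
which deliberately erases absolute pool sizes the way real sequencing
does — the housekeeping genes (stable, intron-retention-free, highly
expressed) carry the information the normalization step needs to restore
them.

Default parameter regime: beta_s ~ U(0.1, 1.0)/h, beta_ir ~ U(0.5, 3.0)/h
(retained transcripts degrade faster), p_ir ~ Beta(2, 8) (mean 0.2),
alpha ~ logU(1, 100). Activation stabilizes the spliced pool of 70% of
genes (beta_s x 0.6), improves splicing of 30% (p_ir x 0.5) and doubles
transcription of 30%, leaving beta_ir untouched.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .gene_models import GeneModel, GenomicInterval, consolidate_gene
from .normalize import HOUSEKEEPING_GENES
from .quantify import ReadAlignment

__all__ = [
    "CohortParams",
    "Cohort",
    "SimulatedLibrary",
    "simulate_cohort",
    "simulate_library",
    "write_fixture",
]


@dataclass(frozen=True)
class CohortParams:
    """Generative settings for a synthetic cohort."""

    n_genes: int = 500
    # kinetic parameter distributions (rates in /h)
    beta_s_range: tuple[float, float] = (0.1, 1.0)
    beta_ir_range: tuple[float, float] = (0.5, 3.0)
    p_ir_beta: tuple[float, float] = (2.0, 8.0)
    alpha_log10_range: tuple[float, float] = (0.0, 2.0)
    # gene structure (bp); single-isoform genes
    n_introns_range: tuple[int, int] = (2, 8)
    exon_len_range: tuple[int, int] = (100, 400)
    intron_len_range: tuple[int, int] = (500, 3000)
    # housekeeping controls
    n_housekeeping: int = 9
    hk_beta_s: float = 0.005
    hk_alpha: float = 100.0
    # activation shifts
    stabilized_fraction: float = 0.7
    stabilization_factor: float = 0.6
    splicing_up_fraction: float = 0.3
    splicing_factor: float = 0.5  # p_ir multiplier for splicing-improved genes
    transcription_up_fraction: float = 0.3
    transcription_factor: float = 2.0
    # chase geometry
    t0: float = 0.5  # h; start of the measurable chase
    # read model
    read_length: int = 100
    min_overlap: int = 8  # junction flank requirement mirrored by the classifier
    intergenic_gap: int = 10_000

    @property
    def junction_footprint(self) -> int:
        """Width of junction-informative start positions: a read of length L
        covers a junction with >= min_overlap aligned bases on each side
        from L - 2*min_overlap start positions."""
        return self.read_length - 2 * self.min_overlap


@dataclass
class Cohort:
    truth: pd.DataFrame  # indexed by gene_id
    models: dict[str, GeneModel]
    params: CohortParams
    seed: int


@dataclass
class SimulatedLibrary:
    library_id: str
    condition: str
    time: float
    seed: int
    counts: pd.DataFrame  # per-gene table (quantify.quants_to_frame schema)
    reads: list[ReadAlignment] | None = None


def _gene_ids(n_genes: int, n_hk: int) -> list[str]:
    hk = list(HOUSEKEEPING_GENES[:n_hk])
    if n_hk > len(HOUSEKEEPING_GENES):
        hk += [f"HK{k:02d}" for k in range(len(HOUSEKEEPING_GENES), n_hk)]
    width = max(4, len(str(n_genes)))
    return hk + [f"G{k:0{width}d}" for k in range(1, n_genes - n_hk + 1)]


def simulate_cohort(
    n_genes: int = 500,
    params: CohortParams | None = None,
    seed: int = 0,
) -> Cohort:
    """Draw a reproducible cohort of genes with known kinetics.

    The first ``n_housekeeping`` genes are stable controls named after
    the default housekeeping set so downstream normalization works
    without configuration. All remaining genes are mixture genes with
    condition-dependent kinetics.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    params = params or CohortParams(n_genes=n_genes)
    if params.n_genes != n_genes:
        params = CohortParams(**{**asdict(params), "n_genes": n_genes})
    _validate(params)
    rng = np.random.default_rng(seed)
    n_hk = min(params.n_housekeeping, n_genes)
    ids = _gene_ids(n_genes, n_hk)

    beta_s = rng.uniform(*params.beta_s_range, n_genes)
    beta_ir = rng.uniform(*params.beta_ir_range, n_genes)
    p_ir = rng.beta(*params.p_ir_beta, n_genes)
    alpha = 10.0 ** rng.uniform(*params.alpha_log10_range, n_genes)
    is_hk = np.arange(n_genes) < n_hk
    beta_s[is_hk] = params.hk_beta_s
    p_ir[is_hk] = 0.0
    alpha[is_hk] = params.hk_alpha

    stabilized = (~is_hk) & (rng.random(n_genes) < params.stabilized_fraction)
    splicing_up = (~is_hk) & (rng.random(n_genes) < params.splicing_up_fraction)
    transcription_up = (~is_hk) & (
        rng.random(n_genes) < params.transcription_up_fraction
    )

    beta_s_act = np.where(stabilized, beta_s * params.stabilization_factor, beta_s)
    p_ir_act = np.where(splicing_up, p_ir * params.splicing_factor, p_ir)
    alpha_act = np.where(transcription_up, alpha * params.transcription_factor, alpha)

    models: dict[str, GeneModel] = {}
    n_introns = np.zeros(n_genes, dtype=int)
    cursor = 1000
    for i, gid in enumerate(ids):
        ni = int(rng.integers(params.n_introns_range[0], params.n_introns_range[1] + 1))
        n_introns[i] = ni
        exon_lens = rng.integers(*params.exon_len_range, ni + 1, endpoint=True)
        intron_lens = rng.integers(*params.intron_len_range, ni, endpoint=True)
        exons = []
        pos = cursor
        for k in range(ni + 1):
            exons.append((pos, pos + int(exon_lens[k])))
            pos += int(exon_lens[k])
            if k < ni:
                pos += int(intron_lens[k])
        strand = "+" if i % 2 == 0 else "-"
        models[gid] = consolidate_gene([exons], gid, chrom="chrSim1", strand=strand)
        cursor = pos + params.intergenic_gap

    truth = pd.DataFrame(
        {
            "gene_id": ids,
            "alpha_rest": alpha,
            "alpha_act": alpha_act,
            "p_ir_rest": p_ir,
            "p_ir_act": p_ir_act,
            "beta_s_rest": beta_s,
            "beta_s_act": beta_s_act,
            "beta_ir_rest": beta_ir,
            "beta_ir_act": beta_ir,  # activation leaves retained-pool decay alone
            "is_housekeeping": is_hk,
            "stabilized_truth": stabilized,
            "splicing_up_truth": splicing_up,
            "transcription_up_truth": transcription_up,
            "n_introns": n_introns,
            "cer_len": [models[g].cer_total_len for g in ids],
            "cir_len": [models[g].cir_total_len for g in ids],
        }
    ).set_index("gene_id")
    return Cohort(truth=truth, models=models, params=params, seed=seed)


def _validate(p: CohortParams) -> None:
    for name in ("beta_s_range", "beta_ir_range", "alpha_log10_range"):
        lo, hi = getattr(p, name)
        if not lo < hi:
            raise ValueError(f"{name}: need lo < hi, got ({lo}, {hi})")
    if min(p.p_ir_beta) <= 0:
        raise ValueError("p_ir_beta parameters must be positive")
    if p.n_introns_range[0] < 1:
        raise ValueError("genes need at least one intron")


def _pools(cohort: Cohort, condition: str, time: float):
    t = cohort.truth
    suffix = {"resting": "rest", "activated": "act"}.get(condition)
    if suffix is None:
        raise ValueError(f"unknown condition {condition!r}")
    dt = time - cohort.params.t0
    alpha = t[f"alpha_{suffix}"].to_numpy()
    p_ir = t[f"p_ir_{suffix}"].to_numpy()
    n_s = alpha * (1 - p_ir) * np.exp(-t[f"beta_s_{suffix}"].to_numpy() * dt)
    n_ir = alpha * p_ir * np.exp(-t[f"beta_ir_{suffix}"].to_numpy() * dt)
    return n_s, n_ir


def simulate_library(
    cohort: Cohort,
    condition: str,
    time: float,
    depth: float = 1e6,
    seed: int = 0,
    mode: str = "counts",
    exact: bool = False,
) -> SimulatedLibrary:
    """Sample one chase-time library from the cohort's generative model.

    ``exact=True`` returns the (float) expectation table instead of
    Poisson draws — the infinite-depth limit, in which the gene IRI
    equals N_IR/(N_S + N_IR) identically. ``mode="reads"`` additionally
    materializes BED-style read alignments (uniform placement within
    regions, junction reads straddling annotated junctions) for
    exercising the read-level classifiers.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    n_s, n_ir = _pools(cohort, condition, time)
    truth = cohort.truth
    cer_len = truth["cer_len"].to_numpy(dtype=float)
    cir_len = truth["cir_len"].to_numpy(dtype=float)
    n_introns = truth["n_introns"].to_numpy(dtype=float)
    fp = cohort.params.junction_footprint

    w_cer = (n_s + n_ir) * cer_len
    w_cir = n_ir * cir_len
    w_ee = n_s * n_introns * fp
    w_ei = n_ir * 2 * n_introns * fp
    total = w_cer.sum() + w_cir.sum()
    if total <= 0:
        raise ValueError("zero total read expectation")
    c = depth / total

    rng = np.random.default_rng(seed)
    if exact:
        cer = w_cer * c
        cir = w_cir * c
        ee = w_ee * c
        ei = w_ei * c
    else:
        cer = rng.poisson(w_cer * c).astype(float)
        cir = rng.poisson(w_cir * c).astype(float)
        ee = rng.poisson(w_ee * c).astype(float)
        ei = rng.poisson(w_ei * c).astype(float)

    library_size = float(cer.sum() + cir.sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        iri = np.where(
            (cer > 0) & (cir_len > 0),
            (cir / np.where(cir_len > 0, cir_len, 1))
            / np.where(cer > 0, cer / cer_len, np.nan),
            np.nan,
        )
        rpkm_v = cer / (cer_len / 1000.0) / (library_size / 1e6)

    counts = pd.DataFrame(
        {
            "cer_reads": cer,
            "cir_reads": cir,
            "x_ee": ee,
            "x_ei": ei,
            "cer_len": cer_len.astype(int),
            "cir_len": cir_len.astype(int),
            "iri": iri,
            "rpkm": rpkm_v,
        },
        index=truth.index,
    )
    lib = SimulatedLibrary(
        library_id=f"{condition}_{time:g}h",
        condition=condition,
        time=time,
        seed=seed,
        counts=counts,
    )
    if mode == "reads":
        lib.reads = _place_reads(cohort, counts, rng)
    elif mode != "counts":
        raise ValueError(f"unknown mode {mode!r}")
    return lib


def _place_reads(cohort: Cohort, counts: pd.DataFrame, rng) -> list[ReadAlignment]:
    """Uniformly place region reads and construct junction-straddling reads."""
    L = cohort.params.read_length
    half = L // 2
    reads: list[ReadAlignment] = []
    for gid, row in counts.iterrows():
        m = cohort.models[gid]
        for region_set, n in ((m.cers, int(row["cer_reads"])), (m.cirs, int(row["cir_reads"]))):
            if n == 0 or not region_set:
                continue
            lens = np.array([len(iv) for iv in region_set], dtype=float)
            picks = rng.choice(len(region_set), size=n, p=lens / lens.sum())
            for k in picks:
                iv = region_set[k]
                rl = min(L, len(iv))
                s = int(rng.integers(iv.start, iv.end - rl + 1))
                reads.append(
                    ReadAlignment(m.chrom, ((s, s + rl),), strand=m.strand)
                )
        # exon–intron reads: contiguous, centred on a junction point
        n_ei = int(row["x_ei"])
        if n_ei and m.cjs:
            picks = rng.integers(0, len(m.cjs), n_ei)
            for k in picks:
                pos = m.cjs[k][0]
                reads.append(
                    ReadAlignment(m.chrom, ((pos - half, pos + half),), strand=m.strand)
                )
        # exon–exon reads: gapped, exactly bridging a CIR
        n_ee = int(row["x_ee"])
        if n_ee and m.cirs:
            cer_ends = {iv.end: iv for iv in m.cers}
            cer_starts = {iv.start: iv for iv in m.cers}
            bridgeable = [
                cir for cir in m.cirs
                if cir.start in cer_ends and cir.end in cer_starts
            ]
            if bridgeable:
                picks = rng.integers(0, len(bridgeable), n_ee)
                for k in picks:
                    cir = bridgeable[k]
                    lh = min(half, len(cer_ends[cir.start]))
                    rh = min(half, len(cer_starts[cir.end]))
                    reads.append(
                        ReadAlignment(
                            m.chrom,
                            ((cir.start - lh, cir.start), (cir.end, cir.end + rh)),
                            strand=m.strand,
                        )
                    )
    return reads


def simulate_experiment(
    cohort: Cohort,
    depth: float = 1e6,
    times: tuple[float, ...] = (0.5, 2.0),
    conditions: tuple[str, ...] = ("resting", "activated"),
    seed: int = 0,
    mode: str = "counts",
    exact: bool = False,
) -> tuple[dict[str, pd.DataFrame], list[dict]]:
    """Simulate the full library grid; returns (libraries, manifest) in the
    shape the normalization step consumes."""
    libraries: dict[str, pd.DataFrame] = {}
    manifest: list[dict] = []
    k = 0
    for cond in conditions:
        for t in times:
            lib = simulate_library(
                cohort, cond, t, depth=depth, seed=seed * 1000 + k,
                mode=mode, exact=exact,
            )
            libraries[lib.library_id] = lib.counts
            manifest.append(
                {
                    "library_id": lib.library_id,
                    "condition": cond,
                    "time": t,
                    "strandedness": "forward",
                }
            )
            k += 1
    return libraries, manifest


def write_fixture(
    cohort: Cohort,
    outdir: str,
    depth: float = 1e5,
    times: tuple[float, ...] = (0.5, 2.0),
    conditions: tuple[str, ...] = ("resting", "activated"),
    mode: str = "counts",
    seed: int = 0,
) -> dict:
    """Write a self-contained on-disk fixture: annotation (GTF + BED set),
    per-library tables (or read BEDs), a YAML manifest, and truth.tsv."""
    from .gene_models import write_gene_models

    os.makedirs(outdir, exist_ok=True)
    gtf_path = os.path.join(outdir, "annotation.gtf")
    with open(gtf_path, "w") as fh:
        for gid, m in cohort.models.items():
            exons = m.cers  # single-isoform genes: CERs are the exons
            for iv in exons:
                fh.write(
                    f"{m.chrom}\tbrudecay\texon\t{iv.start + 1}\t{iv.end}\t.\t"
                    f'{m.strand}\t.\tgene_id "{gid}"; transcript_id "{gid}.t1";\n'
                )
    write_gene_models(cohort.models, os.path.join(outdir, "models"))
    cohort.truth.to_csv(os.path.join(outdir, "truth.tsv"), sep="\t")

    manifest: list[dict] = []
    k = 0
    for cond in conditions:
        for t in times:
            lib = simulate_library(
                cohort, cond, t, depth=depth, seed=seed * 1000 + k, mode=mode
            )
            k += 1
            entry = {
                "library_id": lib.library_id,
                "condition": cond,
                "time": float(t),
                "strandedness": "forward",
                "fraction": "total",
            }
            if mode == "reads":
                path = os.path.join(outdir, f"{lib.library_id}.reads.bed")
                with open(path, "w") as fh:
                    for ri, read in enumerate(lib.reads):
                        for bs, be in read.blocks:
                            fh.write(
                                f"{read.chrom}\t{bs}\t{be}\tr{ri}\t0\t{read.strand}\n"
                            )
                entry["reads"] = os.path.basename(path)
            path = os.path.join(outdir, f"{lib.library_id}.counts.tsv")
            lib.counts.to_csv(path, sep="\t")
            entry["counts"] = os.path.basename(path)
            manifest.append(entry)

    meta = {
        "seed": seed,
        "depth": depth,
        "mode": mode,
        "n_genes": int(len(cohort.truth)),
        "libraries": manifest,
    }
    with open(os.path.join(outdir, "manifest.yaml"), "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)
    return meta
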