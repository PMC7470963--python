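"""Per-gene degradation-rate estimation from pulse-chase time courses.

With labeling stopped at the start of the chase, a labeled transcript
pool decays exponentially, X(t) = X(t0) * exp(-beta * (t - t0)). The
degradation rate beta is estimated per gene by weighted least squares in
log space, with the measured expression values as weights:

    beta: minimize  sum_i X(t_i) * [ln X(t_i) - ln X0 + beta*(t_i - t0)]^2

The two-component mixture model treats each gene's labeled pool as a
mixture of spliced transcripts (rate beta_S) and intron-retained
transcripts (rate beta_IR). The intron retention index links the
components to the measurements:

    X1(t) = X(t) * (1 - IRI(t))     spliced
    X2(t) = X(t) * IRI(t)           intron-retained

and the mixture objective is the sum of two weighted single-component
objectives, one per component — so it separates exactly into independent
fits on X1 and X2. A junction-read variant fits beta_S on normalized
exon–exon junction counts and beta_IR on exon–intron junction counts.

Weighting by X(t_i) down-weights late, low-count points whose log values
are noisiest (Poisson counting noise gives Var[ln X] ~ 1/X).

The weighted objective is an exactly solvable weighted linear regression
of ln X on (t - t0); no iterative optimization is involved. With exactly
two time points any weighting gives the interpolating line, so
beta = ln(X(t1)/X(t2)) / (t2 - t1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .normalize import TimeCourse

__all__ = [
    "DecayFit",
    "fit_one_component",
    "fit_mixture",
    "fit_mixture_junction",
    "weighted_log_linear",
    "pst",
    "expressed_gene_filter",
    "half_life",
]


@dataclass
class DecayFit:
    """Fitted decay parameters for one gene under one model."""

    gene_id: str
    condition: str = ""
    model: str = "one_component"  # one_component | mixture | mixture_junction
    beta: float | None = None  # one-component rate, /h
    beta_s: float | None = None  # spliced rate, /h
    beta_ir: float | None = None  # intron-retained rate, /h
    x0_hat: float | None = None  # fitted intercept X^(t0)
    x0_s: float | None = None
    x0_ir: float | None = None
    flags: set[str] = field(default_factory=set)

    @property
    def half_life(self) -> float | None:
        rate = self.beta_s if self.model.startswith("mixture") else self.beta
        return half_life(rate) if rate is not None and rate > 0 else None

    @property
    def determinable(self) -> bool:
        if "insufficient_points" in self.flags:
            return False
        rate = self.beta_s if self.model.startswith("mixture") else self.beta
        return rate is not None and math.isfinite(rate) and rate > 0


def weighted_log_linear(
    times: np.ndarray, x: np.ndarray
) -> tuple[float, float]:
    """Minimize sum_i x_i [ln x_i - ln x0 + beta (t_i - t0)]^2.

    Returns (beta, x0_hat) with t0 = times[0]. All x must be > 0 and at
    least two points are required. Closed-form weighted regression:
    beta = -cov_w(tau, ln x)/var_w(tau) with weights w = x.
    """
    times = np.asarray(times, dtype=float)
    x = np.asarray(x, dtype=float)
    if times.size < 2:
        raise ValueError("need >= 2 time points")
    if np.any(x <= 0):
        raise ValueError("all expression values must be > 0")
    tau = times - times[0]
    y = np.log(x)
    w = x
    wsum = w.sum()
    tbar = (w * tau).sum() / wsum
    ybar = (w * y).sum() / wsum
    var = (w * (tau - tbar) ** 2).sum()
    if var == 0:
        raise ValueError("all time points identical")
    cov = (w * (tau - tbar) * (y - ybar)).sum()
    beta = -cov / var
    ln_x0 = ybar + beta * tbar
    return float(beta), float(np.exp(ln_x0))


def _fit_component(times, x) -> tuple[float | None, float | None, set[str]]:
    flags: set[str] = set()
    times = np.asarray(times, dtype=float)
    x = np.asarray(x, dtype=float)
    if times.size < 2 or np.any(~np.isfinite(x)) or np.any(x <= 0):
        return None, None, {"insufficient_points"}
    beta, x0 = weighted_log_linear(times, x)
    if beta < 0:
        flags.add("negative_rate")
    return beta, x0, flags


def fit_one_component(tc: TimeCourse) -> DecayFit:
    """Conventional single-pool exponential fit on X(t)."""
    beta, x0, flags = _fit_component(tc.times, tc.x)
    return DecayFit(
        gene_id=tc.gene_id, condition=tc.condition, model="one_component",
        beta=beta, x0_hat=x0, flags=flags,
    )


def fit_mixture(tc: TimeCourse) -> DecayFit:
    """Two-component fit: spliced (beta_S) and intron-retained (beta_IR).

    X is decomposed via the IRI into X1 = X*(1-IRI) and X2 = X*IRI and
    each component fitted independently (the mixture objective is
    separable). Genes whose IRI exceeds 1 at any used point are not fit
    (``iri_gt_1`` flag); an identically-zero retained component yields
    beta_S only (``zero_component``).
    """
    iri = np.asarray(tc.iri, dtype=float)
    if np.any(np.isfinite(iri) & (iri > 1)):
        return DecayFit(
            gene_id=tc.gene_id, condition=tc.condition, model="mixture",
            flags={"iri_gt_1"},
        )
    iri_eff = np.where(np.isfinite(iri), iri, 0.0)
    x1 = tc.x * (1.0 - iri_eff)
    x2 = tc.x * iri_eff

    beta_s, x0_s, flags_s = _fit_component(tc.times, x1)
    fit = DecayFit(
        gene_id=tc.gene_id, condition=tc.condition, model="mixture",
        beta_s=beta_s, x0_s=x0_s, flags=set(flags_s),
    )
    if np.all(x2 == 0):
        fit.flags.add("zero_component")
        return fit
    beta_ir, x0_ir, flags_ir = _fit_component(tc.times, x2)
    if "insufficient_points" in flags_ir:
        # retained pool dropped out at some point; beta_S stands alone
        fit.flags.add("zero_component")
        return fit
    fit.beta_ir, fit.x0_ir = beta_ir, x0_ir
    fit.flags |= flags_ir
    return fit


def fit_mixture_junction(tc: TimeCourse) -> DecayFit:
    """Junction-read variant: beta_S from exon–exon junction counts,
    beta_IR from exon–intron junction counts (both already normalized by
    the library factors)."""
    beta_s, x0_s, flags_s = _fit_component(tc.times, tc.x_ee)
    fit = DecayFit(
        gene_id=tc.gene_id, condition=tc.condition, model="mixture_junction",
        beta_s=beta_s, x0_s=x0_s, flags=set(flags_s),
    )
    if "insufficient_points" in flags_s:
        fit.flags = {"insufficient_points"}
        return fit
    x_ei = np.asarray(tc.x_ei, dtype=float)
    if np.all(x_ei == 0):
        fit.flags.add("zero_component")
        return fit
    beta_ir, x0_ir, flags_ir = _fit_component(tc.times, x_ei)
    if "insufficient_points" in flags_ir:
        fit.flags.add("zero_component")
        return fit
    fit.beta_ir, fit.x0_ir = beta_ir, x0_ir
    fit.flags |= flags_ir
    return fit


def pst(tc: TimeCourse, at_time: float = 0.5) -> float | None:
    """Percentage of spliced transcripts: 1 - IRI at the 0.5 h chase point.

    The early-chase IRI estimates the fraction of transcripts that still
    carry introns shortly after synthesis, so its complement proxies
    splicing efficiency. Returns None when the 0.5 h point is absent or
    its IRI is undefined or outside [0, 1].
    """
    idx = np.flatnonzero(np.isclose(tc.times, at_time))
    if idx.size == 0:
        return None
    v = float(tc.iri[idx[0]])
    if not np.isfinite(v) or v < 0 or v > 1:
        return None
    return 1.0 - v


def expressed_gene_filter(
    timecourses: dict[str, TimeCourse],
    fits: dict[str, DecayFit],
) -> set[str]:
    """Genes whose decay is measurable: IRI <= 1 at every used time point
    and a determinable fit (all X > 0, fitted rate finite and positive).
    Negative-rate and undetermined genes stay in the output tables with
    flags; they are only excluded from this set."""
    keep: set[str] = set()
    for gid, fit in fits.items():
        tc = timecourses.get(gid)
        if tc is None:
            continue
        iri = np.asarray(tc.iri, dtype=float)
        if np.any(np.isfinite(iri) & (iri > 1)):
            continue
        if not fit.determinable:
            continue
        keep.add(gid)
    return keep


def half_life(rate: float) -> float:
    """ln(2)/rate, hours — the one-phase decay half-life."""
    if rate is None or rate <= 0:
        raise ValueError("half-life defined only for positive rates")
    return math.log(2) / rate
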