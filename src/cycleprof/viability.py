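"""Viability arm: % viability, the 3-SD cytotoxicity call, and 4PL potency.

Percent viability normalizes raw luminescence to the DMSO mean.  A compound
is called cytotoxic when its viability falls more than k (default 3) sample
standard deviations below the DMSO mean.  Potency is the EC50 of a
four-parameter logistic (4PL) fit on log10 dose,

    response(d) = bottom + (top - bottom) / (1 + (d / ec50)^hill),

with ECf = ec50 * (f/(100-f))^(1/hill) generalizing to any percent effect.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from cycleprof.errors import (
    FlatCurveError,
    InsufficientDesignError,
    ValidationError,
)


@dataclass(frozen=True)
class DoseResponseFit:
    ec50: float  # µM
    hill: float
    top: float  # % viability as dose -> 0
    bottom: float  # % viability as dose -> inf
    rss: float
    converged: bool


def four_param_logistic(dose, ec50: float, hill: float, top: float, bottom: float):
    """The 4PL curve itself; vectorized over dose."""
    dose = np.asarray(dose, float)
    return bottom + (top - bottom) / (1.0 + (dose / ec50) ** hill)


def percent_viability(raw, dmso_mean: float):
    """100 * raw / dmso_mean; may legitimately exceed 100."""
    if dmso_mean <= 0:
        raise ValidationError(f"DMSO mean must be > 0, got {dmso_mean}")
    raw = np.asarray(raw, float)
    out = 100.0 * raw / dmso_mean
    return float(out) if out.ndim == 0 else out


def cytotoxic_hits(
    compound_viability: Mapping[str, float], dmso_percents, k: float = 3.0
) -> pd.DataFrame:
    """Compounds whose viability is below mean(DMSO) - k * sd(DMSO).

    Sample (n-1) standard deviation.  Returns one row per hit with the
    threshold and the margin (threshold - viability), most cytotoxic first.
    """
    if k <= 0:
        raise ValidationError(f"k must be > 0, got {k}")
    dmso = np.asarray(dmso_percents, float)
    if dmso.size < 2:
        raise ValidationError("need >= 2 DMSO viability values")
    threshold = float(dmso.mean() - k * dmso.std(ddof=1))
    rows = [
        {"compound": name, "viability_pct": v, "threshold": threshold,
         "margin": threshold - v}
        for name, v in compound_viability.items()
        if v < threshold
    ]
    df = pd.DataFrame(rows, columns=["compound", "viability_pct", "threshold", "margin"])
    return df.sort_values(["viability_pct", "compound"], ignore_index=True)


def _fit_once(logd, resp, start, bounds):
    def residuals(p):
        bottom, span, log_ec50, hill = p
        return bottom + span / (1.0 + 10.0 ** ((logd - log_ec50) * hill)) - resp

    return least_squares(residuals, start, bounds=bounds, method="trf")


def fit_four_param_logistic(
    doses,
    responses,
    top_bounds: tuple[float, float] | None = None,
    bottom_bounds: tuple[float, float] | None = None,
) -> DoseResponseFit:
    """Least-squares 4PL fit on log10 dose with multi-start initialization.

    Parametrized as (bottom, span, log10 EC50, hill) with span = top - bottom
    constrained >= 0 and hill > 0, i.e. an inhibitory (decreasing) curve.
    EC50 starts at the geometric mean of the doses and at every interior
    dose; the best residual sum of squares wins.  ``converged`` is False when
    the sigmoid does not beat a flat (mean-only) model — as happens for
    monotone-increasing data under the inhibitory constraint — and the
    best-RSS parameters are still returned.
    """
    doses = np.asarray(doses, float)
    responses = np.asarray(responses, float)
    if doses.shape != responses.shape:
        raise ValidationError("doses and responses must have equal length")
    if (doses <= 0).any():
        raise ValidationError("doses must be > 0")
    if not np.isfinite(responses).all():
        raise ValidationError("responses must be finite")
    if np.unique(doses).size < 4:
        raise InsufficientDesignError(
            f"need >= 4 distinct doses, got {np.unique(doses).size}"
        )
    if np.ptp(responses) == 0:
        raise FlatCurveError("all responses equal; no EC50 exists")

    logd = np.log10(doses)
    resp_lo, resp_hi = float(responses.min()), float(responses.max())
    span0 = resp_hi - resp_lo
    b_lo, b_hi = bottom_bounds if bottom_bounds else (resp_lo - span0, resp_hi)
    if top_bounds:
        t_lo, t_hi = top_bounds
    else:
        t_lo, t_hi = resp_lo, resp_hi + span0
    lower = np.array([b_lo, 0.0, logd.min() - 3.0, 0.05])
    upper = np.array([b_hi, max(t_hi - b_lo, 1e-9), logd.max() + 3.0, 20.0])

    interior = np.unique(logd)[1:-1]
    ec50_starts = [float(logd.mean())] + [float(v) for v in interior]
    best = None
    any_success = False
    for le in ec50_starts:
        start = np.clip(
            np.array([resp_lo, span0, le, 1.0]), lower + 1e-12, upper - 1e-12
        )
        try:
            res = _fit_once(logd, resp=responses, start=start, bounds=(lower, upper))
        except Exception:
            continue
        any_success = any_success or res.success
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise FlatCurveError("all optimization starts failed")

    bottom, span, log_ec50, hill = best.x
    rss = float(2.0 * best.cost)
    rss_flat = float(((responses - responses.mean()) ** 2).sum())
    beats_flat = rss < 0.99 * rss_flat and span > 1e-6 * max(1.0, span0)
    return DoseResponseFit(
        ec50=float(10.0**log_ec50),
        hill=float(hill),
        top=float(bottom + span),
        bottom=float(bottom),
        rss=rss,
        converged=bool(any_success and beats_flat),
    )


def fit_dose_table(table: pd.DataFrame, **kwargs) -> DoseResponseFit:
    """Fit a long-format (dose_uM, response) replicate table."""
    return fit_four_param_logistic(
        table["dose_uM"].to_numpy(float), table["response"].to_numpy(float), **kwargs
    )


def effective_concentration(fit: DoseResponseFit, f: float = 90.0) -> float:
    """ECf = ec50 * (f / (100 - f))^(1/hill); EC50 at f = 50 by definition."""
    if not (0.0 < f < 100.0):
        raise ValidationError(f"f must be in (0, 100), got {f}")
    if fit.hill == 0:
        raise ValidationError("ECf undefined for hill = 0")
    return fit.ec50 * (f / (100.0 - f)) ** (1.0 / fit.hill)
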