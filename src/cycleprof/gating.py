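"""Histogram gating of DNA-content events into cell-cycle phases, and Z' QC.

A DNA histogram of a cycling population shows a 2N (G1) peak and a 4N
(G2/M) peak at twice its intensity.  Gates are placed at k sigma around the
peaks: events below the G1 gate are subG1, between the gates S, at or above
the G2 lower gate G2/M (events above 4N are merged into G2/M).  Assay
quality is summarized by the Z' factor, 1 - 3(sigma_p + sigma_n)/|mu_p - mu_n|.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.signal import argrelextrema
from scipy.stats import norm

from cycleprof.errors import (
    EmptyWellError,
    GatingFailureError,
    UndefinedSeparationError,
    ValidationError,
)
from cycleprof.synthcyto import PhaseFractions, WellEvents

_FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # 2.355


@dataclass(frozen=True)
class Histogram:
    bin_edges: np.ndarray  # length B+1, strictly increasing
    counts: np.ndarray  # length B, non-negative ints

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, float)
        if (np.diff(edges) <= 0).any():
            raise ValidationError("bin edges must be strictly increasing")

    @property
    def centers(self) -> np.ndarray:
        e = np.asarray(self.bin_edges, float)
        return 0.5 * (e[:-1] + e[1:])


@dataclass(frozen=True)
class PeakPair:
    """Located 2N and 4N peaks with their widths."""

    g1_peak: float
    g2_peak: float
    g1_sigma: float
    g2_sigma: float

    def __post_init__(self) -> None:
        ratio = self.g2_peak / self.g1_peak
        if not (1.8 <= ratio <= 2.2):
            raise ValidationError(f"g2/g1 peak ratio {ratio:.3f} outside [1.8, 2.2]")
        if self.g1_sigma <= 0 or self.g2_sigma <= 0:
            raise ValidationError("peak sigmas must be > 0")


@dataclass(frozen=True)
class QCStats:
    mu_p: float
    sigma_p: float
    mu_n: float
    sigma_n: float
    zprime: float


def build_histogram(
    events: WellEvents, bins: int = 128, range_: tuple[float, float] | None = None
) -> Histogram:
    """Bin intensities into a DNA-content histogram.

    Bins are half-open [lo, hi) with the last bin closed (numpy convention).
    Default range is [0, 1.05 x 99.5th percentile] so rare outliers do not
    stretch the axis.
    """
    if bins < 10:
        raise ValidationError(f"need >= 10 bins, got {bins}")
    x = events.intensities
    if x.size == 0:
        raise EmptyWellError(events.well_id)
    if range_ is None:
        range_ = (0.0, 1.05 * float(np.percentile(x, 99.5)))
    counts, edges = np.histogram(x, bins=bins, range=range_)
    return Histogram(bin_edges=edges, counts=counts)


def _smooth3(counts: np.ndarray) -> np.ndarray:
    """3-bin moving average with edge replication; suppresses shot noise
    without moving the mode by more than one bin at B = 128."""
    padded = np.concatenate([counts[:1], counts, counts[-1:]]).astype(float)
    return (padded[:-2] + padded[1:-1] + padded[2:]) / 3.0


def _local_maxima(y: np.ndarray) -> np.ndarray:
    """Indices of local maxima of y, plateau-tolerant, edges included."""
    idx = set(argrelextrema(y, np.greater_equal, order=1)[0])
    if len(y) >= 2 and y[0] >= y[1]:
        idx.add(0)
    if len(y) >= 2 and y[-1] >= y[-2]:
        idx.add(len(y) - 1)
    # drop flat-zero stretches; keep only bins with mass
    return np.array(sorted(i for i in idx if y[i] > 0), dtype=int)


def _refine_peak(y: np.ndarray, centers: np.ndarray, idx: int) -> float:
    """Sub-bin peak location by a parabola through the mode and neighbors.

    The vertex stays inside the mode bin; degenerate (flat or edge) cases
    fall back to the bin center.
    """
    if idx <= 0 or idx >= len(y) - 1:
        return float(centers[idx])
    y0, y1, y2 = y[idx - 1], y[idx], y[idx + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom >= 0:  # not concave around the mode
        return float(centers[idx])
    shift = 0.5 * (y0 - y2) / denom
    shift = float(np.clip(shift, -0.5, 0.5))
    w = centers[1] - centers[0]
    return float(centers[idx] + shift * w)


def _fwhm_sigma(
    y: np.ndarray,
    centers: np.ndarray,
    peak_idx: int,
    bin_width: float = 0.0,
    baseline: float = 0.0,
) -> float | None:
    """Sigma from full width at half maximum around one peak; None if the
    half-height crossings cannot both be bracketed.

    ``baseline`` is the pedestal the peak rides on (the S-phase plateau for
    the 4N peak); the half height is measured above it.  The 3-bin moving
    average and the binning itself widen the apparent peak; their variance
    contribution ((3w)^2/12 + w^2/12 for bin width w) is subtracted back
    out so the estimate tracks the underlying spread.
    """
    half = baseline + (y[peak_idx] - baseline) / 2.0
    if half <= 0 or y[peak_idx] <= baseline:
        return None
    left = None
    for i in range(peak_idx, 0, -1):
        if y[i - 1] < half <= y[i]:
            # linear interpolation between centers i-1 and i
            t = (half - y[i - 1]) / (y[i] - y[i - 1])
            left = centers[i - 1] + t * (centers[i] - centers[i - 1])
            break
    right = None
    for i in range(peak_idx, len(y) - 1):
        if y[i + 1] < half <= y[i]:
            t = (y[i] - half) / (y[i] - y[i + 1])
            right = centers[i] + t * (centers[i + 1] - centers[i])
            break
    if left is None or right is None or right <= left:
        return None
    sigma_sq = ((right - left) / _FWHM_TO_SIGMA) ** 2 - (10.0 / 12.0) * bin_width**2
    if sigma_sq <= (0.25 * bin_width) ** 2:
        return None
    return float(np.sqrt(sigma_sq))


def detect_g1_g2_peaks(
    hist: Histogram, cv_assumed: float = 0.05, well_id: str | None = None
) -> PeakPair:
    """Locate the 2N and 4N peaks of a smoothed DNA histogram.

    The tallest peak anchors the pair.  If another local maximum sits at
    [1.8, 2.2] x its position, the tallest peak is the 2N mode and that
    partner the 4N mode (equal-height bimodal histograms thus resolve with
    the leftmost mode as G1).  Failing that, a 4N-dominant well (strong
    G2/M arrest) is recognized by a genuine maximum near half the tallest
    peak — at least 8% of its height, to ignore pedestal shot noise — which
    then becomes the 2N mode.  With no partner either way (e.g. a pure-G1
    well) the 4N peak is synthesized at exactly 2 x g1_peak.  Sigmas come
    from FWHM/2.355 (deconvolved for smoothing/binning spread) with a
    cv_assumed x peak fallback.
    """
    y = _smooth3(np.asarray(hist.counts, float))
    centers = hist.centers
    bin_width = float(np.mean(np.diff(hist.bin_edges)))
    if not (y > 0).any() or float(y.max()) == float(y.min()):
        raise GatingFailureError("flat histogram, no discernible peak", well_id)
    maxima = _local_maxima(y)
    if maxima.size == 0:
        raise GatingFailureError("no local maximum found", well_id)

    heights = y[maxima]
    tall_idx = int(maxima[int(np.argmax(heights))])  # argmax -> leftmost tie-break
    tall_pos = centers[tall_idx]

    def prominent(i: int) -> bool:
        # candidate must rise clearly above the valley separating it from
        # the tallest peak, else it is shot noise on the S/debris pedestal
        lo_i, hi_i = min(i, tall_idx), max(i, tall_idx)
        valley = float(y[lo_i:hi_i + 1].min())
        return y[i] - valley >= 0.05 * y[tall_idx]

    # tallest = 2N with a 4N partner above it?
    up = [i for i in maxima
          if 1.8 * tall_pos <= centers[i] <= 2.2 * tall_pos
          and i != tall_idx and prominent(i)]
    if up:
        g1_idx = tall_idx
        g2_idx = int(max(up, key=lambda i: (y[i], -i)))
    else:
        # tallest = 4N with a real 2N mode below it (G2/M-arrested well)?
        down = [i for i in maxima
                if tall_pos / 2.2 <= centers[i] <= tall_pos / 1.8
                and y[i] >= 0.08 * y[tall_idx] and i != tall_idx and prominent(i)]
        if down:
            g1_idx = int(max(down, key=lambda i: (y[i], -i)))
            g2_idx = tall_idx
        else:
            g1_idx, g2_idx = tall_idx, None

    g1_peak = _refine_peak(y, centers, g1_idx)
    if g2_idx is not None:
        # both peaks ride on the S-phase pedestal between them
        valley = float(y[g1_idx:g2_idx + 1].min())
        g1_sigma = _fwhm_sigma(y, centers, g1_idx, bin_width, baseline=valley)
        g2_peak = _refine_peak(y, centers, g2_idx)
        g2_sigma = _fwhm_sigma(y, centers, g2_idx, bin_width, baseline=valley)
    else:
        g1_sigma = _fwhm_sigma(y, centers, g1_idx, bin_width)
        g2_peak = 2.0 * g1_peak
        g2_sigma = None

    if g1_sigma is None:
        g1_sigma = cv_assumed * g1_peak
    if g2_sigma is None:
        g2_sigma = cv_assumed * g2_peak
    # gates at ~2.5 sigma must fit between the peaks; wider estimates mean
    # the pedestal, not the peak, set the apparent width
    cap = 0.15 * (g2_peak - g1_peak)
    if cap > 0:
        g1_sigma = min(g1_sigma, cap)
        g2_sigma = min(g2_sigma, cap)
    return PeakPair(g1_peak=g1_peak, g2_peak=g2_peak, g1_sigma=g1_sigma, g2_sigma=g2_sigma)


def _gate_bounds(
    peaks: PeakPair,
    k: float,
    k_g2m: float | None = None,
    k_g1s: float | None = None,
) -> tuple[float, float, float]:
    if k <= 0:
        raise ValidationError(f"gate half-width k must be > 0, got {k}")
    if k_g2m is None:
        k_g2m = k
    if k_g1s is None:
        k_g1s = k
    if k_g2m <= 0 or k_g1s <= 0:
        raise ValidationError("gate half-widths must be > 0")
    b0 = peaks.g1_peak - k * peaks.g1_sigma
    b1 = peaks.g1_peak + k_g1s * peaks.g1_sigma
    b2 = peaks.g2_peak - k_g2m * peaks.g2_sigma
    return b0, b1, b2


def gate_phases(
    events: WellEvents,
    peaks: PeakPair,
    k: float = 2.5,
    k_g2m: float | None = None,
    k_g1s: float | None = None,
) -> PhaseFractions:
    """Assign every event to a phase by intensity gates at k sigma.

    Boundaries: b0 = g1_peak - k*g1_sigma, b1 = g1_peak + k_g1s*g1_sigma,
    b2 = g2_peak - k_g2m*g2_sigma (both half-widths default to k).
    subG1 < b0 <= G1 < b1 <= S < b2 <= G2/M (everything above 4N counts as
    G2/M).  Fractions sum to 1 exactly over all events.

    S-phase DNA content runs right up to both peaks, so symmetric bands
    trade S mass against the Gaussian peak tails; :func:`gate_well`
    chooses ``k_g1s`` and ``k_g2m`` per well to balance the two fluxes in
    expectation.
    """
    x = events.intensities
    if x.size == 0:
        raise EmptyWellError(events.well_id)
    b0, b1, b2 = _gate_bounds(peaks, k, k_g2m, k_g1s)
    if b1 >= b2:
        raise GatingFailureError(
            f"overlapping gates: G1 upper bound {b1:.3g} >= G2 lower bound {b2:.3g}",
            events.well_id,
        )
    n = x.size
    n_sub = int((x < b0).sum())
    n_g1 = int(((x >= b0) & (x < b1)).sum())
    n_s = int(((x >= b1) & (x < b2)).sum())
    n_g2m = n - n_sub - n_g1 - n_s
    return PhaseFractions(g1=n_g1 / n, s=n_s / n, g2m=n_g2m / n, subg1=n_sub / n)


def gate_labels(
    events: WellEvents,
    peaks: PeakPair,
    k: float = 2.5,
    k_g2m: float | None = None,
    k_g1s: float | None = None,
) -> np.ndarray:
    """Per-event phase labels under the same gates as :func:`gate_phases`."""
    x = events.intensities
    b0, b1, b2 = _gate_bounds(peaks, k, k_g2m, k_g1s)
    out = np.where(x < b0, "subg1", np.where(x < b1, "g1", np.where(x < b2, "s", "g2m")))
    return out


def _solve_balance(peak_mass: float, s_flux_per_k: float, lo: float, hi: float) -> float | None:
    """Root of s_flux_per_k * kx = peak_mass * Phi(-kx) on [lo, hi]."""

    def imbalance(kx: float) -> float:
        return s_flux_per_k * kx - peak_mass * norm.sf(kx)

    if hi <= lo or imbalance(lo) * imbalance(hi) > 0:
        return None
    return float(brentq(imbalance, lo, hi))


def _balanced_gates(
    events: WellEvents, peaks: PeakPair, k: float
) -> tuple[float | None, float | None]:
    """(k_g1s, k_g2m) half-widths that are unbiased to first order.

    Hard gates trade the S pedestal mass inside each peak band against the
    Gaussian tail of that peak falling outside its gate.  A provisional
    symmetric gate estimates the S density (uniform pedestal between the
    peaks) and the G1/G2M masses, then each inner boundary is placed where
    the two expected fluxes cancel:

        s_density * kx * sigma = peak_mass * Phi(-kx).

    Either entry is None (symmetric gate) when its side is empty or no
    root lies in a usable range.  The subG1 boundary stays at k sigma: the
    debris distribution below the 2N peak has no comparable pedestal model.
    """
    try:
        prov = gate_phases(events, peaks, k=k)
    except GatingFailureError:
        return None, None
    span = peaks.g2_peak - peaks.g1_peak
    if span <= 0 or prov.s <= 0:
        return None, None
    # the symmetric gate clips the S pedestal by k*sigma at each end and
    # hands the clipped slices to G1 and G2/M; undo to first order
    visible = span - k * (peaks.g1_sigma + peaks.g2_sigma)
    if visible <= 0:
        return None, None
    s_density = prov.s / visible
    g1_mass = max(
        (prov.g1 - s_density * k * peaks.g1_sigma) / (1.0 - 2.0 * norm.sf(k)), 1e-9
    )
    g2m_mass = max(
        (prov.g2m - s_density * k * peaks.g2_sigma) / (1.0 - norm.sf(k)), 1e-9
    )
    mid_cap = 0.5 * span  # keep each boundary on its own side of the midpoint
    k1 = _solve_balance(
        g1_mass, s_density * peaks.g1_sigma, 0.3,
        min(6.0, mid_cap / peaks.g1_sigma - 1e-6),
    )
    k2 = _solve_balance(
        g2m_mass, s_density * peaks.g2_sigma, 0.3,
        min(6.0, mid_cap / peaks.g2_sigma - 1e-6),
    )
    return k1, k2


def gate_well(
    events: WellEvents,
    bins: int = 128,
    k: float = 2.5,
    k_g2m: float | None = None,
    k_g1s: float | None = None,
    cv_assumed: float = 0.05,
) -> PhaseFractions:
    """Histogram -> peak detection -> bias-balanced gating for one well.

    Unless overridden, the G1|S and S|G2M boundaries are refined per well
    by :func:`_balanced_gates` so the recovered fractions are unbiased to
    first order.
    """
    hist = build_histogram(events, bins=bins)
    peaks = detect_g1_g2_peaks(hist, cv_assumed=cv_assumed, well_id=events.well_id)
    if k_g2m is None or k_g1s is None:
        bal_g1s, bal_g2m = _balanced_gates(events, peaks, k)
        if k_g1s is None:
            k_g1s = bal_g1s
        if k_g2m is None:
            k_g2m = bal_g2m
    return gate_phases(events, peaks, k=k, k_g2m=k_g2m, k_g1s=k_g1s)


def zprime_factor(pos, neg) -> QCStats:
    """Z' = 1 - 3(sigma_p + sigma_n)/|mu_p - mu_n| with sample (n-1) SDs.

    Z' <= 1 always; > 0.5 marks a robust screening assay.
    """
    pos = np.asarray(pos, float)
    neg = np.asarray(neg, float)
    if pos.size < 2 or neg.size < 2:
        raise ValidationError("each control list needs >= 2 readings")
    mu_p, mu_n = float(pos.mean()), float(neg.mean())
    if mu_p == mu_n:
        raise UndefinedSeparationError("control means coincide; Z' undefined")
    sigma_p = float(pos.std(ddof=1))
    sigma_n = float(neg.std(ddof=1))
    z = 1.0 - 3.0 * (sigma_p + sigma_n) / abs(mu_p - mu_n)
    return QCStats(mu_p=mu_p, sigma_p=sigma_p, mu_n=mu_n, sigma_n=sigma_n, zprime=z)
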