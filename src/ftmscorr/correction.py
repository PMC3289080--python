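"""Correctability checks and ICM estimation of the monotone correction function.

Observed isotope-pair profiles y1 (¹²C) and y2 (¹³C) of one peptide are
related to the true profiles by x1 = f(y1), x2 = f(y2), with a correction
function f shared by both isotopes of the peptide.  Above a distortion-free
intensity threshold (1e6 ion counts by default) the instrument is faithful
and f is the identity; below it, suppression only attenuates, so f(y) >= y.
The inverse of f is the distortion function g.

Because the true profiles obey x2 = r * x1 with a known theoretical isotope
ratio r, f is identifiable from a single pair: iterative conditional modes
(ICM) alternates between (a) splitting the current total ion count
T = x1 + x2 into targets x1* = T/(1+r), x2* = r*T/(1+r) and (b) refitting f
as the best monotone piecewise-linear map (isotonic least squares in
log10-log10 space) from observed to target intensities, anchored to the
identity above the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import nnls

from .errors import ConvergenceError, InputError, NotCorrectableError
from .preprocess import (
    ElutionProfile,
    IsotopePair,
    PeakInterval,
    detect_peak_interval,
)

_EPS_LOG = 1e-9  # minimal log10 spacing between knots; keeps f invertible


@dataclass(frozen=True)
class CorrectionConfig:
    """Correction-condition and ICM fitting parameters."""

    ratio_low: float = 0.2  # isotope ratios outside [low, high] carry
    ratio_high: float = 0.8  # too little suppression contrast
    identity_threshold: float = 1e6  # distortion-free lower limit (ion counts)
    n_knots: int = 16  # piecewise-linear knots below the threshold
    tol: float = 1e-5  # relative change in total corrected area
    max_iter: int = 3000
    stall_tol: float = 1e-3  # accept a non-improving limit cycle below this
    stall_iter: int = 30  # ... after this many iterations without improvement
    min_knot_spacing: float = 0.02  # log10 decades between adjacent knots
    smooth_lambda: float = 0.01  # curvature penalty selecting the smoothest fit
    ratio_tol: float = 0.1  # required agreement of corrected area ratio with r
    min_points: int = 3  # minimum usable points in the peak interval
    intensity_floor: float = 1.0  # ignore points below this in the fit


@dataclass(frozen=True)
class CorrectabilityVerdict:
    correctable: bool
    reason: str  # "ok" | "ratio_out_of_range" | "below_intensity_limit"

    def __post_init__(self):
        if self.correctable != (self.reason == "ok"):
            raise InputError("verdict flag inconsistent with reason")


@dataclass(frozen=True)
class CorrectionFunction:
    """Monotone piecewise-linear map f from observed to true intensity.

    Parameterized by knots in log10 space; identity at and above
    ``identity_threshold``.  Inputs below the lowest knot are mapped by
    extrapolating the lowest segment (exact for power-law suppression,
    which is linear in log-log coordinates).
    """

    log_knots_observed: np.ndarray  # ascending log10 intensities
    log_knots_true: np.ndarray  # ascending log10 intensities
    identity_threshold: float = 1e6

    def __post_init__(self):
        ko = np.asarray(self.log_knots_observed, dtype=float)
        kt = np.asarray(self.log_knots_true, dtype=float)
        if ko.shape != kt.shape or ko.ndim != 1 or ko.size < 1:
            raise InputError("knot arrays must be equal-length 1-D")
        if np.any(np.diff(ko) <= 0) or np.any(np.diff(kt) <= 0):
            raise InputError("correction-function knots must be strictly increasing")
        lthr = np.log10(self.identity_threshold)
        if np.any(kt[ko < lthr] < ko[ko < lthr] - 1e-12):
            raise InputError("f(y) < y below the distortion-free threshold")
        object.__setattr__(self, "log_knots_observed", ko)
        object.__setattr__(self, "log_knots_true", kt)

    @classmethod
    def identity(cls, identity_threshold: float = 1e6) -> "CorrectionFunction":
        lthr = np.log10(identity_threshold)
        return cls(np.array([lthr - 1.0, lthr]), np.array([lthr - 1.0, lthr]),
                   identity_threshold)

    @property
    def valid_range(self) -> tuple[float, float]:
        """Observed-intensity span of the fitted knots (ion counts)."""
        return (10.0 ** self.log_knots_observed[0],
                10.0 ** self.log_knots_observed[-1])

    @staticmethod
    def _interp(x: np.ndarray, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
        """Piecewise-linear interpolation, extrapolated below the fitted range.

        Extrapolation follows the chord from the lowest knot to the identity
        anchor at the threshold: the average log-log slope of the whole fit,
        which is robust to noise in the lowest segment and exact when the
        suppression is a power law in log space.
        """
        out = np.interp(x, xs, ys)
        if xs.size >= 2:
            lo = x < xs[0]
            if lo.any():
                slope = (ys[-1] - ys[0]) / (xs[-1] - xs[0])
                out[lo] = ys[0] + slope * (x[lo] - xs[0])
            hi = x > xs[-1]
            if hi.any():
                slope = (ys[-1] - ys[-2]) / (xs[-1] - xs[-2])
                out[hi] = ys[-1] + slope * (x[hi] - xs[-1])
        return out

    def _map(self, values: np.ndarray, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        scalar = values.ndim == 0
        v = np.atleast_1d(values)
        out = np.array(v, dtype=float)
        pos = v > 0
        below = pos & (v < self.identity_threshold)
        if below.any():
            mapped = 10.0 ** self._interp(np.log10(v[below]), xs, ys)
            out[below] = np.minimum(mapped, self.identity_threshold)
        return float(out[0]) if scalar else out

    def __call__(self, y):
        """Corrected (true) intensity f(y); identity at/above the threshold."""
        return self._map(y, self.log_knots_observed, self.log_knots_true)

    def distortion(self, x):
        """Inverse map g(x) = f^-1(x), the distortion function."""
        return self._map(x, self.log_knots_true, self.log_knots_observed)

    def apply(self, profile: ElutionProfile) -> ElutionProfile:
        return profile.with_intensities(self(profile.intensities))


def apply_correction(profile: ElutionProfile, f: CorrectionFunction) -> ElutionProfile:
    """Pointwise f applied to a profile; preserves the time grid."""
    return f.apply(profile)


def profile_area(profile: ElutionProfile, interval: PeakInterval | None = None) -> float:
    """Trapezoidal integral of intensity over time within the interval."""
    sl = interval.slice() if interval is not None else slice(None)
    t = profile.times[sl]
    y = profile.intensities[sl]
    if len(t) < 2:
        return 0.0
    return float(np.trapezoid(y, t))


def check_correction_conditions(
    pair: IsotopePair, config: CorrectionConfig = CorrectionConfig()
) -> CorrectabilityVerdict:
    """Decide whether a pair can be corrected.

    Correction requires (a) an isotope ratio not close to 0 or 1 — otherwise
    the suppression leaves no contrast between y1 and y2 — and (b) the ¹³C
    profile apex above the distortion-free lower limit, so the correction
    function can be anchored over the full range needing correction.
    """
    if not 0.0 < config.ratio_low < config.ratio_high < 1.0:
        raise InputError("require 0 < ratio_low < ratio_high < 1")
    if config.identity_threshold <= 0:
        raise InputError("identity_threshold must be > 0")
    if not config.ratio_low <= pair.r <= config.ratio_high:
        return CorrectabilityVerdict(False, "ratio_out_of_range")
    sl = pair.interval.slice() if pair.interval is not None else slice(None)
    if pair.y2.intensities[sl].max() <= config.identity_threshold:
        return CorrectabilityVerdict(False, "below_intensity_limit")
    return CorrectabilityVerdict(True, "ok")


def _interp_matrix(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Rows of piecewise-linear (hat-function) interpolation weights."""
    n, k = len(x), len(knots)
    A = np.zeros((n, k))
    idx = np.clip(np.searchsorted(knots, x, side="right") - 1, 0, k - 2)
    frac = (x - knots[idx]) / (knots[idx + 1] - knots[idx])
    rows = np.arange(n)
    A[rows, idx] = 1.0 - frac
    A[rows, idx + 1] = frac
    return A


def _fit_monotone_map(
    observed: np.ndarray,
    target: np.ndarray,
    config: CorrectionConfig,
) -> CorrectionFunction:
    """Best monotone piecewise-linear fit of log-true vs log-observed intensity.

    Knot values are parameterized as the identity anchor at the threshold
    minus cumulative non-negative decrements, turning the monotone
    least-squares problem into NNLS.  Targets at/above the identity
    threshold are pinned to the identity and the constraint f(y) >= y is
    imposed below it.
    """
    lthr = np.log10(config.identity_threshold)
    ly = np.log10(observed)
    lx = np.log10(target)
    lx = np.where(ly >= lthr, ly, lx)  # distortion-free above threshold
    lx = np.maximum(lx, ly)  # suppression only attenuates
    below = ly < lthr
    if below.sum() < 2:
        return CorrectionFunction.identity(config.identity_threshold)
    qs = np.linspace(0.0, 1.0, config.n_knots)
    knots = np.quantile(ly[below], qs)
    knots = np.append(knots, lthr)
    # merge knots closer than min_knot_spacing: micro-segments carry no
    # information and would poison the below-range extrapolation slope
    kept = [knots[0]]
    for k in knots[1:-1]:
        if k - kept[-1] >= config.min_knot_spacing:
            kept.append(k)
    if knots[-1] - kept[-1] < config.min_knot_spacing and len(kept) > 1:
        kept.pop()
    kept.append(lthr)
    knots = np.array(kept)
    if len(knots) < 2:
        return CorrectionFunction.identity(config.identity_threshold)
    # v_k = lthr - sum_{j>k} w_j with w >= 0 enforces monotone knot values
    # ending at the identity anchor; the fit is then linear in w
    ly_b, lx_b = ly[below], lx[below]
    A = _interp_matrix(np.clip(ly_b, knots[0], lthr), knots)
    K = len(knots)
    S = np.triu(np.ones((K, K - 1)), k=0)  # S[k, j] = 1 iff j >= k
    M = A @ S
    b = lthr - lx_b
    if K > 2:
        # data points pin the fit only where they fall; a light curvature
        # penalty selects the smoothest monotone solution in between,
        # keeping evaluation and extrapolation away from the data stable
        h = np.diff(knots)
        D = np.zeros((K - 2, K))
        rows = np.arange(K - 2)
        D[rows, rows] = 1.0 / h[:-1]
        D[rows, rows + 1] = -(1.0 / h[:-1] + 1.0 / h[1:])
        D[rows, rows + 2] = 1.0 / h[1:]
        lam = config.smooth_lambda * np.sqrt(len(ly_b)) / np.sqrt(K)
        M = np.vstack([M, lam * (D @ S)])
        b = np.concatenate([b, np.zeros(K - 2)])
    w, _ = nnls(M, b)
    kx = lthr - S @ w
    kx = np.maximum(kx, knots)  # f(y) >= y below the threshold
    kx = np.maximum.accumulate(kx)
    kx += _EPS_LOG * np.arange(K)
    kx[-1] = lthr
    if np.any(np.diff(kx) <= 0):
        return CorrectionFunction.identity(config.identity_threshold)
    return CorrectionFunction(knots, kx, config.identity_threshold)


def fit_correction_function(
    pair: IsotopePair,
    config: CorrectionConfig = CorrectionConfig(),
    diagnostics: dict | None = None,
) -> tuple[CorrectionFunction, ElutionProfile, ElutionProfile]:
    """ICM estimation of f for one correctable isotope pair.

    Returns the converged correction function and the corrected profiles
    x1 = f(y1), x2 = f(y2) (on the full time grid; the fit itself uses the
    points inside the pair's peak interval).  When a ``diagnostics`` dict is
    supplied it receives the per-iteration ``deltas`` and the iteration count.

    Raises :class:`NotCorrectableError` if the pair fails the correction
    conditions and :class:`ConvergenceError` if ICM does not converge or the
    corrected area ratio disagrees with the theoretical isotope ratio.
    """
    verdict = check_correction_conditions(pair, config)
    if not verdict.correctable:
        raise NotCorrectableError(
            f"pair {pair.peptide.sequence} not correctable: {verdict.reason}"
        )
    interval = pair.interval
    if interval is None:
        # the fit is meaningful only over the elution peak; tail points far
        # below the peak would dominate the least-squares compromise
        interval = detect_peak_interval(pair.y1, pair.peptide.elution_time,
                                        rt_window_s=np.inf)
        pair = replace(pair, interval=interval)
    sl = interval.slice()
    y1 = pair.y1.intensities[sl]
    y2 = pair.y2.intensities[sl]
    usable = (y1 > config.intensity_floor) & (y2 > config.intensity_floor)
    if usable.sum() < config.min_points:
        raise ConvergenceError(
            f"degenerate peak: only {int(usable.sum())} usable points in interval"
        )
    y1u, y2u = y1[usable], y2[usable]
    r = pair.r
    T = y1u + y2u
    f = CorrectionFunction.identity(config.identity_threshold)
    prev_total = float(T.sum())
    delta = np.inf
    best_delta = np.inf
    since_improvement = 0
    for _ in range(config.max_iter):
        x1_target = T / (1.0 + r)
        x2_target = r * T / (1.0 + r)
        f = _fit_monotone_map(
            np.concatenate([y1u, y2u]),
            np.concatenate([x1_target, x2_target]),
            config,
        )
        x1u, x2u = f(y1u), f(y2u)
        T = x1u + x2u
        total = float(T.sum())
        delta = abs(total - prev_total) / max(prev_total, 1e-300)
        prev_total = total
        if diagnostics is not None:
            diagnostics.setdefault("deltas", []).append(delta)
        if delta < config.tol:
            break
        # with measurement noise the alternation can settle into a tiny limit
        # cycle instead of a fixed point; accept it once it stops improving
        if delta < 0.9 * best_delta:
            best_delta, since_improvement = delta, 0
        else:
            since_improvement += 1
            if since_improvement >= config.stall_iter and delta < config.stall_tol:
                break
    else:
        raise ConvergenceError(
            f"ICM did not converge in {config.max_iter} iterations "
            f"(last delta {delta:.3g})",
            last_delta=delta,
        )
    x1 = apply_correction(pair.y1, f)
    x2 = apply_correction(pair.y2, f)
    area1 = profile_area(x1, pair.interval)
    area2 = profile_area(x2, pair.interval)
    if area1 <= 0:
        raise ConvergenceError("zero corrected area")
    ratio = area2 / area1
    if abs(ratio - r) / r > config.ratio_tol:
        raise ConvergenceError(
            f"corrected area ratio {ratio:.4f} deviates from r={r:.4f} "
            f"beyond ratio_tol={config.ratio_tol}"
        )
    return f, x1, x2
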