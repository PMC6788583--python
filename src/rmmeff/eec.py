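"""Extrapolated-concentration estimation from decay traces.

After a solvent transfer ends, the airborne concentration in a well-mixed
room relaxes back to background as ``y(t) = y0 * exp(-k t)`` with ``t`` in
minutes from the end of the transfer.  The intercept ``y0`` — the
extrapolated ethanol concentration (EEC) — is the proxy used for the
emission level of the activity, and ``60 k`` must reproduce the room's
known air-exchange rate (about 1/h with room ventilation off, 11 +/- 1/h
with it on).  That physical constraint drives the choice of fit window:
among all candidate post-event windows on the sampling grid, only those
whose fitted ``60 k`` lies within tolerance of the target air-exchange
rate are admissible, and the longest admissible window (ties broken by
highest r-squared, then earliest start) defines the reported fit.

The reference fit is ordinary least squares on
``ln(conc - background)`` versus ``(t - t_end) / 60``; an optional
nonlinear least-squares refinement on the same window is available but the
log-linear fit defines the reference numbers.

:class:`EECEstimator` exposes this as a scikit-learn style estimator
(``fit`` / ``predict`` / ``get_params``); the module-level functions
(:func:`estimate_background`, :func:`select_decay_window`,
:func:`fit_decay`, :func:`compute_eec`) are thin wrappers over it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from .trace import ConcentrationTrace, TransferEvent

__all__ = [
    "DecayFit",
    "ScenarioSummary",
    "EECEstimator",
    "UnfittableTraceError",
    "NoPreEventDataError",
    "estimate_background",
    "select_decay_window",
    "fit_decay",
    "compute_eec",
    "mean_concentration_between",
    "summarize_scenario",
]


class UnfittableTraceError(ValueError):
    """No candidate window satisfies the air-exchange-rate constraint."""

    def __init__(self, target_ach: float, ach_tol: float,
                 best_ach_fit: float | None):
        self.target_ach = target_ach
        self.ach_tol = ach_tol
        self.best_ach_fit = best_ach_fit
        best = ("no candidate window at all" if best_ach_fit is None
                else f"best achieved air-exchange rate {best_ach_fit:.3f}/h")
        super().__init__(
            f"unfittable trace: no window with fitted air-exchange rate "
            f"within {target_ach} +/- {ach_tol}/h ({best})")


class NoPreEventDataError(ValueError):
    """Too few pre-event samples to estimate the background."""


@dataclass(frozen=True)
class DecayFit:
    """Result of the constrained exponential-decay fit.

    ``eec_ppm`` is the background-subtracted concentration extrapolated to
    the moment the transfer ended; ``ach_fit`` (= 60 * k) is the implied
    air-exchange rate.  ``flag`` is ``"ok"`` for a regular fit or
    ``"noe"`` when no emission is observable above background, in which
    case the numeric fields are NaN.
    """

    eec_ppm: float
    k_per_min: float
    window: tuple[int, int]        # [start, stop) sample indices
    background_ppm: float
    r_squared: float
    n_points: int
    flag: str = "ok"
    scenario_id: int | None = None
    replicate: int | None = None

    @property
    def ach_fit(self) -> float:
        return 60.0 * self.k_per_min

    @property
    def is_noe(self) -> bool:
        return self.flag == "noe"

    def __post_init__(self) -> None:
        if self.flag == "ok":
            if not (np.isfinite(self.eec_ppm) and self.eec_ppm >= 0):
                raise ValueError("eec_ppm must be finite and >= 0")
            if self.n_points < 3:
                raise ValueError("a decay fit needs at least 3 points")


def _noe_fit(background: float, trace: ConcentrationTrace) -> DecayFit:
    return DecayFit(float("nan"), float("nan"), (0, 0), background,
                    float("nan"), 0, flag="noe",
                    scenario_id=trace.scenario_id, replicate=trace.replicate)


def _prefix_ols(x: np.ndarray, y: np.ndarray):
    """Slope/intercept/r^2 of OLS on every prefix of (x, y), vectorised.

    Returns arrays indexed by prefix length - 1; entries for lengths < 2
    are undefined and must be masked by the caller.
    """
    n = np.arange(1, x.size + 1, dtype=float)
    cx, cy = np.cumsum(x), np.cumsum(y)
    cxx, cxy, cyy = np.cumsum(x * x), np.cumsum(x * y), np.cumsum(y * y)
    sxx = cxx - cx * cx / n
    sxy = cxy - cx * cy / n
    syy = cyy - cy * cy / n
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = sxy / sxx
        intercept = (cy - slope * cx) / n
        r2 = np.where(syy > 0, (sxy * sxy) / (sxx * syy), 1.0)
    return slope, intercept, r2


class EECEstimator(BaseEstimator):
    """Ventilation-constrained exponential-decay fit of a concentration trace.

    Parameters
    ----------
    target_ach : float or None
        Expected air-exchange rate in 1/h.  ``None`` means take it from
        the trace metadata at fit time.
    ach_tol : float
        Admissibility half-width for the fitted air-exchange rate
        (default 1.0/h, from the "11 +/- 1" ventilation-on band).
    floor_abs_ppm, floor_frac : float
        Positivity floor for fit points: background-subtracted samples at
        or below ``max(floor_abs_ppm, floor_frac * post-event peak excess)``
        are excluded (the log transform blows up near background).
    max_start_offset : int
        Candidate windows may start 0..max_start_offset samples after the
        first post-event sample.
    min_points : int
        Minimum candidate-window length on the sampling grid.
    noe_sd_multiple : float
        Declare "no observable emission" when no post-event sample exceeds
        background by more than this multiple of the pre-event sample
        standard deviation.
    method : {"log-ols", "nls"}
        "log-ols" (reference) or a nonlinear least-squares refinement of
        the same window, initialised at the log-OLS solution.

    Attributes (after ``fit``)
    --------------------------
    background_ppm_, window_, eec_ppm_, k_per_min_, ach_fit_, r_squared_,
    n_points_, floor_ppm_, noe_ : the fitted quantities; ``noe_`` is True
    when the trace shows no emission above background (numeric attributes
    are then NaN).
    """

    def __init__(self, target_ach: float | None = None, ach_tol: float = 1.0,
                 floor_abs_ppm: float = 0.1, floor_frac: float = 0.01,
                 max_start_offset: int = 10, min_points: int = 5,
                 noe_sd_multiple: float = 3.0, method: str = "log-ols"):
        self.target_ach = target_ach
        self.ach_tol = ach_tol
        self.floor_abs_ppm = floor_abs_ppm
        self.floor_frac = floor_frac
        self.max_start_offset = max_start_offset
        self.min_points = min_points
        self.noe_sd_multiple = noe_sd_multiple
        self.method = method

    # -- sklearn-style API -------------------------------------------------

    def fit(self, X, y=None, *, t_start_s: float | None = None,
            t_end_s: float | None = None, target_ach: float | None = None,
            background_ppm: float | None = None) -> "EECEstimator":
        """Fit the decay model to a sampled trace.

        ``X`` is either the sample times in seconds (with ``y`` the
        concentrations in ppm) or an (n, 2) array of ``[time_s, conc_ppm]``
        columns.  ``t_end_s`` (required) is the end of the transfer — the
        extrapolation origin; ``t_start_s`` marks the source-on time and is
        only needed when the background has to be estimated from the
        pre-event window.
        """
        X = np.asarray(X, dtype=float)
        if y is None:
            if X.ndim != 2 or X.shape[1] != 2:
                raise ValueError("without y, X must be an (n, 2) array of "
                                 "[time_s, conc_ppm]")
            times, conc = X[:, 0], X[:, 1]
        else:
            times = X.ravel()
            conc = np.asarray(y, dtype=float).ravel()
        if t_end_s is None:
            raise ValueError("t_end_s (end of transfer) is required")
        if t_start_s is None:
            if background_ppm is None:
                raise ValueError("t_start_s is required unless background_ppm "
                                 "is supplied")
            # no pre-event window: treat the whole record up to t_end as
            # potentially source-affected
            t_start_s = float(times.min())
            if not t_start_s < t_end_s:
                raise ValueError("t_end_s must lie after the first sample")
        trace = ConcentrationTrace(
            times, conc, TransferEvent(t_start_s, t_end_s),
            target_ach=(target_ach if target_ach is not None
                        else (self.target_ach or 0.0)))
        return self.fit_trace(trace, background_ppm=background_ppm)

    def fit_trace(self, trace: ConcentrationTrace, *,
                  background_ppm: float | None = None) -> "EECEstimator":
        """Fit directly from a :class:`ConcentrationTrace`."""
        target = self.target_ach if self.target_ach is not None else trace.target_ach
        if not target > 0:
            raise ValueError("a positive target air-exchange rate is required")
        if background_ppm is None:
            background_ppm = estimate_background(trace)
        self.t_end_s_ = float(trace.event.t_end_s)
        self.background_ppm_ = float(background_ppm)

        if self._is_noe(trace, background_ppm):
            self.noe_ = True
            self.window_ = (0, 0)
            self.eec_ppm_ = self.k_per_min_ = self.ach_fit_ = float("nan")
            self.r_squared_ = float("nan")
            self.n_points_ = 0
            self.floor_ppm_ = float("nan")
            return self

        self.noe_ = False
        window = self._select_window(trace, background_ppm, target)
        self.window_ = window
        eec, k, r2 = self._fit_window(trace, window, background_ppm)
        if self.method == "nls":
            eec, k = self._refine_nls(trace, window, background_ppm, eec, k)
        self.eec_ppm_ = eec
        self.k_per_min_ = k
        self.ach_fit_ = 60.0 * k
        self.r_squared_ = r2
        self.n_points_ = window[1] - window[0]
        return self

    def predict(self, T) -> np.ndarray:
        """Model concentration (background + fitted decay) at times T (s)."""
        if not hasattr(self, "eec_ppm_"):
            raise ValueError("estimator is not fitted")
        T = np.asarray(T, dtype=float)
        return (self.background_ppm_
                + self.eec_ppm_ * np.exp(-self.k_per_min_
                                         * (T - self.t_end_s_) / 60.0))

    def result_(self, trace: ConcentrationTrace | None = None) -> DecayFit:
        """The fit as a :class:`DecayFit` record."""
        sid = trace.scenario_id if trace is not None else None
        rep = trace.replicate if trace is not None else None
        if self.noe_:
            return DecayFit(float("nan"), float("nan"), (0, 0),
                            self.background_ppm_, float("nan"), 0,
                            flag="noe", scenario_id=sid, replicate=rep)
        return DecayFit(self.eec_ppm_, self.k_per_min_, self.window_,
                        self.background_ppm_, self.r_squared_,
                        self.n_points_, scenario_id=sid, replicate=rep)

    # -- internals ---------------------------------------------------------

    def _is_noe(self, trace: ConcentrationTrace, background: float) -> bool:
        pre = trace.conc_ppm[trace.pre_event_mask()]
        post = trace.conc_ppm[trace.post_event_mask()]
        if post.size == 0:
            return True
        pre_sd = float(np.std(pre, ddof=1)) if pre.size >= 2 else 0.0
        return not np.any(post - background
                          > self.noe_sd_multiple * pre_sd)

    def _admissible_run(self, trace: ConcentrationTrace, background: float):
        """First post-event index, run length above the floor, the floor."""
        i0 = int(np.searchsorted(trace.times_s, trace.event.t_end_s, "left"))
        excess = trace.conc_ppm[i0:] - background
        if excess.size == 0:
            return i0, 0, self.floor_abs_ppm
        floor = max(self.floor_abs_ppm, self.floor_frac * float(excess.max()))
        below = excess <= floor
        run = int(np.argmax(below)) if below.any() else excess.size
        return i0, run, floor

    def _select_window(self, trace: ConcentrationTrace, background: float,
                       target: float) -> tuple[int, int]:
        n_post = int(np.sum(trace.post_event_mask()))
        if n_post < 10:
            raise ValueError("need at least 10 samples after the end of the "
                             f"transfer, got {n_post}")
        i0, run, floor = self._admissible_run(trace, background)
        self.floor_ppm_ = floor
        if run < self.min_points:
            raise UnfittableTraceError(target, self.ach_tol, None)
        t_rel_min = (trace.times_s[i0:i0 + run] - trace.event.t_end_s) / 60.0
        ylog = np.log(trace.conc_ppm[i0:i0 + run] - background)

        best = None          # (n, r2, -start_offset, window)
        closest = None       # (|ach - target|, ach)
        max_off = min(self.max_start_offset, run - self.min_points)
        for s in range(0, max_off + 1):
            slope, _, r2 = _prefix_ols(t_rel_min[s:], ylog[s:])
            lengths = np.arange(1, run - s + 1)
            ok_len = lengths >= self.min_points
            ach = -slope * 60.0
            dist = np.abs(ach - target)
            # track closest-achieved rate for the error message
            if ok_len.any():
                j = int(np.argmin(np.where(ok_len, dist, np.inf)))
                if closest is None or dist[j] < closest[0]:
                    closest = (float(dist[j]), float(ach[j]))
            admissible = ok_len & (dist <= self.ach_tol)
            if admissible.any():
                max_len = int(lengths[admissible].max())
                at_max = admissible & (lengths == max_len)
                j = int(np.argmax(np.where(at_max, r2, -np.inf)))
                cand = (max_len, float(r2[j]), -s,
                        (i0 + s, i0 + s + max_len))
                if best is None or cand[:3] > best[:3]:
                    best = cand
        if best is None:
            raise UnfittableTraceError(
                target, self.ach_tol,
                closest[1] if closest is not None else None)
        return best[3]

    @staticmethod
    def _fit_window(trace: ConcentrationTrace, window: tuple[int, int],
                    background: float) -> tuple[float, float, float]:
        i, j = window
        if j - i < 3:
            raise ValueError("fit window must contain at least 3 points")
        excess = trace.conc_ppm[i:j] - background
        if np.any(excess <= 0):
            raise ValueError("window contains samples at or below background")
        x = (trace.times_s[i:j] - trace.event.t_end_s) / 60.0
        res = stats.linregress(x, np.log(excess))
        return float(np.exp(res.intercept)), float(-res.slope), float(res.rvalue ** 2)

    @staticmethod
    def _refine_nls(trace, window, background, eec0, k0):
        i, j = window
        x = (trace.times_s[i:j] - trace.event.t_end_s) / 60.0
        yv = trace.conc_ppm[i:j] - background
        popt, _ = optimize.curve_fit(
            lambda t, a, k: a * np.exp(-k * t), x, yv, p0=(eec0, k0),
            maxfev=10000)
        return float(popt[0]), float(popt[1])


# -- module-level operation wrappers ---------------------------------------

def estimate_background(trace: ConcentrationTrace) -> float:
    """Median concentration over the pre-event window [0, t_start).

    The median is robust to the occasional movement spike.  Requires at
    least 10 pre-event samples; supply the background manually otherwise.
    """
    pre = trace.conc_ppm[trace.pre_event_mask()]
    if pre.size < 10:
        raise NoPreEventDataError(
            f"only {pre.size} samples before the event; need >= 10 "
            "(or supply background_ppm explicitly)")
    return float(np.median(pre))


def select_decay_window(trace: ConcentrationTrace, background_ppm: float,
                        **params) -> tuple[int, int]:
    """Index range [start, stop) of post-event samples to fit.

    Enumerates candidate windows (start offset x length on the sampling
    grid) over the contiguous run of samples above the positivity floor,
    keeps those whose fitted air-exchange rate lies within
    ``target_ach +/- ach_tol``, and returns the longest (ties: highest
    r-squared, then earliest start).  Raises :class:`UnfittableTraceError`
    when no window satisfies the constraint.
    """
    est = EECEstimator(**params)
    target = est.target_ach if est.target_ach is not None else trace.target_ach
    if not target > 0:
        raise ValueError("a positive target air-exchange rate is required")
    return est._select_window(trace, background_ppm, target)


def fit_decay(trace: ConcentrationTrace, window: tuple[int, int],
              background_ppm: float) -> DecayFit:
    """Log-linear OLS fit of the given window; time origin at t_end."""
    eec, k, r2 = EECEstimator._fit_window(trace, window, background_ppm)
    return DecayFit(eec, k, window, background_ppm, r2, window[1] - window[0],
                    scenario_id=trace.scenario_id, replicate=trace.replicate)


def compute_eec(trace: ConcentrationTrace, **params) -> DecayFit:
    """Background estimate -> window selection -> decay fit, in one call.

    The public entry point for transfer traces.  Returns a
    :class:`DecayFit`; when the trace shows no concentration rise above
    background the result carries ``flag="noe"`` and NaN numerics.
    """
    if trace.trace_kind != "transfer":
        raise ValueError("compute_eec applies to transfer traces; use "
                         "mean_concentration_between for drain/flush traces")
    est = EECEstimator(**params)
    est.fit_trace(trace)
    return est.result_(trace)


def mean_concentration_between(trace: ConcentrationTrace) -> float:
    """Mean of all samples between the event markers, no background
    subtraction — the summary used when the concentration rise is too
    small and irregular for a decay fit (drain/flush traces)."""
    if trace.trace_kind != "drain_flush":
        raise ValueError("mean_concentration_between applies to drain/flush "
                         "traces")
    m = ((trace.times_s >= trace.event.t_start_s)
         & (trace.times_s <= trace.event.t_end_s))
    if not m.any():
        raise ValueError("no samples between the event markers")
    return float(trace.conc_ppm[m].mean())


@dataclass(frozen=True)
class ScenarioSummary:
    """Replicate emission values for one exposure scenario.

    ``values_ppm`` holds replicate extrapolated concentrations (transfer
    scenarios) or mean concentrations (drain/flush).  ``min_ppm`` /
    ``mean_ppm`` / ``max_ppm`` are the E_L / E_M / E_H inputs of the
    emission-reduction formulas; ``cv_percent`` uses the n-1 (sample)
    standard deviation.
    """

    scenario_id: int
    values_ppm: tuple[float, ...]
    mean_ppm: float
    min_ppm: float
    max_ppm: float
    cv_percent: float

    @property
    def n(self) -> int:
        return len(self.values_ppm)


def summarize_scenario(values_ppm, scenario_id: int) -> ScenarioSummary:
    """Mean / extrema / CV of a replicate set (>= 2 non-negative values)."""
    v = np.asarray(list(values_ppm), dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 replicate values")
    if not np.all(np.isfinite(v)) or np.any(v < 0):
        raise ValueError("replicate values must be finite and >= 0")
    mean = float(v.mean())
    sd = float(v.std(ddof=1))
    if sd == 0:
        cv = 0.0
    elif mean == 0:
        raise ValueError("CV undefined: zero mean with non-equal replicates")
    else:
        cv = 100.0 * sd / mean
    return ScenarioSummary(scenario_id, tuple(float(x) for x in v),
                           mean, float(v.min()), float(v.max()), cv)
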