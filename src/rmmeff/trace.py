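"""Concentration-trace containers.

A trace is a regularly sampled airborne-concentration time series (ppm vs
seconds) recorded by a stationary probe in a well-mixed room, together with
the event markers the downstream decay fit needs: for a solvent transfer the
source-on/source-off times (the fit's time origin is source-off), for a
drain/flush measurement the lid-open/lid-close times.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TransferEvent", "ConcentrationTrace"]

#: trace kinds: "transfer" traces get an extrapolated-concentration decay
#: fit; "drain_flush" traces are summarised by the mean concentration
#: between the event markers.
TRACE_KINDS = ("transfer", "drain_flush")


@dataclass(frozen=True)
class TransferEvent:
    """Source-on / source-off markers, in trace time (seconds).

    ``t_end_s`` is the moment the transfer (or lid-open period) ended and is
    the time origin of the decay extrapolation.
    """

    t_start_s: float
    t_end_s: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.t_start_s) and np.isfinite(self.t_end_s)):
            raise ValueError("event times must be finite")
        if not self.t_start_s < self.t_end_s:
            raise ValueError(
                f"t_start_s ({self.t_start_s}) must precede t_end_s ({self.t_end_s})"
            )

    def shifted(self, dt_s: float) -> "TransferEvent":
        return TransferEvent(self.t_start_s + dt_s, self.t_end_s + dt_s)


@dataclass
class ConcentrationTrace:
    """A validated concentration-time series with event metadata.

    Parameters
    ----------
    times_s : array-like
        Strictly increasing sample times in seconds, nominally on a regular
        grid (constant interval within 1%).
    conc_ppm : array-like
        Concentrations in ppm; finite and non-negative.
    event : TransferEvent
        Source (or lid) on/off markers; must lie inside the sampled span.
    target_ach : float
        Expected room air-exchange rate in 1/h (about 1 with room
        ventilation off, 11 +/- 1 with it on); constrains the decay fit.
    trace_kind : {"transfer", "drain_flush"}
    scenario_id, replicate : identifiers carried through reporting.
    """

    times_s: np.ndarray
    conc_ppm: np.ndarray
    event: TransferEvent
    target_ach: float
    trace_kind: str = "transfer"
    scenario_id: int | None = None
    replicate: int | None = None

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.conc_ppm = np.asarray(self.conc_ppm, dtype=float)
        if self.times_s.ndim != 1 or self.conc_ppm.ndim != 1:
            raise ValueError("times_s and conc_ppm must be 1-D")
        if self.times_s.shape != self.conc_ppm.shape:
            raise ValueError(
                f"length mismatch: {self.times_s.size} times vs "
                f"{self.conc_ppm.size} concentrations"
            )
        if self.times_s.size < 3:
            raise ValueError("trace needs at least 3 samples")
        dt = np.diff(self.times_s)
        if np.any(dt <= 0):
            i = int(np.argmax(dt <= 0))
            raise ValueError(f"times not strictly increasing at sample {i + 1}")
        # regular grid check: spread of intervals within 1% of the median
        dt_med = float(np.median(dt))
        if np.any(np.abs(dt - dt_med) > 0.01 * dt_med):
            i = int(np.argmax(np.abs(dt - dt_med) > 0.01 * dt_med))
            raise ValueError(
                f"sampling interval not constant within 1% at sample {i + 1}"
            )
        if not np.all(np.isfinite(self.conc_ppm)):
            raise ValueError("concentrations must be finite")
        if np.any(self.conc_ppm < 0):
            raise ValueError("concentrations must be non-negative")
        if self.trace_kind not in TRACE_KINDS:
            raise ValueError(f"trace_kind must be one of {TRACE_KINDS}")
        if not (self.times_s[0] <= self.event.t_start_s
                and self.event.t_end_s <= self.times_s[-1]):
            raise ValueError("event markers must lie within the sampled span")
        if not np.isfinite(self.target_ach) or self.target_ach < 0:
            raise ValueError("target_ach must be finite and >= 0")

    # -- convenience views -------------------------------------------------

    @property
    def sampling_interval_s(self) -> float:
        return float(np.median(np.diff(self.times_s)))

    def pre_event_mask(self) -> np.ndarray:
        """Samples recorded before the source switched on."""
        return self.times_s < self.event.t_start_s

    def post_event_mask(self) -> np.ndarray:
        """Samples at or after the end of the transfer (decay limb)."""
        return self.times_s >= self.event.t_end_s

    def shifted(self, dt_s: float) -> "ConcentrationTrace":
        """Same trace on a shifted clock (fit results are invariant)."""
        return ConcentrationTrace(
            self.times_s + dt_s, self.conc_ppm.copy(), self.event.shifted(dt_s),
            self.target_ach, self.trace_kind, self.scenario_id, self.replicate,
        )

    def scaled(self, c: float) -> "ConcentrationTrace":
        """Concentrations multiplied by ``c`` (ppm-scale equivariance)."""
        if c <= 0:
            raise ValueError("scale factor must be positive")
        return ConcentrationTrace(
            self.times_s.copy(), self.conc_ppm * c, self.event,
            self.target_ach, self.trace_kind, self.scenario_id, self.replicate,
        )
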