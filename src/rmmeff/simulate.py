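"""Well-mixed-room (one-box) simulator for solvent-transfer traces.

Generates IR-probe-like concentration-time series with the structure the
decay-extrapolation analysis assumes: a first-order ventilation loss at the
room air-exchange rate, a constant concentration-equivalent source during
the transfer phase, a low steady background, and optional measurement noise
(multiplicative lognormal scatter plus occasional transient spikes from air
movement / vapour pockets).

The governing model for the room-average concentration ``C`` (ppm) is

    dC/dt = S * 1[t_start, t_end](t) - lam * (C - B)

with ``S`` the source rate in ppm/min, ``lam = ach / 60`` the loss rate in
1/min and ``B`` the background.  The closed-form piecewise solution (rise
toward the plateau ``B + S/lam`` while the source is on, pure exponential
relaxation back to ``B`` afterwards) is the reference implementation; a
numerical integrator is used only as an independent test oracle.

Source strength is expressed directly as a concentration-equivalent rate
(ppm/min delivered to the mixed volume) — evaporation physics is out of
scope.  Scenario presets approximating the nine laboratory exposure
scenarios (gravity transfer, drum-pump transfer, drain/flush) are calibrated
so that the noiseless end-of-transfer excess concentration of the baseline
equals 454 ppm and the other presets scale by their reduction factors.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .trace import ConcentrationTrace, TransferEvent

__all__ = [
    "RoomModelParams",
    "NoiseModel",
    "ScenarioPreset",
    "PRESETS",
    "get_preset",
    "calibrated_source_rate",
    "simulate_trace",
    "simulate_preset",
    "generate_scenario_set",
    "BASELINE_EEC_PPM",
    "DRAIN_BASELINE_EEC_PPM",
]

#: calibration anchors: noiseless end-of-transfer excess concentration of
#: the two baseline scenarios (open gravity transfer; just-drained drum).
BASELINE_EEC_PPM = 454.0
DRAIN_BASELINE_EEC_PPM = 53.0


@dataclass(frozen=True)
class RoomModelParams:
    """Physical parameters of the simulated room and transfer.

    ``source_rate`` is the concentration-equivalent emission rate in
    ppm/min delivered to the well-mixed volume while the source is on.
    """

    volume_m3: float = 45.0
    ach: float = 1.0                  # air-exchange rate, 1/h
    background_ppm: float = 1.0
    source_rate: float = 0.0          # ppm/min while source on
    sampling_interval_s: float = 20.0
    duration_s: float = 3600.0

    def __post_init__(self) -> None:
        vals = dataclasses.asdict(self)
        if not all(np.isfinite(v) for v in vals.values()):
            raise ValueError("room-model parameters must be finite")
        if self.volume_m3 <= 0:
            raise ValueError("volume_m3 must be > 0")
        if self.ach < 0 or self.background_ppm < 0 or self.source_rate < 0:
            raise ValueError("ach, background_ppm, source_rate must be >= 0")
        if self.sampling_interval_s <= 0 or self.duration_s <= 0:
            raise ValueError("sampling_interval_s and duration_s must be > 0")


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise model for the simulated probe.

    multiplicative_sd
        Relative lognormal scatter per sample (the clean value is the
        median, so log-space regression is unbiased).
    spike_rate_per_min
        Poisson rate of transient positive spikes (personnel movement,
        vapour pockets).  Spikes decay with the room's own air-exchange
        rate — they are vapour, not instrument glitches.
    spike_magnitude_ppm
        Mean spike height (exponentially distributed).  ``None`` means
        10% of the clean concentration at spike onset.
    seed
        Identical seed, identical trace.
    """

    multiplicative_sd: float = 0.05
    spike_rate_per_min: float = 0.2
    spike_magnitude_ppm: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.multiplicative_sd < 0 or self.spike_rate_per_min < 0:
            raise ValueError("noise rates/sds must be >= 0")
        if self.spike_magnitude_ppm is not None and self.spike_magnitude_ppm < 0:
            raise ValueError("spike_magnitude_ppm must be >= 0")

    def with_seed(self, seed: int) -> "NoiseModel":
        return dataclasses.replace(self, seed=int(seed))


NOISELESS = NoiseModel(multiplicative_sd=0.0, spike_rate_per_min=0.0, seed=0)


@dataclass(frozen=True)
class ScenarioPreset:
    """One of the nine laboratory exposure scenarios.

    ``reduction_factor`` multiplies the family baseline's calibrated
    emission level (1.0 for the two baselines, 0.0 for the fully enclosed
    scenario whose emission is not observable above background).
    ``family`` selects the calibration anchor: "transfer" scenarios are
    calibrated against the 454 ppm gravity-transfer baseline, the
    "drain_flush" pair against the 53 ppm just-drained-drum baseline.
    """

    scenario_id: int
    label: str
    reduction_factor: float
    ach: float
    transfer_duration_min: float
    trace_kind: str = "transfer"
    family: str = "transfer"
    n_replicates_default: int = 3

    def __post_init__(self) -> None:
        if not 0.0 <= self.reduction_factor <= 1.0:
            raise ValueError("reduction_factor must lie in [0, 1]")
        if self.scenario_id in (1, 8) and self.reduction_factor != 1.0:
            raise ValueError("baseline presets (1, 8) must have reduction_factor 1")

    @property
    def anchor_ppm(self) -> float:
        return (BASELINE_EEC_PPM if self.family == "transfer"
                else DRAIN_BASELINE_EEC_PPM)

    @property
    def target_excess_ppm(self) -> float:
        """Noiseless end-of-transfer excess (transfer traces) or mean
        excess over the lid-open window (drain/flush traces)."""
        return self.reduction_factor * self.anchor_ppm


# Gravity transfer of 50 l at ~12.5 l/min takes 4 min; drum-pump transfer at
# ~50 l/min takes 1 min.  Room ventilation off: ach ~1/h; on: 11 +/- 1/h.
PRESETS: tuple[ScenarioPreset, ...] = (
    ScenarioPreset(1, "Baseline - open gravity transfer (splash loading), "
                      "no exhaust or ventilation", 1.0, 1.0, 4.0,
                   n_replicates_default=5),
    ScenarioPreset(2, "Vented open gravity transfer with partial enclosure",
                   6.0 / 454.0, 11.0, 4.0, n_replicates_default=5),
    ScenarioPreset(3, "Vented gravity transfer with full enclosure",
                   0.0, 11.0, 4.0),
    ScenarioPreset(4, "Gravity transfer with local exhaust (elephant trunk), "
                      "no enclosure", 13.0 / 454.0, 11.0, 4.0),
    ScenarioPreset(5, "Drum pump transfer (submerged loading), no exhaust or "
                      "ventilation", 29.0 / 454.0, 1.0, 1.0),
    ScenarioPreset(6, "Vented drum pump transfer with partial enclosure",
                   2.0 / 454.0, 11.0, 1.0),
    ScenarioPreset(7, "Drum pump transfer with local exhaust and room "
                      "ventilation", 5.0 / 454.0, 11.0, 1.0),
    ScenarioPreset(8, "Just-drained drum, lid removed, no ventilation "
                      "(drain/flush baseline)", 1.0, 1.0, 1.0,
                   family="drain_flush"),
    ScenarioPreset(9, "Drained and flushed drum, lid open, no ventilation",
                   1.5 / 53.0, 1.0, 4.0, trace_kind="drain_flush",
                   family="drain_flush"),
)


def get_preset(scenario_id: int) -> ScenarioPreset:
    for p in PRESETS:
        if p.scenario_id == scenario_id:
            return p
    raise KeyError(f"no preset for scenario {scenario_id}")


def calibrated_source_rate(target_excess_ppm: float, ach: float,
                           duration_min: float, *,
                           mode: str = "end") -> float:
    """Source rate (ppm/min) reaching a stated excess concentration.

    ``mode="end"`` targets the excess at the end of the source-on phase
    (the quantity the decay fit extrapolates to); ``mode="mean"`` targets
    the time-average excess over the source-on window (the drain/flush
    summary statistic).
    """
    if target_excess_ppm < 0 or duration_min <= 0 or ach < 0:
        raise ValueError("invalid calibration inputs")
    if target_excess_ppm == 0:
        return 0.0
    lam = ach / 60.0  # 1/min
    d = duration_min
    if mode == "end":
        if lam == 0:
            return target_excess_ppm / d
        return target_excess_ppm * lam / -np.expm1(-lam * d)
    if mode == "mean":
        if lam == 0:
            return 2.0 * target_excess_ppm / d
        shape = 1.0 + np.expm1(-lam * d) / (lam * d)  # mean/plateau ratio
        return target_excess_ppm * lam / shape
    raise ValueError("mode must be 'end' or 'mean'")


def _clean_concentration(t_s: np.ndarray, params: RoomModelParams,
                         event: TransferEvent) -> np.ndarray:
    """Closed-form piecewise solution of the one-box balance, in ppm."""
    lam = params.ach / 60.0  # 1/min
    B, S = params.background_ppm, params.source_rate
    t_min = np.asarray(t_s, dtype=float) / 60.0
    t0, t1 = event.t_start_s / 60.0, event.t_end_s / 60.0
    c = np.full_like(t_min, B)
    on = (t_min >= t0) & (t_min < t1)
    after = t_min >= t1
    if lam > 0:
        c[on] = B + (S / lam) * -np.expm1(-lam * (t_min[on] - t0))
        e_end = (S / lam) * -np.expm1(-lam * (t1 - t0))
        c[after] = B + e_end * np.exp(-lam * (t_min[after] - t1))
    else:
        c[on] = B + S * (t_min[on] - t0)
        c[after] = B + S * (t1 - t0)
    return c


def simulate_trace(params: RoomModelParams, event: TransferEvent,
                   noise: NoiseModel = NOISELESS, *,
                   trace_kind: str = "transfer",
                   scenario_id: int | None = None,
                   replicate: int | None = None) -> ConcentrationTrace:
    """Simulate one probe recording on the regular sampling grid.

    Samples start at t = 0 and are emitted every ``sampling_interval_s``
    up to ``duration_s``.  Deterministic for a fixed noise seed; all
    samples are non-negative.
    """
    if event.t_end_s >= params.duration_s:
        raise ValueError("duration_s too short to contain the event")
    if event.t_start_s < 0:
        raise ValueError("event must start at or after t = 0")
    t = np.arange(0.0, params.duration_s + 0.5 * params.sampling_interval_s,
                  params.sampling_interval_s)
    c = _clean_concentration(t, params, event)

    rng = np.random.default_rng(noise.seed)
    # transient spikes: vapour pockets decaying at the room's own rate
    lam = params.ach / 60.0
    n_spikes = rng.poisson(noise.spike_rate_per_min * params.duration_s / 60.0)
    if n_spikes > 0:
        ts = np.sort(rng.uniform(0.0, params.duration_s, n_spikes))
        u = rng.exponential(1.0, n_spikes)
        for tk, uk in zip(ts, u):
            mean_amp = (noise.spike_magnitude_ppm
                        if noise.spike_magnitude_ppm is not None
                        else 0.1 * float(np.interp(tk, t, c)))
            mask = t >= tk
            c[mask] += uk * mean_amp * np.exp(-lam * (t[mask] - tk) / 60.0)
    if noise.multiplicative_sd > 0:
        c = c * np.exp(noise.multiplicative_sd * rng.standard_normal(t.size))
    c = np.maximum(c, 0.0)
    return ConcentrationTrace(t, c, event, target_ach=params.ach,
                              trace_kind=trace_kind, scenario_id=scenario_id,
                              replicate=replicate)


def _preset_setup(preset: ScenarioPreset,
                  background_ppm: float = 1.0,
                  pre_event_s: float = 240.0,
                  ) -> tuple[RoomModelParams, TransferEvent]:
    """Room parameters and event markers for a scenario preset.

    The trace opens with a quiet pre-event window (background estimation),
    then the source-on phase, then enough decay tail for the fit: an hour
    with room ventilation off (slow ~1/h decay), half an hour with it on.
    """
    mode = "mean" if preset.trace_kind == "drain_flush" else "end"
    src = calibrated_source_rate(preset.target_excess_ppm, preset.ach,
                                 preset.transfer_duration_min, mode=mode)
    t_end = pre_event_s + preset.transfer_duration_min * 60.0
    tail_s = 3600.0 if preset.ach <= 2.0 else 1800.0
    params = RoomModelParams(ach=preset.ach, background_ppm=background_ppm,
                             source_rate=src, duration_s=t_end + tail_s)
    return params, TransferEvent(pre_event_s, t_end)


def simulate_preset(preset: ScenarioPreset | int, *,
                    noise: NoiseModel = NOISELESS,
                    replicate: int = 1,
                    background_ppm: float = 1.0) -> ConcentrationTrace:
    """Simulate one replicate of a scenario preset."""
    if isinstance(preset, int):
        preset = get_preset(preset)
    params, event = _preset_setup(preset, background_ppm=background_ppm)
    return simulate_trace(params, event, noise, trace_kind=preset.trace_kind,
                          scenario_id=preset.scenario_id, replicate=replicate)


def replicate_seed(base_seed: int, scenario_id: int, replicate: int) -> int:
    """Deterministic per-trace seed derived from a base seed (< 2**31)."""
    ss = np.random.SeedSequence(int(base_seed),
                                spawn_key=(int(scenario_id), int(replicate)))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def generate_scenario_set(presets: list[ScenarioPreset] | tuple[ScenarioPreset, ...],
                          n_replicates: int | None = None,
                          noise: NoiseModel = NoiseModel(),
                          *, background_ppm: float = 1.0,
                          ) -> list[ConcentrationTrace]:
    """Simulate a full replicate set: one trace per (preset, replicate).

    ``n_replicates=None`` uses each preset's default replicate count.
    Per-trace seeds are derived deterministically from ``noise.seed``, so
    the whole set is reproducible from the one base seed.
    """
    presets = list(presets)
    if not presets:
        raise ValueError("preset list must not be empty")
    if n_replicates is not None and n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    traces: list[ConcentrationTrace] = []
    for p in presets:
        n = n_replicates if n_replicates is not None else p.n_replicates_default
        for rep in range(1, n + 1):
            nz = noise.with_seed(replicate_seed(noise.seed, p.scenario_id, rep))
            traces.append(simulate_preset(p, noise=nz, replicate=rep,
                                          background_ppm=background_ppm))
    return traces
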