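"""Volume-controlled ventilation trace synthesis for the SLS lung.

Generates sampled pressure/flow/volume traces for continuous mandatory
ventilation (CMV) with an inspiratory pause, emulating what a ventilator
datalogger would record from the physical bellows simulator:

* inspiration — constant flow Q delivering the tidal volume, airway
  pressure ``Raw*Q + V(t)/C`` plus the actuator's end-inspiratory pressure;
* inspiratory pause — flow occluded at zero; without the actuator the
  pressure sits at the plateau ``VT/C``; with it, the plateau is topped by
  the actuator's relaxation decay (exponential in phenomenological mode,
  force-model driven in mechanistic mode);
* expiration — passive single-compartment emptying with time constant
  ``Raw*C`` (cosmetic realism: the analysis pipeline only uses inspiration
  and pause).

Phase boundaries snap to the sample grid and the constant inspiratory flow
is rescaled to the snapped flow time so the trapezoid-integrated delivered
volume equals the set tidal volume exactly. The actuator's pause clock
starts at the first zero-flow sample, matching the landmark convention
that the relaxation time origin is the instant flow reaches zero.

Measurement noise is additive white Gaussian on pressure; replicate
variability is a per-cycle Gaussian perturbation of the actuator drop
amplitude, calibrated by default to the bench replicate spreads
(SD 0.22 / 0.17 cmH2O at AB 25 / 30 mm).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from pydantic import BaseModel, ConfigDict, model_validator
from scipy.integrate import cumulative_trapezoid

from .actuator import Actuator

__all__ = [
    "VentilatorSettings",
    "LungSettings",
    "NoiseModel",
    "PressureTrace",
    "simulate_cycle",
    "simulate_run",
    "DEFAULT_SAMPLING_RATE",
]

#: Datalogger acquisition rate, Hz.
DEFAULT_SAMPLING_RATE = 31.25


class VentilatorSettings(BaseModel):
    """CMV settings: rate (breaths/min), tidal volume (mL), pause fraction
    of the cycle period, airway resistance Raw (cmH2O/L/s) and the fraction
    of the cycle spent delivering flow."""

    model_config = ConfigDict(frozen=True)

    respiratory_rate: float = 13.0
    tidal_volume: float = 150.0
    pause_fraction: float = 0.20
    Raw: float = 18.0
    insp_flow_fraction: float = 0.25

    @model_validator(mode="after")
    def _check(self) -> "VentilatorSettings":
        if not self.respiratory_rate > 0:
            raise ValueError("respiratory_rate must be positive")
        if not self.tidal_volume > 0:
            raise ValueError("tidal_volume must be positive")
        if self.Raw < 0:
            raise ValueError("Raw must be non-negative")
        if not 0 <= self.pause_fraction <= 0.5:
            raise ValueError("pause_fraction must be in [0, 0.5]")
        if not 0 < self.insp_flow_fraction < 1:
            raise ValueError("insp_flow_fraction must be in (0, 1)")
        if self.insp_flow_fraction + self.pause_fraction >= 1:
            raise ValueError(
                "insp_flow_fraction + pause_fraction must be < 1 "
                "(some of the cycle must remain for expiration)"
            )
        return self

    @property
    def cycle_period(self) -> float:
        return 60.0 / self.respiratory_rate


class LungSettings(BaseModel):
    """Single-compartment lung: exactly one of ``compliance`` (mL/cmH2O)
    or ``E0_override`` (cmH2O, the plateau pressure at the set tidal
    volume) must be given."""

    model_config = ConfigDict(frozen=True)

    compliance: float | None = None
    E0_override: float | None = None

    @model_validator(mode="after")
    def _check(self) -> "LungSettings":
        if (self.compliance is None) == (self.E0_override is None):
            raise ValueError(
                "exactly one of compliance or E0_override must be set"
            )
        if self.compliance is not None and not self.compliance > 0:
            raise ValueError("compliance must be positive")
        if self.E0_override is not None and not self.E0_override > 0:
            raise ValueError("E0_override must be positive")
        return self

    def effective_compliance(self, tidal_volume: float) -> float:
        """Compliance in mL/cmH2O (derived from E0_override if needed)."""
        if self.compliance is not None:
            return self.compliance
        return tidal_volume / self.E0_override

    def plateau_pressure(self, tidal_volume: float) -> float:
        """End-inspiratory elastic (plateau) pressure, cmH2O."""
        if self.E0_override is not None:
            return self.E0_override
        return tidal_volume / self.compliance


class NoiseModel(BaseModel):
    """Measurement + replicate noise. ``pressure_sd`` is additive white
    Gaussian per pressure sample (cmH2O); ``drop_sd`` perturbs the actuator
    drop amplitude once per cycle (cmH2O). Same seed + config reproduce the
    trace bit for bit."""

    model_config = ConfigDict(frozen=True)

    pressure_sd: float = 0.1
    drop_sd: float = 0.0
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "NoiseModel":
        if self.pressure_sd < 0 or self.drop_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        return self


@dataclass
class PressureTrace:
    """Uniformly sampled time/pressure/flow/volume series.

    ``cycle_index`` marks which ventilatory cycle each sample belongs to;
    volume is the running trapezoid integral of flow within each cycle.
    """

    sampling_rate: float
    time: np.ndarray
    pressure: np.ndarray
    flow: np.ndarray
    volume: np.ndarray
    cycle_index: np.ndarray = field(default=None)

    def __post_init__(self):
        n = len(self.time)
        if self.cycle_index is None:
            self.cycle_index = np.zeros(n, dtype=int)
        for name in ("pressure", "flow", "volume", "cycle_index"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length differs from time")

    @property
    def n_cycles(self) -> int:
        return int(self.cycle_index.max()) + 1 if len(self.time) else 0

    def cycle(self, i: int) -> "PressureTrace":
        """View of cycle ``i`` with time rebased to its first sample."""
        m = self.cycle_index == i
        if not m.any():
            raise IndexError(f"no cycle {i} in trace")
        return PressureTrace(
            sampling_rate=self.sampling_rate,
            time=self.time[m] - self.time[m][0],
            pressure=self.pressure[m],
            flow=self.flow[m],
            volume=self.volume[m],
            cycle_index=np.zeros(m.sum(), dtype=int),
        )


def _cycle_arrays(
    vent: VentilatorSettings,
    lung: LungSettings,
    actuator: Actuator | None,
    sampling_rate: float,
    drop_scale: float,
):
    """Noiseless single-cycle synthesis on the sample grid."""
    dt = 1.0 / sampling_rate
    period = vent.cycle_period
    n_total = int(round(period * sampling_rate))
    n_flow = max(int(round(vent.insp_flow_fraction * period * sampling_rate)), 1)
    n_pause = int(round(vent.pause_fraction * period * sampling_rate))
    if n_flow + n_pause >= n_total:
        raise ValueError("cycle too short for the configured phase fractions")

    c_ml = lung.effective_compliance(vent.tidal_volume)  # mL/cmH2O
    q = vent.tidal_volume / 1000.0 / (n_flow * dt)  # L/s, conserves VT on grid

    flow = np.zeros(n_total)
    flow[1 : n_flow + 1] = q  # zero at k=0 so the trapezoid edge is exact

    # Passive expiration: V' = -V / (Raw*C); first expiratory sample index.
    k_exp = n_flow + n_pause + 1
    tau_exp = vent.Raw * c_ml / 1000.0  # s
    n_exp = n_total - k_exp
    vt_l = vent.tidal_volume / 1000.0
    if n_exp > 0:
        if tau_exp > 0:
            t_exp = np.arange(n_exp) * dt
            profile = -(vt_l / tau_exp) * np.exp(-t_exp / tau_exp)
            # The flow step at expiration onset biases the trapezoid
            # integral; rescale so the trapezoid-exhaled volume matches the
            # analytic single-compartment decay (keeps the volume column an
            # exact running trapezoid of flow, ending non-negative).
            raw_drop = -np.trapezoid(np.concatenate([[0.0], profile]), dx=dt)
            target_drop = vt_l * (1.0 - np.exp(-n_exp * dt / tau_exp))
            flow[k_exp:] = profile * (target_drop / raw_drop)
        else:
            flow[k_exp] = -2.0 * vt_l / dt  # instantaneous emptying

    volume = np.concatenate(
        [[0.0], cumulative_trapezoid(flow, dx=dt) * 1000.0]
    )  # mL

    time = np.arange(n_total) * dt
    elastic = volume / c_ml
    # The trapezoid volume column lags the analytic ramp by half a flow
    # step, which would shave Raw*Q-independent pressure off the peak
    # sample; the elastic term during inspiration therefore follows the
    # analytic ramp (exactly VT/C at the end-inspiratory sample) so the
    # decomposition Ppeak = Raw*Q + plateau + actuator holds exactly.
    elastic[: n_flow + 1] = (
        np.arange(n_flow + 1) / n_flow * (vent.tidal_volume / c_ml)
    )
    pressure = vent.Raw * flow + elastic

    if actuator is not None:
        act = np.empty(n_total)
        act[: n_flow + 1] = actuator.end_inspiratory_pressure(drop_scale)
        t_pause = (np.arange(n_total - n_flow - 1)) * dt
        act[n_flow + 1 :] = actuator.pause_pressure(t_pause, drop_scale)
        pressure = pressure + act

    return time, pressure, flow, volume


def simulate_cycle(
    vent: VentilatorSettings,
    lung: LungSettings,
    actuator: Actuator | None = None,
    noise: NoiseModel | None = None,
    sampling_rate: float = DEFAULT_SAMPLING_RATE,
) -> PressureTrace:
    """Simulate one CMV cycle; see module docstring for the phase model."""
    return simulate_run(vent, lung, actuator, noise, 1, sampling_rate)


def simulate_run(
    vent: VentilatorSettings,
    lung: LungSettings,
    actuator: Actuator | None = None,
    noise: NoiseModel | None = None,
    n_cycles: int = 1,
    sampling_rate: float = DEFAULT_SAMPLING_RATE,
) -> PressureTrace:
    """Simulate ``n_cycles`` consecutive cycles.

    Cycles are identical up to noise: each cycle draws its own actuator
    drop perturbation (``drop_sd``) and its own pressure noise. With a
    fixed seed the trace is bit-reproducible.
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    rng = (
        np.random.default_rng(noise.seed) if noise is not None else None
    )
    e1_nominal = actuator.e1_equiv if actuator is not None else 0.0

    parts = []
    for i in range(n_cycles):
        drop_scale = 1.0
        if rng is not None and actuator is not None and noise.drop_sd > 0 and e1_nominal > 0:
            drop_scale = 1.0 + rng.normal(0.0, noise.drop_sd) / e1_nominal
        t, p, f, v = _cycle_arrays(vent, lung, actuator, sampling_rate, drop_scale)
        if rng is not None and noise.pressure_sd > 0:
            p = p + rng.normal(0.0, noise.pressure_sd, size=p.shape)
        parts.append((t, p, f, v))

    n = len(parts[0][0])
    dt = 1.0 / sampling_rate
    time = np.concatenate([t + i * n * dt for i, (t, *_ ) in enumerate(parts)])
    pressure = np.concatenate([p for _, p, _, _ in parts])
    flow = np.concatenate([f for _, _, f, _ in parts])
    volume = np.concatenate([v for _, _, _, v in parts])
    cyc = np.repeat(np.arange(n_cycles), n)
    return PressureTrace(
        sampling_rate=sampling_rate,
        time=time,
        pressure=pressure,
        flow=flow,
        volume=volume,
        cycle_index=cyc,
    )
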