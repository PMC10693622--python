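"""Magnet–pneumatic-cylinder actuator: force law, kinematics, calibration.

The physical mechanism: a magnet on a pneumatic cylinder rod faces a
same-pole magnet glued to the bottom of the lung-simulator bellows. The
repulsion force raises the internal bellows pressure by an amount set by
the magnet separation ("AB distance") at end-inspiration. At the moment of
the inspiratory pause the cylinder's return stroke pulls the rod magnet
away at a speed set by a PWM duty cycle on a proportional valve; the force
— and with it the extra bellows pressure — decays, emulating viscoelastic
stress relaxation. AB distance therefore controls the elastic magnitude
(the E1-equivalent pressure) and PWM the decay speed (eta, hence tau).

The force–distance law is calibrated to bench measurements: the repulsion
force at the 10 mm baseline separation and the percentage force decay after
10 s of constant-speed separation at 30 / 50 / 80 mm/min (which place
three more force anchors at 15, 18.33 and 23.33 mm). The construction is a
power-law-with-offset backbone fitted to the anchors, corrected by a
monotone (PCHIP) multiplicative interpolant so every anchor is reproduced
exactly. A synthetic far-field anchor at baseline + stroke (80 mm, 0.5% of
the baseline force) pins the tail, which the bench data do not reach.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from pydantic import BaseModel, ConfigDict, model_validator
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq, curve_fit

__all__ = [
    "MagnetForceModel",
    "ActuatorSettings",
    "ActuatorCalibration",
    "Actuator",
    "magnet_force",
    "force_decay_timecourse",
    "pwm_to_tau",
    "actuator_pressure",
    "BASELINE_DISTANCE_MM",
    "STROKE_MM",
    "MAGNET_ANCHOR_FORCES_N",
    "DECAY_ANCHORS",
]

#: Bench-characterisation baseline magnet separation, mm.
BASELINE_DISTANCE_MM = 10.0
#: Cylinder stroke (rod travel during extension/return), mm.
STROKE_MM = 70.0
#: Repulsion force at the 10 mm baseline for each characterised magnet pair
#: (rod magnet is always the 4 mm neodymium disc), newtons.
MAGNET_ANCHOR_FORCES_N = {
    "neodymium-4mm": 6.91,
    "neodymium-2mm": 2.60,
    "ceramic-4mm": 1.59,
}
#: (separation speed mm/min, % force decay after 10 s) bench anchors,
#: measured for the neodymium-4mm/neodymium-4mm pair.
DECAY_ANCHORS = ((30.0, 46.74), (50.0, 64.25), (80.0, 79.16))

CMH2O_PER_PA = 1.0 / 98.0665
#: Pressure (cmH2O) exerted by 1 N over 1 cm^2.
CMH2O_PER_N_PER_CM2 = 1.0 / (98.0665 * 1e-4)


def _power_law(d, A, c, n):
    return A / (d - c) ** n


@dataclass(frozen=True)
class MagnetForceModel:
    """Monotone force–distance law through the bench anchors.

    ``F(d) = backbone(d) * correction(d)`` where the backbone is
    ``A / (d - c)^n`` least-squares fitted (in log space) to the anchor set
    and the correction is a PCHIP interpolant of the residual ratios,
    clamped to its end values outside the anchor range. Anchors are
    reproduced exactly by construction.

    The decay anchors were measured only for the neodymium-4mm pair; the
    other pairs reuse that decay shape rescaled to their own baseline force
    (a documented assumption — their own time-domain curves were not
    characterised numerically).
    """

    magnet_pair_id: str = "neodymium-4mm"
    baseline_distance: float = BASELINE_DISTANCE_MM
    anchor_force_at_baseline: float = MAGNET_ANCHOR_FORCES_N["neodymium-4mm"]
    decay_anchors: tuple[tuple[float, float], ...] = DECAY_ANCHORS
    #: Synthetic far-field pin (distance mm, force fraction of baseline);
    #: not a bench measurement.
    farfield_anchor: tuple[float, float] = (
        BASELINE_DISTANCE_MM + STROKE_MM,
        0.005,
    )
    _backbone: tuple[float, float, float] = field(init=False, repr=False, default=(0, 0, 0))
    _correction: PchipInterpolator = field(init=False, repr=False, default=None)
    _anchor_d: np.ndarray = field(init=False, repr=False, default=None)

    @classmethod
    def for_pair(cls, magnet_pair_id: str) -> "MagnetForceModel":
        try:
            anchor = MAGNET_ANCHOR_FORCES_N[magnet_pair_id]
        except KeyError:
            raise KeyError(
                f"unknown magnet pair {magnet_pair_id!r}; "
                f"known: {sorted(MAGNET_ANCHOR_FORCES_N)}"
            ) from None
        return cls(magnet_pair_id=magnet_pair_id, anchor_force_at_baseline=anchor)

    def __post_init__(self) -> None:
        d0 = self.baseline_distance
        f0 = self.anchor_force_at_baseline
        dists = [d0]
        forces = [f0]
        for speed, pct in self.decay_anchors:
            dists.append(d0 + speed / 60.0 * 10.0)  # 10 s of travel
            forces.append(f0 * (1.0 - pct / 100.0))
        dists.append(self.farfield_anchor[0])
        forces.append(f0 * self.farfield_anchor[1])
        d = np.asarray(dists)
        f = np.asarray(forces)

        popt, _ = curve_fit(
            lambda x, logA, c, n: logA - n * np.log(x - c),
            d,
            np.log(f),
            p0=(np.log(f0) + 2.0, -10.0, 2.0),
            bounds=((-np.inf, -500.0, 0.1), (np.inf, d0 - 1e-6, 20.0)),
            maxfev=20000,
        )
        logA, c, n = popt
        backbone = (float(np.exp(logA)), float(c), float(n))
        ratios = f / _power_law(d, *backbone)
        correction = PchipInterpolator(d, np.log(ratios), extrapolate=False)
        object.__setattr__(self, "_backbone", backbone)
        object.__setattr__(self, "_correction", correction)
        object.__setattr__(self, "_anchor_d", d)

        # Constraint: the constructed law must be strictly decreasing.
        grid = np.linspace(d0, d[-1] + 50.0, 2000)
        vals = self.force(grid)
        if np.any(np.diff(vals) >= 0):
            raise RuntimeError(
                "calibrated force law is not strictly decreasing; "
                "anchor set inconsistent with a monotone law"
            )

    def force(self, distance):
        """Repulsion force in newtons at magnet separation ``distance`` mm."""
        d = np.asarray(distance, dtype=float)
        if np.any(d < self.baseline_distance - 1e-12):
            raise ValueError(
                f"distance below characterised baseline "
                f"({self.baseline_distance} mm): uncharacterised region"
            )
        dmin, dmax = self._anchor_d[0], self._anchor_d[-1]
        clipped = np.clip(d, dmin, dmax)
        log_r = self._correction(clipped)
        out = _power_law(d, *self._backbone) * np.exp(log_r)
        return float(out) if np.isscalar(distance) or d.ndim == 0 else out


def magnet_force(model: MagnetForceModel, distance):
    """Evaluate ``model`` at ``distance`` (mm); thin functional wrapper."""
    return model.force(distance)


def force_decay_timecourse(
    model: MagnetForceModel,
    separation_speed: float,
    duration: float,
    sampling_rate: float = 50.0,
):
    """Percent force decay vs time for constant-speed magnet separation.

    Emulates the bench tensile-rig experiment: starting at the baseline
    separation, the magnets move apart at ``separation_speed`` mm/min and
    the decay is ``100 * (1 - F(baseline + speed*t) / F(baseline))``.

    Returns ``(time_s, decay_percent)`` sampled at ``sampling_rate``
    (default 50 Hz, the bench acquisition rate), including ``t=0`` and
    ``t=duration``.
    """
    if separation_speed <= 0:
        raise ValueError("separation speed must be positive")
    n = int(round(duration * sampling_rate))
    t = np.linspace(0.0, duration, n + 1)
    d = model.baseline_distance + separation_speed / 60.0 * t
    f0 = model.force(model.baseline_distance)
    decay = 100.0 * (1.0 - model.force(d) / f0)
    return t, decay


class ActuatorSettings(BaseModel):
    """Operator-facing actuator configuration.

    AB_distance is the magnet separation at end-inspiration (mm, >= the
    10 mm characterisation baseline); PWM the proportional-valve duty cycle
    (%) governing the return-stroke speed. ``mode`` selects how the pause
    pressure decay is generated: ``phenomenological`` uses the calibrated
    exponential E1·exp(-t/tau) directly; ``mechanistic`` moves the rod
    magnet at the calibrated return speed and converts force to pressure
    through ``effective_area`` (cm^2).
    """

    model_config = ConfigDict(frozen=True)

    AB_distance: float = 25.0
    PWM: float = 74.51
    stroke: float = STROKE_MM
    mode: Literal["phenomenological", "mechanistic"] = "phenomenological"
    effective_area: float | None = None
    magnet_pair_id: str = "neodymium-4mm"

    @model_validator(mode="after")
    def _check(self) -> "ActuatorSettings":
        if not 0 <= self.PWM <= 100:
            raise ValueError(f"PWM must be in [0, 100] %, got {self.PWM}")
        if self.AB_distance < BASELINE_DISTANCE_MM:
            raise ValueError(
                f"AB_distance must be >= baseline {BASELINE_DISTANCE_MM} mm"
            )
        if not self.stroke > 0:
            raise ValueError("stroke must be positive")
        return self


@dataclass(frozen=True)
class ActuatorCalibration:
    """Maps bench settings to SLS-equivalent parameters.

    * ``e1_by_ab``: AB distance (mm) -> E1-equivalent pressure drop (cmH2O).
    * ``eta_by_pwm_ab``: (PWM %, AB mm) -> fitted viscosity (cmH2O*s);
      tau is derived as eta / E1.
    * ``drop_sd_by_ab``: replicate-to-replicate SD of the measured drop
      (cmH2O), used to drive the replicate noise model.

    The default calibration is the fitted-parameter set from the bench
    2x2 runs: E1 = 3.48 / 2.20 cmH2O at AB 25 / 30 mm; eta = 1.181, 0.403,
    1.166, 0.442 cmH2O*s at (PWM, AB) = (68.63, 25), (74.51, 25),
    (68.63, 30), (74.51, 30). Interpolation between calibrated points is
    linear (bilinear for eta); values requested outside the calibrated
    range are linearly extrapolated with a warning.
    """

    e1_by_ab: dict[float, float]
    eta_by_pwm_ab: dict[tuple[float, float], float]
    drop_sd_by_ab: dict[float, float] = field(default_factory=dict)
    provenance: str = "bench 2x2 fitted parameters"

    @classmethod
    def default(cls) -> "ActuatorCalibration":
        return cls(
            e1_by_ab={25.0: 3.48, 30.0: 2.20},
            eta_by_pwm_ab={
                (68.63, 25.0): 1.181,
                (74.51, 25.0): 0.403,
                (68.63, 30.0): 1.166,
                (74.51, 30.0): 0.442,
            },
            drop_sd_by_ab={25.0: 0.22, 30.0: 0.17},
        )

    @property
    def ab_points(self) -> np.ndarray:
        return np.asarray(sorted(self.e1_by_ab), dtype=float)

    @property
    def pwm_points(self) -> np.ndarray:
        return np.asarray(sorted({p for p, _ in self.eta_by_pwm_ab}), dtype=float)

    def _interp(self, x, xs, ys, what):
        xs = np.asarray(xs, float)
        ys = np.asarray(ys, float)
        if x < xs[0] or x > xs[-1]:
            warnings.warn(
                f"{what}={x} outside calibrated range [{xs[0]}, {xs[-1]}]; "
                "extrapolating linearly",
                stacklevel=3,
            )
        if xs.size == 1:
            return float(ys[0])
        # np.interp clamps; do explicit linear extrapolation at the edges.
        i = np.clip(np.searchsorted(xs, x) - 1, 0, xs.size - 2)
        x0, x1 = xs[i], xs[i + 1]
        y0, y1 = ys[i], ys[i + 1]
        return float(y0 + (y1 - y0) * (x - x0) / (x1 - x0))

    def e1_equiv(self, ab_distance: float) -> float:
        """E1-equivalent pressure (cmH2O) at a given AB distance (mm)."""
        abs_ = self.ab_points
        return self._interp(
            ab_distance, abs_, [self.e1_by_ab[a] for a in abs_], "AB_distance"
        )

    def eta(self, pwm: float, ab_distance: float) -> float:
        """Fitted viscosity (cmH2O*s) at (PWM %, AB mm), bilinear."""
        if not 0 <= pwm <= 100:
            raise ValueError(f"PWM must be in [0, 100] %, got {pwm}")
        abs_ = self.ab_points
        eta_at_ab = []
        for a in abs_:
            pwms = sorted(p for p, aa in self.eta_by_pwm_ab if aa == a)
            etas = [self.eta_by_pwm_ab[(p, a)] for p in pwms]
            eta_at_ab.append(self._interp(pwm, pwms, etas, "PWM"))
        return self._interp(ab_distance, abs_, eta_at_ab, "AB_distance")

    def tau(self, pwm: float, ab_distance: float) -> float:
        """Relaxation time eta/E1 (s) at (PWM %, AB mm)."""
        return self.eta(pwm, ab_distance) / self.e1_equiv(ab_distance)

    def drop_sd(self, ab_distance: float) -> float:
        if not self.drop_sd_by_ab:
            return 0.0
        abs_ = np.asarray(sorted(self.drop_sd_by_ab), float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return self._interp(
                ab_distance, abs_, [self.drop_sd_by_ab[a] for a in abs_], "AB"
            )


def pwm_to_tau(
    calibration: ActuatorCalibration, pwm: float, ab_distance: float
) -> float:
    """Relaxation time (s) for a PWM duty cycle at a given AB distance."""
    return calibration.tau(pwm, ab_distance)


@dataclass(frozen=True)
class Actuator:
    """Settings + calibration + force model, ready to produce pressures."""

    settings: ActuatorSettings = field(default_factory=ActuatorSettings)
    calibration: ActuatorCalibration = field(
        default_factory=ActuatorCalibration.default
    )
    force_model: MagnetForceModel | None = None

    def __post_init__(self):
        if self.force_model is None:
            object.__setattr__(
                self,
                "force_model",
                MagnetForceModel.for_pair(self.settings.magnet_pair_id),
            )
        if self.settings.mode == "mechanistic" and self.effective_area is None:
            raise ValueError(
                "mechanistic mode requires an effective_area (or a default "
                "calibration from which one can be derived)"
            )

    @property
    def e1_equiv(self) -> float:
        return self.calibration.e1_equiv(self.settings.AB_distance)

    @property
    def tau(self) -> float:
        return self.calibration.tau(self.settings.PWM, self.settings.AB_distance)

    @property
    def effective_area(self) -> float | None:
        """Bellows effective area, cm^2 (mechanistic force->pressure).

        Default is derived so the mechanistic end-inspiratory pressure at
        AB = 25 mm matches the calibrated 25 mm E1-equivalent.
        """
        if self.settings.effective_area is not None:
            return self.settings.effective_area
        try:
            e1_ref = self.calibration.e1_equiv(25.0)
        except Exception:  # pragma: no cover
            return None
        f_ref = self.force_model.force(25.0)
        return f_ref * CMH2O_PER_N_PER_CM2 / e1_ref

    @property
    def return_speed(self) -> float:
        """Return-stroke speed, mm/s, from the PWM->tau calibration.

        Calibrated so the mechanistic force decay reaches 1/e of the
        end-inspiratory force after one calibrated time constant.
        """
        ab = self.settings.AB_distance
        f0 = self.force_model.force(ab)
        target = f0 / np.e
        d_far = self.force_model._anchor_d[-1] + 200.0
        if self.force_model.force(d_far) > target:  # pragma: no cover
            raise RuntimeError("force model tail too heavy for speed calibration")
        d_e = brentq(lambda d: self.force_model.force(d) - target, ab, d_far)
        return (d_e - ab) / self.tau

    def end_inspiratory_pressure(self, amplitude_scale: float = 1.0) -> float:
        """Extra bellows pressure (cmH2O) with the rod extended."""
        if self.settings.mode == "phenomenological":
            return amplitude_scale * self.e1_equiv
        f = self.force_model.force(self.settings.AB_distance)
        return amplitude_scale * f * CMH2O_PER_N_PER_CM2 / self.effective_area

    def pause_pressure(self, t_since_pause, amplitude_scale: float = 1.0):
        """Extra bellows pressure (cmH2O) ``t_since_pause`` s after pause onset.

        Phenomenological: ``E1_equiv * exp(-t/tau)``. Mechanistic: force at
        the instantaneous magnet separation ``AB + v_return * t`` (clamped
        at full stroke) divided by the effective area.
        """
        t = np.asarray(t_since_pause, dtype=float)
        if np.any(t < 0):
            raise ValueError("t_since_pause must be non-negative")
        if self.settings.mode == "phenomenological":
            out = amplitude_scale * self.e1_equiv * np.exp(-t / self.tau)
        else:
            d = self.settings.AB_distance + np.minimum(
                self.return_speed * t, self.settings.stroke
            )
            out = (
                amplitude_scale
                * self.force_model.force(d)
                * CMH2O_PER_N_PER_CM2
                / self.effective_area
            )
        if np.isscalar(t_since_pause) or t.ndim == 0:
            return float(out)
        return out


def actuator_pressure(
    settings: ActuatorSettings,
    calibration: ActuatorCalibration,
    model: MagnetForceModel,
    phase_time,
):
    """Actuator pressure at ``phase_time`` (s; 0 = pause onset).

    Negative ``phase_time`` denotes inspiration (rod extended): the
    end-inspiratory pressure is returned. Non-negative times follow the
    pause decay of the configured mode.
    """
    act = Actuator(settings=settings, calibration=calibration, force_model=model)
    t = np.asarray(phase_time, dtype=float)
    insp = act.end_inspiratory_pressure()
    out = np.where(t < 0, insp, act.pause_pressure(np.maximum(t, 0.0)))
    if np.isscalar(phase_time) or t.ndim == 0:
        return float(out)
    return out
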