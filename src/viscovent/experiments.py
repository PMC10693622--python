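"""Factorial experiment runner, scenario config, and fixture generation.

Reproduces the bench experiment bookkeeping: a two-level factorial design
(every combination of factor levels, times ``replicates``) is executed by
running simulate -> segment -> estimate for each run, with a documented
per-run seed scheme so a master seed makes the whole design
bit-reproducible.

The two designs exercised on the bench are available as presets:

* ``two_by_two`` — PWM (68.63, 74.51 %) x AB distance (25, 30 mm), rate 13
  rpm, Raw 18 cmH2O/L/s, VT 150 mL, pause 35% of the cycle; 3 replicates
  -> 12 executions.
* ``two_by_four`` — Raw (5, 8 cmH2O/L/s) x compliance (15, 20 mL/cmH2O) x
  VT (100, 150 mL) x AB distance (25, 30 mm), rate 13 rpm, pause 20%, PWM
  70%; 3 replicates -> 48 executions.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import sys
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict

from .actuator import Actuator, ActuatorCalibration, ActuatorSettings, MagnetForceModel
from .estimation import NoPauseError, fit_relaxation, segment_pause
from .traceio import write_trace
from .ventilator import (
    DEFAULT_SAMPLING_RATE,
    LungSettings,
    NoiseModel,
    PressureTrace,
    VentilatorSettings,
    simulate_run,
)

__all__ = [
    "Scenario",
    "FactorialDesign",
    "run_design",
    "make_fixtures",
    "load_scenario",
    "scenario_hash",
    "FIXTURE_CATALOGS",
    "CALIBRATION_RUNS",
]

#: The four bench calibration runs (fitted SLS parameters per condition).
CALIBRATION_RUNS = {
    "P1": {"AB_distance": 25.0, "PWM": 68.63, "E0": 7.0999, "eta": 1.181, "E1": 3.48},
    "P2": {"AB_distance": 25.0, "PWM": 74.51, "E0": 6.7999, "eta": 0.403, "E1": 3.48},
    "P3": {"AB_distance": 30.0, "PWM": 68.63, "E0": 6.5999, "eta": 1.166, "E1": 2.20},
    "P4": {"AB_distance": 30.0, "PWM": 74.51, "E0": 6.6999, "eta": 0.442, "E1": 2.20},
}


class Scenario(BaseModel):
    """A complete simulated-run configuration (ventilator + lung +
    optional actuator + noise + acquisition)."""

    model_config = ConfigDict(frozen=True)

    ventilator: VentilatorSettings = VentilatorSettings()
    lung: LungSettings = LungSettings(compliance=20.0)
    actuator: ActuatorSettings | None = ActuatorSettings()
    noise: NoiseModel | None = NoiseModel()
    sampling_rate: float = DEFAULT_SAMPLING_RATE
    n_cycles: int = 1

    def build_actuator(
        self, calibration: ActuatorCalibration | None = None
    ) -> Actuator | None:
        if self.actuator is None:
            return None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # interpolated PWM flagged elsewhere
            return Actuator(
                settings=self.actuator,
                calibration=calibration or ActuatorCalibration.default(),
            )

    def simulate(
        self, calibration: ActuatorCalibration | None = None
    ) -> PressureTrace:
        return simulate_run(
            self.ventilator,
            self.lung,
            self.build_actuator(calibration),
            self.noise,
            self.n_cycles,
            self.sampling_rate,
        )


def scenario_hash(scenario: Scenario) -> str:
    """Stable SHA-256 of the canonical scenario config (provenance tag)."""
    blob = json.dumps(scenario.model_dump(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def load_scenario(path) -> Scenario:
    """Load a scenario from a YAML config file (keys mirror the types)."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return Scenario.model_validate(data)


# Factor name -> (section, field) in the scenario config.
_FACTOR_FIELDS = {
    "PWM": ("actuator", "PWM"),
    "AB_distance": ("actuator", "AB_distance"),
    "Raw": ("ventilator", "Raw"),
    "compliance": ("lung", "compliance"),
    "tidal_volume": ("ventilator", "tidal_volume"),
    "pause_fraction": ("ventilator", "pause_fraction"),
}


@dataclass(frozen=True)
class FactorialDesign:
    """Two-level factorial design over scenario factors.

    ``factors`` maps a factor name (a key of the scenario config, e.g.
    ``PWM``, ``AB_distance``, ``Raw``, ``compliance``, ``tidal_volume``)
    to its (low, high) levels. Run count = 2**len(factors) * replicates.

    Seed policy: run ``i`` (enumerated condition-major, replicate-minor)
    uses child seed ``(master_seed * 100003 + i) % 2**31`` — a documented
    counter scheme recorded in every run's output row.
    """

    factors: dict[str, tuple[float, float]]
    replicates: int = 3
    base_scenario: Scenario = field(default_factory=Scenario)
    master_seed: int = 0

    def __post_init__(self):
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if not self.factors:
            raise ValueError("at least one factor required")
        for name, levels in self.factors.items():
            if name not in _FACTOR_FIELDS:
                raise KeyError(
                    f"unknown factor {name!r}; known: {sorted(_FACTOR_FIELDS)}"
                )
            if len(levels) != 2:
                raise ValueError(f"factor {name!r} must have exactly 2 levels")

    @property
    def n_conditions(self) -> int:
        return 2 ** len(self.factors)

    @property
    def n_runs(self) -> int:
        return self.n_conditions * self.replicates

    def child_seed(self, run_index: int) -> int:
        return (self.master_seed * 100003 + run_index) % 2**31

    def conditions(self):
        names = list(self.factors)
        for combo in itertools.product(*(self.factors[n] for n in names)):
            yield dict(zip(names, combo))

    def scenario_for(self, condition: dict, seed: int) -> Scenario:
        cfg = self.base_scenario.model_dump()
        for name, value in condition.items():
            section, fld = _FACTOR_FIELDS[name]
            if cfg.get(section) is None:
                raise ValueError(f"factor {name!r} needs a {section} section")
            cfg[section][fld] = value
            if section == "lung":
                cfg["lung"]["E0_override"] = None
        if cfg.get("noise") is not None:
            cfg["noise"]["seed"] = seed
        return Scenario.model_validate(cfg)


@dataclass(frozen=True)
class PresetDesigns:
    """Bench design presets (see module docstring)."""

    @staticmethod
    def two_by_two(master_seed: int = 0, noise: NoiseModel | None = None) -> FactorialDesign:
        base = Scenario(
            ventilator=VentilatorSettings(
                respiratory_rate=13.0,
                Raw=18.0,
                tidal_volume=150.0,
                pause_fraction=0.35,
            ),
            lung=LungSettings(compliance=20.0),
            actuator=ActuatorSettings(),
            noise=noise or NoiseModel(),
        )
        return FactorialDesign(
            factors={"PWM": (68.63, 74.51), "AB_distance": (25.0, 30.0)},
            replicates=3,
            base_scenario=base,
            master_seed=master_seed,
        )

    @staticmethod
    def two_by_four(master_seed: int = 0, noise: NoiseModel | None = None) -> FactorialDesign:
        base = Scenario(
            ventilator=VentilatorSettings(
                respiratory_rate=13.0, pause_fraction=0.20
            ),
            lung=LungSettings(compliance=20.0),
            actuator=ActuatorSettings(PWM=70.0),
            noise=noise or NoiseModel(),
        )
        return FactorialDesign(
            factors={
                "Raw": (5.0, 8.0),
                "compliance": (15.0, 20.0),
                "tidal_volume": (100.0, 150.0),
                "AB_distance": (25.0, 30.0),
            },
            replicates=3,
            base_scenario=base,
            master_seed=master_seed,
        )


def run_design(
    design: FactorialDesign,
    calibration: ActuatorCalibration | None = None,
    ledger_path=None,
    log=lambda msg: print(msg, file=sys.stderr),
) -> pd.DataFrame:
    """Execute every run of a factorial design and aggregate per condition.

    Each run simulates the scenario, segments the pause, and records the
    P1 - P2 drop. Per condition, the drops are averaged and the relaxation
    is fitted (E1 fixed at the condition mean drop) on the first successful
    replicate's pause window. Failed runs are recorded with their error,
    never dropped silently.

    Returns a DataFrame with one row per condition (factor levels, mean
    drop, E0_hat, eta_hat, E1_hat, tau_hat, R2) plus per-run bookkeeping in
    ``df.attrs["runs"]``. Deterministic under a fixed master seed.
    """
    calibration = calibration or ActuatorCalibration.default()
    pwm_lo, pwm_hi = calibration.pwm_points[0], calibration.pwm_points[-1]

    run_records = []
    rows = []
    run_index = 0
    ledger_lines = []
    for cond in design.conditions():
        drops = []
        fit_data = None
        for rep in range(design.replicates):
            seed = design.child_seed(run_index)
            status = "ok"
            err = ""
            try:
                scenario = design.scenario_for(cond, seed)
                trace = scenario.simulate(calibration)
                seg = segment_pause(trace)
                drops.append(seg.drop)
                if fit_data is None:
                    lo, hi = seg.pause_window
                    cyc = trace.cycle(0)
                    fit_data = (
                        cyc.time[lo:hi] - cyc.time[lo],
                        cyc.pressure[lo:hi],
                    )
            except (NoPauseError, ValueError, RuntimeError) as exc:
                status = "failed"
                err = str(exc)
            run_records.append(
                {
                    "run_index": run_index,
                    "seed": seed,
                    **cond,
                    "replicate": rep,
                    "status": status,
                    "error": err,
                    "drop": drops[-1] if status == "ok" else float("nan"),
                }
            )
            ledger_lines.append(
                json.dumps(
                    {"run": run_index, "seed": seed, "condition": cond, "status": status}
                )
            )
            log(f"run {run_index + 1}/{design.n_runs} {cond} -> {status}")
            run_index += 1

        row = dict(cond)
        pwm = cond.get(
            "PWM",
            design.base_scenario.actuator.PWM
            if design.base_scenario.actuator
            else float("nan"),
        )
        row["pwm_interpolated"] = bool(pwm_lo < pwm < pwm_hi and
                                       pwm not in calibration.pwm_points)
        if drops:
            mean_drop = float(np.mean(drops))
            row.update(mean_drop=mean_drop, n_ok=len(drops))
            if fit_data is not None and len(fit_data[0]) >= 10:
                fit = fit_relaxation(*fit_data, E1_fixed=mean_drop)
                row.update(
                    E1_hat=mean_drop,
                    E0_hat=fit.E0_hat,
                    eta_hat=fit.eta_hat,
                    tau_hat=fit.tau_hat,
                    R2=fit.R2,
                )
        else:
            row.update(mean_drop=float("nan"), n_ok=0)
        rows.append(row)

    if ledger_path is not None:
        Path(ledger_path).write_text("\n".join(ledger_lines) + "\n")
    df = pd.DataFrame(rows)
    df.attrs["runs"] = pd.DataFrame(run_records)
    df.attrs["master_seed"] = design.master_seed
    return df


# ---------------------------------------------------------------------------
# Fixture catalogs


def _fixture_calibration_roundtrip(out: Path, seed: int) -> list[Path]:
    """Noiseless traces for the four calibration runs + expected sidecars."""
    paths = []
    for name, run in CALIBRATION_RUNS.items():
        scenario = Scenario(
            ventilator=VentilatorSettings(
                respiratory_rate=13.0,
                Raw=18.0,
                tidal_volume=150.0,
                pause_fraction=0.35,
            ),
            lung=LungSettings(E0_override=run["E0"]),
            actuator=ActuatorSettings(
                AB_distance=run["AB_distance"], PWM=run["PWM"]
            ),
            noise=None,
        )
        trace = scenario.simulate()
        p = write_trace(
            trace,
            out / f"calibration_{name}.csv",
            metadata={"scenario_hash": scenario_hash(scenario)},
        )
        expected = dict(run)
        expected["tau"] = run["eta"] / run["E1"]
        (out / f"calibration_{name}.expected.json").write_text(
            json.dumps(expected, indent=1, sort_keys=True) + "\n"
        )
        paths.extend([p, out / f"calibration_{name}.expected.json"])
    return paths


def _fixture_noisy_2x4(out: Path, seed: int) -> list[Path]:
    design = PresetDesigns.two_by_four(
        master_seed=seed,
        noise=NoiseModel(pressure_sd=0.1, drop_sd=0.22, seed=seed),
    )
    paths = []
    for i, cond in enumerate(design.conditions()):
        scenario = design.scenario_for(cond, design.child_seed(i))
        trace = scenario.simulate()
        p = write_trace(
            trace,
            out / f"noisy_2x4_c{i:02d}.csv",
            metadata={
                "condition": cond,
                "scenario_hash": scenario_hash(scenario),
            },
        )
        paths.append(p)
    return paths


def _fixture_magnet_anchors(out: Path, seed: int) -> list[Path]:
    model = MagnetForceModel.for_pair("neodymium-4mm")
    d = np.arange(model.baseline_distance, 80.0 + 1e-9, 0.5)
    df = pd.DataFrame({"distance_mm": d, "force_N": model.force(d)})
    p = out / "magnet_force_distance.csv"
    df.to_csv(p, index=False, float_format="%.10g")
    return [p]


def _fixture_degenerate_cases(out: Path, seed: int) -> list[Path]:
    paths = []
    # No-pause trace: segmentation downstream must raise NoPauseError.
    scenario = Scenario(
        ventilator=VentilatorSettings(pause_fraction=0.0),
        lung=LungSettings(compliance=20.0),
        actuator=None,
        noise=None,
    )
    paths.append(write_trace(scenario.simulate(), out / "no_pause.csv"))
    # Constant-plateau trace: no actuator, drop should be ~0.
    scenario = Scenario(
        ventilator=VentilatorSettings(pause_fraction=0.20),
        lung=LungSettings(compliance=20.0),
        actuator=None,
        noise=None,
    )
    paths.append(write_trace(scenario.simulate(), out / "no_actuator.csv"))
    return paths


FIXTURE_CATALOGS = {
    "calibration_roundtrip": _fixture_calibration_roundtrip,
    "noisy_2x4": _fixture_noisy_2x4,
    "magnet_anchors": _fixture_magnet_anchors,
    "degenerate_cases": _fixture_degenerate_cases,
}


def make_fixtures(catalog_name: str, out_dir, seed: int = 0) -> list[Path]:
    """Write a named fixture file set; bit-identical under a fixed seed."""
    try:
        builder = FIXTURE_CATALOGS[catalog_name]
    except KeyError:
        raise KeyError(
            f"unknown fixture catalog {catalog_name!r}; "
            f"available: {sorted(FIXTURE_CATALOGS)}"
        ) from None
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    return builder(out, seed)
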