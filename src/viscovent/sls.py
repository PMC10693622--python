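"""Standard Linear Solid (SLS) viscoelastic model in the Maxwell form.

The model is the simplest rheological network that exhibits both stress
relaxation and creep: a lone spring of modulus ``E0`` in parallel with a
Maxwell arm, i.e. a spring of modulus ``E1`` in series with a dashpot of
viscosity ``eta``.  Under a strain step held constant the Maxwell arm
relaxes exponentially with time constant ``tau = eta / E1`` and the total
stress decays from the instantaneous value ``(E0 + E1) * strain`` to the
equilibrium value ``E0 * strain``.

In the mechanical-ventilation setting the "stress" is airway pressure and
the "strain" is lung inflation normalised to 1 at end-inspiration, so the
moduli carry pressure units (cmH2O) and the relaxation curve is directly
the slow pressure drop observed during an inspiratory pause: ``E0`` plays
the role of the plateau pressure (set by compliance), ``E1`` the magnitude
of the viscoelastic pressure drop (P1 - P2), and ``eta`` the viscosity that
sets how fast the drop happens.

Two routes to the relaxation response are provided:

* :func:`relaxation_pressure` — the closed form
  ``P(t) = E0 + E1 * exp(-t / tau)`` under unit end-inspiratory strain;
* :func:`integrate_sls_ode` — direct numerical integration of the
  constitutive differential equation for an arbitrary sampled strain
  history, used as an independent cross-check (oracle) of the closed form.
"""

from __future__ import annotations

import math

import numpy as np
from pydantic import BaseModel, ConfigDict, model_validator
from scipy.integrate import solve_ivp

__all__ = ["SLSParameters", "relaxation_pressure", "integrate_sls_ode"]


class SLSParameters(BaseModel):
    """The viscoelastic triple (E0, E1, eta), pressure-normalised.

    Parameters
    ----------
    E0 : float
        Modulus of the lone (equilibrium) spring, cmH2O per unit strain.
        With strain normalised to 1 at end-inspiration this is the plateau
        pressure. Must be positive.
    E1 : float
        Modulus of the Maxwell-arm spring, cmH2O. Equals the total
        relaxation drop P(0) - P(inf). Non-negative; ``E1 == 0`` degenerates
        to a pure spring.
    eta : float
        Maxwell-arm dashpot viscosity, cmH2O*s. Must be positive whenever
        ``E1 > 0``.

    The relaxation time ``tau = eta / E1`` is always recomputed from the
    stored fields, never stored independently; it is NaN (flagged by
    :attr:`has_relaxation`) in the degenerate elastic case ``E1 == 0``.
    """

    model_config = ConfigDict(frozen=True)

    E0: float
    E1: float = 0.0
    eta: float = 0.0

    @model_validator(mode="after")
    def _check(self) -> "SLSParameters":
        if not self.E0 > 0:
            raise ValueError(f"E0 must be positive, got {self.E0}")
        if self.E1 < 0:
            raise ValueError(f"E1 must be non-negative, got {self.E1}")
        if self.E1 > 0 and not self.eta > 0:
            raise ValueError(
                f"eta must be positive when E1 > 0, got eta={self.eta}"
            )
        return self

    @property
    def has_relaxation(self) -> bool:
        """Whether the Maxwell arm is active (``E1 > 0``)."""
        return self.E1 > 0

    @property
    def tau(self) -> float:
        """Relaxation time eta / E1 in seconds; NaN when ``E1 == 0``."""
        if self.E1 == 0:
            return math.nan
        return self.eta / self.E1


def relaxation_pressure(params: SLSParameters, t):
    """Closed-form stress-relaxation pressure under unit held strain.

    ``P(t) = E0 + E1 * exp(-t / tau)`` with ``tau = eta / E1``; ``t`` is
    seconds since pause onset (the instant the strain step is applied).

    Parameters
    ----------
    params : SLSParameters
    t : float or array_like
        Time(s) since pause onset, seconds. Must be non-negative.

    Returns
    -------
    float or ndarray
        Pressure in cmH2O: ``E0 + E1`` at ``t = 0``, decaying
        monotonically toward the asymptote ``E0``.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("relaxation time t must be non-negative")
    if not params.has_relaxation:
        out = np.full_like(t_arr, params.E0)
        return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out
    out = params.E0 + params.E1 * np.exp(-t_arr / params.tau)
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def integrate_sls_ode(
    params: SLSParameters,
    time,
    strain,
    initial_stress: float | None = None,
    rtol: float = 1e-10,
    atol: float = 1e-12,
):
    """Integrate the Maxwell-form SLS constitutive ODE for a sampled strain.

    The network topology (spring ``E0`` parallel to the series ``E1``-``eta``
    arm) gives total stress ``sigma = E0*eps + sigma_m`` where the Maxwell-arm
    stress obeys::

        d(sigma_m)/dt = E1 * d(eps)/dt - sigma_m / tau

    The strain history is taken piecewise-linear between the (uniform)
    samples and the state is integrated with a stiff-safe adaptive scheme
    (Radau). This is the brute-force oracle for
    :func:`relaxation_pressure`: under a step-and-hold strain the output
    matches the closed form to well below 1e-6 cmH2O.

    Parameters
    ----------
    params : SLSParameters
    time : array_like
        Uniformly spaced sample times, seconds, step > 0.
    strain : array_like
        Dimensionless strain at each sample time.
    initial_stress : float, optional
        Total stress at ``time[0]`` in cmH2O. Default treats ``strain[0]``
        as having just arrived as a step, i.e. the instantaneous-modulus
        response ``(E0 + E1) * strain[0]``.

    Returns
    -------
    ndarray
        Total stress (pressure, cmH2O) at each sample time.
    """
    time = np.asarray(time, dtype=float)
    strain = np.asarray(strain, dtype=float)
    if time.ndim != 1 or time.size < 2 or time.shape != strain.shape:
        raise ValueError("time and strain must be 1-D arrays of equal length >= 2")
    steps = np.diff(time)
    if np.any(steps <= 0):
        raise ValueError("time must be strictly increasing")
    dt = steps[0]
    if not np.allclose(steps, dt, rtol=1e-8, atol=1e-12):
        raise ValueError("strain history must be uniformly sampled")

    if not params.has_relaxation:
        # Pure spring: stress tracks strain instantaneously.
        return params.E0 * strain

    if initial_stress is None:
        initial_stress = (params.E0 + params.E1) * strain[0]
    sigma_m0 = float(initial_stress) - params.E0 * strain[0]

    slopes = np.diff(strain) / dt
    tau = params.tau

    def rhs(t, y):
        # Piecewise-constant strain rate from the sampled history.
        i = min(int((t - time[0]) / dt), slopes.size - 1)
        return [params.E1 * slopes[i] - y[0] / tau]

    sol = solve_ivp(
        rhs,
        (time[0], time[-1]),
        [sigma_m0],
        method="Radau",
        t_eval=time,
        rtol=rtol,
        atol=atol,
        max_step=max(dt, tau / 10),
    )
    if not sol.success:  # pragma: no cover - diagnostic path
        raise RuntimeError(f"SLS ODE integration failed: {sol.message}")
    return params.E0 * strain + sol.y[0]
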