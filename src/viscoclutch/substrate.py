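"""Standard Linear Solid (SLS) substrate mechanics.

The substrate every engaged clutch pulls on is modelled as a Standard
Linear Solid: a spring ``k2`` in parallel with a Maxwell arm (spring
``k1`` in series with a dashpot of viscosity ``eta``).  This is the
minimal viscoelastic *solid*: it resists deformation instantaneously
with stiffness ``k1 + k2`` and relaxes over the timescale
``tau_relax = eta / k1`` to the equilibrium stiffness ``k2``.

Stiffnesses are expressed as spring constants in pN/nm, the natural
units of a single adhesion pulling on its local patch of matrix.  As a
rule of thumb for polyacrylamide hydrogels, 1 pN/nm of adhesion-scale
spring constant corresponds to roughly 1 kPa of bulk Young's modulus,
so "soft" (~0.4 kPa) substrates sit below 1 pN/nm and "stiff" (~25 kPa)
substrates around 20-30 pN/nm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

__all__ = [
    "SLSParams",
    "SubstrateState",
    "relaxation_force",
    "dynamic_moduli",
    "step_substrate",
]


@dataclass(frozen=True)
class SLSParams:
    """Spring constants and viscosity of the SLS substrate.

    Parameters
    ----------
    k1 : float
        Maxwell-arm spring stiffness (pN/nm).  Sets the *relaxing* part
        of the response; ``k1 = 0`` degenerates to a pure spring ``k2``.
    k2 : float
        Parallel equilibrium spring stiffness (pN/nm).  The long-time
        stiffness the substrate relaxes to.
    eta : float
        Dashpot viscosity (pN*s/nm).  Must be positive.
    """

    k1: float
    k2: float
    eta: float

    def __post_init__(self) -> None:
        if self.k1 < 0 or self.k2 < 0:
            raise ValueError(f"spring constants must be >= 0 (k1={self.k1}, k2={self.k2})")
        if self.eta <= 0:
            raise ValueError(f"dashpot viscosity must be > 0 (eta={self.eta})")

    @property
    def tau_relax(self) -> float:
        """Stress-relaxation time constant eta/k1 (s); inf when k1 = 0."""
        return self.eta / self.k1 if self.k1 > 0 else math.inf

    @property
    def k_instant(self) -> float:
        """Instantaneous (glassy) stiffness k1 + k2 (pN/nm)."""
        return self.k1 + self.k2

    @property
    def k_equilibrium(self) -> float:
        """Fully relaxed stiffness k2 (pN/nm)."""
        return self.k2

    def to_dict(self) -> dict:
        return {"k1": self.k1, "k2": self.k2, "eta": self.eta}

    @classmethod
    def from_dict(cls, d: dict) -> "SLSParams":
        return cls(k1=float(d["k1"]), k2=float(d["k2"]), eta=float(d["eta"]))


@dataclass(frozen=True)
class SubstrateState:
    """State-space form of the SLS constitutive law.

    ``x`` is the substrate deformation (nm) and ``f_maxwell`` the force
    currently carried by the Maxwell arm (pN).  Total substrate force is
    ``k2 * x + f_maxwell``.
    """

    x: float = 0.0
    f_maxwell: float = 0.0

    def total_force(self, params: SLSParams) -> float:
        return params.k2 * self.x + self.f_maxwell


def relaxation_force(params: SLSParams, x0: float, t: float) -> float:
    """Force response to a step displacement ``x0`` held for time ``t``.

    Closed form: ``x0 * (k2 + k1 * exp(-t / tau_relax))``.  Monotone
    non-increasing in ``t``, bounded between the equilibrium response
    ``x0*k2`` and the instantaneous response ``x0*(k1+k2)``.
    """
    if t < 0:
        raise ValueError(f"t must be >= 0, got {t}")
    if params.k1 == 0.0:
        return x0 * params.k2
    return x0 * (params.k2 + params.k1 * math.exp(-t / params.tau_relax))


def dynamic_moduli(params: SLSParams, omega: float) -> tuple[float, float]:
    """Storage and loss stiffness at angular frequency ``omega`` (rad/s).

    Returns ``(storage, loss)`` with

    * storage = k2 + k1 * (w*tau)^2 / (1 + (w*tau)^2)
    * loss    = k1 * (w*tau)   / (1 + (w*tau)^2)

    The loss stiffness peaks at ``omega = 1/tau_relax`` with value
    ``k1/2``; the loss tangent is ``loss/storage``.
    """
    if omega < 0:
        raise ValueError(f"omega must be >= 0, got {omega}")
    if params.k1 == 0.0:
        return params.k2, 0.0
    wt = omega * params.tau_relax
    if math.isinf(wt):  # glassy limit
        return params.k1 + params.k2, 0.0
    denom = 1.0 + wt * wt
    storage = params.k2 + params.k1 * wt * wt / denom
    loss = params.k1 * wt / denom
    return storage, loss


def _exp_update_coeffs(params: SLSParams, dt: float) -> tuple[float, float]:
    """Exact exponential update coefficients (a, b) for the Maxwell arm.

    Over a step of length dt with deformation varying linearly from
    ``x_old`` to ``x_new``, the Maxwell force evolves exactly as

        f_m' = a * f_m + b * (x_new - x_old)

    with ``a = exp(-dt/tau)`` and ``b = k1 * (tau/dt) * (1 - a)``.
    This is unconditionally accurate for any dt, unlike explicit Euler.
    """
    if params.k1 == 0.0:
        return 1.0, 0.0
    tau = params.tau_relax
    a = math.exp(-dt / tau)
    b = params.k1 * (tau / dt) * (1.0 - a)
    return a, b


def step_substrate(
    params: SLSParams,
    state: SubstrateState,
    applied_force: float,
    dt: float,
    *,
    enforce_dt_contract: bool = True,
) -> SubstrateState:
    """Advance the substrate one step under a prescribed end-of-step load.

    The load is treated as piecewise-constant over the step: the
    substrate first responds elastically to the new force (the dashpot
    cannot move instantaneously), then creeps at constant load, for
    which the Maxwell force decays exactly with the creep time constant
    ``tau_c = eta*(k1+k2)/(k1*k2)``.  The returned state satisfies
    ``k2*x + f_maxwell = applied_force`` exactly, and repeated steps
    under a constant load reproduce the closed-form SLS creep response
    to machine precision; under a held deformation use
    :func:`hold_displacement`, which reproduces :func:`relaxation_force`.

    dt must be positive and, by the configuration contract, no larger
    than ``tau_relax / 10`` so that a single step never spans the bulk
    of a relaxation event.
    """
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    if enforce_dt_contract and dt > params.tau_relax / 10.0:
        raise ValueError(
            f"dt={dt} exceeds the stability contract dt <= tau_relax/10 "
            f"(tau_relax={params.tau_relax}); reduce the step size"
        )
    F = applied_force
    if params.k1 == 0.0:
        return replace(state, x=F / params.k2, f_maxwell=0.0)
    # instantaneous elastic response to the new load
    x_j = (F - state.f_maxwell + params.k1 * state.x) / params.k_instant
    f_j = state.f_maxwell + params.k1 * (x_j - state.x)
    if params.k2 == 0.0:
        # Maxwell fluid: the arm carries the full load and flows
        return replace(state, x=x_j + F / params.eta * dt, f_maxwell=F)
    # creep at constant load: f_maxwell -> 0 with the creep time constant
    tau_c = params.eta * params.k_instant / (params.k1 * params.k2)
    f_m_new = f_j * math.exp(-dt / tau_c)
    x_new = (F - f_m_new) / params.k2
    return replace(state, x=x_new, f_maxwell=f_m_new)


def hold_displacement(
    params: SLSParams, state: SubstrateState, x_held: float, dt: float
) -> SubstrateState:
    """Advance one step with the deformation clamped at ``x_held``.

    Companion to :func:`step_substrate` for displacement-controlled
    protocols (e.g. an indenter hold phase).
    """
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    a, b = _exp_update_coeffs(params, dt)
    f_m_new = a * state.f_maxwell + b * (x_held - state.x)
    return SubstrateState(x=x_held, f_maxwell=f_m_new)
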