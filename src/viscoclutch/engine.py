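"""Monte Carlo simulation of the molecular clutch on a viscoelastic substrate.

The model couples a pool of integrin-based "clutches" between the
rearward-flowing actin cytoskeleton and a Standard Linear Solid
substrate.  Myosin motors drive actin rearward with a linear
force-velocity relation; clutches bind stochastically, load as actin
advances, and unbind as slip bonds whose dissociation rate grows
exponentially with force.  Forces above the talin unfolding threshold
expose vinculin binding sites; vinculin binds at a finite stochastic
rate, and each binding event recruits additional integrins (adhesion
growth) up to a cap.  Piezo1 knockdown is represented purely as a
multiplicative increase of the force-free clutch dissociation rate.

Fixed-step tau-leaping is used: every stochastic transition fires per
step with probability ``1 - exp(-rate * dt)``, which is exact for a
constant rate over the step.  The inner loop is JIT-compiled with
numba; an event-driven formulation exists only as a test oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .substrate import SLSParams
from ._kernel import run_clutch_kernel

__all__ = [
    "ClutchParams",
    "MotorParams",
    "Genotype",
    "SimConfig",
    "SimulationResult",
    "koff_of_force",
    "retrograde_velocity",
    "step_ensemble",
    "run_simulation",
    "replicate_seed",
    "DEFAULT_CLUTCH",
    "DEFAULT_MOTORS",
]

_BOND_SLIP = 0
_BOND_CATCH_SLIP = 1


@dataclass(frozen=True)
class ClutchParams:
    """Kinetic and mechanical parameters of the clutch ensemble.

    The defaults are the package's calibrated reference set: magnitudes
    start from the motor-clutch modelling literature (clutch spring
    ~pN/nm, tens of clutches) and the free kinetic constants were
    calibrated once so that the default substrate grid reproduces the
    qualitative stiffness x viscoelasticity x Piezo1 phenotype
    orderings; they are not measured molecular constants, and every
    field is config-overridable.

    The default bond law is catch-slip: integrin-fibronectin bonds
    (alpha5beta1-class) live longest near an intermediate force, here
    ~5 pN, with force-free rate k_off0 and a steep slip arm beyond
    ~10 pN.  The talin unfolding threshold f_unfold sits inside that
    long-lived regime, so clutches *held* near the catch force (slow,
    viscous or near-stall loading) have time to bind vinculin, while
    fast-loaded clutches shoot through into the slip regime and unbind
    before reinforcement.  A pure slip law is available via
    ``bond_law="slip"``.

    Attributes
    ----------
    n_clutch_init : int
        Clutches available before any reinforcement.
    n_clutch_max : int
        Hard cap on the recruited clutch pool.
    k_on : float
        Clutch association rate (1/s).
    k_off0 : float
        Force-free dissociation rate (1/s).
    f_bond : float
        Force scale of slip-bond unbinding (pN): k_off multiplies by e
        every f_bond of load.
    k_clutch : float
        Clutch spring stiffness (pN/nm).
    f_unfold : float
        Talin unfolding force threshold (pN).
    k_vin : float
        Vinculin binding rate to unfolded talin (1/s).
    d_recruit : int
        Integrins added per vinculin-binding (reinforcement) event.
    bond_law : str
        "slip" (default) or "catch-slip".  The catch-slip option mixes a
        decaying catch pathway into the slip law; at zero force both
        laws return k_off0.
    f_catch : float
        Force scale of the catch pathway (pN); only used for catch-slip.
    catch_share : float
        Zero-force weight of the catch pathway in [0, 1).
    """

    n_clutch_init: int = 75
    n_clutch_max: int = 750
    k_on: float = 0.5
    k_off0: float = 10.0
    f_bond: float = 2.0
    k_clutch: float = 5.0
    f_unfold: float = 6.0
    k_vin: float = 0.5
    d_recruit: int = 3
    bond_law: str = "catch-slip"
    f_catch: float = 3.0
    catch_share: float = 0.98

    def __post_init__(self) -> None:
        if min(self.k_on, self.k_off0, self.f_bond, self.k_clutch, self.k_vin) < 0:
            raise ValueError("rates, force scales and stiffnesses must be >= 0")
        if self.f_unfold <= 0:
            raise ValueError(f"f_unfold must be > 0, got {self.f_unfold}")
        if self.n_clutch_init > self.n_clutch_max:
            raise ValueError(
                f"n_clutch_init ({self.n_clutch_init}) exceeds n_clutch_max ({self.n_clutch_max})"
            )
        if self.bond_law not in ("slip", "catch-slip"):
            raise ValueError(f"unknown bond_law {self.bond_law!r}")
        if not 0.0 <= self.catch_share < 1.0:
            raise ValueError(f"catch_share must be in [0, 1), got {self.catch_share}")

    @property
    def _bond_mode(self) -> int:
        return _BOND_SLIP if self.bond_law == "slip" else _BOND_CATCH_SLIP

    def to_dict(self) -> dict:
        return {
            "n_clutch_init": self.n_clutch_init,
            "n_clutch_max": self.n_clutch_max,
            "k_on": self.k_on,
            "k_off0": self.k_off0,
            "f_bond": self.f_bond,
            "k_clutch": self.k_clutch,
            "f_unfold": self.f_unfold,
            "k_vin": self.k_vin,
            "d_recruit": self.d_recruit,
            "bond_law": self.bond_law,
            "f_catch": self.f_catch,
            "catch_share": self.catch_share,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ClutchParams":
        return cls(**d)


@dataclass(frozen=True)
class MotorParams:
    """Myosin motor ensemble driving retrograde actin flow.

    n_myosin motors each stalling at f_stall (pN) give a linear
    force-velocity law from v_unloaded (nm/s) down to zero at the total
    stall force ``n_myosin * f_stall``.
    """

    n_myosin: int = 75
    f_stall: float = 2.0
    v_unloaded: float = 110.0

    def __post_init__(self) -> None:
        if self.n_myosin <= 0 or self.f_stall <= 0:
            raise ValueError("n_myosin and f_stall must be > 0")
        if self.v_unloaded < 0:
            # zero is allowed: the myosin-inhibited (force-free) limit
            raise ValueError(f"v_unloaded must be >= 0, got {self.v_unloaded}")

    @property
    def stall_force(self) -> float:
        return self.n_myosin * self.f_stall

    def to_dict(self) -> dict:
        return {
            "n_myosin": self.n_myosin,
            "f_stall": self.f_stall,
            "v_unloaded": self.v_unloaded,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MotorParams":
        return cls(**d)


@dataclass(frozen=True)
class Genotype:
    """Piezo1 genotype, reduced to a scalar on clutch dissociation.

    Piezo1-integrin cooperation stabilises the clutch, so silencing
    Piezo1 (siPiezo1) raises the force-free unbinding rate; the default
    factor is 1.15 (a 15% increase) for siPiezo1 and 1.0 for the
    scrambled-siRNA control (scRNA).
    """

    label: str = "scRNA"
    koff_factor: float = 1.0

    _DEFAULT_FACTORS = {"scRNA": 1.0, "siPiezo1": 1.15}

    def __post_init__(self) -> None:
        if self.label not in ("scRNA", "siPiezo1"):
            raise ValueError(f"genotype label must be scRNA or siPiezo1, got {self.label!r}")
        if self.koff_factor <= 0:
            raise ValueError(f"koff_factor must be > 0, got {self.koff_factor}")

    @classmethod
    def control(cls) -> "Genotype":
        return cls("scRNA", 1.0)

    @classmethod
    def piezo1_kd(cls, koff_factor: float = 1.15) -> "Genotype":
        return cls("siPiezo1", koff_factor)

    @classmethod
    def from_label(cls, label: str) -> "Genotype":
        return cls(label, cls._DEFAULT_FACTORS[label])

    def to_dict(self) -> dict:
        return {"label": self.label, "koff_factor": self.koff_factor}

    @classmethod
    def from_dict(cls, d: dict) -> "Genotype":
        return cls(label=d["label"], koff_factor=float(d["koff_factor"]))


@dataclass(frozen=True)
class SimConfig:
    """Run-level settings for a single clutch simulation.

    duration (s) must cover a transient plus a steady-state averaging
    window; summaries are computed over the trailing ``steady_frac`` of
    the run.  The 200 s default is ~100x the slowest default timescale
    (substrate relaxation and vinculin binding, ~2 s).  ``dt = None``
    auto-selects the step so that (i) no zero-force transition rate
    exceeds 0.1 per step and (ii) actin advances by at most
    f_bond/(5*k_clutch) per step, resolving the force ramp a bond
    experiences.  record_dt (s) is the output stride.
    """

    duration: float = 200.0
    dt: float | None = None
    record_dt: float = 0.1
    steady_frac: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.dt is not None and self.dt <= 0:
            raise ValueError("dt must be > 0 when given")
        if not 0.0 < self.steady_frac < 1.0:
            raise ValueError("steady_frac must be in (0, 1)")

    def to_dict(self) -> dict:
        return {
            "duration": self.duration,
            "dt": self.dt,
            "record_dt": self.record_dt,
            "steady_frac": self.steady_frac,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        return cls(**d)


DEFAULT_CLUTCH = ClutchParams()
DEFAULT_MOTORS = MotorParams()


def koff_of_force(f: float, params: ClutchParams, genotype: Genotype) -> float:
    """Force-dependent clutch dissociation rate (1/s).

    Slip bond: ``koff_factor * k_off0 * exp(f / f_bond)``.  The
    catch-slip variant mixes in a catch pathway that decays with force,
    normalised so that the zero-force rate is still
    ``koff_factor * k_off0``.
    """
    if f < 0:
        raise ValueError(f"clutch force must be >= 0, got {f} (force-balance bug?)")
    base = genotype.koff_factor * params.k_off0
    if params._bond_mode == _BOND_SLIP:
        return base * math.exp(f / params.f_bond)
    c = params.catch_share
    return base * (c * math.exp(-f / params.f_catch) + (1.0 - c) * math.exp(f / params.f_bond))


def retrograde_velocity(f_total: float, motors: MotorParams) -> float:
    """Linear myosin force-velocity law, clamped at stall.

    v = v_unloaded * max(0, 1 - F / (n_myosin * f_stall)).
    """
    if f_total < 0:
        raise ValueError(f"substrate load must be >= 0, got {f_total}")
    return motors.v_unloaded * max(0.0, 1.0 - f_total / motors.stall_force)


def auto_dt(
    clutch: ClutchParams,
    motors: MotorParams,
    sls: SLSParams,
    genotype: Genotype,
) -> float:
    """Default time step honouring the rate and force-resolution contracts.

    dt = min(0.1 / max zero-force rate,
             f_bond / (5 * k_clutch * v_unloaded),
             tau_relax / 10).
    """
    max_rate = max(clutch.k_on, clutch.k_off0 * genotype.koff_factor, clutch.k_vin)
    dt = 0.1 / max_rate if max_rate > 0 else math.inf
    if clutch.k_clutch > 0 and motors.v_unloaded > 0:
        dt = min(dt, clutch.f_bond / (5.0 * clutch.k_clutch * motors.v_unloaded))
    if math.isfinite(sls.tau_relax):
        dt = min(dt, sls.tau_relax / 10.0)
    if not math.isfinite(dt):
        raise ValueError("cannot auto-select dt: all rates are zero")
    return dt


def _check_dt(dt: float, clutch: ClutchParams, genotype: Genotype) -> None:
    max_rate = max(clutch.k_on, clutch.k_off0 * genotype.koff_factor, clutch.k_vin)
    if max_rate * dt > 0.1 + 1e-12:
        raise ValueError(
            f"dt={dt} violates the tau-leaping contract max(rate)*dt <= 0.1 "
            f"(max zero-force rate {max_rate}/s)"
        )


@dataclass
class ClutchEnsembleState:
    """Full per-clutch state of the ensemble at one instant.

    Arrays are sized to ``n_clutch_max``; only the first ``n_recruited``
    slots are part of the active pool.  Invariants: vinculin-bound
    implies talin-unfolded implies bound; n_recruited is bounded by
    [n_clutch_init, n_clutch_max].
    """

    bound: np.ndarray
    x_clutch: np.ndarray
    unfolded: np.ndarray
    vinculin: np.ndarray
    x_sub: float
    f_maxwell: float
    n_recruited: int
    t: float
    v: float

    @classmethod
    def initial(cls, clutch: ClutchParams, motors: MotorParams) -> "ClutchEnsembleState":
        n = clutch.n_clutch_max
        return cls(
            bound=np.zeros(n, dtype=np.bool_),
            x_clutch=np.zeros(n, dtype=np.float64),
            unfolded=np.zeros(n, dtype=np.bool_),
            vinculin=np.zeros(n, dtype=np.bool_),
            x_sub=0.0,
            f_maxwell=0.0,
            n_recruited=clutch.n_clutch_init,
            t=0.0,
            v=motors.v_unloaded,
        )

    def clutch_forces(self, clutch: ClutchParams) -> np.ndarray:
        """Spring force on each bound clutch (pN), floored at zero."""
        f = clutch.k_clutch * (self.x_clutch - self.x_sub)
        f[~self.bound] = 0.0
        return np.maximum(f, 0.0)

    def substrate_force(self, sls: SLSParams) -> float:
        return sls.k2 * self.x_sub + self.f_maxwell


def step_ensemble(
    state: ClutchEnsembleState,
    clutch: ClutchParams,
    motors: MotorParams,
    sls: SLSParams,
    genotype: Genotype,
    dt: float,
    rng: np.random.Generator,
) -> ClutchEnsembleState:
    """Advance the ensemble by one tau-leaping step (pure-python reference).

    Sub-steps, in order: (1) unbound clutches in the recruited pool bind
    with probability 1-exp(-k_on*dt); (2) bound clutches advance with
    actin by v*dt; (3) the substrate deformation is updated so its force
    balances the summed clutch load (exact exponential Maxwell update);
    (4) bound clutches unbind with probability 1-exp(-koff(f)*dt),
    resetting extension, talin and vinculin; (5) survivors at force >=
    f_unfold unfold talin; (6) unfolded clutches acquire vinculin with
    probability 1-exp(-k_vin*dt); (7) each vinculin event recruits
    d_recruit clutches up to the cap, and the substrate is re-balanced
    elastically against the surviving bound set (bond release recoils
    the substrate within the step); (8) the retrograde velocity is
    recomputed from the substrate load.

    This reference implementation defines the semantics; production runs
    go through the numba kernel in :func:`run_simulation`, which applies
    the identical update with the identical random-number draw order.
    """
    _check_dt(dt, clutch, genotype)
    n = state.n_recruited
    bound = state.bound.copy()
    x_c = state.x_clutch.copy()
    unfolded = state.unfolded.copy()
    vinc = state.vinculin.copy()

    # (1) binding
    p_on = 1.0 - math.exp(-clutch.k_on * dt)
    for i in range(n):
        if not bound[i] and rng.random() < p_on:
            bound[i] = True
            x_c[i] = state.x_sub
            unfolded[i] = False
            vinc[i] = False

    # (2) actin advance
    adv = state.v * dt
    x_c[bound] += adv

    # (3) substrate force balance: k2*x + a*f_m + b*(x - x_old) = k_c * sum(x_i - x)
    if sls.k1 > 0.0:
        tau = sls.tau_relax
        a = math.exp(-dt / tau)
        b = sls.k1 * (tau / dt) * (1.0 - a)
    else:
        a, b = 1.0, 0.0
    nb = int(bound[:n].sum())
    s = float(x_c[:n][bound[:n]].sum())
    x_old = state.x_sub
    x_sub = (clutch.k_clutch * s + b * x_old - a * state.f_maxwell) / (
        sls.k2 + b + nb * clutch.k_clutch
    )
    f_m = a * state.f_maxwell + b * (x_sub - x_old)

    # (4)-(7)
    p_vin = 1.0 - math.exp(-clutch.k_vin * dt)
    n_rec = state.n_recruited
    for i in range(n):
        if not bound[i]:
            continue
        f = max(0.0, clutch.k_clutch * (x_c[i] - x_sub))
        koff = koff_of_force(f, clutch, genotype)
        if rng.random() < 1.0 - math.exp(-koff * dt):
            bound[i] = False
            unfolded[i] = False
            vinc[i] = False
            x_c[i] = 0.0
            continue
        if f >= clutch.f_unfold:
            unfolded[i] = True
        if unfolded[i] and not vinc[i] and rng.random() < p_vin:
            vinc[i] = True
            n_rec = min(clutch.n_clutch_max, n_rec + clutch.d_recruit)

    # (7b) instantaneous elastic re-balance: bond release recoils the
    # substrate through k2 and the Maxwell spring (dashpot frozen), so
    # the output state satisfies the force balance exactly
    nb2 = int(bound[:n].sum())
    s2 = float(x_c[:n][bound[:n]].sum())
    x_new = (clutch.k_clutch * s2 + sls.k1 * x_sub - f_m) / (
        sls.k2 + sls.k1 + nb2 * clutch.k_clutch
    )
    f_m = f_m + sls.k1 * (x_new - x_sub)
    x_sub = x_new

    # (8) flow
    f_sub = max(0.0, sls.k2 * x_sub + f_m)
    v = retrograde_velocity(f_sub, motors)

    return ClutchEnsembleState(
        bound=bound,
        x_clutch=x_c,
        unfolded=unfolded,
        vinculin=vinc,
        x_sub=x_sub,
        f_maxwell=f_m,
        n_recruited=n_rec,
        t=state.t + dt,
        v=v,
    )


@dataclass
class SimulationResult:
    """Trajectory and steady-state summary of one clutch simulation.

    Time series are sampled every ``record_dt``; summaries are time
    averages over the trailing steady-state window.
    """

    t: np.ndarray
    substrate_force: np.ndarray  # pN
    bound_fraction: np.ndarray
    integrin_density: np.ndarray  # recruited pool, arb. units
    flow: np.ndarray  # nm/s
    summary: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.t,
                "substrate_force_pN": self.substrate_force,
                "bound_fraction": self.bound_fraction,
                "integrin_density": self.integrin_density,
                "retrograde_flow_nm_s": self.flow,
            }
        )


def replicate_seed(root_seed: int, condition_id: str, replicate: int) -> int:
    """Deterministic per-replicate seed from (condition, replicate, root).

    Uses numpy's SeedSequence so nearby (root, replicate) pairs give
    statistically independent streams.  Result fits in 31 bits.
    """
    cond_key = [ord(c) for c in condition_id]
    ss = np.random.SeedSequence([root_seed, replicate, *cond_key])
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)


def run_simulation(
    clutch: ClutchParams,
    motors: MotorParams,
    sls: SLSParams,
    genotype: Genotype,
    sim: SimConfig,
) -> SimulationResult:
    """Run one full clutch simulation and summarise its steady state.

    Deterministic: identical inputs (including sim.seed) give
    bit-identical results.  Raises if the trajectory goes non-finite.
    """
    dt = sim.dt if sim.dt is not None else auto_dt(clutch, motors, sls, genotype)
    _check_dt(dt, clutch, genotype)
    n_steps = max(1, int(round(sim.duration / dt)))
    record_every = max(1, int(round(sim.record_dt / dt)))

    t, f_sub, frac, dens, flow = run_clutch_kernel(
        np.uint32(sim.seed & 0x7FFFFFFF),
        n_steps,
        dt,
        record_every,
        clutch.n_clutch_init,
        clutch.n_clutch_max,
        clutch.k_on,
        clutch.k_off0 * genotype.koff_factor,
        clutch.f_bond,
        clutch.k_clutch,
        clutch.f_unfold,
        clutch.k_vin,
        clutch.d_recruit,
        motors.stall_force,
        motors.v_unloaded,
        sls.k1,
        sls.k2,
        sls.eta,
        clutch._bond_mode,
        clutch.f_catch,
        clutch.catch_share,
    )

    if not (np.all(np.isfinite(f_sub)) and np.all(np.isfinite(flow))):
        raise FloatingPointError(
            "non-finite force or flow in clutch trajectory; check substrate "
            f"and clutch parameters (sls={sls}, clutch={clutch})"
        )

    window = t >= (1.0 - sim.steady_frac) * sim.duration
    summary = {
        "integrin_density": float(dens[window].mean()),
        "bound_fraction": float(frac[window].mean()),
        "substrate_force_pN": float(f_sub[window].mean()),
        "retrograde_flow_nm_s": float(flow[window].mean()),
    }
    meta = {
        "dt": dt,
        "n_steps": n_steps,
        "seed": sim.seed,
        "genotype": genotype.label,
        "steady_window_start_s": float((1.0 - sim.steady_frac) * sim.duration),
    }
    return SimulationResult(
        t=t,
        substrate_force=f_sub,
        bound_fraction=frac,
        integrin_density=dens,
        flow=flow,
        summary=summary,
        meta=meta,
    )
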