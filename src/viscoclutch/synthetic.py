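"""Synthetic-data generators with known ground truth.

Forward models for every analysis stage in the package: SLS-governed
stress-relaxation curves following the nanoindentation protocol
(spherical probe R = 27.5 um, depth 3 um approached at 5 um/s and held
60 s), Hertzian force-depth curves, and the default 8-condition
simulation grid (soft/stiff x V-/V+ x scRNA/siPiezo1).  All randomness
flows from explicit seeds.

Two stiffness scales coexist and are easily confused:

* hydrogel scale — SLS parameters in "kPa-equivalent" spring units used
  to generate indentation fixtures (an SLS with k1 + k2 = 0.4 plays the
  0.4 kPa gel);
* adhesion scale — SLS spring constants in pN/nm felt by a single
  adhesion in the clutch simulation, with relaxation times of order
  seconds (local matrix rearrangement is faster than bulk relaxation).

``default_curve_specs`` returns the former, ``make_default_grid`` the
latter.  Neither set is a fitted material constant; both are declared
package defaults chosen to mirror the soft/stiff (~0.4 / ~25 kPa)
classes, the ~2x faster relaxation of V+ gels, and matched equilibrium
stiffness within each pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .relaxometry import ForceTimeCurve, IndentationCurve
from .substrate import SLSParams

__all__ = [
    "CurveGenSpec",
    "GridSpec",
    "make_relaxation_curve",
    "make_indentation_curve",
    "make_default_grid",
    "default_curve_specs",
    "hertz_force",
    "sls_reduced_relaxation",
    "t80_of_sls",
]

_POISSON = 0.5


def hertz_force(E_pa: float, R_um: float, depth_um: np.ndarray, poisson: float = _POISSON):
    """Spherical Hertz force (nN) at the given depths (um).

    F = (4/3) * E/(1-nu^2) * sqrt(R) * d^(3/2); with E in kPa and
    lengths in um the result is in nN.
    """
    e_kpa = E_pa / 1e3
    return (4.0 / 3.0) * (e_kpa / (1.0 - poisson**2)) * np.sqrt(R_um) * depth_um**1.5


def sls_reduced_relaxation(sls: SLSParams, t: np.ndarray) -> np.ndarray:
    """Normalised SLS hold-phase force (k2 + k1*exp(-t/tau)) / (k1 + k2)."""
    if sls.k1 == 0.0:
        return np.ones_like(np.asarray(t, dtype=float))
    return (sls.k2 + sls.k1 * np.exp(-np.asarray(t, float) / sls.tau_relax)) / sls.k_instant


def t80_of_sls(sls: SLSParams) -> float | None:
    """Closed-form t80 of the SLS reduced relaxation; None if never reached.

    Solves (k2 + k1*exp(-t/tau)) / (k1+k2) = 0.8, which requires the
    relaxing amplitude k1/(k1+k2) to exceed 0.2.
    """
    target = 0.8 * sls.k_instant - sls.k2
    if target <= 0 or sls.k1 == 0.0:
        return None
    return float(sls.tau_relax * np.log(sls.k1 / target))


@dataclass(frozen=True)
class CurveGenSpec:
    """Recipe for one synthetic stress-relaxation curve.

    Defaults mirror the indentation protocol: R = 27.5 um spherical
    probe driven at 5 um/s to a 3 um depth held for 60 s.  ``sls`` is on
    the hydrogel scale (k1 + k2 ~ bulk E in kPa); ``noise_sd`` is the
    additive Gaussian force noise as a fraction of the peak force F0.
    """

    sls: SLSParams
    R: float = 27.5
    h: float = 3.0
    approach_speed: float = 5.0
    hold_time: float = 60.0
    sampling_rate: float = 50.0
    baseline_time: float = 0.5
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hold_time <= 0:
            raise ValueError("hold_time must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if min(self.R, self.h, self.approach_speed, self.sampling_rate) <= 0:
            raise ValueError("R, h, approach_speed and sampling_rate must be > 0")


def make_relaxation_curve(spec: CurveGenSpec) -> ForceTimeCurve:
    """Generate one synthetic force-time relaxation record.

    The record has a flat zero-force baseline, a monotone Hertz-shaped
    approach ramp lasting h/approach_speed, and a hold phase whose
    force follows F0 times the SLS reduced relaxation function (the
    quasi-static assumption: the <1 s approach is not ramp-corrected,
    matching an analysis that discards everything before the peak).
    i.i.d. Gaussian noise of SD noise_sd * F0 is added throughout.
    Seed-deterministic.
    """
    dt = 1.0 / spec.sampling_rate
    t_approach = spec.h / spec.approach_speed
    t_contact = spec.baseline_time
    t_peak = t_contact + t_approach
    f0 = float(hertz_force(spec.sls.k_instant * 1e3, spec.R, np.array(spec.h)))

    t = np.arange(0.0, t_peak + spec.hold_time + dt / 2, dt)
    F = np.zeros_like(t)
    approach = (t >= t_contact) & (t < t_peak)
    depth = np.clip((t[approach] - t_contact) * spec.approach_speed, 0.0, spec.h)
    F[approach] = f0 * (depth / spec.h) ** 1.5
    hold = t >= t_peak
    F[hold] = f0 * sls_reduced_relaxation(spec.sls, t[hold] - t_peak)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        F = F + rng.normal(0.0, spec.noise_sd * f0, size=F.shape)
    return ForceTimeCurve(
        t=t,
        F=F,
        R=spec.R,
        h=spec.h,
        normalized=False,
        meta={
            "true_F0_nN": f0,
            "true_tau_s": spec.sls.tau_relax,
            "true_k1": spec.sls.k1,
            "true_k2": spec.sls.k2,
            "noise_sd": spec.noise_sd,
            "seed": spec.seed,
        },
    )


def make_indentation_curve(
    E: float,
    R: float = 27.5,
    depth_max: float = 3.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_points: int = 200,
    poisson: float = _POISSON,
) -> IndentationCurve:
    """Hertz forward model: force-depth fixture for a known E (Pa).

    noise_sd is additive Gaussian noise as a fraction of the maximum
    force.  A noiseless curve round-trips exactly through hertz_fit.
    """
    if E < 0:
        raise ValueError(f"E must be >= 0, got {E}")
    depth = np.linspace(0.0, depth_max, n_points)
    F = hertz_force(E, R, depth, poisson)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        fmax = F[-1] if F[-1] > 0 else 1.0
        F = F + rng.normal(0.0, noise_sd * fmax, size=F.shape)
    return IndentationCurve(depth=depth, F=F, R=R, meta={"true_E_pa": E, "seed": seed})


_STIFFNESSES = ("soft", "stiff")
_RELAXATIONS = ("V-", "V+")


@dataclass(frozen=True)
class GridSpec:
    """The 8-condition simulation grid (4 substrates x 2 genotypes).

    ``sls`` maps (stiffness, relaxation) to adhesion-scale SLSParams.
    Invariants: within each stiffness pair the equilibrium stiffness k2
    is matched, and the V+ member has a larger Maxwell-arm share and a
    shorter relaxation time than V-.
    """

    sls: dict = field(default_factory=dict)
    genotypes: tuple = ("scRNA", "siPiezo1")
    n_replicates: int = 26
    root_seed: int = 0

    def __post_init__(self) -> None:
        for key in ((s, r) for s in _STIFFNESSES for r in _RELAXATIONS):
            if key not in self.sls:
                raise ValueError(f"grid is missing the substrate condition {key}")
        for s in _STIFFNESSES:
            vm, vp = self.sls[(s, "V-")], self.sls[(s, "V+")]
            if not np.isclose(vm.k2, vp.k2):
                raise ValueError(f"{s}: equilibrium stiffness k2 must match within the pair")
            share_m = vm.k1 / vm.k_instant if vm.k_instant else 0.0
            share_p = vp.k1 / vp.k_instant if vp.k_instant else 0.0
            if not (share_p > share_m or vp.tau_relax < vm.tau_relax):
                raise ValueError(
                    f"{s}: V+ must have a larger Maxwell share and/or shorter tau than V-"
                )

    def substrate_conditions(self):
        return [(s, r) for s in _STIFFNESSES for r in _RELAXATIONS]

    def sls_for(self, stiffness: str, relaxation: str) -> SLSParams:
        return self.sls[(stiffness, relaxation)]

    def to_dict(self) -> dict:
        return {
            "substrates": {
                f"{s} {r}": self.sls[(s, r)].to_dict() for s, r in self.substrate_conditions()
            },
            "genotypes": list(self.genotypes),
            "n_replicates": self.n_replicates,
            "root_seed": self.root_seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GridSpec":
        sls = {}
        for key, params in d["substrates"].items():
            s, r = key.split()
            sls[(s, r)] = SLSParams.from_dict(params)
        return cls(
            sls=sls,
            genotypes=tuple(d.get("genotypes", ("scRNA", "siPiezo1"))),
            n_replicates=int(d.get("n_replicates", 26)),
            root_seed=int(d.get("root_seed", 0)),
        )


def make_default_grid(n_replicates: int = 26, root_seed: int = 0) -> GridSpec:
    """Default adhesion-scale substrate grid for the clutch simulation.

    Soft substrates sit well below 1 pN/nm (the ~0.4 kPa class), stiff
    ones an order of magnitude higher (the ~25 kPa class; adhesion-
    scale springs grow sub-linearly with bulk modulus because the
    ligand patch a single adhesion loads is finite).  Within each pair
    the equilibrium spring k2 is identical and the V+ member relaxes
    faster.  The two pairs encode dissipation differently, mirroring
    the distinct gel chemistries of each stiffness class:

    * soft V+ carries a much larger Maxwell arm than soft V- (entrapped
      linear chains add transient stiffness and drag), so viscous
      resistance adds load that drives clutch engagement;
    * stiff V+ carries a stiffer, fast-relaxing Maxwell arm (loosely
      crosslinked chains resist sharply, then let held stress drain),
      so clutches load through the long-lived bond regime faster than
      vinculin can bind.

    These are calibrated package defaults, not fitted material values.
    """
    sls = {
        ("soft", "V-"): SLSParams(k1=0.1, k2=0.25, eta=0.1),  # tau 1.0 s
        ("soft", "V+"): SLSParams(k1=1.5, k2=0.25, eta=0.75),  # tau 0.5 s
        ("stiff", "V-"): SLSParams(k1=4.0, k2=5.0, eta=8.0),  # tau 2.0 s
        ("stiff", "V+"): SLSParams(k1=15.0, k2=5.0, eta=1.5),  # tau 0.1 s
    }
    return GridSpec(sls=sls, n_replicates=n_replicates, root_seed=root_seed)


def default_curve_specs(noise_sd: float = 0.02, seed: int = 0) -> dict:
    """Hydrogel-scale SLS truths for relaxation-curve fixtures.

    Keys are (stiffness, relaxation).  Instantaneous stiffness k1 + k2
    plays the bulk Young's modulus in kPa (soft ~0.4, stiff ~25); V+
    members have twice the V- Maxwell share and half its relaxation
    time (tau 10 s vs 20 s), so they reach t80 sooner and dissipate
    more over a 60 s hold.
    """
    hydrogel = {
        ("soft", "V-"): SLSParams(k1=0.12, k2=0.28, eta=2.4),  # tau 20 s
        ("soft", "V+"): SLSParams(k1=0.32, k2=0.28, eta=3.2),  # tau 10 s
        ("stiff", "V-"): SLSParams(k1=7.0, k2=18.0, eta=140.0),  # tau 20 s
        ("stiff", "V+"): SLSParams(k1=14.0, k2=18.0, eta=140.0),  # tau 10 s
    }
    return {
        key: CurveGenSpec(sls=params, noise_sd=noise_sd, seed=seed + i)
        for i, (key, params) in enumerate(hydrogel.items())
    }
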