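"""Condition-grid observables: focal-adhesion length, flow, trends, YAP.

Converts raw clutch-simulation output into the quantities reported for
cells: a scaled focal-adhesion (FA) length derived from the recruited
integrin density, retrograde flow speed, per-condition mean +/- SD over
replicates, and the qualitative stiffness/viscoelasticity/Piezo1 trend
assertions.  Also provides the area-normalised nuclear-to-cytoplasmic
YAP intensity ratio used as a mechanotransduction readout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import (
    ClutchParams,
    Genotype,
    MotorParams,
    SimConfig,
    SimulationResult,
    replicate_seed,
    run_simulation,
)

__all__ = [
    "INTEGRIN_DENSITY_PER_UM",
    "ConditionSummary",
    "YapMeasurement",
    "scale_to_fa_length",
    "summarise_condition",
    "run_condition_grid",
    "trend_check",
    "yap_ratio",
]

# One micron of focal-adhesion length per 84.1 arbitrary units of
# recruited integrin density (anchored on the stiff elastic control).
INTEGRIN_DENSITY_PER_UM = 84.1


@dataclass(frozen=True)
class ConditionSummary:
    """Mean +/- SD of scaled FA length and retrograde flow for one condition."""

    stiffness: str  # "soft" | "stiff"
    relaxation: str  # "V-" | "V+"
    genotype: str  # "scRNA" | "siPiezo1"
    fa_length_um_mean: float
    fa_length_um_sd: float
    flow_nm_s_mean: float
    flow_nm_s_sd: float
    n_replicates: int

    @property
    def condition_id(self) -> str:
        return f"{self.stiffness} {self.relaxation} {self.genotype}"


@dataclass(frozen=True)
class YapMeasurement:
    """Integrated YAP intensities and areas of one segmented cell.

    All four values must be in consistent arbitrary units; the nucleus
    is a subset of the cell, so cellYAP >= nucYAP and cellA > nucA.
    """

    nucYAP: float
    nucA: float
    cellYAP: float
    cellA: float

    def __post_init__(self) -> None:
        if not (self.cellYAP >= self.nucYAP >= 0):
            raise ValueError("requires cellYAP >= nucYAP >= 0")
        if not (self.cellA > self.nucA > 0):
            raise ValueError("requires cellA > nucA > 0")


def scale_to_fa_length(integrin_density: float | np.ndarray) -> float | np.ndarray:
    """Scale recruited integrin density (arb. units) to FA length (um).

    Linear through the origin: density / 84.1.
    """
    dens = np.asarray(integrin_density, dtype=float)
    if np.any(dens < 0):
        raise ValueError("integrin density must be >= 0")
    out = dens / INTEGRIN_DENSITY_PER_UM
    return float(out) if out.ndim == 0 else out


def summarise_condition(
    results: list[SimulationResult],
    *,
    stiffness: str = "",
    relaxation: str = "",
    genotype: str = "",
) -> ConditionSummary:
    """Mean and sample SD of scaled FA length and flow across replicates."""
    if len(results) < 2:
        raise ValueError(f"need >= 2 replicates, got {len(results)}")
    fa = np.array([scale_to_fa_length(r.summary["integrin_density"]) for r in results])
    flow = np.array([r.summary["retrograde_flow_nm_s"] for r in results])
    return ConditionSummary(
        stiffness=stiffness,
        relaxation=relaxation,
        genotype=genotype,
        fa_length_um_mean=float(fa.mean()),
        fa_length_um_sd=float(fa.std(ddof=1)),
        flow_nm_s_mean=float(flow.mean()),
        flow_nm_s_sd=float(flow.std(ddof=1)),
        n_replicates=len(results),
    )


def run_condition_grid(
    grid,
    clutch: ClutchParams | None = None,
    motors: MotorParams | None = None,
    sim: SimConfig | None = None,
    n_replicates: int | None = None,
    root_seed: int = 0,
    *,
    keep_results: bool = False,
):
    """Run every condition of a grid spec and tabulate summaries.

    ``grid`` is a ``synthetic.GridSpec`` (substrate parameters for the
    four stiffness x relaxation conditions plus a genotype list).  Each
    replicate gets a seed derived deterministically from (condition id,
    replicate index, root_seed), so the whole table is reproducible from
    root_seed alone.

    Returns a tidy DataFrame with one row per condition (and per
    replicate the raw values if ``keep_results``), columns matching
    :class:`ConditionSummary`.
    """
    clutch = clutch or ClutchParams()
    motors = motors or MotorParams()
    sim = sim or SimConfig()
    n_rep = n_replicates if n_replicates is not None else grid.n_replicates
    if n_rep < 2:
        raise ValueError("need >= 2 replicates per condition")

    rows = []
    raw: dict[str, list[SimulationResult]] = {}
    for stiffness, relaxation in grid.substrate_conditions():
        sls = grid.sls_for(stiffness, relaxation)
        for geno_label in grid.genotypes:
            genotype = Genotype.from_label(geno_label)
            cond_id = f"{stiffness}|{relaxation}|{geno_label}"
            results = []
            for rep in range(n_rep):
                seed = replicate_seed(root_seed, cond_id, rep)
                res = run_simulation(
                    clutch, motors, sls, genotype,
                    SimConfig(
                        duration=sim.duration,
                        dt=sim.dt,
                        record_dt=sim.record_dt,
                        steady_frac=sim.steady_frac,
                        seed=seed,
                    ),
                )
                results.append(res)
            summ = summarise_condition(
                results, stiffness=stiffness, relaxation=relaxation, genotype=geno_label
            )
            rows.append(
                {
                    "stiffness": stiffness,
                    "relaxation": relaxation,
                    "genotype": geno_label,
                    "fa_length_um_mean": summ.fa_length_um_mean,
                    "fa_length_um_sd": summ.fa_length_um_sd,
                    "flow_nm_s_mean": summ.flow_nm_s_mean,
                    "flow_nm_s_sd": summ.flow_nm_s_sd,
                    "n_replicates": summ.n_replicates,
                    "fa_length_um_values": [
                        float(scale_to_fa_length(r.summary["integrin_density"]))
                        for r in results
                    ],
                    "flow_nm_s_values": [
                        float(r.summary["retrograde_flow_nm_s"]) for r in results
                    ],
                }
            )
            if keep_results:
                raw[cond_id] = results
    table = pd.DataFrame(rows)
    if keep_results:
        return table, raw
    return table


def _row(table: pd.DataFrame, stiffness: str, relaxation: str, genotype: str) -> pd.Series:
    m = (
        (table["stiffness"] == stiffness)
        & (table["relaxation"] == relaxation)
        & (table["genotype"] == genotype)
    )
    sub = table[m]
    if len(sub) != 1:
        raise ValueError(f"grid table is missing condition {stiffness} {relaxation} {genotype}")
    return sub.iloc[0]


def _perm_pvalue_greater(
    a: np.ndarray, b: np.ndarray, n_perm: int = 5000, seed: int = 0
) -> float:
    """One-sided permutation p-value for mean(a) > mean(b)."""
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([a, b])
    na = len(a)
    obs = a.mean() - b.mean()
    count = 0
    for _ in range(n_perm):
        rng.shuffle(pooled)
        if pooled[:na].mean() - pooled[na:].mean() >= obs:
            count += 1
    return (count + 1) / (n_perm + 1)


def trend_check(table: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Evaluate the qualitative condition-grid trends on an 8-row table.

    Assertions (on condition means):

    a. control soft V+ FA length > soft V- (viscosity grows soft adhesions)
    b. control stiff V- FA length > soft V- (stiffness grows adhesions)
    c. control soft V+ FA length > stiff V+ (stiffness reverses the
       viscous gain within viscoelastic substrates)
    d. Piezo1 knockdown never *significantly* exceeds control FA length
       in any condition (one-sided permutation test at alpha; a raw
       inequality would be inverted by chance with stochastic replicates)
    e. within each stiffness/genotype pair, flow orders opposite to FA
       length whenever the FA-length difference is itself significant
    f. the soft V+ minus V- FA-length gain is attenuated by Piezo1
       knockdown relative to control — asserted, like (d), as "the
       knockdown gain does not significantly exceed the control gain"
       (one-sided permutation test on the interaction at alpha), with
       the point estimates reported in the details

    Returns {"assertions": {name: bool}, "details": {...}, "all_pass": bool}.
    """
    required = {("soft", "V-"), ("soft", "V+"), ("stiff", "V-"), ("stiff", "V+")}
    have = set(zip(table["stiffness"], table["relaxation"]))
    if not required <= have:
        raise ValueError(f"trend_check needs the full 4-substrate grid, missing {required - have}")
    genotypes = set(table["genotype"])
    has_kd = "siPiezo1" in genotypes

    def fa(s, r, g="scRNA"):
        return _row(table, s, r, g)["fa_length_um_mean"]

    def flow(s, r, g="scRNA"):
        return _row(table, s, r, g)["flow_nm_s_mean"]

    def fa_vals(s, r, g):
        return np.asarray(_row(table, s, r, g)["fa_length_um_values"], dtype=float)

    assertions: dict[str, bool] = {}
    details: dict[str, object] = {}

    assertions["a_soft_viscous_gain"] = fa("soft", "V+") > fa("soft", "V-")
    assertions["b_stiffness_gain"] = fa("stiff", "V-") > fa("soft", "V-")
    assertions["c_stiffness_reverses_viscous"] = fa("soft", "V+") > fa("stiff", "V+")

    if has_kd:
        worst_p = 1.0
        ok = True
        for s, r in required:
            sc = fa_vals(s, r, "scRNA")
            si = fa_vals(s, r, "siPiezo1")
            p = _perm_pvalue_greater(si, sc, seed=17)
            worst_p = min(worst_p, p)
            if p < alpha:  # knockdown significantly above control
                ok = False
        assertions["d_knockdown_not_above_control"] = ok
        details["d_min_pvalue"] = worst_p

        dsc = fa("soft", "V+") - fa("soft", "V-")
        dsi = fa("soft", "V+", "siPiezo1") - fa("soft", "V-", "siPiezo1")
        # interaction permutation: shuffle genotype labels within each
        # soft condition and recompute the difference of viscous gains
        rng = np.random.default_rng(43)
        vp_sc, vp_si = fa_vals("soft", "V+", "scRNA"), fa_vals("soft", "V+", "siPiezo1")
        vm_sc, vm_si = fa_vals("soft", "V-", "scRNA"), fa_vals("soft", "V-", "siPiezo1")
        obs = dsi - dsc
        count = 0
        n_perm = 5000
        for _ in range(n_perm):
            pp = rng.permutation(np.concatenate([vp_sc, vp_si]))
            pm = rng.permutation(np.concatenate([vm_sc, vm_si]))
            delta_sc = pp[: len(vp_sc)].mean() - pm[: len(vm_sc)].mean()
            delta_si = pp[len(vp_sc):].mean() - pm[len(vm_sc):].mean()
            if delta_si - delta_sc >= obs:
                count += 1
        p_amplified = (count + 1) / (n_perm + 1)
        assertions["f_knockdown_attenuates_soft_viscous"] = (dsi < dsc) or (
            p_amplified >= alpha
        )
        details["f_soft_viscous_delta"] = {
            "scRNA": float(dsc),
            "siPiezo1": float(dsi),
            "p_amplified": float(p_amplified),
        }

    pair_ok = True
    pair_detail = {}
    for s in ("soft", "stiff"):
        for g in sorted(genotypes):
            va = fa_vals(s, "V+", g)
            vb = fa_vals(s, "V-", g)
            d_fa = va.mean() - vb.mean()
            p_hi = _perm_pvalue_greater(va, vb, seed=29)
            p_lo = _perm_pvalue_greater(vb, va, seed=29)
            significant = min(p_hi, p_lo) < alpha
            d_flow = flow(s, "V+", g) - flow(s, "V-", g)
            anti = (not significant) or (d_fa * d_flow < 0)
            pair_detail[f"{s}/{g}"] = {
                "d_fa_um": float(d_fa),
                "d_flow_nm_s": float(d_flow),
                "fa_diff_significant": bool(significant),
                "anti_parallel": bool(anti),
            }
            pair_ok = pair_ok and anti
    assertions["e_flow_anti_parallel_to_fa"] = pair_ok
    details["e_pairs"] = pair_detail

    return {
        "assertions": assertions,
        "details": details,
        "all_pass": all(assertions.values()),
    }


def yap_ratio(m: YapMeasurement) -> float:
    """Area-normalised nuclear over cytoplasmic YAP intensity ratio.

    (nucYAP/nucA) / (cytoYAP/cytoA) with cytoYAP = cellYAP - nucYAP and
    cytoA = cellA - nucA.  A homogeneous intensity density gives 1.0.
    """
    cyto_yap = m.cellYAP - m.nucYAP
    cyto_a = m.cellA - m.nucA
    if cyto_yap <= 0 or cyto_a <= 0:
        raise ValueError("cytoplasmic YAP signal/area is zero; ratio undefined")
    return (m.nucYAP / m.nucA) / (cyto_yap / cyto_a)
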