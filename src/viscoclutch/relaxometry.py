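"""Nanoindentation stress-relaxation and Hertz-fit analysis.

Implements the hydrogel characterisation pipeline: indentation strain
for a spherical probe, preprocessing of force-time relaxation records
(baseline alignment, peak detection, cropping to the hold phase,
normalisation by the peak force), pointwise averaging across replicate
curves, the t80 relaxation-time metric (time for the normalised force
to fall to 0.8), percent energy dissipation, and spherical-Hertz
Young's-modulus extraction from force-depth curves.

Curves travel as plain two-column delimited text with a small ``# key:
value`` header carrying units and probe geometry.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "ForceTimeCurve",
    "IndentationCurve",
    "RelaxationSummary",
    "compute_strain",
    "preprocess_relaxation",
    "average_curves",
    "time_to_80pct",
    "energy_dissipation_pct",
    "hertz_fit",
    "analyze_relaxation_group",
    "read_curve",
    "write_curve",
]


@dataclass(frozen=True)
class ForceTimeCurve:
    """A force-time record from a stress-relaxation indentation.

    t in seconds (strictly increasing), F in nN (dimensionless after
    normalisation), probe radius R and target depth h in um.
    """

    t: np.ndarray
    F: np.ndarray
    R: float = 27.5
    h: float = 3.0
    normalized: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        F = np.asarray(self.F, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "F", F)
        if t.shape != F.shape or t.ndim != 1:
            raise ValueError("t and F must be 1-D arrays of equal length")
        if len(t) > 1 and np.any(np.diff(t) <= 0):
            raise ValueError("t must be strictly increasing")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(F))):
            raise ValueError("curve contains non-finite values")


@dataclass(frozen=True)
class IndentationCurve:
    """Force (nN) versus indentation depth (um) for a spherical probe."""

    depth: np.ndarray
    F: np.ndarray
    R: float = 27.5
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        d = np.asarray(self.depth, dtype=float)
        F = np.asarray(self.F, dtype=float)
        object.__setattr__(self, "depth", d)
        object.__setattr__(self, "F", F)
        if d.shape != F.shape or d.ndim != 1:
            raise ValueError("depth and F must be 1-D arrays of equal length")
        if np.any(d < 0):
            raise ValueError("depth must be non-negative")


@dataclass(frozen=True)
class RelaxationSummary:
    """Quantification of an averaged, normalised relaxation curve."""

    F0_nN: float
    t80_s: float | None  # None when the curve never reaches 0.8
    energy_dissipation_pct: float
    n_curves: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.energy_dissipation_pct <= 100.0:
            raise ValueError("energy dissipation must be within [0, 100] %")
        if self.t80_s is not None and self.t80_s < 0:
            raise ValueError("t80 must be >= 0 when defined")


def compute_strain(h: float, R: float) -> float:
    """Indentation strain of a spherical probe: 0.2 * a / R, a = sqrt(h*R).

    Equivalently 0.2 * sqrt(h / R); for the standard protocol (h = 3 um,
    R = 27.5 um) this is ~0.066, i.e. approximately 7% strain.
    """
    if R <= 0:
        raise ValueError(f"probe radius must be > 0, got {R}")
    if h < 0:
        raise ValueError(f"indentation depth must be >= 0, got {h}")
    return 0.2 * math.sqrt(h * R) / R


def preprocess_relaxation(curve: ForceTimeCurve) -> ForceTimeCurve:
    """Normalise a raw relaxation record to its hold phase.

    Steps: (1) shift force up if the baseline (minimum before the peak)
    is negative; (2) locate the force maximum (t0, F0); (3) shift time
    so the peak sits at t = 0 and crop to the hold phase [t0, end];
    (4) divide by F0.  The result starts at (0, 1) and is dimensionless.

    Idempotent: running it on an already-normalised curve is a no-op up
    to floating point.  Raises if the force is still rising at the last
    sample (no hold phase) or if the detected peak is non-positive.
    """
    t = curve.t
    F = curve.F.copy()

    i0 = int(np.argmax(F))
    if i0 == len(F) - 1:
        raise ValueError("force maximum at final sample: curve has no hold phase")

    baseline = F[: i0 + 1].min()
    if baseline < 0:
        F = F - baseline

    F0 = float(F[i0])
    if F0 <= 0:
        raise ValueError(f"detected peak force {F0} <= 0; cannot normalise")

    t_out = t[i0:] - t[i0]
    F_out = F[i0:] / F0
    meta = dict(curve.meta)
    meta["F0_nN"] = F0 if not curve.normalized else curve.meta.get("F0_nN", F0)
    return ForceTimeCurve(
        t=t_out, F=F_out, R=curve.R, h=curve.h, normalized=True, meta=meta
    )


def average_curves(curves: list[ForceTimeCurve]) -> tuple[ForceTimeCurve, np.ndarray]:
    """Pointwise mean and SD of normalised curves on a common time grid.

    The grid is the first curve's time base restricted to the window
    shared by all curves; other curves are linearly interpolated onto
    it.  Returns (mean_curve, sd_array).
    """
    if len(curves) < 2:
        raise ValueError(f"need >= 2 curves to average, got {len(curves)}")
    t_lo = max(c.t[0] for c in curves)
    t_hi = min(c.t[-1] for c in curves)
    if t_hi <= t_lo:
        raise ValueError("curves have disjoint time windows; nothing to average")
    base = curves[0]
    mask = (base.t >= t_lo) & (base.t <= t_hi)
    grid = base.t[mask]
    if len(grid) < 2:
        raise ValueError("shared time window contains fewer than 2 grid points")
    stack = np.vstack([np.interp(grid, c.t, c.F) for c in curves])
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)
    meta = {"n_curves": len(curves)}
    f0s = [c.meta.get("F0_nN") for c in curves if c.meta.get("F0_nN") is not None]
    if f0s:
        meta["F0_nN"] = float(np.mean(f0s))
    return (
        ForceTimeCurve(t=grid, F=mean, R=base.R, h=base.h, normalized=True, meta=meta),
        sd,
    )


def time_to_80pct(curve: ForceTimeCurve) -> float | None:
    """First time at which the normalised force crosses 0.8.

    Linear interpolation between the bracketing samples; ties broken by
    the earliest crossing.  Returns 0.0 if the first sample is already
    below the threshold and None ("not reached") if the curve never
    drops to 0.8.
    """
    F = curve.F
    t = curve.t
    threshold = 0.8
    if F[0] <= threshold:
        return 0.0
    below = np.nonzero(F <= threshold)[0]
    if len(below) == 0:
        return None
    j = int(below[0])
    i = j - 1
    # linear interpolation on the bracketing segment
    frac = (F[i] - threshold) / (F[i] - F[j])
    return float(t[i] + frac * (t[j] - t[i]))


def energy_dissipation_pct(curve: ForceTimeCurve, method: str = "amplitude") -> float:
    """Percent of the peak force relaxed away over the hold phase.

    "amplitude" (default): 100 * (1 - F_end / F0) on the normalised
    curve — the relaxation amplitude.  "area": 100 * (1 - mean(F)/F0),
    i.e. one minus the normalised area under the hold-phase curve.
    """
    F = curve.F
    if method == "amplitude":
        val = 100.0 * (1.0 - F[-1] / F[0])
    elif method == "area":
        area = np.trapezoid(F, curve.t) / (F[0] * (curve.t[-1] - curve.t[0]))
        val = 100.0 * (1.0 - area)
    else:
        raise ValueError(f"unknown energy-dissipation method {method!r}")
    return float(min(100.0, max(0.0, val)))


def hertz_fit(curve: IndentationCurve, poisson: float = 0.5) -> float:
    """Young's modulus (Pa) from a spherical-probe indentation curve.

    Least-squares fit of F = (4/3) * E/(1 - nu^2) * sqrt(R) * d^(3/2)
    with F in nN, depth and R in um (so the raw coefficient is in kPa).
    The fit is linear in E, solved in closed form.  Negative fitted
    moduli (possible only with pathological input) raise.
    """
    d = curve.depth
    F = curve.F
    post = d > 0
    if post.sum() < 10:
        raise ValueError(f"need >= 10 post-contact points, got {int(post.sum())}")
    x = d[post] ** 1.5
    y = F[post]
    denom = float(np.dot(x, x))
    coeff = float(np.dot(x, y)) / denom  # nN / um^1.5
    e_kpa = coeff * 0.75 * (1.0 - poisson**2) / math.sqrt(curve.R)
    e_pa = e_kpa * 1e3
    if e_pa < 0:
        raise ValueError(
            f"Hertz fit returned negative modulus {e_pa:.3g} Pa "
            f"(coefficient {coeff:.3g} nN/um^1.5); check contact-point handling"
        )
    return e_pa


def analyze_relaxation_group(
    curves: list[ForceTimeCurve], ed_method: str = "amplitude"
) -> tuple[RelaxationSummary, ForceTimeCurve, np.ndarray]:
    """Full pipeline for one hydrogel condition.

    Preprocess every raw curve, average the normalised curves, then
    quantify t80 and percent energy dissipation on the average.  Returns
    (summary, average curve, per-point SD).
    """
    processed = [preprocess_relaxation(c) for c in curves]
    avg, sd = average_curves(processed)
    f0 = float(np.mean([c.meta["F0_nN"] for c in processed]))
    summary = RelaxationSummary(
        F0_nN=f0,
        t80_s=time_to_80pct(avg),
        energy_dissipation_pct=energy_dissipation_pct(avg, method=ed_method),
        n_curves=len(curves),
    )
    return summary, avg, sd


# ---------------------------------------------------------------------------
# plain-text curve I/O

_FTC_KIND = "force-time"
_IND_KIND = "force-depth"


def write_curve(curve: ForceTimeCurve | IndentationCurve, path: str | Path) -> None:
    """Write a curve as two-column text with a ``# key: value`` header."""
    path = Path(path)
    buf = io.StringIO()
    if isinstance(curve, ForceTimeCurve):
        buf.write(f"# kind: {_FTC_KIND}\n")
        buf.write(f"# x_units: {'s'}\n")
        buf.write(f"# f_units: {'dimensionless' if curve.normalized else 'nN'}\n")
        buf.write(f"# R_um: {curve.R}\n")
        buf.write(f"# h_um: {curve.h}\n")
        for k, v in curve.meta.items():
            buf.write(f"# meta_{k}: {v}\n")
        buf.write("# columns: t F\n")
        x, y = curve.t, curve.F
    else:
        buf.write(f"# kind: {_IND_KIND}\n")
        buf.write("# x_units: um\n")
        buf.write("# f_units: nN\n")
        buf.write(f"# R_um: {curve.R}\n")
        buf.write("# columns: depth F\n")
        x, y = curve.depth, curve.F
    for xi, yi in zip(x, y):
        buf.write(f"{xi:.9g}\t{yi:.9g}\n")
    path.write_text(buf.getvalue())


def read_curve(path: str | Path) -> ForceTimeCurve | IndentationCurve:
    """Read a curve written by :func:`write_curve`.

    Raises ValueError (naming the file) on unknown kinds or unit
    mismatches, so callers can list-and-skip bad files explicitly.
    """
    path = Path(path)
    header: dict[str, str] = {}
    xs: list[float] = []
    ys: list[float] = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if ":" in body:
                k, v = body.split(":", 1)
                header[k.strip()] = v.strip()
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ValueError(f"{path}: expected two columns, got {line!r}")
        xs.append(float(parts[0]))
        ys.append(float(parts[1]))
    kind = header.get("kind")
    if kind == _FTC_KIND:
        funits = header.get("f_units", "nN")
        if funits not in ("nN", "dimensionless"):
            raise ValueError(f"{path}: unsupported force units {funits!r}")
        if header.get("x_units", "s") != "s":
            raise ValueError(f"{path}: unsupported time units {header.get('x_units')!r}")
        meta = {
            k[len("meta_"):]: _maybe_float(v)
            for k, v in header.items()
            if k.startswith("meta_")
        }
        return ForceTimeCurve(
            t=np.array(xs),
            F=np.array(ys),
            R=float(header.get("R_um", 27.5)),
            h=float(header.get("h_um", 3.0)),
            normalized=funits == "dimensionless",
            meta=meta,
        )
    if kind == _IND_KIND:
        if header.get("x_units", "um") != "um":
            raise ValueError(f"{path}: unsupported depth units {header.get('x_units')!r}")
        if header.get("f_units", "nN") != "nN":
            raise ValueError(f"{path}: unsupported force units {header.get('f_units')!r}")
        return IndentationCurve(
            depth=np.array(xs), F=np.array(ys), R=float(header.get("R_um", 27.5))
        )
    raise ValueError(f"{path}: unknown or missing curve kind {kind!r}")


def _maybe_float(v: str):
    try:
        return float(v)
    except ValueError:
        return v
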