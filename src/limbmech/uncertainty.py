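"""Sensitivity analyses and Monte Carlo simulated error margins.

Three deterministic sensitivity analyses quantify modelling choices:

* attachment placement - each end point is translated by a fixed magnitude
  (default exactly 1 cm) along two anatomical axes, giving four variant
  moment-arm curves per muscle;
* wrapping-surface dimensions - each wrap radius is changed by +/- 2 cm and
  every assigned muscle recomputed;
* muscle/segment mass - mass tables are scaled by fixed factors (default
  +10% and +15%) and the between-model comparison re-run.

On top of these, a Monte Carlo procedure perturbs each member curve of a
functional group by a single uniform scale factor within +/-20% (one draw
per muscle per iteration, so perturbed curves stay smooth), re-sums the
group over many iterations and reports the pointwise min-max envelope - a
simulated error margin around the nominal group curve.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import LimbmechError, PathResolutionError
from .moment_arms import MomentArmCurve, group_summed_normalized, moment_arm_curve
from .path_engine import MusculotendonUnit, PathPoint

logger = logging.getLogger(__name__)

# anatomical axis -> joint-frame axis column (X abd/add points anteroposteriorly,
# Y along the long axis, Z flexion-extension points mediolaterally)
_ANATOMICAL_AXIS = {"anteroposterior": 0, "proximodistal": 1, "mediolateral": 2}

__all__ = [
    "PerturbationSpec",
    "EnvelopeResult",
    "attachment_sensitivity",
    "wrap_sensitivity",
    "mass_sensitivity",
    "monte_carlo_envelope",
]


@dataclass
class PerturbationSpec:
    kind: str                      # attachment | wrap_dimension | muscle_mass | segment_mass
    magnitude: float               # m for geometric kinds, factor-1 for mass kinds
    directions: tuple = ("mediolateral", "anteroposterior")
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("attachment", "wrap_dimension",
                             "muscle_mass", "segment_mass"):
            raise ValueError(f"unknown perturbation kind {self.kind!r}")
        if self.magnitude < 0:
            raise ValueError("perturbation magnitude must be non-negative")
        for d in self.directions:
            if d not in _ANATOMICAL_AXIS:
                raise ValueError(f"unknown anatomical direction {d!r}")


@dataclass
class EnvelopeResult:
    group: str
    angles_deg: np.ndarray
    nominal: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    iterations: int
    amplitude: float
    seed: int
    statistic: str = "minmax"

    def __post_init__(self):
        for name in ("angles_deg", "nominal", "lower", "upper"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if np.any(self.lower > self.nominal + 1e-12) or \
           np.any(self.upper < self.nominal - 1e-12):
            raise LimbmechError("envelope does not contain the nominal curve")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "group": self.group, "angle_deg": self.angles_deg,
            "nominal": self.nominal, "lower": self.lower, "upper": self.upper,
        })


# ---------------------------------------------------------------------------
# attachment sensitivity
# ---------------------------------------------------------------------------

def _axis_direction(model, segment: str, anatomical: str) -> np.ndarray:
    """Unit direction of an anatomical axis in a segment's frame.

    Taken from the segment's parent-joint axis triad (for the root, the
    world axes): the flexion-extension axis is mediolateral, the
    abduction/adduction axis anteroposterior, the long axis proximodistal.
    """
    joint = model.parent_joint(segment)
    axes = np.eye(3) if joint is None else joint.axes
    return axes[:, _ANATOMICAL_AXIS[anatomical]]


def _moved_mtu(mtu: MusculotendonUnit, which: str, offset: np.ndarray,
               label: str) -> MusculotendonUnit:
    pts = [PathPoint(p.point.copy(), p.segment) for p in mtu.points]
    idx = 0 if which == "origin" else -1
    pts[idx] = PathPoint(pts[idx].point + offset, pts[idx].segment)
    return MusculotendonUnit(f"{mtu.name}[{label}]", pts,
                             wraps=dict(mtu.wraps), mass=mtu.mass,
                             groups=list(mtu.groups))


def attachment_sensitivity(mtu, model, joint: str, dof: str, angles_deg,
                           wrap_objects=None, endpoint: str = "insertion",
                           magnitude: float = 0.01,
                           directions=("mediolateral", "anteroposterior")):
    """Moment-arm curves with the attachment moved +/-``magnitude`` along
    each of two anatomical axes (four variants), plus a deviation summary.

    For shaft attachments pass ``directions`` including 'proximodistal'.
    Variants whose path cannot be resolved (e.g. the moved point falls
    inside a wrap surface) are flagged failed; the others proceed.

    Returns ``(nominal_curve, {variant_label: curve_or_None}, summary_df)``.
    """
    spec = PerturbationSpec("attachment", magnitude, tuple(directions))
    nominal = moment_arm_curve(mtu, model, joint, dof, angles_deg, wrap_objects)
    seg = mtu.points[0 if endpoint == "origin" else -1].segment
    variants: dict = {}
    for direction in spec.directions:
        axis = _axis_direction(model, seg, direction)
        for sgn, tag in ((+1.0, "+"), (-1.0, "-")):
            label = f"{direction}{tag}"
            moved = _moved_mtu(mtu, endpoint, sgn * magnitude * axis, label)
            try:
                variants[label] = moment_arm_curve(
                    moved, model, joint, dof, angles_deg, wrap_objects)
            except PathResolutionError as exc:
                logger.warning("%s: variant %s failed: %s", mtu.name, label, exc)
                variants[label] = None
    rows = []
    for label, curve in variants.items():
        if curve is None:
            rows.append({"variant": label, "failed": True,
                         "max_abs_deviation_m": np.nan, "max_pct_deviation": np.nan})
            continue
        dev = np.abs(curve.values_m - nominal.values_m)
        scale = np.abs(nominal.values_m).max()
        rows.append({
            "variant": label, "failed": False,
            "max_abs_deviation_m": float(dev.max()),
            "max_pct_deviation": float(100.0 * dev.max() / scale) if scale > 0 else np.nan,
        })
    return nominal, variants, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# wrap-dimension sensitivity
# ---------------------------------------------------------------------------

def wrap_sensitivity(wrap, model, mtus, joint: str, dof: str, angles_deg,
                     wrap_objects, delta: float = 0.02,
                     min_radius: float = 1e-3):
    """Recompute assigned muscles with the wrap radius changed by +/-delta.

    A shrink below ``min_radius`` is clamped with a warning. Returns
    ``{variant_label: {muscle: curve_or_None}}`` plus a deviation summary.
    """
    nominal = {m.name: moment_arm_curve(m, model, joint, dof, angles_deg,
                                        wrap_objects) for m in mtus}
    results = {}
    rows = []
    for sgn, tag in ((+1.0, f"radius+{delta:g}"), (-1.0, f"radius-{delta:g}")):
        r = wrap.radius + sgn * delta
        if r < min_radius:
            logger.warning("wrap %s: shrink clamps radius %.4f -> %.4f m",
                           wrap.name, r, min_radius)
            r = min_radius
        variant_objects = dict(wrap_objects)
        variant_objects[wrap.name] = wrap.with_radius(r)
        per_muscle = {}
        for m in mtus:
            try:
                curve = moment_arm_curve(m, model, joint, dof, angles_deg,
                                         variant_objects)
            except PathResolutionError as exc:
                logger.warning("%s under %s: failed: %s", m.name, tag, exc)
                curve = None
            per_muscle[m.name] = curve
            dev = (np.nan if curve is None else
                   float(np.abs(curve.values_m - nominal[m.name].values_m).max()))
            rows.append({"variant": tag, "muscle": m.name,
                         "failed": curve is None, "max_abs_deviation_m": dev})
        results[tag] = per_muscle
    return nominal, results, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# mass sensitivity
# ---------------------------------------------------------------------------

def mass_sensitivity(masses: dict, factors=(1.10, 1.15)) -> dict:
    """Scaled copies of a mass table, one per factor."""
    if any(f <= 0 for f in factors):
        raise ValueError("mass factors must be positive")
    return {f: {k: v * f for k, v in masses.items()} for f in factors}


# ---------------------------------------------------------------------------
# Monte Carlo simulated error margin
# ---------------------------------------------------------------------------

def monte_carlo_envelope(curves, group: str, iterations: int = 1000,
                         amplitude: float = 0.20, seed: int = 0,
                         sign: float = 1.0,
                         renormalize_per_iteration: bool = False,
                         statistic: str = "minmax") -> EnvelopeResult:
    """Min-max (or percentile) envelope of the group curve under random
    per-muscle magnitude perturbation.

    Each iteration multiplies each member curve by an independent
    ``1 + u``, ``u ~ Uniform(-amplitude, +amplitude)`` (one draw per muscle,
    so each perturbed curve keeps its shape), sums the group and normalizes
    by the nominal summed peaks. ``renormalize_per_iteration`` divides by
    the perturbed peaks instead. Reproducible for a fixed seed.
    """
    if not 0.0 <= amplitude < 1.0:
        raise ValueError("amplitude must be in [0, 1)")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    if statistic not in ("minmax", "percentile"):
        raise ValueError("statistic must be 'minmax' or 'percentile'")
    curves = list(curves)
    nominal_group = group_summed_normalized(curves, group, sign=sign)
    grid = nominal_group.angles_deg
    oriented = np.array([sign * c.values_m for c in curves])   # (n_muscles, n_angles)
    peaks = oriented.max(axis=1)
    rng = np.random.default_rng(seed)
    u = rng.uniform(-amplitude, amplitude, size=(iterations, len(curves)))
    sums = (1.0 + u) @ oriented                                # (iters, n_angles)
    if renormalize_per_iteration:
        denom = ((1.0 + u) * peaks).sum(axis=1, keepdims=True)
    else:
        denom = peaks.sum()
    samples = sums / denom
    if statistic == "minmax":
        lower, upper = samples.min(axis=0), samples.max(axis=0)
    else:
        lower = np.percentile(samples, 2.5, axis=0)
        upper = np.percentile(samples, 97.5, axis=0)
    # amplitude 0 and containment guarantees
    lower = np.minimum(lower, nominal_group.normalized)
    upper = np.maximum(upper, nominal_group.normalized)
    return EnvelopeResult(group=group, angles_deg=grid.copy(),
                          nominal=nominal_group.normalized.copy(),
                          lower=lower, upper=upper, iterations=iterations,
                          amplitude=amplitude, seed=seed, statistic=statistic)
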