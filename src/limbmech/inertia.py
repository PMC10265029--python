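"""Convex-hull segment mass properties and segment-composition statistics.

Convex hulls over bony segments systematically under-estimate soft-tissue
segment mass, so a multiplicative per-segment correction factor is applied
to the hull mass (and, proportionally, to the inertia tensor; the centre of
mass is unchanged). Correction factors are user inputs: no published
per-segment values are bundled, and leaving the factor at 1.0 (the raw,
uncorrected baseline) triggers a warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import LimbmechError
from .mesh_core import TriMesh, convex_hull, mesh_inertia

logger = logging.getLogger(__name__)

HULL_DENSITY_DEFAULT = 1000.0  # kg m^-3, whole-segment proxy density

__all__ = [
    "HULL_DENSITY_DEFAULT",
    "HullSegmentProperties",
    "hull_properties",
    "segment_composition",
    "mass_comparison_table",
]


@dataclass
class HullSegmentProperties:
    segment: str
    hull: TriMesh
    raw_mass: float
    corrected_mass: float
    correction: float
    com: np.ndarray
    inertia: np.ndarray            # about com, corrected


def hull_properties(segment_name: str, meshes, density: float = HULL_DENSITY_DEFAULT,
                    correction: float = 1.0) -> HullSegmentProperties:
    """Convex-hull mass/COM/inertia over all vertices of a segment's meshes.

    ``correction`` multiplies the hull mass (inertia scales with it, COM is
    unchanged).
    """
    if density <= 0:
        raise ValueError("density must be positive")
    if correction <= 0:
        raise ValueError("correction factor must be positive")
    if correction == 1.0:
        logger.warning("%s: hull correction factor left at 1.0 (raw hull mass "
                       "is known to under-estimate segment mass)", segment_name)
    pts = np.vstack([np.asarray(m.vertices, dtype=float) for m in meshes])
    hull = convex_hull(pts, name=f"{segment_name}_hull")
    mass, com, inertia = mesh_inertia(hull, density)
    return HullSegmentProperties(
        segment=segment_name, hull=hull, raw_mass=mass,
        corrected_mass=mass * correction, correction=correction,
        com=com, inertia=inertia * correction)


def segment_composition(muscle_masses: dict, segment_mass: float,
                        subset=None) -> float:
    """Percentage of a segment's mass made up by the listed muscles."""
    if segment_mass <= 0:
        raise ValueError("segment mass must be positive")
    if subset is None:
        subset = list(muscle_masses)
    unknown = [m for m in subset if m not in muscle_masses]
    if unknown:
        raise LimbmechError(f"unknown muscles in subset: {unknown}")
    return 100.0 * sum(muscle_masses[m] for m in subset) / segment_mass


def mass_comparison_table(masses_a: dict, masses_b: dict,
                          segment_mass_a: dict, segment_mass_b: dict,
                          segment_of: dict,
                          labels=("A", "B")) -> pd.DataFrame:
    """Per-muscle comparison of segment-normalized masses between two models.

    ``segment_of`` maps muscle name -> segment name (shared across models).
    Columns include the normalized ratios, percentage difference, factor and
    log10 values for plotting; only muscles present in both models are
    compared.
    """
    shared = sorted(set(masses_a) & set(masses_b))
    if not shared:
        raise LimbmechError("no shared muscle names to compare")
    la, lb = labels
    rows = []
    for m in shared:
        seg = segment_of[m]
        na = masses_a[m] / segment_mass_a[seg]
        nb = masses_b[m] / segment_mass_b[seg]
        factor = na / nb if nb > 0 else np.inf
        rows.append({
            "muscle": m,
            "segment": seg,
            f"mass_{la}_kg": masses_a[m],
            f"mass_{lb}_kg": masses_b[m],
            f"normalized_{la}": na,
            f"normalized_{lb}": nb,
            "pct_difference": 100.0 * (na - nb) / nb if nb > 0 else np.inf,
            "factor": factor,
            "log10_factor": np.log10(factor) if factor > 0 else np.nan,
            "larger_in": la if na > nb else (lb if nb > na else "equal"),
        })
    df = pd.DataFrame(rows)
    df.attrs["n_larger"] = {
        la: int((df["larger_in"] == la).sum()),
        lb: int((df["larger_in"] == lb).sum()),
    }
    return df
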