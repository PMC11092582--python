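"""Per-atom solvent-accessible surface area (Shrake-Rupley).

Each atom's sphere is inflated by the probe radius and covered with a fixed,
deterministic set of quasi-uniform test points (golden-spiral placement, so
results are exactly reproducible for a given ``n_points``).  A test point is
accessible if it falls outside every neighbouring atom's inflated sphere;
the accessible fraction times the inflated sphere area gives the atomic
SASA in Angstrom^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from scipy.spatial import cKDTree

from cavscan.structio import Atom, Structure, StructureError

__all__ = ["SASAResult", "sphere_points", "compute_sasa", "classify_polarity"]

DEFAULT_PROBE = 1.4  # water probe radius, Angstrom
DEFAULT_N_POINTS = 960


@dataclass
class SASAResult:
    """Per-atom accessible areas aligned with the atom order of the input."""

    per_atom_area: np.ndarray  # Angstrom^2
    probe_radius: float
    n_points: int
    atom_serials: list[int] = field(default_factory=list)

    @property
    def total_area(self) -> float:
        return float(self.per_atom_area.sum())


def sphere_points(n: int) -> np.ndarray:
    """``n`` quasi-uniform unit vectors by the golden-spiral rule."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def compute_sasa(
    structure: Structure,
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
    restrict_to_chains: Iterable[str] | None = None,
) -> SASAResult:
    """Shrake-Rupley SASA for every heavy atom.

    With ``restrict_to_chains`` the named chains are evaluated *in the
    context of only those chains* (apo mode): atoms of other chains neither
    receive areas nor occlude anything.
    """
    if n_points < 60:
        raise ValueError("n_points must be >= 60 for a usable quadrature")
    atoms = structure.atoms(restrict_to_chains)
    if not atoms:
        raise StructureError("empty atom selection for SASA")

    centers = np.array([a.coords for a in atoms])
    radii = np.array([a.radius for a in atoms]) + probe
    unit = sphere_points(n_points)

    tree = cKDTree(centers)
    r_max = radii.max()
    areas = np.empty(len(atoms))
    for i in range(len(atoms)):
        # any sphere overlapping sphere i lies within r_i + r_max
        neigh = [j for j in tree.query_ball_point(centers[i], radii[i] + r_max)
                 if j != i
                 and np.linalg.norm(centers[j] - centers[i]) < radii[i] + radii[j]]
        pts = centers[i] + radii[i] * unit
        if neigh:
            d2 = ((pts[:, None, :] - centers[neigh][None, :, :]) ** 2).sum(axis=2)
            buried = (d2 < (radii[neigh] ** 2)[None, :]).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        areas[i] = frac * 4.0 * np.pi * radii[i] ** 2
    return SASAResult(
        per_atom_area=areas,
        probe_radius=probe,
        n_points=n_points,
        atom_serials=[a.serial for a in atoms],
    )


def classify_polarity(atom: Atom) -> str:
    """``"polar"`` for N/O atoms, ``"apolar"`` for C/S/P and anything else."""
    return "polar" if atom.element.upper() in {"N", "O"} else "apolar"
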