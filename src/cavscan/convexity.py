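"""Signed interface convexity from RANSAC sphere fits.

The curvature of a binding surface is summarized by fitting a sphere to the
interfacial heavy atoms (RANSAC: spheres through random 4-point samples,
consensus by inlier count at a distance threshold, default 1.0 Angstrom and
at most 100 000 iterations) and taking the reciprocal of the fitted radius.
The sign comes from an inner-product rule: with g_int the centroid of the
interfacial atoms and g_body the centroid of all heavy atoms of the protein
whose surface is assessed, the dot product

    (g_body - g_int) . (sphere_center - g_int)

is negative when the fitted sphere's center lies on the solvent side of the
surface — a concave pocket (convexity -1/R) — and positive when the center
is behind the surface, inside the body — a convex bulge (+1/R).  Near-flat
surfaces (huge fitted radius, or an ambiguous dot product) are classed flat
with convexity 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from cavscan.interface import DEFAULT_DSASA_THRESHOLD, find_interface
from cavscan.sasa import DEFAULT_N_POINTS, DEFAULT_PROBE, compute_sasa
from cavscan.structio import DegenerateGeometryError, Structure

__all__ = [
    "SphereFit",
    "ConvexityResult",
    "SphereFitError",
    "exact_sphere_through_4",
    "least_squares_sphere",
    "fit_sphere_ransac",
    "signed_convexity",
    "interface_convexity",
    "assign_helices",
    "scaffold_face_convexity",
]

DEFAULT_INLIER_THRESHOLD = 1.0  # Angstrom
DEFAULT_MAX_ITER = 100_000
RADIUS_CAP = 10_000.0  # Angstrom; fits at the cap are classed flat
FLAT_EPS = 1e-4  # 1/Angstrom
DEGENERATE_COND = 1e8
RANSAC_CONFIDENCE = 0.999


class SphereFitError(RuntimeError):
    """No acceptable sphere could be fitted to the points."""


@dataclass
class SphereFit:
    center: np.ndarray  # Angstrom
    radius: float  # Angstrom
    inlier_ids: np.ndarray  # indices into the input point array
    rms_residual: float  # Angstrom, over inliers
    iterations_run: int = 0
    seed: int | None = None
    inlier_threshold: float = DEFAULT_INLIER_THRESHOLD
    max_iter: int = DEFAULT_MAX_ITER
    refined: bool = False


@dataclass
class ConvexityResult:
    convexity: float  # signed, 1/Angstrom; 0 when flat
    shape_class: str  # concave | convex | flat
    fit: SphereFit
    sign_dot: float
    interface_centroid: np.ndarray
    body_centroid: np.ndarray
    n_interface_points: int = 0

    @property
    def is_concave(self) -> bool:
        return self.shape_class == "concave"


def exact_sphere_through_4(points: Sequence[np.ndarray] | np.ndarray) -> SphereFit | None:
    """Unique sphere through 4 points, or ``None`` when they are
    (near-)coplanar.

    Subtracting the first point's equation from the other three linearizes
    |p - c|^2 = R^2 into a 3x3 system for the center; quadruples whose
    system has condition number above 1e8 are treated as degenerate.
    """
    P = np.asarray(points, dtype=float)
    if P.shape != (4, 3):
        raise ValueError("exactly 4 points required")
    A = 2.0 * (P[1:] - P[0])
    b = (P[1:] ** 2).sum(axis=1) - (P[0] ** 2).sum()
    try:
        cond = np.linalg.cond(A)
    except np.linalg.LinAlgError:
        return None
    if not np.isfinite(cond) or cond > DEGENERATE_COND:
        return None
    center = np.linalg.solve(A, b)
    radius = float(np.linalg.norm(P[0] - center))
    res = np.abs(np.linalg.norm(P - center, axis=1) - radius)
    return SphereFit(
        center=center,
        radius=radius,
        inlier_ids=np.arange(4),
        rms_residual=float(np.sqrt((res**2).mean())),
    )


def least_squares_sphere(points: Sequence[np.ndarray] | np.ndarray) -> SphereFit:
    """Algebraic least-squares sphere (linearized on ``|p|^2``).

    Solves ``[2p | 1] [c; k] = |p|^2`` in the least-squares sense, with
    ``R^2 = k + |c|^2``.  Exact for noiseless sphere samples; raises
    :class:`~cavscan.structio.DegenerateGeometryError` on (near-)coplanar
    input, where the normal system loses rank.
    """
    P = np.asarray(points, dtype=float)
    if P.ndim != 2 or P.shape[1] != 3 or P.shape[0] < 4:
        raise ValueError("need >= 4 points of dimension 3")
    # coplanarity: centered covariance must have 3 significant directions
    C = P - P.mean(axis=0)
    sv = np.linalg.svd(C, compute_uv=False)
    if sv[0] == 0 or sv[2] / sv[0] < 1e-9:
        raise DegenerateGeometryError("points are coplanar; sphere is unconstrained")
    A = np.column_stack([2.0 * P, np.ones(len(P))])
    b = (P**2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    center, k = sol[:3], sol[3]
    r2 = k + (center**2).sum()
    if r2 <= 0:
        raise DegenerateGeometryError("least-squares sphere has non-positive radius")
    radius = float(np.sqrt(r2))
    res = np.linalg.norm(P - center, axis=1) - radius
    return SphereFit(
        center=center,
        radius=radius,
        inlier_ids=np.arange(len(P)),
        rms_residual=float(np.sqrt((res**2).mean())),
    )


def _adaptive_iters(inlier_ratio: float) -> int:
    if inlier_ratio >= 1.0:
        return 1
    w4 = inlier_ratio**4
    if w4 <= 0:
        return DEFAULT_MAX_ITER
    denom = math.log1p(-min(w4, 1 - 1e-12))
    return max(1, math.ceil(math.log(1.0 - RANSAC_CONFIDENCE) / denom))


def fit_sphere_ransac(
    points: Sequence[np.ndarray] | np.ndarray,
    inlier_threshold: float = DEFAULT_INLIER_THRESHOLD,
    max_iter: int = DEFAULT_MAX_ITER,
    seed: int = 0,
    refine: bool = True,
) -> SphereFit:
    """RANSAC consensus sphere through a noisy/outlier-laden point cloud.

    Random 4-point samples propose candidate spheres; the candidate with the
    most points within ``inlier_threshold`` of its surface wins (ties broken
    by lower inlier RMS residual).  With ``refine`` the winning consensus set
    is re-fit by :func:`least_squares_sphere` when that refit keeps at least
    as many inliers.  Iteration stops at the adaptive bound implied by the
    best inlier ratio (99.9% confidence) or at ``max_iter``, whichever is
    smaller; identical seeds give identical fits.
    """
    P = np.asarray(points, dtype=float)
    if P.ndim != 2 or P.shape[1] != 3 or P.shape[0] < 4:
        raise ValueError("need >= 4 points of dimension 3")
    n = P.shape[0]
    rng = np.random.default_rng(seed)

    best: SphereFit | None = None
    best_count = 0
    iters_needed = max_iter
    it = 0
    while it < min(max_iter, iters_needed):
        it += 1
        idx = rng.choice(n, size=4, replace=False)
        cand = exact_sphere_through_4(P[idx])
        if cand is None or cand.radius > RADIUS_CAP * 10:
            continue
        dist = np.abs(np.linalg.norm(P - cand.center, axis=1) - cand.radius)
        inliers = np.flatnonzero(dist <= inlier_threshold)
        if len(inliers) < 4:
            continue
        rms = float(np.sqrt((dist[inliers] ** 2).mean()))
        if len(inliers) > best_count or (
            best is not None and len(inliers) == best_count and rms < best.rms_residual
        ):
            best = SphereFit(
                center=cand.center,
                radius=cand.radius,
                inlier_ids=inliers,
                rms_residual=rms,
            )
            best_count = len(inliers)
            iters_needed = _adaptive_iters(best_count / n)

    if best is None:
        raise SphereFitError(
            "RANSAC found no sphere with >= 4 inliers (degenerate point cloud?)"
        )

    refined = False
    if refine:
        try:
            ls = least_squares_sphere(P[best.inlier_ids])
        except (DegenerateGeometryError, ValueError):
            ls = None
        if ls is not None:
            dist = np.abs(np.linalg.norm(P - ls.center, axis=1) - ls.radius)
            inliers = np.flatnonzero(dist <= inlier_threshold)
            if len(inliers) >= best_count:
                best = SphereFit(
                    center=ls.center,
                    radius=ls.radius,
                    inlier_ids=inliers,
                    rms_residual=float(np.sqrt((dist[inliers] ** 2).mean())),
                )
                refined = True

    best.iterations_run = it
    best.seed = seed
    best.inlier_threshold = inlier_threshold
    best.max_iter = max_iter
    best.refined = refined
    return best


def signed_convexity(
    interface_points: Sequence[np.ndarray] | np.ndarray,
    body_points: Sequence[np.ndarray] | np.ndarray,
    fit: SphereFit,
    flat_eps: float = FLAT_EPS,
) -> ConvexityResult:
    """Attach the concave/convex sign to a sphere fit.

    See the module docstring for the inner-product rule.  Flat when the
    unsigned curvature 1/R falls below ``flat_eps`` (includes radius-cap
    fits) or when the dot product is angularly ambiguous
    (|dot| < 1e-3 * |v1| * |v2|).
    """
    I = np.asarray(interface_points, dtype=float).reshape(-1, 3)
    B = np.asarray(body_points, dtype=float).reshape(-1, 3)
    if len(I) == 0 or len(B) == 0:
        raise ValueError("interface and body point sets must be non-empty")
    g_int = I.mean(axis=0)
    g_body = B.mean(axis=0)
    v1 = g_body - g_int
    v2 = fit.center - g_int
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        raise DegenerateGeometryError("interface and body centroids coincide")
    dot = float(v1 @ v2)

    kappa_abs = 0.0 if fit.radius >= RADIUS_CAP else 1.0 / fit.radius
    ambiguous = abs(dot) < 1e-3 * n1 * n2
    if kappa_abs < flat_eps or ambiguous:
        if ambiguous and kappa_abs >= flat_eps:
            import warnings

            warnings.warn("sign of convexity is angularly ambiguous; classed flat")
        kappa, shape = 0.0, "flat"
    elif dot > 0:
        kappa, shape = +kappa_abs, "convex"
    else:
        kappa, shape = -kappa_abs, "concave"
    return ConvexityResult(
        convexity=kappa,
        shape_class=shape,
        fit=fit,
        sign_dot=dot,
        interface_centroid=g_int,
        body_centroid=g_body,
        n_interface_points=len(I),
    )


def interface_convexity(
    complex_structure: Structure,
    partner: Iterable[str],
    other: Iterable[str],
    dsasa_threshold: float = DEFAULT_DSASA_THRESHOLD,
    inlier_threshold: float = DEFAULT_INLIER_THRESHOLD,
    max_iter: int = DEFAULT_MAX_ITER,
    seed: int = 0,
    refine: bool = True,
    min_interface_atoms: int = 10,
    n_points: int = DEFAULT_N_POINTS,
    body: str = "partner",
) -> ConvexityResult:
    """End-to-end convexity of ``partner``'s binding surface against ``other``.

    Detects interfacial heavy atoms by dSASA, RANSAC-fits a sphere to them,
    and applies the sign rule with the body centroid taken over all heavy
    atoms of ``partner`` (``body="complex"`` uses the whole complex instead).
    """
    partner, other = frozenset(partner), frozenset(other)
    iface = find_interface(
        complex_structure, partner, other, dsasa_threshold, n_points=n_points
    )
    serials = iface.interface_atoms_a
    pts = [a.coords for _, _, a in complex_structure.iter_atoms(partner)
           if a.serial in serials]
    if len(pts) < min_interface_atoms:
        raise SphereFitError(
            f"interface too small: {len(pts)} atoms < {min_interface_atoms}"
        )
    fit = fit_sphere_ransac(np.array(pts), inlier_threshold, max_iter, seed, refine)
    body_chains = partner if body == "partner" else partner | other
    body_pts = complex_structure.coords(body_chains)
    return signed_convexity(np.array(pts), body_pts, fit)


# --- secondary structure -----------------------------------------------------

def _dihedral(p0, p1, p2, p3) -> float:
    """Signed torsion angle p0-p1-p2-p3 in degrees (cis = 0)."""
    b0, b1, b2 = p0 - p1, p2 - p1, p3 - p2
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - (b0 @ b1) * b1
    w = b2 - (b2 @ b1) * b1
    x = v @ w
    y = np.cross(b1, v) @ w
    return math.degrees(math.atan2(y, x))


def assign_helices(structure: Structure, min_run: int = 5) -> dict[str, str]:
    """Per-chain secondary-structure strings over ``{H, -}``.

    Residues with full N/CA/C backbones are scored by phi/psi windows
    (phi in [-100, -30], psi in [-80, -5]); chains carrying only a CA trace
    fall back to the i->i+2 / i->i+3 CA-distance signature of an alpha
    helix.  Only runs of at least ``min_run`` residues are labeled H.
    """
    out: dict[str, str] = {}
    for chain in structure.chains:
        n = len(chain.residues)
        labels = ["-"] * n
        has_backbone = all(
            r.atom("N") and r.atom("CA") and r.atom("C") for r in chain.residues
        ) and n >= 3
        if has_backbone:
            for i in range(1, n - 1):
                prev_c = chain.residues[i - 1].atom("C").coords
                nn = chain.residues[i].atom("N").coords
                ca = chain.residues[i].atom("CA").coords
                cc = chain.residues[i].atom("C").coords
                next_n = chain.residues[i + 1].atom("N").coords
                phi = _dihedral(prev_c, nn, ca, cc)
                psi = _dihedral(nn, ca, cc, next_n)
                if -100 <= phi <= -30 and -80 <= psi <= -5:
                    labels[i] = "H"
        else:
            cas = [r.atom("CA") for r in chain.residues]
            for i in range(n):
                ok = True
                if i + 3 < n and all(cas[j] for j in (i, i + 2, i + 3)):
                    d13 = np.linalg.norm(cas[i + 2].coords - cas[i].coords)
                    d14 = np.linalg.norm(cas[i + 3].coords - cas[i].coords)
                    ok = 4.7 <= d13 <= 6.2 and 4.2 <= d14 <= 6.3
                else:
                    ok = False
                if ok:
                    for j in range(i, min(i + 4, n)):
                        labels[j] = "H"
        # chain breaks: consecutive CA atoms further apart than a bonded
        # residue step delimit helix runs even when labels are contiguous
        breaks = set()
        cas = [r.atom("CA") for r in chain.residues]
        for i in range(n - 1):
            if cas[i] is None or cas[i + 1] is None:
                breaks.add(i)
            elif np.linalg.norm(cas[i + 1].coords - cas[i].coords) > 4.5:
                breaks.add(i)
        # enforce minimum run length within break-delimited segments
        s = "".join(labels)
        cleaned = list(s)
        i = 0
        while i < n:
            if s[i] == "H":
                j = i
                while j < n and s[j] == "H" and not (j > i and (j - 1) in breaks):
                    j += 1
                if j - i < min_run:
                    cleaned[i:j] = "-" * (j - i)
                i = j
            else:
                i += 1
        out[chain.id] = "".join(cleaned)
    return out


def helix_segments(structure: Structure, min_run: int = 5) -> list[tuple[str, int, int]]:
    """Helix runs as ``(chain_id, start, stop)`` residue-index triples.

    Unlike reading the label string alone, runs are split at chain breaks
    (consecutive CA atoms > 4.5 A apart), so back-to-back helical segments
    with no loop residues between them count separately.
    """
    labels = assign_helices(structure, min_run=min_run)
    segments: list[tuple[str, int, int]] = []
    for chain in structure.chains:
        s = labels[chain.id]
        cas = [r.atom("CA") for r in chain.residues]
        i = 0
        n = len(s)
        while i < n:
            if s[i] != "H":
                i += 1
                continue
            j = i + 1
            while j < n and s[j] == "H":
                if (
                    cas[j - 1] is None
                    or cas[j] is None
                    or np.linalg.norm(cas[j].coords - cas[j - 1].coords) > 4.5
                ):
                    break
                j += 1
            if j - i >= min_run:
                segments.append((chain.id, i, j))
            i = j
    return segments


def helix_runs(labels: str) -> list[tuple[int, int]]:
    """(start, stop) index pairs (half-open) of the H runs in a label string."""
    runs = []
    i = 0
    while i < len(labels):
        if labels[i] == "H":
            j = i
            while j < len(labels) and labels[j] == "H":
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def scaffold_face_convexity(
    structure: Structure,
    face_helices: Iterable[int] = (1, 3, 5),
    surface_rel_sasa: float = 0.25,
    inlier_threshold: float = DEFAULT_INLIER_THRESHOLD,
    max_iter: int = DEFAULT_MAX_ITER,
    seed: int = 0,
    refine: bool = True,
    n_points: int = DEFAULT_N_POINTS,
) -> ConvexityResult:
    """Convexity of the face formed by the named helices of a scaffold.

    Helices are detected with :func:`assign_helices` and numbered 1..k in
    chain order.  The face point set holds heavy atoms of residues on the
    named helices that are solvent exposed (atomic SASA over the isolated-
    atom area >= ``surface_rel_sasa``) and sit on the half-space of the face
    helices opposite the remaining helices' centroid.  A sphere is RANSAC-
    fitted to those atoms and signed against the whole scaffold body;
    concave faces (negative convexity) are the ones a binder-design campaign
    keeps, convex ones are filtered out.
    """
    wanted = sorted(set(face_helices))
    # helices numbered across chains in chain order
    runs = helix_segments(structure)
    if not runs or wanted[-1] > len(runs):
        raise ValueError(
            f"scaffold has {len(runs)} helices; requested {wanted}"
        )
    face = [runs[i - 1] for i in wanted]
    backs = [runs[i] for i in range(len(runs)) if (i + 1) not in wanted]

    sasa = compute_sasa(structure, n_points=n_points)
    rel = {}
    for (c, r, a), area in zip(structure.iter_atoms(), sasa.per_atom_area):
        iso = 4.0 * np.pi * (a.radius + sasa.probe_radius) ** 2
        rel[a.serial] = area / iso

    def run_atoms(cid: str, start: int, stop: int):
        chain = structure.chain(cid)
        return [a for r in chain.residues[start:stop] for a in r.atoms]

    face_atoms = [a for run in face for a in run_atoms(*run)]
    back_atoms = [a for run in backs for a in run_atoms(*run)]
    if not face_atoms:
        raise ValueError("no atoms on the requested face helices")

    face_centroid = np.mean([a.coords for a in face_atoms], axis=0)
    if back_atoms:
        back_centroid = np.mean([a.coords for a in back_atoms], axis=0)
        away = face_centroid - back_centroid  # direction pointing off the face
        away = away / np.linalg.norm(away)
    else:
        away = None

    # local helix-axis estimate per residue (smoothed CA positions), so the
    # half-space test picks the face-side monolayer of each helix rather
    # than slicing the whole bundle with one plane
    selected = []
    for cid, start, stop in face:
        chain = structure.chain(cid)
        residues = chain.residues[start:stop]
        cas = [r.atom("CA") for r in residues]
        for j, r in enumerate(residues):
            lo, hi = max(0, j - 2), min(len(residues), j + 3)
            window = [cas[k].coords for k in range(lo, hi) if cas[k] is not None]
            axis_pt = np.mean(window, axis=0) if window else None
            for a in r.atoms:
                if rel[a.serial] < surface_rel_sasa:
                    continue
                if away is not None and axis_pt is not None:
                    if (a.coords - axis_pt) @ away <= 0:
                        continue
                selected.append(a.coords)
    if len(selected) < 4:
        raise SphereFitError(
            f"only {len(selected)} exposed face atoms; cannot fit a sphere"
        )
    pts = np.array(selected)
    fit = fit_sphere_ransac(pts, inlier_threshold, max_iter, seed, refine)
    return signed_convexity(pts, structure.coords(), fit)
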