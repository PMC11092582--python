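"""Synthetic structures and point clouds with known ground truth.

Every generator here is deterministic for a given seed and embeds its
ground truth (helix runs, face curvature, sphere parameters) in the
returned object's metadata, so the geometric pipeline — SASA, interface
detection, RANSAC sphere fits, sign classification — can be validated end
to end without downloading structures.

Geometry emulated:

* ideal alpha helices — 1.5 A rise and 100 degrees twist per residue, CA
  ring radius 2.3 A, giving the canonical ~3.8 A CA-CA spacing;
* five-helix bundles whose three odd-numbered helices line a spherical face
  of known radius (concave toward the sphere center, or convex), with the
  two even-numbered helices buttressing the back — the scaffold shape used
  for concave binder design;
* spherical-cap point clouds with Gaussian noise and uniform box outliers
  for sphere-fit recovery tests;
* toy two-chain dimers: a convex knob capped by a complementary concave
  socket, with a tunable contact gap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from cavscan.structio import Atom, Chain, Residue, Structure

__all__ = [
    "HelixSpec",
    "CapCloudSpec",
    "CapCloud",
    "make_ideal_helix",
    "make_concave_bundle",
    "make_cap_cloud",
    "make_toy_dimer",
]

RISE = 1.5  # A per residue along the helix axis
TWIST = 100.0  # degrees per residue
CA_RADIUS = 2.3  # A, radius of the CA ring around the axis


@dataclass
class HelixSpec:
    n_residues: int
    rise: float = RISE
    twist: float = TWIST
    ca_radius: float = CA_RADIUS
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)


@dataclass
class CapCloudSpec:
    radius: float
    cap_half_angle: float = 60.0  # degrees
    n_points: int = 300
    noise_sigma: float = 0.0  # A, isotropic
    outlier_fraction: float = 0.0
    seed: int = 0
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)


@dataclass
class CapCloud:
    points: np.ndarray
    center: np.ndarray
    radius: float
    inlier_mask: np.ndarray  # True for on-sphere samples, False for outliers


def _rotation_to(axis: np.ndarray) -> np.ndarray:
    """Rotation matrix taking +z onto the given axis direction."""
    z = np.array([0.0, 0.0, 1.0])
    a = np.asarray(axis, dtype=float)
    a = a / np.linalg.norm(a)
    v = np.cross(z, a)
    c = float(z @ a)
    if np.linalg.norm(v) < 1e-12:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))


def _mk_residue(resnum: int, coords: np.ndarray, serial: int,
                name: str = "ALA") -> Residue:
    atom = Atom(serial=serial, name="CA", element="C", coords=coords)
    return Residue(name=name, resnum=resnum, atoms=[atom])


_BACKBONE_GEOM = {
    # bond (A), angle (deg) used by the internal-coordinate builder
    "N-CA": 1.458, "CA-C": 1.525, "C-N": 1.329, "C-O": 1.231,
    "N-CA-C": 111.2, "CA-C-N": 116.2, "C-N-CA": 121.7, "CA-C-O": 120.8,
}
PHI_HELIX, PSI_HELIX, OMEGA = -57.0, -47.0, 180.0


def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray,
           bond: float, angle: float, torsion: float) -> np.ndarray:
    """Place atom d from internal coordinates relative to a-b-c (NeRF)."""
    ang, tor = math.radians(angle), math.radians(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * math.cos(ang),
            bond * math.sin(ang) * math.cos(tor),
            bond * math.sin(ang) * math.sin(tor),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def make_ideal_helix(
    n_residues: int,
    rise: float = RISE,
    twist: float = TWIST,
    ca_radius: float = CA_RADIUS,
    origin=(0.0, 0.0, 0.0),
    axis=(0.0, 0.0, 1.0),
    backbone: bool = False,
    chain_id: str = "A",
) -> Structure:
    """A single ideal alpha helix along ``axis``.

    Default mode is a CA trace placed parametrically on a helix of the
    given rise/twist/radius; ``backbone=True`` instead builds full N/CA/C/O
    backbones from ideal internal coordinates (phi -57, psi -47), aligned to
    the requested axis, so dihedral-based secondary-structure assignment has
    real phi/psi angles to work with.
    """
    if n_residues < 4:
        raise ValueError("a helix needs at least 4 residues")
    origin = np.asarray(origin, dtype=float)
    R = _rotation_to(np.asarray(axis, dtype=float))

    chain = Chain(id=chain_id)
    serial = 0
    if not backbone:
        for i in range(n_residues):
            ang = math.radians(twist * i)
            local = np.array(
                [ca_radius * math.cos(ang), ca_radius * math.sin(ang), rise * i]
            )
            serial += 1
            chain.residues.append(_mk_residue(i + 1, origin + R @ local, serial))
    else:
        g = _BACKBONE_GEOM
        # seed residue in an arbitrary frame; the chain is re-aligned below
        n0 = np.array([0.0, 0.0, 0.0])
        ca0 = n0 + np.array([g["N-CA"], 0.0, 0.0])
        ang = math.radians(g["N-CA-C"])
        c0 = ca0 + g["CA-C"] * np.array([math.cos(math.pi - ang), math.sin(math.pi - ang), 0.0])
        coords = [{"N": n0, "CA": ca0, "C": c0}]
        for _ in range(1, n_residues):
            prev = coords[-1]
            n = _place(prev["N"], prev["CA"], prev["C"], g["C-N"], g["CA-C-N"], PSI_HELIX)
            ca = _place(prev["CA"], prev["C"], n, g["N-CA"], g["C-N-CA"], OMEGA)
            c = _place(prev["C"], n, ca, g["CA-C"], g["N-CA-C"], PHI_HELIX)
            coords.append({"N": n, "CA": ca, "C": c})
        for i in range(n_residues - 1):
            coords[i]["O"] = _place(
                coords[i]["N"], coords[i]["CA"], coords[i]["C"],
                g["C-O"], g["CA-C-O"], PSI_HELIX + 180.0,
            )
        # align the helix axis (first principal direction of CAs) to +z,
        # then rotate to the requested axis
        cas = np.array([c["CA"] for c in coords])
        centered = cas - cas.mean(axis=0)
        _, _, Vt = np.linalg.svd(centered)
        ax = Vt[0]
        if ax @ (cas[-1] - cas[0]) < 0:
            ax = -ax
        to_z = _rotation_to(ax).T
        shift = cas[0]
        for i, res_atoms in enumerate(coords):
            residue = Residue(name="ALA", resnum=i + 1)
            for name in ("N", "CA", "C", "O"):
                if name not in res_atoms:
                    continue
                serial += 1
                pos = origin + R @ (to_z @ (res_atoms[name] - shift))
                residue.atoms.append(
                    Atom(serial=serial, name=name,
                         element="N" if name == "N" else ("O" if name == "O" else "C"),
                         coords=pos)
                )
            chain.residues.append(residue)

    st = Structure(chains=[chain], name="ideal_helix")
    st.metadata = {"generator": "make_ideal_helix", "n_residues": n_residues,
                   "rise": rise, "twist": twist, "ca_radius": ca_radius}
    return st


def make_concave_bundle(
    n_helices: int = 5,
    face_radius: float = 15.0,
    helix_len: int = 20,
    face: str = "concave",
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> Structure:
    """Five-helix bundle whose odd helices line a spherical face.

    Helices 1, 3, 5 (chain order) are wound around great-circle arcs so
    that their face-side CA atoms lie near a sphere of ``face_radius``
    centered at the origin; helices 2 and 4 buttress the opposite side.
    With ``face="concave"`` the body sits outside the sphere (face curves
    away from the body toward the center: ground-truth convexity
    ``-1/face_radius``); ``face="convex"`` mirrors the construction
    (ground truth ``+1/face_radius``).

    Ground truth is stored in ``Structure.metadata``.
    """
    if n_helices != 5:
        raise ValueError("bundle generator supports exactly 5 helices")
    if face_radius < 10.0:
        raise ValueError("face_radius must be >= 10 A for a packable bundle")
    if face_radius > 5000.0:
        raise ValueError("face_radius beyond 5000 A is indistinguishable from flat")
    if face not in ("concave", "convex"):
        raise ValueError("face must be 'concave' or 'convex'")
    rng = np.random.default_rng(seed)

    r_h = CA_RADIUS
    sign = +1.0 if face == "concave" else -1.0
    # axis-circle radius: face-side atoms (offset r_h toward the sphere
    # center for a concave face, away for a convex one) land on face_radius
    r_axis = face_radius + sign * r_h
    back_off = 9.0  # radial offset of the buttressing helices
    sep = 10.5  # lateral center-to-center spacing between face helices
    gamma = sep / r_axis

    # helix slots in chain order: (azimuth about x-axis, radial shift, is_face)
    slots = [
        (-gamma, 0.0, True),
        (-gamma / 2.0, sign * back_off, False),
        (0.0, 0.0, True),
        (gamma / 2.0, sign * back_off, False),
        (gamma, 0.0, True),
    ]

    chain = Chain(id="A")
    serial = 0
    resnum = 0
    arc_step = RISE  # arc length per residue along the bent axis
    for k, (az, roff, _is_face) in enumerate(slots):
        r_ax = r_axis + roff
        dalpha = arc_step / r_ax
        alpha0 = -dalpha * (helix_len - 1) / 2.0
        direction = 1 if k % 2 == 0 else -1  # antiparallel packing
        for j in range(helix_len):
            jj = j if direction == 1 else helix_len - 1 - j
            alpha = alpha0 + dalpha * jj
            # arc on the sphere of radius r_ax, tilted by az about x
            u = np.array(
                [
                    math.sin(alpha),
                    math.sin(az) * math.cos(alpha),
                    math.cos(az) * math.cos(alpha),
                ]
            )
            a_pt = r_ax * u
            # local frame: tangent along the arc, inward normal toward origin
            t = np.array(
                [
                    math.cos(alpha),
                    -math.sin(az) * math.sin(alpha),
                    -math.cos(az) * math.sin(alpha),
                ]
            )
            n_in = -u * sign  # toward the sphere center for a concave face
            b = np.cross(t, n_in)
            psi = math.radians(TWIST) * jj
            pos = a_pt + r_h * (math.cos(psi) * n_in + math.sin(psi) * b)
            if noise_sigma > 0:
                pos = pos + rng.normal(0.0, noise_sigma, 3)
            resnum += 1
            serial += 1
            chain.residues.append(_mk_residue(resnum, pos, serial))

    st = Structure(chains=[chain], name="bundle")
    st.metadata = {
        "generator": "make_concave_bundle",
        "face_radius": face_radius,
        "face": face,
        "kappa_true": -sign / face_radius,
        "helix_len": helix_len,
        "n_helices": n_helices,
        "face_helices": (1, 3, 5),
        "seed": seed,
    }
    return st


def make_cap_cloud(spec: CapCloudSpec) -> CapCloud:
    """Seeded spherical-cap samples plus uniform box outliers."""
    if spec.n_points < 10:
        raise ValueError("need at least 10 points")
    rng = np.random.default_rng(spec.seed)
    center = np.asarray(spec.center, dtype=float)
    n_out = int(round(spec.outlier_fraction * spec.n_points))
    n_in = spec.n_points - n_out

    cos_max = math.cos(math.radians(spec.cap_half_angle))
    cosphi = rng.uniform(cos_max, 1.0, n_in)
    sinphi = np.sqrt(1.0 - cosphi**2)
    theta = rng.uniform(0.0, 2.0 * math.pi, n_in)
    pts = spec.radius * np.column_stack(
        [sinphi * np.cos(theta), sinphi * np.sin(theta), cosphi]
    )
    if spec.noise_sigma > 0:
        pts = pts + rng.normal(0.0, spec.noise_sigma, pts.shape)
    half = spec.radius * 1.1
    outliers = rng.uniform(-half, half, (n_out, 3))
    points = np.vstack([pts, outliers]) + center
    mask = np.zeros(spec.n_points, dtype=bool)
    mask[:n_in] = True
    return CapCloud(points=points, center=center, radius=spec.radius, inlier_mask=mask)


def _cap_grid(radius: float, half_angle_deg: float, spacing: float,
              rng: np.random.Generator | None = None,
              noise_sigma: float = 0.0) -> np.ndarray:
    """Quasi-uniform atom positions covering a spherical cap about +z."""
    area = 2.0 * math.pi * radius**2 * (1.0 - math.cos(math.radians(half_angle_deg)))
    n = max(8, int(round(area / spacing**2)))
    i = np.arange(n) + 0.5
    cos_max = math.cos(math.radians(half_angle_deg))
    cosphi = 1.0 - (1.0 - cos_max) * i / n
    sinphi = np.sqrt(1.0 - cosphi**2)
    theta = math.pi * (1.0 + math.sqrt(5.0)) * i
    pts = radius * np.column_stack(
        [sinphi * np.cos(theta), sinphi * np.sin(theta), cosphi]
    )
    if rng is not None and noise_sigma > 0:
        pts = pts + rng.normal(0.0, noise_sigma, pts.shape)
    return pts


def make_toy_dimer(
    contact_gap: float = 0.5,
    radius: float = 12.0,
    noise_sigma: float = 0.3,
    seed: int = 0,
    cap_half_angle: float = 55.0,
    spacing: float = 3.2,
) -> Structure:
    """Complementary knob/socket dimer with a tunable contact gap.

    Chain A is a convex knob: a cap of atoms on a sphere of ``radius``
    centered at the origin (bulging toward +z) backed by body atoms on an
    inner shell.  Chain B is the matching concave socket: a cap on a
    concentric sphere ``4.0 + contact_gap`` A further out, backed by body
    atoms on an outer shell.  At small gaps the two caps bury each other's
    surface (a real dSASA interface); at large gaps the chains do not touch.
    Ground-truth signed curvatures (+1/R knob, -1/R_socket socket) are in
    ``Structure.metadata``.
    """
    if contact_gap < 0:
        raise ValueError("contact_gap must be >= 0")
    rng = np.random.default_rng(seed)
    r_knob = radius
    r_sock = radius + 4.0 + contact_gap

    knob_iface = _cap_grid(r_knob, cap_half_angle, spacing, rng, noise_sigma)
    knob_body = _cap_grid(r_knob - 4.5, cap_half_angle + 15, spacing, rng, noise_sigma)
    sock_iface = _cap_grid(r_sock, cap_half_angle, spacing, rng, noise_sigma)
    sock_body = _cap_grid(r_sock + 4.5, cap_half_angle + 15, spacing, rng, noise_sigma)

    st = Structure(name="toy_dimer")
    serial = 0
    for cid, layers in (("A", (knob_iface, knob_body)), ("B", (sock_iface, sock_body))):
        chain = Chain(id=cid)
        resnum = 0
        for layer in layers:
            for pos in layer:
                resnum += 1
                serial += 1
                chain.residues.append(_mk_residue(resnum, pos, serial, name="GLY"))
        st.chains.append(chain)
    st.metadata = {
        "generator": "make_toy_dimer",
        "contact_gap": contact_gap,
        "knob_radius": r_knob,
        "socket_radius": r_sock,
        "kappa_knob_true": +1.0 / r_knob,
        "kappa_socket_true": -1.0 / r_sock,
        "noise_sigma": noise_sigma,
        "seed": seed,
    }
    return st
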