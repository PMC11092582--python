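"""Macromolecular structure I/O, the heavy-atom model, and rigid superposition.

The in-memory model is deliberately small: chains -> residues -> heavy
atoms, with van der Waals radii attached at read time so downstream surface
code never needs to know about element chemistry.  Parsing and writing of
PDB/mmCIF goes through :mod:`gemmi`; this module owns filtering (hydrogens,
waters, hetero groups, altlocs) and the mapping onto the light containers.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Literal, Sequence

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "Structure",
    "SuperpositionResult",
    "VDW_RADII",
    "DEFAULT_RADIUS",
    "STANDARD_AA",
    "StructureError",
    "DegenerateGeometryError",
    "read_structure",
    "write_structure",
    "superpose_kabsch",
    "ca_rmsd",
]

# Heavy-atom van der Waals radii (Angstrom).  Elements not listed fall back
# to DEFAULT_RADIUS; the choice is recorded in output metadata by callers.
VDW_RADII: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
}
DEFAULT_RADIUS = 1.70

POLAR_ELEMENTS = frozenset({"N", "O"})

STANDARD_AA = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO "
    "SER THR TRP TYR VAL MSE".split()
)

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M",
}


class StructureError(ValueError):
    """Raised for unreadable, malformed or empty structures."""


class DegenerateGeometryError(ValueError):
    """Raised when point geometry is too degenerate for the requested fit."""


@dataclass
class Atom:
    """A single heavy atom with coordinates and a vdW radius in Angstrom."""

    serial: int
    name: str
    element: str
    coords: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""
    radius: float = DEFAULT_RADIUS
    is_polar: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise StructureError(f"atom {self.serial} {self.name}: bad coordinates")
        if self.radius <= 0:
            raise StructureError(f"atom {self.serial} {self.name}: radius must be > 0")
        self.is_polar = self.element.upper() in POLAR_ELEMENTS


@dataclass
class Residue:
    name: str
    resnum: int
    icode: str = ""
    atoms: list[Atom] = field(default_factory=list)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def key(self) -> tuple[int, str]:
        return (self.resnum, self.icode)


@dataclass
class Chain:
    id: str
    residues: list[Residue] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class Structure:
    """Ordered chains of residues of heavy atoms.

    After standard read-time filtering only heavy atoms of polymer residues
    remain; waters and hetero groups are dropped unless explicitly kept.
    """

    chains: list[Chain] = field(default_factory=list)
    name: str = ""
    metadata: dict = field(default_factory=dict)

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.id == chain_id:
                return c
        raise KeyError(f"no chain {chain_id!r} in structure")

    @property
    def chain_ids(self) -> list[str]:
        return [c.id for c in self.chains]

    def iter_atoms(
        self, chains: Iterable[str] | None = None
    ) -> Iterator[tuple[Chain, Residue, Atom]]:
        wanted = None if chains is None else set(chains)
        for c in self.chains:
            if wanted is not None and c.id not in wanted:
                continue
            for r in c.residues:
                for a in r.atoms:
                    yield c, r, a

    def atoms(self, chains: Iterable[str] | None = None) -> list[Atom]:
        return [a for _, _, a in self.iter_atoms(chains)]

    def coords(self, chains: Iterable[str] | None = None) -> np.ndarray:
        ats = self.atoms(chains)
        if not ats:
            return np.empty((0, 3))
        return np.array([a.coords for a in ats])

    def n_atoms(self) -> int:
        return sum(len(r.atoms) for c in self.chains for r in c.residues)

    def subset(self, chains: Iterable[str]) -> "Structure":
        wanted = set(chains)
        missing = wanted - set(self.chain_ids)
        if missing:
            raise KeyError(f"chains not in structure: {sorted(missing)}")
        return Structure(
            chains=[copy.deepcopy(c) for c in self.chains if c.id in wanted],
            name=self.name,
        )

    def sequence(self, chain_id: str) -> str:
        return "".join(
            THREE_TO_ONE.get(r.name, "X") for r in self.chain(chain_id).residues
        )

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """Return a rigidly transformed deep copy (x -> R x + t)."""
        out = copy.deepcopy(self)
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        for _, _, a in out.iter_atoms():
            a.coords = R @ a.coords + t
        return out


@dataclass
class SuperpositionResult:
    rotation: np.ndarray  # 3x3, det +1
    translation: np.ndarray  # Angstrom
    rmsd: float
    n_pairs: int


def _radius_for(element: str) -> float:
    return VDW_RADII.get(element.upper(), DEFAULT_RADIUS)


def _pick_altloc(atoms: list[gemmi.Atom]) -> gemmi.Atom:
    # highest occupancy; ties resolved toward 'A' then alphabetical altloc
    def key(a: gemmi.Atom) -> tuple[float, int, str]:
        alt = a.altloc if a.altloc else "A"
        return (-a.occ, 0 if alt == "A" else 1, alt)

    return sorted(atoms, key=key)[0]


def read_structure(
    path: str | Path,
    format: Literal["pdb", "mmcif", "auto"] = "auto",
    keep_hetero: bool = False,
    keep_hydrogens: bool = False,
) -> Structure:
    """Read a PDB or mmCIF file into the filtered heavy-atom model.

    Parameters
    ----------
    path:
        File to read.
    format:
        ``"pdb"``, ``"mmcif"`` or ``"auto"`` (detect from extension/content).
    keep_hetero:
        Keep non-polymer hetero residues (waters are governed by the same
        flag; by default both are dropped).
    keep_hydrogens:
        Keep H/D atoms; dropped by default so the model holds heavy atoms
        only, as the surface and curvature calculations expect.

    Raises
    ------
    StructureError
        If the file cannot be parsed or contains no atoms after filtering.
    """
    path = Path(path)
    if not path.exists():
        raise StructureError(f"no such file: {path}")
    try:
        if format == "pdb":
            st = gemmi.read_pdb(str(path))
        elif format == "mmcif":
            st = gemmi.make_structure_from_block(gemmi.cif.read(str(path))[0])
        else:
            st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError, IndexError) as exc:
        raise StructureError(f"cannot parse {path}: {exc}") from exc

    st.setup_entities()
    if not len(st):
        raise StructureError(f"{path}: no models")
    model = st[0]

    out = Structure(name=path.stem)
    serial = 0
    for ch in model:
        chain = Chain(id=ch.name)
        for res in ch:
            is_water = res.name == "HOH" or res.is_water()
            is_polymer = res.name in STANDARD_AA or res.het_flag == "A"
            if is_water and not keep_hetero:
                continue
            if not is_polymer and not is_water and not keep_hetero:
                continue
            residue = Residue(name=res.name, resnum=res.seqid.num,
                              icode=res.seqid.icode.strip())
            by_name: dict[str, list[gemmi.Atom]] = {}
            for at in res:
                if not keep_hydrogens and at.element.name in ("H", "D"):
                    continue
                by_name.setdefault(at.name, []).append(at)
            for name, alts in by_name.items():
                at = _pick_altloc(alts)
                serial += 1
                elem = at.element.name.upper()
                residue.atoms.append(
                    Atom(
                        serial=serial,
                        name=name,
                        element=elem,
                        coords=np.array([at.pos.x, at.pos.y, at.pos.z]),
                        occupancy=at.occ,
                        altloc=at.altloc or "",
                        radius=_radius_for(elem),
                    )
                )
            if residue.atoms:
                chain.residues.append(residue)
        if chain.residues:
            out.chains.append(chain)

    if not out.chains:
        raise StructureError(f"{path}: empty structure after filtering")
    return out


def write_structure(structure: Structure, path: str | Path) -> None:
    """Write the structure as a PDB file (hybrid-36 serials past 99999)."""
    if structure.n_atoms() == 0:
        raise StructureError("refusing to write an empty structure")
    st = gemmi.Structure()
    st.name = structure.name or "cavscan"
    model = gemmi.Model("1")
    serial = 0
    for chain in structure.chains:
        gch = gemmi.Chain(chain.id)
        for res in chain.residues:
            gres = gemmi.Residue()
            gres.name = res.name
            gres.seqid = gemmi.SeqId(res.resnum, res.icode or " ")
            for atom in res.atoms:
                serial += 1
                gat = gemmi.Atom()
                gat.name = atom.name
                gat.element = gemmi.Element(atom.element)
                gat.pos = gemmi.Position(*atom.coords)
                gat.occ = atom.occupancy
                gat.serial = serial
                gres.add_atom(gat)
            gch.add_residue(gres)
        model.add_chain(gch)
    st.add_model(model)
    st.setup_entities()
    try:
        st.write_pdb(str(path))
    except (RuntimeError, OSError) as exc:
        raise IOError(f"cannot write {path}: {exc}") from exc


def superpose_kabsch(
    mobile: Sequence[np.ndarray] | np.ndarray,
    reference: Sequence[np.ndarray] | np.ndarray,
) -> SuperpositionResult:
    """Optimal least-squares rigid superposition (Kabsch/SVD).

    Returns the rotation R and translation t minimizing
    ``sum || (R x_i + t) - y_i ||^2`` over the paired points, together with
    the post-fit RMSD.  R always has determinant +1 (proper rotation).
    """
    X = np.asarray(mobile, dtype=float)
    Y = np.asarray(reference, dtype=float)
    if X.shape != Y.shape or X.ndim != 2 or X.shape[1] != 3:
        raise ValueError("mobile and reference must be matching (n, 3) arrays")
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 point pairs")
    xc, yc = X.mean(axis=0), Y.mean(axis=0)
    X0, Y0 = X - xc, Y - yc
    # collinearity check: rank of centered cloud must be >= 2
    if np.linalg.matrix_rank(X0, tol=1e-8) < 2 or np.linalg.matrix_rank(Y0, tol=1e-8) < 2:
        raise DegenerateGeometryError("points are collinear or coincident")
    H = X0.T @ Y0
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = yc - R @ xc
    diff = (X @ R.T + t) - Y
    rmsd = float(np.sqrt((diff**2).sum() / n))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd, n_pairs=n)


def _ca_pairs_auto(a: Structure, b: Structure) -> tuple[np.ndarray, np.ndarray]:
    coords_a, coords_b, missing = [], [], []
    b_index: dict[tuple[str, int, str], Residue] = {}
    for ch in b.chains:
        for r in ch.residues:
            b_index[(ch.id, r.resnum, r.icode)] = r
    for ch in a.chains:
        for r in ch.residues:
            ca = r.atom("CA")
            if ca is None:
                continue
            other = b_index.get((ch.id, r.resnum, r.icode))
            if other is None:
                continue
            ca_b = other.atom("CA")
            if ca_b is None:
                missing.append((ch.id, r.resnum))
                continue
            coords_a.append(ca.coords)
            coords_b.append(ca_b.coords)
    return np.array(coords_a), np.array(coords_b)


def ca_rmsd(
    struct_a: Structure,
    struct_b: Structure,
    pairing: Literal["auto"] | Sequence[tuple[tuple[str, int], tuple[str, int]]] = "auto",
) -> float:
    """Kabsch-superposed C-alpha RMSD between two structures, in Angstrom.

    ``pairing="auto"`` matches residues by (chain id, residue number,
    insertion code); an explicit pairing is a list of
    ``((chain, resnum), (chain, resnum))`` tuples and every listed residue
    must exist with a CA atom in both structures.
    """
    if pairing == "auto":
        A, B = _ca_pairs_auto(struct_a, struct_b)
    else:
        coords_a, coords_b, missing = [], [], []
        for (ca_id, ra), (cb_id, rb) in pairing:
            try:
                res_a = next(r for r in struct_a.chain(ca_id).residues if r.resnum == ra)
                at_a = res_a.atom("CA")
            except (KeyError, StopIteration):
                at_a = None
            try:
                res_b = next(r for r in struct_b.chain(cb_id).residues if r.resnum == rb)
                at_b = res_b.atom("CA")
            except (KeyError, StopIteration):
                at_b = None
            if at_a is None or at_b is None:
                missing.append(((ca_id, ra), (cb_id, rb)))
                continue
            coords_a.append(at_a.coords)
            coords_b.append(at_b.coords)
        if missing:
            raise ValueError(f"pairing entries without CA in both structures: {missing}")
        A, B = np.array(coords_a), np.array(coords_b)
    if len(A) < 3:
        raise ValueError(f"only {len(A)} CA pairs resolved; need >= 3")
    return superpose_kabsch(A, B).rmsd
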