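"""Interface detection by apo-vs-holo dSASA, buried surface area, hotspot span.

An atom is interfacial when its solvent-accessible area drops by at least a
threshold (0.5 Angstrom^2 by default) on complex formation: per-atom
``dSASA = SASA(partner alone) - SASA(partner in complex)``, clamped at zero.
The buried surface area (BSA) sums dSASA over both partners and decomposes
it into polar (N/O) and apolar contributions, the quantities reported in
per-interface profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np

from cavscan.sasa import DEFAULT_N_POINTS, DEFAULT_PROBE, classify_polarity, compute_sasa
from cavscan.structio import Structure

__all__ = [
    "InterfaceDefinition",
    "BuriedSurface",
    "find_interface",
    "buried_surface_area",
    "hotspot_span",
    "extract_chain_pairs",
]

DEFAULT_DSASA_THRESHOLD = 0.5  # Angstrom^2 per heavy atom


@dataclass
class InterfaceDefinition:
    partner_a: frozenset[str]
    partner_b: frozenset[str]
    per_atom_dsasa: dict[int, float]  # atom serial -> dSASA (clamped >= 0)
    interface_atoms_a: frozenset[int]
    interface_atoms_b: frozenset[int]
    dsasa_threshold: float
    structure: Structure = field(repr=False)

    @property
    def interface_residues_a(self) -> set[tuple[str, int, str]]:
        return self._residues(self.partner_a, self.interface_atoms_a)

    @property
    def interface_residues_b(self) -> set[tuple[str, int, str]]:
        return self._residues(self.partner_b, self.interface_atoms_b)

    def _residues(self, chains: frozenset[str], serials: frozenset[int]):
        out = set()
        for c, r, a in self.structure.iter_atoms(chains):
            if a.serial in serials:
                out.add((c.id, r.resnum, r.icode))
        return out


@dataclass
class BuriedSurface:
    polar: float
    apolar: float
    convention: Literal["sum-both-partners", "half"] = "sum-both-partners"

    @property
    def total(self) -> float:
        return self.polar + self.apolar


def find_interface(
    complex_structure: Structure,
    partner_a: Iterable[str],
    partner_b: Iterable[str],
    dsasa_threshold: float = DEFAULT_DSASA_THRESHOLD,
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
) -> InterfaceDefinition:
    """Flag interfacial heavy atoms of two chain groups by apo-holo dSASA."""
    set_a, set_b = frozenset(partner_a), frozenset(partner_b)
    if not set_a or not set_b:
        raise ValueError("both partners must name at least one chain")
    if set_a & set_b:
        raise ValueError(f"partners overlap: {sorted(set_a & set_b)}")
    for cid in set_a | set_b:
        complex_structure.chain(cid)  # raises KeyError if absent

    both = set_a | set_b
    holo = compute_sasa(complex_structure, probe, n_points, restrict_to_chains=both)
    holo_by_serial = dict(zip(holo.atom_serials, holo.per_atom_area))

    dsasa: dict[int, float] = {}
    iface: dict[frozenset[str], set[int]] = {set_a: set(), set_b: set()}
    for chains in (set_a, set_b):
        apo = compute_sasa(complex_structure, probe, n_points, restrict_to_chains=chains)
        for serial, apo_area in zip(apo.atom_serials, apo.per_atom_area):
            d = max(0.0, apo_area - holo_by_serial[serial])
            dsasa[serial] = d
            if d >= dsasa_threshold:
                iface[chains].add(serial)

    return InterfaceDefinition(
        partner_a=set_a,
        partner_b=set_b,
        per_atom_dsasa=dsasa,
        interface_atoms_a=frozenset(iface[set_a]),
        interface_atoms_b=frozenset(iface[set_b]),
        dsasa_threshold=dsasa_threshold,
        structure=complex_structure,
    )


def buried_surface_area(
    iface: InterfaceDefinition,
    convention: Literal["sum-both-partners", "half"] = "sum-both-partners",
) -> BuriedSurface:
    """Polar/apolar decomposition of the total buried area.

    polar = sum of dSASA over N/O atoms of both partners, apolar = the rest;
    the ``half`` convention divides both by two.
    """
    polar = apolar = 0.0
    for _, _, atom in iface.structure.iter_atoms(iface.partner_a | iface.partner_b):
        d = iface.per_atom_dsasa.get(atom.serial, 0.0)
        if classify_polarity(atom) == "polar":
            polar += d
        else:
            apolar += d
    if convention == "half":
        polar, apolar = polar / 2.0, apolar / 2.0
    return BuriedSurface(polar=polar, apolar=apolar, convention=convention)


def hotspot_span(
    structure: Structure,
    residue_set: Iterable[tuple[str, int] | tuple[str, int, str]],
    atom_rule: Literal["CA", "CB-or-CA"] = "CA",
) -> float:
    """Largest pairwise distance between representative atoms of the
    selected (hot-spot) residues, in Angstrom."""
    wanted = set()
    for sel in residue_set:
        cid, num = sel[0], sel[1]
        icode = sel[2] if len(sel) > 2 else ""
        wanted.add((cid, num, icode))
    if not wanted:
        raise ValueError("empty residue selection")

    reps = []
    seen = set()
    for c, r, _ in structure.iter_atoms():
        key = (c.id, r.resnum, r.icode)
        if key not in wanted or key in seen:
            continue
        seen.add(key)
        atom = None
        if atom_rule == "CB-or-CA":
            atom = r.atom("CB") or r.atom("CA")
        else:
            atom = r.atom("CA")
        if atom is None:
            import warnings

            warnings.warn(f"residue {key} lacks a representative atom; skipped")
            continue
        reps.append(atom.coords)
    if not reps:
        raise ValueError("no residue in the selection has a representative atom")
    if len(reps) == 1:
        return 0.0
    P = np.array(reps)
    d2 = ((P[:, None, :] - P[None, :, :]) ** 2).sum(axis=2)
    return float(np.sqrt(d2.max()))


def extract_chain_pairs(
    structure: Structure,
    min_chain_length: int = 40,
    min_dsasa: float = 400.0,
    dsasa_threshold: float = DEFAULT_DSASA_THRESHOLD,
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
) -> list[tuple[str, str, float, tuple[int, int]]]:
    """All unordered chain pairs whose chains are long enough and whose
    total buried area reaches ``min_dsasa`` (Angstrom^2).

    Returns ``(chain_a, chain_b, total_dsasa, (len_a, len_b))`` tuples.
    """
    ids = structure.chain_ids
    out = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            a, b = ids[i], ids[j]
            la, lb = len(structure.chain(a)), len(structure.chain(b))
            if la < min_chain_length or lb < min_chain_length:
                continue
            iface = find_interface(structure, {a}, {b}, dsasa_threshold, probe, n_points)
            total = buried_surface_area(iface).total
            if total >= min_dsasa:
                out.append((a, b, total, (la, lb)))
    return out
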