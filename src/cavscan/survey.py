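"""Survey of interface convexity across many complexes.

Interacting chain pairs are de-redundified by greedy leader clustering at a
sequence-identity threshold applied to *both* chains (40% by default), with
cluster representatives favouring higher resolution and shorter proteins.
For each representative complex the convexity of the two partners is
computed, and the survey summarizes the partner-convexity relationship —
for shape-complementary interfaces the two signed convexities are strongly
negatively correlated (a convex partner meets a concave one).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from cavscan.convexity import SphereFitError, interface_convexity
from cavscan.interface import buried_surface_area, find_interface
from cavscan.structio import Structure, StructureError, read_structure

__all__ = [
    "ChainPairRecord",
    "ClusterSet",
    "pairwise_identity",
    "greedy_cluster",
    "convexity_survey",
]

AA20 = "ACDEFGHIKLMNPQRSTVWY"
_VALID = frozenset(AA20 + "X")

MATCH, MISMATCH, GAP = 1, 0, -1


@dataclass
class ChainPairRecord:
    source_id: str
    chain_ids: tuple[str, str]
    lengths: tuple[int, int]
    total_dsasa: float
    convexity_1: float | None = None
    convexity_2: float | None = None
    resolution: float | None = None
    sequences: tuple[str, str] | None = None


@dataclass
class ClusterSet:
    clusters: list[list[int]]  # member indices into the input record list
    representatives: list[int]  # one per cluster
    identity_threshold: float


def _check_sequence(seq: str, label: str) -> str:
    seq = seq.upper()
    if not seq:
        raise ValueError(f"{label}: empty sequence")
    for i, c in enumerate(seq):
        if c not in _VALID:
            raise ValueError(f"{label}: invalid character {c!r} at position {i}")
    return seq


def _nw_align(a: str, b: str) -> tuple[str, str]:
    """Needleman-Wunsch global alignment (match +1, mismatch 0, gap -1).

    Deterministic traceback preference: diagonal, then gap in b (up), then
    gap in a (left).  'X' never matches anything, including itself.
    """
    n, m = len(a), len(b)
    score = np.zeros((n + 1, m + 1), dtype=np.int32)
    score[:, 0] = GAP * np.arange(n + 1)
    score[0, :] = GAP * np.arange(m + 1)
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            s = MATCH if (ai == b[j - 1] and ai != "X") else MISMATCH
            score[i, j] = max(score[i - 1, j - 1] + s,
                              score[i - 1, j] + GAP,
                              score[i, j - 1] + GAP)
    # traceback
    out_a, out_b = [], []
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0:
            s = MATCH if (a[i - 1] == b[j - 1] and a[i - 1] != "X") else MISMATCH
            if score[i, j] == score[i - 1, j - 1] + s:
                out_a.append(a[i - 1])
                out_b.append(b[j - 1])
                i, j = i - 1, j - 1
                continue
        if i > 0 and score[i, j] == score[i - 1, j] + GAP:
            out_a.append(a[i - 1])
            out_b.append("-")
            i -= 1
            continue
        out_a.append("-")
        out_b.append(b[j - 1])
        j -= 1
    return "".join(reversed(out_a)), "".join(reversed(out_b))


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Global-alignment sequence identity as a fraction in [0, 1].

    Identity = identical aligned columns / aligned columns, where terminal
    gap columns (overhangs at either end) are excluded from the denominator.
    """
    a = _check_sequence(seq_a, "seq_a")
    b = _check_sequence(seq_b, "seq_b")
    al_a, al_b = _nw_align(a, b)
    # trim terminal gap columns
    start = 0
    while al_a[start] == "-" or al_b[start] == "-":
        start += 1
    end = len(al_a)
    while al_a[end - 1] == "-" or al_b[end - 1] == "-":
        end -= 1
    cols = end - start
    if cols <= 0:
        return 0.0
    ident = sum(
        1
        for x, y in zip(al_a[start:end], al_b[start:end])
        if x == y and x != "-" and x != "X"
    )
    return ident / cols


def greedy_cluster(
    records: Sequence[ChainPairRecord],
    identity_threshold: float = 0.40,
) -> ClusterSet:
    """Leader-style greedy clustering of chain pairs.

    Records are visited by (higher resolution first i.e. lower Angstrom
    value, then shorter total length, then input order) so the output does
    not depend on input shuffling; a record joins an existing cluster only
    if BOTH of its chains reach the identity threshold against the cluster
    representative (checked in the better of the two chain orderings).
    """
    if not records:
        raise ValueError("no records to cluster")
    for k, r in enumerate(records):
        if r.sequences is None:
            raise ValueError(f"record {k} has no sequences; cannot cluster")

    def sort_key(k: int):
        r = records[k]
        res = r.resolution if r.resolution is not None else float("inf")
        return (res, sum(r.lengths), k)

    order = sorted(range(len(records)), key=sort_key)
    reps: list[int] = []
    clusters: list[list[int]] = []
    for k in order:
        sa, sb = records[k].sequences
        placed = False
        for ci, rep in enumerate(reps):
            ra, rb = records[rep].sequences
            direct = min(pairwise_identity(sa, ra), pairwise_identity(sb, rb))
            swapped = min(pairwise_identity(sa, rb), pairwise_identity(sb, ra))
            if max(direct, swapped) >= identity_threshold:
                clusters[ci].append(k)
                placed = True
                break
        if not placed:
            reps.append(k)
            clusters.append([k])
    return ClusterSet(
        clusters=clusters, representatives=reps, identity_threshold=identity_threshold
    )


def convexity_survey(
    structures: Sequence[str | Path | Structure],
    partner_pairs: Sequence[tuple[Sequence[str], Sequence[str]]] | None = None,
    seed: int = 0,
    dsasa_threshold: float = 0.5,
    n_points: int = 960,
    min_interface_atoms: int = 10,
) -> tuple[list[ChainPairRecord], dict]:
    """Per-complex partner convexities plus a correlation summary.

    Each input is a two-chain complex (or ``partner_pairs`` names the chain
    groups).  Complexes whose interface is too small or whose sphere fit
    fails are skipped and counted, not fatal.  The summary reports Pearson
    and Spearman correlations of (convexity_1, convexity_2) when at least
    three usable pairs with non-degenerate spread exist.
    """
    records: list[ChainPairRecord] = []
    skipped = 0
    for idx, item in enumerate(structures):
        if isinstance(item, Structure):
            st = item
        else:
            try:
                st = read_structure(item)
            except StructureError:
                skipped += 1
                continue
        if partner_pairs is not None:
            pa, pb = partner_pairs[idx]
            pa, pb = list(pa), list(pb)
        else:
            if len(st.chains) < 2:
                skipped += 1
                continue
            pa, pb = [st.chains[0].id], [st.chains[1].id]
        try:
            r1 = interface_convexity(
                st, pa, pb, dsasa_threshold=dsasa_threshold, seed=seed,
                n_points=n_points, min_interface_atoms=min_interface_atoms,
            )
            r2 = interface_convexity(
                st, pb, pa, dsasa_threshold=dsasa_threshold, seed=seed,
                n_points=n_points, min_interface_atoms=min_interface_atoms,
            )
        except (SphereFitError, ValueError):
            skipped += 1
            continue
        iface = find_interface(st, pa, pb, dsasa_threshold, n_points=n_points)
        records.append(
            ChainPairRecord(
                source_id=st.name or f"complex_{idx}",
                chain_ids=(pa[0], pb[0]),
                lengths=(
                    sum(len(st.chain(c)) for c in pa),
                    sum(len(st.chain(c)) for c in pb),
                ),
                total_dsasa=buried_surface_area(iface).total,
                convexity_1=r1.convexity,
                convexity_2=r2.convexity,
                sequences=(st.sequence(pa[0]), st.sequence(pb[0])),
            )
        )

    k1 = np.array([r.convexity_1 for r in records], dtype=float)
    k2 = np.array([r.convexity_2 for r in records], dtype=float)
    summary: dict = {"n_pairs": len(records), "n_skipped": skipped}
    if len(records) >= 3 and np.std(k1) > 0 and np.std(k2) > 0:
        summary["pearson_r"] = float(stats.pearsonr(k1, k2).statistic)
        summary["spearman_rho"] = float(stats.spearmanr(k1, k2).statistic)
        summary["degenerate"] = False
    else:
        summary["pearson_r"] = None
        summary["spearman_rho"] = None
        summary["degenerate"] = True
    return records, summary
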