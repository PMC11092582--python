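"""Site-saturation mutagenesis (SSM) analysis and degenerate-codon design.

SSM deep-sequencing count tables (positions x 20 amino acids, selected pool
vs reference pool) are converted to log2 enrichment matrices — the numbers
behind selection heat maps — and to per-position Shannon entropies in bits,
a conservation score (0 bits: one residue tolerated; log2 20 ~ 4.32 bits:
no constraint).  The codon tools pick, by exhaustive search over all 15^3
IUPAC triplets, the degenerate codon that best encodes a wished-for amino
acid set, and account for combinatorial library sizes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "AA20",
    "SSMMatrix",
    "DegenerateCodon",
    "ssm_log_enrichment",
    "position_entropy",
    "design_degenerate_codon",
    "library_size",
    "read_counts_tsv",
    "write_counts_tsv",
]

AA20 = tuple("ACDEFGHIKLMNPQRSTVWY")

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

# standard genetic code (translation table 1); '*' = stop
CODON_TABLE = {}
_BASES = "TCAG"
_AAS = (
    "FFLLSSSSYY**CC*W"
    "LLLLPPPPHHQQRRRR"
    "IIIMTTTTNNKKSSRR"
    "VVVVAAAADDEEGGGG"
)
for _i, (_b1, _b2, _b3) in enumerate(itertools.product(_BASES, _BASES, _BASES)):
    CODON_TABLE[_b1 + _b2 + _b3] = _AAS[_i]


@dataclass
class SSMMatrix:
    """positions x 20 log2-enrichment matrix with the underlying counts."""

    positions: list[tuple[str, int]]  # (parent aa, position index)
    enrichment: np.ndarray  # shape (n_positions, 20)
    counts_selected: np.ndarray
    counts_reference: np.ndarray
    pseudocount: float = 1.0
    amino_acids: tuple[str, ...] = AA20

    def to_frame(self) -> pd.DataFrame:
        idx = pd.MultiIndex.from_tuples(self.positions, names=["parent_aa", "position"])
        return pd.DataFrame(self.enrichment, index=idx, columns=list(self.amino_acids))


@dataclass
class DegenerateCodon:
    iupac_triplet: str
    expanded_codons: tuple[str, ...]
    encoded_aas: tuple[str, ...]  # multiset: one entry per expanded codon
    contains_stop: bool
    codon_count: int
    is_exact: bool = True  # encodes exactly the requested aa set (no extras)

    @property
    def encoded_aa_set(self) -> frozenset[str]:
        return frozenset(a for a in self.encoded_aas if a != "*")


def expand_triplet(triplet: str) -> tuple[str, ...]:
    """All concrete codons an IUPAC triplet stands for."""
    if len(triplet) != 3 or any(b not in IUPAC for b in triplet.upper()):
        raise ValueError(f"not an IUPAC triplet: {triplet!r}")
    t = triplet.upper()
    return tuple(
        "".join(c) for c in itertools.product(IUPAC[t[0]], IUPAC[t[1]], IUPAC[t[2]])
    )


def describe_triplet(triplet: str, desired: frozenset[str] | None = None) -> DegenerateCodon:
    codons = expand_triplet(triplet)
    aas = tuple(CODON_TABLE[c] for c in codons)
    dc = DegenerateCodon(
        iupac_triplet=triplet.upper(),
        expanded_codons=codons,
        encoded_aas=aas,
        contains_stop="*" in aas,
        codon_count=len(codons),
    )
    if desired is not None:
        dc.is_exact = dc.encoded_aa_set == desired and not dc.contains_stop
    return dc


def _load_counts(table) -> tuple[list[tuple[str, int]], np.ndarray]:
    if isinstance(table, (str, Path)):
        table = read_counts_tsv(table)
    if isinstance(table, pd.DataFrame):
        missing = [a for a in AA20 if a not in table.columns]
        if missing:
            raise ValueError(f"count table lacks amino-acid columns: {missing}")
        if "position" in table.columns and "parent_aa" in table.columns:
            positions = list(zip(table["parent_aa"], table["position"].astype(int)))
        else:
            positions = [("X", i) for i in range(len(table))]
        counts = table[list(AA20)].to_numpy(dtype=float)
    else:
        counts = np.asarray(table, dtype=float)
        positions = [("X", i) for i in range(len(counts))]
    if counts.ndim != 2 or counts.shape[1] != 20:
        raise ValueError(f"count table must be positions x 20, got {counts.shape}")
    if (counts < 0).any():
        raise ValueError("negative counts")
    return positions, counts


def ssm_log_enrichment(
    counts_selected,
    counts_reference,
    pseudocount: float = 1.0,
) -> SSMMatrix:
    """log2 enrichment of each substitution under selection.

    ``E[i, aa] = log2( f_sel(i, aa) / f_ref(i, aa) )`` with pseudocounted
    frequencies ``f = (c + pc) / N`` and ``N`` the pseudocount-inclusive
    total over the whole table.  Positive values mark substitutions the
    selection enriched, negative ones substitutions it depleted.
    """
    pos_s, sel = _load_counts(counts_selected)
    pos_r, ref = _load_counts(counts_reference)
    if sel.shape != ref.shape:
        raise ValueError(f"shape mismatch: selected {sel.shape} vs reference {ref.shape}")
    if sel.sum() <= 0 or ref.sum() <= 0:
        raise ValueError("count tables must have positive totals")
    n_sel = (sel + pseudocount).sum()
    n_ref = (ref + pseudocount).sum()
    f_sel = (sel + pseudocount) / n_sel
    f_ref = (ref + pseudocount) / n_ref
    return SSMMatrix(
        positions=pos_s,
        enrichment=np.log2(f_sel / f_ref),
        counts_selected=sel,
        counts_reference=ref,
        pseudocount=pseudocount,
    )


def position_entropy(ssm: SSMMatrix) -> np.ndarray:
    """Per-position Shannon entropy in bits from selected-pool frequencies.

    ``p(aa) = (c_sel + pc) / sum_row(c_sel + pc)``; ``H = -sum p log2 p``.
    Bounded by [0, log2 20].
    """
    c = ssm.counts_selected + ssm.pseudocount
    p = c / c.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log2(p), 0.0)
    return -terms.sum(axis=1)


def design_degenerate_codon(
    desired: set[str] | frozenset[str] | str,
    forbid_stop: bool = True,
    allow_extras: bool = True,
) -> DegenerateCodon:
    """Best IUPAC degenerate codon for a desired amino-acid set.

    Exhaustive search over all 15^3 = 3375 triplets, ranked by: covers all
    desired amino acids; fewest *undesired* distinct amino acids; stop-free
    (when ``forbid_stop``); smallest expanded codon count; lexicographic
    triplet.  With ``allow_extras=False`` only exact encodings qualify; when
    none exists the best compromise is returned with ``is_exact=False``.
    """
    if isinstance(desired, str):
        desired = set(desired)
    desired = frozenset(a.upper() for a in desired)
    if not desired:
        raise ValueError("desired amino-acid set is empty")
    bad = desired - set(AA20)
    if bad:
        raise ValueError(f"not standard amino acids: {sorted(bad)}")

    def rank(t: str):
        aas = frozenset(CODON_TABLE[c] for c in expand_triplet(t))
        covers = desired <= aas
        extras = len(aas - desired - {"*"})
        stop = "*" in aas
        count = 1
        for b in t:
            count *= len(IUPAC[b])
        return (
            0 if covers else 1,
            extras,
            1 if (forbid_stop and stop) else 0,
            count,
            t,
        )

    symbols = sorted(IUPAC)
    best = min(
        ("".join(t) for t in itertools.product(symbols, repeat=3)),
        key=rank,
    )
    result = describe_triplet(best, desired)
    key = rank(best)
    result.is_exact = key[0] == 0 and key[1] == 0 and not result.contains_stop
    if not allow_extras and not result.is_exact:
        result.is_exact = False  # best compromise, flagged
    return result


def library_size(
    position_specs: list[set[str] | frozenset[str] | str],
    forbid_stop: bool = True,
) -> tuple[int, int]:
    """(protein variants, DNA variants) of a combinatorial library.

    Protein variants multiply the distinct amino acids encoded at each
    position by its designed degenerate codon; DNA variants multiply the
    expanded codon counts.  Python integers, so arbitrarily large libraries
    are exact.
    """
    if not position_specs:
        raise ValueError("no positions specified")
    n_protein, n_dna = 1, 1
    for spec in position_specs:
        dc = design_degenerate_codon(spec, forbid_stop=forbid_stop)
        n_protein *= len(dc.encoded_aa_set)
        n_dna *= dc.codon_count
    return n_protein, n_dna


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    """Read a counts table: columns ``position, parent_aa, A..Y`` (20 aas)."""
    df = pd.read_csv(path, sep="\t")
    required = ["position", "parent_aa", *AA20]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"counts TSV missing columns: {missing}")
    return df


def write_counts_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
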