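"""Canonical peptide sequences, positional residue access and pool records.

Every downstream stage of the screening pipeline (reference lookup, digestion,
filtering, SAR matching) operates on the types defined here.  A peptide is an
uppercase string over the 20 canonical one-letter amino-acid codes; screening
pool members are 2-50 residues long (food-digest peptidomes are dominated by
di- to octa-peptides).  Positions are 1-based from the N-terminus, matching
how the field writes SAR rules ("second position", "third position").
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from pyteomics import mass as _ptmass

__all__ = [
    "CANONICAL_RESIDUES",
    "WATER_MONO",
    "PeptideRecord",
    "ResidueFeatureSets",
    "SequenceError",
    "validate_sequence",
    "residue_at",
    "monoisotopic_mass",
    "load_pool",
    "write_pool",
]

#: The 20 canonical one-letter amino-acid codes.
CANONICAL_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Monoisotopic mass of one water molecule (Da), the condensation term.
WATER_MONO = 18.0105646863


class SequenceError(ValueError):
    """Raised for empty input or characters outside the canonical alphabet."""


def validate_sequence(raw: str) -> str:
    """Normalize and validate a peptide sequence.

    Input is case-insensitive; the return value is the uppercase sequence.
    Rejects empty input and any character outside the 20 canonical codes
    (so B, J, O, U, X, Z, digits and punctuation all fail), naming the
    offending character and its 1-based position.

    Idempotent: validating an already-validated sequence returns it unchanged.
    """
    if not isinstance(raw, str):
        raise SequenceError(f"sequence must be text, got {type(raw).__name__}")
    seq = raw.strip().upper()
    if not seq:
        raise SequenceError("empty peptide sequence")
    for i, ch in enumerate(seq, start=1):
        if ch not in CANONICAL_RESIDUES:
            raise SequenceError(
                f"non-canonical residue {ch!r} at position {i} in {seq!r}"
            )
    return seq


def residue_at(sequence: str, where: int | str) -> str:
    """Return the residue at a named or numbered position.

    ``where`` is either a 1-based integer index from the N-terminus or one of
    the position names ``"n_term"`` (index 1), ``"c_term"`` (the last
    residue) or ``"penultimate"`` (the residue before the C-terminus).
    """
    seq = validate_sequence(sequence)
    n = len(seq)
    if isinstance(where, str):
        name = where.lower()
        if name == "n_term":
            idx = 1
        elif name == "c_term":
            idx = n
        elif name == "penultimate":
            idx = n - 1
        else:
            raise ValueError(f"unknown position name {where!r}")
    else:
        idx = int(where)
    if not 1 <= idx <= n:
        raise IndexError(f"position {where!r} out of range for length {n}")
    return seq[idx - 1]


def monoisotopic_mass(sequence: str) -> float:
    """Monoisotopic mass of the neutral peptide in Da.

    Sum of residue monoisotopic masses plus one water; delegated to
    pyteomics' composition-based calculator.
    """
    return float(_ptmass.calculate_mass(sequence=validate_sequence(sequence),
                                        monoisotopic=True))


@dataclass(frozen=True)
class ResidueFeatureSets:
    """Fixed residue classes used by the DPP-IV SAR feature catalog.

    These are the residue sets reported in the structure-activity literature
    for potent (IC50 < 100 umol/L) DPP-IV-inhibitory peptides; they are
    constants, not tunables.
    """

    hydrophobic_nterm: frozenset[str] = frozenset("ILVAFW")
    hydrophobic_cterm_tri: frozenset[str] = frozenset("AILGMF")
    pos2_set: frozenset[str] = frozenset("PA")
    cterm_tetra_set: frozenset[str] = frozenset("PLR")
    pos3_tetra_set: frozenset[str] = frozenset("AVGP")


@dataclass
class PeptideRecord:
    """One member of a screening pool.

    ``rank_score`` is an externally computed 0-1 bioactivity likelihood
    (PeptideRanker-style); ``binding_pvalue`` an externally computed
    active-site binding p-value (PepSite2-style).  Both are consumed as
    input columns, never computed here; ``None`` means the external tool
    was not run on this peptide.
    """

    sequence: str
    precursor_ids: set[str] = field(default_factory=set)
    rank_score: float | None = None
    binding_pvalue: float | None = None
    known_activities: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.sequence = validate_sequence(self.sequence)
        if len(self.sequence) < 2:
            raise SequenceError(
                f"pool peptides must have >= 2 residues, got {self.sequence!r}"
            )
        if self.rank_score is not None and not 0.0 <= self.rank_score <= 1.0:
            raise ValueError(f"rank_score {self.rank_score} outside [0, 1]")
        if self.binding_pvalue is not None and not 0.0 < self.binding_pvalue <= 1.0:
            raise ValueError(
                f"binding_pvalue {self.binding_pvalue} outside (0, 1]"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


def _read_table(path: Path) -> pd.DataFrame:
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


def load_pool(path: str | Path) -> list[PeptideRecord]:
    """Read a peptide pool from a TSV/CSV file.

    Required column ``sequence``; optional ``precursor`` (semicolon-separated
    protein ids), ``rank_score`` and ``binding_pvalue``.  Empty optional
    fields become ``None``/empty sets.  Delimiter is inferred from the file
    extension (``.csv`` -> comma, anything else -> tab).
    """
    path = Path(path)
    df = _read_table(path)
    if "sequence" not in df.columns:
        raise ValueError(f"{path}: missing required column 'sequence'")
    records: list[PeptideRecord] = []
    for row in df.itertuples(index=False):
        rec = PeptideRecord(
            sequence=getattr(row, "sequence"),
            precursor_ids=set(
                p for p in str(getattr(row, "precursor", "")).split(";") if p
            ),
            rank_score=_opt_float(getattr(row, "rank_score", "")),
            binding_pvalue=_opt_float(getattr(row, "binding_pvalue", "")),
        )
        records.append(rec)
    return records


def _opt_float(value: object) -> float | None:
    text = str(value).strip()
    return float(text) if text else None


def write_pool(records: Iterable[PeptideRecord], path: str | Path) -> None:
    """Write a peptide pool to TSV/CSV (inverse of :func:`load_pool`)."""
    path = Path(path)
    rows = [
        {
            "sequence": r.sequence,
            "precursor": ";".join(sorted(r.precursor_ids)),
            "rank_score": "" if r.rank_score is None else r.rank_score,
            "binding_pvalue": "" if r.binding_pvalue is None else r.binding_pvalue,
        }
        for r in records
    ]
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


def pool_from_sequences(sequences: Sequence[str]) -> list[PeptideRecord]:
    """Convenience: build bare records from raw sequences."""
    return [PeptideRecord(sequence=s) for s in sequences]
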