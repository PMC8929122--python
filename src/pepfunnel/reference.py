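"""Known-bioactive-peptide reference table with exact-identity lookup.

A BIOPEP-style lookup: each entry maps a peptide sequence to the set of
bioactivities previously reported for it.  The package bundles the reference
of 37 short peptides (2-4 residues) recovered from an in vitro-digested
pinto bean protein extract, annotated with ACE-inhibitory, DPP-IV-inhibitory
and antioxidant activities.

Matching is exact full-length identity ("100% sequence homology"): a
di-peptide entry matches only the identical di-peptide, never a longer
peptide containing it.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable

from .peptides import validate_sequence

__all__ = [
    "ACE_INHIBITION",
    "DPPIV_INHIBITION",
    "ANTIOXIDANT",
    "KNOWN_ACTIVITIES",
    "BioactivityEntry",
    "BioactivityReferenceTable",
    "load_reference",
    "write_reference",
    "bundled_reference",
]

ACE_INHIBITION = "ACE-inhibition"
DPPIV_INHIBITION = "DPP-IV-inhibition"
ANTIOXIDANT = "Antioxidant"

#: Activity labels this package recognizes.
KNOWN_ACTIVITIES = frozenset({ACE_INHIBITION, DPPIV_INHIBITION, ANTIOXIDANT})


@dataclass(frozen=True)
class BioactivityEntry:
    sequence: str
    activities: frozenset[str]
    precursor_note: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", validate_sequence(self.sequence))
        if not self.activities:
            raise ValueError(f"entry {self.sequence}: empty activity set")


class BioactivityReferenceTable:
    """Sequence -> activity-set map over unique peptide entries."""

    def __init__(self, entries: Iterable[BioactivityEntry]):
        self._entries: dict[str, BioactivityEntry] = {}
        for e in entries:
            if e.sequence in self._entries:
                raise ValueError(f"duplicate sequence {e.sequence!r} in reference")
            self._entries[e.sequence] = e

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self):
        return iter(self._entries.values())

    def __contains__(self, sequence: str) -> bool:
        return validate_sequence(sequence) in self._entries

    def lookup(self, sequence: str) -> frozenset[str]:
        """Activities reported for this exact sequence; empty set if absent.

        Case-insensitive exact full-length match only — no substring or
        partial-homology matching.
        """
        entry = self._entries.get(validate_sequence(sequence))
        return entry.activities if entry is not None else frozenset()

    def is_known(self, sequence: str, activity: str) -> bool:
        """True iff ``activity`` has been reported for this exact sequence."""
        if activity not in KNOWN_ACTIVITIES:
            raise ValueError(
                f"unknown activity label {activity!r}; "
                f"expected one of {sorted(KNOWN_ACTIVITIES)}"
            )
        return activity in self.lookup(sequence)

    def classify_counts(self) -> dict[str, int]:
        """Partition entries by inhibitory-activity profile.

        Returns counts ``{dppiv_only, ace_only, both, other}`` where
        ``other`` collects entries with neither ACE- nor DPP-IV-inhibitory
        annotation (e.g. antioxidant-only).  The four counts always sum to
        the table size.
        """
        counts = {"dppiv_only": 0, "ace_only": 0, "both": 0, "other": 0}
        for e in self._entries.values():
            has_dppiv = DPPIV_INHIBITION in e.activities
            has_ace = ACE_INHIBITION in e.activities
            if has_dppiv and has_ace:
                counts["both"] += 1
            elif has_dppiv:
                counts["dppiv_only"] += 1
            elif has_ace:
                counts["ace_only"] += 1
            else:
                counts["other"] += 1
        return counts


def load_reference(path: str | Path) -> BioactivityReferenceTable:
    """Parse a reference TSV with columns sequence, activities, precursor_note.

    Activities are semicolon-separated labels.  Malformed rows raise with the
    offending line number; duplicate sequences are rejected by the table.
    """
    path = Path(path)
    entries: list[BioactivityEntry] = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        required = {"sequence", "activities"}
        if not required.issubset(header):
            raise ValueError(f"{path}: header must contain {sorted(required)}")
        col = {name: i for i, name in enumerate(header)}
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < len(required):
                raise ValueError(f"{path}:{lineno}: malformed row {line!r}")
            try:
                activities = frozenset(
                    a.strip() for a in fields[col["activities"]].split(";")
                    if a.strip()
                )
                bad = activities - KNOWN_ACTIVITIES
                if bad:
                    raise ValueError(f"unrecognized activities {sorted(bad)}")
                note_idx = col.get("precursor_note")
                note = (
                    fields[note_idx]
                    if note_idx is not None and note_idx < len(fields)
                    else ""
                )
                entries.append(
                    BioactivityEntry(
                        sequence=fields[col["sequence"]],
                        activities=activities,
                        precursor_note=note,
                    )
                )
            except ValueError as err:
                raise ValueError(f"{path}:{lineno}: {err}") from err
    return BioactivityReferenceTable(entries)


def write_reference(table: BioactivityReferenceTable, path: str | Path) -> None:
    """Write a reference table back to TSV (row order: by sequence)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("sequence\tactivities\tprecursor_note\n")
        for e in sorted(table, key=lambda e: e.sequence):
            fh.write(f"{e.sequence}\t{';'.join(sorted(e.activities))}\t"
                     f"{e.precursor_note}\n")


def bundled_reference() -> BioactivityReferenceTable:
    """The packaged 37-entry known-bioactive-peptide table."""
    ref = resources.files("pepfunnel.data") / "known_bioactive_peptides.tsv"
    with resources.as_file(ref) as path:
        return load_reference(path)
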