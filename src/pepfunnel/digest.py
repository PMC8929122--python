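"""Cleavage-rule simulation of gastrointestinal protein digestion.

Simulates the two-phase digestion a food protein undergoes: a gastric phase
(pepsin) followed by an intestinal phase (pancreatin, represented by trypsin
plus chymotrypsin).  Rules follow the widely used PeptideCutter-style
specificity encoding: an enzyme cleaves C-terminally of a P1 residue unless
the next residue (P1') blocks the cut.  Defaults:

* pepsin (pH > 2): cleaves after F, L, W, Y; blocked by P at P1'
* trypsin: cleaves after K, R; blocked by P at P1'
* chymotrypsin (high specificity): cleaves after F, Y, W; blocked by P at P1'

The simulator is a pool generator for screening experiments, not a kinetic
model: every permitted bond is cut (optionally leaving up to
``missed_cleavages`` internal sites uncut), with no cleavage probabilities.

Coordinates are 1-based inclusive on the precursor.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from .peptides import PeptideRecord, validate_sequence

__all__ = [
    "CleavageRule",
    "ProteinRecord",
    "Fragment",
    "DigestResult",
    "PEPSIN",
    "TRYPSIN",
    "CHYMOTRYPSIN",
    "GASTRIC_PHASE",
    "INTESTINAL_PHASE",
    "cleavage_sites",
    "digest",
    "gastrointestinal_digest",
    "read_fasta",
    "map_peptide_to_proteins",
    "pool_statistics",
]


@dataclass(frozen=True)
class CleavageRule:
    """Protease specificity: cut after ``p1_residues`` unless P1' blocks."""

    enzyme_name: str
    p1_residues: frozenset[str]
    blocked_p1prime: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.p1_residues:
            raise ValueError(f"{self.enzyme_name}: empty P1 residue set")


PEPSIN = CleavageRule("pepsin", frozenset("FLWY"), frozenset("P"))
TRYPSIN = CleavageRule("trypsin", frozenset("KR"), frozenset("P"))
CHYMOTRYPSIN = CleavageRule("chymotrypsin", frozenset("FYW"), frozenset("P"))

GASTRIC_PHASE = ("gastric", (PEPSIN,))
INTESTINAL_PHASE = ("intestinal", (TRYPSIN, CHYMOTRYPSIN))


@dataclass(frozen=True)
class ProteinRecord:
    id: str
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", validate_sequence(self.sequence))


@dataclass(frozen=True)
class Fragment:
    """One digest product with its precursor coordinates (1-based inclusive)."""

    sequence: str
    precursor_id: str
    start: int
    end: int
    phase: str
    missed: int  # internal uncut sites left in this fragment


@dataclass
class DigestResult:
    fragments: list[Fragment]
    missed_cleavages: int

    def to_records(self, min_length: int = 2) -> list[PeptideRecord]:
        """Screening-pool view: unique sequences of at least ``min_length``.

        Fragments shorter than ``min_length`` stay in :attr:`fragments` but
        are excluded here — pool members must be at least di-peptides.
        """
        by_seq: dict[str, set[str]] = {}
        for f in self.fragments:
            if len(f.sequence) >= min_length:
                by_seq.setdefault(f.sequence, set()).add(f.precursor_id)
        return [
            PeptideRecord(sequence=s, precursor_ids=ids)
            for s, ids in sorted(by_seq.items())
        ]

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("sequence\tprecursor\tstart\tend\tphase\tmissed_cleavages\n")
            for f in self.fragments:
                fh.write(f"{f.sequence}\t{f.precursor_id}\t{f.start}\t{f.end}"
                         f"\t{f.phase}\t{f.missed}\n")


def cleavage_sites(sequence: str, rules: CleavageRule | Sequence[CleavageRule]
                   ) -> list[int]:
    """Cut positions for one or more co-acting proteases.

    Position ``i`` (1-based) is returned when the bond after residue ``i`` is
    cut by any rule: residue ``i`` is in the rule's P1 set and residue
    ``i + 1`` is not in its blocked P1' set.  There is never a cut after the
    final residue.  Multiple rules contribute the union of their sites.
    """
    seq = validate_sequence(sequence)
    if isinstance(rules, CleavageRule):
        rules = (rules,)
    sites: set[int] = set()
    for rule in rules:
        for i in range(1, len(seq)):  # no cut after the final residue
            if seq[i - 1] in rule.p1_residues and seq[i] not in rule.blocked_p1prime:
                sites.add(i)
    return sorted(sites)


def _spans(seq_len: int, cuts: list[int], missed: int
           ) -> Iterable[tuple[int, int, int]]:
    """(start, end, n_missed) spans over boundaries implied by ``cuts``.

    Boundaries are 0, each cut position, and the sequence end; a span covering
    k+1 consecutive segments carries k missed cleavages.
    """
    bounds = [0, *cuts, seq_len]
    for i, j in itertools.combinations(range(len(bounds)), 2):
        n_missed = j - i - 1
        if n_missed <= missed:
            yield bounds[i] + 1, bounds[j], n_missed


def digest(protein: ProteinRecord,
           phases: Sequence[tuple[str, Sequence[CleavageRule]]],
           missed_cleavages: int = 0) -> DigestResult:
    """Apply protease phases sequentially and collect all fragments.

    Phase 1 rules act on the intact protein; each later phase acts on every
    fragment produced by the phase before it.  Within a phase, fragments with
    up to ``missed_cleavages`` internal uncut sites are emitted.  A fragment
    untouched by a phase (no sites for that phase's rules) keeps its earlier
    phase label; duplicates (same sequence and coordinates) are removed,
    keeping the later phase's version.
    """
    if missed_cleavages < 0:
        raise ValueError("missed_cleavages must be >= 0")
    current: list[Fragment] = [
        Fragment(protein.sequence, protein.id, 1, len(protein.sequence),
                 phase="intact", missed=0)
    ]
    if not phases:
        return DigestResult(fragments=current, missed_cleavages=missed_cleavages)

    for phase_name, rules in phases:
        next_fragments: dict[tuple[str, int, int], Fragment] = {}
        for frag in current:
            cuts = cleavage_sites(frag.sequence, tuple(rules))
            if not cuts:
                key = (frag.sequence, frag.start, frag.end)
                next_fragments.setdefault(key, frag)
                continue
            for s, e, n_missed in _spans(len(frag.sequence), cuts,
                                         missed_cleavages):
                sub = frag.sequence[s - 1:e]
                abs_start = frag.start + s - 1
                abs_end = frag.start + e - 1
                next_fragments[(sub, abs_start, abs_end)] = Fragment(
                    sub, frag.precursor_id, abs_start, abs_end,
                    phase=phase_name, missed=n_missed,
                )
        current = list(next_fragments.values())
    current.sort(key=lambda f: (f.start, f.end))
    return DigestResult(fragments=current, missed_cleavages=missed_cleavages)


def gastrointestinal_digest(protein: ProteinRecord,
                            missed_cleavages: int = 0) -> DigestResult:
    """Gastric (pepsin) then intestinal (trypsin + chymotrypsin) digestion."""
    return digest(protein, [GASTRIC_PHASE, INTESTINAL_PHASE], missed_cleavages)


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read protein records from a (multi-record) FASTA file."""
    return [
        ProteinRecord(id=rec.id, sequence=str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def map_peptide_to_proteins(peptide: str, proteins: Iterable[ProteinRecord]
                            ) -> list[tuple[str, int, int]]:
    """All exact substring occurrences of ``peptide`` in ``proteins``.

    Overlapping occurrences are all reported; coordinates are 1-based
    inclusive ``(protein_id, start, end)`` tuples.
    """
    pep = validate_sequence(peptide)
    hits: list[tuple[str, int, int]] = []
    for prot in proteins:
        start = prot.sequence.find(pep)
        while start != -1:
            hits.append((prot.id, start + 1, start + len(pep)))
            start = prot.sequence.find(pep, start + 1)
    return hits


def pool_statistics(pool: Iterable[PeptideRecord]) -> dict:
    """Summary of a peptide pool: size, length histogram, precursor counts.

    Lengths outside the plausible peptidomics window [2, 50] are listed under
    ``out_of_range`` rather than silently dropped.
    """
    pool = list(pool)
    lengths = Counter(r.length for r in pool)
    per_precursor: Counter[str] = Counter()
    for r in pool:
        for pid in r.precursor_ids:
            per_precursor[pid] += 1
    return {
        "count": len(pool),
        "length_histogram": dict(sorted(lengths.items())),
        "per_precursor_counts": dict(per_precursor),
        "out_of_range": sorted(
            r.sequence for r in pool if not 2 <= r.length <= 50
        ),
    }
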