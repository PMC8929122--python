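"""Rule-based structure-activity-relationship engine for DPP-IV inhibition.

Potent DPP-IV-inhibitory peptides (IC50 below ~100 umol/L) share recurring
positional residue features reported across SAR studies of food-derived
peptides.  The catalog encodes them as pure predicates on the sequence:

F1_HYDRO_NTERM   hydrophobic residue (I, L, V, A, F, W) at the N-terminus
F2_PA_POS2       P or A in second position
F3_Q_NTERM       Q at the N-terminus            (tri-peptides only)
F4_HYDRO_CTERM   hydrophobic C-terminus (A, I, L, G, M, F)  (tri-peptides only)
F5_PLR_CTERM     P, L or R at the C-terminus    (tetra-peptides and longer)
F6_AVGP_POS3     A, V, G or P in third position (tetra-peptides and longer)
S_NTERM_NOVEL    S at the N-terminus — a proposed new marker, reported as an
                 annotation but never counted toward selection

A peptide is selected as a candidate inhibitor when at least ``min_features``
(default 2) selection-eligible features match.  The default threshold is the
minimal rule consistent with the known accept/reject pattern on short
food-digest candidates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

from .peptides import PeptideRecord, ResidueFeatureSets, validate_sequence

__all__ = [
    "SARFeature",
    "SARCatalog",
    "SARResult",
    "default_catalog",
    "match_features",
    "sar_select",
    "batch_sar",
]

logger = logging.getLogger(__name__)

_SETS = ResidueFeatureSets()


@dataclass(frozen=True)
class SARFeature:
    """One positional residue feature.

    ``applicable`` restricts the feature to a length class (tri-peptide-only
    rules, tetra-and-longer rules).  ``eligible`` distinguishes features that
    count toward selection from annotation-only markers.
    """

    id: str
    description: str
    applicable: Callable[[int], bool]
    predicate: Callable[[str], bool]
    eligible: bool = True

    def matches(self, sequence: str) -> bool:
        return self.applicable(len(sequence)) and self.predicate(sequence)


def _feature_list() -> tuple[SARFeature, ...]:
    return (
        SARFeature(
            "F1_HYDRO_NTERM",
            "hydrophobic residue (I/L/V/A/F/W) at the N-terminus",
            lambda n: n >= 2,
            lambda s: s[0] in _SETS.hydrophobic_nterm,
        ),
        SARFeature(
            "F2_PA_POS2",
            "P or A residue in second position",
            lambda n: n >= 2,
            lambda s: s[1] in _SETS.pos2_set,
        ),
        SARFeature(
            "F3_Q_NTERM",
            "Q residue at the N-terminus (tri-peptides)",
            lambda n: n == 3,
            lambda s: s[0] == "Q",
        ),
        SARFeature(
            "F4_HYDRO_CTERM",
            "hydrophobic residue (A/I/L/G/M/F) at the C-terminus (tri-peptides)",
            lambda n: n == 3,
            lambda s: s[-1] in _SETS.hydrophobic_cterm_tri,
        ),
        SARFeature(
            "F5_PLR_CTERM",
            "P, L or R residue at the C-terminus (tetra-peptides and longer)",
            lambda n: n >= 4,
            lambda s: s[-1] in _SETS.cterm_tetra_set,
        ),
        SARFeature(
            "F6_AVGP_POS3",
            "A, V, G or P residue in third position (tetra-peptides and longer)",
            lambda n: n >= 4,
            lambda s: s[2] in _SETS.pos3_tetra_set,
        ),
        SARFeature(
            "S_NTERM_NOVEL",
            "S residue at the N-terminus (proposed marker, annotation only)",
            lambda n: n >= 2,
            lambda s: s[0] == "S",
            eligible=False,
        ),
    )


@dataclass(frozen=True)
class SARCatalog:
    """Feature catalog plus the selection threshold."""

    features: tuple[SARFeature, ...] = field(default_factory=_feature_list)
    min_features: int = 2

    def by_id(self, feature_id: str) -> SARFeature:
        for f in self.features:
            if f.id == feature_id:
                return f
        raise KeyError(feature_id)


def default_catalog(min_features: int = 2) -> SARCatalog:
    return SARCatalog(min_features=min_features)


@dataclass(frozen=True)
class SARResult:
    sequence: str
    matched_features: frozenset[str]
    selected: bool
    rationale: str


def match_features(sequence: str, catalog: SARCatalog | None = None
                   ) -> frozenset[str]:
    """Ids of every applicable feature whose predicate holds.

    Features restricted to a different length class are never reported.
    For peptides longer than four residues the third-position rule (F6) is
    tested at position 3 from the N-terminus; for tetra-peptides this is the
    same residue as the penultimate position, but for longer peptides the two
    readings diverge (a warning is logged).
    """
    seq = validate_sequence(sequence)
    if len(seq) < 2:
        raise ValueError(f"SAR matching needs >= 2 residues, got {seq!r}")
    catalog = catalog or default_catalog()
    matched = frozenset(f.id for f in catalog.features if f.matches(seq))
    if "F6_AVGP_POS3" in matched and len(seq) > 4:
        logger.warning(
            "%s: third-position rule applied at position 3; for peptides "
            "longer than 4 residues this differs from the penultimate "
            "position", seq,
        )
    return matched


def sar_select(sequence: str, catalog: SARCatalog | None = None) -> SARResult:
    """Selection verdict: >= ``catalog.min_features`` eligible features match.

    Annotation-only features (``S_NTERM_NOVEL``) appear in the result but do
    not count toward the threshold.
    """
    catalog = catalog or default_catalog()
    matched = match_features(sequence, catalog)
    eligible = [fid for fid in sorted(matched) if catalog.by_id(fid).eligible]
    selected = len(eligible) >= catalog.min_features
    parts = [catalog.by_id(fid).description for fid in sorted(matched)]
    rationale = "; ".join(parts) if parts else "no catalog feature matched"
    return SARResult(
        sequence=validate_sequence(sequence),
        matched_features=matched,
        selected=selected,
        rationale=rationale,
    )


def batch_sar(records: Iterable[PeptideRecord | str],
              catalog: SARCatalog | None = None
              ) -> tuple[list[SARResult], dict[str, int]]:
    """Per-record SAR verdicts in input order, plus summary counts."""
    catalog = catalog or default_catalog()
    results = [
        sar_select(r.sequence if isinstance(r, PeptideRecord) else r, catalog)
        for r in records
    ]
    summary = {
        "total": len(results),
        "selected": sum(r.selected for r in results),
    }
    return results, summary
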