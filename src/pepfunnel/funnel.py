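"""Staged candidate-selection funnel for inhibitory-peptide screening.

The funnel reduces a peptide pool to validation candidates in four stages:

1. **rank filter** — keep peptides whose external bioactivity rank score is
   strictly above a threshold (default 0.4);
2. **binding filter** — keep peptides whose external active-site binding
   p-value is strictly below a threshold (default 0.01);
3. **novelty partition** — split survivors into peptides already reported
   with the target activity (known) and the rest (novel);
4. **SAR selection** — apply the structure-activity rule engine to the novel
   peptides only.

Rank scores and binding p-values are consumed as input columns from external
predictors; a record missing the column for a stage is excluded at that stage
with a distinct removal reason (absence of a score is not a pass).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

from .peptides import PeptideRecord
from .reference import (
    DPPIV_INHIBITION,
    KNOWN_ACTIVITIES,
    BioactivityReferenceTable,
)
from .sar import SARCatalog, default_catalog, sar_select

__all__ = [
    "FunnelConfig",
    "FunnelReport",
    "rank_filter",
    "binding_filter",
    "novelty_partition",
    "run_funnel",
]


@dataclass(frozen=True)
class FunnelConfig:
    """Thresholds and target activity for one funnel run.

    ``rank_threshold=None`` skips the rank stage entirely — for pools that
    were already rank-screened upstream.
    """

    rank_threshold: float | None = 0.4
    pvalue_threshold: float = 0.01
    target_activity: str = DPPIV_INHIBITION

    def __post_init__(self) -> None:
        if self.rank_threshold is not None and not 0.0 <= self.rank_threshold <= 1.0:
            raise ValueError(f"rank_threshold {self.rank_threshold} outside [0, 1]")
        if not 0.0 < self.pvalue_threshold < 1.0:
            raise ValueError(
                f"pvalue_threshold {self.pvalue_threshold} outside (0, 1)"
            )
        if self.target_activity not in KNOWN_ACTIVITIES:
            raise ValueError(f"unknown activity {self.target_activity!r}")


@dataclass
class FunnelReport:
    """Machine-readable account of one funnel run.

    ``stage_counts`` shrink monotonically along the funnel;
    ``known + novel == after_binding`` and ``sar_selected <= novel``.
    ``trail`` records, per input peptide, where it left the funnel and which
    SAR features matched if it reached that stage.
    """

    stage_counts: dict[str, int]
    selected: list[str]
    trail: list[dict]
    config: dict

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(
            {
                "stage_counts": self.stage_counts,
                "selected": self.selected,
                "trail": self.trail,
                "config": self.config,
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(text + "\n", encoding="utf-8")
        return text

    def summary(self) -> str:
        c = self.stage_counts
        lines = [
            "screening funnel summary",
            f"  input pool          {c['input']:>4d}",
            f"  after rank filter   {c['after_rank']:>4d}",
            f"  after binding filter{c['after_binding']:>4d}",
            f"  known inhibitors    {c['known']:>4d}",
            f"  novel candidates    {c['novel']:>4d}",
            f"  SAR-selected        {c['sar_selected']:>4d}",
        ]
        if self.selected:
            lines.append("  selected: " + ", ".join(self.selected))
        return "\n".join(lines)


def rank_filter(pool: Sequence[PeptideRecord], threshold: float
                ) -> list[PeptideRecord]:
    """Keep records with rank score strictly greater than ``threshold``.

    Records without a rank score are dropped (the external predictor was not
    run on them, which is not a pass).
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"rank threshold {threshold} outside [0, 1]")
    return [
        r for r in pool
        if r.rank_score is not None and r.rank_score > threshold
    ]


def binding_filter(records: Sequence[PeptideRecord], threshold: float
                   ) -> list[PeptideRecord]:
    """Keep records with binding p-value strictly less than ``threshold``."""
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"p-value threshold {threshold} outside (0, 1)")
    return [
        r for r in records
        if r.binding_pvalue is not None and r.binding_pvalue < threshold
    ]


def novelty_partition(records: Sequence[PeptideRecord],
                      reference: BioactivityReferenceTable,
                      activity: str = DPPIV_INHIBITION,
                      ) -> tuple[list[PeptideRecord], list[PeptideRecord]]:
    """Split records into (known, novel) for the target activity.

    A record is *known* when the reference table lists the target activity
    for its exact sequence; everything else is *novel*.  The partition is
    exhaustive and disjoint, and each record's ``known_activities`` is
    filled from the reference as a side effect of the lookup.
    """
    if activity not in KNOWN_ACTIVITIES:
        raise ValueError(f"unknown activity label {activity!r}")
    known: list[PeptideRecord] = []
    novel: list[PeptideRecord] = []
    for r in records:
        r.known_activities = set(reference.lookup(r.sequence))
        (known if activity in r.known_activities else novel).append(r)
    return known, novel


def run_funnel(pool: Sequence[PeptideRecord],
               config: FunnelConfig,
               reference: BioactivityReferenceTable,
               catalog: SARCatalog | None = None) -> FunnelReport:
    """Run all four stages and assemble the report.

    Order is preserved at every stage, so reports are deterministic given
    the input order.
    """
    catalog = catalog or default_catalog()
    pool = list(pool)
    removed: dict[str, tuple[str, str]] = {}  # sequence -> (stage, reason)

    if config.rank_threshold is None:
        after_rank = pool
    else:
        after_rank = rank_filter(pool, config.rank_threshold)
        kept = {id(r) for r in after_rank}
        for r in pool:
            if id(r) not in kept:
                reason = (
                    "no rank score" if r.rank_score is None
                    else f"rank score {r.rank_score} <= {config.rank_threshold}"
                )
                removed[r.sequence] = ("rank_filter", reason)

    after_binding = binding_filter(after_rank, config.pvalue_threshold)
    kept = {id(r) for r in after_binding}
    for r in after_rank:
        if id(r) not in kept:
            reason = (
                "no binding p-value" if r.binding_pvalue is None
                else f"p-value {r.binding_pvalue} >= {config.pvalue_threshold}"
            )
            removed[r.sequence] = ("binding_filter", reason)

    known, novel = novelty_partition(after_binding, reference,
                                     config.target_activity)
    for r in known:
        removed[r.sequence] = (
            "novelty_partition",
            f"already reported with {config.target_activity}",
        )

    sar_results = {r.sequence: sar_select(r.sequence, catalog) for r in novel}
    selected = [r.sequence for r in novel if sar_results[r.sequence].selected]
    for r in novel:
        if not sar_results[r.sequence].selected:
            removed[r.sequence] = (
                "sar_select",
                f"fewer than {catalog.min_features} eligible SAR features",
            )

    trail = []
    for r in pool:
        stage, reason = removed.get(r.sequence, ("selected", "passed all stages"))
        entry = {"sequence": r.sequence, "outcome": stage, "reason": reason}
        if r.sequence in sar_results:
            entry["matched_features"] = sorted(
                sar_results[r.sequence].matched_features
            )
        trail.append(entry)

    return FunnelReport(
        stage_counts={
            "input": len(pool),
            "after_rank": len(after_rank),
            "after_binding": len(after_binding),
            "known": len(known),
            "novel": len(novel),
            "sar_selected": len(selected),
        },
        selected=selected,
        trail=trail,
        config={
            "rank_threshold": config.rank_threshold,
            "pvalue_threshold": config.pvalue_threshold,
            "target_activity": config.target_activity,
            "min_features": catalog.min_features,
        },
    )
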