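"""Screening funnel: filters, novelty partition, staged reports."""

import pytest
from hypothesis import given, settings, strategies as st

from pepfunnel import (
    DPPIV_INHIBITION,
    FunnelConfig,
    PeptideRecord,
    binding_filter,
    novelty_partition,
    rank_filter,
    run_funnel,
)
from pepfunnel.peptides import CANONICAL_RESIDUES

KNOWN_NINE = {"IP", "LP", "LPQ", "GI", "MI", "ML", "GL", "VF", "AL"}
NOVEL_SIX = {"PR", "FT", "SIPR", "SAPI", "FVPH", "FV"}


def rec(seq, rank=None, pval=None):
    return PeptideRecord(sequence=seq, rank_score=rank, binding_pvalue=pval)


class TestRankFilter:
    def test_strictly_above_threshold(self):
        assert rank_filter([rec("AL", rank=0.41)], 0.4)

    def test_boundary_excluded(self):
        assert rank_filter([rec("AL", rank=0.40)], 0.4) == []

    def test_counts(self):
        pool = [rec("AL", 0.2), rec("ML", 0.45), rec("VF", 0.9)]
        assert [r.sequence for r in rank_filter(pool, 0.4)] == ["ML", "VF"]

    def test_missing_score_excluded(self):
        assert rank_filter([rec("AL")], 0.4) == []

    def test_threshold_out_of_range(self):
        with pytest.raises(ValueError):
            rank_filter([], 1.5)


class TestBindingFilter:
    def test_strictly_below_threshold(self):
        assert binding_filter([rec("SIPR", pval=1.77e-3)], 0.01)

    def test_boundary_excluded(self):
        assert binding_filter([rec("AL", pval=0.01)], 0.01) == []

    def test_all_fifteen_retained(self, screening_pool):
        assert len(binding_filter(screening_pool, 0.01)) == 15

    def test_missing_pvalue_excluded(self):
        assert binding_filter([rec("AL")], 0.01) == []


class TestNoveltyPartition:
    def test_bundled_pool_partition(self, screening_pool, reference):
        known, novel = novelty_partition(screening_pool, reference,
                                         DPPIV_INHIBITION)
        assert {r.sequence for r in known} == KNOWN_NINE
        assert {r.sequence for r in novel} == NOVEL_SIX

    def test_antioxidant_only_entry_is_novel_for_dppiv(self, reference):
        known, novel = novelty_partition([rec("FVPH")], reference,
                                         DPPIV_INHIBITION)
        assert not known and [r.sequence for r in novel] == ["FVPH"]

    def test_empty_input(self, reference):
        assert novelty_partition([], reference) == ([], [])

    def test_unknown_activity_rejected(self, reference):
        with pytest.raises(ValueError):
            novelty_partition([], reference, "Clairvoyance")


class TestRunFunnel:
    def test_bundled_pool_end_to_end(self, screening_pool, reference):
        report = run_funnel(screening_pool, FunnelConfig(rank_threshold=None),
                            reference)
        assert report.stage_counts == {
            "input": 15, "after_rank": 15, "after_binding": 15,
            "known": 9, "novel": 6, "sar_selected": 3,
        }
        assert set(report.selected) == {"SIPR", "SAPI", "FVPH"}

    def test_empty_pool(self, reference):
        report = run_funnel([], FunnelConfig(), reference)
        assert all(v == 0 for v in report.stage_counts.values())

    def test_nothing_passes_binding(self, reference):
        pool = [rec("AL", rank=0.9, pval=0.5)]
        report = run_funnel(pool, FunnelConfig(), reference)
        assert report.stage_counts["after_binding"] == 0
        assert report.stage_counts["known"] == 0
        assert report.stage_counts["sar_selected"] == 0

    def test_trail_records_removal_stage(self, screening_pool, reference):
        report = run_funnel(screening_pool, FunnelConfig(rank_threshold=None),
                            reference)
        by_seq = {t["sequence"]: t for t in report.trail}
        assert by_seq["ML"]["outcome"] == "novelty_partition"
        assert by_seq["FT"]["outcome"] == "sar_select"
        assert by_seq["SAPI"]["outcome"] == "selected"

    def test_report_json_round_trip(self, screening_pool, reference, tmp_path):
        import json

        report = run_funnel(screening_pool, FunnelConfig(rank_threshold=None),
                            reference)
        path = tmp_path / "report.json"
        report.to_json(path)
        data = json.loads(path.read_text())
        assert data["stage_counts"] == report.stage_counts

    @given(st.lists(
        st.tuples(
            st.text(alphabet=sorted(CANONICAL_RESIDUES), min_size=2,
                    max_size=6),
            st.one_of(st.none(), st.floats(0, 1)),
            st.one_of(st.none(),
                      st.floats(1e-6, 1, exclude_min=False)),
        ),
        max_size=25,
    ))
    @settings(derandomize=True, max_examples=50)
    def test_partition_identities_on_random_pools(self, reference, raw):
        pool = [rec(s, r, p) for s, r, p in raw]
        report = run_funnel(pool, FunnelConfig(), reference)
        c = report.stage_counts
        assert c["input"] >= c["after_rank"] >= c["after_binding"]
        assert c["known"] + c["novel"] == c["after_binding"]
        assert c["sar_selected"] <= c["novel"]


class TestFunnelConfig:
    @pytest.mark.parametrize("kwargs", [
        {"rank_threshold": 1.5},
        {"pvalue_threshold": 0.0},
        {"pvalue_threshold": 1.0},
        {"target_activity": "Levitation"},
    ])
    def test_invalid_config(self, kwargs):
        with pytest.raises(ValueError):
            FunnelConfig(**kwargs)
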