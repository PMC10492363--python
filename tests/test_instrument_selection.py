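"""Instrument selection: significance filter, LD clumping, confounder
screening, and the weak-instrument F filter."""

import numpy as np
import pytest

from conftest import make_record
from mrkit.errors import ValidationError
from mrkit.instrument_selection import (
    ClumpConfig,
    ExclusionReason,
    InstrumentRecord,
    clump_greedy,
    compute_f_statistic,
    exclude_confounded,
    filter_by_pvalue,
    select_instruments,
)
from mrkit.summary_data import LDMatrix, Study, TraitAnnotation


def build_study(records, trait_type="continuous", name="exposure"):
    study = Study(name, trait_type)
    for r in records:
        study.add(r)
    return study


def identity_ld(ids):
    return LDMatrix(ids, np.eye(len(ids)))


class TestPValueFilter:
    def test_strict_threshold(self):
        study = build_study([
            make_record("rs_a", pvalue=5.26e-33),
            make_record("rs_b", pvalue=5e-8),   # exactly at threshold: excluded
            make_record("rs_c", pvalue=1e-3),
        ])
        recs = filter_by_pvalue(study, 5e-8)
        status = {r.snp_id: r.exclusion_reason for r in recs}
        assert status["rs_a"] is None
        assert status["rs_b"] is ExclusionReason.ABOVE_P_THRESHOLD
        assert status["rs_c"] is ExclusionReason.ABOVE_P_THRESHOLD

    def test_empty_study(self):
        assert filter_by_pvalue(build_study([]), 5e-8) == []

    def test_invalid_threshold(self):
        with pytest.raises(ValidationError):
            filter_by_pvalue(build_study([]), 1.5)


class TestClumping:
    def two_snp_ld(self, r2):
        return LDMatrix(["rs_a", "rs_b"], np.array([[1.0, r2], [r2, 1.0]]))

    def test_leader_kept_by_lowest_p(self):
        recs = [
            InstrumentRecord(record=make_record("rs_a", pvalue=1e-9)),
            InstrumentRecord(record=make_record("rs_b", pvalue=1e-12)),
        ]
        out = clump_greedy(recs, self.two_snp_ld(0.9), ClumpConfig())
        status = {r.snp_id: r.exclusion_reason for r in out}
        assert status["rs_b"] is None
        assert status["rs_a"] is ExclusionReason.CLUMPED

    def test_below_r2_cutoff_both_kept(self):
        recs = [InstrumentRecord(record=make_record(s, pvalue=p))
                for s, p in [("rs_a", 1e-12), ("rs_b", 1e-9)]]
        out = clump_greedy(recs, self.two_snp_ld(0.0005), ClumpConfig())
        assert all(r.retained for r in out)

    def test_outside_window_both_kept(self):
        # high r2 but 20,000 kb apart: the distance rule spares the pair
        recs = [
            InstrumentRecord(record=make_record("rs_a", pvalue=1e-12, chrom="1", pos=1_000_000)),
            InstrumentRecord(record=make_record("rs_b", pvalue=1e-9, chrom="1", pos=21_000_000)),
        ]
        out = clump_greedy(recs, self.two_snp_ld(0.9), ClumpConfig(window_kb=10_000))
        assert all(r.retained for r in out)

    def test_missing_from_ld_treated_independent(self):
        recs = [InstrumentRecord(record=make_record(s, pvalue=p))
                for s, p in [("rs_a", 1e-12), ("rs_x", 1e-9)]]
        out = clump_greedy(recs, identity_ld(["rs_a"]), ClumpConfig())
        assert all(r.retained for r in out)

    def test_order_invariance_and_pairwise_property(self):
        """Retained set is input-order invariant and contains no pair with
        r2 above threshold inside the window (brute-force scan)."""
        rng = np.random.default_rng(7)
        n = 30
        ids = [f"rs{i}" for i in range(n)]
        # random block structure
        blocks = rng.integers(0, 6, size=n)
        r2 = np.where(blocks[:, None] == blocks[None, :], 0.8, 0.0)
        np.fill_diagonal(r2, 1.0)
        ld = LDMatrix(ids, r2)
        recs = [
            InstrumentRecord(record=make_record(ids[i], pvalue=float(rng.uniform(1e-30, 1e-8)),
                                                chrom="1", pos=int(1 + i * 1_000_000)))
            for i in range(n)
        ]
        cfg = ClumpConfig()
        kept = {r.snp_id for r in clump_greedy(recs, ld, cfg) if r.retained}
        shuffled = list(recs)
        rng.shuffle(shuffled)
        kept2 = {r.snp_id for r in clump_greedy(shuffled, ld, cfg) if r.retained}
        assert kept == kept2
        pos = {r.snp_id: r.record.pos for r in recs}
        for a in kept:
            for b in kept:
                if a < b and abs(pos[a] - pos[b]) < cfg.window_kb * 1000:
                    assert ld.get(a, b) <= cfg.r2_threshold

    def test_tie_break_lexicographic(self):
        recs = [InstrumentRecord(record=make_record(s, pvalue=1e-10))
                for s in ("rs_b", "rs_a")]
        out = clump_greedy(recs, self.two_snp_ld(0.9), ClumpConfig())
        status = {r.snp_id: r.retained for r in out}
        assert status["rs_a"] and not status["rs_b"]


class TestConfounderExclusion:
    CONFOUNDERS = {"smoking", "alcohol consumption", "diabetes mellitus"}

    def run(self, annotations):
        recs = [InstrumentRecord(record=make_record("rs1"))]
        return exclude_confounded(recs, annotations, "periodontitis", self.CONFOUNDERS)[0]

    def test_single_confounder_tolerated(self):
        out = self.run([TraitAnnotation("rs1", "smoking", 1e-9)])
        assert out.retained

    def test_two_confounders_excluded(self):
        out = self.run([
            TraitAnnotation("rs1", "smoking", 1e-9),
            TraitAnnotation("rs1", "diabetes mellitus", 1e-10),
        ])
        assert out.exclusion_reason is ExclusionReason.MULTI_CONFOUNDER

    def test_outcome_association_excluded(self):
        out = self.run([TraitAnnotation("rs1", "periodontitis", 1e-10)])
        assert out.exclusion_reason is ExclusionReason.OUTCOME_ASSOCIATED

    def test_weak_associations_ignored(self):
        out = self.run([
            TraitAnnotation("rs1", "smoking", 1e-4),
            TraitAnnotation("rs1", "diabetes mellitus", 1e-5),
        ])
        assert out.retained

    def test_unknown_trait_ignored_with_warning(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING):
            out = self.run([TraitAnnotation("rs1", "height", 1e-20)])
        assert out.retained
        assert "unknown trait" in caplog.text


class TestFStatistic:
    def test_forced_arithmetic(self):
        assert compute_f_statistic(make_record(beta=0.1, se=0.01)) == pytest.approx(100.0)
        assert compute_f_statistic(make_record(beta=0.0, se=0.3)) == 0.0

    def test_published_weak_instrument(self, table1):
        # on the (beta/se)^2 scale the rs1057868 instrument sits just below 10
        rec = table1[0]["rs1057868"]
        assert compute_f_statistic(rec) == pytest.approx(9.729, abs=1e-3)

    def test_variance_explained_alternative(self):
        rec = make_record(beta=0.05, se=0.01, eaf=0.3, n=100_000)
        r2 = 2 * 0.3 * 0.7 * 0.05**2
        expected = r2 * (100_000 - 2) / (1 - r2)
        assert compute_f_statistic(rec, method="variance_explained") == pytest.approx(expected)

    def test_variance_explained_needs_eaf(self):
        with pytest.raises(ValidationError):
            compute_f_statistic(make_record(eaf=None), method="variance_explained")


class TestSelectInstruments:
    def build(self):
        rng = np.random.default_rng(11)
        records = []
        for i in range(8):
            records.append(make_record(
                f"rs{i}", beta=0.5, se=0.05,
                pvalue=float(10.0 ** -rng.uniform(9, 20)),
                chrom="1", pos=int(1 + i * 1_000_000),
            ))
        # rs8: above threshold; rs9: weak (F = 4); rs0/rs1 in LD (rs with lower p wins)
        records.append(make_record("rs8", pvalue=1e-3))
        records.append(make_record("rs9", beta=0.1, se=0.05, pvalue=1e-9))
        study = build_study(records)
        ids = [r.snp_id for r in records]
        r2 = np.eye(len(ids))
        r2[0, 1] = r2[1, 0] = 0.95
        ld = LDMatrix(ids, r2)
        annotations = [
            TraitAnnotation("rs2", "smoking", 1e-9),
            TraitAnnotation("rs2", "diabetes mellitus", 1e-9),
            TraitAnnotation("rs3", "periodontitis", 1e-9),
        ]
        return study, ld, annotations

    def test_stage_order_and_reasons(self):
        study, ld, annotations = self.build()
        out = select_instruments(
            study, ld, annotations, ClumpConfig(), f_min=10.0,
            outcome_trait="periodontitis",
            confounder_traits={"smoking", "diabetes mellitus"},
        )
        by_id = {r.snp_id: r for r in out}
        assert by_id["rs8"].exclusion_reason is ExclusionReason.ABOVE_P_THRESHOLD
        assert by_id["rs9"].exclusion_reason is ExclusionReason.WEAK_INSTRUMENT
        assert by_id["rs2"].exclusion_reason is ExclusionReason.MULTI_CONFOUNDER
        assert by_id["rs3"].exclusion_reason is ExclusionReason.OUTCOME_ASSOCIATED
        clumped = {s for s, r in by_id.items() if r.exclusion_reason is ExclusionReason.CLUMPED}
        assert len(clumped) == 1 and clumped <= {"rs0", "rs1"}
        assert sum(r.retained for r in out) == 5
        assert all(r.f_stat is not None for r in out)

    def test_f_filter_disabled_mode(self):
        study, ld, annotations = self.build()
        out = select_instruments(
            study, ld, annotations, ClumpConfig(p_threshold=5e-6), f_min=None,
            outcome_trait="periodontitis",
            confounder_traits={"smoking", "diabetes mellitus"},
        )
        reasons = {r.exclusion_reason for r in out}
        assert ExclusionReason.WEAK_INSTRUMENT not in reasons
        assert sum(r.retained for r in out) == 6  # rs9 survives

    def test_f_filter_removes_exactly_below_threshold(self):
        study, ld, _ = self.build()
        out = select_instruments(study, ld, [], ClumpConfig(), f_min=10.0)
        for r in out:
            if r.exclusion_reason in (None, ExclusionReason.WEAK_INSTRUMENT):
                f = (r.record.beta / r.record.se) ** 2
                assert r.retained == (f > 10.0)

    def test_all_above_threshold(self, caplog):
        import logging

        study = build_study([make_record("rs1", pvalue=0.5)])
        with caplog.at_level(logging.WARNING):
            out = select_instruments(study, identity_ld(["rs1"]), [], ClumpConfig())
        assert not any(r.retained for r in out)
        assert "no instruments retained" in caplog.text
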