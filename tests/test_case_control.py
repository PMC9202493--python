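"""Crude and Cochran-Mantel-Haenszel odds ratios, masking, demographics."""

import math
from fractions import Fraction

import numpy as np
import pytest

from _oracles import mantel_haenszel_statsmodels
from comorbnet import reference_data
from comorbnet.case_control import (
    CMHResult,
    StratifiedTable,
    TwoByTwo,
    cmh_or,
    crude_or,
    masked_input_handling,
    read_stratified_tsv,
    summarize_demographics,
    write_stratified_tsv,
)
from comorbnet.preprocess import CaseReport
from comorbnet.synthetic_data import (
    CohortGenSpec,
    StratumSpec,
    generate_stratified_cohort,
    mask_stratified_table,
)


class TestCrudeOR:
    def test_null_table(self):
        assert crude_or(TwoByTwo(10, 10, 10, 10)) == 1.0

    def test_published_diabetes_counts_give_or_3_32(self):
        """Crude OR from the published cohort totals, vs exact rational arithmetic."""
        t = reference_data.outcome_two_by_two("Type2Diabetes")
        oracle = Fraction(t.a * t.d, t.b * t.c_)
        assert crude_or(t) == pytest.approx(float(oracle), rel=1e-12)
        assert round(crude_or(t), 2) == 3.32

    def test_haldane_correction_yields_finite_value(self):
        t = TwoByTwo(0, 10, 5, 20)
        assert crude_or(t, continuity=True) == pytest.approx(
            (0.5 * 20.5) / (10.5 * 5.5)
        )

    def test_zero_denominator_raises_without_correction(self):
        with pytest.raises(ZeroDivisionError):
            crude_or(TwoByTwo(5, 0, 5, 5))


class TestCMH:
    STRATA = StratifiedTable([
        ("s1", TwoByTwo(12, 88, 30, 270)),
        ("s2", TwoByTwo(40, 160, 25, 175)),
        ("s3", TwoByTwo(7, 43, 14, 136)),
    ])

    def test_single_stratum_reduces_to_crude_or(self):
        t = TwoByTwo(23, 77, 11, 89)
        res = cmh_or(StratifiedTable([("only", t)]))
        assert res.aor == pytest.approx(crude_or(t), rel=1e-12)

    def test_two_identical_strata_pool_to_single_stratum_value(self):
        t = TwoByTwo(23, 77, 11, 89)
        single = cmh_or(StratifiedTable([("a", t)]))
        double = cmh_or(StratifiedTable([("a", t), ("b", t)]))
        assert double.aor == pytest.approx(single.aor, rel=1e-12)

    def test_exposure_transposition_inverts_or_and_negates_log_ci(self):
        res = cmh_or(self.STRATA)
        flipped = cmh_or(
            StratifiedTable([(lab, t.transposed_exposure()) for lab, t in self.STRATA])
        )
        assert flipped.aor == pytest.approx(1.0 / res.aor, rel=1e-12)
        assert math.log(flipped.ci_low) == pytest.approx(-math.log(res.ci_high), rel=1e-9)
        assert math.log(flipped.ci_high) == pytest.approx(-math.log(res.ci_low), rel=1e-9)
        assert flipped.p_value == pytest.approx(res.p_value, rel=1e-9)

    def test_agrees_with_statsmodels(self):
        res = cmh_or(self.STRATA)
        est, low, high, p = mantel_haenszel_statsmodels(self.STRATA)
        assert res.aor == pytest.approx(est, rel=1e-10)
        assert res.ci_low == pytest.approx(low, rel=1e-6)
        assert res.ci_high == pytest.approx(high, rel=1e-6)
        assert res.p_value == pytest.approx(p, rel=1e-6)

    def test_empty_strata_skipped_and_counted(self):
        table = StratifiedTable(list(self.STRATA) + [("empty", TwoByTwo(0, 0, 0, 0))])
        res = cmh_or(table)
        assert res.strata_used == 3
        assert res.strata_skipped == 1
        assert res.aor == pytest.approx(cmh_or(self.STRATA).aor)

    def test_estimator_consistency_with_growing_counts(self):
        """Estimate within 3 SE of truth at both sizes; CI shrinks with n."""
        widths = {}
        for scale in (1, 8):
            spec = CohortGenSpec(
                strata=(
                    StratumSpec("a", 5_000 * scale, 50_000 * scale, 0.05),
                    StratumSpec("b", 4_000 * scale, 40_000 * scale, 0.10),
                ),
                common_or=1.45,
                rng_seed=13,
            )
            res = cmh_or(generate_stratified_cohort(spec))
            se_log = (math.log(res.ci_high) - math.log(res.ci_low)) / (2 * 1.959964)
            assert abs(math.log(res.aor) - math.log(1.45)) < 3 * se_log
            widths[scale] = math.log(res.ci_high) - math.log(res.ci_low)
        assert widths[8] < widths[1] / 2  # ~1/sqrt(8) shrinkage

    def test_result_invariants_enforced(self):
        with pytest.raises(ValueError):
            CMHResult(aor=2.0, ci_low=2.5, ci_high=3.0, p_value=0.1,
                      chi2=1.0, strata_used=1, strata_skipped=0)


class TestConfounding:
    def test_confounder_inflates_crude_or_above_cmh(self):
        """Adjuster tied to both exposure and outcome: crude OR > common OR.

        Stratum z1 has 4x the exposure rate and 6x the baseline outcome
        odds of z0 while the within-stratum OR is 1.3 in both, so the
        pooled (crude) table overstates the association.
        """
        strata = []
        for label, exposed, unexposed, odds0 in (
            ("z1", 40_000, 10_000, 0.30),
            ("z0", 10_000, 40_000, 0.05),
        ):
            p0 = odds0 / (1 + odds0)
            odds1 = odds0 * 1.3
            p1 = odds1 / (1 + odds1)
            a, c = round(exposed * p1), round(unexposed * p0)
            strata.append((label, TwoByTwo(a, exposed - a, c, unexposed - c)))
        table = StratifiedTable(strata)
        adjusted = cmh_or(table).aor
        pooled = TwoByTwo(
            sum(t.a for _, t in table), sum(t.b for _, t in table),
            sum(t.c_ for _, t in table), sum(t.d for _, t in table),
        )
        assert crude_or(pooled) > adjusted
        assert adjusted == pytest.approx(1.3, rel=0.02)


class TestMaskedHandling:
    MASKED = StratifiedTable([
        ("clean", TwoByTwo(30, 120, 40, 310)),
        ("holey", TwoByTwo(None, 90, 20, None)),
    ])

    def test_no_masked_cells_is_identity(self):
        clean = StratifiedTable([("s", TwoByTwo(5, 5, 5, 5))])
        out = masked_input_handling(clean)
        assert list(out) == list(clean)
        assert out.provenance["masked_cells"] == 0

    def test_drop_policy_removes_stratum(self):
        out = masked_input_handling(self.MASKED, policy="drop")
        assert [lab for lab, _ in out] == ["clean"]
        assert out.provenance["strata_dropped_masked"] == 1

    def test_midpoint_policy_fills_with_five(self):
        out = masked_input_handling(self.MASKED, policy="midpoint")
        holey = dict(out.strata)["holey"]
        assert (holey.a, holey.d) == (5, 5)

    def test_policies_stay_near_unmasked_truth(self):
        """Midpoint- and drop-resolved estimates track the unmasked estimate."""
        spec = CohortGenSpec(
            strata=tuple(
                StratumSpec(f"s{i}", 150, 2_000, 0.02 + 0.02 * i) for i in range(6)
            ),
            common_or=2.0,
            rng_seed=21,
        )
        unmasked = generate_stratified_cohort(spec)
        masked = mask_stratified_table(unmasked, mask_below=10, round_to=1)
        assert any(t.masked for _, t in masked)
        truth = cmh_or(unmasked).aor
        for policy in ("midpoint", "drop"):
            est = cmh_or(masked_input_handling(masked, policy=policy)).aor
            assert abs(est - truth) / truth < 0.20, (policy, est, truth)

    def test_unresolved_masked_cells_rejected_by_cmh(self):
        with pytest.raises(ValueError, match="suppressed"):
            cmh_or(self.MASKED)

    def test_tsv_roundtrip_preserves_suppression(self, tmp_path):
        path = tmp_path / "strata.tsv"
        write_stratified_tsv(self.MASKED, path)
        back = read_stratified_tsv(path)
        assert [(lab, t) for lab, t in back] == list(self.MASKED)
        assert "<10" in path.read_text()


class TestDemographics:
    def test_single_female_cohort_is_100_percent(self):
        reports = [CaseReport("1", frozenset(), frozenset(), frozenset(),
                              demographics=("Adult", "Female"))]
        summary = summarize_demographics({"tiny": reports})
        assert summary.percent("tiny", "sex", "Female") == 100

    def test_published_oud_female_share_is_51_percent(self):
        summary = summarize_demographics(
            {"OUD": reference_data.DEMOGRAPHIC_COUNTS["OUD"]}
        )
        count, pct = summary.table["OUD"]["sex"]["Female"]
        assert count == 188_490
        assert pct == 51

    def test_synthetic_tally_matches_hand_count(self):
        rng = np.random.default_rng(2)
        sexes = ["Female", "Male"]
        ages = ["Adult", "Senior"]
        reports = [
            CaseReport(str(i), frozenset(), frozenset(), frozenset(),
                       demographics=(ages[rng.integers(2)], sexes[rng.integers(2)]))
            for i in range(200)
        ]
        summary = summarize_demographics({"synth": reports})
        n_female = sum(1 for r in reports if r.demographics[1] == "Female")
        count, pct = summary.table["synth"]["sex"]["Female"]
        assert count == n_female
        assert pct == math.floor(100 * n_female / 200 + 0.5)

    def test_multireported_categories_may_exceed_total(self):
        counts = {"total": 100, "sex": {"Female": 60, "Male": 50}}
        summary = summarize_demographics({"c": counts})
        assert summary.percent("c", "sex", "Female") == 60
        assert summary.percent("c", "sex", "Male") == 50
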