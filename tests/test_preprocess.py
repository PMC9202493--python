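"""De-duplication, term normalization, cohort flagging, transactions."""

import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from comorbnet.preprocess import (
    CaseReport,
    CohortLexicon,
    build_transactions,
    deduplicate_cases,
    flag_oud_cases,
    normalize_terms,
)

LEXICON = CohortLexicon(
    opioid_drugs=frozenset({"morphine", "oxycodone"}),
    disorder_terms=frozenset({"drug dependence", "opioid abuse"}),
    oud_label="opioid use disorder",
)


def _tables(demo_rows, drug_rows=(), indi_rows=(), reac_rows=()):
    return {
        "demo": pd.DataFrame(demo_rows, columns=["case_id", "version", "quarter", "age_group", "sex"]),
        "drug": pd.DataFrame(drug_rows, columns=["case_id", "version", "drug_raw"]),
        "indi": pd.DataFrame(indi_rows, columns=["case_id", "version", "indication_raw"]),
        "reac": pd.DataFrame(reac_rows, columns=["case_id", "version", "reaction_raw"]),
    }


class TestDeduplication:
    def test_only_latest_version_survives(self):
        tables = _tables(
            [("7", 1, "2019Q1", "Adult", "Female"), ("7", 2, "2020Q3", "Adult", "Female")],
            drug_rows=[("7", 1, "OLD DRUG"), ("7", 2, "NEW DRUG")],
        )
        out, report = deduplicate_cases(tables)
        assert list(out["demo"]["version"]) == [2]
        assert list(out["drug"]["drug_raw"]) == ["NEW DRUG"]
        assert report["cases"] == 1

    def test_no_duplicates_is_identity(self):
        tables = _tables([("1", 1, "2019Q1", "Adult", "Male"), ("2", 1, "2019Q2", "Senior", "Female")])
        out, _ = deduplicate_cases(tables)
        pd.testing.assert_frame_equal(out["demo"], tables["demo"])

    def test_matches_groupby_max_oracle_on_mixed_fixture(self):
        # 20 cases, 5 of them duplicated at an earlier version
        rows = []
        for i in range(20):
            cid = str(i)
            if i < 5:
                rows.append((cid, 1, "2019Q1", "Adult", "Female"))
            rows.append((cid, 2 if i < 5 else 1, "2020Q2", "Adult", "Female"))
        tables = _tables(rows)
        out, report = deduplicate_cases(tables)
        # brute-force oracle: group by case, keep max version rows
        df = tables["demo"]
        oracle = df[df["version"] == df.groupby("case_id")["version"].transform("max")]
        assert report["cases"] == 20
        pd.testing.assert_frame_equal(
            out["demo"].reset_index(drop=True), oracle.reset_index(drop=True)
        )

    def test_idempotence(self):
        tables = _tables(
            [("7", 1, "2019Q1", "Adult", "Female"), ("7", 2, "2020Q3", "Adult", "Female")]
        )
        once, _ = deduplicate_cases(tables)
        twice, _ = deduplicate_cases(once)
        for name in tables:
            pd.testing.assert_frame_equal(once[name], twice[name])

    def test_missing_version_rows_are_dropped(self):
        tables = _tables(
            [("1", 1, "2019Q1", "Adult", "Male"), ("2", None, "2019Q1", "Adult", "Male")]
        )
        out, report = deduplicate_cases(tables)
        assert report["cases"] == 1
        assert list(out["demo"]["case_id"]) == ["1"]


class TestNormalization:
    MAPS = {
        "drug": {"morphine sulfate": "morphine"},
        "indi": {"back pain": "pain"},
        "reac": {"nausea nos": "nausea"},
    }

    def test_raw_string_mapped_to_canonical(self):
        tables = _tables(
            [("1", 1, "2019Q1", "Adult", "Male")],
            drug_rows=[("1", 1, "MORPHINE SULFATE")],
        )
        out, coverage = normalize_terms(tables, self.MAPS)
        assert list(out["drug"]["term"]) == ["morphine"]
        assert coverage["drug"]["coverage"] == 1.0

    def test_unmapped_strings_dropped_and_counted(self):
        tables = _tables(
            [("1", 1, "2019Q1", "Adult", "Male")],
            drug_rows=[("1", 1, "MORPHINE SULFATE"), ("1", 1, "GARBLED STRING")],
        )
        out, coverage = normalize_terms(tables, self.MAPS)
        assert list(out["drug"]["term"]) == ["morphine"]
        assert coverage["drug"] == {
            "unique_raw": 2, "unique_mapped": 1, "coverage": 0.5, "rows_dropped": 1,
        }

    def test_seventy_percent_coverage_fixture(self):
        vocab = {f"raw {i}": f"term_{i}" for i in range(7)}
        raws = [f"RAW {i}" for i in range(10)]  # 3 of 10 unmapped
        tables = _tables(
            [("1", 1, "2019Q1", "Adult", "Male")],
            indi_rows=[("1", 1, r) for r in raws],
        )
        maps = {"drug": {"x": "x"}, "indi": vocab, "reac": {"x": "x"}}
        _, coverage = normalize_terms(tables, maps)
        assert coverage["indi"]["coverage"] == pytest.approx(0.70)

    def test_empty_map_rejected(self):
        tables = _tables([("1", 1, "2019Q1", "Adult", "Male")])
        with pytest.raises(ValueError, match="empty vocabulary"):
            normalize_terms(tables, {"drug": {}, "indi": {"a": "a"}, "reac": {"a": "a"}})


class TestCohortFlagging:
    @pytest.mark.parametrize(
        "drugs, indications, reactions, expect",
        [
            ({"morphine"}, set(), {"drug dependence"}, True),
            ({"morphine"}, {"opioid abuse"}, set(), True),  # indication trigger counts
            ({"morphine"}, {"pain"}, {"nausea"}, False),  # no disorder term
            (set(), {"opioid abuse"}, set(), False),  # no opioid drug
            ({"aspirin"}, set(), {"drug dependence"}, False),
        ],
    )
    def test_conjunction_rule(self, drugs, indications, reactions, expect):
        case = CaseReport("1", frozenset(drugs), frozenset(indications), frozenset(reactions))
        flagged, n = flag_oud_cases([case], LEXICON)
        assert (LEXICON.oud_label in flagged[0].indications) is expect
        assert n == int(expect)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        drugs=st.sets(st.sampled_from(["aspirin", "morphine", "ibuprofen"])),
        indications=st.sets(st.sampled_from(["pain", "opioid abuse", "fever"])),
        reactions=st.sets(st.sampled_from(["nausea", "drug dependence"])),
        extra=st.sampled_from(["morphine", "oxycodone"]),
    )
    def test_flagging_is_monotone_in_opioid_drugs(self, drugs, indications, reactions, extra):
        """Adding an opioid drug or disorder term never removes the flag."""
        base = CaseReport("1", frozenset(drugs), frozenset(indications), frozenset(reactions))
        grown = CaseReport(
            "1", frozenset(drugs | {extra}),
            frozenset(indications | {"opioid abuse"}), frozenset(reactions),
        )
        (fb,), _ = flag_oud_cases([base], LEXICON)
        (fg,), _ = flag_oud_cases([grown], LEXICON)
        if LEXICON.oud_label in fb.indications:
            assert LEXICON.oud_label in fg.indications

    def test_flagged_set_equals_planted_seed_set(self, small_bundle, small_cases):
        truth = small_bundle["truth"]
        planted = {
            r.case_id for r in small_bundle["reports"]
            if truth.seed_disease in r.indications
        }
        flagged = {
            c.case_id for c in small_cases["cases"]
            if small_cases["lexicon"].oud_label in c.indications
        }
        assert flagged == planted
        assert small_cases["n_flagged"] == len(planted)

    def test_roundtrip_reconstructs_generated_reports(self, small_bundle, small_cases):
        """dedup + normalize + flag reproduces the generator's truth exactly."""
        recon = {c.case_id: c for c in small_cases["cases"]}
        for truth_case in small_bundle["reports"]:
            assert recon[truth_case.case_id] == truth_case


class TestTransactions:
    def test_projection_and_empty_filter(self):
        cases = [
            CaseReport("1", frozenset(), frozenset({"pain", "opioid use disorder"}), frozenset()),
            CaseReport("2", frozenset({"aspirin"}), frozenset(), frozenset({"nausea"})),
        ]
        transactions = build_transactions(cases)
        assert transactions == [("1", frozenset({"pain", "opioid use disorder"}))]

    def test_transaction_count_matches_oracle(self, small_cases):
        transactions = build_transactions(small_cases["cases"])
        n_nonempty = sum(1 for c in small_cases["cases"] if c.indications)
        assert len(transactions) == n_nonempty
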