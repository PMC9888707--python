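"""Phenotype derivation: PTA, degree bins, phecode status, hybrid assignment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st_h

from hlburden import phenotype as ph


class TestPTA:
    def test_arithmetic_mean_of_three_frequencies(self):
        assert ph.compute_pta({500.0: 10, 1000.0: 20, 2000.0: 30}) == 20.0
        assert ph.compute_pta((0, 0, 0)) == 0.0
        assert ph.compute_pta((15, 25, 35)) == 25.0

    def test_extra_frequencies_ignored(self):
        assert ph.compute_pta({250.0: 99, 500.0: 10, 1000.0: 20, 2000.0: 30, 8000.0: 99}) == 20.0

    def test_missing_frequency_raises(self):
        with pytest.raises(ph.MissingDataError):
            ph.compute_pta({500.0: 10, 1000.0: 20})


class TestDegreeBins:
    @pytest.mark.parametrize(
        "pta,degree",
        [
            (-5, 0),
            (0, 0),
            (15, 0),
            (15.5, 1),
            (16, 1),
            (20, 1),
            (25, 1),
            (25.5, 2),
            (30, 2),
            (40, 2),
            (40.5, 3),
            (55, 3),
            (55.5, 4),
            (56, 4),
            (120, 4),
        ],
    )
    def test_boundaries(self, pta, degree):
        assert ph.pta_to_degree(pta) == degree

    def test_vectorised(self):
        np.testing.assert_array_equal(ph.pta_to_degree([10, 20, 30, 50, 60]), [0, 1, 2, 3, 4])

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            ph.pta_to_degree(float("nan"))

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(
        st_h.floats(min_value=-50, max_value=150, allow_nan=False),
        st_h.floats(min_value=0, max_value=50, allow_nan=False),
    )
    def test_monotone_partition(self, pta, delta):
        """Every finite PTA maps to exactly one degree; the map is nondecreasing."""
        d1 = ph.pta_to_degree(pta)
        d2 = ph.pta_to_degree(pta + delta)
        assert d1 in {0, 1, 2, 3, 4}
        assert d2 >= d1


class TestPhecodeStatus:
    @pytest.mark.parametrize("count,status", [(0, "control"), (1, "NA"), (2, "case"), (7, "case")])
    def test_rule(self, count, status):
        assert ph.phecode_status(count) == status

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            ph.phecode_status(-1)

    def test_table_counts_missing_individuals_as_controls(self):
        phe = pd.DataFrame({"individual_id": ["A", "A", "B"], "phecode": "389", "date": "2020-01-01"})
        tab = ph.phecode_status_table(phe, ["A", "B", "C"], phecode="389")
        assert dict(zip(tab["individual_id"], tab["status"])) == {"A": "case", "B": "NA", "C": "control"}

    def test_other_codes_not_counted(self):
        phe = pd.DataFrame({"individual_id": ["A", "A"], "phecode": ["389", "401"], "date": "x"})
        tab = ph.phecode_status_table(phe, ["A"], phecode="389")
        assert tab.loc[0, "status"] == "NA"


class TestWorseEar:
    def test_larger_ear_wins(self, audiogram_rows):
        rec = pd.concat(
            [audiogram_rows(ear="left", thresholds=(13, 18, 23)), audiogram_rows(ear="right", thresholds=(27, 32, 37))]
        )
        assert ph.worse_ear_pta(rec) == 32.0

    def test_single_complete_ear(self, audiogram_rows):
        rec = audiogram_rows(ear="left", thresholds=(35, 40, 45))
        assert ph.worse_ear_pta(rec) == 40.0

    def test_latest_exam_convention(self, audiogram_rows):
        early = pd.concat(
            [audiogram_rows(date="2018-01-01", ear="left", thresholds=(40, 40, 40))]
        )
        late = pd.concat(
            [
                audiogram_rows(date="2020-01-01", ear="left", thresholds=(18, 20, 22)),
                audiogram_rows(date="2020-01-01", ear="right", thresholds=(20, 22, 24)),
            ]
        )
        rec = pd.concat([early, late])
        assert ph.worse_ear_pta(rec, exam="latest") == 22.0
        assert ph.worse_ear_pta(rec, exam="worst") == 40.0

    def test_bone_conduction_not_used(self, audiogram_rows):
        rec = pd.concat(
            [
                audiogram_rows(conduction="air", thresholds=(10, 10, 10)),
                audiogram_rows(conduction="bone", thresholds=(90, 90, 90)),
            ]
        )
        assert ph.worse_ear_pta(rec) == 10.0

    def test_no_complete_ear_raises(self, audiogram_rows):
        rec = audiogram_rows().iloc[:2]  # only two frequencies
        with pytest.raises(ph.MissingDataError):
            ph.worse_ear_pta(rec)


class TestAssignPhenotype:
    @pytest.fixture()
    def tables(self, audiogram_rows):
        aud = pd.concat(
            [
                audiogram_rows(ind="AUD_CASE", thresholds=(25, 30, 35)),  # PTA 30 -> degree 2
                audiogram_rows(ind="AUD_CTRL", thresholds=(5, 5, 5)),  # degree 0
            ]
        )
        phe = pd.DataFrame(
            {
                "individual_id": ["AUD_CASE", "AUD_CASE", "PHE_CASE", "PHE_CASE", "PHE_NA"],
                "phecode": "389",
                "date": "2020-01-01",
            }
        )
        ids = ["AUD_CASE", "AUD_CTRL", "PHE_CASE", "PHE_NA", "PHE_CTRL"]
        return aud, phe, ids

    def test_hybrid_assignment(self, tables):
        aud, phe, ids = tables
        out = ph.assign_phenotype(aud, phe, ids, phecode="389").set_index("individual_id")
        # audiogram wins over phecode status
        assert out.loc["AUD_CASE", "degree_hl"] == 2 and out.loc["AUD_CASE", "included"]
        assert out.loc["AUD_CTRL", "degree_hl"] == 0
        # phecode control without audiogram kept at degree 0
        assert out.loc["PHE_CTRL", "degree_hl"] == 0 and out.loc["PHE_CTRL", "source"] == "phecode-control"
        # phecode case / NA without audiograms excluded with reasons
        assert not out.loc["PHE_CASE", "included"]
        assert out.loc["PHE_CASE", "exclusion_reason"] == "phecode-case-without-audiogram"
        assert out.loc["PHE_NA", "exclusion_reason"] == "phecode-NA-without-audiogram"

    def test_output_size_invariant(self, tables):
        aud, phe, ids = tables
        out = ph.assign_phenotype(aud, phe, ids, phecode="389")
        n_aud = out["source"].eq("audiogram").sum()
        n_ctrl = out["source"].eq("phecode-control").sum()
        assert out["included"].sum() == n_aud + n_ctrl
        # each individual is included-with-degree xor excluded-with-reason
        inc = out["included"]
        assert out.loc[inc, "degree_hl"].notna().all()
        assert (out.loc[~inc, "exclusion_reason"] != "").all()

    def test_duplicate_ids_rejected(self, tables):
        aud, phe, _ = tables
        with pytest.raises(ValueError):
            ph.assign_phenotype(aud, phe, ["A", "A"])

    def test_binarize(self, tables):
        aud, phe, ids = tables
        out = ph.assign_phenotype(aud, phe, ids, phecode="389")
        lab = ph.binarize_case_control(out)
        assert lab["AUD_CASE"] == True  # noqa: E712  (degree 2 -> case)
        assert lab["AUD_CTRL"] == False  # noqa: E712
        assert lab["PHE_CTRL"] == False  # noqa: E712
        assert pd.isna(lab["PHE_CASE"])


def test_misclassification_crosstab_matches_hand_count(audiogram_rows):
    aud = pd.concat(
        [
            audiogram_rows(ind=f"P{i}", thresholds=(40, 40, 40)) for i in range(3)  # positive
        ]
        + [audiogram_rows(ind=f"N{i}", thresholds=(5, 5, 5)) for i in range(2)]  # negative
    )
    # P0, P1, N0 are phecode cases; P2, N1 controls
    phe = pd.DataFrame(
        {"individual_id": ["P0", "P0", "P1", "P1", "N0", "N0"], "phecode": "389", "date": "x"}
    )
    ids = [f"P{i}" for i in range(3)] + ["N0", "N1"]
    out = ph.assign_phenotype(aud, phe, ids, phecode="389")
    status = ph.phecode_status_table(phe, ids, phecode="389")
    tab = ph.misclassification_table(out, status).set_index("status")
    assert tab.loc["case", "n"] == 3 and tab.loc["case", "n_audiogram_positive"] == 2
    assert tab.loc["control", "n"] == 2 and tab.loc["control", "frac_audiogram_positive"] == 0.5
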