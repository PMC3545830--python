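"""Cross-platform pairing, expression floors and Spearman machinery."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from conftest import spearman_rank_formula
from vitiseq import (
    InsufficientDataError,
    STAGES,
    apply_expression_floors,
    build_matched_pairs,
    global_stage_correlation,
    pattern_correlation_histogram,
)


def probeset_frame(rows):
    """rows: (probeset_id, suffix, transcript_id, evalue, i1..i4)."""
    frame = pd.DataFrame(
        rows,
        columns=["probeset_id", "suffix_class", "transcript_id", "evalue", *STAGES],
    )
    return frame


def rpkm_frame(profiles: dict) -> pd.DataFrame:
    return pd.DataFrame.from_dict(profiles, orient="index", columns=list(STAGES))


def pairs_from(intensities: dict, rpkm: dict) -> pd.DataFrame:
    rows = [
        ("p" + t, "", t, 0.0, *vals) for t, vals in intensities.items()
    ]
    return build_matched_pairs(probeset_frame(rows), rpkm_frame(rpkm))


class TestBuildMatchedPairs:
    def test_crosshyb_suffix_removed_unconditionally(self):
        rpkm = rpkm_frame({"t1": (1, 2, 3, 4)})
        table = probeset_frame(
            [("p1", "_x", "t1", 0.0, 1, 2, 3, 4), ("p2", "", "t1", 0.0, 1, 2, 3, 4)]
        )
        out = build_matched_pairs(table, rpkm)
        assert list(out["probeset_id"]) == ["p2"]

    def test_nonzero_evalue_removed(self):
        rpkm = rpkm_frame({"t1": (1, 2, 3, 4)})
        table = probeset_frame([("p1", "", "t1", 1e-30, 1, 2, 3, 4)])
        assert build_matched_pairs(table, rpkm).empty

    def test_single_eligible_probeset_retained(self):
        rpkm = rpkm_frame({"t1": (1, 2, 3, 4)})
        table = probeset_frame([("p1", "", "t1", 0.0, 5, 5, 5, 5)])
        out = build_matched_pairs(table, rpkm)
        assert len(out) == 1

    def test_best_correlating_probeset_wins(self):
        rpkm = rpkm_frame({"t1": (1, 2, 3, 4)})
        table = probeset_frame(
            [
                ("good", "", "t1", 0.0, 1, 2, 3, 4),   # pattern rho 1.0
                ("poor", "", "t1", 0.0, 4, 3, 2, 1),   # pattern rho -1.0
            ]
        )
        out = build_matched_pairs(table, rpkm)
        assert list(out["probeset_id"]) == ["good"]

    def test_unknown_transcript_dropped_with_warning(self, caplog):
        rpkm = rpkm_frame({"t1": (1, 2, 3, 4)})
        table = probeset_frame(
            [("p1", "", "ghost", 0.0, 1, 2, 3, 4), ("p2", "", "t1", 0.0, 1, 2, 3, 4)]
        )
        with caplog.at_level("WARNING", logger="vitiseq.platform"):
            out = build_matched_pairs(table, rpkm)
        assert list(out["transcript_id"]) == ["t1"]
        assert "unknown transcript" in caplog.text


class TestExpressionFloors:
    def test_zero_rpkm_pair_excluded(self):
        pairs = pairs_from(
            {"t1": (8, 8, 8, 8), "t2": (8, 8, 8, 8), "t3": (8, 8, 8, 8)},
            {"t1": (0, 0, 0, 0), "t2": (5, 5, 5, 5), "t3": (5, 5, 5, 5)},
        )
        out = apply_expression_floors(pairs).set_index("transcript_id")
        assert not out.loc["t1", "retained"]
        assert out.loc["t2", "retained"]

    def test_percentile_threshold_splits_cohort_exactly(self):
        n = 100
        intensities = {f"t{i}": (float(i), float(i), float(i), float(i)) for i in range(n)}
        rpkm = {f"t{i}": (5.0, 5.0, 5.0, 5.0) for i in range(n)}
        out = apply_expression_floors(pairs_from(intensities, rpkm))
        assert int((~out["expressed_intensity"]).sum()) == 25

    def test_pair_exactly_at_threshold_included(self):
        intensities = {f"t{i}": (float(i), float(i), float(i), float(i)) for i in range(5)}
        rpkm = {f"t{i}": (5.0, 5.0, 5.0, 5.0) for i in range(5)}
        out = apply_expression_floors(pairs_from(intensities, rpkm))
        threshold = np.percentile(
            out[[f"int_{s}" for s in STAGES]].mean(axis=1), 25
        )
        at = out[out[[f"int_{s}" for s in STAGES]].mean(axis=1) == threshold]
        assert at["expressed_intensity"].all()

    def test_floor_order_independence(self):
        rng = np.random.default_rng(1)
        intensities = {f"t{i}": tuple(rng.uniform(2, 12, 4)) for i in range(50)}
        rpkm = {f"t{i}": tuple(rng.lognormal(0, 1.5, 4)) for i in range(50)}
        pairs = pairs_from(intensities, rpkm)
        both = apply_expression_floors(pairs)
        # intensity flag computed on the full cohort is unaffected by the
        # rpkm flag and vice versa: retained is their conjunction
        assert (
            both["retained"]
            == (both["expressed_intensity"] & both["expressed_rnaseq"])
        ).all()


class TestGlobalStageCorrelation:
    def test_monotone_noiseless_intensities_give_unit_rho(self):
        rng = np.random.default_rng(2)
        rpkm = {f"t{i}": tuple(rng.lognormal(1, 1, 4) + 0.5) for i in range(30)}
        intensities = {
            t: tuple(2 + 3 * np.log2(np.array(v) + 1)) for t, v in rpkm.items()
        }
        out = global_stage_correlation(pairs_from(intensities, rpkm))
        for stage in STAGES:
            assert out[stage] == pytest.approx(1.0)
        assert out["mean"] == pytest.approx(1.0)

    def test_hand_computed_three_point_rho(self):
        # intensity ranks (1,2,3) vs expression ranks (2,1,3) -> rho = 0.5
        lrpkm = {"a": 2.0, "b": 1.0, "c": 3.0}
        rpkm = {t: tuple([2.0**v - 1.0] * 4) for t, v in lrpkm.items()}
        intensities = {"a": (1.0,) * 4, "b": (2.0,) * 4, "c": (3.0,) * 4}
        out = global_stage_correlation(pairs_from(intensities, rpkm))
        assert out["EL31"] == pytest.approx(0.5)

    def test_spearman_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        rpkm = {f"t{i}": tuple(rng.lognormal(1, 1, 4) + 0.5) for i in range(40)}
        base = {t: tuple(5 + np.log2(np.array(v) + 1)) for t, v in rpkm.items()}
        warped = {t: tuple(np.exp(0.3 * np.array(v))) for t, v in base.items()}
        a = global_stage_correlation(pairs_from(base, rpkm))
        b = global_stage_correlation(pairs_from(warped, rpkm))
        for stage in STAGES:
            assert a[stage] == pytest.approx(b[stage])

    def test_too_few_pairs_rejected(self):
        pairs = pairs_from({"t1": (1, 2, 3, 4)}, {"t1": (1, 2, 3, 4)})
        with pytest.raises(InsufficientDataError):
            global_stage_correlation(pairs)


class TestPatternCorrelation:
    def test_identical_and_reversed_patterns(self):
        rpkm = {"same": (1, 2, 3, 4), "rev": (1, 2, 3, 4)}
        intensities = {"same": (1, 2, 3, 4), "rev": (4, 3, 2, 1)}
        rho, counts = pattern_correlation_histogram(pairs_from(intensities, rpkm))
        assert rho["same"] == pytest.approx(1.0)
        assert rho["rev"] == pytest.approx(-1.0)
        assert counts["rho >= 0.9"] == 1
        assert counts["rho < -0.9"] == 1

    def test_hand_computed_four_point_rho(self):
        rho, _ = pattern_correlation_histogram(
            pairs_from({"t": (1, 2, 4, 3)}, {"t": (1, 2, 3, 4)})
        )
        assert rho["t"] == pytest.approx(0.8)

    def test_constant_pattern_counted_as_undefined(self):
        rho, counts = pattern_correlation_histogram(
            pairs_from({"t": (5, 5, 5, 5)}, {"t": (1, 2, 3, 4)})
        )
        assert np.isnan(rho["t"])
        assert counts["undefined"] == 1

    def test_four_point_spearman_attains_only_the_permutation_values(self):
        """All 24 rank orders, against scipy and the closed-form formula."""
        attainable = {-1.0, -0.8, -0.6, -0.4, -0.2, 0.0, 0.2, 0.4, 0.6, 0.8, 1.0}
        base = (1.0, 2.0, 3.0, 4.0)
        for perm in itertools.permutations(base):
            expected = spearman_rank_formula(base, perm)
            got = float(spearmanr(base, perm).statistic)
            assert got == pytest.approx(expected, abs=1e-12)
            assert round(expected, 10) in {round(v, 10) for v in attainable}

    def test_histogram_counts_cover_every_pair(self):
        rng = np.random.default_rng(4)
        rpkm = {f"t{i}": tuple(rng.lognormal(1, 1, 4) + 0.5) for i in range(60)}
        intensities = {
            t: tuple(np.log2(np.array(v) + 1) + rng.normal(0, 1, 4))
            for t, v in rpkm.items()
        }
        rho, counts = pattern_correlation_histogram(pairs_from(intensities, rpkm))
        assert counts.sum() == len(rho) == 60
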