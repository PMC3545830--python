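"""Counting stage: filters, proportional allocation, RPKM, detection, bins."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import brute_force_allocate
from vitiseq import (
    ConsistencyError,
    DataError,
    ExpressionMatrix,
    abundance_bins,
    allocate_reads,
    build_expression_matrix,
    compute_rpkm,
    detect,
    expected_coverage,
    filter_alignments,
    filter_reads,
)


def reads_frame(rows):
    return pd.DataFrame(
        rows, columns=["read_id", "stage", "length_after_trim", "ambiguous_count"]
    )


def cand_frame(rows):
    return pd.DataFrame(
        rows,
        columns=["read_id", "transcript_id", "percent_identity", "aligned_fraction"],
    )


class TestReadFilter:
    @pytest.mark.parametrize(
        "length,ambiguous,kept",
        [
            (59, 0, False),   # under the length minimum
            (100, 2, True),   # exactly two ambiguous bases pass
            (60, 3, False),   # over the ambiguity maximum
            (60, 2, True),    # both boundaries inclusive on the keep side
        ],
    )
    def test_boundary_rules(self, length, ambiguous, kept):
        frame = reads_frame([("r1", "EL31", length, ambiguous)])
        assert (len(filter_reads(frame)) == 1) is kept

    def test_order_preserved_and_empty_ok(self):
        frame = reads_frame(
            [("r2", "EL31", 70, 0), ("r1", "EL31", 10, 0), ("r3", "EL31", 80, 1)]
        )
        kept = filter_reads(frame)
        assert list(kept["read_id"]) == ["r2", "r3"]
        assert filter_reads(frame.iloc[:0]).empty


class TestAlignmentFilter:
    @pytest.mark.parametrize(
        "identity,fraction,kept",
        [
            (0.99, 0.6, True),
            (0.98, 0.6, False),  # identity threshold is strict
            (1.00, 0.5, False),  # aligned-fraction threshold is strict
        ],
    )
    def test_strict_thresholds(self, identity, fraction, kept):
        frame = cand_frame([("r1", "t1", identity, fraction)])
        assert (len(filter_alignments(frame)) == 1) is kept

    def test_unknown_read_raises(self):
        frame = cand_frame([("ghost", "t1", 0.99, 0.9)])
        with pytest.raises(ConsistencyError):
            filter_alignments(frame, known_read_ids=pd.Index(["r1"]))


class TestAllocation:
    def test_proportional_split_example(self):
        # A has 8 unique, B has 2 unique, one read hits both -> 0.8 / 0.2
        pairs = [(f"u{i}", "A") for i in range(8)]
        pairs += [(f"v{i}", "B") for i in range(2)]
        pairs += [("m", "A"), ("m", "B")]
        out = allocate_reads(cand_frame([(r, t, 0.99, 0.9) for r, t in pairs]))
        alloc = dict(zip(out["transcript_id"], out["allocated_reads"]))
        assert alloc["A"] == pytest.approx(8.8)
        assert alloc["B"] == pytest.approx(2.2)

    def test_zero_unique_tie_splits_equally(self):
        out = allocate_reads(
            cand_frame([("m", "A", 0.99, 0.9), ("m", "B", 0.99, 0.9)])
        )
        alloc = dict(zip(out["transcript_id"], out["allocated_reads"]))
        assert alloc == {"A": pytest.approx(0.5), "B": pytest.approx(0.5)}

    def test_no_multimapping_identity(self):
        pairs = [("r1", "A"), ("r2", "A"), ("r3", "B")]
        out = allocate_reads(cand_frame([(r, t, 0.99, 0.9) for r, t in pairs]))
        assert (out["allocated_reads"] == out["unique_reads"]).all()

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(
        data=st.lists(
            st.tuples(
                st.integers(0, 19),  # read index
                st.sets(st.integers(0, 5), min_size=1, max_size=4),  # hit transcripts
            ),
            min_size=1,
            max_size=20,
            unique_by=lambda pair: pair[0],
        )
    )
    def test_matches_brute_force_on_small_instances(self, data):
        """Two-pass allocation equals an independent enumeration."""
        pairs = [
            (f"r{read}", f"t{t}") for read, hits in data for t in sorted(hits)
        ]
        out = allocate_reads(cand_frame([(r, t, 0.99, 0.9) for r, t in pairs]))
        expected_alloc, expected_unique = brute_force_allocate(pairs)
        got_alloc = dict(zip(out["transcript_id"], out["allocated_reads"]))
        got_unique = dict(zip(out["transcript_id"], out["unique_reads"]))
        assert set(got_alloc) == set(expected_alloc)
        for t, value in expected_alloc.items():
            assert got_alloc[t] == pytest.approx(value, abs=1e-12)
            assert got_unique[t] == expected_unique.get(t, 0)
        # conservation: allocation redistributes, never creates or loses reads
        assert sum(got_alloc.values()) == pytest.approx(len(data), abs=1e-9)


class TestRpkm:
    @pytest.mark.parametrize(
        "allocated,length,total,expected",
        [
            (20.0, 1000, 40e6, 0.5),   # coverage-2 worked example
            (0.0, 1000, 40e6, 0.0),
            (10.0, 2000, 1e6, 5.0),
        ],
    )
    def test_formula(self, allocated, length, total, expected):
        rpkm = compute_rpkm(
            pd.Series({"t": allocated}), pd.Series({"t": length}), total
        )
        assert rpkm["t"] == pytest.approx(expected)

    def test_zero_total_rejected(self):
        with pytest.raises(DataError):
            compute_rpkm(pd.Series({"t": 1.0}), pd.Series({"t": 100}), 0)

    def test_missing_length_rejected(self):
        with pytest.raises(ConsistencyError):
            compute_rpkm(pd.Series({"t": 1.0}), pd.Series({"u": 100}), 1e6)

    def test_scale_invariance(self):
        alloc = pd.Series({"a": 7.0, "b": 3.0})
        lengths = pd.Series({"a": 500, "b": 2000})
        base = compute_rpkm(alloc, lengths, 1e6)
        scaled = compute_rpkm(alloc * 13, lengths, 13e6)
        pd.testing.assert_series_equal(base, scaled)


class TestCoverage:
    @pytest.mark.parametrize(
        "rpkm,expected", [(0.5, 2.0), (0.0, 0.0), (1.0, 4.0)]
    )
    def test_worked_examples(self, rpkm, expected):
        assert expected_coverage(rpkm, 1000, 100, 40) == pytest.approx(expected)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(DataError):
            expected_coverage(0.5, 0, 100, 40)


class TestDetection:
    @pytest.mark.parametrize(
        "rpkm,unique,expected",
        [(0.4, 5, True), (0.6, 0, True), (0.4, 4, False), (0.5, 0, True)],
    )
    def test_rule(self, rpkm, unique, expected):
        r = pd.DataFrame({"EL31": [rpkm]})
        u = pd.DataFrame({"EL31": [unique]})
        assert bool(detect(r, u).iloc[0, 0]) is expected

    def test_adding_unique_read_never_undetects(self):
        rng = np.random.default_rng(0)
        r = pd.DataFrame({"EL31": rng.uniform(0, 2, 50)})
        u = pd.DataFrame({"EL31": rng.integers(0, 10, 50)})
        before = detect(r, u)
        after = detect(r, u + 1)
        assert (after | ~before).all().all()


class TestAbundanceBins:
    def make_matrix(self, rpkm_values, unique_values):
        stages = ["EL31"]
        r = pd.DataFrame({"EL31": rpkm_values})
        u = pd.DataFrame({"EL31": unique_values})
        return ExpressionMatrix(r, u, pd.Series({"EL31": 1e6}))

    def test_empty_matrix_all_zero(self):
        bins = abundance_bins(self.make_matrix([0.0, 0.0], [0, 0]))
        assert (bins["EL31"] == 0).all()

    def test_boundary_200_goes_to_middle_bin(self):
        bins = abundance_bins(self.make_matrix([200.0], [100]))
        assert bins.loc["RPKM 10-200", "EL31"] == 1
        assert bins.loc["RPKM > 200", "EL31"] == 0

    def test_counts_match_direct_tally_and_sum_to_detected(self):
        rng = np.random.default_rng(1)
        rpkm = rng.lognormal(1.0, 2.5, 300)
        unique = rng.integers(0, 12, 300)
        matrix = self.make_matrix(rpkm, unique)
        bins = abundance_bins(matrix)
        assert bins.loc["RPKM > 200", "EL31"] == (rpkm > 200).sum()
        assert bins.loc["RPKM 10-200", "EL31"] == ((rpkm >= 10) & (rpkm <= 200)).sum()
        assert bins.loc["RPKM 0.5-10", "EL31"] == ((rpkm >= 0.5) & (rpkm < 10)).sum()
        assert (
            bins.loc["total_detected", "EL31"]
            == matrix.detected()["EL31"].sum()
        )


class TestEndToEndCounting:
    def test_conservation_through_the_full_stage(self, small_catalog, small_alignments):
        catalog, _ = small_catalog
        reads, candidates = small_alignments
        lengths = pd.Series({r.transcript_id: r.length for r in catalog})
        matrix = build_expression_matrix(reads, candidates, lengths)
        kept = filter_reads(reads)
        for stage in matrix.stages:
            ids = kept.loc[kept["stage"] == stage, "read_id"]
            accepted = filter_alignments(
                candidates.loc[candidates["read_id"].isin(ids)], ids
            )
            n_counted = accepted["read_id"].nunique()
            assert matrix.total_mapped[stage] == pytest.approx(
                n_counted, rel=1e-6
            )

    def test_rpkm_recovers_planted_expression_ranks(self, small_catalog):
        from vitiseq import generate_alignments

        catalog, truth = small_catalog
        # deeper sequencing than the shared fixture so sampling noise does
        # not dominate the rank comparison
        reads, candidates = generate_alignments(
            truth, catalog, reads_per_stage=40_000, multimap_rate=0.15,
            qc_fail_rate=0.05, seed=21,
        )
        lengths = pd.Series({r.transcript_id: r.length for r in catalog})
        matrix = build_expression_matrix(reads, candidates, lengths)
        from scipy.stats import spearmanr

        # strongly expressed transcripts should rank like the planted truth
        top = truth.true_rpkm["EL31"].nlargest(150).index
        rho = spearmanr(
            matrix.rpkm.loc[top, "EL31"], truth.true_rpkm.loc[top, "EL31"]
        ).statistic
        assert rho > 0.9
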