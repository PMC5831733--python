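"""Filtering, RPKM, peak normalization, internal standard, annotation."""

import numpy as np
import pandas as pd
import pytest

from echinodev import (
    AnnotationTables,
    CountMatrix,
    EchinodevError,
    SimulationConfig,
    TimeCourseMatrix,
    compute_rpkm,
    filter_low_count,
    normalize_by_standard,
    peak_normalize,
    propagate_annotation,
    select_internal_standard,
    simulate_timecourse,
)


class TestFilterLowCount:
    def test_strict_less_than_boundary(self, small_counts):
        kept = filter_low_count(small_counts, min_reads=10)
        assert list(kept.ec_ids) == ["EC_b", "EC_c"]  # total 9 removed, 10 kept

    def test_all_zero_matrix_empties(self, small_counts):
        zero = CountMatrix(
            counts=small_counts.counts * 0, sample_meta=small_counts.sample_meta
        )
        assert len(filter_low_count(zero).ec_ids) == 0

    def test_idempotent(self, small_counts):
        once = filter_low_count(small_counts)
        twice = filter_low_count(once)
        pd.testing.assert_frame_equal(once.counts, twice.counts)

    def test_excluded_samples_ignored_in_totals(self, small_counts):
        meta = small_counts.sample_meta.copy()
        meta.loc["S9hpf", "included"] = False
        cm = CountMatrix(counts=small_counts.counts, sample_meta=meta)
        # EC_b loses 3 reads -> total 7 -> removed as well
        kept = filter_low_count(cm, min_reads=10)
        assert list(kept.ec_ids) == ["EC_c"]

    def test_planted_subthreshold_removed(self):
        cfg = SimulationConfig(n_genes=100, n_standard=10, n_lowcount=12, seed=21)
        cm, _, _, _ = simulate_timecourse(cfg)
        assert len(filter_low_count(cm).ec_ids) == 88


class TestRpkm:
    def test_direct_formula(self):
        counts = pd.DataFrame({"S1": [10, 0]}, index=pd.Index(["a", "b"], name="ec"))
        # library: 10^6 reads total (pad with a dummy high-count gene)
        counts.loc["pad"] = 10**6 - 10
        meta = pd.DataFrame({"hpf": [9.0], "included": [True]}, index=pd.Index(["S1"], name="sample"))
        cm = CountMatrix(counts=counts, sample_meta=meta)
        t = compute_rpkm(cm, {"a": 1000, "b": 500, "pad": 1000})
        assert t.values.loc["a", 9.0] == pytest.approx(10.0)
        assert t.values.loc["b", 9.0] == 0.0

    def test_matches_bruteforce_recomputation(self, small_counts):
        lengths = {"EC_a": 700, "EC_b": 1500, "EC_c": 2100}
        t = compute_rpkm(small_counts, lengths)
        for ec in small_counts.ec_ids:
            for sample, hpf in small_counts.sample_meta["hpf"].items():
                lib = small_counts.counts[sample].sum()
                expected = small_counts.counts.loc[ec, sample] * 1e9 / (lengths[ec] * lib)
                assert t.values.loc[ec, float(hpf)] == pytest.approx(expected)

    def test_missing_length_names_ec(self, small_counts):
        with pytest.raises(EchinodevError, match="EC_c"):
            compute_rpkm(small_counts, {"EC_a": 100, "EC_b": 100})


class TestPeakNormalize:
    def test_divides_by_row_max(self, toy_timecourse):
        pn = peak_normalize(toy_timecourse)
        assert pn.unit == "peak_normalized"
        assert list(pn.values.loc["EC_peak"]) == [0.25, 0.5, 1.0, 0.5]
        assert (pn.values.loc["EC_flat"] == 1.0).all()
        assert (pn.values.max(axis=1) == 1.0).all()

    def test_idempotent(self, toy_timecourse):
        once = peak_normalize(toy_timecourse)
        twice = peak_normalize(once)
        pd.testing.assert_frame_equal(once.values, twice.values)

    def test_all_zero_row_rejected(self, toy_timecourse):
        vals = toy_timecourse.values.copy()
        vals.loc["EC_zero"] = 0.0
        with pytest.raises(EchinodevError, match="EC_zero"):
            peak_normalize(TimeCourseMatrix(values=vals, unit="rpkm"))


class TestInternalStandard:
    def test_sample_sd_selection(self, toy_timecourse):
        pn = peak_normalize(toy_timecourse)
        chosen = select_internal_standard(pn, sd_threshold=0.01)
        # flat row: SD 0; wobble row (1, .99, 1, 1): sample SD = 0.005
        assert chosen == {"EC_flat", "EC_wobble"}
        assert np.std([1, 0.99, 1, 1], ddof=1) == pytest.approx(0.005)

    def test_shaped_row_excluded(self):
        row = np.array([0.25, 0.5, 1.0, 0.5])
        assert np.std(row, ddof=1) == pytest.approx(0.3146, abs=1e-4)

    def test_requires_peak_normalized_unit(self, toy_timecourse):
        with pytest.raises(EchinodevError, match="peak-normalized"):
            select_internal_standard(toy_timecourse)

    def test_empty_selection_is_error(self, toy_timecourse):
        pn = peak_normalize(toy_timecourse)
        with pytest.raises(EchinodevError, match="threshold"):
            select_internal_standard(pn, sd_threshold=0.0)

    def test_planted_standard_recall(self):
        """Recall of 50 planted near-constant genes at threshold 0.01 over many seeds."""
        recalls = []
        for seed in range(20):
            cfg = SimulationConfig(n_genes=2000, n_standard=50, standard_noise_sd=0.002,
                                   noise_sd=0.1, seed=seed)
            _, tc, _, std = simulate_timecourse(cfg)
            chosen = select_internal_standard(peak_normalize(tc))
            recalls.append(len(chosen & std) / len(std))
        assert np.mean(recalls) >= 0.98


class TestNormalizeByStandard:
    def test_single_standard_arithmetic(self):
        vals = pd.DataFrame(
            {9.0: [2.0, 4.0], 18.0: [2.0, 8.0]},
            index=pd.Index(["std", "x"], name="ec"),
        )
        t = TimeCourseMatrix(values=vals, unit="rpkm")
        result = normalize_by_standard(t, {"std"})
        assert result.matrix.values.loc["x", 9.0] == pytest.approx(2e6)
        assert result.matrix.values.loc["x", 18.0] == pytest.approx(4e6)

    def test_standard_mean_equals_scale(self, toy_timecourse):
        result = normalize_by_standard(toy_timecourse, {"EC_flat", "EC_wobble"})
        means = result.matrix.values.loc[["EC_flat", "EC_wobble"]].mean(axis=0)
        assert np.allclose(means, 1e6, rtol=1e-9)

    def test_preserves_within_timepoint_ratios(self, toy_timecourse):
        result = normalize_by_standard(toy_timecourse, {"EC_flat"})
        before = toy_timecourse.values
        after = result.matrix.values
        for t in before.columns:
            r_before = before.loc["EC_peak", t] / before.loc["EC_wobble", t]
            r_after = after.loc["EC_peak", t] / after.loc["EC_wobble", t]
            assert r_after == pytest.approx(r_before)

    def test_empty_standard_rejected(self, toy_timecourse):
        with pytest.raises(EchinodevError, match="empty"):
            normalize_by_standard(toy_timecourse, set())


class TestAnnotationPropagation:
    @pytest.mark.parametrize(
        "annotations, expected",
        [
            # a single ortholog outweighs more frequent homologs
            ({"c1": ("A", "homolog"), "c2": ("A", "homolog"), "c3": ("B", "ortholog")},
             ("B", "ortholog", False)),
            # plurality among homologs
            ({"c1": ("A", "homolog"), "c2": ("A", "homolog"), "c3": ("B", "homolog")},
             ("A", "homolog", False)),
            # tie breaks lexicographically and flags ambiguity
            ({"c1": ("A", "ortholog"), "c2": ("B", "ortholog")},
             ("A", "ortholog", True)),
        ],
    )
    def test_priority_and_tiebreak(self, annotations, expected):
        tables = AnnotationTables(
            ec_members={"EC1": sorted(annotations)}, contig_annotation=annotations
        )
        out = propagate_annotation(tables)
        row = out.loc["EC1"]
        assert (row["annotation"], row["tier"], bool(row["ambiguous"])) == expected

    def test_unannotated_contig_is_none_tier(self):
        tables = AnnotationTables(ec_members={"EC1": ["c1"]}, contig_annotation={})
        out = propagate_annotation(tables)
        assert out.loc["EC1", "tier"] == "none"
        assert out.loc["EC1", "annotation"] is None

    def test_contig_in_two_ecs_rejected(self):
        with pytest.raises(EchinodevError, match="more than one EC"):
            AnnotationTables(
                ec_members={"EC1": ["c1"], "EC2": ["c1"]},
                contig_annotation={"c1": ("A", "homolog")},
            )
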