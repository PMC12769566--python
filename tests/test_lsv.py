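"""TPM normalisation, ratio tracks, sliding windows, LSV calling, proximity
classes and Tukey-fence outliers."""

import numpy as np
import pandas as pd
import pytest

import tetralog as tl
from tetralog.lsv import RatioTrack


def _genes(n, chrom="Chr1A", length=2000, gap=1000):
    starts = np.arange(n) * (length + gap)
    return pd.DataFrame({
        "gene_id": [f"g{i}" for i in range(n)], "chromosome": chrom,
        "start": starts, "end": starts + length, "strand": "+",
        "order_index": np.arange(n), "length": length})


class TestTpmNormalize:
    def test_equal_counts_equal_lengths(self):
        counts = pd.DataFrame({"s1": [7] * 10}, index=[f"g{i}" for i in range(10)])
        lengths = pd.Series(1000, index=counts.index)
        tpm = tl.tpm_normalize(counts, lengths)
        assert np.allclose(tpm["s1"], 1e5)

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame({"s1": rng.integers(1, 100, 20)},
                              index=[f"g{i}" for i in range(20)])
        lengths = pd.Series(rng.integers(500, 5000, 20), index=counts.index)
        a = tl.tpm_normalize(counts, lengths)
        b = tl.tpm_normalize(counts * 2, lengths)
        assert np.allclose(a, b)

    def test_length_normalisation(self):
        counts = pd.DataFrame({"s1": [10, 10]}, index=["long", "short"])
        lengths = pd.Series([2000, 1000], index=counts.index)
        tpm = tl.tpm_normalize(counts, lengths)
        assert tpm.loc["long", "s1"] == pytest.approx(tpm.loc["short", "s1"] / 2)

    def test_columns_sum_to_1e6(self):
        rng = np.random.default_rng(1)
        counts = pd.DataFrame(rng.integers(0, 50, (30, 4)),
                              index=[f"g{i}" for i in range(30)],
                              columns=list("abcd"))
        lengths = pd.Series(rng.integers(300, 3000, 30), index=counts.index)
        tpm = tl.tpm_normalize(counts, lengths)
        assert np.allclose(tpm.sum(axis=0), 1e6, rtol=1e-6)

    def test_all_zero_column_names_accession(self):
        counts = pd.DataFrame({"ok": [1, 2], "empty": [0, 0]}, index=["g0", "g1"])
        lengths = pd.Series([1000, 1000], index=counts.index)
        with pytest.raises(ValueError, match="empty"):
            tl.tpm_normalize(counts, lengths)


class TestCoverageRatio:
    def test_reference_track_is_one_and_low_ref_masked(self):
        genes = _genes(5)
        tpm = pd.DataFrame({"JK-8": [100.0, 100, 0.0, 100, 100],
                            "acc": [100.0, 50, 80, 100, 100]},
                           index=genes["gene_id"])
        tracks = tl.coverage_ratio(tpm, genes, "JK-8")
        ref = next(t for t in tracks if t.accession == "JK-8")
        acc = next(t for t in tracks if t.accession == "acc")
        assert np.allclose(ref.ratio[~ref.masked], 1.0)
        assert acc.masked[2] and np.isnan(acc.ratio[2])
        assert acc.ratio[1] == pytest.approx(0.5)

    def test_missing_reference_rejected(self):
        genes = _genes(3)
        tpm = pd.DataFrame({"a": [1.0, 2, 3]}, index=genes["gene_id"])
        with pytest.raises(KeyError):
            tl.coverage_ratio(tpm, genes, "JK-8")


def _track(values, masked=None):
    n = len(values)
    genes = _genes(n)
    masked = np.zeros(n, bool) if masked is None else np.asarray(masked)
    return RatioTrack("acc", "Chr1A", genes["gene_id"].to_numpy(),
                      np.arange(n), genes["start"].to_numpy(),
                      genes["end"].to_numpy(),
                      np.where(masked, np.nan, np.asarray(values, float)), masked)


class TestSmooth:
    def test_constant_track(self):
        wt = tl.smooth(_track([1.0] * 40))
        assert np.allclose(wt.mean_ratio, 1.0)

    def test_window_count_100_genes(self):
        wt = tl.smooth(_track([1.0] * 100), window=20, step=5)
        assert len(wt) == (100 - 20) // 5 + 1 == 17

    def test_single_zero_in_window(self):
        values = [1.0] * 20
        values[10] = 0.0
        wt = tl.smooth(_track(values), window=20, step=5)
        assert wt.mean_ratio[0] == pytest.approx(0.95)

    def test_masked_genes_never_contribute(self):
        values = [1.0] * 25
        masked = np.zeros(25, bool)
        masked[[3, 7]] = True
        values[3] = values[7] = 1e9  # would wreck the mean if included
        wt = tl.smooth(_track(values, masked), window=20, step=5)
        assert np.allclose(wt.mean_ratio, 1.0)
        assert len(wt) == 1  # only 23 unmasked slots

    def test_too_few_unmasked_genes_warns_empty(self):
        with pytest.warns(UserWarning):
            wt = tl.smooth(_track([1.0] * 10), window=20)
        assert len(wt) == 0


class TestCallLsvs:
    def test_flat_tracks_no_calls(self):
        wt = tl.smooth(_track([1.0] * 100))
        assert tl.call_lsvs([wt], reference="JK-8") == []

    def test_contradictory_thresholds_rejected(self):
        wt = tl.smooth(_track([1.0] * 100))
        with pytest.raises(ValueError):
            tl.call_lsvs([wt], "JK-8", del_threshold=1.7, dup_threshold=1.6)

    def test_reference_never_called(self):
        values = [1.0] * 100
        values[40:70] = [0.0] * 30
        track = _track(values)
        track.accession = "JK-8"
        wt = tl.smooth(track)
        assert tl.call_lsvs([wt], reference="JK-8") == []

    def test_hom_del_call_contains_planted_span(self):
        values = [1.0] * 100
        values[40:70] = [0.0] * 30
        calls = tl.call_lsvs([tl.smooth(_track(values))], "JK-8")
        assert len(calls) == 1
        call = calls[0]
        assert call.kind == "DEL"
        assert call.first_gene_order <= 40 and call.last_gene_order >= 69
        assert call.carriers == ["acc"]
        assert call.span_bp > 40_000

    def test_identical_coordinates_merge_carriers(self):
        values = [1.0] * 100
        values[40:70] = [0.0] * 30
        t1, t2 = _track(values), _track(values)
        t2.accession = "acc2"
        calls = tl.call_lsvs([tl.smooth(t1), tl.smooth(t2)], "JK-8")
        assert len(calls) == 1
        assert sorted(calls[0].carriers) == ["acc", "acc2"]

    def test_short_span_discarded_by_size_rule(self):
        # 20 deleted genes over ~25 kb: the window rule fires but the event
        # span is below the 40 kb floor
        n = 100
        starts = np.arange(n) * 1250
        genes = pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(n)], "chromosome": "Chr1A",
            "start": starts, "end": starts + 800, "strand": "+",
            "order_index": np.arange(n), "length": 800})
        values = np.ones(n)
        values[40:60] = 0.0
        track = RatioTrack("acc", "Chr1A", genes["gene_id"].to_numpy(),
                           np.arange(n), genes["start"].to_numpy(),
                           genes["end"].to_numpy(), values, np.zeros(n, bool))
        wt = tl.smooth(track)
        assert tl.call_lsvs([wt], "JK-8") == []
        rescued = tl.call_lsvs([wt], "JK-8", min_span_bp=20_000)
        assert len(rescued) == 1 and rescued[0].kind == "DEL"


class TestProximity:
    def test_classes(self):
        genes = _genes(3, length=2000, gap=10_000)  # genes at 0, 12000, 24000
        svs = pd.DataFrame({
            "chromosome": ["Chr1A"] * 4,
            "start": [500, 2500, 4500, 8000],
            "end": [800, 2600, 4600, 8100]})
        classes = tl.annotate_proximity(svs, genes)
        assert list(classes) == ["genic", "within_1kb", "within_3kb", "intergenic"]

    def test_one_bp_overlap_is_genic(self):
        genes = _genes(1)
        sv = pd.DataFrame({"chromosome": ["Chr1A"], "start": [1999], "end": [2500]})
        assert tl.annotate_proximity(sv, genes).item() == "genic"


class TestIqrOutliers:
    def test_hand_computed_fences_21_values(self):
        # accessions 1..20 plus a carrier at 100: linear-interpolation
        # quartiles over all 21 values give Q1=6, Q3=16, fences (-9, 31)
        values = list(range(1, 21)) + [100]
        pheno = pd.DataFrame({
            "accession": [f"a{i}" for i in range(21)],
            "dataset": "pooled", "trait": values})
        report = tl.iqr_outliers(pheno, carriers={"a20": ["lsv"]})
        assert len(report) == 1
        row = report.iloc[0]
        assert row["lower_fence"] == pytest.approx(-9.0)
        assert row["upper_fence"] == pytest.approx(31.0)
        assert row["direction"] == "high" and row["accession"] == "a20"

    def test_constant_trait_no_flags(self):
        pheno = pd.DataFrame({"accession": [f"a{i}" for i in range(10)],
                              "dataset": "pooled", "trait": 5.0})
        assert tl.iqr_outliers(pheno).empty

    def test_fence_value_not_flagged_strictly_outside_required(self):
        values = np.array([1.0, 2, 3, 4, 5, 6, 7, 8])
        lower, upper = tl.tukey_fences(values)
        pheno = pd.DataFrame({"accession": [f"a{i}" for i in range(9)],
                              "dataset": "d",
                              "trait": list(values) + [upper]})
        report = tl.iqr_outliers(pheno, min_values=4)
        assert (report["value"] > report["upper_fence"]).all() if len(report) else True

    def test_null_flag_rate_near_nominal(self):
        # under a normal trait the 1.5 IQR rule flags ~0.7% of values
        rng = np.random.default_rng(0)
        pheno = pd.DataFrame({"accession": [f"a{i}" for i in range(20_000)],
                              "dataset": "pooled",
                              "trait": rng.normal(size=20_000)})
        rate = len(tl.iqr_outliers(pheno)) / 20_000
        assert 0.003 < rate < 0.012

    def test_too_few_values_skipped_with_warning(self):
        pheno = pd.DataFrame({"accession": ["a", "b"], "dataset": "d",
                              "trait": [1.0, 2.0]})
        with pytest.warns(UserWarning):
            assert tl.iqr_outliers(pheno).empty


def test_calls_invariant_to_single_sample_rescaling(small_dataset):
    """TPM invariance: multiplying one accession's raw counts by a constant
    does not change the LSV calls."""
    data = small_dataset
    calls = tl.lsv_pipeline(data.counts, data.annotation, "JK-8")
    scaled = data.counts.copy()
    scaled["LM-007"] = scaled["LM-007"] * 3
    calls2 = tl.lsv_pipeline(scaled, data.annotation, "JK-8")
    assert tl.lsv_table(calls).equals(tl.lsv_table(calls2))
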