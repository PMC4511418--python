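import numpy as np
import pandas as pd
import pytest

from seedfx.profiles import (
    FeatureMask,
    MAD_SCALE,
    aggregate_sequences,
    aggregate_wells,
    build_feature_mask,
    compute_norm_stats,
    fit_pca,
    normalize,
    project,
)


def make_cells(rows, features):
    """rows: list of (plate, well, cell, values...)."""
    cols = ["Plate", "Well", "Cell"] + features
    return pd.DataFrame(rows, columns=cols)


def make_meta(wells):
    """wells: list of (plate, well, untreated, treatment_id)."""
    return pd.DataFrame(
        [(p, w, 1, t, "" if u else "GENE01", "" if u else "A" * 21,
          "" if u else "AAAAAA", 0 if u else 1, u, False)
         for p, w, u, t in wells],
        columns=["Plate", "Well", "Layout", "TreatmentID", "Gene", "Sequence",
                 "Seed", "ReplicateIndex", "IsUntreated", "IsControl"],
    )


class TestNormalizationStats:
    def test_hand_computed_median_and_mad(self):
        """Untreated values {1..5}: median 3, raw MAD of |x-3| is 1."""
        cells = make_cells(
            [("p1", "A01", i, float(v)) for i, v in enumerate([1, 2, 3, 4, 5])],
            ["f1"],
        )
        meta = make_meta([("p1", "A01", True, "UNTREATED")])
        stats = compute_norm_stats(cells, meta)
        assert stats.median.loc["p1", "f1"] == 3.0
        assert stats.mad.loc["p1", "f1"] == 1.0

    def test_constant_feature_has_zero_mad(self):
        cells = make_cells([("p1", "A01", i, 7.0, float(i)) for i in range(4)],
                           ["f1", "f2"])
        meta = make_meta([("p1", "A01", True, "UNTREATED")])
        stats = compute_norm_stats(cells, meta)
        assert stats.mad.loc["p1", "f1"] == 0.0
        assert stats.mad.loc["p1", "f2"] > 0.0

    def test_per_plate_stats_differ(self):
        cells = make_cells(
            [("p1", "A01", i, float(i)) for i in range(5)]
            + [("p2", "A01", i, 10.0 * i) for i in range(5)],
            ["f1"],
        )
        meta = make_meta([("p1", "A01", True, "UNTREATED"),
                          ("p2", "A01", True, "UNTREATED")])
        stats = compute_norm_stats(cells, meta)
        assert stats.median.loc["p1", "f1"] != stats.median.loc["p2", "f1"]
        assert stats.mad.loc["p1", "f1"] != stats.mad.loc["p2", "f1"]

    def test_plate_without_untreated_fails_naming_plate(self):
        cells = make_cells([("p1", "A01", 0, 1.0), ("p2", "B01", 0, 1.0)], ["f1"])
        meta = make_meta([("p1", "A01", True, "UNTREATED"),
                         ("p2", "B01", False, "sh0001")])
        with pytest.raises(ValueError, match="p2"):
            compute_norm_stats(cells, meta)


class TestNormalize:
    def _stats(self):
        cells = make_cells(
            [("p1", "A01", i, float(v)) for i, v in enumerate([1, 2, 3, 4, 5])],
            ["f1"],
        )
        meta = make_meta([("p1", "A01", True, "UNTREATED")])
        return compute_norm_stats(cells, meta)

    def test_printed_constant_arithmetic(self):
        """(5 - 3) / (1 * 1.4826) with the normal-consistency constant."""
        stats = self._stats()
        cells = make_cells([("p1", "B01", 0, 5.0)], ["f1"])
        out = normalize(cells, stats)
        assert out["f1"].iloc[0] == pytest.approx(2.0 / 1.4826)
        assert out["f1"].iloc[0] == pytest.approx(1.3490, abs=5e-5)

    def test_value_at_median_maps_to_zero(self):
        stats = self._stats()
        cells = make_cells([("p1", "B01", 0, 3.0)], ["f1"])
        assert normalize(cells, stats)["f1"].iloc[0] == 0.0

    def test_untreated_median_zero_and_mad_one_after_normalization(self, small_bundle):
        """Per plate, normalized untreated cells have median 0 and scaled MAD 1."""
        cells, meta = small_bundle["cells"], small_bundle["metadata"]
        stats = small_bundle["stats"]
        normed = normalize(cells, stats)
        untr = meta[meta.IsUntreated][["Plate", "Well"]]
        key = pd.MultiIndex.from_frame(untr)
        sel = pd.MultiIndex.from_frame(normed[["Plate", "Well"]]).isin(key)
        for plate, sub in normed[sel].groupby("Plate"):
            values = sub.drop(columns=["Plate", "Well", "Cell"]).to_numpy()
            med = np.median(values, axis=0)
            scaled_mad = np.median(np.abs(values - med), axis=0) * MAD_SCALE
            np.testing.assert_allclose(med, 0.0, atol=1e-12)
            np.testing.assert_allclose(scaled_mad, 1.0, rtol=1e-9)

    def test_zero_mad_feature_left_untouched(self):
        cells = make_cells([("p1", "A01", i, 7.0, float(i)) for i in range(4)],
                           ["f1", "f2"])
        meta = make_meta([("p1", "A01", True, "UNTREATED")])
        stats = compute_norm_stats(cells, meta)
        out = normalize(cells, stats)
        assert (out["f1"] == 7.0).all()

    def test_unknown_plate_fails(self):
        stats = self._stats()
        cells = make_cells([("pX", "B01", 0, 5.0)], ["f1"])
        with pytest.raises(ValueError, match="pX"):
            normalize(cells, stats)


class TestFeatureMask:
    def test_feature_degenerate_on_one_plate_is_excluded(self):
        """MAD = 0 on any single plate excludes the feature everywhere."""
        cells = make_cells(
            [("p1", "A01", i, float(i), float(i)) for i in range(4)]
            + [("p2", "A01", i, 5.0, float(i)) for i in range(4)],
            ["f1", "f2"],
        )
        meta = make_meta([("p1", "A01", True, "UNTREATED"),
                          ("p2", "A01", True, "UNTREATED")])
        mask = build_feature_mask(compute_norm_stats(cells, meta))
        assert mask.retained_features == ["f2"]
        assert mask.n_retained == 1

    def test_all_nondegenerate_all_retained(self, small_bundle):
        mask = small_bundle["mask"]
        assert mask.n_retained == len(mask.features)


class TestAggregateWells:
    def test_median_is_outlier_robust(self):
        cells = make_cells([("p1", "A01", 0, 0.0), ("p1", "A01", 1, 1.0),
                            ("p1", "A01", 2, 100.0)], ["f1"])
        meta = make_meta([("p1", "A01", False, "sh0001")])
        mask = FeatureMask(features=("f1",), retained=(True,))
        wp = aggregate_wells(cells, mask, meta)
        assert wp["f1"].iloc[0] == 1.0

    def test_cell_order_irrelevant(self, small_bundle):
        cells, meta = small_bundle["cells"], small_bundle["metadata"]
        mask = small_bundle["mask"]
        shuffled = cells.sample(frac=1.0, random_state=0).reset_index(drop=True)
        a = aggregate_wells(cells, mask, meta)
        b = aggregate_wells(shuffled, mask, meta)
        pd.testing.assert_frame_equal(a, b)

    def test_excluded_wells_are_dropped(self):
        cells = make_cells([("p1", "A01", 0, 1.0), ("p1", "B01", 0, 2.0)], ["f1"])
        meta = make_meta([("p1", "A01", False, "sh0001"),
                          ("p1", "B01", False, "sh0002")])
        excl = pd.DataFrame({"Plate": ["p1"], "Well": ["A01"], "Reason": ["blurry"]})
        mask = FeatureMask(features=("f1",), retained=(True,))
        wp = aggregate_wells(cells, mask, meta, excluded_wells=excl)
        assert list(wp["Well"]) == ["B01"]


class TestPca:
    def test_noiseless_rank2_retains_two_components(self):
        rng = np.random.default_rng(0)
        basis = rng.normal(size=(2, 6))
        scores = rng.normal(size=(30, 2))
        X = scores @ basis
        wp = pd.DataFrame(X, columns=[f"f{i}" for i in range(6)])
        wp.insert(0, "Well", [f"W{i:02d}" for i in range(30)])
        wp.insert(0, "Plate", "p1")
        model = fit_pca(wp, variance_threshold=0.99)
        assert model.k == 2

    def test_full_rank_at_threshold_one(self):
        """Brute-force check on a 5x4 instance: k = min(n-1, F) = 4."""
        rng = np.random.default_rng(1)
        X = rng.normal(size=(5, 4))
        wp = pd.DataFrame(X, columns=list("abcd"))
        wp.insert(0, "Well", [f"W{i}" for i in range(5)])
        wp.insert(0, "Plate", "p1")
        model = fit_pca(wp, variance_threshold=1.0)
        assert model.k == 4
        # oracle: eigendecomposition of the sample covariance
        eig = np.linalg.eigvalsh(np.cov(X.T))[::-1]
        np.testing.assert_allclose(
            model.explained_variance_ratio[:4], eig[:4] / eig.sum(), atol=1e-12
        )

    def test_variance_fractions_sum_to_one_and_k_is_minimal(self, small_bundle):
        model = small_bundle["pca_model"]
        ratios = model.explained_variance_ratio
        assert abs(ratios.sum() - 1.0) < 1e-9
        assert np.all(np.diff(ratios) <= 1e-12)
        cum = np.cumsum(ratios)
        assert cum[model.k - 1] >= model.variance_threshold - 1e-12
        if model.k > 1:
            assert cum[model.k - 2] < model.variance_threshold

    def test_projection_centering_and_reconstruction(self):
        rng = np.random.default_rng(2)
        basis = rng.normal(size=(3, 8))
        X = rng.normal(size=(40, 3)) @ basis
        wp = pd.DataFrame(X, columns=[f"f{i}" for i in range(8)])
        wp.insert(0, "Well", [f"W{i:02d}" for i in range(40)])
        wp.insert(0, "Plate", "p1")
        model = fit_pca(wp, variance_threshold=0.999)
        proj = project(wp, model)
        # the mean profile projects to the origin
        mean_row = wp.iloc[:1].copy()
        mean_row[wp.columns[2:]] = X.mean(axis=0)
        np.testing.assert_allclose(
            project(mean_row, model).iloc[0, 2:].to_numpy(float), 0.0, atol=1e-9
        )
        # back-projection reproduces rank-k data
        scores = proj.iloc[:, 2:].to_numpy(float)
        recon = scores @ model.components[: model.k] + model.mean
        np.testing.assert_allclose(recon, X, atol=1e-8)

    def test_feature_mismatch_rejected(self):
        rng = np.random.default_rng(3)
        wp = pd.DataFrame(rng.normal(size=(5, 3)), columns=list("abc"))
        wp.insert(0, "Well", list("VWXYZ"))
        wp.insert(0, "Plate", "p1")
        model = fit_pca(wp, variance_threshold=0.9)
        other = wp.rename(columns={"c": "d"})
        with pytest.raises(ValueError):
            project(other, model)

    def test_too_few_profiles_rejected(self):
        wp = pd.DataFrame({"Plate": ["p1"], "Well": ["A01"], "f1": [1.0]})
        with pytest.raises(ValueError):
            fit_pca(wp)


class TestAggregateSequences:
    def _projected(self, rows):
        df = pd.DataFrame(rows, columns=["Plate", "Well", "PC_001", "PC_002"])
        return df

    def test_coordinatewise_median_by_hand(self):
        """Replicates (0,0), (2,2), (10,-4) -> (2, 0)."""
        proj = self._projected([("p1", "A01", 0.0, 0.0), ("p1", "B01", 2.0, 2.0),
                                ("p1", "C01", 10.0, -4.0)])
        meta = make_meta([("p1", "A01", False, "sh1"), ("p1", "B01", False, "sh1"),
                          ("p1", "C01", False, "sh1")])
        seq = aggregate_sequences(proj, meta)
        assert seq.loc[0, "PC_001"] == 2.0
        assert seq.loc[0, "PC_002"] == 0.0

    def test_identical_replicates_pass_through(self):
        proj = self._projected([("p1", "A01", 1.5, -2.0), ("p1", "B01", 1.5, -2.0)])
        meta = make_meta([("p1", "A01", False, "sh1"), ("p1", "B01", False, "sh1")])
        seq = aggregate_sequences(proj, meta)
        assert list(seq.loc[0, ["PC_001", "PC_002"]]) == [1.5, -2.0]

    def test_single_replicate_is_its_own_profile(self):
        proj = self._projected([("p1", "A01", 3.0, 4.0)])
        meta = make_meta([("p1", "A01", False, "sh1")])
        seq = aggregate_sequences(proj, meta)
        assert list(seq.loc[0, ["PC_001", "PC_002"]]) == [3.0, 4.0]

    def test_untreated_wells_never_aggregated(self, small_bundle):
        seq = small_bundle["sequence_profiles"]
        assert "UNTREATED" not in set(seq["TreatmentID"])


class TestPipelineOracle:
    def test_full_pipeline_matches_brute_force(self):
        """6-cell, 4-feature fixture: normalize + median + PCA vs a from-
        scratch reimplementation with sorting-based medians and an
        eigendecomposition of the covariance."""
        cells = make_cells(
            [
                ("p1", "A01", 0, 1.0, 10.0, 5.0, 0.0),
                ("p1", "A01", 1, 2.0, 20.0, 5.0, 1.0),
                ("p1", "A01", 2, 3.0, 30.0, 5.0, 4.0),
                ("p1", "B01", 0, 4.0, 10.0, 6.0, 9.0),
                ("p1", "B01", 1, 6.0, 50.0, 7.0, 16.0),
                ("p1", "C01", 0, 0.0, 25.0, 5.5, 25.0),
            ],
            ["f1", "f2", "f3", "f4"],
        )
        meta = make_meta([("p1", "A01", True, "UNTREATED"),
                          ("p1", "B01", False, "sh1"),
                          ("p1", "C01", False, "sh2")])

        def sort_median(v):
            s = sorted(v)
            n = len(s)
            return s[n // 2] if n % 2 else 0.5 * (s[n // 2 - 1] + s[n // 2])

        # brute-force normalization from the untreated well A01
        untr = cells[cells.Well == "A01"]
        feats = ["f1", "f2", "f3", "f4"]
        med = {f: sort_median(untr[f]) for f in feats}
        mad = {f: sort_median([abs(x - med[f]) for x in untr[f]]) for f in feats}
        kept = [f for f in feats if mad[f] > 0]
        assert kept == ["f1", "f2", "f4"]  # f3 constant in untreated cells

        expected = {}
        for well in ("A01", "B01", "C01"):
            sub = cells[cells.Well == well]
            expected[well] = [
                sort_median([(x - med[f]) / (mad[f] * 1.4826) for x in sub[f]])
                for f in kept
            ]

        stats = compute_norm_stats(cells, meta)
        normed = normalize(cells, stats)
        mask = build_feature_mask(stats)
        wp = aggregate_wells(normed, mask, meta)
        assert mask.retained_features == kept
        for well, exp in expected.items():
            got = wp[wp.Well == well][kept].iloc[0].tolist()
            np.testing.assert_allclose(got, exp, atol=1e-12)

        # brute-force PCA: eigendecomposition of the 3x3 sample covariance
        X = np.array([expected[w] for w in ("A01", "B01", "C01")])
        C = np.cov(X.T)
        evals = np.sort(np.linalg.eigvalsh(C))[::-1]
        evals = evals[evals > 1e-12]
        model = fit_pca(wp, variance_threshold=1.0)
        np.testing.assert_allclose(
            model.explained_variance_ratio[: len(evals)],
            evals / evals.sum(), atol=1e-10,
        )


class TestSequenceSpaceSwitch:
    def test_feature_space_aggregation_close_but_not_identical(self, small_bundle):
        """Median-then-project and project-then-median agree closely on
        well-behaved data but are distinct estimators."""
        from seedfx.pipeline import run_profiling

        prof = run_profiling(small_bundle["cells"], small_bundle["metadata"],
                             sequence_space="feature")
        a = small_bundle["sequence_profiles"].set_index("TreatmentID")
        b = prof["sequence_profiles"].set_index("TreatmentID")
        assert set(a.index) == set(b.index)
        corr = [np.corrcoef(a.loc[t].to_numpy(float), b.loc[t].to_numpy(float))[0, 1]
                for t in a.index]
        assert min(corr) > 0.9

    def test_unknown_space_rejected(self, small_bundle):
        from seedfx.pipeline import run_profiling

        with pytest.raises(ValueError):
            run_profiling(small_bundle["cells"], small_bundle["metadata"],
                          sequence_space="banana")
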