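import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import fcluster
from sklearn.metrics import adjusted_rand_score

from feaspath.phenome import (
    ConditionClusterer,
    GrowthClassifier,
    GrowthMetrics,
    aggregate_replicates,
    classify_growth,
    cluster_conditions,
    compute_metrics,
    condition_features,
    correlation_at_time,
)


class TestComputeMetrics:
    def test_flat_zero_curve(self):
        t = np.arange(0, 96.25, 0.25)
        m = compute_metrics(t, np.zeros_like(t))
        assert m.max_signal == 0 and m.auc == 0 and m.lag_time is None

    def test_step_curve_auc_matches_rectangle(self):
        t = np.arange(0, 96.25, 0.25)
        y = np.where(t >= 48, 100.0, 0.0)
        m = compute_metrics(t, y)
        assert m.auc == pytest.approx(4800.0, abs=100 * 0.25)
        assert m.max_signal == 100.0
        assert m.value_at_48h == 100.0
        assert m.lag_time == 48.0

    def test_value_at_48_interpolates(self):
        m = compute_metrics([0.0, 96.0], [0.0, 96.0])
        assert m.value_at_48h == pytest.approx(48.0)

    def test_unsorted_times_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics([0.0, 2.0, 1.0], [0.0, 1.0, 2.0])

    def test_glucose_well_beats_no_growth_thresholds(self, plate_fixture):
        plates, _ = plate_fixture
        clf = GrowthClassifier().fit(plates)
        glucose = clf.anchor_metrics_
        neg = clf.neg_metrics_["PM1"]
        assert glucose.max_signal - neg.max_signal > 50.0
        assert glucose.auc > neg.auc * 5


class TestAggregateReplicates:
    def test_identical_replicates_have_zero_dispersion(self):
        rows = []
        for rep in (1, 2):
            for t, y in [(0.0, 1.0), (1.0, 3.0)]:
                rows.append(("PM1", "A1", "c", rep, t, y))
        ps_rows = pd.DataFrame(
            rows, columns=["plate", "well", "condition", "replicate", "time_h", "omnilog_units"]
        )
        from feaspath.phenome import PlateSet

        ps = PlateSet(kinetics=ps_rows, plate_map=pd.DataFrame(
            [("PM1", "A1", "c", "test")], columns=["plate", "well", "condition", "role"]
        ))
        mean, sd = aggregate_replicates(ps)
        np.testing.assert_allclose(mean.to_numpy(), [[1.0, 3.0]])
        np.testing.assert_allclose(sd.to_numpy(), 0.0)

    def test_mean_of_offset_replicates(self):
        from feaspath.phenome import PlateSet

        rows = []
        for rep, off in ((1, 0.0), (2, 4.0)):
            for t in (0.0, 1.0):
                rows.append(("PM1", "A1", "c", rep, t, off))
        ps = PlateSet(
            kinetics=pd.DataFrame(
                rows,
                columns=["plate", "well", "condition", "replicate", "time_h", "omnilog_units"],
            ),
            plate_map=pd.DataFrame(
                [("PM1", "A1", "c", "test")], columns=["plate", "well", "condition", "role"]
            ),
        )
        mean, _ = aggregate_replicates(ps)
        np.testing.assert_allclose(mean.to_numpy(), [[2.0, 2.0]])

    def test_fixture_mean_tracks_generating_curve(self, plate_fixture):
        from feaspath.simulate.plates import CLASS_PARAMS

        plates, truth = plate_fixture
        mean, _ = aggregate_replicates(plates)
        times = mean.columns.to_numpy(dtype=float)
        # pick one high-class well and compare with the canonical logistic
        (plate, well), _cls = next(
            (k, c) for k, c in truth.growth_class_by_well.items() if c == "high"
        )
        cond = plates.plate_map.query("plate == @plate and well == @well")["condition"].iloc[0]
        curve = mean.loc[(plate, well, cond)].to_numpy()
        p = CLASS_PARAMS["high"]
        ideal = p["A"] / (1 + np.exp(-p["k"] * (times - p["t0"])))
        # jitter (A +/-5%, t0 +/-1.5 h) and replicate noise stay well under 25 OU rms
        assert np.sqrt(np.mean((curve - ideal) ** 2)) < 25.0


class TestClassifyGrowth:
    _neg = GrowthMetrics(max_signal=30.0, auc=700.0, value_at_48h=8.0, lag_time=None)
    _anchor = GrowthMetrics(max_signal=250.0, auc=19600.0, value_at_48h=247.0, lag_time=20.0)

    def test_negative_control_itself_is_none(self):
        assert classify_growth(self._neg, self._neg, self._anchor) == "none"

    def test_anchor_itself_is_high(self):
        assert classify_growth(self._anchor, self._neg, self._anchor) == "high"

    def test_intermediate_curve_is_moderate(self):
        mid = GrowthMetrics(max_signal=120.0, auc=8000.0, value_at_48h=100.0, lag_time=30.0)
        assert classify_growth(mid, self._neg, self._anchor) == "moderate"

    def test_monotone_in_curve_level(self):
        rank = {"none": 0, "moderate": 1, "high": 2}
        lo = GrowthMetrics(60.0, 3000.0, 40.0, 30.0)
        hi = GrowthMetrics(200.0, 15000.0, 180.0, 25.0)
        assert (
            rank[classify_growth(hi, self._neg, self._anchor)]
            >= rank[classify_growth(lo, self._neg, self._anchor)]
        )

    def test_fixture_class_counts_recovered(self, plate_fixture):
        plates, truth = plate_fixture
        calls = GrowthClassifier().fit_predict(plates)
        counts = calls["growth_class"].value_counts().to_dict()
        assert counts == {"high": 167, "moderate": 96, "none": 21}
        by_cond = calls.set_index("condition")["growth_class"]
        assert all(
            by_cond[c] == cls for c, cls in truth.growth_class_by_condition.items()
        )

    def test_one_class_per_condition_summing_to_wells(self, plate_fixture):
        plates, _ = plate_fixture
        calls = GrowthClassifier().fit_predict(plates)
        assert len(calls) == 284
        assert calls["condition"].is_unique


class TestCorrelationAtTime:
    def test_identical_replicates_give_one(self, plate_fixture):
        plates, _ = plate_fixture
        rep1 = plates.kinetics[plates.kinetics["replicate"] == 1]
        doubled = pd.concat(
            [rep1, rep1.assign(replicate=2)], ignore_index=True
        )
        from feaspath.phenome import PlateSet

        ps = PlateSet(kinetics=doubled, plate_map=plates.plate_map)
        assert correlation_at_time(ps, 48.0) == pytest.approx(1.0)

    def test_fixture_correlation_near_target(self, plate_fixture):
        plates, _ = plate_fixture
        assert 0.90 <= correlation_at_time(plates, 48.0) <= 0.96

    def test_shuffled_pairing_destroys_correlation(self, plate_fixture):
        from feaspath.phenome import PlateSet

        plates, _ = plate_fixture
        rng = np.random.default_rng(0)
        rep2 = plates.kinetics[plates.kinetics["replicate"] == 2].copy()
        wells = rep2[["plate", "well"]].drop_duplicates()
        perm = wells.sample(frac=1.0, random_state=1).reset_index(drop=True)
        mapping = {
            (a.plate, a.well): (b.plate, b.well)
            for a, b in zip(wells.itertuples(), perm.itertuples())
        }
        keys = list(zip(rep2["plate"], rep2["well"]))
        rep2[["plate", "well"]] = [mapping[k] for k in keys]
        # conditions must follow the plate map of the shuffled wells
        cond = plates.plate_map.set_index(["plate", "well"])["condition"]
        rep2["condition"] = [cond[k] for k in zip(rep2["plate"], rep2["well"])]
        shuffled = PlateSet(
            kinetics=pd.concat(
                [plates.kinetics[plates.kinetics["replicate"] == 1], rep2],
                ignore_index=True,
            ),
            plate_map=plates.plate_map,
        )
        assert abs(correlation_at_time(shuffled, 48.0)) < 0.35


class TestConditionClustering:
    def test_identical_profiles_merge_first(self):
        X = pd.DataFrame(
            [[0, 1, 2, 3], [0, 1, 2, 3], [3, 1, 0, 2]],
            index=["a", "b", "c"],
            dtype=float,
        )
        cl = ConditionClusterer(n_clusters=2).fit(X)
        # first merge joins the two identical rows at distance ~0
        assert cl.linkage_[0, 2] == pytest.approx(0.0, abs=1e-12)
        assert cl.labels_["a"] == cl.labels_["b"] != cl.labels_["c"]

    def test_four_point_linkage_matches_exhaustive_oracle(self):
        X = pd.DataFrame(
            [
                [0.0, 1.0, 2.0, 3.1],
                [0.0, 1.1, 1.9, 3.0],
                [5.0, 1.0, 4.0, 0.0],
                [5.1, 1.2, 4.0, 0.2],
            ],
            index=list("abcd"),
        )
        cl = ConditionClusterer(n_clusters=2).fit(X)
        # exhaustive average-linkage agglomeration on the 4x4 1-r matrix
        r = np.corrcoef(X.to_numpy())
        d = 1 - r
        clusters = {i: [i] for i in range(4)}
        merges = []
        next_id = 4
        while len(clusters) > 1:
            best = None
            for i in sorted(clusters):
                for j in sorted(clusters):
                    if i >= j:
                        continue
                    dij = np.mean([d[a, b] for a in clusters[i] for b in clusters[j]])
                    if best is None or dij < best[0]:
                        best = (dij, i, j)
            dij, i, j = best
            merges.append((min(i, j), max(i, j), dij))
            clusters[next_id] = clusters.pop(i) + clusters.pop(j)
            next_id += 1
        got = [
            (int(min(row[0], row[1])), int(max(row[0], row[1])), row[2])
            for row in cl.linkage_
        ]
        for (gi, gj, gd), (oi, oj, od) in zip(got, merges):
            assert (gi, gj) == (oi, oj)
            assert gd == pytest.approx(od)

    def test_pm1_clusters_recover_growth_classes(self, plate_fixture):
        plates, truth = plate_fixture
        features = condition_features(plates, plate="PM1")
        cl = cluster_conditions(features, k=3)
        want = [truth.growth_class_by_condition[c] for c in cl.labels_.index]
        assert adjusted_rand_score(want, cl.labels_) >= 0.9

    def test_distance_properties(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(6, 20))
        from scipy.spatial.distance import squareform, pdist

        D = squareform(pdist(X, metric="correlation"))
        np.testing.assert_allclose(D, D.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(D), 0.0, atol=1e-12)
        assert (D >= -1e-12).all() and (D <= 2 + 1e-12).all()

    def test_newick_leaves_match_conditions(self, plate_fixture):
        plates, _ = plate_fixture
        features = condition_features(plates, plate="PM5")
        cl = cluster_conditions(features, k=3)
        nwk = cl.to_newick()
        assert nwk.endswith(";\n") or nwk.endswith(";")
        for cond in features.index[:5]:
            assert cond.replace(" ", "_") in nwk or cond in nwk

    def test_constant_rows_dropped_with_warning(self):
        X = pd.DataFrame(
            [[1.0, 1.0, 1.0], [0.0, 1.0, 2.0], [2.0, 1.0, 0.0]],
            index=["flat", "up", "down"],
        )
        with pytest.warns(UserWarning, match="flat"):
            cl = ConditionClusterer(n_clusters=2).fit(X)
        assert list(cl.labels_.index) == ["up", "down"]
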