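import numpy as np
import pandas as pd
import pytest

from reeftrack.cluster import (
    ClusterResult,
    agglomerate,
    class_occupancy,
    cut_by_merger_score,
    fit_pca,
    label_classes,
    merge_classes,
    merger_score_classes,
)
from reeftrack.prep import DayWindow


class TestPca:
    def test_variance_fractions_complete_and_sorted(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, (200, 13))
        model, scores = fit_pca(x, k=4)
        assert model.variance_fractions.sum() == pytest.approx(1.0, abs=1e-12)
        assert (np.diff(model.variance_fractions) <= 1e-12).all()
        assert scores.shape == (200, 4)

    def test_planar_data_explained_by_two_components(self):
        rng = np.random.default_rng(1)
        basis = rng.normal(0, 1, (2, 13))
        x = rng.normal(0, 3, (300, 2)) @ basis + rng.normal(0, 1e-3, (300, 13))
        model, _ = fit_pca(x, k=4)
        assert model.variance_fractions[:2].sum() > 0.99

    def test_matches_covariance_eigendecomposition_oracle(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 2, (150, 13))
        model, _ = fit_pca(x, k=4)
        # brute-force oracle: eigh of the centered covariance matrix
        xc = x - x.mean(axis=0)
        w, v = np.linalg.eigh(np.cov(xc.T))
        w, v = w[::-1], v[:, ::-1]
        np.testing.assert_allclose(model.variance_fractions, w / w.sum(), atol=1e-9)
        for i in range(4):
            vec = v[:, i]
            if vec[np.argmax(np.abs(vec))] < 0:
                vec = -vec
            np.testing.assert_allclose(model.loadings[i], vec, atol=1e-9)

    def test_variance_target_selects_smallest_k(self):
        rng = np.random.default_rng(1)
        basis = rng.normal(0, 1, (2, 13))
        x = rng.normal(0, 3, (300, 2)) @ basis + rng.normal(0, 1e-3, (300, 13))
        model, _ = fit_pca(x, variance_target=0.95)
        assert model.k == 2

    def test_too_many_components_rejected(self):
        with pytest.raises(ValueError):
            fit_pca(np.zeros((10, 13)), k=14)


class TestLinkage:
    def test_two_points_merge_at_their_distance(self):
        z = agglomerate(np.array([[0.0, 0.0], [3.0, 4.0]]))
        assert z.shape == (1, 4)
        assert z[0, 2] == pytest.approx(5.0)

    def test_duplicates_merge_at_zero(self):
        pts = np.array([[1.0, 1.0], [1.0, 1.0], [5.0, 5.0]])
        z = agglomerate(pts)
        assert z[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_matches_naive_lance_williams_oracle(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, (20, 3))
        z = agglomerate(x, "ward")
        # naive O(n^3) Ward via the Lance-Williams update on squared distances
        d2 = ((x[:, None] - x[None]) ** 2).sum(-1)
        active = {i: 1 for i in range(len(x))}  # cluster -> size
        dist = {(i, j): d2[i, j] for i in range(len(x)) for j in range(i + 1, len(x))}
        heights = []
        next_id = len(x)
        while len(active) > 1:
            (a, b), dab = min(dist.items(), key=lambda kv: kv[1])
            heights.append(np.sqrt(dab))
            na, nb = active.pop(a), active.pop(b)
            new = {}
            for (i, j), dij in dist.items():
                if a in (i, j) or b in (i, j):
                    continue
                new[(i, j)] = dij
            for c, nc in active.items():
                dac = dist[tuple(sorted((a, c)))]
                dbc = dist[tuple(sorted((b, c)))]
                n_tot = na + nb + nc
                new[(c, next_id)] = (
                    (na + nc) * dac + (nb + nc) * dbc - nc * dab
                ) / n_tot
            active[next_id] = na + nb
            dist = new
            next_id += 1
        np.testing.assert_allclose(np.sort(z[:, 2]), np.sort(heights), atol=1e-9)

    def test_nonfinite_scores_rejected(self):
        with pytest.raises(ValueError):
            agglomerate(np.array([[0.0, np.nan], [1.0, 1.0]]))


def toy_tree():
    """8 leaves: four tight pairs, pairs merging at 2 and 3, top at 10."""
    return np.array(
        [
            [0, 1, 1.0, 2],
            [2, 3, 1.0, 2],
            [4, 5, 1.0, 2],
            [6, 7, 1.0, 2],
            [8, 9, 2.0, 4],
            [10, 11, 3.0, 4],
            [12, 13, 10.0, 8],
        ]
    )


class TestMergerScoreCut:
    def test_hand_computed_toy_tree(self):
        # heights sum to 19; normalized increments are
        # [0, 0, 0, 1/19, 1/19, 7/19] so the first exceedance of 1.5%
        # (bottom-up) sits at the fourth increment -> 4 classes
        z = toy_tree()
        assert merger_score_classes(z, 0.015) == 4
        result = cut_by_merger_score(z, 0.015)
        assert result.n_classes == 4
        # the four flat classes are exactly the four tight pairs
        labels = result.labels
        assert all(labels[2 * i] == labels[2 * i + 1] for i in range(4))
        assert len(set(labels)) == 4

    def test_four_separated_blobs_found_at_every_threshold(self):
        rng = np.random.default_rng(0)
        centers = [(0, 0), (40, 0), (0, 40), (40, 40)]
        x = np.vstack([rng.normal(c, 2.0, (60, 2)) for c in centers])
        z = agglomerate(x)
        for th in (0.01, 0.015, 0.02, 0.03):
            assert merger_score_classes(z, th) == 4

    def test_single_blob_stays_coarse(self):
        rng = np.random.default_rng(2)
        z = agglomerate(rng.normal(0, 3.0, (250, 2)))
        for th in (0.01, 0.015, 0.02, 0.03):
            assert 1 <= merger_score_classes(z, th) <= 3

    def test_all_increments_below_threshold_warns_single_class(self):
        z = np.array([[0, 1, 1.0, 2], [2, 3, 1.01, 2], [4, 5, 1.02, 4]])
        with pytest.warns(UserWarning):
            result = cut_by_merger_score(z, 0.5)
        assert result.n_classes == 1

    def test_sensitivity_report_attached(self):
        z = toy_tree()
        result = cut_by_merger_score(z)
        assert set(result.sensitivity) == {0.01, 0.015, 0.02, 0.03}


def labeled_result(labels, tree=None):
    labels = np.asarray(labels)
    return ClusterResult(
        tree=tree if tree is not None else np.empty((0, 4)),
        threshold=0.015,
        n_classes=len(set(labels)),
        labels=labels,
    )


class TestLabelingAndMerging:
    def features_for(self, labels):
        rng = np.random.default_rng(0)
        ms = {1: 0.2, 2: 6.0, 3: 10.0, 4: 15.0}
        d = {1: 2.0, 2: 25.0, 3: 60.0, 4: 90.0}
        return pd.DataFrame(
            {
                "MS": [ms[c] + rng.normal(0, 0.1) for c in labels],
                "D": [d[c] + rng.normal(0, 1) for c in labels],
                "F": 0.9,
            }
        )

    def test_kinematic_names_assigned(self):
        labels = np.repeat([1, 2, 3, 4], 25)
        result = label_classes(labeled_result(labels), self.features_for(labels))
        assert result.class_names == {
            1: "dwelling",
            2: "scanning",
            3: "slow_ranging",
            4: "fast_ranging",
        }

    def test_merge_reduces_count_by_one_and_coarsens(self):
        labels = np.repeat([1, 2, 3, 4], 10)
        result = labeled_result(labels)
        merged = merge_classes(result, [(1, 2)])
        assert merged.n_classes == 3
        # the merge only coarsens the partition
        for a in range(len(labels)):
            for b in range(a + 1, len(labels)):
                if labels[a] == labels[b]:
                    assert merged.labels[a] == merged.labels[b]

    def test_merging_missing_class_rejected(self):
        result = labeled_result(np.repeat([1, 2], 10))
        with pytest.raises(ValueError):
            merge_classes(result, [(1, 9)])

    def test_naming_never_changes_partition(self):
        labels = np.repeat([1, 2, 3, 4], 25)
        result = label_classes(labeled_result(labels), self.features_for(labels))
        named = result.named_labels()
        for a in range(0, len(labels), 7):
            for b in range(a, len(labels), 13):
                assert (labels[a] == labels[b]) == (named[a] == named[b])


class TestClassOccupancy:
    def windows(self, n):
        return {d: DayWindow(d, 360.0, 1080.0) for d in range(n)}

    def frame(self, n_days, cls):
        rows = []
        for d in range(n_days):
            for k, start in enumerate(np.arange(360.0, 1080.0 - 30 + 1e-9, 15.0)):
                rows.append(
                    {"fish_id": "F1", "day": d, "start_min": start, "class": cls(d, k)}
                )
        return pd.DataFrame(rows)

    def test_single_class_occupies_everything(self):
        labels = self.frame(4, lambda d, k: "scanning")
        occ = class_occupancy(labels, self.windows(4))
        assert np.allclose(occ.fractions["scanning"], 1.0)
        assert occ.standard_error["scanning"] == pytest.approx(0.0, abs=1e-12)

    def test_fractions_sum_to_one_per_day(self):
        rng = np.random.default_rng(4)
        names = ["a", "b", "c"]
        labels = self.frame(8, lambda d, k: names[rng.integers(3)])
        occ = class_occupancy(labels, self.windows(8))
        np.testing.assert_allclose(occ.fractions.sum(axis=1), 1.0, atol=1e-9)

    def test_across_day_variability_within_binomial_bound(self, day_traj):
        """Daily mode fractions of a stationary Markov policy scatter no more
        than twice the bout-level binomial sampling error."""
        cfg, traj, days = day_traj
        sr, ss = cfg.day_window
        rows = []
        for d in days:
            for start in np.arange(sr, ss - 30 + 1e-9, 15.0):
                lab = traj.mode_labels[int(d * 1440 + start) : int(d * 1440 + start) + 30]
                vals, cnt = np.unique(lab, return_counts=True)
                rows.append(
                    {"fish_id": "F1", "day": d, "start_min": float(start), "class": str(vals[np.argmax(cnt)])}
                )
        labels = pd.DataFrame(rows)
        occ = class_occupancy(labels, {d: DayWindow(d, float(sr), float(ss)) for d in days})
        daily_sd = occ.fractions.std(axis=0, ddof=1)
        # bout-level binomial oracle: a day holds ~daylength/mean-bout
        # independent draws of the stationary mode distribution
        p_mode = occ.fractions.mean(axis=0)
        mean_bout = 1.0 / (1.0 - 0.995)
        n_eff = (ss - sr) / mean_bout
        for mode, p in p_mode.items():
            bound = 2.0 * np.sqrt(p * (1 - p) / n_eff)
            assert daily_sd[mode] <= bound + 1e-9, mode
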