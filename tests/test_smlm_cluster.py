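"""Ripley statistics, DBSCAN cluster maps, and DoC colocalization."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from myovi.smlm_cluster import (
    LocalizationTable,
    cluster_dbscan,
    doc_scores,
    ripley_L_minus_r,
    ripley_csr_envelope,
    suggest_eps_from_ripley,
)
from myovi.synthetic_data import GeneratorConfig, gen_smlm


def make_table(xy, precision=20.0, channel=1, roi=None, extra=None):
    df = pd.DataFrame(
        {
            "frame": np.arange(len(xy)),
            "x": xy[:, 0],
            "y": xy[:, 1],
            "precision": precision,
            "channel": channel,
        }
    )
    if extra is not None:
        df = pd.concat([df, extra], ignore_index=True)
    return LocalizationTable(df, roi=roi)


def brute_force_K(xy, area, interior, r_grid):
    """O(n^2) double-loop Ripley estimator (oracle)."""
    n = len(xy)
    counts = np.zeros(len(r_grid))
    for i in np.flatnonzero(interior):
        d = np.sqrt(((xy - xy[i]) ** 2).sum(axis=1))
        d[i] = np.inf
        for j, r in enumerate(r_grid):
            counts[j] += (d <= r).sum()
    return area * counts / (interior.sum() * (n - 1))


class TestRipley:
    def test_equals_brute_force_double_loop(self, rng):
        L = 2000.0
        roi = box(0, 0, L, L)
        centers = rng.uniform(300, L - 300, (8, 2))
        pts = centers.repeat(60, axis=0) + rng.normal(0, 40, (480, 2))
        pts = np.vstack([pts, rng.uniform(0, L, (300, 2))])
        pts = np.clip(pts, 0, L)
        locs = make_table(pts, roi=roi)
        r_grid = np.arange(25.0, 251.0, 25.0)
        curve = ripley_L_minus_r(locs, 1, r_grid)
        interior = (
            (pts[:, 0] >= 250) & (pts[:, 0] <= L - 250)
            & (pts[:, 1] >= 250) & (pts[:, 1] <= L - 250)
        )
        K_oracle = brute_force_K(pts, L * L, interior, r_grid)
        assert np.allclose(curve.K, K_oracle, rtol=1e-12, atol=1e-9)

    def test_csr_stays_inside_envelope(self):
        rng = np.random.default_rng(7)
        L = 4000.0
        roi = box(0, 0, L, L)
        r_grid = np.arange(25.0, 501.0, 25.0)
        n = 5000
        xy = rng.uniform(0, L, (n, 2))
        curve = ripley_L_minus_r(make_table(xy, roi=roi), 1, r_grid)
        env = ripley_csr_envelope(n, roi, r_grid, n_sim=100, rng=rng)
        assert np.max(np.abs(curve.L_minus_r)) <= env

    def test_clustered_pattern_peaks_at_cluster_scale(self, rng):
        locs, _ = gen_smlm(GeneratorConfig(seed=2))
        r_grid = np.arange(10.0, 501.0, 10.0)
        curve = ripley_L_minus_r(locs, 1, r_grid)
        peak_r = curve.r[np.argmax(curve.L_minus_r)]
        assert curve.L_minus_r.max() > 50  # far outside any CSR envelope
        assert 30 <= peak_r <= 300  # on the order of the cluster size

    def test_too_few_points_refused(self):
        with pytest.raises(ValueError):
            ripley_L_minus_r(
                make_table(np.array([[50.0, 50.0]]), roi=box(0, 0, 100, 100)),
                1,
                [10.0],
            )


def brute_force_dbscan(xy, eps, min_pts):
    """Reference density clustering by explicit BFS over core points."""
    n = len(xy)
    d = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1))
    neighbors = [np.flatnonzero(d[i] <= eps) for i in range(n)]
    core = np.array([len(nb) >= min_pts for nb in neighbors])
    labels = np.full(n, -1)
    cid = 0
    for start in range(n):
        if labels[start] != -1 or not core[start]:
            continue
        stack = [start]
        labels[start] = cid
        while stack:
            i = stack.pop()
            if not core[i]:
                continue
            for j in neighbors[i]:
                if labels[j] == -1:
                    labels[j] = cid
                    stack.append(j)
        cid += 1
    return labels


class TestClusterDbscan:
    def test_planted_clusters_fully_recovered(self, rng):
        centers = np.array([[x, y] for x in range(5) for y in range(2)], float)
        centers = centers * 600.0 + 300.0
        pts = centers.repeat(50, axis=0) + rng.normal(0, 20, (500, 2))
        locs = make_table(pts, roi=box(0, 0, 3300, 1500))
        res = cluster_dbscan(locs, eps=25.0)
        assert res.n_clusters == 10
        # a Gaussian blob keeps a few stragglers beyond density reach, so
        # full recovery means all but the extreme tail
        assert res.pct_in_clusters >= 95.0
        # partition agrees with the brute-force connected-component oracle
        oracle = brute_force_dbscan(pts, 25.0, 5)
        assert sorted(np.bincount(oracle[oracle >= 0])) == sorted(
            res.clusters["n_molecules"]
        )
        assert res.pct_in_clusters == pytest.approx(100.0 * np.mean(oracle >= 0))

    def test_sparse_csr_has_no_clusters(self, rng):
        xy = rng.uniform(0, 10000, (200, 2))  # nn distance >> eps
        res = cluster_dbscan(make_table(xy), eps=20.0)
        assert res.pct_in_clusters == 0.0

    def test_coincident_points_single_zero_area_cluster(self):
        xy = np.zeros((8, 2)) + 500.0
        res = cluster_dbscan(make_table(xy, roi=box(0, 0, 1000, 1000)), eps=20.0)
        assert res.n_clusters == 1
        assert res.mean_area_nm2 == 0.0

    def test_rigid_motion_invariance(self, rng):
        locs, _ = gen_smlm(GeneratorConfig(seed=4))
        res = cluster_dbscan(locs, eps=50.0)
        xy = locs.data[["x", "y"]].to_numpy()
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        moved = xy @ R.T + np.array([1e4, -2e3])
        df = locs.data.copy()
        df[["x", "y"]] = moved
        res2 = cluster_dbscan(LocalizationTable(df), eps=50.0)
        assert res2.n_clusters == res.n_clusters
        assert res2.pct_in_clusters == pytest.approx(res.pct_in_clusters)
        assert sorted(res2.clusters["n_molecules"]) == sorted(res.clusters["n_molecules"])
        assert np.allclose(
            np.sort(res2.clusters["area_nm2"]), np.sort(res.clusters["area_nm2"]), rtol=1e-6
        )

    @pytest.mark.parametrize("fraction", [0.3, 0.65, 0.9])
    def test_percent_in_clusters_recovery(self, fraction):
        # Ripley-informed eps; mean over 20 seeds within +/-5 points
        r_grid = np.arange(10.0, 201.0, 10.0)
        vals = []
        for seed in range(20):
            locs, truth = gen_smlm(
                GeneratorConfig(seed=seed), clustered_fraction=fraction
            )
            eps = suggest_eps_from_ripley(ripley_L_minus_r(locs, 1, r_grid))
            vals.append(cluster_dbscan(locs, eps=eps).pct_in_clusters)
        assert abs(np.mean(vals) - 100 * fraction) <= 5.0


class TestDocScores:
    def _clustered_pair(self, rng, coincident=True):
        L = 4000.0
        centers = rng.uniform(600, L - 600, (12, 2))
        pts1 = centers.repeat(40, axis=0) + rng.normal(0, 30, (480, 2))
        if coincident:
            pts2 = pts1.copy()
        else:
            pts2 = rng.uniform(600, L - 600, (12, 2)).repeat(40, axis=0)
            pts2 = pts2 + rng.normal(0, 30, (480, 2))
        df = pd.concat(
            [
                pd.DataFrame({"frame": 0, "x": p[:, 0], "y": p[:, 1],
                              "precision": 20.0, "channel": ch})
                for ch, p in ((1, np.clip(pts1, 0, L)), (2, np.clip(pts2, 0, L)))
            ],
            ignore_index=True,
        )
        return LocalizationTable(df, roi=box(0, 0, L, L))

    def test_coincident_channels_score_near_one(self, rng):
        locs = self._clustered_pair(rng, coincident=True)
        res = doc_scores(locs, eps=50.0)
        assert res.scores["doc"].mean() > 0.9
        for ch in (1, 2):
            assert res.clusters[ch]["colocalized"].all()

    def test_separated_half_planes_score_nonpositive(self, rng):
        L = 20000.0
        xy1 = rng.uniform([0, 0], [2000, 2000], (300, 2))
        xy2 = rng.uniform([18000, 18000], [L, L], (300, 2))
        df = pd.concat(
            [
                pd.DataFrame({"frame": 0, "x": p[:, 0], "y": p[:, 1],
                              "precision": 20.0, "channel": ch})
                for ch, p in ((1, xy1), (2, xy2))
            ],
            ignore_index=True,
        )
        res = doc_scores(LocalizationTable(df, roi=box(0, 0, L, L)), eps=60.0)
        assert (res.scores["doc"] <= 1e-9).all()
        for ch in (1, 2):
            assert not res.clusters[ch]["colocalized"].any()

    def test_partial_coincidence_recovers_planted_fraction(self):
        flagged = []
        for seed in range(5):
            locs, _ = gen_smlm(GeneratorConfig(seed=seed), coincidence=0.5)
            res = doc_scores(locs, eps=50.0)
            flagged.append(res.clusters[2]["colocalized"].mean())
        assert 0.3 <= np.mean(flagged) <= 0.75

    def test_colocalized_clusters_larger_and_denser(self):
        # planted coincidence: flagged clusters out-count and out-size the rest
        sizes = {True: [], False: []}
        for seed in range(5):
            locs, _ = gen_smlm(GeneratorConfig(seed=seed), coincidence=0.5)
            res = doc_scores(locs, eps=50.0)
            for ch in (1, 2):
                t = res.clusters[ch]
                for flag in (True, False):
                    sizes[flag].extend(t.loc[t["colocalized"] == flag, "n_molecules"])
        assert np.mean(sizes[True]) > np.mean(sizes[False])

    def test_empty_channel_refused(self, rng):
        xy = rng.uniform(0, 1000, (200, 2))
        with pytest.raises(ValueError):
            doc_scores(make_table(xy, roi=box(0, 0, 1000, 1000)))
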