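import math

import numpy as np
import pytest

from stclust import SpatialCoords, ValidationError
from stclust.containers import MatchedLabels
from stclust.cluster import ClusteringResult, compute_pca, match_labels
from stclust.containers import GeneSelection
from stclust.metrics import (
    ami,
    build_neighborhoods,
    entropy_weights,
    evaluate_all,
    mean_spatial_ami,
    pearson_gamma,
    spatial_concordance,
    weighted_f1,
)


def matched(u, u_star):
    n = len(u)
    ids = np.array([f"c{i}" for i in range(n)])
    return MatchedLabels(ids, np.asarray(u, dtype=str), np.asarray(u_star, dtype=str))


# ---------------------------------------------------------------------------
# independent oracles


def ami_bruteforce(u, v):
    """AMI from first principles: MI, entropies, and hypergeometric-model EMI."""
    u, v = np.asarray(u), np.asarray(v)
    n = u.size
    uc, vc = np.unique(u), np.unique(v)
    a = np.array([(u == c).sum() for c in uc], dtype=float)
    b = np.array([(v == c).sum() for c in vc], dtype=float)

    mi = 0.0
    for i, cu in enumerate(uc):
        for j, cv in enumerate(vc):
            nij = float(np.sum((u == cu) & (v == cv)))
            if nij > 0:
                mi += nij / n * math.log(n * nij / (a[i] * b[j]))

    def H(counts):
        p = counts / n
        return -np.sum(p * np.log(p))

    emi = 0.0
    for ai in a:
        for bj in b:
            lo = int(max(ai + bj - n, 1))
            hi = int(min(ai, bj))
            for nij in range(lo, hi + 1):
                term = nij / n * math.log(n * nij / (ai * bj))
                lp = (
                    math.lgamma(ai + 1) - math.lgamma(nij + 1) - math.lgamma(ai - nij + 1)
                    + math.lgamma(n - ai + 1) - math.lgamma(bj - nij + 1)
                    - math.lgamma(n - ai - bj + nij + 1)
                    - (math.lgamma(n + 1) - math.lgamma(bj + 1) - math.lgamma(n - bj + 1))
                )
                emi += term * math.exp(lp)
    denom = 0.5 * (H(a) + H(b)) - emi
    if denom == 0:
        return 1.0 if mi == emi else 0.0
    return (mi - emi) / denom


def sc_bruteforce(u, u_star, xy, k):
    """Spatial concordance via direct per-cell loops (independent of the impl)."""
    u, u_star = np.asarray(u), np.asarray(u_star)
    n = len(u)
    e = np.zeros(n)
    for i in range(n):
        d = np.hypot(xy[:, 0] - xy[i, 0], xy[:, 1] - xy[i, 1])
        d[i] = -np.inf
        order = sorted(range(n), key=lambda j: (d[j], j))
        members = order[: k + 1]
        ent = 0.0
        for lab in set(u[members]):
            p = sum(u[m] == lab for m in members) / (k + 1)
            ent -= p * math.log(p)
        e[i] = ent
    total = e.sum()
    w = e / total if total > 0 else np.full(n, 1.0 / n)
    return sum(w[i] for i in range(n) if u[i] == u_star[i])


# ---------------------------------------------------------------------------


class TestAMI:
    def test_identity_and_relabeling(self):
        u = ["A", "A", "B", "B", "C"]
        assert ami(u, u) == pytest.approx(1.0)
        assert ami(u, ["x", "x", "y", "y", "z"]) == pytest.approx(1.0)

    def test_matches_bruteforce_oracle(self):
        u = ["A", "A", "B", "B"]
        v = ["A", "B", "A", "B"]
        assert ami(u, v) == pytest.approx(ami_bruteforce(u, v), abs=1e-10)
        rng = np.random.default_rng(0)
        for _ in range(10):
            u = rng.choice(["A", "B", "C"], size=12)
            v = rng.choice(["A", "B"], size=12)
            if len(set(u)) < 2 or len(set(v)) < 2:
                continue
            assert ami(u, v) == pytest.approx(ami_bruteforce(u, v), abs=1e-10)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            ami(["A", "B"], ["A", "B", "C"])


class TestWeightedF1:
    def test_identity(self):
        m = matched(["A", "B", "A"], ["A", "B", "A"])
        assert weighted_f1(m) == pytest.approx(1.0)

    def test_hand_computed_instance(self):
        m = matched(["A", "A", "B", "B", "B"], ["A", "A", "A", "B", "B"])
        # F1_A = 0.8 (precision 2/3, recall 1), F1_B = 0.8; weights 0.4/0.6
        assert weighted_f1(m) == pytest.approx(0.8)

    def test_class_missing_from_predictions(self):
        m = matched(["A", "A", "B"], ["A", "A", "A"])
        assert weighted_f1(m) < 1.0


class TestPearsonGamma:
    def test_printed_four_point_instance(self):
        pts = np.array([0.0, 0.1, 10.0, 10.1])
        val = pearson_gamma(["a", "a", "b", "b"], pts)
        assert val == pytest.approx(0.99990, abs=1e-4)

    def test_single_cluster_is_undefined(self):
        with pytest.warns(UserWarning):
            val = pearson_gamma(["a", "a", "a"], np.array([0.0, 1.0, 2.0]))
        assert np.isnan(val)

    def test_random_labels_give_near_zero(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            pts = rng.uniform(size=200)
            labels = rng.permutation(np.repeat(["a", "b"], 100))
            hits += abs(pearson_gamma(labels, pts)) < 0.1
        assert hits >= 95

    def test_subsampling_is_seeded(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(2500, 2))
        labels = rng.choice(["a", "b"], size=2500)
        v1 = pearson_gamma(labels, pts, max_n=500, random_state=3)
        v2 = pearson_gamma(labels, pts, max_n=500, random_state=3)
        assert v1 == v2


class TestNeighborhoods:
    def test_nearest_neighbor_pairs_on_a_line(self):
        coords = SpatialCoords(
            np.array(["a", "b", "c", "d"]),
            np.array([0.0, 1.0, 2.5, 3.5]),
            np.zeros(4),
        )
        nb = build_neighborhoods(coords, k_spatial=1)
        assert {tuple(sorted(m)) for m in nb.members} == {(0, 1), (2, 3)}

    def test_every_neighborhood_contains_its_cell(self, small_dataset):
        nb = build_neighborhoods(small_dataset.coords, k_spatial=5)
        assert np.array_equal(nb.members[:, 0], np.arange(len(nb.members)))

    def test_order_invariance(self):
        rng = np.random.default_rng(2)
        xy = rng.uniform(size=(30, 2))
        nb1 = build_neighborhoods(xy, k_spatial=4)
        perm = rng.permutation(30)
        nb2 = build_neighborhoods(xy[perm], k_spatial=4)
        sets1 = {frozenset(m) for m in nb1.members}
        sets2 = {frozenset(perm[m]) for m in nb2.members}
        assert sets1 == sets2


class TestEntropyWeights:
    def test_pure_tissue_falls_back_to_uniform(self):
        xy = np.random.default_rng(3).uniform(size=(10, 2))
        nb = build_neighborhoods(xy, k_spatial=3)
        ew = entropy_weights(["A"] * 10, nb)
        np.testing.assert_allclose(ew.w, 0.1)
        np.testing.assert_allclose(ew.e, 0.0)

    def test_worked_line_instance(self, line_coords, line_labels):
        nb = build_neighborhoods(line_coords, k_spatial=1)
        ew = entropy_weights(line_labels.labels, nb)
        np.testing.assert_allclose(ew.e, [np.log(2), np.log(2), 0.0, 0.0])
        np.testing.assert_allclose(ew.w, [0.5, 0.5, 0.0, 0.0])

    def test_weights_sum_to_one(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            n = rng.integers(8, 40)
            xy = rng.uniform(size=(n, 2))
            labels = rng.choice(["A", "B", "C"], size=n)
            nb = build_neighborhoods(xy, k_spatial=min(5, n - 1))
            assert entropy_weights(labels, nb).w.sum() == pytest.approx(1.0)


class TestSpatialConcordance:
    def test_identity_scores_one(self, line_coords, line_labels):
        nb = build_neighborhoods(line_coords, k_spatial=1)
        ew = entropy_weights(line_labels.labels, nb)
        m = matched(line_labels.labels, line_labels.labels)
        assert spatial_concordance(m, ew) == pytest.approx(1.0)

    def test_worked_line_instance_scores_half(self, line_coords, line_labels):
        nb = build_neighborhoods(line_coords, k_spatial=1)
        ew = entropy_weights(line_labels.labels, nb)
        m = matched(line_labels.labels, ["A", "A", "B", "B"])
        assert spatial_concordance(m, ew) == pytest.approx(0.5)

    def test_matches_bruteforce_on_random_instances(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = 12
            xy = rng.uniform(size=(n, 2))
            u = rng.choice(["A", "B", "C"], size=n)
            v = rng.choice(["A", "B", "C"], size=n)
            nb = build_neighborhoods(xy, k_spatial=3)
            ew = entropy_weights(u, nb)
            got = spatial_concordance(matched(u, v), ew)
            want = sc_bruteforce(u, v, xy, 3)
            assert got == pytest.approx(want, abs=1e-12)


class TestMeanSpatialAMI:
    def test_identity_scores_one(self, line_coords, line_labels):
        nb = build_neighborhoods(line_coords, k_spatial=1)
        ew = entropy_weights(line_labels.labels, nb)
        m = matched(line_labels.labels, line_labels.labels)
        assert mean_spatial_ami(m, nb, ew) == pytest.approx(1.0)

    def test_worked_line_instance_scores_zero(self, line_coords, line_labels):
        nb = build_neighborhoods(line_coords, k_spatial=1)
        ew = entropy_weights(line_labels.labels, nb)
        m = matched(line_labels.labels, ["A", "A", "B", "B"])
        assert mean_spatial_ami(m, nb, ew) == pytest.approx(0.0)

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(6)
        xy = rng.uniform(size=(30, 2))
        u = rng.choice(["A", "B"], size=30)
        v = rng.choice(["A", "B", "C"], size=30)
        nb = build_neighborhoods(xy, k_spatial=5)
        ew = entropy_weights(u, nb)
        a = mean_spatial_ami(matched(u, v), nb, ew)
        relabel = {"A": "z", "B": "q", "C": "m"}
        v2 = np.array([relabel[x] for x in v])
        b = mean_spatial_ami(matched(u, v2), nb, ew)
        assert a == pytest.approx(b, abs=1e-12)


def test_bounded_metrics_stay_in_range_under_fuzz():
    rng = np.random.default_rng(7)
    for _ in range(300):
        n = int(rng.integers(6, 40))
        k = int(rng.integers(1, min(6, n - 1)))
        xy = rng.uniform(size=(n, 2))
        u = rng.choice(list("ABC")[: rng.integers(1, 4)], size=n)
        v = rng.choice(list("ABC"), size=n)
        nb = build_neighborhoods(xy, k_spatial=k)
        ew = entropy_weights(u, nb)
        m = matched(u, v)
        sc = spatial_concordance(m, ew)
        ms = mean_spatial_ami(m, nb, ew)
        f1 = weighted_f1(m)
        assert 0.0 <= sc <= 1.0
        assert 0.0 <= ms <= 1.0
        assert 0.0 <= f1 <= 1.0
        if len(set(u)) > 1 and len(set(v)) > 1:
            assert ami(u, v) <= 1.0


def test_evaluate_all_composes_the_individual_metrics(small_dataset):
    ds = small_dataset
    sel = GeneSelection("all", "low", ds.matrix.gene_ids)
    emb = compute_pca(ds.matrix.with_values(ds.matrix.to_dense(), "lognorm"), sel)
    # perfect predictions: u* = u
    clustering = ClusteringResult(ds.truth.cell_ids, ds.truth.labels.copy(), "kmeans")
    m = match_labels(
        clustering, ds.truth, ds.matrix.with_values(ds.matrix.to_dense(), "lognorm"), sel
    )
    records = evaluate_all(m, emb, ds.coords, dataset="t", gene_set="all")
    assert len(records) == 5
    by_name = {r.metric: r.value for r in records}
    assert by_name["ami"] == pytest.approx(1.0)
    assert by_name["weighted_f1"] == pytest.approx(1.0)
    assert by_name["spatial_concordance"] == pytest.approx(1.0)
    assert by_name["mean_spatial_ami"] == pytest.approx(1.0)
    assert by_name["pearson_gamma"] > 0

    nb = build_neighborhoods(ds.coords, k_spatial=15)
    ew = entropy_weights(m.u, nb)
    assert by_name["spatial_concordance"] == pytest.approx(spatial_concordance(m, ew))
    assert by_name["mean_spatial_ami"] == pytest.approx(mean_spatial_ami(m, nb, ew))
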