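"""Consensus clustering, marker discovery, projection, outcome association."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.special import comb
from scipy.stats import hypergeom, pearsonr

from mclsubtype.clustering import (
    associate_outcome,
    cophenetic_coefficient,
    find_markers,
    nmf_consensus,
    nmf_kl,
    project_cohort,
)
from mclsubtype.encoding import LesionMatrix


def block_matrix(sizes, lesions_per_block, noise=0):
    """Perfectly exclusive lesion blocks: block b's samples carry only block b's lesions."""
    rows = []
    for b, n in enumerate(sizes):
        for _ in range(n):
            row = []
            for bb in range(len(sizes)):
                row += [1 if bb == b else 0] * lesions_per_block
            rows.append(row)
    scores = pd.DataFrame(
        rows,
        index=[f"S{i}" for i in range(sum(sizes))],
        columns=[f"L{j}" for j in range(lesions_per_block * len(sizes))],
    )
    return LesionMatrix(scores=scores, lesion_meta={c: "mutation" for c in scores.columns})


class TestNMFKernel:
    def test_matches_sklearn_from_identical_initialization(self):
        """The in-package KL multiplicative updates converge to the same
        objective as sklearn's KL solver started from the same factors."""
        from sklearn.decomposition import NMF

        rng = np.random.default_rng(0)
        X = (rng.random((60, 20)) < 0.3).astype(float) + (rng.random((60, 20)) < 0.05)

        init_rng = np.random.default_rng(1)
        W0 = np.ones((60, 4))
        H0 = init_rng.random((4, 20)) + 1e-3

        W, H, obj = nmf_kl(X, 4, np.random.default_rng(1))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = NMF(n_components=4, init="custom", solver="mu",
                        beta_loss="kullback-leibler", tol=1e-6, max_iter=2000)
            Ws = model.fit_transform(X, W=W0.copy(), H=H0.copy())
        eps = 1e-12
        WHs = Ws @ model.components_
        obj_sk = float(np.sum(np.where(X > 0, X * np.log((X + eps) / (WHs + eps)), 0)
                              - X + WHs))
        # same start, same objective: the kernels agree to local-optimum noise
        assert obj == pytest.approx(obj_sk, rel=2e-2)
        assert obj <= obj_sk * 1.001 + 1e-9

    def test_factors_nonnegative(self):
        rng = np.random.default_rng(3)
        X = rng.random((20, 8))
        W, H, _ = nmf_kl(X, 3, rng)
        assert (W >= 0).all() and (H >= 0).all()


class TestConsensus:
    def test_separable_two_blocks_recovered_exactly(self):
        matrix = block_matrix([10, 10], 4)
        res = nmf_consensus(matrix, (2,), n_restarts=10, seed=0)
        labels = res.labels.to_numpy()
        assert len(set(labels[:10])) == 1 and len(set(labels[10:])) == 1
        assert labels[0] != labels[-1]

    def test_single_restart_consensus_is_binary(self):
        matrix = block_matrix([6, 6], 3)
        res = nmf_consensus(matrix, (2,), n_restarts=1, seed=0)
        assert set(np.unique(res.consensus[2])) <= {0.0, 1.0}

    def test_permutation_equivariance(self):
        matrix = block_matrix([6, 6, 6], 3)
        perm = np.random.default_rng(0).permutation(18)
        shuffled = LesionMatrix(
            scores=matrix.scores.iloc[perm], lesion_meta=matrix.lesion_meta
        )
        r1 = nmf_consensus(matrix, (3,), n_restarts=15, seed=4)
        r2 = nmf_consensus(shuffled, (3,), n_restarts=15, seed=4)
        np.testing.assert_allclose(
            r1.consensus[3][np.ix_(perm, perm)], r2.consensus[3], atol=1e-12
        )

    def test_all_zero_matrix_rejected(self):
        scores = pd.DataFrame(np.zeros((5, 3), dtype=int),
                              index=list("abcde"), columns=["x", "y", "z"])
        with pytest.raises(ValueError, match="all-zero"):
            nmf_consensus(LesionMatrix(scores=scores), (2,), n_restarts=2, seed=0)

    def test_k_exceeding_samples_rejected(self):
        matrix = block_matrix([3, 3], 2)
        with pytest.raises(ValueError, match="exceeds"):
            nmf_consensus(matrix, (6,), n_restarts=2, seed=0)

    def test_two_seed_label_stability_on_separable_cohort(self, reference_cohort):
        from sklearn.metrics import adjusted_rand_score

        matrix, _, _ = reference_cohort
        r1 = nmf_consensus(matrix, (4,), n_restarts=20, seed=10)
        r2 = nmf_consensus(matrix, (4,), n_restarts=20, seed=11)
        assert adjusted_rand_score(r1.labels, r2.labels) >= 0.95


class TestCophenetic:
    def test_perfect_block_consensus_is_one(self):
        co = np.kron(np.eye(2), np.ones((5, 5)))
        assert cophenetic_coefficient(co) == pytest.approx(1.0)

    def test_constant_offdiagonal_flagged_degenerate(self):
        co = np.full((6, 6), 0.5)
        np.fill_diagonal(co, 1.0)
        with pytest.warns(UserWarning, match="degenerate"):
            assert cophenetic_coefficient(co) == 1.0

    def test_matches_independent_textbook_implementation(self):
        """Naive UPGMA cophenetic distances, built by explicit cluster merging."""
        rng = np.random.default_rng(12)
        co = rng.random((20, 20))
        co = (co + co.T) / 2
        np.fill_diagonal(co, 1.0)
        dist = 1.0 - co

        # textbook UPGMA: merge the closest pair of clusters, record heights
        clusters = {i: [i] for i in range(20)}
        d = {(i, j): dist[i, j] for i in range(20) for j in range(i + 1, 20)}
        coph = np.zeros_like(dist)
        next_id = 20
        while len(clusters) > 1:
            (a, b), h = min(d.items(), key=lambda kv: kv[1])
            for i in clusters[a]:
                for j in clusters[b]:
                    coph[i, j] = coph[j, i] = h
            merged = clusters.pop(a) + clusters.pop(b)
            new_d = {}
            for key, val in d.items():
                if a in key or b in key:
                    continue
                new_d[key] = val
            for c, members in clusters.items():
                num = sum(dist[i, j] for i in merged for j in members)
                new_d[tuple(sorted((c, next_id)))] = num / (len(merged) * len(members))
            clusters[next_id] = merged
            d = new_d
            next_id += 1

        iu = np.triu_indices(20, 1)
        expected, _ = pearsonr(coph[iu], dist[iu])
        assert cophenetic_coefficient(co) == pytest.approx(expected, abs=1e-10)


def bh_oracle(pvals, alpha):
    """Step-up BH: flag all p_(i) with i <= max{i: p_(i) <= i/m * alpha}."""
    m = len(pvals)
    order = np.argsort(pvals)
    flagged = np.zeros(m, dtype=bool)
    kmax = 0
    for rank, idx in enumerate(order, start=1):
        if pvals[idx] <= rank / m * alpha:
            kmax = rank
    flagged[order[:kmax]] = True
    return flagged


class TestMarkers:
    def test_exclusive_lesion_matches_hypergeometric_closed_form(self):
        # lesion in all 10 cluster-A samples, 0 of 90 others: p = 1 / C(100,10)
        scores = pd.DataFrame({"L": [1] * 10 + [0] * 90},
                              index=[f"S{i}" for i in range(100)])
        matrix = LesionMatrix(scores=scores, lesion_meta={"L": "mutation"})
        labels = pd.Series(["A"] * 10 + ["B"] * 90, index=scores.index)
        table = find_markers(matrix, labels)
        row = table[(table["Lesion"] == "L") & (table["Cluster"] == "A")].iloc[0]
        assert row["P"] == pytest.approx(1.0 / comb(100, 10, exact=True), rel=1e-12)
        assert row["Marker"]

    def test_uniform_lesion_not_flagged(self):
        scores = pd.DataFrame({"L": [1, 1, 0, 0] * 10}, index=[f"S{i}" for i in range(40)])
        matrix = LesionMatrix(scores=scores, lesion_meta={"L": "mutation"})
        labels = pd.Series((["A"] * 4 + ["B"] * 4) * 5, index=scores.index)
        table = find_markers(matrix, labels)
        assert not table["Marker"].any()
        assert (table["P"] > 0.5).all()

    def test_single_cluster_rejected(self):
        scores = pd.DataFrame({"L": [1, 0]}, index=["a", "b"])
        matrix = LesionMatrix(scores=scores, lesion_meta={"L": "mutation"})
        with pytest.raises(ValueError, match="two clusters"):
            find_markers(matrix, pd.Series(["A", "A"], index=["a", "b"]))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_exhaustive_fisher_bh_oracle(self, seed):
        """Every p equals the hypergeometric tail; flags equal step-up BH."""
        rng = np.random.default_rng(seed)
        n, n_lesions, n_clusters = 24, 6, 3
        scores = pd.DataFrame(
            (rng.random((n, n_lesions)) < 0.35).astype(int),
            index=[f"S{i}" for i in range(n)],
            columns=[f"L{j}" for j in range(n_lesions)],
        )
        matrix = LesionMatrix(
            scores=scores, lesion_meta={c: "mutation" for c in scores.columns}
        )
        labels = pd.Series(rng.integers(0, n_clusters, n), index=scores.index)
        table = find_markers(matrix, labels)

        for _, row in table.iterrows():
            K = row["CountIn"] + row["CountOut"]  # total carriers
            # P(X >= count_in) for X ~ Hypergeom(N=n, K=carriers, n=cluster size)
            expected = hypergeom.sf(row["CountIn"] - 1, n, K, row["NIn"])
            assert row["P"] == pytest.approx(expected, rel=1e-9)
        np.testing.assert_array_equal(
            table["Marker"].to_numpy(), bh_oracle(table["P"].to_numpy(), 0.1)
        )


class TestProjection:
    def test_self_projection_agreement(self, reference_cohort, reference_consensus):
        matrix, _, _ = reference_cohort
        projected = project_cohort(matrix, reference_consensus)
        agreement = (projected == reference_consensus.labels).mean()
        assert agreement >= 0.95

    def test_identical_sample_gets_same_cluster(self, reference_cohort, reference_consensus):
        matrix, _, _ = reference_cohort
        one = LesionMatrix(
            scores=matrix.scores.iloc[[0]], lesion_meta=matrix.lesion_meta
        )
        projected = project_cohort(one, reference_consensus)
        assert projected.iloc[0] == reference_consensus.labels.iloc[0]

    def test_all_zero_sample_unassignable(self, reference_consensus):
        lesions = list(reference_consensus.basis.columns)
        zero = LesionMatrix(
            scores=pd.DataFrame([[0] * len(lesions)], index=["Z"], columns=lesions),
            lesion_meta={l: "mutation" for l in lesions},
        )
        assert project_cohort(zero, reference_consensus).iloc[0] == -1

    def test_empty_lesion_overlap_rejected(self, reference_consensus):
        other = LesionMatrix(
            scores=pd.DataFrame({"unrelated": [1]}, index=["V1"]),
            lesion_meta={"unrelated": "mutation"},
        )
        with pytest.raises(ValueError, match="share no lesions"):
            project_cohort(other, reference_consensus)


def logrank_by_hand(times, events, groups):
    """Two-group log-rank chi-square, stepping through distinct event times."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    groups = np.asarray(groups)
    obs_minus_exp = 0.0
    var = 0.0
    for t in sorted(set(times[events == 1])):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & (groups == 1)).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & (groups == 1)).sum()
        obs_minus_exp += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return obs_minus_exp**2 / var


class TestOutcome:
    def test_matches_hand_computed_logrank(self):
        surv = pd.DataFrame(
            {"Time": [2.0, 4.0, 6.0, 1.0, 3.0, 5.0], "Event": [1, 1, 1, 1, 1, 1]},
            index=[f"P{i}" for i in range(6)],
        )
        labels = pd.Series([0, 0, 0, 1, 1, 1], index=surv.index)
        _, result = associate_outcome(labels, surv)
        expected = logrank_by_hand(surv["Time"], surv["Event"], labels)
        assert result.test_statistic == pytest.approx(expected, rel=1e-10)

    def test_km_curves_emitted_per_cluster(self):
        rng = np.random.default_rng(0)
        surv = pd.DataFrame(
            {"Time": rng.exponential(20, 30) + 0.1, "Event": rng.integers(0, 2, 30)},
            index=[f"P{i}" for i in range(30)],
        )
        labels = pd.Series([0] * 15 + [1] * 15, index=surv.index)
        km, _ = associate_outcome(labels, surv)
        assert set(km["Cluster"]) == {0, 1}
        assert ((km["Survival"] >= 0) & (km["Survival"] <= 1)).all()

    def test_single_group_rejected(self):
        surv = pd.DataFrame({"Time": [1.0, 2.0], "Event": [1, 1]}, index=["a", "b"])
        with pytest.raises(ValueError, match="two clusters"):
            associate_outcome(pd.Series([0, 0], index=["a", "b"]), surv)
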