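"""NMF tissue scores: factorization, AUROC ranking, constrained logistic,
projection and end-to-end classification of the synthetic reference."""

import numpy as np
import pandas as pd
import pytest

import circlex as cx
from circlex.containers import CirclexError, ConfigError
from circlex.scores import fit_nmf


@pytest.fixture(scope="module")
def trained_models():
    ref, labels = cx.generate_reference(n_nsc_like=30, seed=11)
    core = labels[labels != "nsc_like"]
    rng = np.random.default_rng(5)
    hold = rng.random(len(core)) < 0.2
    train_ids, test_ids = core.index[~hold], core.index[hold]
    V = ref[train_ids].to_numpy() - ref[train_ids].to_numpy().min()
    cache = fit_nmf(V, k=8, seed=11)
    mp = cx.train_tissue_score_model(ref[train_ids], labels[train_ids], "pluripotent", seed=11, _nmf_cache=cache)
    mn = cx.train_tissue_score_model(ref[train_ids], labels[train_ids], "brain", seed=11, _nmf_cache=cache)
    return ref, labels, test_ids, mp, mn


class TestNMF:
    def test_rank_one_exact(self):
        rng = np.random.default_rng(1)
        V = np.outer(rng.random(30), rng.random(10))
        W, H, obj = fit_nmf(V, k=1, seed=0)
        rel = np.linalg.norm(V - W @ H) / np.linalg.norm(V)
        assert rel < 1e-6

    @pytest.mark.parametrize("seed", [0, 1, 7])
    def test_objective_non_increasing(self, seed):
        rng = np.random.default_rng(seed)
        V = rng.random((50, 20))
        _, _, obj = fit_nmf(V, k=4, seed=seed, max_iter=100)
        assert all(a >= b - 1e-9 * max(a, 1) for a, b in zip(obj, obj[1:]))

    def test_reconstructs_signature_mixture(self):
        ref, _ = cx.generate_reference(seed=3)
        V = ref.to_numpy() - ref.to_numpy().min()
        W, H, _ = fit_nmf(V, k=8, seed=3)
        rel = np.linalg.norm(V - W @ H) / np.linalg.norm(V)
        assert rel < 0.15  # below the configured mixing-noise floor

    def test_negative_input_rejected(self):
        with pytest.raises(ConfigError):
            fit_nmf(np.array([[-1.0, 2.0]]), k=1)

    def test_k_too_large_rejected(self):
        with pytest.raises(ConfigError):
            fit_nmf(np.ones((3, 3)), k=4)


class TestAuroc:
    def test_perfect_separation(self):
        assert cx.auroc([1, 2, 10, 11], [False, False, True, True]) == 1.0

    def test_one_win_one_loss(self):
        assert cx.auroc([1, 2, 3], [False, True, False]) == 0.5

    def test_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(4)
        scores = rng.normal(size=200).round(1)  # rounding forces ties
        y = rng.random(200) < 0.3
        wins = ties = 0
        for i in np.where(y)[0]:
            for j in np.where(~y)[0]:
                wins += scores[i] > scores[j]
                ties += scores[i] == scores[j]
        expected = (wins + 0.5 * ties) / (y.sum() * (~y).sum())
        assert abs(cx.auroc(scores, y) - expected) < 1e-12

    def test_rank_components_sorted(self):
        rng = np.random.default_rng(6)
        H = rng.random((4, 60))
        labels = ["t"] * 20 + ["o"] * 40
        H[2, :20] += 5  # component 2 separates
        aurocs, ranking = cx.rank_components(H, labels, "t")
        assert ranking[0] == 2
        assert (np.diff(aurocs[ranking]) <= 0).all()

    def test_single_class_rejected(self):
        with pytest.raises(ConfigError):
            cx.rank_components(np.ones((2, 5)), ["a"] * 5, "a")


class TestNonnegLogistic:
    def test_separating_component_gets_positive_weight(self):
        rng = np.random.default_rng(2)
        H = rng.random((3, 80))
        y = np.array(["o"] * 40 + ["t"] * 40)
        H[1, y == "t"] += 4.0
        w, b = cx.fit_nonneg_logistic(H, y, "t")
        assert w[1] > 0
        pred = (H.T @ w + b) > 0
        assert (pred == (y == "t")).mean() == 1.0

    def test_negatively_oriented_feature_zeroed(self):
        """KKT: a feature informative only with a negative coefficient ends
        at the boundary w = 0 of the constraint set."""
        rng = np.random.default_rng(3)
        n = 120
        y = np.array(["o"] * 60 + ["t"] * 60)
        H = rng.random((2, n))
        H[0, y == "t"] -= 2.0  # anti-oriented
        w, b = cx.fit_nonneg_logistic(H, y, "t", ridge=1e-3)
        assert w[0] == pytest.approx(0.0, abs=1e-8)
        # grid check: no positive w[0] improves the objective
        def objective(w0):
            eta = H.T @ np.array([w0, w[1]]) + b
            t = (y == "t").astype(float)
            loss = np.mean(np.log1p(np.exp(-np.abs(eta))) + np.maximum(eta, 0) - t * eta)
            return loss + 0.5e-3 * (w0**2 + w[1] ** 2)
        base = objective(0.0)
        assert all(objective(v) >= base - 1e-9 for v in [0.01, 0.1, 0.5, 1.0])

    def test_shuffled_labels_near_chance(self):
        rng = np.random.default_rng(9)
        aurocs = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            H = r.random((5, 60))
            y = np.array(["t"] * 30 + ["o"] * 30)
            r.shuffle(y)
            w, b = cx.fit_nonneg_logistic(H, y, "t")
            aurocs.append(cx.auroc(H.T @ w + b, y == "t"))
        assert 0.45 <= np.mean(aurocs) <= 0.65


class TestProjection:
    def test_recovers_known_mixture(self):
        rng = np.random.default_rng(5)
        W = rng.random((100, 4)) + 0.1
        h0 = np.array([0.5, 2.0, 0.0, 1.2])
        h = cx.project_sample(W @ h0, W)
        assert np.allclose(h, h0, atol=1e-6)

    def test_zero_profile_zero_weights(self):
        W = np.random.default_rng(1).random((20, 3))
        assert np.allclose(cx.project_sample(np.zeros(20), W), 0.0)

    def test_nnls_optimality_spot_check(self):
        rng = np.random.default_rng(7)
        W = rng.random((50, 4))
        x = rng.random(50)
        h = cx.project_sample(x, W)
        best = np.linalg.norm(x - W @ h)
        for _ in range(30):
            h_alt = rng.random(4) * 2
            assert best <= np.linalg.norm(x - W @ h_alt) + 1e-12

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ConfigError):
            cx.project_sample(np.ones(5), np.ones((6, 2)))


class TestEndToEnd:
    def test_holdout_classification(self, trained_models):
        ref, labels, test_ids, mp, mn = trained_models
        scored = cx.score_samples(ref[list(test_ids)], mp, mn)
        y = labels[test_ids]
        assert cx.auroc(scored["pluripotency_score"], y == "pluripotent") >= 0.95
        assert cx.auroc(scored["neurality_score"], y == "brain") >= 0.95

    def test_weights_nonnegative(self, trained_models):
        *_, mp, mn = trained_models
        assert (mp.weights >= 0).all() and (mn.weights >= 0).all()

    def test_class_ordering_of_scores(self, trained_models):
        ref, labels, test_ids, mp, mn = trained_models
        ids = labels.index[labels.isin(["pluripotent", "brain"])]
        scored = cx.score_samples(ref[list(ids)], mp, mn)
        scored["label"] = labels[ids]
        med = scored.groupby("label").median()
        assert med.loc["pluripotent", "pluripotency_score"] > med.loc["brain", "pluripotency_score"]
        assert med.loc["brain", "neurality_score"] > med.loc["pluripotent", "neurality_score"]

    def test_nsc_like_mixtures_intermediate(self, trained_models):
        ref, labels, _, mp, mn = trained_models
        ids = labels.index[labels.isin(["pluripotent", "brain", "nsc_like"])]
        scored = cx.score_samples(ref[list(ids)], mp, mn)
        scored["label"] = labels[ids]
        med = scored.groupby("label").median()
        for axis in ("pluripotency_score", "neurality_score"):
            lo = min(med.loc["pluripotent", axis], med.loc["brain", axis])
            hi = max(med.loc["pluripotent", axis], med.loc["brain", axis])
            assert lo < med.loc["nsc_like", axis] < hi

    def test_duplicate_sample_identical_scores(self, trained_models):
        ref, _, test_ids, mp, mn = trained_models
        sid = test_ids[0]
        dup = ref[[sid, sid]].copy()
        dup.columns = ["a", "b"]
        scored = cx.score_samples(dup, mp, mn)
        assert scored.loc["a"].equals(scored.loc["b"])

    def test_model_roundtrip(self, tmp_path, trained_models):
        ref, _, test_ids, mp, _ = trained_models
        mp.save(tmp_path / "m")
        loaded = cx.TissueScoreModel.load(tmp_path / "m")
        a = mp.score(ref[list(test_ids[:3])])
        b = loaded.score(ref[list(test_ids[:3])])
        assert np.allclose(a, b)
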