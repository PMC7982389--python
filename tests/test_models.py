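import numpy as np
import pytest

from potbench.curation import PotencyMatrix
from potbench.fingerprints import fingerprint_matrix, tanimoto_kernel
from potbench.models import (
    MaskedMLPRegressor,
    masked_mse_grad,
    masked_mse_loss,
    rfr_grid,
    svr_grid,
    dnn_grid,
)
from potbench.models.training import (
    TanimotoSVR,
    grid_search_cv,
    predict,
    train_mt_dnn,
    train_st_model,
)
from potbench.splitting import SplitSpec, Strategy, derive_training_mask, make_split


class TestMaskedLoss:
    def test_single_entry_mean(self):
        pred = np.array([[1.5, 99.0]])
        labels = np.array([[1.0, 0.0]])
        mask = np.array([[True, False]])
        assert masked_mse_loss(pred, labels, mask) == pytest.approx(0.25)

    def test_full_mask_equals_dense_mse_exactly(self):
        rng = np.random.default_rng(0)
        pred = rng.normal(size=(13, 7))
        labels = rng.normal(size=(13, 7))
        mask = np.ones_like(pred, dtype=bool)
        assert masked_mse_loss(pred, labels, mask) == np.mean((pred - labels) ** 2)

    def test_two_entry_average(self):
        pred = np.array([[1.0, 0.0]])
        labels = np.array([[0.0, 0.0]])
        mask = np.array([[True, True]])
        assert masked_mse_loss(pred, labels, mask) == pytest.approx(0.5)

    def test_invariant_to_masked_out_values(self):
        rng = np.random.default_rng(1)
        pred = rng.normal(size=(5, 4))
        labels = rng.normal(size=(5, 4))
        mask = rng.random((5, 4)) < 0.5
        mask[0, 0] = True  # keep non-empty
        garbage = labels.copy()
        garbage[~mask] = 1e9
        assert masked_mse_loss(pred, labels, mask) == masked_mse_loss(pred, garbage, mask)

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError, match="mask"):
            masked_mse_loss(np.zeros((2, 2)), np.zeros((2, 2)), np.zeros((2, 2), bool))

    def test_gradient_zero_at_masked_positions(self):
        rng = np.random.default_rng(2)
        pred = rng.normal(size=(6, 3))
        labels = rng.normal(size=(6, 3))
        mask = rng.random((6, 3)) < 0.4
        mask[0, 0] = True
        grad = masked_mse_grad(pred, labels, mask)
        assert np.all(grad[~mask] == 0.0)
        # masked-in entries match central finite differences
        eps = 1e-6
        for (i, j) in zip(*np.nonzero(mask)):
            up, down = pred.copy(), pred.copy()
            up[i, j] += eps
            down[i, j] -= eps
            fd = (masked_mse_loss(up, labels, mask) - masked_mse_loss(down, labels, mask)) / (2 * eps)
            assert grad[i, j] == pytest.approx(fd, abs=1e-6)

    def test_training_ignores_masked_out_labels(self):
        """Two fits differing only at masked-out label values are identical."""
        rng = np.random.default_rng(3)
        X = (rng.random((30, 32)) < 0.3).astype(float)
        Y = rng.normal(7, 1, size=(30, 2))
        mask = rng.random((30, 2)) < 0.6
        mask[0, :] = True
        garbage = Y.copy()
        garbage[~mask] = -123.0
        kw = dict(hidden_layers=(16,), n_outputs=2, learning_rate=1e-3,
                  batch_size=8, max_epochs=10, seed=4)
        m1 = MaskedMLPRegressor(**kw).fit(X, Y, mask)
        m2 = MaskedMLPRegressor(**kw).fit(X, garbage, mask)
        assert np.array_equal(m1.predict(X), m2.predict(X))


class TestGridSearch:
    def test_single_point_grid(self):
        rng = np.random.default_rng(0)
        X = (rng.random((20, 16)) < 0.4).astype(float)
        y = rng.normal(7, 1, 20)
        res = grid_search_cv("svr", [{"C": 1.0}], X, y, seed=0)
        assert res.best_params == {"C": 1.0} and res.best_index == 0

    def test_degenerate_labels_warn_and_first_point(self):
        X = (np.random.default_rng(1).random((20, 16)) < 0.4).astype(float)
        y = np.full(20, 7.0)
        with pytest.warns(UserWarning, match="degenerate"):
            res = grid_search_cv("svr", svr_grid(), X, y, seed=0)
        assert res.best_index == 0 and res.degenerate

    def test_selection_matches_brute_force_oracle(self, dense_single_target):
        """CV selection equals an independently coded exhaustive evaluation."""
        from sklearn.model_selection import KFold
        from sklearn.svm import SVR as SkSVR

        _, library, matrix, _ = dense_single_target
        cids = [c for c, _ in library][:80]
        X = fingerprint_matrix([s for _, s in library][:80])
        t = matrix.targets[0]
        y = np.array([matrix.entries[(c, t)] for c in cids])
        for seed in (0, 1, 2):
            res = grid_search_cv("svr", svr_grid(), X, y, folds=2, seed=seed)
            # independent oracle: plain loops over the same deterministic folds
            folds = list(KFold(2, shuffle=True, random_state=seed).split(X))
            K = tanimoto_kernel(X)
            oracle_mse = []
            for params in svr_grid():
                per_fold = []
                for tr, va in folds:
                    est = SkSVR(kernel="precomputed", C=params["C"], epsilon=0.1)
                    est.fit(K[np.ix_(tr, tr)], y[tr])
                    per_fold.append(np.mean((est.predict(K[np.ix_(va, tr)]) - y[va]) ** 2))
                oracle_mse.append(np.mean(per_fold))
            assert res.best_index == int(np.argmin(oracle_mse))
            assert res.best_index > 0  # the rig: tiny C underfits badly

    def test_repeated_run_same_seed_same_selection(self, dense_single_target):
        _, library, matrix, _ = dense_single_target
        cids = [c for c, _ in library][:60]
        X = fingerprint_matrix([s for _, s in library][:60])
        t = matrix.targets[0]
        y = np.array([matrix.entries[(c, t)] for c in cids])
        r1 = grid_search_cv("rfr", rfr_grid()[:6], X, y, seed=3, n_estimators=50)
        r2 = grid_search_cv("rfr", rfr_grid()[:6], X, y, seed=3, n_estimators=50)
        assert r1.best_index == r2.best_index and r1.cv_mse == r2.cv_mse

    def test_grid_shapes_match_protocol(self):
        assert len(svr_grid()) == 6
        assert len(rfr_grid()) == 18
        assert all(g["n_estimators"] == 500 for g in rfr_grid())
        full = dnn_grid()
        assert {g["learning_rate"] for g in full} == {0.01, 0.001, 0.0001}
        assert {g["dropout"] for g in full} == {0.1, 0.25, 0.4}
        assert {g["batch_size"] for g in full} == {64, 128}
        assert {len(g["hidden_layers"]) for g in full} == {2, 3, 4}
        assert all(
            all(a >= b for a, b in zip(g["hidden_layers"], g["hidden_layers"][1:]))
            for g in full
        )


class TestSTModels:
    @pytest.mark.parametrize("family, params", [
        ("rfr", {"n_estimators": 50}),
        ("svr", {"C": 10.0}),
    ])
    def test_constant_labels_predict_constant(self, family, params):
        rng = np.random.default_rng(5)
        X = (rng.random((20, 64)) < 0.3).astype(float)
        y = np.full(20, 6.5)
        m = train_st_model(family, X, y, params=params, seed=0)
        assert np.allclose(m.model.predict(X), 6.5, atol=1e-6)

    def test_refuses_tiny_training_set(self):
        X = np.ones((5, 16))
        with pytest.raises(ValueError, match="min_train"):
            train_st_model("rfr", X, np.arange(5.0), params={}, seed=0)

    def test_duplicate_rows_have_identical_kernel_and_predictions(self):
        rng = np.random.default_rng(6)
        X = (rng.random((15, 64)) < 0.3).astype(float)
        y = rng.normal(7, 1, 15)
        Xdup = np.vstack([X, X[:3]])
        ydup = np.concatenate([y, y[:3]])
        K = tanimoto_kernel(Xdup)
        assert np.array_equal(K[0], K[15]) and np.array_equal(K[:, 0], K[:, 15])
        m = TanimotoSVR(C=10).fit(Xdup, ydup)
        pred = m.predict(Xdup)
        assert pred[0] == pytest.approx(pred[15], abs=1e-10)

    def test_rfr_memorizes_training_compounds(self, dense_single_target):
        _, library, matrix, _ = dense_single_target
        cids = [c for c, _ in library][:60]
        X = fingerprint_matrix([s for _, s in library][:60])
        t = matrix.targets[0]
        y = np.array([matrix.entries[(c, t)] for c in cids])
        m = train_st_model("rfr", X, y, params={"n_estimators": 200}, seed=0)
        assert np.mean((m.model.predict(X) - y) ** 2) < 0.05

    def test_bit_signal_learnable_by_rfr(self):
        """A single informative bit among random context bits: tree ensembles
        recover it essentially perfectly on held-out data."""
        rng = np.random.default_rng(7)
        X = (rng.random((100, 256)) < 0.1).astype(float)
        X[:50, 0], X[50:, 0] = 1.0, 0.0
        y = 6.0 + 2.0 * X[:, 0]
        perm = rng.permutation(100)
        tr, te = perm[:70], perm[70:]
        m = train_st_model("rfr", X[tr], y[tr], params={"n_estimators": 200}, seed=0)
        assert np.mean((m.model.predict(X[te]) - y[te]) ** 2) < 0.05

    def test_reproducible_with_fixed_seed(self):
        rng = np.random.default_rng(8)
        X = (rng.random((30, 64)) < 0.3).astype(float)
        y = rng.normal(7, 1, 30)
        for family, params in [
            ("rfr", {"n_estimators": 50}),
            ("svr", {"C": 1.0}),
            ("dnn", {"hidden_layers": (16,), "max_epochs": 15}),
        ]:
            m1 = train_st_model(family, X, y, params=params, seed=9)
            m2 = train_st_model(family, X, y, params=params, seed=9)
            assert np.array_equal(
                np.asarray(m1.model.predict(X)), np.asarray(m2.model.predict(X))
            )


def _tiny_mt_setup(seed=0, n=24, k=3):
    rng = np.random.default_rng(seed)
    cids = [f"c{i}" for i in range(n)]
    targets = [f"T{j}" for j in range(k)]
    X = (rng.random((n, 64)) < 0.3).astype(float)
    entries = {}
    for i, c in enumerate(cids):
        for j, t in enumerate(targets):
            if rng.random() < 0.7:
                entries[(c, t)] = float(rng.normal(7, 1))
    matrix = PotencyMatrix(cids, targets, entries)
    mask = frozenset(entries)
    return cids, targets, X, matrix, mask


class TestMTDNN:
    def test_output_width_and_finite_predictions(self):
        cids, targets, X, matrix, mask = _tiny_mt_setup()
        m = train_mt_dnn(X, matrix, mask, cids,
                         params={"hidden_layers": (16,)}, seed=0, max_epochs=5)
        pred = m.model.predict(X)
        assert pred.shape == (len(cids), len(targets))
        assert np.all(np.isfinite(pred))

    def test_all_masked_column_still_predicts(self):
        cids, targets, X, matrix, mask = _tiny_mt_setup()
        # drop one target from the training mask entirely
        mask2 = frozenset((c, t) for c, t in mask if t != targets[-1])
        m = train_mt_dnn(X, matrix, mask2, cids,
                         params={"hidden_layers": (16,)}, seed=0, max_epochs=5)
        assert np.all(np.isfinite(m.model.predict(X)[:, -1]))

    def test_empty_mask_raises(self):
        cids, targets, X, matrix, _ = _tiny_mt_setup()
        with pytest.raises(ValueError, match="mask"):
            train_mt_dnn(X, matrix, frozenset(), cids, seed=0)

    def test_single_target_matrix_reduces_to_st_shape(self):
        cids, _, X, _, _ = _tiny_mt_setup()
        rng = np.random.default_rng(1)
        entries = {(c, "T0"): float(rng.normal(7, 1)) for c in cids}
        matrix = PotencyMatrix(cids, ["T0"], entries)
        m = train_mt_dnn(X, matrix, frozenset(entries), cids,
                         params={"hidden_layers": (16,)}, seed=0, max_epochs=5)
        assert m.model.predict(X).shape == (len(cids), 1)


class TestPredict:
    def test_only_observed_pairs_returned(self):
        cids, targets, X, matrix, mask = _tiny_mt_setup()
        m = train_mt_dnn(X, matrix, mask, cids,
                         params={"hidden_layers": (16,)}, seed=0, max_epochs=5)
        ps = predict(m, X, cids, matrix)
        assert len(ps) == len(matrix.entries)
        assert set(zip(ps.compound_id, ps.target_id)) == set(matrix.entries)
        assert np.all(np.isfinite(ps.y_hat))

    def test_empty_compound_list_gives_empty_set(self):
        cids, targets, X, matrix, mask = _tiny_mt_setup()
        m = train_mt_dnn(X, matrix, mask, cids,
                         params={"hidden_layers": (16,)}, seed=0, max_epochs=5)
        assert len(predict(m, X[:0], [], matrix)) == 0

    def test_st_model_rejects_unknown_target(self):
        rng = np.random.default_rng(2)
        X = (rng.random((15, 32)) < 0.3).astype(float)
        y = rng.normal(7, 1, 15)
        cids = [f"c{i}" for i in range(15)]
        matrix = PotencyMatrix(cids, ["A", "B"], {(c, "A"): 7.0 for c in cids})
        m = train_st_model("rfr", X, y, target_id="A", params={"n_estimators": 20}, seed=0)
        with pytest.raises(ValueError, match="cannot predict"):
            predict(m, X, cids, matrix, targets=["B"])
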