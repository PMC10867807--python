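"""KRR/KREG fitting, model trees, delta-learning, model selection."""

import numpy as np
import pytest

from mlpot.data import Atom, Molecule, MolecularDatabase
from mlpot.descriptors import DescriptorSpec
from mlpot.kernels import KernelSpec, kernel_matrix, kernel_value
from mlpot.models import (
    KREG,
    ArrayDataset,
    KernelRidge,
    KREGTrainerConfig,
    ModelTreeNode,
    ValidationLossSpec,
    cross_validate,
    grid_search,
    learning_curve,
    load_model,
    save_model,
    train_delta_model,
    train_kreg,
    train_krr,
    train_self_correcting,
    validation_loss,
)
from mlpot.toys import ToyPotential, generate_database, make_diatomic


class TestKernelRidge:
    def test_single_point_reproduced(self):
        res = train_krr([[1.0, 2.0]], [3.0],
                        KernelSpec("gaussian", sigma=1.0), 0.0)
        assert res.predict([[1.0, 2.0]])[0] == pytest.approx(3.0)

    def test_interpolation_at_tiny_lambda(self):
        rng = np.random.default_rng(0)
        X, y = rng.normal(size=(15, 3)), rng.normal(size=15)
        res = train_krr(X, y, KernelSpec("gaussian", sigma=1.5), 1e-14)
        np.testing.assert_allclose(res.predict(X), y, rtol=1e-8, atol=1e-10)

    def test_large_lambda_ridge_limit(self):
        rng = np.random.default_rng(1)
        X, y = rng.normal(size=(10, 2)), rng.normal(size=10)
        res = train_krr(X, y, KernelSpec("gaussian", sigma=1.0), 1e8)
        assert np.max(np.abs(res.alpha)) < 1e-6
        np.testing.assert_allclose(res.predict(X), res.label_shift, atol=1e-6)

    def test_sin_regression_held_out(self):
        x = np.linspace(0, 2 * np.pi, 20)[:, None]
        res = train_krr(x, np.sin(x).ravel(),
                        KernelSpec("gaussian", sigma=1.0), 1e-10)
        xq = np.linspace(0.1, 2 * np.pi - 0.1, 50)[:, None]
        rmse = np.sqrt(np.mean((res.predict(xq) - np.sin(xq).ravel()) ** 2))
        assert rmse < 1e-3

    def test_alpha_solves_reference_dense_system(self):
        # oracle: independent linear-algebra path (numpy lstsq on full system)
        rng = np.random.default_rng(2)
        X, y = rng.normal(size=(12, 2)), rng.normal(size=12)
        lam = 1e-6
        res = train_krr(X, y, KernelSpec("gaussian", sigma=1.0), lam)
        K = kernel_matrix(KernelSpec("gaussian", sigma=1.0), X)
        alpha_ref = np.linalg.lstsq(
            K + lam * np.eye(12), y - y.mean(), rcond=None)[0]
        np.testing.assert_allclose(res.alpha, alpha_ref, atol=1e-8)

    def test_prediction_matches_naive_double_loop(self):
        rng = np.random.default_rng(3)
        X, y = rng.normal(size=(8, 3)), rng.normal(size=8)
        spec = KernelSpec("matern", sigma=1.2, n=1)
        res = train_krr(X, y, spec, 1e-8)
        Xq = rng.normal(size=(5, 3))
        pred = res.predict(Xq)
        for i, xq in enumerate(Xq):
            naive = sum(
                res.alpha[j] * kernel_value(spec, xq, X[j]) for j in range(8)
            ) + res.label_shift
            assert pred[i] == pytest.approx(naive, abs=1e-12)

    def test_query_permutation_permutes_outputs(self):
        rng = np.random.default_rng(4)
        X, y = rng.normal(size=(6, 2)), rng.normal(size=6)
        res = train_krr(X, y, KernelSpec("gaussian", sigma=1.0), 1e-10)
        Xq = rng.normal(size=(4, 2))
        perm = [2, 0, 3, 1]
        np.testing.assert_allclose(res.predict(Xq[perm]), res.predict(Xq)[perm])

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            KernelRidge([[0.0]], [1.0], lambda_reg=-1.0)

    def test_summary_mentions_kernel(self):
        res = train_krr([[0.0], [1.0]], [0.0, 1.0],
                        KernelSpec("gaussian", sigma=1.0), 1e-10)
        assert "gaussian" in res.summary()


class TestKREG:
    def test_gradient_training_reproduces_training_gradients(self, morse_db):
        res = train_kreg(
            morse_db, kernel=KernelSpec("gaussian", sigma=0.5),
            lambda_E=1e-12, lambda_G=1e-12, use_gradients=True,
        )
        for mol in morse_db:
            out = res.evaluate(mol)
            np.testing.assert_allclose(
                out["energy_gradients"], mol.properties["energy_gradients"],
                atol=1e-6,
            )

    def test_model_gradient_consistent_with_own_energy(self, morse_db):
        res = train_kreg(
            morse_db, kernel=KernelSpec("gaussian", sigma=0.5),
            lambda_E=1e-12, lambda_G=1e-12, use_gradients=True,
        )
        mol = make_diatomic(1.07)
        grad = res.evaluate(mol)["energy_gradients"]
        step = 1e-4
        fd = np.zeros_like(grad)
        for i in range(2):
            for c in range(3):
                probe = mol.copy()
                xyz = mol.coordinates
                xyz[i, c] += step
                probe.coordinates = xyz
                ep = res.predict_energy(probe)
                xyz[i, c] -= 2 * step
                probe.coordinates = xyz
                em = res.predict_energy(probe)
                fd[i, c] = (ep - em) / (2 * step)
        np.testing.assert_allclose(grad, fd, atol=1e-5)

    def test_gradient_training_beats_energy_only(self, morse_db, morse_test_db):
        kw = dict(kernel=KernelSpec("gaussian", sigma=0.5), lambda_E=1e-12)
        with_g = train_kreg(morse_db, lambda_G=1e-12, use_gradients=True, **kw)
        without = train_kreg(morse_db, **kw)

        def rmse(model):
            pred = np.array([model.predict_energy(m) for m in morse_test_db])
            return np.sqrt(np.mean((pred - morse_test_db.energies()) ** 2))

        assert rmse(with_g) < rmse(without)

    def test_heterogeneous_database_rejected(self):
        db = MolecularDatabase([
            make_diatomic(1.0),
            Molecule([Atom("O", [0, 0, 0]), Atom("H", [1, 0, 0])]),
        ])
        for m in db:
            m.set_property("energy", 0.0)
        with pytest.raises(ValueError, match="homogeneous"):
            KREG(db)

    def test_missing_gradients_rejected(self, morse_db):
        db = morse_db.copy()
        for m in db:
            m.properties.pop("energy_gradients")
        with pytest.raises(ValueError, match="gradient"):
            KREG(db, use_gradients=True)


class TestModelTree:
    class Const:
        def __init__(self, e, g=None):
            self.e, self.g = e, g

        def evaluate(self, mol, gradients=True):
            out = {"energy": self.e}
            if gradients and self.g is not None:
                out["energy_gradients"] = np.asarray(self.g, dtype=float)
            return out

    def test_average_and_uncertainty(self):
        node = ModelTreeNode([self.Const(1.0), self.Const(3.0)], "average")
        out = node.evaluate(make_diatomic(1.0), gradients=False)
        assert out["energy"] == pytest.approx(2.0)
        assert out["energy_uncertainty"] == pytest.approx(1.0)  # population SD

    def test_sum_of_three_children(self):
        node = ModelTreeNode(
            [self.Const(-1.0), self.Const(0.25), self.Const(0.001)], "sum"
        )
        out = node.evaluate(make_diatomic(1.0), gradients=False)
        assert out["energy"] == pytest.approx(-0.749)

    def test_gradients_averaged_componentwise(self):
        g1 = np.ones((2, 3))
        g2 = np.full((2, 3), 3.0)
        node = ModelTreeNode(
            [self.Const(0.0, g1), self.Const(0.0, g2)], "average"
        )
        out = node.evaluate(make_diatomic(1.0))
        np.testing.assert_allclose(out["energy_gradients"], 2.0)

    def test_weighted_average(self):
        node = ModelTreeNode(
            [(self.Const(0.0), 3.0), (self.Const(4.0), 1.0)], "average"
        )
        assert node.evaluate(make_diatomic(1.0), gradients=False)["energy"] \
            == pytest.approx(1.0)

    def test_empty_children_rejected(self):
        with pytest.raises(ValueError):
            ModelTreeNode([], "sum")


class TestDeltaLearning:
    R0, DE, A = 0.95, 0.17, 0.6

    @pytest.fixture
    def setup(self, triatomic):
        target = ToyPotential("morse", De=self.DE, a=self.A, r0=self.R0)
        baseline = ToyPotential(
            "harmonic_bond", k=2 * self.DE * self.A**2, r0=self.R0
        )
        train = generate_database(
            target, triatomic, 15, seed=2,
            mode="normal_displacement", sigma_disp=0.03,
        )
        test = generate_database(
            target, triatomic, 60, seed=9,
            mode="normal_displacement", sigma_disp=0.03,
        )
        cfg = KREGTrainerConfig(
            kernel=KernelSpec("gaussian", sigma=1.0), lambda_E=1e-10
        )
        return target, baseline, train, test, cfg

    def test_zero_residuals_reproduce_target(self, setup):
        target, _, train, _, cfg = setup
        comp = train_delta_model(target, train, cfg)  # baseline == target
        for mol in train:
            assert comp.evaluate(mol, gradients=False)["energy"] \
                == pytest.approx(mol.properties["energy"], abs=1e-7)

    def test_exact_sum_decomposition(self, setup):
        _, baseline, train, test, cfg = setup
        comp = train_delta_model(baseline, train, cfg)
        for mol in list(test)[:10]:
            total = comp.evaluate(mol, gradients=False)["energy"]
            base = baseline.evaluate(mol, gradients=False)["energy"]
            corr = comp.children[1][0].evaluate(mol, gradients=False)["energy"]
            assert total - base - corr == pytest.approx(0.0, abs=1e-14)

    def test_composite_beats_direct_ml(self, setup):
        target, baseline, train, test, cfg = setup
        comp = train_delta_model(baseline, train, cfg)
        direct = cfg.train(train)

        def rmse(model):
            res = [
                model.evaluate(m, gradients=False)["energy"]
                - m.properties["energy"]
                for m in test
            ]
            return float(np.sqrt(np.mean(np.square(res))))

        assert rmse(comp) < rmse(direct)


class TestSelfCorrection:
    def test_one_layer_equals_plain_model(self, morse_db):
        cfg = KREGTrainerConfig(
            kernel=KernelSpec("gaussian", sigma=0.5), lambda_E=1e-10
        )
        stack = train_self_correcting(morse_db, 1, cfg)
        plain = cfg.train(morse_db)
        mol = make_diatomic(1.02)
        assert stack.evaluate(mol, gradients=False)["energy"] == pytest.approx(
            plain.predict_energy(mol), abs=1e-12
        )

    def test_training_residual_norm_non_increasing(self, morse_db):
        cfg = KREGTrainerConfig(
            kernel=KernelSpec("gaussian", sigma=0.5), lambda_E=1e-6
        )
        norms = []
        for n_layers in (1, 2, 3):
            stack = train_self_correcting(morse_db, n_layers, cfg)
            resid = [
                stack.evaluate(m, gradients=False)["energy"]
                - m.properties["energy"]
                for m in morse_db
            ]
            norms.append(np.linalg.norm(resid))
        assert norms[1] <= norms[0] + 1e-12
        assert norms[2] <= norms[1] + 1e-12


class TestValidationLoss:
    def test_geometric_mean(self):
        spec = ValidationLossSpec("geometric_mean")
        assert validation_loss(4.0, 1.0, spec) == pytest.approx(2.0)

    def test_weighted_sum(self):
        spec = ValidationLossSpec("weighted_sum", weight=0.5)
        assert validation_loss(4.0, 1.0, spec) == pytest.approx(4.5)

    def test_custom_passthrough(self):
        spec = ValidationLossSpec("custom", custom_fn=lambda e, g: e * 10)
        assert validation_loss(0.3, None, spec) == pytest.approx(3.0)

    def test_geometric_mean_requires_gradients(self):
        with pytest.raises(ValueError, match="gradient"):
            validation_loss(1.0, None, ValidationLossSpec("geometric_mean"))


def _gp_style_data(sigma_star=2.0, n=60, seed=42):
    rng = np.random.default_rng(seed)
    X = rng.uniform(-4, 4, size=(n, 2))
    centers = rng.uniform(-4, 4, size=(8, 2))
    w = rng.normal(size=8)
    y = kernel_matrix(KernelSpec("gaussian", sigma=sigma_star), X, centers) @ w
    return ArrayDataset(X, y)


def _sigma_trainer(X, y, sigma):
    return train_krr(X, y, KernelSpec("gaussian", sigma=sigma), 1e-10)


class TestGridSearch:
    def test_recovers_generating_sigma(self):
        data = _gp_style_data(sigma_star=2.0)
        result = grid_search(_sigma_trainer, data, {"sigma": [0.5, 2, 8]}, seed=3)
        assert result.best_params == {"sigma": 2}

    def test_single_candidate_returned(self):
        data = _gp_style_data()
        result = grid_search(_sigma_trainer, data, {"sigma": [1.0]}, seed=0)
        assert result.best_params == {"sigma": 1.0}
        assert len(result.table) == 1

    def test_table_is_exhaustive_product(self):
        data = _gp_style_data()

        def trainer(X, y, sigma, lambda_reg):
            return train_krr(X, y, KernelSpec("gaussian", sigma=sigma),
                             lambda_reg)

        result = grid_search(
            trainer, data,
            {"sigma": [0.5, 1, 2], "lambda_reg": [1e-10, 1e-6]}, seed=0,
        )
        assert len(result.table) == 6
        assert "loss" in result.table[0]

    def test_final_model_retrained_on_full_set(self):
        data = _gp_style_data()
        result = grid_search(_sigma_trainer, data, {"sigma": [2.0]}, seed=0)
        assert len(result.final_model.alpha) == len(data)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            grid_search(_sigma_trainer, _gp_style_data(), {"sigma": []})


class TestCrossValidation:
    def test_loo_on_linear_data_with_linear_kernel(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(12, 3))
        data = ArrayDataset(X, X @ np.array([1.0, -2.0, 0.5]))

        def trainer(Xs, ys):
            # a constant offset is outside the linear-kernel span: no shift
            return train_krr(Xs, ys, KernelSpec("linear"), 1e-12,
                             shift_labels=False)

        mean, per_fold = cross_validate(trainer, data, k_folds=12, seed=0)
        assert mean < 1e-8
        assert len(per_fold) == 12

    def test_fold_sizes_differ_by_at_most_one(self):
        data = _gp_style_data(n=23)
        sizes = []

        def trainer(Xs, ys):
            sizes.append(len(ys))
            return train_krr(Xs, ys, KernelSpec("gaussian", sigma=2.0), 1e-8)

        cross_validate(trainer, data, k_folds=5, seed=1)
        test_sizes = [23 - s for s in sizes]
        assert max(test_sizes) - min(test_sizes) <= 1
        assert sum(test_sizes) == 23

    def test_same_seed_same_folds(self):
        data = _gp_style_data(n=20)
        losses = [
            cross_validate(
                lambda Xs, ys: train_krr(
                    Xs, ys, KernelSpec("gaussian", sigma=2.0), 1e-8),
                data, 4, seed=7,
            )[1]
            for _ in range(2)
        ]
        np.testing.assert_array_equal(losses[0], losses[1])

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError):
            cross_validate(_sigma_trainer, _gp_style_data(n=5), k_folds=6)


class TestLearningCurve:
    def test_morse_error_strictly_decreasing(self, morse, diatomic):
        db = generate_database(
            morse, diatomic, 60, seed=4, mode="uniform_bond",
            bond_range=(0.75, 1.4),
        )
        cfg = KREGTrainerConfig(
            kernel=KernelSpec("gaussian", sigma=0.5), lambda_E=1e-12
        )
        rows = learning_curve(
            lambda d: cfg.train(d), db, [5, 10, 20, 40], n_repeats=5, seed=5
        )
        losses = [r["mean_loss"] for r in rows]
        assert all(a > b for a, b in zip(losses, losses[1:]))
        assert len(rows) == 4

    def test_size_exhausting_pool_single_repeat(self):
        data = _gp_style_data(n=20)
        rows = learning_curve(_lc_trainer, data, [15], n_repeats=5, seed=0)
        assert rows[0]["n_repeats"] == 1

    def test_oversized_training_set_rejected(self):
        data = _gp_style_data(n=20)
        with pytest.raises(ValueError):
            learning_curve(_lc_trainer, data, [20], n_repeats=2, seed=0)


def _lc_trainer(X, y):
    return train_krr(X, y, KernelSpec("gaussian", sigma=2.0), 1e-10)


class TestSerialization:
    @pytest.mark.parametrize("fmt", ["json", "npz"])
    def test_round_trip_predictions(self, tmp_path, fmt):
        rng = np.random.default_rng(5)
        X, y = rng.normal(size=(10, 3)), rng.normal(size=10)
        res = train_krr(X, y, KernelSpec("matern", sigma=1.1, n=1), 1e-9)
        path = tmp_path / f"model.{fmt}"
        save_model(res, path, fmt=fmt)
        back = load_model(path, fmt=fmt)
        Xq = rng.normal(size=(6, 3))
        np.testing.assert_allclose(back.predict(Xq), res.predict(Xq),
                                   atol=1e-14)
        assert back.kernel.family == "matern"
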