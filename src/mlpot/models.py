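"""Kernel ridge regression models, composite model trees, model selection.

The regression core follows the model/results convention: a model object is
built from data and hyperparameters, ``fit()`` solves the linear system and
returns a results object that carries the coefficients, predicts new points,
and prints a summary.

Two model classes are provided:

* :class:`KernelRidge` — KRR on raw input vectors ``X`` with labels ``y``:
  f(x) = sum_j alpha_j k(x, x_j) + shift, with (K + lambda I) alpha = y - shift.
* :class:`KREG` — a molecular potential: KRR on a geometry descriptor
  (default: equilibrium-normalized inverse distances with a Gaussian
  kernel), optionally trained on Cartesian energy gradients as well.
  Gradient training augments the kernel matrix with first- and
  second-derivative blocks obtained through the descriptor Jacobian chain
  rule, with separate regularizers for energy and gradient rows.

Composite models are model trees: leaves are any objects with an
``evaluate(molecule) -> dict`` method, internal nodes combine children by
``sum`` or (weighted) ``average``; averaging nodes also report the
population standard deviation of the children's energies as an ensemble
uncertainty.  Delta-learning (baseline + ML correction on residuals) and
self-correcting stacks (each layer fits the residual left by the previous
layers) are built on top of the tree type.

Model selection: hold-out grid search, k-fold cross-validation and learning
curves, driven by a validation loss that can be the energy RMSE, the
geometric mean of energy and gradient RMSEs, a weighted sum, or a custom
callable.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import scipy.linalg

from .data import Molecule, MolecularDatabase
from .descriptors import DescriptorSpec, descriptor, descriptor_jacobian
from .kernels import KernelSpec, kernel_derivatives, kernel_matrix, kernel_value

__all__ = [
    "KernelRidge",
    "KernelRidgeResults",
    "KREG",
    "KREGResults",
    "ModelTreeNode",
    "train_krr",
    "predict_krr",
    "train_kreg",
    "train_delta_model",
    "train_self_correcting",
    "ValidationLossSpec",
    "validation_loss",
    "grid_search",
    "cross_validate",
    "learning_curve",
    "ArrayDataset",
    "save_model",
    "load_model",
]

_JITTERS = (0.0, 1e-12, 1e-10, 1e-8)


def _solve_spd(K: np.ndarray, lam_diag: np.ndarray, rhs: np.ndarray) -> np.ndarray:
    """Solve (K + diag(lam_diag)) a = rhs, Cholesky first.

    Escalating jitter covers the numerically semidefinite case.  Kernel
    matrices that are symmetric but slightly indefinite (the periodic
    families on multivariate inputs are not guaranteed PSD) fall back to a
    symmetric LDL^T solve; only a genuinely singular system raises.
    """
    A0 = K + np.diag(lam_diag)
    for jitter in _JITTERS:
        try:
            c, low = scipy.linalg.cho_factor(
                A0 + jitter * np.eye(len(A0)), lower=True
            )
            return scipy.linalg.cho_solve((c, low), rhs)
        except np.linalg.LinAlgError:
            continue
    try:
        alpha = scipy.linalg.solve(A0, rhs, assume_a="sym")
    except (np.linalg.LinAlgError, scipy.linalg.LinAlgError):
        alpha = None
    if alpha is not None and np.all(np.isfinite(alpha)):
        resid = np.linalg.norm(A0 @ alpha - rhs)
        if resid <= 1e-6 * max(np.linalg.norm(rhs), 1.0):
            return alpha
    raise np.linalg.LinAlgError(
        "kernel system is singular even with jitter; "
        "increase the regularization parameter lambda"
    )


# ---------------------------------------------------------------------------
# KRR on raw vectors
# ---------------------------------------------------------------------------

class KernelRidge:
    """Kernel ridge regression on raw input vectors.

    Parameters
    ----------
    X : (N, D) array of training inputs.
    y : (N,) array of labels.
    kernel : KernelSpec, default Gaussian with sigma=1.
    lambda_reg : ridge regularizer lambda >= 0.
    shift_labels : subtract the training-label mean before solving
        (restored on prediction); improves conditioning.
    """

    def __init__(
        self,
        X: np.ndarray,
        y: np.ndarray,
        kernel: KernelSpec | None = None,
        lambda_reg: float = 1e-10,
        shift_labels: bool = True,
    ) -> None:
        self.X = np.atleast_2d(np.asarray(X, dtype=float))
        self.y = np.asarray(y, dtype=float).ravel()
        if self.X.shape[0] != self.y.size:
            raise ValueError("X and y must have the same number of rows")
        if lambda_reg < 0:
            raise ValueError("lambda_reg must be >= 0")
        self.kernel = kernel if kernel is not None else KernelSpec("gaussian", sigma=1.0)
        self.lambda_reg = float(lambda_reg)
        self.shift_labels = shift_labels

    def fit(self) -> "KernelRidgeResults":
        shift = float(np.mean(self.y)) if self.shift_labels else 0.0
        K = kernel_matrix(self.kernel, self.X)
        lam = np.full(len(K), self.lambda_reg)
        alpha = _solve_spd(K, lam, self.y - shift)
        return KernelRidgeResults(self, alpha, shift)


class KernelRidgeResults:
    """Fitted KRR model: coefficients alpha, label shift, predictions."""

    def __init__(self, model: KernelRidge, alpha: np.ndarray, shift: float) -> None:
        self.model = model
        self.alpha = alpha
        self.label_shift = shift

    @property
    def kernel(self) -> KernelSpec:
        return self.model.kernel

    def predict(self, Xq: np.ndarray) -> np.ndarray:
        Xq = np.atleast_2d(np.asarray(Xq, dtype=float))
        K = kernel_matrix(self.kernel, Xq, self.model.X)
        return K @ self.alpha + self.label_shift

    def fittedvalues(self) -> np.ndarray:
        return self.predict(self.model.X)

    def resid(self) -> np.ndarray:
        return self.fittedvalues() - self.model.y

    def summary(self) -> str:
        from .data import error_statistics

        stats = error_statistics(self.fittedvalues(), self.model.y)
        head = (
            f"Kernel ridge regression ({self.kernel.family} kernel)\n"
            f"  N_train = {len(self.alpha)}, lambda = {self.model.lambda_reg:g}, "
            f"label shift = {self.label_shift:g}\n"
            f"  hyperparameters: sigma={self.kernel.sigma}, n={self.kernel.n}, "
            f"p={self.kernel.p}, sigma_p={self.kernel.sigma_p}\n"
            "Training-set fit:\n"
        )
        return head + str(stats)


def train_krr(X, y, kernel=None, lambda_reg=1e-10,
              shift_labels=True) -> KernelRidgeResults:
    """Functional wrapper: build and fit a :class:`KernelRidge`."""
    return KernelRidge(
        X, y, kernel=kernel, lambda_reg=lambda_reg, shift_labels=shift_labels
    ).fit()


def predict_krr(results: KernelRidgeResults, Xq) -> np.ndarray:
    return results.predict(Xq)


# ---------------------------------------------------------------------------
# KREG: molecular potential with optional gradient training
# ---------------------------------------------------------------------------

def _grad_wrt_second(spec: KernelSpec, xi: np.ndarray, xj: np.ndarray) -> np.ndarray:
    # dk(xi, xj)/dxj = dk(xj, xi)/d(first arg) by kernel symmetry
    return kernel_derivatives(spec, xj, xi)[0]


class KREG:
    """Kernel-method potential on a molecular database.

    Trains on energies and, optionally, Cartesian energy gradients.  The
    default descriptor is the equilibrium-normalized inverse internuclear
    distance vector (reference = lowest-energy training geometry) with a
    Gaussian kernel.

    Parameters
    ----------
    db : homogeneous MolecularDatabase with ``energy`` labels (and
        ``energy_gradients`` when ``use_gradients``).
    descriptor : DescriptorSpec; default RE on the lowest-energy geometry.
    kernel : KernelSpec; default Gaussian, sigma=1.
    lambda_E, lambda_G : regularizers for the energy and gradient rows.
        Gradient labels live on a different scale than energies, hence the
        separate knob; ``lambda_G`` defaults to ``lambda_E``.
    use_gradients : include gradient observations in the training system.
    """

    def __init__(
        self,
        db: MolecularDatabase,
        descriptor: DescriptorSpec | None = None,
        kernel: KernelSpec | None = None,
        lambda_E: float = 1e-10,
        lambda_G: float | None = None,
        use_gradients: bool = False,
    ) -> None:
        if not db.is_homogeneous:
            raise ValueError(
                "descriptor-based models require a homogeneous database "
                "(identical element sequence across molecules)"
            )
        if any("energy" not in m.properties for m in db):
            raise ValueError("every molecule needs an energy label")
        if use_gradients and any(
            "energy_gradients" not in m.properties for m in db
        ):
            raise ValueError("gradient training requires gradient labels")
        self.db = db
        if descriptor is None:
            i_min = int(np.argmin(db.energies()))
            descriptor = DescriptorSpec("RE", reference_geometry=db[i_min].copy())
        self.descriptor = descriptor
        self.kernel = kernel if kernel is not None else KernelSpec("gaussian", sigma=1.0)
        self.lambda_E = float(lambda_E)
        self.lambda_G = float(lambda_E if lambda_G is None else lambda_G)
        self.use_gradients = use_gradients

    def fit(self) -> "KREGResults":
        db = self.db
        spec, kspec = self.descriptor, self.kernel
        X = np.array([descriptor(m, spec) for m in db])
        y = db.energies()
        shift = float(np.mean(y))
        N = len(db)

        if not self.use_gradients:
            K = kernel_matrix(kspec, X)
            alpha = _solve_spd(K, np.full(N, self.lambda_E), y - shift)
            return KREGResults(self, X, None, alpha, shift)

        jacs = [descriptor_jacobian(m, spec) for m in db]
        n3 = jacs[0].shape[1]
        M = N * (1 + n3)
        K = np.empty((M, M))
        # energy-energy block
        K[:N, :N] = kernel_matrix(kspec, X)
        # energy-gradient and gradient-gradient blocks
        for j in range(N):
            cols = slice(N + j * n3, N + (j + 1) * n3)
            for i in range(N):
                gj = _grad_wrt_second(kspec, X[i], X[j])
                K[i, cols] = jacs[j].T @ gj
            for i in range(N):
                rows = slice(N + i * n3, N + (i + 1) * n3)
                _, H = kernel_derivatives(kspec, X[i], X[j])
                K[rows, cols] = jacs[i].T @ H @ jacs[j]
        K[N:, :N] = K[:N, N:].T
        K = 0.5 * (K + K.T)
        rhs = np.concatenate([y - shift, db.gradients().reshape(N * n3)])
        lam = np.concatenate(
            [np.full(N, self.lambda_E), np.full(N * n3, self.lambda_G)]
        )
        coeffs = _solve_spd(K, lam, rhs)
        return KREGResults(self, X, jacs, coeffs, shift)


class KREGResults:
    """Fitted molecular kernel model: predicts energy and Cartesian gradients.

    Implements the evaluator protocol used across the package:
    ``evaluate(molecule, gradients=True) -> dict`` with keys ``energy``
    (hartree) and ``energy_gradients`` (natoms x 3, hartree/angstrom).
    """

    def __init__(self, model, X_train, jacs_train, coeffs, shift) -> None:
        self.model = model
        self.X_train = X_train
        self.jacs_train = jacs_train
        self.coeffs = coeffs
        self.label_shift = shift

    @property
    def alpha(self) -> np.ndarray:
        return self.coeffs

    @property
    def gradient_trained(self) -> bool:
        return self.jacs_train is not None

    def _energy_grad_descriptor(self, xq: np.ndarray) -> tuple[float, np.ndarray]:
        """Model value and its gradient in descriptor space at xq."""
        kspec = self.model.kernel
        X = self.X_train
        N = X.shape[0]
        e = self.label_shift
        dE_dx = np.zeros_like(xq)
        kvals = kernel_matrix(kspec, xq[None, :], X)[0]
        if not self.gradient_trained:
            e += kvals @ self.coeffs
            for j in range(N):
                g, _ = kernel_derivatives(kspec, xq, X[j])
                dE_dx += self.coeffs[j] * g
            return float(e), dE_dx
        n3 = self.jacs_train[0].shape[1]
        a = self.coeffs[:N]
        b = self.coeffs[N:].reshape(N, n3)
        e += kvals @ a
        for j in range(N):
            g, H = kernel_derivatives(kspec, xq, X[j])
            # derivative-center basis function and its descriptor gradient
            gj = _grad_wrt_second(kspec, xq, X[j])
            e += (self.jacs_train[j].T @ gj) @ b[j]
            dE_dx += a[j] * g + H @ (self.jacs_train[j] @ b[j])
        return float(e), dE_dx

    def evaluate(self, mol: Molecule, gradients: bool = True) -> dict:
        xq = descriptor(mol, self.model.descriptor)
        e, dE_dx = self._energy_grad_descriptor(xq)
        out = {"energy": e}
        if gradients:
            Jq = descriptor_jacobian(mol, self.model.descriptor)
            out["energy_gradients"] = (Jq.T @ dE_dx).reshape(mol.natoms, 3)
        return out

    def predict_energy(self, mol: Molecule) -> float:
        return self.evaluate(mol, gradients=False)["energy"]

    def summary(self) -> str:
        from .data import error_statistics

        db = self.model.db
        fitted = np.array([self.predict_energy(m) for m in db])
        stats = error_statistics(fitted, db.energies())
        kind = "energy+gradient" if self.gradient_trained else "energy-only"
        head = (
            f"Kernel-method potential ({self.model.kernel.family} kernel on "
            f"{self.model.descriptor.kind} descriptor, {kind} training)\n"
            f"  N_train = {len(db)}, lambda_E = {self.model.lambda_E:g}, "
            f"lambda_G = {self.model.lambda_G:g}\n"
            "Training-set energy fit:\n"
        )
        return head + str(stats)


def train_kreg(
    db: MolecularDatabase,
    descriptor_spec: DescriptorSpec | None = None,
    kernel: KernelSpec | None = None,
    lambda_E: float = 1e-10,
    lambda_G: float | None = None,
    use_gradients: bool = False,
) -> KREGResults:
    """Functional wrapper: build and fit a :class:`KREG` potential."""
    return KREG(
        db,
        descriptor=descriptor_spec,
        kernel=kernel,
        lambda_E=lambda_E,
        lambda_G=lambda_G,
        use_gradients=use_gradients,
    ).fit()


# ---------------------------------------------------------------------------
# Model trees: composition, delta-learning, self-correction
# ---------------------------------------------------------------------------

class ModelTreeNode:
    """Composite model: combines children's predictions by sum or average.

    ``children`` is a list of ``(model, weight)`` pairs or bare models
    (weight 1); every child must implement ``evaluate(mol) -> dict``.  For
    ``operation='average'`` with >= 2 children the node also reports the
    population standard deviation of the children's energies under the key
    ``energy_uncertainty``.
    """

    def __init__(self, children, operation: str = "sum") -> None:
        if operation not in ("sum", "average"):
            raise ValueError("operation must be 'sum' or 'average'")
        norm = []
        for ch in children:
            if isinstance(ch, tuple):
                model, w = ch
            else:
                model, w = ch, 1.0
            if not np.isfinite(w):
                raise ValueError("child weight must be finite")
            norm.append((model, float(w)))
        if not norm:
            raise ValueError("a model tree node needs at least one child")
        self.children = norm
        self.operation = operation

    def evaluate(self, mol: Molecule, gradients: bool = True) -> dict:
        results = []
        for model, w in self.children:
            try:
                r = model.evaluate(mol, gradients=gradients)
            except TypeError:
                r = model.evaluate(mol)
            results.append((r, w))
        keys = set(results[0][0])
        for r, _ in results[1:]:
            keys &= set(r)
        if "energy" not in keys:
            raise ValueError("every child must provide an energy")
        if gradients and any("energy_gradients" not in r for r, _ in results):
            gradients = False
        out = {}
        wsum = sum(w for _, w in self.children)
        for key in keys:
            vals = [np.asarray(r[key], dtype=float) * w for r, w in results]
            total = sum(vals)
            if self.operation == "average":
                total = total / wsum
            out[key] = float(total) if np.ndim(total) == 0 else total
        if self.operation == "average" and len(results) >= 2:
            energies = np.array([r["energy"] for r, _ in results])
            out["energy_uncertainty"] = float(np.std(energies))
        return out

    def predict_energy(self, mol: Molecule) -> float:
        return self.evaluate(mol, gradients=False)["energy"]


def model_tree_predict(node: ModelTreeNode, mol: Molecule) -> dict:
    """Functional alias for ``node.evaluate(mol)``."""
    return node.evaluate(mol)


@dataclass
class KREGTrainerConfig:
    """Hyperparameters forwarded to :class:`KREG` by the composite trainers."""

    descriptor: DescriptorSpec | None = None
    kernel: KernelSpec | None = None
    lambda_E: float = 1e-10
    lambda_G: float | None = None
    use_gradients: bool = False

    def train(self, db: MolecularDatabase) -> KREGResults:
        return KREG(
            db,
            descriptor=self.descriptor,
            kernel=self.kernel,
            lambda_E=self.lambda_E,
            lambda_G=self.lambda_G,
            use_gradients=self.use_gradients,
        ).fit()


def train_delta_model(
    baseline, db: MolecularDatabase, trainer_config: KREGTrainerConfig | None = None
) -> ModelTreeNode:
    """Delta-learning: correct a low-level baseline toward target labels.

    The correction model is trained on residuals (target - baseline) over
    the database geometries; the returned tree predicts
    baseline + correction (exact sum decomposition at every query).
    """
    cfg = trainer_config or KREGTrainerConfig()
    resid_db = MolecularDatabase()
    for mol in db:
        base = baseline.evaluate(mol, gradients=cfg.use_gradients)
        m = mol.copy()
        m.set_property("energy", mol.properties["energy"] - base["energy"])
        if cfg.use_gradients:
            m.set_property(
                "energy_gradients",
                mol.properties["energy_gradients"] - base["energy_gradients"],
            )
        resid_db.append(m)
    correction = cfg.train(resid_db)
    return ModelTreeNode([baseline, correction], operation="sum")


def train_self_correcting(
    db: MolecularDatabase,
    n_layers: int,
    trainer_config: KREGTrainerConfig | None = None,
) -> ModelTreeNode:
    """Stack of models, each fitting the residual left by the previous sum."""
    if n_layers < 1:
        raise ValueError("n_layers must be >= 1")
    cfg = trainer_config or KREGTrainerConfig()
    layers = []
    work = db.copy()
    for _ in range(n_layers):
        layer = cfg.train(work)
        layers.append(layer)
        for mol in work:
            pred = layer.evaluate(mol, gradients=cfg.use_gradients)
            mol.set_property("energy", mol.properties["energy"] - pred["energy"])
            if cfg.use_gradients:
                mol.set_property(
                    "energy_gradients",
                    mol.properties["energy_gradients"] - pred["energy_gradients"],
                )
    return ModelTreeNode(layers, operation="sum")


# ---------------------------------------------------------------------------
# Validation loss, grid search, cross-validation, learning curves
# ---------------------------------------------------------------------------

@dataclass
class ValidationLossSpec:
    """How energy and gradient RMSEs combine into one scalar loss.

    modes: ``energy_only`` (RMSE_E), ``geometric_mean``
    (sqrt(RMSE_E * RMSE_G)), ``weighted_sum`` (RMSE_E + weight * RMSE_G), or
    ``custom`` (``custom_fn(rmse_E, rmse_G)``).
    """

    mode: str = "energy_only"
    weight: float = 1.0
    custom_fn: Callable[[float, float | None], float] | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("energy_only", "geometric_mean", "weighted_sum", "custom"):
            raise ValueError(f"unknown loss mode {self.mode!r}")
        if self.mode == "weighted_sum" and self.weight <= 0:
            raise ValueError("weighted_sum requires weight > 0")
        if self.mode == "custom" and self.custom_fn is None:
            raise ValueError("custom mode requires custom_fn")

    @property
    def needs_gradients(self) -> bool:
        return self.mode in ("geometric_mean", "weighted_sum")


def validation_loss(
    rmse_E: float, rmse_G: float | None, spec: ValidationLossSpec
) -> float:
    """Combine energy/gradient RMSEs per the loss specification."""
    if spec.mode == "energy_only":
        return float(rmse_E)
    if spec.mode == "custom":
        return float(spec.custom_fn(rmse_E, rmse_G))
    if rmse_G is None:
        raise ValueError(f"loss mode {spec.mode!r} requires a gradient RMSE")
    if spec.mode == "geometric_mean":
        return float(np.sqrt(rmse_E * rmse_G))
    return float(rmse_E + spec.weight * rmse_G)


class ArrayDataset:
    """Minimal (X, y) dataset exposing the same subset API as a database."""

    def __init__(self, X: np.ndarray, y: np.ndarray) -> None:
        self.X = np.atleast_2d(np.asarray(X, dtype=float))
        self.y = np.asarray(y, dtype=float).ravel()
        if self.X.shape[0] != self.y.size:
            raise ValueError("X and y must have the same number of rows")

    def __len__(self) -> int:
        return self.X.shape[0]

    def take(self, indices) -> "ArrayDataset":
        idx = np.asarray(indices, dtype=int)
        return ArrayDataset(self.X[idx], self.y[idx])


def _measure(model, data, needs_gradients: bool) -> tuple[float, float | None]:
    """(RMSE_E, RMSE_G) of a fitted model on a held-out dataset."""
    if isinstance(data, ArrayDataset):
        pred = model.predict(data.X)
        return float(np.sqrt(np.mean((pred - data.y) ** 2))), None
    e_res, g_res = [], []
    for mol in data:
        out = model.evaluate(mol, gradients=needs_gradients)
        e_res.append(out["energy"] - mol.properties["energy"])
        if needs_gradients:
            g_res.append(
                (out["energy_gradients"] - mol.properties["energy_gradients"]).ravel()
            )
    rmse_E = float(np.sqrt(np.mean(np.square(e_res))))
    rmse_G = (
        float(np.sqrt(np.mean(np.square(np.concatenate(g_res)))))
        if g_res
        else None
    )
    return rmse_E, rmse_G


@dataclass
class GridSearchResult:
    best_params: dict
    best_loss: float
    table: list[dict] = field(repr=False)
    final_model: object = None

    def table_csv(self) -> str:
        keys = list(self.table[0])
        lines = [",".join(keys)]
        for row in self.table:
            lines.append(",".join(f"{row[k]}" for k in keys))
        return "\n".join(lines) + "\n"


def _fit_candidate(train_fn, data, params):
    if isinstance(data, ArrayDataset):
        return train_fn(data.X, data.y, **params)
    return train_fn(data, **params)


def grid_search(
    train_fn: Callable,
    data,
    grids: dict[str, Sequence],
    loss_spec: ValidationLossSpec | None = None,
    validation_fraction: float = 0.2,
    seed: int = 0,
    retrain_on_full: bool = True,
) -> GridSearchResult:
    """Exhaustive hyperparameter search on a hold-out subtraining/validation split.

    ``train_fn(data_subset, **params)`` (or ``train_fn(X, y, **params)`` for
    an :class:`ArrayDataset`) must return a fitted model.  Every point of
    the Cartesian product of ``grids`` is evaluated on the validation
    subset; ties break toward smaller ``sigma`` then smaller ``lambda``.
    The winning hyperparameters are finally retrained on the full training
    set (the standard closed-form advantage of kernel methods).
    """
    loss_spec = loss_spec or ValidationLossSpec()
    if not grids or any(len(v) == 0 for v in grids.values()):
        raise ValueError("grids must be non-empty")
    N = len(data)
    rng = np.random.default_rng(seed)
    order = rng.permutation(N)
    n_val = max(1, int(round(validation_fraction * N)))
    val_idx, sub_idx = order[:n_val], order[n_val:]
    data_sub, data_val = data.take(sub_idx), data.take(val_idx)

    names = list(grids)
    table: list[dict] = []
    candidates: list[tuple[float, dict]] = []
    for combo in itertools.product(*(grids[n] for n in names)):
        params = dict(zip(names, combo))
        try:
            model = _fit_candidate(train_fn, data_sub, params)
            rmse_E, rmse_G = _measure(model, data_val, loss_spec.needs_gradients)
            loss = validation_loss(rmse_E, rmse_G, loss_spec)
        except (np.linalg.LinAlgError, ValueError) as exc:
            table.append({**params, "loss": float("nan"), "error": str(exc)})
            continue
        table.append({**params, "loss": loss})
        candidates.append((loss, params))
    if not candidates:
        raise RuntimeError("every hyperparameter candidate failed to train")

    def tie_key(item):
        loss, params = item
        return (
            loss,
            params.get("sigma", np.inf),
            params.get("lambda_reg", params.get("lambda_E", np.inf)),
        )

    best_loss, best_params = min(candidates, key=tie_key)
    final = None
    if retrain_on_full:
        final = _fit_candidate(train_fn, data, best_params)
    return GridSearchResult(best_params, best_loss, table, final)


def cross_validate(
    train_fn: Callable,
    data,
    k_folds: int,
    loss_spec: ValidationLossSpec | None = None,
    seed: int = 0,
) -> tuple[float, list[float]]:
    """k-fold cross-validation (k = N is leave-one-out).

    Folds are a seeded permutation cut into k near-equal parts (sizes differ
    by at most one); returns the mean loss and the per-fold losses.
    """
    loss_spec = loss_spec or ValidationLossSpec()
    N = len(data)
    if not 2 <= k_folds <= N:
        raise ValueError(f"k_folds must be in [2, {N}]")
    rng = np.random.default_rng(seed)
    order = rng.permutation(N)
    folds = np.array_split(order, k_folds)
    losses = []
    for i, test_idx in enumerate(folds):
        train_idx = np.concatenate([f for j, f in enumerate(folds) if j != i])
        model = _fit_candidate(train_fn, data.take(train_idx), {})
        rmse_E, rmse_G = _measure(model, data.take(test_idx), loss_spec.needs_gradients)
        losses.append(validation_loss(rmse_E, rmse_G, loss_spec))
    return float(np.mean(losses)), losses


def learning_curve(
    train_fn: Callable,
    data,
    train_sizes: Sequence[int],
    n_repeats: int = 5,
    loss_spec: ValidationLossSpec | None = None,
    seed: int = 0,
) -> list[dict]:
    """Test error versus training-set size.

    A fixed test set (everything beyond the largest training size) is held
    out once; for each size, ``n_repeats`` random draws from the remaining
    pool are trained and evaluated on that same test set.  Returns one row
    per size with mean loss and the standard deviation across repeats.
    """
    loss_spec = loss_spec or ValidationLossSpec()
    sizes = sorted(int(s) for s in train_sizes)
    N = len(data)
    if sizes[-1] >= N:
        raise ValueError("largest training size must leave a non-empty test set")
    rng = np.random.default_rng(seed)
    order = rng.permutation(N)
    pool, test_idx = order[: sizes[-1]], order[sizes[-1]:]
    data_test = data.take(test_idx)
    rows = []
    for size in sizes:
        losses = []
        repeats = n_repeats if size < len(pool) else 1
        for _ in range(repeats):
            draw = rng.choice(pool, size=size, replace=False)
            model = _fit_candidate(train_fn, data.take(draw), {})
            rmse_E, rmse_G = _measure(model, data_test, loss_spec.needs_gradients)
            losses.append(validation_loss(rmse_E, rmse_G, loss_spec))
        rows.append(
            {
                "size": size,
                "mean_loss": float(np.mean(losses)),
                "std_loss": float(np.std(losses)),
                "n_repeats": repeats,
            }
        )
    return rows


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def _kernel_to_dict(spec: KernelSpec) -> dict:
    return {
        "family": spec.family,
        "sigma": spec.sigma,
        "n": spec.n,
        "p": spec.p,
        "sigma_p": spec.sigma_p,
    }


def save_model(results: KernelRidgeResults, path, fmt: str = "json") -> None:
    """Persist a raw-vector KRR model (kernel spec, alpha, training inputs)."""
    payload = {
        "kernel": _kernel_to_dict(results.kernel),
        "lambda_reg": results.model.lambda_reg,
        "alpha": results.alpha.tolist(),
        "X": results.model.X.tolist(),
        "y": results.model.y.tolist(),
        "label_shift": results.label_shift,
    }
    path = Path(path)
    if fmt == "json":
        path.write_text(json.dumps(payload))
    elif fmt == "npz":
        np.savez(
            path,
            alpha=results.alpha,
            X=results.model.X,
            y=results.model.y,
            label_shift=np.array(results.label_shift),
            lambda_reg=np.array(results.model.lambda_reg),
            kernel=np.array(json.dumps(payload["kernel"])),
        )
    else:
        raise ValueError(f"unknown format {fmt!r}")


def load_model(path, fmt: str = "json") -> KernelRidgeResults:
    path = Path(path)
    if fmt == "json":
        payload = json.loads(path.read_text())
        kd = payload["kernel"]
    elif fmt == "npz":
        with np.load(path.with_suffix(".npz") if path.suffix != ".npz" else path) as d:
            kd = json.loads(str(d["kernel"]))
            payload = {
                "alpha": d["alpha"],
                "X": d["X"],
                "y": d["y"],
                "label_shift": float(d["label_shift"]),
                "lambda_reg": float(d["lambda_reg"]),
            }
    else:
        raise ValueError(f"unknown format {fmt!r}")
    kernel = KernelSpec(
        family=kd["family"],
        sigma=kd["sigma"],
        n=kd["n"],
        p=kd["p"],
        sigma_p=kd["sigma_p"],
    )
    model = KernelRidge(
        np.asarray(payload["X"], dtype=float),
        np.asarray(payload["y"], dtype=float),
        kernel=kernel,
        lambda_reg=payload["lambda_reg"],
    )
    return KernelRidgeResults(
        model, np.asarray(payload["alpha"], dtype=float), float(payload["label_shift"])
    )
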