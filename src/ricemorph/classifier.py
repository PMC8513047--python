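"""Bayesian-regularized feedforward network for grain classification.

The classifier is a two-layer feedforward pattern-recognition network:
nine standardized morpho-colorimetric inputs, one tanh hidden layer, and
15 logistic outputs (one-hot class coding).  Training minimizes the
regularized objective

    F = beta * E_D + alpha * E_W

where E_D is the sum of squared output errors and E_W the sum of squared
weights, by Levenberg–Marquardt.  After every accepted step the
hyperparameters are re-estimated with MacKay's evidence framework:

    gamma = N_w − 2*alpha*tr(H^-1),   H = 2*beta*J'J + 2*alpha*I
    alpha = gamma / (2*E_W),          beta  = (N_t − gamma) / (2*E_D)

with N_w the number of weights, N_t the number of target values and gamma
the effective number of parameters.  No validation subset is held out: the
evidence framework replaces early stopping.

A plain gradient-descent-with-momentum trainer (``train_gdm``) is included
as a baseline.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .specs import FEATURE_NAMES
from .features import METADATA_COLUMNS


class SchemaError(ValueError):
    """Feature-table columns do not match the expected nine-feature schema."""


@dataclass
class BRConfig:
    """Levenberg–Marquardt / Bayesian-regularization hyperparameters."""

    max_epochs: int = 300
    mu_init: float = 0.005
    mu_factor: float = 10.0
    mu_max: float = 1e10
    grad_tol: float = 1e-7
    seed: int = 0


@dataclass
class NetworkModel:
    """Weights, input scaling and evidence hyperparameters of a trained net."""

    W1: np.ndarray  # (n_hidden, 9)
    b1: np.ndarray  # (n_hidden,)
    W2: np.ndarray  # (n_classes, n_hidden)
    b2: np.ndarray  # (n_classes,)
    input_center: np.ndarray  # (9,)
    input_scale: np.ndarray  # (9,)
    class_ids: list[int]
    alpha: float
    beta: float
    gamma: float
    n_hidden: int
    class_labels: dict[int, str] = field(default_factory=dict)
    objective_history: list[tuple[float, float]] = field(default_factory=list)
    n_epochs: int = 0

    @property
    def n_weights(self) -> int:
        return self.W1.size + self.b1.size + self.W2.size + self.b2.size

    def forward(self, X: np.ndarray) -> np.ndarray:
        """Class scores in [0, 1] for standardized-input rows of X (raw units)."""
        Xs = (X - self.input_center) / self.input_scale
        h = np.tanh(Xs @ self.W1.T + self.b1)
        return _sigmoid(h @ self.W2.T + self.b2)

    def save(self, path: str | Path) -> None:
        payload = {
            "n_hidden": self.n_hidden,
            "class_ids": self.class_ids,
            "class_labels": {str(k): v for k, v in self.class_labels.items()},
            "alpha": self.alpha,
            "beta": self.beta,
            "gamma": self.gamma,
            "n_epochs": self.n_epochs,
            "feature_names": list(FEATURE_NAMES),
            "W1": self.W1.tolist(),
            "b1": self.b1.tolist(),
            "W2": self.W2.tolist(),
            "b2": self.b2.tolist(),
            "input_center": self.input_center.tolist(),
            "input_scale": self.input_scale.tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "NetworkModel":
        d = json.loads(Path(path).read_text())
        return cls(
            W1=np.asarray(d["W1"]),
            b1=np.asarray(d["b1"]),
            W2=np.asarray(d["W2"]),
            b2=np.asarray(d["b2"]),
            input_center=np.asarray(d["input_center"]),
            input_scale=np.asarray(d["input_scale"]),
            class_ids=[int(c) for c in d["class_ids"]],
            class_labels={int(k): v for k, v in d.get("class_labels", {}).items()},
            alpha=d["alpha"],
            beta=d["beta"],
            gamma=d["gamma"],
            n_hidden=d["n_hidden"],
            n_epochs=d.get("n_epochs", 0),
        )


@dataclass
class EvalReport:
    """Accuracy/MSE/confusion/ROC summary for one evaluation stage."""

    stage: str
    n: int
    accuracy: float  # percent
    mse: float
    confusion: np.ndarray  # (K, K), rows = true class, cols = predicted
    roc: dict[int, np.ndarray]  # class_id -> (m, 2) array of (fpr, tpr)
    class_ids: list[int]

    @property
    def error(self) -> float:
        return 100.0 - self.accuracy

    def summary_row(self) -> dict:
        return {
            "stage": self.stage,
            "n": self.n,
            "accuracy_pct": round(self.accuracy, 1),
            "error_pct": round(self.error, 1),
            "mse": self.mse,
        }


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def feature_matrix(
    table: pd.DataFrame, require_labels: bool = False
) -> tuple[np.ndarray, np.ndarray | None]:
    """Validate the nine-feature schema and return (X, labels-or-None).

    Unknown columns are rejected rather than silently ignored, so a table
    with a stray extra column fails loudly instead of producing scores that
    look valid.
    """
    missing = [c for c in FEATURE_NAMES if c not in table.columns]
    if missing:
        raise SchemaError(f"missing feature columns: {missing}")
    unknown = [
        c for c in table.columns if c not in FEATURE_NAMES and c not in METADATA_COLUMNS
    ]
    if unknown:
        raise SchemaError(f"unexpected columns in feature table: {unknown}")
    X = table[list(FEATURE_NAMES)].to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("feature table contains non-finite values")
    y = None
    if "class_id" in table.columns and table["class_id"].notna().all():
        y = table["class_id"].to_numpy(dtype=int)
    elif require_labels:
        raise ValueError("labeled rows required: class_id column missing or incomplete")
    return X, y


def split_dataset(
    table: pd.DataFrame,
    train_fraction: float = 0.7,
    seed: int | None = None,
    stratify: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random 70/30-style partition; training size = floor(fraction * N)."""
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must lie strictly between 0 and 1")
    if len(table) == 0:
        raise ValueError("cannot split an empty table")
    rng = np.random.default_rng(seed)
    n = len(table)
    if stratify:
        train_idx: list[int] = []
        for _, grp in table.groupby("class_id"):
            idx = rng.permutation(grp.index.to_numpy())
            train_idx.extend(idx[: int(np.floor(train_fraction * len(idx)))])
        train_mask = table.index.isin(train_idx)
        return table[train_mask].copy(), table[~train_mask].copy()
    perm = rng.permutation(n)
    n_train = int(np.floor(train_fraction * n))
    return (
        table.iloc[perm[:n_train]].reset_index(drop=True),
        table.iloc[perm[n_train:]].reset_index(drop=True),
    )


def _init_weights(
    n_in: int, n_hidden: int, n_out: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Nguyen–Widrow-style scaled uniform initialization."""
    W1 = rng.uniform(-1, 1, (n_hidden, n_in))
    norms = np.linalg.norm(W1, axis=1, keepdims=True)
    scale = 0.7 * n_hidden ** (1.0 / n_in)
    W1 = scale * W1 / np.maximum(norms, 1e-12)
    b1 = scale * np.linspace(-1, 1, n_hidden) * np.sign(W1[:, 0])
    W2 = rng.uniform(-0.5, 0.5, (n_out, n_hidden))
    b2 = rng.uniform(-0.5, 0.5, n_out)
    return W1, b1, W2, b2


def _pack(W1, b1, W2, b2) -> np.ndarray:
    return np.concatenate([W1.ravel(), b1, W2.ravel(), b2])


def _unpack(w: np.ndarray, n_in: int, n_hidden: int, n_out: int):
    i = 0
    W1 = w[i : i + n_hidden * n_in].reshape(n_hidden, n_in); i += n_hidden * n_in
    b1 = w[i : i + n_hidden]; i += n_hidden
    W2 = w[i : i + n_out * n_hidden].reshape(n_out, n_hidden); i += n_out * n_hidden
    b2 = w[i : i + n_out]
    return W1, b1, W2, b2


def _forward_parts(w, Xs, n_in, n_hidden, n_out):
    W1, b1, W2, b2 = _unpack(w, n_in, n_hidden, n_out)
    h = np.tanh(Xs @ W1.T + b1)
    y = _sigmoid(h @ W2.T + b2)
    return h, y, W2


def _jacobian(w, Xs, n_in, n_hidden, n_out):
    """Jacobian of the stacked outputs w.r.t. the packed weight vector."""
    h, y, W2 = _forward_parts(w, Xs, n_in, n_hidden, n_out)
    N = Xs.shape[0]
    s2 = y * (1.0 - y)  # (N, K) logistic derivative
    dh = 1.0 - h**2  # (N, H)
    # dz2/dW1 path: s2 * W2 * (1 - h^2) * x
    back = s2[:, :, None] * W2[None, :, :] * dh[:, None, :]  # (N, K, H)
    J_W1 = back[:, :, :, None] * Xs[:, None, None, :]  # (N, K, H, n_in)
    J_b1 = back  # (N, K, H)
    J_W2 = np.zeros((N, n_out, n_out, n_hidden))
    idx = np.arange(n_out)
    J_W2[:, idx, idx, :] = s2[:, :, None] * h[:, None, :]
    J_b2 = np.zeros((N, n_out, n_out))
    J_b2[:, idx, idx] = s2
    J = np.concatenate(
        [
            J_W1.reshape(N * n_out, n_hidden * n_in),
            J_b1.reshape(N * n_out, n_hidden),
            J_W2.reshape(N * n_out, n_out * n_hidden),
            J_b2.reshape(N * n_out, n_out),
        ],
        axis=1,
    )
    return J, y


def _lm_br_fit(Xs, T, w0, n_in, n_hidden, n_out, cfg: BRConfig):
    """Core Levenberg–Marquardt loop with evidence re-estimation.

    Returns (weights, alpha, beta, gamma, objective_history, epochs).
    ``objective_history`` holds (F_before, F_after) per accepted step, both
    evaluated under the hyperparameters used for that step's acceptance
    test, so F_after <= F_before throughout.
    """
    w = w0.copy()
    n_w = w.size
    n_t = T.size
    alpha, beta = 0.01, 1.0
    mu = cfg.mu_init
    I = np.eye(n_w)
    history: list[tuple[float, float]] = []
    gamma = float(n_w)

    J, y = _jacobian(w, Xs, n_in, n_hidden, n_out)
    e = (y - T).ravel()
    E_D = float(e @ e)
    E_W = float(w @ w)
    epoch = 0
    while epoch < cfg.max_epochs:
        epoch += 1
        g = 2.0 * beta * (J.T @ e) + 2.0 * alpha * w
        if np.max(np.abs(g)) < cfg.grad_tol:
            break
        A = 2.0 * beta * (J.T @ J) + 2.0 * alpha * I
        F_old = beta * E_D + alpha * E_W
        accepted = False
        while mu <= cfg.mu_max:
            try:
                step = np.linalg.solve(A + mu * I, -g)
            except np.linalg.LinAlgError:
                mu *= cfg.mu_factor
                continue
            w_new = w + step
            _, y_new, _ = _forward_parts(w_new, Xs, n_in, n_hidden, n_out)
            e_new = (y_new - T).ravel()
            E_D_new = float(e_new @ e_new)
            E_W_new = float(w_new @ w_new)
            F_new = beta * E_D_new + alpha * E_W_new
            if F_new < F_old:
                accepted = True
                break
            mu *= cfg.mu_factor
        if not accepted:
            break
        history.append((F_old, F_new))
        mu = max(mu / cfg.mu_factor, 1e-20)
        w, E_D, E_W = w_new, E_D_new, E_W_new
        J, y = _jacobian(w, Xs, n_in, n_hidden, n_out)
        e = (y - T).ravel()
        # evidence-framework re-estimation of alpha, beta, gamma
        H = 2.0 * beta * (J.T @ J) + 2.0 * alpha * I
        try:
            tr_Hinv = float(np.trace(np.linalg.inv(H)))
        except np.linalg.LinAlgError:
            tr_Hinv = float(np.trace(np.linalg.pinv(H)))
        gamma = float(np.clip(n_w - 2.0 * alpha * tr_Hinv, 0.0, n_w))
        alpha = gamma / max(2.0 * E_W, 1e-12)
        beta = max(n_t - gamma, 1e-3) / max(2.0 * E_D, 1e-12)
    return w, alpha, beta, gamma, history, epoch


def train_br(
    train: pd.DataFrame,
    n_hidden: int = 10,
    config: BRConfig | None = None,
    seed: int | None = None,
) -> NetworkModel:
    """Train the network with Levenberg–Marquardt + Bayesian regularization.

    Deterministic for a fixed seed (weight initialization and LM path).
    ``seed`` overrides ``config.seed`` when given.
    """
    if n_hidden < 1:
        raise ValueError("n_hidden must be >= 1")
    cfg = config or BRConfig()
    if seed is not None:
        cfg = BRConfig(**{**cfg.__dict__, "seed": seed})
    X, labels = feature_matrix(train, require_labels=True)
    class_ids = sorted(set(int(c) for c in labels))
    if len(class_ids) < 2:
        raise ValueError("training requires at least two classes")
    n_in, n_out = X.shape[1], len(class_ids)
    N = X.shape[0]

    center = X.mean(axis=0)
    scale = X.std(axis=0, ddof=0)
    scale[scale == 0] = 1.0
    Xs = (X - center) / scale
    col = {c: j for j, c in enumerate(class_ids)}
    T = np.zeros((N, n_out))
    T[np.arange(N), [col[c] for c in labels]] = 1.0

    rng = np.random.default_rng(cfg.seed)
    w0 = _pack(*_init_weights(n_in, n_hidden, n_out, rng))
    if w0.size >= N:
        warnings.warn(
            f"network has {w0.size} weights for only {N} training rows; "
            "over-parameterization risk",
            stacklevel=2,
        )
    w, alpha, beta, gamma, history, epoch = _lm_br_fit(
        Xs, T, w0, n_in, n_hidden, n_out, cfg
    )
    W1, b1, W2, b2 = _unpack(w, n_in, n_hidden, n_out)
    return NetworkModel(
        W1=W1.copy(),
        b1=b1.copy(),
        W2=W2.copy(),
        b2=b2.copy(),
        input_center=center,
        input_scale=scale,
        class_ids=class_ids,
        alpha=float(alpha),
        beta=float(beta),
        gamma=float(gamma),
        n_hidden=n_hidden,
        objective_history=history,
        n_epochs=epoch,
    )


def train_gdm(
    train: pd.DataFrame,
    n_hidden: int = 10,
    learning_rate: float = 0.05,
    momentum: float = 0.9,
    max_epochs: int = 2000,
    seed: int = 0,
) -> NetworkModel:
    """Gradient-descent-with-momentum baseline on the same architecture."""
    X, labels = feature_matrix(train, require_labels=True)
    class_ids = sorted(set(int(c) for c in labels))
    n_in, n_out = X.shape[1], len(class_ids)
    N = X.shape[0]
    center, scale = X.mean(axis=0), X.std(axis=0, ddof=0)
    scale[scale == 0] = 1.0
    Xs = (X - center) / scale
    col = {c: j for j, c in enumerate(class_ids)}
    T = np.zeros((N, n_out))
    T[np.arange(N), [col[c] for c in labels]] = 1.0
    rng = np.random.default_rng(seed)
    w = _pack(*_init_weights(n_in, n_hidden, n_out, rng))
    v = np.zeros_like(w)
    for _ in range(max_epochs):
        J, y = _jacobian(w, Xs, n_in, n_hidden, n_out)
        g = 2.0 * (J.T @ (y - T).ravel()) / N
        v = momentum * v - learning_rate * g
        w = w + v
    W1, b1, W2, b2 = _unpack(w, n_in, n_hidden, n_out)
    return NetworkModel(
        W1=W1, b1=b1, W2=W2, b2=b2,
        input_center=center, input_scale=scale, class_ids=class_ids,
        alpha=0.0, beta=1.0, gamma=float(w.size), n_hidden=n_hidden,
        n_epochs=max_epochs,
    )


def predict(model: NetworkModel, rows: pd.DataFrame) -> pd.DataFrame:
    """Per-row class scores and argmax label (lowest class id wins ties)."""
    X, _ = feature_matrix(rows)
    scores = model.forward(X)
    # argmax returns the first maximum; class_ids are sorted ascending, so
    # ties resolve to the lowest class id
    pred = np.asarray(model.class_ids)[np.argmax(scores, axis=1)]
    out = pd.DataFrame(
        scores, columns=[f"score_{c}" for c in model.class_ids], index=rows.index
    )
    out["predicted_class"] = pred
    return out


def _roc_points(scores: np.ndarray, positive: np.ndarray) -> np.ndarray:
    """One-vs-rest ROC curve: (fpr, tpr) staircase from (0,0) to (1,1)."""
    order = np.argsort(-scores, kind="stable")
    pos = positive[order].astype(float)
    tp = np.concatenate([[0.0], np.cumsum(pos)])
    fp = np.concatenate([[0.0], np.cumsum(1.0 - pos)])
    n_pos, n_neg = max(pos.sum(), 1.0), max((1.0 - pos).sum(), 1.0)
    return np.column_stack([fp / n_neg, tp / n_pos])


def roc_auc(points: np.ndarray) -> float:
    return float(np.trapezoid(points[:, 1], points[:, 0]))


def evaluate(model: NetworkModel, table: pd.DataFrame, stage: str = "testing") -> EvalReport:
    """Accuracy, MSE against one-hot targets, confusion matrix and ROC."""
    X, labels = feature_matrix(table, require_labels=True)
    if labels is None:
        raise ValueError("evaluate requires labeled rows")
    scores = model.forward(X)
    K = len(model.class_ids)
    col = {c: j for j, c in enumerate(model.class_ids)}
    unknown = set(labels) - set(model.class_ids)
    if unknown:
        raise ValueError(f"table contains classes unknown to the model: {unknown}")
    true_col = np.asarray([col[c] for c in labels])
    T = np.zeros((len(labels), K))
    T[np.arange(len(labels)), true_col] = 1.0
    pred_col = np.argmax(scores, axis=1)
    accuracy = 100.0 * float(np.mean(pred_col == true_col))
    mse = float(np.mean((scores - T) ** 2))
    confusion = np.zeros((K, K), dtype=int)
    np.add.at(confusion, (true_col, pred_col), 1)
    roc = {
        c: _roc_points(scores[:, j], true_col == j) for c, j in col.items()
    }
    return EvalReport(
        stage=stage,
        n=len(labels),
        accuracy=accuracy,
        mse=mse,
        confusion=confusion,
        roc=roc,
        class_ids=list(model.class_ids),
    )


def combine_stage_accuracies(stages: "list[tuple[int, float]]") -> float:
    """Overall accuracy as the count-weighted mean of stage accuracies."""
    ns = np.asarray([n for n, _ in stages], dtype=float)
    accs = np.asarray([a for _, a in stages], dtype=float)
    return float((ns * accs).sum() / ns.sum())


def fit_flags(
    train_mse: float,
    test_mse: float,
    train_accuracy: float,
    test_accuracy: float,
    accuracy_gap_limit: float = 10.0,
) -> "list[str]":
    """Apply the no-overfit rule to one trained configuration.

    Training MSE must not exceed testing MSE ('underfit-suspect' otherwise,
    since a model that fits its own training data worse than unseen data
    has not converged), and testing accuracy must stay within
    ``accuracy_gap_limit`` points of training accuracy ('overfit-suspect').
    """
    flags = []
    if train_mse > test_mse:
        flags.append("underfit-suspect")
    if train_accuracy - test_accuracy > accuracy_gap_limit:
        flags.append("overfit-suspect")
    return flags


@dataclass
class TrimmingReport:
    """Hidden-neuron sweep with over/under-fitting flags and a recommendation."""

    table: pd.DataFrame
    recommended_n_hidden: int | None
    recommended_seed: int | None


def neuron_trimming(
    table: pd.DataFrame,
    neuron_counts: "list[int]" = (10, 7, 5, 3),
    seeds: "list[int]" = (0,),
    train_fraction: float = 0.7,
    config: BRConfig | None = None,
    accuracy_gap_limit: float = 10.0,
) -> TrimmingReport:
    """Sweep hidden-layer sizes and flag configurations that violate the
    no-overfit rule (training MSE must not exceed testing MSE; testing
    accuracy must stay within ``accuracy_gap_limit`` points of training).

    The recommendation is the flag-free configuration with the highest
    overall (count-weighted) accuracy.
    """
    if not neuron_counts:
        raise ValueError("neuron_counts must be non-empty")
    rows = []
    for seed in seeds:
        train, test = split_dataset(table, train_fraction, seed=seed)
        for n_hidden in neuron_counts:
            model = train_br(train, n_hidden=n_hidden, config=config, seed=seed)
            r_train = evaluate(model, train, "training")
            r_test = evaluate(model, test, "testing")
            flags = fit_flags(
                r_train.mse, r_test.mse, r_train.accuracy, r_test.accuracy,
                accuracy_gap_limit,
            )
            rows.append(
                {
                    "n_hidden": n_hidden,
                    "seed": seed,
                    "train_accuracy": r_train.accuracy,
                    "test_accuracy": r_test.accuracy,
                    "train_mse": r_train.mse,
                    "test_mse": r_test.mse,
                    "overall_accuracy": combine_stage_accuracies(
                        [(r_train.n, r_train.accuracy), (r_test.n, r_test.accuracy)]
                    ),
                    "flags": ";".join(flags),
                }
            )
    frame = pd.DataFrame(rows)
    clean = frame[frame["flags"] == ""]
    pick = clean if len(clean) else frame
    best = pick.loc[pick["overall_accuracy"].idxmax()]
    return TrimmingReport(
        table=frame,
        recommended_n_hidden=int(best["n_hidden"]),
        recommended_seed=int(best["seed"]),
    )


def retrain(
    old_table: pd.DataFrame,
    new_table: pd.DataFrame,
    n_hidden: int = 10,
    config: BRConfig | None = None,
    seed: int | None = None,
    warm_start: NetworkModel | None = None,
) -> tuple[NetworkModel, dict[str, EvalReport]]:
    """Retrain on the union of the original and new datasets.

    The combined table is re-split 70/30 and a fresh network is trained
    (pass ``warm_start`` to instead continue from an existing model's
    weights).  Returns the model plus training/testing/overall reports.
    """
    if new_table is not None and len(new_table):
        if set(old_table.columns) != set(new_table.columns):
            raise SchemaError(
                "old and new tables have different columns: "
                f"{sorted(set(old_table.columns) ^ set(new_table.columns))}"
            )
        combined = pd.concat([old_table, new_table], ignore_index=True)
    else:
        combined = old_table.reset_index(drop=True)
    train, test = split_dataset(combined, 0.7, seed=seed if seed is not None else 0)
    if warm_start is not None:
        cfg = config or BRConfig()
        model = _continue_training(warm_start, train, cfg)
    else:
        model = train_br(train, n_hidden=n_hidden, config=config, seed=seed)
    reports = {
        "training": evaluate(model, train, "training"),
        "testing": evaluate(model, test, "testing"),
    }
    return model, reports


def _continue_training(
    model: NetworkModel, train: pd.DataFrame, cfg: BRConfig
) -> NetworkModel:
    """Resume LM/BR training from an existing model's weights (warm start).

    The original model's input standardization and class map are kept so
    its weights remain meaningful; the new training rows must not contain
    classes the model does not know.
    """
    X, labels = feature_matrix(train, require_labels=True)
    unknown = set(int(c) for c in labels) - set(model.class_ids)
    if unknown:
        raise ValueError(f"warm start cannot add new classes: {unknown}")
    Xs = (X - model.input_center) / model.input_scale
    col = {c: j for j, c in enumerate(model.class_ids)}
    T = np.zeros((len(labels), len(model.class_ids)))
    T[np.arange(len(labels)), [col[c] for c in labels]] = 1.0
    w0 = _pack(model.W1, model.b1, model.W2, model.b2)
    n_in, n_hidden, n_out = model.W1.shape[1], model.n_hidden, len(model.class_ids)
    w, alpha, beta, gamma, history, epoch = _lm_br_fit(
        Xs, T, w0, n_in, n_hidden, n_out, cfg
    )
    W1, b1, W2, b2 = _unpack(w, n_in, n_hidden, n_out)
    return NetworkModel(
        W1=W1.copy(), b1=b1.copy(), W2=W2.copy(), b2=b2.copy(),
        input_center=model.input_center, input_scale=model.input_scale,
        class_ids=list(model.class_ids), class_labels=dict(model.class_labels),
        alpha=float(alpha), beta=float(beta), gamma=float(gamma),
        n_hidden=n_hidden, objective_history=history, n_epochs=epoch,
    )
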