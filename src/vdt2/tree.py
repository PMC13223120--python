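"""Soft decision tree of attention-weighted logistic units.

The classifier arranges logistic-regression units in a complete binary
tree of depth ``D`` (``2**D - 1`` internal nodes, ``2**D`` leaves).  Each
internal node ``j`` owns a weight vector ``w_j``, bias ``b_j`` and
attention logits ``a_j``; its gate is

    g_j(x) = sigmoid( w_j . (alpha_j * x) + b_j ),
    alpha_j = softmax(a_j),

so the attention weights form a convex combination that modulates each
feature's contribution along that decision path.  Routing is soft: an
input reaches leaf ``l`` with probability ``prod`` over its ancestors of
``g_j`` (right branch) or ``1 - g_j`` (left branch), and the model output
is the leaf-probability mixture

    P(y=1 | x) = sum_l pathprob_l(x) * sigmoid(theta_l).

Soft routing makes the whole tree differentiable, so all parameters are
trained jointly by bounded quasi-Newton (L-BFGS-B) on the mean binary
cross-entropy, with an optional ridge penalty on ``w`` and ``theta``
(attention logits are left unpenalized: shrinking them biases every node
toward uniform attention).

The public surface follows the statsmodels convention: build a
:class:`VowelDiabetesTree` model from data, call :meth:`~VowelDiabetesTree.fit`,
and work with the returned :class:`VDTResults`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .exceptions import ConfigError, VDT2Error
from .features import GROUP_T2DM

__all__ = [
    "VDTParams",
    "FitConfig",
    "init_params",
    "forward",
    "leaf_path_probs",
    "loss_and_grad",
    "fit_tree",
    "predict_proba",
    "predict",
    "VowelDiabetesTree",
    "VDTResults",
]

_EPS = 1e-12


@dataclass
class VDTParams:
    """Complete-binary-tree parameters.

    ``w`` and ``a`` are ``(n_internal, n_features)``; ``b`` is
    ``(n_internal,)``; ``theta`` holds one logit per leaf.
    """

    depth: int
    n_features: int
    w: np.ndarray
    b: np.ndarray
    a: np.ndarray
    theta: np.ndarray

    @property
    def n_internal(self) -> int:
        return 2**self.depth - 1

    @property
    def n_leaves(self) -> int:
        return 2**self.depth

    def __post_init__(self) -> None:
        m, d, leaves = self.n_internal, self.n_features, self.n_leaves
        if self.w.shape != (m, d) or self.a.shape != (m, d):
            raise ConfigError(f"w and a must have shape ({m}, {d})")
        if self.b.shape != (m,) or self.theta.shape != (leaves,):
            raise ConfigError(f"b must have shape ({m},), theta ({leaves},)")

    def to_vector(self) -> np.ndarray:
        return np.concatenate(
            [self.w.ravel(), self.b, self.a.ravel(), self.theta]
        )

    @classmethod
    def from_vector(cls, vec: np.ndarray, depth: int, n_features: int) -> "VDTParams":
        m, leaves, d = 2**depth - 1, 2**depth, n_features
        sizes = [m * d, m, m * d, leaves]
        if len(vec) != sum(sizes):
            raise ConfigError("parameter vector has wrong length")
        parts = np.split(np.asarray(vec, dtype=float), np.cumsum(sizes)[:-1])
        return cls(
            depth=depth,
            n_features=d,
            w=parts[0].reshape(m, d),
            b=parts[1],
            a=parts[2].reshape(m, d),
            theta=parts[3],
        )

    def attention(self, mode: str = "softmax") -> np.ndarray:
        """Per-node attention weights, ``(n_internal, n_features)``."""
        return _attention(self.a, mode)

    def to_dict(self) -> dict:
        return {
            "depth": self.depth,
            "n_features": self.n_features,
            "w": self.w.tolist(),
            "b": self.b.tolist(),
            "a": self.a.tolist(),
            "theta": self.theta.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "VDTParams":
        return cls(
            depth=int(d["depth"]),
            n_features=int(d["n_features"]),
            w=np.asarray(d["w"], dtype=float),
            b=np.asarray(d["b"], dtype=float),
            a=np.asarray(d["a"], dtype=float),
            theta=np.asarray(d["theta"], dtype=float),
        )


@dataclass
class FitConfig:
    """Optimizer and decision settings.

    ``grad_tol`` is the L-BFGS-B projected-gradient tolerance (the quoted
    "learning rate" of quasi-Newton training is interpreted as this
    tolerance — L-BFGS-B has no step-size hyperparameter).
    """

    max_iter: int = 200
    grad_tol: float = 1e-5
    l2_penalty: float = 0.0
    threshold: float = 0.5
    attention: str = "softmax"  # or "sigmoid"

    def __post_init__(self) -> None:
        if self.max_iter < 1:
            raise ConfigError("max_iter must be >= 1")
        if self.grad_tol <= 0:
            raise ConfigError("grad_tol must be > 0")
        if not 0.0 < self.threshold < 1.0:
            raise ConfigError("threshold must be in (0, 1)")
        if self.attention not in ("softmax", "sigmoid"):
            raise ConfigError(f"unknown attention mode {self.attention!r}")


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _attention(a: np.ndarray, mode: str) -> np.ndarray:
    if mode == "softmax":
        shifted = a - a.max(axis=-1, keepdims=True)
        e = np.exp(shifted)
        return e / e.sum(axis=-1, keepdims=True)
    if mode == "sigmoid":
        return _sigmoid(a)
    raise ConfigError(f"unknown attention mode {mode!r}")


def init_params(
    depth: int = 4, n_features: int = 13, init_sd: float = 0.1, seed: int = 42
) -> VDTParams:
    """Gaussian-initialized parameters, i.i.d. N(0, init_sd^2)."""
    if depth < 1 or n_features < 1:
        raise ConfigError("depth and n_features must be >= 1")
    rng = np.random.default_rng(seed)
    m, leaves = 2**depth - 1, 2**depth
    return VDTParams(
        depth=depth,
        n_features=n_features,
        w=rng.normal(0.0, init_sd, (m, n_features)),
        b=rng.normal(0.0, init_sd, m),
        a=rng.normal(0.0, init_sd, (m, n_features)),
        theta=rng.normal(0.0, init_sd, leaves),
    )


def _forward_full(params: VDTParams, X: np.ndarray, mode: str):
    """Gates, node reach probabilities and output probability.

    Heap indexing over ``2*m + 1`` nodes: node j's children are 2j+1 and
    2j+2 (left = low gate); leaves occupy heap slots m .. 2m.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    m = params.n_internal
    if X.shape[1] != params.n_features:
        raise VDT2Error(
            f"input has {X.shape[1]} features, model expects {params.n_features}"
        )
    alpha = _attention(params.a, mode)
    z = X @ (params.w * alpha).T + params.b  # (n, m)
    g = _sigmoid(z)
    n = X.shape[0]
    reach = np.empty((n, 2 * m + 1))
    reach[:, 0] = 1.0
    for j in range(m):
        reach[:, 2 * j + 1] = reach[:, j] * (1.0 - g[:, j])
        reach[:, 2 * j + 2] = reach[:, j] * g[:, j]
    pi = reach[:, m:]
    p = pi @ _sigmoid(params.theta)
    return alpha, z, g, reach, pi, p


def forward(params: VDTParams, X, attention: str = "softmax") -> np.ndarray:
    """P(y=1 | x) for each row of X."""
    return _forward_full(params, X, attention)[5]


def leaf_path_probs(params: VDTParams, X, attention: str = "softmax") -> np.ndarray:
    """Soft-routing probabilities over the ``2**D`` leaves, rows sum to 1."""
    return _forward_full(params, X, attention)[4]


def loss_and_grad(
    params: VDTParams, X, y, config: FitConfig | None = None
) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy (+ ridge on w, theta) and its analytic
    gradient as a flat vector in ``to_vector`` order."""
    config = config or FitConfig()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    if not np.all(np.isin(y, (0.0, 1.0))):
        raise VDT2Error("labels must be binary 0/1")
    if len(y) != X.shape[0]:
        raise VDT2Error("X and y have inconsistent lengths")

    m, n = params.n_internal, X.shape[0]
    alpha, z, g, reach, pi, p = _forward_full(params, X, config.attention)
    pc = np.clip(p, _EPS, 1.0 - _EPS)
    loss = float(-np.mean(y * np.log(pc) + (1.0 - y) * np.log(1.0 - pc)))

    sig_theta = _sigmoid(params.theta)
    # subtree values V: P restricted to the subtree below each heap node
    values = np.empty((n, 2 * m + 1))
    values[:, m:] = sig_theta[np.newaxis, :]
    for j in range(m - 1, -1, -1):
        values[:, j] = (1.0 - g[:, j]) * values[:, 2 * j + 1] + g[:, j] * values[
            :, 2 * j + 2
        ]

    c = (pc - y) / (pc * (1.0 - pc)) / n  # dLoss/dP per sample
    # dP/dz_j = reach_j * (V_right - V_left) * g'(z_j)
    dp_dz = (
        reach[:, :m]
        * (values[:, 2 * np.arange(m) + 2] - values[:, 2 * np.arange(m) + 1])
        * g
        * (1.0 - g)
    )
    s = c[:, np.newaxis] * dp_dz  # (n, m)

    grad_b = s.sum(axis=0)
    sx = s.T @ X  # (m, d)
    grad_w = sx * alpha
    u = sx * params.w  # (m, d): sum_n s_nj * (w_j * x_n)
    if config.attention == "softmax":
        grad_a = alpha * (u - (alpha * u).sum(axis=1, keepdims=True))
    else:
        grad_a = u * alpha * (1.0 - alpha)
    grad_theta = (c @ pi) * sig_theta * (1.0 - sig_theta)

    if config.l2_penalty:
        loss += config.l2_penalty * (
            float(np.sum(params.w**2)) + float(np.sum(params.theta**2))
        )
        grad_w = grad_w + 2.0 * config.l2_penalty * params.w
        grad_theta = grad_theta + 2.0 * config.l2_penalty * params.theta

    grad = np.concatenate([grad_w.ravel(), grad_b, grad_a.ravel(), grad_theta])
    return loss, grad


def fit_tree(
    X, y, params0: VDTParams, config: FitConfig | None = None
) -> tuple[VDTParams, dict]:
    """Minimize the training objective from ``params0`` with L-BFGS-B.

    Returns the final parameters and a trace dict (per-iteration losses,
    iteration count, convergence flag and optimizer message).  On optimizer
    failure the partial parameters are still returned, with
    ``trace['converged'] = False``.
    """
    config = config or FitConfig()
    y = np.asarray(y, dtype=float)
    if len(np.unique(y)) < 2:
        raise VDT2Error("training labels must contain both classes")
    depth, d = params0.depth, params0.n_features

    def objective(vec: np.ndarray):
        pars = VDTParams.from_vector(vec, depth, d)
        return loss_and_grad(pars, X, y, config)

    losses: list[float] = [objective(params0.to_vector())[0]]

    def callback(vec: np.ndarray) -> None:
        losses.append(objective(vec)[0])

    res = minimize(
        objective,
        params0.to_vector(),
        jac=True,
        method="L-BFGS-B",
        callback=callback,
        options={
            "maxiter": config.max_iter,
            "gtol": config.grad_tol,
            "ftol": 1e-14,
        },
    )
    fitted = VDTParams.from_vector(res.x, depth, d)
    trace = {
        "losses": losses,
        "n_iter": int(res.nit),
        "converged": bool(res.success),
        "message": str(res.message),
        "final_loss": float(res.fun),
        "initial_loss": losses[0],
    }
    return fitted, trace


def predict_proba(params: VDTParams, X, attention: str = "softmax") -> np.ndarray:
    return forward(params, X, attention)


def predict(
    params: VDTParams,
    X,
    threshold: float = 0.5,
    attention: str = "softmax",
    hard_routing: bool = False,
) -> np.ndarray:
    """0/1 labels; a probability exactly at the threshold is positive.

    ``hard_routing=True`` follows the argmax gate to a single leaf instead
    of mixing over all leaves.
    """
    if hard_routing:
        _, _, g, _, _, _ = _forward_full(params, X, attention)
        m = params.n_internal
        node = np.zeros(g.shape[0], dtype=int)
        for _ in range(params.depth):
            go_right = g[np.arange(g.shape[0]), node] >= 0.5
            node = 2 * node + 1 + go_right.astype(int)
        p = _sigmoid(params.theta)[node - m]
    else:
        p = forward(params, X, attention)
    return (p >= threshold).astype(int)


class VowelDiabetesTree:
    """Soft decision tree classifier model (statsmodels-style).

    Parameters
    ----------
    endog : array-like
        Binary 0/1 labels (1 = disease / positive class).
    exog : DataFrame or array
        Feature matrix; normalize with the training-set z-score first.
    depth : int
        Internal-node levels; depth 4 gives 15 internal nodes, 16 leaves.
    attention : {"softmax", "sigmoid"}
        Per-node attention normalization.
    """

    def __init__(
        self,
        endog,
        exog,
        depth: int = 4,
        feature_names=None,
        attention: str = "softmax",
        l2_penalty: float = 0.0,
        init_sd: float = 0.1,
        seed: int = 42,
    ):
        if isinstance(exog, pd.DataFrame):
            feature_names = feature_names or list(exog.columns)
            exog = exog.to_numpy(dtype=float)
        self.exog = np.atleast_2d(np.asarray(exog, dtype=float))
        self.endog = np.asarray(endog, dtype=float)
        if not np.all(np.isin(self.endog, (0.0, 1.0))):
            raise VDT2Error("endog must be binary 0/1")
        self.depth = depth
        self.feature_names = list(
            feature_names or (f"x{i}" for i in range(self.exog.shape[1]))
        )
        self.config = FitConfig(attention=attention, l2_penalty=l2_penalty)
        self.init_sd = init_sd
        self.seed = seed

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        features,
        label_col: str = "group",
        positive: str = GROUP_T2DM,
        **kwargs,
    ) -> "VowelDiabetesTree":
        """Build from a cohort table: features from ``features`` columns,
        labels 1 where ``label_col`` equals ``positive``."""
        y = (data[label_col] == positive).astype(int).to_numpy()
        return cls(y, data[list(features)], feature_names=list(features), **kwargs)

    def start_params(self) -> VDTParams:
        return init_params(
            self.depth, self.exog.shape[1], init_sd=self.init_sd, seed=self.seed
        )

    def loss(self, params: VDTParams) -> float:
        return loss_and_grad(params, self.exog, self.endog, self.config)[0]

    def fit(
        self,
        max_iter: int = 200,
        grad_tol: float = 1e-5,
        start_params: VDTParams | None = None,
    ) -> "VDTResults":
        self.config.max_iter = max_iter
        self.config.grad_tol = grad_tol
        params0 = start_params or self.start_params()
        fitted, trace = fit_tree(self.exog, self.endog, params0, self.config)
        return VDTResults(self, fitted, trace)


class VDTResults:
    """Fit results: final parameters, optimization trace, prediction and
    diagnostics."""

    def __init__(self, model: VowelDiabetesTree, params: VDTParams, trace: dict):
        self.model = model
        self.params = params
        self.trace = trace

    @property
    def converged(self) -> bool:
        return self.trace["converged"]

    @property
    def final_loss(self) -> float:
        return self.trace["final_loss"]

    @property
    def n_iter(self) -> int:
        return self.trace["n_iter"]

    def _as_matrix(self, X) -> np.ndarray:
        if X is None:
            return self.model.exog
        if isinstance(X, pd.DataFrame):
            X = X[self.model.feature_names].to_numpy(dtype=float)
        return np.atleast_2d(np.asarray(X, dtype=float))

    def predict_proba(self, X=None) -> np.ndarray:
        return forward(self.params, self._as_matrix(X), self.model.config.attention)

    def predict(self, X=None, threshold: float | None = None, hard_routing=False):
        return predict(
            self.params,
            self._as_matrix(X),
            threshold if threshold is not None else self.model.config.threshold,
            self.model.config.attention,
            hard_routing,
        )

    def attention_frame(self) -> pd.DataFrame:
        """Per-internal-node attention weights over the features."""
        return pd.DataFrame(
            self.params.attention(self.model.config.attention),
            columns=self.model.feature_names,
            index=[f"node{j}" for j in range(self.params.n_internal)],
        )

    def summary(self) -> str:
        att = self.attention_frame()
        top = att.idxmax(axis=1)
        lines = [
            "Soft Decision Tree of Logistic Units",
            "=" * 54,
            f"No. observations: {len(self.model.endog):>8d}"
            f"    Depth (internal levels): {self.params.depth}",
            f"No. features:     {self.params.n_features:>8d}"
            f"    Internal nodes / leaves: {self.params.n_internal}/{self.params.n_leaves}",
            f"Attention: {self.model.config.attention:<15s}"
            f" L2 penalty: {self.model.config.l2_penalty:g}",
            f"Converged: {str(self.converged):<15s} Iterations: {self.n_iter}",
            f"Initial loss: {self.trace['initial_loss']:.6f}"
            f"    Final loss: {self.final_loss:.6f}",
            "-" * 54,
            "Dominant attention feature per node:",
        ]
        for node, feat in top.items():
            lines.append(f"  {node:>7s}: {feat:<16s} (alpha={att.loc[node, feat]:.3f})")
        lines.append("-" * 54)
        lines.append(
            "Leaf logits theta: "
            + np.array2string(self.params.theta, precision=3, separator=", ")
        )
        return "\n".join(lines)

    def save(self, path) -> None:
        """Serialize model, parameters, config and trace to JSON
        (round-trips losslessly via :meth:`load`)."""
        payload = {
            "schema_version": 1,
            "params": self.params.to_dict(),
            "feature_names": self.model.feature_names,
            "config": {
                "max_iter": self.model.config.max_iter,
                "grad_tol": self.model.config.grad_tol,
                "l2_penalty": self.model.config.l2_penalty,
                "threshold": self.model.config.threshold,
                "attention": self.model.config.attention,
            },
            "seed": self.model.seed,
            "trace": self.trace,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)

    @classmethod
    def load(cls, path) -> "VDTResults":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        params = VDTParams.from_dict(payload["params"])
        dummy_y = np.array([0.0, 1.0])
        dummy_x = np.zeros((2, params.n_features))
        model = VowelDiabetesTree(
            dummy_y,
            dummy_x,
            depth=params.depth,
            feature_names=payload["feature_names"],
            attention=payload["config"]["attention"],
            l2_penalty=payload["config"]["l2_penalty"],
            seed=payload["seed"],
        )
        model.config = FitConfig(**payload["config"])
        return cls(model, params, payload["trace"])
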