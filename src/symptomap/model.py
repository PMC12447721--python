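"""The multi-output network: shared trunk, per-output sub-layers, typed heads.

Architecture (all dense, ReLU):

    X --standardize--> Z1 (64, dropout) --> Z2 (32, dropout)
        --> one 8-node sub-layer z3_i per output --> one typed head per output

Heads and losses are assigned by output type: sigmoid + binary cross-entropy,
softmax + categorical cross-entropy, or a linear head + Huber loss.  The total
training loss is the unweighted sum of per-output losses plus an L2 penalty
(lambda/2) * sum(W^2) on kernel matrices only.  Training uses Adam on
mini-batches with inverted dropout; everything is implemented on NumPy arrays
with manual backpropagation (verified against finite differences in the test
suite), so a trained model is a plain dict of float64 arrays.

An auxiliary "score layer" regresses the n predicted scores into a binary
disease probability; it is fitted after the network, never with it.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import (
    OmicsMatrix,
    OutputSpec,
    ScoreMatrix,
    ScoreSchema,
    StandardizationStats,
    align_samples,
    standardize,
)


@dataclass
class ArchitectureSpec:
    """Layer widths and regularization of the network."""

    n_features: int
    width_z1: int = 64
    width_z2: int = 32
    width_z3: int = 8
    dropout_rate: float = 0.5
    l2_lambda: float = 0.008
    dropout_z3: bool = False  # figure places dropout on Z1/Z2 only; flag extends it

    def __post_init__(self) -> None:
        if min(self.n_features, self.width_z1, self.width_z2, self.width_z3) <= 0:
            raise ValueError("widths and n_features must be positive")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.l2_lambda < 0:
            raise ValueError("l2_lambda must be >= 0")


@dataclass
class Hyperparams:
    """Training hyperparameters (defaults are the grid-searched values)."""

    learning_rate: float = 0.0005
    epochs: int = 500
    batch_size: int = 64
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_epsilon: float = 1e-7
    huber_delta: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.learning_rate, self.adam_beta1, self.adam_beta2,
               self.adam_epsilon, self.huber_delta) <= 0:
            raise ValueError("hyperparameters must be positive")
        if self.epochs <= 0 or self.batch_size <= 0:
            raise ValueError("epochs and batch_size must be positive integers")


def head_dim(spec: OutputSpec) -> int:
    return spec.n_levels if spec.dtype == "categorical" else 1


def assign_loss(spec: OutputSpec) -> str:
    """Map an output type to its loss: bce / cce / huber."""
    if spec.dtype == "binary":
        return "bce"
    if spec.dtype == "categorical":
        return "cce"
    if spec.dtype == "continuous":
        return "huber"
    raise ValueError(f"unknown output dtype {spec.dtype!r}")


def huber(y, yhat, delta: float = 1.0):
    """Piecewise loss: 0.5 e^2 for |e| <= delta, delta(|e| - 0.5 delta) beyond."""
    if delta <= 0:
        raise ValueError("delta must be > 0")
    e = np.asarray(y, dtype=float) - np.asarray(yhat, dtype=float)
    a = np.abs(e)
    out = np.where(a <= delta, 0.5 * e**2, delta * (a - 0.5 * delta))
    return out if out.ndim else float(out)


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(0.0, x)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * x))  # numerically stable

def _softmax(x: np.ndarray) -> np.ndarray:
    z = x - x.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _output_rng(seed: int, name: str) -> np.random.Generator:
    # per-output stream keyed by name, so permuting schema order does not
    # change any output's initialization
    return np.random.default_rng([seed, zlib.crc32(name.encode())])


@dataclass
class TrainedModel:
    """Architecture + weights + fitted standardization + feature list."""

    arch: ArchitectureSpec
    schema: ScoreSchema
    params: dict[str, np.ndarray]
    stats: StandardizationStats | None = None
    feature_ids: list[str] | None = None
    history: dict[str, list[float]] = field(default_factory=dict)

    # -- persistence ---------------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Write a model bundle: weights.npz + manifest.json in a directory."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        arrays = dict(self.params)
        if self.stats is not None:
            arrays["__mean__"] = self.stats.mean
            arrays["__sd__"] = self.stats.sd
        np.savez(path / "weights.npz", **arrays)
        manifest = {
            "arch": self.arch.__dict__,
            "schema": self.schema.to_dict(),
            "feature_ids": self.feature_ids,
            "history": self.history,
        }
        (path / "manifest.json").write_text(json.dumps(manifest))

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        path = Path(path)
        manifest = json.loads((path / "manifest.json").read_text())
        with np.load(path / "weights.npz") as z:
            arrays = {k: z[k] for k in z.files}
        stats = None
        if "__mean__" in arrays:
            stats = StandardizationStats(
                mean=arrays.pop("__mean__"),
                sd=arrays.pop("__sd__"),
                feature_ids=list(manifest["feature_ids"]),
            )
        return cls(
            arch=ArchitectureSpec(**manifest["arch"]),
            schema=ScoreSchema.from_dict(manifest["schema"]),
            params=arrays,
            stats=stats,
            feature_ids=manifest["feature_ids"],
            history=manifest.get("history", {}),
        )

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params.values()))


def build_model(arch: ArchitectureSpec, schema: ScoreSchema, seed: int = 0) -> TrainedModel:
    """He-normal-initialized network: one 8-node sub-layer and one head per output."""
    if schema.n_outputs == 0:
        raise ValueError("schema declares zero outputs")

    def he(rng, fan_in, shape):
        return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)

    rng = np.random.default_rng([seed, 0])
    params: dict[str, np.ndarray] = {
        "W1": he(rng, arch.n_features, (arch.n_features, arch.width_z1)),
        "b1": np.zeros(arch.width_z1),
        "W2": he(rng, arch.width_z1, (arch.width_z1, arch.width_z2)),
        "b2": np.zeros(arch.width_z2),
    }
    for spec in schema.outputs:
        orng = _output_rng(seed, spec.name)
        h = head_dim(spec)
        params[f"W3:{spec.name}"] = he(orng, arch.width_z2, (arch.width_z2, arch.width_z3))
        params[f"b3:{spec.name}"] = np.zeros(arch.width_z3)
        params[f"W4:{spec.name}"] = he(orng, arch.width_z3, (arch.width_z3, h))
        params[f"b4:{spec.name}"] = np.zeros(h)
    return TrainedModel(arch=arch, schema=schema, params=params)


# ---------------------------------------------------------------------------
# forward / loss / backward
# ---------------------------------------------------------------------------

def _forward(
    params: Mapping[str, np.ndarray],
    arch: ArchitectureSpec,
    schema: ScoreSchema,
    Xs: np.ndarray,
    train: bool = False,
    rng: np.random.Generator | None = None,
) -> dict:
    """Forward pass on standardized input; returns activations for backprop."""
    cache: dict = {"X": Xs}
    H1 = Xs @ params["W1"] + params["b1"]
    A1 = relu(H1)
    if train and arch.dropout_rate > 0:
        keep = 1.0 - arch.dropout_rate
        M1 = (rng.random(A1.shape) < keep) / keep
        A1 = A1 * M1
        cache["M1"] = M1
    H2 = A1 @ params["W2"] + params["b2"]
    A2 = relu(H2)
    if train and arch.dropout_rate > 0:
        keep = 1.0 - arch.dropout_rate
        M2 = (rng.random(A2.shape) < keep) / keep
        A2 = A2 * M2
        cache["M2"] = M2
    cache.update(H1=H1, A1=A1, H2=H2, A2=A2)
    cache["out"] = {}
    for spec in schema.outputs:
        H3 = A2 @ params[f"W3:{spec.name}"] + params[f"b3:{spec.name}"]
        A3 = relu(H3)
        if train and arch.dropout_z3 and arch.dropout_rate > 0:
            keep = 1.0 - arch.dropout_rate
            M3 = (rng.random(A3.shape) < keep) / keep
            A3 = A3 * M3
        else:
            M3 = None
        O = A3 @ params[f"W4:{spec.name}"] + params[f"b4:{spec.name}"]
        if spec.dtype == "binary":
            pred = _sigmoid(O[:, 0])
        elif spec.dtype == "categorical":
            pred = _softmax(O)
        else:
            pred = O[:, 0]
        cache["out"][spec.name] = {"H3": H3, "A3": A3, "M3": M3, "O": O, "pred": pred}
    return cache


def _l2_penalty(params: Mapping[str, np.ndarray], lam: float) -> float:
    return 0.5 * lam * sum(
        float((w**2).sum()) for k, w in params.items() if k.startswith("W")
    )


def loss_and_grads(
    params: Mapping[str, np.ndarray],
    arch: ArchitectureSpec,
    schema: ScoreSchema,
    Xs: np.ndarray,
    Y: Mapping[str, np.ndarray],
    huber_delta: float = 1.0,
    train: bool = False,
    rng: np.random.Generator | None = None,
    loss_weights: Mapping[str, float] | None = None,
) -> tuple[float, dict[str, np.ndarray], dict[str, float]]:
    """Total loss (summed per-output losses + L2) and its gradients.

    ``Y`` maps output name to a raw target vector; NaN entries are masked.
    Returns (total, grads, per_output_losses).
    """
    cache = _forward(params, arch, schema, Xs, train=train, rng=rng)
    grads = {k: np.zeros_like(v) for k, v in params.items()}
    dA2 = np.zeros_like(cache["A2"])
    per_output: dict[str, float] = {}
    total = 0.0

    for spec in schema.outputs:
        name = spec.name
        w_i = 1.0 if loss_weights is None else float(loss_weights.get(name, 1.0))
        oc = cache["out"][name]
        y = np.asarray(Y[name], dtype=float)
        mask = ~np.isnan(y)
        nv = int(mask.sum())
        if nv == 0:
            per_output[name] = float("nan")
            continue
        O = oc["O"]
        dO = np.zeros_like(O)
        if spec.dtype == "binary":
            p = np.clip(oc["pred"], 1e-12, 1 - 1e-12)
            li = -(y[mask] * np.log(p[mask]) + (1 - y[mask]) * np.log(1 - p[mask])).mean()
            dO[mask, 0] = (oc["pred"][mask] - y[mask]) / nv
        elif spec.dtype == "categorical":
            P = np.clip(oc["pred"], 1e-12, None)
            onehot = np.zeros_like(O)
            onehot[mask, y[mask].astype(int)] = 1.0
            li = -(onehot[mask] * np.log(P[mask])).sum(axis=1).mean()
            dO[mask] = (oc["pred"][mask] - onehot[mask]) / nv
        else:
            e = y[mask] - oc["pred"][mask]
            li = float(np.mean(huber(y[mask], oc["pred"][mask], huber_delta)))
            dO[mask, 0] = -np.clip(e, -huber_delta, huber_delta) / nv
        li *= w_i
        dO *= w_i
        per_output[name] = float(li)
        total += float(li)

        A3, H3 = oc["A3"], oc["H3"]
        grads[f"W4:{name}"] += A3.T @ dO
        grads[f"b4:{name}"] += dO.sum(axis=0)
        dA3 = dO @ params[f"W4:{name}"].T
        if oc["M3"] is not None:
            dA3 = dA3 * oc["M3"]
        dH3 = dA3 * (H3 > 0)
        grads[f"W3:{name}"] += cache["A2"].T @ dH3
        grads[f"b3:{name}"] += dH3.sum(axis=0)
        dA2 += dH3 @ params[f"W3:{name}"].T

    if "M2" in cache:
        dA2 = dA2 * cache["M2"]
    dH2 = dA2 * (cache["H2"] > 0)
    grads["W2"] += cache["A1"].T @ dH2
    grads["b2"] += dH2.sum(axis=0)
    dA1 = dH2 @ params["W2"].T
    if "M1" in cache:
        dA1 = dA1 * cache["M1"]
    dH1 = dA1 * (cache["H1"] > 0)
    grads["W1"] += cache["X"].T @ dH1
    grads["b1"] += dH1.sum(axis=0)

    # L2 on kernels only
    lam = arch.l2_lambda
    if lam > 0:
        total += _l2_penalty(params, lam)
        for k in params:
            if k.startswith("W"):
                grads[k] += lam * params[k]
    return total, grads, per_output


def _targets_from_scores(Y: ScoreMatrix) -> dict[str, np.ndarray]:
    return {name: Y.data[name].to_numpy() for name in Y.schema.names}


def train(
    model: TrainedModel,
    X: OmicsMatrix,
    Y: ScoreMatrix,
    hp: Hyperparams,
    loss_weights: Mapping[str, float] | None = None,
) -> TrainedModel:
    """Fit the network with Adam on mini-batches.

    The standardization layer is fitted here on the training data and stored
    with the weights; ``X`` is given raw.  Deterministic given ``hp.seed``.
    """
    X, Y = align_samples(X, Y)
    Xstd, stats = standardize(X)
    Xs = Xstd.values
    targets = _targets_from_scores(Y)
    schema = model.schema
    arch = model.arch
    if arch.n_features != X.n_features:
        raise ValueError(f"model expects {arch.n_features} features, got {X.n_features}")

    params = {k: v.copy() for k, v in model.params.items()}
    m_adam = {k: np.zeros_like(v) for k, v in params.items()}
    v_adam = {k: np.zeros_like(v) for k, v in params.items()}
    t = 0
    rng = np.random.default_rng([hp.seed, 1])
    n = Xs.shape[0]
    history: dict[str, list[float]] = {name: [] for name in schema.names}
    history["total"] = []

    for epoch in range(hp.epochs):
        order = rng.permutation(n)
        epoch_total = 0.0
        epoch_out = {name: 0.0 for name in schema.names}
        n_batches = 0
        for start in range(0, n, hp.batch_size):
            idx = order[start : start + hp.batch_size]
            total, grads, per_out = loss_and_grads(
                params, arch, schema, Xs[idx],
                {k: v[idx] for k, v in targets.items()},
                huber_delta=hp.huber_delta, train=True, rng=rng,
                loss_weights=loss_weights,
            )
            if not np.isfinite(total):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}; try a lower learning rate "
                    f"than {hp.learning_rate}"
                )
            t += 1
            for k in params:
                m_adam[k] = hp.adam_beta1 * m_adam[k] + (1 - hp.adam_beta1) * grads[k]
                v_adam[k] = hp.adam_beta2 * v_adam[k] + (1 - hp.adam_beta2) * grads[k] ** 2
                mhat = m_adam[k] / (1 - hp.adam_beta1**t)
                vhat = v_adam[k] / (1 - hp.adam_beta2**t)
                params[k] -= hp.learning_rate * mhat / (np.sqrt(vhat) + hp.adam_epsilon)
            epoch_total += total
            for name, li in per_out.items():
                if np.isfinite(li):
                    epoch_out[name] += li
            n_batches += 1
        history["total"].append(epoch_total / n_batches)
        for name in schema.names:
            history[name].append(epoch_out[name] / n_batches)

    return TrainedModel(
        arch=arch, schema=schema, params=params, stats=stats,
        feature_ids=X.feature_ids, history=history,
    )


class ModelEnsemble:
    """Average of models trained on the iterations of an under-sampling plan."""

    def __init__(self, models: Sequence[TrainedModel]):
        if not models:
            raise ValueError("empty ensemble")
        self.models = list(models)
        self.schema = models[0].schema
        self.feature_ids = models[0].feature_ids

    def predict(self, X: OmicsMatrix) -> dict[str, np.ndarray]:
        preds = [predict_scores(m, X) for m in self.models]
        return {
            name: np.mean([p[name] for p in preds], axis=0)
            for name in self.schema.names
        }


def train_resampled(
    model: TrainedModel,
    X: OmicsMatrix,
    Y: ScoreMatrix,
    hp: Hyperparams,
    plan,
    mode: str = "ensemble",
) -> TrainedModel | ModelEnsemble:
    """Train under a :class:`~symptomap.resampling.ResamplePlan`.

    ``mode="ensemble"`` (default) trains one model per balanced subset and
    averages predictions at inference; ``mode="single"`` trains once on the
    first subset.  Both are interpretations of training "per iteration".
    """
    X, Y = align_samples(X, Y)
    iters = plan.iterations if mode == "ensemble" else plan.iterations[:1]
    fitted = []
    for i, idx in enumerate(iters):
        Xi = OmicsMatrix(X.data.iloc[idx], kind=X.kind)
        Yi = ScoreMatrix(Y.data.iloc[idx], Y.schema)
        init = build_model(model.arch, model.schema, seed=hp.seed + i)
        fitted.append(train(init, Xi, Yi, Hyperparams(**{**hp.__dict__, "seed": hp.seed + i})))
    return fitted[0] if mode == "single" else ModelEnsemble(fitted)


def predict_scores(model: TrainedModel, X: OmicsMatrix) -> dict[str, np.ndarray]:
    """Inference pass (dropout off): name -> vector, or (n, C) for categorical."""
    if model.feature_ids is not None:
        missing = [f for f in model.feature_ids if f not in X.data.columns]
        if missing:
            raise ValueError(f"input lacks model features, e.g. {missing[:5]}")
        X = OmicsMatrix(X.data[model.feature_ids], kind=X.kind)
    if X.n_features != model.arch.n_features:
        raise ValueError(f"model expects {model.arch.n_features} features, got {X.n_features}")
    if model.stats is not None:
        Xstd, _ = standardize(X, model.stats)
        Xs = Xstd.values
    else:
        Xs = X.values
    cache = _forward(model.params, model.arch, model.schema, Xs, train=False)
    return {name: cache["out"][name]["pred"] for name in model.schema.names}


def encode_scores(
    values: Mapping[str, np.ndarray], schema: ScoreSchema, index=None, clip: bool = False
) -> pd.DataFrame:
    """Flatten typed predictions to one column per output.

    Categorical probability vectors become the expected level sum(l * p_l);
    ``clip`` clips continuous outputs to [0, 1] (reporting only — never done
    inside a loss).
    """
    out = {}
    for spec in schema.outputs:
        v = np.asarray(values[spec.name], dtype=float)
        if spec.dtype == "categorical" and v.ndim == 2:
            v = v @ np.arange(spec.n_levels)
        if spec.dtype == "continuous" and clip:
            v = np.clip(v, 0.0, 1.0)
        out[spec.name] = v
    return pd.DataFrame(out, index=index)


# ---------------------------------------------------------------------------
# auxiliary score layer: predicted scores -> disease probability
# ---------------------------------------------------------------------------

@dataclass
class ScoreLayerWeights:
    """Weights of the scores -> diagnosis sigmoid layer."""

    w: np.ndarray
    bias: float = 0.0

    def predict(self, Y_scores: np.ndarray) -> np.ndarray:
        return _sigmoid(np.asarray(Y_scores) @ self.w + self.bias)


def score_layer_init(
    Y_true: np.ndarray, labels: np.ndarray, mode: str = "clinical"
) -> ScoreLayerWeights:
    """Initial weights for the score layer.

    ``clinical`` derives them from the observed clinical data — a logistic fit
    of the true scores on the disease label, rescaled to unit norm; ``uniform``
    starts from equal weights.
    """
    k = Y_true.shape[1]
    if mode == "uniform":
        return ScoreLayerWeights(w=np.full(k, 1.0 / k), bias=0.0)
    from sklearn.linear_model import LogisticRegression

    lr = LogisticRegression(max_iter=2000)
    lr.fit(Y_true, np.asarray(labels).astype(int))
    w = lr.coef_[0]
    norm = np.linalg.norm(w)
    if norm > 0:
        w = w / norm
    return ScoreLayerWeights(w=w, bias=float(lr.intercept_[0]) / max(norm, 1e-12))


def score_layer_fit(
    Y_pred: np.ndarray,
    labels: np.ndarray,
    w0: ScoreLayerWeights,
    n_steps: int = 500,
    eta: float = 0.1,
) -> tuple[ScoreLayerWeights, list[float]]:
    """Gradient descent on the MSE between sigmoid(w.Y + b) and the labels.

    The network's weights are untouched; only (w, b) move, by
    w_new = w_old - eta * grad(L_MSE).  Returns the weights and the loss trace.
    """
    if eta <= 0:
        raise ValueError("eta must be > 0")
    Y = np.asarray(Y_pred, dtype=float)
    y = np.asarray(labels, dtype=float)
    w = w0.w.astype(float).copy()
    b = float(w0.bias)
    n = len(y)
    trace = []
    for _ in range(n_steps):
        p = _sigmoid(Y @ w + b)
        loss = float(np.mean((p - y) ** 2))
        trace.append(loss)
        dlogit = 2.0 * (p - y) * p * (1 - p) / n
        w -= eta * (Y.T @ dlogit)
        b -= eta * float(dlogit.sum())
    return ScoreLayerWeights(w=w, bias=b), trace


# ---------------------------------------------------------------------------
# combined-omics panel from per-omics attributions
# ---------------------------------------------------------------------------

def build_combined_omics(
    attributions_by_kind: Mapping[str, Sequence],
    omics: Mapping[str, OmicsMatrix],
    top_counts: Mapping[str, int],
) -> OmicsMatrix:
    """Concatenate each kind's most attributed features into one matrix.

    Features are ranked per kind by mean |phi| across outputs and samples;
    ``top_counts`` says how many to take from each kind (the reference panel
    used 50 immune + 32 species + 30 KEGG genes + 42 metabolites = 154).
    Duplicate names across kinds are kind-prefixed to stay unique.
    """
    frames = []
    seen: set[str] = set()
    for kind, count in top_counts.items():
        X = omics[kind]
        atts = attributions_by_kind[kind]
        if count > X.n_features:
            raise ValueError(f"requested {count} features from {kind!r} but only {X.n_features} exist")
        importance = np.mean([np.abs(a.phi).mean(axis=0) for a in atts], axis=0)
        order = np.argsort(-importance, kind="stable")[:count]
        cols = [X.feature_ids[i] for i in sorted(order)]  # preserve original order
        df = X.data[cols].copy()
        df.columns = [c if c not in seen else f"{kind}_{c}" for c in df.columns]
        seen.update(df.columns)
        frames.append(df)
    return OmicsMatrix(pd.concat(frames, axis=1), kind="combined")
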