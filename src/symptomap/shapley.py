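"""Decode the network: per-output sub-models, Shapley attributions, biomarkers.

Because the trunk (Z1, Z2) is shared and each output owns its sub-layer and
head, the full model factors exactly into one single-output sub-model per
output.  Each sub-model is explained with Shapley values: the contribution of
feature j to the prediction at x is

    phi_j = sum over S subset of N\\{j} of  |S|! (m-|S|-1)! / m!
            * [ f(x with S+{j} present) - f(x with S present) ]

with absent features replaced by background means (single-reference
interventional baseline).  Two estimators are provided: exact enumeration over
all 2^m coalitions (m <= 15; the oracle) and the kernel estimator — a weighted
least-squares fit over sampled coalitions with the Shapley kernel weights and
the local-accuracy constraint sum(phi) = f(x) - f(background).  With the full
coalition set the kernel estimate coincides with the exact values.

Features are then categorized: ranked per output by mean |phi|, a feature that
is a top-k contributor in at least a cutoff fraction (default 75%) of outputs
is a disease-level biomarker; features ranking for fewer outputs are
symptom-specific to those outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb, factorial
from typing import Callable, Mapping, Sequence

import numpy as np

from .io import OmicsMatrix
from .model import TrainedModel, _forward, relu, _sigmoid, _softmax

Predictor = Callable[[np.ndarray], np.ndarray]


@dataclass
class AttributionMatrix:
    """Per-output sample x feature Shapley values."""

    output_name: str
    phi: np.ndarray               # (n_samples, n_features)
    base_value: float             # sub-model output at the background reference
    feature_ids: list[str]
    sample_ids: list[str]
    background: str = ""          # how the reference was built

    def mean_abs(self) -> np.ndarray:
        return np.abs(self.phi).mean(axis=0)


@dataclass
class BiomarkerCatalog:
    """Shared (disease-level) vs output-specific biomarker partition."""

    disease_specific: list[str]
    symptom_specific: dict[str, list[str]]
    top_rank_counts: dict[str, int]   # feature -> number of outputs where top-k
    rankings: dict[str, list[str]]    # output -> ordered top-k features
    top_k: int
    cutoff: float

    def to_dict(self) -> dict:
        return {
            "disease_specific": self.disease_specific,
            "symptom_specific": self.symptom_specific,
            "top_rank_counts": self.top_rank_counts,
            "rankings": self.rankings,
            "top_k": self.top_k,
            "cutoff": self.cutoff,
        }


# ---------------------------------------------------------------------------
# sub-model reconstruction
# ---------------------------------------------------------------------------

def extract_submodel(model: TrainedModel, output_index: int) -> Predictor:
    """Reconstruct the single-output predictor trunk + z3_i + head_i.

    The callable takes a raw (n, m) array in the model's feature order,
    applies the stored standardization, and returns one scalar per sample
    (probability for binary heads, expected level for categorical heads).
    It shares the full model's weights, so it agrees with the full model's
    i-th output exactly and never mutates it.
    """
    if not 0 <= output_index < model.schema.n_outputs:
        raise IndexError(f"output index {output_index} out of range")
    spec = model.schema.outputs[output_index]
    name = spec.name
    W1, b1 = model.params["W1"], model.params["b1"]
    W2, b2 = model.params["W2"], model.params["b2"]
    W3, b3 = model.params[f"W3:{name}"], model.params[f"b3:{name}"]
    W4, b4 = model.params[f"W4:{name}"], model.params[f"b4:{name}"]
    stats = model.stats

    def f(X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if stats is not None:
            denom = np.where(stats.sd == 0, 1.0, stats.sd)
            X = (X - stats.mean) / denom
        A2 = relu(relu(X @ W1 + b1) @ W2 + b2)
        O = relu(A2 @ W3 + b3) @ W4 + b4
        if spec.dtype == "binary":
            return _sigmoid(O[:, 0])
        if spec.dtype == "categorical":
            return _softmax(O) @ np.arange(spec.n_levels)
        return O[:, 0]

    f.output_name = name  # type: ignore[attr-defined]
    return f


# ---------------------------------------------------------------------------
# exact enumeration oracle
# ---------------------------------------------------------------------------

def _background_reference(background: np.ndarray) -> np.ndarray:
    bg = np.atleast_2d(np.asarray(background, dtype=float))
    if bg.size == 0:
        raise ValueError("background must be non-empty")
    return bg.mean(axis=0)


def exact_shapley(f: Predictor, x: np.ndarray, background: np.ndarray) -> np.ndarray:
    """Shapley values by full enumeration over all 2^m coalitions (m <= 15)."""
    x = np.asarray(x, dtype=float).ravel()
    m = len(x)
    if m > 15:
        raise ValueError(f"{m} features is too many for enumeration; use kernel_shapley")
    ref = _background_reference(background)

    masks = np.arange(2**m)
    bits = (masks[:, None] >> np.arange(m)) & 1  # (2^m, m)
    inputs = np.where(bits.astype(bool), x, ref)
    v = np.asarray(f(inputs), dtype=float)

    sizes = bits.sum(axis=1)
    weight_by_size = np.array(
        [factorial(s) * factorial(m - s - 1) / factorial(m) for s in range(m)]
    )
    phi = np.zeros(m)
    for j in range(m):
        without_j = (bits[:, j] == 0)
        s = sizes[without_j]
        gain = v[masks[without_j] | (1 << j)] - v[without_j]
        phi[j] = float((weight_by_size[s] * gain).sum())
    return phi


# ---------------------------------------------------------------------------
# kernel estimator (weighted least squares over coalitions)
# ---------------------------------------------------------------------------

def _all_proper_masks(m: int) -> np.ndarray:
    bits = (np.arange(2**m)[:, None] >> np.arange(m)) & 1
    sizes = bits.sum(axis=1)
    return bits[(sizes > 0) & (sizes < m)].astype(float)


def _sample_masks(m: int, n_coalitions: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Coalition masks and regression weights.

    Full enumeration (when the budget covers all 2^m - 2 proper coalitions)
    uses the analytic Shapley kernel weights; otherwise coalition sizes are
    sampled proportional to the kernel mass per size and unit regression
    weights apply (importance sampling).
    """
    total = 2**m - 2
    if n_coalitions >= total:
        Z = _all_proper_masks(m)
        s = Z.sum(axis=1).astype(int)
        w = (m - 1) / (np.array([comb(m, k) for k in s]) * s * (m - s))
        return Z, w
    size_mass = np.array([(m - 1) / (s * (m - s)) for s in range(1, m)])
    size_p = size_mass / size_mass.sum()
    sizes = rng.choice(np.arange(1, m), size=n_coalitions, p=size_p)
    Z = np.zeros((n_coalitions, m))
    for i, s in enumerate(sizes):
        Z[i, rng.choice(m, size=s, replace=False)] = 1.0
    return Z, np.ones(n_coalitions)


def _solve_constrained_wls(
    Z: np.ndarray, w: np.ndarray, y: np.ndarray, total: np.ndarray
) -> np.ndarray:
    """Solve min sum w_z (y_z - Z phi)^2  s.t.  sum(phi) = total.

    ``y`` may be (K,) or (K, n_samples); ``total`` scalar or (n_samples,).
    The constraint is eliminated through the last coordinate.
    """
    m = Z.shape[1]
    y = np.atleast_2d(y.T).T  # (K, B)
    total = np.atleast_1d(total)
    sw = np.sqrt(w)[:, None]
    X_red = (Z[:, :-1] - Z[:, -1:]) * sw
    Y_red = (y - Z[:, -1:] * total[None, :]) * sw
    beta, *_ = np.linalg.lstsq(X_red, Y_red, rcond=None)  # (m-1, B)
    phi = np.vstack([beta, total[None, :] - beta.sum(axis=0)])
    return phi if phi.shape[1] > 1 else phi[:, 0]


def kernel_shapley(
    f: Predictor,
    x: np.ndarray,
    background: np.ndarray,
    n_coalitions: int | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Kernel (regression) estimate of the Shapley values for one sample."""
    x = np.asarray(x, dtype=float).ravel()
    m = len(x)
    if n_coalitions is None:
        n_coalitions = min(2**m - 2, 2 * m + 2048)
    if n_coalitions < m + 2:
        raise ValueError(f"n_coalitions={n_coalitions} under-determines {m} features (need >= m+2)")
    ref = _background_reference(background)
    rng = np.random.default_rng(seed)
    Z, w = _sample_masks(m, n_coalitions, rng)

    inputs = np.where(Z.astype(bool), x, ref)
    base = float(np.asarray(f(ref[None, :]))[0])
    fx = float(np.asarray(f(x[None, :]))[0])
    y = np.asarray(f(inputs), dtype=float) - base
    return _solve_constrained_wls(Z, w, y, np.array([fx - base]))


def explain_all(
    model: TrainedModel,
    X: OmicsMatrix,
    background_size: int | str = 100,
    n_coalitions: int | None = None,
    seed: int = 0,
    mode: str = "kernel",
    sample_ids: Sequence[str] | None = None,
) -> list[AttributionMatrix]:
    """Attribute every output of the model over the samples of ``X``.

    The background is a seeded random subset of ``X`` (``background_size``
    rows; pass ``"all"`` to use every row), summarized by its feature means.
    One coalition design is drawn per call and shared across samples, so the
    per-sample solves collapse to a single least-squares with many right-hand
    sides.  ``mode="exact"`` enumerates all coalitions (m <= 15).
    """
    if model.feature_ids is not None:
        X = OmicsMatrix(X.data[model.feature_ids], kind=X.kind)
    Xv = X.values
    n, m = Xv.shape
    rng = np.random.default_rng(seed)
    if background_size == "all":
        bg = Xv
        bg_desc = f"all {n} samples (mean reference)"
    else:
        if background_size > n:
            raise ValueError(f"background_size {background_size} exceeds {n} samples")
        idx = rng.choice(n, size=int(background_size), replace=False)
        bg = Xv[idx]
        bg_desc = f"random subset of {background_size} samples (mean reference), seed {seed}"
    ref = _background_reference(bg)

    if sample_ids is not None:
        keep = [X.sample_ids.index(s) for s in sample_ids]
        Xv = Xv[keep]
        ids = list(sample_ids)
        n = len(ids)
    else:
        ids = X.sample_ids

    if mode == "exact":
        if m > 15:
            raise ValueError("exact mode limited to 15 features")
        Z = _all_proper_masks(m)
        w = None  # unused; exact path below
    else:
        if n_coalitions is None:
            n_coalitions = min(2**m - 2, 2 * m + 2048)
        if n_coalitions < m + 2:
            raise ValueError(f"n_coalitions={n_coalitions} under-determines {m} features")
        Z, w = _sample_masks(m, n_coalitions, rng)

    out = []
    for i in range(model.schema.n_outputs):
        f = extract_submodel(model, i)
        base = float(np.asarray(f(ref[None, :]))[0])
        fx = np.asarray(f(Xv), dtype=float)
        if mode == "exact":
            phi = np.vstack([exact_shapley(f, Xv[s], bg) for s in range(n)])
        else:
            K = Z.shape[0]
            Y = np.empty((K, n))
            mask = Z.astype(bool)
            for s in range(n):  # chunked evaluation keeps memory bounded
                inputs = np.where(mask, Xv[s], ref)
                Y[:, s] = f(inputs)
            Y -= base
            phi = _solve_constrained_wls(Z, w, Y, fx - base)  # (m, n) or (m,)
            phi = phi.T if phi.ndim == 2 else phi[None, :]
        out.append(
            AttributionMatrix(
                output_name=model.schema.names[i],
                phi=np.atleast_2d(phi),
                base_value=base,
                feature_ids=X.feature_ids,
                sample_ids=ids,
                background=bg_desc,
            )
        )
    return out


# ---------------------------------------------------------------------------
# biomarker categorization and variance decomposition
# ---------------------------------------------------------------------------

def categorize_biomarkers(
    attributions: Sequence[AttributionMatrix],
    top_k: int = 10,
    cutoff: float = 0.75,
) -> BiomarkerCatalog:
    """Partition features into disease-level vs output-specific biomarkers.

    Per output, features are ranked by mean |phi| (ties broken lexicographically
    by feature id).  A feature in the top-k of at least ``cutoff`` of the
    outputs (inclusive: 9 of 12 qualifies at 0.75) is disease-specific; one in
    fewer outputs is symptom-specific for the outputs where it ranks.
    """
    if len(attributions) < 2:
        raise ValueError("need at least two outputs to categorize biomarkers")
    feats = attributions[0].feature_ids
    if top_k > len(feats):
        raise ValueError(f"top_k={top_k} exceeds {len(feats)} features")
    n_outputs = len(attributions)

    rankings: dict[str, list[str]] = {}
    counts: dict[str, int] = {}
    for att in attributions:
        imp = att.mean_abs()
        order = sorted(range(len(feats)), key=lambda j: (-imp[j], feats[j]))
        top = [feats[j] for j in order[:top_k]]
        rankings[att.output_name] = top
        for fid in top:
            counts[fid] = counts.get(fid, 0) + 1

    disease = sorted(f for f, c in counts.items() if c / n_outputs >= cutoff)
    disease_set = set(disease)
    symptom = {
        att.output_name: [f for f in rankings[att.output_name] if f not in disease_set]
        for att in attributions
    }
    return BiomarkerCatalog(
        disease_specific=disease,
        symptom_specific=symptom,
        top_rank_counts=counts,
        rankings=rankings,
        top_k=top_k,
        cutoff=cutoff,
    )


def _r2(y: np.ndarray, design: np.ndarray) -> float:
    X = np.column_stack([np.ones(len(y)), design])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    tot = float(((y - y.mean()) ** 2).sum())
    return 1.0 - float((resid**2).sum()) / tot


def variance_decomposition(
    attribution: AttributionMatrix,
    catalog: BiomarkerCatalog,
    predictions: np.ndarray,
) -> tuple[float, float, float]:
    """Share of a sub-model's prediction variance carried by each biomarker class.

    The prediction is regressed on the summed phi of the disease-specific
    features, then additionally on the summed phi of this output's
    symptom-specific features; shares are the incremental R^2 and the residual
    completes to 1.  A constant prediction yields (0, 0, 1).
    """
    y = np.asarray(predictions, dtype=float)
    if np.allclose(y.std(), 0):
        return (0.0, 0.0, 1.0)
    fidx = {f: j for j, f in enumerate(attribution.feature_ids)}
    d_cols = [fidx[f] for f in catalog.disease_specific if f in fidx]
    s_cols = [
        fidx[f]
        for f in catalog.symptom_specific.get(attribution.output_name, [])
        if f in fidx
    ]
    d_sum = attribution.phi[:, d_cols].sum(axis=1) if d_cols else np.zeros(len(y))
    s_sum = attribution.phi[:, s_cols].sum(axis=1) if s_cols else np.zeros(len(y))

    r2_d = _r2(y, d_sum[:, None]) if d_cols else 0.0
    r2_ds = _r2(y, np.column_stack([d_sum, s_sum])) if (d_cols or s_cols) else 0.0
    disease = max(0.0, min(1.0, r2_d))
    symptom = max(0.0, min(1.0 - disease, r2_ds - r2_d))
    residual = 1.0 - disease - symptom
    return (disease, symptom, residual)
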