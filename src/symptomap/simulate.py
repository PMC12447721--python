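"""Synthetic multi-omics cohorts with planted, shaped feature effects.

The generator emulates the statistical skeleton of a case/control multi-omics
study: compositional species abundances (Dirichlet), sparse non-negative gene
abundances, bounded immune-cell proportions, log-normal metabolite intensities
and gaussian blood labs, together with a 2:1 case:control imbalance.  A chosen
set of features is "planted" to drive the clinical scores — either every score
(shared, disease-level biomarkers) or exactly one score (symptom-specific
biomarkers) — through one of three contribution shapes:

* ``monotonic`` — linear in the standardized feature,
* ``biphasic``  — quadratic ``(x - x0)^2`` (both tails deviate),
* ``sparse``    — linear but active only in a random subset of samples.

The planted ledger (:class:`GroundTruth`) is the oracle for attribution and
biomarker-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import OmicsMatrix, ScoreMatrix, ScoreSchema, default_schema

DEFAULT_FEATURE_COUNTS = {
    "species": 60,
    "kegg": 120,
    "immune": 40,
    "metabolome": 60,
    "blood": 12,
}

#: multiplier ladder for planted effect strengths.  Real biomarker panels are
#: heterogeneous: most markers carry comparable signal, a minority are weak.
#: One in five shared markers and one in three per-symptom markers are weak.
STRONG, WEAK = 1.0, 0.3
SHARED_LADDER_PERIOD = 5   # every 5th shared marker is weak
SPECIFIC_LADDER_PERIOD = 3  # every 3rd specific marker is weak


@dataclass
class SimConfig:
    """Study conditions for one synthetic cohort."""

    n_samples: int = 300
    case_control_ratio: float = 2.0
    feature_counts: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_FEATURE_COUNTS))
    n_shared_biomarkers: int = 10
    n_specific_per_output: int = 3
    effect_shapes: Sequence[str] | str = "monotonic"
    effect_size: float = 1.0
    noise_sd: float = 0.5
    module_size: int = 4
    batch_shift: float = 0.0
    seed: int = 0
    schema: ScoreSchema = field(default_factory=default_schema)

    def __post_init__(self) -> None:
        if self.n_samples < 20:
            raise ValueError("n_samples must be >= 20")
        if any(c < 0 for c in self.feature_counts.values()):
            raise ValueError("feature counts must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.case_control_ratio <= 0:
            raise ValueError("case_control_ratio must be > 0")
        n_cases = round(self.n_samples * self.case_control_ratio / (1 + self.case_control_ratio))
        if n_cases in (0, self.n_samples):
            raise ValueError(
                f"case_control_ratio {self.case_control_ratio} infeasible for n={self.n_samples}"
            )

    @property
    def n_cases(self) -> int:
        return round(self.n_samples * self.case_control_ratio / (1 + self.case_control_ratio))


@dataclass
class PlantedEffect:
    """One planted feature -> score(s) effect."""

    feature: str          # kind-prefixed feature id
    kind: str
    targets: list[str]    # output names; all outputs for shared markers
    shape: str            # monotonic | biphasic | sparse
    sign: int
    multiplier: float     # position on the strength ladder
    shared: bool
    x0: float = 0.0       # biphasic vertex (on the standardized scale)


@dataclass
class GroundTruth:
    """The generator's planted-effect ledger (oracle for recovery tests)."""

    planted: list[PlantedEffect]
    severity: pd.DataFrame        # sample x output latent severity
    disease_latent: pd.Series
    labels: pd.Series             # 1 = case
    config_seed: int
    module_assignment: dict[str, str] = field(default_factory=dict)  # feature -> module

    @property
    def shared_features(self) -> list[str]:
        return [p.feature for p in self.planted if p.shared]

    def specific_features(self, output: str) -> list[str]:
        return [p.feature for p in self.planted if not p.shared and p.targets == [output]]

    def to_dict(self) -> dict:
        return {
            "planted": [asdict(p) for p in self.planted],
            "labels": self.labels.to_dict(),
            "config_seed": self.config_seed,
        }


# ---------------------------------------------------------------------------
# correlated latent blocks and per-kind observation models
# ---------------------------------------------------------------------------
# Features come in co-abundance modules: feature j = sqrt(r_j) g_m + sqrt(1-r_j) e_j
# with a shared module factor g_m and loading r_j ~ U(0.3, 0.7).  A planted
# biomarker is the HUB of its module (r = 0.85), mirroring how real biomarkers
# tend to be the cleanest readout of a co-regulated pathway.

HUB_LOADING = 0.85


def _observation_params(kind: str, p: int, rng: np.random.Generator) -> dict:
    """Per-feature observation-model parameters (structural: shared across
    cohorts drawn from the same study design)."""
    if kind == "species":
        return {"offset": rng.normal(-1.0, 1.5, size=p)}
    if kind == "kegg":
        return {"prevalence": rng.uniform(0.3, 1.0, size=p)}
    if kind == "immune":
        return {}
    if kind == "metabolome":
        return {"mu": rng.normal(0.0, 0.5, size=p)}
    if kind == "blood":
        return {"scale": rng.uniform(0.5, 3.0, size=p), "loc": rng.uniform(1.0, 10.0, size=p)}
    raise ValueError(f"unknown omics kind {kind!r}")


def _observe(kind: str, Z: np.ndarray, params: dict, rng: np.random.Generator) -> np.ndarray:
    """Map latent gaussians to each assay's observation scale."""
    n, p = Z.shape
    if p == 0:
        return Z
    if kind == "species":
        # logistic-normal composition: skewed offsets, rows sum to 1 exactly
        A = np.exp(params["offset"] + Z)
        return A / A.sum(axis=1, keepdims=True)
    if kind == "kegg":
        # sparse non-negative gene abundances: lognormal intensity x presence
        present = rng.random((n, p)) < params["prevalence"]
        return np.where(present, np.exp(Z), 0.0)
    if kind == "immune":
        # Beta(2, 5) marginal cell frequencies via the probability transform
        from scipy.stats import beta, norm

        return beta.ppf(norm.cdf(Z), 2.0, 5.0)
    if kind == "metabolome":
        return np.exp(params["mu"] + Z)
    if kind == "blood":
        return params["loc"] + params["scale"] * Z
    raise ValueError(f"unknown omics kind {kind!r}")


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (x - x.mean(axis=0)) / sd


def _contribution(
    x: np.ndarray, shape: str, sign: int, x0: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit-variance-ish contribution of one standardized planted feature."""
    if shape == "monotonic":
        c = sign * x
    elif shape == "biphasic":
        q = (x - x0) ** 2
        c = sign * (q - q.mean()) / max(q.std(), 1e-12)
    elif shape == "sparse":
        active = rng.random(x.shape[0]) < 0.3
        c = sign * np.where(active, x, 0.0) / np.sqrt(0.3)
    else:
        raise ValueError(f"unknown effect shape {shape!r}")
    return c


def _ladder(i: int, period: int) -> float:
    return WEAK if (i + 1) % period == 0 else STRONG


def simulate_cohort(
    config: SimConfig, sample_seed: int | None = None
) -> tuple[dict[str, OmicsMatrix], ScoreMatrix, pd.Series, GroundTruth]:
    """Draw one cohort under ``config``.

    Returns per-kind omics matrices, the score matrix, binary disease labels
    (1 = case) and the :class:`GroundTruth` ledger.  The same config (hence the
    same seed) reproduces everything bit-identically.

    Structural randomness (module layout, which features are planted, effect
    signs, per-feature observation parameters) is keyed by ``config.seed``;
    per-sample randomness is keyed by ``sample_seed`` (defaulting to the config
    seed).  Passing a different ``sample_seed`` therefore draws a NEW cohort
    from the SAME study design — the mechanism behind external-cohort
    simulation.
    """
    rng = np.random.default_rng([config.seed, 17])           # structural stream
    srng = np.random.default_rng(
        [config.seed if sample_seed is None else sample_seed, 29]
    )                                                        # per-sample stream
    n = config.n_samples
    schema = config.schema
    sample_ids = [f"S{i:04d}" for i in range(n)]

    # 1. co-abundance module layout per kind (labels, loadings)
    layout: dict[str, tuple[list[str], np.ndarray]] = {}
    feature_names: dict[str, list[str]] = {}
    obs_params: dict[str, dict] = {}
    for kind, p in config.feature_counts.items():
        if config.module_size <= 1 or p == 0:
            labels_k = [f"{kind}_M{j:03d}" for j in range(p)]
            loadings = np.zeros(p)
        else:
            n_modules = max(1, p // config.module_size)
            labels_k = [f"{kind}_M{j % n_modules:03d}" for j in range(p)]
            loadings = rng.uniform(0.3, 0.7, size=p)
        layout[kind] = (labels_k, loadings)
        feature_names[kind] = [f"{kind}_f{j:03d}" for j in range(p)]
        obs_params[kind] = _observation_params(kind, p, rng)

    n_specific_total = config.n_specific_per_output * schema.n_outputs
    n_planted = config.n_shared_biomarkers + n_specific_total
    n_features_total = sum(config.feature_counts.values())
    if n_planted > n_features_total:
        raise ValueError(f"{n_planted} planted effects exceed {n_features_total} features")

    # 2. planted biomarkers: one hub feature in each of n_planted distinct modules
    module_members: dict[str, list[tuple[str, int]]] = {}
    for kind, (labels_k, _) in layout.items():
        for j, mname in enumerate(labels_k):
            module_members.setdefault(mname, []).append((kind, j))
    module_list = sorted(module_members)
    if n_planted > len(module_list):
        raise ValueError(
            f"{n_planted} planted biomarkers need {n_planted} distinct modules "
            f"but only {len(module_list)} exist; lower module_size or raise feature counts"
        )
    chosen_modules = rng.choice(len(module_list), size=n_planted, replace=False)
    if isinstance(config.effect_shapes, str):
        shapes = [config.effect_shapes] * n_planted
    else:
        shapes = [config.effect_shapes[i % len(config.effect_shapes)] for i in range(n_planted)]

    planted: list[PlantedEffect] = []
    hub_of: dict[tuple[str, int], bool] = {}
    for idx, mi in enumerate(chosen_modules):
        members = module_members[module_list[mi]]
        kind, j = members[rng.integers(len(members))]
        if config.module_size > 1:
            layout[kind][1][j] = HUB_LOADING  # the biomarker is the module hub
        hub_of[(kind, j)] = True
        name = feature_names[kind][j]
        shared = idx < config.n_shared_biomarkers
        if shared:
            targets = list(schema.names)
            mult = _ladder(idx, SHARED_LADDER_PERIOD)
        else:
            jj = idx - config.n_shared_biomarkers
            targets = [schema.names[jj // config.n_specific_per_output]]
            mult = _ladder(jj % config.n_specific_per_output, SPECIFIC_LADDER_PERIOD)
        sign = int(rng.choice([-1, 1]))
        planted.append(
            PlantedEffect(
                feature=name, kind=kind, targets=targets, shape=shapes[idx],
                sign=sign, multiplier=mult, shared=shared,
            )
        )

    # 3. observed matrices from the latent blocks (per-sample stream)
    factors: dict[str, np.ndarray] = {}
    for kind in config.feature_counts:
        for mname in dict.fromkeys(layout[kind][0]):
            factors[mname] = srng.normal(size=n)
    matrices: dict[str, pd.DataFrame] = {}
    for kind, p in config.feature_counts.items():
        labels_k, loadings = layout[kind]
        Z = np.empty((n, p))
        for j in range(p):
            r = loadings[j]
            if r > 0:
                Z[:, j] = np.sqrt(r) * factors[labels_k[j]] + np.sqrt(1 - r) * srng.normal(size=n)
            else:
                Z[:, j] = srng.normal(size=n)
        vals = _observe(kind, Z, obs_params[kind], srng)
        matrices[kind] = pd.DataFrame(vals, index=sample_ids, columns=feature_names[kind])

    module_assignment = {
        feature_names[kind][j]: layout[kind][0][j]
        for kind in layout
        for j in range(config.feature_counts[kind])
    }

    contribs = {}
    for p_eff in planted:
        col = _zscore(matrices[p_eff.kind][p_eff.feature].to_numpy())
        contribs[p_eff.feature] = _contribution(col, p_eff.shape, p_eff.sign, p_eff.x0, srng)

    # 3. latent severities: a plain sum of planted effects plus gaussian noise;
    #    shared markers enter every output, specific markers exactly one
    shared_effects = [p for p in planted if p.shared]
    shared_part = sum(
        (p.multiplier * contribs[p.feature] for p in shared_effects), np.zeros(n)
    )

    severity = {}
    for out in schema.names:
        spec_effects = [p for p in planted if not p.shared and p.targets == [out]]
        spec_part = sum(
            (p.multiplier * contribs[p.feature] for p in spec_effects), np.zeros(n)
        )
        s = config.effect_size * (shared_part + spec_part)
        severity[out] = s + srng.normal(0, config.noise_sd, size=n)
    severity = pd.DataFrame(severity, index=sample_ids)

    disease_latent = pd.Series(
        config.effect_size * shared_part + srng.normal(0, config.noise_sd, size=n),
        index=sample_ids,
    )

    # 4. labels: top fraction of the disease latent are cases (exact ratio)
    order = np.argsort(-disease_latent.to_numpy(), kind="stable")
    labels = np.zeros(n, dtype=int)
    labels[order[: config.n_cases]] = 1
    labels = pd.Series(labels, index=sample_ids, name="disease")

    # 5. scores from severity, typed per schema
    scores = {}
    for spec in schema.outputs:
        s = severity[spec.name].to_numpy()
        if spec.dtype == "continuous":
            scores[spec.name] = 1.0 / (1.0 + np.exp(-s))
        elif spec.dtype == "binary":
            scores[spec.name] = (s > np.median(s)).astype(float)
        else:
            # quantile binning populates all C levels
            ranks = pd.Series(s).rank(method="first").to_numpy()
            scores[spec.name] = np.minimum(
                (ranks - 1) // (n / spec.n_levels), spec.n_levels - 1
            ).astype(float)
    score_matrix = ScoreMatrix(pd.DataFrame(scores, index=sample_ids), schema)

    omics = {k: OmicsMatrix(v, kind=k) for k, v in matrices.items()}
    truth = GroundTruth(
        planted=planted, severity=severity, disease_latent=disease_latent,
        labels=labels, config_seed=config.seed, module_assignment=module_assignment,
    )
    return omics, score_matrix, labels, truth


def concatenate_omics(omics: Mapping[str, OmicsMatrix]) -> OmicsMatrix:
    """Column-concatenate several kinds into one ``combined`` matrix.

    Feature ids are already kind-prefixed by the generator; duplicates across
    kinds are prefixed again to stay unique.
    """
    frames = []
    seen: set[str] = set()
    for kind, X in omics.items():
        df = X.data.copy()
        df.columns = [c if c not in seen else f"{kind}_{c}" for c in df.columns]
        seen.update(df.columns)
        frames.append(df)
    return OmicsMatrix(pd.concat(frames, axis=1), kind="combined")


@dataclass
class ExternalCohort:
    """An independently drawn cohort measuring only part of the feature panel."""

    X: OmicsMatrix
    labels: pd.Series
    measured_features: list[str]


def simulate_external_cohort(
    config: SimConfig,
    overlap_fraction: float,
    rename_fraction: float = 0.0,
    seed: int | None = None,
) -> ExternalCohort:
    """Draw a validation cohort that measures only ``overlap_fraction`` of the
    reference panel, with an optional per-feature location shift (batch effect,
    ``config.batch_shift`` on the standardized scale) and a fraction of kept
    features renamed to unmatched ids (identifier mismatch across studies).

    The external cohort shares the study's structural design — the same
    co-abundance modules, planted biomarkers and observation parameters — but
    consists of entirely new samples (``seed`` keys the sample draw).
    """
    if not 0 < overlap_fraction <= 1:
        raise ValueError("overlap_fraction must be in (0, 1]")
    if not 0 <= rename_fraction <= 1:
        raise ValueError("rename_fraction must be in [0, 1]")
    sample_seed = config.seed + 1 if seed is None else seed
    omics, _, labels, _ = simulate_cohort(config, sample_seed=sample_seed)
    X = concatenate_omics(omics)
    rng = np.random.default_rng([sample_seed, 7])

    n_keep = int(round(overlap_fraction * X.n_features))
    n_keep = max(n_keep, 1)
    kept_idx = np.sort(rng.choice(X.n_features, size=n_keep, replace=False))
    df = X.data.iloc[:, kept_idx].copy()

    if config.batch_shift:
        sd = df.std(axis=0).replace(0, 1.0)
        shift = rng.normal(0, config.batch_shift, size=df.shape[1])
        df = df + shift * sd.to_numpy()

    measured = list(df.columns)
    if rename_fraction > 0:
        n_ren = int(round(rename_fraction * len(measured)))
        ren_idx = rng.choice(len(measured), size=n_ren, replace=False)
        cols = list(df.columns)
        for i in ren_idx:
            cols[i] = f"ext_only_{cols[i]}"
        df.columns = cols
        measured = [c for c in cols if not c.startswith("ext_only_")]

    return ExternalCohort(
        X=OmicsMatrix(df, kind="combined"), labels=labels, measured_features=measured
    )


def asdict_config(config: SimConfig) -> dict:
    d = {
        "n_samples": config.n_samples,
        "case_control_ratio": config.case_control_ratio,
        "feature_counts": dict(config.feature_counts),
        "n_shared_biomarkers": config.n_shared_biomarkers,
        "n_specific_per_output": config.n_specific_per_output,
        "effect_shapes": config.effect_shapes,
        "effect_size": config.effect_size,
        "noise_sd": config.noise_sd,
        "module_size": config.module_size,
        "batch_shift": config.batch_shift,
        "seed": config.seed,
        "schema": config.schema,
    }
    return d


def make_worked_fixture() -> tuple[OmicsMatrix, ScoreMatrix, pd.Series, GroundTruth]:
    """A deterministic 12-sample, 6-feature, 2-output mini-cohort.

    Used in the docs and unit tests: 8 cases vs 4 controls, two shared markers
    and one specific marker per output.
    """
    from .io import OutputSpec

    schema = ScoreSchema(
        [
            OutputSpec("fatigue", "continuous", raw_min=0.0, raw_max=1.0),
            OutputSpec("flare", "binary"),
        ]
    )
    # deliberately below the n >= 20 floor enforced for real simulations
    cfg = object.__new__(SimConfig)
    cfg.n_samples = 12
    cfg.case_control_ratio = 2.0
    cfg.feature_counts = {"immune": 3, "metabolome": 3}
    cfg.n_shared_biomarkers = 2
    cfg.n_specific_per_output = 1
    cfg.effect_shapes = "monotonic"
    cfg.effect_size = 2.0
    cfg.noise_sd = 0.2
    cfg.module_size = 1
    cfg.batch_shift = 0.0
    cfg.seed = 42
    cfg.schema = schema
    omics, scores, labels, truth = simulate_cohort(cfg)
    return concatenate_omics(omics), scores, labels, truth
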