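"""Feature tables, score matrices and preprocessing.

The containers here are thin, validated wrappers around :class:`pandas.DataFrame`:
an omics matrix is samples x features with a kind tag, a score matrix is
samples x outputs constrained by a schema, and preprocessing covers the four
steps applied before modeling: z-score standardization, abundance/prevalence
feature filtering, confounder residualization, and 0-1 severity scaling of the
clinical scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

OMICS_KINDS = ("species", "kegg", "immune", "metabolome", "blood", "combined")

#: kinds whose values are non-negative abundances (zero is "absent")
ABUNDANCE_KINDS = ("species", "kegg")


class ValidationError(ValueError):
    """Raised when an input table violates a container invariant."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    counts = pd.Index(ids).value_counts()
    dups = counts[counts > 1].index.tolist()
    if dups:
        raise ValidationError(f"duplicate {what}: {dups}")


@dataclass
class OmicsMatrix:
    """A samples x features numeric table from one assay.

    Parameters
    ----------
    data
        DataFrame with sample ids as the index and feature ids as columns.
    kind
        One of ``species, kegg, immune, metabolome, blood, combined``.
    """

    data: pd.DataFrame
    kind: str = "combined"

    def __post_init__(self) -> None:
        if self.kind not in OMICS_KINDS:
            raise ValidationError(f"unknown omics kind {self.kind!r}; expected one of {OMICS_KINDS}")
        _check_unique(self.data.index, "sample ids")
        _check_unique(self.data.columns, "feature ids")
        if self.data.isna().any().any():
            bad = self.data.isna().stack()
            addr = bad[bad].index[0]
            raise ValidationError(f"missing value at sample {addr[0]!r}, feature {addr[1]!r}")
        self.data = self.data.astype(float)
        if self.kind == "species":
            vals = self.data.to_numpy()
            if (vals < 0).any():
                raise ValidationError("species relative abundances must be non-negative")
            rowsum = vals.sum(axis=1)
            if (rowsum > 1 + 1e-6).any():
                i = int(np.argmax(rowsum))
                raise ValidationError(
                    f"species row sums must be <= 1 (sample {self.data.index[i]!r} sums to {rowsum[i]:.6f})"
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]


@dataclass
class OutputSpec:
    """Declaration of a single clinical score output."""

    name: str
    dtype: str  # binary | categorical | continuous
    n_levels: int | None = None
    severity_direction: int = 1
    raw_min: float | None = None
    raw_max: float | None = None

    def __post_init__(self) -> None:
        if self.dtype not in ("binary", "categorical", "continuous"):
            raise ValidationError(f"output {self.name!r}: unknown dtype {self.dtype!r}")
        if self.dtype == "categorical":
            if self.n_levels is None or self.n_levels < 2:
                raise ValidationError(f"categorical output {self.name!r} needs n_levels >= 2")
        if self.severity_direction not in (1, -1):
            raise ValidationError(f"output {self.name!r}: severity_direction must be +1 or -1")


@dataclass
class ScoreSchema:
    """Ordered declaration of the model's outputs (default: 12 symptom scores)."""

    outputs: list[OutputSpec]

    def __post_init__(self) -> None:
        _check_unique([o.name for o in self.outputs], "output names")

    @property
    def names(self) -> list[str]:
        return [o.name for o in self.outputs]

    @property
    def n_outputs(self) -> int:
        return len(self.outputs)

    def __getitem__(self, name: str) -> OutputSpec:
        for o in self.outputs:
            if o.name == name:
                return o
        raise KeyError(name)

    def to_dict(self) -> list[dict]:
        return [
            {
                "name": o.name,
                "dtype": o.dtype,
                "n_levels": o.n_levels,
                "severity_direction": o.severity_direction,
                "raw_min": o.raw_min,
                "raw_max": o.raw_max,
            }
            for o in self.outputs
        ]

    @classmethod
    def from_dict(cls, blocks: Iterable[Mapping]) -> "ScoreSchema":
        return cls([OutputSpec(**dict(b)) for b in blocks])


def default_schema() -> ScoreSchema:
    """The default 12-output schema: ten continuous symptom severities on
    [0, 1], one 5-level categorical physical-health score, and one binary flag.
    """
    continuous = [
        "fatigue", "pain", "sleep", "gastrointestinal", "cognitive",
        "emotional", "social_function", "general_health", "energy",
        "post_exertional_malaise",
    ]
    outputs = [OutputSpec(n, "continuous", raw_min=0.0, raw_max=1.0) for n in continuous]
    outputs.append(OutputSpec("physical_health", "categorical", n_levels=5))
    outputs.append(OutputSpec("symptom_flare", "binary"))
    return ScoreSchema(outputs)


@dataclass
class ScoreMatrix:
    """Samples x outputs score values conforming to a :class:`ScoreSchema`.

    Missing clinical scores are allowed and encoded as NaN; they are masked in
    losses and metrics downstream.
    """

    data: pd.DataFrame
    schema: ScoreSchema

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "sample ids")
        missing = [n for n in self.schema.names if n not in self.data.columns]
        if missing:
            raise ValidationError(f"score matrix lacks declared outputs: {missing}")
        self.data = self.data[self.schema.names].astype(float)
        for spec in self.schema.outputs:
            col = self.data[spec.name].dropna()
            if spec.dtype == "continuous":
                if ((col < 0) | (col > 1)).any():
                    raise ValidationError(f"continuous output {spec.name!r} outside [0, 1]")
            elif spec.dtype == "binary":
                if not col.isin([0.0, 1.0]).all():
                    raise ValidationError(f"binary output {spec.name!r} has non-0/1 values")
            else:
                levels = np.arange(spec.n_levels, dtype=float)
                if not col.isin(levels).all():
                    raise ValidationError(
                        f"categorical output {spec.name!r} has levels outside 0..{spec.n_levels - 1}"
                    )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()


@dataclass
class StandardizationStats:
    """Per-feature mean/sd fitted on training data (population sd, divide by n)."""

    mean: np.ndarray
    sd: np.ndarray
    feature_ids: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"mean": self.mean, "sd": self.sd}, index=self.feature_ids)


@dataclass
class ConfounderTable:
    """Named numeric covariates (e.g. medication 0/1 indicators) per sample."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "sample ids")
        if self.data.isna().any().any():
            raise ValidationError("confounder table contains missing values")
        self.data = self.data.astype(float)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_matrix(
    path: str | Path,
    orientation: str = "samples-in-rows",
    kind: str = "combined",
    impute_zero: bool = False,
) -> OmicsMatrix:
    """Read a delimited feature table (TSV by default, CSV by extension).

    The first column holds ids and the first row is the header.  With
    ``orientation="features-in-rows"`` the table is transposed after reading.
    ``impute_zero`` replaces missing cells with 0 for abundance kinds instead of
    failing (absence-coded assays); any other kind fails on missing cells.
    """
    path = Path(path)
    if orientation not in ("samples-in-rows", "features-in-rows"):
        raise ValidationError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    if orientation == "features-in-rows":
        df = df.T
    # locate non-numeric cells before the cast so the error names an address
    coerced = df.apply(pd.to_numeric, errors="coerce")
    bad = coerced.isna() & df.notna()
    if bad.any().any():
        addr = bad.stack()[lambda s: s].index[0]
        raise ValidationError(
            f"non-numeric value {df.loc[addr[0], addr[1]]!r} at row {addr[0]!r}, column {addr[1]!r}"
        )
    if coerced.isna().any().any():
        if impute_zero and kind in ABUNDANCE_KINDS:
            coerced = coerced.fillna(0.0)
        # else: OmicsMatrix raises with the address
    return OmicsMatrix(coerced, kind=kind)


def write_matrix(X: OmicsMatrix, path: str | Path) -> None:
    """Write samples-in-rows with full float precision (round-trip safe)."""
    path = Path(path)
    X.data.to_csv(path, sep=_sep_for(path), float_format="%.17g")


def read_scores(path: str | Path, schema: ScoreSchema) -> ScoreMatrix:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    return ScoreMatrix(df, schema)


def write_scores(Y: ScoreMatrix, path: str | Path) -> None:
    Y.data.to_csv(Path(path), sep=_sep_for(Path(path)), float_format="%.17g")


def read_confounders(path: str | Path) -> ConfounderTable:
    path = Path(path)
    return ConfounderTable(pd.read_csv(path, sep=_sep_for(path), index_col=0))


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def standardize(
    X: OmicsMatrix, stats: StandardizationStats | None = None
) -> tuple[OmicsMatrix, StandardizationStats]:
    """Z-score each feature to zero mean and unit variance.

    When ``stats`` is given (train-fitted), it is applied as-is; otherwise the
    stats are fitted on ``X`` with the population sd (divide by n).  Constant
    features (sd = 0) are centered but left unscaled.
    """
    if stats is None:
        mean = X.values.mean(axis=0)
        sd = X.values.std(axis=0)  # population convention
        stats = StandardizationStats(mean=mean, sd=sd, feature_ids=X.feature_ids)
    elif stats.feature_ids != X.feature_ids:
        raise ValidationError("standardization stats were fitted on a different feature list")
    denom = np.where(stats.sd == 0, 1.0, stats.sd)
    out = (X.values - stats.mean) / denom
    kind = X.kind if X.kind not in ("species",) else "combined"  # no longer compositional
    return OmicsMatrix(pd.DataFrame(out, index=X.sample_ids, columns=X.feature_ids), kind=kind), stats


def filter_features(
    X: OmicsMatrix, min_mean_abundance: float = 0.0, min_prevalence: float = 0.0
) -> OmicsMatrix:
    """Keep features with mean abundance strictly above ``min_mean_abundance``
    AND nonzero-sample fraction strictly above ``min_prevalence``.

    Defaults used for the assays: species mean relative abundance > 1e-4,
    gene prevalence > 0.20.  Both thresholds are strict, and feature order is
    preserved.
    """
    means = X.values.mean(axis=0)
    prevalence = (X.values != 0).mean(axis=0)
    keep = (means > min_mean_abundance) & (prevalence > min_prevalence)
    if not keep.any():
        raise ValidationError(
            f"all {X.n_features} features removed; lower min_mean_abundance "
            f"({min_mean_abundance}) or min_prevalence ({min_prevalence})"
        )
    return OmicsMatrix(X.data.loc[:, keep], kind=X.kind)


def residualize(X: OmicsMatrix, confounders: ConfounderTable) -> OmicsMatrix:
    """Replace each feature by its OLS residual on the covariates (with intercept).

    Removes linear confounder structure while keeping the sample space; the
    residuals of every feature are exactly orthogonal to the design columns.
    """
    missing = [s for s in X.sample_ids if s not in confounders.data.index]
    if missing:
        raise ValidationError(f"confounder table lacks samples: {missing[:5]}")
    C = confounders.data.loc[X.sample_ids]
    design = np.column_stack([np.ones(X.n_samples), C.to_numpy()])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # name offending columns: drop one at a time and see which restores rank
        cols = ["(intercept)"] + list(C.columns)
        collinear = [
            cols[j]
            for j in range(design.shape[1])
            if np.linalg.matrix_rank(np.delete(design, j, axis=1)) == rank
        ]
        raise ValidationError(f"rank-deficient confounder design; collinear columns: {collinear}")
    beta, *_ = np.linalg.lstsq(design, X.values, rcond=None)
    resid = X.values - design @ beta
    kind = X.kind if X.kind != "species" else "combined"  # residuals are not compositional
    return OmicsMatrix(pd.DataFrame(resid, index=X.sample_ids, columns=X.feature_ids), kind=kind)


def scale_scores(raw: pd.DataFrame, schema: ScoreSchema) -> ScoreMatrix:
    """Map raw instrument values to the modeling scale.

    Continuous outputs are mapped affinely from their declared ``[raw_min,
    raw_max]`` range to [0, 1] with 1 = maximum severity; well-being-oriented
    instruments (``severity_direction = -1``) are inverted.  Binary and
    categorical outputs pass through after level validation.
    """
    out = {}
    for spec in schema.outputs:
        if spec.name not in raw.columns:
            raise ValidationError(f"raw score table lacks output {spec.name!r}")
        col = raw[spec.name].astype(float)
        if spec.dtype == "continuous":
            if spec.raw_min is None or spec.raw_max is None or spec.raw_max <= spec.raw_min:
                raise ValidationError(f"output {spec.name!r}: declare raw_min < raw_max")
            oob = col.dropna()[(col.dropna() < spec.raw_min) | (col.dropna() > spec.raw_max)]
            if len(oob):
                s = oob.index[0]
                raise ValidationError(
                    f"raw value {oob.iloc[0]} outside [{spec.raw_min}, {spec.raw_max}] "
                    f"for sample {s!r}, score {spec.name!r}"
                )
            scaled = (col - spec.raw_min) / (spec.raw_max - spec.raw_min)
            if spec.severity_direction == -1:
                scaled = 1.0 - scaled
            out[spec.name] = scaled
        else:
            out[spec.name] = col  # validated by ScoreMatrix
    return ScoreMatrix(pd.DataFrame(out, index=raw.index), schema)


def align_samples(X: OmicsMatrix, Y: ScoreMatrix) -> tuple[OmicsMatrix, ScoreMatrix]:
    """Restrict both tables to their shared samples, in X's order."""
    shared = [s for s in X.sample_ids if s in set(Y.sample_ids)]
    if not shared:
        raise ValidationError("no overlapping samples between omics and scores")
    return (
        OmicsMatrix(X.data.loc[shared], kind=X.kind),
        ScoreMatrix(Y.data.loc[shared], Y.schema),
    )
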