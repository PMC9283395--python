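"""Reading, screening and standardizing the fGCM sample and individual tables.

The screening rule discards any sample whose concentration lies more than
three sample standard deviations (n−1 denominator) from the mean of its own
individual's samples, computed on the raw ng/g scale with the candidate
included, in a single pass.  A consequence of internal studentization is that
no point can ever be discarded from an individual with ten or fewer samples
(the maximum attainable |y − mean|/sd is (n−1)/√n, which first exceeds 3 at
n = 11).

All covariates and the response — binary columns included — are standardized
to mean 0 and sample SD 1 before model fitting; per-individual means of the
standardized response form the level-1 data vector.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError

__all__ = [
    "SAMPLE_COLUMNS",
    "INDIVIDUAL_COLUMNS",
    "LEVEL1_COVARIATES",
    "LEVEL2_COVARIATES",
    "StandardizationParams",
    "ModelInputs",
    "read_tables",
    "remove_outliers",
    "standardize_columns",
    "build_design",
]

SAMPLE_COLUMNS = ("individual_id", "sample_id", "date", "y_ngg", "g", "l", "p", "t", "s", "v", "z", "b")
INDIVIDUAL_COLUMNS = ("individual_id", "f", "m", "o", "a")

#: Fixed column order of the individual-level design (matches beta1..beta5).
LEVEL1_COVARIATES = ("f", "m", "n", "o", "a")
#: Fixed column order of the sample-level design (matches gamma1..gamma8[,9]).
LEVEL2_COVARIATES = ("g", "l", "s", "t", "v", "p", "z", "b")


@dataclass(frozen=True)
class StandardizationParams:
    """Per-column centering/scaling constants; invert the transform exactly."""

    means: dict[str, float]
    sds: dict[str, float]

    def destandardize(self, column: str, values: np.ndarray) -> np.ndarray:
        return np.asarray(values) * self.sds[column] + self.means[column]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"means": self.means, "sds": self.sds}, indent=2, sort_keys=True)
        )


@dataclass(frozen=True)
class ModelInputs:
    """Standardized design matrices for both model levels.

    ``X`` (I×5) carries the individual-level covariates in
    :data:`LEVEL1_COVARIATES` order; ``Z`` (N×8 or N×9) the sample-level
    covariates in :data:`LEVEL2_COVARIATES` order (plus ``w`` when the fecal
    egg count model is requested); ``y`` is the standardized response and
    ``ybar`` its per-individual means; ``sample_index[j]`` maps sample j to
    its row in ``individual_index``.
    """

    individual_index: tuple[str, ...]
    X: np.ndarray
    ybar: np.ndarray
    sample_index: np.ndarray
    Z: np.ndarray
    y: np.ndarray
    standardization: StandardizationParams
    level1_names: tuple[str, ...] = LEVEL1_COVARIATES
    level2_names: tuple[str, ...] = LEVEL2_COVARIATES

    @property
    def n_individuals(self) -> int:
        return len(self.individual_index)

    @property
    def n_samples(self) -> int:
        return len(self.y)

    def validate(self) -> None:
        I, N = self.n_individuals, self.n_samples
        if self.X.shape[0] != I or self.ybar.shape != (I,):
            raise ValidationError("X/ybar dimensions do not match individual_index")
        if self.Z.shape[0] != N or self.sample_index.shape != (N,):
            raise ValidationError("Z/sample_index dimensions do not match y")
        if self.sample_index.min() < 0 or self.sample_index.max() >= I:
            raise ValidationError("sample_index refers to an unknown individual")
        ybar = np.bincount(self.sample_index, weights=self.y, minlength=I) / np.bincount(
            self.sample_index, minlength=I
        )
        if not np.allclose(ybar, self.ybar, atol=1e-10):
            raise ValidationError("ybar is not the per-individual mean of y")


def _require_columns(frame: pd.DataFrame, required: tuple[str, ...], what: str) -> None:
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(f"{what} table is missing column(s): {', '.join(missing)}")


def _report_rows(mask: pd.Series, message: str, errors: list[str]) -> None:
    if mask.any():
        rows = [str(i + 2) for i in np.flatnonzero(mask.to_numpy())[:10]]  # +2: header + 1-based
        errors.append(f"{message} (file rows {', '.join(rows)}{'…' if mask.sum() > 10 else ''})")


def read_tables(samples_path: str | Path, individuals_path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read and validate the two input CSVs.

    The sample table requires columns ``individual_id, sample_id, date, y_ngg,
    g, l, p, t, s, v, z, b`` (optional ``w`` fecal egg counts, optional
    ``is_outlier``/``discarded`` provenance flags); the individual table
    requires ``individual_id, f, m, o, a``.  Raises :class:`SchemaError` for
    missing columns and :class:`ValidationError` listing offending file rows
    for value-level failures, including samples that reference an unknown
    individual.
    """
    samples = pd.read_csv(samples_path)
    individuals = pd.read_csv(individuals_path)
    _require_columns(samples, SAMPLE_COLUMNS, "sample")
    _require_columns(individuals, INDIVIDUAL_COLUMNS, "individual")
    if "w" not in samples.columns:
        samples["w"] = np.nan

    errors: list[str] = []
    num_cols = ["y_ngg", "g", "l", "p", "t", "s", "v", "z", "b", "w"]
    for col in num_cols:
        coerced = pd.to_numeric(samples[col], errors="coerce")
        if col == "w":  # the only column where missing values are meaningful
            bad = coerced.isna() & samples[col].notna()
            _report_rows(bad, f"sample column '{col}' has unparsable values", errors)
        else:
            _report_rows(coerced.isna(), f"sample column '{col}' has missing or unparsable values", errors)
        samples[col] = coerced
    try:
        pd.to_datetime(samples["date"], format="ISO8601")
    except ValueError:
        errors.append("sample column 'date' has non-ISO-8601 values")

    _report_rows(samples["y_ngg"] <= 0, "y_ngg must be > 0", errors)
    _report_rows((samples["t"] < 0) | (samples["t"] >= 1), "t must lie in [0, 1)", errors)
    for col in ("s", "b"):
        _report_rows(samples[col] < 0, f"{col} must be >= 0", errors)
    _report_rows(samples["w"] < 0, "w must be >= 0 when present", errors)
    for col in ("l", "p"):
        _report_rows(~samples[col].isin([0, 1]), f"{col} must be binary 0/1", errors)

    for col in ("f", "m", "o", "a"):
        individuals[col] = pd.to_numeric(individuals[col], errors="coerce")
    _report_rows(~individuals["o"].isin([0, 1]), "o must be binary 0/1", errors)
    _report_rows(~individuals["a"].isin([0, 1]), "a must be binary 0/1", errors)
    _report_rows(
        (individuals["a"] == 1) & (individuals["o"] != 1),
        "a = 1 (non-natal) requires o = 1 (all non-natal subjects are orphans)",
        errors,
    )
    _report_rows(individuals["f"] < 0, "f must be >= 0", errors)
    _report_rows(individuals["m"] < 0, "m must be >= 0", errors)
    if individuals["individual_id"].duplicated().any():
        errors.append("individual_id values are not unique in the individual table")

    unknown = ~samples["individual_id"].isin(individuals["individual_id"])
    _report_rows(unknown, "sample references unknown individual_id", errors)

    if errors:
        raise ValidationError("; ".join(errors))
    return samples, individuals


def remove_outliers(samples: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Single-pass within-individual 3-SD screen on the raw ng/g scale.

    Per individual, mean and sample SD are computed from all of that
    individual's samples (candidate included); a sample is discarded iff
    |y − mean| > 3·sd, strictly.  Returns ``(kept, discarded)`` preserving the
    input row order; their union is the input.  An individual with a single
    sample has no defined SD and raises :class:`ValidationError`.
    """
    counts = samples["individual_id"].value_counts()
    single = counts[counts < 2]
    if not single.empty:
        raise ValidationError(
            "individual(s) with fewer than 2 samples (SD undefined): "
            + ", ".join(map(str, single.index[:10]))
        )
    grp = samples.groupby("individual_id")["y_ngg"]
    mean_i = grp.transform("mean")
    sd_i = grp.transform(lambda x: x.std(ddof=1))
    discard = (samples["y_ngg"] - mean_i).abs() > 3.0 * sd_i
    discard &= sd_i > 0  # zero-SD individuals have zero deviations anyway
    return samples[~discard].copy(), samples[discard].copy()


def standardize_columns(values: np.ndarray | pd.Series, name: str = "column") -> tuple[np.ndarray, float, float]:
    """Center and scale to sample SD 1; returns ``(standardized, mean, sd)``.

    Raises :class:`ValidationError` on constant or length-<2 input: a constant
    covariate is unidentifiable once an intercept is present.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValidationError(f"column '{name}' needs at least 2 values to standardize")
    if np.isnan(x).any():
        raise ValidationError(f"column '{name}' has missing values")
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    if sd == 0:
        raise ValidationError(f"column '{name}' is constant and cannot be standardized")
    return (x - mean) / sd, mean, sd


def build_design(
    samples: pd.DataFrame,
    individuals: pd.DataFrame,
    include_fec: bool = False,
) -> ModelInputs:
    """Assemble standardized two-level design matrices from screened tables.

    The per-individual sample count covariate ``n`` is recomputed from the
    retained samples.  With ``include_fec``, rows with a missing fecal egg
    count are dropped first and everything is re-standardized on the reduced
    table, mirroring the subset analysis that adds the ninth sample-level
    coefficient.
    """
    samples = samples.copy()
    if include_fec:
        if "w" not in samples.columns or samples["w"].notna().sum() == 0:
            raise ValidationError("include_fec requested but no non-missing w values")
        samples = samples[samples["w"].notna()].copy()

    observed = set(samples["individual_id"])
    missing = [i for i in individuals["individual_id"] if i not in observed]
    if missing:
        raise ValidationError(
            "individual(s) with no retained samples: " + ", ".join(map(str, missing[:10]))
        )

    ind = individuals.set_index("individual_id")
    index = tuple(ind.index)
    pos = {ind_id: k for k, ind_id in enumerate(index)}
    sample_index = samples["individual_id"].map(pos).to_numpy(dtype=int)
    n_retained = samples["individual_id"].value_counts()

    means: dict[str, float] = {}
    sds: dict[str, float] = {}

    def _std(raw: np.ndarray, name: str) -> np.ndarray:
        std, mean, sd = standardize_columns(raw, name)
        means[name], sds[name] = mean, sd
        return std

    level1 = {
        "f": ind["f"].to_numpy(dtype=float),
        "m": ind["m"].to_numpy(dtype=float),
        "n": ind.index.map(n_retained).to_numpy(dtype=float),
        "o": ind["o"].to_numpy(dtype=float),
        "a": ind["a"].to_numpy(dtype=float),
    }
    X = np.column_stack([_std(level1[c], c) for c in LEVEL1_COVARIATES])

    level2_names = LEVEL2_COVARIATES + (("w",) if include_fec else ())
    Z = np.column_stack([_std(samples[c].to_numpy(dtype=float), c) for c in level2_names])

    y = _std(samples["y_ngg"].to_numpy(dtype=float), "y_ngg")
    ybar = np.bincount(sample_index, weights=y, minlength=len(index)) / np.bincount(
        sample_index, minlength=len(index)
    )

    inputs = ModelInputs(
        individual_index=index,
        X=X,
        ybar=ybar,
        sample_index=sample_index,
        Z=Z,
        y=y,
        standardization=StandardizationParams(means=means, sds=sds),
        level2_names=level2_names,
    )
    inputs.validate()
    return inputs
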