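"""Ratings tables: reading, validation, cleaning and sample splitting.

A ratings table holds one row per subject and one integer option code per
item.  Covariate columns (age, gender, diagnosis, race, subject_id) are
carried along but ignored by the IRT machinery; they feed the
subsample-comparison report only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .scale import ScaleDefinition

#: Covariate columns recognised in a ratings CSV (all optional).
COVARIATE_COLUMNS = ("subject_id", "age", "gender", "diagnosis", "race")


class RatingsError(ValueError):
    """Raised for schema or range violations in a ratings table."""


@dataclass
class RatingsMatrix:
    """Subjects x items option codes, plus optional covariates.

    ``values`` is a DataFrame whose item columns are floats so missing
    scores can be carried as NaN until :func:`clean_ratings` removes them.
    """

    values: pd.DataFrame
    scale: ScaleDefinition
    covariates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        missing = [it for it in self.scale.items if it not in self.values.columns]
        if missing:
            raise RatingsError(f"ratings table missing item columns: {missing}")
        self.values = self.values[list(self.scale.items)].astype(float)
        if self.covariates is not None and len(self.covariates) != len(self.values):
            raise RatingsError("covariates and values must have equal row counts")
        if self.values.index.has_duplicates:
            raise RatingsError("subject IDs (index) must be unique")
        arr = self.values.to_numpy()
        finite = np.isfinite(arr)
        in_range = (arr >= self.scale.option_min) & (arr <= self.scale.option_max)
        bad = finite & ~in_range
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            raise RatingsError(
                f"option code {arr[i, j]:g} out of range "
                f"[{self.scale.option_min}, {self.scale.option_max}] "
                f"at row {self.values.index[i]!r}, item {self.scale.items[j]!r}"
            )
        nonint = finite & (arr != np.round(arr))
        if nonint.any():
            i, j = map(int, np.argwhere(nonint)[0])
            raise RatingsError(
                f"non-integer option code {arr[i, j]!r} at row "
                f"{self.values.index[i]!r}, item {self.scale.items[j]!r}"
            )

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def items(self) -> tuple[str, ...]:
        return self.scale.items

    def has_missing(self) -> bool:
        return bool(self.values.isna().any().any())

    def summed_scores(self, subscale: str | None = None) -> pd.Series:
        cols = list(self.scale.subscales[subscale]) if subscale else list(self.scale.items)
        return self.values[cols].sum(axis=1)

    def subset_items(self, scale: ScaleDefinition) -> "RatingsMatrix":
        """Restrict to the items of another (e.g. short-form) definition."""
        return RatingsMatrix(self.values[list(scale.items)].copy(), scale,
                             None if self.covariates is None else self.covariates.copy())

    def take(self, index) -> "RatingsMatrix":
        cov = None if self.covariates is None else self.covariates.loc[index]
        return RatingsMatrix(self.values.loc[index].copy(), self.scale, cov)


@dataclass
class CleaningReport:
    """Tally of rows removed by :func:`clean_ratings`.

    Counts always reconcile: ``n_input == n_retained + sum(removed.values())``.
    ``percent_removed`` is 100 * removed / input, reported to 2 decimals.
    """

    n_input: int
    n_retained: int
    removed: dict[str, int] = field(default_factory=dict)

    @property
    def n_removed(self) -> int:
        return sum(self.removed.values())

    @property
    def percent_removed(self) -> float:
        if self.n_input == 0:
            return 0.0
        return round(100.0 * self.n_removed / self.n_input, 2)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"reason": k, "n_removed": v} for k, v in self.removed.items()]
        rows.append({"reason": "Total", "n_removed": self.n_removed})
        df = pd.DataFrame(rows)
        df["percent"] = (100.0 * df["n_removed"] / max(self.n_input, 1)).round(2)
        return df


# ---------------------------------------------------------------------------
# I/O


def read_ratings(path: str | Path, scale: ScaleDefinition) -> RatingsMatrix:
    """Read a ratings CSV (header = item IDs, one subject per row).

    Empty cells are missing scores; any non-integer or out-of-range cell
    raises :class:`RatingsError` naming the offending row and item.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [it for it in scale.items if it not in df.columns]
    if missing:
        raise RatingsError(f"ratings CSV {path} missing item columns: {missing}")
    if "subject_id" in df.columns:
        df = df.set_index("subject_id")
        df.index.name = "subject_id"
        try:
            df.index = df.index.astype(int)
        except (TypeError, ValueError):
            pass
    vals = pd.DataFrame(index=df.index)
    for it in scale.items:
        col = df[it].replace("", np.nan)
        try:
            vals[it] = col.astype(float)
        except ValueError as exc:
            bad = col[~col.isna() & col.apply(_not_number)]
            where = bad.index[0] if len(bad) else "?"
            raise RatingsError(
                f"non-numeric cell {bad.iloc[0]!r} at row {where!r}, item {it!r}"
            ) from exc
    cov_cols = [c for c in COVARIATE_COLUMNS if c in df.columns and c != "subject_id"]
    cov = df[cov_cols].copy() if cov_cols else None
    if cov is not None and "age" in cov.columns:
        cov["age"] = pd.to_numeric(cov["age"].replace("", np.nan))
    return RatingsMatrix(vals, scale, cov)


def _not_number(x: str) -> bool:
    try:
        float(x)
        return False
    except ValueError:
        return True


def write_ratings(data: RatingsMatrix, path: str | Path) -> None:
    """Write a ratings CSV readable by :func:`read_ratings` (identity round-trip)."""
    out = data.values.copy()
    # keep integer appearance for complete cells
    for c in out.columns:
        out[c] = out[c].map(lambda v: "" if pd.isna(v) else str(int(v)))
    if data.covariates is not None:
        out = pd.concat([data.covariates, out], axis=1)
    out.index.name = data.values.index.name or "subject_id"
    include_index = data.values.index.name is not None or not isinstance(
        data.values.index, pd.RangeIndex
    )
    out.to_csv(path, index=include_index)


# ---------------------------------------------------------------------------
# Cleaning and splitting


def clean_ratings(
    raw: RatingsMatrix,
    diagnosis_whitelist: tuple[str, ...] | None = ("Schizophrenia", "Schizoaffective"),
) -> tuple[RatingsMatrix, CleaningReport]:
    """Listwise deletion of excluded diagnoses and incomplete item scores.

    A row matching several removal reasons is counted once, under its first
    matching reason; diagnoses are checked before missingness, and each
    non-whitelisted diagnosis value is tallied separately.  Rows with any
    missing item score are removed (kernel IRT needs complete summed
    scores), counted under ``"Item score missing"``.
    """
    removed: dict[str, int] = {}
    drop = pd.Series(False, index=raw.values.index)

    if (
        diagnosis_whitelist is not None
        and raw.covariates is not None
        and "diagnosis" in raw.covariates.columns
    ):
        diag = raw.covariates["diagnosis"].astype(str)
        for value in diag[~diag.isin(diagnosis_whitelist)].unique():
            mask = (diag == value) & ~drop
            removed[str(value)] = int(mask.sum())
            drop |= mask

    miss = raw.values.isna().any(axis=1) & ~drop
    if miss.any():
        removed["Item score missing"] = int(miss.sum())
        drop |= miss

    retained = raw.take(raw.values.index[~drop])
    if retained.n == 0:
        raise RatingsError("no rows retained after cleaning")
    report = CleaningReport(n_input=raw.n, n_retained=retained.n, removed=removed)
    assert report.n_input == report.n_retained + report.n_removed
    return retained, report


def split_sample(
    data: RatingsMatrix, seed: int
) -> tuple[RatingsMatrix, RatingsMatrix]:
    """Random disjoint halves (evaluation, validation).

    The evaluation half receives floor(N/2) subjects and the validation
    half ceil(N/2); their union is the input.  Deterministic under ``seed``.
    """
    if data.n < 2:
        raise RatingsError("need at least 2 subjects to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(data.n)
    n_eval = data.n // 2
    idx = data.values.index
    eval_half = data.take(idx[np.sort(perm[:n_eval])])
    valid_half = data.take(idx[np.sort(perm[n_eval:])])
    return eval_half, valid_half
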