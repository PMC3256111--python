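"""Packaged fixtures transcribing the published PANSS item-evaluation study.

The clinical dataset behind the published PANSS short-form analysis
(7,187 trial baselines) is proprietary, so its printed result tables are
shipped here as plain-text fixtures:

* ``item_criteria.tsv`` -- per item: the criterion-1 option count, the five
  operational criterion ratings, the ICC slope, the item-total (biserial)
  correlation, and the printed global rating (Very Good / Good / Weak).
* ``eigenvalues.tsv`` -- first/second unrotated PCA eigenvalues, their
  printed ratio and unidimensionality verdict, for the full (30-item) and
  short (19-item) forms.
* ``cleaning.tsv`` -- per-reason removal counts from the raw cohort of
  7,348 records.
* ``conversion_tables.tsv`` -- the published short-to-full summed-score
  conversion tables per subscale.
* ``panss_scale.json`` -- the PANSS scale definition itself.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

#: Size of the raw cohort before cleaning, as printed with the removal table.
CLEANING_INPUT_ROWS = 7348

_RATING_LEVELS = ("Yes", "Somewhat", "No")
_GLOBAL_LEVELS = ("Very Good", "Good", "Weak")


def _read(name: str) -> pd.DataFrame:
    with resources.files(__name__).joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_criteria_fixture() -> pd.DataFrame:
    """The 30-item criterion-rating table (one row per PANSS item).

    Columns: item, subscale, c1_count, c1..c5 (ratings), slope,
    item_total_r, rating.  Validates the rating vocabularies and row count.
    """
    df = _read("item_criteria.tsv")
    if len(df) != 30:
        raise ValueError(f"criteria fixture must have 30 rows, got {len(df)}")
    for col in ("c2", "c3"):
        bad = set(df[col]) - set(_RATING_LEVELS)
        if bad:
            raise ValueError(f"bad ratings in {col}: {bad}")
    for col in ("c1", "c4", "c5"):
        bad = set(df[col]) - {"Yes", "No"}
        if bad:
            raise ValueError(f"criterion {col} only takes Yes/No, got {bad}")
    bad = set(df["rating"]) - set(_GLOBAL_LEVELS)
    if bad:
        raise ValueError(f"bad global ratings: {bad}")
    if not df["slope"].between(-1, 1).all() or not df["item_total_r"].between(-1, 1).all():
        raise ValueError("slope / item-total correlation out of printed range")
    return df.set_index("item", drop=False)


def load_eigen_fixture() -> pd.DataFrame:
    """Printed PCA eigenvalue pairs, ratios and verdicts (both forms)."""
    df = _read("eigenvalues.tsv")
    if (df[["lambda1", "lambda2"]] <= 0).any().any():
        raise ValueError("eigenvalues must be positive")
    return df


def load_cleaning_fixture() -> pd.DataFrame:
    """Per-reason removal counts of the raw cohort (without the total row)."""
    return _read("cleaning.tsv")


def load_conversion_fixture() -> pd.DataFrame:
    """Published short-to-full summed-score conversion rows per subscale."""
    return _read("conversion_tables.tsv")
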