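"""Unidimensionality and classical-psychometrics checks.

PCA eigenvalue-ratio rule (first eigenvalue at least three times the
second), Bartlett's test of sphericity, the Kaiser-Meyer-Olkin measure of
sampling adequacy, Cronbach's alpha, and evaluation/validation subsample
comparisons (t tests with Cohen's d, chi-square tests with Cramer's V).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import RatingsMatrix

#: Unidimensionality is assumed when lambda1 / lambda2 >= this ratio.
EIGEN_RATIO_CUT = 3.0


@dataclass
class DimensionalityReport:
    subscale: str
    eigenvalues: np.ndarray
    ratio: float
    unidimensional: bool
    bartlett_stat: float
    bartlett_df: int
    bartlett_p: float
    kmo: float

    def to_dict(self) -> dict:
        return {
            "subscale": self.subscale,
            "lambda1": float(self.eigenvalues[0]),
            "lambda2": float(self.eigenvalues[1]),
            "ratio": self.ratio,
            "unidimensional": self.unidimensional,
            "bartlett_stat": self.bartlett_stat,
            "bartlett_df": self.bartlett_df,
            "bartlett_p": self.bartlett_p,
            "kmo": self.kmo,
        }


def correlation_matrix(data: RatingsMatrix, items: list[str]) -> np.ndarray:
    x = data.values[list(items)].to_numpy(dtype=float)
    sd = x.std(axis=0)
    if np.any(sd == 0):
        const = [items[i] for i in np.nonzero(sd == 0)[0]]
        raise ValueError(f"constant items have no correlation: {const}")
    return np.corrcoef(x, rowvar=False)


def pca_eigen(data: RatingsMatrix, items: list[str]) -> np.ndarray:
    """Descending eigenvalues of the Pearson correlation matrix (unrotated
    PCA); they sum to the number of items."""
    if data.n <= len(items):
        raise ValueError("need more subjects than items")
    r = correlation_matrix(data, items)
    return np.linalg.eigvalsh(r)[::-1]


def eigen_ratio_verdict(lambda1: float, lambda2: float) -> tuple[float, bool]:
    """Ratio (3 decimals) and the unidimensionality verdict (ratio >= 3)."""
    if lambda2 <= 0:
        raise ValueError("second eigenvalue must be positive")
    ratio = round(lambda1 / lambda2, 3)
    return ratio, ratio >= EIGEN_RATIO_CUT


def bartlett_sphericity(r: np.ndarray, n: int) -> tuple[float, int, float]:
    """Chi-square test that the correlation matrix is the identity:
    ``stat = -(N - 1 - (2p + 5)/6) ln det(R)``, df = p(p-1)/2."""
    r = np.asarray(r, dtype=float)
    p = r.shape[0]
    sign, logdet = np.linalg.slogdet(r)
    if sign <= 0:
        raise ValueError("correlation matrix must be positive definite")
    stat = -(n - 1 - (2 * p + 5) / 6.0) * logdet
    df = p * (p - 1) // 2
    pval = float(stats.chi2.sf(stat, df))
    return float(stat), df, pval


def kmo(r: np.ndarray) -> float:
    """Kaiser-Meyer-Olkin sampling adequacy.

    ``KMO = sum r_ij^2 / (sum r_ij^2 + sum q_ij^2)`` over i != j, where q
    are the anti-image partial correlations obtained from the inverse
    correlation matrix.
    """
    r = np.asarray(r, dtype=float)
    inv = np.linalg.inv(r)
    d = 1.0 / np.sqrt(np.diag(inv))
    partial = -inv * d[:, None] * d[None, :]
    off = ~np.eye(r.shape[0], dtype=bool)
    r2 = (r[off] ** 2).sum()
    q2 = (partial[off] ** 2).sum()
    return float(r2 / (r2 + q2))


def cronbach_alpha(data: RatingsMatrix, items: list[str]) -> float:
    """alpha = k/(k-1) * (1 - sum item variances / variance of the sum)."""
    x = data.values[list(items)].to_numpy(dtype=float)
    k = x.shape[1]
    if k < 2:
        raise ValueError("alpha needs at least 2 items")
    total_var = x.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("zero total variance")
    return float(k / (k - 1) * (1 - x.var(axis=0, ddof=1).sum() / total_var))


def dimensionality_report(data: RatingsMatrix, subscale: str) -> DimensionalityReport:
    items = list(data.scale.subscales[subscale])
    eig = pca_eigen(data, items)
    ratio, verdict = eigen_ratio_verdict(eig[0], eig[1])
    r = correlation_matrix(data, items)
    stat, df, p = bartlett_sphericity(r, data.n)
    return DimensionalityReport(
        subscale=subscale, eigenvalues=eig, ratio=ratio, unidimensional=verdict,
        bartlett_stat=stat, bartlett_df=df, bartlett_p=p, kmo=kmo(r),
    )


# ---------------------------------------------------------------------------
# subsample comparison


def cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = len(a), len(b)
    pooled = np.sqrt(
        ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1)) / (na + nb - 2)
    )
    if pooled == 0:
        return 0.0
    return float((np.mean(a) - np.mean(b)) / pooled)


def cramers_v(table: np.ndarray, chi2: float) -> float:
    n = table.sum()
    k = min(table.shape) - 1
    if n == 0 or k == 0:
        return 0.0
    return float(np.sqrt(chi2 / (n * k)))


def compare_subsamples(a: RatingsMatrix, b: RatingsMatrix) -> pd.DataFrame:
    """Evaluation-vs-validation comparison table.

    Continuous rows (age if present, each subscale summed score, the total
    score): pooled-variance two-sample t with df = N_a + N_b - 2 and
    Cohen's d.  Categorical rows (gender/diagnosis/race if present):
    chi-square with Cramer's V.
    """
    if a.scale.items != b.scale.items:
        raise ValueError("subsamples must share the scale")
    rows = []

    continuous: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    if (
        a.covariates is not None
        and b.covariates is not None
        and "age" in a.covariates.columns
        and "age" in b.covariates.columns
    ):
        continuous["age"] = (
            a.covariates["age"].dropna().to_numpy(float),
            b.covariates["age"].dropna().to_numpy(float),
        )
    for sub in a.scale.subscales:
        continuous[sub] = (
            a.summed_scores(sub).to_numpy(),
            b.summed_scores(sub).to_numpy(),
        )
    continuous["Total"] = (a.summed_scores().to_numpy(), b.summed_scores().to_numpy())

    for name, (xa, xb) in continuous.items():
        t, p = stats.ttest_ind(xa, xb, equal_var=True)
        rows.append(
            {
                "variable": name,
                "type": "continuous",
                "mean_a": np.mean(xa),
                "sd_a": np.std(xa, ddof=1),
                "mean_b": np.mean(xb),
                "sd_b": np.std(xb, ddof=1),
                "statistic": float(t),
                "df": len(xa) + len(xb) - 2,
                "p": float(p),
                "effect_size": cohens_d(xa, xb),
            }
        )

    if a.covariates is not None and b.covariates is not None:
        for name in ("gender", "diagnosis", "race"):
            if name not in a.covariates.columns or name not in b.covariates.columns:
                continue
            ca = a.covariates[name].value_counts()
            cb = b.covariates[name].value_counts()
            cats = sorted(set(ca.index) | set(cb.index))
            table = np.array(
                [[ca.get(c, 0) for c in cats], [cb.get(c, 0) for c in cats]],
                dtype=float,
            )
            table = table[:, table.sum(axis=0) > 0]
            if table.shape[1] < 2:
                chi2, p, df = 0.0, 1.0, 0
            else:
                chi2, p, df, _ = stats.chi2_contingency(table)
            rows.append(
                {
                    "variable": name,
                    "type": "categorical",
                    "mean_a": np.nan,
                    "sd_a": np.nan,
                    "mean_b": np.nan,
                    "sd_b": np.nan,
                    "statistic": float(chi2),
                    "df": int(df),
                    "p": float(p),
                    "effect_size": cramers_v(table, chi2),
                }
            )
    return pd.DataFrame(rows)
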