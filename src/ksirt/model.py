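"""Model/Results interface over the kernel-IRT estimation chain.

:class:`KernelIRT` is built from a ratings table plus a scale definition
and a subscale name; ``fit()`` returns a :class:`KernelIRTResults` holding
the option characteristic curves, item characteristic curves, subscale
curves (expected summed score, information, score density, standard
error) and per-item diagnostics, with ``summary()`` for a readable table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import kernel as K
from .data import RatingsMatrix
from .scale import ScaleDefinition


class KernelIRT:
    """Kernel-smoothed nonparametric IRT for one subscale.

    Parameters
    ----------
    data
        Complete ratings (no missing scores among the modelled items).
    subscale
        Name of the subscale to model; ``None`` models all items as one scale.
    scoring_items
        Items whose summed score defines the latent ranking.  Defaults to
        the modelled items themselves (each item then contributes to its
        own ranking, as in the classical procedure).  Passing a disjoint
        anchor set scores candidate items against an external criterion.
    extra_items
        Optional mapping item ID -> integer response vector for candidate
        items not in the scale; their curves are estimated on the same
        latent scores.
    """

    def __init__(
        self,
        data: RatingsMatrix,
        subscale: str | None = None,
        scoring_items: list[str] | None = None,
        extra_items: dict[str, np.ndarray] | None = None,
    ):
        self.data = data
        self.scale: ScaleDefinition = data.scale
        self.subscale = subscale
        self.item_ids = list(
            self.scale.subscales[subscale] if subscale else self.scale.items
        )
        self.scoring_items = list(scoring_items) if scoring_items else list(self.item_ids)
        unknown = set(self.scoring_items) - set(self.scale.items)
        if unknown:
            raise ValueError(f"scoring items not in scale: {sorted(unknown)}")
        self.extra_items = {
            k: np.asarray(v) for k, v in (extra_items or {}).items()
        }
        cols = self.data.values[self.item_ids]
        if cols.isna().any().any():
            raise ValueError("modelled items contain missing scores; clean first")

    def fit(
        self,
        bandwidth: float | None = None,
        grid: K.LatentGrid | None = None,
    ) -> "KernelIRTResults":
        grid = grid or K.LatentGrid()
        n = self.data.n
        h = bandwidth if bandwidth is not None else K.default_bandwidth(n)
        totals = self.data.values[self.scoring_items].sum(axis=1).to_numpy()
        scores = K.latent_scores(totals)
        codes = np.arange(self.scale.option_min, self.scale.option_max + 1)

        occ: dict[str, K.OccSet] = {}
        icc: dict[str, K.IccCurve] = {}
        series = {it: self.data.values[it].to_numpy() for it in self.item_ids}
        series.update(self.extra_items)
        for item_id, values in series.items():
            occ[item_id] = K.estimate_occ(values, scores, grid, h, codes, item=item_id)
            icc[item_id] = K.icc_from_occ(occ[item_id])

        member_iccs = [icc[it] for it in self.item_ids]
        t = K.expected_subscale_score(member_iccs)
        curves = K.SubscaleCurves(
            subscale=self.subscale or "all",
            grid=grid,
            expected_score=t,
            information=K.average_information(member_iccs),
            density=K.score_density(scores, t, grid),
            se=K.summed_score_se(member_iccs),
        )

        median_option = 0.5 * (self.scale.option_min + self.scale.option_max)
        bounds = K.dense_bounds(grid, K.SLOPE_TRIM)
        diags = []
        for item_id in list(self.item_ids) + list(self.extra_items):
            vals = series[item_id]
            diags.append(
                K.ItemDiagnostics(
                    item=item_id,
                    slope=K.icc_slope_at_median(icc[item_id], median_option,
                                                bounds=bounds),
                    item_total_r=K.item_total_correlation(vals, totals),
                )
            )
        return KernelIRTResults(
            model=self, grid=grid, bandwidth=h, scores=scores,
            occ=occ, icc=icc, curves=curves, diagnostics=diags,
        )


@dataclass
class KernelIRTResults:
    """Fitted curves and diagnostics for one subscale."""

    model: KernelIRT
    grid: K.LatentGrid
    bandwidth: float
    scores: K.LatentScores
    occ: dict[str, K.OccSet]
    icc: dict[str, K.IccCurve]
    curves: K.SubscaleCurves
    diagnostics: list[K.ItemDiagnostics]

    # -- accessors -----------------------------------------------------------

    @property
    def item_ids(self) -> list[str]:
        return list(self.model.item_ids)

    @property
    def expected_score(self) -> np.ndarray:
        return self.curves.expected_score

    def score_function(self, label: str = "full"):
        from .linking import ScoreFunction

        return ScoreFunction(
            theta=self.grid.points,
            values=self.curves.expected_score,
            label=label,
            subscale=self.curves.subscale,
        )

    def classify_items(self, thresholds=None) -> pd.DataFrame:
        """Apply the five operational item-selection criteria to every
        modelled (and extra) item; see :mod:`ksirt.criteria`."""
        from .criteria import classify_results

        return classify_results(self, thresholds=thresholds)

    # -- tabular export --------------------------------------------------

    def occ_frame(self) -> pd.DataFrame:
        rows = []
        for item_id, occ in self.occ.items():
            for m, code in enumerate(occ.option_codes):
                rows.append(
                    pd.DataFrame(
                        {
                            "item": item_id,
                            "theta": self.grid.points,
                            "option": int(code),
                            "probability": occ.probs[:, m],
                        }
                    )
                )
        return pd.concat(rows, ignore_index=True)

    def icc_frame(self) -> pd.DataFrame:
        rows = []
        for item_id, c in self.icc.items():
            rows.append(
                pd.DataFrame(
                    {"item": item_id, "theta": self.grid.points,
                     "expected": c.e, "variance": c.v}
                )
            )
        return pd.concat(rows, ignore_index=True)

    def curves_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "theta": self.grid.points,
                "expected_score": self.curves.expected_score,
                "information": self.curves.information,
                "density": self.curves.density,
                "se": self.curves.se,
            }
        )

    def diagnostics_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"item": d.item, "slope": d.slope, "item_total_r": d.item_total_r}
             for d in self.diagnostics]
        )

    def summary(self) -> str:
        lines = [
            "Kernel-smoothed nonparametric IRT",
            "=" * 50,
            f"subscale:        {self.curves.subscale}",
            f"items:           {len(self.item_ids)}",
            f"subjects:        {self.model.data.n}",
            f"bandwidth h:     {self.bandwidth:.4f}",
            f"grid:            {self.grid.q} points on "
            f"[{self.grid.lo:g}, {self.grid.hi:g}]",
            f"expected score:  [{self.curves.expected_score.min():.2f}, "
            f"{self.curves.expected_score.max():.2f}]",
            "",
            "Item diagnostics (slope at median option, item-total r):",
        ]
        for d in self.diagnostics:
            lines.append(f"  {d.item:<6} slope={d.slope:6.3f}   r={d.item_total_r:6.3f}")
        return "\n".join(lines)

    # -- plotting (optional convenience) ----------------------------------

    def plot_occ(self, item: str, ax=None):
        import matplotlib.pyplot as plt

        ax = ax or plt.gca()
        occ = self.occ[item]
        x = self.curves.expected_score
        for m, code in enumerate(occ.option_codes):
            ax.plot(x, occ.probs[:, m], label=f"option {code}")
        ax.set_xlabel("expected subscale score")
        ax.set_ylabel("P(option)")
        ax.set_title(f"OCC: {item}")
        ax.legend(fontsize="x-small")
        return ax

    def plot_icc(self, item: str, ax=None):
        import matplotlib.pyplot as plt

        ax = ax or plt.gca()
        ax.plot(self.curves.expected_score, self.icc[item].e)
        ax.set_xlabel("expected subscale score")
        ax.set_ylabel("expected item score")
        ax.set_title(f"ICC: {item}")
        return ax

    def plot_curves(self, axes=None):
        import matplotlib.pyplot as plt

        if axes is None:
            _, axes = plt.subplots(1, 3, figsize=(12, 3.5))
        x = self.curves.expected_score
        axes[0].plot(x, self.curves.information)
        axes[0].set_title("average item information")
        axes[1].plot(x, self.curves.density)
        axes[1].set_title("score density")
        axes[2].plot(x, self.curves.se)
        axes[2].set_title("standard error")
        for ax in axes:
            ax.set_xlabel("expected subscale score")
        return axes
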