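"""End-to-end pipeline: clean -> split -> fit -> classify -> select ->
refit short form -> dimensionality/reliability -> link -> report.

Item evaluation runs on the evaluation half of a random split; reliability,
long-vs-short correlations and linking bias are measured on the held-out
validation half.  Everything is reproducible from the master seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sstats

from . import dimstats, linking
from .criteria import CriteriaThresholds, classify_results, select_short_form
from .data import RatingsMatrix, CleaningReport, clean_ratings, read_ratings, split_sample
from .grm import panss_like_config, simulate_cohort
from .kernel import LatentGrid
from .model import KernelIRT, KernelIRTResults
from .scale import ScaleDefinition, panss

log = logging.getLogger("ksirt")


@dataclass
class PipelineConfig:
    """Paths, kernel settings, criteria thresholds and the master seed."""

    ratings_path: str | None = None
    scale_path: str | None = None
    out_dir: str | None = None
    simulate_n: int | None = None  # simulate a PANSS-like cohort instead of reading
    seed: int = 0
    bandwidth: float | None = None
    grid_lo: float = -3.0
    grid_hi: float = 3.0
    grid_points: int = 51
    thresholds: CriteriaThresholds = field(default_factory=CriteriaThresholds)
    diagnosis_whitelist: tuple[str, ...] | None = ("Schizophrenia", "Schizoaffective")
    reuse_full_ranks: bool = False  # short-form curves on full-form latent ranks

    @property
    def grid(self) -> LatentGrid:
        return LatentGrid(self.grid_lo, self.grid_hi, self.grid_points)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        th = raw.pop("thresholds", None)
        cfg = cls(**raw)
        if th:
            cfg.thresholds = CriteriaThresholds(**th)
        if cfg.diagnosis_whitelist is not None:
            cfg.diagnosis_whitelist = tuple(cfg.diagnosis_whitelist)
        return cfg


@dataclass
class PipelineResult:
    """Everything the pipeline produced, ready for export."""

    config: PipelineConfig
    scale: ScaleDefinition
    cleaning: CleaningReport
    comparison: pd.DataFrame
    full_fits: dict[str, KernelIRTResults]
    classifications: pd.DataFrame
    short_scale: ScaleDefinition
    short_fits: dict[str, KernelIRTResults]
    dimensionality_full: pd.DataFrame
    dimensionality_short: pd.DataFrame
    reliability: pd.DataFrame
    conversion_tables: dict[str, linking.ConversionTable]
    biases: list[linking.LinkingBias]
    summary: dict

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.cleaning.to_frame().to_csv(out / "cleaning.tsv", sep="\t", index=False)
        self.comparison.to_csv(out / "comparison.tsv", sep="\t", index=False)
        for name, res in self.full_fits.items():
            res.occ_frame().to_csv(out / f"occ_{name}.tsv", sep="\t", index=False)
            res.icc_frame().to_csv(out / f"icc_{name}.tsv", sep="\t", index=False)
            res.curves_frame().to_csv(out / f"curves_{name}.tsv", sep="\t", index=False)
            res.diagnostics_frame().to_csv(
                out / f"diagnostics_{name}.tsv", sep="\t", index=False
            )
        self.classifications.to_csv(out / "classification.tsv", sep="\t", index=False)
        self.dimensionality_full.to_csv(
            out / "dimensionality_full.tsv", sep="\t", index=False
        )
        self.dimensionality_short.to_csv(
            out / "dimensionality_short.tsv", sep="\t", index=False
        )
        self.reliability.to_csv(out / "reliability.tsv", sep="\t", index=False)
        for name, table in self.conversion_tables.items():
            table.to_frame().to_csv(out / f"conversion_{name}.tsv", sep="\t", index=False)
        pd.DataFrame([b.__dict__ for b in self.biases]).to_csv(
            out / "bias.tsv", sep="\t", index=False
        )
        self.short_scale.save(out / "short_scale.json")
        (out / "summary.json").write_text(json.dumps(self.summary, indent=2))


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    stage = "load"
    try:
        scale = (
            ScaleDefinition.load(config.scale_path) if config.scale_path else panss()
        )
        if config.simulate_n:
            log.info("simulating PANSS-like cohort: n=%d seed=%d",
                     config.simulate_n, config.seed)
            raw = simulate_cohort(panss_like_config(config.simulate_n, config.seed))
        elif config.ratings_path:
            raw = read_ratings(config.ratings_path, scale)
        else:
            raise ValueError("config needs ratings_path or simulate_n")
        log.info("loaded %d subjects x %d items", raw.n, scale.n_items)

        stage = "clean"
        cleaned, cleaning = clean_ratings(raw, config.diagnosis_whitelist)
        log.info("cleaning: removed %d of %d (%.2f%%)",
                 cleaning.n_removed, cleaning.n_input, cleaning.percent_removed)

        stage = "split"
        eval_half, valid_half = split_sample(cleaned, config.seed)
        log.info("split: evaluation n=%d, validation n=%d", eval_half.n, valid_half.n)
        comparison = dimstats.compare_subsamples(eval_half, valid_half)

        stage = "fit"
        full_fits = {
            name: KernelIRT(eval_half, name).fit(config.bandwidth, config.grid)
            for name in scale.subscales
        }

        stage = "criteria"
        tables = [
            classify_results(res, config.thresholds) for res in full_fits.values()
        ]
        classifications = pd.concat(tables)
        classifications = classifications.loc[list(scale.items)]

        stage = "select"
        short_scale = select_short_form(classifications, scale)
        log.info("short form: %d of %d items retained",
                 short_scale.n_items, scale.n_items)

        stage = "refit-short"
        short_eval = eval_half.subset_items(short_scale)
        short_fits = {
            name: KernelIRT(short_eval, name).fit(config.bandwidth, config.grid)
            for name in short_scale.subscales
        }

        stage = "stats"
        dim_full = pd.DataFrame(
            [dimstats.dimensionality_report(eval_half, s).to_dict()
             for s in scale.subscales]
        )
        short_valid = valid_half.subset_items(short_scale)
        dim_short = pd.DataFrame(
            [dimstats.dimensionality_report(short_valid, s).to_dict()
             for s in short_scale.subscales]
        )
        reliability = _reliability_table(valid_half, scale, short_scale)

        stage = "link"
        conversion_tables = {}
        biases = []
        for name in scale.subscales:
            t_full = full_fits[name].score_function("full")
            if config.reuse_full_ranks:
                t_short = _short_t_from_full_fit(
                    full_fits[name], short_scale.subscales[name], name
                )
            else:
                t_short = short_fits[name].score_function("short")
            table = linking.build_conversion_table(t_short, t_full, subscale=name)
            conversion_tables[name] = table
            biases.append(
                linking.evaluate_linking(table, valid_half, scale, short_scale, name)
            )
        biases.append(_total_bias(conversion_tables, valid_half, scale, short_scale))

        stage = "summarize"
        n_retained = int(classifications["retained"].sum())
        summary = {
            "seed": config.seed,
            "n_input": cleaning.n_input,
            "n_retained_rows": cleaning.n_retained,
            "percent_removed": cleaning.percent_removed,
            "n_evaluation": eval_half.n,
            "n_validation": valid_half.n,
            "bandwidth": full_fits[next(iter(full_fits))].bandwidth,
            "n_items_full": scale.n_items,
            "n_items_short": short_scale.n_items,
            "retained_items": n_retained,
            "retained_by_subscale": {
                s: len(short_scale.subscales[s]) for s in short_scale.subscales
            },
            "rating_counts": classifications["rating"].value_counts().to_dict(),
            "linking_bias": {b.subscale: b.mean for b in biases},
            "cronbach_alpha": dict(
                zip(reliability["subscale"], reliability["alpha"])
            ),
        }
        result = PipelineResult(
            config=config, scale=scale, cleaning=cleaning, comparison=comparison,
            full_fits=full_fits, classifications=classifications,
            short_scale=short_scale, short_fits=short_fits,
            dimensionality_full=dim_full, dimensionality_short=dim_short,
            reliability=reliability, conversion_tables=conversion_tables,
            biases=biases, summary=summary,
        )
        if config.out_dir:
            result.save(config.out_dir)
        return result
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc


def _short_t_from_full_fit(
    full_fit: KernelIRTResults, short_items, subscale: str
) -> linking.ScoreFunction:
    """Short-form expected-score function on the full form's latent ranks:
    the sum of the retained items' ICCs from the full-form fit."""
    from .kernel import expected_subscale_score

    t = expected_subscale_score([full_fit.icc[it] for it in short_items])
    return linking.ScoreFunction(
        theta=full_fit.grid.points, values=t, label="short", subscale=subscale
    )


def _reliability_table(
    valid: RatingsMatrix, scale: ScaleDefinition, short_scale: ScaleDefinition
) -> pd.DataFrame:
    rows = []
    for name in scale.subscales:
        short_items = list(short_scale.subscales[name])
        alpha = dimstats.cronbach_alpha(valid, short_items)
        long_sum = valid.values[list(scale.subscales[name])].sum(axis=1)
        short_sum = valid.values[short_items].sum(axis=1)
        r, p = sstats.pearsonr(long_sum, short_sum)
        rows.append(
            {"subscale": name, "alpha": float(alpha),
             "long_short_r": float(r), "p": float(p)}
        )
    long_total = valid.values[list(scale.items)].sum(axis=1)
    short_total = valid.values[list(short_scale.items)].sum(axis=1)
    r, p = sstats.pearsonr(long_total, short_total)
    rows.append(
        {
            "subscale": "Total",
            "alpha": float(dimstats.cronbach_alpha(valid, list(short_scale.items))),
            "long_short_r": float(r),
            "p": float(p),
        }
    )
    return pd.DataFrame(rows)


def _total_bias(
    tables: dict[str, linking.ConversionTable],
    valid: RatingsMatrix,
    scale: ScaleDefinition,
    short_scale: ScaleDefinition,
) -> linking.LinkingBias:
    mapped_total = np.zeros(valid.n)
    for name, table in tables.items():
        short_sum = valid.values[list(short_scale.subscales[name])].sum(axis=1)
        mapped_total += table(short_sum.to_numpy().astype(int))
    full_total = valid.values[list(scale.items)].sum(axis=1).to_numpy()
    diff = mapped_total - full_total
    return linking.LinkingBias(
        subscale="Total",
        mean=round(float(diff.mean()), 3),
        min=float(diff.min()),
        max=float(diff.max()),
        n=len(diff),
    )


# ---------------------------------------------------------------------------
# report rendering


def render_report(result: PipelineResult) -> str:
    """Human-readable markdown report of the whole run."""
    s = result.summary
    lines = [
        "# Kernel-IRT item evaluation report",
        "",
        f"- subjects: {s['n_retained_rows']} retained of {s['n_input']} "
        f"({s['percent_removed']:.2f}% removed)",
        f"- split: evaluation n={s['n_evaluation']}, validation n={s['n_validation']}",
        f"- bandwidth: {s['bandwidth']:.4f}; seed {s['seed']}",
        f"- short form: {s['n_items_short']} of {s['n_items_full']} items retained",
        "",
        "## Item classification",
        "",
        "| item | c1 | c2 | c3 | c4 | c5 | slope | yes | rating |",
        "|------|----|----|----|----|----|-------|-----|--------|",
    ]
    for _, row in result.classifications.iterrows():
        lines.append(
            f"| {row['item']} | {row['c1_count']} ({row['c1']}) | {row['c2']} "
            f"| {row['c3']} | {row['c4']} | {row['c5']} | {row['slope']:.3f} "
            f"| {row['yes_count']} | {row['rating']} |"
        )
    lines += ["", "## Dimensionality (evaluation half, full form)", ""]
    lines += _df_to_md(result.dimensionality_full.round(3))
    lines += ["", "## Dimensionality (validation half, short form)", ""]
    lines += _df_to_md(result.dimensionality_short.round(3))
    lines += ["", "## Reliability and long-short correlations (validation half)", ""]
    lines += _df_to_md(result.reliability.round(3))
    lines += ["", "## Linking bias (validation half)", ""]
    lines += _df_to_md(pd.DataFrame([b.__dict__ for b in result.biases]).round(3))
    return "\n".join(lines) + "\n"


def _df_to_md(df: pd.DataFrame) -> list[str]:
    header = "| " + " | ".join(map(str, df.columns)) + " |"
    sep = "|" + "|".join("---" for _ in df.columns) + "|"
    rows = ["| " + " | ".join(str(v) for v in row) + " |" for row in df.itertuples(index=False)]
    return [header, sep, *rows]
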