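"""Effect reporting and pipeline orchestration.

Posterior coefficients of the per-trait logistic models are log-odds per 1 SD
of the z-scored trait.  Reporting translates them to odds ratios
(``exp(coef)``) and percent changes in the odds (``100 * (exp(coef) - 1)``),
with the 90% HPDI mapped through the same monotone transform endpoint-wise;
assembles category-grouped results tables and bar-plot-ready series; and runs
the full pipeline (recode -> binarize -> impute -> z-score -> PLS ->
per-trait Bayesian scan -> report) from a single config.
"""

from __future__ import annotations

import json
import logging
import math
import time
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import bayes, impute as impute_mod, pls as pls_mod, simulate as sim_mod
from .codebook import Codebook, CohortTable

__all__ = [
    "OddsEffect",
    "coef_to_odds_effect",
    "scan_traits",
    "build_results_table",
    "export_barplot_data",
    "run_pipeline",
    "PipelineError",
]

log = logging.getLogger("isorisk")


@dataclass(frozen=True)
class OddsEffect:
    """A posterior coefficient translated to the odds scale."""

    trait: str
    target: str
    category: str
    mean: float
    hpdi_low: float
    hpdi_high: float
    odds_ratio: float
    percent_change: float
    odds_ratio_low: float
    odds_ratio_high: float

    def describe(self) -> str:
        direction = "increase" if self.percent_change >= 0 else "decrease"
        if self.odds_ratio >= 2.0:
            return (
                f"{self.trait}: odds of {self.target} {self.odds_ratio:.1f} times greater "
                f"per 1 SD"
            )
        return (
            f"{self.trait}: {_format_percent(abs(self.percent_change))}% {direction} "
            f"in the odds of {self.target} per 1 SD"
        )


def _format_percent(pct: float) -> str:
    # one decimal place, but three significant figures below 10 (9.86 vs 29.0)
    if abs(pct) < 10:
        return f"{pct:.3g}"
    return f"{pct:.1f}"


def coef_to_odds_effect(
    mean: float,
    hpdi: tuple[float, float],
    trait: str = "",
    target: str = "",
    category: str = "none",
    trait_sd: float | None = None,
) -> OddsEffect:
    """Exponential translation of a log-odds coefficient and its HPDI.

    ``trait_sd`` optionally rescales the per-1-SD coefficient to a per-raw-unit
    effect (dividing by the trait's raw SD) before exponentiating.
    """
    low, high = hpdi
    if not all(map(math.isfinite, (mean, low, high))):
        raise ValueError("coefficient and HPDI bounds must be finite")
    if low > high:
        raise ValueError(f"HPDI bounds out of order: ({low}, {high})")
    if trait_sd is not None:
        if trait_sd <= 0:
            raise ValueError("trait_sd must be positive")
        mean, low, high = mean / trait_sd, low / trait_sd, high / trait_sd
    oratio = math.exp(mean)
    return OddsEffect(
        trait=trait,
        target=target,
        category=category,
        mean=mean,
        hpdi_low=low,
        hpdi_high=high,
        odds_ratio=oratio,
        percent_change=100.0 * (oratio - 1.0),
        odds_ratio_low=math.exp(low),
        odds_ratio_high=math.exp(high),
    )


def scan_traits(
    table: CohortTable,
    targets: Sequence[str] | None = None,
    traits: Sequence[str] | None = None,
    chains: int = 4,
    draws: int = 1000,
    warmup: int = 1000,
    seed: int = 0,
    bayesian_missing: bool = False,
) -> list[bayes.PosteriorSummary]:
    """Fit one hierarchical Bayesian model per (trait, target) pair.

    The table's trait columns must be z-scored unless ``bayesian_missing`` is
    set, in which case raw columns with NaNs are standardized on observed
    entries and missing cells declared latent.
    """
    targets = list(targets) if targets is not None else table.targets
    traits = list(traits) if traits is not None else table.risk_traits
    unknown = [t for t in traits if t not in table.data.columns]
    if unknown:
        raise ValueError(f"unknown trait columns: {unknown}")
    summaries = []
    rng = np.random.default_rng(seed)
    for trait in traits:
        for target in targets:
            fit_seed = int(rng.integers(0, 2**31 - 1))
            if bayesian_missing:
                model = impute_mod.build_risk_model_with_missing(table, trait, target)
            else:
                model = bayes.build_risk_model(table, trait, target)
            t0 = time.perf_counter()
            draws_obj = bayes.sample_posterior(
                model, chains=chains, draws=draws, warmup=warmup, seed=fit_seed
            )
            summary = bayes.summarize(draws_obj)
            log.info(
                "fit %s ~ %s: mean=%.3f [%.3f, %.3f] (%.1fs)",
                target,
                trait,
                summary["risktrait"].mean,
                summary["risktrait"].hpdi_low,
                summary["risktrait"].hpdi_high,
                time.perf_counter() - t0,
            )
            summaries.append(summary)
    return summaries


def _category_lookup(codebook) -> Mapping[str, str]:
    if isinstance(codebook, Codebook):
        return {e.name: e.category for e in codebook}
    if isinstance(codebook, Mapping):
        return codebook
    raise TypeError("codebook must be a Codebook or a trait -> category mapping")


CATEGORY_ORDER = ("lifestyle", "physical", "mental", "societal", "none")


def build_results_table(
    summaries: Sequence[bayes.PosteriorSummary], codebook
) -> pd.DataFrame:
    """Category-grouped wide table: one row per trait, three numeric columns
    (mean / 5% HDPI / 95% HDPI) per target."""
    categories = _category_lookup(codebook)
    if not summaries:
        return pd.DataFrame(columns=["category", "trait"])
    records: dict[tuple[str, str], dict[str, float]] = {}
    target_order: list[str] = []
    for s in summaries:
        if s.trait not in categories:
            raise ValueError(f"trait {s.trait!r} absent from codebook")
        if s.target not in target_order:
            target_order.append(s.target)
        key = (categories[s.trait], s.trait)
        row = records.setdefault(key, {})
        p = s["risktrait"]
        row[f"{s.target}_mean"] = p.mean
        row[f"{s.target}_hpdi_5"] = p.hpdi_low
        row[f"{s.target}_hpdi_95"] = p.hpdi_high
    cols = [f"{t}_{c}" for t in target_order for c in ("mean", "hpdi_5", "hpdi_95")]
    keys = sorted(
        records,
        key=lambda k: (CATEGORY_ORDER.index(k[0]) if k[0] in CATEGORY_ORDER else 99, k[1]),
    )
    out = pd.DataFrame(
        [{"category": c, "trait": t, **records[(c, t)]} for c, t in keys],
        columns=["category", "trait", *cols],
    )
    return out


def export_barplot_data(table: pd.DataFrame) -> dict[tuple[str, str], pd.DataFrame]:
    """Per-category, per-target series of (trait, mean, hpdi_low, hpdi_high),
    values identical to the results table."""
    if table.empty:
        raise ValueError("results table is empty")
    targets = sorted({c.rsplit("_mean", 1)[0] for c in table.columns if c.endswith("_mean")})
    series: dict[tuple[str, str], pd.DataFrame] = {}
    for category, group in table.groupby("category", sort=False):
        for target in targets:
            series[(category, target)] = pd.DataFrame(
                {
                    "trait": group["trait"].to_numpy(),
                    "mean": group[f"{target}_mean"].to_numpy(),
                    "hpdi_low": group[f"{target}_hpdi_5"].to_numpy(),
                    "hpdi_high": group[f"{target}_hpdi_95"].to_numpy(),
                }
            )
    return series


class PipelineError(RuntimeError):
    """Raised when a pipeline stage fails; message names the stage."""


def _stage(name: str):
    class _Ctx:
        def __enter__(self):
            log.info("stage %s: start", name)
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            log.info("stage %s: done (%.1fs)", name, time.perf_counter() - self.t0)
            return False

    return _Ctx()


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        text = Path(config).read_text()
        if str(config).endswith((".yaml", ".yml")):
            import yaml

            return yaml.safe_load(text)
        return json.loads(text)
    return dict(config)


def run_pipeline(config, out_dir: str | Path | None = None) -> dict:
    """Run the end-to-end analysis from a config dict or YAML/JSON path.

    Config keys: either ``simulation`` (a :class:`SimulationSpec` field dict)
    or ``input`` (``table`` CSV + ``codebook`` CSV/JSON, optionally with raw
    labels to recode); ``impute`` in {hotdeck, bayesian, none};
    ``donor_class``; ``targets``; ``traits``; ``sampler`` (chains / draws /
    warmup); ``pls`` (n_modes); ``seed``; ``out_dir``.

    Writes results_table.csv, odds_effects.csv, pls_summary.json,
    barplot_data/*.csv and manifest.json; returns the artifacts in memory.
    Rerunning the same config + seed reproduces all numeric outputs.
    """
    cfg = _load_config(config)
    out = Path(out_dir or cfg.get("out_dir", "isorisk_out"))
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    truth = None
    codebook = None

    with _stage("load"):
        if "simulation" in cfg:
            sim_cfg = dict(cfg["simulation"])
            sim_cfg.setdefault("seed", seed)
            if "trait_specs" in sim_cfg:
                sim_cfg["trait_specs"] = [sim_mod.TraitSpec(**t) for t in sim_cfg["trait_specs"]]
            spec = sim_mod.SimulationSpec(**sim_cfg)
            table, truth = sim_mod.simulate_cohort(spec)
            categories = dict(table.categories)
        elif "input" in cfg:
            cb_path = cfg["input"]["codebook"]
            codebook = (
                Codebook.from_json(cb_path)
                if str(cb_path).endswith(".json")
                else Codebook.from_csv(cb_path)
            )
            table = _load_raw_table(cfg["input"]["table"], codebook)
            categories = {e.name: e.category for e in codebook}
        else:
            raise ValueError("config needs a 'simulation' or 'input' section")

    traits = cfg.get("traits") or table.risk_traits
    unknown = [t for t in traits if t not in table.data.columns]
    if unknown:
        raise PipelineError(f"stage 'config' failed: unknown trait(s) {unknown}")
    targets = cfg.get("targets") or table.targets
    method = cfg.get("impute", "hotdeck")

    with _stage("impute"):
        bayesian_missing = False
        has_missing = table.missing_fraction(traits) > 0
        if method == "hotdeck" and has_missing:
            ispec = impute_mod.ImputationSpec(
                method="hot_deck",
                donor_class_vars=tuple(cfg.get("donor_class", ("age_decade", "sex"))),
                seed=seed,
            )
            table = impute_mod.hot_deck_impute(table, ispec)
        elif method == "bayesian" and has_missing:
            bayesian_missing = True
        elif method not in ("hotdeck", "bayesian", "none"):
            raise ValueError(f"unknown imputation method {method!r}")

    with _stage("zscore"):
        if bayesian_missing:
            zs_table = table  # standardization on observed entries happens per model
        else:
            zs_table = table.zscored(traits)

    with _stage("pls"):
        pls_table = (
            impute_mod.hot_deck_impute(
                table, impute_mod.ImputationSpec(method="hot_deck", seed=seed)
            )
            if bayesian_missing
            else table
        ).zscored(traits)
        X = pls_table.data[traits].to_numpy(dtype=float)
        y_cols = pls_table.social_indicators or targets
        Y = np.column_stack([pls_table.data[c].to_numpy(dtype=float) for c in y_cols])
        Y = (Y - Y.mean(0)) / Y.std(0, ddof=1)
        n_modes = (cfg.get("pls") or {}).get("n_modes") or min(len(y_cols), len(traits))
        pls_res = pls_mod.fit_pls(X, Y, n_modes=n_modes)
        pls_summary = {
            "y_block": list(y_cols),
            "x_block": list(traits),
            "mode_correlations": pls_res.mode_correlations.tolist(),
            "covariance_explained": pls_res.covariance_explained.tolist(),
            "singular_values": pls_res.singular_values.tolist(),
        }
        pd.DataFrame(pls_res.x_weights, index=traits).to_csv(out / "pls_x_loadings.csv")
        pd.DataFrame(pls_res.y_weights, index=y_cols).to_csv(out / "pls_y_loadings.csv")
        with open(out / "pls_summary.json", "w") as fh:
            json.dump(pls_summary, fh, indent=2)

    with _stage("bayes_scan"):
        sampler = cfg.get("sampler") or {}
        summaries = scan_traits(
            zs_table,
            targets=targets,
            traits=traits,
            chains=int(sampler.get("chains", 4)),
            draws=int(sampler.get("draws", 1000)),
            warmup=int(sampler.get("warmup", 1000)),
            seed=seed,
            bayesian_missing=bayesian_missing,
        )

    with _stage("report"):
        results = build_results_table(summaries, categories)
        results.to_csv(out / "results_table.csv", index=False)
        effects = [
            coef_to_odds_effect(
                s["risktrait"].mean,
                (s["risktrait"].hpdi_low, s["risktrait"].hpdi_high),
                trait=s.trait,
                target=s.target,
                category=categories.get(s.trait, "none"),
            )
            for s in summaries
        ]
        pd.DataFrame([asdict(e) for e in effects]).to_csv(out / "odds_effects.csv", index=False)
        bar_dir = out / "barplot_data"
        bar_dir.mkdir(exist_ok=True)
        for (category, target), frame in export_barplot_data(results).items():
            frame.to_csv(bar_dir / f"{category}_{target}.csv", index=False)
        if truth is not None:
            truth.to_json(out / "synthetic_truth.json")
        manifest = {
            "seed": seed,
            "config": {k: v for k, v in cfg.items() if k != "trait_specs"},
            "targets": list(targets),
            "traits": list(traits),
            "imputation": method,
            "n_participants": table.n,
            "convergence_warnings": sorted({w for s in summaries for w in s.warnings}),
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)

    return {
        "table": table,
        "results": results,
        "effects": effects,
        "pls": pls_res,
        "pls_summary": pls_summary,
        "summaries": summaries,
        "truth": truth,
        "out_dir": out,
    }


def _load_raw_table(path: str | Path, codebook: Codebook) -> CohortTable:
    """Read a raw CSV and apply the codebook: recode risk traits and
    indicators, binarize targets, pass confounds through numerically."""
    from .codebook import binarize_target, recode_variable

    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    try:
        ids = pd.to_numeric(df[CohortTable.ID])
    except (ValueError, TypeError):
        ids = df[CohortTable.ID]
    data = {CohortTable.ID: ids}
    roles, categories = {}, {}
    for entry in codebook:
        if entry.name not in df.columns:
            continue
        raw = df[entry.name].replace("", np.nan)
        if entry.role == "target":
            data[entry.name] = binarize_target(raw, entry)
        elif entry.role == "confound":
            data[entry.name] = pd.to_numeric(raw, errors="raise")
        else:
            data[entry.name] = recode_variable(raw, entry)
        roles[entry.name] = entry.role
        categories[entry.name] = entry.category
    return CohortTable(pd.DataFrame(data), roles, categories)
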