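"""End-to-end orchestration: split by trait category, fit intercept-only and
one-at-a-time moderator models, run the sensitivity and bias diagnostics, and
(when raw allometry tables are supplied) the GSI-vs-ANCOVA comparison.

Outputs are delimited tables (`fit_summary.csv`, `moderators.csv`,
`levels.csv`, `bias.csv`, `gsi_compare.csv`) plus a machine-readable run
manifest sufficient to reproduce every number.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .allometry import AllometryTable, ancova_effect, compare_methods, gsi_effect, significance_counts
from .bias import precision_regression, time_lag_regression
from .effects import DirectionRule
from .meta import (
    MetaDataset,
    fit_reml,
    level_means,
    meta_regression,
    sensitivity_suite,
    sneaker_frequency_models,
)

__all__ = ["RunConfig", "run_all", "split_by_trait", "subset_filters", "gsi_comparison"]

log = logging.getLogger("artmeta")

CATEGORICAL_MODERATORS = ["taxon_group", "fert_mode", "tactic_type", "measurement"]


@dataclass
class RunConfig:
    """Paths, model settings and variant switches for one full run."""

    effects_path: str
    tree_path: str | None = None
    allometry_dir: str | None = None
    output_dir: str = "artmeta_out"
    rho: float = 0.5
    alpha: float = 0.05
    include_directionless: bool = True
    exclude_species: list[str] = field(default_factory=list)
    min_category_size: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if not Path(self.effects_path).exists():
            raise ValueError(f"effects table not found: {self.effects_path}")
        if self.tree_path and not Path(self.tree_path).exists():
            raise ValueError(f"tree not found: {self.tree_path}")
        if self.allometry_dir and not Path(self.allometry_dir).exists():
            raise ValueError(f"allometry directory not found: {self.allometry_dir}")


def split_by_trait(dataset: MetaDataset) -> dict[str, MetaDataset]:
    """One dataset per trait category present (tree re-pruned lazily at fit)."""
    out = {}
    for category in ("testes_size", "sperm_quantity", "sperm_trait"):
        mask = dataset.effects["trait_category"] == category
        if mask.sum() == 0:
            log.warning("trait category %s absent; skipped", category)
            continue
        if mask.sum() < 2:
            log.warning("trait category %s has < 2 effects; skipped", category)
            continue
        out[category] = dataset.subset(mask)
    return out


def subset_filters(
    dataset: MetaDataset,
    exclude_measurements: list[str] | None = None,
    exclude_tactic_types: list[str] | None = None,
    drop_directionless: bool = False,
) -> MetaDataset:
    """Declarative row filters (measurement / tactic-type exclusions,
    directionless removal); raises if the result is empty."""
    df = dataset.effects
    mask = pd.Series(True, index=df.index)
    if exclude_measurements:
        mask &= ~df["measurement"].isin(exclude_measurements)
    if exclude_tactic_types:
        mask &= ~df["tactic_type"].isin(exclude_tactic_types)
    if drop_directionless and "directionless" in df.columns:
        mask &= ~df["directionless"].fillna(False).astype(bool)
    if mask.sum() == 0:
        raise ValueError("filters removed every effect size")
    return dataset.subset(mask)


def gsi_comparison(tables: list[AllometryTable], alpha: float = 0.05) -> dict:
    """Per-study GSI vs ANCOVA effect sizes, the paired t-test, and the
    per-method significance counts."""
    rows, pairs = [], []
    for table in tables:
        low, high = table.tactics
        rule = DirectionRule(low_tactic=low, high_tactic=high)
        try:
            d_gsi = gsi_effect(table, rule).d
            result, eff = ancova_effect(table, rule, alpha=alpha)
        except (ValueError, RuntimeError) as err:
            log.warning("allometry study %s failed: %s", table.study_id, err)
            continue
        pairs.append((d_gsi, eff.d))
        rows.append(
            {
                "study_id": table.study_id,
                "species": table.species,
                "d_gsi": d_gsi,
                "d_ancova": eff.d,
                "partial_eta2": result.partial_eta2,
                "interaction_p": result.interaction_p,
                "interaction_dropped": result.interaction_dropped,
                "slope_common": result.slope_common,
            }
        )
    table_df = pd.DataFrame(rows)
    out: dict = {"per_study": table_df}
    if len(pairs) >= 2:
        try:
            t, dof, p, mean_diff = compare_methods(pairs)
            out["paired_t"] = {"t": t, "df": dof, "p": p, "mean_diff": mean_diff}
        except ValueError as err:
            log.warning("paired comparison degenerate: %s", err)
    n_gsi, n_anc, failures = significance_counts(tables, alpha=alpha)
    out["significance_counts"] = {
        "gsi": n_gsi,
        "ancova": n_anc,
        "n_tables": len(tables),
        "failures": failures,
    }
    return out


def _fit_row(name: str, est) -> dict:
    row = {
        "dataset": name,
        "k": est.k_,
        "mean_d": est.beta_.get("intercept", float("nan")),
        "ci_low": est.ci_low_.get("intercept", float("nan")),
        "ci_high": est.ci_high_.get("intercept", float("nan")),
        "significant": est.significant_("intercept") if "intercept" in est.X_names_ else False,
        "i2_total": est.i2_total_,
        "loglik_reml": est.loglik_reml_,
    }
    for level, value in est.i2_partition_.items():
        row[f"i2_{level}"] = value
    for level, value in est.sigma2_.items():
        row[f"sigma2_{level}"] = value
    return row


def run_all(config: RunConfig) -> dict:
    """Run the full analysis; stage failures are logged and reported, not fatal."""
    from .io import load_dataset, read_allometry_dir

    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    dataset = load_dataset(config.effects_path, config.tree_path, rho=config.rho)
    if not config.include_directionless:
        dataset = subset_filters(dataset, drop_directionless=True)

    fit_rows, mod_rows, level_rows, bias_rows, sens_frames = [], [], [], [], []
    errors: list[str] = []
    for name, sub in split_by_trait(dataset).items():
        log.info("dataset %s: k=%d", name, sub.k)
        try:
            fit_rows.append(_fit_row(name, fit_reml(sub)))
        except (ValueError, RuntimeError) as err:
            errors.append(f"{name}/fit: {err}")
            continue
        moderators = CATEGORICAL_MODERATORS + (
            ["allocation_vs_expenditure"] if "allocation_vs_expenditure" in sub.effects else []
        )
        for moderator in moderators:
            try:
                est = meta_regression(sub, moderator, min_category_size=config.min_category_size)
                mod_rows.append(
                    {
                        "dataset": name,
                        "moderator": moderator,
                        "k": est.k_,
                        "QM": est.qm_,
                        "df": est.qm_df_,
                        "p": est.qm_p_,
                        "R2_marginal": est.r2_marginal_,
                    }
                )
                lm = level_means(sub, moderator, min_category_size=config.min_category_size)
                lm.insert(0, "moderator", moderator)
                lm.insert(0, "dataset", name)
                level_rows.append(lm)
            except (ValueError, RuntimeError) as err:
                errors.append(f"{name}/moderator {moderator}: {err}")
        try:
            sf = sneaker_frequency_models(sub)
            for form in ("quadratic", "linear"):
                est = sf[form]
                mod_rows.append(
                    {
                        "dataset": name,
                        "moderator": f"sneaker_freq ({form})",
                        "k": est.k_,
                        "QM": est.qm_,
                        "df": est.qm_df_,
                        "p": est.qm_p_,
                        "R2_marginal": est.r2_marginal_,
                    }
                )
        except (ValueError, RuntimeError) as err:
            errors.append(f"{name}/sneaker_freq: {err}")
        for fn, label in ((precision_regression, "inverse_se"), (time_lag_regression, "pub_year")):
            try:
                rep = fn(sub)
                bias_rows.append(
                    {
                        "dataset": name,
                        "covariate": label,
                        "k": rep.k,
                        "slope": rep.slope,
                        "ci_low": rep.ci_low,
                        "ci_high": rep.ci_high,
                        "QM": rep.qm,
                        "p": rep.p,
                        "flagged": rep.flagged,
                    }
                )
            except (ValueError, RuntimeError) as err:
                errors.append(f"{name}/bias {label}: {err}")
        try:
            sens = sensitivity_suite(sub, exclude_species=config.exclude_species or None)
            sens.insert(0, "dataset", name)
            sens_frames.append(sens)
        except (ValueError, RuntimeError) as err:
            errors.append(f"{name}/sensitivity: {err}")

    report: dict = {"errors": errors}
    pd.DataFrame(fit_rows).to_csv(out_dir / "fit_summary.csv", index=False)
    pd.DataFrame(mod_rows).to_csv(out_dir / "moderators.csv", index=False)
    (pd.concat(level_rows, ignore_index=True) if level_rows else pd.DataFrame()).to_csv(
        out_dir / "levels.csv", index=False
    )
    pd.DataFrame(bias_rows).to_csv(out_dir / "bias.csv", index=False)
    (pd.concat(sens_frames, ignore_index=True) if sens_frames else pd.DataFrame()).to_csv(
        out_dir / "sensitivity.csv", index=False
    )

    if config.allometry_dir:
        tables = read_allometry_dir(config.allometry_dir)
        comparison = gsi_comparison(tables, alpha=config.alpha)
        comparison["per_study"].to_csv(out_dir / "gsi_compare.csv", index=False)
        report["gsi_compare"] = {
            key: val for key, val in comparison.items() if key != "per_study"
        }

    manifest = {
        "version": __version__,
        "config": {
            "effects_path": str(config.effects_path),
            "tree_path": str(config.tree_path) if config.tree_path else None,
            "allometry_dir": str(config.allometry_dir) if config.allometry_dir else None,
            "rho": config.rho,
            "alpha": config.alpha,
            "include_directionless": config.include_directionless,
            "exclude_species": config.exclude_species,
            "min_category_size": config.min_category_size,
            "seed": config.seed,
        },
        "outputs": sorted(p.name for p in out_dir.glob("*.csv")),
        "errors": errors,
        "gsi_compare": report.get("gsi_compare"),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    report["manifest"] = manifest
    return report
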