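"""Gonadal-investment effect sizes from raw individual-level morphometry.

Two routes from the same (tactic, body mass, testes mass) table:

* GSI route — per-individual gonadosomatic index, 100 * testes / soma, then a
  plain two-group Hedges' d.  GSI only removes body size when testes scale
  isometrically with body (allometric slope 1 through the origin); under
  negative allometry the smaller morph gets a spuriously higher GSI.
* ANCOVA route — testes mass ~ soma mass + tactic (+ interaction, dropped if
  non-significant at alpha), partial eta-squared for the tactic term turned
  into a signed Hedges' d.  This is the allometry-robust comparison.

`compare_methods` runs the paired t-test across studies, and
`significance_counts` tallies how often each route declares a significant
tactic difference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .effects import DirectionRule, EffectSize, GroupSummary, apply_direction, d_from_partial_eta2, hedges_d_from_summary

__all__ = [
    "AllometryTable",
    "AncovaResult",
    "soma_mass",
    "gsi",
    "gsi_effect",
    "ancova_effect",
    "compare_methods",
    "significance_counts",
]


@dataclass
class AllometryTable:
    """Individual-level tactic / body mass / testes mass rows for one study."""

    data: pd.DataFrame
    study_id: str = ""
    species: str = ""

    def __post_init__(self) -> None:
        required = {"individual_id", "tactic", "body_mass", "testes_mass"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"allometry table missing columns: {sorted(missing)}")
        df = self.data
        if (df["testes_mass"] <= 0).any():
            raise ValueError("testes_mass must be positive")
        if (df["body_mass"] <= df["testes_mass"]).any():
            raise ValueError("body_mass must exceed testes_mass for every row")
        tactics = df["tactic"].unique()
        if len(tactics) != 2:
            raise ValueError(f"expected exactly two tactic labels, got {list(tactics)}")

    @property
    def tactics(self) -> tuple[str, str]:
        a, b = sorted(self.data["tactic"].unique())
        return a, b


@dataclass
class AncovaResult:
    interaction_p: float
    interaction_dropped: bool
    partial_eta2: float
    d: float
    slope_common: float
    tactic_p: float


def soma_mass(body_mass, testes_mass):
    """Soma mass = body mass minus testes mass (must stay positive)."""
    body = np.asarray(body_mass, dtype=float)
    testes = np.asarray(testes_mass, dtype=float)
    out = body - testes
    if np.any(out <= 0):
        raise ValueError("soma mass must be positive (body_mass > testes_mass)")
    return out if out.ndim else float(out)


def gsi(testes_mass, soma):
    """Gonadosomatic index: 100 * testes mass / soma mass."""
    soma_arr = np.asarray(soma, dtype=float)
    if np.any(soma_arr <= 0):
        raise ValueError("soma mass must be positive")
    out = 100.0 * np.asarray(testes_mass, dtype=float) / soma_arr
    return out if out.ndim else float(out)


def _check_rule(table: AllometryTable, rule: DirectionRule) -> None:
    labels = set(table.tactics)
    if {rule.low_tactic, rule.high_tactic} != labels:
        raise ValueError(
            f"direction rule ({rule.low_tactic!r}, {rule.high_tactic!r}) does not "
            f"match table tactics {sorted(labels)}"
        )


def gsi_effect(table: AllometryTable, rule: DirectionRule, **meta) -> EffectSize:
    """Hedges' d between tactic groups on per-individual GSI values."""
    _check_rule(table, rule)
    df = table.data
    values = gsi(df["testes_mass"], soma_mass(df["body_mass"], df["testes_mass"]))
    first, second = table.tactics
    groups = {}
    for name in (first, second):
        x = np.asarray(values)[df["tactic"].to_numpy() == name]
        if len(x) < 2:
            raise ValueError(f"need >= 2 individuals per tactic, got {len(x)} for {name!r}")
        groups[name] = GroupSummary(n=len(x), mean=float(x.mean()), sd=float(x.std(ddof=1)))
    raw = hedges_d_from_summary(groups[second], groups[first], measurement="GSI", **meta)
    return apply_direction(raw, rule, observed_order=(first, second))


def _ancova_fits(table: AllometryTable):
    df = table.data
    y = df["testes_mass"].to_numpy(dtype=float)
    soma = soma_mass(df["body_mass"], df["testes_mass"])
    first, second = table.tactics
    tac = (df["tactic"].to_numpy() == second).astype(float)
    x_cov = sm.add_constant(np.column_stack([soma]))
    x_main = sm.add_constant(np.column_stack([soma, tac]))
    x_full = sm.add_constant(np.column_stack([soma, tac, soma * tac]))
    fit_cov = sm.OLS(y, x_cov).fit()
    fit_main = sm.OLS(y, x_main).fit()
    fit_full = sm.OLS(y, x_full).fit()
    return fit_cov, fit_main, fit_full, tac


def ancova_effect(
    table: AllometryTable, rule: DirectionRule, alpha: float = 0.05, **meta
) -> tuple[AncovaResult, EffectSize]:
    """Allometry-corrected tactic effect: ANCOVA partial eta^2 -> Hedges' d.

    Fits testes ~ soma * tactic; if the slope-heterogeneity interaction is
    non-significant at ``alpha`` it is dropped and the tactic term is tested in
    the common-slope model.  Partial eta^2 = SS_tactic / (SS_tactic + SS_res)
    with the tactic sum of squares taken after the soma covariate; the sign of
    d comes from the adjusted (equal-soma) group difference.
    """
    _check_rule(table, rule)
    counts = table.data["tactic"].value_counts()
    if counts.min() < 3:
        raise ValueError("need >= 3 individuals per tactic for the ANCOVA")
    fit_cov, fit_main, fit_full, tac = _ancova_fits(table)
    interaction_p = float(fit_full.pvalues[3])
    dropped = bool(interaction_p >= alpha)

    ss_tactic = float(fit_cov.ssr - fit_main.ssr)
    ss_res = float(fit_main.ssr)
    eta2 = max(0.0, ss_tactic / (ss_tactic + ss_res)) if (ss_tactic + ss_res) > 0 else 0.0
    eta2 = min(eta2, 1.0 - 1e-12)
    adj_diff = float(fit_main.params[2])  # tactic coefficient == adjusted mean difference
    sign = 1 if adj_diff >= 0 else -1
    first, second = table.tactics
    n2 = int(tac.sum())
    n1 = len(tac) - n2
    raw = d_from_partial_eta2(eta2, n1, n2, sign=sign, measurement="ANCOVA", **meta)
    eff = apply_direction(raw, rule, observed_order=(first, second))
    result = AncovaResult(
        interaction_p=interaction_p,
        interaction_dropped=dropped,
        partial_eta2=eta2,
        d=eff.d,
        slope_common=float(fit_main.params[1]),
        tactic_p=float(fit_main.pvalues[2]),
    )
    return result, eff


def compare_methods(pairs: list[tuple[float, float]]):
    """Paired t-test on (d_GSI, d_ANCOVA) pairs across studies.

    Returns (t, df, two-sided p, mean difference) for GSI minus ANCOVA.
    """
    if len(pairs) < 2:
        raise ValueError("need at least two (d_gsi, d_ancova) pairs")
    arr = np.asarray(pairs, dtype=float)
    diffs = arr[:, 0] - arr[:, 1]
    sd = diffs.std(ddof=1)
    if sd == 0:
        raise ValueError("differences have zero variance; paired t-test undefined")
    n = len(diffs)
    t = diffs.mean() / (sd / math.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), n - 1)
    return float(t), n - 1, float(p), float(diffs.mean())


def significance_counts(
    tables: list[AllometryTable], alpha: float = 0.05
) -> tuple[int, int, list[str]]:
    """Per study, test the tactic difference by a two-sample t-test on GSI and
    by the ANCOVA tactic term; return counts of significant results per route
    (plus study IDs whose fits failed)."""
    gsi_sig = ancova_sig = 0
    failures: list[str] = []
    for table in tables:
        try:
            df = table.data
            values = gsi(df["testes_mass"], soma_mass(df["body_mass"], df["testes_mass"]))
            first, second = table.tactics
            mask = df["tactic"].to_numpy() == second
            g1 = np.asarray(values)[mask]
            g0 = np.asarray(values)[~mask]
            p_gsi = stats.ttest_ind(g1, g0, equal_var=True).pvalue
            # tactic term tested in the common-slope model (the model the
            # effect size is computed from, whether or not slopes differ)
            _, fit_main, _, _ = _ancova_fits(table)
            p_anc = float(fit_main.pvalues[2])
            gsi_sig += int(p_gsi < alpha)
            ancova_sig += int(p_anc < alpha)
        except (ValueError, np.linalg.LinAlgError) as err:  # propagate per-table, not fatal
            failures.append(f"{table.study_id}: {err}")
    return gsi_sig, ancova_sig, failures
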