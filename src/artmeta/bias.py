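"""Publication-bias diagnostics inside the multilevel model.

Both checks are ordinary one-moderator meta-regressions:

* precision regression — covariate 1/SE_i (study precision).  A slope whose
  CI excludes zero flags funnel asymmetry, the signature of missing small,
  weak effects (a small-study effect).
* time-lag regression — covariate publication year (mean-centred).  A slope
  CI entirely below zero flags a decline effect.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .meta import MetaDataset, MultilevelMetaRegression, meta_regression

__all__ = ["BiasReport", "precision_regression", "time_lag_regression"]


@dataclass
class BiasReport:
    covariate: str  # "inverse_se" or "pub_year"
    slope: float
    ci_low: float
    ci_high: float
    qm: float
    p: float
    flagged: bool
    k: int
    model: MultilevelMetaRegression

    def __post_init__(self) -> None:
        if self.covariate not in ("inverse_se", "pub_year"):
            raise ValueError(f"unsupported bias covariate {self.covariate!r}")


def _report(model: MultilevelMetaRegression, name: str, covariate: str, flagged) -> BiasReport:
    return BiasReport(
        covariate=covariate,
        slope=float(model.beta_[name]),
        ci_low=float(model.ci_low_[name]),
        ci_high=float(model.ci_high_[name]),
        qm=float(model.qm_),
        p=float(model.qm_p_),
        flagged=bool(flagged),
        k=model.k_,
        model=model,
    )


def precision_regression(dataset: MetaDataset, **kwargs) -> BiasReport:
    """Meta-regression of effect size on inverse standard error."""
    if dataset.k < 3:
        raise ValueError("need at least three effects")
    eff = dataset.effects.copy()
    eff["inverse_se"] = 1.0 / np.sqrt(eff["var"].astype(float))
    if eff["inverse_se"].nunique() < 2:
        raise ValueError("all effects share one precision; asymmetry slope undefined")
    ds = replace(dataset, effects=eff)
    model = meta_regression(ds, "inverse_se", **kwargs)
    flagged = model.ci_low_["inverse_se"] > 0 or model.ci_high_["inverse_se"] < 0
    return _report(model, "inverse_se", "inverse_se", flagged)


def time_lag_regression(dataset: MetaDataset, **kwargs) -> BiasReport:
    """Meta-regression of effect size on publication year (centred; the slope
    is per year and unchanged by centring)."""
    eff = dataset.effects.copy()
    years = eff["pub_year"].astype(float)
    if years.nunique() < 2:
        raise ValueError("need at least two distinct publication years")
    eff["pub_year_c"] = years - years.mean()
    ds = replace(dataset, effects=eff)
    model = meta_regression(ds, "pub_year_c", **kwargs)
    flagged = model.ci_high_["pub_year_c"] < 0  # decline: CI entirely negative
    return _report(model, "pub_year_c", "pub_year", flagged)
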