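"""Multiple regression of trait responses on treatment factors, with
backward AIC selection.

The full model regresses a trait value Y on the treatment factors and their
products,

    Y = b1*X1 + b2*X2 + b3*X3 + b4*X4
        + b12*X1X2 + b13*X1X3 + b23*X2X3 + b123*X1X2X3 + e,

where X1 is the daily maximum temperature (degC), X2 the relative humidity
(%), X3 the duration (days), and X4 the cultivar's control value of the same
trait — a covariate that absorbs varietal baseline differences. Interaction
regressors are raw products. Backward elimination greedily removes the term
whose removal most lowers AIC, subject to marginality (a main effect never
leaves while an interaction containing it stays; X4, the varietal covariate,
is never dropped), and stops at a local AIC minimum.

AIC here is n*ln(RSS/n) + 2*(p + 1) with p the number of mean parameters
(including the intercept) and +1 for the residual variance; additive
constants are irrelevant for selection and omitted consistently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import MissingControlError, RankDeficiencyError
from .trial import Trial, cell_means

#: Candidate terms of the full model, in canonical order.
FULL_TERMS = ("X1", "X2", "X3", "X4", "X1X2", "X1X3", "X2X3", "X1X2X3")

#: Lower-order terms each interaction contains (marginality relations).
CONTAINS = {
    "X1X2": ("X1", "X2"),
    "X1X3": ("X1", "X3"),
    "X2X3": ("X2", "X3"),
    "X1X2X3": ("X1", "X2", "X3", "X1X2", "X1X3", "X2X3"),
}


def build_design(
    trial: Trial, trait: str, granularity: str = "replicate"
) -> pd.DataFrame:
    """Design frame for one trait: response y plus all candidate regressors.

    ``granularity='replicate'`` yields one row per cultivar x treatment x
    replicate; ``'cell_means'`` one row per cultivar x treatment. X4 is the
    cultivar's control cell mean for the trait in both modes.
    """
    if granularity not in ("replicate", "cell_means"):
        raise ValueError(f"unknown granularity {granularity!r}")
    obs = trial.observations
    ctrl = cell_means(obs)
    ctrl = ctrl[ctrl["is_control"] & (ctrl["trait"] == trait)]
    x4 = ctrl.set_index("cultivar")["x"]

    if granularity == "replicate":
        rows = obs[(~obs["is_control"]) & (obs["trait"] == trait)].copy()
        rows = rows.rename(columns={"value": "y"})
    else:
        m = cell_means(obs)
        rows = m[(~m["is_control"]) & (m["trait"] == trait)].copy()
        rows = rows.rename(columns={"x": "y"})

    missing = sorted(set(rows["cultivar"]) - set(x4.index))
    if missing:
        raise MissingControlError(
            f"no control observations for cultivar(s) {missing} ({trait})"
        )

    out = pd.DataFrame(
        {
            "cultivar": rows["cultivar"].to_numpy(),
            "y": rows["y"].to_numpy(),
            "X1": rows["temperature_c"].to_numpy(float),
            "X2": rows["rh_pct"].to_numpy(float),
            "X3": rows["duration_d"].to_numpy(float),
            "X4": x4.reindex(rows["cultivar"]).to_numpy(float),
        }
    )
    out["X1X2"] = out["X1"] * out["X2"]
    out["X1X3"] = out["X1"] * out["X3"]
    out["X2X3"] = out["X2"] * out["X3"]
    out["X1X2X3"] = out["X1"] * out["X2"] * out["X3"]
    return out.reset_index(drop=True)


@dataclass
class RegressionFit:
    """OLS fit of one candidate model."""

    terms: tuple
    params: pd.Series  # intercept + term coefficients
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    aic: float
    r_squared: float
    adj_r_squared: float
    f_value: float
    f_pvalue: float
    nobs: int
    rss: float
    trace: list = field(default_factory=list)  # backward-elimination steps

    def stars(self) -> pd.Series:
        from .anova import significance_stars

        return self.pvalues.map(significance_stars)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coefficient": self.params,
                "se": self.bse,
                "t": self.tvalues,
                "p": self.pvalues,
                "stars": self.stars(),
            }
        )


def _aic(n: int, rss: float, n_params: int) -> float:
    # Gaussian likelihood with profiled variance; +1 counts sigma^2
    return float(n * np.log(rss / n) + 2 * (n_params + 1))


def fit_ols(design: pd.DataFrame, terms) -> RegressionFit:
    """Least-squares fit of y on the given terms plus an intercept."""
    terms = tuple(terms)
    X = sm.add_constant(design.loc[:, list(terms)], has_constant="add")
    y = design["y"].to_numpy(float)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise RankDeficiencyError(
            "design matrix is rank deficient; drop collinear terms",
            terms=terms,
        )
    res = sm.OLS(y, X).fit()
    n = int(res.nobs)
    rss = float(res.ssr)
    params = res.params.rename({"const": "intercept"})
    return RegressionFit(
        terms=terms,
        params=params,
        bse=res.bse.rename({"const": "intercept"}),
        tvalues=res.tvalues.rename({"const": "intercept"}),
        pvalues=res.pvalues.rename({"const": "intercept"}),
        aic=_aic(n, rss, len(terms) + 1),
        r_squared=float(res.rsquared),
        adj_r_squared=float(res.rsquared_adj),
        f_value=float(res.fvalue),
        f_pvalue=float(res.f_pvalue),
        nobs=n,
        rss=rss,
    )


def droppable_terms(terms, forced=("X4",), contains: dict | None = None):
    """Terms removable without violating marginality or the forced set."""
    contains = CONTAINS if contains is None else contains
    terms = tuple(terms)
    present = set(terms)
    protected = set(forced)
    for t in terms:
        protected.update(set(contains.get(t, ())) & present)
    return tuple(t for t in terms if t not in protected)


def backward_aic(
    design: pd.DataFrame,
    full_terms=FULL_TERMS,
    forced=("X4",),
    contains: dict | None = None,
) -> RegressionFit:
    """Greedy backward elimination by AIC under the marginality constraint.

    At each step the single removal that most lowers AIC is taken; the search
    stops when every allowed removal would raise it. The elimination path is
    recorded on the returned fit's ``trace`` as (dropped term, AIC after).
    """
    current = fit_ols(design, full_terms)
    trace = []
    while True:
        candidates = droppable_terms(current.terms, forced=forced,
                                     contains=contains)
        best = None
        for term in candidates:
            reduced = tuple(t for t in current.terms if t != term)
            fit = fit_ols(design, reduced)
            if fit.aic < current.aic - 1e-10 and (
                best is None or fit.aic < best.aic
            ):
                best = fit
                best_term = term
        if best is None:
            break
        trace.append((best_term, best.aic))
        current = best
    current.trace = trace
    return current


def fit_all_traits(
    trial: Trial, granularity: str = "replicate"
) -> dict[str, RegressionFit]:
    """Backward-selected fit per trait (the reporting pipeline's entry)."""
    return {
        trait: backward_aic(build_design(trial, trait, granularity))
        for trait in trial.design.traits
    }
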