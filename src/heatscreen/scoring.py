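"""Fuzzy membership-function scoring of heat tolerance.

The screening statistic works trait by trait. For traits that decline under
stress (grain weight, head rice rate) each treated cell mean X_ijk is first
expressed as a heat-tolerance coefficient relative to the same cultivar's
control,

    HC_ijk = X_ijk / CK_ij,

and the coefficient is min-max normalised over the pool of all cultivars and
all treatments of that trait into a membership function value

    MFV_ijk = (HC_ijk - min HC_i) / (max HC_i - min HC_i)  in [0, 1].

Chalkiness rises under stress and its control values are small, so its MFV is
computed on the raw cell means and inverted:

    MFV_ijk = 1 - (X_ijk - min X_i) / (max X_i - min X_i).

Trait MFVs are averaged into a per-treatment tolerance index, and the twelve
per-treatment indices into a per-cultivar index used for ranking. The
treatment with the widest cultivar spread of per-treatment indices is the
most discriminating screening condition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import (
    DegeneratePoolError,
    InvalidBaselineError,
    MissingCellError,
    MissingControlError,
)
from .trial import (
    INVERTED_TRAITS,
    RATIO_TRAITS,
    Trial,
    cell_means,
)

_FACTORS = ["temperature_c", "rh_pct", "duration_d"]


def heat_tolerance_coefficient(x, ck):
    """Treated-to-control ratio HC = x / ck (vectorised over arrays)."""
    ck_arr = np.asarray(ck, dtype=float)
    if np.any(ck_arr <= 0):
        raise InvalidBaselineError("control baseline must be positive")
    x_arr = np.asarray(x, dtype=float)
    if np.any(x_arr < 0):
        raise InvalidBaselineError("treated values must be non-negative")
    out = x_arr / ck_arr
    return float(out) if out.ndim == 0 else out


def _pool_range(pool) -> tuple[float, float]:
    arr = np.asarray(pool, dtype=float)
    lo, hi = float(arr.min()), float(arr.max())
    if hi == lo:
        raise DegeneratePoolError(
            "all pooled values identical: min-max normalisation undefined"
        )
    return lo, hi


def mfv_ratio(hc, pool):
    """Min-max normalise a tolerance coefficient over its trait pool."""
    lo, hi = _pool_range(pool)
    out = (np.asarray(hc, dtype=float) - lo) / (hi - lo)
    return float(out) if out.ndim == 0 else out


def mfv_inverted(x, pool):
    """Inverted min-max score for traits where larger raw values are worse."""
    lo, hi = _pool_range(pool)
    out = 1.0 - (np.asarray(x, dtype=float) - lo) / (hi - lo)
    return float(out) if out.ndim == 0 else out


@dataclass
class ScoreTable:
    """Scores at the three aggregation levels.

    ``scores``: one row per cultivar x treatment x trait with the cell mean
    ``x``, the coefficient ``hc`` (NaN for chalkiness) and ``mfv``.
    ``treatment_means``: per cultivar x treatment, mean of the trait MFVs.
    ``cultivar_means``: per cultivar, mean of its per-treatment means.
    """

    scores: pd.DataFrame
    treatment_means: pd.DataFrame
    cultivar_means: pd.Series


def aggregate_mfv(trait_mfv: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Average trait MFVs into treatment- and cultivar-level indices.

    ``trait_mfv`` is long: cultivar, temperature_c, rh_pct, duration_d,
    trait, mfv. Aggregation is unweighted at both levels, at full precision.
    """
    tm = (
        trait_mfv.groupby(["cultivar"] + _FACTORS)["mfv"]
        .mean()
        .reset_index()
        .rename(columns={"mfv": "mean_mfv"})
        .sort_values(["cultivar"] + _FACTORS)
        .reset_index(drop=True)
    )
    cm = tm.groupby("cultivar")["mean_mfv"].mean().sort_index()
    cm.name = "mean_mfv"
    return tm, cm


def score_trial(trial: Trial, pool_includes_control: bool = False) -> ScoreTable:
    """Score a whole trial: HC, trait MFVs, and both aggregation levels.

    Min-max pools are formed per trait over all cultivars and all non-control
    treatments; ``pool_includes_control`` adds the control cells to the pool
    (HC = 1 for ratio traits), compressing the scale.
    """
    means = cell_means(trial.observations)
    controls = means[means["is_control"]].set_index(["cultivar", "trait"])["x"]
    treated = means[~means["is_control"]].copy()
    if treated.empty:
        raise MissingCellError("trial contains no treated cells")

    rows = []
    for trait in trial.design.traits:
        sub = treated[treated["trait"] == trait].copy()
        if trait in RATIO_TRAITS:
            ck = []
            for c in sub["cultivar"]:
                try:
                    ck.append(float(controls.loc[(c, trait)]))
                except KeyError:
                    raise MissingControlError(
                        f"no control observations for ({c}, {trait})"
                    ) from None
            sub["hc"] = heat_tolerance_coefficient(sub["x"].to_numpy(), np.array(ck))
            pool = sub["hc"].to_numpy()
            if pool_includes_control:
                pool = np.concatenate([pool, np.ones(sub["cultivar"].nunique())])
            sub["mfv"] = mfv_ratio(sub["hc"].to_numpy(), pool)
        elif trait in INVERTED_TRAITS:
            # raw chalkiness, inverted: control baselines are too small for a
            # stable ratio
            for c in sub["cultivar"].unique():
                if (c, trait) not in controls.index:
                    raise MissingControlError(
                        f"no control observations for ({c}, {trait})"
                    )
            sub["hc"] = np.nan
            pool = sub["x"].to_numpy()
            if pool_includes_control:
                ctrl_vals = controls.xs(trait, level="trait").to_numpy()
                pool = np.concatenate([pool, ctrl_vals])
            sub["mfv"] = mfv_inverted(sub["x"].to_numpy(), pool)
        else:  # pragma: no cover - trait set is closed
            raise ValueError(f"no scoring rule for trait {trait}")
        rows.append(sub)

    scores = (
        pd.concat(rows)
        .sort_values(["cultivar"] + _FACTORS + ["trait"])
        .reset_index(drop=True)
        .loc[:, ["cultivar"] + _FACTORS + ["trait", "x", "hc", "mfv"]]
    )
    tm, cm = aggregate_mfv(scores.rename(columns={"mfv": "mfv"}))
    return ScoreTable(scores=scores, treatment_means=tm, cultivar_means=cm)


def rank_cultivars(table: ScoreTable | pd.Series) -> pd.DataFrame:
    """Cultivars ordered by mean MFV, descending; ties broken by identifier."""
    cm = table.cultivar_means if isinstance(table, ScoreTable) else table
    out = cm.reset_index()
    out.columns = ["cultivar", "mean_mfv"]
    out = out.sort_values(
        ["mean_mfv", "cultivar"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    out.insert(0, "rank", np.arange(1, len(out) + 1))
    return out


def screening_discrimination(table: ScoreTable | pd.DataFrame) -> pd.DataFrame:
    """Per-treatment cultivar spread of the tolerance index.

    Spread = max - min over cultivars of the per-treatment mean MFV; the
    treatment(s) with maximal spread separate tolerant from susceptible
    material best and are flagged ``best=True`` (ties all flagged).
    """
    tm = table.treatment_means if isinstance(table, ScoreTable) else table
    if tm["cultivar"].nunique() < 2:
        raise ValueError("spread is undefined with fewer than two cultivars")
    g = tm.groupby(_FACTORS)["mean_mfv"]
    out = (g.max() - g.min()).reset_index().rename(columns={"mean_mfv": "spread"})
    out["max_mfv"] = g.max().to_numpy()
    out["min_mfv"] = g.min().to_numpy()
    out = out.sort_values(_FACTORS).reset_index(drop=True)
    out["best"] = np.isclose(out["spread"], out["spread"].max())
    return out


def rh_contrast(
    source: Trial | pd.DataFrame,
    trait: str,
    rh_low: float = 75.0,
    rh_high: float = 85.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Paired low-RH minus high-RH differences per temperature x duration.

    For each cultivar and (temperature, duration) cell, the trait cell mean at
    the drier level minus that at the moister level; positive values for
    chalkiness and negative values for grain weight indicate extra damage from
    dry air. Returns (per-cultivar differences, per-cell summary with median
    and quartiles).
    """
    if isinstance(source, Trial):
        means = cell_means(source.observations)
        means = means[(~means["is_control"]) & (means["trait"] == trait)]
        val = "x"
    else:
        means = source[source["trait"] == trait].copy()
        val = "x" if "x" in means.columns else "value"

    lo = means[means["rh_pct"] == rh_low]
    hi = means[means["rh_pct"] == rh_high]
    key = ["cultivar", "temperature_c", "duration_d"]
    merged = lo.merge(hi, on=key, suffixes=("_lo", "_hi"), how="outer")
    missing = merged[merged[f"{val}_lo"].isna() | merged[f"{val}_hi"].isna()]
    if len(missing):
        cell = missing.iloc[0][key].to_dict()
        raise MissingCellError(f"missing RH counterpart for cell {cell}")
    merged["difference"] = merged[f"{val}_lo"] - merged[f"{val}_hi"]
    diffs = merged[key + ["difference"]].sort_values(key).reset_index(drop=True)

    summary = (
        diffs.groupby(["temperature_c", "duration_d"])["difference"]
        .agg(
            median="median",
            q1=lambda s: s.quantile(0.25),
            q3=lambda s: s.quantile(0.75),
            n="count",
        )
        .reset_index()
    )
    return diffs, summary
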