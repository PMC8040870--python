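"""Balanced three-way fixed-effects ANOVA and LSD mean separation.

For each cultivar x trait, replicate-level observations from the full
T x RH x D factorial (control excluded) are decomposed into main-effect and
interaction sums of squares via marginal means. On a balanced design this
equals the least-squares (sum-to-zero effect coding) decomposition, and the
Type I/II/III distinctions collapse. F for each term is MS_term / MS_residual
with the usual degrees of freedom.

Mean separation uses Fisher's least significant difference at level alpha:

    LSD = t(1 - alpha/2, df_res) * sqrt(2 * MS_res / n),

with letters assigned by the insert-and-absorb compact-letter-display
algorithm so that two groups share a letter iff their means do not differ by
more than the LSD. When the unheated control is compared alongside the twelve
treatments, MS_res comes from a one-way ANOVA on the thirteen groups (the
control has no factor levels and cannot enter the factorial).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import UnbalancedDesignError
from .trial import Trial, TreatmentKey

TERM_ORDER = ("T", "RH", "D", "T:RH", "T:D", "RH:D", "T:RH:D", "residual")


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass
class AnovaTable:
    """Term-wise df, SS, MS, F and p for the factorial decomposition."""

    table: pd.DataFrame
    zero_residual: bool = False

    def f_value(self, term: str) -> float:
        return float(self.table.set_index("term").loc[term, "F"])


def _marginal_ss(cube: np.ndarray) -> dict:
    """Sums of squares from marginal means of a (a, b, c, n) data cube."""
    a, b, c, n = cube.shape
    grand = cube.mean()
    m_a = cube.mean(axis=(1, 2, 3))
    m_b = cube.mean(axis=(0, 2, 3))
    m_c = cube.mean(axis=(0, 1, 3))
    m_ab = cube.mean(axis=(2, 3))
    m_ac = cube.mean(axis=(1, 3))
    m_bc = cube.mean(axis=(0, 3))
    m_abc = cube.mean(axis=3)

    ss = {}
    ss["T"] = b * c * n * np.sum((m_a - grand) ** 2)
    ss["RH"] = a * c * n * np.sum((m_b - grand) ** 2)
    ss["D"] = a * b * n * np.sum((m_c - grand) ** 2)
    ss["T:RH"] = c * n * np.sum(
        (m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2
    )
    ss["T:D"] = b * n * np.sum(
        (m_ac - m_a[:, None] - m_c[None, :] + grand) ** 2
    )
    ss["RH:D"] = a * n * np.sum(
        (m_bc - m_b[:, None] - m_c[None, :] + grand) ** 2
    )
    interaction_abc = (
        m_abc
        - m_ab[:, :, None]
        - m_ac[:, None, :]
        - m_bc[None, :, :]
        + m_a[:, None, None]
        + m_b[None, :, None]
        + m_c[None, None, :]
        - grand
    )
    ss["T:RH:D"] = n * np.sum(interaction_abc**2)
    ss["residual"] = np.sum((cube - m_abc[..., None]) ** 2)
    ss["total"] = np.sum((cube - grand) ** 2)
    return ss


def anova_from_cube(cube: np.ndarray) -> AnovaTable:
    """ANOVA of a balanced (levels_T, levels_RH, levels_D, n) data cube."""
    a, b, c, n = cube.shape
    if n < 2:
        raise UnbalancedDesignError("at least 2 replicates per cell required")
    ss = _marginal_ss(cube)
    dfs = {
        "T": a - 1,
        "RH": b - 1,
        "D": c - 1,
        "T:RH": (a - 1) * (b - 1),
        "T:D": (a - 1) * (c - 1),
        "RH:D": (b - 1) * (c - 1),
        "T:RH:D": (a - 1) * (b - 1) * (c - 1),
        "residual": a * b * c * (n - 1),
    }
    ms_res = ss["residual"] / dfs["residual"]
    zero_res = ms_res == 0.0

    rows = []
    for term in TERM_ORDER:
        df_t = dfs[term]
        ms = ss[term] / df_t
        if term == "residual":
            f = np.nan
            p = np.nan
        elif zero_res:
            f = np.inf
            p = 0.0
        else:
            f = ms / ms_res
            p = float(stats.f.sf(f, df_t, dfs["residual"]))
        rows.append(
            {
                "term": term,
                "df": df_t,
                "sum_sq": float(ss[term]),
                "mean_sq": float(ms),
                "F": float(f),
                "p": p,
                "stars": "" if term == "residual" else significance_stars(p),
            }
        )
    return AnovaTable(table=pd.DataFrame(rows), zero_residual=bool(zero_res))


def _pivot_cube(df: pd.DataFrame) -> np.ndarray:
    """Arrange one cultivar x trait's treated observations into a cube."""
    t_levels = np.sort(df["temperature_c"].unique())
    rh_levels = np.sort(df["rh_pct"].unique())
    d_levels = np.sort(df["duration_d"].unique())
    counts = df.groupby(["temperature_c", "rh_pct", "duration_d"]).size()
    expected = len(t_levels) * len(rh_levels) * len(d_levels)
    if len(counts) != expected or counts.nunique() != 1:
        offending = [
            {"cell": k, "n": int(v)}
            for k, v in counts.items()
            if v != counts.max()
        ]
        missing = expected - len(counts)
        raise UnbalancedDesignError(
            f"unequal replicate counts across cells ({missing} cells absent)",
            cells=offending,
        )
    n = int(counts.iloc[0])
    if n < 2:
        raise UnbalancedDesignError("at least 2 replicates per cell required")
    cube = np.empty((len(t_levels), len(rh_levels), len(d_levels), n))
    grouped = df.sort_values("replicate").groupby(
        ["temperature_c", "rh_pct", "duration_d"]
    )["value"]
    for (t, r, d), vals in grouped:
        i = np.searchsorted(t_levels, t)
        j = np.searchsorted(rh_levels, r)
        k = np.searchsorted(d_levels, d)
        cube[i, j, k, :] = vals.to_numpy()
    return cube


def fit_anova(observations: pd.DataFrame) -> AnovaTable:
    """Factorial ANOVA for one cultivar x trait's replicate-level data.

    ``observations`` must hold treated rows only (control rows are dropped if
    present) for a single cultivar and trait; the design must be a complete
    balanced factorial.
    """
    df = observations[~observations["is_control"]] if "is_control" in observations \
        else observations
    return anova_from_cube(_pivot_cube(df))


def anova_by_group(trial: Trial) -> pd.DataFrame:
    """Table-style summary: one ANOVA per cultivar x trait, stacked long."""
    frames = []
    for cultivar in trial.design.cultivars:
        for trait in trial.design.traits:
            sub = trial.observations[
                (trial.observations["cultivar"] == cultivar)
                & (trial.observations["trait"] == trait)
            ]
            tab = fit_anova(sub).table.copy()
            tab.insert(0, "trait", trait)
            tab.insert(0, "cultivar", cultivar)
            frames.append(tab)
    return pd.concat(frames, ignore_index=True)


@dataclass
class LsdGrouping:
    """Group means with compact letters; shared letter = not distinguishable."""

    means: pd.Series  # index: group labels, sorted descending by mean
    letters: dict  # group label -> letter string, e.g. "ab"
    lsd: float
    alpha: float
    df_residual: int

    def share_letter(self, g1, g2) -> bool:
        return bool(set(self.letters[g1]) & set(self.letters[g2]))


def _insert_absorb(nonsig: np.ndarray) -> list[set]:
    """Compact-letter columns from a boolean non-significance matrix.

    Start from one column holding every group; for each significant pair
    split any column containing both; absorb columns that became subsets.
    Groups are assumed ordered (descending means) so letters read from the
    top mean down.
    """
    k = nonsig.shape[0]
    columns: list[set] = [set(range(k))]
    for i in range(k):
        for j in range(i + 1, k):
            if nonsig[i, j]:
                continue
            for col in list(columns):
                if i in col and j in col:
                    columns.remove(col)
                    a, b = col - {j}, col - {i}
                    for new in (a, b):
                        if not any(new <= other for other in columns):
                            columns.append(new)
    # absorb: drop duplicates and columns that are subsets of others
    unique = list({frozenset(c) for c in columns})
    columns = [
        set(c) for c in unique if not any(c < other for other in unique)
    ]
    columns.sort(key=lambda c: (min(c), -len(c)))
    return columns


def lsd_test(
    means: pd.Series,
    n: int,
    ms_residual: float,
    df_residual: int,
    alpha: float = 0.05,
) -> LsdGrouping:
    """Fisher's LSD over equally replicated groups, with compact letters.

    ``means`` maps group labels to their means; all groups share the
    replicate count ``n`` and the pooled residual mean square.
    """
    if n < 2:
        raise ValueError("LSD requires at least 2 replicates per group")
    t_crit = stats.t.ppf(1 - alpha / 2, df_residual)
    lsd = float(t_crit * np.sqrt(2.0 * ms_residual / n))

    ordered = means.sort_values(ascending=False, kind="mergesort")
    vals = ordered.to_numpy()
    nonsig = np.abs(vals[:, None] - vals[None, :]) <= lsd
    columns = _insert_absorb(nonsig)

    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {g: "" for g in ordered.index}
    for letter, col in zip(alphabet, columns):
        for idx in sorted(col):
            letters[ordered.index[idx]] += letter
    return LsdGrouping(
        means=ordered, letters=letters, lsd=lsd, alpha=alpha,
        df_residual=df_residual,
    )


def lsd_with_control(
    trial: Trial,
    cultivar,
    trait: str,
    alpha: float = 0.05,
    include_control: bool = True,
) -> LsdGrouping:
    """LSD letters across the treatment groups (optionally plus control).

    The residual mean square comes from a one-way ANOVA on the groups being
    compared, since the control carries no factor levels.
    """
    df = trial.observations[
        (trial.observations["cultivar"] == cultivar)
        & (trial.observations["trait"] == trait)
    ]
    if not include_control:
        df = df[~df["is_control"]]

    def group_label(row):
        if row.is_control:
            return "control"
        return TreatmentKey(row.temperature_c, row.rh_pct, row.duration_d).label()

    labels = [group_label(r) for r in df.itertuples()]
    values = df["value"].to_numpy()
    groups = pd.DataFrame({"group": labels, "value": values})
    sizes = groups.groupby("group").size()
    if sizes.nunique() != 1:
        raise ValueError("heterogeneous group sizes; LSD assumes equal n")
    n = int(sizes.iloc[0])
    means = groups.groupby("group")["value"].mean()
    ss_res = float(
        ((groups["value"] - groups.groupby("group")["value"].transform("mean")) ** 2)
        .sum()
    )
    df_res = len(groups) - len(means)
    ms_res = ss_res / df_res
    return lsd_test(means, n=n, ms_residual=ms_res, df_residual=df_res, alpha=alpha)
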