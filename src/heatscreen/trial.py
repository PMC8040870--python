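"""Domain types and tidy-CSV I/O for factorial heat-stress trials.

A trial is a long (tidy) table of replicate-level trait observations from a
temperature x relative-humidity x duration factorial on a panel of rice
cultivars, plus an unheated natural-condition control per cultivar. The
canonical in-memory container is a :class:`pandas.DataFrame` with the columns
in :data:`CANONICAL_COLUMNS`; :class:`Trial` bundles it with the inferred
:class:`TrialDesign` and a balance report.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    IntegrityError,
    MissingCellError,
    SchemaError,
)

#: Trait identifiers, in canonical order. Grain weight is g per 1000 grains;
#: head rice rate and chalkiness are percentages.
TRAITS = ("grain_weight", "head_rice_rate", "chalkiness")

#: Traits that decrease under heat stress and are scored through the
#: heat-tolerance coefficient (treated / control ratio).
RATIO_TRAITS = ("grain_weight", "head_rice_rate")

#: Traits that increase under stress and are scored on raw values, inverted.
INVERTED_TRAITS = ("chalkiness",)

#: Percentage traits bounded above by 100.
PERCENT_TRAITS = ("head_rice_rate", "chalkiness")

CANONICAL_COLUMNS = (
    "cultivar",
    "temperature_c",
    "rh_pct",
    "duration_d",
    "is_control",
    "replicate",
    "trait",
    "value",
)


@dataclass(frozen=True)
class TreatmentKey:
    """One temperature x RH x duration treatment, or the control sentinel.

    Controls carry no factor levels (the control is the ambient natural
    condition, not a factorial cell); their factor fields are ``nan``.
    Ordering sorts non-control keys by (temperature, rh, duration) and places
    the control last, so derived tables are deterministic.
    """

    temperature: float = float("nan")
    rh: float = float("nan")
    duration: float = float("nan")
    is_control: bool = False

    def __post_init__(self):
        if self.is_control:
            object.__setattr__(self, "temperature", float("nan"))
            object.__setattr__(self, "rh", float("nan"))
            object.__setattr__(self, "duration", float("nan"))
            return
        if not (self.temperature > 0):
            raise ValueError(f"temperature must be positive, got {self.temperature}")
        if not (0 < self.rh <= 100):
            raise ValueError(f"rh must lie in (0, 100], got {self.rh}")
        if not (self.duration >= 1):
            raise ValueError(f"duration must be >= 1 day, got {self.duration}")

    @classmethod
    def control(cls) -> "TreatmentKey":
        return cls(is_control=True)

    def sort_key(self) -> tuple:
        if self.is_control:
            return (1, 0.0, 0.0, 0.0)
        return (0, self.temperature, self.rh, self.duration)

    def __lt__(self, other: "TreatmentKey") -> bool:
        return self.sort_key() < other.sort_key()

    def label(self) -> str:
        if self.is_control:
            return "control"
        return f"{self.temperature:g}C_rh{self.rh:g}_{self.duration:g}d"


@dataclass(frozen=True)
class TrialDesign:
    """Shape of a balanced trial: who, what, and how many replicates."""

    cultivars: tuple
    treatments: tuple  # non-control TreatmentKeys, sorted
    n_replicates: int
    traits: tuple


@dataclass
class BalanceReport:
    """Result of checking that every cell carries the same replicate count.

    Scoring tolerates imbalance (cell means are still defined); the factorial
    ANOVA refuses it.
    """

    balanced: bool
    offending_cells: list

    def __bool__(self) -> bool:
        return self.balanced


@dataclass
class Trial:
    """Validated observations plus the inferred design."""

    observations: pd.DataFrame
    design: TrialDesign
    balance: BalanceReport


def treatment_key_from_row(row) -> TreatmentKey:
    if bool(row["is_control"]):
        return TreatmentKey.control()
    return TreatmentKey(
        temperature=float(row["temperature_c"]),
        rh=float(row["rh_pct"]),
        duration=float(row["duration_d"]),
    )


def validate_observations(df: pd.DataFrame) -> pd.DataFrame:
    """Check schema, value ranges and key uniqueness; return a clean copy."""
    missing = [c for c in CANONICAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    out = df.loc[:, list(CANONICAL_COLUMNS)].copy()
    out["is_control"] = out["is_control"].astype(bool)
    out["value"] = out["value"].astype(float)
    out["replicate"] = out["replicate"].astype(int)

    bad_trait = set(out["trait"]) - set(TRAITS)
    if bad_trait:
        raise SchemaError(f"unknown traits: {sorted(bad_trait)}")
    if (out["value"] < 0).any():
        raise SchemaError("negative trait values are not permitted")
    pct = out["trait"].isin(PERCENT_TRAITS)
    if (out.loc[pct, "value"] > 100).any():
        raise SchemaError("percentage traits must not exceed 100")
    if (out["replicate"] < 1).any():
        raise SchemaError("replicate indices must be positive")

    keys = ["cultivar", "temperature_c", "rh_pct", "duration_d", "is_control",
            "replicate", "trait"]
    dup = out.duplicated(subset=keys, keep=False)
    if dup.any():
        first = out.loc[dup, keys].iloc[0].to_dict()
        raise IntegrityError(
            f"duplicate observation key, e.g. {first}"
        )
    return out


def infer_design(df: pd.DataFrame) -> tuple[TrialDesign, BalanceReport]:
    """Infer the factorial design from observations and check balance.

    Deterministic: the same observation multiset always yields the same
    ordering (cultivars and traits sorted; treatments by factor levels).
    """
    cultivars = tuple(sorted(df["cultivar"].unique()))
    traits = tuple(t for t in TRAITS if t in set(df["trait"]))
    treated = df[~df["is_control"]]
    keys = sorted(
        {
            TreatmentKey(float(t), float(r), float(d))
            for t, r, d in zip(
                treated["temperature_c"], treated["rh_pct"], treated["duration_d"]
            )
        }
    )
    counts = (
        df.groupby(
            ["cultivar", "temperature_c", "rh_pct", "duration_d", "is_control",
             "trait"],
            dropna=False,
        )
        .size()
        .reset_index(name="n")
    )
    n_rep = int(counts["n"].mode().iloc[0]) if len(counts) else 0

    offending = []
    seen = {
        (row.cultivar, row.is_control, row.temperature_c, row.rh_pct,
         row.duration_d, row.trait): row.n
        for row in counts.itertuples()
    }
    for c in cultivars:
        for trait in traits:
            cells = [(c, True, np.nan, np.nan, np.nan, trait)] + [
                (c, False, k.temperature, k.rh, k.duration, trait) for k in keys
            ]
            for cell in cells:
                got = _lookup_count(seen, cell)
                if got != n_rep:
                    offending.append({"cell": cell, "n": got})

    design = TrialDesign(cultivars, tuple(keys), n_rep, traits)
    return design, BalanceReport(balanced=not offending, offending_cells=offending)


def _lookup_count(seen: dict, cell: tuple) -> int:
    # nan != nan, so control cells need a tolerant match
    for key, n in seen.items():
        if key[0] == cell[0] and key[1] == cell[1] and key[5] == cell[5]:
            if cell[1]:  # control: factor levels ignored
                return n
            if key[2:5] == cell[2:5]:
                return n
    return 0


def make_trial(df: pd.DataFrame) -> Trial:
    """Validate a canonical DataFrame and infer its design."""
    clean = validate_observations(df)
    design, balance = infer_design(clean)
    return Trial(observations=clean, design=design, balance=balance)


def read_trial_table(
    path: str | Path, schema: Mapping[str, str] | None = None
) -> Trial:
    """Read a long-format trial CSV into a validated :class:`Trial`.

    ``schema`` maps canonical column names to the file's column names, so
    exports with different headers (e.g. converted per-trait sheets) can be
    ingested without rewriting the file.
    """
    df = pd.read_csv(path)
    if schema:
        rename = {src: canon for canon, src in schema.items() if src in df.columns}
        missing = [canon for canon, src in schema.items() if src not in df.columns]
        if missing:
            raise SchemaError(f"schema maps to absent columns: {missing}")
        df = df.rename(columns=rename)
    return make_trial(df)


def write_trial_table(trial: Trial | pd.DataFrame, path: str | Path) -> None:
    """Write observations as canonical CSV (full precision)."""
    df = trial.observations if isinstance(trial, Trial) else trial
    df.loc[:, list(CANONICAL_COLUMNS)].to_csv(path, index=False)


def cell_mean(
    df: pd.DataFrame, cultivar, treatment: TreatmentKey, trait: str
) -> float:
    """Arithmetic mean of replicate values in one cell."""
    if treatment.is_control:
        mask = (df["cultivar"] == cultivar) & df["is_control"] & (df["trait"] == trait)
    else:
        mask = (
            (df["cultivar"] == cultivar)
            & ~df["is_control"]
            & (df["temperature_c"] == treatment.temperature)
            & (df["rh_pct"] == treatment.rh)
            & (df["duration_d"] == treatment.duration)
            & (df["trait"] == trait)
        )
    vals = df.loc[mask, "value"]
    if vals.empty:
        raise MissingCellError(
            f"no observations for ({cultivar}, {treatment.label()}, {trait})"
        )
    return float(vals.mean())


def cell_means(df: pd.DataFrame) -> pd.DataFrame:
    """Replicate-averaged values for every cultivar x treatment x trait cell.

    Returns a long frame with the treatment factor columns retained (control
    rows keep ``is_control=True`` and NaN factor levels).
    """
    out = (
        df.groupby(
            ["cultivar", "is_control", "temperature_c", "rh_pct", "duration_d",
             "trait"],
            dropna=False,
        )["value"]
        .mean()
        .reset_index()
        .rename(columns={"value": "x"})
    )
    return out.sort_values(
        ["cultivar", "is_control", "temperature_c", "rh_pct", "duration_d", "trait"]
    ).reset_index(drop=True)


def design_treatments(design: TrialDesign, include_control: bool = False):
    keys = list(design.treatments)
    if include_control:
        keys.append(TreatmentKey.control())
    return keys


def trial_to_frame(observations: Sequence[dict]) -> pd.DataFrame:
    """Build a canonical frame from row dicts (used by the generator)."""
    return pd.DataFrame(list(observations), columns=list(CANONICAL_COLUMNS))


def design_as_dict(design: TrialDesign) -> dict:
    return {
        "cultivars": list(design.cultivars),
        "treatments": [dataclasses.asdict(k) for k in design.treatments],
        "n_replicates": design.n_replicates,
        "traits": list(design.traits),
    }
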