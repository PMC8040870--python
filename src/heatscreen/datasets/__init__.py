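"""Bundled reference data.

``load_reference_mfv`` returns the published membership-function values from
a six-cultivar indica rice heat-tolerance screening trial (three temperature
levels x two relative-humidity levels x two durations, scored on grain
weight, head rice rate and chalkiness). Values are as printed, rounded to
two decimals; ``mean_mfv`` is the published per-treatment mean of the three
trait MFVs. The table is the standard worked example for the aggregation,
ranking and screening-discrimination operators.
"""

from importlib import resources

import pandas as pd

__all__ = ["load_reference_mfv", "reference_trait_mfv_long"]


def load_reference_mfv() -> pd.DataFrame:
    """Published MFV table: one row per cultivar x treatment, wide by trait."""
    with resources.files(__package__).joinpath("reference_mfv.csv").open() as fh:
        df = pd.read_csv(fh, dtype={"cultivar": str})
    for col in ("temperature_c", "rh_pct", "duration_d"):
        df[col] = df[col].astype(float)
    return df


def reference_trait_mfv_long() -> pd.DataFrame:
    """The same table melted to long form (cultivar, factors, trait, mfv)."""
    df = load_reference_mfv()
    long = df.melt(
        id_vars=["cultivar", "temperature_c", "rh_pct", "duration_d"],
        value_vars=["mfv_grain_weight", "mfv_head_rice_rate", "mfv_chalkiness"],
        var_name="trait",
        value_name="mfv",
    )
    long["trait"] = long["trait"].str.removeprefix("mfv_")
    return long
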