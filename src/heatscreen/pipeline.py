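"""End-to-end orchestration: simulate/load -> score -> ANOVA -> regression.

``run_pipeline`` takes a :class:`RunConfig` pointing either at a trial CSV or
at a generator configuration, runs every stage, and writes diff-able CSV/JSON
outputs plus a manifest into the output directory. All numerical output is
full precision; presentation rounding happens only in the Markdown summary.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .anova import anova_by_group, lsd_with_control
from .errors import ConfigError
from .regression import fit_all_traits
from .scoring import rank_cultivars, score_trial, screening_discrimination
from .simulate import GeneratorConfig, config_to_yaml, generate_trial
from .trial import Trial, read_trial_table, write_trial_table

log = logging.getLogger("heatscreen")


@dataclass
class RunConfig:
    """Everything one pipeline run needs."""

    out_dir: str | Path
    input_path: str | Path | None = None
    generator: GeneratorConfig | None = None
    seed: int = 0
    alpha: float = 0.05
    pool_includes_control: bool = False
    regression_granularity: str = "replicate"
    include_control_in_letters: bool = True

    def validate(self):
        if (self.input_path is None) == (self.generator is None):
            raise ConfigError(
                "exactly one of input_path or generator must be provided"
            )
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must lie in (0, 1)")


def _config_hash(config: RunConfig) -> str:
    doc = {
        "seed": config.seed,
        "alpha": config.alpha,
        "pool_includes_control": config.pool_includes_control,
        "regression_granularity": config.regression_granularity,
        "include_control_in_letters": config.include_control_in_letters,
        "input_path": str(config.input_path) if config.input_path else None,
        "generator": _generator_doc(config.generator),
    }
    return hashlib.sha256(
        json.dumps(doc, sort_keys=True).encode()
    ).hexdigest()[:16]


def _generator_doc(gen: GeneratorConfig | None):
    if gen is None:
        return None
    doc = dataclasses.asdict(gen)
    doc["cultivars"] = [
        {"name": p.name, "baselines": dict(p.baselines), "tolerance": p.tolerance}
        for p in gen.cultivars
    ]
    return doc


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write the report bundle; returns it in memory."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.generator is not None:
        log.info("simulating trial (seed=%d)", config.seed)
        trial = generate_trial(config.generator, seed=config.seed)
        write_trial_table(trial, out / "trial.csv")
        config_to_yaml(config.generator, out / "generator.yaml")
    else:
        log.info("reading trial from %s", config.input_path)
        trial = read_trial_table(config.input_path)
    if not trial.balance.balanced:
        log.warning(
            "trial is unbalanced in %d cells; scoring proceeds, ANOVA will refuse",
            len(trial.balance.offending_cells),
        )

    scores = score_trial(trial, pool_includes_control=config.pool_includes_control)
    ranking = rank_cultivars(scores)
    discrimination = screening_discrimination(scores)
    scores.scores.to_csv(out / "scores.csv", index=False)
    scores.treatment_means.to_csv(out / "treatment_means.csv", index=False)
    ranking.to_csv(out / "ranking.csv", index=False)
    discrimination.to_csv(out / "discrimination.csv", index=False)

    anova = anova_by_group(trial)
    anova.to_csv(out / "anova.csv", index=False)

    letter_rows = []
    for cultivar in trial.design.cultivars:
        for trait in trial.design.traits:
            grouping = lsd_with_control(
                trial, cultivar, trait, alpha=config.alpha,
                include_control=config.include_control_in_letters,
            )
            for group, mean in grouping.means.items():
                letter_rows.append(
                    {
                        "cultivar": cultivar,
                        "trait": trait,
                        "group": group,
                        "mean": mean,
                        "letters": grouping.letters[group],
                        "lsd": grouping.lsd,
                    }
                )
    letters = pd.DataFrame(letter_rows)
    letters.to_csv(out / "letters.csv", index=False)

    fits = fit_all_traits(trial, granularity=config.regression_granularity)
    regression_doc = {}
    for trait, fit in fits.items():
        regression_doc[trait] = {
            "terms": list(fit.terms),
            "coefficients": fit.params.to_dict(),
            "se": fit.bse.to_dict(),
            "t": fit.tvalues.to_dict(),
            "p": fit.pvalues.to_dict(),
            "aic": fit.aic,
            "r_squared": fit.r_squared,
            "adj_r_squared": fit.adj_r_squared,
            "f_value": fit.f_value,
            "f_pvalue": fit.f_pvalue,
            "nobs": fit.nobs,
            "trace": [[t, a] for t, a in fit.trace],
        }
    (out / "regression.json").write_text(json.dumps(regression_doc, indent=2))

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "n_cultivars": len(trial.design.cultivars),
        "n_treatments": len(trial.design.treatments),
        "n_replicates": trial.design.n_replicates,
        "balanced": trial.balance.balanced,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    _write_summary(out, ranking, discrimination, regression_doc)

    return {
        "trial": trial,
        "scores": scores,
        "ranking": ranking,
        "discrimination": discrimination,
        "anova": anova,
        "letters": letters,
        "regression": fits,
        "manifest": manifest,
    }


def _write_summary(out: Path, ranking, discrimination, regression_doc) -> None:
    lines = ["# Heat-tolerance screening summary", "", "## Cultivar ranking", ""]
    for row in ranking.itertuples():
        lines.append(f"{row.rank}. {row.cultivar}: mean MFV {row.mean_mfv:.2f}")
    best = discrimination[discrimination["best"]]
    lines += ["", "## Most discriminating screening treatment", ""]
    for row in best.itertuples():
        lines.append(
            f"- {row.temperature_c:g} degC x RH{row.rh_pct:g}% x "
            f"{row.duration_d:g} d (spread {row.spread:.2f})"
        )
    lines += ["", "## Regression (backward-AIC final models)", ""]
    for trait, doc in regression_doc.items():
        lines.append(
            f"- {trait}: terms {', '.join(doc['terms'])}; "
            f"R^2 = {doc['r_squared']:.4f}, F = {doc['f_value']:.2f}"
        )
    (out / "summary.md").write_text("\n".join(lines) + "\n")
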