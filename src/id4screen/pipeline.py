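"""Config-driven orchestration of the full in-silico analysis chain.

Stage order mirrors the analysis narrative: expression group comparisons,
median-dichotomized survival, the promoter-methylation correlation panel, and
the stratified association screen with its Venn partition.  Stages are
isolated: a failing stage is recorded in the run manifest and the remaining
stages still run.  The manifest (config echo, seed, versions, per-stage row
counts and status) is the reproducibility record of a run; it contains no
timestamps, so two runs of the same config are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import pathlib
import time
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
import scipy
import yaml

from . import __version__
from .assoc_screen import run_screen, venn_partition
from .cohort_io import (
    Cohort,
    harmonize_cohort,
    read_clinical_table,
    read_expression_matrix,
    read_methylation_matrix,
    write_results_table,
)
from .errors import ValidationError
from .group_stats import bonferroni_adjust, one_way_anova, probe_correlation_panel, student_t_test
from .panel import PANEL_66, read_panel_file
from .survival import stratified_survival_analysis
from .synthetic_cohort import SyntheticConfig, generate_cohort

logger = logging.getLogger(__name__)

STAGES = ("expression_groups", "survival", "methylation_correlation",
          "association_screen")

_INPUT_KEYS = ("expression", "methylation", "annotation", "clinical")


@dataclass
class AnalysisConfig:
    """Flat run configuration; exactly one of input paths / simulate."""

    expression: str | None = None
    methylation: str | None = None
    annotation: str | None = None
    clinical: str | None = None
    simulate: bool = False
    target_gene: str = "ID4"
    panel_file: str | None = None
    stratum_variable: str = "er_status"
    screen_quantile: float = 0.5
    screen_mode: str = "jacobi_position"
    output_dir: str = "id4screen_out"
    seed: int = 0
    log_level: str = "INFO"
    clinical_column_map: dict[str, Any] = field(default_factory=dict)

    def validate(self) -> None:
        has_inputs = any(getattr(self, k) for k in _INPUT_KEYS)
        if self.simulate and has_inputs:
            raise ValidationError(
                "config must provide either input paths or simulate, not both"
            )
        if not self.simulate and not all(
            getattr(self, k) for k in _INPUT_KEYS
        ):
            raise ValidationError(
                "config must provide all four input paths or set simulate: true"
            )


def load_config(path: str | pathlib.Path) -> AnalysisConfig:
    """Load an AnalysisConfig from a flat, commented YAML key-value file."""
    raw = yaml.safe_load(pathlib.Path(path).read_text()) or {}
    known = {f.name for f in dataclasses.fields(AnalysisConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    config = AnalysisConfig(**raw)
    config.validate()
    return config


def _load_cohort(config: AnalysisConfig) -> Cohort:
    if config.simulate:
        cohort, _ = generate_cohort(SyntheticConfig(seed=config.seed))
        return cohort
    expr = read_expression_matrix(config.expression)
    meth = read_methylation_matrix(config.methylation, config.annotation)
    clin = read_clinical_table(config.clinical, config.clinical_column_map)
    return harmonize_cohort(expr, meth, clin)


def _stage_expression_groups(cohort: Cohort, config: AnalysisConfig) -> pd.DataFrame:
    """Target expression by stratum (t-test) and PAM50 subtype (ANOVA + posthoc)."""
    expr = cohort.expression.values
    clin = cohort.clinical.data
    target = expr.loc[config.target_gene]
    rows = []
    strata = sorted(
        s for s in clin[config.stratum_variable].unique() if s != "unknown"
    )
    if len(strata) == 2:
        a, b = strata
        cmp_t = student_t_test(
            target[clin[config.stratum_variable] == a],
            target[clin[config.stratum_variable] == b],
            labels=(a, b),
        )
        rows.append(
            {"comparison": f"{a}_vs_{b}", "statistic_name": cmp_t.statistic_name,
             "statistic": cmp_t.statistic, "p_value": cmp_t.p_value,
             "p_adjusted": np.nan}
        )
    subtypes = clin["pam50"]
    usable = subtypes[subtypes != "unknown"]
    counts = usable.value_counts()
    levels = sorted(counts.index[counts >= 2])
    if len(levels) >= 2:
        keep = subtypes.isin(levels)
        anova = one_way_anova(target[keep], subtypes[keep])
        rows.append(
            {"comparison": "pam50_anova", "statistic_name": anova.statistic_name,
             "statistic": anova.statistic, "p_value": anova.p_value,
             "p_adjusted": np.nan}
        )
        pair_rows = []
        for i, a in enumerate(levels):
            for b in levels[i + 1:]:
                cmp_ab = student_t_test(
                    target[subtypes == a], target[subtypes == b], labels=(a, b)
                )
                pair_rows.append(
                    {"comparison": f"pam50_{a}_vs_{b}",
                     "statistic_name": cmp_ab.statistic_name,
                     "statistic": cmp_ab.statistic, "p_value": cmp_ab.p_value}
                )
        adjusted = bonferroni_adjust([r["p_value"] for r in pair_rows])
        for row, p_adj in zip(pair_rows, adjusted):
            row["p_adjusted"] = float(p_adj)
        rows.extend(pair_rows)
    return pd.DataFrame(rows)


def _stage_survival(cohort: Cohort, config: AnalysisConfig,
                    outdir: pathlib.Path) -> pd.DataFrame:
    results = stratified_survival_analysis(
        cohort, config.target_gene, config.stratum_variable
    )
    rows = []
    for res in results:
        row: dict[str, Any] = {"stratum": res.stratum}
        if res.skipped_reason:
            row.update({"status": f"skipped: {res.skipped_reason}"})
        else:
            row.update(
                {
                    "status": "ok",
                    "median_used": res.dichotomy.median_used,
                    "n_high": len(res.dichotomy.arm("high")),
                    "n_low": len(res.dichotomy.arm("low")),
                    "chi_square": res.logrank.chi_square,
                    "p_value": res.logrank.p_value,
                    "observed_high": res.logrank.observed[0],
                    "expected_high": res.logrank.expected[0],
                }
            )
            for arm, km in (("high", res.km_high), ("low", res.km_low)):
                steps = pd.DataFrame(
                    {
                        "time_months": km.event_times,
                        "at_risk": km.at_risk,
                        "events": km.events,
                        "survival": km.survival,
                    }
                )
                write_results_table(
                    steps.to_dict("records"),
                    outdir / f"km_{_slug(res.stratum)}_{arm}.tsv",
                    columns=["time_months", "at_risk", "events", "survival"],
                )
        rows.append(row)
    return pd.DataFrame(rows)


def _stage_methylation(cohort: Cohort, config: AnalysisConfig) -> pd.DataFrame:
    return probe_correlation_panel(
        cohort.methylation, cohort.expression, config.target_gene
    )


def _stage_screen(cohort: Cohort, config: AnalysisConfig,
                  outdir: pathlib.Path) -> pd.DataFrame:
    panel = (read_panel_file(config.panel_file) if config.panel_file
             else list(PANEL_66))
    results = run_screen(
        cohort, config.target_gene, panel,
        stratum_variable=config.stratum_variable,
        selection_quantile=config.screen_quantile,
        mode=config.screen_mode,
    )
    strata = sorted({r.stratum for r in results})
    if len(strata) == 2:
        part = venn_partition(
            [r for r in results if r.stratum == strata[0]],
            [r for r in results if r.stratum == strata[1]],
        )
        venn_rows = [
            {"set": f"only_{strata[0]}", "genes": ",".join(sorted(part.only_a))},
            {"set": f"only_{strata[1]}", "genes": ",".join(sorted(part.only_b))},
            {"set": "shared", "genes": ",".join(sorted(part.shared))},
        ]
        write_results_table(venn_rows, outdir / "venn_partition.tsv",
                            columns=["set", "genes"])
    frame = pd.DataFrame([dataclasses.asdict(r) for r in results])
    return frame.sort_values(["stratum", "gene"], kind="stable")


def _slug(text: str) -> str:
    return text.replace("+", "pos").replace("-", "neg").replace(" ", "_")


def run_analysis(config: AnalysisConfig) -> dict[str, Any]:
    """Execute all stages; returns the manifest (also written to disk)."""
    config.validate()
    logging.basicConfig(level=config.log_level)
    outdir = pathlib.Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort = _load_cohort(config)  # unreadable inputs abort before any stage

    manifest: dict[str, Any] = {
        "config": dataclasses.asdict(config),
        "seed": config.seed,
        "versions": {
            "id4screen": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
        "n_samples": len(cohort.sample_ids),
        "dropped": dict(cohort.dropped),
        "stages": {},
    }
    runners = {
        "expression_groups": lambda: _stage_expression_groups(cohort, config),
        "survival": lambda: _stage_survival(cohort, config, outdir),
        "methylation_correlation": lambda: _stage_methylation(cohort, config),
        "association_screen": lambda: _stage_screen(cohort, config, outdir),
    }
    for stage in STAGES:
        start = time.perf_counter()
        try:
            frame = runners[stage]()
            frame.to_csv(outdir / f"{stage}.tsv", sep="\t", index=False,
                         na_rep="NA", float_format="%.17g")
            manifest["stages"][stage] = {"status": "ok", "rows": int(len(frame))}
            logger.info("stage %s: %d rows in %.2fs", stage, len(frame),
                        time.perf_counter() - start)
        except Exception as err:  # stage isolation: record, keep going
            logger.error("stage %s failed: %s", stage, err)
            manifest["stages"][stage] = {"status": f"failed: {err}", "rows": 0}
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest
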