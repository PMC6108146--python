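"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator emulates a TCGA-like breast cohort stratified by ER status:

* the target gene (ID4 by default) is expressed lower in ER+ tumors;
* each panel gene carries a planted Pearson correlation with the target,
  realized exactly in distribution through a shared-latent Gaussian copula
  (gene_j = r_j * T + sqrt(1 - r_j^2) * eps_j on standard-normal margins,
  which is positive semi-definite for any |r_j| < 1);
* promoter 450K probes carry a planted negative beta-vs-expression
  correlation, produced by a logistic squash of a latent Gaussian tied to the
  target (betas stay inside (0, 1); the squash attenuates the attained
  Pearson correlation by ~1%, and the attained value is recorded);
* overall survival is exponential with a stratum-specific hazard ratio
  applied to the strictly-above-median "high" target-expression arm, with
  independent exponential censoring.

Default sizes and effects mirror the TCGA breast cohort the analysis is
aimed at: 601 ER+ / 179 ER- samples, a 66-gene panel with ER+-specific hits
(FOXA1, GATA3, ESR1, CCND1, AKT1, IGF1R at r = -0.326 ... -0.065),
ER--specific hits (VEGFA, JUN, MKI67) and shared hits (CTNNB1, ERBB2, CTSD,
KRT19, MMP2, XBP1), a promoter methylation/expression correlation of -0.4,
and a protective high-expression hazard ratio of 0.5 in ER+ only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .cohort_io import ClinicalTable, Cohort, ExpressionMatrix, MethylationMatrix
from .errors import ValidationError
from .molecular_quant import DEFAULT_DROPLET_VOLUME_NL, DropletCount, MlpaProbeReading
from .panel import PANEL_66
from .survival import dichotomize_by_median

#: ER+-specific target correlations as reported for the TCGA screen.
ERPOS_HITS: Mapping[str, float] = {
    "FOXA1": -0.326, "GATA3": -0.3515, "ESR1": -0.333,
    "CCND1": -0.19, "AKT1": -0.068, "IGF1R": -0.065,
}
#: ER--specific and shared hits; magnitudes not reported, defaulted to the
#: strong end of the ER+ range.
ERNEG_HITS: Mapping[str, float] = {"VEGFA": -0.33, "JUN": -0.33, "MKI67": -0.33}
SHARED_HITS: Mapping[str, float] = {
    "CTNNB1": -0.33, "ERBB2": -0.33, "CTSD": -0.33,
    "KRT19": -0.33, "MMP2": -0.33, "XBP1": -0.33,
}

#: Baseline log2(norm_count+1) expression level around which genes vary.
BASE_EXPRESSION = 8.0
#: Slope of the logistic squash mapping latent N(0,1) values to beta values.
BETA_SQUASH_SCALE = 0.7


def default_planted_correlations() -> dict[tuple[str, str], float]:
    planted: dict[tuple[str, str], float] = {}
    for gene, r in ERPOS_HITS.items():
        planted[("ER+", gene)] = r
    for gene, r in ERNEG_HITS.items():
        planted[("ER-", gene)] = r
    for gene, r in SHARED_HITS.items():
        planted[("ER+", gene)] = r
        planted[("ER-", gene)] = r
    return planted


@dataclass(frozen=True)
class SyntheticConfig:
    """Ground-truth parameters of a generated cohort.

    Rates are per month; ``target_shift`` is the log2 expression offset added
    to the target gene in ER+ samples; ``noise_sd`` scales the marginal SD of
    expression values (the copula is correlation-preserving, so planted
    correlations are unaffected by the scale).
    """

    n_samples_per_stratum: Mapping[str, int] = field(
        default_factory=lambda: {"ER+": 601, "ER-": 179}
    )
    target_gene: str = "ID4"
    panel_genes: tuple[str, ...] = PANEL_66
    planted_correlations: Mapping[tuple[str, str], float] = field(
        default_factory=default_planted_correlations
    )
    target_shift: float = -1.5
    promoter_probe_count: int = 5
    nonpromoter_probe_count: int = 8
    meth_expr_correlation: float = -0.4
    survival_hr_high_vs_low: Mapping[str, float] = field(
        default_factory=lambda: {"ER+": 0.5, "ER-": 1.0}
    )
    baseline_hazard: float = 0.01
    censoring_rate: float = 0.01
    noise_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if len(self.n_samples_per_stratum) < 2:
            raise ValidationError("need at least 2 strata")
        for stratum, n in self.n_samples_per_stratum.items():
            if n < 4:
                raise ValidationError(f"stratum {stratum!r} needs n >= 4, got {n}")
        if self.target_gene in self.panel_genes:
            raise ValidationError("target gene must not be part of the panel")
        for (stratum, gene), r in self.planted_correlations.items():
            if not -1.0 < r < 1.0:
                raise ValidationError(
                    f"planted correlation for ({stratum}, {gene}) is {r}; the "
                    "implied correlation matrix is not positive definite - "
                    "choose values strictly inside (-1, 1)"
                )
            if gene not in self.panel_genes:
                raise ValidationError(f"planted gene {gene!r} not in panel")
        if not -1.0 < self.meth_expr_correlation <= 0.0:
            raise ValidationError("meth_expr_correlation must lie in (-1, 0]")
        for stratum, hr in self.survival_hr_high_vs_low.items():
            if hr <= 0:
                raise ValidationError(f"hazard ratio for {stratum!r} must be > 0")
        if self.baseline_hazard <= 0 or self.censoring_rate <= 0:
            raise ValidationError("hazard and censoring rates must be > 0")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be > 0")


@dataclass(frozen=True)
class PlantedStructure:
    """Realized ground truth, the oracle for recovery tests."""

    selected_by_stratum: dict[str, frozenset[str]]
    correlations: dict[tuple[str, str], float]
    attained_promoter_correlations: dict[str, float]
    hazard_ratios: dict[str, float]
    high_samples_by_stratum: dict[str, frozenset[str]]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def generate_cohort(config: SyntheticConfig) -> tuple[Cohort, PlantedStructure]:
    """Draw a cohort realizing ``config``; bit-reproducible from its seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    strata = list(config.n_samples_per_stratum)

    sample_ids: list[str] = []
    er_status: list[str] = []
    offset = 0
    per_stratum_samples: dict[str, list[str]] = {}
    frames = []
    for stratum in strata:
        n = config.n_samples_per_stratum[stratum]
        ids = [f"S{offset + i:05d}" for i in range(n)]
        offset += n
        per_stratum_samples[stratum] = ids
        sample_ids.extend(ids)
        er_status.extend([stratum] * n)

        t = rng.standard_normal(n)  # latent target, N(0,1)
        shift = config.target_shift if stratum == "ER+" else 0.0
        block = {config.target_gene: BASE_EXPRESSION + shift + config.noise_sd * t}
        for gene in config.panel_genes:
            r = config.planted_correlations.get((stratum, gene), 0.0)
            eps = rng.standard_normal(n)
            latent = r * t + np.sqrt(1.0 - r * r) * eps
            block[gene] = BASE_EXPRESSION + config.noise_sd * latent
        frames.append(pd.DataFrame(block, index=ids).T)
    expr = pd.concat(frames, axis=1)
    expression = ExpressionMatrix(expr)

    # methylation: promoter probes tied to the pooled *observed* target
    # expression (z-scored): tying them to the pre-shift latent instead would
    # attenuate the realized beta-vs-expression correlation by the variance
    # the ER+ shift adds
    target_expr = expr.loc[config.target_gene].to_numpy(dtype=float)
    t_all = (target_expr - target_expr.mean()) / target_expr.std()
    n_total = t_all.size
    rho = config.meth_expr_correlation
    probe_rows = {}
    annotation_rows = []
    attained: dict[str, float] = {}
    n_probes = config.promoter_probe_count + config.nonpromoter_probe_count
    centers = np.linspace(-0.5, 0.5, n_probes)
    for k in range(n_probes):
        promoter = k < config.promoter_probe_count
        probe = f"cg{k + 1:08d}"
        eps = rng.standard_normal(n_total)
        if promoter:
            latent = rho * t_all + np.sqrt(1.0 - rho * rho) * eps
        else:
            latent = eps
        betas = _sigmoid(BETA_SQUASH_SCALE * latent + centers[k])
        probe_rows[probe] = betas
        annotation_rows.append(
            {"probe": probe, "position": f"chr6:1983{7000 + 100 * k}",
             "promoter": promoter}
        )
        if promoter:
            attained[probe] = float(np.corrcoef(betas, t_all)[0, 1])
    betas_df = pd.DataFrame(probe_rows, index=sample_ids).T
    annotation = pd.DataFrame(annotation_rows).set_index("probe")
    methylation = MethylationMatrix(betas_df, annotation)

    # clinical: PAM50 composition by receptor status, survival per stratum
    pam50 = np.empty(n_total, dtype=object)
    os_months = np.empty(n_total, dtype=float)
    os_event = np.empty(n_total, dtype=object)
    high_by_stratum: dict[str, frozenset[str]] = {}
    pos = {s: i for i, s in enumerate(sample_ids)}
    for stratum in strata:
        ids = per_stratum_samples[stratum]
        idx = np.array([pos[s] for s in ids])
        if stratum == "ER+":
            pam50[idx] = rng.choice(["LumA", "LumB", "Her2"], size=len(ids),
                                    p=[0.65, 0.28, 0.07])
        else:
            pam50[idx] = rng.choice(["Basal", "Normal", "Her2"], size=len(ids),
                                    p=[0.55, 0.35, 0.10])
        target_vals = {s: float(expr.loc[config.target_gene, s]) for s in ids}
        labels = dichotomize_by_median(target_vals)
        high = frozenset(labels.arm("high"))
        high_by_stratum[stratum] = high
        hr = config.survival_hr_high_vs_low.get(stratum, 1.0)
        for s in ids:
            hazard = config.baseline_hazard * (hr if s in high else 1.0)
            event_time = rng.exponential(1.0 / hazard)
            censor_time = rng.exponential(1.0 / config.censoring_rate)
            i = pos[s]
            os_months[i] = min(event_time, censor_time)
            os_event[i] = bool(event_time <= censor_time)
    clinical = ClinicalTable(
        pd.DataFrame(
            {
                "er_status": er_status,
                "pam50": pam50,
                "os_months": os_months,
                "os_event": os_event,
            },
            index=pd.Index(sample_ids, name="sample_id"),
        )
    )

    truth = PlantedStructure(
        selected_by_stratum={
            stratum: frozenset(
                g for (s, g), r in config.planted_correlations.items()
                if s == stratum and r != 0.0
            )
            for stratum in strata
        },
        correlations=dict(config.planted_correlations),
        attained_promoter_correlations=attained,
        hazard_ratios={
            s: config.survival_hr_high_vs_low.get(s, 1.0) for s in strata
        },
        high_samples_by_stratum=high_by_stratum,
    )
    cohort = Cohort(expression=expression, methylation=methylation,
                    clinical=clinical, dropped={})
    return cohort, truth


def generate_droplet_readout(
    lambda_per_droplet: float,
    n_droplets: int,
    seed: int | np.random.Generator,
    droplet_volume_nl: float = DEFAULT_DROPLET_VOLUME_NL,
) -> DropletCount:
    """Simulate a ddPCR well: positives ~ Binomial(n, 1 - exp(-lambda))."""
    if lambda_per_droplet < 0:
        raise ValidationError("lambda must be >= 0")
    if n_droplets < 1:
        raise ValidationError("need >= 1 droplet")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    p = -np.expm1(-lambda_per_droplet)
    positives = int(rng.binomial(n_droplets, p))
    return DropletCount(n_total=n_droplets, n_positive=positives,
                        droplet_volume_nl=droplet_volume_nl)


def generate_mlpa_readout(
    true_methylated_fraction: float,
    reference_signal: float,
    noise_cv: float,
    seed: int | np.random.Generator,
) -> MlpaProbeReading:
    """Simulate the four MS-MLPA peak signals for one target probe.

    The digested target signal is the methylated fraction of the undigested
    one; every signal carries multiplicative lognormal noise with coefficient
    of variation ``noise_cv`` (mean-one noise, sigma^2 = ln(1 + cv^2)).
    """
    if not 0.0 <= true_methylated_fraction <= 1.0:
        raise ValidationError("methylated fraction must lie in [0, 1]")
    if reference_signal <= 0:
        raise ValidationError("reference signal must be positive")
    if noise_cv < 0:
        raise ValidationError("noise_cv must be >= 0")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    sigma2 = np.log1p(noise_cv**2)

    def _noise() -> float:
        if noise_cv == 0.0:
            return 1.0
        return float(rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2)))

    target_undigested = reference_signal * _noise()
    return MlpaProbeReading(
        target_digested=true_methylated_fraction * target_undigested * _noise(),
        target_undigested=target_undigested,
        reference_digested=reference_signal * _noise(),
        reference_undigested=reference_signal * _noise(),
    )


def with_seed(config: SyntheticConfig, seed: int) -> SyntheticConfig:
    """A copy of ``config`` with a different seed (convenience for sweeps)."""
    return replace(config, seed=seed)
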