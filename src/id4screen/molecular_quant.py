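"""Quantification math for droplet digital PCR/MSP and MS-MLPA assays.

Droplet digital PCR partitions a reaction into ~20,000 droplets; template
molecules land in droplets as a Poisson process, so the fraction of positive
droplets p relates to the mean occupancy by lambda = -ln(1 - p).  Dividing by
the droplet volume converts occupancy to concentration (copies per microliter
of reaction).  MS-MLPA infers methylation from the dosage ratio of a target
probe's signal after methylation-sensitive digestion, normalized by an
undigested aliquot and reference probes; a site is called methylated when the
ratio exceeds a cutoff (default 8%, strict).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from statsmodels.stats.proportion import proportion_confint

from .errors import UndefinedRatioError, ValidationError

#: De-facto droplet volume of the QX200 system, nanoliters.
DEFAULT_DROPLET_VOLUME_NL = 0.85


@dataclass(frozen=True)
class DropletCount:
    n_total: int
    n_positive: int
    droplet_volume_nl: float = DEFAULT_DROPLET_VOLUME_NL

    def __post_init__(self) -> None:
        if self.n_total < 1:
            raise ValidationError("n_total must be >= 1")
        if not 0 <= self.n_positive <= self.n_total:
            raise ValidationError(
                f"n_positive {self.n_positive} outside [0, {self.n_total}]"
            )
        if self.droplet_volume_nl <= 0:
            raise ValidationError("droplet volume must be positive")


@dataclass(frozen=True)
class QuantResult:
    lambda_per_droplet: float
    copies_per_ul: float
    ci95_low: float
    ci95_high: float
    saturated: bool = False


@dataclass(frozen=True)
class MlpaProbeReading:
    target_digested: float
    target_undigested: float
    reference_digested: float
    reference_undigested: float

    def __post_init__(self) -> None:
        for name in ("target_digested", "target_undigested",
                     "reference_digested", "reference_undigested"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} is negative")


def poisson_concentration(count: DropletCount) -> QuantResult:
    """Poisson-corrected concentration from a droplet count.

    lambda = -ln(1 - p_hat) copies per droplet; copies/uL divides by the
    droplet volume.  The 95% CI propagates the binomial Wilson interval on
    p_hat through the same transform.  All-negative wells return an all-zero
    result; all-positive (saturated) wells return a flagged lower bound built
    from (n - 0.5)/n.
    """
    vol_ul = count.droplet_volume_nl * 1e-3
    if count.n_positive == 0:
        return QuantResult(0.0, 0.0, 0.0, 0.0, saturated=False)
    saturated = count.n_positive == count.n_total
    if saturated:
        warnings.warn(
            "all droplets positive: reporting a lower-bound concentration",
            stacklevel=2,
        )
        p_hat = (count.n_total - 0.5) / count.n_total
    else:
        p_hat = count.n_positive / count.n_total
    lam = -np.log1p(-p_hat)
    low, high = proportion_confint(
        count.n_positive, count.n_total, alpha=0.05, method="wilson"
    )
    lam_low = -np.log1p(-min(float(low), p_hat))
    lam_high = np.inf if saturated or high >= 1.0 else -np.log1p(-float(high))
    return QuantResult(
        lambda_per_droplet=float(lam),
        copies_per_ul=float(lam / vol_ul),
        ci95_low=float(lam_low / vol_ul),
        ci95_high=float(lam_high / vol_ul),
        saturated=saturated,
    )


def combine_replicates(results: list[QuantResult]) -> float:
    """Mean concentration over technical replicates (copies per microliter)."""
    if not results:
        raise ValidationError("no replicates to combine")
    return float(np.mean([r.copies_per_ul for r in results]))


def methylation_ratio(methylated: QuantResult, unmethylated: QuantResult) -> float:
    """Methylated/unmethylated concentration ratio from two parallel assays."""
    if unmethylated.copies_per_ul == 0.0:
        raise UndefinedRatioError(
            "unmethylated assay has zero concentration; ratio undefined"
        )
    return methylated.copies_per_ul / unmethylated.copies_per_ul


def mlpa_dosage_ratio(reading: MlpaProbeReading) -> float:
    """Reference-normalized digested/undigested dosage ratio.

    ratio = (target_digested / reference_digested)
          / (target_undigested / reference_undigested), clipped at 0.
    """
    if (reading.target_undigested <= 0 or reading.reference_undigested <= 0
            or reading.reference_digested <= 0):
        raise UndefinedRatioError(
            "undigested and reference-digested signals must be positive"
        )
    ratio = (reading.target_digested / reading.reference_digested) / (
        reading.target_undigested / reading.reference_undigested
    )
    return max(0.0, ratio)


def mean_reference_reading(
    target_digested: float,
    target_undigested: float,
    reference_digested,
    reference_undigested,
) -> MlpaProbeReading:
    """Collapse several reference probes to their mean signal per aliquot."""
    return MlpaProbeReading(
        target_digested=float(target_digested),
        target_undigested=float(target_undigested),
        reference_digested=float(np.mean(np.asarray(reference_digested, float))),
        reference_undigested=float(np.mean(np.asarray(reference_undigested, float))),
    )


def mlpa_call(ratio: float, cutoff: float = 0.08) -> bool:
    """Methylation call: True iff the dosage ratio strictly exceeds the cutoff."""
    if ratio < 0:
        raise ValidationError("dosage ratio must be nonnegative")
    return ratio > cutoff
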