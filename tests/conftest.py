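import numpy as np
import pandas as pd
import pytest

from id4screen import (
    ClinicalTable,
    Cohort,
    ExpressionMatrix,
    MethylationMatrix,
    SyntheticConfig,
    generate_cohort,
)


def make_expression(genes, samples, values) -> ExpressionMatrix:
    return ExpressionMatrix(
        pd.DataFrame(np.asarray(values, dtype=float), index=genes, columns=samples)
    )


def make_methylation(probes, samples, betas, promoter=None) -> MethylationMatrix:
    promoter = promoter if promoter is not None else [True] * len(probes)
    ann = pd.DataFrame(
        {"position": [f"chr6:{i}" for i in range(len(probes))],
         "promoter": promoter},
        index=probes,
    )
    return MethylationMatrix(
        pd.DataFrame(np.asarray(betas, dtype=float), index=probes, columns=samples),
        ann,
    )


def make_clinical(sample_ids, er, pam50=None, months=None, events=None) -> ClinicalTable:
    n = len(sample_ids)
    return ClinicalTable(
        pd.DataFrame(
            {
                "er_status": er,
                "pam50": pam50 or ["LumA"] * n,
                "os_months": months if months is not None else [12.0] * n,
                "os_event": events if events is not None else [True] * n,
            },
            index=pd.Index(sample_ids, name="sample_id"),
        )
    )


@pytest.fixture(scope="session")
def default_cohort():
    """One realization of the default synthetic cohort (TCGA-like sizes)."""
    return generate_cohort(SyntheticConfig(seed=20260924))


@pytest.fixture
def tiny_cohort() -> Cohort:
    """Hand-built 8-sample cohort with two strata, for plumbing tests."""
    samples = [f"S{i}" for i in range(8)]
    rng = np.random.default_rng(7)
    expr = make_expression(
        ["ID4", "G1", "G2"], samples, rng.normal(8, 1, size=(3, 8))
    )
    meth = make_methylation(
        ["cg1", "cg2"], samples, rng.uniform(0.1, 0.9, size=(2, 8)),
        promoter=[True, False],
    )
    clin = make_clinical(
        samples,
        ["ER+"] * 4 + ["ER-"] * 4,
        pam50=["LumA", "LumB", "LumA", "LumB", "Basal", "Basal", "Normal", "Normal"],
        months=list(rng.uniform(5, 80, size=8)),
        events=[True, False, True, True, False, True, True, False],
    )
    return Cohort(expression=expr, methylation=meth, clinical=clin)
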