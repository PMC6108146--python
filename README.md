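# id4screen

Toolkit for asking whether a gene that is epigenetically silenced in one
molecular subtype of breast cancer behaves differently across subtypes — the
motivating case being **ID4**, a dominant-negative bHLH regulator that is
promoter-hypermethylated and downregulated in estrogen-receptor-positive
(ER+) tumors but not in ER− ones.  The package covers the complete in-silico
chain on a harmonized expression / 450K-methylation / clinical cohort
(TCGA-style TSV matrices), plus the quantification math for the wet-lab
readouts (droplet digital PCR/MSP and MS-MLPA), and a synthetic-cohort
generator with planted ground truth so every stage is testable without
external downloads.

Intended users: computational biologists reproducing or extending
ER-stratified target-gene analyses, and anyone needing clean, tested
implementations of the individual pieces.

## What it computes

**SVD association screen** (`assoc_screen`).  For a target gene *t* and each
panel gene *g*, both standardized to mean 0 and unit norm, the two-column
system [*t* *g*] is orthogonalized by a single one-sided Jacobi rotation that
leaves the singular values *unsorted*, preserving the column↔gene
correspondence.  The score read from the gene's column is

    s(g) = sqrt(1 − r),   r = Pearson correlation(t, g),

so strong negative correlates of the target rank highest (the pair's singular
values are {√(1+r), √(1−r)}).  A sign-agnostic mode √(1+|r|) is available.
Per stratum (ER+ / ER−), genes strictly above a quantile of the stratum's
score distribution (default: the median) are selected, and the two strata are
combined into a Venn partition (ER+-only / ER−-only / shared).

**Methylation–expression correlation** (`group_stats`).  Per 450K probe,
Pearson r (with t-test p) between beta values and target expression, promoter
probes flagged.  Also: pooled-variance Student's t, one-way ANOVA with
Bonferroni post-hoc, and a Wilcoxon rank-sum test with exact enumeration for
small samples and a tie- and continuity-corrected normal approximation
otherwise.

**Survival** (`survival`).  Within each stratum, expression is dichotomized
at the sample median (strictly greater ⇒ "high"), Kaplan–Meier product-limit
curves are fitted per arm, and arms are compared with the standard two-group
log-rank test, Ŝ(t) = Π_{tᵢ≤t} (1 − dᵢ/nᵢ) and χ² = (O−E)²/V from the
hypergeometric 2×2 table at each event time.

**Molecular quantification** (`molecular_quant`).  ddPCR Poisson correction
λ = −ln(1 − p̂) with Wilson-interval CIs and copies/µL = λ / droplet volume;
methylated/unmethylated concentration ratios for ddMSP; MS-MLPA dosage ratio
(target_digested/reference_digested) / (target_undigested/reference_undigested)
with a strict 8% methylation-call cutoff.

**Synthetic cohorts** (`synthetic_cohort`).  Gaussian-copula expression with
planted per-stratum target–gene correlations, promoter betas squashed from a
latent Gaussian tied to target expression, exponential survival with a
stratum-specific hazard ratio on the high-expression arm, exponential
censoring; the realized ground truth is returned for recovery testing.

## Worked example

```python
from id4screen import (SyntheticConfig, generate_cohort, run_screen,
                       venn_partition, stratified_survival_analysis,
                       DropletCount, poisson_concentration)
from id4screen.panel import PANEL_66

cohort, truth = generate_cohort(SyntheticConfig(seed=1))   # 780 samples
results = run_screen(cohort, "ID4", PANEL_66,
                     selection_quantile=0.83, mode="abs_correlation")
part = venn_partition([r for r in results if r.stratum == "ER+"],
                      [r for r in results if r.stratum == "ER-"])
print(sorted(part.only_a))
print(sorted(part.shared))
for s in stratified_survival_analysis(cohort, "ID4"):
    print(s.stratum, f"chi2={s.logrank.chi_square:.2f}",
          f"p={s.logrank.p_value:.2e}")
q = poisson_concentration(DropletCount(20000, 11000, 0.85))
print(f"{q.copies_per_ul:.1f} copies/uL [{q.ci95_low:.1f}, {q.ci95_high:.1f}]")
```

prints

```
['AKT1', 'BCL2', 'CCND1', 'ESR1', 'FOXA1', 'GATA3']
['CTNNB1', 'CTSD', 'ERBB2', 'KRT19', 'MMP2', 'XBP1']
ER+ chi2=43.66 p=3.90e-11
ER- chi2=0.12 p=7.28e-01
939.4 copies/uL [921.5, 957.6]
```

The ER+-only set recovers the planted ER-pathway hits (FOXA1, GATA3, ESR1,
CCND1, AKT1; the weakly planted IGF1R at r = −0.065 falls below the selection
threshold in this realization, and one null gene, BCL2, is picked up in its
place — the screen is a ranking, not a hypothesis test).  The shared set is
recovered exactly.  Survival shows the planted protective effect of high
target expression in ER+ (p ≈ 4e-11) and nothing in ER− (p = 0.73).  The
ddPCR line converts 11,000 positive of 20,000 droplets into a
Poisson-corrected concentration with its 95% CI.

The same functionality is exposed on the command line:
`id4screen simulate | screen | compare | probes | ddquant | ddmsp | mlpa |
survival | analyze` (see `id4screen --help`; `analyze --config run.yaml`
drives the whole pipeline and writes per-stage TSVs plus a deterministic run
manifest).

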