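"""Recovery experiments and independent reference oracles.

These routines validate the toolkit end to end on synthetic data: they
re-derive each quantity through an independent route (closed forms, exact
rational arithmetic, full SVDs, scipy reference tests) and measure how well
the package implementations and estimators recover planted ground truth.
They are exercised by the test suite and by the reproduction script.

All seeds are threaded explicitly; replicate ``i`` of an experiment with base
seed ``s`` uses seed ``s + i``.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np
from scipy import stats

from .assoc_screen import selected_genes, standardize, svd_assoc_score
from .group_stats import one_way_anova, student_t_test, wilcoxon_rank_sum
from .molecular_quant import poisson_concentration
from .panel import PANEL_66
from .survival import km_estimate, logrank_test, stratified_survival_analysis
from .synthetic_cohort import (
    ERNEG_HITS,
    ERPOS_HITS,
    SHARED_HITS,
    SyntheticConfig,
    generate_cohort,
    generate_droplet_readout,
)


# ---------------------------------------------------------------------------
# independent oracles


def brute_force_pearson(x, y) -> float:
    """Double-loop covariance Pearson r; no shared code with the vector path."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sxx = syy = 0.0
    for xi, yi in zip(x, y):
        sxy += (xi - mx) * (yi - my)
        sxx += (xi - mx) ** 2
        syy += (yi - my) ** 2
    return sxy / (sxx * syy) ** 0.5


def logrank_chi2_oracle(ta, ea, tb, eb) -> float:
    """Log-rank chi-square via exact Fractions over explicit 2x2 tables."""
    events = sorted({t for t, e in zip(ta, ea) if e}
                    | {t for t, e in zip(tb, eb) if e})
    obs = exp = var = Fraction(0)
    for u in events:
        n_a = sum(1 for t in ta if t >= u)
        n_b = sum(1 for t in tb if t >= u)
        d_a = sum(1 for t, e in zip(ta, ea) if e and t == u)
        d_b = sum(1 for t, e in zip(tb, eb) if e and t == u)
        n, d = n_a + n_b, d_a + d_b
        obs += d_a
        exp += Fraction(d * n_a, n)
        if n > 1:
            var += Fraction(d * n_a * n_b * (n - d), n * n * (n - 1))
    return float((obs - exp) ** 2 / var)


# ---------------------------------------------------------------------------
# experiments


def svd_score_oracle_errors(
    n_pairs: int = 1000, n: int = 50, seed: int = 0
) -> dict[str, float]:
    """Worst-case deviation of the Jacobi score from sqrt(1-r) and from a
    full SVD of the standardized pair matrix, over random pairs."""
    rng = np.random.default_rng(seed)
    max_score_err = 0.0
    max_sv_err = 0.0
    for _ in range(n_pairs):
        x = rng.normal(size=n)
        y = rng.uniform(-0.9, 0.9) * x + rng.normal(size=n)
        score, _ = svd_assoc_score(x, y)
        r = brute_force_pearson(list(x), list(y))
        max_score_err = max(max_score_err, abs(score - np.sqrt(1.0 - r)))
        m = np.column_stack([standardize(x), standardize(y)])
        sv = np.sort(np.linalg.svd(m, compute_uv=False))
        expected = np.sort([np.sqrt(1.0 - r), np.sqrt(1.0 + r)])
        max_sv_err = max(max_sv_err, float(np.abs(sv - expected).max()))
    return {"max_score_error": max_score_err, "max_singular_value_error": max_sv_err}


def recovery_screen_config(n_per_stratum: int = 500, seed: int = 0) -> SyntheticConfig:
    """Screen-recovery condition: 6 ER+-only, 3 ER--only and 6 shared panel
    genes planted at r = -0.4 against an otherwise null 66-gene panel."""
    planted: dict[tuple[str, str], float] = {}
    for gene in ERPOS_HITS:
        planted[("ER+", gene)] = -0.4
    for gene in ERNEG_HITS:
        planted[("ER-", gene)] = -0.4
    for gene in SHARED_HITS:
        planted[("ER+", gene)] = -0.4
        planted[("ER-", gene)] = -0.4
    return SyntheticConfig(
        n_samples_per_stratum={"ER+": n_per_stratum, "ER-": n_per_stratum},
        planted_correlations=planted,
        seed=seed,
    )


#: Selection quantile used in recovery experiments.  The strict above-median
#: rule always selects ~half the panel, so it cannot separate a planted
#: minority from the null bulk; with 9-12 planted genes in a 66-gene panel
#: (14-18%), a 0.83 quantile places the threshold order statistic in the score
#: gap between the null bulk and the planted band.  Fixed by this analysis,
#: not fitted to data.
RECOVERY_QUANTILE = 0.83


def screen_recovery_rates(
    n_seeds: int = 100,
    n_per_stratum: int = 500,
    seed: int = 0,
    quantile: float = RECOVERY_QUANTILE,
) -> dict[str, float]:
    """Micro-averaged sensitivity/specificity of the screen's Venn partition
    against the planted per-stratum gene sets, across replicate cohorts."""
    from .assoc_screen import run_screen

    tp = fn = fp = tn = 0
    for i in range(n_seeds):
        config = recovery_screen_config(n_per_stratum, seed=seed + i)
        cohort, truth = generate_cohort(config)
        results = run_screen(
            cohort, config.target_gene, PANEL_66,
            selection_quantile=quantile, mode="abs_correlation",
        )
        for stratum in ("ER+", "ER-"):
            selected = selected_genes(results, stratum)
            planted = truth.selected_by_stratum[stratum]
            nulls = set(PANEL_66) - planted
            tp += len(selected & planted)
            fn += len(planted - selected)
            fp += len(selected & nulls)
            tn += len(nulls - selected)
    return {
        "sensitivity": tp / (tp + fn),
        "specificity": tn / (tn + fp),
        "n_seeds": n_seeds,
    }


def methylation_recovery(n_total: int = 600, seed: int = 0) -> dict[str, float]:
    """Promoter-probe correlation recovery on one cohort of ``n_total``."""
    config = SyntheticConfig(
        n_samples_per_stratum={"ER+": n_total // 2, "ER-": n_total - n_total // 2},
        seed=seed,
    )
    cohort, _ = generate_cohort(config)
    from .group_stats import probe_correlation_panel

    panel = probe_correlation_panel(cohort.methylation, cohort.expression,
                                    config.target_gene)
    promoter = panel[panel["promoter_flag"]]
    deviations = (promoter["pearson_r"] - config.meth_expr_correlation).abs()
    return {
        "max_abs_deviation": float(deviations.max()),
        "fraction_negative": float((promoter["pearson_r"] < 0).mean()),
        "n_probes": int(len(promoter)),
    }


def logrank_fixture_error() -> float:
    """|implementation - exact-rational oracle| on the hand-checkable fixture."""
    a = ([1.0, 2.0], [True, True])
    b = ([3.0, 4.0], [True, True])
    res = logrank_test(a, b)
    oracle = logrank_chi2_oracle(a[0], a[1], b[0], b[1])
    return abs(res.chi_square - oracle)


def survival_power_rates(
    n_seeds: int = 100, n_per_stratum: int = 300, seed: int = 0
) -> dict[str, float]:
    """Detection rate of the planted ER+-only hazard effect (HR 0.5) and the
    false-rejection rate in the null ER- stratum, at alpha = 0.05."""
    detected = fabricated = 0
    for i in range(n_seeds):
        config = SyntheticConfig(
            n_samples_per_stratum={"ER+": n_per_stratum, "ER-": n_per_stratum},
            panel_genes=("FILLER1",),
            planted_correlations={},
            promoter_probe_count=1,
            nonpromoter_probe_count=0,
            seed=seed + i,
        )
        cohort, _ = generate_cohort(config)
        results = {r.stratum: r for r in
                   stratified_survival_analysis(cohort, config.target_gene)}
        detected += results["ER+"].logrank.p_value < 0.05
        fabricated += results["ER-"].logrank.p_value < 0.05
    return {
        "er_pos_detection_rate": detected / n_seeds,
        "er_neg_rejection_rate": fabricated / n_seeds,
        "n_seeds": n_seeds,
    }


def ddpcr_recovery_rate(
    n_seeds: int = 200,
    true_lambda: float = 1.2,
    n_droplets: int = 20000,
    seed: int = 0,
    tolerance: float = 0.02,
) -> float:
    """Fraction of simulated wells whose Poisson-corrected lambda estimate
    falls within ``tolerance`` (relative) of the true occupancy."""
    hits = 0
    for i in range(n_seeds):
        count = generate_droplet_readout(true_lambda, n_droplets, seed=seed + i)
        est = poisson_concentration(count).lambda_per_droplet
        hits += abs(est - true_lambda) / true_lambda <= tolerance
    return hits / n_seeds


def anova_t_identity_error(n_reps: int = 50, seed: int = 0) -> float:
    """Worst |F - t^2| over random two-group datasets."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_reps):
        x = rng.normal(size=rng.integers(5, 30))
        y = rng.normal(rng.uniform(-1, 1), 1.5, size=rng.integers(5, 30))
        t = student_t_test(x, y).statistic
        f = one_way_anova(
            np.concatenate([x, y]), ["a"] * x.size + ["b"] * y.size
        ).statistic
        worst = max(worst, abs(f - t * t))
    return worst


def wilcoxon_exact_error(seed: int = 0) -> float:
    """Worst |p - scipy exact enumeration| over tie-free samples, n1+n2 <= 10."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for n1 in range(2, 6):
        for n2 in range(2, 6):
            if n1 + n2 > 10:
                continue
            for _ in range(10):
                x = rng.normal(size=n1)
                y = rng.normal(size=n2)
                p = wilcoxon_rank_sum(x, y).p_value
                p_oracle = stats.mannwhitneyu(
                    x, y, method="exact", alternative="two-sided"
                ).pvalue
                worst = max(worst, abs(p - float(p_oracle)))
    return worst


def km_empirical_error(n: int = 57, seed: int = 0) -> float:
    """Worst |KM - empirical survival| with no censoring (they must agree)."""
    rng = np.random.default_rng(seed)
    times = rng.exponential(10, size=n)
    km = km_estimate(times, np.ones(n, dtype=bool))
    worst = 0.0
    for t in np.linspace(0, float(times.max()) * 1.1, 50):
        worst = max(worst, abs(km.survival_at(t) - (times > t).mean()))
    return worst
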