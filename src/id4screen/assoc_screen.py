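"""SVD association screen between a target gene and a candidate gene panel.

The score treats each (target, gene) pair as a two-column linear system.  Both
columns are standardized to mean zero and unit Euclidean norm, and the system
is orthogonalized by a single one-sided Jacobi rotation.  The rotation keeps
the singular values *unsorted*: each post-rotation column norm is a singular
value of the pair matrix, and the norm read from the gene's original column
position is the score for that gene.  For standardized columns the two
singular values are {sqrt(1+r), sqrt(1-r)} with r the Pearson correlation, and
the gene-position value is sqrt(1-r): strong *negative* correlates of the
target score highest.  The sign-agnostic alternative sqrt(1+|r|) is available
as mode ``abs_correlation``.

Per stratum (typically ER+ vs ER-), genes whose score lies strictly above a
quantile of that stratum's score distribution (default: the median) are
selected; the selections from two strata are combined into a Venn partition.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .cohort_io import Cohort
from .errors import DegenerateInputError, ValidationError

logger = logging.getLogger(__name__)

SCORE_MODES = ("jacobi_position", "abs_correlation")


@dataclass(frozen=True)
class AssociationResult:
    gene: str
    stratum: str
    svd_score: float
    pearson_r: float
    pearson_p: float
    n_used: int
    selected: bool


@dataclass(frozen=True)
class VennPartition:
    only_a: frozenset[str]
    only_b: frozenset[str]
    shared: frozenset[str]
    threshold_per_stratum: dict[str, float]


def _finite_pair(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError(f"length mismatch: {x.shape} vs {y.shape}")
    keep = np.isfinite(x) & np.isfinite(y)
    return x[keep], y[keep]


def standardize(values) -> np.ndarray:
    """Center to mean 0 and scale to unit Euclidean norm."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 2:
        raise DegenerateInputError("standardize needs at least 2 finite values")
    if np.ptp(v) == 0:
        raise DegenerateInputError("constant vector cannot be standardized")
    centered = v - v.mean()
    norm = np.linalg.norm(centered)
    if norm == 0.0:
        raise DegenerateInputError("vector has zero variance after centering")
    return centered / norm


def _jacobi_gene_norm(target_std: np.ndarray, gene_std: np.ndarray) -> float:
    """One one-sided Jacobi sweep on [target, gene]; norm of the gene column.

    Rotation angle by the tan(2*theta) = 2c/(a-b) convention with |theta| <=
    pi/4; standardized columns have a = b, which resolves to theta = +pi/4
    (the tie goes to the positive branch so the correspondence between column
    position and variable is kept rather than re-sorted by magnitude).
    """
    m = np.column_stack([target_std, gene_std])
    a = m[:, 0] @ m[:, 0]
    b = m[:, 1] @ m[:, 1]
    c = m[:, 0] @ m[:, 1]
    if abs(a - b) <= 1e-12 * max(a, b, 1.0):
        theta = np.pi / 4.0
    else:
        theta = 0.5 * np.arctan2(2.0 * c, a - b)
    ct, st = np.cos(theta), np.sin(theta)
    rotated = m @ np.array([[ct, -st], [st, ct]])
    return float(np.linalg.norm(rotated[:, 1]))


def svd_assoc_score(
    target, gene, mode: str = "jacobi_position"
) -> tuple[float, float]:
    """Association score of ``gene`` with ``target``; returns (score, r).

    mode ``jacobi_position``: the unsorted-singular-value score sqrt(1-r)
    (computed by actually performing the Jacobi rotation).  mode
    ``abs_correlation``: sqrt(1+|r|), the larger singular value of the pair.
    """
    if mode not in SCORE_MODES:
        raise ValidationError(f"unknown score mode {mode!r}")
    x, y = _finite_pair(target, gene)
    if x.size < 3:
        raise DegenerateInputError(
            f"need >= 3 pairwise-complete observations, got {x.size}"
        )
    xs = standardize(x)
    ys = standardize(y)
    r = float(np.clip(xs @ ys, -1.0, 1.0))
    if mode == "jacobi_position":
        score = _jacobi_gene_norm(xs, ys)
    else:
        score = float(np.sqrt(1.0 + abs(r)))
    return score, r


def pearson_correlation(x, y) -> tuple[float, float, int]:
    """Pearson r with its two-sided t-test p-value on pairwise-complete data."""
    xc, yc = _finite_pair(x, y)
    n = int(xc.size)
    if n < 3:
        raise DegenerateInputError(f"need >= 3 pairwise-complete observations, got {n}")
    if np.ptp(xc) == 0 or np.ptp(yc) == 0:
        raise DegenerateInputError("constant vector in correlation")
    res = stats.pearsonr(xc, yc)
    # perfectly collinear data would give p = 0 exactly; keep p in (0, 1]
    p = float(min(max(res.pvalue, np.finfo(float).tiny), 1.0))
    return float(res.statistic), p, n


def run_screen(
    cohort: Cohort,
    target_gene: str,
    panel,
    stratum_variable: str = "er_status",
    selection_quantile: float = 0.5,
    mode: str = "jacobi_position",
) -> list[AssociationResult]:
    """Score every panel gene against the target within each stratum.

    The per-stratum selection threshold is the ``selection_quantile`` quantile
    of that stratum's scores; a gene is selected iff its score is *strictly*
    greater than the threshold (so with all-equal scores nothing is selected).
    Strata with fewer than 4 samples, and the "unknown" level, are skipped
    with a warning.  Results are ordered by (stratum, gene).
    """
    panel = list(panel)
    expr = cohort.expression.values
    absent = [g for g in [target_gene, *panel] if g not in expr.index]
    if absent:
        raise ValidationError(f"genes absent from expression matrix: {absent}")
    strata = [
        s for s in cohort.clinical.data[stratum_variable].unique() if s != "unknown"
    ]
    if len(strata) < 2:
        raise ValidationError(
            f"need >= 2 stratum levels in {stratum_variable!r}, got {strata}"
        )
    results: list[AssociationResult] = []
    for stratum in sorted(strata):
        members = cohort.clinical.data.index[
            cohort.clinical.data[stratum_variable] == stratum
        ]
        if len(members) < 4:
            warnings.warn(
                f"stratum {stratum!r} has {len(members)} samples (<4); skipped",
                stacklevel=2,
            )
            continue
        target_vals = expr.loc[target_gene, members].to_numpy(dtype=float)
        per_gene: list[tuple[str, float, float, float, int]] = []
        for gene in panel:
            gene_vals = expr.loc[gene, members].to_numpy(dtype=float)
            score, _ = svd_assoc_score(target_vals, gene_vals, mode=mode)
            r, p, n = pearson_correlation(target_vals, gene_vals)
            per_gene.append((gene, score, r, p, n))
        scores = np.array([t[1] for t in per_gene])
        threshold = float(np.quantile(scores, selection_quantile))
        for gene, score, r, p, n in sorted(per_gene):
            results.append(
                AssociationResult(
                    gene=gene, stratum=stratum, svd_score=score,
                    pearson_r=r, pearson_p=p, n_used=n,
                    selected=bool(score > threshold),
                )
            )
    return results


def selected_genes(results: list[AssociationResult], stratum: str) -> frozenset[str]:
    return frozenset(r.gene for r in results if r.stratum == stratum and r.selected)


def screen_threshold(results: list[AssociationResult], stratum: str) -> float:
    """Recover the selection threshold implied by a stratum's result list."""
    scores = np.array([r.svd_score for r in results if r.stratum == stratum])
    unselected = [r.svd_score for r in results if r.stratum == stratum and not r.selected]
    return float(max(unselected)) if unselected else float(scores.min())


def venn_partition(
    results_a: list[AssociationResult], results_b: list[AssociationResult]
) -> VennPartition:
    """Partition the selected genes of two strata into only-A / only-B / shared."""
    genes_a = {r.gene for r in results_a}
    genes_b = {r.gene for r in results_b}
    if genes_a != genes_b:
        raise ValidationError("the two result lists do not cover the same panel")
    strata_a = {r.stratum for r in results_a}
    strata_b = {r.stratum for r in results_b}
    if len(strata_a) != 1 or len(strata_b) != 1:
        raise ValidationError("each result list must come from a single stratum")
    (stratum_a,) = strata_a
    (stratum_b,) = strata_b
    sel_a = frozenset(r.gene for r in results_a if r.selected)
    sel_b = frozenset(r.gene for r in results_b if r.selected)
    return VennPartition(
        only_a=sel_a - sel_b,
        only_b=sel_b - sel_a,
        shared=sel_a & sel_b,
        threshold_per_stratum={
            stratum_a: screen_threshold(results_a, stratum_a),
            stratum_b: screen_threshold(results_b, stratum_b),
        },
    )
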