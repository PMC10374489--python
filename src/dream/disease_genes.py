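"""Disease-relevant gene selection.

Two per-gene tests between disease and control samples:

* a two-sided Wilcoxon rank-sum (Mann-Whitney) test for a shift in
  expression level, exact when ``min(n1, n2) <= 8`` with no ties and by
  normal approximation (midranks, tie correction, continuity correction)
  otherwise;
* a two-sided variance-ratio F-test, ``F = s2_disease / s2_control`` with
  sample variances (denominator n-1), probing expression stability.

P-values are Benjamini-Hochberg adjusted within each test family and genes
are selected at an FDR level ``alpha`` by a configurable combination rule
(default: union of the two tests).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from dream.dataio import ExpressionDataset

EXACT_MAX_GROUP = 8  # exact rank-sum null up to this min group size (no ties)

SelectionMode = Literal["union", "intersection", "location_only", "variance_only"]


@dataclass
class GeneTestResult:
    """Per-gene statistics from the location and variance scans."""

    gene_id: str
    wilcoxon_stat: float = np.nan  # rank sum of the disease group
    wilcoxon_p: float = np.nan
    f_stat: float = np.nan  # s2_disease / s2_control
    f_p: float = np.nan
    wilcoxon_q: float = np.nan
    f_q: float = np.nan
    selected: bool = False
    flags: set[str] = field(default_factory=set)


def _rank_sum_test(disease: np.ndarray, control: np.ndarray) -> tuple[float, float, set[str]]:
    n1 = disease.size
    pooled = np.concatenate([disease, control])
    ranks = stats.rankdata(pooled)
    w = float(ranks[:n1].sum())
    if np.ptp(pooled) == 0.0:
        return w, 1.0, {"constant"}
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(n1, control.size) <= EXACT_MAX_GROUP and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        disease, control, alternative="two-sided", method=method, use_continuity=True
    )
    return w, float(min(res.pvalue, 1.0)), set()


def wilcoxon_scan(ds: ExpressionDataset) -> list[GeneTestResult]:
    """Rank-sum scan of every gene; fills the location fields only.

    A gene constant across all samples gets p = 1 and the ``constant`` flag.
    """
    disease = ds.condition_values("disease")
    control = ds.condition_values("control")
    if disease.shape[1] < 2 or control.shape[1] < 2:
        raise ValueError("need at least 2 samples per condition")
    out = []
    for gene, d_row, c_row in zip(ds.gene_ids, disease, control):
        w, p, flags = _rank_sum_test(d_row, c_row)
        out.append(GeneTestResult(gene_id=gene, wilcoxon_stat=w, wilcoxon_p=p, flags=flags))
    return out


def variance_f_scan(ds: ExpressionDataset) -> list[GeneTestResult]:
    """Variance-ratio scan of every gene; fills the variance fields only.

    Genes with zero variance in either group are flagged ``zero_variance``
    and carry an undefined (NaN) p-value; they are excluded from BH later.
    """
    disease = ds.condition_values("disease")
    control = ds.condition_values("control")
    n1, n2 = disease.shape[1], control.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 samples per condition")
    s1 = disease.var(axis=1, ddof=1)
    s2 = control.var(axis=1, ddof=1)
    out = []
    for gene, v1, v2 in zip(ds.gene_ids, s1, s2):
        if v1 <= 0.0 or v2 <= 0.0:
            out.append(GeneTestResult(gene_id=gene, flags={"zero_variance"}))
            continue
        f = float(v1 / v2)
        p = 2.0 * min(stats.f.cdf(f, n1 - 1, n2 - 1), stats.f.sf(f, n1 - 1, n2 - 1))
        out.append(GeneTestResult(gene_id=gene, f_stat=f, f_p=float(min(p, 1.0))))
    return out


def test_genes(ds: ExpressionDataset) -> list[GeneTestResult]:
    """Run both scans and merge into one result per gene (q-values filled)."""
    loc = wilcoxon_scan(ds)
    var = variance_f_scan(ds)
    merged = []
    for a, b in zip(loc, var):
        merged.append(
            GeneTestResult(
                gene_id=a.gene_id,
                wilcoxon_stat=a.wilcoxon_stat,
                wilcoxon_p=a.wilcoxon_p,
                f_stat=b.f_stat,
                f_p=b.f_p,
                flags=a.flags | b.flags,
            )
        )
    _adjust(merged, "wilcoxon_p", "wilcoxon_q")
    _adjust(merged, "f_p", "f_q")
    return merged


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _adjust(results: list[GeneTestResult], p_attr: str, q_attr: str) -> None:
    idx = [i for i, r in enumerate(results) if np.isfinite(getattr(r, p_attr))]
    if not idx:
        return
    q = bh_adjust([getattr(results[i], p_attr) for i in idx])
    for i, qi in zip(idx, q):
        setattr(results[i], q_attr, float(qi))


def select_genes(
    results: Iterable[GeneTestResult],
    alpha: float = 0.05,
    mode: SelectionMode = "union",
) -> set[str]:
    """Select genes at FDR ``alpha`` by combining the two adjusted tests.

    ``union`` (default) keeps a gene significant in level OR stability;
    ``intersection`` requires both; the ``*_only`` modes use a single test.
    Flagged (NaN-q) tests never count as significant.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    selected = set()
    for r in results:
        w_hit = np.isfinite(r.wilcoxon_q) and r.wilcoxon_q < alpha
        f_hit = np.isfinite(r.f_q) and r.f_q < alpha
        hit = {
            "union": w_hit or f_hit,
            "intersection": w_hit and f_hit,
            "location_only": w_hit,
            "variance_only": f_hit,
        }[mode]
        r.selected = bool(hit)
        if hit:
            selected.add(r.gene_id)
    return selected


def results_to_rows(results: Iterable[GeneTestResult]) -> list[dict]:
    """Serializable rows for the per-gene output table."""
    return [
        {
            "gene_id": r.gene_id,
            "wilcoxon_stat": r.wilcoxon_stat,
            "wilcoxon_p": r.wilcoxon_p,
            "wilcoxon_q": r.wilcoxon_q,
            "f_stat": r.f_stat,
            "f_p": r.f_p,
            "f_q": r.f_q,
            "selected": int(r.selected),
            "flags": ";".join(sorted(r.flags)),
        }
        for r in results
    ]
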