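"""Downstream statistics: differential expression, enrichment, survival.

Differential expression is a per-gene two-sample Student's t-test
(pooled variance, Welch available behind a flag) with Benjamini-Hochberg
adjustment.  Gene-set enrichment is an upper-tail hypergeometric test with
BH control across sets.  Survival analysis follows the minimum-p cutoff
scan: each gene's expression is dichotomized at a grid of quantile cutoffs
(default 90 levels spanning 5-95%), a two-group log-rank test is run at
every cutoff, and the split with the smallest p is reported together with
the Kaplan-Meier curves of its two groups.  The scan's selection bias (the
minimum over many correlated tests is anti-conservative for null genes) is
a documented property, not corrected for.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .data_io import ExpressionMatrix, GeneSetCollection, PhenotypeTable

logger = logging.getLogger(__name__)

__all__ = [
    "DEResult",
    "differential_expression",
    "benjamini_hochberg",
    "EnrichmentResult",
    "hypergeom_enrichment",
    "km_curve",
    "LogrankResult",
    "logrank_test",
    "SurvivalScanResult",
    "survival_cutoff_scan",
    "cox_univariate_binary",
]


# ---------------------------------------------------------------------------
# Differential expression
# ---------------------------------------------------------------------------

@dataclass
class DEResult:
    """Per-gene t-test results; ``direction`` is tumor relative to normal."""

    table: pd.DataFrame  # index gene; mean_A, mean_B, t_statistic, raw_p, adjusted_p,
    #                      direction, zero_variance

    def significant(self, alpha: float = 0.05) -> list[str]:
        t = self.table
        return list(t.index[t["adjusted_p"] < alpha])


def differential_expression(
    X: ExpressionMatrix, pheno: PhenotypeTable, welch: bool = False
) -> DEResult:
    """Two-sample t-test per gene between normal (A) and tumor (B).

    Pooled-variance Student's t by default; ``welch=True`` switches to the
    unequal-variance form.  Genes with zero pooled variance get p = 1 and a
    flag instead of an exception.
    """
    pheno.validate_against(X)
    cond = pheno.condition_of(X.sample_ids)
    a = X.values[:, cond == "normal"]
    b = X.values[:, cond == "tumor"]
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("need >= 2 samples per condition for a t-test")
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat, raw_p = sps.ttest_ind(b, a, axis=1, equal_var=not welch)
    zero_var = ~np.isfinite(t_stat)
    t_stat = np.where(zero_var, 0.0, t_stat)
    raw_p = np.where(zero_var, 1.0, raw_p)
    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    table = pd.DataFrame(
        {
            "mean_A": mean_a,
            "mean_B": mean_b,
            "t_statistic": t_stat,
            "raw_p": raw_p,
            "adjusted_p": benjamini_hochberg(raw_p),
            "direction": np.where(mean_b - mean_a >= 0, "up", "down"),
            "zero_variance": zero_var,
        },
        index=X.gene_ids,
    )
    return DEResult(table)


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    ``p_(i) * m / i`` with cumulative-minimum enforcement from the largest
    rank down and a cap at 1; adjusted values follow their p's under input
    reordering.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


# ---------------------------------------------------------------------------
# Hypergeometric enrichment
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentResult:
    table: pd.DataFrame  # index set name; k, K, n, N, p_value, adjusted_p


def hypergeom_enrichment(
    query: list[str], sets: GeneSetCollection, universe: list[str]
) -> EnrichmentResult:
    """Upper-tail hypergeometric enrichment of a gene list in each set.

    ``p = P(overlap >= k)`` for drawing ``n = |query|`` genes from a universe
    of ``N`` containing ``K`` set members; BH adjustment across sets; results
    sorted by ascending p.  Query genes outside the universe are dropped with
    a warning; set members outside the universe do not count toward ``K``.
    """
    uni = list(dict.fromkeys(universe))
    uni_set = set(uni)
    q = list(dict.fromkeys(query))
    outside = [g for g in q if g not in uni_set]
    if outside:
        logger.warning("dropping %d query genes outside the universe", len(outside))
        q = [g for g in q if g in uni_set]
    if not q:
        raise ValueError("query is empty after intersecting with the universe")
    n = len(q)
    big_n = len(uni)
    q_set = set(q)
    rows = []
    for name, members in sets.sets.items():
        inside = [g for g in members if g in uni_set]
        big_k = len(inside)
        k = len(q_set.intersection(inside))
        # P(X >= k); k = 0 gives p = 1 by definition of the observed tail
        p = float(sps.hypergeom.sf(k - 1, big_n, big_k, n))
        rows.append((name, k, big_k, n, big_n, min(p, 1.0)))
    table = pd.DataFrame(
        rows, columns=["set", "k", "K", "n", "N", "p_value"]
    ).set_index("set")
    table["adjusted_p"] = benjamini_hochberg(table["p_value"].to_numpy())
    table = table.sort_values(["p_value", "k"], ascending=[True, False])
    return EnrichmentResult(table)


# ---------------------------------------------------------------------------
# Kaplan-Meier and log-rank
# ---------------------------------------------------------------------------

def km_curve(times, events) -> pd.DataFrame:
    """Product-limit (Kaplan-Meier) survival curve.

    Returns one row per distinct event time with the at-risk count, event
    count and the survival estimate after that time.  Censored-only times
    reduce the risk set without producing a step.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=float)
    if t.size == 0:
        raise ValueError("empty survival input")
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    if not set(np.unique(e)) <= {0.0, 1.0}:
        raise ValueError("events must be binary 0/1")
    order = np.argsort(t, kind="mergesort")
    t, e = t[order], e[order]
    event_times = np.unique(t[e == 1])
    rows = []
    surv = 1.0
    for et in event_times:
        at_risk = int(np.sum(t >= et))
        d = int(np.sum((t == et) & (e == 1)))
        surv *= 1.0 - d / at_risk
        rows.append((float(et), at_risk, d, surv))
    return pd.DataFrame(rows, columns=["time", "n_at_risk", "n_events", "survival"])


@dataclass
class LogrankResult:
    chi_square: float
    p_value: float
    no_events: bool = False


def logrank_test(times_1, events_1, times_2, events_2) -> LogrankResult:
    """Standard two-group log-rank test (1 df).

    At each distinct event time the observed minus expected events in group 1
    is accumulated with its hypergeometric variance; subjects censored
    exactly at an event time remain in the risk set for that time.  With no
    events at all, p = 1 is returned with a flag.
    """
    t1 = np.asarray(times_1, dtype=float)
    e1 = np.asarray(events_1, dtype=float)
    t2 = np.asarray(times_2, dtype=float)
    e2 = np.asarray(events_2, dtype=float)
    if t1.size == 0 or t2.size == 0:
        raise ValueError("both groups must be non-empty")
    all_t = np.concatenate([t1, t2])
    all_e = np.concatenate([e1, e2])
    in_1 = np.concatenate([np.ones(t1.size), np.zeros(t2.size)])
    order = np.argsort(all_t, kind="mergesort")
    t, e, g1 = all_t[order], all_e[order], in_1[order]
    # one block per distinct time; everyone at or after a block start is at risk
    _, first = np.unique(t, return_index=True)
    n_total = t.size
    at_risk = n_total - first
    at_risk_1 = np.cumsum(g1[::-1])[::-1][first]
    d = np.add.reduceat(e, first)
    d1 = np.add.reduceat(e * g1, first)
    use = (d > 0) & (at_risk > 1)
    if not use.any():
        return LogrankResult(0.0, 1.0, no_events=True)
    n = at_risk[use].astype(float)
    n1 = at_risk_1[use].astype(float)
    dj = d[use]
    frac = n1 / n
    o_minus_e = float(np.sum(d1[use] - dj * frac))
    var = float(np.sum(dj * frac * (1 - frac) * (n - dj) / (n - 1)))
    if var <= 0:
        return LogrankResult(0.0, 1.0, no_events=True)
    chi2 = o_minus_e**2 / var
    p = float(sps.chi2.sf(chi2, df=1))
    return LogrankResult(float(chi2), p)


# ---------------------------------------------------------------------------
# Minimum-p cutoff scan
# ---------------------------------------------------------------------------

@dataclass
class SurvivalScanResult:
    """Result of dichotomizing one gene at many cutoffs.

    ``scan`` holds one row per evaluated cutoff; ``best_cutoff_quantile`` is
    the argmin-p quantile level (ties resolved toward the lower quantile),
    ``min_p`` its log-rank p (reported raw: the minimum over ~90 correlated
    tests is selection-biased for null genes), and the KM curves describe the
    low/high groups at the best split.  ``hazard_ratio`` is the descriptive
    univariate Cox hazard ratio (high vs low) at the best cutoff.
    """

    gene: str
    scan: pd.DataFrame  # quantile, cutoff, n_low, n_high, chi_square, p_value
    best_cutoff_quantile: float
    best_cutoff_value: float
    min_p: float
    km_low: pd.DataFrame
    km_high: pd.DataFrame
    significant: bool
    hazard_ratio: float


def survival_cutoff_scan(
    x,
    pheno: PhenotypeTable,
    n_cutoffs: int = 90,
    gene: str = "",
    sample_ids: list[str] | None = None,
) -> SurvivalScanResult:
    """Log-rank scan over expression cutoffs for one gene.

    The cutoff grid is ``n_cutoffs`` evenly spaced quantile levels spanning
    [0.05, 0.95] inclusive; samples split into low (< cutoff) and high
    (>= cutoff); cutoffs yielding an empty group are skipped.  Only samples
    with a complete (time, event) record enter the scan.
    """
    surv = pheno.survival_records()
    if surv.empty:
        raise ValueError("phenotype table has no survival records")
    x = np.asarray(x, dtype=float)
    if sample_ids is not None:
        keep = [s for s in sample_ids if s in surv.index]
        pos = {s: i for i, s in enumerate(sample_ids)}
        x = x[[pos[s] for s in keep]]
        surv = surv.loc[keep]
    if x.size != len(surv):
        raise ValueError(
            f"expression vector length {x.size} does not match "
            f"{len(surv)} samples with survival records"
        )
    times = surv["survival_time"].to_numpy()
    events = surv["event"].to_numpy()
    grid = np.linspace(0.05, 0.95, n_cutoffs)
    rows = []
    for q in grid:
        cut = float(np.quantile(x, q))  # linear interpolation between order stats
        high = x >= cut
        if high.all() or not high.any():
            continue
        res = logrank_test(times[~high], events[~high], times[high], events[high])
        rows.append((float(q), cut, int((~high).sum()), int(high.sum()), res.chi_square, res.p_value))
    if len(rows) < 2:
        raise ValueError("fewer than 2 valid cutoffs (is the expression constant?)")
    scan = pd.DataFrame(
        rows, columns=["quantile", "cutoff", "n_low", "n_high", "chi_square", "p_value"]
    )
    best_idx = int(scan["p_value"].idxmin())  # idxmin takes the first = lowest quantile
    best = scan.loc[best_idx]
    high = x >= best["cutoff"]
    km_low = km_curve(times[~high], events[~high])
    km_high = km_curve(times[high], events[high])
    hr = cox_univariate_binary(times, events, high.astype(float))
    return SurvivalScanResult(
        gene=gene,
        scan=scan,
        best_cutoff_quantile=float(best["quantile"]),
        best_cutoff_value=float(best["cutoff"]),
        min_p=float(best["p_value"]),
        km_low=km_low,
        km_high=km_high,
        significant=bool(best["p_value"] < 0.05),
        hazard_ratio=hr,
    )


def cox_univariate_binary(times, events, covariate) -> float:
    """Hazard ratio from a univariate Cox fit with a binary covariate.

    Newton-Raphson on the Breslow partial likelihood; used descriptively at
    the best cutoff (selection is by log-rank p, not by this fit).  Returns
    ``exp(beta)``, or NaN when the fit is degenerate.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=float)
    x = np.asarray(covariate, dtype=float)
    if e.sum() == 0 or len(np.unique(x)) < 2:
        return float("nan")
    order = np.argsort(t, kind="mergesort")
    t, e, x = t[order], e[order], x[order]
    _, first = np.unique(t, return_index=True)
    d = np.add.reduceat(e, first)
    dx = np.add.reduceat(e * x, first)
    use = d > 0
    beta = 0.0
    for _ in range(50):
        w = np.exp(beta * x)
        # suffix sums give risk-set aggregates at each block start
        s0 = np.cumsum(w[::-1])[::-1][first]
        s1 = np.cumsum((w * x)[::-1])[::-1][first]
        s2 = np.cumsum((w * x * x)[::-1])[::-1][first]
        mean = s1[use] / s0[use]
        score = float(np.sum(dx[use] - d[use] * mean))
        info = float(np.sum(d[use] * (s2[use] / s0[use] - mean**2)))
        if info <= 0:
            return float("nan")
        step = score / info
        beta += step
        if abs(step) < 1e-10:
            break
        if abs(beta) > 50:  # one group has no events; HR diverges
            return float("nan")
    return float(np.exp(beta))
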