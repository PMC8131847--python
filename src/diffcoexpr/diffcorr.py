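"""Differential correlation between two conditions.

For every gene pair the per-condition Pearson correlations ``r_A`` (normal)
and ``r_B`` (tumor) are variance-stabilized with Fisher's transform
``z = 0.5 * log((1 + r) / (1 - r))`` and compared with

    Z = (z_A - z_B) / sqrt(1 / (n_A - 3) + 1 / (n_B - 3)),

which is standard normal under the null of equal population correlations.
Significance across the many pairs is controlled with a local false
discovery rate: an empirical-Bayes two-component model
``lfdr(z) = eta0 * phi(z) / f(z)`` with a theoretical standard-normal null
``phi``, the null fraction ``eta0`` estimated from the upper half of the
p-value distribution, and the marginal density ``f`` estimated by Gaussian
kernel density with Silverman bandwidth.

A pair whose correlation is significant and flips sign between conditions
("switching mechanism") is the object of interest; switching pairs can be
intersected with differential expression of the member genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .data_io import ExpressionMatrix, PhenotypeTable, NetworkEdgeTable, make_edge_table
from .network import first_principal_component, correlation_p_value

logger = logging.getLogger(__name__)

__all__ = [
    "SCALING_METHODS",
    "scale",
    "fisher_z",
    "z_difference",
    "condition_correlation_tests",
    "estimate_eta0",
    "local_fdr",
    "detect_switching",
    "cluster_molecules",
    "eigen_module_diffcorr",
    "EigenModuleNetwork",
]

#: internal clamp applied before the Fisher transform so empirical |r| == 1
#: (duplicated genes) maps to a large finite z instead of infinity
_R_CLAMP = 1.0 - 1e-12

RECORD_COLUMNS = [
    "gene_a", "gene_b", "r_A", "r_B", "z_A", "z_B", "n_A", "n_B",
    "Z_diff", "p_A", "p_B", "p_diff",
]


# ---------------------------------------------------------------------------
# Scaling transforms
# ---------------------------------------------------------------------------

SCALING_METHODS = ("auto", "range", "pareto", "vast", "level", "power")


def scale(X: ExpressionMatrix, method: str) -> ExpressionMatrix:
    """Apply a per-gene pretreatment transform across samples.

    With per-gene mean ``m``, SD ``s`` (ddof=1), min and max:

    ========  ==================================
    auto      (x - m) / s
    range     (x - m) / (max - min)
    pareto    (x - m) / sqrt(s)
    vast      ((x - m) / s) * (m / s)
    level     (x - m) / m
    power     sqrt(x) - mean(sqrt(x))
    ========  ==================================
    """
    if method not in SCALING_METHODS:
        raise ValueError(f"unknown scaling method {method!r}; choose from {SCALING_METHODS}")
    v = X.values
    m = v.mean(axis=1, keepdims=True)
    s = v.std(axis=1, ddof=1, keepdims=True)

    def _require(ok: np.ndarray, why: str) -> None:
        bad = np.flatnonzero(~ok.ravel())
        if bad.size:
            raise ValueError(
                f"scaling method {method!r} undefined for gene "
                f"{X.gene_ids[bad[0]]!r}: {why}"
            )

    if method == "auto":
        _require(s > 0, "zero variance")
        out = (v - m) / s
    elif method == "range":
        rng = v.max(axis=1, keepdims=True) - v.min(axis=1, keepdims=True)
        _require(rng > 0, "max equals min")
        out = (v - m) / rng
    elif method == "pareto":
        _require(s > 0, "zero variance")
        out = (v - m) / np.sqrt(s)
    elif method == "vast":
        _require(s > 0, "zero variance")
        out = ((v - m) / s) * (m / s)
    elif method == "level":
        _require(m != 0, "zero mean")
        out = (v - m) / m
    else:  # power
        _require((v >= 0).all(axis=1, keepdims=True), "negative values")
        sq = np.sqrt(v)
        out = sq - sq.mean(axis=1, keepdims=True)
    return ExpressionMatrix(list(X.gene_ids), list(X.sample_ids), out)


# ---------------------------------------------------------------------------
# Fisher z and the difference test
# ---------------------------------------------------------------------------

def fisher_z(r):
    """Fisher's variance-stabilizing transform ``z = 0.5 log((1+r)/(1-r))``."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1):
        raise ValueError("Fisher transform undefined for |r| >= 1")
    z = 0.5 * np.log((1.0 + r) / (1.0 - r))
    return float(z) if z.ndim == 0 else z


def z_difference(r_a, r_b, n_a: int, n_b: int):
    """Z statistic and two-sided normal p for a difference of correlations.

    Accepts scalars or arrays for ``r_a`` / ``r_b``.  Sample sizes must
    exceed 3 because the Fisher variance is ``1 / (n - 3)``.
    """
    if n_a <= 3 or n_b <= 3:
        raise ValueError("sample sizes must exceed 3 (Fisher variance 1/(n-3))")
    z_a = fisher_z(r_a)
    z_b = fisher_z(r_b)
    se = np.sqrt(1.0 / (n_a - 3) + 1.0 / (n_b - 3))
    z = (np.asarray(z_a) - np.asarray(z_b)) / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    if np.ndim(z) == 0:
        return float(z), float(p)
    return z, p


def condition_correlation_tests(
    X: ExpressionMatrix,
    pheno: PhenotypeTable,
    gene_subset: list[str] | None = None,
) -> pd.DataFrame:
    """Per-condition correlations and the z-difference test for all pairs.

    Returns one row per unordered gene pair within ``gene_subset`` (all genes
    by default), with per-condition correlations, Fisher z's, correlation-test
    p-values (t distribution, n-2 df) and the difference statistic.
    """
    pheno.validate_against(X)
    genes = list(gene_subset) if gene_subset is not None else list(X.gene_ids)
    if len(genes) < 2:
        raise ValueError("need at least two genes")
    sub = X.subset_genes(genes)
    cond = pheno.condition_of(sub.sample_ids)
    blocks = {}
    for level in ("normal", "tumor"):
        cols = np.flatnonzero(cond == level)
        if cols.size < 4:
            raise ValueError(f"condition {level!r} has {cols.size} samples; need >= 4")
        blocks[level] = sub.values[:, cols]
    n_a, n_b = blocks["normal"].shape[1], blocks["tumor"].shape[1]
    ra = np.clip(np.corrcoef(blocks["normal"]), -1.0, 1.0)
    rb = np.clip(np.corrcoef(blocks["tumor"]), -1.0, 1.0)
    iu, ju = np.triu_indices(len(genes), k=1)
    r_a = ra[iu, ju]
    r_b = rb[iu, ju]
    rc_a = np.clip(r_a, -_R_CLAMP, _R_CLAMP)
    rc_b = np.clip(r_b, -_R_CLAMP, _R_CLAMP)
    z_a = 0.5 * np.log((1 + rc_a) / (1 - rc_a))
    z_b = 0.5 * np.log((1 + rc_b) / (1 - rc_b))
    se = np.sqrt(1.0 / (n_a - 3) + 1.0 / (n_b - 3))
    z_diff = (z_a - z_b) / se
    p_diff = 2.0 * stats.norm.sf(np.abs(z_diff))
    gene_arr = np.asarray(genes, dtype=object)
    records = pd.DataFrame(
        {
            "gene_a": gene_arr[iu],
            "gene_b": gene_arr[ju],
            "r_A": r_a,
            "r_B": r_b,
            "z_A": z_a,
            "z_B": z_b,
            "n_A": n_a,
            "n_B": n_b,
            "Z_diff": z_diff,
            "p_A": correlation_p_value(r_a, n_a),
            "p_B": correlation_p_value(r_b, n_b),
            "p_diff": p_diff,
        }
    )
    return records


# ---------------------------------------------------------------------------
# Local false discovery rate
# ---------------------------------------------------------------------------

def estimate_eta0(z: np.ndarray) -> float:
    """Null-fraction estimate ``min(1, 2 * mean(p > 0.5))``.

    p-values above 0.5 are (almost surely) null under a two-sided test, so
    twice their frequency estimates the null proportion.
    """
    p = 2.0 * stats.norm.sf(np.abs(np.asarray(z, dtype=float)))
    return float(min(1.0, 2.0 * np.mean(p > 0.5)))


def local_fdr(z_values, min_tests: int = 200) -> np.ndarray:
    """Local false discovery rate of z statistics under a theoretical null.

    ``lfdr(z) = eta0 * phi(z) / f(z)`` with ``phi`` the standard normal
    density and ``f`` a Silverman-bandwidth Gaussian KDE of the observed
    statistics, clipped to [0, 1].  Below ``min_tests`` statistics the
    density estimate is unreliable and Benjamini-Hochberg adjusted two-sided
    p-values are returned instead (logged).
    """
    z = np.asarray(z_values, dtype=float)
    if z.ndim != 1 or z.size == 0:
        raise ValueError("z_values must be a non-empty 1-D array")
    if np.allclose(z, z[0]):
        raise ValueError("degenerate input: all z statistics identical")
    if z.size < min_tests:
        from .stats import benjamini_hochberg

        logger.info(
            "only %d tests (< %d); falling back to BH-adjusted p-values", z.size, min_tests
        )
        p = 2.0 * stats.norm.sf(np.abs(z))
        return benjamini_hochberg(p)
    eta0 = estimate_eta0(z)
    kde = stats.gaussian_kde(z, bw_method="silverman")
    f = kde(z)
    with np.errstate(divide="ignore", invalid="ignore"):
        lfdr = eta0 * stats.norm.pdf(z) / f
    lfdr[~np.isfinite(lfdr)] = 1.0
    return np.clip(lfdr, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Switching pairs
# ---------------------------------------------------------------------------

def attach_lfdr(records: pd.DataFrame, min_tests: int = 200) -> pd.DataFrame:
    """Return a copy of the records with an ``lfdr`` column."""
    out = records.copy()
    out["lfdr"] = local_fdr(out["Z_diff"].to_numpy(), min_tests=min_tests)
    return out


def detect_switching(
    records: pd.DataFrame,
    de_table: pd.DataFrame | None = None,
    alpha_lfdr: float = 0.05,
    alpha_de: float = 0.05,
    min_abs_r: float = 0.0,
    de_rule: str = "both",
) -> pd.DataFrame:
    """Select significant oppositely-correlated ("switching") gene pairs.

    Keeps pairs whose correlations have opposite signs in the two conditions,
    with ``lfdr < alpha_lfdr`` and ``|r| >= min_abs_r`` in both conditions.
    When ``de_table`` (indexed by gene, column ``adjusted_p``) is supplied,
    the pair must additionally be differentially expressed: both member genes
    at adjusted p < ``alpha_de`` under the default strict rule, or at least
    one under ``de_rule="either"``.  Output is sorted by ascending lfdr, then
    descending |Z|, then pair name.
    """
    if "lfdr" not in records.columns:
        raise ValueError("records carry no lfdr column; run attach_lfdr first")
    if de_rule not in ("both", "either"):
        raise ValueError("de_rule must be 'both' or 'either'")
    rec = records.copy()
    keep = (
        (np.sign(rec["r_A"]) * np.sign(rec["r_B"]) < 0)
        & (rec["lfdr"] < alpha_lfdr)
        & (rec["r_A"].abs() >= min_abs_r)
        & (rec["r_B"].abs() >= min_abs_r)
    )
    if de_table is not None:
        genes = pd.unique(pd.concat([rec["gene_a"], rec["gene_b"]]))
        missing = [g for g in genes if g not in de_table.index]
        if missing:
            raise ValueError(f"genes missing from DE table: {missing[:5]}")
        de_sig = de_table["adjusted_p"] < alpha_de
        sig_a = rec["gene_a"].map(de_sig).astype(bool)
        sig_b = rec["gene_b"].map(de_sig).astype(bool)
        keep &= (sig_a & sig_b) if de_rule == "both" else (sig_a | sig_b)
    out = rec[keep].copy()
    out["abs_Z"] = out["Z_diff"].abs()
    out = out.sort_values(
        ["lfdr", "abs_Z", "gene_a", "gene_b"], ascending=[True, False, True, True]
    ).drop(columns="abs_Z")
    out["switching"] = True
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Eigen-molecule module networks
# ---------------------------------------------------------------------------

@dataclass
class EigenModuleNetwork:
    """Per-condition correlation-distance clustering of the analyzed genes."""

    gene_ids: list[str]
    clusters: dict[str, pd.Series]  # condition -> Series(gene -> cluster id)
    r_cutoff: float

    def members(self, condition: str, cluster_id: int) -> list[str]:
        lab = self.clusters[condition]
        return list(lab.index[lab == cluster_id])


def cluster_molecules(
    X: ExpressionMatrix, pheno: PhenotypeTable, r_cutoff: float = 0.6
) -> EigenModuleNetwork:
    """Cluster genes per condition with one-minus-correlation distance.

    Average-linkage hierarchical clustering on the signed distance
    ``d = 1 - r`` (range [0, 2]); the tree is cut at absolute height
    ``1 - r_cutoff`` so genes correlated above the cutoff end up together.
    Singleton clusters are allowed.
    """
    if not 0 < r_cutoff < 1:
        raise ValueError("r_cutoff must be in (0, 1)")
    pheno.validate_against(X)
    cond = pheno.condition_of(X.sample_ids)
    clusters: dict[str, pd.Series] = {}
    for level in ("normal", "tumor"):
        cols = np.flatnonzero(cond == level)
        r = np.clip(np.corrcoef(X.values[:, cols]), -1.0, 1.0)
        d = 1.0 - r
        np.fill_diagonal(d, 0.0)
        z = linkage(squareform(d, checks=False), method="average")
        raw = fcluster(z, t=1.0 - r_cutoff, criterion="distance")
        clusters[level] = pd.Series(raw.astype(int), index=X.gene_ids)
    return EigenModuleNetwork(list(X.gene_ids), clusters, r_cutoff)


def eigen_module_diffcorr(
    net: EigenModuleNetwork,
    X: ExpressionMatrix,
    pheno: PhenotypeTable,
    reference: str = "normal",
) -> pd.DataFrame:
    """Differential correlation between eigen-molecule modules.

    Cluster membership is taken from the ``reference`` condition; each
    cluster's eigen-molecule (first PC, or the standardized profile for a
    singleton) is computed separately within each condition's samples, and
    every unordered cluster pair gets the z-difference treatment with the
    per-condition sample sizes.
    """
    labels = net.clusters[reference]
    cluster_ids = sorted(labels.unique())
    if len(cluster_ids) < 2:
        raise ValueError("need at least 2 clusters for a module network")
    cond = pheno.condition_of(X.sample_ids)
    eigen: dict[str, np.ndarray] = {}
    sizes = {"normal": 0, "tumor": 0}
    per_condition: dict[str, list[np.ndarray]] = {"normal": [], "tumor": []}
    for level in ("normal", "tumor"):
        cols = np.flatnonzero(cond == level)
        sizes[level] = cols.size
        for cid in cluster_ids:
            members = net.members(reference, cid)
            block = X.subset_genes(members).values[:, cols]
            if len(members) == 1:
                v = block[0]
                scores = (v - v.mean()) / v.std(ddof=1)
            else:
                scores, _ = first_principal_component(block)
            per_condition[level].append(scores)
    n_a, n_b = sizes["normal"], sizes["tumor"]
    ea = np.vstack(per_condition["normal"])
    eb = np.vstack(per_condition["tumor"])
    ra = np.clip(np.corrcoef(ea), -1.0, 1.0)
    rb = np.clip(np.corrcoef(eb), -1.0, 1.0)
    iu, ju = np.triu_indices(len(cluster_ids), k=1)
    r_a = np.clip(ra[iu, ju], -_R_CLAMP, _R_CLAMP)
    r_b = np.clip(rb[iu, ju], -_R_CLAMP, _R_CLAMP)
    z, p = z_difference(r_a, r_b, n_a, n_b)
    ids = np.asarray(cluster_ids)
    return pd.DataFrame(
        {
            "cluster_a": ids[iu],
            "cluster_b": ids[ju],
            "r_A": ra[iu, ju],
            "r_B": rb[iu, ju],
            "n_A": n_a,
            "n_B": n_b,
            "Z_diff": z,
            "p_diff": p,
        }
    )


def eigen_network_edges(
    eigen_records: pd.DataFrame, condition: str = "normal", prefix: str = "module"
) -> NetworkEdgeTable:
    """Edge table of the eigen-module network for one condition.

    Nodes are clusters; edge weight is |r| in the chosen condition with the
    sign carried separately, matching the module-network export format.
    """
    col = {"normal": "r_A", "tumor": "r_B"}[condition]
    edges = []
    for row in eigen_records.itertuples(index=False):
        r = getattr(row, col)
        edges.append(
            (
                f"{prefix}{row.cluster_a}",
                f"{prefix}{row.cluster_b}",
                abs(float(r)),
                "+" if r >= 0 else "-",
                f"Z_diff={row.Z_diff:.3f}",
            )
        )
    return make_edge_table(edges)
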