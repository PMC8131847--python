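"""Weighted co-expression network construction and module detection.

The network is unsigned: adjacency is ``|cor(x_i, x_j)| ** beta`` with the
soft-threshold power ``beta`` chosen so that connectivity approximates a
scale-free degree distribution (log-log fit R^2 of at least 0.8, with the
fit index forced to zero when the slope is positive, since scale-freeness
requires frequency to FALL with connectivity).  Genes are clustered by
average linkage on the topological-overlap dissimilarity ``1 - TOM``; the
tree is cut statically, small clusters are relabelled "grey", and surviving
modules are named from a fixed color palette by decreasing size.  Module
eigengenes are first principal components of the standardized module
expression, sign-anchored to the module mean profile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy import stats

from .data_io import ExpressionMatrix, PhenotypeTable
from .palette import GREY, MODULE_COLORS

logger = logging.getLogger(__name__)

__all__ = [
    "pairwise_correlation",
    "filter_invariant_genes",
    "select_soft_threshold",
    "adjacency",
    "topological_overlap",
    "detect_modules",
    "module_eigengenes",
    "module_trait",
    "SoftThresholdReport",
    "AdjacencyMatrix",
    "TOMMatrix",
    "ModuleAssignment",
    "EigengeneSet",
    "ModuleTraitResult",
]


# ---------------------------------------------------------------------------
# Correlation and adjacency
# ---------------------------------------------------------------------------

def pairwise_correlation(X: ExpressionMatrix) -> np.ndarray:
    """All-pairs Pearson correlation of gene expression profiles.

    Every gene must have nonzero variance (enforce with
    :func:`filter_invariant_genes` first); the result is symmetric with unit
    diagonal.
    """
    sd = X.values.std(axis=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        raise ValueError(f"zero-variance gene: {X.gene_ids[zero[0]]!r}")
    r = np.corrcoef(X.values)
    np.fill_diagonal(r, 1.0)
    return np.clip(r, -1.0, 1.0)


def filter_invariant_genes(
    X: ExpressionMatrix, pheno: PhenotypeTable | None = None
) -> tuple[ExpressionMatrix, list[str]]:
    """Drop genes with zero variance, pooled or within either condition.

    When a phenotype table is supplied a gene constant within either single
    condition is removed too, since per-condition correlations would be
    undefined for it.
    """
    bad = X.values.std(axis=1) == 0
    if pheno is not None:
        pheno.validate_against(X)
        cond = pheno.condition_of(X.sample_ids)
        for level in ("normal", "tumor"):
            cols = cond == level
            if cols.sum() >= 2:
                bad |= X.values[:, cols].std(axis=1) == 0
    removed = [g for g, b in zip(X.gene_ids, bad) if b]
    if len(removed) == X.n_genes:
        raise ValueError("all genes removed as invariant")
    if removed:
        logger.info("removed %d invariant genes (first: %s)", len(removed), removed[0])
        keep = [g for g, b in zip(X.gene_ids, bad) if not b]
        return X.subset_genes(keep), removed
    return X, []


@dataclass
class AdjacencyMatrix:
    """Unsigned weighted adjacency ``a_ij = |r_ij| ** beta`` (diagonal 0)."""

    gene_ids: list[str]
    values: np.ndarray
    beta: int

    @property
    def connectivity(self) -> np.ndarray:
        """Per-gene connectivity ``k_i = sum_{u != i} a_iu``."""
        return self.values.sum(axis=0)


def adjacency(X: ExpressionMatrix, beta: int) -> AdjacencyMatrix:
    """Soft-thresholded unsigned adjacency from the correlation matrix."""
    if beta < 1:
        raise ValueError("soft-threshold power must be >= 1")
    r = pairwise_correlation(X)
    a = np.abs(r) ** beta
    np.fill_diagonal(a, 0.0)  # diagonal excluded from connectivity
    return AdjacencyMatrix(list(X.gene_ids), a, int(beta))


# ---------------------------------------------------------------------------
# Scale-free fit and power selection
# ---------------------------------------------------------------------------

@dataclass
class SoftThresholdReport:
    """Scale-free fit index and mean connectivity per candidate power."""

    table: pd.DataFrame  # columns: power, r_squared, slope, mean_connectivity
    chosen_power: int
    reached_floor: bool


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Signed scale-free fit index of a connectivity vector.

    Connectivities are grouped into ``n_bins`` equal-occupancy bins; the
    log10 per-bin frequency density is regressed on the log10 mean
    connectivity over non-empty bins.  Returns ``(r_squared, slope)`` with
    ``r_squared`` forced to 0 for a positive slope (the scale-free criterion
    requires frequency to decrease with connectivity).
    """
    k = np.asarray(k, dtype=float)
    k = k[k > 0]
    edges = np.unique(np.quantile(k, np.linspace(0, 1, n_bins + 1)))
    if len(edges) < 2:
        raise ValueError("connectivity degenerate: fewer than 3 non-empty bins")
    counts, edges = np.histogram(k, bins=edges)
    mean_k = np.empty(len(counts))
    for i in range(len(counts)):
        upper = k < edges[i + 1] if i + 1 < len(counts) else k <= edges[i + 1]
        sel = k[(k >= edges[i]) & upper]
        mean_k[i] = sel.mean() if sel.size else np.nan
    widths = np.diff(edges)
    with np.errstate(divide="ignore", invalid="ignore"):
        density = counts / (k.size * widths)
    ok = (counts > 0) & np.isfinite(mean_k) & (mean_k > 0) & (density > 0)
    if ok.sum() < 3:
        raise ValueError("connectivity degenerate: fewer than 3 non-empty bins")
    fit = stats.linregress(np.log10(mean_k[ok]), np.log10(density[ok]))
    r2 = float(fit.rvalue**2)
    if fit.slope > 0:
        r2 = 0.0
    return r2, float(fit.slope)


def select_soft_threshold(
    X: ExpressionMatrix,
    candidates: list[int] | None = None,
    r2_floor: float = 0.8,
    n_bins: int = 10,
) -> SoftThresholdReport:
    """Pick the soft-threshold power by the scale-free topology criterion.

    The chosen power is the smallest candidate whose fit index reaches
    ``r2_floor`` (default 0.8).  If no candidate reaches the floor, the
    candidate with the maximal fit index is returned with a logged warning.
    """
    if candidates is None:
        candidates = list(range(1, 13))
    powers = sorted(set(int(b) for b in candidates))
    if not powers:
        raise ValueError("no candidate powers supplied")
    r = pairwise_correlation(X)
    abs_r = np.abs(r)
    np.fill_diagonal(abs_r, 0.0)
    rows = []
    for beta in powers:
        a = abs_r**beta
        k = a.sum(axis=0)
        r2, slope = scale_free_fit(k, n_bins=n_bins)
        rows.append((beta, r2, slope, float(k.mean())))
    table = pd.DataFrame(rows, columns=["power", "r_squared", "slope", "mean_connectivity"])
    passing = table[table["r_squared"] >= r2_floor]
    if len(passing):
        chosen = int(passing["power"].iloc[0])
        reached = True
    else:
        chosen = int(table.loc[table["r_squared"].idxmax(), "power"])
        reached = False
        logger.warning(
            "no candidate power reaches scale-free R^2 >= %.2f; "
            "falling back to power %d (R^2 = %.3f)",
            r2_floor, chosen, table["r_squared"].max(),
        )
    return SoftThresholdReport(table, chosen, reached)


# ---------------------------------------------------------------------------
# Topological overlap
# ---------------------------------------------------------------------------

@dataclass
class TOMMatrix:
    """Topological overlap similarity; ``1 - values`` is the clustering dissimilarity."""

    gene_ids: list[str]
    values: np.ndarray

    @property
    def dissimilarity(self) -> np.ndarray:
        return 1.0 - self.values


def topological_overlap(A: AdjacencyMatrix) -> TOMMatrix:
    """Unsigned topological overlap of a weighted adjacency.

    ``TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij)`` where
    ``l_ij = sum_{u != i,j} a_iu * a_uj`` counts shared neighborhood and
    ``k_i`` is connectivity; the diagonal is 1 by convention.  Pairs with a
    zero denominator (two fully isolated genes) get overlap 0.
    """
    a = A.values
    k = a.sum(axis=0)
    # full matrix product includes u=i and u=j terms; remove them:
    # sum_u a_iu a_uj = l_ij + a_ii a_ij + a_ij a_jj, and a_ii = 0 here.
    l = a @ a
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = (l + a) / denom
    zero_den = denom <= 0
    if zero_den.any():
        logger.info("TOM: %d pairs with zero denominator set to 0", int(zero_den.sum()))
        tom[zero_den] = 0.0
    np.fill_diagonal(tom, 1.0)
    tom = np.clip(tom, 0.0, 1.0)
    return TOMMatrix(list(A.gene_ids), tom)


# ---------------------------------------------------------------------------
# Module detection
# ---------------------------------------------------------------------------

@dataclass
class ModuleAssignment:
    """Partition of genes into color-named modules plus the grey bucket."""

    module_of_gene: pd.Series  # index: gene_id, values: color labels
    linkage_matrix: np.ndarray
    cut_height: float

    @property
    def labels(self) -> list[str]:
        """Non-grey module labels, ordered by decreasing module size."""
        counts = self.module_of_gene[self.module_of_gene != GREY].value_counts()
        return sorted(counts.index, key=lambda m: (-counts[m], MODULE_COLORS.index(m)))

    def genes_in(self, label: str) -> list[str]:
        return list(self.module_of_gene.index[self.module_of_gene == label])

    def sizes(self) -> dict[str, int]:
        return {m: len(self.genes_in(m)) for m in self.labels}


def detect_modules(
    TOM: TOMMatrix, min_module_size: int = 30, cut_height: float = 0.995
) -> ModuleAssignment:
    """Detect modules by average-linkage clustering of TOM dissimilarity.

    The dendrogram is cut statically at ``cut_height`` times the maximal
    merge height; clusters smaller than ``min_module_size`` become "grey",
    the rest are named from the color palette by decreasing size (largest =
    "turquoise").
    """
    if min_module_size < 2:
        raise ValueError("min_module_size must be >= 2")
    if not 0 < cut_height < 1:
        raise ValueError("cut_height must be in (0, 1)")
    d = TOM.dissimilarity.copy()
    np.fill_diagonal(d, 0.0)
    z = linkage(squareform(d, checks=False), method="average")
    threshold = cut_height * z[:, 2].max()
    raw = fcluster(z, t=threshold, criterion="distance")
    genes = TOM.gene_ids
    labels = pd.Series(GREY, index=genes, dtype=object)
    cluster_members: dict[int, list[int]] = {}
    for i, c in enumerate(raw):
        cluster_members.setdefault(int(c), []).append(i)
    surviving = [
        (len(members), min(members), cid)
        for cid, members in cluster_members.items()
        if len(members) >= min_module_size
    ]
    # deterministic naming: by decreasing size, ties broken by first gene index
    surviving.sort(key=lambda t: (-t[0], t[1]))
    if len(surviving) > len(MODULE_COLORS):
        raise ValueError(
            f"{len(surviving)} modules exceed the {len(MODULE_COLORS)}-color palette"
        )
    for color, (_size, _first, cid) in zip(MODULE_COLORS, surviving):
        for i in cluster_members[cid]:
            labels.iloc[i] = color
    if not surviving:
        logger.warning("no cluster reached min_module_size=%d; all genes grey", min_module_size)
    return ModuleAssignment(labels, z, float(threshold))


# ---------------------------------------------------------------------------
# Eigengenes and module-trait association
# ---------------------------------------------------------------------------

@dataclass
class EigengeneSet:
    """First-PC summary profile per module, unit variance, sign-anchored."""

    sample_ids: list[str]
    eigengenes: pd.DataFrame  # samples x modules
    variance_explained: dict[str, float]


def _standardize_rows(values: np.ndarray) -> np.ndarray:
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("cannot standardize a zero-variance gene")
    return (values - mean) / sd


def first_principal_component(values: np.ndarray) -> tuple[np.ndarray, float]:
    """First PC score vector (over samples) of a genes-x-samples block.

    Rows are standardized first; the score vector is scaled to unit variance
    and sign-flipped to correlate positively with the mean standardized
    profile.  Returns (scores, variance_explained).
    """
    xs = _standardize_rows(values)
    # SVD of the centered gene x sample matrix; right singular vector = PC scores
    u, s, vt = np.linalg.svd(xs, full_matrices=False)
    scores = vt[0]
    var_explained = float(s[0] ** 2 / np.sum(s**2))
    mean_profile = xs.mean(axis=0)
    if np.dot(scores, mean_profile) < 0:
        scores = -scores
    sd = scores.std(ddof=1)
    if sd > 0:
        scores = scores / sd
    return scores, var_explained


def module_eigengenes(X: ExpressionMatrix, M: ModuleAssignment) -> EigengeneSet:
    """Compute the eigengene of every non-grey module."""
    eig: dict[str, np.ndarray] = {}
    var_exp: dict[str, float] = {}
    for label in M.labels:
        genes = M.genes_in(label)
        block = X.subset_genes(genes).values
        if len(genes) == 1:
            logger.info("module %s has a single gene; eigengene = its profile", label)
            scores = _standardize_rows(block)[0]
            scores = scores / scores.std(ddof=1)
            var = 1.0
        else:
            scores, var = first_principal_component(block)
        eig[label] = scores
        var_exp[label] = var
    frame = pd.DataFrame(eig, index=X.sample_ids)
    return EigengeneSet(list(X.sample_ids), frame, var_exp)


@dataclass
class ModuleTraitResult:
    """Module-trait correlations plus per-gene GS and MM."""

    module_stats: pd.DataFrame  # index: module; columns: r_mt, p_value, n_genes
    gene_stats: pd.DataFrame  # index: gene; columns: module, GS, MM


def correlation_p_value(r: float | np.ndarray, n: int) -> float | np.ndarray:
    """Two-sided p for a Pearson correlation via the t distribution, n-2 df."""
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    return np.where(np.abs(r) >= 1.0, 0.0, p) if np.ndim(r) else (
        0.0 if abs(r) >= 1 else float(p)
    )


def module_trait(
    E: EigengeneSet,
    pheno: PhenotypeTable,
    X: ExpressionMatrix,
    M: ModuleAssignment,
) -> ModuleTraitResult:
    """Correlate eigengenes with the binary trait; compute GS and MM per gene.

    The trait is coded normal=0 / tumor=1, so a module up-regulated in tumor
    gets a positive module-trait correlation.
    """
    trait = pheno.trait_vector(E.sample_ids)
    if np.all(trait == trait[0]):
        raise ValueError("trait is constant; module-trait correlation undefined")
    n = len(trait)
    rows = []
    for label in E.eigengenes.columns:
        e = E.eigengenes[label].to_numpy()
        r_mt = float(np.corrcoef(e, trait)[0, 1])
        p = correlation_p_value(r_mt, n)
        rows.append((label, r_mt, p, len(M.genes_in(label))))
    module_stats = pd.DataFrame(
        rows, columns=["module", "r_mt", "p_value", "n_genes"]
    ).set_index("module")

    gs_rows = []
    for gene, label in M.module_of_gene.items():
        x = X.subset_genes([gene]).values[0]
        if x.std() == 0:
            gs = np.nan
        else:
            gs = abs(float(np.corrcoef(x, trait)[0, 1]))
        if label == GREY:
            mm = np.nan
        else:
            e = E.eigengenes[label].to_numpy()
            mm = abs(float(np.corrcoef(x, e)[0, 1]))
        gs_rows.append((gene, label, gs, mm))
    gene_stats = pd.DataFrame(
        gs_rows, columns=["gene", "module", "GS", "MM"]
    ).set_index("gene")
    return ModuleTraitResult(module_stats, gene_stats)
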