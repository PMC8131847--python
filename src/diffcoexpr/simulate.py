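"""Synthetic two-condition expression data with planted, recoverable structure.

The generator emulates the statistical design of a tumor/normal RNA-seq
comparison: two conditions with (by default, strongly) unequal sample sizes,
block-correlated gene modules, "switching" gene pairs whose correlation flips
sign between conditions, mean-shift differential expression, and survival
times whose hazard depends on the expression of designated genes.  Everything
planted is reported back in a :class:`SyntheticTruth` so recovery can be
scored.

Correlated blocks use a single shared-factor construction,
``x = lam * f_m + sqrt(1 - lam^2) * eps``, which gives closed-form expected
correlations (``lam^2`` within a module, ``+-switch_r`` for a switching pair)
and therefore an analytic handle for power calculations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .data_io import ExpressionMatrix, PhenotypeTable
import pandas as pd

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "simulate",
    "null_pair_sample",
    "simulate_scale_free",
]


@dataclass
class SimulationConfig:
    """Parameters of the planted-structure simulation.

    Condition A is "normal", condition B is "tumor".  The default sample
    sizes (58 normal vs 468 tumor) mirror the design imbalance of a typical
    TCGA tumor/normal comparison.

    Attributes
    ----------
    n_genes
        Total number of genes; must accommodate all planted structure.
    n_samples_a, n_samples_b
        Samples in the normal and tumor condition.
    module_sizes
        Sizes of the block-correlated modules (genes are laid out module
        blocks first, then switching pairs, then independent noise).
    within_module_loading
        Factor loading ``lam`` in (0, 1); expected within-module correlation
        is ``lam**2``.
    n_switch_pairs, switch_r
        Number of planted switching pairs and their target |correlation|
        (expected ``+switch_r`` in A and ``-switch_r`` in B).
    n_de_genes, de_shift
        Differentially expressed genes receive a mean shift ``de_shift``
        (in residual-SD units) in condition B.  Genes are chosen at random
        unless ``de_gene_indices`` pins them down.
    survival_genes
        ``(gene_index, log_hazard_coefficient)`` pairs; survival times for
        condition-B samples are exponential with hazard
        ``baseline_hazard * exp(sum(beta * x_gene))``, censored at
        ``censor_horizon``.
    """

    n_genes: int = 200
    n_samples_a: int = 58
    n_samples_b: int = 468
    module_sizes: list[int] = field(default_factory=list)
    within_module_loading: float = 0.8
    n_switch_pairs: int = 0
    switch_r: float = 0.6
    n_de_genes: int = 0
    de_shift: float = 1.0
    de_gene_indices: list[int] | None = None
    survival_genes: list[tuple[int, float]] = field(default_factory=list)
    baseline_hazard: float = 0.1
    censor_horizon: float = 20.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0 or self.n_samples_a <= 0 or self.n_samples_b <= 0:
            raise ValueError("n_genes and sample sizes must be positive")
        if any(s <= 0 for s in self.module_sizes):
            raise ValueError("module sizes must be positive")
        if not 0 < self.within_module_loading < 1:
            raise ValueError("within_module_loading must be in (0, 1)")
        if not 0 < self.switch_r < 1:
            raise ValueError("switch_r must be in (0, 1)")
        if self.n_switch_pairs < 0 or self.n_de_genes < 0:
            raise ValueError("counts must be non-negative")
        if sum(self.module_sizes) + 2 * self.n_switch_pairs > self.n_genes:
            raise ValueError(
                "sum(module_sizes) + 2*n_switch_pairs exceeds n_genes"
            )
        if self.de_gene_indices is not None:
            if len(self.de_gene_indices) != self.n_de_genes:
                raise ValueError("de_gene_indices length must equal n_de_genes")
            if any(not 0 <= i < self.n_genes for i in self.de_gene_indices):
                raise ValueError("de_gene_indices out of range")
        if self.n_de_genes > self.n_genes:
            raise ValueError("n_de_genes exceeds n_genes")
        for g, _beta in self.survival_genes:
            if not 0 <= g < self.n_genes:
                raise ValueError(f"survival gene index {g} out of range")
        if self.baseline_hazard <= 0 or self.censor_horizon <= 0:
            raise ValueError("baseline_hazard and censor_horizon must be positive")


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside a simulated dataset."""

    module_of_gene: dict[str, str | None]
    switch_pairs: list[tuple[str, str, float, float]]  # (a, b, r_A_target, r_B_target)
    de_genes: list[tuple[str, float]]
    survival_genes: list[tuple[str, float]]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "module_of_gene": self.module_of_gene,
            "switch_pairs": [list(t) for t in self.switch_pairs],
            "de_genes": [list(t) for t in self.de_genes],
            "survival_genes": [list(t) for t in self.survival_genes],
        }
        Path(path).write_text(json.dumps(payload, indent=1) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            module_of_gene=payload["module_of_gene"],
            switch_pairs=[tuple(t) for t in payload["switch_pairs"]],
            de_genes=[(g, float(d)) for g, d in payload["de_genes"]],
            survival_genes=[(g, float(b)) for g, b in payload["survival_genes"]],
        )

    @property
    def switch_pair_keys(self) -> set[frozenset[str]]:
        return {frozenset((a, b)) for a, b, _, _ in self.switch_pairs}


def _gene_names(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(n)]


def simulate(config: SimulationConfig) -> tuple[ExpressionMatrix, PhenotypeTable, SyntheticTruth]:
    """Draw one dataset from the planted-structure model.

    The root seed is split into independent per-stage child streams (module
    block, switching pairs, background noise, DE gene choice, survival), so
    enabling one stage never perturbs the draws of another.
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    ss_module, ss_switch, ss_noise, ss_de, ss_surv = root.spawn(5)
    rng_module = np.random.default_rng(ss_module)
    rng_switch = np.random.default_rng(ss_switch)
    rng_noise = np.random.default_rng(ss_noise)
    rng_de = np.random.default_rng(ss_de)
    rng_surv = np.random.default_rng(ss_surv)

    n_a, n_b = config.n_samples_a, config.n_samples_b
    n_samples = n_a + n_b
    genes = _gene_names(config.n_genes)
    samples = [f"N{i + 1:03d}" for i in range(n_a)] + [f"T{i + 1:03d}" for i in range(n_b)]
    values = np.empty((config.n_genes, n_samples))

    module_of: dict[str, str | None] = {g: None for g in genes}
    lam = config.within_module_loading
    resid = np.sqrt(1.0 - lam**2)
    row = 0
    for m, size in enumerate(config.module_sizes, start=1):
        f = rng_module.standard_normal(n_samples)
        eps = rng_module.standard_normal((size, n_samples))
        values[row : row + size] = lam * f + resid * eps
        for g in genes[row : row + size]:
            module_of[g] = f"M{m}"
        row += size

    switch_pairs: list[tuple[str, str, float, float]] = []
    a_load = np.sqrt(config.switch_r)
    s_resid = np.sqrt(1.0 - config.switch_r)
    for _ in range(config.n_switch_pairs):
        f = rng_switch.standard_normal(n_samples)
        eps = rng_switch.standard_normal((2, n_samples))
        load2 = np.full(n_samples, a_load)
        load2[n_a:] = -a_load  # second gene flips sign in condition B
        values[row] = a_load * f + s_resid * eps[0]
        values[row + 1] = load2 * f + s_resid * eps[1]
        switch_pairs.append((genes[row], genes[row + 1], config.switch_r, -config.switch_r))
        row += 2

    if row < config.n_genes:
        values[row:] = rng_noise.standard_normal((config.n_genes - row, n_samples))

    if config.de_gene_indices is not None:
        de_idx = list(config.de_gene_indices)
    else:
        de_idx = sorted(rng_de.choice(config.n_genes, size=config.n_de_genes, replace=False))
    for i in de_idx:
        values[i, n_a:] += config.de_shift
    de_genes = [(genes[i], config.de_shift) for i in de_idx]

    pheno_frame = pd.DataFrame(
        {"condition": ["normal"] * n_a + ["tumor"] * n_b}, index=samples
    )
    survival_genes = [(genes[g], float(b)) for g, b in config.survival_genes]
    if config.survival_genes:
        log_h = np.log(config.baseline_hazard) + sum(
            beta * values[g, n_a:] for g, beta in config.survival_genes
        )
        t_raw = rng_surv.exponential(scale=np.exp(-log_h))
        event = (t_raw <= config.censor_horizon).astype(float)
        t_obs = np.minimum(t_raw, config.censor_horizon)
        pheno_frame["survival_time"] = np.concatenate([np.full(n_a, np.nan), t_obs])
        pheno_frame["event"] = np.concatenate([np.full(n_a, np.nan), event])

    X = ExpressionMatrix(genes, samples, values)
    pheno = PhenotypeTable(pheno_frame)
    truth = SyntheticTruth(module_of, switch_pairs, de_genes, survival_genes)
    return X, pheno, truth


def null_pair_sample(
    n_a: int, n_b: int, rho: float, n_pairs: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Sample correlations of null pairs sharing the SAME rho in both conditions.

    Each pair is drawn as a bivariate normal with correlation ``rho`` in both
    conditions; the returned arrays are the per-condition sample correlations,
    the null model against which the z-difference test is calibrated.
    """
    if not abs(rho) < 1:
        raise ValueError("|rho| must be < 1")
    if n_a < 4 or n_b < 4:
        raise ValueError(
            "sample sizes must be >= 4 (Fisher variance undefined, denominators n-3)"
        )
    rng = np.random.default_rng(seed)

    def _corrs(n: int) -> np.ndarray:
        out = np.empty(n_pairs)
        chunk = 5000
        for start in range(0, n_pairs, chunk):
            stop = min(start + chunk, n_pairs)
            m = stop - start
            z1 = rng.standard_normal((m, n))
            z2 = rng.standard_normal((m, n))
            x = z1
            y = rho * z1 + np.sqrt(1 - rho**2) * z2
            xc = x - x.mean(axis=1, keepdims=True)
            yc = y - y.mean(axis=1, keepdims=True)
            num = (xc * yc).sum(axis=1)
            den = np.sqrt((xc**2).sum(axis=1) * (yc**2).sum(axis=1))
            out[start:stop] = num / den
        return out

    return _corrs(n_a), _corrs(n_b)


def simulate_scale_free(
    n_genes: int = 2500,
    n_samples: int = 10_000,
    power: int = 6,
    min_loading: float = 0.25,
    max_loading: float = 0.9,
    seed: int = 0,
) -> tuple[ExpressionMatrix, np.ndarray]:
    """Expression whose weighted network is scale-free at ``power``.

    All genes load on one shared factor, ``x_i = u_i f + sqrt(1-u_i^2) eps``,
    with gene loadings laid down as the exact quantiles of the density
    ``p(u) ~ u^(gamma-1)`` on [min_loading, max_loading], gamma = 0.8*power.
    Under soft thresholding at ``beta`` the connectivity of gene i scales as
    ``u_i^beta``, so the degree density in log-log space has slope
    ``gamma/beta - 1``: RISING with connectivity for every power below the
    target (where the scale-free fit index is zero, since scale-freeness
    demands a falling density) and an exact, shallow decreasing power law at
    the target power.  The large sample count keeps correlation sampling
    noise from blurring that law.

    Returns the matrix and the loading vector.
    """
    if power < 2:
        raise ValueError("power must be >= 2")
    if not 0 < min_loading < max_loading < 1:
        raise ValueError("need 0 < min_loading < max_loading < 1")
    rng = np.random.default_rng(seed)
    gamma = 0.8 * power
    q = (np.arange(n_genes) + 0.5) / n_genes
    lo, hi = min_loading**gamma, max_loading**gamma
    u = (lo + q * (hi - lo)) ** (1.0 / gamma)
    f = rng.standard_normal(n_samples)
    eps = rng.standard_normal((n_genes, n_samples))
    values = u[:, None] * f + np.sqrt(1.0 - u**2)[:, None] * eps
    genes = _gene_names(n_genes)
    samples = [f"S{j + 1:05d}" for j in range(n_samples)]
    return ExpressionMatrix(genes, samples, values), u
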