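"""Synthetic multi-environment trial data with known variance structure.

The generator produces, in order:

1. a biallelic SNP dosage matrix (independent markers, per-marker allele
   frequency uniform on a MAF range),
2. genotype-in-environment cell values

       y_ij = mu + E_i + L_j + g_j + gE_ij + e_ij

   where E_i ~ N(0, var_E) are environment main effects, L_j ~ N(0, var_L)
   iid line effects, g ~ MVN(0, G var_g) genomic effects with G the VanRaden
   relationship matrix built from the simulated markers, gE_ij a
   genotype-by-environment interaction with Cov(gE_ij, gE_i'j') =
   var_gE * G_jj' * 1[i = i'], and e_ij iid cell residuals,
3. optionally plot-level records inside a replicate / incomplete-block
   layout: y_jkl = cell value + rep effect + block-within-rep effect + plot
   noise.

Drawing gE per environment as an independent MVN(0, G var_gE) vector is
exactly the Hadamard-kernel covariance (Z_g G Z_g') o (Z_E Z_E') var_gE for a
complete one-cell-per-(i,j) layout with unstructured-free environments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .markers import GRMatrix, MarkerMatrix, compute_grm, impute_and_standardize, qc_filter

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "simulate_markers",
    "simulate_phenotypes",
    "simulate_plot_trial",
    "simulate_dataset",
]

#: diagonal jitter added to G before Cholesky; standardized-marker GRMs are
#: frequently rank-deficient (p < n or duplicated genotypes)
_CHOL_JITTER = 1e-8


@dataclass
class SimulationConfig:
    """Parameters of the synthetic trial generator.

    Variances are on the trait scale (squared trait units).  The defaults
    mirror a desk-scale version of a maize hybrid trial: 300 genotypes,
    2,000 markers, 3 environments, and an implied between-environment
    phenotypic correlation of (var_L + var_g) / (var_L + var_g + var_gE +
    var_e) ~ 0.31.
    """

    n_genotypes: int = 300
    n_markers: int = 2000
    n_envs: int = 3
    maf_range: tuple[float, float] = (0.05, 0.5)
    geno_missing_rate: float = 0.0
    mu: float = 6.0
    var_E: float = 0.5
    var_L: float = 0.1
    var_g: float = 0.3
    var_gE: float = 0.5
    var_e: float = 0.4
    # plot stage (replicates within environments, incomplete blocks within reps)
    n_reps: int = 2
    n_blocks: int = 5
    var_rep: float = 0.2
    var_block: float = 0.1
    var_plot: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("var_E", "var_L", "var_g", "var_gE", "var_e",
                     "var_rep", "var_block", "var_plot"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < min <= max <= 0.5")
        if not 0 <= self.geno_missing_rate < 1:
            raise ValueError("geno_missing_rate must be in [0, 1)")
        if self.n_genotypes < 2 or self.n_markers < 1 or self.n_envs < 1:
            raise ValueError("need n_genotypes >= 2, n_markers >= 1, n_envs >= 1")


@dataclass
class SimulatedDataset:
    """Markers, true effects and phenotypes from one generator run."""

    markers: MarkerMatrix
    grm: GRMatrix
    true_effects: dict
    cell_values: pd.DataFrame  # columns: env, genotype, value
    plot_table: Optional[pd.DataFrame] = None  # env, rep, block, genotype, value
    config: Optional[SimulationConfig] = None


def simulate_markers(
    n_genotypes: int,
    n_markers: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
    geno_missing_rate: float = 0.0,
    seed: int = 0,
) -> MarkerMatrix:
    """Draw independent biallelic dosages Binomial(2, f_m), f_m ~ U(maf_range).

    Missing calls are flagged completely at random at ``geno_missing_rate``.
    """
    if n_genotypes < 2 or n_markers < 1:
        raise ValueError("need n_genotypes >= 2 and n_markers >= 1")
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must satisfy 0 < min <= max <= 0.5")
    if not 0 <= geno_missing_rate < 1:
        raise ValueError("geno_missing_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    freq = rng.uniform(lo, hi, size=n_markers)
    dosage = rng.binomial(2, freq, size=(n_genotypes, n_markers)).astype(float)
    if geno_missing_rate > 0:
        miss = rng.random((n_genotypes, n_markers)) < geno_missing_rate
        dosage[miss] = np.nan
    ids = np.array([f"G{i + 1:04d}" for i in range(n_genotypes)], dtype=object)
    mids = np.array([f"M{m + 1:05d}" for m in range(n_markers)], dtype=object)
    return MarkerMatrix(genotype_ids=ids, marker_ids=mids, dosage=dosage)


def _chol_psd(G: np.ndarray) -> np.ndarray:
    """Cholesky factor of G after a documented diagonal jitter."""
    n = G.shape[0]
    try:
        return np.linalg.cholesky(G + _CHOL_JITTER * np.eye(n))
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"G is not positive semidefinite even after +{_CHOL_JITTER} jitter"
        ) from exc


def simulate_phenotypes(markers: MarkerMatrix, config: SimulationConfig) -> SimulatedDataset:
    """Generate cell values y_ij = mu + E_i + L_j + g_j + gE_ij + e_ij.

    The genomic relationship matrix is built from ``markers`` after default
    quality control; g and the per-environment gE vectors are drawn from
    MVN(0, G var) via a jittered Cholesky factor.
    """
    if markers.n_genotypes != config.n_genotypes:
        raise ValueError(
            f"markers have {markers.n_genotypes} genotypes, "
            f"config expects {config.n_genotypes}"
        )
    grm = compute_grm(
        impute_and_standardize(qc_filter(markers)), genotype_ids=markers.genotype_ids
    )
    n, q = config.n_genotypes, config.n_envs
    rng = np.random.default_rng(config.seed)
    envs = np.array([f"Env{i + 1}" for i in range(q)], dtype=object)

    E = rng.normal(0.0, np.sqrt(config.var_E), size=q)
    L = rng.normal(0.0, np.sqrt(config.var_L), size=n)
    chol = _chol_psd(grm.G)
    g = np.sqrt(config.var_g) * (chol @ rng.standard_normal(n))
    gE = np.sqrt(config.var_gE) * (chol @ rng.standard_normal((n, q)))  # col per env
    e = rng.normal(0.0, np.sqrt(config.var_e), size=(n, q))

    cell = config.mu + E[None, :] + L[:, None] + g[:, None] + gE + e
    cell_values = pd.DataFrame(
        {
            "env": np.repeat(envs, n),
            "genotype": np.tile(markers.genotype_ids, q),
            "value": cell.T.ravel(),
        }
    )
    true_effects = {
        "E": pd.Series(E, index=envs),
        "L": pd.Series(L, index=markers.genotype_ids),
        "g": pd.Series(g, index=markers.genotype_ids),
        "gE": pd.DataFrame(gE, index=markers.genotype_ids, columns=envs),
    }
    return SimulatedDataset(
        markers=markers,
        grm=grm,
        true_effects=true_effects,
        cell_values=cell_values,
        config=config,
    )


def simulate_plot_trial(
    cell_values: pd.DataFrame,
    n_reps: int,
    n_blocks: int,
    var_rep: float,
    var_block: float,
    var_plot: float,
    seed: int = 0,
) -> pd.DataFrame:
    """Expand cell values into a replicate / incomplete-block plot layout.

    Within each environment every genotype appears once per replicate;
    genotypes are partitioned at random into ``n_blocks`` near-equal
    incomplete blocks, re-randomized per replicate.  Plot values are
    cell value + rep effect + block-within-rep effect + plot noise.
    """
    if n_reps < 1 or n_blocks < 1:
        raise ValueError("n_reps and n_blocks must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for env, sub in cell_values.groupby("env", sort=False):
        genos = sub["genotype"].to_numpy()
        values = sub["value"].to_numpy()
        n = len(genos)
        rep_eff = rng.normal(0.0, np.sqrt(var_rep), size=n_reps)
        for k in range(n_reps):
            order = rng.permutation(n)
            block_of = np.empty(n, dtype=int)
            block_of[order] = np.arange(n) * n_blocks // n  # near-equal sizes
            blk_eff = rng.normal(0.0, np.sqrt(var_block), size=n_blocks)
            noise = rng.normal(0.0, np.sqrt(var_plot), size=n)
            rows.append(
                pd.DataFrame(
                    {
                        "env": env,
                        "rep": f"R{k + 1}",
                        "block": [f"B{b + 1}" for b in block_of],
                        "genotype": genos,
                        "value": values + rep_eff[k] + blk_eff[block_of] + noise,
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


def simulate_dataset(config: SimulationConfig, with_plots: bool = True) -> SimulatedDataset:
    """Full generator run: markers, cell values and (optionally) plot records."""
    markers = simulate_markers(
        config.n_genotypes,
        config.n_markers,
        config.maf_range,
        config.geno_missing_rate,
        seed=config.seed,
    )
    data = simulate_phenotypes(markers, config)
    if with_plots:
        data.plot_table = simulate_plot_trial(
            data.cell_values,
            config.n_reps,
            config.n_blocks,
            config.var_rep,
            config.var_block,
            config.var_plot,
            seed=config.seed + 1,
        )
    return data
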