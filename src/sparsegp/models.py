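"""The three genomic prediction models and their cell-level kernels.

M1 (E+L)      y_ij = mu + E_i + L_j + e_ij
M2 (E+L+G)    adds the genomic value g_j, Cov(g) = G sigma2_g
M3 (E+L+G+GE) adds the genotype-by-environment interaction gE_ij with
              Cov(gE) = (Z_g G Z_g') o (Z_E Z_E') sigma2_gE  (Hadamard product)

All terms are random with iid-normal (E, L) or kernel-structured (g, gE)
covariances.  Over a vector of cells (environment, genotype) the kernels are

    K_E  = Z_E Z_E'   (1 iff same environment)
    K_L  = Z_g Z_g'   (1 iff same genotype)
    K_g  = Z_g G Z_g'
    K_GE = K_g o K_E

Fitting is delegated to :class:`~sparsegp.gibbs.GibbsKernelRegressor`; both L
and g are retained in M2/M3 so that iid line effects can absorb what
imperfect marker information leaves unexplained.  A genotype never observed
in any environment receives its prediction only through K_g (and K_GE): the
iid L term has no covariance with unobserved lines and contributes 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .designs import AllocationDesign
from .gibbs import GibbsKernelRegressor
from .markers import GRMatrix

__all__ = [
    "MODEL_KERNELS",
    "ModelSpec",
    "GibbsConfig",
    "ModelFit",
    "cell_index",
    "build_kernels",
    "fit_model",
    "pct_unexplained",
]

MODEL_KERNELS = {
    "M1": ("E", "L"),
    "M2": ("E", "L", "G"),
    "M3": ("E", "L", "G", "GE"),
}


@dataclass(frozen=True)
class ModelSpec:
    """One of the three model names with its ordered kernel labels."""

    name: str

    def __post_init__(self):
        if self.name not in MODEL_KERNELS:
            raise ValueError(f"unknown model {self.name!r}; choose from {list(MODEL_KERNELS)}")

    @property
    def kernel_labels(self) -> tuple:
        return MODEL_KERNELS[self.name]


@dataclass
class GibbsConfig:
    """Sampler settings (chain length, prior hyperparameters, seed)."""

    n_iter: int = 12000
    burn_in: int = 2000
    thin: int = 5
    prior_df: float = 5.0
    prior_r2: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.burn_in < self.n_iter:
            raise ValueError("need 0 <= burn_in < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if not 0 < self.prior_r2 < 1:
            raise ValueError("prior_r2 must be in (0, 1)")


@dataclass
class ModelFit:
    """Posterior summaries and cell predictions of one model on one design."""

    model: str
    varcomps: dict  # per-kernel variance plus "residual", posterior means
    mu_hat: float
    cell_predictions: pd.DataFrame  # env, genotype, set, predicted
    pct_unexplained: float
    diagnostics: dict  # effective sample sizes per variance chain
    estimator: GibbsKernelRegressor | None = None


def cell_index(env_ids: Sequence, genotype_ids: Sequence) -> pd.DataFrame:
    """Canonical cell ordering: environments outer, genotypes inner."""
    return pd.DataFrame(
        {
            "env": np.repeat(np.asarray(env_ids, dtype=object), len(genotype_ids)),
            "genotype": np.tile(np.asarray(genotype_ids, dtype=object), len(env_ids)),
        }
    )


def build_kernels(
    grm: GRMatrix,
    design: AllocationDesign,
    model: ModelSpec | str,
) -> tuple[pd.DataFrame, dict]:
    """Cell-level covariance kernels over the full factorial of a design.

    Returns the cell table (env, genotype, in canonical order) and a dict of
    (n_cells, n_cells) kernels restricted to the model's terms.
    """
    if isinstance(model, str):
        model = ModelSpec(model)
    missing = set(design.genotype_ids) - set(grm.genotype_ids)
    if missing:
        raise KeyError(
            f"{len(missing)} design genotype(s) absent from the GRM, "
            f"e.g. {sorted(missing)[:3]}"
        )
    cells = cell_index(design.env_ids, design.genotype_ids)
    env_codes = pd.Categorical(cells["env"]).codes
    gpos = grm.index_of(cells["genotype"])

    kernels: dict[str, np.ndarray] = {}
    same_env = (env_codes[:, None] == env_codes[None, :]).astype(float)
    same_geno = (gpos[:, None] == gpos[None, :]).astype(float)
    for lab in model.kernel_labels:
        if lab == "E":
            kernels[lab] = same_env
        elif lab == "L":
            kernels[lab] = same_geno
        elif lab == "G":
            kernels[lab] = grm.G[np.ix_(gpos, gpos)]
        elif lab == "GE":
            kernels[lab] = grm.G[np.ix_(gpos, gpos)] * same_env
    return cells, kernels


def fit_model(
    blues: pd.DataFrame,
    grm: GRMatrix,
    design: AllocationDesign,
    model: ModelSpec | str,
    config: GibbsConfig | None = None,
    fixed_varcomps: dict | None = None,
) -> ModelFit:
    """Fit one model on a design's calibration cells and predict every cell.

    ``blues`` must provide a value for every calibration cell (columns env,
    genotype, blue); prediction-cell values, if present, are ignored by the
    fit and used only downstream for scoring.
    """
    if isinstance(model, str):
        model = ModelSpec(model)
    config = config or GibbsConfig()
    cells, kernels = build_kernels(grm, design, model)
    key = pd.MultiIndex.from_frame(cells[["env", "genotype"]])
    lookup = blues.set_index(["env", "genotype"])["blue"]

    is_cal = np.array(
        [(e, g) in design.calibration_cells for e, g in zip(cells["env"], cells["genotype"])]
    )
    cal_idx = np.nonzero(is_cal)[0]
    cal_key = key[cal_idx]
    missing = cal_key.difference(lookup.index)
    if len(missing):
        raise KeyError(
            f"{len(missing)} calibration cell(s) have no adjusted value, "
            f"e.g. {list(missing[:3])}"
        )
    y_cal = lookup.reindex(cal_key).to_numpy(dtype=float)

    est = GibbsKernelRegressor(
        kernels=kernels,
        n_iter=config.n_iter,
        burn_in=config.burn_in,
        thin=config.thin,
        prior_df=config.prior_df,
        prior_r2=config.prior_r2,
        fixed_varcomps=fixed_varcomps,
        random_state=config.seed,
    )
    est.fit(cal_idx.reshape(-1, 1), y_cal)

    all_idx = np.arange(len(cells))
    preds = est.predict(all_idx.reshape(-1, 1))
    out = cells.copy()
    out["set"] = np.where(is_cal, "calibration", "prediction")
    out["predicted"] = preds

    return ModelFit(
        model=model.name,
        varcomps=dict(est.varcomps_),
        mu_hat=est.mu_,
        cell_predictions=out,
        pct_unexplained=pct_unexplained(est.varcomps_),
        diagnostics=dict(est.ess_),
        estimator=est,
    )


def pct_unexplained(varcomps: dict) -> float:
    """Residual variance as a percentage of the total fitted variance."""
    if "residual" not in varcomps:
        raise ValueError("varcomps must include a 'residual' entry")
    total = float(sum(varcomps.values()))
    if total <= 0:
        raise ValueError("all variance components are zero; percentage undefined")
    return 100.0 * float(varcomps["residual"]) / total
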