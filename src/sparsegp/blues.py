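"""Per-environment adjusted genotype means (BLUEs) from plot-level records.

Stage 1 of a two-stage multi-environment analysis.  Within each environment
the plot model is

    y_jkl = mu + L_j + r_k + d_l(r) + e_jkl

with genotype effects L_j fixed, replicate effects r_k ~ iid N(0, var_rep),
incomplete-block-within-replicate effects d_l(r) ~ iid N(0, var_block) and
plot residuals e_jkl ~ iid N(0, var_error).  Variance components are
estimated by REML via derivative-free profile-likelihood optimization over
the two variance ratios; the genotype BLUEs are then the generalized
least-squares solutions of the cell-means parameterization, which equal
mu-hat + L-hat_j of any identifiable genotype coding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

__all__ = ["Stage1VarComps", "estimate_stage1_varcomps", "compute_blues", "adjust_all"]

logger = logging.getLogger(__name__)

_LOG_RATIO_BOUNDS = (-12.0, 6.0)  # search range for log10 variance ratios


@dataclass
class Stage1VarComps:
    """REML variance components of the plot model (one environment)."""

    var_rep: float
    var_block: float
    var_error: float


class RankError(np.linalg.LinAlgError):
    """Fixed-effect system is singular (confounded genotype labels)."""


def _env_frame(plots: pd.DataFrame, env) -> pd.DataFrame:
    sub = plots.loc[plots["env"] == env]
    if sub.empty:
        raise ValueError(f"no plot records for environment {env!r}")
    dup = sub.duplicated(subset=["rep", "genotype"])
    if dup.any():
        raise ValueError(
            f"duplicate (rep, genotype) plot records in environment {env!r}"
        )
    return sub.reset_index(drop=True)


def _design(sub: pd.DataFrame):
    """Incidence matrices for genotype (fixed), replicate and block-in-rep."""
    geno = pd.Categorical(sub["genotype"])
    rep = pd.Categorical(sub["rep"])
    blk = pd.Categorical(
        sub["rep"].astype(str) + "/" + sub["block"].astype(str)
    )  # blocks nested in replicates
    n = len(sub)
    X = np.zeros((n, len(geno.categories)))
    X[np.arange(n), geno.codes] = 1.0
    Zr = np.zeros((n, len(rep.categories)))
    Zr[np.arange(n), rep.codes] = 1.0
    Zb = np.zeros((n, len(blk.categories)))
    Zb[np.arange(n), blk.codes] = 1.0
    return X, Zr, Zb, list(geno.categories)


class _RemlWorkspace:
    """Cross-products for fast profile-REML evaluations.

    With V0 = I + sum_t gamma_t Z_t Z_t' and U = [sqrt(gamma_t) Z_t], the
    Woodbury identity V0^{-1} = I - U (I + U'U)^{-1} U' reduces every
    criterion evaluation to dense algebra in the (small) total number of
    replicate/block levels plus one q x q factorization for the fixed
    effects.
    """

    def __init__(self, X, y, Z_list):
        self.n, self.q = X.shape
        self.y = y
        self.Z = np.hstack(Z_list) if Z_list else np.empty((self.n, 0))
        self.sizes = [Z.shape[1] for Z in Z_list]
        self.XtX = X.T @ X  # diagonal for the cell-means X, kept general
        self.Xty = X.T @ y
        self.yty = float(y @ y)
        self.XtZ = X.T @ self.Z
        self.Zty = self.Z.T @ y
        self.ZtZ = self.Z.T @ self.Z

    def crit(self, theta):
        """-2 restricted log-likelihood (profiled) and the profiled var_error."""
        gam = np.repeat(10.0 ** np.asarray(theta), self.sizes)
        sq = np.sqrt(gam)
        M = np.eye(len(gam)) + sq[:, None] * self.ZtZ * sq[None, :]
        sign_m, logdet_V = np.linalg.slogdet(M)
        if sign_m <= 0:
            return np.inf, np.nan
        Mi = np.linalg.inv(M)
        XtU = self.XtZ * sq[None, :]
        Uty = sq * self.Zty
        XtViX = self.XtX - XtU @ Mi @ XtU.T
        XtViy = self.Xty - XtU @ Mi @ Uty
        ytViy = self.yty - Uty @ Mi @ Uty
        sign_x, logdet_X = np.linalg.slogdet(XtViX)
        if sign_x <= 0:
            return np.inf, np.nan
        beta = np.linalg.solve(XtViX, XtViy)
        quad = ytViy - float(beta @ XtViy)
        dof = self.n - self.q
        if dof <= 0 or quad <= 0:
            return np.inf, np.nan
        s2 = max(quad / dof, 1e-12)
        return logdet_V + logdet_X + dof * np.log(s2), s2


def estimate_stage1_varcomps(plots: pd.DataFrame, env) -> Stage1VarComps:
    """REML estimates of (var_rep, var_block, var_error) for one environment.

    With a single replicate (or a single block per replicate) the
    corresponding component is not estimable and is fixed at 0 with a logged
    note.  Boundary estimates (0) are allowed.
    """
    sub = _env_frame(plots, env)
    y = sub["value"].to_numpy(dtype=float)
    X, Zr, Zb, _ = _design(sub)
    n, q = X.shape

    if np.ptp(y) == 0 or n <= q:
        # constant data, or no residual degrees of freedom
        return Stage1VarComps(0.0, 0.0, float(np.var(y, ddof=0)) if n > q else 0.0)

    active = []
    Z_list = []
    if Zr.shape[1] > 1:
        active.append("rep")
        Z_list.append(Zr)
    else:
        logger.info("environment %r has a single replicate; var_rep fixed at 0", env)
    if Zb.shape[1] > Zr.shape[1]:
        active.append("block")
        Z_list.append(Zb)
    else:
        logger.info(
            "environment %r has a single block per replicate; var_block fixed at 0", env
        )

    if not active:
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        resid = y - X @ beta
        s2 = float(resid @ resid / (n - q))
        return Stage1VarComps(0.0, 0.0, s2)

    k = len(Z_list)
    ws = _RemlWorkspace(X, y, Z_list)

    def objective(theta):
        return ws.crit(np.clip(theta, *_LOG_RATIO_BOUNDS))[0]

    best = None
    for start in (np.full(k, -1.0), np.full(k, 0.0), np.full(k, -3.0)):
        res = minimize(objective, start, method="Nelder-Mead",
                       options={"xatol": 1e-4, "fatol": 1e-7, "maxiter": 400})
        if best is None or res.fun < best.fun:
            best = res
    theta = np.clip(best.x, *_LOG_RATIO_BOUNDS)
    _, s2 = ws.crit(theta)
    ratios = 10.0 ** theta
    # snap effectively-zero ratios to the boundary
    ratios[ratios < 1e-8] = 0.0

    out = {"rep": 0.0, "block": 0.0}
    for name, r in zip(active, ratios):
        out[name] = float(r * s2)
    return Stage1VarComps(out["rep"], out["block"], float(s2))


def compute_blues(
    plots: pd.DataFrame,
    env,
    varcomps: Stage1VarComps | None = None,
) -> pd.DataFrame:
    """Generalized-least-squares genotype means for one environment.

    Fits the cell-means parameterization at the stage-1 variance estimates
    (estimated from the data unless ``varcomps`` is supplied) and returns a
    frame with columns (env, genotype, blue); the value reported per genotype
    is mu-hat + L-hat_j on that environment's trait scale.
    """
    sub = _env_frame(plots, env)
    if varcomps is None:
        varcomps = estimate_stage1_varcomps(plots, env)
    y = sub["value"].to_numpy(dtype=float)
    X, Zr, Zb, genotypes = _design(sub)
    n = len(y)
    ve = varcomps.var_error if varcomps.var_error > 0 else 1.0
    V = ve * np.eye(n) + varcomps.var_rep * (Zr @ Zr.T) + varcomps.var_block * (Zb @ Zb.T)
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    if np.linalg.matrix_rank(XtViX) < XtViX.shape[0]:
        raise RankError(
            f"singular fixed-effect system in environment {env!r}: "
            "genotype labels are confounded"
        )
    blue = np.linalg.solve(XtViX, X.T @ Vi @ y)
    return pd.DataFrame({"env": env, "genotype": genotypes, "blue": blue})


def adjust_all(plots: pd.DataFrame) -> pd.DataFrame:
    """Stage-1 adjustment for every environment, strictly one at a time."""
    out = [compute_blues(plots, env) for env in pd.unique(plots["env"])]
    return pd.concat(out, ignore_index=True)
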