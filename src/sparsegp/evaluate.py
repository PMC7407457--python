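"""Repetition x design x model cross-validation and its summaries.

The full factorial of adjusted values is known; each repetition draws a fresh
allocation, masks the prediction cells, fits each model on the calibration
cells only, and scores the masked cells per environment with the Pearson
correlation between adjusted (observed) and predicted values.  Summaries
average first across environments within a repetition, then across
repetitions; the spread reported is the standard deviation over repetitions
of the environment-averaged value.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .designs import DesignGrid, make_design
from .markers import GRMatrix
from .models import GibbsConfig, ModelSpec, fit_model

__all__ = ["CVResult", "pearson_by_env", "run_cv", "summarize", "summary_grid"]

logger = logging.getLogger(__name__)

_VARCOMP_COLUMNS = {"E": "var_E", "L": "var_L", "G": "var_g", "GE": "var_gE",
                    "residual": "var_e"}


@dataclass
class CVResult:
    """Long-format records, one per (rep, design, model, environment)."""

    records: pd.DataFrame
    n_reps: int
    base_seed: int


def pearson_by_env(observed: pd.DataFrame, predicted: pd.DataFrame,
                   prediction_cells, env) -> float:
    """Pearson correlation over one environment's prediction cells.

    ``observed`` has columns (env, genotype, blue); ``predicted`` has
    (env, genotype, predicted).  Returns NaN with a warning if either vector
    is constant (the correlation is undefined, never silently 0).
    """
    genos = [g for e, g in prediction_cells if e == env]
    if len(genos) < 3:
        raise ValueError(f"need >= 3 prediction cells in environment {env!r}")
    obs = observed.set_index(["env", "genotype"])["blue"]
    pred = predicted.set_index(["env", "genotype"])["predicted"]
    key = pd.MultiIndex.from_tuples([(env, g) for g in genos])
    x = obs.reindex(key).to_numpy(dtype=float)
    y = pred.reindex(key).to_numpy(dtype=float)
    if np.isnan(x).any() or np.isnan(y).any():
        raise KeyError(f"missing observed/predicted values in environment {env!r}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn(
            f"zero variance in environment {env!r}; correlation undefined",
            UserWarning, stacklevel=2,
        )
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def run_cv(
    blues: pd.DataFrame,
    grm: GRMatrix,
    grid: DesignGrid,
    models=("M1", "M2", "M3"),
    n_reps: int = 25,
    base_seed: int = 0,
    config: GibbsConfig | None = None,
    env_ids=None,
    progress: bool = False,
) -> CVResult:
    """Cross-validate every grid design x model over ``n_reps`` repetitions.

    ``blues`` must cover the full environment x genotype factorial (masking
    happens here, per repetition).  Repetition r draws its allocation with
    seed ``base_seed + r``; each fit gets an isolated sampler seed so a
    skipped fit never shifts later draws.  Single fit failures are logged and
    skipped; the run continues.
    """
    config = config or GibbsConfig()
    if env_ids is None:
        env_ids = list(pd.unique(blues["env"]))
    genotype_ids = list(pd.unique(blues["genotype"]))
    full = pd.MultiIndex.from_product([env_ids, genotype_ids])
    have = pd.MultiIndex.from_frame(blues[["env", "genotype"]])
    if len(full.difference(have)):
        raise ValueError("blues must cover the full environment x genotype factorial")

    models = [m if isinstance(m, ModelSpec) else ModelSpec(m) for m in models]
    rows = []
    designs = list(grid)
    iterator = enumerate(designs)
    if progress:
        from tqdm import tqdm

        iterator = enumerate(tqdm(designs, desc="designs"))
    for d_idx, (size, no, o) in iterator:
        for rep in range(n_reps):
            design = make_design(
                genotype_ids, len(env_ids), no, o,
                seed=base_seed + rep, env_ids=env_ids,
            )
            for m_idx, model in enumerate(models):
                fit_seed = int(
                    np.random.SeedSequence(
                        (base_seed, d_idx, m_idx, rep)
                    ).generate_state(1)[0] % (2**31)
                )
                cfg = GibbsConfig(
                    n_iter=config.n_iter, burn_in=config.burn_in, thin=config.thin,
                    prior_df=config.prior_df, prior_r2=config.prior_r2, seed=fit_seed,
                )
                try:
                    fit = fit_model(blues, grm, design, model, cfg)
                except Exception:  # noqa: BLE001 - a single fit must not kill the run
                    logger.exception(
                        "fit failed (design %s/%s, model %s, rep %s); skipped",
                        no, o, model.name, rep,
                    )
                    continue
                vc = {
                    _VARCOMP_COLUMNS[k]: v
                    for k, v in fit.varcomps.items()
                    if k in _VARCOMP_COLUMNS
                }
                for env in env_ids:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore", UserWarning)
                        r = pearson_by_env(
                            blues, fit.cell_predictions,
                            design.prediction_cells, env,
                        )
                    rows.append(
                        {
                            "rep": rep, "sample_size": size, "NO": no, "O": o,
                            "model": model.name, "env": env, "pearson_r": r,
                            "pct_unexplained": fit.pct_unexplained, **vc,
                        }
                    )
    return CVResult(records=pd.DataFrame(rows), n_reps=n_reps, base_seed=base_seed)


def summarize(result: CVResult) -> pd.DataFrame:
    """Mean and sd of accuracy and unexplained-variance share per design x model.

    The accuracy is first averaged across environments within each
    repetition (undefined correlations excluded, with their count reported),
    then averaged across repetitions; the sd is over repetitions.
    """
    rec = result.records
    if rec.empty:
        raise ValueError("empty cross-validation result")
    keys = ["sample_size", "NO", "O", "model"]
    per_rep = (
        rec.groupby(keys + ["rep"], sort=False)
        .agg(
            r_env_mean=("pearson_r", "mean"),  # skips NaN by default
            n_missing_r=("pearson_r", lambda s: int(s.isna().sum())),
            pct_unexplained=("pct_unexplained", "mean"),
        )
        .reset_index()
    )
    out = (
        per_rep.groupby(keys, sort=False)
        .agg(
            mean_r=("r_env_mean", "mean"),
            sd_r=("r_env_mean", lambda s: s.std(ddof=1) if len(s) > 1 else 0.0),
            mean_pct_unexplained=("pct_unexplained", "mean"),
            sd_pct_unexplained=(
                "pct_unexplained", lambda s: s.std(ddof=1) if len(s) > 1 else 0.0
            ),
            n_reps=("rep", "nunique"),
            n_missing_r=("n_missing_r", "sum"),
        )
        .reset_index()
    )
    return out


def plot_accuracy(summary: pd.DataFrame, value: str = "mean_r", ax=None):
    """Mean accuracy per model across NO/O compositions, with +-1 sd bands.

    One line per model over the compositions of a single sample size,
    ordered from all-non-overlapping (left) to all-overlapping (right).
    """
    import matplotlib.pyplot as plt

    sd_col = {"mean_r": "sd_r", "mean_pct_unexplained": "sd_pct_unexplained"}[value]
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    colors = {"M1": "black", "M2": "tab:blue", "M3": "tab:green"}
    for model, sub in summary.groupby("model"):
        sub = sub.sort_values("O")
        x = np.arange(len(sub))
        ax.plot(x, sub[value], label=model, color=colors.get(model))
        ax.fill_between(
            x, sub[value] - sub[sd_col], sub[value] + sub[sd_col],
            alpha=0.2, color=colors.get(model),
        )
        ax.set_xticks(x)
        ax.set_xticklabels(
            [f"{no}/{o}" for no, o in zip(sub["NO"], sub["O"])], rotation=45
        )
    ax.set_xlabel("non-overlapping / overlapping composition")
    ax.set_ylabel(value.replace("_", " "))
    ax.legend()
    return ax


def summary_grid(summary: pd.DataFrame, value: str = "mean_r") -> pd.DataFrame:
    """Pivot a summary into the sample-size x NO/O grid layout."""
    s = summary.copy()
    s["composition"] = s["NO"].astype(str) + "/" + s["O"].astype(str)
    return s.pivot_table(
        index=["model", "sample_size"], columns="composition", values=value,
        sort=False,
    )
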