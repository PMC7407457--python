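"""Sparse-testing allocation designs for multi-environment trials.

A design allocates a fixed plot budget across environments by splitting each
environment's calibration set into *overlapping* genotypes (O, grown in every
environment, connecting environments) and *non-overlapping* genotypes (NO,
each grown in exactly one environment, maximizing genotype coverage).  The
remaining genotype-in-environment cells form the prediction set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "AllocationDesign",
    "DesignGrid",
    "make_design",
    "design_summary",
    "enumerate_grid",
]


@dataclass(frozen=True)
class AllocationDesign:
    """One NO/O allocation: per-environment calibration sets and cell masks."""

    genotype_ids: tuple
    env_ids: tuple
    no_per_env: int
    o_count: int
    env_sets: tuple  # per-environment tuple of calibration genotype IDs
    overlap_set: tuple
    calibration_cells: frozenset  # of (env, genotype)
    prediction_cells: frozenset
    seed: int

    @property
    def n_envs(self) -> int:
        return len(self.env_ids)

    @property
    def sample_size_per_env(self) -> int:
        return self.no_per_env + self.o_count


@dataclass(frozen=True)
class DesignGrid:
    """Rows of (per-environment sample size, list of (NO, O) pairs)."""

    rows: tuple  # of (sample_size, tuple of (NO, O))

    def __iter__(self):
        for size, pairs in self.rows:
            for no, o in pairs:
                yield size, no, o

    def n_designs(self) -> int:
        return sum(len(pairs) for _, pairs in self.rows)


def make_design(
    genotype_ids: Sequence,
    n_envs: int,
    no_per_env: int,
    o_count: int,
    seed: int = 0,
    env_ids: Sequence | None = None,
) -> AllocationDesign:
    """Sample an NO/O allocation uniformly without replacement.

    The O genotypes are drawn first, then ``n_envs`` pairwise-disjoint NO
    sets from the remainder.  Calibration cells are the union of each
    environment's (env, genotype) pairs; prediction cells are the complement
    over the full environment-by-genotype factorial.
    """
    ids = np.asarray(list(genotype_ids), dtype=object)
    n = len(ids)
    if len(set(ids)) != n:
        raise ValueError("genotype IDs must be unique")
    if n_envs < 1 or no_per_env < 0 or o_count < 0:
        raise ValueError("n_envs >= 1 and NO, O >= 0 required")
    need = n_envs * no_per_env + o_count
    if need > n:
        raise ValueError(
            f"infeasible design: {n_envs} x NO={no_per_env} + O={o_count} "
            f"= {need} genotypes needed but only {n} available "
            f"(short by {need - n})"
        )
    if env_ids is None:
        env_ids = tuple(f"Env{i + 1}" for i in range(n_envs))
    else:
        env_ids = tuple(env_ids)
        if len(env_ids) != n_envs:
            raise ValueError("env_ids length must equal n_envs")

    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    overlap = ids[perm[:o_count]]
    env_sets = []
    pos = o_count
    for _ in range(n_envs):
        no_set = ids[perm[pos: pos + no_per_env]]
        pos += no_per_env
        env_sets.append(tuple(np.concatenate([overlap, no_set])))

    calibration = frozenset(
        (env, g) for env, genos in zip(env_ids, env_sets) for g in genos
    )
    prediction = frozenset(
        (env, g) for env in env_ids for g in ids if (env, g) not in calibration
    )
    return AllocationDesign(
        genotype_ids=tuple(ids),
        env_ids=env_ids,
        no_per_env=no_per_env,
        o_count=o_count,
        env_sets=tuple(env_sets),
        overlap_set=tuple(overlap),
        calibration_cells=calibration,
        prediction_cells=prediction,
        seed=seed,
    )


def design_summary(design: AllocationDesign, total_genotypes: int | None = None) -> dict:
    """Headline counts of a design.

    Returns the number of calibration plots, the per-environment sample size,
    how many genotypes are observed in exactly k environments (k = 0..n_envs)
    and the overlap percentage 100 * O / (NO + O).
    """
    if total_genotypes is None:
        total_genotypes = len(design.genotype_ids)
    counts = {g: 0 for g in design.genotype_ids}
    for _, g in design.calibration_cells:
        counts[g] += 1
    observed_in = {
        k: sum(1 for v in counts.values() if v == k) for k in range(design.n_envs + 1)
    }
    s = design.sample_size_per_env
    overlap_pct = 100.0 * design.o_count / s if s > 0 else float("nan")
    return {
        "n_plots": len(design.calibration_cells),
        "sample_size_per_env": s,
        "no_per_env": design.no_per_env,
        "o_count": design.o_count,
        "genotypes_observed_in_k_envs": observed_in,
        "n_unobserved_genotypes": observed_in[0],
        "overlap_pct": overlap_pct,
        "n_prediction_cells": len(design.prediction_cells),
    }


def enumerate_grid(
    total_genotypes: int,
    n_envs: int,
    sample_sizes: Sequence[int],
    o_step: int = 10,
) -> DesignGrid:
    """Enumerate the NO/O composition grid for the given per-environment sizes.

    For each sample size s the pairs are (s, 0), (s - o_step, o_step), ...
    stepping the overlap up by ``o_step`` while NO >= 1; the all-overlap
    design (0, s) is constructible via :func:`make_design` but is not part of
    the default grid.  Pairs infeasible for ``total_genotypes`` are excluded.
    """
    if o_step < 1:
        raise ValueError("o_step must be >= 1")
    rows = []
    for s in sample_sizes:
        pairs = []
        for o in range(0, s, o_step):
            no = s - o
            if no >= 1 and n_envs * no + o <= total_genotypes:
                pairs.append((no, o))
        rows.append((int(s), tuple(pairs)))
    return DesignGrid(rows=tuple(rows))
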