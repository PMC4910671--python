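"""Monte Carlo harness: the sample-size x categorization condition grid.

Each replication simulates one sample under the single-trait--multistate
population model, optionally coarsens it into k Likert categories, computes
the Pearson correlation matrix, fits both competing models to that same
matrix, and applies three decision rules: the exact-fit chi-square test at
alpha, the chi-square difference test between the models, and the
RMSEA < 0.08 convention.  A condition aggregates replications into the five
percentage outcomes; the default grid crosses five sample sizes (100, 500,
750, 1000, 5000) with four response scales (3, 5, 7 categories, continuous),
giving 20 cells.

Seeding: every replication draws from a stream derived from the base seed
and the (condition, replication, attempt) indices via ``SeedSequence`` spawn
keys, so a run is bit-reproducible and each replication is independently
re-runnable.  A replication whose categorized sample has a zero-variance
column (possible at n = 100 with 3 categories) is resampled with the next
attempt index and the event counted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import estimation, sem_models, synthetic_data
from .estimation import DecisionFlags, DeltaTest, FitResult
from .synthetic_data import DataMatrix, DegenerateSampleError, GeneratingParams

logger = logging.getLogger(__name__)

DEFAULT_SAMPLE_SIZES = (100, 500, 750, 1000, 5000)
DEFAULT_CATEGORIES = (3, 5, 7, "continuous")
DEFAULT_REPS = 1000
MAX_RESAMPLE_ATTEMPTS = 50


@dataclass(frozen=True)
class ConditionSpec:
    """One cell of the design: a sample size and a response scale."""

    n: int
    categories: int | str  # 3 | 5 | 7 | "continuous"

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("sample size must be positive")
        if self.categories != "continuous" and self.categories not in (
            synthetic_data.SUPPORTED_CATEGORIES
        ):
            raise ValueError(f"unsupported categories {self.categories!r}")

    @property
    def is_continuous(self) -> bool:
        return self.categories == "continuous"

    @property
    def label(self) -> str:
        cat = "Con." if self.is_continuous else str(self.categories)
        return f"n={self.n}, {cat}"


@dataclass(frozen=True)
class ReplicationRecord:
    """Both model fits and all decisions for one simulated sample."""

    condition: ConditionSpec
    replication: int
    seed: tuple[int, ...]
    fit1: FitResult
    fit2: FitResult
    delta: DeltaTest
    flags1: DecisionFlags
    flags2: DecisionFlags
    n_resampled: int = 0

    @property
    def converged(self) -> bool:
        return self.fit1.converged and self.fit2.converged


@dataclass(frozen=True)
class ConditionSummary:
    """The five outcome percentages for one condition.

    Denominator is the count of replications where both fits converged;
    ``n_attempted`` keeps the raw count so the difference is visible.
    """

    condition: ConditionSpec
    pct_accept_m1: float
    pct_accept_m2: float
    pct_delta_sig: float
    pct_rmsea_m1: float
    pct_rmsea_m2: float
    n_converged: int
    n_attempted: int
    n_resampled: int = 0


def condition_grid(
    sample_sizes: Sequence[int] = DEFAULT_SAMPLE_SIZES,
    categories: Sequence[int | str] = DEFAULT_CATEGORIES,
) -> list[ConditionSpec]:
    """The full factorial grid, ordered by sample size then scale."""
    if not sample_sizes or not categories:
        raise ValueError("sample_sizes and categories must be non-empty")
    return [
        ConditionSpec(n=n, categories=c) for n in sample_sizes for c in categories
    ]


def _replication_seed(base_seed: int, cond_index: int, rep: int, attempt: int):
    """Stable per-replication stream: SeedSequence spawn key derived from the
    condition, replication and resampling-attempt indices."""
    return np.random.SeedSequence(
        base_seed, spawn_key=(cond_index, rep, attempt)
    )


def _simulate_matrix(
    cond: ConditionSpec,
    params: GeneratingParams,
    base_seed: int,
    cond_index: int,
    rep: int,
) -> tuple[np.ndarray, tuple[int, ...], int]:
    """Sample, categorize, correlate; resample on a degenerate column."""
    for attempt in range(MAX_RESAMPLE_ATTEMPTS):
        seq = _replication_seed(base_seed, cond_index, rep, attempt)
        data: DataMatrix = synthetic_data.simulate_sample(params, cond.n, seq)
        if not cond.is_continuous:
            data = synthetic_data.discretize(data, int(cond.categories))
        try:
            r = synthetic_data.pearson_matrix(data)
        except DegenerateSampleError:
            logger.info(
                "degenerate sample (%s, rep %d, attempt %d); resampling",
                cond.label, rep, attempt,
            )
            continue
        return r, (base_seed, cond_index, rep, attempt), attempt
    raise RuntimeError(
        f"exceeded {MAX_RESAMPLE_ATTEMPTS} resampling attempts for {cond.label}"
    )


def run_replication(
    cond: ConditionSpec,
    params: GeneratingParams,
    base_seed: int,
    cond_index: int = 0,
    rep: int = 0,
    alpha: float = 0.05,
    rmsea_cut: float = 0.08,
) -> ReplicationRecord:
    """One full replication: simulate, correlate, fit both models, decide."""
    r, seed, n_resampled = _simulate_matrix(
        cond, params, base_seed, cond_index, rep
    )
    spec1 = sem_models.model1_spec()
    spec2 = sem_models.model2_spec()
    fit1 = estimation.fit(spec1, r, cond.n)
    fit2 = estimation.fit(spec2, r, cond.n)
    delta = estimation.delta_chi2_test(fit1, fit2, alpha=alpha)
    return ReplicationRecord(
        condition=cond,
        replication=rep,
        seed=seed,
        fit1=fit1,
        fit2=fit2,
        delta=delta,
        flags1=estimation.decide(fit1, alpha, rmsea_cut),
        flags2=estimation.decide(fit2, alpha, rmsea_cut),
        n_resampled=n_resampled,
    )


def summarize(
    cond: ConditionSpec, records: Iterable[ReplicationRecord]
) -> ConditionSummary:
    records = list(records)
    ok = [r for r in records if r.converged]
    m = len(ok)

    def pct(flags: Iterable[bool]) -> float:
        return 100.0 * sum(flags) / m if m else float("nan")

    return ConditionSummary(
        condition=cond,
        pct_accept_m1=pct(r.flags1.accept_h0 for r in ok),
        pct_accept_m2=pct(r.flags2.accept_h0 for r in ok),
        pct_delta_sig=pct(r.delta.significant for r in ok),
        pct_rmsea_m1=pct(r.flags1.rmsea_ok for r in ok),
        pct_rmsea_m2=pct(r.flags2.rmsea_ok for r in ok),
        n_converged=m,
        n_attempted=len(records),
        n_resampled=sum(r.n_resampled for r in records),
    )


def run_condition(
    cond: ConditionSpec,
    params: GeneratingParams | None = None,
    reps: int = DEFAULT_REPS,
    base_seed: int = 0,
    cond_index: int = 0,
    progress_every: int = 0,
) -> ConditionSummary:
    """Run ``reps`` replications of one condition and aggregate them."""
    if reps < 1:
        raise ValueError("reps must be >= 1")
    params = params or synthetic_data.default_params()
    records = []
    for rep in range(reps):
        records.append(
            run_replication(cond, params, base_seed, cond_index, rep)
        )
        if progress_every and (rep + 1) % progress_every == 0:
            logger.info("%s: %d/%d replications", cond.label, rep + 1, reps)
    summary = summarize(cond, records)
    logger.info(
        "%s: accept M1=%.1f%% M2=%.1f%% | delta sig=%.1f%% | "
        "RMSEA<cut M1=%.1f%% M2=%.1f%% (%d/%d converged)",
        cond.label, summary.pct_accept_m1, summary.pct_accept_m2,
        summary.pct_delta_sig, summary.pct_rmsea_m1, summary.pct_rmsea_m2,
        summary.n_converged, summary.n_attempted,
    )
    return summary


def run_grid(
    params: GeneratingParams | None = None,
    reps: int = DEFAULT_REPS,
    base_seed: int = 0,
    sample_sizes: Sequence[int] = DEFAULT_SAMPLE_SIZES,
    categories: Sequence[int | str] = DEFAULT_CATEGORIES,
) -> pd.DataFrame:
    """Run the full grid; one row per condition, mirroring the five outcome
    columns (percent accepted H0 per model, percent significant chi-square
    difference, percent RMSEA below cutoff per model)."""
    params = params or synthetic_data.default_params()
    grid = condition_grid(sample_sizes, categories)
    rows = []
    for idx, cond in enumerate(grid):
        s = run_condition(
            cond, params, reps=reps, base_seed=base_seed, cond_index=idx
        )
        rows.append(summary_to_row(s))
    return pd.DataFrame(rows)


def summary_to_row(s: ConditionSummary) -> dict:
    cat = "Con." if s.condition.is_continuous else str(s.condition.categories)
    return {
        "n": s.condition.n,
        "categories": cat,
        "pct_accept_m1": s.pct_accept_m1,
        "pct_accept_m2": s.pct_accept_m2,
        "pct_delta_sig": s.pct_delta_sig,
        "pct_rmsea_m1": s.pct_rmsea_m1,
        "pct_rmsea_m2": s.pct_rmsea_m2,
        "n_converged": s.n_converged,
        "n_attempted": s.n_attempted,
        "n_resampled": s.n_resampled,
    }


def to_long_form(table: pd.DataFrame) -> pd.DataFrame:
    """Long-form (condition, metric, value) view of a grid results table."""
    metrics = [
        "pct_accept_m1", "pct_accept_m2", "pct_delta_sig",
        "pct_rmsea_m1", "pct_rmsea_m2",
    ]
    return table.melt(
        id_vars=["n", "categories"], value_vars=metrics,
        var_name="metric", value_name="value",
    )


def records_to_frame(records: Iterable[ReplicationRecord]) -> pd.DataFrame:
    """Per-replication records as a flat table (streamable to CSV)."""
    rows = []
    for r in records:
        rows.append(
            {
                "n": r.condition.n,
                "categories": "Con." if r.condition.is_continuous
                else r.condition.categories,
                "replication": r.replication,
                "seed": ":".join(str(s) for s in r.seed),
                "chi2_m1": r.fit1.chi2,
                "chi2_m2": r.fit2.chi2,
                "df_m1": r.fit1.df,
                "df_m2": r.fit2.df,
                "p_m1": r.fit1.p_value,
                "p_m2": r.fit2.p_value,
                "rmsea_m1": r.fit1.rmsea,
                "rmsea_m2": r.fit2.rmsea,
                "delta_chi2": r.delta.delta_chi2,
                "delta_df": r.delta.delta_df,
                "delta_p": r.delta.p_value,
                "converged_m1": r.fit1.converged,
                "converged_m2": r.fit2.converged,
            }
        )
    return pd.DataFrame(rows)
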