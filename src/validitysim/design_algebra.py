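"""Implied moment equalities of the non-equivalent control-group design.

Crossing measurement occasion (pre-test f0, post-test f1) with group
(control X=0, experimental X=1) gives a 4 x 4 table of variances and
covariances over the units' scores.  Under the classical-test-theory null —
each unit carries one stable true score, no treatment effect and no threat —
two sets of moments are implied equal:

* set **A**: the pre-test control-experimental covariance equals both
  pre-test variances, the control post-test variance, and the control
  pre-post covariance;
* set **B**: the experimental pre-post covariance equals the post-test
  control-experimental covariance and the cross (pre-control,
  post-experimental) covariance.

A treatment effect or a threat acting on the experimental post-test
perturbs only the moments touching that cell, which is what makes the
equalities testable: a violated member localizes the disturbance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: cell order of the moment table
CELLS = ("pre_control", "pre_exptal", "post_control", "post_exptal")

#: printable labels, matching the standard design notation
CELL_LABELS = {
    "pre_control": "f0/X=0",
    "pre_exptal": "f0/X=1",
    "post_control": "f1/X=0",
    "post_exptal": "f1/X=1",
}


@dataclass(frozen=True)
class DesignMoments:
    """The 4 x 4 variance-covariance table over design cells."""

    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (4, 4):
            raise ValueError("moment table must be 4 x 4")
        if not np.allclose(m, m.T):
            raise ValueError("moment table must be symmetric")
        if np.any(np.diag(m) <= 0):
            raise ValueError("variances must be positive")
        object.__setattr__(self, "matrix", (m + m.T) / 2.0)

    def get(self, a: str, b: str) -> float:
        return float(self.matrix[CELLS.index(a), CELLS.index(b)])

    def to_frame(self) -> pd.DataFrame:
        labels = [CELL_LABELS[c] for c in CELLS]
        return pd.DataFrame(self.matrix, index=labels, columns=labels)


@dataclass(frozen=True)
class EqualitySet:
    """A named list of moment labels asserted equal under the design null."""

    name: str
    members: tuple[tuple[str, str], ...]

    def values(self, moments: DesignMoments) -> dict[str, float]:
        return {
            _label(a, b): moments.get(a, b) for a, b in self.members
        }


def _label(a: str, b: str) -> str:
    if a == b:
        return f"S2[{CELL_LABELS[a]}]"
    return f"S[{CELL_LABELS[a]},{CELL_LABELS[b]}]"


def implied_equalities() -> tuple[EqualitySet, EqualitySet]:
    """The two equality sets implied by the design (5 members and 3)."""
    set_a = EqualitySet(
        name="A",
        members=(
            ("pre_control", "pre_exptal"),    # S[f0,f0/X=1,X=0]
            ("pre_control", "pre_control"),   # S2[f0/X=0]
            ("pre_exptal", "pre_exptal"),     # S2[f0/X=1]
            ("post_control", "post_control"), # S2[f1/X=0]
            ("pre_control", "post_control"),  # S[f1,f0/X=0]
        ),
    )
    set_b = EqualitySet(
        name="B",
        members=(
            ("pre_exptal", "post_exptal"),    # S[f1,f0/X=1]
            ("post_control", "post_exptal"),  # S[f1,f1/X=0,X=1]
            ("pre_control", "post_exptal"),   # S[f1,f0/X=1,X=0]
        ),
    )
    return set_a, set_b


def simulate_design(
    true_score_var: float,
    error_var: float,
    treatment_shift_var: float,
    threat_shift_var: float,
    n: int,
    seed: int | np.random.SeedSequence = 0,
) -> DesignMoments:
    """Simulate the four-cell design under the CTT score model.

    Each unit has one stable true score (variance ``true_score_var``); the
    observed score in each cell adds an independent error (variance
    ``error_var``).  Treatment and threat components, when their variances
    are positive, are independent shifts added to the experimental
    post-test only.  Returns the empirical moment table of the four
    observed-score columns.
    """
    if min(true_score_var, error_var, treatment_shift_var, threat_shift_var) < 0:
        raise ValueError("variances must be nonnegative")
    if n < 10:
        raise ValueError("need n >= 10 units")
    rng = np.random.default_rng(seed)
    true = rng.normal(0.0, np.sqrt(true_score_var), size=n)
    scores = np.empty((n, 4))
    for k in range(4):
        scores[:, k] = true + rng.normal(0.0, np.sqrt(error_var), size=n)
    extra = treatment_shift_var + threat_shift_var
    if extra > 0:
        scores[:, 3] += rng.normal(0.0, np.sqrt(extra), size=n)
    return DesignMoments(np.cov(scores, rowvar=False))


def moments_from_frame(df: pd.DataFrame) -> DesignMoments:
    """Moment table from a long table with columns (unit, group, pre, post).

    ``group`` is 0/1 or 'control'/'experimental'.  Units must appear in both
    groups (the counterfactual bookkeeping of the design null); scores are
    matched on ``unit``.
    """
    df = df.copy()
    df["group"] = df["group"].map(
        lambda g: {"control": 0, "experimental": 1, "exptal": 1}.get(g, g)
    )
    wide = df.pivot(index="unit", columns="group", values=["pre", "post"])
    cols = [("pre", 0), ("pre", 1), ("post", 0), ("post", 1)]
    missing = [c for c in cols if c not in wide.columns]
    if missing or wide.isna().any().any():
        raise ValueError("every unit needs pre and post scores in both groups")
    return DesignMoments(np.cov(wide[cols].to_numpy(), rowvar=False))


@dataclass(frozen=True)
class EqualityReport:
    """Per-set outcome of a tolerance check."""

    name: str
    passed: bool
    max_rel_deviation: float
    values: dict[str, float]


def check_equalities(
    moments: DesignMoments, tol: float = 0.05
) -> dict[str, EqualityReport]:
    """Check both equality sets at a relative tolerance.

    A set passes when the maximum pairwise relative difference among its
    members (relative to the mean absolute member) is at most ``tol``.
    Scale-invariant: multiplying all moments by a constant changes nothing.
    """
    reports = {}
    for eq in implied_equalities():
        vals = eq.values(moments)
        arr = np.array(list(vals.values()))
        scale = np.mean(np.abs(arr))
        dev = 0.0 if scale == 0 else float((arr.max() - arr.min()) / scale)
        reports[eq.name] = EqualityReport(
            name=eq.name,
            passed=bool(dev <= tol),
            max_rel_deviation=dev,
            values=vals,
        )
    return reports
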