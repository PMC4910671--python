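"""Population model and data generation.

The generating model is a single-trait--multistate structure: four latent
state factors eta_1..eta_4, each measured by three indicators with a common
loading lambda, a trait factor f0 feeding all four states, and a threat
factor T feeding states 3 and 4 only.  Structural equation per state j:

    eta_j = gamma_j * f0 + tau_j * T + zeta_j,     Var(eta_j) = 1

and per indicator i of state j:

    Y_i = lambda * eta_j + delta_i,                Var(Y_i) = 1

with f0, T, zeta, delta mutually independent zero-mean normals.  Unit state
and indicator variances make every observed variable marginally N(0, 1).
Continuous indicators can be coarsened into k equal-width Likert categories
on [-3, 3], which restricts range and attenuates Pearson correlations.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

N_STATES = 4
N_IND_PER_STATE = 3
N_INDICATORS = N_STATES * N_IND_PER_STATE

#: column labels Y1..Y12; Y1..Y3 load on eta_1, ..., Y10..Y12 on eta_4
COLUMNS = tuple(f"Y{i + 1}" for i in range(N_INDICATORS))

SUPPORTED_CATEGORIES = (3, 5, 7)


@dataclass(frozen=True)
class GeneratingParams:
    """Population parameters of the generating model.

    Invariants (checked by :meth:`validate`):

    * ``gamma[j]**2 + tau[j]**2 + zeta_var[j] == 1`` for every state j
      (unit state variance);
    * ``lambda_loading**2 + error_var[i] == 1`` for every indicator
      (unit marginal variance);
    * ``tau[0] == tau[1] == 0`` (the threat touches states 3 and 4 only).
    """

    lambda_loading: float = 0.8
    gamma: tuple[float, ...] = (0.4, 0.4, 0.4, 0.4)
    tau: tuple[float, ...] = (0.0, 0.0, 0.4, 0.4)
    zeta_var: tuple[float, ...] = field(default=None)  # type: ignore[assignment]
    error_var: tuple[float, ...] = field(default=None)  # type: ignore[assignment]
    n_indicators_per_state: int = N_IND_PER_STATE
    n_states: int = N_STATES

    def __post_init__(self):
        if self.zeta_var is None:
            zv = tuple(
                1.0 - g * g - t * t for g, t in zip(self.gamma, self.tau)
            )
            object.__setattr__(self, "zeta_var", zv)
        if self.error_var is None:
            ev = (1.0 - self.lambda_loading**2,) * (
                self.n_states * self.n_indicators_per_state
            )
            object.__setattr__(self, "error_var", ev)
        object.__setattr__(self, "gamma", tuple(float(g) for g in self.gamma))
        object.__setattr__(self, "tau", tuple(float(t) for t in self.tau))
        object.__setattr__(
            self, "zeta_var", tuple(float(z) for z in self.zeta_var)
        )
        object.__setattr__(
            self, "error_var", tuple(float(e) for e in self.error_var)
        )

    @property
    def n_indicators(self) -> int:
        return self.n_states * self.n_indicators_per_state

    def validate(self, atol: float = 1e-10) -> None:
        """Raise ``ValueError`` on any violated invariant."""
        if len(self.gamma) != self.n_states or len(self.tau) != self.n_states:
            raise ValueError("gamma and tau must have one entry per state")
        if len(self.zeta_var) != self.n_states:
            raise ValueError("zeta_var must have one entry per state")
        if len(self.error_var) != self.n_indicators:
            raise ValueError("error_var must have one entry per indicator")
        if abs(self.tau[0]) > atol or abs(self.tau[1]) > atol:
            raise ValueError("threat coefficients on states 1 and 2 must be 0")
        for j in range(self.n_states):
            tot = self.gamma[j] ** 2 + self.tau[j] ** 2 + self.zeta_var[j]
            if abs(tot - 1.0) > atol:
                raise ValueError(
                    f"state {j + 1} variance {tot:.6g} != 1 "
                    "(gamma^2 + tau^2 + zeta_var must be 1)"
                )
            if self.zeta_var[j] < 0:
                raise ValueError(f"negative disturbance variance, state {j+1}")
        lam2 = self.lambda_loading**2
        for i, ev in enumerate(self.error_var):
            if abs(lam2 + ev - 1.0) > atol:
                raise ValueError(
                    f"indicator {i + 1} marginal variance {lam2 + ev:.6g} != 1"
                )

    def to_dict(self) -> dict:
        return {
            "lambda_loading": self.lambda_loading,
            "gamma": list(self.gamma),
            "tau": list(self.tau),
            "zeta_var": list(self.zeta_var),
            "error_var": list(self.error_var),
            "n_indicators_per_state": self.n_indicators_per_state,
            "n_states": self.n_states,
        }

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratingParams":
        d = dict(d)
        for key in ("gamma", "tau", "zeta_var", "error_var"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, text: str) -> "GeneratingParams":
        return cls.from_dict(yaml.safe_load(text))


@dataclass(frozen=True)
class ThresholdVector:
    """Cutpoints of an equal-width Likert categorization on [-3, 3]."""

    cutpoints: tuple[float, ...]

    def __post_init__(self):
        cp = tuple(float(c) for c in self.cutpoints)
        object.__setattr__(self, "cutpoints", cp)
        if any(b <= a for a, b in zip(cp, cp[1:])):
            raise ValueError("cutpoints must be strictly increasing")
        if cp and (cp[0] <= -3.0 or cp[-1] >= 3.0):
            raise ValueError("cutpoints must lie strictly inside (-3, 3)")

    @property
    def n_categories(self) -> int:
        return len(self.cutpoints) + 1


@dataclass(frozen=True)
class DataMatrix:
    """An n x 12 table of indicator scores.

    ``scale_kind`` is ``"continuous"`` or ``"categorical-k"``; categorical
    entries are 1-based integer codes in ``1..k``.
    """

    values: pd.DataFrame
    scale_kind: str = "continuous"

    def __post_init__(self):
        df = self.values
        if list(df.columns) != list(COLUMNS[: df.shape[1]]):
            df = df.copy()
            df.columns = COLUMNS[: df.shape[1]]
            object.__setattr__(self, "values", df)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def is_continuous(self) -> bool:
        return self.scale_kind == "continuous"

    @property
    def n_categories(self) -> int | None:
        if self.is_continuous:
            return None
        return int(self.scale_kind.split("-")[1])

    def to_csv(self, path_or_buf=None) -> str | None:
        """Write a headered CSV with columns Y1..Y12."""
        return self.values.to_csv(path_or_buf, index=False)

    @classmethod
    def from_csv(cls, path_or_buf, scale_kind: str = "continuous") -> "DataMatrix":
        if isinstance(path_or_buf, str) and "\n" in path_or_buf:
            path_or_buf = io.StringIO(path_or_buf)
        return cls(pd.read_csv(path_or_buf), scale_kind=scale_kind)


def default_params() -> GeneratingParams:
    """Default population model: lambda = 0.8, gamma = 0.4 on all states,
    tau = 0.4 on states 3-4, disturbance and error variances filled so that
    every state and every indicator has unit variance.

    The structural magnitudes are calibrated so that the multistate model
    (which omits f0 and T) is a mild misspecification: its population RMSEA
    stays well below the 0.08 convention while its exact-fit chi-square test
    and the chi-square difference test reject essentially always from
    n = 500 on.
    """
    p = GeneratingParams()
    p.validate()
    return p


def population_sigma(params: GeneratingParams) -> np.ndarray:
    """Closed-form 12 x 12 population covariance of the indicators.

    Within a state, cov = lambda^2; across states j != m,
    cov = lambda^2 * (gamma_j gamma_m + tau_j tau_m); diagonal = 1.
    """
    params.validate()
    g = np.asarray(params.gamma)
    t = np.asarray(params.tau)
    # state covariance: gamma gamma' + tau tau' off-diagonal, 1 on diagonal
    phi = np.outer(g, g) + np.outer(t, t)
    np.fill_diagonal(phi, 1.0)
    lam = np.repeat(params.lambda_loading, params.n_indicators)
    state_of = np.repeat(np.arange(params.n_states), params.n_indicators_per_state)
    sigma = np.outer(lam, lam) * phi[np.ix_(state_of, state_of)]
    np.fill_diagonal(sigma, 1.0)
    return sigma


def simulate_sample(
    params: GeneratingParams, n: int, seed: int | np.random.SeedSequence
) -> DataMatrix:
    """Draw n rows from the generating model (continuous indicators).

    f0, T, the four state disturbances and the twelve indicator errors are
    independent normals; identical seed gives an identical matrix.
    """
    if n < 1:
        raise ValueError(f"sample size must be >= 1, got {n}")
    params.validate()
    rng = np.random.default_rng(seed)
    f0 = rng.standard_normal(n)
    thr = rng.standard_normal(n)
    zeta = rng.standard_normal((n, params.n_states)) * np.sqrt(params.zeta_var)
    eta = (
        np.outer(f0, params.gamma) + np.outer(thr, params.tau) + zeta
    )
    delta = rng.standard_normal((n, params.n_indicators)) * np.sqrt(
        params.error_var
    )
    state_of = np.repeat(np.arange(params.n_states), params.n_indicators_per_state)
    y = params.lambda_loading * eta[:, state_of] + delta
    return DataMatrix(pd.DataFrame(y, columns=COLUMNS), scale_kind="continuous")


def likert_thresholds(k: int) -> ThresholdVector:
    """k-1 equally spaced cutpoints dividing [-3, 3] into k equal intervals."""
    if k not in SUPPORTED_CATEGORIES:
        raise ValueError(
            f"unsupported category count {k}; expected one of {SUPPORTED_CATEGORIES}"
        )
    cut = tuple(-3.0 + 6.0 * i / k for i in range(1, k))
    return ThresholdVector(cut)


def discretize(data: DataMatrix, k: int) -> DataMatrix:
    """Map continuous scores to 1-based category codes.

    Values at or below the lowest cutpoint go to category 1; values above the
    highest cutpoint go to category k (scores outside [-3, 3] are clamped to
    the extreme categories rather than dropped).
    """
    if not data.is_continuous:
        raise ValueError("discretize expects a continuous DataMatrix")
    thr = likert_thresholds(k)
    codes = (
        np.searchsorted(np.asarray(thr.cutpoints), data.values.to_numpy(), side="left")
        + 1
    )
    return DataMatrix(
        pd.DataFrame(codes, columns=COLUMNS), scale_kind=f"categorical-{k}"
    )


class DegenerateSampleError(ValueError):
    """A column of the (categorized) sample has zero variance, so a Pearson
    correlation matrix cannot be formed.  The Monte Carlo harness catches
    this and resamples the replication."""


def pearson_matrix(data: DataMatrix) -> np.ndarray:
    """Pearson correlation matrix of the 12 columns.

    Computed on raw category codes when the matrix is categorical (the
    study deliberately uses product-moment, not polychoric, correlations).
    """
    x = data.values.to_numpy(dtype=float)
    if x.shape[0] < 3:
        raise ValueError("need at least 3 rows for a correlation matrix")
    sd = x.std(axis=0)
    if np.any(sd == 0.0):
        bad = [COLUMNS[i] for i in np.flatnonzero(sd == 0.0)]
        raise DegenerateSampleError(
            f"zero-variance column(s) {bad}; replication must be resampled"
        )
    r = np.corrcoef(x, rowvar=False)
    np.fill_diagonal(r, 1.0)
    return r


def params_to_json(params: GeneratingParams) -> str:
    return json.dumps(params.to_dict(), indent=2)
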