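"""Declarative confirmatory factor / structural model specifications.

Two competing measurement structures for the 12 indicators:

* **Model 1 (multistate)** — four mutually orthogonal state factors, three
  indicators each, factor variances fixed to 1.  Its implied covariance has
  identically zero cross-state blocks, so it cannot absorb a common trait or
  a threat running across states.
* **Model 2 (single-trait--multistate with threat)** — the same four state
  factors now driven by a common trait f0 (all states) and a threat factor T
  (states 3 and 4).  Under-identification is resolved by fixing four
  components to one: the f0 -> eta_1 path, the T -> eta_3 path, and the
  variances of f0 and T; the first loadings of eta_2 and eta_4 are fixed to
  one as reference indicators.

A :class:`ModelSpec` is an ordered table of parameter entries (free or fixed
with a value) over the matrices of the covariance-structure composition

    Sigma(theta) = Lambda (Gamma Phi Gamma' + Psi) Lambda' + Theta

with Lambda the indicator loadings, Gamma the exogenous-factor paths, Phi
the (diagonal, here fixed) exogenous variances, Psi the diagonal state
residual variances, and Theta the diagonal indicator error variances.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .synthetic_data import N_IND_PER_STATE, N_INDICATORS, N_STATES

ROLES = (
    "loading",
    "structural-path",
    "factor-variance",
    "disturbance-variance",
    "error-variance",
)
VARIANCE_ROLES = ("factor-variance", "disturbance-variance", "error-variance")


@dataclass(frozen=True)
class ParamEntry:
    """One cell of a model matrix.

    ``row``/``col`` index into the matrix named by ``role``: indicator x
    state for loadings, state x exogenous factor for structural paths, and
    the diagonal index for the three variance roles.
    """

    symbol: str
    role: str
    row: int
    col: int
    free: bool
    value: float | None = None

    def __post_init__(self):
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}")
        if not self.free and self.value is None:
            raise ValueError(f"fixed entry {self.symbol} needs a value")


@dataclass(frozen=True)
class ModelSpec:
    """Ordered free/fixed parameter table defining one model."""

    name: str
    entries: tuple[ParamEntry, ...]
    n_indicators: int = N_INDICATORS
    n_states: int = N_STATES
    n_exo: int = 0
    exo_names: tuple[str, ...] = field(default=())

    @property
    def free_entries(self) -> tuple[ParamEntry, ...]:
        return tuple(e for e in self.entries if e.free)

    @property
    def fixed_entries(self) -> tuple[ParamEntry, ...]:
        return tuple(e for e in self.entries if not e.free)

    @property
    def free_names(self) -> tuple[str, ...]:
        return tuple(e.symbol for e in self.free_entries)

    def to_table(self) -> str:
        """Plain-text TSV of the parameter table (editable, round-trips)."""
        lines = ["symbol\trole\trow\tcol\tstatus\tvalue"]
        for e in self.entries:
            status = "free" if e.free else "fixed"
            value = "" if e.value is None else repr(e.value)
            lines.append(f"{e.symbol}\t{e.role}\t{e.row}\t{e.col}\t{status}\t{value}")
        return "\n".join(lines) + "\n"

    def to_json(self) -> str:
        return json.dumps(
            {
                "name": self.name,
                "n_indicators": self.n_indicators,
                "n_states": self.n_states,
                "n_exo": self.n_exo,
                "exo_names": list(self.exo_names),
                "entries": [
                    {
                        "symbol": e.symbol,
                        "role": e.role,
                        "row": e.row,
                        "col": e.col,
                        "free": e.free,
                        "value": e.value,
                    }
                    for e in self.entries
                ],
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "ModelSpec":
        d = json.loads(text)
        entries = tuple(ParamEntry(**e) for e in d.pop("entries"))
        d["exo_names"] = tuple(d.get("exo_names", ()))
        return cls(entries=entries, **d)


@dataclass(frozen=True)
class ParameterVector:
    """Free-parameter values in the order of ``spec.free_entries``."""

    theta: np.ndarray

    def __post_init__(self):
        object.__setattr__(
            self, "theta", np.asarray(self.theta, dtype=float).ravel()
        )

    def __len__(self) -> int:
        return self.theta.size

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.theta, dtype=dtype)


def _as_theta(theta) -> np.ndarray:
    if isinstance(theta, ParameterVector):
        return theta.theta
    return np.asarray(theta, dtype=float).ravel()


def state_of_indicator(i: int, per_state: int = N_IND_PER_STATE) -> int:
    return i // per_state


def model1_spec() -> ModelSpec:
    """Multistate model: 4 orthogonal state factors, variances fixed to 1,
    12 free loadings, 12 free error variances (24 free, df = 54)."""
    entries: list[ParamEntry] = []
    for i in range(N_INDICATORS):
        j = state_of_indicator(i)
        entries.append(
            ParamEntry(f"lambda_{i + 1}", "loading", i, j, free=True)
        )
    for j in range(N_STATES):
        entries.append(
            ParamEntry(
                f"var_eta{j + 1}", "disturbance-variance", j, j,
                free=False, value=1.0,
            )
        )
    for i in range(N_INDICATORS):
        entries.append(
            ParamEntry(f"theta_{i + 1}", "error-variance", i, i, free=True)
        )
    return ModelSpec(name="multistate", entries=tuple(entries), n_exo=0)


def model2_spec() -> ModelSpec:
    """Single-trait--multistate model with threat T (30 free, df = 48).

    Four components are fixed to one for identification: the f0 -> eta_1 and
    T -> eta_3 paths and the variances of f0 and T.  The first loadings of
    eta_2 and eta_4 (whose scale no fixed path pins down) are fixed to one.
    """
    entries: list[ParamEntry] = []
    # loadings: eta_1 and eta_3 fully free (scale set by the fixed structural
    # paths); eta_2 and eta_4 use a fixed reference indicator
    for i in range(N_INDICATORS):
        j = state_of_indicator(i)
        first = i % N_IND_PER_STATE == 0
        if j in (1, 3) and first:
            entries.append(
                ParamEntry(
                    f"lambda_{i + 1}", "loading", i, j, free=False, value=1.0
                )
            )
        else:
            entries.append(
                ParamEntry(f"lambda_{i + 1}", "loading", i, j, free=True)
            )
    # structural paths: column 0 = f0, column 1 = T
    entries.append(
        ParamEntry("beta_f0_eta1", "structural-path", 0, 0, free=False, value=1.0)
    )
    for j in (1, 2, 3):
        entries.append(
            ParamEntry(f"beta_f0_eta{j + 1}", "structural-path", j, 0, free=True)
        )
    entries.append(
        ParamEntry("beta_T_eta3", "structural-path", 2, 1, free=False, value=1.0)
    )
    entries.append(
        ParamEntry("beta_T_eta4", "structural-path", 3, 1, free=True)
    )
    entries.append(
        ParamEntry("var_f0", "factor-variance", 0, 0, free=False, value=1.0)
    )
    entries.append(
        ParamEntry("var_T", "factor-variance", 1, 1, free=False, value=1.0)
    )
    for j in range(N_STATES):
        entries.append(
            ParamEntry(f"psi_{j + 1}", "disturbance-variance", j, j, free=True)
        )
    for i in range(N_INDICATORS):
        entries.append(
            ParamEntry(f"theta_{i + 1}", "error-variance", i, i, free=True)
        )
    return ModelSpec(
        name="singletrait-multistate",
        entries=tuple(entries),
        n_exo=2,
        exo_names=("f0", "T"),
    )


def count_free(spec: ModelSpec) -> int:
    return len(spec.free_entries)


def count_df(spec: ModelSpec) -> int:
    """Parameter-count degrees of freedom: p(p+1)/2 distinct moments minus
    free parameters.  See :func:`effective_df` for the rank-based count that
    the test statistics use."""
    p = spec.n_indicators
    return p * (p + 1) // 2 - count_free(spec)


def effective_df(spec: ModelSpec, theta) -> int:
    """Degrees of freedom from the rank of the implied-covariance Jacobian.

    The single-trait--multistate model carries one intrinsic parameter
    redundancy: the threat factor's variance contributions to its two state
    factors are absorbed by their free disturbance variances, so only the
    cross-state excess covariance identifies a threat parameter and the
    Jacobian of vech Sigma(theta) has rank 29, not 30.  The chi-square
    reference distribution of the exact-fit test therefore has
    p(p+1)/2 - rank degrees of freedom (49 here); using the naive parameter
    count (48) would leave the test miscalibrated.  For identified models
    (the multistate model, saturated-rank toys) this equals
    :func:`count_df`.
    """
    _, grads = implied_sigma_and_grad(spec, theta)
    p = spec.n_indicators
    iu = np.triu_indices(p)
    jac = np.array([g[iu] for g in grads]).T
    if jac.size == 0:
        rank = 0
    else:
        sv = np.linalg.svd(jac, compute_uv=False)
        rank = int(np.sum(sv > 1e-8 * sv[0]))
    return p * (p + 1) // 2 - rank


def _build_matrices(spec: ModelSpec, theta) -> tuple[np.ndarray, ...]:
    theta = _as_theta(theta)
    if theta.size != count_free(spec):
        raise ValueError(
            f"theta has {theta.size} entries, spec has {count_free(spec)} free"
        )
    lam = np.zeros((spec.n_indicators, spec.n_states))
    gamma = np.zeros((spec.n_states, spec.n_exo))
    phi = np.zeros(spec.n_exo)
    psi = np.zeros(spec.n_states)
    theta_d = np.zeros(spec.n_indicators)
    k = 0
    for e in spec.entries:
        v = theta[k] if e.free else e.value
        if e.free:
            k += 1
        if e.role == "loading":
            lam[e.row, e.col] = v
        elif e.role == "structural-path":
            gamma[e.row, e.col] = v
        elif e.role == "factor-variance":
            phi[e.row] = v
        elif e.role == "disturbance-variance":
            psi[e.row] = v
        else:
            theta_d[e.row] = v
    return lam, gamma, phi, psi, theta_d


def implied_sigma(spec: ModelSpec, theta) -> np.ndarray:
    """Model-implied covariance Sigma(theta) = Lambda Phi_eta Lambda' + Theta
    with Phi_eta = Gamma Phi Gamma' + Psi."""
    lam, gamma, phi, psi, theta_d = _build_matrices(spec, theta)
    phi_eta = (gamma * phi) @ gamma.T + np.diag(psi)
    sigma = lam @ phi_eta @ lam.T + np.diag(theta_d)
    return (sigma + sigma.T) / 2.0


def implied_sigma_and_grad(
    spec: ModelSpec, theta
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Sigma(theta) plus the list of derivative matrices dSigma/dtheta_k,
    one 12 x 12 (symmetric) matrix per free parameter, in spec order."""
    lam, gamma, phi, psi, theta_d = _build_matrices(spec, theta)
    phi_eta = (gamma * phi) @ gamma.T + np.diag(psi)
    sigma = lam @ phi_eta @ lam.T + np.diag(theta_d)
    sigma = (sigma + sigma.T) / 2.0
    lam_phi = lam @ phi_eta  # p x m, column j = Lambda Phi_eta e_j
    grads: list[np.ndarray] = []
    p = spec.n_indicators
    for e in spec.free_entries:
        d = np.zeros((p, p))
        if e.role == "loading":
            # dLambda = E[row, col]
            d[e.row, :] = lam_phi[:, e.col]
            d += d.T  # adds the transposed term; doubles the (row,row) cell
        elif e.role == "structural-path":
            # dPhi_eta = E_jk Phi Gamma' + Gamma Phi E_kj
            v = lam[:, :] @ (phi[e.col] * gamma[:, e.col])  # Lambda Gamma Phi e_k
            d = np.outer(lam[:, e.row], v)
            d += d.T
        elif e.role == "factor-variance":
            u = lam @ gamma[:, e.row]
            d = np.outer(u, u)
        elif e.role == "disturbance-variance":
            d = np.outer(lam[:, e.row], lam[:, e.row])
        else:  # error-variance
            d[e.row, e.row] = 1.0
        grads.append(d)
    return sigma, grads


def start_values(spec: ModelSpec, S: np.ndarray) -> ParameterVector:
    """Deterministic starting vector: free loadings at 0.7 times the sign of
    the correlation with the factor's first indicator (sign 0 -> +), free
    variances at 0.5, free structural paths at 0.3."""
    S = np.asarray(S, dtype=float)
    eig_min = np.linalg.eigvalsh(S).min()
    if eig_min <= 0:
        raise ValueError(
            f"input matrix is not positive-definite (min eigenvalue {eig_min:.3g})"
        )
    first_ind = {}
    for e in spec.entries:
        if e.role == "loading" and e.col not in first_ind:
            first_ind[e.col] = e.row
    vals = []
    for e in spec.free_entries:
        if e.role == "loading":
            r = S[e.row, first_ind[e.col]]
            sign = -1.0 if r < 0 else 1.0
            vals.append(0.7 * sign)
        elif e.role == "structural-path":
            vals.append(0.3)
        else:
            vals.append(0.5)
    return ParameterVector(np.array(vals))
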