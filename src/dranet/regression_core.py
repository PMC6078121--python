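"""Model-family computations for distributed regression analysis.

Each data partner evaluates *local* aggregate statistics on its own
patient-level data — a sums-of-squares-and-cross-products (SSCP) block for
linear regression, or a score vector / observed-information matrix /
log-likelihood triple for logistic and Cox models at a supplied parameter
vector.  Because all three statistics are sums over independent patients
(for Cox, over within-site risk sets), they are additive across partners:
the analysis center recovers the pooled quantities by elementwise summation
and drives an ordinary Newton–Raphson iteration without ever seeing a
patient-level row.

Cox models are *site-stratified*: every partner forms risk sets only within
its own data, so the distributed fit is exactly a pooled Cox model with one
baseline hazard per site (Breslow tie handling).  This keeps each partner's
contribution additive and avoids sharing per-event-time aggregates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Family",
    "DesignSpec",
    "BetaState",
    "LinearSummaries",
    "ScoreInfo",
    "ConvergenceState",
    "ConvergenceStatus",
    "FitResult",
    "SchemaError",
    "DataError",
    "EstimationError",
    "ProtocolError",
    "build_model_matrix",
    "linear_local_summaries",
    "linear_solve",
    "logistic_local_score_info",
    "cox_local_score_info",
    "aggregate_statistics",
    "newton_step",
    "assess_convergence",
    "wald_inference",
]

#: Normal quantile used for all 95% Wald intervals, every family.
Z_95 = 1.959964


class SchemaError(ValueError):
    """A required column is missing or mis-typed in an analytic dataset."""


class DataError(ValueError):
    """Patient-level values violate a model precondition (missingness, range)."""


class EstimationError(RuntimeError):
    """The estimation problem is degenerate (rank deficiency, separation)."""


class ProtocolError(RuntimeError):
    """Partners and center disagree about iteration index, dimension, or family."""


class Family(str, Enum):
    LINEAR = "linear"
    LOGISTIC = "logistic"
    COX = "cox"


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DesignSpec:
    """Model design shared by every node in a run.

    The column order is part of the distributed analysis package: all
    partners must build their model matrices in the identical order or the
    aggregated statistics would be meaningless.
    """

    family: Family
    covariate_columns: tuple[str, ...]
    outcome_column: str | None = None
    time_column: str | None = None
    event_column: str | None = None
    include_intercept: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "family", Family(self.family))
        object.__setattr__(self, "covariate_columns", tuple(self.covariate_columns))
        if not self.covariate_columns:
            raise SchemaError("covariate_columns must be non-empty")
        if len(set(self.covariate_columns)) != len(self.covariate_columns):
            raise SchemaError("covariate_columns contains duplicates")
        if self.family is Family.COX:
            if self.time_column is None or self.event_column is None:
                raise SchemaError("cox family requires time_column and event_column")
            # The Cox partial likelihood is invariant to an intercept shift;
            # an intercept column would make the information singular.
            object.__setattr__(self, "include_intercept", False)
        else:
            if self.outcome_column is None:
                raise SchemaError(f"{self.family.value} family requires outcome_column")
            object.__setattr__(self, "include_intercept", True)

    @property
    def p(self) -> int:
        """Number of model-matrix columns."""
        return len(self.covariate_columns) + (1 if self.include_intercept else 0)

    @property
    def model_column_names(self) -> tuple[str, ...]:
        names = ("(Intercept)",) if self.include_intercept else ()
        return names + self.covariate_columns


@dataclass(frozen=True)
class BetaState:
    """A parameter 'guess' broadcast by the analysis center."""

    iteration: int
    beta: np.ndarray
    job_done: bool = False

    def __post_init__(self) -> None:
        beta = np.asarray(self.beta, dtype=float)
        object.__setattr__(self, "beta", beta)
        if self.iteration < 0:
            raise ProtocolError("iteration must be non-negative")
        if not np.all(np.isfinite(beta)):
            raise ProtocolError("beta contains non-finite entries")


@dataclass(frozen=True)
class LinearSummaries:
    """SSCP aggregates for distributed least squares.

    Additive: the summaries of concatenated data equal the elementwise sum
    of per-part summaries, which is what lets the center solve the pooled
    normal equations.
    """

    n: int
    xtx: np.ndarray
    xty: np.ndarray
    yty: float
    iteration: int = 1

    def __add__(self, other: "LinearSummaries") -> "LinearSummaries":
        if self.xtx.shape != other.xtx.shape:
            raise ProtocolError("mismatched SSCP dimensions")
        return LinearSummaries(
            n=self.n + other.n,
            xtx=self.xtx + other.xtx,
            xty=self.xty + other.xty,
            yty=self.yty + other.yty,
            iteration=self.iteration,
        )


@dataclass(frozen=True)
class ScoreInfo:
    """Score / observed information / log-likelihood at a fixed beta."""

    n: int
    n_events: int
    gradient: np.ndarray
    information: np.ndarray
    loglik: float
    iteration: int

    def __add__(self, other: "ScoreInfo") -> "ScoreInfo":
        if self.gradient.shape != other.gradient.shape:
            raise ProtocolError("mismatched score dimensions")
        return ScoreInfo(
            n=self.n + other.n,
            n_events=self.n_events + other.n_events,
            gradient=self.gradient + other.gradient,
            information=self.information + other.information,
            loglik=self.loglik + other.loglik,
            iteration=self.iteration,
        )


class ConvergenceState(str, Enum):
    CONTINUING = "continuing"
    CONVERGED = "converged"
    MAX_ITERATIONS_REACHED = "max_iterations_reached"
    FAILED = "failed"


@dataclass(frozen=True)
class ConvergenceStatus:
    state: ConvergenceState
    iteration: int
    max_abs_delta: float
    loglik_delta: float
    message: str = ""

    @property
    def terminal(self) -> bool:
        return self.state is not ConvergenceState.CONTINUING


@dataclass
class FitResult:
    """Converged (or terminal) estimates with Wald inference and history."""

    family: Family
    beta_hat: np.ndarray
    cov: np.ndarray
    se: np.ndarray
    wald_z: np.ndarray
    ci95: np.ndarray
    loglik_final: float
    sigma2: float
    n_total: int
    n_events_total: int
    n_iterations: int
    converged: bool
    status: ConvergenceState
    column_names: tuple[str, ...] = ()
    history: list[tuple[int, np.ndarray, float, float]] = field(default_factory=list)
    diagnostics: dict | None = None

    def summary_frame(self) -> pd.DataFrame:
        names = self.column_names or tuple(f"b{i}" for i in range(self.beta_hat.size))
        return pd.DataFrame(
            {
                "coef": self.beta_hat,
                "se": self.se,
                "z": self.wald_z,
                "ci95_low": self.ci95[:, 0],
                "ci95_high": self.ci95[:, 1],
            },
            index=list(names),
        )


# ---------------------------------------------------------------------------
# Model matrix
# ---------------------------------------------------------------------------


def build_model_matrix(
    dataset: pd.DataFrame, spec: DesignSpec
) -> tuple[np.ndarray, np.ndarray] | tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Assemble (X, y) — or (X, time, event) for Cox — from an analytic dataset.

    Raises :class:`SchemaError` for absent columns and :class:`DataError`
    for missing values; missing data are never dropped silently because a
    complete-case decision belongs upstream, at dataset assembly.
    """
    needed = list(spec.covariate_columns)
    if spec.family is Family.COX:
        needed += [spec.time_column, spec.event_column]
    else:
        needed += [spec.outcome_column]
    for col in needed:
        if col not in dataset.columns:
            raise SchemaError(f"dataset is missing required column {col!r}")
    used = dataset[needed]
    n_missing = int(used.isna().any(axis=1).sum())
    if n_missing:
        raise DataError(
            f"{n_missing} row(s) have missing values in model columns; "
            "resolve missingness upstream"
        )
    covs = used[list(spec.covariate_columns)].to_numpy(dtype=float)
    if spec.include_intercept:
        X = np.column_stack([np.ones(len(used)), covs])
    else:
        X = covs
    if spec.family is Family.COX:
        time = used[spec.time_column].to_numpy(dtype=float)
        event = used[spec.event_column].to_numpy(dtype=float)
        return X, time, event
    y = used[spec.outcome_column].to_numpy(dtype=float)
    return X, y


# ---------------------------------------------------------------------------
# Linear family
# ---------------------------------------------------------------------------


def linear_local_summaries(X: np.ndarray, y: np.ndarray) -> LinearSummaries:
    """SSCP blocks X'X, X'y, y'y for one partner (beta-independent)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[0] != y.shape[0]:
        raise DataError("X and y row counts disagree")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise DataError("non-finite values in model matrix or outcome")
    if X.shape[0] == 0:
        p = X.shape[1]
        return LinearSummaries(0, np.zeros((p, p)), np.zeros(p), 0.0)
    return LinearSummaries(
        n=X.shape[0], xtx=X.T @ X, xty=X.T @ y, yty=float(y @ y)
    )


def _solve_spd(mat: np.ndarray, rhs: np.ndarray, context: str) -> np.ndarray:
    """Solve a symmetric positive-definite system, failing loudly if singular."""
    try:
        c = np.linalg.cholesky(mat)
    except np.linalg.LinAlgError as exc:
        raise EstimationError(
            f"{context}: matrix is singular or not positive definite "
            "(check for collinear covariates or, for logistic models, "
            "complete separation)"
        ) from exc
    z = np.linalg.solve(c, rhs)
    return np.linalg.solve(c.T, z)


def _inv_spd(mat: np.ndarray, context: str) -> np.ndarray:
    return _solve_spd(mat, np.eye(mat.shape[0]), context)


def linear_solve(total: LinearSummaries, p: int) -> FitResult:
    """Solve the pooled normal equations from aggregated SSCP blocks.

    beta solves (X'X) beta = X'y; the residual variance comes from the
    identity RSS = y'y - 2 beta'X'y + beta'X'X beta, so no residual vector
    is ever formed.  Single shot: linear regression needs no iteration.
    """
    if total.n <= p:
        raise EstimationError(
            f"insufficient data: n={total.n} must exceed p={p}"
        )
    beta = _solve_spd(total.xtx, total.xty, "linear normal equations")
    rss = float(total.yty - 2.0 * beta @ total.xty + beta @ total.xtx @ beta)
    sigma2 = max(rss, 0.0) / (total.n - p)
    cov = sigma2 * _inv_spd(total.xtx, "linear covariance")
    return _make_fit_result(
        Family.LINEAR,
        beta,
        cov,
        loglik_final=math.nan,
        sigma2=sigma2,
        n_total=total.n,
        n_events_total=0,
        n_iterations=1,
        converged=True,
        status=ConvergenceState.CONVERGED,
    )


# ---------------------------------------------------------------------------
# Logistic family
# ---------------------------------------------------------------------------

_LOG_GUARD = 1e-300


def logistic_local_score_info(
    X: np.ndarray, y: np.ndarray, beta: np.ndarray, iteration: int = 0
) -> ScoreInfo:
    """Score X'(y - pi), information X'WX, and Bernoulli log-likelihood.

    pi = expit(X beta); W = diag(pi (1 - pi)).  Logs are guarded so that an
    extreme beta yields a very negative but finite log-likelihood.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if not np.all(np.isin(y, (0.0, 1.0))):
        raise DataError("logistic outcome must be binary 0/1")
    p = X.shape[1]
    if beta.shape != (p,):
        raise ProtocolError(f"beta length {beta.size} != model dimension {p}")
    if X.shape[0] == 0:
        return ScoreInfo(0, 0, np.zeros(p), np.zeros((p, p)), 0.0, iteration)
    eta = X @ beta
    # expit via tanh is stable at both tails
    pi = 0.5 * (1.0 + np.tanh(0.5 * eta))
    w = pi * (1.0 - pi)
    gradient = X.T @ (y - pi)
    information = (X * w[:, None]).T @ X
    loglik = float(
        np.sum(
            y * np.log(np.maximum(pi, _LOG_GUARD))
            + (1.0 - y) * np.log(np.maximum(1.0 - pi, _LOG_GUARD))
        )
    )
    return ScoreInfo(
        n=X.shape[0],
        n_events=int(y.sum()),
        gradient=gradient,
        information=information,
        loglik=loglik,
        iteration=iteration,
    )


# ---------------------------------------------------------------------------
# Cox family (site-stratified, Breslow ties)
# ---------------------------------------------------------------------------


def cox_local_score_info(
    X: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    beta: np.ndarray,
    iteration: int = 0,
) -> ScoreInfo:
    """Breslow partial-likelihood score/information with this partner as a stratum.

    Risk sets never cross partners, so the sum of these statistics over
    partners is exactly the score/information of a pooled Cox model
    stratified by site.  With the data sorted by descending time, the risk
    set at each event time is a prefix, so the Breslow sums

        S0(t) = sum_{risk} exp(eta_i)
        S1(t) = sum_{risk} x_i exp(eta_i)
        S2(t) = sum_{risk} x_i x_i' exp(eta_i)

    are running cumulations.  Per distinct event time t with d_t events:
    loglik += sum_events eta_i - d_t log S0; score += sum_events x_i -
    d_t S1/S0; information += d_t (S2/S0 - (S1/S0)(S1/S0)').
    """
    X = np.asarray(X, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=float)
    beta = np.asarray(beta, dtype=float)
    p = X.shape[1]
    if beta.shape != (p,):
        raise ProtocolError(f"beta length {beta.size} != model dimension {p}")
    if np.any(time <= 0):
        raise DataError("follow-up times must be strictly positive")
    if not np.all(np.isin(event, (0.0, 1.0))):
        raise DataError("event indicator must be binary 0/1")
    n = X.shape[0]
    n_events = int(event.sum())
    if n == 0 or n_events == 0:
        return ScoreInfo(n, 0, np.zeros(p), np.zeros((p, p)), 0.0, iteration)

    order = np.argsort(-time, kind="stable")
    X = X[order]
    time = time[order]
    event = event[order]
    eta = X @ beta
    # rescale hazards by max(eta) for overflow safety; log-lik correction is exact
    eta_max = float(eta.max())
    w = np.exp(eta - eta_max)

    loglik = 0.0
    gradient = np.zeros(p)
    information = np.zeros((p, p))
    s0 = 0.0
    s1 = np.zeros(p)
    s2 = np.zeros((p, p))
    i = 0
    while i < n:
        t = time[i]
        j = i
        while j < n and time[j] == t:
            j += 1
        block = slice(i, j)
        # everyone with time >= t (this block and all earlier blocks) is at risk
        s0 += float(w[block].sum())
        s1 += w[block] @ X[block]
        s2 += (X[block] * w[block, None]).T @ X[block]
        ev = event[block] == 1.0
        d = int(ev.sum())
        if d:
            xe = X[block][ev]
            loglik += float(eta[block][ev].sum()) - d * (math.log(s0) + eta_max)
            s1_bar = s1 / s0
            gradient += xe.sum(axis=0) - d * s1_bar
            information += d * (s2 / s0 - np.outer(s1_bar, s1_bar))
        i = j
    return ScoreInfo(
        n=n,
        n_events=n_events,
        gradient=gradient,
        information=information,
        loglik=loglik,
        iteration=iteration,
    )


# ---------------------------------------------------------------------------
# Center-side aggregation, Newton updates, convergence, inference
# ---------------------------------------------------------------------------


def aggregate_statistics(
    payloads: Sequence[ScoreInfo] | Sequence[LinearSummaries],
) -> ScoreInfo | LinearSummaries:
    """Elementwise sum of per-partner statistics for one iteration.

    Payloads must agree on type, dimension, and iteration index; summation
    runs in the given (ascending-partner) order so results are bit-reproducible.
    """
    if not payloads:
        raise ProtocolError("no payloads to aggregate")
    first = payloads[0]
    for k, pl in enumerate(payloads):
        if type(pl) is not type(first):
            raise ProtocolError(f"payload {k} has mismatched family/type")
        if pl.iteration != first.iteration:
            raise ProtocolError(
                f"payload {k} answers iteration {pl.iteration}, "
                f"expected {first.iteration}"
            )
    total = first
    for pl in payloads[1:]:
        total = total + pl
    return total


def newton_step(beta: np.ndarray, total: ScoreInfo) -> np.ndarray:
    """Full Newton–Raphson candidate beta + I(beta)^{-1} U(beta).

    Step-halving, if the aggregated log-likelihood later turns out to
    decrease, is the caller's responsibility (it needs another protocol
    round trip to evaluate).
    """
    beta = np.asarray(beta, dtype=float)
    delta = _solve_spd(total.information, total.gradient, "Newton step")
    return beta + delta


def assess_convergence(
    beta_old: np.ndarray,
    beta_new: np.ndarray,
    loglik_old: float,
    loglik_new: float,
    tolerance: float,
    max_iterations: int,
    iteration: int,
) -> ConvergenceStatus:
    """Declare converged when max |change| <= tolerance, else cap on iterations."""
    beta_old = np.asarray(beta_old, dtype=float)
    beta_new = np.asarray(beta_new, dtype=float)
    loglik_delta = float(loglik_new - loglik_old)
    if not np.all(np.isfinite(beta_new)):
        return ConvergenceStatus(
            ConvergenceState.FAILED,
            iteration,
            math.inf,
            loglik_delta,
            message="non-finite parameter estimates (divergence or separation)",
        )
    max_abs_delta = float(np.max(np.abs(beta_new - beta_old)))
    if max_abs_delta <= tolerance:
        state = ConvergenceState.CONVERGED
    elif iteration >= max_iterations:
        state = ConvergenceState.MAX_ITERATIONS_REACHED
    else:
        state = ConvergenceState.CONTINUING
    return ConvergenceStatus(state, iteration, max_abs_delta, loglik_delta)


def _make_fit_result(
    family: Family,
    beta: np.ndarray,
    cov: np.ndarray,
    *,
    loglik_final: float,
    sigma2: float,
    n_total: int,
    n_events_total: int,
    n_iterations: int,
    converged: bool,
    status: ConvergenceState,
) -> FitResult:
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        wald_z = np.where(se > 0, beta / se, np.nan)
    ci95 = np.column_stack([beta - Z_95 * se, beta + Z_95 * se])
    return FitResult(
        family=family,
        beta_hat=beta,
        cov=cov,
        se=se,
        wald_z=wald_z,
        ci95=ci95,
        loglik_final=loglik_final,
        sigma2=sigma2,
        n_total=n_total,
        n_events_total=n_events_total,
        n_iterations=n_iterations,
        converged=converged,
        status=status,
    )


def wald_inference(
    family: Family,
    beta_hat: np.ndarray,
    total: ScoreInfo | LinearSummaries,
    *,
    sigma2: float | None = None,
    n_iterations: int = 1,
    converged: bool = True,
    status: ConvergenceState = ConvergenceState.CONVERGED,
) -> FitResult:
    """Wald covariance, standard errors, z statistics, and 95% CIs.

    cov = I(beta_hat)^{-1} for logistic/Cox; sigma2 (X'X)^{-1} for linear.
    """
    family = Family(family)
    if family is Family.LINEAR:
        assert sigma2 is not None
        cov = sigma2 * _inv_spd(total.xtx, "linear covariance")
        return _make_fit_result(
            family, beta_hat, cov,
            loglik_final=math.nan, sigma2=sigma2,
            n_total=total.n, n_events_total=0,
            n_iterations=n_iterations, converged=converged, status=status,
        )
    cov = _inv_spd(total.information, "Wald covariance")
    return _make_fit_result(
        family, beta_hat, cov,
        loglik_final=total.loglik, sigma2=math.nan,
        n_total=total.n, n_events_total=total.n_events,
        n_iterations=n_iterations, converged=converged, status=status,
    )
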