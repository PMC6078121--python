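"""The analysis-center loop: broadcast guesses, aggregate, update, decide.

The center drives the distributed Newton–Raphson: it deposits the current
parameter 'guesses' (with a ``files_done.ok`` trigger) into every partner's
``inputfiles`` folder, waits for each partner's aggregate statistics to
appear in the per-partner inboxes (``msoc1`` ... ``msocK``), sums them, takes
a Newton step, and assesses convergence.  If the aggregated log-likelihood
ever decreases the center re-distributes a half-step — an extra protocol
round trip — up to ten times before declaring failure.  On any terminal
state it broadcasts the final beta under a ``job_done.ok`` trigger, collects
each partner's diagnostics, and assembles the :class:`FitResult`.

Linear regression needs no iteration (its SSCP statistics are
beta-independent) and completes in a single request/response; the same
workflow machinery carries it.

A separate in-memory driver, :func:`fit_distributed`, runs the identical
aggregation/update arithmetic directly on a list of per-partner datasets —
useful for simulation studies where the file bus would only add I/O.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import transport
from .diagnostics import aggregate_diagnostics
from .regression_core import (
    BetaState,
    ConvergenceState,
    ConvergenceStatus,
    DesignSpec,
    EstimationError,
    Family,
    FitResult,
    LinearSummaries,
    ProtocolError,
    ScoreInfo,
    aggregate_statistics,
    assess_convergence,
    build_model_matrix,
    cox_local_score_info,
    linear_local_summaries,
    linear_solve,
    logistic_local_score_info,
    newton_step,
    wald_inference,
)
from .transport import (
    AuditLog,
    AutomationLevel,
    ErrorPayload,
    FolderLayout,
    PayloadFile,
    TriggerKind,
    deposit,
    poll_for_trigger,
    serialize_payload,
)

__all__ = ["CenterConfig", "AnalysisCenter", "RunFailure", "fit_distributed"]

MAX_HALVINGS = 10
# a log-likelihood "decrease" smaller than rounding noise is not a decrease
def _noise_floor(loglik: float) -> float:
    return 1e-10 * (1.0 + abs(loglik))


class RunFailure(RuntimeError):
    """A distributed run could not proceed (timeout, partner error, protocol)."""


@dataclass
class CenterConfig:
    tolerance: float = 1e-6
    max_iterations: int = 25
    poll_interval: float = 0.5
    timeout: float = 300.0
    automation: AutomationLevel = AutomationLevel.FULLY_AUTOMATED

    def __post_init__(self) -> None:
        self.automation = AutomationLevel(self.automation)
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass
class AnalysisCenter:
    """Center-side state machine for one distributed regression run."""

    layout: FolderLayout
    spec: DesignSpec
    partner_ids: list[int]
    config: CenterConfig = field(default_factory=CenterConfig)
    approval: transport.ApprovalCallback | None = None
    iteration: int = 0
    beta_history: list[BetaState] = field(default_factory=list)
    loglik_history: list[float] = field(default_factory=list)
    history: list[tuple] = field(default_factory=list)

    # internal Newton state
    _accepted_beta: np.ndarray | None = None
    _accepted_loglik: float = -math.inf
    _accepted_total: ScoreInfo | None = None
    _halvings: int = 0
    _fit: FitResult | None = None
    _terminal_status: ConvergenceStatus | None = None

    def __post_init__(self) -> None:
        self.partner_ids = sorted(self.partner_ids)
        if not self.partner_ids:
            raise transport.ConfigurationError("partner list is empty")
        self.audit = AuditLog(self.layout.audit_path)

    # ------------------------------------------------------------------
    # Protocol operations
    # ------------------------------------------------------------------

    def distribute_parameters(self, beta_state: BetaState) -> list:
        """Broadcast one parameter file to every partner's inputfiles folder."""
        trigger = TriggerKind.JOB_DONE if beta_state.job_done else TriggerKind.FILES_DONE
        pf = PayloadFile(
            kind="beta_state",
            family=self.spec.family.value,
            iteration=beta_state.iteration,
            partner_id=0,
            body=beta_state,
        )
        content = serialize_payload(pf)
        name = f"parameters_it{beta_state.iteration:03d}.txt"
        records = []
        for pid in self.partner_ids:
            try:
                records.append(
                    deposit(
                        [(name, content)],
                        self.layout.inputfiles(pid),
                        trigger,
                        direction="center_to_partner",
                        iteration=beta_state.iteration,
                        partner_id=pid,
                        automation=self.config.automation,
                        outbound_from_partner=False,
                        approval=self.approval,
                        audit=self.audit,
                        archive_dir=self.layout.archive_dir,
                    )
                )
            except transport.ApprovalDenied:
                raise
            except Exception as exc:
                raise RunFailure(
                    f"parameter distribution to partner {pid} failed: {exc}"
                ) from exc
        self.beta_history.append(beta_state)
        return records

    def collect_intermediates(self, timeout: float | None = None) -> list[PayloadFile]:
        """Gather one payload from every partner for the current iteration.

        Models the network hop explicitly: each partner's msoc folder is
        picked up (this is where the semi-automated review gate sits),
        re-deposited into the center's per-partner inbox, and consumed
        there.  All partners must answer before the center updates.
        """
        timeout = self.config.timeout if timeout is None else timeout
        payloads = []
        for pid in self.partner_ids:  # ascending: bit-reproducible summation order
            msoc = self.layout.msoc(pid)
            if not poll_for_trigger(
                msoc, TriggerKind.FILES_DONE,
                interval=self.config.poll_interval, timeout=timeout,
            ):
                raise RunFailure(
                    f"timeout waiting for intermediate statistics from "
                    f"partner {pid} (iteration {self.iteration})"
                )
            staged = transport.consume(
                msoc, TriggerKind.FILES_DONE,
                self.layout.workspace / "relay",
                automation=self.config.automation,
                outbound_from_partner=True,
                approval=self.approval,
            )
            deposit(
                [(p.name, p.read_text(encoding="utf-8")) for p in staged],
                self.layout.center_inbox(pid),
                TriggerKind.FILES_DONE,
                direction="partner_to_center",
                iteration=self.iteration,
                partner_id=pid,
                automation=self.config.automation,
                outbound_from_partner=False,
                approval=self.approval,
                audit=self.audit,
            )
            files = transport.consume(
                self.layout.center_inbox(pid), TriggerKind.FILES_DONE,
                self.layout.workspace / "center",
                automation=self.config.automation,
                approval=self.approval,
            )
            if not files:
                raise RunFailure(f"partner {pid} sent an empty transfer")
            pf = transport.parse_payload(files[0].read_text(encoding="utf-8"))
            if isinstance(pf.body, ErrorPayload):
                raise RunFailure(
                    f"partner {pid} reported an error: {pf.body.message}"
                )
            payloads.append(pf)
        return payloads

    def update_and_check(
        self, payloads: list[PayloadFile]
    ) -> tuple[ConvergenceStatus, BetaState | None]:
        """Aggregate partner statistics, update beta, and decide what is next.

        Returns the convergence status and, when the run continues, the
        next :class:`BetaState` to distribute (a Newton candidate, or a
        halved step if the aggregated log-likelihood decreased).  A
        terminal status returns ``None`` as the next state.
        """
        bodies = []
        for pf in payloads:
            if pf.family != self.spec.family.value:
                raise ProtocolError(
                    f"partner {pf.partner_id} answered for family {pf.family}"
                )
            if not isinstance(pf.body, (ScoreInfo, LinearSummaries)):
                raise ProtocolError(
                    f"partner {pf.partner_id} sent unexpected kind {pf.kind}"
                )
            p_sent = (
                pf.body.gradient.size
                if isinstance(pf.body, ScoreInfo)
                else pf.body.xty.size
            )
            if p_sent != self.spec.p:
                raise ProtocolError(
                    f"partner {pf.partner_id} sent dimension {p_sent}, "
                    f"model has p={self.spec.p}"
                )
            bodies.append(pf.body)
        try:
            total = aggregate_statistics(bodies)
        except ProtocolError as exc:
            offenders = {pf.partner_id: pf.iteration for pf in payloads}
            raise ProtocolError(f"{exc}; partner iterations: {offenders}") from exc

        if self.spec.family is Family.LINEAR:
            try:
                fit = linear_solve(total, self.spec.p)
            except EstimationError as exc:
                status = ConvergenceStatus(
                    ConvergenceState.FAILED, self.iteration, math.inf, math.nan,
                    message=str(exc),
                )
                self._terminal_status = status
                return status, None
            fit.n_iterations = 1
            fit.column_names = self.spec.model_column_names
            self._fit = fit
            self._accepted_beta = fit.beta_hat
            status = ConvergenceStatus(
                ConvergenceState.CONVERGED, self.iteration, 0.0, math.nan
            )
            self._terminal_status = status
            self.history.append((self.iteration, fit.beta_hat, math.nan, 0.0))
            return status, None

        distributed_beta = self.beta_history[-1].beta
        if self._accepted_beta is None:
            # first evaluation, at beta0: accept unconditionally
            self._accept(distributed_beta, total)
            candidate = self._newton_candidate(total)
            return (
                ConvergenceStatus(
                    ConvergenceState.CONTINUING, self.iteration,
                    math.inf, math.nan,
                ),
                self._next_state(candidate),
            )

        decreased = total.loglik < self._accepted_loglik - _noise_floor(
            self._accepted_loglik
        )
        if decreased and self._halvings < MAX_HALVINGS:
            # likelihood went down: retry from the last accepted beta with
            # half the step (costs one more protocol round trip)
            self._halvings += 1
            halved = self._accepted_beta + 0.5 * (
                distributed_beta - self._accepted_beta
            )
            return (
                ConvergenceStatus(
                    ConvergenceState.CONTINUING, self.iteration,
                    float(np.max(np.abs(distributed_beta - self._accepted_beta))),
                    float(total.loglik - self._accepted_loglik),
                ),
                self._next_state(halved),
            )
        if decreased:
            status = ConvergenceStatus(
                ConvergenceState.FAILED, self.iteration, math.inf,
                float(total.loglik - self._accepted_loglik),
                message=f"log-likelihood still decreasing after {MAX_HALVINGS} "
                        "step-halvings",
            )
            self._terminal_status = status
            return status, None

        status = assess_convergence(
            self._accepted_beta, distributed_beta,
            self._accepted_loglik, total.loglik,
            self.config.tolerance, self.config.max_iterations, self.iteration,
        )
        self._accept(distributed_beta, total)
        if status.terminal:
            self._terminal_status = status
            self._fit = wald_inference(
                self.spec.family, self._accepted_beta, total,
                n_iterations=self.iteration,
                converged=status.state is ConvergenceState.CONVERGED,
                status=status.state,
            )
            self._fit.column_names = self.spec.model_column_names
            return status, None
        candidate = self._newton_candidate(total)
        return status, self._next_state(candidate)

    # ------------------------------------------------------------------
    # Newton bookkeeping
    # ------------------------------------------------------------------

    def _accept(self, beta: np.ndarray, total: ScoreInfo) -> None:
        self._accepted_beta = np.asarray(beta, dtype=float)
        self._accepted_loglik = total.loglik
        self._accepted_total = total
        self._halvings = 0
        self.loglik_history.append(total.loglik)
        self.history.append(
            (
                self.iteration,
                self._accepted_beta.copy(),
                total.loglik,
                float(np.max(np.abs(total.gradient))),
            )
        )

    def _newton_candidate(self, total: ScoreInfo) -> np.ndarray:
        try:
            return newton_step(self._accepted_beta, total)
        except EstimationError as exc:
            self._terminal_status = ConvergenceStatus(
                ConvergenceState.FAILED, self.iteration, math.inf, math.nan,
                message=str(exc),
            )
            raise RunFailure(str(exc)) from exc

    def _next_state(self, beta: np.ndarray) -> BetaState:
        return BetaState(iteration=self.iteration + 1, beta=beta)

    # ------------------------------------------------------------------
    # Run driver
    # ------------------------------------------------------------------

    def run(self) -> FitResult:
        """Drive a complete distributed regression to its FitResult."""
        next_state = BetaState(iteration=1, beta=np.zeros(self.spec.p))
        status = None
        while True:
            self.iteration = next_state.iteration
            self.distribute_parameters(next_state)
            payloads = self.collect_intermediates()
            status, next_state = self.update_and_check(payloads)
            if next_state is None:
                break
            if self.iteration > self.config.max_iterations + MAX_HALVINGS * 2 + 2:
                raise RunFailure("protocol iteration budget exhausted")
        if status.state is ConvergenceState.FAILED and self._fit is None:
            # still signal partners to shut down before surfacing the failure
            self._broadcast_job_done()
            raise RunFailure(status.message or "distributed fit failed")
        diag = self.finalize()
        fit = self._fit
        fit.diagnostics = diag
        return fit

    def _broadcast_job_done(self, collect: bool = True) -> list[PayloadFile]:
        beta = (
            self._accepted_beta
            if self._accepted_beta is not None
            else np.zeros(self.spec.p)
        )
        done = BetaState(iteration=self.iteration + 1, beta=beta, job_done=True)
        self.distribute_parameters(done)
        if not collect:
            return []
        try:
            return self.collect_intermediates()
        except RunFailure:
            return []

    def finalize(self) -> dict:
        """Broadcast job-done, collect diagnostics, persist the run report."""
        if self._terminal_status is None:
            raise RunFailure("finalize() before a terminal state was reached")
        diag_payloads = self._broadcast_job_done()
        diag_bodies = [
            pf.body for pf in diag_payloads
            if pf.kind == "diagnostics"
        ]
        if len(diag_bodies) == len(self.partner_ids) and diag_bodies:
            try:
                report = aggregate_diagnostics(diag_bodies)
                report["complete"] = True
            except ProtocolError as exc:
                report = {"complete": False, "error": str(exc)}
        else:
            report = {
                "complete": False,
                "error": f"received {len(diag_bodies)} of "
                         f"{len(self.partner_ids)} diagnostics payloads",
            }
        fit = self._fit
        fit.history = list(self.history)
        # cross-check against the audit log: the number of center broadcasts
        # per partner must equal the number of parameter distributions
        n_broadcasts = sum(
            1 for r in self.audit.records()
            if r.direction == "center_to_partner"
            and r.partner_id == self.partner_ids[0]
        )
        report["center_broadcasts"] = n_broadcasts
        report["audit_consistent"] = n_broadcasts == len(self.beta_history)
        self._write_report(fit, report)
        return report

    def _write_report(self, fit: FitResult, diag: dict) -> None:
        frame = fit.summary_frame()
        lines = [
            "Distributed regression analysis report",
            f"family: {fit.family.value}",
            f"n_total: {fit.n_total}   n_events: {fit.n_events_total}",
            f"iterations: {fit.n_iterations}   converged: {fit.converged} "
            f"({fit.status.value})",
            f"loglik_final: {fit.loglik_final!r}",
            "",
            frame.to_string(float_format=lambda v: f"{v: .6f}"),
        ]
        (self.layout.center_root / "report.txt").write_text(
            "\n".join(lines) + "\n", encoding="utf-8"
        )
        machine = {
            "family": fit.family.value,
            "beta_hat": fit.beta_hat.tolist(),
            "se": fit.se.tolist(),
            "wald_z": np.asarray(fit.wald_z, dtype=float).tolist(),
            "ci95": fit.ci95.tolist(),
            "loglik_final": None if math.isnan(fit.loglik_final)
            else fit.loglik_final,
            "sigma2": None if math.isnan(fit.sigma2) else fit.sigma2,
            "n_total": fit.n_total,
            "n_events_total": fit.n_events_total,
            "n_iterations": fit.n_iterations,
            "converged": fit.converged,
            "status": fit.status.value,
            "column_names": list(fit.column_names),
            "diagnostics": {
                k: v for k, v in diag.items() if _json_safe(v)
            },
        }
        (self.layout.center_root / "report.json").write_text(
            json.dumps(machine, indent=2, default=float) + "\n", encoding="utf-8"
        )


def _json_safe(v) -> bool:
    return not (isinstance(v, float) and math.isnan(v))


# ---------------------------------------------------------------------------
# In-memory distributed fit (same arithmetic, no file bus)
# ---------------------------------------------------------------------------


def fit_distributed(
    datasets: list[pd.DataFrame],
    spec: DesignSpec,
    tolerance: float = 1e-6,
    max_iterations: int = 25,
) -> FitResult:
    """Distributed fit over in-memory per-partner datasets.

    Runs exactly the aggregation / Newton–Raphson / step-halving arithmetic
    of the file-based protocol, with function calls standing in for file
    transfers.  Intended for simulation studies (many replicates) where
    the message bus itself is not under test.
    """
    arrays = [build_model_matrix(d, spec) for d in datasets]

    if spec.family is Family.LINEAR:
        summaries = [linear_local_summaries(X, y) for X, y in arrays]
        total = aggregate_statistics(summaries)
        fit = linear_solve(total, spec.p)
        fit.column_names = spec.model_column_names
        return fit

    def evaluate(beta: np.ndarray, iteration: int) -> ScoreInfo:
        if spec.family is Family.LOGISTIC:
            locals_ = [
                logistic_local_score_info(X, y, beta, iteration)
                for X, y in arrays
            ]
        else:
            locals_ = [
                cox_local_score_info(X, t, e, beta, iteration)
                for X, t, e in arrays
            ]
        return aggregate_statistics(locals_)

    beta = np.zeros(spec.p)
    total = evaluate(beta, 1)
    history = [(1, beta.copy(), total.loglik, float(np.max(np.abs(total.gradient))))]
    iteration = 1
    status = None
    while True:
        candidate = newton_step(beta, total)
        halvings = 0
        while True:
            iteration += 1
            cand_total = evaluate(candidate, iteration)
            if cand_total.loglik >= total.loglik - _noise_floor(total.loglik):
                break
            halvings += 1
            if halvings > MAX_HALVINGS:
                raise EstimationError(
                    "log-likelihood decreasing after repeated step-halving"
                )
            candidate = beta + 0.5 * (candidate - beta)
        status = assess_convergence(
            beta, candidate, total.loglik, cand_total.loglik,
            tolerance, max_iterations, iteration,
        )
        beta, total = candidate, cand_total
        history.append(
            (iteration, beta.copy(), total.loglik,
             float(np.max(np.abs(total.gradient))))
        )
        if status.terminal:
            break
    fit = wald_inference(
        spec.family, beta, total,
        n_iterations=iteration,
        converged=status.state is ConvergenceState.CONVERGED,
        status=status.state,
    )
    fit.column_names = spec.model_column_names
    fit.history = history
    return fit
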