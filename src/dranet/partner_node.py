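"""One simulated data partner: the continuously running local analysis loop.

A partner holds its patient-level analytic dataset in ``dplocal`` (which
never leaves the site), watches its ``inputfiles`` folder for parameter
'guesses' from the analysis center, computes the family-appropriate local
aggregate statistics at the supplied beta, and publishes them to its
``msoc`` folder under a ``files_done.ok`` trigger.  When the job-done
signal arrives the partner computes its local diagnostics at the final
beta, publishes them the same way, and terminates — mirroring a
continuously running site program that is shut down when the analysis
completes.

Malformed or stale requests never crash the loop: the partner publishes a
structured error payload instead of statistics and lets the center decide.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import transport
from .diagnostics import cox_local_diagnostics, local_diagnostics
from .regression_core import (
    BetaState,
    DataError,
    DesignSpec,
    Family,
    ProtocolError,
    SchemaError,
    build_model_matrix,
    cox_local_score_info,
    linear_local_summaries,
    logistic_local_score_info,
)
from .transport import (
    AutomationLevel,
    ErrorPayload,
    FolderLayout,
    PayloadFile,
    TriggerKind,
    deposit,
    poll_for_trigger,
    serialize_payload,
)

__all__ = ["PartnerState", "execute_iteration", "run_partner_loop"]


@dataclass
class PartnerState:
    """Everything one site needs to serve a distributed regression run."""

    partner_id: int
    layout: FolderLayout
    spec: DesignSpec
    dataset: pd.DataFrame
    bin_edges: np.ndarray | None = None
    last_iteration_answered: int = -1
    payloads_published: int = 0
    _arrays: tuple | None = field(default=None, repr=False)

    def model_arrays(self) -> tuple:
        if self._arrays is None:
            self._arrays = build_model_matrix(self.dataset, self.spec)
        return self._arrays


def execute_iteration(state: PartnerState, beta_state: BetaState) -> PayloadFile:
    """Compute this partner's intermediate statistics at the supplied beta.

    Linear statistics are beta-independent, so the linear family answers
    with SSCP blocks regardless of the iteration's guess; logistic and Cox
    evaluate score/information/log-likelihood at exactly the distributed
    beta.  The payload echoes the iteration index so the center can reject
    stale answers.
    """
    spec = state.spec
    if beta_state.beta.size != spec.p:
        raise ProtocolError(
            f"beta length {beta_state.beta.size} != model dimension {spec.p}"
        )
    if spec.family is Family.LINEAR:
        X, y = state.model_arrays()
        body = linear_local_summaries(X, y)
        body = type(body)(
            n=body.n, xtx=body.xtx, xty=body.xty, yty=body.yty,
            iteration=beta_state.iteration,
        )
        kind = "linear_summaries"
    elif spec.family is Family.LOGISTIC:
        X, y = state.model_arrays()
        body = logistic_local_score_info(X, y, beta_state.beta, beta_state.iteration)
        kind = "score_info"
    else:
        X, time, event = state.model_arrays()
        body = cox_local_score_info(
            X, time, event, beta_state.beta, beta_state.iteration
        )
        kind = "score_info"
    return PayloadFile(
        kind=kind,
        family=spec.family.value,
        iteration=beta_state.iteration,
        partner_id=state.partner_id,
        body=body,
    )


def _diagnostics_payload(state: PartnerState, beta_state: BetaState) -> PayloadFile:
    spec = state.spec
    if spec.family is Family.LOGISTIC:
        X, y = state.model_arrays()
        edges = state.bin_edges
        if edges is None:
            from .diagnostics import default_bin_edges

            edges = default_bin_edges()
        body = local_diagnostics(
            X, y, beta_state.beta, edges, partner_id=state.partner_id
        )
    elif spec.family is Family.COX:
        X, time, event = state.model_arrays()
        si = cox_local_score_info(X, time, event, beta_state.beta)
        body = cox_local_diagnostics(
            si.loglik, si.n, si.n_events, partner_id=state.partner_id
        )
    else:
        X, y = state.model_arrays()
        body = cox_local_diagnostics(float("nan"), X.shape[0], 0,
                                     partner_id=state.partner_id)
        body = type(body)(
            partner_id=body.partner_id, family="linear",
            bin_edges=body.bin_edges, bin_n=body.bin_n,
            bin_sum_y=body.bin_sum_y, bin_sum_p=body.bin_sum_p,
            loglik_final=body.loglik_final, n_events=body.n_events,
        )
    return PayloadFile(
        kind="diagnostics",
        family=spec.family.value,
        iteration=beta_state.iteration,
        partner_id=state.partner_id,
        body=body,
    )


def _publish(
    state: PartnerState,
    pf: PayloadFile,
    automation: AutomationLevel,
    approval,
    audit,
) -> None:
    name = f"dp{state.partner_id}_{pf.kind}_it{pf.iteration:03d}.txt"
    deposit(
        [(name, serialize_payload(pf))],
        state.layout.msoc(state.partner_id),
        TriggerKind.FILES_DONE,
        direction="partner_to_center",
        iteration=pf.iteration,
        partner_id=state.partner_id,
        automation=automation,
        outbound_from_partner=False,  # the review gate sits on the msoc pickup
        approval=approval,
        audit=audit,
        archive_dir=state.layout.archive_dir,
    )
    state.payloads_published += 1


def run_partner_loop(
    state: PartnerState,
    automation: AutomationLevel = AutomationLevel.FULLY_AUTOMATED,
    *,
    approval=None,
    audit=None,
    poll_interval: float = 0.5,
    timeout: float = 300.0,
    max_wall_iterations: int = 200,
) -> dict:
    """Serve parameter requests until the job-done signal or timeout.

    Returns a run summary with the number of requests served and how the
    loop ended.  Every published payload (statistics, diagnostics, or
    error) is accompanied by a ``files_done.ok`` trigger in this partner's
    msoc folder.
    """
    inbox = state.layout.inputfiles(state.partner_id)
    served = 0
    ended = "timeout"
    for _ in range(max_wall_iterations):
        if not poll_for_trigger(
            inbox, list(TriggerKind), interval=poll_interval, timeout=timeout
        ):
            break
        job_trigger = (inbox / TriggerKind.JOB_DONE.filename).exists()
        trigger = TriggerKind.JOB_DONE if job_trigger else TriggerKind.FILES_DONE
        files = transport.consume(
            inbox, trigger, state.layout.workspace / f"dp{state.partner_id}",
            automation=automation, approval=approval,
        )
        try:
            if not files:
                raise ProtocolError("parameter transfer contained no payload file")
            pf = transport.parse_payload(files[0].read_text(encoding="utf-8"))
            if not isinstance(pf.body, BetaState):
                raise ProtocolError(f"expected a parameter file, got {pf.kind}")
            beta_state = pf.body
            if beta_state.job_done or job_trigger:
                out = _diagnostics_payload(state, beta_state)
                _publish(state, out, automation, approval, audit)
                served += 1
                ended = "job_done"
                break
            if beta_state.iteration <= state.last_iteration_answered:
                raise ProtocolError(
                    f"stale iteration {beta_state.iteration} "
                    f"(already answered {state.last_iteration_answered})"
                )
            out = execute_iteration(state, beta_state)
            state.last_iteration_answered = beta_state.iteration
        except (ProtocolError, SchemaError, DataError) as exc:
            out = PayloadFile(
                kind="error",
                family=state.spec.family.value,
                iteration=getattr(locals().get("beta_state"), "iteration", 0),
                partner_id=state.partner_id,
                body=ErrorPayload(message=str(exc)),
            )
        _publish(state, out, automation, approval, audit)
        served += 1
    return {
        "partner_id": state.partner_id,
        "requests_served": served,
        "ended": ended,
    }
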