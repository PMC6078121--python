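"""Distributed post-convergence model diagnostics from binned aggregates.

After the final parameter estimates are fixed, each partner scores its own
patients, assigns the predicted probabilities to a *global* fixed grid of
bins, and ships only per-bin aggregates: patient count, observed outcome
sum, and predicted-probability sum.  Those three totals are additive across
sites, which makes two pooled diagnostics computable without patient-level
data:

* a Hosmer–Lemeshow-type calibration statistic over the pooled bins, which
  equals the identically-binned pooled computation *exactly*, and
* a binned AUC — the probability that a random case falls in a higher bin
  than a random control, with ties counted half — which approaches the
  exact pooled AUC as the grid is refined.

Exact AUC would need patient-level scores and is excluded by the privacy
contract.  For Cox models the payload degenerates to the final stratified
partial log-likelihood and event count; for linear models only the patient
count is reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .regression_core import DataError, ProtocolError

__all__ = [
    "DiagnosticsPayload",
    "default_bin_edges",
    "local_diagnostics",
    "cox_local_diagnostics",
    "aggregate_diagnostics",
]


@dataclass(frozen=True)
class DiagnosticsPayload:
    """Per-partner binned aggregates; size depends on bin count, never on n."""

    partner_id: int
    family: str
    bin_edges: np.ndarray
    bin_n: np.ndarray
    bin_sum_y: np.ndarray
    bin_sum_p: np.ndarray
    loglik_final: float
    n_events: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "bin_edges", np.asarray(self.bin_edges, dtype=float))
        object.__setattr__(self, "bin_n", np.asarray(self.bin_n, dtype=int))
        object.__setattr__(self, "bin_sum_y", np.asarray(self.bin_sum_y, dtype=float))
        object.__setattr__(self, "bin_sum_p", np.asarray(self.bin_sum_p, dtype=float))

    @property
    def n(self) -> int:
        return int(self.bin_n.sum())


def default_bin_edges(n_bins: int = 20) -> np.ndarray:
    """Equal-width predicted-probability cut points spanning [0, 1].

    Fixed global edges (rather than pooled deciles) avoid a second protocol
    round trip to agree on data-dependent quantiles.
    """
    if n_bins < 1:
        raise ValueError("need at least one bin")
    return np.linspace(0.0, 1.0, n_bins + 1)


def local_diagnostics(
    X: np.ndarray,
    y: np.ndarray,
    beta_final: np.ndarray,
    bin_edges: np.ndarray,
    partner_id: int = 0,
) -> DiagnosticsPayload:
    """Bin one partner's predicted probabilities and accumulate aggregates."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    bin_edges = np.asarray(bin_edges, dtype=float)
    if bin_edges.ndim != 1 or bin_edges.size < 2 or np.any(np.diff(bin_edges) <= 0):
        raise ValueError("bin_edges must be strictly increasing with >= 2 points")
    if not (bin_edges[0] <= 0.0 and bin_edges[-1] >= 1.0):
        raise ValueError("bin_edges must span [0, 1]")
    eta = X @ np.asarray(beta_final, dtype=float)
    pi = 0.5 * (1.0 + np.tanh(0.5 * eta))
    if np.any(pi < 0.0) or np.any(pi > 1.0):
        raise DataError("predicted probability outside [0, 1]: upstream corruption")
    b = bin_edges.size - 1
    # right-closed last bin so pi == 1 lands in the top bin
    idx = np.clip(np.searchsorted(bin_edges, pi, side="right") - 1, 0, b - 1)
    bin_n = np.bincount(idx, minlength=b)
    bin_sum_y = np.bincount(idx, weights=y, minlength=b)
    bin_sum_p = np.bincount(idx, weights=pi, minlength=b)
    loglik = float(
        np.sum(y * np.log(np.maximum(pi, 1e-300))
               + (1.0 - y) * np.log(np.maximum(1.0 - pi, 1e-300)))
    )
    return DiagnosticsPayload(
        partner_id=partner_id,
        family="logistic",
        bin_edges=bin_edges,
        bin_n=bin_n,
        bin_sum_y=bin_sum_y,
        bin_sum_p=bin_sum_p,
        loglik_final=loglik,
        n_events=int(y.sum()),
    )


def cox_local_diagnostics(
    loglik_final: float, n: int, n_events: int, partner_id: int = 0
) -> DiagnosticsPayload:
    """Cox diagnostics: final stratified partial loglik and event count only."""
    return DiagnosticsPayload(
        partner_id=partner_id,
        family="cox",
        bin_edges=np.array([0.0, 1.0]),
        bin_n=np.array([n]),
        bin_sum_y=np.array([float(n_events)]),
        bin_sum_p=np.array([0.0]),
        loglik_final=loglik_final,
        n_events=n_events,
    )


def aggregate_diagnostics(payloads: list[DiagnosticsPayload]) -> dict:
    """Pool per-partner binned aggregates into calibration and discrimination.

    Hosmer–Lemeshow-type statistic over nonempty pooled bins g:

        HL = sum_g (O_g - E_g)^2 / (E_g (1 - E_g / n_g)),  df = G - 2

    with O_g the summed outcomes and E_g the summed predictions.  Binned
    AUC treats each bin as one tied score level:

        AUC = [sum_{g<h} D_g C_h + 1/2 sum_g D_g C_g] / (D C)

    over case counts C and control counts D.  Exact zero-variance bins
    (E_g = 0 or E_g = n_g) are skipped with df reduced accordingly.
    """
    if not payloads:
        raise ProtocolError("no diagnostics payloads to aggregate")
    first = payloads[0]
    for pl in payloads[1:]:
        if pl.bin_edges.shape != first.bin_edges.shape or not np.allclose(
            pl.bin_edges, first.bin_edges, rtol=0, atol=0
        ):
            raise ProtocolError("partners used different bin_edges")
        if pl.family != first.family:
            raise ProtocolError("partners report different model families")
    n_total = int(sum(pl.n for pl in payloads))
    n_events = int(sum(pl.n_events for pl in payloads))
    loglik = float(sum(pl.loglik_final for pl in payloads))
    report: dict = {
        "family": first.family,
        "n": n_total,
        "n_events": n_events,
        "loglik_final": loglik,
    }
    if first.family != "logistic":
        return report

    bin_n = np.sum([pl.bin_n for pl in payloads], axis=0)
    bin_o = np.sum([pl.bin_sum_y for pl in payloads], axis=0)
    bin_e = np.sum([pl.bin_sum_p for pl in payloads], axis=0)

    nonempty = bin_n > 0
    hl = 0.0
    g_used = 0
    for ng, og, eg in zip(bin_n[nonempty], bin_o[nonempty], bin_e[nonempty]):
        denom = eg * (1.0 - eg / ng)
        if denom <= 0:
            continue
        hl += (og - eg) ** 2 / denom
        g_used += 1
    report["hl_statistic"] = hl
    report["hl_df"] = max(g_used - 2, 0)
    report["n_nonempty_bins"] = int(nonempty.sum())

    cases = bin_o
    controls = bin_n - bin_o
    c_total = float(cases.sum())
    d_total = float(controls.sum())
    if c_total == 0 or d_total == 0:
        report["auc_binned"] = math.nan
    else:
        # cumulative controls strictly below each bin
        below = np.concatenate([[0.0], np.cumsum(controls)[:-1]])
        auc = float(np.sum(cases * (below + 0.5 * controls)) / (c_total * d_total))
        report["auc_binned"] = auc
    return report
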