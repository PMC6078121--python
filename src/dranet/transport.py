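"""File-and-trigger message bus between data partners and the analysis center.

Emulates the folder-monitoring transfer workflow of a distributed data
network: each site exposes the four-folder convention (``sasprogram``,
``inputfiles``, ``dplocal``, ``msoc``) and the center keeps one inbox per
partner (``msoc1`` ... ``msocK``).  A sender deposits payload files and then
creates a zero-length trigger file (``files_done.ok`` during iterations,
``job_done.ok`` to end the run); a receiver polls for the trigger, moves the
payload into its own workspace, and deletes the trigger so that the next
trigger's appearance starts the next cycle.

Two hard contracts live here:

* **Atomicity** — every file becomes visible via write-to-temporary-name
  then rename, and the trigger is always created after the payload, so a
  poller that sees the trigger never sees a half-written payload.
* **Privacy boundary** — nothing in this module reads ``dplocal``, and
  :func:`audit_payload` verifies that each transferred file's numeric
  content scales with the number of model parameters (and diagnostic bins),
  never with the number of patients.
"""

from __future__ import annotations

import json
import math
import os
import time as _time
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np

from .diagnostics import DiagnosticsPayload
from .regression_core import (
    BetaState,
    Family,
    LinearSummaries,
    ProtocolError,
    ScoreInfo,
)

__all__ = [
    "TriggerKind",
    "AutomationLevel",
    "FolderLayout",
    "TransferRecord",
    "AuditLog",
    "ApprovalDenied",
    "ConfigurationError",
    "PayloadFile",
    "ErrorPayload",
    "serialize_payload",
    "parse_payload",
    "deposit",
    "poll_for_trigger",
    "consume",
    "audit_payload",
]

PARTNER_FOLDER_NAMES = ("sasprogram", "inputfiles", "dplocal", "msoc")
FORMAT_VERSION = 1


class ConfigurationError(RuntimeError):
    """Folder tree or run configuration is unusable."""


class ApprovalDenied(RuntimeError):
    """A human (or scripted) gate refused a transfer."""


class TriggerKind(Enum):
    FILES_DONE = "files_done.ok"
    JOB_DONE = "job_done.ok"

    @property
    def filename(self) -> str:
        return self.value


TRIGGER_FILENAMES = frozenset(t.filename for t in TriggerKind)


class AutomationLevel(str, Enum):
    """How much human approval the iterative transfer process requires.

    ``manual`` gates every deposit and every consume; ``semi_automated``
    gates only files leaving a partner's msoc folder (the partner's chance
    to review outbound statistics); ``fully_automated`` gates nothing.
    """

    MANUAL = "manual"
    SEMI_AUTOMATED = "semi_automated"
    FULLY_AUTOMATED = "fully_automated"

    def requires_approval(self, *, outbound_from_partner: bool) -> bool:
        if self is AutomationLevel.MANUAL:
            return True
        if self is AutomationLevel.SEMI_AUTOMATED:
            return outbound_from_partner
        return False


# ---------------------------------------------------------------------------
# Folder layout
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FolderLayout:
    """The on-disk contract: per-partner four-folder sites plus center inboxes."""

    root: Path
    n_partners: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "root", Path(self.root))
        if self.n_partners < 1:
            raise ConfigurationError("need at least one data partner")

    # -- partner side -------------------------------------------------------
    def partner_root(self, partner_id: int) -> Path:
        self._check_pid(partner_id)
        return self.root / f"dp{partner_id}"

    def partner_folder(self, partner_id: int, name: str) -> Path:
        if name not in PARTNER_FOLDER_NAMES:
            raise ConfigurationError(f"unknown partner folder {name!r}")
        return self.partner_root(partner_id) / name

    def inputfiles(self, partner_id: int) -> Path:
        return self.partner_folder(partner_id, "inputfiles")

    def dplocal(self, partner_id: int) -> Path:
        return self.partner_folder(partner_id, "dplocal")

    def msoc(self, partner_id: int) -> Path:
        return self.partner_folder(partner_id, "msoc")

    def sasprogram(self, partner_id: int) -> Path:
        return self.partner_folder(partner_id, "sasprogram")

    # -- center side --------------------------------------------------------
    @property
    def center_root(self) -> Path:
        return self.root / "center"

    def center_inbox(self, partner_id: int) -> Path:
        """Per-partner inbox at the center, named msoc<k>, k 1-based."""
        self._check_pid(partner_id)
        return self.center_root / f"msoc{partner_id}"

    @property
    def center_inputfiles(self) -> Path:
        return self.center_root / "inputfiles"

    @property
    def archive_dir(self) -> Path:
        return self.root / "archive"

    @property
    def audit_path(self) -> Path:
        return self.root / "audit.jsonl"

    @property
    def workspace(self) -> Path:
        return self.root / "workspace"

    def all_monitored_folders(self) -> list[Path]:
        folders = [self.center_inputfiles]
        for k in range(1, self.n_partners + 1):
            folders += [self.inputfiles(k), self.msoc(k), self.center_inbox(k)]
        return folders

    def create(self) -> None:
        for k in range(1, self.n_partners + 1):
            for name in PARTNER_FOLDER_NAMES:
                self.partner_folder(k, name).mkdir(parents=True, exist_ok=True)
            self.center_inbox(k).mkdir(parents=True, exist_ok=True)
        self.center_inputfiles.mkdir(parents=True, exist_ok=True)
        self.archive_dir.mkdir(parents=True, exist_ok=True)
        self.workspace.mkdir(parents=True, exist_ok=True)

    def _check_pid(self, partner_id: int) -> None:
        if not 1 <= partner_id <= self.n_partners:
            raise ConfigurationError(
                f"partner_id {partner_id} outside 1..{self.n_partners}"
            )


# ---------------------------------------------------------------------------
# Audit log
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TransferRecord:
    timestamp: float
    direction: str  # center_to_partner | partner_to_center
    iteration: int
    partner_id: int
    files: tuple[str, ...]
    byte_sizes: tuple[int, ...]
    approved_by: str  # "auto" or the approver's label

    def to_json(self) -> str:
        return json.dumps(
            {
                "timestamp": self.timestamp,
                "direction": self.direction,
                "iteration": self.iteration,
                "partner_id": self.partner_id,
                "files": list(self.files),
                "byte_sizes": list(self.byte_sizes),
                "approved_by": self.approved_by,
            }
        )

    @staticmethod
    def from_json(line: str) -> "TransferRecord":
        d = json.loads(line)
        return TransferRecord(
            timestamp=d["timestamp"],
            direction=d["direction"],
            iteration=d["iteration"],
            partner_id=d["partner_id"],
            files=tuple(d["files"]),
            byte_sizes=tuple(d["byte_sizes"]),
            approved_by=d["approved_by"],
        )


class AuditLog:
    """Append-only JSON-lines record of every deposit on the bus."""

    def __init__(self, path: Path):
        self.path = Path(path)

    def append(self, record: TransferRecord) -> None:
        with open(self.path, "a", encoding="utf-8") as fh:
            fh.write(record.to_json() + "\n")

    def records(self) -> list[TransferRecord]:
        if not self.path.exists():
            return []
        with open(self.path, encoding="utf-8") as fh:
            return [TransferRecord.from_json(line) for line in fh if line.strip()]


# ---------------------------------------------------------------------------
# Payload file format
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ErrorPayload:
    """A structured failure report a partner publishes instead of statistics."""

    message: str
    iteration: int = 0


@dataclass(frozen=True)
class PayloadFile:
    """One transferred file: envelope metadata plus a typed body.

    ``partner_id`` 0 denotes the analysis center.
    """

    kind: str
    family: str
    iteration: int
    partner_id: int
    body: BetaState | LinearSummaries | ScoreInfo | DiagnosticsPayload | ErrorPayload


def _fmt(x: float) -> str:
    # 17 significant digits round-trips any IEEE double exactly
    return f"{float(x):.17g}"


def _vec_lines(v: np.ndarray) -> list[str]:
    return [_fmt(x) for x in np.asarray(v, dtype=float).ravel()]


def _upper_triangle(m: np.ndarray) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    iu = np.triu_indices(m.shape[0])
    return m[iu]


def _from_upper_triangle(vals: Sequence[float], p: int) -> np.ndarray:
    m = np.zeros((p, p))
    iu = np.triu_indices(p)
    m[iu] = vals
    m = m + m.T - np.diag(np.diag(m))
    return m


def serialize_payload(pf: PayloadFile) -> str:
    """Render a payload as the labeled-section delimited text format.

    Header keys come first (format_version, kind, family, iteration,
    partner_id, p); each ``[section]`` is followed by one number per line.
    Symmetric matrices travel as their upper triangle.
    """
    body = pf.body
    lines = [
        f"format_version = {FORMAT_VERSION}",
        f"kind = {pf.kind}",
        f"family = {pf.family}",
        f"iteration = {pf.iteration}",
        f"partner_id = {pf.partner_id}",
    ]

    def section(name: str, values: Iterable[str]) -> None:
        lines.append(f"[{name}]")
        lines.extend(values)

    if isinstance(body, BetaState):
        lines.append(f"p = {body.beta.size}")
        section("beta", _vec_lines(body.beta))
        section("job_done", [str(int(body.job_done))])
    elif isinstance(body, LinearSummaries):
        p = body.xty.size
        lines.append(f"p = {p}")
        section("n", [str(body.n)])
        section("xtx_upper", _vec_lines(_upper_triangle(body.xtx)))
        section("xty", _vec_lines(body.xty))
        section("yty", [_fmt(body.yty)])
    elif isinstance(body, ScoreInfo):
        p = body.gradient.size
        lines.append(f"p = {p}")
        section("n", [str(body.n)])
        section("n_events", [str(body.n_events)])
        section("loglik", [_fmt(body.loglik)])
        section("gradient", _vec_lines(body.gradient))
        section("information_upper", _vec_lines(_upper_triangle(body.information)))
    elif isinstance(body, DiagnosticsPayload):
        b = len(body.bin_n)
        lines.append(f"p = {b}")  # payload dimension = bin count, not patients
        section("n_bins", [str(b)])
        section("bin_edges", _vec_lines(body.bin_edges))
        section("bin_n", [str(int(c)) for c in body.bin_n])
        section("bin_sum_y", _vec_lines(body.bin_sum_y))
        section("bin_sum_p", _vec_lines(body.bin_sum_p))
        section("loglik_final", [_fmt(body.loglik_final)])
        section("n_events", [str(body.n_events)])
    elif isinstance(body, ErrorPayload):
        lines.append("p = 0")
        section("message", [body.message.replace("\n", " ")])
    else:  # pragma: no cover
        raise TypeError(f"unserializable payload body {type(body)!r}")
    return "\n".join(lines) + "\n"


def parse_payload(text: str) -> PayloadFile:
    """Parse the labeled-section format back into a typed payload.

    Raises :class:`ProtocolError` on any structural defect — an unparseable
    transferred file is treated as a protocol (and privacy-audit) failure.
    """
    header: dict[str, str] = {}
    sections: dict[str, list[str]] = {}
    current: list[str] | None = None
    for raw in text.splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("[") and line.endswith("]"):
            name = line[1:-1]
            current = sections.setdefault(name, [])
        elif current is None:
            if "=" not in line:
                raise ProtocolError(f"malformed header line: {line!r}")
            key, _, val = line.partition("=")
            header[key.strip()] = val.strip()
        else:
            current.append(line)
    try:
        if int(header["format_version"]) != FORMAT_VERSION:
            raise ProtocolError(
                f"unsupported format_version {header['format_version']}"
            )
        kind = header["kind"]
        family = header["family"]
        iteration = int(header["iteration"])
        partner_id = int(header["partner_id"])
        p = int(header["p"])
    except KeyError as exc:
        raise ProtocolError(f"payload missing header key {exc}") from exc

    def floats(name: str, expected: int) -> np.ndarray:
        vals = sections.get(name)
        if vals is None:
            raise ProtocolError(f"payload missing section [{name}]")
        if len(vals) != expected:
            raise ProtocolError(
                f"section [{name}] has {len(vals)} values, expected {expected}"
            )
        try:
            return np.array([float(v) for v in vals])
        except ValueError as exc:
            raise ProtocolError(f"non-numeric value in [{name}]") from exc

    if kind == "beta_state":
        beta = floats("beta", p)
        job_done = bool(int(floats("job_done", 1)[0]))
        body = BetaState(iteration=iteration, beta=beta, job_done=job_done)
    elif kind == "linear_summaries":
        n = int(floats("n", 1)[0])
        xtx = _from_upper_triangle(floats("xtx_upper", p * (p + 1) // 2), p)
        xty = floats("xty", p)
        yty = float(floats("yty", 1)[0])
        body = LinearSummaries(n=n, xtx=xtx, xty=xty, yty=yty, iteration=iteration)
    elif kind == "score_info":
        n = int(floats("n", 1)[0])
        n_events = int(floats("n_events", 1)[0])
        loglik = float(floats("loglik", 1)[0])
        gradient = floats("gradient", p)
        information = _from_upper_triangle(
            floats("information_upper", p * (p + 1) // 2), p
        )
        body = ScoreInfo(
            n=n, n_events=n_events, gradient=gradient,
            information=information, loglik=loglik, iteration=iteration,
        )
    elif kind == "diagnostics":
        b = int(floats("n_bins", 1)[0])
        if b != p:
            raise ProtocolError("diagnostics bin count disagrees with header p")
        body = DiagnosticsPayload(
            partner_id=partner_id,
            family=family,
            bin_edges=floats("bin_edges", b + 1),
            bin_n=floats("bin_n", b).astype(int),
            bin_sum_y=floats("bin_sum_y", b),
            bin_sum_p=floats("bin_sum_p", b),
            loglik_final=float(floats("loglik_final", 1)[0]),
            n_events=int(floats("n_events", 1)[0]),
        )
    elif kind == "error":
        msg_lines = sections.get("message", [])
        body = ErrorPayload(message=" ".join(msg_lines), iteration=iteration)
    else:
        raise ProtocolError(f"unknown payload kind {kind!r}")
    return PayloadFile(
        kind=kind, family=family, iteration=iteration,
        partner_id=partner_id, body=body,
    )


# ---------------------------------------------------------------------------
# Bus primitives
# ---------------------------------------------------------------------------

ApprovalCallback = Callable[[str, Path, Sequence[str]], bool]


def _atomic_write(path: Path, content: str | bytes) -> int:
    """Write via temporary name + rename so readers never see partial files."""
    mode = "wb" if isinstance(content, bytes) else "w"
    tmp = path.with_name(f".{path.name}.tmp")
    with open(tmp, mode) as fh:
        fh.write(content)
        fh.flush()
        os.fsync(fh.fileno())
    os.replace(tmp, path)
    return path.stat().st_size


def deposit(
    files: Sequence[tuple[str, str]],
    destination: Path,
    trigger: TriggerKind,
    *,
    direction: str,
    iteration: int,
    partner_id: int,
    automation: AutomationLevel = AutomationLevel.FULLY_AUTOMATED,
    outbound_from_partner: bool = False,
    approval: ApprovalCallback | None = None,
    approver: str = "auto",
    audit: AuditLog | None = None,
    archive_dir: Path | None = None,
) -> TransferRecord:
    """Deposit payload files then the trigger file into ``destination``.

    All payload files are fully written (atomically) *before* the trigger is
    created — the trigger's appearance is the only signal consumers act on.
    An approval denial aborts before any file is written.
    """
    destination = Path(destination)
    if not destination.is_dir():
        raise ConfigurationError(f"destination folder does not exist: {destination}")
    names = [name for name, _ in files]
    if automation.requires_approval(outbound_from_partner=outbound_from_partner):
        if approval is None or not approval(direction, destination, names):
            raise ApprovalDenied(
                f"transfer to {destination} ({direction}, iteration {iteration}) "
                "was not approved; no files were written"
            )
        approved_by = approver if approver != "auto" else "approved"
    else:
        approved_by = "auto"
    sizes = []
    for name, content in files:
        if name in TRIGGER_FILENAMES:
            raise ConfigurationError("payload file may not be named like a trigger")
        sizes.append(_atomic_write(destination / name, content))
        if archive_dir is not None:
            stamp = f"{direction}.it{iteration:03d}.dp{partner_id}.{name}"
            _atomic_write(Path(archive_dir) / stamp, content)
    _atomic_write(destination / trigger.filename, "")  # zero-length marker
    record = TransferRecord(
        timestamp=_time.time(),
        direction=direction,
        iteration=iteration,
        partner_id=partner_id,
        files=tuple(names),
        byte_sizes=tuple(sizes),
        approved_by=approved_by,
    )
    if audit is not None:
        audit.append(record)
    return record


def poll_for_trigger(
    folder: Path,
    trigger: TriggerKind | Sequence[TriggerKind],
    interval: float = 0.5,
    timeout: float = 300.0,
) -> bool:
    """Poll ``folder`` until a trigger file appears; never consumes it.

    Returns True as soon as any requested trigger exists, False once
    ``timeout`` seconds have elapsed without one.
    """
    if interval <= 0:
        raise ConfigurationError("poll interval must be positive")
    folder = Path(folder)
    if not folder.is_dir():
        raise ConfigurationError(f"monitored folder does not exist: {folder}")
    kinds = [trigger] if isinstance(trigger, TriggerKind) else list(trigger)
    deadline = _time.monotonic() + timeout
    while True:
        if any((folder / k.filename).exists() for k in kinds):
            return True
        if _time.monotonic() >= deadline:
            return False
        _time.sleep(min(interval, max(deadline - _time.monotonic(), 0.0)))


def consume(
    folder: Path,
    trigger: TriggerKind,
    workspace: Path,
    *,
    automation: AutomationLevel = AutomationLevel.FULLY_AUTOMATED,
    outbound_from_partner: bool = False,
    approval: ApprovalCallback | None = None,
) -> list[Path]:
    """Move payload files out of ``folder`` and delete the trigger.

    Deleting the trigger is what re-arms the folder: the next trigger's
    appearance starts the next transfer cycle.  Consuming without a trigger
    present is a protocol error (single-shot semantics).
    """
    folder = Path(folder)
    workspace = Path(workspace)
    trigger_path = folder / trigger.filename
    if not trigger_path.exists():
        raise ProtocolError(f"no {trigger.filename} trigger present in {folder}")
    payload_paths = sorted(
        p for p in folder.iterdir()
        if p.is_file() and p.name not in TRIGGER_FILENAMES
        and not p.name.startswith(".")
    )
    if automation.requires_approval(outbound_from_partner=outbound_from_partner):
        names = [p.name for p in payload_paths]
        if approval is None or not approval("consume", folder, names):
            raise ApprovalDenied(f"consume from {folder} was not approved")
    workspace.mkdir(parents=True, exist_ok=True)
    moved = []
    for src in payload_paths:
        dst = workspace / src.name
        os.replace(src, dst)  # move, not copy: prevents double-processing
        moved.append(dst)
    trigger_path.unlink()
    return moved


# ---------------------------------------------------------------------------
# Privacy audit
# ---------------------------------------------------------------------------


def _expected_scalars(pf: PayloadFile) -> int:
    """Scalar count a conforming payload must have — a function of p / bins only."""
    body = pf.body
    if isinstance(body, BetaState):
        return body.beta.size + 2  # beta + iteration + job_done flag
    if isinstance(body, ScoreInfo):
        p = body.gradient.size
        return p + p * (p + 1) // 2 + 3  # gradient + info triangle + n/n_events/loglik
    if isinstance(body, LinearSummaries):
        p = body.xty.size
        return p * (p + 1) // 2 + p + 2  # xtx triangle + xty + yty + n
    if isinstance(body, DiagnosticsPayload):
        b = len(body.bin_n)
        return (b + 1) + 3 * b + 2  # edges + three per-bin aggregates + loglik/events
    if isinstance(body, ErrorPayload):
        return 0
    raise ProtocolError(f"unauditable body {type(body)!r}")  # pragma: no cover


def _count_numeric_lines(text: str) -> int:
    count = 0
    in_section = False
    for raw in text.splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("[") and line.endswith("]"):
            in_section = True
            continue
        if in_section:
            try:
                float(line)
            except ValueError:
                continue
            count += 1
    return count


def audit_payload(paths: Sequence[Path]) -> dict:
    """Verify transferred files carry only aggregate, parameter-sized content.

    Every file must parse as a known payload kind and contain exactly the
    scalar count the format prescribes for its dimension p (or bin count).
    A file whose numeric volume could encode patient rows fails the audit.
    """
    checks = []
    ok = True
    for path in paths:
        path = Path(path)
        entry = {"file": path.name, "pass": False, "detail": ""}
        try:
            pf = parse_payload(path.read_text(encoding="utf-8"))
        except (ProtocolError, OSError, UnicodeDecodeError) as exc:
            entry["detail"] = f"unparseable as aggregate payload: {exc}"
            ok = False
            checks.append(entry)
            continue
        expected = _expected_scalars(pf)
        # iteration/job_done ride in the header for most kinds; count only
        # sectioned numeric lines and compare with the section budget.
        sectioned = _count_numeric_lines(path.read_text(encoding="utf-8"))
        budget = {
            "beta_state": pf.body.beta.size + 1 if isinstance(pf.body, BetaState) else 0,
            "score_info": expected,
            "linear_summaries": expected,
            "diagnostics": expected + 1,  # +1 for the n_bins count itself
            "error": 0,
        }[pf.kind]
        if sectioned != budget:
            entry["detail"] = (
                f"{sectioned} numeric values on file, format allows {budget} "
                f"for kind={pf.kind}, p-dimension {expected}"
            )
            ok = False
        else:
            entry["pass"] = True
            entry["detail"] = f"kind={pf.kind}, {sectioned} aggregate scalars"
        entry["kind"] = pf.kind
        checks.append(entry)
    return {"pass": ok, "n_files": len(checks), "checks": checks}
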