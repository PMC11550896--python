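"""Confirmation procedure and five-way spot taxonomy.

A candidate spot is identified by a positive thermal report during a search
sweep (sweep 0), then re-stimulated up to four more times. Any positive
report on a confirmation sweep confirms the spot and ends the confirmation
loop; the reported quality need not match the stimulus. Confirmed spots are
classified:

* **cold / warm** — all positive reports agree with each other and with the
  stimulus polarity of their block;
* **incongruous** — all positive reports agree with each other but
  contradict the stimulus polarity;
* **inconsistent** — positive reports disagree with each other, or the spot
  produced positive reports in both the cold and the warm stimulus block.

A spot with no positive confirmation sweep is **unconfirmed**.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field

from .spot_model import SpotTable

__all__ = [
    "TrialReport",
    "ResponseLog",
    "CategorySummary",
    "ContractError",
    "is_confirmed",
    "classify_spot",
    "classify_table",
    "summarize_categories",
    "read_response_logs",
    "write_response_logs",
    "round_percent",
]

BLOCKS = ("cold", "warm")
REPORTS = ("cold", "warm", "none")


class ContractError(ValueError):
    """An operation was called outside its contract."""


@dataclass(frozen=True)
class TrialReport:
    """One stimulation of a spot: block polarity, sweep index, verbal report.

    ``sweep_index`` 0 is the identification sweep; 1-4 are confirmation
    sweeps. ``report`` is what the participant said ("none" = no sensation).
    """

    block: str
    sweep_index: int
    report: str

    def __post_init__(self) -> None:
        if self.block not in BLOCKS:
            raise ValueError(f"block must be cold/warm, got {self.block!r}")
        if not 0 <= self.sweep_index <= 4:
            raise ValueError(f"sweep_index must be 0-4, got {self.sweep_index}")
        if self.report not in REPORTS:
            raise ValueError(f"report must be cold/warm/none, got {self.report!r}")


@dataclass
class ResponseLog:
    """All trial reports for one spot, grouped by stimulus block."""

    log_id: str
    trials: list[TrialReport] = field(default_factory=list)

    def blocks(self) -> list[str]:
        out = []
        for t in self.trials:
            if t.block not in out:
                out.append(t.block)
        return out

    def block_trials(self, block: str) -> list[TrialReport]:
        return sorted(
            (t for t in self.trials if t.block == block),
            key=lambda t: t.sweep_index,
        )

    def validate(self) -> None:
        for block in self.blocks():
            trials = self.block_trials(block)
            indices = [t.sweep_index for t in trials]
            if len(set(indices)) != len(indices):
                raise ValueError(
                    f"log {self.log_id}: duplicate sweep index in {block} block"
                )
            if 0 not in indices:
                raise ValueError(
                    f"log {self.log_id}: {block} block lacks identification sweep"
                )
            # confirmation loop stops at the first positive report
            confirmations = [t for t in trials if t.sweep_index >= 1]
            for i, t in enumerate(confirmations):
                if t.report != "none" and i != len(confirmations) - 1:
                    raise ValueError(
                        f"log {self.log_id}: {block} block continues past a "
                        "positive confirmation"
                    )


def _positive_reports(log: ResponseLog, block: str) -> list[str]:
    return [t.report for t in log.block_trials(block) if t.report != "none"]


def is_confirmed(log: ResponseLog) -> bool:
    """True iff any confirmation sweep (index >= 1) got a positive report.

    A log only exists after a positive identification, so a log whose every
    identification sweep is "none" violates the contract.
    """
    if not any(t.sweep_index == 0 and t.report != "none" for t in log.trials):
        raise ContractError(
            f"log {log.log_id}: no positive identification report"
        )
    return any(t.sweep_index >= 1 and t.report != "none" for t in log.trials)


def classify_spot(log: ResponseLog) -> str:
    """Classify a confirmed spot as cold, warm, inconsistent or incongruous.

    Agreement is evaluated over positive reports only; "none" reports are
    ignored. Cross-block responsiveness dominates: a spot positive in both
    blocks is inconsistent regardless of within-block agreement.
    """
    if not is_confirmed(log):
        raise ContractError(
            f"log {log.log_id}: unconfirmed; route through is_confirmed first"
        )
    positives = {
        b: _positive_reports(log, b) for b in log.blocks() if _positive_reports(log, b)
    }
    if len(positives) > 1:
        return "inconsistent"
    (block, reports), = positives.items()
    if len(set(reports)) > 1:
        return "inconsistent"
    return reports[0] if reports[0] == block else "incongruous"


def classify_table(table: SpotTable, logs: dict[str, ResponseLog]) -> SpotTable:
    """Re-derive every record's category from its response log."""
    categories: dict[str, str] = {}
    for rec in table.records:
        log = logs.get(rec.response_log_id)
        if log is None:
            raise ContractError(
                f"spot ({rec.participant_id}, s{rec.session_id}) references "
                f"missing response log {rec.response_log_id!r}"
            )
        categories[log.log_id] = (
            classify_spot(log) if is_confirmed(log) else "unconfirmed"
        )
    return table.with_categories(categories)


def round_percent(fraction: float) -> int:
    """Percentage rounded to the nearest integer, halves away from zero."""
    return int(math.floor(100.0 * fraction + 0.5))


@dataclass
class CategorySummary:
    """Counts and percentages of spot categories, plus participant means.

    Percentages are computed over confirmed spots only. Per-participant SDs
    use the n-1 denominator; with a single participant the SD is reported as
    0.0 and ``sd_degenerate`` is set.
    """

    counts: dict[str, int]
    percents: dict[str, int]
    per_participant_mean_sd: dict[str, tuple[float, float]]
    n_confirmed: int
    n_total: int
    n_participants: int
    sd_degenerate: bool = False

    @property
    def unconfirmed_rate_percent(self) -> float:
        if self.n_total == 0:
            return 0.0
        return 100.0 * self.counts.get("unconfirmed", 0) / self.n_total


def summarize_categories(table: SpotTable) -> CategorySummary:
    """Tabulate the five-way taxonomy over a spot table.

    Per-participant means and SDs are taken over the participants present in
    the table (a participant contributes 0 to a category it has no spots in).
    """
    from .spot_model import CATEGORIES

    counts = {c: 0 for c in CATEGORIES}
    per_part: dict[str, dict[str, int]] = {}
    for rec in table.records:
        counts[rec.category] += 1
        per_part.setdefault(rec.participant_id, {c: 0 for c in CATEGORIES})
        per_part[rec.participant_id][rec.category] += 1

    n_total = len(table.records)
    n_confirmed = n_total - counts["unconfirmed"]
    percents = {
        c: round_percent(counts[c] / n_confirmed) if n_confirmed else 0
        for c in CATEGORIES
        if c != "unconfirmed"
    }

    n_p = len(per_part)
    mean_sd: dict[str, tuple[float, float]] = {}
    for c in CATEGORIES:
        vals = [per_part[p][c] for p in per_part]
        if not vals:
            mean_sd[c] = (0.0, 0.0)
        elif len(vals) == 1:
            mean_sd[c] = (float(vals[0]), 0.0)
        else:
            mean = sum(vals) / n_p
            var = sum((v - mean) ** 2 for v in vals) / (n_p - 1)
            mean_sd[c] = (mean, math.sqrt(var))

    return CategorySummary(
        counts=counts,
        percents=percents,
        per_participant_mean_sd=mean_sd,
        n_confirmed=n_confirmed,
        n_total=n_total,
        n_participants=n_p,
        sd_degenerate=n_p < 2,
    )


_LOG_FIELDS = ("response_log_id", "block", "sweep_index", "report")


def read_response_logs(path) -> dict[str, ResponseLog]:
    """Read the companion response-log CSV (one row per trial)."""
    logs: dict[str, ResponseLog] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or list(reader.fieldnames) != list(_LOG_FIELDS):
            raise ValueError(
                f"{path}: expected header {','.join(_LOG_FIELDS)}, "
                f"got {reader.fieldnames}"
            )
        for rownum, row in enumerate(reader, start=2):
            try:
                log_id = row["response_log_id"]
                trial = TrialReport(
                    block=row["block"],
                    sweep_index=int(row["sweep_index"]),
                    report=row["report"],
                )
            except (KeyError, ValueError) as exc:
                raise ValueError(f"{path} row {rownum}: {exc}") from exc
            logs.setdefault(log_id, ResponseLog(log_id)).trials.append(trial)
    for log in logs.values():
        log.validate()
    return logs


def write_response_logs(logs: dict[str, ResponseLog], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(_LOG_FIELDS)
        for log_id in logs:
            log = logs[log_id]
            for t in sorted(log.trials, key=lambda t: (t.block, t.sweep_index)):
                writer.writerow([log.log_id, t.block, t.sweep_index, t.report])
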