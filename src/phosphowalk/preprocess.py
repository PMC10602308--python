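"""Signal filtering and fold-change computation for probe measurements.

Three quality filters are applied, in order, before any network mapping:

1. **Low signal** — a probe is dropped when either channel falls strictly
   below the array design's low-signal cutoff (1,000 units for KAM-1325,
   500 units for KAM-2000). Equality retains. Using the minimum of the two
   channels also protects the CFC denominator from zero controls.
2. **Relative error** — a probe is dropped when its summed channel error is
   high relative to the signal change: (treated_error + control_error) /
   |treated - control| > ``ratio_threshold`` (default 1.0, i.e. the change is
   within the summed error). A zero change with nonzero error is an infinite
   ratio and is dropped; a zero change with zero error is retained.
3. **Total error** — with replicate tables, a probe is blacklisted when its
   summed treatment-channel error across all tables strictly exceeds its
   summed control-channel error.

Retained probes get ``cfc_percent = 100*(treated-control)/control`` and
``log2fc = log2(treated/control)``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

from .arrays import ArraySpec, ProbeMeasurement
from .errors import TableValidationError, UndefinedValueError

__all__ = [
    "FilterReport",
    "compute_cfc",
    "compute_log2fc",
    "filter_low_signal",
    "filter_relative_error",
    "filter_total_error",
    "preprocess_pipeline",
]


def compute_cfc(treated_signal: float, control_signal: float) -> float:
    """Percent change from control: 100*(treated - control)/control.

    Raises :class:`UndefinedValueError` for ``control_signal <= 0`` — such
    probes must already have been removed by the low-signal filter.
    """
    if control_signal <= 0:
        raise UndefinedValueError(
            f"CFC undefined for control signal {control_signal!r} (must be > 0)"
        )
    return 100.0 * (treated_signal - control_signal) / control_signal


def compute_log2fc(treated_signal: float, control_signal: float) -> float:
    """log2(treated/control); both signals must be strictly positive."""
    if treated_signal <= 0 or control_signal <= 0:
        raise UndefinedValueError(
            f"log2 fold change undefined for signals ({treated_signal!r}, {control_signal!r})"
        )
    return math.log2(treated_signal / control_signal)


def filter_low_signal(
    measurements: Sequence[ProbeMeasurement], spec: ArraySpec
) -> tuple[list[ProbeMeasurement], list[ProbeMeasurement]]:
    """Split measurements into (retained, removed) by the low-signal rule.

    A probe is removed iff min(treated, control) is strictly below
    ``spec.low_signal_threshold``; order is preserved.
    """
    retained, removed = [], []
    for m in measurements:
        if min(m.treated_signal, m.control_signal) < spec.low_signal_threshold:
            removed.append(m)
        else:
            retained.append(m)
    return retained, removed


def filter_relative_error(
    measurements: Sequence[ProbeMeasurement], ratio_threshold: float = 1.0
) -> tuple[list[ProbeMeasurement], list[ProbeMeasurement]]:
    """Split measurements into (retained, removed) by the relative-error rule."""
    if ratio_threshold <= 0:
        raise ValueError("ratio_threshold must be > 0")
    retained, removed = [], []
    for m in measurements:
        delta = abs(m.treated_signal - m.control_signal)
        error_sum = m.treated_error + m.control_error
        if delta == 0:
            drop = error_sum > 0
        else:
            drop = error_sum / delta > ratio_threshold
        (removed if drop else retained).append(m)
    return retained, removed


def filter_total_error(tables: Sequence[Sequence[ProbeMeasurement]]) -> set[str]:
    """Probe ids whose total treatment-channel error exceeds the control-channel total.

    ``tables`` are replicate measurement tables sharing a probe_id set; each row
    carries both channels, so the treatment arrays contribute ``treated_error``
    and the control arrays ``control_error``. Strict inequality blacklists;
    equal totals (including all-zero errors) retain.
    """
    if not tables:
        return set()
    ids = [{m.probe.probe_id for m in t} for t in tables]
    common = ids[0]
    for s in ids[1:]:
        if s != common:
            one_sided = common.symmetric_difference(s)
            raise TableValidationError(
                "probe(s) present in one condition/table only: "
                + ", ".join(sorted(one_sided)[:5])
            )
    treated: dict[str, float] = {}
    control: dict[str, float] = {}
    for table in tables:
        for m in table:
            pid = m.probe.probe_id
            treated[pid] = treated.get(pid, 0.0) + m.treated_error
            control[pid] = control.get(pid, 0.0) + m.control_error
    return {pid for pid in treated if treated[pid] > control[pid]}


@dataclass
class FilterReport:
    """Bookkeeping for one preprocessing run; counts always conserve:
    n_input = n_retained + n_low_signal_removed + n_relative_error_removed
    + n_total_error_removed."""

    n_input: int = 0
    n_low_signal_removed: int = 0
    n_relative_error_removed: int = 0
    n_total_error_removed: int = 0
    n_retained: int = 0
    removed_probe_ids: list[str] = field(default_factory=list)

    def check(self) -> None:
        total = (
            self.n_retained
            + self.n_low_signal_removed
            + self.n_relative_error_removed
            + self.n_total_error_removed
        )
        if total != self.n_input:
            raise AssertionError(f"filter report does not conserve counts: {self}")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    def to_text(self) -> str:
        lines = [
            f"probes in:                {self.n_input}",
            f"removed (low signal):     {self.n_low_signal_removed}",
            f"removed (relative error): {self.n_relative_error_removed}",
            f"removed (total error):    {self.n_total_error_removed}",
            f"retained:                 {self.n_retained}",
        ]
        return "\n".join(lines)


def _average_tables(tables: Sequence[Sequence[ProbeMeasurement]]) -> list[ProbeMeasurement]:
    """Average replicate tables channel-wise into one combined table.

    Probe order follows the first table; probe id sets must agree.
    """
    if len(tables) == 1:
        return list(tables[0])
    by_id = [{m.probe.probe_id: m for m in t} for t in tables]
    combined = []
    n = len(tables)
    for m0 in tables[0]:
        pid = m0.probe.probe_id
        ms = [d[pid] for d in by_id]
        combined.append(
            ProbeMeasurement(
                probe=m0.probe,
                treated_signal=sum(m.treated_signal for m in ms) / n,
                treated_error=sum(m.treated_error for m in ms) / n,
                control_signal=sum(m.control_signal for m in ms) / n,
                control_error=sum(m.control_error for m in ms) / n,
            )
        )
    return combined


def preprocess_pipeline(
    measurements: Sequence[ProbeMeasurement] | Sequence[Sequence[ProbeMeasurement]],
    spec: ArraySpec,
    *,
    relative_error_threshold: float = 1.0,
) -> tuple[list[ProbeMeasurement], FilterReport]:
    """Run low-signal -> relative-error -> total-error filtering, then compute fold changes.

    Accepts either one measurement table or a list of replicate tables (which
    are error-compared for the total-error rule and averaged channel-wise for
    fold-change computation). Idempotent: re-running on its own output removes
    nothing further.
    """
    if measurements and isinstance(measurements[0], ProbeMeasurement):
        tables: list[Sequence[ProbeMeasurement]] = [measurements]  # type: ignore[list-item]
    else:
        tables = list(measurements)  # type: ignore[arg-type]
    if not tables or not any(len(t) for t in tables):
        return [], FilterReport()

    combined = _average_tables(tables)
    report = FilterReport(n_input=len(combined))

    kept, low = filter_low_signal(combined, spec)
    report.n_low_signal_removed = len(low)
    report.removed_probe_ids += [m.probe.probe_id for m in low]

    kept, noisy = filter_relative_error(kept, relative_error_threshold)
    report.n_relative_error_removed = len(noisy)
    report.removed_probe_ids += [m.probe.probe_id for m in noisy]

    surviving_ids = {m.probe.probe_id for m in kept}
    filtered_tables = [[m for m in t if m.probe.probe_id in surviving_ids] for t in tables]
    blacklist = filter_total_error(filtered_tables)
    report.n_total_error_removed = len(blacklist)
    report.removed_probe_ids += sorted(blacklist)
    kept = [m for m in kept if m.probe.probe_id not in blacklist]

    annotated = [
        m.with_fold_changes(
            compute_cfc(m.treated_signal, m.control_signal),
            compute_log2fc(m.treated_signal, m.control_signal),
        )
        for m in kept
    ]
    report.n_retained = len(annotated)
    report.check()
    return annotated, report
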