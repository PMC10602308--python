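"""Probe, relation and lead tables for antibody-microarray runs.

An antibody microarray reports, per probe, a fluorescence signal for a
treated sample and for a control sample, each with an error estimate.
Probes are either *phosphosite-specific* (they measure one phosphorylated
residue, written as residue letter + position, e.g. ``S473``) or
*pan-specific* (total protein expression; the sentinel site ``"pan"``).

All tables are delimited text with a required header; tab is the default
separator and comma is accepted via ``sep=","``. Gene symbols are upper-cased
on read and may be canonicalised through an optional alias table (symbol ->
canonical symbol), because signalling literature freely mixes aliases
(BAD/BCL2, RPS6KB1/p70S6K, PDK1/PDPK1, ...).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import FormatError, TableValidationError

__all__ = [
    "PAN_SITE",
    "SITE_PATTERN",
    "AntibodyProbe",
    "ProbeMeasurement",
    "ArraySpec",
    "KSRelation",
    "KAM_1325",
    "KAM_2000",
    "ARRAY_SPECS",
    "EFFECTS",
    "is_valid_site",
    "read_probe_table",
    "write_probe_table",
    "read_ks_relations",
    "write_ks_relations",
    "write_lead_table",
]

#: Sentinel site label for pan-specific (total expression) antibodies.
PAN_SITE = "pan"

#: One phospho-acceptor residue (Ser/Thr/Tyr) followed by a 1-based position.
SITE_PATTERN = re.compile(r"^[STY][1-9][0-9]*$")

EFFECTS = ("activation", "inhibition", "unknown")

PROBE_COLUMNS = [
    "probe_id",
    "target",
    "site",
    "treated_signal",
    "treated_error",
    "control_signal",
    "control_error",
]

RELATION_COLUMNS = ["kinase", "substrate", "site", "effect"]
LEAD_COLUMNS = ["target", "site", "direction", "cfc_percent", "n_chains"]


def is_valid_site(site: str) -> bool:
    """True for ``"pan"`` or a residue+position phosphosite label like ``"S473"``."""
    return site == PAN_SITE or bool(SITE_PATTERN.match(site))


@dataclass(frozen=True)
class AntibodyProbe:
    """One antibody spot on an array design."""

    probe_id: str
    target_symbol: str
    site: str
    array_id: str = ""

    def __post_init__(self) -> None:
        if not self.target_symbol:
            raise TableValidationError("target_symbol must be nonempty")
        if not is_valid_site(self.site):
            raise TableValidationError(
                f"invalid site label {self.site!r}: expected one of S/T/Y followed "
                f"by a positive integer, or {PAN_SITE!r}"
            )

    @property
    def is_pan(self) -> bool:
        return self.site == PAN_SITE


@dataclass(frozen=True)
class ProbeMeasurement:
    """Paired treated/control signals for one probe, with derived fold changes.

    ``cfc_percent`` (percent change from control, 100*(treated-control)/control)
    and ``log2fc`` are absent (None) until preprocessing computes them.
    """

    probe: AntibodyProbe
    treated_signal: float
    treated_error: float
    control_signal: float
    control_error: float
    cfc_percent: float | None = None
    log2fc: float | None = None

    def __post_init__(self) -> None:
        for name in ("treated_signal", "treated_error", "control_signal", "control_error"):
            value = getattr(self, name)
            if not math.isfinite(value) or value < 0:
                raise TableValidationError(
                    f"probe {self.probe.probe_id!r}: {name} must be finite and >= 0, got {value!r}"
                )

    def with_fold_changes(self, cfc_percent: float, log2fc: float) -> "ProbeMeasurement":
        return replace(self, cfc_percent=cfc_percent, log2fc=log2fc)


@dataclass(frozen=True)
class ArraySpec:
    """An array design: its identifier, low-signal cutoff and nominal probe count."""

    array_id: str
    low_signal_threshold: float
    n_probes_nominal: int

    def __post_init__(self) -> None:
        if self.low_signal_threshold <= 0:
            raise TableValidationError("low_signal_threshold must be > 0")


KAM_1325 = ArraySpec("KAM-1325", 1000.0, 1325)
KAM_2000 = ArraySpec("KAM-2000", 500.0, 2000)
ARRAY_SPECS: Mapping[str, ArraySpec] = {s.array_id: s for s in (KAM_1325, KAM_2000)}


@dataclass(frozen=True)
class KSRelation:
    """A directed kinase -> substrate phosphorylation relation at one site.

    ``effect`` is the downstream consequence of the phosphorylation for the
    substrate: ``activation``, ``inhibition``, or ``unknown`` (no curated
    biological data).
    """

    kinase: str
    substrate: str
    site: str
    effect: str

    def __post_init__(self) -> None:
        if not self.kinase or not self.substrate:
            raise TableValidationError("kinase and substrate must be nonempty")
        if not is_valid_site(self.site):
            raise TableValidationError(f"invalid site label {self.site!r}")
        if self.effect not in EFFECTS:
            raise FormatError(
                f"unknown effect token {self.effect!r}; expected one of {EFFECTS}"
            )

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.kinase, self.substrate, self.site)


def _canonical(symbol: str, aliases: Mapping[str, str] | None) -> str:
    symbol = symbol.strip().upper()
    if aliases:
        symbol = aliases.get(symbol, symbol)
    return symbol


def _read_table(path: str | Path, required: Sequence[str], sep: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path, sep=sep, dtype=str, comment="#", skip_blank_lines=True)
    frame.columns = [c.strip() for c in frame.columns]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")
    return frame


def _float_cell(frame_value: str, row: int, column: str, path: Path) -> float:
    try:
        return float(frame_value)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path}:row {row}: column {column!r} is not numeric: {frame_value!r}") from exc


def read_probe_table(
    path: str | Path,
    spec: ArraySpec | None = None,
    *,
    sep: str = "\t",
    aliases: Mapping[str, str] | None = None,
) -> list[ProbeMeasurement]:
    """Read a probe measurement table; one :class:`ProbeMeasurement` per row, in file order.

    Raises :class:`FormatError` for missing columns / non-numeric cells and
    :class:`TableValidationError` (with the offending row number, counted from 1
    over data rows) for negative signals, bad site labels or duplicate probe ids.
    """
    path = Path(path)
    frame = _read_table(path, PROBE_COLUMNS, sep)
    array_id = spec.array_id if spec is not None else ""
    seen: set[str] = set()
    measurements: list[ProbeMeasurement] = []
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        probe_id = str(row.probe_id).strip()
        if probe_id in seen:
            raise TableValidationError(f"{path}:row {i}: duplicate probe_id {probe_id!r}")
        seen.add(probe_id)
        site = str(row.site).strip()
        if not is_valid_site(site):
            raise TableValidationError(
                f"{path}:row {i}: invalid site {site!r} (residue must be one of S, T, Y)"
            )
        values = {
            c: _float_cell(getattr(row, c), i, c, path)
            for c in PROBE_COLUMNS[3:]
        }
        for c, v in values.items():
            if v < 0:
                raise TableValidationError(f"{path}:row {i}: negative value in {c!r}: {v}")
        probe = AntibodyProbe(probe_id, _canonical(str(row.target), aliases), site, array_id)
        measurements.append(ProbeMeasurement(probe=probe, **values))
    return measurements


def write_probe_table(
    measurements: Iterable[ProbeMeasurement], path: str | Path, *, sep: str = "\t"
) -> None:
    rows = [
        {
            "probe_id": m.probe.probe_id,
            "target": m.probe.target_symbol,
            "site": m.probe.site,
            "treated_signal": m.treated_signal,
            "treated_error": m.treated_error,
            "control_signal": m.control_signal,
            "control_error": m.control_error,
        }
        for m in measurements
    ]
    pd.DataFrame(rows, columns=PROBE_COLUMNS).to_csv(path, sep=sep, index=False)


def read_ks_relations(
    path: str | Path,
    *,
    sep: str = "\t",
    aliases: Mapping[str, str] | None = None,
) -> list[KSRelation]:
    """Read a kinase-substrate relation table.

    Two layouts are accepted:

    * four columns ``kinase, substrate, site, effect``;
    * SIF-like three columns ``kinase, effect, substrate`` where the substrate
      cell is ``SYMBOL@SITE``.

    Duplicate ``(kinase, substrate, site)`` triples are rejected.
    """
    path = Path(path)
    frame = _read_table(path, ["kinase", "effect"], sep)
    sif = "site" not in frame.columns
    if sif and "substrate" not in frame.columns:
        raise FormatError(f"{path}: need either (substrate, site) columns or a substrate@site column")
    relations: list[KSRelation] = []
    seen: set[tuple[str, str, str]] = set()
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        effect = str(row.effect).strip().lower()
        if effect not in EFFECTS:
            raise FormatError(
                f"{path}:row {i}: unknown effect token {row.effect!r}; expected one of {EFFECTS}"
            )
        if sif:
            cell = str(row.substrate).strip()
            if "@" not in cell:
                raise FormatError(f"{path}:row {i}: expected SUBSTRATE@SITE, got {cell!r}")
            substrate, site = cell.rsplit("@", 1)
        else:
            substrate, site = str(row.substrate), str(row.site)
        site = site.strip()
        if not is_valid_site(site):
            raise TableValidationError(f"{path}:row {i}: invalid site {site!r}")
        rel = KSRelation(
            _canonical(str(row.kinase), aliases), _canonical(substrate, aliases), site, effect
        )
        if rel.key in seen:
            raise TableValidationError(
                f"{path}:row {i}: duplicate relation {rel.kinase}->{rel.substrate}@{rel.site}"
            )
        seen.add(rel.key)
        relations.append(rel)
    return relations


def write_ks_relations(
    relations: Iterable[KSRelation], path: str | Path, *, sep: str = "\t"
) -> None:
    rows = [
        {"kinase": r.kinase, "substrate": r.substrate, "site": r.site, "effect": r.effect}
        for r in relations
    ]
    pd.DataFrame(rows, columns=RELATION_COLUMNS).to_csv(path, sep=sep, index=False)


def lead_table(chains) -> pd.DataFrame:
    """Aggregate selected chains into a lead table.

    One row per distinct *measured* phosphosite appearing in any chain:
    target, site, direction (up/down), its measured CFC, and the number of
    chains it appears in. Sorted by (target, site) for stable output.
    """
    records: dict[tuple[str, str, str], dict] = {}
    for chain in chains:
        seen_in_chain: set[tuple[str, str, str]] = set()
        for (kinase, substrate, site, _effect), (value, source) in zip(
            chain.edges, chain.per_edge_cfc
        ):
            if source != "measured":
                continue
            key = (substrate, site, chain.direction)
            if key in seen_in_chain:
                continue
            seen_in_chain.add(key)
            rec = records.setdefault(
                key,
                {
                    "target": substrate,
                    "site": site,
                    "direction": chain.direction,
                    "cfc_percent": value,
                    "n_chains": 0,
                },
            )
            rec["n_chains"] += 1
    frame = pd.DataFrame(list(records.values()), columns=LEAD_COLUMNS)
    return frame.sort_values(["target", "site", "direction"], kind="stable").reset_index(drop=True)


def write_lead_table(chains, path: str | Path, *, sep: str = "\t") -> None:
    """Write the lead table for a set of selected chains (header-only if empty)."""
    lead_table(chains).to_csv(path, sep=sep, index=False)
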