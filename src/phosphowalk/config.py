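"""Run configuration.

A single :class:`RunConfig` carries every tunable of the pipeline; it
round-trips through YAML so a run can be reproduced from its emitted
provenance record. Every key has a default except the input paths, which are
command-line arguments rather than config entries.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields
from pathlib import Path

import yaml

from .errors import ParameterError

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    #: array design whose low-signal cutoff applies ("KAM-1325" or "KAM-2000")
    array_id: str = "KAM-1325"
    #: relative-error filter cutoff: summed error / |signal change|
    relative_error_threshold: float = 1.0
    #: walks per direction for the observed frequency estimate
    n_walks: int = 2000
    #: permutation reruns behind the null expectation
    n_permutations: int = 50
    #: pseudo-weight (percent points) keeping unmeasured edges reachable
    epsilon: float = 1.0
    #: keep chains with enrichment >= hi ...
    enrichment_hi: float = 1.5
    #: ... or <= lo (reciprocal of hi by default)
    enrichment_lo: float = 0.667
    #: gate chains on enrichment at all (the bundled demo config turns this off)
    enrichment_gate: bool = True
    #: chains must have strictly more than this many internal nodes
    min_intermediates: int = 2
    #: every per-edge |CFC| must strictly exceed this percent
    min_cfc: float = 5.0
    #: per-edge CFC bound applies to "all_edges" or to the chain "mean"
    cfc_mode: str = "all_edges"
    #: hard cap on walk length (edges); guarantees termination on cyclic input
    max_length: int = 25
    #: single-path imputation: "uniform" draw in [0, 20] or "fixed" midpoint 10
    impute_mode: str = "uniform"
    #: dataset condition: "experimental" imputes in [0, 20]; "control" imputes 20 exactly
    condition: str = "experimental"
    #: global seed; stage seeds are derived from it by stable hashing
    seed: int = 0

    def validate(self) -> "RunConfig":
        if self.enrichment_hi < self.enrichment_lo:
            raise ParameterError(
                f"enrichment_hi ({self.enrichment_hi}) must be >= enrichment_lo "
                f"({self.enrichment_lo})"
            )
        if self.n_walks < 1 or self.n_permutations < 1:
            raise ParameterError("n_walks and n_permutations must be >= 1")
        if self.epsilon <= 0:
            raise ParameterError("epsilon must be > 0")
        if self.max_length < 1:
            raise ParameterError("max_length must be >= 1")
        if self.impute_mode not in ("uniform", "fixed"):
            raise ParameterError(f"unknown impute_mode {self.impute_mode!r}")
        if self.condition not in ("experimental", "control"):
            raise ParameterError(f"unknown condition {self.condition!r}")
        if self.cfc_mode not in ("all_edges", "mean"):
            raise ParameterError(f"unknown cfc_mode {self.cfc_mode!r}")
        return self

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ParameterError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        return cls(**data).validate()

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})
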