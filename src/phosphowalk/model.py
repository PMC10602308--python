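"""Model/Results interface over the full pipeline.

:class:`PhosphoChainModel` bundles the data of one comparison — probe
measurement table(s) and the prior kinase-substrate relations — with an
array design and a run configuration. ``fit()`` executes preprocessing,
network attachment and the two-direction chain inference, and returns a
:class:`ChainInferenceResults` carrying the selected chains, the hit list,
walk diagnostics and export helpers.

    >>> from phosphowalk import PhosphoChainModel, fixtures
    >>> model = PhosphoChainModel(
    ...     fixtures.load_demo_probes(),
    ...     fixtures.load_demo_relations(),
    ...     config=fixtures.demo_config(),
    ... )
    >>> results = model.fit(seed=1)
    >>> print(results.summary())            # doctest: +SKIP
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__ as _version
from .arrays import (
    ARRAY_SPECS,
    ArraySpec,
    KSRelation,
    ProbeMeasurement,
    lead_table,
    read_ks_relations,
    read_probe_table,
    write_lead_table,
)
from .config import RunConfig
from .errors import ParameterError
from .network import SignedNetwork, attach_measurements, build_network, find_roots
from .pathmap import PathwayMap, assemble_map, export_map, style_edges
from .preprocess import FilterReport, preprocess_pipeline
from .walks import InferenceRun, PhosphoChain, infer_direction_run

__all__ = ["PhosphoChainModel", "ChainInferenceResults"]


class PhosphoChainModel:
    """Phosphorylation-chain inference model for one treated-vs-control comparison.

    Parameters
    ----------
    measurements
        One probe measurement table or a list of replicate tables (raw, not
        yet filtered).
    relations
        Prior kinase-substrate relations (site-resolved, signed).
    array_spec
        The array design; defaults to the design named in ``config.array_id``.
    config
        Run configuration; defaults to :class:`RunConfig` defaults.
    """

    def __init__(
        self,
        measurements: Sequence[ProbeMeasurement] | Sequence[Sequence[ProbeMeasurement]],
        relations: Sequence[KSRelation],
        array_spec: ArraySpec | None = None,
        config: RunConfig | None = None,
    ):
        self.config = (config or RunConfig()).validate()
        if array_spec is None:
            try:
                array_spec = ARRAY_SPECS[self.config.array_id]
            except KeyError:
                raise ParameterError(
                    f"unknown array design {self.config.array_id!r}; "
                    f"known: {sorted(ARRAY_SPECS)}"
                ) from None
        self.array_spec = array_spec
        if measurements and isinstance(measurements[0], ProbeMeasurement):
            self.tables: list[Sequence[ProbeMeasurement]] = [measurements]  # type: ignore[list-item]
        else:
            self.tables = list(measurements)  # type: ignore[arg-type]
        self.relations = list(relations)

    @classmethod
    def from_tables(
        cls,
        probe_paths: str | Path | Sequence[str | Path],
        relation_path: str | Path,
        array_spec: ArraySpec | None = None,
        config: RunConfig | None = None,
        *,
        sep: str = "\t",
        aliases: Mapping[str, str] | None = None,
    ) -> "PhosphoChainModel":
        """Build the model from delimited-text tables on disk."""
        config = (config or RunConfig()).validate()
        spec = array_spec or ARRAY_SPECS.get(config.array_id)
        if isinstance(probe_paths, (str, Path)):
            probe_paths = [probe_paths]
        tables = [read_probe_table(p, spec, sep=sep, aliases=aliases) for p in probe_paths]
        relations = read_ks_relations(relation_path, sep=sep, aliases=aliases)
        return cls(tables, relations, array_spec=spec, config=config)

    def fit(self, seed: int | None = None, **overrides) -> "ChainInferenceResults":
        """Run preprocessing, measurement attachment and both direction analyses."""
        config = dataclasses.replace(self.config, **overrides).validate()
        seed = config.seed if seed is None else int(seed)
        annotated, report = preprocess_pipeline(
            self.tables,
            self.array_spec,
            relative_error_threshold=config.relative_error_threshold,
        )
        network = attach_measurements(build_network(self.relations), annotated)
        run = infer_direction_run(network, config, seed)
        return ChainInferenceResults(
            model=self,
            config=config,
            seed=seed,
            filter_report=report,
            network=network,
            run=run,
        )


class ChainInferenceResults:
    """Fitted results: selected chains, hits, diagnostics and exports."""

    def __init__(
        self,
        model: PhosphoChainModel,
        config: RunConfig,
        seed: int,
        filter_report: FilterReport,
        network: SignedNetwork,
        run: InferenceRun,
    ):
        self.model = model
        self.config = config
        self.seed = seed
        self.filter_report = filter_report
        self.network = network
        self.run = run

    # -- primary outputs ----------------------------------------------------

    @property
    def up_chains(self) -> list[PhosphoChain]:
        return self.run.up_chains

    @property
    def down_chains(self) -> list[PhosphoChain]:
        return self.run.down_chains

    @property
    def hits(self) -> list[tuple[str, str, str, float]]:
        """(target, site, direction, measured CFC) for every hit phosphosite."""
        return self.run.hits

    @property
    def n_hits(self) -> int:
        return len(self.run.hits)

    def hits_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.run.hits, columns=["target", "site", "direction", "cfc_percent"]
        )

    def chains_frame(self) -> pd.DataFrame:
        rows = []
        for chain in self.run.up_chains + self.run.down_chains:
            rows.append(
                {
                    "direction": chain.direction,
                    "root": chain.root,
                    "path": chain.path_label(),
                    "n_intermediates": chain.n_intermediates,
                    "score": chain.score,
                    "termination": chain.termination_reason,
                    "per_edge_cfc": ";".join(
                        "NA" if v is None else f"{v:+.4g}{'*' if s == 'imputed' else ''}"
                        for v, s in chain.per_edge_cfc
                    ),
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "direction", "root", "path", "n_intermediates",
                "score", "termination", "per_edge_cfc",
            ],
        )

    def lead_frame(self) -> pd.DataFrame:
        return lead_table(self.run.all_chains())

    def to_pathway_map(self, width_range: tuple[float, float] = (0.5, 4.0)) -> PathwayMap:
        return style_edges(
            assemble_map(self.run.up_chains, self.run.down_chains), width_range
        )

    # -- persistence --------------------------------------------------------

    def provenance(self) -> dict:
        config = self.config.to_dict()
        digest = hashlib.sha256(
            json.dumps(config, sort_keys=True).encode()
        ).hexdigest()[:16]
        return {
            "package": "phosphowalk",
            "version": _version,
            "seed": self.seed,
            "config": config,
            "config_sha256_16": digest,
        }

    def save_chains(self, tsv_path: str | Path, json_path: str | Path | None = None) -> None:
        """Chain table as TSV; optionally a JSON record with full provenance."""
        self.chains_frame().to_csv(tsv_path, sep="\t", index=False)
        if json_path is not None:
            doc = {
                "provenance": self.provenance(),
                "chains": [
                    {
                        "direction": c.direction,
                        "edges": [list(e) for e in c.edges],
                        "per_edge_cfc": [
                            [v, s] for v, s in c.per_edge_cfc
                        ],
                        "termination_reason": c.termination_reason,
                    }
                    for c in self.run.up_chains + self.run.down_chains
                ],
            }
            Path(json_path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")

    def save_leads(self, path: str | Path) -> None:
        write_lead_table(self.run.all_chains(), path)

    def save_map(self, path: str | Path, format: str = "graphml") -> None:
        export_map(self.to_pathway_map(), path, format)

    # -- presentation -------------------------------------------------------

    def summary(self) -> str:
        """Human-readable run summary."""
        report = self.filter_report
        roots = sorted(find_roots(self.network))
        up, down = self.run.up_chains, self.run.down_chains
        width = 66
        lines = [
            "Phosphorylation chain inference".center(width),
            "=" * width,
            f"array design:      {self.model.array_spec.array_id} "
            f"(low-signal cutoff {self.model.array_spec.low_signal_threshold:g} units)",
            f"probes:            {report.n_input} in, {report.n_retained} retained "
            f"(low-signal {report.n_low_signal_removed}, relative-error "
            f"{report.n_relative_error_removed}, total-error {report.n_total_error_removed})",
            f"network:           {len(self.network.nodes)} proteins, "
            f"{self.network.n_edges()} site edges, "
            f"{len(self.network.measured_edges())} measured; roots: "
            + ", ".join(roots[:6]) + (" ..." if len(roots) > 6 else ""),
            f"walks:             {self.config.n_walks} walks x "
            f"{self.config.n_permutations} permutations, seed {self.seed}",
            "-" * width,
            f"selected chains:   {len(up)} up, {len(down)} down",
            f"hits:              {self.n_hits} measured phosphosites in selected chains",
        ]
        for direction, chains in (("up", up), ("down", down)):
            for chain in chains[:5]:
                lines.append(
                    f"  [{direction:>4}] {chain.path_label()}  "
                    f"(score {chain.score:.1f}, {chain.termination_reason})"
                )
            if len(chains) > 5:
                lines.append(f"  [{direction:>4}] ... {len(chains) - 5} more")
        lines.append("=" * width)
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<ChainInferenceResults: {len(self.up_chains)} up / "
            f"{len(self.down_chains)} down chains, {self.n_hits} hits, seed={self.seed}>"
        )
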