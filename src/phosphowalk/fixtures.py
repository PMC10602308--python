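"""Bundled demonstration data.

Two small text fixtures ship with the package:

* ``toy_array.tsv`` — a 12-probe array whose signals were chosen by hand so
  each preprocessing filter removes at least one probe; used for exact filter
  bookkeeping checks and as a minimal worked input.
* ``akt_cdk1_relations.tsv`` / ``akt_cdk1_probes.tsv`` — a curated two-arm
  signalling network (growth/survival AKT arm, cell-cycle CDK1 arm) with
  synthetic, sign-consistent measurements: the AKT arm is up-regulated, the
  CDK1 arm down-regulated. It serves as the qualitative regression fixture
  for the whole pipeline.

The demo run configuration disables the enrichment gate and the
intermediate-count bound: the curated network's arms are only 2-3 edges
long, and a permutation null over ~17 edges carries no information, so the
demo exercises direction recovery, termination and parallel resolution
rather than enrichment statistics.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .arrays import KAM_1325, KSRelation, ProbeMeasurement, read_ks_relations, read_probe_table
from .config import RunConfig

__all__ = [
    "toy_array_path",
    "load_toy_array",
    "demo_relations_path",
    "demo_probes_path",
    "load_demo_relations",
    "load_demo_probes",
    "demo_config",
]


def _data_path(name: str) -> Path:
    return Path(resources.files("phosphowalk") / "data" / name)


def toy_array_path() -> Path:
    return _data_path("toy_array.tsv")


def load_toy_array() -> list[ProbeMeasurement]:
    return read_probe_table(toy_array_path(), KAM_1325)


def demo_relations_path() -> Path:
    return _data_path("akt_cdk1_relations.tsv")


def demo_probes_path() -> Path:
    return _data_path("akt_cdk1_probes.tsv")


def load_demo_relations() -> list[KSRelation]:
    return read_ks_relations(demo_relations_path())


def load_demo_probes() -> list[ProbeMeasurement]:
    return read_probe_table(demo_probes_path(), KAM_1325)


def demo_config(**overrides) -> RunConfig:
    base = dict(
        array_id="KAM-1325",
        min_intermediates=0,
        enrichment_gate=False,
        n_walks=4000,
        n_permutations=20,
    )
    base.update(overrides)
    return RunConfig(**base).validate()
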