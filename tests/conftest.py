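"""Shared fixtures: hand-built micro-networks and measurement helpers."""

from __future__ import annotations

import math

import pytest

from phosphowalk.arrays import AntibodyProbe, KSRelation, ProbeMeasurement
from phosphowalk.network import SignedNetwork, attach_measurements, build_network
from phosphowalk.walks import PhosphoChain


def measurement(
    probe_id: str,
    target: str,
    site: str,
    cfc: float,
    *,
    control: float = 2000.0,
    error: float = 10.0,
) -> ProbeMeasurement:
    """An annotated measurement whose CFC is exactly ``cfc``."""
    treated = control * (1.0 + cfc / 100.0)
    m = ProbeMeasurement(AntibodyProbe(probe_id, target, site), treated, error, control, error)
    return m.with_fold_changes(cfc, math.log2(1.0 + cfc / 100.0))


def attach_cfc(network: SignedNetwork, site_cfcs: dict[tuple[str, str], float]) -> SignedNetwork:
    """Attach one probe per (target, site) with the given CFC values."""
    ms = [
        measurement(f"m{i}", target, site, cfc)
        for i, ((target, site), cfc) in enumerate(sorted(site_cfcs.items()))
    ]
    return attach_measurements(network, ms)


def chain(
    edge_specs: list[tuple[str, str, str, str]],
    cfcs: list[float | None],
    direction: str = "up",
    *,
    sources: list[str] | None = None,
    termination: str = "sink",
) -> PhosphoChain:
    """Build a PhosphoChain literal for rule tests."""
    if sources is None:
        sources = ["measured" if v is not None else "none" for v in cfcs]
    return PhosphoChain(
        edges=tuple(edge_specs),
        direction=direction,
        per_edge_cfc=tuple(zip(cfcs, sources)),
        termination_reason=termination,
    )


@pytest.fixture
def fork_network() -> SignedNetwork:
    """A -> B (act); B -> C (act); B -| D (inh); equal (unmeasured) weights."""
    return build_network(
        [
            KSRelation("A", "B", "S1", "activation"),
            KSRelation("B", "C", "S2", "activation"),
            KSRelation("B", "D", "S3", "inhibition"),
        ]
    )


@pytest.fixture
def single_path_network() -> SignedNetwork:
    return build_network([KSRelation("A", "B", "T7", "activation")])


@pytest.fixture
def two_cycle_network() -> SignedNetwork:
    return build_network(
        [
            KSRelation("A", "B", "S1", "activation"),
            KSRelation("B", "A", "S2", "activation"),
        ]
    )
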