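"""End-to-end validation benchmarks.

Because no raw array data are publicly available for the setting this
package targets, its correctness case rests on property benchmarks that any
faithful implementation must satisfy:

* **Sampler vs oracle** — on small random networks the random-walk chain
  frequencies must match the exact enumeration of the same walk process.
* **Zero-noise identifiability** — a planted cascade simulated without noise
  must always be recovered.
* **Recovery under noise** — a planted +30% cascade under 5% multiplicative
  noise must be recovered with high edge precision/recall, and its effect
  size re-estimated accurately.
* **Null calibration** — with nothing planted, the pipeline must almost
  never select any chain.
* **Demonstration regression** — the bundled two-arm network must yield its
  known qualitative directions.
* **Determinism** — identical seeds must give byte-identical outputs.

Each benchmark is seeded and returns plain numbers; the test suite asserts
on them and ``scripts/acceptance.py`` reports them.
"""

from __future__ import annotations

import json
import math
from io import StringIO

import numpy as np

from .arrays import KAM_1325, AntibodyProbe, ProbeMeasurement
from .config import RunConfig
from .fixtures import demo_config, load_demo_probes, load_demo_relations
from .model import PhosphoChainModel
from .network import attach_measurements, build_network
from .seeds import derive_seed
from .synthetic import build_scenario, recovery_metrics, simulate_arrays
from .walks import enumerate_chains, random_walk

__all__ = [
    "oracle_tv_distances",
    "zero_noise_recovery",
    "noisy_recovery",
    "null_calibration",
    "demo_regression",
    "determinism_check",
]


def _random_measured_network(rng: np.random.Generator, seed: int):
    """A small random DAG (<=12 nodes, <=20 edges) with CFCs on ~half the sites."""
    from .synthetic import generate_network

    while True:
        n = int(rng.integers(6, 13))
        rels = generate_network(n, 1.3, 0.2, seed=seed)
        seed += 10_007
        if 1 <= len(rels) <= 20:
            break
    net = build_network(rels)
    ms = []
    for j, (sub, site) in enumerate(sorted({(r.substrate, r.site) for r in rels})):
        if rng.random() < 0.5:
            cfc = float(rng.uniform(-50.0, 50.0))
            m = ProbeMeasurement(
                AntibodyProbe(f"q{j}", sub, site),
                1000.0 * (1.0 + cfc / 100.0), 10.0, 1000.0, 10.0,
            ).with_fold_changes(cfc, math.log2(1.0 + cfc / 100.0))
            ms.append(m)
    return attach_measurements(net, ms)


def oracle_tv_distances(
    n_networks: int = 200, n_walks: int = 100_000, seed: int = 0
) -> list[float]:
    """Total-variation distance between sampled and exact chain distributions,
    one value per random network."""
    rng = np.random.default_rng(derive_seed(seed, "oracle"))
    distances = []
    for i in range(n_networks):
        net = _random_measured_network(rng, derive_seed(seed, "oracle-net", i))
        exact = enumerate_chains(net, 25)
        est = random_walk(net, n_walks, seed=derive_seed(seed, "oracle-walk", i))
        keys = set(exact) | set(est.observed)
        tv = 0.5 * sum(abs(exact.get(k, 0.0) - est.observed.get(k, 0.0)) for k in keys)
        distances.append(tv)
    return distances


def _run_scenario(seed: int, **scenario_kwargs):
    scenario = build_scenario(seed=derive_seed(seed, "scenario"), **scenario_kwargs)
    tables = simulate_arrays(scenario, KAM_1325)
    model = PhosphoChainModel(tables, scenario.relations, KAM_1325, RunConfig(seed=seed))
    results = model.fit()
    return scenario, results


def zero_noise_recovery(n_seeds: int = 50, seed: int = 0) -> list[float]:
    """site_hit_recall of the planted cascade per seed, noise and error off."""
    recalls = []
    for i in range(n_seeds):
        scenario, results = _run_scenario(
            derive_seed(seed, "zero-noise", i),
            noise_sd_fraction=0.0,
            error_sd_fraction=0.0,
        )
        _, _, site_recall = recovery_metrics(results.run.all_chains(), scenario)
        recalls.append(site_recall)
    return recalls


def noisy_recovery(n_seeds: int = 50, seed: int = 0) -> dict:
    """Planted-cascade recovery under the default noisy conditions.

    Returns per-seed precision/recall plus the pooled mean of the measured
    CFC over recovered planted edges (the pipeline's estimate of the planted
    +30% effect).
    """
    precisions, recalls, cfc_values = [], [], []
    for i in range(n_seeds):
        scenario, results = _run_scenario(derive_seed(seed, "noisy", i))
        chains = results.run.all_chains()
        precision, recall, _ = recovery_metrics(chains, scenario)
        precisions.append(precision)
        recalls.append(recall)
        planted = scenario.planted_edges()
        cfc_values += [
            value
            for c in chains
            for (k, s, site, _), (value, src) in zip(c.edges, c.per_edge_cfc)
            if src == "measured" and (k, s, site) in planted
        ]
    return {
        "precision": precisions,
        "recall": recalls,
        "median_precision": float(np.median(precisions)),
        "median_recall": float(np.median(recalls)),
        "mean_planted_cfc": float(np.mean(cfc_values)) if cfc_values else float("nan"),
    }


def null_calibration(n_seeds: int = 50, seed: int = 0) -> dict:
    """Fraction of no-cascade scenarios in which any chain gets selected."""
    positives = 0
    for i in range(n_seeds):
        _, results = _run_scenario(derive_seed(seed, "null", i), n_cascades=0)
        positives += bool(results.run.all_chains())
    return {"n_seeds": n_seeds, "n_positive": positives,
            "false_positive_rate": positives / n_seeds}


def demo_regression(seed: int = 1) -> dict:
    """Qualitative direction checks on the bundled two-arm demonstration."""
    model = PhosphoChainModel(
        load_demo_probes(), load_demo_relations(), config=demo_config()
    )
    results = model.fit(seed=seed)
    hits = {(t, s): d for t, s, d, _ in results.hits}
    past_inhibition = 0
    for est in (results.run.up_estimate, results.run.down_estimate):
        for c in est.chains.values():
            if "inhibition" in [e[3] for e in c.edges[:-1]]:
                past_inhibition += 1
    return {
        "akt_s473_up": hits.get(("AKT", "S473")) == "up",
        "cdk1_y15_down": hits.get(("CDK1", "Y15")) == "down",
        "jun_s73_down": hits.get(("JUN", "S73")) == "down",
        "chains_past_inhibitory_edge": past_inhibition,
        "n_hits": results.n_hits,
    }


def _fingerprint(results) -> str:
    buf = StringIO()
    results.chains_frame().to_csv(buf, sep="\t", index=False)
    results.lead_frame().to_csv(buf, sep="\t", index=False)
    pm = results.to_pathway_map()
    buf.write(json.dumps(
        [[u, v, k, sorted(pm.edge_data(u, v, k).items())] for u, v, k in pm.edge_keys()]
    ))
    return buf.getvalue()


def determinism_check(seed: int = 0) -> bool:
    """True iff repeated runs with one seed give identical chain/lead/map output."""
    def run_once():
        scenario, results = _run_scenario(derive_seed(seed, "determinism"))
        demo = PhosphoChainModel(
            load_demo_probes(), load_demo_relations(), config=demo_config()
        ).fit(seed=seed)
        return _fingerprint(results) + _fingerprint(demo)

    return run_once() == run_once()
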