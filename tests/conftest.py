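"""Shared fixtures: a well-conditioned five-item benchmark instrument with
known true parameters, simulated datasets at several sizes, and one large
end-to-end pipeline run reused by the slower checks."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from saqirt.calibrate import calibrate_domain
from saqirt.grm import GrmItemParams, from_thresholds
from saqirt.instrument import InstrumentSpec
from saqirt.simulate import GroupMix, SimulationConfig, generate_dataset


def make_benchmark_items(
    n_items: int = 5,
    prefix: str = "D",
    seed: int = 7,
    slope_range: tuple[float, float] = (1.0, 2.0),
    base_thresholds: tuple[float, ...] = (-1.8, -0.6, 0.6, 1.8),
) -> dict[str, GrmItemParams]:
    """Moderate, well-separated GRM items for recovery/fit studies."""
    rng = np.random.default_rng(seed)
    items: dict[str, GrmItemParams] = {}
    for j in range(1, n_items + 1):
        a = float(rng.uniform(*slope_range))
        b = np.sort(np.asarray(base_thresholds) + rng.uniform(-0.3, 0.3, len(base_thresholds)))
        items[f"{prefix}{j}"] = from_thresholds(f"{prefix}{j}", a, b)
    return items


def single_domain_spec(item_ids, domain: str = "D", k: int = 5) -> InstrumentSpec:
    return InstrumentSpec(
        domains=((domain, tuple(item_ids)),),
        n_categories={i: k for i in item_ids},
    )


def simulate_single_group(
    spec: InstrumentSpec,
    true_items: dict[str, GrmItemParams],
    n: int,
    seed: int,
):
    """One-population dataset (standard-normal trait, no missingness)."""
    d = len(spec.domain_ids)
    cfg = SimulationConfig(
        n_respondents=n,
        spec=spec,
        true_items=true_items,
        group_mix=(GroupMix("all", 1.0, 0.0, 1.0),),
        latent_corr=np.eye(d),
        seed=seed,
    )
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def bench_items() -> dict[str, GrmItemParams]:
    return make_benchmark_items()


@pytest.fixture(scope="session")
def bench_spec(bench_items) -> InstrumentSpec:
    return single_domain_spec(tuple(bench_items))


@pytest.fixture(scope="session")
def bench_item_list(bench_items, bench_spec):
    return [bench_items[i] for i in bench_spec.item_ids]


@pytest.fixture(scope="session")
def recovery_dataset(bench_spec, bench_items):
    """n=2000 single-group draw from the benchmark truth (frozen seed)."""
    matrix, truth = simulate_single_group(bench_spec, bench_items, n=2000, seed=10)
    return matrix, truth


@pytest.fixture(scope="session")
def recovery_calib(recovery_dataset, bench_spec):
    matrix, _ = recovery_dataset
    return calibrate_domain(matrix, "D", bench_spec)


@pytest.fixture(scope="session")
def big_pipeline(tmp_path_factory):
    """Collected-scale end-to-end run: simulate, filter, calibrate all five
    domains, score both ways, compare.  Shared across the slow checks."""
    from saqirt.pipeline import run_pipeline

    out = tmp_path_factory.mktemp("pipeline")
    return run_pipeline(
        {
            "seed": 1,
            "simulate": {"n_respondents": 45242},
            "fit": {"enabled": False},
        },
        out_dir=out,
    )
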