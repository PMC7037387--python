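"""Synthetic SAQ-C-like survey data with known ground truth.

The study data behind this package (a national safety-culture survey) is
restricted, so every downstream stage is exercised on simulated
questionnaires instead.  The generator draws correlated domain traits
from a multivariate normal (group-specific location/scale by hospital
level), produces item responses from the graded response model at each
respondent's domain trait, and injects completely-at-random missingness
in item cells and in the group label.  All randomness derives from one
seed, with independent streams per stage so that toggling missingness
never changes the drawn responses.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
import numpy as np
import pandas as pd

from .grm import GrmItemParams, category_probs, from_thresholds
from .instrument import InstrumentSpec, ResponseMatrix, saqc_instrument

__all__ = [
    "GroupMix",
    "SimulationConfig",
    "TruthBundle",
    "default_saqc_config",
    "generate_dataset",
]

#: hospital-level shares observed in the analyzed national sample
SAQC_GROUP_SHARES = (0.447, 0.364, 0.153, 0.036)
SAQC_GROUP_LABELS = (
    "medical_center",
    "regional",
    "district",
    "psychiatric",
)


@dataclass(frozen=True)
class GroupMix:
    """One group's share of respondents and its latent trait distribution."""

    label: str
    proportion: float
    mu: float = 0.0
    sigma: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.proportion <= 1.0:
            raise ValueError(f"group {self.label!r}: proportion outside [0, 1]")
        if self.sigma < 0:
            raise ValueError(f"group {self.label!r}: sigma must be >= 0")


@dataclass(frozen=True)
class SimulationConfig:
    """Everything needed to draw one synthetic survey dataset."""

    n_respondents: int
    spec: InstrumentSpec
    true_items: dict[str, GrmItemParams]
    group_mix: tuple[GroupMix, ...]
    latent_corr: np.ndarray
    missing_rate_items: float = 0.0
    missing_rate_group: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_respondents < 1:
            raise ValueError("n_respondents must be >= 1")
        props = sum(g.proportion for g in self.group_mix)
        if not np.isclose(props, 1.0, atol=1e-8):
            raise ValueError(f"group proportions must sum to 1, got {props}")
        corr = np.asarray(self.latent_corr, dtype=float)
        d = len(self.spec.domain_ids)
        if corr.shape != (d, d):
            raise ValueError(f"latent_corr must be {d}x{d}")
        if not np.allclose(corr, corr.T, atol=1e-10):
            raise ValueError("latent_corr must be symmetric")
        if not np.allclose(np.diag(corr), 1.0, atol=1e-10):
            raise ValueError("latent_corr must have unit diagonal")
        if np.linalg.eigvalsh(corr).min() <= 0:
            raise ValueError("latent_corr must be positive definite")
        for rate, name in (
            (self.missing_rate_items, "missing_rate_items"),
            (self.missing_rate_group, "missing_rate_group"),
        ):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} outside [0, 1]")
        for it in self.spec.item_ids:
            if it not in self.true_items:
                raise ValueError(f"no true parameters for item {it!r}")
        object.__setattr__(self, "latent_corr", corr)

    def to_dict(self) -> dict:
        return {
            "n_respondents": self.n_respondents,
            "instrument": self.spec.name,
            "true_items": [
                {"item_id": it.item_id, "a": it.a, "c": list(it.c)}
                for it in (self.true_items[i] for i in self.spec.item_ids)
            ],
            "group_mix": [
                {"label": g.label, "proportion": g.proportion, "mu": g.mu, "sigma": g.sigma}
                for g in self.group_mix
            ],
            "latent_corr": np.asarray(self.latent_corr).tolist(),
            "missing_rate_items": self.missing_rate_items,
            "missing_rate_group": self.missing_rate_group,
            "seed": self.seed,
        }


@dataclass(frozen=True)
class TruthBundle:
    """Ground truth behind a simulated dataset: traits, labels, config."""

    theta: pd.DataFrame  # respondents x domains, trait-SD units
    group_labels: pd.Series  # true labels, before missingness injection
    config: SimulationConfig

    def __post_init__(self) -> None:
        d = len(self.config.spec.domain_ids)
        if self.theta.shape != (self.config.n_respondents, d):
            raise ValueError("theta dimensions do not match config")


#: base thresholds (trait-SD units) for agreement-heavy safety items:
#: most category switches sit below the trait mean
_BASE_THRESHOLDS = (-3.1, -2.2, -1.3, 0.2)


def default_saqc_config(
    n_respondents: int,
    seed: int,
    missing_rate_items: float = 0.005,
    missing_rate_group: float = 0.04,
) -> SimulationConfig:
    """SAQ-C-like simulation settings with realistic item and group structure.

    Item slopes are uniform on [1.0, 2.5] (bracketing the 1.54-2.31 a
    well-calibrated national survey reports); thresholds sit in a skewed
    negative band so agreement categories dominate, giving first
    intercepts c1 = -a*b1 of roughly 3-8.  Group shares follow the
    four-level hospital mix (44.7/36.4/15.3/3.6%); inter-domain trait
    correlations are drawn in [0.75, 0.91].  Default missingness rates
    exclude roughly one-sixth of questionnaires, the same order as the
    national administration.
    """
    spec = saqc_instrument()
    rng = np.random.default_rng(seed)
    true_items: dict[str, GrmItemParams] = {}
    for item_id in spec.item_ids:
        a = float(rng.uniform(1.0, 2.5))
        b = np.asarray(_BASE_THRESHOLDS) + rng.uniform(-0.3, 0.3, size=4)
        b.sort()
        for m in range(1, b.size):  # keep switch points apart
            b[m] = max(b[m], b[m - 1] + 0.25)
        true_items[item_id] = from_thresholds(item_id, a, b)

    mus = (0.0, -0.1, -0.2, -0.3)
    sigmas = (1.0, 0.95, 1.05, 0.9)
    group_mix = tuple(
        GroupMix(label=l, proportion=p, mu=m, sigma=s)
        for l, p, m, s in zip(SAQC_GROUP_LABELS, SAQC_GROUP_SHARES, mus, sigmas)
    )

    d = len(spec.domain_ids)
    corr = np.eye(d)
    for i in range(d):
        for j in range(i + 1, d):
            corr[i, j] = corr[j, i] = rng.uniform(0.75, 0.91)
    # shrink toward the equicorrelation center until positive definite
    target = np.full((d, d), 0.83)
    np.fill_diagonal(target, 1.0)
    lam = 0.0
    while np.linalg.eigvalsh((1 - lam) * corr + lam * target).min() <= 1e-8:
        lam += 0.05
    corr = (1 - lam) * corr + lam * target

    return SimulationConfig(
        n_respondents=n_respondents,
        spec=spec,
        true_items=true_items,
        group_mix=group_mix,
        latent_corr=corr,
        missing_rate_items=missing_rate_items,
        missing_rate_group=missing_rate_group,
        seed=seed,
    )


def generate_dataset(config: SimulationConfig) -> tuple[ResponseMatrix, TruthBundle]:
    """Draw one dataset: labels, latent traits, GRM responses, missingness.

    Fully reproducible from ``config.seed``; the four random streams
    (labels / traits / responses / missingness) are split so changing the
    missingness rates leaves the drawn responses untouched.
    """
    spec = config.spec
    n = config.n_respondents
    ss = np.random.SeedSequence(config.seed)
    rng_labels, rng_theta, rng_resp, rng_miss = (
        np.random.default_rng(child) for child in ss.spawn(4)
    )

    props = np.array([g.proportion for g in config.group_mix])
    g_idx = rng_labels.choice(len(props), size=n, p=props / props.sum())
    labels = np.array([config.group_mix[i].label for i in g_idx], dtype=object)

    d = len(spec.domain_ids)
    chol = np.linalg.cholesky(config.latent_corr)
    z = rng_theta.standard_normal((n, d)) @ chol.T
    mu_g = np.array([g.mu for g in config.group_mix])[g_idx]
    sigma_g = np.array([g.sigma for g in config.group_mix])[g_idx]
    theta = mu_g[:, None] + sigma_g[:, None] * z

    data = pd.DataFrame(index=pd.RangeIndex(n, name="respondent_id"))
    dom_index = {dom: i for i, dom in enumerate(spec.domain_ids)}
    for dom, items in spec.domains:
        th = theta[:, dom_index[dom]]
        for item_id in items:
            probs = category_probs(config.true_items[item_id], th)  # (n, K)
            u = rng_resp.uniform(size=n)
            cum = np.cumsum(probs, axis=1)
            codes = (u[:, None] > cum[:, :-1]).sum(axis=1) + 1
            data[item_id] = pd.array(codes, dtype="Int64")

    group = pd.Series(labels, index=data.index, dtype="string", name="group")
    if config.missing_rate_items > 0:
        mask = rng_miss.uniform(size=(n, spec.n_items)) < config.missing_rate_items
        for j, item_id in enumerate(spec.item_ids):
            col = data[item_id].copy()
            col[mask[:, j]] = pd.NA
            data[item_id] = col
    if config.missing_rate_group > 0:
        gmask = rng_miss.uniform(size=n) < config.missing_rate_group
        group = group.where(~gmask)

    matrix = ResponseMatrix(data=data, group=group)
    truth = TruthBundle(
        theta=pd.DataFrame(theta, index=data.index, columns=list(spec.domain_ids)),
        group_labels=pd.Series(labels, index=data.index, dtype="string", name="group"),
        config=config,
    )
    return matrix, truth


def write_simulation(
    matrix: ResponseMatrix,
    truth: TruthBundle,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write responses CSV, truth CSV and the config JSON side by side."""
    from .instrument import write_responses

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "responses": out / "responses.csv",
        "truth": out / "truth.csv",
        "config": out / "simulation_config.json",
    }
    write_responses(matrix, paths["responses"])
    truth_frame = truth.theta.copy()
    truth_frame["group"] = truth.group_labels
    truth_frame.to_csv(paths["truth"])
    paths["config"].write_text(json.dumps(truth.config.to_dict(), indent=2) + "\n")
    return paths
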