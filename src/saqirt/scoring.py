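"""EAP trait scoring, summed-score conversion tables, and 0-100 rescaling.

Expected a posteriori (EAP) scoring reports the posterior mean of the
latent trait given a response pattern, a calibrated item set and a
normal prior, evaluated by quadrature.  Scores are in trait-SD units and
are additionally reported rounded to 2 decimal places, the practical
reporting convention the resolution comparison counts unique values on.

For datasets where only domain totals survive, the Lord-Wingersky
recursion builds the summed-score distribution conditional on the trait,
from which a summed score -> EAP conversion table follows.  A linear
map to the familiar 0-100 format is provided for reporting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .calibrate import CalibrationResult, LatentGroupParams, QuadratureGrid
from .grm import GrmItemParams, category_probs
from .instrument import InstrumentSpec, ResponseMatrix

__all__ = [
    "EapScore",
    "RescaleConfig",
    "eap_pattern",
    "score_matrix",
    "summed_score_table",
    "rescale_0_100",
]


@dataclass(frozen=True)
class EapScore:
    """Posterior mean and SD of the trait for one response pattern."""

    theta_hat: float
    posterior_sd: float

    @property
    def theta_rounded(self) -> float:
        return round(self.theta_hat, 2)


@dataclass(frozen=True)
class RescaleConfig:
    """Linear map from trait-SD units to the 0-100 reporting scale."""

    theta_low: float = -5.0
    theta_high: float = 5.0
    clip: bool = True

    def __post_init__(self) -> None:
        if not self.theta_low < self.theta_high:
            raise ValueError("theta_low must be below theta_high")


def _default_grid() -> QuadratureGrid:
    return QuadratureGrid.equally_spaced()


def _posterior(
    items: Sequence[GrmItemParams],
    responses: Sequence,
    prior: LatentGroupParams | None,
    grid: QuadratureGrid | None,
) -> tuple[np.ndarray, np.ndarray]:
    grid = grid or _default_grid()
    if prior is not None and (prior.mu != 0.0 or prior.sigma != 1.0):
        grid = grid.reweight(prior.mu, prior.sigma)
    log_post = grid.log_weights.copy()
    n_used = 0
    for item, x in zip(items, responses, strict=True):
        if x is None:
            continue
        xf = float(x)
        if np.isnan(xf):
            continue
        k = int(xf)
        if k != xf or not 1 <= k <= item.n_categories:
            raise ValueError(
                f"item {item.item_id!r}: code {x!r} outside 1..{item.n_categories}"
            )
        log_post = log_post + np.log(category_probs(item, grid.nodes)[:, k - 1])
        n_used += 1
    if n_used == 0:
        raise ValueError("cannot score a pattern with all responses missing")
    post = np.exp(log_post - logsumexp(log_post))
    return grid.nodes, post


def eap_pattern(
    items: Sequence[GrmItemParams],
    responses: Sequence,
    prior: LatentGroupParams | None = None,
    grid: QuadratureGrid | None = None,
) -> EapScore:
    """EAP trait estimate for one response pattern under a normal prior.

    ``theta_hat`` is the quadrature posterior mean; ``posterior_sd`` the
    matching posterior SD.  Missing responses are skipped; at least one
    response must be present.
    """
    nodes, post = _posterior(items, responses, prior, grid)
    mean = float(post @ nodes)
    var = float(post @ (nodes - mean) ** 2)
    return EapScore(theta_hat=mean, posterior_sd=float(np.sqrt(max(var, 0.0))))


def score_matrix(
    matrix: ResponseMatrix,
    calibs: Mapping[str, CalibrationResult] | CalibrationResult,
    spec: InstrumentSpec,
    grid: QuadratureGrid | None = None,
) -> pd.DataFrame:
    """EAP-score every respondent on every calibrated domain.

    Returns a frame with columns ``{domain}_theta``, ``{domain}_theta_2dp``
    and ``{domain}_psd``.  When a calibration carries group parameters,
    each respondent is scored under their group's latent prior (reference
    prior when the label is unknown).  Identical (pattern, prior) pairs
    are computed once.
    """
    if isinstance(calibs, CalibrationResult):
        calibs = {calibs.domain: calibs}
    grid = grid or _default_grid()
    out = pd.DataFrame(index=matrix.respondent_ids)
    for dom, calib in calibs.items():
        item_ids = calib.item_order
        codes = matrix.codes(item_ids)
        # apply the calibration's category recodes (collapsed categories)
        for j, item_id in enumerate(item_ids):
            mapping = calib.category_maps.get(item_id)
            if mapping:
                col = codes[:, j]
                recoded = col.copy()
                for old, new in mapping.items():
                    recoded[col == old] = new
                codes[:, j] = recoded
        if np.isnan(codes).all(axis=1).any():
            raise ValueError(
                f"domain {dom!r}: some respondents are missing every item"
            )
        items = calib.item_list
        multigroup = len(calib.groups) > 1
        if multigroup and matrix.group is not None:
            labels = matrix.group.astype("string")
            known = {g.label for g in calib.groups}
            prior_key = labels.where(labels.isin(known)).to_numpy("object")
        else:
            prior_key = np.array([None] * len(codes), dtype=object)

        key = np.column_stack(
            [np.where(np.isnan(codes), 0, codes).astype(np.int64),
             pd.factorize(prior_key, use_na_sentinel=False)[0][:, None]]
        )
        uniq, inv = np.unique(key, axis=0, return_inverse=True)
        theta = np.empty(len(uniq))
        psd = np.empty(len(uniq))
        first_row = np.full(len(uniq), -1, dtype=int)
        first_row[inv[::-1]] = np.arange(len(codes))[::-1]
        for u in range(len(uniq)):
            row = first_row[u]
            resp = [None if np.isnan(v) else int(v) for v in codes[row]]
            prior = calib.group_for(prior_key[row]) if multigroup else None
            score = eap_pattern(items, resp, prior=prior, grid=grid)
            theta[u] = score.theta_hat
            psd[u] = score.posterior_sd
        out[f"{dom}_theta"] = theta[inv]
        out[f"{dom}_theta_2dp"] = np.round(theta[inv], 2)
        out[f"{dom}_psd"] = psd[inv]
    return out


def summed_score_table(
    items: Sequence[GrmItemParams],
    prior: LatentGroupParams | None = None,
    grid: QuadratureGrid | None = None,
) -> pd.DataFrame:
    """Summed score -> EAP conversion table via the Lord-Wingersky recursion.

    Rows run over raw-code sums s = n_items .. sum(K_j); columns are the
    marginal probability P(s), the EAP of the trait given s, and the
    posterior SD given s.  P(s) sums to 1 and (for positive slopes) the
    EAP column is nondecreasing in s.
    """
    items = list(items)
    if not items:
        raise ValueError("summed_score_table needs at least one item")
    grid = grid or _default_grid()
    if prior is not None and (prior.mu != 0.0 or prior.sigma != 1.0):
        grid = grid.reweight(prior.mu, prior.sigma)
    nodes, w = grid.nodes, grid.weights
    q = nodes.size

    # Lord-Wingersky: distribution of the 0-based sum, item by item
    f = np.ones((q, 1))
    for item in items:
        pk = category_probs(item, nodes)  # (Q, K)
        k = item.n_categories
        new = np.zeros((q, f.shape[1] + k - 1))
        for kk in range(k):
            new[:, kk : kk + f.shape[1]] += f * pk[:, [kk]]
        f = new

    p_s = w @ f  # marginal P(s) over quadrature
    num_mean = (w * nodes) @ f
    num_sq = (w * nodes**2) @ f
    eap = num_mean / p_s
    var = num_sq / p_s - eap**2
    s_values = np.arange(f.shape[1]) + len(items)  # raw-code sums
    return pd.DataFrame(
        {
            "summed_score": s_values,
            "probability": p_s,
            "eap": eap,
            "posterior_sd": np.sqrt(np.maximum(var, 0.0)),
        }
    )


def rescale_0_100(theta, cfg: RescaleConfig | None = None):
    """Linear transform of trait-SD scores onto the 0-100 reporting scale."""
    cfg = cfg or RescaleConfig()
    arr = np.asarray(theta, dtype=float)
    scaled = 100.0 * (arr - cfg.theta_low) / (cfg.theta_high - cfg.theta_low)
    if cfg.clip:
        scaled = np.clip(scaled, 0.0, 100.0)
    return float(scaled) if np.isscalar(theta) else scaled
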