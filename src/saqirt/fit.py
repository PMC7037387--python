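"""Limited-information goodness of fit and construct-validity summaries.

Full-information chi-square tests are useless for a 30-item ordinal
instrument: the response-pattern contingency table is far too sparse.
The M2 family instead compares observed and model-implied univariate and
bivariate category margins.  Here the full (uncollapsed) M2 is built on
all ``n(K-1)`` univariate and ``C(n,2)(K-1)^2`` bivariate indicator
margins: with ``e`` the residual margin vector, ``Xi`` its asymptotic
covariance and ``Delta`` the Jacobian of the implied margins in the free
parameters,

    M2 = n * e' [Xi^-1 - Xi^-1 Delta (Delta' Xi^-1 Delta)^-1 Delta' Xi^-1] e,

asymptotically chi-square with df = s - q for ML parameter estimates.
The statistic is evaluated in orthogonal-complement form (whitening by
the covariance eigendecomposition, then projecting out the Jacobian
column space), which keeps it nonnegative by construction.

RMSEA and NNFI are derived from M2 in the usual way; the NNFI baseline
is the independence model (all slopes zero, intercepts free).  Latent
inter-domain correlations are approximated by Pearson correlations of
EAP scores with an attenuation correction based on marginal reliability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import chi2

from .calibrate import CalibrationResult
from .grm import category_probs, slope_to_loading
from .instrument import ResponseMatrix

__all__ = [
    "FitReport",
    "m2_statistic",
    "independence_baseline",
    "rmsea_nnfi",
    "marginal_reliability",
    "domain_correlations",
    "fit_report",
]


@dataclass
class FitReport:
    """Fit indices, loadings and (optionally) inter-domain correlations."""

    m2: float
    df: int
    p_value: float
    rmsea: float
    nnfi: float
    loadings: dict[str, float]
    n: int
    baseline_m2: float
    baseline_df: int
    domain_corr: pd.DataFrame | None = None
    domain_corr_disattenuated: pd.DataFrame | None = None
    reliabilities: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {
            "m2": self.m2,
            "df": self.df,
            "p_value": self.p_value,
            "rmsea": self.rmsea,
            "nnfi": self.nnfi,
            "n": self.n,
            "baseline_m2": self.baseline_m2,
            "baseline_df": self.baseline_df,
            "loadings": self.loadings,
            "reliabilities": self.reliabilities,
        }
        if self.domain_corr is not None:
            out["domain_corr"] = self.domain_corr.round(10).to_dict()
        if self.domain_corr_disattenuated is not None:
            out["domain_corr_disattenuated"] = (
                self.domain_corr_disattenuated.round(10).to_dict()
            )
        return out


# ---------------------------------------------------------------------------
# margin bookkeeping

class _Margins:
    """Index arrays for univariate and bivariate indicator margins.

    Margins use categories 1..K-1 of each item (the K-th is redundant):
    s = sum(K_j - 1) univariate entries plus, for every item pair,
    (K_i - 1)(K_j - 1) bivariate entries.
    """

    def __init__(self, k_list: Sequence[int]):
        self.k_list = list(k_list)
        n_items = len(self.k_list)
        uni_item, uni_cat = [], []
        for j, k in enumerate(self.k_list):
            for cat in range(k - 1):
                uni_item.append(j)
                uni_cat.append(cat)
        bi_i, bi_j, bi_ci, bi_cj = [], [], [], []
        for i in range(n_items):
            for j in range(i + 1, n_items):
                for ci in range(self.k_list[i] - 1):
                    for cj in range(self.k_list[j] - 1):
                        bi_i.append(i)
                        bi_j.append(j)
                        bi_ci.append(ci)
                        bi_cj.append(cj)
        self.uni_item = np.array(uni_item)
        self.uni_cat = np.array(uni_cat)
        self.bi_i = np.array(bi_i)
        self.bi_j = np.array(bi_j)
        self.bi_ci = np.array(bi_ci)
        self.bi_cj = np.array(bi_cj)
        self.s = self.uni_item.size + self.bi_i.size

        # node-independent masks for the second-moment blocks
        ui, uc = self.uni_item, self.uni_cat
        self._uu_same = ui[:, None] == ui[None, :]
        self._ub_i = ui[:, None] == self.bi_i[None, :]
        self._ub_i_cat = self._ub_i & (uc[:, None] == self.bi_ci[None, :])
        self._ub_j = ui[:, None] == self.bi_j[None, :]
        self._ub_j_cat = self._ub_j & (uc[:, None] == self.bi_cj[None, :])
        rel = []
        for a_item, a_cat, b_item, b_cat in (
            (self.bi_i, self.bi_ci, self.bi_i, self.bi_ci),
            (self.bi_i, self.bi_ci, self.bi_j, self.bi_cj),
            (self.bi_j, self.bi_cj, self.bi_i, self.bi_ci),
            (self.bi_j, self.bi_cj, self.bi_j, self.bi_cj),
        ):
            share = a_item[:, None] == b_item[None, :]
            match = share & (a_cat[:, None] == b_cat[None, :])
            rel.append((share, match, a_item, a_cat))
        self._bb_relations = rel

    def observed(self, x: np.ndarray) -> np.ndarray:
        """Sample margin proportions from 1-based codes (n, J)."""
        n = x.shape[0]
        u = np.array(
            [np.mean(x[:, j] == cat + 1) for j, cat in zip(self.uni_item, self.uni_cat)]
        )
        ind = {}  # (item, cat) -> indicator vector
        for j, cat in zip(self.uni_item, self.uni_cat):
            ind[(j, cat)] = x[:, j] == cat + 1
        b = np.array(
            [
                np.mean(ind[(i, ci)] & ind[(j, cj)])
                for i, j, ci, cj in zip(self.bi_i, self.bi_j, self.bi_ci, self.bi_cj)
            ]
        )
        return np.concatenate([u, b])

    def mean_vector(self, p_tables: np.ndarray, w: np.ndarray) -> np.ndarray:
        """Implied margins: ``p_tables`` is (Q, J, K_max), ``w`` prior masses."""
        u_nodes = p_tables[:, self.uni_item, self.uni_cat]  # (Q, su)
        b_nodes = (
            p_tables[:, self.bi_i, self.bi_ci] * p_tables[:, self.bi_j, self.bi_cj]
        )
        return np.concatenate([w @ u_nodes, w @ b_nodes])

    def covariance(self, p_tables: np.ndarray, w: np.ndarray) -> np.ndarray:
        """Asymptotic covariance of the sample margins under the model."""
        pi = self.mean_vector(p_tables, w)
        su, sb = self.uni_item.size, self.bi_i.size
        second = np.zeros((self.s, self.s))
        for q in range(p_tables.shape[0]):
            P = p_tables[q]
            u = P[self.uni_item, self.uni_cat]
            b = P[self.bi_i, self.bi_ci] * P[self.bi_j, self.bi_cj]

            uu = np.where(self._uu_same, 0.0, u[:, None] * u[None, :])
            np.fill_diagonal(uu, u)

            ub = np.where(
                self._ub_i | self._ub_j, 0.0, u[:, None] * b[None, :]
            )
            ub = np.where(
                self._ub_i_cat | self._ub_j_cat, np.broadcast_to(b, ub.shape), ub
            )

            bb = b[:, None] * b[None, :]
            for share, match, a_item, a_cat in self._bb_relations:
                div = P[a_item, a_cat][:, None]
                bb = np.where(match, bb / div, np.where(share, 0.0, bb))

            block = np.empty((self.s, self.s))
            block[:su, :su] = uu
            block[:su, su:] = ub
            block[su:, :su] = ub.T
            block[su:, su:] = bb
            second += w[q] * block
        return second - np.outer(pi, pi)


def _safe_step(item, kind: str, m: int | None) -> float:
    """Central-difference step that keeps the perturbed item valid.

    Slopes stay positive; intercept steps stay below half the gap to the
    neighboring intercepts so the strict ordering survives.
    """
    if kind == "a":
        return min(1e-5 * max(1.0, abs(item.a)), item.a / 2)
    h = 1e-5 * max(1.0, abs(item.c[m]))
    if m > 0:
        h = min(h, (item.c[m - 1] - item.c[m]) / 2)
    if m < len(item.c) - 1:
        h = min(h, (item.c[m] - item.c[m + 1]) / 2)
    return max(h, 1e-12)


def _grm_prob_tables(
    items: Sequence, nodes: np.ndarray, k_max: int
) -> np.ndarray:
    p = np.zeros((nodes.size, len(items), k_max))
    for j, item in enumerate(items):
        p[:, j, : item.n_categories] = category_probs(item, nodes)
    return p


def _quadratic_form(
    e: np.ndarray, sigma: np.ndarray, delta: np.ndarray, n: int
) -> float:
    """n * e' C e with C the orthogonal-complement weight; >= 0 by construction."""
    vals, vecs = np.linalg.eigh(sigma)
    keep = vals > max(vals.max(), 1.0) * 1e-12
    if not keep.any():
        raise ValueError("singular margin covariance matrix")
    white = vecs[:, keep] / np.sqrt(vals[keep])  # (s, s_k)
    e_t = white.T @ e
    g = white.T @ delta
    qmat, _ = np.linalg.qr(g)
    proj = qmat.T @ e_t
    return float(n * (e_t @ e_t - proj @ proj))


def m2_statistic(
    calib: CalibrationResult,
    matrix: ResponseMatrix,
) -> tuple[float, int, float]:
    """Limited-information M2 statistic, degrees of freedom and p-value.

    Residuals between observed and model-implied univariate + bivariate
    category margins, weighted by the orthogonal-complement construction;
    ``df = s - q`` with ``q`` the number of free item parameters.
    Requires a converged single-group calibration.
    """
    if len(calib.groups) > 1:
        raise ValueError("M2 is implemented for single-group calibrations")
    items = calib.item_list
    codes = matrix.codes(calib.item_order)
    if np.isnan(codes).any():
        raise ValueError("matrix has missing codes; filter first")
    x = codes.astype(np.int64)
    for j, item_id in enumerate(calib.item_order):
        mapping = calib.category_maps.get(item_id)
        if mapping:
            lut = np.zeros(max(mapping) + 1, dtype=np.int64)
            for old, new in mapping.items():
                lut[old] = new
            x[:, j] = lut[x[:, j]]
    n = x.shape[0]
    k_list = [it.n_categories for it in items]
    k_max = max(k_list)
    margins = _Margins(k_list)

    grid = calib.em.grid()
    nodes, w = grid.nodes, grid.weights

    p_obs = margins.observed(x)
    p_tab = _grm_prob_tables(items, nodes, k_max)
    pi = margins.mean_vector(p_tab, w)
    sigma = margins.covariance(p_tab, w)

    # Jacobian of implied margins w.r.t. (a_j, c_j1..c_j,K-1), central differences
    q_free = sum(k_list)
    if n < margins.s:
        raise ValueError(f"need n >= {margins.s} margins, got n = {n}")
    df = margins.s - q_free
    if df <= 0:
        raise ValueError("model saturated in the low-order margins (df <= 0)")
    delta = np.empty((margins.s, q_free))
    col = 0
    for j, item in enumerate(items):
        params = [("a", None)] + [("c", m) for m in range(len(item.c))]
        for kind, m in params:
            h = _safe_step(item, kind, m)
            cols = []
            for signed in (+h, -h):
                if kind == "a":
                    pert = type(item)(item.item_id, item.a + signed, item.c)
                else:
                    c = list(item.c)
                    c[m] += signed
                    pert = type(item)(item.item_id, item.a, tuple(c))
                p_j = np.zeros_like(p_tab)
                p_j[:] = p_tab
                p_j[:, j, : item.n_categories] = category_probs(pert, nodes)
                cols.append(margins.mean_vector(p_j, w))
            delta[:, col] = (cols[0] - cols[1]) / (2 * h)
            col += 1

    m2 = _quadratic_form(p_obs - pi, sigma, delta, n)
    return m2, df, float(chi2.sf(m2, df))


def independence_baseline(
    calib: CalibrationResult,
    matrix: ResponseMatrix,
) -> tuple[float, int]:
    """M2 of the independence model (slopes 0, intercepts from the margins).

    Serves as the NNFI baseline: items are mutually independent
    multinomials whose category probabilities equal the observed
    univariate margins, so only the bivariate residuals contribute.
    """
    items = calib.item_list
    codes = matrix.codes(calib.item_order)
    x = codes.astype(np.int64)
    for j, item_id in enumerate(calib.item_order):
        mapping = calib.category_maps.get(item_id)
        if mapping:
            lut = np.zeros(max(mapping) + 1, dtype=np.int64)
            for old, new in mapping.items():
                lut[old] = new
            x[:, j] = lut[x[:, j]]
    n = x.shape[0]
    k_list = [it.n_categories for it in items]
    k_max = max(k_list)
    margins = _Margins(k_list)
    p_obs = margins.observed(x)

    # ML intercepts under independence: category probs = observed margins
    def tables_from_intercepts(c_all: list[np.ndarray]) -> np.ndarray:
        p = np.zeros((1, len(items), k_max))
        for j, c in enumerate(c_all):
            cum = np.concatenate([[1.0], expit(c), [0.0]])
            p[0, j, : k_list[j]] = np.maximum(-np.diff(cum), 1e-12)
        return p

    c_hat: list[np.ndarray] = []
    for j, k in enumerate(k_list):
        cum_prop = np.array([(x[:, j] >= kk + 1).mean() for kk in range(1, k)])
        c_hat.append(logit(np.clip(cum_prop, 1e-9, 1 - 1e-9)))

    w1 = np.ones(1)
    p_tab = tables_from_intercepts(c_hat)
    pi = margins.mean_vector(p_tab, w1)
    sigma = margins.covariance(p_tab, w1)

    q_free = sum(k - 1 for k in k_list)
    df_b = margins.s - q_free
    delta = np.empty((margins.s, q_free))
    col = 0
    for j, k in enumerate(k_list):
        for m in range(k - 1):
            h = 1e-5 * max(1.0, abs(c_hat[j][m]))
            cols = []
            for signed in (+h, -h):
                c_pert = [c.copy() for c in c_hat]
                c_pert[j][m] += signed
                cols.append(margins.mean_vector(tables_from_intercepts(c_pert), w1))
            delta[:, col] = (cols[0] - cols[1]) / (2 * h)
            col += 1

    m2_b = _quadratic_form(p_obs - pi, sigma, delta, n)
    return m2_b, df_b


def rmsea_nnfi(
    m2: float, df: int, n: int, baseline: tuple[float, int]
) -> tuple[float, float]:
    """RMSEA and NNFI (Tucker-Lewis) from the M2 statistics.

    ``RMSEA = sqrt(max(0, (M2 - df) / (df * n)))``;
    ``NNFI = ((M2_b/df_b) - (M2/df)) / ((M2_b/df_b) - 1)`` with the
    independence model as baseline.
    """
    if df <= 0:
        raise ValueError("df must be positive")
    m2_b, df_b = baseline
    if df_b <= 0:
        raise ValueError("baseline df must be positive")
    rmsea = float(np.sqrt(max(0.0, (m2 - df) / (df * n))))
    ratio_b = m2_b / df_b
    nnfi = float((ratio_b - m2 / df) / (ratio_b - 1.0))
    return rmsea, nnfi


def marginal_reliability(posterior_sd, prior_var: float = 1.0) -> float:
    """Marginal EAP reliability: 1 - mean posterior variance / prior variance."""
    psd = np.asarray(posterior_sd, dtype=float)
    return float(1.0 - np.mean(psd**2) / prior_var)


def domain_correlations(
    theta: pd.DataFrame,
    reliabilities: Mapping[str, float] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Pearson correlations of per-domain EAP scores, optionally disattenuated.

    EAP scores are shrunken toward the prior mean, so their raw
    correlations understate the latent correlations; dividing by
    ``sqrt(rel_i * rel_j)`` (capped at 1 in absolute value) corrects for
    that attenuation.
    """
    if theta.shape[1] < 2:
        raise ValueError("need at least two domains")
    stds = theta.std(ddof=0)
    zero = stds[stds == 0]
    if len(zero):
        raise ValueError(f"zero-variance score vector(s): {list(zero.index)}")
    raw = theta.corr()
    if reliabilities is None:
        return raw, None
    rel = np.array([reliabilities[d] for d in theta.columns])
    denom = np.sqrt(np.outer(rel, rel))
    dis = raw.to_numpy() / denom
    dis = np.clip(dis, -1.0, 1.0)
    np.fill_diagonal(dis, 1.0)
    return raw, pd.DataFrame(dis, index=theta.columns, columns=theta.columns)


def fit_report(
    calib: CalibrationResult,
    matrix: ResponseMatrix,
    theta: pd.DataFrame | None = None,
    reliabilities: Mapping[str, float] | None = None,
) -> FitReport:
    """Assemble M2/RMSEA/NNFI, loadings and correlations into one report."""
    m2, df, p = m2_statistic(calib, matrix)
    baseline = independence_baseline(calib, matrix)
    rmsea, nnfi = rmsea_nnfi(m2, df, matrix.n_respondents, baseline)
    loadings = {i: slope_to_loading(calib.items[i].a) for i in calib.item_order}
    corr = dis = None
    if theta is not None:
        corr, dis = domain_correlations(theta, reliabilities)
    return FitReport(
        m2=m2,
        df=df,
        p_value=p,
        rmsea=rmsea,
        nnfi=nnfi,
        loadings=loadings,
        n=matrix.n_respondents,
        baseline_m2=baseline[0],
        baseline_df=baseline[1],
        domain_corr=corr,
        domain_corr_disattenuated=dis,
        reliabilities=dict(reliabilities or {}),
    )
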