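"""Marginal maximum-likelihood item calibration via Bock-Aitkin EM.

Item parameters are estimated per domain under a unidimensional graded
response model: the latent trait is integrated out over a fixed
quadrature grid with a normal prior, the E-step computes each response
pattern's posterior over the grid, and the M-step maximizes the expected
complete-data multinomial log-likelihood item by item.  Intercept
ordering and slope positivity are enforced by reparameterizing each item
as ``(log a, c_1, log(c_k - c_{k+1}))``, so every M-step iterate is a
valid GRM item.

An optional multigroup extension shares the item parameters across
groups (e.g. hospital levels) while giving each non-reference group its
own latent mean and SD, estimated in the same EM; the reference group is
fixed at N(0, 1) for identification.  Every accepted M-step weakly
increases the expected complete-data log-likelihood, so the marginal
log-likelihood trace is nondecreasing (a generalized EM).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logit, logsumexp
from scipy.stats import norm

from .grm import GrmItemParams, category_probs
from .instrument import InstrumentSpec, ResponseMatrix

__all__ = [
    "QuadratureGrid",
    "LatentGroupParams",
    "EmConfig",
    "CalibrationResult",
    "calibrate_domain",
    "standard_errors",
]


@dataclass(frozen=True)
class QuadratureGrid:
    """Fixed trait grid with prior masses (weights sum to 1)."""

    nodes: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        nodes = np.asarray(self.nodes, dtype=float)
        weights = np.asarray(self.weights, dtype=float)
        if nodes.ndim != 1 or nodes.shape != weights.shape:
            raise ValueError("nodes and weights must be 1-D arrays of equal length")
        if np.any(np.diff(nodes) <= 0):
            raise ValueError("nodes must be strictly increasing")
        if np.any(weights < 0) or not np.isclose(weights.sum(), 1.0, atol=1e-10):
            raise ValueError("weights must be nonnegative and sum to 1")
        object.__setattr__(self, "nodes", nodes)
        object.__setattr__(self, "weights", weights)

    @classmethod
    def equally_spaced(
        cls,
        n: int = 49,
        lo: float = -6.0,
        hi: float = 6.0,
        mu: float = 0.0,
        sigma: float = 1.0,
    ) -> "QuadratureGrid":
        """Rectangular grid on [lo, hi] with renormalized N(mu, sigma) masses."""
        if n < 5:
            raise ValueError(f"need at least 5 quadrature points, got {n}")
        nodes = np.linspace(lo, hi, n)
        dens = norm.pdf(nodes, loc=mu, scale=sigma)
        return cls(nodes=nodes, weights=dens / dens.sum())

    def reweight(self, mu: float, sigma: float) -> "QuadratureGrid":
        """Same nodes, masses from a renormalized N(mu, sigma) prior."""
        dens = norm.pdf(self.nodes, loc=mu, scale=sigma)
        return QuadratureGrid(nodes=self.nodes, weights=dens / dens.sum())

    @property
    def log_weights(self) -> np.ndarray:
        return np.log(np.maximum(self.weights, 1e-300))


@dataclass
class LatentGroupParams:
    """Latent trait distribution of one group: N(mu, sigma^2) in trait-SD units."""

    label: str
    mu: float = 0.0
    sigma: float = 1.0
    is_reference: bool = False

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError(f"group {self.label!r}: sigma must be positive")


@dataclass(frozen=True)
class EmConfig:
    """EM control knobs: quadrature size/range, stopping rule, start jitter."""

    n_quadrature: int = 49
    quad_range: tuple[float, float] = (-6.0, 6.0)
    max_cycles: int = 500
    tol: float = 1e-4
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_quadrature < 5:
            raise ValueError("n_quadrature must be >= 5")
        if self.tol <= 0:
            raise ValueError("tolerance must be positive")

    def grid(self) -> QuadratureGrid:
        lo, hi = self.quad_range
        return QuadratureGrid.equally_spaced(self.n_quadrature, lo, hi)


@dataclass
class CalibrationResult:
    """Fitted item and group parameters plus the EM audit trail."""

    items: dict[str, GrmItemParams]
    groups: list[LatentGroupParams]
    loglik_trace: list[float]
    converged: bool
    n_cycles: int
    domain: str
    item_order: tuple[str, ...]
    category_maps: dict[str, dict[int, int]] = field(default_factory=dict)
    em: EmConfig = field(default_factory=EmConfig)
    standard_errors: dict[str, float | None] | None = None

    @property
    def item_list(self) -> list[GrmItemParams]:
        return [self.items[i] for i in self.item_order]

    @property
    def loglik(self) -> float:
        return self.loglik_trace[-1]

    def group_for(self, label: str | None) -> LatentGroupParams:
        """Group params by label; the reference group when label is unknown/None."""
        for g in self.groups:
            if g.label == label:
                return g
        return next(g for g in self.groups if g.is_reference)

    def n_free_parameters(self) -> int:
        n_item = sum(it.n_categories for it in self.items.values())  # a + (K-1) intercepts
        n_group = 2 * sum(not g.is_reference for g in self.groups)
        return n_item + n_group


# ---------------------------------------------------------------------------
# parameter transforms: item <-> unconstrained vector

def _item_to_u(a: float, c: np.ndarray) -> np.ndarray:
    gaps = -np.diff(c)
    return np.concatenate([[np.log(a), c[0]], np.log(np.maximum(gaps, 1e-8))])


def _u_to_item(u: np.ndarray) -> tuple[float, np.ndarray]:
    a = float(np.exp(u[0]))
    c1 = u[1]
    gaps = np.exp(u[2:])
    c = c1 - np.concatenate([[0.0], np.cumsum(gaps)])
    return a, c


def _item_negll_grad(u: np.ndarray, nodes: np.ndarray, r: np.ndarray):
    """Expected negative complete-data log-likelihood of one item + gradient.

    ``r`` is the (Q, K) table of expected response counts per node/category.
    """
    a, c = _u_to_item(u)
    km1 = c.size
    z = a * nodes[:, None] + c[None, :]  # (Q, K-1) boundary logits
    cum = expit(z)
    p = -np.diff(
        np.concatenate(
            [np.ones((nodes.size, 1)), cum, np.zeros((nodes.size, 1))], axis=1
        ),
        axis=1,
    )  # upper - lower
    p = np.maximum(p, 1e-300)
    f = -np.sum(r * np.log(p))

    ratio = r / p  # (Q, K)
    s = cum * (1.0 - cum)  # d expit / d logit
    # boundary m sits between categories m and m+1 (0-based: p[:, m] and p[:, m+1])
    t = s * (ratio[:, 1:] - ratio[:, :-1])  # (Q, K-1)
    g_c = -t.sum(axis=0)
    g_a = -float(nodes @ t.sum(axis=1))
    # chain rule to (log a, c1, log gaps)
    grad = np.empty_like(u)
    grad[0] = g_a * a
    grad[1] = g_c.sum()
    for m in range(1, km1):
        grad[1 + m] = -g_c[m:].sum() * np.exp(u[1 + m])
    return f, grad


def _group_negll(params: np.ndarray, nodes: np.ndarray, r_q: np.ndarray) -> float:
    """Negative expected log prior mass for one group's (mu, log sigma)."""
    mu, log_sigma = params
    sigma = np.exp(log_sigma)
    logd = norm.logpdf(nodes, loc=mu, scale=sigma)
    logw = logd - logsumexp(logd)
    return float(-(r_q @ logw))


# ---------------------------------------------------------------------------

def _collapse_categories(x: np.ndarray, k: int, item_id: str):
    """Recode away categories never observed; return (codes, K', old->new map)."""
    observed = np.zeros(k, dtype=bool)
    observed[np.unique(x) - 1] = True
    if observed.all():
        return x, k, None
    new_codes = np.cumsum(observed)  # old category -> new 1-based code
    k_new = int(observed.sum())
    if k_new < 2:
        raise ValueError(f"item {item_id!r}: fewer than 2 observed categories")
    warnings.warn(
        f"item {item_id!r}: {k - k_new} unobserved categor(ies) collapsed into "
        "the adjacent category",
        stacklevel=3,
    )
    mapping = {old + 1: int(new_codes[old]) for old in range(k) if observed[old]}
    return new_codes[x - 1], k_new, mapping


def _start_values(x: np.ndarray, k: int, rng: np.random.Generator | None):
    """a=1, intercepts from inverse-logistic cumulative category frequencies."""
    n = x.size
    cum_prop = np.array([(x >= kk + 1).sum() / n for kk in range(1, k)])
    cum_prop = np.clip(cum_prop, 1e-3, 1 - 1e-3)
    c = logit(cum_prop)
    # enforce strict decrease
    for m in range(1, c.size):
        c[m] = min(c[m], c[m - 1] - 1e-2)
    a = 1.0
    if rng is not None:
        a *= float(np.exp(rng.normal(0.0, 0.1)))
        c = c + rng.normal(0.0, 0.1)
        c = np.sort(c)[::-1]
        for m in range(1, c.size):
            c[m] = min(c[m], c[m - 1] - 1e-2)
    return a, c


def calibrate_domain(
    matrix: ResponseMatrix,
    domain: str,
    spec: InstrumentSpec,
    em: EmConfig | None = None,
    groups: bool | Sequence[str] | None = None,
) -> CalibrationResult:
    """Calibrate one domain's GRM items by Bock-Aitkin EM (MML).

    ``groups`` selects the multigroup model: None/False fits a single
    N(0, 1) population; True uses the matrix's group labels (optionally a
    sequence restricts to a label subset).  The largest group is the
    reference, fixed at N(0, 1).  Responses must be complete for the
    domain's items -- run :func:`saqirt.instrument.filter_complete` first.
    """
    em = em or EmConfig()
    item_ids = spec.items_for(domain)
    codes = matrix.codes(item_ids)
    if np.isnan(codes).any():
        raise ValueError(
            f"domain {domain!r} has missing item codes; run filter_complete first"
        )
    x_all = codes.astype(np.int64)  # (n, J), 1-based
    n, n_items = x_all.shape

    # category collapsing for unobserved categories
    category_maps: dict[str, dict[int, int]] = {}
    k_list: list[int] = []
    for j, item_id in enumerate(item_ids):
        xj, kj, mapping = _collapse_categories(
            x_all[:, j], spec.n_categories[item_id], item_id
        )
        x_all[:, j] = xj
        k_list.append(kj)
        if mapping is not None:
            category_maps[item_id] = mapping

    # group assignment
    if groups:
        if matrix.group is None:
            raise ValueError("multigroup calibration requested but matrix has no groups")
        labels = matrix.group.astype("string")
        if labels.isna().any():
            raise ValueError("group labels contain missing values; filter first")
        if not isinstance(groups, bool):
            allowed = set(map(str, groups))
            bad = set(labels.unique()) - allowed
            if bad:
                raise ValueError(f"unexpected group labels {sorted(bad)}")
        counts = labels.value_counts()
        # deterministic: reference = most frequent, ties broken by label order
        ref_label = counts.sort_index().idxmax()
        ordered = [ref_label] + sorted(l for l in counts.index if l != ref_label)
        group_idx = labels.map({l: i for i, l in enumerate(ordered)}).to_numpy(int)
        group_params = [
            LatentGroupParams(label=str(l), mu=0.0, sigma=1.0, is_reference=(i == 0))
            for i, l in enumerate(ordered)
        ]
    else:
        group_idx = np.zeros(n, dtype=int)
        group_params = [LatentGroupParams(label="all", is_reference=True)]
    n_groups = len(group_params)

    # collapse to unique (pattern, group) rows
    stacked = np.column_stack([x_all, group_idx])
    uniq, inv, counts_p = np.unique(
        stacked, axis=0, return_inverse=True, return_counts=True
    )
    xp = uniq[:, :n_items]
    gp = uniq[:, n_items]
    n_p = counts_p.astype(float)

    grid = em.grid()
    nodes = grid.nodes
    rng = np.random.default_rng(em.seed) if em.seed is not None else None

    a_cur: list[float] = []
    c_cur: list[np.ndarray] = []
    for j in range(n_items):
        a0, c0 = _start_values(x_all[:, j], k_list[j], rng)
        a_cur.append(a0)
        c_cur.append(c0)
    mus = np.zeros(n_groups)
    sigmas = np.ones(n_groups)

    def log_prior_weights() -> np.ndarray:
        lw = np.empty((n_groups, nodes.size))
        for g in range(n_groups):
            logd = norm.logpdf(nodes, loc=mus[g], scale=sigmas[g])
            lw[g] = logd - logsumexp(logd)
        return lw

    def pattern_logliks() -> np.ndarray:
        L = np.zeros((xp.shape[0], nodes.size))
        for j in range(n_items):
            item = GrmItemParams(item_ids[j], a_cur[j], tuple(c_cur[j]))
            logp = np.log(category_probs(item, nodes))  # (Q, K)
            L += logp[:, xp[:, j] - 1].T
        return L

    loglik_trace: list[float] = []
    converged = False
    cycle = 0
    for cycle in range(1, em.max_cycles + 1):
        # E-step
        L = pattern_logliks()
        logw = log_prior_weights()
        joint = L + logw[gp]
        lse = logsumexp(joint, axis=1)
        loglik_trace.append(float(n_p @ lse))
        post = np.exp(joint - lse[:, None])
        weighted = post * n_p[:, None]  # (P, Q)

        delta = 0.0
        # M-step: items
        for j in range(n_items):
            kj = k_list[j]
            onehot = np.eye(kj)[xp[:, j] - 1]  # (P, K)
            r = weighted.T @ onehot  # (Q, K) expected counts
            u0 = _item_to_u(a_cur[j], c_cur[j])
            f0, _ = _item_negll_grad(u0, nodes, r)
            res = minimize(
                _item_negll_grad, u0, args=(nodes, r), jac=True, method="L-BFGS-B"
            )
            if np.isfinite(res.fun) and res.fun <= f0:
                a_new, c_new = _u_to_item(res.x)
                delta = max(
                    delta,
                    abs(a_new - a_cur[j]),
                    float(np.max(np.abs(c_new - c_cur[j]))),
                )
                a_cur[j], c_cur[j] = a_new, c_new

        # M-step: non-reference group latent means/SDs
        for g in range(1, n_groups):
            r_q = weighted[gp == g].sum(axis=0)
            if r_q.sum() <= 0:
                continue
            # moment estimates as a candidate start alongside the current point
            m1 = float(r_q @ nodes / r_q.sum())
            v = float(r_q @ (nodes - m1) ** 2 / r_q.sum())
            starts = [
                np.array([mus[g], np.log(sigmas[g])]),
                np.array([m1, 0.5 * np.log(max(v, 1e-4))]),
            ]
            f_best = _group_negll(starts[0], nodes, r_q)
            best = starts[0]
            for s0 in starts:
                res = minimize(_group_negll, s0, args=(nodes, r_q), method="Nelder-Mead")
                if np.isfinite(res.fun) and res.fun < f_best:
                    f_best, best = res.fun, res.x
            mu_new, sigma_new = float(best[0]), float(np.exp(best[1]))
            delta = max(delta, abs(mu_new - mus[g]), abs(sigma_new - sigmas[g]))
            mus[g], sigmas[g] = mu_new, sigma_new

        if delta < em.tol:
            converged = True
            break

    # final marginal log-likelihood at the accepted parameters
    L = pattern_logliks()
    logw = log_prior_weights()
    loglik_trace.append(float(n_p @ logsumexp(L + logw[gp], axis=1)))

    if not converged:
        warnings.warn(
            f"domain {domain!r}: EM did not converge in {em.max_cycles} cycles",
            stacklevel=2,
        )

    for g, gpars in enumerate(group_params):
        gpars.mu = float(mus[g])
        gpars.sigma = float(sigmas[g])
    items = {
        item_ids[j]: GrmItemParams(item_ids[j], a_cur[j], tuple(c_cur[j]))
        for j in range(n_items)
    }
    return CalibrationResult(
        items=items,
        groups=group_params,
        loglik_trace=loglik_trace,
        converged=converged,
        n_cycles=cycle,
        domain=domain,
        item_order=tuple(item_ids),
        category_maps=category_maps,
        em=em,
    )


# ---------------------------------------------------------------------------

def _parameter_vector(result: CalibrationResult):
    names: list[str] = []
    values: list[float] = []
    for item_id in result.item_order:
        it = result.items[item_id]
        names.append(f"a[{item_id}]")
        values.append(it.a)
        for m, ck in enumerate(it.c, start=1):
            names.append(f"c{m}[{item_id}]")
            values.append(ck)
    for g in result.groups:
        if not g.is_reference:
            names.append(f"mu[{g.label}]")
            values.append(g.mu)
            names.append(f"sigma[{g.label}]")
            values.append(g.sigma)
    return names, np.array(values)


def standard_errors(
    result: CalibrationResult,
    matrix: ResponseMatrix,
    spec: InstrumentSpec,
) -> dict[str, float | None]:
    """Per-parameter SEs from the empirical cross-product of score vectors.

    The score of each respondent's marginal log-likelihood is taken by
    central finite differences in every free parameter; the information
    matrix is the sum of outer products (BHHH).  Parameters whose variance
    is unavailable (singular information) report None.
    """
    if not result.converged:
        raise ValueError("standard errors require a converged calibration")
    item_ids = result.item_order
    codes = matrix.codes(item_ids)
    if np.isnan(codes).any():
        raise ValueError("matrix has missing codes for the calibrated domain")
    x_all = codes.astype(np.int64)
    for j, item_id in enumerate(item_ids):
        mapping = result.category_maps.get(item_id)
        if mapping:
            lut = np.zeros(max(mapping) + 1, dtype=np.int64)
            for old, new in mapping.items():
                lut[old] = new
            x_all[:, j] = lut[x_all[:, j]]

    multi = len(result.groups) > 1
    if multi:
        label_to_idx = {g.label: i for i, g in enumerate(result.groups)}
        group_idx = matrix.group.astype("string").map(label_to_idx).to_numpy(int)
    else:
        group_idx = np.zeros(len(x_all), dtype=int)

    stacked = np.column_stack([x_all, group_idx])
    uniq, counts_p = np.unique(stacked, axis=0, return_counts=True)
    xp, gp_idx = uniq[:, :-1], uniq[:, -1]
    n_p = counts_p.astype(float)

    grid = result.em.grid()
    nodes = grid.nodes
    names, theta0 = _parameter_vector(result)
    n_items = len(item_ids)

    def per_pattern_ll(vec: np.ndarray) -> np.ndarray:
        pos = 0
        items = []
        for item_id in item_ids:
            kj = result.items[item_id].n_categories
            a = vec[pos]
            c = vec[pos + 1 : pos + kj]
            pos += kj
            items.append(GrmItemParams(item_id, a, tuple(c)))
        mus = [g.mu for g in result.groups]
        sigmas = [g.sigma for g in result.groups]
        for g in range(len(result.groups)):
            if not result.groups[g].is_reference:
                mus[g] = vec[pos]
                sigmas[g] = vec[pos + 1]
                pos += 2
        L = np.zeros((xp.shape[0], nodes.size))
        for j in range(n_items):
            logp = np.log(category_probs(items[j], nodes))
            L += logp[:, xp[:, j] - 1].T
        lw = np.empty((len(result.groups), nodes.size))
        for g in range(len(result.groups)):
            logd = norm.logpdf(nodes, loc=mus[g], scale=sigmas[g])
            lw[g] = logd - logsumexp(logd)
        return logsumexp(L + lw[gp_idx], axis=1)

    # per-parameter steps that keep slopes positive, intercepts ordered
    # and sigmas positive under perturbation
    steps = []
    for item_id in item_ids:
        it = result.items[item_id]
        steps.append(min(1e-4 * max(1.0, it.a), it.a / 2))
        for m in range(len(it.c)):
            h = 1e-4 * max(1.0, abs(it.c[m]))
            if m > 0:
                h = min(h, (it.c[m - 1] - it.c[m]) / 2)
            if m < len(it.c) - 1:
                h = min(h, (it.c[m] - it.c[m + 1]) / 2)
            steps.append(max(h, 1e-12))
    for g in result.groups:
        if not g.is_reference:
            steps.append(1e-4 * max(1.0, abs(g.mu)))
            steps.append(min(1e-4 * max(1.0, g.sigma), g.sigma / 2))

    q = theta0.size
    scores = np.empty((xp.shape[0], q))
    for i in range(q):
        h = steps[i]
        up = theta0.copy()
        up[i] += h
        dn = theta0.copy()
        dn[i] -= h
        scores[:, i] = (per_pattern_ll(up) - per_pattern_ll(dn)) / (2 * h)

    info = scores.T @ (scores * n_p[:, None])
    ses: dict[str, float | None] = {}
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(info)
    diag = np.diag(cov)
    for name, v in zip(names, diag):
        ses[name] = float(np.sqrt(v)) if np.isfinite(v) and v > 0 else None
    result.standard_errors = ses
    return ses
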