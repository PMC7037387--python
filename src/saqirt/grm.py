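"""Graded response model probability machinery.

Samejima's graded response model (GRM) treats an ordinal item with K
response categories as a stack of K-1 cumulative "boundary" curves.  In
the slope/intercept parameterization used throughout this package,

    P(X >= k+1 | theta) = logistic(a * theta + c_k),    k = 1..K-1,

where ``theta`` is the latent trait in SD units, ``a`` the discrimination
(how sharply response probabilities change with the trait) and
``c_1 > c_2 > ... > c_{K-1}`` the intercepts.  Category probabilities are
adjacent differences of the boundary curves.  The threshold (location)
form is ``b_k = -c_k / a``: the trait level at which a respondent is
equally likely to be above or below boundary k.  Intercepts are inversely
proportional to the thresholds, so large positive intercepts mean
boundaries crossed far below the trait mean -- typical of agreement-heavy
safety-climate items.

All probabilities are on the pure logistic metric.  The scaling constant
D = 1.702 appears only in :func:`slope_to_loading`, which converts a
logistic slope to a normal-ogive standardized factor loading.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.special import expit

__all__ = [
    "GrmItemParams",
    "boundary_prob",
    "category_probs",
    "pattern_loglik",
    "to_thresholds",
    "from_thresholds",
    "slope_to_loading",
    "load_item_params",
    "load_category_maps",
    "save_item_params",
]

#: logistic-to-normal-ogive scaling constant
D_SCALING = 1.702

#: probability floor guarding logs of saturated category probabilities
_P_FLOOR = 1e-300


@dataclass(frozen=True)
class GrmItemParams:
    """Slope/intercept parameters of one graded-response item.

    Parameters
    ----------
    item_id
        Unique item label, e.g. ``"TC1"``.
    a
        Discrimination (slope), logit units per trait SD; must be > 0.
    c
        Intercepts ``(c_1, ..., c_{K-1})``, strictly decreasing so the
        derived thresholds ``b_k = -c_k / a`` are strictly increasing.
    """

    item_id: str
    a: float
    c: tuple[float, ...]

    def __post_init__(self) -> None:
        if not np.isfinite(self.a) or self.a <= 0:
            raise ValueError(f"item {self.item_id!r}: slope a must be positive, got {self.a}")
        c = tuple(float(v) for v in self.c)
        if len(c) < 1:
            raise ValueError(f"item {self.item_id!r}: needs at least one intercept")
        if not all(np.isfinite(c)):
            raise ValueError(f"item {self.item_id!r}: non-finite intercept in {c}")
        if any(c[i] <= c[i + 1] for i in range(len(c) - 1)):
            raise ValueError(
                f"item {self.item_id!r}: intercepts must be strictly decreasing, got {c}"
            )
        object.__setattr__(self, "c", c)
        object.__setattr__(self, "a", float(self.a))

    @property
    def n_categories(self) -> int:
        return len(self.c) + 1


def boundary_prob(a: float, c_k: float, theta) -> np.ndarray | float:
    """Cumulative boundary curve ``P(X >= k+1 | theta) = logistic(a*theta + c_k)``.

    Saturates smoothly at 0/1 for extreme logits; never NaN for finite input.
    """
    return expit(a * np.asarray(theta, dtype=float) + c_k)


def category_probs(item: GrmItemParams, theta) -> np.ndarray:
    """Category probabilities ``P(X = k | theta)`` for k = 1..K.

    Returns an array of shape ``theta.shape + (K,)``; rows sum to 1 and all
    entries are >= 0 (a tiny positive floor guards downstream logs).
    """
    th = np.asarray(theta, dtype=float)
    cum = expit(item.a * th[..., None] + np.asarray(item.c))  # (..., K-1)
    ones = np.ones(th.shape + (1,))
    zeros = np.zeros(th.shape + (1,))
    upper = np.concatenate([ones, cum], axis=-1)
    lower = np.concatenate([cum, zeros], axis=-1)
    return np.maximum(upper - lower, _P_FLOOR)


def pattern_loglik(
    items: Sequence[GrmItemParams],
    responses: Sequence,
    theta,
) -> np.ndarray | float:
    """Log-likelihood of a response pattern at trait value(s) ``theta``.

    ``responses`` aligns with ``items``; entries that are None/NaN are
    treated as not administered and skipped.  Codes are 1-based.
    """
    th = np.asarray(theta, dtype=float)
    total = np.zeros(th.shape)
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
        total = total + np.log(category_probs(item, th)[..., k - 1])
    return total


def to_thresholds(item: GrmItemParams) -> np.ndarray:
    """Threshold parameters ``b_k = -c_k / a`` (trait-SD units, strictly increasing)."""
    return -np.asarray(item.c) / item.a


def from_thresholds(item_id: str, a: float, b: Sequence[float]) -> GrmItemParams:
    """Build an item from threshold form: ``c_k = -a * b_k`` (inverse of to_thresholds)."""
    return GrmItemParams(item_id=item_id, a=a, c=tuple(-a * float(bk) for bk in b))


def slope_to_loading(a: float) -> float:
    """Standardized normal-ogive factor loading implied by a logistic slope.

    ``lambda = (a/D) / sqrt(1 + (a/D)^2)`` with D = 1.702; strictly
    increasing in ``a`` and confined to (0, 1).
    """
    if a <= 0:
        raise ValueError(f"slope must be positive, got {a}")
    astar = a / D_SCALING
    return float(astar / np.sqrt(1.0 + astar**2))


# ---------------------------------------------------------------------------
# item-parameter file I/O (JSON array or CSV with columns item_id,a,c1..c_{K-1})

def load_item_params(path: str | Path) -> list[GrmItemParams]:
    """Read item parameters from a JSON array or a CSV file (by extension)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        records = json.loads(path.read_text())
        return [GrmItemParams(r["item_id"], float(r["a"]), tuple(r["c"])) for r in records]
    items: list[GrmItemParams] = []
    with path.open(newline="") as fh:
        for row in csv.DictReader(fh):
            c_cols = sorted(
                (k for k in row if k.startswith("c") and k[1:].isdigit()),
                key=lambda k: int(k[1:]),
            )
            c = tuple(float(row[k]) for k in c_cols if row[k] != "")
            items.append(GrmItemParams(row["item_id"], float(row["a"]), c))
    return items


def load_category_maps(path: str | Path) -> dict[str, dict[int, int]]:
    """Category recode maps stored alongside item parameters (JSON only).

    When calibration collapsed unobserved categories, the parameter file
    records how raw codes map onto the fitted item's categories; scoring
    must apply the same recode.  CSV parameter files carry no maps.
    """
    path = Path(path)
    if path.suffix.lower() != ".json":
        return {}
    maps: dict[str, dict[int, int]] = {}
    for record in json.loads(path.read_text()):
        if record.get("category_map"):
            maps[record["item_id"]] = {
                int(k): int(v) for k, v in record["category_map"].items()
            }
    return maps


def save_item_params(
    items: Iterable[GrmItemParams],
    path: str | Path,
    category_maps: dict[str, dict[int, int]] | None = None,
) -> None:
    """Write item parameters as JSON or CSV, chosen by file extension.

    ``category_maps`` (raw code -> fitted category, per item) is stored in
    JSON output for items whose categories were collapsed.
    """
    path = Path(path)
    items = list(items)
    if path.suffix.lower() == ".json":
        payload = []
        for it in items:
            record: dict = {"item_id": it.item_id, "a": it.a, "c": list(it.c)}
            if category_maps and it.item_id in category_maps:
                record["category_map"] = {
                    str(k): v for k, v in category_maps[it.item_id].items()
                }
            payload.append(record)
        path.write_text(json.dumps(payload, indent=2) + "\n")
        return
    k_max = max(it.n_categories for it in items)
    header = ["item_id", "a"] + [f"c{i}" for i in range(1, k_max)]
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for it in items:
            padded = list(it.c) + [""] * (k_max - it.n_categories)
            writer.writerow([it.item_id, it.a, *padded])
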