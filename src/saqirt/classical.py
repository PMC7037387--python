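"""Traditional mean-rubric domain scoring and its resolution bound.

The classical SAQ rubric maps each raw item code 1..5 to (code-1)*25 and
averages over the domain's items, yielding a 0-100 score.  Because that
average lives on a lattice, a domain of n five-point items can realize at
most (5-1)*n + 1 distinct scores -- the resolution ceiling the IRT
comparison is measured against.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .instrument import InstrumentSpec, ResponseMatrix

__all__ = [
    "mean_domain_score",
    "domain_mean_scores",
    "theoretical_max_unique",
    "percent_agreement",
]


def mean_domain_score(responses: Sequence, n_items: int | None = None) -> float:
    """Mean rubric score of one domain's responses on the 0-100 scale.

    Each code ``x`` in 1..5 contributes ``(x - 1) * 25``; the domain score
    is the average.  Any missing item yields NaN (no partial means -- the
    domains are too short for ad hoc missing handling).
    """
    arr = np.asarray(
        [np.nan if r is None else float(r) for r in responses], dtype=float
    )
    if n_items is not None and arr.size != n_items:
        raise ValueError(f"expected {n_items} item responses, got {arr.size}")
    if np.isnan(arr).any():
        return float("nan")
    if ((arr < 1) | (arr > 5) | (arr != np.round(arr))).any():
        raise ValueError(f"codes must be integers in 1..5, got {arr}")
    return float(np.mean((arr - 1.0) * 25.0))


def domain_mean_scores(matrix: ResponseMatrix, spec: InstrumentSpec) -> pd.DataFrame:
    """Mean rubric score per respondent per domain (NaN where incomplete)."""
    out = pd.DataFrame(index=matrix.respondent_ids)
    for dom in spec.domain_ids:
        codes = matrix.codes(spec.items_for(dom))
        out[dom] = ((codes - 1.0) * 25.0).mean(axis=1)  # NaN propagates listwise
    return out


def theoretical_max_unique(n_items: int, n_categories: int = 5) -> int:
    """Maximum number of distinct mean-rubric scores a domain can produce.

    The item sum ranges over ``(n_categories - 1) * n_items + 1``
    consecutive integers and the mean score is a bijection of the sum.
    """
    if n_items < 1:
        raise ValueError(f"n_items must be >= 1, got {n_items}")
    if n_categories < 2:
        raise ValueError(f"n_categories must be >= 2, got {n_categories}")
    return (n_categories - 1) * n_items + 1


def percent_agreement(scores, threshold: float = 75.0) -> float:
    """Share (%) of non-null scores at or above the rubric's 75-point cut.

    The SAQ rubric reads a 0-100 domain score of 75 or more as a positive
    safety attitude; the comparison is inclusive at the threshold.
    """
    arr = np.asarray(scores, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        raise ValueError("percent_agreement needs at least one non-null score")
    return float(100.0 * np.mean(arr >= threshold))
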