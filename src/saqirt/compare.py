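"""Resolution and precision comparison of mean-rubric vs IRT scores.

The headline analysis: for every domain, count the distinct scores each
method actually produces (the mean rubric is capped at its lattice bound,
EAP scores at 2 dp number in the hundreds), compare score ranges, compute
the between-method correlation, and -- the precision argument -- measure
how widely the IRT scores spread among respondents who share a single
mean score.  A wide conditional spread at, say, the rubric's 75-point
"positive attitude" cut means the mean score lumps together respondents
the items can actually distinguish.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
import pandas as pd

from .classical import theoretical_max_unique
from .instrument import InstrumentSpec

__all__ = [
    "SpreadRecord",
    "DomainComparison",
    "ComparisonReport",
    "count_unique",
    "score_range",
    "conditional_spread",
    "method_correlation",
    "compare_domain",
    "comparison_report",
]


@dataclass(frozen=True)
class SpreadRecord:
    """IRT-score spread among respondents sharing one mean-rubric score."""

    mean_score: float
    n: int
    irt_min: float
    irt_max: float
    width: float
    width_pct_of_total: float | None

    def to_dict(self) -> dict:
        return {
            "mean_score": self.mean_score,
            "n": self.n,
            "irt_min": self.irt_min,
            "irt_max": self.irt_max,
            "width": self.width,
            "width_pct_of_total": self.width_pct_of_total,
        }


@dataclass(frozen=True)
class DomainComparison:
    """One domain's resolution/precision contrast between the two methods."""

    domain: str
    n: int
    n_unique_mean: int
    n_unique_irt: int
    theoretical_max_mean: int
    mean_low: float
    mean_high: float
    mean_width: float
    irt_low: float
    irt_high: float
    irt_width: float
    correlation: float
    spread: tuple[SpreadRecord, ...] = field(default_factory=tuple)

    def to_dict(self) -> dict:
        return {
            "domain": self.domain,
            "n": self.n,
            "n_unique_mean": self.n_unique_mean,
            "n_unique_irt": self.n_unique_irt,
            "theoretical_max_mean": self.theoretical_max_mean,
            "mean_range": [self.mean_low, self.mean_high, self.mean_width],
            "irt_range": [self.irt_low, self.irt_high, self.irt_width],
            "correlation": self.correlation,
            "spread": [s.to_dict() for s in self.spread],
        }


@dataclass(frozen=True)
class ComparisonReport:
    """Per-domain comparisons for one dataset."""

    domains: tuple[DomainComparison, ...]

    def to_dict(self) -> dict:
        return {"domains": [d.to_dict() for d in self.domains]}

    def table(self) -> pd.DataFrame:
        rows = []
        for d in self.domains:
            rows.append(
                {
                    "domain": d.domain,
                    "n_unique_mean": d.n_unique_mean,
                    "n_unique_irt": d.n_unique_irt,
                    "mean_low": d.mean_low,
                    "mean_high": d.mean_high,
                    "irt_low": d.irt_low,
                    "irt_high": d.irt_high,
                    "irt_width": d.irt_width,
                    "correlation": d.correlation,
                }
            )
        return pd.DataFrame(rows).set_index("domain")


def _clean(scores) -> np.ndarray:
    arr = np.asarray(scores, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        raise ValueError("no non-null scores")
    return arr


def count_unique(scores, decimals: int | None = None) -> int:
    """Distinct score values, optionally after rounding to ``decimals``."""
    arr = _clean(scores)
    if decimals is not None:
        arr = np.round(arr, decimals)
    return int(np.unique(arr).size)


def score_range(scores) -> tuple[float, float, float]:
    """(lowest, highest, width) over the non-null scores."""
    arr = _clean(scores)
    lo, hi = float(arr.min()), float(arr.max())
    return lo, hi, hi - lo


def conditional_spread(mean_scores, irt_scores) -> list[SpreadRecord]:
    """IRT-score spread at each unique mean score.

    Spread widths are also expressed as a percentage of the overall IRT
    score range (None when that range is zero).
    """
    m = np.asarray(mean_scores, dtype=float)
    t = np.asarray(irt_scores, dtype=float)
    if m.shape != t.shape:
        raise ValueError("score vectors must align")
    ok = ~(np.isnan(m) | np.isnan(t))
    m, t = m[ok], t[ok]
    if m.size == 0:
        raise ValueError("no paired non-null scores")
    _, _, total_width = score_range(t)
    records = []
    for value in np.unique(m):
        sel = t[m == value]
        width = float(sel.max() - sel.min())
        pct = 100.0 * width / total_width if total_width > 0 else None
        records.append(
            SpreadRecord(
                mean_score=float(value),
                n=int(sel.size),
                irt_min=float(sel.min()),
                irt_max=float(sel.max()),
                width=width,
                width_pct_of_total=pct,
            )
        )
    return records


def method_correlation(mean_scores, irt_scores) -> float:
    """Pearson correlation between the two methods' scores."""
    m = np.asarray(mean_scores, dtype=float)
    t = np.asarray(irt_scores, dtype=float)
    ok = ~(np.isnan(m) | np.isnan(t))
    m, t = m[ok], t[ok]
    if m.size < 3:
        raise ValueError("need at least 3 paired scores")
    if m.std() == 0 or t.std() == 0:
        raise ValueError("zero variance in a score vector")
    return float(np.corrcoef(m, t)[0, 1])


def compare_domain(
    domain: str,
    mean_scores,
    irt_scores,
    n_items: int,
    n_categories: int = 5,
    irt_decimals: int | None = 2,
) -> DomainComparison:
    """Full comparison record for one domain.

    Unique IRT values are counted on the 2-dp rounded scores by default
    (the practical reporting convention); mean scores are exact lattice
    values and are not rounded.
    """
    m = np.asarray(mean_scores, dtype=float)
    t = np.asarray(irt_scores, dtype=float)
    ok = ~(np.isnan(m) | np.isnan(t))
    m, t = m[ok], t[ok]
    mean_lo, mean_hi, mean_w = score_range(m)
    irt_lo, irt_hi, irt_w = score_range(t)
    return DomainComparison(
        domain=domain,
        n=int(m.size),
        n_unique_mean=count_unique(m),
        n_unique_irt=count_unique(t, decimals=irt_decimals),
        theoretical_max_mean=theoretical_max_unique(n_items, n_categories),
        mean_low=mean_lo,
        mean_high=mean_hi,
        mean_width=mean_w,
        irt_low=irt_lo,
        irt_high=irt_hi,
        irt_width=irt_w,
        correlation=method_correlation(m, t),
        spread=tuple(conditional_spread(m, t)),
    )


def comparison_report(
    mean_scores: pd.DataFrame,
    irt_theta: pd.DataFrame,
    spec: InstrumentSpec,
    irt_decimals: int | None = 2,
) -> ComparisonReport:
    """Compare the two scoring methods across all instrument domains.

    ``mean_scores`` has one 0-100 column per domain; ``irt_theta`` one
    trait-SD column per domain (same respondents).  The report is
    invariant to respondent ordering.
    """
    domains = []
    for dom in spec.domain_ids:
        k = max(spec.n_categories[i] for i in spec.items_for(dom))
        domains.append(
            compare_domain(
                dom,
                mean_scores[dom].to_numpy(),
                irt_theta[dom].to_numpy(),
                n_items=len(spec.items_for(dom)),
                n_categories=k,
                irt_decimals=irt_decimals,
            )
        )
    return ComparisonReport(domains=tuple(domains))
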