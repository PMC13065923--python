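"""Hit-rate extrapolation statistics and experiment-table aggregation.

A random subset of an enumerated library is rescreened; the fraction
passing is the extrapolated virtual hit rate of the whole library.  The
point estimate is reported in percent with a Wilson 95% confidence
interval (robust at small rates, unlike the Wald interval — the interval
is an additive contract on top of the plain point estimates the upstream
screening reports).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from statsmodels.stats.proportion import proportion_confint


@dataclass(frozen=True)
class HitRateResult:
    hits: int
    n: int
    rate_percent: float
    ci95: tuple[float, float]  # Wilson interval, percent

    def formatted(self, decimals: int = 1) -> str:
        """Display rounding only; the stored values stay at full precision."""
        return f"{self.rate_percent:.{decimals}f}%"


def hit_rate(hits: int, n: int, alpha: float = 0.05) -> HitRateResult:
    """Virtual hit rate with a Wilson confidence interval, in percent."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= hits <= n:
        raise ValueError(f"hits must be in [0, n], got {hits}/{n}")
    lo, hi = proportion_confint(hits, n, alpha=alpha, method="wilson")
    return HitRateResult(
        hits=hits,
        n=n,
        rate_percent=100.0 * hits / n,
        ci95=(100.0 * float(lo), 100.0 * float(hi)),
    )


def relative_increase(a: float, b: float) -> float:
    """Percent change of ``a`` over the reference ``b``: 100·(a − b)/b."""
    if b == 0:
        raise ValueError("reference value must be nonzero")
    return 100.0 * (a - b) / b


def aggregate_counts(table: Iterable[tuple[str, int]]) -> int:
    """Exact integer total of per-experiment counts."""
    total = 0
    for _exp_id, count in table:
        if count < 0:
            raise ValueError("counts must be non-negative")
        total += int(count)
    return total
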