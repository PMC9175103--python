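"""Evaluation arithmetic: 2x2 metrics and rates with exact binomial CIs.

Percentages are rounded half-up to one decimal.  The default confidence
interval is the exact Clopper-Pearson interval from beta-distribution
quantiles; Wilson score intervals are available as an alternative.  The
method used is recorded in every result.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

from scipy import stats


def round_half_up(value: float, decimals: int = 1) -> float:
    """Decimal half-up rounding (printed-table style), avoiding binary-float
    banker's rounding artifacts."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def clopper_pearson(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact binomial confidence interval for k successes out of n."""
    if not 0 <= k <= n or n <= 0:
        raise ValueError(f"need 0 <= k <= n, n > 0; got k={k}, n={n}")
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return (lo, hi)


def wilson(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Wilson score interval."""
    if not 0 <= k <= n or n <= 0:
        raise ValueError(f"need 0 <= k <= n, n > 0; got k={k}, n={n}")
    z = stats.norm.ppf(1 - alpha / 2)
    p = k / n
    denom = 1 + z * z / n
    center = (p + z * z / (2 * n)) / denom
    half = z * math.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom
    return (max(0.0, center - half), min(1.0, center + half))


_CI_METHODS = {"clopper_pearson": clopper_pearson, "wilson": wilson}


@dataclass(frozen=True)
class RateWithCI:
    numerator: int
    denominator: int
    rate_percent: float  # half-up, 1 decimal
    ci_low_percent: float
    ci_high_percent: float
    ci_method: str = "clopper_pearson"


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def compute_confirmation_rate(
    n_confirmed: int,
    n_identified: int,
    ci_method: str = "clopper_pearson",
) -> RateWithCI:
    """Chart-confirmation rate: confirmed / identified, as a percentage with CI."""
    if n_identified <= 0:
        raise ValueError("n_identified must be positive")
    if not 0 <= n_confirmed <= n_identified:
        raise ValueError("need 0 <= n_confirmed <= n_identified")
    lo, hi = _CI_METHODS[ci_method](n_confirmed, n_identified)
    return RateWithCI(
        numerator=n_confirmed,
        denominator=n_identified,
        rate_percent=round_half_up(100.0 * n_confirmed / n_identified),
        ci_low_percent=round_half_up(100.0 * lo),
        ci_high_percent=round_half_up(100.0 * hi),
        ci_method=ci_method,
    )


def compute_metrics(
    counts: ConfusionCounts,
    ci_method: str = "clopper_pearson",
) -> dict[str, RateWithCI | None]:
    """Sensitivity, specificity, PPV and NPV with CIs.

    A metric whose denominator is zero is reported as None (undefined), not
    an error.
    """
    pairs = {
        "sensitivity": (counts.tp, counts.tp + counts.fn),
        "specificity": (counts.tn, counts.tn + counts.fp),
        "ppv": (counts.tp, counts.tp + counts.fp),
        "npv": (counts.tn, counts.tn + counts.fn),
    }
    out: dict[str, RateWithCI | None] = {}
    for name, (k, n) in pairs.items():
        out[name] = compute_confirmation_rate(k, n, ci_method) if n > 0 else None
    return out
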