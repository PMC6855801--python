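"""Population statistics: OLS regressions, Fisher's exact test, effect sizes.

The regressions relate per-population translocation frequency to genomic
size, median intermixing volume, or contact frequency; each point is one
(chromosome pair × replicate population).  Significance of a slope is the
two-sided t-test with n−2 degrees of freedom.  Two-by-two contrasts
(contact/no-contact × condition, normal/translocated × condition) use the
two-sided Fisher exact test under the probability-mass ordering convention:
the p-value sums, over all tables with the observed margins, the
hypergeometric probabilities not exceeding that of the observed table.
Effect summaries report fold change and signed percent change relative to a
control, with percent frequencies carried on the 0–100 scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "RegressionResult",
    "EffectSummary",
    "linear_regression",
    "fisher_exact",
    "percent_reduction",
    "percent_change",
    "fold_change",
    "size_regression",
]


@dataclass(frozen=True)
class RegressionResult:
    m: float  # slope
    intercept: float
    r_squared: float
    p_value: float
    n_points: int
    stderr: float  # standard error of the slope
    degenerate: bool = False  # SS_tot == 0 (constant y)


@dataclass(frozen=True)
class EffectSummary:
    control_value: float
    treated_value: float

    @property
    def fold_change(self) -> float:
        if self.control_value <= 0:
            raise ValueError("fold change undefined for control <= 0")
        return self.treated_value / self.control_value

    @property
    def percent_change(self) -> float:
        return 100.0 * (self.treated_value - self.control_value) / self.control_value


def linear_regression(x: Sequence[float], y: Sequence[float]) -> RegressionResult:
    """Ordinary least squares of y on x with a two-sided slope t-test.

    Requires n ≥ 3 and non-constant x.  A constant y (SS_tot = 0) is a
    degenerate but valid input: the fit is flat, r² is defined as 0 and
    p as 1, with the ``degenerate`` flag set.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D sequences of equal length")
    n = len(x)
    if n < 3:
        raise ValueError(f"regression needs at least 3 points, got {n}")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; slope undefined")
    if np.ptp(y) == 0:
        return RegressionResult(
            m=0.0, intercept=float(y[0]), r_squared=0.0, p_value=1.0,
            n_points=n, stderr=0.0, degenerate=True,
        )
    fit = sps.linregress(x, y)
    return RegressionResult(
        m=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        p_value=float(fit.pvalue),
        n_points=n,
        stderr=float(fit.stderr),
    )


def fisher_exact(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p for a 2×2 table, by exact enumeration.

    All tables with the observed margins are weighted by integer
    hypergeometric weights C(r1, k)·C(r2, c1−k); the p-value is the weight
    fraction of tables no more probable than the observed one.  Integer
    comparison makes tie handling exact.  A table with an empty margin
    carries no information: p = 1.
    """
    t = np.asarray(table, dtype=object)
    if t.shape != (2, 2):
        raise ValueError("table must be 2×2")
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    if min(a, b, c, d) < 0:
        raise ValueError("table entries must be non-negative")
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if n == 0 or r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0
    k_min, k_max = max(0, c1 - r2), min(c1, r1)
    weights = [comb(r1, k) * comb(r2, c1 - k) for k in range(k_min, k_max + 1)]
    observed = weights[a - k_min]
    numer = sum(w for w in weights if w <= observed)
    return float(numer / sum(weights))


def percent_change(control: float, treated: float) -> float:
    """Signed percent change of treated vs control (negative = decrease)."""
    if control <= 0:
        raise ValueError("percent change undefined for control <= 0")
    return 100.0 * (treated - control) / control


def percent_reduction(control: float, treated: float, round_whole: bool = True) -> float:
    """Percent reduction from control to treated, optionally to whole percent.

    Both inputs are on the same scale (e.g. percent frequencies); the result
    is 100·(control − treated)/control.
    """
    if control <= 0:
        raise ValueError("percent reduction undefined for control <= 0")
    value = 100.0 * (control - treated) / control
    return float(round(value)) if round_whole else value


def fold_change(control: float, treated: float) -> float:
    return EffectSummary(control, treated).fold_change


def size_regression(
    per_pair_frequencies: Sequence[tuple[tuple[str, str], float]],
    chromosome_lengths_mb: dict[str, float],
) -> RegressionResult:
    """Translocation frequency vs summed genomic size of the pair.

    ``per_pair_frequencies`` lists ((chromA, chromB), frequency) points,
    one per pair × replicate; x is the summed length (Mb) of the two
    chromosomes.  Raises KeyError for a chromosome without a length.
    """
    xs, ys = [], []
    for (ca, cb), freq in per_pair_frequencies:
        for c in (ca, cb):
            if c not in chromosome_lengths_mb:
                raise KeyError(f"no genomic length configured for chromosome {c!r}")
        xs.append(chromosome_lengths_mb[ca] + chromosome_lengths_mb[cb])
        ys.append(freq)
    return linear_regression(xs, ys)
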