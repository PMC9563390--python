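"""McNemar tests and discordant-pair odds ratios for matched binary data.

For one code group, matched case-control pairs collapse to a 2x2 paired
table (n11, n10, n01, n00) where n10 counts pairs with only the case
exposed and n01 pairs with only the control exposed.  Concordant pairs
carry no information about the within-pair association: the McNemar
statistic and the conditional odds ratio depend on (n10, n01) alone.

Test modes
----------
chi2            (n10 - n01)^2 / (n10 + n01), upper tail of chi-square(1).
chi2_corrected  (|n10 - n01| - 1)^2 / (n10 + n01), same reference.
exact           two-sided binomial test of n10 successes in n10 + n01
                trials at 1/2; p = min(1, 2 * smaller tail), statistic
                min(n10, n01).
auto            chi2 when n10 + n01 >= EXACT_SWITCH (25), exact below.

The conditional OR is n10/n01 with a Wald interval on the log scale,
exp(ln OR +/- z * sqrt(1/n10 + 1/n01)), z = 1.96 by default.  Zero
discordant cells are flagged rather than raised; an opt-in +0.5
continuity correction (applied to all four cells) yields finite
estimates when one cell is empty.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "PairedTable",
    "EffectEstimate",
    "mcnemar_test",
    "mcnemar_pvalues",
    "discordant_or",
    "paired_table_from_vectors",
    "EXACT_SWITCH",
]

EXACT_SWITCH = 25  # discordant-pair count below which 'auto' uses the exact test


@dataclass(frozen=True)
class PairedTable:
    """2x2 matched-pair counts for one code group."""

    n11: int
    n10: int  # case exposed only (McNemar's b)
    n01: int  # control exposed only (McNemar's c)
    n00: int

    def __post_init__(self):
        for name in ("n11", "n10", "n01", "n00"):
            v = getattr(self, name)
            if not float(v).is_integer() or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def n_pairs(self) -> int:
        return self.n11 + self.n10 + self.n01 + self.n00

    @property
    def n_discordant(self) -> int:
        return self.n10 + self.n01


@dataclass(frozen=True)
class EffectEstimate:
    """Conditional odds ratio n10/n01 with Wald CI on the log scale.

    ``degenerate_flag`` is 'ok' for a finite estimate, 'no_discordant'
    when both discordant cells are empty, 'zero_cell' when exactly one
    is (OR and CI are NaN unless the continuity correction was applied).
    """

    odds_ratio: float
    ci_lower: float
    ci_upper: float
    z: float = 1.96
    degenerate_flag: str = "ok"


def paired_table_from_vectors(case_exposed, control_exposed) -> PairedTable:
    """Collapse aligned binary exposure vectors (one entry per pair)."""
    a = np.asarray(case_exposed, dtype=bool)
    b = np.asarray(control_exposed, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("case and control vectors must have equal length")
    return PairedTable(
        n11=int(np.sum(a & b)),
        n10=int(np.sum(a & ~b)),
        n01=int(np.sum(~a & b)),
        n00=int(np.sum(~a & ~b)),
    )


def mcnemar_test(table: PairedTable, mode: str = "auto",
                 exact_switch: int = EXACT_SWITCH) -> tuple[float, float]:
    """McNemar statistic and p-value for one paired table.

    With no discordant pairs the test is degenerate: (0.0, 1.0) is
    returned rather than raising, matching how the screen treats
    untestable codes.
    """
    b, c = table.n10, table.n01
    n = b + c
    if n == 0:
        return 0.0, 1.0
    if mode == "auto":
        mode = "chi2" if n >= exact_switch else "exact"
    if mode == "chi2":
        stat = (b - c) ** 2 / n
        return float(stat), float(stats.chi2.sf(stat, df=1))
    if mode == "chi2_corrected":
        stat = max(abs(b - c) - 1, 0) ** 2 / n
        return float(stat), float(stats.chi2.sf(stat, df=1))
    if mode == "exact":
        k = min(b, c)
        p = min(1.0, 2.0 * stats.binom.cdf(k, n, 0.5))
        return float(k), float(p)
    raise ValueError(f"unknown mode {mode!r}")


def mcnemar_pvalues(n10, n01, mode: str = "auto",
                    exact_switch: int = EXACT_SWITCH) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised McNemar statistics and p-values over many code groups.

    Degenerate codes (no discordant pairs) get statistic 0 and p = 1.
    Returns (statistics, p_values) aligned with the inputs.
    """
    b = np.asarray(n10, dtype=np.int64)
    c = np.asarray(n01, dtype=np.int64)
    n = b + c
    stat = np.zeros(b.shape, dtype=float)
    p = np.ones(b.shape, dtype=float)
    if mode == "auto":
        use_chi2 = n >= exact_switch
        use_exact = (n > 0) & ~use_chi2
    elif mode in ("chi2", "chi2_corrected"):
        use_chi2 = n > 0
        use_exact = np.zeros(b.shape, dtype=bool)
    elif mode == "exact":
        use_exact = n > 0
        use_chi2 = np.zeros(b.shape, dtype=bool)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if use_chi2.any():
        diff = np.abs(b[use_chi2] - c[use_chi2]).astype(float)
        if mode == "chi2_corrected":
            diff = np.maximum(diff - 1.0, 0.0)
        s = diff ** 2 / n[use_chi2]
        stat[use_chi2] = s
        p[use_chi2] = stats.chi2.sf(s, df=1)
    if use_exact.any():
        k = np.minimum(b[use_exact], c[use_exact])
        stat[use_exact] = k
        p[use_exact] = np.minimum(1.0, 2.0 * stats.binom.cdf(k, n[use_exact], 0.5))
    return stat, p


def discordant_or(table: PairedTable, z: float = 1.96,
                  continuity: bool = False) -> EffectEstimate:
    """Conditional (discordant-pair) odds ratio with Wald 95% CI.

    OR = n10/n01; CI = exp(ln OR +/- z*sqrt(1/n10 + 1/n01)).  When a
    discordant cell is zero the estimate is undefined: the flag records
    it and, unless ``continuity`` adds 0.5 to all four cells, OR and CI
    are NaN.  Rounding happens only at presentation.
    """
    if z <= 0:
        raise ValueError("z must be positive")
    b, c = float(table.n10), float(table.n01)
    if b == 0 and c == 0:
        return EffectEstimate(math.nan, math.nan, math.nan, z, "no_discordant")
    flag = "ok"
    if b == 0 or c == 0:
        flag = "zero_cell"
        if not continuity:
            return EffectEstimate(math.nan, math.nan, math.nan, z, flag)
        b, c = b + 0.5, c + 0.5
    log_or = math.log(b / c)
    se = math.sqrt(1.0 / b + 1.0 / c)
    return EffectEstimate(
        odds_ratio=b / c,
        ci_lower=math.exp(log_or - z * se),
        ci_upper=math.exp(log_or + z * se),
        z=z,
        degenerate_flag=flag,
    )
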