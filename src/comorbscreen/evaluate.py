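"""Monte-Carlo error-rate evaluation and printed-table count inversion.

``evaluate_procedure`` measures the empirical family-wise error rate,
false discovery proportion, and power of Bonferroni / BH / BY applied
to per-code McNemar p-values on synthetic cohorts with known ground
truth.  Procedures are compared on identical data by deriving each
replicate's seed from the root seed and the replicate index.

``reconstruct_counts`` inverts a printed (OR, 95% CI) pair back to the
integer discordant counts (n10, n01) that produce it under the Wald
construction — useful for checking published tables that print effect
estimates but not the underlying counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .multtest import PValueSet, adjust
from .paired import EXACT_SWITCH, mcnemar_pvalues
from .simulate import SimulationDesign, simulate_cohort, simulate_discordant_counts

__all__ = ["EvaluationSummary", "evaluate_procedure", "reconstruct_counts"]

_SEED_MOD = 2**31 - 1


@dataclass(frozen=True)
class EvaluationSummary:
    """Aggregate error rates over replicates.

    empirical_fwer  fraction of replicates with >= 1 false rejection
    empirical_fdr   mean of V / max(R, 1) (false discovery proportion)
    power           mean fraction of non-null codes rejected (NaN when
                    the design has no non-null codes)
    """

    procedure: str
    level: float
    replicates: int
    empirical_fwer: float
    empirical_fdr: float
    power: float
    rejections: np.ndarray  # R per replicate
    false_rejections: np.ndarray  # V per replicate


def evaluate_procedure(design: SimulationDesign, procedure: str = "by",
                       level: float = 0.05, replicates: int = 200,
                       seed: int = 0, mcnemar_mode: str = "auto",
                       exact_switch: int = EXACT_SWITCH) -> EvaluationSummary:
    """Empirical FWER / FDR / power of one procedure on one design.

    Per replicate: simulate a cohort (the fast independence shortcut
    when rho = 0 and no frailty, otherwise the full copula path), test
    every code with McNemar, adjust, and compare rejections with the
    planted truth.  Codes with no discordant pairs keep p = 1 and are
    never rejected.  Replicate r draws its seed from SeedSequence
    ((seed, r)), so different procedures at the same root seed see
    identical data while different root seeds give independent streams.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    fast = design.rho == 0.0 and design.frailty_sd == 0.0
    labels = [str(i) for i in range(design.m_codes)]
    R = np.zeros(replicates, dtype=int)
    V = np.zeros(replicates, dtype=int)
    fdp = np.zeros(replicates)
    pow_ = np.zeros(replicates)
    any_nonnull = False
    for r in range(replicates):
        rep_seed = int(np.random.SeedSequence((seed, r)).generate_state(1)[0])
        d = replace(design, seed=rep_seed % _SEED_MOD)
        if fast:
            n10, n01, truth = simulate_discordant_counts(d)
        else:
            cohort, truth = simulate_cohort(d)
            n10, n01 = cohort.discordant_counts()
        _, p = mcnemar_pvalues(n10, n01, mode=mcnemar_mode,
                               exact_switch=exact_switch)
        res = adjust(PValueSet(labels, p), procedure, level)
        rejected = res.rejected
        null = truth.is_null
        R[r] = rejected.sum()
        V[r] = (rejected & null).sum()
        fdp[r] = V[r] / max(R[r], 1)
        n_nonnull = (~null).sum()
        if n_nonnull:
            any_nonnull = True
            pow_[r] = (rejected & ~null).sum() / n_nonnull
    return EvaluationSummary(
        procedure=procedure, level=level, replicates=replicates,
        empirical_fwer=float((V > 0).mean()),
        empirical_fdr=float(fdp.mean()),
        power=float(pow_.mean()) if any_nonnull else math.nan,
        rejections=R, false_rejections=V,
    )


def _round2(x: float) -> float:
    return float(np.round(x, 2))


def reconstruct_counts(or_printed: float, ci: tuple[float, float],
                       z: float = 1.96, max_count: int = 2000
                       ) -> tuple[int, int] | None:
    """Invert a printed OR and Wald 95% CI to discordant counts.

    Searches integer (n10, n01) with 1 <= n01 <= max_count for pairs
    whose ratio rounds to ``or_printed`` (2 decimals) and whose Wald
    bounds exp(ln(n10/n01) +/- z*sqrt(1/n10 + 1/n01)) round to the
    printed CI.  Returns the solution with the smallest n01 (then
    smallest n10), or None when no count pair reproduces the print.
    """
    low, high = ci
    if or_printed <= 0 or not (0 < low < high):
        raise ValueError("need or_printed > 0 and 0 < low < high")
    for n01 in range(1, max_count + 1):
        # candidate n10 values whose ratio rounds to the printed OR
        lo = math.ceil((or_printed - 0.005) * n01)
        hi = math.floor((or_printed + 0.005) * n01 + 1e-12)
        for n10 in range(max(lo, 1), hi + 1):
            if _round2(n10 / n01) != _round2(or_printed):
                continue
            se = math.sqrt(1.0 / n10 + 1.0 / n01)
            log_or = math.log(n10 / n01)
            if (_round2(math.exp(log_or - z * se)) == _round2(low)
                    and _round2(math.exp(log_or + z * se)) == _round2(high)):
                return n10, n01
    return None
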