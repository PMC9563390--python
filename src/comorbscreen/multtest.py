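"""Multiple-testing procedures implemented from their step-up definitions.

Three procedures over a family of m p-values:

* **Bonferroni** controls the family-wise error rate (FWER): reject
  every test with p <= alpha/m; adjusted p = min(1, m*p).
* **Benjamini-Hochberg (BH)** controls the false discovery rate (FDR)
  under independence: sort p ascending, find the largest rank k with
  p_(k) <= k*q/m, reject ranks 1..k.
* **Benjamini-Yekutieli (BY)** controls FDR under arbitrary dependence:
  BH with q deflated by the harmonic sum c(m) = sum_{i=1..m} 1/i, i.e.
  BY(q) is identical to BH(q / c(m)).

Adjusted p-values use the monotone step-up construction
``adj_(i) = min_{j >= i} min(1, m*p_(j)/j)`` (times c(m) for BY), so
``rejected[i] <=> adjusted_p[i] <= level`` reproduces the step-up set
exactly, boundary inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = ["PValueSet", "AdjustmentResult", "bonferroni", "bh", "by", "harmonic_number", "adjust"]


def harmonic_number(m: int) -> float:
    """c(m) = sum_{i=1..m} 1/i, the BY dependence inflation factor."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return float(np.sum(1.0 / np.arange(1, m + 1)))


@dataclass(frozen=True)
class PValueSet:
    """A labelled family of p-values, one per code group."""

    labels: tuple[str, ...]
    p_values: np.ndarray

    def __init__(self, labels: Sequence[str], p_values: Sequence[float]):
        labels = tuple(str(x) for x in labels)
        p = np.asarray(p_values, dtype=float)
        if len(labels) != p.size:
            raise ValueError("labels and p_values must have equal length")
        if len(set(labels)) != len(labels):
            raise ValueError("labels must be unique")
        if p.size == 0:
            raise ValueError("empty p-value set")
        if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
            bad = np.where(~((p >= 0) & (p <= 1)))[0]
            raise ValueError(f"p-values outside [0, 1] at positions {bad.tolist()}")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "p_values", p)

    def __len__(self) -> int:
        return self.p_values.size


@dataclass(frozen=True)
class AdjustmentResult:
    """Outcome of one multiplicity adjustment over a p-value family.

    ``adjusted_p`` and ``rejected`` are aligned with ``labels`` (the input
    order, not sorted order).  ``cutoff`` is the largest raw p-value that
    was rejected, or None when nothing was.
    """

    method: str
    level: float
    m: int
    labels: tuple[str, ...]
    adjusted_p: np.ndarray
    rejected: np.ndarray
    cutoff: float | None
    harmonic_cm: float | None = field(default=None)

    @property
    def n_rejected(self) -> int:
        return int(self.rejected.sum())

    def rejected_labels(self) -> list[str]:
        return [lab for lab, r in zip(self.labels, self.rejected) if r]


def _check_level(level: float) -> None:
    if not (0.0 < level < 1.0):
        raise ValueError(f"level must be in (0, 1), got {level}")


def bonferroni(pset: PValueSet, alpha: float = 0.05) -> AdjustmentResult:
    """Bonferroni FWER control: reject {i : p_i <= alpha/m}."""
    _check_level(alpha)
    p = pset.p_values
    m = p.size
    adjusted = np.minimum(1.0, m * p)
    rejected = p <= alpha / m
    cutoff = float(p[rejected].max()) if rejected.any() else None
    return AdjustmentResult("bonferroni", alpha, m, pset.labels, adjusted, rejected, cutoff)


def _step_up(pset: PValueSet, q: float, scale: float) -> tuple[np.ndarray, np.ndarray, float | None]:
    """Shared BH/BY step-up machinery.

    ``scale`` is 1 for BH and c(m) for BY.  Ties in p share a fate
    automatically: the step-up maximum is taken over ranks, so equal
    p-values receive equal adjusted values regardless of sort order; the
    stable label tie-break only fixes an arbitrary internal ordering.
    """
    p = pset.p_values
    m = p.size
    # stable sort on p with label as tie-breaker
    order = np.lexsort((np.array(pset.labels), p))
    p_sorted = p[order]
    ranks = np.arange(1, m + 1)
    raw_adj = np.minimum(1.0, scale * m * p_sorted / ranks)
    # monotone step-up adjustment: running min from the largest rank down
    adj_sorted = np.minimum.accumulate(raw_adj[::-1])[::-1]
    adjusted = np.empty(m)
    adjusted[order] = adj_sorted
    # step-up rejection: largest k with p_(k) <= k*q/(m*scale)
    passes = p_sorted <= ranks * q / (m * scale)
    if passes.any():
        k = int(np.max(np.where(passes)[0])) + 1
        rejected_sorted = ranks <= k
        cutoff = float(p_sorted[k - 1])
    else:
        rejected_sorted = np.zeros(m, dtype=bool)
        cutoff = None
    rejected = np.empty(m, dtype=bool)
    rejected[order] = rejected_sorted
    return adjusted, rejected, cutoff


def bh(pset: PValueSet, q: float = 0.05) -> AdjustmentResult:
    """Benjamini-Hochberg step-up FDR control (independence / PRDS)."""
    _check_level(q)
    adjusted, rejected, cutoff = _step_up(pset, q, scale=1.0)
    return AdjustmentResult("bh", q, len(pset), pset.labels, adjusted, rejected, cutoff)


def by(pset: PValueSet, q: float = 0.05) -> AdjustmentResult:
    """Benjamini-Yekutieli step-up FDR control under arbitrary dependence.

    Identical to ``bh`` with q replaced by q/c(m), c(m) the harmonic sum.
    """
    _check_level(q)
    cm = harmonic_number(len(pset))
    adjusted, rejected, cutoff = _step_up(pset, q, scale=cm)
    return AdjustmentResult("by", q, len(pset), pset.labels, adjusted, rejected, cutoff,
                            harmonic_cm=cm)


_METHODS = {"bonferroni": bonferroni, "bh": bh, "by": by}


def adjust(pset: PValueSet, method: str, level: float = 0.05) -> AdjustmentResult:
    """Dispatch by method name ('bonferroni', 'bh', 'by')."""
    try:
        fn = _METHODS[method]
    except KeyError:
        raise ValueError(f"unknown method {method!r}; expected one of {sorted(_METHODS)}") from None
    return fn(pset, level)
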