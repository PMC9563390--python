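"""Three-stage screen / confirm / report protocol over matched pairs.

Matched pairs are split 50-25-25 into training, validation and test
sets at the pair level.  Stage 1 screens every code group observed in
the training exposures with a McNemar test and Benjamini-Yekutieli FDR
control, then keeps only codes whose conditional OR exceeds 1 (the
relevance filter: inverse associations in this design are typically
selection artefacts, not protective comorbidities).  Stage 2 re-tests
the surviving codes on the validation pairs with BY over the reduced
family.  Stage 3 reports ORs with 95% CIs for the confirmed codes from
the test pairs alone, sorted by OR descending.

The stages touch disjoint pair sets, so the confirmed associations and
their reported effect sizes come from data not used to select them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import ExposureMatrix
from .multtest import PValueSet, by
from .paired import EXACT_SWITCH, mcnemar_pvalues
from .simulate import MatchedCohort

__all__ = ["SplitSpec", "StageResult", "ScreeningReport", "RESULT_COLUMNS",
           "split_pairs", "screen", "confirm", "report", "run_screening",
           "pairs_and_matrix_from_cohort"]

RESULT_COLUMNS = ["code_group", "n_pairs", "n11", "n10", "n01", "n00",
                  "mcnemar_stat", "p_value", "p_adjusted", "significant",
                  "odds_ratio", "ci_lower", "ci_upper", "relevant", "stage"]


@dataclass(frozen=True)
class SplitSpec:
    """Pair-level train/validate/test split fractions (default 50-25-25)."""

    fractions: tuple[float, float, float] = (0.50, 0.25, 0.25)
    seed: int = 0

    def __post_init__(self):
        f = self.fractions
        if len(f) != 3 or any(x < 0 for x in f):
            raise ValueError("fractions must be three non-negative numbers")
        if abs(sum(f) - 1.0) > 1e-9:
            raise ValueError(f"fractions must sum to 1, got {sum(f)}")


@dataclass(frozen=True)
class StageResult:
    """Per-code results for one stage plus the derived code sets."""

    results: pd.DataFrame
    significant: frozenset
    relevant: frozenset
    untestable: tuple[str, ...]
    m: int


@dataclass(frozen=True)
class ScreeningReport:
    stage1: StageResult
    stage2_confirmed: frozenset
    stage2_results: pd.DataFrame
    stage3_estimates: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    @property
    def stage1_significant(self) -> frozenset:
        return self.stage1.significant

    @property
    def stage1_relevant(self) -> frozenset:
        return self.stage1.relevant

    def all_results(self) -> pd.DataFrame:
        return pd.concat([self.stage1.results, self.stage2_results,
                          self.stage3_estimates], ignore_index=True)


def split_pairs(pairs: pd.DataFrame, spec: SplitSpec = SplitSpec()
                ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Partition pairs into train/validate/test by seeded assignment.

    Splitting is at the pair level — a case and its control never
    separate.  Subset sizes follow the fractions by largest-remainder
    rounding, so each is within one pair of its target and the three
    subsets are disjoint with union equal to the input.
    """
    n = len(pairs)
    if n < 3:
        raise ValueError("need at least 3 pairs to split three ways")
    targets = np.array(spec.fractions) * n
    sizes = np.floor(targets).astype(int)
    remainder = n - sizes.sum()
    if remainder:
        frac_order = np.argsort(-(targets - sizes), kind="stable")
        for i in frac_order[:remainder]:
            sizes[i] += 1
    rng = np.random.default_rng(spec.seed)
    perm = rng.permutation(n)
    bounds = np.cumsum(sizes)[:2]
    chunks = np.split(perm, bounds)
    return tuple(pairs.iloc[np.sort(c)].reset_index(drop=True) for c in chunks)


def _stage_tables(pairs: pd.DataFrame, matrix: ExposureMatrix):
    """Vectorised 2x2 paired counts for every code column."""
    missing = [pid for pid in pd.concat([pairs["case_id"], pairs["control_id"]])
               if pid not in matrix.data.index]
    if missing:
        raise KeyError(f"pair member(s) absent from exposure matrix: {sorted(set(missing))[:10]}")
    case = matrix.data.loc[pairs["case_id"]].to_numpy(dtype=bool)
    ctrl = matrix.data.loc[pairs["control_id"]].to_numpy(dtype=bool)
    n11 = (case & ctrl).sum(axis=0)
    n10 = (case & ~ctrl).sum(axis=0)
    n01 = (~case & ctrl).sum(axis=0)
    n00 = len(pairs) - n11 - n10 - n01
    return n11, n10, n01, n00


def _or_with_ci(n10: np.ndarray, n01: np.ndarray, z: float = 1.96):
    """Vectorised discordant-pair OR and Wald CI; NaN where a cell is 0."""
    ok = (n10 > 0) & (n01 > 0)
    odds = np.full(n10.shape, np.nan)
    lcl = np.full(n10.shape, np.nan)
    ucl = np.full(n10.shape, np.nan)
    b, c = n10[ok].astype(float), n01[ok].astype(float)
    odds[ok] = b / c
    se = np.sqrt(1.0 / b + 1.0 / c)
    lcl[ok] = np.exp(np.log(b / c) - z * se)
    ucl[ok] = np.exp(np.log(b / c) + z * se)
    return odds, lcl, ucl


def _results_frame(codes, n_pairs, n11, n10, n01, n00, stat, p, p_adj,
                   significant, odds, lcl, ucl, relevant, stage) -> pd.DataFrame:
    df = pd.DataFrame({
        "code_group": codes, "n_pairs": n_pairs,
        "n11": n11, "n10": n10, "n01": n01, "n00": n00,
        "mcnemar_stat": stat, "p_value": p, "p_adjusted": p_adj,
        "significant": np.asarray(significant, dtype=int),
        "odds_ratio": odds, "ci_lower": lcl, "ci_upper": ucl,
        "relevant": np.asarray(relevant, dtype=int), "stage": stage,
    })
    return df[RESULT_COLUMNS]


def screen(train_pairs: pd.DataFrame, matrix: ExposureMatrix, q: float = 0.05,
           mcnemar_mode: str = "auto", exact_switch: int = EXACT_SWITCH,
           z: float = 1.96) -> StageResult:
    """Stage 1: BY-adjusted McNemar screen plus the OR > 1 filter.

    Every code group observed in the training exposures and having at
    least one discordant pair is tested; the multiplicity family size m
    is the number of codes actually tested.  Codes with no discordant
    pair are reported as untestable, not silently dropped.  Relevant =
    significant AND OR strictly greater than 1; codes whose OR is
    undefined (a zero discordant cell) are never flagged relevant.
    """
    n11, n10, n01, n00 = _stage_tables(train_pairs, matrix)
    codes = np.array(matrix.code_groups)
    observed = (n11 + n10 + n01) > 0
    testable = observed & ((n10 + n01) > 0)
    untestable = tuple(codes[observed & ~testable])
    if not testable.any():
        raise ValueError("no testable code groups in the training split")

    t = testable
    stat, p = mcnemar_pvalues(n10[t], n01[t], mode=mcnemar_mode,
                              exact_switch=exact_switch)
    adj = by(PValueSet(codes[t], p), q)
    odds, lcl, ucl = _or_with_ci(n10[t], n01[t], z)
    significant = adj.rejected
    relevant = significant & (np.nan_to_num(odds, nan=0.0) > 1.0)
    results = _results_frame(codes[t], len(train_pairs), n11[t], n10[t],
                             n01[t], n00[t], stat, p, adj.adjusted_p,
                             significant, odds, lcl, ucl, relevant, "train")
    return StageResult(results=results,
                       significant=frozenset(codes[t][significant]),
                       relevant=frozenset(codes[t][relevant]),
                       untestable=untestable, m=int(t.sum()))


def confirm(relevant: frozenset | set, validation_pairs: pd.DataFrame,
            matrix: ExposureMatrix, q: float = 0.05, mcnemar_mode: str = "auto",
            exact_switch: int = EXACT_SWITCH, z: float = 1.96,
            m: int | None = None) -> tuple[frozenset, pd.DataFrame]:
    """Stage 2: re-test the stage-1 relevant codes on validation pairs.

    The BY family defaults to the full relevant set (m = |relevant|);
    codes with no validation discordant pairs keep the degenerate p = 1
    and so are never confirmed, but they still count toward m.  Codes
    absent from the exposure matrix are flagged with NaN results.
    """
    if not relevant:
        raise ValueError("relevant set is empty")
    relevant = sorted(relevant)
    present = [c for c in relevant if c in matrix.data.columns]
    absent = [c for c in relevant if c not in matrix.data.columns]
    sub = ExposureMatrix(matrix.data[present])
    n11, n10, n01, n00 = _stage_tables(validation_pairs, sub)
    stat, p = mcnemar_pvalues(n10, n01, mode=mcnemar_mode, exact_switch=exact_switch)

    all_codes = present + absent
    p_all = np.concatenate([p, np.ones(len(absent))])
    pset = PValueSet(all_codes, p_all)
    adj = by(pset, q)
    if m is not None and m != len(all_codes):
        # explicit family size: rescale via a padded family
        pad = [f"__pad{i}" for i in range(m - len(all_codes))]
        adj = by(PValueSet(all_codes + pad, np.concatenate([p_all, np.ones(len(pad))])), q)
    keep = np.arange(len(all_codes))
    rejected = adj.rejected[keep]
    adjusted = adj.adjusted_p[keep]

    odds, lcl, ucl = _or_with_ci(n10, n01, z)
    nan = np.full(len(absent), np.nan)
    results = _results_frame(
        all_codes, len(validation_pairs),
        np.concatenate([n11, nan]), np.concatenate([n10, nan]),
        np.concatenate([n01, nan]), np.concatenate([n00, nan]),
        np.concatenate([stat, nan]), p_all, adjusted, rejected,
        np.concatenate([odds, nan]), np.concatenate([lcl, nan]),
        np.concatenate([ucl, nan]), rejected & (np.nan_to_num(
            np.concatenate([odds, nan]), nan=0.0) > 1.0), "validate")
    confirmed = frozenset(np.array(all_codes)[rejected])
    return confirmed, results


def report(confirmed: frozenset | set, test_pairs: pd.DataFrame,
           matrix: ExposureMatrix, z: float = 1.96) -> pd.DataFrame:
    """Stage 3: ORs with 95% CIs on the held-out test pairs.

    One row per confirmed code, sorted by OR descending (undefined ORs
    last).  Codes absent from the test exposures carry NaN estimates.
    """
    if not confirmed:
        raise ValueError("confirmed set is empty")
    confirmed = sorted(confirmed)
    present = [c for c in confirmed if c in matrix.data.columns]
    absent = [c for c in confirmed if c not in matrix.data.columns]
    sub = ExposureMatrix(matrix.data[present])
    n11, n10, n01, n00 = _stage_tables(test_pairs, sub)
    stat, p = mcnemar_pvalues(n10, n01)
    odds, lcl, ucl = _or_with_ci(n10, n01, z)
    nan = np.full(len(absent), np.nan)
    results = _results_frame(
        present + absent, len(test_pairs),
        np.concatenate([n11, nan]), np.concatenate([n10, nan]),
        np.concatenate([n01, nan]), np.concatenate([n00, nan]),
        np.concatenate([stat, nan]), np.concatenate([p, nan]),
        np.concatenate([p, nan]) * np.nan,
        np.zeros(len(confirmed), dtype=bool),
        np.concatenate([odds, nan]), np.concatenate([lcl, nan]),
        np.concatenate([ucl, nan]),
        np.zeros(len(confirmed), dtype=bool), "test")
    results = results.sort_values("odds_ratio", ascending=False,
                                  na_position="last", kind="stable")
    return results.reset_index(drop=True)


def run_screening(pairs: pd.DataFrame, matrix: ExposureMatrix,
                  split: SplitSpec = SplitSpec(), q: float = 0.05,
                  mcnemar_mode: str = "auto", z: float = 1.96) -> ScreeningReport:
    """End-to-end protocol: split, screen, confirm, report."""
    train, valid, test = split_pairs(pairs, split)
    stage1 = screen(train, matrix, q=q, mcnemar_mode=mcnemar_mode, z=z)
    if stage1.relevant:
        confirmed, stage2_results = confirm(stage1.relevant, valid, matrix,
                                            q=q, mcnemar_mode=mcnemar_mode, z=z)
    else:
        confirmed = frozenset()
        stage2_results = pd.DataFrame(columns=RESULT_COLUMNS)
    if confirmed:
        stage3 = report(confirmed, test, matrix, z=z)
    else:
        stage3 = pd.DataFrame(columns=RESULT_COLUMNS)
    provenance = {
        "split_seed": split.seed, "fractions": split.fractions, "q": q,
        "n_pairs": {"train": len(train), "validate": len(valid), "test": len(test)},
        "m": {"train": stage1.m, "validate": len(stage1.relevant)},
        "counts": {"significant": len(stage1.significant),
                   "relevant": len(stage1.relevant),
                   "confirmed": len(confirmed)},
    }
    return ScreeningReport(stage1=stage1, stage2_confirmed=confirmed,
                           stage2_results=stage2_results,
                           stage3_estimates=stage3, provenance=provenance)


def pairs_and_matrix_from_cohort(cohort: MatchedCohort
                                 ) -> tuple[pd.DataFrame, ExposureMatrix]:
    """Adapt a simulated cohort to the pairs + exposure-matrix interface."""
    n = cohort.n_pairs
    case_ids = [f"case{i:05d}" for i in range(n)]
    ctrl_ids = [f"ctrl{i:05d}" for i in range(n)]
    data = pd.DataFrame(
        np.vstack([cohort.case_exposures, cohort.control_exposures]),
        index=pd.Index(case_ids + ctrl_ids, name="patient_id"),
        columns=list(cohort.codes), dtype=np.uint8)
    pairs = pd.DataFrame({"case_id": case_ids, "control_id": ctrl_ids})
    return pairs, ExposureMatrix(data)
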