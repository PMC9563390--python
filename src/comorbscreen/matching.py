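"""1:1 case-control matching: exact strata plus an age caliper.

Cases and controls are matched without replacement, exactly on the
categorical variables (default sex, income quintile, rurality) and
within a caliper on age (default 2 years, inclusive).  Within each
exact stratum the default algorithm is greedy nearest-age: cases are
visited in a seeded random order and each takes the unused control with
the smallest age gap inside the caliper, ties broken by lowest control
id.  An optimal assignment variant (minimum total age gap via the
Hungarian algorithm) is available with ``method="optimal"``.

Unmatched cases are reported, never silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["MatchSpec", "MatchResult", "match_pairs"]


@dataclass(frozen=True)
class MatchSpec:
    exact_vars: tuple[str, ...] = ("sex", "income_quintile", "rurality")
    caliper_var: str = "age_years"
    caliper_width: float = 2.0
    seed: int = 0
    method: str = "greedy"  # or "optimal"

    def __post_init__(self):
        if not self.exact_vars:
            raise ValueError("exact_vars must be non-empty")
        if self.caliper_width < 0:
            raise ValueError("caliper_width must be non-negative")
        if self.method not in ("greedy", "optimal"):
            raise ValueError(f"unknown matching method {self.method!r}")


@dataclass(frozen=True)
class MatchResult:
    """Matched pairs plus the cases that found no admissible control."""

    pairs: pd.DataFrame  # columns: case_id, control_id, age_gap + exact vars
    unmatched_cases: list = field(default_factory=list)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def match_rate(self) -> float:
        total = self.n_pairs + len(self.unmatched_cases)
        return self.n_pairs / total if total else float("nan")


def _greedy_stratum(cases: pd.DataFrame, controls: pd.DataFrame,
                    spec: MatchSpec, rng: np.random.Generator):
    """Greedy nearest-age matching inside one exact stratum."""
    order = rng.permutation(len(cases))
    # controls sorted by (age, id) so ties resolve to the lowest id
    ctrl = controls.sort_values([spec.caliper_var, "patient_id"],
                                kind="stable").reset_index(drop=True)
    used = np.zeros(len(ctrl), dtype=bool)
    ctrl_age = ctrl[spec.caliper_var].to_numpy(dtype=float)
    pairs, unmatched = [], []
    for i in order:
        case = cases.iloc[i]
        age = float(case[spec.caliper_var])
        gaps = np.abs(ctrl_age - age)
        gaps[used] = np.inf
        j = int(np.argmin(gaps))  # first minimum = smallest gap, lowest id
        if np.isfinite(gaps[j]) and gaps[j] <= spec.caliper_width:
            used[j] = True
            pairs.append((case["patient_id"], ctrl.loc[j, "patient_id"], float(gaps[j])))
        else:
            unmatched.append(case["patient_id"])
    return pairs, unmatched


def _optimal_stratum(cases: pd.DataFrame, controls: pd.DataFrame,
                     spec: MatchSpec, rng: np.random.Generator):
    """Minimum-total-age-gap assignment inside one stratum."""
    from scipy.optimize import linear_sum_assignment

    case_age = cases[spec.caliper_var].to_numpy(dtype=float)
    ctrl = controls.sort_values([spec.caliper_var, "patient_id"],
                                kind="stable").reset_index(drop=True)
    ctrl_age = ctrl[spec.caliper_var].to_numpy(dtype=float)
    cost = np.abs(case_age[:, None] - ctrl_age[None, :])
    # out-of-caliper pairs carry a prohibitive but finite cost so the
    # assignment stays feasible; such pairs are discarded afterwards
    big = spec.caliper_width + max(1.0, cost[np.isfinite(cost)].max() if cost.size else 1.0) * 10
    cost = np.where(cost <= spec.caliper_width, cost, big)
    rows, cols = linear_sum_assignment(cost)
    pairs, matched_cases = [], set()
    for r, c in zip(rows, cols):
        gap = abs(case_age[r] - ctrl_age[c])
        if gap <= spec.caliper_width:
            pairs.append((cases.iloc[r]["patient_id"], ctrl.loc[c, "patient_id"], float(gap)))
            matched_cases.add(cases.iloc[r]["patient_id"])
    unmatched = [pid for pid in cases["patient_id"] if pid not in matched_cases]
    return pairs, unmatched


def match_pairs(profiles: pd.DataFrame, spec: MatchSpec = MatchSpec()) -> MatchResult:
    """Match each case to at most one control under ``spec``.

    ``profiles`` needs columns ``patient_id``, ``cohort`` (values
    'case'/'control'), every exact variable, and the caliper variable.
    Deterministic given ``spec.seed``.
    """
    required = {"patient_id", "cohort", spec.caliper_var, *spec.exact_vars}
    missing = sorted(required - set(profiles.columns))
    if missing:
        raise ValueError(f"profiles missing matching variable(s): {missing}")
    cases = profiles[profiles["cohort"] == "case"]
    controls = profiles[profiles["cohort"] == "control"]
    if len(cases) == 0 or len(controls) == 0:
        raise ValueError("both cases and controls are required for matching")

    rng = np.random.default_rng(spec.seed)
    match_fn = _greedy_stratum if spec.method == "greedy" else _optimal_stratum
    exact = list(spec.exact_vars)
    all_pairs, all_unmatched = [], []
    # iterate strata in sorted key order for determinism
    case_strata = cases.groupby(exact, sort=True)
    control_groups = dict(iter(controls.groupby(exact, sort=True)))
    for key, cgroup in case_strata:
        ctrl_group = control_groups.get(key)
        if ctrl_group is None or len(ctrl_group) == 0:
            all_unmatched.extend(cgroup["patient_id"])
            continue
        pairs, unmatched = match_fn(cgroup.reset_index(drop=True),
                                    ctrl_group.reset_index(drop=True), spec, rng)
        key = key if isinstance(key, tuple) else (key,)
        all_pairs.extend((*p, *key) for p in pairs)
        all_unmatched.extend(unmatched)

    pairs_df = pd.DataFrame(all_pairs, columns=["case_id", "control_id", "age_gap", *exact])
    pairs_df = pairs_df.sort_values("case_id", kind="stable").reset_index(drop=True)
    return MatchResult(pairs=pairs_df, unmatched_cases=sorted(all_unmatched))
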