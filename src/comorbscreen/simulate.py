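"""Synthetic matched-pair cohorts with known ground truth.

The generator emulates the structure of a matched case-control
comorbidity screen: for each of ``m_codes`` code groups a control
exposure prevalence p0_j is drawn, a fraction ``pi1`` of codes carry a
planted conditional odds ratio psi_j (logit(p1_j) = logit(p0_j) +
ln psi_j), and within each pair the case and control exposures are
independent given the code parameters, so the discordant-pair ratio
E(n10)/E(n01) equals psi_j exactly.  Cross-code dependence — the reason
a Benjamini-Yekutieli adjustment is needed at all — is induced by a
latent Gaussian copula with block-diagonal equicorrelation (blocks of
``block_size``, off-diagonal ``rho``), thresholded at the marginal
quantiles, independently for the case and control sides.  A fraction of
the non-null codes can be made protective (psi < 1), mimicking the
collider-style inverse associations that care-seeking selection
produces in real administrative data.

An optional pair-level frailty (shared logit shift with standard
deviation ``frailty_sd``) breaks the within-pair independence to
stress-test robustness; it defaults off.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit

from .codes import enumerate_universe
from .multtest import harmonic_number

__all__ = [
    "SimulationDesign",
    "GroundTruth",
    "MatchedCohort",
    "simulate_cohort",
    "simulate_discordant_counts",
    "cohort_to_records",
    "synthetic_sample_table",
]


@dataclass(frozen=True)
class SimulationDesign:
    """Ground-truth parameters for one synthetic cohort.

    Defaults mirror the screening setting: the full 2,600-group grid,
    control prevalences of 0.5-5% per group (typical for three-character
    groups over a multi-year observation window), independent codes, and
    no protective codes unless requested.
    """

    n_pairs: int
    m_codes: int = 2600
    pi1: float = 0.0
    log_or: float | tuple[float, float] = np.log(2.0)
    prevalence_range: tuple[float, float] = (0.005, 0.05)
    block_size: int = 50
    rho: float = 0.0
    protective_fraction: float = 0.0
    frailty_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_pairs < 0 or self.m_codes < 1:
            raise ValueError("n_pairs must be >= 0 and m_codes >= 1")
        if not (0.0 <= self.pi1 < 1.0):
            raise ValueError("pi1 must be in [0, 1)")
        lo, hi = self.prevalence_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("prevalence_range must satisfy 0 < low <= high < 1")
        if not (0.0 <= self.rho < 1.0):
            raise ValueError("rho must be in [0, 1)")
        if self.block_size < 1:
            raise ValueError("block_size must be >= 1")
        if not (0.0 <= self.protective_fraction <= 1.0):
            raise ValueError("protective_fraction must be in [0, 1]")
        if self.frailty_sd < 0:
            raise ValueError("frailty_sd must be non-negative")


@dataclass(frozen=True)
class GroundTruth:
    """Per-code truth: conditional OR psi_j, with psi_j = 1 iff null."""

    codes: tuple[str, ...]
    psi: np.ndarray
    p0: np.ndarray

    @property
    def is_null(self) -> np.ndarray:
        return self.psi == 1.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"code_group": self.codes, "psi": self.psi,
                             "is_null": self.is_null.astype(int)})


@dataclass(frozen=True)
class MatchedCohort:
    """Aligned binary exposures for n matched pairs over m code groups."""

    codes: tuple[str, ...]
    case_exposures: np.ndarray  # (n_pairs, m) uint8
    control_exposures: np.ndarray

    @property
    def n_pairs(self) -> int:
        return self.case_exposures.shape[0]

    def discordant_counts(self) -> tuple[np.ndarray, np.ndarray]:
        """(n10, n01) per code: case-only and control-only exposed pairs."""
        case = self.case_exposures.astype(bool)
        ctrl = self.control_exposures.astype(bool)
        n10 = (case & ~ctrl).sum(axis=0)
        n01 = (~case & ctrl).sum(axis=0)
        return n10.astype(np.int64), n01.astype(np.int64)


def _pick_codes(design: SimulationDesign, rng: np.random.Generator) -> tuple[str, ...]:
    universe = enumerate_universe()
    if design.m_codes > len(universe):
        raise ValueError("m_codes exceeds the 2,600-group universe")
    if design.m_codes == len(universe):
        return tuple(universe)
    chosen = rng.choice(len(universe), size=design.m_codes, replace=False)
    return tuple(universe[i] for i in np.sort(chosen))


def _draw_truth(design: SimulationDesign, rng: np.random.Generator) -> GroundTruth:
    """Draw per-code prevalences and planted effects (shared by both paths)."""
    m = design.m_codes
    codes = _pick_codes(design, rng)
    lo, hi = design.prevalence_range
    p0 = rng.uniform(lo, hi, size=m)
    n_nonnull = int(round(design.pi1 * m))
    log_psi = np.zeros(m)
    if n_nonnull:
        which = rng.choice(m, size=n_nonnull, replace=False)
        if isinstance(design.log_or, tuple):
            mag = rng.uniform(design.log_or[0], design.log_or[1], size=n_nonnull)
        else:
            mag = np.full(n_nonnull, float(design.log_or))
        mag = np.abs(mag)
        n_prot = int(round(design.protective_fraction * n_nonnull))
        sign = np.ones(n_nonnull)
        if n_prot:
            sign[rng.choice(n_nonnull, size=n_prot, replace=False)] = -1.0
        log_psi[which] = sign * mag
    return GroundTruth(codes=codes, psi=np.exp(log_psi), p0=p0)


def _latent_normals(n: int, m: int, block_size: int, rho: float,
                    rng: np.random.Generator) -> np.ndarray:
    """(n, m) standard normals with block-equicorrelation.

    One-factor representation per block: z = sqrt(rho)*u_block +
    sqrt(1-rho)*eps has unit variance and pairwise latent correlation
    rho within a block, 0 across blocks.  Thresholding z at the normal
    quantile of a marginal probability yields correlated Bernoullis
    with exact marginals (Gaussian copula).
    """
    eps = rng.standard_normal((n, m))
    if rho == 0.0:
        return eps
    n_blocks = -(-m // block_size)
    u = rng.standard_normal((n, n_blocks))
    block_of = np.minimum(np.arange(m) // block_size, n_blocks - 1)
    return np.sqrt(rho) * u[:, block_of] + np.sqrt(1.0 - rho) * eps


def simulate_cohort(design: SimulationDesign) -> tuple[MatchedCohort, GroundTruth]:
    """Draw a full matched cohort of binary exposures plus its truth.

    Control exposure ~ Bernoulli(p0_j); case exposure ~ Bernoulli(p1_j)
    with logit(p1_j) = logit(p0_j) + ln(psi_j).  Exposure j is 1 when the
    code's latent normal falls below the quantile of its marginal
    probability, so the marginals are exact while cross-code dependence
    follows the latent block correlation.  Fully reproducible from
    ``design.seed``.
    """
    rng = np.random.default_rng(design.seed)
    truth = _draw_truth(design, rng)
    n, m = design.n_pairs, design.m_codes
    p0 = truth.p0
    p1 = expit(logit(p0) + np.log(truth.psi))

    z_case = _latent_normals(n, m, design.block_size, design.rho, rng)
    z_ctrl = _latent_normals(n, m, design.block_size, design.rho, rng)
    if design.frailty_sd > 0:
        delta = rng.normal(0.0, design.frailty_sd, size=(n, 1))
        case_cut = stats.norm.ppf(expit(logit(p1)[None, :] + delta))
        ctrl_cut = stats.norm.ppf(expit(logit(p0)[None, :] + delta))
    else:
        case_cut = stats.norm.ppf(p1)
        ctrl_cut = stats.norm.ppf(p0)
    cohort = MatchedCohort(
        codes=truth.codes,
        case_exposures=(z_case < case_cut).astype(np.uint8),
        control_exposures=(z_ctrl < ctrl_cut).astype(np.uint8),
    )
    return cohort, truth


def simulate_discordant_counts(design: SimulationDesign) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Fast path: per-code (n10, n01) without materialising exposures.

    Valid only for independent codes (rho = 0) with no frailty.  Each
    pair is discordant with probability p1(1-p0) + p0(1-p1) and, given
    discordance, is case-only exposed with probability
    p1(1-p0) / (p1(1-p0) + p0(1-p1)) — distributionally identical to
    the full path at rho = 0.
    """
    if design.rho != 0.0:
        raise ValueError("independence shortcut requires rho = 0")
    if design.frailty_sd != 0.0:
        raise ValueError("independence shortcut requires frailty_sd = 0")
    rng = np.random.default_rng(design.seed)
    truth = _draw_truth(design, rng)
    p0 = truth.p0
    p1 = expit(logit(p0) + np.log(truth.psi))
    pr_case_only = p1 * (1.0 - p0)
    pr_ctrl_only = p0 * (1.0 - p1)
    pr_disc = pr_case_only + pr_ctrl_only
    n_disc = rng.binomial(design.n_pairs, pr_disc)
    n10 = rng.binomial(n_disc, pr_case_only / pr_disc)
    n01 = n_disc - n10
    return n10.astype(np.int64), n01.astype(np.int64), truth


def cohort_to_records(cohort: MatchedCohort, seed: int = 0,
                      index_date: str = "2015-06-15",
                      window_days: tuple[int, int] = (45, 1700),
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Materialise a cohort as profile and visit tables.

    Synthesises the delimited-text dialect the exposure builder
    consumes: one profile row per patient (pair members share matching
    demographics, ages within the 2-year caliper) and one qualifying
    visit per positive exposure, dated uniformly inside
    ``window_days`` before the index date.  The code recorded on each
    visit is the group plus a random decimal suffix, exercising
    truncation.
    """
    rng = np.random.default_rng(seed)
    n, m = cohort.case_exposures.shape
    codes = np.array(cohort.codes)
    idx = pd.Timestamp(index_date)

    profiles = []
    visits = []
    sexes = rng.choice(["F", "M"], size=n)
    quintiles = rng.integers(1, 6, size=n)
    rural = rng.choice(["rural", "urban"], size=n, p=[0.2, 0.8])
    ages = rng.uniform(18, 90, size=n)
    for i in range(n):
        for role, pid, expo in (("case", f"case{i:05d}", cohort.case_exposures[i]),
                                ("control", f"ctrl{i:05d}", cohort.control_exposures[i])):
            age = ages[i] if role == "case" else ages[i] + rng.uniform(-2, 2)
            profiles.append((pid, role, sexes[i], round(max(age, 18.0), 1),
                             int(quintiles[i]), rural[i], index_date))
            pos = np.where(expo)[0]
            if pos.size:
                days = rng.integers(window_days[0], window_days[1], size=pos.size)
                for j, d in zip(pos, days):
                    date = (idx - pd.Timedelta(days=int(d))).strftime("%Y-%m-%d")
                    suffix = rng.integers(0, 10)
                    visits.append((pid, date, f"{codes[j]}.{suffix}",
                                   rng.choice(["ED", "acute"])))
    profiles_df = pd.DataFrame(profiles, columns=[
        "patient_id", "cohort", "sex", "age_years", "income_quintile",
        "rurality", "index_date"])
    visits_df = pd.DataFrame(visits, columns=["patient_id", "visit_date",
                                              "icd10_code", "setting"])
    return profiles_df, visits_df


def synthetic_sample_table(seed: int = 0, n_codes: int = 1239,
                           n_significant: int = 781, n_relevant: int = 781 - 95,
                           q: float = 0.05) -> pd.DataFrame:
    """SYNTHETIC stand-in for an illustrative per-code results table.

    Constructs a p-value/OR table with known ground truth: exactly
    ``n_significant`` of ``n_codes`` p-values fall at or below their
    Benjamini-Yekutieli step-up thresholds at level ``q``, and exactly
    ``n_relevant`` of those carry OR > 1 (the remainder are protective,
    OR < 1).  The defaults plant the 1,239 / 781 / 686 structure of the
    published walkthrough so the step-up implementation can be checked
    against a table whose answer is known by construction.  Statistics
    and Wald-style CIs are filled in for format fidelity; this is not
    real data.
    """
    if not (0 < n_relevant <= n_significant <= n_codes):
        raise ValueError("need 0 < n_relevant <= n_significant <= n_codes")
    rng = np.random.default_rng(seed)
    m = n_codes
    cm = harmonic_number(m)
    ranks = np.arange(1, m + 1)
    thresh = ranks * q / (m * cm)
    p = np.empty(m)
    # significant ranks sit safely below their step-up thresholds,
    # the rest safely above every threshold (max threshold < 0.007)
    p[:n_significant] = 0.6 * thresh[:n_significant]
    rest = np.arange(m - n_significant)
    p[n_significant:] = 0.02 + 0.97 * rest / max(len(rest) - 1, 1)

    odds = np.empty(m)
    odds[:n_relevant] = np.exp(rng.uniform(np.log(1.2), np.log(60.0), size=n_relevant))
    odds[n_relevant:n_significant] = rng.uniform(0.05, 0.9,
                                                 size=n_significant - n_relevant)
    odds[n_significant:] = np.exp(rng.normal(0.0, 0.3, size=m - n_significant))

    log_or = np.abs(np.log(np.where(odds == 1.0, 1.01, odds)))
    se = np.empty(m)
    se[:n_significant] = log_or[:n_significant] / (1.96 + rng.uniform(0.5, 3.0, n_significant))
    se[n_significant:] = log_or[n_significant:] / rng.uniform(0.2, 1.5, m - n_significant)
    lcl = np.exp(np.log(odds) - 1.96 * se)
    ucl = np.exp(np.log(odds) + 1.96 * se)
    stat = stats.chi2.isf(np.clip(p, 1e-300, 1.0), df=1)

    universe = enumerate_universe()
    codes = [universe[i] for i in np.sort(rng.choice(len(universe), size=m, replace=False))]
    order = rng.permutation(m)
    return pd.DataFrame({
        "code_group": np.array(codes),
        "mcnemar_stat": stat[order],
        "p_value": p[order],
        "odds_ratio": odds[order],
        "ci_lower": lcl[order],
        "ci_upper": ucl[order],
    })
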