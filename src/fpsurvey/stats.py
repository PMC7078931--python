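"""Scenario-level statistics: false-positive rates, binomial standard
errors, and the saturated two-factor logistic regression on the
(experience x method) design, reported on the odds-ratio scale.

The design is saturated (two binary factors, four cells), so the maximum-
likelihood logistic fit is available in closed form from the cell odds:

* intercept: odds of a false positive in the reference cell, a/(N-a);
* main effects: odds ratio of the corresponding cell vs the reference;
* interaction: ratio of odds ratios (the 2x2x2 cross-product ratio);
* standard errors: exp(sqrt(sum 1/k)) over the 2, 4 or 8 cell components
  (FP and correct counts) entering each term — the delta-method Wald SE of
  the log odds (ratio), exponentiated.

An iteratively fitted binomial GLM necessarily agrees; the test suite checks
the closed form against statsmodels to 1e-6 relative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps


@dataclass(frozen=True)
class ScenarioCounts:
    """Aggregated detection and false-positive counts for one survey arm."""

    experience: str
    method: str
    n_surveys: int
    n_detections: int
    n_fp: int

    def __post_init__(self) -> None:
        if not (0 <= self.n_fp <= self.n_detections):
            raise ValueError("need 0 <= n_fp <= n_detections")

    @property
    def n_correct(self) -> int:
        return self.n_detections - self.n_fp


@dataclass(frozen=True)
class RateEstimate:
    rate: float
    se: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.rate <= 1.0) or self.se < 0:
            raise ValueError("invalid rate/se")


def fp_rate(n_fp: int, n_detections: int) -> RateEstimate:
    """False-positive rate n_fp / n_detections with its binomial SE.

    se = sqrt(rate * (1 - rate) / n_detections). This is the "SD" printed
    alongside scenario rates in removal-design survey summaries.
    """
    if n_detections <= 0:
        raise ValueError("rate undefined for zero detections")
    r = n_fp / n_detections
    return RateEstimate(rate=r, se=math.sqrt(r * (1.0 - r) / n_detections))


def rate_from_counts(counts: ScenarioCounts) -> RateEstimate:
    return fp_rate(counts.n_fp, counts.n_detections)


@dataclass(frozen=True)
class TermEstimate:
    """One regression term on the odds (intercept) or odds-ratio scale."""

    estimate: float
    exp_se: float
    ci_low: float
    ci_high: float
    p_value: float

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.estimate <= self.ci_high):
            raise ValueError("CI must bracket the estimate")


@dataclass(frozen=True)
class LogitResult:
    intercept: TermEstimate
    experience: TermEstimate  # non-reference experience level main effect
    method: TermEstimate  # non-reference method main effect
    interaction: TermEstimate
    reference: tuple[str, str]
    levels: tuple[str, str]  # (non-ref experience, non-ref method)

    def terms(self) -> dict[str, TermEstimate]:
        return {
            "intercept": self.intercept,
            self.levels[0]: self.experience,
            self.levels[1]: self.method,
            f"{self.levels[0]} x {self.levels[1]}": self.interaction,
        }


def _wald_term(log_est: float, cells: Sequence[int], z: float = 1.96) -> TermEstimate:
    if any(k <= 0 for k in cells):
        raise ValueError(
            "zero cell count: the saturated fit is undefined; aggregate further "
            "or apply an explicit continuity correction (not done silently)"
        )
    se_log = math.sqrt(sum(1.0 / k for k in cells))
    est = math.exp(log_est)
    zstat = log_est / se_log
    return TermEstimate(
        estimate=est,
        exp_se=math.exp(se_log),
        ci_low=est * math.exp(-z * se_log),
        ci_high=est * math.exp(z * se_log),
        p_value=2.0 * sps.norm.sf(abs(zstat)),
    )


def fit_saturated_logit(
    cells: Sequence[ScenarioCounts],
    reference: tuple[str, str] = ("expert", "DDO"),
    ci_method: str = "wald",
) -> LogitResult:
    """Closed-form saturated logistic regression of FP status on
    experience x method, reported on the odds(-ratio) scale.

    ``cells`` must contain exactly the four (experience x method)
    combinations with strictly positive FP and correct counts.
    ``ci_method`` is "wald" (default) or "profile" (likelihood-ratio CIs,
    found numerically; slightly wider than Wald for these counts).
    """
    by_key = {(c.experience, c.method): c for c in cells}
    if len(by_key) != 4 or len(cells) != 4:
        raise ValueError("need exactly four distinct (experience, method) cells")
    e0, m0 = reference
    exps = sorted({c.experience for c in cells} - {e0})
    mets = sorted({c.method for c in cells} - {m0})
    if len(exps) != 1 or len(mets) != 1 or (e0, m0) not in by_key:
        raise ValueError("cells must form a 2x2 design containing the reference")
    e1, m1 = exps[0], mets[0]

    def odds(key):
        c = by_key[key]
        if c.n_fp <= 0 or c.n_correct <= 0:
            raise ValueError(
                f"zero cell in {key}: saturated fit undefined; refuse rather than "
                "silently applying a continuity correction"
            )
        return c.n_fp / c.n_correct

    o00, o01 = odds((e0, m0)), odds((e0, m1))
    o10, o11 = odds((e1, m0)), odds((e1, m1))
    c00, c01 = by_key[(e0, m0)], by_key[(e0, m1)]
    c10, c11 = by_key[(e1, m0)], by_key[(e1, m1)]

    def parts(*cs):
        out = []
        for c in cs:
            out.extend([c.n_fp, c.n_correct])
        return out

    result = LogitResult(
        intercept=_wald_term(math.log(o00), parts(c00)),
        experience=_wald_term(math.log(o10 / o00), parts(c10, c00)),
        method=_wald_term(math.log(o01 / o00), parts(c01, c00)),
        interaction=_wald_term(
            math.log((o11 * o00) / (o10 * o01)), parts(c00, c01, c10, c11)
        ),
        reference=(e0, m0),
        levels=(e1, m1),
    )
    if ci_method == "wald":
        return result
    if ci_method == "profile":
        return _with_profile_cis(result, (c00, c01, c10, c11))
    raise ValueError(f"unknown ci_method {ci_method!r}")


def _loglik(beta: np.ndarray, X: np.ndarray, fp: np.ndarray, n: np.ndarray) -> float:
    eta = X @ beta
    return float(fp @ eta - n @ np.log1p(np.exp(eta)))


def _with_profile_cis(result: LogitResult, cells4) -> LogitResult:
    """Replace Wald CIs with profile-likelihood CIs (estimates unchanged).

    For each coefficient, the CI endpoints solve
    2*(llmax - profile_ll(beta_j)) = chi2_{1,0.95}; the three remaining
    coefficients are re-maximized at each fixed beta_j. Because the design is
    saturated, the profile optimum is found with an unconstrained quasi-Newton
    solve on the 3 free coefficients.
    """
    c00, c01, c10, c11 = cells4
    X = np.array(
        [[1, 0, 0, 0], [1, 0, 1, 0], [1, 1, 0, 0], [1, 1, 1, 1]], dtype=float
    )
    fp = np.array([c.n_fp for c in (c00, c01, c10, c11)], dtype=float)
    n = np.array([c.n_detections for c in (c00, c01, c10, c11)], dtype=float)
    beta_hat = np.log(
        [
            result.intercept.estimate,
            result.experience.estimate,
            result.method.estimate,
            result.interaction.estimate,
        ]
    )
    llmax = _loglik(beta_hat, X, fp, n)
    crit = sps.chi2.ppf(0.95, df=1)

    def profile_ll(j: int, val: float) -> float:
        free = [k for k in range(4) if k != j]

        def negll(b_free):
            beta = np.empty(4)
            beta[j] = val
            beta[free] = b_free
            return -_loglik(beta, X, fp, n)

        res = optimize.minimize(negll, beta_hat[free], method="BFGS")
        return -res.fun

    def endpoint(j: int, direction: int) -> float:
        lo = beta_hat[j]
        step = direction * 0.25
        hi = lo + step
        while 2.0 * (llmax - profile_ll(j, hi)) < crit:
            hi += step
            if abs(hi - lo) > 50:  # pathological; give up on a finite bound
                return float(direction * np.inf)
        f = lambda v: 2.0 * (llmax - profile_ll(j, v)) - crit
        return optimize.brentq(f, min(lo, hi), max(lo, hi), xtol=1e-8)

    def reterm(term: TermEstimate, j: int) -> TermEstimate:
        lo = math.exp(endpoint(j, -1))
        hi = math.exp(endpoint(j, +1))
        return TermEstimate(term.estimate, term.exp_se, lo, hi, term.p_value)

    return LogitResult(
        intercept=reterm(result.intercept, 0),
        experience=reterm(result.experience, 1),
        method=reterm(result.method, 2),
        interaction=reterm(result.interaction, 3),
        reference=result.reference,
        levels=result.levels,
    )


def percent_reduction(rate_iso: float, rate_ddo: float, rounding: int | None = 3) -> float:
    """Percent reduction of the DDO rate relative to the ISO rate.

    Inputs are rounded to ``rounding`` decimals before the ratio (default 3,
    matching printed-precision arithmetic); pass None to skip rounding.
    """
    if rounding is not None:
        rate_iso = round(rate_iso, rounding)
        rate_ddo = round(rate_ddo, rounding)
    if rate_iso <= 0:
        raise ValueError("reduction undefined for zero ISO rate")
    return 100.0 * (rate_iso - rate_ddo) / rate_iso


def per_species_rates(counts: pd.DataFrame, z: float = 1.96) -> pd.DataFrame:
    """Per-species FP rate, binomial SE and normal-approximation 95% CI.

    ``counts`` needs columns n_fp and n_detections (any grouping index).
    Species with zero detections get NaN (undefined), not zero. CIs are
    truncated to [0, 1]; with zero observed FPs the approximate CI collapses
    to [0, 0] — a known limitation of the Wald interval near the boundary.
    """
    out = counts.copy()
    rate = np.where(out["n_detections"] > 0, out["n_fp"] / out["n_detections"], np.nan)
    se = np.sqrt(rate * (1 - rate) / out["n_detections"].where(out["n_detections"] > 0))
    out["rate"] = rate
    out["se"] = se
    out["ci_low"] = np.clip(rate - z * se, 0.0, 1.0)
    out["ci_high"] = np.clip(rate + z * se, 0.0, 1.0)
    return out


def scenario_table(scores_by_scenario: Mapping[tuple[str, str], Sequence]) -> list[ScenarioCounts]:
    """Collapse per-survey scores into ScenarioCounts rows.

    ``scores_by_scenario`` maps (experience, method) to that arm's
    SurveyScore list.
    """
    rows = []
    for (exp, met), scores in scores_by_scenario.items():
        rows.append(
            ScenarioCounts(
                experience=exp,
                method=met,
                n_surveys=len(scores),
                n_detections=sum(s.n_detections for s in scores),
                n_fp=sum(s.n_fp for s in scores),
            )
        )
    return rows
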