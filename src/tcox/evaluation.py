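"""Survival-model evaluation protocol.

A model arm is assessed by repeated random 70/30 splits that preserve the
censoring proportion in both parts, fitting on the training part, splitting
the test part at the median fitted relative risk, and comparing the two risk
groups' Kaplan-Meier curves with the two-group log-rank test. Each run ends
in one of three outcomes: S (test log-rank p < 0.05), NS (not significant),
or NA (the model could not be estimated: empty support, degenerate risks, or
a fitting/cross-validation failure). Counts and mean p-values per outcome
class are aggregated across runs, together with per-gene selection
frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .comparators import DegreeWeights
from .data import SurvivalDataset
from .model import WeightedCoxnet
from .weights import PenaltyWeights

__all__ = [
    "KaplanMeierCurve",
    "LogRankResult",
    "RunRecord",
    "RunSummary",
    "stratified_split",
    "km_estimate",
    "logrank_test",
    "median_risk_groups",
    "run_experiment",
]

SIGNIFICANCE_LEVEL = 0.05


@dataclass
class KaplanMeierCurve:
    """Product-limit survival estimate evaluated at the distinct event times."""

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray

    def survival_at(self, t: float) -> float:
        """Step-function value S(t); S = 1 before the first event."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.event_times,
                "survival": self.survival,
                "at_risk": self.at_risk,
                "events": self.events,
            }
        )


class LogRankResult(NamedTuple):
    statistic: float
    pvalue: float


def stratified_split(
    data: SurvivalDataset, train_frac: float = 0.7, seed: int = 0
) -> tuple[SurvivalDataset, SurvivalDataset]:
    """Random train/test partition preserving the censoring proportion.

    Censored and uncensored samples are each split at ``train_frac`` with
    rounding to nearest (exact halves round toward train), so e.g. 100
    samples with 40 censored at 0.7 give a 70-sample train part containing
    exactly 28 censored samples. Deterministic for a fixed seed.
    """
    if not 0.0 < train_frac < 1.0:
        raise ValueError("train_frac must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for value in (0, 1):
        stratum = np.flatnonzero(data.status == value)
        if len(stratum) == 0:
            raise ValueError("both censored and uncensored samples must be present")
        n_train = int(np.floor(len(stratum) * train_frac + 0.5))
        if n_train == 0 or n_train == len(stratum):
            raise ValueError(
                f"stratum with {len(stratum)} samples too small to appear on both sides"
            )
        perm = rng.permutation(stratum)
        train_idx.extend(perm[:n_train])
        test_idx.extend(perm[n_train:])
    return data.subset(np.sort(train_idx)), data.subset(np.sort(test_idx))


def km_estimate(time: np.ndarray, status: np.ndarray) -> KaplanMeierCurve:
    """Kaplan-Meier product-limit estimator S(t) = prod_{t_k <= t} (1 - d_k/n_k).

    Censored times contribute to the at-risk counts n_k but never to the
    event counts d_k. Requires at least one observed event.
    """
    time = np.asarray(time, dtype=float)
    status = np.asarray(status, dtype=int)
    if np.any(time <= 0):
        raise ValueError("times must be positive")
    if status.sum() == 0:
        raise ValueError("no events observed")
    event_times = np.unique(time[status == 1])
    n_at_risk = np.array([(time >= t).sum() for t in event_times], dtype=float)
    d_events = np.array(
        [((time == t) & (status == 1)).sum() for t in event_times], dtype=float
    )
    survival = np.cumprod(1.0 - d_events / n_at_risk)
    return KaplanMeierCurve(event_times, survival, n_at_risk.astype(int), d_events.astype(int))


def logrank_test(
    time: np.ndarray, status: np.ndarray, group: np.ndarray
) -> LogRankResult:
    """Classic two-group log-rank test.

    At each distinct event time the observed group-1 events are compared with
    the hypergeometric expectation given the at-risk counts; the statistic
    (sum of O1-E1)^2 / (sum of hypergeometric variances) is referred to the
    chi-square distribution with 1 degree of freedom (two-sided). Symmetric
    in the group labelling.
    """
    time = np.asarray(time, dtype=float)
    status = np.asarray(status, dtype=int)
    group = np.asarray(group).astype(bool)
    if group.all() or (~group).all():
        raise ValueError("both groups must be non-empty")
    if status.sum() == 0:
        raise ValueError("no events observed")
    event_times = np.unique(time[status == 1])
    o_minus_e = 0.0
    var = 0.0
    for t in event_times:
        at_risk = time >= t
        n_k = float(at_risk.sum())
        n1_k = float((at_risk & group).sum())
        events_now = (time == t) & (status == 1)
        d_k = float(events_now.sum())
        d1_k = float((events_now & group).sum())
        o_minus_e += d1_k - d_k * n1_k / n_k
        if n_k > 1:
            var += d_k * (n1_k / n_k) * (1.0 - n1_k / n_k) * (n_k - d_k) / (n_k - 1.0)
    if var == 0.0:
        return LogRankResult(0.0, 1.0)
    statistic = o_minus_e**2 / var
    return LogRankResult(float(statistic), float(stats.chi2.sf(statistic, df=1)))


def median_risk_groups(risks: np.ndarray) -> np.ndarray:
    """Dichotomize samples at the median fitted relative risk.

    High-risk label where risk > median; ties at the median go to the
    low-risk group (a fixed convention for reproducibility). Constant risks,
    or a tie pattern emptying one group, signal a degenerate model.
    """
    risks = np.asarray(risks, dtype=float)
    if len(risks) < 2:
        raise ValueError("need at least 2 samples")
    if np.all(risks == risks[0]):
        raise ValueError("constant relative risks: degenerate model")
    high = risks > np.median(risks)
    if high.all() or (~high).all():
        raise ValueError("median dichotomization left one group empty")
    return high


@dataclass
class RunRecord:
    """Outcome of one split/fit/test repetition."""

    seed: int
    outcome: str  # "S", "NS" or "NA"
    train_p: float
    test_p: float
    selected_genes: list[str]
    n_selected: int
    reason: str = ""


@dataclass
class RunSummary:
    """Aggregate of repeated evaluation runs for one model arm."""

    arm: str
    records: list[RunRecord]
    gene_ids: list[str] = field(default_factory=list)

    @property
    def n_runs(self) -> int:
        return len(self.records)

    def counts(self) -> dict[str, int]:
        c = {"NA": 0, "S": 0, "NS": 0}
        for r in self.records:
            c[r.outcome] += 1
        return c

    def mean_p(self, outcome: str) -> float:
        """Mean test p-value within one outcome class (NaN if the class is empty)."""
        ps = [r.test_p for r in self.records if r.outcome == outcome]
        return float(np.mean(ps)) if ps else float("nan")

    def selection_frequencies(self) -> pd.Series:
        """Fraction of runs in which each gene was selected (estimated runs only)."""
        est = [r for r in self.records if r.outcome != "NA"]
        counts = pd.Series(0.0, index=pd.Index(self.gene_ids, name="gene_id"))
        for r in est:
            counts[r.selected_genes] += 1.0
        return counts / max(len(est), 1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "seed": [r.seed for r in self.records],
                "outcome": [r.outcome for r in self.records],
                "train_p": [r.train_p for r in self.records],
                "test_p": [r.test_p for r in self.records],
                "n_selected": [r.n_selected for r in self.records],
            }
        )

    def aggregate_row(self) -> dict[str, float]:
        c = self.counts()
        return {
            "arm": self.arm,
            "NA": c["NA"],
            "S": c["S"],
            "NS": c["NS"],
            "mean_p_S": self.mean_p("S"),
            "mean_p_NS": self.mean_p("NS"),
        }


def _extract_factors(
    weights: PenaltyWeights | DegreeWeights | np.ndarray | None, p: int
) -> tuple[np.ndarray | None, np.ndarray | None]:
    if weights is None:
        return None, None
    if isinstance(weights, PenaltyWeights):
        return weights.factors, weights.excluded
    if isinstance(weights, DegreeWeights):
        return weights.factors, None
    return np.asarray(weights, dtype=float), None


def run_experiment(
    data: SurvivalDataset,
    weights: PenaltyWeights | DegreeWeights | np.ndarray | None = None,
    alpha: float = 0.1,
    n_runs: int = 100,
    seed: int = 0,
    train_frac: float = 0.7,
    folds: int = 5,
    n_lambdas: int = 100,
    penalty_mode: str = "literal",
    arm: str = "model",
) -> RunSummary:
    """Repeated split/fit/evaluate protocol for one model arm.

    Per run: a fresh censoring-stratified split, a weighted elastic-net Cox
    fit on the training part with cross-validated lambda selection, median
    dichotomization of the test-set relative risks, and a log-rank test
    between the two risk groups (the training part is tested the same way
    for reference). Failures inside a run are recorded as NA and never abort
    the batch. Fully reproducible for a fixed master seed; per-run seeds are
    derived from it and never shared between runs.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    factors, excluded = _extract_factors(weights, data.n_genes)
    run_seeds = np.random.SeedSequence(seed).generate_state(2 * n_runs) % (2**31)
    records: list[RunRecord] = []
    for r in range(n_runs):
        split_seed = int(run_seeds[2 * r])
        cv_seed = int(run_seeds[2 * r + 1])
        try:
            train, test = stratified_split(data, train_frac, split_seed)
            model = WeightedCoxnet(
                train,
                alpha=alpha,
                penalty_factors=factors,
                excluded=excluded,
                penalty_mode=penalty_mode,
            )
            res = model.fit(n_lambdas=n_lambdas, cv_folds=folds, seed=cv_seed)
            beta = res.coef()
            if not np.all(np.isfinite(beta)):
                raise FloatingPointError("non-finite coefficients")
            selected = res.support_genes()
            if len(selected) == 0:
                raise ValueError("empty support")
            groups_test = median_risk_groups(res.predict_relative_risk(test.X))
            test_p = logrank_test(test.time, test.status, groups_test).pvalue
            try:
                groups_train = median_risk_groups(res.predict_relative_risk(train.X))
                train_p = logrank_test(train.time, train.status, groups_train).pvalue
            except ValueError:
                train_p = float("nan")
            outcome = "S" if test_p < SIGNIFICANCE_LEVEL else "NS"
            records.append(
                RunRecord(split_seed, outcome, train_p, test_p, selected, len(selected))
            )
        except (ValueError, RuntimeError, FloatingPointError) as exc:
            records.append(
                RunRecord(split_seed, "NA", float("nan"), float("nan"), [], 0, str(exc))
            )
    return RunSummary(arm, records, list(data.gene_ids))
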