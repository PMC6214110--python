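"""Validation battery for quantitative pharmacophore models.

Covers the standard checks applied to a fit-value QSAR model: four-bin
activity scales at 1/8/18 μM, signed max/min error ratios, log10-scale
regression statistics, the Fischer randomization (Y-scrambling) permutation
test, and leave-one-out regeneration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .hypothesis_engine import (
    CostReport,
    EngineConfig,
    Hypothesis,
    TrainingCompound,
    calibrate,
    compute_cost,
    estimate_activity,
    generate_hypotheses,
    map_to_hypothesis,
)

#: Activity scale bins (μM upper edges, half-open) and their labels:
#: IC50 < 1 most active (++++), 1 <= IC50 < 8 active (+++),
#: 8 <= IC50 < 18 moderately active (++), IC50 >= 18 inactive (+).
SCALE_EDGES = (1.0, 8.0, 18.0)
SCALE_LABELS = ("++++", "+++", "++", "+")


def classify_activity(ic50_uM: float) -> str:
    """Four-bin activity scale of a positive IC50 in μM."""
    if ic50_uM <= 0:
        raise ValueError("IC50 must be positive")
    for edge, label in zip(SCALE_EDGES, SCALE_LABELS):
        if ic50_uM < edge:
            return label
    return SCALE_LABELS[-1]


def error_value(exp_uM: float, est_uM: float) -> float:
    """Signed ratio between estimated and experimental activity.

    Magnitude is max/min (always >= 1); positive when the estimate is the
    larger of the two, negative otherwise; an exact tie returns +1.
    """
    if exp_uM <= 0 or est_uM <= 0:
        raise ValueError("activities must be positive")
    magnitude = max(exp_uM, est_uM) / min(exp_uM, est_uM)
    return magnitude if est_uM >= exp_uM else -magnitude


@dataclass
class ActivityRecord:
    """Experimental vs estimated activity of one compound."""

    compound_id: str
    exp_ic50: float  # μM
    est_ic50: float  # μM
    error: float = field(init=False)
    exp_scale: str = field(init=False)
    est_scale: str = field(init=False)

    def __post_init__(self) -> None:
        self.error = error_value(self.exp_ic50, self.est_ic50)
        self.exp_scale = classify_activity(self.exp_ic50)
        self.est_scale = classify_activity(self.est_ic50)


@dataclass
class RegressionStats:
    r: float  # Pearson correlation of log10 activities
    r2: float
    rmsd_log: float  # RMS of log10 residuals

    def __post_init__(self) -> None:
        if not -1.0 - 1e-9 <= self.r <= 1.0 + 1e-9:
            raise ValueError("correlation out of range")


def regression_stats(pairs) -> RegressionStats:
    """Log10-scale regression statistics of (experimental, estimated) pairs.

    All statistics are computed on log10(IC50/μM); at least 3 positive pairs
    are required.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 3 or arr.shape[1] != 2:
        raise ValueError("regression_stats needs >= 3 (exp, est) pairs")
    if (arr <= 0).any():
        raise ValueError("activities must be positive")
    x = np.log10(arr[:, 0])
    y = np.log10(arr[:, 1])
    r = float(stats.pearsonr(x, y).statistic)
    return RegressionStats(r=r, r2=r * r, rmsd_log=float(np.sqrt(np.mean((y - x) ** 2))))


def scale_agreement(records: list[ActivityRecord]) -> tuple[int, float]:
    """Mismatch count between experimental and estimated activity scales and
    the prediction rate in percent (1 decimal place)."""
    if not records:
        raise ValueError("scale_agreement needs at least one record")
    mismatches = sum(1 for rec in records if rec.exp_scale != rec.est_scale)
    rate = round(100.0 * (len(records) - mismatches) / len(records), 1)
    return mismatches, rate


@dataclass
class ValidationReport:
    records: list[ActivityRecord]
    mismatches: int
    prediction_rate: float  # %
    stats: RegressionStats

    @classmethod
    def from_pairs(cls, ids, exp, est) -> "ValidationReport":
        records = [ActivityRecord(str(i), e, s) for i, e, s in zip(ids, exp, est)]
        mm, rate = scale_agreement(records)
        return cls(records, mm, rate,
                   regression_stats(list(zip(exp, est))))


def evaluate_hypothesis(
    h: Hypothesis,
    compounds: list[TrainingCompound],
    cfg: EngineConfig | None = None,
) -> ValidationReport:
    """Map compounds onto a calibrated hypothesis and score the estimates."""
    cfg = cfg or EngineConfig()
    ids = [tc.compound_id for tc in compounds]
    exp = [tc.ic50 for tc in compounds]
    est = [
        estimate_activity(h, map_to_hypothesis(tc.clouds, h, cfg).fit)
        for tc in compounds
    ]
    return ValidationReport.from_pairs(ids, exp, est)


# -- Fischer randomization ---------------------------------------------------

def required_permutations(confidence: float) -> int:
    """Permuted runs needed for a given confidence level in percent:
    ceil(100 / (100 - confidence)) - 1 (95% -> 19, 98% -> 49)."""
    if not 0 < confidence < 100:
        raise ValueError("confidence must be in (0, 100)")
    return math.ceil(100.0 / (100.0 - confidence)) - 1


@dataclass
class FischerReport:
    confidence: float
    original_cost: float
    permuted_costs: list[float]  # best total cost per permuted run; inf = no model
    passed: bool  # no permuted run undercut the original


def fischer_randomization(
    training: list[TrainingCompound],
    cfg: EngineConfig | None = None,
    confidence: float = 95.0,
) -> FischerReport:
    """Y-scrambling: regenerate hypotheses on activity-permuted training sets.

    Runs ``required_permutations(confidence)`` full generations, each on a
    seeded non-identity shuffle of the activities, with the same engine
    configuration as the original model.  A permuted run that produces no
    hypothesis at all reports an infinite cost.  The test passes when no
    permuted run achieves a lower best total cost than the original.
    """
    cfg = cfg or EngineConfig()
    n_runs = required_permutations(confidence)
    original = generate_hypotheses(training, cfg)
    if not original:
        raise ValueError("original training set yields no hypothesis")
    original_cost = original[0][1].total_cost

    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 0xF15C)))
    acts = np.array([tc.ic50 for tc in training])
    permuted_costs: list[float] = []
    for run in range(n_runs):
        perm = rng.permutation(len(acts))
        while np.all(perm == np.arange(len(acts))):  # identity would duplicate
            perm = rng.permutation(len(acts))
        shuffled = [
            TrainingCompound(tc.compound_id, tc.clouds, float(acts[perm[i]]))
            for i, tc in enumerate(training)
        ]
        run_cfg = replace(cfg, seed=int((cfg.seed + 7919 * (run + 1)) % 2**31))
        ranked = generate_hypotheses(shuffled, run_cfg)
        permuted_costs.append(ranked[0][1].total_cost if ranked else math.inf)
    passed = all(c >= original_cost for c in permuted_costs)
    return FischerReport(confidence, original_cost, permuted_costs, passed)


# -- leave-one-out -----------------------------------------------------------

@dataclass
class LooReport:
    r_full: float
    fold_rs: list[float]  # top-model training correlation per fold
    rmsd_r: float  # sqrt(mean (r_full - r_fold)^2)


def loo_validation(
    training: list[TrainingCompound], cfg: EngineConfig | None = None
) -> LooReport:
    """Leave-one-out regeneration: n full generations, each dropping one
    compound, summarised by the RMS deviation of the per-fold correlation
    from the full-model correlation."""
    cfg = cfg or EngineConfig()
    if len(training) < 4:
        raise ValueError("leave-one-out needs at least 4 compounds")
    full = generate_hypotheses(training, cfg)
    if not full:
        raise ValueError("training set yields no hypothesis")
    r_full = full[0][1].r

    fold_rs: list[float] = []
    for i in range(len(training)):
        fold = training[:i] + training[i + 1:]
        ranked = generate_hypotheses(fold, cfg)
        fold_rs.append(ranked[0][1].r if ranked else 0.0)
    rmsd_r = float(np.sqrt(np.mean((r_full - np.array(fold_rs)) ** 2)))
    return LooReport(r_full=r_full, fold_rs=fold_rs, rmsd_r=rmsd_r)
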