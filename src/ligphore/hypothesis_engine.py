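"""Quantitative pharmacophore hypotheses: generation, cost scoring, mapping.

A hypothesis is a set of 3-5 typed features (centroid, distance tolerance,
weight) plus a log-linear activity calibration.  A compound is scored by
searching, over its conformers, for the fit-maximizing assignment of typed
cloud features to hypothesis features (allowing a bounded number of omitted
features), with a least-squares rigid superposition of the matched points:

    fit = sum_f  w_f * max(0, 1 - (d_f / t_f)^2)

where d_f is the residual displacement of matched feature f.  Estimated
activity is IC50 = 10^(b0 - b1*fit).

Hypothesis generation follows the classic three-phase scheme: a constructive
phase enumerates feature subsets shared by the lead (most active) compounds,
a subtractive phase discards arrangements fully present in inactive
compounds, and an optimization phase anneals geometry/tolerances/weights
against a description-length cost in bits (error + weight + configuration
components, with null and fixed reference costs).
"""

from __future__ import annotations

import copy
import itertools
import json
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .feature_perception import FEATURE_TYPES, FeatureCloud

LN2 = math.log(2.0)


# -- rigid superposition -----------------------------------------------------

@dataclass
class Transform:
    """Proper rigid motion x -> R x + t."""

    rotation: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,)

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.rotation.T + self.translation

    @classmethod
    def identity(cls) -> "Transform":
        return cls(np.eye(3), np.zeros(3))


def superpose(a: np.ndarray, b: np.ndarray) -> tuple[Transform, float]:
    """Least-squares rigid superposition of point set ``a`` onto ``b``.

    Kabsch algorithm with the reflection corrected to a proper rotation.
    Fewer than 3 points degenerate to translation-only alignment (identity
    rotation), which keeps the problem well-posed.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3 or a.shape[0] < 1:
        raise ValueError("superpose requires two equally-sized (n, 3) arrays, n >= 1")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    if a.shape[0] < 3:
        t = Transform(np.eye(3), cb - ca)
    else:
        am, bm = a - ca, b - cb
        h = am.T @ bm
        u, _s, vt = np.linalg.svd(h)
        d = np.sign(np.linalg.det(vt.T @ u.T))
        r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
        t = Transform(r, cb - r @ ca)
    moved = t.apply(a)
    rmsd = float(np.sqrt(np.mean(np.sum((moved - b) ** 2, axis=1))))
    return t, rmsd


def _batch_align(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Align each point set in ``a`` (n, m, 3) onto targets ``b`` (n, m, 3).

    Returns (displacements (n, m), rmsd (n,)).  Batched Kabsch via stacked
    3x3 SVDs; m < 3 falls back to translation-only alignment.
    """
    n, m, _ = a.shape
    ca = a.mean(axis=1, keepdims=True)
    cb = b.mean(axis=1, keepdims=True)
    am, bm = a - ca, b - cb
    if m < 3:
        moved = am + cb
    else:
        h = np.einsum("nmi,nmj->nij", am, bm)
        u, _s, vt = np.linalg.svd(h)
        d = np.sign(np.linalg.det(vt.transpose(0, 2, 1) @ u.transpose(0, 2, 1)))
        diag = np.zeros((n, 3, 3))
        diag[:, 0, 0] = diag[:, 1, 1] = 1.0
        diag[:, 2, 2] = d
        r = vt.transpose(0, 2, 1) @ diag @ u.transpose(0, 2, 1)
        moved = np.einsum("nij,nmj->nmi", r, am) + cb
    disp = np.linalg.norm(moved - b, axis=2)
    rmsd = np.sqrt(np.mean(disp**2, axis=1))
    return disp, rmsd


# -- domain types ------------------------------------------------------------

@dataclass
class PharmacophoreFeature:
    ftype: str
    centroid: np.ndarray  # (3,), Å
    tolerance: float = 1.6  # Å
    weight: float = 2.0

    def __post_init__(self) -> None:
        if self.ftype not in FEATURE_TYPES:
            raise ValueError(f"unknown feature type {self.ftype!r}")
        self.centroid = np.asarray(self.centroid, dtype=float)
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.weight < 0:
            raise ValueError("weight must be non-negative")


@dataclass
class Hypothesis:
    """3-5 typed features plus the activity-regression coefficients.

    ``b0`` is the log10(IC50/μM) intercept, ``b1 >= 0`` the per-fit-unit
    slope; estimated IC50 = 10^(b0 - b1*fit).
    """

    features: list[PharmacophoreFeature]
    b0: float | None = None
    b1: float | None = None
    rank: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 3 <= len(self.features) <= 5:
            raise ValueError("a hypothesis has 3-5 features")
        if self.b1 is not None and self.b1 < -1e-12:
            raise ValueError("b1 must be non-negative")

    def centroids(self) -> np.ndarray:
        return np.array([f.centroid for f in self.features])

    def type_multiset(self) -> tuple[str, ...]:
        return tuple(sorted(f.ftype for f in self.features))

    def total_weight(self) -> float:
        return float(sum(f.weight for f in self.features))

    def min_interfeature_distance(self) -> float:
        c = self.centroids()
        d = np.linalg.norm(c[:, None] - c[None, :], axis=2)
        return float(d[np.triu_indices(len(c), 1)].min())

    def validate(self, min_distance: float) -> None:
        if self.min_interfeature_distance() < min_distance - 1e-9:
            raise ValueError(
                f"inter-feature distance below the {min_distance} Å minimum"
            )

    def to_json(self) -> str:
        return json.dumps(
            {
                "features": [
                    {
                        "type": f.ftype,
                        "xyz": f.centroid.tolist(),
                        "tolerance": f.tolerance,
                        "weight": f.weight,
                    }
                    for f in self.features
                ],
                "b0": self.b0,
                "b1": self.b1,
                "meta": {k: v for k, v in self.meta.items() if _json_safe(v)},
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "Hypothesis":
        d = json.loads(text)
        return cls(
            features=[
                PharmacophoreFeature(
                    f["type"], np.array(f["xyz"]), f["tolerance"], f["weight"]
                )
                for f in d["features"]
            ],
            b0=d.get("b0"),
            b1=d.get("b1"),
            meta=d.get("meta", {}),
        )


def _json_safe(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False


@dataclass
class MappingResult:
    """Best correspondence of one compound's clouds onto a hypothesis."""

    correspondence: list[tuple[int, int]]  # (hypothesis idx, cloud idx)
    omitted: list[int]
    transform: Transform | None
    displacements: np.ndarray  # Å, aligned with correspondence
    fit: float
    conformer_index: int
    rmsd: float

    @property
    def mapped(self) -> bool:
        return bool(self.correspondence)


@dataclass
class CostReport:
    """Description-length score of a hypothesis over a training set (bits)."""

    error_cost: float
    weight_cost: float
    config_cost: float
    total_cost: float
    null_cost: float
    fixed_cost: float
    rmsd_log: float  # log10 units
    r: float  # Pearson correlation of log10 activities

    @property
    def cost_difference(self) -> float:
        return self.null_cost - self.total_cost


def cost_difference(null_cost: float, other_cost: float) -> float:
    """Bits of evidence over the featureless null model."""
    return null_cost - other_cost


@dataclass
class AnnealSchedule:
    start_temp: float = 1.0
    cooling: float = 0.90
    steps: int = 40


@dataclass
class EngineConfig:
    """Knobs of the generation/scoring pipeline.

    ``uncertainty`` is the multiplicative activity-measurement uncertainty u
    (leads are compounds within u^2 of the activity minimum; the error model
    width is log10(u)); ``inactive_gap`` is the log10 gap above the minimum
    activity beyond which a compound counts as inactive in the subtractive
    phase.
    """

    uncertainty: float = 1.5
    min_interfeature_distance: float = 2.0  # Å
    max_omitted: int = 1
    inactive_gap: float = 3.5  # log10 units
    n_hypotheses: int = 10
    anneal: AnnealSchedule = field(default_factory=AnnealSchedule)
    seed: int = 20181017
    default_tolerance: float = 1.6  # Å
    default_weight: float = 2.0
    sigma_weight: float = 0.5  # width of the weight-cost prior
    config_cost_cap: float = 17.0  # bits
    max_lead_conformers: int = 3
    remap_every: int = 10  # full correspondence re-search cadence in annealing
    dedup_distance: float = 0.5  # Å, candidate distance-matrix dedup

    def __post_init__(self) -> None:
        if self.uncertainty <= 1:
            raise ValueError("uncertainty must exceed 1")
        if self.min_interfeature_distance <= 0:
            raise ValueError("min_interfeature_distance must be positive")
        if self.n_hypotheses < 1:
            raise ValueError("n_hypotheses must be >= 1")

    @property
    def sigma_log(self) -> float:
        return math.log10(self.uncertainty)


@dataclass
class TrainingCompound:
    """One compound's feature clouds (one per conformer) and its activity."""

    compound_id: str
    clouds: list[FeatureCloud]
    ic50: float  # μM

    def __post_init__(self) -> None:
        if self.ic50 <= 0:
            raise ValueError("IC50 must be positive")


# -- mapping -----------------------------------------------------------------

def _unmapped(k: int) -> MappingResult:
    return MappingResult(
        correspondence=[],
        omitted=list(range(k)),
        transform=None,
        displacements=np.zeros(0),
        fit=0.0,
        conformer_index=-1,
        rmsd=math.inf,
    )


def _subset_assignments(subset: tuple[int, ...], hyp_types: list[str],
                        cloud_idx_by_type: dict[str, list[int]]):
    """Injective type-compatible assignments for one hypothesis subset,
    yielded in lexicographic order as tuples of cloud indices."""
    per_type_slots: dict[str, list[int]] = {}
    for pos, hi in enumerate(subset):
        per_type_slots.setdefault(hyp_types[hi], []).append(pos)
    type_perms = []
    for t, slots in per_type_slots.items():
        cands = cloud_idx_by_type.get(t, [])
        if len(cands) < len(slots):
            return
        type_perms.append((slots, list(itertools.permutations(cands, len(slots)))))
    for combo in itertools.product(*(perms for _slots, perms in type_perms)):
        assign = [0] * len(subset)
        for (slots, _perms), perm in zip(type_perms, combo):
            for s, c in zip(slots, perm):
                assign[s] = c
        yield tuple(assign)


def _map_single_cloud(cloud: FeatureCloud, h: Hypothesis, cfg: EngineConfig,
                      max_omitted: int | None = None, prune: bool = False):
    """Best (fit, rmsd, correspondence, displacements) over all admissible
    correspondences for one cloud. Returns None if nothing is admissible.

    ``prune=True`` drops assignments whose pairwise distances rule out both
    endpoints landing inside their tolerances (|d_cloud - d_hyp| >
    t_i + t_j).  Such assignments carry at least one zero-contribution
    feature, so the pruned score is a tight lower bound used for candidate
    shortlisting; the exact search leaves ``prune`` off.
    """
    k = len(h.features)
    if max_omitted is None:
        max_omitted = cfg.max_omitted
    hyp_types = [f.ftype for f in h.features]
    centroids = h.centroids()
    tol = np.array([f.tolerance for f in h.features])
    wgt = np.array([f.weight for f in h.features])
    cloud_pos = cloud.positions()
    cloud_idx_by_type: dict[str, list[int]] = {}
    for i, f in enumerate(cloud.features):
        cloud_idx_by_type.setdefault(f.ftype, []).append(i)
    if prune:
        cdist = np.linalg.norm(cloud_pos[:, None] - cloud_pos[None, :], axis=2)
        hdist = np.linalg.norm(centroids[:, None] - centroids[None, :], axis=2)

    best = None  # key = (-fit, rmsd, correspondence tuple)
    m_low = max(1, k - max_omitted)
    for m in range(k, m_low - 1, -1):
        # all subsets of size m share one batched alignment call
        subsets, assigns = [], []
        for subset in itertools.combinations(range(k), m):
            for assign in _subset_assignments(subset, hyp_types, cloud_idx_by_type):
                if prune and any(
                    abs(cdist[assign[x], assign[y]] - hdist[subset[x], subset[y]])
                    > tol[subset[x]] + tol[subset[y]]
                    for x in range(m) for y in range(x + 1, m)
                ):
                    continue
                subsets.append(subset)
                assigns.append(assign)
        if not assigns:
            continue
        sub_idx = np.array(subsets)  # (n, m)
        idx = np.array(assigns)  # (n, m)
        a = cloud_pos[idx]  # (n, m, 3)
        b = centroids[sub_idx]  # (n, m, 3)
        disp, rmsd = _batch_align(a, b)
        contrib = wgt[sub_idx] * np.maximum(0.0, 1.0 - (disp / tol[sub_idx]) ** 2)
        fits = contrib.sum(axis=1)
        order = np.lexsort((rmsd, -fits))
        top = order[0]
        # resolve exact (fit, rmsd) ties lexicographically by correspondence
        ties = np.flatnonzero((fits == fits[top]) & (rmsd == rmsd[top]))
        if len(ties) > 1:
            top = min(ties, key=lambda j: tuple(zip(subsets[j], assigns[j])))
        corr = tuple(zip(subsets[top], assigns[top]))
        key = (-fits[top], rmsd[top], corr)
        if best is None or key < best[0]:
            best = (key, corr, disp[top])
    if best is None:
        return None
    (_negfit, rmsd, _corr), corr, disp = best
    return (-_negfit, rmsd, list(corr), disp)


def map_to_hypothesis(
    clouds: list[FeatureCloud],
    h: Hypothesis,
    cfg: EngineConfig | None = None,
    max_omitted: int | None = None,
    prune: bool = False,
) -> MappingResult:
    """Fit-maximizing mapping of one compound onto a hypothesis.

    Exhaustive over (conformer x type-compatible injective correspondence x
    allowed omissions); the matched cloud points are rigidly superposed onto
    the hypothesis centroids and the residual displacements d_f are scored by
    the fit formula.  Ties break toward lower superposition RMSD, then
    lexicographically smallest correspondence, then lowest conformer index.
    Returns an unmapped result (fit 0) when no admissible correspondence
    exists.
    """
    cfg = cfg or EngineConfig()
    k = len(h.features)
    best = None
    best_key = None
    for ci, cloud in enumerate(clouds):
        res = _map_single_cloud(cloud, h, cfg, max_omitted=max_omitted, prune=prune)
        if res is None:
            continue
        fit, rmsd, corr, disp = res
        key = (-fit, rmsd, tuple(corr), ci)
        if best_key is None or key < best_key:
            best_key = key
            best = (fit, rmsd, corr, disp, ci)
    if best is None:
        return _unmapped(k)
    fit, rmsd, corr, disp, ci = best
    matched_cloud = clouds[ci].positions()[[c for _h, c in corr]]
    matched_hyp = h.centroids()[[hh for hh, _c in corr]]
    transform, _ = superpose(matched_cloud, matched_hyp)
    omitted = sorted(set(range(k)) - {hh for hh, _c in corr})
    return MappingResult(
        correspondence=corr,
        omitted=omitted,
        transform=transform,
        displacements=np.asarray(disp, dtype=float),
        fit=float(fit),
        conformer_index=ci,
        rmsd=float(rmsd),
    )


def compute_fit(mr: MappingResult, h: Hypothesis) -> float:
    """fit = sum over matched f of w_f * max(0, 1 - (d_f/t_f)^2); omitted
    features contribute nothing."""
    fit = 0.0
    for (hi, _ci), d in zip(mr.correspondence, mr.displacements):
        f = h.features[hi]
        fit += f.weight * max(0.0, 1.0 - (d / f.tolerance) ** 2)
    return fit


def estimate_activity(h: Hypothesis, fit: float) -> float:
    """Estimated IC50 in μM: 10^(b0 - b1*fit)."""
    if h.b0 is None or h.b1 is None:
        raise ValueError("hypothesis has no activity calibration")
    return float(10.0 ** (h.b0 - h.b1 * fit))


def full_map(clouds: list[FeatureCloud], h: Hypothesis, cfg: EngineConfig) -> bool:
    """True when every hypothesis feature maps with displacement within its
    tolerance (no omissions) in at least one conformer."""
    return _exists_map(clouds, h, max_omitted=0)


def maps_within_tolerance(
    clouds: list[FeatureCloud], h: Hypothesis, cfg: EngineConfig
) -> bool:
    """True when the compound maps onto ``h`` with every *matched* feature
    inside its tolerance, allowing up to ``cfg.max_omitted`` omissions."""
    return _exists_map(clouds, h, max_omitted=cfg.max_omitted)


def _exists_map(clouds: list[FeatureCloud], h: Hypothesis, max_omitted: int) -> bool:
    """Existence of an in-tolerance correspondence.

    Assignments whose pairwise distances are incompatible with both
    endpoints landing inside their tolerances are pruned
    (|d_cloud - d_hyp| <= t_i + t_j is necessary), and the search exits on
    the first witness.
    """
    k = len(h.features)
    hyp_types = [f.ftype for f in h.features]
    centroids = h.centroids()
    tol = np.array([f.tolerance for f in h.features])
    m_low = max(1, k - max_omitted)
    for cloud in clouds:
        cloud_pos = cloud.positions()
        if len(cloud.features) == 0:
            continue
        cdist = np.linalg.norm(cloud_pos[:, None] - cloud_pos[None, :], axis=2)
        hdist = np.linalg.norm(centroids[:, None] - centroids[None, :], axis=2)
        by_type: dict[str, list[int]] = {}
        for i, f in enumerate(cloud.features):
            by_type.setdefault(f.ftype, []).append(i)
        for m in range(k, m_low - 1, -1):
            for subset in itertools.combinations(range(k), m):
                ok_assigns = []
                for assign in _subset_assignments(subset, hyp_types, by_type):
                    compatible = all(
                        abs(cdist[assign[x], assign[y]] - hdist[subset[x], subset[y]])
                        <= tol[subset[x]] + tol[subset[y]]
                        for x in range(m) for y in range(x + 1, m)
                    )
                    if compatible:
                        ok_assigns.append(assign)
                if not ok_assigns:
                    continue
                idx = np.array(ok_assigns)
                a = cloud_pos[idx]
                b = np.broadcast_to(centroids[list(subset)], a.shape)
                disp, _rmsd = _batch_align(a, b)
                if np.any(np.all(disp <= tol[list(subset)] + 1e-9, axis=1)):
                    return True
    return False


# -- activity calibration ----------------------------------------------------

def calibrate_regression(fits: np.ndarray, log_activities: np.ndarray) -> tuple[float, float]:
    """Least-squares (b0, b1) of log10(IC50) = b0 - b1*fit, with b1 >= 0.

    A non-negative slope (activity not improving with fit) collapses to the
    constant predictor b1 = 0, b0 = mean log activity.
    """
    fits = np.asarray(fits, dtype=float)
    y = np.asarray(log_activities, dtype=float)
    if fits.size < 2 or np.ptp(fits) < 1e-12:
        return float(y.mean()), 0.0
    slope, intercept = np.polyfit(fits, y, 1)
    if slope >= 0:
        return float(y.mean()), 0.0
    return float(intercept), float(-slope)


def calibrate(h: Hypothesis, training: list[TrainingCompound], cfg: EngineConfig) -> Hypothesis:
    """Set (b0, b1) on ``h`` from the training compounds' fits. In place."""
    fits = np.array([map_to_hypothesis(tc.clouds, h, cfg).fit for tc in training])
    logs = np.log10([tc.ic50 for tc in training])
    h.b0, h.b1 = calibrate_regression(fits, logs)
    return h


# -- cost model --------------------------------------------------------------

def _gaussian_bits(residuals: np.ndarray, sigma: float) -> float:
    """Description length in bits of residuals under a N(0, sigma) code."""
    residuals = np.asarray(residuals, dtype=float)
    per_point = math.log2(sigma * math.sqrt(2.0 * math.pi))
    return float(np.sum(residuals**2) / (2.0 * sigma**2 * LN2)
                 + residuals.size * per_point)


def compute_cost(
    h: Hypothesis,
    training: list[TrainingCompound],
    cfg: EngineConfig,
    n_config: int | None = None,
    fits: np.ndarray | None = None,
) -> CostReport:
    """Bits-based cost of a calibrated hypothesis over the training set.

    error_cost codes the log10 prediction residuals at width sigma =
    log10(u); weight_cost penalizes weights away from the nominal 2.0;
    config_cost = log2(number of candidates retained after the subtractive
    phase), capped; total = their sum.  null_cost is the error cost of the
    geometric-mean constant predictor, fixed_cost the cost of an ideal
    zero-residual model.
    """
    if any(tc.ic50 <= 0 for tc in training):
        raise ValueError("activities must be positive")
    if h.b0 is None:
        calibrate(h, training, cfg)
    if fits is None:
        fits = np.array([map_to_hypothesis(tc.clouds, h, cfg).fit for tc in training])
    exp_log = np.log10([tc.ic50 for tc in training])
    est_log = h.b0 - h.b1 * fits
    sigma = cfg.sigma_log
    n = len(training)
    per_point = math.log2(sigma * math.sqrt(2.0 * math.pi))

    error_cost = _gaussian_bits(est_log - exp_log, sigma)
    weight_cost = float(
        sum((f.weight - cfg.default_weight) ** 2 for f in h.features)
        / (2.0 * cfg.sigma_weight**2 * LN2)
    )
    if n_config is None:
        n_config = int(h.meta.get("n_config", 1))
    config_cost = min(cfg.config_cost_cap, math.log2(max(n_config, 1)))
    null_cost = _gaussian_bits(exp_log - exp_log.mean(), sigma)
    fixed_cost = config_cost + n * per_point

    resid = est_log - exp_log
    if np.ptp(est_log) < 1e-12:
        r = 0.0
    else:
        r = float(np.corrcoef(exp_log, est_log)[0, 1])
    return CostReport(
        error_cost=error_cost,
        weight_cost=weight_cost,
        config_cost=config_cost,
        total_cost=error_cost + weight_cost + config_cost,
        null_cost=null_cost,
        fixed_cost=fixed_cost,
        rmsd_log=float(np.sqrt(np.mean(resid**2))),
        r=r,
    )


# -- three-phase generation --------------------------------------------------

def select_leads(training: list[TrainingCompound], cfg: EngineConfig) -> list[TrainingCompound]:
    """Leads: compounds with IC50 within u^2 of the activity minimum."""
    cut = cfg.uncertainty**2 * min(tc.ic50 for tc in training)
    return [tc for tc in training if tc.ic50 <= cut + 1e-12]


def _candidate_signature(h: Hypothesis) -> tuple[tuple[str, ...], np.ndarray]:
    c = h.centroids()
    d = np.linalg.norm(c[:, None] - c[None, :], axis=2)
    return h.type_multiset(), np.sort(d[np.triu_indices(len(c), 1)])


def constructive_phase(
    training: list[TrainingCompound], cfg: EngineConfig | None = None
) -> list[Hypothesis]:
    """Enumerate candidate hypotheses common to the lead compounds.

    Every 3-5-feature subset of a lead's clouds whose pairwise distances
    respect the minimum inter-feature distance and which maps into every
    other lead with all matched displacements within tolerance (omissions up
    to the engine's ``max_omitted`` allowed, as in compound mapping) is a
    candidate; near-duplicates (same type multiset, distance matrices within
    the dedup threshold) are merged.
    """
    cfg = cfg or EngineConfig()
    if not training:
        raise ValueError("constructive phase needs at least one compound")
    leads = select_leads(training, cfg)
    candidates: list[Hypothesis] = []
    signatures: list[tuple[tuple[str, ...], np.ndarray]] = []
    for lead in leads:
        others = [o for o in leads if o is not lead]
        for cloud in lead.clouds[: cfg.max_lead_conformers]:
            feats = cloud.features
            pos = cloud.positions()
            for k in range(3, min(5, len(feats)) + 1):
                for subset in itertools.combinations(range(len(feats)), k):
                    sub_pos = pos[list(subset)]
                    dists = np.linalg.norm(
                        sub_pos[:, None] - sub_pos[None, :], axis=2
                    )[np.triu_indices(k, 1)]
                    if dists.min() < cfg.min_interfeature_distance:
                        continue
                    cand = Hypothesis(
                        features=[
                            PharmacophoreFeature(
                                feats[i].ftype,
                                pos[i].copy(),
                                cfg.default_tolerance,
                                cfg.default_weight,
                            )
                            for i in subset
                        ],
                        meta={"source_compound": lead.compound_id},
                    )
                    if not all(maps_within_tolerance(o.clouds, cand, cfg) for o in others):
                        continue
                    sig = _candidate_signature(cand)
                    dup = any(
                        sig[0] == s0 and len(sig[1]) == len(s1)
                        and np.max(np.abs(sig[1] - s1)) < cfg.dedup_distance
                        for s0, s1 in signatures
                    )
                    if not dup:
                        signatures.append(sig)
                        candidates.append(cand)
    return candidates


def subtractive_phase(
    candidates: list[Hypothesis],
    training: list[TrainingCompound],
    cfg: EngineConfig | None = None,
) -> list[Hypothesis]:
    """Drop candidates fully present in any inactive compound (activity more
    than 10^inactive_gap above the minimum)."""
    cfg = cfg or EngineConfig()
    cut = min(tc.ic50 for tc in training) * 10.0**cfg.inactive_gap
    inactives = [tc for tc in training if tc.ic50 > cut]
    if not inactives:
        return list(candidates)
    return [
        c for c in candidates
        if not any(full_map(tc.clouds, c, cfg) for tc in inactives)
    ]


def _fast_fits(
    h: Hypothesis,
    training: list[TrainingCompound],
    corrs: list[MappingResult],
) -> np.ndarray:
    """Fits under frozen correspondences (re-superposes matched sets only)."""
    centroids = h.centroids()
    tol = np.array([f.tolerance for f in h.features])
    wgt = np.array([f.weight for f in h.features])
    fits = np.zeros(len(training))
    groups: dict[int, list[tuple[int, np.ndarray, list[int]]]] = {}
    for i, (tc, mr) in enumerate(zip(training, corrs)):
        if not mr.mapped:
            continue
        cloud = tc.clouds[mr.conformer_index]
        a = cloud.positions()[[c for _h, c in mr.correspondence]]
        hyp_idx = [hh for hh, _c in mr.correspondence]
        groups.setdefault(len(hyp_idx), []).append((i, a, hyp_idx))
    for m, entries in groups.items():
        a = np.stack([e[1] for e in entries])
        b = np.stack([centroids[e[2]] for e in entries])
        disp, _rmsd = _batch_align(a, b)
        for row, (i, _a, hyp_idx) in enumerate(entries):
            contrib = wgt[hyp_idx] * np.maximum(
                0.0, 1.0 - (disp[row] / tol[hyp_idx]) ** 2
            )
            fits[i] = contrib.sum()
    return fits


def _evaluate(h, training, cfg, n_config, full: bool, corrs=None):
    if full or corrs is None:
        mrs = [map_to_hypothesis(tc.clouds, h, cfg) for tc in training]
        fits = np.array([mr.fit for mr in mrs])
    else:
        mrs = corrs
        fits = _fast_fits(h, training, corrs)
    logs = np.log10([tc.ic50 for tc in training])
    h.b0, h.b1 = calibrate_regression(fits, logs)
    report = compute_cost(h, training, cfg, n_config=n_config, fits=fits)
    return report, mrs, fits


def _propose(h: Hypothesis, rng: np.random.Generator, cfg: EngineConfig) -> Hypothesis:
    prop = copy.deepcopy(h)
    f = prop.features[int(rng.integers(len(prop.features)))]
    kind = int(rng.integers(3))
    if kind == 0:  # centroid move, <= 0.5 Å
        step = rng.normal(size=3)
        step *= rng.uniform(0.0, 0.5) / max(np.linalg.norm(step), 1e-12)
        f.centroid = f.centroid + step
    elif kind == 1:  # tolerance rescale
        f.tolerance = float(np.clip(f.tolerance * rng.uniform(0.8, 1.25), 0.4, 5.0))
    else:  # weight step
        f.weight = float(max(0.0, f.weight + rng.choice([-0.2, 0.2])))
    return prop


def optimize_hypotheses(
    candidates: list[Hypothesis],
    training: list[TrainingCompound],
    cfg: EngineConfig | None = None,
) -> list[tuple[Hypothesis, CostReport]]:
    """Simulated-annealing refinement of the candidate hypotheses.

    Candidates are shortlisted to the top ``n_hypotheses`` by a cheap
    distance-pruned proxy cost, then each is annealed with small
    centroid/tolerance/weight perturbations; (b0, b1) are refit by least
    squares at every evaluation.  Correspondences are re-searched every
    ``remap_every`` steps and frozen in between; the best fully-evaluated
    state per candidate is kept.  Deterministic for a fixed config seed.
    Result is sorted by total cost ascending (ties toward more features).
    """
    cfg = cfg or EngineConfig()
    if not candidates:
        raise ValueError("optimize_hypotheses needs at least one candidate")
    n_config = len(candidates)

    # shortlist by a cheap distance-pruned proxy cost, then evaluate fully
    logs = np.log10([tc.ic50 for tc in training])
    scored = []
    for idx, cand in enumerate(candidates):
        cand = copy.deepcopy(cand)
        cand.meta["n_config"] = n_config
        fits = np.array(
            [map_to_hypothesis(tc.clouds, cand, cfg, prune=True).fit
             for tc in training]
        )
        cand.b0, cand.b1 = calibrate_regression(fits, logs)
        proxy = compute_cost(cand, training, cfg, n_config=n_config, fits=fits)
        scored.append((proxy.total_cost, -len(cand.features), idx, cand))
    scored.sort(key=lambda t: t[:3])
    selected = []
    for _tc, _nk, idx, cand in scored[: cfg.n_hypotheses]:
        report, mrs, _fits = _evaluate(cand, training, cfg, n_config, full=True)
        selected.append((idx, cand, report, mrs))

    results: list[tuple[Hypothesis, CostReport]] = []
    for idx, cand, report, mrs in selected:
        rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, idx)))
        current, current_report, corrs = cand, report, mrs
        current_cost = current_report.total_cost
        best, best_report = copy.deepcopy(current), current_report
        trace: list[tuple[float, float]] = []
        temp = cfg.anneal.start_temp
        for step in range(cfg.anneal.steps):
            prop = _propose(current, rng, cfg)
            if prop.min_interfeature_distance() < cfg.min_interfeature_distance:
                temp *= cfg.anneal.cooling
                continue
            full = step % cfg.remap_every == 0
            prop_report, prop_mrs, _ = _evaluate(
                prop, training, cfg, n_config, full=full, corrs=corrs
            )
            dcost = prop_report.total_cost - current_cost
            accept = dcost < 0 or (
                temp > 1e-12 and rng.random() < math.exp(-dcost / temp)
            )
            if accept:
                current, current_report = prop, prop_report
                current_cost = prop_report.total_cost
                if full:
                    corrs = prop_mrs
                trace.append((temp, current_cost))
                if full and current_cost < best_report.total_cost:
                    best, best_report = copy.deepcopy(current), current_report
            temp *= cfg.anneal.cooling
        # final full evaluation of the annealed state
        final_report, _mrs, _ = _evaluate(current, training, cfg, n_config, full=True)
        if final_report.total_cost < best_report.total_cost:
            best, best_report = current, final_report
        best.meta["anneal_trace"] = trace
        results.append((best, best_report))

    results.sort(key=lambda hr: (hr[1].total_cost, -len(hr[0].features)))
    for rank, (h, _r) in enumerate(results, start=1):
        h.rank = rank
    return results


def generate_hypotheses(
    training: list[TrainingCompound], cfg: EngineConfig | None = None
) -> list[tuple[Hypothesis, CostReport]]:
    """Full three-phase generation: constructive, subtractive, optimization.

    Returns the ranked (hypothesis, cost report) list; empty when no feature
    arrangement is common to the lead compounds (as happens on randomized
    activity data).
    """
    cfg = cfg or EngineConfig()
    candidates = constructive_phase(training, cfg)
    candidates = subtractive_phase(candidates, training, cfg)
    if not candidates:
        return []
    return optimize_hypotheses(candidates, training, cfg)
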