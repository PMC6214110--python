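"""Ground-truth-bearing synthetic inputs plus the embedded reference tables.

Two kinds of test substrate:

* **Published activity tables** of the ANO1 inhibitor study (20 training and
  32 test compounds, experimental and estimated IC50 in μM together with the
  printed error values and activity scales) ship as packaged CSV fixtures,
  so the validation statistics can be recomputed without any download.

* **Synthetic feature-cloud libraries** with a planted pharmacophore ->
  activity relationship: actives carry a jittered copy of a planted
  hypothesis plus random distractor features, decoys carry distractors only,
  and true log10 IC50 is log-linear in the noise-free fit with log-normal
  noise, clamped to the configured activity range (0.107-29.2 μM by
  default).  Compounds are abstract feature clouds rather than molecules:
  the engine's contracts are geometric, and this keeps recovery experiments
  free of chemistry confounds.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .feature_perception import FEATURE_TYPES, Feature, FeatureCloud
from .hypothesis_engine import (
    EngineConfig,
    Hypothesis,
    PharmacophoreFeature,
    TrainingCompound,
    full_map,
    map_to_hypothesis,
)


# -- embedded reference tables ----------------------------------------------

@dataclass
class FixtureTable:
    """One published activity table (training: 20 rows, test: 32 rows)."""

    split: str  # "training" | "test"
    frame: pd.DataFrame

    @property
    def records(self) -> list[tuple[str, float, float]]:
        return [
            (str(r.compound_id), float(r.exp_ic50_uM), float(r.est_ic50_uM))
            for r in self.frame.itertuples()
        ]

    def pairs(self) -> list[tuple[float, float]]:
        return [(e, s) for _i, e, s in self.records]

    def content_hash(self) -> str:
        return hashlib.sha256(
            self.frame.to_csv(index=False).encode()
        ).hexdigest()


def _load_fixture(name: str, split: str) -> FixtureTable:
    with resources.files("ligphore.data").joinpath(name).open() as fh:
        frame = pd.read_csv(fh, dtype={"compound_id": str})
    return FixtureTable(split=split, frame=frame)


def published_fixtures() -> tuple[FixtureTable, FixtureTable]:
    """The embedded training (n=20) and test (n=32) activity tables."""
    return (
        _load_fixture("training_activities.csv", "training"),
        _load_fixture("test_activities.csv", "test"),
    )


#: Published cost summary of the reference study's model generation run.
REFERENCE_NULL_COST = 194.608
REFERENCE_FIXED_COST = 63.804
REFERENCE_CONFIG_COST = 15.343
REFERENCE_BEST_TOTAL_COST = 73.604  # the selected model (rank 2 by cost)


def reference_model_stats() -> pd.DataFrame:
    """Per-model statistics (total cost, cost difference, RMSD, correlations,
    feature composition) of the reference study's ten ranked hypotheses."""
    with resources.files("ligphore.data").joinpath("reference_model_stats.csv").open() as fh:
        return pd.read_csv(fh)


# -- synthetic generator -----------------------------------------------------

@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic library.

    Defaults emulate the reference dataset: activities spanning
    0.107-29.2 μM, log-linear in fit with slope sized so a perfect
    full-weight map of a 4-feature hypothesis (fit 8) reaches the bottom of
    the range and an unmapped compound sits at the top.
    """

    n_compounds: int = 20
    activity_range: tuple[float, float] = (0.107, 29.2)  # μM
    noise_sigma: float = 0.2  # log10 units
    b0: float = 1.4654  # log10(29.2)
    b1: float = 0.3045  # (log10(29.2) - log10(0.107)) / 8
    decoy_fraction: float = 0.25
    jitter_sigma: float = 0.3  # Å
    full_retention_fraction: float = 0.4  # actives carrying every planted feature
    distractors: tuple[int, int] = (3, 5)  # inclusive range per compound
    box_size: float = 10.0  # Å, distractor placement cube
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_compounds < 2:
            raise ValueError("need at least 2 compounds")
        lo, hi = self.activity_range
        if not 0 < lo < hi:
            raise ValueError("activity range must satisfy 0 < min < max")
        if self.noise_sigma < 0 or self.jitter_sigma < 0:
            raise ValueError("sigmas must be non-negative")
        if not 0.0 <= self.decoy_fraction <= 1.0:
            raise ValueError("decoy fraction must be in [0, 1]")


def plant_hypothesis(seed: int, k: int = 4, min_distance: float = 2.0,
                     tolerance: float = 1.6, weight: float = 2.0) -> Hypothesis:
    """A random ground-truth hypothesis with k features (3-5).

    Types are drawn without replacement from {HBA, HBD, HY, RA} (the default
    k=4 therefore has one of each; k=5 adds one repeat); centroids are
    rejection-sampled in a box until all pairwise distances reach the
    minimum inter-feature distance.  Deterministic per seed.
    """
    if not 3 <= k <= 5:
        raise ValueError("k must be between 3 and 5")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0x9A97)))
    types = [str(t) for t in rng.permutation(FEATURE_TYPES)[: min(k, 4)]]
    while len(types) < k:
        types.append(str(rng.choice(FEATURE_TYPES)))
    while True:
        pts = rng.uniform(-4.0, 4.0, size=(k, 3))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        if d[np.triu_indices(k, 1)].min() >= min_distance:
            break
    return Hypothesis(
        features=[
            PharmacophoreFeature(t, p, tolerance, weight)
            for t, p in zip(types, pts)
        ],
        meta={"planted_seed": seed},
    )


@dataclass
class SyntheticLibrary:
    """Generated library plus its ground truth."""

    entries: list[tuple[str, list[FeatureCloud]]]  # (compound id, clouds)
    ic50: list[float]  # μM, truth
    is_active: list[bool]
    true_fits: list[float]  # noise-free fit of the planted arrangement
    clamp_count: int = 0

    def training_compounds(self) -> list[TrainingCompound]:
        return [
            TrainingCompound(cid, clouds, act)
            for (cid, clouds), act in zip(self.entries, self.ic50)
        ]


def _random_frame(points: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Re-express a cloud in an arbitrary rigid frame (mapping is
    superposition-based, so this only removes accidental alignment)."""
    rot = Rotation.random(rng=rng).as_matrix()
    shift = rng.uniform(-20.0, 20.0, size=3)
    return points @ rot.T + shift


def _distractor_features(n: int, rng: np.random.Generator, box: float) -> list[Feature]:
    return [
        Feature(
            str(rng.choice(FEATURE_TYPES)),
            rng.uniform(-box / 2, box / 2, size=3),
        )
        for _ in range(n)
    ]


def generate_library(h: Hypothesis, spec: SyntheticSpec) -> SyntheticLibrary:
    """Generate a feature-cloud library with a planted activity relationship.

    Actives carry a Gaussian-jittered copy of the planted features plus
    distractors; feature retention among actives is graded, as in real
    training sets (a ``full_retention_fraction`` of them carry every planted
    feature, the rest a random 2..k-1 subset), which spreads fits — and
    hence activities — across the configured range and makes each feature's
    activity contribution identifiable.  Decoys carry distractors only
    (re-sampled if they happen to fully map the hypothesis).  True log10
    IC50 = b0 - b1*(noise-free fit) +
    N(0, noise_sigma), clamped to the activity range; clamp events are
    counted.  The noise-free fit is the cloud's actual best-mapping fit
    against the planted hypothesis (a decoy that accidentally part-maps
    receives the correspondingly better activity), so the planted hypothesis
    is exactly the data-generating model and zero noise/jitter yields a
    perfect fit-activity regression.  Deterministic per spec seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 0x11B)))
    cfg = EngineConfig()
    n = spec.n_compounds
    n_decoys = int(round(n * spec.decoy_fraction))
    n_actives = n - n_decoys
    lo, hi = np.log10(spec.activity_range[0]), np.log10(spec.activity_range[1])
    planted = h.centroids()

    entries: list[tuple[str, list[FeatureCloud]]] = []
    ic50: list[float] = []
    active_mask: list[bool] = []
    true_fits: list[float] = []
    clamps = 0
    for i in range(n):
        cid = f"syn-{i + 1:03d}"
        active = i < n_actives
        n_distract = int(rng.integers(spec.distractors[0], spec.distractors[1] + 1))
        if active:
            k = len(h.features)
            if i < math.ceil(spec.full_retention_fraction * n_actives):
                retained = list(range(k))
            else:
                r = int(rng.integers(2, k))  # partial carrier: 2..k-1 features
                retained = sorted(rng.choice(k, size=r, replace=False))
            jittered = planted[retained] + rng.normal(
                0.0, spec.jitter_sigma, size=(len(retained), 3)
            )
            feats = [
                Feature(h.features[j].ftype, p)
                for j, p in zip(retained, jittered)
            ] + _distractor_features(n_distract, rng, spec.box_size)
        else:
            for _attempt in range(25):
                feats = _distractor_features(
                    len(h.features) + n_distract, rng, spec.box_size
                )
                cloud = FeatureCloud(cid, 0, feats)
                if not full_map([cloud], h, cfg):
                    break
        pos = np.array([f.position for f in feats])
        moved = _random_frame(pos, rng)
        feats = [Feature(f.ftype, p) for f, p in zip(feats, moved)]
        feats.sort(key=lambda f: f.ftype)
        cloud = FeatureCloud(cid, 0, feats)
        fit_nf = map_to_hypothesis([cloud], h, cfg).fit

        log_act = spec.b0 - spec.b1 * fit_nf + rng.normal(0.0, spec.noise_sigma)
        clamped = min(max(log_act, lo), hi)
        if clamped != log_act:
            clamps += 1
        entries.append((cid, [cloud]))
        ic50.append(float(10.0**clamped))
        active_mask.append(active)
        true_fits.append(fit_nf)
    return SyntheticLibrary(entries, ic50, active_mask, true_fits, clamps)


def make_training(h: Hypothesis, spec: SyntheticSpec) -> list[TrainingCompound]:
    """Convenience: a generated library as engine training compounds."""
    return generate_library(h, spec).training_compounds()
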