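"""Virtual-screening funnel: drug-likeness and ADMET filters, pharmacophore
screening with an estimated-activity cutoff, ranking, scaffold deduplication.

The funnel mirrors the classic ligand-based pipeline: Lipinski rule-of-five
-> declared ADMET criteria -> conformer generation -> pharmacophore mapping
-> estimated-IC50 cutoff -> ranking -> one representative per Murcko
scaffold.  ADMET values come from a pluggable per-compound profile table (no
built-in predictor); stage-wise survivor counts are logged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from rdkit.Chem.Scaffolds import MurckoScaffold

from .chem_io import (
    ConformerConfig,
    EmbeddingError,
    Molecule,
    MolProperties,
    compute_properties,
    generate_conformers,
)
from .feature_perception import FeatureCloud, FeatureRules, perceive_ensemble
from .hypothesis_engine import (
    EngineConfig,
    Hypothesis,
    estimate_activity,
    map_to_hypothesis,
)

#: Sentinel scaffold key for acyclic molecules (empty Murcko framework).
ACYCLIC_SCAFFOLD = "<acyclic>"


@dataclass
class LipinskiThresholds:
    max_hbd: int = 5
    max_hba: int = 10
    max_mol_weight: float = 500.0  # Da
    max_logp: float = 5.0


@dataclass
class AdmetProfile:
    """Declared ADMET levels/flags for one compound (external predictor)."""

    solubility_level: int
    bbb_level: int
    absorption_level: int
    cyp2d6_inhibitor: bool
    hepatotoxic: bool

    def __post_init__(self) -> None:
        for level in (self.solubility_level, self.bbb_level, self.absorption_level):
            if level < 0:
                raise ValueError("ADMET levels are non-negative integers")


@dataclass
class ScreeningCriteria:
    """Filter thresholds: all four Lipinski rules are strict inequalities;
    ADMET criteria name the allowed levels; hits must beat the activity
    cutoff (default 0.1 μM, i.e. estimated IC50 below 100 nM)."""

    lipinski: LipinskiThresholds = field(default_factory=LipinskiThresholds)
    admet: dict = field(
        default_factory=lambda: {
            "solubility_level": {3, 4},
            "bbb_level": {3},
            "absorption_level": {0},
            "cyp2d6_inhibitor": {False},
            "hepatotoxic": {False},
        }
    )
    activity_cutoff: float = 0.1  # μM

    def __post_init__(self) -> None:
        if self.activity_cutoff <= 0:
            raise ValueError("activity cutoff must be positive")


def lipinski_filter(
    p: MolProperties, c: ScreeningCriteria | None = None
) -> tuple[bool, list[str]]:
    """Rule-of-five check; returns (pass, violated rule names).

    All four rules are strict ("less than"): HBD < 5, HBA < 10, MW < 500 Da,
    LogP < 5.
    """
    c = c or ScreeningCriteria()
    t = c.lipinski
    violations = []
    if not p.hbd_count < t.max_hbd:
        violations.append("HBD")
    if not p.hba_count < t.max_hba:
        violations.append("HBA")
    if not p.mol_weight < t.max_mol_weight:
        violations.append("MW")
    if not p.logp < t.max_logp:
        violations.append("LogP")
    return not violations, violations


def admet_filter(
    a: AdmetProfile | None,
    c: ScreeningCriteria | None = None,
    strict: bool = True,
) -> bool:
    """True when every declared ADMET criterion is satisfied.

    A missing profile raises in strict mode and passes (flagged by the
    caller's counters) in lenient mode.
    """
    c = c or ScreeningCriteria()
    if a is None:
        if strict:
            raise ValueError("missing ADMET profile in strict mode")
        return True
    for prop, allowed in c.admet.items():
        if getattr(a, prop) not in allowed:
            return False
    return True


def scaffold_key(m: Molecule) -> str:
    """Canonical SMILES of the ring-and-linker (Murcko) framework; acyclic
    molecules share a sentinel key."""
    smiles = MurckoScaffold.MurckoScaffoldSmiles(mol=m.rdmol, includeChirality=False)
    return smiles if smiles else ACYCLIC_SCAFFOLD


@dataclass
class ScreenHit:
    compound_id: str
    fit: float
    est_ic50: float  # μM
    scaffold: str
    rank: int = 0


@dataclass
class FunnelLog:
    """Stage-wise survivor counts; monotonically non-increasing."""

    input: int = 0
    lipinski: int = 0
    admet: int = 0
    mapped: int = 0
    hits: int = 0
    embedding_failures: int = 0
    missing_admet: int = 0

    def counts(self) -> list[int]:
        return [self.input, self.lipinski, self.admet, self.mapped, self.hits]


def _rank(hits: list[ScreenHit]) -> list[ScreenHit]:
    hits.sort(key=lambda h: (h.est_ic50, h.compound_id))
    for i, h in enumerate(hits, start=1):
        h.rank = i
    return hits


def screen_clouds(
    library: list[tuple[str, list[FeatureCloud]]],
    h: Hypothesis,
    criteria: ScreeningCriteria | None = None,
    cfg: EngineConfig | None = None,
    scaffolds: dict[str, str] | None = None,
) -> tuple[list[ScreenHit], FunnelLog]:
    """Pharmacophore screening of pre-perceived feature clouds.

    Entries are (compound id, clouds); hits are compounds whose estimated
    IC50 beats the cutoff, ranked ascending.  Used directly for abstract
    (synthetic) libraries and as the final stages of :func:`screen_library`.
    """
    criteria = criteria or ScreeningCriteria()
    cfg = cfg or EngineConfig()
    log = FunnelLog(input=len(library), lipinski=len(library), admet=len(library))
    hits: list[ScreenHit] = []
    for cid, clouds in library:
        mr = map_to_hypothesis(clouds, h, cfg)
        if not mr.mapped:
            continue
        log.mapped += 1
        est = estimate_activity(h, mr.fit)
        if est < criteria.activity_cutoff:
            hits.append(
                ScreenHit(
                    compound_id=cid,
                    fit=mr.fit,
                    est_ic50=est,
                    scaffold=(scaffolds or {}).get(cid, ""),
                )
            )
    log.hits = len(hits)
    return _rank(hits), log


def screen_library(
    library: list[Molecule],
    h: Hypothesis,
    criteria: ScreeningCriteria | None = None,
    cfg: EngineConfig | None = None,
    admet_profiles: dict[str, AdmetProfile] | None = None,
    conformer_cfg: ConformerConfig | None = None,
    rules: FeatureRules | None = None,
    strict_admet: bool = False,
) -> tuple[list[ScreenHit], FunnelLog]:
    """Full screening funnel over a molecule library.

    Per compound: properties -> Lipinski -> ADMET -> conformers -> feature
    perception -> pharmacophore mapping -> activity estimate; survivors of
    the cutoff are ranked by estimated IC50 ascending.  An empty library
    yields an empty hit list.  Compound order does not affect the ranked
    output.
    """
    criteria = criteria or ScreeningCriteria()
    cfg = cfg or EngineConfig()
    conformer_cfg = conformer_cfg or ConformerConfig(max_conformers=20)
    admet_profiles = admet_profiles or {}
    log = FunnelLog(input=len(library))

    survivors: list[tuple[str, list[FeatureCloud]]] = []
    scaffolds: dict[str, str] = {}
    for m in library:
        ok, _violations = lipinski_filter(compute_properties(m), criteria)
        if not ok:
            continue
        log.lipinski += 1
        profile = admet_profiles.get(m.id)
        if profile is None and not strict_admet:
            log.missing_admet += 1
        if not admet_filter(profile, criteria, strict=strict_admet):
            continue
        log.admet += 1
        try:
            ensemble = generate_conformers(m, conformer_cfg)
        except EmbeddingError:
            log.embedding_failures += 1
            continue
        clouds = perceive_ensemble(ensemble, rules=rules)
        survivors.append((m.id, clouds))
        scaffolds[m.id] = scaffold_key(m)

    hits, sublog = screen_clouds(survivors, h, criteria, cfg, scaffolds=scaffolds)
    log.mapped, log.hits = sublog.mapped, sublog.hits
    return hits, log


def dedup_by_scaffold(hits: list[ScreenHit]) -> list[ScreenHit]:
    """One representative per scaffold key: the best-scoring member (lowest
    estimated IC50, ties toward the lexicographically lower id); the output
    is re-ranked from 1."""
    best: dict[str, ScreenHit] = {}
    for hit in sorted(hits, key=lambda h: (h.est_ic50, h.compound_id)):
        best.setdefault(hit.scaffold, hit)
    return _rank(list(best.values()))
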