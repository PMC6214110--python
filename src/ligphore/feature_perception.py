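"""Typed 3D pharmacophore feature perception (HBA, HBD, HY, RA).

A conformer is converted into a cloud of typed feature points:

* HBD — donor heavy atom position, direction along the mean H-bond axis;
* HBA — acceptor heavy atom position, lone-pair axis direction;
* RA  — centroid of each 5/6-membered aromatic ring, ring-normal direction;
* HY  — centroid of each contiguous cluster of >= 2 non-polar carbons or
  halogens (a ring is a single cluster).

Feature chemistry is defined by SMARTS rule tables shipped as a versioned
YAML data file (``data/feature_rules.yaml``); perception itself is purely
topological plus coordinate averaging, so rigid motions of the input
coordinates move every feature by the same motion.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml
from rdkit import Chem

from .chem_io import ConformerEnsemble, Molecule

FEATURE_TYPES = ("HBA", "HBD", "HY", "RA")


@dataclass
class Feature:
    ftype: str
    position: np.ndarray  # (3,), Å
    direction: np.ndarray | None = None  # unit vector, optional
    anchor_atoms: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.ftype not in FEATURE_TYPES:
            raise ValueError(f"unknown feature type {self.ftype!r}")
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError("feature position must be a finite 3D point")
        if self.direction is not None:
            self.direction = np.asarray(self.direction, dtype=float)
            if abs(np.linalg.norm(self.direction) - 1.0) > 1e-6:
                raise ValueError("feature direction must be a unit vector")


@dataclass
class FeatureCloud:
    """All features perceived from one conformer of one compound."""

    compound_id: str
    conformer_index: int
    features: list[Feature] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.features)

    def type_multiset(self) -> tuple[str, ...]:
        return tuple(sorted(f.ftype for f in self.features))

    def positions(self) -> np.ndarray:
        if not self.features:
            return np.zeros((0, 3))
        return np.array([f.position for f in self.features])

    def to_json(self) -> str:
        return json.dumps(
            {
                "compound_id": self.compound_id,
                "conformer_index": self.conformer_index,
                "features": [
                    {
                        "type": f.ftype,
                        "xyz": f.position.tolist(),
                        "direction": None if f.direction is None else f.direction.tolist(),
                    }
                    for f in self.features
                ],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "FeatureCloud":
        d = json.loads(text)
        return cls(
            compound_id=d["compound_id"],
            conformer_index=d["conformer_index"],
            features=[
                Feature(
                    ftype=f["type"],
                    position=np.array(f["xyz"]),
                    direction=None if f.get("direction") is None else np.array(f["direction"]),
                )
                for f in d["features"]
            ],
        )


class FeatureRules:
    """Compiled SMARTS rule tables for the four feature classes."""

    def __init__(self, spec: dict):
        self.version = spec.get("version", 0)
        self.hbd = [Chem.MolFromSmarts(p) for p in spec["hbd"]["patterns"]]
        self.hba = [Chem.MolFromSmarts(p) for p in spec["hba"]["patterns"]]
        self.hy_atoms = [Chem.MolFromSmarts(p) for p in spec["hy"]["atom_patterns"]]
        self.hy_min_cluster = int(spec["hy"].get("min_cluster_size", 2))
        self.ra_sizes = set(spec["ra"].get("ring_sizes", [5, 6]))
        if any(p is None for p in self.hbd + self.hba + self.hy_atoms):
            raise ValueError("invalid SMARTS pattern in feature rules")

    @classmethod
    def load(cls, path: str | Path | None = None) -> "FeatureRules":
        if path is None:
            text = resources.files("ligphore.data").joinpath("feature_rules.yaml").read_text()
        else:
            text = Path(path).read_text()
        return cls(yaml.safe_load(text))


_default_rules: FeatureRules | None = None


def default_rules() -> FeatureRules:
    global _default_rules
    if _default_rules is None:
        _default_rules = FeatureRules.load()
    return _default_rules


def _unit(v: np.ndarray) -> np.ndarray | None:
    n = np.linalg.norm(v)
    if n < 1e-8:
        return None
    return v / n


def _match_atoms(mol: Chem.Mol, patterns) -> set[int]:
    hits: set[int] = set()
    for patt in patterns:
        for match in mol.GetSubstructMatches(patt):
            hits.add(match[0])
    return hits


def perceive_features(
    m: Molecule | Chem.Mol,
    coords: np.ndarray,
    rules: FeatureRules | None = None,
) -> FeatureCloud:
    """Perceive the typed feature cloud of one conformer.

    ``coords`` must have one row per atom of the molecule (explicit hydrogens
    included when the molecule carries them). Features are ordered
    deterministically by (type, lowest anchor atom index). Molecules with no
    features yield an empty cloud.
    """
    rules = rules or default_rules()
    mol = m.rdmol if isinstance(m, Molecule) else m
    coords = np.asarray(coords, dtype=float)
    if coords.shape != (mol.GetNumAtoms(), 3):
        raise ValueError("coordinates must cover all atoms")
    compound_id = m.id if isinstance(m, Molecule) else (
        mol.GetProp("_Name") if mol.HasProp("_Name") else ""
    )

    features: list[Feature] = []

    # HBD: donor heavy atom, direction = mean axis toward attached hydrogens
    for idx in sorted(_match_atoms(mol, rules.hbd)):
        atom = mol.GetAtomWithIdx(idx)
        h_idx = [n.GetIdx() for n in atom.GetNeighbors() if n.GetAtomicNum() == 1]
        if h_idx:
            axis = _unit(coords[h_idx].mean(axis=0) - coords[idx])
        else:  # implicit hydrogens: point away from the heavy neighbors
            nbrs = [n.GetIdx() for n in atom.GetNeighbors()]
            axis = _unit(coords[idx] - coords[nbrs].mean(axis=0)) if nbrs else None
        features.append(Feature("HBD", coords[idx], axis, (idx,)))

    # HBA: acceptor heavy atom, lone-pair axis away from bonded neighbors
    for idx in sorted(_match_atoms(mol, rules.hba)):
        atom = mol.GetAtomWithIdx(idx)
        nbrs = [n.GetIdx() for n in atom.GetNeighbors()]
        axis = _unit(coords[idx] - coords[nbrs].mean(axis=0)) if nbrs else None
        features.append(Feature("HBA", coords[idx], axis, (idx,)))

    # HY: connected clusters of eligible non-polar atoms
    eligible = _match_atoms(mol, rules.hy_atoms)
    seen: set[int] = set()
    clusters: list[list[int]] = []
    for start in sorted(eligible):
        if start in seen:
            continue
        stack, comp = [start], []
        seen.add(start)
        while stack:
            a = stack.pop()
            comp.append(a)
            for n in mol.GetAtomWithIdx(a).GetNeighbors():
                j = n.GetIdx()
                if j in eligible and j not in seen:
                    seen.add(j)
                    stack.append(j)
        if len(comp) >= rules.hy_min_cluster:
            clusters.append(sorted(comp))
    for comp in clusters:
        features.append(Feature("HY", coords[comp].mean(axis=0), None, tuple(comp)))

    # RA: fully aromatic rings of the allowed sizes; normal = plane normal
    ring_info = mol.GetRingInfo()
    for ring in ring_info.AtomRings():
        if len(ring) not in rules.ra_sizes:
            continue
        if not all(mol.GetAtomWithIdx(i).GetIsAromatic() for i in ring):
            continue
        pts = coords[list(ring)]
        centroid = pts.mean(axis=0)
        centered = pts - centroid
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        normal = _unit(vt[-1])
        features.append(Feature("RA", centroid, normal, tuple(sorted(ring))))

    features.sort(key=lambda f: (f.ftype, f.anchor_atoms))
    return FeatureCloud(compound_id=compound_id, conformer_index=0, features=features)


def perceive_ensemble(
    ensemble: ConformerEnsemble, rules: FeatureRules | None = None
) -> list[FeatureCloud]:
    """One feature cloud per conformer.

    Perception is topology-driven, so the feature type multiset is identical
    across conformers; only positions (and directions) differ.
    """
    clouds = []
    for i, coords in enumerate(ensemble.coordinates):
        cloud = perceive_features(ensemble.rdmol_h, coords, rules=rules)
        cloud.compound_id = ensemble.molecule.id
        cloud.conformer_index = i
        clouds.append(cloud)
    return clouds
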