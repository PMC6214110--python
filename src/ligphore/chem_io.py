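"""Molecule I/O, drug-likeness properties, and bounded conformer ensembles.

RDKit does the chemistry heavy lifting (SMILES/SDF parsing, descriptor
calculation, ETKDG embedding, MMFF minimization); this module wraps it behind
small domain types and enforces the contracts the rest of the pipeline relies
on: a fixed pH-7.4 protonation rule set, a conformer count cap, a strain-energy
window relative to the ensemble minimum, and seed-determinism.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem, Crippen, Descriptors, Lipinski

RDLogger.DisableLog("rdApp.*")

#: Default embedding seed, recorded in every ensemble.
DEFAULT_CONFORMER_SEED = 20181017


class MoleculeParseError(ValueError):
    """Raised when a SMILES string or SDF record cannot be sanitized."""


@dataclass
class Molecule:
    """A sanitized small molecule with implicit hydrogens resolved.

    Wraps an RDKit mol; ``atoms`` and ``bonds`` views expose the plain
    connection table (element, formal charge, aromatic flag / index pair,
    order) for code that does not want to touch RDKit.
    """

    id: str
    rdmol: Chem.Mol
    source_line: int | None = None

    def __post_init__(self) -> None:
        if self.rdmol is None or self.rdmol.GetNumAtoms() == 0:
            raise MoleculeParseError(f"molecule {self.id!r} has no atoms")

    @property
    def atoms(self) -> list[tuple[str, int, bool]]:
        return [
            (a.GetSymbol(), a.GetFormalCharge(), a.GetIsAromatic())
            for a in self.rdmol.GetAtoms()
        ]

    @property
    def bonds(self) -> list[tuple[tuple[int, int], float]]:
        return [
            ((b.GetBeginAtomIdx(), b.GetEndAtomIdx()), b.GetBondTypeAsDouble())
            for b in self.rdmol.GetBonds()
        ]

    @property
    def num_heavy_atoms(self) -> int:
        return self.rdmol.GetNumHeavyAtoms()

    @property
    def num_rings(self) -> int:
        return self.rdmol.GetRingInfo().NumRings()

    @property
    def smiles(self) -> str:
        return Chem.MolToSmiles(self.rdmol)


@dataclass
class MolProperties:
    """Lipinski-style drug-likeness properties."""

    mol_weight: float  # Da, includes implicit hydrogens
    hbd_count: int
    hba_count: int
    logp: float  # Crippen atomic-contribution estimate

    def __post_init__(self) -> None:
        if self.mol_weight <= 0:
            raise ValueError("molecular weight must be positive")
        if self.hbd_count < 0 or self.hba_count < 0:
            raise ValueError("donor/acceptor counts must be non-negative")


@dataclass
class ConformerConfig:
    """Ensemble generation bounds: count cap, strain-energy window, seed."""

    max_conformers: int = 255
    energy_window: float = 10.0  # kcal/mol above the ensemble minimum
    seed: int = DEFAULT_CONFORMER_SEED
    prune_rms_threshold: float = 0.5  # Å, drops duplicate embeddings

    def __post_init__(self) -> None:
        if self.max_conformers < 1:
            raise ValueError("max_conformers must be >= 1")
        if self.energy_window <= 0:
            raise ValueError("energy_window must be positive")


@dataclass
class ConformerEnsemble:
    """Bounded conformer set with strain energies relative to the minimum.

    ``rdmol_h`` carries explicit hydrogens; each coordinate set has one row
    per atom of ``rdmol_h``.
    """

    molecule: Molecule
    rdmol_h: Chem.Mol
    coordinates: list[np.ndarray]  # each (n_atoms, 3), Å
    energies: list[float] = field(default_factory=list)  # kcal/mol, relative

    def __post_init__(self) -> None:
        if not self.coordinates:
            raise ValueError(f"empty ensemble for molecule {self.molecule.id!r}")
        n = self.rdmol_h.GetNumAtoms()
        for c in self.coordinates:
            if c.shape != (n, 3):
                raise ValueError("coordinate set shape does not match atom count")
        if self.energies and min(self.energies) < -1e-9:
            raise ValueError("relative energies must be >= 0")

    def __len__(self) -> int:
        return len(self.coordinates)


# -- parsing -----------------------------------------------------------------

_DEPROTONATE_COOH = Chem.MolFromSmarts("[CX3](=O)[OX2H1]")
_PROTONATE_AMINE = Chem.MolFromSmarts(
    "[NX3;H2,H1,H0;+0;!$(N-[CX3]=[OX1,SX1,NX2]);!$(N~[O,N]);!$(N=*);!a]"
)


def _apply_ph74_protonation(mol: Chem.Mol) -> Chem.Mol:
    """Fixed pH-7.4 ionization rules: carboxylic acids lose the proton,
    aliphatic amines gain one. No pKa engine; amides/anilines untouched."""
    rw = Chem.RWMol(mol)
    for match in rw.GetSubstructMatches(_DEPROTONATE_COOH):
        o = rw.GetAtomWithIdx(match[2])
        o.SetFormalCharge(-1)
        o.SetNoImplicit(True)
        o.SetNumExplicitHs(0)
    for match in rw.GetSubstructMatches(_PROTONATE_AMINE):
        n = rw.GetAtomWithIdx(match[0])
        n.SetFormalCharge(1)
        n.SetNumExplicitHs(n.GetTotalNumHs() + 1)
    out = rw.GetMol()
    Chem.SanitizeMol(out)
    return out


def parse_molecule(smiles: str, mol_id: str = "", protonate: bool = True) -> Molecule:
    """Parse a SMILES string into a sanitized :class:`Molecule`.

    Protonation states follow the fixed pH-7.4 rule set unless ``protonate``
    is False. Raises :class:`MoleculeParseError` on malformed input, naming
    the offending string.
    """
    if not smiles or not smiles.strip():
        raise MoleculeParseError("empty SMILES string")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise MoleculeParseError(f"malformed SMILES: {smiles!r}")
    if protonate:
        mol = _apply_ph74_protonation(mol)
    return Molecule(id=mol_id or smiles, rdmol=mol)


LibraryFormat = Literal["smiles", "sdf"]


def read_library(
    path: str | Path, format: LibraryFormat = "smiles", protonate: bool = True
) -> list[Molecule]:
    """Read a compound library; one :class:`Molecule` per valid record.

    SMILES files are one record per line (optional tab-separated id); SDF is
    V2000. Invalid records are skipped and counted in a single warning;
    ordering is preserved. A file with zero valid records yields an empty
    list, not an error.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"library file not found: {path}")
    mols: list[Molecule] = []
    skipped = 0
    if format == "smiles":
        for lineno, line in enumerate(path.read_text().splitlines(), start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            smiles = parts[0].strip()
            mol_id = parts[1].strip() if len(parts) > 1 else f"mol{lineno}"
            try:
                m = parse_molecule(smiles, mol_id=mol_id, protonate=protonate)
                m.source_line = lineno
                mols.append(m)
            except MoleculeParseError:
                skipped += 1
    elif format == "sdf":
        supplier = Chem.SDMolSupplier(str(path), sanitize=True, removeHs=True)
        for i, mol in enumerate(supplier):
            if mol is None:
                skipped += 1
                continue
            name = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
            if protonate:
                try:
                    mol = _apply_ph74_protonation(mol)
                except Exception:
                    skipped += 1
                    continue
            mols.append(Molecule(id=name or f"mol{i + 1}", rdmol=mol, source_line=i + 1))
    else:
        raise ValueError(f"unknown library format: {format!r}")
    if skipped:
        warnings.warn(f"skipped {skipped} invalid record(s) in {path.name}")
    return mols


def write_library(molecules: Iterable[Molecule], path: str | Path,
                  format: LibraryFormat = "smiles") -> None:
    """Write a library as SMILES lines or SDF V2000 (2D coordinates)."""
    path = Path(path)
    if format == "smiles":
        lines = [f"{m.smiles}\t{m.id}" for m in molecules]
        path.write_text("\n".join(lines) + "\n")
    elif format == "sdf":
        writer = Chem.SDWriter(str(path))
        writer.SetForceV3000(False)
        for m in molecules:
            mol = Chem.Mol(m.rdmol)
            if mol.GetNumConformers() == 0:
                AllChem.Compute2DCoords(mol)
            mol.SetProp("_Name", m.id)
            writer.write(mol)
        writer.close()
    else:
        raise ValueError(f"unknown library format: {format!r}")


# -- properties --------------------------------------------------------------

def compute_properties(m: Molecule) -> MolProperties:
    """Drug-likeness properties: MW (implicit H included), HBD/HBA counts
    (Lipinski N-H/O-H and N/O rules), Crippen LogP.

    Conformation-independent by construction: only the molecular graph is
    consulted.
    """
    return MolProperties(
        mol_weight=Descriptors.MolWt(m.rdmol),
        hbd_count=Lipinski.NumHDonors(m.rdmol),
        hba_count=Lipinski.NumHAcceptors(m.rdmol),
        logp=Crippen.MolLogP(m.rdmol),
    )


# -- conformers --------------------------------------------------------------

class EmbeddingError(RuntimeError):
    """Raised when a molecule cannot be embedded in 3D."""


def generate_conformers(m: Molecule, cfg: ConformerConfig | None = None) -> ConformerEnsemble:
    """Generate a bounded conformer ensemble.

    ETKDG embedding (explicit hydrogens, fixed seed) followed by MMFF94
    minimization; conformers whose strain energy exceeds ``cfg.energy_window``
    kcal/mol above the ensemble minimum are discarded and the count is capped
    at ``cfg.max_conformers``. Deterministic for a fixed seed.
    """
    cfg = cfg or ConformerConfig()
    molh = Chem.AddHs(m.rdmol)
    params = AllChem.ETKDGv3()
    params.randomSeed = cfg.seed
    params.pruneRmsThresh = cfg.prune_rms_threshold
    params.numThreads = 1
    conf_ids = AllChem.EmbedMultipleConfs(molh, numConfs=cfg.max_conformers, params=params)
    if len(conf_ids) == 0:
        raise EmbeddingError(f"3D embedding failed for molecule {m.id!r}")

    energies: list[float] = []
    if AllChem.MMFFHasAllMoleculeParams(molh):
        results = AllChem.MMFFOptimizeMoleculeConfs(molh, maxIters=500)
        energies = [e for _converged, e in results]
    else:  # exotic atoms: fall back to UFF
        results = AllChem.UFFOptimizeMoleculeConfs(molh, maxIters=500)
        energies = [e for _converged, e in results]

    e_min = min(energies)
    rel = [e - e_min for e in energies]
    keep = [i for i, e in enumerate(rel) if e <= cfg.energy_window]
    # sort retained conformers by strain energy, minimum first
    keep.sort(key=lambda i: (rel[i], i))
    keep = keep[: cfg.max_conformers]

    coords = [
        np.array(molh.GetConformer(conf_ids[i]).GetPositions(), dtype=float)
        for i in keep
    ]
    return ConformerEnsemble(
        molecule=m,
        rdmol_h=molh,
        coordinates=coords,
        energies=[rel[i] for i in keep],
    )


# -- activity tables ---------------------------------------------------------

def read_activity_table(path: str | Path):
    """Read a CSV activity table with header ``compound_id,ic50_uM``."""
    import pandas as pd

    df = pd.read_csv(path)
    required = {"compound_id", "ic50_uM"}
    if not required.issubset(df.columns):
        raise ValueError(f"activity table must have columns {sorted(required)}")
    if (df["ic50_uM"] <= 0).any():
        raise ValueError("IC50 values must be positive")
    return df
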