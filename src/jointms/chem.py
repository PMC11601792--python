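"""Molecule handling: parsing, graph featurization, fingerprints, formulas.

Molecules are parsed with RDKit and carried around as lightweight records
(canonical SMILES, InChIKey, Hill formula). For the graph encoder each
molecule becomes a :class:`MolGraph`: per-atom and per-bond feature matrices
over the heavy-atom skeleton, with atoms in RDKit canonical order so that two
SMILES spellings of the same structure yield byte-identical graphs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import rdMolDescriptors
from rdkit.Chem import rdFingerprintGenerator

RDLogger.DisableLog("rdApp.*")

PROTON_MASS = 1.00728  # Da, mass of H+ for the [M+H]+ adduct

ELEMENTS = ("C", "N", "O", "S", "P", "F", "Cl", "Br", "I", "H", "other")
_CHIRALITY = (
    Chem.ChiralType.CHI_TETRAHEDRAL_CW,
    Chem.ChiralType.CHI_TETRAHEDRAL_CCW,
)
_BOND_TYPES = (
    Chem.BondType.SINGLE,
    Chem.BondType.DOUBLE,
    Chem.BondType.TRIPLE,
    Chem.BondType.AROMATIC,
)
_BOND_STEREO = (Chem.BondStereo.STEREOZ, Chem.BondStereo.STEREOE)


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed into a molecule."""


@dataclass(frozen=True)
class Molecule:
    """A small molecule: canonical SMILES plus identity and formula."""

    smiles: str
    inchikey: str
    formula: str
    id: str

    def rdkit_mol(self) -> Chem.Mol:
        return Chem.MolFromSmiles(self.smiles)


@dataclass
class FeatureConfig:
    """Featurization settings shared by every graph fed to one encoder.

    standardize scales the unbounded scalar node features (atomic mass,
    valence, degree, hydrogen count) to order 1. The default keeps them on
    their natural scales: letting atomic mass dominate the feature vector
    makes mass-additive structure easier for the graph layers to pick up,
    which is what fragment peaks are made of.
    """

    elements: tuple = ELEMENTS
    standardize: bool = False

    @property
    def node_dim(self) -> int:
        # one-hot elements + mass + valence + ring + charge + radicals
        # + chirality one-hot(3) + degree + numH + aromatic
        return len(self.elements) + 1 + 1 + 1 + 1 + 1 + 3 + 1 + 1 + 1

    @property
    def edge_dim(self) -> int:
        # bond type one-hot(4) + ring + conjugated + stereo one-hot(3)
        return 4 + 1 + 1 + 3


@dataclass
class MolGraph:
    """Attributed undirected molecular graph for the encoder.

    node_features: (n_atoms, node_dim); edge_features: (n_directed_edges,
    edge_dim); edges: (n_directed_edges, 2) array of (src, dst) with both
    directions of every bond present.
    """

    node_features: np.ndarray
    edge_features: np.ndarray
    edges: np.ndarray

    @property
    def n_nodes(self) -> int:
        return self.node_features.shape[0]

    @property
    def n_bonds(self) -> int:
        return self.edges.shape[0] // 2


@dataclass(frozen=True)
class Fingerprint:
    """ECFP-style circular fingerprint as a fixed-length bit vector."""

    bits: np.ndarray
    nbits: int
    radius: int


def parse_molecule(smiles: str, mol_id: str | None = None) -> Molecule:
    """Parse a SMILES string into a Molecule with canonical identity fields."""
    if not smiles:
        raise SmilesParseError("empty SMILES string")
    rd = Chem.MolFromSmiles(smiles)
    if rd is None or rd.GetNumHeavyAtoms() < 1:
        raise SmilesParseError(f"could not parse SMILES: {smiles!r}")
    canonical = Chem.MolToSmiles(rd)
    inchikey = Chem.MolToInchiKey(rd)
    formula = rdMolDescriptors.CalcMolFormula(rd)
    return Molecule(
        smiles=canonical,
        inchikey=inchikey,
        formula=formula,
        id=mol_id if mol_id is not None else inchikey,
    )


def molecular_formula(mol: Molecule) -> str:
    """Hill-notation molecular formula, hydrogens included."""
    return rdMolDescriptors.CalcMolFormula(mol.rdkit_mol())


def _one_hot(value, choices) -> list:
    v = [0.0] * (len(choices) + 1)
    try:
        v[choices.index(value)] = 1.0
    except ValueError:
        v[-1] = 1.0
    return v


def build_graph(mol: Molecule, config: FeatureConfig | None = None) -> MolGraph:
    """Build the attributed heavy-atom graph consumed by the molecular encoder.

    Atoms are renumbered into RDKit canonical order first, so isomorphic
    inputs produce identical (not merely isomorphic) graphs.
    """
    config = config or FeatureConfig()
    rd = mol.rdkit_mol()
    if rd is None:
        raise SmilesParseError(f"could not parse SMILES: {mol.smiles!r}")
    order = tuple(
        int(i)
        for i in np.argsort(list(Chem.CanonicalRankAtoms(rd, breakTies=True)))
    )
    rd = Chem.RenumberAtoms(rd, order)

    mass_scale = 100.0 if config.standardize else 1.0
    count_scale = 4.0 if config.standardize else 1.0

    nodes = []
    for atom in rd.GetAtoms():
        feats = list(_one_hot(atom.GetSymbol(), list(config.elements[:-1])))
        feats += [
            atom.GetMass() / mass_scale,
            atom.GetTotalValence() / count_scale,
            1.0 if atom.IsInRing() else 0.0,
            float(atom.GetFormalCharge()),
            float(atom.GetNumRadicalElectrons()),
        ]
        chir = [0.0, 0.0, 0.0]
        if atom.GetChiralTag() in _CHIRALITY:
            chir[_CHIRALITY.index(atom.GetChiralTag())] = 1.0
        else:
            chir[2] = 1.0
        feats += chir
        feats += [
            atom.GetDegree() / count_scale,
            atom.GetTotalNumHs() / count_scale,
            1.0 if atom.GetIsAromatic() else 0.0,
        ]
        nodes.append(feats)

    edges = []
    efeats = []
    for bond in rd.GetBonds():
        bt = [0.0] * 4
        if bond.GetBondType() in _BOND_TYPES:
            bt[_BOND_TYPES.index(bond.GetBondType())] = 1.0
        stereo = [0.0, 0.0, 0.0]
        if bond.GetStereo() in _BOND_STEREO:
            stereo[_BOND_STEREO.index(bond.GetStereo())] = 1.0
        else:
            stereo[2] = 1.0
        f = bt + [
            1.0 if bond.IsInRing() else 0.0,
            1.0 if bond.GetIsConjugated() else 0.0,
        ] + stereo
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        edges.append((i, j))
        efeats.append(f)
        edges.append((j, i))
        efeats.append(f)

    node_features = np.asarray(nodes, dtype=np.float64)
    if edges:
        edge_features = np.asarray(efeats, dtype=np.float64)
        edge_index = np.asarray(edges, dtype=np.intp)
    else:
        edge_features = np.zeros((0, config.edge_dim), dtype=np.float64)
        edge_index = np.zeros((0, 2), dtype=np.intp)
    return MolGraph(node_features=node_features, edge_features=edge_features, edges=edge_index)


def fingerprint(mol: Molecule, radius: int = 2, nbits: int = 2048) -> Fingerprint:
    """ECFP (Morgan) fingerprint; defaults are the field's conventional 2/2048."""
    if radius not in (2, 3):
        raise ValueError("radius must be 2 or 3")
    if nbits < 256 or (nbits & (nbits - 1)) != 0:
        raise ValueError("nbits must be a power of two >= 256")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=nbits)
    bv = gen.GetFingerprintAsNumPy(mol.rdkit_mol())
    return Fingerprint(bits=bv.astype(bool), nbits=nbits, radius=radius)


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Jaccard index |a&b|/|a|b| on fingerprint bit sets."""
    if a.nbits != b.nbits:
        raise ValueError(f"fingerprint length mismatch: {a.nbits} != {b.nbits}")
    inter = np.count_nonzero(a.bits & b.bits)
    union = np.count_nonzero(a.bits | b.bits)
    return 1.0 if union == 0 else inter / union


# --- library I/O -----------------------------------------------------------

def write_library(molecules: list, path) -> None:
    """Write a molecule library as a tab-separated table (smiles, id, inchikey, formula)."""
    with open(path, "w") as fh:
        fh.write("smiles\tid\tinchikey\tformula\n")
        for m in molecules:
            fh.write(f"{m.smiles}\t{m.id}\t{m.inchikey}\t{m.formula}\n")


def read_library(path) -> list:
    """Read a molecule library written by :func:`write_library` or a bare SMILES list."""
    out = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        return out
    start = 1 if lines[0].lower().startswith("smiles") else 0
    for ln in lines[start:]:
        parts = ln.split("\t")
        smiles = parts[0]
        mol_id = parts[1] if len(parts) > 1 and parts[1] else None
        out.append(parse_molecule(smiles, mol_id=mol_id))
    return out
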