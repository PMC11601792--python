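"""Synthetic molecule libraries and simulated MS/MS spectra.

The generator emulates the statistical structure the annotation task needs,
without any physical fragmentation chemistry: a pool of small C/N/O molecules
grown as random valence-respecting trees (so molecular formulas collide and
candidate sets are non-trivial), and spectra whose peaks are a deterministic
function of molecular substructure — each acyclic single bond is cleaved and
both fragment masses appear as [fragment+H]+ peaks — plus Gaussian m/z
jitter, log-normal intensity noise, and Poisson-count spurious peaks.
Replicate spectra of one molecule share the true fragment peaks and differ
only in noise, emulating repeated measurement under different instrument
conditions. Everything is a pure function of the seed.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import Descriptors

from .chem import PROTON_MASS, Molecule, parse_molecule
from .spectra import Spectrum

_H_MASS = 1.007825  # monoisotopic hydrogen
_PT = Chem.GetPeriodicTable()

# substituent vocabulary for the combinatorial library: small groups that
# recur across molecules, so held-out molecules are new combinations of
# building blocks seen during training (the property that makes the
# structure->spectrum map learnable from a small library)
_SUBSTITUENTS = ("O", "N", "C", "CC", "OC", "CO", "NC", "C=O", "CCO", "CN")
_CHAIN_LENGTHS = (4, 5, 6)
_MAX_SUBSTITUENTS = 2


@dataclass
class SimConfig:
    """Conditions of the synthetic study.

    spectra_per_molecule is an inclusive integer range; the default (1, 3)
    emulates a library-like spectra-to-molecule ratio (roughly 2 spectra per
    molecule on average). library_multiplier controls how many same-formula
    decoys surround each target: the molecule pool has about
    n_molecules * library_multiplier members, and targets are drawn from
    multi-member formula buckets so candidate sets are never singletons.
    n_fragment_rules caps how many cleavage fragments contribute peaks.
    fragment_signal=False replaces the structure-derived peaks with pure
    noise (negative control: spectra carry no information about structure).
    """

    n_molecules: int = 50
    spectra_per_molecule: tuple = (1, 3)
    n_fragment_rules: int = 30
    noise_peaks: float = 2.0
    intensity_noise_cv: float = 0.25
    mz_jitter_sd: float = 0.01
    seed: int = 0
    library_multiplier: int = 30
    min_heavy_atoms: int = 5
    max_heavy_atoms: int = 12
    fragment_signal: bool = True

    def __post_init__(self):
        if self.n_molecules < 1 or self.n_fragment_rules < 1:
            raise ValueError("counts must be >= 1")
        lo, hi = self.spectra_per_molecule
        if lo < 1 or hi < lo:
            raise ValueError("spectra_per_molecule must be a range with 1 <= lo <= hi")


def _stable_hash(*parts) -> int:
    """Deterministic 32-bit hash (Python's hash() is salted per process)."""
    h = hashlib.md5("|".join(str(p) for p in parts).encode()).hexdigest()
    return int(h[:8], 16)


def _enumerate_scaffold_space() -> list:
    """All unique molecules in the chain-scaffold x substituent space.

    A linear carbon backbone (4-6 atoms) carries 1-2 substituents from the
    vocabulary at any positions (at most 2 on one carbon). The space is
    enumerated exhaustively and deduplicated by canonical SMILES, so it is
    identical on every call.
    """
    import itertools
    from collections import Counter as _Counter

    seen: set = set()
    out: list = []
    for chain_len in _CHAIN_LENGTHS:
        for n_sub in range(1, _MAX_SUBSTITUENTS + 1):
            for pos in itertools.combinations_with_replacement(range(chain_len), n_sub):
                if _Counter(pos).most_common(1)[0][1] > 2:
                    continue
                for subs in itertools.product(_SUBSTITUENTS, repeat=n_sub):
                    branches: dict[int, list] = {}
                    for p, s in zip(pos, subs):
                        branches.setdefault(p, []).append(s)
                    smi = "".join(
                        "C" + "".join(f"({b})" for b in branches.get(p, []))
                        for p in range(chain_len)
                    )
                    rd = Chem.MolFromSmiles(smi)
                    if rd is None:
                        continue
                    can = Chem.MolToSmiles(rd)
                    if can not in seen:
                        seen.add(can)
                        out.append(can)
    return out


def generate_library(config: SimConfig) -> list:
    """A deterministic pool of small molecules with colliding formulas.

    The pool is a seeded subsample (~n_molecules*library_multiplier) of the
    combinatorial scaffold space, filtered to the configured heavy-atom
    range; ids are assigned in a canonical order so the output is
    byte-stable per seed.
    """
    space = []
    for smi in _enumerate_scaffold_space():
        m = parse_molecule(smi)
        n_heavy = m.rdkit_mol().GetNumHeavyAtoms()
        if config.min_heavy_atoms <= n_heavy <= config.max_heavy_atoms:
            space.append(m)
    space.sort(key=lambda m: (m.formula, m.inchikey))
    pool_size = min(config.n_molecules * config.library_multiplier, len(space))
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x11B]))
    idx = sorted(rng.choice(len(space), size=pool_size, replace=False))
    return [
        Molecule(smiles=space[i].smiles, inchikey=space[i].inchikey,
                 formula=space[i].formula, id=f"M{j:04d}")
        for j, i in enumerate(idx)
    ]


def select_targets(library: list, config: SimConfig) -> list:
    """Pick the n_molecules targets, preferring large formula buckets.

    Targets always come from buckets with >=2 members when enough exist, so
    every target has at least one same-formula decoy to rank against. Within
    a bucket the target is drawn at seeded random — a deterministic position
    (e.g. always the canonically first member) would give targets a shared
    structural signature that a model can exploit without any spectrum
    information.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x7A6]))
    buckets: dict[str, list] = {}
    for m in library:
        buckets.setdefault(m.formula, []).append(m)
    ordered = sorted(buckets.values(), key=lambda b: (-len(b), b[0].formula))
    ordered = [[b[i] for i in rng.permutation(len(b))] for b in ordered]
    targets: list = []
    depth = 0
    while len(targets) < config.n_molecules:
        advanced = False
        for bucket in ordered:
            if len(targets) >= config.n_molecules:
                break
            if len(bucket) >= 2 and depth < len(bucket) - 1:
                targets.append(bucket[depth])
                advanced = True
        if not advanced:  # ran out of multi-member buckets; take singletons
            singles = [b[0] for b in ordered if len(b) == 1]
            targets.extend(singles[: config.n_molecules - len(targets)])
            break
        depth += 1
    if len(targets) < config.n_molecules:
        raise ValueError(
            f"library too small: {len(targets)} eligible targets "
            f"< n_molecules={config.n_molecules}"
        )
    return sorted(targets, key=lambda m: m.id)


def _true_fragments(mol: Molecule) -> list:
    """Deterministic fragment peak list [(mz, rel_intensity)] for a molecule.

    Each acyclic single bond is cleaved; both sides appear as [side+H]+ at
    the sum of their atomic monoisotopic masses (implicit hydrogens included)
    plus a proton. Ring systems survive cleavage intact. Relative intensities
    are a stable hash of the fragment, so they are reproducible but vary
    across fragments. The intact [M+H]+ ion is always present at full height.
    """
    rd = mol.rdkit_mol()
    atom_mass = [
        _PT.GetMostCommonIsotopeMass(a.GetSymbol()) + a.GetTotalNumHs() * _H_MASS
        for a in rd.GetAtoms()
    ]
    n = rd.GetNumAtoms()
    adj = {i: [] for i in range(n)}
    cleavable = []
    for b in rd.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        adj[i].append(j)
        adj[j].append(i)
        if not b.IsInRing() and b.GetBondType() == Chem.BondType.SINGLE:
            cleavable.append((i, j))

    peaks = []
    total = sum(atom_mass)
    # intact [M+H]+ at modest height: within a candidate set it is common to
    # every member, so letting it dominate would wash out the discriminative
    # fragment peaks
    peaks.append((total + PROTON_MASS, 0.45))
    for (i, j) in cleavable:
        # atoms on i's side of the cut bond
        side = {i}
        stack = [i]
        while stack:
            a = stack.pop()
            for nb in adj[a]:
                if (a, nb) in ((i, j), (j, i)):
                    continue
                if nb not in side:
                    side.add(nb)
                    stack.append(nb)
        for atoms in (side, set(range(n)) - side):
            mass = sum(atom_mass[a] for a in atoms)
            if mass < 15:  # below CH3; lighter fragments are not informative
                continue
            u = _stable_hash(mol.inchikey, round(mass, 4)) / 2**32
            peaks.append((mass + PROTON_MASS, 0.25 + 0.7 * u))
    # deduplicate identical fragment masses, keep the tallest
    dedup: dict[float, float] = {}
    for mz, inten in peaks:
        key = round(mz, 5)
        dedup[key] = max(dedup.get(key, 0.0), inten)
    return sorted(dedup.items(), key=lambda t: (-t[1], t[0]))


def simulate_spectrum(mol: Molecule, config: SimConfig, replicate: int = 0) -> Spectrum:
    """One simulated [M+H]+ spectrum of a molecule.

    Replicates share the deterministic fragment peaks and differ in
    log-normal intensity noise, Gaussian m/z jitter and spurious peaks. The
    noise stream depends only on (seed, molecule, replicate), so the output
    is independent of call order.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, _stable_hash(mol.inchikey), replicate])
    )
    rd = mol.rdkit_mol()
    precursor = Descriptors.ExactMolWt(rd) + PROTON_MASS

    peaks = []
    if config.fragment_signal:
        frags = _true_fragments(mol)
        keep = frags[: config.n_fragment_rules + 1]  # +1 keeps [M+H]+
        for mz, inten in keep:
            if config.intensity_noise_cv > 0:
                sigma = math.sqrt(math.log(1 + config.intensity_noise_cv**2))
                inten *= rng.lognormal(mean=-sigma**2 / 2, sigma=sigma)
            if config.mz_jitter_sd > 0:
                mz += rng.normal(0, config.mz_jitter_sd)
            peaks.append((max(mz, 1.0), inten))
        n_noise = rng.poisson(config.noise_peaks)
    else:
        n_noise = 6 + rng.poisson(max(config.noise_peaks, 2.0))
    for _ in range(n_noise):
        peaks.append((
            float(rng.uniform(20.0, precursor + 0.5)),
            float(rng.uniform(0.05, 0.4)),
        ))
    peaks.sort()
    return Spectrum(
        peaks=np.asarray(peaks),
        precursor_mz=float(precursor),
        adduct="[M+H]+",
        molecule_id=mol.id,
        spectrum_id=f"{mol.id}_r{replicate}",
        collision_energy=10.0 * (replicate + 1),
    )


@dataclass
class SimDataset:
    """A complete synthetic study: decoy-rich library, targets, and spectra."""

    library: list
    targets: list
    spectra: list
    config: SimConfig


def generate_dataset(config: SimConfig | None = None) -> SimDataset:
    """Library + targets + replicate spectra, fully determined by the seed."""
    config = config or SimConfig()
    library = generate_library(config)
    targets = select_targets(library, config)
    lo, hi = config.spectra_per_molecule
    spectra = []
    for mol in targets:
        n_rep = int(
            np.random.default_rng(
                np.random.SeedSequence([config.seed, _stable_hash(mol.inchikey), 0x5EC])
            ).integers(lo, hi + 1)
        )
        for rep in range(n_rep):
            spectra.append(simulate_spectrum(mol, config, replicate=rep))
    return SimDataset(library=library, targets=targets, spectra=spectra, config=config)


@dataclass
class Split:
    """Structure-disjoint train/test partition; all spectra of a molecule
    travel together."""

    train_molecules: list
    test_molecules: list
    train_spectra: list
    test_spectra: list


def make_split(targets: list, spectra: list, test_fraction: float = 0.2,
               seed: int = 0) -> Split:
    """Partition molecules (and their spectra) so no InChIKey crosses sides."""
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    n_test = int(round(test_fraction * len(targets)))
    if n_test < 1 or n_test >= len(targets):
        raise ValueError(
            f"library too small for test_fraction={test_fraction} "
            f"({len(targets)} molecules)"
        )
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5711]))
    order = rng.permutation(len(targets))
    test_keys = {targets[i].inchikey for i in order[:n_test]}
    train_mols = [m for m in targets if m.inchikey not in test_keys]
    test_mols = [m for m in targets if m.inchikey in test_keys]
    by_key = {m.inchikey: m for m in targets}
    train_spec, test_spec = [], []
    mol_by_id = {m.id: m for m in targets}
    for s in spectra:
        mol = mol_by_id[s.molecule_id]
        (test_spec if mol.inchikey in test_keys else train_spec).append(s)
    return Split(train_molecules=train_mols, test_molecules=test_mols,
                 train_spectra=train_spec, test_spectra=test_spec)
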