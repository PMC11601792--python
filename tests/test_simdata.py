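"""Synthetic library, spectrum simulator and structure-disjoint splits."""

import numpy as np
import pytest
from collections import Counter

from jointms.chem import PROTON_MASS, parse_molecule
from jointms.simdata import (SimConfig, generate_dataset, generate_library,
                             make_split, select_targets, simulate_spectrum,
                             _true_fragments)

H = 1.007825
C = 12.0
O = 15.994915
N = 14.003074


@pytest.fixture(scope="module")
def default_library():
    return generate_library(SimConfig(seed=0))


def test_library_deterministic(default_library):
    again = generate_library(SimConfig(seed=0))
    assert [m.smiles for m in again] == [m.smiles for m in default_library]
    other = generate_library(SimConfig(seed=1))
    assert [m.smiles for m in other] != [m.smiles for m in default_library]


def test_library_molecules_valid_with_isomer_rich_formulas(default_library):
    assert all(parse_molecule(m.smiles) for m in default_library[:50])
    buckets = Counter(m.formula for m in default_library)
    multi = sum(1 for c in buckets.values() if c >= 2)
    assert multi / len(buckets) >= 0.2


def test_targets_have_decoys(default_library):
    cfg = SimConfig(seed=0)
    targets = select_targets(default_library, cfg)
    assert len(targets) == cfg.n_molecules
    buckets = Counter(m.formula for m in default_library)
    assert all(buckets[t.formula] >= 2 for t in targets)


def test_zero_noise_replicates_identical(default_library):
    cfg = SimConfig(seed=0, noise_peaks=0.0, intensity_noise_cv=0.0, mz_jitter_sd=0.0)
    mol = default_library[0]
    a = simulate_spectrum(mol, cfg, replicate=0)
    b = simulate_spectrum(mol, cfg, replicate=1)
    np.testing.assert_array_equal(a.peaks, b.peaks)


def test_ethanol_fragments_hand_enumerated():
    """Ethanol CH3-CH2-OH: cleaving C-C gives CH3 / CH2OH, cleaving C-O
    gives C2H5 / OH; every side >= 15 Da appears as [side + H]+ along with
    the [M+H]+ ion."""
    ethanol = parse_molecule("CCO")
    frags = dict(_true_fragments(ethanol))
    masses = sorted(frags)
    ch3 = C + 3 * H
    ch2oh = C + 2 * H + O + H
    c2h5 = 2 * C + 5 * H
    oh = O + H
    m = 2 * C + 6 * H + O
    expected = sorted(x + PROTON_MASS for x in [ch3, ch2oh, c2h5, oh, m])
    assert len(masses) == len(expected)
    np.testing.assert_allclose(masses, expected, atol=1e-4)


def test_isomers_have_distinct_zero_noise_peaks(default_library):
    buckets = {}
    for mol in default_library:
        buckets.setdefault(mol.formula, []).append(mol)
    pair = next(b for b in buckets.values() if len(b) >= 2)
    pa = {round(mz, 3) for mz, _ in _true_fragments(pair[0])}
    pb = {round(mz, 3) for mz, _ in _true_fragments(pair[1])}
    assert pa != pb


def test_signal_free_spectra_carry_no_fragments(default_library):
    cfg = SimConfig(seed=0, fragment_signal=False)
    mol = default_library[0]
    s = simulate_spectrum(mol, cfg, replicate=0)
    true_masses = {round(mz, 2) for mz, _ in _true_fragments(mol)}
    observed = {round(mz, 2) for mz in s.mz}
    # random peaks may graze a true bin, but not reproduce the set
    assert len(true_masses & observed) <= 1


def test_dataset_spectra_counts_and_linkage():
    cfg = SimConfig(n_molecules=12, library_multiplier=10, seed=3)
    sim = generate_dataset(cfg)
    per_mol = Counter(s.molecule_id for s in sim.spectra)
    lo, hi = cfg.spectra_per_molecule
    assert set(per_mol) == {m.id for m in sim.targets}
    assert all(lo <= c <= hi for c in per_mol.values())


def test_structure_disjoint_split():
    sim = generate_dataset(SimConfig(n_molecules=20, library_multiplier=10, seed=2))
    split = make_split(sim.targets, sim.spectra, test_fraction=0.2, seed=2)
    assert len(split.test_molecules) == 4
    train_keys = {m.inchikey for m in split.train_molecules}
    test_keys = {m.inchikey for m in split.test_molecules}
    assert not (train_keys & test_keys)
    # spectra travel with their molecule
    test_ids = {m.id for m in split.test_molecules}
    assert all(s.molecule_id in test_ids for s in split.test_spectra)
    per_mol_all = Counter(s.molecule_id for s in sim.spectra)
    per_mol_test = Counter(s.molecule_id for s in split.test_spectra)
    for mid, n in per_mol_test.items():
        assert n == per_mol_all[mid]
    # deterministic per seed
    again = make_split(sim.targets, sim.spectra, test_fraction=0.2, seed=2)
    assert [m.id for m in again.test_molecules] == [m.id for m in split.test_molecules]


def test_split_too_small_errors():
    sim = generate_dataset(SimConfig(n_molecules=3, library_multiplier=10, seed=2))
    with pytest.raises(ValueError):
        make_split(sim.targets, sim.spectra, test_fraction=0.01, seed=0)
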