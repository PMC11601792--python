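"""Candidate retrieval, ranking, rank@k and similarity diagnostics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from jointms import annotate
from jointms.annotate import (FormulaLibrary, RankingResult, rank_at_k,
                              rank_candidates, retrieve_candidates,
                              similarity_distributions, sorted_training_candidates)
from jointms.chem import FeatureConfig, parse_molecule
from jointms.encoders import Checkpoint, EncoderConfig, init_parameters
from jointms.spectra import Spectrum


@pytest.fixture(scope="module")
def library():
    mols = [parse_molecule(s, mol_id=i) for s, i in [
        ("CCO", "ethanol"), ("COC", "ether"), ("c1ccccc1", "benzene"),
        ("CC(=O)O", "acetic"), ("OCC=O", "glycolaldehyde"),
    ]]
    return FormulaLibrary(mols)


def test_retrieve_candidates_by_formula(library):
    target = next(m for m in library.molecules if m.id == "ethanol")
    cs = retrieve_candidates(target, library)
    assert {c.id for c in cs.candidates} == {"ethanol", "ether"}
    # singleton formula
    benz = next(m for m in library.molecules if m.id == "benzene")
    assert [c.id for c in retrieve_candidates(benz, library).candidates] == ["benzene"]
    # bucket size conserved
    assert len(cs.candidates) == len(library.bucket(target.formula))


def test_retrieve_missing_target_errors(library):
    stranger = parse_molecule("CCCCCCCC", mol_id="octane")
    with pytest.raises(ValueError):
        retrieve_candidates(stranger, library)


def test_training_candidates_sorted_and_exclude_target(library):
    target = next(m for m in library.molecules if m.id == "ethanol")
    cs = sorted_training_candidates(target, library)
    assert all(c.inchikey != target.inchikey for c in cs.candidates)
    assert cs.tanimoto_to_target == sorted(cs.tanimoto_to_target, reverse=True)


@pytest.fixture(scope="module")
def model():
    fc = FeatureConfig()
    ec = EncoderConfig(gcn_layers=2, hidden_dim=16, embed_dim=8, dropout=0.0)
    params = init_parameters(ec, fc, np.random.default_rng(0))
    return Checkpoint(params=params, encoder_config=ec, feature_config=fc)


def query(mol_id="ethanol"):
    return Spectrum(peaks=np.array([[31.0, 50.0], [47.0, 99.0]]),
                    spectrum_id="q1", molecule_id=mol_id)


def test_rank_singleton_target_first(library, model):
    benz = next(m for m in library.molecules if m.id == "benzene")
    res = rank_candidates(query(), retrieve_candidates(benz, library), model,
                          target_id="benzene")
    assert res.target_rank == 1


def test_rank_deduplicates_inchikey(library, model):
    target = next(m for m in library.molecules if m.id == "ethanol")
    cs = retrieve_candidates(target, library)
    cs.candidates = cs.candidates + [cs.candidates[0]]  # duplicate entry
    res = rank_candidates(query(), cs, model, target_id=target.id)
    assert len(res.ranking) == 2
    scores = [s for _, s in res.ranking]
    assert scores == sorted(scores, reverse=True)


def test_cosine_vs_dot_product_ranking(library, model, monkeypatch):
    """Scaling one candidate's embedding flips dot-product order but never
    cosine order — the mechanism behind comparing the two ranking modes."""
    target = next(m for m in library.molecules if m.id == "ethanol")
    cs = retrieve_candidates(target, library)
    zq = np.array([1.0, 0.0])
    # candidate A: well aligned, small norm; candidate B: worse aligned, huge norm
    embs = {"ethanol": np.array([0.9, 0.1]), "ether": np.array([30.0, 25.0])}

    monkeypatch.setattr(annotate, "_embed_spectrum", lambda s, m: zq)
    monkeypatch.setattr(annotate, "_embed_molecules",
                        lambda mols, m: np.stack([embs[x.id] for x in mols]))
    cos = rank_candidates(query(), cs, model, fn="cosine", target_id="ethanol")
    dot = rank_candidates(query(), cs, model, fn="dot_product", target_id="ethanol")
    assert cos.target_rank == 1
    assert dot.target_rank == 2


def test_pessimistic_tie_handling(library, model, monkeypatch):
    """Exactly tied scores count against the target."""
    target = next(m for m in library.molecules if m.id == "ethanol")
    cs = retrieve_candidates(target, library)
    monkeypatch.setattr(annotate, "_embed_spectrum", lambda s, m: np.array([1.0, 0.0]))
    monkeypatch.setattr(annotate, "_embed_molecules",
                        lambda mols, m: np.tile([[0.5, 0.5]], (len(mols), 1)))
    res = rank_candidates(query(), cs, model, target_id="ethanol")
    assert res.target_rank == len(res.ranking)


def rr(ranks):
    return [RankingResult(spectrum_id=str(i), ranking=[], target_rank=r,
                          ranking_function="cosine") for i, r in enumerate(ranks)]


def test_rank_at_k_examples():
    results = rr([1, 3, 21, 2])
    assert rank_at_k(results, 5) == 75.0
    assert rank_at_k(results, 2) == 50.0
    assert rank_at_k(results, 100) == 100.0
    assert rank_at_k(rr([2, 2, 2]), 1) == 0.0
    with pytest.raises(ValueError):
        rank_at_k([], 1)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.lists(st.integers(1, 50), min_size=1, max_size=30))
def test_rank_at_k_monotone(ranks):
    results = rr(ranks)
    values = [rank_at_k(results, k) for k in range(1, 55)]
    assert all(b >= a for a, b in zip(values, values[1:]))
    assert values[-1] == 100.0


def test_similarity_distributions_identical_groups(library, model):
    target = next(m for m in library.molecules if m.id == "benzene")
    spectra = [query("benzene"), query("benzene")]
    d = similarity_distributions(spectra, {"benzene": target}, library, model)
    # benzene has no same-formula decoys: candidate list empty, matching has 2
    assert len(d.matching) == 2 and len(d.candidates) == 0
    assert d.matching[0] == pytest.approx(d.matching[1])
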