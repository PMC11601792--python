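"""Candidate retrieval and ranking for spectrum annotation.

At inference a query spectrum is embedded once, every candidate molecule
sharing the target's molecular formula is embedded, and candidates are sorted
by similarity to the spectrum embedding — cosine by default, raw dot product
as an alternative ranking function for magnitude-sensitivity comparisons.
The reported target rank is pessimistic: ties count against the target.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chem import Molecule, build_graph, fingerprint, tanimoto
from .encoders import Checkpoint, batch_graphs, mol_forward, spec_forward
from .spectra import Spectrum, bin_spectrum


@dataclass
class CandidateSet:
    """Same-formula candidate molecules for one target.

    At inference time the target itself is a member (it must be rankable);
    tanimoto_to_target is populated only when built for training-time
    regularization, where the target is excluded.
    """

    target_id: str
    candidates: list
    tanimoto_to_target: list | None = None


class FormulaLibrary:
    """A molecule collection indexed by Hill formula for candidate retrieval."""

    def __init__(self, molecules: list):
        self.molecules = list(molecules)
        self._by_formula: dict[str, list] = {}
        for m in self.molecules:
            self._by_formula.setdefault(m.formula, []).append(m)

    def bucket(self, formula: str) -> list:
        return list(self._by_formula.get(formula, []))

    def mean_bucket_size(self) -> float:
        return float(np.mean([len(v) for v in self._by_formula.values()]))


def retrieve_candidates(target: Molecule, library) -> CandidateSet:
    """All library molecules sharing the target's formula, target included."""
    if not isinstance(library, FormulaLibrary):
        library = FormulaLibrary(library)
    cands = library.bucket(target.formula)
    if not any(c.inchikey == target.inchikey for c in cands):
        raise ValueError(
            f"target {target.id} ({target.formula}) not present in its own library"
        )
    return CandidateSet(target_id=target.id, candidates=cands)


def sorted_training_candidates(target: Molecule, library) -> CandidateSet:
    """Training-time candidate set: target excluded, sorted by Tanimoto descending."""
    if not isinstance(library, FormulaLibrary):
        library = FormulaLibrary(library)
    cands = [c for c in library.bucket(target.formula) if c.inchikey != target.inchikey]
    fp_t = fingerprint(target)
    scored = sorted(((tanimoto(fp_t, fingerprint(c)), c) for c in cands),
                    key=lambda t: (-t[0], t[1].id))
    return CandidateSet(target_id=target.id,
                        candidates=[c for _, c in scored],
                        tanimoto_to_target=[s for s, _ in scored])


@dataclass
class RankingResult:
    """Ordered candidate list for one query spectrum."""

    spectrum_id: str
    ranking: list  # list of (candidate_id, score), scores non-increasing
    target_rank: int | None
    ranking_function: str  # "cosine" | "dot_product"


def _embed_spectrum(spec: Spectrum, model: Checkpoint) -> np.ndarray:
    binned = bin_spectrum(spec)
    return spec_forward(model.params, binned.values[None, :],
                        model.encoder_config).data[0]


def _embed_molecules(mols: list, model: Checkpoint) -> np.ndarray:
    graphs = [build_graph(m, model.feature_config) for m in mols]
    return mol_forward(model.params, batch_graphs(graphs), model.encoder_config).data


def rank_candidates(query: Spectrum, cands: CandidateSet, model: Checkpoint,
                    fn: str = "cosine", target_id: str | None = None) -> RankingResult:
    """Rank a candidate set against a query spectrum.

    Duplicate candidates (same InChIKey) are collapsed before ranking. The
    target's reported rank is 1 + the number of other candidates scoring >=
    the target (ties counted against it); the listed order breaks exact ties
    by candidate id for reproducibility.
    """
    if fn not in ("cosine", "dot_product"):
        raise ValueError(f"unknown ranking function {fn!r}")
    if not cands.candidates:
        raise ValueError("empty candidate set")
    seen: dict[str, Molecule] = {}
    for c in cands.candidates:
        seen.setdefault(c.inchikey, c)
    mols = list(seen.values())

    zq = _embed_spectrum(query, model)
    zc = _embed_molecules(mols, model)
    if fn == "cosine":
        scores = (zc @ zq) / (np.linalg.norm(zc, axis=1) * np.linalg.norm(zq))
    else:
        scores = zc @ zq

    order = sorted(range(len(mols)), key=lambda i: (-scores[i], mols[i].id))
    ranking = [(mols[i].id, float(scores[i])) for i in order]

    tid = target_id if target_id is not None else cands.target_id
    target_rank = None
    target_pos = [i for i, m in enumerate(mols) if m.id == tid]
    if target_pos:
        ts = scores[target_pos[0]]
        target_rank = 1 + sum(
            1 for i, m in enumerate(mols) if m.id != tid and scores[i] >= ts
        )
    return RankingResult(spectrum_id=query.spectrum_id or "", ranking=ranking,
                         target_rank=target_rank, ranking_function=fn)


def rank_at_k(results: list, k: int) -> float:
    """Percentage of queries whose target ranks at k or better."""
    if not results:
        raise ValueError("no ranking results")
    ranks = [r.target_rank for r in results]
    if any(r is None for r in ranks):
        raise ValueError("every result needs a known target rank")
    return 100.0 * sum(1 for r in ranks if r <= k) / len(ranks)


def rank_curve(results: list, ks=(1, 5, 20)) -> dict:
    return {k: rank_at_k(results, k) for k in ks}


@dataclass
class SimilarityDistributions:
    """Cosine similarities of matching pairs vs candidate (non-matching) pairs."""

    matching: np.ndarray
    candidates: np.ndarray

    @property
    def matching_mean(self) -> float:
        return float(np.mean(self.matching))

    @property
    def matching_sd(self) -> float:
        return float(np.std(self.matching, ddof=1)) if len(self.matching) > 1 else 0.0

    @property
    def candidate_mean(self) -> float:
        return float(np.mean(self.candidates))

    @property
    def candidate_sd(self) -> float:
        return float(np.std(self.candidates, ddof=1)) if len(self.candidates) > 1 else 0.0

    @property
    def separation(self) -> float:
        return self.matching_mean - self.candidate_mean


def similarity_distributions(spectra: list, molecules_by_id: dict, library,
                             model: Checkpoint) -> SimilarityDistributions:
    """Empirical cosine distributions for matched pairs and same-formula decoys.

    Non-matching partners are restricted to the target's candidate molecules
    (same formula, different InChIKey), the hardest decoys.
    """
    if not isinstance(library, FormulaLibrary):
        library = FormulaLibrary(library)
    match, cand = [], []
    emb_cache: dict[str, np.ndarray] = {}

    def mol_embedding(m):
        if m.id not in emb_cache:
            emb_cache[m.id] = _embed_molecules([m], model)[0]
        return emb_cache[m.id]

    for spec in spectra:
        target = molecules_by_id[spec.molecule_id]
        zq = _embed_spectrum(spec, model)
        zt = mol_embedding(target)
        match.append(np.dot(zq, zt) / (np.linalg.norm(zq) * np.linalg.norm(zt)))
        for c in library.bucket(target.formula):
            if c.inchikey == target.inchikey:
                continue
            zc = mol_embedding(c)
            cand.append(np.dot(zq, zc) / (np.linalg.norm(zq) * np.linalg.norm(zc)))
    return SimilarityDistributions(matching=np.asarray(match),
                                   candidates=np.asarray(cand))


def write_rankings(results: list, path, top: int | None = None) -> None:
    """Tab-separated (spectrum_id, rank, candidate_id, score) table."""
    with open(path, "w") as fh:
        fh.write("spectrum_id\trank\tcandidate_id\tscore\n")
        for r in results:
            rows = r.ranking if top is None else r.ranking[:top]
            for pos, (cid, score) in enumerate(rows, start=1):
                fh.write(f"{r.spectrum_id}\t{pos}\t{cid}\t{score:.6f}\n")
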