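"""Contrastive training of the joint embedding space.

The objective is spectrum-anchored InfoNCE over a batch of k matched
(spectrum, molecule) pairs: the discriminator h(zspec, zmol) =
exp(cosine(zspec, zmol)/tau) scores every pairing, and each spectrum must
assign its own molecule the largest share of the batch softmax. A
regularization term — the mean cosine similarity between each spectrum and
the k_aug same-formula candidate molecules most Tanimoto-similar to its
target — is switched on for the last few percent of epochs and minimized, so
near-duplicate candidates are pushed away from the spectra. The total loss is
alpha*L_contrastive + beta*L_regularization with (alpha, beta) = (1.0, 0.0)
before the switch-on epoch and (0.9, 0.1) after.

Candidates are consumed sequentially: each spectrum keeps a cursor into its
target's Tanimoto-sorted candidate list and advances k_aug positions per
epoch, wrapping at the end, so successive epochs regularize against
successively less similar candidates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from . import _autograd as ag
from ._autograd import Tensor
from . import encoders as enc
from .chem import FeatureConfig, MolGraph, Molecule, build_graph, fingerprint, tanimoto
from .encoders import Checkpoint, EncoderConfig, GraphBatch, batch_graphs
from .spectra import BinnedSpectrum, Spectrum, bin_spectrum


@dataclass
class LossConfig:
    """Loss and optimization hyperparameters.

    tau is the softmax temperature (lower sharpens the contrast between
    matching and non-matching pairs). reg_start_fraction is the fraction of
    epochs trained before regularization switches on (default: the last 3%
    of epochs are regularized, with alpha_reg/beta_reg = 0.9/0.1).
    """

    tau: float = 0.15
    alpha: float = 1.0
    beta: float = 0.0
    alpha_reg: float = 0.9
    beta_reg: float = 0.1
    kaug: int = 16
    symmetric: bool = False  # add a molecule-anchored InfoNCE term (non-standard)
    reg_start_fraction: float = 0.97
    batch_size: int = 16
    epochs: int = 30
    learning_rate: float = 1e-3
    weight_decay: float = 1e-3
    seed: int = 0

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("temperature tau must be > 0")
        if self.kaug < 0:
            raise ValueError("kaug must be >= 0")

    @property
    def reg_start_epoch(self) -> int:
        """First 0-based epoch with regularization active."""
        return int(math.floor(self.reg_start_fraction * self.epochs + 1e-9))


def alpha_beta(epoch: int, config: LossConfig) -> tuple:
    """The two-phase (alpha, beta) weight schedule."""
    if epoch >= config.reg_start_epoch:
        return config.alpha_reg, config.beta_reg
    return config.alpha, config.beta


def _as_matrix(embs) -> np.ndarray:
    if isinstance(embs, np.ndarray):
        return np.atleast_2d(embs)
    vecs = [e.vector if hasattr(e, "vector") else np.asarray(e) for e in embs]
    return np.asarray(vecs, dtype=np.float64)


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for zero-norm vector")
    return float(np.dot(a, b) / (na * nb))


def discriminator(zspec, zmol, tau: float) -> float:
    """Temperature-scaled cosine kernel h = exp(cos(zspec, zmol)/tau)."""
    if tau <= 0:
        raise ValueError("tau must be > 0")
    a = zspec.vector if hasattr(zspec, "vector") else np.asarray(zspec, dtype=np.float64)
    b = zmol.vector if hasattr(zmol, "vector") else np.asarray(zmol, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("embedding length mismatch")
    return float(np.exp(cosine_similarity(a, b) / tau))


def contrastive_loss(spec_embs, mol_embs, tau: float) -> float:
    """Spectrum-anchored InfoNCE over index-aligned matched pairs.

    (1/k) * sum_n -log[ h(zspec_n, zmol_n) / sum_m h(zspec_n, zmol_m) ].
    """
    S = _as_matrix(spec_embs)
    M = _as_matrix(mol_embs)
    if S.shape != M.shape:
        raise ValueError(f"mismatched batch shapes {S.shape} vs {M.shape}")
    k = S.shape[0]
    Sn = S / np.linalg.norm(S, axis=1, keepdims=True)
    Mn = M / np.linalg.norm(M, axis=1, keepdims=True)
    logits = (Sn @ Mn.T) / tau
    row_max = logits.max(axis=1, keepdims=True)
    lse = row_max[:, 0] + np.log(np.exp(logits - row_max).sum(axis=1))
    return float(np.mean(lse - np.diag(logits)))


def regularization_loss(spec_embs, cand_embs) -> float:
    """Mean spectrum-candidate cosine similarity, averaged per spectrum.

    cand_embs is a length-k sequence of candidate-embedding blocks, one per
    spectrum (each (kaug, dim) or a list of vectors). Minimizing this pushes
    same-formula candidates away from the spectra.
    """
    S = _as_matrix(spec_embs)
    k = S.shape[0]
    if len(cand_embs) != k:
        raise ValueError("candidate blocks must align with spectra")
    per_spec = []
    for n in range(k):
        block = _as_matrix(cand_embs[n])
        if block.shape[0] == 0:
            raise ValueError("kaug must be >= 1; skip the term for empty blocks")
        cos = [cosine_similarity(S[n], block[m]) for m in range(block.shape[0])]
        per_spec.append(float(np.mean(cos)))
    return float(np.mean(per_spec))


def total_loss(lc: float, lr: float, epoch: int, config: LossConfig) -> float:
    """alpha(epoch)*Lc + beta(epoch)*Lr with the two-phase schedule."""
    a, b = alpha_beta(epoch, config)
    return a * lc + b * lr


# --- differentiable versions used inside the trainer -----------------------

def _normalize_rows_t(z: Tensor) -> Tensor:
    sq = ag.tsum(ag.mul(z, z), axis=1, keepdims=True)
    return ag.div(z, ag.sqrt(sq))


def _contrastive_loss_t(zs: Tensor, zm: Tensor, tau: float) -> Tensor:
    k = zs.shape[0]
    logits = ag.mul(ag.matmul(_normalize_rows_t(zs), _transpose(_normalize_rows_t(zm))),
                    Tensor(1.0 / tau))
    row_max = Tensor(logits.data.max(axis=1, keepdims=True))  # detached, exact for LSE
    lse = ag.add(ag.log(ag.tsum(ag.exp(ag.sub(logits, row_max)), axis=1, keepdims=True)),
                 row_max)
    diag = ag.tsum(ag.mul(logits, Tensor(np.eye(k))), axis=1, keepdims=True)
    return ag.mul(ag.tsum(ag.sub(lse, diag)), Tensor(1.0 / k))


def _transpose(t: Tensor) -> Tensor:
    out = Tensor(t.data.T, parents=(t,))

    def backward(g):
        if t.requires_grad:
            t._accumulate(g.T)

    out._backward = backward
    return out


def _regularization_loss_t(zs: Tensor, zc: Tensor, rep_idx: np.ndarray,
                           weights: np.ndarray) -> Tensor:
    """Weighted mean cosine between spectra (repeated by rep_idx) and candidates."""
    s = ag.gather_rows(_normalize_rows_t(zs), rep_idx)
    c = _normalize_rows_t(zc)
    cos = ag.tsum(ag.mul(s, c), axis=1, keepdims=True)
    return ag.tsum(ag.mul(cos, Tensor(weights[:, None])))


# --- dataset and batching --------------------------------------------------

@dataclass
class PairedDataset:
    """Matched spectra and molecules, with graphs, binned vectors and
    Tanimoto-sorted candidate lists precomputed.

    candidate_index maps molecule id -> list of candidate Molecules sharing
    the formula (target itself excluded by InChIKey), sorted descending by
    ECFP Tanimoto similarity to the target.
    """

    molecules: list
    spectra: list
    feature_config: FeatureConfig = field(default_factory=FeatureConfig)
    graphs: dict = field(default_factory=dict)
    binned: list = field(default_factory=list)
    candidate_index: dict = field(default_factory=dict)
    mol_by_id: dict = field(default_factory=dict)

    @classmethod
    def build(cls, molecules: list, spectra: list, library: list | None = None,
              feature_config: FeatureConfig | None = None,
              exclude_from_candidates: set | None = None) -> "PairedDataset":
        """Assemble a training dataset.

        library defaults to the target molecules themselves; candidate sets
        are formula buckets of the library. exclude_from_candidates removes
        molecules (by InChIKey) from the regularization decoy pool — used to
        emulate an external decoy database that does not contain the study's
        own annotated molecules.
        """
        fc = feature_config or FeatureConfig()
        library = library if library is not None else molecules
        if exclude_from_candidates:
            library = [m for m in library if m.inchikey not in exclude_from_candidates]
        mol_by_id = {m.id: m for m in molecules}
        missing = [s.spectrum_id for s in spectra if s.molecule_id not in mol_by_id]
        if missing:
            raise ValueError(f"spectra with unknown molecule_id: {missing[:5]}")

        graphs = {m.id: build_graph(m, fc) for m in library}
        for m in molecules:
            if m.id not in graphs:
                graphs[m.id] = build_graph(m, fc)

        by_formula: dict[str, list] = {}
        for m in library:
            by_formula.setdefault(m.formula, []).append(m)

        fps: dict[str, object] = {}

        def fp(m):
            if m.id not in fps:
                fps[m.id] = fingerprint(m)
            return fps[m.id]

        candidate_index = {}
        for m in molecules:
            cands = [c for c in by_formula.get(m.formula, [])
                     if c.inchikey != m.inchikey]
            scored = sorted(
                ((tanimoto(fp(m), fp(c)), c) for c in cands),
                key=lambda t: (-t[0], t[1].id),
            )
            candidate_index[m.id] = [c for _, c in scored]

        binned = [bin_spectrum(s) for s in spectra]
        return cls(molecules=molecules, spectra=spectra, feature_config=fc,
                   graphs=graphs, binned=binned, candidate_index=candidate_index,
                   mol_by_id=mol_by_id)

    def __len__(self) -> int:
        return len(self.spectra)


@dataclass
class TrainBatch:
    """One optimization step: k binned spectra, their k target graphs, and a
    ragged block of up to kaug candidate graphs per spectrum."""

    spectra: np.ndarray  # (k, 1000)
    target_graphs: list
    candidate_graphs: list  # list (len k) of lists of MolGraph (possibly empty)
    spectrum_indices: np.ndarray


def make_batches(dataset: PairedDataset, config: LossConfig, epoch: int,
                 rng: np.random.Generator, cursors: dict | None = None):
    """Yield TrainBatches for one epoch.

    Each spectrum appears exactly once. Its kaug candidates advance
    sequentially through the target's Tanimoto-sorted candidate list across
    epochs (cursors carries the positions between calls), wrapping around.
    """
    cursors = cursors if cursors is not None else {}
    order = rng.permutation(len(dataset.spectra))
    for start in range(0, len(order), config.batch_size):
        idx = order[start:start + config.batch_size]
        spec_mat = np.stack([dataset.binned[i].values for i in idx])
        targets = []
        cand_blocks = []
        for i in idx:
            spec = dataset.spectra[i]
            mol = dataset.mol_by_id[spec.molecule_id]
            targets.append(dataset.graphs[mol.id])
            cands = dataset.candidate_index.get(mol.id, [])
            block = []
            if cands and config.kaug > 0:
                pos = cursors.get(i, 0)
                for j in range(min(config.kaug, len(cands))):
                    block.append(dataset.graphs[cands[(pos + j) % len(cands)].id])
                cursors[i] = (pos + config.kaug) % len(cands)
            cand_blocks.append(block)
        yield TrainBatch(spectra=spec_mat, target_graphs=targets,
                         candidate_graphs=cand_blocks,
                         spectrum_indices=np.asarray(idx))


# --- optimizer and training loop ------------------------------------------

class Adam:
    """Adam over a dict of named parameter Tensors."""

    def __init__(self, params: dict, lr: float = 1e-3, betas=(0.9, 0.999), eps=1e-8,
                 weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self) -> None:
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mh = self.m[k] / (1 - self.b1 ** self.t)
            vh = self.v[k] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mh / (np.sqrt(vh) + self.eps)
            if self.weight_decay > 0 and not k.endswith(".b"):
                p.data -= self.lr * self.weight_decay * p.data  # decoupled decay

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None


def train(dataset: PairedDataset, config: LossConfig,
          encoder_config: EncoderConfig | None = None,
          progress: bool = False) -> Checkpoint:
    """Train both encoders jointly; returns a Checkpoint with the loss log.

    One seed (config.seed) governs weight initialization, batch shuffling and
    dropout. The per-epoch log records mean Lc, mean Lr (None while
    regularization is off) and mean Ltotal.
    """
    ec = encoder_config or EncoderConfig()
    root = np.random.SeedSequence(config.seed)
    init_ss, loop_ss = root.spawn(2)
    params = enc.init_parameters(ec, dataset.feature_config, np.random.default_rng(init_ss))
    rng = np.random.default_rng(loop_ss)
    opt = Adam(params, lr=config.learning_rate, weight_decay=config.weight_decay)
    cursors: dict = {}
    log = []

    epochs_iter = range(config.epochs)
    if progress:
        from tqdm import tqdm
        epochs_iter = tqdm(epochs_iter, desc="epochs")

    for epoch in epochs_iter:
        a, b = alpha_beta(epoch, config)
        lc_vals, lr_vals, lt_vals = [], [], []
        for batch in make_batches(dataset, config, epoch, rng, cursors):
            drop_rng = rng if ec.dropout > 0 else None
            zs = enc.spec_forward(params, batch.spectra, ec, rng=drop_rng)
            zm = enc.mol_forward(params, batch_graphs(batch.target_graphs), ec, rng=drop_rng)
            lc_t = _contrastive_loss_t(zs, zm, config.tau)
            if config.symmetric:
                lc_rev = _contrastive_loss_t(zm, zs, config.tau)
                lc_t = ag.mul(ag.add(lc_t, lc_rev), Tensor(0.5))

            lr_val = None
            if b > 0:
                flat, rep_idx, weights = [], [], []
                n_with = sum(1 for blk in batch.candidate_graphs if blk)
                for n, blk in enumerate(batch.candidate_graphs):
                    for g in blk:
                        flat.append(g)
                        rep_idx.append(n)
                        weights.append(1.0 / (n_with * len(blk)))
                if flat:
                    zc = enc.mol_forward(params, batch_graphs(flat), ec, rng=drop_rng)
                    lr_t = _regularization_loss_t(
                        zs, zc, np.asarray(rep_idx, dtype=np.intp),
                        np.asarray(weights))
                    loss_t = ag.add(ag.mul(lc_t, Tensor(a)), ag.mul(lr_t, Tensor(b)))
                    lr_val = float(lr_t.data)
                else:
                    loss_t = ag.mul(lc_t, Tensor(a))
            else:
                loss_t = ag.mul(lc_t, Tensor(a))

            if not np.isfinite(loss_t.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch} "
                    f"(Lc={float(lc_t.data)!r}, Lr={lr_val!r}); "
                    "lower the learning rate or raise tau"
                )
            opt.zero_grad()
            loss_t.backward()
            opt.step()

            lc_vals.append(float(lc_t.data))
            lt_vals.append(float(loss_t.data))
            if lr_val is not None:
                lr_vals.append(lr_val)

        log.append({
            "epoch": epoch,
            "Lc": float(np.mean(lc_vals)),
            "Lr": float(np.mean(lr_vals)) if lr_vals else None,
            "Ltotal": float(np.mean(lt_vals)),
            "alpha": a,
            "beta": b,
        })

    return Checkpoint(params=params, encoder_config=ec,
                      feature_config=dataset.feature_config,
                      training_log=log, loss_config=asdict(config))
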