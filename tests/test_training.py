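"""Losses (against naive reference implementations), schedule, batching,
and the training loop."""

import math

import numpy as np
import pytest

from jointms import _autograd as ag
from jointms._autograd import Tensor
from jointms.chem import FeatureConfig, build_graph, parse_molecule
from jointms.encoders import EncoderConfig, batch_graphs, init_parameters, mol_forward, spec_forward
from jointms.training import (LossConfig, PairedDataset, alpha_beta,
                              contrastive_loss, discriminator, make_batches,
                              regularization_loss, total_loss, train,
                              _contrastive_loss_t, _regularization_loss_t)


# --- naive reference implementations (kept deliberately dumb) --------------

def naive_contrastive(S, M, tau):
    k = S.shape[0]
    total = 0.0
    for n in range(k):
        num = math.exp(np.dot(S[n], M[n]) / (np.linalg.norm(S[n]) * np.linalg.norm(M[n])) / tau)
        den = 0.0
        for m in range(k):
            den += math.exp(np.dot(S[n], M[m]) / (np.linalg.norm(S[n]) * np.linalg.norm(M[m])) / tau)
        total += -math.log(num / den)
    return total / k


def naive_regularization(S, C):
    k = len(S)
    total = 0.0
    for n in range(k):
        inner = 0.0
        for c in C[n]:
            inner += np.dot(S[n], c) / (np.linalg.norm(S[n]) * np.linalg.norm(c))
        total += inner / len(C[n])
    return total / k


def test_discriminator_analytic_values():
    v = np.array([1.0, 2.0, -1.0])
    assert abs(discriminator(v, 2 * v, tau=1.0) - math.e) < 1e-12
    a = np.array([1.0, 0.0])
    b = np.array([0.0, 3.0])
    assert abs(discriminator(a, b, tau=1.0) - 1.0) < 1e-12
    assert abs(discriminator(a, -a, tau=0.5) - math.exp(-2.0)) < 1e-12
    with pytest.raises(ValueError):
        discriminator(np.zeros(3), v, tau=1.0)


def test_contrastive_single_pair_is_zero():
    z = np.array([[0.3, -0.7, 1.1]])
    assert contrastive_loss(z, z * 5.0, tau=0.07) == pytest.approx(0.0, abs=1e-12)


def test_contrastive_two_pair_analytic():
    """Orthogonal design: each spectrum parallel to its molecule, orthogonal
    to the other; per-row loss is -log(e/(e+1))."""
    S = np.eye(2)
    M = np.eye(2) * 3.0
    expected = -math.log(math.e / (math.e + 1.0))
    assert contrastive_loss(S, M, tau=1.0) == pytest.approx(expected, abs=1e-12)


def test_loss_oracle_equivalence(rng):
    """Vectorized losses match naive double loops on random batches."""
    for _ in range(100):
        k = int(rng.integers(1, 9))
        d = int(rng.integers(2, 17))
        kaug = int(rng.integers(1, 5))
        tau = float(rng.uniform(0.05, 1.0))
        S = rng.normal(size=(k, d))
        M = rng.normal(size=(k, d))
        C = [rng.normal(size=(kaug, d)) for _ in range(k)]
        assert abs(contrastive_loss(S, M, tau) - naive_contrastive(S, M, tau)) <= 1e-6
        assert abs(regularization_loss(S, C) - naive_regularization(S, C)) <= 1e-6
        # differentiable versions agree too
        lc_t = _contrastive_loss_t(Tensor(S), Tensor(M), tau)
        assert abs(float(lc_t.data) - naive_contrastive(S, M, tau)) <= 1e-6


def test_contrastive_rescale_invariance(rng):
    S = rng.normal(size=(5, 8))
    M = rng.normal(size=(5, 8))
    base = contrastive_loss(S, M, tau=0.2)
    S2 = S.copy()
    S2[2] *= 37.5
    assert contrastive_loss(S2, M, tau=0.2) == pytest.approx(base, abs=1e-9)


def test_contrastive_bounds(rng):
    for _ in range(20):
        k = int(rng.integers(1, 9))
        S = rng.normal(size=(k, 6))
        M = rng.normal(size=(k, 6))
        tau = float(rng.uniform(0.05, 1.0))
        loss = contrastive_loss(S, M, tau)
        assert -1e-9 <= loss <= math.log(k) + 2.0 / tau + 1e-9


def test_temperature_sharpens_hard_easy_gap():
    """Lower tau widens the loss gap between a hard batch (high off-diagonal
    cosine) and an easy batch (orthogonal negatives)."""
    e1, e2 = np.eye(2)
    hard_M = np.stack([e1, e1 * 0.9 + e2 * 0.435889894354])  # cos ~0.9 to e1
    easy_M = np.stack([e1, e2])
    S = np.stack([e1, e2])
    gaps = []
    # moderate temperatures: at extreme tau both losses saturate (to log k
    # and 0 respectively) and the gap shrinks again
    for tau in (2.0, 1.0, 0.5):
        gaps.append(contrastive_loss(S, hard_M, tau) - contrastive_loss(S, easy_M, tau))
    assert gaps[0] < gaps[1] < gaps[2]


def test_regularization_analytic_values():
    S = [np.array([1.0, 0.0])]
    assert regularization_loss(S, [np.array([[0.0, 1.0], [0.0, -2.0]])]) == \
        pytest.approx(0.0, abs=1e-12)
    assert regularization_loss(S, [np.array([[5.0, 0.0]])]) == pytest.approx(1.0)
    # cosines 0.8 and -0.2 average to 0.3
    c1 = np.array([0.8, 0.6])
    c2 = np.array([-0.2, -np.sqrt(1 - 0.04)])
    val = regularization_loss(S, [np.stack([c1, c2])])
    assert val == pytest.approx(0.3, abs=1e-9)
    with pytest.raises(ValueError):
        regularization_loss(S, [np.zeros((0, 2))])


def test_total_loss_schedule():
    cfg = LossConfig(epochs=100)
    assert cfg.reg_start_epoch == 97
    assert total_loss(2.0, 0.9, epoch=0, config=cfg) == 2.0
    assert total_loss(2.0, 0.9, epoch=96, config=cfg) == 2.0
    assert total_loss(2.0, 0.9, epoch=97, config=cfg) == pytest.approx(1.89)
    # Lr has no influence while beta = 0
    assert total_loss(2.0, 123.0, epoch=50, config=cfg) == total_loss(2.0, -5.0, 50, cfg)
    # 30-epoch run regularizes exactly its final epoch
    cfg30 = LossConfig(epochs=30)
    assert cfg30.reg_start_epoch == 29
    assert alpha_beta(28, cfg30) == (1.0, 0.0)
    assert alpha_beta(29, cfg30) == (0.9, 0.1)


def test_gradients_match_finite_differences(rng):
    """End-to-end backprop through both encoders and both losses."""
    fc = FeatureConfig()
    ec = EncoderConfig(gcn_layers=2, hidden_dim=8, embed_dim=6, dropout=0.0)
    params = init_parameters(ec, fc, rng)
    graphs = [build_graph(parse_molecule(s), fc) for s in ["CCO", "CCN", "CC=O"]]
    batch = batch_graphs(graphs)
    spec_mat = rng.random((3, 1000)) * 0.5

    def loss_fn():
        zs = spec_forward(params, spec_mat, ec)
        zm = mol_forward(params, batch, ec)
        lc = _contrastive_loss_t(zs, zm, 0.2)
        zc = mol_forward(params, batch_graphs(graphs), ec)
        lr = _regularization_loss_t(zs, zc, np.array([0, 1, 2]), np.full(3, 1 / 3))
        return ag.add(lc, ag.mul(lr, Tensor(0.3)))

    loss = loss_fn()
    loss.backward()
    for name in ["gcn0.w_nbr", "spec_mlp0.w", "mol_mlp1.w"]:
        p = params[name]
        ix = tuple(int(rng.integers(0, s)) for s in p.data.shape)
        eps, old = 1e-6, p.data[ix]
        p.data[ix] = old + eps
        lp = float(loss_fn().data)
        p.data[ix] = old - eps
        lm = float(loss_fn().data)
        p.data[ix] = old
        num = (lp - lm) / (2 * eps)
        assert abs(num - p.grad[ix]) < 1e-5 * max(1.0, abs(num))


@pytest.fixture(scope="module")
def tiny_dataset(tiny_sim):
    split_targets = tiny_sim.targets
    return PairedDataset.build(split_targets, tiny_sim.spectra,
                               library=tiny_sim.library)


def test_make_batches_shapes_and_coverage(tiny_dataset):
    cfg = LossConfig(batch_size=4, kaug=2, epochs=2, seed=0)
    rng = np.random.default_rng(0)
    batches = list(make_batches(tiny_dataset, cfg, epoch=0, rng=rng))
    sizes = [b.spectra.shape[0] for b in batches]
    n = len(tiny_dataset.spectra)
    assert sum(sizes) == n
    assert all(s <= 4 for s in sizes)
    seen = np.concatenate([b.spectrum_indices for b in batches])
    assert sorted(seen) == list(range(n))


def test_candidate_cursor_wraps(tiny_dataset):
    """kaug candidates advance sequentially per epoch and wrap at list end."""
    cfg = LossConfig(batch_size=64, kaug=2, epochs=10, seed=0)
    # find a spectrum whose target has >= 3 candidates
    target_id, cands = next(
        (mid, c) for mid, c in tiny_dataset.candidate_index.items() if len(c) >= 3
    )
    spec_idx = next(i for i, s in enumerate(tiny_dataset.spectra)
                    if s.molecule_id == target_id)
    cursors = {}
    seen_rounds = []
    for epoch in range(4):
        rng = np.random.default_rng(99)
        for b in make_batches(tiny_dataset, cfg, epoch, rng, cursors):
            if spec_idx in b.spectrum_indices:
                pos = list(b.spectrum_indices).index(spec_idx)
                seen_rounds.append(b.candidate_graphs[pos])
    L = len(cands)
    expected_starts = [0, 2 % L, 4 % L, 6 % L]
    for got, start in zip(seen_rounds, expected_starts):
        want = [tiny_dataset.graphs[cands[(start + j) % L].id] for j in range(2)]
        assert [id(g) for g in got] == [id(g) for g in want]


def test_candidates_exclude_target(tiny_dataset):
    for mid, cands in tiny_dataset.candidate_index.items():
        target = tiny_dataset.mol_by_id.get(mid)
        if target is None:
            continue
        assert all(c.inchikey != target.inchikey for c in cands)


def test_train_reproducible_and_logged(tiny_dataset):
    ec = EncoderConfig(gcn_layers=2, hidden_dim=12, embed_dim=8, dropout=0.0)
    cfg = LossConfig(epochs=3, batch_size=8, kaug=2, reg_start_fraction=0.5, seed=5)
    ck1 = train(tiny_dataset, cfg, encoder_config=ec)
    ck2 = train(tiny_dataset, cfg, encoder_config=ec)
    assert len(ck1.training_log) == 3
    for a, b in zip(ck1.training_log, ck2.training_log):
        assert a == b  # bit-for-bit reproducibility per seed
    # regularization appears exactly from the scheduled epoch on
    assert ck1.training_log[0]["beta"] == 0.0 and ck1.training_log[0]["Lr"] is None
    assert ck1.training_log[1]["beta"] == 0.1 and ck1.training_log[1]["Lr"] is not None
    # loss decreases over training
    assert ck1.training_log[-1]["Lc"] < ck1.training_log[0]["Lc"]
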