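"""The two encoders of the joint embedding space.

Molecules: a stack of graph-convolution layers with symmetric-normalized
aggregation (edge features concatenated onto neighbor messages), a max-pool
readout over atoms, then a 2-layer MLP. Spectra: the 1000-bin log-scaled
vector through a 3-layer MLP. Both map into the same embed_dim so cosine
similarity between any (spectrum, molecule) pair is defined. Embeddings are
stored unnormalized; normalization happens inside the cosine discriminator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import _autograd as ag
from ._autograd import Tensor
from .chem import FeatureConfig, MolGraph
from .spectra import N_BINS, BinnedSpectrum


@dataclass
class EncoderConfig:
    """Architecture hyperparameters shared by both encoders.

    spec_mlp_layers and mol_mlp_layers are architectural constants (3 and 2);
    the rest are tunable.
    """

    gcn_layers: int = 3
    hidden_dim: int = 128
    embed_dim: int = 48
    conv: str = "gcn"  # "gcn" | "directed" (edge-message passing)
    spec_mlp_layers: int = 3
    mol_mlp_layers: int = 2
    activation: str = "relu"
    dropout: float = 0.0
    spec_smooth_sigma: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.gcn_layers < 1:
            raise ValueError("gcn_layers must be >= 1")
        if self.spec_mlp_layers != 3 or self.mol_mlp_layers != 2:
            raise ValueError("spec MLP is 3 layers and mol MLP is 2 layers by construction")


@dataclass
class Embedding:
    """A point in the joint space, tagged with the view it came from."""

    vector: np.ndarray
    source: str  # "molecule" | "spectrum"

    def __post_init__(self):
        self.vector = np.asarray(self.vector, dtype=np.float64)
        if not np.all(np.isfinite(self.vector)):
            raise ValueError("embedding has non-finite entries")


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def _smooth_columns(w: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian-smooth each column of w along axis 0, preserving its variance."""
    radius = int(np.ceil(3 * sigma))
    x = np.arange(-radius, radius + 1)
    kern = np.exp(-0.5 * (x / sigma) ** 2)
    kern /= kern.sum()
    sm = np.apply_along_axis(lambda col: np.convolve(col, kern, mode="same"), 0, w)
    return sm * (w.std() / sm.std())


def init_parameters(
    config: EncoderConfig, feature_config: FeatureConfig, rng: np.random.Generator
) -> dict:
    """Glorot-uniform initialization of every weight in both encoders."""
    p: dict[str, Tensor] = {}
    h, d = config.hidden_dim, config.embed_dim
    in_dim = feature_config.node_dim
    e_dim = feature_config.edge_dim
    if config.conv == "directed":
        p["dmp.w_in"] = Tensor(_glorot(rng, in_dim + e_dim, h), requires_grad=True)
        p["dmp.w_h"] = Tensor(_glorot(rng, h, h), requires_grad=True)
        p["dmp.w_o"] = Tensor(_glorot(rng, in_dim + h, h), requires_grad=True)
        p["dmp.b_o"] = Tensor(np.zeros((1, h)), requires_grad=True)
    else:
        for layer in range(config.gcn_layers):
            p[f"gcn{layer}.w_self"] = Tensor(_glorot(rng, in_dim, h), requires_grad=True)
            p[f"gcn{layer}.w_nbr"] = Tensor(_glorot(rng, in_dim + e_dim, h), requires_grad=True)
            p[f"gcn{layer}.b"] = Tensor(np.zeros((1, h)), requires_grad=True)
            in_dim = h
    p["mol_mlp0.w"] = Tensor(_glorot(rng, h, h), requires_grad=True)
    p["mol_mlp0.b"] = Tensor(np.zeros((1, h)), requires_grad=True)
    p["mol_mlp1.w"] = Tensor(_glorot(rng, h, d), requires_grad=True)
    p["mol_mlp1.b"] = Tensor(np.zeros((1, d)), requires_grad=True)

    w0 = _glorot(rng, N_BINS, h)
    if config.spec_smooth_sigma > 0:
        # the m/z axis is ordered: smoothing first-layer columns along it makes
        # nearby mass bins map similarly, so bins unseen in training borrow
        # their neighbors' mapping instead of staying at random init
        w0 = _smooth_columns(w0, config.spec_smooth_sigma)
    p["spec_mlp0.w"] = Tensor(w0, requires_grad=True)
    p["spec_mlp0.b"] = Tensor(np.zeros((1, h)), requires_grad=True)
    p["spec_mlp1.w"] = Tensor(_glorot(rng, h, h), requires_grad=True)
    p["spec_mlp1.b"] = Tensor(np.zeros((1, h)), requires_grad=True)
    p["spec_mlp2.w"] = Tensor(_glorot(rng, h, d), requires_grad=True)
    p["spec_mlp2.b"] = Tensor(np.zeros((1, d)), requires_grad=True)
    return p


@dataclass
class GraphBatch:
    """Several MolGraphs packed into one node/edge block for vectorized layers."""

    node_features: np.ndarray
    edge_features: np.ndarray
    edges: np.ndarray  # (E, 2) src, dst into the packed node block
    graph_ids: np.ndarray  # (N,) graph index per node
    n_graphs: int
    edge_norm: np.ndarray  # (E, 1) symmetric normalization 1/sqrt(deg_src*deg_dst)
    self_norm: np.ndarray  # (N, 1) 1/deg with self-loop counted


def batch_graphs(graphs: list) -> GraphBatch:
    nodes, efeats, edges, gids = [], [], [], []
    offset = 0
    for gi, g in enumerate(graphs):
        nodes.append(g.node_features)
        gids.append(np.full(g.n_nodes, gi, dtype=np.intp))
        if g.edges.shape[0]:
            edges.append(g.edges + offset)
            efeats.append(g.edge_features)
        offset += g.n_nodes
    node_features = np.concatenate(nodes, axis=0)
    n_total = node_features.shape[0]
    if edges:
        edges_arr = np.concatenate(edges, axis=0)
        efeat_arr = np.concatenate(efeats, axis=0)
    else:
        edges_arr = np.zeros((0, 2), dtype=np.intp)
        efeat_arr = np.zeros((0, graphs[0].edge_features.shape[1] if graphs else 0))
    deg = np.ones(n_total)  # self-loop
    np.add.at(deg, edges_arr[:, 1], 1.0)
    if edges_arr.shape[0]:
        edge_norm = 1.0 / np.sqrt(deg[edges_arr[:, 0]] * deg[edges_arr[:, 1]])
        edge_norm = edge_norm[:, None]
    else:
        edge_norm = np.zeros((0, 1))
    return GraphBatch(
        node_features=node_features,
        edge_features=efeat_arr,
        edges=edges_arr,
        graph_ids=np.concatenate(gids),
        n_graphs=len(graphs),
        edge_norm=edge_norm,
        self_norm=(1.0 / deg)[:, None],
    )


def _dropout(t: Tensor, rate: float, rng: np.random.Generator | None) -> Tensor:
    if rng is None or rate <= 0:
        return t
    mask = (rng.random(t.shape) >= rate) / (1.0 - rate)
    return ag.mul(t, Tensor(mask))


def mol_forward(
    params: dict,
    batch: GraphBatch,
    config: EncoderConfig,
    rng: np.random.Generator | None = None,
) -> Tensor:
    """Molecular embeddings for a packed graph batch; (n_graphs, embed_dim).

    rng enables dropout (training mode); None means inference.
    """
    if config.conv == "directed":
        return _mol_forward_directed(params, batch, config, rng)
    if batch.node_features.shape[1] != params["gcn0.w_self"].shape[0]:
        raise ValueError(
            f"node feature dim {batch.node_features.shape[1]} does not match "
            f"trained parameters ({params['gcn0.w_self'].shape[0]})"
        )
    h = Tensor(batch.node_features)
    self_norm = Tensor(batch.self_norm)
    edge_norm = Tensor(batch.edge_norm)
    e_feat = Tensor(batch.edge_features)
    src, dst = batch.edges[:, 0], batch.edges[:, 1]
    n_nodes = batch.node_features.shape[0]
    for layer in range(config.gcn_layers):
        self_msg = ag.mul(ag.matmul(h, params[f"gcn{layer}.w_self"]), self_norm)
        if batch.edges.shape[0]:
            msg_in = ag.concat([ag.gather_rows(h, src), e_feat], axis=1)
            msg = ag.mul(ag.matmul(msg_in, params[f"gcn{layer}.w_nbr"]), edge_norm)
            agg = ag.segment_sum(msg, dst, n_nodes)
            pre = ag.add(ag.add(self_msg, agg), params[f"gcn{layer}.b"])
        else:
            pre = ag.add(self_msg, params[f"gcn{layer}.b"])
        h = _dropout(ag.relu(pre), config.dropout, rng)
    pooled = ag.segment_max(h, batch.graph_ids, batch.n_graphs)
    z = ag.relu(ag.add(ag.matmul(pooled, params["mol_mlp0.w"]), params["mol_mlp0.b"]))
    z = _dropout(z, config.dropout, rng)
    return ag.add(ag.matmul(z, params["mol_mlp1.w"]), params["mol_mlp1.b"])


def _mol_forward_directed(
    params: dict,
    batch: GraphBatch,
    config: EncoderConfig,
    rng: np.random.Generator | None = None,
) -> Tensor:
    """Directed edge-message passing molecular encoder.

    Messages live on directed bonds and exclude the reverse edge, so after T
    rounds the message on bond i->j aggregates the subtree hanging off i away
    from j — the quantity bond-cleavage fragments are made of. Readout is the
    same max-pool + 2-layer MLP as the symmetric variant.
    """
    if batch.node_features.shape[1] + batch.edge_features.shape[1] != \
            params["dmp.w_in"].shape[0]:
        raise ValueError(
            "node/edge feature dims do not match trained parameters"
        )
    x = Tensor(batch.node_features)
    n_nodes = batch.node_features.shape[0]
    n_edges = batch.edges.shape[0]
    if n_edges:
        src, dst = batch.edges[:, 0], batch.edges[:, 1]
        rev = np.arange(n_edges) ^ 1  # bonds stored as (i,j),(j,i) pairs
        ef = Tensor(batch.edge_features)
        h0 = ag.relu(ag.matmul(ag.concat([ag.gather_rows(x, src), ef], axis=1),
                               params["dmp.w_in"]))
        h = h0
        for _ in range(config.gcn_layers - 1):
            s = ag.segment_sum(h, dst, n_nodes)
            agg = ag.sub(ag.gather_rows(s, src), ag.gather_rows(h, rev))
            h = ag.relu(ag.add(h0, ag.matmul(agg, params["dmp.w_h"])))
            h = _dropout(h, config.dropout, rng)
        m = ag.segment_sum(h, dst, n_nodes)
    else:
        m = Tensor(np.zeros((n_nodes, config.hidden_dim)))
    hn = ag.relu(ag.add(ag.matmul(ag.concat([x, m], axis=1), params["dmp.w_o"]),
                        params["dmp.b_o"]))
    hn = _dropout(hn, config.dropout, rng)
    pooled = ag.segment_max(hn, batch.graph_ids, batch.n_graphs)
    z = ag.relu(ag.add(ag.matmul(pooled, params["mol_mlp0.w"]), params["mol_mlp0.b"]))
    z = _dropout(z, config.dropout, rng)
    return ag.add(ag.matmul(z, params["mol_mlp1.w"]), params["mol_mlp1.b"])


def spec_forward(
    params: dict,
    binned_matrix: np.ndarray,
    config: EncoderConfig,
    rng: np.random.Generator | None = None,
) -> Tensor:
    """Spectral embeddings for a (k, 1000) matrix of binned vectors."""
    if binned_matrix.ndim != 2 or binned_matrix.shape[1] != N_BINS:
        raise ValueError(f"binned input must be (k, {N_BINS})")
    z = Tensor(binned_matrix)
    z = ag.relu(ag.add(ag.matmul(z, params["spec_mlp0.w"]), params["spec_mlp0.b"]))
    z = _dropout(z, config.dropout, rng)
    z = ag.relu(ag.add(ag.matmul(z, params["spec_mlp1.w"]), params["spec_mlp1.b"]))
    z = _dropout(z, config.dropout, rng)
    return ag.add(ag.matmul(z, params["spec_mlp2.w"]), params["spec_mlp2.b"])


def encode_molecule(graph: MolGraph, params: dict, config: EncoderConfig) -> Embedding:
    """Inference-mode embedding of a single molecule graph."""
    out = mol_forward(params, batch_graphs([graph]), config, rng=None)
    return Embedding(vector=out.data[0], source="molecule")


def encode_spectrum(binned: BinnedSpectrum, params: dict, config: EncoderConfig) -> Embedding:
    """Inference-mode embedding of a single binned spectrum."""
    out = spec_forward(params, binned.values[None, :], config, rng=None)
    return Embedding(vector=out.data[0], source="spectrum")


# --- checkpointing ---------------------------------------------------------

@dataclass
class Checkpoint:
    """Trained parameters plus the configs needed to rebuild the encoders."""

    params: dict
    encoder_config: EncoderConfig
    feature_config: FeatureConfig
    training_log: list = field(default_factory=list)
    loss_config: dict | None = None

    def save(self, path) -> None:
        arrays = {k: v.data for k, v in self.params.items()}
        meta = {
            "encoder_config": asdict(self.encoder_config),
            "feature_config": {
                "elements": list(self.feature_config.elements),
                "standardize": self.feature_config.standardize,
            },
            "training_log": self.training_log,
            "loss_config": self.loss_config,
        }
        np.savez(path, __meta__=np.array(json.dumps(meta)), **arrays)

    @classmethod
    def load(cls, path) -> "Checkpoint":
        with np.load(path, allow_pickle=False) as npz:
            meta = json.loads(str(npz["__meta__"]))
            params = {
                k: Tensor(npz[k], requires_grad=True)
                for k in npz.files
                if k != "__meta__"
            }
        fc = meta["feature_config"]
        return cls(
            params=params,
            encoder_config=EncoderConfig(**meta["encoder_config"]),
            feature_config=FeatureConfig(
                elements=tuple(fc["elements"]), standardize=fc["standardize"]
            ),
            training_log=meta.get("training_log", []),
            loss_config=meta.get("loss_config"),
        )
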