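"""Model/Results interface over the joint-embedding pipeline.

:class:`JointEmbeddingModel` bundles a paired spectrum-molecule dataset with
the architecture and loss settings; ``fit()`` runs contrastive training and
returns a :class:`JointEmbeddingResults` carrying the trained parameters, the
loss history, ranking and diagnostic methods, and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import asdict

import numpy as np

from .annotate import (FormulaLibrary, RankingResult, SimilarityDistributions,
                       rank_at_k, rank_candidates, retrieve_candidates,
                       similarity_distributions)
from .chem import FeatureConfig, Molecule
from .encoders import Checkpoint, EncoderConfig
from .training import LossConfig, PairedDataset, train


class JointEmbeddingModel:
    """A joint molecule-spectrum embedding model bound to a training dataset.

    Parameters
    ----------
    dataset : PairedDataset
        Matched spectra and molecules with candidate sets precomputed.
    encoder_config, loss_config : optional
        Architecture and loss/optimization settings; defaults are the
        package defaults.

    Examples
    --------
    >>> from jointms import simdata
    >>> from jointms.model import JointEmbeddingModel
    >>> sim = simdata.generate_dataset(simdata.SimConfig(seed=1))
    >>> model = JointEmbeddingModel.from_components(
    ...     sim.targets, sim.spectra, library=sim.library)
    >>> results = model.fit()                                   # doctest: +SKIP
    >>> print(results.summary())                                # doctest: +SKIP
    """

    def __init__(self, dataset: PairedDataset,
                 encoder_config: EncoderConfig | None = None,
                 loss_config: LossConfig | None = None):
        self.dataset = dataset
        self.encoder_config = encoder_config or EncoderConfig()
        self.loss_config = loss_config or LossConfig()

    @classmethod
    def from_components(cls, molecules: list, spectra: list,
                        library: list | None = None,
                        encoder_config: EncoderConfig | None = None,
                        loss_config: LossConfig | None = None,
                        feature_config: FeatureConfig | None = None):
        """Build from molecule/spectrum lists; candidate sets are derived from
        the library's formula buckets."""
        ds = PairedDataset.build(molecules, spectra, library=library,
                                 feature_config=feature_config)
        return cls(ds, encoder_config=encoder_config, loss_config=loss_config)

    @classmethod
    def from_dataframe(cls, molecules_df, spectra: list,
                       library_df=None, **kwargs):
        """Build from pandas DataFrames with columns (smiles, id[, inchikey])."""
        from .chem import parse_molecule

        def to_mols(df):
            return [parse_molecule(r["smiles"], mol_id=str(r["id"]))
                    for _, r in df.iterrows()]

        molecules = to_mols(molecules_df)
        library = to_mols(library_df) if library_df is not None else None
        return cls.from_components(molecules, spectra, library=library, **kwargs)

    def fit(self, progress: bool = False) -> "JointEmbeddingResults":
        """Train both encoders; returns the fitted results object."""
        ckpt = train(self.dataset, self.loss_config,
                     encoder_config=self.encoder_config, progress=progress)
        return JointEmbeddingResults(self, ckpt)


class JointEmbeddingResults:
    """Fitted joint-embedding model: parameters, loss history, diagnostics."""

    def __init__(self, model: JointEmbeddingModel, checkpoint: Checkpoint):
        self.model = model
        self.checkpoint = checkpoint

    @property
    def training_log(self) -> list:
        return self.checkpoint.training_log

    @property
    def final_contrastive_loss(self) -> float:
        return self.training_log[-1]["Lc"]

    def save(self, path) -> None:
        self.checkpoint.save(path)

    @classmethod
    def from_checkpoint(cls, path, model: JointEmbeddingModel | None = None):
        ckpt = Checkpoint.load(path)
        return cls(model, ckpt)

    # --- inference ---------------------------------------------------------

    def rank(self, spectra: list, molecules_by_id: dict, library,
             fn: str = "cosine") -> list:
        """Rank each spectrum's formula-matched candidate set; target included."""
        if not isinstance(library, FormulaLibrary):
            library = FormulaLibrary(library)
        results = []
        for spec in spectra:
            target = molecules_by_id[spec.molecule_id]
            cands = retrieve_candidates(target, library)
            results.append(rank_candidates(spec, cands, self.checkpoint, fn=fn,
                                           target_id=target.id))
        return results

    def evaluate(self, spectra: list, molecules_by_id: dict, library,
                 ks=(1, 5, 20), fn: str = "cosine") -> dict:
        """rank@k over a labeled spectrum set (per-spectrum aggregation)."""
        results = self.rank(spectra, molecules_by_id, library, fn=fn)
        return {f"rank@{k}": rank_at_k(results, k) for k in ks}

    def similarity_distributions(self, spectra: list, molecules_by_id: dict,
                                 library) -> SimilarityDistributions:
        """Matching vs candidate-pair cosine distributions (diagnostics)."""
        return similarity_distributions(spectra, molecules_by_id, library,
                                        self.checkpoint)

    # --- presentation ------------------------------------------------------

    def summary(self) -> str:
        ec = self.checkpoint.encoder_config
        lc = self.checkpoint.loss_config or asdict(self.model.loss_config)
        log = self.training_log
        reg_epochs = [e for e in log if e["beta"] > 0]
        lines = [
            "Joint molecule-spectrum embedding — fit summary",
            "=" * 56,
            f"{'embed_dim':<28}{ec.embed_dim}",
            f"{'hidden_dim':<28}{ec.hidden_dim}",
            f"{'gcn_layers':<28}{ec.gcn_layers}",
            f"{'temperature tau':<28}{lc['tau']}",
            f"{'epochs':<28}{len(log)}",
            f"{'regularized epochs':<28}{len(reg_epochs)}",
            f"{'k_aug':<28}{lc['kaug']}",
            f"{'training spectra':<28}{len(self.model.dataset) if self.model else 'n/a'}",
            "-" * 56,
            f"{'final contrastive loss':<28}{log[-1]['Lc']:.4f}",
        ]
        if reg_epochs:
            lines.append(f"{'final regularization loss':<28}{reg_epochs[-1]['Lr']:.4f}")
        lines.append(f"{'final total loss':<28}{log[-1]['Ltotal']:.4f}")
        lines.append("=" * 56)
        return "\n".join(lines)

    def plot_loss(self, ax=None):
        """Per-epoch loss curves (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        epochs = [e["epoch"] for e in self.training_log]
        ax.plot(epochs, [e["Lc"] for e in self.training_log], label="contrastive")
        reg = [(e["epoch"], e["Lr"]) for e in self.training_log if e["Lr"] is not None]
        if reg:
            ax.plot(*zip(*reg), label="regularization")
        ax.set_xlabel("epoch")
        ax.set_ylabel("loss")
        ax.legend()
        return ax
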