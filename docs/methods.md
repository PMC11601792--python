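# Methods

## The annotation problem

Tandem mass spectrometry measures a molecule indirectly: a precursor ion is
fragmented and the instrument records a peak list of fragment mass-to-charge
values and intensities. Annotation means deciding which candidate structure —
typically one of tens to thousands of molecules sharing the precursor's
molecular formula — produced an observed spectrum. `jointms` ranks those
candidates by learning a *joint embedding space* in which a molecule and its
spectra are two views of the same object: a graph encoder maps molecular
structures into the space, a multilayer perceptron maps vectorized spectra
into the same space, and candidates are ranked by the cosine similarity of
their embedding to the query spectrum's embedding. No intermediate spectrum
prediction or fingerprint prediction is involved.

## Model

**Spectrum vectorization.** Peaks at or above 1000 Da are dropped; the
remaining intensities are rescaled so the tallest peak is 999 (the NIST
convention); peaks are summed within 1-Da bins (bin *n* covers [*n*, *n*+1));
and each non-empty bin value *v* becomes log10(*v*)/3. The result is a fixed
1000-dimensional non-negative vector. Two decisions the pipeline's brief
description leaves open are resolved as follows: intensities are normalized
*before* same-bin summation, which makes the output exactly invariant to
uniform intensity rescaling (a property the tests rely on), and bin sums
below 1 are clamped to 1 before the log so the vector stays non-negative.
A peak at exactly 1000 Da is dropped.

**Encoders.** The spectral encoder is a 3-layer MLP (1000 → hidden → hidden →
embed, ReLU between layers). The molecular encoder applies a stack of graph
convolutions over the heavy-atom graph, max-pools node states, and finishes
with a 2-layer MLP. Node features: element one-hot over
(C,N,O,S,P,F,Cl,Br,I,H,other), atomic mass, total valence, in-ring flag,
formal charge, radical electron count, chirality one-hot, degree, implicit
hydrogen count, aromaticity. Edge features: bond-type one-hot, in-ring,
conjugation, stereo one-hot. Hydrogens are implicit; hydrogen counts are
node features. Two message-passing variants are provided:

- `conv="gcn"` (default): symmetric-normalized aggregation with a separate
  self-loop weight; edge features are concatenated onto neighbor messages.
- `conv="directed"`: messages live on directed bonds and exclude the reverse
  edge, so after *T* rounds the message on bond i→j summarizes the subtree
  hanging off i away from j — the quantity single-bond fragments are made of.

Atoms are renumbered into RDKit canonical order during featurization, so two
SMILES spellings of one structure produce byte-identical graphs and therefore
bit-identical embeddings; the encoders' permutation invariance is exact, not
approximate.

Embeddings are stored unnormalized; all similarity computations normalize
through the cosine.

**Objective.** Over a batch of k matched (spectrum, molecule) pairs, the
discriminator h(z_s, z_m) = exp(cos(z_s, z_m)/τ) scores every pairing and
the contrastive loss is the spectrum-anchored InfoNCE

    L_c = (1/k) Σ_n −log [ h(z_s^n, z_m^n) / Σ_m h(z_s^n, z_m^m) ].

The loss is deliberately asymmetric (no molecule-anchored term), and in-batch
duplicate molecules are not masked. A regularization term

    L_r = (1/k) Σ_n (1/k_aug) Σ_m cos(z_s^n, z_cand^m)

averages the cosine between each spectrum and the k_aug candidate molecules
most similar (ECFP Tanimoto) to its target, and is *minimized*, pushing
same-formula near-duplicates away from the spectra. The total loss is
α·L_c + β·L_r with (α, β) = (1.0, 0.0) for the first 97% of epochs and
(0.9, 0.1) for the final 3% — regularization is a fine-tuning phase.
The switch-on epoch is floor(0.97·epochs): a 100-epoch run regularizes
epochs 97–99, a 30-epoch run its final epoch. Candidates advance
*sequentially* through each target's Tanimoto-sorted list across epochs
(wrapping at the end), so successive regularized epochs use successively
less similar decoys; candidates equal to the target by InChIKey are removed
before sorting. Spectra whose targets have no candidates stay in the batch
but are excluded from L_r (the average runs over spectra that have
candidates).

**Inference.** Candidates are retrieved from a formula-indexed library (the
target is a member — it must be rankable), deduplicated by InChIKey, and
sorted by cosine similarity to the query spectrum's embedding; a raw
dot-product mode exists for comparing magnitude-sensitive ranking. The
reported rank of the target is pessimistic: 1 + the number of other
candidates scoring ≥ the target, so exact ties count against it. rank@k is
the percentage of query spectra whose target ranks ≤ k; each spectrum is
ranked independently (per-spectrum aggregation).

## Numerical core

PyTorch-class frameworks are not dependencies of this package; both encoders
and the training loop run on a small reverse-mode automatic-differentiation
module (`jointms._autograd`) over float64 numpy arrays: dense algebra plus
the segment operations graph batching needs (scatter-sum, scatter-max,
row gather) with topological-order backpropagation. Gradients are verified
against central finite differences in the test suite. The optimizer is Adam
(β₁ = 0.9, β₂ = 0.999, ε = 1e-8) with decoupled weight decay applied to
weight matrices only. The contrastive softmax is computed via a row-max
shifted log-sum-exp. Max-pool backward routes gradient to the first argmax
row per (segment, column). One seed governs weight initialization, batch
shuffling and dropout; runs are bit-for-bit reproducible for a fixed seed on
one platform.

## Defaults and why

| Parameter | Default | Rationale |
|---|---|---|
| τ (temperature) | 0.15 | Selected on development seeds: sharper values (0.07) memorize the small training set; softer ones blur top-1 discrimination. |
| hidden_dim | 128 | Smallest width that did not cost held-out accuracy. |
| embed_dim | 48 | Lower-dimensional joint spaces spread decoys further apart on held-out molecules; much larger spaces memorize. |
| gcn_layers | 3 | Receptive field covers the fragment-relevant neighborhoods of the default molecules. |
| dropout | 0.0 | Dropout noise consistently destroyed held-out separation at this data scale. |
| k_aug | 16 | Covers most of a default candidate list within one regularized epoch. |
| weight decay | 1e-3 | Decoupled; main defense against pair memorization. |
| learning rate | 1e-3 | Adam default for this size. |
| batch size | 16 | k−1 = 15 in-batch negatives per anchor. |
| epochs | 30 | The default study's budget; loss plateaus before this. |
| spec_smooth_sigma | 2.0 | First-layer columns of the spectral MLP are Gaussian-smoothed along the bin axis at init: the m/z axis is ordered, so bins unseen in training borrow their neighbors' mapping instead of staying random. |
| standardize (features) | off | Unscaled atomic mass dominates the node features, which makes mass-additive structure — what fragment peaks are made of — easy for the graph layers to express. |

ECFP fingerprints use radius 2 and 2048 bits, the field's conventional
defaults. All of the above are config fields, not constants.

## The synthetic data generator

The generator emulates the statistical structure of a spectral-library
annotation study without any fragmentation chemistry:

- **Library.** The combinatorial space of linear carbon scaffolds (4–6
  backbone atoms) carrying 1–2 substituents from a 10-group vocabulary
  (–OH, –NH2, methyl, ethyl, methoxy, hydroxymethyl, aminomethyl,
  methylamino, aldehyde, 2-hydroxyethyl) is enumerated exhaustively,
  deduplicated by canonical SMILES, and subsampled per seed to
  ~n_molecules × library_multiplier (default 1500) molecules. Building
  blocks recur across molecules, so held-out molecules are new combinations
  of seen motifs — the property that makes the structure→spectrum map
  learnable from a 40-molecule training set. Molecular formulas collide
  heavily: target candidate sets average ~25 same-formula isomers.
- **Targets.** 50 molecules drawn from multi-member formula buckets, at a
  seeded-random position within each bucket. (Always taking the canonically
  first member gives targets a shared structural signature that a model can
  exploit with no spectral information at all — the negative control
  caught exactly this.)
- **Spectra.** Each acyclic single bond is cleaved; both fragments ≥ 15 Da
  appear as [fragment + H]+ peaks (proton mass 1.00728 Da) with a
  deterministic per-fragment intensity (a stable hash), plus the intact
  [M+H]+ ion at modest height (0.45 of scale) so the peak every candidate
  shares does not wash out the discriminative ones. Replicates (1–3 per
  molecule, emulating a low spectra-to-molecule-ratio library) share the true
  peaks and differ in log-normal intensity noise (CV 0.25), Gaussian m/z
  jitter (SD 0.01 Da) and Poisson-count spurious peaks (mean 2).
  `fragment_signal=False` replaces the peaks with pure noise — the negative
  control.
- **Split.** Structure-disjoint by InChIKey (no molecule on both sides);
  all spectra of a molecule travel together; default test fraction 0.2.

What the generator does *not* emulate: real fragmentation chemistry
(rearrangements, multi-bond cleavage, neutral losses), adducts other than
[M+H]+, collision-energy dependence beyond a replicate index, isotope
patterns, and chimeric spectra. Passing tests therefore show that the
training objective, encoders and ranking machinery work end to end on data
with the assumed statistical structure — not that the model annotates real
spectra.

## Evaluation protocol

A default study is small (50 molecules, ~20 held-out spectra), so rank
percentages move in ~5-point steps per spectrum. All end-to-end quantities
are therefore reported over three replicate studies (consecutive seeds),
pooled at the spectrum level for rank metrics and at the pair level for
cosine distributions; the chance rate is 1/⟨candidate-set size⟩ over the
pooled test molecules. With the defaults this takes a few minutes on one
CPU core.

Observed behavior under the default conditions (the test suite and
`scripts/acceptance.py` recompute all of these at run time): pooled held-out
rank@1 lands several-fold above chance; matched pairs sit ≈0.2 cosine above
same-formula decoys; and with fragments disabled rank@1 collapses to within
sampling error of chance.

**Regularization at this scale.** The fine-tuning phase reliably lowers the
mean spectrum–candidate cosine (the mechanism it targets), measured on
held-out molecules. Its effect on held-out rank@1, however, is at the noise
level and slightly negative in our replicates — at 50 molecules the extra
push perturbs matched-pair alignment about as much as it separates decoys.
This mirrors the regime reported for hard generalization splits of real
benchmarks, where regularization's benefit also fails to materialize; the
ablation machinery reports both arms so the comparison is always explicit.

## Degenerate inputs and edge cases

Single-atom molecules encode fine (max-pool over one node). Spectra whose
peaks all sit ≥ 1000 Da raise an error rather than yielding a zero vector.
Zero-norm embeddings make the cosine undefined and raise. Exact score ties
order candidates by identifier for reproducibility, and the target's rank
counts ties against it. MSP records must declare `Num Peaks`; MGF blocks
without peaks are skipped with a warning. Candidate sets missing their own
target raise at retrieval.

## Known limitations

- The fragmentation model is a caricature; none of the learned weights are
  meaningful for real spectra.
- Hyperparameter defaults were chosen for the 50-molecule default study and
  will be wrong for materially larger data.
- Training is single-threaded numpy; a few hundred molecules is comfortable,
  tens of thousands is not.
- The contrastive loss keeps the published asymmetric (spectrum-anchored)
  form and does not mask in-batch false negatives; a symmetric
  (additionally molecule-anchored) variant is a config flag
  (`LossConfig.symmetric`) but is off by default and is not part of the
  published formulation.
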