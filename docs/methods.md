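# Methods

## Overview

`molclsp` implements a multimodal self-supervised representation learner
for small molecules.  One molecule enters as three coupled views — the 1D
SMILES substructure-token sequence, the 2D attributed heavy-atom graph,
and the 3D conformer — and the model learns by *perturbing disjoint
substructures in each view* and reconstructing what was lost, using the
other views' intact information through a shared fusion transformer.

The key structural device is the substructure/atom alignment: a
frequency-learned (BPE-style) vocabulary segments each SMILES into e
fragments, and each fragment maps to a definite set of atom indices that
partitions the molecule.  All three perturbations address substructures
through this map, so "mask fragment 3" means the same atoms in the token
sequence, the graph and the conformer.

## Substructure vocabulary and tokenization

Atom-level units are extracted from the canonical SMILES (one unit per
atom token; bonds, ring-closure digits and parentheses attach to the
preceding atom's unit and carry no atoms).  Vocabulary learning repeatedly
merges the most frequent adjacent unit pair with corpus frequency ≥
`min_frequency` (default 2) until no pair qualifies or `max_size`
substructure tokens exist (default 2048).  Ties break by higher frequency,
then lexicographically smaller merged string, so the vocabulary depends
only on corpus content, never its order.  Atom indices are reported in the
*input* molecule's atom order (recovered through RDKit's canonical-output
order map), which is the indexing the graph and conformer use — this is
what makes cross-modal alignment exact.

Unknown residual units map to a dedicated unknown id with singleton atom
sets, so the partition invariant (disjoint, exhaustive) holds for any
molecule, in or out of the training corpus.

## Non-overlapping perturbations

Per molecule and step, target counts are `floor(r_m · e)` for ratios
`r_m ∈ [0,1]` (defaults 0.15/0.15/0.15).  Selection is uniform without
replacement in the order 1D → 2D → 3D, each later pool excluding all
earlier selections, so the three sets are pairwise disjoint by
construction.  `floor` with no forced minimum means small molecules may
legitimately receive no perturbation in a modality; that keeps tiny
molecules from being over-corrupted but also means the masking losses are
exactly zero for them (their 3D denoising term still trains the decoder to
keep atoms in place).

Perturbations: 1D replaces selected fragments' token ids with the mask id;
2D replaces selected atoms' feature rows with a dedicated mask row (a
learned embedding downstream — zeros would collide with real feature
codes); 3D adds i.i.d. N(0, σ²) noise per coordinate axis (default σ =
0.1 Å, small against ~1.5 Å bond lengths).  Each molecule's augmentation
PRNG is seeded from (global seed, molecule id, step), so data-loader order
can never change the augmentation stream.

## Encoders, fusion, decoders

All neural components run on a small reverse-mode automatic
differentiation engine over NumPy float64 (`molclsp.autodiff`,
`molclsp.nn`).  This keeps the package dependency-light and bit-
deterministic on CPU; the trade-off is scale — the intended regime is
hundreds to thousands of small molecules, not millions.

* **1D**: token embedding (width z) + learned positional embedding, then a
  pre-norm transformer encoder (default 2 layers, 4 heads).
* **2D**: GIN-style message passing with edge-feature injection
  (`h_i' = MLP((1+ε)h_i + Σ_j relu(h_j + W_e e_ij))`, default 3 layers);
  sum aggregation makes it exactly permutation-equivariant.
* **3D**: directional message passing.  Messages live on directed edges
  within a 5 Å cutoff; each is initialized from its endpoint embeddings
  and a Gaussian radial basis (8 centers) of the edge length, then refined
  by aggregating incoming messages weighted through a cosine angular basis
  (4 terms) of the k→j→i angle.  Only distances and angles enter, so the
  output is invariant to rigid motions to machine precision.  Atoms with
  no neighbor inside the cutoff fall back to their own embedding (with a
  warning).

A learned length-d identity vector per modality is broadcast-added to that
modality's rows before concatenation ([1D rows, 2D rows, 3D rows]) — the
only shape-consistent reading of per-modality identity offsets when e and
n vary per molecule.  The fusion stack (default 2 pre-norm blocks, 4
heads) has **no positional table**: order information reaches it only
through the 1D encoder's positions, and the fused output is decomposed by
slicing rows back into the three modalities.  Pre-norm blocks make the
zero-weight fusion stack an exact identity, which the tests exploit as a
closed-form check.

Decoders: the 1D head is dense → GELU → layer-norm → vocabulary
projection; the 2D and 3D heads are one light GIN layer plus a linear
readout (to d target channels and to 3 coordinates respectively).

## Objectives

Per molecule: masked-token cross entropy summed over masked positions; the
structural contrastive embedding loss Σ (1 − cos(h_i, h_i*))^γ over masked
atoms with γ = 2; and coordinate denoising λ_L2·MSE + λ_cos·(1 − mean
cosine), both evaluated over **all** n atoms so the decoder must keep
clean atoms in place too (defaults λ_L2 = λ_cos = 1).  The 2D target h_i*
is the input-layer node-feature embedding of the clean graph,
gradient-stopped — the simplest well-posed target given that the
reconstruction target representation is otherwise open.  The total is a
sum of the three modality terms; batches average per-molecule sums.

## Training

Adam (lr 1e-3, no schedule, no warmup), batch size 16, float64 CPU.
Batches are processed molecule-by-molecule and averaged rather than padded
and masked: with no cross-molecule attention anywhere in the architecture
the two are semantically identical, and per-molecule processing is exact
for variable (e, n).  A fresh perturbation is drawn per molecule per step.
Runs are bit-reproducible given (corpus, config): two runs with the same
seed produce identical loss trajectories.  Checkpoints store the config,
the vocabulary fingerprint and all named float64 parameter tensors;
save→load→save is byte-identical, and loading verifies the vocabulary
fingerprint.

## Fine-tuning

The pretrained encoders and fusion stack are reused on clean
(unperturbed) inputs.  All fused rows — e substructure tokens + n atoms
(+ n more when the 3D branch is enabled) — are pooled with
`α_i = softmax_i(w·tanh(h_i))`, `z = Σ α_i h_i`; α is a strict probability
vector and z lies in the convex hull of the rows.  A 2-layer tanh MLP maps
z to the prediction; classification uses binary cross entropy on sigmoid
outputs and reports AUROC, regression minimizes and reports MAE.  By
default the whole network is tuned (a freeze-encoders switch trains only
the pooling vector and head).  Epoch selection is by validation metric, with
ties resolved toward the later epoch (rank metrics such as AUROC saturate
early while calibration keeps improving); with no usable validation metric
the final epoch is kept.  The α vector is
exported per row with modality and fragment/atom labels as the
interpretability surface.

The 3D branch is optional at fine-tuning time; disabling it removes the
3D rows from pooling and leaves every 3D parameter untouched (verified by
parameter-delta inspection in the tests).

## Synthetic fixtures

`generate_fixture_set` draws from ~57 curated templates (alkanes, branched
alkanes, alcohols, ethers, amines, carbonyls, halogenated species, benzene
/ pyridine / naphthalene derivatives) spanning 3–20 heavy atoms, with
deterministic 3D coordinates from seeded ETKDG distance-geometry embedding
(idealized planar fallback if embedding fails).  Each record carries a
`halogen` binary label and an `mw` regression label.  The fixtures
exercise rings, branches, heteroatoms, all common bond orders and both
halogen classes, but they do **not** emulate real assay data: no label
noise, no activity cliffs, no large flexible molecules, no stereochemistry
or charged species.  Passing tests therefore demonstrate mechanism
correctness (alignment, non-overlap, symmetries, optimization behavior),
not benchmark-level predictive performance, which would require pretraining
corpora and labeled benchmarks far beyond this package's scale.

## Problem sizes and numerical choices

The shipped exercises use desk-scale sizes chosen to run in minutes on one
CPU core: vocabulary from the fixture corpus itself; pretraining descent
on 64 molecules × 200 steps (default config, d = 128); masked-token
recovery on an 8-molecule overfit run × 500 steps with a granular
vocabulary (min_frequency 4, max_size 40) and ratios (0.5, 0.2, 0.2) so
every molecule carries a defined masking task; fine-tuning separability on
20 molecules (halogenated vs not) at the default 40 epochs, lr 5e-4.  Numerical details:
float64 throughout; softmax/log-softmax are max-shifted; cosine terms use
a 1e-12 epsilon guard on norms (with a warning on genuine zero rows); the
angular basis clips cosines into [−1, 1] before arccos; Adam ε = 1e-8.

## Known limitations

* No GPU, no batching across molecules inside a single matmul — throughput
  is ~20 molecules/s/core at the default width.
* Dot-separated (multi-fragment) SMILES are unsupported, as are conformer
  ensembles; one conformer per molecule.
* Hydrogens are never graph nodes; SDF blocks with explicit H are stripped
  to heavy atoms (coordinates included) so n matches across modalities.
* The 2D reconstruction target is the input-layer embedding of the clean
  graph; richer targets (e.g. deep clean-encoder features) are plausible
  alternatives and untested.
* Scaffold splitting assigns whole Bemis–Murcko groups greedily (largest
  first, to the part furthest below target); acyclic molecules group by
  their canonical SMILES.  Exact 8:1:1 sizes are only achievable when
  group sizes permit.
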