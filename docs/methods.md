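# Methods

## Overview

The package implements a three-stage molecule-design procedure: (1) a
hybrid sequence + descriptor QSAR regressor is trained on an activity table
and becomes the reward model; (2) a decoder-only autoregressive token
policy is supervised-fine-tuned on the same molecules; (3) proximal policy
optimization shifts the policy toward molecules the reward model predicts
to be potent, under a per-token KL penalty against the frozen fine-tuned
reference. A synthetic-data module supplies BindingDB-shaped tables with a
known structure–activity oracle so that every stage is trainable, and so
tests can compare learned behavior against ground truth.

## Data model and preprocessing

Activity tables carry one row per measurement: a SMILES string and an IC50
in nM. Conversion uses pIC50 = 9 − log10(IC50/nM), i.e. −log10 of the molar
concentration. Rows with nonpositive or missing IC50 are rejected and
logged. Molecules are canonicalized with RDKit; rows sharing a canonical
SMILES are merged into one record whose pIC50 is the arithmetic mean of the
measurements (the measurement count is retained). The dataset is shuffled
and split 80/20 exactly once under a recorded seed; every later experiment
reuses that evaluation split unchanged.

Descriptors are the full numeric RDKit descriptor panel (sorted by name for
determinism; the names are stored in the dataset sidecar and in reward-model
checkpoints). Descriptors that fail for a molecule become NaN and are
imputed with the training-column mean. Columns are z-scored with location
and scale fitted on the training rows only; zero-variance columns map to
zero. Inside the QSAR forward pass descriptor z-scores are clamped to
±10 — beyond the range spanned by training data a z-score carries no
calibrated signal, and unclamped extrapolation lets a policy being
optimized against the model inflate predictions without bound.

## The token codec

Molecules are represented as sequences of bracketed tokens over a
derivation grammar in the SELFIES family, implemented in
`molppo.codec`. The decoder is total: atoms are emitted with a proposed
bond order that is reduced to the minimum of the orders and both atoms'
remaining valence capacity; branch and ring symbols that cannot apply are
skipped (with their index digits); derivation stops when the current atom
is saturated. Consequently *every* string over the alphabet decodes to a
molecule RDKit sanitizes, which is the property PPO relies on — validity
never constrains optimization. A sequence containing no applicable atom
token decodes to the empty molecule; such sequences are rare (≈1% of
uniformly random strings, far fewer after fine-tuning), receive the floor
reward during PPO, and are excluded from property panels because
descriptors are undefined for them.

The alphabet covers neutral C, N, O, F, P, S, Cl, Br with bond orders 1–3,
branches, and ring closures with one- or two-digit indices. Phosphorus is
capped at valence 3 so the decoder cannot build hypervalent P that RDKit's
sanitizer would rewrite into charge-separated forms (which would break
round-tripping). Stereochemistry, charges and isotopes are outside the
alphabet: the encoder raises on such molecules, and the synthetic generator
never produces them.

## Reward model

Architecture (defaults in `QSARConfig`): token embedding (dim 128), two
stacked LSTM layers of 256 units read out at each sequence's true last
position, a dense descriptor branch (one 256-unit layer), concatenation,
one 256-unit fusion layer, and a single linear output neuron; ReLU
activations and dropout 0.3 throughout. Training uses Adam (lr 1e-3, betas
0.9/0.999), batch 16, up to 100 epochs, a reduce-on-plateau schedule
(factor 0.5, patience 5), and keeps the checkpoint with the best evaluation
MSE. The sequence-only ablation (`use_descriptors=False`) and the SMILES
character-level representation variant share the architecture, differing
only in inputs and vocabulary.

Agreement metrics are MSE and Lin's concordance correlation coefficient
with population moments; CCC is defined as 0 when both vectors are
constant. The data-efficiency experiment retrains on nested subsets of the
training split (nesting reduces between-size variance) against the fixed
evaluation split.

## Policy and supervised fine-tuning

The policy is a pre-norm decoder-only transformer (defaults: 4 layers, 4
heads, embedding 128, learned positional embeddings, context 256) with a
language-model head and a scalar value head on the final hidden states. It
is trained from scratch — at this scale the method, not a pretrained
checkpoint, is the object of study — with AdamW (lr 7e-5, weight decay
0.01), batch 16, 10 epochs, minimizing masked next-token cross-entropy on
`[bos] … [eos]`-delimited molecules.

Preprocessing offers two routes: padding each molecule to the batch
maximum, or chunking the concatenated corpus into fixed context-length
windows (the final short chunk is kept and padded, so no tokens are lost;
chunks carry full attention). The comparison harness trains both and keeps
the lower evaluation cross-entropy, always computed on untouched held-out
molecules so the variants are comparable.

Generation is inclusive nucleus sampling: the smallest probability-sorted
prefix whose mass reaches top-p (a straddling token is included) is
renormalized and sampled. top-p = 1 is full ancestral sampling; top-p → 0
degenerates to greedy decoding.

## PPO

Per rollout batch of 16: prompts are bare `[bos]` with probability
`fraction_from_scratch`, otherwise `[bos]` plus the first k ∈ [2, 8] tokens
of a training molecule; continuations are sampled at top-p = 1.0. Each
decoded molecule is scored by the reward model — the sequence branch reads
the canonical re-encoding of the decoded molecule, not the sampled
spelling, because the reward must be a function of the molecule (scoring
raw spellings lets the policy inflate rewards by re-spelling, which we
observed as a large train/eval reward gap). Rewards are clipped to the
physically plausible pIC50 range [0, 12]; undecodable output receives the
floor reward 0.

The scalar reward is attributed to the final generated token; a per-token
penalty `kl_coef · (log π_θ − log π_ref)` is subtracted along the sequence.
Advantages are GAE(γ=1, λ=0.95) over the generated region using the value
head, whitened within the batch. The update maximizes the clipped surrogate
(ε = 0.2) plus 0.1 × value loss for 4 optimization passes per rollout
batch. The value head reads gradient-stopped hidden states by default so
value-regression error cannot perturb the policy — this makes the
dominant-KL limit exact (with a huge coefficient the policy provably stays
at the reference). An optional proportional controller adapts the KL
coefficient toward a target per-sequence KL (init 0.2, target 6, horizon
10 000); training aborts early if the mean per-token KL exceeds a ceiling.

The PPO learning-rate default is 1.41e-5, the documented default of widely
used RLHF PPO trainers; the desk-scale pipeline overrides it (1e-3) because
a ~0.3M-parameter from-scratch policy needs far larger steps to move within
14 epochs.

Because advantages are whitened to unit scale every batch, the magnitude of
a policy update is set by the learning rate rather than by the raw reward
or penalty scale. Two consequences worth knowing: a very large KL
coefficient pins the policy to the reference only up to an lr-dependent
noise floor (at the default learning rate the residual KL is ~1e-4
nats/token), and raising the coefficient beyond the point where the penalty
dominates the reward has no further effect on step sizes.

## Synthetic data

`generate_molecules` draws random token strings (length 8–40) over a
drug-like token subset (C/N/O/F/S/Cl/Br, single/double bonds, one-digit
branches and rings) and decodes them, which cannot fail; duplicates and
empty decodes are re-drawn. The efficacy oracle is an explicit descriptor
function: pIC50 = 4 + 5·sigmoid(w·z), where z are five named descriptors
(MolWt, MolLogP, TPSA, NumHDonors, RingCount) standardized by fixed
drug-like constants — *not* dataset statistics, so the oracle is a pure
function of the molecule. Default weights (1.0, 0.7, −0.5, −0.3, 0.4) make
larger, more lipophilic, less polar molecules more potent; the >7 region
occupies roughly the top 1–2% of randomly drawn molecules, which
`oracle_admits_high_efficacy` verifies by rejection sampling before any PPO
run. Measurement tables add Gaussian noise (sd 0.3 pIC50 units, typical of
inter-assay variability) per measurement and Poisson-distributed repeated
measurements (mean 0.25 extra rows per ligand), then convert to nM.

What the generator does not emulate: real pharmacology (no target-specific
chemistry), stereochemistry, charged species, assay artifacts, or the
clustered scaffold structure of real medicinal-chemistry series. Passing
tests therefore demonstrate that the machinery — reward learning, policy
fine-tuning, PPO exploitation of a descriptor-driven landscape — works; they
do not certify performance on real activity data.

## Desk-scale study conditions

The default end-to-end configuration (`molppo.pipeline`) is sized for a
single CPU: a 500-molecule synthetic dataset; reward model with hidden size
64, embedding 32, dropout 0.1, 30 epochs; policy with 2 layers, 2 heads,
embedding 64, context 64, SFT lr 1e-3 for 10 epochs; PPO for 14 epochs of
16 rollout batches (batch 16, 4 inner passes, lr 1e-3, initial KL
coefficient 0.05, value-loss weight 0.25, 75% of prompts bare `[bos]`). A full pipeline run takes
on the order of a minute. The corpus of random-string molecules is near
incompressible, so SFT evaluation losses plateau around 2 nats/token —
unlike a real medicinal-chemistry corpus, whose regularities a language
model can compress much further.

## Numerical choices and limitations

- All tensors are float64; training is exactly reproducible given a seed.
- LSTM readout uses the final hidden state at each sequence's true length;
  QSAR batches are right-padded with the pad id.
- Nucleus sampling includes the straddling token (inclusive cut).
- The data-efficiency monotonicity check allows 10% relative slack per size
  step for training noise.
- The fold-change metric uses arithmetic means of linear-scale IC50; a
  geometric-mean variant is reported alongside.
- Novelty counts each generated sequence against the canonical train+eval
  union; a separate uniqueness fraction reports duplicate collapse.
- KDE plots use scipy's Scott's-rule bandwidth, recorded in the report.
- The reward model is only as good as its training distribution; PPO can
  still exploit residual misestimation inside the clamped region, so
  reported efficacies of generated molecules are model predictions.
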