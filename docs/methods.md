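# Methods

## Problem setting

Proteochemometric (PCM) affinity regression predicts `y = −log10 K` for a
compound–kinase pair from a joint feature vector. Activity panels are
imbalanced: inactive pairs (y < 6, weaker than 1 µM) typically outnumber
actives several-fold, and a least-squares regressor trained on such data
shifts its predictions toward the inactive range, costing recall at the 1 µM
decision threshold. The package treats this as an *imbalanced regression*
problem and repairs it by generative oversampling of the active region,
compared against SmoteR interpolation and random undersampling.

## Standardization

Concentrations (Ki/Kd) are unified to nanomolar and transformed as
`p = 9 − log10(value_nM)`, so 1 µM → 6, 1 nM → 9, 0.01 nM → 11. pKi/pKd
inputs pass through untouched. Percent-of-control readouts are a percentage,
not a concentration; no universal mapping to p-affinity exists, so they are
accepted only through a user-supplied conversion callback and dropped (with a
warning) otherwise. Repeated measurements of one compound–kinase pair are
collapsed by a coefficient-of-variation rule: CV = sample SD / mean of the
group's p-affinities; a group with CV ≤ 0.05 keeps one randomly chosen
member (seeded), a group above the threshold is discarded. CV is computed on
the *transformed* values, which makes the rule invariant to the reporting
unit; computing it on raw concentrations would make the same assay pass or
fail depending on the unit scale. The activity cutoff is inclusive
(p ≥ 6 is active) because 1 µM itself maps exactly to 6.

## Representations

Compound sentences are Morgan substructure identifiers at radii 0 and 1, one
per (atom, radius), in atom order. Symmetry-equivalent environments are kept
(`includeRedundantEnvironments`), so the sentence length equals 2 × heavy
atoms for any molecule in which every atom has a bond; an isolated atom
(methane) has no radius-1 environment and contributes a single identifier.
Protein sequences are split into three frames of non-overlapping 3-grams
(offsets 0, 1, 2; partial trailing words dropped), giving exactly three
frame sequences per protein. Embeddings are skip-gram with negative
sampling, implemented in NumPy (single-threaded, fully seeded); any
pre-trained key→vector table in word2vec text format can be loaded instead.
Tokens missing from a vocabulary embed as the zero vector, preserving the
sum semantics of sentence embedding. The default combination scheme
concatenates a 300-dim compound embedding with the elementwise sum of the
three 300-dim frame embeddings (600 features; 601 with the label). Frame
vectors are token-sums before the cross-frame sum — the only reading
consistent with summing three frame embeddings.

## PCM-AAE and PCM-GAN

All networks are fully connected and trained with Adam (learning rate 0.01,
batch size 64, 50 epochs by default, or an exact iteration count when set).
Defaults: latent dimension 16; encoder 601→128→64→16 and mirrored decoder,
both with batch normalization and dropout 0.1 in every layer (these
stabilize the adversarial game); generator and discriminator 2×64 plain ReLU
stacks. Per iteration the AAE takes a reconstruction step (MSE), a
discriminator step (binary cross-entropy; encoder latents labeled real,
generator latents fake) and a non-saturating generator step. The
discriminator sees latent vectors only — the adversarial game is placed in
the low-dimensional latent space, which is what makes label generation
reliable where the data-space GAN fails. The adversarial loss weight ramps
linearly 0 → 1 over the first half of training (cost annealing, implemented
as a learning-rate scale on the adversarial steps; Adam is invariant to loss
rescaling, so scaling the step size is the operative form). Gradients are
clipped to global norm 5 as a safeguard at this relatively high learning
rate. Divergent (non-finite) losses abort with a diagnostic.

Sampling goes `z ~ N(0, I) → generator → latent → decoder → 601-dim row`
with batch-norm in inference mode (running statistics). A generated row is
*valid* when its label lies in [6, 11] — the 1 µM–0.01 nM window actives
live in. Generator checkpoints are saved every epoch after a 10-epoch
burn-in; when the stored count exceeds 24 the set is thinned to every other
checkpoint and the saving interval doubles, so at most 24 checkpoints always
span the whole post-burn-in run. This is a deterministic stand-in for
saving generators at random times, and it is what gives the ensemble
*diverse* generator states: early checkpoints sample broadly, late ones
match the training distribution closely.

PCM-GAN maps noise straight to 601-dim rows with a data-space
discriminator. Its training is unstable by nature; the implementation
promises bounded finite losses and dimension conservation, not convergence.

## Balancing

"Balanced" means equal active/inactive counts. Generator augmentation draws
rows, keeps those passing the valid-label filter, and appends exactly enough
to reach parity; originals are never modified and appended rows carry a
synthetic flag. If fewer than 1 % of draws are valid after 100× the needed
rows, the generator is declared starved and an error raised. SmoteR
interpolates a rare (active) row with one of its k = 5 nearest rare
neighbours, `x = a + u(b − a)`, `u ~ U(0,1)`, labeling the child with the
distance-weighted average of the parents (the child label always lies
between them); the binary-relevance form with the activity cutoff as rarity
threshold is used since no continuous relevance function is specified for
this domain. Random undersampling removes majority negatives uniformly.

## Predictors and the ensemble

The DNN regressor has three ReLU hidden layers of 200 units and a sigmoid
output; labels are divided by `label_scale = 14` (comfortably above any
plausible p-affinity) so they fit the sigmoid range, making the prediction
range exactly [0, 14]. Loss is MSE under Adam (default lr 1e-3, 100 epochs —
the predictor's own schedule is a free choice here and is exposed in
`DnnConfig`). Features must be standardized to zero mean/unit variance with
training-set statistics (population SD; constant features keep a unit
divisor); the test suite verifies the convergence advantage of
standardization directionally. Random forest (500 trees, ≤ 200 features per
split) and XGBoost are the classical baselines.

EPA fits one member DNN per generator on a generator-balanced copy of the
training set; all members share one scaler fitted on the original training
features so their outputs are comparable. The n × m matrix of member
re-predictions of the *original* rows trains the RF stacker against the
original labels — synthetic rows never reach the stacker's targets, so the
stacker calibrates the ensemble on measured data only. ENB is identical
minus augmentation, members differing only by seed; EPA/ENB comparisons are
run on identical splits with identical member seeds (paired design), and
`epa_vs_enb` packages the 20-repetition paired-t-test protocol.

## Evaluation

CV1 draws a stratified 80/20 row split. CV2/CV3 partition kinases/compounds
(each entity to the training side with probability 0.8), CV4 partitions both
axes at 2/3 (so used train:test rows land near 4:1) and keeps only
train-side×train-side and test-side×test-side rows. Partitions are
resampled (default ≤ 500 tries) until the train fraction is within 0.02 of
0.8 and, when requested, both sides are within 0.05 of class parity; failure
reports the best-achieved constraint state. Entity disjointness holds by
construction for every candidate. Strict-unseen filtering removes test rows
whose kinase exceeds 25 % global-alignment identity (match 1, mismatch 0,
gap open −1, extend −0.5; identity = matches/alignment length) or whose
compound exceeds 0.8 Tanimoto on 2048-bit radius-2 Morgan fingerprints to
anything in training; thresholds are strict inequalities, so boundary values
survive.

Metrics use scikit-learn/SciPy (PCC, MAE, MSE, AUC with midrank ties, F1,
precision, recall; predictions are thresholded at the same cutoff 6 used for
the true classes). BEDROC follows the Truchon–Bailey closed form at
α = 80.5, with tied scores resolved by averaging the rank weights inside a
tie. The selectivity score is hits/tested kinases; the subfamily odds ratio
is built on the 2 × 2 {hit, non-hit} × {in, out} table with the
Haldane–Anscombe 0.5 correction when any cell is zero. The space projection
is PCA to 50 components followed by Barnes–Hut t-SNE (perplexity 30,
seeded). The paired comparison is a two-sided paired t-test; a difference
vector with (numerically) zero variance is flagged degenerate.

## Synthetic data: what it emulates and what it does not

The fixtures generate (i) raw activity tables with engineered duplicate
groups whose CV sits on either side of 0.05, with survivor counts known in
advance; (ii) toy SMILES/FASTA corpora for embedding and similarity-filter
tests; (iii) structured PCM datasets. For (iii), class structure is drawn
in a 12-dimensional latent space — Gaussian clusters per class, standard
normal centers, spread `cluster_sd` — and lifted to 600 observed features
by a fixed random linear map plus small white noise. The low intrinsic
dimension mirrors real PCM embeddings, where a few dozen principal
components carry ~90 % of the variance; the default `cluster_sd = 1.0`
leaves the classes moderately overlapping, so the minority class is
genuinely hard to fit and imbalance has a measurable cost (at ≲ 0.2 the
classes are nearly separable and nearest-centroid recovers them at > 95 %).
Positive labels are uniform in [6, 11] and negative in [3, 6), so the cutoff
separates classes exactly and generated-label validity is a meaningful
learning target. Default imbalance is 1:4. Each row gets a distinct
synthetic (compound, kinase) pair so the CV2–CV4 splitters have entity
structure.

Passing tests on these fixtures show that the machinery behaves as
specified under controlled conditions — they do not show that EPA improves
real kinome panels: the fixtures have no structure–activity relationships,
no activity cliffs, no assay noise structure, and labels carry no
information beyond class membership.

## Problem sizes and numerical choices in the shipped experiments

The packaged experiments use desk-scale sizes chosen as the smallest at
which the studied effects are stable: the generator-validity experiment
trains on 500 positive rows for exactly 1000 iterations and evaluates 1000
samples over five seeds (median reported); the EPA-vs-ENB experiment uses
n = 500 at 1:4 imbalance, m = 6 members (64-64 hidden units, 60 epochs —
small members keep the 240 model fits of the 20-repetition paired protocol
tractable while leaving the augmentation effect intact), one AAE trained
for 2000 iterations on the positives with checkpoints reused across
repetitions (reuse is the default mode; per-repetition retraining is also
supported).

## Known limitations

* The AAE inherits GAN-style failure modes: partial variance collapse early
  in training (visible as a generated-feature SD below the training SD); the
  checkpoint ensemble is the designed mitigation.
* SmoteR is implemented in binary-relevance form only.
* Sequence identity uses a simple identity matrix with affine gaps, not a
  substitution matrix; for distant homologs this underestimates similarity.
* The skip-gram trainer is single-threaded NumPy: fine for toy corpora,
  not for ZINC/Swiss-Prot-scale corpora — pre-trained vector tables are the
  intended route there.
* Kinase-domain extraction from full-length sequences is out of scope; the
  featurizer embeds whatever sequence it is given.
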