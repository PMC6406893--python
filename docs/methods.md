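# Methods

## Problem and model

Natural products (NPs) — secondary metabolites of living organisms — occupy
regions of chemical space that synthetic screening compounds (SMs) rarely
reach: they tend to carry more oxygen, more stereocenters, fewer nitrogen
atoms and a lower element-distribution entropy. `npscout` quantifies
*NP-likeness* two ways:

1. **Random-forest class probability.** A forest of 100 trees
   (`max_features = sqrt`, `class_weight = "balanced"`, otherwise
   scikit-learn defaults) is trained on binary molecular fingerprints with
   NP = 1 as the positive class. The NP-likeness of a molecule is the soft-vote
   probability — the mean of the per-tree leaf class distributions — which
   produces a fine-grained score in [0, 1] rather than a step function.
   A molecule is called NP iff p > 0.5; a tie at exactly 0.5 classifies as SM,
   so "probability above threshold" is strict. Three feature flavors share one
   training path: MACCS keys (166 public SMARTS keys; the default model, chosen
   for interpretability), Morgan fingerprints of radius 2 hashed to 1024 bits
   (required for similarity maps), and a 16-descriptor physicochemical vector.
2. **Fragment-frequency baseline.** Every heavy atom contributes an *atom
   signature*: the canonical SMILES of its circular environment up to bond
   depth 3, rooted at the atom. A signature f with occurrence counts c_NP(f),
   c_SM(f) and corpus totals T_NP, T_SM receives the weight

       w(f) = clamp( log10((c_NP+α)/(T_NP+α)) − log10((c_SM+α)/(T_SM+α)), −3, 3 )

   with pseudo-count α = 1. A molecule's score is the mean weight over its
   atoms (unseen signatures contribute 0), hence also in [−3, 3]; score > 0
   labels NP, and (s+3)/6 maps scores onto [0, 1] for ROC analysis. The
   weight is evaluated as a *difference* of logarithms so that swapping the
   two training corpora negates every weight exactly, bit for bit.

## Standardization pipeline

Raw records pass through: parse → keep the largest salt component → element
whitelist {H, B, C, N, O, F, Si, P, S, Cl, Se, Br, I} → neutralize and merge
tautomers → strip all stereo descriptors → molecular-weight window
150–1500 Da (inclusive; the filters are strict "below"/"above") → deduplicate
on canonical SMILES. Every removal is tallied and the report enforces the
conservation identity n_out = n_in − Σ removals. Choices where the pipeline
order was open:

* Salt stripping keeps the fragment with the most heavy atoms; ties break by
  higher molecular weight, then lexicographically smallest canonical SMILES —
  fully deterministic.
* The MW filter is applied to the final neutralized parent (the conservative
  reading when only post-pipeline counts are observable).
* Neutralization and tautomer merging use RDKit's `rdMolStandardize`
  Uncharger + TautomerEnumerator; the contract asserted by tests is
  idempotence and the merging of keto/enol and stereoisomer pairs, not a
  specific transform-rule set. Non-removable charges (e.g. quaternary N) are
  retained.
* Parse failures are counted and skipped, never fatal.

## Descriptors

The physicochemical vector holds the 15 classical 2D descriptors (weight,
Crippen log P, Ertl TPSA, H-bond acceptors/donors, heavy atoms, rotatable-bond
fraction, N and O counts, acidic and basic atom counts, formal-charge sum,
aromatic atoms, potential stereocenters, rings) plus the Shannon entropy of
the element distribution. Conventions that needed fixing:

* Element entropy uses log base 2 and includes implicit hydrogens; a
  single-element atom set has entropy 0. Base choice affects scale only, not
  ranking.
* Acidic atoms are the O–H oxygens of carboxylic/sulfonic/phosphonic groups
  (phenols excluded); basic atoms are non-amide, non-aromatic sp3 amines plus
  amidine/guanidine nitrogens. The SMARTS lists are module constants.
* Stereocenter counts include unassigned centers, since stereochemistry is
  stripped upstream.
* MACCS key k (1-based) is stored at array index k−1; the convention is
  recorded in model metadata so fingerprints are never mixed.
* log P / TPSA are atomic-contribution approximations; no attempt is made to
  reproduce any proprietary descriptor engine numerically.

## Training-set construction

The SM pool is first purged of any molecule whose canonical SMILES occurs in
the NP corpus, then sampled without replacement to the NP corpus size. The
merged library is split 4:1 into train/test on molecules (before
featurization). Training fingerprints are then deduplicated within class and
*conflict-filtered*: a bit set occurring under both labels is removed from
both classes, so the representation carries no contradictory supervision.
Test data is never conflict-filtered. All steps are deterministic given their
seeds; the dataset container records counts at each reduction.

## Evaluation

MCC is computed from the closed confusion-matrix formula with the
0-denominator → 0 convention; AUC is the normalized Mann–Whitney statistic
(ties count ½). Cross-validation uses stratified folds, shuffled with a fixed
seed; when k exceeds the minority-class count (e.g. leave-one-out) plain
k-fold is used instead, since stratification is then impossible. Pooled
out-of-fold metrics are reported alongside per-fold values.

## Similarity maps

For a Morgan2 model, the weight of atom i is
P(NP | full fingerprint) − P(NP | fingerprint with atom i masked), where
masking removes the bits whose every generating environment is *centered* on
atom i; bits also supported by other atoms survive. This is the established
convention for hashed circular fingerprints and keeps the weights
fine-grained; an alternative "containing" mode (mask any environment that
touches the atom) is available behind a flag. Rendering maps positive weights
to green and negative to orange, with opacity scaled by the molecule's
maximum absolute weight (an absolute scale can be supplied for cross-molecule
comparison). Attribution is defined only for Morgan2 models — MACCS keys are
not atom-local in the same sense and requesting maps for them is an error.

## Library profiling

PCA operates on z-scored descriptors (the columns mix Da, Å² and counts;
unscaled PCA would be dominated by molecular weight). Constant columns are
dropped with a warning; component signs are fixed by making each component's
largest-magnitude loading positive, so projections are reproducible.
Probability histograms use 20 fixed-width bins over [0, 1] (so the
[0.4, 0.6] near-threshold band aligns exactly with bin edges); exact 1.0
falls in the top bin. Profiles report the fraction predicted NP, the
fractions pinned at exactly 0 and 1, and the near-threshold fraction; an
empty library reports null fractions.

## Synthetic corpora: what they emulate and what they do not

The fixture generator assembles molecules from scaffold grammars with seeded
random decoration: NP-like from oxygen-rich, nitrogen-free aliphatic
scaffolds (pyranose, lactones, decalin/spiro cores; ≥ 2 stereocenter-capable
carbons), SM-like from aromatic amine/amide/sulfonamide scaffolds (≥ 2
nitrogens). This reproduces the class contrasts the method exploits — N
count, O count, chirality, element entropy — and guarantees separability: a
depth-1 rule on nitrogen count alone reaches ≥ 0.9 accuracy on noise-free
corpora. A `noise_rate` fraction of each class (default 0.05) is replaced by
motif-free decoys (alkyl benzenes/cyclohexanes/tetrahydrofurans) so that
classifier tests assert thresholds (AUC ≥ 0.95, MCC ≥ 0.80) rather than
perfection. Every generated record is passed through the standardization
pipeline at generation time, so fixture corpora re-standardize unchanged.

These corpora are *not* realistic natural products: they lack macrocycles,
glycosylation patterns, rare ring systems and the long tail of real NP
diversity, and their separability is planted. Passing tests demonstrate that
the pipeline, models and metrics behave correctly on data with the stated
statistical structure — not that any particular accuracy will be achieved on
real chemical libraries.

## Problem sizes and defaults

The study-scale corpus used by the acceptance tests and the acceptance script
is 2000 NP-like + 2000 SM-like molecules at noise rate 0.05 with a 4:1
train/test split and 10-fold CV — large enough for stable metric estimates
on a single CPU. Unit tests use 150–300 molecules per class. Forest seeds,
split seeds and generator seeds are explicit everywhere; there is no hidden
global randomness.

## Known limitations

* Tautomer canonicalization follows RDKit's transform rules; molecules whose
  preferred tautomer differs from RDKit's canonical choice are represented by
  the latter.
* The fragment-score table grows with corpus diversity (one entry per distinct
  depth-3 environment); no pruning is applied.
* Attribution masks fingerprint bits, not atoms in the graph: the masked
  vector may not correspond to any realizable molecule. This is inherent to
  the similarity-map construction.
* The physchem-flavor forest trains on 16 descriptors, not a full commercial
  descriptor suite.
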