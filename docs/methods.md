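# Methods

This document records what the models compute, the conventions the pipeline
commits to, the design of the synthetic-data generator, and the training
recipes used by the test and acceptance runs — including why two of those
recipes deviate from the defaults.

## 1. Site calling from 3'-end reads

**PASS reads.** A polyA-site-supporting read is identified from its alignment:
the untemplated poly(A) tail must appear as a terminal soft clip (3' clip for
plus-strand alignments; leading clip, read as Ts, for minus-strand ones). Tail
adenosines that continue a genomic A-run beyond the alignment end are genomic,
not untemplated, and are subtracted; a read qualifies when ≥2 non-genomic As
remain. Because cleavage adjacent to a genomic A-run is intrinsically
ambiguous, the cleavage position is normalised to the **first A of the run**
whenever the alignment ends inside one — all reads from such a site collapse
to a single canonical coordinate. A small fraction of simulated reads is
unrecoverable by construction: when tail As chance-match the reference, the
genomic subtraction can push the non-genomic count below threshold.

**Clustering.** Cleavage positions are clustered greedily within ±24 nt:
positions are visited in order of decreasing read count (ties broken to the
5'-most position in transcript orientation, i.e. the larger coordinate on the
minus strand), and each seed absorbs every unassigned position in its window.
The seed is the representative position; every read joins exactly one cluster,
so read counts are conserved exactly.

**Filtering and gene assignment.** A site is kept when it has ≥10 reads and
its share of the host gene's reads strictly exceeds 2% in at least one
lineage. Genes are matched by span, optionally extended past the annotated
terminal exon (capped by a maximum extension, the next same-strand TSS, and
the chromosome end) to capture sites in unannotated 3' UTR extensions.

## 2. Training examples

Each called site yields 51 windows of 240 nt, anchored at offsets −25..+25
from the representative position. The cleavage target is the empirical
distribution of read 3' ends over the 50 positions at offsets −25..+24 from
the window anchor; reads falling outside the window are dropped and the
vector renormalised (windows left empty are skipped). Negatives come from
four origins — background-transcript, shuffled-positive, site-distal, and
intergenic windows — and carry the constant 1/50 = 0.02 vector. Splits are
made at the **site** level so no site's shifted windows straddle train/val/
test. Strength labels are usage log-odds with a 0.5 pseudocount guarding the
0 and 1 boundaries.

## 3. Model architecture and losses

Both networks share a trunk: 1-D convolution (window 8) over the one-hot
(240×4) input, ReLU, max-pool (3), bidirectional LSTM, flatten, dense layer
with dropout 0.3. The classification network ends in two heads: a sigmoid
unit (site present?) and a length-50 softmax (cleavage distribution). Its
loss is the equally weighted sum of binary cross-entropy and
KL(observed ‖ predicted); the KL term reduces to cross-entropy minus the
(constant) entropy of the target, so its gradient is the usual softmax
residual. The strength network replaces the heads with a single linear unit
trained by mean squared error against usage log-odds. Optimisation is Nadam
(Adam with Nesterov momentum), batch size 100, default learning rate 0.001;
training restores the weights of the best validation epoch.

The whole engine is NumPy (float32, channels-last): convolution via im2col,
LSTM gates in i, f, g, o order with forget-gate bias 1, inverted dropout.
Layer gradients are verified against central finite differences in the unit
suite. Models serialise to a single `.npz` holding parameters plus a JSON
config, so save/load round trips are exact.

### Reduced-capacity training choices

Desk-scale runs use 16 conv filters / 16 recurrent units / 32 dense units.
Two deviations from the defaults are deliberate, and both are
capacity-dependent — full-size models did not need them:

- **Learning rate 0.003 for classification.** At reduced capacity with the
  default 0.001, the classifier frequently settles on "predict the class
  prior", a saddle where the validation loss is flat and no feature is
  learned. The higher rate escapes it within the small epoch budgets used
  here. Regression shows no such saddle, so strength models keep 0.001.
- **`train_with_restarts`.** Even at 0.003 the saddle occasionally recurs, so
  training is wrapped in a detector: if the validation-loss trace stays
  within a 0.05 band (or never improves on epoch 0), the model is rebuilt
  with a new seed, up to three times. Restarts are driven purely by the
  validation trace, never by test data.

## 4. Scanning, consolidation, and variant effects

The classifier is slid across the sequence one nucleotide at a time (minus
strand: reverse complement, with exact coordinate bookkeeping verified by
shift-equivariance tests). Confident anchors are consolidated: runs of
retained anchors (gap 0 by default) pool their cleavage vectors in genomic
coordinates, average over contributing records, and report the position with
the largest mean cleavage mass (ties to the 5'-most) along with the pooled
vector, its mean cleavage position (MCP), and the maximum classification
probability. Calls are classified by genomic location with the precedence
terminal-exonic > upstream-exonic > intronic > extended-terminal-exonic >
intergenic.

Variant effects are predicted by scanning the reference and alternate
haplotypes: a variant is screened out unless it touches an important hexamer
(in either allele or orientation, within ±5 nt); a mismatch between the
stated and actual reference allele raises an error rather than miscalling. A
call is significant when classification probability ≥0.9, strength ≥ −9, and
|Δ strength| ≥ 1.

## 5. Grammar analyses

Hexamer importance replaces one hexamer at a time with random sequence
(multiple replicates) and records the change in predicted log-odds; profiles
aggregate these by (hexamer, position relative to the site). Significance is
assessed against a flank null built from positions |offset| > 40. Cleavage
entropy is the Shannon entropy of the (renormalised) cleavage vector.
`motif_distance_perturbation` moves one element away from another while
preserving the window's base multiset, so base-composition effects cancel;
`count_optimal_motifs` checks the grammar precondition (a PAS ending within
~30 nt upstream, a GU-core element downstream by ≤10 nt) and tallies optional
elements.

## 6. Context and usage

Gene-architecture features (distances to splice sites on log scale, exon and
intron sizes, PWM splice-site strengths learned from the annotation itself,
last-intron flags, proximal/distal pair features) feed a logistic usage
model: features are standardised, fitted by maximum likelihood, and pruned by
Wald tests; a penalised scikit-learn fit is the fallback when the unpenalised
likelihood fails (e.g. perfect separation causing a numerical error), flagged
as such with NaN p-values. Quantile matching pairs used and unused sites by
strength before context comparisons. Multiple testing uses Benjamini–
Hochberg (verified against a reference implementation to 1e-12); differential
APA between conditions uses Fisher's exact test per gene×condition with a
minimum usage-change requirement.

## 7. Synthetic-data generator (study conditions)

All evaluations run on data from `synthgen`, whose defaults define the study
conditions:

- **Grammar.** PAS `AATAAA` ending 21 nt upstream of cleavage (sense offsets
  −26..−21); CstF element `TGTGTG` starting at +10; optional motifs, each
  planted with probability 0.5: UGUA at −60..−35, U-rich `TTTTTT` at
  −18..−10, a second CstF `TGTGTG` at +18..19, G-rich `GGGGGG` at +32..50.
- **Strength.** Additive: −4.0 + 1.6 per optional motif + N(0, 0.3) noise;
  per-gene usage is the softmax of site strengths, so usage sums to 1.
- **Reads.** 3' ends scatter around the site as a discretised Gaussian
  (sd 2.0 nt by default); non-genomic tail lengths are uniform on 2..10; 30%
  of sites are planted at the start of a genomic A-run to exercise the
  first-A normalisation; reads can be emitted as TSV or as a coordinate-
  sorted SAM whose alignments deliberately extend through genomic A-runs.
- **Spacing–heterogeneity coupling.** When `cstf_spacing_range` is set, each
  site draws its CstF offset uniformly from the range and its cleavage
  dispersion grows by 0.15 nt per nt of spacing beyond the minimum — tighter
  PAS↔CstF grammars cleave more precisely. Models trained on such windows
  learn the distance→heterogeneity relationship, which is how the
  entropy-vs-distance direction is evaluated: the mechanism is in the truth,
  and the model is probed with motif-moving perturbations it never saw.
- **Hard negatives.** `nonfunctional_mode="element"` corrupts one random PAS
  base or erases the CstF element (50/50), forcing classifiers to learn the
  PAS∧CstF conjunction; `"pas"` corrupts only the PAS. Variants either
  destroy a planted PAS, revert a latent `AATCAA` site to a functional PAS,
  or change an intergenic base far from any site.

Everything is deterministic under fixed seeds.

## 8. Limitations

- The generator's background is i.i.d. uniform; there is no realistic
  expression model, splicing noise, internal priming, or sequencing error.
- The grammar is a single canonical PAS/CstF pair with fixed motif strings;
  real sites use a wider hexamer repertoire and graded element affinities.
- Reduced-capacity networks are used throughout testing; their absolute
  accuracies are not comparable to full-size models trained on large corpora.
- Spurious-call assessment treats a background window as a genuine positive
  when it satisfies the grammar precondition by chance — correct for this
  generator, but not a statement about genomic background rates.
- A small, quantifiable fraction of PASS reads adjacent to A-runs cannot be
  recovered from alignments (Section 1); site-level recovery is unaffected at
  the depths used here.
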