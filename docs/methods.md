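# Methods

This note documents the models, procedures and numerical choices behind
`isomirnet`, the parameters that matter, what the synthetic-data
generator does and does not emulate, and the known limitations.

## Chimera deconvolution

A chimeric read is modeled as `[small-RNA portion][0–4 nt spacer][target
portion]` (miRNA-first, the ligation convention; the reverse layout is
supported via `mirna_first=False`). Calls are built from externally
produced local-alignment hits (BLAST tabular, 1-based inclusive
coordinates converted to 0-based half-open on ingestion; minus strand
recognized by `sstart > send`).

Filter defaults and their meaning:

| parameter | default | meaning |
|---|---|---|
| `max_evalue` | 0.1 | hit significance cutoff (inclusive) |
| strand | `+` only | chimera fragments read off the sense strand |
| `gap_openings` | 0 | "looped"/gapped alignments discarded, keeping variant calling substitution/end-edit only |
| `max_gap` | 4 nt | maximal separation of the two portions in the read |
| `max_overlap` | 0 nt | ligation inserts spacer; portions never overlap |
| `min_variant_quality` | 30 (strict >) | Phred floor at isomiR variant positions |
| `min_support_reads` | 10 | recurrence required of each miRNA/isomiR portion |
| `top_k_pairs` | 1 | pairs kept per read (5 reproduces a published sensitivity variant) |

Pair ranking is total and deterministic: combined e-value ascending
(combined = max of the two hits — conservative on the weaker mate),
combined bit score descending (sum), then lexicographic
(miRNA id, transcript id, positions). The support filter counts
*original* reads: exact duplicates are collapsed early for efficiency but
their multiplicity is preserved and counted, since identical chimeras are
independent observations of the same portion once PCR duplicates are
handled upstream (`count_multiplicity=False` switches to distinct
post-collapse reads). Support is counted after best-pair selection.

The 10-read threshold is backed by `support_probability(n, L, e, k)`:
P(X ≥ k) for X ~ Binomial(n, p) with p = e·(1−e)^(L−1), the chance that a
read shows one *specific* single-error variant (the chosen base wrong,
all others right). The tail is summed exactly in log space
(`lgamma`-based terms + log-sum-exp); at (1000, 22, 0.001, 10) it gives
8.87·10⁻⁸. The single-error form of p is an assumption — it reproduces
the canonical figure and is the dominant term, since multi-error reads
producing the *same* variant are rarer by further factors of e.

## IsomiR classification

The anchored comparison slides the isomiR against its reference at
integer offsets in [−6, +6] (no gaps — gapped hits never reach this
stage) and keeps the offset maximizing matches in the overlap; ties
prefer the smallest |offset|, then the negative one. An error is raised
below 50% identity at the best offset. Types follow from the anchoring:
offset signs give 5′/3′ addition or deletion; a zero offset with a
terminal mismatch run is a replacement (equal-length trim+tail events at
one end are thus read as replacements — the definition adopted for the
ambiguous case); one internal mismatch (not contiguous with an overlap
end) is a SNP, two or more an MNP; labels combine freely; an exact match
has no label. Templated and non-templated additions are not
distinguished (that would need genome context, which classification does
not use).

Type enrichment per miRNA is a one-sided binomial upper tail,
P(X ≥ observed | n = interactions of that miRNA, p = expected type
frequency), with the expected frequency defaulting to the pooled
frequency of the type over all miRNAs in the data set (a uniform 1/8 is
available); correction is Bonferroni over all tests performed —
conservative, chosen because only "corrected" is specified by convention
in this analysis style; the correction method is configurable.

## Training pairs

Sites are extended by 25 nt at the 3′ end, truncated at the transcript
end, and dropped when still shorter than 30 nt. One negative per positive
keeps label balance: same small RNA, decoy interval of the *same length
as its positive* (length distributions matched between classes — the
matching is our choice, made so the classifier cannot separate classes on
length alone), uniformly sampled without replacement from valid 3′UTR
starts, ≥ 10 nt from every positive site, and passing the energy screen.

Duplex energy has two backends. `builtin_proxy` scores the best ungapped
antiparallel alignment of the small RNA against the reversed site with
+3 per G:C, +2 per A:U, +1 per G:U and returns the negated total — a
closed-form, monotone stand-in for hybridization free energy, not a
thermodynamic model. `external_cofold` shells out to an
RNAcofold-compatible executable and parses its ΔG. The acceptance
predicate defaults to `energy < +10 kcal/mol` — the criterion as
conventionally printed, which is permissive (nearly every candidate
passes, since energies are ≤ 0); users who read the criterion as
requiring a stable duplex can set the threshold to −10 and/or flip the
predicate. Both are supported because the sign convention of the printed
criterion is ambiguous.

Splits: `by_pair` is stratified by label with round(0.8·n) per label;
`by_mirna` partitions miRNA identities (no reference miRNA on both
sides), testing generalization to unseen miRNAs.

## The interaction classifier

Architecture (defaults): one-hot 4×30 and 4×60 inputs (rows A,T,C,G; N
uniform; longer sequences trimmed and shorter N-padded at the 3′ end,
preserving the seed); per branch Conv1D with 10 kernels of 4×8 (valid,
stride 1, ReLU) then max pooling (size 4, stride 1), giving 10×23/10×53
then 10×20/10×50; branch concatenation along positions (10×70); a
bidirectional LSTM with 10 units per direction returning per-position
states (20×70; forget-gate bias 1, tanh/sigmoid activations, glorot
input and orthogonal recurrent initialization); flatten (1400); dense 100
(ReLU); sigmoid output. Dropout 0.25 after the merge and 0.5 after the
BLSTM and dense layers (training only, inverted scaling); L1 = 0.01 on
convolution and dense weight matrices (not biases, not recurrent
weights); binary cross-entropy minimized by Adam (lr 0.001, β₁ 0.9,
β₂ 0.999, ε 10⁻⁷), mini-batches of 100, 500 epochs by default, decision
threshold 0.5 (adopted; any calibrated threshold can be passed).
An optional batch-normalization step after each convolution exists
(default off): the mini-batch description in this architecture family is
ambiguous between plain mini-batch training and an explicit BN layer, so
both readings are available.

Everything — forward pass, backpropagation through time, Adam — runs on
numpy float64 arrays. Gradients are verified against central finite
differences in the test suite (relative error < 10⁻⁴ at probe points,
away from the |w| kink). Inference is deterministic; training is exactly
reproducible under a fixed seed (single-threaded numpy arithmetic, no
backend nondeterminism).

**Regularization at small scale.** The default dropout rates and L1
coefficient correspond to the full-scale regime this architecture is
meant for (~10⁵ training pairs, hundreds of epochs ≈ 5·10⁵ optimizer
steps). At desk scale (10³–10⁴ pairs, tens of epochs ≈ 10³ steps) the
summed L1 penalty on the 1400×100 dense kernel exceeds the data gradient
for almost every weight and training measurably collapses to the
constant classifier (held-out AUROC ≈ 0.5 at 20, 60 and 150 epochs in
our experiments). `ModelConfig.desk_scale()` therefore keeps the
architecture byte-for-byte identical and disables L1/dropout; it is the
configuration used by the examples and the small-scale learning checks.
With it, 20 epochs on 3 200 training pairs reach held-out AUROC/AUPR
≥ 0.99 on the separable synthetic set across seeds.

Model artifacts are single JSON files (version-stamped header, config,
full parameter arrays); `load(save(m))` reproduces predictions
bit-identically, and a mismatched format header is rejected.

## Interpretation

Kernels are exported raw and as column fractions via min-shift +
normalize (each column shifted to non-negative and scaled to sum 1) —
chosen over softmax because a constant column maps exactly to the
uniform 0.25 baseline that defines "no nucleotide preference". A kernel
is *informative* when at least half its columns have a maximal fraction
above 0.25 + δ (δ = 0.05; only the baseline is canonical, δ is ours).
PFM matching slides the shorter matrix along the longer over all
full-overlap offsets and takes the maximal Pearson correlation of the
flattened 4×k blocks; zero-variance (uniform) matrices get similarity 0
by convention; no reverse-complement scan by default (inputs are
single-stranded RNA), available by flag; ties rank by motif id.

The perturbation scan replaces each 4-nt window of the *raw* sequence
(after 3′ trimming/padding to the model length) with Ns, so a masked
window encodes as uniform columns, and records
δ(s) = p(original) − p(masked) per window start; a positive δ means the
window supports the interaction call (sign convention ours; means,
variances and mean |δ| are all emitted). Windows whose masking leaves
the encoding unchanged (already all-N padding) score exactly 0. Profile
length is L − 3 per branch (27 and 57 at default lengths). Per-miRNA
mean-δ profiles are clustered agglomeratively (average linkage) on the
distance 1 − Pearson correlation; constant profiles are assigned
distance 1 to all others with a warning.

## Metrics

AUROC uses the midrank statistic (exactly the concordant-pair count with
ties at ½); AUPR is the interpolation-free sum of precision over recall
increments with tied scores processed as one block. Undefined ratios
(zero denominators) are reported as NaN with a warning, never silently
as 0; single-class ranking metrics raise. Cross-validation is stratified
by label with seeded fold assignment, reporting per-fold and mean rows.

## Synthetic data: what it emulates, and what it does not

The generator produces miRNA panels, transcripts with the final 40%
annotated as 3′UTR, target sites planted inside UTRs, isomiRs of each of
the eight types built to be unambiguous (so classification recovers the
constructed type exactly), chimeric reads with 0–4 nt spacers and
`reads_per_pair` copies, per-base substitution errors at rate 0.001 (the
canonical short-read error rate) with Phred 20 at error positions and 40
elsewhere (so a 30 cutoff separates them in both directions), and an
ungapped-alignment hit table with surrogate statistics
(e = L_ref·4^−(length − 2·mismatch), bit = 2·(length − mismatch)) —
monotone stand-ins for BLAST statistics, documented as test-only.

Error-free read layouts are validated against the actual aligner+caller
and redrawn when a junction artifact (a spacer base coincidentally
extending the miRNA reference or the site's transcript context) would
shift hit boundaries; this makes the planted-pair recovery guarantee a
construction property rather than a probabilistic one.

The separable training set (`gen_separable_pairs`) emulates
chimera-derived pairs: positives carry the reverse complement of miRNA
positions 2–16 (crosslink-captured duplexes pair extensively, seed
through the 3′-supplementary region) at a ligation-anchored offset
(20 + 0–6 nt jitter — chimeric sites hold the bound region at a roughly
fixed position relative to the ligation point); negatives keep the same
small RNA and are 50% shuffles of the positive site (composition decoys)
and 50% sites built for a different panel miRNA (specificity decoys that
force the model to consult the small-RNA branch). The default panel of 8
miRNAs keeps per-miRNA pair density at n = 2000 near that of real
crosslinking libraries (several hundred interactions per miRNA).

Not emulated: adapter sequences, indel sequencing errors, realistic
alignment statistics, expression-level structure, RNA secondary
structure, and cross-condition isomiR dynamics. Passing tests on this
generator therefore demonstrate the correctness and learnability of the
*machinery* — filters behave as specified, the classifier inverts the
generator, the network learns planted signals and localizes them at the
seed — not performance on real crosslinking data, which depends on
alignment quality and biological noise absent here.

## Problem sizes used in the checked properties

The test suite runs pipeline-recovery checks on 8 miRNAs × 5 transcripts
× 12 (or 9) reads per pair, the classification round-trip on ≥ 1000
generated isomiRs covering all eight types, and the learning check on
2000 + 2000 pairs for 20 epochs (≈ 640 optimizer steps) with
`desk_scale()`; these sizes keep the full suite within minutes on one
CPU while exercising every filter boundary.

## Known limitations

- The duplex-energy proxy ignores stacking, loops and structure; it is
  ordinal, not thermodynamic. Use the RNAcofold backend for real data.
- Anchored classification cannot represent gapped isomiRs (by design).
- The surrogate e-value is not a BLAST e-value; pipelines on real data
  should consume real BLAST tabular output.
- Training at the published regularization strengths requires
  full-scale data and epoch counts (see above); desk-scale runs must use
  `desk_scale()` or expect the constant classifier.
- Kernel–PFM matching reports correlation, not a match p-value.
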