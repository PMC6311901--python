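# Methods

`ribofeat` asks which properties of a mature lncRNA sequence separate
ribosome-associated (ribo) from ribosome-free (noribo) transcripts. Labels
are an input (they come from ribosome profiling, which this package does
not analyse); everything else — feature extraction, redundancy pruning,
univariate ranking, and sparse multivariate selection — is computed here.

## Pipeline

1. **Deduplication.** Transcripts sharing local similarity over more than
   60% of the shorter sequence are collapsed (the shorter one is dropped).
   Similarity is an internal seeded local-alignment routine: exact 11-mer
   seeds chained along alignment diagonals into blocks whose identity stays
   ≥ 80%; coverage is the union of shorter-sequence positions inside
   qualifying blocks. Processing is greedy longest-first, so every
   retained/discarded comparison measures coverage of the candidate
   (shorter) sequence; equal-length ties discard the later record. A
   precomputed pairwise-hits TSV can replace the internal routine to
   reproduce runs made with an external aligner such as BLAST.

2. **Putative ORFs.** Three ORFs per transcript: the primary ORF (longest
   ATG-initiated), the first ORF (5′-most ATG-initiated), and the upstream
   ORF (longest CTG/GTG/TTG-initiated ORF lying wholly 5′ of the pORF; it
   may abut the pORF start but not overlap it, and exists only when a pORF
   does). All ORFs run to their first in-frame stop (TAG/TGA/TAA),
   inclusive; ORFs without an in-frame stop inside the transcript are
   ignored. Length ties resolve 5′-most, mirroring the longest-ORF
   convention.

3. **k-mer scores.** For each ORF, three CPAT-style scores of the form
   (1/n) Σ log(F(xᵢ)/F′(xᵢ)) in natural log: the *context score* over a
   10-position window at offsets −6…+3 around the start codon (the Kozak
   context; a −6…+1 window is available via configuration), the *trimer
   score* over in-frame codons, and the *hexamer score* over in-frame
   bi-codons (step 3). F comes from a reference CDS set, F′ from a uniform
   per-sequence nucleotide shuffle of the same set; a pseudocount of 0.5 is
   added to every cell before normalisation so unseen units score
   finitely. Units containing N are skipped. Positive scores mark
   coding-like usage.

4. **Stem probabilities.** Per-base pairing probabilities from a nested
   (pseudoknot-free) secondary-structure ensemble with canonical pairs
   (GC/AU/GU on the RNA alphabet; the implementation works on the DNA
   letters), a minimum hairpin loop of 3 nt, and a simple Boltzmann weight
   per pair type (defaults GC = 3, AT = 2, GT = 1). This is deliberately a
   light-weight ensemble model, not a thermodynamically parameterised
   folding engine: the features consume *relative* structure differences
   between regions, and region means and 5′UTR/ORF ratios are robust to the
   absolute energy scale. Pairing distance is constrained to
   |j − i| ≤ max_span with the span defaulting to N−1 (all pairs), 200 for
   very long (> 9500 nt) RNAs, and a complexity guard capping the span at
   200 beyond 2000 nt (all configurable). The implementation is a banded
   McCaskill-style inside–outside algorithm, O(N·span²) time and
   O(N·span) memory, with adaptive per-base scaling for numerical range;
   for short sequences it is verified against exhaustive structure
   enumeration to 1e−9. Precomputed per-base probability tables from an
   external folding tool can be imported in place of the internal backend.
   Features: mean stem probability per region (transcript, ORF, UTRs) and
   the 5′UTR/ORF and 3′UTR/ORF ratios (ratio undefined when the ORF mean
   is below 1e−6).

5. **Sites.** m6A sites default to a DRACH-consensus scan
   ([AGT][AG]AC[ACT], central A reported); imported site tables (e.g. from
   a dedicated m6A predictor) take precedence. G-quadruplexes follow a
   QGRS-style search — four equal G-runs of length t ≥ 2, loops 0–36 nt,
   total ≤ 30 nt — scored by
   `12·t − mean(loops) − 2·MAD(loops)`,
   which rewards more tetrads and short, even loops; candidates with
   G-score ≥ 30 count as stable, and overlaps resolve best-score-first
   (ties 5′-most, then shorter). The exact published constants of the
   original G-score are not recoverable from its description, so the
   constants live in configuration and the detector is validated against
   an independent quadruplet-enumeration oracle using the same constants.
   Per site kind the representative site is the highest-scoring one
   (tie 5′-most); features are its direct distance `log10(1 + bases)` and
   relative distance (percent of transcript length) to the transcript ends
   (TIS/TTS) and to each ORF's start and end.

6. **Splicing and repeats.** Exon/intron counts, lengths and GC (first
   exon/intron singled out; intron GC needs a genome FASTA, otherwise
   missing). Repeat flags are binary per class (LTR, LINE, SINE, Alu,
   SINEB2 by default): 1 when any exon's genomic interval overlaps ≥ 1 bp
   of a repeat of that class; repeats annotated as simple repeats,
   low-complexity, or non-coding RNA are excluded. Overlap is computed on
   exons of the mature transcript (introns configurable off by default).

7. **Matrix, pruning, ranking.** Missing values (absent ORFs, empty UTRs,
   undetected sites…) are mean-imputed per column, then every column is
   min-max scaled to [0, 1] (constant columns → 0). Redundancy pruning
   removes features greedily until no pair has |Pearson r| > 0.8: at each
   step the feature with the most over-threshold partners goes (ties:
   larger mean |r| over its partners, then later registry position).
   Because Pearson r is affine-invariant, pruning commutes with scaling.
   Features are then ranked by KS importance, −log10 p of the two-sample
   Kolmogorov–Smirnov test between class-conditional distributions —
   asymptotic p in general, full permutation enumeration when both groups
   have ≤ 10 samples.

8. **Selection.** L1-regularized logistic regression minimising
   ‖w‖₁ + C Σ log(1 + exp(−yᵢ(Xᵢᵀw + c))) with labels in {−1, +1}
   (0 → −1), fit by liblinear; coefficients (and intercept) below 10·tol
   are reported as exact zeros. One stratified 80:20 split; for each C on
   the grid (default 0.01…1 step 0.001) the model is fit on the training
   part and its held-out accuracy and nonzero count recorded, alongside
   5-fold CV accuracy on the training part as a diagnostic. The chosen C
   is the smallest whose held-out accuracy is within ε = 0.005 of the grid
   maximum — few features at near-peak accuracy; `select_on="cv"` switches
   the selection signal to the CV curve. At vanishing C the model is
   all-zero; prediction ties at decision score 0 go to the training
   majority class, so the baseline accuracy equals the test-set majority
   fraction exactly under stratified splits. Selected features are
   reported by |coefficient| with their signs (positive = associated with
   the ribo class).

## Synthetic cohorts

The generator produces what the analysis assumes: two labeled cohorts
whose features differ by known, planted shifts.

Defaults (chosen once as typical of mammalian lncRNA cohorts): lengths
log-normal with median ≈ 600 nt and σ = 0.6, clipped to [250, 3000];
exon counts 1–5 with probabilities (0.25, 0.30, 0.25, 0.15, 0.05);
introns log-normal median ≈ 800 nt; background GC 0.45; one embedded
ATG ORF of 150–300 nt per transcript; m6A motif count Poisson(2) per
transcript; one G4 motif with probability 0.4; LTR repeat insertion
probability 0.15 per class unless biased.

Planted effects are **mechanistic** where the sequence can realise them —
first-exon GC shift (the non-ORF part of the exon is GC-compensated for
the embedded ORF's composition so the class-conditional mean difference
hits the configured value in expectation), codon-model vs shuffled
embedded ORFs for the hexamer/trimer scores, site-position biases, and
class-dependent repeat insertion — and **injected** otherwise (extra
feature columns of N(0.5, 0.05) with an exact class-mean shift). Both
paths are recorded in the cohort truth. Mechanistic planting makes
correlated features co-vary (an ORF's trimer and hexamer scores move
together, so redundancy pruning may keep either one), which is exactly
what real data does; injected features are independent by construction.
One global seed fans out to per-component generators via
`SeedSequence.spawn`, so cohorts are bit-reproducible.

What the generator does *not* emulate: real lncRNA base composition
beyond a single GC parameter, evolutionary repeat structure, isoform
structure, or the empirical feature distributions of real cohorts.
Passing tests therefore demonstrate that the pipeline recovers effects of
the configured form and size from data obeying its assumptions — not that
any particular biological cohort contains such effects.

## Numerical and design choices

- Coordinates are 0-based half-open on the mature transcript throughout;
  minus-strand annotation is reordered to transcript (5′→3′) order at read
  time.
- The k-mer scores use the mean (1/n) form; context window −6…+3 is the
  default of the two plausible readings (−6…+1 available in config).
- KS p-values are used only for ranking; no multiple-testing correction.
- When a context-table offset was never observed in the reference (bare
  CDS records have no upstream context), pseudocounts make both F and F′
  uniform there, contributing exactly zero to the score.
- Degenerate inputs: all-N or empty strings give missing GC; empty
  intervals give missing region means; a constant feature column scales
  to zero; an all-missing column is an imputation error (dropped with a
  warning during orchestration, e.g. intron GC without a genome).
- The equal-length deduplication tie (discard the later record) and the
  pORF/uORF length ties (5′-most) are fixed so runs are reproducible and
  order-invariant across sequences of distinct lengths.
- Problem sizes used by the test-suite experiments and the acceptance
  script — 20 recovery replicates at 400 transcripts per class and 24
  features, and one 1,000-transcript cohort with structure span capped at
  100 — are the package's standard desk-scale configuration; all are
  parameters.

## Known limitations

- The internal structure backend is an ensemble-counting model, not a
  Turner-parameter folding engine; absolute stem probabilities are not
  comparable to thermodynamic tools, only the within-transcript contrasts
  the features use.
- The similarity routine has no E-value statistics; the threshold
  semantics (percent coverage of the shorter sequence) are the contract.
- The m6A scan is a consensus filter with no model of sequence context
  beyond DRACH; import real predictor output for fidelity.
- Selection accuracy depends on one 80:20 split; the split seed is an
  explicit parameter and headline accuracies vary across seeds as
  expected for held-out estimates.
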