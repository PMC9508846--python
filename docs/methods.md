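# Methods

`autoclip` analyzes autogenous mRNA–protein interactions — an RNA-binding
protein (RBP) binding the mRNA transcribed from its own gene — in CLIP-seq
cross-link peak data. This note documents the models, their assumptions,
the tunable parameters, what the synthetic-data generator does and does not
emulate, and the numerical choices made where the design was genuinely open.

## Interaction calling and confidence

A peak file (BED6) holds cross-link intervals per assayed RBP for one
method/peak-caller combination. An interaction between gene *i* and RBP *j*
is called when at least one peak of *j* overlaps gene *i*'s
primary-transcript envelope (first to last annotated nucleotide of the
selected transcript). Identity is genetic: RBP *j* and gene *i* are
autogenous partners iff they share a gene identifier.

Two per-pair confidence weights are attached to every called interaction:

* **peak density** — `nt_peak / nt_total`, where `nt_peak` is the size of
  the *union* of peak-covered nucleotides (overlapping peaks are never
  double-counted, keeping density ≤ 1) and `nt_total` the region length.
  Region-level densities (5′UTR/CDS/3′UTR/intron) use the single selected
  transcript per gene so that regions are comparable; peaks spanning a
  context boundary are split and each part attributed to its context, which
  conserves peak nucleotides across contexts.
* **top peak score** — the maximum caller score among the pair's peaks.
  Scores are caller-specific and treated as opaque; they are only ever
  compared within one dataset.

The **percentile rank** (%R) of an RBP's own mRNA among its *n* targets is
`100 · (#strictly below + 0.5 · #ties) / (n − 1)`, computed over the other
targets. Midrank tie handling makes the unique maximum 100, the unique
minimum 0, and an all-tied list 50. %R is invariant under monotone
transformations of the weights, so caller-specific score scales do not
matter.

The **interaction support index** (ISI) of a pair counts the
method/peak-caller combinations in which the pair is detected, out of those
in which the RBP was assayed.

**Stringency filtering** keeps the 1-cells whose weight reaches the *q*-th
percentile (linear-interpolation quantile) of all 1-cell weights in the
dataset; ties at the threshold are kept. Margins of the filtered matrix are
recomputed from the surviving cells.

**Jaccard overlap** between two peak sets is computed on nucleotide sets;
the random expectation for coverage fractions *a*, *b* placed independently
is `a·b / (a + b − a·b)`, and the reported ratio J/E[J] measures
concordance beyond chance.

## Null models for autogenous enrichment

Let the binary matrix **B** (genes × RBPs) have column margins *c_j*
(targets per RBP) and row margins *r_i* (binders per mRNA), and let *k* be
the observed number of autogenous 1-cells among the *N* RBPs whose own gene
is annotated.

* **Protein-centric framework.** Each RBP's background probability is
  `p_j = c_j / G`, with *G* the size of the cellular mRNA pool
  (default 20 000, a standard approximation of the human gene count; the
  pipeline substitutes the annotation's own gene count for toy bundles).
  This assumes every mRNA is an equally likely target.
* **Symmetric framework.** Conditions on both margin vectors by sampling
  uniformly from the fixed-margin family of **B** with the Curveball Markov
  chain: a trade picks two random rows, pools the columns unique to each
  and redistributes the pool uniformly while preserving each row's count.
  Per-pair probabilities are occupancy frequencies over `n_matrices`
  independent chains (default 1000 — at that resolution an individual
  probability near 0.5 carries a Clopper–Pearson 95% half-width of 0.0315).
  The chain trades along the smaller matrix dimension: trading rows or
  columns preserves both margin vectors and targets the same uniform
  distribution, and for tall genes × RBPs matrices trading the few columns
  is orders of magnitude cheaper. Default trades per sample: 5 × the traded
  dimension, following the original mixing guidance. For *sampler
  correctness audits* (goodness-of-fit against enumerated families) we burn
  in 200 trades per chain; the shorter default leaves a start-state bias
  that is invisible at 1000-sample resolution but detectable by a
  100 000-sample test.

Either way the *N* per-pair probabilities are pooled into the distribution
of the autogenous count via the **Poisson binomial distribution**. The
implementation is a dynamic-programming convolution over the *N*
probabilities — mathematically identical to the literal sum over all 2^N
outcome combinations, but linear-quadratic instead of exponential; the 2^N
sum is retained as a test oracle for N ≤ 12. A Monte Carlo mode (default
10^6 Bernoulli-vector draws) exists for contexts where an empirical
distribution is wanted; `auto` switches from exact to MC above
`exact_threshold` (default 20) pairs. Because the exact DP is feasible at
any *N*, large-scale simulation studies in this package raise the threshold
and use the exact distribution directly.

Reported per framework: the pmf over *k*, expected count and SD, the
observed count's midrank percentile, the upper-tail p-value P(K ≥ k), and
the observed/expected ratio. Enrichment-versus-stringency curves apply the
filter at q = 0, 10, …, 90 and recompute the enrichment at each point; in
the symmetric framework the background is recomputed on the filtered
matrix.

### Overexpression correction

mRNA binding probability rises with transcript concentration along a
saturating curve; the package models it as hyperbolic,
`p(TPM) = p_max · TPM / (K + TPM)`. For an mRNA assayed at endogenous
concentration but interpreted under overexpression, the observed partner
count is scaled by `p_max / p(TPM_endog)` (clamped at 1 with a warning),
and randomly chosen 0-cells of the row are flipped to 1 until the scaled
margin is met. Modification plus Curveball shuffling is repeated
`n_matrices` times; the diagonal occupancy frequencies of the corrected
ensemble feed the usual Poisson-binomial pooling. The multiplicative (not
additive) correction follows the heteroscedasticity of binding–TPM curves,
with larger spread at high concentration.

## Genomic-context statistics

A **context profile** normalizes the three exonic region densities of a
(gene, RBP) pair to sum to one; it is undefined (and excluded) when all
three are zero. The CDS-preference comparison pairs each autogenous
profile with the unweighted mean profile of the same mRNA's other binders
and applies a one-sided Wilcoxon signed-rank test for a higher autogenous
CDS component (paired data, no normality assumption); a one-sided paired
t-test is reported alongside because both appear in practice for this
comparison — Wilcoxon is primary here. The comparison refuses to run with
fewer than 10 autogenous pairs.

**Intron z-scores** compare an RBP's own-mRNA intron density to reference
targets with similar UTR densities — either within a relative ±10% window
(the window is interpreted multiplicatively, ×0.9–×1.1) or the 20 nearest
by absolute UTR-density difference. UTR density is computed jointly over
the concatenated 5′ and 3′ UTRs. References smaller than 5 or with zero
spread are flagged.

**Motif coverage** is the fraction of sequence positions covered by at
least one exact IUPAC-pattern match of any motif, with overlapping match
footprints unioned (regex lookahead enumeration).

The **group randomization test** draws random same-sized groups without
replacement and reports the two-sided probability that a random group's
outcome proportion deviates from the global proportion at least as much as
observed. For binary outcomes the group count is hypergeometric, which is
how trials are drawn; the test agrees with the exact hypergeometric tail
within Monte Carlo error.

## Complementarity model

The sequence-level model assumes co-aligned binding between an unstructured
mRNA and the protein it encodes at a 1 residue : 3 nucleotide ratio.

* **E_stat** of an alignment is the sum over residues of the pair energies
  between the residue and the three bases of its aligned trinucleotide
  (20 × 4 knowledge-based scale; lower = more favorable). E_stat is
  additive over concatenation, and the scan value at the coding offset
  equals the direct CDS energy exactly.
* **Scans** shift the protein one nucleotide at a time over the full mRNA
  (N→C against 5′→3′ by default). Reverse orientation reads the mRNA 3′→5′
  (the coding offset maps to its mirrored position); shuffle variants
  permute one sequence once per scan. The coding offset's rank is 1-based
  by ascending energy, ties broken by offset order.
* **Profiles** for the matching view: the mRNA's windowed nucleobase-class
  density (e.g. pyrimidine fraction) and the protein's per-residue affinity
  scalar expanded threefold to nucleotide resolution (step replication over
  the codon positions), both smoothed with the same odd window (default
  63 nt, valid windows only — no edge padding). Pearson R between the two
  tracks is computed at every offset; favorable matching appears as
  negative R because lower affinity values mean stronger binding. Offsets
  within ±2 nt of the coding offset are flagged near-CDS so they can be
  excluded from background histograms without being dropped from the scan.
* **Backgrounds**: the query energy is z-scored against the same protein
  aligned to random sequences drawn iid from trinucleotide frequencies
  (uniform by default; supply transcriptome-estimated frequencies for real
  data). Degenerate backgrounds (zero spread) are flagged. Fragment
  analyses average E_stat over all in-frame co-aligned fragments of a given
  length and standardize against random fragments of equal length; the
  planted-signal expectation is a z-score whose magnitude grows ~√length.
  Disorder-restricted variants sum only masked residues against their
  in-frame codons. The bound-versus-unbound comparison z-scores each bound
  RBP's autogenous CDS energy against 1000 random alignment positions in
  unbound CDS pools and applies a two-sided Mann–Whitney U test between
  bound and background z samples, per species.

Stop codons are excluded: scans use the translated CDS only.

## Synthetic data

The generator produces every input class with the statistical structure the
analysis assumes, deterministically under a fixed seed:

* **Interaction matrices** — per-RBP target counts drawn log-uniformly
  (default range 50–9000, matching the span seen across real
  method/peak-caller combinations), targets placed uniformly among genes.
  Conditioned on the realized margins this placement is uniform over the
  fixed-margin family, which is exactly what the symmetric null assumes —
  so with no planted excess the null is calibrated by construction. The
  autogenous cell of RBP *j* is then set with probability
  `min(1, f · c_j/n_genes)`; the enrichment factor *f* (≥ 1) is the planted
  truth that recovery experiments estimate. Weights are log-normal;
  autogenous weights can be upshifted by a chosen number of SDs in log
  space (monotone transform — rank-based statistics see exactly the
  intended shift).
* **Peaks** — context spans are cut into mean-peak-length blocks, each
  becoming a peak independently with the requested per-context density, so
  realized densities fluctuate within binomial error and peaks never cross
  context boundaries.
* **Coding pairs** — random proteins with mRNAs that translate back
  exactly under the standard genetic code; codon usage is uniform over
  synonyms or canonical (one fixed codon per amino acid).
* **Planted affinity scales** — Gaussian noise plus an exact planted gap:
  for every amino acid the mean energy over its canonical codon's distinct
  bases sits `s` units below the mean over the remaining bases. The signal
  is defined against canonical codons because several amino acids
  (Ser, Leu, Arg) have codon sets spanning all four bases, leaving no
  complement to plant against; planted-signal experiments therefore
  generate coding pairs with canonical usage. The attached residue scalar
  anti-correlates with canonical-codon pyrimidine content with the same
  strength, giving coding pairs negative profile-matching R.
* **Expression** — log-normal TPM with the true hyperbolic binding
  probability recorded for oracle use.
* **Bundles** — a complete input directory (peaks per dataset, transcript
  models with one intron inside the CDS, coherent mRNA/protein FASTA,
  scale, TPM, curation flags, planted truth) in which every 1-cell of the
  planted matrix yields at least one peak, so interaction calling recovers
  the matrix.

What the generator does **not** emulate: cross-link biochemistry and
UV-reactivity biases, read-level noise and mapping artifacts, splice
isoform diversity, correlated target sets between related RBPs, motif-driven
spatial clustering of peaks, and realistic codon-usage bias. Passing tests
therefore demonstrate the statistical machinery (calibration, recovery,
ranking, scanning) under the stated generative assumptions — not robustness
to every bias of real CLIP data.

## Simulation study sizes

The shipped verification experiments use these problem sizes, chosen to
make the statistical checks decisive at desk scale:

* sampler uniformity: seven enumerable fixed-margin families up to 4×4,
  100 000 samples each, chi-square at α = 0.01;
* symmetric-null calibration: 100 replicates of 25 RBPs × 10 000 genes
  (margins 50–9000), 250 randomized matrices per replicate, conservative
  central-95% coverage;
* enrichment recovery: 100 replicates of 150 RBPs over a 20 000-gene pool
  with f = 4 (an a-priori power analysis puts the recovered ratio's median
  near 3.5 with ~96% mass in [3, 5]);
* stringency monotonicity: 100 replicates of the calibration-scale
  matrices (10 000 genes, where the planted diagonal is dense enough for
  stable late-grid counts) with f = 4 and a 1-SD weight upshift;
* complementarity: 200 coding pairs of 100–160 residues at planted
  strength 5; background calibration over 1000 replicates of 60-residue
  proteins with 1000-sequence backgrounds.

## Known limitations

* Fixed-margin sampling estimates per-pair probabilities by Monte Carlo;
  very small probabilities (deep tails) carry relative error ~1/√n_matrices.
* The protein-centric framework ignores mRNA-side heterogeneity by design;
  it is retained because it is the natural first-pass null and the contrast
  with the symmetric framework is itself informative.
* The complementarity model scores strictly co-aligned, full-length (or
  fragment-wise) contact and ignores RNA secondary structure, protein
  folding and docking geometry.
* The overexpression correction flips 0-cells uniformly at random;
  concentration-weighted flipping would be a reasonable alternative and the
  choice is pluggable.
* Minus-strand genes are stored as annotated; all coordinate work is
  strand-agnostic nucleotide arithmetic, and sequence-level analyses take
  transcript-oriented sequences as input.
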