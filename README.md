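# autoclip

Analysis of **autogenous mRNA–protein interactions** — RNA-binding proteins
(RBPs) binding the mRNA transcribed from their own gene — in CLIP-seq
cross-link peak data.

CLIP-seq experiments report, per assayed RBP, the transcriptome positions of
its cross-link peaks. Many RBPs regulate their own expression through
feedback loops that begin with binding their own transcript, but a peak on
the own mRNA is not evidence by itself: an RBP with thousands of targets
will hit its own mRNA by chance. `autoclip` provides the statistical
machinery to decide whether autogenous binding is enriched beyond what the
interaction network's structure implies, where on the transcript it occurs,
and whether intrinsic nucleobase–amino-acid affinities could explain it.

## What it computes

Given per-dataset BED peak files, a one-transcript-per-gene annotation and
an RBP↔gene identity map:

* **Interaction matrices** — binary genes × RBPs incidence (≥ 1 peak on the
  gene's transcript), weighted by full-transcript peak density
  (nt_peak/nt_total) and top peak score.
* **Confidence metrics** — percentile rank (%R) of each RBP's own mRNA among
  its targets, interaction support index across method/peak-caller
  combinations, Jaccard peak overlap between datasets, percentile-based
  stringency filtering.
* **Two null frameworks for the autogenous count** *k* among *N* assayed
  RBPs:
  * *protein-centric*: each RBP binds its own mRNA with probability
    `p_j = c_j / G` (targets over the gene pool, default G = 20 000);
  * *symmetric*: per-pair probabilities are occupancy frequencies over
    fixed-margin randomizations of the interaction matrix, sampled with the
    Curveball Markov chain (row and column totals preserved exactly).

  The *N* probabilities are pooled with the **Poisson binomial
  distribution** (exact dynamic-programming convolution, equivalent to the
  full 2^N sum; Monte Carlo fallback for empirical distributions), yielding
  the expected count, the observed/expected ratio and the observed count's
  percentile rank / p-value.
* **Genomic context** — length-normalized 5′UTR/CDS/3′UTR peak profiles,
  paired Wilcoxon tests for CDS preference of autogenous binding, intron
  z-scores against UTR-matched references, IUPAC motif coverage,
  domain/non-domain CDS density comparison, randomized-group proportion
  tests, and an overexpression correction that rescales mRNA margins along
  a saturating TPM–binding curve.
* **Complementarity** — the additive interaction-energy proxy

  `E_stat = Σ_i Σ_{b ∈ triplet(i)} e(aa_i, b)`

  summing knowledge-based nucleobase–amino-acid pair energies over a
  1 residue : 3 nt co-alignment, scanned one nucleotide at a time over the
  full mRNA; windowed nucleobase-density vs residue-affinity profile
  matching by Pearson R (negative R = favorable matching); randomized
  trinucleotide backgrounds, reverse/shuffled controls, fragment-length and
  disorder-restricted variants, bound-vs-unbound comparisons.
* A **synthetic-data generator** for every input class — margin-prescribed
  matrices with a planted autogenous excess, context-density peak sets,
  coding mRNA/protein pairs under the standard genetic code, planted-signal
  affinity scales and saturating expression curves — so the whole pipeline
  is testable without downloads.

## Worked example

Simulate a 300-gene, 20-RBP compendium with a planted four-fold autogenous
excess and a one-SD confidence-weight upshift, then run the full analysis:

```bash
autoclip all --out demo --seed 7 --n-genes 300 --n-rbps 20 \
    --enrichment 4 --n-matrices 500
```

Key numbers from `demo/report.json` (dataset `sim_method0`):

```
observed autogenous binders     9 of 20
median own-mRNA density %R      94.7
protein-centric null            expected 2.36, ratio 3.82, p = 9.6e-05
symmetric (Curveball) null      expected 3.34, percentile rank 100.0
stringency ratios (q=0..90)     3.8, 3.8, 4.2, 4.8, 4.9, 5.9, 6.4, 8.5, 12.7, 21.1
complementarity                 median E_stat CDS rank 1, median background z -13.0,
                                mean profile R at CDS -0.64
```

Reading: 9 of the 20 simulated RBPs bind their own mRNA where the
margin-implied expectation is ~2.4 (the planted factor was 4); own mRNAs
rank near the top of each RBP's targets by peak density; enrichment grows
as interactions are filtered to the highest-confidence fraction; and with
the planted affinity scale the in-frame coding alignment is the energy
minimum of the whole scan, ~13 SDs below randomized backgrounds.

The stages are also available separately (`autoclip simulate / matrix /
rank / enrich / context / comp / report`), and everything in the CLI is a
thin wrapper over the library API (`autoclip.call_interactions`,
`autoclip.pair_probabilities`, `autoclip.estat_scan`, ...).

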