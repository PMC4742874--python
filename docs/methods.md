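# Methods

## Protein abundance (emPAI)

Identification evidence is one row per protein: id, identification
score and the number of distinct observed peptides.  The score is a
MOWSE-based quantity, `−10·log10(P)` with `P` the random-match
probability; scores strictly above 54 correspond to `P < 0.05` and are
retained.  The threshold is exclusive (54.0 itself is dropped) and
configurable.

For each retained protein, `N_observable` is computed by an in-silico
tryptic digest: cleavage C-terminal of K or R except before P, a
configurable number of missed cleavages (default 0), and a
monoisotopic mass window (default 400–6000 Da) standing in for the
instrument's detectable range.  The window and missed-cleavage count
are parameters because "observable" is instrument-dependent; the
defaults describe a typical LC-MS/MS setup.  Residues outside the
20-letter alphabet never block a cleavage decision and contribute zero
mass (with a warning), so degenerate sequences digest
deterministically.  Proteins whose digest yields no in-window peptide
are flagged unquantifiable, excluded from the normalisation and
reported — they never silently divide by zero.

`PAI = N_observed/N_observable`, `emPAI = 10^PAI − 1`, and relative
emPAI is each protein's percent of the summed emPAI over quantifiable
proteins (sums to 100 within 1e−6).  Rankings break emPAI ties
lexicographically by protein id.  The functional profile sums emPAI
per Molecular Function (Level III) class; novel proteins form their
own class and are never absorbed into a GO class, annotated proteins
without a class label fall into "unknown conserved", and multi-class
proteins contribute their full emPAI to each class — the profile is
descriptive, not a partition, and is documented as such in the output.

## Expression quantification and testing

FPKM uses unique reads as fragments:
`FPKM = count · 1e9 / (gene_length_bp · total_mapped_reads)`.  Groups
(male, female, testes, MAG) pool replicate libraries by arithmetic
mean FPKM; unique-read totals are summed alongside.  Fold ratios with
a zero denominator are flagged undefined and routed to an "excluded"
class rather than coerced to infinity.

The proportion test aggregates counts within each group
(`x = Σxᵢ, n = Σnᵢ`) and compares the two proportions with the pooled
two-sample Z statistic.  The overdispersed variant divides the
statistic by `sqrt(φ̂)`, where `φ̂` is the Pearson dispersion of
replicate proportions around their group aggregate, divided by the
residual degrees of freedom (libraries − groups) and floored at 1;
with one library per group it reduces exactly to the plain Z-test.
This is a deliberately simple, fully specified stand-in for
overdispersed proportion testing: it preserves the intent (replicate
variation beyond binomial noise widens the test) with a statistic that
can be validated directly.  Multiple testing uses Benjamini–Hochberg
step-up q-values (via statsmodels), validated in the tests against a
longhand implementation of the step-up rule.

The significance filter (default q ≤ 1e-4) is available where a study
would apply it, but the bias classes below are defined purely by fold
and read-count rules and do not require the test to pass.

## Bias classification

Thresholds (all configurable): sex fold 5 (strict >), minimum male
unique reads 100, tissue fold 5 (inclusive ≥, "at least"), other-tissue
read ceiling 50 (exclusive), low-expression floor 100 combined reads
(exclusive).  The sex fold default follows the 5-fold convention used
in the study's results; a 2-fold variant appears in its methods text,
and both are reachable through `ClassifierThresholds`.

Sex axis: undefined fold → excluded; fold > 5 with ≥ 100 male reads →
male-biased; fold > 5 with < 100 male reads → female-biased (a large
fold on negligible male evidence indicates the female libraries drove
the identification); fold < 1/5 → female-biased; else unbiased.

Tissue axis, in precedence order: low-expression (combined reads
< 100) → specific (fold ≥ 5 toward a tissue and < 50 reads in the
other) → biased (fold ≥ 5) → unbiased.  The precedence makes the five
categories mutually exclusive so counts sum to their denominator.  A
zero mean in the disfavoured tissue counts as an arbitrarily large
fold; the read guards still gate the outcome.  `mag_specific` is a
legal label even though the motivating dataset contained none — the
rule system is symmetric.  Genes called female-biased on the sex axis
are still classified on the tissue axis but reported as a separate
stratum, and they are excluded from the tissue denominator.

Report percentages are integer, rounded half away from zero — the
convention that reproduces the published summary percentages from
their published counts.  Denominators: novelty and orthology over the
full inventory; sex over non-excluded genes; tissue over the main
(non-female-biased) stratum.

## Orthology

Hit tables use the standard 12-column tabular dialect.  Rows at or
above the e-value threshold (default 1e-10, exclusive) are discarded
before best-hit selection, so a strong-but-filtered hit never shadows
a surviving weaker one.  Multiple HSP rows per query–subject pair
collapse to the pair's lowest e-value; the best subject per query
minimises e-value, then maximises bit score, then takes the
lexicographically smallest subject id (the tie-break chain is a
package choice — alignment conventions do not specify one — and makes
the calling deterministic).  Self-hits are dropped defensively.  RBH
pairs are mutual best hits and form a one-to-one matching.  Venn
summaries support up to six named sets; beyond that a membership
matrix is the right tool and the function says so.

## Synthetic data

The generator emulates the study design: two whole-body libraries per
sex and three libraries each (teneral, virgin, mated) for testes and
MAG; 287 genes with 23 novel in the default configuration, planted
bias mirroring the study's class proportions.  Defaults the study does
not pin down were chosen once as field-typical values:

- **Counts**: negative binomial with `variance = μ + φμ²`; default
  dispersion φ = 0.1 (typical for biological RNA-seq replicates),
  φ = 0 degenerates to Poisson.  Expected per-library depth over the
  simulated genes is `mean_depth` (default 1e5).
- **Baseline expression**: log-normal relative abundances (σ = 1.0 in
  log space), normalised to sum to one.
- **Background reads**: the simulated genes emulate a protein
  inventory's gene subset inside a whole transcriptome, so each
  library's recorded `total_mapped_reads` is its realised column sum
  plus a constant background mass (default: the inventory carries 10%
  of the library's reads).  Without the background term, planting fold
  changes in a large fraction of genes would compositionally compress
  every realised FPKM ratio — an artefact of treating a gene subset as
  a whole transcriptome, which real inventories do not suffer.
- **Planted bias**: the fold multiplies the favoured libraries' means
  one-sidedly (sex-planted genes in all libraries of that sex,
  tissue-planted genes in the favoured dissected tissue).  Planted
  tissue-specific genes get off-tissue means forced to 1/1000 of the
  on-tissue mean.  Bias is planted only in genes whose baseline clears
  a detectability floor (expected ≥ 30 reads per library at the
  configured depth, rejection-sampled): bias in genes below the
  classifier's absolute read guards is undetectable by construction,
  and detected inventory proteins are by definition expressed.
- **Sequences**: i.i.d. draws from a fixed proteome-like residue
  frequency table with K+R above 10%, lengths uniform on 100–400
  residues, so tryptic digests are non-degenerate.  Gene length is
  three nucleotides per residue.
- **Evidence**: observed peptide counts are binomial over each
  protein's observable peptides with a per-protein fraction declining
  in planted abundance rank; 15% of rows receive sub-threshold scores
  to exercise the identification filter.
- **Hit tables**: planted pairs appear as mutual best hits with
  e-values between 1e-80 and 1e-20 plus worse secondary hits; decoys
  include one-way best hits, hits above the threshold, and tied
  e-values requiring the tie-break chain.

All randomness flows from one seed through purpose-keyed substreams,
so a bundle is byte-identical across reruns and each artefact is
stable regardless of which others are generated.

What the generator does *not* emulate: real spectra or peptide
detectability physics, read-mapping ambiguity, codon or genome
structure, correlated expression between genes, GC or length biases,
and sequence-similarity structure in the hit tables (e-values are
planted, not computed from the sequences).  Passing the planted-truth
tests therefore demonstrates that the rule systems and estimators
recover the structure they are defined on — not that they would be
robust to every artefact of real LC-MS/MS or RNA-seq data.

## Validation conditions and numerical choices

Planted-truth recovery is measured on ten synthetic studies of 2000
genes at planted fold 10, depth 1e5 and dispersion 0.1 — sizes chosen
so the whole validation runs in seconds while leaving each category
hundreds of planted genes.  Under the all-null configuration the
classifiers call ≥ 90% of genes unbiased on the sex axis; on the
tissue axis the same bound applies among genes above the
low-expression floor, since routing genuinely low-expressed genes to
the guard class is correct behaviour, not a spurious bias call.
Z-test calibration uses a Poisson (dispersion 0) null, the regime the
plain Z-test is exact for; the overdispersed variant exists precisely
because real replicates exceed it.

Degenerate inputs are handled explicitly: empty evidence tables pass
through the filter; zero-variance proportion tests return z = 0,
p = 1; empty groupings, unknown libraries, missing metadata and
malformed hit-table rows raise immediately with context (hit-table
errors carry line numbers).

## Known limitations

- The emPAI observable-peptide definition (mass window, no
  retention-time model) is one of several in use; absolute emPAI
  values shift with the window, though rankings are stable.
- The overdispersed proportion test is a moment-based approximation,
  not a likelihood model; for replicate-rich designs a count
  regression (e.g. negative-binomial GLM) would be preferable.
- Bias classes are hard-threshold rules; genes near a threshold can
  flip between classes under resampling, which the planted-truth
  recovery rates quantify.
- RBH is a heuristic for one-to-one orthology and misses paralog
  families by design.
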