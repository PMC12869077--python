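# Methods

## Scope and model

`mistraq` quantifies amino-acid misincorporation (mistranslation) from
peptide-level mass-spectrometry identification reports and carries the
downstream proteome/phosphoproteome analysis. The setting it models is a
yeast-style experiment: strains expressing mutant tRNAs that misincorporate
alanine or serine at proline codons (Pro→Ala, Pro→Ser) or serine at
arginine codons (Arg→Ser), measured in six biological replicates against an
empty-vector control.

A misincorporation event appears in a database search as a variable
modification with delta mass m(to) − m(from) computed from monoisotopic
residue masses: Pro→Ala −26.0156 Da, Pro→Ser −10.0207 Da, Arg→Ser −69.0690
Da; with phosphorylation of a misinserted serine, the combined deltas are
+69.9456 Da (Pro→pSer) and +10.8972 Da (Arg→pSer). All deltas are computed
from elemental masses at run time, never hard-coded; printed 4-decimal
values are treated as ±0.0005 Da anchors because printed tables mix
rounding and truncation.

## Digestion and the substituted peptide space

Digestion is fully specific. Trypsin follows the Keil rule (cleave after
K/R, not before P); LysC cleaves after K unconditionally; the trypsin+LysC
double digest is their union, so K–P bonds are cut. Defaults are ≤2 missed
cleavages and peptide length 7–50, matching common search-engine defaults;
both are configurable. Coordinates are 1-based inclusive protein positions,
and the initiator methionine is not trimmed.

Substituted peptides are enumerated by applying the substitution to the
protein and digesting the *mutated* sequence, because a substitution can
create a cleavage site (misinserted K/R) or destroy one (R→S under
trypsin). At most one substitution per peptide is assumed by default —
variable-modification searches rarely localize two simultaneous events —
with a configurable bound.

The *sibling* of a substituted peptide is the wild-type peptide with
identical protein coordinates. When the substitution changes the cleavage
pattern no coordinate-identical sibling exists and the peptide cannot be
sibling-validated; this is why frequency estimation is done on LysC
digests, where R→S does not move peptide boundaries.

## Mistranslation statistics

Two estimators are computed per strain after 1% FDR filtering on the global
q-value:

* **Unique-peptide frequency** = 100 × (unique substituted peptides whose
  sibling is also observed) / (unique wild-type peptides containing the
  target amino acid + the accepted substituted peptides). A unique peptide
  is a base sequence plus its full modification string, collapsed over
  charge states and runs. A codon-restricted denominator (only peptides
  whose target residues are encoded by the substitution's target codons) is
  available behind a flag with a CDS index.
* **Intensity fraction** = 100 × Σ intensity(substituted) / Σ
  intensity(all), per replicate, summarized as mean ± SD. This is the
  estimate of the mistranslated share of the measurable proteome.

Strains are compared to the control by a two-sample t-test on per-replicate
intensity fractions with Bonferroni correction over the strain comparisons.

Codon attribution maps each localized substitution site to its encoding
codon through the validated CDS (standard nuclear genetic code only) and
profiles unique-peptide counts and summed intensities over the
from-residue's codon family; both count- and intensity-normalized profiles
are emitted because the normalization used in published codon profiles is
ambiguous. Unlocalized sites go to an ambiguous bucket; sites whose codon
does not encode the from-residue are rejected and reported.

## Differential analysis

Precursor log2 matrices are summarized to protein level by Tukey median
polish (≤10 iterations, tolerance 1e−6), the robust summarization used by
proteomics summarization packages. Differential abundance per feature is a
pooled-variance two-sample t-test (df = nₐ+n_b−2) on log2 values with
Benjamini–Hochberg adjustment across features, applied separately per
strain-vs-control contrast; significance requires adj. p < 0.05 and
|log2 FC| > 0.5 (the 1.5-fold alternative, log2 ≈ 0.585, is available).
Two deliberate simplifications relative to common pipeline packages: no
imputation of missing values by default (transparency over completeness)
and an ordinary rather than moderated t statistic.

Phosphosite fold changes are corrected for protein abundance:
fc\* = fc_site − fc_protein, se\* = √(se_site² + se_protein²), df by
Satterthwaite, p from the t distribution, BH re-applied across sites.
Sites without a protein result pass through uncorrected and are flagged.

Kinase–substrate enrichment (KSEA) is a one-sided Fisher exact test
(hypergeometric upper tail) per kinase × direction of the 2×2 table
substrate/non-substrate × regulated/not, BH-adjusted across kinase ×
direction, reporting only kinases with adj. p < 0.05 and more than 4
regulated substrates. A standardized mean-fold-change z-score mode is
provided as an alternative statistic.

Replicate QC uses per-feature coefficients of variation (100 × SD/mean on
linear intensities within a strain) and their median.

## Novel phosphosites on misinserted serines

Serine misinserted at Pro or Arg codons creates new phospho-acceptors.
Retention of a combined substitution+phospho site is stringent: a
supporting peptidoform must pass peptidoform q ≤ 0.01 and site-localization
confidence > 0.75 row by row, and the site must be present in all required
replicates (default 6). Filters are applied at site level; peptide-level
rows feed the site aggregation.

Motif enrichment follows the motif-x-style binomial procedure: for each
offset in ±6 around the phosphosite (offset 0 excluded) and each residue,
the binomial upper-tail p of the foreground count given the background
frequency at the same offset, background = flanking windows of all
quantified canonical phosphosites in the same dataset. Cells below 10⁻⁶
are flagged enriched. Sites near protein termini simply do not contribute
to out-of-range offsets.

Rank comparisons (e.g. solvent accessibility or protein abundance of novel
vs canonical sites) use a two-sided Mann–Whitney test: exact by full
enumeration of group assignments (midranks for ties) when the smaller
sample has ≤8 values, otherwise the normal approximation with tie
correction. Solvent accessibility is consumed as a precomputed per-residue
RSA table; computing it from structures is out of scope.

## Synthetic-data generator

The generator exists so that every estimator can be tested against known
ground truth. It emulates the study design — 4 strains × 6 replicates on a
desk-scale ORFeome — not raw spectra.

* **ORFeome**: 300 genes by default; protein lengths log-normal (median
  ~350 aa, clipped 60–1200); codons drawn from an S. cerevisiae-like usage
  table (which fixes both amino-acid composition and synonymous-codon
  choice); ATG start, one terminal stop, no internal stops. Every CDS
  passes validation by construction.
* **Abundance and detection**: gene abundances log-normal (median 10⁶,
  ln-SD 1.2) with per-peptide response factors (ln-SD 0.5); multiplicative
  replicate noise ln-SD 0.13 (~13% CV, a precise label-free experiment);
  detection is Bernoulli with logistic probability in log10 intensity
  (midpoint 10², scale 0.35), the simplest mechanism producing realistic
  intensity-dependent missingness. 2% of rows carry failing q-values to
  exercise FDR filters.
* **Misincorporation**: each target-residue site is selected by a per-codon
  Bernoulli draw (defaults CCA/AGA-dominant, mirroring Watson–Crick
  anticodon pairing, scaled so unique-peptide frequencies land in the
  3–8% range); each selected site diverts a conversion fraction of its host
  LysC peptide's intensity into the substituted species, calibrated once
  per simulation so the substituted share of total intensity equals the
  strain's configured fraction (defaults 0.73/0.98/0.25%) exactly before
  noise and detection. Substituted and sibling species therefore share the
  gene's expression level, and the sibling filter fails only when
  detection drops the sibling — the case it exists to handle. The Bernoulli
  construction (rather than substituting every site at a small ratio) is
  what makes the count-based codon profile converge to the planted rates
  instead of to codon usage.
* **Phosphoproteome**: canonical sites on S/T/Y at 5% per residue with
  log-normal stoichiometry; a kinase–substrate annotation over the
  canonical sites (12 kinases × 15 substrates), optionally with one kinase
  whose substrates are shifted (−1.2 log2 by default) in one strain; 30
  proteins with ±1 log2 abundance shifts that propagate into phosphosite
  intensities (so protein correction has real work to do). Misinserted
  serines are phosphorylated with probability 0.1, multiplied by 9 (capped
  at 0.95) when followed by proline — a proline-directed-kinase preference
  that plants the +1-proline motif. Localization confidence is a per-site
  Beta(12, 1.5) draw with per-observation jitter (SD 0.02): localizability
  is a property of the site's fragment-ion context, and a per-row i.i.d.
  draw would make the all-replicates filter almost unsatisfiable.
* **Determinism**: one global seed; each stage uses a derived substream, so
  outputs are byte-identical for a fixed seed and stages can be re-run
  independently.

The manifest records the planted truth: per-codon selection counts and the
expected codon profile, the configured intensity fraction and calibrated
conversion fraction, planted substituted peptide counts with detection
drops, novel phosphosites with their +1-proline status, shifted proteins,
and the planted kinase.

What the generator does **not** model — and hence what passing recovery
tests do not show about real data: chimeric/incorrectly identified spectra
(substitution false positives), shared peptides between paralogs,
missed-cleavage-dependent quantification, correlated (batch) noise across
replicates, retention-time or m/z effects, and real kinase-motif
specificities beyond the single planted +1-proline bias. Protein-level
replicate CVs come out lower (~6%) than typical published medians because
replicate noise is independent per peptide and averages out across a
protein's peptides.

## Problem sizes and numerical choices

Default analyses and the recovery suite run at 300 genes × 6 replicates, a
scale chosen so a full simulate–analyze cycle takes ~3 s and parameter
recovery stays sharp (intensity-fraction SD ≈ 0.01 percentage points over
seeds). Acceptance-style checks use: 20 seeds per planted intensity
fraction; a high-mistranslation Pro→Ser scenario (site rates ×3) for motif
enrichment so the retained foreground exceeds 50 sites; and 20 null seeds
(no planted signal) for KSEA calibration. Degenerate cases are defined
explicitly: zero pooled variance gives p = 1 at zero fold change and p = 0
otherwise; an empty frequency denominator or zero total intensity yields
NaN with a warning; all-tied rank comparisons return p = 1; motif cells
with zero background frequency return p = 0 when the foreground count is
positive; empty 2×2 tables give p = 1.
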