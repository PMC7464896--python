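# Methods

## Scope and coordinate conventions

All genomic intervals are 0-based half-open; GTF I/O converts from/to the
1-based inclusive convention at the boundary, and the conversion is its own
inverse. A back-splice junction stores `acceptor`/`donor` as the genomic
min/max of the circularized span regardless of strand (junction IDs in
BSJ callers are coordinate-sorted); strand is kept for sequence extraction.
Sequence scanning operates in DNA space — RNA inputs are mapped U→T at the
scanning boundary so there is a single comparison alphabet.

## Normalization

Abundance is counts-per-million: `cpm = count × 1e6 / library total`, with no
transcript-length term — a back-splice junction is quantified by reads over a
single point, so length normalization is not meaningful. Library totals are
always taken over the full feature set; filtered subsets (e.g. the DEC set)
are selected *after* normalization, because totals computed over a
differentially expressed subset are condition-dependent and bias every
downstream fold change and correlation. All log transforms are
log₂(CPM + 1).

## Differential expression

* **Paired (tumor vs. normal).** For each feature, per-subject differences of
  log₂(CPM+1) are tested with a two-sided one-sample t-test (≥ 3 complete
  pairs required). Subject-level effects shared by a subject's two samples
  cancel in the differences.
* **Unpaired (knockdown vs. control).** Welch's t on log₂(CPM+1) with
  Satterthwaite degrees of freedom; intended for small (3v3) designs.
* **Degenerate inputs.** All-zero difference vectors give p = 1; zero spread
  around a non-zero mean uses a variance floor ε = 10⁻⁸ so the statistic
  stays defined. Features with zero counts in every sample are dropped (and
  logged) before testing.
* **Fold change.** log₂((meanCPM_A + c)/(meanCPM_B + c)) with pseudocount
  c = 1 CPM, which bounds fold changes for features absent in one condition.
* **Multiple testing.** Benjamini–Hochberg step-up, validated in the test
  suite against an O(n²) definition-chasing implementation.
* **Filters.** circRNA (DEC): |FC| ≥ 2 ∧ p < 0.05 ∧ FDR < 0.001 — the p and
  FDR conditions are partially redundant but both are applied as stated.
  Knockdown DEGs: |FC| ≥ 1.5 ∧ p < 0.05, no FDR condition. Both are config
  overrides, defaulting to these values.

## Seed-site model

Only canonical site types are scored, from the miRNA seed (nt 2–8, 5′→3′):
`7mer-m8` (perfect match to nt 2–8), `7mer-A1` (match to nt 2–7 plus an A
opposite position 1), `8mer` (both). Context/conservation scoring, 6mers and
non-canonical sites are out of scope; site evidence is used only as
presence/absence and counts. When an 8mer matches, the 7mer-m8 at the same
position and the 7mer-A1 one base downstream describe the same physical site
and are suppressed, so no position carries two types. Distinct positions are
counted separately, including overlapping same-miRNA matches at offsets < 7.

Circular targets are scanned as `seq + seq[:7]` with match starts restricted
to one period: every physical site is reported exactly once, positions are
taken modulo the circle length, and sites crossing the origin are flagged
`spans_junction`. A circle shorter than 7 nt is an error; site types longer
than the circle are skipped. The scanner is validated against an
all-rotations brute-force search. mRNA scanning is restricted to the
annotated 3′UTR.

## Junction classification

Host assignment prefers a transcript carrying an exon starting exactly at the
acceptor and one ending exactly at the donor; otherwise the overlapping gene
with the largest span overlap wins, with deterministic id tie-breaks. Exon
ordinals are 1-based in transcript order (reversed on `-`), so a circRNA from
"exons 2–4" reads `[2, 3, 4]` on either strand. Classes: ≥ 2 contained exons
→ multi-exonic; 1 → single-exonic; a junction inside a gene containing no
complete exon is classed single-exonic over the containing region with a
warning (the exact rule used by read-level callers is internal to them; this
boundary-matching rule is this package's stated substitute). No overlapping
gene → intergenic.

## Co-expression and network assembly

Pearson correlation on log₂(CPM+1) with p from t = r√(n−2)/√(1−r²) against
t(n−2) (|r| = 1 → p = 0); Spearman is available by configuration (rank
transform, same t approximation). Edge retention defaults to p < 0.05; an
alternative mode retains padj < 0.05 ∧ r > 0, with BH computed over all
tested pairs in both modes. By default correlations use all samples (both
conditions) — a configuration choice; restricting to one condition is a
matter of passing subset matrices.

A sponge triplet requires a retained edge with r > 0 *and* ≥ 2 sites for the
shared miRNA in the circRNA *and* ≥ 1 site in the mRNA 3′UTR. The looser
"two sites in a circRNA, or one site in a 3′UTR" reading acts only as the
per-target miRNA pre-filter; an axis needs both ends, so triplet formation
uses the conjunction. Knockdown target calls intersect patient co-expression
sign with knockdown response direction: (r > 0) ∩ down-DEGs →
positively regulated, (r < 0) ∩ up-DEGs → negatively regulated; the classes
are disjoint by construction.

## Synthetic cohort: what it emulates

The generator plants every structure the analysis is meant to recover, with
defaults mirroring the emulated study design: 39 subjects with matched
tumor/normal samples (78 libraries), 150 circRNAs (≈ 88% multi-exonic, a few
single-exonic and intergenic), 400 mRNA genes, 20 miRNAs, 30 planted DECs at
|log₂FC| = 2 (half up, half down), 20 planted sponge triplets at correlation
strength ρ = 0.9, 100 + 100 positively/negatively correlated decoy pairs
without shared sites, and a designated knockdown circRNA with 13 planted
targets (9 positive including its triplet mRNA, 4 negative) shifted 4-fold in
a 3v3 experiment.

**Counts.** Negative binomial via Gamma–Poisson (`Var = μ + φμ²`, φ = 0.2 in
patients, 0.05 in the knockdown cell-line experiment). The log-mean combines
a per-feature baseline (log-uniform; 100–1000 expected junction reads for
circRNAs, 50–500 for mRNAs), the planted fold change on tumor samples, a
subject effect shared by both of a subject's samples (SD 0.3), a log-uniform
library-size factor, and a biological latent with SD 0.7. Correlation is
planted through that latent: each circRNA owns an i.i.d. per-sample latent
z, and a gene planted at (sign s, strength ρ) uses
`s·√ρ·z + √(1−ρ)·own noise`, so the expected log-CPM correlation has sign s
and approaches ±1 as ρ → 1 and dispersion → 0. Every non-intergenic circRNA
is also planted positively with its host gene (ρ = 0.6), emulating shared
biogenesis; the host is deliberately *not* a knockdown target — host mRNA
levels are typically unchanged when only the circular isoform is depleted.
The baseline/SD values were chosen once so that biological covariance
dominates counting noise (the regime the planted-recovery checks assume) and
the planted DE mass stays a minority of the library, keeping the CPM
composition shift small (≈ 0.3 log₂ here; zero in real cohorts where DECs
are a vanishing fraction of all junctions).

**Sequences.** Genes are laid out with introns and flanking exons on six
chromosomes; each host's circRNA spans its middle exons (transcript ordinals
2..k+1), so the annotated 3′UTR (in the transcript-last exon) never overlaps
the circularized span. Planted triplets receive exactly two sites in the
circRNA (one spanning the back-splice junction with probability 0.5) and one
in the mRNA 3′UTR. Every scanned sequence is then scrubbed of accidental
seed matches for *all* simulated miRNAs by a rewrite-and-rescan loop, and the
planted counts are verified with the production scanner; miRNA sets are drawn
so that no site string of one miRNA nests inside a planted site of another.

**What passing tests do and do not show.** Because accidental sites are
scrubbed and decoys are built without shared sites, triplet precision near 1
reflects correct wiring of the rules, not the false-positive rate expected on
real sequences, where canonical 7mers occur by chance every ~4⁷ nt and site
evidence alone is weakly specific. Likewise the generator has no batch
effects, no isoform complexity, no miRNA expression tier, and NB counts with
a single dispersion — recovery rates here are upper bounds for real data.

## Numerical choices

Variance floor 10⁻⁸ for degenerate t-tests; |r| ≥ 1 − 10⁻¹⁴ mapped to p = 0;
BH outputs capped at 1; constant-expression features excluded from
correlation maps with a warning; host/gene tie-breaks lexicographic;
all randomness flows from one `numpy` Generator seeded per run (the
knockdown experiment uses seed+1), so identical config + seed gives
byte-identical outputs, which the test suite asserts.

## Closed-form utilities

Xenograft tumor volume = length × width² × 0.52 (mm³); width > length is
swapped with a warning, negative inputs error. RNA-stability time courses are
normalized to the t = 0 abundance (errors if t = 0 is absent or zero).

## Problem sizes used in validation

The shipped validation uses the default cohort (150 × 78 and 400 × 78 count
matrices) over ten seeds for recovery; 10⁴ replicates for null calibration of
the paired test and the correlation p-value; 10³ random vectors (length ≤
1000) against the BH oracle and 10² random circles (50–2000 nt) against the
rotation oracle. These sizes make the whole suite run in well under a minute
on one core while keeping Monte-Carlo error far below the asserted margins.

## Known limitations

Junction-read abundance is a proxy, not an estimate of molar circRNA
concentration; CPM carries composition bias when the DE mass fraction is
large (no TMM/median-of-ratios offsets); the paired t on log-CPM lacks the
variance shrinkage of count-model DE engines and is anticonservative for very
low counts; co-expression p-values assume bivariate normality of log-CPM;
the miRNA tier is sequence-predicted only (no AGO-CLIP or miRNA expression
support); and GO/pathway enrichment of network genes is out of scope.
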