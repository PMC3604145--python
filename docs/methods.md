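# Methods

## Study structure being modelled

The package targets the analysis of a small paired supplementation
trial: eight healthy adults sampled at baseline and after eight weeks of
daily vitamin D3 (three subjects on 400 IU, five on 2000 IU), sixteen
arrays in total. Baseline serum 25-hydroxyvitamin D (25(OH)D, ng/ml)
classifies subjects as deficient (<20, strict) or
insufficient/sufficient (≥20); four subjects fall on each side. Three
questions drive the pipeline: which genes respond to supplementation,
which differ at baseline by vitamin D status, and whether the responsive
genes carry candidate vitamin D response elements (VDREs) near their
transcription start sites.

## Differential expression model

Normalization follows the RMA convention: normexp background correction
on linear-scale intensities (normal background N(μ, σ²) plus exponential
signal with mean α, parameters by per-array maximum likelihood, values
replaced by the posterior signal mean — strictly positive and monotone),
log2, quantile normalization (columns forced to the mean empirical
distribution; ties receive the mean of their tied quantiles, making the
transform idempotent), and Tukey median-polish summarization of probes
into genes. Gene-level input matrices skip the first and last stages.

The supplementation contrast is a split-plot two-way ANOVA with visit
as the within-subject factor and dose arm as the between-subject factor.
Per gene, within-subject differences are regressed on an effect-coded
dose covariate (±½): the intercept tests the visit effect (the
unweighted mean of the two arm means, robust to the 3/5 imbalance), the
slope the visit×dose interaction; the dose main effect is tested the
same way on subject means. All three are exact F(1, n−2) tests,
vectorized over genes in closed form. Degenerate fits (zero residual
variance) report p = 1 when the coefficient is also zero, machine
epsilon otherwise; exact-zero p-values are floored at machine epsilon
before multiple-testing adjustment.

Selection combines Benjamini–Hochberg FDR < 0.1 on the visit p-value
with a closed fold-change cut 2^|log2FC| ≥ 1.5 ("at least" 1.5-fold),
where log2FC is the mean paired difference. The status contrast uses a
pooled-variance two-sample t-test (n = 4 vs 4; Welch optional) on
baseline values at p < 0.01 with a strict fold-change cut > 1.5, and
the candidate subset additionally requires paired before/after
significance (p < 0.01) within both status groups separately. Whether
the original subgroup analysis used t-tests or an ANOVA is not stated
in the source design; the t-test is the smallest-sample convention and
is documented here as an interpretation.

qPCR verification uses ΔΔCt relative quantification against an
endogenous control (18S rRNA): rq = 2^−ΔΔCt with the reference ΔCt
taken as the per-gene mean over the reference condition. Concordance of
qPCR with microarray fold changes is an ordinary least-squares fit with
the textbook t-based 95% prediction interval.

## VDRE model and scanner

A VDRE is modelled as a DR3 direct repeat: 6-nt half-site, 3-nt spacer
(any bases), 6-nt half-site. The spacer length is fixed at 3 because
every packaged candidate site has a 3-nt spacer; it is a constructor
parameter for future extension but only DR3 is supported. Half-site
similarity to the known-VDRE library is Hamming distance in either
orientation: 0 = identical, ≤1 (default, configurable) = similar. The
similarity threshold is an interpretation — the source material never
quantifies "similar" — and is exposed as `max_mismatch`. A 15-mer
qualifies when both half-sites match the library, or when the
(half1, half2) pair fits one of the IUPAC motif definitions (the
consensus RGKTSA–NNN–RGKTSA is always included).

Because half-site matching is orientation-agnostic and the expanded
library is closed under reverse complement, a 15-mer qualifying forward
almost always qualifies in reverse as well. Each position is therefore
reported once: strand '+' when the gene-strand reading qualifies, '−'
only when solely its reverse complement does. Overlapping hits are all
reported (no greedy masking). Positions are signed offsets of the
motif's gene-strand 5′ end from the TSS, first transcribed base at +1,
no position 0; BED input is 0-based half-open. The default window is
−150 kb ‥ +10 kb, wide enough to cover every packaged candidate
position (−142,558 ‥ +7,743) even though most sites lie within 60 kb.
The scanner itself is a vectorized lookup over precomputed
qualification tables for all 4,096 hexamers, so 100-kb windows scan in
milliseconds.

### Reconstructed reference tables

The known-VDRE library, the motif definitions, and the housekeeping
negative-control list ship as synthetic reconstructions (marked
`*_synthetic.tsv`): the originals are not available in machine-readable
form. Half-sites per source gene (RANKL, CYP24A1, osteocalcin,
osteopontin, and others) were chosen so the documented classifications
hold — e.g. TGAACT is RANKL-like, AGGTGA is the CYP24A1 proximal
half-site — and four literal paired motifs cover candidate-table rows
(half-sites GGGTTC, GGCGGG, TCATTC, ACAACC) that no 1-mismatch
half-site match explains; the original search motifs were evidently
broader than the surviving half-site lists. The housekeeping list is
twelve canonical housekeeping genes. The candidate table itself
(17 genes, 48 sites with positions and family labels) is packaged
verbatim.

## Synthetic data generator

The generator defines the study conditions the tests and the acceptance
run operate under.

**Cohort.** `gen_cohort` draws per-arm baseline serum from normals
(400 IU: 18.3±1.1; 2000 IU: 24.0±10.7 ng/ml) and adds a normal increase
(5.7 and 9.8 ±4.9 ng/ml; the demographics-table means are targeted
rather than the subject-level 5.6 figure, which reflects rounding).
`default_study_cohort` instead draws serum per status group from
truncated normals (deficient 16±3.8 on [10, 19.5]; other 27.6±5.4 on
[20.5, 40]) so the exact 4v4 status split the subgroup contrast needs
always holds, with the three 400 IU subjects plus one 2000 IU subject
deficient.

**Expression.** Simulated directly at gene level on the log2 scale (a
probe-level path exists for the RMA stages but no probe model is
claimed). Planted supplementation-responsive genes shift every
subject's follow-up value by a signed log2 fold change drawn uniform on
[0.7, 4.7] — strictly above the 1.5-fold boundary (0.585) so selection
cannot flicker at the threshold under the default residual SD of 0.1
log2. Planted status-dependent genes shift deficient-group baselines
(uniform [1.0, 4.7]), emulating convergence after supplementation. A
gene may carry both effects only when declared. The default designs
plant 291 responsive genes (209 up, 82 down) and 66 status genes
(14 up, 52 down in deficient) among 20,000.

The intensity background is a mixture: 0.65·N(9, 1.2) + 0.35·U(4.5, 15)
for the bulk, plus 2% bright-invariant U(15, 19.8) and 2% dim-invariant
U(0.2, 4.5) genes (never planted), emulating the fat-shouldered
distribution of real arrays whose extremes are constitutive control
features. This shape is load-bearing: quantile normalization is
rank-preserving, so planted mass landing in a low-density region of the
intensity distribution displaces the quantile mapping of neighbouring
genes. With a dense background the displacement stays far below the
0.585 selection boundary; with a thin-tailed or hard-edged background
the unbalanced planted mass (209 up vs 82 down) produces spurious
selections and edge genes lose their fold changes entirely. The
invariant pads extend past the maximum reach of any planted effect
(15 + 4.7 < 19.8) so no planted gene can occupy a global rank extreme,
where a rank-preserving transform cannot represent a fold change at
all.

**Sequences.** Background composition is uniform (25% per base) — the
simplest null for motif-hit-rate arithmetic. Every generated window is
"scrubbed": the scanner runs, every qualifying 15-mer outside the
planted set has its non-planted bases re-drawn, and the loop repeats
until no spurious site remains. Whole-window rejection sampling is not
viable — under the default matcher the per-position hit probability on
uniform sequence is ≈2×10⁻², so a hit-free 100-kb window has
essentially zero prior probability — and iterative local re-drawing is
the only sampler that satisfies the zero-hit guarantee for the
housekeeping negative controls. The guarantee is re-verified on every
generation. Planted motifs are inserted at exact TSS-relative offsets
(reverse-complemented on '−' genes) after scrubbing, junction artifacts
are scrubbed around them, and each planted motif is checked to be
detectable under the active library before insertion. Planted
instances closer than ~30 nt can legitimately combine half-sites into
additional DR3 sites between them; the generator reports such designs
as non-convergent rather than silently relaxing the guarantee.

**Randomness.** One integer seed, split into named substreams (cohort /
expression / sequence) via seed sequences; the noise stream is a child
of the expression stream so design construction and noise stay
decoupled. Regeneration with a fixed seed is byte-identical.

## Design statistics

Sample size uses the normal-approximation formula
N = ⌈2 (z₁₋α/₂ + z_power)² σ²/δ²⌉ with a floor of 2, which reproduces
the study's N = 4 at α = 0.05, power 80%, σ = 1, δ = 2 (δ = 2 is the
midpoint of the stated 1.5–3 detectable-change range; the exact pair
behind the published N is not printed). A noncentral-t iteration
(`sample_size_t`) is available; it is never smaller. Post-hoc power
figures are out of scope — their parameters are unstated.

## Enrichment

EASE score: one-sided Fisher exact upper tail with one gene removed
from the overlap (overlap ≤1 scores 1.0), computed via the
hypergeometric survival function against the array background. Pathway
p-values are reported raw at p < 0.05 by EASE convention; BH adjustment
is available behind a flag. Bundled pathway databases are out of scope;
gene sets are user-supplied, so published pathway counts that depend on
a particular GO snapshot are reproduced structurally, not numerically.

## Problem sizes and what the tests show

The acceptance run and recovery tests use the full 20,000-gene,
16-array scale (seconds per run); sequence tests scan 12×100-kb
negative-control windows and 17×160-kb candidate windows (a few
seconds); property suites run brute-force oracles at reduced sizes
(e.g. exhaustive hypergeometric sums at populations ≤2,000, five
global-null replicates of 20k genes). Passing planted-recovery tests
demonstrate that the pipeline's selection logic is correct and
well-calibrated under the generator's assumptions — independent
Gaussian noise, exactly known effects, no subject-level covariance,
no probe-level artifacts. They do not certify performance on real
arrays, where correlated biological variation and heavier-tailed noise
make recovery necessarily imperfect.

## Known limitations

- Exact numeric agreement with vendor RMA implementations is not
  claimed, only algorithmic equivalence of the three stages.
- The "similar" half-site threshold (Hamming ≤1) and the split-plot
  pairing of the two-way ANOVA are documented interpretations of an
  underspecified original design.
- The scanner's strand label is weakly informative for
  reverse-complement-closed libraries (most hits qualify both ways).
- Status-dependent genes are modelled as baseline shifts that imply a
  convergence response in the deficient half of the cohort; analyses
  that select on overall paired change will pick such genes up once the
  implied mean change (half the baseline shift) crosses the fold
  threshold. Combined designs should size status effects accordingly.
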