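# Methods

## Signal model

ABE deamination produces deoxyinosine, read as G by polymerases.
Endonuclease V cleaves the second phosphodiester bond on the 3′ side of
a dI, so an EndoV-released ssDNA fragment starts one nucleotide 5′ of
the edited base. After alignment, the edited adenosine therefore sits
at the second reference-consuming base counted from the read's 5′ end
in sequencing orientation: for plus-strand alignments this is the
second base from the left (A→G call over reference A); for minus-strand
alignments the 5′ end is the alignment's right edge, and the signature
appears as a T→C call over reference T on the plus strand. All site
calling keys on this truncated-second-base statistic rather than on
bulk mismatch counts, which is what separates enzymatic dI signal from
sequencing noise and SNPs.

Only R1 reads are processed; R2 carries no additional truncation
information under this chemistry and is ignored throughout. Reads must
be primary, properly paired (single-end input counts as proper by
convention) and non-duplicate; these requirements mirror the upstream
sort/markdup contract of a standard short-read preprocessing chain.

## Filter cascade

Seven rules, all thresholds in `PipelineConfig` (defaults in
parentheses):

| rule | meaning | default |
|---|---|---|
| i | minimum mapping quality, enforced at pileup | 5 |
| ii | depth per treated replicate | 5 |
| iii | truncated-mutant reads and proportion of strand depth, per replicate | 3 and 0.20 |
| iv | maximum mutant reads in the untreated control | 1 |
| v | rules ii+iii hold in both treated replicates | — |
| vi | no run of `consec_window` consecutive positions with mutation rate > `consec_mut_rate` and ≥ 2 distinct substitution types | 3, 0.20 |
| vii | not on the known-variant exclusion list | — |

Interpretive choices where the rule statement is ambiguous:

- "Mutation number ≥ 3, proportion ≥ 20%" (rule iii) counts
  *truncated-mutant* reads — the signal class — against strand depth.
  The *edited ratio* used by the classifier is total mutant reads /
  strand depth. Both are reported in the audit TSV, so the alternative
  reading is recoverable from the output.
- Rules ii–iii are audited as "passes in at least one replicate"; rule
  v requires both, so a site present in a single replicate fails v
  specifically.
- Rule vi takes the *modal* substitution per position and requires at
  least two distinct (ref→alt) types across the three-position run;
  this keeps a legitimate homogeneous A→G edit pile from excluding
  itself.
- The score is the fraction of strand-depth reads carrying the
  truncated-mutant signature, pooled over treated replicates, clamped
  to [0, 1]. Zero-depth positions are undefined and skipped.

## Binding-site search and classification

The target is the 20-nt protospacer plus the 3-nt PAM pattern; PAM
IUPAC codes score as matches against any base they admit, so
noncanonical-PAM sites surface with their observed PAM reported and
flagged against the canonical `NRG`. Alignment is semiglobal (global in
the target, free end-gaps in the ±100 nt window) with affine gaps: a
length-L gap costs 24 + 8·(L − 1). Penalty is defined as
5 × target length − score, i.e. the shortfall from a perfect match;
the < 70 retention threshold then reproduces the printed scoring
parameters exactly for perfect (penalty 0) and one-substitution
(penalty 9) sites.

Tie-breaking: the dynamic program prefers, in order, the alignment
ending leftmost in the window, then match/mismatch columns over target
bulges over window bulges (fewest-gap bias). This is deterministic and
stable across runs; equal-score alternatives are scientifically
interchangeable, and all tests compare scores exactly.

Classification thresholds: Cas9-dependent requires score ≥ 0.6, edited
ratio ≥ 0.2, ≤ 1 mutant read in sgRNA(−) (total mutant reads — the
stricter reading), and an accepted binding site. Because the search
window is anchored on the edit, every accepted binding site "contains"
the edit within 100 nt; no further distance gate is applied.
Cas9-independent requires ≥ 3 sgRNA(−) mutant reads and zero untreated
mutant reads. Endogenous-dI labelling deliberately bypasses filter iv
(which would otherwise remove every site present in the untreated
sample before it could be labelled): a candidate passing all other
filters with mutant reads in both controls is endogenous, and is never
reported as an off-target class.

Annotation conventions: protospacer position 1 is PAM-distal; the
editing window defaults to positions 3–9; the seed region (feature
extraction) to the PAM-proximal positions 11–20, the field's usual
convention, both configurable. Out-of-protospacer distances are signed
in protospacer coordinates — negative PAM-distal of position 1,
positive past position 20 (the PAM occupies distances 1–3). An edit is
a target-strand edit when its adenosine lies on the strand
complementary to the protospacer orientation.

## Ridge regression of edit determinants

Nine predictors per Cas9-dependent site (first-5/first-8 mismatch and
gap counts, alignment totals including PAM mismatches, seed-region
counts, binary canonical-PAM flag); binary outcome (out-of-protospacer
edit, or target-strand edit). The model is a linear probability fit
with L2 penalty on standardized predictors and centered response:
β = (XᵀX + λI)⁻¹Xᵀy. Inference uses the sandwich covariance
σ̂²(XᵀX+λI)⁻¹XᵀX(XᵀX+λI)⁻¹ with σ̂² from residuals on effective degrees
of freedom n − tr(H) − 1 (the −1 accounts for the fitted mean), and
two-sided Student's t p-values; p < .01 is flagged significant.
λ defaults to generalized cross-validation over a log grid (10⁻⁴–10⁴)
and can be fixed; λ = 0 reproduces ordinary least squares to machine
precision. Constant columns are dropped with a warning (on clean
simulated data some gap features are legitimately all-zero). A
permutation mode (`permutation_pvalues`) provides a
distribution-free cross-check of the analytic t-test. Whether to
standardize predictors was an open choice; standardization makes
coefficients comparable across count scales and is applied always.

## Amplicon quantification

Read pairs carry 5-nt UMIs at both mates' 5′ ends; the 10-nt
concatenation defines a molecule. Grouping is exact-match (a Hamming-1
merge was considered and rejected for determinism; at 4¹⁰ UMI space and
≤ 10⁴ molecules, collision and split rates are negligible). Consensus
is per-position majority over all R1 payloads and reverse-complemented
R2 payloads in the group; positions with modal agreement < 0.6 become N
and drop out of rate denominators. Rates are computed at every
reference adenosine as (G calls)/(non-N calls) × 100, control-subtracted
and floored at zero, and gated at ≥ 500× consensus coverage in both
test and control (positions failing the gate are reported but flagged).

## Simulator

The simulator is the package's test bed and defines its study
conditions. It emits already-aligned single-end SAM (positions are
ground truth), bypassing a real aligner while still exercising every
filter: MAPQ is sampled from {0, 2, 20, 40, 60} with weights
(.02, .02, .06, .10, .80) so the MAPQ gate sees real rejections;
uniform substitution errors default to 0.1%; background reads fragment
the genome uniformly at 30× default depth with 100-nt reads.

Planted site classes: Cas9-dependent/on-target sites rewrite the genome
so a degenerate protospacer+PAM (requested mismatches, DNA bulges =
extra genomic base, RNA bulges = deleted genomic base, concrete or
IUPAC PAM) flanks an edited adenosine at a requested protospacer
position, on either strand. Cas9-independent and endogenous-dI sites
receive a TAT context centered on the edited A (the sgRNA-free
deaminase preference). SNPs are ordinary 50% A→G alleles in every
sample and populate the exclusion list. Signal reads are drawn
Binomial(depth × multiplier, edit fraction) per replicate
independently, so replicate concordance has genuine stochasticity;
sgRNA(−) receives signal only at independent and endogenous sites,
untreated only at endogenous sites.

`signal_read_multiplier` (default 4.0) models the strong enrichment of
truncated dI fragments by the streptavidin/EndoV capture relative to
background coverage; with it, pooled site scores at 50% edit fraction
concentrate around 0.8, comfortably in the regime the score threshold
expects of enriched libraries. Default edit fraction is 0.5 and default
genome size 1 Mb at GC 0.41 (human-like).

What the simulator does **not** model — and hence what passing tests do
not establish about real data: alignment ambiguity and mapping errors
(positions are truth), indel sequencing errors and quality-score
structure, PCR jackpotting in the genomic library, chromatin
accessibility effects on editing efficiency, UMI sequencing errors
(amplicon UMIs are error-free so grouping is exact), and real SNP
linkage. Recall/precision on simulated data are upper bounds.

## Determinism and numerics

Every stochastic component takes a NumPy `default_rng` seeded from the
user seed plus a fixed per-stream tag, so identical seeds give
byte-identical SAM/FASTQ/TSV outputs (verified by hashing in the run
manifest). Integer alignment scores avoid floating-point ties. Pileups
are dense per-contig uint32 arrays (2 strands × 5 bases × length),
suitable up to tens of Mb of toy genome; the candidate scan only visits
positions with truncated-mutant support. Problem sizes used by the test
suite and acceptance script — 1 Mb genome at 30× for full-scale
recovery, 100 kb for shared fixtures, 10⁴ molecules for amplicon
recovery, 100 replicate designs at n = 1000 for ridge calibration —
were chosen as the smallest scales at which the binomial/recovery
properties under test are statistically unambiguous.

## Known limitations

- The exact published normalization of the site score and the formal
  definition of the alignment "penalty" are not fully specified
  upstream; the fraction-of-depth score and the S_max − S penalty are
  the simplest monotone readings of the stated parameters, and both are
  configurable.
- Endogenous-dI labelling depends on mutant-read presence (≥ 1 read) in
  both controls; at very low coverage this is noisy.
- The caller ignores R2 entirely and does not realign or recalibrate;
  it consumes upstream alignments as-is.
- The ridge p-values are conditional on the selected λ; GCV selection
  uncertainty is not propagated (the permutation mode sidesteps this).
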