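# Methods

This note records the models, conventions and numerical choices behind
each analysis stage, what the synthetic generators do and do not
emulate, and the package's known limitations.

## Codon adaptation

**Weights.** Relative adaptiveness is computed per synonymous family of
the standard genetic code from codon counts pooled, unweighted, over
the expressed transcript set: w = (count + c) / max_family(count + c).
The family maximum is exactly 1 by construction. The pseudocount c
(default 0.5) guarantees w > 0 so log-scores are finite; at
transcriptome scale (10⁶–10⁷ pooled codons) it is numerically
negligible. Expression-weighted pooling (each transcript's counts
multiplied by its expression level) is available as an option for
sensitivity analysis; it is not the default because the comparison set
of interest is "the expressed transcripts", not their molar mixture.

**CAI.** The geometric mean of w over scored codons, computed as
exp(mean ln w). Excluded from scoring: stop codons, ATG and TGG (their
single-codon families always carry w = 1 and would only inflate
n_scored), and any codon containing N. Validated properties: order
invariance, self-concatenation invariance, monotonicity under
better-synonym substitution, and equality with a brute-force
product-then-root oracle to 1e-12 on short sequences.

**Gene-level scores.** Each transcript is scored separately; a gene's
CAI is the median across its transcripts (relevant for multi-isoform
inputs; synthetic genes have one transcript each).

**Ranking.** Midrank percentile, 100·(below + 0.5·equal)/N. "X% of
genes use better-adapted codons" is reported as 100 − percentile. With
continuous scores ties are measure-zero and midrank coincides with the
strictly-greater count.

**Rarity classes.** Codons are classed off the weight table: extremely
rare below w = 0.1, rare below w = 0.3, otherwise common; single-codon
families are always common. The cutoffs are package defaults, exposed
as parameters — weight-based classes make "rare" reference-set-aware
rather than an absolute frequency claim. The windowed rare-codon
profile uses non-overlapping windows (default 30 scored codons) and
reports each window's geometric-mean w plus rare/extremely-rare counts,
so a single full-length window reproduces the gene's CAI.

**Optimizer.** Pure per-codon argmax recoding with deterministic tie
breaking (higher reference count, then lexicographic). No GC-content,
repeat or RNA-structure constraints: the modeled claim is only "higher
codon adaptiveness", and constrained design is out of scope. The
optimized sequence has CAI exactly 1; synonymy is re-verified on every
call.

## Polysome quantification

**Traces.** Baseline correction defaults to `linear_endpoints`: a
least-squares line through the first and last 5% of samples (assumed
peak-free) is subtracted. A `rolling_min` mode (smoothed rolling
minimum) exists for non-linear drifts; it is biased low near steep
drift and is not the default. Region areas use the trapezoid rule on
the sampled grid — no peak fitting. Region boundaries are half-open for
assignment, but integration includes both boundary samples so that
areas are exactly additive when a region is split.

**ddPCR statistic.** normalized_f = target_f / (rrna_f · dilution),
with the rRNA dilution (default 1:10,000) rescaling diluted-cDNA rRNA
counts to the undiluted scale; a zero rRNA count is an error naming the
fraction. P = Σpoly/(Σmono + Σpoly) over 1-based fraction sets, default
monosome {2,3,4} and polysome {7,…,11}; the disome, defaulting to
{5,6}, is excluded (its translational status is ambiguous) and both
sets are configurable because gradient fractionation schemes vary.
P is invariant to any common scaling of target counts. Condition shifts
are labeled rightward/leftward beyond a tolerance of 0.01 in P, which
sits below Poisson counting noise at typical (10³–10⁴) copy numbers.

## Decay kinetics

Log-linear OLS of ln(signal) on chase time, replicates pooled into one
regression; k = −slope clipped at 0, t½ = ln2/k (infinite when k = 0,
with a warning on positive slopes). Rationale for not fitting a
nonlinear exponential: with 3 timepoints and multiplicative error the
log-linear model is the maximum-likelihood fit, is deterministic, and
matches the precision of the quantity ("≈ 4 h"). The stabilization
ratio t½(treated)/t½(control) propagates infinity; with few early
timepoints a long treated half-life is estimated with high variance
and its per-experiment ratio is heavy-tailed — medians across
simulations are reported where a stable summary is needed.

## Synthetic generators

All generators consume an explicit integer seed (one `numpy` Generator
per call, no global state; family iteration is in sorted order so
outputs are platform-stable) and return ground truth beside the data.

**Transcriptome.** Shared within-family preferences follow a geometric
ladder (ratio 0.45, order shuffled per family), giving a realistic
spread of weights; per-gene family distributions are Dirichlet draws
with concentration 100 around the shared preferences, producing a
CAI spread comparable in width to real transcriptomes. Planted
"rare-codon" genes emit from the exactly inverted preferences, the
analogue of a gene whose codon usage anti-correlates with the
transcriptome. Amino acids are used uniformly; sequences are
ATG + body + stop (stop drawn 0.5/0.25/0.25 favoring TAA). Defaults:
2,000 genes of 120–600 codons, kinase fraction 0.045 (mirroring 566
kinases among 12,643 expressed transcripts in the motivating dataset),
log-normal expression (μ = 1, σ = 1.2). Not emulated: amino-acid
composition of real proteomes, isoforms, UTRs, GC gradients along
genes — so passing recovery tests demonstrates the statistics, not
sequence realism.

**ddPCR counts.** Expected target copies split (1−P):P between the
monosome and polysome sets, equally within each set and zero elsewhere;
target and rRNA counts are Poisson. With noise off the exact
expectations are returned, making the statistic's recovery of true P
exact (to float rounding). A delta-method standard error treating
per-fraction target and rRNA counts as independent Poisson is provided
and verified against simulation (empirical SD within 20%, 3-SE coverage
≥ 99%).

**Traces.** Sum of Gaussian peaks (40S, 60S, monosome, disome, broad
polysome) on a linear baseline with i.i.d. Gaussian noise, sampled at
dt = 0.05 position units over 0–80. Ground-truth region areas use the
exact erf integral of every component over each region, so truth stays
exact even for peak mass crossing a region boundary. At SNR 20 (noise
SD = monosome amplitude / 20) the baseline-correct → integrate pipeline
recovers region areas with mean relative error ~1%; single-draw errors
are noise-limited with SD ≈ 1%, which is why accuracy claims are stated
as means over seeded traces rather than per-draw bounds. The
proteasome-inhibition variant multiplies the monosome amplitude by 1.8
and the polysome by 0.45, reproducing the bulk shift into monosomes.

**Pulse-chase.** signal = 100·2^(−t/t½)·exp(ε), ε ~ N(0, σ) with
σ = √ln(1+cv²) so the multiplicative CV equals the requested cv.
Defaults follow the motivating design: chase at 0/2/4 h, 4 replicates,
cv = 0.1, control t½ = 4.2 h, treated t½ = 40 h (degradation largely
blocked). At this design the mean recovered control half-life over 200
simulations is within ~1% of truth (well inside the 5% documented
accuracy), and the median stabilization ratio is ≈ 10.

## Workflow and CLI

The two end-to-end reports (`run_codon_report`,
`run_translation_report`) embed the full parameter set and package
version; the CLI additionally writes a manifest with SHA-256 checksums
of all inputs. Manifests and reports carry no timestamps so reruns are
byte-identical. Exit codes: 0 success, 2 validation error, 3 missing
input. Expression filtering uses strict inequality with default
threshold 0 ("expressed" = any signal), and the functional subset is a
case-insensitive plain-substring keyword match on gene descriptions
(default keyword "kinase"); both are parameters because neither choice
is canonical.

## Problem sizes

Default analysis and test sizes — 2,000-gene transcriptomes of 100–600
codons, 500-draw Poisson coverage checks, 20-trace AUC recovery, 200
pulse-chase simulations — were chosen so every recovery estimate has a
standard error comfortably below the tolerance it is checked against
while the full suite runs in well under a minute per stage.

## Limitations

* CDS inputs must be pre-extracted coding sequences; there is no
  GenBank/GFF CDS extraction, and only the standard genetic code is
  supported.
* The optimizer ignores all constraints other than adaptiveness
  (restriction sites, RNA folding, GC windows).
* Trace analysis has no automatic peak/ribosome-number assignment;
  region boundaries must be supplied or taken from the generator
  defaults.
* Half-life fitting assumes first-order decay with multiplicative
  error; no synthesis term, no Bayesian uncertainty.
* Transcriptome-scale reproduction of published CAI values requires
  the external RefSeq + expression inputs described in the README and
  is additionally sensitive to the (unpublished) reference release and
  expression cutoff used originally; the package exposes both as
  parameters rather than guessing them.
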