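# Methods

This note documents the models, estimators, numerical choices and known
limitations behind each stage of the package. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Dictionaries and silent barcodes

A LiGA dictionary maps each phage clone's silent double barcode (SDB) to a
glycan structure, a modification class (`glycan`, `azidoethanol`,
`unmodified`) and a mean display density in glycans/virion. Barcodes are
stored as the concatenation SDB1+SDB2 (single lookup key) with per-region
sequences retained; the silent-coding validator translates each region in
the configured frame and requires every region to encode the expected
peptide (default `SVEKY`, configurable). Stop codons and wrong peptides
are reported as violations, not exceptions, because they are data-quality
findings; a barcode whose length breaks the codon frame is an error,
because the check itself is then ill-posed.

The published clone sequences are not public, so fixture dictionaries
generate synthetic barcodes as synonymous-codon combinations of the silent
peptide (6×4×2×2×2 = 192 variants per region), shuffled deterministically
from a seed and paired so that any two clones differ in both regions
(concatenated Hamming distance ≥ 2, which keeps optional Hamming-1 read
rescue unambiguous). Three designs mirror the platform's published
libraries: `liga6x5` (6 structures × densities {50, 150, 500, 750, 1000},
plus 10 azidoethanol blanks), `msdb_man3` (paucimannose at 5 densities × 7
barcodes each) and `invivo` (the 6×5 glycan set plus 16 unmodified and 10
azidoethanol blanks). Density relates to coat-protein occupancy as
100·density/2700; a one-significant-figure rounding mode reproduces the
coarse occupancy classes used in discussion (1000/2700 → 37.04% → "40%").

The canonical file dialect is UTF-8 TSV (byte-stable round trips, unlike
spreadsheet formats); a comma-delimited importer accepts the same columns.

## Demultiplexing

Reads are 2×75 bp; the forward read carries both barcode regions, each as
`upstream flank + fixed-length SDB + downstream flank`. Extraction scans
for the upstream flank exactly, then (if allowed) by bounded Hamming
distance, leftmost match winning; the downstream flank is verified at the
same tolerance. Failures are data (the read is counted as unmapped), never
exceptions. Dictionary lookup is exact by default — matching the
platform's published processing, which discards unmappable reads without
error correction — with optional rescue to a unique Hamming-1 neighbour;
ties stay unmapped. Bookkeeping guarantees mapped + unmapped = total per
sample, and counting is order-independent. The reverse mate is used only
as a pairing check; which mate carries the barcode regions is a property
of the amplicon design file, and the synthetic default places both on the
forward read.

## Differential enrichment

**Model.** Counts are negative binomial with var = μ + φμ². Whether a
glycan binds is decided per clone by a two-group contrast (test vs control
samples).

**Normalization.** Default is invariant-set: the blank clones are assumed
equal across conditions, so each sample's size factor is the median over
invariant clones of count / pseudo-reference, the pseudo-reference being
that clone's geometric mean across samples; factors are rescaled to
geometric mean 1. An invariant clone with a zero count in any sample is an
error naming the clone (its ratio is undefined and silently dropping it
would bias the factor). Alternatives: TMM (trimmed mean of M-values, 30%
M-trim, 5% A-trim, computed against the sample of median library size,
multiplied by the library-size ratio) for screens where blank reads are
scarce, and total-count (`naive_composition`) normalization, where the
naive library's composition serves as the baseline of the contrast.

**Dispersion.** The common φ maximizes the conditional NB likelihood
pooled over clones and replicate groups — for n equal-mean NB counts the
likelihood conditional on their sum is free of the mean, so no per-clone
mean need be profiled. Counts are first brought to a common library size
by dividing by the size factors and rounding to the nearest integer (the
conditional argument needs equal library sizes; rounding error is
negligible at LiGA depths). Per-clone dispersions come from a vectorized
grid search (61 log-spaced points, 1e-4…10, plus a Poisson limit point).
Testing uses, per clone, **max(common, per-clone)**: a clone more variable
than the pool is tested at its own dispersion. This conservative rule
(familiar from early count-model packages) guards the false-discovery rate
against variance the common estimate understates — in particular the
size-factor estimation noise that invariant-set normalization injects into
every sample when only ~10 blank clones are available. Linear shrinkage
(`dispersion_rule="shrunk"` with a weight) and pure common dispersion
remain available. With no replicated group at all, the estimator returns
a configured floor (1e-4) and sets a warning flag.

**Test.** Conditional exact test: size-factor-adjusted counts are summed
within each group; given the grand total s, the split follows a negative
hypergeometric law ∝ C(k+r₁−1,k)·C(s−k+r₂−1,s−k) with rᵢ = nᵢ/φ (the
shared NB success probability cancels), reducing exactly to
Binomial(s, n₁/(n₁+n₂)) at φ = 0. The two-sided p-value sums the
probabilities of all outcomes no more probable than the observed one
(tolerance factor 1+1e-9 against floating-point ties). A zero grand total
gives p = 1. p-values are Benjamini–Hochberg adjusted; clones are flagged
at FDR ≤ α (default 0.05).

**Effect size.** log₂FC of normalized group means with a prior count of
0.5 added to both (zeros stay finite); the SE comes from the delta method
with var(mean) = (μ + φμ²)/n per group. Note a fixed prior on the count
scale makes log₂FC invariant to global count rescaling only up to
O(prior/mean) ≈ 1e-3 — exact invariance would require a data-scaled prior.

**Group-level tests.** Fold changes can be compared across glycan classes
or organs by a two-sided Mann–Whitney U-test (exact enumeration when both
n ≤ 10 and no ties, normal approximation with tie correction otherwise;
identical samples return p = 1) or a standard one-way ANOVA F-test (zero
within-group variance with equal means is degenerate and returns NaN).

**Calibration.** The acceptance suite simulates 200 screens with known
8-fold-enriched clones (20% of glycans, 3v3, φ = 0.1) and checks the mean
false-discovery proportion at α = 0.05; the parametrized oracle tests
verify the exact test against `scipy.stats.binomtest` exhaustively for all
totals ≤ 50 at φ = 0 and against brute-force Monte-Carlo conditioning at
φ > 0. No attempt is made to reproduce any other package bit-for-bit; the
agreement claimed and tested is statistical.

## MALDI-TOF quantification

Spectra are two-column text (m/z, intensity; `#` comments). Preprocessing
is deterministic: baseline = rolling minimum followed by a rolling mean of
the same window (default 200 Da, converted to points via the median
spacing), subtracted and clipped at zero, then moving-average smoothing
(default 5 points). This baseline sits below a sloping background by
slope×half-window by construction, which is why peak areas are always
extracted from *windowed fits*, never whole-spectrum integration.

Species masses are predicted from configuration constants — pVIII base
mass (default 5238.4 Da), DBCO adduct (427.2 Da), conjugation linker
(129.1 Da); the exact values depend on the chemistry batch and should be
overridden per run — plus monosaccharide residue masses Hex 162.0528,
HexNAc 203.0794, Neu5Ac 291.0954, dHex 146.0579 Da. Every species with k
sialic residues gets ghost companions at −291.0954·j Da (j ≤ k), flagged
with their parent: these are in-source decay artifacts, not reaction
products, and ghost correction reassigns their area to the parent before
normalizing — changing attribution, never total area.

Peaks are Gaussian (σ free within 0.5–20 Da), fitted by least squares in
windows expected mass ± tolerance (default 15 Da); overlapping windows are
fitted jointly as a sum of Gaussians plus a shared constant offset (the
preprocessed baseline is unbiased only to within the noise floor). A
species whose local maximum minus the local median is below 8× the
high-frequency noise level (std of first differences / √2) is assigned
area 0. Mean density = modified fraction × 2700, rounded; the estimate is
made at the DBCO stage (pVIII vs DBCO-pVIII) because sialylation lowers
ionization efficiency, biasing conjugate-stage fractions. The
fraction→density map assumes modified and unmodified pVIII ionize equally;
this linearity is an assumption of the platform, not something the package
can verify. Timecourses quantify each timepoint independently and report
percentages summing to 100 ± 0.1.

## Affinity fitting

The 1:1 binding model gives fraction bound in closed form (monotone in
ligand concentration and in K_d, clipped to [0,1] against floating-point
undershoot). Fitting is nonlinear least squares in fraction-bound space —
not R space — with uniform weights (the instrument literature specifies no
weighting); K_d is kept positive by optimizing log₁₀K_d, initialized from
a 57-point log-grid over 1e-3…1e4 µM, so the fit cannot converge to a
wrong branch. The reported SE is heteroscedasticity-robust (sandwich
estimator with an n/(n−1) small-sample factor): residual variance varies
along the titration when noise acts multiplicatively on R, and the naive
Jacobian SE is then anticonservative. Monte-Carlo tests at 5% R-noise show
median |relative error| ≈ 2% and ±1.96·SE coverage of ~84% over 200
replicates — below the nominal 95% because n = 8 points is small; users
wanting calibrated intervals at this n should apply a t₇ quantile.
A fit requires ≥3 points spanning ≥4-fold in ligand concentration.
Non-convergence returns the best grid value with a flag.

## Synthetic data

Every generator takes a mandatory seed, uses one private RNG stream, and
returns a truth sidecar sufficient to score any downstream stage.

* **Counts**: NB draws with mean = baseline × FC × library factor.
  Baselines are log-normal (default median 300 reads, log-sd 1.0) — phage
  mixtures are never uniform even when mixed by titer; library factors are
  log-uniform in 0.5–2×; blanks always have FC 1. Defaults (3v3
  replicates, φ = 0.1, 8-fold spikes on 20% of glycans) are the conditions
  of the calibration study.
* **FASTQ**: forward reads embed flank+SDB regions padded with random
  bases; per-base substitution errors at a configurable rate (≤ 0.2);
  mates are random filler. No quality-score structure, no indels, no PCR
  chimeras — so passing round-trip tests demonstrates the counting logic,
  not robustness to real Illumina artifacts.
* **Spectra**: sums of Gaussians with areas ∝ fraction ×
  suppression^(sialic count), ghost satellites carrying a configurable
  share of their parent's area, linear baseline drift and Gaussian noise.
  No isotope structure, matrix clusters, or detector saturation.
* **Titrations**: R = f/(1−f) from the closed form, multiplicative
  log-normal noise; exact saturation (f = 1) is clipped and recorded.

## Problem sizes

The default test and acceptance runs use 40-clone dictionaries, 3v3
replicates, 200 simulation replicates for calibration quantities, 3–4k
point spectra, and 8-point titrations — sizes at which every statistical
property under test is already measurable with the quoted tolerances.

## Known limitations

* The exact test treats estimated size factors and dispersion as known;
  with very few invariant clones the residual factor noise slightly
  inflates the far p-value tail (the conservative dispersion rule exists
  to absorb this).
* TMM here is the unweighted trimmed mean (no precision weights); it
  matches the canonical estimator's behaviour on clean global shifts but
  is not a drop-in numerical replica.
* MALDI density assumes equal ionization of modified and unmodified
  pVIII, and Gaussian line shapes; asymmetric peaks (EMG tails) would bias
  areas.
* The in-solution reference-ligand (competition) affinity workflow is out
  of scope; only the direct titration method is implemented.
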