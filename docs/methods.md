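# Methods

## Model and procedure

The package tests, for a short genomic region of T SNP probes, whether cases
are more likely than controls to carry a copy number variant (CNV) anywhere
in the region. The working assumptions are:

* After per-sample normalization, the Log R Ratio X_it of a diploid probe is
  standard normal and independent across probes given copy state; a
  hemizygous deletion (CN1) shifts its mean down, a single-copy duplication
  (CN3) up.
* CNVs of interest span at least L >= 3 consecutive probes; their boundaries
  may differ between carriers (randomly located) or coincide (recurrent).
  The test uses no between-carrier boundary sharing, which is why its power
  is insensitive to that distinction.
* Intensity distributions are identical in cases and controls apart from
  CNV carriage. The procedure is therefore inappropriate when arms are
  genotyped on different platforms or plates; QQ diagnostics are provided to
  detect such artefacts.

The two stages are (1) per-subject evidence: the interval scan maximum
U_i = max |z_ab| over intervals of >= L probes, with z_ab the standardized
interval mean, converted to a p-value p_i against the Monte-Carlo null
distribution of the maximum; (2) association: carrier calling at a
decreasing grid of thresholds q_k, a one-sided Fisher exact test per
threshold, the minimum Fisher p as the statistic Q, and case-control label
permutation for its significance. Deletion and duplication scans use the
signed statistics -z and +z; the combined test uses |z|.

## Tunable parameters

| parameter | default | meaning / rationale |
|---|---|---|
| L | 3 | minimum probes per CNV; below 3 the scan maximum is dominated by single-probe noise |
| mode | both | deletion (-z), duplication (+z), or either (abs z) |
| expected_false | (5, 2, 1, 0.5, 0.1) | expected false carriers per threshold; q_k = e_k/(m+n). A single e = 2 recovers the natural fixed choice q = 2/(m+n) |
| min_successes | 10 | sequential permutation stopping: stop after this many exceedances |
| max_permutations | 10^6 | permutation budget; resolution floor 1/(max+1) |
| null table draws | 10^6 production / 10^5 test scale | Monte-Carlo sample of the scan maximum; 10^6 resolves evidence p-values to ~10^-6, well below the deepest default threshold |
| BAF window | [0.2, 0.8] | outside it a BAF is consistent with homozygosity under every copy state and carries no duplication information |
| rho | -0.05 | copy-neutral LRR-BAF correlation; fusion denominator sqrt(2+2*rho) = 1.38. A fixed method constant, not re-estimated (a diagnostic reports the empirical correlation, which is ~0 under the independent-given-state simulator) |
| y_cap | 5 | clip on the BAF quantile Y; b = 1/2 maps to -inf otherwise. Clipping at 5 truncates ~6e-7 of the null mass |
| segment size M | 50 | genome-wide tiling unit; trailing remainders shorter than L merge into the previous segment so every tested segment is scannable |

## Numerical choices

* **Scan.** Exact O(T^2) enumeration per subject via prefix sums; regions
  are tens of probes, so no pruning is needed. The interval statistic is
  computed as (S_b - S_{a-1}) / sqrt(len), division not
  reciprocal-multiplication, so independent enumeration reproduces it
  bit-for-bit. Arg-max ties break lexicographically (smallest a, then b).
* **P-values.** All Monte-Carlo and permutation p-values use the add-one
  estimator (1 + #exceedances)/(n + 1) with ties counted as exceedances:
  strictly positive, conservative, valid. Null tables are keyed by
  (T, L, mode, n_sim, seed) and cached as .npz.
* **Permutation fast path.** Carrier sets are label-free, so carriers are
  grouped by their deepest threshold and each permutation draws the
  per-group case counts from a multivariate hypergeometric distribution
  (equivalent to assigning the m case labels at random); Q then needs K
  table lookups. The path is verified exactly equal to naive recomputation.
* **Analytic tail approximation.** The random-walk (Siegmund-type)
  approximation to P(scan max > u) is included for large regions but is
  diagnostic only: as transcribed its bracket evaluates negative, so the
  implementation reports the magnitude, clips to (0, 1], and refuses
  T <= 50 where the approximation is known to degrade. A helper tabulates it
  against the Monte-Carlo table (agreement is within ~6% near p = 1 but
  drifts to ~4x at p = 10^-3); Monte-Carlo tables are authoritative
  everywhere.
* **Degenerate inputs.** Zero-variance subjects fail normalization loudly;
  regions shorter than L, unlabelled subjects, probes missing from the map,
  and BAF outside [0, 1] all raise structured errors naming the offender.
  Missing BAF is uninformative (LRR passes through); a p-value grid with no
  carriers yields Q = 1 and a permutation p of 1.

## Design decisions

* **Normalization scale.** "Unit variance" is implemented as the sample SD
  after median-centering (the literal reading); `robust=True` substitutes
  1.4826*MAD for samples whose CNV burden might inflate the SD. All
  autosomal probes participate; no attempt is made to exclude putative CNV
  probes from the estimate.
* **BAF quantile transform.** The transform is reconstructed as the
  probability-integral transform of the folded distance d = |b - 1/2| under
  the copy-neutral heterozygote model b ~ N(1/2, eta2):
  Y = ndtri(2*ndtr(d/eta2) - 1). This yields Y ~ N(0,1) for diploid
  heterozygotes and large Y near BAF 1/3 and 2/3 (Y ~ 3.1 at b = 1/3 with
  eta2 = 0.05), the two properties that define its role.
* **Which series feeds which mode.** Deletion scans use LRR alone (a
  deletion moves BAF toward 0/1, where it is uninformative); duplication and
  combined scans use the fused series Z. Z is standard normal under the
  null, so the same null tables serve both series. The identity
  U = max(U-, U+) holds within a single series.
* **Fisher sidedness.** One-sided for case enrichment by default (the
  hypothesis is that cases carry more CNVs); two-sided available.
* **Coordinates.** Probe intervals are 1-based closed internally (matching
  the statistic's definition); every file written is BED-like 0-based
  half-open.

## The simulator

The generator emulates Illumina-550k-class intensity data conditioned on
copy state: carrier indicators Bernoulli(f) in controls and Bernoulli(f_+)
in cases with f_+ = OR*f/(OR*f + 1 - f); one CNV of exactly `cnv_len` probes
per carrier, placed uniformly or recurrently; genotypes from two
linkage-free haplotypes with per-probe MAF ~ U[0.05, 0.5]; LRR ~
N(mu_c, sigma_c) with mu = (-3, -0.45, 0, 0.30, 0.50), sigma = (1, 0.26,
0.16, 0.19, 0.22) for copy numbers 0..4; BAF from the genotype-conditional
mixture (uniform under CN0; a 0.5 point mass at the boundary plus a folded
normal of scale eta1 = 0.02 for homozygotes; normals of scale eta2 = 0.05 at
1/2, 1/3, 2/3 for AB, AAB, ABB), clipped to [0, 1]. CN1 retains, and CN3
duplicates, a uniformly chosen haplotype. CN4 parameters are carried but CN4
events are never generated (rare in germline data). Simulated LRRs are
standardized with the diploid parameters, (lrr - mu2)/sigma2 — the
simulation analogue of the genome-wide median/SD normalization applied to
real data.

What the simulator does **not** emulate: linkage disequilibrium between
probes (power is averaged over MAF rather than haplotype structure), GC
waves, batch/plate effects, case-control platform differences, mosaicism,
and multi-CNV subjects. Passing tests therefore demonstrate the statistical
machinery under the stated intensity model, not robustness to array
artefacts — on real data the QQ diagnostics carry that burden.

## Validation scale

The shipped validation runs at desk scale, chosen to exercise the claims
with tight Monte-Carlo error while remaining quick: type-I error from 1,000
null replicates at m = n = 200; power from 300 replicates at m = n = 1000,
f = 0.01, OR = 5, alpha = 0.001 with 10,000 permutations per replicate and
10^5-draw null tables; distributional checks at 10^4 probes. Production
analyses would raise null tables to 10^6 draws and the permutation budget to
10^6 as the defaults do.

## Known limitations

* Evidence p-values are granular below 1/(n_sim + 1); thresholds deeper
  than the table resolution collapse onto the same carrier sets.
* The permutation statistic is discrete: with rare carriers many segments
  have permutation p = 1 (expected, and visible as the flat QQ tail for
  duplications in real data); genome-wide deflation of duplication p-values
  is a feature of that discreteness, not miscalibration.
* Covariates, stratified permutation, sex chromosomes and cross-platform
  meta-analysis are out of scope.
* The analytic tail approximation is a diagnostic, not a calibrated
  p-value (see above).
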