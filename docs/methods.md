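# Methods

## Dosage model

All inference rests on one observation: mean aligned depth is proportional
to copy number. With genome-wide mean depth $\bar d_s$ for sample $s$, the
expected per-base depth at a locus of dosage $k$ copies is
$\bar d_s \cdot k/2$. On a reference chromosome assembled from the
heterogametic sex's unique chromosome (a Y, in an XY system):

| region class          | heterogametic sex | homogametic sex |
|-----------------------|-------------------|-----------------|
| pseudo-autosomal (PAR)| $1$               | $1$             |
| hemizygous (Y-specific)| $1/2$            | $0$             |
| diverged gametolog    | $(1+\lambda)/2$   | $\lambda$       |

entries in units of $\bar d_s$. The mappability leak $\lambda \in [0,1]$
is the efficiency with which reads from the diverged partner chromosome
(the X) still map to the Y reference; $\lambda$ slightly below 1 produces
the characteristic *slightly lower* female coverage in shared regions
(female/male ratio $2\lambda/(1+\lambda)$, ≈0.95 at the default
$\lambda=0.9$). Hemizygous fraction $f$ gives chromosome-level ratio
expectations $1-f$ (homogametic) and $1-f/2$ (heterogametic); these closed
forms are exact when the normalizer excludes the sex chromosome itself and
carry a small $O(f \cdot L_{sex}/L_{genome})$ offset when the whole-genome
mean is used (the pipeline's default normalizer, kept for fidelity to how
coverage ratios are usually plotted; the exclusion is available as an
option).

## Statistics

**Welch's t-test.** $t = (\bar x_1 - \bar x_2)/\sqrt{s_1^2/n_1 + s_2^2/n_2}$
with Welch–Satterthwaite degrees of freedom and a two-sided Student-t
p-value; implemented from the closed forms (only the t tail probability
comes from `scipy.stats.t`). Group order is fixed (females, males)
package-wide so a negative t always means males larger. Degenerate inputs
(both variances zero) return $t=0, p=1$ for equal means and signed infinity
with $p=0$, flagged, otherwise. Tests verify agreement with
`scipy.stats.ttest_ind(equal_var=False)` to 1e-10 on 1,000 random
instances; scipy is the cross-check, never the implementation.

**Candidate detection.** Per-chromosome Welch on coverage ratios,
Bonferroni across chromosomes (default α = 0.05 family-wise), plus a
minimum absolute mean-ratio difference (default 0.05). The effect filter is
load-bearing: normalizing by the whole-genome mean makes *autosomal* ratios
differ between sexes by $O(f \cdot L_{sex}/L_{genome})$ (≈0.005 here) with
tiny variance, which is statistically detectable but biologically
irrelevant; the effect threshold removes such hits and leaves the dosage
signal (≈0.15) untouched.

**VCF filters.** Per-genotype depth window [1, 50] applied first
(genotypes outside become missing), then a site-presence rule (≥ 95% of
individuals non-missing, inclusive at the boundary) — the usual
VCFtools `--minDP/--maxDP` + `--max-missing` semantics. Filtering is
idempotent and each rule's drop count is reported for auditability.
Mapping/base quality thresholds are calling-time filters assumed already
applied upstream.

**Heterozygosity contrast.** Raw per-individual het-site counts (a
per-evaluated-site rate is also emitted) over the *shared* windows of the
candidate chromosome, compared with Welch's t (females − males). The axis
is only consulted when ≥ 50 filtered sites are available, as small site
counts make the contrast unstable.

## Density modes

The quantity whose density is bimodal is the **per-base average across a
sex's samples of normalized depth** $\frac{1}{n}\sum_s d_s(x)/\bar d_s$.
Averaging is essential: a single sample at ~4.4× has Poisson granularity
1/4.4 ≈ 0.23 in normalized units, which merges the 0.5 and 1 dosage modes
into one lump; averaging $n$ samples raises effective depth $n$-fold and
separates them cleanly. The density is a histogram on support [0, 2]
(binwidth 0.02, mirroring the usual axis cap for such plots), lightly
smoothed with a fixed Gaussian kernel (σ = 2 bins) so integer-depth
discreteness does not fragment a mode across adjacent bins; modes are local
maxima with prominence ≥ 5% of the global maximum (support edges count;
ties break toward the smaller location). Mode locations are reported as bin
centers, so a point mass at 0 reports as 0.01.

## Segmentation and sexing

Windows are labeled from depth- and width-normalized per-sex mean counts
$u = \text{count}/(\bar d_s \cdot \text{width})$ averaged within sex:
*sex-specific* when one sex's mean is ≤ 5% of the other's and the covered
sex carries ≥ 10% of its chromosome-wide mean signal; *shared* when the
female/male ratio lies within 1 ± 0.2; *ambiguous* otherwise. The
ambiguous class absorbs boundary windows that mix region types, so
segmentation accuracy is quoted to ± 1 window.

Unknown-sex individuals are assigned only when two axes agree: (i) the
candidate-chromosome ratio is nearer one known-sex cluster mean than the
other *and* more than 10% of the between-cluster distance from the
midpoint (otherwise abstain); (ii) the fraction of sex-specific windows
where the sample's normalized count is ≤ 5% of the covered sex's reference
level falls on the same side of ½. With no sex-specific windows the ratio
axis is used alone and flagged. The pipeline abstains rather than guesses:
a sample at the midpoint is reported `unassigned`.

## Verdict

The coverage direction is the primary axis: females lower on the candidate
⇒ the reference carries the heterogametic-male-specific chromosome ⇒ XY;
the mirror ⇒ ZW. Density modes (heterogametic near {0.5, 1}, homogametic
near {0, 1}, matched within 0.15) and the het contrast corroborate; a
significant het contrast with the *wrong* sign withholds the verdict
(`undetermined` with a machine-readable reason), and absence of any
candidate yields `undetermined("no_candidate")`. Corroborating axes can
never produce a verdict on their own.

## The simulator

`synthetic_data` generates what the analysis consumes, not reads: per-base
depth is drawn directly (Poisson by default; negative binomial with
θ = 10 optionally) from the dosage model above, and window "alignment
counts" are per-window depth sums divided by a nominal 150 bp read length.
Defaults are the package's study conditions:

- cohort 20 males / 7 females / 8 unknowns (half of the unknowns truly
  female), per-sample mean depth log-uniform on [1.3, 11.8]× — mean ≈ 4.6×
  with the right-skew typical of resequencing cohorts — or fixed 4.4×;
- 17 chromosomes totalling 10 Mb, lengths ∝ rank$^{-0.7}$ (a macro/micro
  karyotype in miniature); the 12th largest (~345 kb) is sex-linked;
- region plan 55% PAR / 30% hemizygous / 15% diverged, placed as contiguous
  blocks in seeded random order, with boundaries snapped to the window
  grid so the per-window truth track is exact (realized fractions are
  reported and used by the oracle tests);
- window size 10 kb. This is a deliberate desk-scale choice: it preserves
  the *number* of windows per chromosome (~35 on the sex chromosome,
  matching the granularity a 150 kb grid gives a tens-of-Mb chromosome)
  rather than the absolute window size, which at 1/1000 genome scale would
  leave ~2 windows and no segmentation to test. The io layer's default for
  real-scale inputs remains 150 kb;
- genotypes: background SNVs at 10⁻³/bp (allele frequencies uniform on
  [0.1, 0.5], Hardy–Weinberg genotypes; haploid calls in hemizygous
  regions), fixed gametolog differences at 10⁻³/bp in diverged regions
  rendering the heterogametic sex het, and per-genotype depth drawn
  Poisson at the site's dosage expectation (DP = 0 ⇒ missing).

Same-seed runs are bit-identical, and an XY configuration is the exact
mirror of the ZW configuration with male/female counts swapped — the basis
of the label-swap symmetry tests. Genotype-level depth is re-drawn at sites
rather than read off the per-base track; the two are consistent in
distribution but not jointly sampled.

**What the simulator does not emulate** — and hence what passing tests do
not demonstrate about real data: GC and mappability bias beyond the single
λ parameter, alignment artifacts and repeat-driven coverage spikes,
linkage disequilibrium and realistic allele-frequency spectra, sequencing
error in genotypes, batch effects between libraries. On real cohorts the
thresholds above (especially the shared-band width and the near-zero
threshold) are exposed in `InferenceConfig` and may need loosening.

## Problem sizes

The test and acceptance workloads use the 10 Mb desk-scale genome: one
full cohort simulation is ~1 s and a full analysis ~0.15 s, so the
calibration (100 null cohorts) and recovery (100 XY cohorts plus 200
label-swapped analyses) suites are minutes, not hours. Replicate counts
(100 for rates, 10 for closed-form checks) are the package's chosen
Monte-Carlo sizes; tolerances on rates are ±3 binomial/empirical standard
errors.

## Known limitations

- One candidate chromosome is segmented by default (`--all-candidates`
  for polymorphic or multi-chromosome systems).
- The verdict cannot distinguish an X-assembled reference in an XY system
  from a Z-assembled one in a ZW system when the heterogametic sex's
  specific chromosome is absent from the assembly; it reads the *assembled*
  sex-specific sequence's dosage.
- No dosage-compensation or stratum-age analysis; no identification of the
  gametolog partner elsewhere in the assembly.
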