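# Methods

## Restriction discrimination

Digestion is modelled for linear double-stranded amplicons with complete
cutting. Coordinates are 1-based; a cut at coordinate c splits [1..c] from
[c+1..L], so c equals the prefix-fragment length. For a recognition motif
starting at position p with top-strand cut offset o, the cut coordinate is
c = p + o − 1. This convention makes "cut 1752 bp downstream of the start
codon" of a 1959-bp ORF produce fragments of 1752 and 207 bp exactly. Cuts
at c = 0 or c = L are discarded — they would create zero-length fragments.
Whether a published cut coordinate denotes the cut position or the motif
start is ambiguous in general; we adopt the cut position because it makes
the fragment arithmetic exact.

Motifs may contain IUPAC ambiguity codes (set-match semantics); ambiguity
codes in the *sequence* never match a motif position — the conservative
choice for assay design, since a base call you are not sure of should not
be counted on to be cut. Palindromic motifs are scanned on the top strand
only (their bottom-strand occurrence coincides); non-palindromic motifs are
additionally searched as their reverse complement, with the top-strand cut
of a bottom-strand site at p + (m − o) − 1. Circular molecules, partial
digestion, methylation sensitivity and star activity are out of scope: the
assay digests linear PCR amplicons to completion.

Band classification models co-migration on an agarose gel: fragments whose
relative length difference |Δ|/mean is within a tolerance (default 0.02,
roughly agarose resolution; configurable in [0, 0.2]) cannot be told apart.
Clustering is single linkage, which in one dimension is chaining sorted
lengths by adjacent gap; ties merge. A band class is *diagnostic* iff all
member fragments come from one variant. Classes under 50 bp are flagged
likely undetectable (small fragments run off or stain weakly). Enzyme
screening scores an enzyme by the number of variants owning at least one
diagnostic band; distinct uncut full lengths beyond tolerance count as
diagnostic. Ties rank the enzyme with fewer total bands first (simpler
gel).

## Gel quantification

Intercalating dyes report DNA mass, so band intensity is modelled as
(molar amount) × (fragment length); dividing a diagnostic band's intensity
by its length converts mass signal to molar signal. Diagnostic mode
averages this molar estimate over each variant's diagnostic bands and
ignores shared bands — faithful to manual densitometry practice, where a
band fed by several variants carries no variant-specific information.
Least-squares mode instead solves intensity ≈ M·x for x ≥ 0 by nonnegative
least squares over *all* bands, M being the band × variant mass incidence
matrix; it is a documented extension that uses the shared bands and is the
mode of choice when a variant has no diagnostic band. On noise-free data
the two modes agree to numerical precision (tested to 1e-6 relative).

Abundances are normalized to a loading-control (reference amplicon)
intensity per lane, which makes them invariant to lane-wide intensity
scaling; percent change versus a control condition is 100·(T/C − 1).
Intensities are consumed as supplied: background subtraction is the
upstream densitometry's job. Replicate structure follows the motivating
assay (three biological × three technical, n = 9); technical replicates
should be averaged per biological replicate before testing to avoid
pseudo-replication. Group comparison runs all pairwise two-sample t-tests
with the per-comparison threshold Bonferroni-adjusted to α/m over the
m = g(g−1)/2 pairs, and assigns compact significance letters by the
insert-and-absorb algorithm; groups with zero variance and identical means
are reported not significant rather than as errors.

## Growth-constant estimation

Exponential fitting regresses ln A600 on time. Without an explicit window
the longest contiguous run of ≥ 4 positive-OD points with r² ≥ 0.98 is
selected, then endpoints are greedily trimmed while trimming improves r²;
the trim removes residual lag or plateau points that a long exponential
span would otherwise mask (a handful of flat points barely dents the r² of
a window dominated by exponential rise, yet biases the slope low by
several standard errors). Both thresholds are configurable; a direct
nonlinear exponential fit is available and agrees with the log-linear fit
to 1e-6 relative on clean data. A trace with no qualifying window *and*
less than half a doubling of net growth over the whole assay is assigned
rate 0 (a non-growing culture, typical at zero substrate); a trace that
grows but never looks exponential raises an error instead of guessing.

The growth rate is expressed in doubling times per hour, rate = k/ln 2
(dt = ln 2/k). k_G is invariant to this scaling — it only rescales
k_max — which is why the rate-convention ambiguity is harmless. Replicate
traces are fitted independently; the isotherm entry per concentration is
the replicate mean with its standard error. The Michaelis–Menten fit is
weighted nonlinear least squares (weights = inverse variance of the mean
when replicate SEs are available), initialized from the Hanes–Woolf
linearization S/v vs S, with positivity bounds; parameter standard errors
come from the chi-square-scaled linearized covariance. The S = 0 point is
excluded by default: residual growth without substrate reflects internal
stores, not transport. Negative fitted k (declining culture) clamps to
rate 0 with a warning. The affinity call is high iff k_G ≤ 100 µM
(boundary inclusive, configurable) — micromolar constants characterize
high-affinity transporters, high-micromolar-to-millimolar ones the
low-affinity class.

k_G approximates k_M only while uptake limits growth. Three checks guard
this: (i) the internal substrate store per A600 unit shows no significant
monotone trend over external concentration (Spearman rank test, α = 0.05) —
accumulation would mean assimilation limits growth; (ii) growth on an
organic sulfur source strictly exceeds the fastest substrate-fed growth —
downstream metabolism is not the bottleneck; (iii) the store after growth
without substrate stays below 0.05 nmol per A600 unit — no pre-existing
reserve. A missing organic-source control marks check (ii) indeterminate
and the overall verdict invalid.

## Synthetic data

The generators are exact forward models of the estimators, so noise-free
round trips recover generating parameters to numerical tolerance — the
basis of most oracle tests.

*Paralog sets.* All variants share one random backbone (near-identical
paralogs) purged of the target motif; motifs are implanted so requested cut
coordinates are realized under the coordinate convention, and generated
sequences are rescanned to confirm the exact site count (0/1/2 for the
default trio). The default geometry is the motivating assay's: a 1959-bp
backbone, variant b cut at 1752, variant c at 1098 and 1752, and variant a
carrying a 9-bp insertion immediately after the start-codon analog
(matching its published location at the 5′ end of the coding sequence),
giving 1968 bp and no site. Overlapping motif placements raise an
infeasible-spec error. No substitution process or codon structure is
modelled: the sequences are background randomness plus controlled edits,
sufficient for digestion geometry but not for phylogenetics.

*Growth curves.* The realized exponential rate at concentration S is
k(S) = ln 2 · k_max·S/(k_G + S); OD follows A0·e^(k·t), or logistic growth
with the same initial rate when a plateau OD is set (off by default so
analytic recovery is exact). Defaults copy the published design: ladder
0, 1, 2.5, 5, 7.5, 10, 25, 50, 100 µM; hourly readings over 25 h;
A0 = 0.1; six replicates (two experiments in triplicate). k_max defaults
to 0.5 dt⁻¹ h⁻¹ (a 2-h doubling time at saturation, realistic for
S. cerevisiae in minimal medium; the published reports give k_G but not
k_max, and k_G estimates are invariant to the choice). The default
k_G is 5.46 µM, the first of the published constants.

*Noise.* Measurement noise on OD and band intensity is multiplicative
log-normal (log-sd 0.02 for OD, 0.05 for densitometry) — absorbance and
densitometric errors scale with signal. The magnitudes are defaults chosen
for realism, not measured values; real inter-replicate scatter is not
reported for either assay. Not emulated: plate edge effects, evaporation,
diauxic shifts, gel smiling, lane-to-lane background gradients — so
passing tests demonstrate correctness of the estimators under the stated
noise model, not robustness to every artifact of real instruments.

## Numerical choices and problem sizes

All stochastic behavior lives in the simulators and is seed-controlled;
the estimators are deterministic. The estimator-quality suite runs 200
simulations of the full design at 2% OD noise (median relative k_G error
observed well under 1%; nominal 95% CI coverage above 85%). Bulk
invariants (fragment-length conservation, scanner-vs-naive-oracle
equality) are checked on 1000 random sequences up to 5 kb. The acceptance
script runs the full design once per target; every run derives its
sub-seeds from the single `--seed` argument.

## Known limitations

- Complete-digestion assumption: partial digests produce extra bands the
  band classifier will misassign.
- The incidence-matrix mass model ignores length-dependent staining or
  transfer efficiency beyond strict proportionality.
- The k_G standard error is the within-fit (linearized) error;
  between-experiment variability is visible only through the replicate
  SEs entering the weights.
- Single-linkage band chaining can, in pathological length ladders, link
  fragments whose pairwise difference exceeds the tolerance.
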