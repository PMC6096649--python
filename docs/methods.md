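# Methods

## The coupling model

The package analyzes two forms of cross-frequency coupling between frontal
delta (1–4 Hz) and beta (14–30 Hz) EEG oscillations, both computed *within*
subject over a set of fixed-length epochs:

**Debiased phase-amplitude coupling (dPAC).** With `φ_t` the instantaneous
delta phase and `a_t` the instantaneous beta amplitude over `n` timepoints,

    PC   = (1/n) Σ_t e^{iφ_t}                      (phase clustering)
    PAC  = (1/n) Σ_t a_t e^{iφ_t}                  (mean vector, raw)
    dPAC = |(1/n) Σ_t a_t (e^{iφ_t} − PC)|

Subtracting the phase-clustering vector `PC` from each unit phase vector
before the amplitude-weighted average removes the bias that a non-uniform
phase-angle distribution induces in the raw mean vector: under a uniform
distribution `PC = 0` and dPAC equals |PAC| exactly. dPAC is reported
mean-normalized (the `1/n` form) so the raw and debiased magnitudes are
directly comparable; the surrogate Z below is invariant to that choice.

**Surrogate null and dPACz.** Significance comes from an epoch-shuffling
null: whole epochs of the phase series are re-paired with the intact
amplitude epochs by a uniform random permutation (identity permitted),
dPAC is recomputed over the re-paired concatenation, and this repeats
`n_perm` times (1,000 by default). Then

    dPACz = (dPAC − mean(dPAC_null)) / std(dPAC_null)

with the sample (n−1) standard deviation of the surrogates. Because epoch
shuffling permutes whole phase epochs, the concatenated phase multiset —
hence `PC` and the amplitude mean — is permutation-invariant, and each
surrogate factorizes over precomputed cross-epoch sums
`M[j,k] = Σ_t a_{j,t} e^{iφ_{k,t}}`; the implementation uses this exact
factorization and the test suite verifies it against direct recomputation.

**Amplitude–amplitude correlation (AAC).** The delta and beta Hilbert
envelopes over the same concatenated timepoints are correlated with the
product-moment (Pearson) coefficient; a Spearman variant is available by
flag. Positive AAC means the two bands' power waxes and wanes together.

Both metrics are computed per electrode (F3, Fz, F4) and averaged into a
frontal composite, yielding one dPAC, one dPACz and one AAC value per
subject and condition.

## Preprocessing chain

Epochs are processed in the stated order: (1) anti-alias filtered
decimation from 512 Hz to 128 Hz (zero-phase FIR low-pass, cutoff 0.8× the
target Nyquist, integer factor required); (2) zero-phase Butterworth
band-pass per band — the configured order (8 for delta, 34 for beta) is the
one-pass order of the design, doubled by the forward–backward pass, and the
filter is realized as cascaded second-order sections because a direct
order-34 transfer function at 128 Hz is numerically fragile; (3) Hilbert
analytic signal over the whole epoch (phase 0 at the positive peak of a
cosine, radians in (−π, π]); (4) 16 samples trimmed per edge to discard
filter edge artefacts (an 8-s epoch at 128 Hz yields 992 usable samples,
six epochs 5,952). Epochs are demeaned before filtering by default (a
flag disables this; it is inert for a band-pass). The delta and beta chains
run independently on the same epoch.

Epoch bookkeeping follows the study design: continuous recordings are cut
into non-overlapping 8-s epochs (trailing remainder discarded); six early
and six late clean epochs are drawn uniformly without replacement from the
clean members of the first and last ten (three plus three, combined, for
resting state); the clean mask is caller-supplied since artifact screening
is out of scope.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes, not
the biophysics of EEG. Each epoch is

    x(t) = A_d e_d(t) cos θ(t)
         + A_b e_b(t) [1 + m cos(θ(t) − μ)] cos(2π f_b t + ψ)
         + σ · 1/f noise

with delta phase θ, modulation depth `m = pac_depth`, preferred phase μ,
beta carrier f_b = 22 Hz, amplitude ratio A_b/A_d = 0.25, and Gaussian
noise spectrally shaped to 1/f (exponent 1; white noise by flag) scaled so
its SD is `noise_sd` times the SD of the summed oscillatory components.
Slow envelopes e_d, e_b (Gaussian-smoothed white noise, τ = 0.4 s,
depth 0.35, clipped at 0.05) are mixed from a shared latent so their
population correlation equals `aac_rho`. Defaults: `pac_depth` 0.5,
`noise_sd` 0.5, `aac_rho` 0 (the default study injects 0.3 for the LSA
group and 0 for the HSA group, reproducing the qualitative pattern the
design probes: envelope correlation separates the groups while
phase-amplitude coupling does not).

Two generator choices deserve explanation:

* **Delta carrier at 1.75 Hz, not the 2.5 Hz band centre.** The
  phase-clustering bias is injected as a monotone within-cycle time-warp,
  θ′ = θ − b·sin(θ − μ), which concentrates sample phases near μ. Warping a
  carrier f creates harmonic sidebands at 0 and 2f; for f = 2.5 Hz the 5 Hz
  sideband lies outside the 1–4 Hz band, so band-pass filtering
  re-sinusoidalizes the wave and erases the very non-uniformity the
  debiasing is meant to correct. At 1.75 Hz the second harmonic (3.5 Hz)
  stays in-band and the bias survives the filter; 8 s × 1.75 Hz = 14 whole
  cycles keeps unbiased phase coverage uniform. Both carriers are config
  fields.
* **Per-epoch carrier jitter (±10%).** With a perfectly periodic
  fixed-frequency delta, the beta-amplitude modulation has the same
  frequency in every epoch, so re-pairing epochs merely rotates the
  coupling vector instead of destroying it: the surrogate null grows with
  the injected depth and dPACz saturates regardless of coupling strength.
  Real delta is broadband — phases decorrelate across epochs — and a small
  uniform per-epoch frequency jitter restores that property.

Cohorts derive per-subject generators from a master seed via NumPy seed
sequences; every generator is a pure function of its configuration
including the seed. Optional between-subject coupling variability
(`subject_scale_sd`, truncated-normal multiplier on the injected coupling)
and a synthetic nervousness covariate correlated with that multiplier
(`covariate_rho`) exist solely to exercise the correlation layer and are
off by default.

What the generator does **not** emulate: volume conduction and channel
covariance (the three channels are independent draws), ocular and muscle
artifacts, non-stationary band power over conditions, and realistic scalp
topography. Passing tests therefore certify the estimator chain and its
calibration, not claims about real-EEG effect sizes.

## Statistics

Within-group location tests use the one-sample Wilcoxon signed-rank test
(zero differences dropped, mid-ranks, tie-corrected variance, normal
approximation without continuity correction — the convention under which an
all-positive sample of n = 32 gives Z = 4.94 and n = 20 gives Z = 3.92).
Between-group tests use Mann-Whitney U with the same tie-corrected,
uncorrected-normal Z, reported as |Z|. Correlations with self-report
covariates use Spearman's rho. All p-values are two-sided except the
explicitly one-sided coupled-vs-uncoupled validation contrast. Each family
of tests ("section": dPAC within, dPAC between, AAC within, AAC between,
correlations) is corrected separately with the Benjamini–Yekutieli step-up
procedure, which controls FDR under arbitrary dependence; BY rather than
Benjamini–Hochberg because the tests within a family share subjects and
are dependent.

## Numerical and design choices

* Coupling is computed over the *concatenation* of the six trimmed epochs
  (one phase series, one amplitude series per electrode); the
  epoch-shuffling surrogate is defined relative to that concatenation.
  Per-epoch PC subtraction is available as an option (`pc_scope="epoch"`).
* `PC` is computed once over the concatenated series, mirroring the single
  subtraction in the estimator definition.
* Surrogate draws are uniform permutations with replacement across draws;
  the identity pairing is not excluded. Circular epoch-shift surrogates are
  available by flag.
* Degenerate inputs: an all-zero amplitude series yields dPAC = 0 with a
  `degenerate` flag; a zero-variance surrogate set or envelope raises
  rather than returning NaN.
* Determinism: re-running the pipeline with the same master seed reproduces
  every output file byte-identically; surrogate seeds are derived per
  subject × condition × electrode from the master seed.

## Problem sizes for the test and acceptance runs

The default analysis uses 1,000 surrogate permutations. The repeated
simulation studies in the test suite and the acceptance script use the
reduced profile of 200 permutations (quantifying dPACz only to ~0.07 SD
resolution, ample for the qualitative contrasts checked), 100 seeds for the
type-I calibration run, 50 repeated 30-subject studies for the AAC
specificity rate, and 5–10 master seeds of a 52-subject single-condition
cohort for the depth-recovery check. These sizes are the package's CI
profile; all are configurable.

## Known limitations

* The Hilbert envelope of a band with only ~3.5 cycles per epoch (delta)
  has limited effective degrees of freedom; AAC p-values treat timepoints
  as independent and are anti-conservative in absolute terms. The analysis
  relies on group contrasts and the surrogate-calibrated dPACz, not on raw
  envelope-correlation p-values.
* Under the null, dPACz has a slightly negative median: surrogate dPAC
  magnitudes are right-skewed, so their mean exceeds the typical draw and
  standardizing an exchangeable observation against them centres it below
  zero. Two-sided rejection rates stay near nominal (the type-I check in
  the test suite), but one-sample location tests of dPACz on null data can
  flag this skew as a "significant" negative shift.
* dPACz compresses at strong coupling (the observed value and the null
  spread both scale with modulation depth), so it discriminates presence
  from absence of coupling more sharply than it grades strong couplings.
* EDF export is not implemented; cohorts interchange via the documented
  `.npz` container (EDF *reading* is supported through MNE).
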