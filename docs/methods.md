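# Methods

## Scope and model

`envnet` implements a resting-state source-space analysis chain with two
branches and a synthetic-cohort generator that provides ground truth for
both.

**Static branch.** Per band b ∈ {θ: 4–8 Hz, α: 8–12 Hz, β: 12–30 Hz}, the
recording is band-passed (zero-phase Butterworth, order 4 per pass), the
analytic signal z_j(t) obtained by Hilbert transform, and for each ordered
node pair (i, j) the leakage-corrected envelope correlation computed as

    A[i, j] = corr( lp|z_i|, lp|z_j⊥i| ),   z_j⊥i = Im( z_j · conj(z_i) / |z_i| ),

with lp the 1-Hz zero-phase low-pass and all statistics over edge-trimmed
samples (1 s per side). The connectome is r = (A + Aᵀ)/2 with zero diagonal;
node power is the variance of the band-passed signal. The order of
operations is fixed as: orthogonalize at full rate → magnitude → 1-Hz
low-pass → trim → correlate. The two orthogonalization directions are
averaged after the envelope low-pass. No Fisher z-transform is applied —
downstream tests are rank-based and invariant to monotone transforms.
Collinear pairs (orthogonalization leaves only float noise, detected
relative to the source envelope scale) contribute 0 rather than NaN, so
test tables never contain holes.

**Dynamic branch.** Wide-band (4–30 Hz) envelopes are window-averaged
(100-ms windows sliding every 25 ms; 1000 Hz → 40 Hz; at other input rates
the emitted rate is fs/round(0.025·fs)), edge-trimmed, demeaned per channel,
normalized by the globally pooled SD, concatenated across subjects,
and reduced to their leading principal components scaled to unit variance
(requested 40, capped at the data rank — 32 for the default parcellation,
with a logged warning). A K = 8 state Gaussian HMM with full covariances is
fitted by EM; each of 10 restarts is initialized from a multi-init k-means
*state assignment* — both state means and state covariances are taken from
the cluster moments. (Initializing covariances from the global data
covariance, a common default, spans all clusters, flattens the first E-step
responsibilities and destroys the k-means means; with cluster-moment
initialization planted well-separated states are recovered at ≥ 95% Viterbi
agreement.) The restart with the best final log-likelihood is retained —
maximum-likelihood EM with log-likelihood ranking here stands in for
variational free-energy ranking, which requires variational machinery that
is out of scope. Viterbi decoding yields mutually exclusive binary state
courses split back per subject.

Temporal metrics per state: MLT = mean maximal-run length of activation
(edge-truncated runs included) / f_s; FO = active fraction (sums to 1 across
states by exclusivity; FO = MLT·n_visits/T exactly); MIL = mean *complete*
gap between visits (edge gaps dropped; missing if no complete gap). Never
visited states report FO = 0 and missing MLT/MIL. State power maps are
partial correlations between each state's raw binary course and the demeaned
channel envelopes, controlling for the other K−1 binary courses *without an
intercept*: demeaning all K exclusive indicators would make the controls sum
to a constant and be exactly collinear, nullifying the naive recipe.

**Statistics.** Confound regression (OLS per feature; residual + intercept,
preserving the grand level) precedes testing: connectivity is adjusted for
band-specific global power, sex and acquisition system; power and HMM
metrics for sex and system only. Group effects use Kruskal–Wallis (tie
corrected; degenerate all-equal data yields H = 0, p = 1 by logged
convention) with post-hoc Tukey–Kramer on pooled midranks, rank variance
N(N+1)/12, and the studentized range distribution with k groups and infinite
error degrees of freedom — the standard normal-theory approximation for rank
post-hocs. Bonferroni factors: 3 (global), 18 (network), min(N_eff, raw) for
the connectome with N_eff = n_bands·ρ(ρ−1)/2 and ρ the numerical rank of the
mixing (leadfield stand-in) matrix, and K−1 = 7 for HMM metrics (the
exclusivity constraint removes one degree of freedom). Significance flags
are exactly p·factor < 0.05.

## Synthetic cohort

Each subject is a 32-region, 60-s, 250-Hz recording (both configurable):

    x_j(t) = Σ_b sqrt(P_b) · e_{b,j}(t) · c_{b,j}(t),   then  x ← M x,

with P_b the band power scale, c unit-variance narrowband Gaussian carriers
(filtered white noise, so Hilbert envelopes are nondegenerate), e positive
envelopes, and M an instantaneous real mixing matrix (identity + symmetric
nearest-neighbor cross-talk 0.3, full rank 32) standing in for source
leakage. Envelopes are |G| + 0.1·SD floor, where G are smooth Gaussian
processes (circular frequency-domain synthesis, band-limited below 0.5 Hz —
exactly stationary, with no filter edge transients). Because rectification
shrinks correlation (corr(|X|,|Y|) ≈ 0.60 at Gaussian ρ = 0.8), the Gaussian
correlation is chosen by numerically inverting the closed-form folded-normal
correlation so the *rectified* envelopes hit the requested target; only
non-negative targets are realizable, the natural regime for power envelopes.
A Markov chain (shared across bands within subject) multiplies region j's
envelope by 1 + g[k, j] while state k is active.

Default planted effects, chosen once for detectability at n = 15/group (the
design basis; they are not estimates of any real cohort):

* children: θ power ×2; α/β within-network envelope correlation 0.15
  (cross 0.05, pVIS 0.30);
* young adults: α/β within 0.45, cross 0.15, pVIS (V1–V1) 0.80;
* elders: as young adults except pVIS β 0.25, and the visual state's mean
  dwell halved (0.125 s vs 0.25 s);
* θ connectivity (within 0.30, cross 0.10, pVIS 0.40) identical across
  groups — maturation is planted broadly in α/β, within *and* across
  networks, mirroring the qualitative developmental pattern.
* state modulation: one activation state per network (+1.2 own nodes, −0.2
  elsewhere), one global activation state (+0.5), one quiescent state; all
  states have 0.25-s mean dwell except the elders' visual state.

Covariates are deterministic: sex alternates F/M within group; the first
half of each group is tagged `vectorview`, the rest `triux`. (At n = 2 per
group these two assignments coincide and the confound design is collinear —
the regression raises a clear error; use n ≥ 3.)

## What the generator does and does not emulate

It reproduces the statistical structure the analysis assumes — band-limited
oscillations with slow correlated envelopes, Markov-switching envelope
covariance patterns, instantaneous real mixing — and therefore validates
recovery, leakage correction, decoding and inference end to end. It does
not emulate sensor physics, 1/f background spectra, non-Gaussian artifacts,
heteroscedastic noise floors, head-size or SNR differences between age
groups, or nonstationarities other than the planted Markov switching.
Passing tests demonstrate the pipeline's correctness and sensitivity under
these idealized conditions, not effect sizes in real recordings.

## Numerical choices

* **Filtering.** Band-passes are forward-backward order-4 Butterworth
  (sosfiltfilt) with pad length ≈ 3 time constants of the slowest edge. The
  envelope low-pass is applied in the frequency domain with the
  squared-magnitude response of an order-4 Butterworth after odd-reflection
  padding: IIR recursion is numerically unreliable at the extreme normalized
  cutoffs involved (1 Hz and below at fs = 250).
* **Null bounds on envelope correlations.** A sub-1-Hz envelope carries only
  ~2BT effective samples (≈ 300 in 300 s), so a single pair's null r has
  sampling SD ≈ 0.05; null checks therefore bound the mean |r| over pairs
  and seeds (E|r| = σ√(2/π)), not each pair.
* **Leakage nulling** holds exactly for independent narrowband sources
  (unit planted envelope). With additional planted slow envelope fading,
  pairwise orthogonalization retains a genuine residual coupling (~0.2 at
  mixing 0.3) because the mixing ratio of instantaneous amplitudes
  fluctuates; this is a property of the estimator, not a bug, and it is
  group-invariant in the default cohort (same mixing for all groups).
* **EM stopping.** The pipeline default is tol = 1 (absolute log-likelihood
  gain) with max_iter = 20 and 10 restarts; with cluster-moment
  initialization the likelihood is within a fraction of a percent of its
  plateau in well under 20 iterations at the default problem size
  (~10⁵ samples × 32 PCs). `EnvelopeHMM` accepts larger budgets.
* **Degenerate inputs.** Zero-magnitude analytic samples orthogonalize to 0
  (logged above 1%); rank-deficient confound designs raise naming the
  collinear columns; n_pcs above the data rank is capped with a warning;
  covariance collapse is guarded by diagonal loading (reg_covar).
* **Problem sizes.** Default validation cohorts use 60-s recordings at
  250 Hz and n = 15/group; the HMM recovery checks use 8 states × 6 × 2500
  samples at 40 Hz; the null calibration of the omnibus test uses 5000
  features at n = 30/group. These sizes were chosen so the complete suite
  runs on a desktop in minutes while keeping every planted effect several
  sampling SDs wide.

## Known limitations

* Pairwise orthogonalization leaves "ghost" residual interactions by
  construction (it is not the symmetric multivariate scheme, which is
  deliberately out of scope); the connectome inherits its known asymmetry
  before symmetrization.
* The N_eff formula is exposed parameterized by ρ; with the default
  synthetic mixing ρ = 32, giving N_eff = 1488 = the raw band-specific
  count, so the connectome correction coincides with raw Bonferroni there.
* MIL censoring (complete gaps only) differs from MLT censoring
  (edge-truncated visits included); sequences with very few visits can make
  the FO renewal identity FO ≈ MLT/(MLT+MIL) inexact, which is why it is
  asserted only on long paths with ≥ 50 visits.
* The HMM is fitted on prewhitened PCs; state power maps are computed in
  channel space against the normalized envelopes, so map magnitudes are
  attenuated relative to the planted modulation gains and should be read as
  topographies, not effect sizes.
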