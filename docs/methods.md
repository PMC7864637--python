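# Methods

## Physical model and data model

A molecule is a set of independent *dynamic components*. Component `x` is a
continuous-time Markov chain over emissive states; state `i` has a
fluorescence lifetime `τ_xi` (ns) and a detected-photon rate `b_xi`
(counts/s). Component intensities add. The generator convention is
column-based: `K[j, i]` is the rate from state `i` to `j`, columns sum to
zero, and the propagator is `P(Δt) = exp(K Δt)` with `P[j, i] = P(j at Δt |
i at 0)`. Photon records carry a macrotime (s, since trace start) and a
microtime (ns, since the excitation pulse). Defaults mirror a standard
single-molecule TCSPC setup: 80 MHz excitation (12.5 ns period) and a
Gaussian instrument response of 380 ps FWHM.

The container format is HDF5 (one group per molecule, metadata as
attributes) with a CSV dialect for small fixtures; vendor TTTR formats are
not parsed. Times are stored as 64-bit floats so write/read round-trips are
bit-exact.

## Synthetic data: what it emulates and what it does not

`simulate_ensemble` samples each component's trajectory by Gillespie
simulation (block-vectorized for two states, where the embedded chain
alternates deterministically), draws photon times as an inhomogeneous
Poisson process over the piecewise-constant total rate, attributes each
photon to a component in proportion to its instantaneous rate, and sets its
microtime to an exponential draw at the current state's lifetime plus
Gaussian IRF jitter, wrapped modulo the excitation period (delays beyond one
period and slightly negative jittered delays are physically wrapped).
Bleaching is a single exponential time per molecule that truncates all
signal at once; background (uniform in time and microtime) continues.
Everything derives from one `numpy` Generator seeded from the config, so
identical configs reproduce identical streams.

Default study conditions: components switch between an unquenched state
(2.5 ns, brighter) and a quenched state (0.5 ns, dimmer) with
unquenched:quenched brightness 3:1 (the absolute per-state brightness of a
single complex is not known a priori; 3:1 matches the intensity gap such
states show), with a fast component (dwells of tens of µs), a slow one
(hundreds of µs) and a static one. Desk-scale ensembles used throughout the
tests are 10–20 molecules × 1.5–3 s ≈ 0.25–2.3 × 10⁶ photons; these sizes
make the full pipeline run in seconds-to-minutes while leaving all rate and
energy recoveries comfortably resolved.

Not emulated: triplet blinking, spectral diffusion, detector afterpulsing
and dead time, polarization, and TCSPC discretization (microtimes are
continuous). Passing tests therefore demonstrate correctness of the
analysis chain under the stated stochastic model, not robustness to every
instrumental artifact of real data.

## Change-point segmentation

Within a candidate segment, conditioning on the photon count and the
segment window makes null arrival times uniform order statistics, so the
max-over-photons Poisson GLRT statistic has a rate-free null distribution
depending only on the count. Thresholds are Monte-Carlo calibrated (800
null replicates per grid point, fixed internal seed) on a geometric grid of
counts and interpolated in ln n; the threshold is the nominal `1 − fp_rate`
order statistic shifted by a ~3σ Monte-Carlo margin, a deliberately
conservative choice so calibration noise cannot push the realized
false-positive rate above the nominal one (measured realized rate ≈ 2–4% at
`fp_rate = 0.05`). Candidate splits must leave at least 10 photons per
side, and segments under 20 photons are never tested. Recursion applies the
same test to both children of an accepted split. The split photon belongs
to the left segment; segment intensity is `count/duration × 0.01 s`
(counts per 10 ms). Histogram statistics bootstrap at the segment level —
the unit of the histogram — with 2.5/97.5-percentile intervals.

## MEM inversion

The decay kernel is the analytic exponential ⊗ Gaussian (exponentially
modified Gaussian via `scipy.stats.exponnorm`), integrated over histogram
bins by CDF differences and summed over periodic wraps (m = −1 … enough
that `exp(−mP/τ_max) < 10⁻⁶`); no measured-IRF deconvolution. The 1D
inversion solves

    max S(a)  subject to  χ²_red(a) ≤ target,  a ≥ 0

with Skilling entropy against a flat prior `m_k = N/n_params`, Poisson
weights `max(counts, 1)`, and a co-fitted uniform background. The
Lagrangian `χ²/2 − αS` is minimized in log-amplitude coordinates by
L-BFGS-B (convex for fixed α), and α is bisected (warm-started, up to 40
steps) until the reduced χ² sits just below the target; if even the
unregularized fit cannot reach the target, the minimum-χ² solution is
returned with its achieved value recorded, and only an unbracketable solve
raises (carrying the best iterate). The χ² target encodes the expected
misfit of the data: 1.0 for photon-counting data, near zero for noise-free
forward-model inputs (where demanding χ²_red = 1 would deliberately
under-fit and blur the solution).

Grid: 60 log-spaced lifetimes on [0.05, 10] ns. With ~10⁶ photons the MEM
peak for a single 2.5 ns lifetime localizes to one grid spacing; mixtures
of 0.5/2.5 ns resolve into two peaks with amplitude-weighted means within a
few percent.

State assignment takes peaks of the amplitude profile with prominence
≥ 5% of the maximum, at least 4 grid points apart, and with a separating
valley at least half the peak's own height — MEM solutions ring slightly
around sharp features, and sub-resolution shoulders are one state, not two.
Boundaries sit at inter-peak minima (ties to the lowest index). States are
reported in grid order here; the correlation extraction orders them by
descending mean lifetime so that state 0 is always the unquenched state.

## 2D decays and correlation extraction

`build_2dfd` counts ordered within-molecule photon pairs (earlier, later)
whose macrotime separation falls in each lag bin (searchsorted ranges per
photon), binning the two microtimes into 64 bins over the period. The lag
grid is logarithmic, 10 bins/decade by default. Bins whose true pair count
exceeds the cap (10⁶) are subsampled uniformly with replacement under the
recorded seed, and the true totals are kept for rescaling. The construction
is exact — it equals brute-force pair enumeration bin-for-bin whenever no
cap triggers (a property the tests assert on 50 simulated streams).

The 2D MEM inversion at the shortest lag fits `M ≈ P W Pᵀ` with a
non-negative symmetric lifetime-pair weight matrix `W` (upper-triangle
parameterized, off-diagonal entropy multiplicity 2) and reports the
marginal `A₀` with `g = W/(a aᵀ)`.

Correlation extraction holds the 1D distribution fixed: state decay
profiles are the kernel-projected amplitude slices (plus a flat background
profile when the 1D fit found background), and each lag's matrix is
decomposed onto symmetrized profile outer products by non-negative least
squares. Weighting is two-pass Poisson (first unweighted, then weights from
the fitted model): weighting by observed counts biases sparse short-lag
matrices low. The state-pair weights are normalized by the expected
uncorrelated pair count — per molecule, `λ̂²[(hi−lo)T − (hi²−lo²)/2]` with
`λ̂ = n/T` — and by the per-state photon fractions, so every `G_ij → 1` at
long lag. Empty lag bins are flagged missing, never interpolated.
Uncertainties combine counting noise on the (possibly subsampled) pairs
with a 1% relative systematic floor, the measured accuracy limit of
profile unmixing when the quenched and unquenched decay profiles overlap
(established against the analytic two-state oracle).

## Kinetic model and global fit

The model function is derived from first principles for independent
emitters and validated to 10⁻¹⁰ against the closed-form two-state
correlation: within-component pair rates `b_i C_i [e^{KΔT}]_{ji} b_j`,
cross-component stationary offsets `(b_i C_i)(b_j C_j)`, normalized by the
per-state total rates. A nonzero cross-correlation at ΔT → 0 is therefore
the fingerprint of multiple simultaneous components. Brightness enters only
as the product of extinction coefficient and quantum yield — the two are
not separately identifiable from one sample. Components are constrained to
equilibrium: populations are the stationary distribution of the rate
matrix, which makes the rate-ratio and population routes to ΔE* consistent
by construction. The fit is trust-region least squares on log-rates (bounds
10⁻²–10⁷ /s) and log-brightnesses, with the first component's unquenched
brightness pinned to 1 (a flat direction otherwise) and an optional global
scale; 16 seeded multi-starts guard against local minima. "Static"
components are not special-cased: their rates simply converge to the lower
bound. Component-count selection fits each candidate and takes the smallest
count whose reduced χ² is within 5% of the minimum.

## Free energies

`ΔE* = −k_B T ln(k_{Q→U}/k_{U→Q})` with `k_B = 0.6950348 cm⁻¹/K` and
T = 300 K; positive ΔE* means the quenched state is more stable. The
population route `k_B T ln(C_Q/C_U)` agrees to machine precision for
equilibrated components (asserted over 100 random generators at 10⁻⁹
cm⁻¹). Barrier heights `−k_B T ln(k/A)` use A = 1000 per rate unit with
rates expressed in 1/ms by default — the prefactor's unit is a convention,
so barriers are labeled an illustrative scaling; ΔE*, their difference, is
exactly unit- and prefactor-independent. The quenched state of a fitted
model is identified by the shorter mean lifetime; static components are
skipped with a note rather than given infinite barriers.

## Numerical choices and limitations

* Lag-bin centers are geometric means of the edges; within-bin variation of
  G is below the systematic floor at 10 bins/decade.
* Microtime binning at 64 bins/period for 2D matrices trades lifetime
  resolution against pair-count density; the 1D inversion uses 0.05 ns bins.
* The equilibrium constraint on fitted components means slow
  non-equilibrated preparations would bias populations; the alternative of
  fitting populations as free parameters is not identifiable from
  stationary correlation data alone.
* Recovery accuracy is photon-limited: at ~10⁶ photons, relaxation rates
  come back within ~20%, lifetimes within a few percent, ΔE* within ~10
  cm⁻¹ on the standard two-state conditions. Component-count selection is
  reliable at that scale for well-separated timescales (×10) but degrades
  for smaller ensembles, where the 5% parsimony margin can be crossed by
  residual unmixing systematics.
* Lifetime states above two per component are out of scope (quenched vs
  unquenched is the physical situation addressed); the global fit rejects
  data with a different state count.
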