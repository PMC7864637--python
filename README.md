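# photonflc

Photon-by-photon analysis of single-molecule fluorescence for proteins that
switch between quenched and unquenched conformations — the situation of
photosynthetic photoprotection, where a light-harvesting protein toggles
between a bright, long-lifetime state (~2.5 ns) and a dim, quenched state
(~0.5 ns) on microsecond-to-millisecond timescales. The package is written
for spectroscopists who record time-tagged photon streams (macrotime since
trace start, TCSPC microtime since the excitation pulse) and want
state-resolved kinetics and free-energy landscapes out of them, and for
method developers who need a simulator with exact ground truth to validate
such analyses.

## What it computes

**Intensity segmentation.** Photon arrival times are segmented into
constant-intensity periods by recursive binary segmentation with a Poisson
generalized likelihood-ratio test at every photon; the threshold is
Monte-Carlo calibrated so a constant-rate segment splits with probability
`fp_rate`. Per-period intensities (counts/10 ms) feed histogram statistics
with bootstrap confidence intervals.

**Lifetime distributions by MEM.** The pooled decay histogram is inverted
onto a logarithmic lifetime grid by a maximum-entropy inverse Laplace
transform: among all non-negative amplitude vectors `a` whose forward model
(exponential ⊗ Gaussian IRF, wrapped into the excitation period) matches the
data within a reduced-χ² target, the one maximizing the Shannon–Jaynes
entropy `S = Σ_k [a_k − m_k − a_k ln(a_k/m_k)]` is returned. Peaks of the
distribution define the lifetime states.

**2D fluorescence-lifetime correlation (2D-FLC).** Photon pairs separated by
a lag ΔT are binned by their two microtimes into 2D fluorescence decays; a
2D MEM inversion at the shortest lag gives the initial lifetime distribution
and pair-weight matrix, and per-lag decomposition onto the state decay
profiles yields normalized state-pair correlation functions `G_ij(ΔT)`.
These are globally fit by a multi-component kinetic model: each independent
dynamic component `x` has state brightnesses `b`, populations `C` and a
transition-rate generator `K`, and

    G_ij(ΔT) ∝ Σ_x b_xi C_xi [e^{K_x ΔT}]_{ji} b_xj
               + Σ_{x≠y} (b_xi C_xi)(b_yj C_yj),

so within-component pairs carry the relaxation dynamics while
cross-component pairs add a lag-independent offset — the signature by which
the number of simultaneous dynamic processes is counted (parsimonious
reduced-χ² selection).

**Free-energy landscapes.** Fitted rates map to an equilibrium free-energy
difference via the Arrhenius/Boltzmann relation
`ΔE* = −k_B T ln(k_{Q→U}/k_{U→Q})` at T = 300 K (equivalently from the
populations, `k_B T ln(C_Q/C_U)`), with barrier heights `−k_B T ln(k/A)`
under an assumed prefactor A = 1000 per rate unit (barriers are an
illustrative scaling; ΔE* is prefactor-independent).

**Simulator.** `photonflc.simulate` generates photon streams from
independent continuous-time-Markov components (Gillespie sampling), with
inhomogeneous-Poisson photon times, per-state exponential microtimes blurred
by the 380 ps FWHM IRF and wrapped into the 12.5 ns period of 80 MHz
excitation, uniform background, and single-step photobleaching — all with
per-photon ground-truth labels, plus brute-force and closed-form oracles.

## Worked example

`examples/lifetime_correlation_pipeline.py` simulates 10 molecules of a
two-state switcher (`k_U→Q = 2×10⁴/s`, `k_Q→U = 1×10⁴/s`) and runs the full
analysis:

```
simulated 250304 photons from 10 molecules
lifetime states: [0.5  2.49] ns
G_UU at shortest lag 2.45 (bunching above the plateau of 1)
fitted rates: k_U->Q = 1.84e+04/s, k_Q->U = 9.54e+03/s (truth 2e4, 1e4)
dE* = 137 cm^-1 (truth 145); barriers Q->U 970, U->Q 833 cm^-1
```

The MEM recovers the two lifetime states; the unquenched auto-correlation
starts at 2.45 (photon bunching from state switching) and relaxes to 1 with
rate `k_U→Q + k_Q→U`; the fitted rate ratio puts the quenched state
`k_B T ln 2 ≈ 145 cm⁻¹` below the unquenched one, recovered here to within
8 cm⁻¹ from a quarter-million photons. The other scripts in `examples/`
demonstrate stream simulation and I/O, intensity segmentation, the 1D MEM
inversion and the free-energy arithmetic individually.

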