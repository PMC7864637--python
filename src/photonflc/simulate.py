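"""Synthetic photon-stream generator with known ground truth, plus oracles.

A single molecule is modelled as a set of independent *dynamic components*,
each a continuous-time Markov chain over emissive states.  Each state has a
fluorescence lifetime (ns) and a detected-photon emission rate (counts/s); the
intensities of the components add.  Photon macrotimes follow an inhomogeneous
Poisson process whose rate is the sum of the current-state emission rates plus
a constant background; each signal photon's microtime is an exponential draw
with the emitting state's lifetime, blurred by Gaussian IRF jitter and wrapped
into one excitation period.  Photobleaching is single-step: an exponential
bleach time truncates all signal photons at once (background continues).

This emulates pulsed-excitation (80 MHz) single-molecule TCSPC acquisition of
a two-state quencher-switching emitter: an unquenched state (~2.5 ns,
brighter) and a quenched state (~0.5 ns, dimmer), with dwell times of tens to
hundreds of microseconds plus a static component.

The module also provides the independent oracles used throughout the test
suite: an analytic two-state correlation function and an exhaustive
photon-pair histogram.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io import InstrumentMeta, PhotonStream

__all__ = [
    "EmitterComponentSpec",
    "SimulationConfig",
    "GroundTruth",
    "simulate_ensemble",
    "closed_form_two_state_correlation",
    "intensity_correlation",
    "brute_force_pair_histogram",
    "stationary_distribution",
    "two_state_component",
    "default_config",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def stationary_distribution(rate_matrix: np.ndarray) -> np.ndarray:
    """Stationary distribution of a generator matrix (columns sum to zero).

    ``rate_matrix[j, i]`` is the transition rate from state i to state j.
    """
    K = np.asarray(rate_matrix, dtype=float)
    n = K.shape[0]
    if np.allclose(K, 0):
        raise ValueError("all-zero generator has no unique stationary distribution")
    if n == 2:
        k12, k21 = K[1, 0], K[0, 1]
        return np.array([k21, k12]) / (k12 + k21)
    a = np.vstack([K, np.ones(n)])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(a, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


@dataclass
class EmitterComponentSpec:
    """One independent dynamic component of a molecule.

    ``transition_rates`` follows the generator-matrix convention: entry
    ``[j, i]`` is the rate from state i to state j (off-diagonals >= 0) and
    each column sums to zero.  ``initial_distribution`` defaults to the
    stationary distribution (or uniform for an all-zero generator).
    """

    state_lifetimes_ns: np.ndarray
    state_emission_rates: np.ndarray  # detected counts/s per state
    transition_rates: np.ndarray
    initial_distribution: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.state_lifetimes_ns = np.asarray(self.state_lifetimes_ns, dtype=float)
        self.state_emission_rates = np.asarray(
            self.state_emission_rates, dtype=float
        )
        self.transition_rates = np.asarray(self.transition_rates, dtype=float)
        n = self.n_states
        if self.state_emission_rates.shape != (n,):
            raise ValueError("state_emission_rates must match state_lifetimes_ns")
        if self.transition_rates.shape != (n, n):
            raise ValueError("transition_rates must be square (n_states x n_states)")
        if np.any(self.state_lifetimes_ns <= 0):
            raise ValueError("all lifetimes must be > 0")
        if np.any(self.state_emission_rates < 0):
            raise ValueError("emission rates must be >= 0")
        off = self.transition_rates - np.diag(np.diag(self.transition_rates))
        if np.any(off < 0):
            raise ValueError("off-diagonal transition rates must be >= 0")
        col = self.transition_rates.sum(axis=0)
        if not np.allclose(col, 0.0, atol=1e-9 * max(1.0, np.abs(off).max())):
            raise ValueError("generator columns must sum to zero")
        if self.initial_distribution is None:
            if np.allclose(self.transition_rates, 0):
                self.initial_distribution = np.full(n, 1.0 / n)
            else:
                self.initial_distribution = stationary_distribution(
                    self.transition_rates
                )
        else:
            self.initial_distribution = np.asarray(
                self.initial_distribution, dtype=float
            )
            if self.initial_distribution.shape != (n,) or not np.isclose(
                self.initial_distribution.sum(), 1.0
            ):
                raise ValueError("initial_distribution must be a probability vector")

    @property
    def n_states(self) -> int:
        return int(self.state_lifetimes_ns.size)

    @property
    def is_static(self) -> bool:
        return bool(np.allclose(self.transition_rates, 0))


@dataclass
class SimulationConfig:
    components: Sequence[EmitterComponentSpec]
    n_molecules: int = 1
    trace_duration_s: float = 1.0
    bleach_rate: float = 0.0  # per molecule, 1/s
    background_rate: float = 0.0  # counts/s
    meta: InstrumentMeta = field(default_factory=InstrumentMeta)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_molecules < 1:
            raise ValueError("n_molecules must be >= 1")
        if self.trace_duration_s <= 0:
            raise ValueError("trace_duration_s must be > 0")
        if self.bleach_rate < 0 or self.background_rate < 0:
            raise ValueError("rates must be >= 0")
        if not self.components:
            raise ValueError("at least one component required")
        if all(np.all(c.state_emission_rates == 0) for c in self.components):
            raise ValueError("no emissive state")


@dataclass
class GroundTruth:
    """Per-molecule hidden trajectories and photon origins.

    ``trajectories[mol_id][c]`` is ``(entry_times_s, states)`` for component
    ``c``; entry times start at 0 and the trajectory tiles the full trace.
    ``photon_labels[mol_id]`` gives, per photon (in stream order), the index
    of the emitting component, or -1 for background.
    """

    trajectories: dict[str, list[tuple[np.ndarray, np.ndarray]]]
    bleach_times: dict[str, float]
    photon_labels: dict[str, np.ndarray]


# ---------------------------------------------------------------------------
# continuous-time Markov chain sampling (Gillespie)
# ---------------------------------------------------------------------------


def _sample_ctmc(
    spec: EmitterComponentSpec, duration: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Sample one trajectory over [0, duration]: (entry_times, states)."""
    n = spec.n_states
    K = spec.transition_rates
    exit_rates = -np.diag(K)
    s0 = int(rng.choice(n, p=spec.initial_distribution))
    if n == 1 or not np.any(exit_rates > 0):
        return np.array([0.0]), np.array([s0])
    if n == 2:
        # the embedded chain alternates deterministically; sample in blocks
        mean_dwell = np.mean(
            [1.0 / r if r > 0 else duration for r in exit_rates]
        )
        est = int(duration / max(mean_dwell, 1e-300) * 1.3) + 16
        entry = [0.0]
        states = [s0]
        t, s = 0.0, s0
        while t < duration:
            pattern = (s0 + np.arange(len(states) - 1, len(states) - 1 + est)) % 2
            with np.errstate(divide="ignore"):
                dwells = rng.exponential(size=est) / np.where(
                    exit_rates[pattern] > 0, exit_rates[pattern], np.inf
                )
            ts = t + np.cumsum(dwells)
            cut = int(np.searchsorted(ts, duration))
            new_states = (pattern[:cut] + 1) % 2
            entry.extend(ts[:cut].tolist())
            states.extend(new_states.tolist())
            if cut < est:
                break
            t = ts[-1]
            s = (pattern[-1] + 1) % 2
            if exit_rates[s] == 0:
                break
        return np.asarray(entry), np.asarray(states, dtype=np.int64)
    # generic event-by-event Gillespie for n > 2
    entry = [0.0]
    states = [s0]
    t, s = 0.0, s0
    while True:
        if exit_rates[s] <= 0:
            break
        t += rng.exponential(1.0 / exit_rates[s])
        if t >= duration:
            break
        probs = K[:, s].copy()
        probs[s] = 0.0
        probs /= probs.sum()
        s = int(rng.choice(n, p=probs))
        entry.append(t)
        states.append(s)
    return np.asarray(entry), np.asarray(states, dtype=np.int64)


def _simulate_molecule(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list, float]:
    """Return (macrotimes_s, microtimes_ns, labels, trajectories, bleach_t)."""
    duration = config.trace_duration_s
    meta = config.meta
    period = meta.excitation_period_ns
    sigma = meta.irf_fwhm_ns * _FWHM_TO_SIGMA
    n_comp = len(config.components)

    bleach_t = (
        float(rng.exponential(1.0 / config.bleach_rate))
        if config.bleach_rate > 0
        else np.inf
    )
    t_signal_end = min(duration, bleach_t)

    trajectories = [_sample_ctmc(c, duration, rng) for c in config.components]

    # breakpoints of the piecewise-constant total rate within [0, t_signal_end]
    breaks = [np.array([0.0, t_signal_end])]
    for entry, _ in trajectories:
        inside = entry[(entry > 0) & (entry < t_signal_end)]
        breaks.append(inside)
    edges = np.unique(np.concatenate(breaks))
    starts, stops = edges[:-1], edges[1:]
    lengths = stops - starts

    # state of each component on each interval
    comp_states = np.empty((starts.size, n_comp), dtype=np.int64)
    comp_rates = np.empty((starts.size, n_comp))
    for c, (entry, st) in enumerate(trajectories):
        idx = np.searchsorted(entry, starts, side="right") - 1
        comp_states[:, c] = st[idx]
        comp_rates[:, c] = config.components[c].state_emission_rates[st[idx]]

    total_rate = comp_rates.sum(axis=1)
    counts = rng.poisson(total_rate * lengths)
    n_sig = int(counts.sum())

    rep = np.repeat(np.arange(starts.size), counts)
    mac_sig = starts[rep] + rng.random(n_sig) * lengths[rep]
    # attribute each photon to a component, proportional to its current rate
    if n_sig:
        frac = comp_rates[rep] / total_rate[rep][:, None]
        cum = np.cumsum(frac, axis=1)
        u = rng.random(n_sig)
        labels_sig = (u[:, None] > cum).sum(axis=1).astype(np.int64)
        labels_sig = np.minimum(labels_sig, n_comp - 1)
        states_sig = comp_states[rep, labels_sig]
        taus = np.empty(n_sig)
        for c, spec in enumerate(config.components):
            m = labels_sig == c
            if m.any():
                taus[m] = spec.state_lifetimes_ns[states_sig[m]]
        delay = rng.exponential(taus)
        if sigma > 0:
            delay = delay + rng.normal(0.0, sigma, size=n_sig)
        mic_sig = np.mod(delay, period)
    else:
        labels_sig = np.empty(0, dtype=np.int64)
        mic_sig = np.empty(0)

    n_bg = (
        rng.poisson(config.background_rate * duration)
        if config.background_rate > 0
        else 0
    )
    mac_bg = rng.random(n_bg) * duration
    mic_bg = rng.random(n_bg) * period
    labels_bg = np.full(n_bg, -1, dtype=np.int64)

    mac = np.concatenate([mac_sig, mac_bg])
    mic = np.concatenate([mic_sig, mic_bg])
    labels = np.concatenate([labels_sig, labels_bg])
    order = np.argsort(mac, kind="stable")
    return mac[order], mic[order], labels[order], trajectories, bleach_t


def simulate_ensemble(
    config: SimulationConfig,
) -> tuple[list[PhotonStream], GroundTruth]:
    """Simulate an ensemble of molecules; deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    streams: list[PhotonStream] = []
    trajectories: dict[str, list] = {}
    bleach_times: dict[str, float] = {}
    photon_labels: dict[str, np.ndarray] = {}
    for m in range(config.n_molecules):
        mol_id = f"mol{m:04d}"
        mac, mic, labels, trajs, bleach_t = _simulate_molecule(config, rng)
        streams.append(
            PhotonStream(
                molecule_id=mol_id, macrotimes=mac, microtimes=mic, meta=config.meta
            )
        )
        trajectories[mol_id] = trajs
        bleach_times[mol_id] = bleach_t
        photon_labels[mol_id] = labels
    return streams, GroundTruth(trajectories, bleach_times, photon_labels)


# ---------------------------------------------------------------------------
# analytic two-state oracle
# ---------------------------------------------------------------------------


def closed_form_two_state_correlation(component: EmitterComponentSpec, lags):
    """Analytic state-resolved correlation of a two-state Markov emitter.

    Returns a :class:`~photonflc.correlation.CorrelationSet` whose
    ``values[t, i, j]`` is ``P(j at lag | i at 0) / p_j``; relaxation is
    single-exponential with rate k12 + k21, auto-correlations decay to 1 and
    cross-correlations rise to 1 (anti-correlated dynamics).  The state-pair
    photon fractions carry the brightness weighting (b_i * p_i).
    """
    from .correlation import CorrelationSet

    if component.n_states != 2:
        raise ValueError("closed-form correlation supports exactly 2 states")
    lags = np.asarray(lags, dtype=float)
    K = component.transition_rates
    k12, k21 = K[1, 0], K[0, 1]  # 0->1 and 1->0
    lam = k12 + k21
    if lam > 0:
        p = np.array([k21, k12]) / lam
        decay = np.exp(-lam * lags)
    else:
        p = np.asarray(component.initial_distribution, dtype=float)
        decay = np.ones_like(lags)
    if np.any(p <= 0):
        raise ValueError("degenerate populations: one state is never occupied")
    eye = np.eye(2)
    # G_ij(dT) = 1 + (delta_ij / p_j - 1) * exp(-lam dT)
    amp = eye / p[None, :] - 1.0
    values = 1.0 + decay[:, None, None] * amp[None, :, :]
    b = component.state_emission_rates
    n_state = b * p
    frac = n_state / n_state.sum() if n_state.sum() > 0 else p
    return CorrelationSet(
        lags_s=lags,
        values=values,
        sigmas=np.zeros_like(values),
        state_photon_fractions=frac,
        state_lifetimes_ns=component.state_lifetimes_ns.copy(),
    )


def intensity_correlation(component: EmitterComponentSpec, lags) -> np.ndarray:
    """Normalized photon-intensity correlation g(dT) of a two-state emitter.

    Brightness-weighted sum over state pairs of the state-resolved G; flat
    (identically 1) when the two states are equally bright, i.e. when they are
    indistinguishable by intensity.
    """
    cs = closed_form_two_state_correlation(component, lags)
    f = cs.state_photon_fractions
    return np.einsum("i,j,tij->t", f, f, cs.values)


# ---------------------------------------------------------------------------
# exhaustive pair-histogram oracle
# ---------------------------------------------------------------------------


def brute_force_pair_histogram(
    stream: PhotonStream,
    lag_bin: tuple[float, float],
    microtime_bins: np.ndarray,
) -> np.ndarray:
    """Exhaustively enumerate photon pairs with lag in ``[lo, hi)``.

    Counts every ordered pair (earlier photon, later photon) whose macrotime
    separation lies in the half-open lag interval and bins their
    (microtime_1, microtime_2); no subsampling.  Intended as the oracle for
    the production pair binning on small streams.
    """
    lo, hi = lag_bin
    if not (hi > lo >= 0):
        raise ValueError("lag interval must satisfy 0 <= lo < hi")
    edges = np.asarray(microtime_bins, dtype=float)
    nb = edges.size - 1
    mac, mic = stream.macrotimes, stream.microtimes
    n = mac.size
    if n < 2:
        return np.zeros((nb, nb), dtype=np.int64)
    dt = mac[None, :] - mac[:, None]
    ii, jj = np.nonzero((dt >= lo) & (dt < hi) & (dt > 0))
    keep = jj > ii  # ordered: earlier first (ties in macrotime excluded)
    # include equal-macrotime pairs once, earlier index first
    tie_i, tie_j = np.nonzero((dt == 0) & (lo == 0))
    if tie_i.size:
        m = tie_j > tie_i
        ii = np.concatenate([ii[keep], tie_i[m]])
        jj = np.concatenate([jj[keep], tie_j[m]])
    else:
        ii, jj = ii[keep], jj[keep]
    h, _, _ = np.histogram2d(mic[ii], mic[jj], bins=[edges, edges])
    return h.astype(np.int64)


# ---------------------------------------------------------------------------
# standard configurations
# ---------------------------------------------------------------------------


def two_state_component(
    tau_unquenched_ns: float = 2.5,
    tau_quenched_ns: float = 0.5,
    rate_unquenched: float = 3.0e4,
    rate_quenched: float = 1.0e4,
    k_u_to_q: float = 2.0e4,
    k_q_to_u: float = 1.0e4,
) -> EmitterComponentSpec:
    """Two-state switching emitter; state 0 is unquenched, state 1 quenched.

    Default brightnesses put the unquenched state at 3x the quenched one,
    consistent with the intensity gap between the states.
    """
    K = np.array([[-k_u_to_q, k_q_to_u], [k_u_to_q, -k_q_to_u]])
    return EmitterComponentSpec(
        state_lifetimes_ns=np.array([tau_unquenched_ns, tau_quenched_ns]),
        state_emission_rates=np.array([rate_unquenched, rate_quenched]),
        transition_rates=K,
    )


def static_component(
    tau_unquenched_ns: float = 2.5,
    tau_quenched_ns: float = 0.5,
    rate_unquenched: float = 3.0e4,
    rate_quenched: float = 1.0e4,
    p_unquenched: float = 0.5,
) -> EmitterComponentSpec:
    """Non-interconverting component: zero rates, fixed state mixture."""
    return EmitterComponentSpec(
        state_lifetimes_ns=np.array([tau_unquenched_ns, tau_quenched_ns]),
        state_emission_rates=np.array([rate_unquenched, rate_quenched]),
        transition_rates=np.zeros((2, 2)),
        initial_distribution=np.array([p_unquenched, 1.0 - p_unquenched]),
    )


def default_config(
    n_molecules: int = 100,
    trace_duration_s: float = 3.0,
    seed: int = 0,
    background_rate: float = 200.0,
    bleach_rate: float = 0.2,
) -> SimulationConfig:
    """Three-component default: fast (~tens of us dwells), slow (~hundreds of
    us dwells) and static, each switching between unquenched (2.5 ns) and
    quenched (0.5 ns) states."""
    fast = two_state_component(k_u_to_q=4.0e4, k_q_to_u=2.0e4)
    slow = two_state_component(
        k_u_to_q=4.0e3, k_q_to_u=2.0e3, rate_unquenched=2.0e4, rate_quenched=7.0e3
    )
    static = static_component(rate_unquenched=1.5e4, rate_quenched=5.0e3)
    return SimulationConfig(
        components=[fast, slow, static],
        n_molecules=n_molecules,
        trace_duration_s=trace_duration_s,
        bleach_rate=bleach_rate,
        background_rate=background_rate,
        meta=InstrumentMeta(),
        seed=seed,
    )
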