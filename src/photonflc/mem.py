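"""Lifetime-space inversion of TCSPC decays by the maximum-entropy method.

The microtime histogram of a pulsed-excitation measurement is a sum of
exponential decays convolved with the instrument response, wrapped into one
excitation period.  Rather than fitting a fixed number of exponentials, the
decay is inverted onto a logarithmic lifetime grid: among all non-negative
amplitude vectors whose forward model reproduces the data within a reduced
chi-square target, the one maximizing the Shannon-Jaynes entropy

    S = sum_k [ a_k - m_k - a_k ln(a_k / m_k) ]

relative to a flat prior m is returned.  The trade-off weight is tuned by
bisection so the Poisson-weighted reduced chi-square meets the target.

The same machinery inverts two-dimensional fluorescence decays (joint
microtime histograms of photon pairs separated by a lag dT) into a symmetric
non-negative lifetime-pair weight matrix, the starting point of the
lifetime-correlation analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import optimize, signal, stats

from .io import PhotonStream

__all__ = [
    "LifetimeGrid",
    "DecayHistogram",
    "LifetimeDistribution",
    "StateAssignment",
    "TwoDFDStack",
    "MEMConvergenceError",
    "decay_kernel",
    "build_decay_histogram",
    "mem_ilt_1d",
    "assign_states",
    "build_2dfd",
    "mem_ilt_2d",
    "default_lag_edges",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class LifetimeGrid:
    """Logarithmically spaced fluorescence lifetimes (ns)."""

    lifetimes_ns: np.ndarray

    def __post_init__(self) -> None:
        lt = np.asarray(self.lifetimes_ns, dtype=float)
        object.__setattr__(self, "lifetimes_ns", lt)
        if lt.ndim != 1 or lt.size < 2 or np.any(np.diff(lt) <= 0):
            raise ValueError("lifetimes must be a strictly increasing 1-D sequence")

    @classmethod
    def default(cls, n: int = 60, lo_ns: float = 0.05, hi_ns: float = 10.0):
        return cls(np.geomspace(lo_ns, hi_ns, n))

    @property
    def n(self) -> int:
        return int(self.lifetimes_ns.size)

    @property
    def log_spacing(self) -> float:
        return float(np.log(self.lifetimes_ns[1] / self.lifetimes_ns[0]))


@dataclass
class DecayHistogram:
    """Pooled microtime histogram over one excitation period."""

    bin_edges_ns: np.ndarray
    counts: np.ndarray
    irf_fwhm_ns: float
    excitation_period_ns: float

    @property
    def n_photons(self) -> int:
        return int(self.counts.sum())

    @property
    def bin_centers_ns(self) -> np.ndarray:
        return 0.5 * (self.bin_edges_ns[:-1] + self.bin_edges_ns[1:])


@dataclass
class LifetimeDistribution:
    """Non-negative amplitude over a lifetime grid (MEM inversion result)."""

    grid: LifetimeGrid
    amplitudes: np.ndarray
    chi2_reduced: float
    background: float = 0.0
    n_photons: int = 0

    def normalized(self) -> np.ndarray:
        tot = self.amplitudes.sum()
        return self.amplitudes / tot if tot > 0 else self.amplitudes


@dataclass
class StateAssignment:
    """Partition of the lifetime grid into contiguous lifetime states."""

    n_states: int
    boundaries: np.ndarray  # interior grid indices; state s = [b_{s-1}, b_s)
    mean_lifetimes_ns: np.ndarray  # amplitude-weighted, per state
    weights: np.ndarray  # total amplitude per state

    def state_slices(self, n_grid: int) -> list[slice]:
        edges = [0, *self.boundaries.tolist(), n_grid]
        return [slice(edges[s], edges[s + 1]) for s in range(self.n_states)]


@dataclass
class TwoDFDStack:
    """Two-dimensional fluorescence decays, one per lag bin.

    ``matrices[b]`` counts ordered within-molecule photon pairs (earlier,
    later) with macrotime separation in ``[lag_edges[b], lag_edges[b+1])``,
    binned by the two microtimes.  ``total_pairs`` records the true pair
    count per bin; when it exceeds the cap, pairs are subsampled uniformly
    with replacement (``used_pairs``, ``seed``).
    """

    lag_edges_s: np.ndarray
    microtime_edges_ns: np.ndarray
    matrices: np.ndarray  # (n_lags, nb, nb)
    total_pairs: np.ndarray
    used_pairs: np.ndarray
    seed: int
    irf_fwhm_ns: float
    excitation_period_ns: float
    molecule_photons: np.ndarray | None = None  # per-molecule photon counts
    molecule_durations: np.ndarray | None = None  # per-molecule trace spans (s)

    @property
    def n_lags(self) -> int:
        return int(self.lag_edges_s.size - 1)

    @property
    def lag_centers_s(self) -> np.ndarray:
        return np.sqrt(self.lag_edges_s[:-1] * self.lag_edges_s[1:])


class MEMConvergenceError(RuntimeError):
    """MEM inversion failed to converge; carries the best iterate."""

    def __init__(self, message: str, best):
        super().__init__(message)
        self.best = best


# ---------------------------------------------------------------------------
# decay kernel: bin-integrated exponential (x) Gaussian IRF, wrapped
# ---------------------------------------------------------------------------


def _emg_cdf(t: np.ndarray, tau: float, sigma: float) -> np.ndarray:
    if sigma > 0:
        return stats.exponnorm.cdf(t, tau / sigma, loc=0.0, scale=sigma)
    return stats.expon.cdf(t, scale=tau)


def decay_kernel(
    grid: LifetimeGrid,
    bin_edges_ns: np.ndarray,
    irf_fwhm_ns: float,
    excitation_period_ns: float,
) -> np.ndarray:
    """Bin probabilities ``P[b, k]`` of a photon from lifetime ``tau_k``.

    Analytic exponential (x) Gaussian kernel (the IRF is modelled as a
    Gaussian of the stated FWHM), folded into [0, period) by periodic
    summation: a delay exceeding the period wraps into the next one, and IRF
    jitter can push a delay slightly negative, which wraps to the end of the
    period.  Columns sum to ~1 over a full period.
    """
    edges = np.asarray(bin_edges_ns, dtype=float)
    sigma = irf_fwhm_ns * _FWHM_TO_SIGMA
    period = excitation_period_ns
    taus = grid.lifetimes_ns
    # enough wraps for the slowest lifetime on the grid
    m_max = int(np.ceil(16.0 * taus.max() / period)) + 1
    P = np.zeros((edges.size - 1, taus.size))
    for k, tau in enumerate(taus):
        acc = np.zeros(edges.size)
        for m in range(-1, m_max + 1):
            acc += _emg_cdf(edges + m * period, tau, sigma)
        P[:, k] = np.diff(acc)
    return np.clip(P, 0.0, None)


def build_decay_histogram(
    streams: Sequence[PhotonStream], bin_width_ns: float = 0.05
) -> DecayHistogram:
    """Pooled microtime histogram of all photons of all streams."""
    if not streams:
        raise ValueError("no streams given")
    periods = {s.meta.excitation_period_ns for s in streams}
    if len(periods) != 1:
        raise ValueError(f"mixed excitation periods: {sorted(periods)}")
    period = periods.pop()
    irf = streams[0].meta.irf_fwhm_ns
    nb = max(2, int(round(period / bin_width_ns)))
    edges = np.linspace(0.0, period, nb + 1)
    mics = np.concatenate([s.microtimes for s in streams])
    if mics.size == 0:
        raise ValueError("no photons in input streams")
    counts, _ = np.histogram(mics, bins=edges)
    return DecayHistogram(edges, counts.astype(np.int64), irf, period)


# ---------------------------------------------------------------------------
# generic MEM solver
# ---------------------------------------------------------------------------


def _solve_at_alpha(
    chi2_and_grad: Callable[[np.ndarray], tuple[float, np.ndarray]],
    u0: np.ndarray,
    alpha: float,
    prior: np.ndarray,
    mult: np.ndarray,
    maxiter: int,
) -> tuple[np.ndarray, float, bool]:
    """Minimize chi2/2 - alpha * S in log coordinates; returns (u, chi2, ok)."""

    log_prior = np.log(prior)

    def objective(u):
        a = np.exp(np.clip(u, log_prior - 60.0, log_prior + 60.0))
        chi2, g = chi2_and_grad(a)
        ent = np.sum(mult * (a - prior - a * (np.log(a) - log_prior)))
        f = 0.5 * chi2 - alpha * ent
        grad_a = 0.5 * g + alpha * mult * (np.log(a) - log_prior)
        return f, grad_a * a

    res = optimize.minimize(
        objective,
        u0,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-9},
    )
    a = np.exp(np.clip(res.x, log_prior - 60.0, log_prior + 60.0))
    chi2, _ = chi2_and_grad(a)
    return res.x, chi2, bool(res.success or res.status == 1)


def _mem_solve(
    chi2_and_grad: Callable[[np.ndarray], tuple[float, np.ndarray]],
    n_params: int,
    n_data: int,
    prior: np.ndarray,
    mult: np.ndarray,
    chi2_target: float,
    maxiter: int = 1500,
    n_bisect: int = 40,
) -> tuple[np.ndarray, float]:
    """MEM amplitude solve: max entropy s.t. reduced chi2 <= target.

    Returns (amplitudes, achieved reduced chi2).  If even the unregularized
    fit cannot reach the target, the minimum-chi2 solution is returned with
    its achieved value (recorded in the result for the caller to inspect).
    """
    target = chi2_target * n_data
    u = np.log(prior)

    # nearly unregularized fit: the attainable chi2 floor
    alpha_floor = 1e-10
    u_fit, chi2_min, _ = _solve_at_alpha(
        chi2_and_grad, u, alpha_floor, prior, mult, maxiter * 4
    )
    if chi2_min >= target:
        a = np.exp(u_fit)
        return a, chi2_min / n_data

    # bracket: grow alpha until chi2 exceeds the target
    alpha_lo, u_lo = alpha_floor, u_fit
    alpha_hi = max(chi2_min, 1.0) / max(n_params, 1)
    u_hi = u_fit
    for _ in range(80):
        u_hi, chi2_hi, _ = _solve_at_alpha(
            chi2_and_grad, u_hi, alpha_hi, prior, mult, maxiter
        )
        if chi2_hi > target:
            break
        alpha_lo, u_lo = alpha_hi, u_hi
        alpha_hi *= 8.0
    else:
        raise MEMConvergenceError(
            "could not bracket the entropy weight", np.exp(u_hi)
        )

    # bisection in log(alpha): chi2 is monotone increasing in alpha
    u_best, chi2_best = u_lo, None
    for _ in range(n_bisect):
        alpha_mid = np.sqrt(alpha_lo * alpha_hi) if alpha_lo > 0 else alpha_hi / 2
        u_mid, chi2_mid, _ = _solve_at_alpha(
            chi2_and_grad, u_best, alpha_mid, prior, mult, maxiter
        )
        if chi2_mid <= target:
            alpha_lo, u_lo = alpha_mid, u_mid
            u_best, chi2_best = u_mid, chi2_mid
        else:
            alpha_hi = alpha_mid
        if chi2_best is not None and chi2_best >= 0.995 * target:
            break
        if abs(np.log(alpha_hi / max(alpha_lo, 1e-300))) < 1e-3:
            break
    if chi2_best is None:
        u_best, chi2_best, _ = _solve_at_alpha(
            chi2_and_grad, u_lo, alpha_lo, prior, mult, maxiter
        )
    return np.exp(u_best), chi2_best / n_data


# ---------------------------------------------------------------------------
# 1D inversion
# ---------------------------------------------------------------------------


def mem_ilt_1d(
    decay: DecayHistogram,
    grid: LifetimeGrid | None = None,
    chi2_target: float = 1.0,
    fit_background: bool = True,
) -> LifetimeDistribution:
    """Invert a decay histogram into a lifetime distribution by MEM.

    A constant (microtime-uniform) background is co-fitted by default.  The
    achieved Poisson-weighted reduced chi-square is recorded; when the data
    cannot be fit to the target even without regularization, the best
    achievable fit is returned with its chi2.
    """
    if grid is None:
        grid = LifetimeGrid.default()
    counts = decay.counts.astype(float)
    if counts.sum() <= 0:
        raise ValueError("decay histogram is empty")
    nb = counts.size
    P = decay_kernel(
        grid, decay.bin_edges_ns, decay.irf_fwhm_ns, decay.excitation_period_ns
    )
    weights = np.maximum(counts, 1.0)
    n_k = grid.n
    n_params = n_k + (1 if fit_background else 0)
    total = counts.sum()

    def chi2_and_grad(a):
        amps = a[:n_k]
        mu = P @ amps
        if fit_background:
            mu = mu + a[n_k] / nb
        r = (mu - counts) / weights
        chi2 = float(np.sum(r * (mu - counts)))
        g = np.empty_like(a)
        g[:n_k] = 2.0 * (P.T @ r)
        if fit_background:
            g[n_k] = 2.0 * r.sum() / nb
        return chi2, g

    prior = np.full(n_params, total / n_params)
    if fit_background:
        prior[n_k] = max(total * 1e-3, 1.0)
    mult = np.ones(n_params)
    a, chi2_red = _mem_solve(
        chi2_and_grad, n_params, nb, prior, mult, chi2_target
    )
    return LifetimeDistribution(
        grid=grid,
        amplitudes=a[:n_k],
        chi2_reduced=float(chi2_red),
        background=float(a[n_k]) if fit_background else 0.0,
        n_photons=int(total),
    )


# ---------------------------------------------------------------------------
# state assignment
# ---------------------------------------------------------------------------


def assign_states(
    dist: LifetimeDistribution,
    rel_prominence: float = 0.05,
    min_separation: int = 4,
    min_valley_ratio: float = 0.5,
) -> StateAssignment:
    """Partition the lifetime grid into states at inter-peak minima.

    Peaks are maxima of the amplitude profile with prominence at least
    ``rel_prominence`` times the maximum amplitude, at least
    ``min_separation`` grid points apart, and separated from their
    neighbours by a valley at least ``min_valley_ratio`` of their own height
    (MEM solutions ring slightly around sharp features; shoulders and
    sub-resolution double peaks are one state).  The boundary between two
    consecutive peaks is the minimum between them (ties broken by the lowest
    index).  Each state's amplitude-weighted mean lifetime is reported.
    """
    a = np.asarray(dist.amplitudes, dtype=float)
    if not np.any(a > 0):
        raise ValueError("all-zero lifetime distribution")
    padded = np.concatenate([[0.0], a, [0.0]])
    peaks, props = signal.find_peaks(
        padded, prominence=rel_prominence * a.max(), distance=min_separation
    )
    keep = props["prominences"] >= min_valley_ratio * padded[peaks]
    peaks = peaks[keep] - 1
    if peaks.size == 0:
        peaks = np.array([int(np.argmax(a))])
    boundaries = []
    for p, q in zip(peaks[:-1], peaks[1:]):
        inner = a[p + 1 : q]
        boundaries.append(p + 1 + int(np.argmin(inner)))
    boundaries = np.asarray(boundaries, dtype=int)
    taus = dist.grid.lifetimes_ns
    edges = [0, *boundaries.tolist(), a.size]
    means, weights = [], []
    for s in range(len(edges) - 1):
        sl = slice(edges[s], edges[s + 1])
        w = a[sl].sum()
        means.append(float(np.sum(a[sl] * taus[sl]) / w) if w > 0 else float("nan"))
        weights.append(float(w))
    return StateAssignment(
        n_states=len(edges) - 1,
        boundaries=boundaries,
        mean_lifetimes_ns=np.asarray(means),
        weights=np.asarray(weights),
    )


# ---------------------------------------------------------------------------
# 2D fluorescence decays
# ---------------------------------------------------------------------------


def default_lag_edges(
    lo_s: float = 1e-4, hi_s: float = 10.0, per_decade: int = 10
) -> np.ndarray:
    """Logarithmic lag-bin edges, ``per_decade`` bins per decade."""
    n = int(round(np.log10(hi_s / lo_s) * per_decade))
    return np.geomspace(lo_s, hi_s, n + 1)


def _pair_ranges(mac: np.ndarray, lo: float, hi: float):
    """Partner index range [j0, j1) per photon for lags in [lo, hi)."""
    j0 = np.searchsorted(mac, mac + lo, side="left")
    j0 = np.maximum(j0, np.arange(mac.size) + 1)  # ordered pairs only
    j1 = np.searchsorted(mac, mac + hi, side="left")
    j1 = np.maximum(j1, j0)
    return j0, j1


def build_2dfd(
    streams: Sequence[PhotonStream],
    lag_edges_s: np.ndarray | None = None,
    microtime_bins: int = 64,
    max_pairs_per_bin: int = 1_000_000,
    seed: int = 0,
) -> TwoDFDStack:
    """Construct the stack of 2D fluorescence decays over a lag grid.

    Per lag bin, all ordered within-molecule photon pairs with macrotime
    separation inside the bin are counted; when a bin's pair count exceeds
    ``max_pairs_per_bin``, pairs are subsampled uniformly with replacement
    (seeded), and the true total is recorded.  Agrees exactly with the
    exhaustive pair enumeration when no subsampling triggers.
    """
    if not streams:
        raise ValueError("no streams given")
    periods = {s.meta.excitation_period_ns for s in streams}
    if len(periods) != 1:
        raise ValueError(f"mixed excitation periods: {sorted(periods)}")
    period = periods.pop()
    if lag_edges_s is None:
        lag_edges_s = default_lag_edges()
    lag_edges_s = np.asarray(lag_edges_s, dtype=float)
    if np.any(np.diff(lag_edges_s) <= 0) or lag_edges_s[0] < 0:
        raise ValueError("lag edges must be non-negative and increasing")
    rng = np.random.default_rng(seed)
    nb = int(microtime_bins)
    mic_edges = np.linspace(0.0, period, nb + 1)
    n_lags = lag_edges_s.size - 1
    matrices = np.zeros((n_lags, nb, nb), dtype=np.int64)
    total_pairs = np.zeros(n_lags, dtype=np.int64)
    used_pairs = np.zeros(n_lags, dtype=np.int64)

    macs = [np.asarray(s.macrotimes) for s in streams]
    mics = [np.asarray(s.microtimes) for s in streams]

    for b in range(n_lags):
        lo, hi = lag_edges_s[b], lag_edges_s[b + 1]
        ranges = [_pair_ranges(m, lo, hi) for m in macs]
        counts_per_mol = np.array(
            [int((j1 - j0).sum()) for j0, j1 in ranges], dtype=np.int64
        )
        n_b = int(counts_per_mol.sum())
        total_pairs[b] = n_b
        if n_b == 0:
            continue
        if n_b <= max_pairs_per_bin:
            used_pairs[b] = n_b
            for (j0, j1), mic in zip(ranges, mics):
                c = j1 - j0
                tot = int(c.sum())
                if tot == 0:
                    continue
                i = np.repeat(np.arange(c.size), c)
                offs = np.arange(tot) - np.repeat(np.cumsum(c) - c, c)
                j = j0[i] + offs
                h, _, _ = np.histogram2d(mic[i], mic[j], bins=[mic_edges, mic_edges])
                matrices[b] += h.astype(np.int64)
        else:
            used_pairs[b] = max_pairs_per_bin
            cum_mol = np.cumsum(counts_per_mol)
            r = np.sort(rng.integers(0, n_b, size=max_pairs_per_bin))
            mol_idx = np.searchsorted(cum_mol, r, side="right")
            for m_i in np.unique(mol_idx):
                sel = r[mol_idx == m_i] - (cum_mol[m_i] - counts_per_mol[m_i])
                j0, j1 = ranges[m_i]
                c = j1 - j0
                cum = np.cumsum(c)
                i = np.searchsorted(cum, sel, side="right")
                offs = sel - (cum[i] - c[i])
                j = j0[i] + offs
                mic = mics[m_i]
                h, _, _ = np.histogram2d(mic[i], mic[j], bins=[mic_edges, mic_edges])
                matrices[b] += h.astype(np.int64)

    if total_pairs.sum() == 0:
        empty = [
            f"[{lag_edges_s[b]:g}, {lag_edges_s[b+1]:g}) s" for b in range(n_lags)
        ]
        raise ValueError("no photon pairs in any lag bin: " + ", ".join(empty))
    irf = streams[0].meta.irf_fwhm_ns
    return TwoDFDStack(
        lag_edges_s=lag_edges_s,
        microtime_edges_ns=mic_edges,
        matrices=matrices,
        total_pairs=total_pairs,
        used_pairs=used_pairs,
        seed=seed,
        irf_fwhm_ns=irf,
        excitation_period_ns=period,
        molecule_photons=np.array([s.n_photons for s in streams]),
        molecule_durations=np.array([s.duration_s for s in streams]),
    )


# ---------------------------------------------------------------------------
# 2D inversion at the shortest lag
# ---------------------------------------------------------------------------


def mem_ilt_2d(
    stack: TwoDFDStack,
    grid: LifetimeGrid | None = None,
    chi2_target: float = 1.0,
) -> tuple[LifetimeDistribution, np.ndarray]:
    """Invert the shortest-lag 2D decay into (A0, G0).

    Fits ``M(t1, t2) ~ sum_kl a_k g_kl a_l K_k(t1) K_l(t2)`` with a
    non-negative symmetric lifetime-pair weight matrix W = a g a by MEM;
    returns the marginal amplitude distribution A0 (``a_k = sum_l W_kl``,
    scaled so that ``outer(a, a)`` matches W for separable input) and the
    normalized pair-weight matrix ``g = W / (a a^T)``.
    """
    if grid is None:
        grid = LifetimeGrid.default()
    M = stack.matrices[0].astype(float)
    if M.sum() <= 0:
        raise ValueError("shortest-lag 2D decay is empty")
    nb = M.shape[0]
    P = decay_kernel(
        grid, stack.microtime_edges_ns, stack.irf_fwhm_ns, stack.excitation_period_ns
    )
    weights = np.maximum(M, 1.0)
    K = grid.n
    iu, ju = np.triu_indices(K)
    n_params = iu.size
    mult = np.where(iu == ju, 1.0, 2.0)
    total = M.sum()

    def expand(w):
        W = np.zeros((K, K))
        W[iu, ju] = w
        W[ju, iu] = w
        return W

    def chi2_and_grad(w):
        W = expand(w)
        mu = P @ W @ P.T
        r = (mu - M) / weights
        chi2 = float(np.sum(r * (mu - M)))
        G = P.T @ r @ P  # dchi2/dW (full), symmetric up to noise
        G = G + G.T
        g = G[iu, ju]  # combines the two symmetric entries for off-diagonals
        g[iu == ju] *= 0.5
        return chi2, 2.0 * g

    prior = np.full(n_params, total / (K * K))
    w, chi2_red = _mem_solve(
        chi2_and_grad, n_params, nb * nb, prior, mult, chi2_target
    )
    W = expand(w)
    marg = W.sum(axis=1)
    a = marg / np.sqrt(W.sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        g = W / np.outer(a, a)
    g[~np.isfinite(g)] = 0.0
    A0 = LifetimeDistribution(
        grid=grid,
        amplitudes=a,
        chi2_reduced=float(chi2_red),
        background=0.0,
        n_photons=int(total),
    )
    return A0, g
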