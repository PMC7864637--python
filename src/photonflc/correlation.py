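"""State-pair lifetime correlations and the multi-component kinetic model.

The 2D fluorescence-decay stack resolves, at every lag dT, how photon pairs
distribute over lifetime states.  Holding the lifetime distribution fixed,
each lag's 2D matrix is decomposed onto state decay profiles, yielding
normalized state-pair correlation functions G_ij(dT): auto-correlations decay
from their short-lag bunching amplitude to 1, cross-correlations rise to 1
for anti-correlated two-state switching.

The model function treats a molecule as a set of independent dynamic
components, each with state brightnesses (the product of extinction
coefficient and quantum yield), state populations and a transition-rate
matrix.  Pairs within one component carry that component's relaxation
dynamics through the propagator exp(K dT); pairs across two independent
components contribute a stationary, lag-independent term — which is why the
presence of several components shows up as a nonzero cross-correlation
offset at short lag.  Formally, with per-state emission rates
``n_i = sum_x b_xi C_xi``:

    G_ij(dT) = scale * [ sum_x b_xi C_xi [e^{K_x dT}]_{ji} b_xj
                         + sum_{x != y} (b_xi C_xi)(b_yj C_yj) ] / (n_i n_j)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import linalg, optimize

from .mem import LifetimeDistribution, StateAssignment, TwoDFDStack, decay_kernel
from .simulate import stationary_distribution

__all__ = [
    "CorrelationSet",
    "KineticComponent",
    "FLCModel",
    "extract_correlations",
    "model_correlation",
    "fit_global_model",
    "select_component_count",
]

_RATE_LO, _RATE_HI = 1e-2, 1e7  # 1/s bounds for fitted transition rates


@dataclass
class CorrelationSet:
    """Normalized state-pair correlation curves over a lag grid."""

    lags_s: np.ndarray  # (T,)
    values: np.ndarray  # (T, S, S)
    sigmas: np.ndarray  # (T, S, S)
    state_photon_fractions: np.ndarray  # (S,)
    missing: np.ndarray | None = None  # (T,) bool
    state_lifetimes_ns: np.ndarray | None = None  # (S,) mean lifetime per state

    def __post_init__(self) -> None:
        self.lags_s = np.asarray(self.lags_s, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.sigmas = np.asarray(self.sigmas, dtype=float)
        if self.missing is None:
            self.missing = np.zeros(self.lags_s.size, dtype=bool)

    @property
    def n_states(self) -> int:
        return int(self.values.shape[1])


@dataclass
class KineticComponent:
    """One independent dynamic component of the kinetic model.

    ``brightness[i]`` is the product of extinction coefficient and quantum
    yield of state i (relative units; the two are not separately identifiable
    from one sample).  ``rate_matrix`` uses the generator convention (entry
    [j, i] = rate i -> j, columns sum to zero).  When ``equilibrated`` (the
    default), populations are the stationary distribution of the generator;
    a static component (all-zero generator) keeps its explicit populations.
    """

    brightness: np.ndarray
    rate_matrix: np.ndarray
    populations: np.ndarray | None = None
    equilibrated: bool = True

    def __post_init__(self) -> None:
        self.brightness = np.asarray(self.brightness, dtype=float)
        self.rate_matrix = np.asarray(self.rate_matrix, dtype=float)
        n = self.brightness.size
        if self.rate_matrix.shape != (n, n):
            raise ValueError("rate_matrix must be square and match brightness")
        if np.any(self.brightness < 0):
            raise ValueError("brightness must be >= 0")
        off = self.rate_matrix - np.diag(np.diag(self.rate_matrix))
        if np.any(off < 0):
            raise ValueError("off-diagonal rates must be >= 0")
        scale = max(1.0, np.abs(off).max())
        if not np.allclose(self.rate_matrix.sum(axis=0), 0.0, atol=1e-9 * scale):
            raise ValueError("rate_matrix columns must sum to zero (generator)")
        if self.is_static:
            if self.populations is None:
                self.populations = np.full(n, 1.0 / n)
        elif self.equilibrated or self.populations is None:
            self.populations = stationary_distribution(self.rate_matrix)
        self.populations = np.asarray(self.populations, dtype=float)
        if not np.isclose(self.populations.sum(), 1.0):
            raise ValueError("populations must sum to 1")

    @property
    def n_states(self) -> int:
        return int(self.brightness.size)

    @property
    def is_static(self) -> bool:
        return bool(np.allclose(self.rate_matrix, 0))

    def propagator(self, dt: float) -> np.ndarray:
        """P[j, i] = P(state j at dt | state i at 0)."""
        if self.is_static:
            return np.eye(self.n_states)
        if self.n_states == 2:
            k12, k21 = self.rate_matrix[1, 0], self.rate_matrix[0, 1]
            lam = k12 + k21
            p = np.array([k21, k12]) / lam
            e = np.exp(-lam * dt)
            return p[:, None] + (np.eye(2) - p[:, None]) * e
        return linalg.expm(self.rate_matrix * dt)


@dataclass
class FLCModel:
    """Fitted multi-component kinetic model with diagnostics."""

    components: list[KineticComponent]
    scale: float = 1.0
    chi2_reduced: float | None = None
    n_data: int = 0
    n_free: int = 0
    state_lifetimes_ns: np.ndarray | None = None  # mean lifetime per state

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be > 0")
        sizes = {c.n_states for c in self.components}
        if len(sizes) > 1:
            raise ValueError("all components must share the state count")

    @property
    def n_states(self) -> int:
        return self.components[0].n_states

    def state_rates(self) -> np.ndarray:
        """Per-state photon rates n_i = sum_x b_xi C_xi (relative units)."""
        return np.sum(
            [c.brightness * c.populations for c in self.components], axis=0
        )


def model_correlation(model: FLCModel, lags_s: Sequence[float]) -> CorrelationSet:
    """Evaluate the multi-component correlation model on a lag grid.

    Within-component pairs carry the propagator dynamics; cross-component
    pairs contribute the stationary offset, constant in lag.  Deterministic;
    exactly reproduces the analytic two-state correlation for a single
    two-state component.
    """
    lags = np.asarray(lags_s, dtype=float)
    S = model.n_states
    n = model.state_rates()
    if np.any(n <= 0):
        raise ValueError("every state needs nonzero total brightness")
    bc = np.array([c.brightness * c.populations for c in model.components])
    cross = np.outer(n, n) - np.einsum("xi,xj->ij", bc, bc)
    within = np.zeros((lags.size, S, S))
    for x, comp in enumerate(model.components):
        if comp.is_static:
            P_T = np.broadcast_to(np.eye(S), (lags.size, S, S))
        elif S == 2:
            k12, k21 = comp.rate_matrix[1, 0], comp.rate_matrix[0, 1]
            lam = k12 + k21
            p = np.array([k21, k12]) / lam
            e = np.exp(-lam * lags)[:, None, None]
            P_T = (p[:, None] + (np.eye(2) - p[:, None]) * e).transpose(0, 2, 1)
        else:
            P_T = np.stack(
                [comp.propagator(dt).T for dt in lags], axis=0
            )
        # pair rate (i first, j later): b_i C_i P[j,i] b_j
        within += bc[x][None, :, None] * P_T * comp.brightness[None, None, :]
    values = model.scale * (within + cross[None]) / np.outer(n, n)[None]
    return CorrelationSet(
        lags_s=lags,
        values=values,
        sigmas=np.zeros_like(values),
        state_photon_fractions=n / n.sum(),
    )


# ---------------------------------------------------------------------------
# correlation extraction from a 2D-FD stack
# ---------------------------------------------------------------------------


def extract_correlations(
    stack: TwoDFDStack,
    A: LifetimeDistribution,
    states: StateAssignment,
    systematic_fraction: float = 0.01,
) -> CorrelationSet:
    """Decompose each lag's 2D decay onto state profiles; normalize to G.

    The lifetime distribution A is held fixed: state decay profiles are built
    from its amplitudes within each state's grid slice (plus a flat profile
    for the fitted background), and each lag's matrix is fit by non-negative
    least squares with the state-pair weights free.  The weights are
    normalized by the expected uncorrelated pair count and the per-state
    photon fractions, so G tends to 1 at long lag.  Lag bins without pairs
    are flagged missing, not interpolated.

    Reported uncertainties combine counting noise with a relative systematic
    floor (``systematic_fraction``, default 1%) reflecting the accuracy limit
    of the state-profile unmixing when the state decay profiles overlap.

    States are ordered by descending mean lifetime: state 0 is the unquenched
    (long-lifetime) state, the last state the most quenched.
    """
    grid = A.grid
    P = decay_kernel(
        grid, stack.microtime_edges_ns, stack.irf_fwhm_ns, stack.excitation_period_ns
    )
    nb = stack.microtime_edges_ns.size - 1
    S = states.n_states
    profiles = []
    fracs = []
    total_amp = A.amplitudes.sum() + A.background
    for sl in states.state_slices(grid.n):
        prof = P[:, sl] @ A.amplitudes[sl]
        w = A.amplitudes[sl].sum()
        profiles.append(prof / max(prof.sum(), 1e-300))
        fracs.append(w / total_amp)
    # unquenched (longest-lifetime) state first
    order = np.argsort(states.mean_lifetimes_ns)[::-1]
    profiles = [profiles[s] for s in order]
    fracs = [fracs[s] for s in order]
    state_lifetimes = states.mean_lifetimes_ns[order]
    has_bg = A.background > 1e-6 * total_amp
    if has_bg:
        profiles.append(np.full(nb, 1.0 / nb))
        fracs.append(A.background / total_amp)
    D = np.stack(profiles, axis=1)  # (nb, S[+1]) column-normalized profiles
    fracs = np.asarray(fracs)
    n_src = D.shape[1]

    # basis of symmetrized outer products, flattened
    pairs = [(a, b) for a in range(n_src) for b in range(a, n_src)]
    basis = np.stack(
        [
            (np.outer(D[:, a], D[:, b]) + np.outer(D[:, b], D[:, a])).ravel()
            / (2.0 if a == b else 1.0)
            for a, b in pairs
        ],
        axis=1,
    )

    if stack.molecule_photons is None or stack.molecule_durations is None:
        raise ValueError("stack lacks per-molecule bookkeeping for normalization")
    n_m = np.asarray(stack.molecule_photons, dtype=float)
    T_m = np.asarray(stack.molecule_durations, dtype=float)
    ok = T_m > 0
    lam = np.where(ok, n_m / np.where(ok, T_m, 1.0), 0.0)

    n_lags = stack.n_lags
    values = np.full((n_lags, S, S), np.nan)
    sigmas = np.full((n_lags, S, S), np.nan)
    missing = np.zeros(n_lags, dtype=bool)
    for b in range(n_lags):
        if stack.total_pairs[b] == 0:
            missing[b] = True
            continue
        lo, hi = stack.lag_edges_s[b], stack.lag_edges_s[b + 1]
        lo_c = np.minimum(lo, T_m)
        hi_c = np.minimum(hi, T_m)
        # expected pairs per molecule under no correlation:
        # lam^2 * integral_lo^hi (T - u) du over the attainable lags
        n_exp = float(
            np.sum(lam**2 * ((hi_c - lo_c) * T_m - 0.5 * (hi_c**2 - lo_c**2)))
        )
        if n_exp <= 0:
            missing[b] = True
            continue
        M = stack.matrices[b].astype(float)
        scale_up = stack.total_pairs[b] / max(stack.used_pairs[b], 1)
        # two-pass Poisson weighting: weights from the fitted model, not the
        # observed counts (data-estimated weights bias sparse bins low)
        H, _ = optimize.nnls(basis, M.ravel())
        mu = basis @ H
        wgt = 1.0 / np.sqrt(np.maximum(mu, 1.0))
        H, _ = optimize.nnls(basis * wgt[:, None], M.ravel() * wgt)
        H = H * scale_up
        Hmat = np.zeros((n_src, n_src))
        for (a, c), h in zip(pairs, H):
            Hmat[a, c] = Hmat[c, a] = h
        denom = n_exp * np.outer(fracs, fracs)
        G_full = Hmat / denom
        values[b] = G_full[:S, :S]
        # counting-noise propagation from the (possibly subsampled) pairs
        # counting noise on the (possibly subsampled) observed pairs; the
        # floor is the G-value a single observed count would produce
        eff = Hmat[:S, :S] / max(scale_up, 1.0)
        one_count = scale_up / denom[:S, :S]
        stat = np.maximum(G_full[:S, :S] / np.sqrt(np.maximum(eff, 1.0)), one_count)
        syst = systematic_fraction * np.abs(G_full[:S, :S])
        sigmas[b] = np.hypot(stat, syst)
    frac_states = fracs[:S] / fracs[:S].sum()
    return CorrelationSet(
        lags_s=stack.lag_centers_s,
        values=values,
        sigmas=sigmas,
        state_photon_fractions=frac_states,
        missing=missing,
        state_lifetimes_ns=state_lifetimes,
    )


# ---------------------------------------------------------------------------
# global fitting
# ---------------------------------------------------------------------------


def _pack(model: FLCModel, fit_scale: bool) -> np.ndarray:
    x = []
    for c_i, c in enumerate(model.components):
        b = c.brightness
        if c_i == 0:
            x.append(np.log(max(b[1] / max(b[0], 1e-12), 1e-6)))
        else:
            x.extend(np.log(np.maximum(b, 1e-12)))
        k12 = max(c.rate_matrix[1, 0], _RATE_LO)
        k21 = max(c.rate_matrix[0, 1], _RATE_LO)
        x.extend([np.log(k12), np.log(k21)])
    if fit_scale:
        x.append(np.log(model.scale))
    return np.asarray(x)


def _unpack(
    x: np.ndarray, n_components: int, fit_scale: bool
) -> FLCModel:
    comps = []
    i = 0
    for c_i in range(n_components):
        if c_i == 0:
            b = np.array([1.0, np.exp(x[i])])
            i += 1
        else:
            b = np.exp(x[i : i + 2])
            i += 2
        k12, k21 = np.exp(x[i : i + 2])
        i += 2
        K = np.array([[-k12, k21], [k12, -k21]])
        comps.append(KineticComponent(brightness=b, rate_matrix=K))
    scale = float(np.exp(x[i])) if fit_scale else 1.0
    return FLCModel(components=comps, scale=scale)


def _residuals(
    x: np.ndarray,
    data: CorrelationSet,
    n_components: int,
    fit_scale: bool,
) -> np.ndarray:
    model = _unpack(x, n_components, fit_scale)
    keep = ~data.missing
    pred = model_correlation(model, data.lags_s[keep]).values
    obs = data.values[keep]
    sig = np.maximum(data.sigmas[keep], 1e-6)
    iu = np.triu_indices(data.n_states)
    return ((pred - obs) / sig)[:, iu[0], iu[1]].ravel()


def fit_global_model(
    data: CorrelationSet,
    n_components: int,
    init: FLCModel | None = None,
    seed: int = 0,
    n_starts: int = 16,
    fit_scale: bool = True,
) -> FLCModel:
    """Globally fit all auto- and cross-correlation curves.

    Trust-region least squares weighted by the correlation uncertainties,
    with seeded multi-start initialization; rates stay positive through a
    log parameterization and populations are the stationary distribution of
    each component's generator (equilibrium constraint).  Two lifetime
    states per component.
    """
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    if data.missing.all():
        raise ValueError("all lag bins are missing")
    if data.n_states != 2:
        raise ValueError("global fit supports two lifetime states")
    rng = np.random.default_rng(seed)
    lo_lag = float(np.min(data.lags_s))
    hi_lag = float(np.max(data.lags_s))
    rate_lo = max(_RATE_LO, 0.01 / hi_lag)
    rate_hi = min(_RATE_HI, 100.0 / lo_lag)

    n_free = (1 + 2 * (n_components - 1)) + 2 * n_components + (1 if fit_scale else 0)
    lb = np.full(n_free, -np.inf)
    ub = np.full(n_free, np.inf)
    i = 0
    for c_i in range(n_components):
        nb_ = 1 if c_i == 0 else 2
        lb[i : i + nb_] = np.log(1e-4)
        ub[i : i + nb_] = np.log(1e4)
        i += nb_
        lb[i : i + 2] = np.log(_RATE_LO)
        ub[i : i + 2] = np.log(_RATE_HI)
        i += 2
    if fit_scale:
        lb[i], ub[i] = np.log(0.2), np.log(5.0)

    starts: list[np.ndarray] = []
    if init is not None:
        starts.append(_pack(init, fit_scale))
    while len(starts) < n_starts:
        x0 = np.empty(n_free)
        j = 0
        for c_i in range(n_components):
            nb_ = 1 if c_i == 0 else 2
            x0[j : j + nb_] = rng.uniform(np.log(0.1), np.log(10.0), nb_)
            j += nb_
            x0[j : j + 2] = rng.uniform(np.log(rate_lo), np.log(rate_hi), 2)
            j += 2
        if fit_scale:
            x0[j] = 0.0
        starts.append(x0)

    best = None
    for x0 in starts:
        try:
            res = optimize.least_squares(
                _residuals,
                np.clip(x0, lb + 1e-9, ub - 1e-9),
                args=(data, n_components, fit_scale),
                bounds=(lb, ub),
                method="trf",
                x_scale="jac",
                max_nfev=400 * n_free,
            )
        except (ValueError, FloatingPointError):
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError("global fit failed from every start")
    model = _unpack(best.x, n_components, fit_scale)
    n_data = best.fun.size
    dof = max(n_data - n_free, 1)
    model.chi2_reduced = float(2.0 * best.cost / dof)
    model.n_data = n_data
    model.n_free = n_free
    model.state_lifetimes_ns = data.state_lifetimes_ns
    return model


def select_component_count(
    data: CorrelationSet,
    candidates: Sequence[int] = (1, 2, 3),
    seed: int = 0,
    rel_tolerance: float = 0.05,
    **fit_kwargs,
) -> tuple[int, dict[int, FLCModel]]:
    """Fit each candidate component count; select by parsimony.

    The smallest count whose reduced chi-square is within ``rel_tolerance``
    of the minimum across candidates is returned, together with every fit.
    """
    if not candidates:
        raise ValueError("candidates must be non-empty")
    fits: dict[int, FLCModel] = {}
    for n_c in candidates:
        fits[n_c] = fit_global_model(data, n_c, seed=seed, **fit_kwargs)
    best_chi2 = min(f.chi2_reduced for f in fits.values())
    for n_c in sorted(fits):
        if fits[n_c].chi2_reduced <= best_chi2 * (1.0 + rel_tolerance):
            return n_c, fits
    return max(fits), fits  # unreachable; defensive
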