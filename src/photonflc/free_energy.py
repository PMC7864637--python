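"""Arrhenius free-energy landscapes from fitted rates and populations.

The transition rates of a two-state (quenched Q / unquenched U) component are
related to activation barriers by the Arrhenius law,

    k_{Q->U} = A exp(-E*_{Q->U} / kB T),    k_{U->Q} = A exp(-E*_{U->Q} / kB T),

so at equilibrium the free-energy difference between the states follows from
the rate ratio, k_{Q->U} / k_{U->Q} = exp(-dE* / kB T), or equivalently from
the Boltzmann populations.  dE* is independent of the unknown prefactor A and
of the rate unit; the absolute barrier heights are not — they are an
illustrative scaling tied to the choice A = 1000 per rate unit (rates are
expressed in 1/ms by default, placing barriers in the high hundreds of cm^-1
for dynamics on tens to hundreds of microseconds).

Sign convention: dE* = E_U - E_Q > 0 means the quenched state is the more
stable (lower) one.  Energies are in cm^-1 at T = 300 K by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .correlation import FLCModel, KineticComponent

__all__ = [
    "ThermoConstants",
    "FreeEnergyLandscape",
    "delta_e_star",
    "delta_e_star_from_populations",
    "barrier_height",
    "build_landscapes",
]

#: Boltzmann constant in cm^-1 / K.
KB_CM1_PER_K = 0.6950348


@dataclass(frozen=True)
class ThermoConstants:
    """Temperature, Boltzmann constant and Arrhenius prefactor.

    ``arrhenius_prefactor`` is dimensionless relative to ``rate_unit`` (1/s
    per unit); the default pairs A = 1000 with rates in 1/ms.  dE* never
    depends on either choice — only the illustrative barrier heights do.
    """

    kB: float = KB_CM1_PER_K
    T: float = 300.0
    arrhenius_prefactor: float = 1000.0
    rate_unit: float = 1e-3  # seconds per rate unit: 1e-3 -> rates in 1/ms

    def __post_init__(self) -> None:
        if self.T <= 0 or self.kB <= 0 or self.arrhenius_prefactor <= 0:
            raise ValueError("T, kB and prefactor must be > 0")

    @property
    def kBT(self) -> float:
        return self.kB * self.T


@dataclass
class FreeEnergyLandscape:
    """Per-component free-energy summary (cm^-1).

    ``delta_e_star`` follows the E_U - E_Q convention (positive when the
    quenched state is more stable); the barrier difference identity
    ``delta_e_star == barrier_q_to_u - barrier_u_to_q`` holds exactly.
    """

    component: int
    delta_e_star: float
    barrier_q_to_u: float
    barrier_u_to_q: float
    delta_e_star_from_populations: float | None = None
    source: str = "rates"

    @property
    def discrepancy(self) -> float | None:
        if self.delta_e_star_from_populations is None:
            return None
        return self.delta_e_star - self.delta_e_star_from_populations


def delta_e_star(
    k_q_to_u: float, k_u_to_q: float, constants: ThermoConstants | None = None
) -> float:
    """Equilibrium free-energy difference (cm^-1) from the rate ratio.

    -kB T ln(k_{Q->U} / k_{U->Q}); positive when the quenched state is lower
    in free energy.  Independent of the rate unit and of the prefactor.
    """
    c = constants or ThermoConstants()
    if k_q_to_u <= 0 or k_u_to_q <= 0:
        raise ValueError("both rates must be > 0")
    return float(-c.kBT * np.log(k_q_to_u / k_u_to_q))


def delta_e_star_from_populations(
    c_q: float, c_u: float, constants: ThermoConstants | None = None
) -> float:
    """Free-energy difference (cm^-1) from Boltzmann state populations.

    kB T ln(C_Q / C_U); equals :func:`delta_e_star` exactly when the
    populations are the stationary distribution of the rate matrix.
    """
    c = constants or ThermoConstants()
    if not (0.0 < c_q < 1.0 and 0.0 < c_u < 1.0):
        raise ValueError("populations must lie strictly inside (0, 1)")
    return float(c.kBT * np.log(c_q / c_u))


def barrier_height(k: float, constants: ThermoConstants | None = None) -> float:
    """Activation barrier (cm^-1) from an Arrhenius rate: -kB T ln(k / A).

    ``k`` is in 1/s and is converted to the constants' rate unit before the
    prefactor comparison; the result is an illustrative scaling that depends
    on the assumed prefactor.
    """
    c = constants or ThermoConstants()
    if k <= 0:
        raise ValueError("rate must be > 0")
    k_in_unit = k * c.rate_unit
    return float(-c.kBT * np.log(k_in_unit / c.arrhenius_prefactor))


def build_landscapes(
    model: FLCModel,
    constants: ThermoConstants | None = None,
    quenched_state: int | None = None,
) -> list[FreeEnergyLandscape]:
    """One landscape per dynamic component of a fitted model.

    The quenched state is the one with the shorter mean lifetime when the
    model carries state lifetimes; otherwise state 1 is taken as quenched
    (the convention of models fitted from data, where state 0 is the
    unquenched, long-lifetime state) unless ``quenched_state`` overrides it.
    dE* is computed both from the rate ratio and from the populations, with
    the discrepancy reported; static components are skipped.
    """
    c = constants or ThermoConstants()
    if quenched_state is None:
        if model.state_lifetimes_ns is not None:
            quenched_state = int(np.argmin(model.state_lifetimes_ns))
        else:
            quenched_state = 1
    q, u = quenched_state, 1 - quenched_state
    out: list[FreeEnergyLandscape] = []
    for idx, comp in enumerate(model.components):
        if comp.n_states != 2:
            raise ValueError("landscapes require two states per component")
        if comp.is_static:
            continue
        k_u_to_q = float(comp.rate_matrix[q, u])
        k_q_to_u = float(comp.rate_matrix[u, q])
        if k_u_to_q <= 0 or k_q_to_u <= 0:
            continue
        de = delta_e_star(k_q_to_u, k_u_to_q, c)
        b_qu = barrier_height(k_q_to_u, c)
        b_uq = barrier_height(k_u_to_q, c)
        p_u, p_q = float(comp.populations[u]), float(comp.populations[q])
        de_pop = (
            delta_e_star_from_populations(p_q, p_u, c)
            if 0.0 < p_q < 1.0 and 0.0 < p_u < 1.0
            else None
        )
        out.append(
            FreeEnergyLandscape(
                component=idx,
                delta_e_star=de,
                barrier_q_to_u=b_qu,
                barrier_u_to_q=b_uq,
                delta_e_star_from_populations=de_pop,
                source="rates",
            )
        )
    return out
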