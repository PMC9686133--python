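"""Electrochemistry of supported lipid films on single-crystal electrodes.

Three quantities are extracted from the electrochemical data stream:

* **coverage** of the electrode by the film from differential capacitance,
  θ = (C0 − C)/(C0 − C1), where C0 is the bare-interface capacitance, C1
  the capacitance of a perfect bilayer and C the measured value;
* **absolute charge density** σ(E) from potential-step chronocoulometry —
  each current transient recorded during the desorption step is integrated
  and the relative charges are anchored at the potential of zero charge
  (pzc) of the bare electrode;
* **film surface pressure** π(E) by electrocapillary back-integration of
  the film/bare charge-density difference from a join potential in the
  desorbed region where both interfaces share one surface energy
  (Lippmann: dγ = −σ dE).

All potentials carry a named reference electrode; unit conventions are
V, μF·cm⁻², μA·cm⁻², μC·cm⁻² and mN·m⁻¹ (1 μC·V·cm⁻² = 10 mN·m⁻¹).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

# Reference-electrode potentials vs SHE (V); extend via convert_reference's table arg.
REFERENCE_OFFSETS_VS_SHE = {
    "she": 0.0,
    "sce": 0.2412,
    "ag_agcl_3m_kcl": 0.210,
}

#: mN·m⁻¹ per (μC·cm⁻² · V)
UC_V_PER_CM2_TO_MN_PER_M = 10.0


class EchemError(ValueError):
    pass


def convert_reference(potential, from_ref: str, to_ref: str,
                      table: dict | None = None):
    """Re-reference a potential: E_to = E_from + off(from) − off(to)."""
    table = table or REFERENCE_OFFSETS_VS_SHE
    try:
        return np.asarray(potential, float) + table[from_ref.lower()] - table[to_ref.lower()]
    except KeyError as e:
        raise EchemError(f"unknown reference electrode {e}") from e


@dataclass
class CapacitanceCurve:
    potential: np.ndarray            # V vs `reference`
    specific_capacitance: np.ndarray  # μF·cm⁻²
    reference: str = "ag_agcl_3m_kcl"
    sweep_direction: str = "negative"

    def __post_init__(self) -> None:
        self.potential = np.asarray(self.potential, float)
        self.specific_capacitance = np.asarray(self.specific_capacitance, float)
        if np.any(self.specific_capacitance <= 0):
            raise EchemError("capacitance must be positive")


@dataclass
class Transient:
    time: np.ndarray             # s, increasing from 0
    current_density: np.ndarray  # μA·cm⁻²
    step_potential: float        # V, the held potential stepped *from*
    base_potential: float        # V, the desorbing potential stepped *to*

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, float)
        self.current_density = np.asarray(self.current_density, float)
        if self.time.size and (self.time[0] < -1e-12 or np.any(np.diff(self.time) <= 0)):
            raise EchemError("time must increase from 0")


@dataclass
class ChargeDensityCurve:
    potential: np.ndarray  # V vs `reference`
    sigma: np.ndarray      # μC·cm⁻²
    surface: str           # 'film' or 'bare'
    pzc_bare: float | None = None
    reference: str = "ag_agcl_3m_kcl"

    def __post_init__(self) -> None:
        self.potential = np.asarray(self.potential, float)
        self.sigma = np.asarray(self.sigma, float)
        order = np.argsort(self.potential)
        self.potential = self.potential[order]
        self.sigma = self.sigma[order]


@dataclass
class PressureCurve:
    potential: np.ndarray      # V
    film_pressure: np.ndarray  # mN·m⁻¹
    reference: str = "ag_agcl_3m_kcl"


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def coverage_from_capacitance(C: float, C0: float, C1: float) -> float:
    """Film coverage θ = (C0 − C)/(C0 − C1) from differential capacitance.

    ``C`` is the measured capacitance minimum, ``C0`` the bare interface
    and ``C1`` a defect-free bilayer (all μF·cm⁻²).  Values outside
    (C1, C0] are clipped to [0, 1] with a warning.
    """
    if C0 <= C1:
        raise EchemError("require C0 > C1")
    theta = (C0 - C) / (C0 - C1)
    if not 0.0 <= theta <= 1.0:
        warnings.warn(
            f"capacitance {C} outside ({C1}, {C0}]: coverage clipped", stacklevel=2)
        theta = float(np.clip(theta, 0.0, 1.0))
    return float(theta)


def integrate_transient(t: Transient) -> float:
    """Charge density passed during the step: trapezoidal ∫ j dt (μC·cm⁻²)."""
    if t.time.size < 3:
        raise EchemError("need at least 3 samples to integrate a transient")
    return float(np.trapezoid(t.current_density, t.time))


def assemble_sigma_curve(
    step_potentials: np.ndarray,
    charges: np.ndarray,
    pzc_bare: float,
    surface: str = "bare",
    bare_reference_curve: ChargeDensityCurve | None = None,
    reference: str = "ag_agcl_3m_kcl",
) -> ChargeDensityCurve:
    """Anchor relative chronocoulometric charges to absolute charge density.

    The transient charge measured on stepping from E to the desorbing
    potential is σ(E_des) − σ(E), so ``−charges`` is the relative charge
    density up to one additive constant.  For the bare surface the constant
    is fixed by σ(pzc) = 0; for the film-covered surface it is fixed by
    matching the calibrated bare curve at the most negative common
    potential, where the film is desorbed and both interfaces coincide.
    """
    E = np.asarray(step_potentials, float)
    rel = -np.asarray(charges, float)
    order = np.argsort(E)
    E, rel = E[order], rel[order]
    if surface == "bare":
        if not E[0] <= pzc_bare <= E[-1]:
            raise EchemError("pzc outside the covered potential range")
        offset = -np.interp(pzc_bare, E, rel)
    else:
        if bare_reference_curve is None:
            raise EchemError("film calibration requires the calibrated bare curve")
        e_join = max(E[0], bare_reference_curve.potential[0])
        sigma_bare = np.interp(e_join, bare_reference_curve.potential,
                               bare_reference_curve.sigma)
        offset = sigma_bare - np.interp(e_join, E, rel)
    return ChargeDensityCurve(E, rel + offset, surface=surface,
                              pzc_bare=pzc_bare, reference=reference)


def film_pressure(
    film: ChargeDensityCurve,
    bare: ChargeDensityCurve,
    E_join: float | None = None,
) -> PressureCurve:
    """Film surface pressure by electrocapillary back-integration.

    π(E) = ∫_{E_join}^{E} [σ_film − σ_bare] dE′, converted to mN·m⁻¹.
    ``E_join`` defaults to the most negative common potential (the desorbed
    state, where film and bare interfaces share one surface energy).
    """
    lo = max(film.potential[0], bare.potential[0])
    hi = min(film.potential[-1], bare.potential[-1])
    if hi <= lo:
        raise EchemError("film and bare curves do not overlap in potential")
    if E_join is None:
        E_join = lo
    if not lo <= E_join <= hi:
        raise EchemError("E_join outside the common potential range")

    E = np.union1d(film.potential, bare.potential)
    E = E[(E >= lo) & (E <= hi)]
    if E_join not in E:
        E = np.sort(np.append(E, E_join))
    dsig = (np.interp(E, film.potential, film.sigma)
            - np.interp(E, bare.potential, bare.sigma))
    # cumulative trapezoid anchored at E_join
    cum = np.concatenate([[0.0], np.cumsum(np.diff(E) * 0.5 * (dsig[1:] + dsig[:-1]))])
    cum = cum - np.interp(E_join, E, cum)
    return PressureCurve(E, cum * UC_V_PER_CM2_TO_MN_PER_M, reference=film.reference)
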