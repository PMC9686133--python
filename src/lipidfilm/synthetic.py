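"""Synthetic instrument streams with known ground truth.

Every analysis stage in this package has a matching generator here, so the
whole inference chain (GIXD map → lattice/tilt, capacitance → coverage,
transients → charge density → film pressure, XRR → slab model, PM-IRRAS →
orientation) can be exercised against known parameters without any
measured data.  The defaults emulate the study conditions for a
sphingomyelin (SM) film: an SM-like chain lattice at 40 mN/m, a bilayer on
Au(111) in 0.1 M NaF desorbing near −0.8 V (vs Ag|AgCl|3 M KCl), a
two-slab monolayer of ~25 Å on water, and six-band C–H / two-band amide-I
reflection spectra.

Noise models: additive Gaussian for spectra, diffraction maps and
capacitance (detector/ADC regime); multiplicative log-normal for XRR,
whose dynamic range spans many decades.  A fixed seed makes every stream
bit-identical.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .echem import Transient
from .gixd import LatticeSolution, forward_peak_positions
from .irorient import AMIDE_TEMPLATE, CH_REGION_TEMPLATE, IRBand
from .xrr import SlabModel, monolayer_model, reflectivity


class SyntheticError(ValueError):
    pass


def _rng(seed: int, stream: str) -> np.random.Generator:
    """Independent, reproducible generator per (seed, stream name)."""
    # crc32 is stable across processes (str hash() is salted per run)
    return np.random.default_rng(np.random.SeedSequence(
        entropy=seed, spawn_key=(zlib.crc32(stream.encode()) % 2**31,)))


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

def sm_lattice() -> LatticeSolution:
    """SM-like chain lattice (distorted hexagonal, intermediate tilt azimuth)."""
    return LatticeSolution(a=5.013, gamma=116.2, tilt_theta=20.6, tilt_psi=12.0)


def dppc_lattice() -> LatticeSolution:
    """DPPC-like chain lattice (nearest-neighbour tilt)."""
    return LatticeSolution(a=5.054, gamma=116.1, tilt_theta=27.1, tilt_psi=0.0)


@dataclass
class OrientedBand(IRBand):
    """IR band with orientation bookkeeping for the generator.

    ``iso_area`` is the area the band would have for randomly oriented
    dipoles; ``dipole`` tags which chain-frame dipole the band follows
    ('sym'/'asym' track the chain, anything else uses ``dipole_tilt``).
    """

    iso_area: float = 1.0
    dipole: str = "fixed"
    dipole_tilt: float = 54.7356  # deg; used when dipole == 'fixed'


def default_ch_bands() -> list[OrientedBand]:
    bands = []
    for b, (iso, dip) in zip(CH_REGION_TEMPLATE, [
        (0.030, "sym"),     # ch2_sym
        (0.012, "fixed"),   # ch3_sym
        (0.010, "fixed"),   # fermi_1
        (0.055, "asym"),    # ch2_asym
        (0.010, "fixed"),   # fermi_2
        (0.020, "fixed"),   # ch3_asym
    ]):
        bands.append(OrientedBand(b.name, b.center, b.fwhm, 0.7,
                                  iso_area=iso, dipole=dip))
    return bands


def default_amide_bands() -> list[OrientedBand]:
    return [OrientedBand(b.name, b.center, b.fwhm, 0.75, iso_area=0.02)
            for b in AMIDE_TEMPLATE]


def default_chain_tilt_profile(potential: np.ndarray) -> np.ndarray:
    """Chain tilt vs potential: ~19° at positive potentials, rising through a
    small maximum near −0.4 V to ~30° where the bilayer detaches."""
    E = np.asarray(potential, float)
    base = 19.0 + 11.0 / (1.0 + np.exp((E + 0.25) / 0.12))
    bump = 3.0 * np.exp(-((E + 0.40) / 0.12) ** 2)
    return base + bump


@dataclass
class GroundTruth:
    """All generator parameters in one place; seed fixed ⇒ identical output."""

    lattice: LatticeSolution = field(default_factory=sm_lattice)
    film_capacitance: float = 5.7     # μF·cm⁻², adsorbed-film plateau
    bare_capacitance: float = 24.8    # μF·cm⁻², bare Au(111)|NaF
    pzc_bare: float = 0.25            # V vs Ag|AgCl|3M KCl (config input)
    pzc_film: float = 0.45            # V, zero crossing of the adsorbed-film σ line
    desorption_potential: float = -0.8  # V
    desorption_width: float = 0.05    # V, logistic step width
    slabs: SlabModel = field(default_factory=lambda: monolayer_model(
        tail_thickness=16.5, tail_sld=8.5e-6,
        head_thickness=8.5, head_sld=13.5e-6, roughness=3.5))
    ch_bands: list[OrientedBand] = field(default_factory=default_ch_bands)
    amide_bands: list[OrientedBand] = field(default_factory=default_amide_bands)
    chain_tilt_profile: Callable[[np.ndarray], np.ndarray] = default_chain_tilt_profile
    dipole_twist: float = 45.0        # deg; splits sin²θc between the two dipoles
    amide_high_fraction: tuple[float, float] = (0.2, 0.6)  # range vs |σ|
    electrode_area: float = 0.5       # cm²
    transient_tau: float = 0.005      # s
    step_duration: float = 0.15       # s
    base_potential: float = -0.01     # V (held before desorption steps)
    desorb_step_potential: float = -0.91  # V
    limiting_area: float = 43.0       # Å², isotherm extrapolation truth
    isotherm_slope: float = -6.0      # mN·m⁻¹ per Å² on the condensed branch
    noise_sd: dict = field(default_factory=lambda: {
        "gixd": 0.02, "capacitance": 0.01, "transient": 0.0,
        "xrr": 0.05, "pmirras": 0.02, "isotherm": 0.02,
    })
    seed: int = 0

    def __post_init__(self) -> None:
        for name, val in [("film_capacitance", self.film_capacitance),
                          ("bare_capacitance", self.bare_capacitance),
                          ("electrode_area", self.electrode_area),
                          ("transient_tau", self.transient_tau)]:
            if val <= 0:
                raise SyntheticError(f"{name} must be positive")
        for b in self.ch_bands + self.amide_bands:
            if not 0.0 <= b.gaussian_fraction <= 1.0:
                raise SyntheticError("gaussian_fraction must lie in [0, 1]")


# ---------------------------------------------------------------------------
# charge-density truth (shared by capacitance/transient generators and tests)
# ---------------------------------------------------------------------------

def true_sigma(truth: GroundTruth, potential: np.ndarray, surface: str) -> np.ndarray:
    """Analytic ground-truth charge density (μC·cm⁻²).

    Bare: σ = C0·(E − pzc_bare).  Film: the adsorbed film screens the metal
    weakly, so its charge follows the shallow line Cf·(E − pzc_film); below
    the desorption potential the film lifts off and σ steps down (logistic
    blend of width ``w``) onto the bare curve, so film and bare coincide in
    the desorbed region.  The film line lies above the bare one over the
    adsorbed range, which is what makes the film pressure positive there.
    """
    E = np.asarray(potential, float)
    sig_bare = truth.bare_capacitance * (E - truth.pzc_bare)
    if surface == "bare":
        return sig_bare
    s = 1.0 / (1.0 + np.exp(-(E - truth.desorption_potential) / truth.desorption_width))
    sig_film_line = truth.film_capacitance * (E - truth.pzc_film)
    return s * sig_film_line + (1.0 - s) * sig_bare


def true_capacitance(truth: GroundTruth, potential: np.ndarray, surface: str) -> np.ndarray:
    """dσ/dE of :func:`true_sigma`: bare constant; film logistic step."""
    E = np.asarray(potential, float)
    if surface == "bare":
        return np.full(E.shape, truth.bare_capacitance)
    s = 1.0 / (1.0 + np.exp(-(E - truth.desorption_potential) / truth.desorption_width))
    return truth.bare_capacitance + (truth.film_capacitance - truth.bare_capacitance) * s


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def _pseudo_voigt(x: np.ndarray, center: float, fwhm: float, frac_gauss: float) -> np.ndarray:
    """Unit-area mixed Gaussian–Lorentzian profile."""
    sigma = fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    gauss = np.exp(-0.5 * ((x - center) / sigma) ** 2) / (sigma * math.sqrt(2 * math.pi))
    hwhm = fwhm / 2.0
    lorentz = hwhm / (math.pi * ((x - center) ** 2 + hwhm ** 2))
    return frac_gauss * gauss + (1.0 - frac_gauss) * lorentz


def generate_gixd_map(
    truth: GroundTruth,
    q_xy: np.ndarray,
    q_z: np.ndarray,
    fwhm_xy: float = 0.015,
    fwhm_z: float = 0.30,
    peak_intensity: float = 1000.0,
    background: float = 50.0,
) -> np.ndarray:
    """2D diffraction map (q_z rows × q_xy columns) of the truth lattice.

    Bragg rods are placed at the forward-model positions: pseudo-Voigt in
    q_xy, Gaussian rod profile in q_z, over a smooth linear-plus-broad
    background, with additive Gaussian noise (relative to the peak height).
    Raises if the q ranges exclude every rod.
    """
    q_xy = np.asarray(q_xy, float)
    q_z = np.asarray(q_z, float)
    if np.any(np.diff(q_xy) <= 0) or np.any(np.diff(q_z) <= 0):
        raise SyntheticError("q grids must be strictly increasing")
    rods = forward_peak_positions(truth.lattice)
    visible = [r for r in rods
               if q_xy[0] <= r.q_xy <= q_xy[-1] and r.q_z - fwhm_z <= q_z[-1]]
    if not visible:
        raise SyntheticError("q ranges exclude all Bragg rods: degenerate map")

    QXY, QZ = np.meshgrid(q_xy, q_z)
    sig_z = fwhm_z / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    I = background * (1.0 + 0.1 * QXY) + 0.2 * background * np.exp(-((QZ - 0.1) / 0.5) ** 2)
    for r in rods:
        xy_profile = _pseudo_voigt(QXY, r.q_xy, fwhm_xy, 0.7)
        z_profile = np.exp(-0.5 * ((QZ - r.q_z) / sig_z) ** 2)
        I += peak_intensity * r.multiplicity * fwhm_xy * xy_profile * z_profile
    sd = truth.noise_sd.get("gixd", 0.0)
    if sd > 0:
        I = I + _rng(truth.seed, "gixd").normal(0.0, sd * peak_intensity, I.shape)
    return I


def generate_capacitance_curve(
    truth: GroundTruth, potential: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """(film, bare) differential-capacitance curves over the potential grid.

    The film curve sits at the film plateau positive of the desorption
    potential and merges smoothly (logistic, 50 mV width) with the constant
    bare curve below it.  Additive Gaussian noise, relative to the bare level.
    """
    E = np.asarray(potential, float)
    if not E.min() <= truth.desorption_potential <= E.max():
        raise SyntheticError("desorption potential outside the grid")
    film = true_capacitance(truth, E, "film")
    bare = true_capacitance(truth, E, "bare")
    sd = truth.noise_sd.get("capacitance", 0.0)
    if sd > 0:
        g = _rng(truth.seed, "capacitance")
        film = film + g.normal(0.0, sd * truth.bare_capacitance, E.shape)
        bare = bare + g.normal(0.0, sd * truth.bare_capacitance, E.shape)
    return film, bare


def generate_transients(
    truth: GroundTruth,
    step_potentials: Sequence[float],
    surface: str = "film",
    n_samples: int = 1200,
) -> list[Transient]:
    """Chronocoulometric current transients for a series of held potentials.

    Stepping from the held potential E to the desorbing potential passes the
    charge A·[σ(E_des) − σ(E)]; each transient is a single exponential
    I₀·exp(−t/τ) with I₀ set so its integral equals that charge.
    """
    steps = np.asarray(step_potentials, float)
    if steps.size == 0:
        raise SyntheticError("step list must be nonempty")
    tau, T = truth.transient_tau, truth.step_duration
    t = np.linspace(0.0, T, n_samples)
    sd = truth.noise_sd.get("transient", 0.0)
    g = _rng(truth.seed, "transient")
    out = []
    e_des = truth.desorb_step_potential
    for E in steps:
        dq = (true_sigma(truth, np.array([e_des]), surface)
              - true_sigma(truth, np.array([E]), surface))[0]  # μC·cm⁻²
        I0 = dq / (tau * (1.0 - math.exp(-T / tau)))           # μA·cm⁻²
        j = I0 * np.exp(-t / tau)
        if sd > 0:
            j = j + g.normal(0.0, sd * max(abs(I0), 1e-12), t.shape)
        out.append(Transient(t, j, step_potential=float(E), base_potential=e_des))
    return out


def generate_xrr_curve(truth: GroundTruth, q_z: np.ndarray) -> np.ndarray:
    """Specular reflectivity of the truth slab model with log-normal noise."""
    R = reflectivity(truth.slabs, np.asarray(q_z, float))
    sd = truth.noise_sd.get("xrr", 0.0)
    if sd > 0:
        R = R * np.exp(_rng(truth.seed, "xrr").normal(0.0, sd, R.shape))
    return R


def dipole_tilts_from_chain(chain_tilt_deg: np.ndarray, twist_deg: float
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Tilts of the two mutually orthogonal methylene dipoles.

    Both dipoles are orthogonal to the all-trans chain axis; the twist
    angle about the chain splits sin²θ_chain between them:
    cosθ_sym = sinθ_c·cos(twist), cosθ_asym = sinθ_c·sin(twist), so the
    directional-cosine identity holds exactly.
    """
    tc = np.radians(np.asarray(chain_tilt_deg, float))
    tw = math.radians(twist_deg)
    th_s = np.degrees(np.arccos(np.clip(np.sin(tc) * math.cos(tw), -1, 1)))
    th_a = np.degrees(np.arccos(np.clip(np.sin(tc) * math.sin(tw), -1, 1)))
    return th_s, th_a


def generate_pmirras_set(
    truth: GroundTruth,
    potentials: Sequence[float],
    wavenumber: np.ndarray,
    region: str = "ch",
) -> list[np.ndarray]:
    """PM-IRRA spectra per potential for the C–H or amide-I region.

    Band areas follow the surface selection rule, 3·cos²(dipole tilt) times
    the isotropic reference area.  In the C–H region the methylene sym/asym
    dipole tilts derive from the chain-tilt profile; methyl and Fermi bands
    keep fixed orientations.  In the amide region the two component areas
    follow the configured high-wavenumber fraction ramp against charge
    density.  A gently sloping baseline and additive Gaussian noise
    (relative to the strongest band height) complete each spectrum.
    """
    E = np.asarray(potentials, float)
    nu = np.asarray(wavenumber, float)
    g = _rng(truth.seed, f"pmirras_{region}")
    sd = truth.noise_sd.get("pmirras", 0.0)

    chain = truth.chain_tilt_profile(E)
    th_s, th_a = dipole_tilts_from_chain(chain, truth.dipole_twist)
    spectra = []
    for i, e in enumerate(E):
        spec = 1e-4 * (nu - nu.min()) / (nu.max() - nu.min())  # gentle baseline
        if region == "ch":
            bands = truth.ch_bands
            for b in bands:
                if b.dipole == "sym":
                    tilt = th_s[i]
                elif b.dipole == "asym":
                    tilt = th_a[i]
                else:
                    tilt = b.dipole_tilt
                area = 3.0 * math.cos(math.radians(tilt)) ** 2 * b.iso_area
                spec = spec + area * _pseudo_voigt(nu, b.center, b.fwhm, b.gaussian_fraction)
        elif region == "amide":
            lo_f, hi_f = truth.amide_high_fraction
            sig = abs(true_sigma(truth, np.array([e]), "film")[0])
            sig_max = abs(true_sigma(
                truth, np.array([truth.desorption_potential]), "film")[0])
            frac = lo_f + (hi_f - lo_f) * min(sig / max(sig_max, 1e-12), 1.0)
            total = sum(b.iso_area for b in truth.amide_bands) * 3.0 * 0.5
            for b in truth.amide_bands:
                area = total * (frac if b.name == "amide_high" else 1.0 - frac)
                spec = spec + area * _pseudo_voigt(nu, b.center, b.fwhm, b.gaussian_fraction)
        else:
            raise SyntheticError(f"unknown region {region!r}")
        if sd > 0:
            peak = float(np.max(spec) - np.min(spec))
            spec = spec + g.normal(0.0, sd * peak, nu.shape)
        spectra.append(spec)
    return spectra


def generate_isotherm(
    truth: GroundTruth, area: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Compression isotherm (surface pressure vs molecular area).

    Piecewise: zero pressure at large area, a soft liquid-expanded toe, and
    a linear condensed branch whose extrapolation crosses π = 0 exactly at
    the truth limiting area.  Returns (area, pressure) with the area axis
    sorted decreasing (compression order).
    """
    A = np.sort(np.asarray(area, float))[::-1]
    pi_lin = truth.isotherm_slope * (A - truth.limiting_area)
    pi = np.where(pi_lin > 0, pi_lin, 0.0)
    # soft toe: round the kink over ~2 Å² without moving the linear branch
    toe = 1.5 * np.exp(-np.clip(A - truth.limiting_area, 0, None) / 1.5)
    pi = np.where(pi_lin <= 12.0, np.maximum(pi, toe * np.clip(pi_lin / 12.0 + 1, 0, 1)), pi)
    sd = truth.noise_sd.get("isotherm", 0.0)
    if sd > 0:
        pi = pi + _rng(truth.seed, "isotherm").normal(0.0, sd * 40.0 * 0.5, A.shape)
    return A, pi
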