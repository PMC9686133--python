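"""Molecular orientation from polarization-modulated IR reflection spectra.

On a metal electrode only the surface-normal component of the infrared
electric field survives (surface selection rule), so the integrated
intensity of a vibrational band measures cos² of the tilt of its transition
dipole from the surface normal.  Comparing a measured band area with the
area simulated for a film of the same thickness but randomly oriented
dipoles gives the dipole tilt:

    cos² θ = A_exp / (3 · A_iso)

and the all-trans chain axis, orthogonal to both methylene stretch dipoles,
follows from the directional-cosine identity

    cos² θ_chain = 1 − cos² θ_sym − cos² θ_asym.

The optics side provides isotropic optical constants from transmission
spectra (k from decadic absorbance, n by Kramers–Kronig), a stratified-
medium transfer matrix for the spectro-electrochemical cell (window |
electrolyte gap | film | metal), mean-square field profiles, and a grid
search for the angle-of-incidence / gap-thickness optimum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from lmfit.models import LinearModel, PseudoVoigtModel

MAGIC_ANGLE = float(np.degrees(np.arccos(np.sqrt(1.0 / 3.0))))  # 54.7356°


class IROrientError(ValueError):
    pass


# ---------------------------------------------------------------------------
# optical constants
# ---------------------------------------------------------------------------

@dataclass
class OpticalConstants:
    """Isotropic complex refractive index ñ = n + ik on a wavenumber grid."""

    wavenumber: np.ndarray  # cm⁻¹
    n: np.ndarray
    k: np.ndarray

    def __post_init__(self) -> None:
        self.wavenumber = np.asarray(self.wavenumber, float)
        self.n = np.asarray(self.n, float)
        self.k = np.asarray(self.k, float)
        if np.any(self.k < -1e-12):
            raise IROrientError("extinction coefficient k must be >= 0")

    def complex_index(self, wavenumber: np.ndarray | None = None) -> np.ndarray:
        if wavenumber is None:
            return self.n + 1j * self.k
        nu = np.asarray(wavenumber, float)
        return (np.interp(nu, self.wavenumber, self.n)
                + 1j * np.interp(nu, self.wavenumber, self.k))


def kk_n_from_k(wavenumber: np.ndarray, k: np.ndarray, n_inf: float = 1.41) -> np.ndarray:
    """Kramers–Kronig transform k → n by Maclaurin's alternating-grid method.

    Requires a uniform wavenumber grid; the principal value is handled by
    summing only grid points of opposite parity to the evaluation point.
    ``n_inf`` anchors the dispersion far from the bands (subtractive form).
    """
    nu = np.asarray(wavenumber, float)
    k = np.asarray(k, float)
    h = np.diff(nu)
    if not np.allclose(h, h[0], rtol=1e-6):
        raise IROrientError("Kramers-Kronig transform requires a uniform grid")
    h = h[0]
    g = nu * k  # ν' k(ν')
    denom = nu[None, :] ** 2 - nu[:, None] ** 2  # [i, j] = ν_j² − ν_i²
    idx = np.arange(nu.size)
    odd_mask = ((idx[None, :] - idx[:, None]) % 2).astype(bool)
    with np.errstate(divide="ignore", invalid="ignore"):
        integrand = np.where(odd_mask, g[None, :] / denom, 0.0)
    return n_inf + (2.0 / np.pi) * 2.0 * h * integrand.sum(axis=1)


def kk_k_from_n(wavenumber: np.ndarray, n: np.ndarray, n_inf: float = 1.41) -> np.ndarray:
    """Inverse dispersion relation n → k (Maclaurin grid), for self-consistency checks."""
    nu = np.asarray(wavenumber, float)
    dn = np.asarray(n, float) - n_inf
    h = np.diff(nu)[0]
    denom = nu[None, :] ** 2 - nu[:, None] ** 2
    idx = np.arange(nu.size)
    odd_mask = ((idx[None, :] - idx[:, None]) % 2).astype(bool)
    with np.errstate(divide="ignore", invalid="ignore"):
        integrand = np.where(odd_mask, dn[None, :] / denom, 0.0)
    return -(2.0 / np.pi) * 2.0 * h * nu * integrand.sum(axis=1)


def optical_constants_from_transmission(
    wavenumber: np.ndarray,
    absorbance: np.ndarray,
    path_length_um: float,
    n_inf: float = 1.41,
) -> OpticalConstants:
    """Isotropic n, k from a decadic transmission absorbance spectrum.

    k = ln(10)·A / (4π·d·ν̃) with the path length d in cm (paper-style
    demountable cell, e.g. a 25 μm spacer); n follows by Kramers–Kronig
    anchored at ``n_inf``.  Negative baseline-subtracted absorbance is
    clipped to zero with a warning.
    """
    nu = np.asarray(wavenumber, float)
    A = np.asarray(absorbance, float)
    if path_length_um <= 0:
        raise IROrientError("path length must be positive")
    if np.any(A < 0):
        warnings.warn("negative absorbance clipped to zero", stacklevel=2)
        A = np.clip(A, 0.0, None)
    d_cm = path_length_um * 1e-4
    k = np.log(10.0) * A / (4.0 * np.pi * d_cm * nu)
    n = kk_n_from_k(nu, k, n_inf=n_inf)
    return OpticalConstants(nu, n, k)


# ---------------------------------------------------------------------------
# stratified-medium optics
# ---------------------------------------------------------------------------

@dataclass
class Layer:
    """One stratum: semi-infinite when ``thickness_um`` is None."""

    name: str
    index: complex | OpticalConstants
    thickness_um: float | None = None

    def n_of(self, wavenumber: np.ndarray) -> np.ndarray:
        if isinstance(self.index, OpticalConstants):
            return self.index.complex_index(wavenumber)
        return np.full(np.asarray(wavenumber).shape, complex(self.index))


@dataclass
class LayerStackIR:
    """Ordered layers, incidence from the first (semi-infinite, transparent)."""

    layers: list[Layer]
    angle_of_incidence: float  # degrees, in the first layer

    def __post_init__(self) -> None:
        if len(self.layers) < 2:
            raise IROrientError("stack needs at least two media")
        if self.layers[0].thickness_um is not None or self.layers[-1].thickness_um is not None:
            raise IROrientError("first and last layers must be semi-infinite")
        for lay in self.layers[1:-1]:
            if lay.thickness_um is None or lay.thickness_um < 0:
                raise IROrientError("interior layers need thickness >= 0")

    def without(self, name: str) -> "LayerStackIR":
        return LayerStackIR([l for l in self.layers if l.name != name],
                            self.angle_of_incidence)


def _xi(n_layer: np.ndarray, n0_sin: np.ndarray) -> np.ndarray:
    """ξ = sqrt(ñ² − n0² sin²φ), branch Im ξ >= 0."""
    xi = np.sqrt(n_layer.astype(complex) ** 2 - n0_sin ** 2)
    return np.where(xi.imag < 0, -xi, xi)


def transfer_matrix_reflectivity(
    stack: LayerStackIR, wavenumber: np.ndarray
) -> dict[str, np.ndarray]:
    """Reflectance and transmittance of the stack for p and s polarization.

    Characteristic-matrix (Abelès/Macleod) formalism with tilted optical
    admittances η_s = ξ and η_p = ñ²/ξ; β = 2π ν̃ ξ d.  Returns a dict with
    keys ``Rp, Rs, Tp, Ts`` (transmittance meaningful for a transparent
    exit medium).
    """
    nu = np.asarray(wavenumber, float)
    k0 = 2.0 * np.pi * nu  # cm⁻¹
    n0 = stack.layers[0].n_of(nu)
    if np.any(np.abs(n0.imag) > 1e-9):
        raise IROrientError("incidence medium must be transparent")
    n0_sin = n0.real * np.sin(np.radians(stack.angle_of_incidence))

    out: dict[str, np.ndarray] = {}
    for pol in ("p", "s"):
        B = np.ones(nu.size, dtype=complex)
        C = np.zeros(nu.size, dtype=complex)
        n_sub = stack.layers[-1].n_of(nu)
        xi_sub = _xi(n_sub, n0_sin)
        eta_sub = n_sub ** 2 / xi_sub if pol == "p" else xi_sub
        # build (B, C) = [prod M_j] (1, eta_sub)
        M11 = np.ones(nu.size, complex)
        M12 = np.zeros(nu.size, complex)
        M21 = np.zeros(nu.size, complex)
        M22 = np.ones(nu.size, complex)
        for lay in stack.layers[1:-1]:
            n_l = lay.n_of(nu)
            xi_l = _xi(n_l, n0_sin)
            eta = n_l ** 2 / xi_l if pol == "p" else xi_l
            beta = k0 * xi_l * (lay.thickness_um * 1e-4)
            cb, sb = np.cos(beta), np.sin(beta)
            # e^{+i k z} downward-wave convention: off-diagonals carry −i
            A11, A12, A21, A22 = cb, -1j * sb / eta, -1j * eta * sb, cb
            M11, M12, M21, M22 = (
                M11 * A11 + M12 * A21, M11 * A12 + M12 * A22,
                M21 * A11 + M22 * A21, M21 * A12 + M22 * A22,
            )
        B = M11 + M12 * eta_sub
        C = M21 + M22 * eta_sub
        xi0 = _xi(n0, n0_sin)
        eta0 = n0 ** 2 / xi0 if pol == "p" else xi0
        r = (eta0 * B - C) / (eta0 * B + C)
        out[f"R{pol}"] = np.abs(r) ** 2
        out[f"T{pol}"] = (4.0 * eta0.real * eta_sub.real
                          / np.abs(eta0 * B + C) ** 2)
    return out


def fresnel_recursive_reflectivity(
    stack: LayerStackIR, wavenumber: np.ndarray
) -> dict[str, np.ndarray]:
    """Recursive Fresnel-coefficient reflectance — independent oracle."""
    nu = np.asarray(wavenumber, float)
    k0 = 2.0 * np.pi * nu
    n0 = stack.layers[0].n_of(nu)
    n0_sin = n0.real * np.sin(np.radians(stack.angle_of_incidence))
    ns = [lay.n_of(nu) for lay in stack.layers]
    xis = [_xi(n, n0_sin) for n in ns]

    out: dict[str, np.ndarray] = {}
    for pol in ("p", "s"):
        r_tot = np.zeros(nu.size, dtype=complex)
        for j in range(len(ns) - 2, -1, -1):
            x1, x2 = xis[j], xis[j + 1]
            if pol == "s":
                r_j = (x1 - x2) / (x1 + x2)
            else:
                r_j = (ns[j + 1] ** 2 * x1 - ns[j] ** 2 * x2) / (
                    ns[j + 1] ** 2 * x1 + ns[j] ** 2 * x2)
            if j == len(ns) - 2:
                r_tot = r_j
            else:
                phase = np.exp(2j * k0 * xis[j + 1]
                               * (stack.layers[j + 1].thickness_um * 1e-4))
                r_tot = (r_j + r_tot * phase) / (1.0 + r_j * r_tot * phase)
        out[f"R{pol}"] = np.abs(r_tot) ** 2
    return out


def mean_square_field(
    stack: LayerStackIR,
    wavenumber: np.ndarray,
    layer_index: int,
    z_um: float = 0.0,
) -> dict[str, np.ndarray]:
    """Mean-square E-field components at depth ``z_um`` into layer ``layer_index``.

    Returned values are |E_x|², |E_y|², |E_z|² normalised to the incident
    field intensity; E_y is the s-polarised field, E_x/E_z the p-polarised
    in-plane/surface-normal components.  On a metal at grazing-like
    incidence |E_z|² dominates — the surface selection rule.
    """
    nu = np.asarray(wavenumber, float)
    k0 = 2.0 * np.pi * nu
    n0 = stack.layers[0].n_of(nu)
    n0_sin = n0.real * np.sin(np.radians(stack.angle_of_incidence))
    ns = [lay.n_of(nu) for lay in stack.layers]
    xis = [_xi(n, n0_sin) for n in ns]
    nlay = len(ns)

    def amplitudes(pol: str) -> list[tuple[np.ndarray, np.ndarray]]:
        """(A+, A-) of the principal field (E_y for s, H_y for p) per layer,
        A+ measured at the top of each layer, incident amplitude 1."""
        # impedance factor linking the derivative-continuity equation
        def q(j):
            return xis[j] / ns[j] ** 2 if pol == "p" else xis[j]
        # start from substrate: (1, 0) then renormalise at the end
        amps = [None] * nlay
        Ap = np.ones(nu.size, complex)
        Am = np.zeros(nu.size, complex)
        amps[nlay - 1] = (Ap, Am)
        for j in range(nlay - 2, -1, -1):
            # continuity at the j|j+1 interface, local phase at interface
            u = amps[j + 1][0]
            v = amps[j + 1][1]
            qj, qj1 = q(j), q(j + 1)
            Ap_if = 0.5 * (u * (1 + qj1 / qj) + v * (1 - qj1 / qj))
            Am_if = 0.5 * (u * (1 - qj1 / qj) + v * (1 + qj1 / qj))
            if j == 0:
                amps[j] = (Ap_if, Am_if)
            else:
                d = stack.layers[j].thickness_um * 1e-4
                ph = np.exp(1j * k0 * xis[j] * d)
                amps[j] = (Ap_if * ph, Am_if / ph)  # re-referenced to layer top
        # normalise so incident (downward in layer 0) amplitude is 1
        norm = amps[0][0]
        return [(a / norm, b / norm) for a, b in amps]

    j = layer_index
    d = 0.0 if stack.layers[j].thickness_um is None else stack.layers[j].thickness_um
    z = z_um * 1e-4
    ph = np.exp(1j * k0 * xis[j] * z)

    s_amps = amplitudes("s")
    Ey = s_amps[j][0] * ph + s_amps[j][1] / ph

    p_amps = amplitudes("p")
    Hy = p_amps[j][0] * ph + p_amps[j][1] / ph
    Hdiff = p_amps[j][0] * ph - p_amps[j][1] / ph
    # E from H (plane-wave units where H = ñ E for propagation in medium ñ):
    # E_x = (ξ_j/ñ_j²) (H+ − H−) · n0/xi0-normalisation, E_z = −(n0 sinφ/ñ_j²) H_y
    xi0 = xis[0]
    # incident E for unit incident H is 1/n0; normalise fields to E_inc = 1
    Ex = (xis[j] / ns[j] ** 2) * Hdiff * ns[0]
    Ez = (n0_sin / ns[j] ** 2) * Hy * ns[0]
    return {
        "Ey2": np.abs(Ey) ** 2,
        "Ex2": np.abs(Ex) ** 2,
        "Ez2": np.abs(Ez) ** 2,
    }


def absorbance_spectrum(
    stack_with_film: LayerStackIR,
    stack_without_film: LayerStackIR,
    wavenumber: np.ndarray,
    pol: str = "p",
) -> np.ndarray:
    """ΔS(ν) = −log10(R_film / R_reference) for the chosen polarization."""
    Rf = transfer_matrix_reflectivity(stack_with_film, wavenumber)[f"R{pol}"]
    R0 = transfer_matrix_reflectivity(stack_without_film, wavenumber)[f"R{pol}"]
    return -np.log10(np.clip(Rf, 1e-300, None) / np.clip(R0, 1e-300, None))


def simulate_isotropic_spectrum(
    stack: LayerStackIR,
    film_name: str,
    wavenumber: np.ndarray,
    band_window: tuple[float, float] | None = None,
    pol: str = "p",
) -> tuple[np.ndarray, float]:
    """Reflection-absorbance of the randomly oriented film and its band area.

    The stack must contain a layer named ``film_name`` carrying the film's
    isotropic optical constants (the random-orientation reference: each
    band's oscillator strength is the orientational average, 1/3 per axis).
    Returns (ΔS spectrum, integrated area over ``band_window``).
    """
    film = [l for l in stack.layers if l.name == film_name]
    if not film:
        raise IROrientError(f"no layer named {film_name!r} in stack")
    if film[0].thickness_um == 0.0:
        return np.zeros(np.asarray(wavenumber).size), 0.0
    spec = absorbance_spectrum(stack, stack.without(film_name), wavenumber, pol=pol)
    nu = np.asarray(wavenumber, float)
    if band_window is None:
        band_window = (nu.min(), nu.max())
    m = (nu >= band_window[0]) & (nu <= band_window[1])
    # the film's non-resonant index contrast shifts ΔS by a smooth offset;
    # remove a linear baseline through the window edges before integrating
    numask = nu[m]
    edge = np.linspace(spec[m][0], spec[m][-1], numask.size)
    area = float(np.trapezoid(spec[m] - edge, numask))
    return spec, area


def optimize_cell_geometry(
    stack_builder: Callable[[float, float], tuple[LayerStackIR, LayerStackIR]],
    angles: np.ndarray,
    gaps_um: np.ndarray,
    wavenumber: np.ndarray,
    band_window: tuple[float, float] | None = None,
    pol: str = "p",
) -> tuple[float, float, np.ndarray, bool]:
    """Grid search for the (angle, gap) maximising the film band signal.

    ``stack_builder(angle, gap) -> (stack_with_film, stack_without_film)``.
    Returns (best angle, best gap, objective surface, boundary_flag); the
    flag is set when the optimum lies on the edge of the searched ranges.
    """
    angles = np.asarray(angles, float)
    gaps_um = np.asarray(gaps_um, float)
    nu = np.asarray(wavenumber, float)
    if band_window is None:
        band_window = (nu.min(), nu.max())
    m = (nu >= band_window[0]) & (nu <= band_window[1])
    surface = np.zeros((angles.size, gaps_um.size))
    for i, ang in enumerate(angles):
        for j, gap in enumerate(gaps_um):
            with_f, without_f = stack_builder(float(ang), float(gap))
            spec = absorbance_spectrum(with_f, without_f, nu, pol=pol)
            surface[i, j] = np.trapezoid(spec[m], nu[m])
    if not np.all(np.isfinite(surface)):
        raise IROrientError("objective surface contains non-finite values")
    i, j = np.unravel_index(np.argmax(surface), surface.shape)
    on_boundary = i in (0, angles.size - 1) or j in (0, gaps_um.size - 1)
    if on_boundary:
        warnings.warn("geometry optimum on search boundary", stacklevel=2)
    return float(angles[i]), float(gaps_um[j]), surface, on_boundary


# ---------------------------------------------------------------------------
# band fitting
# ---------------------------------------------------------------------------

@dataclass
class IRBand:
    name: str
    center: float            # cm⁻¹
    fwhm: float              # cm⁻¹
    gaussian_fraction: float = 0.7
    area: float = 1.0
    center_stderr: float | None = None
    area_stderr: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.gaussian_fraction <= 1.0:
            raise IROrientError("gaussian_fraction must be in [0, 1]")


@dataclass
class BandSet:
    bands: list[IRBand]
    potential: float | None = None

    def __getitem__(self, name: str) -> IRBand:
        for b in self.bands:
            if b.name == name:
                return b
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [b.name for b in self.bands]


# Six C–H stretching bands of a saturated phospholipid (centres in cm⁻¹):
# methylene and methyl symmetric/asymmetric stretches plus two Fermi
# resonances of the CH2 stretch with bending overtones.
CH_REGION_TEMPLATE = [
    IRBand("ch2_sym", 2850.0, 9.0),
    IRBand("ch3_sym", 2872.0, 10.0),
    IRBand("fermi_1", 2902.0, 16.0),
    IRBand("ch2_asym", 2920.0, 13.0),
    IRBand("fermi_2", 2936.0, 16.0),
    IRBand("ch3_asym", 2960.0, 11.0),
]

# Amide I of sphingomyelin: hydrogen-bond-accepting (low) and weakly
# bonded (high) carbonyl populations.
AMIDE_TEMPLATE = [
    IRBand("amide_low", 1630.0, 24.0),
    IRBand("amide_high", 1660.0, 20.0),
]


def fit_bands(
    wavenumber: np.ndarray,
    spectrum: np.ndarray,
    template: Sequence[IRBand],
    baseline: str = "linear",
    center_window: float = 8.0,
    potential: float | None = None,
    vary_fraction: bool = False,
) -> tuple[BandSet, object]:
    """Deconvolve a spectrum into mixed Gaussian–Lorentzian bands.

    Each band is a pseudo-Voigt with its centre constrained to
    ±``center_window`` cm⁻¹ of the template position and non-negative area;
    the baseline is linear over the fitted window.  The Gaussian/Lorentzian
    mixing is held at the template value by default (freeing it on heavily
    overlapped regions trades area between neighbours); set
    ``vary_fraction=True`` to fit it.  Raises on non-convergence.
    """
    nu = np.asarray(wavenumber, float)
    spec = np.asarray(spectrum, float)
    for b in template:
        if not nu.min() <= b.center <= nu.max():
            raise IROrientError(f"template centre {b.center} outside window")

    model = LinearModel(prefix="bg_")
    params = model.make_params(slope=0.0, intercept=float(np.min(spec)))
    amp0 = max(float(np.max(spec) - np.min(spec)), 1e-12)
    for i, b in enumerate(template):
        pv = PseudoVoigtModel(prefix=f"b{i}_")
        model = model + pv
        sigma0 = b.fwhm / 2.0
        params.update(pv.make_params(
            center=b.center, sigma=sigma0,
            amplitude=max(b.area, amp0 * b.fwhm * 0.05),
            fraction=1.0 - b.gaussian_fraction,
        ))
        params[f"b{i}_center"].set(min=b.center - center_window,
                                   max=b.center + center_window)
        params[f"b{i}_sigma"].set(min=0.5, max=4.0 * b.fwhm)
        params[f"b{i}_amplitude"].set(min=0.0)
        params[f"b{i}_fraction"].set(min=0.0, max=1.0, vary=vary_fraction)
    result = model.fit(spec, params, x=nu)
    # "tolerance too small" means the minimiser stopped because it cannot
    # tighten further — a converged fit, merely without error bars
    benign = "Tolerance seems to be too small" in str(result.message)
    if not (result.success or benign):
        raise IROrientError(f"band fit failed: {result.message}")

    fitted = []
    for i, b in enumerate(template):
        p = result.params
        fitted.append(IRBand(
            name=b.name,
            center=p[f"b{i}_center"].value,
            fwhm=p[f"b{i}_fwhm"].value,
            gaussian_fraction=1.0 - p[f"b{i}_fraction"].value,
            area=p[f"b{i}_amplitude"].value,
            center_stderr=p[f"b{i}_center"].stderr,
            area_stderr=p[f"b{i}_amplitude"].stderr,
        ))
    return BandSet(fitted, potential=potential), result


# ---------------------------------------------------------------------------
# orientation
# ---------------------------------------------------------------------------

@dataclass
class TiltResult:
    dipole_tilt_sym: float
    dipole_tilt_asym: float
    chain_tilt: float
    potential: float | None = None
    charge_density: float | None = None

    def __post_init__(self) -> None:
        for v in (self.dipole_tilt_sym, self.dipole_tilt_asym, self.chain_tilt):
            if not -1e-9 <= v <= 90.0 + 1e-9:
                raise IROrientError("tilt angles must lie in [0, 90] degrees")

    @property
    def cosine_residual(self) -> float:
        """cos²θ_sym + cos²θ_asym + cos²θ_chain − 1 (zero by construction)."""
        c = np.cos(np.radians([self.dipole_tilt_sym, self.dipole_tilt_asym,
                               self.chain_tilt]))
        return float(np.sum(c ** 2) - 1.0)


def dipole_tilt(A_exp: float, A_iso: float, saturation_tol: float = 0.05) -> float:
    """Transition-dipole tilt from measured vs isotropic-reference band area.

    cos²θ = A_exp/(3·A_iso).  A ratio above 1 by at most ``saturation_tol``
    (noise pushing past the fully-vertical limit) is clipped to θ = 0 with
    a warning; beyond that it is an error.
    """
    if A_iso <= 0:
        raise IROrientError("isotropic reference area must be positive")
    if A_exp < 0:
        raise IROrientError("measured area must be non-negative")
    ratio = A_exp / (3.0 * A_iso)
    if ratio > 1.0:
        if ratio > 1.0 + saturation_tol:
            raise IROrientError(f"area ratio {ratio:.3f} unphysically large")
        warnings.warn("area ratio saturated above 3·A_iso: tilt clipped to 0°",
                      stacklevel=2)
        ratio = 1.0
    return float(np.degrees(np.arccos(np.sqrt(ratio))))


def chain_tilt(theta_sym: float, theta_asym: float, tol: float = 0.02) -> float:
    """Chain-axis tilt from the two orthogonal methylene dipole tilts.

    cos²θ_chain = 1 − cos²θ_sym − cos²θ_asym; a negative residual within
    ``tol`` (noise) is clipped to 0, beyond it is an error.
    """
    for th in (theta_sym, theta_asym):
        if not 0.0 <= th <= 90.0:
            raise IROrientError("dipole tilts must lie in [0, 90] degrees")
    c2 = 1.0 - np.cos(np.radians(theta_sym)) ** 2 - np.cos(np.radians(theta_asym)) ** 2
    if c2 < 0.0:
        if c2 < -tol:
            raise IROrientError(
                f"cos²θ_sym + cos²θ_asym = {1 - c2:.4f} exceeds 1: dipoles not orthogonal")
        c2 = 0.0
    return float(np.degrees(np.arccos(np.sqrt(c2))))


def tilt_from_areas(
    A_sym: float, A_asym: float, A_iso_sym: float, A_iso_asym: float,
    potential: float | None = None, charge_density: float | None = None,
) -> TiltResult:
    """Full per-potential orientation result from the two methylene bands."""
    th_s = dipole_tilt(A_sym, A_iso_sym)
    th_a = dipole_tilt(A_asym, A_iso_asym)
    return TiltResult(th_s, th_a, chain_tilt(th_s, th_a),
                      potential=potential, charge_density=charge_density)


def amide_fraction(band_sets: Sequence[BandSet],
                   high: str = "amide_high", low: str = "amide_low",
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Fraction of total amide-I area in the higher-wavenumber component.

    Returns (fractions, propagated stderrs) per band set; the fraction
    tracks the population of weakly hydrogen-bonded carbonyls against
    potential or charge density.
    """
    fracs, errs = [], []
    for bs in band_sets:
        bh, bl = bs[high], bs[low]
        total = bh.area + bl.area
        if total <= 0:
            raise IROrientError("zero total amide area")
        f = bh.area / total
        if bh.area_stderr is not None and bl.area_stderr is not None:
            df = np.hypot(bl.area * bh.area_stderr, bh.area * bl.area_stderr) / total ** 2
        else:
            df = np.nan
        fracs.append(f)
        errs.append(df)
    return np.asarray(fracs), np.asarray(errs)
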