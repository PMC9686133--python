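"""Specular X-ray reflectivity: slab forward model and fitting.

The monolayer at the air|water interface is modelled as a stack of
homogeneous slabs (thickness, scattering length density, interfacial
roughness) between semi-infinite ambient and subphase.  The forward model
is the Parratt recursion with Névot–Croce Gaussian-roughness damping; an
independent Abelès transfer-matrix implementation is provided as a
numerical oracle.  The standard monolayer model is a hydrocarbon tail slab
over a headgroup slab with every interface sharing one roughness.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import lmfit

SLD_WATER_XRAY = 9.47e-6  # Å⁻², electron-density SLD of H2O at 12.5 keV


class XrrError(ValueError):
    pass


@dataclass
class Slab:
    thickness: float          # Å
    sld: float                # Å⁻²
    roughness_to_next: float  # Å, interface between this slab and the next medium below

    def __post_init__(self) -> None:
        if self.thickness <= 0:
            raise XrrError("slab thickness must be positive")
        if self.roughness_to_next < 0:
            raise XrrError("roughness must be non-negative")


@dataclass
class SlabModel:
    """Ordered slabs bounded by semi-infinite ambient (top) and substrate."""

    ambient_sld: float
    slabs: list[Slab]
    substrate_sld: float
    ambient_roughness: float = 0.0  # interface between ambient and first slab

    @property
    def n_interfaces(self) -> int:
        return len(self.slabs) + 1

    def profile_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(slds, thicknesses, roughnesses) for the full medium sequence."""
        slds = np.array([self.ambient_sld] + [s.sld for s in self.slabs] + [self.substrate_sld])
        thick = np.array([np.inf] + [s.thickness for s in self.slabs] + [np.inf])
        rough = np.array([self.ambient_roughness] + [s.roughness_to_next for s in self.slabs])
        return slds, thick, rough


def monolayer_model(
    tail_thickness: float,
    tail_sld: float,
    head_thickness: float,
    head_sld: float,
    roughness: float,
    subphase_sld: float = SLD_WATER_XRAY,
) -> SlabModel:
    """Two-slab monolayer (tails over heads on water) with shared roughness."""
    return SlabModel(
        ambient_sld=0.0,
        slabs=[
            Slab(tail_thickness, tail_sld, roughness),
            Slab(head_thickness, head_sld, roughness),
        ],
        substrate_sld=subphase_sld,
        ambient_roughness=roughness,
    )


# ---------------------------------------------------------------------------
# forward models
# ---------------------------------------------------------------------------

def _kz_layers(q_z: np.ndarray, slds: np.ndarray) -> np.ndarray:
    """Vertical wavevector in each medium; shape (n_media, n_q), complex."""
    q_z = np.asarray(q_z, float)
    kz0 = q_z[None, :] / 2.0
    contrast = 4.0 * np.pi * (slds[:, None] - slds[0])
    return np.sqrt(kz0.astype(complex) ** 2 - contrast)


def reflectivity(model: SlabModel, q_z: np.ndarray) -> np.ndarray:
    """Specular reflectivity by the Parratt recursion (Névot–Croce roughness)."""
    slds, thick, rough = model.profile_arrays()
    kz = _kz_layers(q_z, slds)
    n = len(slds)
    r_tot = np.zeros(kz.shape[1], dtype=complex)
    for j in range(n - 2, -1, -1):
        k1, k2 = kz[j], kz[j + 1]
        r_j = (k1 - k2) / (k1 + k2) * np.exp(-2.0 * k1 * k2 * rough[j] ** 2)
        if j == n - 2:
            r_tot = r_j
        else:
            phase = np.exp(2j * kz[j + 1] * thick[j + 1])
            r_tot = (r_j + r_tot * phase) / (1.0 + r_j * r_tot * phase)
    R = np.abs(r_tot) ** 2
    return np.clip(R, 0.0, 1.0)


def reflectivity_abeles(model: SlabModel, q_z: np.ndarray) -> np.ndarray:
    """Abelès 2×2 interface/propagation matrix product — independent oracle."""
    slds, thick, rough = model.profile_arrays()
    kz = _kz_layers(q_z, slds)
    nq = kz.shape[1]
    M = np.tile(np.eye(2, dtype=complex)[None, :, :], (nq, 1, 1))
    for j in range(len(slds) - 1):
        k1, k2 = kz[j], kz[j + 1]
        r = (k1 - k2) / (k1 + k2) * np.exp(-2.0 * k1 * k2 * rough[j] ** 2)
        I = np.empty((nq, 2, 2), dtype=complex)
        I[:, 0, 0] = 1.0
        I[:, 0, 1] = r
        I[:, 1, 0] = r
        I[:, 1, 1] = 1.0
        M = M @ I
        if j + 1 < len(slds) - 1:
            beta = kz[j + 1] * thick[j + 1]
            P = np.zeros((nq, 2, 2), dtype=complex)
            P[:, 0, 0] = np.exp(-1j * beta)
            P[:, 1, 1] = np.exp(1j * beta)
            M = M @ P
    r_tot = M[:, 1, 0] / M[:, 0, 0]
    return np.clip(np.abs(r_tot) ** 2, 0.0, 1.0)


def fresnel_reflectivity(q_z: np.ndarray, sld_substrate: float,
                         sld_ambient: float = 0.0) -> np.ndarray:
    """Single-interface Fresnel law (closed form)."""
    return reflectivity(SlabModel(sld_ambient, [], sld_substrate), q_z)


def kiessig_fringe_spacing(
    q_z: np.ndarray,
    R: np.ndarray,
    slab_sld: float | None = None,
    ambient_sld: float = 0.0,
) -> float:
    """Mean Kiessig fringe spacing Δq (→ film thickness d = 2π/Δq).

    Fringe minima are located on the measured grid.  The interference phase
    is set by the wavevector *inside* the slab, so when ``slab_sld`` is
    given each minimum is refraction-corrected,
    q′ = 2·sqrt((q/2)² − 4π(ρ_slab − ρ_ambient)).  The q-dependence of the
    interface amplitudes still shifts each minimum by ~1/m fringe indices,
    so only the upper ``1 − use_fraction`` of the located minima (where the
    shift is negligible) enter the mean.
    """
    q_z = np.asarray(q_z, float)
    logR = np.log(np.clip(np.asarray(R, float), 1e-300, None))
    interior = (logR[1:-1] < logR[:-2]) & (logR[1:-1] < logR[2:])
    minima = q_z[1:-1][interior]
    if minima.size < 2:
        raise XrrError("fewer than two fringe minima found")
    if slab_sld is not None:
        minima = 2.0 * np.sqrt((minima / 2.0) ** 2
                               - 4.0 * np.pi * (slab_sld - ambient_sld))
    if minima.size > 3:
        minima = minima[minima.size // 2:]
    return float(np.mean(np.diff(minima)))


def kiessig_thickness(q_z: np.ndarray, R: np.ndarray,
                      slab_sld: float | None = None,
                      ambient_sld: float = 0.0) -> float:
    """Film thickness from the Kiessig fringe spacing, d = 2π/Δq."""
    return float(2.0 * np.pi
                 / kiessig_fringe_spacing(q_z, R, slab_sld, ambient_sld))


# ---------------------------------------------------------------------------
# geometry correction
# ---------------------------------------------------------------------------

def footprint_correction(
    q_z: np.ndarray,
    R: np.ndarray,
    beam_height: float,
    sample_length: float,
    wavelength: float = 0.9919,
) -> np.ndarray:
    """Correct for beam over-illumination of a finite sample.

    Below the spill-over angle (sin α = h/L) only a fraction
    ``f = L sin(α)/h`` of the beam strikes the sample; the measured
    reflectivity is divided by ``f`` there and unchanged above.
    """
    if beam_height <= 0 or sample_length <= 0:
        raise XrrError("geometry must be positive")
    q_z = np.asarray(q_z, float)
    alpha = np.arcsin(np.clip(q_z * wavelength / (4.0 * np.pi), -1, 1))
    frac = np.clip(sample_length * np.sin(alpha) / beam_height, None, 1.0)
    frac = np.where(frac <= 0, np.nan, frac)
    return np.asarray(R, float) / frac


# ---------------------------------------------------------------------------
# hydration bookkeeping
# ---------------------------------------------------------------------------

def headgroup_hydration(
    head_sld: float,
    head_thickness: float,
    area_per_molecule: float,
    dry_headgroup_scattering_length: float,
    water_scattering_length: float,
    water_volume: float,
    dry_headgroup_volume: float | None = None,
) -> tuple[float, float | None]:
    """Waters per headgroup from the headgroup-slab scattering budget.

    n_w = (SLD·t·A_M − b_head) / b_water.  If the dry headgroup volume is
    given, the volume-consistency residual
    ``t·A_M − (V_head + n_w·V_water)`` is returned alongside (else None).
    A negative water count is flagged as unphysical.
    """
    if min(head_sld, head_thickness, area_per_molecule,
           dry_headgroup_scattering_length, water_scattering_length,
           water_volume) <= 0:
        raise XrrError("all hydration inputs must be positive")
    n_w = (head_sld * head_thickness * area_per_molecule
           - dry_headgroup_scattering_length) / water_scattering_length
    if n_w < 0:
        warnings.warn("negative water count: unphysical headgroup slab", stacklevel=2)
    residual = None
    if dry_headgroup_volume is not None:
        residual = head_thickness * area_per_molecule - (
            dry_headgroup_volume + n_w * water_volume)
    return float(n_w), residual


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class SlabFitResult:
    model: SlabModel
    params: "lmfit.Parameters"
    redchi: float
    success: bool
    mcmc_result: object | None = None
    medians: dict | None = None
    credible_intervals: dict | None = None
    flags: list[str] = field(default_factory=list)


def _params_to_model(params: lmfit.Parameters, template: SlabModel) -> SlabModel:
    slabs = []
    for i in range(len(template.slabs)):
        slabs.append(Slab(
            thickness=params[f"t{i}"].value,
            sld=params[f"sld{i}"].value,
            roughness_to_next=params["rough"].value,
        ))
    return SlabModel(template.ambient_sld, slabs, template.substrate_sld,
                     ambient_roughness=params["rough"].value)


def fit_slabs(
    q_z: np.ndarray,
    R: np.ndarray,
    initial: SlabModel,
    dR: np.ndarray | None = None,
    mode: str = "least_squares",
    bounds_scale: float = 2.0,
    mcmc_steps: int = 500,
    mcmc_walkers: int = 32,
    seed: int = 0,
) -> SlabFitResult:
    """Fit a shared-roughness slab model to a reflectivity curve.

    Fits in log10(R) space.  ``mode='least_squares'`` returns a point
    estimate; ``mode='mcmc'`` additionally runs a seeded affine-invariant
    ensemble sampler (burn-in = half the chain) and reports medians and
    68% credible intervals.  Non-convergence and parameters pinned at their
    bounds are flagged, never silent.
    """
    q_z = np.asarray(q_z, float)
    R = np.asarray(R, float)
    params = lmfit.Parameters()
    for i, s in enumerate(initial.slabs):
        params.add(f"t{i}", value=s.thickness,
                   min=s.thickness / bounds_scale, max=s.thickness * bounds_scale)
        params.add(f"sld{i}", value=s.sld,
                   min=s.sld / bounds_scale, max=s.sld * bounds_scale)
    r0 = initial.slabs[0].roughness_to_next if initial.slabs else 3.0
    params.add("rough", value=r0, min=0.0, max=max(4.0 * r0, 10.0))

    logR = np.log10(np.clip(R, 1e-14, None))
    if dR is not None:
        weight = np.clip(np.asarray(dR, float) / (np.abs(R) * np.log(10.0)), 1e-6, None)
    else:
        weight = None

    def residual(p):
        model = _params_to_model(p, initial)
        res = np.log10(np.clip(reflectivity(model, q_z), 1e-14, None)) - logR
        return res / weight if weight is not None else res

    mini = lmfit.Minimizer(residual, params)
    out = mini.minimize(method="least_squares")
    flags = []
    if not out.success:
        flags.append("non_convergence")
    # a local minimum far from the data leaves log-space residuals well above
    # the measurement-noise level; never return such a fit silently
    if out.redchi > 2e-3:
        flags.append("poor_fit:possible_multimodality")
    for name, par in out.params.items():
        if par.vary and par.min is not None and par.max is not None:
            span = par.max - par.min
            if span > 0 and (par.value - par.min < 1e-3 * span
                             or par.max - par.value < 1e-3 * span):
                flags.append(f"at_bound:{name}")

    result = SlabFitResult(
        model=_params_to_model(out.params, initial),
        params=out.params, redchi=out.redchi, success=out.success, flags=flags,
    )
    if mode == "mcmc":
        mcmc = lmfit.Minimizer(residual, out.params)
        emcee_out = mcmc.minimize(
            method="emcee", nwalkers=mcmc_walkers, steps=mcmc_steps,
            burn=mcmc_steps // 2, seed=seed, progress=False, is_weighted=False,
        )
        medians, ci = {}, {}
        for name in emcee_out.var_names:
            chain = emcee_out.flatchain[name]
            lo, med, hi = np.percentile(chain, [16, 50, 84])
            medians[name] = float(med)
            ci[name] = (float(lo), float(hi))
        result.mcmc_result = emcee_out
        result.medians = medians
        result.credible_intervals = ci
    return result
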