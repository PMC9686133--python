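"""Grazing-incidence X-ray diffraction reduction for Langmuir monolayers.

A condensed phospholipid monolayer packs its hydrocarbon chains on a 2D
lattice; at the surface pressures used for bilayer deposition the cell is
distorted-hexagonal and is described here by an oblique cell with
``a = b`` and cell angle ``gamma`` (90 < gamma < 180 in this convention).
Two low-order reflections are visible: the degenerate {1 0}/{0 1} pair and
the non-degenerate {1 -1} reflection.  Their in-plane positions give the
cell; the out-of-plane maxima of the Bragg rods give the collective chain
tilt ``theta`` from the surface normal and the tilt azimuth ``psi``
(measured from the nearest-neighbour direction, i.e. the bisector of the
two reciprocal basis vectors).

The Bragg-rod relation used throughout is

    q_z(hk) = q_xy(hk) * cos(psi_hk) * tan(theta)

where ``psi_hk`` is the in-plane angle between the chain-tilt direction and
the reciprocal-lattice vector of reflection ``hk``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from lmfit.models import ConstantModel, GaussianModel, LinearModel, PseudoVoigtModel, VoigtModel
from scipy.optimize import least_squares


class GixdError(ValueError):
    """Raised for inconsistent peak positions or degenerate inputs."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class BraggPeak:
    """One fitted reflection: in-plane centre plus (optionally) rod maximum."""

    q_xy_center: float
    q_z_center: float | None = None
    fwhm_xy: float = 0.02
    fwhm_z: float | None = None
    amplitude: float = 1.0
    multiplicity: int = 1
    q_xy_stderr: float | None = None
    q_z_stderr: float | None = None
    at_edge: bool = False

    def __post_init__(self) -> None:
        if self.q_xy_center <= 0:
            raise GixdError("q_xy_center must be positive")
        if self.q_z_center is not None and self.q_z_center < -1e-12:
            raise GixdError("q_z_center must be non-negative")
        if self.fwhm_xy <= 0:
            raise GixdError("widths must be positive")
        if self.multiplicity not in (1, 2):
            raise GixdError("multiplicity must be 1 or 2")


@dataclass
class LatticeSolution:
    """2D chain lattice with per-chain/per-molecule areas and chain tilt."""

    a: float                 # Å, = b by constraint
    gamma: float             # degrees, oblique convention 90 < gamma < 180
    tilt_theta: float = 0.0  # degrees from surface normal
    tilt_psi: float = 0.0    # degrees from the NN direction
    chains_per_molecule: int = 2
    a_stderr: float | None = None
    gamma_stderr: float | None = None
    theta_stderr: float | None = None
    psi_stderr: float | None = None
    area_stderr: float | None = None

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise GixdError("lattice constant must be positive")
        if not 90.0 < self.gamma < 180.0:
            raise GixdError("gamma must lie in (90, 180) degrees")
        if not 0.0 <= self.tilt_theta < 90.0:
            raise GixdError("tilt_theta must lie in [0, 90)")

    @property
    def b(self) -> float:
        return self.a

    @property
    def area_per_chain(self) -> float:
        return self.a * self.b * np.sin(np.radians(self.gamma))

    @property
    def area_per_molecule(self) -> float:
        return self.chains_per_molecule * self.area_per_chain


@dataclass
class IsothermCurve:
    """Surface pressure vs area per molecule along a compression."""

    area_per_molecule: np.ndarray  # Å², decreasing along compression
    surface_pressure: np.ndarray   # mN/m

    def __post_init__(self) -> None:
        self.area_per_molecule = np.asarray(self.area_per_molecule, dtype=float)
        self.surface_pressure = np.asarray(self.surface_pressure, dtype=float)
        if self.area_per_molecule.shape != self.surface_pressure.shape:
            raise GixdError("isotherm arrays must match in length")


@dataclass
class Reflection:
    """Forward-computed Bragg-rod position."""

    h: int
    k: int
    q_xy: float
    q_z: float
    multiplicity: int = 1
    partners: tuple = ()


# ---------------------------------------------------------------------------
# lattice geometry
# ---------------------------------------------------------------------------

def reciprocal_vectors(a: float, gamma_deg: float) -> tuple[np.ndarray, np.ndarray]:
    """Reciprocal basis for the oblique a = b cell, a*.a = 2π convention."""
    g = np.radians(gamma_deg)
    a1 = a * np.array([1.0, 0.0])
    a2 = a * np.array([np.cos(g), np.sin(g)])
    # 2D reciprocal: rotate and scale so a_i* . a_j = 2π δ_ij
    pref = 2.0 * np.pi / (a * a * np.sin(g))
    astar = pref * np.array([a2[1], -a2[0]]) * -1.0
    bstar = pref * np.array([-a1[1], a1[0]])
    # orientation: choose astar with positive dot on a1
    if np.dot(astar, a1) < 0:
        astar = -astar
    return astar, bstar


def area_per_molecule(a: float, gamma: float, chains_per_molecule: int = 2) -> float:
    """Molecular area of a lipid on the a = b oblique chain cell (Å²)."""
    if a <= 0 or not 0 < gamma < 180:
        raise GixdError("invalid cell")
    return chains_per_molecule * a * a * np.sin(np.radians(gamma))


def solve_cell(q_degenerate: float, q_nondegenerate: float) -> tuple[float, float]:
    """Invert the two observed in-plane positions to the (a, gamma) cell.

    The degenerate {1 0}/{0 1} pair sits at ``|a*| = q_degenerate``; the
    {1 -1} reflection at ``|a* - b*|``.  With ``gamma* = 180° - gamma``:

        cos(gamma*) = 1 - q_nondeg² / (2 q_deg²)
        a = 2π / (q_deg · sin gamma)

    Raises :class:`GixdError` when no real cell reproduces the positions.
    """
    if q_degenerate <= 0 or q_nondegenerate <= 0:
        raise GixdError("peak positions must be positive")
    cos_gstar = 1.0 - q_nondegenerate**2 / (2.0 * q_degenerate**2)
    if abs(cos_gstar) >= 1.0:
        raise GixdError(
            f"inconsistent peak positions: cos(gamma*) = {cos_gstar:.4f} out of range"
        )
    gamma_star = np.degrees(np.arccos(cos_gstar))
    gamma = 180.0 - gamma_star
    a = 2.0 * np.pi / (q_degenerate * np.sin(np.radians(gamma)))
    return a, gamma


def forward_peak_positions(
    lattice: LatticeSolution, merge_tol: float = 1e-4
) -> list[Reflection]:
    """Bragg-rod positions of the {1 0}, {0 1} and {1 -1} reflections.

    The tilt azimuth ``psi`` is measured from the bisector of a* and b*
    (the nearest-neighbour direction): at ``psi = 0`` the {1 0}/{0 1} rods
    are exactly degenerate at q_z > 0 and the {1 -1} rod sits at q_z = 0.
    Rods whose (q_xy, q_z) coincide within ``merge_tol`` are merged into a
    single reflection of higher multiplicity.
    """
    astar, bstar = reciprocal_vectors(lattice.a, lattice.gamma)
    gamma_star = np.degrees(
        np.arccos(np.clip(np.dot(astar, bstar) / (np.linalg.norm(astar) * np.linalg.norm(bstar)), -1, 1))
    )
    half = gamma_star / 2.0
    tan_t = np.tan(np.radians(lattice.tilt_theta))
    q_deg = np.linalg.norm(astar)
    q_nd = np.linalg.norm(astar - bstar)
    psi = lattice.tilt_psi
    # psi > 0 rotates the tilt direction from the bisector toward b*, so the
    # angle to a* grows to half+psi and the angle to b* shrinks to half-psi
    raw = [
        Reflection(1, 0, q_deg, q_deg * abs(np.cos(np.radians(psi + half))) * tan_t),
        Reflection(0, 1, q_deg, q_deg * abs(np.cos(np.radians(psi - half))) * tan_t),
        Reflection(1, -1, q_nd, q_nd * abs(np.sin(np.radians(psi))) * tan_t),
    ]
    merged: list[Reflection] = []
    for r in raw:
        for m in merged:
            if abs(m.q_xy - r.q_xy) < merge_tol and abs(m.q_z - r.q_z) < merge_tol:
                m.multiplicity += 1
                m.partners = m.partners + ((r.h, r.k),)
                break
        else:
            merged.append(r)
    return merged


def _predicted_qz(theta: float, psi: float, q_deg: float, q_nd: float,
                  half: float) -> np.ndarray:
    """q_z of ({1 0}, {0 1}, {1 -1}) for tilt (theta, psi), degrees in."""
    t = np.tan(np.radians(theta))
    return np.array([
        q_deg * np.abs(np.cos(np.radians(psi + half))) * t,
        q_deg * np.abs(np.cos(np.radians(psi - half))) * t,
        q_nd * np.abs(np.sin(np.radians(psi))) * t,
    ])


def solve_tilt(
    peaks: Sequence[BraggPeak],
    cell: tuple[float, float],
    psi_bounds: tuple[float, float] = (0.0, 30.0),
) -> tuple[float, float, float | None, float | None]:
    """Least-squares chain tilt (theta, psi) from observed rod maxima.

    Observed peaks are indexed to the degenerate family (q_xy near ``|a*|``)
    or the non-degenerate {1 -1} reflection by in-plane position.  A
    multiplicity-2 peak is compared against the mean q_z of the {1 0}/{0 1}
    pair; two multiplicity-1 peaks of the degenerate family are assigned in
    the order that minimises the residual (the swap maps psi -> -psi).
    Returns ``(theta, psi, theta_stderr, psi_stderr)``; psi is reported in
    the reduced sector [0°, 30°].  If every rod maximum is at q_z = 0 the
    film is untilted and psi is undefined (returned as NaN).
    """
    a, gamma = cell
    astar, bstar = reciprocal_vectors(a, gamma)
    q_deg = np.linalg.norm(astar)
    q_nd = np.linalg.norm(astar - bstar)
    gamma_star = 180.0 - gamma
    half = gamma_star / 2.0

    deg_obs: list[BraggPeak] = []
    nd_obs: list[BraggPeak] = []
    for p in peaks:
        if p.q_z_center is None:
            raise GixdError("solve_tilt requires q_z_center on every peak")
        if abs(p.q_xy_center - q_deg) <= abs(p.q_xy_center - q_nd):
            deg_obs.append(p)
        else:
            nd_obs.append(p)
    if len(deg_obs) + len(nd_obs) < 2:
        raise GixdError("need at least two independent rod positions")

    all_qz = [p.q_z_center for p in deg_obs + nd_obs]
    if max(abs(q) for q in all_qz) < 1e-9:
        return 0.0, float("nan"), None, None

    def make_residual(swap: bool):
        def residual(x):
            theta, psi = x
            pred = _predicted_qz(theta, psi, q_deg, q_nd, half)
            res = []
            singles = list(deg_obs)
            if swap:
                singles = singles[::-1]
            if len(deg_obs) == 1 and deg_obs[0].multiplicity == 2:
                res.append(0.5 * (pred[0] + pred[1]) - deg_obs[0].q_z_center)
            else:
                for i, p in enumerate(singles[:2]):
                    res.append(pred[i] - p.q_z_center)
            for p in nd_obs:
                res.append(pred[2] - p.q_z_center)
            return np.asarray(res)
        return residual

    best = None
    for swap in (False, True) if len(deg_obs) == 2 else (False,):
        fit = least_squares(
            make_residual(swap), x0=[15.0, 10.0],
            bounds=([0.0, psi_bounds[0]], [89.0, psi_bounds[1]]),
            xtol=1e-14, ftol=1e-14, gtol=1e-14,
        )
        if best is None or fit.cost < best.cost:
            best = fit
    theta, psi = best.x

    # delta-method uncertainties from the residual jacobian
    theta_err = psi_err = None
    m, n = best.jac.shape
    if m > n:
        try:
            dof = m - n
            s2 = 2.0 * best.cost / dof
            cov = s2 * np.linalg.inv(best.jac.T @ best.jac)
            theta_err, psi_err = np.sqrt(np.diag(cov))
        except np.linalg.LinAlgError:
            pass
    return float(theta), float(psi), theta_err, psi_err


def solve_tilt_gridsearch(
    peaks: Sequence[BraggPeak],
    cell: tuple[float, float],
    theta_range: tuple[float, float] = (0.0, 60.0),
    psi_range: tuple[float, float] = (0.0, 30.0),
    step: float = 0.05,
) -> tuple[float, float]:
    """Brute-force (theta, psi) grid search; oracle for :func:`solve_tilt`."""
    a, gamma = cell
    astar, bstar = reciprocal_vectors(a, gamma)
    q_deg = np.linalg.norm(astar)
    q_nd = np.linalg.norm(astar - bstar)
    half = (180.0 - gamma) / 2.0

    thetas = np.arange(theta_range[0], theta_range[1] + step / 2, step)
    psis = np.arange(psi_range[0], psi_range[1] + step / 2, step)
    T, P = np.meshgrid(thetas, psis, indexing="ij")
    tan_t = np.tan(np.radians(T))
    pred10 = q_deg * np.abs(np.cos(np.radians(P - half))) * tan_t
    pred01 = q_deg * np.abs(np.cos(np.radians(P + half))) * tan_t
    pred11 = q_nd * np.abs(np.sin(np.radians(P))) * tan_t

    cost = np.zeros_like(T)
    deg = [p for p in peaks
           if abs(p.q_xy_center - q_deg) <= abs(p.q_xy_center - q_nd)]
    nd = [p for p in peaks
          if abs(p.q_xy_center - q_deg) > abs(p.q_xy_center - q_nd)]
    if len(deg) == 1 and deg[0].multiplicity == 2:
        cost += (0.5 * (pred10 + pred01) - deg[0].q_z_center) ** 2
    else:
        # both orderings, take the better one pointwise at the end
        costA = np.zeros_like(T)
        costB = np.zeros_like(T)
        for i, p in enumerate(deg[:2]):
            costA += ([pred10, pred01][i] - p.q_z_center) ** 2
            costB += ([pred01, pred10][i] - p.q_z_center) ** 2
        cost += np.minimum(costA, costB)
    for p in nd:
        cost += (pred11 - p.q_z_center) ** 2
    i, j = np.unravel_index(np.argmin(cost), cost.shape)
    return float(thetas[i]), float(psis[j])


# ---------------------------------------------------------------------------
# map reduction
# ---------------------------------------------------------------------------

def integrate_map(
    q_xy: np.ndarray,
    q_z: np.ndarray,
    intensity: np.ndarray,
    q_z_range: tuple[float, float] = (0.0, 0.7),
) -> np.ndarray:
    """Trapezoidal q_z integral of the 2D map per q_xy column.

    ``intensity`` is shaped (n_qz, n_qxy); the default integration window is
    0.0–0.7 Å⁻¹, covering both Bragg rods of a condensed phospholipid.
    """
    q_z = np.asarray(q_z, float)
    lo, hi = q_z_range
    if hi <= lo:
        raise GixdError("empty q_z integration range")
    mask = (q_z >= lo) & (q_z <= hi)
    if mask.sum() < 2:
        raise GixdError("q_z range selects fewer than two rows")
    return np.trapezoid(np.asarray(intensity, float)[mask, :], q_z[mask], axis=0)


def fit_peaks(
    q_xy: np.ndarray,
    profile: np.ndarray,
    n_peaks: int,
    background: str = "linear",
    lineshape: str = "pseudo_voigt",
    centers_guess: Sequence[float] | None = None,
) -> tuple[list[BraggPeak], object]:
    """Fit ``n_peaks`` Voigt-type peaks plus background to a q_xy profile.

    Pseudo-Voigt is the default lineshape (exact Voigt available via
    ``lineshape='voigt'``).  Returns the peaks sorted by centre and the
    lmfit result for diagnostics.  Non-convergence raises, never returns
    silently wrong centres.
    """
    q_xy = np.asarray(q_xy, float)
    profile = np.asarray(profile, float)
    if n_peaks not in (1, 2, 3):
        raise GixdError("n_peaks must be 1, 2 or 3")
    if profile.size < 10 * n_peaks:
        raise GixdError("profile too short for requested number of peaks")

    if centers_guess is None:
        # crude guesses: local maxima of the background-flattened profile
        flat = profile - np.linspace(profile[0], profile[-1], profile.size)
        order = np.argsort(flat)[::-1]
        centers_guess = []
        for idx in order:
            c = q_xy[idx]
            if all(abs(c - g) > 0.03 for g in centers_guess):
                centers_guess.append(c)
            if len(centers_guess) == n_peaks:
                break
    centers_guess = sorted(centers_guess)

    Peak = VoigtModel if lineshape == "voigt" else PseudoVoigtModel
    model = LinearModel(prefix="bg_") if background == "linear" else ConstantModel(prefix="bg_")
    params = model.make_params(slope=0.0, intercept=float(np.min(profile)), c=float(np.min(profile)))
    span = q_xy[-1] - q_xy[0]
    amp0 = float(np.max(profile) - np.min(profile)) * 0.02
    for i, c in enumerate(centers_guess):
        pk = Peak(prefix=f"p{i}_")
        model = model + pk
        params.update(pk.make_params(center=c, sigma=0.01, amplitude=max(amp0, 1e-9)))
        params[f"p{i}_center"].set(min=q_xy[0], max=q_xy[-1])
        params[f"p{i}_sigma"].set(min=1e-5, max=span)
        params[f"p{i}_amplitude"].set(min=0.0)
    result = model.fit(profile, params, x=q_xy)
    if not result.success:
        raise GixdError(f"peak fit failed to converge: {result.message}")

    peaks = []
    for i in range(n_peaks):
        center = result.params[f"p{i}_center"].value
        fwhm = result.params[f"p{i}_fwhm"].value
        peaks.append(BraggPeak(
            q_xy_center=center,
            fwhm_xy=fwhm,
            amplitude=result.params[f"p{i}_amplitude"].value,
            q_xy_stderr=result.params[f"p{i}_center"].stderr,
        ))
    peaks.sort(key=lambda p: p.q_xy_center)
    return peaks, result


def extract_rod_maxima(
    q_xy: np.ndarray,
    q_z: np.ndarray,
    intensity: np.ndarray,
    peaks: Sequence[BraggPeak],
) -> list[BraggPeak]:
    """Fill q_z_center per peak by Gaussian fits of the Bragg-rod profiles.

    For each in-plane peak the map is averaged over a q_xy window of
    ±1 FWHM around the centre and the resulting rod profile fitted with a
    Gaussian plus constant.  A maximum at the grid edge is flagged via
    ``at_edge`` (a rod peaking at q_z = 0 is physical for untilted or
    NN-tilted chains, but its centre is only bounded by the grid).
    """
    q_xy = np.asarray(q_xy, float)
    q_z = np.asarray(q_z, float)
    out = []
    dz = np.median(np.diff(q_z))
    for p in peaks:
        w = max(p.fwhm_xy, 2 * np.median(np.diff(q_xy)))
        cols = (q_xy >= p.q_xy_center - w) & (q_xy <= p.q_xy_center + w)
        rod = np.asarray(intensity, float)[:, cols].mean(axis=1)
        model = GaussianModel(prefix="g_") + ConstantModel(prefix="bg_")
        c0 = float(q_z[np.argmax(rod)])
        params = model.make_params(
            g_center=c0, g_sigma=0.1,
            g_amplitude=float((rod.max() - rod.min()) * 0.25),
            bg_c=float(rod.min()),
        )
        params["g_center"].set(min=float(q_z[0]), max=float(q_z[-1]))
        params["g_sigma"].set(min=dz / 4)
        params["g_amplitude"].set(min=0.0)
        res = model.fit(rod, params, x=q_z)
        if not res.success:
            raise GixdError(f"rod fit failed: {res.message}")
        center = res.params["g_center"].value
        at_edge = center <= q_z[0] + dz / 2 or center >= q_z[-1] - dz / 2
        out.append(replace(
            p,
            q_z_center=max(center, 0.0),
            fwhm_z=res.params["g_fwhm"].value,
            q_z_stderr=res.params["g_center"].stderr,
            at_edge=at_edge,
        ))
    return out


def reduce_map(
    q_xy: np.ndarray,
    q_z: np.ndarray,
    intensity: np.ndarray,
    n_peaks: int = 2,
    q_z_range: tuple[float, float] = (0.0, 0.7),
    chains_per_molecule: int = 2,
    degenerate: str = "lower",
) -> LatticeSolution:
    """Full reduction of a GIXD map to a :class:`LatticeSolution`.

    ``degenerate`` selects which observed in-plane peak is treated as the
    doubly degenerate {1 0}/{0 1} pair; by standard distorted-hexagonal
    indexing this is the lower-q_xy peak (``'lower'``, default), but the
    assignment can be overridden with ``'upper'``.
    """
    profile = integrate_map(q_xy, q_z, intensity, q_z_range)
    peaks, _ = fit_peaks(q_xy, profile, n_peaks=n_peaks)
    peaks = extract_rod_maxima(q_xy, q_z, intensity, peaks)
    if degenerate == "lower":
        deg_peak, nd_peak = peaks[0], peaks[-1]
    else:
        deg_peak, nd_peak = peaks[-1], peaks[0]
    deg_peak.multiplicity = 2
    a, gamma = solve_cell(deg_peak.q_xy_center, nd_peak.q_xy_center)
    theta, psi, theta_err, psi_err = solve_tilt([deg_peak, nd_peak], (a, gamma))
    # first-order propagation of the in-plane centre uncertainties onto A_M
    area_err = None
    if deg_peak.q_xy_stderr is not None and nd_peak.q_xy_stderr is not None:
        eps = 1e-6
        grads = []
        for dq_deg, dq_nd in ((eps, 0.0), (0.0, eps)):
            a2, g2 = solve_cell(deg_peak.q_xy_center + dq_deg, nd_peak.q_xy_center + dq_nd)
            grads.append((area_per_molecule(a2, g2, chains_per_molecule)
                          - area_per_molecule(a, gamma, chains_per_molecule)) / eps)
        area_err = float(np.hypot(grads[0] * deg_peak.q_xy_stderr,
                                  grads[1] * nd_peak.q_xy_stderr))
    return LatticeSolution(
        a=a, gamma=gamma,
        tilt_theta=theta, tilt_psi=0.0 if np.isnan(psi) else psi,
        chains_per_molecule=chains_per_molecule,
        theta_stderr=theta_err, psi_stderr=psi_err, area_stderr=area_err,
    )


# ---------------------------------------------------------------------------
# isotherm
# ---------------------------------------------------------------------------

def limiting_area(
    isotherm: IsothermCurve,
    branch_window: tuple[float, float] = (20.0, 40.0),
) -> tuple[float, float]:
    """Limiting molecular area by extrapolating the condensed branch to π=0.

    A straight line is fitted to the points whose surface pressure lies in
    ``branch_window`` (default 20–40 mN/m, the condensed region) and
    extrapolated to zero pressure.  Returns ``(area, stderr)``.
    """
    A = isotherm.area_per_molecule
    pi = isotherm.surface_pressure
    mask = (pi >= branch_window[0]) & (pi <= branch_window[1])
    if mask.sum() < 5:
        raise GixdError("fewer than 5 isotherm points in the branch window")
    Aw, piw = A[mask], pi[mask]
    if not (np.all(np.diff(Aw) < 0) or np.all(np.diff(Aw) > 0)):
        raise GixdError("condensed branch is not monotone in area")
    coeffs, cov = np.polyfit(Aw, piw, 1, cov=True)
    slope, intercept = coeffs
    if abs(slope) < 1e-12:
        raise GixdError("zero-slope branch: limiting area undefined")
    a0 = -intercept / slope
    # delta method on a0 = -b/m
    g = np.array([intercept / slope**2, -1.0 / slope])
    err = float(np.sqrt(g @ cov @ g))
    return float(a0), err
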