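"""Forward optical model for whispering-gallery modes of a dielectric sphere.

A lipid droplet (refractive index ``n_LD`` ≈ 1.47) embedded in cytoplasm
(``n_cell`` ≈ 1.33–1.40) acts as a spherical optical microcavity.  Light
circulating near the inner surface by total internal reflection forms sharp
TE/TM resonances whose positions encode the droplet diameter and the index
contrast with the surroundings.

Two routes to the resonance positions are provided:

* :func:`asymptotic_mode_position` — the first-order radial-mode asymptotic
  expansion in the angular mode number, accurate to well below a line width
  for the large droplets (30–100 μm) considered here;
* :func:`exact_mode_position` — roots of the real Mie characteristic
  equations built from Riccati–Bessel functions, used as the numerical
  oracle for the expansion.

Conventions
-----------
* Size parameter ``x = π · n_cell · d / λ`` (diameter-based).
* Wavelengths are vacuum wavelengths in nm; diameters in μm.
* ``ρ = n_LD / n_cell > 1`` is required for guided modes.
* Radial order ``q = 1`` by default (modes hugging the surface).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq
from scipy.special import spherical_jn, spherical_yn

__all__ = [
    "AIRY_ZEROS",
    "OpticalConfig",
    "ModePrediction",
    "NoGuidedModeError",
    "asymptotic_mode_position",
    "asymptotic_size_parameter",
    "exact_mode_position",
    "mode_ladder",
    "fsr_from_geometry",
    "fsr_wavelength_spacing",
    "splitting_parameter",
    "invert_ncell_from_splitting",
    "apparent_size_shift_from_index",
    "penetration_depth",
]

#: First zeros of the Airy function Ai(-z); AIRY_ZEROS[q] is the q-th zero.
AIRY_ZEROS = {1: 2.338107410459767, 2: 4.087949444130970, 3: 5.520559828095551}

NM_PER_UM = 1000.0


class NoGuidedModeError(ValueError):
    """Raised when n_LD <= n_cell, so total internal reflection cannot
    confine light and no guided whispering-gallery modes exist."""


@dataclass(frozen=True)
class OpticalConfig:
    """Optical constants of the droplet-in-cytoplasm cavity.

    Parameters
    ----------
    n_ld : float
        Refractive index of the lipid droplet interior (triglycerides).
    n_cell : float
        Refractive index of the surrounding cytoplasm.
    radial_order : int
        Radial mode order q (number of radial field maxima); first-order
        modes hug the droplet surface.
    band_nm : tuple of float
        Wavelength window (λ_lo, λ_hi) of the dye emission used for sensing.
    expansion_order : int
        Highest inverse power of ν retained in the asymptotic expansion:
        1 keeps terms through ν^(−1/3), 2 (default) through ν^(−2/3).
    """

    n_ld: float = 1.47
    n_cell: float = 1.36
    radial_order: int = 1
    band_nm: tuple[float, float] = (590.0, 650.0)
    expansion_order: int = 2

    def __post_init__(self) -> None:
        if self.n_cell <= 1.0:
            raise ValueError(f"n_cell must exceed 1 (got {self.n_cell})")
        if self.n_ld <= self.n_cell:
            raise NoGuidedModeError(
                f"n_LD ({self.n_ld}) must exceed n_cell ({self.n_cell}) "
                "for guided whispering-gallery modes"
            )
        if self.radial_order < 1:
            raise ValueError("radial_order must be a positive integer")
        if self.radial_order not in AIRY_ZEROS:
            raise ValueError(
                f"radial_order {self.radial_order} not supported "
                f"(have Airy zeros for q in {sorted(AIRY_ZEROS)})"
            )
        if not self.band_nm[0] < self.band_nm[1]:
            raise ValueError("band_nm must satisfy λ_lo < λ_hi")
        if self.expansion_order not in (1, 2):
            raise ValueError("expansion_order must be 1 or 2")

    @property
    def ratio(self) -> float:
        """Index ratio ρ = n_LD / n_cell (> 1)."""
        return self.n_ld / self.n_cell

    @property
    def airy_zero(self) -> float:
        """q-th zero of the Airy function for the configured radial order."""
        return AIRY_ZEROS[self.radial_order]

    def with_ncell(self, n_cell: float) -> "OpticalConfig":
        return replace(self, n_cell=n_cell)


@dataclass(frozen=True)
class ModePrediction:
    """A single predicted resonance."""

    ell: int
    polarization: str  # "TE" | "TM"
    wavelength_nm: float
    size_parameter: float  # x = π n_cell d / λ
    d_um: float

    @property
    def nu(self) -> float:
        return self.ell + 0.5


def _polarization_parameter(polarization: str, rho: float) -> float:
    """P = ρ for TE, 1/ρ for TM (the two polarization families of a sphere)."""
    pol = polarization.upper()
    if pol == "TE":
        return rho
    if pol == "TM":
        return 1.0 / rho
    raise ValueError(f"polarization must be 'TE' or 'TM', got {polarization!r}")


MIN_ELL = 50  # below this the asymptotic expansion is unreliable


def asymptotic_size_parameter(
    ell: int, polarization: str, cfg: OpticalConfig
) -> float:
    """Scaled size parameter ``F = ρ·x = π·n_LD·d/λ`` of mode (ℓ, pol).

    Evaluates the asymptotic expansion

        F(ν) = ν + 2^(−1/3)·α_q·ν^(1/3) − P/√(ρ²−1)
             + (3/10)·2^(−2/3)·α_q²·ν^(−1/3)
             − 2^(−1/3)·P·(ρ² − 2P²/3)·α_q·ν^(−2/3) / (ρ²−1)^(3/2)

    with ν = ℓ + 1/2, α_q the q-th Airy zero and P the polarization
    parameter.  F is independent of the droplet diameter, which is why the
    resonance wavelength scales exactly linearly with d at fixed ℓ.
    """
    if ell < MIN_ELL:
        raise ValueError(
            f"angular mode number ℓ={ell} below minimum {MIN_ELL}; the "
            "asymptotic expansion is not accurate for such small spheres"
        )
    rho = cfg.ratio
    if rho <= 1.0:
        raise NoGuidedModeError("index ratio must exceed 1")
    alpha = cfg.airy_zero
    P = _polarization_parameter(polarization, rho)
    nu = ell + 0.5
    contrast = math.sqrt(rho * rho - 1.0)
    F = (
        nu
        + 2.0 ** (-1.0 / 3.0) * alpha * nu ** (1.0 / 3.0)
        - P / contrast
        + 0.3 * 2.0 ** (-2.0 / 3.0) * alpha * alpha * nu ** (-1.0 / 3.0)
    )
    if cfg.expansion_order >= 2:
        F -= (
            2.0 ** (-1.0 / 3.0)
            * P
            * (rho * rho - 2.0 * P * P / 3.0)
            * alpha
            * nu ** (-2.0 / 3.0)
            / contrast**3
        )
    return F


def asymptotic_mode_position(
    ell: int, polarization: str, d_um: float, cfg: OpticalConfig
) -> float:
    """Resonance wavelength (nm) of mode (ℓ, polarization) for diameter d (μm).

    Solves π·n_LD·d/λ = F(ν) for λ, with F the asymptotic expansion above.
    """
    if d_um <= 0:
        raise ValueError("diameter must be positive")
    F = asymptotic_size_parameter(ell, polarization, cfg)
    return math.pi * cfg.n_ld * d_um * NM_PER_UM / F


def _riccati_psi(ell: int, z: float) -> tuple[float, float]:
    """Riccati–Bessel ψ_ℓ(z) = z·j_ℓ(z) and its derivative."""
    j = spherical_jn(ell, z)
    jp = spherical_jn(ell, z, derivative=True)
    return z * j, j + z * jp


def _riccati_chi(ell: int, z: float) -> tuple[float, float]:
    """Riccati–Bessel χ_ℓ(z) = −z·y_ℓ(z) and its derivative."""
    y = spherical_yn(ell, z)
    yp = spherical_yn(ell, z, derivative=True)
    return -z * y, -(y + z * yp)


def _characteristic(ell: int, polarization: str, rho: float, x: float) -> float:
    """Real Mie characteristic function whose roots are the resonances.

    TE:  ψ_ℓ(ρx)·χ_ℓ′(x) − ρ·χ_ℓ(x)·ψ_ℓ′(ρx)
    TM:  ρ·ψ_ℓ(ρx)·χ_ℓ′(x) − χ_ℓ(x)·ψ_ℓ′(ρx)

    (narrow-resonance approximation: χ replaces the outgoing Hankel
    function, so roots give positions but not widths).
    """
    psi, psip = _riccati_psi(ell, rho * x)
    chi, chip = _riccati_chi(ell, x)
    pol = polarization.upper()
    if pol == "TE":
        return psi * chip - rho * chi * psip
    if pol == "TM":
        return rho * psi * chip - chi * psip
    raise ValueError(f"polarization must be 'TE' or 'TM', got {polarization!r}")


def exact_mode_position(
    ell: int,
    polarization: str,
    d_um: float,
    cfg: OpticalConfig,
    bracket_nm: float = 3.0,
) -> float:
    """Resonance wavelength (nm) from the exact Mie characteristic equation.

    The q-th root in the size parameter x = π·n_cell·d/λ is bracketed within
    ``bracket_nm`` of the asymptotic prediction and refined by Brent's
    method; the root is then converted back to wavelength.  Serves as the
    independent numerical oracle for :func:`asymptotic_mode_position`.
    """
    lam0 = asymptotic_mode_position(ell, polarization, d_um, cfg)
    d_nm = d_um * NM_PER_UM
    x0 = math.pi * cfg.n_cell * d_nm / lam0
    # λ ± bracket_nm maps to a decreasing interval in x
    x_lo = math.pi * cfg.n_cell * d_nm / (lam0 + bracket_nm)
    x_hi = math.pi * cfg.n_cell * d_nm / (lam0 - bracket_nm)
    rho = cfg.ratio

    f = lambda x: _characteristic(ell, polarization, rho, x)

    # scan for a sign change; the characteristic function oscillates with
    # period ~π/ρ in x, so sample densely relative to that
    n_scan = max(32, int(8 * (x_hi - x_lo) * rho / math.pi))
    xs = np.linspace(x_lo, x_hi, n_scan)
    vals = np.array([f(x) for x in xs])
    sign_changes = np.nonzero(np.diff(np.sign(vals)) != 0)[0]
    if len(sign_changes) == 0:
        raise RuntimeError(
            f"no Mie root within ±{bracket_nm} nm of the asymptotic "
            f"prediction for ℓ={ell} {polarization} d={d_um} μm"
        )
    # pick the sign change closest to the asymptotic estimate
    i = sign_changes[np.argmin(np.abs(0.5 * (xs[sign_changes] + xs[sign_changes + 1]) - x0))]
    root = brentq(f, xs[i], xs[i + 1], xtol=1e-12, rtol=8.9e-16)
    return math.pi * cfg.n_cell * d_nm / root


def mode_ladder(
    d_um: float,
    cfg: OpticalConfig,
    polarizations: tuple[str, ...] = ("TE", "TM"),
    band_nm: tuple[float, float] | None = None,
    model: str = "asymptotic",
) -> list[ModePrediction]:
    """All first-order radial modes with wavelengths inside the band.

    Returns predictions sorted by ascending wavelength.  ``model`` selects
    the asymptotic expansion (default) or the exact Mie roots.
    """
    if band_nm is None:
        band_nm = cfg.band_nm
    lo, hi = band_nm
    d_nm = d_um * NM_PER_UM
    position = {
        "asymptotic": asymptotic_mode_position,
        "exact": exact_mode_position,
    }[model]
    out: list[ModePrediction] = []
    for pol in polarizations:
        # invert λ = π n_LD d / F(ν) with F ≈ ν to bracket the ℓ range
        ell_hi = int(math.pi * cfg.n_ld * d_nm / lo) + 2
        ell_lo = max(MIN_ELL, int(math.pi * cfg.n_ld * d_nm / hi) - int(3 * d_um**(1/3)) - 5)
        for ell in range(ell_lo, ell_hi + 1):
            lam = position(ell, pol, d_um, cfg)
            if lo <= lam <= hi:
                x = math.pi * cfg.n_cell * d_nm / lam
                out.append(ModePrediction(ell, pol, lam, x, d_um))
    out.sort(key=lambda m: m.wavelength_nm)
    return out


def fsr_from_geometry(n_eff: float, d_um: float) -> float:
    """Free spectral range in inverse wavelength, FSR = 1/(π·n_eff·d), nm⁻¹.

    Consecutive whispering-gallery modes are evenly spaced in 1/λ with this
    spacing; n_eff is the effective index governing the optical path
    (dominated by the droplet index).
    """
    if n_eff <= 1.0:
        raise ValueError("n_eff must exceed 1")
    if d_um <= 0:
        raise ValueError("diameter must be positive")
    return 1.0 / (math.pi * n_eff * d_um * NM_PER_UM)


def fsr_wavelength_spacing(n_eff: float, d_um: float, wavelength_nm: float) -> float:
    """Mode spacing in wavelength, Δλ ≈ λ²/(π·n_eff·d), nm."""
    return wavelength_nm**2 * fsr_from_geometry(n_eff, d_um)


def splitting_parameter(rho: float) -> float:
    """Leading-order TE–TM splitting S = √(ρ²−1)/ρ in normalized mode units.

    At equal angular mode number the TE and TM resonances differ by
    S = P_TM − P_TE summed into the −P/√(ρ²−1) term of the expansion:
    x_TM − x_TE = (ρ − 1/ρ)/√(ρ²−1) = √(ρ²−1)/ρ.  S vanishes at index
    matching (ρ→1⁺) and grows monotonically with contrast, S ∈ (0, 1).
    """
    if rho <= 1.0:
        raise NoGuidedModeError(f"index ratio must exceed 1, got {rho}")
    return math.sqrt(rho * rho - 1.0) / rho


def invert_ncell_from_splitting(S: float, n_ld: float) -> float:
    """Cytoplasm index from the splitting parameter: n_cell = n_LD·√(1−S²).

    Exact inverse of :func:`splitting_parameter` (since
    S² = 1 − 1/ρ²  ⇒  ρ = 1/√(1−S²)); used as the initializer for the
    model-based refit in the size-and-index inference.
    """
    if not 0.0 <= S < 1.0:
        raise ValueError(f"splitting parameter must lie in [0, 1), got {S}")
    if n_ld <= 1.0:
        raise ValueError("n_LD must exceed 1")
    return n_ld * math.sqrt(1.0 - S * S)


def apparent_size_shift_from_index(
    delta_ncell: float,
    d_um: float,
    wavelength_nm: float,
    cfg: OpticalConfig,
    polarization: str = "TM",
) -> float:
    """Diameter error (nm) made by a fixed-index analysis when n_cell drifts.

    The resonance positions are computed with the cytoplasm index perturbed
    by ``delta_ncell``; the diameter is then re-inferred holding the
    original index.  Because λ ∝ d at fixed ℓ, the apparent diameter change
    is Δd = d·(λ_perturbed − λ)/λ.  A red shift (n_cell increase) is read
    as droplet growth, so the sign of Δd follows the sign of Δn_cell.

    First-order closed form: Δd/d = (1/F)·∂[P/√(ρ²−1)]/∂n_cell·Δn_cell
    with F = π·n_LD·d/λ; the numerical forward-model difference implemented
    here agrees with it to first order and is the operative definition.
    """
    if delta_ncell == 0.0:
        return 0.0
    d_nm = d_um * NM_PER_UM
    # pick ℓ whose unperturbed resonance is closest to the requested λ
    F_target = math.pi * cfg.n_ld * d_nm / wavelength_nm
    ell = max(MIN_ELL, round(F_target))
    # walk to the closest mode
    best_ell, best_err = ell, float("inf")
    for cand in range(ell - 3, ell + 4):
        lam = asymptotic_mode_position(cand, polarization, d_um, cfg)
        err = abs(lam - wavelength_nm)
        if err < best_err:
            best_ell, best_err = cand, err
    lam0 = asymptotic_mode_position(best_ell, polarization, d_um, cfg)
    cfg_pert = cfg.with_ncell(cfg.n_cell + delta_ncell)
    lam1 = asymptotic_mode_position(best_ell, polarization, d_um, cfg_pert)
    return d_nm * (lam1 - lam0) / lam0


def penetration_depth(wavelength_nm: float, n_ld: float, n_cell: float) -> float:
    """1/e decay length (nm) of the evanescent field outside the droplet.

    λ/(4π·√(n_LD²−n_cell²)): the reach over which the resonances sense the
    surrounding cytoplasm (~90 nm for typical indices at 620 nm).
    """
    if n_ld <= n_cell:
        raise ValueError("evanescent decay requires n_LD > n_cell")
    return wavelength_nm / (4.0 * math.pi * math.sqrt(n_ld**2 - n_cell**2))
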