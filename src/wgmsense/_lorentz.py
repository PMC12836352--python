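"""Low-level Lorentzian-comb least squares shared by SNR estimation and
peak fitting.

The comb model is a superposition of unit-area Lorentzians with per-line
amplitude scale factors,

    L(λ) = Σ_i A_i · (1/2π) · Γ_i / [(λ − λ_i)² + (Γ_i/2)²],

so ``A_i·2/(π·Γ_i)`` is the line's peak height.  The width may be shared
across lines (default: all resonances inherit the same cavity linewidth)
or free per line.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import least_squares

__all__ = ["comb_model", "fit_comb", "CombFit"]


def comb_model(
    wl: np.ndarray, centers: np.ndarray, amps: np.ndarray, gammas: np.ndarray
) -> np.ndarray:
    """Evaluate the Lorentzian superposition on the wavelength grid."""
    wl = np.asarray(wl, float)[:, None]
    centers = np.asarray(centers, float)[None, :]
    amps = np.asarray(amps, float)[None, :]
    gammas = np.asarray(gammas, float)[None, :]
    return np.sum(
        amps * gammas / (2.0 * np.pi) / ((wl - centers) ** 2 + (gammas / 2.0) ** 2),
        axis=1,
    )


class CombFit:
    """Result of a comb fit: refined centers, widths, amplitudes,
    covariance-based center uncertainties and residual diagnostics."""

    def __init__(
        self, centers, amps, gammas, sigma_centers, residual, converged,
        background=None, wl_span=None,
    ):
        self.centers = centers
        self.amps = amps
        self.gammas = gammas
        self.sigma_centers = sigma_centers
        self.residual = residual  # per-sample residual array
        self.converged = converged
        self.background = background  # Legendre coefficients or None
        self.wl_span = wl_span

    @property
    def rms(self) -> float:
        return float(np.sqrt(np.mean(self.residual**2)))

    def model(self, wl: np.ndarray, include_background: bool = True) -> np.ndarray:
        out = comb_model(wl, self.centers, self.amps, self.gammas)
        if include_background and self.background is not None:
            out = out + self._background_basis(wl) @ self.background
        return out

    def _background_basis(self, wl: np.ndarray) -> np.ndarray:
        lo, hi = self.wl_span
        x = 2.0 * (np.asarray(wl, float) - lo) / (hi - lo) - 1.0
        return np.polynomial.legendre.legvander(x, len(self.background) - 1)


def _pack(centers, amps, gamma, shared):
    if shared:
        return np.concatenate([[gamma[0]], amps, centers])
    return np.concatenate([gamma, amps, centers])


def _unpack(p, n, shared):
    if shared:
        return p[1 + n:], p[1: 1 + n], np.full(n, p[0])
    return p[2 * n:], p[n: 2 * n], p[:n]


def fit_comb(
    wl: np.ndarray,
    y: np.ndarray,
    centers0: np.ndarray,
    amps0: np.ndarray,
    gamma0: float,
    shared_width: bool = True,
    center_window_nm: float | None = None,
    background_degree: int | None = 5,
) -> CombFit:
    """Least-squares refinement of a Lorentzian comb.

    ``centers0``/``amps0`` are coarse detections (amplitudes as peak
    heights); ``gamma0`` the initial FWHM.  Centers are bounded within
    ``center_window_nm`` of their initial values (default: just under half
    the median spacing, so lines cannot swap).  A low-order Legendre
    background absorbs what baseline subtraction leaves of the inter-line
    tail pedestal.  Uses an analytic Jacobian.
    """
    wl = np.asarray(wl, float)
    y = np.asarray(y, float)
    centers0 = np.asarray(centers0, float)
    n = len(centers0)
    if n == 0:
        raise ValueError("no peaks to fit")
    order = np.argsort(centers0)
    centers0 = centers0[order]
    amps0 = np.asarray(amps0, float)[order]
    # convert peak heights to unit-area amplitude scales
    area0 = np.clip(amps0, 1e-12, None) * np.pi * gamma0 / 2.0
    if center_window_nm is None:
        spacing = np.median(np.diff(centers0)) if n > 1 else wl[-1] - wl[0]
        center_window_nm = min(max(0.45 * spacing, 1.0 * gamma0), 0.49 * spacing if n > 1 else np.inf)

    nb = 0 if background_degree is None else background_degree + 1
    span = (wl[0], wl[-1])
    if nb:
        x = 2.0 * (wl - span[0]) / (span[1] - span[0]) - 1.0
        bg_basis = np.polynomial.legendre.legvander(x, background_degree)

    def split(p):
        c, a, g = _unpack(p[: len(p) - nb], n, shared_width)
        b = p[len(p) - nb:] if nb else None
        return c, a, g, b

    def residual(p):
        c, a, g, b = split(p)
        m = comb_model(wl, c, a, g)
        if nb:
            m = m + bg_basis @ b
        return m - y

    def jacobian(p):
        c, a, g, b = split(p)
        dl = wl[:, None] - c[None, :]
        denom = dl**2 + (g[None, :] / 2.0) ** 2
        base = g[None, :] / (2.0 * np.pi) / denom  # dL/dA per line
        d_amp = base
        d_center = a[None, :] * base * 2.0 * dl / denom
        d_gamma_per = (
            a[None, :]
            / (2.0 * np.pi)
            * (1.0 / denom - g[None, :] ** 2 / (2.0 * denom**2))
        )
        cols = []
        if shared_width:
            cols.append(d_gamma_per.sum(axis=1, keepdims=True))
        else:
            cols.append(d_gamma_per)
        cols.append(d_amp)
        cols.append(d_center)
        if nb:
            cols.append(bg_basis)
        return np.concatenate(cols, axis=1)

    p0 = _pack(centers0, area0, np.full(n, gamma0), shared_width)
    ng = 1 if shared_width else n
    lo = np.concatenate(
        [np.full(ng, gamma0 / 10.0), np.zeros(n), centers0 - center_window_nm]
    )
    hi = np.concatenate(
        [np.full(ng, gamma0 * 10.0), np.full(n, np.inf), centers0 + center_window_nm]
    )
    if nb:
        p0 = np.concatenate([p0, np.zeros(nb)])
        lo = np.concatenate([lo, np.full(nb, -np.inf)])
        hi = np.concatenate([hi, np.full(nb, np.inf)])
    sol = least_squares(
        residual, p0, jac=jacobian, bounds=(lo, hi), method="trf", x_scale="jac"
    )
    c, a, g, b = split(sol.x)
    res = sol.fun
    dof = max(len(wl) - len(sol.x), 1)
    s2 = float(res @ res) / dof
    # covariance of the center parameters from (JᵀJ)⁻¹, Moore–Penrose if singular
    J = sol.jac
    try:
        cov = np.linalg.pinv(J.T @ J) * s2
        diag = np.clip(np.diag(cov), 0.0, None)
        sigma_all = np.sqrt(diag)
        ic = len(sol.x) - nb - n
        sigma_centers = sigma_all[ic: ic + n]
    except np.linalg.LinAlgError:
        sigma_centers = np.full(n, np.nan)
    return CombFit(c, a, g, sigma_centers, res, sol.status > 0, b, span)
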