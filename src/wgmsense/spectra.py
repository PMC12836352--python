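"""Spectrum container, file I/O, preprocessing and SNR estimation.

Raw inputs are two-column wavelength (nm) / intensity tables written by the
spectrometer, either comma- or whitespace-delimited, optionally with a
header line.  Time-lapse experiments are stored as one file per time point
plus a manifest CSV (columns ``cell_id, t_min, path``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter, percentile_filter
from scipy.signal import find_peaks, peak_widths

__all__ = [
    "SpectrumMeta",
    "Spectrum",
    "SpectrumParseError",
    "read_spectrum",
    "write_spectrum",
    "read_manifest",
    "write_manifest",
    "preprocess",
    "estimate_snr",
    "noise_sigma",
    "SNR_CAP",
]

#: Cap applied to SNR estimates (noiseless synthetic spectra are reported
#: at the cap rather than infinity).
SNR_CAP = 1.0e4

MIN_SAMPLES = 16


class SpectrumParseError(ValueError):
    """Raised when a spectrum file cannot be parsed."""


@dataclass(frozen=True)
class SpectrumMeta:
    """Acquisition metadata carried alongside every spectrum."""

    cell_id: str = ""
    t_min: float = 0.0
    source: str = "CW"  # CW | pulsed
    exposure_s: float = 1.0
    resolution_nm: float = 0.07
    baseline_method: str | None = None
    #: peak intensity removed by normalization; lets downstream code
    #: compare raw amplitudes between spectra while staying invariant
    #: under a common rescaling of the raw inputs
    norm_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.resolution_nm <= 0:
            raise ValueError("instrument resolution must be positive")


@dataclass(frozen=True)
class Spectrum:
    """An emission spectrum on a strictly ascending wavelength grid."""

    wavelengths: np.ndarray  # nm, strictly ascending
    intensities: np.ndarray  # arbitrary units
    meta: SpectrumMeta = field(default_factory=SpectrumMeta)

    def __post_init__(self) -> None:
        w = np.asarray(self.wavelengths, dtype=float)
        i = np.asarray(self.intensities, dtype=float)
        if w.ndim != 1 or i.ndim != 1 or len(w) != len(i):
            raise ValueError("wavelengths and intensities must be 1-D and equal length")
        if len(w) and not np.all(np.diff(w) > 0):
            raise ValueError("wavelength grid must be strictly ascending")
        object.__setattr__(self, "wavelengths", w)
        object.__setattr__(self, "intensities", i)

    def __len__(self) -> int:
        return len(self.wavelengths)

    @property
    def step_nm(self) -> float:
        """Median sampling step of the grid."""
        return float(np.median(np.diff(self.wavelengths)))

    @property
    def band_nm(self) -> tuple[float, float]:
        return float(self.wavelengths[0]), float(self.wavelengths[-1])

    def with_intensities(self, intensities: np.ndarray, **meta_updates) -> "Spectrum":
        meta = replace(self.meta, **meta_updates) if meta_updates else self.meta
        return Spectrum(self.wavelengths, np.asarray(intensities, float), meta)


def _parse_two_columns(path: Path, dialect: str) -> tuple[np.ndarray, np.ndarray]:
    sep = "," if dialect == "csv" else None
    wl, it, bad = [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(sep) if sep else line.split()
            parts = [p for p in parts if p != ""]
            if len(parts) < 2:
                bad.append(lineno)
                continue
            try:
                wl.append(float(parts[0]))
                it.append(float(parts[1]))
            except ValueError:
                if lineno == 1:  # header line
                    continue
                bad.append(lineno)
    if bad:
        raise SpectrumParseError(
            f"{path}: unparseable rows at lines {bad[:20]}"
            + (" ..." if len(bad) > 20 else "")
        )
    return np.array(wl), np.array(it)


def read_spectrum(
    path: str | Path, dialect: str | None = None, meta: SpectrumMeta | None = None
) -> Spectrum:
    """Read a two-column wavelength/intensity table.

    ``dialect`` is ``"csv"`` or ``"whitespace"``; when omitted it is guessed
    from the file extension.  Non-monotone grids are sorted (with a
    warning) and duplicate wavelengths averaged.
    """
    path = Path(path)
    if dialect is None:
        dialect = "csv" if path.suffix.lower() == ".csv" else "whitespace"
    if dialect not in ("csv", "whitespace"):
        raise ValueError(f"unknown dialect {dialect!r}")
    wl, it = _parse_two_columns(path, dialect)
    if len(wl) < MIN_SAMPLES:
        raise SpectrumParseError(
            f"{path}: only {len(wl)} samples; at least {MIN_SAMPLES} required"
        )
    if not np.all(np.diff(wl) > 0):
        warnings.warn(f"{path}: wavelength grid not strictly ascending; sorting")
        order = np.argsort(wl, kind="stable")
        wl, it = wl[order], it[order]
        if np.any(np.diff(wl) == 0):
            uniq, inv = np.unique(wl, return_inverse=True)
            summed = np.bincount(inv, weights=it)
            counts = np.bincount(inv)
            wl, it = uniq, summed / counts
    return Spectrum(wl, it, meta or SpectrumMeta())


def write_spectrum(path: str | Path, s: Spectrum, dialect: str | None = None) -> None:
    """Write a spectrum as a two-column text table (bit-exact at float64)."""
    path = Path(path)
    if dialect is None:
        dialect = "csv" if path.suffix.lower() == ".csv" else "whitespace"
    sep = "," if dialect == "csv" else " "
    with open(path, "w") as fh:
        fh.write(f"wavelength_nm{sep}intensity\n")
        for w, i in zip(s.wavelengths, s.intensities):
            fh.write(f"{w:.17g}{sep}{i:.17g}\n")


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a time-series manifest CSV with columns cell_id, t_min, path."""
    df = pd.read_csv(path, dtype={"cell_id": str})
    missing = {"cell_id", "t_min", "path"} - set(df.columns)
    if missing:
        raise SpectrumParseError(f"manifest {path} missing columns {sorted(missing)}")
    return df.sort_values(["cell_id", "t_min"]).reset_index(drop=True)


def write_manifest(path: str | Path, df: pd.DataFrame) -> None:
    df.to_csv(path, index=False)


def _window_points(s: Spectrum, factor: float) -> int:
    window = int(round(factor * s.meta.resolution_nm / s.step_nm))
    return max(3, min(window | 1, len(s) // 2 * 2 - 1))  # odd, < length


def _rolling_median_baseline(s: Spectrum) -> np.ndarray:
    return median_filter(
        s.intensities, size=_window_points(s, 20.0), mode="nearest"
    )


def _rolling_percentile_baseline(s: Spectrum) -> np.ndarray:
    """Valley-floor baseline: 10th percentile over a window of 40
    instrument resolution elements.

    Unlike a median over a mode-spacing-sized window — which tracks the
    resonance comb itself and clips away valley noise — the low percentile
    follows only the slowly varying background, so the comb shape and the
    noise statistics survive subtraction.
    """
    return percentile_filter(
        s.intensities, 10, size=_window_points(s, 40.0), mode="nearest"
    )


def _polynomial_baseline(s: Spectrum, degree: int) -> np.ndarray:
    """Lower-envelope polynomial baseline via iterative clipping."""
    x = s.wavelengths - s.wavelengths.mean()
    y = s.intensities.copy()
    mask = np.ones(len(y), dtype=bool)
    coef = np.polyfit(x[mask], y[mask], degree)
    for _ in range(8):
        fit = np.polyval(coef, x)
        resid = y - fit
        sigma = resid[mask].std() or 1.0
        new_mask = resid < 1.0 * sigma  # drop points sitting on peaks
        if new_mask.sum() < degree + 2 or np.array_equal(new_mask, mask):
            break
        mask = new_mask
        coef = np.polyfit(x[mask], y[mask], degree)
    return np.polyval(coef, x)


def preprocess(s: Spectrum, baseline_method: str = "rolling-percentile") -> Spectrum:
    """Background-subtract, clip at zero and peak-normalize a raw spectrum.

    ``baseline_method`` is ``"rolling-percentile"`` (default; 10th
    percentile over a window of 40 instrument resolution elements — a
    valley-floor estimate that does not eat into the resonance comb),
    ``"rolling-median"`` (window of 20 resolution elements) or
    ``"polynomial(k)"`` for a degree-k lower-envelope polynomial.  The
    method used is recorded in the metadata.  Idempotent up to numerical
    noise.
    """
    if not np.any(s.intensities != 0):
        raise ValueError("cannot preprocess an all-zero spectrum")
    if baseline_method == "rolling-percentile":
        base = _rolling_percentile_baseline(s)
    elif baseline_method == "rolling-median":
        base = _rolling_median_baseline(s)
    elif baseline_method.startswith("polynomial"):
        inside = baseline_method[len("polynomial"):].strip("()")
        degree = int(inside) if inside else 2
        base = _polynomial_baseline(s, degree)
    else:
        raise ValueError(f"unknown baseline method {baseline_method!r}")
    cleaned = np.clip(s.intensities - base, 0.0, None)
    peak = cleaned.max()
    if peak > 0:
        cleaned = cleaned / peak
    return s.with_intensities(
        cleaned,
        baseline_method=baseline_method,
        norm_scale=s.meta.norm_scale * (peak if peak > 0 else 1.0),
    )


_DIFF_NORM = {2: np.sqrt(6.0), 3: np.sqrt(20.0)}


def noise_sigma(
    intensities: np.ndarray, mask: np.ndarray | None = None, order: int = 2
) -> float:
    """Rough noise standard deviation from finite differences.

    For additive white noise, std(Δ²I) = √6·σ and std(Δ³I) = √20·σ;
    smooth spectral structure contributes only high-order curvature, which
    shrinks with each difference order.  When a mask is given, differences
    are taken within contiguous masked runs only.  Returns NaN when too
    few samples are available.
    """
    y = np.asarray(intensities, float)
    if mask is None:
        d = np.diff(y, n=order)
    else:
        idx = np.nonzero(np.asarray(mask, bool))[0]
        pieces = [
            np.diff(y[run], n=order)
            for run in np.split(idx, np.nonzero(np.diff(idx) > 1)[0] + 1)
            if len(run) >= order + 2
        ]
        if not pieces:
            return float("nan")
        d = np.concatenate(pieces)
    if len(d) < 2:
        return float("nan")
    mad = np.median(np.abs(d - np.median(d)))
    return float(1.4826 * mad / _DIFF_NORM[order])


def _coarse_peaks(s: Spectrum) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Quick local-maximum scan used by the SNR estimator (indices,
    amplitudes, FWHM widths in nm)."""
    y = s.intensities
    sigma = noise_sigma(y)
    floor = max(5.0 * sigma, 1e-3 * y.max()) if np.isfinite(sigma) else 1e-3 * y.max()
    distance = max(1, int(round(2.0 * s.meta.resolution_nm / s.step_nm)))
    idx, props = find_peaks(y, prominence=floor, distance=distance)
    if len(idx) == 0:
        return idx, np.array([]), np.array([])
    widths_pts = peak_widths(y, idx, rel_height=0.5)[0]
    return idx, y[idx], widths_pts * s.step_nm


def estimate_snr(s: Spectrum) -> float:
    """Signal-to-noise ratio of a preprocessed spectrum.

    Defined as the mean fitted peak amplitude divided by the standard
    deviation of the comb-fit residuals in peak-free regions (the grid
    minus ±3Γ around each detected peak), capped at :data:`SNR_CAP`
    (noiseless synthetic data reports the cap).  Returns NaN when no
    peaks are detectable (pure noise / flat spectrum).  The estimate is
    invariant under rescaling of the intensities.
    """
    from ._lorentz import fit_comb

    idx, amps, widths = _coarse_peaks(s)
    wl, y = s.wavelengths, s.intensities
    rough = noise_sigma(y)
    if not np.isfinite(rough):
        rough = 0.0
    # gate against pure-noise spikes masquerading as a comb
    if len(idx) < 3 or (rough > 0 and amps.mean() < 10.0 * rough):
        return float("nan")
    gamma0 = float(np.clip(np.median(widths), s.meta.resolution_nm, None))
    fit = fit_comb(wl, y, wl[idx], y[idx], gamma0)
    heights = fit.amps * 2.0 / (np.pi * fit.gammas)
    mask = np.ones(len(wl), dtype=bool)
    for c, g in zip(fit.centers, fit.gammas):
        mask &= np.abs(wl - c) > 3.0 * g
    if mask.sum() < 16:
        mask = np.ones(len(wl), dtype=bool)
    # noise floor from high-order differences in the peak-free region:
    # insensitive to smooth comb-model mismatch, so it cleanly separates
    # a genuinely noiseless spectrum (floor ≈ 0 → cap) from a noisy one
    floor = noise_sigma(y, mask, order=3)
    if not np.isfinite(floor):
        floor = noise_sigma(y, mask, order=2)
    if np.isfinite(floor) and (floor <= 0 or heights.mean() / floor > SNR_CAP):
        return SNR_CAP
    r = (y - fit.model(wl))[mask]
    sigma = 1.4826 * float(np.median(np.abs(r - np.median(r))))
    if sigma <= 0 or heights.mean() / sigma > SNR_CAP:
        return SNR_CAP
    return float(heights.mean() / sigma)
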