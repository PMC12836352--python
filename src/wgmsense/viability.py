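"""Cell-state diagnostics from spectral features.

Damaged cells announce themselves in the whispering-gallery spectrum
before they are visible morphologically: resonances jump from broad
subthreshold lines to narrow, intense lasing-like lines; TE–TM mode
splitting grows as extracellular fluid dilutes the cytoplasm and lowers
its refractive index (membrane rupture); and droplets of damaged cells
stop changing size while healthy neighbours keep remodeling.

The three corresponding flags are driven by explicit, configurable
thresholds.  The defaults were chosen to separate the bundled synthetic
scenarios and are not claimed to be biological constants.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.signal import correlate

from .sizing import SizeTrack, min_resolvable_change
from .spectra import Spectrum

__all__ = [
    "ViabilityThresholds",
    "ViabilityFlags",
    "spectral_transition_score",
    "classify_state",
]


@dataclass(frozen=True)
class ViabilityThresholds:
    """Thresholds and weights of the viability classifier.

    ``weights`` multiply the three components of the transition score
    (spectral decorrelation, amplitude jump, linewidth change).
    ``rupture_dncell`` is the per-step drop in the fitted cytoplasm index
    that flags membrane rupture (the observed ruptures show drops of
    ~0.03).  ``static_window_h`` and ``static_factor`` define the
    static-size criterion: within any window of that length the droplet
    moved less than ``static_factor`` × (Δd)_min while the population
    median exceeded it.
    """

    weights: tuple[float, float, float] = (0.3, 0.4, 0.3)
    lasing_score: float = 0.5
    rupture_dncell: float = 0.01
    static_window_h: float = 3.0
    static_factor: float = 3.0


@dataclass
class ViabilityFlags:
    """Flags for one cell at one time point, with supporting evidence."""

    cell_id: str
    t_min: float
    transition_score: float
    lasing_flag: bool = False
    rupture_flag: bool = False
    static_flag: bool = False
    evidence: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, default=float)


def _component_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """1 − normalized cross-correlation at the best lag, clipped to [0, 1]."""
    a = (a - a.mean())
    b = (b - b.mean())
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 1.0
    cc = correlate(a, b, mode="full") / (na * nb)
    return float(np.clip(1.0 - cc.max(), 0.0, 1.0))


def _relative_change(x0: float, x1: float) -> float:
    """|x1 − x0| / max(|x0|, |x1|) ∈ [0, 1]."""
    denom = max(abs(x0), abs(x1))
    return float(abs(x1 - x0) / denom) if denom > 0 else 0.0


def spectral_transition_score(
    s_prev: Spectrum,
    s_curr: Spectrum,
    width_prev_nm: float | None = None,
    width_curr_nm: float | None = None,
    weights: tuple[float, float, float] = ViabilityThresholds.weights,
) -> float:
    """Composite dissimilarity of two consecutive spectra.

    Weighted sum of three components, each in [0, 1] before weighting:
    (1) one minus the peak normalized cross-correlation over lags — a
    lasing transition decorrelates the line pattern; (2) the relative
    change of the maximum peak amplitude; (3) the relative change of the
    median fitted linewidth (when linewidths are supplied).  Invariant
    under a common intensity rescaling of both spectra.  Identical
    spectra score 0.
    """
    if len(s_prev) != len(s_curr) or not np.allclose(
        s_prev.wavelengths, s_curr.wavelengths
    ):
        raise ValueError("spectra must share one wavelength grid (same band)")
    c_corr = _component_correlation(s_prev.intensities, s_curr.intensities)
    # amplitude change on the raw scale: preprocessing normalizes each
    # spectrum to peak 1 but records the removed factor in norm_scale, so
    # the raw peak amplitude is max(I)·norm_scale; the ratio of the two
    # is invariant under a common rescaling of the raw inputs
    c_amp = _relative_change(
        float(np.max(s_prev.intensities)) * s_prev.meta.norm_scale,
        float(np.max(s_curr.intensities)) * s_curr.meta.norm_scale,
    )
    if width_prev_nm is not None and width_curr_nm is not None:
        c_width = _relative_change(width_prev_nm, width_curr_nm)
    else:
        c_width = 0.0
    w1, w2, w3 = weights
    return float(w1 * c_corr + w2 * c_amp + w3 * c_width)


def classify_state(
    track: SizeTrack,
    transition_scores: np.ndarray | None = None,
    ncell: np.ndarray | None = None,
    population_median_dd_nm: float | None = None,
    thresholds: ViabilityThresholds = ViabilityThresholds(),
) -> list[ViabilityFlags]:
    """Derive viability flags along a cell's time track.

    ``transition_scores[k]`` refers to the step from time point k to k+1
    (as does ``rupture``: the flag lands on the later point).  Flags are
    monotone in their thresholds: raising a threshold never creates a
    flag.  Requires at least 3 time points.
    """
    times = track.times_min
    if len(times) < 3:
        raise ValueError("need at least 3 time points to classify state")
    ncell = ncell if ncell is not None else track.ncell
    flags = [
        ViabilityFlags(track.cell_id, float(t), 0.0) for t in times
    ]

    if transition_scores is not None:
        for k, score in enumerate(transition_scores):
            f = flags[k + 1]
            f.transition_score = float(score)
            if score >= thresholds.lasing_score:
                f.lasing_flag = True
                f.evidence["transition_score"] = float(score)
                f.evidence["lasing_threshold"] = thresholds.lasing_score

    if ncell is not None:
        ncell = np.asarray(ncell, float)
        for k in range(1, len(times)):
            drop = ncell[k - 1] - ncell[k]
            if np.isfinite(drop) and drop >= thresholds.rupture_dncell:
                f = flags[k]
                f.rupture_flag = True
                f.evidence["dncell_drop"] = float(drop)
                f.evidence["rupture_threshold"] = thresholds.rupture_dncell

    # static-size signature: droplet immobile while the population moves
    if population_median_dd_nm is not None and np.isfinite(track.dd_min_nm):
        limit = thresholds.static_factor * track.dd_min_nm
        window = thresholds.static_window_h * 60.0
        if population_median_dd_nm > limit:
            for k in range(len(times)):
                in_win = np.abs(times - times[k]) <= window / 2.0
                if np.ptp(times[in_win]) < window * 0.8:
                    continue  # window not fully covered by data
                dd = track.dd_nm[in_win]
                if np.all(np.isfinite(dd)) and np.ptp(dd) < limit:
                    flags[k].static_flag = True
                    flags[k].evidence["max_dd_in_window_nm"] = float(np.ptp(dd))
                    flags[k].evidence["static_limit_nm"] = float(limit)
    return flags
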