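"""Peak picking, 2D lineshape fitting and the normalized-intensity statistic.

The dynamics readout of the study is simple and robust: for each spectrum,
express the height of a reporter peak (M223, M296) as a ratio to a reference
signal in the same spectrum (M153 by default; M190 or the detergent LMNG
methyl as alternatives), then normalize each reporter's ratios across a
series of receptor states so the maximum is 1.  Values near 1 indicate a
rigid state; small values indicate μs–ms exchange broadening.

SNR values measured at different temperatures can be put on a common footing
with a viscosity correction (peak height ∝ 1/η under the default model).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import lmfit
import numpy as np
from scipy import ndimage

from .nus import Spectrum2D

__all__ = [
    "Peak",
    "PeakFit",
    "IntensityRecord",
    "SNRCorrection",
    "pick_peaks",
    "fit_peaks",
    "estimate_noise",
    "relative_intensity",
    "normalize_series",
    "correct_snr",
    "water_viscosity",
    "match_peaks_to_labels",
]

#: Matching tolerance ellipse for assigning picked peaks to labels (ppm).
MATCH_TOL_H = 0.05
MATCH_TOL_C = 0.5

REFERENCE_LABELS = ("M153", "M190", "LMNG")


@dataclass
class Peak:
    """A picked local maximum."""

    delta_h: float
    delta_c: float
    height: float
    label: str = "unassigned"


@dataclass
class PeakFit:
    """A fitted 2D peak.

    ``volume`` follows the model's closed-form area: for the default 2D
    Lorentzian, volume = amplitude · (π/2·fwhm_H) · (π/2·fwhm_C).
    """

    delta_h: float
    delta_c: float
    fwhm_h: float  # Hz
    fwhm_c: float  # Hz
    amplitude: float
    volume: float
    model: str = "lorentzian"
    rms_residual: float = 0.0
    snr: float | None = None
    label: str = "unassigned"
    converged: bool = True

    @property
    def height(self) -> float:
        return self.amplitude


@dataclass
class IntensityRecord:
    """Relative and normalized intensity of one reporter in one spectrum."""

    spectrum_id: str
    residue: str
    reference_label: str
    relative_intensity: float
    normalized_intensity: float | None = None
    broadened_out: bool = False


@dataclass(frozen=True)
class SNRCorrection:
    """Temperature/viscosity correction factor for SNR comparisons."""

    temperature: float
    temperature_ref: float
    eta: float
    eta_ref: float

    @property
    def factor(self) -> float:
        return self.eta / self.eta_ref


def water_viscosity(temperature_k: float) -> float:
    """Empirical pure-water viscosity (mPa·s), Vogel correlation, 273–373 K."""
    if not (273.0 <= temperature_k <= 373.0):
        raise ValueError("temperature outside the 273–373 K validity range")
    return 2.414e-2 * 10.0 ** (247.8 / (temperature_k - 140.0))


# ---------------------------------------------------------------------------
# Noise and picking


def estimate_noise(spectrum: Spectrum2D, region: tuple[slice, slice] | None = None,
                   tile: int = 32) -> float:
    """Robust noise sigma: 1.4826 × median absolute deviation.

    With no region given, the lowest-variance corner tile is used as the
    signal-free region (the caller is responsible for regions they supply).
    """
    z = spectrum.intensity
    if region is not None:
        sub = z[region]
        if sub.size == 0:
            raise ValueError("noise region lies outside the spectrum")
    else:
        ti = min(tile, z.shape[0])
        tj = min(tile, z.shape[1])
        corners = [
            z[:ti, :tj], z[:ti, -tj:], z[-ti:, :tj], z[-ti:, -tj:],
        ]
        sub = min(corners, key=lambda c: float(np.var(c)))
    med = np.median(sub)
    return float(1.4826 * np.median(np.abs(sub - med)))


def pick_peaks(
    spectrum: Spectrum2D,
    threshold_sigma: float = 5.0,
    min_separation: tuple[float, float] = (0.05, 0.5),
    noise: float | None = None,
) -> list[Peak]:
    """Local maxima above ``threshold_sigma × noise``, height-sorted.

    ``min_separation`` is the deduplication radius in (ppm 1H, ppm 13C):
    of two maxima closer than this ellipse, only the higher is kept.
    """
    if threshold_sigma <= 0:
        raise ValueError("threshold_sigma must be > 0")
    sigma = noise if noise is not None else (
        spectrum.noise_estimate if spectrum.noise_estimate else estimate_noise(spectrum)
    )
    z = spectrum.intensity
    if sigma == 0:
        floor = 1e-12 * max(1.0, float(np.abs(z).max()))
    else:
        floor = threshold_sigma * sigma
    local_max = z == ndimage.maximum_filter(z, size=3, mode="nearest")
    cand = np.argwhere(local_max & (z > floor))
    peaks = [
        Peak(
            delta_h=float(spectrum.ppm_direct[i]),
            delta_c=float(spectrum.ppm_indirect[j]),
            height=float(z[i, j]),
        )
        for i, j in cand
    ]
    peaks.sort(key=lambda p: -p.height)
    kept: list[Peak] = []
    sh, sc = min_separation
    for p in peaks:
        dup = any(
            ((p.delta_h - q.delta_h) / sh) ** 2 + ((p.delta_c - q.delta_c) / sc) ** 2 < 1.0
            for q in kept
        )
        if not dup:
            kept.append(p)
    return kept


# ---------------------------------------------------------------------------
# Fitting


def _lorentzian_1d(x, x0, fwhm):
    return 1.0 / (1.0 + (2.0 * (x - x0) / fwhm) ** 2)


def _gaussian_1d(x, x0, fwhm):
    return np.exp(-4.0 * math.log(2.0) * ((x - x0) / fwhm) ** 2)


_SHAPES = {"lorentzian": _lorentzian_1d, "gaussian": _gaussian_1d}
_AREA_1D = {"lorentzian": math.pi / 2.0, "gaussian": 0.5 * math.sqrt(math.pi / math.log(2.0))}


def _model_volume(model: str, amplitude: float, fwhm_h: float, fwhm_c: float) -> float:
    a = _AREA_1D[model]
    return amplitude * (a * fwhm_h) * (a * fwhm_c)


def _snap_to_local_max(z, ph, pc, h0, c0, max_steps: int = 8):
    """Walk uphill on the grid from (h0, c0) to the nearest local maximum."""
    i = int(np.clip(np.searchsorted(ph, h0), 1, len(ph) - 2))
    j = int(np.clip(np.searchsorted(pc, c0), 1, len(pc) - 2))
    for _ in range(max_steps):
        window = z[max(i - 1, 0):i + 2, max(j - 1, 0):j + 2]
        di, dj = np.unravel_index(int(window.argmax()), window.shape)
        ni, nj = max(i - 1, 0) + di, max(j - 1, 0) + dj
        if (ni, nj) == (i, j):
            break
        i, j = int(np.clip(ni, 1, len(ph) - 2)), int(np.clip(nj, 1, len(pc) - 2))
    return float(ph[i]), float(pc[j])


def _cluster(initial: list[Peak], radius: tuple[float, float]) -> list[list[int]]:
    """Group peak indices whose tolerance ellipses chain together."""
    n = len(initial)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    rh, rc = radius
    for i in range(n):
        for j in range(i + 1, n):
            d = ((initial[i].delta_h - initial[j].delta_h) / rh) ** 2 + (
                (initial[i].delta_c - initial[j].delta_c) / rc
            ) ** 2
            if d < 1.0:
                parent[find(i)] = find(j)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return list(groups.values())


def fit_peaks(
    spectrum: Spectrum2D,
    initial: list[Peak],
    model: str = "lorentzian",
    cluster_radius: tuple[float, float] = (0.12, 1.0),
    window_factor: float = 4.0,
) -> list[PeakFit]:
    """Nonlinear least-squares refinement of peak parameters.

    Peaks within ``cluster_radius`` of each other are fitted jointly on a
    local sub-grid spanning ``window_factor`` initial linewidths.  Volumes
    come from the model's analytic area; ``snr`` is amplitude over the
    spectrum noise estimate.  Non-convergence is flagged per peak, never
    silently replaced.
    """
    if model not in _SHAPES:
        raise ValueError(f"unknown lineshape model {model!r}")
    if not initial:
        return []
    shape = _SHAPES[model]
    ax_h, ax_c = spectrum.axes
    sf_h, sf_c = ax_h.spectrometer_frequency, ax_c.spectrometer_frequency
    noise = spectrum.noise_estimate if spectrum.noise_estimate else estimate_noise(spectrum)
    ph, pc = spectrum.ppm_direct, spectrum.ppm_indirect
    step_h = float(np.mean(np.diff(ph)))
    step_c = float(np.mean(np.diff(pc)))
    # initial linewidth guesses (Hz): the window-limited resolution floor
    w0_h = max(5.0 * step_h * sf_h, 1.0 / ax_h.acquisition_time)
    w0_c = max(5.0 * step_c * sf_c, 1.0 / ax_c.acquisition_time)

    fits: list[PeakFit] = [None] * len(initial)  # type: ignore[list-item]
    for group in _cluster(initial, cluster_radius):
        pks = [initial[i] for i in group]
        span_h = window_factor * w0_h / sf_h
        span_c = window_factor * w0_c / sf_c
        lo_h = min(p.delta_h for p in pks) - span_h
        hi_h = max(p.delta_h for p in pks) + span_h
        lo_c = min(p.delta_c for p in pks) - span_c
        hi_c = max(p.delta_c for p in pks) + span_c
        si = np.searchsorted(ph, [lo_h, hi_h])
        sj = np.searchsorted(pc, [lo_c, hi_c])
        sub = spectrum.intensity[si[0]:si[1], sj[0]:sj[1]]
        gh = ph[si[0]:si[1]][:, None]
        gc = pc[sj[0]:sj[1]][None, :]
        if sub.size < 5 * len(pks):
            for i in group:
                p = initial[i]
                fits[i] = PeakFit(p.delta_h, p.delta_c, w0_h, w0_c, p.height,
                                  _model_volume(model, p.height, w0_h, w0_c),
                                  model=model, converged=False, label=p.label)
            continue

        params = lmfit.Parameters()
        for k, p in enumerate(pks):
            # snap the initial centre to the nearby grid maximum so a guess a
            # grid step off cannot strand the optimizer in a broad-width
            # local minimum
            h0, c0 = _snap_to_local_max(spectrum.intensity, ph, pc,
                                        p.delta_h, p.delta_c)
            params.add(f"a{k}", value=max(p.height, 1e-12), min=0.0)
            params.add(f"h{k}", value=h0, min=p.delta_h - span_h, max=p.delta_h + span_h)
            params.add(f"c{k}", value=c0, min=p.delta_c - span_c, max=p.delta_c + span_c)
            params.add(f"wh{k}", value=w0_h, min=0.3 * w0_h, max=10.0 * w0_h)
            params.add(f"wc{k}", value=w0_c, min=0.3 * w0_c, max=10.0 * w0_c)

        def resid(pars):
            z = np.zeros_like(sub)
            for k in range(len(pks)):
                z = z + pars[f"a{k}"].value * shape(gh, pars[f"h{k}"].value,
                                                   pars[f"wh{k}"].value / sf_h) * shape(
                    gc, pars[f"c{k}"].value, pars[f"wc{k}"].value / sf_c)
            return (z - sub).ravel()

        try:
            out = lmfit.minimize(resid, params, method="leastsq")
            ok = bool(out.success)
            pars = out.params
            rms = float(np.sqrt(np.mean(out.residual**2)))
        except Exception:
            ok, pars, rms = False, params, float("nan")
        for k, i in enumerate(group):
            amp = float(pars[f"a{k}"].value)
            wh = float(pars[f"wh{k}"].value)
            wc = float(pars[f"wc{k}"].value)
            fits[i] = PeakFit(
                delta_h=float(pars[f"h{k}"].value),
                delta_c=float(pars[f"c{k}"].value),
                fwhm_h=wh,
                fwhm_c=wc,
                amplitude=amp,
                volume=_model_volume(model, amp, wh, wc),
                model=model,
                rms_residual=rms,
                snr=amp / noise if noise else None,
                label=initial[i].label,
                converged=ok,
            )
    return fits


def match_peaks_to_labels(
    peaks: list[Peak] | list[PeakFit],
    reference: dict[str, tuple[float, float]],
    tol_h: float = MATCH_TOL_H,
    tol_c: float = MATCH_TOL_C,
) -> None:
    """Assign labels by nearest reference position within a tolerance ellipse.

    ``reference`` maps label -> (δH, δC).  Ties go to the smallest scaled
    (Mahalanobis-style) distance; unmatched peaks keep label 'unassigned'.
    Labels are assigned greedily by distance, one peak per label.
    """
    cand = []
    for i, p in enumerate(peaks):
        for lab, (h, c) in reference.items():
            d = ((p.delta_h - h) / tol_h) ** 2 + ((p.delta_c - c) / tol_c) ** 2
            if d < 1.0:
                cand.append((d, i, lab))
    cand.sort()
    used_peaks: set[int] = set()
    used_labels: set[str] = set()
    for d, i, lab in cand:
        if i in used_peaks or lab in used_labels:
            continue
        peaks[i].label = lab
        used_peaks.add(i)
        used_labels.add(lab)


# ---------------------------------------------------------------------------
# Intensity statistics


def relative_intensity(
    fits: list[PeakFit],
    target_residue: str,
    reference_label: str = "M153",
    spectrum_id: str = "",
) -> IntensityRecord:
    """Height ratio of a target reporter to the in-spectrum reference.

    A missing (broadened-out) target yields ratio 0 with a flag; a missing
    reference is a hard error since every ratio in the spectrum depends on it.
    """
    by_label = {f.label: f for f in fits if f.converged}
    ref = by_label.get(reference_label)
    if ref is None or ref.height <= 0:
        raise ValueError(f"reference peak {reference_label!r} missing or not converged")
    tgt = by_label.get(target_residue)
    if tgt is None:
        return IntensityRecord(spectrum_id, target_residue, reference_label,
                               relative_intensity=0.0, broadened_out=True)
    return IntensityRecord(spectrum_id, target_residue, reference_label,
                           relative_intensity=tgt.height / ref.height)


def normalize_series(records: list[IntensityRecord]) -> list[IntensityRecord]:
    """Normalize relative intensities per residue so each series max is 1.

    Tied maxima all map to exactly 1; an all-zero series is rejected.
    Idempotent: normalizing twice equals normalizing once.
    """
    by_res: dict[str, list[IntensityRecord]] = {}
    for r in records:
        by_res.setdefault(r.residue, []).append(r)
    for res, group in by_res.items():
        mx = max(r.relative_intensity for r in group)
        if mx <= 0:
            raise ValueError(f"all-zero intensity series for residue {res!r}")
        for r in group:
            r.normalized_intensity = r.relative_intensity / mx
    return records


def correct_snr(
    snr: float,
    temperature: float,
    temperature_ref: float,
    viscosity_model=water_viscosity,
) -> tuple[float, SNRCorrection]:
    """Correct an SNR measured at ``temperature`` to ``temperature_ref``.

    Under the default height ∝ 1/η model the correction is multiplicative:
    corrected = snr × η(T)/η(T_ref), so correcting A→B then B→C equals A→C.
    """
    eta = viscosity_model(temperature)
    eta_ref = viscosity_model(temperature_ref)
    corr = SNRCorrection(temperature, temperature_ref, eta, eta_ref)
    return snr * corr.factor, corr
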