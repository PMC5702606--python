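"""Non-uniform sampling schedules and compressed-sensing reconstruction.

Implements Poisson-gap sampling of the indirect (13C) dimension with
sinusoidal gap weighting (dense sampling at early evolution times, where the
signal is strongest), plus iterative hard thresholding (IHT) reconstruction
of the undersampled dimension and conventional 2D FT processing
(apodization, zero-filling, Fourier transform).

The standard acquisition emulated throughout the package is a SOFAST-type
1H,13C HMQC: 1024 direct points over 10 kHz (1H) and 100 complex indirect
points over 4 kHz (13C, t_max 25 ms), with a 60% Poisson-gap schedule
(60 of 100 complex points).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exchange import SpectralAxis

__all__ = [
    "SamplingSchedule",
    "FID2D",
    "Spectrum2D",
    "poisson_gap_schedule",
    "apply_schedule",
    "iht_complete_fid",
    "iht_reconstruct",
    "process_2d",
    "geometric_threshold_schedule",
]

DEFAULT_IHT_ITERATIONS = 200
DEFAULT_IHT_DECAY = 0.97


@dataclass(frozen=True)
class SamplingSchedule:
    """A NUS schedule over the indirect-dimension complex-point grid."""

    total_points: int
    indices: np.ndarray  # sorted, unique, 0-based
    seed: int
    sinusoidal_weighting: bool = True

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=int)
        if idx.ndim != 1 or len(np.unique(idx)) != len(idx):
            raise ValueError("indices must be unique")
        if np.any((idx < 0) | (idx >= self.total_points)):
            raise ValueError("indices must lie in [0, total_points)")
        if 0 not in idx:
            raise ValueError("index 0 must be sampled (anchors phasing)")
        object.__setattr__(self, "indices", np.sort(idx))

    @property
    def n_sampled(self) -> int:
        return len(self.indices)

    @property
    def fraction(self) -> float:
        return self.n_sampled / self.total_points

    def mask(self) -> np.ndarray:
        m = np.zeros(self.total_points, dtype=bool)
        m[self.indices] = True
        return m

    def to_text(self) -> str:
        """Two-column text (index, weight), one line per sampled increment."""
        return "\n".join(f"{i}\t1" for i in self.indices)


@dataclass
class FID2D:
    """Time-domain 2D data, direct dimension along axis 0.

    ``data[i, j]`` is the complex point at direct time i, indirect time j.
    With ``data_imag`` set, the indirect dimension is hypercomplex (States):
    ``data`` holds the cosine-modulated and ``data_imag`` the sine-modulated
    dataset, enabling pure-absorption 2D processing.  Without it the indirect
    dimension is treated as plain complex (adequate for 1D-separable tests,
    but the real part of the 2D FT then carries the phase-twist dispersion
    product).  ``mask`` (optional) marks which indirect increments were
    measured.
    """

    data: np.ndarray
    axes: tuple[SpectralAxis, SpectralAxis]  # (direct, indirect)
    mask: np.ndarray | None = None
    data_imag: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=complex)
        if self.data.shape != (self.axes[0].n_points, self.axes[1].n_points):
            raise ValueError("FID shape inconsistent with axes")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("FID contains non-finite values")
        if self.data_imag is not None:
            self.data_imag = np.asarray(self.data_imag, dtype=complex)
            if self.data_imag.shape != self.data.shape:
                raise ValueError("States components must have identical shape")
            if not np.all(np.isfinite(self.data_imag)):
                raise ValueError("FID contains non-finite values")

    @property
    def is_states(self) -> bool:
        return self.data_imag is not None

    @property
    def direct_axis(self) -> SpectralAxis:
        return self.axes[0]

    @property
    def indirect_axis(self) -> SpectralAxis:
        return self.axes[1]


@dataclass
class Spectrum2D:
    """Real absorptive 2D spectrum with ascending ppm axes and provenance."""

    intensity: np.ndarray
    ppm_direct: np.ndarray
    ppm_indirect: np.ndarray
    axes: tuple[SpectralAxis, SpectralAxis]
    provenance: dict = field(default_factory=dict)
    noise_estimate: float | None = None

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("spectrum intensity must be finite")
        for ax in (self.ppm_direct, self.ppm_indirect):
            if np.any(np.diff(ax) <= 0):
                raise ValueError("ppm axes must be strictly increasing")
        if self.intensity.shape != (len(self.ppm_direct), len(self.ppm_indirect)):
            raise ValueError("intensity shape inconsistent with ppm axes")


def _poisson_gap_once(
    total: int, n_target: int, lam: float, rng: np.random.Generator, sinusoidal: bool
) -> np.ndarray:
    idx = []
    i = 0
    while i < total:
        idx.append(i)
        i += 1
        if sinusoidal:
            w = np.sin(0.5 * np.pi * (i + 0.5) / total)
        else:
            w = 1.0
        i += int(rng.poisson(lam * w))
    return np.asarray(idx, dtype=int)


def poisson_gap_schedule(
    total_points: int,
    fraction: float,
    seed: int,
    sinusoidal_weighting: bool = True,
    max_outer: int = 64,
) -> SamplingSchedule:
    """Poisson-gap NUS schedule with an exact point count.

    Gaps between sampled indices are Poisson-distributed with a mean scaled
    by a sine envelope over the grid (small gaps early, large late).  The
    gap-scale parameter is rescaled iteratively until the schedule contains
    exactly ``round(fraction * total_points)`` indices; if a given stream
    cannot hit the exact count the sub-seed is incremented and sampling
    retried.  Index 0 is always included.
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    if total_points < 2:
        raise ValueError("total_points must be >= 2")
    n_target = int(round(fraction * total_points))
    if n_target < 2:
        raise ValueError("fraction * total_points must be at least 2")
    if n_target == total_points:
        return SamplingSchedule(total_points, np.arange(total_points), seed, sinusoidal_weighting)

    for sub in range(max_outer):
        rng = np.random.default_rng((int(seed) + 1_000_003 * sub) % (2**31))
        lam = 2.0 * (total_points - n_target) / n_target  # sine weighting halves the mean gap
        for _ in range(200):
            idx = _poisson_gap_once(total_points, n_target, lam, rng, sinusoidal_weighting)
            n = len(idx)
            if n == n_target:
                return SamplingSchedule(total_points, idx, seed, sinusoidal_weighting)
            # total gap length is (total - n); rescale toward (total - n_target)
            lam = max(1e-6, lam * (total_points - n_target) / max(total_points - n, 0.5))
    raise RuntimeError("could not construct an exact-count Poisson-gap schedule")


def apply_schedule(fid: FID2D, schedule: SamplingSchedule) -> FID2D:
    """Zero the unsampled indirect increments of a fully sampled FID.

    Sampled columns are copied bit-identically; the schedule mask is retained
    on the returned FID.
    """
    if schedule.total_points != fid.indirect_axis.n_points:
        raise ValueError("schedule size does not match the indirect grid")
    mask = schedule.mask()
    data = np.where(mask[None, :], fid.data, 0.0 + 0.0j)
    imag = None
    if fid.is_states:
        imag = np.where(mask[None, :], fid.data_imag, 0.0 + 0.0j)
    return FID2D(data=data, axes=fid.axes, mask=mask, data_imag=imag)


def geometric_threshold_schedule(
    start: float, n_iterations: int = DEFAULT_IHT_ITERATIONS, decay: float = DEFAULT_IHT_DECAY
) -> np.ndarray:
    """Geometrically decaying hard-threshold schedule."""
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    if not (0 < decay < 1):
        raise ValueError("decay must be in (0, 1)")
    return start * decay ** np.arange(n_iterations)


def _iht_columns(
    columns: np.ndarray, mask: np.ndarray, thresholds_rel: np.ndarray
) -> np.ndarray:
    """Run IHT independently on each row's indirect vector.

    ``columns``: (n_rows, n_indirect) complex, zero-filled at unsampled points.
    ``thresholds_rel``: decreasing thresholds as fractions of each row's
    initial maximum spectral magnitude.
    Returns the completed indirect time-domain data; measured points are
    restored exactly after every iteration.
    """
    measured = columns.copy()
    x = columns.copy()
    s0 = np.abs(np.fft.fft(x, axis=1)).max(axis=1, keepdims=True)  # per-row scale
    for tau in thresholds_rel:
        spec = np.fft.fft(x, axis=1)
        keep = np.abs(spec) >= tau * s0
        spec = np.where(keep, spec, 0.0)
        x = np.fft.ifft(spec, axis=1)
        x[:, mask] = measured[:, mask]
    x[:, mask] = measured[:, mask]
    return x


def iht_complete_fid(
    nus_fid: FID2D,
    schedule: SamplingSchedule | None = None,
    n_iterations: int = DEFAULT_IHT_ITERATIONS,
    threshold_schedule: np.ndarray | None = None,
) -> FID2D:
    """Fill in unsampled indirect increments by IHT compressed sensing.

    The direct dimension is Fourier-transformed first so each indirect vector
    is sparse; each is then reconstructed by iterating {FT → keep components
    above a decreasing threshold → inverse FT → restore measured points}.
    The returned FID reproduces the measured increments exactly.
    """
    mask, threshold_schedule = _resolve_iht_args(
        nus_fid, schedule, n_iterations, threshold_schedule
    )
    if not np.all(np.isfinite(nus_fid.data)):
        raise ValueError("non-finite input FID")
    if nus_fid.is_states:
        raise ValueError(
            "iht_complete_fid operates on plain-complex FIDs; "
            "use iht_reconstruct for States data"
        )
    if mask.all():
        return FID2D(data=nus_fid.data.copy(), axes=nus_fid.axes, mask=mask)

    # mix to (direct frequency) x (indirect time): sampling commutes with the
    # direct-dimension FT, so restoring measured indirect increments here is
    # equivalent to restoring them in the raw FID domain.
    mixed = np.fft.fft(nus_fid.data, axis=0)
    completed = _iht_columns(mixed, mask, threshold_schedule)
    data = np.fft.ifft(completed, axis=0)
    # exact data consistency at sampled increments
    data[:, mask] = nus_fid.data[:, mask]
    return FID2D(data=data, axes=nus_fid.axes, mask=mask)


def iht_reconstruct(
    nus_fid: FID2D,
    schedule: SamplingSchedule | None = None,
    n_iterations: int = DEFAULT_IHT_ITERATIONS,
    threshold_schedule: np.ndarray | None = None,
    window: str = "cos2",
    zero_fill: bool = True,
) -> Spectrum2D:
    """IHT-reconstruct an undersampled FID and process it to a spectrum.

    Plain-complex FIDs are completed in the time domain and processed
    conventionally; States data is reconstructed on the direct-dimension
    absorption interferogram (the domain in which the indirect vectors are
    sparse) before the indirect transform.
    """
    if not nus_fid.is_states:
        completed = iht_complete_fid(nus_fid, schedule, n_iterations, threshold_schedule)
        spec = process_2d(completed, window=window, zero_fill=zero_fill)
        mask = completed.mask
    else:
        mask, thresholds = _resolve_iht_args(nus_fid, schedule, n_iterations,
                                             threshold_schedule)
        ax_d, ax_i = nus_fid.axes
        nd = _next_pow2(ZERO_FILL_FACTOR * ax_d.n_points) if zero_fill else ax_d.n_points
        ni = _next_pow2(ZERO_FILL_FACTOR * ax_i.n_points) if zero_fill else ax_i.n_points
        wd = _window(window, ax_d.n_points)
        g = _states_interferogram(nus_fid, wd, nd)
        if not mask.all():
            g = _iht_columns(g, mask, thresholds)
        wi = _window(window, ax_i.n_points)
        spec_c = np.fft.fft(g * wi[None, :], n=ni, axis=1)
        intensity = np.fft.fftshift(np.real(spec_c), axes=(0, 1))
        spec = Spectrum2D(
            intensity=intensity,
            ppm_direct=ax_d.ppm_grid(nd),
            ppm_indirect=ax_i.ppm_grid(ni),
            axes=nus_fid.axes,
            provenance={"window": window, "zero_fill": [int(nd), int(ni)],
                        "mode": "states"},
        )
    spec.provenance.update(
        {
            "reconstruction": "iht",
            "n_iterations": int(n_iterations if threshold_schedule is None
                                else len(threshold_schedule)),
            "sampled_points": int(np.count_nonzero(mask)),
            "total_points": int(mask.size) if mask is not None else None,
        }
    )
    return spec


def _resolve_iht_args(nus_fid, schedule, n_iterations, threshold_schedule):
    if schedule is None:
        if nus_fid.mask is None:
            raise ValueError("no schedule given and the FID carries no mask")
        mask = nus_fid.mask
    else:
        if schedule.total_points != nus_fid.indirect_axis.n_points:
            raise ValueError("schedule size does not match the indirect grid")
        mask = schedule.mask()
    if threshold_schedule is None:
        thresholds = geometric_threshold_schedule(1.0, n_iterations)
    else:
        thresholds = np.asarray(threshold_schedule, dtype=float)
        if np.any(np.diff(thresholds) > 0):
            raise ValueError("threshold schedule must be monotonically decreasing")
    return mask, thresholds


def _states_interferogram(fid: FID2D, wd: np.ndarray, nd: int) -> np.ndarray:
    """Direct-dimension absorption × indirect-time complex interferogram."""
    ac = np.fft.fft(fid.data * wd[:, None], n=nd, axis=0)
    as_ = np.fft.fft(fid.data_imag * wd[:, None], n=nd, axis=0)
    return np.real(ac) + 1j * np.real(as_)


def _window(kind: str, n: int) -> np.ndarray:
    t = np.arange(n)
    if kind in (None, "none", "uniform"):
        return np.ones(n)
    if kind == "cos2":
        # squared cosine over the acquisition time
        return np.cos(0.5 * np.pi * t / n) ** 2
    if kind == "cos":
        return np.cos(0.5 * np.pi * t / n)
    raise ValueError(f"unknown window {kind!r}")


def _next_pow2(n: int) -> int:
    return 1 << (n - 1).bit_length()


#: Zero-fill each axis to the power of two >= this multiple of the acquired
#: length; generous padding keeps window-limited peaks well sampled for
#: picking and lineshape fitting.
ZERO_FILL_FACTOR = 4


def process_2d(
    fid: FID2D,
    window: str = "cos2",
    zero_fill: bool = True,
    phase0: tuple[float, float] = (0.0, 0.0),
) -> Spectrum2D:
    """Apodize, zero-fill and Fourier-transform a 2D FID.

    Returns the real (absorptive) spectrum with ascending ppm axes computed
    from each axis's carrier and spectrometer frequency.  Only zero-order
    phase correction is applied; synthetic data is generated in-phase.
    """
    ax_d, ax_i = fid.axes
    wd = _window(window, ax_d.n_points)
    wi = _window(window, ax_i.n_points)
    nd = _next_pow2(ZERO_FILL_FACTOR * ax_d.n_points) if zero_fill else ax_d.n_points
    ni = _next_pow2(ZERO_FILL_FACTOR * ax_i.n_points) if zero_fill else ax_i.n_points
    ph = np.exp(-1j * (np.deg2rad(phase0[0]) + np.deg2rad(phase0[1])))
    if fid.is_states:
        # pure-absorption processing: direct-dimension absorption first,
        # then complex FT of the recombined indirect interferogram
        g = _states_interferogram(fid, wd, nd)
        spec = np.fft.fft(g * wi[None, :], n=ni, axis=1)
        intensity = np.fft.fftshift(np.real(spec * ph), axes=(0, 1))
        mode = "states"
    else:
        data = fid.data * wd[:, None] * wi[None, :]
        spec = np.fft.fft(data, n=nd, axis=0)
        spec = np.fft.fft(spec, n=ni, axis=1)
        spec = np.fft.fftshift(spec, axes=(0, 1))
        intensity = np.real(spec * ph)
        mode = "complex"
    ppm_d = ax_d.ppm_grid(nd)
    ppm_i = ax_i.ppm_grid(ni)
    prov = {
        "window": window,
        "zero_fill": [int(nd), int(ni)],
        "phase0": list(phase0),
        "mode": mode,
    }
    return Spectrum2D(
        intensity=intensity,
        ppm_direct=ppm_d,
        ppm_indirect=ppm_i,
        axes=fid.axes,
        provenance=prov,
    )
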