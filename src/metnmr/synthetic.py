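"""Ground-truth scene generation for the two-equilibrium receptor model.

The generator realizes the activation model of a β1-adrenergic receptor
observed through its methyl-methionine reporters: ligand binding sets the
position of a fast-exchange equilibrium between an inactive (I) and a
pre-active (A) state, and, in complex with a G-protein-mimetic nanobody,
between a less active (A^G−) and a fully active (A^G+) ternary state.  The
observed chemical shift of each reporter is the population-weighted average
of the relevant endpoint shifts, with the active-state population set by the
ligand efficacy ε (p_active = ε/100; basal p_A = 0.02 for the apo receptor).

Peak intensities carry the dynamics signature: the pre-active state samples
several active-like substates in intermediate exchange, so full-agonist-bound
receptor is strongly exchange-broadened (some reporters vanish entirely,
e.g. M90 with a full agonist), apo and partial-agonist states sit in a
middle band, nanobody-bound receptor is more rigid, and ternary complexes
are the most rigid of all.  The per-state attenuation curves encoding this
pattern are calibrated once, in config, and converted to per-axis exchange
broadening so that linewidths and heights stay mutually consistent.

Default endpoint shifts for the efficacy-responsive reporters are inverted
from the published efficacy↔shift plane coefficients along the plane's
gradient, so that regression on generated data reproduces those coefficients
by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, model_validator

from .binding import BindingModel, fraction_bound
from .exchange import SpectralAxis
from .nus import FID2D, Spectrum2D, _window, process_2d
from .peaks import water_viscosity

__all__ = [
    "ReceptorStateSpec",
    "ConformerModel",
    "ResidueModel",
    "GroundTruthPeak",
    "SyntheticScene",
    "TitrationSeries",
    "LIGAND_EFFICACY",
    "NANOBODY_KD",
    "LIGAND_PLANES",
    "TERNARY_PLANES",
    "default_axes",
    "default_residue_models",
    "endpoints_from_plane",
    "generate_state_peaks",
    "make_scene",
    "render_spectrum",
    "generate_titration",
    "generate_efficacy_dataset",
    "ligand_series_states",
    "dynamics_series_states",
]

# ---------------------------------------------------------------------------
# Study conditions

#: Ligand efficacies on a 0–100 (% of full-agonist response) scale.
#: Placeholder values consistent with the pharmacological classes
#: (very weak partial ... full agonist); overridable per state.
LIGAND_EFFICACY: dict[str, float] = {
    "7-methylcyanopindolol": 5.0,
    "carvedilol": 10.0,
    "cyanopindolol": 15.0,
    "salbutamol": 50.0,
    "isoprenaline": 95.0,
    "adrenaline": 100.0,
}

#: Apo-receptor nanobody affinities (μM) used as ground truth in titrations.
NANOBODY_KD: dict[str, float] = {"Nb80": 56.0, "Nb6B9": 8.0}

#: Printed efficacy↔shift planes ε = a·δH + b·δC + c for the ligand series
#: (I ⇌ A axis) ...
LIGAND_PLANES: dict[str, tuple[float, float, float]] = {
    "M223": (-1045.1, -111.0, 3839.8),
    "M296": (-634.1, -239.9, 5614.1),
}

#: ... and for the ternary-complex series (A^G− ⇌ A^G+ axis).
TERNARY_PLANES: dict[str, tuple[float, float, float]] = {
    "M178": (1510.6, -732.7, 9863.4),
    "M296": (-5936.4, 5.93, 11985.7),
    "M223": (-1607.4, 1258.4, -19056.1),
    "M153": (-11854.9, 2691.2, -18476.6),
}

#: Basal pre-active population of the apo receptor (low basal activity).
P_A_BASAL = 0.02

#: Reference temperature (K) at which the attenuation curves are defined.
T_REF = 308.0

#: e-folding scale (K) of exchange broadening with temperature: cooling
#: slows the substate exchange out of the intermediate regime.
DYNAMICS_T_SCALE = 10.0

DEFAULT_NOISE_SIGMA = 1.0
DETECTABILITY_SIGMA = 3.0

# Dynamics attenuation calibration (relative height factor vs state), fixed
# from the published normalized-intensity pattern: full agonists ~0.2 of the
# series maximum, apo/partial agonists ~0.5, nanobody-only ~0.7, ternary
# complexes >= ~0.9 with a mild efficacy dependence.
_F_LIGAND_LO = 0.55    # attenuation at epsilon -> 0 (apo-like)
_F_LIGAND_HI = 0.17    # attenuation at epsilon = 100 (full agonist)
_LIGAND_GAMMA = 2.5    # onset sharpness of full-agonist substate sampling
_F_NANOBODY = 0.70
_F_TERNARY_LO = 0.93   # lowest-efficacy ternary complex
_F_TERNARY_SPAN = 0.07


def _ligand_attenuation(eps: float) -> float:
    return _F_LIGAND_LO - (_F_LIGAND_LO - _F_LIGAND_HI) * (eps / 100.0) ** _LIGAND_GAMMA


def _ternary_attenuation(eps: float) -> float:
    return _F_TERNARY_LO + _F_TERNARY_SPAN * eps / 100.0


# ---------------------------------------------------------------------------
# Domain types


class ReceptorStateSpec(BaseModel):
    """One receptor sample: apo, ligand-bound, nanobody-only or ternary."""

    model_config = {"frozen": True}

    state_kind: Literal["apo", "ligand", "nanobody", "ternary"]
    ligand: Optional[str] = None
    efficacy: Optional[float] = None
    nanobody: Optional[str] = None
    temperature: float = T_REF

    @model_validator(mode="after")
    def _check(self) -> "ReceptorStateSpec":
        needs_ligand = self.state_kind in ("ligand", "ternary")
        if needs_ligand and self.ligand is None:
            raise ValueError(f"state_kind={self.state_kind!r} requires a ligand")
        if not needs_ligand and self.ligand is not None:
            raise ValueError(f"state_kind={self.state_kind!r} must not carry a ligand")
        if self.state_kind in ("nanobody", "ternary") and self.nanobody is None:
            object.__setattr__(self, "nanobody", "Nb6B9")
        if needs_ligand and self.efficacy is None:
            if self.ligand not in LIGAND_EFFICACY:
                raise ValueError(
                    f"unknown ligand {self.ligand!r}: give an explicit efficacy"
                )
            object.__setattr__(self, "efficacy", LIGAND_EFFICACY[self.ligand])
        if self.efficacy is not None and not (0.0 <= self.efficacy <= 100.0):
            raise ValueError("efficacy must be within [0, 100]")
        return self

    @property
    def label(self) -> str:
        parts = [self.state_kind]
        if self.ligand:
            parts.append(self.ligand)
        if self.nanobody and self.state_kind in ("nanobody", "ternary"):
            parts.append(self.nanobody)
        if self.temperature != T_REF:
            parts.append(f"{self.temperature:.0f}K")
        return "+".join(parts)

    def active_population(self, p_a_basal: float = P_A_BASAL) -> float:
        """Population of the high end of the relevant equilibrium axis."""
        if self.state_kind == "apo":
            return p_a_basal
        if self.state_kind == "nanobody":
            return 0.0  # basal complex = minimally activated A^G- form
        assert self.efficacy is not None
        return self.efficacy / 100.0


Point = tuple[float, float]  # (delta_1H, delta_13C) in ppm


@dataclass(frozen=True)
class ConformerModel:
    """One conformer of a methionine reporter.

    ``delta_i``/``delta_a`` are the I/A endpoint shifts, ``delta_agm``/
    ``delta_agp`` the A^G−/A^G+ endpoints; a static conformer keeps a fixed
    position.  ``dynamics_exponent`` scales the state attenuation in log
    space (0 = unbroadened reference, >1 = hypersensitive, e.g. M90).
    ``only_state_kinds`` restricts in which sample kinds the conformer is
    populated (None = all).
    """

    name: str = ""
    fraction: float = 1.0
    delta_i: Point = (2.0, 16.0)
    delta_a: Point | None = None
    delta_agm: Point | None = None
    delta_agp: Point | None = None
    dynamics_exponent: float = 1.0
    ternary_dynamics: bool = True   # if False: keep ligand-curve in all states
    only_state_kinds: frozenset[str] | None = None

    def endpoints(self, state_kind: str) -> tuple[Point, Point]:
        if state_kind in ("apo", "ligand"):
            lo, hi = self.delta_i, self.delta_a
        else:
            lo, hi = (self.delta_agm or self.delta_i), (self.delta_agp or self.delta_agm)
        if hi is None:
            hi = lo
        return lo, hi


@dataclass(frozen=True)
class ResidueModel:
    """A methionine reporter with one or more conformers."""

    residue: str
    conformers: tuple[ConformerModel, ...]
    base_height: float = 100.0
    r2_h: float = 100.0   # intrinsic 1H R2, s^-1
    r2_c: float = 60.0    # intrinsic 13C R2, s^-1

    def __post_init__(self) -> None:
        if self.base_height <= 0:
            raise ValueError("base_height must be > 0")
        fracs = sum(c.fraction for c in self.conformers)
        if not self.conformers or abs(fracs - 1.0) > 1e-9:
            raise ValueError(f"{self.residue}: conformer fractions must sum to 1")


@dataclass(frozen=True)
class GroundTruthPeak:
    """A generated peak with its true parameters."""

    residue: str
    conformer: str
    delta_h: float
    delta_c: float
    height: float
    fwhm_h: float  # Hz
    fwhm_c: float  # Hz
    volume: float
    broadening_flag: Literal["detectable", "broadened_out"] = "detectable"

    @property
    def label(self) -> str:
        return self.residue + self.conformer


@dataclass(frozen=True)
class SyntheticScene:
    """A receptor state rendered onto a pair of spectral axes."""

    state: ReceptorStateSpec
    peaks: tuple[GroundTruthPeak, ...]
    axes: tuple[SpectralAxis, SpectralAxis]  # (direct 1H, indirect 13C)
    noise_sigma: float = DEFAULT_NOISE_SIGMA
    seed: int = 0


@dataclass(frozen=True)
class TitrationSeries:
    """Free/bound slow-exchange peak volumes over a titration."""

    receptor_total: float            # μM
    titrant_totals: np.ndarray       # μM
    volumes_free: np.ndarray
    volumes_bound: np.ndarray
    noise_sigma: float
    seed: int
    kd_true: float | None = None

    def __post_init__(self) -> None:
        for name in ("titrant_totals", "volumes_free", "volumes_bound"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if np.any(self.volumes_free < 0) or np.any(self.volumes_bound < 0):
            raise ValueError("volumes must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "titrant_total_uM": self.titrant_totals,
                "receptor_total_uM": self.receptor_total,
                "volume_free": self.volumes_free,
                "volume_bound": self.volumes_bound,
            }
        )


# ---------------------------------------------------------------------------
# Defaults


def default_axes(
    n_direct: int = 512,
    n_indirect: int = 100,
    field_mhz: float = 800.13,
) -> tuple[SpectralAxis, SpectralAxis]:
    """Acquisition grid of the emulated SOFAST HMQC.

    10 kHz 1H sweep (t_max 51.2 ms at 512 complex points) and 4 kHz 13C
    sweep (t_max 25 ms at 100 complex points).
    """
    h = SpectralAxis("1H", field_mhz, 10_000.0, n_direct, carrier=1.8)
    c = SpectralAxis("13C", field_mhz * 0.25144, 4_000.0, n_indirect, carrier=17.0)
    return h, c


def endpoints_from_plane(
    plane: tuple[float, float, float],
    anchor: Point,
    efficacy_span: tuple[float, float] = (0.0, 100.0),
) -> tuple[Point, Point]:
    """Invert a plane ε = a·δH + b·δC + c into two endpoint shifts.

    The low endpoint is the projection of ``anchor`` onto the ε = span[0]
    line and the high endpoint lies along the plane gradient at ε = span[1],
    so points interpolated between them satisfy the plane exactly.
    """
    a, b, c = plane
    g2 = a * a + b * b
    if g2 == 0:
        raise ValueError("degenerate plane: a = b = 0")
    h0, c0 = anchor
    eps_anchor = a * h0 + b * c0 + c
    lo = (h0 - (eps_anchor - efficacy_span[0]) * a / g2,
          c0 - (eps_anchor - efficacy_span[0]) * b / g2)
    span = efficacy_span[1] - efficacy_span[0]
    hi = (lo[0] + span * a / g2, lo[1] + span * b / g2)
    return lo, hi


def _manual_endpoints(anchor: Point, dh: float, dc: float) -> tuple[Point, Point]:
    return anchor, (anchor[0] + dh, anchor[1] + dc)


def default_residue_models(
    include_extra_reporters: bool = True,
    include_lmng: bool = True,
) -> tuple[ResidueModel, ...]:
    """The default seven-reporter receptor (plus optional M108/M190/LMNG).

    Efficacy-responsive trajectories of M223, M296 (ligand series) and
    M178a, M296, M223, M153 (ternary series) are inverted from the printed
    plane coefficients; the remaining reporters get small, plausible manual
    trajectories.  Anchors are spaced so peaks stay resolvable.
    """
    # anchors chosen on (or very near) each printed plane's ε = 0 line, in
    # the methyl-methionine region, so the inverted endpoints stay realistic
    m223_i, m223_a = endpoints_from_plane(LIGAND_PLANES["M223"], (2.007, 15.70))
    m296_i, m296_a = endpoints_from_plane(LIGAND_PLANES["M296"], (2.271, 17.40))
    m223_gm, m223_gp = endpoints_from_plane(TERNARY_PLANES["M223"], (1.923, 17.60))
    m296_gm, m296_gp = endpoints_from_plane(TERNARY_PLANES["M296"], (2.037, 18.00))
    m153_gm, m153_gp = endpoints_from_plane(TERNARY_PLANES["M153"], (2.062, 15.95))
    m178_gm, m178_gp = endpoints_from_plane(TERNARY_PLANES["M178"], (1.692, 16.95))

    models = [
        ResidueModel(
            "M1",
            (ConformerModel(delta_i=(1.30, 15.30), dynamics_exponent=0.0),),
            base_height=90.0,
            r2_h=60.0, r2_c=35.0,  # mobile N-terminus
        ),
        ResidueModel(
            "M90",
            (
                # major, efficacy-responsive conformer; vanishes with a full
                # agonist through its hypersensitive broadening
                ConformerModel(
                    name="a", fraction=0.6,
                    delta_i=(2.30, 16.2), delta_a=(2.16, 16.05),
                    delta_agm=(2.28, 16.15), delta_agp=(2.26, 16.10),
                    dynamics_exponent=3.0,
                ),
                ConformerModel(
                    name="b", fraction=0.25, delta_i=(2.46, 16.45),
                    dynamics_exponent=1.5,
                    only_state_kinds=frozenset({"apo"}),
                ),
                ConformerModel(
                    name="c", fraction=0.15, delta_i=(2.38, 15.6),
                    dynamics_exponent=1.5,
                    only_state_kinds=frozenset({"ligand"}),
                ),
            ),
            base_height=80.0,
        ),
        ResidueModel(
            "M153",
            (
                ConformerModel(
                    delta_i=(2.10, 15.9), delta_a=(2.095, 15.88),
                    delta_agm=m153_gm, delta_agp=m153_gp,
                    dynamics_exponent=0.0,  # intensity reference
                ),
            ),
            base_height=120.0,
        ),
        ResidueModel(
            "M178",
            (
                ConformerModel(
                    name="a", fraction=0.6,
                    delta_i=(1.62, 15.12), delta_a=(1.60, 15.10),
                    delta_agm=m178_gm, delta_agp=m178_gp,
                    dynamics_exponent=0.3,
                ),
                ConformerModel(
                    name="b", fraction=0.4, delta_i=(1.90, 14.6),
                    dynamics_exponent=0.3,
                ),
            ),
            base_height=80.0,
        ),
        ResidueModel(
            "M223",
            (
                ConformerModel(
                    delta_i=m223_i, delta_a=m223_a,
                    delta_agm=m223_gm, delta_agp=m223_gp,
                ),
            ),
            base_height=100.0,
        ),
        ResidueModel(
            "M283",
            (
                ConformerModel(
                    delta_i=(2.55, 16.9), delta_a=(2.52, 16.84),
                    delta_agm=(2.60, 17.1), delta_agp=(2.61, 17.12),
                    dynamics_exponent=0.3,
                ),
            ),
            base_height=95.0,
        ),
        ResidueModel(
            "M296",
            (
                ConformerModel(
                    delta_i=m296_i, delta_a=m296_a,
                    delta_agm=m296_gm, delta_agp=m296_gp,
                ),
            ),
            base_height=100.0,
        ),
    ]
    if include_extra_reporters:
        models += [
            ResidueModel(
                "M108",
                (ConformerModel(delta_i=(2.62, 15.5),
                                delta_agm=(2.66, 15.55), delta_agp=(2.70, 15.6),
                                dynamics_exponent=0.0),),
                base_height=85.0,
            ),
            ResidueModel(
                "M190",
                (ConformerModel(delta_i=(2.85, 16.0),
                                delta_agm=(2.80, 15.95), delta_agp=(2.78, 15.9),
                                dynamics_exponent=0.0),),
                base_height=110.0,
            ),
        ]
    if include_lmng:
        models.append(
            ResidueModel(
                "LMNG",
                (ConformerModel(delta_i=(0.92, 14.25), dynamics_exponent=0.0),),
                base_height=150.0,
                r2_h=40.0, r2_c=25.0,  # detergent methyl, fast tumbling
            )
        )
    return tuple(models)


# ---------------------------------------------------------------------------
# Peak generation


def _state_attenuation(state: ReceptorStateSpec, conformer: ConformerModel) -> float:
    """Relative height factor (≤1) from μs–ms exchange broadening."""
    if conformer.dynamics_exponent == 0.0:
        return 1.0
    kind = state.state_kind
    eps = 100.0 * state.active_population()
    if kind in ("apo", "ligand") or not conformer.ternary_dynamics:
        f = _ligand_attenuation(eps)
    elif kind == "nanobody":
        f = _F_NANOBODY
    else:
        f = _ternary_attenuation(eps)
    f = f ** conformer.dynamics_exponent
    # cooling slows the substate exchange: per-axis broadening shrinks by
    # exp((T - T_ref)/scale); recompose the height factor accordingly
    if state.temperature != T_REF:
        tfac = math.exp((state.temperature - T_REF) / DYNAMICS_T_SCALE)
        rho = f ** -0.5 - 1.0  # per-axis relative broadening at T_ref
        f = (1.0 + rho * tfac) ** -2
    return f


LORENTZIAN_AREA_2D = math.pi * math.pi / 4.0


def generate_state_peaks(
    config: tuple[ResidueModel, ...] | list[ResidueModel],
    state: ReceptorStateSpec,
    seed: int = 0,
    noise_sigma: float = DEFAULT_NOISE_SIGMA,
    p_a_basal: float = P_A_BASAL,
) -> tuple[GroundTruthPeak, ...]:
    """Ground-truth peaks of one receptor state.

    Shifts are population-weighted endpoint averages (fast exchange); heights
    are attenuated by the state's exchange broadening and by the viscosity
    penalty away from the reference temperature; peaks whose height falls
    below ``DETECTABILITY_SIGMA × noise_sigma`` are flagged broadened_out.
    ``seed`` is accepted for interface symmetry; peak parameters themselves
    are deterministic functions of the configuration.
    """
    del seed  # ground truth is deterministic; randomness enters at render time
    if not isinstance(state, ReceptorStateSpec):
        raise TypeError("state must be a ReceptorStateSpec")
    p = state.active_population(p_a_basal)
    visc = water_viscosity(T_REF) / water_viscosity(state.temperature)
    peaks = []
    for res in config:
        for conf in res.conformers:
            if conf.only_state_kinds is not None and state.state_kind not in conf.only_state_kinds:
                continue
            lo, hi = conf.endpoints(state.state_kind)
            dh = (1.0 - p) * lo[0] + p * hi[0]
            dc = (1.0 - p) * lo[1] + p * hi[1]
            f = _state_attenuation(state, conf)
            height = res.base_height * conf.fraction * f * visc
            rho = f ** -0.5 - 1.0  # per-axis broadening consistent with f
            fwhm_h = res.r2_h * (1.0 + rho) / math.pi
            fwhm_c = res.r2_c * (1.0 + rho) / math.pi
            flag = "detectable"
            if height < DETECTABILITY_SIGMA * noise_sigma:
                flag = "broadened_out"
            peaks.append(
                GroundTruthPeak(
                    residue=res.residue,
                    conformer=conf.name,
                    delta_h=dh,
                    delta_c=dc,
                    height=height,
                    fwhm_h=fwhm_h,
                    fwhm_c=fwhm_c,
                    volume=height * LORENTZIAN_AREA_2D * fwhm_h * fwhm_c,
                    broadening_flag=flag,
                )
            )
    if not peaks:
        raise ValueError(f"no reporter is populated in state {state.label!r}")
    return tuple(peaks)


def make_scene(
    config: tuple[ResidueModel, ...] | list[ResidueModel],
    state: ReceptorStateSpec,
    axes: tuple[SpectralAxis, SpectralAxis] | None = None,
    noise_sigma: float = DEFAULT_NOISE_SIGMA,
    seed: int = 0,
) -> SyntheticScene:
    axes = default_axes() if axes is None else axes
    peaks = generate_state_peaks(config, state, seed=seed, noise_sigma=noise_sigma)
    return SyntheticScene(state=state, peaks=peaks, axes=axes,
                          noise_sigma=noise_sigma, seed=seed)


def _windowed_decay_sum(r: float, axis: SpectralAxis, window: str) -> float:
    """Discrete sum Σ w[n]·e^{-r·n·dt}: the on-resonance FT peak height of a
    unit-amplitude windowed, exponentially damped sinusoid."""
    t = axis.time_grid()
    w = _window(window, axis.n_points)
    return float(np.sum(w * np.exp(-r * t)))


def render_spectrum(
    scene: SyntheticScene,
    window: str = "cos2",
    zero_fill: bool = True,
) -> tuple[Spectrum2D, FID2D]:
    """Render a scene to a 2D FID and its processed spectrum.

    The FID is a sum of exponentially damped 2D complex sinusoids with
    per-axis decay π·fwhm; amplitudes are normalized through the window so
    that each peak's spectrum height equals its ground-truth height.  White
    Gaussian noise of ``scene.noise_sigma`` is added to the processed
    spectrum; output is deterministic for a given (config, seed).
    """
    ax_h, ax_c = scene.axes
    t2 = ax_h.time_grid()
    t1 = ax_c.time_grid()
    fid_cos = np.zeros((ax_h.n_points, ax_c.n_points), dtype=complex)
    fid_sin = np.zeros_like(fid_cos)
    for pk in scene.peaks:
        if pk.height <= 0:
            continue
        r_h = math.pi * pk.fwhm_h
        r_c = math.pi * pk.fwhm_c
        amp = pk.height / (
            _windowed_decay_sum(r_h, ax_h, window) * _windowed_decay_sum(r_c, ax_c, window)
        )
        fh = float(ax_h.ppm_to_hz(pk.delta_h))
        fc = float(ax_c.ppm_to_hz(pk.delta_c))
        sig_h = np.exp((2j * math.pi * fh - r_h) * t2)
        sig_c = np.exp((2j * math.pi * fc - r_c) * t1)
        # States acquisition: cosine- and sine-modulated indirect datasets
        fid_cos += amp * np.outer(sig_h, sig_c.real)
        fid_sin += amp * np.outer(sig_h, sig_c.imag)
    fid2d = FID2D(data=fid_cos, axes=scene.axes, data_imag=fid_sin)
    spec = process_2d(fid2d, window=window, zero_fill=zero_fill)
    if scene.noise_sigma > 0:
        rng = np.random.default_rng(scene.seed)
        spec.intensity = spec.intensity + rng.normal(
            0.0, scene.noise_sigma, size=spec.intensity.shape
        )
    spec.noise_estimate = scene.noise_sigma if scene.noise_sigma > 0 else None
    spec.provenance.update({"scene": scene.state.label, "seed": scene.seed,
                            "noise_sigma": scene.noise_sigma})
    return spec, fid2d


# ---------------------------------------------------------------------------
# Titrations and efficacy datasets


def generate_titration(
    model: BindingModel,
    receptor_total: float = 100.0,
    titrant_totals=None,
    noise_sigma: float = 0.0,
    seed: int = 0,
    base_volume: float = 1000.0,
) -> TitrationSeries:
    """Slow-exchange titration volumes under exact 1:1 mass action.

    Per point the bound fraction comes from the quadratic isotherm; free and
    bound peak volumes split a constant total, with optional multiplicative
    Gaussian noise of relative width ``noise_sigma``.
    """
    if titrant_totals is None:
        titrant_totals = np.concatenate([[10.0], np.geomspace(25.0, 1500.0, 7)])
    L = np.asarray(titrant_totals, dtype=float)
    if receptor_total <= 0 or np.any(L < 0):
        raise ValueError("concentrations must be positive")
    frac = np.asarray(fraction_bound(model.kd, receptor_total, L))
    vb = frac * base_volume
    vf = (1.0 - frac) * base_volume
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        vb = np.clip(vb * (1.0 + rng.normal(0, noise_sigma, size=vb.shape)), 0, None)
        vf = np.clip(vf * (1.0 + rng.normal(0, noise_sigma, size=vf.shape)), 0, None)
    return TitrationSeries(
        receptor_total=receptor_total,
        titrant_totals=L,
        volumes_free=vf,
        volumes_bound=vb,
        noise_sigma=noise_sigma,
        seed=seed,
        kd_true=model.kd,
    )


DEFAULT_PLANE_ANCHOR: Point = (2.0, 16.5)


def generate_efficacy_dataset(
    plane,
    n_ligands: int = 6,
    shift_spread: float = 0.01,
    noise_sigma: float = 0.0,
    seed: int = 0,
    efficacy_range: tuple[float, float] = (0.0, 100.0),
    anchor: Point = DEFAULT_PLANE_ANCHOR,
) -> pd.DataFrame:
    """Sample (δH, δC, ε) triples from an efficacy plane.

    Shift pairs are spread along the plane's gradient over ``efficacy_range``
    with perpendicular (off-line) Gaussian scatter of width ``shift_spread``
    ppm, emulating the off-axis residuals of real peak positions; the
    perpendicular direction leaves the plane value unchanged, so with
    ``noise_sigma = 0`` every point satisfies ε = a·δH + b·δC + c exactly.
    """
    a, b, c = _plane_coeffs(plane)
    if n_ligands < 3:
        raise ValueError("need at least 3 points for plane identifiability")
    span = efficacy_range[1] - efficacy_range[0]
    if span == 0 and shift_spread == 0:
        raise ValueError("degenerate dataset: all shift pairs identical")
    g2 = a * a + b * b
    rng = np.random.default_rng(seed)
    if g2 == 0:
        # constant plane: efficacy is c everywhere, scatter shifts isotropically
        if shift_spread == 0:
            raise ValueError("degenerate dataset: all shift pairs identical")
        dh = anchor[0] + rng.normal(0.0, shift_spread, size=n_ligands)
        dc = anchor[1] + rng.normal(0.0, shift_spread, size=n_ligands)
        eps_obs = np.full(n_ligands, c) + (
            rng.normal(0.0, noise_sigma, size=n_ligands) if noise_sigma > 0 else 0.0)
        return pd.DataFrame({"delta_h": dh, "delta_c": dc, "efficacy": eps_obs})
    lo, _ = endpoints_from_plane((a, b, c), anchor, efficacy_span=(efficacy_range[0],) * 2)
    eps = np.linspace(efficacy_range[0], efficacy_range[1], n_ligands)
    perp = rng.normal(0.0, shift_spread, size=n_ligands) if shift_spread > 0 else np.zeros(n_ligands)
    n_hat = np.array([-b, a]) / math.sqrt(g2)
    dh = lo[0] + (eps - efficacy_range[0]) * a / g2 + perp * n_hat[0]
    dc = lo[1] + (eps - efficacy_range[0]) * b / g2 + perp * n_hat[1]
    eps_exact = a * dh + b * dc + c
    eps_obs = eps_exact + (rng.normal(0.0, noise_sigma, size=n_ligands) if noise_sigma > 0 else 0.0)
    return pd.DataFrame({"delta_h": dh, "delta_c": dc, "efficacy": eps_obs})


def _plane_coeffs(plane) -> tuple[float, float, float]:
    if hasattr(plane, "a"):
        return float(plane.a), float(plane.b), float(plane.c)
    a, b, c = plane
    return float(a), float(b), float(c)


# ---------------------------------------------------------------------------
# Standard state series


def ligand_series_states(include_apo: bool = True) -> list[ReceptorStateSpec]:
    states = [ReceptorStateSpec(state_kind="apo")] if include_apo else []
    states += [
        ReceptorStateSpec(state_kind="ligand", ligand=name) for name in LIGAND_EFFICACY
    ]
    return states


def dynamics_series_states(
    nanobody: str = "Nb6B9",
    ternary_ligands: tuple[str, ...] = ("cyanopindolol", "salbutamol", "isoprenaline", "adrenaline"),
) -> list[ReceptorStateSpec]:
    """Apo, all ligands, nanobody-only and ternary complexes: the full
    normalized-intensity comparison series."""
    states = ligand_series_states()
    states.append(ReceptorStateSpec(state_kind="nanobody", nanobody=nanobody))
    states += [
        ReceptorStateSpec(state_kind="ternary", ligand=lig, nanobody=nanobody)
        for lig in ternary_ligands
    ]
    return states


def equivalent_kex(rex: float, p_active: float, delta_omega: float) -> float:
    """Exchange rate implied by a fast-exchange broadening contribution,
    k_ex = p(1−p)·Δω²/Rex; useful to express attenuation curves as two-site
    exchange parameters (see also :func:`metnmr.exchange.two_site_system`)."""
    if rex <= 0:
        return math.inf
    return p_active * (1.0 - p_active) * delta_omega**2 / rex
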