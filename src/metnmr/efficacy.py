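"""Linear efficacy↔chemical-shift relations and two-state populations.

For reporters in fast exchange between two conformational endpoints, the
observed peak moves along a line in the (δ1H, δ13C) plane and ligand
efficacy correlates with position along it.  The study summarizes this as a
plane ε = a·δH + b·δC + c fitted per residue (separately for the
ligand-bound I ⇌ A series and the ternary A^G− ⇌ A^G+ series).  Inverting
the picture, the position of an observed shift between the two endpoint
shifts yields the population of the high (active) state.

Methionine 13Cε shifts additionally report on the χ3 side-chain dihedral;
a simple threshold classifier assigns trans/gauche rotamer character.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "EfficacyFit",
    "TwoStatePopulations",
    "fit_efficacy_plane",
    "predict_efficacy",
    "two_state_populations",
    "classify_rotamer",
]

#: Standardization of the (δH, δC) metric before projecting: 0.1 ppm of 1H
#: counts as much as 1.0 ppm of 13C (typical linewidth scales), so neither
#: axis dominates the projection.
H_SCALE_PPM = 0.1
C_SCALE_PPM = 1.0

#: Rotamer classification thresholds on δ13Cε (ppm); literature-convention
#: placeholders, config-exposed.
ROTAMER_GAUCHE_BELOW = 15.5
ROTAMER_TRANS_ABOVE = 17.0
METHYL_REGION = (10.0, 25.0)


@dataclass
class EfficacyFit:
    """Coefficients of ε = a·δH + b·δC + c with fit diagnostics."""

    a: float
    b: float
    c: float
    r_squared: float
    n_points: int
    residuals: np.ndarray
    residue: str = ""
    series: str = ""
    collinear: bool = False

    def to_dict(self) -> dict:
        return {
            "residue": self.residue,
            "series": self.series,
            "a": self.a,
            "b": self.b,
            "c": self.c,
            "r_squared": self.r_squared,
            "n_points": self.n_points,
            "collinear": self.collinear,
        }


@dataclass
class TwoStatePopulations:
    """Populations of the low/high states from a fast-exchange shift."""

    p_low: float
    p_high: float
    off_axis_distance: float  # standardized-ppm perpendicular residual
    clipped: bool = False


def fit_efficacy_plane(points, residue: str = "", series: str = "") -> EfficacyFit:
    """Ordinary least squares of ε on (δH, δC, 1).

    ``points`` is an (n, 3) array-like of (δH, δC, ε) or a DataFrame with
    columns delta_h/delta_c/efficacy.  The design is centred before solving
    for conditioning.  Identical shift pairs are rejected; exactly collinear
    shift pairs give the minimum-norm solution with ``collinear=True``.
    """
    arr = _as_points(points)
    if len(arr) < 3:
        raise ValueError("need at least 3 points to fit a plane")
    dh, dc, eps = arr[:, 0], arr[:, 1], arr[:, 2]
    if np.ptp(dh) == 0 and np.ptp(dc) == 0:
        raise ValueError("rank-deficient design: all shift pairs identical")
    mh, mc, me = dh.mean(), dc.mean(), eps.mean()
    X = np.column_stack([dh - mh, dc - mc])
    # collinearity of the centred shifts
    svals = np.linalg.svd(X, compute_uv=False)
    collinear = svals[-1] <= 1e-10 * svals[0]
    coef, *_ = np.linalg.lstsq(X, eps - me, rcond=None)
    a, b = float(coef[0]), float(coef[1])
    c = float(me - a * mh - b * mc)
    pred = a * dh + b * dc + c
    resid = eps - pred
    sst = float(np.sum((eps - me) ** 2))
    r2 = 1.0 if sst == 0 else 1.0 - float(np.sum(resid**2)) / sst
    return EfficacyFit(a=a, b=b, c=c, r_squared=r2, n_points=len(arr),
                       residuals=resid, residue=residue, series=series,
                       collinear=bool(collinear))


def predict_efficacy(fit: EfficacyFit, delta_h, delta_c):
    """Evaluate ε = a·δH + b·δC + c."""
    return fit.a * np.asarray(delta_h, dtype=float) + fit.b * np.asarray(
        delta_c, dtype=float) + fit.c


def two_state_populations(
    delta_obs: tuple[float, float],
    delta_low: tuple[float, float],
    delta_high: tuple[float, float],
    h_scale: float = H_SCALE_PPM,
    c_scale: float = C_SCALE_PPM,
) -> TwoStatePopulations:
    """Populations from the scalar projection onto the endpoint axis.

    All shift pairs are standardized per axis before projecting, so the 1H
    and 13C dimensions contribute comparably.  The perpendicular residual is
    returned as ``off_axis_distance`` (standardized ppm); populations outside
    [0, 1] are clipped with a flag.
    """
    obs = np.array([delta_obs[0] / h_scale, delta_obs[1] / c_scale])
    lo = np.array([delta_low[0] / h_scale, delta_low[1] / c_scale])
    hi = np.array([delta_high[0] / h_scale, delta_high[1] / c_scale])
    axis = hi - lo
    norm2 = float(axis @ axis)
    if norm2 == 0:
        raise ValueError("coincident endpoints: populations undefined")
    t = float((obs - lo) @ axis) / norm2
    perp = (obs - lo) - t * axis
    off = float(np.linalg.norm(perp))
    clipped = not (0.0 <= t <= 1.0)
    t_cl = min(max(t, 0.0), 1.0)
    return TwoStatePopulations(p_low=1.0 - t_cl, p_high=t_cl,
                               off_axis_distance=off, clipped=clipped)


def classify_rotamer(
    delta_c_epsilon: float,
    gauche_below: float = ROTAMER_GAUCHE_BELOW,
    trans_above: float = ROTAMER_TRANS_ABOVE,
) -> str:
    """Classify the methionine χ3 rotamer from the 13Cε shift.

    Returns ``trans``, ``gauche`` or ``ambiguous``; shifts outside the
    plausible methyl region are ambiguous with a warning.
    """
    import warnings

    if not (METHYL_REGION[0] <= delta_c_epsilon <= METHYL_REGION[1]):
        warnings.warn(
            f"13C shift {delta_c_epsilon:.2f} ppm outside the methyl region "
            f"{METHYL_REGION}; classification ambiguous",
            stacklevel=2,
        )
        return "ambiguous"
    if delta_c_epsilon > trans_above:
        return "trans"
    if delta_c_epsilon < gauche_below:
        return "gauche"
    return "ambiguous"


def _as_points(points) -> np.ndarray:
    if hasattr(points, "columns"):
        return points[["delta_h", "delta_c", "efficacy"]].to_numpy(dtype=float)
    return np.asarray(points, dtype=float).reshape(-1, 3)
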