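"""Plain-text I/O: Sparky-style peak lists, shift tables, titrations, spectra.

All formats are flat text (TSV/CSV/JSON) so results and fixtures stay
diffable and portable.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .peaks import Peak, PeakFit
from .synthetic import TitrationSeries

__all__ = [
    "write_peak_list",
    "read_peak_list",
    "import_shift_table",
    "export_shift_table",
    "write_titration_csv",
    "read_titration_csv",
    "write_spectrum_text",
]

SHIFT_COLUMNS = ("delta_h", "delta_c", "efficacy")


def write_peak_list(path, peaks: list[Peak] | list[PeakFit]) -> None:
    """Sparky-style .list: Assignment  w1(1H ppm)  w2(13C ppm)  height [volume]."""
    lines = ["Assignment\tw1\tw2\theight\tvolume"]
    for p in peaks:
        vol = getattr(p, "volume", float("nan"))
        lines.append(
            f"{p.label or 'unassigned'}\t{p.delta_h:.4f}\t{p.delta_c:.4f}"
            f"\t{p.height:.6g}\t{vol:.6g}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_peak_list(path) -> list[Peak]:
    peaks = []
    for ln in Path(path).read_text().splitlines():
        parts = ln.split()
        if not parts or parts[0].lower() == "assignment":
            continue
        label, w1, w2 = parts[0], float(parts[1]), float(parts[2])
        height = float(parts[3]) if len(parts) > 3 else 0.0
        peaks.append(Peak(delta_h=w1, delta_c=w2, height=height, label=label))
    return peaks


def import_shift_table(path) -> pd.DataFrame:
    """Read a CSV shift table with columns delta_h, delta_c, efficacy (ppm, ppm, %).

    Missing columns are reported by name; non-numeric entries by row number.
    """
    df = pd.read_csv(path)
    missing = [c for c in SHIFT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"shift table missing column(s): {', '.join(missing)}")
    out = {}
    for col in SHIFT_COLUMNS:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna() & df[col].notna()].tolist()
        if bad or vals.isna().any():
            rows = bad or df.index[vals.isna()].tolist()
            raise ValueError(f"non-numeric entries in column {col!r} at row(s) {rows}")
        out[col] = vals.astype(float)
    keep = [c for c in df.columns if c not in SHIFT_COLUMNS]
    res = pd.DataFrame(out)
    for c in keep:
        res[c] = df[c]
    return res


def export_shift_table(path, df: pd.DataFrame) -> None:
    missing = [c for c in SHIFT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"shift table missing column(s): {', '.join(missing)}")
    df.to_csv(path, index=False)


def write_titration_csv(path, series: TitrationSeries) -> None:
    df = series.to_frame()
    df.insert(0, "point", np.arange(len(df)))
    df.to_csv(path, index=False)


def read_titration_csv(path) -> TitrationSeries:
    df = pd.read_csv(path)
    return TitrationSeries(
        receptor_total=float(df["receptor_total_uM"].iloc[0]),
        titrant_totals=df["titrant_total_uM"].to_numpy(float),
        volumes_free=df["volume_free"].to_numpy(float),
        volumes_bound=df["volume_bound"].to_numpy(float),
        noise_sigma=0.0,
        seed=0,
    )


def write_spectrum_text(path, spectrum) -> None:
    """Row-major text matrix with a JSON sidecar holding axes and provenance."""
    path = Path(path)
    np.savetxt(path, spectrum.intensity, fmt="%.6e")
    sidecar = {
        "ppm_direct": [float(spectrum.ppm_direct[0]), float(spectrum.ppm_direct[-1])],
        "ppm_indirect": [float(spectrum.ppm_indirect[0]), float(spectrum.ppm_indirect[-1])],
        "shape": list(spectrum.intensity.shape),
        "provenance": spectrum.provenance,
        "noise_estimate": spectrum.noise_estimate,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))
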