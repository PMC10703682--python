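"""Minimal STAR (loop_) reader/writer for metadata interchange.

One data block with a ``loop_`` of named columns, the dialect RELION/cisTEM
era tools exchange.  Unknown columns survive a round trip untouched.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["write_star", "read_star", "export_star", "import_star", "STAR_POSE_COLUMNS"]

# mandatory per-projection columns for interchange
STAR_POSE_COLUMNS = [
    "spcetParticleId",
    "spcetTiltIndex",
    "spcetShiftX",
    "spcetShiftY",
    "spcetAngleTheta",
    "spcetAnglePhi",
    "spcetAnglePsi",
    "spcetDefocus1",
    "spcetDefocus2",
    "spcetAstigAngle",
]


def write_star(path, df: pd.DataFrame, block: str = "particles") -> None:
    """Write a DataFrame as a single-block STAR loop."""
    with open(path, "w") as fh:
        fh.write(f"data_{block}\n\nloop_\n")
        for i, col in enumerate(df.columns, start=1):
            fh.write(f"_{col} #{i}\n")
        for _, row in df.iterrows():
            fh.write(" ".join(_fmt(v) for v in row.to_numpy()) + "\n")


def _fmt(v) -> str:
    if isinstance(v, float):
        return f"{v:.6f}"
    return str(v)


def read_star(path) -> pd.DataFrame:
    """Parse a single-block STAR loop into a DataFrame (numeric where possible)."""
    cols: list[str] = []
    rows: list[list[str]] = []
    in_loop = False
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("data_"):
                continue
            if line == "loop_":
                in_loop = True
                continue
            if line.startswith("_"):
                if not in_loop:
                    continue
                cols.append(line.split()[0].lstrip("_"))
                continue
            if in_loop and cols:
                rows.append(line.split())
    if not cols:
        raise ValueError(f"{path}: no loop_ block found")
    df = pd.DataFrame(rows, columns=cols)
    for c in df.columns:
        try:
            df[c] = pd.to_numeric(df[c])
        except (ValueError, TypeError):
            pass
    return df


def export_star(metadata, path) -> None:
    """Export per-projection metadata (pose + CTF, one row per projection)."""
    df = metadata.projections.copy()
    rename = {
        "particle_id": "spcetParticleId",
        "tilt_index": "spcetTiltIndex",
        "shift_x": "spcetShiftX",
        "shift_y": "spcetShiftY",
        "theta": "spcetAngleTheta",
        "phi": "spcetAnglePhi",
        "psi": "spcetAnglePsi",
        "df1": "spcetDefocus1",
        "df2": "spcetDefocus2",
        "astig_angle": "spcetAstigAngle",
        "score": "spcetScore",
        "region_id": "spcetRegionId",
    }
    df = df.rename(columns=rename)
    write_star(path, df)


def import_star(path) -> pd.DataFrame:
    """Import per-projection metadata; unknown extra columns are preserved.

    Raises ``ValueError`` listing any missing mandatory column by name.
    """
    df = read_star(path)
    missing = [c for c in STAR_POSE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory STAR columns: {', '.join(missing)}")
    back = {
        "spcetParticleId": "particle_id",
        "spcetTiltIndex": "tilt_index",
        "spcetShiftX": "shift_x",
        "spcetShiftY": "shift_y",
        "spcetAngleTheta": "theta",
        "spcetAnglePhi": "phi",
        "spcetAnglePsi": "psi",
        "spcetDefocus1": "df1",
        "spcetDefocus2": "df2",
        "spcetAstigAngle": "astig_angle",
        "spcetScore": "score",
        "spcetRegionId": "region_id",
    }
    return df.rename(columns=back)
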