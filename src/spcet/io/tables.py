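"""Plain-text metadata tables: tilt geometry, particles, per-projection rows.

Tilt geometry and particle tables are tab-separated with a ``#``-prefixed
header line.  The per-projection refinement table (pose, CTF, score, region,
class occupancies — one row per particle per tilt) is bzip2-compressed
tab-separated text; a full project's metadata round-trips losslessly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..ctf import CTFParams
from ..geometry import ParticlePose, TiltGeometry

__all__ = [
    "TILT_COLUMNS",
    "PARTICLE_COLUMNS",
    "ProjectMetadata",
    "write_tilt_table",
    "read_tilt_table",
    "write_particle_table",
    "read_particle_table",
    "write_projection_table",
    "read_projection_table",
]

TILT_COLUMNS = [
    "tilt_index",
    "alpha",
    "beta",
    "shift_x",
    "shift_y",
    "df1",
    "df2",
    "astig_angle",
    "exposure_order",
]

PARTICLE_COLUMNS = ["particle_id", "x", "y", "z", "theta", "phi", "psi", "score"]


def _write_hash_tsv(path, df: pd.DataFrame) -> None:
    with open(path, "w") as fh:
        fh.write("# " + "\t".join(df.columns) + "\n")
        df.to_csv(fh, sep="\t", header=False, index=False, float_format="%.6f")


def _read_hash_tsv(path) -> pd.DataFrame:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise ValueError(f"{path}: expected a '#' header line")
        cols = header.lstrip("#").split()
        return pd.read_csv(fh, sep="\t", header=None, names=cols)


def write_tilt_table(path, tilts, tilt_ctfs=None) -> None:
    rows = []
    for i, t in enumerate(tilts):
        c = tilt_ctfs[i] if tilt_ctfs is not None else None
        rows.append(
            {
                "tilt_index": t.tilt_index,
                "alpha": t.alpha,
                "beta": t.beta,
                "shift_x": t.shift_x,
                "shift_y": t.shift_y,
                "df1": c.df1 if c else 0.0,
                "df2": c.df2 if c else 0.0,
                "astig_angle": c.astig_angle if c else 0.0,
                "exposure_order": t.exposure_order,
            }
        )
    _write_hash_tsv(path, pd.DataFrame(rows, columns=TILT_COLUMNS))


def read_tilt_table(path, optics: dict | None = None):
    """Returns ``(tilts, tilt_ctfs)``; optics constants may override defaults."""
    df = _read_hash_tsv(path)
    optics = optics or {}
    tilts, ctfs = [], []
    for _, r in df.iterrows():
        tilts.append(
            TiltGeometry(
                int(r.tilt_index),
                float(r.alpha),
                float(r.beta),
                float(r.shift_x),
                float(r.shift_y),
                int(r.exposure_order),
            )
        )
        ctfs.append(CTFParams(float(r.df1), float(r.df2), float(r.astig_angle), **optics))
    return tilts, ctfs


def write_particle_table(path, particles) -> None:
    rows = [
        {
            "particle_id": p.particle_id,
            "x": p.pos[0],
            "y": p.pos[1],
            "z": p.pos[2],
            "theta": p.angles[0],
            "phi": p.angles[1],
            "psi": p.angles[2],
            "score": p.score,
        }
        for p in particles
    ]
    _write_hash_tsv(path, pd.DataFrame(rows, columns=PARTICLE_COLUMNS))


def read_particle_table(path):
    df = _read_hash_tsv(path)
    return [
        ParticlePose(
            int(r.particle_id),
            np.array([r.x, r.y, r.z]),
            (float(r.theta), float(r.phi), float(r.psi)),
            float(r.score),
        )
        for _, r in df.iterrows()
    ]


def write_projection_table(path, df: pd.DataFrame) -> None:
    """Per-projection refinement metadata, bzip2-compressed TSV (.tsv.bz2)."""
    df.to_csv(path, sep="\t", index=False, compression="bz2")


def read_projection_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", compression="bz2")


@dataclass
class ProjectMetadata:
    """All project tables plus provenance; referentially consistent."""

    tilts: list
    tilt_ctfs: list
    particles: list
    projections: pd.DataFrame  # one row per (particle, tilt)
    provenance: dict = field(default_factory=dict)

    def validate(self) -> None:
        pids = {p.particle_id for p in self.particles}
        tids = {t.tilt_index for t in self.tilts}
        bad_p = set(self.projections["particle_id"]) - pids
        bad_t = set(self.projections["tilt_index"]) - tids
        if bad_p or bad_t:
            raise ValueError(
                f"projection table references unknown particles {sorted(bad_p)} "
                f"or tilts {sorted(bad_t)}"
            )

    def write(self, directory) -> None:
        import json
        from pathlib import Path

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        write_tilt_table(d / "tilt_geometry.tsv", self.tilts, self.tilt_ctfs)
        write_particle_table(d / "particles.tsv", self.particles)
        write_projection_table(d / "projections.tsv.bz2", self.projections)
        (d / "provenance.json").write_text(json.dumps(self.provenance, indent=2, default=str))

    @classmethod
    def read(cls, directory) -> "ProjectMetadata":
        import json
        from pathlib import Path

        d = Path(directory)
        tilts, ctfs = read_tilt_table(d / "tilt_geometry.tsv")
        particles = read_particle_table(d / "particles.tsv")
        projections = read_projection_table(d / "projections.tsv.bz2")
        prov_path = d / "provenance.json"
        provenance = json.loads(prov_path.read_text()) if prov_path.exists() else {}
        meta = cls(tilts, ctfs, particles, projections, provenance)
        meta.validate()
        return meta


def projection_table_from_model(model, particles, tilt_ctfs, region_ids=None, occupancies=None) -> pd.DataFrame:
    """Build the per-projection table from current poses/CTFs/scores."""
    from ..ctf import particle_defocus
    from ..geometry import compose_projection_pose

    stack = model.stack
    table, _ = model.score_table(particles)
    rows = []
    for p, part in enumerate(particles):
        for t in range(stack.n_tilts):
            if not stack.valid[p, t]:
                continue
            pose = compose_projection_pose(stack.tilts[t], part, center=stack.center)
            c = particle_defocus(tilt_ctfs[t], stack.tilts[t], part.pos, stack.pixel_size, stack.center)
            row = {
                "particle_id": part.particle_id,
                "tilt_index": t,
                "shift_x": pose.shift[0],
                "shift_y": pose.shift[1],
                "theta": pose.angles[0],
                "phi": pose.angles[1],
                "psi": pose.angles[2],
                "df1": c.df1,
                "df2": c.df2,
                "astig_angle": c.astig_angle,
                "score": table[p, t],
                "region_id": int(region_ids[p]) if region_ids is not None else 0,
            }
            if occupancies is not None:
                for k in range(occupancies.shape[1]):
                    row[f"occ_{k}"] = occupancies[p, k]
            rows.append(row)
    return pd.DataFrame(rows)
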