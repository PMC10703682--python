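"""Bundle-wise processing with temporary scratch and the storage model.

Large per-projection intermediates (the 2D particle stacks conventional
pipelines write to disk) exist only under a per-bundle scratch directory and
are deleted when the bundle completes; only the partial reconstructions and
metadata persist.  Because partial reconstructions merge by summation, the
final result is independent of the bundle size and processing order.

The storage model quantifies what this avoids: a conventional sub-volume
workflow stores ``n_particles * box^3 * 4`` bytes of sub-volumes, and a
2D-stack workflow stores ``n_particles * n_tilts * box^2 * 4`` bytes of
extracted projections (1 GB = 2^30 bytes, 1 TB = 2^40 bytes).
"""

from __future__ import annotations

import json
import shutil
import tempfile
from pathlib import Path

from ..reconstruction import PartialReconstruction, merge_bundles

__all__ = ["run_bundles", "estimate_storage"]


def run_bundles(
    items,
    stage,
    bundle_size: int,
    scratch_dir,
    checkpoint_path=None,
):
    """Process ``items`` in bundles through ``stage`` and merge the partials.

    ``stage(bundle_items, scratch_subdir)`` must return a
    :class:`~spcet.reconstruction.PartialReconstruction` (or any object
    accepted by :func:`~spcet.reconstruction.merge_bundles`).  Each bundle
    gets a fresh scratch subdirectory that is removed on completion — nothing
    per-projection survives a successful run.  On failure a resumable JSON
    checkpoint (completed bundle count) is written and the error re-raised.

    Returns ``(merged, n_bundles)``.
    """
    if bundle_size < 1:
        raise ValueError("bundle_size must be >= 1")
    items = list(items)
    bundles = [items[i : i + bundle_size] for i in range(0, len(items), bundle_size)]
    scratch = Path(scratch_dir)
    scratch.mkdir(parents=True, exist_ok=True)
    partials = []
    done = 0
    try:
        for bi, bundle in enumerate(bundles):
            sub = Path(tempfile.mkdtemp(prefix=f"bundle{bi}_", dir=scratch))
            try:
                partials.append(stage(bundle, sub))
            finally:
                shutil.rmtree(sub, ignore_errors=True)
            done += 1
    except Exception:
        if checkpoint_path is not None:
            Path(checkpoint_path).write_text(
                json.dumps({"completed_bundles": done, "bundle_size": bundle_size})
            )
        raise
    merged = merge_bundles(partials) if partials else None
    return merged, len(bundles)


_GB = 2**30
_TB = 2**40


def estimate_storage(
    n_particles: int,
    n_tilts: int,
    box: int,
    frames_per_tilt: int | None = None,
    region_grid: tuple[int, int, int] | None = None,
) -> dict:
    """Storage arithmetic of the conventional workflows this package bypasses.

    Returns projection counts and sizes of the hypothetical extracted 2D
    particle stack and sub-volume set (float32), in bytes and in binary
    GB/TB, plus optional frame and region-grid counts.
    """
    n_proj = n_particles * n_tilts
    stack_bytes = n_proj * box * box * 4
    subvol_bytes = n_particles * box**3 * 4
    out = {
        "n_projections": n_proj,
        "stack_bytes": stack_bytes,
        "stack_gb": stack_bytes / _GB,
        "subvolume_bytes": subvol_bytes,
        "subvolume_tb": subvol_bytes / _TB,
    }
    if frames_per_tilt is not None:
        out["total_frames"] = frames_per_tilt * n_tilts
    if region_grid is not None:
        gx, gy, gz = region_grid
        out["n_regions"] = gx * gy * gz
    return out
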