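"""Superposition, RMSD traces and ligand residence-volume grids.

Residence volumes are voxel occupancy grids: every sampled frame is rigidly
superposed on a reference (default fit: transmembrane Cα), then each ligand
atom increments the voxel containing it; counts are pooled across replicas.
Volume overlap between two conditions is the Jaccard index of the voxel
sets occupied above a frame-fraction threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .structure_io import Selection, Topology, Trajectory

__all__ = [
    "RigidTransform",
    "RMSDTrace",
    "OccupancyGrid",
    "kabsch_superpose",
    "rmsd_trace",
    "residence_volume",
    "grid_overlap",
    "export_grid",
    "read_grid",
]


@dataclass(frozen=True)
class RigidTransform:
    """Proper rotation plus translation, applied as R·x + t."""

    rotation: np.ndarray  # 3×3
    translation: np.ndarray  # 3

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if abs(np.linalg.det(R) - 1.0) > 1e-8:
            raise ValueError("rotation must be proper (det = +1)")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation


@dataclass(frozen=True)
class RMSDTrace:
    """Per-frame RMSD (Å) of a selection against a reference structure."""

    times_ns: tuple[float, ...]
    rmsd: tuple[float, ...]
    selection_label: str = ""
    reference_label: str = ""

    def __post_init__(self):
        if len(self.times_ns) != len(self.rmsd):
            raise ValueError("one RMSD per time point required")
        if any(v < 0 for v in self.rmsd):
            raise ValueError("RMSD values must be non-negative")


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray,
                     ) -> tuple[RigidTransform, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns the optimal proper rotation + translation and the post-fit RMSD.
    Degenerate inputs (< 3 points, or all points collinear) are rejected.
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(reference, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("mobile and reference must be matching N×3 arrays")
    if P.shape[0] < 3:
        raise ValueError("superposition needs at least 3 points")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    # collinearity check: second singular value of either centred set ~ 0
    if np.linalg.svd(P0, compute_uv=False)[1] < 1e-10:
        raise ValueError("degenerate (collinear) point set")
    rot, _ = Rotation.align_vectors(Q0, P0)
    R = rot.as_matrix()
    t = qc - R @ pc
    fitted = P @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - Q) ** 2, axis=1))))
    return RigidTransform(rotation=R, translation=t), rmsd


def rmsd_trace(trajectory: Trajectory, reference_coords: np.ndarray,
               selection: Selection, reference_label: str = "reference",
               ) -> RMSDTrace:
    """Superpose every frame on the reference over ``selection`` and report
    the post-fit RMSD over the same selection."""
    idx = selection.as_array()
    ref = np.asarray(reference_coords, dtype=float)
    if ref.shape[0] != trajectory.topology.n_atoms:
        raise ValueError("reference must cover the full topology")
    if len(idx) < 3:
        raise ValueError("selection too small for superposition")
    ref_sel = ref[idx]
    values = []
    for frame in trajectory.coords:
        _, r = kabsch_superpose(frame[idx], ref_sel)
        values.append(r)
    return RMSDTrace(times_ns=tuple(trajectory.times_ns), rmsd=tuple(values),
                     selection_label=selection.label,
                     reference_label=reference_label)


@dataclass(frozen=True)
class OccupancyGrid:
    """3-D voxel counts of ligand-atom positions.

    ``counts[i, j, k]`` counts atom positions falling in the voxel whose
    lower corner is ``origin + spacing · (i, j, k)``. When every position
    lies inside the box, Σcounts = n_frames × n_ligand_atoms; positions
    outside are tallied in ``n_outside``, never silently dropped.
    """

    origin: tuple[float, float, float]
    spacing: float
    counts: np.ndarray  # (nx, ny, nz) non-negative ints
    n_frames: int
    n_ligand_atoms: int
    n_outside: int = 0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        c = np.asarray(self.counts)
        object.__setattr__(self, "counts", c)
        if c.ndim != 3 or (c < 0).any():
            raise ValueError("counts must be a non-negative 3-D array")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.counts.shape

    def total_count(self) -> int:
        return int(self.counts.sum()) + self.n_outside


def _auto_box(points: np.ndarray, spacing: float, padding: float,
              ) -> tuple[np.ndarray, tuple[int, int, int]]:
    lo = np.floor((points.min(axis=0) - padding) / spacing) * spacing
    hi = np.ceil((points.max(axis=0) + padding) / spacing) * spacing
    dims = np.maximum(np.round((hi - lo) / spacing).astype(int), 1)
    return lo, tuple(int(d) for d in dims)


def residence_volume(trajectories: Sequence[Trajectory],
                     ligand_selection: Selection,
                     fit_selection: Selection | None = None,
                     reference_coords: np.ndarray | None = None,
                     spacing: float = 1.0,
                     stride_ns: float = 0.1,
                     padding: float = 3.0,
                     origin: Sequence[float] | None = None,
                     dims: Sequence[int] | None = None,
                     ) -> OccupancyGrid:
    """Pool ligand-atom positions of all replicas into an occupancy grid.

    Frames are sampled every ``stride_ns`` (default 0.1 ns). With a fit
    selection, each sampled frame is first superposed on the reference
    coordinates (first trajectory's first frame by default) before gridding.
    The box is auto-sized to the pooled ligand extent plus ``padding`` Å,
    snapped to the spacing, unless ``origin``/``dims`` are given.
    """
    if len(ligand_selection) == 0:
        raise ValueError("ligand selection is empty")
    if not trajectories:
        raise ValueError("no trajectories given")
    top = trajectories[0].topology
    for tr in trajectories:
        if tr.topology.n_atoms != top.n_atoms:
            raise ValueError("all trajectories must share one topology")
    lig = ligand_selection.as_array()
    fit = fit_selection.as_array() if fit_selection is not None else None
    if fit is not None and reference_coords is None:
        reference_coords = trajectories[0].coords[0]
    ref_fit = (np.asarray(reference_coords)[fit] if fit is not None else None)

    points = []
    n_sampled = 0
    for tr in trajectories:
        t0 = tr.times_ns[0]
        next_t = t0
        eps = 1e-9
        for t, frame in zip(tr.times_ns, tr.coords):
            if t + eps < next_t:
                continue
            next_t = t + stride_ns
            n_sampled += 1
            if fit is not None:
                tf, _ = kabsch_superpose(frame[fit], ref_fit)
                points.append(tf.apply(frame[lig]))
            else:
                points.append(frame[lig])
    pts = np.concatenate(points, axis=0)

    if origin is None or dims is None:
        lo, dim = _auto_box(pts, spacing, padding)
    else:
        lo, dim = np.asarray(origin, dtype=float), tuple(int(d) for d in dims)
    ijk = np.floor((pts - lo) / spacing).astype(int)
    inside = np.all((ijk >= 0) & (ijk < np.asarray(dim)), axis=1)
    counts = np.zeros(dim, dtype=int)
    np.add.at(counts, tuple(ijk[inside].T), 1)
    return OccupancyGrid(
        origin=tuple(float(v) for v in lo), spacing=float(spacing),
        counts=counts, n_frames=n_sampled, n_ligand_atoms=len(lig),
        n_outside=int((~inside).sum()),
        metadata={"stride_ns": stride_ns, "padding_A": padding},
    )


def grid_overlap(grid_a: OccupancyGrid, grid_b: OccupancyGrid,
                 occupancy_threshold: float = 0.05) -> float:
    """Jaccard index of the voxel sets visited in at least
    ``occupancy_threshold`` of each grid's sampled frames.

    Grids must share origin, spacing and dimensions. Two empty thresholded
    sets give 1.0 (identical sets).
    """
    if (grid_a.dims != grid_b.dims or grid_a.spacing != grid_b.spacing
            or not np.allclose(grid_a.origin, grid_b.origin)):
        raise ValueError("grid geometries differ; resample before comparing")
    occ_a = grid_a.counts / max(grid_a.n_frames, 1) >= occupancy_threshold
    occ_b = grid_b.counts / max(grid_b.n_frames, 1) >= occupancy_threshold
    union = int(np.logical_or(occ_a, occ_b).sum())
    if union == 0:
        return 1.0
    inter = int(np.logical_and(occ_a, occ_b).sum())
    return inter / union


# ---------------------------------------------------------------------------
# OpenDX scalar-field export (lossless for integer counts)
# ---------------------------------------------------------------------------

def export_grid(grid: OccupancyGrid) -> str:
    """Serialize a grid as an OpenDX regular scalar field.

    Data order follows the OpenDX convention: the last (z) index varies
    fastest. Counts are written as integers, so re-import is lossless.
    """
    nx, ny, nz = grid.dims
    ox, oy, oz = grid.origin
    s = grid.spacing
    lines = [
        f"# dynifp occupancy grid: n_frames={grid.n_frames} "
        f"n_ligand_atoms={grid.n_ligand_atoms} n_outside={grid.n_outside}",
        f"object 1 class gridpositions counts {nx} {ny} {nz}",
        f"origin {ox:.6f} {oy:.6f} {oz:.6f}",
        f"delta {s:.6f} 0.000000 0.000000",
        f"delta 0.000000 {s:.6f} 0.000000",
        f"delta 0.000000 0.000000 {s:.6f}",
        f"object 2 class gridconnections counts {nx} {ny} {nz}",
        f"object 3 class array type double rank 0 items {nx * ny * nz} data follows",
    ]
    flat = grid.counts.reshape(-1)  # C order: z fastest
    for i in range(0, len(flat), 3):
        lines.append(" ".join(str(int(v)) for v in flat[i:i + 3]))
    lines.append('attribute "dep" string "positions"')
    lines.append('object "density" class field')
    lines.append('component "positions" value 1')
    lines.append('component "connections" value 2')
    lines.append('component "data" value 3')
    return "\n".join(lines) + "\n"


def read_grid(text: str) -> OccupancyGrid:
    """Parse a grid written by :func:`export_grid` (round-trip partner)."""
    meta = {"n_frames": 0, "n_ligand_atoms": 0, "n_outside": 0}
    origin = (0.0, 0.0, 0.0)
    spacing = 1.0
    dims: tuple[int, int, int] | None = None
    values: list[int] = []
    reading = False
    n_items = 0
    for line in text.splitlines():
        line = line.strip()
        if line.startswith("#"):
            for part in line[1:].replace(":", " ").split():
                if "=" in part:
                    k, v = part.split("=")
                    if k in meta:
                        meta[k] = int(v)
            continue
        if line.startswith("object 1"):
            dims = tuple(int(v) for v in line.split()[-3:])
        elif line.startswith("origin"):
            origin = tuple(float(v) for v in line.split()[1:4])
        elif line.startswith("delta"):
            vals = [float(v) for v in line.split()[1:4]]
            spacing = max(vals)
        elif "data follows" in line:
            n_items = int(line.split()[-3])
            reading = True
        elif reading and len(values) < n_items:
            values.extend(int(round(float(v))) for v in line.split())
    if dims is None:
        raise ValueError("not an OpenDX grid written by export_grid")
    counts = np.asarray(values, dtype=int).reshape(dims)
    return OccupancyGrid(origin=origin, spacing=spacing, counts=counts,
                         n_frames=meta["n_frames"],
                         n_ligand_atoms=meta["n_ligand_atoms"],
                         n_outside=meta["n_outside"])
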