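"""The per-subunit aqueduct cylinder and everything measured inside it.

A 13 Å-radius cylinder, perpendicular to the membrane and passing through
the geometric (x, y) center of the aqueduct-lining helices, is defined for
each subunit and divided into 2 Å slabs.  Inside it this module measures:

* per-slab time-averaged water counts (hydration profile)
* per-frame phosphate counts in the 20 Å-thick core, their moving average
  and normalised count histogram
* per-lipid z-traces of head-group phosphorus atoms and the pooled 1 Å
  z-frequency histogram
* flip-flop events (full/half, flip/flop) via a hysteresis state machine
* lipid tail tilt angles (bisector of the two acyl tails vs +z) and
  head-group P->N dipole angles vs +z

Event-detector thresholds: a lipid is "in a leaflet zone" when |z| >= 15 Å
and "at the midplane" when |z| <= 5 Å.  A full event runs from one leaflet
zone to the opposite one; a half event reaches the midplane band but the
trajectory ends before completion.  Radial excursions out of the cylinder
suspend (not cancel) an event; only a return to the entry leaflet zone
cancels it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import AnalysisConfig, resolve_ranges
from .core import FrameSet, unwrap_z


@dataclass
class AqueductCylinder:
    """Membrane-normal cylinder of one subunit's aqueduct.

    ``axis_xy`` has shape (n_frames, 2): the per-frame (x, y) of the axis
    (a single row is broadcast when the axis is fixed).
    """

    subunit_id: str
    axis_xy: np.ndarray
    radius: float = 13.0
    slab_thickness: float = 2.0
    z_extent: Tuple[float, float] = (-18.0, 18.0)

    def __post_init__(self):
        self.axis_xy = np.atleast_2d(np.asarray(self.axis_xy, dtype=float))
        if self.radius <= 0 or self.slab_thickness <= 0:
            raise ValueError("radius and slab thickness must be positive")

    def axis_at(self, frame: int) -> np.ndarray:
        return self.axis_xy[frame % len(self.axis_xy)]

    def slab_edges(self) -> np.ndarray:
        lo, hi = self.z_extent
        n = int(round((hi - lo) / self.slab_thickness))
        return lo + self.slab_thickness * np.arange(n + 1)

    def inside(self, frame: int, xyz: np.ndarray) -> np.ndarray:
        """Radial test: boolean mask of points within ``radius`` of the axis."""
        ax = self.axis_at(frame)
        d = np.hypot(xyz[..., 0] - ax[0], xyz[..., 1] - ax[1])
        return d <= self.radius


@dataclass
class ZTrace:
    entity_id: int
    species: str
    times: np.ndarray
    z: np.ndarray
    inside: np.ndarray  # bool, radially inside the cylinder
    subunit_id: str = ""


@dataclass
class FlipEvent:
    lipid_id: int
    species: str
    event_class: str  # full_flop | full_flip | half_flop | half_flip
    t_enter: float
    t_exit: float
    z_max: float
    z_min: float
    subunit_id: str = ""
    slab_dwell: Optional[Dict[int, float]] = None


def define_cylinder(
    atoms: pd.DataFrame,
    frameset: FrameSet,
    lining_residue_ranges: Sequence[Tuple[int, int]],
    radius: float = 13.0,
    slab_thickness: float = 2.0,
    z_extent: Tuple[float, float] = (-18.0, 18.0),
    per_frame: bool = True,
) -> Dict[str, AqueductCylinder]:
    """One cylinder per subunit; axis (x, y) is the arithmetic mean of the
    lining-helix atom coordinates, recomputed per frame unless ``per_frame``
    is False (then frame 0 defines a fixed axis)."""
    prot = atoms[atoms["role"] == "protein"]
    mask = resolve_ranges(lining_residue_ranges, prot["residue_id"].to_numpy())
    lining = prot[np.asarray(mask)]
    cylinders: Dict[str, AqueductCylinder] = {}
    for su, grp in lining.groupby("subunit_id"):
        idx = grp["atom_id"].to_numpy()
        if idx.size == 0:
            continue
        nf = frameset.n_frames if per_frame else 1
        axis = np.empty((nf, 2))
        for f in range(nf):
            axis[f] = frameset.coords[f, idx, :2].astype(float).mean(axis=0)
        cylinders[su] = AqueductCylinder(su, axis, radius, slab_thickness, z_extent)
    if not cylinders:
        raise ValueError(
            f"lining residue ranges {list(lining_residue_ranges)} select no atoms"
        )
    return cylinders


def hydration_profile(
    frameset: FrameSet,
    cylinder: AqueductCylinder,
    water_oxygen_idx: np.ndarray,
    window: Optional[Tuple[int, int]] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Per-slab time-averaged water-oxygen counts over a frame window
    (half-open ``[start, stop)``; default: all frames).

    Returns (slab_edges, mean_counts).  Waters exactly on a slab boundary
    belong to the upper slab (half-open [low, high) bins).
    """
    water_oxygen_idx = np.asarray(water_oxygen_idx)
    lo_f, hi_f = window if window is not None else (0, frameset.n_frames)
    if lo_f < 0 or hi_f > frameset.n_frames or hi_f <= lo_f:
        raise ValueError(
            f"window {window} outside trajectory of {frameset.n_frames} frames"
        )
    edges = cylinder.slab_edges()
    acc = np.zeros(len(edges) - 1)
    for f in range(lo_f, hi_f):
        pos = frameset.coords[f, water_oxygen_idx, :].astype(float)
        inside = cylinder.inside(f, pos)
        z = pos[inside, 2]
        # half-open [low, high): shift ties up by assigning via floor
        k = np.floor((z - edges[0]) / cylinder.slab_thickness).astype(int)
        valid = (k >= 0) & (k < len(acc))
        np.add.at(acc, k[valid], 1)
    return edges, acc / (hi_f - lo_f)


def aqueduct_phosphate_series(
    frameset: FrameSet,
    cylinder: AqueductCylinder,
    phosphorus_idx: np.ndarray,
    core_half_thickness: float = 10.0,
    moving_average_bin: int = 20,
    histogram_window: Optional[Tuple[int, int]] = None,
) -> Tuple[np.ndarray, np.ndarray, Dict[int, float]]:
    """Phosphate occupancy of one aqueduct's 20 Å-thick core.

    Returns (per-frame counts, moving average over ``moving_average_bin``
    samples, normalised count histogram over ``histogram_window``).
    """
    phosphorus_idx = np.asarray(phosphorus_idx)
    counts = np.zeros(frameset.n_frames, dtype=int)
    for f in range(frameset.n_frames):
        pos = frameset.coords[f, phosphorus_idx, :].astype(float)
        inside = cylinder.inside(f, pos) & (np.abs(pos[:, 2]) <= core_half_thickness)
        counts[f] = int(inside.sum())
    moving = (
        pd.Series(counts).rolling(moving_average_bin, min_periods=1).mean().to_numpy()
    )
    lo, hi = histogram_window if histogram_window is not None else (0, len(counts))
    windowed = counts[lo:hi]
    if len(windowed) == 0:
        raise ValueError("empty histogram window")
    vals, freq = np.unique(windowed, return_counts=True)
    hist = {int(v): float(c) / len(windowed) for v, c in zip(vals, freq)}
    return counts, moving, hist


def trace_lipids(
    frameset: FrameSet,
    cylinder: AqueductCylinder,
    atoms: pd.DataFrame,
    lipid_phosphorus: Dict[int, int],
    bin_width: float = 1.0,
) -> Tuple[List[ZTrace], Tuple[np.ndarray, np.ndarray]]:
    """z-traces of every lipid phosphorus that ever enters the cylinder,
    plus the pooled z-frequency histogram (1 Å bins) accumulated over
    inside-cylinder samples only."""
    species_of = dict(
        zip(atoms["residue_id"], atoms["residue_name"])
    )
    lipid_ids = np.fromiter(lipid_phosphorus.keys(), dtype=int)
    p_idx = np.fromiter(lipid_phosphorus.values(), dtype=int)
    nf = frameset.n_frames
    pos = frameset.coords[:, p_idx, :].astype(float)  # (nf, nl, 3)
    inside = np.zeros((nf, len(p_idx)), dtype=bool)
    for f in range(nf):
        inside[f] = cylinder.inside(f, pos[f])
    ever = inside.any(axis=0)
    traces: List[ZTrace] = []
    box_z = frameset.boxes[:, 2]
    for k in np.nonzero(ever)[0]:
        z = unwrap_z(pos[:, k, 2], box_z)
        traces.append(
            ZTrace(
                int(lipid_ids[k]),
                str(species_of.get(int(lipid_ids[k]), "?")),
                frameset.times,
                z,
                inside[:, k],
                cylinder.subunit_id,
            )
        )
    zlo, zhi = cylinder.z_extent
    edges = np.arange(zlo, zhi + 0.5 * bin_width, bin_width)
    samples = pos[:, :, 2][inside & np.broadcast_to(ever, inside.shape)]
    hist, _ = np.histogram(samples, bins=edges)
    return traces, (edges, hist)


def detect_flip_events(
    traces: Iterable[ZTrace],
    leaflet_zone: float = 15.0,
    midplane_band: float = 5.0,
) -> List[FlipEvent]:
    """Hysteresis state machine turning z-traces into flip-flop events.

    A pending event starts when a lipid leaves a leaflet zone while inside
    the cylinder.  Completion (``full_flop`` inner->outer, ``full_flip``
    outer->inner) is the first frame the opposite leaflet zone is reached;
    returning to the entry zone cancels; a pending event that has touched
    the midplane band when the trajectory ends is a half event.
    """
    events: List[FlipEvent] = []
    for tr in traces:
        entry_side = 0
        t_enter = None
        reached_mid = False
        was_inside = False  # radially inside the cylinder at least once in transit
        z_lo = z_hi = None
        for i, z in enumerate(tr.z):
            zone = 1 if z >= leaflet_zone else (-1 if z <= -leaflet_zone else 0)
            if zone != 0:
                if (
                    entry_side != 0
                    and zone == -entry_side
                    and t_enter is not None
                    and was_inside
                ):
                    # completed: first frame beyond the far leaflet zone
                    events.append(
                        FlipEvent(
                            tr.entity_id,
                            tr.species,
                            "full_flop" if entry_side < 0 else "full_flip",
                            float(t_enter),
                            float(tr.times[i]),
                            float(z_hi),
                            float(z_lo),
                            tr.subunit_id,
                        )
                    )
                # in any leaflet zone: reset pending state
                entry_side = zone
                t_enter = None
                reached_mid = False
                was_inside = False
                z_lo = z_hi = None
            else:
                if entry_side != 0:
                    if t_enter is None:
                        t_enter = tr.times[i]
                        z_lo = z_hi = z
                    z_lo = min(z_lo, z)
                    z_hi = max(z_hi, z)
                    if tr.inside[i]:
                        was_inside = True
                        if abs(z) <= midplane_band:
                            reached_mid = True
        if entry_side != 0 and t_enter is not None and reached_mid:
            events.append(
                FlipEvent(
                    tr.entity_id,
                    tr.species,
                    "half_flop" if entry_side < 0 else "half_flip",
                    float(t_enter),
                    float(tr.times[-1]),
                    float(z_hi),
                    float(z_lo),
                    tr.subunit_id,
                )
            )
    return events


# ---------------------------------------------------------------------------
# lipid orientation
# ---------------------------------------------------------------------------


def _angle_to_z(vec: np.ndarray) -> np.ndarray:
    """Angle (degrees, [0, 180]) between vectors and +z."""
    norm = np.linalg.norm(vec, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.where(norm > 0, vec[..., 2] / norm, np.nan)
    return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))


def tail_tilt_angles(
    frameset: FrameSet,
    atoms: pd.DataFrame,
    lipid_id: int,
    degenerate_tol: float = 1e-8,
) -> np.ndarray:
    """Per-frame tilt of a lipid's tails: the angle between the normalised
    bisector of the two tail vectors (first-to-last carbon of each tail)
    and +z.  Frames with a degenerate (near-zero) bisector are NaN."""
    lip = atoms[(atoms["residue_id"] == lipid_id) & (atoms["role"] == "lipid_tail")]
    tails: Dict[str, pd.DataFrame] = {}
    for name, grp in lip.groupby(lip["atom_name"].str.extract(r"T(\d+)$")[0]):
        tails[name] = grp
    if len(tails) != 2 or any(len(g) < 2 for g in tails.values()):
        raise ValueError(f"lipid {lipid_id} must have two tails with >=2 carbons")
    vecs = []
    for _, grp in sorted(tails.items()):
        order = grp["atom_name"].str.extract(r"C(\d+)")[0].astype(int).to_numpy()
        idx = grp["atom_id"].to_numpy()[np.argsort(order)]
        v = frameset.coords[:, idx[-1], :].astype(float) - frameset.coords[
            :, idx[0], :
        ].astype(float)
        vecs.append(v / np.linalg.norm(v, axis=1, keepdims=True))
    bisector = vecs[0] + vecs[1]
    blen = np.linalg.norm(bisector, axis=1)
    ang = _angle_to_z(bisector)
    ang[blen < degenerate_tol] = np.nan  # antiparallel tails: undefined
    return ang


def pn_dipole_angles(
    frameset: FrameSet,
    atoms: pd.DataFrame,
    lipid_id: int,
    degenerate_tol: float = 1e-8,
) -> Tuple[np.ndarray, np.ndarray]:
    """Per-frame (z of P, angle of the P->N head-group dipole vs +z)."""
    lip = atoms[atoms["residue_id"] == lipid_id]
    p = lip[(lip["atom_name"] == "P")]
    n = lip[(lip["atom_name"].str.startswith("N"))]
    if len(p) != 1 or len(n) < 1:
        raise ValueError(f"lipid {lipid_id} must carry one P and one N atom")
    pi = int(p["atom_id"].iloc[0])
    ni = int(n["atom_id"].iloc[0])
    pvec = frameset.coords[:, pi, :].astype(float)
    vec = frameset.coords[:, ni, :].astype(float) - pvec
    ang = _angle_to_z(vec)
    ang[np.linalg.norm(vec, axis=1) < degenerate_tol] = np.nan
    return pvec[:, 2], ang
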