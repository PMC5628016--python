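"""Structure/trajectory ingestion, membrane-frame conventions, occupancy grids.

The in-memory model is deliberately simple: an :class:`AtomTable`
(a pandas DataFrame of per-atom metadata with a ``role`` column) plus a
:class:`FrameSet` (a dense ``(n_frames, n_atoms, 3)`` coordinate array with
per-frame box vectors and times in ns).  All downstream analyses operate on
these two objects, so real trajectories (PDB/DCD/XTC via MDAnalysis) and
synthetic ones are interchangeable.

Conventions:

* the bilayer midplane defines z = 0; leaflet phosphates sit near z = +/-18 Å
* coordinates in Å, times in ns
* only orthorhombic boxes are supported; minimum-image wrapping is applied
  in x, y, z where periodicity matters
* voxel and slab bins are half-open ``[low, high)``
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import AnalysisConfig, classify_lipid_atom

ROLES = ("protein", "lipid_head", "lipid_tail", "water", "ion", "bound_cation")


class ClassificationError(ValueError):
    """Raised when residues cannot be mapped onto an analysis role."""


class BoxError(ValueError):
    """Raised for unsupported (triclinic) or invalid simulation boxes."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class FrameSet:
    """Ordered coordinate frames with orthorhombic box and time stamps."""

    times: np.ndarray  # (n_frames,) ns, strictly increasing
    boxes: np.ndarray  # (n_frames, 3) Å
    coords: np.ndarray  # (n_frames, n_atoms, 3) Å

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.boxes = np.asarray(self.boxes, dtype=float)
        self.coords = np.asarray(self.coords)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if len(self.times) != len(self.coords) or len(self.boxes) != len(self.coords):
            raise ValueError("times, boxes and coords must agree on n_frames")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("frame times must be strictly increasing")
        if np.any(self.boxes <= 0):
            raise BoxError("box dimensions must be positive")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def frame_durations(self) -> np.ndarray:
        """Per-frame duration in ns: time to the next frame; the last frame
        reuses the previous spacing (single frame: 1 ns)."""
        if self.n_frames == 1:
            return np.array([1.0])
        d = np.diff(self.times)
        return np.append(d, d[-1])

    def copy(self) -> "FrameSet":
        return FrameSet(self.times.copy(), self.boxes.copy(), self.coords.copy())


def make_atom_table(
    atom_names: Sequence[str],
    residue_names: Sequence[str],
    residue_ids: Sequence[int],
    subunit_ids: Sequence[str],
    roles: Sequence[str],
    elements: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Assemble the canonical AtomTable DataFrame."""
    n = len(atom_names)
    if elements is None:
        elements = [_guess_element(a) for a in atom_names]
    table = pd.DataFrame(
        {
            "atom_id": np.arange(n, dtype=int),
            "atom_name": list(atom_names),
            "element": list(elements),
            "residue_name": list(residue_names),
            "residue_id": np.asarray(residue_ids, dtype=int),
            "subunit_id": list(subunit_ids),
            "role": list(roles),
        }
    )
    bad = set(table["role"]) - set(ROLES)
    if bad:
        raise ClassificationError(f"unknown roles: {sorted(bad)}")
    return table


#: CHARMM ion atom names -> element (protein "CA"/"CB" etc. stay carbon)
_ION_ELEMENTS = {
    "SOD": "Na", "NA": "Na", "CLA": "Cl", "CL": "Cl", "POT": "K", "K": "K",
    "CAL": "Ca", "CES": "Cs", "MG": "Mg",
}


def _guess_element(atom_name: str) -> str:
    name = atom_name.strip().upper()
    if name in _ION_ELEMENTS:
        return _ION_ELEMENTS[name]
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    return "X"


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------


def classify_atoms(
    atom_names: Sequence[str],
    residue_names: Sequence[str],
    residue_ids: Sequence[int],
    segment_ids: Sequence[str],
    residue_roles: Dict[str, str],
) -> Tuple[list, list]:
    """Map residue/atom names to roles and protein segments to subunit labels.

    Unknown residue names are tolerated only inside a segment that also
    contains known protein residues (a polymer chain with, e.g., modified
    residues); otherwise a :class:`ClassificationError` lists them.
    """
    roman = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII"]
    seg_has_protein = {}
    for res, seg in zip(residue_names, segment_ids):
        if residue_roles.get(res) == "protein":
            seg_has_protein[seg] = True
    protein_segs = [s for s in dict.fromkeys(segment_ids) if seg_has_protein.get(s)]
    seg_label = {s: roman[i] if i < len(roman) else str(i + 1)
                 for i, s in enumerate(protein_segs)}

    roles, subunits, unknown = [], [], set()
    for name, res, seg in zip(atom_names, residue_names, segment_ids):
        coarse = residue_roles.get(res)
        if coarse is None:
            if seg_has_protein.get(seg):
                coarse = "protein"  # unknown residue within a polymer chain
            else:
                unknown.add(res)
                roles.append("protein")
                subunits.append("-")
                continue
        if coarse == "lipid":
            roles.append(classify_lipid_atom(name))
        else:
            roles.append(coarse)
        subunits.append(seg_label.get(seg, "-") if coarse == "protein" else "-")
    if unknown:
        raise ClassificationError(
            f"unclassified residue names outside any protein chain: {sorted(unknown)}"
        )
    return roles, subunits


def load_system(
    topology_path,
    trajectory_path=None,
    config: Optional[AnalysisConfig] = None,
) -> Tuple[pd.DataFrame, FrameSet]:
    """Load a PDB topology plus DCD/XTC/multi-model-PDB trajectory.

    Returns the classified :class:`AtomTable` and a :class:`FrameSet` with
    times in ns.  Raises on atom-count mismatch and on triclinic boxes.
    """
    import MDAnalysis as mda

    try:
        if trajectory_path is None:
            u = mda.Universe(str(topology_path))
        else:
            u = mda.Universe(str(topology_path), str(trajectory_path))
    except ValueError as exc:
        # MDAnalysis raises ValueError on topology/trajectory atom mismatch;
        # re-raise with both counts named.
        utop = mda.Universe(str(topology_path))
        n_top = utop.atoms.n_atoms
        raise ValueError(
            f"atom count mismatch between topology ({n_top} atoms) and "
            f"trajectory: {exc}"
        ) from exc

    cfg = config or AnalysisConfig()
    atoms = u.atoms
    segids = [getattr(a, "segid", "") or getattr(a, "chainID", "") for a in atoms]
    roles, subunits = classify_atoms(
        [a.name for a in atoms],
        [a.resname for a in atoms],
        [a.resid for a in atoms],
        segids,
        cfg.residue_roles,
    )
    table = make_atom_table(
        [a.name for a in atoms],
        [a.resname for a in atoms],
        [a.resid for a in atoms],
        subunits,
        roles,
    )

    times, boxes, coords = [], [], []
    for ts in u.trajectory:
        dims = ts.dimensions
        if dims is None or np.all(dims[:3] == 0):
            raise BoxError("trajectory frames carry no box information")
        if not np.allclose(dims[3:], 90.0, atol=1e-3):
            raise BoxError(
                f"triclinic box (angles {dims[3:]}) not supported; "
                "orthorhombic boxes only"
            )
        times.append(ts.time / 1000.0)  # MDAnalysis time is ps
        boxes.append(dims[:3].copy())
        coords.append(ts.positions.copy())
    times = np.asarray(times)
    if len(times) > 1 and np.all(times == times[0]):
        times = np.arange(len(times), dtype=float)  # no time metadata: frame index
    frames = FrameSet(times, np.asarray(boxes), np.asarray(coords))
    return table, frames


# ---------------------------------------------------------------------------
# membrane frame
# ---------------------------------------------------------------------------


def _leaflet_phosphate_means(z: np.ndarray) -> Tuple[float, float]:
    """Split phosphate z values into two leaflets about their mean and
    return (outer mean, inner mean)."""
    mid = z.mean()
    upper = z[z > mid]
    lower = z[z <= mid]
    if len(upper) == 0 or len(lower) == 0:
        raise ValueError("cannot identify two leaflets from phosphate z values")
    return float(upper.mean()), float(lower.mean())


def center_membrane(
    frameset: FrameSet,
    phosphorus_idx: np.ndarray,
    per_frame: bool = True,
) -> FrameSet:
    """Shift z so that the bilayer midplane (midpoint of the two leaflet
    phosphate mean-z values) sits at z = 0.

    ``per_frame=False`` uses the first frame's shift for the whole
    trajectory (fixed reference midplane).
    """
    phosphorus_idx = np.asarray(phosphorus_idx)
    if phosphorus_idx.size == 0:
        raise ValueError("empty phosphorus selection")
    out = frameset.copy()
    shift0 = None
    for f in range(out.n_frames):
        z = out.coords[f, phosphorus_idx, 2].astype(float)
        if per_frame or shift0 is None:
            up, lo = _leaflet_phosphate_means(z)
            shift = 0.5 * (up + lo)
            if shift0 is None:
                shift0 = shift
        if not per_frame:
            shift = shift0
        out.coords[f, :, 2] -= shift
    return out


def assign_leaflets(
    frameset: FrameSet,
    lipid_phosphorus: Dict[int, int],
    frame: int = 0,
    previous: Optional[Dict[int, str]] = None,
) -> Dict[int, str]:
    """Assign each lipid to ``outer`` (P z > 0) or ``inner`` (P z < 0) at the
    designated reference frame of a centered trajectory.

    A phosphorus exactly at z = 0 inherits the previous assignment; without
    one, an error is raised.
    """
    out: Dict[int, str] = {}
    for lipid_id, atom_idx in lipid_phosphorus.items():
        z = float(frameset.coords[frame, atom_idx, 2])
        if z > 0:
            out[lipid_id] = "outer"
        elif z < 0:
            out[lipid_id] = "inner"
        else:
            if previous and lipid_id in previous:
                out[lipid_id] = previous[lipid_id]
            else:
                raise ValueError(
                    f"lipid {lipid_id}: phosphorus exactly at z=0 and no "
                    "previous assignment available"
                )
    return out


def lipid_phosphorus_map(atoms: pd.DataFrame) -> Dict[int, int]:
    """lipid residue_id -> atom index of its head-group phosphorus."""
    lip = atoms[(atoms["role"] == "lipid_head") & (atoms["element"] == "P")]
    counts = lip.groupby("residue_id").size()
    bad = counts[counts != 1]
    if len(bad):
        raise ClassificationError(
            f"lipids must have exactly one phosphorus; offenders: {list(bad.index)}"
        )
    return dict(zip(lip["residue_id"].to_numpy(), lip["atom_id"].to_numpy()))


def unwrap_z(z_trace: np.ndarray, box_z: np.ndarray) -> np.ndarray:
    """Remove periodic-boundary jumps from a z time series.

    Assumes true frame-to-frame displacements are below box_z/2; a raw jump
    exceeding that is corrected by +/- box_z.
    """
    z = np.asarray(z_trace, dtype=float)
    box = np.broadcast_to(np.asarray(box_z, dtype=float), z.shape)
    d = np.diff(z)
    shift = -np.round(d / box[1:]) * box[1:]
    out = z.copy()
    out[1:] += np.cumsum(shift)
    return out


def min_image_displacement(d: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Minimum-image displacement vectors for an orthorhombic box."""
    return d - box * np.round(d / box)


# ---------------------------------------------------------------------------
# occupancy grids
# ---------------------------------------------------------------------------


@dataclass
class OccupancyGrid:
    """3-D occupancy map.

    ``fraction_of_frames``: voxel value = fraction of frames in which at
    least one selected atom visits the voxel (values in [0, 1]).
    ``relative_to_bulk``: time-averaged number density divided by the bulk
    density of the same species.
    """

    origin: np.ndarray  # (3,) Å, low corner
    voxel_edge: float
    values: np.ndarray  # (nx, ny, nz)
    normalization_mode: str
    metadata: Dict = field(default_factory=dict)

    @property
    def dims(self) -> Tuple[int, int, int]:
        return self.values.shape

    def write_dx(self, path) -> None:
        """Write the grid in OpenDX format (via gridData)."""
        from gridData import Grid

        g = Grid(
            self.values.astype(float),
            origin=np.asarray(self.origin, dtype=float) + self.voxel_edge / 2.0,
            delta=[self.voxel_edge] * 3,
        )
        g.export(str(path), file_format="dx")
        if self.metadata:
            # append provenance as DX comments
            with open(path, "a") as fh:
                for k, v in self.metadata.items():
                    fh.write(f"# {k}: {v}\n")


def occupancy_grid(
    frameset: FrameSet,
    selection_idx: np.ndarray,
    voxel_edge: float,
    region: Sequence[Tuple[float, float]],
    normalization_mode: str = "fraction_of_frames",
    bulk_density: Optional[float] = None,
) -> OccupancyGrid:
    """Accumulate an occupancy map of the selected atoms over the trajectory.

    ``region`` is ((xlo, xhi), (ylo, yhi), (zlo, zhi)); voxels are half-open
    cubes of edge ``voxel_edge``.  For ``relative_to_bulk``, a ``bulk_density``
    (atoms/Å^3, e.g. from :func:`estimate_bulk_density`) must be supplied.
    """
    if voxel_edge <= 0:
        raise ValueError("voxel_edge must be positive")
    if normalization_mode not in ("fraction_of_frames", "relative_to_bulk"):
        raise ValueError(f"unknown normalization mode {normalization_mode!r}")
    selection_idx = np.asarray(selection_idx)
    region = np.asarray(region, dtype=float)
    lo = region[:, 0]
    hi = region[:, 1]
    dims = np.maximum(np.ceil((hi - lo - 1e-9) / voxel_edge).astype(int), 1)
    edges = [lo[k] + voxel_edge * np.arange(dims[k] + 1) for k in range(3)]

    if selection_idx.size == 0:
        warnings.warn("occupancy_grid: empty selection, returning zero grid")
        return OccupancyGrid(lo, voxel_edge, np.zeros(dims), normalization_mode)

    acc = np.zeros(dims)
    for f in range(frameset.n_frames):
        pos = frameset.coords[f, selection_idx, :].astype(float)
        counts, _ = np.histogramdd(pos, bins=edges)
        if normalization_mode == "fraction_of_frames":
            acc += counts > 0
        else:
            acc += counts
    if normalization_mode == "fraction_of_frames":
        values = acc / frameset.n_frames
    else:
        if bulk_density is None or bulk_density <= 0:
            raise ValueError("relative_to_bulk mode requires a positive bulk_density")
        mean_density = acc / (frameset.n_frames * voxel_edge**3)
        values = mean_density / bulk_density
    return OccupancyGrid(lo, voxel_edge, values, normalization_mode)


def estimate_bulk_density(
    frameset: FrameSet,
    selection_idx: np.ndarray,
    protein_idx: np.ndarray,
    exclusion_distance: float = 20.0,
    n_volume_samples: int = 20000,
) -> float:
    """Bulk number density (atoms/Å^3) of a species, measured at least
    ``exclusion_distance`` from any protein atom.

    The accessible bulk volume is estimated by uniform Monte-Carlo sampling
    of the box (fixed internal seed: the estimate is deterministic).
    Raises if the box contains no bulk region.
    """
    from scipy.spatial import cKDTree

    rng = np.random.default_rng(1234567)
    total_atoms = 0.0
    total_volume = 0.0
    for f in range(frameset.n_frames):
        box = frameset.boxes[f]
        prot = frameset.coords[f, protein_idx, :].astype(float)
        tree = cKDTree(prot)
        sel = frameset.coords[f, selection_idx, :].astype(float)
        d_sel, _ = tree.query(sel, k=1)
        total_atoms += np.sum(d_sel >= exclusion_distance)
        center = frameset.coords[f].astype(float).mean(axis=0)
        samples = rng.uniform(
            low=center - box / 2.0,
            high=center + box / 2.0,
            size=(n_volume_samples, 3),
        )
        d_smp, _ = tree.query(samples, k=1)
        frac = np.mean(d_smp >= exclusion_distance)
        total_volume += frac * np.prod(box)
    if total_volume <= 0:
        raise ValueError(
            f"no bulk region at least {exclusion_distance} Å from the protein; "
            "box too small"
        )
    return float(total_atoms / total_volume)
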