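"""Lipid-protein and ion-environment interaction statistics.

Electrostatic (polar) contacts are protein N/O atoms within 4 Å of lipid
head-group N/O/P atoms, restricted to head groups inside the aqueduct
cylinder; hydrophobic contacts are protein-carbon / lipid-tail-carbon
pairs within 4 Å anywhere.  Coordination counts donor atoms (water O,
protein N/O, lipid N/O) within 3 Å of an ion or of a lipid head group's
P/O/N atoms.  A residue donating two oxygens in one frame contributes two
coordinations (the coordination *ratio* is a total divided by time) but
only one frame to the contact *fraction* (>=1 contact per frame).

All cutoffs are inclusive (<=) and configurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .aqueduct import AqueductCylinder
from .core import FrameSet


def _pairs_within(
    a: np.ndarray, b: np.ndarray, cutoff: float
) -> List[Tuple[int, int]]:
    """Index pairs (i into a, j into b) with distance <= cutoff."""
    if len(a) == 0 or len(b) == 0:
        return []
    tree = cKDTree(b)
    out: List[Tuple[int, int]] = []
    for i, neigh in enumerate(tree.query_ball_point(a, cutoff)):
        out.extend((i, j) for j in neigh)
    return out


def polar_contacts(
    frameset: FrameSet,
    frame: int,
    atoms: pd.DataFrame,
    cylinder: Optional[AqueductCylinder] = None,
    cutoff: float = 4.0,
) -> List[Tuple[int, int]]:
    """Electrostatic contacts in one frame: (protein atom_id, head-group
    atom_id) pairs within ``cutoff``, head group restricted to N/O/P atoms
    inside the cylinder (if one is given)."""
    prot = atoms[
        (atoms["role"] == "protein") & atoms["element"].isin(["N", "O"])
    ]["atom_id"].to_numpy()
    head = atoms[
        (atoms["role"] == "lipid_head") & atoms["element"].isin(["N", "O", "P"])
    ]["atom_id"].to_numpy()
    pos = frameset.coords[frame].astype(float)
    if cylinder is not None and len(head):
        head = head[cylinder.inside(frame, pos[head])]
    pairs = _pairs_within(pos[prot], pos[head], cutoff)
    return [(int(prot[i]), int(head[j])) for i, j in pairs]


def hydrophobic_contacts(
    frameset: FrameSet,
    frame: int,
    atoms: pd.DataFrame,
    cutoff: float = 4.0,
) -> List[Tuple[int, int]]:
    """Carbon-carbon contacts between protein and lipid tails in one frame."""
    prot = atoms[
        (atoms["role"] == "protein") & (atoms["element"] == "C")
    ]["atom_id"].to_numpy()
    tail = atoms[
        (atoms["role"] == "lipid_tail") & (atoms["element"] == "C")
    ]["atom_id"].to_numpy()
    pos = frameset.coords[frame].astype(float)
    pairs = _pairs_within(pos[prot], pos[tail], cutoff)
    return [(int(prot[i]), int(tail[j])) for i, j in pairs]


def residue_contact_fraction(
    frameset: FrameSet,
    atoms: pd.DataFrame,
    contact_op,
    window: Optional[Tuple[int, int]] = None,
) -> pd.DataFrame:
    """Fraction of frames each protein residue forms >=1 contact.

    ``contact_op(frameset, frame, atoms)`` must return (protein atom_id,
    other atom_id) pairs; the denominator is the number of frames in the
    (half-open) window.
    """
    lo, hi = window if window is not None else (0, frameset.n_frames)
    if hi <= lo:
        raise ValueError("empty analysis window")
    res_of = atoms.set_index("atom_id")[["subunit_id", "residue_id", "residue_name"]]
    counts: Dict[Tuple, int] = {}
    for f in range(lo, hi):
        seen = set()
        for prot_atom, _ in contact_op(frameset, f, atoms):
            row = res_of.loc[prot_atom]
            seen.add((row["subunit_id"], int(row["residue_id"]), row["residue_name"]))
        for key in seen:
            counts[key] = counts.get(key, 0) + 1
    rows = [
        {
            "subunit_id": k[0],
            "residue_id": k[1],
            "residue_name": k[2],
            "fraction": v / (hi - lo),
        }
        for k, v in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=["subunit_id", "residue_id",
                                       "residue_name", "fraction"])


# ---------------------------------------------------------------------------
# coordination
# ---------------------------------------------------------------------------


@dataclass
class CoordinationSeries:
    """Per-frame donor counts by class around one entity (ion or lipid
    head group), at a 3 Å cutoff by default."""

    entity_id: int
    times: np.ndarray
    water_O: np.ndarray
    protein_O_N: np.ndarray
    lipid_O_N: np.ndarray
    cutoff: float = 3.0

    def total(self) -> np.ndarray:
        return self.water_O + self.protein_O_N + self.lipid_O_N


def _donor_indices(atoms: pd.DataFrame, exclude_residue: Optional[int] = None):
    water = atoms[(atoms["role"] == "water") & (atoms["element"] == "O")][
        "atom_id"
    ].to_numpy()
    prot = atoms[
        (atoms["role"] == "protein") & atoms["element"].isin(["O", "N"])
    ]["atom_id"].to_numpy()
    lip = atoms[
        atoms["role"].isin(["lipid_head", "lipid_tail"])
        & atoms["element"].isin(["O", "N"])
    ]
    if exclude_residue is not None:
        lip = lip[lip["residue_id"] != exclude_residue]
    return water, prot, lip["atom_id"].to_numpy()


def coordination_series(
    frameset: FrameSet,
    atoms: pd.DataFrame,
    center: int | Sequence[int],
    cutoff: float = 3.0,
    center_is_lipid: bool = False,
) -> CoordinationSeries:
    """Donor counts within ``cutoff`` of an entity, per frame.

    ``center`` is an ion atom_id, or (for a lipid) the residue_id whose
    head-group P/O/N atoms define the center; the lipid's own atoms are
    excluded from the donors.
    """
    if center_is_lipid:
        lipid_id = int(center)
        centers = atoms[
            (atoms["residue_id"] == lipid_id)
            & (atoms["role"] == "lipid_head")
            & atoms["element"].isin(["P", "O", "N"])
        ]["atom_id"].to_numpy()
        water, prot, lip = _donor_indices(atoms, exclude_residue=lipid_id)
        entity = lipid_id
    else:
        centers = np.asarray([int(center)])
        water, prot, lip = _donor_indices(atoms)
        entity = int(center)

    nf = frameset.n_frames
    out = {k: np.zeros(nf, dtype=int) for k in ("water_O", "protein_O_N", "lipid_O_N")}
    for f in range(nf):
        pos = frameset.coords[f].astype(float)
        c = pos[centers]
        for key, donors in (("water_O", water), ("protein_O_N", prot),
                            ("lipid_O_N", lip)):
            if len(donors) == 0:
                continue
            d = np.linalg.norm(pos[donors][None, :, :] - c[:, None, :], axis=2)
            out[key][f] = int(np.sum(d.min(axis=0) <= cutoff))
    return CoordinationSeries(
        entity, frameset.times, out["water_O"], out["protein_O_N"],
        out["lipid_O_N"], cutoff,
    )


def event_average_coordination(
    series: CoordinationSeries,
    event_window: Tuple[float, float],
    frame_durations: Optional[np.ndarray] = None,
) -> Tuple[float, Dict[str, float]]:
    """Duration-weighted mean coordination over an event, plus the
    percentage split of total coordinations by donor class (sums to 100)."""
    t0, t1 = event_window
    mask = (series.times >= t0) & (series.times <= t1)
    if not mask.any() or t1 <= t0:
        raise ValueError(f"zero-length or out-of-range event window {event_window}")
    if frame_durations is None:
        dt = np.diff(series.times)
        frame_durations = np.append(dt, dt[-1]) if len(dt) else np.array([1.0])
    w = frame_durations[mask]
    totals = {
        "water_O": float(np.sum(series.water_O[mask] * w)),
        "protein_O_N": float(np.sum(series.protein_O_N[mask] * w)),
        "lipid_O_N": float(np.sum(series.lipid_O_N[mask] * w)),
    }
    grand = sum(totals.values())
    mean = grand / float(np.sum(w))
    percents = {
        k: (100.0 * v / grand if grand > 0 else 0.0) for k, v in totals.items()
    }
    return mean, percents


def headgroup_coordination_histogram(
    series: CoordinationSeries,
    event_window: Tuple[float, float],
    donor: str = "protein_O_N",
) -> Tuple[Dict[int, float], float]:
    """Normalised histogram of the head-group coordination number during an
    event, plus the fraction of frames with count >= 2."""
    t0, t1 = event_window
    mask = (series.times >= t0) & (series.times <= t1)
    if not mask.any():
        raise ValueError(f"event window {event_window} outside the series")
    counts = getattr(series, donor)[mask]
    vals, freq = np.unique(counts, return_counts=True)
    hist = {int(v): float(c) / len(counts) for v, c in zip(vals, freq)}
    frac_ge2 = float(np.mean(counts >= 2))
    return hist, frac_ge2


def coordination_ratio(
    frameset: FrameSet,
    atoms: pd.DataFrame,
    lipid_ids_by_species: Dict[str, Sequence[int]],
    residue_ids: Sequence[int],
    cutoff: float = 3.0,
    window: Optional[Tuple[int, int]] = None,
) -> pd.DataFrame:
    """Per-residue, per-species coordination ratio (coordinations/ns).

    For each protein residue, the total number of its N/O donor atoms found
    within ``cutoff`` of any head-group P/O/N atom of lipids of a species —
    counted per donor atom per frame and weighted by frame duration — is
    divided by the window duration.
    """
    lo, hi = window if window is not None else (0, frameset.n_frames)
    durations = frameset.frame_durations()[lo:hi]
    total_time = float(durations.sum())
    if total_time <= 0:
        raise ValueError("window duration must be positive")
    prot = atoms[
        (atoms["role"] == "protein")
        & atoms["element"].isin(["O", "N"])
        & atoms["residue_id"].isin(list(residue_ids))
    ]
    rows = []
    for species, lipid_ids in lipid_ids_by_species.items():
        heads = atoms[
            atoms["residue_id"].isin(list(lipid_ids))
            & (atoms["role"] == "lipid_head")
            & atoms["element"].isin(["P", "O", "N"])
        ]["atom_id"].to_numpy()
        per_res = {}
        for (su, rid), grp in prot.groupby(["subunit_id", "residue_id"]):
            donors = grp["atom_id"].to_numpy()
            tot = 0.0
            for fi, f in enumerate(range(lo, hi)):
                pos = frameset.coords[f].astype(float)
                if len(heads) == 0:
                    break
                d = np.linalg.norm(
                    pos[donors][:, None, :] - pos[heads][None, :, :], axis=2
                )
                # one coordination per donor atom per frame (donor may serve
                # any head atom); weighted by the frame's duration
                tot += float(np.sum(d.min(axis=1) <= cutoff)) * durations[fi]
            per_res[(su, rid)] = tot / total_time
        for (su, rid), ratio in sorted(per_res.items()):
            rows.append(
                {
                    "subunit_id": su,
                    "residue_id": rid,
                    "species": species,
                    "ratio_per_ns": ratio,
                }
            )
    return pd.DataFrame(
        rows, columns=["subunit_id", "residue_id", "species", "ratio_per_ns"]
    )
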