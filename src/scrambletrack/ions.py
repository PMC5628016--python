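"""Ion permeation through the aqueduct and applied-field voltage conversion.

A permeation event is a crossing from beyond one boundary plane
(z = +/-15 Å by default) to beyond the opposite one, with the ion radially
inside the subunit's aqueduct cylinder throughout the |z| <= 10 Å core
(ions may approach through the wide vestibules outside the cylinder).
Completion time is the first frame beyond the far plane; an ion that
reverses before reaching the far plane produces no event (hysteresis), and
periodic-boundary wraps are removed before detection so a wrap is never a
permeation.

The membrane potential of an applied uniform field E along -z is
V = -E * Lz (inward-negative), e.g. E = 3.74 mV/Å with Lz = 133.64 Å gives
approximately -500 mV.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np
import pandas as pd

from .aqueduct import AqueductCylinder
from .core import FrameSet, unwrap_z


@dataclass
class PermeationEvent:
    ion_id: int
    species: str
    direction: str  # inward (extracellular -> intracellular) | outward
    subunit_id: str
    t_start: float
    t_complete: float

    @property
    def duration(self) -> float:
        return self.t_complete - self.t_start


def ion_z_traces(
    frameset: FrameSet, atoms: pd.DataFrame
) -> Dict[int, Tuple[str, np.ndarray, np.ndarray]]:
    """ion residue_id -> (species, unwrapped z trace, xy positions)."""
    ions = atoms[atoms["role"] == "ion"]
    out = {}
    box_z = frameset.boxes[:, 2]
    for _, row in ions.iterrows():
        i = int(row["atom_id"])
        z = unwrap_z(frameset.coords[:, i, 2].astype(float), box_z)
        xy = frameset.coords[:, i, :2].astype(float)
        out[int(row["residue_id"])] = (str(row["element"]), z, xy)
    return out


def detect_ion_permeations(
    frameset: FrameSet,
    atoms: pd.DataFrame,
    cylinders: Dict[str, AqueductCylinder],
    boundary_planes: float = 15.0,
    core_half_thickness: float = 10.0,
) -> List[PermeationEvent]:
    """Detect full ion crossings through any subunit's aqueduct."""
    events: List[PermeationEvent] = []
    traces = ion_z_traces(frameset, atoms)
    for ion_id, (species, z, xy) in traces.items():
        side = 0
        t_start = None
        start_index = None
        for i, zi in enumerate(z):
            zone = 1 if zi >= boundary_planes else (-1 if zi <= -boundary_planes else 0)
            if zone != 0:
                if side != 0 and zone == -side and t_start is not None:
                    su = _core_subunit(
                        frameset, cylinders, xy, z, start_index, i,
                        core_half_thickness,
                    )
                    if su is not None:
                        events.append(
                            PermeationEvent(
                                ion_id,
                                species,
                                "inward" if side > 0 else "outward",
                                su,
                                float(frameset.times[start_index]),
                                float(frameset.times[i]),
                            )
                        )
                side = zone
                t_start = None
                start_index = None
            else:
                if side != 0 and t_start is None:
                    t_start = frameset.times[i]
                    start_index = i
    return events


def _core_subunit(
    frameset: FrameSet,
    cylinders: Dict[str, AqueductCylinder],
    xy: np.ndarray,
    z: np.ndarray,
    i0: int,
    i1: int,
    core_half_thickness: float,
) -> Optional[str]:
    """The subunit whose cylinder radially contains the ion for every frame
    of the crossing with |z| <= core_half_thickness, or None."""
    core_frames = [i for i in range(i0, i1) if abs(z[i]) <= core_half_thickness]
    for su, cyl in cylinders.items():
        ok = all(
            np.hypot(*(xy[i] - cyl.axis_at(i))) <= cyl.radius for i in core_frames
        )
        if ok:
            return su
    return None


def permeation_summary(events: Iterable[PermeationEvent]) -> pd.DataFrame:
    """Counts per (species, direction, subunit) plus sorted completion times."""
    rows: Dict[Tuple[str, str, str], List[float]] = {}
    for ev in events:
        rows.setdefault((ev.species, ev.direction, ev.subunit_id), []).append(
            ev.t_complete
        )
    out = [
        {
            "species": k[0],
            "direction": k[1],
            "subunit_id": k[2],
            "count": len(v),
            "completion_times": sorted(v),
        }
        for k, v in sorted(rows.items())
    ]
    return pd.DataFrame(
        out, columns=["species", "direction", "subunit_id", "count",
                      "completion_times"]
    )


def applied_voltage(E: float, Lz: float) -> float:
    """Transmembrane potential (mV) of a uniform field E (mV/Å) applied
    along -z across a box of height Lz (Å): V = -E * Lz, inward-negative."""
    if Lz <= 0:
        raise ValueError("Lz must be positive")
    return -E * Lz
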