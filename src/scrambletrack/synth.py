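"""Ground-truth-labelled synthetic scramblase systems.

Builds a minimal stand-in for a membrane-embedded two-subunit scramblase:
an asymmetric POPC/POPS bilayer (outer leaflet phosphates near z = +18 Å,
inner near z = -18 Å; inner leaflet a 2:1 POPC:POPS mixture), two rigid
pseudo-protein helix bundles that define per-subunit aqueduct cylinders,
cylinder water at a configurable per-slab density, bulk ions, a bound
Ca2+ pair per subunit, and *scripted* events — lipid flip-flops through
the aqueduct (with an optional dwell at the central site near z = -3 Å),
ion crossings, and gate pinch toggling — each logged to a
:class:`TruthLog` so every event detector can be validated exactly.

The generator is purely positional (no velocities); i.i.d. Gaussian noise
of width ``noise_sigma`` is added to every atom in every frame.  The same
seed always yields byte-identical output.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .core import FrameSet, make_atom_table

EVENT_TYPES = ("full_flop", "full_flip", "half_flop", "half_flip", "ion_in", "ion_out")


@dataclass
class FlipScript:
    """A scripted lipid translocation through one subunit's aqueduct.

    Full events run leaflet to leaflet; half events reach the midplane dwell
    site and hold it until the trajectory ends.
    """

    kind: str  # full_flop | full_flip | half_flop | half_flip
    species: str  # POPC | POPS
    subunit: str  # I | II
    start_frame: int
    end_frame: int
    dwell_fraction: float = 0.3  # fraction of the event spent at the central site

    def __post_init__(self):
        if self.kind not in ("full_flop", "full_flip", "half_flop", "half_flip"):
            raise ValueError(f"unknown flip kind {self.kind!r}")


@dataclass
class IonScript:
    """A scripted ion crossing through one subunit's aqueduct."""

    species: str  # Na | Cl
    direction: str  # inward (extracellular -> intracellular) | outward
    subunit: str
    start_frame: int
    end_frame: int

    def __post_init__(self):
        if self.direction not in ("inward", "outward"):
            raise ValueError(f"unknown direction {self.direction!r}")


@dataclass
class SyntheticScenario:
    """Parameters of the stated synthetic world.

    Defaults mirror the simulated system: 204 x 162 x 130 Å box, leaflet
    phosphates at +/-18 Å, outer leaflet pure POPC, inner 2:1 POPC:POPS.
    The default event schedule scripts the reported event census: 5 full
    floppings (2 POPS + 3 POPC), 3 half-flops (2 POPC + 1 POPS), 1
    half-flip (POPC), and 24 inward Na+ crossings, plus a 40% gate-pinch
    duty cycle.
    """

    n_lipids_per_leaflet: int = 128
    leaflet_z: float = 18.0
    box: Tuple[float, float, float] = (204.0, 162.0, 130.0)
    inner_pops_fraction: float = 1.0 / 3.0  # 2:1 POPC:POPS inner leaflet
    event_schedule: Optional[List[object]] = None  # None -> default schedule
    water_per_slab: int = 6
    water_placement: str = "per_slab"  # per_slab | uniform
    n_background_ions: int = 20
    pinch_duty_cycle: float = 0.40
    pinch_closed_distance: float = 2.5
    pinch_open_distance: float = 8.0
    noise_sigma: float = 0.5
    seed: int = 2017
    n_frames: int = 2000
    dt: float = 0.5  # ns

    # geometry of the pseudo-protein (rigid helix bundles)
    subunit_axis_x: float = 34.0  # subunits at (-x, 0) and (+x, 0)
    helix_radius: float = 9.0
    n_helices: int = 6
    helix_z: Tuple[float, float, float] = (-20.0, 20.0, 2.0)  # lo, hi, step
    cylinder_radius: float = 13.0

    def default_schedule(self) -> List[object]:
        n = self.n_frames
        if n < 40:
            raise ValueError("default schedule needs at least 40 frames")
        s = []
        # 5 full floppings: 2 POPS + 3 POPC, alternating subunits
        full = [("POPS", "I"), ("POPC", "II"), ("POPS", "I"),
                ("POPC", "II"), ("POPC", "I")]
        for k, (sp, su) in enumerate(full):
            a = int(n * (0.05 + 0.16 * k))
            b = a + int(n * 0.14)
            s.append(FlipScript("full_flop", sp, su, a, min(b, n - 2)))
        # 3 half-flops (2 POPC + 1 POPS) and 1 half-flip (POPC): run to the end
        for k, (sp, su) in enumerate([("POPC", "II"), ("POPC", "I"), ("POPS", "II")]):
            a = int(n * (0.10 + 0.2 * k))
            s.append(FlipScript("half_flop", sp, su, a, n - 1))
        s.append(FlipScript("half_flip", "POPC", "II", int(n * 0.3), n - 1))
        # 24 inward Na+ crossings, 12 per subunit
        for k in range(24):
            su = "I" if k % 2 == 0 else "II"
            a = int(n * (0.03 + 0.039 * k))
            s.append(IonScript("Na", "inward", su, a, min(a + max(n // 50, 4), n - 1)))
        return s


@dataclass
class TruthEvent:
    type: str
    entity_id: int
    species: str
    subunit: str
    start_frame: int
    end_frame: int

    def __post_init__(self):
        if self.type not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.type!r}")


@dataclass
class TruthLog:
    """One record per scripted event, plus the gate pinch schedule."""

    events: List[TruthEvent] = field(default_factory=list)
    pinch_schedule: Optional[np.ndarray] = None  # (n_frames,) bool

    def to_json(self, path) -> None:
        data = {
            "events": [asdict(e) for e in self.events],
            "pinch_schedule": (
                self.pinch_schedule.astype(int).tolist()
                if self.pinch_schedule is not None
                else None
            ),
        }
        with open(path, "w") as fh:
            json.dump(data, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "TruthLog":
        with open(path) as fh:
            data = json.load(fh)
        events = [TruthEvent(**e) for e in data["events"]]
        sched = data.get("pinch_schedule")
        return cls(events, None if sched is None else np.asarray(sched, bool))

    def count(self, type: str, species: Optional[str] = None) -> int:
        return sum(
            1
            for e in self.events
            if e.type == type and (species is None or e.species == species)
        )


# gate pseudo-residues: (resid, resname, side, z); TM4 side carries the
# mobile atoms, TM6 side is fixed.  The (333, 439) pair is coplanar so the
# closed-gate minimum distance equals pinch_closed_distance exactly.
_GATE_RESIDUES = [
    (330, "PHE", "TM4", 8.0),
    (333, "THR", "TM4", 10.0),
    (336, "LEU", "TM4", 12.0),
    (337, "VAL", "TM4", 9.0),
    (439, "TYR", "TM6", 10.0),
    (443, "THR", "TM6", 9.0),
]

#: residue ranges of the six lining helices (per subunit)
LINING_RANGES: List[Tuple[int, int]] = [
    (501, 521), (531, 551), (561, 581), (591, 611), (621, 641), (651, 671)
]


def _c2(xy: np.ndarray) -> np.ndarray:
    """Apply the dimer's C2 symmetry (180 deg rotation about z)."""
    return -xy


def generate(scenario: SyntheticScenario) -> Tuple[pd.DataFrame, FrameSet, TruthLog]:
    """Build the synthetic system and its ground-truth event log."""
    sc = scenario
    rng = np.random.default_rng(sc.seed)
    n_frames = sc.n_frames
    schedule = sc.event_schedule if sc.event_schedule is not None else sc.default_schedule()
    for ev in schedule:
        if ev.end_frame >= n_frames or ev.start_frame < 0:
            raise ValueError(
                f"scripted event {ev} exceeds the {n_frames}-frame trajectory"
            )
        if ev.end_frame <= ev.start_frame:
            raise ValueError(f"scripted event {ev} has non-positive duration")

    axes = {"I": np.array([-sc.subunit_axis_x, 0.0]),
            "II": np.array([+sc.subunit_axis_x, 0.0])}

    names: List[str] = []
    resnames: List[str] = []
    resids: List[int] = []
    subunits: List[str] = []
    roles: List[str] = []
    segids: List[str] = []
    base: List[np.ndarray] = []  # static base positions

    # ---- pseudo-protein: two rigid bundles related by C2 symmetry ----
    zlo, zhi, zstep = sc.helix_z
    helix_zs = np.arange(zlo, zhi + 0.5 * zstep, zstep)
    gate_atom_idx: Dict[Tuple[str, int], int] = {}
    for su, seg in (("I", "PROA"), ("II", "PROB")):
        ax = axes[su]
        for h in range(sc.n_helices):
            ang = 2 * math.pi * h / sc.n_helices
            hx = sc.helix_radius * math.cos(ang)
            hy = sc.helix_radius * math.sin(ang)
            lo_res = LINING_RANGES[h % len(LINING_RANGES)][0]
            for i, z in enumerate(helix_zs):
                xy = np.array([hx, hy])
                if su == "II":
                    xy = _c2(xy + ax) - _c2(ax)  # rotate offset, keep own axis
                names.append("CA")
                resnames.append("ALA")
                resids.append(lo_res + i)
                subunits.append(su)
                roles.append("protein")
                segids.append(seg)
                base.append(np.array([ax[0] + xy[0], ax[1] + xy[1], z]))
        for resid, resname, side, z in _GATE_RESIDUES:
            off = np.array([0.0, sc.pinch_open_distance / 2.0])
            if side == "TM6":
                off = -off
            if su == "II":
                off = _c2(off)
            gate_atom_idx[(su, resid)] = len(names)
            names.append("CB")
            resnames.append(resname)
            resids.append(resid)
            subunits.append(su)
            roles.append("protein")
            segids.append(seg)
            base.append(np.array([ax[0] + off[0], ax[1] + off[1], z]))

    # ---- lipids ----
    bx, by, bz = sc.box
    spacing = 14.0
    xs = np.arange(-bx / 2 + 8, bx / 2 - 8, spacing)
    ys = np.arange(-by / 2 + 8, by / 2 - 8, spacing)
    sites = []
    for x in xs:
        for y in ys:
            if all(np.hypot(x - a[0], y - a[1]) > sc.cylinder_radius + 3.0
                   for a in axes.values()):
                sites.append((x, y))
    if len(sites) < sc.n_lipids_per_leaflet:
        raise ValueError(
            f"box too small: {len(sites)} lipid sites for "
            f"{sc.n_lipids_per_leaflet} lipids per leaflet"
        )

    n_inner_pops = int(round(sc.n_lipids_per_leaflet * sc.inner_pops_fraction))
    lipid_species: List[str] = []
    lipid_leaflet: List[str] = []
    for leaflet in ("outer", "inner"):
        for k in range(sc.n_lipids_per_leaflet):
            if leaflet == "outer":
                lipid_species.append("POPC")
            else:
                lipid_species.append("POPS" if k < n_inner_pops else "POPC")
            lipid_leaflet.append(leaflet)
    n_lipids = len(lipid_species)

    # assign scripted lipids: pick from the correct leaflet and species pool
    flip_scripts = [ev for ev in schedule if isinstance(ev, FlipScript)]
    ion_scripts = [ev for ev in schedule if isinstance(ev, IonScript)]
    free = {
        ("outer", "POPC"): [i for i in range(n_lipids)
                            if lipid_leaflet[i] == "outer"],
        ("inner", "POPS"): [i for i in range(n_lipids)
                            if lipid_leaflet[i] == "inner" and lipid_species[i] == "POPS"],
        ("inner", "POPC"): [i for i in range(n_lipids)
                            if lipid_leaflet[i] == "inner" and lipid_species[i] == "POPC"],
    }
    script_lipid: List[int] = []
    per_subunit_count: Dict[str, int] = {"I": 0, "II": 0}
    script_offset_angle: List[float] = []
    for ev in flip_scripts:
        leaf = "outer" if ev.kind in ("full_flip", "half_flip") else "inner"
        pool = free[(leaf, ev.species)]
        if not pool:
            raise ValueError(f"no free {leaf} {ev.species} lipid for event {ev}")
        script_lipid.append(pool.pop(0))
        script_offset_angle.append(
            2 * math.pi * per_subunit_count[ev.subunit] / max(len(flip_scripts), 1)
        )
        per_subunit_count[ev.subunit] += 1

    # leaflets stack: each leaflet draws from its own copy of the site grid
    lipid_xy = np.zeros((n_lipids, 2))
    site_counter = {"outer": 0, "inner": 0}
    for i in range(n_lipids):
        if i in script_lipid:
            ev = flip_scripts[script_lipid.index(i)]
            ang = script_offset_angle[script_lipid.index(i)]
            lipid_xy[i] = axes[ev.subunit] + 3.0 * np.array(
                [math.cos(ang), math.sin(ang)]
            )
        else:
            leaf = lipid_leaflet[i]
            lipid_xy[i] = sites[site_counter[leaf]]
            site_counter[leaf] += 1

    # lipid z paths (phosphorus), shape (n_frames, n_lipids)
    sgn0 = np.array([+1.0 if l == "outer" else -1.0 for l in lipid_leaflet])
    lipid_pz = np.tile(sgn0 * sc.leaflet_z, (n_frames, 1))
    truth = TruthLog()
    for ev, lid in zip(flip_scripts, script_lipid):
        z0 = -sc.leaflet_z if ev.kind in ("full_flop", "half_flop") else sc.leaflet_z
        dwell_z = -3.0 if z0 < 0 else 3.0
        path = np.full(n_frames, z0)
        a, b = ev.start_frame, ev.end_frame
        if ev.kind.startswith("full"):
            z1 = -z0
            # piecewise-linear: leaflet -> dwell site -> far leaflet
            t_mid = a + int((b - a) * (1 - ev.dwell_fraction) * 0.5)
            t_mid2 = t_mid + int((b - a) * ev.dwell_fraction)
            path[a:t_mid] = np.linspace(z0, dwell_z, t_mid - a, endpoint=False)
            path[t_mid:t_mid2] = dwell_z
            path[t_mid2:b] = np.linspace(dwell_z, z1, b - t_mid2, endpoint=False)
            path[b:] = z1
        else:
            # half event: reach the midplane dwell site and hold to the end
            t_reach = min(b, a + max((b - a) // 4, 2))
            path[a:t_reach] = np.linspace(z0, dwell_z, t_reach - a, endpoint=False)
            path[t_reach:] = dwell_z
        lipid_pz[:, lid] = path
        truth.events.append(
            TruthEvent(ev.kind, int(lid) + 1, ev.species, ev.subunit,
                       ev.start_frame, ev.end_frame)  # residue_id = index + 1
        )

    # lipid atoms: P, N, two 8-carbon tails (minimal set for tilt/dipole/
    # contact analyses); tails point toward the midplane, N sits outward.
    n_tail = 8
    lipid_atom_start = len(names)
    for i in range(n_lipids):
        rid = i + 1
        names.append("P")
        resnames.append(lipid_species[i])
        resids.append(rid)
        subunits.append("-")
        roles.append("lipid_head")
        segids.append("MEMB")
        base.append(np.zeros(3))
        names.append("N")
        resnames.append(lipid_species[i])
        resids.append(rid)
        subunits.append("-")
        roles.append("lipid_head")
        segids.append("MEMB")
        base.append(np.zeros(3))
        for t in range(2):
            for c in range(n_tail):
                names.append(f"C{c + 1}T{t + 1}")
                resnames.append(lipid_species[i])
                resids.append(rid)
                subunits.append("-")
                roles.append("lipid_tail")
                segids.append("MEMB")
                base.append(np.zeros(3))
    atoms_per_lipid = 2 + 2 * n_tail

    # ---- cylinder water (oxygen pseudo-atoms) ----
    water_start = len(names)
    water_base = []
    zlo_c, zhi_c = -sc.leaflet_z, sc.leaflet_z
    n_slabs = int(round((zhi_c - zlo_c) / 2.0))
    wid = 1000
    for su, ax in axes.items():
        if sc.water_placement == "per_slab":
            for s in range(n_slabs):
                z0s = zlo_c + 2.0 * s
                for _ in range(sc.water_per_slab):
                    r = sc.cylinder_radius * math.sqrt(rng.uniform())
                    th = rng.uniform(0, 2 * math.pi)
                    z = rng.uniform(z0s, z0s + 2.0)
                    water_base.append(
                        [ax[0] + r * math.cos(th), ax[1] + r * math.sin(th), z]
                    )
        elif sc.water_placement == "uniform":
            n_total = sc.water_per_slab * n_slabs
            for _ in range(n_total):
                r = sc.cylinder_radius * math.sqrt(rng.uniform())
                th = rng.uniform(0, 2 * math.pi)
                z = rng.uniform(zlo_c, zhi_c)
                water_base.append(
                    [ax[0] + r * math.cos(th), ax[1] + r * math.sin(th), z]
                )
        else:
            raise ValueError(f"unknown water placement {sc.water_placement!r}")
    for pos in water_base:
        names.append("OH2")
        resnames.append("TIP3")
        resids.append(wid)
        subunits.append("-")
        roles.append("water")
        segids.append("SOLV")
        base.append(np.asarray(pos))
        wid += 1

    # ---- ions ----
    ion_start = len(names)
    iid = 3000
    ion_scripted_idx = []
    for ev in ion_scripts:
        ion_scripted_idx.append(len(names))
        names.append("SOD" if ev.species == "Na" else "CLA")
        resnames.append("SOD" if ev.species == "Na" else "CLA")
        resids.append(iid)
        subunits.append("-")
        roles.append("ion")
        segids.append("IONS")
        base.append(np.zeros(3))
        iid += 1
    for k in range(sc.n_background_ions):
        species = "SOD" if k % 2 == 0 else "CLA"
        names.append(species)
        resnames.append(species)
        resids.append(iid)
        subunits.append("-")
        roles.append("ion")
        segids.append("IONS")
        x = rng.uniform(-bx / 2 + 5, bx / 2 - 5)
        y = rng.uniform(-by / 2 + 5, by / 2 - 5)
        z = rng.choice([-1.0, 1.0]) * rng.uniform(30.0, bz / 2 - 5)
        base.append(np.array([x, y, z]))
        iid += 1
    # bound Ca2+ pair per subunit, near the cytoplasmic end of the aqueduct
    for su, ax in axes.items():
        for k, z in enumerate((-10.0, -12.0)):
            names.append("CAL")
            resnames.append("CAL")
            resids.append(iid)
            subunits.append("-")
            roles.append("bound_cation")
            segids.append("IONS")
            base.append(np.array([ax[0], ax[1] - 6.0, z]))
            iid += 1

    if len(names) == 0:
        raise ValueError("empty system")

    # ---- assemble frames ----
    n_atoms = len(names)
    base_arr = np.asarray(base)
    coords = np.empty((n_frames, n_atoms, 3), dtype=np.float32)
    coords[:] = base_arr[None, :, :]

    # lipid positions follow the scripted phosphorus z; rebuild per lipid
    tail_dz = 1.8 * (np.arange(n_tail) + 1)
    for i in range(n_lipids):
        a0 = lipid_atom_start + i * atoms_per_lipid
        pz = lipid_pz[:, i]
        s = np.where(pz >= 0, 1.0, -1.0)
        x0, y0 = lipid_xy[i]
        coords[:, a0, 0] = x0
        coords[:, a0, 1] = y0
        coords[:, a0, 2] = pz
        coords[:, a0 + 1, 0] = x0 + 0.8
        coords[:, a0 + 1, 1] = y0
        coords[:, a0 + 1, 2] = pz + 1.5 * s
        for t in range(2):
            xoff = x0 + (0.75 if t == 0 else -0.75)
            for c in range(n_tail):
                j = a0 + 2 + t * n_tail + c
                coords[:, j, 0] = xoff
                coords[:, j, 1] = y0
                coords[:, j, 2] = pz - s * tail_dz[c]

    # scripted ions: idle beyond the membrane, cross linearly through the
    # cylinder during their window
    for ev, j in zip(ion_scripts, ion_scripted_idx):
        ax = axes[ev.subunit]
        k = ion_scripted_idx.index(j)
        ang = 2 * math.pi * (k % 8) / 8.0
        coords[:, j, 0] = ax[0] + 2.0 * math.cos(ang)
        coords[:, j, 1] = ax[1] + 2.0 * math.sin(ang)
        z_hi, z_lo = 30.0, -30.0
        z0, z1 = (z_hi, z_lo) if ev.direction == "inward" else (z_lo, z_hi)
        a, b = ev.start_frame, ev.end_frame
        zpath = np.full(n_frames, z0)
        zpath[a:b] = np.linspace(z0, z1, b - a, endpoint=False)
        zpath[b:] = z1
        coords[:, j, 2] = zpath
        truth.events.append(
            TruthEvent(
                "ion_in" if ev.direction == "inward" else "ion_out",
                int(resids[j]), ev.species, ev.subunit, a, b,
            )
        )

    # gate pinch: TM4 gate atoms slide toward TM6 during pinched frames
    n_pinched = int(round(sc.pinch_duty_cycle * n_frames))
    pinched = np.zeros(n_frames, dtype=bool)
    if n_pinched > 0:
        # evenly interleaved duty cycle with exactly n_pinched closed frames
        idx = np.floor(np.linspace(0, n_frames, n_pinched, endpoint=False)).astype(int)
        pinched[idx] = True
    truth.pinch_schedule = pinched
    shift = sc.pinch_open_distance - sc.pinch_closed_distance
    for su in ("I", "II"):
        direction = np.array([0.0, -1.0])
        if su == "II":
            direction = _c2(direction)
        for resid, resname, side, z in _GATE_RESIDUES:
            if side != "TM4":
                continue
            j = gate_atom_idx[(su, resid)]
            coords[pinched, j, 0] += shift * direction[0]
            coords[pinched, j, 1] += shift * direction[1]

    if sc.noise_sigma > 0:
        coords += rng.normal(0.0, sc.noise_sigma, size=coords.shape).astype(np.float32)

    times = np.arange(n_frames) * sc.dt
    boxes = np.tile(np.asarray(sc.box), (n_frames, 1))
    frames = FrameSet(times, boxes, coords)
    table = make_atom_table(names, resnames, resids, subunits, roles)
    table["segid"] = segids
    table["species"] = [
        resnames[i] if roles[i].startswith("lipid") else "-" for i in range(n_atoms)
    ]
    return table, frames, truth


# ---------------------------------------------------------------------------
# fixture I/O
# ---------------------------------------------------------------------------


def write_fixture(
    atoms: pd.DataFrame, frames: FrameSet, truth: TruthLog, out_dir
) -> Dict[str, Path]:
    """Write PDB topology + DCD trajectory + truth-log JSON.

    A generate -> write -> load roundtrip preserves coordinates to format
    precision (PDB 0.001 Å; DCD single precision).
    """
    import MDAnalysis as mda

    if len(atoms) == 0 or frames.n_frames == 0:
        raise ValueError("refusing to write an empty system")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    resid_key = atoms["segid"].astype(str) + "/" + atoms["residue_id"].astype(str)
    _, res_index = np.unique(resid_key, return_inverse=False), None
    codes, uniques = pd.factorize(resid_key)
    seg_codes, seg_uniques = pd.factorize(atoms["segid"])
    res_seg = np.zeros(len(uniques), dtype=int)
    res_resid = np.zeros(len(uniques), dtype=int)
    res_resname = np.empty(len(uniques), dtype=object)
    for atom_i, res_i in enumerate(codes):
        res_seg[res_i] = seg_codes[atom_i]
        res_resid[res_i] = atoms["residue_id"].iloc[atom_i]
        res_resname[res_i] = atoms["residue_name"].iloc[atom_i]

    u = mda.Universe.empty(
        n_atoms=len(atoms),
        n_residues=len(uniques),
        n_segments=len(seg_uniques),
        atom_resindex=codes,
        residue_segindex=res_seg,
        trajectory=True,
    )
    u.add_TopologyAttr("names", atoms["atom_name"].to_numpy())
    u.add_TopologyAttr("resnames", res_resname)
    u.add_TopologyAttr("resids", res_resid)
    u.add_TopologyAttr("segids", np.asarray(seg_uniques, dtype=object))
    u.add_TopologyAttr("elements", atoms["element"].to_numpy())

    pdb_path = out_dir / "system.pdb"
    dcd_path = out_dir / "trajectory.dcd"
    truth_path = out_dir / "truth.json"

    box0 = np.concatenate([frames.boxes[0], [90.0, 90.0, 90.0]])
    u.atoms.positions = frames.coords[0]
    u.dimensions = box0
    u.atoms.write(str(pdb_path))

    dt_ps = (frames.times[1] - frames.times[0]) * 1000.0 if frames.n_frames > 1 else 1.0
    with mda.coordinates.DCD.DCDWriter(
        str(dcd_path), n_atoms=len(atoms), dt=dt_ps
    ) as w:
        for f in range(frames.n_frames):
            u.atoms.positions = frames.coords[f]
            u.dimensions = np.concatenate([frames.boxes[f], [90.0, 90.0, 90.0]])
            w.write(u.atoms)

    truth.to_json(truth_path)
    return {"pdb": pdb_path, "dcd": dcd_path, "truth": truth_path}
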