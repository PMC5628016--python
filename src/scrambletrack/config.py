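"""Analysis configuration: atom-classification rules and cutoff defaults.

All distances are in Angstrom, times in ns, angles in degrees.  Defaults
follow the conventions of atomistic CHARMM-style membrane simulations of
the nhTMEM16 scramblase: a 13 Å aqueduct cylinder cut into 2 Å slabs,
4 Å contact cutoffs, 3 Å coordination cutoff, and a strict 3.0 Å pinch
criterion for the TM4-TM6 gate.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import yaml

#: residue-name -> coarse role.  Lipid residues are split into head/tail
#: at the atom level (see :data:`HEAD_ATOM_PREFIXES`).
DEFAULT_RESIDUE_ROLES: Dict[str, str] = {
    # protein residues (three-letter codes)
    **{
        name: "protein"
        for name in (
            "ALA ARG ASN ASP CYS GLN GLU GLY HIS HSD HSE HSP ILE LEU LYS "
            "MET PHE PRO SER THR TRP TYR VAL"
        ).split()
    },
    # phospholipids
    "POPC": "lipid",
    "POPS": "lipid",
    "POPE": "lipid",
    # water models
    "TIP3": "water",
    "TIP3P": "water",
    "HOH": "water",
    "SOL": "water",
    "WAT": "water",
    # monovalent ions
    "SOD": "ion",
    "NA": "ion",
    "CLA": "ion",
    "CL": "ion",
    "POT": "ion",
    "K": "ion",
    "CES": "ion",
    # structurally bound divalent cations (the Ca2+ pair of each subunit)
    "CAL": "bound_cation",
    "CA2": "bound_cation",
}

#: atom-name prefixes that mark a lipid atom as part of the head group
#: (phosphate, choline/amine nitrogen, ester oxygens); carbons and
#: hydrogens default to the tail.
HEAD_ATOM_PREFIXES: Tuple[str, ...] = ("P", "N", "O")


def classify_lipid_atom(atom_name: str) -> str:
    """Return ``lipid_head`` or ``lipid_tail`` for an atom of a lipid residue."""
    return "lipid_head" if atom_name.startswith(HEAD_ATOM_PREFIXES) else "lipid_tail"


@dataclass
class AnalysisConfig:
    """All tunable cutoffs of the pipeline, with simulation-paper defaults."""

    # aqueduct cylinder
    cylinder_radius: float = 13.0
    slab_thickness: float = 2.0
    z_extent: Tuple[float, float] = (-18.0, 18.0)
    #: residue ranges (inclusive) of the helices lining the aqueduct,
    #: resolved per subunit; must be overridden to match the topology.
    lining_residue_ranges: List[Tuple[int, int]] = field(default_factory=list)
    #: recompute the cylinder axis each frame (protein drifts in NPT)
    per_frame_axis: bool = True

    # membrane frame
    #: recompute the bilayer midplane each frame
    per_frame_midplane: bool = True

    # membrane deformation metrics
    shell_radius: float = 10.0
    core_thicknesses: Tuple[float, ...] = (20.0, 25.0)
    histogram_bin_width: float = 1.0

    # contacts / coordination
    contact_cutoff: float = 4.0
    coordination_cutoff: float = 3.0

    # event detection
    leaflet_zone: float = 15.0
    midplane_band: float = 5.0
    boundary_planes: float = 15.0
    ion_core_half_thickness: float = 10.0

    # gating
    pinch_cutoff: float = 3.0
    tm4_pinch_residues: Tuple[int, ...] = (330, 333, 336, 337)
    tm6_pinch_residues: Tuple[int, ...] = (439, 443)

    # electrophysiology
    rtf: float = 25.7  # RT/F in mV at ~25 degC

    residue_roles: Dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_RESIDUE_ROLES)
    )

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**{k: v for k, v in raw.items() if k in known})
        if cfg.lining_residue_ranges:
            cfg.lining_residue_ranges = [tuple(r) for r in cfg.lining_residue_ranges]
        return cfg

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data["lining_residue_ranges"] = [list(r) for r in self.lining_residue_ranges]
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


def resolve_ranges(ranges: Sequence[Tuple[int, int]], resids) -> "list[bool]":
    """Boolean mask of residue ids falling in any of the inclusive ranges."""
    import numpy as np

    resids = np.asarray(resids)
    mask = np.zeros(len(resids), dtype=bool)
    for lo, hi in ranges:
        mask |= (resids >= lo) & (resids <= hi)
    return mask
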