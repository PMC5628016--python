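"""Conformational comparison between Ca2+-liganded and Ca2+-free states.

Least-squares rigid superposition (Kabsch), per-residue RMSD after a single
global alignment (no per-residue re-fitting), per-frame best-fit RMSD
series, the TM4-TM6 center-of-mass distance, and the gate pinch statistic:
a frame is "pinched" iff the minimum sidechain heavy-atom distance over the
configured TM4 x TM6 residue pairs is strictly below 3.0 Å.
"""

from __future__ import annotations

import warnings
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import FrameSet

#: standard atomic masses for COM computations
_MASSES = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "P": 30.974,
           "S": 32.06, "Na": 22.990, "Cl": 35.45, "K": 39.098, "Ca": 40.078,
           "Cs": 132.905, "Mg": 24.305}

_BACKBONE = {"N", "CA", "C", "O", "OT1", "OT2", "HA", "HN"}


def superpose(
    coords_a: np.ndarray, coords_b: np.ndarray
) -> Tuple[np.ndarray, np.ndarray, float]:
    """Optimal least-squares rigid superposition of B onto A (Kabsch).

    Returns (rotation R, translation t, rmsd) such that ``B @ R.T + t``
    best fits A.  Degenerate (collinear or <3 atoms) inputs raise.
    """
    A = np.asarray(coords_a, dtype=float)
    B = np.asarray(coords_b, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise ValueError("coordinate sets must be matched (n, 3) arrays")
    if len(A) < 3:
        raise ValueError("superposition needs at least 3 atoms")
    ca, cb = A.mean(axis=0), B.mean(axis=0)
    A0, B0 = A - ca, B - cb
    s = np.linalg.svd(B0, compute_uv=False)
    if s[1] < 1e-9 * max(s[0], 1.0):
        raise ValueError("degenerate (collinear) atom subset")
    H = B0.T @ A0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ca - R @ cb
    fitted = B @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - A) ** 2, axis=1))))
    return R, t, rmsd


def apply_transform(coords: np.ndarray, R: np.ndarray, t: np.ndarray) -> np.ndarray:
    return np.asarray(coords, dtype=float) @ R.T + t


def per_residue_rmsd(
    coords_a: np.ndarray,
    coords_b: np.ndarray,
    residue_keys: Sequence,
) -> pd.DataFrame:
    """Per-residue heavy-atom RMSD between two already-superposed structures.

    ``residue_keys[i]`` labels atom i's residue in both structures; atoms
    must be matched one-to-one.  No re-fitting is performed per residue.
    """
    A = np.asarray(coords_a, dtype=float)
    B = np.asarray(coords_b, dtype=float)
    if A.shape != B.shape or len(residue_keys) != len(A):
        raise ValueError("structures and residue keys must be matched")
    keys = pd.Series(list(residue_keys))
    sq = np.sum((A - B) ** 2, axis=1)
    rows = []
    for key, idx in keys.groupby(keys).groups.items():
        rows.append({"residue": key, "rmsd": float(np.sqrt(np.mean(sq[np.asarray(idx)])))})
    return pd.DataFrame(rows, columns=["residue", "rmsd"])


def rmsd_series(
    frameset: FrameSet,
    reference: np.ndarray,
    selection_idx: np.ndarray,
) -> np.ndarray:
    """Per-frame best-fit RMSD of the selection against a reference
    coordinate set (same selection, same order)."""
    selection_idx = np.asarray(selection_idx)
    ref = np.asarray(reference, dtype=float)
    out = np.empty(frameset.n_frames)
    for f in range(frameset.n_frames):
        _, _, out[f] = superpose(ref, frameset.coords[f, selection_idx].astype(float))
    return out


def tm_com_distance(
    frameset: FrameSet,
    atoms: pd.DataFrame,
    tm4_residues: Sequence[int],
    tm6_residues: Sequence[int],
    subunit: Optional[str] = None,
) -> np.ndarray:
    """Per-frame distance between the mass-weighted centers of two helix
    selections.  Atoms with unknown element masses get unit mass (with a
    warning)."""
    sel = atoms if subunit is None else atoms[atoms["subunit_id"] == subunit]
    groups = []
    for resids in (tm4_residues, tm6_residues):
        grp = sel[(sel["role"] == "protein") & sel["residue_id"].isin(list(resids))]
        if len(grp) == 0:
            raise ValueError(f"empty helix selection for residues {list(resids)}")
        idx = grp["atom_id"].to_numpy()
        masses = np.array([_MASSES.get(e, np.nan) for e in grp["element"]])
        if np.isnan(masses).any():
            warnings.warn("unknown element masses; using unit masses")
            masses = np.where(np.isnan(masses), 1.0, masses)
        groups.append((idx, masses))
    out = np.empty(frameset.n_frames)
    for f in range(frameset.n_frames):
        coms = []
        for idx, m in groups:
            pos = frameset.coords[f, idx].astype(float)
            coms.append((pos * m[:, None]).sum(axis=0) / m.sum())
        out[f] = float(np.linalg.norm(coms[0] - coms[1]))
    return out


def _sidechain_heavy(atoms: pd.DataFrame, subunit: str, resid: int) -> np.ndarray:
    grp = atoms[
        (atoms["role"] == "protein")
        & (atoms["subunit_id"] == subunit)
        & (atoms["residue_id"] == resid)
        & (~atoms["atom_name"].isin(_BACKBONE))
        & (atoms["element"] != "H")
    ]
    if len(grp) == 0:
        name = atoms[
            (atoms["subunit_id"] == subunit) & (atoms["residue_id"] == resid)
        ]["residue_name"]
        label = name.iloc[0] if len(name) else "?"
        raise ValueError(
            f"residue {label}{resid} (subunit {subunit}) has no sidechain "
            "heavy atoms (glycine?)"
        )
    return grp["atom_id"].to_numpy()


def pinch_fraction(
    frameset: FrameSet,
    atoms: pd.DataFrame,
    pair_set: Sequence[Tuple[int, int]],
    subunit: str,
    cutoff: float = 3.0,
    window: Optional[Tuple[int, int]] = None,
) -> Tuple[np.ndarray, float]:
    """Per-frame pinch indicator and the pinched fraction over a window.

    A frame is pinched iff the minimum sidechain heavy-atom distance over
    any configured (TM4 residue, TM6 residue) pair is strictly below
    ``cutoff`` (a pair exactly at the cutoff is open).
    """
    pairs = [
        (_sidechain_heavy(atoms, subunit, a), _sidechain_heavy(atoms, subunit, b))
        for a, b in pair_set
    ]
    lo, hi = window if window is not None else (0, frameset.n_frames)
    indicator = np.zeros(frameset.n_frames, dtype=bool)
    for f in range(frameset.n_frames):
        pos = frameset.coords[f].astype(float)
        dmin = np.inf
        for ia, ib in pairs:
            d = np.linalg.norm(pos[ia][:, None, :] - pos[ib][None, :, :], axis=2)
            dmin = min(dmin, float(d.min()))
        indicator[f] = dmin < cutoff
    fraction = float(np.mean(indicator[lo:hi]))
    return indicator, fraction


def default_pinch_pairs(
    tm4: Sequence[int] = (330, 333, 336, 337),
    tm6: Sequence[int] = (439, 443),
) -> List[Tuple[int, int]]:
    """All TM4 x TM6 gate residue pairs (F330/T333/L336/V337 x Y439/T443)."""
    return [(a, b) for a in tm4 for b in tm6]
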