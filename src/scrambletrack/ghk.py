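"""Goldman-Hodgkin-Katz dilution-potential analysis.

For a single cation X plus Cl-, the reversal-potential shift upon changing
solutions is

    dErev = rtf * ln[(X_o + Cl_i * r) / (X_i + Cl_o * r)],   r = P_Cl / P_X

with rtf = RT/F = 25.7 mV at room temperature.  Concentrations in mM,
potentials in mV.  The forward map is strictly monotone in r, so the
closed-form inversion

    r = (X_o - X_i * e^(d/rtf)) / (Cl_o * e^(d/rtf) - Cl_i)

is safe inside the achievable shift range.  In the dilution-potential
protocol the Cl- concentration follows the cation salt on each side
(mannitol keeps osmolarity), so typically Cl_o = X_o and Cl_i = X_i.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

RTF_MV = 25.7


@dataclass
class GHKMeasurement:
    """A dilution-potential measurement and its permeability ratio."""

    X_o: float  # extracellular cation, mM
    X_i: float  # intracellular cation, mM
    Cl_o: float
    Cl_i: float
    dErev: float  # mV
    rtf: float = RTF_MV

    @property
    def ratio_cl_over_x(self) -> float:
        return ratio_from_shift(
            self.dErev, self.X_o, self.X_i, self.Cl_o, self.Cl_i, self.rtf
        )

    @property
    def ratio_x_over_cl(self) -> float:
        return 1.0 / self.ratio_cl_over_x


def _check_positive(**kwargs: float) -> None:
    for name, v in kwargs.items():
        if not (v > 0):
            raise ValueError(f"{name} must be positive, got {v}")


def shift_from_ratio(
    ratio: float,
    X_o: float,
    X_i: float,
    Cl_o: float,
    Cl_i: float,
    rtf: float = RTF_MV,
) -> float:
    """Reversal-potential shift (mV) for permeability ratio r = P_Cl/P_X."""
    _check_positive(ratio=ratio, X_o=X_o, X_i=X_i, Cl_o=Cl_o, Cl_i=Cl_i, rtf=rtf)
    return rtf * math.log((X_o + Cl_i * ratio) / (X_i + Cl_o * ratio))


def ratio_from_shift(
    dErev: float,
    X_o: float,
    X_i: float,
    Cl_o: float,
    Cl_i: float,
    rtf: float = RTF_MV,
) -> float:
    """Closed-form inverse: permeability ratio P_Cl/P_X from a measured
    shift.  Shifts outside the achievable open interval raise with the
    bounds named."""
    _check_positive(X_o=X_o, X_i=X_i, Cl_o=Cl_o, Cl_i=Cl_i, rtf=rtf)
    # limits r -> 0 and r -> inf of the forward map
    b0 = rtf * math.log(X_o / X_i)
    binf = rtf * math.log(Cl_i / Cl_o)
    lo, hi = min(b0, binf), max(b0, binf)
    if hi - lo < 1e-12:
        # symmetric solutions: every ratio gives the same (zero) shift
        if abs(dErev - lo) < 1e-9:
            return 1.0
        raise ValueError(
            f"shift {dErev} mV unachievable: these concentrations always "
            f"give {lo:.2f} mV"
        )
    e = math.exp(dErev / rtf)
    denom = Cl_o * e - Cl_i
    r = (X_o - X_i * e) / denom if denom != 0 else float("inf")
    if not (r > 0) or not (lo < dErev < hi):
        raise ValueError(
            f"shift {dErev} mV outside the achievable range "
            f"({lo:.2f}, {hi:.2f}) mV for these concentrations"
        )
    return r


def selectivity_fold_change(ratio_before: float, ratio_after: float) -> float:
    """Fold change in anion selectivity between two measurements."""
    _check_positive(ratio_before=ratio_before, ratio_after=ratio_after)
    return ratio_before / ratio_after
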