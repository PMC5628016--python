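# scrambletrack

Trajectory analysis for TMEM16-family lipid scramblases — proteins whose
membrane-exposed hydrophilic groove (the *aqueduct*) conducts both
phospholipid head groups and ions across the bilayer. Given a structure
(PDB) and a trajectory (DCD/XTC/multi-model PDB) of a two-subunit
scramblase in an asymmetric POPC/POPS membrane, the package measures:

* **membrane deformation** — phosphate counts within 10 Å of the protein
  entering the 20/25 Å membrane core, z-histograms, and bulk-normalised
  phosphate density maps (OpenDX output);
* **aqueduct hydration and occupancy** — per-subunit 13 Å cylinders in
  2 Å slabs: water counts, phosphate series with moving average and
  count histograms, per-lipid z-traces;
* **flip-flop events** — hysteresis detection of full (leaflet-to-
  leaflet) and half (leaflet-to-midplane) lipid translocations, with
  species, direction, and timing;
* **ion permeation** — full crossings through the aqueduct with
  per-species/direction/subunit summaries, and applied-field voltage
  conversion V = −E·L_z;
* **contacts and coordination** — 4 Å polar and hydrophobic contacts,
  per-residue contact-time fractions, 3 Å coordination series,
  event-averaged coordination, and per-residue coordination ratios
  (coordinations/ns) that expose POPS-vs-POPC selectivity;
* **gating** — Kabsch superposition, per-residue RMSD, TM4–TM6
  center-of-mass distance, and the <3.0 Å TM4–TM6 pinch fraction;
* **GHK selectivity** — reversal-potential shift ⇄ permeability ratio
  under the dilution-potential protocol,
  ΔE_rev = 25.7·ln[(X_o + Cl_i·r)/(X_i + Cl_o·r)], r = P_Cl/P_X.

Because no trajectories of this system are publicly deposited, the
package ships a first-class synthetic generator
(`scrambletrack.synth`): a two-subunit pseudo-protein in an asymmetric
bilayer with *scripted* flip-flops, ion crossings, aqueduct water, and
gate pinching, each exported with a ground-truth log so every detector
can be validated exactly.

## Worked example

```python
import numpy as np
import scrambletrack as st
from scrambletrack.synth import LINING_RANGES

# a labelled synthetic system: 128 lipids/leaflet, 2000 frames, 1 Å noise
atoms, frames, truth = st.generate(st.SyntheticScenario(noise_sigma=1.0))
pmap = st.lipid_phosphorus_map(atoms)
frames = st.center_membrane(frames, np.fromiter(pmap.values(), dtype=int))
cyls = st.define_cylinder(atoms, frames, LINING_RANGES)

events = []
for cyl in cyls.values():
    traces, _ = st.trace_lipids(frames, cyl, atoms, pmap)
    events += st.detect_flip_events(traces)
for ev in sorted(events, key=lambda e: e.t_exit):
    print(f"{ev.event_class:>9} {ev.species} lipid {ev.lipid_id:3d} "
          f"subunit {ev.subunit_id}: {ev.t_enter:6.1f} -> {ev.t_exit:6.1f} ns")

ions = st.detect_ion_permeations(frames, atoms, cyls)
print(len(ions), "Na+ influx events")
print(f"P_Cl:P_Cs at +45 mV: {st.ratio_from_shift(45.0, 10, 150, 10, 150):.2f}")
```

prints

```
full_flop POPS lipid 129 subunit I:   63.5 ->  182.0 ns
full_flop POPC lipid 172 subunit II:  224.0 ->  341.0 ns
full_flop POPS lipid 130 subunit I:  384.5 ->  504.5 ns
full_flop POPC lipid 173 subunit II:  546.5 ->  662.5 ns
full_flop POPC lipid 174 subunit I:  701.5 ->  822.0 ns
half_flop POPC lipid 176 subunit I:  349.0 ->  999.5 ns
half_flip POPC lipid   1 subunit II:  368.5 ->  999.5 ns
half_flop POPS lipid 131 subunit II:  540.5 ->  999.5 ns
half_flop POPC lipid 175 subunit II:  170.0 ->  999.5 ns
24 Na+ influx events
P_Cl:P_Cs at +45 mV: 9.24
```

— five full floppings (2 POPS + 3 POPC) completing leaflet-to-leaflet,
three half-flops and one half-flip still holding the central dwell site
(z ≈ −3 Å) when the trajectory ends, all 24 scripted Na⁺ influx events,
and the strongly Cl⁻-selective permeability ratio implied by a +45 mV
reversal-potential shift under a 150→10 mM CsCl dilution.

A CLI mirrors the library: `scrambletrack synth | deform | flips |
ions | gating | ghk` (see `scrambletrack --help`).

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
re-runs the whole pipeline from scratch: it generates the default
scripted scenario with the given seed, executes membrane centering,
cylinder construction, hydration and phosphate profiling, flip-flop and
ion-permeation detection, and pinch statistics, evaluates the GHK and
applied-voltage conversions, prints the summary, and writes the results
JSON to `--out`.

See `docs/methods.md` for the model, thresholds, conventions, and the
limits of what the synthetic tests establish.
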