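"""Per-frame residue-pair distance series (the per-contact stability view).

Extracts the minimum heavy-atom distance between the pY+3 glutamine of the
synthetic peptide and its receptor tyrosine partner over the final 15 frames
— the kind of trace used to judge whether a single contact is stable or
fluctuating over the simulation.
"""

from sh2fp import distance_timeseries
from sh2fp.synth import table1_style_fixture

traj, truth, peptide = table1_style_fixture(n_frames=24, seed=1)

# final 15 frames of the 24-frame trajectory
series = distance_timeseries(traj, "B", 117, "A", 657, window=(9, 24))
print(series.to_string(index=False))

on = series[series.distance_A < 3.0]
print(f"\nframes in contact (< 3.0 A): {len(on)} of {len(series)}")
# Low flat stretches are contact episodes; excursions to the planted
# off-distance (8 A) are frames in which the bond is broken.
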