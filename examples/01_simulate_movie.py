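"""Simulate one calibrated organelle-trafficking movie with ground truth.

Builds a 60-frame single-channel stack of 20 organelles (half
stationary, half moving processively along the axon axis) and prints
the population summary. Anterograde means leftward (toward the distal
site), retrograde rightward (toward the soma-proximal site).
"""

from collections import Counter

from ohp import Calibration
from ohp.simulate import AppearanceModel, MotilityModel, simulate_movie

cal = Calibration()  # 0.22955 um/px, 3.3 frames/s
motility = MotilityModel(n_organelles=20, stationary_fraction=0.5, pause_probability=0.0)
appearance = AppearanceModel(diameter_um=0.8)

movie, truth = simulate_movie(motility, appearance, geometry=(60, 128, 64), calibration=cal, seed=7)

print(f"movie: {movie.n_frames} frames of {movie.height}x{movie.width} px "
      f"({movie.height_um:.1f} x {movie.width_um:.1f} um), dtype {movie.frames.dtype}")
counts = Counter(org.direction for org in truth.organelles)
print(f"ground truth: {len(truth)} organelles -> {dict(counts)}")
for org in truth.organelles[:3]:
    print(f"  organelle {org.id}: {org.direction}, speed {org.speed_um_s:.2f} um/s, "
          f"net x displacement {org.net_x_displacement_um():+.2f} um")
# Moving organelles drift along x at their drawn speed; stationary ones
# only jitter by ~0.02 um, far below the 1.2 um processivity filter.
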