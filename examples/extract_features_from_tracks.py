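"""From raw cell tracks to regression features.

Samples 2D-style cell tracks from a spring-chain ERK-wave simulation,
applies the trajectory quality filters, and extracts the per-cell,
per-frame features of the acceleration model: Savitzky-Golay velocity
and acceleration, local quadratic-fit gradients of ERK and density, and
velocity curvature.
"""

import numpy as np

from erkmech import (
    SmoothingConfig,
    assemble_feature_table,
    feature_crosscorrelation,
    filter_trajectories,
    reference_wave_simulation,
    tracks_from_simulation,
)

traj = reference_wave_simulation("instantaneous", duration=300.0, dt=0.05)
tracks = tracks_from_simulation(traj, frame_interval=2.0, y_jitter_sd=1.5, seed=0)
print(f"simulated tracks: {len(tracks)} cells x {len(tracks[0])} frames")

tracks = filter_trajectories(tracks, min_frames=100)
print(f"after quality filtering: {len(tracks)} tracks")

# chain spacing is ~1 cell length, so the fit radii span a few neighbors
cfg = SmoothingConfig(fit_radius_erk=4.0, fit_radius_vel=4.0, kde_sigma=3.0)
table = assemble_feature_table(tracks, cfg, axis="orthogonal")
print(f"feature records: {len(table)} (drops: {table.attrs['drops']})")
print(table[["x1_vel", "x2_erk_grad", "x3_rho_grad", "x4_d2v_dx2"]].describe()
      .loc[["mean", "std"]].round(4))

xc = feature_crosscorrelation(table, max_lag_minutes=60)
pair = xc[(xc.feature_a == "x2_erk_grad") & (xc.feature_b == "x3_rho_grad")]
peak = pair.loc[pair["corr"].abs().idxmax()]
print(f"ERK-gradient vs density-gradient cross-correlation peaks at "
      f"{peak.lag_min:+.0f} min (r = {peak['corr']:+.2f})")
print("(in the wave simulation the density gradient trails the ERK "
      "gradient, so the peak sits at a nonzero lag — the temporal "
      "structure the convolutional model exploits.)")
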