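"""Ensemble analyses: RMSD series, equilibration onset, conformational clusters.

Builds a noisy ensemble that drifts toward an equilibrated plateau, detects
the onset, and clusters a mixed two-conformer ensemble at the 2 Å backbone
threshold.
"""

import numpy as np

from porexlink import cluster_frames, detect_equilibration, rmsd_timeseries
from porexlink.structure_io import FrameEnsemble
from porexlink.synthetic_data import default_channel_spec, make_channel, perturb_ensemble

base, _ = make_channel(default_channel_spec(), "open")

# drifting ensemble: frames relax toward a displaced conformation
target = perturb_ensemble(base, 2.0, 1, seed=10, mode="rigid-helix-jitter")
n = 60
mix = np.minimum(np.arange(n) / 25.0, 1.0)[:, None, None]
coords = (1 - mix) * base.coords[0] + mix * target.coords[0]
coords += np.random.default_rng(0).normal(0, 0.05, coords.shape)
drift = FrameEnsemble(atoms=base.atoms, coords=coords, frame_labels=list(range(n)))

series = rmsd_timeseries(drift, reference="first-frame", selection="CA")
onset = detect_equilibration(series, window=15, slope_tol=0.02)
print(f"RMSD rises to {series.rmsd.max():.2f} Å; plateau detected from frame {onset}")

# two-conformer mixture: quality-threshold clustering at 2 Å backbone RMSD
conf_b = perturb_ensemble(base, 3.0, 1, seed=11, mode="rigid-helix-jitter")
frames = np.concatenate(
    [perturb_ensemble(base, 0.15, 12, seed=1).coords,
     perturb_ensemble(conf_b, 0.15, 8, seed=2).coords]
)
mixture = FrameEnsemble(atoms=base.atoms, coords=frames, frame_labels=list(range(20)))
result = cluster_frames(mixture, threshold=2.0, selection="backbone")
sizes = [len(result.members(c)) for c in range(result.n_clusters)]
print(f"{result.n_clusters} clusters of sizes {sizes}; centroid frames {result.centroids}")
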