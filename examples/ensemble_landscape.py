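"""From dihedral trajectory to free-energy landscape and state decomposition.

A hidden-Markov trajectory with three metastable states (a planted slow
coordinate) is featurized as sin/cos dihedral pairs, projected with tICA,
binned into a free-energy surface, and decomposed with mini-batch k-means;
paired coordinate frames give centre-of-mass loop distances per state.
"""

import numpy as np

from icl3kit.ensemble_analysis import (
    cluster_states,
    com_distance,
    featurize_dihedrals,
    fit_tica,
    free_energy_surface,
)
from icl3kit.synthetic_data import gen_metastable_trajectory

traj, labels, frames, meta = gen_metastable_trajectory(
    k_states=3, stay_probabilities=(0.99, 0.98, 0.99),
    frames=8_000, seed=7, make_frames=True,
)
features = featurize_dihedrals(traj)
proj = fit_tica(features, lag=1)
print(f"leading tICA eigenvalues: {np.round(proj.eigenvalues[:3], 3)}")
# eigenvalue ~ autocorrelation of the slowest process at the chosen lag

fes = free_energy_surface(proj.projection, bins=40)
print(f"free-energy range over occupied bins: 0 .. {fes.free_energy.max():.2f} kT")

model = cluster_states(proj.projection, k=3, seed=0)
print(f"cluster populations: {np.bincount(model.labels)}")

# Loop-packing distances per true state (ICL3-like segment vs ICL1-like ref)
dists = np.array([com_distance(f, (236, 257), (61, 66)) for f in frames])
for s in range(3):
    print(
        f"state {s}: median ICL3-ICL1 distance "
        f"{np.median(dists[labels == s]):.1f} A "
        f"(planted {meta['state_distances_A'][s]:.0f} A)"
    )
# The intermediate state packs the loop closest to the intracellular face;
# the open state swings it away from the G-protein cavity.
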