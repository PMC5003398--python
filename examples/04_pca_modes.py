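"""Essential-dynamics PCA of a Cα trajectory with a known motional mode.

Constructs a trajectory in which one residue oscillates along a fixed
direction, aligns the frames on the iterative mean structure, and runs the
covariance analysis: the single constructed mode should absorb ~all the
variance and its per-residue square-displacement profile should peak at
the moving residue.
"""

import numpy as np

import lidmotion as lm

scaffold, _ = lm.make_two_domain_scaffold(lm.ScaffoldSpec(seed=4))
base = np.array([a.coord for a in scaffold.atoms])
mode = np.zeros_like(base)
mode[7] = [0.8, 0.0, 0.0]          # residue 8 oscillates along x
frames = [base + np.sin(t) * mode for t in np.linspace(0, 2 * np.pi, 25)]

aligned = lm.align_trajectory(lm.Trajectory(topology_ref=scaffold, frames=frames),
                              reference="mean_iterative")
result = lm.compute_pca(aligned)

print(lm.scree_table(result, k=3).to_string(index=False,
                                            float_format=lambda x: f"{x:.4f}"))
sq = lm.mode_square_displacements(result, 1)
print(f"mode-1 variance fraction: {result.variance_fractions[0]:.4f}")
print(f"mode-1 mass at residue 8: {sq[7] / sq.sum():.4f} "
      f"(peak residue index: {int(np.argmax(sq))})")
err = np.abs(lm.reconstruct(result) - aligned.coords).max()
print(f"reconstruction max error over all modes: {err:.2e} A")
# One dominant eigenvalue, all of its mass on the constructed residue, and
# exact reconstruction: the covariance analysis is self-consistent.
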