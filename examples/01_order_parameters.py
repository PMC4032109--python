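"""Sidechain order parameters from a wobble-in-a-cone trajectory.

Builds a synthetic poly-Asp trajectory whose Cβ→Cγ bond vector wobbles
uniformly in a 60° cone (closed-form S² = 0.140625), adds random global
tumbling, removes it again by per-frame backbone superposition, and
estimates S² with a block-averaged standard error.
"""

import sitedyn as sd

traj, truth = sd.gen_cone_trajectory(theta0_deg=60.0, n_frames=50_000, seed=1)
tumbled = sd.apply_global_tumbling(traj, seed=2)
aligned = sd.align_frames(tumbled, traj.topology)

(series,) = sd.extract_bond_vectors(aligned)
result = sd.block_sem(series, n_blocks=10)

print(f"residue {result.label}: S2 = {result.s2:.4f} +/- {result.sem:.4f} "
      f"({result.n_frames} frames, {result.n_blocks} blocks)")
print(f"analytic S2 for a 60 deg cone: {truth['s2_analytic']:.6f}")
print("S2 near 1 means a rigid sidechain; the cone model's plateau depends")
print("only on the cone semi-angle, and alignment has removed the tumbling.")
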