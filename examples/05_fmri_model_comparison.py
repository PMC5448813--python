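"""Model-based fMRI on synthetic BOLD: designs, GLM and voxel-wise selection.

Builds the three design matrices (PE, Conventional, Block) from one
synthetic subject's filtered trajectory, simulates voxel populations from
each design, and runs voxel-wise Bayesian model comparison across a small
group.  The exceedance maps should assign most voxels to their generating
design, and noiseless PE voxels show the pre-transition signal build-up.
"""

import numpy as np

from bistablepc.study import run_fmri_recovery

result = run_fmri_recovery(
    n_subjects=6, voxels_per_model=50, noise_sd=1.0, seed=11
)

kinds = result["model_kinds"]
print("voxel-wise group model selection (150 synthetic voxels, 6 subjects)")
print(f"assignment accuracy: {result['accuracy']:.1%}")
for j, kind in enumerate(kinds):
    counts = np.bincount(
        result["assignment"][result["truth"] == j], minlength=len(kinds)
    )
    print(f"  voxels generated by {kind:<13} assigned to {dict(zip(kinds, counts))}")

ramp = result["pre_transition_ramp"]
print()
print("epoch-averaged PE-voxel signal at the last overlaps before a")
print("transition:", np.round(ramp, 3))
print("The rising course mirrors the prediction-error build-up that")
print("precedes endogenous perceptual transitions.")
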