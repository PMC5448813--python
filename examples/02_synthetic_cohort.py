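"""Build the experiment's session structure and a synthetic cohort.

Constructs the block design (three runs of eight ambiguous/replay pairs,
overlap frequency titrated per subject) and simulates observers with known
parameters.  Replay blocks reimpose each subject's own ambiguous percept
sequence through the disparity track, exactly as the experiment's replay
condition mimicked the preceding ambiguous block.
"""

import numpy as np
from scipy import stats

from bistablepc import synth_cohort, transition_frequency

cohort = synth_cohort(n_subjects=9, master_seed=7, runs=3, pairs_per_run=8)

print("subject  freq(Hz)  true pi_init  true pi_stereo  transition prob")
for s in cohort:
    print(
        f"{s.subject_id:>7}  {s.session.overlap_frequency_hz:>8.2f}"
        f"  {s.true_params.pi_init:>12.2f}  {s.true_params.pi_stereo:>14.2f}"
        f"  {transition_frequency(s.responses):>15.3f}"
    )

pi = [s.true_params.pi_init for s in cohort]
tf = [transition_frequency(s.responses) for s in cohort]
rho = stats.spearmanr(pi, tf).statistic
print()
print(f"rank correlation pi_init vs transition probability: {rho:+.2f}")
print("Stronger initial stabilisation -> fewer transitions, the behavioural")
print("fingerprint of the stability prior.")
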