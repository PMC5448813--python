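"""Simulate bistable dominance phases from the belief-update model.

Runs the model under purely ambiguous input (mu_stereo = 0.5, no
stereodisparity weight) at the published settings and prints the dominance
duration statistics alongside the semi-analytic survival-product
expectation.  The mean near 10.4 s, gamma shape above 1 ("sharp rise, slow
fall") and the agreement with the oracle are the signatures that the
additive prediction-error update reproduces bistable temporal dynamics.
"""

from bistablepc import ModelParams, duration_stats, expected_mean_duration
from bistablepc import phase_durations, simulate_timecourse

params = ModelParams(pi_init=3.5, pi_stereo=0.0, zeta=1.0)
sim = simulate_timecourse(params, total_seconds=2e5, sampling_rate_hz=0.33, seed=1)
durations = phase_durations(sim.decisions, sim.dt)
stats = duration_stats(durations)

print(f"complete dominance phases: {stats['n']}")
print(f"mean duration:             {stats['mean']:.2f} s")
print(f"median duration:           {stats['median']:.2f} s")
print(f"gamma shape (ML fit):      {stats['gamma_shape']:.2f}")
print(f"survival-product oracle:   {expected_mean_duration(params, 0.33):.2f} s")
print()
print("The mean matches the oracle; shape > 1 gives the classic right-skewed,")
print("gamma-like dominance distribution of bistable perception.")
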