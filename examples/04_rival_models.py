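"""Simulate the rival dynamical models of bistable perception.

The oscillator (mutual inhibition + adaptation) alternates quasi-
periodically even without noise; the noise-driven attractor produces
approximately exponential dwell times; the intermediate model mixes both.
All three are simulated here and summarised by their dominance-duration
statistics, which bracket the behaviour of the predictive-coding model.
"""

from bistablepc.rivals import (
    AttractorParams,
    OscillatorParams,
    simulate_attractor,
    simulate_intermediate,
    simulate_oscillator,
)
from bistablepc.simulate import duration_stats, phase_durations

runs = {
    "oscillator (deterministic)": simulate_oscillator(
        OscillatorParams(), total_s=600
    ),
    "intermediate (adaptation+noise)": simulate_intermediate(
        OscillatorParams(noise=0.08), total_s=1200, seed=1
    ),
    "attractor (noise-driven)": simulate_attractor(
        AttractorParams(barrier=0.8, noise=0.6), total_s=3000, seed=2
    ),
}

print(f"{'model':<33} {'mean (s)':>9} {'CV':>6} {'n phases':>9}")
for name, traj in runs.items():
    d = phase_durations(traj.percepts, traj.dt)
    stats = duration_stats(d)
    print(f"{name:<33} {stats['mean']:>9.2f} {stats['cv']:>6.2f} {stats['n']:>9}")

print()
print("CV near 0: clock-like adaptation cycling. CV near 1: memoryless")
print("Kramers escapes. The intermediate regime sits in between, like the")
print("gamma-shaped durations of human observers.")
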