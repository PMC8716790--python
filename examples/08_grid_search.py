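"""Grid search over control parameters with common random numbers.

Each cell re-runs the closed loop with one parameter combination on the
same noise realization and is scored on detection agreement, energy, and
lock behavior.
"""

from cldbs import grid_search, high_snr_scenario
from cldbs.scenarios import closed_loop_cell_runner

scenario = high_snr_scenario(seed=11, duration=240.0)
runner = closed_loop_cell_runner(scenario)

result = grid_search(
    runner,
    grid={"onset_counter": [2, 4], "percentile": [40.0, 60.0]},
    seed=12,
)
cols = ["onset_counter", "percentile", "agreement", "energy", "locks", "score"]
print(result.table[cols].to_string(index=False,
                                   float_format=lambda v: f"{v:.3g}"))
print(f"\nchosen cell: {result.chosen}")
print("-> the score is w_miss*(1-agreement) + w_energy*energy/max(energy)")
print("   + w_lock*[locks>0]; a lower threshold percentile buys agreement at")
print("   the cost of energy, and any lock is heavily penalized.")
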