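"""Convergence of plain vs fractional-order cuckoo search on the sphere.

Runs both optimizers from the same seed on a 10-dimensional sphere
function and prints the best fitness at a few checkpoints, showing the
faster descent of the gradient-modulated variant.
"""

from fraccs import OptimizerConfig, SearchBounds, run_cfo_cs, run_cs, sphere

bounds = SearchBounds.cube(10, -5.0, 5.0)
config = OptimizerConfig(seed=3, max_iter=100, alpha=0.7, memory_terms=4)

trace_cs = run_cs(sphere, bounds, config)
trace_cfo = run_cfo_cs(sphere, bounds, config)

print(f"{'iter':>5} {'CS best':>12} {'CFO-CS best':>12}")
for i in (0, 9, 24, 49, 99):
    print(f"{i + 1:>5} {trace_cs.best_fitness_per_iter[i]:>12.5f} "
          f"{trace_cfo.best_fitness_per_iter[i]:>12.5f}")
print(f"\nobjective evaluations: CS={trace_cs.evaluations} "
      f"CFO-CS={trace_cfo.evaluations}")
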