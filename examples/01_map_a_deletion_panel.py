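"""Map a small deletion panel and read off the marker order.

Builds an 18-marker, 8-mutant panel with a known true order, shuffles the
marker columns (so the solver cannot inherit the answer from the input
layout), and runs the full clustered pipeline.
"""

from delmap import SimulationSpec, generate, map_pipeline, shuffle_markers

matrix, true_order = generate(SimulationSpec(n_markers=18, n_mutants=8, n_deleted=60, seed=3))
shuffled = shuffle_markers(matrix, seed=4)

solution = map_pipeline(shuffled, n=6, opt="any")

print(f"minimum obligate breaks : {solution.best_cost}")
print(f"co-optimal maps         : {solution.n_best_maps}")
print(f"true order              : {' '.join(true_order)}")
for k, order in enumerate(solution.best_orders, 1):
    print(f"map {k}                   : {' '.join(order)}")

# The break count is the number of present->deleted transitions summed over
# all mutants: every map printed attains the minimum.  Markers sharing one
# deletion profile are interchangeable, so each map is one representative
# of a family; n_best_maps counts families, and a count of 1 means the
# panel pins the order down completely (up to reading direction).
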