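"""Encode flower phenotypes as sex-determining locus markers and merge panels.

Deletion mapping of a Y chromosome can place the sex-determining loci
themselves on the map: a hermaphroditic mutant implies loss of the
gynoecium-suppressing function (GSF), an asexual mutant loss of the
stamen-promoting function (SPF), and a female-like mutant loss of both.
Panels genotyped in different experiments merge by marker name.
"""

import numpy as np

from delmap import (
    DeletionMatrix,
    PhenotypeCall,
    encode_phenotypes,
    map_pipeline,
    merge_matrices,
)

lab_a = DeletionMatrix(
    mutant_names=("herm-1", "asex-1"),
    marker_names=("mk1", "mk2", "mk3", "mk4"),
    states=np.array([[1, 0, 1, 1], [1, 1, 0, 1]]),
)
lab_b = DeletionMatrix(
    mutant_names=("fem-1", "male-1"),
    marker_names=("mk4", "mk3", "mk2", "mk1"),  # columns align by name
    states=np.array([[1, 0, 0, 1], [1, 1, 1, 1]]),
)
panel = merge_matrices([lab_a, lab_b])

calls = [
    PhenotypeCall("herm-1", "hermaphrodite"),
    PhenotypeCall("asex-1", "asexual"),
    PhenotypeCall("fem-1", "female_like"),
    PhenotypeCall("male-1", "male"),
]
with_loci = encode_phenotypes(panel, calls, gsf_name="GSF", spf_name="SPF")

print("mutants x markers:", with_loci.n_mutants, "x", with_loci.n_markers)
print("GSF column:", with_loci.column("GSF"), "(0 in herm-1 and fem-1)")
print("SPF column:", with_loci.column("SPF"), "(0 in asex-1 and fem-1)")

solution = map_pipeline(with_loci, n=with_loci.n_markers, opt="any")
print("best cost:", solution.best_cost)
print("one best map:", " ".join(solution.best_orders[0]))
# GSF and SPF now appear in the marker order itself, located by which
# deletions remove them together with which molecular markers.
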