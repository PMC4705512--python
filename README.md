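# delmap — deletion mapping of non-recombining chromosome regions

Genes in regions that never recombine — Y chromosomes, pericentromeric
blocks, supergenes — cannot be ordered by genetic mapping. `delmap` builds
physical maps of such regions from panels of **deletion mutants**: each
mutant has lost a contiguous chromosome segment, genotyping tells which
markers survive in which mutant, and markers that are co-deleted must be
neighbours. Because the method needs no recombination and no dose model, it
can pool mutants from different experiments, mutagens and laboratories in
one analysis. It was developed for mapping plant Y chromosomes (including
the sex-determining GSF and SPF loci of *Silene latifolia*-type systems,
which enter the matrix as phenotype-derived markers), but applies to any
presence/absence deletion panel.

## The model

The input is a mutant-by-marker 0/1 matrix (0 = deleted, 1 = present). For
a candidate marker order, an adjacency where mutant *m* keeps one marker
but has lost its neighbour implies at least one physical chromosome break
in *m* — an *obligate break*. With markers *i*, *j* adjacent and
*breaks_m(i, j) = 1* iff their states differ in *m*,

    cost(i, j)  = Σ_m breaks_m(i, j)                 (m = 1 … Mu)
    total cost  = Σ_k cost(marker_k, marker_k+1)     (k = 0 … Ma)

where *marker_0* and *marker_Ma+1* are virtual markers for the two ends of
the mapped region: the start end is present in every mutant, and the
opposite end is either deleted in every mutant (`del` option) or copies its
neighbour and costs nothing (`any` option, tolerant of phenotype-ascertained
panels). The best map is the order (equivalently, the travelling-salesman
path over markers) minimising the total break count — and every co-optimal
order matters, because their multiplicity measures how ambiguous the data
leave the map.

Exhaustive ordering is infeasible beyond ~14 markers, so the pipeline
first groups markers into *n* clusters (asymmetric-binary profile distance,
Ward agglomeration), orders the clusters exactly by branch and bound —
each cluster acting as one multi-state virtual marker whose state is its
count of present members, with a present/deleted classification propagated
along the walk — then orders the actual markers inside every cluster
between virtual markers representing the adjoining clusters, and finally
ranks every assembled complete order by its exact break count. A cluster
state of *num* − 1 in a cluster of more than three markers is treated as a
PCR genotyping error and smoothed to *num*.

## A worked example

```sh
python examples/01_map_a_deletion_panel.py
```

```
minimum obligate breaks : 12
co-optimal maps         : 1
true order              : M01 M02 M03 M04 M05 M06 M07 M08 M09 M10 M11 M12 M13 M14 M15 M16 M17 M18
map 1                   : M17 M18 M16 M15 M14 M13 M12 M10 M11 M09 M08 M07 M06 M01 M02 M03 M05 M04
```

The 18-marker, 8-mutant panel is solved to a single best map with 12
obligate breaks. Read right-to-left, the map reproduces the true order up
to markers with identical deletion profiles (M17/M18, M10/M11, M01–M05
fall in such groups): a physical map has no orientation, and markers no
mutant separates cannot be ordered by any data. The other examples
(`examples/0*.py`) simulate panels, run a scaled accuracy study, and place
phenotype-derived sex-determining loci on a map.

## Command line

```sh
delmap simulate --markers 71 --mutants 41 --deleted 442 --seed 1 \
                --out panel.csv --truth truth.txt
delmap map --matrix panel.csv --clusters 12 --end any --report map.txt
delmap evaluate --seed 1 --reps 30 --out sweep_tables/
```

`map` prints the minimal break count, the co-optimal maps with
interchangeable-marker groups bracketed, and their count; `--json` emits
the same machine-readably. `evaluate` runs the four accuracy sweeps
(deleted elements × bias × end option, mutant count, marker count, PCR
errors) and writes one table per panel — roughly an hour at full scale,
scaling down with `--markers/--mutants/--reps`.

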