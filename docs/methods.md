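# Methods

## The statistic

Let G = (V, E) be an undirected simple graph over chromatin fragments and
f : V → [0, 1] a feature's per-fragment value.  ChAs is the Pearson
correlation of (f(u), f(v)) over the doubled edge list in which every edge
appears in both orientations.  Symmetrization makes the statistic exactly
orientation-independent and identical to the standard continuous
assortativity coefficient of the graph (the mixing-matrix form); the test
suite asserts agreement with igraph's `assortativity` to 1e-10 on random
graphs.

Degenerate cases are reported as missing (NaN), with a warning, never as 0:

- an edgeless network (no pairs to correlate);
- a feature constant over edge endpoints.  Constancy is detected by exact
  value range (`ptp == 0`), not by a standard-deviation threshold — the
  float standard deviation of a constant vector can be a ~1e-17 residue of
  the mean, which would otherwise fabricate a correlation of ±1.

A missing node value is an error (naming the node), not a silent 0:
imputation changes the statistic.

## Network construction

Nodes are restriction/capture fragments in 0-based half-open coordinates;
CHiCAGO-style tables (1-based inclusive) are converted on read.  A fragment
is a promoter iff it is a bait on any input row or listed in an explicit
bait-id set (which overrides row flags); a bait that also appears as an
other end stays a promoter, since capture design guarantees baits are
promoters.  Edge classes (PP/PO/OO) follow endpoint classes.

Filtering conventions:

- interaction score threshold is inclusive (`score ≥ 5` by default, the
  CHiCAGO significance convention); a file without scores passes only a
  non-positive threshold;
- duplicate unordered pairs collapse to the maximum score (order
  independent); self-pairs are dropped with a warning;
- linear distance is the absolute difference of fragment midpoints,
  symmetric under unequal fragment sizes; trans edges are retained by
  default with undefined distance and can be excluded with `cis_only`.

## Feature mapping

Peaks are binarized over fixed windows (200 bp default) tiling each
chromosome from coordinate 0; a window is called iff it overlaps a peak by
at least 1 bp.  A fragment's value is (called windows overlapping the
fragment) / (windows overlapping the fragment) — the same any-overlap rule
on both sides, so the two binarization steps cannot disagree at
boundaries.  The denominator counts windows, not bp, reproducing the
window-averaged construction rather than a bp-precise coverage.  Abundance
is the column mean over the fragments of the network being analysed (so a
subnetwork's abundance is computed over its own nodes).

## Null models and significance

Empirical p values use the add-one rule p = (k + 1)/(n + 1) over the n
defined replicates, which never returns 0; two-sided p doubles the smaller
one-sided tail (capped at 1).  All procedures derive per-replicate
generators from one root seed by replicate index, so results are
bit-reproducible.

- **Label shuffle** (default 100 replicates): permutes the feature column
  over nodes; preserves topology and the value multiset (hence abundance)
  exactly.  Calibration: for features generated independently of topology
  the one-sided p is uniform; the acceptance suite checks a 2–10 %
  rejection rate at α = 0.05 over 200 simulated datasets.
- **Distance-preserving relocation**: every other-end fragment is replaced
  by a random same-length fragment on its chromosome at the original
  distance from its anchor bait (side uniform; the opposite side is tried
  when out of bounds, then an error is raised), and its feature values are
  recomputed from the binarized tracks.  The anchor is the smallest-id
  same-chromosome promoter neighbour; other ends without one keep their
  observed value.  Topology is untouched.  A `chroms` argument restricts
  the procedure to chosen chromosomes (the construction is per-chromosome
  by nature).
- **Partial rewiring**: double-edge swaps until the requested fraction of
  edges has been exchanged (each accepted swap exchanges two edges);
  degree sequence and simplicity are preserved exactly, edge classes are
  recomputed, swapped-in edges carry no score.  Rigid or tiny graphs yield
  a logged best effort rather than an error.
- **Edge removal**: per fraction, drop edges uniformly at random over
  replicates, or deterministically in decreasing order of the mean
  endpoint feature value ("targeted" mode, an interpretation of
  abundance-targeted removal); report mean ± sd of ChAs.

## Topology

Betweenness is exact, unnormalized shortest-path counting (networkx
Brandes), computed on the largest connected component by default with a
flag for the whole network.  Non-overlapping modules come from greedy
modularity (CNM) with nodes and edges fed in sorted order for determinism.

Overlapping communities use **clique percolation (k = 3)** rather than the
ModuLand family: the analyses here depend only on the bridgeness contract
— overlapping modules covering all nodes, with bridgeness = number of
modules containing the node — not on a particular algorithm's internals.
Nodes in no percolating community become singleton modules so the cover is
total; such nodes have bridgeness 1.  The method label is recorded on the
assignment object and in output tables.

Enrichment of a feature in the top-N nodes of a score ranking (N = 500 by
default) is the ratio of the top-N mean to the global mean (undefined when
the global mean is 0), with an empirical p from random same-size node
subsets; boundary ties break by fragment id.  "Date" features are those
with bridgeness enrichment above threshold (default 1); "party" features
have only betweenness enrichment above threshold; both statistics are
reported so other thresholds can be applied downstream.  The module ×
feature p matrix uses the same resampling construction per module.  The
enrichment statistic itself is a documented design choice of this package;
no standard definition exists.

## Synthetic fixtures

The generator states a scaled-down promoter-capture world and keeps its
structural ratios fixed: 4,000 fragments of 2 kb on four 3.2-Mb
chromosomes (the real mESC network is ~56k nodes; sizes are scaled, ratios
are not), 30 % promoter baits, mean degree 2.5, a connected group of
modules holding 63 % of nodes (the LCC) plus many small components with
mean size ~6, and interaction scores uniform in [5, 20] so the default
score filter keeps everything.

Wiring (default mode): modules of ~25 nodes built from random spanning
trees plus extra within-module edges; 6 % of the edge budget connects
modules of the giant group.  A planted-partition mode (explicit
within/between edge probabilities over equal blocks) serves the
community-recovery and overlap fixtures; designated overlap nodes get four
extra edges into a second module — enough to form a triangle there (so
clique percolation sees the dual membership) but too sparse to percolate
the two communities into one.

Feature planting: v = clip01(μ0 + σ·(w·L + √(1−w²)·ε)) quantized to
multiples of 1/(windows per fragment), with ε node-level standard normal
and L a module-level latent (standard normal per module) for positive
targets or an alternating two-coloring of each module's spanning tree for
negative targets.  σ = 0.05 + 0.8·min(a, 1−a) for target abundance a.  For
each candidate w, μ0 is solved by bisection so the realized
post-clip/quantize mean matches a; w itself is then bisected until the
realized symmetrized edge correlation matches the target ρ.  Targets
beyond the topology's reachable extreme (≈ the within-module edge
fraction) raise an error naming the achievable bound.  Because
quantization is shared by co-module nodes it barely attenuates the edge
correlation, so targets up to ≈0.9 are reachable at default wiring.

Peak BEDs are written as one window-aligned interval per fragment covering
the first k = v·W windows, so re-deriving values through the feature
mapper is lossless — the round-trip test asserts equality within one
window of quantization (in practice exact).

What a green test does *not* establish: the generator has no Hi-C
distance decay, no fragment-size heterogeneity, no trans contacts, no
correlated feature panel, and its peaks are fragment-aligned rather than
free-floating — conclusions about real promoter-capture data still require
real data.

`perturb` degrades a fixture by shuffling the values of a random node
fraction; expected ChAs decreases monotonically in the fraction, reaching
~0 at full scramble.

## Numerical and interface choices

- All tables are TSV with headers; the pipeline writes a JSON manifest
  (version, parameters, seeds, outputs) sufficient to reproduce a run.
- The run configuration is YAML with per-stage sections flattened into one
  keyspace; CLI flags override config values.
- Warnings (undefined ChAs, empty subnetworks) never abort batch runs; a
  stage failure aborts with the stage name, preserving completed outputs.
- Seeds: every stochastic routine takes an explicit integer seed;
  per-replicate streams come from `SeedSequence(seed, spawn_key=(rep,))`.

## Known limitations

- The CHiCAGO model itself is out of scope: its scored output is consumed,
  never recomputed.
- O–O edges are accepted (ChIA-PET inputs) but the enhancer-class
  restriction applies to P–O edges only, by definition.
- Raw continuous signal tracks are not supported; inputs must be peak
  calls (or pre-binarized windows).
- Clique percolation on very sparse graphs (mean degree ~2.5) leaves most
  nodes outside any triangle community; their bridgeness is 1 by the
  singleton fill-in, which is the honest reading on such graphs but means
  bridgeness is informative mainly in dense neighbourhoods.
- The distance-preserving null re-scores relocated fragments from the peak
  tracks; whether the original construction recomputed or resampled values
  is underdetermined, and this choice is stated rather than resolved.
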