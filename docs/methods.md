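# Methods

This note documents the models, statistical procedures, parameter choices
and known limitations of the `dreamer` package in enough detail to audit or
extend it.  Empirical figures quoted here are the ones the test suite and
`scripts/acceptance.py` compute; nothing is reported that the code does not
itself measure.

## Knowledge-graph model and construction filters

The knowledge graph holds five node namespaces (drugs, diseases, proteins,
ADRs, DPs), six bipartite edge sets and an undirected PPI with a STRING-style
confidence per edge (0–1000; thresholds given on a 0–1 scale are multiplied
by 1000).  Construction applies, in order: removal of ADRs with more than 50
drugs and DPs with more than 100 diseases (both strict inequalities — an ADR
with exactly 50 drugs survives); deletion of drug→ADR links whose ADR term
matches one of the drug's indication terms (an explicit disease→ADR term map
is honoured, with exact string identity as the fallback, since
cross-vocabulary matching is deployment-specific); a seeded uniform draw
keeping exactly one ADR per DP; removal of PPI edges with confidence ≤ the
threshold (default 800); and finally pruning of drugs without targets,
diseases without protein links, and phenotype pairs left without assets.
Pruning must run last — every other filter pair commutes, and the composed
build is idempotent (property-tested).  The filter order ahead of pruning is
a convention; it is recorded in the JSON build report each run emits.

Proteins that appear only in bipartite edge sets but not in the PPI remain
graph members but receive no diffusion mass; seeds placing weight on them
trigger a warning and that weight is dropped (not renormalised), so the
reported profile mass equals the on-network seed mass.

## Diffusion and significance

The transition operator is the column-normalised adjacency matrix of the
*unweighted* filtered PPI; a confidence-weighted variant sits behind a
config switch.  Stochasticity is required for convergence and probability
conservation, which is why the adjacency is normalised at all; zero-degree
proteins receive a unit self-loop, which preserves their restart mass
without teleporting it elsewhere.  The fixed point of
`P ← αAP + (1−α)P₀` is computed by damped power iteration (L1 convergence
tolerance 1e-10, geometric rate α = 0.7, typically ~65 iterations); the
observed seed and all K permutation seeds are propagated as columns of one
matrix, which is what keeps a full permutation ensemble at K = 200–1000
essentially free.  On random graphs up to 50 nodes the fixed point agrees
with the dense solve `(I − αA)⁻¹(1−α)P₀` to L1 ≤ 1e-10 (measured; the
acceptance bound is 1e-8).

α = 0.7 follows the recommendation for STRING-scale interactomes; smaller
values keep mass near the seeds, larger values push it toward the global
stationary distribution.  K defaults to 1000; the benchmark suite uses
K = 200, which changes only the noise of the null-mean estimate because the
p-value comes from a parametric fit, not an empirical quantile.

The null model reassigns the seed's value multiset uniformly over all PPI
proteins (a toggle restricts the shuffle to the seeded support — the choice
between the two is a genuine modelling ambiguity; "all proteins" is the
default because it measures surprise relative to graph position, not just
relative to the asset lists).  Each protein's K null scores get an
exponential fit with rate 1/mean — hub proteins and dense-community members
have systematically larger null means, so the fit is per protein, never
pooled — and the one-sided tail `p = exp(−s/mean)` is BH-corrected over all
PPI proteins.  A protein with an all-zero null but positive observed score
receives a floored p of 1/(K+1) with a warning.

**Calibration caveat.**  The exponential is an approximation: the true null
score distribution is a permutation mixture that is more skewed than
exponential in its bulk.  Under exchangeable seeds (observed and null drawn
from the same shuffle) on a 300-protein mean-degree-4 graph with 40 seeded
proteins, the pooled raw p-value distribution sits at Kolmogorov–Smirnov
distance ≈ 0.09–0.11 from uniform across RNG seeds (200 replicates,
K = 200) — mid-range p-values are conservative.  The decisions that matter
downstream are made after BH at level 0.05, where the procedure is clearly
conservative: the measured BH-significant fraction under the null is ~0.001,
far below the nominal 5%.  Users should treat raw p-values as scores with
approximately correct tails, not as exactly uniform-under-null quantities.

## Linking, baseline, confounders, holdout, repurposing

The overlap universe for the hypergeometric test is the filtered PPI protein
set — the common measurement space of both sides; whether off-network
proteins should count is ambiguous, and the universe size is an explicit
argument.  BH families are: all PPI proteins within one phenotype side; all
phenotypes in the run for the intersection test; all screened phenotypes for
the indication-confounder test.  The baseline method assigns a protein to a
phenotype when its drug (disease) set overlaps the phenotype's asset set
beyond chance, with the universe taken as assets having at least one protein
link (anything else is unobservable after pruning) and BH over proteins.

The organ screen removes the phenotype's drugs whose indication organs
intersect the ADR's organs (annotations are inputs, never derived;
unannotated drugs are kept by default, with a toggle), reruns the full
identification on the reduced drug list, and tests the overlap of old and
new ADR-DP sets.  The indication screen seeds diffusion from the proteins of
the indications of the phenotype's drugs — link counts duplicated across
drugs sharing an indication, so indications common to many of the
phenotype's drugs dominate (a toggle de-duplicates) — and flags the
phenotype when the resulting significant set overlaps the ADR-DP set after
BH.  A phenotype is "clean" when it survives every screen that could be run
on it.  The 3-D diffusion-map export adds the indication-side score as a
z-coordinate per protein.

Holdout validation splits one side's assets `round(0.8·n)` / rest (clipped
so both halves are non-empty), samples an equal number of negatives
uniformly from protein-linked, non-associated same-type assets per
phenotype, and reruns discovery with the reduced asset list.  An asset's
distance to the identified set is the minimum over its associated proteins
of the unweighted BFS hop distance (0 if a protein is in the set, infinite
if disconnected); the minimum is the right aggregation because the
underlying hypothesis is that *at least one* associated protein is close.
Distances are pooled across phenotypes before the one-sided Fisher test at
each hop threshold X.  Phenotypes whose discovery run identifies nothing
contribute infinite distances — degenerate tables then give p = 1, which is
exactly why the procedure stays calibrated on structureless graphs.

Repurposing classifies drugs with ≥1 target in a phenotype's ADR-DP set:
"indicated" if they also carry an indication matching the phenotype term
(term map or exact string), otherwise "candidate" provided they have neither
the ADR nor the indication.  Candidates are scored by
|targets ∩ set| / |targets| with the target universe being the pruned graph's
drug-target edges (the only consistent denominator), sorted by score, then
in-set count, then drug id — the tie-break is a documented convention.
"Trial-supported" is a caller-supplied annotation; "shares-indicated-target"
is computed.

## Synthetic benchmark generator

The generator emulates the structure the method's hypothesis presumes: each
phenotype owns a 20-protein mechanism module, dense inside
(Erdős–Rényi at density 0.8), embedded in a 200-protein background
interactome (mean degree 4) and attached to it through 10 bridge edges.
The limited bridge count is deliberate: a mechanism module inside a
~19k-protein interactome has its external edges diluted over thousands of
non-members, so per-walk leakage across the module boundary is small; giving
every member of a 20-protein module background-rate external edges in a
260-node toy would make the boundary proportionally far leakier than the
real system and destroy the scale separation the method relies on.  Bridge
count is a config parameter.

Per phenotype, 10 drugs and 10 diseases each receive 5 distinct protein
links (drug-target and disease-gene tables list distinct partners; 5 is a
realistic curated-database scale and gives each module protein an expected
≥2 links, i.e. the asset set collectively covers the module it perturbs).
Each link lands on the module with probability `signal` (default 0.9) and
otherwise on a uniform background protein.  Decoy drugs and diseases (50% of
the true asset count) use the `noise` rate (default 0.05) and carry no
phenotype links; they populate the holdout's negative pools.  Setting
`signal = noise` removes all association structure, and the pipeline then
retains essentially no phenotypes — the no-information control.

Two special wiring regimes exist for specific experiments.
`target_mode="neighbors"` adds, per phenotype, a periphery of 10
regulator-like proteins, each adjacent to 4 module members plus one
background protein, and points drug targets at the periphery instead of the
module: the link-overlap baseline then cannot assign any module member
(recall exactly 0) while diffusion still recovers some (mean ADR-side recall
≈ 0.1 at default power) — the qualitative separation between the two
methods.  `indication_mode` wires drug indications either onto proteins of a
disconnected 20-node PPI component ("remote", the specificity control: no
confounder flag should ever fire) or onto the phenotype's own module
("overlapping": every screen should fire).  Organ annotations label each ADR
with one organ and 30% of its drugs with the matching organ.

What the generator does **not** emulate: scale-free degree distributions,
realistic module size/overlap heterogeneity, shared modules between
phenotypes, edge-confidence structure (confidences are uniform above the
default cutoff), or chemical similarity between drugs.  Passing benchmarks
therefore demonstrate correctness and calibration of the machinery at desk
scale, not performance on real pharmacovigilance data.

## Numerical and reproducibility choices

Convergence is declared on the worst-column L1 change < 1e-10; max 10,000
iterations, with a hard error (carrying the last iterate) on
non-convergence.  All stochastic stages draw from `numpy` Generators seeded
via `SeedSequence`; pipeline stages derive independent child seeds from one
master seed and stage-identifying keys, so any run is reproducible from a
single integer and generator output is byte-identical across runs.  Default
problem sizes in the test and acceptance suites (260–300 proteins, K = 200,
10 seeds, 100 null repetitions) are the package's benchmark conditions;
the full suite runs in well under a minute of compute.

## Known limitations

- The exponential-tail p-value is approximate (see the calibration caveat);
  an empirical-quantile alternative would be exactly calibrated but
  discrete at resolution 1/(K+1).
- Diffusion runs on the full graph rather than the largest connected
  component; isolated proteins retain their restart mass via self-loops and
  can appear significant only if seeded.
- Term matching for indications is exact-string unless a cross-vocabulary
  map is supplied.
- The organ screen treats unannotated drugs as unfiltered by default, which
  overstates robustness when annotations are sparse.
- Confounder screening reruns the full pipeline once per screened phenotype;
  at hundreds of phenotypes this quadratic cost would need batching.
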