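# dreamer

Network-diffusion discovery of protein modules shared by adverse drug
reactions (ADRs) and phenotypically equivalent disease phenotypes (DPs).

## The problem

Most adverse drug reactions arise from unintended on- or off-target
drug–protein interactions, and many clinical phenotypes of genetic disease
are driven by variation in the same proteins.  When an ADR and a disease
phenotype describe the same clinical picture (say, ventricular arrhythmia),
the drugs that cause the reaction and the diseases that present the
phenotype plausibly perturb one shared mechanism — a module of the
protein–protein interaction (PPI) network.  `dreamer` implements the DREAMER
method for finding that module from a heterogeneous knowledge graph of
drug–ADR, disease–DP, drug–target, disease–gene and PPI links, along with
the method's confounder screens, holdout validation, a non-diffusion
baseline, and a drug-repurposing ranking over the recovered modules.

It is aimed at computational pharmacologists and systems biologists who have
(or can construct) such a knowledge graph as plain edge tables.  The
external databases the method was designed around (SIDER, HPO, DrugBank,
DisGeNET, STRING) are licensed or large and are **not** bundled; a
first-class synthetic generator plants ground-truth mechanism modules so the
whole pipeline is testable offline.

## The method

For one ADR *j* with drug set *D(j)*, each protein *i* gets a seed
probability proportional to its link frequency,

```
p_ADRj(i) = #links(i, D(j)) / Σ_i' #links(i', D(j))
```

and symmetrically for the DP side over disease–protein links.  The seed is
diffused over the PPI with personalized PageRank,

```
P_{t+1} = α · A · P_t + (1 − α) · P_0,        α = 0.7
```

where `A` is the column-stochastic transition matrix of the
confidence-filtered PPI.  Significance of each protein's diffusion score is
assessed against K permutation nulls (seed values reassigned uniformly over
proteins), with a one-sided tail p-value from an exponential fit
`p = exp(−s / mean(s_null))` per protein, Benjamini–Hochberg corrected over
all PPI proteins.  A phenotype's ADR-DP protein set is the intersection of
its two significant sets, kept only when the intersection itself is
significant under a hypergeometric test BH-corrected across phenotypes.
Two confounder screens (organ/tissue-matched drug removal; diffusion from
drug-indication proteins) flag phenotypes whose module may reflect what the
drugs treat rather than what they cause.  Candidate repurposing drugs are
ranked by the fraction of their targets inside the module.

## Worked example

Generate a synthetic knowledge graph (three phenotypes, each with a planted
20-protein module, 10 drugs and 10 diseases) and run the full pipeline:

```
$ dreamer simulate --seed 7 --out kg
wrote synthetic KG (260 proteins, 3 phenotype pairs) to kg

$ dreamer run --kg kg --k 200 --seed 7 --out results
3 of 3 phenotypes retained -> results

$ cat results/phenotypes.tsv
adr_id  dp_id  n_adr  n_dp  n_overlap  p_raw      p_adj      retained
ADR0    DP0    20     18    18         7.53e-26   7.53e-26   True
ADR1    DP1    20     21    20         5.43e-29   8.14e-29   True
ADR2    DP2    20     20    20         2.58e-30   7.75e-30   True
```

Each row is one ADR–DP pair: `n_adr` and `n_dp` are the sizes of the two
significant protein sets, `n_overlap` their intersection, and `p_adj` the
BH-adjusted hypergeometric probability of an overlap at least that large in
a 260-protein universe.  All three planted modules are recovered almost
exactly (the per-phenotype protein lists are written alongside).  Holdout
validation then asks whether drugs held out of discovery land closer to the
identified proteins than random drugs:

```
$ dreamer holdout --kg kg --side adr --k 200 --seed 7 --out holdout.tsv
holdout [adr] over 3 phenotypes -> holdout.tsv

side  X  pos_le  pos_gt  neg_le  neg_gt  fisher_p
adr   0  6       0       0       6       0.00108
adr   1  6       0       1       5       0.00758
adr   2  6       0       4       2       0.22727
```

All six held-out drugs target the identified sets directly (distance 0)
while no negative does, giving one-sided Fisher p ≈ 0.001 at X = 0 — the
enrichment decays as the hop threshold X grows, as it should.

Other subcommands: `dreamer build-kg` (apply the construction filters to raw
edge tables), `dreamer diffuse` (one phenotype side), `dreamer baseline`,
`dreamer confound` (both confounder screens plus 3-D diffusion-map tables)
and `dreamer repurpose` (indicated drugs and ranked candidates).

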