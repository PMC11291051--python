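"""Synthetic knowledge-graph generator with planted mechanism modules.

Each phenotype gets a dedicated dense protein module embedded in a sparse
Erdős–Rényi interactome.  The phenotype's drugs target module proteins with
probability ``signal`` (else a uniform off-module protein) and its diseases
do the same, so the module is the planted ground-truth mechanism shared by
both sides — the structure the diffusion pipeline is designed to recover.
Decoy drugs/diseases hit modules only at the ``noise`` rate and carry no
phenotype links; they populate the negative pools for holdout validation.

Indication wiring modes let the confounder screens be exercised:
``none`` adds no indications, ``remote`` links drug indications to proteins
in a disconnected PPI component, ``overlapping`` links them onto the
phenotype's own module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kg import KnowledgeGraph
from .linking import PhenotypeResult

__all__ = ["GeneratorConfig", "GroundTruth", "generate", "evaluate_recovery"]


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic benchmark.

    Defaults: a 200-protein background with one 20-protein near-clique
    module per phenotype, 10 drugs and 10 diseases per phenotype with 5
    distinct protein links each, a 0.9 on-module hit probability for true
    assets against 0.05 for decoys, mean background degree 4, and 10 bridge
    edges attaching each module to the background.
    """

    n_background_proteins: int = 200
    background_degree: float = 4.0
    n_phenotypes: int = 3
    module_size: int = 20
    module_density: float = 0.8
    n_drugs: int = 10
    n_diseases: int = 10
    targets_per_drug: int = 5
    proteins_per_disease: int = 5
    signal: float = 0.9
    noise: float = 0.05
    decoy_fraction: float = 0.5
    #: bridge edges connecting each module to the background interactome
    bridge_edges_per_module: int = 10
    #: where true drugs aim: module ``members`` or strict module ``neighbors``
    #: (a periphery of regulator-like proteins wired onto the module)
    target_mode: str = "members"
    n_periphery: int = 10
    periphery_attachment: int = 4
    #: none | remote | overlapping
    indication_mode: str = "none"
    n_indications: int = 2
    remote_component_size: int = 20
    #: fraction of each phenotype's drugs annotated with the ADR's organ
    organ_matched_fraction: float = 0.3
    rng_seed: int = 0

    def __post_init__(self):
        for name in ("module_density", "signal", "noise", "decoy_fraction",
                     "organ_matched_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.module_size * self.n_phenotypes > self.n_background_proteins:
            raise ValueError(
                "modules larger than the background protein pool"
            )
        if self.target_mode not in ("members", "neighbors"):
            raise ValueError("target_mode must be 'members' or 'neighbors'")
        if self.indication_mode not in ("none", "remote", "overlapping"):
            raise ValueError(
                "indication_mode must be 'none', 'remote' or 'overlapping'"
            )


@dataclass
class GroundTruth:
    """Planted structure: phenotype -> module, asset -> on/off-module label."""

    modules: dict = field(default_factory=dict)   # (adr_id, dp_id) -> set
    asset_labels: dict = field(default_factory=dict)  # asset id -> label

    def module_for(self, adr_id: str, dp_id: str) -> set:
        key = (adr_id, dp_id)
        if key not in self.modules:
            raise KeyError(f"unknown phenotype {key}")
        return self.modules[key]


def _er_edges(nodes, p, rng):
    """Erdős–Rényi edge list over ``nodes`` (sorted pair iteration order)."""
    edges = []
    n = len(nodes)
    for i in range(n):
        draws = rng.random(n - i - 1)
        for off, hit in enumerate(draws < p):
            if hit:
                edges.append((nodes[i], nodes[i + 1 + off]))
    return edges


def generate(config: GeneratorConfig | None = None):
    """Build ``(KnowledgeGraph, GroundTruth)``; deterministic under the seed.

    Module members are carved from the front of the protein list, one
    disjoint block per phenotype; background edges are drawn over all main
    proteins at mean degree ``background_degree`` and confidences are
    sampled uniformly above the default STRING cutoff, so the graph passes
    the standard build untouched.
    """
    config = config or GeneratorConfig()
    rng = np.random.default_rng(config.rng_seed)
    kg = KnowledgeGraph()
    truth = GroundTruth()

    n_main = config.n_background_proteins + config.n_phenotypes * config.module_size
    proteins = [f"P{i:04d}" for i in range(n_main)]
    modules = [
        proteins[k * config.module_size:(k + 1) * config.module_size]
        for k in range(config.n_phenotypes)
    ]
    module_members = {p for mod in modules for p in mod}
    background = [p for p in proteins if p not in module_members]

    # --- PPI: sparse background ER graph + dense planted modules, attached
    # through a limited number of bridge edges so each module keeps the
    # low-conductance boundary a mechanism module has inside a large
    # interactome (full-rate external edges would make a 200-node toy far
    # leakier, proportionally, than the real thing)
    p_bg = config.background_degree / max(len(background) - 1, 1)
    edges = _er_edges(background, p_bg, rng)
    for mod in modules:
        edges.extend(_er_edges(mod, config.module_density, rng))
        members = rng.choice(len(mod), config.bridge_edges_per_module)
        anchors = rng.choice(
            len(background),
            min(config.bridge_edges_per_module, len(background)),
            replace=False,
        )
        for m_i, b_i in zip(members, anchors):
            edges.append((mod[int(m_i)], background[int(b_i)]))

    # neighbors regime: a periphery of regulator-like proteins, each wired to
    # several module members (never members themselves) — drugs then target
    # these instead of the module, while only diffusion can reach the module
    periphery_sets = []
    if config.target_mode == "neighbors":
        for k, mod in enumerate(modules):
            periphery = [f"N{k}_{j:02d}" for j in range(config.n_periphery)]
            for p in periphery:
                attach = rng.choice(
                    len(mod),
                    min(config.periphery_attachment, len(mod)),
                    replace=False,
                )
                for m_i in attach:
                    edges.append((p, mod[int(m_i)]))
                edges.append(
                    (p, background[int(rng.integers(len(background)))])
                )
            periphery_sets.append(periphery)
            proteins.extend(periphery)

    seen = set()
    for u, v in edges:
        key = (u, v) if u < v else (v, u)
        if key in seen:
            continue
        seen.add(key)
        kg.ppi.add_edge(*key, confidence=float(rng.integers(810, 1001)))
    kg.ppi.add_nodes_from(proteins)
    kg.proteins.update(proteins)

    def draw_links(n_links, on_module_p, pool_on, pool_off):
        """Distinct proteins per asset: each link lands in ``pool_on`` with
        the given probability, drawn without replacement within each pool."""
        n_on = int((rng.random(n_links) < on_module_p).sum()) if pool_on else 0
        n_on = min(n_on, len(pool_on))
        n_off = min(n_links - n_on, len(pool_off))
        picks = [
            pool_on[i] for i in rng.choice(len(pool_on), n_on, replace=False)
        ] if n_on else []
        picks += [
            pool_off[i] for i in rng.choice(len(pool_off), n_off, replace=False)
        ] if n_off else []
        return set(picks)

    # --- phenotypes: ADR-DP pair + drugs + diseases
    for k, mod in enumerate(modules):
        adr, dp = f"ADR{k}", f"DP{k}"
        kg.adrs.add(adr)
        kg.dps.add(dp)
        kg.adr_dp.add((adr, dp))
        truth.modules[(adr, dp)] = set(mod)
        drug_pool = periphery_sets[k] if config.target_mode == "neighbors" else mod
        for j in range(config.n_drugs):
            drug = f"DRUG{k}_{j}"
            kg.drugs.add(drug)
            kg.drug_adr.add((drug, adr))
            truth.asset_labels[drug] = "signal"
            for p in draw_links(
                config.targets_per_drug, config.signal, drug_pool, background
            ):
                kg.drug_target.add((drug, p))
        for j in range(config.n_diseases):
            disease = f"DIS{k}_{j}"
            kg.diseases.add(disease)
            kg.disease_dp.add((disease, dp))
            truth.asset_labels[disease] = "signal"
            for p in draw_links(
                config.proteins_per_disease, config.signal, mod, background
            ):
                kg.disease_protein.add((disease, p))

    # --- decoys: protein-linked but phenotype-free
    n_decoy = int(round(config.decoy_fraction * config.n_phenotypes * config.n_drugs))
    all_module = sorted(module_members)
    for j in range(n_decoy):
        drug = f"DECOYDRUG{j}"
        kg.drugs.add(drug)
        truth.asset_labels[drug] = "decoy"
        for p in draw_links(
            config.targets_per_drug, config.noise, all_module, background
        ):
            kg.drug_target.add((drug, p))
    n_decoy_dis = int(
        round(config.decoy_fraction * config.n_phenotypes * config.n_diseases)
    )
    for j in range(n_decoy_dis):
        disease = f"DECOYDIS{j}"
        kg.diseases.add(disease)
        truth.asset_labels[disease] = "decoy"
        for p in draw_links(
            config.proteins_per_disease, config.noise, all_module, background
        ):
            kg.disease_protein.add((disease, p))

    # --- indications for the confounder screens
    if config.indication_mode != "none":
        if config.indication_mode == "remote":
            remote = [f"R{i:04d}" for i in range(config.remote_component_size)]
            for u, v in _er_edges(remote, config.module_density, rng):
                kg.ppi.add_edge(u, v, confidence=float(rng.integers(810, 1001)))
            kg.ppi.add_nodes_from(remote)
            kg.proteins.update(remote)
            indication_pools = [remote] * config.n_phenotypes
        else:  # overlapping: indications sit on the mechanism module itself
            indication_pools = modules
        for k in range(config.n_phenotypes):
            adr = f"ADR{k}"
            pool = indication_pools[k]
            ind_ids = []
            for j in range(config.n_indications):
                ind = f"IND{k}_{j}"
                kg.diseases.add(ind)
                ind_ids.append(ind)
                for p in draw_links(
                    config.proteins_per_disease, 1.0, pool, pool
                ):
                    kg.disease_protein.add((ind, p))
            for j, drug in enumerate(sorted(kg.drugs_of_adr(adr))):
                kg.drug_indication.add((drug, ind_ids[j % len(ind_ids)]))

    # --- organ annotations (ADR organ + matched fraction of its drugs)
    for k in range(config.n_phenotypes):
        adr, organ = f"ADR{k}", f"organ{k}"
        kg.adr_organs[adr] = frozenset({organ})
        drugs = sorted(kg.drugs_of_adr(adr))
        n_matched = int(round(config.organ_matched_fraction * len(drugs)))
        for j, drug in enumerate(drugs):
            kg.drug_organs[drug] = frozenset(
                {organ if j < n_matched else f"other_organ{k}"}
            )

    kg.validate()
    return kg, truth


def evaluate_recovery(predicted, truth: GroundTruth,
                      adr_id: str | None = None, dp_id: str | None = None):
    """Precision/recall/F1 of a predicted protein set vs the planted module.

    ``predicted`` may be a :class:`~dreamer.linking.PhenotypeResult` (its
    ADR-DP set and ids are used) or a plain protein set with explicit ids.
    An empty prediction scores (0, 0, 0) by convention.
    """
    if isinstance(predicted, PhenotypeResult):
        adr_id, dp_id = predicted.adr_id, predicted.dp_id
        predicted = predicted.adr_dp_proteins
    module = truth.module_for(adr_id, dp_id)
    predicted = set(predicted)
    if not predicted:
        return 0.0, 0.0, 0.0
    tp = len(predicted & module)
    precision = tp / len(predicted)
    recall = tp / len(module)
    f1 = (
        0.0 if precision + recall == 0
        else 2 * precision * recall / (precision + recall)
    )
    return precision, recall, f1
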