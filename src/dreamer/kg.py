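"""Heterogeneous knowledge-graph model and construction-time filtering.

The graph ties together five node namespaces — drugs, diseases, proteins,
adverse drug reactions (ADRs) and disease phenotypes (DPs) — through six
bipartite edge sets plus a confidence-weighted protein–protein interaction
(PPI) network.  Everything downstream (diffusion, overlap testing, holdout
validation, repurposing) runs on this substrate.

Construction applies a fixed sequence of filters:

1. drop ADRs linked to too many drugs (very common, uninformative ADRs);
2. drop DPs linked to too many diseases;
3. remove drug→ADR links where the ADR term equals one of the drug's
   indication terms (the reported "reaction" is the treated condition);
4. deduplicate the ADR–DP pairing so each DP keeps exactly one ADR
   (uniform random draw, seeded);
5. keep only high-confidence PPI edges;
6. prune drugs without targets, diseases without associated proteins, and
   phenotype pairs left without assets.

All filters are pure: they return a new :class:`KnowledgeGraph`.
"""

from __future__ import annotations

import json
import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "KnowledgeGraph",
    "BuildConfig",
    "read_kg",
    "write_kg",
    "filter_common_adrs",
    "filter_common_dps",
    "remove_indication_matched_adr_links",
    "dedupe_adr_dp",
    "prune_orphans",
    "filter_ppi",
    "build_kg",
]

NAMESPACES = ("drug", "disease", "protein", "adr", "dp")

#: edge-set name -> (source namespace, target namespace)
EDGE_SCHEMAS = {
    "drug_adr": ("drug", "adr"),
    "disease_dp": ("disease", "dp"),
    "adr_dp": ("adr", "dp"),
    "drug_target": ("drug", "protein"),
    "disease_protein": ("disease", "protein"),
    "drug_indication": ("drug", "disease"),
}


class KGError(ValueError):
    """Raised when a knowledge graph violates a structural invariant."""


@dataclass
class KnowledgeGraph:
    """Typed node sets, bipartite edge sets and the weighted PPI.

    Edge sets are sets of ``(source_id, target_id)`` tuples.  The PPI is an
    undirected :class:`networkx.Graph` whose edges carry a ``confidence``
    attribute on the STRING 0–1000 scale.  Proteins that appear only as drug
    targets or disease proteins but not in the PPI are legal graph members;
    they simply carry no diffusion mass.
    """

    drugs: set = field(default_factory=set)
    diseases: set = field(default_factory=set)
    proteins: set = field(default_factory=set)
    adrs: set = field(default_factory=set)
    dps: set = field(default_factory=set)

    drug_adr: set = field(default_factory=set)
    disease_dp: set = field(default_factory=set)
    adr_dp: set = field(default_factory=set)
    drug_target: set = field(default_factory=set)
    disease_protein: set = field(default_factory=set)
    drug_indication: set = field(default_factory=set)

    ppi: nx.Graph = field(default_factory=nx.Graph)

    #: optional organ/tissue annotations, entity id -> frozenset of organ labels
    adr_organs: dict = field(default_factory=dict)
    drug_organs: dict = field(default_factory=dict)

    # ------------------------------------------------------------------ copy
    def copy(self) -> "KnowledgeGraph":
        return KnowledgeGraph(
            drugs=set(self.drugs),
            diseases=set(self.diseases),
            proteins=set(self.proteins),
            adrs=set(self.adrs),
            dps=set(self.dps),
            drug_adr=set(self.drug_adr),
            disease_dp=set(self.disease_dp),
            adr_dp=set(self.adr_dp),
            drug_target=set(self.drug_target),
            disease_protein=set(self.disease_protein),
            drug_indication=set(self.drug_indication),
            ppi=self.ppi.copy(),
            adr_organs=dict(self.adr_organs),
            drug_organs=dict(self.drug_organs),
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, KnowledgeGraph):
            return NotImplemented
        same_edges = all(
            getattr(self, name) == getattr(other, name) for name in EDGE_SCHEMAS
        )
        same_nodes = all(
            getattr(self, ns + "s") == getattr(other, ns + "s") for ns in NAMESPACES
        )
        ppi_a = {tuple(sorted(e)): round(d.get("confidence", 0.0), 9)
                 for *e, d in self.ppi.edges(data=True)}
        ppi_b = {tuple(sorted(e)): round(d.get("confidence", 0.0), 9)
                 for *e, d in other.ppi.edges(data=True)}
        return (same_edges and same_nodes and ppi_a == ppi_b
                and set(self.ppi.nodes) == set(other.ppi.nodes))

    # --------------------------------------------------------------- indexes
    def _index(self, edge_set: str, forward: bool = True) -> dict:
        idx: dict = defaultdict(set)
        for s, t in getattr(self, edge_set):
            if forward:
                idx[s].add(t)
            else:
                idx[t].add(s)
        return idx

    def drugs_of_adr(self, adr: str) -> set:
        return {d for d, a in self.drug_adr if a == adr}

    def diseases_of_dp(self, dp: str) -> set:
        return {d for d, p in self.disease_dp if p == dp}

    def targets_of_drug(self, drug: str) -> set:
        return {p for d, p in self.drug_target if d == drug}

    def proteins_of_disease(self, disease: str) -> set:
        return {p for d, p in self.disease_protein if d == disease}

    def indications_of_drug(self, drug: str) -> set:
        return {i for d, i in self.drug_indication if d == drug}

    def drugs_of_protein(self, protein: str) -> set:
        return {d for d, p in self.drug_target if p == protein}

    def diseases_of_protein(self, protein: str) -> set:
        return {d for d, p in self.disease_protein if p == protein}

    def phenotype_pairs(self) -> list:
        """All ADR–DP pairs, sorted for deterministic iteration."""
        return sorted(self.adr_dp)

    def dp_of_adr(self, adr: str) -> str | None:
        for a, p in self.adr_dp:
            if a == adr:
                return p
        return None

    # ------------------------------------------------------------ invariants
    def validate(self) -> None:
        """Raise :class:`KGError` on any violated structural invariant."""
        node_sets = {ns: getattr(self, ns + "s") for ns in NAMESPACES}
        for name, (src_ns, tgt_ns) in EDGE_SCHEMAS.items():
            for s, t in getattr(self, name):
                if s not in node_sets[src_ns]:
                    raise KGError(f"{name} edge ({s}, {t}): unknown {src_ns} {s!r}")
                if t not in node_sets[tgt_ns]:
                    raise KGError(f"{name} edge ({s}, {t}): unknown {tgt_ns} {t!r}")
        for u, v in self.ppi.edges():
            if u == v:
                raise KGError(f"PPI self-loop at {u!r}")
            if u not in self.proteins or v not in self.proteins:
                raise KGError(f"PPI edge ({u}, {v}) references unknown protein")
        # partial injection: each DP maps to at most one ADR
        seen: dict = {}
        for a, p in self.adr_dp:
            if p in seen and seen[p] != a:
                raise KGError(f"DP {p!r} linked to multiple ADRs ({seen[p]!r}, {a!r})")
            seen[p] = a


@dataclass(frozen=True)
class BuildConfig:
    """Thresholds and switches for :func:`build_kg`.

    ``ppi_min_confidence`` accepts either the STRING 0–1000 integer scale or
    the equivalent 0–1 fraction; values ≤ 1 are multiplied by 1000
    internally.  The comparison is strict: an edge is retained only when its
    confidence is *greater than* the threshold.
    """

    max_drugs_per_adr: int = 50
    max_diseases_per_dp: int = 100
    ppi_min_confidence: float = 800.0
    rng_seed: int = 0
    filter_adrs: bool = True
    filter_dps: bool = True
    filter_indication_matches: bool = True
    dedupe: bool = True
    do_filter_ppi: bool = True
    prune: bool = True
    #: optional disease-term -> ADR-term equivalence map used by the
    #: indication filter; exact string identity is the fallback
    term_map: dict | None = None

    def __post_init__(self):
        if self.max_drugs_per_adr <= 0 or self.max_diseases_per_dp <= 0:
            raise ValueError("count thresholds must be positive")
        if self.ppi_min_confidence < 0:
            raise ValueError("ppi_min_confidence must be non-negative")

    @property
    def ppi_threshold(self) -> float:
        """Threshold normalised to the 0–1000 scale."""
        c = self.ppi_min_confidence
        return c * 1000.0 if c <= 1.0 else c


# --------------------------------------------------------------------- I/O

_EDGE_FILES = {name: f"{name}.tsv" for name in EDGE_SCHEMAS}


def _read_edge_table(path: Path, name: str, with_score: bool = False):
    if not path.exists():
        raise FileNotFoundError(f"missing edge file for {name}: {path}")
    df = pd.read_csv(path, sep="\t", dtype={"source_id": str, "target_id": str})
    required = ["source_id", "target_id"] + (["score"] if with_score else [])
    for col in required:
        if col not in df.columns:
            raise KGError(f"{path}: missing required column {col!r}")
    bad = df.index[df[required].isna().any(axis=1)].tolist()
    if bad:
        warnings.warn(
            f"{path}: rejected {len(bad)} malformed row(s) at {bad}", stacklevel=3
        )
        df = df.drop(index=bad)
    if with_score and not pd.api.types.is_numeric_dtype(df["score"]):
        raise KGError(f"{path}: non-numeric PPI score column")
    return df


def read_kg(indir, config: BuildConfig | None = None) -> KnowledgeGraph:
    """Read an unfiltered knowledge graph from a directory of TSV files.

    Expected files: one per bipartite edge set (``drug_adr.tsv`` …,
    columns ``source_id``/``target_id``), ``ppi.tsv`` (plus ``score``), and
    optional ``adr_organs.tsv`` / ``drug_organs.tsv`` (columns
    ``entity_id``/``organ``).  Node sets are the union of edge endpoints.
    Duplicate edges and PPI self-loops are rejected with a warning.
    """
    indir = Path(indir)
    kg = KnowledgeGraph()
    for name, (src_ns, tgt_ns) in EDGE_SCHEMAS.items():
        df = _read_edge_table(indir / _EDGE_FILES[name], name)
        edges = set()
        dupes = 0
        for s, t in zip(df["source_id"], df["target_id"]):
            if (s, t) in edges:
                dupes += 1
                continue
            edges.add((s, t))
            getattr(kg, src_ns + "s").add(s)
            getattr(kg, tgt_ns + "s").add(t)
        if dupes:
            warnings.warn(f"{name}: dropped {dupes} duplicate edge(s)", stacklevel=2)
        if not edges and name == "adr_dp":
            warnings.warn("adr_dp is empty: no phenotype pairs to analyse",
                          stacklevel=2)
        setattr(kg, name, edges)

    ppi_df = _read_edge_table(indir / "ppi.tsv", "ppi", with_score=True)
    for row_i, (u, v, score) in enumerate(
        zip(ppi_df["source_id"], ppi_df["target_id"], ppi_df["score"])
    ):
        if u == v:
            warnings.warn(f"ppi row {row_i}: self-loop {u!r} rejected", stacklevel=2)
            continue
        a, b = sorted((u, v))
        if kg.ppi.has_edge(a, b):
            warnings.warn(f"ppi row {row_i}: duplicate edge ({a}, {b})", stacklevel=2)
            continue
        kg.ppi.add_edge(a, b, confidence=float(score))
        kg.proteins.update((a, b))
    nodes_path = indir / "ppi_nodes.tsv"
    if nodes_path.exists():
        roster = pd.read_csv(nodes_path, sep="\t", dtype=str)["node_id"]
        kg.ppi.add_nodes_from(roster)
        kg.proteins.update(roster)

    for attr, fname in (("adr_organs", "adr_organs.tsv"),
                        ("drug_organs", "drug_organs.tsv")):
        path = indir / fname
        if path.exists():
            df = pd.read_csv(path, sep="\t", dtype=str)
            if not {"entity_id", "organ"} <= set(df.columns):
                raise KGError(f"{path}: needs columns entity_id, organ")
            ann: dict = defaultdict(set)
            for e, o in zip(df["entity_id"], df["organ"]):
                ann[e].add(o)
            setattr(kg, attr, {e: frozenset(v) for e, v in ann.items()})

    kg.validate()
    return kg


def write_kg(kg: KnowledgeGraph, outdir, report: dict | None = None) -> None:
    """Write the graph as normalized, sorted TSVs (byte-stable given a graph)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name in EDGE_SCHEMAS:
        rows = sorted(getattr(kg, name))
        pd.DataFrame(rows, columns=["source_id", "target_id"]).to_csv(
            outdir / _EDGE_FILES[name], sep="\t", index=False
        )
    ppi_rows = sorted(
        (u, v, d["confidence"]) if u < v else (v, u, d["confidence"])
        for u, v, d in kg.ppi.edges(data=True)
    )
    pd.DataFrame(ppi_rows, columns=["source_id", "target_id", "score"]).to_csv(
        outdir / "ppi.tsv", sep="\t", index=False
    )
    # node roster preserves isolated PPI proteins across a round-trip
    pd.DataFrame({"node_id": sorted(kg.ppi.nodes)}).to_csv(
        outdir / "ppi_nodes.tsv", sep="\t", index=False
    )
    for attr, fname in (("adr_organs", "adr_organs.tsv"),
                        ("drug_organs", "drug_organs.tsv")):
        ann = getattr(kg, attr)
        if ann:
            rows = sorted((e, o) for e, organs in ann.items() for o in organs)
            pd.DataFrame(rows, columns=["entity_id", "organ"]).to_csv(
                outdir / fname, sep="\t", index=False
            )
    if report is not None:
        (outdir / "build_report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True) + "\n"
        )


# ----------------------------------------------------------------- filters

def filter_common_adrs(kg: KnowledgeGraph, max_drugs: int = 50) -> KnowledgeGraph:
    """Drop ADRs linked to strictly more than ``max_drugs`` drugs."""
    counts: dict = defaultdict(int)
    for _, a in kg.drug_adr:
        counts[a] += 1
    doomed = {a for a, c in counts.items() if c > max_drugs}
    out = kg.copy()
    out.adrs -= doomed
    out.drug_adr = {(d, a) for d, a in out.drug_adr if a not in doomed}
    out.adr_dp = {(a, p) for a, p in out.adr_dp if a not in doomed}
    out.adr_organs = {a: v for a, v in out.adr_organs.items() if a not in doomed}
    return out


def filter_common_dps(kg: KnowledgeGraph, max_diseases: int = 100) -> KnowledgeGraph:
    """Drop DPs linked to strictly more than ``max_diseases`` diseases."""
    counts: dict = defaultdict(int)
    for _, p in kg.disease_dp:
        counts[p] += 1
    doomed = {p for p, c in counts.items() if c > max_diseases}
    out = kg.copy()
    out.dps -= doomed
    out.disease_dp = {(d, p) for d, p in out.disease_dp if p not in doomed}
    out.adr_dp = {(a, p) for a, p in out.adr_dp if p not in doomed}
    return out


def remove_indication_matched_adr_links(
    kg: KnowledgeGraph, term_map: dict | None = None
) -> KnowledgeGraph:
    """Delete drug→ADR links whose ADR term matches a drug indication.

    A drug listed with a "reaction" that is also one of its treated
    conditions (e.g. an antihypertensive with hypertension as a recorded
    reaction) is a reporting artefact, not a mechanism signal.  Equivalence
    between a disease term and an ADR term uses ``term_map``
    (disease id -> ADR id) when supplied, else exact string identity.
    """
    def equivalent(disease: str, adr: str) -> bool:
        if term_map is not None and disease in term_map:
            return term_map[disease] == adr
        return disease == adr

    out = kg.copy()
    ind_idx = out._index("drug_indication")
    out.drug_adr = {
        (d, a)
        for d, a in out.drug_adr
        if not any(equivalent(i, a) for i in ind_idx.get(d, ()))
    }
    return out


def dedupe_adr_dp(kg: KnowledgeGraph, rng_seed: int = 0) -> KnowledgeGraph:
    """Keep exactly one ADR per DP, drawn uniformly with the given seed."""
    by_dp: dict = defaultdict(list)
    for a, p in kg.adr_dp:
        by_dp[p].append(a)
    rng = np.random.default_rng(rng_seed)
    kept = set()
    for p in sorted(by_dp):
        adrs = sorted(by_dp[p])
        kept.add((adrs[int(rng.integers(len(adrs)))], p))
    out = kg.copy()
    out.adr_dp = kept
    return out


def filter_ppi(kg: KnowledgeGraph, min_confidence: float = 800.0) -> KnowledgeGraph:
    """Keep PPI edges with confidence strictly above the threshold.

    Accepts the threshold on either the 0–1000 or the 0–1 scale.  Proteins
    left without edges stay in the graph as isolated PPI nodes.
    """
    thr = min_confidence * 1000.0 if 0 < min_confidence <= 1.0 else min_confidence
    out = kg.copy()
    doomed = [
        (u, v) for u, v, d in out.ppi.edges(data=True) if d["confidence"] <= thr
    ]
    out.ppi.remove_edges_from(doomed)
    return out


def prune_orphans(kg: KnowledgeGraph) -> KnowledgeGraph:
    """Remove protein-less drugs/diseases and asset-less phenotype pairs.

    Drugs without any target and diseases without any associated protein are
    removed with all their incident edges.  ADR–DP pairs whose ADR ends up
    with zero drugs or whose DP ends up with zero diseases are dropped, along
    with the now-unusable ADR/DP nodes.  Must run after all other filters.
    """
    out = kg.copy()
    targeted = {d for d, _ in out.drug_target}
    protein_linked = {d for d, _ in out.disease_protein}
    out.drugs &= targeted
    out.diseases &= protein_linked
    out.drug_adr = {(d, a) for d, a in out.drug_adr if d in out.drugs}
    out.drug_target = {(d, p) for d, p in out.drug_target if d in out.drugs}
    out.drug_indication = {
        (d, i) for d, i in out.drug_indication if d in out.drugs and i in out.diseases
    }
    out.disease_dp = {(d, p) for d, p in out.disease_dp if d in out.diseases}
    out.disease_protein = {
        (d, p) for d, p in out.disease_protein if d in out.diseases
    }
    out.drug_organs = {d: v for d, v in out.drug_organs.items() if d in out.drugs}

    adrs_with_drugs = {a for _, a in out.drug_adr}
    dps_with_diseases = {p for _, p in out.disease_dp}
    out.adr_dp = {
        (a, p)
        for a, p in out.adr_dp
        if a in adrs_with_drugs and p in dps_with_diseases
    }
    out.adrs &= adrs_with_drugs
    out.dps &= dps_with_diseases
    out.drug_adr = {(d, a) for d, a in out.drug_adr if a in out.adrs}
    out.disease_dp = {(d, p) for d, p in out.disease_dp if p in out.dps}
    out.adr_organs = {a: v for a, v in out.adr_organs.items() if a in out.adrs}
    return out


def build_kg(kg: KnowledgeGraph, config: BuildConfig | None = None):
    """Apply the full filter sequence; return ``(graph, build report)``.

    Order: common-ADR → common-DP → indication-match → ADR–DP dedup →
    PPI confidence filter → orphan pruning.  The report records node/edge
    counts after each stage plus the dedup seed.
    """
    config = config or BuildConfig()
    report: dict = {"config": {
        "max_drugs_per_adr": config.max_drugs_per_adr,
        "max_diseases_per_dp": config.max_diseases_per_dp,
        "ppi_min_confidence": config.ppi_threshold,
        "rng_seed": config.rng_seed,
    }, "stages": []}

    def snapshot(stage: str, g: KnowledgeGraph):
        report["stages"].append({
            "stage": stage,
            "n_drugs": len(g.drugs), "n_diseases": len(g.diseases),
            "n_proteins": len(g.proteins), "n_adrs": len(g.adrs),
            "n_dps": len(g.dps), "n_pairs": len(g.adr_dp),
            "n_ppi_edges": g.ppi.number_of_edges(),
        })

    out = kg
    snapshot("input", out)
    if config.filter_adrs:
        out = filter_common_adrs(out, config.max_drugs_per_adr)
        snapshot("filter_common_adrs", out)
    if config.filter_dps:
        out = filter_common_dps(out, config.max_diseases_per_dp)
        snapshot("filter_common_dps", out)
    if config.filter_indication_matches:
        out = remove_indication_matched_adr_links(out, config.term_map)
        snapshot("remove_indication_matched_adr_links", out)
    if config.dedupe:
        out = dedupe_adr_dp(out, config.rng_seed)
        snapshot("dedupe_adr_dp", out)
    if config.do_filter_ppi:
        out = filter_ppi(out, config.ppi_threshold)
        snapshot("filter_ppi", out)
    if config.prune:
        out = prune_orphans(out)
        snapshot("prune_orphans", out)
    out.validate()
    off_network = {p for _, p in out.drug_target} | {
        p for _, p in out.disease_protein
    }
    off_network -= set(out.ppi.nodes)
    if off_network:
        warnings.warn(
            f"{len(off_network)} linked protein(s) absent from the PPI carry "
            "zero diffusion mass", stacklevel=2
        )
    return out, report
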