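"""Drug-repurposing ranking over a phenotype's ADR-DP protein set.

"Indicated" drugs are already indicated for the phenotype's term and target
the set — evidence that hitting these proteins treats the phenotype.
"Candidate" drugs target the set but carry neither the ADR nor the
indication; they are ranked by the fraction of their targets inside the set.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .kg import KnowledgeGraph
from .linking import PhenotypeResult

__all__ = [
    "RepurposingTable",
    "find_indicated_drugs",
    "find_candidate_drugs",
    "rank_candidates",
    "repurpose",
]


@dataclass
class RepurposingTable:
    adr_id: str
    dp_id: str
    indicated: pd.DataFrame   # drug, targets_in_set
    candidates: pd.DataFrame  # drug, n_in_set, n_targets, score, category


def _matches_phenotype(disease: str, adr_id: str, dp_id: str,
                       term_map: dict | None) -> bool:
    """Cross-vocabulary equivalence of an indication disease term with the
    phenotype; explicit map first, exact string identity as fallback."""
    if term_map is not None and disease in term_map:
        return term_map[disease] in (adr_id, dp_id)
    return disease in (adr_id, dp_id)


def find_indicated_drugs(
    kg: KnowledgeGraph,
    result: PhenotypeResult,
    term_map: dict | None = None,
) -> list:
    """Drugs indicated for the phenotype term with >= 1 target in the set."""
    if not result.adr_dp_proteins:
        return []
    out = []
    for drug in sorted(kg.drugs):
        if not any(
            _matches_phenotype(i, result.adr_id, result.dp_id, term_map)
            for i in kg.indications_of_drug(drug)
        ):
            continue
        if kg.targets_of_drug(drug) & result.adr_dp_proteins:
            out.append(drug)
    return out


def find_candidate_drugs(
    kg: KnowledgeGraph,
    result: PhenotypeResult,
    term_map: dict | None = None,
) -> list:
    """Drugs targeting the set with neither the ADR nor the indication."""
    if not result.adr_dp_proteins:
        return []
    out = []
    for drug in sorted(kg.drugs):
        if not (kg.targets_of_drug(drug) & result.adr_dp_proteins):
            continue
        if (drug, result.adr_id) in kg.drug_adr:
            continue
        if any(
            _matches_phenotype(i, result.adr_id, result.dp_id, term_map)
            for i in kg.indications_of_drug(drug)
        ):
            continue
        out.append(drug)
    return out


def rank_candidates(
    kg: KnowledgeGraph,
    result: PhenotypeResult,
    candidates,
    indicated,
    trial_supported: set | None = None,
) -> pd.DataFrame:
    """Score candidates by in-set target ratio and categorise them.

    score = |targets ∩ ADR-DP set| / |targets|; sorted by score descending,
    ties broken by in-set count descending, then drug id.  Category is
    ``trial-supported`` (caller-supplied annotation), else
    ``shares-indicated-target`` when the candidate hits a protein also hit
    by an indicated drug, else ``novel``.
    """
    trial_supported = trial_supported or set()
    indicated_targets = set()
    for drug in indicated:
        indicated_targets |= kg.targets_of_drug(drug) & result.adr_dp_proteins
    rows = []
    for drug in candidates:
        targets = kg.targets_of_drug(drug)
        assert targets, f"candidate {drug!r} has no targets (unpruned graph?)"
        in_set = targets & result.adr_dp_proteins
        if drug in trial_supported:
            category = "trial-supported"
        elif in_set & indicated_targets:
            category = "shares-indicated-target"
        else:
            category = "novel"
        rows.append(
            {
                "drug": drug,
                "n_in_set": len(in_set),
                "n_targets": len(targets),
                "score": len(in_set) / len(targets),
                "category": category,
            }
        )
    df = pd.DataFrame(
        rows, columns=["drug", "n_in_set", "n_targets", "score", "category"]
    )
    if not df.empty:
        df = df.sort_values(
            ["score", "n_in_set", "drug"], ascending=[False, False, True]
        ).reset_index(drop=True)
    return df


def repurpose(
    kg: KnowledgeGraph,
    result: PhenotypeResult,
    term_map: dict | None = None,
    trial_supported: set | None = None,
) -> RepurposingTable:
    """Indicated drugs, candidate drugs and the ranked score table."""
    indicated = find_indicated_drugs(kg, result, term_map)
    candidates = find_candidate_drugs(kg, result, term_map)
    ind_rows = [
        {
            "drug": d,
            "targets_in_set": ",".join(
                sorted(kg.targets_of_drug(d) & result.adr_dp_proteins)
            ),
        }
        for d in indicated
    ]
    return RepurposingTable(
        adr_id=result.adr_id,
        dp_id=result.dp_id,
        indicated=pd.DataFrame(ind_rows, columns=["drug", "targets_in_set"]),
        candidates=rank_candidates(
            kg, result, candidates, indicated, trial_supported
        ),
    )
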