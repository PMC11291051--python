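"""Combine ADR-side and DP-side protein sets into phenotype mechanism sets.

A phenotype (ADR–DP pair) keeps the intersection of its two significant
protein sets only when that overlap is itself significant under a
hypergeometric test, Benjamini–Hochberg corrected across all phenotypes in
the run.  The sampling universe is the filtered PPI protein set — the common
measurement space of both diffusion sides.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy.stats import hypergeom

from .diffusion import DiffusionProfile, SignificanceResult, bh_adjust
from .kg import KnowledgeGraph

__all__ = [
    "PhenotypeResult",
    "hypergeometric_overlap",
    "link_phenotypes",
    "export_diffusion_map",
]


@dataclass
class PhenotypeResult:
    """Outcome of the overlap test for one ADR–DP pair."""

    adr_id: str
    dp_id: str
    adr_proteins: set
    dp_proteins: set
    overlap_p_raw: float
    overlap_p_adj: float
    adr_dp_proteins: set
    universe_size: int

    @property
    def retained(self) -> bool:
        return bool(self.adr_dp_proteins)


def hypergeometric_overlap(set_a, set_b, universe: int) -> float:
    """Upper-tail P[X >= |A ∩ B|] for X ~ Hypergeom(universe, |A|, |B|).

    The probability that two uniformly drawn subsets of the given sizes
    share at least as many elements as observed.
    """
    set_a, set_b = set(set_a), set(set_b)
    if len(set_a) > universe or len(set_b) > universe:
        raise ValueError("universe smaller than one of the sets")
    k = len(set_a & set_b)
    # sf(k-1) = P[X >= k]
    return float(hypergeom.sf(k - 1, universe, len(set_a), len(set_b)))


def link_phenotypes(
    side_results: dict,
    universe_size: int,
    significance_level: float = 0.05,
) -> list[PhenotypeResult]:
    """Overlap-test every phenotype and BH-correct across the family.

    ``side_results`` maps ``(adr_id, dp_id)`` to a pair of
    :class:`~dreamer.diffusion.SignificanceResult` (ADR side, DP side); a
    phenotype with a missing side is skipped.  Phenotypes whose adjusted
    overlap p-value is below the level keep their intersection as the
    ADR-DP protein set; the rest get an empty set.
    """
    pairs, raw = [], []
    for (adr_id, dp_id) in sorted(side_results):
        adr_res, dp_res = side_results[(adr_id, dp_id)]
        if adr_res is None or dp_res is None:
            continue
        a, b = adr_res.significant, dp_res.significant
        raw.append(hypergeometric_overlap(a, b, universe_size))
        pairs.append((adr_id, dp_id, a, b))
    adj = bh_adjust(raw)
    results = []
    for (adr_id, dp_id, a, b), p_raw, p_adj in zip(pairs, raw, adj):
        keep = p_adj < significance_level
        results.append(
            PhenotypeResult(
                adr_id=adr_id,
                dp_id=dp_id,
                adr_proteins=a,
                dp_proteins=b,
                overlap_p_raw=float(p_raw),
                overlap_p_adj=float(p_adj),
                adr_dp_proteins=(a & b) if keep else set(),
                universe_size=universe_size,
            )
        )
    return results


def phenotypes_table(results: list[PhenotypeResult]) -> pd.DataFrame:
    """Flat per-phenotype summary table (one row per ADR–DP pair)."""
    return pd.DataFrame(
        [
            {
                "adr_id": r.adr_id,
                "dp_id": r.dp_id,
                "n_adr": len(r.adr_proteins),
                "n_dp": len(r.dp_proteins),
                "n_overlap": len(r.adr_proteins & r.dp_proteins),
                "p_raw": r.overlap_p_raw,
                "p_adj": r.overlap_p_adj,
                "retained": r.retained,
            }
            for r in results
        ]
    )


def export_diffusion_map(
    kg: KnowledgeGraph,
    result: PhenotypeResult,
    adr_profile: DiffusionProfile | SignificanceResult,
    dp_profile: DiffusionProfile | SignificanceResult,
) -> pd.DataFrame:
    """Per-protein scatter table: ADR score vs DP score.

    Each protein is classed by its bipartite links to the phenotype's assets
    — ``drug-target``, ``disease-protein``, ``both`` or ``neither`` — and
    flagged when it belongs to the final ADR-DP set.  Plot x against y to
    reproduce the two-dimensional diffusion map.
    """
    adr_scores = _scores_of(adr_profile)
    dp_scores = _scores_of(dp_profile)
    if set(adr_scores) != set(dp_scores):
        raise ValueError("ADR and DP profiles cover different protein universes")
    drug_targets = set()
    for d in kg.drugs_of_adr(result.adr_id):
        drug_targets |= kg.targets_of_drug(d)
    disease_proteins = set()
    for d in kg.diseases_of_dp(result.dp_id):
        disease_proteins |= kg.proteins_of_disease(d)

    rows = []
    for p in sorted(adr_scores):
        is_t, is_d = p in drug_targets, p in disease_proteins
        klass = ("both" if is_t and is_d
                 else "drug-target" if is_t
                 else "disease-protein" if is_d
                 else "neither")
        rows.append(
            {
                "protein": p,
                "adr_score": adr_scores[p],
                "dp_score": dp_scores[p],
                "class": klass,
                "adr_dp_member": p in result.adr_dp_proteins,
            }
        )
    return pd.DataFrame(rows)


def _scores_of(profile) -> dict:
    if isinstance(profile, SignificanceResult):
        return dict(zip(profile.table.index, profile.table["score"]))
    return profile.scores
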