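"""Indication-confounder analyses.

Two screens guard against the possibility that a phenotype's protein set
reflects what its drugs *treat* rather than the reaction they cause:

1. organ/tissue filter — drop drugs whose indication affects the same
   organ/tissue as the ADR, rerun the identification, and test whether the
   new protein set still overlaps the original one (robustness);
2. indication diffusion — diffuse from the proteins associated with the
   indications of the phenotype's drugs and test whether the resulting
   significant proteins overlap the ADR-DP set (confounding).

A phenotype is "clean" when it survives both screens.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import pandas as pd

from .diffusion import (
    DiffusionConfig,
    EmptySeedError,
    SignificanceResult,
    TransitionOperator,
    seed_from_links,
    significant_proteins,
)
from .kg import KnowledgeGraph
from .linking import PhenotypeResult, hypergeometric_overlap
from .diffusion import bh_adjust
from .pipeline import PipelineResult, derive_seed, run_dreamer

__all__ = [
    "ConfounderReport",
    "organ_filter_drugs",
    "robustness_retest",
    "indication_diffusion",
    "screen_confounded",
    "export_diffusion_map_3d",
]


@dataclass
class ConfounderReport:
    """Both confounder screens for one phenotype."""

    adr_id: str
    dp_id: str
    # organ/tissue screen
    n_drugs_before: int = 0
    n_drugs_after: int = 0
    organ_testable: bool = False
    proteins_before: set | None = None
    proteins_after: set | None = None
    robustness_p: float | None = None
    robust: bool | None = None
    # indication screen
    indication_testable: bool = False
    indication_proteins: set | None = None
    indication_result: SignificanceResult | None = None
    indication_overlap_p_raw: float | None = None
    indication_overlap_p_adj: float | None = None
    confounded: bool | None = None

    @property
    def clean(self) -> bool:
        """Survives every screen that could be run."""
        if self.organ_testable and self.robust is False:
            return False
        if self.indication_testable and self.confounded:
            return False
        return True


def organ_filter_drugs(
    kg: KnowledgeGraph,
    adr_id: str,
    keep_unannotated: bool = True,
) -> list:
    """Drugs of the ADR whose indication organs avoid the ADR's organs.

    Requires organ annotations on the graph (``adr_organs`` for the ADR,
    ``drug_organs`` for drug indications).  Drugs without an annotation are
    kept by default; set ``keep_unannotated=False`` to restrict the analysis
    to annotated drugs only.
    """
    adr_organs = kg.adr_organs.get(adr_id, frozenset())
    kept = []
    for drug in sorted(kg.drugs_of_adr(adr_id)):
        organs = kg.drug_organs.get(drug)
        if organs is None:
            if keep_unannotated:
                kept.append(drug)
            continue
        if not (organs & adr_organs):
            kept.append(drug)
    return kept


def robustness_retest(
    kg: KnowledgeGraph,
    result: PhenotypeResult,
    filtered_drugs,
    config: DiffusionConfig | None = None,
    operator: TransitionOperator | None = None,
) -> tuple[float | None, set]:
    """Re-identify the phenotype's proteins from the filtered drug list.

    Returns ``(overlap p-value, new ADR-DP set)``; the p-value is the
    hypergeometric upper tail of the overlap between the original and the
    re-identified set over the PPI universe, or ``None`` when the phenotype
    is untestable (no drugs left, or an empty seed).
    """
    config = config or DiffusionConfig()
    filtered_drugs = set(filtered_drugs)
    if not filtered_drugs:
        return None, set()
    op = operator or TransitionOperator(kg.ppi, weighted=config.weighted)
    sub = run_dreamer(
        kg,
        config=config,
        drug_subsets={result.adr_id: filtered_drugs},
    )
    new = sub.result_for(result.adr_id, result.dp_id)
    new_set = new.adr_dp_proteins if new is not None else set()
    if not result.adr_dp_proteins and not new_set:
        return None, new_set
    p = hypergeometric_overlap(result.adr_dp_proteins, new_set, op.n)
    return p, new_set


def indication_diffusion(
    kg: KnowledgeGraph,
    adr_id: str,
    config: DiffusionConfig | None = None,
    operator: TransitionOperator | None = None,
    per_drug: bool = True,
) -> SignificanceResult | None:
    """Diffuse from the proteins of the indications of the ADR's drugs.

    The seed weighs each protein by its link frequency with the indication
    diseases, and — when ``per_drug`` — duplicates an indication's links once
    per drug that carries it, so indications shared by many of the
    phenotype's drugs dominate the seed.  Returns ``None`` when no drug has
    an indication with associated proteins.
    """
    config = config or DiffusionConfig()
    links = []
    for drug in sorted(kg.drugs_of_adr(adr_id)):
        for indication in sorted(kg.indications_of_drug(drug)):
            ind_links = [
                (indication, p) for p in sorted(kg.proteins_of_disease(indication))
            ]
            if per_drug:
                links.extend(ind_links)
            else:
                for lk in ind_links:
                    if lk not in links:
                        links.append(lk)
    if not links:
        return None
    seed = seed_from_links(links, provenance=f"indication:{adr_id}")
    try:
        return significant_proteins(
            kg,
            adr_id,
            side="adr",
            config=config,
            seed=seed,
            operator=operator,
        )
    except EmptySeedError:
        return None


def screen_confounded(
    kg: KnowledgeGraph,
    pipeline_result: PipelineResult,
    config: DiffusionConfig | None = None,
    keep_unannotated: bool = True,
) -> list[ConfounderReport]:
    """Run both confounder screens on every retained phenotype.

    The indication-overlap p-values are BH-corrected across the screened
    phenotypes; ``confounded`` means the adjusted p is below the
    significance level.  The organ screen compares protein sets before and
    after removing organ-matched drugs (plain hypergeometric test, per
    phenotype).
    """
    config = config or DiffusionConfig()
    op = TransitionOperator(kg.ppi, weighted=config.weighted)
    reports: list[ConfounderReport] = []
    for res in pipeline_result.retained:
        rep = ConfounderReport(adr_id=res.adr_id, dp_id=res.dp_id)
        drugs = kg.drugs_of_adr(res.adr_id)
        rep.n_drugs_before = len(drugs)
        rep.proteins_before = set(res.adr_dp_proteins)

        # --- screen 1: organ/tissue-matched drug removal
        kept = organ_filter_drugs(kg, res.adr_id, keep_unannotated)
        rep.n_drugs_after = len(kept)
        if kept:
            child = replace(
                config,
                rng_seed=derive_seed(config.rng_seed, res.adr_id, "organ"),
            )
            p, new_set = robustness_retest(kg, res, kept, child, operator=op)
            rep.proteins_after = new_set
            rep.robustness_p = p
            if p is not None:
                rep.organ_testable = True
                rep.robust = bool(p < config.significance_level)

        # --- screen 2: indication-seeded diffusion
        child = replace(
            config,
            rng_seed=derive_seed(config.rng_seed, res.adr_id, "indication"),
        )
        ind = indication_diffusion(kg, res.adr_id, child, operator=op)
        if ind is not None:
            rep.indication_testable = True
            rep.indication_proteins = ind.significant
            rep.indication_result = ind
            rep.indication_overlap_p_raw = hypergeometric_overlap(
                ind.significant, res.adr_dp_proteins, op.n
            )
        reports.append(rep)

    # BH across the phenotypes that could be screened for indication overlap
    screened = [r for r in reports if r.indication_overlap_p_raw is not None]
    if screened:
        adj = bh_adjust([r.indication_overlap_p_raw for r in screened])
        for rep, p_adj in zip(screened, adj):
            rep.indication_overlap_p_adj = float(p_adj)
            rep.confounded = bool(p_adj < config.significance_level)
    return reports


def confounders_table(reports: list[ConfounderReport]) -> pd.DataFrame:
    """Flat TSV-ready summary, one row per screened phenotype."""
    return pd.DataFrame(
        [
            {
                "adr_id": r.adr_id,
                "dp_id": r.dp_id,
                "n_drugs_before": r.n_drugs_before,
                "n_drugs_after": r.n_drugs_after,
                "robustness_p": r.robustness_p,
                "robust": r.robust,
                "indication_p_raw": r.indication_overlap_p_raw,
                "indication_p_adj": r.indication_overlap_p_adj,
                "confounded": r.confounded,
                "clean": r.clean,
            }
            for r in reports
        ]
    )


def export_diffusion_map_3d(
    kg: KnowledgeGraph,
    result: PhenotypeResult,
    adr_result: SignificanceResult,
    dp_result: SignificanceResult,
    indication_result: SignificanceResult,
) -> pd.DataFrame:
    """Three-dimensional diffusion map table: x=ADR, y=DP, z=indication.

    ADR-DP proteins sitting high on z are candidates for reverse causality —
    the reaction may be downstream of what the drugs treat.
    """
    from .linking import export_diffusion_map

    df = export_diffusion_map(kg, result, adr_result, dp_result)
    z = dict(zip(indication_result.table.index, indication_result.table["score"]))
    if set(df["protein"]) != set(z):
        raise ValueError("indication profile covers a different protein universe")
    df = df.rename(columns={"adr_score": "x", "dp_score": "y"})
    df["z"] = df["protein"].map(z)
    return df[["protein", "x", "y", "z", "class", "adr_dp_member"]]
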