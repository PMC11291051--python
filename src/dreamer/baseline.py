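"""Significant-overlap-association baseline: no diffusion, bipartite links only.

A protein is assigned to an ADR when the set of drugs targeting it overlaps
the ADR's drug set more than chance allows (hypergeometric upper tail over
the drug universe), BH-corrected over proteins; symmetrically for DPs with
diseases.  Serves as the comparison method for the diffusion pipeline — it
can only ever recover proteins directly linked to the phenotype's assets.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .diffusion import bh_adjust
from .kg import KnowledgeGraph
from .linking import hypergeometric_overlap

__all__ = ["baseline_proteins"]


def baseline_proteins(
    kg: KnowledgeGraph,
    phenotype_id: str,
    side: str,
    significance_level: float = 0.05,
) -> pd.DataFrame:
    """Per-protein overlap test between asset sets; returns the full table.

    Universe = assets with at least one protein link (others are pruned at
    build time and never observable).  Columns: ``n_asset_links``,
    ``n_overlap``, ``p_raw``, ``p_adj``, ``significant``.
    """
    if side == "adr":
        pheno_assets = kg.drugs_of_adr(phenotype_id)
        asset_of = kg.drugs_of_protein
        universe = {d for d, _ in kg.drug_target}
    elif side == "dp":
        pheno_assets = kg.diseases_of_dp(phenotype_id)
        asset_of = kg.diseases_of_protein
        universe = {d for d, _ in kg.disease_protein}
    else:
        raise ValueError(f"side must be 'adr' or 'dp', got {side!r}")

    proteins = sorted(kg.proteins)
    raw = np.ones(len(proteins))
    n_links = np.zeros(len(proteins), dtype=int)
    n_overlap = np.zeros(len(proteins), dtype=int)
    for i, p in enumerate(proteins):
        assets = asset_of(p)
        n_links[i] = len(assets)
        n_overlap[i] = len(assets & pheno_assets)
        if assets and pheno_assets:
            raw[i] = hypergeometric_overlap(assets, pheno_assets, len(universe))
    adj = bh_adjust(raw)
    return pd.DataFrame(
        {
            "n_asset_links": n_links,
            "n_overlap": n_overlap,
            "p_raw": raw,
            "p_adj": adj,
            "significant": adj < significance_level,
        },
        index=pd.Index(proteins, name="protein"),
    )
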