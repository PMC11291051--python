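"""End-to-end orchestration: every phenotype, both sides, then linking."""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .diffusion import (
    DiffusionConfig,
    EmptySeedError,
    TransitionOperator,
    significant_proteins,
)
from .kg import KnowledgeGraph
from .linking import PhenotypeResult, link_phenotypes

__all__ = ["PipelineResult", "derive_seed", "run_dreamer"]


def derive_seed(master: int, *key) -> int:
    """Deterministic child seed (< 2**31) for a named pipeline stage."""
    entropy = [int(master)] + [
        k if isinstance(k, int) else int.from_bytes(str(k).encode(), "little") % (2**32)
        for k in key
    ]
    return int(np.random.SeedSequence(entropy).generate_state(1)[0] % (2**31))


@dataclass
class PipelineResult:
    """Everything one full run produces."""

    phenotypes: list[PhenotypeResult]
    side_results: dict
    universe_size: int

    @property
    def retained(self) -> list[PhenotypeResult]:
        return [r for r in self.phenotypes if r.retained]

    def result_for(self, adr_id: str, dp_id: str) -> PhenotypeResult | None:
        for r in self.phenotypes:
            if r.adr_id == adr_id and r.dp_id == dp_id:
                return r
        return None


def run_dreamer(
    kg: KnowledgeGraph,
    config: DiffusionConfig | None = None,
    drug_subsets: dict | None = None,
    disease_subsets: dict | None = None,
) -> PipelineResult:
    """Run diffusion + significance on both sides of every ADR–DP pair.

    ``drug_subsets`` / ``disease_subsets`` optionally restrict the asset
    lists per ADR / DP id (holdout discovery runs, organ-filtered reruns).
    Phenotypes whose restricted side has no protein-linked assets are
    skipped.  Per-phenotype, per-side RNG streams are derived from
    ``config.rng_seed`` so the whole run is reproducible from one integer.
    """
    config = config or DiffusionConfig()
    op = TransitionOperator(kg.ppi, weighted=config.weighted)
    side_results: dict = {}
    for adr_id, dp_id in kg.phenotype_pairs():
        entry = []
        for side, pid, subsets in (
            ("adr", adr_id, drug_subsets),
            ("dp", dp_id, disease_subsets),
        ):
            assets = None if subsets is None else subsets.get(pid)
            child = replace(
                config, rng_seed=derive_seed(config.rng_seed, pid, side)
            )
            try:
                res = significant_proteins(
                    kg, pid, side, config=child, assets=assets, operator=op
                )
            except EmptySeedError:
                res = None
            entry.append(res)
        if entry[0] is not None and entry[1] is not None:
            side_results[(adr_id, dp_id)] = tuple(entry)
    phenotypes = link_phenotypes(
        side_results, universe_size=op.n,
        significance_level=config.significance_level,
    )
    return PipelineResult(
        phenotypes=phenotypes, side_results=side_results, universe_size=op.n
    )
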