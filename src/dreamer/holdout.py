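"""Holdout validation: are unseen assets network-close to identified proteins?

Assets (drugs on the ADR side, diseases on the DP side) are split into a
discovery and a validation fraction.  The pipeline identifies the phenotype's
protein set from the discovery assets only; held-out positives and an equal
number of randomly drawn non-associated negatives are then compared by their
shortest-path distance to the identified set.  Pooling across phenotypes, a
one-sided Fisher exact test asks, for each hop threshold X, whether positives
reach the set within X hops more often than negatives.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from .diffusion import DiffusionConfig
from .kg import KnowledgeGraph
from .pipeline import derive_seed, run_dreamer

__all__ = [
    "HoldoutConfig",
    "HoldoutReport",
    "split_assets",
    "asset_distance",
    "set_distances",
    "holdout_fisher",
    "run_holdout",
]


@dataclass(frozen=True)
class HoldoutConfig:
    """Split fraction, hop thresholds and the RNG seed for the holdout."""

    discovery_fraction: float = 0.8
    thresholds: tuple = (0, 1, 2, 3, 4, 5, 6)
    rng_seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.discovery_fraction < 1.0:
            raise ValueError("discovery_fraction must lie strictly in (0, 1)")
        if list(self.thresholds) != sorted(set(self.thresholds)) or any(
            x < 0 for x in self.thresholds
        ):
            raise ValueError("thresholds must be sorted, unique, non-negative")


@dataclass
class HoldoutReport:
    """Pooled 2x2 tables and Fisher p-values per side and threshold.

    ``table`` columns: side, X, pos_le, pos_gt, neg_le, neg_gt, fisher_p.
    """

    table: pd.DataFrame
    n_phenotypes: int
    rng_seed: int

    def p_at(self, side: str, x: int) -> float:
        sel = self.table[(self.table["side"] == side) & (self.table["X"] == x)]
        if sel.empty:
            raise KeyError(f"no row for side={side!r}, X={x}")
        return float(sel["fisher_p"].iloc[0])


def split_assets(
    kg: KnowledgeGraph,
    phenotype_id: str,
    side: str,
    config: HoldoutConfig | None = None,
    rng: np.random.Generator | None = None,
):
    """Uniform discovery/validation split plus matched negative sampling.

    Returns ``(discovery, validation, negatives)`` as sorted lists.  The
    discovery size is ``round(fraction * n)``, clipped so both halves are
    non-empty.  Negatives are drawn uniformly, without replacement, from
    same-type assets not associated with the phenotype, matching the
    validation count.
    """
    config = config or HoldoutConfig()
    if rng is None:
        rng = np.random.default_rng(
            derive_seed(config.rng_seed, phenotype_id, side, "split")
        )
    if side == "adr":
        assets = sorted(kg.drugs_of_adr(phenotype_id))
        pool = sorted({d for d, _ in kg.drug_target})
    elif side == "dp":
        assets = sorted(kg.diseases_of_dp(phenotype_id))
        pool = sorted({d for d, _ in kg.disease_protein})
    else:
        raise ValueError(f"side must be 'adr' or 'dp', got {side!r}")
    if len(assets) < 2:
        raise ValueError(
            f"{phenotype_id}: needs at least 2 assets on side {side!r} to split"
        )
    n = len(assets)
    n_disc = int(round(config.discovery_fraction * n))
    n_disc = min(max(n_disc, 1), n - 1)
    perm = rng.permutation(n)
    discovery = sorted(assets[i] for i in perm[:n_disc])
    validation = sorted(assets[i] for i in perm[n_disc:])
    negatives_pool = sorted(set(pool) - set(assets))
    if len(negatives_pool) < len(validation):
        raise ValueError(
            f"{phenotype_id}: only {len(negatives_pool)} non-associated assets "
            f"available, need {len(validation)} negatives"
        )
    idx = rng.choice(len(negatives_pool), size=len(validation), replace=False)
    negatives = sorted(negatives_pool[i] for i in idx)
    return discovery, validation, negatives


def set_distances(kg: KnowledgeGraph, protein_set) -> dict:
    """Multi-source BFS hop distance from ``protein_set`` to every PPI node."""
    dist: dict = {}
    queue: deque = deque()
    for p in protein_set:
        if p in kg.ppi:
            dist[p] = 0
            queue.append(p)
    while queue:
        u = queue.popleft()
        for v in kg.ppi.neighbors(u):
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def asset_distance(
    kg: KnowledgeGraph,
    protein_set,
    asset: str,
    side: str,
    dist: dict | None = None,
) -> float:
    """Hops from an asset's closest associated protein to the identified set.

    0 when one of the asset's proteins is itself in the set; ``inf`` when
    every associated protein is disconnected from it.
    """
    proteins = (
        kg.targets_of_drug(asset) if side == "adr" else kg.proteins_of_disease(asset)
    )
    if not proteins:
        raise ValueError(f"asset {asset!r} has no associated proteins")
    if dist is None:
        dist = set_distances(kg, protein_set)
    in_set = set(protein_set)
    best = math.inf
    for p in proteins:
        if p in in_set:
            return 0.0
        best = min(best, dist.get(p, math.inf))
    return best


def holdout_fisher(
    pos_distances,
    neg_distances,
    thresholds,
    side: str,
    n_phenotypes: int = 0,
    rng_seed: int = 0,
) -> HoldoutReport:
    """Pooled one-sided Fisher tests over the given hop thresholds.

    ``pos_distances`` / ``neg_distances`` are the pooled per-asset distances
    across all phenotypes.  For each X the 2x2 table is
    ``[[pos<=X, pos>X], [neg<=X, neg>X]]`` and the alternative is that
    positives are enriched below the threshold.
    """
    pos = np.asarray(list(pos_distances), dtype=float)
    neg = np.asarray(list(neg_distances), dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("pooled positive and negative sets must be non-empty")
    rows = []
    for x in thresholds:
        a = int((pos <= x).sum())
        b = int(pos.size - a)
        c = int((neg <= x).sum())
        d = int(neg.size - c)
        _, p = fisher_exact([[a, b], [c, d]], alternative="greater")
        rows.append(
            {"side": side, "X": x, "pos_le": a, "pos_gt": b,
             "neg_le": c, "neg_gt": d, "fisher_p": float(p)}
        )
    return HoldoutReport(
        table=pd.DataFrame(rows), n_phenotypes=n_phenotypes, rng_seed=rng_seed
    )


def run_holdout(
    kg: KnowledgeGraph,
    side: str,
    holdout_config: HoldoutConfig | None = None,
    diffusion_config: DiffusionConfig | None = None,
) -> HoldoutReport:
    """Full holdout experiment for one side, pooled across phenotypes.

    For each ADR–DP pair the side's assets are split; the pipeline runs with
    the discovery subset (the other side keeps all assets); distances of
    validation positives and matched negatives to the resulting ADR-DP
    protein set are pooled.  Phenotypes that cannot be split or that yield an
    empty identified set still contribute their assets (at infinite
    distance), keeping the test honest about failures.
    """
    holdout_config = holdout_config or HoldoutConfig()
    diffusion_config = diffusion_config or DiffusionConfig()
    subsets: dict = {}
    held: dict = {}
    for adr_id, dp_id in kg.phenotype_pairs():
        pid = adr_id if side == "adr" else dp_id
        try:
            disc, valid, neg = split_assets(kg, pid, side, holdout_config)
        except ValueError:
            continue
        subsets[pid] = set(disc)
        held[(adr_id, dp_id)] = (valid, neg)
    if not held:
        raise ValueError("no phenotype could be split on side " + repr(side))

    result = run_dreamer(
        kg,
        config=diffusion_config,
        drug_subsets=subsets if side == "adr" else None,
        disease_subsets=subsets if side == "dp" else None,
    )
    pos_pool, neg_pool = [], []
    for (adr_id, dp_id), (valid, neg) in sorted(held.items()):
        res = result.result_for(adr_id, dp_id)
        identified = res.adr_dp_proteins if res is not None else set()
        dist = set_distances(kg, identified)
        for asset in valid:
            pos_pool.append(asset_distance(kg, identified, asset, side, dist))
        for asset in neg:
            neg_pool.append(asset_distance(kg, identified, asset, side, dist))
    return holdout_fisher(
        pos_pool,
        neg_pool,
        holdout_config.thresholds,
        side,
        n_phenotypes=len(held),
        rng_seed=holdout_config.rng_seed,
    )
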