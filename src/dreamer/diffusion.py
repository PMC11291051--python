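"""Personalized-PageRank diffusion with a permutation null model.

For one phenotype side (ADR or DP) the workflow is: build a seed
probability vector from link frequencies, diffuse it over the PPI with the
damped iteration ``P_{t+1} = alpha * A * P_t + (1 - alpha) * P0``, draw a
null ensemble by reassigning the seed values uniformly over proteins, fit an
exponential to each protein's null scores, and correct the resulting
one-sided tail p-values across all PPI proteins with Benjamini–Hochberg.

``A`` is the column-stochastic transition operator of the (by default
unweighted) filtered PPI; zero-degree proteins receive a self-loop so mass
is conserved and the iteration converges geometrically at rate ``alpha``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp
from statsmodels.stats.multitest import multipletests

from .kg import KnowledgeGraph

__all__ = [
    "SeedVector",
    "DiffusionConfig",
    "DiffusionProfile",
    "SignificanceResult",
    "EmptySeedError",
    "build_seed_vector",
    "seed_from_links",
    "TransitionOperator",
    "personalized_pagerank",
    "permutation_null",
    "exponential_tail_pvalue",
    "bh_adjust",
    "significant_proteins",
]


class EmptySeedError(ValueError):
    """A phenotype has no protein-linked assets to seed from."""


class ConvergenceError(RuntimeError):
    """Power iteration failed to reach the tolerance; carries last iterate."""

    def __init__(self, msg, last_iterate):
        super().__init__(msg)
        self.last_iterate = last_iterate


@dataclass(frozen=True)
class DiffusionConfig:
    """Parameters of one diffusion + significance run.

    ``alpha`` is the damping factor (fraction of mass that keeps walking
    each step; ``1 - alpha`` restarts at the seed).  ``n_permutations`` is
    the size K of the null ensemble.  ``permute_scope`` controls whether the
    seed's values are reassigned over *all* PPI proteins (default) or only
    shuffled among the originally seeded proteins.
    """

    alpha: float = 0.7
    tol: float = 1e-10
    max_iter: int = 10_000
    n_permutations: int = 1000
    rng_seed: int = 0
    significance_level: float = 0.05
    weighted: bool = False
    permute_scope: str = "all"

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie strictly between 0 and 1")
        if self.n_permutations < 2:
            raise ValueError("need at least 2 permutations")
        if self.permute_scope not in ("all", "seeded"):
            raise ValueError("permute_scope must be 'all' or 'seeded'")


@dataclass
class SeedVector:
    """Protein -> restart probability, summing to one."""

    scores: dict
    provenance: str = ""

    def validate(self) -> None:
        vals = np.array(list(self.scores.values()), dtype=float)
        if vals.size == 0:
            raise EmptySeedError(f"empty seed vector ({self.provenance})")
        if (vals < 0).any():
            raise ValueError("seed probabilities must be non-negative")
        if abs(vals.sum() - 1.0) > 1e-9:
            raise ValueError(f"seed must sum to 1, got {vals.sum()!r}")


@dataclass
class DiffusionProfile:
    """Stationary diffusion scores for one seed."""

    scores: dict
    iterations_used: int
    converged: bool
    provenance: str = ""

    def as_array(self, nodes) -> np.ndarray:
        return np.array([self.scores.get(p, 0.0) for p in nodes])


@dataclass
class SignificanceResult:
    """Per-protein significance table for one phenotype side.

    ``table`` is indexed by protein with columns ``seed_prob``, ``score``,
    ``null_mean``, ``p_raw``, ``p_adj`` and ``significant``.
    """

    phenotype_id: str
    side: str
    table: pd.DataFrame
    n_permutations: int
    rng_seed: int
    iterations_used: int = 0
    converged: bool = True
    seed: SeedVector | None = None
    profile: DiffusionProfile | None = None

    @property
    def significant(self) -> set:
        return set(self.table.index[self.table["significant"]])


# ------------------------------------------------------------------- seeds

def seed_from_links(links, provenance: str = "") -> SeedVector:
    """Seed vector from a collection of (asset, protein) link tuples.

    Each link contributes one count to its protein, so a protein linked by
    two assets weighs twice as much as one linked by a single asset.
    """
    links = list(links)
    if not links:
        raise EmptySeedError(f"no asset-protein links ({provenance})")
    counts: dict = {}
    for _, p in links:
        counts[p] = counts.get(p, 0) + 1
    total = float(len(links))
    return SeedVector(
        scores={p: c / total for p, c in sorted(counts.items())},
        provenance=provenance,
    )


def build_seed_vector(
    kg: KnowledgeGraph,
    phenotype_id: str,
    side: str,
    assets: set | None = None,
) -> SeedVector:
    """Link-frequency seed for an ADR (over drug targets) or DP (over
    disease proteins).

    ``phenotype_id`` is the ADR id when ``side == "adr"`` and the DP id when
    ``side == "dp"``.  ``assets`` optionally restricts the drug/disease list
    (used by the holdout and confounder analyses).
    """
    if side == "adr":
        all_assets = kg.drugs_of_adr(phenotype_id)
        link_source = kg.drug_target
    elif side == "dp":
        all_assets = kg.diseases_of_dp(phenotype_id)
        link_source = kg.disease_protein
    else:
        raise ValueError(f"side must be 'adr' or 'dp', got {side!r}")
    if assets is not None:
        all_assets = all_assets & set(assets)
    links = [(a, p) for a, p in link_source if a in all_assets]
    return seed_from_links(links, provenance=f"{side}:{phenotype_id}")


# ---------------------------------------------------------------- operator

class TransitionOperator:
    """Column-stochastic transition matrix of the PPI with fixed node order.

    Built once per graph and reused across the observed run and the whole
    permutation ensemble.  Zero-degree nodes get a unit self-loop.
    """

    def __init__(self, ppi: nx.Graph, weighted: bool = False):
        if ppi.number_of_nodes() == 0:
            raise ValueError("PPI is empty; nothing to diffuse on")
        self.nodes = sorted(ppi.nodes)
        self.index = {p: i for i, p in enumerate(self.nodes)}
        n = len(self.nodes)
        rows, cols, vals = [], [], []
        for u, v, data in ppi.edges(data=True):
            w = data.get("confidence", 1.0) / 1000.0 if weighted else 1.0
            i, j = self.index[u], self.index[v]
            rows += [i, j]
            cols += [j, i]
            vals += [w, w]
        A = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
        colsum = np.asarray(A.sum(axis=0)).ravel()
        dangling = colsum == 0
        if dangling.any():
            idx = np.flatnonzero(dangling)
            A = A + sp.csr_matrix(
                (np.ones(idx.size), (idx, idx)), shape=(n, n)
            )
            colsum[idx] = 1.0
        self.matrix = (A @ sp.diags(1.0 / colsum)).tocsr()
        self.n = n

    def seed_array(self, seed: SeedVector, strict: bool = True) -> np.ndarray:
        """Dense seed over the node order; off-network mass is dropped."""
        seed.validate()
        p0 = np.zeros(self.n)
        off = 0.0
        for p, v in seed.scores.items():
            i = self.index.get(p)
            if i is None:
                off += v
            else:
                p0[i] += v
        if off > 0:
            if off >= 1.0 - 1e-12:
                raise EmptySeedError(
                    f"seed {seed.provenance!r} lies entirely off the PPI"
                )
            warnings.warn(
                f"seed {seed.provenance!r}: {off:.3g} of the seed mass is on "
                "proteins absent from the PPI and is dropped", stacklevel=3
            )
        return p0

    def propagate(self, P0: np.ndarray, config: DiffusionConfig):
        """Damped power iteration; ``P0`` may hold many seeds as columns.

        Returns ``(P, iterations, converged)`` where convergence means the
        worst-column L1 change fell below ``config.tol``.
        """
        alpha, A = config.alpha, self.matrix
        P = P0.copy()
        restart = (1.0 - alpha) * P0
        for it in range(1, config.max_iter + 1):
            P_next = alpha * (A @ P) + restart
            delta = np.abs(P_next - P)
            change = delta.sum(axis=0).max() if P.ndim == 2 else delta.sum()
            P = P_next
            if change < config.tol:
                return P, it, True
        return P, config.max_iter, False


# -------------------------------------------------------------- operations

def personalized_pagerank(
    ppi: nx.Graph | TransitionOperator,
    seed: SeedVector,
    config: DiffusionConfig | None = None,
) -> DiffusionProfile:
    """Fixed point of ``P = alpha*A*P + (1-alpha)*P0`` for one seed."""
    config = config or DiffusionConfig()
    op = ppi if isinstance(ppi, TransitionOperator) else TransitionOperator(
        ppi, weighted=config.weighted
    )
    p0 = op.seed_array(seed)
    scores, its, converged = op.propagate(p0, config)
    profile = DiffusionProfile(
        scores=dict(zip(op.nodes, scores.tolist())),
        iterations_used=its,
        converged=converged,
        provenance=seed.provenance,
    )
    if not converged:
        raise ConvergenceError(
            f"PPR did not reach tol={config.tol} in {config.max_iter} "
            f"iterations ({seed.provenance})",
            profile,
        )
    return profile


def permutation_null(
    ppi: nx.Graph | TransitionOperator,
    seed: SeedVector,
    config: DiffusionConfig | None = None,
) -> tuple[np.ndarray, list]:
    """Null diffusion ensemble from randomly reassigned seed values.

    Returns ``(null_scores, nodes)`` with ``null_scores`` of shape
    ``(K, n_proteins)``: row k is the diffusion profile of the seed's value
    multiset placed uniformly at random over the PPI proteins (or shuffled
    within the seeded support when ``permute_scope == "seeded"``).
    """
    config = config or DiffusionConfig()
    op = ppi if isinstance(ppi, TransitionOperator) else TransitionOperator(
        ppi, weighted=config.weighted
    )
    p0 = op.seed_array(seed)
    rng = np.random.default_rng(np.random.SeedSequence(config.rng_seed))
    K = config.n_permutations
    P0s = np.empty((op.n, K))
    if config.permute_scope == "seeded":
        support = np.flatnonzero(p0)
        for k in range(K):
            col = p0.copy()
            col[support] = p0[support][rng.permutation(support.size)]
            P0s[:, k] = col
    else:
        for k in range(K):
            P0s[:, k] = p0[rng.permutation(op.n)]
    null, its, converged = op.propagate(P0s, config)
    if not converged:
        raise ConvergenceError(
            f"null ensemble did not converge in {config.max_iter} iterations",
            null,
        )
    return null.T, op.nodes


def exponential_tail_pvalue(observed, null_samples) -> float | np.ndarray:
    """One-sided (greater) tail probability from an exponential null fit.

    The rate is the maximum-likelihood estimate ``1 / mean(null)``, giving
    ``p = exp(-observed / mean(null))``.  Broadcasts: ``observed`` may be a
    vector with ``null_samples`` of shape ``(K, n)``.

    Degenerate all-zero nulls yield p = 1 for a zero observation and a
    floored value ``1 / (K + 1)`` (with a warning) otherwise.
    """
    observed = np.asarray(observed, dtype=float)
    null = np.asarray(null_samples, dtype=float)
    if null.size == 0:
        raise ValueError("null_samples must be non-empty")
    if (null < 0).any():
        raise ValueError("null samples must be non-negative")
    mean = null.mean(axis=0)
    K = null.shape[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.exp(-observed / mean)
    zero_null = mean == 0
    if np.any(zero_null):
        floor = 1.0 / (K + 1)
        p = np.where(zero_null & (observed > 0), floor, p)
        p = np.where(zero_null & (observed == 0), 1.0, p)
        if np.any(zero_null & (observed > 0)):
            warnings.warn(
                "all-zero null for a protein with positive score; "
                f"p-value floored at {floor:.3g}", stacklevel=2
            )
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return float(p) if p.ndim == 0 else p


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (capped at 1)."""
    pvalues = np.asarray(pvalues, dtype=float)
    if pvalues.size == 0:
        return pvalues
    return multipletests(pvalues, method="fdr_bh")[1]


def significant_proteins(
    kg: KnowledgeGraph,
    phenotype_id: str,
    side: str,
    config: DiffusionConfig | None = None,
    assets: set | None = None,
    seed: SeedVector | None = None,
    operator: TransitionOperator | None = None,
) -> SignificanceResult:
    """Full one-side pipeline: seed → PPR → permutation null → BH.

    The observed profile and the K null profiles are propagated in a single
    batched power iteration.  BH is applied over all PPI proteins; a protein
    is significant when its adjusted p-value is below
    ``config.significance_level``.
    """
    config = config or DiffusionConfig()
    if config.n_permutations < 100:
        warnings.warn(
            f"K={config.n_permutations} permutations is low; p-values will "
            "be noisy", stacklevel=2
        )
    if seed is None:
        seed = build_seed_vector(kg, phenotype_id, side, assets=assets)
    op = operator or TransitionOperator(kg.ppi, weighted=config.weighted)
    p0 = op.seed_array(seed)

    rng = np.random.default_rng(np.random.SeedSequence(config.rng_seed))
    K = config.n_permutations
    batch = np.empty((op.n, K + 1))
    batch[:, 0] = p0
    if config.permute_scope == "seeded":
        support = np.flatnonzero(p0)
        for k in range(K):
            col = p0.copy()
            col[support] = p0[support][rng.permutation(support.size)]
            batch[:, k + 1] = col
    else:
        for k in range(K):
            batch[:, k + 1] = p0[rng.permutation(op.n)]

    P, its, converged = op.propagate(batch, config)
    if not converged:
        raise ConvergenceError(
            f"diffusion for {seed.provenance!r} did not converge", P
        )
    observed = P[:, 0]
    null = P[:, 1:].T  # (K, n)
    p_raw = exponential_tail_pvalue(observed, null)
    p_adj = bh_adjust(p_raw)
    table = pd.DataFrame(
        {
            "seed_prob": p0,
            "score": observed,
            "null_mean": null.mean(axis=0),
            "p_raw": p_raw,
            "p_adj": p_adj,
            "significant": p_adj < config.significance_level,
        },
        index=pd.Index(op.nodes, name="protein"),
    )
    return SignificanceResult(
        phenotype_id=phenotype_id,
        side=side,
        table=table,
        n_permutations=K,
        rng_seed=config.rng_seed,
        iterations_used=its,
        converged=converged,
        seed=seed,
        profile=DiffusionProfile(
            scores=dict(zip(op.nodes, observed.tolist())),
            iterations_used=its,
            converged=converged,
            provenance=seed.provenance,
        ),
    )
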