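"""Preranked gene-set enrichment and enrichment-map similarity edges.

Implements the weighted Kolmogorov-Smirnov enrichment statistic on a
ranked protein list: walking down the ranking, hits increment the running
sum proportionally to |score|^p and misses decrement it uniformly; the
enrichment score (ES) is the maximum deviation from zero.  Significance
uses gene-set permutation (random same-size sets drawn from the ranked
universe) -- chosen because the 3-vs-3 design makes phenotype permutation
degenerate.  The normalized score (NES) divides ES by the mean |null ES|
of matching sign; nominal p comes from the matching-sign null tail and the
FDR q from the standard NES-based procedure.

Enrichment-map edges connect significant sets whose Jaccard-overlap
combined coefficient ``c*O + (1-c)*J`` exceeds a threshold (defaults
c = 0.5, threshold 0.375, q < 0.1); clusters are the connected components
of the resulting similarity graph.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "GeneSet",
    "GseaResult",
    "SimilarityEdge",
    "read_gmt",
    "write_gmt",
    "enrichment_score",
    "preranked_gsea",
    "similarity_edges",
    "enrichment_map_components",
    "ranking_from_de",
]


@dataclass
class GeneSet:
    name: str
    members: set[str]
    collection: str = ""

    def __post_init__(self) -> None:
        self.members = set(self.members)


@dataclass
class GseaResult:
    name: str
    es: float
    nes: float
    p_value: float
    q_value: float
    size: int
    leading_edge: list[str] = field(default_factory=list)
    members_in_ranking: set[str] = field(default_factory=set)


@dataclass
class SimilarityEdge:
    set_a: str
    set_b: str
    jaccard: float
    overlap: float
    combined: float


def read_gmt(path) -> list[GeneSet]:
    """Read a GMT file (name <tab> description <tab> member...)."""
    sets = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets.append(GeneSet(parts[0], set(parts[2:]), collection=parts[1]))
    return sets


def write_gmt(sets: list[GeneSet], path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.collection, *sorted(s.members)]) + "\n")


def _sorted_ranking(ranking) -> tuple[list[str], np.ndarray]:
    """Order (id, score) pairs by decreasing score, ties broken by id."""
    if isinstance(ranking, pd.DataFrame):
        pairs = list(zip(ranking.iloc[:, 0], ranking.iloc[:, 1]))
    elif isinstance(ranking, dict):
        pairs = list(ranking.items())
    else:
        pairs = list(ranking)
    ids = [p[0] for p in pairs]
    if len(set(ids)) != len(ids):
        raise ValueError("ranking ids must be unique")
    scores = np.array([p[1] for p in pairs], dtype=float)
    if not np.isfinite(scores).all():
        raise ValueError("ranking scores must be finite")
    order = sorted(range(len(ids)), key=lambda i: (-scores[i], ids[i]))
    return [ids[i] for i in order], scores[order]


def enrichment_score(
    ranked_ids: list[str], scores: np.ndarray, members: set[str], weight: float = 1.0
) -> tuple[float, np.ndarray]:
    """ES and the full running sum for one set on a pre-sorted ranking."""
    hit = np.fromiter((g in members for g in ranked_ids), bool, len(ranked_ids))
    n, nh = len(ranked_ids), int(hit.sum())
    if nh == 0 or nh == n:
        raise ValueError("set must hit a strict subset of the ranking")
    w = np.abs(scores) ** weight
    w_hit = np.where(hit, w, 0.0)
    denom = w_hit.sum()
    if denom == 0:  # all hit scores are zero: fall back to unweighted steps
        w_hit = hit.astype(float)
        denom = w_hit.sum()
    p_hit = np.cumsum(w_hit) / denom
    p_miss = np.cumsum(~hit) / (n - nh)
    running = p_hit - p_miss
    es = running[np.argmax(np.abs(running))]
    return float(es), running


def _es_from_positions(
    pos: np.ndarray, w: np.ndarray, n: int
) -> np.ndarray:
    """Vectorized ES for many hit-position sets.

    ``pos`` is (B, m) of sorted 0-based hit indices, ``w`` the |score|^p
    weight of every rank.  The running sum is piecewise linear between hits,
    so its extrema occur just before or just after a hit.
    """
    B, m = pos.shape
    wj = w[pos]
    cumw = np.cumsum(wj, axis=1)
    tot = cumw[:, -1:]
    tot = np.where(tot == 0, 1.0, tot)
    j = np.arange(1, m + 1)
    miss = n - m
    after = cumw / tot - (pos + 1 - j) / miss
    before = np.concatenate(
        [np.zeros((B, 1)), cumw[:, :-1]], axis=1
    ) / tot - (pos - (j - 1)) / miss
    cand = np.concatenate([after, before], axis=1)
    return np.take_along_axis(
        cand, np.argmax(np.abs(cand), axis=1)[:, None], axis=1
    )[:, 0]


def preranked_gsea(
    ranking,
    sets: list[GeneSet],
    weight: float = 1.0,
    n_perm: int = 1000,
    seed: int | None = None,
    min_size: int = 10,
    max_size: int = 500,
) -> list[GseaResult]:
    """Preranked GSEA with gene-set permutation.

    ``ranking`` is an ordered id->score mapping (dict, DataFrame or pair
    list); sets are filtered to ``min_size <= |members in ranking| <=
    max_size``.  Null ES distributions are shared between sets of equal
    size.  Results come back sorted by decreasing |NES|.
    """
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives unstable p-values", stacklevel=2)
    ranked_ids, scores = _sorted_ranking(ranking)
    n = len(ranked_ids)
    index = {g: i for i, g in enumerate(ranked_ids)}
    w = np.abs(scores) ** weight
    rng = np.random.default_rng(seed)

    eligible: list[tuple[GeneSet, np.ndarray]] = []
    for s in sets:
        pos = np.array(sorted(index[g] for g in s.members if g in index))
        if min_size <= len(pos) <= max_size and len(pos) < n:
            eligible.append((s, pos))
    if not eligible:
        warnings.warn("no gene set within size bounds", stacklevel=2)
        return []

    null_by_size: dict[int, np.ndarray] = {}
    for _, pos in eligible:
        m = len(pos)
        if m not in null_by_size:
            perm = np.argsort(rng.random((n_perm, n)), axis=1)[:, :m]
            perm.sort(axis=1)
            null_by_size[m] = _es_from_positions(perm, w, n)

    es_obs = np.array(
        [_es_from_positions(pos[None, :], w, n)[0] for _, pos in eligible]
    )

    nes_obs = np.empty(len(eligible))
    pvals = np.empty(len(eligible))
    null_nes_pool: list[np.ndarray] = []
    for i, (s, pos) in enumerate(eligible):
        null = null_by_size[len(pos)]
        pos_mean = null[null > 0].mean() if (null > 0).any() else np.nan
        neg_mean = -null[null < 0].mean() if (null < 0).any() else np.nan
        es = es_obs[i]
        if es >= 0:
            nes_obs[i] = es / pos_mean if np.isfinite(pos_mean) else 0.0
            pvals[i] = ((null >= es).sum() + 1) / (len(null) + 1)
        else:
            nes_obs[i] = es / neg_mean if np.isfinite(neg_mean) else 0.0
            pvals[i] = ((null <= es).sum() + 1) / (len(null) + 1)
    # pooled null NES for the FDR step, each null ES normalized by its own
    # size-matched sign mean
    for m, null in null_by_size.items():
        pos_mean = null[null > 0].mean() if (null > 0).any() else np.nan
        neg_mean = -null[null < 0].mean() if (null < 0).any() else np.nan
        nn = np.where(null >= 0, null / pos_mean, null / neg_mean)
        null_nes_pool.append(nn[np.isfinite(nn)])
    null_nes = np.concatenate(null_nes_pool)

    qvals = np.empty(len(eligible))
    for i, nes in enumerate(nes_obs):
        if nes >= 0:
            denom_null = max((null_nes >= 0).sum(), 1)
            num = (null_nes >= nes).sum() / denom_null
            denom_obs = (nes_obs >= nes).sum() / max((nes_obs >= 0).sum(), 1)
        else:
            denom_null = max((null_nes < 0).sum(), 1)
            num = (null_nes <= nes).sum() / denom_null
            denom_obs = (nes_obs <= nes).sum() / max((nes_obs < 0).sum(), 1)
        qvals[i] = min(1.0, num / denom_obs) if denom_obs > 0 else 1.0

    results = []
    for i, (s, pos) in enumerate(eligible):
        es, running = enrichment_score(
            ranked_ids, scores, {ranked_ids[j] for j in pos}, weight
        )
        peak = int(np.argmax(np.abs(running)))
        if es >= 0:
            lead = [ranked_ids[j] for j in pos if j <= peak]
        else:
            lead = [ranked_ids[j] for j in pos if j >= peak]
        results.append(
            GseaResult(
                name=s.name,
                es=float(es_obs[i]),
                nes=float(nes_obs[i]),
                p_value=float(pvals[i]),
                q_value=float(qvals[i]),
                size=len(pos),
                leading_edge=lead,
                members_in_ranking={ranked_ids[j] for j in pos},
            )
        )
    results.sort(key=lambda r: -abs(r.nes))
    return results


def similarity_edges(
    results: list[GseaResult],
    threshold: float = 0.375,
    constant: float = 0.5,
    q_cut: float = 0.1,
) -> list[SimilarityEdge]:
    """Edges between significant sets (q < q_cut) whose combined
    Jaccard/overlap coefficient ``c*O + (1-c)*J`` exceeds the threshold."""
    keep = [r for r in results if r.q_value < q_cut]
    edges = []
    for i, a in enumerate(keep):
        for b in keep[i + 1:]:
            inter = len(a.members_in_ranking & b.members_in_ranking)
            if inter == 0:
                continue
            union = len(a.members_in_ranking | b.members_in_ranking)
            j = inter / union
            o = inter / min(len(a.members_in_ranking), len(b.members_in_ranking))
            combined = constant * o + (1.0 - constant) * j
            if combined > threshold:
                edges.append(SimilarityEdge(a.name, b.name, j, o, combined))
    return edges


def enrichment_map_components(
    results: list[GseaResult], edges: list[SimilarityEdge], q_cut: float = 0.1
) -> list[set[str]]:
    """Clusters of the enrichment map as connected components of the
    similarity graph (stand-in for interactive map annotation)."""
    g = nx.Graph()
    g.add_nodes_from(r.name for r in results if r.q_value < q_cut)
    g.add_edges_from((e.set_a, e.set_b) for e in edges)
    return [set(c) for c in nx.connected_components(g)]


def ranking_from_de(de_frame: pd.DataFrame) -> list[tuple[str, float]]:
    """Signed ranking metric from a DE table: -log10(p) * sign(log2 FC)."""
    p = np.clip(de_frame["p_value"].to_numpy(dtype=float), 1e-300, 1.0)
    score = -np.log10(p) * np.sign(de_frame["log2_fc"].to_numpy(dtype=float))
    return list(zip(de_frame["protein_id"], score))


def ranking_from_meta(meta_frame: pd.DataFrame) -> list[tuple[str, float]]:
    """Signed ranking from a cross-tissue meta table:
    -log10(combined p) * sign(log2 combined FC)."""
    p = np.clip(meta_frame["combined_p"].to_numpy(dtype=float), 1e-300, 1.0)
    sign = np.sign(np.log2(meta_frame["combined_fc"].to_numpy(dtype=float)))
    return list(zip(meta_frame["protein_id"], -np.log10(p) * sign))
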