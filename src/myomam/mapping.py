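"""Multi-source subcellular compartment assignment and enrichment.

Assigns MAM proteins to subcellular compartments by combining heterogeneous
localization evidence: categorical annotation sources (immunofluorescence
atlases, curated single-location annotations, proximity-labeling
predictions) and profile sources (fractionation abundance profiles mapped
by marker-anchored k-means, the MetaMass strategy).  Proteins listed with
more than one location in a categorical source are excluded from that
source's vote; the consensus is the strict plurality of the remaining
per-source calls, with ties reported as ambiguous.  Compartment
over-representation in a deregulated set is scored with the one-sided
hypergeometric test and Benjamini-Hochberg correction.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

__all__ = [
    "COMPARTMENTS",
    "AnnotationSource",
    "CompartmentAssignment",
    "EnrichmentResult",
    "assign_compartments",
    "metamass_map",
    "compartment_enrichment",
]

COMPARTMENTS = (
    "mitochondrion",
    "ER",
    "cytosol",
    "nucleus",
    "plasma membrane",
    "cytoskeleton",
    "Golgi",
    "other",
)

EXCLUDED = "excluded: multi-location"


@dataclass
class AnnotationSource:
    """One localization evidence source.

    ``kind='categorical'`` maps protein -> list of location labels from the
    fixed eight-compartment vocabulary; ``kind='profile'`` carries a numeric
    fractionation/abundance vector per protein (used by :func:`metamass_map`,
    not by the categorical consensus).
    """

    name: str
    mapping: dict[str, list[str]] | pd.DataFrame
    kind: str = "categorical"

    def __post_init__(self) -> None:
        if self.kind not in ("categorical", "profile"):
            raise ValueError(f"source {self.name!r}: unknown kind {self.kind!r}")
        if self.kind == "categorical":
            for pid, locs in self.mapping.items():
                bad = set(locs) - set(COMPARTMENTS)
                if bad:
                    raise ValueError(
                        f"source {self.name!r}, protein {pid!r}: "
                        f"unknown location label(s) {sorted(bad)}"
                    )


@dataclass
class CompartmentAssignment:
    protein_id: str
    per_source: dict[str, str]  # source -> label, EXCLUDED, or 'unannotated'
    consensus: str  # compartment, 'ambiguous', or 'unknown'
    votes: dict[str, int] = field(default_factory=dict)


def assign_compartments(
    proteins: list[str], sources: list[AnnotationSource]
) -> list[CompartmentAssignment]:
    """Single-location filter per source, then plurality consensus.

    Per categorical source a protein votes with its location only if the
    source lists exactly one; multi-location entries are excluded for that
    source.  The consensus is the strict plurality of votes (tie ->
    'ambiguous'); proteins with no votes at all are 'unknown'.
    """
    cat = [s for s in sources if s.kind == "categorical"]
    if not cat:
        raise ValueError("need at least one categorical source")
    out = []
    for pid in proteins:
        per_source: dict[str, str] = {}
        votes: Counter[str] = Counter()
        for src in cat:
            locs = src.mapping.get(pid)
            if locs is None or len(locs) == 0:
                per_source[src.name] = "unannotated"
            elif len(locs) > 1:
                per_source[src.name] = EXCLUDED
            else:
                per_source[src.name] = locs[0]
                votes[locs[0]] += 1
        if not votes:
            consensus = "unknown"
        else:
            ranked = votes.most_common()
            if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
                consensus = "ambiguous"
            else:
                consensus = ranked[0][0]
        out.append(CompartmentAssignment(pid, per_source, consensus, dict(votes)))
    return out


def metamass_map(
    reference_profiles: pd.DataFrame,
    markers: dict[str, str],
    query_profiles: pd.DataFrame,
    k: int = 8,
    seed: int | None = None,
    n_restarts: int = 10,
) -> dict[str, str]:
    """Marker-anchored k-means mapping of query proteins onto a
    fractionation reference.

    Reference rows (protein x fraction profiles) are row-sum normalized and
    clustered with k-means (``n_restarts`` seeded restarts, best inertia);
    each cluster takes the plurality compartment of the reference markers it
    contains ('unassigned' if it holds none).  Every query protein then
    inherits the label of its nearest centroid.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if list(reference_profiles.columns) != list(query_profiles.columns):
        raise ValueError("reference and query profiles must share columns")
    marker_comps = set(markers.values())
    n_marked = sum(1 for pid in markers if pid in reference_profiles.index)
    if n_marked < k or len(marker_comps) < 2:
        raise ValueError("markers must cover >=k reference proteins and >=2 compartments")

    def norm(df: pd.DataFrame) -> np.ndarray:
        x = df.to_numpy(dtype=float)
        rowsum = x.sum(axis=1, keepdims=True)
        if (rowsum <= 0).any():
            raise ValueError("profiles must have positive row sums")
        return x / rowsum

    ref = norm(reference_profiles)
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    ref_labels = km.fit_predict(ref)

    cluster_names: dict[int, str] = {}
    for c in range(k):
        members = reference_profiles.index[ref_labels == c]
        counts = Counter(markers[pid] for pid in members if pid in markers)
        if counts:
            ranked = counts.most_common()
            # plurality; a tie falls back to the lexicographically first label
            top = ranked[0][1]
            cluster_names[c] = sorted(n for n, ct in ranked if ct == top)[0]
        else:
            cluster_names[c] = "unassigned"

    query = norm(query_profiles)
    d = np.linalg.norm(query[:, None, :] - km.cluster_centers_[None, :, :], axis=2)
    nearest = d.argmin(axis=1)
    return {
        pid: cluster_names[int(c)] for pid, c in zip(query_profiles.index, nearest)
    }


@dataclass
class EnrichmentResult:
    term: str
    overlap: int
    set_size: int
    query_size: int
    background_size: int
    p_value: float
    q_value: float
    share_up: float = np.nan
    share_down: float = np.nan


def compartment_enrichment(
    query: set[str],
    background: set[str],
    compartment_sets: dict[str, set[str]],
    direction: dict[str, str] | None = None,
) -> list[EnrichmentResult]:
    """One-sided hypergeometric over-representation of each compartment set
    in ``query`` against ``background``, BH-corrected across compartments
    and sorted by q.  ``direction`` may map query proteins to 'up'/'down'
    to annotate the direction share of each overlap."""
    query = set(query)
    background = set(background)
    if not query or not background:
        raise ValueError("query and background must be non-empty")
    if not query <= background:
        raise ValueError("query must be a subset of background")
    M, n = len(background), len(query)
    rows = []
    for term, members in compartment_sets.items():
        inset = members & background
        overlap = inset & query
        k, K = len(overlap), len(inset)
        p = float(stats.hypergeom.sf(k - 1, M, K, n)) if K else 1.0
        share_up = share_down = np.nan
        if direction and overlap:
            ups = sum(1 for pid in overlap if direction.get(pid) == "up")
            downs = sum(1 for pid in overlap if direction.get(pid) == "down")
            share_up, share_down = ups / len(overlap), downs / len(overlap)
        rows.append((term, k, K, p, share_up, share_down))
    pvals = [r[3] for r in rows]
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    results = [
        EnrichmentResult(term, k, K, n, M, p, float(q), su, sd)
        for (term, k, K, p, su, sd), q in zip(rows, qvals)
    ]
    results.sort(key=lambda r: (r.q_value, r.p_value, r.term))
    return results
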