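"""Seeded synthetic MAM-proteome generator.

Emulates the study design of the proteomics arm: two tissues (heart and
gastrocnemius), one 6-plex isobaric run each (3 young vs 3 old channels),
log-normal baseline protein intensities with per-channel loading biases
(so median normalization has real work to do), planted old/young fold
changes for a configurable fraction of proteins (a configurable share
deregulated concordantly in both tissues), a mitochondria-predominant
compartment composition with noisy categorical annotation sources and a
marker-anchored fractionation reference, a literature-style consensus
subset, and one gene set planted among the concordantly up-regulated
proteins so the whole normalization -> DE -> meta -> mapping -> GSEA chain
is testable offline against recorded truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mapping import COMPARTMENTS, AnnotationSource
from .enrich import GeneSet
from .quant import QuantTable

__all__ = ["ProteomeSimConfig", "SyntheticProteomeTruth", "simulate_proteome"]

# striated muscle is "mitochondria-predominant": the mitochondrion dominates
# the mix, the ER comes second
DEFAULT_MIX = {
    "mitochondrion": 0.45,
    "ER": 0.20,
    "cytosol": 0.12,
    "nucleus": 0.04,
    "plasma membrane": 0.06,
    "cytoskeleton": 0.05,
    "Golgi": 0.03,
    "other": 0.05,
}


@dataclass(frozen=True)
class ProteomeSimConfig:
    n_proteins: int = 1500
    de_fraction: float = 0.12
    shared_fraction: float = 0.6  # of DE proteins, deregulated in both tissues
    log2fc_mean: float = math.log2(1.8)
    log2fc_sd: float = 0.15
    cv: float = 0.10  # within-group intensity coefficient of variation
    channel_bias_sd: float = 0.15  # log-normal sd of per-channel loading bias
    compartment_mix: dict = field(default_factory=lambda: dict(DEFAULT_MIX))
    annotation_error: float = 0.08  # per-source mislabeling probability
    multi_location_rate: float = 0.10  # per-source multi-location listings
    consensus_size: int = 216
    pathway_size: int = 40
    n_background_sets: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValueError("de_fraction must be in [0, 1]")
        if self.de_fraction > 0 and self.n_proteins < 10:
            raise ValueError("need >=10 proteins to plant effects")
        total = sum(self.compartment_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("compartment_mix probabilities must sum to 1")
        if set(self.compartment_mix) - set(COMPARTMENTS):
            raise ValueError("compartment_mix uses unknown compartments")


@dataclass
class SyntheticProteomeTruth:
    """Per-protein ground truth sufficient to score every downstream stage."""

    table: pd.DataFrame
    # columns: protein_id, compartment, consensus_member, pathway_member,
    #          de_heart, de_ga (+1 up / -1 down / 0 null), log2fc_heart,
    #          log2fc_ga
    config: ProteomeSimConfig

    def true_positives(self, tissue: str | None = None) -> set[str]:
        t = self.table
        if tissue is None:
            mask = (t.de_heart != 0) & (t.de_ga != 0)
        else:
            mask = t[f"de_{tissue}"] != 0
        return set(t.loc[mask, "protein_id"])


def _make_quant(
    rng: np.random.Generator,
    ids: list[str],
    baseline: np.ndarray,
    log2fc: np.ndarray,
    tissue: str,
    cfg: ProteomeSimConfig,
) -> QuantTable:
    n = len(ids)
    samples = [f"{tissue}_{g}{i+1}" for g in ("young", "old") for i in range(3)]
    design = pd.DataFrame(
        {
            "sample": samples,
            "tissue": tissue,
            "group": ["young"] * 3 + ["old"] * 3,
            "plex_channel": [f"TMT{i+1}" for i in range(6)],
        }
    )
    sigma = math.log(1.0 + cfg.cv)
    bias = np.exp(rng.normal(0.0, cfg.channel_bias_sd, 6))
    cols = {}
    for j, sample in enumerate(samples):
        fc = np.exp2(log2fc) if j >= 3 else np.ones(n)
        noise = np.exp(rng.normal(0.0, sigma, n))
        cols[sample] = baseline * fc * bias[j] * noise
    intensities = pd.DataFrame(cols, index=pd.Index(ids, name="protein_id"))
    return QuantTable(intensities=intensities, design=design)


def _categorical_source(
    rng: np.random.Generator,
    name: str,
    ids: list[str],
    compartments: np.ndarray,
    cfg: ProteomeSimConfig,
) -> AnnotationSource:
    mapping: dict[str, list[str]] = {}
    comp_list = list(COMPARTMENTS)
    for pid, comp in zip(ids, compartments):
        call = comp
        if rng.random() < cfg.annotation_error:
            call = comp_list[rng.integers(len(comp_list))]
        if rng.random() < cfg.multi_location_rate:
            extra = comp_list[rng.integers(len(comp_list))]
            if extra == call:
                extra = comp_list[(comp_list.index(call) + 1) % len(comp_list)]
            mapping[pid] = [call, extra]
        else:
            mapping[pid] = [call]
    return AnnotationSource(name=name, mapping=mapping, kind="categorical")


def simulate_proteome(config: ProteomeSimConfig):
    """Simulate the full proteomics arm's inputs.

    Returns ``(heart QuantTable, ga QuantTable, sources, reference, gene_sets,
    truth)`` where ``sources`` is a list of categorical
    :class:`~myomam.mapping.AnnotationSource`, ``reference`` is a dict with
    the fractionation reference profiles, markers and query profiles for
    marker-anchored k-means mapping, and ``gene_sets`` contains the planted
    pathway plus background sets.  Deterministic under ``config.seed``.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_proteins
    ids = [f"P{i:05d}" for i in range(n)]

    # compartments and consensus membership (consensus skews mito/ER, like
    # literature-consensus MAM lists)
    comp_names = list(cfg.compartment_mix)
    compartments = rng.choice(
        comp_names, size=n, p=[cfg.compartment_mix[c] for c in comp_names]
    )
    weights = np.where(
        np.isin(compartments, ["mitochondrion", "ER"]), 3.0, 1.0
    )
    consensus_ids = set(
        rng.choice(ids, size=min(cfg.consensus_size, n), replace=False,
                   p=weights / weights.sum())
    )

    # planted effects
    n_de = int(round(cfg.de_fraction * n))
    de_ids = rng.choice(n, size=n_de, replace=False)
    n_shared = int(round(cfg.shared_fraction * n_de))
    shared = de_ids[:n_shared]
    rest = de_ids[n_shared:]
    heart_only = rest[: len(rest) // 2]
    ga_only = rest[len(rest) // 2:]

    log2fc_heart = np.zeros(n)
    log2fc_ga = np.zeros(n)
    sign = rng.choice([-1.0, 1.0], size=n_de)
    mag = np.maximum(rng.normal(cfg.log2fc_mean, cfg.log2fc_sd, n_de), 0.1)
    effects = sign * mag
    shared_set, heart_set = set(shared.tolist()), set(heart_only.tolist())
    for k, idx in enumerate(de_ids):
        if idx in shared_set:
            log2fc_heart[idx] = effects[k]
            log2fc_ga[idx] = effects[k]
        elif idx in heart_set:
            log2fc_heart[idx] = effects[k]
        else:
            log2fc_ga[idx] = effects[k]

    baseline = np.exp(rng.normal(math.log(1e6), 1.0, n))
    heart = _make_quant(rng, ids, baseline, log2fc_heart, "heart", cfg)
    ga = _make_quant(rng, ids, baseline, log2fc_ga, "ga", cfg)

    sources = [
        _categorical_source(rng, name, ids, compartments, cfg)
        for name in ("HPA", "UniprotGO", "NMF", "SAFE")
    ]

    # fractionation reference: one centroid per compartment in an 8-fraction
    # profile space, well separated; markers from the reference, queries from
    # each protein's own compartment centroid
    n_frac = 8
    centroids = {
        c: np.abs(rng.normal(1.0, 0.2, n_frac)) + 4.0 * np.eye(n_frac)[i]
        for i, c in enumerate(COMPARTMENTS)
    }
    ref_ids, ref_rows, markers = [], [], {}
    for i, c in enumerate(COMPARTMENTS):
        for j in range(40):
            rid = f"R_{c.replace(' ', '')}_{j}"
            ref_ids.append(rid)
            ref_rows.append(np.abs(centroids[c] + rng.normal(0, 0.25, n_frac)))
            if j < 25:
                markers[rid] = c
    reference_profiles = pd.DataFrame(
        ref_rows, index=ref_ids, columns=[f"frac{k}" for k in range(n_frac)]
    )
    query_rows = [
        np.abs(centroids[c] + rng.normal(0, 0.25, n_frac)) for c in compartments
    ]
    query_profiles = pd.DataFrame(
        query_rows, index=ids, columns=[f"frac{k}" for k in range(n_frac)]
    )

    # gene sets: one pathway planted among concordantly up-regulated proteins
    shared_up = [ids[i] for i in shared if log2fc_heart[i] > 0]
    pathway = set(shared_up[: cfg.pathway_size])
    if len(pathway) < cfg.pathway_size:
        filler = [p for p in ids if p not in pathway]
        pathway |= set(
            rng.choice(filler, size=cfg.pathway_size - len(pathway), replace=False)
        )
    gene_sets = [GeneSet("PLANTED_PATHWAY", pathway, collection="synthetic")]
    for b in range(cfg.n_background_sets):
        size = int(rng.integers(15, 60))
        gene_sets.append(
            GeneSet(
                f"BG_SET_{b:02d}",
                set(rng.choice(ids, size=size, replace=False)),
                collection="synthetic",
            )
        )

    truth = SyntheticProteomeTruth(
        table=pd.DataFrame(
            {
                "protein_id": ids,
                "compartment": compartments,
                "consensus_member": [p in consensus_ids for p in ids],
                "pathway_member": [p in pathway for p in ids],
                "de_heart": np.sign(log2fc_heart).astype(int),
                "de_ga": np.sign(log2fc_ga).astype(int),
                "log2fc_heart": log2fc_heart,
                "log2fc_ga": log2fc_ga,
            }
        ),
        config=cfg,
    )
    reference = {
        "reference_profiles": reference_profiles,
        "markers": markers,
        "query_profiles": query_profiles,
    }
    return heart, ga, sources, reference, gene_sets, truth
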