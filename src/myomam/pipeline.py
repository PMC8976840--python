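"""End-to-end orchestration of the two analysis arms.

A :class:`RunConfig` (mirroring the CLI flags / a YAML file) drives seeded,
reproducible runs: the ultrastructure arm simulates or loads contour
fields, measures every mitochondrion, and produces group statistics and
coverage-cristae regressions; the proteome arm simulates or loads
quantification tables and runs normalization, per-tissue differential
expression, cross-tissue meta-analysis, compartment mapping and preranked
GSEA with enrichment-map edges.  Every run writes a manifest echoing all
parameters, the seed, package version and input digests, so identical
config + seed reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .contours import read_contour_fields, write_contour_fields
from .enrich import (
    preranked_gsea,
    ranking_from_meta,
    similarity_edges,
    enrichment_map_components,
    write_gmt,
)
from .groupstats import aging_summary, compare_groups, fit_simple_regression
from .mapping import assign_compartments, compartment_enrichment, metamass_map
from .morphometry import MercParams, summarize_fieldset
from .quant import (
    de_results_frame,
    differential_expression,
    median_normalize,
    meta_deregulated,
    meta_results_frame,
)
from .simulate_prot import ProteomeSimConfig, simulate_proteome
from .simulate_ultra import make_preset, simulate_fieldset

__all__ = ["RunConfig", "run", "run_ultrastructure", "run_proteome"]

_ULTRA_KEYS = {"presets", "n_mito", "pixel", "band_min", "band_max", "step",
               "min_length", "merge_gap", "contours_path"}
_PROT_KEYS = {"simulate", "quant_paths"} | {
    f.name for f in dataclasses.fields(ProteomeSimConfig) if f.name != "seed"
}


@dataclass
class RunConfig:
    """Validated run configuration; unknown keys are rejected."""

    arm: str  # 'ultrastructure' | 'proteome' | 'both'
    seed: int = 0
    out_dir: str = "myomam_out"
    ultra: dict = field(default_factory=dict)
    proteome: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.arm not in ("ultrastructure", "proteome", "both"):
            raise ValueError(f"unknown arm {self.arm!r}")
        unknown = set(self.ultra) - _ULTRA_KEYS
        if unknown:
            raise ValueError(f"unknown ultrastructure keys: {sorted(unknown)}")
        unknown = set(self.proteome) - _PROT_KEYS
        if unknown:
            raise ValueError(f"unknown proteome keys: {sorted(unknown)}")


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def records_frame(records) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in records])


def run_ultrastructure(cfg: RunConfig, out: Path) -> dict:
    u = cfg.ultra
    params = MercParams(
        band_min=u.get("band_min", 10.0),
        band_max=u.get("band_max", 30.0),
        step=u.get("step", 1.0),
        min_length=u.get("min_length", 10.0),
        merge_gap=u.get("merge_gap", 5.0),
    )
    all_records = []
    seg_rows = []
    truth_frames = []
    if u.get("contours_path"):
        fieldsets = {("input", "input"): read_contour_fields(u["contours_path"])}
    else:
        presets = u.get(
            "presets",
            [(t, a) for t in ("heart", "ga") for a in ("young", "middle", "old")],
        )
        presets = [tuple(p.split(":")) if isinstance(p, str) else tuple(p)
                   for p in presets]
        fieldsets = {}
        for i, (tissue, age) in enumerate(presets):
            fields, truth = simulate_fieldset(
                make_preset(tissue, age),
                n_mito=u.get("n_mito", 100),
                seed=cfg.seed + i,
                pixel=u.get("pixel", 2.0),
            )
            fieldsets[(tissue, age)] = fields
            tf = truth.per_mito.copy()
            tf["tissue"], tf["age_group"] = tissue, age
            truth_frames.append(tf)
            write_contour_fields(fields, out / f"contours_{tissue}_{age}.json")

    for (tissue, age), fields in fieldsets.items():
        records, segments = summarize_fieldset(
            fields, params, age_group=age, tissue=tissue
        )
        all_records.extend(records)
        for key, segs in segments.items():
            for seg in segs:
                seg_rows.append(
                    {
                        "tissue": tissue,
                        "age_group": age,
                        "mito": key,
                        "arc_start_nm": seg.arc_start,
                        "arc_end_nm": seg.arc_end,
                        "length_nm": seg.length,
                        "mean_thickness_nm": float(np.mean(seg.thickness_samples)),
                        "er_id": seg.er_id,
                    }
                )
    rec_df = records_frame(all_records)
    _write_tsv(rec_df, out / "morphometry.tsv")
    _write_tsv(pd.DataFrame(seg_rows), out / "contacts.tsv")
    if truth_frames:
        _write_tsv(pd.concat(truth_frames), out / "truth.tsv")

    stats_rows, reg_rows = [], []
    for tissue, sub in rec_df.groupby("tissue"):
        ages = sub["age_group"].nunique()
        for var in ("merc_coverage", "merc_mean_thickness", "cristae_abundance",
                    "area_um2", "circularity", "aspect_ratio"):
            groups = {
                a: g[var].dropna().to_numpy() for a, g in sub.groupby("age_group")
            }
            groups = {a: v for a, v in groups.items() if len(v) >= 2}
            if len(groups) < 2:
                continue
            cmp_res = compare_groups(
                groups,
                method="t_test" if len(groups) == 2 else "anova_bonferroni",
                variable=var,
            )
            stats_rows.append(
                {
                    "tissue": tissue,
                    "variable": var,
                    "test": cmp_res.test,
                    "statistic": cmp_res.statistic,
                    "p_value": cmp_res.p_value,
                    **{
                        f"p_adj[{a} vs {b}]": p
                        for (a, b), p in cmp_res.pairwise_adjusted.items()
                    },
                }
            )
        ok = sub["merc_coverage"].notna() & sub["cristae_abundance"].notna()
        if ok.sum() >= 3 and sub.loc[ok, "merc_coverage"].nunique() > 1:
            reg = fit_simple_regression(
                sub.loc[ok, "merc_coverage"], sub.loc[ok, "cristae_abundance"]
            )
            reg_rows.append(
                {
                    "tissue": tissue,
                    "x": "merc_coverage",
                    "y": "cristae_abundance",
                    "slope": reg.slope,
                    "intercept": reg.intercept,
                    "r": reg.r,
                    "p_value": reg.p_value,
                    "n": reg.n,
                }
            )
    _write_tsv(pd.DataFrame(stats_rows), out / "group_stats.tsv")
    _write_tsv(pd.DataFrame(reg_rows), out / "regressions.tsv")
    if "age_group" in rec_df and "young" in set(rec_df["age_group"]):
        summary = aging_summary(
            rec_df.drop(columns=["mito_id", "field_id", "tissue"]), "age_group"
        )
        _write_tsv(summary, out / "aging_summary.tsv")
    return {"n_mitochondria": len(rec_df), "n_contacts": len(seg_rows)}


def run_proteome(cfg: RunConfig, out: Path) -> dict:
    p = cfg.proteome
    sim_kwargs = {
        k: v for k, v in p.items() if k not in ("simulate", "quant_paths")
    }
    sim_cfg = ProteomeSimConfig(seed=cfg.seed, **sim_kwargs)
    heart, ga, sources, reference, gene_sets, truth = simulate_proteome(sim_cfg)
    heart_n, ga_n = median_normalize(heart), median_normalize(ga)
    de_heart = differential_expression(heart_n, "heart")
    de_ga = differential_expression(ga_n, "ga")
    meta = meta_deregulated(de_heart, de_ga)
    meta_df = meta_results_frame(meta)
    _write_tsv(de_results_frame(de_heart), out / "de_heart.tsv")
    _write_tsv(de_results_frame(de_ga), out / "de_ga.tsv")
    _write_tsv(meta_df, out / "meta.tsv")
    _write_tsv(truth.table, out / "truth_proteome.tsv")
    write_gmt(gene_sets, out / "gene_sets.gmt")

    proteins = list(truth.table["protein_id"])
    assigns = assign_compartments(proteins, sources)
    mm = metamass_map(
        reference["reference_profiles"],
        reference["markers"],
        reference["query_profiles"],
        k=8,
        seed=cfg.seed,
    )
    assign_df = pd.DataFrame(
        {
            "protein_id": [a.protein_id for a in assigns],
            "consensus": [a.consensus for a in assigns],
            "metamass": [mm.get(a.protein_id, "unassigned") for a in assigns],
        }
    )
    _write_tsv(assign_df, out / "compartments.tsv")

    dereg = set(meta_df.loc[meta_df.meta_flag != "ns", "protein_id"])
    background = set(meta_df["protein_id"])
    comp_sets = {
        c: set(assign_df.loc[assign_df.consensus == c, "protein_id"])
        for c in assign_df["consensus"].unique()
        if c not in ("unknown", "ambiguous")
    }
    enr_rows = []
    if dereg and comp_sets:
        direction = dict(zip(meta_df.protein_id, meta_df.meta_flag))
        for r in compartment_enrichment(dereg, background, comp_sets, direction):
            enr_rows.append(dataclasses.asdict(r))
    _write_tsv(pd.DataFrame(enr_rows), out / "compartment_enrichment.tsv")

    ranking = ranking_from_meta(meta_df)
    gsea = preranked_gsea(ranking, gene_sets, n_perm=1000, seed=cfg.seed)
    gsea_df = pd.DataFrame(
        [
            {
                "set": r.name,
                "size": r.size,
                "es": r.es,
                "nes": r.nes,
                "p_value": r.p_value,
                "q_value": r.q_value,
                "neg_log10_p_gt_1p5": -np.log10(max(r.p_value, 1e-300)) > 1.5,
                "leading_edge": ";".join(r.leading_edge),
            }
            for r in gsea
        ]
    )
    _write_tsv(gsea_df, out / "gsea.tsv")
    edges = similarity_edges(gsea)
    _write_tsv(
        pd.DataFrame([dataclasses.asdict(e) for e in edges]), out / "gsea_edges.tsv"
    )
    components = enrichment_map_components(gsea, edges)

    # truth-scored summary
    tp = truth.true_positives()
    flagged = dereg
    sens = len(flagged & tp) / len(tp) if tp else float("nan")
    summary = {
        "n_proteins": len(proteins),
        "n_meta_flagged": len(flagged),
        "meta_sensitivity_shared": sens,
        "top_gsea_set": gsea[0].name if gsea else None,
        "n_similarity_edges": len(edges),
        "n_map_components": len(components),
    }
    return summary


def run(config: RunConfig) -> dict:
    """Execute the configured arm(s); returns the manifest dictionary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "arm": config.arm,
        "parameters": {"ultra": config.ultra, "proteome": config.proteome},
        "assumptions": [
            "input ER traces are curated ribosome-free",
            "organelles treated as independent observations (pooled)",
        ],
        "stages": {},
    }
    if config.ultra.get("contours_path"):
        manifest["input_digests"] = {
            config.ultra["contours_path"]: _digest(Path(config.ultra["contours_path"]))
        }
    try:
        if config.arm in ("ultrastructure", "both"):
            manifest["stages"]["ultrastructure"] = run_ultrastructure(config, out)
        if config.arm in ("proteome", "both"):
            manifest["stages"]["proteome"] = run_proteome(config, out)
    except Exception as exc:
        manifest["failed_stage"] = f"{type(exc).__name__}: {exc}"
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        raise
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
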