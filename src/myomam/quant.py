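"""TMT quantification post-processing: normalization, differential
expression, cross-tissue meta-analysis, and fraction protein yield.

The quantitative contract follows standard isobaric-label practice for a
6-plex design (two tissues, 3 young vs 3 old channels each):

* per-channel median scaling to correct label-loading differences;
* per-protein old/young fold change with a two-sided Welch t-test on log2
  intensities, deregulation called at ratio >1.2 or <0.83 with P < 0.05;
* cross-tissue combination of per-tissue p-values by Fisher's method
  (chi2 = -2*sum(ln p) on 2k degrees of freedom) with the geometric-mean
  fold change, the same cutoffs deciding the meta flag;
* fraction protein yield = volume x concentration / tissue mass (mg/g).

No multiple-testing correction is applied to per-protein p-values: the
fold-change gate plus raw P < 0.05 is the deregulation rule.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "QuantTable",
    "DEResult",
    "MetaResult",
    "YieldRecord",
    "median_normalize",
    "differential_expression",
    "fisher_combine",
    "meta_deregulated",
    "yield_abundance",
    "percent_reduction",
    "FC_UP",
    "FC_DOWN",
    "P_CUT",
]

logger = logging.getLogger(__name__)

FC_UP = 1.2
FC_DOWN = 0.83
P_CUT = 0.05
P_FLOOR = 1e-300


def _flag(fold_change: float, p: float) -> str:
    if p < P_CUT and fold_change > FC_UP:
        return "up"
    if p < P_CUT and fold_change < FC_DOWN:
        return "down"
    return "ns"


@dataclass
class QuantTable:
    """Protein x sample intensity matrix with its design.

    ``intensities`` is indexed by unique protein ids with one column per
    sample; ``design`` has one row per sample with columns
    ``sample, tissue, group`` (tissue in {heart, ga}, group in {young, old}).
    """

    intensities: pd.DataFrame
    design: pd.DataFrame
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.intensities.index.duplicated().any():
            dup = self.intensities.index[self.intensities.index.duplicated()][:3]
            raise ValueError(f"duplicate protein ids, e.g. {list(dup)}")
        if not np.isfinite(self.intensities.to_numpy(dtype=float)).all():
            raise ValueError("intensities must be finite")
        if (self.intensities.to_numpy(dtype=float) < 0).any():
            raise ValueError("intensities must be non-negative")
        missing = set(self.intensities.columns) - set(self.design["sample"])
        if missing:
            raise ValueError(f"samples missing from design: {sorted(missing)}")
        counts = self.design.groupby(["tissue", "group"]).size()
        if (counts < 2).any():
            raise ValueError("every tissue/group cell needs >=2 samples")

    def samples_for(self, tissue: str, group: str) -> list[str]:
        d = self.design
        return list(d.loc[(d.tissue == tissue) & (d.group == group), "sample"])

    def tissues(self) -> list[str]:
        return sorted(self.design["tissue"].unique())


@dataclass
class DEResult:
    protein_id: str
    fold_change: float  # old/young ratio of group mean intensities
    log2_fc: float
    p_value: float
    flag: str  # 'up' | 'down' | 'ns'


@dataclass
class MetaResult:
    protein_id: str
    tissue_p: dict[str, float]
    tissue_fc: dict[str, float]
    chi2: float
    df: int
    combined_p: float
    combined_fc: float  # geometric mean of per-tissue fold changes
    meta_flag: str


@dataclass
class YieldRecord:
    fraction: str
    volume_ml: float
    concentration_mg_per_ml: float
    tissue_mass_g: float
    abundance_mg_per_g: float = field(init=False)

    def __post_init__(self) -> None:
        if min(self.volume_ml, self.concentration_mg_per_ml, self.tissue_mass_g) <= 0:
            raise ValueError("volume, concentration and tissue mass must be positive")
        self.abundance_mg_per_g = (
            self.volume_ml * self.concentration_mg_per_ml / self.tissue_mass_g
        )


def median_normalize(table: QuantTable) -> QuantTable:
    """Scale each sample so its median equals the grand median of the
    pre-scaling sample medians.  Idempotent; errors on a zero-median sample."""
    medians = table.intensities.median(axis=0)
    zero = medians[medians <= 0]
    if len(zero):
        raise ValueError(
            f"cannot median-normalize: non-positive median in sample(s) "
            f"{list(zero.index)}"
        )
    grand = float(np.median(medians.to_numpy()))
    scaled = table.intensities * (grand / medians)
    return replace(table, intensities=scaled, normalized=True)


def differential_expression(
    table: QuantTable, tissue: str, equal_var: bool = False
) -> list[DEResult]:
    """Per-protein old-vs-young differential expression within one tissue.

    Fold change is mean(old)/mean(young) of normalized intensities; the
    p-value is a two-sided Welch t-test on log2 intensities.  Proteins with
    any zero channel are excluded (log2 undefined) and logged.
    """
    if not table.normalized:
        warnings.warn("quant table is not median-normalized", stacklevel=2)
    young = table.samples_for(tissue, "young")
    old = table.samples_for(tissue, "old")
    if len(young) < 2 or len(old) < 2:
        raise ValueError(f"tissue {tissue!r} needs >=2 samples per group")
    sub = table.intensities[young + old]
    nonzero = (sub > 0).all(axis=1)
    excluded = sub.index[~nonzero]
    if len(excluded):
        logger.info(
            "differential_expression(%s): excluded %d proteins with zero "
            "intensity (e.g. %s)", tissue, len(excluded), list(excluded[:3])
        )
    sub = sub.loc[nonzero]
    y = sub[young].to_numpy(dtype=float)
    o = sub[old].to_numpy(dtype=float)
    fc = o.mean(axis=1) / y.mean(axis=1)
    t = stats.ttest_ind(np.log2(o), np.log2(y), axis=1, equal_var=equal_var)
    pvals = np.asarray(t.pvalue)
    return [
        DEResult(pid, float(f), float(np.log2(f)), float(p), _flag(float(f), float(p)))
        for pid, f, p in zip(sub.index, fc, pvals)
    ]


def fisher_combine(p_values) -> tuple[float, int, float]:
    """Fisher's method: chi2 = -2*sum(ln p), df = 2k, upper-tail chi-square p.

    Zeros are floored at 1e-300 with a warning; values outside (0, 1] raise.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if (p == 0).any():
        warnings.warn("p-value of 0 floored at 1e-300", stacklevel=2)
        p = np.maximum(p, P_FLOOR)
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    chi2 = float(-2.0 * np.log(p).sum())
    df = 2 * p.size
    return chi2, df, float(stats.chi2.sf(chi2, df))


def meta_deregulated(
    heart: list[DEResult], ga: list[DEResult]
) -> list[MetaResult]:
    """Cross-tissue meta-analysis over proteins quantified in both tissues.

    Per protein: Fisher-combined p over the two per-tissue tests, geometric
    mean fold change, and the same ratio/p cutoffs applied to the combined
    values.
    """
    by_heart = {r.protein_id: r for r in heart}
    by_ga = {r.protein_id: r for r in ga}
    shared = sorted(set(by_heart) & set(by_ga))
    if not shared:
        warnings.warn("no proteins shared between tissues", stacklevel=2)
        return []
    out = []
    for pid in shared:
        rh, rg = by_heart[pid], by_ga[pid]
        chi2, df, combined_p = fisher_combine([rh.p_value, rg.p_value])
        combined_fc = math.sqrt(rh.fold_change * rg.fold_change)
        out.append(
            MetaResult(
                protein_id=pid,
                tissue_p={"heart": rh.p_value, "ga": rg.p_value},
                tissue_fc={"heart": rh.fold_change, "ga": rg.fold_change},
                chi2=chi2,
                df=df,
                combined_p=combined_p,
                combined_fc=combined_fc,
                meta_flag=_flag(combined_fc, combined_p),
            )
        )
    return out


def yield_abundance(
    volume_ml: float, concentration_mg_per_ml: float, tissue_mass_g: float,
    fraction: str = "MAM",
) -> YieldRecord:
    """Fraction protein yield: volume x concentration normalized by tissue
    mass, in mg protein per g tissue."""
    return YieldRecord(fraction, volume_ml, concentration_mg_per_ml, tissue_mass_g)


def percent_reduction(young: float, old: float) -> float:
    """Percent loss of a quantity from young to old: 100*(1 - old/young)."""
    if young <= 0:
        raise ValueError("young value must be positive")
    return 100.0 * (1.0 - old / young)


def de_results_frame(results: list[DEResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "protein_id": r.protein_id,
                "fold_change": r.fold_change,
                "log2_fc": r.log2_fc,
                "p_value": r.p_value,
                "flag": r.flag,
            }
            for r in results
        ]
    )


def meta_results_frame(results: list[MetaResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "protein_id": r.protein_id,
                "p_heart": r.tissue_p.get("heart"),
                "p_ga": r.tissue_p.get("ga"),
                "fc_heart": r.tissue_fc.get("heart"),
                "fc_ga": r.tissue_fc.get("ga"),
                "chi2": r.chi2,
                "df": r.df,
                "combined_p": r.combined_p,
                "combined_fc": r.combined_fc,
                "meta_flag": r.meta_flag,
            }
            for r in results
        ]
    )
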