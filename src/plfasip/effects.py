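"""Mixture-vs-average contrasts, nested ANOVA and effect classification.

The design question is whether a quaternary residue mixture behaves
like the average of its four monoculture (non-mixture) treatments.  For
every response (a carbon pool at some aggregation level) the contrast
is ``mixture mean − unweighted mean of the four non-mixture treatment
means``.  Inference uses a nested ANOVA with treatment (mix vs non-mix,
1 df) and crop species nested within treatment (the four non-mixture
species plus the mixture as a fifth level; 3 df), tested against the
within-cell residual with sequential (Type I) sums of squares.  The
effect is *additive* when the treatment term is non-significant,
*synergistic* when significant with a positive difference, and
*antagonistic* when significant with a negative difference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .biomarkers import BACTERIAL_GROUPS, Group
from .datamodel import EffectClass, MixtureEffect

__all__ = [
    "MixtureContrast",
    "NestedAnovaResult",
    "mix_vs_average",
    "nested_anova",
    "classify_effect",
    "group_ratios",
    "significance_stars",
    "mixture_effects_table",
]


@dataclass(frozen=True)
class MixtureContrast:
    mix_mean: float
    avg_nonmix_mean: float
    difference: float
    percent: float  # 100 × difference / avg_nonmix_mean; NaN when avg <= 0


def mix_vs_average(
    values: Mapping[str, Sequence[float]],
    mix_id: str = "MIX",
    nonmix_ids: Sequence[str] | None = None,
) -> MixtureContrast:
    """Mixture mean vs the unweighted average of non-mixture treatment means.

    ``values`` maps treatment id to its replicate observations.  With a
    balanced design the unweighted mean of treatment means equals the
    pooled replicate mean; with unbalanced inputs the treatment means
    are averaged, matching the "average of the four non-mixture
    treatments" framing.
    """
    if mix_id not in values:
        raise ValueError(f"missing mixture treatment {mix_id!r}")
    if nonmix_ids is None:
        nonmix_ids = [k for k in values if k != mix_id]
    missing = [t for t in nonmix_ids if t not in values]
    if missing:
        raise ValueError(f"missing non-mixture treatment(s): {', '.join(missing)}")
    if not nonmix_ids:
        raise ValueError("no non-mixture treatments supplied")
    for tid in (mix_id, *nonmix_ids):
        if len(np.atleast_1d(values[tid])) < 1:
            raise ValueError(f"treatment {tid!r} has no replicates")
    mix_mean = float(np.mean(values[mix_id]))
    avg = float(np.mean([np.mean(values[t]) for t in nonmix_ids]))
    diff = mix_mean - avg
    percent = 100.0 * diff / avg if avg > 0 else math.nan
    return MixtureContrast(mix_mean, avg, diff, percent)


@dataclass(frozen=True)
class NestedAnovaResult:
    """Sequential sums-of-squares decomposition for the nested layout."""

    ss_treatment: float
    df_treatment: int
    ss_species: float
    df_species: int
    ss_residual: float
    df_residual: int
    f_treatment: float
    p_treatment: float
    f_species: float
    p_species: float

    @property
    def no_variance(self) -> bool:
        return (self.ss_treatment + self.ss_species + self.ss_residual) == 0.0


def nested_anova(y, treatment, species) -> NestedAnovaResult:
    """Nested ANOVA: treatment, then species within treatment, by Type I SS.

    The decomposition is sequential on group means:

    * SS_treatment = Σ_t n_t (ȳ_t − ȳ)²
    * SS_species(treatment) = Σ_cells n_c (ȳ_c − ȳ)² − SS_treatment
    * SS_residual = SS_total − Σ_cells n_c (ȳ_c − ȳ)²

    with F = MS_effect / MS_residual.  When all observations are equal
    (SS_total = 0) the F ratios are undefined and reported as NaN; the
    result's ``no_variance`` property marks the case.
    """
    y = np.asarray(y, dtype=float)
    treatment = np.asarray(treatment)
    species = np.asarray(species)
    if not (len(y) == len(treatment) == len(species)):
        raise ValueError("y, treatment and species must have equal length")
    cells = pd.DataFrame({"y": y, "t": treatment, "s": species})
    grand = y.mean()
    ss_total = float(((y - grand) ** 2).sum())

    by_t = cells.groupby("t")["y"].agg(["mean", "count"])
    ss_trt = float((by_t["count"] * (by_t["mean"] - grand) ** 2).sum())
    df_trt = len(by_t) - 1

    by_cell = cells.groupby(["t", "s"])["y"].agg(["mean", "count"])
    ss_cells = float((by_cell["count"] * (by_cell["mean"] - grand) ** 2).sum())
    ss_sp = ss_cells - ss_trt
    df_sp = len(by_cell) - len(by_t)

    ss_res = ss_total - ss_cells
    df_res = len(y) - len(by_cell)
    if df_res < 2:
        raise ValueError(f"only {df_res} residual degrees of freedom; need >= 2")

    # snap float dust to zero so exactly-replicated inputs report the
    # no-variance case instead of an infinite F ratio
    scale = max(ss_total, grand * grand * len(y), 1e-300)
    ss_trt = 0.0 if ss_trt < 1e-12 * scale else ss_trt
    ss_sp = 0.0 if ss_sp < 1e-12 * scale else ss_sp
    ss_res = 0.0 if ss_res < 1e-12 * scale else ss_res

    ms_res = ss_res / df_res
    with np.errstate(divide="ignore", invalid="ignore"):
        if ms_res > 0:
            f_trt = (ss_trt / df_trt) / ms_res if df_trt > 0 else math.nan
            f_sp = (ss_sp / df_sp) / ms_res if df_sp > 0 else math.nan
        else:
            # zero residual variance: any systematic effect is infinitely
            # strong; no effect at all leaves F undefined
            f_trt = math.inf if ss_trt > 0 else math.nan
            f_sp = math.inf if ss_sp > 0 else math.nan
    p_trt = float(stats.f.sf(f_trt, df_trt, df_res)) if math.isfinite(f_trt) else (
        0.0 if f_trt == math.inf else math.nan
    )
    p_sp = float(stats.f.sf(f_sp, df_sp, df_res)) if math.isfinite(f_sp) else (
        0.0 if f_sp == math.inf else math.nan
    )
    return NestedAnovaResult(
        ss_treatment=ss_trt, df_treatment=df_trt,
        ss_species=max(ss_sp, 0.0), df_species=df_sp,
        ss_residual=max(ss_res, 0.0), df_residual=df_res,
        f_treatment=float(f_trt), p_treatment=p_trt,
        f_species=float(f_sp), p_species=p_sp,
    )


def classify_effect(difference: float, p_treatment: float, alpha: float = 0.05) -> EffectClass:
    """Synergistic / antagonistic / additive classification.

    Additive unless the treatment contrast is significant (p < α); an
    undefined p (no-variance case) also classifies as additive, as does
    a difference of exactly zero.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    significant = p_treatment < alpha  # NaN compares False
    if not significant or difference == 0.0:
        return EffectClass.ADDITIVE
    return EffectClass.SYNERGISTIC if difference > 0 else EffectClass.ANTAGONISTIC


def group_ratios(group_totals: Mapping[str | Group, float]) -> dict[str, float]:
    """Fungi:bacteria and Gram-positive:Gram-negative ratios for one sample.

    Bacteria pools general, Gram-positive and Gram-negative biomass.
    A zero denominator yields NaN (flagged undefined) rather than an
    error, since single samples can miss a group.
    """
    totals = {Group(k) if not isinstance(k, Group) else k: float(v)
              for k, v in group_totals.items()}
    bacteria = sum(totals.get(g, 0.0) for g in BACTERIAL_GROUPS)
    fungi = totals.get(Group.FUNGI, 0.0)
    gpos = totals.get(Group.GRAM_POSITIVE, 0.0)
    gneg = totals.get(Group.GRAM_NEGATIVE, 0.0)
    return {
        "fungi_to_bacteria": fungi / bacteria if bacteria > 0 else math.nan,
        "gpos_to_gneg": gpos / gneg if gneg > 0 else math.nan,
    }


def significance_stars(p: float) -> str:
    """Conventional significance stars at 0.05 / 0.01 / 0.001."""
    if not math.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


_POOL_LABELS = {"c_total": "total", "c_plant": "plant-derived", "c_som": "SOM-derived"}


def mixture_effects_table(
    replicate_partition: pd.DataFrame,
    alpha: float = 0.05,
    mix_id: str = "MIX",
    levels: Sequence[str] = ("total", "group"),
    pools: Sequence[str] = ("c_total", "c_plant", "c_som"),
    bh_correction: bool = False,
) -> pd.DataFrame:
    """Build the effects table from a replicate-level partition table.

    One row per response (pool × aggregation key): means, difference,
    percent (rounded to integer for reporting), nested-ANOVA F/p for
    the treatment and species-within-treatment terms, stars, and the
    effect class.  ``bh_correction`` optionally applies
    Benjamini–Hochberg across the treatment p-values before
    classification (off by default).
    """
    df = replicate_partition
    records: list[dict] = []
    results: list[tuple[MixtureContrast, NestedAnovaResult]] = []
    for level in levels:
        sub_level = df[df["level"] == level]
        for key in sub_level["key"].unique():
            sub = sub_level[sub_level["key"] == key]
            for pool in pools:
                vals = {
                    tid: grp[pool].to_numpy()
                    for tid, grp in sub.groupby("treatment_id")
                }
                if mix_id not in vals or len(vals) < 2:
                    continue
                contrast = mix_vs_average(vals, mix_id=mix_id)
                anova = nested_anova(
                    sub[pool].to_numpy(),
                    np.where(sub["treatment_id"] == mix_id, "mix", "non_mix"),
                    sub["species"].to_numpy(),
                )
                results.append((contrast, anova))
                records.append({
                    "response": f"{_POOL_LABELS.get(pool, pool)} / {key}",
                    "level": level,
                    "key": key,
                    "pool": pool,
                    "mix_mean": contrast.mix_mean,
                    "avg_nonmix_mean": contrast.avg_nonmix_mean,
                    "difference": contrast.difference,
                    "percent": round(contrast.percent) if math.isfinite(contrast.percent) else math.nan,
                    "f_treatment": anova.f_treatment,
                    "p_treatment": anova.p_treatment,
                    "f_nested": anova.f_species,
                    "p_nested": anova.p_species,
                })
    out = pd.DataFrame(records)
    if out.empty:
        raise ValueError("no responses with both mixture and non-mixture data")
    p_for_class = out["p_treatment"].to_numpy(dtype=float)
    if bh_correction:
        from statsmodels.stats.multitest import multipletests

        finite = np.isfinite(p_for_class)
        adj = p_for_class.copy()
        if finite.any():
            adj[finite] = multipletests(p_for_class[finite], method="fdr_bh")[1]
        out["p_treatment_adj"] = adj
        p_for_class = adj
    out["stars"] = [significance_stars(p) for p in p_for_class]
    out["effect_class"] = [
        classify_effect(d, p, alpha).value
        for d, p in zip(out["difference"], p_for_class)
    ]
    return out


def effects_as_records(table: pd.DataFrame) -> list[MixtureEffect]:
    """Convert an effects table into typed ``MixtureEffect`` records."""
    return [
        MixtureEffect(
            response=r["response"],
            mix_mean=r["mix_mean"],
            avg_nonmix_mean=r["avg_nonmix_mean"],
            difference=r["difference"],
            percent=r["percent"],
            f_treatment=r["f_treatment"],
            p_treatment=r["p_treatment"],
            f_nested=r["f_nested"],
            p_nested=r["p_nested"],
            effect_class=EffectClass(r["effect_class"]),
        )
        for _, r in table.iterrows()
    ]
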