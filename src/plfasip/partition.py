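"""Two-pool isotope mixing: attribute biomarker carbon to its sources.

Each labelled treatment supplies residue C at a known ¹³C atom fraction
far above natural abundance.  For a biomarker with measured atom
fraction F_sample, background F_control (control-soil mean) and label
endmember F_label, the tracer-derived share of its carbon is

    f = (F_sample − F_control) / (F_label − F_control)

assuming microbes do not discriminate between ¹³C and ¹²C and that
PLFA synthesized from the residue carries the residue's bulk atom
fraction.  Design-aware scaling turns tracer-derived C into
residue-derived C:

* non-mixture treatments: only 25 % of the (chemically identical)
  residue C is labelled, so residue-derived C = tracer C / 0.25;
* mixture treatments: the labelled species' entire share is labelled,
  so tracer C *is* that species' contribution, and the mixture total is
  the sum over the four labelled sub-treatments.

Primed-SOM-derived C then follows by mass balance:
c_som = c_total − c_baseline − c_plant, where c_baseline is the
control-treatment mean.  Small negative pools produced by measurement
noise are clipped to zero and flagged; the clipping adjustment is
propagated so that stored pools always sum exactly to the total.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .biomarkers import Group, carbon_count, default_group_mapping
from .datamodel import IsotopeConstants, TreatmentClass, TreatmentDesign
from .isotope import (
    atom_fraction_to_delta,
    correct_fame_atom_fraction,
    correct_fame_to_plfa,
    delta_to_atom_fraction,
)

logger = logging.getLogger("plfasip")

__all__ = [
    "tracer_fraction",
    "plant_derived_c",
    "sum_species_contributions",
    "som_derived",
    "total_from_pools",
    "aggregate_by_group",
    "added_13c",
    "mixture_cn",
    "partition_experiment",
    "PartitionTables",
]

#: |f| beyond the unit interval by more than this triggers a warning, not just a flag.
F_WARN_TOLERANCE = 0.05

MIXTURE_ID = "MIX"


def tracer_fraction(f_sample, f_control, f_label):
    """Fraction of biomarker C derived from the labelled residue.

    Returns ``(f, flags)`` with f clipped into [0, 1]; values below
    −0.05 or above 1.05 additionally log a warning (they indicate more
    than measurement noise).  Scalar or array inputs.
    """
    f_sample = np.asarray(f_sample, dtype=float)
    f_control = np.asarray(f_control, dtype=float)
    f_label = np.asarray(f_label, dtype=float)
    if np.any(f_label <= f_control):
        raise ValueError("degenerate mixing endmembers: f_label must exceed f_control")
    raw = (f_sample - f_control) / (f_label - f_control)
    if np.any(raw < -F_WARN_TOLERANCE) or np.any(raw > 1.0 + F_WARN_TOLERANCE):
        logger.warning(
            "tracer fraction outside [%.2f, %.2f]: min %.3f max %.3f",
            -F_WARN_TOLERANCE, 1 + F_WARN_TOLERANCE, raw.min(), raw.max(),
        )
    clipped = np.clip(raw, 0.0, 1.0)
    if raw.ndim == 0:
        flags = set()
        if raw < 0:
            flags.add("clipped_low")
        elif raw > 1:
            flags.add("clipped_high")
        return float(clipped), flags
    flag_low = raw < 0
    flag_high = raw > 1
    return clipped, (flag_low, flag_high)


def plant_derived_c(c_total, f_tracer, design: TreatmentDesign):
    """Residue-derived C (non-mix) or labelled-species contribution (mix).

    Tracer-derived C is ``c_total × f_tracer``.  In a non-mixture
    treatment the labelled and unlabelled residue are the same species
    and assumed identical substrates, so residue-derived C is tracer C
    divided by the labelled fraction of added C.  In a mixture the
    labelled species' share is entirely labelled, so the tracer
    quantifies that species' contribution directly.
    """
    if design.klass not in (TreatmentClass.NON_MIX, TreatmentClass.MIX):
        raise ValueError(f"{design.treatment_id}: treatment carries no tracer")
    if design.labelled_c_fraction <= 0:
        raise ValueError(f"{design.treatment_id}: labelled_c_fraction is zero")
    tracer_c = np.asarray(c_total, dtype=float) * np.asarray(f_tracer, dtype=float)
    if design.klass is TreatmentClass.NON_MIX:
        out = tracer_c / design.labelled_c_fraction
    else:
        out = tracer_c
    return float(out) if out.ndim == 0 else out


def sum_species_contributions(contributions: dict[str, float], species: list[str] | None = None):
    """Total mixture plant-derived C from the four labelled sub-treatments.

    Returns ``(total, breakdown)`` where breakdown preserves the
    per-species contributions for stacked reporting.
    """
    if species is not None:
        missing = [s for s in species if s not in contributions]
        if missing:
            raise ValueError(f"missing species contribution(s): {', '.join(missing)}")
        extra = [s for s in contributions if s not in species]
        if extra:
            raise ValueError(f"unexpected species contribution(s): {', '.join(extra)}")
    if not contributions:
        raise ValueError("no species contributions supplied")
    total = math.fsum(contributions.values())  # order-independent
    return total, dict(contributions)


def som_derived(c_total: float, c_baseline: float, c_som_free_plant: float):
    """Primed-SOM-derived C by mass balance.

    ``c_som = c_total − c_baseline − c_plant``; a negative result is
    floored at zero with flag ``clipped_low`` and the shortfall logged.
    Returns ``(c_som, flags)``.
    """
    c_total = float(c_total)
    c_baseline = float(c_baseline)
    c_plant = float(c_som_free_plant)
    if min(c_total, c_baseline, c_plant) < 0:
        raise ValueError("carbon pools must be non-negative")
    som = c_total - c_baseline - c_plant
    flags: set[str] = set()
    if som < 0:
        logger.info("SOM pool floored at 0 (shortfall %.4g μg C g⁻¹)", -som)
        flags.add("clipped_low")
        som = 0.0
    return som, flags


def total_from_pools(c_baseline: float, c_plant: float, c_som: float) -> float:
    """Reassemble total PLFA-C from its three source pools."""
    return float(c_baseline) + float(c_plant) + float(c_som)


def aggregate_by_group(
    results: pd.DataFrame, mapping: dict[str, Group] | None = None
) -> pd.DataFrame:
    """Sum per-biomarker partition rows into per-group rows plus a grand total.

    ``results`` needs columns ``sample_id, biomarker, c_total,
    c_baseline, c_plant, c_som`` (``flags`` optional).  Biomarkers
    mapping to ``unassigned`` are excluded from named group sums but
    included in the grand total, with a log record.
    """
    if results.empty:
        raise ValueError("empty partition input")
    if mapping is None:
        mapping = default_group_mapping()
    df = results.copy()
    if "group" not in df.columns:
        df["group"] = [mapping.get(b, Group.UNASSIGNED).value for b in df["biomarker"]]
    n_unassigned = int((df["group"] == Group.UNASSIGNED.value).sum())
    if n_unassigned:
        logger.info("%d biomarker rows unassigned; kept in grand totals only", n_unassigned)
    pools = ["c_total", "c_baseline", "c_plant", "c_som"]
    agg: dict = {p: "sum" for p in pools}
    if "flags" in df.columns:
        agg["flags"] = lambda s: ";".join(sorted({f for v in s if v for f in str(v).split(";")}))
    by_group = df.groupby(["sample_id", "group"], as_index=False).agg(agg)
    grand = df.groupby("sample_id", as_index=False).agg(agg)
    grand["group"] = "total"
    return pd.concat([by_group, grand[by_group.columns]], ignore_index=True)


def added_13c(design: TreatmentDesign) -> float:
    """Mass of ¹³C added with the residues, mg ¹³C per g soil.

    ``c_rate × labelled_c_fraction × atom fraction of the labelled
    residue``, rounded half-up to 4 decimal places as conventionally
    reported.  Decimal arithmetic avoids binary half-way artefacts
    (e.g. 1 × 0.25 × 0.067 = 0.016750 must round to 0.0168).
    """
    if design.klass is TreatmentClass.CONTROL:
        raise ValueError("control treatment adds no residue C")
    if not design.is_labelled:
        raise ValueError(f"{design.treatment_id}: no labelled residue")
    atom = design.residue_atom_fraction[design.labelled_species]
    exact = (
        Decimal(str(design.c_rate))
        * Decimal(str(design.labelled_c_fraction))
        * Decimal(str(atom))
    )
    return float(exact.quantize(Decimal("0.0001"), rounding=ROUND_HALF_UP))


def mixture_cn(design: TreatmentDesign) -> float:
    """C:N ratio of the blended residue: total C over total N.

    For C shares w_s of components with ratios CN_s this is the
    C-weighted harmonic mean 1 / Σ_s (w_s / CN_s) — the ratio obtained
    by physically blending the residues, not the arithmetic mean of the
    component ratios.
    """
    if design.klass is TreatmentClass.CONTROL:
        raise ValueError("control treatment has no residue")
    inv = 0.0
    for sp, share in design.species_c_share.items():
        cn = design.residue_cn.get(sp)
        if cn is None or cn <= 0:
            raise ValueError(f"{design.treatment_id}: non-positive or missing C:N for {sp!r}")
        inv += share / cn
    return 1.0 / inv


# -- full-experiment pipeline ----------------------------------------------

@dataclass
class PartitionTables:
    """Partition output at the three aggregation levels.

    ``sample_biomarker``
        Per labelled sample × biomarker.  For mixture sub-treatments
        ``c_plant`` is the labelled species' contribution and ``c_som``
        is not defined at this level (NaN).
    ``replicate``
        Per replicate of each non-mixture treatment and of the
        assembled mixture (id ``MIX``), long over levels ``biomarker``,
        ``group`` and ``total``.  Mixture totals are replicate-wise
        means over the four sub-treatments; mixture plant C sums their
        tracer contributions; the baseline enters once.
    ``mixture_breakdown``
        Per replicate × species plant-derived contribution for stacked
        reporting (the control baseline is attributed ¼ to each).
    """

    sample_biomarker: pd.DataFrame
    replicate: pd.DataFrame
    mixture_breakdown: pd.DataFrame
    baseline: pd.DataFrame


def _balance_pools(c_total, c_baseline, c_plant):
    """Vectorized mass balance with clip propagation.

    Ensures plant ≤ total, then reduces the baseline share when
    total − plant falls below it (the pre-existing pool cannot exceed
    what is left after the residue-derived share), leaving SOM ≥ 0 and
    pools that sum exactly to the total.
    """
    c_total = np.asarray(c_total, dtype=float)
    c_plant = np.asarray(c_plant, dtype=float)
    c_baseline = np.asarray(c_baseline, dtype=float)
    plant_capped = np.minimum(c_plant, c_total)
    base_eff = np.minimum(c_baseline, c_total - plant_capped)
    som = c_total - plant_capped - base_eff
    clipped = (c_plant > c_total) | (c_baseline > c_total - plant_capped)
    return plant_capped, base_eff, som, clipped


def _flags_join(*flag_arrays):
    n = len(flag_arrays[0][1])
    out = [[] for _ in range(n)]
    for name, arr in flag_arrays:
        for i, v in enumerate(np.asarray(arr, dtype=bool)):
            if v:
                out[i].append(name)
    return [";".join(v) for v in out]


def partition_experiment(
    measurements: pd.DataFrame,
    designs: dict[str, TreatmentDesign],
    constants: IsotopeConstants,
    mapping: dict[str, Group] | None = None,
    correction_space: str = "delta",
) -> PartitionTables:
    """Partition every labelled sample's biomarker C into source pools.

    ``measurements`` is the long table from
    :func:`plfasip.io.read_measurements` (δ¹³C required for labelled
    treatments and the control).  Baselines (mean concentration and
    mean background atom fraction per biomarker) come from the control
    treatment; biomarkers absent from the control use the configured
    natural-abundance atom fraction and a zero baseline, flagged
    ``baseline_imputed``.
    """
    if correction_space not in ("delta", "atom_fraction"):
        raise ValueError(f"unknown correction_space {correction_space!r}")
    delta_methanol = constants.require_delta_methanol()
    df = measurements.copy()
    if "group" not in df.columns:
        mapping = mapping if mapping is not None else default_group_mapping()
        df["group"] = [mapping.get(b, Group.UNASSIGNED).value for b in df["biomarker"]]
    df["n_carbon"] = [carbon_count(b) for b in df["biomarker"]]

    def to_atom_fraction(sub: pd.DataFrame) -> np.ndarray:
        delta_fame = sub["delta13C_fame"].to_numpy(dtype=float)
        n = sub["n_carbon"].to_numpy(dtype=float)
        if correction_space == "delta":
            delta_plfa = correct_fame_to_plfa(delta_fame, n, delta_methanol)
            return delta_to_atom_fraction(delta_plfa, constants)
        f_fame = delta_to_atom_fraction(delta_fame, constants)
        return correct_fame_atom_fraction(f_fame, n, delta_methanol, constants)

    control_ids = [t for t, d in designs.items() if d.klass is TreatmentClass.CONTROL]
    if not control_ids:
        raise ValueError("design contains no control treatment")
    control = df[df["treatment_id"].isin(control_ids)]
    if control.empty:
        raise ValueError("no control-treatment measurements found")
    if control["delta13C_fame"].isna().any():
        raise ValueError("control measurements need δ¹³C values")
    control = control.assign(f_plfa=to_atom_fraction(control))
    baseline = (
        control.groupby("biomarker")
        .agg(c_baseline=("conc_ugC", "mean"), f_control=("f_plfa", "mean"))
        .reset_index()
    )

    labelled_ids = [t for t, d in designs.items() if d.is_labelled]
    lab = df[df["treatment_id"].isin(labelled_ids)].copy()
    if lab.empty:
        raise ValueError("no labelled-treatment measurements found")
    if lab["delta13C_fame"].isna().any():
        raise ValueError("labelled measurements need δ¹³C values")

    # enrichment sanity gate: label endmembers must sit far above background
    for tid in labelled_ids:
        d = designs[tid]
        f_label = d.residue_atom_fraction[d.labelled_species]
        if atom_fraction_to_delta(f_label, constants) < 1000.0:
            logger.warning(
                "%s: labelled residue at δ¹³C < 1000 ‰ — weak enrichment, "
                "tracer fractions will be noise-sensitive", tid,
            )

    lab = lab.merge(baseline, on="biomarker", how="left")
    imputed = lab["f_control"].isna()
    if imputed.any():
        missing = sorted(lab.loc[imputed, "biomarker"].unique())
        logger.warning(
            "biomarker(s) absent from control, baseline imputed at natural "
            "abundance: %s", ", ".join(missing),
        )
        lab.loc[imputed, "f_control"] = constants.natural_atom_fraction_default
        lab.loc[imputed, "c_baseline"] = 0.0

    lab["f_plfa"] = to_atom_fraction(lab)
    lab["f_label"] = [
        designs[t].residue_atom_fraction[designs[t].labelled_species]
        for t in lab["treatment_id"]
    ]
    f, (flag_low, flag_high) = tracer_fraction(
        lab["f_plfa"].to_numpy(), lab["f_control"].to_numpy(), lab["f_label"].to_numpy()
    )
    lab["f_tracer"] = f
    lab["labelled_c_fraction"] = [designs[t].labelled_c_fraction for t in lab["treatment_id"]]
    lab["klass"] = [designs[t].klass.value for t in lab["treatment_id"]]
    tracer_c = lab["conc_ugC"].to_numpy() * f
    is_nonmix = (lab["klass"] == TreatmentClass.NON_MIX.value).to_numpy()
    c_plant = np.where(
        is_nonmix, tracer_c / lab["labelled_c_fraction"].to_numpy(), tracer_c
    )
    lab["c_plant"] = c_plant
    lab["c_total"] = lab["conc_ugC"]

    # per-sample mass balance is only defined where the tracer sees the whole
    # residue input (non-mixture samples)
    nm = lab[is_nonmix].copy()
    plant_adj, base_eff, som, clip_bal = _balance_pools(
        nm["c_total"], nm["c_baseline"], nm["c_plant"]
    )
    nm["c_plant"], nm["c_baseline"], nm["c_som"] = plant_adj, base_eff, som
    nm["flags"] = _flags_join(
        ("clipped_low", flag_low[is_nonmix] | clip_bal),
        ("clipped_high", flag_high[is_nonmix]),
        ("baseline_imputed", imputed.to_numpy()[is_nonmix]),
    )

    mx = lab[~is_nonmix].copy()
    mx["c_som"] = np.nan
    mx["flags"] = _flags_join(
        ("clipped_low", flag_low[~is_nonmix]),
        ("clipped_high", flag_high[~is_nonmix]),
        ("baseline_imputed", imputed.to_numpy()[~is_nonmix]),
    )
    keep = [
        "sample_id", "treatment_id", "replicate", "biomarker", "group",
        "c_total", "c_baseline", "c_plant", "c_som", "f_tracer", "flags",
    ]
    sample_biomarker = pd.concat([nm[keep], mx[keep]], ignore_index=True)

    # ---- replicate-level table: non-mixtures as-is, mixture assembled ----
    pools = ["c_total", "c_baseline", "c_plant", "c_som"]
    _join = lambda s: ";".join(sorted({f for v in s if v for f in str(v).split(";")}))

    def add_levels(frame: pd.DataFrame) -> pd.DataFrame:
        """Expand a per-(treatment, replicate, biomarker) frame into the
        long biomarker/group/total levels (columns: treatment_id, species,
        replicate, level, key, pools, flags)."""
        keys = ["treatment_id", "species", "replicate"]
        bio = frame.rename(columns={"biomarker": "key"})[keys + ["key", *pools, "flags"]].copy()
        bio.insert(3, "level", "biomarker")
        grp = frame.groupby(keys + ["group"], as_index=False)[pools].sum()
        grp = grp.rename(columns={"group": "key"})
        grp.insert(3, "level", "group")
        grp["flags"] = ""
        tot = frame.groupby(keys, as_index=False).agg({**{p: "sum" for p in pools}, "flags": _join})
        tot["key"] = "total"
        tot.insert(3, "level", "total")
        cols = keys + ["level", "key", *pools, "flags"]
        return pd.concat([bio[cols], grp[cols], tot[cols]], ignore_index=True)

    nonmix_ids = [t for t in labelled_ids if designs[t].klass is TreatmentClass.NON_MIX]
    mix_ids = [t for t in labelled_ids if designs[t].klass is TreatmentClass.MIX]
    nm["species"] = [designs[t].labelled_species for t in nm["treatment_id"]]
    parts = [add_levels(nm)] if len(nm) else []

    breakdown = pd.DataFrame(columns=["replicate", "species", "c_plant", "c_baseline_share"])
    if mix_ids:
        mix_species = sorted({designs[t].labelled_species for t in mix_ids})
        if len(mix_species) != len(mix_ids):
            raise ValueError("mixture sub-treatments must label distinct species")
        sub = mx[mx["treatment_id"].isin(mix_ids)].copy()
        sub["species"] = [designs[t].labelled_species for t in sub["treatment_id"]]
        counts = sub.groupby(["replicate", "biomarker"])["species"].nunique()
        if (counts != len(mix_species)).any():
            raise ValueError(
                "mixture assembly needs every labelled sub-treatment per "
                "replicate × biomarker"
            )
        asm = sub.groupby(["replicate", "biomarker", "group"], as_index=False).agg(
            c_total=("c_total", "mean"),
            c_baseline=("c_baseline", "first"),
            c_plant=("c_plant", "sum"),
            flags=("flags", _join),
        )
        plant_adj, base_eff, som, clip_bal = _balance_pools(
            asm["c_total"], asm["c_baseline"], asm["c_plant"]
        )
        asm["c_plant"], asm["c_baseline"], asm["c_som"] = plant_adj, base_eff, som
        if clip_bal.any():
            extra = np.where(clip_bal, "clipped_low", "")
            asm["flags"] = [_join([a, b]) for a, b in zip(asm["flags"], extra)]
        asm["treatment_id"] = MIXTURE_ID
        asm["species"] = "mixture"
        parts.append(add_levels(asm))

        breakdown = sub.groupby(["replicate", "species"], as_index=False).agg(
            c_plant=("c_plant", "sum"), c_baseline_share=("c_baseline", "sum")
        )
        breakdown["c_baseline_share"] /= len(mix_species)

    replicate = pd.concat(parts, ignore_index=True)
    return PartitionTables(
        sample_biomarker=sample_biomarker,
        replicate=replicate,
        mixture_breakdown=breakdown,
        baseline=baseline,
    )
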