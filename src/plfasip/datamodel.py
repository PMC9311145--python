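"""Core record types for the residue-mixture PLFA-SIP experiment.

The experiment amends soil microcosms with crop residues at a fixed
carbon rate.  Treatments are either *pure* (all unlabelled residue of a
single species), *non-mixture* (25 % of added C as ¹³C-labelled residue
plus 75 % unlabelled residue of the same species), *mixture* (25 % of
added C as one labelled species plus 75 % from the other three species,
unlabelled), or an unamended *control*.  ``TreatmentDesign`` captures
one treatment's composition; measurement rows, isotope constants and
derived results have their own records below.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

from .biomarkers import Group


class TreatmentClass(str, Enum):
    PURE = "pure"
    NON_MIX = "non_mix"
    MIX = "mix"
    CONTROL = "control"


class EffectClass(str, Enum):
    """Mixture outcome relative to the average of monoculture treatments."""

    SYNERGISTIC = "synergistic"
    ANTAGONISTIC = "antagonistic"
    ADDITIVE = "additive"


@dataclass(frozen=True)
class TreatmentDesign:
    """Composition of one treatment.

    Parameters
    ----------
    treatment_id
        Short label, e.g. ``"NB"`` (non-mix buckwheat) or ``"control"``.
    klass
        Treatment class (pure / non_mix / mix / control).
    species_c_share
        Fraction of added C supplied by each species; sums to 1 for
        amended treatments, empty for the control.
    labelled_species
        The species supplied as ¹³C-labelled residue, or ``None``.
    labelled_c_fraction
        Fraction of total added C supplied as labelled residue
        (0.25 for non-mix and mix treatments, 0 otherwise).
    residue_atom_fraction
        Atom fraction ¹³C of each species' residue bulk C
        (atom % / 100; natural abundance is about 0.0108).
    residue_cn
        C:N ratio of each species' residue as added.
    c_rate
        Added C, mg C per g dry soil (1.0 in the reference design).
    """

    treatment_id: str
    klass: TreatmentClass
    species_c_share: dict[str, float] = field(default_factory=dict)
    labelled_species: str | None = None
    labelled_c_fraction: float = 0.0
    residue_atom_fraction: dict[str, float] = field(default_factory=dict)
    residue_cn: dict[str, float] = field(default_factory=dict)
    c_rate: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.labelled_c_fraction <= 1.0:
            raise ValueError(
                f"{self.treatment_id}: labelled_c_fraction must be in [0, 1]"
            )
        if self.klass is TreatmentClass.CONTROL:
            if self.species_c_share:
                raise ValueError(f"{self.treatment_id}: control has no added residue")
            return
        shares = self.species_c_share
        if not shares:
            raise ValueError(f"{self.treatment_id}: amended treatment needs C shares")
        if any(not 0.0 <= v <= 1.0 for v in shares.values()):
            raise ValueError(f"{self.treatment_id}: C shares must be in [0, 1]")
        if not math.isclose(sum(shares.values()), 1.0, abs_tol=1e-9):
            raise ValueError(f"{self.treatment_id}: C shares must sum to 1")
        if self.labelled_c_fraction > 0 and self.labelled_species is None:
            raise ValueError(f"{self.treatment_id}: labelled fraction without species")
        if self.klass is TreatmentClass.MIX and self.labelled_species is not None:
            share = shares.get(self.labelled_species, 0.0)
            if not math.isclose(share, self.labelled_c_fraction, abs_tol=1e-9):
                raise ValueError(
                    f"{self.treatment_id}: in a mixture the labelled species' share "
                    "must equal labelled_c_fraction"
                )

    @property
    def is_labelled(self) -> bool:
        return self.labelled_c_fraction > 0 and self.labelled_species is not None


@dataclass(frozen=True)
class IsotopeConstants:
    """Constants of the δ¹³C scale and of FAME derivatization.

    ``delta_methanol`` (the δ¹³C of the derivatization methanol) has no
    default: instrument logs must supply it, and operations that need it
    raise if it is missing rather than silently assuming 0 ‰.
    ``natural_atom_fraction_default`` is the background atom fraction
    used for biomarkers absent from the control soil; the default is
    derived from δ¹³C = −28 ‰ (a C3-dominated soil).
    """

    r_pdb: float = 0.01118
    delta_methanol: float | None = None
    natural_atom_fraction_default: float = 0.01118 * (1 - 28e-3) / (1 + 0.01118 * (1 - 28e-3))

    def __post_init__(self) -> None:
        if self.r_pdb <= 0:
            raise ValueError("r_pdb must be positive")
        if not 0.0 < self.natural_atom_fraction_default < 0.02:
            raise ValueError("natural_atom_fraction_default outside (0, 0.02)")

    def require_delta_methanol(self) -> float:
        if self.delta_methanol is None:
            raise ValueError(
                "delta_methanol is not set; supply the derivatization methanol "
                "δ¹³C in the configuration"
            )
        return self.delta_methanol


@dataclass(frozen=True)
class PLFAMeasurement:
    """One sample × biomarker record from GC-FID (+ optional GC-C-IRMS)."""

    sample_id: str
    treatment_id: str
    replicate: int
    biomarker: str
    conc_ugC: float
    delta13C_fame: float | None = None

    def __post_init__(self) -> None:
        if self.conc_ugC < 0:
            raise ValueError(f"{self.sample_id}/{self.biomarker}: negative concentration")
        if self.delta13C_fame is not None and not math.isfinite(self.delta13C_fame):
            raise ValueError(f"{self.sample_id}/{self.biomarker}: non-finite δ¹³C")


@dataclass(frozen=True)
class PartitionResult:
    """Carbon pools for one sample at one aggregation key (biomarker or group).

    ``c_total ≈ c_baseline + c_plant + c_som`` holds exactly after any
    clipping adjustment has been propagated into the stored pools.
    """

    sample_id: str
    key: str
    c_total: float
    c_baseline: float
    c_plant: float
    c_som: float
    f_tracer: float | None = None
    flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        for name in ("c_total", "c_baseline", "c_plant", "c_som"):
            if getattr(self, name) < -1e-12:
                raise ValueError(f"{self.sample_id}/{self.key}: negative {name}")
        if not math.isclose(
            self.c_total, self.c_baseline + self.c_plant + self.c_som, abs_tol=1e-9
        ):
            raise ValueError(
                f"{self.sample_id}/{self.key}: pools do not sum to total"
            )


@dataclass(frozen=True)
class MixtureEffect:
    """Mixture-vs-average contrast for one response variable."""

    response: str
    mix_mean: float
    avg_nonmix_mean: float
    difference: float
    percent: float
    f_treatment: float
    p_treatment: float
    f_nested: float
    p_nested: float
    effect_class: EffectClass


GROUP_ORDER = [
    Group.GENERAL_BACTERIA,
    Group.GRAM_POSITIVE,
    Group.GRAM_NEGATIVE,
    Group.FUNGI,
    Group.PROTOZOA,
    Group.UNASSIGNED,
]
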