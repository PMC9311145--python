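"""Two-pool mixing partition: unit checks, mass balance and full-chain oracle."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from plfasip import (
    Group,
    IsotopeConstants,
    TreatmentClass,
    TreatmentDesign,
    added_13c,
    aggregate_by_group,
    default_design,
    mixture_cn,
    paper_like_preset,
    partition_experiment,
    plant_derived_c,
    simulate_experiment,
    som_derived,
    sum_species_contributions,
    total_from_pools,
    tracer_fraction,
)


def _nonmix(labelled_fraction=0.25) -> TreatmentDesign:
    return TreatmentDesign(
        treatment_id="NB",
        klass=TreatmentClass.NON_MIX,
        species_c_share={"buckwheat": 1.0},
        labelled_species="buckwheat",
        labelled_c_fraction=labelled_fraction,
        residue_atom_fraction={"buckwheat": 0.067},
        residue_cn={"buckwheat": 10.0},
    )


def _mix() -> TreatmentDesign:
    species = ["buckwheat", "clover", "radish", "sunflower"]
    return TreatmentDesign(
        treatment_id="MB",
        klass=TreatmentClass.MIX,
        species_c_share={s: 0.25 for s in species},
        labelled_species="buckwheat",
        labelled_c_fraction=0.25,
        residue_atom_fraction={"buckwheat": 0.067},
        residue_cn={"buckwheat": 10.0, "clover": 30.0, "radish": 21.0, "sunflower": 22.0},
    )


class TestTracerFraction:
    def test_unlabelled_endmember_gives_zero(self):
        f, flags = tracer_fraction(0.0110, 0.0110, 0.0668)
        assert f == 0.0 and not flags

    def test_fully_labelled_endmember_gives_one(self):
        f, flags = tracer_fraction(0.0668, 0.0110, 0.0668)
        assert f == 1.0 and not flags

    def test_midpoint_of_endmembers(self):
        f, _ = tracer_fraction(0.0389, 0.0110, 0.0668)
        assert f == pytest.approx(0.5)

    def test_clipping_flags(self):
        f_low, flags_low = tracer_fraction(0.0100, 0.0110, 0.0668)
        assert f_low == 0.0 and flags_low == {"clipped_low"}
        f_high, flags_high = tracer_fraction(0.0700, 0.0110, 0.0668)
        assert f_high == 1.0 and flags_high == {"clipped_high"}

    def test_degenerate_endmembers_error(self):
        with pytest.raises(ValueError, match="endmember"):
            tracer_fraction(0.02, 0.0110, 0.0110)


class TestPlantDerivedC:
    def test_zero_tracer_gives_zero(self):
        assert plant_derived_c(2.0, 0.0, _nonmix()) == 0.0
        assert plant_derived_c(2.0, 0.0, _mix()) == 0.0

    def test_nonmix_rescales_by_labelled_fraction(self):
        assert plant_derived_c(2.0, 0.10, _nonmix()) == pytest.approx(0.8)

    def test_mix_contribution_not_rescaled(self):
        assert plant_derived_c(2.0, 0.10, _mix()) == pytest.approx(0.2)

    def test_zero_labelled_fraction_errors(self):
        design = TreatmentDesign(
            treatment_id="PB",
            klass=TreatmentClass.PURE,
            species_c_share={"buckwheat": 1.0},
        )
        with pytest.raises(ValueError):
            plant_derived_c(2.0, 0.1, design)

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=2, max_size=8, unique=True))
    def test_monotone_in_tracer_fraction(self, fs):
        out = [plant_derived_c(2.0, f, _nonmix()) for f in sorted(fs)]
        assert all(b >= a for a, b in zip(out, out[1:]))


class TestSpeciesContributions:
    def test_all_zero(self):
        total, _ = sum_species_contributions({s: 0.0 for s in "abcd"})
        assert total == 0.0

    def test_reference_sum(self):
        contributions = {"buckwheat": 1.0, "clover": 2.0, "radish": 1.5, "sunflower": 1.84}
        total, breakdown = sum_species_contributions(contributions)
        assert total == pytest.approx(6.34)
        assert breakdown == contributions

    def test_permutation_invariant(self):
        c = {"a": 0.3, "b": 1.1, "c": 0.7, "d": 0.2}
        t1, _ = sum_species_contributions(dict(sorted(c.items())))
        t2, _ = sum_species_contributions(dict(sorted(c.items(), reverse=True)))
        assert t1 == t2

    def test_missing_species_named(self):
        with pytest.raises(ValueError, match="radish"):
            sum_species_contributions({"buckwheat": 1.0}, ["buckwheat", "radish"])


class TestMassBalance:
    def test_mixture_worked_example(self):
        som, flags = som_derived(17.74, 7.50, 6.34)
        assert som == pytest.approx(3.90)
        assert not flags

    def test_average_nonmixture_worked_example(self):
        som, _ = som_derived(14.05, 7.50, 2.73)
        assert som == pytest.approx(3.82)

    def test_unamended_identity(self):
        som, flags = som_derived(7.50, 7.50, 0.0)
        assert som == 0.0 and not flags

    def test_negative_floored_with_flag(self):
        som, flags = som_derived(7.0, 7.50, 0.2)
        assert som == 0.0 and flags == {"clipped_low"}

    def test_total_reassembles_from_pools(self):
        assert total_from_pools(7.50, 6.34, 3.90) == pytest.approx(17.74)


class TestAggregation:
    def test_single_biomarker_equals_its_group(self):
        df = pd.DataFrame([{
            "sample_id": "s1", "biomarker": "18:2w6",
            "c_total": 2.0, "c_baseline": 1.0, "c_plant": 0.6, "c_som": 0.4,
        }])
        out = aggregate_by_group(df)
        fungi = out[out["group"] == "fungi"].iloc[0]
        assert fungi["c_plant"] == pytest.approx(0.6)

    def test_two_fungal_biomarkers_sum(self):
        df = pd.DataFrame([
            {"sample_id": "s1", "biomarker": "18:2w6",
             "c_total": 2.0, "c_baseline": 0.7, "c_plant": 1.0, "c_som": 0.3},
            {"sample_id": "s1", "biomarker": "18:3w3",
             "c_total": 1.8, "c_baseline": 0.5, "c_plant": 0.95, "c_som": 0.35},
        ])
        out = aggregate_by_group(df)
        fungi = out[out["group"] == "fungi"].iloc[0]
        assert fungi["c_plant"] == pytest.approx(1.95)

    def test_grand_total_conserves_groups_plus_unassigned(self):
        rng = np.random.default_rng(4)
        biomarkers = ["16:0", "i15:0", "18:2w6", "19:1w8"]  # last one unassigned
        df = pd.DataFrame({
            "sample_id": "s1",
            "biomarker": biomarkers,
            "c_total": rng.random(4) + 1,
            "c_baseline": rng.random(4),
            "c_plant": rng.random(4),
            "c_som": rng.random(4),
        })
        out = aggregate_by_group(df)
        named = out[(out["group"] != "total") & (out["group"] != Group.UNASSIGNED.value)]
        unassigned = out[out["group"] == Group.UNASSIGNED.value]
        grand = out[out["group"] == "total"]
        for pool in ("c_total", "c_baseline", "c_plant", "c_som"):
            assert named[pool].sum() + unassigned[pool].sum() == pytest.approx(
                grand[pool].iloc[0], abs=1e-9
            )

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            aggregate_by_group(pd.DataFrame())


class TestDesignArithmetic:
    @pytest.mark.parametrize(
        "treatment_id, expected",
        [("NB", 0.0168), ("NC", 0.0195), ("NR", 0.0195), ("NS", 0.0200),
         ("MB", 0.0168), ("MC", 0.0195)],
    )
    def test_added_13c_reference_design(self, treatment_id, expected):
        designs = {d.treatment_id: d for d in default_design()}
        assert added_13c(designs[treatment_id]) == expected

    def test_added_13c_control_errors(self):
        control = TreatmentDesign("control", TreatmentClass.CONTROL, c_rate=0.0)
        with pytest.raises(ValueError):
            added_13c(control)

    def test_mixture_cn_single_species(self):
        assert mixture_cn(_nonmix()) == pytest.approx(10.0)

    def test_mixture_cn_equal_shares_harmonic(self):
        design = TreatmentDesign(
            treatment_id="M", klass=TreatmentClass.PURE,
            species_c_share={s: 0.25 for s in "abcd"},
            residue_cn={"a": 10.0, "b": 32.0, "c": 18.0, "d": 19.0},
        )
        # 4 / (1/10 + 1/32 + 1/18 + 1/19)
        assert mixture_cn(design) == pytest.approx(16.706, abs=5e-3)

    def test_mixture_cn_identical_components(self):
        design = TreatmentDesign(
            treatment_id="M", klass=TreatmentClass.PURE,
            species_c_share={s: 0.25 for s in "abcd"},
            residue_cn={s: 17.0 for s in "abcd"},
        )
        assert mixture_cn(design) == pytest.approx(17.0)

    def test_mixture_cn_nonpositive_errors(self):
        design = TreatmentDesign(
            treatment_id="M", klass=TreatmentClass.PURE,
            species_c_share={"a": 1.0}, residue_cn={"a": 0.0},
        )
        with pytest.raises(ValueError):
            mixture_cn(design)

    def test_reference_mixture_cn_rounds_to_printed_value(self):
        designs = {d.treatment_id: d for d in default_design()}
        for tid in ("MB", "MC", "MR", "MS"):
            assert mixture_cn(designs[tid]) == pytest.approx(17.0, abs=1.0)


def test_full_chain_matches_hand_calculation():
    """Three-biomarker toy: correction → conversion → mixing → scaling,
    checked against a spreadsheet-style calculation written out inline."""
    r_pdb = 0.01118
    delta_meoh = -40.0
    delta_nat = -28.0
    f_label = 0.067

    def f_of_delta(d):
        r = r_pdb * (1 + d / 1000.0)
        return r / (1 + r)

    def delta_of_f(f):
        return (f / (1 - f) / r_pdb - 1) * 1000.0

    f_nat = f_of_delta(delta_nat)
    biomarkers = {"16:0": 16, "i15:0": 15, "18:2w6": 18}
    baseline_conc = {"16:0": 1.0, "i15:0": 0.8, "18:2w6": 0.6}
    sample_conc = {"16:0": 2.0, "i15:0": 1.2, "18:2w6": 1.5}
    true_f_tracer = {"16:0": 0.05, "i15:0": 0.02, "18:2w6": 0.08}

    rows = []
    for rep in (1, 2):
        for b, n in biomarkers.items():
            delta_fame = (n * delta_nat + delta_meoh) / (n + 1)
            rows.append({"sample_id": f"control-r{rep}", "treatment_id": "control",
                         "replicate": rep, "biomarker": b,
                         "conc_ugC": baseline_conc[b], "delta13C_fame": delta_fame})
    expected = {}
    for b, n in biomarkers.items():
        f_sample = f_nat + true_f_tracer[b] * (f_label - f_nat)
        delta_fame = (n * delta_of_f(f_sample) + delta_meoh) / (n + 1)
        rows.append({"sample_id": "NB-r1", "treatment_id": "NB", "replicate": 1,
                     "biomarker": b, "conc_ugC": sample_conc[b],
                     "delta13C_fame": delta_fame})
        plant = sample_conc[b] * true_f_tracer[b] / 0.25
        expected[b] = {
            "c_plant": plant,
            "c_som": sample_conc[b] - baseline_conc[b] - plant,
        }

    designs = {
        "NB": _nonmix(),
        "control": TreatmentDesign("control", TreatmentClass.CONTROL, c_rate=0.0),
    }
    constants = IsotopeConstants(delta_methanol=delta_meoh)
    tables = partition_experiment(pd.DataFrame(rows), designs, constants)
    out = tables.sample_biomarker.set_index("biomarker")
    for b in biomarkers:
        assert out.loc[b, "c_plant"] == pytest.approx(expected[b]["c_plant"], abs=1e-6)
        assert out.loc[b, "c_som"] == pytest.approx(expected[b]["c_som"], abs=1e-6)
        assert out.loc[b, "f_tracer"] == pytest.approx(true_f_tracer[b], abs=1e-9)


class TestPipelineBalance:
    def test_conservation_on_noisy_experiment(self, noisy_experiment):
        sim = noisy_experiment
        tables = partition_experiment(sim.measurements, sim.designs, sim.config.constants())
        nm = tables.sample_biomarker.dropna(subset=["c_som"])
        residual = nm["c_total"] - (nm["c_baseline"] + nm["c_plant"] + nm["c_som"])
        assert np.abs(residual).max() < 1e-9
        rep = tables.replicate
        residual_rep = rep["c_total"] - (rep["c_baseline"] + rep["c_plant"] + rep["c_som"])
        assert np.abs(residual_rep).max() < 1e-9

    def test_mixture_assembly_sums_and_averages(self, noiseless_partition):
        tables = noiseless_partition
        rep = tables.replicate
        mix_total = rep[(rep.treatment_id == "MIX") & (rep.level == "total")]
        # assembled mixture plant C is the sum of the four species contributions
        bd = tables.mixture_breakdown
        for r, sub in bd.groupby("replicate"):
            row = mix_total[mix_total.replicate == r].iloc[0]
            assert sub["c_plant"].sum() == pytest.approx(row["c_plant"], abs=1e-9)
            assert sub["c_baseline_share"].sum() == pytest.approx(row["c_baseline"], abs=1e-9)

    def test_baseline_imputed_for_biomarker_missing_from_control(self, noiseless_experiment):
        sim = noiseless_experiment
        meas = sim.measurements
        trimmed = meas[~((meas.treatment_id == "control") & (meas.biomarker == "20:4w6"))]
        tables = partition_experiment(trimmed, sim.designs, sim.config.constants())
        rows = tables.sample_biomarker
        flagged = rows[rows.biomarker == "20:4w6"]
        assert (flagged["flags"].str.contains("baseline_imputed")).all()
        assert (flagged["c_baseline"] == 0).all()


def test_design_symmetry_under_exchangeable_species():
    """With exchangeable species (equal label strength and assimilation),
    every mixture sub-treatment contributes equally and the assembled
    mixture reproduces synergy × average exactly at zero noise."""
    preset = paper_like_preset(seed=3, noise_sd_conc=0.0, noise_sd_delta=0.0)
    species = ["buckwheat", "clover", "radish", "sunflower"]
    exchangeable_assim = {
        (sp, g): np.mean([preset.assimilation_ugC[(s, g)] for s in species])
        for sp in species
        for g in {k[1] for k in preset.assimilation_ugC}
    }
    preset.assimilation_ugC = exchangeable_assim
    for d in preset.design:
        if d.is_labelled:
            d.residue_atom_fraction[d.labelled_species] = 0.078
    sim = simulate_experiment(preset)
    tables = partition_experiment(sim.measurements, sim.designs, sim.config.constants())
    bd = tables.mixture_breakdown
    spread = bd.groupby("replicate")["c_plant"].agg(lambda s: s.max() - s.min())
    assert spread.max() < 1e-9
    rep = tables.replicate
    mix_plant = rep[(rep.treatment_id == "MIX") & (rep.level == "total")]["c_plant"].mean()
    nonmix_plant = (
        rep[(rep.treatment_id != "MIX") & (rep.level == "total")]
        .groupby("treatment_id")["c_plant"].mean().mean()
    )
    assert mix_plant == pytest.approx(
        preset.synergy_multiplier * nonmix_plant, rel=1e-9
    )
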