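"""Tests of the synthetic incubation generator: identities, determinism,
compositional validity and planted structure."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from strawcue.composition import SKELETON_CLASSES, OaComposition
from strawcue.synthetic import (
    CommunityTruth,
    ExperimentDesign,
    GroundTruth,
    atom_fraction_to_delta,
    default_truth,
    generate_asv_tables,
    generate_gene_abundances,
    generate_isotope_samples,
    generate_oa_composition,
)


def _single_cell_truth(co2_13, co2_native, mbc13, mbc_native):
    key = ("CM", 7)
    return GroundTruth(
        co2_13={key: co2_13},
        mbc13={key: mbc13},
        co2_native={key: co2_native},
        mbc_native={key: mbc_native},
        noise_sd_delta=0.0,
        noise_cv_pools=0.0,
    )


class TestIsotopeGenerator:
    def test_zero_noise_f0_sits_at_soil_endmember(self):
        design = ExperimentDesign(treatments=("CM",), timepoints_days=(7,), seed=1)
        truth = _single_cell_truth(co2_13=0.0, co2_native=100.0, mbc13=0.0,
                                   mbc_native=200.0)
        s = generate_isotope_samples(design, truth)
        labeled = s[s["arm"] == "labeled"]
        assert (labeled["delta_co2"] == design.delta_soil_permil).all()

    def test_zero_noise_f1_sits_at_straw_endmember(self):
        design = ExperimentDesign(treatments=("CM",), timepoints_days=(7,), seed=1)
        truth = _single_cell_truth(co2_13=100.0, co2_native=0.0, mbc13=50.0,
                                   mbc_native=0.0)
        s = generate_isotope_samples(design, truth)
        labeled = s[s["arm"] == "labeled"]
        assert labeled["delta_co2"].to_numpy() == pytest.approx(
            np.full(len(labeled), design.delta_straw_permil)
        )

    def test_seed_determinism_across_all_generators(self):
        design = ExperimentDesign(seed=7)
        truth = default_truth(design)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            first = (
                generate_isotope_samples(design, truth),
                generate_asv_tables(design, truth),
                generate_gene_abundances(design, truth),
            )
            second = (
                generate_isotope_samples(design, truth),
                generate_asv_tables(design, truth),
                generate_gene_abundances(design, truth),
            )
        pd.testing.assert_frame_equal(first[0], second[0])
        pd.testing.assert_frame_equal(first[1][0].counts, second[1][0].counts)
        pd.testing.assert_frame_equal(first[1][1].counts, second[1][1].counts)
        pd.testing.assert_frame_equal(first[2], second[2])

    def test_truth_invariants(self):
        design = ExperimentDesign()
        truth = default_truth(design)
        for trt, day in design.cells:
            c = truth.true_cue(trt, day)
            m13, c13 = truth.mbc13[(trt, day)], truth.co2_13[(trt, day)]
            assert c == pytest.approx(m13 / (m13 + c13))
            assert 0 <= truth.true_f_co2(trt, day) <= 1
            assert 0 <= truth.true_f_mbc(trt, day) <= 1

    def test_negative_noise_rejected(self):
        design = ExperimentDesign()
        with pytest.raises(ValueError):
            default_truth(design, noise_sd_delta=-1.0)

    def test_atom_fraction_mode(self):
        # natural abundance ~1.11% 13C maps to delta ~ 0 permil
        assert atom_fraction_to_delta(0.0110566) == pytest.approx(0.0, abs=2.0)
        d = ExperimentDesign(atom_fraction_straw=0.02)
        assert d.delta_straw_permil > 700  # strongly enriched


class TestAsvGenerator:
    def test_null_effects_give_no_treatment_signal(self):
        design = ExperimentDesign(
            treatments=("Ctrl", "CM"), timepoints_days=(7,), n_reps_community=12,
            seed=3,
        )
        truth = default_truth(
            design,
            community=CommunityTruth(
                n_asvs_bacterial=80, n_asvs_fungal=40, effect_sizes={},
                latent_loading=0.0,
            ),
        )
        bact, _ = generate_asv_tables(design, truth)
        props = bact.counts.div(bact.counts.sum(axis=1), axis=0)
        grp = bact.sample_metadata["treatment"]
        n_sig = 0
        for asv in props.columns:
            a = props.loc[grp == "Ctrl", asv]
            b = props.loc[grp == "CM", asv]
            if stats.mannwhitneyu(a, b).pvalue < 0.01:
                n_sig += 1
        assert n_sig <= 0.05 * props.shape[1]

    def test_planted_module_members_correlate(self):
        design = ExperimentDesign(timepoints_days=(7,), seed=5)  # 24 samples
        ct = CommunityTruth(
            n_asvs_bacterial=60, n_asvs_fungal=30, latent_loading=0.9,
            module_size_bacterial=7, module_size_fungal=3, effect_sizes={},
        )
        truth = default_truth(design, community=ct)
        bact, fungi = generate_asv_tables(design, truth)
        combined = pd.concat(
            [
                bact.counts.div(bact.counts.sum(axis=1), axis=0),
                fungi.counts.div(fungi.counts.sum(axis=1), axis=0),
            ],
            axis=1,
        )
        members = [a for a, m in ct.planted_modules.items() if m == 1]
        others = [c for c in combined.columns if c not in ct.planted_modules]
        rho = combined.corr(method="spearman")
        within = rho.loc[members, members].to_numpy()
        within_mean = within[np.triu_indices(len(members), 1)].mean()
        cross_mean = rho.loc[members, others].to_numpy().mean()
        assert within_mean > cross_mean + 0.3

    def test_ascomycota_enriched_under_cm(self, asv_pair):
        _, fungi = asv_pair
        props = fungi.counts.div(fungi.counts.sum(axis=1), axis=0)
        asco = props[fungi.taxonomy.index[fungi.taxonomy["phylum"] == "Ascomycota"]]
        total = asco.sum(axis=1)
        meta = fungi.sample_metadata
        assert (
            total[meta["treatment"] == "CM"].mean()
            > total[meta["treatment"] == "Ctrl"].mean()
        )

    def test_compositional_validity(self, asv_pair):
        for table in asv_pair:
            vals = table.counts.to_numpy()
            assert (vals >= 0).all()
            assert np.issubdtype(vals.dtype, np.integer)
            props = table.counts.div(table.counts.sum(axis=1), axis=0)
            assert props.sum(axis=1).to_numpy() == pytest.approx(
                np.ones(table.n_samples)
            )

    def test_zero_library_size_rejected(self):
        with pytest.raises(ValueError):
            CommunityTruth(library_size_bacterial=0)

    def test_unknown_clade_effect_rejected(self):
        design = ExperimentDesign()
        truth = default_truth(
            design, community=CommunityTruth(effect_sizes={"Nonexistia": {"CM": 1.0}})
        )
        with pytest.raises(ValueError, match="unknown clade"):
            generate_asv_tables(design, truth)


class TestGeneGenerator:
    def test_zero_noise_orderings_exact(self, design):
        truth = default_truth(design)
        truth.genes.noise_cv = 0.0
        genes = generate_gene_abundances(design, truth)
        day7 = genes[genes["timepoint_days"] == 7].groupby("treatment").mean(
            numeric_only=True
        )
        fb = day7["copies_its"] / day7["copies_16s"]
        assert fb["CM"] > fb["Ctrl"]
        by_day = genes.groupby("timepoint_days").mean(numeric_only=True)
        assert by_day.loc[28, "copies_cbhi"] > by_day.loc[7, "copies_cbhi"]
        assert by_day.loc[28, "copies_gh48"] > by_day.loc[7, "copies_gh48"]
        # configured growth factors hold exactly without noise
        assert by_day.loc[28, "copies_cbhi"] / by_day.loc[7, "copies_cbhi"] == (
            pytest.approx(truth.genes.time_factor_cbhi)
        )

    def test_nonpositive_means_rejected(self):
        with pytest.raises(ValueError):
            from strawcue.synthetic import GeneTruth

            GeneTruth(copies_16s=0.0)


class TestOaComposition:
    def test_cm_preset_is_hete_dominant(self, design):
        comps = {c.oa_label: c for c in generate_oa_composition(design)}
        cm = comps["CM"].class_proportions
        assert max(cm, key=cm.get) == "Hete_C"
        lm = comps["LM"].class_proportions
        assert max(lm, key=lm.get) == "Arom_C"
        mm = comps["MM"].class_proportions
        assert mm["Hete_C"] == pytest.approx(mm["Arom_C"])

    def test_proportions_sum_to_one(self, design):
        for comp in generate_oa_composition(design):
            assert sum(comp.class_proportions.values()) == pytest.approx(1.0, abs=1e-9)
            assert sum(comp.group_proportions.values()) == pytest.approx(1.0, abs=1e-9)

    def test_user_preset_not_summing_to_one_rejected(self, design):
        bad = {"CM": {"Hete_C": 0.4, "Arom_C": 0.2, "Alip_C": 0.1, "Alic_C": 0.1}}
        with pytest.raises(ValueError, match="sum"):
            generate_oa_composition(design, presets=bad)

    def test_class_vocabulary_closed(self):
        with pytest.raises(ValueError, match="unknown"):
            OaComposition(
                "X",
                {g: 1.0 / 8 for g in
                 ("lignin", "phenol", "carbohydrate", "saturated hydrocarbon",
                  "unsaturated hydrocarbon", "N-containing",
                  "aromatic hydrocarbon", "poly-aromatic hydrocarbon")},
                {"ester": 1.0},
            )
        _ = SKELETON_CLASSES  # closed vocabulary exported for callers
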