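"""Generator contracts: profile synthesis, rendering, cohort sampling."""

import numpy as np
import pandas as pd
import pytest

from gapatlas import (DomainSpec, Effect, PerturbationSpec, fit_profile,
                      make_embryo_image, make_profile, sample_cohort)
from gapatlas.profiles import EmbryoImage, extract_profile
from gapatlas.synthetic import (DynamicsTable, cohort_boundary_table,
                                cohort_truth_table,
                                default_wildtype_dynamics)


class TestDomainSpec:
    @pytest.mark.parametrize("a,p,amp,steep", [
        (63, 40, 1.0, 1.0),      # edges out of order
        (40, 63, 0.0, 1.0),      # zero amplitude
        (40, 63, 1.5, 1.0),      # amplitude above 1
        (40, 63, 1.0, 0.0),      # zero steepness
        (-2, 63, 1.0, 1.0),      # off the egg
    ])
    def test_invalid_specs_rejected(self, a, p, amp, steep):
        with pytest.raises(ValueError):
            DomainSpec("Kr", "central", a, p, amp, steep)


class TestMakeProfile:
    def test_half_max_crossings_at_domain_edges(self, kr_profile):
        """A symmetric sigmoidal edge crosses half-max at its midpoint."""
        doms = fit_profile(kr_profile, gene="Kr")
        assert len(doms) == 1
        assert doms[0].a_position == pytest.approx(40.0, abs=0.25)
        assert doms[0].p_position == pytest.approx(63.0, abs=0.25)

    def test_empty_domain_list_gives_flat_baseline(self):
        prof, truth = make_profile([], baseline=0.1)
        assert np.allclose(prof.values, 0.1)
        assert truth == []

    def test_merged_same_gene_domains_flagged(self):
        d1 = DomainSpec("gt", "anterior", 20, 45)
        d2 = DomainSpec("gt", "posterior", 40, 70)
        _, truth = make_profile([d1, d2])
        assert all(t["merged"] for t in truth)

    def test_noise_requires_nonnegative_sd(self):
        with pytest.raises(ValueError):
            make_profile([], noise_sd=-0.1)


class TestMakeEmbryoImage:
    def test_render_extract_round_trip(self, kr_profile, kr_image):
        """The extracted strip profile reproduces the generating profile
        up to mask-edge registration error."""
        p = extract_profile(kr_image, normalise=False)
        assert np.abs(p.values - kr_profile.values).max() < 0.05

    def test_constant_dv_modulation_gives_uniform_columns(self, kr_profile):
        emb = make_embryo_image(kr_profile, dv_modulation=lambda v: np.ones_like(v))
        col = emb.image[:, emb.image.shape[1] // 2]
        inside = emb.mask[:, emb.image.shape[1] // 2] > 0
        assert np.ptp(col[inside]) < 1e-12

    def test_fixed_seed_bit_identical(self, kr_profile):
        a = make_embryo_image(kr_profile, seed=7, noise_sd=0.05)
        b = make_embryo_image(kr_profile, seed=7, noise_sd=0.05)
        assert np.array_equal(a.image, b.image)

    def test_degenerate_shape_rejected(self, kr_profile):
        with pytest.raises(ValueError, match="strip"):
            make_embryo_image(kr_profile, shape=(20, 260))


class TestSampleCohort:
    def test_sample_medians_near_ground_truth(self, wildtype_dynamics):
        """With 20 embryos and s.d. 1, per-edge sample medians scatter
        ~0.27 %EL around the table values."""
        coh = sample_cohort(wildtype_dynamics, 20, seed=11,
                            time_classes=("T4",))
        truth = cohort_truth_table(coh)
        errs = []
        for (g, d, e), grp in truth.groupby(["gene", "domain_id", "edge"]):
            med = grp["true_position"].median()
            errs.append(abs(med - wildtype_dynamics.position(g, d, e, "T4")))
        errs = np.asarray(errs)
        assert errs.mean() < 0.35
        assert (errs <= 0.5).mean() >= 0.75
        assert errs.max() < 1.5

    def test_zero_efficacy_matches_wildtype(self, wildtype_dynamics):
        spec = PerturbationSpec("kni", effects=(
            Effect("Kr", "central", "posterior", "expand", 10.0),),
            efficacy=("point", 0.0))
        wt = cohort_truth_table(sample_cohort(wildtype_dynamics, 5, seed=3,
                                              time_classes=("T4",)))
        kd = cohort_truth_table(sample_cohort(wildtype_dynamics, 5, seed=3,
                                              perturbation=spec,
                                              time_classes=("T4",)))
        assert np.allclose(wt["true_position"], kd["true_position"])

    def test_absent_mode_removes_domain_in_all_embryos(self, wildtype_dynamics):
        spec = PerturbationSpec("tll", effects=(
            Effect("hb", "posterior", "anterior", "absent", threshold=0.5),
            Effect("hb", "posterior", "posterior", "absent", threshold=0.5),
        ), efficacy=("point", 1.0))
        coh = sample_cohort(wildtype_dynamics, 8, seed=5, genes=["hb"],
                            perturbation=spec, time_classes=("T4",))
        truth = cohort_truth_table(coh)
        post = truth[truth["domain_id"] == "posterior"]
        assert post["absent"].all()
        ant = truth[truth["domain_id"] == "anterior"]
        assert not ant["absent"].any()

    def test_positions_truncated_to_egg(self):
        dyn = DynamicsTable.from_anchors(
            {("hb", "posterior", "anterior"): [("T1", 99.0), ("T8", 99.0)]},
            sd=5.0)
        coh = sample_cohort(dyn, 50, seed=1)
        truth = cohort_truth_table(coh)
        assert truth["true_position"].between(0, 100).all()

    def test_unknown_perturbed_gene_rejected(self, wildtype_dynamics):
        spec = PerturbationSpec("x", effects=(
            Effect("nope", "central", "posterior", "expand", 5.0),))
        with pytest.raises(ValueError, match="absent from dynamics"):
            sample_cohort(wildtype_dynamics, 3, perturbation=spec)

    def test_fixed_seed_reproducible_different_seed_not(self, wildtype_dynamics):
        a = cohort_truth_table(sample_cohort(wildtype_dynamics, 4, seed=9,
                                             time_classes=("T2",)))
        b = cohort_truth_table(sample_cohort(wildtype_dynamics, 4, seed=9,
                                             time_classes=("T2",)))
        c = cohort_truth_table(sample_cohort(wildtype_dynamics, 4, seed=10,
                                             time_classes=("T2",)))
        pd.testing.assert_frame_equal(a, b)
        assert not np.allclose(a["true_position"], c["true_position"])


class TestRoundTripInvariant:
    def test_rendered_edges_recovered(self, wildtype_dynamics):
        """Render -> extract -> fit recovers ground-truth edges: within
        0.5 %EL noiseless, within 1.5 %EL at intensity noise 0.05."""
        coh = sample_cohort(wildtype_dynamics, 1, seed=21, genes=["Kr"],
                            time_classes=("C12", "T4"), render="image",
                            profile_noise_sd=0.0)
        coh += sample_cohort(wildtype_dynamics, 3, seed=22, genes=["Kr"],
                             time_classes=("T4",), render="image",
                             profile_noise_sd=0.05)
        for i, emb in enumerate(coh):
            tol = 0.5 if i < 2 else 1.5
            img = EmbryoImage(pixels=emb.image, mask=emb.mask, gene="Kr")
            doms = fit_profile(extract_profile(img), gene="Kr")
            assert len(doms) == 1
            truth = {t["edge"]: t["position"] for t in emb.ground_truth}
            assert doms[0].a_position == pytest.approx(truth["anterior"], abs=tol)
            assert doms[0].p_position == pytest.approx(truth["posterior"], abs=tol)


class TestDynamicsTable:
    def test_interpolated_classes_flagged_and_linear(self, wildtype_dynamics):
        t = wildtype_dynamics.table
        row = t[(t.gene == "Kr") & (t.edge == "posterior")
                & (t.time_class == "T3")]
        # C12=63 -> T8=51 over 9 class steps: T3 sits 4 steps in
        assert row["position"].iloc[0] == pytest.approx(63 - 12 * 4 / 9)
        assert bool(row["interpolated"].iloc[0])

    def test_anchor_positions_exact(self, wildtype_dynamics):
        assert wildtype_dynamics.position("Kr", "central", "anterior", "C12") == 40
        assert wildtype_dynamics.position("Kr", "central", "posterior", "C12") == 63
        assert wildtype_dynamics.position("hb", "posterior", "anterior", "T8") == 72
        assert wildtype_dynamics.position("gt", "posterior", "posterior", "T1") == 86
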