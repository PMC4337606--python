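"""RNAi scoring: envelopes, phenotype calls, penetrance, network."""

import numpy as np
import pandas as pd
import pytest

from gapatlas import TRUE_NETWORK, run_synthetic_study
from gapatlas.atlas import aggregate
from gapatlas.reference import rnai_penetrance_counts
from gapatlas.rnai import (InteractionEdge, WtEnvelope, allelic_series,
                           build_envelope, classify_cohort, classify_embryo,
                           infer_network, penetrance, penetrance_percent,
                           posterior_bias)
from gapatlas.synthetic import (DynamicsTable, Effect, PerturbationSpec,
                                cohort_boundary_table,
                                default_wildtype_dynamics, sample_cohort)


def simple_envelope(centre=50.0, half=2.0, gene="Kr", domain="central",
                    tc="T4"):
    rows = []
    for edge, c in (("anterior", centre - 10), ("posterior", centre + 10)):
        rows.append({"gene": gene, "domain_id": domain, "edge": edge,
                     "time_class": tc, "centre": c, "half_width": half,
                     "n": 20, "flags": ""})
    return WtEnvelope(cells=pd.DataFrame(rows), k=2.0)


def embryo_rows(a_pos, p_pos, gene="Kr", domain="central", tc="T4",
                embryo_id="e1"):
    return pd.DataFrame([
        {"embryo_id": embryo_id, "gene": gene, "time_class": tc,
         "domain_id": domain, "edge": "anterior", "position": a_pos,
         "flags": ""},
        {"embryo_id": embryo_id, "gene": gene, "time_class": tc,
         "domain_id": domain, "edge": "posterior", "position": p_pos,
         "flags": ""}])


class TestBuildEnvelope:
    def test_half_width_is_k_times_variability(self):
        tab = pd.DataFrame([{"gene": "Kr", "domain_id": "central",
                             "edge": "posterior", "time_class": "T4",
                             "n": 10, "median": 55.0, "variability": 1.5,
                             "flags": ""}])
        from gapatlas.atlas import SpatioTemporalAtlas
        env = build_envelope(SpatioTemporalAtlas(tab), k=2.0)
        assert env.cells["half_width"].iloc[0] == pytest.approx(3.0)
        env0 = build_envelope(SpatioTemporalAtlas(tab), k=0.0)
        assert env0.cells["half_width"].iloc[0] == 0.0

    def test_envelope_covers_fresh_wildtype_cohort(self):
        """At k=2 the envelope holds ~95% of fresh wild-type boundaries."""
        dyn = default_wildtype_dynamics()
        wt = sample_cohort(dyn, 100, seed=31, time_classes=("T2", "T4"))
        env = build_envelope(aggregate(cohort_boundary_table(wt)))
        fresh = cohort_boundary_table(
            sample_cohort(dyn, 40, seed=32, time_classes=("T2", "T4")))
        inside = [
            abs(r["position"] - env.cell(r["gene"], r["domain_id"],
                                         r["edge"], r["time_class"])["centre"])
            <= env.cell(r["gene"], r["domain_id"], r["edge"],
                        r["time_class"])["half_width"] + 1e-9
            for _, r in fresh.iterrows()]
        assert np.mean(inside) >= 0.93


class TestClassifyEmbryo:
    def test_posterior_expansion_labelled(self):
        env = simple_envelope()
        rec = classify_embryo(embryo_rows(40.0, 66.0), env, "kni")
        assert rec.labels == ("expanded_posterior",)
        assert rec.severity == pytest.approx(6.0)

    def test_inside_envelope_unaffected(self):
        env = simple_envelope()
        rec = classify_embryo(embryo_rows(40.5, 59.5), env, "kni")
        assert rec.labels == ("unaffected",)
        assert not rec.affected

    def test_whole_domain_displacement(self):
        env = simple_envelope()
        rec = classify_embryo(embryo_rows(45.0, 65.0), env, "x")
        assert rec.labels == ("displaced_posterior",)

    def test_absent_domain(self):
        env = simple_envelope()
        rows = embryo_rows(np.nan, np.nan)
        rec = classify_embryo(rows, env, "tll")
        assert rec.labels == ("absent",)
        assert rec.severity == pytest.approx(20.0)  # wild-type width

    def test_retraction_failure_at_pole(self):
        rows = []
        for edge, c in (("anterior", 75.0), ("posterior", 85.0)):
            rows.append({"gene": "hb", "domain_id": "posterior",
                         "edge": edge, "time_class": "T8", "centre": c,
                         "half_width": 2.0, "n": 20, "flags": ""})
        env = WtEnvelope(cells=pd.DataFrame(rows), k=2.0)
        emb = embryo_rows(76.0, 100.0, gene="hb", domain="posterior",
                          tc="T8")
        emb["pole_intensity"] = [0.0, 0.9]
        rec = classify_embryo(emb, env, "hkb")
        assert "retraction_failure" in rec.labels
        emb["pole_intensity"] = [0.0, 0.3]
        rec = classify_embryo(emb, env, "hkb")
        assert "partial_retraction" in rec.labels

    def test_unknown_time_class_rejected(self):
        env = simple_envelope(tc="T4")
        with pytest.raises(KeyError, match="T8"):
            classify_embryo(embryo_rows(40, 60, tc="T8"), env, "x")

    def test_affected_fraction_monotone_in_effect_size(self):
        """Stronger generated expansions affect more embryos."""
        dyn = default_wildtype_dynamics()
        wt = sample_cohort(dyn, 40, seed=41, genes=["Kr"],
                           time_classes=("T4",))
        env = build_envelope(aggregate(cohort_boundary_table(wt)))
        fractions = []
        for delta in (1.0, 6.0, 14.0):
            spec = PerturbationSpec("kni", effects=(
                Effect("Kr", "central", "posterior", "expand", delta),))
            coh = sample_cohort(dyn, 40, seed=42, genes=["Kr"],
                                perturbation=spec, time_classes=("T4",))
            recs = classify_cohort(cohort_boundary_table(coh), env, "kni")
            fractions.append(np.mean([r.affected for r in recs]))
        assert fractions[0] < fractions[1] < fractions[2]


class TestPenetrance:
    @pytest.mark.parametrize("affected,total,expected", [
        (35, 52, 67), (15, 15, 100), (0, 30, 0), (24, 53, 45),
        (7, 18, 39), (1, 3, 33),
    ])
    def test_rounding_half_away_from_zero(self, affected, total, expected):
        assert penetrance_percent(affected, total) == expected

    def test_printed_dataset_percentages_reproduced(self):
        """Every printed penetrance cell follows from its counts by
        half-away-from-zero rounding — except three cells whose published
        integers are inconsistent with their own counts (17/28 printed as
        60%, 24/53 as 46%, 7/18 as 38%; arithmetic gives 61, 45, 39)."""
        counts = rnai_penetrance_counts()
        mismatches = []
        for _, r in counts.iterrows():
            got = penetrance_percent(r.n_affected, r.n_total)
            if got != r.printed_percent:
                mismatches.append((r.stained_gene, r.knockdown_gene, got,
                                   r.printed_percent))
        assert mismatches == [("hb", "gt", 61, 60), ("Kr", "hb", 45, 46),
                              ("Kr", "tll", 39, 38)]

    def test_table_from_records(self):
        env = simple_envelope()
        recs = [classify_embryo(embryo_rows(40, 66, embryo_id=f"a{i}"),
                                env, "kni") for i in range(3)]
        recs += [classify_embryo(embryo_rows(40.5, 60, embryo_id=f"b{i}"),
                                 env, "kni") for i in range(2)]
        tab = penetrance(recs)
        row = tab.iloc[0]
        assert (row.n_affected, row.n_total, row.percent) == (3, 5, 60)

    def test_order_invariance(self):
        env = simple_envelope()
        recs = [classify_embryo(embryo_rows(40, 66, embryo_id=f"e{i}"),
                                env, "kni") for i in range(4)]
        pd.testing.assert_frame_equal(penetrance(recs),
                                      penetrance(list(reversed(recs))))


class TestAllelicSeries:
    def test_severity_tracks_efficacy(self):
        """Displacement proportional to knock-down efficacy yields a
        strong rank correlation between the two (rho >= 0.8)."""
        dyn = DynamicsTable.from_anchors(
            {("hb", "anterior", "anterior"): [("T4", 0.0)],
             ("hb", "anterior", "posterior"): [("T4", 48.0)]}, sd=0.5)
        wt = sample_cohort(dyn, 60, seed=51, time_classes=("T4",))
        env = build_envelope(aggregate(cohort_boundary_table(wt)))
        spec = PerturbationSpec("bcd", effects=(
            Effect("hb", "anterior", "posterior", "displace", 10.0,
                   direction=-1),))
        coh = sample_cohort(dyn, 30, seed=52, perturbation=spec,
                            time_classes=("T4",))
        recs = classify_cohort(cohort_boundary_table(coh), env, "bcd",
                               efficacies={e.embryo_id: e.efficacy
                                           for e in coh})
        series = allelic_series(recs)
        assert series["severity"].is_monotonic_increasing
        assert series.attrs["efficacy_severity_spearman"] >= 0.8

    def test_too_few_affected_rejected(self):
        env = simple_envelope()
        recs = [classify_embryo(embryo_rows(40, 66, embryo_id=f"e{i}"),
                                env, "kni") for i in range(2)]
        with pytest.raises(ValueError, match=">= 3"):
            allelic_series(recs)

    def test_all_unaffected_gives_empty_series(self):
        env = simple_envelope()
        recs = [classify_embryo(embryo_rows(40.2, 60.1, embryo_id=f"e{i}"),
                                env, "kni") for i in range(5)]
        assert allelic_series(recs).empty


class TestInferNetwork:
    def test_strong_repression_from_expansion(self):
        env = simple_envelope()
        recs = [classify_embryo(embryo_rows(40, 70, embryo_id=f"e{i}"),
                                env, "kni") for i in range(26)]
        recs += [classify_embryo(embryo_rows(40.2, 60, embryo_id=f"u{i}"),
                                 env, "kni") for i in range(14)]
        edges = infer_network(recs, env,
                              layout={"kni": [("abdominal", 69.5)]})
        (edge,) = edges
        assert (edge.regulator, edge.target) == ("kni", "Kr")
        assert edge.sign == "repression"
        assert edge.strength == "strong"
        assert edge.penetrance_pct == 65

    def test_subthreshold_penetrance_gives_no_edge(self):
        env = simple_envelope()
        recs = [classify_embryo(embryo_rows(40.2, 60.1, embryo_id=f"e{i}"),
                                env, "gt") for i in range(20)]
        assert infer_network(recs, env) == []

    def test_posterior_bias_by_construction(self):
        def edge(reg, tgt, strength):
            return InteractionEdge(regulator=reg, target=tgt,
                                   sign="repression", strength=strength,
                                   penetrance_pct=80, n_affected=20,
                                   n_total=25, median_severity=8.0)
        edges = [edge("kni", "Kr", "strong"), edge("gt", "kni", "strong"),
                 edge("hb", "gt", "strong")]
        assert posterior_bias(edges) == pytest.approx(2.0)
        assert posterior_bias([]) == 0.0


class TestEndToEndStudy:
    def test_known_network_recovered(self):
        """The full synthetic perturbation experiment recovers every strong
        interaction at the correct sign, with no spurious strong edges."""
        s = run_synthetic_study(seed=3)
        strong = {(e.regulator, e.target, e.sign) for e in s.edges
                  if e.strength == "strong"}
        truth = {(r, t, sign) for r, t, sign, st in TRUE_NETWORK
                 if st == "strong"}
        assert strong == truth
        assert s.posterior_bias > 0

    def test_classification_deterministic(self):
        a = run_synthetic_study(seed=4)
        b = run_synthetic_study(seed=4)
        pd.testing.assert_frame_equal(a.penetrance, b.penetrance)
        assert [e.strength for e in a.edges] == [e.strength for e in b.edges]
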