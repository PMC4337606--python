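"""Widths, shifts, overlaps and cross-dataset convergence times."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gapatlas.atlas import SpatioTemporalAtlas
from gapatlas.metrics import (DomainExtent, boundary_shift, convergence_time,
                              domain_overlap, domain_width)
from gapatlas.reference import load_reference
from gapatlas.timeclasses import TIME_CLASSES


def atlas_from(positions: dict, gene="hb", domain="posterior",
               edge="anterior", var=1.0) -> SpatioTemporalAtlas:
    rows = [{"gene": gene, "domain_id": domain, "edge": edge,
             "time_class": tc, "n": 10, "median": float(p),
             "variability": var, "flags": ""} for tc, p in positions.items()]
    return SpatioTemporalAtlas(pd.DataFrame(rows))


class TestDomainWidth:
    def test_kr_central_at_c12(self):
        """The central Kr domain spans 40-63% A-P at C12: width 23 %EL."""
        ref = load_reference("mab")
        sub = ref[(ref.gene == "Kr") & (ref.time_class == "C12")]
        pos = dict(zip(sub.edge, sub.position))
        ext = DomainExtent("Kr", "central", "C12", pos["anterior"],
                           pos["posterior"])
        assert domain_width(ext) == 23.0

    def test_cad_posterior_stripe(self):
        """The late posterior cad stripe at 79-90% A-P is 11 %EL wide."""
        ref = load_reference("mab")
        sub = ref[(ref.gene == "cad") & (ref.time_class == "T5")]
        pos = dict(zip(sub.edge, sub.position))
        assert domain_width(DomainExtent("cad", "posterior", "T5",
                                         pos["anterior"], pos["posterior"])) == 11.0

    def test_degenerate_and_invalid(self):
        assert domain_width(DomainExtent("x", "central", "T1", 50, 50)) == 0
        with pytest.raises(ValueError):
            DomainExtent("x", "central", "T1", np.nan, 60)
        with pytest.raises(ValueError):
            DomainExtent("x", "central", "T1", 60, 50)


class TestBoundaryShift:
    def test_posterior_hb_anterior_edge_shift(self):
        """Posterior hb anterior border: 90% (C13) to 72% (T8) = +18 %EL
        anterior shift."""
        ref = load_reference("mab")
        sub = ref[(ref.gene == "hb") & (ref.domain_id == "posterior")
                  & (ref.edge == "anterior")]
        atlas = atlas_from(dict(zip(sub.time_class, sub.position)))
        rec = boundary_shift(atlas, "hb", "posterior", "anterior",
                             "C13", "T8")
        assert rec.shift == 18.0

    def test_zero_for_stationary_boundary(self):
        atlas = atlas_from({"T1": 50.0, "T8": 50.0})
        assert boundary_shift(atlas, "hb", "posterior", "anterior",
                              "T1", "T8").shift == 0.0

    def test_missing_cell_named_in_error(self):
        atlas = atlas_from({"T1": 50.0})
        with pytest.raises(KeyError, match="T8"):
            boundary_shift(atlas, "hb", "posterior", "anterior", "T1", "T8")

    @given(st.lists(st.floats(0, 100), min_size=3, max_size=3))
    @settings(max_examples=50, deadline=None)
    def test_antisymmetry_and_additivity(self, positions):
        atlas = atlas_from(dict(zip(["C13", "T4", "T8"], positions)))

        def s(a, b):
            return boundary_shift(atlas, "hb", "posterior", "anterior",
                                  a, b).shift

        assert s("C13", "T8") == pytest.approx(-s("T8", "C13"))
        assert s("C13", "T4") + s("T4", "T8") == pytest.approx(s("C13", "T8"))


class TestDomainOverlap:
    def kr_kni_extents(self):
        return (DomainExtent("Kr", "central", "C12", 40, 63),
                DomainExtent("kni", "abdominal", "C12", 61, 78))

    def test_kr_kni_overlap_at_c12(self):
        """Central Kr [40,63] and abdominal kni [61,78] share 2 %EL."""
        a, b = self.kr_kni_extents()
        assert domain_overlap(a, b) == 2.0
        assert domain_overlap(b, a) == 2.0

    def test_disjoint_and_mismatched_class(self):
        a = DomainExtent("Kr", "central", "C12", 40, 50)
        b = DomainExtent("gt", "posterior", "C12", 73, 100)
        assert domain_overlap(a, b) == 0.0
        with pytest.raises(ValueError):
            domain_overlap(a, DomainExtent("gt", "posterior", "T4", 73, 100))

    @given(st.lists(st.floats(0, 100), min_size=4, max_size=4))
    @settings(max_examples=50, deadline=None)
    def test_overlap_bounded_by_widths(self, vals):
        a1, a2, b1, b2 = vals
        a = DomainExtent("x", "central", "T1", min(a1, a2), max(a1, a2))
        b = DomainExtent("y", "central", "T1", min(b1, b2), max(b1, b2))
        ov = domain_overlap(a, b)
        assert 0 <= ov <= min(a.width, b.width) + 1e-9


class TestConvergenceTime:
    def test_identical_atlases_converge_immediately(self):
        a = atlas_from({"T1": 50, "T4": 48, "T8": 45})
        rec = convergence_time(a, a, "hb", "posterior", "anterior",
                               tolerance=1.0)
        assert rec.convergence_class == "T1"

    def test_constructed_convergence_at_t6(self):
        """Two trajectories closing from 10 %EL apart to coincidence at T6."""
        a = atlas_from({c: 60.0 for c in ["T1", "T2", "T3", "T4", "T5",
                                          "T6", "T7", "T8"]})
        gaps = {"T1": 10, "T2": 8, "T3": 6, "T4": 4, "T5": 3, "T6": 1,
                "T7": 0.5, "T8": 0.2}
        b = atlas_from({c: 60.0 + g for c, g in gaps.items()})
        rec = convergence_time(a, b, "hb", "posterior", "anterior",
                               tolerance=2.0)
        assert rec.convergence_class == "T6"

    def test_transient_contact_reported_separately(self):
        a = atlas_from({"T1": 50, "T2": 50, "T3": 50, "T4": 50})
        b = atlas_from({"T1": 50.5, "T2": 55, "T3": 50.5, "T4": 50.5})
        rec = convergence_time(a, b, "hb", "posterior", "anterior",
                               tolerance=1.0)
        assert rec.first_contact_class == "T1"
        assert rec.convergence_class == "T3"

    def test_no_shared_classes_rejected(self):
        a = atlas_from({"T1": 50})
        b = atlas_from({"T8": 50})
        with pytest.raises(ValueError, match="shared"):
            convergence_time(a, b, "hb", "posterior", "anterior", 1.0)

    @given(st.lists(st.floats(0, 100), min_size=4, max_size=4),
           st.lists(st.floats(0, 100), min_size=4, max_size=4))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_tolerance(self, pa, pb):
        classes = ["T1", "T3", "T5", "T7"]
        a = atlas_from(dict(zip(classes, pa)))
        b = atlas_from(dict(zip(classes, pb)))
        order = {c: i for i, c in enumerate(TIME_CLASSES)}

        def cls_at(tol):
            rec = convergence_time(a, b, "hb", "posterior", "anterior", tol)
            return (order[rec.convergence_class]
                    if rec.convergence_class else np.inf)

        assert cls_at(5.0) >= cls_at(20.0)

    def test_auto_tolerance_uses_variability(self):
        a = atlas_from({"T1": 50, "T8": 50}, var=3.0)
        b = atlas_from({"T1": 52, "T8": 52}, var=0.5)
        rec = convergence_time(a, b, "hb", "posterior", "anterior", "auto")
        assert rec.convergence_class == "T1"  # within max(3.0, 0.5)
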