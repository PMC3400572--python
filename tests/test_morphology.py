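"""Morphology construction, SWC round trips, and the discretization rule."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dendsum.biophysics import MembraneParams
from dendsum.morphology import (
    Morphology,
    MorphologyError,
    Section,
    SectionKind,
    SWCFormatError,
    build_ball_and_stick,
    discretize,
    lambda_f,
    load_swc,
    write_swc,
)

MEM = MembraneParams()


class TestBallAndStick:
    def test_default_reduced_morphology(self):
        m = build_ball_and_stick(4, 275.0, 1.0, 20.0)
        assert len(m.sections) == 5
        for b in m.basal_ids:
            assert m.path_distance(b) == pytest.approx(275.0)
            assert m.section(b).spine_corrected

    def test_tip_path_distance_excludes_soma(self):
        m = build_ball_and_stick(1, 200.0, 1.0, 20.0)
        assert len(m.sections) == 2
        assert m.path_distance(m.basal_ids[0]) == pytest.approx(200.0)

    def test_identical_dendrites_discretize_identically(self):
        m = discretize(build_ball_and_stick(2, 100.0, 0.8, 15.0), MEM)
        b1, b2 = m.basal_ids
        assert m.nseg[b1] == m.nseg[b2]

    @pytest.mark.parametrize("args", [(0, 275, 1, 20), (4, -1, 1, 20),
                                      (4, 275, 0, 20), (4, 275, 1, 0)])
    def test_invalid_dimensions_rejected(self, args):
        with pytest.raises(MorphologyError):
            build_ball_and_stick(*args)


class TestTreeInvariants:
    def test_single_root_enforced(self):
        secs = [Section(0, None, SectionKind.SOMA, 20, 20),
                Section(1, None, SectionKind.BASAL, 100, 1)]
        with pytest.raises(MorphologyError):
            Morphology(secs)

    def test_dangling_parent_rejected(self):
        secs = [Section(0, None, SectionKind.SOMA, 20, 20),
                Section(1, 7, SectionKind.BASAL, 100, 1)]
        with pytest.raises(MorphologyError):
            Morphology(secs)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(1.0, 300.0), min_size=1, max_size=8),
           st.data())
    def test_path_distance_additivity_on_random_trees(self, lengths, data):
        """Path distance to a tip equals the sum of lengths on its path."""
        secs = [Section(0, None, SectionKind.SOMA, 15, 15)]
        for i, L in enumerate(lengths, start=1):
            parent = data.draw(st.integers(0, i - 1))
            secs.append(Section(i, parent, SectionKind.BASAL, L, 1.0))
        m = Morphology(secs)
        for s in secs[1:]:
            total, cur = 0.0, s
            while cur.parent_id is not None:
                if cur.kind is not SectionKind.SOMA:
                    total += cur.length
                cur = m.section(cur.parent_id)
            assert m.path_distance(s.id) == pytest.approx(total)


class TestSWC:
    def test_three_point_chain(self, tmp_path):
        p = tmp_path / "chain.swc"
        p.write_text("1 3 0 0 0 0.5 -1\n2 3 10 0 0 0.5 1\n3 3 20 0 0 0.5 2\n")
        m = load_swc(p)
        assert len(m.sections) == 1
        assert m.sections[0].length == pytest.approx(20.0)
        assert m.sections[0].diameter == pytest.approx(1.0)

    def test_dangling_parent_named(self, tmp_path):
        p = tmp_path / "bad.swc"
        p.write_text("1 1 0 0 0 5 -1\n2 3 10 0 0 0.5 9\n")
        with pytest.raises(SWCFormatError, match="dangling parent"):
            load_swc(p)

    def test_malformed_row_names_line(self, tmp_path):
        p = tmp_path / "bad.swc"
        p.write_text("1 1 0 0 0 5 -1\n2 3 ten 0 0 0.5 1\n")
        with pytest.raises(SWCFormatError, match="line 2"):
            load_swc(p)

    def test_multiple_roots_rejected(self, tmp_path):
        p = tmp_path / "two_roots.swc"
        p.write_text("1 1 0 0 0 5 -1\n2 3 10 0 0 0.5 -1\n")
        with pytest.raises(SWCFormatError, match="root"):
            load_swc(p)

    def test_round_trip_preserves_cable(self, tmp_path):
        m = build_ball_and_stick(4, 275.0, 1.0, 20.0)
        p = tmp_path / "cell.swc"
        write_swc(m, p)
        m2 = load_swc(p)
        assert m2.total_length() == pytest.approx(m.total_length(), abs=1e-9)
        assert sorted(s.length for s in m2.sections) == pytest.approx(
            sorted(s.length for s in m.sections), abs=1e-9)
        assert sorted(s.diameter for s in m2.sections) == pytest.approx(
            sorted(s.diameter for s in m.sections), abs=1e-9)


class TestDiscretize:
    def test_short_section_single_segment(self):
        secs = [Section(0, None, SectionKind.SOMA, 5.0, 20.0)]
        m = discretize(Morphology(secs), MEM)
        assert m.nseg[0] == 1

    def test_ten_micron_cap_binds(self):
        # lambda_100/10 for a 1 um dendrite exceeds 10 um, so the cap rules
        lam = lambda_f(1.0, 100.0, MEM.r_a, MEM.c_m_dend * 2)
        assert lam / 10 > 10
        m = build_ball_and_stick(1, 200.0, 1.0, 20.0)
        m = discretize(m, MEM)
        assert m.nseg[m.basal_ids[0]] >= 21
        assert m.nseg[m.basal_ids[0]] % 2 == 1

    def test_segment_lengths_obey_rule(self):
        m = discretize(build_ball_and_stick(4, 275.0, 0.7, 60.0), MEM)
        for s in m.sections:
            c_m = MEM.c_m_for(s.kind) * (2 if s.spine_corrected else 1)
            cap = min(lambda_f(s.diameter, 100.0, MEM.r_a, c_m) / 10, 10.0)
            assert s.length / m.nseg[s.id] <= cap + 1e-9
            assert m.nseg[s.id] % 2 == 1
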