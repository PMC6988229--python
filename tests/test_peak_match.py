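"""Peak-list I/O, neutral-mass conversion, and tolerance matching."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from alpform.peak_match import (
    Peak,
    PeakList,
    PeakParseError,
    Tolerance,
    match,
    neutral_mass,
    read_peaks,
)
from alpform.proteoform import Proteoform
from alpform.seq_model import PROTON_AVERAGE_MASS


def hypo(mass, parent="P", fragment=(1, 100), alkylated=True, mods=()):
    return Proteoform(
        parent_id=parent,
        fragment=fragment,
        alkylated=alkylated,
        n_cys=0,
        mass=mass,
        extra_mods=mods,
        label="MW2" if fragment == (1, 100) else "MW2d",
    )


class TestReadPeaks:
    def test_two_column_file_with_header(self, tmp_path):
        f = tmp_path / "peaks.csv"
        f.write_text("mz,intensity\n18423.0,55\n17000.5,10\n")
        peaks = read_peaks(f)
        assert len(peaks) == 2
        assert [p.mz for p in peaks.peaks] == [17000.5, 18423.0]  # sorted

    def test_bare_columns_and_whitespace_delimiter(self, tmp_path):
        f = tmp_path / "peaks.txt"
        f.write_text("18423.0 55\n17000.5 10\n")
        assert len(read_peaks(f)) == 2

    def test_empty_body_gives_empty_list(self, tmp_path):
        f = tmp_path / "peaks.csv"
        f.write_text("mz,intensity\n")
        assert len(read_peaks(f)) == 0

    def test_negative_mz_rejected_with_row(self, tmp_path):
        f = tmp_path / "peaks.csv"
        f.write_text("mz,intensity\n-5,1\n")
        with pytest.raises(PeakParseError, match="row 2"):
            read_peaks(f)

    def test_non_numeric_cell_rejected_with_row(self, tmp_path):
        f = tmp_path / "peaks.csv"
        f.write_text("18423.0,55\noops,1\n")
        with pytest.raises(PeakParseError, match="row 2"):
            read_peaks(f)

    def test_out_of_range_peaks_retained_but_flagged(self, tmp_path):
        f = tmp_path / "peaks.csv"
        f.write_text("mz,intensity\n9000,5\n18000,5\n")
        peaks = read_peaks(f)
        assert len(peaks) == 2
        flags = [peaks.in_range(p) for p in peaks.peaks]
        assert flags == [False, True]


class TestNeutralMass:
    def test_subtracts_one_proton(self):
        assert neutral_mass(18423.0, 1) == pytest.approx(18421.99, abs=0.005)

    def test_zero_charge_rejected(self):
        with pytest.raises(ValueError):
            neutral_mass(18423.0, 0)

    @given(m=st.floats(min_value=1000, max_value=45000))
    @settings(max_examples=50, derandomize=True)
    def test_charge_two_consistency(self, m):
        z1 = neutral_mass(m + PROTON_AVERAGE_MASS, 1)
        z2 = neutral_mass(m / 2 + PROTON_AVERAGE_MASS, 2)
        assert z1 == pytest.approx(z2, abs=1e-6)


class TestMatch:
    def test_assignment_within_relative_tolerance(self):
        peaks = PeakList("s", (Peak(18423.0, 1.0),))
        forms = [hypo(18420.0)]
        (a,) = match(peaks, forms, Tolerance(relative=0.001))
        assert a.assigned
        assert abs(a.error_da) <= 18.42
        assert a.rank == 1

    def test_empty_peak_list(self):
        assert match(PeakList("s", ()), [hypo(18000.0)]) == []

    def test_no_hypotheses_yields_unassigned_peaks(self):
        peaks = PeakList("s", (Peak(18423.0, 1.0),))
        (a,) = match(peaks, [])
        assert not a.assigned
        assert a.rank == 0

    def test_every_assignment_obeys_its_tolerance(self):
        peaks = PeakList("s", tuple(Peak(mz) for mz in (17000.0, 18000.0, 18010.0)))
        forms = [hypo(17995.0), hypo(18005.0, fragment=(1, 50))]
        tol = Tolerance(absolute=12.0, relative=None)
        for a in match(peaks, forms, tol):
            if a.assigned:
                assert abs(a.error_da) <= 12.0

    def test_parsimony_rank_prefers_fewer_mods_on_ties(self):
        base = hypo(18000.0)
        modded = hypo(18000.0, fragment=(1, 99), mods=(("oxidation", 1),))
        peaks = PeakList("s", (Peak(18000.0 + PROTON_AVERAGE_MASS),))
        ranked = match(peaks, [modded, base], Tolerance(relative=0.001))
        assert ranked[0].proteoform is base
        assert ranked[0].rank == 1
        assert ranked[1].proteoform is modded

    def test_shared_hypothesis_across_peaks_unless_unique(self):
        form = hypo(18000.0)
        peaks = PeakList(
            "s",
            (Peak(18001.0 + PROTON_AVERAGE_MASS), Peak(18002.0 + PROTON_AVERAGE_MASS)),
        )
        both = match(peaks, [form], Tolerance(relative=0.001))
        assert sum(1 for a in both if a.assigned) == 2
        uniq = match(peaks, [form], Tolerance(relative=0.001), unique=True)
        assigned = [a for a in uniq if a.assigned]
        assert len(assigned) == 1
        assert assigned[0].error_da == pytest.approx(1.0)  # the closer peak

    def test_neutral_input_skips_proton_subtraction(self):
        peaks = PeakList("s", (Peak(18000.0),))
        (a,) = match(peaks, [hypo(18000.0)], neutral_input=True)
        assert a.error_da == pytest.approx(0.0, abs=1e-9)

    @given(
        tol_big=st.floats(min_value=2.0, max_value=30.0),
        shrink=st.floats(min_value=0.05, max_value=0.95),
        offsets=st.lists(
            st.floats(min_value=-25, max_value=25), min_size=1, max_size=6
        ),
    )
    @settings(max_examples=60, derandomize=True)
    def test_shrinking_tolerance_never_adds_assignments(
        self, tol_big, shrink, offsets
    ):
        forms = [hypo(18000.0), hypo(18030.0, fragment=(1, 60))]
        peaks = PeakList(
            "s", tuple(Peak(18000.0 + PROTON_AVERAGE_MASS + o) for o in offsets)
        )
        big = match(peaks, forms, Tolerance(absolute=tol_big, relative=None))
        small = match(
            peaks, forms, Tolerance(absolute=tol_big * shrink, relative=None)
        )
        keys_big = {
            (a.mz, id(a.proteoform)) for a in big if a.assigned
        }
        keys_small = {
            (a.mz, id(a.proteoform)) for a in small if a.assigned
        }
        assert keys_small <= keys_big


class TestTolerance:
    def test_exactly_one_mode(self):
        with pytest.raises(ValueError):
            Tolerance(absolute=1.0, relative=0.001)
        with pytest.raises(ValueError):
            Tolerance(absolute=None, relative=None)
        with pytest.raises(ValueError):
            Tolerance(absolute=-1.0, relative=None)

    def test_windows(self):
        assert Tolerance(absolute=5.0, relative=None).window(20000) == 5.0
        assert Tolerance(relative=0.001).window(20000) == pytest.approx(20.0)
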