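"""Fragment m/z calculation, linkage feasibility, and spectrum annotation."""

import itertools

import pytest
from hypothesis import given
from hypothesis import strategies as st

from mlgkit.cid_fragments import (
    Feasibility,
    MassSpec,
    PENTAOSE_ANCHORS,
    PeakList,
    Series,
    anchored_fragment_mz,
    annotate_spectrum,
    enumerate_fragments,
    fragment_mz,
    precursor_mz,
    read_peaklist_mgf,
    read_peaklist_tsv,
    validate_anchors,
    write_peaklist_mgf,
    write_peaklist_tsv,
)
from mlgkit.glucan_core import GlucanChain, Linkage, parse_chain

MONO = MassSpec()
AVG = MassSpec(mass_convention="average")
# one permethylated anhydroglucose residue under each convention
PERM_RESIDUE = {False: 204.0998, True: 204.222}


@pytest.mark.parametrize("label, series, index, printed", PENTAOSE_ANCHORS)
def test_published_anchor_masses_from_first_principles(label, series, index, printed, c5b):
    """Every published pentasaccharide ion m/z is reproduced within 1 Da
    by the composition tables under at least one mass convention."""
    deltas = [abs(fragment_mz(c5b, series, index, spec) - printed) for spec in (MONO, AVG)]
    assert min(deltas) <= 1.0


def test_anchor_validation_is_leave_one_out_safe():
    """The calculator consumes no anchors, so each prediction is independent
    of the withheld value by construction."""
    records = validate_anchors(leave_one_out=True)
    assert len(records) == len(PENTAOSE_ANCHORS)
    for rec in records:
        assert abs(rec["delta"]) <= 1.0
        assert rec["independent_of_anchor"]


def test_anchored_mode_leave_one_out(c5b):
    """The exploratory per-series-offset mode, calibrated on all other
    anchors, still predicts a held-out anchor within 1 Da."""
    for held_out in PENTAOSE_ANCHORS:
        label, series, index, printed = held_out
        calibration = [a for a in PENTAOSE_ANCHORS if a is not held_out]
        predicted = anchored_fragment_mz(c5b, series, index, calibration)
        assert abs(predicted - printed) <= 1.0


@pytest.mark.parametrize("spec", [MONO, AVG], ids=["mono", "avg"])
@pytest.mark.parametrize("series", list(Series))
def test_series_spacing_is_one_permethylated_residue(spec, series):
    """Consecutive same-series indices differ by exactly one permethylated
    residue mass, for every chain and both conventions."""
    chain = parse_chain("G3G4G3G4G3G")
    residue = PERM_RESIDUE[spec.average]
    indices = [
        f.index
        for f in enumerate_fragments(chain, spec)
        if f.series is series
    ]
    for k in range(min(indices), max(indices)):
        gap = fragment_mz(chain, series, k + 1, spec) - fragment_mz(chain, series, k, spec)
        assert gap == pytest.approx(residue, abs=1e-4)


def test_e1_g1_isobaric_16_below_d1(c5b):
    d1 = fragment_mz(c5b, Series.D, 1, MONO)
    e1 = fragment_mz(c5b, Series.E, 1, MONO)
    g1 = fragment_mz(c5b, Series.G, 1, MONO)
    assert e1 == g1
    assert d1 - e1 == pytest.approx(16.00, abs=0.3)


def test_a35_spacing_example(c5b):
    gap = fragment_mz(c5b, Series.A35, 5, MONO) - fragment_mz(c5b, Series.A35, 3, MONO)
    assert gap == pytest.approx(2 * 204.0998, abs=1e-4)


def test_v_ion_values(c5b):
    assert fragment_mz(c5b, Series.V, 3, MONO) == pytest.approx(605.4, abs=1.0)
    assert fragment_mz(c5b, Series.V, 2, MONO) == pytest.approx(401.4, abs=1.0)


# --- feasibility ------------------------------------------------------------

def feas(chain, series, index):
    for f in enumerate_fragments(chain):
        if f.series is series and f.index == index:
            return f.feasibility
    raise KeyError((series, index))


def test_c5b_diagnostic_pattern(c5b):
    """The full strong/weak/absent pattern of the cellobiosyl-unit
    pentasaccharide: 3,5A ions only at 1,4-linked rings, V4/D4 absent,
    D1 enhanced over E1/G1."""
    assert feas(c5b, Series.A35, 2) is Feasibility.INFEASIBLE
    assert feas(c5b, Series.A35, 3) is Feasibility.STRONG
    assert feas(c5b, Series.A35, 4) is Feasibility.INFEASIBLE
    assert feas(c5b, Series.A35, 5) is Feasibility.STRONG
    assert feas(c5b, Series.V, 4) is Feasibility.INFEASIBLE
    assert feas(c5b, Series.V, 3) is Feasibility.STRONG
    assert feas(c5b, Series.V, 2) is Feasibility.WEAK
    assert feas(c5b, Series.D, 1) is Feasibility.STRONG
    assert feas(c5b, Series.D, 4) is Feasibility.INFEASIBLE
    assert feas(c5b, Series.E, 1) is Feasibility.WEAK
    assert feas(c5b, Series.G, 1) is Feasibility.WEAK


def test_homopolymer_patterns(cellopentaose, laminaripentaose):
    assert feas(cellopentaose, Series.A35, 2) is Feasibility.STRONG
    assert feas(cellopentaose, Series.D, 1) is Feasibility.WEAK
    assert feas(cellopentaose, Series.E, 1) is Feasibility.STRONG
    # all-1,3: no 3,5A series at all
    for f in enumerate_fragments(laminaripentaose):
        if f.series is Series.A35:
            assert f.feasibility is Feasibility.INFEASIBLE


def test_series_truncate_at_chain_length():
    ions = enumerate_fragments(parse_chain("G3G"))
    a_indices = [f.index for f in ions if f.series is Series.A35]
    assert a_indices == [2]
    assert all(f.index <= 1 for f in ions if f.series in (Series.B, Series.Y))


def test_dp_bounds_and_invalid_indices(c5b):
    with pytest.raises(ValueError):
        enumerate_fragments(parse_chain("G"))
    with pytest.raises(ValueError):
        enumerate_fragments(GlucanChain((Linkage.L4,) * 10))  # DP 11
    with pytest.raises(ValueError):
        fragment_mz(c5b, Series.A35, 1, MONO)
    with pytest.raises(ValueError):
        fragment_mz(c5b, Series.V, 5, MONO)
    with pytest.raises(ValueError):
        fragment_mz(c5b, "Q", 1, MONO)


@given(
    st.lists(st.sampled_from([Linkage.L3, Linkage.L4]), min_size=1, max_size=9).map(
        lambda ls: GlucanChain(tuple(ls))
    )
)
def test_all_fragment_mz_positive_and_below_precursor(chain):
    prec = precursor_mz(chain)
    for f in enumerate_fragments(chain):
        assert 0 < f.mz < prec


# --- annotation --------------------------------------------------------------

def test_clean_spectrum_fully_annotated(c5b, clean_sim):
    from mlgkit.synthetic_data import simulate_spectrum

    peaks = simulate_spectrum(c5b, clean_sim)
    result = annotate_spectrum(peaks, c5b, tolerance=0.5)
    assert result.unassigned == ()
    labels = set(result.labels())
    assert "3,5A2" not in labels and "V4" not in labels
    assert {"3,5A3", "3,5A5", "V3", "D1"} <= labels


def test_annotation_empty_peaklist(c5b):
    empty = PeakList.from_pairs([])
    result = annotate_spectrum(empty, c5b)
    assert result.assignments == () and result.unassigned == ()


def test_annotation_tolerance_validation(c5b):
    with pytest.raises(ValueError):
        annotate_spectrum(PeakList.from_pairs([(227.1, 1.0)]), c5b, tolerance=0.0)


def test_annotation_greedy_is_deterministic(c5b):
    peaks = PeakList.from_pairs([(227.2, 1.0), (211.1, 0.4)])
    first = annotate_spectrum(peaks, c5b)
    second = annotate_spectrum(peaks, c5b)
    assert [a.ion.label for a in first.assignments] == [
        a.ion.label for a in second.assignments
    ]
    assert {a.ion.label for a in first.assignments} == {"D1", "E1"}


# --- peak-list files ----------------------------------------------------------

def test_peaklist_tsv_round_trip(tmp_path, c5b, clean_sim):
    from mlgkit.synthetic_data import simulate_spectrum

    peaks = simulate_spectrum(c5b, clean_sim)
    path = tmp_path / "spec.tsv"
    write_peaklist_tsv(path, peaks)
    back = read_peaklist_tsv(path)
    assert len(back) == len(peaks)
    assert back.precursor_mz == pytest.approx(peaks.precursor_mz, abs=1e-3)
    for (m1, i1), (m2, i2) in zip(back.peaks, peaks.peaks):
        assert m1 == pytest.approx(m2, abs=1e-3)
        assert i1 == pytest.approx(i2, abs=1e-3)


def test_peaklist_mgf_round_trip(tmp_path, c5b, clean_sim):
    from mlgkit.synthetic_data import simulate_spectrum

    peaks = simulate_spectrum(c5b, clean_sim)
    path = tmp_path / "spec.mgf"
    write_peaklist_mgf(path, peaks, title="c5b")
    back = read_peaklist_mgf(path)
    assert len(back) == len(peaks)
    assert back.precursor_mz == pytest.approx(peaks.precursor_mz, abs=1e-3)
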