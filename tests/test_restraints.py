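"""NOE calibration, restraint compilation, symmetry duplication, violations."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from duplexlens import (
    DistanceRestraint,
    Peak,
    assign_bounds,
    backbone_dihedral_restraints,
    calibrate,
    compile_restraints,
    duplicate_symmetry,
    merge_mixing_times,
    violation_report,
    wc_restraints,
)
from duplexlens.errors import RestraintError
from duplexlens.restraints import (
    OXOG_EPSILON_RANGE,
    OXOG_ZETA_RANGE,
    _arc_violation,
    read_peaklist,
    write_peaklist,
)


def _peak(pid, vol, t, res=2, atoms=("H1'", "H8")):
    return Peak(pid, ("A", res, atoms[0]), ("A", res + 1, atoms[1]), vol, t)


def _ref_peak(vol, t, res=3):
    return Peak(f"ref{res}@{t}", ("A", res, "H5"), ("A", res, "H6"), vol, t)


class TestCalibration:
    def test_reference_volume_maps_to_reference_distance(self):
        peaks = [_ref_peak(1000.0, 70.0), _peak("p1", 1000.0, 70.0)]
        out = calibrate(peaks, r_ref=2.45)
        dist, _ = out[70.0][peaks[1].pair]
        assert dist == pytest.approx(2.45)

    def test_sixty_fourfold_weaker_doubles_the_distance(self):
        peaks = [_ref_peak(6400.0, 70.0), _peak("p1", 100.0, 70.0)]
        out = calibrate(peaks, r_ref=2.45)
        assert out[70.0][peaks[1].pair][0] == pytest.approx(4.9)

    @given(st.floats(0.01, 1e4))
    @settings(deadline=None, max_examples=50)
    def test_scale_invariance(self, c):
        base = [_ref_peak(1000.0, 70.0), _peak("p1", 370.0, 70.0)]
        scaled = [Peak(p.id, p.atom_i, p.atom_j, p.volume * c, p.mixing_time)
                  for p in base]
        d0 = calibrate(base)[70.0][base[1].pair][0]
        d1 = calibrate(scaled)[70.0][base[1].pair][0]
        assert d1 == pytest.approx(d0, rel=1e-9)

    def test_missing_reference_is_an_error(self):
        with pytest.raises(RestraintError):
            calibrate([_peak("p1", 100.0, 70.0)])


class TestMerging:
    def test_present_in_all_sets_is_averaged(self):
        per_set = {t: {frozenset({("A", 2, "H1'"), ("A", 3, "H8")}): (d, 100.0)}
                   for t, d in zip((70.0, 140.0, 200.0), (3.0, 3.2, 3.4))}
        merged = merge_mixing_times(per_set)
        (dist, prov), = merged.values()
        assert dist == pytest.approx(3.2)
        assert prov == "averaged"

    def test_partial_presence_takes_highest_volume(self):
        pair = frozenset({("A", 2, "H1'"), ("A", 3, "H8")})
        per_set = {70.0: {pair: (3.1, 50.0)}, 140.0: {pair: (3.5, 90.0)}, 200.0: {}}
        dist, prov = merge_mixing_times(per_set)[pair]
        assert (dist, prov) == (3.5, "non-averaged")


class TestBounds:
    def test_short_group_default_tolerances(self):
        r = assign_bounds(2.5, ("A", 2, "H1'"), ("A", 3, "H8"), "averaged")
        assert (r.group, r.lower, r.upper) == ("short", pytest.approx(2.1), pytest.approx(2.9))

    @pytest.mark.parametrize("d,group", [(2.99, "short"), (3.0, "medium"),
                                         (4.0, "medium"), (5.0, "medium"), (5.01, "long")])
    def test_grouping_partition(self, d, group):
        assert assign_bounds(d, ("A", 2, "H1'"), ("A", 3, "H8"), "averaged").group == group

    def test_methyl_override_and_pseudoatom_correction(self):
        r = assign_bounds(3.5, ("A", 7, "H71"), ("A", 6, "H6"), "averaged")
        assert r.group == "methyl"
        assert r.upper == pytest.approx(3.5 + 0.7 + 1.0)

    def test_non_positive_distance_rejected(self):
        with pytest.raises(RestraintError):
            assign_bounds(0.0, ("A", 2, "H1'"), ("A", 3, "H8"), "averaged")


class TestSymmetry:
    def _restraint(self, i, j, ai="H1'", aj="H8"):
        return DistanceRestraint(("A", i, ai), ("A", j, aj), 3.0, 2.6, 3.4,
                                 "medium", "averaged")

    def test_copy_lands_on_the_other_strand(self, ddd_map):
        out = duplicate_symmetry([self._restraint(2, 3)], ddd_map)
        assert len(out) == 2
        copy = out[1]
        assert copy.provenance == "symmetry-copy"
        assert copy.atom_i == ("B", 2, "H1'") and copy.atom_j == ("B", 3, "H8")

    def test_doubles_the_count(self, ddd_map):
        rs = [self._restraint(i, i + 1) for i in range(2, 11)]
        assert len(duplicate_symmetry(rs, ddd_map)) == 2 * len(rs)

    def test_involutive_up_to_provenance(self, ddd_map):
        rs = [self._restraint(2, 3), self._restraint(5, 6, "H2'", "H6")]
        once = duplicate_symmetry(rs, ddd_map)
        twice = duplicate_symmetry(once, ddd_map)
        assert sorted(r.pair for r in twice for _ in [0]).count(once[0].pair) == 2
        from collections import Counter
        assert Counter(r.pair for r in twice) == Counter(
            {r.pair: 2 for r in once})

    def test_cross_strand_fixed_point_emitted_once(self, ddd_map):
        r = DistanceRestraint(("A", 2, "H1'"), ("B", 2, "H1'"), 3.0, 2.6, 3.4,
                              "medium", "averaged")
        out = duplicate_symmetry([r], ddd_map)
        assert len(out) == 1 and out[0].provenance == "self-symmetric"


class TestWatsonCrickRestraints:
    def test_ddd_count_is_26(self, ddd_map):
        rs = wc_restraints(ddd_map)
        # 10 non-terminal pairs: 6 G:C-type x3 + 4 A:T x2
        assert len(rs) == 26

    def test_terminal_pairs_excluded(self, ddd_map):
        rs = wc_restraints(ddd_map)
        assert not any(k[1] in (1, 12) and k[0] == "A" for r in rs
                       for k in (r.atom_i, r.atom_j))

    def test_oxog_pair_still_three_restraints(self, oxog4_helix):
        from duplexlens import pair_duplex
        s, _ = oxog4_helix
        m = pair_duplex(s, "CGCXAATTCGCG", "CGCGAATTCGCG")
        rs = wc_restraints(m)
        at4 = [r for r in rs if ("A", 4) in (r.atom_i[:2], r.atom_j[:2])]
        assert len(at4) == 3


class TestDihedralRestraints:
    def test_lesion_gets_bii_ranges(self):
        rs = backbone_dihedral_restraints("CGCXAATTCGCG", [4])
        eps4 = next(r for r in rs if r.name == "epsilon:A:4")
        zeta4 = next(r for r in rs if r.name == "zeta:A:4")
        assert (eps4.lo, eps4.hi) == OXOG_EPSILON_RANGE and eps4.label == "oxoG-epsilon"
        assert (zeta4.lo, zeta4.hi) == OXOG_ZETA_RANGE and zeta4.label == "oxoG-zeta"

    def test_no_lesion_all_bi_standard(self):
        rs = backbone_dihedral_restraints("CGCGAATTCGCG", [])
        assert {r.label for r in rs} == {"BI-standard"}

    def test_neighbors_broadened_by_twenty_degrees(self):
        base = {r.name: r for r in backbone_dihedral_restraints("CGCGAATTCGCG", [])}
        mod = {r.name: r for r in backbone_dihedral_restraints("CGCXAATTCGCG", [4])}
        for name in ("delta:A:4", "gamma:A:4", "alpha:A:5", "beta:A:5"):
            assert mod[name].label == "neighbor-broadened"
            assert mod[name].lo == base[name].lo - 20.0
            assert mod[name].hi == base[name].hi + 20.0

    def test_out_of_range_position_rejected(self):
        with pytest.raises(RestraintError):
            backbone_dihedral_restraints("CGCG", [5])


class TestViolations:
    def test_satisfied_set_scores_zero(self, ddd_helix, ddd_map):
        from duplexlens import synth_peaklist
        s, _ = ddd_helix
        peaks = synth_peaklist(s, noise=0.0, seed=0)
        rs, _ = compile_restraints(peaks, ddd_map)
        dih = backbone_dihedral_restraints("CGCGAATTCGCG", [])
        rep = violation_report(s, rs + wc_restraints(ddd_map), dih)
        assert rep.overall_max_distance == pytest.approx(0.0, abs=1e-6)
        assert rep.overall_max_dihedral == pytest.approx(0.0, abs=1e-6)

    def test_constructed_displacement_scores_its_excess(self, ddd_helix):
        s, _ = ddd_helix
        d0 = float(np.linalg.norm(s.residue("A", 2).xyz("H1'") -
                                  s.residue("A", 3).xyz("H6")))
        r = DistanceRestraint(("A", 2, "H1'"), ("A", 3, "H6"),
                              d0 - 0.65, d0 - 0.9, d0 - 0.25, "medium", "averaged")
        rep = violation_report(s, [r])
        assert rep.overall_max_distance == pytest.approx(0.25, abs=0.01)

    def test_arc_violation_arithmetic(self):
        assert _arc_violation(310.0, 215.0, 295.0) == pytest.approx(15.0)
        assert _arc_violation(250.0, 215.0, 295.0) == 0.0
        assert _arc_violation(10.0, 215.0, 295.0) == pytest.approx(75.0)  # wraps to hi side

    def test_unresolvable_atom_listed_not_fatal(self, ddd_helix):
        s, _ = ddd_helix
        r = DistanceRestraint(("A", 2, "H99"), ("A", 3, "H8"), 3.0, 2.6, 3.4,
                              "medium", "averaged")
        with pytest.warns(UserWarning):
            rep = violation_report(s, [r])
        assert rep.skipped


class TestLedgerAndIO:
    def test_ledger_identity_on_synthetic_compilation(self, ddd_helix, ddd_map):
        from duplexlens import synth_peaklist
        s, _ = ddd_helix
        peaks = synth_peaklist(s, noise=0.05, seed=5, drop_fraction=0.3)
        rs, ledger = compile_restraints(peaks, ddd_map)
        assert ledger.averaged + ledger.non_averaged + ledger.methyl == ledger.total
        assert ledger.averaged > 0 and ledger.non_averaged > 0 and ledger.methyl > 0
        originals = [r for r in rs if r.provenance != "symmetry-copy"]
        assert len(originals) == ledger.total

    def test_peaklist_tsv_round_trip(self, tmp_path):
        peaks = [_ref_peak(1000.0, 70.0), _peak("p1", 123.4, 140.0)]
        path = tmp_path / "peaks.tsv"
        write_peaklist(peaks, path)
        assert read_peaklist(path) == peaks
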