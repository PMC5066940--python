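"""Generator/analyzer closure: everything the builders set is recovered."""

import numpy as np
import pytest

from duplexlens import (
    GeneratorSpec,
    backbone_torsions,
    build_helix,
    build_torsion_exact,
    classify_step,
    complement_sequence,
    make_ensemble,
    pair_duplex,
    synth_peaklist,
    twist_profile,
)
from duplexlens.errors import BuildError
from duplexlens.synthetic import _bridge_phosphate


class TestSpecValidation:
    def test_invalid_symbol_rejected(self):
        with pytest.raises(ValueError):
            GeneratorSpec(sequence="CGZ")

    def test_out_of_range_overrides_rejected(self):
        with pytest.raises(ValueError):
            GeneratorSpec(sequence="CGCG", twist_overrides={4: 30.0})
        with pytest.raises(ValueError):
            GeneratorSpec(sequence="CGCG", eps_zeta={4: (270.0, 180.0)})
        with pytest.raises(ValueError):
            GeneratorSpec(sequence="CGCG", jitter=-0.1)

    def test_bad_eps_zeta_target_rejected(self):
        with pytest.raises(BuildError):
            build_torsion_exact(GeneratorSpec(sequence="CGCG", eps_zeta={2: (400.0, 180.0)}))


class TestBuildHelix:
    def test_lesion_symbol_builds_8og_with_o8(self, oxog4_helix):
        s, _ = oxog4_helix
        r4 = s.residue("A", 4)
        assert r4.code == "8OG" and r4.has_atom("O8") and r4.has_atom("H7")
        assert not r4.has_atom("H8")

    def test_ground_truth_equals_request(self):
        spec = GeneratorSpec(sequence="CGCGAATTCGCG", twist=34.0, rise=3.3,
                             twist_overrides={5: 24.0})
        s, truth = build_helix(spec)
        assert [t["twist"] for t in truth] == [34.0] * 4 + [24.0] + [34.0] * 6
        dmap = pair_duplex(s, spec.sequence, complement_sequence(spec.sequence))
        prof = twist_profile(s, dmap)
        for sp, t in zip(prof, truth):
            assert sp.twist == pytest.approx(t["twist"], abs=0.5)
            assert sp.rise == pytest.approx(t["rise"], abs=0.05)

    def test_backbone_is_connected(self, ddd_helix):
        s, _ = ddd_helix
        for cid in ("A", "B"):
            res = s.chain(cid)
            for i in range(len(res) - 1):
                d = np.linalg.norm(res[i].xyz("O3'") - res[i + 1].xyz("P"))
                assert d == pytest.approx(1.607, abs=0.01)

    def test_unbridgeable_gap_raises(self):
        a = {"O3'": np.zeros(3), "C3'": np.array([1.4, 0, 0]), "C4'": np.array([2.0, 1.0, 0])}
        b = {"O5'": np.array([9.0, 0, 0]), "C5'": np.array([10.0, 0.5, 0])}
        with pytest.raises(BuildError):
            _bridge_phosphate(a, b)


class TestBuildTorsionExact:
    def test_requested_eps_zeta_realized_exactly(self, oxog4_bii):
        ts = backbone_torsions(oxog4_bii, 0, "A", 4)
        assert ts.epsilon == pytest.approx(270.0, abs=0.1)
        assert ts.zeta == pytest.approx(180.0, abs=0.1)

    def test_single_bii_step_on_lesion_strand(self, oxog4_bii):
        states = {}
        for r in oxog4_bii.chain("A")[:-1]:
            states[r.index] = classify_step(backbone_torsions(oxog4_bii, 0, "A", r.index)).state
        assert states[4] == "BII"
        assert all(v == "BI" for k, v in states.items() if k != 4)

    def test_all_default_build_is_all_bi(self, ddd_exact):
        for r in ddd_exact.chain("A")[:-1]:
            assert classify_step(backbone_torsions(ddd_exact, 0, "A", r.index)).state == "BI"

    def test_restraint_midpoint_build_satisfies_lesion_restraints(self):
        from duplexlens import backbone_dihedral_restraints, violation_report
        s = build_torsion_exact(
            GeneratorSpec(sequence="CGCXAATTCGCG", eps_zeta={4: (255.0, 180.0)}))
        dih = backbone_dihedral_restraints("CGCXAATTCGCG", [4])
        rep = violation_report(s, [], dih)
        assert rep.overall_max_dihedral == pytest.approx(0.0, abs=1e-6)


class TestMakeEnsemble:
    def test_zero_sigma_gives_identical_models(self, ddd_helix):
        s, _ = ddd_helix
        ens = make_ensemble(s, 0.0, 4, seed=1)
        for m in range(1, 4):
            assert np.array_equal(ens.coords(m), ens.coords(0))

    def test_same_seed_is_bit_identical(self, ddd_helix):
        s, _ = ddd_helix
        a = make_ensemble(s, 0.2, 5, seed=42)
        b = make_ensemble(s, 0.2, 5, seed=42)
        for m in range(5):
            assert np.array_equal(a.coords(m), b.coords(m))

    def test_mean_pairwise_rmsd_matches_simulation_expectation(self, ddd_helix):
        from duplexlens import pairwise_rmsd
        s, _ = ddd_helix
        ens = make_ensemble(s, 0.1, 20, seed=6)
        M = pairwise_rmsd(ens, "all-atom")
        mean = M[np.triu_indices_from(M, 1)].mean()
        assert mean == pytest.approx(0.1 * np.sqrt(6.0), rel=0.10)


class TestSynthPeaklist:
    def test_r6_law(self, ddd_helix):
        s, _ = ddd_helix
        peaks = synth_peaklist(s, noise=0.0, seed=0, mixing_times=(200.0,))
        by_pair = {p.pair: p for p in peaks}
        ref = next(p for p in peaks if {p.atom_i[2], p.atom_j[2]} == {"H5", "H6"})
        d_ref = np.linalg.norm(s.residue(*ref.atom_i[:2]).xyz(ref.atom_i[2]) -
                               s.residue(*ref.atom_j[:2]).xyz(ref.atom_j[2]))
        for p in list(by_pair.values())[:50]:
            d = np.linalg.norm(s.residue(*p.atom_i[:2]).xyz(p.atom_i[2]) -
                               s.residue(*p.atom_j[:2]).xyz(p.atom_j[2]))
            assert p.volume / ref.volume == pytest.approx((d_ref / d) ** 6, rel=1e-9)

    def test_reference_pairs_always_present(self, ddd_helix):
        s, _ = ddd_helix
        peaks = synth_peaklist(s, noise=0.3, seed=9, drop_fraction=0.5)
        for t in (70.0, 140.0, 200.0):
            assert any({p.atom_i[2], p.atom_j[2]} == {"H5", "H6"}
                       and p.mixing_time == t for p in peaks)

    def test_no_hydrogens_is_an_error(self, ddd_helix):
        s, _ = ddd_helix
        stripped_model = {}
        for cid, residues in s.models[0].items():
            stripped_model[cid] = [
                type(r)(r.index, r.code, [a for a in r.atoms if a.element != "H"])
                for r in residues]
        from duplexlens.structures import Structure
        with pytest.raises(BuildError):
            synth_peaklist(Structure([stripped_model]))

    def test_zero_noise_compiles_to_true_distances(self, ddd_helix, ddd_map):
        from duplexlens import compile_restraints
        s, _ = ddd_helix
        peaks = synth_peaklist(s, noise=0.0, seed=0)
        # exact closure needs the calibration reference to equal the
        # structure's own cytosine H5-H6 distance
        r_ref = float(np.linalg.norm(s.residue("A", 3).xyz("H5") -
                                     s.residue("A", 3).xyz("H6")))
        rs, _ = compile_restraints(peaks, ddd_map, r_ref=r_ref)
        for r in [x for x in rs if x.provenance == "averaged"][:40]:
            d = np.linalg.norm(s.residue(*r.atom_i[:2]).xyz(r.atom_i[2]) -
                               s.residue(*r.atom_j[:2]).xyz(r.atom_j[2]))
            assert r.target == pytest.approx(d, abs=1e-6)
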