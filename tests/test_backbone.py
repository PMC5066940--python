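"""Backbone torsions, BI/BII classification and sugar pseudorotation."""

import numpy as np
import pytest

from duplexlens import (
    GeneratorSpec,
    backbone_torsions,
    bii_frequency,
    build_torsion_exact,
    classify_step,
    make_ensemble,
    pseudorotation,
    pseudorotation_torsions,
    step_table,
)
from duplexlens.backbone import BII_THRESHOLD, TorsionSet, bii_profile
from duplexlens.errors import MissingAtomError
from duplexlens.geometry import wrap_signed


def brute_force_call(eps, zeta):
    """Direct transcription of the classification rule: BI at or below +20
    degrees of (eps - zeta) wrapped to (-180, 180], BII above."""
    d = (eps - zeta) % 360.0
    if d > 180.0:
        d -= 360.0
    return "BII" if d > 20.0 else "BI"


def _ts(eps, zeta):
    return TorsionSet("A", 1, "DG", {"epsilon": eps, "zeta": zeta})


class TestClassifier:
    @pytest.mark.parametrize("eps,zeta,expected", [
        (190.0, 270.0, "BI"),    # canonical BI, eps-zeta = -80
        (270.0, 180.0, "BII"),   # canonical BII, eps-zeta = +90
        (255.0, 180.0, "BII"),   # midpoints of the lesion restraint ranges
        (200.0, 180.0, "BI"),    # boundary: exactly +20 assigned to BI
        (200.1, 180.0, "BII"),
    ])
    def test_canonical_calls(self, eps, zeta, expected):
        call = classify_step(_ts(eps, zeta))
        assert call.state == expected
        assert call.eps_minus_zeta == pytest.approx(wrap_signed(eps - zeta))

    def test_agrees_with_rule_enumeration_on_degree_grid(self):
        eps_grid = np.arange(0.0, 360.0, 1.0)
        zeta_grid = np.arange(0.0, 360.0, 7.0)  # coarser second axis, still >18k pairs
        for zeta in zeta_grid:
            for eps in eps_grid:
                assert classify_step(_ts(eps, zeta)).state == brute_force_call(eps, zeta)

    def test_unavailable_angles_give_null_call(self):
        call = classify_step(TorsionSet("A", 12, "DG", {"epsilon": None, "zeta": 100.0}))
        assert call.state is None and not call.classifiable


class TestBackboneTorsions:
    def test_injected_eps_zeta_recovered_exactly(self, oxog4_bii):
        ts = backbone_torsions(oxog4_bii, 0, "A", 4)
        assert ts.epsilon == pytest.approx(270.0, abs=0.1)
        assert ts.zeta == pytest.approx(180.0, abs=0.1)

    def test_three_prime_terminus_lacks_eps_zeta(self, ddd_exact):
        ts = backbone_torsions(ddd_exact, 0, "A", 12)
        assert not ts.available("epsilon") and not ts.available("zeta")
        assert ts.available("delta")

    def test_five_prime_terminus_lacks_alpha_beta(self, ddd_exact):
        ts = backbone_torsions(ddd_exact, 0, "A", 1)
        assert not ts.available("alpha") and not ts.available("beta")

    def test_helix_build_is_bi_everywhere(self, ddd_helix):
        s, _ = ddd_helix
        for r in s.chain("A")[:-1]:
            call = classify_step(backbone_torsions(s, 0, "A", r.index))
            assert call.state == "BI"
            assert -120.0 < call.eps_minus_zeta < 0.0  # canonical BI region

    def test_missing_internal_atom_is_an_error(self, ddd_exact):
        import copy
        s = copy.deepcopy(ddd_exact)
        res = s.residue("A", 5)
        res.atoms = [a for a in res.atoms if a.name != "O3'"]
        with pytest.raises(MissingAtomError) as e:
            backbone_torsions(s, 0, "A", 5)
        assert "O3'" in str(e.value) and "5" in str(e.value)


class TestPseudorotation:
    def test_inverse_model_round_trip(self):
        nus = pseudorotation_torsions(162.0, 38.0)
        p = pseudorotation(*nus)
        assert p.P == pytest.approx(162.0, abs=0.01)
        assert p.tau_m == pytest.approx(38.0, abs=0.01)
        assert p.label == "C2'-endo"

    @pytest.mark.parametrize("P,tm", [(18.0, 42.0), (95.0, 35.0), (162.0, 38.0), (342.0, 40.0)])
    def test_round_trip_across_the_wheel(self, P, tm):
        got = pseudorotation(*pseudorotation_torsions(P, tm))
        assert got.P == pytest.approx(P, abs=0.01)
        assert got.tau_m == pytest.approx(tm, abs=0.01)

    def test_negating_all_nus_shifts_phase_half_turn(self):
        nus = pseudorotation_torsions(150.0, 40.0)
        a = pseudorotation(*nus)
        b = pseudorotation(*(-n for n in nus))
        assert b.P == pytest.approx((a.P + 180.0) % 360.0, abs=1e-6)
        assert b.tau_m == pytest.approx(a.tau_m, abs=1e-6)

    def test_builder_sugars_are_c2_endo(self, ddd_exact):
        ts = backbone_torsions(ddd_exact, 0, "A", 6)
        p = pseudorotation(*ts.nus)
        assert 144.0 <= p.P < 180.0


class TestBIIFrequency:
    def test_small_jitter_never_crosses_threshold(self, ddd_helix):
        s, _ = ddd_helix
        ens = make_ensemble(s, sigma=0.05, n=10, seed=3)
        prof = bii_profile(ens, "A")
        assert all(f == 0.0 for f in prof.values())

    def test_constructed_mixture_fraction(self, ddd_helix):
        from duplexlens.structures import Structure
        bi = build_torsion_exact(GeneratorSpec(sequence="CGCG"))
        bii = build_torsion_exact(GeneratorSpec(sequence="CGCG", eps_zeta={2: (270.0, 180.0)}))
        mixed = Structure([bi.models[0]] * 7 + [bii.models[0]] * 3)
        assert bii_frequency(mixed, "A", 2) == pytest.approx(0.3)
        assert bii_frequency(mixed, "A", 1) == 0.0

    def test_single_model_gives_zero_or_one(self, oxog4_bii):
        assert bii_frequency(oxog4_bii, "A", 4) == 1.0
        assert bii_frequency(oxog4_bii, "A", 5) == 0.0

    def test_exactly_one_bii_step_after_injection(self, oxog4_bii):
        prof = bii_profile(oxog4_bii, "A")
        assert [k for k, f in prof.items() if f and f > 0.5] == [4]


def test_step_table_is_parseable_tsv(oxog4_bii):
    table = step_table(oxog4_bii)
    lines = table.strip().splitlines()
    assert lines[0].split("\t") == ["model", "chain", "step", "epsilon", "zeta",
                                    "eps_minus_zeta", "state"]
    rows = [ln.split("\t") for ln in lines[1:]]
    a_states = {int(r[2]): r[6] for r in rows if r[1] == "A"}
    assert a_states[4] == "BII"
    assert all(v == "BI" for k, v in a_states.items() if k != 4)
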