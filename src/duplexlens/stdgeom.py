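"""Standard nucleotide geometry: reference base tables and nucleoside assembly.

Base heavy-atom coordinates are embedded as literal tables expressed in the
standard base reference frame (x toward the major groove, y toward the
sugar-bearing strand, z along the base normal; origin near the pair centre).
In this frame an ideal Watson-Crick partner is obtained by a 180° rotation
about x, which is how the duplex builder places the complementary strand.

Everything else is constructed programmatically and cached: base hydrogens
from ideal sp2/sp3 geometry, the C2'-endo deoxyribose ring by least-squares
ring closure against pseudorotation targets, and complete nucleosides with a
chosen glycosidic torsion.  8-oxoguanine is derived from guanine by placing
O8 on C8 along the former C8-H8 direction (1.23 Å) and a proton on N7; the
Watson-Crick edge is untouched.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy.optimize import least_squares

from duplexlens.geometry import bond_angle, dihedral, kabsch, place_atom

__all__ = [
    "BASE_TABLES",
    "RING_ATOMS",
    "base_table",
    "standard_nucleoside",
    "sugar_ring_template",
    "PSEUDOROTATION_P",
    "PSEUDOROTATION_TM",
]

# ---------------------------------------------------------------------------
# Standard base reference frames (heavy atoms, Å).  z = 0 plane is the base
# plane; C1' is included to anchor the glycosidic bond.
# ---------------------------------------------------------------------------

BASE_TABLES: dict[str, dict[str, np.ndarray]] = {
    "DA": {
        "C1'": (-2.479, 5.346, 0.000),
        "N9": (-1.291, 4.498, 0.000),
        "C8": (0.024, 4.897, 0.000),
        "N7": (0.877, 3.902, 0.000),
        "C5": (0.071, 2.771, 0.000),
        "C6": (0.369, 1.398, 0.000),
        "N6": (1.611, 0.909, 0.000),
        "N1": (-0.668, 0.532, 0.000),
        "C2": (-1.912, 1.023, 0.000),
        "N3": (-2.320, 2.290, 0.000),
        "C4": (-1.267, 3.124, 0.000),
    },
    "DG": {
        "C1'": (-2.477, 5.399, 0.000),
        "N9": (-1.289, 4.551, 0.000),
        "C8": (0.023, 4.962, 0.000),
        "N7": (0.870, 3.969, 0.000),
        "C5": (0.071, 2.833, 0.000),
        "C6": (0.424, 1.460, 0.000),
        "O6": (1.554, 0.955, 0.000),
        "N1": (-0.700, 0.641, 0.000),
        "C2": (-1.999, 1.087, 0.000),
        "N2": (-2.949, 0.139, -0.001),
        "N3": (-2.342, 2.364, 0.001),
        "C4": (-1.265, 3.177, 0.000),
    },
    "DC": {
        "C1'": (-2.477, 5.402, 0.000),
        "N1": (-1.285, 4.542, 0.000),
        "C2": (-1.472, 3.158, 0.000),
        "O2": (-2.628, 2.709, 0.001),
        "N3": (-0.391, 2.344, 0.000),
        "C4": (0.837, 2.868, 0.000),
        "N4": (1.875, 2.027, 0.001),
        "C5": (1.056, 4.275, 0.000),
        "C6": (-0.023, 5.068, 0.000),
    },
    "DT": {
        "C1'": (-2.481, 5.354, 0.000),
        "N1": (-1.284, 4.500, 0.000),
        "C2": (-1.462, 3.135, 0.000),
        "O2": (-2.562, 2.608, 0.000),
        "N3": (-0.298, 2.407, 0.000),
        "C4": (0.994, 2.897, 0.000),
        "O4": (1.944, 2.119, 0.000),
        "C5": (1.106, 4.338, 0.000),
        "C7": (2.466, 4.961, 0.001),
        "C6": (-0.024, 5.057, 0.000),
    },
}
BASE_TABLES = {
    code: {name: np.asarray(xyz, float) for name, xyz in atoms.items()}
    for code, atoms in BASE_TABLES.items()
}

#: six-membered-ring atoms used for reference-frame fitting (all base types)
RING_ATOMS = ("N1", "C2", "N3", "C4", "C5", "C6")

#: glycosidic nitrogen and the chi-defining base atom, per base type
GLYCOSIDIC = {
    "DA": ("N9", "C4", "C8"),
    "DG": ("N9", "C4", "C8"),
    "8OG": ("N9", "C4", "C8"),
    "DC": ("N1", "C2", "C6"),
    "DT": ("N1", "C2", "C6"),
}

PURINES = {"DA", "DG", "8OG"}

# bond lengths (Å)
_CH = 1.09
_NH = 1.01
_C8_O8 = 1.23  # carbonyl formed at C8 in 8-oxoguanine

# sugar ring targets: canonical C2'-endo pucker of B-form DNA
PSEUDOROTATION_P = 162.0
PSEUDOROTATION_TM = 38.0


def _unit(v):
    v = np.asarray(v, float)
    return v / np.linalg.norm(v)


def _sp2_h(center, n1, n2, length):
    """Place one substituent on an sp2 centre bonded to n1 and n2."""
    d = -(_unit(n1 - center) + _unit(n2 - center))
    return center + length * _unit(d)


def _amino_h(n, c, plane_ref, length=_NH):
    """Two hydrogens of a planar amino group N(-C)H2, in the base plane."""
    e = _unit(c - n)
    # in-plane perpendicular to the N-C bond
    normal = _unit(np.cross(c - n, plane_ref - n))
    perp = _unit(np.cross(normal, e))
    h1 = n + length * _unit(-e * np.cos(np.radians(60)) + perp * np.sin(np.radians(60)))
    h2 = n + length * _unit(-e * np.cos(np.radians(60)) - perp * np.sin(np.radians(60)))
    return h1, h2


def _derive_8og(g: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """8-oxoguanine from the guanine table: O8 replaces H8, N7 is protonated."""
    t = {k: v.copy() for k, v in g.items()}
    h8_dir = _unit(-(_unit(t["N7"] - t["C8"]) + _unit(t["N9"] - t["C8"])))
    t["O8"] = t["C8"] + _C8_O8 * h8_dir
    t["H7"] = _sp2_h(t["N7"], t["C8"], t["C5"], _NH)
    return t


def _base_hydrogens(code: str, t: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    h: dict[str, np.ndarray] = {}
    if code == "DA":
        h["H8"] = _sp2_h(t["C8"], t["N7"], t["N9"], _CH)
        h["H2"] = _sp2_h(t["C2"], t["N1"], t["N3"], _CH)
        h["H61"], h["H62"] = _amino_h(t["N6"], t["C6"], t["N1"])
    elif code in ("DG", "8OG"):
        if code == "DG":
            h["H8"] = _sp2_h(t["C8"], t["N7"], t["N9"], _CH)
        h["H1"] = _sp2_h(t["N1"], t["C2"], t["C6"], _NH)
        h["H21"], h["H22"] = _amino_h(t["N2"], t["C2"], t["N1"])
    elif code == "DC":
        h["H5"] = _sp2_h(t["C5"], t["C4"], t["C6"], _CH)
        h["H6"] = _sp2_h(t["C6"], t["C5"], t["N1"], _CH)
        h["H41"], h["H42"] = _amino_h(t["N4"], t["C4"], t["N3"])
    elif code == "DT":
        h["H6"] = _sp2_h(t["C6"], t["C5"], t["N1"], _CH)
        h["H3"] = _sp2_h(t["N3"], t["C2"], t["C4"], _NH)
        # methyl: tetrahedral about C7, staggered with respect to C4
        for name, tor in (("H71", 60.0), ("H72", 180.0), ("H73", 300.0)):
            h[name] = place_atom(t["C4"], t["C5"], t["C7"], _CH, 109.5, tor)
    return h


@lru_cache(maxsize=None)
def base_table(code: str, hydrogens: bool = True) -> dict[str, np.ndarray]:
    """Standard-frame coordinates for one base type, optionally with hydrogens."""
    if code == "8OG":
        t = _derive_8og(BASE_TABLES["DG"])
    else:
        t = {k: v.copy() for k, v in BASE_TABLES[code].items()}
    if hydrogens:
        t.update(_base_hydrogens(code, t))
    return t


# ---------------------------------------------------------------------------
# Deoxyribose ring by ring closure against pseudorotation targets
# ---------------------------------------------------------------------------

_RING = ("C4'", "O4'", "C1'", "C2'", "C3'")
_RING_BONDS = {  # Å, around the ring C4'-O4'-C1'-C2'-C3'-C4'
    ("C4'", "O4'"): 1.446,
    ("O4'", "C1'"): 1.420,
    ("C1'", "C2'"): 1.521,
    ("C2'", "C3'"): 1.523,
    ("C3'", "C4'"): 1.525,
}
_RING_ANGLES = {  # degrees
    ("C3'", "C4'", "O4'"): 105.6,
    ("C4'", "O4'", "C1'"): 109.7,
    ("O4'", "C1'", "C2'"): 106.1,
    ("C1'", "C2'", "C3'"): 102.7,
    ("C2'", "C3'", "C4'"): 103.2,
}
# nu torsions in ring order: nu0 about O4'-C1', ..., nu4 about C4'-O4'
_NU_DEFS = (
    ("C4'", "O4'", "C1'", "C2'"),  # nu0
    ("O4'", "C1'", "C2'", "C3'"),  # nu1
    ("C1'", "C2'", "C3'", "C4'"),  # nu2
    ("C2'", "C3'", "C4'", "O4'"),  # nu3
    ("C3'", "C4'", "O4'", "C1'"),  # nu4
)


def pseudorotation_to_nus(P: float, tau_m: float) -> np.ndarray:
    """The five endocyclic torsions implied by phase P and amplitude tau_m."""
    j = np.arange(5)
    return tau_m * np.cos(np.radians(P + 144.0 * (j - 2)))


@lru_cache(maxsize=None)
def sugar_ring_template(P: float = PSEUDOROTATION_P,
                        tau_m: float = PSEUDOROTATION_TM) -> dict[str, np.ndarray]:
    """Five-membered furanose ring realizing the requested pucker.

    Solved once by least squares over the 15 ring coordinates against the
    ideal bond lengths, ring angles and the five pseudorotation torsions;
    the result is cached.
    """
    nus = pseudorotation_to_nus(P, tau_m)

    # initial guess: flat regular pentagon with a small out-of-plane kick
    r0 = 1.45 / (2 * np.sin(np.pi / 5))
    ang = 2 * np.pi * np.arange(5) / 5
    x0 = np.column_stack([r0 * np.cos(ang), r0 * np.sin(ang), 0.05 * np.sin(2 * ang)])

    def resid(flat):
        X = flat.reshape(5, 3)
        pos = dict(zip(_RING, X))
        out = []
        for (a, b), d in _RING_BONDS.items():
            out.append(np.linalg.norm(pos[a] - pos[b]) - d)
        for (a, b, c), th in _RING_ANGLES.items():
            out.append(0.02 * (bond_angle(pos[a], pos[b], pos[c]) - th))
        for (a, b, c, d), nu in zip(_NU_DEFS, nus):
            out.append(0.2 * (dihedral(pos[a], pos[b], pos[c], pos[d]) - nu))
        return out

    sol = least_squares(resid, x0.ravel(), xtol=1e-14, ftol=1e-14)
    X = sol.x.reshape(5, 3)
    ring = dict(zip(_RING, X))
    # verify: realized torsions must reproduce the requested pucker
    got = [dihedral(*(ring[a] for a in quad)) for quad in _NU_DEFS]
    if np.max(np.abs(np.asarray(got) - nus)) > 0.5:
        raise RuntimeError("sugar ring closure failed to realize the pucker")
    return ring


def _sp3_two_h(c, n1, n2, length=_CH, half_angle=54.25):
    """Two hydrogens on an sp3 carbon with two heavy neighbours n1, n2."""
    b = -_unit(_unit(n1 - c) + _unit(n2 - c))
    perp = _unit(np.cross(n1 - c, n2 - c))
    h1 = c + length * _unit(b * np.cos(np.radians(half_angle))
                            + perp * np.sin(np.radians(half_angle)))
    h2 = c + length * _unit(b * np.cos(np.radians(half_angle))
                            - perp * np.sin(np.radians(half_angle)))
    return h1, h2


def _sp3_one_h(c, n1, n2, n3, length=_CH):
    """The lone hydrogen on an sp3 carbon with three heavy neighbours."""
    d = -(_unit(n1 - c) + _unit(n2 - c) + _unit(n3 - c))
    return c + length * _unit(d)


@lru_cache(maxsize=None)
def standard_nucleoside(code: str, chi: float = 243.0,
                        P: float = PSEUDOROTATION_P,
                        tau_m: float = PSEUDOROTATION_TM,
                        gamma: float = 50.0,
                        hydrogens: bool = True) -> dict[str, np.ndarray]:
    """Full nucleoside (sugar + base, no phosphate) in the standard base frame.

    ``chi`` is the glycosidic torsion O4'-C1'-N9-C4 (purines) or
    O4'-C1'-N1-C2 (pyrimidines) in degrees; the default 243° is in the
    B-form *anti* range.  Returned coordinates are expressed in the base's
    standard reference frame, so a duplex builder can place the nucleoside
    with the base-pair frame directly.
    """
    ring = {k: v.copy() for k, v in sugar_ring_template(P, tau_m).items()}
    n_name, chi_atom, other_anchor = GLYCOSIDIC[code]

    # glycosidic nitrogen: on the beta face of the sugar
    n_pos = place_atom(ring["C4'"], ring["O4'"], ring["C1'"],
                       1.468, 108.2,
                       dihedral(ring["C4'"], ring["O4'"], ring["C1'"], ring["C2'"]) - 122.0)
    # anchor atoms of the base ring, realizing chi exactly
    if code in PURINES:
        a1 = place_atom(ring["O4'"], ring["C1'"], n_pos, 1.374, 126.3, chi)
        a2 = place_atom(ring["O4'"], ring["C1'"], n_pos, 1.372, 127.7, chi - 180.0)
    else:
        a1 = place_atom(ring["O4'"], ring["C1'"], n_pos, 1.397, 117.8, chi)
        a2 = place_atom(ring["O4'"], ring["C1'"], n_pos, 1.367, 121.3, chi - 180.0)

    table = base_table(code, hydrogens=hydrogens)
    src = np.array([table[n_name], table[chi_atom], table[other_anchor]])
    dst = np.array([n_pos, a1, a2])
    R, t, _ = kabsch(src, dst)
    base = {name: xyz @ R.T + t for name, xyz in table.items() if name != "C1'"}

    nuc = dict(ring)
    nuc.update(base)

    # exocyclic heavy atoms: C5' and O3' occupy the remaining tetrahedral
    # slots of C4' and C3' on the backbone (exo) face of the ring
    nuc["C5'"] = place_atom(ring["C2'"], ring["C3'"], ring["C4'"], 1.510, 114.7,
                            dihedral(ring["C2'"], ring["C3'"], ring["C4'"], ring["O4'"]) - 119.0)
    nuc["O3'"] = place_atom(ring["C1'"], ring["C2'"], ring["C3'"], 1.423, 110.6,
                            dihedral(ring["C1'"], ring["C2'"], ring["C3'"], ring["C4'"]) + 119.0)
    # torsion C3'-C4'-C5'-O5' equals gamma (dihedrals are reversal-symmetric)
    nuc["O5'"] = place_atom(ring["C3'"], ring["C4'"], nuc["C5'"], 1.440, 110.2, gamma)

    if hydrogens:
        nuc["H1'"] = _sp3_one_h(ring["C1'"], ring["O4'"], ring["C2'"], n_pos)
        nuc["H2'"], nuc["H2''"] = _sp3_two_h(ring["C2'"], ring["C1'"], ring["C3'"])
        nuc["H3'"] = _sp3_one_h(ring["C3'"], ring["C2'"], ring["C4'"], nuc["O3'"])
        nuc["H4'"] = _sp3_one_h(ring["C4'"], ring["C3'"], ring["O4'"], nuc["C5'"])
        nuc["H5'"], nuc["H5''"] = _sp3_two_h(nuc["C5'"], ring["C4'"], nuc["O5'"])

    # express in the standard base frame: the fit above moved the base to the
    # sugar; invert so the base table coordinates are restored and the sugar
    # follows.  (Rotation R, t maps table -> current; apply the inverse.)
    out = {}
    for name, xyz in nuc.items():
        out[name] = (xyz - t) @ R
    return out
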