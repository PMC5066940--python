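"""Ground-truth-known synthetic duplexes, ensembles and NOESY peak lists.

Two builders cover the two kinds of ground truth the analysis layer needs:

* :func:`build_helix` places ideal base pairs along a straight axis with
  exactly the requested per-step twist and rise (default 36 degrees and
  3.38 Å, the B-form fiber values) and bridges the sugar-phosphate backbone
  afterwards — helical parameters are exact, backbone torsions emerge near
  canonical BI.
* :func:`build_torsion_exact` grows the lesion-bearing strand by internal
  coordinates so the requested epsilon/zeta are realized exactly at the
  requested positions (to inject BII at chosen steps), then places the
  complementary strand by ideal pairing geometry — torsions are exact,
  helical parameters emerge.

Exact helical placement cannot simultaneously guarantee exact backbone
torsions, which is why there are two builders; every downstream test uses
the builder that owns its ground truth.

:func:`make_ensemble` adds independent Gaussian coordinate jitter per model
(no attempt is made to mimic the covariance of a physical trajectory), and
:func:`synth_peaklist` emits cross-peak volumes as noisy r^-6 transforms of
the true interproton distances.  All randomness flows from explicit seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial import cKDTree

from duplexlens.errors import BuildError
from duplexlens.geometry import bond_angle, dihedral, place_atom, wrap_signed
from duplexlens.helix import FLIP_X, base_frame
from duplexlens.restraints import Peak
from duplexlens.stdgeom import standard_nucleoside
from duplexlens.structures import (
    Atom,
    Residue,
    Structure,
    complement_sequence,
    parse_sequence,
)

__all__ = [
    "GeneratorSpec",
    "build_helix",
    "build_torsion_exact",
    "make_ensemble",
    "synth_peaklist",
    "DEFAULT_TORSIONS",
]

# bond lengths (Å) and angles (degrees) of the phosphodiester linkage
_L = {"O3'-P": 1.607, "P-O5'": 1.593, "O5'-C5'": 1.440, "C5'-C4'": 1.510,
      "C4'-C3'": 1.525, "C3'-O3'": 1.423, "P-OP": 1.485}
_A = {"C3'-O3'-P": 119.7, "O3'-P-O5'": 104.0, "P-O5'-C5'": 120.9,
      "O5'-C5'-C4'": 110.2, "C5'-C4'-C3'": 114.7, "C4'-C3'-O3'": 110.6,
      "OP-P-OP": 119.6}

#: canonical B-form/BI backbone and glycosidic torsions, degrees
DEFAULT_TORSIONS = {"alpha": 300.0, "beta": 176.0, "gamma": 50.0,
                    "epsilon": 190.0, "zeta": 265.0, "chi": 243.0}

_ELEMENT_OVERRIDES = {"OP1": "O", "OP2": "O"}

# atom emission order within a residue (present atoms only)
_ATOM_ORDER = [
    "P", "OP1", "OP2", "O5'", "C5'", "C4'", "O4'", "C3'", "O3'", "C2'", "C1'",
    "H5'", "H5''", "H4'", "H3'", "H2'", "H2''", "H1'",
    "N9", "C8", "N7", "O8", "C5", "C6", "O6", "N6", "N1", "C2", "N2", "O2",
    "N3", "C4", "N4", "O4", "C7",
    "H8", "H7", "H1", "H2", "H3", "H5", "H6",
    "H21", "H22", "H41", "H42", "H61", "H62", "H71", "H72", "H73",
]


def _element(name: str) -> str:
    return _ELEMENT_OVERRIDES.get(name, name[0])


@dataclass
class GeneratorSpec:
    """Everything the synthetic builders need, with study-matched defaults.

    ``sequence`` uses one-letter IUPAC codes plus X for 8-oxoguanine; the
    complementary strand is derived automatically.  ``twist_overrides`` maps
    step index -> degrees, ``eps_zeta`` maps nucleotide position -> target
    (epsilon, zeta) in degrees for the step 3' of that nucleotide.
    """

    sequence: str
    twist: float = 36.0
    rise: float = 3.38
    twist_overrides: dict[int, float] = field(default_factory=dict)
    eps_zeta: dict[int, tuple[float, float]] = field(default_factory=dict)
    jitter: float = 0.0
    n_models: int = 1
    seed: int = 0

    def __post_init__(self):
        parse_sequence(self.sequence)  # validates symbols
        if self.jitter < 0:
            raise ValueError("jitter sigma must be >= 0")
        if self.n_models < 1:
            raise ValueError("n_models must be >= 1")
        n = len(self.sequence)
        for k in self.twist_overrides:
            if not 1 <= k <= n - 1:
                raise ValueError(f"twist override step {k} outside 1..{n - 1}")
        for p in self.eps_zeta:
            if not 1 <= p <= n - 1:
                raise ValueError(f"eps/zeta target position {p} outside 1..{n - 1}")

    @property
    def step_twists(self) -> list[float]:
        return [self.twist_overrides.get(k, self.twist)
                for k in range(1, len(self.sequence))]


def _rz(theta_deg: float) -> np.ndarray:
    c, s = np.cos(np.radians(theta_deg)), np.sin(np.radians(theta_deg))
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _make_residue(index: int, code: str, coords: dict[str, np.ndarray]) -> Residue:
    atoms = [Atom(n, _element(n), coords[n]) for n in _ATOM_ORDER if n in coords]
    leftovers = set(coords) - {a.name for a in atoms}
    if leftovers:
        raise BuildError(f"atoms without an emission slot: {sorted(leftovers)}")
    return Residue(index, code, atoms)


def _bridge_phosphate(prev: dict[str, np.ndarray], nxt: dict[str, np.ndarray],
                      eps_target: float = DEFAULT_TORSIONS["epsilon"],
                      zeta_target: float = DEFAULT_TORSIONS["zeta"]) -> dict[str, np.ndarray]:
    """Place P (and OP1/OP2) linking prev O3' to next O5' by least squares.

    Bond lengths and angles are hard targets; epsilon/zeta of the linkage are
    soft targets that keep the bridged backbone in the BI region.
    """
    o3, c3, c4 = prev["O3'"], prev["C3'"], prev["C4'"]
    o5, c5 = nxt["O5'"], nxt["C5'"]

    # P lies on the circle where the two bond-length spheres intersect;
    # the remaining circle angle is chosen to best satisfy the bond angles
    # and (softly) the epsilon/zeta targets.
    r1, r2 = _L["O3'-P"], _L["P-O5'"]
    d_vec = o5 - o3
    d = float(np.linalg.norm(d_vec))
    if d >= r1 + r2 - 0.05 or d <= 0.5:
        raise BuildError(
            f"cannot bridge phosphate: O3'..O5' gap {d:.2f} Å is unphysical")
    a = (r1 ** 2 - r2 ** 2 + d ** 2) / (2.0 * d)
    rho = np.sqrt(max(r1 ** 2 - a ** 2, 1e-12))
    e1 = d_vec / d
    ref = c3 - o3
    e2 = ref - np.dot(ref, e1) * e1
    e2 /= np.linalg.norm(e2)
    e3 = np.cross(e1, e2)
    centre = o3 + a * e1

    def candidate(phi):
        return centre + rho * (np.cos(phi) * e2 + np.sin(phi) * e3)

    def score(phi):
        p = candidate(phi)
        s = (bond_angle(c3, o3, p) - _A["C3'-O3'-P"]) ** 2
        s += (bond_angle(p, o5, c5) - _A["P-O5'-C5'"]) ** 2
        s += 0.3 * wrap_signed(dihedral(c4, c3, o3, p) - eps_target) ** 2
        s += 0.3 * wrap_signed(dihedral(c3, o3, p, o5) - zeta_target) ** 2
        return s

    grid = np.linspace(0.0, 2.0 * np.pi, 180, endpoint=False)
    phi0 = grid[int(np.argmin([score(g) for g in grid]))]
    sol = least_squares(lambda x: np.sqrt(score(x[0])), [phi0], diff_step=1e-4)
    p = candidate(float(sol.x[0]))
    # the two non-bridging oxygens, symmetric about the O3'-P-O5' bisector
    u1 = (o3 - p) / np.linalg.norm(o3 - p)
    u2 = (o5 - p) / np.linalg.norm(o5 - p)
    bis = -(u1 + u2)
    bis /= np.linalg.norm(bis)
    perp = np.cross(u1, u2)
    perp /= np.linalg.norm(perp)
    half = np.radians(_A["OP-P-OP"] / 2.0)
    op1 = p + _L["P-OP"] * (bis * np.cos(half) + perp * np.sin(half))
    op2 = p + _L["P-OP"] * (bis * np.cos(half) - perp * np.sin(half))
    return {"P": p, "OP1": op1, "OP2": op2}


def _clash_check(model: dict, min_dist: float = 0.8) -> None:
    xyz, keys = [], []
    for cid, residues in model.items():
        for r in residues:
            for a in r.atoms:
                xyz.append(a.xyz)
                keys.append((cid, r.index, a.name))
    xyz = np.asarray(xyz)
    tree = cKDTree(xyz)
    for i, j in tree.query_pairs(min_dist):
        # atoms of the same or adjacent residues may be covalently bonded
        if keys[i][0] == keys[j][0] and abs(keys[i][1] - keys[j][1]) <= 1:
            continue
        raise BuildError(f"steric clash between {keys[i]} and {keys[j]}")


def _strand_residues(placed: list[tuple[int, str, dict[str, np.ndarray]]],
                     eps_targets: dict[int, tuple[float, float]] | None = None
                     ) -> list[Residue]:
    """Assemble residues 5'->3', bridging phosphates between neighbours."""
    eps_targets = eps_targets or {}
    out = []
    for k, (idx, code, coords) in enumerate(placed):
        coords = dict(coords)
        if k > 0:
            et, zt = eps_targets.get(
                placed[k - 1][0],
                (DEFAULT_TORSIONS["epsilon"], DEFAULT_TORSIONS["zeta"]))
            coords.update(_bridge_phosphate(placed[k - 1][2], coords, et, zt))
        out.append(_make_residue(idx, code, coords))
    return out


def build_helix(spec: GeneratorSpec):
    """Ideal duplex with exactly the requested per-step twist and rise.

    Base-pair frames are stacked along the z axis; within each frame the
    strand-A nucleoside sits in the standard base frame and the strand-B
    partner is its 180-degree flip about x.  Phosphates are bridged in
    afterwards with BI-soft targets.  Returns the single-model Structure and
    the ground-truth (twist, rise) per step.
    """
    codes_a = parse_sequence(spec.sequence)
    seq_b = complement_sequence(spec.sequence)
    codes_b_by_pair = parse_sequence(seq_b)[::-1]  # indexed by pair number
    n = len(codes_a)
    twists = spec.step_twists

    placed_a, placed_b = [], []
    theta, z = 0.0, 0.0
    for k in range(n):
        if k > 0:
            theta += twists[k - 1]
            z += spec.rise
        R = _rz(theta)
        origin = np.array([0.0, 0.0, z])
        nuc_a = standard_nucleoside(codes_a[k])
        placed_a.append((k + 1, codes_a[k],
                         {nm: origin + R @ xyz for nm, xyz in nuc_a.items()}))
        nuc_b = standard_nucleoside(codes_b_by_pair[k])
        placed_b.append((n - k, codes_b_by_pair[k],
                         {nm: origin + R @ (FLIP_X @ xyz) for nm, xyz in nuc_b.items()}))

    # eps/zeta targets act as soft preferences on the strand-A phosphate
    # placement here (exact realization is build_torsion_exact's job)
    chain_a = _strand_residues(placed_a, spec.eps_zeta)
    chain_b = _strand_residues(placed_b[::-1])  # strand B runs 5'->3' as pair n..1
    model = {"A": chain_a, "B": chain_b}
    _clash_check(model)
    s = Structure([model], meta=f"synthetic helix {spec.sequence}")
    truth = [{"step": k + 1, "twist": twists[k], "rise": spec.rise}
             for k in range(n - 1)]
    return s, truth


def _chain_step(atoms_in, alpha, beta, gamma, delta, eps, zeta):
    """Grow one backbone repeat: returns this residue's atoms and the next seed."""
    o5, c5, c4 = atoms_in
    at = {"O5'": o5, "C5'": c5, "C4'": c4}
    at["C3'"] = place_atom(o5, c5, c4, _L["C4'-C3'"], _A["C5'-C4'-C3'"], gamma)
    at["O3'"] = place_atom(c5, c4, at["C3'"], _L["C3'-O3'"], _A["C4'-C3'-O3'"], delta)
    p = place_atom(c4, at["C3'"], at["O3'"], _L["O3'-P"], _A["C3'-O3'-P"], eps)
    o5n = place_atom(at["C3'"], at["O3'"], p, _L["P-O5'"], _A["O3'-P-O5'"], zeta)
    c5n = place_atom(at["O3'"], p, o5n, _L["O5'-C5'"], _A["P-O5'-C5'"], alpha)
    c4n = place_atom(p, o5n, c5n, _L["C5'-C4'"], _A["O5'-C5'-C4'"], beta)
    at["P_next"] = p
    return at, (o5n, c5n, c4n)


def _seed_atoms():
    o5 = np.zeros(3)
    c5 = np.array([_L["O5'-C5'"], 0.0, 0.0])
    ang = np.radians(_A["O5'-C5'-C4'"])
    c4 = c5 + _L["C5'-C4'"] * np.array([-np.cos(ang), np.sin(ang), 0.0])
    return o5, c5, c4


def _dress(code, chain_atoms, chi=None):
    """Rigidly attach sugar ring, base and hydrogens onto chain C5'-C4'-C3'."""
    from duplexlens.geometry import kabsch

    tmpl = standard_nucleoside(code) if chi is None else standard_nucleoside(code, chi=chi)
    src = np.array([tmpl["C5'"], tmpl["C4'"], tmpl["C3'"]])
    dst = np.array([chain_atoms["C5'"], chain_atoms["C4'"], chain_atoms["C3'"]])
    R, tr, rmsd = kabsch(src, dst)
    if rmsd > 0.05:
        raise BuildError("nucleoside template mismatch during chain dressing")
    # chain atoms are authoritative: the ring solver's ~1e-3 Å bond residue
    # would otherwise leak into the realized backbone torsions
    skip = ("O5'", "C5'", "C4'", "C3'", "O3'")
    coords = {nm: xyz @ R.T + tr for nm, xyz in tmpl.items() if nm not in skip}
    for nm in skip:
        coords[nm] = chain_atoms[nm]
    return coords


def _template_delta() -> float:
    tmpl = standard_nucleoside("DG")
    return dihedral(tmpl["C5'"], tmpl["C4'"], tmpl["C3'"], tmpl["O3'"],
                    range="unsigned")


_CALIB_CACHE: dict[tuple[float, float], tuple[float, float, float]] = {}


def _calibrate_chain(eps: float, zeta: float) -> tuple[float, float, float, float, float]:
    """Backbone parameters keeping the internal-coordinate chain on a B-form helix.

    For the default BI linkage, the five uniform-chain knobs (alpha, beta,
    gamma, chi, delta) are solved so that every step realizes twist ~36
    degrees, rise ~3.38 Å and a bridgeable complementary-strand backbone.
    For an overridden (eps, zeta) linkage — a BII injection — only alpha and
    beta of the following residue compensate (the beta/gamma crankshaft that
    accompanies a BI->BII transition); its ring shape stays at the uniform
    default so every downstream step is unaffected.  Solutions are cached.
    """
    key = (round(eps, 3), round(zeta, 3))
    if key in _CALIB_CACHE:
        return _CALIB_CACHE[key]
    from duplexlens.helix import step_twist  # deferred: cycle at module load
    from duplexlens.structures import Atom as _Atom, Residue as _Residue

    default_key = (190.0, 265.0)
    is_default = key == default_key
    if not is_default and default_key not in _CALIB_CACHE:
        _calibrate_chain(*default_key)
    delta_centre = _template_delta()

    def params(x):
        if is_default:
            alpha, beta, gamma, chi, dlt = x
            defaults = x
        else:
            alpha, beta = x
            _, _, gamma, chi, dlt = _CALIB_CACHE[default_key]
            defaults = _CALIB_CACHE[default_key]
        seed = _seed_atoms()
        frames = []
        for k in range(2):
            # the probed linkage sits between residues 1 and 2; alpha/beta of
            # a _chain_step call seed the *next* residue, gamma/delta shape
            # the current one
            at, seed = _chain_step(
                seed,
                alpha=alpha if k == 0 else defaults[0],
                beta=beta if k == 0 else defaults[1],
                gamma=defaults[2] if k == 0 else gamma,
                delta=defaults[4] if k == 0 else dlt,
                eps=eps if k == 0 else 190.0,
                zeta=zeta if k == 0 else 265.0,
            )
            coords = _dress("DG", at, chi=defaults[3] if k == 0 else chi)
            atoms = [_Atom(nm, _element(nm), xyz) for nm in _ATOM_ORDER
                     if (xyz := coords.get(nm)) is not None]
            frames.append(base_frame(_Residue(k + 1, "DG", atoms)))
        sp = step_twist(frames[0], frames[1])
        # complementary-strand linkage of the same step: its 5'->3' runs from
        # the partner of residue 2 to the partner of residue 1
        partner = []
        for fr in frames:
            nucb = standard_nucleoside("DC")
            partner.append({nm: fr.origin + fr.axes @ (FLIP_X @ xyz)
                            for nm, xyz in nucb.items()})
        gap_b = float(np.linalg.norm(partner[1]["O3'"] - partner[0]["O5'"]))
        return sp.twist, sp.rise, gap_b

    if is_default:
        def wrongness(x):
            tw, ri, gb = params(x)
            return [tw - 36.0, 3.0 * (ri - 3.38), 2.0 * (gb - 2.50),
                    0.02 * (x[0] - 300.0), 0.02 * (x[1] - 176.0),
                    0.02 * (x[2] - 50.0), 0.05 * (x[3] - 243.0),
                    0.05 * (x[4] - delta_centre)]

        sol = least_squares(wrongness, [300.0, 176.0, 50.0, 243.0, delta_centre],
                            diff_step=1e-3)
        out = tuple(float(v) for v in sol.x)
        tol_twist = 3.0
    else:
        def wrongness(x):
            tw, ri, gb = params(x)
            return [0.3 * (tw - 36.0), 3.0 * (ri - 3.38), 3.0 * (gb - 2.50),
                    0.01 * (x[0] - 300.0), 0.01 * (x[1] - 176.0)]

        sol = least_squares(wrongness, [300.0, 176.0], diff_step=1e-3)
        d0 = _CALIB_CACHE[default_key]
        out = (float(sol.x[0]), float(sol.x[1]), d0[2], d0[3], d0[4])
        tol_twist = 12.0  # a BII linkage legitimately under- or over-winds

    tw, ri, gb = params(sol.x)
    if abs(tw - 36.0) > tol_twist or abs(ri - 3.38) > 0.5 or not 1.9 < gb < 3.1:
        raise BuildError(
            f"no B-form-compatible backbone for eps={eps}, zeta={zeta} "
            f"(best twist {tw:.1f}, rise {ri:.2f}, partner gap {gb:.2f})")
    _CALIB_CACHE[key] = out
    return out


def build_torsion_exact(spec: GeneratorSpec) -> Structure:
    """Duplex whose strand-A backbone realizes requested torsions exactly.

    Strand A is grown 5'->3' by internal-coordinate chaining with canonical
    B-form torsions; per-position (epsilon, zeta) targets from
    ``spec.eps_zeta`` are realized exactly (they are chain torsions).  The
    complementary strand is placed by ideal Watson-Crick geometry from each
    strand-A base frame and its backbone is bridged with BI-soft targets.
    """
    for p, (e, zt) in spec.eps_zeta.items():
        if not (0 <= e < 360 and 0 <= zt < 360):
            raise BuildError("epsilon/zeta targets must lie in [0, 360)")
    codes_a = parse_sequence(spec.sequence)
    n = len(codes_a)
    t = DEFAULT_TORSIONS
    # chain torsions are pre-calibrated so the default linkage realizes a
    # B-form helix; an overridden (eps, zeta) linkage gets compensating
    # alpha/beta/gamma on the following residue
    defaults5 = _calibrate_chain(t["epsilon"], t["zeta"])
    a0, b0, g0, x0, d0 = defaults5

    seed = _seed_atoms()
    chain_atoms: list[dict[str, np.ndarray]] = []
    chis: list[float] = []
    gamma_next, chi_next, delta_next = g0, x0, d0
    for i in range(1, n + 1):
        eps, zeta = spec.eps_zeta.get(i, (t["epsilon"], t["zeta"]))
        if (eps, zeta) == (t["epsilon"], t["zeta"]):
            alpha, beta, gamma_after, chi_after, delta_after = defaults5
        else:
            alpha, beta, gamma_after, chi_after, delta_after = _calibrate_chain(eps, zeta)
        atoms, seed = _chain_step(seed, alpha, beta, gamma_next,
                                  delta_next, eps, zeta)
        if i == n:
            atoms.pop("P_next", None)
        chain_atoms.append(atoms)
        chis.append(chi_next)
        gamma_next, chi_next, delta_next = gamma_after, chi_after, delta_after

    # dress each strand-A residue with its sugar ring, base and hydrogens by
    # rigid fit of the standard nucleoside onto the chain C5'-C4'-C3' triad
    placed_a = [(i, code, _dress(code, chain_atoms[i - 1], chi=chis[i - 1]))
                for i, code in enumerate(codes_a, start=1)]

    # exact phosphates from the chain construction
    chain_a: list[Residue] = []
    for k, (idx, code, coords) in enumerate(placed_a):
        coords = dict(coords)
        if k > 0:
            prev = dict(placed_a[k - 1][2])
            p = chain_atoms[k - 1]["P_next"]
            o3, o5b, c5b = prev["O3'"], coords["O5'"], coords["C5'"]
            u1 = (o3 - p) / np.linalg.norm(o3 - p)
            u2 = (o5b - p) / np.linalg.norm(o5b - p)
            bis = -(u1 + u2)
            bis /= np.linalg.norm(bis)
            perp = np.cross(u1, u2)
            perp /= np.linalg.norm(perp)
            half = np.radians(_A["OP-P-OP"] / 2.0)
            coords["P"] = p
            coords["OP1"] = p + _L["P-OP"] * (bis * np.cos(half) + perp * np.sin(half))
            coords["OP2"] = p + _L["P-OP"] * (bis * np.cos(half) - perp * np.sin(half))
        chain_a.append(_make_residue(idx, code, coords))

    # complementary strand from the strand-A base frames
    seq_b = complement_sequence(spec.sequence)
    codes_b = parse_sequence(seq_b)
    placed_b = []
    for i in range(1, n + 1):  # pair index along strand A
        fr = base_frame(chain_a[i - 1])
        code_b = codes_b[n - i]  # strand-B residue paired with A:i
        nuc = standard_nucleoside(code_b)
        coords = {nm: fr.origin + fr.axes @ (FLIP_X @ xyz) for nm, xyz in nuc.items()}
        placed_b.append((n + 1 - i, code_b, coords))
    chain_b = _strand_residues(placed_b[::-1])

    model = {"A": chain_a, "B": chain_b}
    _clash_check(model)
    return Structure([model], meta=f"synthetic torsion-exact {spec.sequence}")


def make_ensemble(s: Structure, sigma: float, n: int, seed: int = 0) -> Structure:
    """n models, each model 0 of ``s`` plus iid Gaussian jitter of scale sigma."""
    if sigma < 0 or n < 1:
        raise ValueError("need sigma >= 0 and n >= 1")
    rng = np.random.default_rng(seed)
    base = s.coords(0)
    frames = [base + rng.normal(0.0, sigma, size=base.shape) if sigma > 0
              else base.copy() for _ in range(n)]
    return s.with_coords(frames, meta=f"{s.meta} [{n} jittered models, sigma={sigma}]")


def synth_peaklist(s: Structure, max_distance: float = 5.0, noise: float = 0.0,
                   seed: int = 0, mixing_times: tuple[float, ...] = (70.0, 140.0, 200.0),
                   chains: tuple[str, ...] = ("A",), model: int = 0,
                   drop_fraction: float = 0.0) -> list[Peak]:
    """NOESY-like peak list from true interproton distances of one model.

    Every proton pair within ``max_distance`` (default 5 Å, the NOE horizon)
    produces one peak per mixing time with volume c_t * r^-6 * exp(noise * g),
    g ~ N(0, 1) drawn independently per observation.  Cytosine H5-H6 pairs —
    the calibration standard — are always included.  ``drop_fraction``
    randomly removes that fraction of non-reference observations, emulating
    peaks too weak or overlapped to integrate in some spectra.
    """
    rng = np.random.default_rng(seed)
    protons = []
    for cid, r, a in s.iter_atoms(model):
        if cid in chains and a.element == "H":
            protons.append(((cid, r.index, a.name), a.xyz, r.code))
    if not protons:
        raise BuildError("structure carries no hydrogens in the selected chains")
    peaks = []
    pid = 0
    for i in range(len(protons)):
        for j in range(i + 1, len(protons)):
            (ki, xi, ci), (kj, xj, cj) = protons[i], protons[j]
            r_ij = float(np.linalg.norm(xi - xj))
            is_ref = (ki[:2] == kj[:2] and ci == "DC"
                      and {ki[2], kj[2]} == {"H5", "H6"})
            if r_ij > max_distance and not is_ref:
                continue
            pid += 1
            for tmix in mixing_times:
                if not is_ref and drop_fraction > 0 and rng.random() < drop_fraction:
                    continue
                c_t = 1.0e6 * (tmix / max(mixing_times))
                vol = c_t * r_ij ** -6.0
                if noise > 0:
                    vol *= float(np.exp(noise * rng.normal()))
                peaks.append(Peak(f"p{pid}@{tmix:g}", ki, kj, vol, tmix))
    return peaks
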