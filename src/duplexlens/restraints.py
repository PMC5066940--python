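"""NOESY peak calibration, restraint compilation and violation scoring.

The workflow mirrors standard solution-NMR structure determination of DNA
duplexes:

1. cross-peak volumes are calibrated to distances by the isolated-spin-pair
   r^-6 law against the fixed cytosine H5-H6 distance, independently within
   each mixing-time set;
2. a proton pair observed in every mixing-time set contributes its mean
   distance ("averaged"); otherwise the highest-volume observation is used
   ("non-averaged");
3. distances are grouped short (< 3.0 Å) / medium (3.0-5.0 Å) / long
   (> 5.0 Å), with methyl-containing restraints set apart and given a
   +1.0 Å pseudoatom correction on the upper bound;
4. every restraint is duplicated onto the second strand of a
   self-complementary duplex through the palindromic dyad;
5. Watson-Crick heavy-atom restraints are emitted for non-terminal pairs,
   and backbone dihedral restraints enforce BI everywhere except the
   8-oxoguanine step, which is held in the BII ranges (epsilon 215-295,
   zeta 155-205 degrees) with the four flanking dihedrals broadened by
   +/- 20 degrees.

Violation of a candidate structure is the distance outside [lower, upper]
(Å) or the angular distance outside the allowed arc (degrees), maximized
per model.
"""

from __future__ import annotations

import io
import json
import warnings
from collections import Counter
from dataclasses import dataclass, field, replace

import numpy as np

from duplexlens.errors import RestraintError
from duplexlens.geometry import dihedral, wrap_unsigned
from duplexlens.structures import DuplexMap, Structure

__all__ = [
    "Peak",
    "DistanceRestraint",
    "DihedralRestraint",
    "ViolationReport",
    "RestraintLedger",
    "DEFAULT_TOLERANCES",
    "DEFAULT_BI_RANGES",
    "OXOG_EPSILON_RANGE",
    "OXOG_ZETA_RANGE",
    "REFERENCE_H5_H6",
    "calibrate",
    "merge_mixing_times",
    "assign_bounds",
    "duplicate_symmetry",
    "wc_restraints",
    "backbone_dihedral_restraints",
    "violation_report",
    "compile_restraints",
    "read_peaklist",
    "write_peaklist",
    "write_restraints_tsv",
    "write_upl",
]

AtomKey = tuple[str, int, str]  # (chain, residue index, atom name)

#: fixed covalent cytosine H5-H6 distance used as the calibration standard (Å)
REFERENCE_H5_H6 = 2.45

#: package-default no-penalty tolerances (lower, upper) per distance group, Å
DEFAULT_TOLERANCES: dict[str, tuple[float, float]] = {
    "short": (0.4, 0.4),
    "medium": (0.7, 0.7),
    "long": (1.0, 1.0),
}

#: pseudoatom correction added to the upper bound of methyl restraints, Å
METHYL_CORRECTION = 1.0

#: default BI backbone ranges per torsion name, degrees (package defaults,
#: centred on canonical B-form values; override via config where needed)
DEFAULT_BI_RANGES: dict[str, tuple[float, float]] = {
    "alpha": (270.0, 330.0),
    "beta": (106.0, 246.0),  # beta occupies a broad trans basin in B-DNA
    "gamma": (18.0, 78.0),
    "delta": (110.0, 170.0),
    "epsilon": (155.0, 245.0),
    "zeta": (235.0, 325.0),
}

#: BII ranges applied to the 8-oxoguanine phosphodiester step, degrees
OXOG_EPSILON_RANGE = (215.0, 295.0)
OXOG_ZETA_RANGE = (155.0, 205.0)

#: broadening applied to the dihedrals flanking the lesion's epsilon/zeta
NEIGHBOR_BROADENING = 20.0

#: heavy-atom Watson-Crick restraint target and half-width, Å
WC_TARGET = 2.9
WC_TOL = 0.2

_METHYL_ATOMS = {"H71", "H72", "H73", "C7", "M7", "Q7"}


@dataclass(frozen=True)
class Peak:
    """One NOESY cross-peak: assigned proton pair, volume, mixing time (ms)."""

    id: str
    atom_i: AtomKey
    atom_j: AtomKey
    volume: float
    mixing_time: float

    def __post_init__(self):
        if self.volume <= 0:
            raise ValueError(f"peak {self.id}: volume must be positive")

    @property
    def pair(self) -> frozenset:
        return frozenset((self.atom_i, self.atom_j))


@dataclass
class DistanceRestraint:
    """NOE or hydrogen-bond distance restraint with no-penalty bounds."""

    atom_i: AtomKey
    atom_j: AtomKey
    target: float
    lower: float
    upper: float
    group: str  # short | medium | long | methyl | wc
    provenance: str  # averaged | non-averaged | wc-hbond | symmetry-copy

    def __post_init__(self):
        if not (self.lower <= self.target <= self.upper):
            raise ValueError("restraint bounds must bracket the target")

    @property
    def pair(self) -> frozenset:
        return frozenset((self.atom_i, self.atom_j))


@dataclass
class DihedralRestraint:
    """Allowed arc [lo, hi] (degrees, in [0, 360)) on a backbone torsion."""

    atoms: tuple[AtomKey, AtomKey, AtomKey, AtomKey]
    lo: float
    hi: float
    label: str  # BI-standard | oxoG-epsilon | oxoG-zeta | neighbor-broadened
    name: str = ""  # torsion name + residue, e.g. "epsilon:A:4"

    def __post_init__(self):
        if not self.hi > self.lo:
            raise ValueError("dihedral restraint range must have positive width")


@dataclass
class ViolationReport:
    """Per-model restraint violation maxima and the offending restraints."""

    max_distance: list[float]
    max_dihedral: list[float]
    worst_distance_id: list[str]
    worst_dihedral_id: list[str]
    skipped: list[str] = field(default_factory=list)

    @property
    def overall_max_distance(self) -> float:
        return max(self.max_distance) if self.max_distance else 0.0

    @property
    def overall_max_dihedral(self) -> float:
        return max(self.max_dihedral) if self.max_dihedral else 0.0

    def to_json(self) -> str:
        return json.dumps({
            "per_model": [
                {"model": k + 1, "max_distance_A": d, "max_dihedral_deg": a,
                 "worst_distance": wd, "worst_dihedral": wa}
                for k, (d, a, wd, wa) in enumerate(
                    zip(self.max_distance, self.max_dihedral,
                        self.worst_distance_id, self.worst_dihedral_id))
            ],
            "overall_max_distance_A": self.overall_max_distance,
            "overall_max_dihedral_deg": self.overall_max_dihedral,
            "skipped": self.skipped,
        }, indent=2)


@dataclass
class RestraintLedger:
    """Bookkeeping of a compiled restraint set by provenance and group."""

    averaged: int
    non_averaged: int
    methyl: int

    @property
    def total(self) -> int:
        # methyl restraints are a distance group, counted apart from the
        # averaged/non-averaged provenance split of the remaining NOEs
        return self.averaged + self.non_averaged + self.methyl


# ---------------------------------------------------------------------------
# calibration and merging
# ---------------------------------------------------------------------------

def calibrate(peaks: list[Peak], ref_pair: frozenset | None = None,
              r_ref: float = REFERENCE_H5_H6) -> dict[float, dict[frozenset, tuple[float, float]]]:
    """Volume-to-distance calibration, independent per mixing-time set.

    ``ref_pair`` names the reference proton pair; when None, every cytosine
    H5-H6 pair found in a set serves as reference and their volumes are
    averaged.  Returns {mixing_time: {pair: (distance, volume)}}.

    r_i = r_ref * (V_ref / V_i)^(1/6)
    """
    by_time: dict[float, list[Peak]] = {}
    for p in peaks:
        by_time.setdefault(p.mixing_time, []).append(p)
    out: dict[float, dict[frozenset, tuple[float, float]]] = {}
    for t, plist in sorted(by_time.items()):
        if ref_pair is not None:
            ref_vols = [p.volume for p in plist if p.pair == ref_pair]
        else:
            ref_vols = [p.volume for p in plist if _is_h5h6(p)]
        if not ref_vols:
            raise RestraintError(
                f"mixing time {t} ms: reference peak absent, cannot calibrate")
        v_ref = float(np.mean(ref_vols))
        out[t] = {p.pair: (r_ref * (v_ref / p.volume) ** (1.0 / 6.0), p.volume)
                  for p in plist}
    return out


def _is_h5h6(p: Peak) -> bool:
    names = sorted(a[2] for a in (p.atom_i, p.atom_j))
    same_res = p.atom_i[:2] == p.atom_j[:2]
    return same_res and names == ["H5", "H6"]


def merge_mixing_times(per_set: dict[float, dict[frozenset, tuple[float, float]]]
                       ) -> dict[frozenset, tuple[float, str]]:
    """Combine calibrated distances across mixing-time sets.

    A pair present in *every* set gets the arithmetic mean ("averaged");
    otherwise the observation with the highest volume — the most reliable
    cross-peak — supplies the distance ("non-averaged").
    """
    n_sets = len(per_set)
    pairs: dict[frozenset, list[tuple[float, float]]] = {}
    for dset in per_set.values():
        for pair, (dist, vol) in dset.items():
            pairs.setdefault(pair, []).append((dist, vol))
    merged = {}
    for pair, obs in pairs.items():
        if len(obs) == n_sets and n_sets > 1:
            merged[pair] = (float(np.mean([d for d, _ in obs])), "averaged")
        else:
            best = max(obs, key=lambda dv: dv[1])
            merged[pair] = (best[0], "non-averaged")
    return merged


def assign_bounds(distance: float, atom_i: AtomKey, atom_j: AtomKey,
                  provenance: str,
                  tolerances: dict[str, tuple[float, float]] | None = None,
                  involves_methyl: bool | None = None) -> DistanceRestraint:
    """Group a distance and attach no-penalty bounds.

    Grouping: short < 3.0 Å, medium 3.0-5.0 Å, long > 5.0 Å.  A restraint
    involving a methyl proton is labelled "methyl" regardless of its length
    and its upper bound receives the +1.0 Å pseudoatom correction.
    """
    if distance <= 0:
        raise RestraintError("distance must be positive")
    tol = dict(DEFAULT_TOLERANCES)
    if tolerances:
        tol.update(tolerances)
    if distance < 3.0:
        group = "short"
    elif distance <= 5.0:
        group = "medium"
    else:
        group = "long"
    lo_t, hi_t = tol[group]
    if involves_methyl is None:
        involves_methyl = atom_i[2] in _METHYL_ATOMS or atom_j[2] in _METHYL_ATOMS
    upper = distance + hi_t
    if involves_methyl:
        group = "methyl"
        upper += METHYL_CORRECTION
    return DistanceRestraint(atom_i, atom_j, distance,
                             max(distance - lo_t, 0.0), upper, group, provenance)


def duplicate_symmetry(restraints: list[DistanceRestraint],
                       dmap: DuplexMap) -> list[DistanceRestraint]:
    """Duplicate every restraint onto the other strand through the dyad.

    The palindromic dyad of a self-complementary duplex maps residue i of
    one strand to residue i of the other.  A restraint whose image is itself
    is emitted once with provenance "self-symmetric"; everything else is
    emitted twice, the copy marked "symmetry-copy".
    """
    out = []
    for r in restraints:
        try:
            img_i = dmap.symmetry_image(*r.atom_i[:2]) + (r.atom_i[2],)
            img_j = dmap.symmetry_image(*r.atom_j[:2]) + (r.atom_j[2],)
        except KeyError as e:
            raise RestraintError(
                f"restraint references residue outside the duplex map: {e}") from e
        if frozenset((img_i, img_j)) == r.pair:
            out.append(replace(r, provenance="self-symmetric"))
            continue
        out.append(r)
        out.append(replace(r, atom_i=img_i, atom_j=img_j,
                           provenance="symmetry-copy"))
    return out


# ---------------------------------------------------------------------------
# Watson-Crick and dihedral restraints
# ---------------------------------------------------------------------------

_WC_PAIRS = {
    frozenset({"G", "C"}): [("O6", "N4"), ("N1", "N3"), ("N2", "O2")],
    frozenset({"X", "C"}): [("O6", "N4"), ("N1", "N3"), ("N2", "O2")],
    frozenset({"A", "T"}): [("N6", "O4"), ("N1", "N3")],
}
_PURINE_LETTERS = {"A", "G", "X"}


def wc_restraints(dmap: DuplexMap, target: float = WC_TARGET,
                  tol: float = WC_TOL) -> list[DistanceRestraint]:
    """Canonical heavy-atom hydrogen-bond restraints for non-terminal pairs.

    Three per G:C (or 8OG:C) pair, two per A:T; terminal pairs are excluded
    because fraying makes their imino signatures unreliable.
    """
    out = []
    for (i, j), term in zip(dmap.pairs, dmap.terminal):
        if term:
            continue
        la, lb = dmap.seq_a[i - 1], dmap.seq_b[j - 1]
        bonds = _WC_PAIRS[frozenset({la, lb})]
        pur_on_a = la in _PURINE_LETTERS
        for pur_atom, pyr_atom in bonds:
            if pur_on_a:
                ai = (dmap.chain_a, i, pur_atom)
                aj = (dmap.chain_b, j, pyr_atom)
            else:
                ai = (dmap.chain_a, i, pyr_atom)
                aj = (dmap.chain_b, j, pur_atom)
            out.append(DistanceRestraint(ai, aj, target, target - tol,
                                         target + tol, "wc", "wc-hbond"))
    return out


_TORSION_ATOMS = {
    "alpha": ((-1, "O3'"), (0, "P"), (0, "O5'"), (0, "C5'")),
    "beta": ((0, "P"), (0, "O5'"), (0, "C5'"), (0, "C4'")),
    "gamma": ((0, "O5'"), (0, "C5'"), (0, "C4'"), (0, "C3'")),
    "delta": ((0, "C5'"), (0, "C4'"), (0, "C3'"), (0, "O3'")),
    "epsilon": ((0, "C4'"), (0, "C3'"), (0, "O3'"), (1, "P")),
    "zeta": ((0, "C3'"), (0, "O3'"), (1, "P"), (1, "O5'")),
}


def backbone_dihedral_restraints(sequence: str, oxo_positions: list[int],
                                 chain: str = "A",
                                 bi_ranges: dict[str, tuple[float, float]] | None = None
                                 ) -> list[DihedralRestraint]:
    """BI backbone restraints with BII ranges at the lesion.

    Canonical residues get the standard BI ranges on all defined backbone
    torsions.  At each 8-oxoguanine position the epsilon/zeta pair is
    restrained to the BII ranges (epsilon 215-295, zeta 155-205 degrees) and
    the two dihedrals on either side of that pair — delta and gamma of the
    lesion, alpha and beta of the next residue — keep their parent ranges
    broadened by +/- 20 degrees.
    """
    n = len(sequence)
    for p in oxo_positions:
        if not 1 <= p <= n:
            raise RestraintError(f"lesion position {p} outside sequence 1..{n}")
        if p == n:
            raise RestraintError(
                f"lesion at the 3'-terminal position {p} has no epsilon/zeta step")
    ranges = dict(DEFAULT_BI_RANGES)
    if bi_ranges:
        ranges.update(bi_ranges)
    broadened: dict[tuple[int, str], str] = {}
    special: dict[tuple[int, str], tuple[tuple[float, float], str]] = {}
    for p in oxo_positions:
        special[(p, "epsilon")] = (OXOG_EPSILON_RANGE, "oxoG-epsilon")
        special[(p, "zeta")] = (OXOG_ZETA_RANGE, "oxoG-zeta")
        for key in ((p, "delta"), (p, "gamma"), (p + 1, "alpha"), (p + 1, "beta")):
            broadened[key] = "neighbor-broadened"

    out = []
    for i in range(1, n + 1):
        for name in ("alpha", "beta", "gamma", "delta", "epsilon", "zeta"):
            if i == 1 and name in ("alpha", "beta"):
                continue  # no 5'-terminal phosphate
            if i == n and name in ("epsilon", "zeta"):
                continue  # no step 3' of the last residue
            atoms = tuple((chain, i + off, a) for off, a in _TORSION_ATOMS[name])
            if (i, name) in special:
                (lo, hi), label = special[(i, name)]
            elif (i, name) in broadened:
                lo, hi = ranges[name]
                lo, hi = lo - NEIGHBOR_BROADENING, hi + NEIGHBOR_BROADENING
                label = broadened[(i, name)]
            else:
                lo, hi = ranges[name]
                label = "BI-standard"
            out.append(DihedralRestraint(atoms, lo, hi, label, f"{name}:{chain}:{i}"))
    return out


# ---------------------------------------------------------------------------
# violation scoring
# ---------------------------------------------------------------------------

def _resolve(s: Structure, model: int, key: AtomKey):
    chain, idx, name = key
    return s.residue(chain, idx, model).xyz(name)


def _arc_violation(value: float, lo: float, hi: float) -> float:
    """Angular distance (degrees) of a torsion outside the arc [lo, hi]."""
    v = wrap_unsigned(value)
    if lo <= v <= hi:
        return 0.0
    d_lo = min(abs(v - lo), 360.0 - abs(v - lo))
    d_hi = min(abs(v - hi), 360.0 - abs(v - hi))
    return min(d_lo, d_hi)


def violation_report(s: Structure, distance_restraints: list[DistanceRestraint],
                     dihedral_restraints: list[DihedralRestraint] | None = None
                     ) -> ViolationReport:
    """Maximum restraint violations per model of a candidate structure.

    Distance violation is max(0, d - upper, lower - d); dihedral violation
    is the angular distance outside the allowed arc.  Restraints whose atoms
    cannot be resolved in the structure are excluded and listed, with a
    warning.
    """
    dihedral_restraints = dihedral_restraints or []
    skipped: list[str] = []
    max_d, max_a, worst_d, worst_a = [], [], [], []
    for m in range(s.n_models):
        md, wd = 0.0, ""
        for k, r in enumerate(distance_restraints):
            try:
                xi = _resolve(s, m, r.atom_i)
                xj = _resolve(s, m, r.atom_j)
            except KeyError:
                label = f"distance[{k}] {r.atom_i}-{r.atom_j}"
                if m == 0:
                    skipped.append(label)
                    warnings.warn(f"skipping unresolvable restraint {label}")
                continue
            d = float(np.linalg.norm(xi - xj))
            v = max(0.0, d - r.upper, r.lower - d)
            if v > md:
                md, wd = v, f"{r.atom_i}-{r.atom_j}"
        ma, wa = 0.0, ""
        for k, r in enumerate(dihedral_restraints):
            try:
                pts = [_resolve(s, m, a) for a in r.atoms]
            except KeyError:
                label = f"dihedral[{k}] {r.name}"
                if m == 0:
                    skipped.append(label)
                    warnings.warn(f"skipping unresolvable restraint {label}")
                continue
            v = _arc_violation(dihedral(*pts, range="unsigned"), r.lo, r.hi)
            if v > ma:
                ma, wa = v, r.name
        max_d.append(md)
        max_a.append(ma)
        worst_d.append(wd)
        worst_a.append(wa)
    return ViolationReport(max_d, max_a, worst_d, worst_a, skipped)


# ---------------------------------------------------------------------------
# end-to-end compilation
# ---------------------------------------------------------------------------

def compile_restraints(peaks: list[Peak], dmap: DuplexMap | None = None,
                       r_ref: float = REFERENCE_H5_H6,
                       tolerances: dict[str, tuple[float, float]] | None = None,
                       duplicate: bool = True
                       ) -> tuple[list[DistanceRestraint], RestraintLedger]:
    """Peak list -> calibrated, merged, grouped (and duplicated) restraints.

    Returns the restraints together with the ledger of unique-NOE counts
    (averaged + non-averaged + methyl = total); symmetry copies are not
    counted in the ledger.
    """
    per_set = calibrate(peaks, r_ref=r_ref)
    merged = merge_mixing_times(per_set)
    unique = []
    for pair, (dist, prov) in sorted(merged.items(), key=lambda kv: sorted(kv[0])):
        ai, aj = sorted(pair)
        unique.append(assign_bounds(dist, ai, aj, prov, tolerances))
    counts = Counter(
        "methyl" if r.group == "methyl" else r.provenance for r in unique)
    ledger = RestraintLedger(averaged=counts.get("averaged", 0),
                             non_averaged=counts.get("non-averaged", 0),
                             methyl=counts.get("methyl", 0))
    out = duplicate_symmetry(unique, dmap) if (duplicate and dmap) else unique
    return out, ledger


# ---------------------------------------------------------------------------
# flat-file dialects
# ---------------------------------------------------------------------------

_PEAK_HEADER = "peak_id\tchain_i\tres_i\tatom_i\tchain_j\tres_j\tatom_j\tvolume\tmixing_time_ms"


def write_peaklist(peaks: list[Peak], path) -> None:
    lines = [_PEAK_HEADER]
    for p in peaks:
        ci, ri, ai = p.atom_i
        cj, rj, aj = p.atom_j
        lines.append(f"{p.id}\t{ci}\t{ri}\t{ai}\t{cj}\t{rj}\t{aj}\t"
                     f"{p.volume:.6g}\t{p.mixing_time:g}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_peaklist(path) -> list[Peak]:
    peaks = []
    with open(path) as fh:
        header = fh.readline().strip()
        if header != _PEAK_HEADER:
            raise RestraintError(f"unexpected peak list header: {header!r}")
        for line in fh:
            if not line.strip():
                continue
            pid, ci, ri, ai, cj, rj, aj, vol, t = line.rstrip("\n").split("\t")
            peaks.append(Peak(pid, (ci, int(ri), ai), (cj, int(rj), aj),
                              float(vol), float(t)))
    return peaks


def write_restraints_tsv(restraints: list[DistanceRestraint], path) -> None:
    lines = ["atom1\tatom2\tlower\ttarget\tupper\tgroup\tprovenance"]
    for r in restraints:
        a1 = ":".join(map(str, r.atom_i))
        a2 = ":".join(map(str, r.atom_j))
        lines.append(f"{a1}\t{a2}\t{r.lower:.3f}\t{r.target:.3f}\t"
                     f"{r.upper:.3f}\t{r.group}\t{r.provenance}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_upl(restraints: list[DistanceRestraint], path,
              code_of: dict[tuple[str, int], str] | None = None) -> None:
    """CYANA-style upper-limit file (upper bounds only)."""
    lines = []
    for r in restraints:
        (ci, ri, ai), (cj, rj, aj) = r.atom_i, r.atom_j
        code_i = (code_of or {}).get((ci, ri), "DN")
        code_j = (code_of or {}).get((cj, rj), "DN")
        lines.append(f"{ri:4d} {code_i:>4s} {ai:<5s}{rj:4d} {code_j:>4s} "
                     f"{aj:<5s}{r.upper:8.2f}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
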