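"""Backbone and glycosidic torsions, BI/BII substate calls, sugar pucker.

The two B-DNA backbone substates are separated by the difference of the
phosphodiester torsions epsilon (C4'-C3'-O3'-P) and zeta (C3'-O3'-P-O5'):
BI has epsilon-zeta at or below +20 degrees (canonically around -80), BII
above +20 (canonically around +90).  Step k spans nucleotides k -> k+1, so
the 3'-terminal nucleotide of a strand has no epsilon/zeta and no step.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field

import numpy as np

from duplexlens.errors import MissingAtomError
from duplexlens.geometry import dihedral, wrap_signed, wrap_unsigned
from duplexlens.structures import Residue, Structure

__all__ = [
    "TorsionSet",
    "StepCall",
    "SugarPucker",
    "BII_THRESHOLD",
    "backbone_torsions",
    "classify_step",
    "pseudorotation",
    "pseudorotation_torsions",
    "bii_frequency",
    "bii_profile",
    "step_table",
]

#: epsilon-minus-zeta boundary between BI and BII, degrees
BII_THRESHOLD = 20.0

# torsion definitions: atom names with residue offsets (0 = this, -1/+1 = neighbours)
_BACKBONE_DEFS = {
    "alpha": (("O3'", -1), ("P", 0), ("O5'", 0), ("C5'", 0)),
    "beta": (("P", 0), ("O5'", 0), ("C5'", 0), ("C4'", 0)),
    "gamma": (("O5'", 0), ("C5'", 0), ("C4'", 0), ("C3'", 0)),
    "delta": (("C5'", 0), ("C4'", 0), ("C3'", 0), ("O3'", 0)),
    "epsilon": (("C4'", 0), ("C3'", 0), ("O3'", 0), ("P", 1)),
    "zeta": (("C3'", 0), ("O3'", 0), ("P", 1), ("O5'", 1)),
}

_NU_DEFS = {
    "nu0": ("C4'", "O4'", "C1'", "C2'"),
    "nu1": ("O4'", "C1'", "C2'", "C3'"),
    "nu2": ("C1'", "C2'", "C3'", "C4'"),
    "nu3": ("C2'", "C3'", "C4'", "O4'"),
    "nu4": ("C3'", "C4'", "O4'", "C1'"),
}

_CHI_PURINE = ("O4'", "C1'", "N9", "C4")
_CHI_PYRIMIDINE = ("O4'", "C1'", "N1", "C2")


@dataclass
class TorsionSet:
    """Backbone, glycosidic and sugar torsions of one nucleotide.

    Backbone/glycosidic angles are reported in [0, 360); sugar nu angles in
    (-180, 180].  Angles that cannot be computed (chain termini, missing
    atoms) are ``None`` and flagged unavailable.
    """

    chain: str
    index: int
    code: str
    angles: dict[str, float | None] = field(default_factory=dict)

    def __getattr__(self, name):
        try:
            return self.__dict__["angles"][name]
        except KeyError:
            raise AttributeError(name) from None

    def available(self, name: str) -> bool:
        return self.angles.get(name) is not None

    @property
    def nus(self) -> list[float] | None:
        vals = [self.angles.get(f"nu{i}") for i in range(5)]
        return None if any(v is None for v in vals) else vals


@dataclass
class StepCall:
    """BI/BII call for dinucleotide step k (nucleotides k -> k+1)."""

    chain: str
    step: int
    epsilon: float | None
    zeta: float | None
    eps_minus_zeta: float | None
    state: str | None  # "BI", "BII" or None when unclassifiable

    @property
    def classifiable(self) -> bool:
        return self.state is not None


@dataclass
class SugarPucker:
    """Pseudorotation phase P and amplitude tau_m of a furanose ring."""

    P: float
    tau_m: float
    label: str
    ambiguous: bool = False


def _torsion_atoms(chain_res: list[Residue], pos: int, spec) -> list[np.ndarray] | None:
    """Resolve a torsion's four atoms around residue at list position pos."""
    pts = []
    for name, off in spec:
        j = pos + off
        if j < 0 or j >= len(chain_res):
            return None
        r = chain_res[j]
        if not r.has_atom(name):
            return None
        pts.append(r.xyz(name))
    return pts


def backbone_torsions(s: Structure, model: int, chain: str, residue: int,
                      strict: bool = True) -> TorsionSet:
    """All backbone/glycosidic/sugar torsions of one nucleotide.

    Terminal residues lack some angles by construction (no 5' phosphate:
    alpha/beta; 3' end: epsilon/zeta); these are flagged unavailable rather
    than raised.  A *non-terminal* missing backbone atom raises
    :class:`MissingAtomError` when ``strict``.
    """
    residues = s.chain(chain, model)
    pos = next((k for k, r in enumerate(residues) if r.index == residue), None)
    if pos is None:
        raise KeyError(f"chain {chain} has no residue {residue}")
    res = residues[pos]
    angles: dict[str, float | None] = {}

    for name, spec in _BACKBONE_DEFS.items():
        pts = _torsion_atoms(residues, pos, spec)
        if pts is None:
            terminal = (pos == 0 and name in ("alpha", "beta")) or (
                pos == len(residues) - 1 and name in ("epsilon", "zeta"))
            if strict and not terminal:
                missing = [a for a, off in spec
                           if 0 <= pos + off < len(residues)
                           and not residues[pos + off].has_atom(a)]
                raise MissingAtomError(
                    f"residue {chain}:{residue} ({res.code}): cannot compute {name}, "
                    f"missing atom(s) {missing}")
            angles[name] = None
        else:
            angles[name] = dihedral(*pts, range="unsigned")

    chi_def = _CHI_PURINE if res.code in ("DA", "DG", "8OG") else _CHI_PYRIMIDINE
    if all(res.has_atom(a) for a in chi_def):
        angles["chi"] = dihedral(*(res.xyz(a) for a in chi_def), range="unsigned")
    else:
        angles["chi"] = None

    for name, quad in _NU_DEFS.items():
        if all(res.has_atom(a) for a in quad):
            angles[name] = dihedral(*(res.xyz(a) for a in quad), range="signed")
        else:
            angles[name] = None

    return TorsionSet(chain, residue, res.code, angles)


def classify_step(ts: TorsionSet) -> StepCall:
    """BI/BII call for the step 3' of the given nucleotide.

    eps_minus_zeta is wrapped into (-180, 180]; values above +20 degrees are
    BII, at or below are BI (the boundary itself is assigned to BI).  If
    epsilon or zeta is unavailable the call is explicit null, not an error.
    """
    eps, zeta = ts.angles.get("epsilon"), ts.angles.get("zeta")
    if eps is None or zeta is None:
        return StepCall(ts.chain, ts.index, eps, zeta, None, None)
    emz = wrap_signed(eps - zeta)
    state = "BII" if emz > BII_THRESHOLD else "BI"
    return StepCall(ts.chain, ts.index, eps, zeta, emz, state)


def pseudorotation(nu0: float, nu1: float, nu2: float, nu3: float, nu4: float) -> SugarPucker:
    """Pseudorotation phase and amplitude from the five endocyclic torsions.

    tan P = ((nu4 + nu1) - (nu3 + nu0)) / (2 nu2 (sin 36 + sin 72));
    tau_m = nu2 / cos P.  P is reported in [0, 360).  A near-zero nu2 with a
    near-zero numerator makes the phase indeterminate; the result is then
    flagged ambiguous instead of raising.
    """
    num = (nu4 + nu1) - (nu3 + nu0)
    den = 2.0 * nu2 * (math.sin(math.radians(36.0)) + math.sin(math.radians(72.0)))
    ambiguous = abs(nu2) < 1e-6 and abs(num) < 1e-6
    P = math.degrees(math.atan2(num, den))
    P = wrap_unsigned(P)
    cosP = math.cos(math.radians(P))
    if abs(cosP) > 1e-9:
        tau_m = nu2 / cosP
    else:
        tau_m = num / (2.0 * (math.sin(math.radians(36.0)) + math.sin(math.radians(72.0)))) \
            / math.sin(math.radians(P))
    if tau_m < 0:  # keep amplitude non-negative by shifting the phase half a turn
        tau_m = -tau_m
        P = wrap_unsigned(P + 180.0)
    label = _pucker_label(P)
    return SugarPucker(P, tau_m, label, ambiguous)


def _pucker_label(P: float) -> str:
    bins = [
        (0.0, 36.0, "C3'-endo"), (36.0, 72.0, "C4'-exo"),
        (72.0, 108.0, "O4'-endo"), (108.0, 144.0, "C1'-exo"),
        (144.0, 180.0, "C2'-endo"), (180.0, 216.0, "C3'-exo"),
        (216.0, 252.0, "C4'-endo"), (252.0, 288.0, "O4'-exo"),
        (288.0, 324.0, "C1'-endo"), (324.0, 360.0, "C2'-exo"),
    ]
    for lo, hi, lab in bins:
        if lo <= P < hi:
            return lab
    return "?"


def pseudorotation_torsions(P: float, tau_m: float) -> list[float]:
    """Inverse model: the nu0..nu4 implied by (P, tau_m)."""
    return [tau_m * math.cos(math.radians(P + 144.0 * (j - 2))) for j in range(5)]


def bii_frequency(s: Structure, chain: str, step: int) -> float | None:
    """Fraction of models whose step call is BII; None if unclassifiable."""
    calls = [classify_step(backbone_torsions(s, m, chain, step))
             for m in range(s.n_models)]
    ok = [c for c in calls if c.classifiable]
    if not ok:
        return None
    return sum(c.state == "BII" for c in ok) / len(ok)


def bii_profile(s: Structure, chain: str) -> dict[int, float | None]:
    """Per-step BII frequency over the whole chain (steps 1..n-1)."""
    residues = s.chain(chain)
    return {r.index: bii_frequency(s, chain, r.index) for r in residues[:-1]}


def step_table(s: Structure, chains: list[str] | None = None) -> str:
    """Per-step TSV: model, chain, step, epsilon, zeta, eps_minus_zeta, state."""
    buf = io.StringIO()
    buf.write("model\tchain\tstep\tepsilon\tzeta\teps_minus_zeta\tstate\n")
    for m in range(s.n_models):
        for cid in chains or s.chain_ids:
            for r in s.chain(cid, m)[:-1]:
                if not r.is_nucleotide:
                    continue
                call = classify_step(backbone_torsions(s, m, cid, r.index, strict=False))
                if call.classifiable:
                    buf.write(f"{m + 1}\t{cid}\t{r.index}\t{call.epsilon:.2f}\t"
                              f"{call.zeta:.2f}\t{call.eps_minus_zeta:.2f}\t{call.state}\n")
                else:
                    buf.write(f"{m + 1}\t{cid}\t{r.index}\tNA\tNA\tNA\tNA\n")
    return buf.getvalue()
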