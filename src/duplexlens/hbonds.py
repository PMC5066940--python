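"""Geometric hydrogen-bond detection and per-ensemble occupancy.

Detection uses the common molecular-dynamics criteria: heavy-atom
donor-acceptor distance at most 3.5 Å and, where the donor hydrogen is
present, a D-H...A angle of at least 120 degrees.  Both cutoffs are
arguments, not constants.  Donor/acceptor typing for the nucleobases is
embedded below; 8-oxoguanine adds the N7-H donor and the O8 acceptor while
keeping the Watson-Crick edge of guanine.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np

from duplexlens.geometry import bond_angle
from duplexlens.structures import Residue, Structure

__all__ = [
    "HBond",
    "OccupancyRecord",
    "DONORS",
    "ACCEPTORS",
    "WC_BONDS",
    "detect_hbonds",
    "hbond_occupancy",
    "occupancy_table",
]

#: donor heavy atom -> names of its hydrogens, per residue code
DONORS: dict[str, dict[str, tuple[str, ...]]] = {
    "DA": {"N6": ("H61", "H62")},
    "DC": {"N4": ("H41", "H42")},
    "DG": {"N1": ("H1",), "N2": ("H21", "H22")},
    "DT": {"N3": ("H3",)},
    "8OG": {"N1": ("H1",), "N2": ("H21", "H22"), "N7": ("H7",)},
}

#: acceptor heavy atoms per residue code
ACCEPTORS: dict[str, tuple[str, ...]] = {
    "DA": ("N1", "N3", "N7"),
    "DC": ("O2", "N3"),
    "DG": ("O6", "N3", "N7"),
    "DT": ("O2", "O4"),
    "8OG": ("O6", "N3", "O8"),
}

#: canonical Watson-Crick bonds as (purine atom, pyrimidine atom)
WC_BONDS: dict[frozenset, list[tuple[str, str]]] = {
    frozenset({"DG", "DC"}): [("O6", "N4"), ("N1", "N3"), ("N2", "O2")],
    frozenset({"8OG", "DC"}): [("O6", "N4"), ("N1", "N3"), ("N2", "O2")],
    frozenset({"DA", "DT"}): [("N6", "O4"), ("N1", "N3")],
}

AtomKey = tuple[str, int, str]  # (chain, residue index, atom name)


@dataclass
class HBond:
    """One detected hydrogen bond (heavy-atom geometry, H optional)."""

    donor: AtomKey
    acceptor: AtomKey
    hydrogen: AtomKey | None
    distance: float
    angle: float | None  # D-H...A, degrees; None when no hydrogen present

    @property
    def key(self) -> tuple[AtomKey, AtomKey]:
        return (self.donor, self.acceptor)


@dataclass
class OccupancyRecord:
    """Presence fraction and mean length of one bond across models."""

    donor: AtomKey
    acceptor: AtomKey
    fraction: float
    mean_length: float


def _residue_pairs(model):
    items = [(cid, r) for cid, residues in model.items() for r in residues
             if r.code in DONORS or r.code in ACCEPTORS]
    for a in range(len(items)):
        for b in range(len(items)):
            if a != b:
                yield items[a], items[b]


def detect_hbonds(s: Structure, model: int = 0, max_da: float = 3.5,
                  min_angle: float = 120.0) -> list[HBond]:
    """All base-base hydrogen bonds of one model satisfying the criteria.

    Iterates donor atoms against acceptor atoms of every other residue.
    When the donor's hydrogens are absent from the model, the angle
    criterion is skipped and the bond's ``angle`` is None.  Results are
    sorted by donor residue, then distance.
    """
    found: list[HBond] = []
    for (cid_d, rd), (cid_a, ra) in _residue_pairs(s.models[model]):
        for d_name, h_names in DONORS.get(rd.code, {}).items():
            if not rd.has_atom(d_name):
                continue
            d_xyz = rd.xyz(d_name)
            for a_name in ACCEPTORS.get(ra.code, ()):
                if not ra.has_atom(a_name):
                    continue
                a_xyz = ra.xyz(a_name)
                dist = float(np.linalg.norm(d_xyz - a_xyz))
                if dist > max_da:
                    continue
                hs = [h for h in h_names if rd.has_atom(h)]
                if hs:
                    best = None
                    for h in hs:
                        ang = bond_angle(d_xyz, rd.xyz(h), a_xyz)
                        if best is None or ang > best[1]:
                            best = (h, ang)
                    h_name, ang = best
                    if ang < min_angle:
                        continue
                    found.append(HBond((cid_d, rd.index, d_name),
                                       (cid_a, ra.index, a_name),
                                       (cid_d, rd.index, h_name), dist, ang))
                else:
                    found.append(HBond((cid_d, rd.index, d_name),
                                       (cid_a, ra.index, a_name),
                                       None, dist, None))
    found.sort(key=lambda b: (b.donor[0], b.donor[1], b.distance))
    return found


def hbond_occupancy(s: Structure, site: dict[str, range] | None = None,
                    max_da: float = 3.5, min_angle: float = 120.0) -> list[OccupancyRecord]:
    """Per-bond presence fraction over all models.

    ``site`` restricts the report to bonds with at least one partner inside
    the given per-chain residue ranges (e.g. the GAATTC hexamer); None means
    the whole structure.  A bond is counted present in a model when it
    satisfies the detection criteria there.
    """
    counts: dict[tuple[AtomKey, AtomKey], list[float]] = {}
    for m in range(s.n_models):
        for b in detect_hbonds(s, m, max_da=max_da, min_angle=min_angle):
            counts.setdefault(b.key, []).append(b.distance)
    out = []
    for (donor, acceptor), dists in sorted(counts.items()):
        if site is not None:
            keep = any(
                key[0] in site and key[1] in site[key[0]]
                for key in (donor, acceptor)
            )
            if not keep:
                continue
        out.append(OccupancyRecord(donor, acceptor,
                                   fraction=len(dists) / s.n_models,
                                   mean_length=float(np.mean(dists))))
    return out


def occupancy_table(records: list[OccupancyRecord]) -> str:
    """TSV rendering: donor, acceptor, fraction, mean_length_A."""
    buf = io.StringIO()
    buf.write("donor\tacceptor\tfraction\tmean_length_A\n")
    for r in records:
        d = ":".join(map(str, r.donor))
        a = ":".join(map(str, r.acceptor))
        buf.write(f"{d}\t{a}\t{r.fraction:.3f}\t{r.mean_length:.3f}\n")
    return buf.getvalue()
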