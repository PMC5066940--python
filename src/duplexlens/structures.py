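"""Coordinate containers for multi-model DNA duplexes and duplex pairing maps.

The hierarchy is Structure -> models -> chains -> residues -> atoms.  All
models of a Structure share one atom topology (same chains, residues and
atom names in the same order); only coordinates differ between models, as
in a deposited NMR ensemble.

Nomenclature is normalized internally: sugar atoms carry ASCII primes
(``O3'``), never stars; residues use the chemical-component codes DA, DC,
DG, DT and 8OG (8-oxoguanine, recognizable by its O8 atom).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from duplexlens.errors import NomenclatureError, PairingError, TopologyError

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "DuplexMap",
    "normalize_nomenclature",
    "pair_duplex",
    "parse_sequence",
    "complement_sequence",
    "one_letter",
]

#: chemical-component codes of the nucleotides this package analyses
NUCLEOTIDE_CODES = {"DA", "DC", "DG", "DT", "8OG"}

#: residue-name aliases seen in PDB dialects, mapped to internal codes
RESIDUE_ALIASES = {
    "A": "DA", "ADE": "DA", "DA": "DA",
    "C": "DC", "CYT": "DC", "DC": "DC",
    "G": "DG", "GUA": "DG", "DG": "DG",
    "T": "DT", "THY": "DT", "DT": "DT",
    "8OG": "8OG", "OG8": "8OG", "GOX": "8OG",
}

#: residues accepted but not analysed (pass-through)
IGNORABLE_RESIDUES = {
    "HOH", "WAT", "DOD",
    # the 20 standard amino acids: protein chains are parsed but not analysed
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

_ONE_LETTER = {"DA": "A", "DC": "C", "DG": "G", "DT": "T", "8OG": "X"}
_FROM_ONE_LETTER = {v: k for k, v in _ONE_LETTER.items()}

#: Watson-Crick complement rule on one-letter codes (X = 8-oxoguanine)
COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G", "X": "C"}


def normalize_atom_name(name: str) -> str:
    """Map an atom label to the internal convention (stars/primes -> ASCII ')."""
    name = name.strip().replace("*", "'").replace("′", "'")
    # historic phosphate oxygen names
    return {"O1P": "OP1", "O2P": "OP2", "C5M": "C7"}.get(name, name)


@dataclass
class Atom:
    """A single atom: PDB-convention name, element symbol, coordinates in Å."""

    name: str
    element: str
    xyz: np.ndarray

    def __post_init__(self):
        self.xyz = np.asarray(self.xyz, dtype=float)
        if not self.name:
            raise ValueError("atom name must be non-empty")
        if self.xyz.shape != (3,) or not np.all(np.isfinite(self.xyz)):
            raise ValueError(f"atom {self.name}: coordinates must be a finite 3-vector")


@dataclass
class Residue:
    """One nucleotide (or pass-through residue) with uniquely named atoms."""

    index: int
    code: str
    atoms: list[Atom] = field(default_factory=list)

    def __post_init__(self):
        if self.index < 1:
            raise ValueError("residue index is 1-based (>= 1)")
        names = [a.name for a in self.atoms]
        if len(names) != len(set(names)):
            raise ValueError(f"duplicate atom names in residue {self.code}{self.index}")

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"{self.code}{self.index} has no atom {name!r}")

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)

    def xyz(self, name: str) -> np.ndarray:
        return self.atom(name).xyz

    @property
    def is_nucleotide(self) -> bool:
        return self.code in NUCLEOTIDE_CODES


# one model = ordered mapping chain id -> list of residues
Model = dict[str, list[Residue]]


class Structure:
    """A multi-model coordinate set with identical topology across models."""

    def __init__(self, models: list[Model], meta: str = ""):
        if not models:
            raise ValueError("a Structure needs at least one model")
        self.models = models
        self.meta = meta
        self._check_topology()

    def _check_topology(self):
        ref = self._topology(self.models[0])
        for k, m in enumerate(self.models[1:], start=2):
            if self._topology(m) != ref:
                raise TopologyError(f"model {k} differs in atom topology from model 1")

    @staticmethod
    def _topology(model: Model):
        return [
            (cid, r.index, r.code, tuple(a.name for a in r.atoms))
            for cid, residues in model.items()
            for r in residues
        ]

    @property
    def n_models(self) -> int:
        return len(self.models)

    @property
    def chain_ids(self) -> list[str]:
        return list(self.models[0].keys())

    def chain(self, chain_id: str, model: int = 0) -> list[Residue]:
        return self.models[model][chain_id]

    def residue(self, chain_id: str, index: int, model: int = 0) -> Residue:
        for r in self.models[model][chain_id]:
            if r.index == index:
                return r
        raise KeyError(f"chain {chain_id} has no residue {index}")

    def sequence(self, chain_id: str) -> str:
        return "".join(
            _ONE_LETTER.get(r.code, "?") for r in self.chain(chain_id)
        )

    def iter_atoms(self, model: int = 0) -> Iterator[tuple[str, Residue, Atom]]:
        for cid, residues in self.models[model].items():
            for r in residues:
                for a in r.atoms:
                    yield cid, r, a

    def coords(self, model: int = 0) -> np.ndarray:
        """All atom coordinates of one model, topology order, shape (n, 3)."""
        return np.array([a.xyz for _, _, a in self.iter_atoms(model)])

    def atom_keys(self) -> list[tuple[str, int, str]]:
        """(chain, residue index, atom name) keys in topology order."""
        return [(cid, r.index, a.name) for cid, r, a in self.iter_atoms(0)]

    def with_coords(self, coords_per_model: list[np.ndarray], meta: str | None = None) -> "Structure":
        """New Structure with this topology and replaced coordinates."""
        models: list[Model] = []
        for X in coords_per_model:
            X = np.asarray(X, float)
            k = 0
            m: Model = {}
            for cid, residues in self.models[0].items():
                m[cid] = []
                for r in residues:
                    atoms = []
                    for a in r.atoms:
                        atoms.append(Atom(a.name, a.element, X[k]))
                        k += 1
                    m[cid].append(Residue(r.index, r.code, atoms))
            if k != X.shape[0]:
                raise ValueError("coordinate array does not match topology size")
            models.append(m)
        return Structure(models, meta=self.meta if meta is None else meta)


def normalize_nomenclature(s: Structure, ignore_unknown: bool = False) -> Structure:
    """Return a copy of ``s`` with atom and residue names in internal convention.

    Residue aliases (G/GUA -> DG, ...) are resolved; a DG carrying an O8 atom
    is promoted to 8OG.  Water and amino-acid residues pass through untouched.
    Anything else raises :class:`NomenclatureError` unless ``ignore_unknown``.
    """
    models: list[Model] = []
    for m in s.models:
        new_m: Model = {}
        for cid, residues in m.items():
            out = []
            for r in residues:
                atoms = [Atom(normalize_atom_name(a.name), a.element, a.xyz.copy())
                         for a in r.atoms]
                code = r.code.strip()
                if code in RESIDUE_ALIASES:
                    code = RESIDUE_ALIASES[code]
                    if code == "DG" and any(a.name == "O8" for a in atoms):
                        code = "8OG"
                elif code in IGNORABLE_RESIDUES or ignore_unknown:
                    pass  # flagged pass-through
                else:
                    raise NomenclatureError(
                        f"residue {code!r} at {cid}:{r.index} is not a recognized "
                        "nucleotide and not an ignorable residue"
                    )
                out.append(Residue(r.index, code, atoms))
            new_m[cid] = out
        models.append(new_m)
    return Structure(models, meta=s.meta)


def parse_sequence(seq: str) -> list[str]:
    """One-letter sequence (X = 8-oxoguanine) to residue codes."""
    codes = []
    for i, ch in enumerate(seq.upper(), start=1):
        if ch not in _FROM_ONE_LETTER:
            raise ValueError(f"invalid sequence symbol {ch!r} at position {i}")
        codes.append(_FROM_ONE_LETTER[ch])
    return codes


def one_letter(code: str) -> str:
    return _ONE_LETTER[code]


def complement_sequence(seq: str) -> str:
    """Reverse complement under A:T, G:C, 8OG(X):C.

    Note the X:C rule is one-directional: the complement of X is C, while the
    complement of C is G, so a lesion strand's complement is lesion-free.
    """
    return "".join(COMPLEMENT[ch] for ch in reversed(seq.upper()))


def _pairs_ok(a: str, b: str) -> bool:
    """Watson-Crick (or 8OG:C wobble-free) complementarity of two symbols."""
    return COMPLEMENT[a] == b or COMPLEMENT[b] == a


@dataclass
class DuplexMap:
    """Antiparallel base-pairing map between two chains of a duplex.

    ``pairs[k] = (i, j)`` pairs residue i of ``chain_a`` with residue j of
    ``chain_b``; ``terminal[k]`` marks the outermost pairs, which are excluded
    from Watson-Crick restraint emission.
    """

    chain_a: str
    chain_b: str
    seq_a: str
    seq_b: str
    pairs: list[tuple[int, int]]
    terminal: list[bool]

    def partner(self, chain: str, index: int) -> tuple[str, int]:
        """The paired (chain, residue) of a residue; KeyError if unpaired."""
        if chain == self.chain_a:
            for i, j in self.pairs:
                if i == index:
                    return self.chain_b, j
        elif chain == self.chain_b:
            for i, j in self.pairs:
                if j == index:
                    return self.chain_a, i
        raise KeyError(f"{chain}:{index} is not part of the duplex map")

    def is_terminal(self, chain: str, index: int) -> bool:
        for (i, j), t in zip(self.pairs, self.terminal):
            if (chain == self.chain_a and i == index) or (
                chain == self.chain_b and j == index
            ):
                return t
        raise KeyError(f"{chain}:{index} is not part of the duplex map")

    @property
    def self_complementary(self) -> bool:
        # the 8-oxoguanine lesion (X) is guanine-like for strand symmetry:
        # an X-bearing strand of a palindrome still maps onto its partner
        return self.seq_a.replace("X", "G") == self.seq_b.replace("X", "G")

    def symmetry_image(self, chain: str, index: int) -> tuple[str, int]:
        """Image of a residue under the palindromic dyad of a self-complementary duplex.

        The dyad swaps the two strands while preserving the 5'->3' position,
        so residue i of one strand maps to residue i of the other.
        """
        if not self.self_complementary:
            raise PairingError("palindromic symmetry requires a self-complementary duplex")
        if chain == self.chain_a:
            return self.chain_b, index
        if chain == self.chain_b:
            return self.chain_a, index
        raise KeyError(f"unknown chain {chain!r}")


def pair_duplex(s: Structure, seq_a: str, seq_b: str,
                chain_a: str | None = None, chain_b: str | None = None) -> DuplexMap:
    """Build the antiparallel pairing map of a duplex.

    Residue i of chain A pairs with residue N+1-i of chain B; the sequences
    must be reverse-complementary under {A:T, G:C, X:C}.  The first and last
    pairs are flagged terminal.
    """
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    if len(seq_a) != len(seq_b):
        raise PairingError("strand lengths differ")
    n = len(seq_a)
    bad = [i + 1 for i in range(n) if not _pairs_ok(seq_a[i], seq_b[n - 1 - i])]
    if bad:
        raise PairingError(f"non-complementary base pairs at positions {bad}")
    cids = s.chain_ids
    chain_a = chain_a or cids[0]
    chain_b = chain_b or (cids[1] if len(cids) > 1 else cids[0])
    for cid, seq in ((chain_a, seq_a), (chain_b, seq_b)):
        have = s.sequence(cid)
        if have != seq:
            raise PairingError(f"chain {cid} sequence {have} does not match {seq}")
    pairs = [(i, n + 1 - i) for i in range(1, n + 1)]
    terminal = [i == 1 or i == n for i in range(1, n + 1)]
    return DuplexMap(chain_a, chain_b, seq_a, seq_b, pairs, terminal)
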