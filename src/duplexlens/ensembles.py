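"""Rigid-body superposition and RMSD statistics for multi-model ensembles.

``superpose`` solves the orthogonal Procrustes problem (Kabsch, via SVD)
for a chosen atom selection; ``pairwise_rmsd`` applies it to every model
pair of an ensemble; ``representative`` condenses an ensemble to a single
coordinate set by iterative mean coordinates or by the medoid model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from duplexlens.errors import CorrespondenceError
from duplexlens.geometry import kabsch
from duplexlens.structures import Structure

__all__ = [
    "Superposition",
    "BACKBONE_ATOMS",
    "select_indices",
    "superpose",
    "pairwise_rmsd",
    "representative",
    "rmsd_report",
]

#: sugar-phosphate backbone atoms used by the "backbone" selection
BACKBONE_ATOMS = ("P", "OP1", "OP2", "O5'", "C5'", "C4'", "C3'", "O3'")


@dataclass
class Superposition:
    """Optimal rigid fit of one coordinate set onto another."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    selection: str

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, float) @ self.rotation.T + self.translation


def select_indices(s: Structure, selection: str,
                   custom: list[int] | None = None) -> np.ndarray:
    """Atom indices (topology order) for a named selection.

    "all-atom" keeps everything, "all-heavy" drops hydrogens, "backbone"
    keeps the sugar-phosphate backbone heavy atoms, "custom" uses the given
    index list.
    """
    if selection == "custom":
        if custom is None:
            raise ValueError("custom selection requires an index list")
        return np.asarray(custom, dtype=int)
    idx = []
    for k, (cid, r, a) in enumerate(s.iter_atoms(0)):
        if selection == "all-atom":
            idx.append(k)
        elif selection == "all-heavy":
            if a.element != "H":
                idx.append(k)
        elif selection == "backbone":
            if a.name in BACKBONE_ATOMS:
                idx.append(k)
        else:
            raise ValueError(f"unknown selection {selection!r}")
    return np.asarray(idx, dtype=int)


def superpose(A: np.ndarray, B: np.ndarray, selection: str = "custom") -> Superposition:
    """Least-squares fit of coordinate set A onto B (same atom order).

    Raises :class:`CorrespondenceError` when the two sets do not match
    one-to-one or hold fewer than three atoms.
    """
    A = np.asarray(A, float)
    B = np.asarray(B, float)
    if A.shape != B.shape:
        raise CorrespondenceError(
            f"selections do not match: {A.shape[0]} vs {B.shape[0]} atoms")
    if A.shape[0] < 3:
        raise CorrespondenceError("need at least three atoms to superpose")
    R, t, rmsd = kabsch(A, B)
    return Superposition(R, t, rmsd, selection)


def superpose_structures(a: Structure, b: Structure, selection: str = "all-heavy",
                         model_a: int = 0, model_b: int = 0) -> Superposition:
    """Superpose one model of structure ``a`` onto one model of ``b``.

    Both structures must expose identical atom keys under the selection;
    mismatches are reported atom by atom.
    """
    ia = select_indices(a, selection)
    ib = select_indices(b, selection)
    keys_a = [a.atom_keys()[k] for k in ia]
    keys_b = [b.atom_keys()[k] for k in ib]
    if keys_a != keys_b:
        extra_a = sorted(set(keys_a) - set(keys_b))[:5]
        extra_b = sorted(set(keys_b) - set(keys_a))[:5]
        raise CorrespondenceError(
            f"atom selections differ between structures "
            f"(only in first: {extra_a}; only in second: {extra_b})")
    sp = superpose(a.coords(model_a)[ia], b.coords(model_b)[ib])
    sp.selection = selection
    return sp


def pairwise_rmsd(s: Structure, selection: str = "all-atom") -> np.ndarray:
    """Symmetric matrix of superposition RMSDs between all model pairs."""
    if s.n_models < 2:
        raise ValueError("pairwise RMSD needs at least two models")
    idx = select_indices(s, selection)
    X = [s.coords(m)[idx] for m in range(s.n_models)]
    n = s.n_models
    M = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            M[i, j] = M[j, i] = superpose(X[i], X[j]).rmsd
    return M


def representative(s: Structure, mode: str = "mean-coordinates") -> Structure:
    """Single-model summary of an ensemble.

    "mean-coordinates": all models are superposed onto the first (all-atom),
    then averaged (no force-field minimization is applied to the average).
    "medoid": the member minimizing its summed RMSD to all other members.
    """
    if s.n_models == 1:
        return Structure([s.models[0]], meta=s.meta)
    if mode == "mean-coordinates":
        ref = s.coords(0)
        stack = [ref]
        for m in range(1, s.n_models):
            sp = superpose(s.coords(m), ref)
            stack.append(sp.apply(s.coords(m)))
        mean = np.mean(stack, axis=0)
        return s.with_coords([mean], meta=f"{s.meta} [mean of {s.n_models} models]")
    if mode == "medoid":
        M = pairwise_rmsd(s, "all-atom")
        k = int(np.argmin(M.sum(axis=1)))
        return s.with_coords([s.coords(k)],
                             meta=f"{s.meta} [medoid model {k + 1}]")
    raise ValueError(f"unknown representative mode {mode!r}")


def rmsd_report(s: Structure, selection: str = "all-atom") -> str:
    """JSON report: selection, per-pair matrix, max and mean off-diagonal."""
    M = pairwise_rmsd(s, selection)
    off = M[np.triu_indices_from(M, k=1)]
    return json.dumps({
        "selection": selection,
        "n_models": s.n_models,
        "matrix": np.round(M, 4).tolist(),
        "max": float(off.max()),
        "mean": float(off.mean()),
    }, indent=2)
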