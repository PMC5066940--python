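"""Base and base-pair reference frames; inter-pair step twist and rise.

Frames follow the standard-reference-frame convention: x points toward the
major groove, y toward the strand-A sugar, z along the base normal, origin
near the pair centre.  A frame is obtained by least-squares superposition of
the embedded standard base geometry onto the observed six-membered-ring
atoms.  Twist is measured between successive base-pair frames about their
mean z-axis (mid-step-triad convention, as in 3DNA); no global helix axis is
fitted.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np

from duplexlens.errors import FrameError
from duplexlens.geometry import kabsch, orthonormalize
from duplexlens.stdgeom import RING_ATOMS, base_table
from duplexlens.structures import DuplexMap, Residue, Structure

__all__ = [
    "Frame",
    "StepParams",
    "base_frame",
    "pair_frame",
    "step_twist",
    "twist_profile",
    "twist_table",
    "FLIP_X",
]

#: 180-degree rotation about x: maps a base frame onto its Watson-Crick
#: partner's frame in an ideal pair
FLIP_X = np.diag([1.0, -1.0, -1.0])


@dataclass
class Frame:
    """A right-handed orthonormal reference frame (columns of axes = x, y, z)."""

    origin: np.ndarray
    axes: np.ndarray
    fit_rmsd: float = 0.0

    def __post_init__(self):
        self.origin = np.asarray(self.origin, float)
        self.axes = np.asarray(self.axes, float)
        if not np.allclose(self.axes @ self.axes.T, np.eye(3), atol=1e-8):
            raise ValueError("frame axes must be orthonormal")
        if np.linalg.det(self.axes) < 0:
            raise ValueError("frame must be right-handed")

    @property
    def x(self):
        return self.axes[:, 0]

    @property
    def y(self):
        return self.axes[:, 1]

    @property
    def z(self):
        return self.axes[:, 2]


@dataclass
class StepParams:
    """Twist (degrees) and rise (Å) of one base-pair step."""

    step: int
    twist: float
    rise: float


def base_frame(r: Residue) -> Frame:
    """Standard reference frame of one base.

    The embedded standard geometry of the base type is superposed onto the
    observed six ring atoms (N1, C2, N3, C4, C5, C6 — shared by purines and
    pyrimidines; the 8-oxoguanine O8 plays no role in the fit).  The fitted
    rotation and translation define the frame; the fit RMSD is reported.
    """
    table = base_table(r.code, hydrogens=False)
    missing = [a for a in RING_ATOMS if not r.has_atom(a)]
    if missing:
        raise FrameError(f"residue {r.code}{r.index}: missing ring atom(s) {missing}")
    src = np.array([table[a] for a in RING_ATOMS])
    dst = np.array([r.xyz(a) for a in RING_ATOMS])
    R, t, rmsd = kabsch(src, dst)
    return Frame(origin=t, axes=R, fit_rmsd=rmsd)


def pair_frame(fA: Frame, fB: Frame, flip_b: bool = True) -> Frame:
    """Mid-frame of a Watson-Crick pair.

    The strand-B frame is first flipped 180 degrees about its x-axis (the
    antiparallel partner's z points the other way); the pair frame is the
    geodesic mean of the two rotations (polar decomposition of their sum)
    with the mean origin.
    """
    axes_b = fB.axes @ FLIP_X if flip_b else fB.axes
    mean_axes = orthonormalize(fA.axes + axes_b)
    origin = 0.5 * (fA.origin + fB.origin)
    return Frame(origin=origin, axes=mean_axes)


def step_twist(pf1: Frame, pf2: Frame, step: int = 0) -> StepParams:
    """Twist and rise between two successive base-pair frames.

    Twist is the rotation from the first pair's y-axis to the second's,
    projected onto the plane perpendicular to the mid-step z-axis and signed
    about it; rise is the origin displacement projected onto that axis.
    """
    mid = orthonormalize(pf1.axes + pf2.axes)
    zm = mid[:, 2]

    def proj(v):
        p = v - np.dot(v, zm) * zm
        n = np.linalg.norm(p)
        if n < 1e-9:
            raise FrameError("pair y-axis parallel to the step axis; twist undefined")
        return p / n

    y1, y2 = proj(pf1.y), proj(pf2.y)
    twist = float(np.degrees(np.arctan2(np.dot(zm, np.cross(y1, y2)), np.dot(y1, y2))))
    rise = float(np.dot(pf2.origin - pf1.origin, zm))
    return StepParams(step=step, twist=twist, rise=rise)


def _pair_frames(s: Structure, dmap: DuplexMap, model: int) -> list[Frame]:
    frames = []
    for i, j in dmap.pairs:
        fA = base_frame(s.residue(dmap.chain_a, i, model))
        fB = base_frame(s.residue(dmap.chain_b, j, model))
        frames.append(pair_frame(fA, fB))
    return frames


def twist_profile(s: Structure, dmap: DuplexMap, model: int = 0) -> list[StepParams]:
    """Per-step twist/rise along a duplex; step k is pair k against pair k+1."""
    frames = _pair_frames(s, dmap, model)
    return [step_twist(frames[k], frames[k + 1], step=k + 1)
            for k in range(len(frames) - 1)]


def twist_table(s: Structure, dmap: DuplexMap) -> str:
    """Per-step TSV over all models: model, step, twist_deg, rise_A."""
    buf = io.StringIO()
    buf.write("model\tstep\ttwist_deg\trise_A\n")
    for m in range(s.n_models):
        for sp in twist_profile(s, dmap, m):
            buf.write(f"{m + 1}\t{sp.step}\t{sp.twist:.2f}\t{sp.rise:.3f}\n")
    return buf.getvalue()
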