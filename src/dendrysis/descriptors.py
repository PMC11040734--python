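"""Per-frame structural descriptors of dendrimer conformations.

Covers the gyration-tensor observables (radius of gyration, principal
moments, sphericity, oblate/prolate shape), the permutation-corrected RMSD
of pseudo-symmetric branched molecules, central-structure selection, and the
membrane-orientation descriptor.

Shape conventions
-----------------
The gyration tensor is mass-unweighted,

    S_ab = (1/N) sum_i (r_i,a - <r_a>) (r_i,b - <r_b>),

with principal components sorted so that ``Rgx >= Rgy >= Rgz`` (longest,
intermediate, shortest) and ``Rg**2 = Rgx**2 + Rgy**2 + Rgz**2``.

*Asphericity* maps a perfect sphere (Rgz**2 = Rg**2/3) to 0 and a collinear
arrangement (Rgz = 0) to 1:

    A = 1 - 3*Rgz**2 / Rg**2,        sphericity% = 100*(1 - A).

The *shape* descriptor compares the intermediate moment to the mean of the
extremes, alpha = (Rgx + Rgz)/2: positive when Rgy is closer to the longest
moment (oblate, Frisbee-like), negative when closer to the shortest
(prolate, rugby-ball-like):

    shape = (Rgy - alpha) / alpha.

Permutation-corrected RMSD
--------------------------
The arms hanging off each branching lysine are chemically identical, so a
plain RMSD between two conformations is inflated whenever equivalent arms
have swapped places.  ``symmetric_rmsd`` relabels one frame by every
branch-swap permutation (128 for a full third-generation dendrimer),
re-superposes for each relabeling, and keeps the minimum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .ensemble import Frame
from .topology import DendrimerTopology, enumerate_branch_permutations

__all__ = [
    "GyrationMoments",
    "ShapeResult",
    "gyration_moments",
    "sphericity",
    "shape_parameter",
    "kabsch_rmsd",
    "symmetric_rmsd",
    "central_structure",
    "orientation",
]


@dataclass(frozen=True)
class GyrationMoments:
    """Principal gyration components in Angstrom, sorted descending."""

    rg: float
    rgx: float  # longest
    rgy: float  # intermediate
    rgz: float  # shortest


@dataclass(frozen=True)
class ShapeResult:
    sphericity_pct: float
    shape: float


def _coords(frame_or_array) -> np.ndarray:
    if isinstance(frame_or_array, Frame):
        return frame_or_array.coordinates
    return np.asarray(frame_or_array, dtype=float)


def gyration_moments(frame, selection=None) -> GyrationMoments:
    """Principal components of the (mass-unweighted) gyration tensor.

    Parameters
    ----------
    frame:
        A :class:`~dendrysis.ensemble.Frame` or an ``(n, 3)`` array.
    selection:
        Optional iterable of bead/residue indices restricting the
        calculation to a subset (at least 3 beads).
    """
    x = _coords(frame)
    if selection is not None:
        x = x[np.asarray(list(selection), dtype=int)]
    if len(x) < 3:
        raise ValueError(f"gyration moments need >=3 beads, got {len(x)}")
    centered = x - x.mean(axis=0)
    tensor = centered.T @ centered / len(x)
    eigvals = np.linalg.eigvalsh(tensor)[::-1]  # descending
    eigvals = np.clip(eigvals, 0.0, None)
    rgx, rgy, rgz = np.sqrt(eigvals)
    return GyrationMoments(rg=float(np.sqrt(eigvals.sum())),
                           rgx=float(rgx), rgy=float(rgy), rgz=float(rgz))


def sphericity(moments: GyrationMoments) -> float:
    """Sphericity percentage: 100 for a perfect sphere, 0 for a line.

    Computed as ``100*(1 - A)`` with asphericity ``A = 1 - 3*Rgz^2/Rg^2``.
    """
    if moments.rg <= 0.0:
        raise ValueError("sphericity undefined for Rg = 0")
    asph = 1.0 - 3.0 * moments.rgz**2 / moments.rg**2
    return 100.0 * (1.0 - asph)


def shape_parameter(moments: GyrationMoments) -> float:
    """Signed oblate/prolate descriptor.

    Positive when the intermediate moment sits closer to the longest one
    (oblate, disk-like), negative when closer to the shortest (prolate,
    rod-like); 0 when exactly halfway.  Fully degenerate moments
    (Rgx = Rgz) return 0 with a warning.
    """
    alpha = 0.5 * (moments.rgx + moments.rgz)
    if moments.rgx <= moments.rgz or alpha == 0.0:
        warnings.warn("degenerate gyration moments (Rgx = Rgz): shape set to 0",
                      stacklevel=2)
        return 0.0
    return (moments.rgy - alpha) / alpha


def shape_result(frame, selection=None) -> ShapeResult:
    m = gyration_moments(frame, selection)
    return ShapeResult(sphericity_pct=sphericity(m), shape=shape_parameter(m))


# ---------------------------------------------------------------------------
# RMSD
# ---------------------------------------------------------------------------

def _batched_kabsch_rmsd(mobile: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Minimum RMSD after optimal rigid-body superposition.

    ``mobile`` has shape (P, n, 3) — a batch of P candidate relabelings —
    and ``reference`` (n, 3).  Uses the closed-form Kabsch result
    ``n*rmsd^2 = tr(X'X) + tr(Y'Y) - 2*(s1 + s2 +/- s3)`` with the sign of
    the smallest singular value fixed by the determinant (proper rotations
    only).
    """
    n = reference.shape[0]
    ref = reference - reference.mean(axis=0)
    mob = mobile - mobile.mean(axis=1, keepdims=True)
    # covariance per batch element: (P, 3, 3)
    cov = np.einsum("pni,nj->pij", mob, ref)
    u, s, vt = np.linalg.svd(cov)
    sign = np.sign(np.linalg.det(np.einsum("pij,pjk->pik", u, vt)))
    weighted = s[:, 0] + s[:, 1] + sign * s[:, 2]
    sq = (np.einsum("pni,pni->p", mob, mob) + np.einsum("ni,ni->", ref, ref)
          - 2.0 * weighted) / n
    return np.sqrt(np.clip(sq, 0.0, None))


def kabsch_rmsd(mobile, reference) -> float:
    """RMSD between two conformations after optimal superposition."""
    a = _coords(mobile)
    b = _coords(reference)
    if a.shape != b.shape:
        raise ValueError("conformations must have identical shapes")
    return float(_batched_kabsch_rmsd(a[None], b)[0])


def symmetric_rmsd(frame, reference, permutations) -> float:
    """Branch-permutation-corrected RMSD (Angstrom).

    For each residue-id relabeling the frame beads are permuted, the frame
    is optimally superposed onto the reference, and the lowest RMSD over all
    relabelings is returned.  Superposition is redone per permutation since
    relabeling changes the optimal fit.
    """
    a = _coords(frame)
    b = _coords(reference)
    if a.shape != b.shape:
        raise ValueError("frame and reference must share a topology")
    perms = np.asarray(permutations, dtype=int)
    if perms.ndim == 1:
        perms = perms[None]
    n = a.shape[0]
    for p in perms:
        if np.bincount(p, minlength=n).max() != 1 or p.shape[0] != n:
            raise ValueError("permutation is not a bijection on beads")
    # relabeled[k, new, :] = a[old, :] with perm[old] = new
    relabeled = np.empty((len(perms), n, 3))
    np.put_along_axis(relabeled, perms[:, :, None], a[None], axis=1)
    return float(_batched_kabsch_rmsd(relabeled, b).min())


def central_structure(structures, permutations=None,
                      topology: DendrimerTopology | None = None,
                      use_symmetry: bool = True) -> int:
    """Index of the most central conformation of a set.

    Computes the full symmetric cross matrix of (permutation-corrected)
    RMSD values and returns the index with the lowest row sum; ties break
    to the lowest index.  With ``use_symmetry=False`` the plain
    identity-permutation RMSD is used instead.
    """
    frames = [_coords(s) for s in structures]
    if len(frames) == 0:
        raise ValueError("central_structure needs at least one structure")
    if permutations is None:
        if use_symmetry:
            if topology is None:
                top = getattr(structures[0], "topology", None)
                if top is None:
                    raise ValueError(
                        "need permutations or a topology to derive them")
                topology = top
            permutations = enumerate_branch_permutations(topology)
        else:
            permutations = [np.arange(frames[0].shape[0])]
    elif not use_symmetry:
        permutations = [np.arange(frames[0].shape[0])]
    m = len(frames)
    cross = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            r = symmetric_rmsd(frames[i], frames[j], permutations)
            cross[i, j] = cross[j, i] = r
    return int(np.argmin(cross.sum(axis=1)))


# ---------------------------------------------------------------------------
# orientation
# ---------------------------------------------------------------------------

def orientation(frame, topology: DendrimerTopology | None = None,
                membrane_center_z: float = 0.0,
                core_selection=None) -> float:
    """Membrane orientation of the dendrimer (Angstrom, signed).

    Returns ``|z_rest - z_c| - |z_core - z_c|`` where ``z_core`` is the
    geometric center of the hydrophobic core (all generation-0 residues,
    including any core tail) and ``z_rest`` the center of the remainder
    (G1+G2+G3), both measured from the membrane center ``z_c``.  Positive
    values mean the hydrophobic core is turned toward the membrane;
    negative, toward the water phase.

    ``core_selection`` overrides the default G0 residue set.
    """
    x = _coords(frame)
    if topology is None:
        topology = getattr(frame, "topology", None)
    if topology is None:
        raise ValueError("orientation requires a topology (generation labels)")
    if core_selection is None:
        core_ids = topology.residues_in_generation(0)
    else:
        core_ids = list(core_selection)
    if not core_ids:
        raise ValueError("no generation-0 residues in topology")
    rest_ids = [r.id for r in topology.residues if r.id not in set(core_ids)]
    if not rest_ids:
        raise ValueError("no residues outside the core selection")
    z_core = x[core_ids, 2].mean() - membrane_center_z
    z_rest = x[rest_ids, 2].mean() - membrane_center_z
    return float(abs(z_rest) - abs(z_core))
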