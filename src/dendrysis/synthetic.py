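"""Seeded synthetic data with known ground truth.

Generators emulating the statistical structure of constant-pH MD output so
that every analysis stage is testable end-to-end:

* bead-level conformational ensembles of a dendrimer tree with prescribed
  mean radius of gyration and principal-moment anisotropy;
* Bernoulli protonation series drawn from Hill curves, optionally with an
  insertion-dependent pKa shift emulating membrane desolvation;
* planar phosphate bilayers whose proximal lipids are displaced by a
  dendrimer-shaped Gaussian dimple of known depth.

Frames are exchangeable (no MD autocorrelation); replicates generated with
different seeds are the intended unit of statistical independence.  All
generators are bit-reproducible given (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ensemble import Ensemble
from .membrane import MembraneFrame
from .titration import ProtonationSeries
from .topology import DendrimerTopology

__all__ = [
    "EnsembleSpec",
    "ProtonationSpec",
    "MembraneSpec",
    "BOND_LENGTH",
    "generate_dendrimer_ensemble",
    "generate_protonation_series",
    "generate_membrane_system",
]

#: Calpha-Calpha virtual bond length, Angstrom
BOND_LENGTH = 3.8


@dataclass
class EnsembleSpec:
    """Target statistics for a synthetic conformational ensemble.

    ``compactness`` in (0, 1] scales the target mean Rg relative to the
    ideal-chain scale ``BOND_LENGTH * sqrt(n_residues)``; ``anisotropy``
    gives the target ratios of the principal gyration moments (longest to
    shortest, non-increasing).
    """

    topology: DendrimerTopology
    n_frames: int
    pH: float = 7.0
    compactness: float = 0.5
    anisotropy: tuple[float, float, float] = (1.3, 1.0, 0.75)
    rg_jitter: float = 0.05  # relative sd of per-frame Rg about the target
    anisotropy_jitter: float = 0.0  # relative sd of per-frame moment ratios
    seed: int = 0

    def __post_init__(self):
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if not 0.0 < self.compactness <= 1.0:
            raise ValueError("compactness must lie in (0, 1]")
        a = np.asarray(self.anisotropy, dtype=float)
        if a.shape != (3,) or np.any(a <= 0):
            raise ValueError("anisotropy must be three positive ratios")
        if np.any(np.diff(a) > 0):
            raise ValueError(
                "anisotropy ratios must be ordered longest >= intermediate "
                f">= shortest, got {tuple(a)}")

    @property
    def target_rg(self) -> float:
        return self.compactness * BOND_LENGTH * np.sqrt(
            self.topology.n_residues)


def _tree_walk_frames(topology: DendrimerTopology, n_frames: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Random tree embedding: each residue placed one bond from its parent
    in a random direction plus Gaussian jitter."""
    n = topology.n_residues
    coords = np.zeros((n_frames, n, 3))
    order = [topology.root.id]
    stack = list(topology.root.children)
    while stack:
        rid = stack.pop()
        order.append(rid)
        stack.extend(topology.residue(rid).children)
    for rid in order[1:]:
        parent = topology.residue(rid).parent
        direction = rng.normal(size=(n_frames, 3))
        direction /= np.linalg.norm(direction, axis=1, keepdims=True)
        jitter = rng.normal(scale=0.3, size=(n_frames, 3))
        coords[:, rid] = coords[:, parent] + BOND_LENGTH * direction + jitter
    return coords


def generate_dendrimer_ensemble(spec: EnsembleSpec) -> Ensemble:
    """Synthetic bead ensemble with prescribed size and anisotropy.

    Each frame is a random tree embedding, rotated into its principal
    gyration frame, rescaled per axis to the target moment ratios, and
    scaled so the frame Rg fluctuates around ``spec.target_rg`` (lognormal-
    like multiplicative jitter, mean-preserving); the ensemble-mean Rg and
    moment ratios therefore converge to the targets as 1/sqrt(n_frames).
    """
    rng = np.random.default_rng(spec.seed)
    coords = _tree_walk_frames(spec.topology, spec.n_frames, rng)
    coords -= coords.mean(axis=1, keepdims=True)

    target = np.asarray(spec.anisotropy, dtype=float)
    # moment targets normalized so sum of squares = 1; axis k scale applied
    # in each frame's principal basis
    t2 = target**2 / (target**2).sum()
    rg_targets = spec.target_rg * (
        1.0 + spec.rg_jitter * rng.standard_normal(spec.n_frames))
    rg_targets = np.clip(rg_targets, 0.1 * spec.target_rg, None)

    # per-frame wobble of the moment ratios keeps the shape distribution
    # non-degenerate while the ensemble mean stays on target
    ratio_jitter = np.abs(1.0 + spec.anisotropy_jitter
                          * rng.standard_normal((spec.n_frames, 3)))

    out = np.empty_like(coords)
    for f in range(spec.n_frames):
        x = coords[f]
        tensor = x.T @ x / len(x)
        evals, evecs = np.linalg.eigh(tensor)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        principal = x @ evecs  # axis 0 = longest
        t2_f = np.sort(t2 * ratio_jitter[f])[::-1]
        t2_f /= t2_f.sum()
        scale = np.sqrt(t2_f / np.clip(evals / evals.sum(), 1e-12, None))
        y = principal * scale
        y *= rg_targets[f] / np.sqrt((y**2).sum() / len(y))
        out[f] = y
    return Ensemble(coordinates=out, topology=spec.topology, pH=spec.pH)


@dataclass
class ProtonationSpec:
    """Ground-truth titration model for Bernoulli protonation sampling.

    Per-frame site protonation is Bernoulli with

        p = 1 / (1 + 10**(hill_n * (pH - pKa_eff))),

    where ``pKa_eff = pKa - dpka_max * sigmoid(steepness*(insertion -
    midpoint))`` when insertion coupling is enabled (emulating desolvation-
    driven pKa drops upon membrane insertion), else the site's bulk pKa.
    """

    pka: dict[int, float]  # site_id -> bulk pKa
    hill_n: float = 1.0
    pH: float = 7.0
    n_frames: int = 1000
    insertion_coupling: tuple[float, float, float] | None = None  # (dpKa_max, midpoint A, steepness 1/A)
    seed: int = 0

    def __post_init__(self):
        if self.hill_n <= 0:
            raise ValueError("hill_n must be positive")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")


def effective_pka(spec: ProtonationSpec, insertions=None) -> np.ndarray:
    """(n_frames, n_sites) effective pKa implied by the spec."""
    site_ids = sorted(spec.pka)
    base = np.array([spec.pka[s] for s in site_ids], dtype=float)
    if spec.insertion_coupling is None:
        return np.broadcast_to(base, (spec.n_frames, len(base))).copy()
    if insertions is None:
        raise ValueError("insertion coupling requires per-frame insertions")
    ins = np.asarray(insertions, dtype=float)
    if ins.shape != (spec.n_frames,):
        raise ValueError(
            f"insertions have length {ins.shape}, expected ({spec.n_frames},)")
    dpka, midpoint, steepness = spec.insertion_coupling
    shift = dpka / (1.0 + np.exp(-steepness * (ins - midpoint)))
    return base[None, :] - shift[:, None]


def generate_protonation_series(spec: ProtonationSpec, insertions=None,
                                topology: DendrimerTopology | None = None,
                                system: str = "", replicate: int = 0) -> ProtonationSeries:
    """Sample a Bernoulli protonation series from the spec's Hill model."""
    rng = np.random.default_rng(spec.seed)
    site_ids = sorted(spec.pka)
    pka_eff = effective_pka(spec, insertions)
    p = 1.0 / (1.0 + 10.0 ** (spec.hill_n * (spec.pH - pka_eff)))
    states = (rng.random(p.shape) < p).astype(np.int8)
    data = pd.DataFrame(states, columns=site_ids)
    return ProtonationSeries(data=data, topology=topology, system=system,
                             pH=spec.pH, replicate=replicate)


@dataclass
class MembraneSpec:
    """Geometry and perturbation of a synthetic phosphate bilayer.

    The unperturbed monolayer thickness is ``leaflet_separation / 2``
    (default 38/2 = 19 A, the phosphate-plane half-distance of a POPC-like
    bilayer).  ``dimple = (depth, width)`` displaces interacting-leaflet
    phosphates toward the membrane center by ``depth*exp(-r^2/(2*width^2))``
    with r the lateral distance to the dendrimer center.
    """

    n_lipids_per_leaflet: int = 256
    box: tuple[float, float] = (100.0, 100.0)
    leaflet_separation: float = 38.0
    dimple: tuple[float, float] | None = None  # (depth A, width A)
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_lipids_per_leaflet < 1:
            raise ValueError("need at least one lipid per leaflet")
        if self.dimple is not None and self.dimple[0] < 0:
            raise ValueError("dimple depth must be >= 0")


def _grid_positions(n: int, box, rng: np.random.Generator) -> np.ndarray:
    nx = int(np.ceil(np.sqrt(n)))
    xs = (np.arange(nx) + 0.5) * box[0] / nx
    ys = (np.arange(nx) + 0.5) * box[1] / nx
    xy = np.stack(np.meshgrid(xs, ys), axis=-1).reshape(-1, 2)[:n]
    xy += rng.normal(scale=0.5, size=xy.shape)
    xy[:, 0] %= box[0]
    xy[:, 1] %= box[1]
    return xy


def generate_membrane_system(mspec: MembraneSpec, dendrimer_track) -> tuple[list[MembraneFrame], Ensemble]:
    """Synthetic bilayer frames aligned to a dendrimer center track.

    ``dendrimer_track`` is an (n_frames, 3) array of dendrimer geometric
    centers (wrapped into the box laterally).  The leaflet nearer the track
    is dimpled toward the membrane center when ``mspec.dimple`` is set.
    Returns the membrane frames plus a one-bead ensemble of the track.
    """
    track = np.asarray(dendrimer_track, dtype=float)
    if track.ndim != 2 or track.shape[1] != 3:
        raise ValueError("dendrimer_track must have shape (n_frames, 3)")
    rng = np.random.default_rng(mspec.seed)
    half = mspec.leaflet_separation / 2.0
    n = mspec.n_lipids_per_leaflet
    base_xy = {leaf: _grid_positions(n, mspec.box, rng)
               for leaf in ("upper", "lower")}

    frames = []
    for f, center in enumerate(track):
        cxy = center[:2] % np.asarray(mspec.box)
        leaflets = {}
        interacting = "upper" if center[2] >= 0 else "lower"
        for leaf, sign in (("upper", 1.0), ("lower", -1.0)):
            xy = base_xy[leaf] + rng.normal(scale=0.2, size=(n, 2))
            xy[:, 0] %= mspec.box[0]
            xy[:, 1] %= mspec.box[1]
            z = np.full(n, sign * half)
            if mspec.dimple is not None and leaf == interacting:
                depth, width = mspec.dimple
                d = xy - cxy
                for k, L in enumerate(mspec.box):
                    d[:, k] -= L * np.round(d[:, k] / L)
                r2 = (d**2).sum(axis=1)
                z -= sign * depth * np.exp(-r2 / (2.0 * width**2))
            z += rng.normal(scale=mspec.noise_sd, size=n)
            leaflets[leaf] = np.column_stack([xy, z])
        frames.append(MembraneFrame(upper=leaflets["upper"],
                                    lower=leaflets["lower"],
                                    box=mspec.box, index=f))
    track_ens = Ensemble(coordinates=track[:, None, :], system="dendrimer-track")
    return frames, track_ens
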