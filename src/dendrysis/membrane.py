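"""Membrane insertion coordinates, insertion-conditioned profiles, and
bilayer deformation analysis.

The bilayer is reduced to its phosphate reference atoms, split into an
upper and a lower leaflet by the sign of z relative to the membrane center
(the midpoint of the two leaflet phosphate means).  Two insertion
conventions are supported:

``center``
    Unsigned distance of a group center to the membrane center z; the
    convention of structural-property profiles.
``insertion``
    Signed distance past the interacting leaflet's mean phosphate plane —
    positive once the group passes the phosphates toward the membrane
    center, negative while still in water; zero at the phosphate plane.
    The interacting leaflet is the one whose plane is nearer the group.

Deformation observables use the *monolayer thickness* |z_P - z_center| of
interacting-leaflet phosphates.  Lipids more than ``bulk_cutoff`` (15 A)
laterally away from the dendrimer are treated as unperturbed bulk and set
the reference thickness; deviations are reported as local - bulk, so lipids
dragged toward the membrane center give negative values and protruding
lipids positive ones.

Binned profiles enforce a minimum-sampling rule: slices with fewer points
than ``min_count`` are discarded (carry no value).  Default thresholds are
400 points for structural observables, 1500 for protonation and 2500 for
pKa slices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .titration import TitrationCurve, _sem, hill_fit, jackknife_pka

__all__ = [
    "MembraneFrame",
    "InsertionProfile",
    "DeformationProfile",
    "MIN_COUNT_OBSERVABLE",
    "MIN_COUNT_PROTONATION",
    "MIN_COUNT_PKA",
    "insertion_coordinate",
    "profile_by_insertion",
    "conditional_pka_profile",
    "local_deformation",
    "radial_thickness_profile",
]

MIN_COUNT_OBSERVABLE = 400
MIN_COUNT_PROTONATION = 1500
MIN_COUNT_PKA = 2500


@dataclass
class MembraneFrame:
    """Leaflet-resolved phosphate reference positions for one frame."""

    upper: np.ndarray  # (n_up, 3) phosphate positions, Angstrom
    lower: np.ndarray  # (n_low, 3)
    box: tuple[float, float]  # (Lx, Ly), periodic in x/y
    index: int = 0

    def __post_init__(self):
        self.upper = np.asarray(self.upper, dtype=float)
        self.lower = np.asarray(self.lower, dtype=float)
        if len(self.upper) == 0 or len(self.lower) == 0:
            raise ValueError("both leaflets must be non-empty")

    @property
    def center_z(self) -> float:
        return 0.5 * (self.upper[:, 2].mean() + self.lower[:, 2].mean())

    def leaflet_plane_z(self, leaflet: str) -> float:
        return float(getattr(self, leaflet)[:, 2].mean())

    def interacting_leaflet(self, z: float) -> str:
        du = abs(self.leaflet_plane_z("upper") - z)
        dl = abs(self.leaflet_plane_z("lower") - z)
        return "upper" if du <= dl else "lower"


def _lateral_distance(points_xy: np.ndarray, ref_xy: np.ndarray,
                      box: tuple[float, float]) -> np.ndarray:
    """Minimum-image lateral distances from each point to the nearest
    reference position.  ``ref_xy`` may be a single (2,) center or an
    (m, 2) set of bead positions."""
    ref = np.atleast_2d(np.asarray(ref_xy, dtype=float))
    d = points_xy[:, None, :] - ref[None, :, :]
    for k, L in enumerate(box):
        d[..., k] -= L * np.round(d[..., k] / L)
    return np.sqrt((d ** 2).sum(axis=-1)).min(axis=1)


def insertion_coordinate(group_center, membrane: MembraneFrame,
                         mode: str = "insertion") -> float:
    """Insertion coordinate of a group center (Angstrom).

    ``mode="center"``: unsigned distance to the membrane center plane.
    ``mode="insertion"``: signed distance past the interacting leaflet's
    mean phosphate plane (positive = inserted, negative = in water).
    """
    gc = np.asarray(group_center, dtype=float).reshape(-1)
    if gc.shape[0] != 3:
        raise ValueError("group_center must be a 3-vector")
    z = float(gc[2])
    if mode == "center":
        return abs(z - membrane.center_z)
    if mode == "insertion":
        leaflet = membrane.interacting_leaflet(z)
        plane = membrane.leaflet_plane_z(leaflet)
        if plane >= membrane.center_z:  # upper leaflet: inserted means below
            return plane - z
        return z - plane
    raise ValueError(f"unknown insertion mode {mode!r}")


@dataclass
class InsertionProfile:
    """Binned observable vs insertion with the minimum-sampling rule applied.

    Discarded (under-sampled) bins carry NaN mean/SEM and
    ``retained=False``."""

    coordinate: str
    bin_edges: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    count: np.ndarray
    retained: np.ndarray
    min_count: int

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin_center": self.bin_centers, "mean": self.mean,
            "sem": self.sem, "count": self.count, "retained": self.retained,
        })


def profile_by_insertion(values, insertions, bin_width: float = 1.0,
                         min_count: int = MIN_COUNT_OBSERVABLE,
                         replicate_ids=None,
                         coordinate: str = "insertion") -> InsertionProfile:
    """Bin an observable along the insertion coordinate.

    Per bin: mean and SEM of the observable; bins with fewer than
    ``min_count`` points are discarded.  If ``replicate_ids`` is given the
    SEM is computed over replicate means (the unit of independence);
    otherwise over the pooled points.
    """
    values = np.asarray(values, dtype=float)
    insertions = np.asarray(insertions, dtype=float)
    if values.shape != insertions.shape:
        raise ValueError("values and insertions must be aligned")
    if bin_width <= 0:
        raise ValueError(f"bin width must be positive, got {bin_width}")

    lo = np.floor(insertions.min() / bin_width) * bin_width
    hi = np.ceil(insertions.max() / bin_width) * bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    if len(edges) < 2:
        edges = np.array([lo, lo + bin_width])
    idx = np.clip(np.digitize(insertions, edges) - 1, 0, len(edges) - 2)

    nb = len(edges) - 1
    mean = np.full(nb, np.nan)
    sem = np.full(nb, np.nan)
    count = np.zeros(nb, dtype=int)
    for b in range(nb):
        sel = idx == b
        count[b] = sel.sum()
        if count[b] < min_count or count[b] == 0:
            continue
        v = values[sel]
        mean[b] = v.mean()
        if replicate_ids is not None:
            rids = np.asarray(replicate_ids)[sel]
            rmeans = np.array([v[rids == r].mean() for r in np.unique(rids)])
            sem[b] = _sem(rmeans[None, :])[0]
        else:
            sem[b] = v.std(ddof=1) / np.sqrt(count[b]) if count[b] > 1 else 0.0
    retained = count >= min_count
    return InsertionProfile(coordinate=coordinate, bin_edges=edges, mean=mean,
                            sem=sem, count=count, retained=retained,
                            min_count=min_count)


def conditional_pka_profile(series, insertions, grouping="ALL",
                            bin_width: float = 1.0,
                            min_count: int = MIN_COUNT_PKA,
                            fix_n: float | None = None) -> pd.DataFrame:
    """pKa re-estimated within each membrane-insertion slice.

    Parameters
    ----------
    series:
        List of :class:`~dendrysis.titration.ProtonationSeries` spanning at
        least two pH values (and their replicates).
    insertions:
        List of per-frame insertion coordinates aligned 1:1 with ``series``.
    grouping:
        Site group passed through to the protonation averaging
        (``"ALL"``, ``(generation, kind)`` or a site id).
    min_count:
        Minimum number of (frame x site) protonation observations a slice
        must hold *at every pH* to be retained (default 2500).
    fix_n:
        Fix the Hill coefficient; by default n is free with >=3 informative
        pH points and fixed at 1 otherwise (the two-pH extrapolation regime
        of deeply inserted slices).

    Returns
    -------
    DataFrame with one row per slice: bin_center, pka, pka_err, count,
    retained, defined.  Slices whose protonation saturates at 0 or 1 at
    every pH have ``defined=False`` (pKa is NaN but the slice is not an
    error).  ``pka_err`` is the leave-one-replicate-out jackknife SE when
    >=3 replicates are available.
    """
    if len(series) != len(insertions):
        raise ValueError("series and insertions must be aligned")
    ph_values = sorted({float(s.pH) for s in series})
    if len(ph_values) < 2:
        raise ValueError("conditional pKa needs series at >=2 pH values")

    all_ins = np.concatenate([np.asarray(i, dtype=float) for i in insertions])
    lo = np.floor(all_ins.min() / bin_width) * bin_width
    hi = np.ceil(all_ins.max() / bin_width) * bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    nb = len(edges) - 1

    def group_cols(s):
        if grouping == "ALL":
            return s.site_ids
        if isinstance(grouping, tuple):
            return s.site_columns(generation=grouping[0], kind=grouping[1])
        return [int(grouping)]

    # per (bin, pH, replicate): sum and count of protonation observations
    reps = sorted({int(s.replicate) for s in series})
    rix = {r: k for k, r in enumerate(reps)}
    pix = {p: k for k, p in enumerate(ph_values)}
    sums = np.zeros((nb, len(ph_values), len(reps)))
    nobs = np.zeros((nb, len(ph_values), len(reps)), dtype=int)
    for s, ins in zip(series, insertions):
        ins = np.asarray(ins, dtype=float)
        if len(ins) != s.n_frames:
            raise ValueError("insertions misaligned with series frames")
        prot = s.data[group_cols(s)].to_numpy()
        idx = np.clip(np.digitize(ins, edges) - 1, 0, nb - 1)
        j, k = pix[float(s.pH)], rix[int(s.replicate)]
        for b in np.unique(idx):
            sel = idx == b
            sums[b, j, k] += prot[sel].sum()
            nobs[b, j, k] += prot[sel].size

    rows = []
    for b in range(nb):
        count = int(nobs[b].sum(axis=1).min())  # worst-sampled pH decides
        retained = count >= min_count
        pka = np.nan
        err = np.nan
        defined = False
        if retained:
            with np.errstate(invalid="ignore"):
                rep_means = sums[b] / nobs[b]  # (n_ph, n_rep), NaN if empty
            ok_rep = ~np.isnan(rep_means).any(axis=0)
            rm = rep_means[:, ok_rep]
            mean = np.nansum(sums[b], axis=1) / np.nansum(nobs[b], axis=1)
            informative = (mean > 0) & (mean < 1)
            if informative.any():
                defined = True
                n_fix = fix_n  # hill_fit auto-fixes n in the sparse regime
                curve = TitrationCurve(label=f"slice_{b}",
                                       ph=np.asarray(ph_values), mean=mean,
                                       sem=np.zeros(len(ph_values)),
                                       replicate_means=(rm if rm.shape[1] >= 1
                                                        else None))
                if rm.shape[1] >= 3:
                    pka, err = jackknife_pka(curve, fix_n=n_fix)
                else:
                    pka = hill_fit(curve, fix_n=n_fix).pka
        rows.append({"bin_center": 0.5 * (edges[b] + edges[b + 1]),
                     "pka": pka, "pka_err": err, "count": count,
                     "retained": retained, "defined": defined})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# deformation
# ---------------------------------------------------------------------------

def _dendrimer_xy_z(positions) -> tuple[np.ndarray, float]:
    """(m, 2) lateral bead positions and the mean z of one frame's
    dendrimer coordinates ((3,) center or (m, 3) beads)."""
    pos = np.asarray(positions, dtype=float)
    if pos.ndim == 1:
        pos = pos[None, :]
    return pos[:, :2], float(pos[:, 2].mean())


def local_deformation(membranes, dendrimer_positions,
                      proximal_cutoff: float = 6.0,
                      bulk_cutoff: float = 15.0,
                      replicate_ids=None) -> tuple[float, float]:
    """Mean thickness deviation of lipids in direct contact with the dendrimer.

    Per frame, interacting-leaflet phosphates within ``proximal_cutoff``
    (lateral distance to the nearest dendrimer bead, default 6 A) are
    compared against the bulk reference (same leaflet, beyond
    ``bulk_cutoff``, default 15 A):

        deviation = <thickness_proximal> - <thickness_bulk>,

    negative when proximal lipids are dragged toward the membrane center.
    Returns ``(mean deviation, SEM)`` with the SEM over replicates when
    ``replicate_ids`` is given, else over frames.
    """
    devs = []
    for mem, pos in zip(membranes, dendrimer_positions):
        xy, z = _dendrimer_xy_z(pos)
        leaflet = getattr(mem, mem.interacting_leaflet(z))
        dist = _lateral_distance(leaflet[:, :2], xy, mem.box)
        thickness = np.abs(leaflet[:, 2] - mem.center_z)
        bulk = thickness[dist > bulk_cutoff]
        if len(bulk) == 0:
            raise ValueError(f"frame {mem.index}: no bulk lipids beyond "
                             f"{bulk_cutoff} A")
        prox = thickness[dist <= proximal_cutoff]
        devs.append(prox.mean() - bulk.mean() if len(prox) else np.nan)
    devs = np.asarray(devs)
    if np.isnan(devs).all():
        raise ValueError("no proximal lipids in any frame")
    if replicate_ids is not None:
        rids = np.asarray(replicate_ids)
        rmeans = np.array([np.nanmean(devs[rids == r])
                           for r in np.unique(rids)])
        return float(np.nanmean(rmeans)), float(_sem(rmeans[None, :])[0])
    ok = devs[~np.isnan(devs)]
    sem = float(ok.std(ddof=1) / np.sqrt(len(ok))) if len(ok) > 1 else 0.0
    return float(ok.mean()), sem


@dataclass
class DeformationProfile:
    """Radial monolayer-thickness deviation around the dendrimer."""

    r_centers: np.ndarray
    deviation: np.ndarray  # local - bulk thickness, Angstrom
    sem: np.ndarray
    count: np.ndarray
    bulk_thickness: float
    slice_width: float
    step: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"r": self.r_centers, "deviation": self.deviation,
                             "sem": self.sem, "count": self.count})


def radial_thickness_profile(membranes, dendrimer_positions,
                             slice_width: float = 1.0, step: float = 0.5,
                             r_max: float = 25.0,
                             bulk_cutoff: float = 15.0) -> DeformationProfile:
    """Monolayer-thickness deviation in radial slices around the dendrimer.

    Overlapping radial slices of width ``slice_width`` advance by ``step``
    (defaults 1 A and 0.5 A) out to ``r_max`` (25 A).  Each slice reports
    the mean interacting-leaflet thickness minus the bulk reference
    (phosphates beyond ``bulk_cutoff``); lipids beyond ``r_max`` contribute
    only to the bulk.
    """
    if slice_width <= 0 or step <= 0:
        raise ValueError("slice width and step must be positive")
    starts = np.arange(0.0, r_max - slice_width + step / 2, step)
    centers = starts + slice_width / 2

    per_slice = [[] for _ in starts]
    bulk_all = []
    counts = np.zeros(len(starts), dtype=int)
    for mem, pos in zip(membranes, dendrimer_positions):
        xy, z = _dendrimer_xy_z(pos)
        leaflet = getattr(mem, mem.interacting_leaflet(z))
        dist = _lateral_distance(leaflet[:, :2], xy, mem.box)
        thickness = np.abs(leaflet[:, 2] - mem.center_z)
        bulk = thickness[dist > bulk_cutoff]
        if len(bulk) == 0:
            raise ValueError(f"frame {mem.index}: no bulk lipids beyond "
                             f"{bulk_cutoff} A")
        bulk_all.append(bulk.mean())
        for k, r0 in enumerate(starts):
            sel = (dist >= r0) & (dist < r0 + slice_width)
            if sel.any():
                per_slice[k].append(thickness[sel] - bulk.mean())
                counts[k] += int(sel.sum())

    deviation = np.full(len(starts), np.nan)
    sem = np.full(len(starts), np.nan)
    for k, chunks in enumerate(per_slice):
        if not chunks:
            continue
        frame_means = np.array([c.mean() for c in chunks])
        deviation[k] = frame_means.mean()
        sem[k] = (frame_means.std(ddof=1) / np.sqrt(len(frame_means))
                  if len(frame_means) > 1 else 0.0)
    return DeformationProfile(r_centers=centers, deviation=deviation, sem=sem,
                              count=counts, bulk_thickness=float(np.mean(bulk_all)),
                              slice_width=slice_width, step=step)
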