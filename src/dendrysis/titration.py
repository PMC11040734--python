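"""Titration analytics: protonation aggregation, Hill fits, jackknife errors.

Per-frame binary protonation states (one column per titratable site) are
aggregated into titration curves — total, per (generation, kind) group, or
per site — and fitted to the Hill equation for cationic groups,

    <prot>(pH) = 1 / (1 + 10**(n * (pH - pKa))),

which decreases with pH (amines release their proton as the solution turns
basic).  Errors on fitted pKa values come from leave-one-replicate-out
jackknife resampling; the unit of statistical independence is the replicate
simulation, never the (autocorrelated) frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .topology import DendrimerTopology

__all__ = [
    "ProtonationSeries",
    "TitrationCurve",
    "HillFit",
    "NoTransitionError",
    "hill_curve",
    "mean_protonation",
    "hill_fit",
    "jackknife_pka",
    "total_charge",
]


class NoTransitionError(ValueError):
    """Raised when a titration curve is flat at 0 or 1 everywhere."""


def hill_curve(ph, pka: float, n: float = 1.0):
    """Hill equation for a cationic group (protonation decreasing in pH)."""
    ph = np.asarray(ph, dtype=float)
    return 1.0 / (1.0 + 10.0 ** (n * (ph - pka)))


@dataclass
class ProtonationSeries:
    """Per-frame binary protonation states for one (system, pH, replicate).

    ``data`` columns are site ids matching the topology's titratable-site
    list; entries are 0 (deprotonated) or 1 (protonated).
    """

    data: pd.DataFrame
    topology: DendrimerTopology | None = None
    system: str = ""
    pH: float = float("nan")
    replicate: int = 0

    def __post_init__(self):
        vals = self.data.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("protonation states must be binary 0/1")
        if self.topology is not None:
            expected = [s.site_id for s in self.topology.sites]
            got = [int(c) for c in self.data.columns]
            if sorted(got) != sorted(expected):
                raise ValueError(
                    "protonation columns do not match the topology's "
                    f"titratable sites (got {len(got)}, expected {len(expected)})")

    @property
    def n_frames(self) -> int:
        return len(self.data)

    @property
    def site_ids(self) -> list[int]:
        return [int(c) for c in self.data.columns]

    def site_columns(self, generation: int | None = None,
                     kind: str | None = None) -> list[int]:
        if self.topology is None:
            raise ValueError("site grouping requires a topology")
        ids = [s.site_id
               for s in self.topology.sites_in_group(generation, kind)]
        if not ids:
            raise ValueError(
                f"empty titratable-site group (generation={generation}, "
                f"kind={kind}) for {self.topology.name}")
        return ids

    def to_tsv(self, path) -> None:
        out = self.data.copy()
        out.insert(0, "frame_idx", np.arange(len(out)))
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, topology=None, system="", pH=float("nan"),
                 replicate=0) -> "ProtonationSeries":
        df = pd.read_csv(path, sep="\t")
        df = df.drop(columns=["frame_idx"], errors="ignore").astype(np.int8)
        df.columns = [int(c) for c in df.columns]
        return cls(data=df, topology=topology, system=system, pH=pH,
                   replicate=replicate)


@dataclass
class TitrationCurve:
    """Mean protonation vs pH with replicate-based errors.

    ``replicate_means`` holds the per-replicate means (n_pH, n_replicates)
    backing the SEM and the jackknife; ``mean`` is their average.
    """

    label: str
    ph: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    replicate_means: np.ndarray | None = None

    def __post_init__(self):
        self.ph = np.asarray(self.ph, dtype=float)
        self.mean = np.asarray(self.mean, dtype=float)
        self.sem = np.asarray(self.sem, dtype=float)
        if np.any(np.diff(self.ph) <= 0):
            raise ValueError("pH values must be strictly increasing")
        if np.any((self.mean < 0) | (self.mean > 1)):
            raise ValueError("mean protonation must lie in [0, 1]")

    @property
    def n_replicates(self) -> int:
        if self.replicate_means is None:
            return 1
        return self.replicate_means.shape[1]

    def leave_one_out(self, k: int) -> "TitrationCurve":
        """Curve rebuilt from all replicates except the k-th."""
        if self.replicate_means is None:
            raise ValueError("no replicate decomposition stored")
        rm = np.delete(self.replicate_means, k, axis=1)
        return TitrationCurve(label=self.label, ph=self.ph,
                              mean=rm.mean(axis=1), sem=_sem(rm),
                              replicate_means=rm)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"pH": self.ph, "mean_protonation": self.mean,
                             "sem": self.sem})


def _sem(replicate_means: np.ndarray) -> np.ndarray:
    m = replicate_means.shape[1]
    if m < 2:
        return np.zeros(replicate_means.shape[0])
    return replicate_means.std(axis=1, ddof=1) / np.sqrt(m)


def mean_protonation(series, grouping="ALL") -> TitrationCurve:
    """Aggregate protonation series into a titration curve.

    Parameters
    ----------
    series:
        List of :class:`ProtonationSeries` sharing one topology, spanning
        one or more pH values and replicates.
    grouping:
        ``"ALL"`` (every site), a ``(generation, kind)`` tuple, or a single
        site id (int).

    At each pH, frames and grouped sites are averaged within each replicate;
    the curve mean and SEM are taken over the replicate means.
    """
    if not series:
        raise ValueError("no protonation series given")
    label = "ALL" if grouping == "ALL" else str(grouping)

    by_ph: dict[float, list[float]] = {}
    for s in series:
        if grouping == "ALL":
            cols = s.site_ids
        elif isinstance(grouping, tuple):
            gen, kind = grouping
            cols = s.site_columns(generation=gen, kind=kind)
        else:
            cols = [int(grouping)]
            if cols[0] not in s.site_ids:
                raise ValueError(f"site {grouping} absent from series")
        by_ph.setdefault(float(s.pH), []).append(
            float(s.data[cols].to_numpy().mean()))

    ph = np.array(sorted(by_ph))
    counts = {len(v) for v in by_ph.values()}
    if len(counts) != 1:
        raise ValueError("unequal replicate counts across pH values")
    rep = np.array([by_ph[p] for p in ph])  # (n_ph, n_rep)
    return TitrationCurve(label=label, ph=ph, mean=rep.mean(axis=1),
                          sem=_sem(rep), replicate_means=rep)


@dataclass
class HillFit:
    pka: float
    hill_n: float
    pka_error: float | None = None
    residual_norm: float = float("nan")
    n_points: int = 0
    n_fixed: bool = False


#: a pH point constrains the Hill coefficient only inside the transition
#: region; points this close to saturation carry no slope information
INFORMATIVE_MARGIN = 0.01


def _informative(curve: TitrationCurve,
                 eps: float = INFORMATIVE_MARGIN) -> np.ndarray:
    return (curve.mean > eps) & (curve.mean < 1.0 - eps)


def hill_fit(curve: TitrationCurve, fix_n: float | None = None) -> HillFit:
    """Least-squares Hill fit of a titration curve.

    A free Hill coefficient needs at least 3 pH points inside the
    transition region (mean within ``(0.01, 0.99)``); with fewer — the
    sparsely-sampled or extrapolated membrane-slice regime — ``n`` is fixed
    at 1 and only the pKa is fitted.  The loss is unweighted least squares
    on the mean protonation.
    """
    if not ((curve.mean > 0) & (curve.mean < 1)).any():
        raise NoTransitionError(
            f"curve {curve.label!r} is saturated at 0 or 1 at every pH")
    n_info = int(_informative(curve).sum())
    if fix_n is None and n_info < 3:
        fix_n = 1.0

    # initial pKa: pH where the curve crosses 1/2 (interpolated)
    p0_pka = float(np.interp(0.5, curve.mean[::-1], curve.ph[::-1]))

    if fix_n is not None:
        popt, _ = curve_fit(lambda ph, pka: hill_curve(ph, pka, fix_n),
                            curve.ph, curve.mean, p0=[p0_pka], maxfev=10000)
        pka, n = float(popt[0]), float(fix_n)
        fixed = True
    else:
        popt, _ = curve_fit(hill_curve, curve.ph, curve.mean,
                            p0=[p0_pka, 1.0],
                            bounds=([-np.inf, 1e-6], [np.inf, np.inf]),
                            maxfev=10000)
        pka, n = float(popt[0]), float(popt[1])
        fixed = False
    resid = curve.mean - hill_curve(curve.ph, pka, n)
    return HillFit(pka=pka, hill_n=n, residual_norm=float(np.linalg.norm(resid)),
                   n_points=len(curve.ph), n_fixed=fixed)


def jackknife_pka(curve_or_replicates, fix_n: float | None = None) -> tuple[float, float]:
    """pKa with a leave-one-replicate-out jackknife standard error.

    Accepts either a :class:`TitrationCurve` carrying its replicate
    decomposition or a list of per-replicate curves on a common pH axis
    (at least 3 replicates).  Returns ``(pKa, SE)`` where pKa is the
    full-sample fit and SE the jackknife standard error
    ``sqrt((m-1)/m * sum((theta_i - theta_bar)^2))``.
    """
    if isinstance(curve_or_replicates, TitrationCurve):
        curve = curve_or_replicates
        if curve.replicate_means is None:
            raise ValueError("curve carries no replicate decomposition")
    else:
        reps = list(curve_or_replicates)
        ph = reps[0].ph
        for c in reps[1:]:
            if not np.array_equal(c.ph, ph):
                raise ValueError("replicate curves must share a pH axis")
        rm = np.stack([c.mean for c in reps], axis=1)
        curve = TitrationCurve(label=reps[0].label, ph=ph, mean=rm.mean(axis=1),
                               sem=_sem(rm), replicate_means=rm)
    m = curve.n_replicates
    if m < 3:
        raise ValueError(f"jackknife needs >=3 replicates, got {m}")

    full = hill_fit(curve, fix_n=fix_n)
    loo = np.empty(m)
    for k in range(m):
        try:
            loo[k] = hill_fit(curve.leave_one_out(k), fix_n=fix_n).pka
        except Exception as err:  # noqa: BLE001 - annotate the failing replicate
            raise RuntimeError(
                f"leave-one-out Hill fit failed with replicate {k} "
                f"removed") from err
    se = float(np.sqrt((m - 1) / m * np.sum((loo - loo.mean()) ** 2)))
    return full.pka, se


def total_charge(series: ProtonationSeries,
                 topology: DendrimerTopology | None = None) -> np.ndarray:
    """Per-frame total charge in elementary charges.

    Every protonated site (lysine side-chain amine or free N-terminus)
    contributes +1; deprotonated sites are neutral.
    """
    del topology  # all sites here are cationic; kept for interface symmetry
    return series.data.to_numpy().sum(axis=1).astype(int)
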