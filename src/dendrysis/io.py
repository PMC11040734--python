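"""File I/O: descriptor tables, landscapes, trajectories and run manifests.

Coordinate ensembles are written/read through MDAnalysis as a one-frame GRO
topology plus a multi-frame XYZ trajectory (both plain text); protonation
series travel as TSV with a ``frame_idx`` column followed by one 0/1 column
per site id; the run manifest (systems x pH x replicates) is YAML.
"""

from __future__ import annotations

import os
import warnings

import numpy as np
import pandas as pd
import yaml

from .ensemble import Ensemble
from .topology import DendrimerTopology

__all__ = [
    "write_ensemble",
    "read_ensemble",
    "write_descriptor_table",
    "write_landscape_tsv",
    "write_profile_tsv",
    "read_manifest",
]

_ANGSTROM_TO_NM = 0.1


def write_ensemble(ensemble: Ensemble, prefix: str) -> tuple[str, str]:
    """Write an ensemble as ``<prefix>.gro`` (first frame, topology) plus
    ``<prefix>.xyz`` (all frames).  Returns the two paths."""
    import MDAnalysis as mda

    n = ensemble.n_beads
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # MDAnalysis guesses missing fields
        u = mda.Universe.empty(n, n_residues=n,
                               atom_resindex=np.arange(n),
                               trajectory=True)
        u.add_TopologyAttr("names", ["CA"] * n)
        if ensemble.topology is not None:
            resnames = [r.code for r in ensemble.topology.residues]
        else:
            resnames = ["BEA"] * n
        u.add_TopologyAttr("resnames", resnames)
        u.add_TopologyAttr("resids", np.arange(1, n + 1))
        u.dimensions = [200.0, 200.0, 200.0, 90.0, 90.0, 90.0]
        gro = f"{prefix}.gro"
        xyz = f"{prefix}.xyz"
        u.atoms.positions = ensemble.coordinates[0]
        u.atoms.write(gro)
        with mda.Writer(xyz, n) as w:
            for frame in ensemble.coordinates:
                u.atoms.positions = frame
                w.write(u.atoms)
    return gro, xyz


def read_ensemble(topology_file: str, trajectory_file: str | None = None,
                  topology: DendrimerTopology | None = None,
                  selection: str = "all") -> Ensemble:
    """Load a coordinate ensemble from standard MD formats via MDAnalysis
    (GRO/PDB topology, optionally an XYZ/XTC/DCD trajectory)."""
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if trajectory_file is None:
            u = mda.Universe(topology_file)
        else:
            u = mda.Universe(topology_file, trajectory_file)
        atoms = u.select_atoms(selection)
        coords = np.stack([atoms.positions.copy() for _ in u.trajectory])
    return Ensemble(coordinates=coords.astype(float), topology=topology,
                    system=os.path.basename(topology_file))


def write_descriptor_table(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_landscape_tsv(landscape, path: str, energy_cap: float = 50.0) -> None:
    """Gridded landscape as TSV columns (x, y, P, E); infinite energies
    (zero-density cells) are capped at ``energy_cap`` kJ/mol."""
    xx, yy = np.meshgrid(landscape.x, landscape.y, indexing="ij")
    energy = landscape.energy
    if energy is None:
        energy = np.full_like(landscape.density, np.nan)
    energy = np.minimum(energy, energy_cap)
    df = pd.DataFrame({"x": xx.ravel(), "y": yy.ravel(),
                       "P": landscape.density.ravel(), "E": energy.ravel()})
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_profile_tsv(profile, path: str) -> None:
    profile.to_frame().to_csv(path, sep="\t", index=False,
                              float_format="%.6g")


def read_manifest(path: str) -> dict:
    """Run manifest: mapping of systems to sequence strings plus the pH and
    replicate grid, e.g.::

        systems:
          MH18: "(KL)_8(*K*KL)_4(*K*LL)_2*K*LLLL"
        ph_values: [3, 4, 5]
        replicates: 5
    """
    with open(path) as fh:
        manifest = yaml.safe_load(fh)
    if not isinstance(manifest, dict) or "systems" not in manifest:
        raise ValueError(f"manifest {path} must map 'systems' to sequences")
    return manifest
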