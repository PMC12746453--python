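"""File formats: initial-conditions text files, HDF5 trace containers,
and provenance records.

The initial-conditions file is a versioned plain-text format carrying one
record per phase-space sample, optionally extended with the selection
outcome (initial electronic state and start time); rejected records are
flagged, never dropped.  Bulk numerical histories (population traces,
trajectory swarms, grid wavepackets) go into HDF5 containers.
"""

from __future__ import annotations

import hashlib
import json

import h5py
import numpy as np

from .eod import EnsemblePopulations
from .sampling import WignerSample
from .select import SelectionResult
from .units import AUT_FS, fs_to_au

__all__ = [
    "write_initial_conditions",
    "read_initial_conditions",
    "save_ensemble_populations",
    "load_ensemble_populations",
    "provenance_record",
]

_ICFILE_HEADER = "# eoexcite initial conditions v1"


def write_initial_conditions(path, samples, selection=None) -> None:
    """Write samples (and optionally selection results) as text records.

    Columns: index, R [bohr], v [au], then either ``unselected`` /
    ``rejected`` or ``state <alpha> t_start <fs>``.
    """
    by_id = {}
    if selection is not None:
        by_id = {s.geometry_id: s for s in selection}
    with open(path, "w") as fh:
        fh.write(_ICFILE_HEADER + "\n")
        fh.write("# index  R[bohr]  v[au]  status...\n")
        for s in samples:
            line = f"{s.index:8d} {s.r:18.12f} {s.v: 18.12e}"
            res = by_id.get(s.index)
            if res is None:
                line += "  unselected"
            elif res.accepted:
                line += f"  state {res.state} t_start {res.t_start * AUT_FS:.6f}"
            else:
                line += "  rejected"
            fh.write(line + "\n")


def read_initial_conditions(path):
    """Read a file written by :func:`write_initial_conditions`.

    Returns ``(samples, selection)``; ``selection`` is ``None`` when the
    file holds bare samples.
    """
    samples, selection = [], []
    has_selection = False
    with open(path) as fh:
        first = fh.readline().strip()
        if first != _ICFILE_HEADER:
            raise ValueError(f"not an eoexcite initial-conditions file: {path}")
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.split()
            idx, r, v = int(parts[0]), float(parts[1]), float(parts[2])
            samples.append(WignerSample(index=idx, r=r, v=v))
            tag = parts[3]
            if tag == "unselected":
                selection.append(None)
            elif tag == "rejected":
                has_selection = True
                selection.append(SelectionResult(geometry_id=idx, accepted=False))
            elif tag == "state":
                has_selection = True
                selection.append(
                    SelectionResult(
                        geometry_id=idx, accepted=True, state=int(parts[4]),
                        t_start=fs_to_au(float(parts[6])),
                    )
                )
            else:
                raise ValueError(f"unrecognized record: {line!r}")
    if not has_selection:
        return samples, None
    return samples, [s for s in selection if s is not None]


def save_ensemble_populations(path, ens: EnsemblePopulations) -> None:
    with h5py.File(path, "w") as fh:
        fh.attrs["format"] = "eoexcite-eod-v1"
        fh.attrs["initial_state"] = ens.initial_state
        fh.create_dataset("times", data=ens.times)
        fh.create_dataset("populations", data=ens.populations,
                          compression="gzip", compression_opts=4)
        fh.create_dataset("geometry_ids", data=ens.geometry_ids)
        fh.create_dataset("orientations", data=ens.orientations)


def load_ensemble_populations(path) -> EnsemblePopulations:
    with h5py.File(path, "r") as fh:
        if fh.attrs.get("format") != "eoexcite-eod-v1":
            raise ValueError("not an eoexcite electron-only trace container")
        return EnsemblePopulations(
            times=fh["times"][()],
            populations=fh["populations"][()],
            initial_state=int(fh.attrs["initial_state"]),
            geometry_ids=fh["geometry_ids"][()],
            orientations=fh["orientations"][()],
        )


def save_qd_trajectory(path, traj) -> None:
    """HDF5 container for a grid-propagation history."""
    with h5py.File(path, "w") as fh:
        fh.attrs["format"] = "eoexcite-qd-v1"
        fh.attrs["mass"] = traj.mass
        fh.create_dataset("grid", data=traj.grid)
        fh.create_dataset("times", data=traj.times)
        fh.create_dataset("psi", data=traj.psi, compression="gzip",
                          compression_opts=4)


def load_qd_trajectory(path):
    from .qdgrid import QDTrajectory

    with h5py.File(path, "r") as fh:
        if fh.attrs.get("format") != "eoexcite-qd-v1":
            raise ValueError("not an eoexcite grid-trajectory container")
        return QDTrajectory(
            grid=fh["grid"][()], times=fh["times"][()], psi=fh["psi"][()],
            mass=float(fh.attrs["mass"]),
        )


def save_trajectory_ensemble(path, ens) -> None:
    """HDF5 container for a surface-hopping swarm."""
    with h5py.File(path, "w") as fh:
        fh.attrs["format"] = "eoexcite-tsh-v1"
        fh.attrs["dt"] = ens.dt
        for name in ("times", "r", "v", "active", "populations", "alive",
                     "geometry_ids", "frustrated"):
            fh.create_dataset(name, data=getattr(ens, name))
        hops = np.array(
            [(t, k, a, b, fr) for (t, k, a, b, fr) in ens.hops],
            dtype=float,
        ).reshape(-1, 5)
        fh.create_dataset("hops", data=hops)


def load_trajectory_ensemble(path):
    from .tsh1d import TrajectoryEnsemble

    with h5py.File(path, "r") as fh:
        if fh.attrs.get("format") != "eoexcite-tsh-v1":
            raise ValueError("not an eoexcite swarm container")
        hops = [
            (row[0], int(row[1]), int(row[2]), int(row[3]), bool(row[4]))
            for row in fh["hops"][()]
        ]
        return TrajectoryEnsemble(
            times=fh["times"][()], r=fh["r"][()], v=fh["v"][()],
            active=fh["active"][()], populations=fh["populations"][()],
            alive=fh["alive"][()].astype(bool),
            geometry_ids=fh["geometry_ids"][()], hops=hops,
            frustrated=fh["frustrated"][()], dt=float(fh.attrs["dt"]),
        )


def provenance_record(config: dict, seeds: dict) -> dict:
    """Reproducibility stamp: config hash, seeds, package versions."""
    import eoexcite

    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return {
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seeds": seeds,
        "versions": {
            "eoexcite": eoexcite.__version__,
            "numpy": np.__version__,
        },
    }
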