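"""Photon stream persistence: Photon-HDF5-style containers and flat CSV.

The HDF5 layout follows the Photon-HDF5 convention of a ``photon_data``
group holding ``timestamps``, ``nanotimes`` and ``detectors`` arrays, one
group per molecule, with units recorded as attributes. The flat CSV form is
``molecule_id, macrotime_s, nanotime_ns, channel``.
"""

from __future__ import annotations

from typing import Sequence

import h5py
import numpy as np
import pandas as pd

from .synthetic import PhotonStream

__all__ = [
    "write_photon_hdf5",
    "read_photon_hdf5",
    "write_photon_csv",
    "read_photon_csv",
]


def write_photon_hdf5(streams: Sequence[PhotonStream], path) -> None:
    with h5py.File(path, "w") as fh:
        fh.attrs["format"] = "photon-hdf5-style"
        for stream in streams:
            grp = fh.create_group(f"molecule_{stream.molecule_id:05d}/photon_data")
            grp.create_dataset("timestamps", data=stream.macrotimes)
            grp["timestamps"].attrs["units"] = "s"
            grp.create_dataset("nanotimes", data=stream.nanotimes)
            grp["nanotimes"].attrs["units"] = "ns"
            grp.create_dataset("detectors", data=stream.channels)
            grp.attrs["duration_s"] = stream.duration
            for key, val in stream.meta.items():
                if isinstance(val, (int, float, str)):
                    grp.attrs[key] = val


def read_photon_hdf5(path) -> list[PhotonStream]:
    streams = []
    with h5py.File(path, "r") as fh:
        for name in sorted(fh):
            grp = fh[name]["photon_data"]
            meta = {k: v for k, v in grp.attrs.items() if k != "duration_s"}
            streams.append(
                PhotonStream(
                    macrotimes=grp["timestamps"][()],
                    nanotimes=grp["nanotimes"][()],
                    channels=grp["detectors"][()],
                    duration=float(grp.attrs["duration_s"]),
                    molecule_id=int(name.split("_")[1]),
                    meta=meta,
                )
            )
    return streams


def write_photon_csv(streams: Sequence[PhotonStream], path) -> None:
    frames = [
        pd.DataFrame(
            {
                "molecule_id": s.molecule_id,
                "macrotime_s": s.macrotimes,
                "nanotime_ns": s.nanotimes,
                "channel": s.channels,
            }
        )
        for s in streams
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_photon_csv(path, duration: float | None = None) -> list[PhotonStream]:
    """Read flat photon CSV. ``duration`` defaults per molecule to the last
    macrotime (a lower bound; pass the acquisition length if known)."""
    df = pd.read_csv(path)
    streams = []
    for mol_id, sub in df.groupby("molecule_id", sort=True):
        dur = duration if duration is not None else float(sub["macrotime_s"].max())
        streams.append(
            PhotonStream(
                macrotimes=sub["macrotime_s"].to_numpy(),
                nanotimes=sub["nanotime_ns"].to_numpy(),
                channels=sub["channel"].to_numpy(),
                duration=dur,
                molecule_id=int(mol_id),
            )
        )
    return streams
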