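"""Reading and writing cohort data: HDF5 recordings, lead fields, CSV tables.

Recordings are stored as channels x samples datasets with the sampling rate
and channel labels in attributes. EDF files can be read through :mod:`mne`
when it is installed (optional extra); all package-internal storage is HDF5
and CSV.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np

from .cohort import LeadFieldModel, SyntheticSubject, cohort_covariates
from .spectral import Recording


def save_lead_field(path, lf: LeadFieldModel) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("gain", data=lf.gain)
        f.create_dataset("source_positions", data=lf.source_positions)
        if lf.sensor_positions is not None:
            f.create_dataset("sensor_positions", data=lf.sensor_positions)
        f.attrs["sensor_labels"] = [str(x) for x in lf.sensor_labels]


def load_lead_field(path) -> LeadFieldModel:
    with h5py.File(path, "r") as f:
        return LeadFieldModel(
            f["gain"][()], f["source_positions"][()],
            [str(x) for x in f.attrs["sensor_labels"]],
            sensor_positions=f["sensor_positions"][()]
            if "sensor_positions" in f else None,
        )


def save_recordings(path, subjects: list[SyntheticSubject]) -> None:
    with h5py.File(path, "w") as f:
        for s in subjects:
            g = f.create_group(s.subject_id)
            g.create_dataset("data", data=s.recording.data.astype(np.float32))
            if s.emg.size:
                g.create_dataset("emg", data=s.emg.astype(np.float32))
            g.attrs["rate_hz"] = s.recording.rate_hz
            g.attrs["labels"] = [str(x) for x in s.recording.labels]
            g.attrs["group"] = s.group_label


def load_recordings(path):
    """Returns (subject_ids, groups, recordings) sorted by subject id."""
    ids, groups, recs = [], [], []
    with h5py.File(path, "r") as f:
        for sid in sorted(f.keys()):
            g = f[sid]
            ids.append(sid)
            groups.append(str(g.attrs["group"]))
            recs.append(Recording(g["data"][()].astype(float),
                                  float(g.attrs["rate_hz"]),
                                  [str(x) for x in g.attrs["labels"]]))
    return ids, groups, recs


def save_cohort(out_dir, subjects, lead_field: LeadFieldModel) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_lead_field(out / "leadfield.h5", lead_field)
    save_recordings(out / "recordings.h5", subjects)
    cohort_covariates(subjects).to_csv(out / "covariates.csv", index=False)


def read_edf(path) -> Recording:
    """Read an EDF recording via mne (optional dependency)."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("reading EDF files requires the 'mne' extra") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    return Recording(raw.get_data() * 1e6, float(raw.info["sfreq"]),
                     list(raw.ch_names))
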