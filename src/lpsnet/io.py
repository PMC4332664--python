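"""Readers for external study inputs.

Continuous EEG comes in as EDF (annotations become the event list) or
through the internal HDF5 study store; leadfields and trial tables come
in as CSV (or an HDF5 matrix for the leadfield).
"""
from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .containers import LeadField, RawRecording

__all__ = ["read_raw_edf", "leadfield_from_csv", "leadfield_from_hdf5", "read_trial_table"]


def read_raw_edf(path: str | Path, eog_channel: str | None = None,
                 emg_channel: str | None = None) -> RawRecording:
    """Load a continuous EDF recording; annotations become events.

    Requires ``mne``.  Channels named in ``eog_channel``/``emg_channel``
    are moved to the auxiliary dict.
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("reading EDF requires the 'mne' package") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data()
    labels = list(raw.ch_names)
    aux = {}
    keep = np.ones(len(labels), dtype=bool)
    for name, key in ((eog_channel, "eog"), (emg_channel, "emg")):
        if name is not None:
            idx = labels.index(name)
            aux[key] = data[idx]
            keep[idx] = False
    events = pd.DataFrame(
        {
            "time_s": np.asarray(raw.annotations.onset, dtype=float),
            "label": list(raw.annotations.description),
        }
    )
    return RawRecording(
        samples=data[keep],
        sampling_rate=float(raw.info["sfreq"]),
        channel_labels=[l for l, k in zip(labels, keep) if k],
        events=events,
        aux=aux,
    )


def leadfield_from_csv(path: str | Path) -> LeadField:
    """Channels x sources gain matrix with ROI labels as the CSV header."""
    frame = pd.read_csv(path)
    return LeadField(gain=frame.to_numpy(dtype=float), roi_labels=list(frame.columns))


def leadfield_from_hdf5(path: str | Path, dataset: str = "leadfield/gain") -> LeadField:
    with h5py.File(path, "r") as f:
        gain = np.asarray(f[dataset], dtype=float)
        labels = f[dataset].attrs.get("roi_labels")
    if labels is None:
        from .containers import default_roi_labels

        labels = default_roi_labels(gain.shape[1])
    else:
        labels = [l.decode() if isinstance(l, bytes) else str(l) for l in labels]
    return LeadField(gain=gain, roi_labels=list(labels))


def read_trial_table(path: str | Path) -> pd.DataFrame:
    """Trial table CSV: subject, condition, trial, stimulus_on_s, stimulus_off_s."""
    table = pd.read_csv(path)
    required = {"subject", "condition", "trial", "stimulus_on_s"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    return table
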