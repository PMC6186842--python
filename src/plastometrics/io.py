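"""Readers and writers for the interchange formats.

Clinical tables are CSV (empty field = missing); region time series are
TSV (first column the region label, remaining columns time points) with
a JSON sidecar carrying TR, subject, session and lesion side; EEG is a
delimited sample matrix with a JSON sidecar (or an EDF file when mne is
installed).  Tabular outputs carry a ``#``-prefixed provenance header;
JSON reports embed the same provenance block.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .clinical import ClinicalTable, TIME_COLUMNS
from .spectral import EpochedEEG, MONTAGE_16
from .variability import RegionTimeSeries, VariabilityProfile

__all__ = [
    "load_bundled_clinical",
    "read_clinical",
    "read_region_timeseries",
    "write_region_timeseries",
    "write_variability",
    "read_eeg",
    "write_report",
    "provenance",
]


def provenance(config: dict | None = None, seed=None) -> dict:
    return {
        "package": "plastometrics",
        "version": __version__,
        "seed": seed,
        "config": config or {},
    }


# ---------------------------------------------------------------------------
# clinical tables
# ---------------------------------------------------------------------------


def read_clinical(path) -> ClinicalTable:
    """Read a clinical CSV into a validated ClinicalTable."""
    path = Path(path)
    frame = pd.read_csv(path, dtype={"subject_id": str})
    if frame.empty:
        raise ValueError(f"{path}: no subjects found")
    for col in TIME_COLUMNS:
        if col in frame.columns:
            coerced = pd.to_numeric(frame[col], errors="coerce")
            bad = frame[col].notna() & coerced.isna()
            if bad.any():
                row = frame.loc[bad].iloc[0]
                raise ValueError(
                    f"{path}: malformed score {row[col]!r} in column {col}, "
                    f"subject {row['subject_id']}"
                )
            frame[col] = coerced
    return ClinicalTable(frame)


def load_bundled_clinical() -> ClinicalTable:
    """The bundled 24-subject demographics/score table of the study."""
    path = resources.files("plastometrics.data").joinpath("clinical_table.csv")
    with resources.as_file(path) as file:
        return read_clinical(file)


# ---------------------------------------------------------------------------
# region time series
# ---------------------------------------------------------------------------


def read_region_timeseries(path, sidecar=None) -> RegionTimeSeries:
    """TSV (label + time points per row) with a JSON sidecar of metadata."""
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", header=None, comment="#")
    labels = frame.iloc[:, 0].astype(str).tolist()
    if len(set(labels)) != len(labels):
        dupes = sorted({x for x in labels if labels.count(x) > 1})
        raise ValueError(f"{path}: duplicate region labels {dupes}")
    data = frame.iloc[:, 1:].to_numpy(dtype=float)
    meta = {}
    sidecar = Path(sidecar) if sidecar else path.with_suffix(".json")
    if Path(sidecar).exists():
        meta = json.loads(Path(sidecar).read_text())
    return RegionTimeSeries(
        region_labels=tuple(labels),
        data=data,
        tr_seconds=float(meta.get("tr_seconds", 2.0)),
        subject_id=str(meta.get("subject_id", "")),
        session=str(meta.get("session", "")),
        lesion_side=str(meta.get("lesion_side", "")),
    )


def write_region_timeseries(ts: RegionTimeSeries, path, sidecar=None) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for label, row in zip(ts.region_labels, ts.data):
            fh.write(label + "\t" + "\t".join(f"{v:.9g}" for v in row) + "\n")
    sidecar = Path(sidecar) if sidecar else path.with_suffix(".json")
    sidecar.write_text(json.dumps({
        "tr_seconds": ts.tr_seconds,
        "subject_id": ts.subject_id,
        "session": ts.session,
        "lesion_side": ts.lesion_side,
    }, indent=1))


def write_variability(profile: VariabilityProfile, path,
                      config: dict | None = None, seed=None) -> None:
    """Per-region V as TSV with a provenance header comment."""
    path = Path(path)
    prov = provenance(config, seed)
    with path.open("w") as fh:
        fh.write("# " + json.dumps(prov) + "\n")
        fh.write("# window_lengths: "
                 + ",".join(str(L) for L in profile.window_lengths_used) + "\n")
        fh.write("region\tV\n")
        for label, v in zip(profile.region_labels, profile.values):
            fh.write(f"{label}\t{v:.9g}\n")


# ---------------------------------------------------------------------------
# EEG
# ---------------------------------------------------------------------------


def read_eeg(path, sidecar=None) -> EpochedEEG:
    """Read epoched EEG from a delimited matrix + JSON sidecar, or EDF.

    The delimited format holds channels x samples of the continuous
    recording; the sidecar supplies ``rate_hz``, ``channel_labels``,
    ``lesion_side``, ``trial_onsets`` (seconds, one per trial) and
    ``segment_durations`` {"task": s, "rest": s}, with the rest segment
    taken immediately before each onset.
    """
    path = Path(path)
    if path.suffix.lower() == ".edf":
        return _read_edf(path, sidecar)
    sidecar = Path(sidecar) if sidecar else path.with_suffix(".json")
    meta = json.loads(Path(sidecar).read_text())
    raw = np.loadtxt(path, delimiter="\t")
    labels = tuple(meta["channel_labels"])
    unknown = set(labels) - set(MONTAGE_16)
    if unknown:
        raise ValueError(
            f"unknown channel labels {sorted(unknown)}; montage is {MONTAGE_16}"
        )
    rate = float(meta["rate_hz"])
    dur = meta["segment_durations"]
    n_task = int(round(dur["task"] * rate))
    n_rest = int(round(dur["rest"] * rate))
    trials = []
    for onset in meta["trial_onsets"]:
        start = int(round(onset * rate))
        if start - n_rest < 0 or start + n_task > raw.shape[1]:
            raise ValueError(f"trial at {onset}s extends beyond the recording")
        trials.append((raw[:, start:start + n_task],
                       raw[:, start - n_rest:start]))
    return EpochedEEG(
        channel_labels=labels,
        sampling_rate=rate,
        trials=trials,
        lesion_side=str(meta.get("lesion_side", "R")),
        session_ids=meta.get("session_ids"),
    )


def _read_edf(path, sidecar=None) -> EpochedEEG:
    try:
        import mne
    except ImportError as err:  # pragma: no cover
        raise ImportError("EDF input requires the 'mne' package") from err
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    labels = tuple(raw.ch_names)
    unknown = set(labels) - set(MONTAGE_16)
    if unknown:
        raise ValueError(
            f"unknown channel labels {sorted(unknown)}; montage is {MONTAGE_16}"
        )
    if sidecar is None:
        raise ValueError("EDF input still needs the JSON sidecar for trial timing")
    meta = json.loads(Path(sidecar).read_text())
    rate = float(raw.info["sfreq"])
    data = raw.get_data()
    dur = meta["segment_durations"]
    n_task = int(round(dur["task"] * rate))
    n_rest = int(round(dur["rest"] * rate))
    trials = [
        (data[:, int(round(o * rate)):int(round(o * rate)) + n_task],
         data[:, int(round(o * rate)) - n_rest:int(round(o * rate))])
        for o in meta["trial_onsets"]
    ]
    return EpochedEEG(
        channel_labels=labels, sampling_rate=rate, trials=trials,
        lesion_side=str(meta.get("lesion_side", "R")),
        session_ids=meta.get("session_ids"),
    )


def write_eeg(epochs: EpochedEEG, path, sidecar=None) -> None:
    """Write epoched EEG back to the delimited + sidecar format.

    Segments are concatenated as rest-then-task per trial so that
    ``read_eeg`` recovers them from the stored onsets.
    """
    path = Path(path)
    rate = epochs.sampling_rate
    chunks, onsets = [], []
    cursor = 0
    n_task = epochs.trials[0][0].shape[1]
    n_rest = epochs.trials[0][1].shape[1]
    for task, rest in epochs.trials:
        chunks.extend([rest, task])
        onsets.append((cursor + n_rest) / rate)
        cursor += n_rest + n_task
    np.savetxt(path, np.concatenate(chunks, axis=1), delimiter="\t", fmt="%.9g")
    sidecar = Path(sidecar) if sidecar else path.with_suffix(".json")
    sidecar.write_text(json.dumps({
        "rate_hz": rate,
        "channel_labels": list(epochs.channel_labels),
        "lesion_side": epochs.lesion_side,
        "trial_onsets": onsets,
        "segment_durations": {"task": n_task / rate, "rest": n_rest / rate},
        "session_ids": epochs.session_ids,
    }, indent=1))


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------


def write_report(results: dict, path, config: dict | None = None, seed=None) -> None:
    """Flat JSON report with an embedded provenance block."""
    path = Path(path)
    payload = {"provenance": provenance(config, seed), "results": results}
    path.write_text(json.dumps(payload, indent=1, default=_json_default))


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"cannot serialise {type(obj).__name__}")
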