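"""Readers and writers for recordings, epochs and score tables.

Readers for the two clinical formats (EDF, BrainVision) go through MNE.
Writers are minimal but standard-conforming: EDF with 16-bit samples and
one data record per second, and BrainVision with IEEE float32 multiplexed
data.  A plain-text fixture format (TSV data + JSON sidecar + annotations
TSV) is provided for fully text-based round trips.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError
from .types import ANNOTATION_COLUMNS, EpochSet, RawRecording

SCORE_COLUMNS = [
    "subject", "epoch", "session_order", "condition", "channel",
    "measure", "raw", "surrogate", "normalized", "degenerate_flag",
]


# ---------------------------------------------------------------- annotations

def write_annotations_tsv(annotations: pd.DataFrame, path) -> None:
    annotations[ANNOTATION_COLUMNS].to_csv(path, sep="\t", index=False)


def read_annotations_tsv(path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", dtype={"condition": str})
    missing = set(ANNOTATION_COLUMNS) - set(ann.columns)
    if missing:
        raise ParseError(f"annotation file {path} missing columns {sorted(missing)}")
    return ann


# ------------------------------------------------------------------------ EDF

def _edf_field(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(recording: RawRecording, path) -> Path:
    """Write a recording to EDF (16-bit, one data record per second).

    The sampling rate must be an integer; trailing samples that do not fill
    a whole record are dropped.  Annotations are written to a companion
    ``<stem>_annotations.tsv`` next to the EDF file.
    """
    path = Path(path)
    fs = recording.sfreq
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    n_ch = recording.n_channels
    n_records = recording.n_samples // fs
    data = recording.data[:, : n_records * fs]

    phys_max = np.maximum(np.abs(data).max(axis=1), 1e-6)
    dig_max = 32767
    scaled = np.rint(data / phys_max[:, None] * dig_max).astype("<i2")

    header = b""
    header += _edf_field("0", 8)
    header += _edf_field("X X X X", 80)
    header += _edf_field("Startdate X X X X", 80)
    header += _edf_field("01.01.00", 8)
    header += _edf_field("00.00.00", 8)
    header += _edf_field(256 * (1 + n_ch), 8)
    header += _edf_field("", 44)
    header += _edf_field(n_records, 8)
    header += _edf_field(1, 8)
    header += _edf_field(n_ch, 4)
    for get, width in [
        (lambda i: recording.ch_names[i], 16),
        (lambda i: "", 80),
        (lambda i: "uV", 8),
        (lambda i: f"{-phys_max[i]:.6g}"[:8], 8),
        (lambda i: f"{phys_max[i]:.6g}"[:8], 8),
        (lambda i: -dig_max, 8),
        (lambda i: dig_max, 8),
        (lambda i: "", 80),
        (lambda i: fs, 8),
        (lambda i: "", 32),
    ]:
        for i in range(n_ch):
            header += _edf_field(get(i), width)

    with open(path, "wb") as fh:
        fh.write(header)
        for rec in range(n_records):
            block = scaled[:, rec * fs : (rec + 1) * fs]
            fh.write(block.tobytes())
    if recording.annotations is not None:
        write_annotations_tsv(
            recording.annotations, path.with_name(path.stem + "_annotations.tsv")
        )
    return path


# ----------------------------------------------------------------- BrainVision

def write_brainvision(recording: RawRecording, basepath) -> Path:
    """Write a BrainVision triplet (.vhdr/.vmrk/.eeg, IEEE float32, µV)."""
    base = Path(basepath)
    vhdr, vmrk, eeg = (base.with_suffix(s) for s in (".vhdr", ".vmrk", ".eeg"))
    interval_us = 1e6 / recording.sfreq
    lines = [
        "Brain Vision Data Exchange Header File Version 1.0",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={eeg.name}",
        f"MarkerFile={vmrk.name}",
        "DataFormat=BINARY",
        "DataOrientation=MULTIPLEXED",
        f"NumberOfChannels={recording.n_channels}",
        f"SamplingInterval={interval_us:.6f}",
        "[Binary Infos]",
        "BinaryFormat=IEEE_FLOAT_32",
        "[Channel Infos]",
    ]
    for i, name in enumerate(recording.ch_names, start=1):
        lines.append(f"Ch{i}={name},,1,µV")
    vhdr.write_text("\n".join(lines) + "\n", encoding="utf-8")
    vmrk.write_text(
        "\n".join(
            [
                "Brain Vision Data Exchange Marker File, Version 1.0",
                "[Common Infos]",
                "Codepage=UTF-8",
                f"DataFile={eeg.name}",
                "[Marker Infos]",
                "Mk1=New Segment,,1,1,0,00000000000000000000",
            ]
        )
        + "\n",
        encoding="utf-8",
    )
    recording.data.astype("<f4").T.tofile(eeg)  # multiplexed: sample-major
    if recording.annotations is not None:
        write_annotations_tsv(
            recording.annotations, base.with_name(base.stem + "_annotations.tsv")
        )
    return vhdr


# --------------------------------------------------------------- mne readers

def _from_mne_raw(raw, annotations: pd.DataFrame | None) -> RawRecording:
    import mne

    data = raw.get_data()
    types = raw.get_channel_types()
    scale = np.array([1e6 if t in ("eeg", "eog", "ecg", "emg") else 1.0 for t in types])
    return RawRecording(
        data=data * scale[:, None],
        sfreq=float(raw.info["sfreq"]),
        ch_names=list(raw.ch_names),
        annotations=annotations,
        meta={"source": "mne"},
    )


def _sidecar_annotations(path: Path) -> pd.DataFrame | None:
    side = path.with_name(path.stem + "_annotations.tsv")
    if side.exists():
        return read_annotations_tsv(side)
    return None


def read_edf(path) -> RawRecording:
    import mne

    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    return _from_mne_raw(raw, _sidecar_annotations(path))


def read_brainvision(path) -> RawRecording:
    import mne

    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    # fail with a clear message when the declared data file is absent
    for line in path.read_text(encoding="utf-8", errors="replace").splitlines():
        if line.startswith("DataFile="):
            datafile = path.with_name(line.split("=", 1)[1].strip())
            if not datafile.exists():
                raise ParseError(f"missing BrainVision data file: {datafile}")
    raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
    return _from_mne_raw(raw, _sidecar_annotations(path))


# ------------------------------------------------------------- fixture format

def write_fixture(recording: RawRecording, basepath) -> Path:
    """Column-oriented TSV (one column per channel) + JSON sidecar."""
    base = Path(basepath)
    df = pd.DataFrame(recording.data.T, columns=recording.ch_names)
    df.to_csv(base.with_suffix(".tsv"), sep="\t", index=False, float_format="%.6f")
    sidecar = {
        "sampling_rate_hz": recording.sfreq,
        "ch_names": recording.ch_names,
        "units": "uV",
        "positions": None
        if recording.positions is None
        else recording.positions.tolist(),
    }
    base.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    if recording.annotations is not None:
        write_annotations_tsv(
            recording.annotations, base.with_name(base.stem + "_annotations.tsv")
        )
    return base.with_suffix(".tsv")


def read_fixture(basepath) -> RawRecording:
    base = Path(basepath)
    tsv, js = base.with_suffix(".tsv"), base.with_suffix(".json")
    if not js.exists():
        raise ParseError(f"missing JSON sidecar: {js}")
    sidecar = json.loads(js.read_text())
    df = pd.read_csv(tsv, sep="\t")
    ann_path = base.with_name(base.stem + "_annotations.tsv")
    return RawRecording(
        data=df.to_numpy().T,
        sfreq=float(sidecar["sampling_rate_hz"]),
        ch_names=list(sidecar["ch_names"]),
        annotations=read_annotations_tsv(ann_path) if ann_path.exists() else None,
        positions=None
        if sidecar.get("positions") is None
        else np.asarray(sidecar["positions"]),
    )


# ------------------------------------------------------------------- epochs

def write_epochs(epochs: EpochSet, basepath) -> Path:
    """EpochSet as long TSV (one row per epoch x channel) + JSON sidecar."""
    base = Path(basepath)
    n_samp = epochs.data.shape[2]
    rows = []
    for e in range(epochs.n_epochs):
        for c, name in enumerate(epochs.ch_names):
            rows.append(
                [e, name, *np.round(epochs.data[e, c], 6)]
            )
    cols = ["epoch", "channel", *[f"s{i}" for i in range(n_samp)]]
    pd.DataFrame(rows, columns=cols).to_csv(base.with_suffix(".tsv"), sep="\t", index=False)
    meta = {
        "sampling_rate_hz": epochs.sfreq,
        "epoch_length_s": epochs.epoch_length_s,
        "ch_names": epochs.ch_names,
        "labels": epochs.labels.to_dict(orient="list"),
        "rejected": epochs.rejected.astype(int).tolist(),
        "positions": None if epochs.positions is None else epochs.positions.tolist(),
    }
    base.with_suffix(".json").write_text(json.dumps(meta))
    return base.with_suffix(".tsv")


def read_epochs(basepath) -> EpochSet:
    base = Path(basepath)
    meta = json.loads(base.with_suffix(".json").read_text())
    df = pd.read_csv(base.with_suffix(".tsv"), sep="\t")
    ch_names = meta["ch_names"]
    n_ep = df["epoch"].nunique()
    n_samp = len([c for c in df.columns if c.startswith("s")])
    data = np.empty((n_ep, len(ch_names), n_samp))
    sample_cols = [f"s{i}" for i in range(n_samp)]
    for (e, ch), row in df.set_index(["epoch", "channel"]).iterrows():
        data[e, ch_names.index(ch)] = row[sample_cols].to_numpy()
    return EpochSet(
        data=data,
        sfreq=meta["sampling_rate_hz"],
        epoch_length_s=meta["epoch_length_s"],
        labels=pd.DataFrame(meta["labels"]),
        ch_names=ch_names,
        rejected=np.asarray(meta["rejected"], dtype=bool),
        positions=None
        if meta.get("positions") is None
        else np.asarray(meta["positions"]),
    )


def write_rejection_report(epochs: EpochSet, path) -> None:
    report = epochs.labels.copy()
    report["rejected"] = epochs.rejected.astype(int)
    report.to_csv(path, sep="\t", index=False)


# -------------------------------------------------------------------- scores

def write_scores(scores: pd.DataFrame, path) -> None:
    scores[SCORE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_scores(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"condition": str, "channel": str})
    missing = set(SCORE_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"score table missing columns {sorted(missing)}")
    return df


def load_recording(path) -> RawRecording:
    """Dispatch on extension: .edf, .vhdr, or the TSV/JSON fixture format."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".edf":
        return read_edf(path)
    if suffix == ".vhdr":
        return read_brainvision(path)
    if suffix in (".tsv", ".json", ""):
        return read_fixture(path.with_suffix(""))
    raise ParseError(f"unsupported recording format: {path.name}")
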