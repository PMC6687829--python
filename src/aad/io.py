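"""File I/O: the HDF5 session container, EEG readers (EDF, BrainVision),
WAV audio, and part-annotation tables.

Session container layout (all datasets float64 for bit-exact round-trips)::

    /eeg/data        (n_channels, n_samples)
    /eeg/fs          scalar
    /eeg/labels      (n_channels,) strings
    /eeg/positions   (n_channels, 2), optional
    /audio/<talker>/envelope   (n_samples,)
    /audio/<talker>/fs         scalar
    /parts/start     (n_parts,) sample indices
    /parts/stop      (n_parts,) exclusive sample indices
    /parts/attended  (n_parts,) talker-id strings
    attrs: subject_id

The EDF and BrainVision readers are minimal, self-contained parsers for the
uncompressed variants of those formats (16-bit EDF records; BrainVision
binary multiplexed INT_16 / IEEE_FLOAT_32).  Matching writers are provided
mainly to support round-trip testing.
"""

from __future__ import annotations

import configparser
import io as _io
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from scipy.io import wavfile

from .containers import Envelope, EEGRecording, Session

# ---------------------------------------------------------------------------
# HDF5 session container
# ---------------------------------------------------------------------------

def save_session(session: Session, path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["subject_id"] = session.subject_id
        g = f.create_group("eeg")
        g.create_dataset("data", data=session.eeg.data)
        g.create_dataset("fs", data=float(session.eeg.fs))
        g.create_dataset("labels",
                         data=np.array(session.eeg.channel_labels, dtype="S"))
        if session.eeg.channel_positions is not None:
            g.create_dataset("positions", data=session.eeg.channel_positions)
        a = f.create_group("audio")
        for talker, env in session.envelopes.items():
            t = a.create_group(talker)
            t.create_dataset("envelope", data=env.values)
            t.create_dataset("fs", data=float(env.fs))
        p = f.create_group("parts")
        starts = [s for s, _, _ in session.parts_index]
        stops = [e for _, e, _ in session.parts_index]
        att = [a_ for _, _, a_ in session.parts_index]
        p.create_dataset("start", data=np.array(starts, dtype=np.int64))
        p.create_dataset("stop", data=np.array(stops, dtype=np.int64))
        p.create_dataset("attended", data=np.array(att, dtype="S"))


def load_session(path) -> Session:
    with h5py.File(path, "r") as f:
        labels = [l.decode() for l in f["eeg/labels"][()]]
        positions = f["eeg/positions"][()] if "positions" in f["eeg"] else None
        eeg = EEGRecording(
            data=f["eeg/data"][()], fs=float(f["eeg/fs"][()]),
            channel_labels=labels, channel_positions=positions,
        )
        envelopes = {}
        for talker in f["audio"]:
            envelopes[talker] = Envelope(
                f[f"audio/{talker}/envelope"][()], talker_id=talker,
                fs=float(f[f"audio/{talker}/fs"][()]),
            )
        parts_index = [
            (int(s), int(e), a.decode())
            for s, e, a in zip(f["parts/start"][()], f["parts/stop"][()],
                               f["parts/attended"][()])
        ]
        return Session(
            subject_id=str(f.attrs["subject_id"]), eeg=eeg,
            envelopes=envelopes, parts_index=parts_index,
        )


# ---------------------------------------------------------------------------
# WAV audio
# ---------------------------------------------------------------------------

def read_wav(path) -> tuple[np.ndarray, float]:
    """Mono audio as float in [-1, 1] plus its sampling rate."""
    fs, data = wavfile.read(path)
    data = np.asarray(data)
    if data.ndim > 1:
        data = data[:, 0]
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(float) / float(np.iinfo(data.dtype).max)
    else:
        data = data.astype(float)
    return data, float(fs)


# ---------------------------------------------------------------------------
# part annotations
# ---------------------------------------------------------------------------

def read_parts_table(path) -> pd.DataFrame:
    """TSV with columns start, stop (seconds) and attended (talker id)."""
    df = pd.read_csv(path, sep="\t")
    required = {"start", "stop", "attended"}
    if not required.issubset(df.columns):
        raise ValueError(f"parts table needs columns {sorted(required)}")
    return df


# ---------------------------------------------------------------------------
# EDF (16-bit continuous records)
# ---------------------------------------------------------------------------

def read_edf(path) -> EEGRecording:
    """Read a continuous 16-bit EDF recording (all signals, one rate)."""
    with open(path, "rb") as f:
        hdr = f.read(256)
        n_records = int(hdr[236:244].decode().strip())
        record_dur = float(hdr[244:252].decode().strip())
        n_signals = int(hdr[252:256].decode().strip())
        sig_hdr = f.read(256 * n_signals)

        # fields are stored per-field for all signals consecutively; offsets
        # are cumulative widths: label 16, transducer 80, dim 8, phys_min 8,
        # phys_max 8, dig_min 8, dig_max 8, prefilter 80, samples/record 8
        def nfield(byte_off, width):
            return [
                sig_hdr[byte_off * n_signals + i * width:
                        byte_off * n_signals + (i + 1) * width].decode().strip()
                for i in range(n_signals)
            ]

        labels = nfield(0, 16)
        off = 16 + 80 + 8
        phys_min = np.array([float(v) for v in nfield(off, 8)])
        phys_max = np.array([float(v) for v in nfield(off + 8, 8)])
        dig_min = np.array([float(v) for v in nfield(off + 16, 8)])
        dig_max = np.array([float(v) for v in nfield(off + 24, 8)])
        spr = [int(v) for v in nfield(off + 32 + 80, 8)]
        if len(set(spr)) != 1:
            raise ValueError("mixed per-signal sampling rates are unsupported")
        spr0 = spr[0]
        raw = np.frombuffer(f.read(), dtype="<i2")
    expected = n_records * n_signals * spr0
    raw = raw[:expected].reshape(n_records, n_signals, spr0)
    data = raw.transpose(1, 0, 2).reshape(n_signals, -1).astype(float)
    gain = (phys_max - phys_min) / (dig_max - dig_min)
    data = (data - dig_min[:, None]) * gain[:, None] + phys_min[:, None]
    fs = spr0 / record_dur
    return EEGRecording(data=data, fs=fs, channel_labels=labels)


def write_edf(rec: EEGRecording, path, record_seconds: float = 1.0) -> None:
    """Write a minimal continuous 16-bit EDF file (testing/interchange)."""
    spr = int(round(rec.fs * record_seconds))
    n_records = rec.n_samples // spr
    if n_records < 1:
        raise ValueError("recording shorter than one EDF record")
    data = rec.data[:, : n_records * spr]
    phys_min = data.min(axis=1)
    phys_max = data.max(axis=1)
    span = np.where(phys_max > phys_min, phys_max - phys_min, 1.0)
    dig = np.round((data - phys_min[:, None]) / span[:, None]
                   * 65535.0 - 32768.0).astype("<i2")
    n_sig = rec.n_channels

    def pad(v, w):
        s = str(v)[:w]
        return s.ljust(w).encode("ascii")

    hdr = _io.BytesIO()
    hdr.write(pad("0", 8))          # version
    hdr.write(pad("X", 80))         # patient
    hdr.write(pad("X", 80))         # recording
    hdr.write(pad("01.01.00", 8))
    hdr.write(pad("00.00.00", 8))
    hdr.write(pad(256 * (1 + n_sig), 8))
    hdr.write(pad("", 44))
    hdr.write(pad(n_records, 8))
    hdr.write(pad(record_seconds, 8))
    hdr.write(pad(n_sig, 4))
    for width, values in (
        (16, rec.channel_labels),
        (80, [""] * n_sig),
        (8, ["uV"] * n_sig),
        (8, [f"{v:.6g}" for v in phys_min]),
        (8, [f"{v:.6g}" for v in phys_min + span]),
        (8, ["-32768"] * n_sig),
        (8, ["32767"] * n_sig),
        (80, [""] * n_sig),
        (8, [spr] * n_sig),
        (32, [""] * n_sig),
    ):
        for v in values:
            hdr.write(pad(v, width))
    with open(path, "wb") as f:
        f.write(hdr.getvalue())
        blocks = dig.reshape(n_sig, n_records, spr).transpose(1, 0, 2)
        f.write(np.ascontiguousarray(blocks).tobytes())


# ---------------------------------------------------------------------------
# BrainVision (.vhdr + binary .eeg)
# ---------------------------------------------------------------------------

def read_brainvision(vhdr_path) -> EEGRecording:
    """Read a BrainVision header + multiplexed binary data file."""
    vhdr_path = Path(vhdr_path)
    cp = configparser.ConfigParser()
    text = vhdr_path.read_text()
    # strip the signature line; the rest is INI-formatted
    cp.read_string("\n".join(l for l in text.splitlines()
                             if not l.startswith("Brain Vision")))
    common = cp["Common Infos"]
    if common.get("DataFormat", "BINARY").upper() != "BINARY":
        raise ValueError("only BINARY BrainVision data is supported")
    if common.get("DataOrientation", "MULTIPLEXED").upper() != "MULTIPLEXED":
        raise ValueError("only MULTIPLEXED orientation is supported")
    n_ch = int(common["NumberOfChannels"])
    fs = 1e6 / float(common["SamplingInterval"])
    fmt = cp["Binary Infos"]["BinaryFormat"].upper()
    dtype = {"IEEE_FLOAT_32": "<f4", "INT_16": "<i2"}.get(fmt)
    if dtype is None:
        raise ValueError(f"unsupported BinaryFormat {fmt!r}")
    labels, resolutions = [], []
    for i in range(1, n_ch + 1):
        parts = cp["Channel Infos"][f"Ch{i}"].split(",")
        labels.append(parts[0])
        res = parts[2] if len(parts) > 2 and parts[2] else "1"
        resolutions.append(float(res))
    data_file = vhdr_path.parent / common["DataFile"]
    raw = np.fromfile(data_file, dtype=dtype)
    raw = raw[: (raw.size // n_ch) * n_ch].reshape(-1, n_ch).T.astype(float)
    raw *= np.array(resolutions)[:, None]
    return EEGRecording(data=raw, fs=fs, channel_labels=labels)


def write_brainvision(rec: EEGRecording, vhdr_path) -> None:
    """Write a minimal BrainVision pair (IEEE float, multiplexed)."""
    vhdr_path = Path(vhdr_path)
    data_name = vhdr_path.with_suffix(".eeg").name
    lines = [
        "Brain Vision Data Exchange Header File Version 1.0",
        "[Common Infos]",
        "DataFormat=BINARY",
        "DataOrientation=MULTIPLEXED",
        f"DataFile={data_name}",
        f"NumberOfChannels={rec.n_channels}",
        f"SamplingInterval={1e6 / rec.fs:.6f}",
        "[Binary Infos]",
        "BinaryFormat=IEEE_FLOAT_32",
        "[Channel Infos]",
    ]
    for i, label in enumerate(rec.channel_labels, start=1):
        lines.append(f"Ch{i}={label},,1,uV")
    vhdr_path.write_text("\n".join(lines) + "\n")
    rec.data.T.astype("<f4").tofile(vhdr_path.parent / data_name)
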