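"""Core in-memory containers for two-talker attention-decoding sessions.

A *session* is one continuous recording from one subject: multichannel EEG
plus the broadband envelopes of the two competing speech streams, all on a
common 100-Hz timeline.  A *part* is one uninterrupted listening interval
(the unit of cross-validation); parts are stored as (start, stop) sample
ranges into the session timeline together with the attended talker's id.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

FS_TARGET = 100.0  #: common analysis sampling rate, Hz


@dataclass
class EEGRecording:
    """Multichannel EEG: ``data`` is (n_channels, n_samples) in microvolts."""

    data: np.ndarray
    fs: float
    channel_labels: list[str]
    channel_positions: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("EEG data must be 2-D (channels x samples)")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {self.data.shape[0]} data rows"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("EEG data contains NaN/Inf")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def copy_with(self, data: np.ndarray, fs: float | None = None) -> "EEGRecording":
        return EEGRecording(
            data=data,
            fs=self.fs if fs is None else fs,
            channel_labels=list(self.channel_labels),
            channel_positions=None
            if self.channel_positions is None
            else np.array(self.channel_positions),
        )


@dataclass
class Envelope:
    """Broadband speech envelope at 100 Hz; non-negative before scaling."""

    values: np.ndarray
    talker_id: str
    fs: float = FS_TARGET

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if not np.all(np.isfinite(self.values)):
            raise ValueError("envelope contains NaN/Inf")

    def __len__(self) -> int:
        return self.values.size


@dataclass
class Part:
    """One uninterrupted listening interval, aligned at 100 Hz."""

    part_id: str
    subject_id: str
    eeg: EEGRecording
    env_attended: Envelope
    env_unattended: Envelope
    attended_talker_id: str

    def __post_init__(self) -> None:
        n = self.eeg.n_samples
        if len(self.env_attended) != n or len(self.env_unattended) != n:
            raise ValueError("EEG and envelopes must have equal sample counts")
        if self.eeg.fs != FS_TARGET:
            raise ValueError("parts must be resampled to 100 Hz")
        ids = {self.env_attended.talker_id, self.env_unattended.talker_id}
        if self.attended_talker_id not in ids:
            raise ValueError("attended_talker_id matches neither envelope")
        if self.attended_talker_id != self.env_attended.talker_id:
            raise ValueError("attended_talker_id must match env_attended")

    @property
    def n_samples(self) -> int:
        return self.eeg.n_samples


@dataclass
class Session:
    """Continuous subject recording with part annotations.

    ``envelopes`` maps talker id -> full-session Envelope; ``parts_index``
    rows are (start, stop, attended_talker_id) with stop exclusive, in
    samples on the 100-Hz timeline.
    """

    subject_id: str
    eeg: EEGRecording
    envelopes: dict[str, Envelope]
    parts_index: list[tuple[int, int, str]]
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.envelopes) != 2:
            raise ValueError("a session needs exactly two talkers")
        n = self.eeg.n_samples
        for env in self.envelopes.values():
            if len(env) != n:
                raise ValueError("envelope/EEG length mismatch")
        for start, stop, att in self.parts_index:
            if not (0 <= start < stop <= n):
                raise ValueError(f"part range ({start}, {stop}) outside session")
            if att not in self.envelopes:
                raise ValueError(f"attended id {att!r} is not a session talker")

    @property
    def talker_ids(self) -> list[str]:
        return list(self.envelopes)

    def iter_parts(self):
        """Yield :class:`Part` objects cut from the continuous timeline."""
        for k, (start, stop, att) in enumerate(self.parts_index):
            other = next(t for t in self.envelopes if t != att)
            eeg = self.eeg.copy_with(self.eeg.data[:, start:stop])
            yield Part(
                part_id=f"part{k:03d}",
                subject_id=self.subject_id,
                eeg=eeg,
                env_attended=Envelope(
                    self.envelopes[att].values[start:stop], talker_id=att
                ),
                env_unattended=Envelope(
                    self.envelopes[other].values[start:stop], talker_id=other
                ),
                attended_talker_id=att,
            )

    @property
    def parts(self) -> list[Part]:
        return list(self.iter_parts())
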