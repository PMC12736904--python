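"""Reading EEG recordings and cutting fixed-length analysis windows.

Supported on-disk formats are delimited text (one column per channel,
optional header row of 10-20 channel labels), EDF/EDF+, and continuous
EEGLAB ``.set`` files laid out as a BIDS EEG dataset
(``sub-*/eeg/*_eeg.set``).  No filtering, re-referencing or artifact
rejection happens here: windows are cut from the raw samples exactly as
stored.

Amplitudes are kept in microvolts whenever the source format declares
units (EDF and EEGLAB files do; plain text does not, in which case values
pass through unscaled and a warning is logged).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: default analysis window: 40 s at 500 Hz
DEFAULT_WINDOW_SAMPLES = 20_000
#: sampling rate the pipeline expects; a mismatch is only a warning
DEFAULT_FS_EXPECTED = 500.0

_BIDS_SUBJECT_RE = re.compile(r"(sub-[A-Za-z0-9]+)")


class SignalFormatError(ValueError):
    """A file could not be parsed in its declared format."""


class EmptyRecordingError(ValueError):
    """A parsed file contained no channels."""


@dataclass
class Recording:
    """A multichannel EEG recording.

    Parameters
    ----------
    channels
        Channel labels (10-20 system names such as ``Fp1`` ... ``O2``).
    data
        Array of shape ``(n_channels, n_samples)`` in microvolts (or raw
        units for unit-less sources).
    fs
        Sampling rate in Hz.
    subject_id
        Opaque subject identifier (e.g. a BIDS ``sub-0XX`` label).
    group_label
        Optional diagnostic class (``AD`` | ``FTD`` | ``HC``).
    """

    channels: list[str]
    data: np.ndarray
    fs: float
    subject_id: str = ""
    group_label: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channels):
            raise ValueError(
                f"data shape {self.data.shape} inconsistent with "
                f"{len(self.channels)} channel labels"
            )
        if len(self.channels) == 0:
            raise EmptyRecordingError("recording has zero channels")
        if self.data.shape[1] < 2:
            raise ValueError("channels must hold at least 2 samples")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def channel_index(self, channel: str) -> int:
        try:
            return self.channels.index(channel)
        except ValueError:
            raise KeyError(
                f"channel {channel!r} not in recording "
                f"(available: {', '.join(self.channels)})"
            ) from None


@dataclass(frozen=True)
class Segment:
    """A finite, uniformly sampled amplitude series x_t, t = 0..n-1."""

    x: np.ndarray
    fs: float
    source: tuple[str, str, int] = field(default=("", "", 0))

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        object.__setattr__(self, "x", x)
        if x.ndim != 1 or x.size < 2:
            raise ValueError("a segment needs a 1-D series of length >= 2")
        if not np.all(np.isfinite(x)):
            raise ValueError("segment contains non-finite samples")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")

    def __len__(self) -> int:
        return self.x.size


def _subject_from_path(path: Path) -> str:
    """Extract a BIDS subject label (``sub-XXX``) from any path component."""
    m = _BIDS_SUBJECT_RE.search(str(path))
    return m.group(1) if m else path.stem


def _load_csv(path: Path) -> Recording:
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    try:
        head = pd.read_csv(path, sep=sep, nrows=1, header=None)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise SignalFormatError(f"could not parse {path} as delimited text: {exc}") from exc
    has_header = any(not _is_number(v) for v in head.iloc[0])
    try:
        frame = pd.read_csv(path, sep=sep, header=0 if has_header else None,
                            float_precision="round_trip")
        data = frame.to_numpy(dtype=float).T
    except (ValueError, TypeError) as exc:
        raise SignalFormatError(f"non-numeric sample values in {path}: {exc}") from exc
    if data.shape[0] == 0 or frame.shape[1] == 0:
        raise EmptyRecordingError(f"{path} contains no channels")
    channels = [str(c) for c in frame.columns] if has_header else [
        f"ch{i}" for i in range(data.shape[0])
    ]
    logger.warning(
        "%s: text files carry no unit declaration; amplitudes passed through unscaled",
        path.name,
    )
    return Recording(channels=channels, data=data, fs=DEFAULT_FS_EXPECTED,
                     subject_id=_subject_from_path(path))


def _is_number(v) -> bool:
    try:
        float(v)
        return True
    except (TypeError, ValueError):
        return False


def _load_edf(path: Path) -> Recording:
    import mne

    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:
        raise SignalFormatError(f"could not parse {path} as EDF: {exc}") from exc
    return _from_mne_raw(raw, path)


def _load_eeglab_set(path: Path) -> Recording:
    import mne

    try:
        raw = mne.io.read_raw_eeglab(path, preload=True, verbose="error")
    except TypeError as exc:
        # mne raises TypeError for epoched .set content read as raw
        raise SignalFormatError(
            f"{path} holds epoched EEGLAB data; only continuous recordings are supported"
        ) from exc
    except Exception as exc:
        raise SignalFormatError(f"could not parse {path} as an EEGLAB set: {exc}") from exc
    return _from_mne_raw(raw, path)


def _from_mne_raw(raw, path: Path) -> Recording:
    data = raw.get_data()  # volts for EEG channels
    if data.shape[0] == 0:
        raise EmptyRecordingError(f"{path} contains no channels")
    return Recording(
        channels=list(raw.ch_names),
        data=data * 1e6,  # V -> µV
        fs=float(raw.info["sfreq"]),
        subject_id=_subject_from_path(path),
    )


_LOADERS = {"csv": _load_csv, "edf": _load_edf, "eeglab_set": _load_eeglab_set}
_SUFFIX_FORMATS = {".csv": "csv", ".tsv": "csv", ".txt": "csv",
                   ".edf": "edf", ".set": "eeglab_set"}


def load_timeseries(path, format: str | None = None,
                    fs_expected: float | None = DEFAULT_FS_EXPECTED) -> Recording:
    """Load an EEG recording from ``path``.

    Parameters
    ----------
    path
        File to read.
    format
        One of ``csv``, ``edf``, ``eeglab_set``; inferred from the file
        suffix when omitted.
    fs_expected
        Sampling rate the pipeline is configured for; a mismatch with the
        file's declared rate logs a warning (pass ``None`` to skip the
        check).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        try:
            format = _SUFFIX_FORMATS[path.suffix.lower()]
        except KeyError:
            raise SignalFormatError(
                f"cannot infer format from suffix {path.suffix!r}; pass format="
            ) from None
    if format not in _LOADERS:
        raise ValueError(f"unknown format {format!r}; expected one of {sorted(_LOADERS)}")
    rec = _LOADERS[format](path)
    if fs_expected is not None and abs(rec.fs - fs_expected) > 1e-9:
        logger.warning(
            "%s: sampling rate %g Hz differs from expected %g Hz",
            path.name, rec.fs, fs_expected,
        )
    return rec


def write_csv(recording: Recording, path) -> None:
    """Write a recording as one column per channel with a header row.

    Values are formatted with :func:`repr`-level precision so that a
    reload reproduces the amplitudes bit-exactly.
    """
    frame = pd.DataFrame(recording.data.T, columns=recording.channels)
    frame.to_csv(path, index=False, float_format="%.17g")


def segment(recording: Recording, channel: str,
            window_samples: int = DEFAULT_WINDOW_SAMPLES,
            start: int = 0, window_index: int = 0) -> Segment:
    """Cut the half-open sample window ``[start, start + window_samples)``.

    The default window of 20,000 samples corresponds to 40 s at 500 Hz.
    """
    if window_samples < 2:
        raise ValueError("window_samples must be >= 2")
    if start < 0:
        raise ValueError("start must be >= 0")
    idx = recording.channel_index(channel)
    n = recording.n_samples
    if start + window_samples > n:
        raise ValueError(
            f"window [{start}, {start + window_samples}) exceeds channel "
            f"length {n}"
        )
    return Segment(
        x=recording.data[idx, start:start + window_samples].copy(),
        fs=recording.fs,
        source=(recording.subject_id, channel, window_index),
    )


def iter_segments(recording: Recording, channel: str,
                  window_samples: int = DEFAULT_WINDOW_SAMPLES):
    """Yield consecutive non-overlapping windows covering the channel."""
    n = recording.n_samples
    for w, start in enumerate(range(0, n - window_samples + 1, window_samples)):
        yield segment(recording, channel, window_samples, start, window_index=w)
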