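"""Shared fixtures: synthetic cohorts (feature-extracted once per session)
and writers for small on-disk EEG fixtures (EDF, EEGLAB SET)."""

from __future__ import annotations

import numpy as np
import pytest

from conect.dataset import LabeledDataset, feature_column
from conect.graph_features import extract_dataset
from conect.synthetic_data import easy_profiles, generate_cohort, geometry_cohort


@pytest.fixture(scope="session")
def easy_features() -> LabeledDataset:
    """15-feature table of the shipped easy 3-class cohort.

    10 subjects per class, 2 channels, 2,000-sample segments at 500 Hz.
    """
    cohort = generate_cohort(easy_profiles(), subjects_per_class=10,
                             channels=2, n=2000, seed=1)
    return extract_dataset(cohort)


@pytest.fixture(scope="session")
def geometry_features() -> LabeledDataset:
    """Feature table of the geometry cohort (time-reversal + sharpness)."""
    return extract_dataset(geometry_cohort(seed=0))


def random_feature_table(n_subjects_per_class: int, classes: tuple[str, ...],
                         seed: int, rows_per_subject: int = 2,
                         informative: dict[int, float] | None = None
                         ) -> LabeledDataset:
    """Pure-noise 15-feature table, optionally with class-shifted columns.

    ``informative`` maps 1-based feature indices to the per-class mean
    shift added as ``shift * class_index``.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    rows, labels, groups = [], [], []
    for ci, cls in enumerate(classes):
        for si in range(n_subjects_per_class):
            for _ in range(rows_per_subject):
                row = rng.normal(size=15)
                for idx, shift in (informative or {}).items():
                    row[idx - 1] += shift * ci
                rows.append(row)
                labels.append(cls)
                groups.append(f"{cls}-s{si}")
    X = pd.DataFrame(np.array(rows),
                     columns=[feature_column(i) for i in range(1, 16)])
    return LabeledDataset(X=X, labels=labels, groups=groups)


def write_minimal_edf(path, channels: list[str], data: np.ndarray,
                      fs: float) -> None:
    """Write a one-record EDF file (synthetic test fixture).

    ``data`` is (n_channels, n_samples) in µV; values are rounded to
    integers so the 16-bit digital/physical identity mapping is exact.
    """
    nch, nsamp = data.shape
    hdr = b"0" + b" " * 7
    hdr += ("synthetic".ljust(80)).encode()
    hdr += ("synthetic".ljust(80)).encode()
    hdr += b"01.01.20" + b"00.00.00"
    hdr += str(256 * (1 + nch)).ljust(8).encode()
    hdr += b" " * 44
    hdr += b"1".ljust(8)
    hdr += ("%g" % (nsamp / fs)).ljust(8).encode()
    hdr += str(nch).ljust(4).encode()

    def field(vals, width):
        return b"".join(str(v).ljust(width).encode() for v in vals)

    hdr += field(channels, 16)
    hdr += field(["EEG"] * nch, 80)
    hdr += field(["uV"] * nch, 8)
    hdr += field([-32768] * nch, 8) + field([32767] * nch, 8)  # physical
    hdr += field([-32768] * nch, 8) + field([32767] * nch, 8)  # digital
    hdr += field([""] * nch, 80)
    hdr += field([nsamp] * nch, 8)
    hdr += b" " * (32 * nch)
    assert len(hdr) == 256 * (1 + nch)
    with open(path, "wb") as fh:
        fh.write(hdr)
        fh.write(np.round(data).astype("<i2").tobytes())


def write_minimal_set(path, channels: list[str], data: np.ndarray,
                      fs: float) -> None:
    """Write a continuous EEGLAB .set file (synthetic test fixture)."""
    from scipy.io import savemat

    nch, nsamp = data.shape
    chanlocs = np.zeros((nch,), dtype=[("labels", "O"), ("X", "O"),
                                       ("Y", "O"), ("Z", "O")])
    for i, lab in enumerate(channels):
        chanlocs[i] = (lab, 0.0, 0.0, 0.0)
    eeg = dict(data=data.astype(np.float64), setname="synthetic",
               nbchan=float(nch), pnts=float(nsamp), trials=1.0,
               srate=float(fs), xmin=0.0, xmax=(nsamp - 1) / fs,
               chanlocs=chanlocs, icawinv=np.array([]),
               icasphere=np.array([]), icaweights=np.array([]),
               icaact=np.array([]), event=np.array([]),
               epoch=np.array([]), ref="Cz")
    savemat(path, dict(EEG=eeg), appendmat=False)
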