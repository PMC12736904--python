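"""Labeled synthetic EEG-like cohorts for exercising the full pipeline.

Each class profile is a sum of cosine oscillations plus AR(1) Gaussian
noise plus Poisson-placed transients.  Three transient families are
available: symmetric triangular spikes (sharp, high-curvature), wide
low-curvature bumps, and asymmetric sawtooth events (different rise and
decay times).  The three shipped "easy" profiles encode the qualitative
contrasts the geometry-aware features are designed to detect:

* ``HC`` — 10 Hz alpha with a 20 Hz harmonic, moderate noise, no spikes
  (rich but smooth geometry);
* ``AD`` — slowed 6 Hz oscillation with strongly autocorrelated (smooth)
  noise (reduced integration, smoother curvature dynamics);
* ``FTD`` — 10 Hz oscillation with sharp triangular transients
  (curvature discontinuities, sharper local transitions).

A second cohort (:func:`geometry_cohort`) is constructed so that the two
geometric indices each carry class signal that no classical descriptor
can see: two classes differ only by time reversal of asymmetric sawtooth
transients — invisible to every classical feature (all are computed from
the undirected graph view and absolute amplitude differences, hence
time-reversal invariant) but visible to WAII, the one direction-sensitive
feature — and a third class adds small sharp spikes whose curvature only
CBEFI resolves once per-subject nuisance jitter (oscillation frequency,
AR smoothness, variable wide bumps) scrambles the classical features.

The generator is a test harness, not a neural simulator: it does not
reproduce real EEG spectra, amplitude ranges, artifact structure or the
effect sizes of any clinical cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.signal import lfilter

from .dataset import SegmentCohort
from .signal_io import Segment

__all__ = [
    "ClassProfile",
    "generate_segment",
    "generate_cohort",
    "easy_profiles",
    "geometry_cohort",
]


@dataclass(frozen=True)
class ClassProfile:
    """Generative recipe for one class of EEG-like signals.

    Parameters
    ----------
    label
        Class name attached to generated segments.
    osc_freqs
        Cosine components as ``(frequency_hz, amplitude)`` pairs.
    ar_coeff
        AR(1) coefficient of the additive noise, in ``[0, 1)``; larger
        values give smoother, more autocorrelated noise.
    noise_sd
        Standard deviation of the AR(1) *innovations* (the stationary
        noise variance is ``noise_sd^2 / (1 - ar_coeff^2)``).
    spike_rate, spike_amp, spike_width
        Symmetric triangular spikes: expected events per second, peak
        amplitude, and half-width in samples (support ``2*width + 1``).
    bump_rate, bump_amp, bump_width
        A second triangular family meant for wide, low-curvature bumps
        (same kernel shape, independent Poisson placement).
    saw_rate, saw_amp, saw_rise, saw_decay
        Asymmetric sawtooth events: linear rise over ``saw_rise`` samples
        to ``saw_amp`` followed by a linear decay over ``saw_decay``
        samples.  Swapping rise and decay time-reverses the event shape.
    """

    label: str
    osc_freqs: tuple[tuple[float, float], ...] = ((10.0, 1.0),)
    ar_coeff: float = 0.0
    noise_sd: float = 0.0
    spike_rate: float = 0.0
    spike_amp: float = 0.0
    spike_width: int = 5
    bump_rate: float = 0.0
    bump_amp: float = 0.0
    bump_width: int = 25
    saw_rate: float = 0.0
    saw_amp: float = 0.0
    saw_rise: int = 6
    saw_decay: int = 20

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.ar_coeff < 1:
            raise ValueError("ar_coeff must lie in [0, 1)")
        if min(self.spike_rate, self.bump_rate, self.saw_rate) < 0:
            raise ValueError("event rates must be >= 0")
        if min(self.spike_width, self.bump_width, self.saw_rise,
               self.saw_decay) < 1:
            raise ValueError("event widths must be >= 1 sample")


def easy_profiles() -> list[ClassProfile]:
    """The shipped three-class cohort recipe (HC / AD / FTD contrasts)."""
    return [
        ClassProfile("HC", osc_freqs=((10.0, 1.0), (20.0, 0.3)),
                     ar_coeff=0.5, noise_sd=0.2),
        ClassProfile("AD", osc_freqs=((6.0, 1.0),),
                     ar_coeff=0.9, noise_sd=0.2),
        ClassProfile("FTD", osc_freqs=((10.0, 1.0),),
                     ar_coeff=0.5, noise_sd=0.2,
                     spike_rate=2.0, spike_amp=3.0, spike_width=5),
    ]


def profile_to_config(profile: ClassProfile) -> str:
    """Serialize a profile as plain ``key = value`` lines."""
    lines = [f"label = {profile.label}"]
    lines += [f"osc_freq = {f}:{a}" for f, a in profile.osc_freqs]
    for key in ("ar_coeff", "noise_sd", "spike_rate", "spike_amp",
                "spike_width", "bump_rate", "bump_amp", "bump_width",
                "saw_rate", "saw_amp", "saw_rise", "saw_decay"):
        lines.append(f"{key} = {getattr(profile, key)}")
    return "\n".join(lines) + "\n"


def profile_from_config(text: str) -> ClassProfile:
    """Parse the ``key = value`` format written by :func:`profile_to_config`."""
    kwargs: dict = {}
    freqs: list[tuple[float, float]] = []
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        key, _, value = (part.strip() for part in line.partition("="))
        if not _:
            raise ValueError(f"malformed profile line: {raw!r}")
        if key == "label":
            kwargs["label"] = value
        elif key == "osc_freq":
            f, _, a = value.partition(":")
            freqs.append((float(f), float(a)))
        elif key in ("spike_width", "bump_width", "saw_rise", "saw_decay"):
            kwargs[key] = int(value)
        else:
            kwargs[key] = float(value)
    if "label" not in kwargs:
        raise ValueError("profile config lacks a label")
    return ClassProfile(osc_freqs=tuple(freqs), **kwargs)


def _add_triangles(x: np.ndarray, rng: np.random.Generator, rate: float,
                   amp: float, width: int, fs: float) -> None:
    n = x.size
    n_events = rng.poisson(rate * n / fs)
    if n_events == 0:
        return
    centers = rng.integers(0, n, size=n_events)
    kernel = amp * (1.0 - np.abs(np.arange(-width, width + 1)) / (width + 1.0))
    for c in centers:
        lo = max(0, c - width)
        hi = min(n, c + width + 1)
        x[lo:hi] += kernel[lo - (c - width): hi - (c - width)]


def _add_sawtooths(x: np.ndarray, rng: np.random.Generator, rate: float,
                   amp: float, rise: int, decay: int, fs: float) -> None:
    n = x.size
    n_events = rng.poisson(rate * n / fs)
    if n_events == 0:
        return
    kernel = np.concatenate([
        amp * np.arange(1, rise + 1) / rise,
        amp * (1.0 - np.arange(1, decay + 1) / decay),
    ])
    for c in rng.integers(0, n, size=n_events):
        hi = min(n, c + kernel.size)
        x[c:hi] += kernel[:hi - c]


def generate_segment(profile: ClassProfile, n: int, fs: float,
                     seed: int) -> Segment:
    """Deterministic synthetic segment for ``(profile, n, fs, seed)``.

    The signal is the sum of the profile's cosine components, AR(1)
    Gaussian noise and its Poisson-placed transient families.
    """
    if n < 2:
        raise ValueError("a segment needs n >= 2 samples")
    rng = np.random.default_rng(seed)
    t = np.arange(n, dtype=float) / fs
    x = np.zeros(n)
    for freq, amp in profile.osc_freqs:
        x += amp * np.cos(2.0 * np.pi * freq * t)
    if profile.noise_sd > 0:
        innov = rng.normal(0.0, profile.noise_sd, size=n)
        x += lfilter([1.0], [1.0, -profile.ar_coeff], innov)
    if profile.spike_rate > 0 and profile.spike_amp != 0:
        _add_triangles(x, rng, profile.spike_rate, profile.spike_amp,
                       profile.spike_width, fs)
    if profile.bump_rate > 0 and profile.bump_amp != 0:
        _add_triangles(x, rng, profile.bump_rate, profile.bump_amp,
                       profile.bump_width, fs)
    if profile.saw_rate > 0 and profile.saw_amp != 0:
        _add_sawtooths(x, rng, profile.saw_rate, profile.saw_amp,
                       profile.saw_rise, profile.saw_decay, fs)
    return Segment(x=x, fs=fs, source=(f"synt-{profile.label}", "synthetic", seed))


def _subject_seed(master_seed: int, class_idx: int, subject_idx: int,
                  channel_idx: int) -> int:
    """Counter-based derivation so cohort subsets reproduce in isolation."""
    ss = np.random.SeedSequence([int(master_seed), class_idx, subject_idx,
                                 channel_idx])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def generate_cohort(profiles: Sequence[ClassProfile],
                    subjects_per_class: int, channels: int, n: int,
                    seed: int, fs: float = 500.0) -> SegmentCohort:
    """One segment per (subject, channel) for every class profile."""
    if len(profiles) < 2:
        raise ValueError("a cohort needs at least 2 class profiles")
    if subjects_per_class < 1:
        raise ValueError("subjects_per_class must be >= 1: an empty dataset "
                         "cannot be classified")
    if channels < 1:
        raise ValueError("channels must be >= 1")
    segments, labels, groups, chans = [], [], [], []
    for ci, profile in enumerate(profiles):
        for si in range(subjects_per_class):
            subject = f"{profile.label}-s{si:03d}"
            for ch in range(channels):
                seg_seed = _subject_seed(seed, ci, si, ch)
                seg = generate_segment(profile, n, fs, seg_seed)
                seg = Segment(x=seg.x, fs=fs, source=(subject, f"ch{ch}", 0))
                segments.append(seg)
                labels.append(profile.label)
                groups.append(subject)
                chans.append(f"ch{ch}")
    return SegmentCohort(segments=segments, labels=labels, groups=groups,
                         channel=chans)


#: class recipes of the geometry cohort: (label, saw rise, saw decay,
#: sharp-spike rate).  Classes 0 and 1 are exact time reversals of each
#: other's transients; class 2 repeats class 0 plus sharp spikes.
_GEOMETRY_CLASSES = (
    ("steep_rise", 6, 20, 0.0),
    ("steep_fall", 20, 6, 0.0),
    ("sharp", 6, 20, 6.0),
)


def geometry_cohort(subjects_per_class: int = 8, channels: int = 1,
                    n: int = 2000, seed: int = 0,
                    fs: float = 500.0) -> SegmentCohort:
    """Three classes separated only along the geometric feature axes.

    ``steep_rise`` and ``steep_fall`` carry the same sawtooth transients
    (12/s, amplitude 5) up to time reversal (rise/decay 6/20 vs 20/6
    samples), a contrast no time-reversal-invariant feature can detect;
    ``sharp`` repeats ``steep_rise`` and adds small narrow spikes (6/s,
    amplitude 3, half-width 1) whose curvature CBEFI resolves.  Every
    subject additionally draws nuisance parameters — oscillation
    frequency U(7, 13) Hz, AR coefficient U(0.45, 0.65), and wide bumps
    with rate U(1, 5)/s and amplitude U(3, 10) — from the same
    distributions in all classes, which scrambles the classical
    descriptors without touching the two geometric contrasts.
    """
    if subjects_per_class < 1:
        raise ValueError("subjects_per_class must be >= 1")
    segments, labels, groups, chans = [], [], [], []
    for ci, (label, rise, decay, spike_rate) in enumerate(_GEOMETRY_CLASSES):
        for si in range(subjects_per_class):
            nuisance = np.random.default_rng(
                np.random.SeedSequence([int(seed), 1000 + ci, si]))
            freq = nuisance.uniform(7.0, 13.0)
            ar = nuisance.uniform(0.45, 0.65)
            bump_rate = nuisance.uniform(1.0, 5.0)
            bump_amp = nuisance.uniform(3.0, 10.0)
            profile = ClassProfile(
                label, osc_freqs=((freq, 1.0),), ar_coeff=ar, noise_sd=0.2,
                spike_rate=spike_rate, spike_amp=3.0, spike_width=1,
                bump_rate=bump_rate, bump_amp=bump_amp, bump_width=25,
                saw_rate=12.0, saw_amp=5.0, saw_rise=rise, saw_decay=decay,
            )
            subject = f"{label}-s{si:03d}"
            for ch in range(channels):
                seg = generate_segment(profile, n, fs,
                                       _subject_seed(seed, ci, si, ch))
                segments.append(Segment(x=seg.x, fs=fs,
                                        source=(subject, f"ch{ch}", 0)))
                labels.append(label)
                groups.append(subject)
                chans.append(f"ch{ch}")
    return SegmentCohort(segments=segments, labels=labels, groups=groups,
                         channel=chans)
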