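"""Deterministic signal conditioning and epoching.

Cleaning follows the fully automatic rules used for naturalistic dual-EEG:
1-20 Hz zero-phase band-pass, robust (median) average reference,
correlation-based bad-channel interpolation (0.7 threshold), and rejection
of 1-s epochs in which >70 % of channels exceed mean power + 5 SD.
Epoching covers both the event-locked (-2.5..+2.5 s trials) and the
non-event-locked (per-look gaze-state segments) analysis families, plus
the 1:n condition count matching that keeps data amounts comparable.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import signal

from .simulate import DyadRecording, GazeEvent, _runs_of

__all__ = [
    "EpochSet",
    "StateSegmentSet",
    "bandpass_filter",
    "robust_average_reference",
    "interpolate_bad_channels",
    "reject_highpower_segments",
    "extract_event_epochs",
    "segment_by_gaze_state",
    "match_condition_counts",
    "preprocess_recording",
]


@dataclass
class EpochSet:
    """Event-locked trials: (n_trials, n_channels, n_samples) in µV.

    ``window`` is (t_start, t_end) in seconds relative to the onset;
    t = 0 maps to sample index ``round(-t_start * fs)``.
    """

    data: np.ndarray
    window: tuple
    fs: float
    events: list = field(default_factory=list)
    condition: str = ""
    channel_labels: Sequence[str] = ()

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("EpochSet data must be trials x channels x samples")
        expected = int(round((self.window[1] - self.window[0]) * self.fs))
        if self.data.shape[0] and self.data.shape[2] != expected:
            raise ValueError(
                f"samples {self.data.shape[2]} != round(window span * fs) = {expected}"
            )

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def times(self) -> np.ndarray:
        n = int(round((self.window[1] - self.window[0]) * self.fs))
        return self.window[0] + np.arange(n) / self.fs

    @property
    def onset_index(self) -> int:
        return int(round(-self.window[0] * self.fs))

    def channel_mean(self, labels) -> np.ndarray:
        """Trials x samples average over a channel subset."""
        from .channels import channel_indices

        idx = channel_indices(list(self.channel_labels), labels)
        return self.data[:, idx, :].mean(axis=1)


@dataclass
class StateSegmentSet:
    """Paired per-look EEG segments for one gaze state.

    ``infant[i]`` and ``adult[i]`` are (n_channels, len_i) slices taken at
    the same clock samples; segment i covers one look of the state.
    """

    state: str
    infant: list
    adult: list
    fs: float
    channel_labels: Sequence[str] = ()

    def __post_init__(self):
        if len(self.infant) != len(self.adult):
            raise ValueError("paired segment lists must have equal length")
        for a, b in zip(self.infant, self.adult):
            if a.shape != b.shape:
                raise ValueError("paired segments must be sample-aligned")

    @property
    def n_segments(self) -> int:
        return len(self.infant)

    @property
    def lengths(self) -> np.ndarray:
        return np.array([seg.shape[1] for seg in self.infant], dtype=int)

    @property
    def total_samples(self) -> int:
        return int(self.lengths.sum()) if self.n_segments else 0

    @property
    def total_seconds(self) -> float:
        return self.total_samples / self.fs


# --------------------------------------------------------------------------


def bandpass_filter(data: np.ndarray, fs: float, low: float = 1.0, high: float = 20.0):
    """Zero-phase Butterworth band-pass along the last axis."""
    if high >= fs / 2:
        raise ValueError("upper edge must be below Nyquist")
    if low <= 0 or low >= high:
        raise ValueError("need 0 < low < high")
    sos = signal.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(data, dtype=float), axis=-1)


def robust_average_reference(data: np.ndarray) -> np.ndarray:
    """Subtract the per-sample cross-channel median (robust common mode)."""
    data = np.asarray(data, dtype=float)
    if data.shape[0] < 2:
        raise ValueError("robust average reference needs at least 2 channels")
    return data - np.median(data, axis=0, keepdims=True)


def _loo_median(data: np.ndarray) -> np.ndarray:
    """Leave-one-out median across channels for every channel at once.

    Removing channel c from the per-sample sorted values shifts the
    median order statistic by one position depending on c's rank, so the
    LOO median can be read off the sorted array without materialising
    n_channels copies of the data.
    """
    n = data.shape[0]
    v = np.sort(data, axis=0)
    m = n - 1  # size of the leave-one-out set
    if m % 2:  # odd: single order statistic
        q = (m - 1) // 2
        return np.where(data > v[q], v[q], v[q + 1])
    q1, q2 = m // 2 - 1, m // 2
    a = np.where(data > v[q1], v[q1], v[q1 + 1])
    b = np.where(data > v[q2], v[q2], v[q2 + 1])
    return 0.5 * (a + b)


def interpolate_bad_channels(data: np.ndarray, corr_threshold: float = 0.7):
    """Replace channels poorly correlated with their robust estimate.

    Each channel is compared against the leave-one-out median of the other
    channels; channels with Pearson r below ``corr_threshold`` are replaced
    by the median of the remaining good channels.

    Returns
    -------
    (cleaned, flagged) : cleaned array and list of flagged channel indices.
    """
    data = np.asarray(data, dtype=float)
    n_ch = data.shape[0]
    est = _loo_median(data)
    xc = data - data.mean(axis=1, keepdims=True)
    ec = est - est.mean(axis=1, keepdims=True)
    denom = np.linalg.norm(xc, axis=1) * np.linalg.norm(ec, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, (xc * ec).sum(axis=1) / denom, 0.0)
    flagged = list(np.flatnonzero(r < corr_threshold))
    if len(flagged) > n_ch / 2:
        raise ValueError(
            f"{len(flagged)}/{n_ch} channels below correlation threshold; data unusable"
        )
    if flagged:
        good = np.setdiff1d(np.arange(n_ch), flagged)
        fill = np.median(data[good], axis=0)
        data = data.copy()
        for c in flagged:
            data[c] = fill
    return data, flagged


def reject_highpower_segments(
    data: np.ndarray,
    fs: float,
    win: float = 1.0,
    channel_frac: float = 0.70,
    sd_mult: float = 5.0,
):
    """Mask non-overlapping ``win``-second epochs with extreme power.

    Per-channel epoch power is the variance of the mean-removed epoch;
    per-channel mean/SD are computed over all epochs of the recording.  An
    epoch is rejected when more than ``channel_frac`` of channels exceed
    mean + ``sd_mult``·SD.  Returns a per-sample boolean mask (True = keep)
    and the fraction of samples removed.
    """
    data = np.asarray(data, dtype=float)
    n_ch, n_samples = data.shape
    w = int(round(win * fs))
    if n_samples < w:
        raise ValueError("recording shorter than one rejection window")
    n_ep = n_samples // w
    epochs = data[:, : n_ep * w].reshape(n_ch, n_ep, w)
    power = epochs.var(axis=2)  # (n_ch, n_ep)
    mu = power.mean(axis=1, keepdims=True)
    sd = power.std(axis=1, keepdims=True)
    exceed = power > mu + sd_mult * sd
    reject = exceed.mean(axis=0) > channel_frac
    mask = np.ones(n_samples, dtype=bool)
    for i in np.flatnonzero(reject):
        mask[i * w : (i + 1) * w] = False
    return mask, float((~mask).sum() / n_samples)


def extract_event_epochs(
    dyad: DyadRecording,
    events: Sequence[GazeEvent],
    window=(-2.5, 2.5),
    mask: Optional[np.ndarray] = None,
    condition: str = "",
):
    """Slice both partners' EEG around each event on the shared clock.

    Trials whose span leaves the recording or overlaps masked samples are
    dropped; the drop log lists (event, reason).  Returns
    (infant EpochSet, adult EpochSet, dropped).
    """
    fs = dyad.fs
    n = dyad.n_samples
    length = int(round((window[1] - window[0]) * fs))
    pre = int(round(-window[0] * fs))
    kept, slabs_i, slabs_a, dropped = [], [], [], []
    for ev in events:
        s0 = int(round(ev.onset_time * fs)) - pre
        s1 = s0 + length
        if s0 < 0 or s1 > n:
            dropped.append((ev, "edge"))
            continue
        if mask is not None and not mask[s0:s1].all():
            dropped.append((ev, "masked"))
            continue
        kept.append(ev)
        slabs_i.append(dyad.infant[:, s0:s1])
        slabs_a.append(dyad.adult[:, s0:s1])
    shape = (0, dyad.infant.shape[0], length)
    data_i = np.stack(slabs_i) if slabs_i else np.empty(shape)
    data_a = np.stack(slabs_a) if slabs_a else np.empty(shape)
    mk = lambda d: EpochSet(d, tuple(window), fs, list(kept), condition, dyad.channel_labels)
    return mk(data_i), mk(data_a), dropped


def segment_by_gaze_state(
    dyad: DyadRecording,
    timelines=None,
    mask: Optional[np.ndarray] = None,
):
    """Per-look paired EEG segments for mutual and non-mutual gaze.

    Mutual: frames where both partners are on ``partner``; non-mutual:
    frames where exactly one is.  Each maximal run of frames becomes one
    segment (onset to end of the look); looks overlapping masked samples
    are dropped so rejected data never re-enters the analysis.
    """
    if timelines is None:
        timelines = dyad.timelines
    inf, adu = timelines["infant"], timelines["adult"]
    if inf.n_frames != adu.n_frames:
        raise ValueError("timelines must be aligned")
    on_i = inf.states == "partner"
    on_a = adu.states == "partner"
    frame_masks = {
        "mutual": on_i & on_a,
        "nonmutual": on_i ^ on_a,
    }
    fr = inf.frame_rate
    out = {}
    for state, fmask in frame_masks.items():
        segs_i, segs_a = [], []
        for a, b in _runs_of(fmask):
            s0 = int(round(a / fr * dyad.fs))
            s1 = min(int(round(b / fr * dyad.fs)), dyad.n_samples)
            if s1 <= s0:
                continue
            if mask is not None and not mask[s0:s1].all():
                continue
            segs_i.append(dyad.infant[:, s0:s1])
            segs_a.append(dyad.adult[:, s0:s1])
        out[state] = StateSegmentSet(state, segs_i, segs_a, dyad.fs, dyad.channel_labels)
    return out


def _truncate_segments(segset: StateSegmentSet, n_keep: int) -> StateSegmentSet:
    segs_i, segs_a, total = [], [], 0
    for a, b in zip(segset.infant, segset.adult):
        if total >= n_keep:
            break
        take = min(a.shape[1], n_keep - total)
        segs_i.append(a[:, :take])
        segs_a.append(b[:, :take])
        total += take
    return StateSegmentSet(segset.state, segs_i, segs_a, segset.fs, segset.channel_labels)


def match_condition_counts(a, b):
    """Equalise data amounts between two conditions by 1:n truncation.

    EpochSets are cut to the first ``n = min(trial counts)`` trials;
    StateSegmentSets to the first ``n = min(total samples)`` samples
    (segment order preserved, last kept segment clipped).  Idempotent.
    """
    if isinstance(a, EpochSet) != isinstance(b, EpochSet):
        raise TypeError("both inputs must be the same kind")
    if isinstance(a, EpochSet):
        n = min(a.n_trials, b.n_trials)
        cut = lambda e: EpochSet(
            e.data[:n], e.window, e.fs, e.events[:n], e.condition, e.channel_labels
        )
        return cut(a), cut(b)
    n = min(a.total_samples, b.total_samples)
    return _truncate_segments(a, n), _truncate_segments(b, n)


def preprocess_recording(
    dyad: DyadRecording,
    low: float = 1.0,
    high: float = 20.0,
    corr_threshold: float = 0.7,
    reject: bool = True,
):
    """Full conditioning chain for one dyad.

    Filter → channel interpolation → robust reference per partner; the
    high-power rejection masks are combined (a sample must be clean in
    both partners to survive, keeping the dyad on one shared clock).
    Interpolation runs before referencing because the correlation of a
    channel with the leave-one-out median of the others is only
    informative while the shared scalp field is still present; once the
    per-sample median has been subtracted the residuals are centred and
    the criterion would flag every channel.

    Returns (cleaned DyadRecording, mask, info dict).
    """
    cleaned = {}
    info = {"interpolated": {}, "fraction_rejected": {}}
    mask = np.ones(dyad.n_samples, dtype=bool)
    for role in ("infant", "adult"):
        x = bandpass_filter(dyad.data(role), dyad.fs, low, high)
        x, flagged = interpolate_bad_channels(x, corr_threshold)
        x = robust_average_reference(x)
        info["interpolated"][role] = [dyad.channel_labels[c] for c in flagged]
        if reject:
            m, frac = reject_highpower_segments(x, dyad.fs)
            info["fraction_rejected"][role] = frac
            mask &= m
        cleaned[role] = x
    out = DyadRecording(
        infant=cleaned["infant"],
        adult=cleaned["adult"],
        channel_labels=dyad.channel_labels,
        fs=dyad.fs,
        events=list(dyad.events),
        timelines=dyad.timelines,
    )
    return out, mask, info
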