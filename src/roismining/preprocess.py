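"""Event-related EEG preprocessing.

Turns a continuous multichannel recording into one artifact-free,
trial-averaged waveform per subject:

    bandpass filter -> epoch around stimulus onsets -> amplitude-based
    artifact rejection -> average reference -> bad-channel removal ->
    trial averaging

Conventions
-----------
* Amplitudes are microvolts throughout.
* Samples are 0-based; within an epoch, sample index ``t`` maps to time
  ``(t - pre_samples) / rate_hz`` relative to stimulus onset.
* Ocular ("eye") channels are carried along for rejection decisions but are
  excluded from the average reference, from scalp amplitude rejection, and
  from the final averaged waveform.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml
from scipy import signal

from .errors import EmptyEpochSetError, InvalidParameterError, InvalidStateError

logger = logging.getLogger(__name__)

#: Event tags understood by the segmenter.  ``target`` trials (the attention
#: catch stimulus) are excluded from analysis epochs.
STIMULUS_TAGS = ("sound", "nonsound")
ALL_TAGS = STIMULUS_TAGS + ("target",)

#: Default epoch window (ms before / after stimulus onset).
DEFAULT_PRE_MS = 100.0
DEFAULT_POST_MS = 600.0

#: Default rejection thresholds (microvolts).
DEFAULT_AMP_UV = 75.0
DEFAULT_BLINK_UV = 140.0
DEFAULT_MOVE_UV = 55.0

#: Default bad-channel rule parameters.
FLAT_STD_UV = 0.1
EXTREME_STD_FACTOR = 5.0


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class Recording:
    """Continuous multichannel EEG with stimulus event markers.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Amplitudes in microvolts.
    rate_hz : float
        Sampling rate in samples/second.
    channel_labels : list of str
        One unique label per row of ``data``.
    eye_channel_labels : sequence of str
        Subset of ``channel_labels`` designated as ocular channels.
    events : list of (int, str)
        ``(onset_sample, condition_tag)`` pairs; tags are ``sound``,
        ``nonsound`` or ``target``.
    """

    data: np.ndarray
    rate_hz: float
    channel_labels: list[str]
    eye_channel_labels: tuple[str, ...] = ()
    events: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise InvalidParameterError("data must be 2-D (channels x samples)")
        if self.rate_hz <= 0:
            raise InvalidParameterError(f"rate_hz must be positive, got {self.rate_hz}")
        self.channel_labels = list(self.channel_labels)
        if len(self.channel_labels) != self.data.shape[0]:
            raise InvalidParameterError(
                f"{len(self.channel_labels)} labels for {self.data.shape[0]} channels"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise InvalidParameterError("channel labels must be unique")
        self.eye_channel_labels = tuple(self.eye_channel_labels)
        unknown = set(self.eye_channel_labels) - set(self.channel_labels)
        if unknown:
            raise InvalidParameterError(f"eye channels not in montage: {sorted(unknown)}")
        n = self.data.shape[1]
        for onset, tag in self.events:
            if not 0 <= onset < n:
                raise InvalidParameterError(f"event onset {onset} outside [0, {n})")
            if tag not in ALL_TAGS:
                raise InvalidParameterError(f"unknown condition tag {tag!r}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class EpochSet:
    """Stimulus-locked trials cut from a recording.

    ``data`` has shape (n_trials, n_channels, n_samples); ``accepted`` flags
    which trials survive artifact rejection — rejection never deletes data,
    it only clears flags, so the decision trail stays inspectable.
    """

    data: np.ndarray
    pre_ms: float
    post_ms: float
    rate_hz: float
    condition_tags: np.ndarray
    accepted: np.ndarray
    channel_labels: list[str]
    eye_channel_labels: tuple[str, ...] = ()
    removed_channels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.condition_tags = np.asarray(self.condition_tags)
        self.accepted = np.asarray(self.accepted, dtype=bool)
        expected = int(round((self.pre_ms + self.post_ms) / 1000.0 * self.rate_hz))
        if self.data.shape[2] != expected:
            raise InvalidParameterError(
                f"epoch length {self.data.shape[2]} != round((pre+post)/1000*rate) = {expected}"
            )

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_accepted(self) -> int:
        return int(self.accepted.sum())

    @property
    def pre_samples(self) -> int:
        return int(np.floor(self.pre_ms / 1000.0 * self.rate_hz))

    def scalp_mask(self) -> np.ndarray:
        """Boolean mask of non-eye channels, in channel order."""
        eye = set(self.eye_channel_labels)
        return np.array([lab not in eye for lab in self.channel_labels])


@dataclass
class AveragedWaveform:
    """Per-subject trial average over accepted trials (scalp channels only)."""

    data: np.ndarray
    channel_labels: list[str]
    rate_hz: float
    n_trials_averaged: int

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def _bandpass_sos(low_hz: float, high_hz: float, rate_hz: float, order: int = 4) -> np.ndarray:
    nyq = rate_hz / 2.0
    if not (0 < low_hz < high_hz < nyq):
        raise InvalidParameterError(
            f"band edges ({low_hz}, {high_hz}) must satisfy 0 < low < high < Nyquist ({nyq})"
        )
    return signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=rate_hz, output="sos")


def bandpass_filter(
    rec: Recording, low_hz: float = 0.3, high_hz: float = 30.0, order: int = 4
) -> Recording:
    """Zero-phase Butterworth bandpass of the continuous recording.

    A forward-backward (``sosfiltfilt``) order-``order`` Butterworth design:
    zero phase distortion preserves event-locked latencies, at the price of
    doubling the effective filter order.  Events are unchanged.  The input
    dtype is preserved (float32 recordings stay float32).
    """
    sos = _bandpass_sos(low_hz, high_hz, rec.rate_hz, order)
    if rec.data.dtype == np.float32:
        sos = sos.astype(np.float32)
    filtered = signal.sosfiltfilt(sos, rec.data, axis=-1)
    return replace(rec, data=filtered.astype(rec.data.dtype, copy=False))


def segment_epochs(
    rec: Recording, pre_ms: float = DEFAULT_PRE_MS, post_ms: float = DEFAULT_POST_MS
) -> EpochSet:
    """Cut one trial per sound/nonsound event.

    Epochs run from ``pre_ms`` before to ``post_ms`` after each onset; the
    stimulus lands on epoch sample ``floor(pre_ms/1000 * rate)``.  Target
    (catch) events are excluded, and events without enough history/future
    are dropped with a warning.
    """
    if pre_ms < 0 or post_ms <= 0:
        raise InvalidParameterError("pre_ms must be >= 0 and post_ms > 0")
    n_pre = int(np.floor(pre_ms / 1000.0 * rec.rate_hz))
    n_len = int(round((pre_ms + post_ms) / 1000.0 * rec.rate_hz))
    n_post = n_len - n_pre

    trials, tags, dropped = [], [], 0
    for onset, tag in rec.events:
        if tag not in STIMULUS_TAGS:
            continue
        start, stop = onset - n_pre, onset + n_post
        if start < 0 or stop > rec.n_samples:
            dropped += 1
            continue
        trials.append(rec.data[:, start:stop])
        tags.append(tag)
    if dropped:
        logger.warning("segment_epochs: dropped %d event(s) too close to recording edges", dropped)
    if not trials:
        raise EmptyEpochSetError("no retainable sound/nonsound events")

    data = np.stack(trials)
    return EpochSet(
        data=data,
        pre_ms=pre_ms,
        post_ms=post_ms,
        rate_hz=rec.rate_hz,
        condition_tags=np.array(tags),
        accepted=np.ones(len(trials), dtype=bool),
        channel_labels=list(rec.channel_labels),
        eye_channel_labels=rec.eye_channel_labels,
    )


def reject_artifacts(
    ep: EpochSet,
    amp_uV: float = DEFAULT_AMP_UV,
    blink_uV: float = DEFAULT_BLINK_UV,
    move_uV: float = DEFAULT_MOVE_UV,
) -> EpochSet:
    """Flag trials containing amplitude artifacts.

    A trial is rejected when any scalp channel exceeds ``amp_uV`` in absolute
    amplitude at any sample, or any eye channel exceeds ``blink_uV`` (blink)
    or ``move_uV`` (eye movement).  Thresholds apply to the filtered,
    baseline-uncorrected signal.  Flags are ANDed with prior flags (a trial
    already rejected stays rejected); data are untouched.
    """
    scalp = ep.scalp_mask()
    peak = np.abs(ep.data).max(axis=2)  # (trials, channels)
    bad_scalp = (peak[:, scalp] > amp_uV).any(axis=1)
    eye = ~scalp
    if eye.any():
        eye_peak = peak[:, eye]
        bad_blink = (eye_peak > blink_uV).any(axis=1)
        bad_move = (eye_peak > move_uV).any(axis=1)
    else:
        bad_blink = bad_move = np.zeros(ep.n_trials, dtype=bool)
    bad = bad_scalp | bad_blink | bad_move
    accepted = ep.accepted & ~bad
    logger.info(
        "reject_artifacts: %d/%d trials rejected (scalp %d, blink %d, movement %d)",
        int((ep.accepted & bad).sum()), ep.n_trials,
        int(bad_scalp.sum()), int(bad_blink.sum()), int(bad_move.sum()),
    )
    return replace(ep, accepted=accepted)


def baseline_correct(ep: EpochSet) -> EpochSet:
    """Subtract the mean of the prestimulus interval per trial and channel.

    Off by default in the pipeline; provided as an option since some labs
    baseline before averaging.
    """
    n_pre = ep.pre_samples
    if n_pre == 0:
        return ep
    base = ep.data[:, :, :n_pre].mean(axis=2, keepdims=True)
    return replace(ep, data=ep.data - base)


def rereference_average(ep: EpochSet) -> EpochSet:
    """Re-express scalp channels relative to the all-scalp average.

    After this, the cross-channel mean over retained scalp channels is zero
    at every trial and sample.  Eye channels are left untouched.  Idempotent.
    """
    scalp = ep.scalp_mask()
    if scalp.sum() < 2:
        raise InvalidStateError("average reference needs at least 2 scalp channels")
    data = ep.data.copy()
    mean = data[:, scalp, :].mean(axis=1, keepdims=True)
    data[:, scalp, :] -= mean
    return replace(ep, data=data)


def remove_bad_channels(
    ep: EpochSet,
    manual_list: tuple[str, ...] = (),
    auto: bool = True,
    flat_uV: float = FLAT_STD_UV,
    extreme_factor: float = EXTREME_STD_FACTOR,
) -> EpochSet:
    """Drop bad scalp channels: a manual list plus automatic flat/extreme rules.

    Automatic rules (over accepted trials): a channel is flat when its std is
    below ``flat_uV`` and extreme when its std exceeds ``extreme_factor``
    times the median scalp-channel std.  Removed labels are recorded on the
    returned epoch set.
    """
    unknown = set(manual_list) - set(ep.channel_labels)
    if unknown:
        raise InvalidParameterError(f"manual bad channels not in montage: {sorted(unknown)}")
    bad = set(manual_list)

    scalp = ep.scalp_mask()
    if auto and ep.n_accepted > 0:
        acc = ep.data[ep.accepted]
        stds = acc.transpose(1, 0, 2).reshape(len(ep.channel_labels), -1).std(axis=1)
        scalp_stds = stds[scalp]
        med = np.median(scalp_stds)
        for lab, sd, is_scalp in zip(ep.channel_labels, stds, scalp):
            if not is_scalp:
                continue
            if sd < flat_uV:
                bad.add(lab)
                logger.info("remove_bad_channels: %s flat (std %.3g uV)", lab, sd)
            elif med > 0 and sd > extreme_factor * med:
                bad.add(lab)
                logger.info(
                    "remove_bad_channels: %s extreme (std %.3g uV, median %.3g)", lab, sd, med
                )

    keep = [i for i, lab in enumerate(ep.channel_labels) if lab not in bad]
    kept_labels = [ep.channel_labels[i] for i in keep]
    eye = set(ep.eye_channel_labels)
    if sum(lab not in eye for lab in kept_labels) < 2:
        raise InvalidStateError("bad-channel removal would leave fewer than 2 scalp channels")
    removed = [lab for lab in ep.channel_labels if lab in bad]
    return replace(
        ep,
        data=ep.data[:, keep, :],
        channel_labels=kept_labels,
        eye_channel_labels=tuple(l for l in ep.eye_channel_labels if l not in bad),
        removed_channels=list(ep.removed_channels) + removed,
    )


def average_trials(ep: EpochSet, mode: str = "pooled") -> AveragedWaveform:
    """Average accepted trials into a single waveform (scalp channels only).

    ``mode="pooled"`` averages every accepted trial of both stimulus
    conditions together; ``mode="balanced"`` averages the two per-condition
    means, which differs only by trial-count weighting when the conditions
    retain unequal trial counts.
    """
    if mode not in ("pooled", "balanced"):
        raise InvalidParameterError(f"unknown averaging mode {mode!r}")
    if ep.n_accepted == 0:
        raise EmptyEpochSetError("cannot average: zero accepted trials")
    scalp = ep.scalp_mask()
    acc = ep.accepted
    if mode == "pooled":
        avg = ep.data[acc][:, scalp, :].mean(axis=0)
    else:
        means = []
        for tag in STIMULUS_TAGS:
            sel = acc & (ep.condition_tags == tag)
            if sel.any():
                means.append(ep.data[sel][:, scalp, :].mean(axis=0))
        avg = np.mean(means, axis=0)
    labels = [lab for lab, s in zip(ep.channel_labels, scalp) if s]
    return AveragedWaveform(
        data=np.asarray(avg, dtype=np.float64),
        channel_labels=labels,
        rate_hz=ep.rate_hz,
        n_trials_averaged=ep.n_accepted,
    )


def preprocess_pipeline(
    rec: Recording,
    low_hz: float = 0.3,
    high_hz: float = 30.0,
    pre_ms: float = DEFAULT_PRE_MS,
    post_ms: float = DEFAULT_POST_MS,
    amp_uV: float = DEFAULT_AMP_UV,
    blink_uV: float = DEFAULT_BLINK_UV,
    move_uV: float = DEFAULT_MOVE_UV,
    manual_bad_channels: tuple[str, ...] = (),
    auto_bad_channels: bool = True,
    baseline: bool = False,
    average_mode: str = "pooled",
) -> AveragedWaveform:
    """Full preprocessing chain: filter, epoch, reject, rereference, clean, average.

    Rereferencing is applied before bad-channel removal and again afterwards,
    so the zero-mean property holds on the surviving channel set.
    """
    rec = bandpass_filter(rec, low_hz, high_hz)
    ep = segment_epochs(rec, pre_ms, post_ms)
    ep = reject_artifacts(ep, amp_uV, blink_uV, move_uV)
    if baseline:
        ep = baseline_correct(ep)
    ep = rereference_average(ep)
    ep = remove_bad_channels(ep, manual_bad_channels, auto=auto_bad_channels)
    ep = rereference_average(ep)
    wf = average_trials(ep, mode=average_mode)
    logger.info(
        "preprocess_pipeline: %d/%d trials averaged, %d channel(s) removed, %d scalp channels out",
        wf.n_trials_averaged, ep.n_trials, len(ep.removed_channels), wf.n_channels,
    )
    return wf


# ---------------------------------------------------------------------------
# File formats
# ---------------------------------------------------------------------------
#
# Delimited fixture format: <stem>.tsv holds a header line of channel labels
# followed by one row per channel; <stem>.events.tsv holds onset/tag pairs;
# <stem>.meta.yaml holds the sampling rate and the eye-channel designation.

def write_recording_text(rec: Recording, stem: str | Path) -> None:
    """Write a recording in the plain-text fixture format."""
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    with open(stem.with_suffix(".tsv"), "w") as fh:
        fh.write("\t".join(rec.channel_labels) + "\n")
        np.savetxt(fh, rec.data, fmt="%.6g", delimiter="\t")
    with open(stem.parent / (stem.name + ".events.tsv"), "w") as fh:
        for onset, tag in rec.events:
            fh.write(f"{onset}\t{tag}\n")
    meta = {
        "rate_hz": float(rec.rate_hz),
        "eye_channel_labels": list(rec.eye_channel_labels),
    }
    with open(stem.parent / (stem.name + ".meta.yaml"), "w") as fh:
        yaml.safe_dump(meta, fh)


def read_recording_text(stem: str | Path) -> Recording:
    """Read a recording written by :func:`write_recording_text`."""
    stem = Path(stem)
    with open(stem.with_suffix(".tsv")) as fh:
        labels = fh.readline().rstrip("\n").split("\t")
        data = np.loadtxt(fh, delimiter="\t", ndmin=2)
    events = []
    ev_path = stem.parent / (stem.name + ".events.tsv")
    if ev_path.exists():
        with open(ev_path) as fh:
            for line in fh:
                if line.strip():
                    onset, tag = line.split("\t")
                    events.append((int(onset), tag.strip()))
    with open(stem.parent / (stem.name + ".meta.yaml")) as fh:
        meta = yaml.safe_load(fh)
    return Recording(
        data=data,
        rate_hz=float(meta["rate_hz"]),
        channel_labels=labels,
        eye_channel_labels=tuple(meta.get("eye_channel_labels", ())),
        events=events,
    )


def write_waveform_text(wf: AveragedWaveform, stem: str | Path) -> None:
    """Write an averaged waveform in the delimited format (+ meta sidecar)."""
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    with open(stem.with_suffix(".tsv"), "w") as fh:
        fh.write("\t".join(wf.channel_labels) + "\n")
        np.savetxt(fh, wf.data, fmt="%.10g", delimiter="\t")
    meta = {"rate_hz": float(wf.rate_hz), "n_trials_averaged": int(wf.n_trials_averaged)}
    with open(stem.parent / (stem.name + ".meta.yaml"), "w") as fh:
        yaml.safe_dump(meta, fh)


def read_waveform_text(stem: str | Path) -> AveragedWaveform:
    stem = Path(stem)
    with open(stem.with_suffix(".tsv")) as fh:
        labels = fh.readline().rstrip("\n").split("\t")
        data = np.loadtxt(fh, delimiter="\t", ndmin=2)
    with open(stem.parent / (stem.name + ".meta.yaml")) as fh:
        meta = yaml.safe_load(fh)
    return AveragedWaveform(
        data=data,
        channel_labels=labels,
        rate_hz=float(meta["rate_hz"]),
        n_trials_averaged=int(meta["n_trials_averaged"]),
    )


def read_edf(
    path: str | Path,
    events_path: str | Path | None = None,
    eye_channel_labels: tuple[str, ...] = (),
) -> Recording:
    """Read an EDF file (via mne) plus an optional sidecar events file.

    mne returns data in volts; amplitudes are converted to microvolts.
    """
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data_uv = raw.get_data() * 1e6
    events: list[tuple[int, str]] = []
    if events_path is not None:
        with open(events_path) as fh:
            for line in fh:
                if line.strip():
                    onset, tag = line.split("\t")
                    events.append((int(onset), tag.strip()))
    return Recording(
        data=data_uv,
        rate_hz=float(raw.info["sfreq"]),
        channel_labels=list(raw.ch_names),
        eye_channel_labels=eye_channel_labels,
        events=events,
    )


def write_edf(rec: Recording, path: str | Path) -> None:
    """Write a minimal plain EDF file (16-bit, one 1-second record per second).

    Implements the base European Data Format: ASCII header plus int16 data
    records with per-channel physical scaling.  Events are not embedded; use
    the sidecar events file of the delimited format.  Requires an integer
    sampling rate; the data are zero-padded to a whole number of records.
    """
    rate = int(round(rec.rate_hz))
    if abs(rate - rec.rate_hz) > 1e-9 or rate <= 0:
        raise InvalidParameterError("EDF writer requires an integer sampling rate")
    n_ch = rec.n_channels
    n_rec = int(np.ceil(rec.n_samples / rate))
    padded = np.zeros((n_ch, n_rec * rate))
    padded[:, : rec.n_samples] = rec.data

    phys_max = np.maximum(np.abs(padded).max(axis=1), 1.0)
    phys_min = -phys_max
    dig_min, dig_max = -32768, 32767
    scale = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.round((padded - phys_min[:, None]) * scale[:, None] + dig_min).astype("<i2")

    def f(text: str, width: int) -> bytes:
        return text[:width].ljust(width).encode("ascii")

    header = b"".join([
        f("0", 8),
        f("X X X X", 80),
        f("Startdate X X X X", 80),
        f("01.01.00", 8),
        f("00.00.00", 8),
        f(str(256 * (n_ch + 1)), 8),
        f("", 44),
        f(str(n_rec), 8),
        f("1", 8),
        f(str(n_ch), 4),
    ])
    fields = [
        [f(lab, 16) for lab in rec.channel_labels],
        [f("AgAgCl electrode", 80)] * n_ch,
        [f("uV", 8)] * n_ch,
        [f(f"{v:.6g}", 8) for v in phys_min],
        [f(f"{v:.6g}", 8) for v in phys_max],
        [f(str(dig_min), 8)] * n_ch,
        [f(str(dig_max), 8)] * n_ch,
        [f("", 80)] * n_ch,
        [f(str(rate), 8)] * n_ch,
        [f("", 32)] * n_ch,
    ]
    with open(path, "wb") as fh:
        fh.write(header)
        for fld in fields:
            fh.write(b"".join(fld))
        # data records: record-major, channel-major within a record
        for r in range(n_rec):
            fh.write(digital[:, r * rate : (r + 1) * rate].tobytes())
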