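"""Synthetic event-related EEG cohorts with region-structured coupling.

Emulates the recording design every pipeline stage expects — 128 channels at
1 kHz, ~100 trials per stimulus condition with 1 s pictures and 1.2-1.7 s
blank intervals, 100 ms pre / 600 ms post epochs — so the full pipeline is
testable without access to clinical recordings.

Signal model
------------
Each subject carries a set of stimulus-locked latent sources, one per region
plus one global source plus one per coupled region pair.  Sources are
sinusoids on the epoch's exact Fourier grid (frequency = integer multiple of
rate/epoch_length) with subject-specific random phases, so distinct sources
are *orthogonal by construction* over the epoch and planted correlations are
analytic rather than approximate.  The region signal is a weighted mixture

    s_k = sqrt(base_inter) * g + sqrt(delta) * p_kl [if (k,l) coupled,
          positive group only] + sqrt(residual) * u_k

with squared weights summing to 1, and each channel in region k is

    x = sqrt(base_intra) * s_k + sqrt(1 - base_intra) * private_noise,

all scaled to ``noise_std`` microvolts.  The expected channel-pair
correlation of the trial-averaged waveform is then ``base_intra`` times
(1 within a region, ``base_inter`` across regions, ``base_inter + delta``
across coupled pairs in the positive group) up to residual trial noise.
Coupled-pair sources sit at the Fourier bins nearest ``oscillation_hz``
(default 6 Hz, theta), so the group difference is band-localised; the other
sources are spread over 2-26 Hz.

A fixed half-sine deflection 80-300 ms post-onset — identical across groups
and regions — plays the role of the evoked response, so classification must
rely on connectivity rather than waveform shape.  A configurable fraction of
trials carries injected high-amplitude scalp or ocular excursions to
exercise the rejection rules.

Recordings are generated in float32 (a full-scale subject is ~128 ch x
520 s x 1 kHz ~ 266 MB); generate and preprocess one subject at a time for
large cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sp_signal

from .errors import InvalidParameterError
from .preprocess import Recording
from .roi_model import ROIPartition, load_partition

#: Default montage: HydroCel GSN-128 style labels, last four designated ocular.
N_CHANNELS = 128
CHANNEL_LABELS = [f"E{i}" for i in range(1, N_CHANNELS + 1)]
EYE_CHANNEL_LABELS = ("E125", "E126", "E127", "E128")

#: Experimental-block timing (ms): picture duration and blank-interval range.
STIMULUS_MS = 1000.0
ISI_RANGE_MS = (1200.0, 1700.0)


def default_effect_pairs(
    partition: ROIPartition, delta: float = 0.5
) -> list[tuple[str, str, float]]:
    """Two anterior-posterior region pairs with raised coupling.

    Picks regions 2 & 8 and 3 & 9 in partition order, which for the bundled
    partition I gives the left/right anterior-lateral to occipitotemporal
    pairs.
    """
    r = partition.region_labels
    return [(r[1], r[7], delta), (r[2], r[8], delta)]


@dataclass
class CouplingSpec:
    """Generative coupling structure for one synthetic cohort.

    Parameters
    ----------
    partition : ROIPartition
        Region layout shared by both groups (default: bundled partition I).
    base_intra : float
        Within-region coupling strength in [0, 1]; the fraction of each
        channel's variance carried by its region source.
    base_inter : float
        Baseline cross-region coupling in [0, 1], realised through a global
        source shared by every region.
    effect_pairs : list of (region_k, region_l, delta)
        Region pairs whose coupling is raised by ``delta`` in the positive
        (implanted) group only.  This is the class-discriminative structure.
    oscillation_hz : float
        Carrier frequency for the coupled-pair sources (default 6 Hz,
        inside theta and well inside the 0.3-30 Hz passband).
    noise_std : float
        Overall amplitude scale in microvolts; both shared sources and
        private noise are scaled so each scalp channel has ~this std inside
        epochs.
    erp_template : ndarray, optional
        Post-stimulus deflection added to all scalp channels at every onset.
        Default: a half-sine of ``erp_amplitude`` microvolts spanning
        80-300 ms post-onset, built at generation time for the actual rate.
    artifact_fraction : float
        Fraction of stimulus trials carrying an injected artifact
        (scalp > 75 uV, eye blink > 140 uV or eye movement > 55 uV class).
    """

    partition: ROIPartition = field(default_factory=lambda: load_partition("partition_I"))
    base_intra: float = 0.9
    base_inter: float = 0.2
    effect_pairs: list[tuple[str, str, float]] | None = None
    oscillation_hz: float = 6.0
    noise_std: float = 10.0
    erp_amplitude: float = 4.0
    erp_template: np.ndarray | None = None
    artifact_fraction: float = 0.12
    eye_noise_std: float = 5.0

    def __post_init__(self) -> None:
        if self.effect_pairs is None:
            self.effect_pairs = default_effect_pairs(self.partition)
        if not 0 <= self.base_intra <= 1 or not 0 <= self.base_inter <= 1:
            raise InvalidParameterError("base_intra and base_inter must lie in [0, 1]")
        if self.noise_std < 0 or self.artifact_fraction < 0 or self.artifact_fraction > 1:
            raise InvalidParameterError("noise_std >= 0 and artifact_fraction in [0, 1] required")
        labels = set(self.partition.region_labels)
        budget = {lab: self.base_inter for lab in labels}
        for rk, rl, delta in self.effect_pairs:
            if rk not in labels or rl not in labels or rk == rl:
                raise InvalidParameterError(f"bad effect pair ({rk}, {rl})")
            if delta < 0:
                raise InvalidParameterError("effect delta must be >= 0")
            budget[rk] += delta
            budget[rl] += delta
        for lab, total in budget.items():
            if total > 1 + 1e-12:
                raise InvalidParameterError(
                    f"region {lab!r}: base_inter + effect deltas = {total:.3f} exceeds 1"
                )


def _source_bins(spec: CouplingSpec, epoch_len: int, rate_hz: float) -> tuple[list[int], int, list[int]]:
    """Assign each latent source a distinct Fourier bin of the epoch grid.

    Returns (pair_bins, global_bin, region_bins).  Pair sources take the
    bins nearest ``oscillation_hz``; the global and per-region sources are
    spread over 2-26 Hz, skipping taken bins.
    """
    df = rate_hz / epoch_len  # bin spacing, Hz
    n_pairs = len(spec.effect_pairs)
    k0 = max(2, int(round(spec.oscillation_hz / df)))
    pair_bins = []
    offset = 0
    while len(pair_bins) < n_pairs:
        for k in (k0 + offset, k0 - offset) if offset else (k0,):
            if k >= 2 and k not in pair_bins and len(pair_bins) < n_pairs:
                pair_bins.append(k)
        offset += 1
    taken = set(pair_bins)
    candidates = [k for k in range(2, int(26.0 / df) + 1) if k not in taken]
    needed = 1 + spec.partition.n_regions
    if len(candidates) < needed:
        raise InvalidParameterError(
            "epoch too short to assign distinct source frequencies below 26 Hz"
        )
    # spread region sources evenly across the available range
    picks = [candidates[int(round(i * (len(candidates) - 1) / (needed - 1)))] for i in range(needed)]
    # de-duplicate while preserving spread
    seen, spread = set(), []
    for k in picks:
        while k in seen:
            k += 1
        seen.add(k)
        spread.append(k)
    return pair_bins, spread[0], spread[1:]


def _latent_sources(
    spec: CouplingSpec, epoch_len: int, rate_hz: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Build orthogonal unit-std latent sources over one epoch.

    Returns (pair_sources, global_source, region_sources, taper); sources
    are tapered sinusoids on the epoch Fourier grid with random phases.
    """
    pair_bins, global_bin, region_bins = _source_bins(spec, epoch_len, rate_hz)
    t = np.arange(epoch_len)
    taper = sp_signal.windows.tukey(epoch_len, alpha=0.15)

    def tone(k: int) -> np.ndarray:
        phase = rng.uniform(0, 2 * np.pi)
        return np.sqrt(2.0) * np.cos(2 * np.pi * k * t / epoch_len + phase)

    pairs = np.stack([tone(k) for k in pair_bins]) if pair_bins else np.zeros((0, epoch_len))
    glob = tone(global_bin)
    regions = np.stack([tone(k) for k in region_bins])
    return pairs, glob, regions, taper


def _erp(spec: CouplingSpec, rate_hz: float) -> tuple[int, np.ndarray]:
    """(offset_samples, template) for the stimulus-locked deflection."""
    if spec.erp_template is not None:
        return 0, np.asarray(spec.erp_template, dtype=np.float64)
    start = int(round(0.080 * rate_hz))
    stop = int(round(0.300 * rate_hz))
    n = stop - start
    return start, spec.erp_amplitude * np.sin(np.pi * np.arange(n) / n)


def generate_subject(
    group: str,
    spec: CouplingSpec | None = None,
    n_trials_per_condition: int = 100,
    n_target_trials: int = 10,
    rate_hz: float = 1000.0,
    seed: int = 0,
    pre_ms: float = 100.0,
    post_ms: float = 600.0,
) -> Recording:
    """Generate one subject's continuous recording with event markers.

    ``group`` is ``"positive"`` (implanted; effect-pair deltas applied) or
    ``"negative"`` (control).  Onsets follow the experimental block timing:
    1 s picture + 1.2-1.7 s blank, uniformly drawn.  Deterministic in
    ``seed``.
    """
    if group not in ("positive", "negative"):
        raise InvalidParameterError(f"group must be 'positive' or 'negative', got {group!r}")
    spec = spec or CouplingSpec()
    rng = np.random.default_rng(seed)

    epoch_len = int(round((pre_ms + post_ms) / 1000.0 * rate_hz))
    n_pre = int(np.floor(pre_ms / 1000.0 * rate_hz))

    # --- event sequence -----------------------------------------------------
    tags = (
        ["sound"] * n_trials_per_condition
        + ["nonsound"] * n_trials_per_condition
        + ["target"] * n_target_trials
    )
    rng.shuffle(tags)
    gap_lo = (STIMULUS_MS + ISI_RANGE_MS[0]) / 1000.0 * rate_hz
    gap_hi = (STIMULUS_MS + ISI_RANGE_MS[1]) / 1000.0 * rate_hz
    onsets = np.empty(len(tags), dtype=int)
    pos = int(rate_hz)  # 1 s lead-in
    for i in range(len(tags)):
        onsets[i] = pos
        pos += int(rng.uniform(gap_lo, gap_hi))
    n_samples = int(onsets[-1] + epoch_len + rate_hz)

    # --- private noise ------------------------------------------------------
    data = rng.standard_normal((N_CHANNELS, n_samples), dtype=np.float32)
    region_of: dict[str, int] = {}
    for r_idx, (_, channels) in enumerate(spec.partition.regions):
        for ch in channels:
            region_of[ch] = r_idx
    eye = set(EYE_CHANNEL_LABELS)
    scale = np.empty(N_CHANNELS, dtype=np.float32)
    for i, lab in enumerate(CHANNEL_LABELS):
        if lab in eye:
            scale[i] = spec.eye_noise_std
        elif lab in region_of:
            scale[i] = spec.noise_std * np.sqrt(1.0 - spec.base_intra)
        else:
            scale[i] = spec.noise_std
    data *= scale[:, None]

    # --- region mixtures ----------------------------------------------------
    pair_src, global_src, region_src, taper = _latent_sources(spec, epoch_len, rate_hz, rng)
    n_regions = spec.partition.n_regions
    w_pair = np.zeros((n_regions, len(spec.effect_pairs)))
    budget = np.full(n_regions, spec.base_inter)
    if group == "positive":
        labels = spec.partition.region_labels
        for m, (rk, rl, delta) in enumerate(spec.effect_pairs):
            for r in (labels.index(rk), labels.index(rl)):
                w_pair[r, m] = np.sqrt(delta)
                budget[r] += delta
    w_glob = np.sqrt(spec.base_inter)
    w_resid = np.sqrt(np.maximum(1.0 - budget, 0.0))
    # (n_regions, epoch_len): stimulus-locked signal of each region source
    s = (
        w_glob * global_src[None, :]
        + w_pair @ pair_src
        + w_resid[:, None] * region_src
    )
    block = (np.sqrt(spec.base_intra) * spec.noise_std) * s * taper[None, :]
    block = block.astype(np.float32)

    erp_offset, erp = _erp(spec, rate_hz)
    scalp_idx = [i for i, lab in enumerate(CHANNEL_LABELS) if lab not in eye]
    region_idx = np.array([region_of.get(CHANNEL_LABELS[i], -1) for i in range(N_CHANNELS)])

    for onset, tag in zip(onsets, tags):
        start = onset - n_pre
        for i in scalp_idx:
            r = region_idx[i]
            if r >= 0:
                data[i, start : start + epoch_len] += block[r]
        data[scalp_idx, onset + erp_offset : onset + erp_offset + len(erp)] += erp.astype(
            np.float32
        )

    # --- injected artifacts -------------------------------------------------
    n_art = int(np.floor(0.200 * rate_hz))
    art_pulse = np.sin(np.pi * np.arange(n_art) / n_art).astype(np.float32)
    eye_idx = [i for i, lab in enumerate(CHANNEL_LABELS) if lab in eye]
    for onset, tag in zip(onsets, tags):
        if tag == "target" or rng.uniform() >= spec.artifact_fraction:
            continue
        kind = rng.choice(["scalp", "blink", "movement"])
        t0 = onset + int(rng.uniform(0, 0.300 * rate_hz))
        if kind == "scalp":
            ch = scalp_idx[rng.integers(len(scalp_idx))]
            amp = 150.0
        else:
            ch = eye_idx[rng.integers(len(eye_idx))] if eye_idx else scalp_idx[0]
            amp = 250.0 if kind == "blink" else 90.0
        data[ch, t0 : t0 + n_art] += amp * art_pulse

    events = [(int(o), t) for o, t in zip(onsets, tags)]
    return Recording(
        data=data,
        rate_hz=rate_hz,
        channel_labels=list(CHANNEL_LABELS),
        eye_channel_labels=EYE_CHANNEL_LABELS,
        events=events,
    )


def cohort_manifest(n_pos: int = 17, n_neg: int = 8, seed: int = 0) -> pd.DataFrame:
    """Subject table (subject id, group, per-subject seed) for a cohort.

    Deriving per-subject seeds up front lets large cohorts be generated one
    subject at a time without holding 25 recordings in memory.
    """
    if n_pos < 1 or n_neg < 1:
        raise InvalidParameterError("n_pos and n_neg must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_pos + n_neg):
        group = "positive" if i < n_pos else "negative"
        rows.append(
            {
                "subject": f"{'CI' if group == 'positive' else 'NC'}{i + 1:02d}",
                "group": 1 if group == "positive" else 0,
                "seed": int(rng.integers(0, 2**31)),
            }
        )
    return pd.DataFrame(rows)


def generate_cohort(
    n_pos: int = 17,
    n_neg: int = 8,
    spec: CouplingSpec | None = None,
    seed: int = 0,
    **subject_kwargs,
) -> list[tuple[Recording, int]]:
    """Generate an independent cohort; returns ``[(recording, label), ...]``.

    Labels are 1 (positive/implanted) and 0 (negative/control).  For
    full-scale cohorts prefer iterating :func:`cohort_manifest` and calling
    :func:`generate_subject` per row to bound memory.
    """
    spec = spec or CouplingSpec()
    manifest = cohort_manifest(n_pos, n_neg, seed)
    out = []
    for row in manifest.itertuples():
        rec = generate_subject(
            "positive" if row.group == 1 else "negative",
            spec,
            seed=row.seed,
            **subject_kwargs,
        )
        out.append((rec, int(row.group)))
    return out
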