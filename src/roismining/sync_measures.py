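"""Pairwise EEG synchronization measures and connectivity matrices.

Four functional-connectivity measures between channel pairs of the averaged
waveform:

* COR  — Pearson correlation coefficient (population-std convention),
* XCOR — lagged cross-correlation coefficient r(tau),
* COH  — magnitude-squared coherence, averaged over a frequency band,
* PLV  — phase-locking value from the analytic-signal instantaneous phase.

Normalisation follows the classical printed formulas: population standard
deviations (divisor N) and prefactors 1/N (COR, PLV) and 1/(N-tau) (XCOR),
so that self-correlation is exactly 1.  COH needs spectral averaging to be
non-degenerate: a single averaged waveform per subject means Welch
segmentation is mandatory, and single-segment coherence is refused.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal as sp_signal
from scipy.signal import hilbert

from .errors import (
    DegenerateCoherenceError,
    InvalidParameterError,
    UndefinedCorrelationError,
)
from .preprocess import AveragedWaveform

logger = logging.getLogger(__name__)

MEASURES = ("cor", "xcor", "coh", "plv")

#: The six analysis frequency bands (Hz).  Band membership is half-open
#: [low, high); the printed Alpha2/Beta gap (13-14 Hz) belongs to neither.
#: Gamma1 extends beyond the default 30 Hz filter cutoff, so its upper half
#: carries attenuated signal when the default preprocessing is used.
FREQUENCY_BANDS: dict[str, tuple[float, float]] = {
    "Delta": (1.0, 4.0),
    "Theta": (4.0, 8.0),
    "Alpha1": (8.0, 10.0),
    "Alpha2": (10.0, 13.0),
    "Beta": (14.0, 25.0),
    "Gamma1": (25.0, 45.0),
}


@dataclass(frozen=True)
class SyncParams:
    """Parameters selecting and configuring a synchronization measure.

    Parameters
    ----------
    measure : {"cor", "xcor", "coh", "plv"}
    tau : int
        Lag in samples (XCOR only).  Default 1: lag 0 would duplicate COR.
    band : (float, float), optional
        Frequency band in Hz over which COH is averaged.  ``None`` averages
        over all positive-frequency bins.
    welch_segment, welch_overlap, welch_nfft
        Welch estimation settings for COH.  ``welch_nfft`` zero-pads each
        segment so narrow bands contain evaluation bins even at short
        segment lengths (bin spacing rate/nfft instead of rate/segment).
    edge_trim : float
        Fraction of samples dropped at each edge before the PLV sum, to
        discount Hilbert-transform edge effects.  Default 0 (no trimming).
    """

    measure: str = "xcor"
    tau: int = 1
    band: tuple[float, float] | None = None
    welch_segment: int = 128
    welch_overlap: float = 0.5
    welch_nfft: int = 1024
    edge_trim: float = 0.0

    def __post_init__(self) -> None:
        if self.measure not in MEASURES:
            raise InvalidParameterError(f"unknown measure {self.measure!r}; choose from {MEASURES}")
        if self.band is not None and not (0 < self.band[0] < self.band[1]):
            raise InvalidParameterError(f"band must satisfy 0 < low < high, got {self.band}")
        if not 0 <= self.welch_overlap < 1:
            raise InvalidParameterError("welch_overlap must be in [0, 1)")
        if self.welch_nfft < self.welch_segment:
            raise InvalidParameterError("welch_nfft must be >= welch_segment")
        if not 0 <= self.edge_trim < 0.5:
            raise InvalidParameterError("edge_trim must be in [0, 0.5)")

    def to_dict(self) -> dict:
        return {
            "measure": self.measure,
            "tau": self.tau,
            "band": list(self.band) if self.band else None,
            "welch_segment": self.welch_segment,
            "welch_overlap": self.welch_overlap,
            "welch_nfft": self.welch_nfft,
            "edge_trim": self.edge_trim,
        }


@dataclass
class CrossSpectrum:
    """Welch-averaged cross- and auto-spectra of a signal pair."""

    freqs: np.ndarray
    Pxy: np.ndarray
    Pxx: np.ndarray
    Pyy: np.ndarray


@dataclass
class PhaseSeries:
    """Instantaneous phase of a signal, wrapped to (-pi, pi]."""

    phi: np.ndarray
    analytic_imag: np.ndarray


@dataclass
class ConnectivityMatrix:
    """Symmetric channel-by-channel synchrony values for one measure."""

    values: np.ndarray
    channel_labels: list[str]
    params: SyncParams

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        n = len(self.channel_labels)
        if self.values.shape != (n, n):
            raise InvalidParameterError(
                f"matrix shape {self.values.shape} does not match {n} labels"
            )

    def index_of(self, label: str) -> int:
        return self.channel_labels.index(label)

    def to_csv(self, path: str | Path) -> None:
        """Write as CSV with a label header row/column plus a JSON params sidecar."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            fh.write("," + ",".join(self.channel_labels) + "\n")
            for lab, row in zip(self.channel_labels, self.values):
                fh.write(lab + "," + ",".join(f"{v:.12g}" for v in row) + "\n")
        with open(path.with_suffix(".params.json"), "w") as fh:
            json.dump(self.params.to_dict(), fh, indent=2)


# ---------------------------------------------------------------------------
# Scalar measures
# ---------------------------------------------------------------------------

def _check_pair(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.ndim != 1 or y.ndim != 1:
        raise InvalidParameterError("inputs must be 1-D time series")
    if len(x) != len(y):
        raise InvalidParameterError(f"length mismatch: {len(x)} vs {len(y)}")
    if len(x) < 2:
        raise InvalidParameterError("time series must have at least 2 samples")
    return x, y


def pearson_cor(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation with population-std normalisation.

    r = (1/N) * sum(((x - xbar)/sx) * ((y - ybar)/sy)), sx and sy with
    divisor N, so pearson_cor(x, x) == 1 exactly.
    """
    x, y = _check_pair(x, y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("correlation undefined for constant input")
    sx, sy = x.std(), y.std()
    return float(np.mean((x - x.mean()) / sx * (y - y.mean()) / sy))


def cross_cor(x: np.ndarray, y: np.ndarray, tau: int) -> float:
    """Lagged cross-correlation coefficient r(tau).

    For tau >= 0:
    r(tau) = 1/(N-tau) * sum_{n=0}^{N-tau-1} ((x[n+tau]-xbar)/sx)*((y[n]-ybar)/sy)
    with the mean/std of the full series; r(tau; x, y) := r(-tau; y, x) for
    negative lags.  r(0) coincides with the Pearson correlation.
    """
    x, y = _check_pair(x, y)
    tau = int(tau)
    if abs(tau) >= len(x):
        raise InvalidParameterError(f"|tau| = {abs(tau)} must be < N = {len(x)}")
    if tau < 0:
        return cross_cor(y, x, -tau)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("cross-correlation undefined for constant input")
    sx, sy = x.std(), y.std()
    n = len(x)
    num = np.sum((x[tau:] - x.mean()) * (y[: n - tau] - y.mean()))
    return float(num / ((n - tau) * sx * sy))


def _welch_segments(
    x: np.ndarray, params: SyncParams
) -> tuple[np.ndarray, np.ndarray]:
    """Hann-windowed, mean-detrended, zero-padded segment spectra.

    Returns (freqs, S) with S of shape (n_segments, n_freqs).  Raises when
    fewer than two segments fit.
    """
    seg = params.welch_segment
    step = max(1, int(round(seg * (1 - params.welch_overlap))))
    n = len(x)
    starts = range(0, n - seg + 1, step)
    if len(starts) < 2:
        raise DegenerateCoherenceError(
            f"only {len(starts)} Welch segment(s) fit in {n} samples "
            f"(segment {seg}, overlap {params.welch_overlap}); coherence needs >= 2"
        )
    win = sp_signal.get_window("hann", seg)
    chunks = np.stack([x[s : s + seg] for s in starts])
    chunks = chunks - chunks.mean(axis=1, keepdims=True)
    S = np.fft.rfft(chunks * win, n=params.welch_nfft, axis=1)
    freqs = np.fft.rfftfreq(params.welch_nfft)
    return freqs, S


def cross_spectrum(
    x: np.ndarray, y: np.ndarray, rate_hz: float, params: SyncParams
) -> CrossSpectrum:
    """Welch-averaged cross-spectrum Pxy = <X(f) Y*(f)> and auto-spectra."""
    x, y = _check_pair(x, y)
    freqs, Sx = _welch_segments(x, params)
    _, Sy = _welch_segments(y, params)
    return CrossSpectrum(
        freqs=freqs * rate_hz,
        Pxy=(Sx * np.conj(Sy)).mean(axis=0),
        Pxx=(np.abs(Sx) ** 2).mean(axis=0),
        Pyy=(np.abs(Sy) ** 2).mean(axis=0),
    )


def _band_mask(freqs: np.ndarray, band: tuple[float, float] | None) -> np.ndarray:
    if band is None:
        mask = freqs > 0
    else:
        mask = (freqs >= band[0]) & (freqs < band[1])
    if not mask.any():
        raise InvalidParameterError(
            f"no frequency bins fall in band {band}; increase welch_nfft or widen the band"
        )
    return mask


def msc(x: np.ndarray, y: np.ndarray, rate_hz: float, params: SyncParams) -> float:
    """Band-averaged magnitude-squared coherence.

    c(f) = |Pxy(f)|^2 / (Pxx(f) Pyy(f)) from Welch-averaged spectra; the
    returned value is the mean of c(f) over bins in ``params.band``
    (half-open [low, high)).
    """
    cs = cross_spectrum(x, y, rate_hz, params)
    mask = _band_mask(cs.freqs, params.band)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.abs(cs.Pxy) ** 2 / (cs.Pxx * cs.Pyy)
    c = np.nan_to_num(c[mask], nan=0.0)
    return float(c.mean())


def instantaneous_phase(x: np.ndarray) -> PhaseSeries:
    """Instantaneous phase via the analytic signal x + i*hilbert(x)."""
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1 or len(x) < 8:
        raise InvalidParameterError("instantaneous phase needs a 1-D series of >= 8 samples")
    analytic = hilbert(x)
    return PhaseSeries(phi=np.angle(analytic), analytic_imag=np.imag(analytic))


def plv(x: np.ndarray, y: np.ndarray, edge_trim: float = 0.0) -> float:
    """Phase-locking value: resultant length of the phase-difference distribution.

    gamma = | (1/N) sum_n exp(i (phi_x[n] - phi_y[n])) |.  The modulus makes
    the complex mean a real synchrony index in [0, 1]; it is 1 for any
    constant phase offset and is invariant to amplitude scaling of either
    input.  ``edge_trim`` drops that fraction of samples at each edge before
    the sum.
    """
    x, y = _check_pair(x, y)
    dphi = instantaneous_phase(x).phi - instantaneous_phase(y).phi
    if edge_trim > 0:
        k = int(len(dphi) * edge_trim)
        if k > 0:
            dphi = dphi[k:-k]
    return float(np.abs(np.mean(np.exp(1j * dphi))))


# ---------------------------------------------------------------------------
# Matrix assembly
# ---------------------------------------------------------------------------

def _standardized(data: np.ndarray, labels: list[str]) -> np.ndarray:
    dead = np.where(np.ptp(data, axis=1) == 0)[0]
    if len(dead):
        raise UndefinedCorrelationError(
            f"constant channel(s): {[labels[i] for i in dead]}"
        )
    mean = data.mean(axis=1, keepdims=True)
    std = data.std(axis=1, keepdims=True)
    return (data - mean) / std


def _symmetrize_upper(m: np.ndarray) -> np.ndarray:
    """Mirror the upper triangle so the matrix equals its transpose exactly."""
    out = np.triu(m, 1)
    out = out + out.T
    np.fill_diagonal(out, np.diag(m))
    return out


def connectivity_matrix(w: AveragedWaveform, params: SyncParams) -> ConnectivityMatrix:
    """Apply the selected measure to every unordered channel pair.

    The result is symmetric by construction: for XCOR, whose pairwise value
    is direction-dependent at tau != 0, the (i, j) entry with i < j in
    channel order defines the unordered-pair value.  The diagonal is exactly
    1 for COR/COH/PLV and the tau-lagged self-correlation for XCOR.
    """
    if w.n_channels < 2:
        raise InvalidParameterError("connectivity needs at least 2 channels")
    data = np.asarray(w.data, dtype=np.float64)
    n_ch, n = data.shape
    labels = list(w.channel_labels)

    if params.measure == "cor":
        z = _standardized(data, labels)
        m = (z @ z.T) / n
        m = _symmetrize_upper(m)
        np.fill_diagonal(m, 1.0)
    elif params.measure == "xcor":
        tau = abs(int(params.tau))
        if tau >= n:
            raise InvalidParameterError(f"|tau| = {tau} must be < N = {n}")
        z = _standardized(data, labels)
        m = (z[:, tau:] @ z[:, : n - tau].T) / (n - tau)
        if params.tau < 0:
            m = m.T
        m = _symmetrize_upper(m)
    elif params.measure == "plv":
        analytic = hilbert(data, axis=1)
        e = np.exp(1j * np.angle(analytic))
        if params.edge_trim > 0:
            k = int(n * params.edge_trim)
            if k > 0:
                e = e[:, k:-k]
        m = np.abs(e @ np.conj(e).T) / e.shape[1]
        m = _symmetrize_upper(m)
        np.fill_diagonal(m, 1.0)
    else:  # coh
        freqs = None
        specs = []
        for row in data:
            freqs, S = _welch_segments(row, params)
            specs.append(S)
        S = np.stack(specs)  # (n_ch, n_seg, n_freq)
        mask = _band_mask(freqs * w.rate_hz, params.band)
        S = S[:, :, mask]
        n_seg = S.shape[1]
        Pxy = np.einsum("isf,jsf->ijf", S, np.conj(S)) / n_seg
        Pauto = np.real(np.einsum("iif->if", Pxy))
        with np.errstate(invalid="ignore", divide="ignore"):
            c = np.abs(Pxy) ** 2 / (Pauto[:, None, :] * Pauto[None, :, :])
        m = np.nan_to_num(c, nan=0.0).mean(axis=2)
        m = _symmetrize_upper(m)
        np.fill_diagonal(m, 1.0)

    return ConnectivityMatrix(values=m, channel_labels=labels, params=params)
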