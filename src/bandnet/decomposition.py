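"""Frequency-band decomposition of voxel BOLD time series.

Each voxel signal is taken to the frequency domain with a real FFT, the
spectrum is masked to a named band, and the band component is restored to
the time domain with the inverse transform, at the original length.  The
mask is an ideal (brick-wall) bin selector: bins whose frequency falls in
the half-open interval ``[f_low, f_high)`` are kept, everything else —
including the DC bin — is zeroed.  The topmost band of a partition
additionally owns its closed upper edge, so touching bands partition the
spectrum exactly and the band components sum to the band-passed signal.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "FrequencyBand",
    "BoldMatrix",
    "BandSignals",
    "DEFAULT_BANDS",
    "FULL_BAND_HZ",
    "bandpass_full",
    "decompose",
]


class InvalidBandError(ValueError):
    """A frequency band is empty, overlapping, or outside the Nyquist range."""


@dataclass(frozen=True)
class FrequencyBand:
    """A named frequency interval in Hz, half-open ``[f_low, f_high)``."""

    name: str
    f_low_hz: float
    f_high_hz: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.f_low_hz < self.f_high_hz):
            raise InvalidBandError(
                f"band {self.name!r}: need 0 <= f_low < f_high, "
                f"got [{self.f_low_hz}, {self.f_high_hz}]"
            )

    @property
    def width_hz(self) -> float:
        return self.f_high_hz - self.f_low_hz


#: The canonical three-band split of resting-state BOLD fluctuations:
#: low (0.01–0.06 Hz), intermediate (0.06–0.15 Hz), high (0.15–0.2 Hz).
DEFAULT_BANDS: tuple[FrequencyBand, ...] = (
    FrequencyBand("low", 0.01, 0.06),
    FrequencyBand("intermediate", 0.06, 0.15),
    FrequencyBand("high", 0.15, 0.20),
)

#: Edges of the full analysis band (the union of the three default bands).
FULL_BAND_HZ: tuple[float, float] = (0.01, 0.20)


@dataclass
class BoldMatrix:
    """A voxel-by-timepoint BOLD signal matrix with its sampling interval.

    Parameters
    ----------
    values
        Real matrix of shape ``(n_voxels, n_timepoints)``.
    tr_seconds
        Repetition time (sampling interval) in seconds.
    voxel_coords
        ``(n_voxels, 3)`` voxel coordinates; one row per voxel, unique.
    """

    values: np.ndarray
    tr_seconds: float
    voxel_coords: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.voxel_coords = np.asarray(self.voxel_coords, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D voxel-by-timepoint matrix")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values contain NaN or Inf")
        if self.values.shape[1] < 8:
            raise ValueError("need at least 8 timepoints")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if self.voxel_coords.shape != (self.values.shape[0], 3):
            raise ValueError("voxel_coords must be (n_voxels, 3)")
        if len(np.unique(self.voxel_coords, axis=0)) != self.values.shape[0]:
            raise ValueError("voxel coordinates must be unique per voxel")

    @property
    def n_voxels(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]

    @property
    def nyquist_hz(self) -> float:
        return 1.0 / (2.0 * self.tr_seconds)


@dataclass
class BandSignals:
    """The time-domain reconstruction of one frequency band of a BoldMatrix."""

    band: FrequencyBand
    values: np.ndarray
    tr_seconds: float
    voxel_coords: np.ndarray

    @property
    def n_voxels(self) -> int:
        return self.values.shape[0]


def _check_band_in_range(name: str, f_low: float, f_high: float, nyquist: float) -> None:
    if f_high > nyquist + 1e-12:
        raise InvalidBandError(
            f"band {name!r} [{f_low}, {f_high}] Hz exceeds the Nyquist "
            f"frequency {nyquist:.6g} Hz of this acquisition"
        )
    if f_low >= f_high:
        raise InvalidBandError(f"band {name!r}: f_low must be < f_high")


def _bin_mask(
    freqs: np.ndarray, f_low: float, f_high: float, close_upper: bool
) -> np.ndarray:
    """Boolean mask over rfft bins for [f_low, f_high), optionally closing
    the upper edge; the DC bin is never included."""
    mask = (freqs >= f_low - 1e-12) & (freqs < f_high - 1e-12)
    if close_upper:
        mask |= np.isclose(freqs, f_high, rtol=0.0, atol=1e-12)
    mask[0] = False
    return mask


def _apply_mask(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    spectrum = np.fft.rfft(values, axis=-1)
    spectrum[..., ~mask] = 0.0
    return np.fft.irfft(spectrum, n=values.shape[-1], axis=-1)


def bandpass_full(
    bold: BoldMatrix,
    f_low: float = FULL_BAND_HZ[0],
    f_high: float = FULL_BAND_HZ[1],
    close_upper: bool = True,
) -> BoldMatrix:
    """Brick-wall band-pass of every voxel signal; the "full band" signal.

    Retains frequency bins in ``[f_low, f_high)`` (plus the exact upper
    edge when ``close_upper``), removes the mean (DC bin), and restores
    the time-domain signal at the original length.
    """
    _check_band_in_range("full", f_low, f_high, bold.nyquist_hz)
    freqs = np.fft.rfftfreq(bold.n_timepoints, d=bold.tr_seconds)
    mask = _bin_mask(freqs, f_low, f_high, close_upper)
    filtered = _apply_mask(bold.values, mask)
    return dataclasses.replace(bold, values=filtered)


def decompose(
    bold: BoldMatrix, bands: Sequence[FrequencyBand] = DEFAULT_BANDS
) -> list[BandSignals]:
    """Split each voxel signal into per-band time-domain components.

    Bands must be pairwise disjoint as half-open intervals and each must
    contain at least one frequency bin at this (n_timepoints, TR).  The
    band with the highest upper edge owns that edge (closed), so that a
    touching partition covers the union interval exactly: the elementwise
    sum of the outputs equals ``bandpass_full`` over the union.

    Returns one :class:`BandSignals` per band, in input order.
    """
    if not bands:
        raise InvalidBandError("no bands given")
    intervals = sorted(bands, key=lambda b: b.f_low_hz)
    for a, b in zip(intervals, intervals[1:]):
        if b.f_low_hz < a.f_high_hz - 1e-12:
            raise InvalidBandError(
                f"bands {a.name!r} and {b.name!r} overlap as half-open intervals"
            )
    freqs = np.fft.rfftfreq(bold.n_timepoints, d=bold.tr_seconds)
    top_edge = max(b.f_high_hz for b in bands)
    out: list[BandSignals] = []
    for band in bands:
        _check_band_in_range(band.name, band.f_low_hz, band.f_high_hz, bold.nyquist_hz)
        mask = _bin_mask(
            freqs,
            band.f_low_hz,
            band.f_high_hz,
            close_upper=(band.f_high_hz == top_edge),
        )
        if not mask.any():
            raise InvalidBandError(
                f"band {band.name!r} [{band.f_low_hz}, {band.f_high_hz}] Hz contains "
                f"no frequency bin at n={bold.n_timepoints}, TR={bold.tr_seconds}s "
                f"(resolution {freqs[1]:.6g} Hz)"
            )
        out.append(
            BandSignals(
                band=band,
                values=_apply_mask(bold.values, mask),
                tr_seconds=bold.tr_seconds,
                voxel_coords=bold.voxel_coords,
            )
        )
    return out
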