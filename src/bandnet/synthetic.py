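"""Synthetic voxel BOLD signals with known band-specific structure.

Each frequency band carries one random-phase multi-sine "carrier" per
community: a sum of sinusoids whose frequencies are DFT bins strictly
inside the open band interval, normalised to unit standard deviation.
A voxel's signal is the amplitude-weighted sum of its communities'
carriers across bands plus i.i.d. Gaussian noise.  Because carriers sit
exactly on interior frequency bins, each band component's spectral
power lies entirely inside its nominal band and the FFT decomposition
recovers the components exactly.

Cohorts pair a base specification with a group effect: group B scales
the within-community coupling (the carrier amplitude) of one affected
band by (1 + effect_size), emulating a patient group whose connectivity
differs in a single band.  Per-subject seeds are spawned deterministically
from the cohort seed, so cohorts are reproducible and subjects independent.

This generator makes no claim about fMRI physics: no hemodynamics, no
spatially correlated noise, no motion.  It exists so that every
downstream stage is testable with known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .decomposition import DEFAULT_BANDS, BoldMatrix, FrequencyBand, InvalidBandError
from .metrics import RegionAtlas
from .network import scan_order_coords

__all__ = [
    "SyntheticSpec",
    "SyntheticCohortSpec",
    "generate_bold",
    "generate_cohort",
    "generate_atlas",
    "default_communities",
]

#: sinusoids per community carrier (capped by available interior bins)
N_SINES = 6


def default_communities(
    n_voxels: int, bands: Sequence[FrequencyBand] = DEFAULT_BANDS
) -> dict[str, np.ndarray]:
    """Two communities per band, partitioned differently in each band
    (contiguous halves, even/odd interleave, quarters) so that the band
    structures are mutually distinguishable."""
    idx = np.arange(n_voxels)
    half = (idx >= n_voxels // 2).astype(int)
    evenodd = idx % 2
    quarters = ((idx % (max(n_voxels, 4) // 2)) >= max(n_voxels, 4) // 4).astype(int)
    patterns = [half, evenodd, quarters]
    return {
        band.name: patterns[i % len(patterns)].copy()
        for i, band in enumerate(bands)
    }


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic subject.

    Defaults emulate a short resting-state acquisition (TR 2 s, 128
    volumes ≈ 4.3 min).  Band carriers have unit variance with the low
    band spectrally densest (its power sits in the narrowest interval),
    and the noise floor dominates the voxel signal: with noise_sd 10 the
    structured carriers explain ≈2% of per-voxel variance, the regime
    where band networks are partially — not perfectly — recoverable,
    as with real voxel BOLD.
    """

    n_voxels: int = 60
    n_timepoints: int = 128
    tr_seconds: float = 2.0
    bands: tuple[FrequencyBand, ...] = DEFAULT_BANDS
    communities_per_band: Mapping[str, np.ndarray] | None = None
    amplitude_per_band: Mapping[str, float] = field(
        default_factory=lambda: {"low": 1.0, "intermediate": 1.0, "high": 0.6}
    )
    noise_sd: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_voxels < 1 or self.n_timepoints < 8:
            raise ValueError("need n_voxels >= 1 and n_timepoints >= 8")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if self.noise_sd < 0 or not np.isfinite(self.noise_sd):
            raise ValueError("noise_sd must be finite and non-negative")
        min_width = min(b.width_hz for b in self.bands)
        if self.n_timepoints < 2.0 / (self.tr_seconds * min_width):
            raise ValueError(
                "n_timepoints too small: the narrowest band holds no frequency bin"
            )
        if self.communities_per_band is None:
            self.communities_per_band = default_communities(self.n_voxels, self.bands)
        for band in self.bands:
            if band.name not in self.amplitude_per_band:
                raise ValueError(f"no amplitude for band {band.name!r}")
            if self.amplitude_per_band[band.name] < 0:
                raise ValueError("amplitudes must be non-negative")
            labels = np.asarray(self.communities_per_band[band.name])
            if labels.shape != (self.n_voxels,):
                raise ValueError(
                    f"community labels for {band.name!r} must have one entry per voxel"
                )


def _interior_bins(
    band: FrequencyBand, n_timepoints: int, tr: float
) -> np.ndarray:
    """DFT bin frequencies strictly inside the open band interval."""
    freqs = np.fft.rfftfreq(n_timepoints, d=tr)
    inside = (freqs > band.f_low_hz + 1e-12) & (freqs < band.f_high_hz - 1e-12)
    inside[0] = False
    return freqs[inside]


def _carrier(
    band: FrequencyBand, n_timepoints: int, tr: float, rng: np.random.Generator
) -> np.ndarray:
    """Random-phase multi-sine with frequencies on interior bins, unit sd."""
    candidates = _interior_bins(band, n_timepoints, tr)
    if len(candidates) == 0:
        raise InvalidBandError(
            f"band {band.name!r} has no representable interior frequency bin "
            f"at n={n_timepoints}, TR={tr}s"
        )
    k = min(N_SINES, len(candidates))
    freqs = rng.choice(candidates, size=k, replace=False)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=k)
    t = np.arange(n_timepoints) * tr
    sig = np.sum(np.cos(2.0 * np.pi * freqs[:, None] * t[None, :] + phases[:, None]), axis=0)
    sd = sig.std()
    return sig / sd if sd > 0 else sig


def generate_bold(
    spec: SyntheticSpec,
) -> tuple[BoldMatrix, dict[str, np.ndarray]]:
    """Generate one subject's voxel-by-timepoint BOLD matrix.

    Each voxel's signal is the sum over bands of the band amplitude
    times its community's carrier, plus independent Gaussian noise.
    Deterministic given ``spec.seed``.  Returns the matrix and the
    per-band ground-truth community labels actually used.
    """
    rng = np.random.default_rng(spec.seed)
    values = np.zeros((spec.n_voxels, spec.n_timepoints))
    truth: dict[str, np.ndarray] = {}
    for band in spec.bands:
        labels = np.asarray(spec.communities_per_band[band.name], dtype=int)
        truth[band.name] = labels.copy()
        amp = float(spec.amplitude_per_band[band.name])
        carriers = {
            c: _carrier(band, spec.n_timepoints, spec.tr_seconds, rng)
            for c in np.unique(labels)
        }
        if amp == 0.0:
            continue
        for c, carrier in carriers.items():
            values[labels == c] += amp * carrier
    if spec.noise_sd > 0:
        values += rng.normal(0.0, spec.noise_sd, size=values.shape)
    coords = scan_order_coords(spec.n_voxels)
    return BoldMatrix(values=values, tr_seconds=spec.tr_seconds, voxel_coords=coords), truth


@dataclass
class SyntheticCohortSpec:
    """A labelled two-group cohort: group A draws from ``base``; group B
    scales within-community coupling in ``affected_band`` by
    (1 + effect_size)."""

    base: SyntheticSpec
    n_per_group: int = 20
    affected_band: str = "intermediate"
    effect_size: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if not (-1.0 <= self.effect_size <= 1.0):
            raise ValueError("effect_size must be in [-1, 1]")
        if self.affected_band not in {b.name for b in self.base.bands}:
            raise ValueError(
                f"affected_band {self.affected_band!r} not among base bands"
            )
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")


def _subject_seed(cohort_seed: int, index: int) -> int:
    ss = np.random.SeedSequence(entropy=cohort_seed, spawn_key=(index,))
    return int(ss.generate_state(1)[0] % (2**31))


def generate_cohort(
    cspec: SyntheticCohortSpec,
) -> list[tuple[str, BoldMatrix, int]]:
    """Generate a balanced labelled cohort of synthetic subjects.

    Subjects 0..n-1 are group A (label 0, base spec); subjects n..2n-1
    are group B (label 1, affected-band amplitude scaled by
    1 + effect_size).  Per-subject seeds derive deterministically from
    ``cspec.seed``, so two calls with the same spec are bit-identical.
    """
    amps_b = dict(cspec.base.amplitude_per_band)
    amps_b[cspec.affected_band] *= 1.0 + cspec.effect_size
    cohort: list[tuple[str, BoldMatrix, int]] = []
    for idx in range(2 * cspec.n_per_group):
        label = 0 if idx < cspec.n_per_group else 1
        spec = replace(
            cspec.base,
            amplitude_per_band=amps_b if label == 1 else dict(cspec.base.amplitude_per_band),
            communities_per_band=dict(cspec.base.communities_per_band),
            seed=_subject_seed(cspec.seed, idx),
        )
        bold, _ = generate_bold(spec)
        cohort.append((f"sub-{idx:03d}", bold, label))
    return cohort


def generate_atlas(
    n_regions: int = 90,
    bounding_box: tuple[Sequence[float], Sequence[float]] = ((0.0, 0.0, 0.0), (10.0, 10.0, 10.0)),
) -> RegionAtlas:
    """Region centers on a regular grid inside a bounding box.

    A synthetic stand-in for an anatomical parcellation table: labels
    1..n_regions, centers evenly spaced on the smallest grid that holds
    them, placed at cell midpoints.
    """
    if n_regions < 1:
        raise ValueError("n_regions must be >= 1")
    lo = np.asarray(bounding_box[0], dtype=float)
    hi = np.asarray(bounding_box[1], dtype=float)
    if lo.shape != (3,) or hi.shape != (3,) or np.any(hi <= lo):
        raise ValueError("bounding_box must be two 3-vectors with hi > lo")
    side = int(np.ceil(n_regions ** (1.0 / 3.0)))
    axes = [lo[d] + (hi[d] - lo[d]) * (np.arange(side) + 0.5) / side for d in range(3)]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    centers = np.column_stack([xx.ravel(order="F"), yy.ravel(order="F"), zz.ravel(order="F")])
    centers = centers[:n_regions]
    names = [f"R{i}" for i in range(1, n_regions + 1)]
    return RegionAtlas(centers=centers, names=names)
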