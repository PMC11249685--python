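"""Patient-level averaging and low-level fusion into the fused fingerprint.

One preprocessed mean spectrum per patient per modality is concatenated,
Raman first then NIR-SWIR, both segments ordered high-to-low wavenumber on
their native grids (no resampling). With the default grids the fingerprint
has 1011 Raman points followed by 512 NIR-SWIR points (1523 total), and a
SegmentMap makes every fingerprint index translatable back to its modality
and wavenumber.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import vector_normalize
from .spectrum import Spectrum


@dataclass(frozen=True)
class Segment:
    """One contiguous fingerprint block owned by a single modality."""

    modality: str
    start: int  # inclusive, 0-based
    stop: int  # exclusive
    axis: np.ndarray  # native wavenumber grid, high -> low

    def __post_init__(self) -> None:
        if self.stop - self.start != len(self.axis):
            raise ValueError("segment span must equal its axis length")


@dataclass(frozen=True)
class SegmentMap:
    """Ordered, contiguous, non-overlapping cover of 0..total_length."""

    segments: tuple[Segment, ...]

    def __post_init__(self) -> None:
        pos = 0
        for seg in self.segments:
            if seg.start != pos:
                raise ValueError("segments must be contiguous from index 0")
            pos = seg.stop
        if pos == 0:
            raise ValueError("segment map cannot be empty")

    @property
    def total_length(self) -> int:
        return self.segments[-1].stop

    def segment_for(self, modality: str) -> Segment:
        for seg in self.segments:
            if seg.modality == modality:
                return seg
        raise KeyError(modality)

    def junction_indices(self) -> set[int]:
        """The index pairs flanking each internal segment boundary."""
        out: set[int] = set()
        for seg in self.segments[:-1]:
            out.update((seg.stop - 1, seg.stop))
        return out


@dataclass
class SpectromicsFingerprint:
    """A patient's fused vector plus the map back to wavenumber space."""

    patient_id: str | None
    class_label: str | None
    values: np.ndarray
    segment_map: SegmentMap

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size != self.segment_map.total_length:
            raise ValueError("fingerprint length must match its segment map")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("fingerprint values must be finite")


def patient_mean_spectrum(spectra: list[Spectrum]) -> Spectrum:
    """Pointwise mean of one patient's preprocessed spectra, re-normalized.

    All spectra must share one axis and modality. The mean is re-scaled to
    unit Euclidean norm so both modalities enter the fingerprint at
    compatible magnitude.
    """
    if not spectra:
        raise ValueError("patient_mean_spectrum needs at least one spectrum")
    first = spectra[0]
    for s in spectra[1:]:
        if s.modality != first.modality:
            raise ValueError("cannot average spectra of mixed modality")
        if not np.array_equal(s.wavenumbers, first.wavenumbers):
            raise ValueError("cannot average spectra on mixed axes")
    stack = np.vstack([s.intensities for s in spectra])
    # canonical row order makes the floating-point sum exactly
    # permutation-invariant
    stack = stack[np.lexsort(stack.T[::-1])]
    mean = stack.mean(axis=0)
    return vector_normalize(first.with_intensities(mean))


def concatenate_fingerprint(
    raman_mean: Spectrum, nirswir_mean: Spectrum
) -> SpectromicsFingerprint:
    """Fuse one patient's mean Raman and mean NIR-SWIR spectra.

    Both segments are stored high-to-low wavenumber; inputs on ascending
    axes are flipped, never resampled or rescaled.
    """
    if raman_mean.modality == nirswir_mean.modality:
        raise ValueError("fingerprint needs one spectrum of each modality")
    if raman_mean.modality != "Raman":
        raman_mean, nirswir_mean = nirswir_mean, raman_mean
    if (
        raman_mean.patient_id is not None
        and nirswir_mean.patient_id is not None
        and raman_mean.patient_id != nirswir_mean.patient_id
    ):
        raise ValueError("cannot fuse spectra from different patients")

    parts = []
    segments = []
    pos = 0
    for spec in (raman_mean, nirswir_mean):
        wn = spec.wavenumbers
        vals = spec.intensities
        if wn[0] < wn[-1]:  # enforce the high->low convention
            wn = wn[::-1]
            vals = vals[::-1]
        parts.append(vals)
        segments.append(
            Segment(spec.modality, pos, pos + wn.size, np.array(wn))
        )
        pos += wn.size

    return SpectromicsFingerprint(
        patient_id=raman_mean.patient_id,
        class_label=raman_mean.class_label or nirswir_mean.class_label,
        values=np.concatenate(parts),
        segment_map=SegmentMap(tuple(segments)),
    )


def map_index_to_band(index: int, segment_map: SegmentMap) -> tuple[str, float]:
    """Translate a fingerprint index to (modality, wavenumber in cm^-1)."""
    if not 0 <= index < segment_map.total_length:
        raise IndexError(
            f"fingerprint index {index} outside [0, {segment_map.total_length})"
        )
    for seg in segment_map.segments:
        if seg.start <= index < seg.stop:
            return seg.modality, float(seg.axis[index - seg.start])
    raise IndexError(index)  # unreachable: map covers the range
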