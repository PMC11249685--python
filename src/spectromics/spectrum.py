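"""Core spectral containers shared by every stage of the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

RAMAN = "Raman"
NIRSWIR = "NIRSWIR"
MODALITIES = (RAMAN, NIRSWIR)

CONTROL = "Control"
OA = "OA"
CLASSES = (CONTROL, OA)


@dataclass(frozen=True)
class AxisSpec:
    """A uniform wavenumber grid for one modality.

    Axes are stored high-to-low wavenumber for both modalities; this is the
    concatenation convention used throughout the package.
    """

    start_wavenumber: float
    end_wavenumber: float
    n_points: int
    modality: str

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError("AxisSpec requires n_points >= 2")
        if self.start_wavenumber == self.end_wavenumber:
            raise ValueError("AxisSpec start and end wavenumbers must differ")
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")

    def values(self) -> np.ndarray:
        """Strictly monotone axis values (cm^-1)."""
        return np.linspace(
            self.start_wavenumber, self.end_wavenumber, self.n_points
        )


#: Default Raman grid: 1011 points spanning 1722–614 cm^-1 (stored high→low).
RAMAN_AXIS = AxisSpec(1722.0, 614.0, 1011, RAMAN)
#: Default NIR-SWIR grid: 512 points spanning 11127–3993 cm^-1.
NIRSWIR_AXIS = AxisSpec(11127.0, 3993.0, 512, NIRSWIR)

DEFAULT_AXES = {RAMAN: RAMAN_AXIS, NIRSWIR: NIRSWIR_AXIS}


@dataclass
class Spectrum:
    """One single-point measurement: a wavenumber axis plus intensities.

    Parameters
    ----------
    wavenumbers : array, cm^-1, strictly monotone
    intensities : array, arbitrary units, same length, finite
    modality : "Raman" or "NIRSWIR"
    patient_id, sample_id : metadata carried through the pipeline
    class_label : "Control" or "OA" (may be None for unlabeled data)
    """

    wavenumbers: np.ndarray
    intensities: np.ndarray
    modality: str
    patient_id: str | None = None
    sample_id: str | None = None
    class_label: str | None = None

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavenumbers.ndim != 1 or self.intensities.ndim != 1:
            raise ValueError("wavenumbers and intensities must be 1-D")
        if self.wavenumbers.shape != self.intensities.shape:
            raise ValueError(
                "wavenumbers and intensities must have equal length "
                f"({self.wavenumbers.size} != {self.intensities.size})"
            )
        d = np.diff(self.wavenumbers)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("axis must be strictly monotone")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.class_label is not None and self.class_label not in CLASSES:
            raise ValueError(f"unknown class label {self.class_label!r}")

    @property
    def n_points(self) -> int:
        return self.wavenumbers.size

    def with_intensities(self, intensities: np.ndarray) -> "Spectrum":
        """Copy of this spectrum with new intensities on the same axis."""
        return replace(self, intensities=np.asarray(intensities, dtype=float))
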