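"""Synthetic cartilage cohort generator.

Generates cohorts of raw Raman and NIR-SWIR spectra with known, configurable
Control-vs-OA differences so that every downstream stage (preprocessing,
fusion, classification, biomarker mining) can be exercised and validated
without access to patient data.

The model for one raw spectrum is a sum of Gaussian bands on top of a
slowly varying background plus white noise:

    I(nu) = sum_b A_b * exp(-(nu - c_b)^2 / (2 w_b^2)) + B(nu) + eps(nu)

with A_b = base_amplitude_b * (1 + oa_effect_b * effect_size * [class=OA])
          * patient_effect_b.

Patient effects are log-normal multipliers drawn once per patient per band,
emulating between-patient biochemical heterogeneity; the background B is a
random low-order polynomial (fluorescence-like for Raman, offset-plus-slope
scattering trend for NIR-SWIR); eps is i.i.d. Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .spectrum import (
    CONTROL,
    NIRSWIR,
    NIRSWIR_AXIS,
    OA,
    RAMAN,
    RAMAN_AXIS,
    AxisSpec,
    Spectrum,
)


@dataclass(frozen=True)
class BandSpec:
    """One Gaussian band with an optional multiplicative OA class effect.

    ``oa_effect`` is the fractional amplitude change in the OA class at
    effect_size 1 (e.g. -0.2 means 20% lower in OA).
    """

    center: float
    width: float
    base_amplitude: float
    oa_effect: float = 0.0
    assignment: str = ""

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("band width must be positive")
        if self.base_amplitude < 0:
            raise ValueError("band base_amplitude must be non-negative")


# Default band tables. Centers follow the cartilage band-assignment table
# (reference.BAND_ASSIGNMENTS) plus a few strong non-discriminating tissue
# bands; widths reflect the two instruments' very different resolutions.
# Directions: matrix bands (amide I, sGAG, GAG, amide III, PG/N-H, ECM C-H)
# decrease in OA, water bands increase.
DEFAULT_RAMAN_BANDS: tuple[BandSpec, ...] = (
    BandSpec(1004.0, 8.0, 0.55, 0.0, "phenylalanine ring breathing"),
    BandSpec(1063.5, 10.0, 0.80, -0.20, "SO3- symmetric stretch (sGAG)"),
    BandSpec(1250.0, 14.0, 0.90, -0.12, "amide III (C-N stretch)"),
    BandSpec(1338.0, 12.0, 0.70, -0.15, "CH wagging (GAG)"),
    BandSpec(1450.0, 12.0, 1.00, 0.0, "CH2 deformation"),
    BandSpec(1616.5, 9.0, 0.50, -0.18, "amide I"),
    BandSpec(1665.0, 16.0, 1.20, 0.0, "amide I (collagen backbone)"),
)

DEFAULT_NIRSWIR_BANDS: tuple[BandSpec, ...] = (
    BandSpec(4385.0, 120.0, 0.50, -0.12, "C-H bend 2nd overtone (ECM)"),
    BandSpec(5345.0, 160.0, 1.00, 0.30, "water combination band"),
    BandSpec(6500.0, 150.0, 0.60, -0.22, "N-H stretch 1st overtone (PG)"),
    BandSpec(7120.0, 170.0, 0.80, 0.15, "O-H stretch 1st overtone (water)"),
    BandSpec(8755.0, 150.0, 0.40, -0.08, "C-H stretch 2nd overtone"),
)

#: Centers of the default bands that carry a class effect, per modality.
PLANTED_BIOMARKERS = {
    RAMAN: tuple(b.center for b in DEFAULT_RAMAN_BANDS if b.oa_effect != 0.0),
    NIRSWIR: tuple(
        b.center for b in DEFAULT_NIRSWIR_BANDS if b.oa_effect != 0.0
    ),
}


def complementary_band_tables(
    raman_effect: float = -0.08,
    nirswir_effect: float = 0.06,
) -> tuple[tuple[BandSpec, ...], tuple[BandSpec, ...]]:
    """Band tables where each modality carries partial, complementary signal.

    Only the sulphated-GAG Raman band and the water-combination NIR-SWIR
    band discriminate, at deliberately weak effects, so neither modality
    alone classifies perfectly and fusion can pool the two signals.
    """
    from dataclasses import replace

    raman = tuple(
        replace(b, oa_effect=(raman_effect if b.center == 1063.5 else 0.0))
        for b in DEFAULT_RAMAN_BANDS
    )
    nirswir = tuple(
        replace(b, oa_effect=(nirswir_effect if b.center == 5345.0 else 0.0))
        for b in DEFAULT_NIRSWIR_BANDS
    )
    return raman, nirswir


@dataclass(frozen=True)
class CohortConfig:
    """Study-design parameters of a synthetic cohort.

    Defaults mirror the study conditions: 14 Control and 13 OA patients,
    3 samples per patient, 10 spectra per sample (30 spectra per patient
    per modality).
    """

    n_control: int = 14
    n_oa: int = 13
    samples_per_patient: int = 3
    spectra_per_sample: int = 10
    effect_size: float = 1.0
    noise_sd: float = 0.02
    baseline_order: int = 3
    baseline_scale: float = 1.5
    patient_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_control",
            "n_oa",
            "samples_per_patient",
            "spectra_per_sample",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.patient_sd < 0:
            raise ValueError("patient_sd must be >= 0")
        if self.baseline_order < 0:
            raise ValueError("baseline_order must be >= 0")

    @property
    def n_patients(self) -> int:
        return self.n_control + self.n_oa

    @property
    def spectra_per_modality(self) -> int:
        return (
            self.n_patients * self.samples_per_patient * self.spectra_per_sample
        )


def generate_spectrum(
    axis: AxisSpec,
    bands: list[BandSpec] | tuple[BandSpec, ...],
    class_label: str,
    patient_effect: np.ndarray | None = None,
    noise_sd: float = 0.0,
    baseline_coeffs: np.ndarray | None = None,
    effect_size: float = 1.0,
    rng: np.random.Generator | None = None,
    patient_id: str | None = None,
    sample_id: str | None = None,
) -> Spectrum:
    """Render one raw spectrum from the generative model.

    ``patient_effect`` holds one multiplier per band (defaults to ones);
    ``baseline_coeffs`` are ordinary polynomial coefficients in the
    normalized axis coordinate t in [0, 1] (defaults to no background).
    Reproducible for a fixed rng state.
    """
    nu = axis.values()
    lo, hi = min(nu[0], nu[-1]), max(nu[0], nu[-1])
    if patient_effect is None:
        patient_effect = np.ones(len(bands))
    patient_effect = np.asarray(patient_effect, dtype=float)
    if patient_effect.shape != (len(bands),):
        raise ValueError("patient_effect must hold one multiplier per band")

    y = np.zeros_like(nu)
    is_oa = class_label == OA
    for b, pe in zip(bands, patient_effect):
        if not (lo <= b.center <= hi):
            raise ValueError(
                f"band at {b.center} cm^-1 lies outside the "
                f"{axis.modality} axis range [{lo}, {hi}]"
            )
        amp = b.base_amplitude * (
            1.0 + (b.oa_effect * effect_size if is_oa else 0.0)
        )
        amp = max(amp, 0.0) * pe
        y += amp * np.exp(-((nu - b.center) ** 2) / (2.0 * b.width**2))

    if baseline_coeffs is not None:
        t = (nu - lo) / (hi - lo)
        y += np.polynomial.polynomial.polyval(t, baseline_coeffs)

    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        y = y + rng.normal(0.0, noise_sd, size=nu.size)

    return Spectrum(
        wavenumbers=nu,
        intensities=y,
        modality=axis.modality,
        patient_id=patient_id,
        sample_id=sample_id,
        class_label=class_label,
    )


@dataclass
class Cohort:
    """A generated cohort: spectra per modality, metadata, and provenance."""

    raman: list[Spectrum]
    nirswir: list[Spectrum]
    metadata: pd.DataFrame
    config: CohortConfig

    @property
    def seed(self) -> int:
        return self.config.seed

    def spectra(self, modality: str) -> list[Spectrum]:
        return self.raman if modality == RAMAN else self.nirswir


def _baseline_coeffs(
    rng: np.random.Generator, modality: str, order: int, scale: float
) -> np.ndarray:
    """Random smooth background: fluorescence-like polynomial for Raman,
    offset + scattering slope for NIR-SWIR."""
    if modality == RAMAN:
        k = np.arange(order + 1)
        return rng.normal(0.0, scale / (k + 1.0))
    offset = rng.uniform(0.1, 0.4) * scale
    slope = rng.normal(0.0, 0.3) * scale
    return np.array([offset, slope])


def generate_cohort(
    config: CohortConfig | None = None,
    raman_bands: tuple[BandSpec, ...] = DEFAULT_RAMAN_BANDS,
    nirswir_bands: tuple[BandSpec, ...] = DEFAULT_NIRSWIR_BANDS,
    raman_axis: AxisSpec = RAMAN_AXIS,
    nirswir_axis: AxisSpec = NIRSWIR_AXIS,
) -> Cohort:
    """Generate a full paired Raman + NIR-SWIR cohort.

    Patient-level band multipliers are drawn once per patient (shared by
    all of that patient's spectra in the modality), so within-patient
    replicates differ only through their backgrounds and noise.
    Deterministic for a fixed ``config`` (the seed is part of it).
    """
    if config is None:
        config = CohortConfig()
    rng = np.random.default_rng(config.seed)

    classes = [CONTROL] * config.n_control + [OA] * config.n_oa
    patients = [f"P{i + 1:02d}" for i in range(config.n_patients)]

    collections: dict[str, list[Spectrum]] = {RAMAN: [], NIRSWIR: []}
    rows = []
    for pid, cls in zip(patients, classes):
        effects = {
            RAMAN: rng.lognormal(
                0.0, config.patient_sd, size=len(raman_bands)
            ),
            NIRSWIR: rng.lognormal(
                0.0, config.patient_sd, size=len(nirswir_bands)
            ),
        }
        for s in range(1, config.samples_per_patient + 1):
            sid = f"{pid}-S{s}"
            for r in range(1, config.spectra_per_sample + 1):
                for axis, bands in (
                    (raman_axis, raman_bands),
                    (nirswir_axis, nirswir_bands),
                ):
                    coeffs = _baseline_coeffs(
                        rng,
                        axis.modality,
                        config.baseline_order,
                        config.baseline_scale,
                    )
                    spec = generate_spectrum(
                        axis,
                        bands,
                        cls,
                        patient_effect=effects[axis.modality],
                        noise_sd=config.noise_sd,
                        baseline_coeffs=coeffs,
                        effect_size=config.effect_size,
                        rng=rng,
                        patient_id=pid,
                        sample_id=sid,
                    )
                    collections[axis.modality].append(spec)
                    rows.append(
                        {
                            "measurement_id": f"{sid}-R{r}-{axis.modality}",
                            "patient_id": pid,
                            "sample_id": sid,
                            "class": cls,
                            "modality": axis.modality,
                        }
                    )

    metadata = pd.DataFrame(rows)
    return Cohort(
        raman=collections[RAMAN],
        nirswir=collections[NIRSWIR],
        metadata=metadata,
        config=config,
    )
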