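"""Reading and writing the wide delimited-text interchange format.

A spectra file holds the wavenumber axis in its first column and one column
per measurement id; a metadata sidecar (CSV/TSV) holds one row per
measurement column with measurement_id, patient_id, sample_id, class and
modality. The delimiter is auto-detected among comma and tab; the decimal
point is '.'.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .spectrum import CLASSES, MODALITIES, Spectrum
from .synthetic import Cohort

SIDECAR_COLUMNS = [
    "measurement_id",
    "patient_id",
    "sample_id",
    "class",
    "modality",
]


def _detect_delimiter(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


def read_spectra(path, sidecar_path) -> list[Spectrum]:
    """Read a wide spectra file plus its metadata sidecar.

    Every measurement column must have exactly one sidecar row; the axis
    must be strictly monotone. Errors name the offending row or column.
    """
    path = Path(path)
    sidecar_path = Path(sidecar_path)
    table = pd.read_csv(path, sep=_detect_delimiter(path))
    meta = pd.read_csv(sidecar_path, sep=_detect_delimiter(sidecar_path))

    missing = [c for c in SIDECAR_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"sidecar {sidecar_path} lacks columns {missing}")
    if meta["measurement_id"].duplicated().any():
        dupes = meta.loc[
            meta["measurement_id"].duplicated(), "measurement_id"
        ].tolist()
        raise ValueError(f"duplicated measurement ids in sidecar: {dupes}")

    axis_col = table.columns[0]
    axis = pd.to_numeric(table[axis_col], errors="coerce")
    if axis.isna().any():
        rows = (axis.index[axis.isna()] + 2).tolist()  # 1-based + header
        raise ValueError(
            f"non-numeric axis values in column {axis_col!r}, file rows {rows}"
        )
    axis = axis.to_numpy(dtype=float)
    d = np.diff(axis)
    if not (np.all(d > 0) or np.all(d < 0)):
        bad = (np.flatnonzero(np.sign(d) != np.sign(d[0])) + 2).tolist()
        raise ValueError(
            f"axis in {path} is not strictly monotone (check rows {bad})"
        )

    meta_by_id = meta.set_index("measurement_id")
    spectra = []
    for col in table.columns[1:]:
        if col not in meta_by_id.index:
            raise ValueError(
                f"measurement column {col!r} has no sidecar row in"
                f" {sidecar_path}"
            )
        vals = pd.to_numeric(table[col], errors="coerce")
        if vals.isna().any():
            rows = (vals.index[vals.isna()] + 2).tolist()
            raise ValueError(
                f"non-numeric cells in measurement column {col!r}, rows {rows}"
            )
        row = meta_by_id.loc[col]
        if row["modality"] not in MODALITIES:
            raise ValueError(
                f"sidecar row {col!r} has unknown modality {row['modality']!r}"
            )
        if row["class"] not in CLASSES:
            raise ValueError(
                f"sidecar row {col!r} has unknown class {row['class']!r}"
            )
        spectra.append(
            Spectrum(
                wavenumbers=axis,
                intensities=vals.to_numpy(dtype=float),
                modality=row["modality"],
                patient_id=str(row["patient_id"]),
                sample_id=str(row["sample_id"]),
                class_label=row["class"],
            )
        )
    return spectra


def write_spectra(
    spectra: list[Spectrum],
    path,
    sidecar_path,
    measurement_ids: list[str] | None = None,
    delimiter: str = ",",
) -> None:
    """Write spectra sharing one axis to the wide format plus sidecar."""
    if not spectra:
        raise ValueError("no spectra to write")
    axis = spectra[0].wavenumbers
    for s in spectra[1:]:
        if not np.array_equal(s.wavenumbers, axis):
            raise ValueError("all spectra in one file must share the axis")
    if measurement_ids is None:
        measurement_ids = [f"M{i + 1:04d}" for i in range(len(spectra))]
    if len(measurement_ids) != len(spectra):
        raise ValueError("need one measurement id per spectrum")

    data = {"wavenumber_cm-1": axis}
    rows = []
    for mid, s in zip(measurement_ids, spectra):
        data[mid] = s.intensities
        rows.append(
            {
                "measurement_id": mid,
                "patient_id": s.patient_id or "",
                "sample_id": s.sample_id or "",
                "class": s.class_label or "",
                "modality": s.modality,
            }
        )
    pd.DataFrame(data).to_csv(path, sep=delimiter, index=False)
    pd.DataFrame(rows, columns=SIDECAR_COLUMNS).to_csv(
        sidecar_path, sep=delimiter, index=False
    )


def write_cohort(cohort: Cohort, out_dir) -> dict[str, Path]:
    """Write a generated cohort: one file pair per modality + a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for modality, spectra in (("Raman", cohort.raman), ("NIRSWIR", cohort.nirswir)):
        ids = cohort.metadata.loc[
            cohort.metadata["modality"] == modality, "measurement_id"
        ].tolist()
        spath = out / f"{modality.lower()}_spectra.csv"
        mpath = out / f"{modality.lower()}_metadata.csv"
        write_spectra(spectra, spath, mpath, measurement_ids=ids)
        paths[f"{modality.lower()}_spectra"] = spath
        paths[f"{modality.lower()}_metadata"] = mpath

    manifest = out / "manifest.yaml"
    with open(manifest, "w") as fh:
        yaml.safe_dump(
            {
                "seed": cohort.seed,
                "config": {
                    k: getattr(cohort.config, k)
                    for k in cohort.config.__dataclass_fields__
                },
            },
            fh,
            sort_keys=True,
        )
    paths["manifest"] = manifest
    return paths


def write_fingerprint_matrix(fingerprints, path, sidecar_path) -> None:
    """Write patient fingerprints as a wide table + segment-map sidecar."""
    if not fingerprints:
        raise ValueError("no fingerprints to write")
    segmap = fingerprints[0].segment_map
    data = {"fingerprint_index": np.arange(segmap.total_length)}
    for fp in fingerprints:
        data[fp.patient_id or "patient"] = fp.values
    pd.DataFrame(data).to_csv(path, index=False)

    seg_rows = [
        {
            "modality": seg.modality,
            "start_index": seg.start,
            "stop_index": seg.stop,
            "wavenumber_first": float(seg.axis[0]),
            "wavenumber_last": float(seg.axis[-1]),
        }
        for seg in segmap.segments
    ]
    pd.DataFrame(seg_rows).to_csv(sidecar_path, index=False)
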