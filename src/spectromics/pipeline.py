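"""End-to-end pipeline: simulate/read → preprocess → fuse → classify →
biomarkers, with a serializable run configuration and result bundle."""

from __future__ import annotations

import hashlib
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import (
    PCALDA,
    SvmConfig,
    SpectromicsSVM,
    quality_parameters,
)
from .features import corroborate, corroborate_nir_assignment, extract_all_features
from .fusion import concatenate_fingerprint, patient_mean_spectrum
from .io import read_spectra, write_fingerprint_matrix
from .preprocess import preprocess
from .spectrum import CONTROL, NIRSWIR, OA, RAMAN
from .synthetic import Cohort, CohortConfig, generate_cohort

log = logging.getLogger("spectromics")

FINGERPRINT_SETS = (RAMAN, NIRSWIR, "Concatenated")


@dataclass
class RunConfig:
    """Fully resolved configuration of one pipeline run."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    raman_path: str | None = None  # read instead of simulate when set
    raman_sidecar: str | None = None
    nirswir_path: str | None = None
    nirswir_sidecar: str | None = None
    n_pcs: tuple[int, ...] = (20, 10, 5)
    svm_k: int = 3
    svm_repeats: int = 1
    feature_window: int = 5
    feature_min_hits: int = 3
    feature_alpha: float = 0.01
    ffs_repeats: int = 100
    seed: int = 0
    out_dir: str | None = None

    def to_yaml(self) -> str:
        d = asdict(self)
        d["n_pcs"] = list(self.n_pcs)
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        d = yaml.safe_load(text)
        cohort = CohortConfig(**d.pop("cohort"))
        d["n_pcs"] = tuple(d.get("n_pcs", (20, 10, 5)))
        return cls(cohort=cohort, **d)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]


@dataclass
class PipelineResults:
    """Everything one run produces."""

    fingerprints: dict[str, np.ndarray]  # per fingerprint set: (n, p) matrix
    labels: np.ndarray
    patient_ids: list[str]
    fused: list  # SpectromicsFingerprint per patient
    pcalda_table: pd.DataFrame
    svm_table: pd.DataFrame
    regions: list
    traces: dict[str, list]
    manifest: dict


def patient_fingerprints(
    cohort_like: Cohort | tuple[list, list],
) -> tuple[dict[str, np.ndarray], np.ndarray, list[str], list]:
    """Preprocess every spectrum, average per patient per modality, fuse.

    Returns the three fingerprint matrices (Raman, NIR-SWIR, Concatenated),
    the label vector, the patient ids, and the fused fingerprint objects.
    """
    if isinstance(cohort_like, Cohort):
        raman, nirswir = cohort_like.raman, cohort_like.nirswir
    else:
        raman, nirswir = cohort_like

    processed: dict[str, dict[str, list]] = {RAMAN: {}, NIRSWIR: {}}
    classes: dict[str, str] = {}
    for spec in list(raman) + list(nirswir):
        out, _trace = preprocess(spec)
        processed[spec.modality].setdefault(spec.patient_id, []).append(out)
        classes[spec.patient_id] = spec.class_label

    patients = sorted(classes)
    means = {
        mod: {
            pid: patient_mean_spectrum(processed[mod][pid]) for pid in patients
        }
        for mod in (RAMAN, NIRSWIR)
    }
    fused = [
        concatenate_fingerprint(means[RAMAN][pid], means[NIRSWIR][pid])
        for pid in patients
    ]
    X = {
        RAMAN: np.vstack([means[RAMAN][p].intensities for p in patients]),
        NIRSWIR: np.vstack([means[NIRSWIR][p].intensities for p in patients]),
        "Concatenated": np.vstack([fp.values for fp in fused]),
    }
    labels = np.array([classes[p] for p in patients])
    return X, labels, patients, fused


def run_pipeline(config: RunConfig) -> PipelineResults:
    """Execute the full analysis and return (and optionally write) results.

    Classification covers all three fingerprint sets; biomarker mining runs
    on the concatenated fingerprint only.
    """

    def _stage(name):
        log.info("stage: %s", name)

    _stage("load")
    if config.raman_path:
        try:
            raman = read_spectra(config.raman_path, config.raman_sidecar)
            nirswir = read_spectra(
                config.nirswir_path, config.nirswir_sidecar
            )
        except Exception as exc:  # annotate with the stage name
            raise RuntimeError(f"stage 'load' failed: {exc}") from exc
        source = {"raman_path": str(config.raman_path)}
        cohort_like: Cohort | tuple = (raman, nirswir)
    else:
        cohort = generate_cohort(config.cohort)
        source = {"simulated": True, "cohort_seed": cohort.seed}
        cohort_like = cohort
    log.info("seed: %s", config.seed)
    log.info("raman chain: poly_baseline(5) > wavelet(6,haar) > rubberband >"
             " vector_normalize")
    log.info("nirswir chain: first_derivative > sg_smooth(2,9) > rubberband >"
             " wavelet(6,haar) > vector_normalize")

    _stage("preprocess+fuse")
    try:
        X, labels, patients, fused = patient_fingerprints(cohort_like)
    except Exception as exc:
        raise RuntimeError(f"stage 'preprocess+fuse' failed: {exc}") from exc

    _stage("classify")
    pcalda_rows = []
    for n_pcs in config.n_pcs:
        for name in FINGERPRINT_SETS:
            res = PCALDA(X[name], labels).fit(n_pcs)
            q = quality_parameters(res.confusion()).rounded()
            sep = res.mahalanobis_separation()
            pcalda_rows.append(
                {
                    "n_pcs": n_pcs,
                    "fingerprint": name,
                    **q.as_dict(),
                    "mahalanobis_mean_diff": round(sep.mean_difference, 4),
                    "mahalanobis_median_diff": round(sep.median_difference, 4),
                }
            )
    pcalda_table = pd.DataFrame(pcalda_rows)

    svm_rows = []
    for scheme in ("kfold", "loo"):
        for name in FINGERPRINT_SETS:
            cfg = SvmConfig(
                cv_scheme=scheme,
                k=config.svm_k,
                repeats=config.svm_repeats if scheme == "kfold" else 1,
                seed=config.seed,
            )
            cv = SpectromicsSVM(X[name], labels, cfg).cross_validate()
            q = cv.quality.rounded()
            svm_rows.append(
                {
                    "cv": "3-fold" if scheme == "kfold" else "loo",
                    "fingerprint": name,
                    **q.as_dict(),
                    "tp": cv.counts.tp,
                    "tn": cv.counts.tn,
                    "fp": cv.counts.fp,
                    "fn": cv.counts.fn,
                }
            )
    svm_table = pd.DataFrame(svm_rows)

    _stage("features")
    feat_model = PCALDA(X["Concatenated"], labels).fit(min(config.n_pcs))
    scores = extract_all_features(
        X["Concatenated"],
        labels,
        feat_model,
        alpha=config.feature_alpha,
        ffs_repeats=config.ffs_repeats,
        seed=config.seed,
    )
    segmap = fused[0].segment_map
    regions = corroborate(
        scores,
        segmap,
        window=config.feature_window,
        min_hits=config.feature_min_hits,
    )
    nir_mean_zero_order = None
    if isinstance(cohort_like, Cohort):
        # zero-order (raw) NIR-SWIR class-agnostic mean for attribution
        raw = cohort_like.nirswir
        nir_mean_zero_order = raw[0].with_intensities(
            np.mean([s.intensities for s in raw], axis=0)
        )
    regions = [
        corroborate_nir_assignment(r, nir_mean_zero_order)
        if r.modality == NIRSWIR and nir_mean_zero_order is not None
        else r
        for r in regions
    ]

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "source": source,
        "n_patients": len(patients),
        "n_control": int(np.sum(labels == CONTROL)),
        "n_oa": int(np.sum(labels == OA)),
    }

    results = PipelineResults(
        fingerprints=X,
        labels=labels,
        patient_ids=patients,
        fused=fused,
        pcalda_table=pcalda_table,
        svm_table=svm_table,
        regions=regions,
        traces={},
        manifest=manifest,
    )

    if config.out_dir:
        _write_results(config, results)
    return results


def _write_results(config: RunConfig, results: PipelineResults) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results.pcalda_table.to_csv(out / "pcalda_quality.csv", index=False)
    results.svm_table.to_csv(out / "svm_quality.csv", index=False)
    region_rows = [
        {
            "modality": r.modality,
            "wavenumber_high": r.wavenumber_high,
            "wavenumber_low": r.wavenumber_low,
            "hit_count": r.hit_count,
            "tests": "+".join(r.tests),
            "assignment": r.assignment or "",
            "zero_order_attribution": r.zero_order_attribution or "",
        }
        for r in results.regions
    ]
    pd.DataFrame(
        region_rows,
        columns=[
            "modality",
            "wavenumber_high",
            "wavenumber_low",
            "hit_count",
            "tests",
            "assignment",
            "zero_order_attribution",
        ],
    ).to_csv(out / "biomarker_regions.csv", index=False)
    write_fingerprint_matrix(
        results.fused, out / "fingerprints.csv", out / "segment_map.csv"
    )
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(results.manifest, fh, sort_keys=True)
    with open(out / "config.yaml", "w") as fh:
        fh.write(config.to_yaml())
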