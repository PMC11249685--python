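"""Biomarker mining over the fused fingerprint.

Six independent feature scorers rank fingerprint indices by how strongly
they separate Control from OA patients:

* ``lda_loadings_features`` — highest |loading| indices of the 3 PCs that
  carry the largest |LD weight|;
* ``cluster_vector_features`` — class centroids back-projected through the
  top discriminant PCs; the class-difference vector ranks indices;
* ``dbms`` — differences between the class mean spectra;
* ``pointwise_tests`` — per-index Student t and Mann-Whitney U tests,
  scored as -log10(p), peaks above p < alpha;
* ``feature_forward_selection`` — greedy forward selection of features for
  a small linear discriminant over repeated random 90/10 splits; the
  selection histogram ranks indices.

Agreement between the scorers' top lists is then counted by
:func:`corroborate`: indices within a small window merge into regions whose
hit count is the number of distinct tests landing there. Regions reaching
the hit threshold are translated back to modality + wavenumber and
annotated from the packaged cartilage band table. NIR-SWIR regions can be
attributed to zero-order band positions via first/second-derivative
corroboration (:func:`corroborate_nir_assignment`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.signal import find_peaks

from .classify import PCALDAResults, _as_labels
from .fusion import SegmentMap
from .reference import lookup_assignment
from .spectrum import CONTROL, NIRSWIR, OA, Spectrum

TOP_N_DEFAULT = 20
FFS_TOP_N = 7


def _peak_ranked_indices(
    score: np.ndarray, n_top: int, min_separation: int = 5
) -> list[int]:
    """Indices of the highest local maxima of |score|, tallest first.

    Ranking peaks rather than raw indices keeps one strong band from
    filling the whole list with its contiguous neighbours; peaks closer
    than ``min_separation`` points (the corroboration merge window, so one
    candidate per resolvable region) are thinned to the tallest. When
    fewer than ``n_top`` interior peaks exist (tiny or monotone inputs)
    the list is padded with the remaining indices by |score|; ties break
    toward the lower index.
    """
    mag = np.abs(score)
    peaks, _ = find_peaks(mag, distance=min_separation)
    ranked = [int(i) for i in peaks[np.argsort(-mag[peaks], kind="stable")]]
    if len(ranked) < n_top:
        chosen = set(ranked)
        rest = [
            int(i)
            for i in np.argsort(-mag, kind="stable")
            if int(i) not in chosen
        ]
        ranked.extend(rest)
    return ranked[:n_top]


@dataclass
class FeatureScore:
    """One scorer's per-index track and its ranked top indices."""

    test_name: str
    scores: np.ndarray
    top_indices: list[int]
    notes: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# PCA-LDA based scorers
# ---------------------------------------------------------------------------


def _top_discriminant_pcs(results: PCALDAResults, k: int = 3) -> tuple[np.ndarray, list[str]]:
    notes: list[str] = []
    w = np.abs(results.ld_weights)
    if w.size < k:
        notes.append(
            f"only {w.size} PCs available; using all instead of top {k}"
        )
        k = w.size
    order = np.argsort(-w, kind="stable")[:k]
    return order, notes


def lda_loadings_features(
    results: PCALDAResults, n_top: int = TOP_N_DEFAULT
) -> FeatureScore:
    """Top-|loading| indices of the 3 highest-|LD-weight| PCs.

    Each selected PC contributes its loading-magnitude peaks ranked by
    absolute loading; the per-PC rankings are merged rank-interleaved (all
    rank-1 indices first, then rank-2, ...), deduplicated, ties broken
    toward the lower index, and truncated to ``n_top``.
    """
    pcs, notes = _top_discriminant_pcs(results)
    L = results.loadings[:, pcs]  # (p, k)
    w = results.ld_weights[pcs]
    scores = np.abs(L) @ np.abs(w)

    per_pc_rank = [
        _peak_ranked_indices(L[:, j], L.shape[0]) for j in range(L.shape[1])
    ]
    merged: list[int] = []
    seen: set[int] = set()
    for rank in range(max(len(r) for r in per_pc_rank)):
        at_rank = sorted(r[rank] for r in per_pc_rank if rank < len(r))
        for idx in at_rank:
            if idx not in seen:
                seen.add(idx)
                merged.append(idx)
                if len(merged) == n_top:
                    return FeatureScore("lda_loadings", scores, merged, notes)
    return FeatureScore("lda_loadings", scores, merged, notes)


def back_project(
    results: PCALDAResults, score_vector: np.ndarray, pcs: np.ndarray
) -> np.ndarray:
    """Reconstruct a score-space point in fingerprint space through the
    chosen PCs: center + loadings[:, pcs] @ score_vector[pcs]."""
    return results.center + results.loadings[:, pcs] @ np.asarray(
        score_vector, dtype=float
    )[pcs]


def cluster_vector_features(
    results: PCALDAResults, n_top: int = TOP_N_DEFAULT
) -> FeatureScore:
    """Class centroids back-projected through the top discriminant PCs.

    The difference of the two back-projected class centroids is the
    cluster-difference vector; its absolute values rank the indices. When
    the centroids coincide the ranking is flagged as meaningless.
    """
    pcs, notes = _top_discriminant_pcs(results)
    scores_space = results.transform()
    y = results.model.y
    centroids = {
        c: scores_space[y == c].mean(axis=0) for c in (CONTROL, OA)
    }
    v = {c: back_project(results, centroids[c], pcs) for c in centroids}
    diff = v[OA] - v[CONTROL]
    scores = np.abs(diff)
    if np.allclose(scores, 0.0):
        notes.append("class centroids coincide; ranking is meaningless")
        return FeatureScore("cluster_vector", scores, [], notes)
    top = _peak_ranked_indices(diff, n_top)
    return FeatureScore("cluster_vector", scores, top, notes)


# ---------------------------------------------------------------------------
# mean-difference and pointwise-test scorers
# ---------------------------------------------------------------------------


def dbms(X: np.ndarray, y, n_top: int = TOP_N_DEFAULT) -> FeatureScore:
    """Differences Between Mean Spectra: mean(OA) - mean(Control).

    Sign is retained in the score track; the ranking uses |score|.
    """
    X = np.asarray(X, dtype=float)
    y = _as_labels(y)
    diff = X[y == OA].mean(axis=0) - X[y == CONTROL].mean(axis=0)
    top = _peak_ranked_indices(diff, n_top)
    return FeatureScore("dbms", diff, top)


def pointwise_tests(
    X: np.ndarray,
    y,
    alpha: float = 0.01,
    n_top: int = TOP_N_DEFAULT,
) -> tuple[FeatureScore, FeatureScore]:
    """Per-index two-sample Student t and Mann-Whitney U tests.

    The t test uses the classic pooled-variance form; the U test uses the
    exact null distribution for small classes (n <= 15 per class, no ties)
    and the tie-corrected normal approximation otherwise. Scores are
    -log10(p); the top list holds the ``n_top`` highest local maxima of
    the score track whose p-value clears ``alpha``. Zero-variance indices
    are skipped for the t test and logged.
    """
    X = np.asarray(X, dtype=float)
    y = _as_labels(y)
    a, b = X[y == OA], X[y == CONTROL]
    if min(len(a), len(b)) < 2:
        raise ValueError("pointwise tests need >= 2 samples per class")

    notes_t: list[str] = []
    with np.errstate(invalid="ignore", divide="ignore"):
        t_stat, t_p = stats.ttest_ind(a, b, axis=0, equal_var=True)
    undefined = ~np.isfinite(t_p)
    if undefined.any():
        notes_t.append(
            f"{int(undefined.sum())} zero-variance indices skipped for t test"
        )
        t_p = np.where(undefined, 1.0, t_p)

    small = max(len(a), len(b)) <= 15
    has_ties = np.any(
        [np.unique(col).size < col.size for col in X.T]
    ) if small else True
    method = "exact" if small and not has_ties else "asymptotic"
    _, u_p = stats.mannwhitneyu(
        a, b, axis=0, alternative="two-sided", method=method
    )

    def build(p: np.ndarray, name: str, notes: list[str]) -> FeatureScore:
        score = -np.log10(np.maximum(p, np.finfo(float).tiny))
        peaks, _ = find_peaks(score, distance=5)
        sig = peaks[p[peaks] < alpha]
        if sig.size == 0:
            return FeatureScore(
                name, score, [], notes + [f"no peaks below p = {alpha}"]
            )
        order = sig[np.argsort(-score[sig], kind="stable")][:n_top]
        return FeatureScore(name, score, [int(i) for i in order], notes)

    return build(t_p, "ttest", notes_t), build(u_p, "utest", [])


# ---------------------------------------------------------------------------
# feature forward selection
# ---------------------------------------------------------------------------


def _batched_lda_accuracy(
    X_tr: np.ndarray,
    y_tr: np.ndarray,
    X_te: np.ndarray,
    y_te: np.ndarray,
    selected: list[int],
    candidates: np.ndarray,
) -> np.ndarray:
    """Held-out accuracy of a pooled-covariance linear discriminant on
    ``selected + [j]`` for every candidate j, evaluated in one batch."""
    n1 = selected.__len__()
    k = n1 + 1
    oa = y_tr == OA
    ctrl = ~oa

    def stats_for(cols: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        mu_oa = cols[oa].mean(axis=0)
        mu_c = cols[ctrl].mean(axis=0)
        return mu_oa, mu_c

    S = X_tr[:, selected]  # (n, n1)
    C = X_tr[:, candidates]  # (n, m)
    m = candidates.size
    mu_oa_S, mu_c_S = stats_for(S) if n1 else (np.zeros(0), np.zeros(0))
    mu_oa_C, mu_c_C = stats_for(C)

    dS_oa = S[oa] - mu_oa_S
    dS_c = S[ctrl] - mu_c_S
    dC_oa = C[oa] - mu_oa_C
    dC_c = C[ctrl] - mu_c_C
    denom = len(y_tr) - 2

    S_SS = (dS_oa.T @ dS_oa + dS_c.T @ dS_c) / denom  # (n1, n1)
    S_SC = (dS_oa.T @ dC_oa + dS_c.T @ dC_c) / denom  # (n1, m)
    S_CC = (
        np.einsum("ij,ij->j", dC_oa, dC_oa)
        + np.einsum("ij,ij->j", dC_c, dC_c)
    ) / denom  # (m,)

    Sw = np.empty((m, k, k))
    Sw[:, :n1, :n1] = S_SS
    Sw[:, :n1, n1] = S_SC.T
    Sw[:, n1, :n1] = S_SC.T
    Sw[:, n1, n1] = S_CC
    ridge = 1e-9 + 1e-9 * np.trace(Sw, axis1=1, axis2=2) / k
    Sw += ridge[:, None, None] * np.eye(k)

    dmu = np.empty((m, k))
    dmu[:, :n1] = mu_oa_S - mu_c_S
    dmu[:, n1] = mu_oa_C - mu_c_C
    w = np.linalg.solve(Sw, dmu[:, :, None])[:, :, 0]  # (m, k)

    mid = np.empty((m, k))
    mid[:, :n1] = 0.5 * (mu_oa_S + mu_c_S)
    mid[:, n1] = 0.5 * (mu_oa_C + mu_c_C)
    offset = np.einsum("mk,mk->m", w, mid)

    Z = np.empty((len(y_te), m, k))
    Z[:, :, :n1] = X_te[:, selected][:, None, :]
    Z[:, :, n1] = X_te[:, candidates]
    proj = np.einsum("tmk,mk->tm", Z, w) - offset[None, :]
    pred_oa = proj > 0
    truth_oa = (y_te == OA)[:, None]
    test_acc = (pred_oa == truth_oa).mean(axis=0)

    # held-out margin in pooled-SD (Mahalanobis) units: positive when the
    # test sample falls on its own class's side, large when far from the
    # decision threshold
    scale = np.sqrt(np.einsum("mk,mkl,ml->m", w, Sw, w))
    signed = np.where(truth_oa, proj, -proj) / np.maximum(scale, 1e-30)
    test_margin = signed.mean(axis=0)
    return test_acc, test_margin


def feature_forward_selection(
    X: np.ndarray,
    y,
    n_top: int = FFS_TOP_N,
    repeats: int = 100,
    seed: int = 0,
    max_features: int = 10,
) -> FeatureScore:
    """Greedy forward feature selection over random stratified 90/10 splits.

    Each repeat draws a stratified 90/10 train/test split, then greedily
    adds the index that most improves held-out accuracy of a small linear
    discriminant on the selected indices, stopping at ``max_features`` or
    when no candidate improves. A histogram counts how often each index is
    selected across repeats; the ``n_top`` highest bins are returned.
    Fully reproducible from ``seed``.
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    X = np.asarray(X, dtype=float)
    y = _as_labels(y)
    n, p = X.shape
    rng = np.random.default_rng(seed)
    hist = np.zeros(p)
    notes: list[str] = []

    idx_oa = np.flatnonzero(y == OA)
    idx_c = np.flatnonzero(y == CONTROL)
    n_te_oa = max(1, round(0.1 * idx_oa.size))
    n_te_c = max(1, round(0.1 * idx_c.size))

    done = 0
    attempts = 0
    while done < repeats:
        attempts += 1
        if attempts > 20 * repeats:
            notes.append("excessive degenerate splits; stopping early")
            break
        te = np.concatenate(
            [
                rng.choice(idx_oa, n_te_oa, replace=False),
                rng.choice(idx_c, n_te_c, replace=False),
            ]
        )
        tr = np.setdiff1d(np.arange(n), te)
        y_tr, y_te = y[tr], y[te]
        if np.unique(y_tr).size < 2 or min(
            np.sum(y_tr == OA), np.sum(y_tr == CONTROL)
        ) < 2:
            notes.append("degenerate split redrawn")
            continue

        selected: list[int] = []
        best_acc = -np.inf
        while len(selected) < max_features:
            candidates = np.setdiff1d(np.arange(p), selected)
            accs, margins = _batched_lda_accuracy(
                X[tr], y_tr, X[te], y_te, selected, candidates
            )
            # held-out accuracy decides; ties (frequent with tiny test
            # sets) resolve by held-out margin, then lowest index
            key = accs + 1e-3 * np.tanh(margins)
            j = int(np.argmax(key))
            if accs[j] <= best_acc:
                break
            best_acc = float(accs[j])
            selected.append(int(candidates[j]))
            if best_acc == 1.0:
                break
        for idx in selected:
            hist[idx] += 1
        done += 1

    top = [int(i) for i in np.argsort(-hist, kind="stable")[:n_top] if hist[i] > 0]
    return FeatureScore("ffs", hist, top, notes)


# ---------------------------------------------------------------------------
# corroboration
# ---------------------------------------------------------------------------


@dataclass
class BiomarkerRegion:
    """A contiguous fingerprint region where several tests' top features
    agree."""

    index_start: int  # inclusive
    index_stop: int  # exclusive
    modality: str
    wavenumber_high: float
    wavenumber_low: float
    hit_count: int
    tests: tuple[str, ...]
    assignment: str | None = None
    zero_order_attribution: float | str | None = None

    @property
    def center_index(self) -> int:
        return (self.index_start + self.index_stop - 1) // 2


def corroborate(
    scores: list[FeatureScore],
    segment_map: SegmentMap,
    window: int = 5,
    min_hits: int = 3,
    use_assignments: bool = True,
) -> list[BiomarkerRegion]:
    """Count agreement between the scorers' top lists.

    Top indices from all tests are pooled per modality segment (regions
    never straddle the concatenation junction) and merged whenever
    neighbouring indices are at most ``window`` points apart. Each region's
    hit count is the number of distinct contributing tests; regions with at
    least ``min_hits`` hits are returned sorted by hit count then center,
    mapped to modality + wavenumber interval and annotated from the
    packaged cartilage band table. The two indices flanking the junction
    are artifacts of concatenation and are excluded from the pooling.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if len(scores) < 2:
        raise ValueError("corroboration needs at least 2 feature scores")

    junction = segment_map.junction_indices()
    pooled: list[tuple[int, str]] = []
    for fs in scores:
        for idx in fs.top_indices:
            if not 0 <= idx < segment_map.total_length:
                raise IndexError(
                    f"{fs.test_name} top index {idx} outside fingerprint"
                )
            if idx in junction:
                continue  # concatenation artifact, logged by callers
            pooled.append((idx, fs.test_name))
    if not pooled:
        return []

    regions: list[BiomarkerRegion] = []
    for seg in segment_map.segments:
        hits = sorted(
            (i, t) for i, t in pooled if seg.start <= i < seg.stop
        )
        if not hits:
            continue
        cluster: list[tuple[int, str]] = [hits[0]]
        for item in hits[1:]:
            if item[0] - cluster[-1][0] <= window:
                cluster.append(item)
            else:
                regions.extend(_finish_region(cluster, seg, use_assignments))
                cluster = [item]
        regions.extend(_finish_region(cluster, seg, use_assignments))

    regions = [r for r in regions if r.hit_count >= min_hits]
    regions.sort(key=lambda r: (-r.hit_count, r.center_index))
    return regions


def _finish_region(cluster, seg, use_assignments: bool) -> list[BiomarkerRegion]:
    lo = min(i for i, _ in cluster)
    hi = max(i for i, _ in cluster)
    tests = tuple(sorted({t for _, t in cluster}))
    wn_a = float(seg.axis[lo - seg.start])
    wn_b = float(seg.axis[hi - seg.start])
    wn_high, wn_low = max(wn_a, wn_b), min(wn_a, wn_b)
    assignment = (
        lookup_assignment(seg.modality, wn_low, wn_high)
        if use_assignments
        else None
    )
    return [
        BiomarkerRegion(
            index_start=lo,
            index_stop=hi + 1,
            modality=seg.modality,
            wavenumber_high=wn_high,
            wavenumber_low=wn_low,
            hit_count=len(tests),
            tests=tests,
            assignment=assignment,
        )
    ]


def corroborate_nir_assignment(
    region: BiomarkerRegion,
    zero_order_mean: Spectrum,
    search_window: int = 3,
) -> BiomarkerRegion:
    """Attribute a NIR-SWIR region to a zero-order band position.

    An absorbance band shows up in the derivative fingerprint through its
    first-derivative lobes; its center is where the second derivative has a
    local minimum. The region is corroborated against the nearest
    first-derivative extremum, and attributed to the zero-order wavenumber
    of the nearest second-derivative local minimum within
    ``search_window`` resolution elements of the region center. Marked
    "unresolved" when no such minimum (or no derivative extremum at all)
    exists.
    """
    if region.modality != NIRSWIR:
        raise ValueError("zero-order corroboration applies to NIRSWIR regions")
    x = zero_order_mean.wavenumbers
    y = zero_order_mean.intensities
    d1 = np.gradient(y, x)
    d2 = np.gradient(d1, x)

    center_wn = 0.5 * (region.wavenumber_high + region.wavenumber_low)
    center = int(np.argmin(np.abs(x - center_wn)))
    lo = max(1, center - search_window)
    hi = min(x.size - 1, center + search_window + 1)

    d1_extrema = [
        i
        for i in range(1, x.size - 1)
        if (d1[i] - d1[i - 1]) * (d1[i + 1] - d1[i]) < 0
    ]
    d2_minima = [
        i for i in range(lo, hi) if d2[i] < d2[i - 1] and d2[i] < d2[i + 1]
    ]
    if not d1_extrema or not d2_minima:
        attribution: float | str = "unresolved"
    else:
        best = min(d2_minima, key=lambda i: abs(i - center))
        attribution = float(x[best])
    return BiomarkerRegion(
        **{**region.__dict__, "zero_order_attribution": attribution}
    )


def extract_all_features(
    X: np.ndarray,
    y,
    pcalda_results: PCALDAResults,
    alpha: float = 0.01,
    ffs_repeats: int = 100,
    seed: int = 0,
) -> list[FeatureScore]:
    """Run all six scorers on one fingerprint matrix."""
    t_score, u_score = pointwise_tests(X, y, alpha=alpha)
    return [
        lda_loadings_features(pcalda_results),
        cluster_vector_features(pcalda_results),
        dbms(X, y),
        t_score,
        u_score,
        feature_forward_selection(X, y, repeats=ffs_repeats, seed=seed),
    ]
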