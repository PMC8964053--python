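"""The microstate method: GFP, peak extraction, polarity-invariant modified
k-means, global explained variance, two-level template aggregation,
backfitting, label smoothing, and the three temporal dynamics metrics.

Conventions
-----------
Topographies are average-referenced row vectors.  Similarity is the spatial
Pearson correlation between two zero-mean maps; because scalp polarity is
uninformative for broadband microstates, clustering and fitting use its
absolute value (equivalently, squared correlation).  Cluster centroids are
principal eigenvectors of the outer-product sum of assigned maps — the
"modified" (polarity-invariant) k-means — rather than plain means.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .types import (
    UNASSIGNED,
    EpochSet,
    GfpSeries,
    MicrostateSegmentation,
    SubjectMetrics,
    TemplateSet,
    class_names,
)

logger = logging.getLogger(__name__)

__all__ = [
    "compute_gfp",
    "detect_peaks",
    "spatial_correlation",
    "extract_peak_maps",
    "modified_kmeans",
    "compute_gev",
    "aggregate_templates",
    "label_canonical",
    "align_templates",
    "backfit",
    "smooth_labels",
    "compute_metrics",
    "MicrostateTemplateResult",
]

_AVG_REF_TOL = 1e-6


def _check_average_referenced(data: np.ndarray, axis: int) -> None:
    dev = np.abs(data.mean(axis=axis))
    scale = np.abs(data).max() or 1.0
    if dev.max() > _AVG_REF_TOL * scale:
        raise ValueError(
            "input is not average-referenced (channel mean deviates from 0)"
        )


# --------------------------------------------------------------------------
# GFP and peaks
# --------------------------------------------------------------------------

def compute_gfp(eps: EpochSet, normalization: str = "population") -> GfpSeries:
    """Global field power: the spatial standard deviation of the topography
    at each sample.  ``population`` divides by C (maps are already
    zero-mean); ``sample`` divides by C-1.
    """
    _check_average_referenced(eps.data, axis=1)
    c = eps.n_channels
    denom = {"population": c, "sample": c - 1}.get(normalization)
    if denom is None:
        raise ValueError(f"unknown normalization {normalization!r}")
    values = np.sqrt(np.sum(eps.data**2, axis=1) / denom)
    return GfpSeries(values, eps.sfreq)


def detect_peaks(gfp: GfpSeries, min_separation_samples: int = 1
                 ) -> list[np.ndarray]:
    """Strict local maxima of the GFP series, per epoch.

    Plateaus resolve to their center sample; peaks closer than
    ``min_separation_samples`` are pruned keeping the larger; the first and
    last sample of an epoch are never peaks.
    """
    if min_separation_samples < 1:
        raise ValueError("min_separation must be >= 1")
    peaks: list[np.ndarray] = []
    for row in gfp.values:
        idx, _ = sps.find_peaks(row, distance=min_separation_samples)
        peaks.append(idx)
    gfp.peaks = peaks
    return peaks


def extract_peak_maps(
    eps: EpochSet,
    gfp: GfpSeries | None = None,
    min_separation_samples: int = 1,
    max_maps: int | None = None,
    all_samples: bool = False,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Collect the topographies submitted to clustering.

    By default these are the GFP-peak maps (all of them; ``max_maps`` can
    subsample, seeded).  With ``all_samples`` every sample is used instead.
    Returns ``(maps, gfp_values)`` with maps of shape (n_maps, n_channels).
    """
    if gfp is None:
        gfp = compute_gfp(eps)
    if all_samples:
        maps = eps.data.transpose(0, 2, 1).reshape(-1, eps.n_channels)
        weights = gfp.values.ravel()
    else:
        if gfp.peaks is None:
            detect_peaks(gfp, min_separation_samples)
        chunks, wchunks = [], []
        for ep in range(eps.n_epochs):
            idx = gfp.peaks[ep]
            chunks.append(eps.data[ep, :, idx])  # (n_peaks, n_channels)
            wchunks.append(gfp.values[ep, idx])
        maps = np.concatenate(chunks, axis=0)
        weights = np.concatenate(wchunks)
    if max_maps is not None and maps.shape[0] > max_maps:
        rng = np.random.default_rng(seed)
        sel = rng.choice(maps.shape[0], size=max_maps, replace=False)
        maps, weights = maps[sel], weights[sel]
    return maps, weights


# --------------------------------------------------------------------------
# similarity
# --------------------------------------------------------------------------

def spatial_correlation(map1: np.ndarray, map2: np.ndarray) -> float:
    """Pearson correlation of two topographies over channels.

    Both maps are re-centered; a zero-variance map raises (undefined
    similarity).  Polarity-invariant similarity is ``abs()`` of this.
    """
    a = np.asarray(map1, float)
    b = np.asarray(map2, float)
    if a.shape != b.shape:
        raise ValueError("maps must share channel count")
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("zero-variance map: similarity undefined")
    return float(np.clip(a @ b / (na * nb), -1.0, 1.0))


def _corr_matrix(maps: np.ndarray, templates: np.ndarray) -> np.ndarray:
    """Signed correlations between row-maps and row-templates (templates are
    unit-norm zero-mean; maps get centered/normalized here).  Zero-variance
    maps yield correlation 0 with every template."""
    v = maps - maps.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(v, axis=1, keepdims=True)
    ok = norms[:, 0] > 0
    v = np.divide(v, norms, out=np.zeros_like(v), where=norms > 0)
    corr = v @ templates.T
    corr[~ok] = 0.0
    return np.clip(corr, -1.0, 1.0)


# --------------------------------------------------------------------------
# modified k-means
# --------------------------------------------------------------------------

@dataclass
class MicrostateTemplateResult:
    """Outcome of modified k-means: winning templates and diagnostics."""

    templates: TemplateSet
    gev: float
    winning_restart: int
    n_iter: int
    converged: bool
    restart_gevs: np.ndarray | None = None
    gev_trace: list[float] | None = None


def _principal_map(maps: np.ndarray) -> np.ndarray:
    """Principal eigenvector of sum_t v_t v_t^T, zero-meaned, unit norm."""
    # right singular vector of the (n x C) stack == eigenvector of C x C sum
    _, _, vt = np.linalg.svd(maps, full_matrices=False)
    w = vt[0]
    w = w - w.mean()
    n = np.linalg.norm(w)
    if n == 0:
        raise ValueError("degenerate cluster")
    return w / n


def _gev_from_assignment(maps: np.ndarray, weights: np.ndarray,
                         templates: np.ndarray, labels: np.ndarray) -> float:
    corr = _corr_matrix(maps, templates)
    picked = corr[np.arange(len(labels)), labels]
    picked = np.where(labels >= 0, picked, 0.0)
    num = np.sum((weights * picked) ** 2)
    den = np.sum(weights**2)
    if den == 0:
        raise ValueError("all-zero GFP: GEV undefined")
    return float(num / den)


def _kmeans_single(
    maps: np.ndarray,
    weights: np.ndarray,
    k: int,
    rng: np.random.Generator,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, np.ndarray, float, int, bool, list[float]]:
    n = maps.shape[0]
    init = rng.choice(n, size=k, replace=False)
    centered = maps - maps.mean(axis=1, keepdims=True)
    templates = np.stack([_principal_map(centered[i : i + 1]) for i in init])
    prev_gev = -np.inf
    trace: list[float] = []
    converged = False
    labels = np.zeros(n, dtype=int)
    for it in range(1, max_iter + 1):
        corr = _corr_matrix(maps, templates)
        labels = np.argmax(corr**2, axis=1)  # ties -> lowest index (argmax)
        # update step; re-seed empty clusters from the worst-fit map
        best_fit = np.max(np.abs(corr), axis=1)
        for j in range(k):
            members = labels == j
            if not members.any():
                worst = int(np.argmin(best_fit))
                logger.info("empty cluster %d re-seeded from map %d", j, worst)
                labels[worst] = j
                members = labels == j
            templates[j] = _principal_map(centered[members])
        gev = _gev_from_assignment(maps, weights, templates, labels)
        trace.append(gev)
        if prev_gev > -np.inf and abs(gev - prev_gev) <= tol * max(prev_gev, 1e-12):
            converged = True
            break
        prev_gev = gev
    # final assignment consistent with final templates
    corr = _corr_matrix(maps, templates)
    labels = np.argmax(corr**2, axis=1)
    gev = _gev_from_assignment(maps, weights, templates, labels)
    return templates, labels, gev, it, converged, trace


def modified_kmeans(
    peak_maps: np.ndarray,
    k: int = 4,
    n_restarts: int = 20,
    seed: int | None = None,
    tol: float = 1e-7,
    max_iter: int = 500,
    gfp_weights: np.ndarray | None = None,
    labels: list[str] | None = None,
) -> MicrostateTemplateResult:
    """Polarity-invariant modified k-means over topographic maps.

    Each restart initializes K templates from K distinct randomly chosen
    maps, then alternates (a) assigning every map to the template with
    maximal squared spatial correlation and (b) replacing each template by
    the principal eigenvector of its members' outer-product sum, until the
    relative GEV change drops below ``tol``.  The restart with the highest
    GEV wins.  Restart RNG streams are spawned from ``seed`` so the winner
    over the first m restarts is a prefix property (GEV non-decreasing in
    ``n_restarts``).
    """
    maps = np.asarray(peak_maps, dtype=float)
    if maps.ndim != 2:
        raise ValueError("peak maps must be 2-D (maps x channels)")
    n = maps.shape[0]
    if n < k:
        raise ValueError("need at least K maps to fit K templates")
    if gfp_weights is None:
        gfp_weights = np.sqrt(np.mean(
            (maps - maps.mean(axis=1, keepdims=True)) ** 2, axis=1))
    weights = np.asarray(gfp_weights, dtype=float)

    seeds = np.random.SeedSequence(seed).spawn(n_restarts)
    best = None
    restart_gevs = np.empty(n_restarts)
    for r in range(n_restarts):
        rng = np.random.default_rng(seeds[r])
        out = _kmeans_single(maps, weights, k, rng, tol, max_iter)
        restart_gevs[r] = out[2]
        if best is None or out[2] > best[1][2]:
            best = (r, out)
    r_win, (templates, _, gev, n_iter, converged, trace) = best
    names = labels or class_names(k)
    return MicrostateTemplateResult(
        TemplateSet(templates, names),
        gev,
        r_win,
        n_iter,
        converged,
        restart_gevs,
        trace,
    )


def compute_gev(
    maps: np.ndarray,
    gfp_weights: np.ndarray,
    templates: TemplateSet,
    labels: np.ndarray,
) -> float:
    """Global explained variance of a labeled set of maps:
    ``sum_t (gfp_t * corr(v_t, T_label(t)))^2 / sum_t gfp_t^2``.
    Unassigned maps (label < 0) contribute zero to the numerator.
    """
    maps = np.asarray(maps, float)
    labels = np.asarray(labels, int)
    return _gev_from_assignment(maps, np.asarray(gfp_weights, float),
                                templates.maps, labels)


# --------------------------------------------------------------------------
# alignment & aggregation
# --------------------------------------------------------------------------

def align_templates(
    moving: TemplateSet, reference: TemplateSet
) -> tuple[np.ndarray, np.ndarray, float]:
    """Exhaustive permutation x sign alignment of ``moving`` onto
    ``reference``, maximizing the mean absolute spatial correlation.

    Returns ``(perm, signs, score)`` such that
    ``signs[:, None] * moving.maps[perm]`` matches reference row-for-row.
    """
    if moving.n_classes != reference.n_classes:
        raise ValueError("template sets must share K")
    if moving.n_channels != reference.n_channels:
        raise ValueError("template sets must share channel count")
    k = moving.n_classes
    corr = _corr_matrix(moving.maps, reference.maps)  # (moving, ref)
    best_perm, best_score = None, -np.inf
    for perm in itertools.permutations(range(k)):
        score = sum(abs(corr[perm[j], j]) for j in range(k))
        if score > best_score:
            best_score, best_perm = score, perm
    perm = np.array(best_perm)
    signs = np.sign(corr[perm, np.arange(k)])
    signs[signs == 0] = 1.0
    return perm, signs, best_score / k


def label_canonical(templates: TemplateSet, reference: TemplateSet
                    ) -> TemplateSet:
    """Reorder and sign-flip templates so row j best matches reference row j,
    adopting the reference's class labels (canonical A-D naming)."""
    perm, signs, _ = align_templates(templates, reference)
    maps = signs[:, None] * templates.maps[perm]
    return TemplateSet(maps, list(reference.labels), templates.ch_names)


def aggregate_templates(
    subject_templates: list[TemplateSet],
    reference: TemplateSet | None = None,
) -> TemplateSet:
    """Mean template set across subjects (group or grand level).

    Every subject's maps are aligned (exhaustive permutation x sign) to a
    common reference — by default the first subject — then averaged per
    class, re-zero-meaned and renormalized.
    """
    if not subject_templates:
        raise ValueError("no template sets to aggregate")
    k = subject_templates[0].n_classes
    if any(t.n_classes != k for t in subject_templates):
        raise ValueError("inconsistent K across template sets")
    ref = reference or subject_templates[0]
    acc = np.zeros_like(ref.maps)
    for ts in subject_templates:
        perm, signs, _ = align_templates(ts, ref)
        acc += signs[:, None] * ts.maps[perm]
    acc /= len(subject_templates)
    acc = acc - acc.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(acc, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("degenerate aggregate map (cancellation)")
    return TemplateSet(acc / norms, list(ref.labels), ref.ch_names)


# --------------------------------------------------------------------------
# backfitting, smoothing, metrics
# --------------------------------------------------------------------------

def backfit(
    eps: EpochSet,
    templates: TemplateSet,
    fit_domain: str = "all_samples",
) -> MicrostateSegmentation:
    """Label every sample with the template of maximal absolute spatial
    correlation (ties -> lowest class index).

    ``fit_domain="gfp_peaks_interpolated"`` labels only GFP peaks and
    extends each peak's label to the midpoints toward its neighboring
    peaks.  Zero-variance samples are left unassigned.  Epochs are
    processed independently.
    """
    _check_average_referenced(eps.data, axis=1)
    templates.validate(rtol=1e-6)
    n_ep, _, n = eps.data.shape
    k = templates.n_classes
    labels = np.full((n_ep, n), UNASSIGNED, dtype=int)
    best_corr = np.zeros((n_ep, n))
    corr_all = np.zeros((n_ep, k, n))
    for ep in range(n_ep):
        maps = eps.data[ep].T  # (samples, channels)
        corr = _corr_matrix(maps, templates.maps)  # (samples, k)
        corr_all[ep] = corr.T
        variance = np.linalg.norm(
            maps - maps.mean(axis=1, keepdims=True), axis=1)
        lab = np.argmax(np.abs(corr), axis=1)
        lab[variance == 0] = UNASSIGNED
        best_corr[ep] = np.where(
            lab >= 0, np.abs(corr[np.arange(n), np.maximum(lab, 0)]), 0.0
        )
        labels[ep] = lab

    if fit_domain == "gfp_peaks_interpolated":
        gfp = compute_gfp(eps)
        peak_idx = detect_peaks(gfp)
        for ep in range(n_ep):
            idx = peak_idx[ep]
            interp = np.full(n, UNASSIGNED, dtype=int)
            if idx.size:
                # each sample inherits the label of the nearest peak
                edges = (idx[:-1] + idx[1:]) // 2 + 1
                starts = np.concatenate([[0], edges])
                stops = np.concatenate([edges, [n]])
                for p, s, e in zip(idx, starts, stops):
                    interp[s:e] = labels[ep, p]
            labels[ep] = interp
        # correlations re-read against the assigned class
        for ep in range(n_ep):
            ok = labels[ep] >= 0
            best_corr[ep] = np.where(
                ok,
                np.abs(corr_all[ep, np.maximum(labels[ep], 0), np.arange(n)]),
                0.0,
            )
    elif fit_domain != "all_samples":
        raise ValueError(f"unknown fit domain {fit_domain!r}")

    return MicrostateSegmentation(
        labels, best_corr, list(templates.labels), eps.sfreq, corr_all
    )


def _runs(row: np.ndarray) -> list[tuple[int, int, int]]:
    """Maximal same-label runs of a 1-D label array: (start, stop, label)."""
    starts = np.concatenate([[0], np.flatnonzero(np.diff(row)) + 1])
    stops = np.concatenate([starts[1:], [len(row)]])
    return [(int(s), int(e), int(row[s])) for s, e in zip(starts, stops)]


def smooth_labels(
    seg: MicrostateSegmentation, min_duration_ms: float, rate: float | None = None
) -> MicrostateSegmentation:
    """Absorb segments shorter than ``min_duration_ms`` into their
    neighbors, sample by sample, choosing for each sample the neighboring
    class with the higher per-sample correlation.  Iterates until no short
    interior segment remains or a pass changes nothing.  ``min_duration_ms
    = 0`` is the identity."""
    rate = rate or seg.sfreq
    min_samples = int(np.ceil(min_duration_ms * rate / 1000.0))
    if min_samples <= 1:
        return seg.copy()
    if seg.correlation_all is None:
        raise ValueError("smoothing needs the full correlation tensor "
                         "(run backfit first)")
    out = seg.copy()
    for ep in range(out.n_epochs):
        row = out.labels[ep]
        corr = out.correlation_all[ep]
        for _ in range(out.n_samples):
            runs = _runs(row)
            short = [
                (s, e, lab)
                for i, (s, e, lab) in enumerate(runs)
                if lab != UNASSIGNED
                and (e - s) < min_samples
                and 0 < i < len(runs) - 1  # interior segments only
            ]
            if not short:
                break
            changed = False
            for s, e, lab in short:
                left = row[s - 1] if s > 0 else UNASSIGNED
                right = row[e] if e < len(row) else UNASSIGNED
                for t in range(s, e):
                    cands = [c for c in (left, right) if c != UNASSIGNED]
                    if not cands:
                        continue
                    new = max(cands, key=lambda c: abs(corr[c, t]))
                    if row[t] != new:
                        row[t] = new
                        changed = True
            if not changed:
                break
        # refresh assigned-correlation after relabeling
        ok = row >= 0
        out.correlation[ep] = np.where(
            ok, np.abs(corr[np.maximum(row, 0), np.arange(len(row))]), 0.0
        )
    return out


def compute_metrics(
    seg: MicrostateSegmentation,
    rate: float | None = None,
    boundary_policy: str = "include",
) -> SubjectMetrics:
    """Duration (ms), occurrence (1/s) and contribution (fraction) per class.

    Segments are maximal same-label runs within an epoch.  Contribution is
    the labeled-sample share of all analyzed samples.  ``boundary_policy``
    decides whether epoch-edge-truncated runs enter the duration mean and
    the occurrence count (``include``) or not (``exclude_truncated``);
    under ``include`` with no unassigned samples the identity
    ``duration * occurrence == contribution * 1000`` holds exactly.
    """
    if boundary_policy not in ("include", "exclude_truncated"):
        raise ValueError(f"unknown boundary policy {boundary_policy!r}")
    rate = rate or seg.sfreq
    if rate <= 0:
        raise ValueError("rate must be positive")
    if seg.labels.size == 0:
        raise ValueError("empty segmentation")
    k = len(seg.class_names)
    seg_count = np.zeros(k)
    seg_samples = np.zeros(k)
    sample_count = np.zeros(k)
    n = seg.n_samples
    for ep in range(seg.n_epochs):
        for s, e, lab in _runs(seg.labels[ep]):
            if lab == UNASSIGNED:
                continue
            sample_count[lab] += e - s
            truncated = s == 0 or e == n
            if boundary_policy == "exclude_truncated" and truncated:
                continue
            seg_count[lab] += 1
            seg_samples[lab] += e - s
    total_s = seg.labels.size / rate
    with np.errstate(invalid="ignore", divide="ignore"):
        duration_ms = np.where(
            seg_count > 0, seg_samples / seg_count * 1000.0 / rate, np.nan
        )
    occurrence = seg_count / total_s
    contribution = sample_count / seg.labels.size
    return SubjectMetrics(
        list(seg.class_names), duration_ms, occurrence, contribution, total_s
    )
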