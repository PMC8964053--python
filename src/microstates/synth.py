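"""Surrogate resting-state EEG with planted microstate ground truth.

The generator emulates the kind of data the analysis pipeline expects:
64-channel average-referenced scalp EEG at 500 Hz, organized as 2-s epochs
in which a sequence of quasi-stable topographies (default four classes, A-D)
alternates according to a semi-Markov process.  Each segment carries one
template map, a random polarity sign, and a rectified-sinusoid amplitude
envelope; spatially white average-reference-projected Gaussian noise is
added at a requested signal-to-noise ratio measured on the global-field-power
scale.

Two cohort layers sit on top: :func:`draw_cohort_metrics` draws per-subject
dynamics parameters (and symptom scores) around group-level targets, and
:func:`simulate_cohort` turns those parameters into signal-level recordings
whose planted label sequences realize the targets.  Default targets encode a
two-group (first-episode schizophrenia vs. healthy control, n = 23 each)
resting-state study in which group differences concentrate on classes C and
D and the positive-symptom score correlates negatively with class-D
occurrence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import _edf
from .types import (
    DEFAULT_CLASS_NAMES,
    EEGRecording,
    EpochSet,
    SubjectMetrics,
    TemplateSet,
    class_names,
)

__all__ = [
    "DynamicsSpec",
    "CohortSpec",
    "GroundTruth",
    "make_templates",
    "simulate_subject",
    "draw_cohort_metrics",
    "simulate_cohort",
    "write_matrix",
    "write_labels",
    "write_edf_recording",
]


# --------------------------------------------------------------------------
# templates
# --------------------------------------------------------------------------

def _zero_mean_unit(rows: np.ndarray) -> np.ndarray:
    rows = rows - rows.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(rows, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("degenerate zero map")
    return rows / norms


def make_templates(
    n_channels: int,
    n_classes: int = 4,
    separation_mode: str = "well_separated",
    seed: int | None = None,
) -> TemplateSet:
    """Generate K random template maps over C channels.

    Modes
    -----
    ``"random"``
        Independent Gaussian maps, average-referenced and normalized.
    ``"well_separated"``
        As random, but rows are redrawn until every pairwise absolute
        spatial correlation is below 0.5.
    ``"orthogonal"``
        Mutually orthogonal zero-mean rows.  Because average-referenced maps
        live in a (C-1)-dimensional subspace, this requires
        ``n_classes <= n_channels - 1``.
    """
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    if n_classes > n_channels:
        raise ValueError("n_classes may not exceed n_channels")
    if separation_mode == "orthogonal" and n_classes > n_channels - 1:
        raise ValueError(
            "orthogonal zero-mean maps require n_classes <= n_channels - 1"
        )
    rng = np.random.default_rng(seed)
    if separation_mode == "orthogonal":
        raw = rng.standard_normal((n_classes, n_channels))
        raw = raw - raw.mean(axis=1, keepdims=True)
        # Gram-Schmidt in the zero-mean subspace (closed under lin. comb.)
        q, _ = np.linalg.qr(raw.T)
        maps = _zero_mean_unit(q.T[:n_classes])
    elif separation_mode == "random":
        maps = _zero_mean_unit(rng.standard_normal((n_classes, n_channels)))
    elif separation_mode == "well_separated":
        maps = _zero_mean_unit(rng.standard_normal((n_classes, n_channels)))
        for _ in range(10_000):
            corr = maps @ maps.T
            np.fill_diagonal(corr, 0.0)
            bad = np.where(np.any(np.abs(corr) >= 0.5, axis=1))[0]
            if bad.size == 0:
                break
            maps[bad[0]] = _zero_mean_unit(
                rng.standard_normal((1, n_channels))
            )[0]
        else:  # pragma: no cover - only for adversarial C ~ K
            raise RuntimeError("could not find well-separated maps")
    else:
        raise ValueError(f"unknown separation_mode {separation_mode!r}")
    return TemplateSet(maps, class_names(n_classes))


# --------------------------------------------------------------------------
# dynamics
# --------------------------------------------------------------------------

@dataclass
class DynamicsSpec:
    """Generative parameters for one subject's microstate dynamics.

    mean_duration_ms
        Per-class mean segment duration.  Defaults sit in the 60-80 ms
        range typical of resting-state microstates.
    occurrence_weights
        Relative frequency of segments per class (normalized to sum to 1).
    duration_family
        ``"gamma"`` (shape ``gamma_shape``, default 2), ``"geometric"`` or
        ``"fixed"``; all truncated below at 2 samples.
    polarity_flip_p
        Probability that a segment's polarity sign is -1 (default 0.5;
        microstate analysis is polarity-invariant in the 2-20 Hz band).
    oscillation_hz
        Frequency of the rectified-sinusoid amplitude envelope (default
        10 Hz, inside the 2-20 Hz analysis band).
    snr
        Ratio of signal RMS to noise RMS on the GFP scale; ``inf`` disables
        noise.
    """

    mean_duration_ms: tuple[float, ...] = (61.3, 61.9, 62.1, 70.5)
    occurrence_weights: tuple[float, ...] = (0.2405, 0.2494, 0.2386, 0.2730)
    duration_family: str = "gamma"
    gamma_shape: float = 2.0
    polarity_flip_p: float = 0.5
    oscillation_hz: float = 10.0
    amplitude_uv: float = 5.0
    snr: float = 4.0
    sfreq: float = 500.0
    epoch_s: float = 2.0
    n_epochs: int = 110

    def __post_init__(self) -> None:
        if len(self.mean_duration_ms) != len(self.occurrence_weights):
            raise ValueError("per-class parameter lengths differ")
        if any(d <= 0 for d in self.mean_duration_ms):
            raise ValueError("mean durations must be positive")
        if self.snr <= 0:
            raise ValueError("SNR must be positive")
        total = float(sum(self.occurrence_weights))
        if total <= 0:
            raise ValueError("occurrence weights must be positive")
        self.occurrence_weights = tuple(
            w / total for w in self.occurrence_weights
        )
        if self.duration_family not in ("fixed", "geometric", "gamma"):
            raise ValueError(f"unknown duration family {self.duration_family!r}")

    @property
    def n_classes(self) -> int:
        return len(self.mean_duration_ms)

    @property
    def epoch_samples(self) -> int:
        n = self.epoch_s * self.sfreq
        if abs(n - round(n)) > 1e-9:
            raise ValueError("epoch length x rate must be an integer sample count")
        return int(round(n))


@dataclass
class GroundTruth:
    """Planted labels, per-segment polarity signs, and realized metrics."""

    labels: np.ndarray  # (n_epochs, n_samples) int
    segment_signs: list[np.ndarray]  # per epoch, sign of each segment
    realized: SubjectMetrics

    @property
    def n_epochs(self) -> int:
        return self.labels.shape[0]


from functools import lru_cache


@lru_cache(maxsize=256)
def _segment_class_weights(target_freq: tuple) -> np.ndarray:
    """Draw weights w such that a no-self-transition chain with per-step
    class probabilities w_j / (1 - w_cur) has stationary segment frequencies
    equal to ``target_freq``.

    The stationary frequencies of that chain are proportional to
    w_j (1 - w_j); inverting w (1 - w) = c * u under sum(w) = 1 gives a
    one-dimensional root problem in c.  Falls back to w = u when no root
    exists (extremely skewed targets).
    """
    u = np.asarray(target_freq, dtype=float)
    u = u / u.sum()

    def total(c: float) -> float:
        disc = 1.0 - 4.0 * c * u
        return float(np.sum((1.0 - np.sqrt(np.maximum(disc, 0.0))) / 2.0)) - 1.0

    c_hi = 1.0 / (4.0 * u.max())
    if total(c_hi) < 0:
        return u
    c = brentq(total, 1e-9, c_hi, xtol=1e-12)
    return (1.0 - np.sqrt(1.0 - 4.0 * c * u)) / 2.0


def _onset_count_correction(spec: DynamicsSpec) -> float:
    """Asymptotic excess of segment onsets per epoch over T / mean-duration.

    For a renewal process with an onset at t=0, E[#onsets in [0,T)] is
    approximately T/mu + 1/2 + cv^2/2 where cv is the coefficient of
    variation of segment durations.  Mean durations are inflated by the
    matching factor so realized occurrence rates hit their targets; the same
    inflation offsets the downward duration bias from epoch-edge truncation.
    """
    if spec.duration_family == "fixed":
        cv2 = 0.0
    elif spec.duration_family == "geometric":
        cv2 = 1.0
    else:
        cv2 = 1.0 / spec.gamma_shape
    return 0.5 + cv2 / 2.0


def _draw_durations_samples(
    rng: np.random.Generator, spec: DynamicsSpec, classes: np.ndarray,
    mean_samples: np.ndarray,
) -> np.ndarray:
    m = mean_samples[classes]
    if spec.duration_family == "fixed":
        dur = np.rint(m)
    elif spec.duration_family == "geometric":
        # support {2, 3, ...} with mean m: 2 + Geom0(p), p = 1/(m-1)
        p = 1.0 / np.maximum(m - 1.0, 1.0 + 1e-9)
        dur = 2.0 + rng.geometric(p) - 1.0
    else:
        dur = np.rint(rng.gamma(spec.gamma_shape, m / spec.gamma_shape))
    return np.maximum(dur, 2).astype(int)


def _plant_epoch_labels(
    rng: np.random.Generator, spec: DynamicsSpec
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One epoch's label sequence: (labels, segment classes, segment signs)."""
    n = spec.epoch_samples
    k = spec.n_classes
    u = np.asarray(spec.occurrence_weights)
    mean_ms = np.asarray(spec.mean_duration_ms, dtype=float)
    mean_samples = mean_ms * spec.sfreq / 1000.0

    if k == 1:
        labels = np.zeros(n, dtype=int)
        sign = -1.0 if rng.random() < spec.polarity_flip_p else 1.0
        return labels, np.array([0]), np.array([sign])

    w = _segment_class_weights(tuple(np.round(u, 12)))
    # generous upper bound on segment count, extended if ever exhausted
    mean_seg = max(mean_samples.min(), 2.0)
    max_seg = int(np.ceil(n / mean_seg * 3)) + 8
    # cumulative transition distributions, one per previous class
    cum_excl = np.empty((k, k))
    for i in range(k):
        probs = w.copy()
        probs[i] = 0.0
        cum_excl[i] = np.cumsum(probs / probs.sum())
    classes = np.empty(max_seg, dtype=int)
    u_cum = np.cumsum(u)
    uniforms = rng.random(max_seg)
    classes[0] = int(np.searchsorted(u_cum, uniforms[0]))  # stationary start
    for i in range(1, max_seg):
        classes[i] = int(np.searchsorted(cum_excl[classes[i - 1]], uniforms[i]))

    durations = _draw_durations_samples(rng, spec, classes, mean_samples)
    ends = np.cumsum(durations)
    while ends[-1] < n:  # bound exhausted (vanishingly rare): extend
        extra_u = rng.random(max_seg)
        extra_c = np.empty(max_seg, dtype=int)
        prev = classes[-1]
        for i in range(max_seg):
            extra_c[i] = int(np.searchsorted(cum_excl[prev], extra_u[i]))
            prev = extra_c[i]
        classes = np.concatenate([classes, extra_c])
        extra_d = _draw_durations_samples(rng, spec, extra_c, mean_samples)
        durations = np.concatenate([durations, extra_d])
        ends = np.cumsum(durations)
    n_seg = int(np.searchsorted(ends, n) + 1)
    classes = classes[:n_seg]
    durations = durations[:n_seg]
    ends = ends[:n_seg]
    ends[-1] = n  # truncate final segment at the epoch edge

    labels = np.repeat(classes, np.diff(np.concatenate([[0], ends])))
    signs = np.where(
        rng.random(n_seg) < spec.polarity_flip_p, -1.0, 1.0
    )
    return labels, classes, signs


def metrics_from_labels(
    labels: np.ndarray,
    sfreq: float,
    n_classes: int,
    names: list[str] | None = None,
) -> SubjectMetrics:
    """Run-length metrics of a planted (epochs x samples) label array.

    Independent, deliberately simple counting used for ground truth; the
    analysis-side counterpart lives in :func:`microstates.core.compute_metrics`
    and must agree with it exactly (boundary policy: edge-truncated segments
    are included).
    """
    labels = np.asarray(labels)
    if labels.ndim == 1:
        labels = labels[None, :]
    n_ep, n = labels.shape
    names = list(names or class_names(n_classes))
    seg_count = np.zeros(n_classes)
    seg_samples = np.zeros(n_classes)
    sample_count = np.zeros(n_classes)
    for ep in range(n_ep):
        row = labels[ep]
        starts = np.concatenate([[0], np.flatnonzero(np.diff(row)) + 1])
        stops = np.concatenate([starts[1:], [n]])
        labs = row[starts]
        ok = labs >= 0
        np.add.at(seg_count, labs[ok], 1)
        np.add.at(seg_samples, labs[ok], (stops - starts)[ok])
        np.add.at(sample_count, labs[ok], (stops - starts)[ok])
    total_s = n_ep * n / sfreq
    with np.errstate(invalid="ignore", divide="ignore"):
        duration_ms = np.where(
            seg_count > 0, seg_samples / seg_count * 1000.0 / sfreq, np.nan
        )
    occurrence = seg_count / total_s
    contribution = sample_count / (n_ep * n)
    return SubjectMetrics(names, duration_ms, occurrence, contribution, total_s)


def simulate_subject(
    templates: TemplateSet,
    spec: DynamicsSpec,
    seed: int | None | np.random.Generator = None,
) -> tuple[EpochSet, GroundTruth]:
    """Simulate one subject's epoched EEG from planted microstate dynamics.

    Each sample's clean topography is ``sign * envelope(t) * amplitude *
    sqrt(C) * template[class(t)]`` (so the clean GFP equals
    ``amplitude * envelope``); white Gaussian noise is projected onto the
    average-reference subspace and scaled to the requested GFP-scale SNR.
    """
    if templates.n_classes != spec.n_classes:
        raise ValueError("template count does not match dynamics spec")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    n = spec.epoch_samples
    c = templates.n_channels
    t_axis = np.arange(n) / spec.sfreq

    all_labels = np.empty((spec.n_epochs, n), dtype=int)
    all_signs: list[np.ndarray] = []
    data = np.empty((spec.n_epochs, c, n))
    scaled_maps = templates.maps * np.sqrt(c) * spec.amplitude_uv

    for ep in range(spec.n_epochs):
        labels, seg_classes, seg_signs = _plant_epoch_labels(rng, spec)
        all_labels[ep] = labels
        all_signs.append(seg_signs)
        phase = rng.uniform(0.0, 2.0 * np.pi)
        env = np.abs(np.sin(2.0 * np.pi * spec.oscillation_hz * t_axis + phase))
        # per-sample sign: expand segment signs over the label runs
        sign_per_sample = np.empty(n)
        boundaries = np.flatnonzero(np.diff(labels)) + 1
        starts = np.concatenate([[0], boundaries])
        stops = np.concatenate([boundaries, [n]])
        for s, e, sg in zip(starts, stops, seg_signs):
            sign_per_sample[s:e] = sg
        clean = (env * sign_per_sample)[None, :] * scaled_maps[labels].T
        data[ep] = clean

    if np.isfinite(spec.snr):
        gfp2 = np.mean(data**2, axis=1)  # population GFP squared
        rms_sig = np.sqrt(gfp2.mean())
        sigma = rms_sig / (spec.snr * np.sqrt((c - 1) / c))
        noise = rng.standard_normal(data.shape) * sigma
        noise -= noise.mean(axis=1, keepdims=True)  # average-reference proj.
        data = data + noise

    names = [f"E{i + 1:02d}" for i in range(c)]
    eps = EpochSet(data, spec.sfreq, names, log=["synthesized"])
    realized = metrics_from_labels(
        all_labels, spec.sfreq, spec.n_classes, templates.labels
    )
    return eps, GroundTruth(all_labels, all_signs, realized)


# --------------------------------------------------------------------------
# cohorts
# --------------------------------------------------------------------------

_PATIENT_DURATION = ((60.12, 6.35), (64.81, 17.91), (77.07, 20.88), (64.82, 12.68))
_CONTROL_DURATION = ((61.30, 6.48), (61.89, 6.41), (62.12, 6.79), (70.51, 13.12))
_PATIENT_OCCURRENCE = ((3.34, 1.04), (3.54, 1.06), (4.27, 0.65), (3.53, 1.09))
_CONTROL_OCCURRENCE = ((3.77, 0.77), (3.91, 0.57), (3.74, 0.67), (4.28, 0.76))
_PATIENT_CONTRIBUTION = ((20.35, 7.64), (23.53, 11.29), (32.58, 11.06), (23.54, 10.21))
_CONTROL_CONTRIBUTION = ((23.15, 6.04), (23.94, 4.72), (23.04, 5.00), (29.87, 8.41))

_SYMPTOM_MODEL = {
    "panss_positive": (16.96, 5.71),
    "panss_negative": (14.43, 7.67),
    "panss_general": (32.08, 16.80),
}
_DEMOGRAPHICS = {
    "patient": {"age": (28.04, 5.42), "education": (13.36, 2.40),
                "n_male": 16, "n": 23},
    "control": {"age": (26.39, 6.95), "education": (14.14, 1.91),
                "n_male": 13, "n": 23},
}


@dataclass
class CohortSpec:
    """Two-group cohort targets for per-subject microstate dynamics.

    Targets are (mean, SD) pairs per group per class for duration (ms) and
    occurrence (1/s); contribution follows from those two (occurrence x
    duration / 1000) and its targets are kept for reference only.  Defaults
    encode a 23-vs-23 first-episode schizophrenia vs. healthy-control
    resting-state cohort with effects on classes C and D, plus PANSS-like
    symptom subscores in the patient group where the positive-symptom score
    correlates r = -0.416 with class-D occurrence.
    """

    group_names: tuple[str, str] = ("patient", "control")
    group_sizes: tuple[int, int] = (23, 23)
    duration_targets: dict = field(
        default_factory=lambda: {
            "patient": _PATIENT_DURATION,
            "control": _CONTROL_DURATION,
        }
    )
    occurrence_targets: dict = field(
        default_factory=lambda: {
            "patient": _PATIENT_OCCURRENCE,
            "control": _CONTROL_OCCURRENCE,
        }
    )
    contribution_targets: dict = field(
        default_factory=lambda: {
            "patient": _PATIENT_CONTRIBUTION,
            "control": _CONTROL_CONTRIBUTION,
        }
    )
    symptom_model: dict = field(default_factory=lambda: dict(_SYMPTOM_MODEL))
    symptom_group: str = "patient"
    symptom_corr: float = -0.416
    symptom_variable: str = "panss_positive"
    corr_metric: tuple[str, str] = ("occurrence", "D")
    demographics: dict = field(default_factory=lambda: dict(_DEMOGRAPHICS))
    seed: int | None = None

    def __post_init__(self) -> None:
        if any(n < 2 for n in self.group_sizes):
            raise ValueError("group sizes must be >= 2")
        if not abs(self.symptom_corr) < 1:
            raise ValueError("|target correlation| must be < 1")
        for targets in (self.duration_targets, self.occurrence_targets):
            for cells in targets.values():
                for mean, sd in cells:
                    if sd <= 0:
                        raise ValueError("target SDs must be positive")
                    if mean <= 0:
                        raise ValueError("infeasible (non-positive) target mean")

    @property
    def n_classes(self) -> int:
        return len(next(iter(self.duration_targets.values())))


def draw_cohort_metrics(
    cohort: CohortSpec, seed: int | None = None
) -> pd.DataFrame:
    """Draw per-subject dynamics parameters and covariates (no EEG).

    Returns one row per subject with columns ``subject``, ``group``,
    ``sex``, ``age``, ``education_years``, ``duration_<class>``,
    ``occurrence_<class>``, ``contribution_<class>`` (percent) and, for the
    symptom group, PANSS-like subscores.  The designated symptom subscore is
    drawn from a bivariate normal with the designated metric at the target
    correlation.
    """
    rng = np.random.default_rng(cohort.seed if seed is None else seed)
    k = cohort.n_classes
    names = class_names(k)
    rows = []
    sid = 0
    for group, n_sub in zip(cohort.group_names, cohort.group_sizes):
        dur_t = np.array(cohort.duration_targets[group], dtype=float)
        occ_t = np.array(cohort.occurrence_targets[group], dtype=float)
        demo = cohort.demographics.get(group, {})
        # sex counts scale with group size; both sexes always present
        ref_male = demo.get("n_male", n_sub // 2)
        ref_total = demo.get("n", 23)
        n_male = int(np.clip(round(ref_male / ref_total * n_sub), 1, n_sub - 1))
        sexes = np.array(["M"] * n_male + ["F"] * (n_sub - n_male))
        for i in range(n_sub):
            z_dur = rng.standard_normal(k)
            z_occ = rng.standard_normal(k)
            dur = np.maximum(dur_t[:, 0] + dur_t[:, 1] * z_dur, 20.0)
            occ = np.maximum(occ_t[:, 0] + occ_t[:, 1] * z_occ, 0.3)
            # time-budget identity: class occupancies tile each second, so
            # sum_k occ_k * dur_k = 1000 ms/s must hold per subject; the
            # drawn durations absorb the (small) feasibility rescaling,
            # keeping the drawn occurrence parameters exact.
            dur *= 1000.0 / float(occ @ dur)
            row: dict = {"subject": f"S{sid:03d}", "group": group, "sex": sexes[i]}
            age_m, age_sd = demo.get("age", (30.0, 8.0))
            edu_m, edu_sd = demo.get("education", (14.0, 2.5))
            row["age"] = float(np.round(np.clip(
                age_m + age_sd * rng.standard_normal(), 18, 60)))
            row["education_years"] = float(np.round(np.clip(
                edu_m + edu_sd * rng.standard_normal(), 6, 22)))
            contrib = occ * dur / 1000.0
            contrib = contrib / contrib.sum() * 100.0
            for j, cname in enumerate(names):
                row[f"duration_{cname}"] = dur[j]
                row[f"occurrence_{cname}"] = occ[j]
                row[f"contribution_{cname}"] = contrib[j]
            if group == cohort.symptom_group:
                metric, cls = cohort.corr_metric
                j = names.index(cls)
                z_metric = z_occ[j] if metric == "occurrence" else z_dur[j]
                r = cohort.symptom_corr
                for var, (s_mean, s_sd) in cohort.symptom_model.items():
                    if var == cohort.symptom_variable:
                        z = r * z_metric + np.sqrt(1 - r**2) * rng.standard_normal()
                    else:
                        z = rng.standard_normal()
                    row[var] = float(np.round(np.maximum(s_mean + s_sd * z, 7.0)))
                row["panss_total"] = sum(
                    row[v] for v in cohort.symptom_model
                )
            rows.append(row)
            sid += 1
    return pd.DataFrame(rows)


def subject_dynamics(
    duration_ms: np.ndarray, occurrence_per_s: np.ndarray, base: DynamicsSpec
) -> DynamicsSpec:
    """Per-subject :class:`DynamicsSpec` realizing drawn metric targets.

    Within an epoch of length T the expected onset count exceeds
    T/mean-duration by ~1/2 + cv^2/2 (renewal process with an onset at
    t=0); mean durations are inflated by the matching factor so realized
    occurrence rates hit the drawn targets, which incidentally offsets the
    downward duration bias from epoch-edge truncation.
    """
    dur = np.asarray(duration_ms, dtype=float)
    occ = np.asarray(occurrence_per_s, dtype=float)
    u = occ / occ.sum()
    kappa = _onset_count_correction(base)
    mu_bar = float(u @ dur)
    t_ms = 1000.0 * base.epoch_s
    denom = t_ms / mu_bar - kappa
    inflate = (t_ms / mu_bar) / denom if denom > 0 else 1.0
    return replace(
        base,
        mean_duration_ms=tuple(dur * inflate),
        occurrence_weights=tuple(u),
    )


def simulate_cohort(
    cohort: CohortSpec,
    templates: TemplateSet,
    spec: DynamicsSpec,
    seed: int | None = None,
    make_recordings: bool = True,
) -> tuple[pd.DataFrame, list[EpochSet | None], list[GroundTruth]]:
    """Simulate a full two-group cohort.

    Per-subject dynamics parameters come from :func:`draw_cohort_metrics`;
    each subject's label sequence (and, if ``make_recordings``, EEG signal)
    is generated with those parameters, and the returned cohort table holds
    the *realized* metrics recomputed from the planted label sequences
    (contribution reported in percent, as in study tables).
    """
    if templates.n_classes != cohort.n_classes:
        raise ValueError("template count does not match cohort targets")
    master = np.random.default_rng(cohort.seed if seed is None else seed)
    param_seed = int(master.integers(2**31))
    table = draw_cohort_metrics(cohort, seed=param_seed)
    names = class_names(cohort.n_classes)
    recordings: list[EpochSet | None] = []
    truths: list[GroundTruth] = []
    subj_seeds = np.random.SeedSequence(
        int(master.integers(2**31))
    ).spawn(len(table))
    for idx, row in table.iterrows():
        dur = np.array([row[f"duration_{c}"] for c in names])
        occ = np.array([row[f"occurrence_{c}"] for c in names])
        sub_spec = subject_dynamics(dur, occ, spec)
        rng = np.random.default_rng(subj_seeds[idx])
        if make_recordings:
            eps, gt = simulate_subject(templates, sub_spec, rng)
            recordings.append(eps)
        else:
            labels = np.empty((sub_spec.n_epochs, sub_spec.epoch_samples), int)
            signs = []
            for ep in range(sub_spec.n_epochs):
                lab, _, sg = _plant_epoch_labels(rng, sub_spec)
                labels[ep] = lab
                signs.append(sg)
            realized = metrics_from_labels(
                labels, sub_spec.sfreq, cohort.n_classes, names
            )
            gt = GroundTruth(labels, signs, realized)
            recordings.append(None)
        truths.append(gt)
        for j, cname in enumerate(names):
            table.loc[idx, f"duration_{cname}"] = gt.realized.duration_ms[j]
            table.loc[idx, f"occurrence_{cname}"] = gt.realized.occurrence_per_s[j]
            table.loc[idx, f"contribution_{cname}"] = (
                gt.realized.contribution[j] * 100.0
            )
    return table, recordings, truths


# --------------------------------------------------------------------------
# writers
# --------------------------------------------------------------------------

def epochs_to_recording(eps: EpochSet) -> EEGRecording:
    """Concatenate epochs back into one continuous recording."""
    data = eps.data.transpose(1, 0, 2).reshape(eps.n_channels, -1)
    return EEGRecording(data, eps.sfreq, list(eps.ch_names))


def write_matrix(rec: EEGRecording, path: str | Path) -> None:
    """Write a recording as delimited text (samples x channels) plus a JSON
    sidecar ``<stem>.meta.json`` carrying the sampling rate."""
    path = Path(path)
    df = pd.DataFrame(rec.data.T, columns=rec.ch_names)
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")
    meta = {"sfreq": rec.sfreq, "n_channels": rec.n_channels}
    path.with_suffix(path.suffix + ".meta.json").write_text(
        json.dumps(meta, indent=1)
    )


def write_edf_recording(rec: EEGRecording, path: str | Path) -> None:
    _edf.write_edf(path, rec.data, rec.sfreq, rec.ch_names)


def write_labels(gt: GroundTruth, path: str | Path,
                 names: list[str] | None = None) -> None:
    """Write planted labels as delimited text (epoch, sample, class)."""
    names = list(names or class_names(int(gt.labels.max()) + 1))
    n_ep, n = gt.labels.shape
    ep_col = np.repeat(np.arange(n_ep), n)
    samp_col = np.tile(np.arange(n), n_ep)
    lab_col = [names[v] if v >= 0 else "unassigned" for v in gt.labels.ravel()]
    pd.DataFrame({"epoch": ep_col, "sample": samp_col, "class": lab_col}).to_csv(
        path, sep="\t", index=False
    )
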