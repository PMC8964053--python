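"""End-to-end orchestration: simulate -> preprocess -> segment -> aggregate
-> backfit -> metrics -> stats -> report.

All intermediate artifacts are delimited text (plus JSON sidecars), one
directory per run, so any stage can be re-run from the outputs of the stage
before it.  A single global seed is split into per-stage, per-subject
streams with :class:`numpy.random.SeedSequence`, making runs reproducible
end to end.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import core, io_preproc, synth
from .types import EpochSet, TemplateSet, UNASSIGNED, class_names

__version__ = "0.1.0"

STAGES = (
    "simulate",
    "preprocess",
    "segment",
    "aggregate",
    "backfit",
    "metrics",
    "stats",
    "report",
)


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

@dataclass
class SimulateConfig:
    n_channels: int = 64
    n_classes: int = 4
    group_sizes: tuple[int, int] = (23, 23)
    epochs_per_subject: int = 110
    snr: float = 4.0
    format: str = "matrix"  # or "edf"

    def validate(self) -> None:
        if self.n_channels < self.n_classes:
            raise ValueError("simulate.n_channels must be >= n_classes")
        if any(n < 2 for n in self.group_sizes):
            raise ValueError("simulate.group_sizes entries must be >= 2")
        if self.epochs_per_subject < 1:
            raise ValueError("simulate.epochs_per_subject must be >= 1")
        if self.snr <= 0:
            raise ValueError("simulate.snr must be positive")
        if self.format not in ("matrix", "edf"):
            raise ValueError("simulate.format must be 'matrix' or 'edf'")


@dataclass
class PreprocessConfig:
    resample_hz: float = 500.0
    broad_band: tuple[float, float] = (0.1, 70.0)
    notch: tuple[float, float] | None = (48.0, 52.0)
    epoch_s: float = 2.0
    reject_uv: float = 150.0
    narrow_band: tuple[float, float] = (2.0, 20.0)

    def validate(self) -> None:
        if self.epoch_s <= 0:
            raise ValueError("preprocess.epoch_s must be positive")
        if self.reject_uv <= 0:
            raise ValueError("preprocess.reject_uv must be positive")
        if self.resample_hz <= 0:
            raise ValueError("preprocess.resample_hz must be positive")


@dataclass
class ClusterConfig:
    k: int = 4
    n_restarts: int = 20
    tol: float = 1e-7
    max_iter: int = 500
    fit_domain: str = "all_samples"
    smooth_ms: float = 0.0
    boundary_policy: str = "include"

    def validate(self) -> None:
        if self.k < 2:
            raise ValueError("cluster.k must be >= 2")
        if self.n_restarts < 1:
            raise ValueError("cluster.n_restarts must be >= 1")
        if self.fit_domain not in ("all_samples", "gfp_peaks_interpolated"):
            raise ValueError("cluster.fit_domain invalid")
        if self.boundary_policy not in ("include", "exclude_truncated"):
            raise ValueError("cluster.boundary_policy invalid")


@dataclass
class StatsConfig:
    scale: str = "raw"
    variance: str = "pooled"
    chi2_correction: str = "none"
    posthoc_gate: bool = True

    def validate(self) -> None:
        if self.scale not in ("raw", "zscore"):
            raise ValueError("stats.scale must be raw|zscore")
        if self.variance not in ("pooled", "welch"):
            raise ValueError("stats.variance must be pooled|welch")
        if self.chi2_correction not in ("none", "yates"):
            raise ValueError("stats.chi2_correction must be none|yates")


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "microstate_run"
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    cluster: ClusterConfig = field(default_factory=ClusterConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)

    def validate(self) -> None:
        for section in (self.simulate, self.preprocess, self.cluster,
                        self.stats):
            section.validate()

    # -- (de)serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(_listify(self.to_dict()), sort_keys=True)
        )

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw or {})
        sections = {
            "simulate": SimulateConfig,
            "preprocess": PreprocessConfig,
            "cluster": ClusterConfig,
            "stats": StatsConfig,
        }
        kwargs: dict = {}
        for key in list(raw):
            if key in sections:
                sub = raw.pop(key) or {}
                fields = {f.name: f for f in
                          dataclasses.fields(sections[key])}
                for k in sub:
                    if k not in fields:
                        raise ValueError(
                            f"unknown config key {key}.{k!r}"
                        )
                sub = {k: _tuplify(v) for k, v in sub.items()}
                kwargs[key] = sections[key](**sub)
            elif key in ("seed", "outdir"):
                kwargs[key] = raw.pop(key)
            else:
                raise ValueError(f"unknown config key {key!r}")
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw)


def _tuplify(v):
    return tuple(v) if isinstance(v, list) else v


def _listify(obj):
    if isinstance(obj, dict):
        return {k: _listify(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return [_listify(v) for v in obj]
    return obj


def validate_config(path: str | Path) -> PipelineConfig:
    """Parse, default and range-check a YAML config file."""
    return PipelineConfig.from_yaml(path)


# --------------------------------------------------------------------------
# text artifact helpers
# --------------------------------------------------------------------------

def write_templates(ts: TemplateSet, path: Path) -> None:
    names = ts.ch_names or [f"E{i + 1:02d}" for i in range(ts.n_channels)]
    df = pd.DataFrame(ts.maps, columns=names)
    df.insert(0, "class", ts.labels)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_templates(path: Path) -> TemplateSet:
    df = pd.read_csv(path, sep="\t")
    labels = df.pop("class").tolist()
    return TemplateSet(df.to_numpy(float), labels, list(df.columns))


def write_epochs(eps: EpochSet, path: Path) -> None:
    n_ep, n_ch, n = eps.data.shape
    flat = eps.data.transpose(0, 2, 1).reshape(-1, n_ch)
    df = pd.DataFrame(flat, columns=eps.ch_names)
    df.insert(0, "sample", np.tile(np.arange(n), n_ep))
    df.insert(0, "epoch", np.repeat(np.arange(n_ep), n))
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")
    meta = {"sfreq": eps.sfreq, "n_epochs": n_ep, "n_samples": n,
            "log": eps.log}
    path.with_suffix(path.suffix + ".meta.json").write_text(
        json.dumps(meta, indent=1))


def read_epochs(path: Path) -> EpochSet:
    meta = json.loads(
        path.with_suffix(path.suffix + ".meta.json").read_text())
    df = pd.read_csv(path, sep="\t")
    n_ep, n = int(meta["n_epochs"]), int(meta["n_samples"])
    ch = [c for c in df.columns if c not in ("epoch", "sample")]
    data = df[ch].to_numpy(float).reshape(n_ep, n, len(ch)).transpose(0, 2, 1)
    return EpochSet(data, float(meta["sfreq"]), ch, list(meta.get("log", [])))


def write_segmentation(seg, path: Path) -> None:
    n_ep, n = seg.labels.shape
    lab = np.asarray(
        [seg.class_names[v] if v >= 0 else "unassigned"
         for v in seg.labels.ravel()]
    )
    df = pd.DataFrame(
        {
            "epoch": np.repeat(np.arange(n_ep), n),
            "sample": np.tile(np.arange(n), n_ep),
            "label": lab,
            "correlation": seg.correlation.ravel(),
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


# --------------------------------------------------------------------------
# the pipeline
# --------------------------------------------------------------------------

def _stage_seeds(seed: int) -> dict[str, np.random.SeedSequence]:
    children = np.random.SeedSequence(seed).spawn(len(STAGES))
    return dict(zip(STAGES, children))


def run_pipeline(config: PipelineConfig, resume: bool = False) -> dict:
    """Execute all stages in flowchart order and return the run manifest.

    With ``resume=True`` a stage whose outputs already exist is skipped, so
    deleting downstream artifacts and re-running reproduces them from the
    upstream ones.
    """
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    cfg_yaml = yaml.safe_dump(_listify(config.to_dict()), sort_keys=True)
    manifest: dict = {
        "version": __version__,
        "config": _listify(config.to_dict()),
        "config_hash": hashlib.sha256(cfg_yaml.encode()).hexdigest(),
        "stages": {},
        "warnings": [],
    }
    config.to_yaml(out / "config.yaml")

    state: dict = {}
    for stage in STAGES:
        t0 = time.time()
        func = globals()[f"_stage_{stage}"]
        try:
            outputs = func(config, out, seeds[stage], state, resume)
        except Exception as exc:
            manifest["stages"][stage] = {"status": "failed", "error": str(exc)}
            (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        manifest["stages"][stage] = {
            "status": "ok",
            "seconds": round(time.time() - t0, 3),
            "outputs": {str(p.relative_to(out)): _sha256(p) for p in outputs},
        }
    manifest["finished_at"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def _subject_table(out: Path) -> pd.DataFrame:
    return pd.read_csv(out / "cohort_metadata.tsv", sep="\t")


def _stage_simulate(config, out: Path, seed_seq, state, resume) -> list[Path]:
    sc = config.simulate
    meta_path = out / "cohort_metadata.tsv"
    tmpl_path = out / "generator_templates.tsv"
    ext = ".tsv" if sc.format == "matrix" else ".edf"
    if resume and meta_path.exists() and tmpl_path.exists():
        return [meta_path, tmpl_path]
    rngs = seed_seq.spawn(3)
    templates = synth.make_templates(
        sc.n_channels, sc.n_classes, "well_separated",
        int(np.random.default_rng(rngs[0]).integers(2**31)),
    )
    cohort = synth.CohortSpec(group_sizes=tuple(sc.group_sizes))
    table = synth.draw_cohort_metrics(
        cohort, seed=int(np.random.default_rng(rngs[1]).integers(2**31))
    )
    names = class_names(sc.n_classes)
    subj_seeds = rngs[2].spawn(len(table))
    outputs = [meta_path, tmpl_path]
    raw_dir = out / "raw"
    raw_dir.mkdir(exist_ok=True)
    for idx, row in table.iterrows():
        dur = np.array([row[f"duration_{c}"] for c in names])
        occ = np.array([row[f"occurrence_{c}"] for c in names])
        base = synth.DynamicsSpec(snr=sc.snr, n_epochs=sc.epochs_per_subject)
        spec = synth.subject_dynamics(dur, occ, base)
        eps, gt = synth.simulate_subject(
            templates, spec, np.random.default_rng(subj_seeds[idx])
        )
        rec = synth.epochs_to_recording(eps)
        rec_path = raw_dir / f"{row['subject']}{ext}"
        if sc.format == "matrix":
            synth.write_matrix(rec, rec_path)
            outputs.append(rec_path.with_suffix(
                rec_path.suffix + ".meta.json"))
        else:
            synth.write_edf_recording(rec, rec_path)
        lab_path = raw_dir / f"{row['subject']}_labels.tsv"
        synth.write_labels(gt, lab_path, list(templates.labels))
        outputs += [rec_path, lab_path]
        for j, cname in enumerate(names):
            table.loc[idx, f"duration_{cname}"] = gt.realized.duration_ms[j]
            table.loc[idx, f"occurrence_{cname}"] = (
                gt.realized.occurrence_per_s[j])
            table.loc[idx, f"contribution_{cname}"] = (
                gt.realized.contribution[j] * 100.0)
    table.to_csv(meta_path, sep="\t", index=False)
    write_templates(templates, tmpl_path)
    return outputs


def _stage_preprocess(config, out: Path, seed_seq, state, resume) -> list[Path]:
    pc = config.preprocess
    table = _subject_table(out)
    prep = out / "preprocessed"
    prep.mkdir(exist_ok=True)
    outputs = []
    for _, row in table.iterrows():
        dst = prep / f"{row['subject']}_epochs.tsv"
        outputs += [dst, dst.with_suffix(dst.suffix + ".meta.json")]
        if resume and dst.exists():
            continue
        src = out / "raw" / f"{row['subject']}.tsv"
        if not src.exists():
            src = out / "raw" / f"{row['subject']}.edf"
        rec = io_preproc.read_recording(src)
        eps = io_preproc.preprocess_chain(
            rec,
            target_rate=pc.resample_hz,
            broad_band=pc.broad_band,
            notch=pc.notch,
            epoch_s=pc.epoch_s,
            reject_uv=pc.reject_uv,
            narrow_band=pc.narrow_band,
        )
        write_epochs(eps, dst)
    return outputs


def _stage_segment(config, out: Path, seed_seq, state, resume) -> list[Path]:
    cc = config.cluster
    table = _subject_table(out)
    seg_dir = out / "templates"
    seg_dir.mkdir(exist_ok=True)
    outputs = []
    summary_rows = []
    subj_seeds = seed_seq.spawn(len(table))
    for idx, row in table.iterrows():
        dst = seg_dir / f"{row['subject']}_templates.tsv"
        outputs.append(dst)
        eps = read_epochs(out / "preprocessed" / f"{row['subject']}_epochs.tsv")
        maps, weights = core.extract_peak_maps(eps)
        res = core.modified_kmeans(
            maps,
            k=cc.k,
            n_restarts=cc.n_restarts,
            seed=int(np.random.default_rng(subj_seeds[idx]).integers(2**31)),
            tol=cc.tol,
            max_iter=cc.max_iter,
        )
        res.templates.ch_names = list(eps.ch_names)
        write_templates(res.templates, dst)
        summary_rows.append(
            {"subject": row["subject"], "group": row["group"],
             "n_peak_maps": maps.shape[0], "gev": res.gev,
             "winning_restart": res.winning_restart,
             "iterations": res.n_iter, "converged": res.converged}
        )
    summary = seg_dir / "clustering_summary.tsv"
    pd.DataFrame(summary_rows).to_csv(summary, sep="\t", index=False)
    outputs.append(summary)
    return outputs


def _stage_aggregate(config, out: Path, seed_seq, state, resume) -> list[Path]:
    table = _subject_table(out)
    seg_dir = out / "templates"
    by_group: dict[str, list[TemplateSet]] = {}
    all_sets = []
    for _, row in table.iterrows():
        ts = read_templates(seg_dir / f"{row['subject']}_templates.tsv")
        by_group.setdefault(row["group"], []).append(ts)
        all_sets.append(ts)
    gen_path = out / "generator_templates.tsv"
    reference = read_templates(gen_path) if gen_path.exists() else None
    outputs = []
    for group, sets in by_group.items():
        agg = core.aggregate_templates(sets, reference=reference)
        if reference is not None:
            agg = core.label_canonical(agg, reference)
        p = out / f"group_templates_{group}.tsv"
        write_templates(agg, p)
        outputs.append(p)
    grand = core.aggregate_templates(all_sets, reference=reference)
    if reference is not None:
        grand = core.label_canonical(grand, reference)
    p = out / "grand_templates.tsv"
    write_templates(grand, p)
    outputs.append(p)
    return outputs


def _stage_backfit(config, out: Path, seed_seq, state, resume) -> list[Path]:
    cc = config.cluster
    table = _subject_table(out)
    grand = read_templates(out / "grand_templates.tsv")
    fit_dir = out / "segmentations"
    fit_dir.mkdir(exist_ok=True)
    outputs = []
    for _, row in table.iterrows():
        dst = fit_dir / f"{row['subject']}_segmentation.tsv"
        outputs.append(dst)
        eps = read_epochs(out / "preprocessed" / f"{row['subject']}_epochs.tsv")
        seg = core.backfit(eps, grand, fit_domain=cc.fit_domain)
        if cc.smooth_ms > 0:
            seg = core.smooth_labels(seg, cc.smooth_ms)
        write_segmentation(seg, dst)
        state.setdefault("segmentations", {})[row["subject"]] = seg
    return outputs


def _stage_metrics(config, out: Path, seed_seq, state, resume) -> list[Path]:
    cc = config.cluster
    table = _subject_table(out)
    grand = read_templates(out / "grand_templates.tsv")
    tidy_rows = []
    wide = table.copy()
    for _, row in table.iterrows():
        seg = state.get("segmentations", {}).get(row["subject"])
        if seg is None:
            seg = _read_segmentation(
                out / "segmentations" / f"{row['subject']}_segmentation.tsv",
                list(grand.labels), config.preprocess.resample_hz)
        sm = core.compute_metrics(seg, boundary_policy=cc.boundary_policy)
        for j, cname in enumerate(sm.class_names):
            tidy_rows.append(
                {"subject": row["subject"], "group": row["group"],
                 "class": cname, "duration_ms": sm.duration_ms[j],
                 "occurrence_per_s": sm.occurrence_per_s[j],
                 "contribution": sm.contribution[j]}
            )
            wide.loc[wide["subject"] == row["subject"],
                     f"duration_{cname}"] = sm.duration_ms[j]
            wide.loc[wide["subject"] == row["subject"],
                     f"occurrence_{cname}"] = sm.occurrence_per_s[j]
            wide.loc[wide["subject"] == row["subject"],
                     f"contribution_{cname}"] = sm.contribution[j] * 100.0
    tidy_path = out / "metrics.tsv"
    pd.DataFrame(tidy_rows).to_csv(tidy_path, sep="\t", index=False)
    wide_path = out / "cohort_metrics.tsv"
    wide.to_csv(wide_path, sep="\t", index=False)
    return [tidy_path, wide_path]


def _read_segmentation(path: Path, names: list[str], sfreq: float):
    from .types import MicrostateSegmentation

    df = pd.read_csv(path, sep="\t")
    n_ep = int(df["epoch"].max()) + 1
    n = int(df["sample"].max()) + 1
    idx = {name: i for i, name in enumerate(names)}
    lab = df["label"].map(lambda s: idx.get(s, UNASSIGNED)).to_numpy()
    return MicrostateSegmentation(
        lab.reshape(n_ep, n),
        df["correlation"].to_numpy().reshape(n_ep, n),
        names,
        sfreq,
    )


def _stage_stats(config, out: Path, seed_seq, state, resume) -> list[Path]:
    from . import stats as stats_mod

    table = pd.read_csv(out / "cohort_metrics.tsv", sep="\t")
    grand = read_templates(out / "grand_templates.tsv")
    report = stats_mod.run_statistics(
        table,
        class_labels=list(grand.labels),
        scale=config.stats.scale,
        variance=config.stats.variance,
        chi2_correction=config.stats.chi2_correction,
        posthoc_gate=config.stats.posthoc_gate,
    )
    outputs = []
    for name in ("demographics", "rm_anova", "posthoc", "correlations"):
        p = out / f"stats_{name}.tsv"
        report[name].to_csv(p, sep="\t", index=False)
        outputs.append(p)
    log_path = out / "stats_log.txt"
    log_path.write_text("\n".join(report["log"]) + "\n")
    outputs.append(log_path)
    state["stats"] = report
    return outputs


def _stage_report(config, out: Path, seed_seq, state, resume) -> list[Path]:
    table = pd.read_csv(out / "cohort_metrics.tsv", sep="\t")
    cluster_summary = pd.read_csv(
        out / "templates" / "clustering_summary.tsv", sep="\t")
    lines = [
        f"microstates pipeline v{__version__}",
        f"subjects: {len(table)} "
        f"({table.groupby('group').size().to_dict()})",
        f"mean individual GEV: {cluster_summary['gev'].mean():.3f}",
    ]
    gev_by_group = cluster_summary.groupby("group")["gev"].mean()
    for grp, val in gev_by_group.items():
        lines.append(f"  GEV [{grp}]: {100 * val:.1f}%")
    grand = read_templates(out / "grand_templates.tsv")
    lines.append(f"grand templates: K={grand.n_classes}, "
                 f"C={grand.n_channels}")
    rm = pd.read_csv(out / "stats_rm_anova.tsv", sep="\t")
    lines.append("omnibus rm-ANOVA (GG-corrected p):")
    for _, r in rm.iterrows():
        lines.append(
            f"  {r['effect']}: F({r['df1_gg']:.3f},{r['df2_gg']:.3f}) = "
            f"{r['F']:.3f}, p = {r['p_gg']:.4f}"
        )
    summary = out / "report.txt"
    summary.write_text("\n".join(lines) + "\n")
    outputs = [summary]

    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(1, 3, figsize=(12, 3.2))
        names = list(grand.labels)
        for ax, param in zip(axes, ("duration", "occurrence", "contribution")):
            for grp, sub in table.groupby("group"):
                means = [sub[f"{param}_{c}"].mean() for c in names]
                ax.plot(names, means, marker="o", label=grp)
            ax.set_title(param)
        axes[0].legend()
        fig.tight_layout()
        fig_path = out / "metrics_by_group.png"
        fig.savefig(fig_path, dpi=100)
        plt.close(fig)
        outputs.append(fig_path)
    except Exception:  # plotting is best-effort only
        pass
    return outputs
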