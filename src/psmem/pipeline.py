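"""End-to-end orchestration: simulate -> estimate -> rsa -> behavior -> stats
-> searchlight -> report.

Every stage is a pure function of the validated configuration plus the
tabular outputs of earlier stages (persisted as TSV in the output
directory), so stages can be re-run in isolation and two runs with the same
configuration produce byte-identical tidy outputs. A run manifest records
every file written, its content hash, the stage seeds and wall-clock times.
"""

from __future__ import annotations

import time
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from . import io as pio
from .behavior_sim import generate_behavior, generate_fly_performance
from .design import StudyDesign, generate_design
from .estimation import (compute_fd_dvars, detect_outlier_volumes, fit_object_glm,
                         compute_tstat_patterns, qc_participant, usable_presentations)
from .patterns import SESSIONS, GeneratorParams, generate_patterns, generate_pattern_volumes
from .rsa import (build_pair_table, incongruent_category_mean, mds_embed,
                  reorganization, within_day_matrix, SimilarityMatrix)
from .schedule import generate_pvt_schedule
from .scoring import bias_summary, score_behavior
from .searchlight import (TfceParams, build_spheres, sign_flip_test,
                          sphere_stat_map)
from .stats import LmmSpec, fit_lmm, holm_adjust, mixed_anova, wilcoxon_signed_rank
from .timeseries import generate_timeseries

STAGES = ("simulate", "estimate", "rsa", "behavior", "stats", "searchlight", "report")

__all__ = ["PipelineConfig", "run_pipeline", "run_stage", "load_config", "STAGES"]


class GeneratorConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_voxels: int = 60
    category_effect: float = 0.1
    reorg_gap_congruent: float = 0.2
    reorg_gap_incongruent: float = 0.4
    group_reorg_shift: float = 0.1
    relevance_sim_boost: float = 0.15
    noise_sd: float = 1.0
    bias_probs_relevant: tuple[float, float, float] = (0.70, 0.15, 0.15)
    bias_probs_irrelevant: tuple[float, float, float] = (0.40, 0.40, 0.20)
    drop_noise_sd: float = 2.0
    recognition_miss_rate: float = 0.23
    fly_rate: float = 0.05
    fly_miss_rate: float = 0.02

    def to_params(self, seed: int) -> GeneratorParams:
        return GeneratorParams(seed=seed, **self.model_dump())


class EstimationConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    use_glm_path: bool = False
    fd_threshold: float = 0.5
    dvars_z: float = 3.0
    grid: tuple[int, int, int] = (6, 6, 6)
    tr: float = 1.0
    n_blocks: int = 2  # blocks per session in the GLM demonstration path


class StatsConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    holm_within_family: bool = True


class SearchlightConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    enabled: bool = True
    grid: tuple[int, int, int] = (10, 10, 10)
    radius: float = 2.0
    min_size: int = 10
    n_perm: int = 200
    predictor: str = "category"
    plant_signal: bool = True
    region: tuple[tuple[int, int], tuple[int, int], tuple[int, int]] = \
        ((2, 7), (2, 7), (2, 7))
    n_participants: int = 8
    alpha: float = 0.05


class PipelineConfig(BaseModel):
    """Validated pipeline configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")
    seed: int = 0
    n_participants: int = 12
    output_dir: str = "psmem_out"
    generator: GeneratorConfig = Field(default_factory=GeneratorConfig)
    estimation: EstimationConfig = Field(default_factory=EstimationConfig)
    stats: StatsConfig = Field(default_factory=StatsConfig)
    searchlight: SearchlightConfig = Field(default_factory=SearchlightConfig)


def load_config(path: str | Path) -> PipelineConfig:
    import yaml

    raw = yaml.safe_load(Path(path).read_text()) or {}
    return PipelineConfig(**raw)


def _participants(cfg: PipelineConfig) -> list[StudyDesign]:
    out = []
    for i in range(cfg.n_participants):
        group = "cortisol" if i % 2 == 0 else "placebo"
        out.append(generate_design(seed=cfg.seed * 10_000 + i, group=group,
                                   participant_id=f"sub-{i:03d}"))
    return out


def _params_for(cfg: PipelineConfig, design: StudyDesign) -> GeneratorParams:
    return cfg.generator.to_params(seed=design.seed)


# ---------------------------------------------------------------------------
# stages

def stage_simulate(cfg: PipelineConfig, outdir: Path) -> list[Path]:
    designs = _participants(cfg)
    d_frames, b_frames, p_frames, f_frames = [], [], [], []
    for design in designs:
        params = _params_for(cfg, design)
        d_frames.append(design.to_frame())
        b_frames.append(generate_behavior(design, params))
        pats = generate_patterns(design, params)
        for name in SESSIONS:
            df = pd.DataFrame(pats.sessions[name],
                              columns=[f"v{j}" for j in range(params.n_voxels)])
            df.insert(0, "object_id", np.arange(len(df)))
            df.insert(0, "session", name)
            df.insert(0, "participant_id", design.participant_id)
            p_frames.append(df)
        for day in ("pre", "post"):
            sched = generate_pvt_schedule(design, fly_rate=params.fly_rate, day=day)
            f_frames.append(generate_fly_performance(sched, params,
                                                     design.participant_id, day))
    return [
        pio.write_tsv(pd.concat(d_frames, ignore_index=True), outdir / "designs.tsv"),
        pio.write_tsv(pd.concat(b_frames, ignore_index=True), outdir / "behavior_raw.tsv"),
        pio.write_tsv(pd.concat(p_frames, ignore_index=True), outdir / "patterns.tsv"),
        pio.write_tsv(pd.concat(f_frames, ignore_index=True), outdir / "fly_performance.tsv"),
    ]


def stage_estimate(cfg: PipelineConfig, outdir: Path) -> list[Path]:
    """Motion QC for all participants; optionally the full GLM pattern path.

    The default pipeline feeds RSA from the directly simulated patterns; the
    GLM path regenerates them from synthetic time series (slower, used to
    validate the estimation chain end to end).
    """
    designs = _participants(cfg)
    fly = pio.read_tsv(outdir / "fly_performance.tsv")
    qc_rows = []
    glm_frames = []
    for design in designs:
        params = _params_for(cfg, design)
        usable = {}
        for day in ("pre", "post"):
            sched = generate_pvt_schedule(design, fly_rate=params.fly_rate, day=day)
            usable[day] = usable_presentations(sched)
            if cfg.estimation.use_glm_path:
                for session in range(2):
                    run = generate_timeseries(design, sched, params, session=session,
                                              day=day, shape=cfg.estimation.grid,
                                              tr=cfg.estimation.tr,
                                              n_blocks=cfg.estimation.n_blocks)
                    trace = compute_fd_dvars(run.data, run.motion)
                    outliers = detect_outlier_volumes(trace, cfg.estimation.fd_threshold,
                                                      cfg.estimation.dvars_z)
                    glm = fit_object_glm(run.data, run.events, run.motion, outliers,
                                         tr=run.tr)
                    tpat, _ = compute_tstat_patterns(glm)
                    name = f"{day}{session + 1}"
                    # reindex to all 24 objects; unestimable objects stay NaN
                    full = np.full((24, tpat.shape[1]), np.nan)
                    full[list(glm.object_ids)] = tpat
                    df = pd.DataFrame(full, columns=[f"v{j}"
                                                     for j in range(full.shape[1])])
                    df.insert(0, "object_id", np.arange(24))
                    df.insert(0, "session", name)
                    df.insert(0, "participant_id", design.participant_id)
                    glm_frames.append(df)
        perf = fly[fly["participant_id"] == design.participant_id]
        decision = qc_participant(usable, perf)
        qc_rows.append({"participant_id": design.participant_id,
                        "include": decision.include,
                        "reasons": "; ".join(decision.reasons)})
    written = [pio.write_tsv(pd.DataFrame(qc_rows), outdir / "qc.tsv")]
    if glm_frames:
        written.append(pio.write_tsv(pd.concat(glm_frames, ignore_index=True),
                                     outdir / "patterns_glm.tsv"))
    return written


def _load_patterns(cfg: PipelineConfig, outdir: Path) -> dict[str, dict[str, np.ndarray]]:
    src = outdir / ("patterns_glm.tsv" if cfg.estimation.use_glm_path
                    and (outdir / "patterns_glm.tsv").exists() else "patterns.tsv")
    df = pio.read_tsv(src)
    vox_cols = [c for c in df.columns if c.startswith("v")]
    out: dict[str, dict[str, np.ndarray]] = {}
    for (pid, session), grp in df.groupby(["participant_id", "session"]):
        grp = grp.sort_values("object_id")
        out.setdefault(pid, {})[session] = grp[vox_cols].to_numpy()
    return out


def stage_behavior(cfg: PipelineConfig, outdir: Path) -> list[Path]:
    raw = pio.read_tsv(outdir / "behavior_raw.tsv")
    scored = score_behavior(raw)
    summary = bias_summary(scored)
    return [
        pio.write_tsv(scored, outdir / "behavior_scored.tsv"),
        pio.write_tsv(summary, outdir / "bias_summary.tsv"),
    ]


def stage_rsa(cfg: PipelineConfig, outdir: Path) -> list[Path]:
    designs = {d.participant_id: d for d in _participants(cfg)}
    patterns = _load_patterns(cfg, outdir)
    scored = pio.read_tsv(outdir / "behavior_scored.tsv")
    pair_frames, reorg_frames, cond_frames = [], [], []
    mean_pre = None
    for pid, sess in patterns.items():
        design = designs[pid]
        beh = scored[scored["participant_id"] == pid]
        pre = within_day_matrix(sess["pre1"], sess["pre2"], day="pre",
                                participant_id=pid)
        post = within_day_matrix(sess["post1"], sess["post2"], day="post",
                                 participant_id=pid)
        pair_frames.append(build_pair_table(pre, post, design, beh))
        reorg_frames.append(reorganization((sess["pre1"], sess["pre2"]),
                                           (sess["post1"], sess["post2"]),
                                           design, participant_id=pid))
        cond_frames.append(incongruent_category_mean(post, design, "relevance"))
        cond_frames.append(incongruent_category_mean(post, design, "room_choice", beh))
        mean_pre = pre.values if mean_pre is None else mean_pre + pre.values
    mean_pre = mean_pre / len(patterns)
    mds = mds_embed(SimilarityMatrix(values=mean_pre, day="pre"))
    any_design = next(iter(designs.values()))
    mds_df = pd.DataFrame({"object_id": np.arange(len(mds)),
                           "x": mds[:, 0], "y": mds[:, 1],
                           "category": [o.category for o in any_design.objects]})
    return [
        pio.write_tsv(pd.concat(pair_frames, ignore_index=True),
                      outdir / "pair_table.tsv"),
        pio.write_tsv(pd.concat(reorg_frames, ignore_index=True),
                      outdir / "reorganization.tsv"),
        pio.write_tsv(pd.concat(cond_frames, ignore_index=True),
                      outdir / "condition_means.tsv"),
        pio.write_tsv(mds_df, outdir / "mds_pre.tsv"),
    ]


def _family_holm(results: list[dict], enabled: bool) -> list[dict]:
    if not results:
        return results
    if enabled:
        by_family: dict[str, list[int]] = {}
        for i, r in enumerate(results):
            by_family.setdefault(r["family"], []).append(i)
        for idxs in by_family.values():
            adj = holm_adjust([results[i]["p"] for i in idxs])
            for i, a in zip(idxs, adj):
                results[i]["p_holm"] = float(a)
    else:
        adj = holm_adjust([r["p"] for r in results])
        for r, a in zip(results, adj):
            r["p_holm"] = float(a)
    return results


def stage_stats(cfg: PipelineConfig, outdir: Path) -> list[Path]:
    scored = pio.read_tsv(outdir / "behavior_scored.tsv")
    pairs = pio.read_tsv(outdir / "pair_table.tsv")
    reorg = pio.read_tsv(outdir / "reorganization.tsv")
    cond = pio.read_tsv(outdir / "condition_means.tsv")
    bias = pio.read_tsv(outdir / "bias_summary.tsv")
    rows: list[dict] = []

    def add(family: str, res, extra: str = ""):
        for t in (res.tests if hasattr(res, "tests") else res):
            d = t.to_dict()
            d["family"] = family
            d["analysis"] = extra or family
            rows.append(d)

    # drop error ~ congruence * relevance + group (recognized objects only)
    rec = scored[scored["recognized"]]
    if len(rec) and rec["participant_id"].nunique() >= 2:
        add("drop_error", fit_lmm(rec, LmmSpec(
            outcome="drop_error",
            fixed=("congruent", "task_relevant", "congruent:task_relevant"),
            covariates=("group",))))

    # semantic bias: semantic vs unrelated proportions per relevance level
    for relevant in (True, False):
        cell = bias[(bias["task_relevant"] == relevant) & (bias["n"] > 0)]
        if len(cell) >= 3:
            t = wilcoxon_signed_rank(cell["p_semantic"].to_numpy(),
                                     cell["p_unrelated"].to_numpy())
            d = t.to_dict()
            d["effect"] = f"semantic_vs_unrelated[task_relevant={relevant}]"
            d["family"] = "semantic_bias"
            d["analysis"] = "semantic_bias"
            rows.append(d)

    # pre-encoding similarity ~ same_category + group (pair level)
    add("category_pre", fit_lmm(pairs, LmmSpec(
        outcome="z_pre", fixed=("same_category",), covariates=("group",))))

    # incongruent-to-congruent category means: mixed ANOVAs
    for split in ("relevance", "room_choice"):
        sub = cond[cond["split"] == split]
        try:
            add(f"anova_{split}", mixed_anova(sub, dv="mean_z",
                                              within="condition", between="group"))
        except ValueError:
            pass

    # pattern reorganization ~ congruence / relevance (+ group), recognized only
    rec_ids = scored[scored["recognized"]][["participant_id", "object_id"]]
    reorg_rec = reorg.merge(rec_ids, on=["participant_id", "object_id"])
    for pred in ("congruent", "task_relevant"):
        add("reorganization", fit_lmm(reorg_rec, LmmSpec(
            outcome="reorg_z", fixed=(pred,), covariates=("group",))),
            extra=f"reorg_{pred}")

    # pair-level change ~ retrieved distance / confidence (+ group), filtered
    ok_pairs = pairs[~pairs["excluded"].astype(bool)]
    if len(ok_pairs) > 10:
        for pred in ("retrieved_distance", "mean_confidence"):
            add("ps_change", fit_lmm(ok_pairs, LmmSpec(
                outcome="z_change", fixed=(pred,), covariates=("group",))),
                extra=f"change_{pred}")

    rows = _family_holm(rows, cfg.stats.holm_within_family)
    return [pio.write_tsv(pd.DataFrame(rows), outdir / "stats.tsv")]


def stage_searchlight(cfg: PipelineConfig, outdir: Path) -> list[Path]:
    sl = cfg.searchlight
    if not sl.enabled:
        return [pio.write_json({"enabled": False}, outdir / "searchlight.json")]
    shape = tuple(sl.grid)
    region = np.zeros(shape, dtype=bool)
    (x0, x1), (y0, y1), (z0, z1) = sl.region
    region[x0:x1, y0:y1, z0:z1] = True
    mask = np.ones(shape, dtype=bool)
    spheres = build_spheres(mask, radius=sl.radius, min_size=sl.min_size)
    maps = []
    for i in range(sl.n_participants):
        design = generate_design(seed=cfg.seed * 10_000 + 5000 + i,
                                 group="placebo", participant_id=f"sl-{i:03d}")
        params = cfg.generator.to_params(seed=design.seed)
        vols = generate_pattern_volumes(design, params, shape,
                                        signal_mask=region if sl.plant_signal else None)
        maps.append(sphere_stat_map(vols, design, sl.predictor, spheres, shape)["stat"])
    result = sign_flip_test(np.stack(maps), n_perm=sl.n_perm, params=TfceParams(),
                            seed=cfg.seed)
    sig = result.p_corrected < sl.alpha
    valid = ~np.isnan(maps[0])
    summary = {
        "n_spheres": int(valid.sum()),
        "n_significant": int((sig & valid).sum()),
        "n_significant_inside_region": int((sig & valid & region).sum()),
        "n_significant_outside_region": int((sig & valid & ~region).sum()),
        "n_perm": sl.n_perm,
        "alpha": sl.alpha,
        "predictor": sl.predictor,
    }
    return [
        pio.write_json(summary, outdir / "searchlight.json"),
        pio.write_nifti(result.p_corrected, outdir / "searchlight_p_fwe.nii.gz"),
        pio.write_nifti(result.tfce_observed, outdir / "searchlight_tfce.nii.gz"),
    ]


def stage_report(cfg: PipelineConfig, outdir: Path) -> list[Path]:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    lines = ["# Pipeline report", ""]
    written: list[Path] = []

    def section(title: str, path: Path, render) -> None:
        lines.append(f"## {title}")
        if path.exists():
            try:
                render(path)
            except Exception as exc:  # pragma: no cover - defensive
                lines.append(f"_failed to render: {exc}_")
        else:
            lines.append("_no data_")
        lines.append("")

    def render_drop(path: Path) -> None:
        df = pio.read_tsv(outdir / "behavior_scored.tsv")
        df = df[df["recognized"]]
        if df.empty:
            lines.append("_no data_")
            return
        tab = df.groupby(["congruent", "task_relevant"])["drop_error"].mean().reset_index()
        lines.append(tab.to_markdown(index=False))

    def render_bias(path: Path) -> None:
        df = pio.read_tsv(path)
        tab = df.groupby("task_relevant")[["p_episodic", "p_semantic",
                                           "p_unrelated"]].mean().reset_index()
        lines.append(tab.to_markdown(index=False))

    def render_cond(path: Path) -> None:
        df = pio.read_tsv(path)
        tab = df.groupby(["split", "condition"])["mean_z"].mean().reset_index()
        lines.append(tab.to_markdown(index=False))

    def render_reorg(path: Path) -> None:
        df = pio.read_tsv(path)
        tab = df.groupby("congruent")["reorg_z"].mean().reset_index()
        lines.append(tab.to_markdown(index=False))

    def render_stats(path: Path) -> None:
        df = pio.read_tsv(path)
        cols = ["analysis", "effect", "stat_type", "statistic", "df1", "df2",
                "p", "p_holm"]
        lines.append(df[[c for c in cols if c in df.columns]]
                     .to_markdown(index=False))

    def render_sl(path: Path) -> None:
        lines.append("```json")
        lines.append(path.read_text().strip())
        lines.append("```")

    section("Drop error by congruence x relevance", outdir / "behavior_scored.tsv",
            render_drop)
    section("Room-sorting proportions", outdir / "bias_summary.tsv", render_bias)
    section("Incongruent-to-congruent category similarity",
            outdir / "condition_means.tsv", render_cond)
    section("Pattern reorganization by congruence", outdir / "reorganization.tsv",
            render_reorg)
    section("Model results", outdir / "stats.tsv", render_stats)
    section("Searchlight", outdir / "searchlight.json", render_sl)

    mds_path = outdir / "mds_pre.tsv"
    if mds_path.exists():
        df = pio.read_tsv(mds_path)
        fig, ax = plt.subplots(figsize=(5, 5))
        for cat, grp in df.groupby("category"):
            ax.scatter(grp["x"], grp["y"], label=cat)
        ax.legend()
        ax.set_title("MDS of mean pre-encoding similarity")
        fig_path = outdir / "mds_pre.png"
        fig.savefig(fig_path, dpi=100)
        plt.close(fig)
        written.append(fig_path)
        lines.append("## MDS embedding")
        lines.append("![MDS](mds_pre.png)")
        lines.append("")

    report = outdir / "report.md"
    report.write_text("\n".join(lines))
    return [report, *written]


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "estimate": stage_estimate,
    "behavior": stage_behavior,
    "rsa": stage_rsa,
    "stats": stage_stats,
    "searchlight": stage_searchlight,
    "report": stage_report,
}

# behavior scoring must precede RSA (pair tables join scored columns)
_STAGE_ORDER = ("simulate", "estimate", "behavior", "rsa", "stats",
                "searchlight", "report")


def run_stage(cfg: PipelineConfig, stage: str, outdir: Path | None = None) -> list[Path]:
    outdir = Path(cfg.output_dir) if outdir is None else Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if stage not in _STAGE_FUNCS:
        raise ValueError(f"unknown stage {stage!r}; choose from {_STAGE_ORDER}")
    return _STAGE_FUNCS[stage](cfg, outdir)


def run_pipeline(cfg: PipelineConfig, outdir: Path | None = None) -> dict:
    """Run all stages in order; returns and writes the run manifest."""
    outdir = Path(cfg.output_dir) if outdir is None else Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": cfg.seed, "stages": []}
    for stage in _STAGE_ORDER:
        t0 = time.time()
        try:
            files = run_stage(cfg, stage, outdir)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
        manifest["stages"].append({
            "stage": stage,
            "seconds": round(time.time() - t0, 3),
            "outputs": {str(p.relative_to(outdir)): pio.sha256_file(p)
                        for p in files},
        })
    pio.write_json(manifest, outdir / "manifest.json")
    return manifest
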