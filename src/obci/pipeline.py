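"""Configuration and orchestration: simulate -> preprocess -> rois -> tuning ->
population -> decode -> report.

The configuration is YAML, schema-validated (pydantic) before any stage runs,
and serialized into the run directory for provenance together with a manifest
of content hashes of every written artifact.  Every random draw flows from the
single global seed through named per-stage substreams, so re-running with the
same config reproduces identical artifacts and disabling one stage does not
perturb the randomness of the others.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, ValidationError

from . import io as _io
from .errors import ConfigError
from .population import (
    compute_cis,
    compute_tdr_axes,
    orthonormalize_axes,
    project_trajectories,
    trial_tensor,
    variance_spectrum,
)
from .preprocess import compute_dff, register_rigid, zscore_responses
from .rois import (
    ROIMaskSet,
    classify_dendritic,
    cluster_response_check,
    detect_duplicates,
    extract_traces,
)
from .synth import (
    SessionConfig,
    generate_ground_truth,
    generate_trials,
    render_movie,
    save_ground_truth,
    stage_rng,
)
from .tuning import analyze_tuning
from .decode import (
    decode_score_timecourse,
    offline_svm_decode,
    run_session,
    train_templates,
)

log = logging.getLogger("obci")

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]


class StageToggles(BaseModel):
    preprocess: bool = True
    rois: bool = True
    tuning: bool = True
    population: bool = True
    decode: bool = True
    report: bool = True


class DecodeSettings(BaseModel):
    t_skip_ms: float = Field(300.0, ge=0)
    t_int_ms: float = Field(132.0, gt=0)
    sigma_px: float = Field(3.0, ge=0)
    n_train_per_target: int = Field(10, ge=1)
    svm_times_ms: list[float] = Field(default_factory=lambda: [0.0, 100.0, 200.0])
    svm_downsample: int = Field(4, ge=1)  # spatial binning factor for SVM features


class TuningSettings(BaseModel):
    compute_stability: bool = False
    n_shuffles: int = Field(1000, ge=100)


class PipelineConfig(BaseModel):
    seed: int = 0
    out_dir: str = "obci_run"
    control: bool = False
    session: dict = Field(default_factory=dict)
    stages: StageToggles = Field(default_factory=StageToggles)
    decode: DecodeSettings = Field(default_factory=DecodeSettings)
    tuning: TuningSettings = Field(default_factory=TuningSettings)
    verbosity: str = "INFO"

    def session_config(self) -> SessionConfig:
        d = dict(self.session)
        d["rng_seed"] = self.seed
        return SessionConfig.from_dict(d)


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    try:
        return PipelineConfig(**raw)
    except ValidationError as exc:
        raise ConfigError(f"invalid pipeline configuration: {exc}") from exc


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _downsample_movie(movie, factor: int):
    """Spatial block-mean binning (SVM feature reduction at large FOVs)."""
    from .synth import ImagingMovie

    if factor == 1:
        return movie
    T, H, W = movie.frames.shape
    Hc, Wc = H // factor, W // factor
    f = movie.frames[:, : Hc * factor, : Wc * factor]
    f = f.reshape(T, Hc, factor, Wc, factor).mean(axis=(2, 4))
    return ImagingMovie(
        frames=f, frame_times_ms=movie.frame_times_ms, frame_rate=movie.frame_rate
    )


def run_pipeline(config: PipelineConfig) -> Path:
    """Run all enabled stages and return the run directory.

    Failures in one stage propagate immediately (downstream stages never run
    on missing inputs); every artifact's content hash is logged to
    ``manifest.json``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.verbosity.upper(), logging.INFO))
    (out / "config.yaml").write_text(yaml.safe_dump(config.model_dump()))
    manifest: dict[str, str] = {}

    def record(path: Path) -> None:
        manifest[str(path.relative_to(out))] = _sha256(path)

    scfg = config.session_config()

    # --- simulate ---------------------------------------------------------
    log.info("simulate: seed=%d fov=%dx%d targets=%d trials/target=%d control=%s",
             config.seed, scfg.fov_height_px, scfg.fov_width_px, scfg.n_targets,
             scfg.n_trials_per_target, config.control)
    rng = stage_rng(config.seed, "simulate")
    trials, hand = generate_trials(scfg, rng)
    truth = generate_ground_truth(scfg, rng, control=config.control)
    movie = render_movie(truth, trials, hand, scfg, rng)
    _io.write_trials_csv(trials, out / "trials.csv")
    _io.write_hand_csv(hand, out / "hand.csv")
    save_ground_truth(truth, out / "ground_truth.json")
    _io.write_movie_npz(movie, out / "movie.npz")
    if movie.shifts is not None:
        _io.write_shifts_csv(movie.shifts, out / "true_shifts.csv")
    for p in ("trials.csv", "hand.csv", "ground_truth.json", "movie.npz"):
        record(out / p)

    # --- preprocess -------------------------------------------------------
    if config.stages.preprocess and scfg.motion_jitter_px > 0:
        log.info("preprocess: rigid registration of %d frames", movie.n_frames)
        reg = register_rigid(movie)
        _io.write_shifts_csv(reg.estimated_shifts, out / "estimated_shifts.csv")
        record(out / "estimated_shifts.csv")
        work_movie = reg.movie
    else:
        work_movie = movie

    results: dict = {}

    # --- rois -------------------------------------------------------------
    if config.stages.rois:
        masks = ROIMaskSet.from_ground_truth(truth, work_movie.fov_shape)
        masks.to_json(out / "masks.json")
        record(out / "masks.json")
        traces = extract_traces(work_movie, masks)
        dff = np.vstack([
            compute_dff(t, scfg.frame_rate).values for t in traces.values
        ])
        cls = pd.DataFrame(
            [
                dict(roi=i, shape_class=classify_dendritic(m)[0],
                     aspect_ratio=classify_dendritic(m)[1], area_px=m.area_px,
                     true_class=m.label)
                for i, m in enumerate(masks)
            ]
        )
        np.savez_compressed(out / "dff.npz", dff=dff,
                            frame_times_ms=traces.frame_times_ms)
        record(out / "dff.npz")
        dups = detect_duplicates(dff, rho_threshold=0.8)
        cls["duplicate_flag"] = False
        for i, j, _ in dups:
            cls.loc[[i, j], "duplicate_flag"] = True
        cls.to_csv(out / "roi_classification.csv", index=False)
        record(out / "roi_classification.csv")
        log.info("rois: %d ROIs, %d dendritic, %d duplicate pairs",
                 len(masks), int((cls.shape_class == "dendritic").sum()), len(dups))
        results.update(masks=masks, dff=dff, traces=traces, classification=cls)
        if len(masks) >= 5:
            # do trial-averaged responses form a continuum or separable groups?
            tens, _, targets = trial_tensor(
                dff, work_movie.frame_times_ms, trials[trials["success"]]
            )
            dirs = np.sort(np.unique(targets))
            vecs = np.hstack(
                [tens[targets == k].mean(axis=0) for k in dirs]
            )  # (roi, time * n_dirs)
            _, n_clusters, n_noise = cluster_response_check(vecs)
            results["response_clusters"] = (n_clusters, n_noise)
            log.info("rois: response clustering found %d cluster(s), %d noise point(s)",
                     n_clusters, n_noise)
    else:
        if config.stages.tuning or config.stages.population:
            raise ConfigError("tuning/population stages require the rois stage")

    frame_times = work_movie.frame_times_ms

    # --- tuning -----------------------------------------------------------
    if config.stages.tuning:
        log.info("tuning: per-ROI statistics on %d ROIs", results["dff"].shape[0])
        tune = analyze_tuning(
            results["dff"], frame_times, trials, hand,
            compute_stability=config.tuning.compute_stability,
            n_shuffles=config.tuning.n_shuffles,
            rng=stage_rng(config.seed, "tuning"),
        )
        tune.to_csv(out / "tuning.csv", index=False)
        record(out / "tuning.csv")
        results["tuning"] = tune

    # --- population -------------------------------------------------------
    if config.stages.population and config.stages.tuning:
        tune = results["tuning"]
        tuned = tune[tune["direction_tuned"]].index.to_numpy()
        if tuned.size >= 3:
            z, flagged = zscore_responses(results["dff"], frame_times, trials)
            z = np.nan_to_num(z)
            tens, rel, targets = trial_tensor(
                z[tuned], frame_times, trials[trials["success"]]
            )
            dirs = np.sort(np.unique(targets))
            # (roi, time, direction)
            avg = np.stack([tens[targets == k].mean(axis=0) for k in dirs], axis=2)
            cis = compute_cis(avg)
            B = tune.loc[tuned, ["beta_x", "beta_y"]].to_numpy()
            tdr_x, tdr_y = compute_tdr_axes(B)
            axes = orthonormalize_axes(cis, tdr_x, tdr_y)
            single, avg_proj, rel_p, targ = project_trajectories(
                z[tuned], frame_times, trials[trials["success"]], axes
            )
            pd.DataFrame(
                dict(roi=tuned, cis=axes.cis, tdr_x=axes.tdr_x, tdr_y=axes.tdr_y)
            ).to_csv(out / "population_axes.csv", index=False)
            record(out / "population_axes.csv")
            # scree on the spatially binned movie: the pixel Gram matrix at
            # full FOV (16k x 16k at 128 px) does not fit the analysis budget
            scree_movie = _downsample_movie(work_movie, config.decode.svm_downsample)
            scree = variance_spectrum(
                scree_movie.frames.reshape(scree_movie.n_frames, -1)
            )
            pd.DataFrame(dict(eigenvalue=scree)).to_csv(out / "scree.csv", index=False)
            record(out / "scree.csv")
            results["scree"] = scree
            results.update(axes=axes, projections=(single, avg_proj, rel_p, targ))
            log.info("population: %d tuned ROIs, scree captured", tuned.size)
        else:
            log.warning("population: fewer than 3 direction-tuned ROIs; skipped")

    # --- decode -----------------------------------------------------------
    if config.stages.decode:
        dc = config.decode
        log.info("decode: online MMSE (T_skip=%g ms, T_int=%g ms, sigma=%g px)",
                 dc.t_skip_ms, dc.t_int_ms, dc.sigma_px)
        summary, outcomes = run_session(
            movie, trials, dc.t_skip_ms, dc.t_int_ms, dc.sigma_px,
            dc.n_train_per_target,
        )
        outcomes.to_csv(out / "decode_trials.csv", index=False)
        record(out / "decode_trials.csv")
        summary_d = dict(
            n_success=summary.n_success, n_fail=summary.n_fail,
            success_rate_pct=summary.success_rate_pct,
            p_binomial=summary.p_binomial, chance=summary.chance,
        )
        (out / "decode_summary.json").write_text(json.dumps(summary_d, indent=2))
        record(out / "decode_summary.json")
        results["decode_summary"] = summary_d

        # score timecourse and SVM run on the spatially binned movie: the
        # rolling blurred-frame buffer at full FOV would dominate memory
        svm_movie = _downsample_movie(movie, dc.svm_downsample)
        templates = train_templates(
            svm_movie,
            trials[trials["success"]].iloc[: dc.n_train_per_target * scfg.n_targets],
            dc.t_skip_ms, dc.t_int_ms, dc.sigma_px,
        )
        scores, rel_s, targ_s = decode_score_timecourse(svm_movie, trials, templates)
        results["score_timecourse"] = (scores, rel_s, targ_s)

        svm = offline_svm_decode(
            svm_movie, trials, "move", np.asarray(dc.svm_times_ms),
            seed=config.seed,
        )
        svm.to_csv(out / "svm_accuracy.csv", index=False)
        record(out / "svm_accuracy.csv")
        results["svm"] = svm
        log.info("decode: online %.1f%% (p=%.3g), offline SVM @%s ms: %s",
                 summary.success_rate_pct, summary.p_binomial,
                 dc.svm_times_ms, [f"{a:.2f}" for a in svm["accuracy"]])

    # --- report -----------------------------------------------------------
    if config.stages.report:
        _write_report(out, config, scfg, trials, results, record)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    log.info("run complete: %s", out)
    return out


def _write_report(out: Path, config: PipelineConfig, scfg: SessionConfig,
                  trials: pd.DataFrame, results: dict, record) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    lines = [
        "# oBCI pipeline report",
        "",
        f"- seed: {config.seed}",
        f"- FOV: {scfg.fov_height_px}x{scfg.fov_width_px} px at {scfg.frame_rate} Hz",
        f"- targets: {scfg.n_targets}, trials/target: {scfg.n_trials_per_target}",
        f"- control mode: {config.control}",
        "",
    ]

    if "classification" in results:
        cls = results["classification"]
        lines += [
            f"- ROIs: {len(cls)} ({int((cls.shape_class == 'dendritic').sum())} "
            f"classified dendritic)",
        ]
    if "response_clusters" in results:
        n_clusters, n_noise = results["response_clusters"]
        lines += [
            f"- response-continuum check (DBSCAN): {n_clusters} cluster(s), "
            f"{n_noise} noise point(s)",
        ]
    if "tuning" in results:
        tune = results["tuning"]
        lines += [
            f"- movement-responsive (rank-sum p<0.01): "
            f"{int((tune.p_move < 0.01).sum())}/{len(tune)}",
            f"- direction-tuned (ANOVA p<0.01): "
            f"{int(tune.direction_tuned.sum())}/{len(tune)}",
        ]
        if "masks" in results:
            fig, ax = plt.subplots(figsize=(5, 5))
            masks = results["masks"]
            img = np.zeros((*masks.fov_shape, 3))
            import matplotlib.colors as mcolors
            for i, m in enumerate(masks):
                if not tune.loc[i, "direction_tuned"]:
                    continue
                hue = (tune.loc[i, "pd_deg"] % 360.0) / 360.0
                rgb = mcolors.hsv_to_rgb([hue, 1.0, 1.0])
                img[m.rows, m.cols] = rgb * m.weights[:, None]
            ax.imshow(img, origin="upper")
            ax.set_title("preferred-direction map (tuned ROIs)")
            fig.savefig(out / "fig_tuning_map.png", dpi=100)
            plt.close(fig)
            record(out / "fig_tuning_map.png")

        if "dff" in results:
            fig, ax = plt.subplots(figsize=(6, 4))
            order = np.argsort(tune["pd_deg"].to_numpy())
            ax.imshow(results["dff"][order], aspect="auto", cmap="gray_r",
                      interpolation="nearest")
            ax.set_xlabel("frame"); ax.set_ylabel("ROI (sorted by PD)")
            ax.set_title("dF/F raster")
            fig.savefig(out / "fig_raster.png", dpi=100)
            plt.close(fig)
            record(out / "fig_raster.png")

    if "projections" in results:
        single, avg_proj, rel_p, targ = results["projections"]
        fig, axs = plt.subplots(1, 2, figsize=(9, 4))
        dirs = np.sort(np.unique(targ))
        cmap = plt.get_cmap("tab10")
        for di, k in enumerate(dirs):
            axs[0].plot(rel_p, avg_proj[di, 0], color=cmap(di), lw=2,
                        label=f"target {k}")
            axs[1].plot(avg_proj[di, 1], avg_proj[di, 2], color=cmap(di), lw=2)
        axs[0].set_xlabel("time from movement onset (ms)")
        axs[0].set_ylabel("CIS projection"); axs[0].legend(fontsize=7)
        axs[1].set_xlabel("TDR-X"); axs[1].set_ylabel("TDR-Y")
        fig.suptitle("population trajectories")
        fig.savefig(out / "fig_trajectories.png", dpi=100)
        plt.close(fig)
        record(out / "fig_trajectories.png")

    if "scree" in results:
        scree = results["scree"]
        fig, ax = plt.subplots(figsize=(5, 4))
        n_show = min(50, scree.size)
        ax.semilogy(np.arange(1, n_show + 1), np.maximum(scree[:n_show], 1e-12), "o-",
                    ms=3)
        ax.set_xlabel("component"); ax.set_ylabel("eigenvalue")
        ax.set_title("pixel variance spectrum")
        fig.savefig(out / "fig_scree.png", dpi=100)
        plt.close(fig)
        record(out / "fig_scree.png")

    if "decode_summary" in results:
        s = results["decode_summary"]
        lines += [
            "",
            f"- online MMSE decode: {s['n_success']}/{s['n_success'] + s['n_fail']} "
            f"({s['success_rate_pct']:.1f}%), two-sided binomial p = "
            f"{s['p_binomial']:.3g} vs chance {100 * s['chance']:.0f}%",
        ]
    if "svm" in results:
        svm = results["svm"]
        lines += [f"- offline SVM accuracy: " + ", ".join(
            f"{t:.0f} ms: {a:.2f}" for t, a in zip(svm.time_ms, svm.accuracy)
        )]
        fig, axs = plt.subplots(1, 2, figsize=(9, 4))
        axs[0].plot(svm["time_ms"], svm["accuracy"], "o-")
        axs[0].axhline(results["decode_summary"]["chance"], ls="--", c="m")
        axs[0].set_xlabel("time from movement onset (ms)")
        axs[0].set_ylabel("5-fold CV accuracy")
        if "score_timecourse" in results:
            scores, rel_s, targ_s = results["score_timecourse"]
            true_sc = np.nanmean(
                np.stack([scores[i, k] for i, k in enumerate(targ_s)]), axis=0
            )
            other = np.nanmean(
                np.stack([
                    np.delete(scores[i], k, axis=0).mean(axis=0)
                    for i, k in enumerate(targ_s)
                ]), axis=0,
            )
            axs[1].plot(rel_s, true_sc, label="true target")
            axs[1].plot(rel_s, other, label="other targets")
            axs[1].set_xlabel("time from movement onset (ms)")
            axs[1].set_ylabel("decoder score (MSE)"); axs[1].legend(fontsize=8)
        fig.suptitle("decode performance")
        fig.savefig(out / "fig_decode.png", dpi=100)
        plt.close(fig)
        record(out / "fig_decode.png")

    (out / "report.md").write_text("\n".join(lines) + "\n")
    record(out / "report.md")
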