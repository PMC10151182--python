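"""End-to-end orchestration: simulate -> epoch -> band power -> grid fit ->
consistency -> behavior -> group statistics -> report.

The pipeline is driven by a validated :class:`PipelineConfig` (YAML on
disk); a single master seed fans out to per-participant child seeds via
``numpy.random.SeedSequence`` spawn keys, so adding participants does not
perturb existing ones.  Re-running with the same config reproduces all
stochastic results bit-identically; a manifest records the config hash,
seed and package version.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, ValidationError

from . import __version__
from . import behavior as behavior_mod
from . import circstat, cohortstats, epochs as epochs_mod, gridcode, spectral
from .errors import GridThetaError, InvalidArgumentError
from .synthcohort import (ArenaSpec, CohortSpec, DurationDist, KinematicsSpec,
                          OscillatorSpec, Participant, iter_participants)

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "AnalysisParams",
    "ParticipantSummary",
    "GridFitResult",
    "grid_fit",
    "analyze_participant",
    "run_pipeline",
    "report",
]


# ---------------------------------------------------------------------------
# configuration

class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ArenaConfig(_Strict):
    side_length: float = 100.0
    n_object_locations: int = 16


class DurationConfig(_Strict):
    mean: float
    sigma: float = 0.0
    kind: str = "lognormal"


class KinematicsConfig(_Strict):
    top_speed: float = 5.0
    accel_time: float = 0.3
    turn_speed: float = 90.0
    bout_duration: DurationConfig = DurationConfig(mean=2.2, sigma=0.35)
    pause_duration: DurationConfig = DurationConfig(mean=2.5, sigma=0.4)
    behavioral_sample_rate: float = 50.0


class OscillatorConfig(_Strict):
    signal_sample_rate: float = 200.0
    theta_freq: float = 7.0
    base_amp: float = 1.0
    movement_gain: float = 1.0
    onset_lead: float = 0.5
    grid_gain: float = 0.5
    grid_orientation: float = 0.0
    grid_symmetry: int = 6
    noise_exponent: float = 1.0
    noise_amp: float = 1.0
    n_voxels: int = 27
    grid_voxel_index: int = 13


class CohortConfig(_Strict):
    n_controls: int = 23
    n_patients: int = 17
    n_blocks: int = 3
    block_duration_s: float = 400.0
    arena: ArenaConfig = ArenaConfig()
    kinematics: KinematicsConfig = KinematicsConfig()
    oscillator: OscillatorConfig = OscillatorConfig()
    patient_movement_gain: float = 0.6
    patient_grid_gain: float = 0.0
    memory_error_scale_control: float = 8.0
    memory_error_scale_patient: float = 12.0
    participant_scale_sigma: float = 0.25
    orientation_mode: str = "per_block"
    orientation_jitter_deg: float = 5.0
    couple_instability_performance: bool = False


class AnalysisConfig(_Strict):
    alpha: float = 0.05
    band: tuple = spectral.THETA_BAND
    symmetry: int = 6
    symmetries: tuple = (4, 5, 6, 7, 8)
    width_deg: float = 15.0
    margin_vm: float = 25.0
    norm_mode: str = "relative"
    do_spectra: bool = True
    do_control_table: bool = False
    n_perm: int = 1000
    voxel_of_interest: Optional[int] = None  # default: the planted grid voxel


class PipelineConfig(_Strict):
    seed: int = 0
    cohort: CohortConfig = CohortConfig()
    analysis: AnalysisConfig = AnalysisConfig()

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        try:
            return cls.model_validate(raw)
        except ValidationError as e:
            raise InvalidArgumentError(f"invalid pipeline config: {e}") from e

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()

    def to_cohort_spec(self) -> CohortSpec:
        c = self.cohort
        return CohortSpec(
            n_controls=c.n_controls, n_patients=c.n_patients, n_blocks=c.n_blocks,
            block_duration_s=c.block_duration_s,
            arena=ArenaSpec(**c.arena.model_dump()),
            kinematics=KinematicsSpec(
                top_speed=c.kinematics.top_speed, accel_time=c.kinematics.accel_time,
                turn_speed=c.kinematics.turn_speed,
                bout_duration=DurationDist(**c.kinematics.bout_duration.model_dump()),
                pause_duration=DurationDist(**c.kinematics.pause_duration.model_dump()),
                behavioral_sample_rate=c.kinematics.behavioral_sample_rate),
            oscillator=OscillatorSpec(**c.oscillator.model_dump()),
            patient_movement_gain=c.patient_movement_gain,
            patient_grid_gain=c.patient_grid_gain,
            memory_error_scale_control=c.memory_error_scale_control,
            memory_error_scale_patient=c.memory_error_scale_patient,
            participant_scale_sigma=c.participant_scale_sigma,
            orientation_mode=c.orientation_mode,
            orientation_jitter_deg=c.orientation_jitter_deg,
            couple_instability_performance=c.couple_instability_performance,
            seed=self.seed,
        )


@dataclass
class AnalysisParams:
    band: tuple = spectral.THETA_BAND
    symmetry: int = 6
    symmetries: tuple = (4, 5, 6, 7, 8)
    width_deg: float = 15.0
    alpha: float = 0.05
    margin_vm: float = 25.0
    norm_mode: str = "relative"
    do_spectra: bool = True
    do_control_table: bool = False
    voxel_of_interest: Optional[int] = None

    @classmethod
    def from_config(cls, a: AnalysisConfig) -> "AnalysisParams":
        return cls(band=tuple(a.band), symmetry=a.symmetry,
                   symmetries=tuple(a.symmetries), width_deg=a.width_deg,
                   alpha=a.alpha, margin_vm=a.margin_vm, norm_mode=a.norm_mode,
                   do_spectra=a.do_spectra, do_control_table=a.do_control_table,
                   voxel_of_interest=a.voxel_of_interest)


# ---------------------------------------------------------------------------
# participant-level analysis

@dataclass
class ParticipantSummary:
    pid: str
    group: str
    beta: float                       # CV beta at the voxel of interest, Z units
    beta_raw: float                   # de-standardized beta (envelope units)
    beta_per_voxel: np.ndarray
    aligned_diff: float
    aligned_fraction: float
    consistency_voxels: float         # deg; NaN if single voxel
    consistency_partitions: float     # deg
    consistency_blocks: float         # deg; NaN if single block
    theta_contrast: float
    contrast_per_freq: np.ndarray
    contrast_tf: np.ndarray
    performance: float
    mean_error_vm: float
    mean_bout_s: float
    boundary_pct: float
    n_move_epochs: int
    n_move_accepted: int
    n_stat_epochs: int
    n_stat_accepted: int
    control_table: Optional[pd.DataFrame]
    truth: dict


def _subset_epochs(es: epochs_mod.EpochSet, bid) -> epochs_mod.EpochSet:
    sel = es.block_id == bid
    return epochs_mod.EpochSet(es.kind, es.onsets[sel], es.window,
                               es.accepted[sel], es.block_id[sel], es.bout_end[sel])


@dataclass
class GridFitResult:
    """Full grid-fitting stage output for one participant."""

    beta: np.ndarray        # per voxel, Z units
    beta_raw: np.ndarray    # de-standardized (envelope units)
    fits: list              # GridFit per voxel/block/fold
    blocks: list            # BlockSamples per block
    move: epochs_mod.EpochSet
    stat: epochs_mod.EpochSet
    masks: dict             # block_id -> overlap-exclusion mask
    filtered: dict          # block_id -> preprocessed VoxelSeries


def grid_fit(trajectory, voxels: dict, params: AnalysisParams) -> GridFitResult:
    """Preprocess, epoch, extract band power and cross-validate the grid fit."""
    filtered = {bid: spectral.preprocess_filter(s) for bid, s in voxels.items()}
    move = epochs_mod.detect_movement_onsets(trajectory)
    stat = epochs_mod.detect_stationary_onsets(trajectory)
    move = epochs_mod.reject_outlier_epochs(move, filtered, alpha=params.alpha)
    stat = epochs_mod.reject_outlier_epochs(stat, filtered, alpha=params.alpha)
    masks = {bid: epochs_mod.exclude_overlap(_subset_epochs(move, bid),
                                             _subset_epochs(stat, bid),
                                             filtered[bid].times)
             for bid in filtered}
    blocks = []
    for bid, series in filtered.items():
        power = spectral.hilbert_band_power(series, params.band)
        blocks.append(gridcode.movement_samples(
            _subset_epochs(move, bid), trajectory.block(bid), power, masks[bid]))
    beta_per_voxel, fits = gridcode.crossval_grid(blocks, n=params.symmetry)
    env_sd = blocks[0].envelope_sd if blocks else np.ones_like(beta_per_voxel)
    return GridFitResult(beta_per_voxel, beta_per_voxel * env_sd, fits, blocks,
                         move, stat, masks, filtered)


def analyze_participant(p: Participant, params: AnalysisParams) -> ParticipantSummary:
    """Run every analysis stage for one participant."""
    voi = params.voxel_of_interest
    if voi is None:
        voi = int(p.truth.get("grid_voxel_index", 0))

    gf = grid_fit(p.trajectory, p.voxels, params)
    filtered, move, stat, masks, blocks = gf.filtered, gf.move, gf.stat, gf.masks, gf.blocks
    beta = float(gf.beta[voi])
    beta_raw = float(gf.beta_raw[voi])
    beta_per_voxel = gf.beta
    fits = gf.fits
    aligned_diff, aligned_frac = gridcode.crossval_aligned_contrast(
        blocks, voxel=voi, n=params.symmetry, width_deg=params.width_deg)

    cons_vox, cons_part, cons_blk = _consistency_metrics(fits, voi, params.symmetry)

    # --- movement-onset spectral contrast (voxel of interest)
    theta_contrast, per_freq, tf = np.nan, np.empty(0), np.empty((0, 0))
    if params.do_spectra:
        mv_specs, st_specs = [], []
        for bid, series in filtered.items():
            try:
                mv = spectral.epoch_spectrograms(series, _subset_epochs(move, bid),
                                                 voxel=voi, exclude_mask=masks[bid])
                st = spectral.epoch_spectrograms(series, _subset_epochs(stat, bid),
                                                 voxel=voi, exclude_mask=masks[bid])
            except InvalidArgumentError:
                continue
            mv_specs.append(spectral.normalize_power(mv, params.norm_mode))
            st_specs.append(spectral.normalize_power(st, params.norm_mode))
        if mv_specs and st_specs:
            mv_all = spectral.Spectrogram(mv_specs[0].freqs, mv_specs[0].times,
                                          np.concatenate([s.power for s in mv_specs]),
                                          mode=params.norm_mode)
            st_all = spectral.Spectrogram(st_specs[0].freqs, st_specs[0].times,
                                          np.concatenate([s.power for s in st_specs]),
                                          mode=params.norm_mode)
            contrast = spectral.movement_vs_stationary_contrast(mv_all, st_all,
                                                                band=params.band)
            theta_contrast, per_freq, tf = contrast.theta, contrast.per_freq, contrast.tf

    # --- control table (symmetries x bands)
    table = None
    if params.do_control_table:
        samples_by_band = {}
        for name, band in spectral.CONTROL_BANDS.items():
            bb = []
            for bid, series in filtered.items():
                power = spectral.hilbert_band_power(series, band)
                bb.append(gridcode.movement_samples(
                    _subset_epochs(move, bid), p.trajectory.block(bid), power,
                    masks[bid]))
            samples_by_band[name] = bb
        table = gridcode.control_analyses(samples_by_band, voxel=voi,
                                          symmetries=params.symmetries)

    perf = behavior_mod.performance(p.behavior)
    side = 100.0
    if "side_length" in p.truth:
        side = float(p.truth["side_length"])
    return ParticipantSummary(
        pid=p.pid, group=p.group, beta=beta, beta_raw=beta_raw,
        beta_per_voxel=beta_per_voxel,
        aligned_diff=aligned_diff, aligned_fraction=aligned_frac,
        consistency_voxels=cons_vox, consistency_partitions=cons_part,
        consistency_blocks=cons_blk,
        theta_contrast=float(theta_contrast), contrast_per_freq=per_freq,
        contrast_tf=tf,
        performance=perf.score, mean_error_vm=perf.mean_error_vm,
        mean_bout_s=behavior_mod.movement_stats(p.trajectory),
        boundary_pct=behavior_mod.boundary_preference(p.trajectory, 25.0, side),
        n_move_epochs=len(move), n_move_accepted=move.n_accepted,
        n_stat_epochs=len(stat), n_stat_accepted=stat.n_accepted,
        control_table=table, truth=dict(p.truth),
    )


def _consistency_metrics(fits, voi: int, n: int):
    """Across-voxel, across-partition and across-block orientation consistency."""
    df = pd.DataFrame([(f.voxel, f.block_id, f.fold, f.orientation_deg)
                       for f in fits], columns=["voxel", "block", "fold", "phi"])
    if df.empty:
        return np.nan, np.nan, np.nan
    # across voxels: within each block and partition
    vals = []
    for (_, _), grp in df.groupby(["block", "fold"]):
        if grp["voxel"].nunique() >= 2:
            vals.append(circstat.consistency(grp["phi"].to_numpy(), n))
    cons_vox = float(np.mean(vals)) if vals else np.nan
    # across partitions: within each block and voxel (pairwise, two folds)
    vals = []
    for (_, _), grp in df.groupby(["block", "voxel"]):
        if len(grp) == 2:
            vals.append(circstat.consistency(grp["phi"].to_numpy(), n, mode="pairwise"))
    cons_part = float(np.mean(vals)) if vals else np.nan
    # across blocks: within each partition and voxel
    vals = []
    sub = df[df["voxel"] == voi]
    for _, grp in sub.groupby("fold"):
        if grp["block"].nunique() >= 2:
            vals.append(circstat.consistency(grp["phi"].to_numpy(), n))
    cons_blk = float(np.mean(vals)) if vals else np.nan
    return cons_vox, cons_part, cons_blk


# ---------------------------------------------------------------------------
# cohort-level run

def _group_stats(summaries: list, params: AnalysisParams, seed: int) -> dict:
    ctrl = [s for s in summaries if s.group == "control"]
    pat = [s for s in summaries if s.group == "patient"]
    out = {}

    def _vals(group, attr):
        v = np.array([getattr(s, attr) for s in group], dtype=float)
        return v[np.isfinite(v)]

    def _safe(fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except (GridThetaError, ValueError):
            return None

    def _tr(res):
        if res is None:
            return None
        d = {"statistic": res.statistic, "df": res.df, "p": res.p}
        if hasattr(res, "g"):
            d.update(g=res.g, g_ci=list(res.g_ci),
                     mean_a=res.mean_a, mean_b=res.mean_b)
        else:
            d.update(mean=res.mean, sd=res.sd, n=res.n)
        return d

    for attr, key in [("performance", "performance"), ("beta", "beta"),
                      ("theta_contrast", "theta_contrast"),
                      ("aligned_diff", "aligned_diff"),
                      ("mean_bout_s", "mean_bout_s"),
                      ("boundary_pct", "boundary_pct")]:
        vc, vp = _vals(ctrl, attr), _vals(pat, attr)
        entry = {
            "control_mean": float(vc.mean()) if vc.size else None,
            "patient_mean": float(vp.mean()) if vp.size else None,
        }
        if vc.size >= 2 and vp.size >= 2:
            entry["group_comparison"] = _tr(_safe(cohortstats.two_sample_t, vc, vp))
        else:
            entry["group_comparison"] = "not-applicable"
        for name, v in (("control", vc), ("patient", vp)):
            if v.size >= 2:
                mu0 = 0.5 if attr == "aligned_fraction" else 0.0
                entry[f"{name}_one_sample"] = _tr(_safe(cohortstats.one_sample_t, v, mu0))
        out[key] = entry

    # aligned fraction against the geometric expectation 0.5
    vc = _vals(ctrl, "aligned_fraction")
    out["aligned_fraction"] = {
        "control_mean": float(vc.mean()) if vc.size else None,
        "control_vs_half": _tr(_safe(cohortstats.one_sample_t, vc, 0.5)) if vc.size >= 2 else None,
    }

    # orientation consistency vs chance
    chance = circstat.chance_consistency(params.symmetry, "analytic")
    for level in ("voxels", "partitions", "blocks"):
        vc = _vals(ctrl, f"consistency_{level}")
        out[f"consistency_{level}"] = {
            "control_mean": float(vc.mean()) if vc.size else None,
            "chance": chance,
            "test": _tr(_safe(circstat.consistency_tests, vc, params.symmetry))
            if vc.size >= 2 else None,
        }

    # grid (in)stability vs performance, controls
    inst = _vals(ctrl, "consistency_blocks")
    perf = np.array([s.performance for s in ctrl if np.isfinite(s.consistency_blocks)])
    if inst.size >= 3:
        r, pv = _safe(cohortstats.instability_performance_correlation, inst, perf) or (None, None)
        out["instability_performance"] = {"r": r, "p": pv, "n": int(inst.size)}

    # whole-map max-statistic permutation on control betas
    betas = np.array([s.beta_per_voxel for s in ctrl])
    if (betas.size and betas.shape[0] >= 2 and np.isfinite(betas).all()
            and np.all(betas.std(axis=0) > 0)):
        t_vox, p_fwe = cohortstats.max_stat_permutation(betas, n_perm=1000, seed=seed)
        out["voxel_map"] = {"t": t_vox.tolist(), "p_fwe": p_fwe.tolist(),
                            "n_significant": int(np.sum(p_fwe < 0.05))}

    # control table: per-cell one-sample t across controls, Bonferroni over cells
    tables = [s.control_table for s in ctrl if s.control_table is not None]
    if tables:
        merged = pd.concat(tables)
        cells = []
        for (n_sym, band), grp in merged.groupby(["symmetry", "band"]):
            v = grp["beta"].to_numpy()
            v = v[np.isfinite(v)]
            res = _safe(cohortstats.one_sample_t, v) if v.size >= 2 else None
            cells.append({"symmetry": int(n_sym), "band": band,
                          "mean_beta": float(v.mean()) if v.size else None,
                          "t": res.statistic if res else None,
                          "p": res.p if res else None})
        n_cells = len(cells)
        for c in cells:
            c["significant_bonferroni"] = (c["p"] is not None
                                           and c["p"] < 0.05 / n_cells)
        out["symmetry_band_table"] = cells
    return out


def _participant_frame(summaries: list) -> pd.DataFrame:
    cols = ["pid", "group", "beta", "beta_raw", "aligned_diff", "aligned_fraction",
            "consistency_voxels", "consistency_partitions", "consistency_blocks",
            "theta_contrast", "performance", "mean_error_vm", "mean_bout_s",
            "boundary_pct", "n_move_epochs", "n_move_accepted",
            "n_stat_epochs", "n_stat_accepted"]
    return pd.DataFrame([{c: getattr(s, c) for c in cols} for s in summaries])


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run the full pipeline and write results, manifest and tables.

    Returns the results dict.  Stage failures abort with the failing stage
    named; partial outputs already written are retained.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spec = config.to_cohort_spec()
    params = AnalysisParams.from_config(config.analysis)

    summaries = []
    stage = "simulate/analyze"
    try:
        for p in iter_participants(spec):
            summaries.append(analyze_participant(p, params))
            logger.info("analyzed %s (%s)", p.pid, p.group)
        stage = "groupstats"
        stats = _group_stats(summaries, params, seed=config.seed)
    except Exception as e:
        raise GridThetaError(f"pipeline stage {stage!r} failed: {e}") from e

    df = _participant_frame(summaries)
    df.to_csv(outdir / "participants.csv", index=False)

    ctrl_tf = [s.contrast_tf for s in summaries
               if s.group == "control" and s.contrast_tf.size]
    results = {
        "group_stats": stats,
        "n_participants": len(summaries),
        "epoch_counts": {
            "movement_mean": float(df["n_move_epochs"].mean()),
            "stationary_mean": float(df["n_stat_epochs"].mean()),
        },
    }
    if ctrl_tf:
        import warnings as _warnings
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN edges
            results["control_mean_tf_contrast"] = np.nanmean(
                np.array(ctrl_tf), axis=0).tolist()
            results["contrast_freqs"] = spectral.DEFAULT_FREQS.tolist()
            results["control_mean_contrast_per_freq"] = np.nanmean(
                np.array([s.contrast_per_freq for s in summaries
                          if s.group == "control" and s.contrast_per_freq.size]),
                axis=0).tolist()
    with open(outdir / "results.json", "w") as f:
        json.dump(results, f, indent=1)
    manifest = {"config_hash": config.config_hash(), "seed": config.seed,
                "version": __version__,
                "config": config.model_dump(mode="json")}
    with open(outdir / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=1, sort_keys=True)
    return results


# ---------------------------------------------------------------------------
# report

def report(outdir) -> list:
    """Figures and summary tables from a completed result bundle.

    Produces six figures plus ``report.json`` whose values mirror the stage
    outputs (no recomputation happens here).
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    res_path = outdir / "results.json"
    part_path = outdir / "participants.csv"
    for p, name in ((res_path, "groupstats"), (part_path, "participants")):
        if not p.exists():
            raise GridThetaError(f"missing stage output: {name} ({p})")
    with open(res_path) as f:
        results = json.load(f)
    df = pd.read_csv(part_path)
    figures = []

    def _box(col, title, fname, ylabel):
        fig, ax = plt.subplots(figsize=(4, 4))
        groups = [g for g in ("control", "patient") if (df["group"] == g).any()]
        ax.boxplot([df.loc[df["group"] == g, col].dropna() for g in groups],
                   tick_labels=groups)
        ax.set_title(title)
        ax.set_ylabel(ylabel)
        fig.tight_layout()
        path = outdir / fname
        fig.savefig(path, dpi=120)
        plt.close(fig)
        figures.append(path)

    _box("performance", "Spatial memory performance", "fig_performance.png", "1 / vm")
    _box("beta", "Hexadirectional theta modulation", "fig_beta.png", "beta (Z)")
    _box("aligned_diff", "Aligned - misaligned theta power", "fig_aligned.png", "Z")
    _box("theta_contrast", "Movement-onset theta contrast", "fig_theta_contrast.png",
         "norm. power")

    if "control_mean_tf_contrast" in results:
        fig, ax = plt.subplots(figsize=(5, 4))
        tf = np.array(results["control_mean_tf_contrast"])
        im = ax.imshow(tf, aspect="auto", origin="lower",
                       extent=[-3, 3, 0, tf.shape[0]], cmap="RdBu_r")
        ax.set_xlabel("time from movement onset (s)")
        ax.set_ylabel("frequency bin (2-70 Hz, log spaced)")
        fig.colorbar(im, ax=ax, label="norm. power vs stationary")
        fig.tight_layout()
        path = outdir / "fig_tf_contrast.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        figures.append(path)
    else:
        fig, ax = plt.subplots(figsize=(4, 3))
        ax.text(0.5, 0.5, "no spectrogram stage output", ha="center")
        path = outdir / "fig_tf_contrast.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        figures.append(path)

    fig, ax = plt.subplots(figsize=(4, 4))
    sel = df[df["group"] == "control"].dropna(subset=["consistency_blocks"])
    ax.scatter(sel["consistency_blocks"], sel["performance"])
    ax.set_xlabel("across-block orientation deviation (deg)")
    ax.set_ylabel("performance (1 / vm)")
    ax.set_title("Grid stability vs performance")
    fig.tight_layout()
    path = outdir / "fig_stability_performance.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    figures.append(path)

    with open(outdir / "report.json", "w") as f:
        json.dump(results["group_stats"], f, indent=1)
    return figures
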