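"""Config-driven orchestration: simulate -> preprocess -> maps ->
univariate + MVPA, with per-stage seed substreams and a consolidated,
machine-comparable report.

A single run seed fans out to per-stage substreams keyed by stage name, so
disabling one stage never perturbs another stage's random draws. The JSON
report is deterministic for a fixed config + seed (wall-clock timing goes
to a separate log file).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .mvpa import (
    discrimination_map,
    linear_kernel,
    loocv_pairs,
    permutation_test,
    threshold_map,
    train_svm,
)
from .params import FcsSpec, SmoothSpec, compute_subject_maps
from .preproc import BandSpec, preprocess_subject
from .stats import voxelwise_ttest
from .synthgen import EffectSpec, SimulationConfig, generate_cohort
from .types import features_from_maps

ALL_KINDS = ("alff", "falff", "reho", "fcs")
ALL_STAGES = ("simulate", "preprocess", "maps", "univariate", "mvpa")


def stage_seed(run_seed: int, stage: str) -> int:
    """Deterministic per-stage substream seed (stage-name keyed, < 2^31)."""
    return (int(run_seed) * 2654435761 + zlib.crc32(stage.encode())) % (2**31 - 1)


def default_effects(grid_shape: tuple[int, int, int]) -> list[EffectSpec]:
    """Demo effect set for synthetic runs: an amplitude-dominant lesion plus
    milder coherence and hub effects, all in the gray-matter rind."""
    cx = tuple(g // 2 for g in grid_shape)
    edge = [int(round(0.8 * g)) for g in grid_shape]
    return [
        EffectSpec(kind="amplitude", center_voxel=(cx[0], cx[1], edge[2]),
                   radius_voxels=4.0, effect_size=2.0),
        EffectSpec(kind="coherence", center_voxel=(cx[0], edge[1], cx[2]),
                   radius_voxels=4.0, effect_size=0.3),
        EffectSpec(kind="hub", center_voxel=(grid_shape[0] - edge[0], cx[1], cx[2]),
                   radius_voxels=3.0, effect_size=0.25),
    ]


def cohort_features(
    sim_config: SimulationConfig,
    effects: list[EffectSpec],
    kinds: tuple[str, ...] = ("alff",),
    band: BandSpec | None = None,
    smooth: SmoothSpec | None = None,
    fcs_spec: FcsSpec | None = None,
):
    """Generate a cohort and run it through denoising and the map chain for
    the requested kinds; returns (features-by-kind dict, masks, cohort).

    A convenience for simulation studies that need feature matrices without
    the full report machinery of :func:`run_all`.
    """
    cohort, masks = generate_cohort(sim_config, effects)
    band = band or BandSpec(tr_s=sim_config.tr_s)
    smooth = smooth or SmoothSpec(voxel_size_mm=sim_config.voxel_size_mm)
    need_filtered = any(k in ("reho", "fcs") for k in kinds)
    subject_maps = []
    for sub in cohort:
        pre = preprocess_subject(sub.bold, sub.motion, masks, band=band,
                                 bandpass_filter=need_filtered)
        subject_maps.append(compute_subject_maps(
            pre.regressed, pre.filtered, masks.brain, masks.gm,
            band=band, smooth=smooth, fcs_spec=fcs_spec, kinds=kinds,
        ))
    labels = np.array([1 if s.group_label == "patient" else -1 for s in cohort])
    ids = [s.subject_id for s in cohort]
    features = {}
    for kind in kinds:
        mask = masks.gm if kind == "fcs" else masks.brain
        features[kind] = features_from_maps(
            [m[kind] for m in subject_maps], labels, ids, mask=mask)
    return features, masks, cohort


@dataclass
class RunConfig:
    """Everything a run needs; defaults are the pipeline's canonical
    constants (0.01-0.08 Hz band, 0.2 mm FD threshold, 8 mm FWHM, r = 0.2,
    C = 1, 1000 permutations, 30% map threshold, q = 0.05)."""

    seed: int = 0
    out_dir: str | None = None
    stages: tuple[str, ...] = ALL_STAGES
    kinds: tuple[str, ...] = ALL_KINDS
    # simulation
    grid_shape: tuple[int, int, int] = (24, 24, 24)
    voxel_size_mm: float = 3.0
    tr_s: float = 2.0
    n_volumes: int = 200
    n_per_group: int = 20
    noise_model: str = "ar1"
    ar1_rho: float = 0.3
    global_noise_sd: float = 1.0
    motion_spike_rate: float = 1.0
    effects: list[dict] | None = None  # None -> default_effects
    # preprocessing
    band_low_hz: float = 0.01
    band_high_hz: float = 0.08
    fd_threshold_mm: float = 0.2
    n_discard: int = 10
    # maps
    fwhm_mm: float = 8.0
    r_threshold: float = 0.2
    # univariate
    q: float = 0.05
    # mvpa
    C: float = 1.0
    n_perm: int = 1000
    perm_stat: str = "accuracy"
    threshold_fraction: float = 0.30
    run_permutation: bool = True


def validate_config(raw: dict | RunConfig) -> RunConfig:
    """Normalize and validate a config mapping; raises ValueError with all
    problems aggregated. Unknown keys are rejected."""
    if isinstance(raw, RunConfig):
        cfg = raw
    else:
        known = {f.name for f in dataclasses.fields(RunConfig)}
        unknown = sorted(set(raw) - known)
        errors = [f"unknown config key: {k!r}" for k in unknown]
        if errors:
            raise ValueError("; ".join(errors))
        cfg = RunConfig(**raw)
    errors = []
    cfg.stages = tuple(cfg.stages)
    cfg.kinds = tuple(cfg.kinds)
    for s in cfg.stages:
        if s not in ALL_STAGES:
            errors.append(f"unknown stage {s!r} (stages: {ALL_STAGES})")
    for k in cfg.kinds:
        if k not in ALL_KINDS:
            errors.append(f"unknown map kind {k!r} (kinds: {ALL_KINDS})")
    nyquist = 1.0 / (2.0 * cfg.tr_s)
    if not (0.0 < cfg.band_low_hz < cfg.band_high_hz < nyquist):
        errors.append(
            f"band_low_hz/band_high_hz: need 0 < {cfg.band_low_hz} < "
            f"{cfg.band_high_hz} < Nyquist {nyquist:g}"
        )
    if not (0.0 < cfg.threshold_fraction <= 1.0):
        errors.append("threshold_fraction must lie in (0, 1]")
    if not (0.0 < cfg.q < 1.0):
        errors.append("q must lie in (0, 1)")
    if not (0.0 < cfg.r_threshold < 1.0):
        errors.append("r_threshold must lie in (0, 1)")
    if cfg.fwhm_mm <= 0:
        errors.append("fwhm_mm must be positive")
    if cfg.C <= 0:
        errors.append("C must be positive")
    if cfg.n_perm < 1:
        errors.append("n_perm must be >= 1")
    if cfg.perm_stat not in ("accuracy", "joint"):
        errors.append("perm_stat must be 'accuracy' or 'joint'")
    if cfg.fd_threshold_mm <= 0:
        errors.append("fd_threshold_mm must be positive")
    if cfg.n_volumes - cfg.n_discard < 4:
        errors.append("n_volumes - n_discard leaves too few volumes")
    if errors:
        raise ValueError("; ".join(errors))
    return cfg


def config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(dataclasses.asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _digest(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


def run_all(config: RunConfig | dict) -> dict:
    """Execute the enabled stages in order and return the consolidated
    report (also written to ``out_dir`` when set)."""
    cfg = validate_config(config)
    report: dict = {
        "config": dataclasses.asdict(cfg),
        "config_hash": config_hash(cfg),
        "seed": cfg.seed,
        "version": __version__,
        "stage_digests": {},
    }
    wall: dict[str, float] = {}
    t0 = time.time()

    if "simulate" not in cfg.stages:
        raise ValueError("run_all currently requires the simulate stage "
                         "(external-input runs go through the CLI stage commands)")
    sim_config = SimulationConfig(
        grid_shape=cfg.grid_shape,
        voxel_size_mm=cfg.voxel_size_mm,
        tr_s=cfg.tr_s,
        n_volumes=cfg.n_volumes,
        n_per_group=cfg.n_per_group,
        noise_model=cfg.noise_model,
        ar1_rho=cfg.ar1_rho,
        global_noise_sd=cfg.global_noise_sd,
        motion_spike_rate=cfg.motion_spike_rate,
        seed=stage_seed(cfg.seed, "simulate"),
    )
    if cfg.effects is None:
        effects = default_effects(cfg.grid_shape)
    else:
        effects = [EffectSpec(**{**e, "center_voxel": tuple(e["center_voxel"])})
                   for e in cfg.effects]
    try:
        cohort, masks = generate_cohort(sim_config, effects)
    except Exception as exc:
        raise RuntimeError(f"stage 'simulate' failed: {exc}") from exc
    report["n_subjects"] = len(cohort)
    report["effects"] = [dataclasses.asdict(e) for e in effects]
    wall["simulate"] = time.time() - t0

    band = BandSpec(low_hz=cfg.band_low_hz, high_hz=cfg.band_high_hz, tr_s=cfg.tr_s)
    smooth = SmoothSpec(fwhm_mm=cfg.fwhm_mm, voxel_size_mm=cfg.voxel_size_mm)
    fcs_spec = FcsSpec(r_threshold=cfg.r_threshold)

    subject_maps: dict[str, dict] = {}
    if "preprocess" in cfg.stages and "maps" in cfg.stages:
        t1 = time.time()
        for sub in cohort:
            try:
                pre = preprocess_subject(
                    sub.bold, sub.motion, masks, band=band,
                    n_discard=cfg.n_discard, fd_threshold_mm=cfg.fd_threshold_mm,
                )
            except Exception as exc:
                raise RuntimeError(
                    f"stage 'preprocess' failed on {sub.subject_id}: {exc}"
                ) from exc
            try:
                subject_maps[sub.subject_id] = compute_subject_maps(
                    pre.regressed, pre.filtered, masks.brain, masks.gm,
                    band=band, smooth=smooth, fcs_spec=fcs_spec, kinds=cfg.kinds,
                )
            except Exception as exc:
                raise RuntimeError(
                    f"stage 'maps' failed on {sub.subject_id}: {exc}"
                ) from exc
        wall["preprocess+maps"] = time.time() - t1

    labels = np.array([1 if s.group_label == "patient" else -1 for s in cohort])
    subject_ids = [s.subject_id for s in cohort]

    if subject_maps:
        features_by_kind = {}
        for kind in cfg.kinds:
            maps = [subject_maps[sid][kind] for sid in subject_ids]
            mask = masks.gm if kind == "fcs" else masks.brain
            feats = features_from_maps(maps, labels, subject_ids, mask=mask)
            features_by_kind[kind] = feats
            report["stage_digests"][f"features_{kind}"] = _digest(feats.matrix)

        if "univariate" in cfg.stages:
            t1 = time.time()
            report["univariate"] = {}
            for kind in cfg.kinds:
                g1 = [subject_maps[s.subject_id][kind] for s in cohort
                      if s.group_label == "patient"]
                g2 = [subject_maps[s.subject_id][kind] for s in cohort
                      if s.group_label == "control"]
                try:
                    stat = voxelwise_ttest(g1, g2, q=cfg.q)
                except Exception as exc:
                    raise RuntimeError(f"stage 'univariate' failed on {kind}: {exc}") from exc
                report["univariate"][kind] = {
                    "df": stat.df,
                    "n_sig_voxels": int(stat.sig_mask.sum()),
                    "p_cutoff": stat.p_cutoff,
                    "max_abs_t": float(np.abs(stat.t_values).max()),
                }
            wall["univariate"] = time.time() - t1

        if "mvpa" in cfg.stages:
            t1 = time.time()
            report["mvpa"] = {}
            for kind in cfg.kinds:
                feats = features_by_kind[kind]
                try:
                    cv = loocv_pairs(feats, C=cfg.C)
                    if cfg.run_permutation:
                        perm_seed = stage_seed(cfg.seed, f"mvpa_perm_{kind}")
                        p, _ = permutation_test(
                            feats, C=cfg.C, n_perm=cfg.n_perm,
                            seed=perm_seed, statistic=cfg.perm_stat,
                        )
                        cv.permutation_p = p
                        cv.n_permutations = cfg.n_perm
                        cv.seed = perm_seed
                    model = train_svm(linear_kernel(feats), feats.labels, C=cfg.C)
                    dmap = discrimination_map(model, feats)
                    retained = threshold_map(dmap, cfg.threshold_fraction)
                except Exception as exc:
                    raise RuntimeError(f"stage 'mvpa' failed on {kind}: {exc}") from exc
                entry = cv.to_dict()
                entry["n_retained_voxels"] = int(np.count_nonzero(retained))
                report["mvpa"][kind] = entry
                report["stage_digests"][f"weights_{kind}"] = _digest(dmap.weights)
            wall["mvpa"] = time.time() - t1

    if cfg.out_dir is not None:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        (out / "run_log.json").write_text(json.dumps(
            {"wall_s": wall, "config_hash": report["config_hash"]}, indent=2))
        if "mvpa" in report:
            rows = [{"kind": k, **v} for k, v in report["mvpa"].items()]
            pd.DataFrame(rows).drop(columns=["confusion"]).to_csv(
                out / "report.tsv", sep="\t", index=False)
    return report
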