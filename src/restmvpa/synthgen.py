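"""Synthetic two-group BOLD cohort generator.

Every downstream stage of the pipeline (denoising, parameter maps,
univariate tests, MVPA) is exercised on cohorts produced here, with known
regional group effects so recovery can be verified. Three effect families
mirror what the four parameter maps measure:

``amplitude``
    Each voxel inside a sphere receives an independent band-limited
    (0.01-0.08 Hz) signal; in the target group its standard deviation is
    multiplied by ``effect_size``. ALFF/fALFF-sensitive.
``coherence``
    One shared band-limited signal is added to every voxel of the sphere in
    the target group, scaled so it accounts for an ``effect_size`` fraction
    of voxel variance (so the expected pairwise correlation inside the
    sphere equals that share). ReHo-sensitive.
``hub``
    One shared signal couples the sphere to designated long-range partner
    spheres in the target group, raising its degree centrality.
    FCS-sensitive.

Baseline noise is white or AR(1); synthetic CSF and WM nuisance signals are
injected into their compartments and, attenuated, into gray matter, so the
nuisance-regression stage has something real to remove. No hemodynamic
response or physiological (cardiac/respiratory) noise is modelled.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import signal as sp_signal
from scipy import stats as sp_stats

from .types import BoldRun, MaskSet, MotionTrace

LOW_HZ = 0.01
HIGH_HZ = 0.08
FD_SPIKE_THRESHOLD_MM = 0.2

#: Moments used for covariate draws (means/SDs of the emulated study groups).
COVARIATE_MOMENTS = {
    "patient": {
        "age": (30.41, 8.07, 18.0, 60.0),
        "duration_years": (8.15, 5.69, 0.5, 40.0),
        "ybocs_obsession": (10.67, 3.60, 0.0, 20.0),
        "ybocs_compulsion": (10.06, 4.44, 0.0, 20.0),
        "ybocs_total": (20.72, 5.30, 0.0, 40.0),
        "hamd": (8.19, 5.87, 0.0, 52.0),
        "hama": (9.24, 5.15, 0.0, 56.0),
    },
    "control": {
        "age": (28.39, 11.22, 18.0, 60.0),
    },
}
MALE_FRACTION = 34 / 54


@dataclass
class SimulationConfig:
    """Cohort-level generation parameters.

    Defaults are the desk-scale study conditions: 2 s TR, 200 volumes per
    run (10 of which the denoising stage discards), two groups of 20 on a
    24^3 grid of 3 mm voxels. ``n_per_group=54`` restores the emulated
    study's sample size.
    """

    grid_shape: tuple[int, int, int] = (24, 24, 24)
    voxel_size_mm: float = 3.0
    tr_s: float = 2.0
    n_volumes: int = 200
    n_per_group: int = 20
    noise_model: str = "ar1"
    ar1_rho: float = 0.3
    global_noise_sd: float = 1.0
    motion_spike_rate: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(g) for g in self.grid_shape)
        if len(self.grid_shape) != 3 or any(g <= 0 for g in self.grid_shape):
            raise ValueError(f"grid_shape must be 3 positive ints, got {self.grid_shape}")
        if self.n_volumes <= 20:
            raise ValueError(
                "n_volumes must exceed 20 (10 volumes are discarded and a "
                "usable low-frequency spectrum must remain)"
            )
        if self.noise_model not in ("white", "ar1"):
            raise ValueError(f"noise_model must be 'white' or 'ar1', got {self.noise_model!r}")
        if not (0.0 <= self.ar1_rho < 1.0):
            raise ValueError("ar1_rho must lie in [0, 1)")
        if self.global_noise_sd <= 0:
            raise ValueError("global_noise_sd must be positive")
        if self.motion_spike_rate < 0:
            raise ValueError("motion_spike_rate must be non-negative")
        if self.tr_s <= 0 or self.voxel_size_mm <= 0:
            raise ValueError("tr_s and voxel_size_mm must be positive")


@dataclass
class EffectSpec:
    """A localized group effect injected into the BOLD series.

    ``effect_size`` semantics depend on ``kind``: for ``amplitude`` it is the
    patient/control ratio of in-band signal SD inside the sphere (1 = null);
    for ``coherence`` and ``hub`` it is the shared-signal fraction of voxel
    variance (0 = null). ``base_amplitude`` is the in-band signal SD (in
    noise-SD units) every subject receives inside an amplitude sphere.
    """

    kind: str
    center_voxel: tuple[int, int, int]
    radius_voxels: float
    effect_size: float
    target_group: str = "patient"
    base_amplitude: float = 1.0
    partner_centers: list[tuple[int, int, int]] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("amplitude", "coherence", "hub"):
            raise ValueError(f"unknown effect kind {self.kind!r}")
        if self.target_group not in ("patient", "control"):
            raise ValueError(f"unknown target group {self.target_group!r}")
        if self.radius_voxels <= 0:
            raise ValueError("radius_voxels must be positive")
        if self.kind == "amplitude" and self.effect_size < 0:
            raise ValueError("amplitude effect_size must be non-negative")
        if self.kind in ("coherence", "hub") and not (0.0 <= self.effect_size < 1.0):
            raise ValueError(f"{self.kind} effect_size is a variance share in [0, 1)")
        self.center_voxel = tuple(int(c) for c in self.center_voxel)


@dataclass
class SubjectData:
    subject_id: str
    group_label: str  # "patient" | "control"
    bold: BoldRun
    motion: MotionTrace
    covariates: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group_label not in ("patient", "control"):
            raise ValueError(f"unknown group label {self.group_label!r}")
        if self.bold.n_volumes != self.motion.n_volumes:
            raise ValueError(
                f"bold ({self.bold.n_volumes}) and motion ({self.motion.n_volumes}) "
                "volume counts differ"
            )


# ---------------------------------------------------------------------------
# geometry

def make_masks(grid_shape: tuple[int, int, int]) -> MaskSet:
    """Deterministic ellipsoidal head phantom: CSF core, WM shell, GM rind.

    The brain is an ellipsoid with semi-axes 0.45x each grid dimension;
    compartments are nested by normalized ellipsoidal radius rho:
    CSF rho <= 0.20, WM 0.20 < rho <= 0.55, GM 0.55 < rho <= 1.
    """
    grid_shape = tuple(grid_shape)
    coords = np.indices(grid_shape, dtype=float)
    center = (np.asarray(grid_shape, dtype=float) - 1.0) / 2.0
    semi = 0.45 * np.asarray(grid_shape, dtype=float)
    rho2 = sum(((coords[a] - center[a]) / semi[a]) ** 2 for a in range(3))
    rho = np.sqrt(rho2)
    brain = rho <= 1.0
    csf = rho <= 0.20
    wm = (rho > 0.20) & (rho <= 0.55)
    gm = (rho > 0.55) & brain
    return MaskSet(brain=brain, gm=gm, wm=wm, csf=csf)


def sphere_mask(
    grid_shape: tuple[int, int, int],
    center: tuple[int, int, int],
    radius_voxels: float,
) -> np.ndarray:
    coords = np.indices(grid_shape, dtype=float)
    d2 = sum((coords[a] - center[a]) ** 2 for a in range(3))
    return d2 <= radius_voxels**2


def default_partner_centers(
    grid_shape: tuple[int, int, int],
    center: tuple[int, int, int],
    n_partners: int = 2,
) -> list[tuple[int, int, int]]:
    """Long-range partners: the point-reflection of the center through the
    grid midpoint, then axis-mirrored variants."""
    mid = tuple((g - 1) / 2.0 for g in grid_shape)
    mirror = tuple(int(round(2 * m - c)) for m, c in zip(mid, center))
    partners = [mirror]
    for axis in range(3):
        if len(partners) >= n_partners:
            break
        p = list(center)
        p[axis] = int(round(2 * mid[axis] - p[axis]))
        p = tuple(p)
        if p != tuple(center) and p not in partners:
            partners.append(p)
    return partners[:n_partners]


# ---------------------------------------------------------------------------
# signal building blocks

def band_limited_series(
    rng: np.random.Generator,
    n_volumes: int,
    tr_s: float,
    n_series: int = 1,
    low_hz: float = LOW_HZ,
    high_hz: float = HIGH_HZ,
) -> np.ndarray:
    """Unit-SD signals with support exactly in [low_hz, high_hz].

    White noise is ideal-filtered in the frequency domain (bin k maps to
    k/(N*TR) Hz; DC removed) and each series is rescaled to unit sample SD,
    which makes injected amplitude ratios exact by construction.
    """
    x = rng.standard_normal((n_series, n_volumes))
    freqs = np.fft.rfftfreq(n_volumes, d=tr_s)
    keep = (freqs >= low_hz - 1e-12) & (freqs <= high_hz + 1e-12)
    if not np.any(keep):
        raise ValueError(
            f"no frequency bins in [{low_hz}, {high_hz}] Hz at resolution "
            f"{1.0 / (n_volumes * tr_s):.5f} Hz"
        )
    spec = np.fft.rfft(x, axis=1)
    spec[:, ~keep] = 0.0
    y = np.fft.irfft(spec, n=n_volumes, axis=1)
    sd = y.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return y / sd


def _baseline_noise(
    rng: np.random.Generator, shape: tuple[int, ...], config: SimulationConfig
) -> np.ndarray:
    noise = rng.standard_normal(shape) * config.global_noise_sd
    if config.noise_model == "ar1" and config.ar1_rho > 0:
        rho = config.ar1_rho
        # innovations scaled so the stationary marginal SD stays global_noise_sd
        flat = sp_signal.lfilter(
            [np.sqrt(1 - rho**2)], [1.0, -rho], noise.reshape(-1, shape[-1]), axis=-1
        )
        noise = flat.reshape(shape)
    return noise


def generate_subject_bold(
    config: SimulationConfig,
    effects: list[EffectSpec],
    group: str,
    rng: np.random.Generator,
    masks: MaskSet | None = None,
) -> BoldRun:
    """Build one subject's 4D series: baseline noise + nuisance compartment
    signals + the band-limited regional effect signals for this group."""
    if masks is None:
        masks = make_masks(config.grid_shape)
    nt = config.n_volumes
    data = _baseline_noise(rng, config.grid_shape + (nt,), config)

    # shared nuisance sources: into their compartments, attenuated into GM
    csf_sig, wm_sig = band_limited_series(rng, nt, config.tr_s, n_series=2,
                                          low_hz=0.005, high_hz=0.05)
    sd = config.global_noise_sd
    data[masks.csf] += 1.0 * sd * csf_sig
    data[masks.wm] += 1.0 * sd * wm_sig
    data[masks.gm] += 0.3 * sd * (csf_sig + wm_sig)

    for i, eff in enumerate(effects):
        sph = sphere_mask(config.grid_shape, eff.center_voxel, eff.radius_voxels)
        sph &= masks.brain
        nvox = int(sph.sum())
        if nvox == 0:
            raise ValueError(
                f"effect {i} ({eff.kind} at {eff.center_voxel}, "
                f"r={eff.radius_voxels}) does not intersect the brain mask"
            )
        if eff.kind == "amplitude":
            scale = eff.base_amplitude * sd
            if group == eff.target_group:
                scale *= eff.effect_size
            sig = band_limited_series(rng, nt, config.tr_s, n_series=nvox)
            data[sph] += scale * sig
        elif eff.kind in ("coherence", "hub"):
            # consume the shared-draw stream regardless of group so that the
            # two groups' other draws stay aligned under a common seed policy
            regions = [sph]
            if eff.kind == "hub":
                centers = eff.partner_centers or default_partner_centers(
                    config.grid_shape, eff.center_voxel
                )
                for c in centers:
                    p = sphere_mask(config.grid_shape, c, eff.radius_voxels) & masks.brain
                    if not p.any():
                        raise ValueError(
                            f"effect {i} (hub partner at {tuple(c)}) does not "
                            "intersect the brain mask"
                        )
                    regions.append(p)
            shared = band_limited_series(rng, nt, config.tr_s, n_series=1)[0]
            if group == eff.target_group and eff.effect_size > 0:
                share = eff.effect_size
                coef = sd * np.sqrt(share / (1.0 - share))
                for region in regions:
                    data[region] += coef * shared
    if not np.all(np.isfinite(data)):
        raise FloatingPointError("generated series contains non-finite values")
    return BoldRun(
        data=data,
        voxel_size_mm=config.voxel_size_mm,
        tr_s=config.tr_s,
        brain_mask=masks.brain,
        state="raw",
    )


def generate_motion_trace(
    config: SimulationConfig, rng: np.random.Generator
) -> MotionTrace:
    """Smooth low-amplitude drift plus Poisson-placed repositioning spikes.

    The drift is globally rescaled so no drift-only transition reaches the
    0.2 mm framewise-displacement flagging threshold; each spike is a
    sustained step on one random translation axis sized to exceed it.
    """
    nt = config.n_volumes
    if nt <= 0:
        raise ValueError("motion trace needs at least one volume")
    steps = np.zeros((nt, 6))
    steps[1:, :3] = rng.normal(0.0, 0.01, size=(nt - 1, 3))      # mm
    steps[1:, 3:] = rng.normal(0.0, 1e-4, size=(nt - 1, 3))      # rad
    fd_steps = np.abs(steps[1:, :3]).sum(axis=1) + 50.0 * np.abs(steps[1:, 3:]).sum(axis=1)
    max_fd = fd_steps.max() if nt > 1 else 0.0
    if max_fd >= 0.18:  # keep drift safely sub-threshold
        steps[1:] *= 0.18 / max_fd
    params = np.cumsum(steps, axis=0)

    n_spikes = rng.poisson(config.motion_spike_rate)
    if n_spikes > 0 and nt > 1:
        positions = rng.integers(1, nt, size=n_spikes)
        for pos in positions:
            axis = rng.integers(0, 3)
            delta = rng.uniform(0.25, 0.6) * rng.choice([-1.0, 1.0])
            params[pos:, axis] += delta  # sustained repositioning
    return MotionTrace(params=params)


def draw_covariates(
    group: str, subject_index: int, rng: np.random.Generator
) -> dict:
    """Truncated-normal covariate draws matched to the emulated group moments;
    sex follows the study's 34/20 male/female split deterministically."""
    cov: dict = {}
    # deterministic assignment that hits 34/54 males exactly at n = 54
    cov["sex"] = "M" if (subject_index % 54) < round(MALE_FRACTION * 54) else "F"
    for name, (mean, sd, lo, hi) in COVARIATE_MOMENTS[group].items():
        a, b = (lo - mean) / sd, (hi - mean) / sd
        cov[name] = float(sp_stats.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))
    return cov


def generate_cohort(
    config: SimulationConfig, effects: list[EffectSpec] | None = None
) -> tuple[list[SubjectData], MaskSet]:
    """Generate the full two-group cohort deterministically from config.seed.

    Each subject draws from an independent substream spawned from the
    config seed, so cohorts are reproducible and per-subject parallelism
    would not change results.
    """
    effects = effects or []
    masks = make_masks(config.grid_shape)
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(2 * config.n_per_group)
    cohort: list[SubjectData] = []
    idx = 0
    for group in ("patient", "control"):
        for i in range(config.n_per_group):
            rng = np.random.default_rng(children[idx])
            bold = generate_subject_bold(config, effects, group, rng, masks)
            motion = generate_motion_trace(config, rng)
            covariates = draw_covariates(group, i, rng)
            prefix = "sub-P" if group == "patient" else "sub-C"
            cohort.append(
                SubjectData(
                    subject_id=f"{prefix}{i + 1:03d}",
                    group_label=group,
                    bold=bold,
                    motion=motion,
                    covariates=covariates,
                )
            )
            idx += 1
    return cohort, masks


# ---------------------------------------------------------------------------
# on-disk cohort (BIDS-flavoured layout)

def _affine(voxel_size_mm: float) -> np.ndarray:
    aff = np.diag([voxel_size_mm] * 3 + [1.0])
    return aff


def write_cohort(
    cohort: list[SubjectData],
    masks: MaskSet,
    config: SimulationConfig,
    out_dir: str | Path,
    effects: list[EffectSpec] | None = None,
    overwrite: bool = False,
) -> dict:
    """Write NIfTI-1 BOLD runs, motion TSVs, masks, participants.tsv and a
    JSON manifest recording config + seed + effects. Refuses to clobber an
    existing manifest unless ``overwrite`` is set."""
    out = Path(out_dir)
    manifest_path = out / "manifest.json"
    if manifest_path.exists() and not overwrite:
        raise FileExistsError(
            f"{manifest_path} already exists; pass overwrite=True to replace it"
        )
    out.mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(exist_ok=True)
    aff = _affine(config.voxel_size_mm)
    for name in ("brain", "gm", "wm", "csf"):
        img = nib.Nifti1Image(getattr(masks, name).astype(np.uint8), aff)
        nib.save(img, out / "masks" / f"{name}.nii.gz")

    rows = []
    for sub in cohort:
        img = nib.Nifti1Image(sub.bold.data.astype(np.float32), aff)
        img.header.set_zooms((config.voxel_size_mm,) * 3 + (config.tr_s,))
        nib.save(img, out / f"{sub.subject_id}_bold.nii.gz")
        motion_df = pd.DataFrame(sub.motion.params, columns=MotionTrace.COLUMNS)
        motion_df.to_csv(out / f"{sub.subject_id}_motion.tsv", sep="\t", index=False)
        rows.append({"participant_id": sub.subject_id, "group": sub.group_label,
                     **sub.covariates})
    participants = pd.DataFrame(rows)
    participants.to_csv(out / "participants.tsv", sep="\t", index=False)

    manifest = {
        "config": dataclasses.asdict(config),
        "effects": [dataclasses.asdict(e) for e in (effects or [])],
        "n_subjects": len(cohort),
        "subject_ids": [s.subject_id for s in cohort],
    }
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest


def read_cohort(in_dir: str | Path) -> tuple[list[SubjectData], MaskSet, dict]:
    """Round-trip reader for :func:`write_cohort` output."""
    src = Path(in_dir)
    manifest = json.loads((src / "manifest.json").read_text())
    cfg = manifest["config"]
    masks = MaskSet(
        **{
            name: np.asarray(
                nib.load(src / "masks" / f"{name}.nii.gz").dataobj, dtype=bool
            )
            for name in ("brain", "gm", "wm", "csf")
        }
    )
    participants = pd.read_csv(src / "participants.tsv", sep="\t")
    cohort = []
    for _, row in participants.iterrows():
        sid = row["participant_id"]
        data = np.asarray(nib.load(src / f"{sid}_bold.nii.gz").dataobj, dtype=float)
        motion = pd.read_csv(src / f"{sid}_motion.tsv", sep="\t")
        covariates = {
            k: row[k] for k in participants.columns
            if k not in ("participant_id", "group") and not pd.isna(row[k])
        }
        cohort.append(
            SubjectData(
                subject_id=sid,
                group_label=row["group"],
                bold=BoldRun(
                    data=data,
                    voxel_size_mm=cfg["voxel_size_mm"],
                    tr_s=cfg["tr_s"],
                    brain_mask=masks.brain,
                ),
                motion=MotionTrace(params=motion[list(MotionTrace.COLUMNS)].to_numpy()),
                covariates=covariates,
            )
        )
    return cohort, masks, manifest


def cohort_from_manifest(manifest: dict) -> tuple[list[SubjectData], MaskSet]:
    """Regenerate a cohort from a manifest's recorded config + effects."""
    config = SimulationConfig(**{**manifest["config"],
                                 "grid_shape": tuple(manifest["config"]["grid_shape"])})
    effects = [
        EffectSpec(**{**e, "center_voxel": tuple(e["center_voxel"])})
        for e in manifest.get("effects", [])
    ]
    return generate_cohort(config, effects)
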