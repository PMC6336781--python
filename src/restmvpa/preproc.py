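"""Denoising chain for resting-state BOLD runs.

Order of operations: discard the first 10 volumes jointly from BOLD and
motion; compute framewise displacement (Power convention, 50 mm head
radius); flag FD > 0.2 mm volumes plus one back and two forward neighbors
and model each as its own spike regressor; regress one combined nuisance
design (Friston-24 motion block + spikes + CSF mean + WM mean + linear
trend + intercept); then ideal band-pass filter 0.01-0.08 Hz in the
frequency domain.

Spectral amplitude maps (ALFF/fALFF) are computed from the *regressed but
unfiltered* residuals — the band enters their spectral sums — while
ReHo/FCS consume the band-passed series; ``preprocess_subject`` returns
both states.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import BoldRun, MaskSet, MotionTrace

FD_THRESHOLD_MM = 0.2
HEAD_RADIUS_MM = 50.0
N_DISCARD = 10


@dataclass
class BandSpec:
    """Pass band in Hz; must sit strictly inside (0, Nyquist)."""

    low_hz: float = 0.01
    high_hz: float = 0.08
    tr_s: float = 2.0

    def __post_init__(self) -> None:
        nyquist = 1.0 / (2.0 * self.tr_s)
        if not (0.0 < self.low_hz < self.high_hz < nyquist):
            raise ValueError(
                f"band [{self.low_hz}, {self.high_hz}] Hz invalid for "
                f"TR={self.tr_s}s (Nyquist {nyquist:g} Hz)"
            )


@dataclass
class ScrubPlan:
    """FD series, flagging threshold and the spike-regressor block."""

    fd_series: np.ndarray
    fd_threshold_mm: float
    flagged_volumes: np.ndarray  # sorted int indices
    spike_regressors: np.ndarray  # (n_volumes, n_flagged) 0/1

    def to_dict(self) -> dict:
        return {
            "fd_series": self.fd_series.tolist(),
            "fd_threshold_mm": self.fd_threshold_mm,
            "flagged_volumes": self.flagged_volumes.tolist(),
        }


@dataclass
class NuisanceDesign:
    """Combined nuisance design: columns plus human-readable labels."""

    matrix: np.ndarray  # (n_volumes, n_columns)
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("design must be 2D")
        if len(self.labels) != self.matrix.shape[1]:
            raise ValueError("label count does not match columns")


def discard_initial(
    bold: BoldRun, motion: MotionTrace, n: int = N_DISCARD
) -> tuple[BoldRun, MotionTrace]:
    """Drop the first ``n`` volumes jointly from BOLD and motion."""
    if n < 0:
        raise ValueError("n must be non-negative")
    if bold.n_volumes != motion.n_volumes:
        raise ValueError("bold and motion volume counts differ")
    if n >= bold.n_volumes:
        raise ValueError(f"cannot discard {n} of {bold.n_volumes} volumes")
    return bold.with_data(bold.data[..., n:]), MotionTrace(motion.params[n:])


def framewise_displacement(
    motion: MotionTrace, head_radius_mm: float = HEAD_RADIUS_MM
) -> np.ndarray:
    """FD(t) = sum |d translations| + R * sum |d rotations|; FD(0) = 0.

    Rotations (rad) are converted to arc length at ``head_radius_mm``.
    """
    if motion.n_volumes < 2:
        raise ValueError("framewise displacement needs at least 2 volumes")
    if not np.all(np.isfinite(motion.params)):
        raise ValueError("motion parameters must be finite")
    d = np.diff(motion.params, axis=0)
    fd = np.abs(d[:, :3]).sum(axis=1) + head_radius_mm * np.abs(d[:, 3:]).sum(axis=1)
    return np.concatenate([[0.0], fd])


def plan_scrubbing(
    fd_series: np.ndarray,
    threshold: float = FD_THRESHOLD_MM,
    back: int = 1,
    forward: int = 2,
) -> ScrubPlan:
    """Flag supra-threshold volumes with ``back`` preceding and ``forward``
    following neighbors (clipped at run boundaries); one 0/1 indicator
    regressor per flagged volume."""
    fd = np.asarray(fd_series, dtype=float)
    if not np.all(np.isfinite(fd)):
        raise ValueError("FD series must be finite")
    n = fd.shape[0]
    flagged: set[int] = set()
    for v in np.nonzero(fd > threshold)[0]:
        lo = max(0, v - back)
        hi = min(n - 1, v + forward)
        flagged.update(range(lo, hi + 1))
    flagged_idx = np.array(sorted(flagged), dtype=int)
    spikes = np.zeros((n, flagged_idx.size))
    spikes[flagged_idx, np.arange(flagged_idx.size)] = 1.0
    return ScrubPlan(
        fd_series=fd,
        fd_threshold_mm=threshold,
        flagged_volumes=flagged_idx,
        spike_regressors=spikes,
    )


def friston24(motion: MotionTrace) -> np.ndarray:
    """24-column motion block: p(t), p(t-1) (zero-padded first row), and
    their elementwise squares, for each of the 6 rigid-body parameters."""
    if motion.n_volumes < 2:
        raise ValueError("Friston-24 needs at least 2 volumes")
    p = motion.params
    p_back = np.vstack([np.zeros((1, 6)), p[:-1]])
    return np.hstack([p, p_back, p**2, p_back**2])


def mean_compartment_signal(bold: BoldRun, mask: np.ndarray) -> np.ndarray:
    """Per-volume mean over in-mask voxels (e.g. CSF or WM compartments)."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != bold.grid_shape:
        raise ValueError("mask shape does not match grid")
    if not mask.any():
        raise ValueError("empty compartment mask")
    return bold.data[mask].mean(axis=0)


def build_nuisance_design(
    motion: MotionTrace,
    scrub: ScrubPlan | None = None,
    csf_signal: np.ndarray | None = None,
    wm_signal: np.ndarray | None = None,
) -> NuisanceDesign:
    """Assemble the combined design: Friston-24 + spikes + CSF + WM +
    linear trend + intercept."""
    n = motion.n_volumes
    blocks = [friston24(motion)]
    labels = [
        f"{base}_{tag}"
        for tag in ("t", "tm1", "sq", "tm1_sq")
        for base in MotionTrace.COLUMNS
    ]
    if scrub is not None and scrub.spike_regressors.size:
        if scrub.spike_regressors.shape[0] != n:
            raise ValueError("scrub plan length does not match motion")
        blocks.append(scrub.spike_regressors)
        labels += [f"spike_{v}" for v in scrub.flagged_volumes]
    for name, sig in (("csf", csf_signal), ("wm", wm_signal)):
        if sig is not None:
            sig = np.asarray(sig, dtype=float)
            if sig.shape != (n,):
                raise ValueError(f"{name} signal length does not match run")
            blocks.append(sig[:, None])
            labels.append(f"{name}_mean")
    trend = np.linspace(-1.0, 1.0, n)[:, None]
    blocks += [trend, np.ones((n, 1))]
    labels += ["linear_trend", "intercept"]
    return NuisanceDesign(matrix=np.hstack(blocks), labels=labels)


def _prune_duplicate_columns(design: NuisanceDesign) -> NuisanceDesign:
    """Drop all-zero columns and exact duplicates (keeping first occurrence)."""
    X = design.matrix
    keep: list[int] = []
    for j in range(X.shape[1]):
        if not X[:, j].any():
            continue
        if not any(np.array_equal(X[:, j], X[:, k]) for k in keep):
            keep.append(j)
    return NuisanceDesign(matrix=X[:, keep], labels=[design.labels[j] for j in keep])


def nuisance_regression(bold: BoldRun, design: NuisanceDesign) -> BoldRun:
    """Voxelwise OLS residuals against the (duplicate-pruned) design.

    Residuals are zero-mean (the intercept is in the design) and orthogonal
    to every design column. Raises if the pruned design is rank-deficient,
    naming the collinear columns.
    """
    design = _prune_duplicate_columns(design)
    X = design.matrix
    if X.shape[0] != bold.n_volumes:
        raise ValueError("design rows do not match volume count")
    # unit-norm columns: rank and conditioning must not depend on the very
    # different natural scales of mm, rad and squared-rad regressors
    X = X / np.linalg.norm(X, axis=0, keepdims=True)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify a minimal set of offending labels via QR pivoting
        from scipy.linalg import qr

        _, _, piv = qr(X, mode="economic", pivoting=True)
        dropped = sorted(design.labels[j] for j in piv[rank:])
        raise ValueError(f"nuisance design is rank-deficient; collinear columns: {dropped}")
    nx, ny, nz, nt = bold.data.shape
    Y = bold.data.reshape(-1, nt).T  # (t, voxels)
    beta = np.linalg.pinv(X) @ Y  # full column rank was checked above
    resid = (Y - X @ beta).T.reshape(nx, ny, nz, nt)
    return bold.with_data(resid, state="regressed")


def bandpass(bold: BoldRun, band: BandSpec) -> BoldRun:
    """Ideal (brick-wall) frequency-domain band-pass.

    Discrete spectrum bins with low <= f <= high (both inclusive) are
    retained; everything else, including DC, is zeroed. The output is real
    and the operation is idempotent.
    """
    nt = bold.n_volumes
    freqs = np.fft.rfftfreq(nt, d=band.tr_s)
    keep = (freqs >= band.low_hz - 1e-12) & (freqs <= band.high_hz + 1e-12)
    keep[0] = False  # DC never passes
    if not keep.any():
        raise ValueError(
            f"no spectral bins inside [{band.low_hz}, {band.high_hz}] Hz: "
            f"frequency resolution is 1/(N*TR) = {1.0 / (nt * band.tr_s):.6f} Hz"
        )
    spec = np.fft.rfft(bold.data, axis=-1)
    spec[..., ~keep] = 0.0
    out = np.fft.irfft(spec, n=nt, axis=-1)
    return bold.with_data(out, state="bandpassed")


@dataclass
class PreprocessedRun:
    """Both denoised states of one run plus the scrub bookkeeping."""

    regressed: BoldRun          # nuisance-regressed, unfiltered (input to ALFF/fALFF)
    filtered: BoldRun | None    # additionally band-passed (input to ReHo/FCS)
    scrub: ScrubPlan
    design_labels: list[str]


def preprocess_subject(
    bold: BoldRun,
    motion: MotionTrace,
    masks: MaskSet,
    band: BandSpec | None = None,
    n_discard: int = N_DISCARD,
    fd_threshold_mm: float = FD_THRESHOLD_MM,
    bandpass_filter: bool = True,
) -> PreprocessedRun:
    """Full denoising chain for one subject.

    ``bandpass_filter=False`` skips the filtering step (useful when only the
    spectral maps, which consume the unfiltered residuals, are needed).
    """
    if band is None:
        band = BandSpec(tr_s=bold.tr_s)
    bold, motion = discard_initial(bold, motion, n_discard)
    fd = framewise_displacement(motion)
    scrub = plan_scrubbing(fd, threshold=fd_threshold_mm)
    design = build_nuisance_design(
        motion,
        scrub=scrub,
        csf_signal=mean_compartment_signal(bold, masks.csf),
        wm_signal=mean_compartment_signal(bold, masks.wm),
    )
    regressed = nuisance_regression(bold, design)
    filtered = bandpass(regressed, band) if bandpass_filter else None
    return PreprocessedRun(
        regressed=regressed,
        filtered=filtered,
        scrub=scrub,
        design_labels=design.labels,
    )
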