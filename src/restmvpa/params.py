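"""Voxelwise intrinsic-activity parameter maps.

Four maps per subject:

* **ALFF** — mean square-root power over the 0.01-0.08 Hz bins of the
  regressed (unfiltered) series, normalized by its within-brain mean.
* **fALFF** — in-band amplitude sum divided by the amplitude sum over all
  non-DC frequencies; in [0, 1] by construction.
* **ReHo** — Kendall's coefficient of concordance (W) between each voxel's
  band-passed series and its up-to-26 in-mask neighbors, normalized by the
  global mean W.
* **FCS** (degree centrality) — per gray-matter voxel, the sum of
  Fisher-z-transformed positive correlations r > 0.2 with all other GM
  voxels, smoothed and then z-scored.

ALFF/fALFF/ReHo are smoothed after normalization; FCS is smoothed before
z-scoring. Smoothing uses a separable Gaussian with
sigma = FWHM / (2 sqrt(2 ln 2)) applied on the full grid with zero padding,
then re-masked.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from scipy.stats import rankdata

from .preproc import BandSpec
from .types import BoldRun, ParameterMap

FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # approx 2.3548


@dataclass
class FcsSpec:
    """Degree-centrality thresholds: correlations must be positive and
    exceed ``r_threshold`` to count; r is clipped below 1 so the Fisher
    transform stays finite."""

    r_threshold: float = 0.2
    gm_probability_threshold: float = 0.2
    clip_r: float = 1.0 - 1e-7

    def __post_init__(self) -> None:
        if not (0.0 < self.r_threshold < 1.0):
            raise ValueError("r_threshold must lie in (0, 1)")


@dataclass
class SmoothSpec:
    fwhm_mm: float = 8.0
    voxel_size_mm: float = 3.0

    def __post_init__(self) -> None:
        if self.fwhm_mm <= 0 or self.voxel_size_mm <= 0:
            raise ValueError("FWHM and voxel size must be positive")

    @property
    def sigma_voxels(self) -> float:
        return (self.fwhm_mm / self.voxel_size_mm) / FWHM_TO_SIGMA


# ---------------------------------------------------------------------------
# spectral maps

def amplitude_spectrum(series: np.ndarray, tr_s: float) -> tuple[np.ndarray, np.ndarray]:
    """Single-sided amplitude spectrum, DC excluded.

    Returns ``(freqs, amplitude)`` over bins k = 1..floor(N/2), with
    amplitude(k) = sqrt(|X(k)|^2 * 2/N) for the unnormalized DFT X.
    """
    x = np.asarray(series, dtype=float)
    n = x.shape[-1]
    if n < 4:
        raise ValueError("series too short for a spectrum (need >= 4 samples)")
    if not np.all(np.isfinite(x)):
        raise ValueError("series must be finite")
    spec = np.fft.rfft(x, axis=-1)[..., 1:]  # drop DC
    freqs = np.fft.rfftfreq(n, d=tr_s)[1:]
    power = (np.abs(spec) ** 2) * (2.0 / n)
    return freqs, np.sqrt(power)


def _band_bins(freqs: np.ndarray, band: BandSpec) -> np.ndarray:
    return (freqs >= band.low_hz - 1e-12) & (freqs <= band.high_hz + 1e-12)


def alff_map(bold: BoldRun, mask: np.ndarray, band: BandSpec) -> ParameterMap:
    """Mean in-band spectral amplitude per voxel (raw, pre-normalization).

    Requires the regressed-but-unfiltered series: computing ALFF on
    band-passed data would be circular (everything outside the band is
    already zero) and would break the fALFF denominator.
    """
    if bold.state == "bandpassed":
        raise ValueError("ALFF must be computed on unfiltered (regressed) data")
    mask = np.asarray(mask, dtype=bool)
    freqs, amp = amplitude_spectrum(bold.data[mask], bold.tr_s)
    in_band = _band_bins(freqs, band)
    if not in_band.any():
        raise ValueError("no spectral bins inside the ALFF band at this resolution")
    values = np.zeros(bold.grid_shape)
    values[mask] = amp[:, in_band].mean(axis=1)
    prov = {"band": (band.low_hz, band.high_hz), "n_band_bins": int(in_band.sum())}
    return ParameterMap(values=values, kind="alff", state="raw", mask=mask, provenance=prov)


def falff_map(bold: BoldRun, mask: np.ndarray, band: BandSpec) -> ParameterMap:
    """In-band amplitude sum over total (non-DC) amplitude sum per voxel."""
    if bold.state == "bandpassed":
        raise ValueError("fALFF must be computed on unfiltered (regressed) data")
    mask = np.asarray(mask, dtype=bool)
    freqs, amp = amplitude_spectrum(bold.data[mask], bold.tr_s)
    in_band = _band_bins(freqs, band)
    if not in_band.any():
        raise ValueError("no spectral bins inside the fALFF band at this resolution")
    num = amp[:, in_band].sum(axis=1)
    den = amp.sum(axis=1)
    frac = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
    values = np.zeros(bold.grid_shape)
    values[mask] = frac
    prov = {"band": (band.low_hz, band.high_hz)}
    return ParameterMap(values=values, kind="falff", state="raw", mask=mask, provenance=prov)


# ---------------------------------------------------------------------------
# regional homogeneity

def kendalls_w(series_set: np.ndarray) -> float:
    """Kendall's coefficient of concordance across m series ranking n
    time points.

    Ranks use average-rank tie handling with no tie-correction factor:
    W = (12 * sum_t R(t)^2 - 3 m^2 n (n+1)^2) / (m^2 (n^3 - n))
    where R(t) is the cross-series rank sum at time t; equivalently
    W = ((m-1) rho_bar + 1) / m for the mean pairwise Spearman rho_bar.
    If every series is constant the statistic is undefined; 0 is returned
    with a warning.
    """
    x = np.asarray(series_set, dtype=float)
    if x.ndim != 2:
        raise ValueError("series_set must be (m, n)")
    m, n = x.shape
    if m < 2 or n < 2:
        raise ValueError("need at least 2 series of at least 2 time points")
    if not np.all(np.isfinite(x)):
        raise ValueError("series must be finite")
    if np.all(np.ptp(x, axis=1) == 0):
        warnings.warn("all series constant; Kendall's W undefined, returning 0")
        return 0.0
    ranks = rankdata(x, method="average", axis=1)
    r_sum = ranks.sum(axis=0)
    s = float((r_sum**2).sum())
    num = 12.0 * s - 3.0 * m**2 * n * (n + 1) ** 2
    den = m**2 * (n**3 - n)
    return num / den


_NEIGHBOR_OFFSETS = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
]


def _shift_sum(arr: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sum ``arr`` (masked) over the 27-voxel neighborhood of every voxel,
    along with the in-mask neighbor count. Zero-padded at grid edges."""
    total = np.zeros_like(arr)
    count = np.zeros(mask.shape, dtype=float)
    masked = arr * mask[..., None] if arr.ndim == 4 else arr * mask
    for dx, dy, dz in _NEIGHBOR_OFFSETS:
        src = [slice(max(0, -d), arr.shape[i] - max(0, d)) for i, d in enumerate((dx, dy, dz))]
        dst = [slice(max(0, d), arr.shape[i] - max(0, -d)) for i, d in enumerate((dx, dy, dz))]
        total[tuple(dst)] += masked[tuple(src)]
        count[tuple(dst[:3])] += mask[tuple(src[:3])]
    return total, count


def reho_map(bold: BoldRun, mask: np.ndarray, neighborhood: int = 27) -> ParameterMap:
    """Kendall's W of each voxel with its in-mask 26-neighborhood.

    Edge and mask-boundary voxels use whatever in-mask neighbors exist
    (m < 27); voxels with fewer than 2 usable series get 0. Expects
    band-passed input.
    """
    if bold.state != "bandpassed":
        raise ValueError("ReHo must be computed on band-passed data")
    if neighborhood != 27:
        raise ValueError("only the 27-voxel (26-neighbor) cluster is supported")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    nt = bold.n_volumes
    # ordinal ranks via double argsort: exact ties are measure-zero on
    # band-passed continuous data (the scalar kendalls_w keeps average ranks)
    order = np.argsort(bold.data, axis=-1, kind="stable")
    ranks = np.empty(bold.data.shape)
    np.put_along_axis(
        ranks, order,
        np.broadcast_to(np.arange(1.0, nt + 1.0), bold.data.shape), axis=-1,
    )
    r_sum, m_count = _shift_sum(ranks, mask)
    s = (r_sum**2).sum(axis=-1)
    m = m_count
    n = float(nt)
    with np.errstate(divide="ignore", invalid="ignore"):
        w = (12.0 * s - 3.0 * m**2 * n * (n + 1) ** 2) / (m**2 * (n**3 - n))
    w = np.where((m >= 2) & mask, w, 0.0)
    # constant-series neighborhoods can make the formula drift outside [0,1]
    w = np.clip(w, 0.0, 1.0)
    return ParameterMap(values=w, kind="reho", state="raw", mask=mask,
                        provenance={"neighborhood": neighborhood})


# ---------------------------------------------------------------------------
# degree centrality

def fcs_map(
    bold: BoldRun,
    gm_mask: np.ndarray,
    spec: FcsSpec | None = None,
    block_size: int = 512,
) -> ParameterMap:
    """Functional connectivity strength (voxelwise degree centrality).

    For each gray-matter voxel, sums atanh(r) over all other GM voxels with
    r > ``spec.r_threshold`` (positive tail only). Zero-variance voxels get
    0 and never count as partners. Expects band-passed input.
    """
    if bold.state != "bandpassed":
        raise ValueError("FCS must be computed on band-passed data")
    spec = spec or FcsSpec()
    gm_mask = np.asarray(gm_mask, dtype=bool)
    ts = bold.data[gm_mask]  # (v, t)
    sd = ts.std(axis=1)
    usable = sd > 0
    if usable.sum() < 2:
        raise ValueError("need at least 2 GM voxels with nonzero variance")
    nt = ts.shape[1]
    z = np.zeros_like(ts)
    z[usable] = (ts[usable] - ts[usable].mean(axis=1, keepdims=True)) / sd[usable, None]
    z /= np.sqrt(nt)  # so z @ z.T is the correlation matrix
    n_vox = ts.shape[0]
    fcs = np.zeros(n_vox)
    for start in range(0, n_vox, block_size):
        stop = min(start + block_size, n_vox)
        r_block = z[start:stop] @ z.T
        for i, row in enumerate(r_block):
            row[start + i] = 0.0  # exclude self-correlation
        keep = r_block > spec.r_threshold
        r_kept = np.clip(r_block, None, spec.clip_r)
        fcs[start:stop] = np.where(keep, np.arctanh(r_kept), 0.0).sum(axis=1)
    values = np.zeros(bold.grid_shape)
    values[gm_mask] = fcs
    prov = {"r_threshold": spec.r_threshold, "clip_r": spec.clip_r}
    return ParameterMap(values=values, kind="fcs", state="raw", mask=gm_mask,
                        provenance=prov)


# ---------------------------------------------------------------------------
# normalization and smoothing

def normalize_by_mask_mean(pmap: ParameterMap, mask: np.ndarray | None = None) -> ParameterMap:
    """Divide by the in-mask mean so the normalized in-mask mean is 1."""
    mask = pmap.mask if mask is None else np.asarray(mask, dtype=bool)
    mean = pmap.values[mask].mean()
    if not mean > 0:
        raise ValueError(f"in-mask mean must be positive, got {mean}")
    values = np.where(mask, pmap.values / mean, 0.0)
    return replace(pmap, values=values, state="normalized",
                   provenance={**pmap.provenance, "normalization": "mask_mean"})


def zscore_map(pmap: ParameterMap, mask: np.ndarray | None = None) -> ParameterMap:
    """Standardize to in-mask mean 0, SD 1 (population SD convention)."""
    mask = pmap.mask if mask is None else np.asarray(mask, dtype=bool)
    vals = pmap.values[mask]
    sd = vals.std()  # population (ddof=0)
    if sd == 0:
        raise ValueError("in-mask SD is zero; cannot z-score a constant map")
    values = np.where(mask, (pmap.values - vals.mean()) / sd, 0.0)
    return replace(pmap, values=values, state="normalized",
                   provenance={**pmap.provenance, "normalization": "zscore"})


def gaussian_smooth(pmap: ParameterMap, spec: SmoothSpec | None = None) -> ParameterMap:
    """Separable Gaussian smoothing on the full grid (zero-padded), then
    re-masked to the map's support."""
    if spec is None:
        spec = SmoothSpec()
    smoothed = ndimage.gaussian_filter(pmap.values, sigma=spec.sigma_voxels,
                                       mode="constant", cval=0.0)
    values = np.where(pmap.mask, smoothed, 0.0)
    return replace(pmap, values=values, state="smoothed",
                   provenance={**pmap.provenance, "fwhm_mm": spec.fwhm_mm})


# ---------------------------------------------------------------------------
# per-kind processing chains

def finalize_map(pmap: ParameterMap, smooth: SmoothSpec) -> ParameterMap:
    """Apply the kind-specific normalization/smoothing chain:
    alff/falff/reho: normalize by mask mean, then smooth;
    fcs: smooth, then z-score."""
    if pmap.state != "raw":
        raise ValueError("finalize_map expects a raw map")
    if pmap.kind in ("alff", "falff", "reho"):
        return gaussian_smooth(normalize_by_mask_mean(pmap), smooth)
    out = zscore_map(gaussian_smooth(pmap, smooth))
    # fcs ends z-scored after smoothing; report terminal state as smoothed chain
    return replace(out, state="smoothed")


def compute_subject_maps(
    regressed: BoldRun,
    filtered: BoldRun,
    brain_mask: np.ndarray,
    gm_mask: np.ndarray,
    band: BandSpec,
    smooth: SmoothSpec | None = None,
    fcs_spec: FcsSpec | None = None,
    kinds: tuple[str, ...] = ("alff", "falff", "reho", "fcs"),
) -> dict[str, ParameterMap]:
    """All requested finalized maps for one preprocessed subject."""
    smooth = smooth or SmoothSpec(voxel_size_mm=regressed.voxel_size_mm)
    out: dict[str, ParameterMap] = {}
    for kind in kinds:
        if kind == "alff":
            raw = alff_map(regressed, brain_mask, band)
        elif kind == "falff":
            raw = falff_map(regressed, brain_mask, band)
        elif kind == "reho":
            raw = reho_map(filtered, brain_mask)
        elif kind == "fcs":
            raw = fcs_map(filtered, gm_mask, fcs_spec)
        else:
            raise ValueError(f"unknown map kind {kind!r}")
        out[kind] = finalize_map(raw, smooth)
    return out
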