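"""Core in-memory containers shared across the pipeline.

A subject's resting-state run is a 4D BOLD array plus its acquisition
geometry; motion is a per-volume 6-parameter rigid-body trace; derived
voxelwise statistics live in :class:`ParameterMap` objects that carry their
kind (alff / falff / reho / fcs) and processing state so downstream stages
can assert they received the right input.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

PARAM_KINDS = ("alff", "falff", "reho", "fcs")
MAP_STATES = ("raw", "normalized", "smoothed")
#: BOLD processing states, in pipeline order.
BOLD_STATES = ("raw", "regressed", "bandpassed")


@dataclass
class BoldRun:
    """One subject's 4D voxel time series.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz, t)
        Voxel time series in signal units.
    voxel_size_mm : float
        Isotropic voxel edge length.
    tr_s : float
        Repetition time (seconds per volume).
    brain_mask : ndarray of bool, shape (nx, ny, nz)
    state : str
        One of ``raw | regressed | bandpassed``; spectral maps (ALFF/fALFF)
        require regressed-but-unfiltered input while ReHo/FCS require
        band-passed input, and assert on this tag.
    """

    data: np.ndarray
    voxel_size_mm: float
    tr_s: float
    brain_mask: np.ndarray
    state: str = "raw"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"BOLD data must be 4D, got shape {self.data.shape}")
        self.brain_mask = np.asarray(self.brain_mask, dtype=bool)
        if self.brain_mask.shape != self.data.shape[:3]:
            raise ValueError(
                f"brain mask shape {self.brain_mask.shape} does not match "
                f"grid {self.data.shape[:3]}"
            )
        if self.state not in BOLD_STATES:
            raise ValueError(f"unknown BOLD state {self.state!r}")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    def with_data(self, data: np.ndarray, state: str | None = None) -> "BoldRun":
        return replace(self, data=data, state=state if state is not None else self.state)


@dataclass
class MotionTrace:
    """Per-volume rigid-body motion: 3 translations (mm), 3 rotations (rad)."""

    params: np.ndarray  # (t, 6)

    COLUMNS = ("trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z")

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, dtype=float)
        if self.params.ndim != 2 or self.params.shape[1] != 6:
            raise ValueError(f"motion trace must be (t, 6), got {self.params.shape}")
        if not np.all(np.isfinite(self.params)):
            raise ValueError("motion parameters must be finite")

    @property
    def n_volumes(self) -> int:
        return self.params.shape[0]

    @property
    def translations_mm(self) -> np.ndarray:
        return self.params[:, :3]

    @property
    def rotations_rad(self) -> np.ndarray:
        return self.params[:, 3:]


@dataclass
class MaskSet:
    """Brain / gray-matter / white-matter / CSF masks on a common grid.

    Invariant: GM, WM and CSF are disjoint subsets of the brain mask.
    """

    brain: np.ndarray
    gm: np.ndarray
    wm: np.ndarray
    csf: np.ndarray

    def __post_init__(self) -> None:
        for name in ("brain", "gm", "wm", "csf"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=bool))
        shape = self.brain.shape
        for name in ("gm", "wm", "csf"):
            m = getattr(self, name)
            if m.shape != shape:
                raise ValueError(f"{name} mask shape {m.shape} != brain {shape}")
            if np.any(m & ~self.brain):
                raise ValueError(f"{name} mask extends outside the brain mask")


@dataclass
class ParameterMap:
    """3D voxelwise scalar map tagged with its kind and processing state."""

    values: np.ndarray
    kind: str
    state: str
    mask: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.ndim != 3:
            raise ValueError("parameter map must be 3D")
        if self.mask.shape != self.values.shape:
            raise ValueError("mask shape does not match map")
        if self.kind not in PARAM_KINDS:
            raise ValueError(f"unknown map kind {self.kind!r}")
        if self.state not in MAP_STATES:
            raise ValueError(f"unknown map state {self.state!r}")
        if not np.all(np.isfinite(self.values[self.mask])):
            raise ValueError("non-finite values inside mask")

    def in_mask(self) -> np.ndarray:
        """Flat vector of in-mask values (C order of the mask's True voxels)."""
        return self.values[self.mask]


@dataclass
class CohortFeatures:
    """Subjects-by-voxels feature matrix for one map kind.

    ``labels`` are +1 for patients and -1 for controls; ``voxel_index`` maps
    feature columns back to grid coordinates for discrimination maps.
    """

    matrix: np.ndarray  # (n_subjects, n_voxels)
    labels: np.ndarray  # (n_subjects,), values in {+1, -1}
    subject_ids: list[str]
    voxel_index: tuple[np.ndarray, np.ndarray, np.ndarray]
    grid_shape: tuple[int, int, int]
    kind: str
    state: str

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.matrix.ndim != 2:
            raise ValueError("feature matrix must be 2D")
        if self.matrix.shape[0] != self.labels.shape[0]:
            raise ValueError("label count does not match subject rows")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("non-finite feature entries")
        if not set(np.unique(self.labels)) <= {-1, 1}:
            raise ValueError("labels must be +1 (patient) / -1 (control)")
        if len(self.subject_ids) != self.matrix.shape[0]:
            raise ValueError("subject id count does not match rows")

    @property
    def n_subjects(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.matrix.shape[1]


def features_from_maps(
    maps: "list[ParameterMap]",
    labels: np.ndarray,
    subject_ids: list[str],
    mask: np.ndarray | None = None,
) -> CohortFeatures:
    """Stack per-subject maps of one kind/state into a CohortFeatures matrix."""
    if not maps:
        raise ValueError("no maps supplied")
    kind, state = maps[0].kind, maps[0].state
    if mask is None:
        mask = maps[0].mask
    mask = np.asarray(mask, dtype=bool)
    for m in maps:
        if m.kind != kind or m.state != state:
            raise ValueError("all maps must share kind and state")
        if m.values.shape != mask.shape:
            raise ValueError("map grid does not match mask")
    idx = np.nonzero(mask)
    matrix = np.stack([m.values[idx] for m in maps])
    return CohortFeatures(
        matrix=matrix,
        labels=np.asarray(labels),
        subject_ids=list(subject_ids),
        voxel_index=idx,
        grid_shape=mask.shape,
        kind=kind,
        state=state,
    )
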