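"""Volume I/O, run configuration and provenance.

All volumes are exchanged as NIfTI-1 files on a shared reference (atlas)
grid with physical voxel spacing in micrometres.  Axis order is (x, y, z)
with x the left-right axis; voxel indexing is 0-based.  Displacement
fields are stored as 4-D volumes with a trailing 3-component vector axis
and the NIfTI vector intent code so they can be told apart from
multi-channel intensity images.  Tables are TSV with a header row.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import yaml

__all__ = [
    "BrainImage",
    "LabelAtlas",
    "DisplacementField",
    "ScalarMap",
    "RunConfig",
    "read_volume",
    "write_volume",
    "load_config",
    "read_table",
    "write_table",
]

NIFTI_INTENT_VECTOR = 1007


@dataclass
class _Grid:
    """A voxel grid with physical spacing (µm per voxel edge)."""

    data: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive floats, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape[:3]

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in µm³."""
        return float(np.prod(self.spacing))


@dataclass
class ScalarMap(_Grid):
    """Per-voxel scalar volume (LJD map, p-map, statistic map, mask)."""

    subject: str | None = None

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.data.ndim != 3:
            raise ValueError(f"scalar map must be 3-D, got shape {self.data.shape}")


@dataclass
class BrainImage(_Grid):
    """Multi-channel intensity image; channel axis last, shape (x, y, z, c)."""

    channel_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.data.ndim == 3:
            self.data = self.data[..., None]
        if self.data.ndim != 4:
            raise ValueError(f"brain image must be 3-D or 4-D, got shape {self.data.shape}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[3]


@dataclass
class LabelAtlas(_Grid):
    """Integer division labels; 0 is background.

    ``names`` maps each positive label to a division name.  ``divisions``
    optionally carries the geometric specification the labels were built
    from (used by the synthetic cohort generator).
    """

    names: dict[int, str] = field(default_factory=dict)
    divisions: dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.data.ndim != 3:
            raise ValueError(f"label atlas must be 3-D, got shape {self.data.shape}")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("label atlas must have an integer dtype")

    @property
    def labels(self) -> np.ndarray:
        lab = np.unique(self.data)
        return lab[lab > 0]

    def mask(self, label: int) -> np.ndarray:
        return self.data == label

    def brain_mask(self) -> np.ndarray:
        return self.data > 0


@dataclass
class DisplacementField(_Grid):
    """Per-voxel displacement u(x) in µm, shape (x, y, z, 3).

    Convention: the spatial transform T(x) = x + u(x) maps reference
    (atlas) coordinates to subject coordinates, in physical units.
    """

    subject: str | None = None

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.data.ndim != 4 or self.data.shape[3] != 3:
            raise ValueError(
                f"displacement field must have shape (x, y, z, 3), got {self.data.shape}"
            )


def _affine(spacing: Sequence[float]) -> np.ndarray:
    return np.diag(list(spacing) + [1.0])


def write_volume(grid: _Grid, path: str | Path) -> Path:
    """Write a grid as NIfTI-1; round-trips exactly for integer data and
    to float precision for floating data (NaNs preserved)."""
    path = Path(path)
    data = grid.data
    img = nib.Nifti1Image(data, _affine(grid.spacing))
    if isinstance(grid, DisplacementField):
        img.header["intent_code"] = NIFTI_INTENT_VECTOR
    img.header.set_data_dtype(data.dtype)
    try:
        nib.save(img, path)
    except OSError as exc:  # unwritable path
        raise OSError(f"cannot write volume to {path}: {exc}") from exc
    return path


def read_volume(path: str | Path) -> BrainImage | LabelAtlas | DisplacementField | ScalarMap:
    """Read a NIfTI volume and classify it by shape/intent/dtype.

    3-D integer grids load as :class:`LabelAtlas`, 3-D float grids as
    :class:`ScalarMap`; 4-D grids load as :class:`DisplacementField` when
    the NIfTI vector intent code is set (as :func:`write_volume` does for
    fields), otherwise as a multi-channel :class:`BrainImage` — a plain
    3-channel image is indistinguishable from a vector field by shape
    alone, so the intent code is authoritative.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume file not found: {path}")
    img = nib.load(path)
    data = np.asanyarray(img.dataobj)
    if data.ndim < 3 or data.ndim > 5:
        raise ValueError(f"{path}: expected a 3-D or 4-D grid, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    if len(zooms) < 3 or any(not np.isfinite(z) or z <= 0 for z in zooms):
        raise ValueError(f"{path}: missing or invalid voxel spacing {zooms}")
    # squeeze singleton NIfTI time axis (x, y, z, 1, c) -> (x, y, z, c)
    if data.ndim == 5 and data.shape[3] == 1:
        data = data[:, :, :, 0, :]
    spacing = tuple(float(z) for z in zooms)
    if data.ndim == 3:
        if np.issubdtype(data.dtype, np.integer):
            return LabelAtlas(data, spacing)
        return ScalarMap(data, spacing)
    if data.ndim == 4:
        if int(img.header["intent_code"]) == NIFTI_INTENT_VECTOR:
            return DisplacementField(data.astype(np.float64, copy=False), spacing)
        return BrainImage(data, spacing)
    raise ValueError(f"{path}: expected a 3-D or 4-D grid, got shape {data.shape}")


# ---------------------------------------------------------------------------
# tables


def write_table(df, path: str | Path) -> Path:
    path = Path(path)
    df.to_csv(path, sep="\t", index=False)
    return path


def read_table(path: str | Path):
    import pandas as pd

    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Validated parameters shared by the pipeline stages.

    Thresholds must be strictly positive; the RNG seed is recorded in all
    output metadata so every stage is reproducible.
    """

    seed: int = 0
    # voxel map filtering
    alpha: float = 0.01            # voxelwise p threshold (kept iff p <= alpha)
    min_cluster: int = 50          # minimum surviving cluster size, voxels
    sym_tol: int = 2               # bilateral symmetry tolerance radius, voxels
    connectivity: int = 26         # 6, 18 or 26
    # morphometry
    min_jacobian: float = 0.05     # fold clamp for log-Jacobian maps
    # group statistics
    bootstrap_resamples: int = 5000
    # differential expression convergence
    fdr_alpha: float = 0.1         # BH FDR significance level (strict <)
    min_basemean: float = 100.0    # expression filter, required in BOTH experiments
    # fragment analysis
    wt_threshold: float = 0.5      # include crispant iff min wildtype fraction < this
    size_tolerance: float = 2.0    # bp window for matching the wildtype peak
    min_prominence: float = 0.02   # peak prominence as fraction of max signal
    tag_offset: float = 25.0       # bp added to declared product sizes by primer tags
    # paths
    indir: str = "."
    outdir: str = "out"

    _POSITIVE = (
        "alpha", "min_cluster", "sym_tol", "min_jacobian", "bootstrap_resamples",
        "fdr_alpha", "min_basemean", "wt_threshold", "size_tolerance",
        "min_prominence",
    )

    def __post_init__(self) -> None:
        for name in self._POSITIVE:
            val = getattr(self, name)
            if name == "sym_tol":
                if val < 0:
                    raise ValueError(f"config: {name} must be >= 0, got {val}")
                continue
            if not val > 0:
                raise ValueError(f"config: {name} must be strictly positive, got {val}")
        if self.connectivity not in (6, 18, 26):
            raise ValueError(f"config: connectivity must be 6, 18 or 26, got {self.connectivity}")
        if not (0 < self.alpha < 1):
            raise ValueError(f"config: alpha must be in (0, 1), got {self.alpha}")
        if not (0 < self.fdr_alpha < 1):
            raise ValueError(f"config: fdr_alpha must be in (0, 1), got {self.fdr_alpha}")
        self.seed = int(self.seed)

    def provenance(self) -> dict:
        from zbmorph import __version__

        params = {k: v for k, v in dataclasses.asdict(self).items()}
        return {
            "seed": self.seed,
            "version": __version__,
            "config_hash": hashlib.sha256(
                json.dumps(params, sort_keys=True).encode()
            ).hexdigest()[:16],
            "params": params,
        }


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML run configuration; unknown keys are rejected and all
    documented defaults fill unset fields."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping, got {type(raw).__name__}")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    return RunConfig(**raw)
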