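"""Volume/table readers and writers, pipeline configuration.

Volumes travel as multi-page TIFF stacks (float32 density, uint8 masks,
voxel pitch stored as JSON in the image description) or NIfTI (pitch from
the header zooms, which must be isotropic). Profiles and rate curves are
CSV with a ``#``-prefixed JSON metadata header so they round-trip through
pandas untouched.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import FormatError, ValidationError
from .profile import AxialDensityProfile
from .rate import MineralAdditionProfile
from .volume import EnamelMask, Tomogram

_TIFF_SUFFIXES = {".tif", ".tiff"}


def _is_nifti(path: Path) -> bool:
    return path.name.endswith((".nii", ".nii.gz"))


def write_volume(vol: Tomogram | EnamelMask, path: str | Path) -> Path:
    """Write a tomogram (float32) or mask (uint8) as TIFF or NIfTI."""
    path = Path(path)
    is_mask = isinstance(vol, EnamelMask)
    data = vol.voxels.astype(np.uint8 if is_mask else np.float32)
    if path.suffix.lower() in _TIFF_SUFFIXES:
        import tifffile

        meta = {"voxel_um": vol.voxel_um, "enamelmat": __version__}
        tifffile.imwrite(
            path, data, photometric="minisblack", description=json.dumps(meta)
        )
    elif _is_nifti(path):
        import nibabel as nib

        pitch_mm = vol.voxel_um / 1000.0
        affine = np.diag([pitch_mm, pitch_mm, pitch_mm, 1.0])
        nib.save(nib.Nifti1Image(data, affine), str(path))
    else:
        raise FormatError(f"unsupported volume format: {path.name}")
    return path


def _read_array(path: Path, voxel_um: float | None) -> tuple[np.ndarray, float]:
    if path.suffix.lower() in _TIFF_SUFFIXES:
        import tifffile

        with tifffile.TiffFile(path) as tf:
            data = tf.asarray()
            desc = tf.pages[0].description
        if voxel_um is None:
            try:
                voxel_um = float(json.loads(desc)["voxel_um"])
            except (TypeError, ValueError, KeyError):
                raise FormatError(
                    f"{path.name}: voxel pitch not in metadata; pass voxel_um"
                ) from None
        return data, voxel_um
    if _is_nifti(path):
        import nibabel as nib

        img = nib.load(str(path))
        zooms = np.asarray(img.header.get_zooms()[:3], dtype=float)
        if voxel_um is None:
            if not np.allclose(zooms, zooms[0], rtol=1e-5):
                raise FormatError(
                    f"{path.name}: anisotropic voxels {zooms}; resampling is "
                    "not supported — pass an explicit voxel_um to override"
                )
            voxel_um = float(zooms[0] * 1000.0)
        return np.asarray(img.dataobj), voxel_um
    raise FormatError(f"unsupported volume format: {path.name}")


def read_volume(path: str | Path, voxel_um: float | None = None) -> Tomogram:
    """Read a density volume; pitch from metadata unless ``voxel_um`` given."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    data, pitch = _read_array(path, voxel_um)
    if data.ndim != 3:
        raise FormatError(f"{path.name}: expected a 3D stack, got {data.ndim}D")
    if not np.issubdtype(data.dtype, np.number):
        raise FormatError(f"{path.name}: unsupported dtype {data.dtype}")
    return Tomogram(data.astype(np.float32), pitch)


def read_mask(path: str | Path, voxel_um: float | None = None) -> EnamelMask:
    """Read a binary enamel mask (nonzero = enamel)."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    data, pitch = _read_array(path, voxel_um)
    return EnamelMask(np.asarray(data) > 0, pitch)


def write_profile_csv(p: AxialDensityProfile, path: str | Path) -> Path:
    """Profile → CSV with a JSON metadata comment line."""
    path = Path(path)
    meta = {
        "enamelmat": __version__,
        "gumline_mm": p.gumline_mm,
        "smoothed": p.smoothed,
        "window": p.window,
        "axial_step_mm": p.axial_step_mm,
    }
    df = pd.DataFrame(
        {"x_mm": p.x_mm, "mean_density": p.mean_density, "area_mm2": p.area_mm2}
    )
    if p.sd is not None:
        df["sd"] = p.sd
    with open(path, "w") as fh:
        fh.write(f"# {json.dumps(meta)}\n")
        df.to_csv(fh, index=False)
    return path


def read_profile_csv(path: str | Path) -> AxialDensityProfile:
    path = Path(path)
    meta: dict = {}
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            meta = json.loads(first[1:].strip())
    df = pd.read_csv(path, comment="#")
    return AxialDensityProfile(
        x_mm=df["x_mm"].to_numpy(),
        mean_density=df["mean_density"].to_numpy(),
        area_mm2=df["area_mm2"].to_numpy(),
        axial_step_mm=float(meta.get("axial_step_mm", np.median(np.diff(df["x_mm"])))),
        gumline_mm=meta.get("gumline_mm"),
        smoothed=bool(meta.get("smoothed", False)),
        window=meta.get("window"),
        sd=df["sd"].to_numpy() if "sd" in df else None,
    )


def write_rate_csv(r: MineralAdditionProfile, path: str | Path) -> Path:
    """Rate profile → CSV; the header comment records mode and δx."""
    path = Path(path)
    meta = {
        "enamelmat": __version__,
        "mode": r.mode,
        "delta_x_mm": r.delta_x_mm,
        "from_smoothed": r.from_smoothed,
    }
    df = pd.DataFrame({"x_mm": r.x_mm, "rate": r.rate})
    if r.sd is not None:
        df["sd"] = r.sd
    with open(path, "w") as fh:
        fh.write(f"# {json.dumps(meta)}\n")
        df.to_csv(fh, index=False)
    return path


def read_hardness_csv(path: str | Path) -> pd.DataFrame:
    """Read a Vickers table (``animal_id,age_weeks,level,region,side,hv``)."""
    df = pd.read_csv(path, comment="#")
    missing = {"animal_id", "age_weeks", "level", "hv"} - set(df.columns)
    if missing:
        raise FormatError(f"hardness table lacks columns: {sorted(missing)}")
    return df


@dataclass
class PipelineConfig:
    """Parameters of a full densitometry run.

    Stage defaults follow the measurement protocol: 30 um surface shell,
    0.02 mm^2 minimum slice area, 5-sample moving average, δx = 1 mm,
    α = 0.05. ``mask_path`` may be omitted, in which case the volume is
    segmented with the ``lo``/``hi`` density band.
    """

    volume_path: str
    out_dir: str
    gumline_mm: float
    mask_path: str | None = None
    voxel_um: float | None = None
    lo: float = 1400.0
    hi: float = 2600.0
    min_component_voxels: int = 64
    reorient: bool = True
    shell_um: float = 30.0
    #: density above which non-enamel voxels are treated as tissue (dentin),
    #: not exterior air, when extracting the surface shell
    exterior_max_density: float = 600.0
    min_area_mm2: float = 0.02
    window: int = 5
    delta_x_mm: float = 1.0
    mode: str = "absolute"
    surface_band_mm: tuple[float, float] = (0.0, 3.0)
    alpha: float = 0.05
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.mode not in ("absolute", "relative"):
            raise ValidationError("mode must be 'absolute' or 'relative'")
        self.surface_band_mm = tuple(self.surface_band_mm)  # type: ignore[assignment]

    def to_yaml(self, path: str | Path) -> Path:
        import yaml

        path = Path(path)
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def config_hash(self) -> str:
        """Stable short hash of the canonicalized config."""
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]
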