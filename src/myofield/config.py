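"""Pipeline configuration.

Every tunable of the reconstruction pipeline lives here, grouped by stage,
with the reference protocol as defaults (the ``reference_defaults``
profile).  A config can be loaded from / dumped to a single YAML file; any
value not present in the file keeps its default.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

__all__ = [
    "ResolutionConfig",
    "EdgeParams",
    "ElasticParams",
    "DensityParams",
    "Seg2DParams",
    "Seg3DParams",
    "VesselParams",
    "PlacentaParams",
    "WidthParams",
    "PipelineConfig",
]


@dataclass
class ResolutionConfig:
    """Pixel geometry of the input tiles and the coarse-graining grid."""

    um_per_px_x: float = 0.371
    um_per_px_y: float = 0.371
    region_px: int = 128       # coarse-graining region edge, image px
    window_px: int = 32        # local-threshold window edge, image px

    def __post_init__(self) -> None:
        if self.um_per_px_x <= 0 or self.um_per_px_y <= 0:
            raise ValueError("pixel size must be positive")
        if self.region_px % self.window_px != 0:
            raise ValueError("region_px must be a multiple of window_px")

    @property
    def pitch_um(self) -> float:
        """Edge length of one region pixel (= voxel) in µm."""
        return self.region_px * self.um_per_px_x


@dataclass
class NucleiParams:
    """Phase-I thresholding and particle filtering."""

    red_factor: float = 5.0 / 6.0   # upper red threshold, x window mean
    blue_factor: float = 1.0        # upper blue threshold, x window mean
    min_area_px: float = 40.0       # below: noise
    max_area_px: float = 600.0      # above: nuclear clusters
    sm_area_um2: tuple = (10.0, 60.0)   # smooth-muscle nucleus size range
    small_area_um2: float = 14.0        # red-blood-cell upper size


@dataclass
class RegionParams:
    """Phase-II classification thresholds."""

    planar_aspect: float = 2.0      # aspect > this: planar-class
    vertical_aspect: float = 1.6    # aspect < this: vertical-class
    vertical_fraction: float = 5.0 / 9.0
    max_iqr_deg: float = 45.0
    min_count: int = 2
    frame_w: int = 800              # padded frame, region px
    frame_h: int = 1600


@dataclass
class EdgeParams:
    """Canny edge extraction for rigid registration (Table-1 protocol)."""

    count_scale: float = 20.0
    gaussian_sd: float = 3.0
    sobel_radius: int = 1
    hysteresis_high: float = 50.0
    hysteresis_low: float = 30.0


@dataclass
class RigidParams:
    n_steps: int = 7
    max_iterations: int = 10
    frame_w: int = 800
    # rotation bounds per step; the printed sequence has 6 entries for 7
    # steps, so the final ±1 deg is repeated.
    rotation_bounds: tuple = (180.0, 10.0, 5.0, 2.5, 1.25, 1.0, 1.0)
    centre_pitch: int = 50          # grid pitch multiplier per step
    step1_radius: float = 200.0     # step-1 centre grid confinement


@dataclass
class ElasticParams:
    """Per-tile elastic registration (Table-2 protocol)."""

    a_max_deg: float = 20.0
    e_min: float = 0.2
    b0_px: float = 16.0             # 16 for rat blocks, 32 for human
    tile_px: int = 16               # tile edge in region pixels
    theta_bound_deg: float = 30.0
    het_threshold_deg2: float = 45.0**2
    neighbourhood: int = 1          # tile rings for refinement (3x3)
    substack_len: int = 11          # densest-substack length for global ref
    ref_group: int = 5              # slides per local-reference group
    qc_threshold: float = 0.5       # post-registration discard score


@dataclass
class StackParams:
    slice_um: float = 5.0           # physical section thickness l_s


@dataclass
class Direction3DParams:
    l_max: int = 40                 # line-probe cap, voxels
    planar_phi_step: float = 15.0   # candidate elevations -60..60
    vertical_theta_step: float = 11.25
    same_bundle_deg: float = 30.0
    min_length: int = 2             # L_i must exceed this to enter average


@dataclass
class DensityParams:
    """Stereological density weighting (Table-3 protocol)."""

    rM_over_l: float = 0.3
    rm_over_l: float = 0.1
    N0: float = 10.0
    N1: float = 160.0

    def __post_init__(self) -> None:
        if not 0 < self.rm_over_l < self.rM_over_l:
            raise ValueError("need 0 < rm < rM")
        if not self.N0 < self.N1:
            raise ValueError("need N0 < N1")


@dataclass
class Seg2DParams:
    """Two-dimensional segmentation (Table-4 protocol)."""

    gaussian_var: float = 1.0
    vertical_grey_threshold: float = 10.0
    f_min: float = 0.54
    planar_grey_threshold: float = 0.01
    truncate_sigmas: float = 3.0


@dataclass
class Seg3DParams:
    """Three-dimensional segmentation with adaptive smoothing (Table 5)."""

    f_min: float = 0.5
    lam: float = 1.22
    sigma_min: float = 0.4
    sigma_max: float = 4.0
    sigma_step: float = 0.1
    truncate_sigmas: float = 3.0


@dataclass
class VesselParams:
    """Vasculature detection (Table-6 protocol)."""

    max_rbc_um2: float = 14.0
    min_vessel_voxels: int = 9
    gaussian_var: float = 1.0
    fraction_threshold: float = 0.5  # on the smoothed RBC fraction


@dataclass
class PlacentaParams:
    """Placental-tissue detection (Table-7 protocol)."""

    min_density_per_mm2: float = 4500.0
    lower_threshold: float = 0.3
    upper_threshold: float = 0.6
    min_cluster_voxels: int = 10000
    gaussian_sigma: float = 4.0


@dataclass
class WidthParams:
    grid_regions: int = 4           # internodal separation, in-plane
    grid_z: int = 1
    weight_threshold: float = 0.2
    step_voxels: float = 0.5
    effect_interval: tuple = (-0.0488, 0.0513)  # log 5% equivalence bounds
    ks_critical: float = 1.36       # c(0.05)
    ks_sample: int = 1000
    ks_reps: int = 1000
    ks_ci: float = 0.90


@dataclass
class PipelineConfig:
    resolution: ResolutionConfig = field(default_factory=ResolutionConfig)
    nuclei: NucleiParams = field(default_factory=NucleiParams)
    regions: RegionParams = field(default_factory=RegionParams)
    edges: EdgeParams = field(default_factory=EdgeParams)
    rigid: RigidParams = field(default_factory=RigidParams)
    elastic: ElasticParams = field(default_factory=ElasticParams)
    stack: StackParams = field(default_factory=StackParams)
    direction3d: Direction3DParams = field(default_factory=Direction3DParams)
    density: DensityParams = field(default_factory=DensityParams)
    seg2d: Seg2DParams = field(default_factory=Seg2DParams)
    seg3d: Seg3DParams = field(default_factory=Seg3DParams)
    vessels: VesselParams = field(default_factory=VesselParams)
    placenta: PlacentaParams = field(default_factory=PlacentaParams)
    widths: WidthParams = field(default_factory=WidthParams)
    seed: int = 0
    stages: Optional[list] = None   # None: all stages in pipeline order
    synth: Optional[dict] = None    # synthetic-stack parameters for `synth`

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        kwargs: dict = {}
        for f in dataclasses.fields(cls):
            if f.name not in data:
                continue
            val = data[f.name]
            typ = f.default_factory() if f.default_factory is not dataclasses.MISSING else None
            if dataclasses.is_dataclass(typ) and isinstance(val, dict):
                sub = {k: (tuple(v) if isinstance(v, list) else v) for k, v in val.items()}
                kwargs[f.name] = type(typ)(**sub)
            else:
                kwargs[f.name] = val
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def reference_defaults() -> PipelineConfig:
    """The reference parameterisation (high-resolution rat protocol)."""
    return PipelineConfig()
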