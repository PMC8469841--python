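"""Synthetic CT-like phantoms with a geometrically defined target landmark.

Each phantom is a bright spheroid (the "aortic root") with a narrow bright
tube (the "coronary artery") attached at a random point on its surface and
pointing radially outward.  The target landmark is the tube-sphere junction,
the analogue of a coronary ostium.  The spheroid carries a smooth angular
intensity shading -- brightest on the junction side -- so that local 2.5D
patches anywhere on or near the spheroid carry a consistent directional cue
toward the landmark, the synthetic counterpart of the consistent surrounding
anatomy a learnable real target requires.  Gaussian noise is added and
intensities are clipped to [0, 1].

Suites of phantoms (default 32, split 24 train / 8 test) drive training,
localization and the end-to-end tests without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .volume_env import Landmark, Volume, write_landmarks, write_volume

__all__ = ["PhantomConfig", "generate_phantom", "generate_suite"]


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry and intensity parameters of one phantom.

    Distances are voxels; intensities are normalized units in [0, 1].
    ``landmark_margin`` guarantees the junction stays that many voxels from
    every face (so default N=16 observations at the target are padding-free);
    ``shading`` in [0, 1) scales the angular intensity gradient of the
    spheroid (0 disables it).
    """

    dims: tuple[int, int, int] = (64, 64, 64)
    spacing_mm: tuple[float, float, float] = (0.33, 0.33, 0.33)
    sphere_radius_range: tuple[float, float] = (10.0, 14.0)
    tube_radius: float = 2.0
    tube_length: float = 18.0
    foreground: float = 0.8
    background: float = 0.15
    noise_sd: float = 0.03
    shading: float = 0.35
    landmark_margin: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.dims) < 2 * self.landmark_margin:
            raise ValueError(f"dims {self.dims} too small for landmark margin {self.landmark_margin}")
        if self.sphere_radius_range[0] > self.sphere_radius_range[1]:
            raise ValueError("sphere_radius_range must be (lo, hi) with lo <= hi")
        if not 0.0 <= self.shading < 1.0:
            raise ValueError("shading must be in [0, 1)")
        if not (0.0 <= self.background < self.foreground <= 1.0):
            raise ValueError("need 0 <= background < foreground <= 1")


def _sample_geometry(cfg: PhantomConfig, rng: np.random.Generator):
    """Rejection-sample (center, radius, direction) so sphere and tube fit."""
    dims = np.asarray(cfg.dims, dtype=np.float64)
    m = cfg.landmark_margin
    tube_m = cfg.tube_radius + 1.0
    for _ in range(1000):
        center = rng.uniform(dims / 3.0, 2.0 * dims / 3.0)
        radius = rng.uniform(*cfg.sphere_radius_range)
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        junction = center + radius * d
        tip = junction + cfg.tube_length * d
        if np.all(junction >= m) and np.all(junction <= dims - 1 - m) and np.all(
            tip >= tube_m
        ) and np.all(tip <= dims - 1 - tube_m):
            return center, radius, d, junction, tip
    raise ValueError(
        f"phantom geometry does not fit: dims {cfg.dims}, radii {cfg.sphere_radius_range}, "
        f"tube length {cfg.tube_length}, margin {cfg.landmark_margin}"
    )


def generate_phantom(cfg: PhantomConfig) -> tuple[Volume, Landmark]:
    """Deterministically generate one phantom volume and its landmark."""
    rng = np.random.default_rng(cfg.seed)
    center, radius, d, junction, tip = _sample_geometry(cfg, rng)

    xx, yy, zz = np.meshgrid(
        *(np.arange(s, dtype=np.float32) for s in cfg.dims), indexing="ij"
    )
    rel = np.stack([xx - center[0], yy - center[1], zz - center[2]])
    dist_c = np.sqrt(np.sum(rel**2, axis=0))

    vol = np.full(cfg.dims, cfg.background, dtype=np.float32)

    # shaded spheroid: intensity ramps from fg*(1-shading) on the far side
    # to fg on the junction side, via the angle to the tube direction
    sphere = dist_c <= radius
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.einsum("i,ijkl->jkl", d.astype(np.float32), rel) / dist_c
    cosang = np.nan_to_num(cosang, nan=1.0)  # center voxel: take the bright side
    u = 0.5 * (1.0 + np.clip(cosang, -1.0, 1.0))
    shade = cfg.foreground * (1.0 - cfg.shading * (1.0 - u))
    vol[sphere] = shade[sphere].astype(np.float32)

    # tube: cylinder of tube_radius around the segment junction -> tip
    seg = tip - junction
    seg_len2 = float(np.dot(seg, seg))
    relj = np.stack([xx - junction[0], yy - junction[1], zz - junction[2]])
    t = np.clip(np.einsum("i,ijkl->jkl", seg.astype(np.float32), relj) / seg_len2, 0.0, 1.0)
    closest = relj - t[None] * seg[:, None, None, None].astype(np.float32)
    tube = np.sqrt(np.sum(closest**2, axis=0)) <= cfg.tube_radius
    vol[tube] = cfg.foreground

    if cfg.noise_sd > 0:
        vol = vol + rng.normal(0.0, cfg.noise_sd, size=cfg.dims).astype(np.float32)
    vol = np.clip(vol, 0.0, 1.0)

    volume = Volume(data=vol, spacing=cfg.spacing_mm, origin=(0.0, 0.0, 0.0))
    voxel = tuple(int(v) for v in np.rint(junction))
    landmark = Landmark.from_voxel("junction", voxel, volume)
    return volume, landmark


def generate_suite(
    n: int,
    base_seed: int,
    cfg: PhantomConfig | None = None,
    out_dir: str | Path | None = None,
    train_fraction: float = 0.75,
) -> tuple[list[tuple[Volume, Landmark]], pd.DataFrame]:
    """Generate ``n`` phantoms with seeds ``base_seed .. base_seed+n-1``.

    The manifest assigns the first ``round(train_fraction * n)`` phantoms to
    the train split and the rest to test (default 3:1, i.e. 24/8 at n=32).
    With ``out_dir`` set, volumes (``.nii.gz``), ``landmarks.json`` and
    ``manifest.csv`` are written there.
    """
    if cfg is None:
        cfg = PhantomConfig()
    n_train = int(round(train_fraction * n))
    pairs: list[tuple[Volume, Landmark]] = []
    rows = []
    for i in range(n):
        seed = base_seed + i
        volume, landmark = generate_phantom(replace(cfg, seed=seed))
        pairs.append((volume, landmark))
        rows.append(
            {
                "id": f"phantom_{i:03d}",
                "seed": seed,
                "split": "train" if i < n_train else "test",
                "landmark_name": landmark.name,
                "voxel_x": landmark.voxel[0],
                "voxel_y": landmark.voxel[1],
                "voxel_z": landmark.voxel[2],
            }
        )
    manifest = pd.DataFrame(rows)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        landmark_map = {}
        for row, (volume, landmark) in zip(rows, pairs):
            write_volume(volume, out / f"{row['id']}.nii.gz")
            landmark_map[row["id"]] = landmark
        write_landmarks(
            [replace_name(lm, vid) for vid, lm in landmark_map.items()],
            out / "landmarks.json",
        )
        manifest.to_csv(out / "manifest.csv", index=False)
    return pairs, manifest


def replace_name(lm: Landmark, volume_id: str) -> Landmark:
    """Tag a landmark with the id of the volume it belongs to."""
    return Landmark(f"{volume_id}/{lm.name}", lm.voxel, lm.world_mm)
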