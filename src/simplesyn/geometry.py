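"""Active-zone geometry: voxel grid, channel clusters, contour and global regions.

The presynaptic bouton is a cuboid (default 0.9 x 0.5 x 0.5 um) discretized
into cubic voxels (default 10 nm). Voltage-gated Ca2+ channels sit on the
z = 0 face, grouped into clusters (default three clusters of nine channels,
3x3 grids with 20 nm spacing, cluster centres at the vertices of an
equilateral triangle of 126 nm side, centred on the face). Release-relevant
"local" [Ca2+] is averaged over the contour voxels of the first voxel layer
whose in-plane distance to the nearest cluster edge is 40 nm (within half a
voxel); "global" [Ca2+] is averaged over voxels farther than 100 nm from
every cluster edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GeometryConfig", "AZGeometry", "build_geometry"]


@dataclass(frozen=True)
class GeometryConfig:
    box_um: tuple[float, float, float] = (0.9, 0.5, 0.5)
    voxel_nm: float = 10.0
    n_clusters: int = 3
    channels_per_cluster: int = 9
    channel_spacing_nm: float = 20.0
    cluster_spacing_nm: float = 126.0
    contour_distance_nm: float = 40.0
    global_distance_nm: float = 100.0


@dataclass
class AZGeometry:
    """Voxelized active-zone geometry.

    channel_positions are (x, y) in nm on the z = 0 face; channel_voxels are
    the (ix, iy) indices of the voxels receiving influx (z layer 0);
    contour_mask / global_mask are boolean voxel masks of shape ``shape``.
    """

    config: GeometryConfig
    shape: tuple[int, int, int]
    channel_positions: np.ndarray  # (n_channels, 2) nm
    cluster_assignment: np.ndarray  # (n_channels,) int
    channel_voxels: np.ndarray  # (n_channels, 2) int indices in x, y
    contour_mask: np.ndarray = field(repr=False)
    global_mask: np.ndarray = field(repr=False)

    @property
    def voxel_nm(self) -> float:
        return self.config.voxel_nm

    @property
    def voxel_volume_um3(self) -> float:
        return (self.config.voxel_nm * 1e-3) ** 3

    @property
    def n_channels(self) -> int:
        return len(self.channel_positions)


def _cluster_layout(cfg: GeometryConfig) -> tuple[np.ndarray, np.ndarray]:
    """Channel (x, y) positions in nm, centred on the z=0 face, and labels."""
    lx, ly = cfg.box_um[0] * 1e3, cfg.box_um[1] * 1e3
    centre = np.array([lx / 2.0, ly / 2.0])

    # cluster centres: 1 -> face centre; 2 -> pair; >=3 -> regular polygon
    # (equilateral triangle for the default 3) with the printed side length.
    n = cfg.n_clusters
    if n < 1:
        raise ValueError("cluster count must be >= 1")
    if n == 1:
        centres = centre[None, :]
    else:
        # circumradius giving nearest-neighbour (side) distance = spacing
        r = cfg.cluster_spacing_nm / (2.0 * np.sin(np.pi / n))
        ang = np.pi / 2.0 + 2.0 * np.pi * np.arange(n) / n
        centres = centre + r * np.stack([np.cos(ang), np.sin(ang)], axis=1)

    # channels: square grid per cluster with the printed 20 nm spacing
    m = int(np.ceil(np.sqrt(cfg.channels_per_cluster)))
    g = np.arange(m) - (m - 1) / 2.0
    gx, gy = np.meshgrid(g, g, indexing="ij")
    offsets = np.stack([gx.ravel(), gy.ravel()], axis=1)[: cfg.channels_per_cluster]
    offsets = offsets * cfg.channel_spacing_nm

    positions = (centres[:, None, :] + offsets[None, :, :]).reshape(-1, 2)
    labels = np.repeat(np.arange(n), cfg.channels_per_cluster)
    if np.any(positions < 0) or np.any(positions[:, 0] > lx) or np.any(positions[:, 1] > ly):
        raise ValueError("cluster spacing places channels outside the box")
    return positions, labels


def _edge_distance_xy(cfg: GeometryConfig, positions: np.ndarray, labels: np.ndarray,
                      xv: np.ndarray, yv: np.ndarray) -> np.ndarray:
    """In-plane distance (nm) from points (xv, yv) to the nearest cluster edge.

    The cluster edge is the boundary of the convex hull of the cluster's
    channels in the z = 0 plane; for the default 3x3 grids this is the
    square spanned by the outer channels. Points inside the hull are at
    distance 0.
    """
    pts = np.stack([xv.ravel(), yv.ravel()], axis=1)
    best = np.full(len(pts), np.inf)
    for c in np.unique(labels):
        ch = positions[labels == c]
        d = _dist_to_convex_hull(ch, pts)
        best = np.minimum(best, d)
    return best.reshape(xv.shape)


def _dist_to_convex_hull(vertices: np.ndarray, pts: np.ndarray) -> np.ndarray:
    """Distance from pts to the convex hull of ``vertices`` (0 inside)."""
    if len(vertices) == 1:
        return np.hypot(pts[:, 0] - vertices[0, 0], pts[:, 1] - vertices[0, 1])
    try:
        from scipy.spatial import ConvexHull

        hull = ConvexHull(vertices)
        hv = vertices[hull.vertices]
    except Exception:  # collinear degenerate sets
        hv = vertices
    # distance to each edge segment of the hull polygon
    d_min = np.full(len(pts), np.inf)
    nv = len(hv)
    for i in range(nv):
        a, b = hv[i], hv[(i + 1) % nv]
        ab = b - a
        denom = float(ab @ ab)
        if denom == 0.0:
            d = np.hypot(pts[:, 0] - a[0], pts[:, 1] - a[1])
        else:
            t = np.clip((pts - a) @ ab / denom, 0.0, 1.0)
            proj = a + t[:, None] * ab
            d = np.hypot(pts[:, 0] - proj[:, 0], pts[:, 1] - proj[:, 1])
        d_min = np.minimum(d_min, d)
    if nv >= 3:
        inside = np.ones(len(pts), dtype=bool)
        for i in range(nv):
            a, b = hv[i], hv[(i + 1) % nv]
            cross = (b[0] - a[0]) * (pts[:, 1] - a[1]) - (b[1] - a[1]) * (pts[:, 0] - a[0])
            # hull vertices are counter-clockwise from scipy
            inside &= cross >= -1e-9
        d_min = np.where(inside, 0.0, d_min)
    return d_min


def build_geometry(config: GeometryConfig | None = None) -> AZGeometry:
    """Construct the voxelized active-zone geometry.

    Raises if the voxel size is non-positive or does not divide the box,
    or if channels would fall outside the box.
    """
    cfg = config or GeometryConfig()
    if cfg.voxel_nm <= 0:
        raise ValueError("voxel size must be positive")
    box_nm = np.asarray(cfg.box_um) * 1e3
    shape_f = box_nm / cfg.voxel_nm
    shape = tuple(int(round(s)) for s in shape_f)
    if not np.allclose(shape_f, shape, atol=1e-6):
        raise ValueError("voxel size must divide the box dimensions")

    positions, labels = _cluster_layout(cfg)
    channel_voxels = np.floor(positions / cfg.voxel_nm).astype(int)
    channel_voxels = np.clip(channel_voxels, 0, np.array(shape[:2]) - 1)

    # voxel-centre coordinates
    h = cfg.voxel_nm
    x = (np.arange(shape[0]) + 0.5) * h
    y = (np.arange(shape[1]) + 0.5) * h
    z = (np.arange(shape[2]) + 0.5) * h
    xv, yv = np.meshgrid(x, y, indexing="ij")
    d_xy = _edge_distance_xy(cfg, positions, labels, xv, yv)

    contour_mask = np.zeros(shape, dtype=bool)
    ring = np.abs(d_xy - cfg.contour_distance_nm) <= h / 2.0
    contour_mask[:, :, 0] = ring  # first voxel layer above the AZ membrane

    # global region: full 3D distance to the cluster edge (in-plane distance
    # combined with height above the z=0 face) beyond the cutoff
    d3 = np.sqrt(d_xy[:, :, None] ** 2 + z[None, None, :] ** 2)
    global_mask = d3 > cfg.global_distance_nm

    return AZGeometry(
        config=cfg,
        shape=shape,
        channel_positions=positions,
        cluster_assignment=labels,
        channel_voxels=channel_voxels,
        contour_mask=contour_mask,
        global_mask=global_mask,
    )
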