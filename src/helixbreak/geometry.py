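"""Simplified DNA/chromatin geometry.

A chromatin segment is a straight B-DNA double helix laid along the x axis:
each base pair contributes six molecule sites (two phosphates, two
deoxyriboses, two bases) in a plane perpendicular to the fibre axis, with a
34 degree azimuthal twist per base pair.  Histones are 2.5 nm spheres placed
on the fibre axis at a configurable base-pair spacing and act downstream as
perfect radical scavengers.  Container volumes (cell nucleus / cytoplasm)
are ellipsoids specified by their full axis lengths in micrometres.

All coordinates are in nanometres, base-pair indices are 0-based, and
intervals in bp include both endpoints.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Tuple

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

# site-kind codes
PHOSPHATE = 0
DEOXYRIBOSE = 1
BASE = 2
KIND_NAMES = np.array(["phosphate", "deoxyribose", "base"])

DEG = np.pi / 180.0


@dataclass(frozen=True)
class GeometryConfig:
    """Helix construction parameters.

    The 34 deg/bp twist is the only angle the damage model depends on; rise
    and radii follow the canonical B-DNA convention.  Radii in nm.
    """

    rise_nm: float = 0.34
    twist_deg: float = 34.0
    helix_radius_nm: float = 1.0        # radial position of phosphate centres
    deoxyribose_radial_nm: float = 0.75  # radial position of deoxyribose centres
    base_radial_nm: float = 0.30
    r_phosphate_nm: float = 0.228
    r_deoxyribose_nm: float = 0.263
    base_half_axes_nm: Tuple[float, float, float] = (0.35, 0.35, 0.17)
    histone_radius_nm: float = 2.5


DEFAULT_GEOMETRY = GeometryConfig()


@dataclass
class ChromatinSegment:
    """A straight chromatin segment with per-site arrays of length 6*n_bp."""

    segment_id: int
    n_bp: int
    bp_index: np.ndarray          # (6n,) int
    strand: np.ndarray            # (6n,) int, 0|1
    kind: np.ndarray              # (6n,) int codes
    positions: np.ndarray         # (6n, 3) float nm
    radius: np.ndarray            # (6n,) float nm
    base_sequence: np.ndarray     # (n,) 'AT'|'CG'
    histone_centres: np.ndarray = field(
        default_factory=lambda: np.empty((0, 3), dtype=float))
    histone_radius: float = 2.5
    config: GeometryConfig = DEFAULT_GEOMETRY

    def __post_init__(self) -> None:
        self._backbone_tree = None
        self._all_tree = None

    # -- spatial indexes ---------------------------------------------------
    @property
    def backbone_mask(self) -> np.ndarray:
        return self.kind != BASE

    @property
    def backbone_indices(self) -> np.ndarray:
        return np.flatnonzero(self.backbone_mask)

    @property
    def backbone_tree(self) -> cKDTree:
        """KD-tree over phosphate+deoxyribose centres (built lazily)."""
        if self._backbone_tree is None:
            self._backbone_tree = cKDTree(self.positions[self.backbone_mask])
        return self._backbone_tree

    @property
    def all_site_tree(self) -> cKDTree:
        """KD-tree over all molecule centres, bases included."""
        if self._all_tree is None:
            self._all_tree = cKDTree(self.positions)
        return self._all_tree

    @property
    def length_nm(self) -> float:
        return self.n_bp * self.config.rise_nm

    def without_histones(self) -> "ChromatinSegment":
        return replace(self, histone_centres=np.empty((0, 3)))

    def sites_frame(self) -> pd.DataFrame:
        """Tabular export: segment_id, bp_index, strand, kind, x, y, z, radius."""
        return pd.DataFrame({
            "segment_id": np.full(self.bp_index.size, self.segment_id),
            "bp_index": self.bp_index,
            "strand": self.strand,
            "kind": KIND_NAMES[self.kind],
            "x": self.positions[:, 0],
            "y": self.positions[:, 1],
            "z": self.positions[:, 2],
            "radius": self.radius,
        })


@dataclass(frozen=True)
class ContainerModel:
    """Nucleus/cytoplasm ellipsoids; axes are FULL lengths in micrometres."""

    nucleus_axes_um: Tuple[float, float, float] = (14.2, 14.2, 5.0)
    cytoplasm_axes_um: Tuple[float, float, float] = (28.0, 28.0, 5.0)
    total_bp: int = 6_400_000_000
    centre_nm: Tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.nucleus_axes_um + self.cytoplasm_axes_um):
            raise ValueError("container axes must be positive")
        if any(c < n for c, n in zip(self.cytoplasm_axes_um, self.nucleus_axes_um)):
            raise ValueError("cytoplasm ellipsoid must contain the nucleus")
        if self.cytoplasm_volume_um3 <= self.nucleus_volume_um3:
            raise ValueError("cytoplasm volume must exceed nucleus volume")

    @property
    def nucleus_volume_um3(self) -> float:
        return ellipsoid_volume(*self.nucleus_axes_um)

    @property
    def cytoplasm_volume_um3(self) -> float:
        return ellipsoid_volume(*self.cytoplasm_axes_um)

    @property
    def nucleus_mass_kg(self) -> float:
        """Unit-density water mass of the nucleus."""
        return self.nucleus_volume_um3 * 1e-18 * 1000.0


def ellipsoid_volume(a: float, b: float, c: float) -> float:
    """Volume of an ellipsoid from its full axis lengths: (pi/6) a b c."""
    if a <= 0 or b <= 0 or c <= 0:
        raise ValueError("axis lengths must be positive")
    return np.pi / 6.0 * a * b * c


def bp_density(total_bp: float, volume_um3: float) -> float:
    """Base pairs per nm^3 given a genome size and a nuclear volume in um^3."""
    if volume_um3 <= 0:
        raise ValueError("volume must be positive")
    return total_bp / (volume_um3 * 1e9)


def build_helix_segment(n_bp: int, seed: int,
                        config: GeometryConfig = DEFAULT_GEOMETRY,
                        segment_id: int = 0) -> ChromatinSegment:
    """Construct a straight double-helix segment of ``n_bp`` base pairs.

    Six sites per bp; consecutive base pairs rotate by ``config.twist_deg``
    about the fibre (x) axis.  The AT/CG label of each pair is drawn with
    equal probability from ``seed``.  Deterministic for a fixed seed.
    """
    if n_bp < 1:
        raise ValueError(f"n_bp must be >= 1, got {n_bp}")
    rng = np.random.default_rng(seed)
    cfg = config

    bp = np.arange(n_bp)
    theta0 = bp * cfg.twist_deg * DEG          # strand 0 azimuth per bp
    x_axis = bp * cfg.rise_nm

    n_sites = 6 * n_bp
    bp_index = np.repeat(bp, 6)
    # per bp: (strand0: P, D, B), (strand1: P, D, B)
    strand = np.tile(np.array([0, 0, 0, 1, 1, 1]), n_bp)
    kind = np.tile(np.array([PHOSPHATE, DEOXYRIBOSE, BASE] * 2), n_bp)

    radial = np.where(kind == PHOSPHATE, cfg.helix_radius_nm,
                      np.where(kind == DEOXYRIBOSE, cfg.deoxyribose_radial_nm,
                               cfg.base_radial_nm))
    theta = np.repeat(theta0, 6) + strand * np.pi
    positions = np.empty((n_sites, 3))
    positions[:, 0] = np.repeat(x_axis, 6)
    positions[:, 1] = radial * np.cos(theta)
    positions[:, 2] = radial * np.sin(theta)

    base_effective_r = max(cfg.base_half_axes_nm)
    radius = np.where(kind == PHOSPHATE, cfg.r_phosphate_nm,
                      np.where(kind == DEOXYRIBOSE, cfg.r_deoxyribose_nm,
                               base_effective_r))

    base_sequence = rng.choice(np.array(["AT", "CG"]), size=n_bp)
    return ChromatinSegment(
        segment_id=segment_id, n_bp=n_bp, bp_index=bp_index, strand=strand,
        kind=kind, positions=positions, radius=radius,
        base_sequence=base_sequence, histone_radius=cfg.histone_radius_nm,
        config=cfg)


def place_histones(segment: ChromatinSegment, spacing_bp: int) -> ChromatinSegment:
    """Place histone spheres on the fibre axis every ``spacing_bp`` base pairs.

    Centres sit at the middle of each spacing window, on the axis (where no
    molecule site lies), giving floor(n_bp / spacing_bp) histones of radius
    2.5 nm (configurable through the segment's GeometryConfig).
    """
    if spacing_bp < 1:
        raise ValueError(f"spacing_bp must be >= 1, got {spacing_bp}")
    count = segment.n_bp // spacing_bp
    centres = np.zeros((count, 3))
    centres[:, 0] = (np.arange(count) + 0.5) * spacing_bp * segment.config.rise_nm
    return replace(segment, histone_centres=centres,
                   histone_radius=segment.config.histone_radius_nm)


def nearest_backbone_site(point: np.ndarray, segment: ChromatinSegment,
                          tie_tol: float = 1e-9):
    """Nearest phosphate/deoxyribose site to ``point``.

    Ties within ``tie_tol`` nm are broken deterministically: lowest strand,
    then lowest bp_index, then phosphate before deoxyribose.  Returns
    ``(site_index, distance_nm)`` where site_index addresses the segment's
    per-site arrays.
    """
    point = np.asarray(point, dtype=float)
    dist, local = segment.backbone_tree.query(point)
    # collect any co-minimal candidates for the documented tie rule
    cand_local = segment.backbone_tree.query_ball_point(point, dist + tie_tol)
    backbone = segment.backbone_indices
    if len(cand_local) > 1:
        cand = backbone[np.asarray(cand_local)]
        d = np.linalg.norm(segment.positions[cand] - point, axis=1)
        near = cand[d <= d.min() + tie_tol]
        order = np.lexsort((segment.kind[near], segment.bp_index[near],
                            segment.strand[near]))
        idx = int(near[order[0]])
        return idx, float(np.linalg.norm(segment.positions[idx] - point))
    return int(backbone[local]), float(dist)
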