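"""Three-level chromatin fiber geometry and point-in-volume queries.

The model follows the classic volumetric (non-atomistic) description of
B-DNA used in nanodosimetric track-structure work:

* **Nucleotide pair** — a 0.34 nm thick disc of radius 1.15 nm, rotated 36
  degrees per consecutive pair.  Each strand owns a *backbone* volume (a 90
  degree cylinder sector of full radius 1.15 nm with the inner section
  deleted for the base) and a *base* volume (a half-cylinder of diameter
  1 nm filling the deleted section).
* **Nucleosome** — 1.65 left-handed turns of the double helix wound around a
  histone cylinder (radius 3.3 nm, height 5.7 nm).
* **Fiber** — a solenoid of 61 nucleosomes, 6 per turn, inside a cylindrical
  envelope of diameter 37 nm and length 161 nm, holding 10.8 kbp in total.
  Consecutive nucleosomes are joined by linker DNA whose path is a cubic
  Bezier curve matching position and tangent at both ends.

All lengths are nm.  The fiber frame has z along the fiber axis with the
origin at the fiber center.  Base-pair indices are global, 0-based and
contiguous along the DNA path; strand 0 is the strand whose 5'→3' direction
follows increasing bp index (a label only — there is no sequence content).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict, replace
from typing import Iterator, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .errors import GeometryInfeasibleError, InvalidArgumentError
from .transforms import Frame, rot_z

__all__ = [
    "FiberConfig",
    "VolumeSpec",
    "NucleotidePair",
    "VolumeHit",
    "NucleusEnvelope",
    "FiberGeometry",
    "build_double_helix",
    "build_nucleosome",
    "build_linker",
    "build_fiber",
    "locate",
    "geometry_summary",
]

# VolumeHit.kind codes used by the vectorized classifier
KIND_BACKBONE = 0
KIND_BASE = 1
KIND_HISTONE = 2
KIND_WATER = 3
KIND_NAMES = {KIND_BACKBONE: "backbone", KIND_BASE: "base", KIND_HISTONE: "histone", KIND_WATER: "water"}


@dataclass(frozen=True)
class FiberConfig:
    """Geometry parameters.  Defaults reproduce the documented fiber:
    61 nucleosomes, 6 per turn, 37 x 161 nm envelope, 10.8 kbp total."""

    rise_nm: float = 0.34
    twist_deg: float = 36.0
    backbone_radius_nm: float = 1.15
    base_diameter_nm: float = 1.0
    histone_radius_nm: float = 3.3
    histone_height_nm: float = 5.7
    wrap_turns: float = 1.65
    nucleosomes: int = 61
    nucleosomes_per_turn: int = 6
    fiber_diameter_nm: float = 37.0
    fiber_length_nm: float = 161.0
    #: nucleosome repeat length (wrapped + linker bp); 177 bp is a typical
    #: somatic repeat and makes 61 units sum to 10,797 bp = 10.8 kbp.
    nucleosome_repeat_bp: int = 177
    #: radius of the solenoid helix carrying the nucleosome centers.
    solenoid_radius_nm: float = 11.5
    #: axial clearance reserved at each fiber end so every nucleotide volume
    #: stays inside the envelope.
    solenoid_z_margin_nm: float = 6.5
    #: azimuth (deg, about the nucleosome axis from the fiber-radial
    #: direction) at which the DNA wrap starts.  The default orients the
    #: entry/exit points so the inter-nucleosome Bezier arcs come out at the
    #: 0.34 nm/bp rise for the default linker allocation.
    wrap_phase_deg: float = 322.0
    #: tolerance on |linker bp spacing - rise| before the linker is declared
    #: geometrically infeasible.
    linker_spacing_tol_nm: float = 0.05

    # ----- derived quantities -------------------------------------------
    @property
    def twist_rad(self) -> float:
        return math.radians(self.twist_deg)

    @property
    def wrap_radius_nm(self) -> float:
        """Radius of the wrapped DNA path: histone radius + backbone radius."""
        return self.histone_radius_nm + self.backbone_radius_nm

    @property
    def wrap_pitch_nm(self) -> float:
        """Axial advance of the wrap per turn (histone height / turns)."""
        return self.histone_height_nm / self.wrap_turns

    @property
    def wrap_arc_length_nm(self) -> float:
        per_turn = math.hypot(2.0 * math.pi * self.wrap_radius_nm, self.wrap_pitch_nm)
        return self.wrap_turns * per_turn

    @property
    def wrapped_bp(self) -> int:
        return int(round(self.wrap_arc_length_nm / self.rise_nm))

    @property
    def linker_bp(self) -> int:
        n = self.nucleosome_repeat_bp - self.wrapped_bp
        if n < 2:
            raise GeometryInfeasibleError(
                f"nucleosome repeat {self.nucleosome_repeat_bp} bp leaves no room for "
                f"a linker ({self.wrapped_bp} bp are wrapped)"
            )
        return n

    @property
    def total_bp(self) -> int:
        return self.nucleosomes * self.nucleosome_repeat_bp

    @property
    def fiber_radius_nm(self) -> float:
        return self.fiber_diameter_nm / 2.0

    @property
    def bp_bound_radius_nm(self) -> float:
        """Bounding-sphere radius of one nucleotide-pair disc."""
        return math.hypot(self.backbone_radius_nm, self.rise_nm / 2.0)

    def volume_spec(self) -> "VolumeSpec":
        return VolumeSpec(
            backbone_radius_nm=self.backbone_radius_nm,
            base_radius_nm=self.base_diameter_nm / 2.0,
            thickness_nm=self.rise_nm,
            histone_radius_nm=self.histone_radius_nm,
            histone_height_nm=self.histone_height_nm,
        )


@dataclass(frozen=True)
class VolumeSpec:
    """Shapes of the elementary scoring volumes (all lengths nm)."""

    backbone_radius_nm: float
    base_radius_nm: float
    thickness_nm: float
    histone_radius_nm: float
    histone_height_nm: float


@dataclass(frozen=True)
class NucleotidePair:
    """One base pair: a rigid frame plus derived per-strand volume frames.

    The pair frame has z along the local helix axis; the strand-0 backbone
    sector is centered on +x, the strand-1 sector on -x (the 36 degree twist
    is already folded into the frame's rotation).
    """

    bp_index: int
    frame: Frame
    nucleosome_id: int = -1  # -1 marks linker DNA

    def backbone_transform(self, strand: int) -> Frame:
        return self.frame.compose(Frame(rot_z(strand * math.pi)))

    def base_transform(self, strand: int) -> Frame:
        return self.frame.compose(Frame(rot_z(strand * math.pi)))

    @property
    def is_linker(self) -> bool:
        return self.nucleosome_id < 0


@dataclass(frozen=True)
class VolumeHit:
    """Answer to a point->volume query."""

    kind: str  # backbone | base | histone | water
    strand: int | None = None
    bp_index: int | None = None
    nucleosome_id: int | None = None


@dataclass(frozen=True)
class NucleusEnvelope:
    """Cell-nucleus normalization construct: a cylinder with an ellipsoidal
    base mimicking a human fibroblast nucleus.  Used only for dose/bp
    bookkeeping — DNA is never instantiated at nucleus scale."""

    semi_a_nm: float = 9850.0
    semi_b_nm: float = 7100.0
    height_nm: float = 2500.0
    genome_bp: float = 6.0e9

    @property
    def volume_nm3(self) -> float:
        return math.pi * self.semi_a_nm * self.semi_b_nm * self.height_nm

    @property
    def bp_density_per_nm3(self) -> float:
        return self.genome_bp / self.volume_nm3


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------

def build_double_helix(n_bp: int, start_frame: Frame | None = None, config: FiberConfig | None = None) -> list[NucleotidePair]:
    """Straight B-DNA segment: pair *i* is pair *i-1* translated one rise
    along the local z axis and twisted +36 degrees about it."""
    if n_bp < 1:
        raise InvalidArgumentError(f"n_bp must be >= 1, got {n_bp}")
    cfg = config or FiberConfig()
    start = start_frame or Frame()
    step = Frame(rot_z(cfg.twist_rad), np.array([0.0, 0.0, cfg.rise_nm]))
    pairs = []
    frame = start
    for i in range(n_bp):
        pairs.append(NucleotidePair(bp_index=i, frame=frame))
        frame = frame.compose(step)
    return pairs


def _wrap_arrays(cfg: FiberConfig, histone_frame: Frame, twist_offset: int, s_values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Frames of the wrapped DNA path at arc positions ``s_values`` (nm from
    the wrap start), in the lab frame.  Twist accumulates 36 deg per bp index
    ``twist_offset + k`` about the local tangent, measured from the
    radial-outward reference direction."""
    a = cfg.wrap_radius_nm
    per_turn = math.hypot(2.0 * math.pi * a, cfg.wrap_pitch_nm)
    u = s_values / per_turn  # turns travelled
    phase = math.radians(cfg.wrap_phase_deg)
    theta = phase - 2.0 * math.pi * u  # left-handed wrap
    z = (u / cfg.wrap_turns - 0.5) * cfg.histone_height_nm

    cos_t, sin_t = np.cos(theta), np.sin(theta)
    origins_local = np.stack([a * cos_t, a * sin_t, z], axis=1)

    # tangent of the left-handed helix (unit)
    tx = 2.0 * math.pi * a * sin_t
    ty = -2.0 * math.pi * a * cos_t
    tz = np.full_like(tx, cfg.wrap_pitch_nm)
    e3 = np.stack([tx, ty, tz], axis=1)
    e3 /= np.linalg.norm(e3, axis=1, keepdims=True)

    # radial-outward reference is exactly perpendicular to the tangent
    e1 = np.stack([cos_t, sin_t, np.zeros_like(cos_t)], axis=1)
    e2 = np.cross(e3, e1)

    # accumulated twist about the tangent
    k = twist_offset + np.arange(len(s_values))
    psi = (k * cfg.twist_rad) % (2.0 * math.pi)
    cos_p, sin_p = np.cos(psi)[:, None], np.sin(psi)[:, None]
    e1t = cos_p * e1 + sin_p * e2
    e2t = -sin_p * e1 + cos_p * e2

    rot_local = np.stack([e1t, e2t, e3], axis=2)  # columns are axes
    origins = origins_local @ histone_frame.rotation.T + histone_frame.origin
    rotations = np.einsum("ij,njk->nik", histone_frame.rotation, rot_local)
    return origins, rotations


def build_nucleosome(histone_frame: Frame | None = None, config: FiberConfig | None = None,
                     bp_offset: int = 0, nucleosome_id: int = 0) -> tuple[Frame, list[NucleotidePair]]:
    """One nucleosome: the histone placement plus the wrapped nucleotide
    pairs (1.65 left-handed turns at the wrap radius, one pair per 0.34 nm of
    arc).  ``bp_offset`` sets the global index (and hence twist phase) of the
    first wrapped pair."""
    cfg = config or FiberConfig()
    frame = histone_frame or Frame()
    n = cfg.wrapped_bp
    s = np.arange(n) * cfg.rise_nm
    origins, rotations = _wrap_arrays(cfg, frame, bp_offset, s)
    pairs = [
        NucleotidePair(bp_index=bp_offset + i, frame=Frame(rotations[i], origins[i]), nucleosome_id=nucleosome_id)
        for i in range(n)
    ]
    return frame, pairs


def _bezier(p0, p1, p2, p3, t):
    t = np.asarray(t, dtype=float)[:, None]
    mt = 1.0 - t
    return mt**3 * p0 + 3 * mt**2 * t * p1 + 3 * mt * t**2 * p2 + t**3 * p3


def _bezier_tangent(p0, p1, p2, p3, t):
    t = np.asarray(t, dtype=float)[:, None]
    mt = 1.0 - t
    return 3 * mt**2 * (p1 - p0) + 6 * mt * t * (p2 - p1) + 3 * t**2 * (p3 - p2)


def build_linker(end_a: Frame, end_b: Frame, n_bp: int, config: FiberConfig | None = None,
                 bp_offset: int = 0) -> list[NucleotidePair]:
    """Linker DNA along a cubic Bezier curve joining ``end_a`` to ``end_b``
    with continuous position and tangent.

    ``n_bp`` frames are placed at equal arc-length spacing, the first at
    ``end_a`` and the last at ``end_b``.  Frames are transported along the
    curve (rotation-minimizing), twisted 36 degrees per bp, and the residual
    roll misalignment against ``end_b`` is distributed linearly so the final
    frame matches ``end_b`` exactly.  If the implied spacing deviates from
    the 0.34 nm rise by more than the configured tolerance the linker is
    geometrically infeasible.
    """
    if n_bp < 0:
        raise InvalidArgumentError(f"n_bp must be >= 0, got {n_bp}")
    if n_bp == 0:
        return []
    cfg = config or FiberConfig()
    if n_bp == 1:
        return [NucleotidePair(bp_index=bp_offset, frame=end_a, nucleosome_id=-1)]

    p0, p3 = end_a.origin, end_b.origin
    chord = float(np.linalg.norm(p3 - p0))
    handle = chord / 3.0
    p1 = p0 + handle * end_a.z_axis
    p2 = p3 - handle * end_b.z_axis

    # dense sampling for arc length and frame transport
    m = max(40 * n_bp, 400)
    t_fine = np.linspace(0.0, 1.0, m)
    pts = _bezier(p0, p1, p2, p3, t_fine)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s_fine = np.concatenate([[0.0], np.cumsum(seg)])
    arc = s_fine[-1]

    spacing = arc / (n_bp - 1)
    if abs(spacing - cfg.rise_nm) > cfg.linker_spacing_tol_nm:
        raise GeometryInfeasibleError(
            f"linker arc length {arc:.3f} nm over {n_bp} bp gives spacing "
            f"{spacing:.3f} nm, incompatible with the {cfg.rise_nm} nm rise "
            f"(tolerance {cfg.linker_spacing_tol_nm} nm)"
        )

    tangents_fine = _bezier_tangent(p0, p1, p2, p3, t_fine)
    tangents_fine /= np.linalg.norm(tangents_fine, axis=1, keepdims=True)

    # rotation-minimizing transport of end_a's x axis along the fine samples
    e1_fine = np.empty_like(tangents_fine)
    e1 = end_a.x_axis - np.dot(end_a.x_axis, tangents_fine[0]) * tangents_fine[0]
    e1 /= np.linalg.norm(e1)
    e1_fine[0] = e1
    for i in range(1, m):
        e1 = e1 - np.dot(e1, tangents_fine[i]) * tangents_fine[i]
        e1 /= np.linalg.norm(e1)
        e1_fine[i] = e1

    # residual roll so that (transport + twist schedule) ends on end_b
    total_twist = (n_bp - 1) * cfg.twist_rad
    e3_end = tangents_fine[-1]
    e1_end = _rotate_about(e1_fine[-1], e3_end, total_twist)
    e2_end = np.cross(e3_end, e1_end)
    delta = math.atan2(np.dot(end_b.x_axis, e2_end), np.dot(end_b.x_axis, e1_end))

    s_targets = np.arange(n_bp) * spacing
    t_targets = np.interp(s_targets, s_fine, t_fine)
    pos = _bezier(p0, p1, p2, p3, t_targets)
    tan = _bezier_tangent(p0, p1, p2, p3, t_targets)
    tan /= np.linalg.norm(tan, axis=1, keepdims=True)
    idx = np.searchsorted(t_fine, t_targets).clip(0, m - 1)
    pairs = []
    for k in range(n_bp):
        e3 = tan[k]
        e1 = e1_fine[idx[k]] - np.dot(e1_fine[idx[k]], e3) * e3
        e1 /= np.linalg.norm(e1)
        roll = k * cfg.twist_rad + delta * (k / (n_bp - 1))
        e1r = _rotate_about(e1, e3, roll)
        e2r = np.cross(e3, e1r)
        frame = Frame(np.stack([e1r, e2r, e3], axis=1), pos[k])
        if k == 0:
            frame = end_a
        elif k == n_bp - 1:
            frame = end_b
        pairs.append(NucleotidePair(bp_index=bp_offset + k, frame=frame, nucleosome_id=-1))
    return pairs


def _rotate_about(v: np.ndarray, axis: np.ndarray, angle: float) -> np.ndarray:
    c, s = math.cos(angle), math.sin(angle)
    return v * c + np.cross(axis, v) * s + axis * np.dot(axis, v) * (1.0 - c)


# ---------------------------------------------------------------------------
# fiber assembly
# ---------------------------------------------------------------------------

class FiberGeometry:
    """Placed fiber with a spatial index answering point->volume queries.

    Internally all nucleotide-pair frames are stored as arrays (origins,
    rotation matrices, nucleosome ids ordered by global bp index); a k-d tree
    over the frame origins supplies containment candidates which are then
    tested analytically in their local frames.
    """

    def __init__(self, config: FiberConfig, origins: np.ndarray, rotations: np.ndarray,
                 nucleosome_ids: np.ndarray, histone_origins: np.ndarray, histone_rotations: np.ndarray):
        self.config = config
        self.origins = origins
        self.rotations = rotations
        self.nucleosome_ids = nucleosome_ids
        self.histone_origins = histone_origins
        self.histone_rotations = histone_rotations
        self._tree = cKDTree(origins)
        self._query_radius = config.bp_bound_radius_nm * (1.0 + 1e-9) + 1e-9

    # -- bookkeeping -----------------------------------------------------
    @property
    def total_bp(self) -> int:
        return len(self.origins)

    @property
    def nucleosome_count(self) -> int:
        return len(self.histone_origins)

    def pair(self, bp_index: int) -> NucleotidePair:
        return NucleotidePair(
            bp_index=bp_index,
            frame=Frame(self.rotations[bp_index], self.origins[bp_index]),
            nucleosome_id=int(self.nucleosome_ids[bp_index]),
        )

    def pairs(self) -> Iterator[NucleotidePair]:
        for i in range(self.total_bp):
            yield self.pair(i)

    def backbone_centroid(self, bp_index: int, strand: int) -> np.ndarray:
        """Lab-frame centroid of a backbone volume (annular 90 deg sector)."""
        cfg = self.config
        r_in, r_out = cfg.base_diameter_nm / 2.0, cfg.backbone_radius_nm
        alpha = math.pi / 4.0
        rho = (2.0 / 3.0) * (r_out**3 - r_in**3) / (r_out**2 - r_in**2) * math.sin(alpha) / alpha
        sign = 1.0 if strand == 0 else -1.0
        return self.pair(bp_index).frame.apply(np.array([sign * rho, 0.0, 0.0]))

    def base_centroid(self, bp_index: int, strand: int) -> np.ndarray:
        cfg = self.config
        rho = 4.0 * (cfg.base_diameter_nm / 2.0) / (3.0 * math.pi)
        sign = 1.0 if strand == 0 else -1.0
        return self.pair(bp_index).frame.apply(np.array([sign * rho, 0.0, 0.0]))

    # -- queries ---------------------------------------------------------
    def locate_many(self, points: np.ndarray, skip_histone: bool = False) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Vectorized point->volume classification.

        Returns ``(kind, strand, bp_index, nucleosome_id)`` int arrays; the
        sentinel -1 means "not applicable".  Overlap resolution priority is
        backbone > base > histone > water, with ties broken on the lowest
        (bp_index, strand) — deterministic by construction.  ``skip_histone``
        reports histone interiors as water, a cheap shortcut for callers
        that only consume DNA hits.
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        n = len(pts)
        kind = np.full(n, KIND_WATER, dtype=np.int16)
        strand = np.full(n, -1, dtype=np.int16)
        bp_index = np.full(n, -1, dtype=np.int64)
        nuc_id = np.full(n, -1, dtype=np.int64)
        if n == 0:
            return kind, strand, bp_index, nuc_id

        cfg = self.config
        half = cfg.rise_nm / 2.0
        base_r = cfg.base_diameter_nm / 2.0
        bb_r = cfg.backbone_radius_nm

        pt_tree = cKDTree(pts)
        coo = pt_tree.sparse_distance_matrix(self._tree, self._query_radius, output_type="coo_matrix")
        if coo.nnz:
            ev, bp = coo.row, coo.col
            diff = pts[ev] - self.origins[bp]
            loc = np.einsum("mi,mij->mj", diff, self.rotations[bp])
            x, y, z = loc[:, 0], loc[:, 1], loc[:, 2]
            r = np.hypot(x, y)
            in_z = np.abs(z) <= half
            is_base = in_z & (r <= base_r)
            is_backbone = in_z & (r > base_r) & (r <= bb_r) & (np.abs(x) >= np.abs(y))
            cand_strand = (x < 0).astype(np.int16)

            hit = is_base | is_backbone
            if np.any(hit):
                ev_h = ev[hit]
                bp_h = bp[hit]
                kind_h = np.where(is_backbone[hit], KIND_BACKBONE, KIND_BASE).astype(np.int16)
                strand_h = cand_strand[hit]
                # priority: backbone before base, then lowest bp, then strand
                order = np.lexsort((strand_h, bp_h, kind_h, ev_h))
                ev_s = ev_h[order]
                first = np.ones(len(ev_s), dtype=bool)
                first[1:] = ev_s[1:] != ev_s[:-1]
                sel = order[first]
                kind[ev_h[sel]] = kind_h[sel]
                strand[ev_h[sel]] = strand_h[sel]
                bp_index[ev_h[sel]] = bp_h[sel]
                nuc_id[ev_h[sel]] = self.nucleosome_ids[bp_h[sel]]

        # histone test for points not inside DNA volumes
        rest = (kind == KIND_WATER) if not skip_histone else np.zeros(n, dtype=bool)
        if np.any(rest):
            p = pts[rest]
            diff = p[:, None, :] - self.histone_origins[None, :, :]
            loc = np.einsum("nki,kij->nkj", diff, self.histone_rotations)
            r2 = loc[:, :, 0] ** 2 + loc[:, :, 1] ** 2
            inside = (r2 <= cfg.histone_radius_nm**2) & (np.abs(loc[:, :, 2]) <= cfg.histone_height_nm / 2.0)
            any_in = inside.any(axis=1)
            which = inside.argmax(axis=1)
            idx = np.flatnonzero(rest)[any_in]
            kind[idx] = KIND_HISTONE
            nuc_id[idx] = which[any_in]

        # strand/nucleosome sentinels for water
        return kind, strand, bp_index, nuc_id

    def locate(self, point: Sequence[float]) -> VolumeHit:
        kind, strand, bp, nuc = self.locate_many(np.asarray(point, dtype=float)[None, :])
        k = KIND_NAMES[int(kind[0])]
        if k in ("backbone", "base"):
            return VolumeHit(kind=k, strand=int(strand[0]), bp_index=int(bp[0]), nucleosome_id=int(nuc[0]) if nuc[0] >= 0 else None)
        if k == "histone":
            return VolumeHit(kind=k, nucleosome_id=int(nuc[0]))
        return VolumeHit(kind="water")

    # -- export ----------------------------------------------------------
    def to_json(self, path: str) -> None:
        """Write a self-describing JSON snapshot (config, histone frames and
        per-bp frames as origin + rotation rows) for inspection tools."""
        payload = {
            "config": asdict(self.config),
            "bp": {
                "origins_nm": self.origins.round(6).tolist(),
                "rotations": self.rotations.round(9).tolist(),
                "nucleosome_ids": self.nucleosome_ids.tolist(),
            },
            "histones": {
                "origins_nm": self.histone_origins.round(6).tolist(),
                "rotations": self.histone_rotations.round(9).tolist(),
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    def write_centroids_xyz(self, path: str) -> None:
        """Point-cloud export (xyz text) of backbone/base centroids."""
        with open(path, "w") as fh:
            fh.write(f"{4 * self.total_bp}\nchromofiber volume centroids (nm)\n")
            for i in range(self.total_bp):
                for s in (0, 1):
                    bx, by, bz = self.backbone_centroid(i, s)
                    fh.write(f"P {bx:.4f} {by:.4f} {bz:.4f}\n")
                    cx, cy, cz = self.base_centroid(i, s)
                    fh.write(f"B {cx:.4f} {cy:.4f} {cz:.4f}\n")


def build_fiber(config: FiberConfig | None = None) -> FiberGeometry:
    """Assemble the solenoid fiber.

    Nucleosome centers sit on a helix of 6 per turn around the fiber axis
    with their cylinder axes tangent to the helix; wrapped DNA and Bezier
    linkers are concatenated so the global bp index increases monotonically
    along the DNA path.  Raises :class:`GeometryInfeasibleError` if any
    nucleotide volume escapes the 37 x 161 nm envelope.
    """
    cfg = config or FiberConfig()
    n_nuc = cfg.nucleosomes
    n_wrap = cfg.wrapped_bp
    n_link = cfg.linker_bp

    d_phi = 2.0 * math.pi / cfg.nucleosomes_per_turn
    span = cfg.fiber_length_nm - 2.0 * cfg.solenoid_z_margin_nm
    if span <= 0:
        raise GeometryInfeasibleError("fiber length too small for the solenoid margins")
    dz = span / (n_nuc - 1)

    def nucleosome_frame(j: int) -> Frame:
        phi = j * d_phi
        center = np.array([
            cfg.solenoid_radius_nm * math.cos(phi),
            cfg.solenoid_radius_nm * math.sin(phi),
            -span / 2.0 + j * dz,
        ])
        tangent = np.array([
            -cfg.solenoid_radius_nm * math.sin(phi) * d_phi,
            cfg.solenoid_radius_nm * math.cos(phi) * d_phi,
            dz,
        ])
        ez = tangent / np.linalg.norm(tangent)
        radial = np.array([math.cos(phi), math.sin(phi), 0.0])
        ex = radial - np.dot(radial, ez) * ez
        ex /= np.linalg.norm(ex)
        ey = np.cross(ez, ex)
        return Frame(np.stack([ex, ey, ez], axis=1), center)

    unit = n_wrap + n_link
    total = n_nuc * unit
    origins = np.empty((total, 3))
    rotations = np.empty((total, 3, 3))
    nucleosome_ids = np.full(total, -1, dtype=np.int64)
    histone_origins = np.empty((n_nuc, 3))
    histone_rotations = np.empty((n_nuc, 3, 3))

    frames = [nucleosome_frame(j) for j in range(n_nuc + 1)]  # +1 virtual for trailing linker

    def wrap_end_frames(j: int, base_idx: int) -> tuple[Frame, Frame]:
        """(entry, exit) extension frames one rise before/after the wrap."""
        s_entry = np.array([-cfg.rise_nm])
        s_exit = np.array([n_wrap * cfg.rise_nm])
        o_en, r_en = _wrap_arrays(cfg, frames[j], base_idx - 1, s_entry)
        o_ex, r_ex = _wrap_arrays(cfg, frames[j], base_idx + n_wrap, s_exit)
        return Frame(r_en[0], o_en[0]), Frame(r_ex[0], o_ex[0])

    for j in range(n_nuc):
        base_idx = j * unit
        histone_origins[j] = frames[j].origin
        histone_rotations[j] = frames[j].rotation
        s = np.arange(n_wrap) * cfg.rise_nm
        o, r = _wrap_arrays(cfg, frames[j], base_idx, s)
        origins[base_idx : base_idx + n_wrap] = o
        rotations[base_idx : base_idx + n_wrap] = r
        nucleosome_ids[base_idx : base_idx + n_wrap] = j

        # linker from this nucleosome's exit to the next entry (the last
        # linker continues toward the solenoid's virtual next nucleosome)
        _, exit_frame = wrap_end_frames(j, base_idx)
        next_base = (j + 1) * unit
        entry_frame, _ = wrap_end_frames(j + 1, next_base)
        link = build_linker(exit_frame, entry_frame, n_link, cfg, bp_offset=base_idx + n_wrap)
        for k, pair in enumerate(link):
            origins[base_idx + n_wrap + k] = pair.frame.origin
            rotations[base_idx + n_wrap + k] = pair.frame.rotation

    geom = FiberGeometry(cfg, origins, rotations, nucleosome_ids, histone_origins, histone_rotations)
    _check_envelope(geom)
    return geom


def _check_envelope(geom: FiberGeometry) -> None:
    cfg = geom.config
    bound = cfg.bp_bound_radius_nm
    radial = np.hypot(geom.origins[:, 0], geom.origins[:, 1])
    worst_r = float((radial + bound).max())
    worst_z = float((np.abs(geom.origins[:, 2]) + bound).max())
    if worst_r > cfg.fiber_radius_nm or worst_z > cfg.fiber_length_nm / 2.0:
        raise GeometryInfeasibleError(
            f"nucleotide volumes escape the fiber envelope: max radial extent "
            f"{worst_r:.2f} nm (limit {cfg.fiber_radius_nm:.2f}), max |z| extent "
            f"{worst_z:.2f} nm (limit {cfg.fiber_length_nm / 2.0:.2f})"
        )


def locate(point: Sequence[float], geometry: FiberGeometry) -> VolumeHit:
    """Functional wrapper around :meth:`FiberGeometry.locate`."""
    pt = np.asarray(point, dtype=float)
    if not np.all(np.isfinite(pt)):
        raise InvalidArgumentError("point coordinates must be finite")
    return geometry.locate(pt)


def geometry_summary(geometry: FiberGeometry, nucleus: NucleusEnvelope | None = None) -> dict:
    """Headline numbers of a built fiber.

    ``density_per_11nm`` uses the nominal fiber length; ``bp_density_per_nm3``
    uses the fiber envelope volume (and the nucleus envelope when given).
    """
    cfg = geometry.config
    fiber_volume = math.pi * cfg.fiber_radius_nm**2 * cfg.fiber_length_nm
    out = {
        "nucleosome_count": geometry.nucleosome_count,
        "total_bp": geometry.total_bp,
        "total_kbp": round(geometry.total_bp / 1000.0, 1),
        "density_per_11nm": round(geometry.nucleosome_count * 11.0 / cfg.fiber_length_nm, 1),
        "bp_density_per_nm3": geometry.total_bp / fiber_volume,
    }
    if nucleus is not None:
        out["nucleus_bp_density_per_nm3"] = nucleus.bp_density_per_nm3
    return out
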