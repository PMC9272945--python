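"""Acquisition geometries and thick-slice sampling operators.

A super-resolution acquisition observes a high-resolution image plane
through ``N_R`` stacks of thick slices rotated about the phase-encode
axis. Each low-resolution voxel has an in-plane footprint of
``alpha x 1`` high-resolution voxel units (``alpha`` = aspect factor,
the through-plane/in-plane voxel-size ratio) with an idealized box
slice profile. The sampling is linear, ``y_k = A_k x``, and the joint
system stacks all rotations.

Weight convention: ``A(i, j)`` is the area of overlap (in high-res
voxel units) between low-res voxel ``i``'s footprint and high-res
voxel ``j``. Rows of interior low-res voxels therefore sum to
``alpha`` (signal grows with voxel volume) and, per rotation, the
column of every covered high-res voxel sums to 1 (its signal is
deposited exactly once per rotation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

__all__ = [
    "AcquisitionGeometry",
    "SamplingOperator",
    "min_rotations",
    "default_angles",
    "build_sampling_matrix",
    "build_joint_system",
]

_TOL = 1e-9


def min_rotations(aspect_factor: float, override: int | None = None) -> int:
    """Minimum number of rotated stacks for an isotropic reconstruction.

    The lower bound is ``ceil(pi/2 * alpha)``: each rotation contributes
    independent in-plane samples, and ``pi/2 * alpha`` rotations are
    needed for the rotated thick-slice profiles to tile frequency space
    isotropically.

    Parameters
    ----------
    aspect_factor : float
        Ratio ``alpha >= 1`` of through-plane to in-plane voxel size.
    override : int, optional
        Explicit rotation count (>= 1). Published protocols occasionally
        use fewer rotations than the bound; the override reproduces them.
    """
    if aspect_factor < 1:
        raise ValueError(f"aspect_factor must be >= 1, got {aspect_factor}")
    if override is not None:
        if override < 1:
            raise ValueError(f"override must be a positive integer, got {override}")
        return int(override)
    return math.ceil(math.pi / 2 * aspect_factor - _TOL)


def default_angles(n_rotations: int) -> np.ndarray:
    """Uniformly spaced rotation angles ``k * pi / N_R``, starting at 0.

    Angles live in ``[0, pi)``: a rotation by ``theta + pi`` samples the
    same slice stack (magnitude images are insensitive to the sign of
    the slice normal), so the half-circle carries all the information.
    """
    if n_rotations < 1:
        raise ValueError(f"n_rotations must be >= 1, got {n_rotations}")
    return np.arange(n_rotations) * (np.pi / n_rotations)


@dataclass(frozen=True)
class AcquisitionGeometry:
    """One super-resolution protocol: aspect factor, rotations, grid, timing.

    Attributes
    ----------
    aspect_factor : float
        ``alpha >= 1``, the long/short voxel axis ratio of the
        low-resolution acquisition. Also the voxel-volume (and hence
        SNR) gain over the isotropic target.
    rotation_angles : tuple of float
        Slice-stack rotation angles in radians, distinct modulo pi,
        within ``[0, pi)``.
    grid_shape : (int, int)
        High-resolution in-plane voxel counts (rows, cols).
    voxel_size_mm : float
        Isotropic in-plane voxel size of the high-resolution grid.
    tr_seconds : float or None
        Repetition time of this protocol, if timing matters.
    """

    aspect_factor: float
    rotation_angles: tuple[float, ...]
    grid_shape: tuple[int, int]
    voxel_size_mm: float = 1.6
    tr_seconds: float | None = None

    def __post_init__(self) -> None:
        if self.aspect_factor < 1:
            raise ValueError(f"aspect_factor must be >= 1, got {self.aspect_factor}")
        if len(self.rotation_angles) < 1:
            raise ValueError("at least one rotation angle is required")
        ang = np.mod(np.asarray(self.rotation_angles, dtype=float), np.pi)
        if np.any((np.asarray(self.rotation_angles) < -_TOL)
                  | (np.asarray(self.rotation_angles) >= np.pi + _TOL)):
            raise ValueError("rotation angles must lie in [0, pi)")
        if len(np.unique(np.round(ang, 12))) != len(ang):
            raise ValueError("rotation angles must be distinct modulo pi")
        nr, nc = self.grid_shape
        if nr < 1 or nc < 1:
            raise ValueError(f"empty high-resolution grid {self.grid_shape}")
        object.__setattr__(self, "rotation_angles", tuple(float(a) for a in self.rotation_angles))
        object.__setattr__(self, "grid_shape", (int(nr), int(nc)))

    @property
    def n_rotations(self) -> int:
        return len(self.rotation_angles)

    @classmethod
    def protocol(
        cls,
        aspect_factor: float,
        grid_size: int | tuple[int, int],
        n_rotations: int | None = None,
        angles=None,
        voxel_size_mm: float = 1.6,
        tr_seconds: float | None = None,
    ) -> "AcquisitionGeometry":
        """Build a geometry with the default policy.

        The rotation count defaults to the ``ceil(pi/2 * alpha)`` bound
        and the angle schedule to uniform spacing over ``[0, pi)``;
        either can be overridden.
        """
        if angles is None:
            nr = min_rotations(aspect_factor, override=n_rotations)
            angles = default_angles(nr)
        if isinstance(grid_size, int):
            grid_size = (grid_size, grid_size)
        return cls(
            aspect_factor=float(aspect_factor),
            rotation_angles=tuple(float(a) for a in np.asarray(angles).ravel()),
            grid_shape=tuple(grid_size),
            voxel_size_mm=voxel_size_mm,
            tr_seconds=tr_seconds,
        )

    def lowres_shape(self, angle: float) -> tuple[int, int]:
        """Low-resolution image shape ``(m_u, m_v)`` for one rotation.

        ``m_u`` thick slices along the rotated through-plane axis and
        ``m_v`` in-plane voxels, the tightest whole-voxel cover of the
        rotated high-resolution field of view.
        """
        nr, nc = self.grid_shape
        w_u = (nr / 2) * abs(np.cos(angle)) + (nc / 2) * abs(np.sin(angle))
        w_v = (nc / 2) * abs(np.cos(angle)) + (nr / 2) * abs(np.sin(angle))
        m_u = math.ceil(2 * w_u / self.aspect_factor - _TOL)
        m_v = math.ceil(2 * w_v - _TOL)
        return m_u, m_v

    def interior_mask(self, border: int | None = None) -> np.ndarray:
        """Boolean mask of high-resolution voxels unaffected by FOV edges.

        Partial sampling at the field-of-view edge inflates the variance
        of edge voxels; quantitative metrics are restricted to this
        mask. The excluded border defaults to ``ceil(alpha)`` voxels,
        the through-plane footprint extent.
        """
        if border is None:
            border = math.ceil(self.aspect_factor) if self.aspect_factor > 1 else 0
        nr, nc = self.grid_shape
        if 2 * border >= min(nr, nc):
            raise ValueError(f"border {border} leaves no interior in grid {self.grid_shape}")
        mask = np.zeros((nr, nc), dtype=bool)
        mask[border:nr - border, border:nc - border] = True
        return mask

    def to_dict(self) -> dict:
        """JSON-serializable sidecar description of this protocol."""
        return {
            "alpha": self.aspect_factor,
            "angles_rad": list(self.rotation_angles),
            "grid_shape": list(self.grid_shape),
            "voxel_size_mm": self.voxel_size_mm,
            "tr_seconds": self.tr_seconds,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionGeometry":
        return cls(
            aspect_factor=d["alpha"],
            rotation_angles=tuple(d["angles_rad"]),
            grid_shape=tuple(d["grid_shape"]),
            voxel_size_mm=d.get("voxel_size_mm", 1.6),
            tr_seconds=d.get("tr_seconds"),
        )


@dataclass
class SamplingOperator:
    """Sparse linear map from a high-resolution plane to thick-slice stacks.

    Attributes
    ----------
    matrix : scipy.sparse.csr_matrix, shape (m, n_voxels)
        Stacked per-rotation sampling weights.
    geometry : AcquisitionGeometry
    angles : tuple of float
        Rotations included, in stacking order.
    blocks : list of (offset, (m_u, m_v))
        Row offset and image shape of each rotation's block.
    interior_rows : ndarray of bool, shape (m,)
        Low-resolution voxels whose footprint lies fully inside the
        high-resolution field of view (rows summing to alpha).
    """

    matrix: sp.csr_matrix
    geometry: AcquisitionGeometry
    angles: tuple[float, ...]
    blocks: list[tuple[int, tuple[int, int]]]
    interior_rows: np.ndarray = field(repr=False)
    _gram: sp.csc_matrix | None = field(default=None, init=False, repr=False)
    _gram_eigh: tuple | None = field(default=None, init=False, repr=False)

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape

    @property
    def gram(self) -> sp.csc_matrix:
        """Cached normal matrix ``A^T A``."""
        if self._gram is None:
            self._gram = (self.matrix.T @ self.matrix).tocsc()
        return self._gram

    def gram_eigh(self) -> tuple[np.ndarray, np.ndarray]:
        """Cached eigendecomposition of ``A^T A`` (dense).

        Shared across regularization weights: the normal matrix of every
        lambda' is diagonal in this basis, so reconstruction sweeps and
        noise-propagation queries reduce to cheap matrix-vector work.
        Practical for the plane sizes used here (up to ~128^2 voxels).
        """
        if self._gram_eigh is None:
            eigvals, eigvecs = np.linalg.eigh(self.gram.toarray())
            self._gram_eigh = (np.maximum(eigvals, 0.0), eigvecs)
        return self._gram_eigh

    @property
    def n_rotations(self) -> int:
        return len(self.angles)

    def apply(self, image: np.ndarray) -> np.ndarray:
        """Sample a high-resolution plane; returns the stacked y vector."""
        image = np.asarray(image, dtype=float)
        if image.shape != self.geometry.grid_shape:
            raise ValueError(
                f"image shape {image.shape} does not match grid {self.geometry.grid_shape}"
            )
        return self.matrix @ image.ravel()

    def split(self, y: np.ndarray) -> list[np.ndarray]:
        """Split a stacked y vector into per-rotation 2D images."""
        y = np.asarray(y)
        if y.shape[-1] != self.matrix.shape[0]:
            raise ValueError(
                f"vector length {y.shape[-1]} does not match operator rows {self.matrix.shape[0]}"
            )
        out = []
        for offset, (m_u, m_v) in self.blocks:
            out.append(y[..., offset:offset + m_u * m_v].reshape(*y.shape[:-1], m_u, m_v))
        return out

    def stack(self, images) -> np.ndarray:
        """Inverse of :meth:`split`: concatenate per-rotation images."""
        if len(images) != len(self.blocks):
            raise ValueError(f"expected {len(self.blocks)} stacks, got {len(images)}")
        parts = []
        for img, (_, shape) in zip(images, self.blocks):
            img = np.asarray(img, dtype=float)
            if img.shape[-2:] != shape:
                raise ValueError(f"stack shape {img.shape[-2:]} does not match block {shape}")
            parts.append(img.reshape(*img.shape[:-2], shape[0] * shape[1]))
        return np.concatenate(parts, axis=-1)


def _clip_half_plane(verts, count, axis, bound, keep_ge):
    """One Sutherland-Hodgman pass against an axis-aligned half-plane.

    ``verts``: (N, V, 2) padded vertex buffers, ``count``: (N,) valid
    vertex counts. Vectorized over all N polygons at once.
    """
    n_poly, n_v, _ = verts.shape
    idx = np.broadcast_to(np.arange(n_v), (n_poly, n_v))
    valid = idx < count[:, None]
    prev_idx = np.where(idx == 0, np.maximum(count[:, None] - 1, 0), idx - 1)
    prev = np.take_along_axis(verts, prev_idx[:, :, None], axis=1)

    coord = verts[..., axis]
    pcoord = prev[..., axis]
    if keep_ge:
        cur_in, prev_in = coord >= bound, pcoord >= bound
    else:
        cur_in, prev_in = coord <= bound, pcoord <= bound
    cross = (cur_in != prev_in) & valid
    emit_cur = cur_in & valid

    denom = coord - pcoord
    t = (bound - pcoord) / np.where(denom == 0.0, 1.0, denom)
    ipt = prev + t[..., None] * (verts - prev)
    ipt[..., axis] = bound

    # per input slot the pass emits [crossing point, current vertex]
    flags = np.stack([cross, emit_cur], axis=2).reshape(n_poly, 2 * n_v)
    pts = np.stack([ipt, verts], axis=2).reshape(n_poly, 2 * n_v, 2)
    new_count = flags.sum(axis=1)
    v_out = max(int(new_count.max()), 1)
    out = np.zeros((n_poly, v_out, 2))
    pos = np.cumsum(flags, axis=1) - 1
    rows, slots = np.nonzero(flags)
    out[rows, pos[rows, slots]] = pts[rows, slots]
    return out, new_count


def _polygon_box_areas(poly, x0, y0):
    """Exact area of each rectangle ``poly[i]`` clipped to the unit box
    ``[x0[i], x0[i]+1] x [y0[i], y0[i]+1]``."""
    verts = poly
    count = np.full(poly.shape[0], poly.shape[1], dtype=np.int64)
    for axis, bound, keep_ge in ((0, x0, True), (0, x0 + 1, False),
                                 (1, y0, True), (1, y0 + 1, False)):
        verts, count = _clip_half_plane(verts, count, axis, bound[:, None], keep_ge)
    n_poly, n_v, _ = verts.shape
    idx = np.broadcast_to(np.arange(n_v), (n_poly, n_v))
    valid = idx < count[:, None]
    nxt_idx = np.minimum(np.where(idx == count[:, None] - 1, 0, idx + 1), n_v - 1)
    nxt = np.take_along_axis(verts, nxt_idx[:, :, None], axis=1)
    contrib = (verts[..., 0] * nxt[..., 1] - nxt[..., 0] * verts[..., 1])
    area = 0.5 * np.abs(np.where(valid, contrib, 0.0).sum(axis=1))
    area[count < 3] = 0.0
    return area


def _rotation_entries_exact(geometry: AcquisitionGeometry, angle: float):
    """Sparse entries for one rotation with exact footprint overlap areas.

    Every (low-res voxel, high-res voxel) weight is the exact area of
    the rotated ``alpha x 1`` footprint clipped to the axis-aligned
    unit voxel, computed by vectorized polygon clipping. Interior rows
    then sum to alpha and covered columns to 1 to machine precision.
    """
    nr, nc = geometry.grid_shape
    alpha = geometry.aspect_factor
    m_u, m_v = geometry.lowres_shape(angle)
    sin_t, cos_t = np.sin(angle), np.cos(angle)

    # high-res voxel lower corners and centers in centered coordinates
    rr, cc = np.meshgrid(np.arange(nr), np.arange(nc), indexing="ij")
    x0 = (cc - nc / 2).ravel()
    y0 = (rr - nr / 2).ravel()
    xc, yc = x0 + 0.5, y0 + 0.5
    t_u = -xc * sin_t + yc * cos_t
    t_v = xc * cos_t + yc * sin_t
    p_c = np.floor((t_u + m_u * alpha / 2) / alpha).astype(np.int64)
    q_c = np.floor(t_v + m_v / 2).astype(np.int64)

    rows_all, cols_all, data_all = [], [], []
    j_all = np.arange(nr * nc)
    for dp in (-1, 0, 1):
        for dq in (-1, 0, 1):
            p = p_c + dp
            q = q_c + dq
            keep = (p >= 0) & (p < m_u) & (q >= 0) & (q < m_v)
            if not keep.any():
                continue
            pk, qk, jk = p[keep], q[keep], j_all[keep]
            # footprint rectangle corners in the rotated frame, then xy
            u_lo = pk * alpha - m_u * alpha / 2
            v_lo = qk - m_v / 2
            corners_u = np.stack([u_lo, u_lo + alpha, u_lo + alpha, u_lo], axis=1)
            corners_v = np.stack([v_lo, v_lo, v_lo + 1.0, v_lo + 1.0], axis=1)
            poly = np.stack(
                [-corners_u * sin_t + corners_v * cos_t,
                 corners_u * cos_t + corners_v * sin_t], axis=2)
            areas = _polygon_box_areas(poly, x0[keep], y0[keep])
            nz = areas > 1e-12
            rows_all.append((pk * m_v + qk)[nz])
            cols_all.append(jk[nz])
            data_all.append(areas[nz])
    mat = sp.coo_matrix(
        (np.concatenate(data_all), (np.concatenate(rows_all), np.concatenate(cols_all))),
        shape=(m_u * m_v, nr * nc)).tocsr()
    return mat, (m_u, m_v)


def _rotation_entries_subcell(geometry: AcquisitionGeometry, angle: float, subcells: int):
    """Sparse entries for one rotation via subcell rasterization.

    Each high-resolution voxel is subdivided into ``subcells**2`` equal
    subcells; a subcell's full area (``1/subcells**2``) is deposited
    into the low-resolution voxel containing its center, approximating
    the overlap area.
    """
    nr, nc = geometry.grid_shape
    alpha = geometry.aspect_factor
    s = subcells
    m_u, m_v = geometry.lowres_shape(angle)

    # subcell center coordinates relative to the grid center
    xs = (np.arange(nc * s) + 0.5) / s - nc / 2  # along columns
    ys = (np.arange(nr * s) + 0.5) / s - nr / 2  # along rows
    X, Y = np.meshgrid(xs, ys)

    # through-plane axis u = (-sin, cos) so that angle 0 stacks slices
    # along rows and A is exactly the identity when alpha = 1
    sin_t, cos_t = np.sin(angle), np.cos(angle)
    t_u = -X * sin_t + Y * cos_t
    t_v = X * cos_t + Y * sin_t

    p = np.floor((t_u + m_u * alpha / 2) / alpha).astype(np.int64)
    q = np.floor(t_v + m_v / 2).astype(np.int64)
    np.clip(p, 0, m_u - 1, out=p)
    np.clip(q, 0, m_v - 1, out=q)

    row_voxel = np.arange(nr * s) // s
    col_voxel = np.arange(nc * s) // s
    j = (row_voxel[:, None] * nc + col_voxel[None, :]).astype(np.int64)

    rows = (p * m_v + q).ravel()
    cols = j.ravel()
    data = np.full(rows.shape, 1.0 / (s * s))
    mat = sp.coo_matrix((data, (rows, cols)), shape=(m_u * m_v, nr * nc)).tocsr()
    mat.sum_duplicates()

    return mat, (m_u, m_v)


def _interior_row_mask(geometry: AcquisitionGeometry, angle: float) -> np.ndarray:
    """Low-res voxels whose footprint lies fully inside the high-res FOV."""
    nr, nc = geometry.grid_shape
    alpha = geometry.aspect_factor
    m_u, m_v = geometry.lowres_shape(angle)
    sin_t, cos_t = np.sin(angle), np.cos(angle)
    pp, qq = np.meshgrid(np.arange(m_u), np.arange(m_v), indexing="ij")
    cu = (pp + 0.5) * alpha - m_u * alpha / 2
    cv = (qq + 0.5) - m_v / 2
    interior = np.ones((m_u, m_v), dtype=bool)
    for du in (-alpha / 2, alpha / 2):
        for dv in (-0.5, 0.5):
            x = -(cu + du) * sin_t + (cv + dv) * cos_t
            y = (cu + du) * cos_t + (cv + dv) * sin_t
            interior &= (np.abs(x) <= nc / 2 + 1e-6) & (np.abs(y) <= nr / 2 + 1e-6)
    return interior.ravel()


def _rotation_entries(geometry, angle, method, subcells):
    if method == "exact":
        mat, shape = _rotation_entries_exact(geometry, angle)
    elif method == "subcell":
        if subcells < 1:
            raise ValueError("subcells must be >= 1")
        mat, shape = _rotation_entries_subcell(geometry, angle, subcells)
    else:
        raise ValueError(f"unknown overlap method {method!r}")
    return mat, shape, _interior_row_mask(geometry, angle)


def build_sampling_matrix(
    geometry: AcquisitionGeometry,
    angle: float,
    method: str = "exact",
    subcells: int = 4,
) -> SamplingOperator:
    """Sampling operator for a single rotation at ``angle`` radians.

    The rotation is about the geometric grid center ``((n-1)/2, (n-1)/2)``
    in 0-based voxel coordinates; the slice profile is a box of extent
    ``alpha`` high-resolution voxels. ``method="exact"`` (default)
    computes overlap areas by polygon clipping; ``method="subcell"``
    rasterizes each voxel into ``subcells x subcells`` subcells, which
    approximates the areas and is kept for cross-validation.
    """
    if not (0 - _TOL <= angle < np.pi + _TOL):
        raise ValueError(f"angle must lie in [0, pi), got {angle}")
    mat, shape, interior = _rotation_entries(geometry, float(angle), method, subcells)
    return SamplingOperator(
        matrix=mat,
        geometry=geometry,
        angles=(float(angle),),
        blocks=[(0, shape)],
        interior_rows=interior,
    )


def build_joint_system(
    geometry: AcquisitionGeometry, method: str = "exact", subcells: int = 4
) -> SamplingOperator:
    """Joint sampling operator stacking every rotation of the geometry.

    Per-rotation blocks are concatenated vertically in angle order, so
    ``y = A x`` collects all low-resolution observations of one plane.
    """
    mats, blocks, interiors = [], [], []
    offset = 0
    for angle in geometry.rotation_angles:
        mat, shape, interior = _rotation_entries(geometry, angle, method, subcells)
        mats.append(mat)
        blocks.append((offset, shape))
        interiors.append(interior)
        offset += shape[0] * shape[1]
    return SamplingOperator(
        matrix=sp.vstack(mats, format="csr"),
        geometry=geometry,
        angles=tuple(geometry.rotation_angles),
        blocks=blocks,
        interior_rows=np.concatenate(interiors),
    )
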