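"""Solvent-accessible surface sampling, Coulomb potential, and voxelization.

The solvent-accessible surface (SAS) is the locus traced by the centre of a
probe sphere rolled over the atoms.  Here it is *sampled*: each atom sphere is
expanded by the probe radius and covered with a deterministic Fibonacci
lattice of quasi-uniform points; samples falling strictly inside any other
atom's expanded sphere are buried and removed.  Every retained point keeps a
record of the atom that owns it, so a surface computed on a full structure can
be restricted to the points owned by a patch's atoms — occlusion by the
surrounding protein is then accounted for.

The electrostatic potential on the surface is a bare Coulomb sum over atomic
partial charges with a uniform dielectric; only the *spatial pattern* of the
potential (split by sign) feeds the descriptor, so no Poisson-Boltzmann
machinery is involved.

Voxelization maps a weighted point cloud into a cubic grid inscribed in the
unit ball: points are centred on their centroid, isotropically scaled so the
farthest point sits at ``ball_fill`` (< 1), and each point deposits its weight
into its nearest voxel.  The resulting grid is the function f(r, theta, phi)
that the Zernike expansion describes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import GridError, SurfaceError
from .structure_io import AtomSet

__all__ = [
    "SurfacePointSet",
    "VoxelGrid",
    "fibonacci_sphere",
    "compute_sas",
    "coulomb_potential",
    "split_potential",
    "voxelize",
]

#: samples closer than (1 - BURIAL_RTOL) * expanded radius to a foreign atom
#: centre count as buried; the relative tolerance absorbs roundoff at contact.
BURIAL_RTOL = 1e-9


@dataclass
class SurfacePointSet:
    """Sampled SAS points with per-point electrostatic potential and atom owner."""

    points: np.ndarray          # (n, 3), Angstrom
    potential: np.ndarray       # (n,), e/Angstrom scaled by 1/dielectric
    owner_atom: np.ndarray      # (n,), index into the generating AtomSet
    probe_radius: float = 0.0

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        self.potential = np.asarray(self.potential, dtype=float).reshape(-1)
        self.owner_atom = np.asarray(self.owner_atom, dtype=int).reshape(-1)
        if not (len(self.points) == len(self.potential) == len(self.owner_atom)):
            raise ValueError("points, potential and owner_atom must have equal length")

    def __len__(self) -> int:
        return len(self.points)

    def restrict_to_atoms(self, atom_indices) -> "SurfacePointSet":
        """Keep only points owned by the given atom indices (patch restriction)."""
        keep = np.isin(self.owner_atom, np.asarray(atom_indices, dtype=int))
        if not keep.any():
            raise SurfaceError("patch restriction leaves no surface points")
        return SurfacePointSet(
            self.points[keep], self.potential[keep], self.owner_atom[keep],
            self.probe_radius,
        )

    def to_xyz(self, path) -> None:
        """Export as ``x y z potential owner`` text for inspection."""
        header = f"{len(self)}\nSAS points: x y z potential owner_atom"
        data = np.column_stack(
            [self.points, self.potential, self.owner_atom.astype(float)]
        )
        np.savetxt(path, data, fmt="%.6f %.6f %.6f %.6e %d", header=header, comments="")


@dataclass
class VoxelGrid:
    """A cubic nonnegative scalar field on [-1, 1]^3 with its placement record.

    ``scale_record`` stores the affine map used to place the point cloud in
    the unit ball: ``grid coordinates = (x - center) * scale``.
    """

    dim: int
    values: np.ndarray          # (dim, dim, dim), >= 0
    channel: str                # one of {shape, elec_pos, elec_neg}
    scale_record: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.dim,) * 3:
            raise GridError(f"values shape {self.values.shape} != ({self.dim},)*3")
        if np.any(self.values < 0):
            raise GridError("voxel values must be nonnegative (sign lives in the channel)")

    @property
    def voxel_width(self) -> float:
        return 2.0 / self.dim

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """1-D voxel-centre coordinates along each axis, in [-1, 1]."""
        h = self.voxel_width
        c = -1.0 + h * (np.arange(self.dim) + 0.5)
        return c, c, c

    def total_mass(self) -> float:
        return float(self.values.sum())

    def save_text(self, path) -> None:
        """Versioned plain-text serialization (header + flat values)."""
        with open(path, "w") as fh:
            fh.write("zernipatch-voxelgrid v1\n")
            fh.write(f"dim {self.dim}\nchannel {self.channel}\n")
            center = self.scale_record.get("center", np.zeros(3))
            fh.write(
                "center {:.9g} {:.9g} {:.9g}\nscale {:.9g}\n".format(
                    *center, self.scale_record.get("scale", 1.0)
                )
            )
            np.savetxt(fh, self.values.reshape(-1, self.dim))

    @classmethod
    def load_text(cls, path) -> "VoxelGrid":
        with open(path) as fh:
            magic = fh.readline().strip()
            if magic != "zernipatch-voxelgrid v1":
                raise GridError(f"unrecognized grid header: {magic!r}")
            dim = int(fh.readline().split()[1])
            channel = fh.readline().split()[1]
            center = np.array([float(v) for v in fh.readline().split()[1:4]])
            scale = float(fh.readline().split()[1])
            values = np.loadtxt(fh).reshape(dim, dim, dim)
        return cls(dim, values, channel, {"center": center, "scale": scale})


def fibonacci_sphere(n: int) -> np.ndarray:
    """``n`` quasi-uniform unit vectors on the sphere (deterministic lattice)."""
    if n < 1:
        raise ValueError("need at least one sample")
    i = np.arange(n, dtype=float)
    # golden-angle longitude, latitude from equal-area stripes
    phi = i * (np.pi * (3.0 - np.sqrt(5.0)))
    z = 1.0 - (2.0 * i + 1.0) / n
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def compute_sas(
    atoms: AtomSet, probe_radius: float = 1.4, samples_per_atom: int = 200
) -> SurfacePointSet:
    """Sample the solvent-accessible surface of an atom set.

    Each atom contributes ``samples_per_atom`` Fibonacci-lattice points on its
    probe-expanded sphere; points buried inside any *other* atom's expanded
    sphere are removed.  Potentials are initialized to zero.

    Raises
    ------
    SurfaceError
        If the atom set is empty or every sample is buried.
    """
    if len(atoms) == 0:
        raise SurfaceError("empty atom set")
    if probe_radius < 0:
        raise SurfaceError(f"probe radius {probe_radius} < 0")
    if samples_per_atom < 12:
        raise SurfaceError("samples_per_atom must be at least 12")

    centers = atoms.positions
    expanded = atoms.radii + probe_radius
    directions = fibonacci_sphere(samples_per_atom)

    n_atoms = len(atoms)
    # candidate occluders per atom: spheres j can bury samples of i only when
    # |c_i - c_j| < e_i + e_j; the KD-tree query over-approximates with e_max
    tree = cKDTree(centers)
    candidates = tree.query_ball_point(centers, r=expanded + expanded.max())

    kept_pts: list[np.ndarray] = []
    kept_owners: list[np.ndarray] = []
    for i in range(n_atoms):
        pts_i = centers[i] + expanded[i] * directions
        neigh = [
            j
            for j in candidates[i]
            if j != i
            and np.linalg.norm(centers[i] - centers[j]) < expanded[i] + expanded[j]
        ]
        if neigh:
            d = np.linalg.norm(
                pts_i[:, None, :] - centers[neigh][None, :, :], axis=2
            )
            keep = np.all(d >= expanded[neigh][None, :] * (1.0 - BURIAL_RTOL), axis=1)
        else:
            keep = np.ones(samples_per_atom, dtype=bool)
        if keep.any():
            kept_pts.append(pts_i[keep])
            kept_owners.append(np.full(int(keep.sum()), i))
    if not kept_pts:
        raise SurfaceError("no exposed surface: every sample point is buried")
    pts = np.vstack(kept_pts)
    owners = np.concatenate(kept_owners)
    return SurfacePointSet(pts, np.zeros(len(pts)), owners, probe_radius)


def coulomb_potential(
    surface: SurfacePointSet, atoms: AtomSet, dielectric: float = 4.0
) -> SurfacePointSet:
    """Evaluate V(p) = (1/dielectric) * sum_i q_i / |p - x_i| on every surface point.

    Charges are in elementary-charge units, distances in Angstrom; the result
    is in e/Angstrom scaled by the uniform dielectric.
    """
    if dielectric <= 0:
        raise SurfaceError(f"dielectric {dielectric} must be positive")
    if len(atoms) == 0:
        raise SurfaceError("empty atom set")
    from scipy.spatial.distance import cdist

    dists = cdist(surface.points, atoms.positions)
    zero = np.argwhere(dists == 0.0)
    if zero.size:
        p, a = zero[0]
        raise SurfaceError(
            f"surface point {p} coincides with atom {a}: Coulomb sum diverges"
        )
    potential = (1.0 / dielectric) * (1.0 / dists) @ atoms.charges
    return SurfacePointSet(
        surface.points.copy(), potential, surface.owner_atom.copy(), surface.probe_radius
    )


def split_potential(surface: SurfacePointSet) -> tuple[np.ndarray, np.ndarray]:
    """Split the per-point potential by sign into two nonnegative weight vectors.

    Returns ``(pos, neg)`` with ``pos - neg`` reconstructing the potential
    exactly; the Zernike formalism sees only patterns of nonzero values, so
    the two polarities must be described by separate functions.
    """
    v = surface.potential
    return np.maximum(v, 0.0), np.maximum(-v, 0.0)


def voxelize(
    surface: SurfacePointSet,
    weights: np.ndarray | None,
    dim: int = 64,
    ball_fill: float = 0.7,
    channel: str = "shape",
    scale_record: dict | None = None,
) -> VoxelGrid:
    """Accumulate a weighted point cloud into a unit-ball voxel grid.

    Points are translated to their centroid and isotropically scaled so the
    farthest point lands at radius ``ball_fill``; each point adds its weight
    to the voxel containing it (nearest-voxel accumulation, so total grid mass
    equals the weight sum exactly).  ``weights=None`` means unit weights (the
    shape channel).  Passing an explicit ``scale_record`` reuses a previously
    computed placement so several channels of one patch share one frame.
    """
    if dim < 16:
        raise GridError(f"grid dim {dim} < 16 cannot resolve the descriptor order")
    if not (0.0 < ball_fill < 1.0):
        raise GridError(f"ball_fill {ball_fill} must lie in (0, 1)")
    pts = surface.points
    if weights is None:
        weights = np.ones(len(pts))
    weights = np.asarray(weights, dtype=float).reshape(-1)
    if len(weights) != len(pts):
        raise GridError(f"{len(weights)} weights for {len(pts)} points")
    if np.any(weights < 0):
        raise GridError("voxel weights must be nonnegative")

    if scale_record is None:
        center = pts.mean(axis=0)
        rmax = float(np.linalg.norm(pts - center, axis=1).max())
        if rmax <= 0.0:
            raise GridError("degenerate point set: all points coincide")
        scale = ball_fill / rmax
        scale_record = {"center": center, "scale": scale, "ball_fill": ball_fill}
    else:
        center = np.asarray(scale_record["center"], dtype=float)
        scale = float(scale_record["scale"])

    unit = (pts - center) * scale
    if np.any(np.linalg.norm(unit, axis=1) > 1.0):
        raise GridError("scaled points escape the unit ball; check scale_record")

    h = 2.0 / dim
    idx = np.floor((unit + 1.0) / h).astype(int)
    np.clip(idx, 0, dim - 1, out=idx)
    values = np.zeros((dim, dim, dim))
    np.add.at(values, (idx[:, 0], idx[:, 1], idx[:, 2]), weights)
    return VoxelGrid(dim, values, channel, dict(scale_record))
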