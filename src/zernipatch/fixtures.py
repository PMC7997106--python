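"""Synthetic atom-set fixtures: analytic geometries, rigid motions,
complementary bump/cavity pairs, and two-state conformational ensembles.

Everything here is deterministic given (spec, seed): randomness flows through
explicit integer seeds into ``numpy.random.default_rng``, never global state.
The fixtures exist so the full pipeline — file IO, surface sampling,
electrostatics, descriptors, comparison and ensemble statistics — can be
exercised end-to-end without external structure downloads.

Writers for valid PQR and multi-model PDB live in :mod:`zernipatch.structure_io`
and are re-exported here.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.spatial.transform import Rotation

from .structure_io import (  # noqa: F401  (re-exported writers)
    Atom,
    AtomSet,
    write_pdb_models,
    write_pqr,
)

__all__ = [
    "FixtureSpec",
    "make_atomset",
    "apply_rigid_motion",
    "make_complementary_pair",
    "make_two_state_ensemble",
    "write_pqr",
    "write_pdb_models",
]

KINDS = ("sphere", "dipole", "helix_like", "bump", "cavity")


@dataclass(frozen=True)
class FixtureSpec:
    """Declarative description of a synthetic atom set.

    ``params`` hold kind-specific geometry (radii in Angstrom, counts,
    separations) and charge patterns (elementary charges).  Identical
    (spec, seed) always produce identical fixtures.
    """

    kind: str
    seed: int = 0
    params: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown fixture kind {self.kind!r}; expected one of {KINDS}")


def _atoms_from_arrays(
    positions: np.ndarray,
    radii,
    charges,
    label: str,
    residue_start: int = 1,
    atoms_per_residue: int = 1,
) -> AtomSet:
    positions = np.asarray(positions, dtype=float).reshape(-1, 3)
    n = len(positions)
    radii = np.broadcast_to(np.asarray(radii, dtype=float), (n,))
    charges = np.broadcast_to(np.asarray(charges, dtype=float), (n,))
    if np.any(radii <= 0):
        raise ValueError("fixture atom radii must be positive")
    atoms = [
        Atom(
            serial=i + 1,
            name="C",
            residue_name="FIX",
            chain="A",
            residue_number=residue_start + i // atoms_per_residue,
            position=positions[i],
            radius=float(radii[i]),
            partial_charge=float(charges[i]),
        )
        for i in range(n)
    ]
    return AtomSet(atoms, source_label=label)


#: unit directions shared by every cap shell, fixing one angular layout for
#: all feature radii (~12 degree spacing); congruent caps then sample
#: congruent surfaces
N_SHELL_DIRECTIONS = 276
#: lining atoms within this angle of the cap edge act as occluders (residue 2)
#: rather than patch (residue 1), confining the patch surface to the cap
RIM_MARGIN_DEG = 15.0
#: radial offset between a lining shell and its occluding backing shell, A
BACKING_OFFSET = 2.8


def _cap_directions(half_angle_deg: float) -> np.ndarray:
    """Unit vectors of the upward cap, drawn from one fixed global lattice."""
    from .surface_field import fibonacci_sphere

    u = fibonacci_sphere(N_SHELL_DIRECTIONS)
    cap = u[u[:, 2] >= np.cos(np.radians(half_angle_deg))]
    if len(cap) < 4:
        raise ValueError("cap too small: fewer than 4 lining atoms")
    return cap


def _ring_plate(z: float, r_in: float, r_out: float, spacing: float = 2.0) -> np.ndarray:
    """Concentric rings of points in the plane ``z`` between two radii."""
    pts = []
    for r in np.arange(r_in, r_out + 0.5 * spacing, spacing):
        n = max(6, int(round(2 * np.pi * r / spacing)))
        ang = 2 * np.pi * np.arange(n) / n
        pts.append(np.column_stack([r * np.cos(ang), r * np.sin(ang), np.full(n, z)]))
    return np.vstack(pts)


def _capped_feature(
    feature_radius: float,
    half_angle_deg: float,
    concave: bool,
    atom_radius: float,
    lining_charge: float,
    label: str,
    patch_margin_deg: float | None = None,
) -> AtomSet:
    """A spherical-cap shell patch embedded in a neutral occluding support.

    The lining sits on a cap of ``feature_radius`` spanning ``half_angle_deg``
    from the vertical axis; only atoms more than RIM_MARGIN_DEG from the cap
    edge form the *patch* (residue 1, carrying ``lining_charge``), the rim
    band plus a backing shell (concave) or interior filler (convex) plus a
    flat annulus around the base are support (residue 2, neutral).  All shells
    share one angular lattice, so a cavity at radius R and a bump at radius
    R - 2(atom+probe) expose point-inversion-congruent solvent-accessible
    caps — the geometric ground truth behind the complementarity tests.
    """
    half_angle = np.radians(half_angle_deg)
    base_z = feature_radius * np.cos(half_angle)
    base_rho = feature_radius * np.sin(half_angle)
    margin = RIM_MARGIN_DEG if patch_margin_deg is None else patch_margin_deg
    directions = _cap_directions(half_angle_deg)
    lining = feature_radius * directions
    is_patch = directions[:, 2] >= np.cos(np.radians(half_angle_deg - margin))

    def reflect(pts: np.ndarray) -> np.ndarray:
        out = pts.copy()
        out[:, 2] = 2 * base_z - out[:, 2]
        return out

    supports = []
    if concave:
        lining = reflect(lining)  # a bowl opening upward, rim in the base plane
        backing = (feature_radius + BACKING_OFFSET) * _cap_directions(
            min(half_angle_deg + 12.0, 90.0)
        )
        supports.append(reflect(backing))
    elif feature_radius - BACKING_OFFSET >= 2.0:
        supports.append(
            (feature_radius - BACKING_OFFSET)
            * _cap_directions(min(half_angle_deg + 12.0, 90.0))
        )
    else:  # small dome: a single filler atom buries the interior face
        supports.append(np.array([[0.0, 0.0, max(base_z, 0.0)]]))
    supports.append(_ring_plate(base_z, base_rho + 2.0, base_rho + 8.0))
    positions = np.vstack([lining, support := np.vstack(supports)])
    patch_flags = np.concatenate([is_patch, np.zeros(len(support), dtype=bool)])
    charges = np.where(patch_flags, lining_charge, 0.0)
    atoms = _atoms_from_arrays(positions, atom_radius, charges, label)
    renumbered = [
        Atom(
            serial=a.serial, name=a.name, residue_name=a.residue_name, chain=a.chain,
            residue_number=1 if patch_flags[i] else 2,
            position=a.position, radius=a.radius, partial_charge=a.partial_charge,
        )
        for i, a in enumerate(atoms)
    ]
    return AtomSet(renumbered, source_label=label)


def make_atomset(spec: FixtureSpec) -> AtomSet:
    """Build the atom set described by ``spec`` (deterministic)."""
    p = dict(spec.params)
    rng = np.random.default_rng(spec.seed)
    kind = spec.kind

    if kind == "sphere":
        n = int(p.get("n_atoms", 1))
        atom_radius = float(p.get("atom_radius", 1.7))
        shell_radius = float(p.get("shell_radius", 0.0))
        charge = p.get("charge", 0.0)
        if n == 1 or shell_radius == 0.0:
            positions = np.zeros((max(n, 1), 3))
            if n > 1:
                raise ValueError("multiple sphere atoms need a positive shell_radius")
        else:
            from .surface_field import fibonacci_sphere

            positions = shell_radius * fibonacci_sphere(n)
        return _atoms_from_arrays(positions, atom_radius, charge, f"sphere(seed={spec.seed})")

    if kind == "dipole":
        sep = float(p.get("separation", 4.0))
        q = float(p.get("charge", 0.5))
        atom_radius = float(p.get("atom_radius", 1.7))
        positions = np.array([[0.0, 0.0, -sep / 2], [0.0, 0.0, sep / 2]])
        return _atoms_from_arrays(
            positions, atom_radius, [q, -q], f"dipole(seed={spec.seed})"
        )

    if kind == "helix_like":
        n = int(p.get("n_atoms", 20))
        helix_radius = float(p.get("helix_radius", 2.3))
        rise = float(p.get("rise", 1.5))
        turn = float(p.get("turn_deg", 100.0)) * np.pi / 180.0
        jitter = float(p.get("jitter", 0.0))
        atom_radius = float(p.get("atom_radius", 1.9))
        charge = p.get("charge", None)
        residue_start = int(p.get("residue_start", 1))
        i = np.arange(n)
        positions = np.column_stack(
            [helix_radius * np.cos(turn * i), helix_radius * np.sin(turn * i), rise * i]
        )
        if jitter > 0:
            positions = positions + jitter * rng.standard_normal((n, 3))
        if charge is None:
            charges = 0.3 * np.where(i % 2 == 0, 1.0, -1.0)  # alternating dipolar stripe
        else:
            charges = np.broadcast_to(np.asarray(charge, dtype=float), (n,))
        return _atoms_from_arrays(
            positions, atom_radius, charges,
            f"helix_like(n={n},seed={spec.seed})", residue_start=residue_start,
        )

    if kind in ("bump", "cavity"):
        return _capped_feature(
            feature_radius=float(p.get("feature_radius", 10.0 if kind == "cavity" else 3.8)),
            half_angle_deg=float(p.get("half_angle_deg", 90.0)),
            concave=(kind == "cavity"),
            atom_radius=float(p.get("atom_radius", 1.7)),
            lining_charge=float(p.get("lining_charge", 0.0)),
            label=f"{kind}(seed={spec.seed})",
            patch_margin_deg=p.get("patch_margin_deg"),
        )

    raise ValueError(f"unknown fixture kind {kind!r}")


def apply_rigid_motion(
    atoms: AtomSet, rotation_seed: int = 0, translation=(0.0, 0.0, 0.0)
) -> AtomSet:
    """Rotate uniformly at random (drawn from ``rotation_seed``) about the
    centroid, then translate.  Seed 0 is reserved for the identity rotation,
    so ``apply_rigid_motion(a, 0, (0, 0, 0))`` returns an unchanged copy.
    Pairwise distances are preserved to float tolerance."""
    positions = atoms.positions
    centroid = positions.mean(axis=0)
    if rotation_seed == 0:
        rotated = positions
    else:
        R = Rotation.random(random_state=rotation_seed).as_matrix()
        rotated = (positions - centroid) @ R.T + centroid
    moved = rotated + np.asarray(translation, dtype=float)
    return atoms.with_positions(
        moved, label=f"{atoms.source_label}|rot{rotation_seed}"
    )


def make_complementary_pair(
    seed: int = 0, charge: float = 0.4
) -> tuple[AtomSet, AtomSet]:
    """A hemispherical cavity (lining charge ``+charge``) and the matching
    bump (lining charge ``-charge``); the patch of each is its residue-1
    lining (``ResidueSelection.from_string("1")``).

    The bump radius equals the cavity radius minus one atom-plus-probe
    diameter, so the two solvent-accessible patch surfaces are (nearly)
    congruent spherical caps of opposite curvature: a planted positive case
    for both shape and electrostatic complementarity.  A *mismatched* bump —
    e.g. ``make_atomset(FixtureSpec("bump", params={"feature_radius": 10.0,
    "half_angle_deg": 50.0, "lining_charge": +charge}))`` — is the natural
    bump/bump negative control.
    """
    cavity_radius = 10.0
    bump_radius = cavity_radius - 2 * (1.7 + 1.4)  # atom radius + water probe
    # burial truncates a convex solvent-accessible cap earlier than a concave
    # one; the wider cavity margin makes both patch caps end near one polar
    # angle so the planted congruence survives surface construction
    receptor = _capped_feature(
        feature_radius=cavity_radius, half_angle_deg=90.0, concave=True,
        atom_radius=1.7, lining_charge=+charge,
        label=f"receptor_cavity(seed={seed})", patch_margin_deg=30.0,
    )
    ligand = _capped_feature(
        feature_radius=bump_radius, half_angle_deg=90.0, concave=False,
        atom_radius=1.7, lining_charge=-charge,
        label=f"ligand_bump(seed={seed})",
    )
    if charge != 0.0:
        # a concave lining focuses its Coulomb field onto the patch surface far
        # more than the convex bump does; rescale the bump's lining charges so
        # the two patches carry the same mean |potential| and the planted
        # pos<->neg pattern match is an amplitude match too
        scale = _mean_patch_potential(receptor) / _mean_patch_potential(ligand)
        lining_idx = [i for i, a in enumerate(ligand) if a.residue_number == 1]
        q = ligand.charges
        q[lining_idx] *= scale
        ligand = ligand.with_charges(q)
    if seed != 0:  # scramble orientations so nothing relies on a shared frame
        receptor = apply_rigid_motion(receptor, rotation_seed=2 * seed + 1)
        ligand = apply_rigid_motion(ligand, rotation_seed=2 * seed + 2)
    return receptor, ligand


def _mean_patch_potential(fixture: AtomSet) -> float:
    """Mean |Coulomb potential| over the residue-1 patch surface (probe 1.4,
    dielectric 4, coarse sampling); used to balance the pair's amplitudes."""
    from .surface_field import compute_sas, coulomb_potential

    patch_idx = [i for i, a in enumerate(fixture) if a.residue_number == 1]
    surf = compute_sas(fixture, probe_radius=1.4, samples_per_atom=120)
    surf = surf.restrict_to_atoms(patch_idx)
    surf = coulomb_potential(surf, fixture, dielectric=4.0)
    return float(np.abs(surf.potential).mean())


def make_two_state_ensemble(
    n_frames: int,
    seed: int = 1,
    jitter: float = 0.15,
    n_atoms: int = 20,
) -> tuple[list[AtomSet], list[int]]:
    """Frames alternating between two distinct conformers of a helix-like
    fixture (the second has its C-terminal half kinked by 60 degrees), each
    displaced by isotropic Gaussian jitter.  Returns (frames, state_labels).

    Jitter 0 gives exactly two unique geometries; the planted two-state
    structure makes the distance-to-frame-0 series bimodal.
    """
    if n_frames < 4:
        raise ValueError("a two-state ensemble needs at least 4 frames")
    base = make_atomset(FixtureSpec("helix_like", seed=0, params={"n_atoms": n_atoms}))
    pos_a = base.positions
    # state B: kink the second half about the x-axis through the midpoint atom
    half = n_atoms // 2
    pivot = pos_a[half]
    kink = Rotation.from_euler("x", 60, degrees=True).as_matrix()
    pos_b = pos_a.copy()
    pos_b[half:] = (pos_a[half:] - pivot) @ kink.T + pivot

    rng = np.random.default_rng(seed)
    frames: list[AtomSet] = []
    labels: list[int] = []
    for i in range(n_frames):
        state = i % 2
        pos = (pos_a if state == 0 else pos_b).copy()
        if jitter > 0:
            pos = pos + jitter * rng.standard_normal(pos.shape)
        frames.append(base.with_positions(pos, label=f"frame{i}_state{state}"))
        labels.append(state)
    return frames, labels
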