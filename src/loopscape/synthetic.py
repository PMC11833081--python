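"""Seeded synthetic two-chain ensembles with known ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes, without pretending to be real protein geometry:

* an "enzyme" chain (E) with a static body, a designated active-site
  residue group, an allosteric-pocket residue group, and a mobile "loop"
  segment whose heavy-atom COM distance to the active site is drawn from a
  two-state (closed/open) mixture with Gaussian noise;
* optionally a "ligand" chain (I) occupying K discrete binding poses with
  positional jitter, where designated poses are guaranteed to make a
  heavy-atom contact (< 3.3 A) with the pocket and all other poses are
  guaranteed to make no enzyme contact at all.

Residues are schematic clusters of heavy atoms on a geometric template;
the pipeline consumes only coordinates, masses and labels, so statistical
rather than stereochemical realism is the requirement.  Enzyme residue
numbers deliberately include the murine cathepsin B preset groups (loop
185-200, active site 108/278/298, pocket 169/215/221/222/224/333) so
preset-driven analyses resolve on synthetic data unchanged.

Everything is drawn from a single ``numpy`` Generator seeded from the
spec, so (spec, seed) determines the ensemble, the ground truth and every
downstream result bit-for-bit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .elements import is_hydrogen, mass_of
from .ensemble_io import AtomRecord, StructureEnsemble, Topology
from .errors import InputError

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "generate_two_state_enzyme",
    "generate_binding_ensemble",
    "ENZYME_CHAIN",
    "LIGAND_CHAIN",
]

ENZYME_CHAIN = "E"
LIGAND_CHAIN = "I"

_ACTIVE_SITE_RESIDUES = (108, 278, 298)
_LOOP_RESIDUES = tuple(range(185, 201))
_POCKET_RESIDUES = (169, 215, 221, 222, 224, 333)

# Guaranteed pocket-contact distance for bound poses (strictly below the
# 3.3 A contact cutoff, with margin).
_BOUND_CONTACT_DISTANCE = 2.9


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic study conditions.

    Defaults describe a closed-dominant enzyme (f_open = 0.25, states at
    12 and 20 A with 0.8 A COM noise over 2000 frames) and, for binding
    ensembles, a ligand with one pocket-bound pose.  Distances in
    Angstrom.
    """

    n_frames: int = 2000
    f_open: float = 0.25
    d_closed: float = 12.0
    d_open: float = 20.0
    loop_noise_sigma: float = 0.8
    n_enzyme_residues: int = 40
    n_ligand_residues: int = 15
    atoms_per_residue: int = 4
    n_poses: int = 1
    pose_occupancies: tuple[float, ...] = (1.0,)
    pose_offsets: tuple[tuple[float, float, float], ...] | None = None
    pose_jitter_sigma: float = 0.5
    bound_pose_contact_target: tuple[int, ...] = (0,)
    pose_open_fractions: tuple[float, ...] | None = None
    pocket_residues: tuple[int, ...] = _POCKET_RESIDUES
    seed: int = 0

    def validate(self, force: bool = False) -> None:
        if self.n_frames < 1:
            raise InputError("n_frames must be >= 1")
        if not 0.0 <= self.f_open <= 1.0:
            raise InputError("f_open must lie in [0, 1]")
        if not self.d_open > self.d_closed > 0:
            raise InputError("need d_open > d_closed > 0")
        if self.loop_noise_sigma < 0:
            raise InputError("loop_noise_sigma must be >= 0")
        if self.n_enzyme_residues < 25:
            raise InputError(
                "n_enzyme_residues must be >= 25 (active site + loop + pocket)"
            )
        if self.atoms_per_residue < 1:
            raise InputError("atoms_per_residue must be >= 1")
        if self.n_poses < 1:
            raise InputError("n_poses (K) must be >= 1")
        occ = np.asarray(self.pose_occupancies, dtype=float)
        if occ.size != self.n_poses:
            raise InputError("pose_occupancies length must equal n_poses")
        if abs(occ.sum() - 1.0) > 1e-12 or np.any(occ < 0):
            raise InputError("pose_occupancies must be >= 0 and sum to 1")
        if self.pose_offsets is not None and len(self.pose_offsets) != self.n_poses:
            raise InputError("pose_offsets length must equal n_poses")
        if self.pose_open_fractions is not None:
            pof = np.asarray(self.pose_open_fractions, dtype=float)
            if pof.size != self.n_poses or np.any((pof < 0) | (pof > 1)):
                raise InputError("pose_open_fractions must be K values in [0, 1]")
        if any(p < 0 or p >= self.n_poses for p in self.bound_pose_contact_target):
            raise InputError("bound_pose_contact_target indices out of range")
        gap = self.d_open - self.d_closed
        if gap < 6 * self.loop_noise_sigma and not force:
            warnings.warn(
                f"open/closed separation {gap:.2f} A < 6 sigma "
                f"({6 * self.loop_noise_sigma:.2f} A): states not well separable",
                stacklevel=2,
            )
        offsets = self.resolved_pose_offsets()
        if self.n_poses > 1 and not force:
            for i in range(self.n_poses):
                for j in range(i + 1, self.n_poses):
                    sep = float(np.linalg.norm(offsets[i] - offsets[j]))
                    if sep < 3 * self.pose_jitter_sigma:
                        warnings.warn(
                            f"poses {i} and {j} only {sep:.2f} A apart "
                            f"(< 3x jitter): poses not well separable",
                            stacklevel=2,
                        )

    def resolved_pose_offsets(self) -> np.ndarray:
        """Pose offsets as an array, defaulting to 10 A spacing along y."""
        if self.pose_offsets is not None:
            return np.asarray(self.pose_offsets, dtype=float)
        return np.array([[-24.0, 10.0 * p, 0.0] for p in range(self.n_poses)])


@dataclass
class GroundTruth:
    """Per-frame generation truth for benchmarking the pipeline."""

    frame_ids: np.ndarray
    state_labels: np.ndarray  # "open" / "closed", pre-noise
    com_distances: np.ndarray  # exact generated COM distance (post noise)
    pose_labels: np.ndarray  # pose index, or -1 when no ligand exists
    pocket_contact: np.ndarray  # bool: pose guarantees a pocket contact
    expected_contacts: list[list[tuple[tuple[str, int], tuple[str, int]]]] = field(
        default_factory=list
    )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame_id": self.frame_ids,
                "state": self.state_labels,
                "com_distance_angstrom": self.com_distances,
                "pose": self.pose_labels,
                "pocket_contact": self.pocket_contact.astype(int),
            }
        )


# ---------------------------------------------------------------------------
# geometry templates
# ---------------------------------------------------------------------------


def _residue_atom_offsets(n_atoms: int) -> np.ndarray:
    if n_atoms == 4:
        return 0.8 * np.array(
            [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
        )
    k = np.arange(n_atoms)
    return np.column_stack(
        [
            0.8 * np.cos(2 * np.pi * k / max(n_atoms, 2)),
            0.8 * np.sin(2 * np.pi * k / max(n_atoms, 2)),
            0.5 * (k - (n_atoms - 1) / 2),
        ]
    )


def _residue_elements(n_atoms: int) -> list[str]:
    cycle = ["C", "N", "O", "C"]
    return [cycle[i % len(cycle)] for i in range(n_atoms)]


def _enzyme_layout(spec: SyntheticSpec) -> list[tuple[int, np.ndarray, str]]:
    """(residue_number, center, role) for every enzyme residue."""
    layout: list[tuple[int, np.ndarray, str]] = []
    as_centers = np.array([[0.0, -3.0, 0.0], [0.0, 0.0, 0.0], [0.0, 3.0, 0.0]])
    for resnum, c in zip(_ACTIVE_SITE_RESIDUES, as_centers):
        layout.append((resnum, c, "active_site"))
    pocket_base = np.array([-13.0, 0.0, 0.0])
    pocket_local = np.array(
        [
            [0.0, 0.0, 0.0],
            [0.0, 2.4, 0.0],
            [0.0, -2.4, 0.0],
            [0.0, 0.0, 2.4],
            [0.0, 0.0, -2.4],
            [-2.4, 0.0, 0.0],
        ]
    )
    for resnum, off in zip(sorted(spec.pocket_residues), pocket_local):
        layout.append((resnum, pocket_base + off, "pocket"))
    # loop template: a line along y; moved each frame along +x
    for i, resnum in enumerate(_LOOP_RESIDUES):
        layout.append(
            (resnum, np.array([0.0, (i - 7.5) * 1.8, 0.0]), "loop")
        )
    n_filler = spec.n_enzyme_residues - len(layout)
    if n_filler > 100:
        raise InputError("n_enzyme_residues too large (filler numbering would collide)")
    theta = 2 * np.pi * np.arange(max(n_filler, 1)) / max(n_filler, 1)
    for i in range(n_filler):
        layout.append(
            (
                i + 1,
                np.array([-5.0, 9.0 * np.cos(theta[i]), 9.0 * np.sin(theta[i])]),
                "body",
            )
        )
    layout.sort(key=lambda t: t[0])
    return layout


def _ligand_layout(spec: SyntheticSpec) -> list[tuple[int, np.ndarray]]:
    """Ligand residue centers on a compact y-z grid around the origin."""
    n = spec.n_ligand_residues
    ny = int(np.ceil(np.sqrt(n)))
    centers = []
    for i in range(n):
        iy, iz = i % ny, i // ny
        centers.append(
            (
                i + 1,
                np.array(
                    [0.0, (iy - (ny - 1) / 2) * 3.0, (iz - (n // ny) / 2) * 3.0]
                ),
            )
        )
    return centers


def _build_topology_and_template(
    spec: SyntheticSpec, with_ligand: bool
) -> tuple[Topology, np.ndarray, dict[str, np.ndarray]]:
    """Topology, template coordinates and named atom-index groups."""
    atoms: list[AtomRecord] = []
    coords: list[np.ndarray] = []
    groups: dict[str, list[int]] = {
        "active_site": [],
        "loop": [],
        "pocket": [],
        "body": [],
        "ligand": [],
    }
    offsets = _residue_atom_offsets(spec.atoms_per_residue)
    elements = _residue_elements(spec.atoms_per_residue)

    def add_residue(chain: str, resnum: int, center: np.ndarray, role: str) -> None:
        for k in range(spec.atoms_per_residue):
            el = elements[k]
            idx = len(atoms)
            atoms.append(
                AtomRecord(
                    atom_index=idx,
                    atom_name=f"{el}{k + 1}",
                    element=el,
                    chain_id=chain,
                    residue_number=resnum,
                    residue_name="ALA",
                    mass=mass_of(el),
                    is_heavy=not is_hydrogen(el),
                )
            )
            coords.append(center + offsets[k])
            groups[role].append(idx)

    for resnum, center, role in _enzyme_layout(spec):
        add_residue(ENZYME_CHAIN, resnum, center, role)
    if with_ligand:
        for resnum, center in _ligand_layout(spec):
            add_residue(LIGAND_CHAIN, resnum, center, "ligand")

    topology = Topology(atoms=atoms)
    template = np.array(coords)
    index_groups = {k: np.array(v, dtype=int) for k, v in groups.items() if v}
    return topology, template, index_groups


def _mass_com(coords: np.ndarray, masses: np.ndarray) -> np.ndarray:
    w = masses / masses.sum()
    return w @ coords


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def _draw_states(spec: SyntheticSpec, rng: np.random.Generator, poses: np.ndarray | None):
    if poses is not None and spec.pose_open_fractions is not None:
        f = np.asarray(spec.pose_open_fractions, dtype=float)[poses]
    else:
        f = np.full(spec.n_frames, spec.f_open)
    is_open = rng.random(spec.n_frames) < f
    d_state = np.where(is_open, spec.d_open, spec.d_closed)
    noise = rng.normal(0.0, spec.loop_noise_sigma, spec.n_frames)
    distances = np.maximum(d_state + noise, 0.1)
    return is_open, distances


def _place_loop(
    template: np.ndarray,
    groups: dict[str, np.ndarray],
    masses: np.ndarray,
    distances: np.ndarray,
) -> np.ndarray:
    """Frames array with the loop COM placed at the target distance.

    The loop group is rigidly translated along +x so its heavy-atom
    mass-weighted COM sits exactly ``distance`` Angstrom from the
    active-site COM; the noise therefore lives on the COM coordinate
    itself, not on individual atoms.
    """
    n_frames = len(distances)
    loop = groups["loop"]
    site = groups["active_site"]
    site_com = _mass_com(template[site], masses[site])
    loop_com0 = _mass_com(template[loop], masses[loop])
    frames = np.broadcast_to(template, (n_frames,) + template.shape).copy()
    targets = site_com[None, :] + np.outer(distances, np.array([1.0, 0.0, 0.0]))
    shifts = targets - loop_com0[None, :]
    frames[:, loop, :] = template[loop][None, :, :] + shifts[:, None, :]
    return frames


def generate_two_state_enzyme(
    spec: SyntheticSpec, force: bool = False
) -> tuple[StructureEnsemble, GroundTruth]:
    """Single-chain enzyme ensemble with a two-state occluding loop.

    Per frame the state is Bernoulli(f_open); the loop is placed so the
    heavy-atom COM distance to the active site equals the state distance
    plus N(0, loop_noise_sigma) noise.  Deterministic for a fixed spec.
    """
    spec.validate(force=force)
    rng = np.random.default_rng(spec.seed)
    topology, template, groups = _build_topology_and_template(spec, with_ligand=False)
    masses = topology.masses

    is_open, distances = _draw_states(spec, rng, poses=None)
    frames = _place_loop(template, groups, masses, distances)
    frame_ids = np.arange(1, spec.n_frames + 1)

    ensemble = StructureEnsemble(
        topology=topology, coordinates=frames, frame_ids=frame_ids
    )
    truth = GroundTruth(
        frame_ids=frame_ids,
        state_labels=np.where(is_open, "open", "closed"),
        com_distances=distances,
        pose_labels=np.full(spec.n_frames, -1, dtype=int),
        pocket_contact=np.zeros(spec.n_frames, dtype=bool),
        expected_contacts=[[] for _ in range(spec.n_frames)],
    )
    return ensemble, truth


def generate_binding_ensemble(
    spec: SyntheticSpec, force: bool = False
) -> tuple[StructureEnsemble, GroundTruth]:
    """Two-chain ensemble: enzyme with loop dynamics plus a posed ligand.

    Per frame a pose is drawn from ``pose_occupancies`` and the ligand is
    rigidly placed at the pose offset plus component-wise Gaussian jitter
    (clipped at 3 sigma so geometric guarantees hold).  Poses listed in
    ``bound_pose_contact_target`` are then pulled along the closest
    ligand-to-pocket atom axis until that atom pair sits at 2.9 A,
    guaranteeing a pocket contact under the 3.3 A cutoff; all other poses
    are placed far enough that no enzyme contact can occur.  When
    ``pose_open_fractions`` is set, the loop-state probability follows the
    pose, emulating allosteric opening.
    """
    spec.validate(force=force)
    if spec.n_poses != len(spec.pose_occupancies):
        raise InputError("pose_occupancies length must equal n_poses")
    rng = np.random.default_rng(spec.seed)
    topology, template, groups = _build_topology_and_template(spec, with_ligand=True)
    masses = topology.masses
    ligand = groups["ligand"]
    pocket = groups["pocket"]
    offsets = spec.resolved_pose_offsets()
    bound = set(spec.bound_pose_contact_target)

    poses = rng.choice(spec.n_poses, size=spec.n_frames, p=np.asarray(spec.pose_occupancies))
    is_open, distances = _draw_states(spec, rng, poses=poses)
    sigma = spec.pose_jitter_sigma
    jitter = rng.normal(0.0, sigma, size=(spec.n_frames, 3))
    if sigma > 0:
        jitter = np.clip(jitter, -3 * sigma, 3 * sigma)

    frames = _place_loop(template, groups, masses, distances)
    ligand_local = template[ligand] - template[ligand].mean(axis=0)
    pocket_coords = template[pocket]
    pocket_atom_meta = [topology.atoms[i] for i in pocket]
    ligand_atom_meta = [topology.atoms[i] for i in ligand]

    expected: list[list[tuple[tuple[str, int], tuple[str, int]]]] = []
    for f in range(spec.n_frames):
        pose = int(poses[f])
        placed = ligand_local + offsets[pose] + jitter[f]
        contacts: list[tuple[tuple[str, int], tuple[str, int]]] = []
        if pose in bound:
            diff = placed[:, None, :] - pocket_coords[None, :, :]
            dist = np.linalg.norm(diff, axis=2)
            li, pi = np.unravel_index(np.argmin(dist), dist.shape)
            dmin = dist[li, pi]
            if dmin > _BOUND_CONTACT_DISTANCE:
                u = (pocket_coords[pi] - placed[li]) / dmin
                placed = placed + (dmin - _BOUND_CONTACT_DISTANCE) * u
            enz = pocket_atom_meta[pi]
            lig = ligand_atom_meta[li]
            contacts.append(
                (
                    (enz.chain_id, enz.residue_number),
                    (lig.chain_id, lig.residue_number),
                )
            )
        frames[f, ligand, :] = placed
        expected.append(contacts)

    frame_ids = np.arange(1, spec.n_frames + 1)
    ensemble = StructureEnsemble(
        topology=topology, coordinates=frames, frame_ids=frame_ids
    )
    truth = GroundTruth(
        frame_ids=frame_ids,
        state_labels=np.where(is_open, "open", "closed"),
        com_distances=distances,
        pose_labels=poses.astype(int),
        pocket_contact=np.isin(poses, list(bound)),
        expected_contacts=expected,
    )
    return ensemble, truth


def two_pose_spec(
    n_frames: int = 1000,
    occupancies: tuple[float, float] = (0.7, 0.3),
    pose_separation: float = 10.0,
    seed: int = 7,
    **overrides,
) -> SyntheticSpec:
    """Convenience spec: two ligand poses separated along y, pose 0 bound."""
    base = SyntheticSpec(
        n_frames=n_frames,
        n_poses=2,
        pose_occupancies=occupancies,
        pose_offsets=(
            (-24.0, 0.0, 0.0),
            (-24.0, pose_separation, 0.0),
        ),
        bound_pose_contact_target=(0,),
        seed=seed,
    )
    return replace(base, **overrides)
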