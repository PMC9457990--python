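"""Rigid-body shape docking and interaction profiling.

This module supplies the fitness stage of the maturation loop:

* a deliberately coarse 3D embedder that turns a folded aptamer into
  one pseudo-atom per nucleotide (ideal B-form geometry for paired
  stems, extended chain elsewhere);
* an FFT shape-complementarity docking scorer — surface/surface
  overlap is rewarded, core/core clash penalised, and all translations
  of a rotated ligand are scored at once by cross-correlation of the
  two voxel grids;
* a geometric hydrogen-bond profiler for a docked complex;
* an adapter that serves externally computed docking scores (e.g. from
  a dedicated docking server) as a drop-in fitness function.

The internal score is a dimensionless ranking surrogate: its contract
is ordering candidates, not reproducing any particular server's
numeric scale.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve
from scipy.spatial.transform import Rotation

from .energetics import EnergyModel, build_energy_model
from .folding import FoldResult, fold_mfe
from .sequences import NucleotideSequence


# ---------------------------------------------------------------------------
# structures and PDB I/O

@dataclass
class Structure3D:
    """Coarse atomic structure: parallel arrays, coordinates in Angstrom."""

    atom_names: List[str]
    residue_names: List[str]
    chain_ids: List[str]
    residue_indices: np.ndarray  # 1-based, int
    coords: np.ndarray  # (n, 3) float
    source: str = "synthetic"  # pdb_file | coarse_embedding | synthetic

    def __post_init__(self) -> None:
        self.residue_indices = np.asarray(self.residue_indices, dtype=int)
        self.coords = np.asarray(self.coords, dtype=float)
        n = len(self.atom_names)
        if not (len(self.residue_names) == len(self.chain_ids) == len(self.residue_indices) == self.coords.shape[0] == n):
            raise ValueError("inconsistent array lengths")
        if n == 0:
            raise ValueError("empty structure")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")

    def __len__(self) -> int:
        return len(self.atom_names)

    def chain(self, chain_id: str) -> "Structure3D":
        mask = [c == chain_id for c in self.chain_ids]
        if not any(mask):
            raise KeyError(f"chain {chain_id!r} not present")
        idx = np.flatnonzero(mask)
        return Structure3D(
            [self.atom_names[i] for i in idx],
            [self.residue_names[i] for i in idx],
            [self.chain_ids[i] for i in idx],
            self.residue_indices[idx],
            self.coords[idx],
            self.source,
        )

    def translated(self, vec: np.ndarray) -> "Structure3D":
        return replace(self, coords=self.coords + np.asarray(vec, dtype=float))


def read_pdb(path: str | Path) -> Structure3D:
    """Read ATOM/HETATM records from a PDB file."""
    names, resnames, chains, resids, xyz = [], [], [], [], []
    with open(path) as fh:
        for line in fh:
            if not line.startswith(("ATOM", "HETATM")):
                continue
            names.append(line[12:16].strip())
            resnames.append(line[17:20].strip())
            chains.append(line[21].strip() or "A")
            resids.append(int(line[22:26]))
            xyz.append((float(line[30:38]), float(line[38:46]), float(line[46:54])))
    if not names:
        raise ValueError(f"{path}: no ATOM/HETATM records")
    return Structure3D(names, resnames, chains, np.array(resids), np.array(xyz), source="pdb_file")


def write_pdb(structure: Structure3D, path: str | Path) -> None:
    """Write a minimal PDB file (3-decimal coordinate precision)."""
    with open(path, "w") as fh:
        for k in range(len(structure)):
            name = structure.atom_names[k]
            pad = name if len(name) >= 4 else f" {name:<3s}"
            x, y, z = structure.coords[k]
            fh.write(
                f"ATOM  {k + 1:5d} {pad:<4s} {structure.residue_names[k]:<3s} "
                f"{structure.chain_ids[k]:1s}{structure.residue_indices[k]:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00\n"
            )
        fh.write("END\n")


# ---------------------------------------------------------------------------
# coarse embedding of folded aptamers

@dataclass(frozen=True)
class EmbedGeometry:
    """Idealised B-form geometry for the one-bead-per-nucleotide model."""

    rise: float = 3.4          # A per base pair along the helix axis
    twist: float = 36.0        # deg per base pair
    radius: float = 10.0       # helix radius (diameter ~ 20 A)
    backbone_step: float = 6.5  # A between consecutive unpaired beads
    strand_phase: float = 180.0  # deg between paired strands


def embed_coarse_3d(
    fold: FoldResult,
    geometry: EmbedGeometry = EmbedGeometry(),
    chain_id: str = "X",
) -> Structure3D:
    """One pseudo-atom per nucleotide from a secondary structure.

    Maximal helical stems are laid out as ideal B-form double helices
    (paired partners sit across the axis at the helix diameter);
    unpaired stretches continue as an extended chain. The layout is a
    deterministic function of the fold — it is a shape proxy for
    docking, not a tertiary-structure prediction.
    """
    n = fold.structure.length
    partner = {}
    for i, j in fold.structure.pairs:
        partner[i - 1] = j - 1
        partner[j - 1] = i - 1
    coords = np.zeros((n, 3))
    placed = np.zeros(n, dtype=bool)
    cursor = np.zeros(3)
    g = geometry
    i = 0
    while i < n:
        if placed[i]:
            cursor = coords[i].copy()
            i += 1
            continue
        j = partner.get(i)
        if j is not None and j > i:
            # maximal stem starting at (i, j)
            k = 0
            while (
                i + k + 1 < j - k - 1
                and partner.get(i + k + 1) == j - k - 1
            ):
                k += 1
            origin = cursor + np.array([g.backbone_step, 0.0, 0.0])
            phase = np.deg2rad(g.strand_phase)
            for t in range(k + 1):
                th = np.deg2rad(g.twist) * t
                coords[i + t] = origin + np.array(
                    [g.radius * np.cos(th), g.radius * np.sin(th), g.rise * t]
                )
                coords[j - t] = origin + np.array(
                    [g.radius * np.cos(th + phase), g.radius * np.sin(th + phase), g.rise * t]
                )
                placed[i + t] = placed[j - t] = True
            cursor = coords[i + k].copy()
            i = i + k + 1
        else:
            coords[i] = cursor + np.array([g.backbone_step, 0.0, 0.0])
            placed[i] = True
            cursor = coords[i].copy()
            i += 1
    return Structure3D(
        atom_names=["P"] * n,
        residue_names=[f"D{b}" for b in fold.sequence.bases],
        chain_ids=[chain_id] * n,
        residue_indices=np.arange(1, n + 1),
        coords=coords,
        source="coarse_embedding",
    )


# ---------------------------------------------------------------------------
# voxelisation and FFT docking

@dataclass
class VoxelGrid:
    """Occupancy grid; ``origin`` is the centre of voxel (0,0,0)."""

    origin: np.ndarray
    spacing: float
    occupied: np.ndarray  # bool (nx, ny, nz)
    surface: np.ndarray   # bool subset of occupied
    interior: np.ndarray  # occupied minus surface
    interior_weight: float
    surface_weight: float

    @property
    def weights(self) -> np.ndarray:
        return (
            self.surface_weight * self.surface.astype(float)
            + self.interior_weight * self.interior.astype(float)
        )


def voxelize(
    structure: Structure3D,
    spacing: float = 2.0,
    radius: float = 2.0,
    interior_weight: float = 1.0,
    surface_weight: float = 1.0,
    padding: float = 0.0,
) -> VoxelGrid:
    """Mark voxels whose centre lies within ``radius`` of any atom.

    Surface voxels are occupied voxels with at least one unoccupied
    6-neighbour (grid-boundary voxels count as surface); the rest of
    the occupancy is interior. A single-atom structure yields a small
    centred blob, never an error.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    lo = structure.coords.min(axis=0)
    hi = structure.coords.max(axis=0)
    # whole-voxel padding keeps the lattice anchored on the structure
    # minimum, so translating a structure by its own spacing shifts the
    # grid contents not the geometry
    pad_cells = int(np.ceil((radius + padding) / spacing))
    origin = lo - pad_cells * spacing
    shape = np.maximum(
        np.ceil((hi - origin + radius + padding) / spacing).astype(int) + 1, 1
    )
    occ = np.zeros(shape, dtype=bool)
    # vectorised per-atom stamping
    r_vox = int(np.ceil(radius / spacing))
    offs = np.arange(-r_vox, r_vox + 1)
    ox, oy, oz = np.meshgrid(offs, offs, offs, indexing="ij")
    cell = np.stack([ox, oy, oz], axis=-1).reshape(-1, 3)
    for atom in structure.coords:
        centre_idx = np.round((atom - origin) / spacing).astype(int)
        cand = centre_idx + cell
        ok = np.all((cand >= 0) & (cand < shape), axis=1)
        cand = cand[ok]
        centres = origin + cand * spacing
        near = np.linalg.norm(centres - atom, axis=1) <= radius
        sel = cand[near]
        occ[sel[:, 0], sel[:, 1], sel[:, 2]] = True
    interior = occ.copy()
    for axis in range(3):
        for shift in (1, -1):
            rolled = np.zeros_like(occ)
            src = [slice(None)] * 3
            dst = [slice(None)] * 3
            if shift == 1:
                src[axis] = slice(0, -1)
                dst[axis] = slice(1, None)
            else:
                src[axis] = slice(1, None)
                dst[axis] = slice(0, -1)
            rolled[tuple(dst)] = occ[tuple(src)]
            interior &= rolled
    surface = occ & ~interior
    return VoxelGrid(
        origin=origin,
        spacing=spacing,
        occupied=occ,
        surface=surface,
        interior=interior,
        interior_weight=interior_weight,
        surface_weight=surface_weight,
    )


@dataclass(frozen=True)
class DockPose:
    """A scored rigid placement of the ligand on the receptor."""

    rotation_index: int
    rotation: np.ndarray          # quaternion (x, y, z, w)
    translation: Tuple[int, int, int]  # voxel offset, ligand grid -> receptor grid
    shift_angstrom: np.ndarray    # apply after rotating about the ligand centroid
    score: float


_ROTATION_POOL_SIZE = 576
_ROTATION_SEED = 20030  # fixed so rotation sets are nested and reproducible


def rotation_set(n: int) -> List[Rotation]:
    """First ``n`` of a fixed pool of orientations (identity first).

    Drawing prefixes of one deterministic pool makes enlarging the set
    a pure refinement: the best score can only improve.
    """
    if n < 1:
        raise ValueError("rotation set must contain at least one rotation")
    if n > _ROTATION_POOL_SIZE:
        raise ValueError(f"rotation pool holds {_ROTATION_POOL_SIZE} orientations")
    pool = [Rotation.identity()]
    pool.extend(
        Rotation.random(_ROTATION_POOL_SIZE - 1, random_state=_ROTATION_SEED)
    )
    return pool[:n]


# receptor weighting: reward surface contact, punish core clash
RECEPTOR_INTERIOR_WEIGHT = -9.0
RECEPTOR_SURFACE_WEIGHT = 1.0


def receptor_docking_weights(
    grid: VoxelGrid,
    surface_weight: float = RECEPTOR_SURFACE_WEIGHT,
    clash_weight: float = RECEPTOR_INTERIOR_WEIGHT,
) -> np.ndarray:
    """Complementarity weights for the receptor side.

    The favourable region is the empty *contact layer* — unoccupied
    voxels 6-adjacent to the receptor — so a ligand nestling into a
    pocket collects one reward per wall contact; any overlap with the
    receptor body itself is a clash penalty.
    """
    from scipy.ndimage import binary_dilation

    struct = np.zeros((3, 3, 3), dtype=bool)
    struct[1, 1, :] = struct[1, :, 1] = struct[:, 1, 1] = True
    contact = binary_dilation(grid.occupied, structure=struct) & ~grid.occupied
    return surface_weight * contact.astype(float) + clash_weight * grid.occupied.astype(float)


def correlate_grids(receptor: np.ndarray, ligand: np.ndarray) -> np.ndarray:
    """Full cross-correlation: out[d] = sum_v receptor[v + d] * ligand[v].

    Index ``d + (ligand.shape - 1)`` in the returned array corresponds
    to voxel displacement ``d`` (which may be negative).
    """
    return fftconvolve(receptor, ligand[::-1, ::-1, ::-1], mode="full")


def brute_force_correlate(receptor: np.ndarray, ligand: np.ndarray) -> np.ndarray:
    """Direct-sum equivalent of :func:`correlate_grids` (test oracle).

    Loops explicitly over every displacement and sums the overlapping
    products — no Fourier transform anywhere.
    """
    rs, ls = receptor.shape, ligand.shape
    out = np.zeros(tuple(np.array(rs) + np.array(ls) - 1))

    def _ranges(d: int, rn: int, ln: int):
        r0, l0 = max(0, d), max(0, -d)
        span = min(rn - r0, ln - l0)
        return r0, l0, span

    for dx in range(-(ls[0] - 1), rs[0]):
        rx, lx, sx = _ranges(dx, rs[0], ls[0])
        for dy in range(-(ls[1] - 1), rs[1]):
            ry, ly, sy = _ranges(dy, rs[1], ls[1])
            for dz in range(-(ls[2] - 1), rs[2]):
                rz, lz, sz = _ranges(dz, rs[2], ls[2])
                if min(sx, sy, sz) <= 0:
                    continue
                total = np.sum(
                    receptor[rx : rx + sx, ry : ry + sy, rz : rz + sz]
                    * ligand[lx : lx + sx, ly : ly + sy, lz : lz + sz]
                )
                out[dx + ls[0] - 1, dy + ls[1] - 1, dz + ls[2] - 1] = total
    return out


def fft_shape_dock(
    receptor: VoxelGrid,
    ligand: Structure3D,
    rotations: Sequence[Rotation] | None = None,
    top_n: int = 10,
    spacing: float | None = None,
    ligand_radius: float = 2.0,
) -> List[DockPose]:
    """Score all rigid placements of ``ligand`` on ``receptor``.

    For every rotation the ligand is re-voxelised and every translation
    scored by FFT cross-correlation of the complementarity weights;
    the ``top_n`` poses are returned in descending score order with a
    deterministic tie-break (rotation index, then offset). The first
    pose's score is the candidate's docking fitness.
    """
    rotations = list(rotations) if rotations is not None else rotation_set(96)
    if not rotations:
        raise ValueError("rotation set is empty")
    spacing = spacing if spacing is not None else receptor.spacing
    if abs(spacing - receptor.spacing) > 1e-9:
        raise ValueError("ligand spacing must match the receptor grid")
    rw = receptor_docking_weights(receptor)
    centroid = ligand.coords.mean(axis=0)
    poses: List[DockPose] = []
    for ridx, rot in enumerate(rotations):
        rotated = replace(
            ligand, coords=rot.apply(ligand.coords - centroid) + centroid
        )
        lg = voxelize(
            rotated, spacing=spacing, radius=ligand_radius,
            interior_weight=1.0, surface_weight=1.0,
        )
        corr = correlate_grids(rw, lg.weights)
        ls = np.array(lg.weights.shape)
        flat = np.argsort(corr, axis=None, kind="stable")[::-1][: top_n]
        for fidx in flat:
            idx = np.array(np.unravel_index(fidx, corr.shape))
            d = idx - (ls - 1)
            shift = receptor.origin - lg.origin + d * spacing
            poses.append(
                DockPose(
                    rotation_index=ridx,
                    rotation=rot.as_quat(),
                    translation=tuple(int(x) for x in d),
                    shift_angstrom=shift,
                    score=float(corr[tuple(idx)]),
                )
            )
    poses.sort(key=lambda p: (-p.score, p.rotation_index, p.translation))
    return poses[:top_n]


def best_docking_score(
    receptor: VoxelGrid,
    ligand: Structure3D,
    rotations: Sequence[Rotation] | None = None,
) -> float:
    return fft_shape_dock(receptor, ligand, rotations, top_n=1)[0].score


def make_shape_fitness(
    receptor: Structure3D,
    model: EnergyModel | None = None,
    n_rotations: int = 16,
    spacing: float = 2.0,
    geometry: EmbedGeometry = EmbedGeometry(),
) -> Callable[[NucleotideSequence], float]:
    """Fitness for the evolution loop: fold, embed, dock, best score."""
    m = model if model is not None else build_energy_model()
    grid = voxelize(
        receptor, spacing=spacing,
        interior_weight=RECEPTOR_INTERIOR_WEIGHT,
        surface_weight=RECEPTOR_SURFACE_WEIGHT,
    )
    rots = rotation_set(n_rotations)

    def fitness(seq: NucleotideSequence) -> float:
        fold = fold_mfe(seq, model=m)
        ligand = embed_coarse_3d(fold, geometry)
        return best_docking_score(grid, ligand, rots)

    return fitness


# ---------------------------------------------------------------------------
# hydrogen-bond profiling

@dataclass(frozen=True)
class ContactRecord:
    donor: Tuple[str, int, str]     # chain, residue index, atom
    acceptor: Tuple[str, int, str]
    distance: float                 # donor-acceptor, A
    angle: float                    # D-H...A, deg
    type: str = "hydrogen_bond"


def _is_polar(name: str) -> bool:
    return name[:1] in ("N", "O")


def detect_hbonds(
    complex_structure: Structure3D,
    aptamer_chain: str,
    receptor_chain: str,
    dist_cutoff: float = 3.5,
    angle_cutoff: float = 120.0,
    h_bond_length: float = 1.3,
) -> List[ContactRecord]:
    """Inter-chain hydrogen bonds by geometric criteria.

    Donors are polar heavy atoms (N/O by name) carrying an explicit
    hydrogen within ``h_bond_length`` in the same residue; acceptors
    are polar heavy atoms on the other chain. A contact requires
    donor-acceptor distance <= ``dist_cutoff`` and D-H...A angle >=
    ``angle_cutoff``. Records are sorted by donor residue index.
    """
    chains = {aptamer_chain, receptor_chain}
    for c in chains:
        if c not in complex_structure.chain_ids:
            raise KeyError(f"chain {c!r} missing from complex")
    n = len(complex_structure)
    contacts: List[ContactRecord] = []
    coords = complex_structure.coords
    for d in range(n):
        dchain = complex_structure.chain_ids[d]
        if dchain not in chains or not _is_polar(complex_structure.atom_names[d]):
            continue
        # explicit hydrogens on the same residue
        hydrogens = [
            h for h in range(n)
            if complex_structure.atom_names[h].startswith("H")
            and complex_structure.chain_ids[h] == dchain
            and complex_structure.residue_indices[h] == complex_structure.residue_indices[d]
            and np.linalg.norm(coords[h] - coords[d]) <= h_bond_length
        ]
        if not hydrogens:
            continue
        other = receptor_chain if dchain == aptamer_chain else aptamer_chain
        for a in range(n):
            if complex_structure.chain_ids[a] != other or not _is_polar(complex_structure.atom_names[a]):
                continue
            dist = float(np.linalg.norm(coords[a] - coords[d]))
            if dist > dist_cutoff:
                continue
            for h in hydrogens:
                v1 = coords[d] - coords[h]
                v2 = coords[a] - coords[h]
                denom = np.linalg.norm(v1) * np.linalg.norm(v2)
                if denom == 0:
                    continue
                angle = float(np.degrees(np.arccos(np.clip(np.dot(v1, v2) / denom, -1, 1))))
                if angle >= angle_cutoff:
                    contacts.append(
                        ContactRecord(
                            donor=(dchain, int(complex_structure.residue_indices[d]), complex_structure.atom_names[d]),
                            acceptor=(other, int(complex_structure.residue_indices[a]), complex_structure.atom_names[a]),
                            distance=dist,
                            angle=angle,
                        )
                    )
                    break
    contacts.sort(key=lambda c: (c.donor[1], c.acceptor[1]))
    return contacts


def write_contacts(contacts: Sequence[ContactRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("donor_chain\tdonor_res\tdonor_atom\tacceptor_chain\tacceptor_res\tacceptor_atom\tdistance_A\tangle_deg\ttype\n")
        for c in contacts:
            fh.write(
                f"{c.donor[0]}\t{c.donor[1]}\t{c.donor[2]}\t{c.acceptor[0]}\t{c.acceptor[1]}\t{c.acceptor[2]}\t"
                f"{c.distance:.2f}\t{c.angle:.1f}\t{c.type}\n"
            )


# ---------------------------------------------------------------------------
# external docking-score adapter

def import_external_scores(csv_path: str | Path) -> Callable[[NucleotideSequence], float]:
    """Lookup-backed fitness from a CSV of externally computed scores.

    The table needs a ``score`` column and either ``sequence_id`` or
    ``bases`` (or both). Unknown sequences raise; duplicate rows are
    tolerated only when their scores agree.
    """
    df = pd.read_csv(csv_path)
    if "score" not in df.columns:
        raise ValueError(f"{csv_path}: missing 'score' column")
    keys = [c for c in ("sequence_id", "bases") if c in df.columns]
    if not keys:
        raise ValueError(f"{csv_path}: need a 'sequence_id' or 'bases' column")
    table: dict = {}
    for _, row in df.iterrows():
        for key in keys:
            k = str(row[key]).strip()
            if k in table and abs(table[k] - float(row["score"])) > 1e-9:
                raise ValueError(f"{csv_path}: conflicting scores for {k!r}")
            table[k] = float(row["score"])

    def fitness(seq: NucleotideSequence) -> float:
        for k in (seq.bases, seq.id):
            if k in table:
                return table[k]
        raise KeyError(f"no external score for sequence {seq.id!r}")

    return fitness


def write_pose_report(poses: Sequence[DockPose], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("rank\tscore\trotation_index\toffset_x\toffset_y\toffset_z\n")
        for rank, p in enumerate(poses, start=1):
            fh.write(
                f"{rank}\t{p.score:.6f}\t{p.rotation_index}\t{p.translation[0]}\t{p.translation[1]}\t{p.translation[2]}\n"
            )
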