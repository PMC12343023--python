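"""Atom-space molecule representation, file I/O and the toy dataset.

A molecule is represented as ``G = (x, h)``: 3D coordinates ``x`` (N x 3, in
angstroms) together with per-atom scalar features ``h`` (one-hot element type
plus formal charge). This module also provides the empirical molecule-size
distribution ``p(N)`` used at sampling time, and a generator of small
idealized organic molecules (<= 9 atoms over H/C/N/O/F) that serves as a
self-contained stand-in for a real training set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem  # noqa: F401  (registers conformer code)
from rdkit.Geometry import Point3D
from scipy.spatial.transform import Rotation

DEFAULT_ALPHABET: tuple[str, ...] = ("H", "C", "N", "O", "F")


class MoleculeParseError(ValueError):
    """Raised when a molecule record cannot be parsed or validated."""


@dataclass
class MoleculeGraph:
    """3D molecular graph: positions in angstroms, element symbols, charges.

    ``condition`` optionally carries a scalar property value used for
    conditional generation.
    """

    positions: np.ndarray
    atom_types: tuple[str, ...]
    charges: np.ndarray
    condition: float | None = None
    alphabet: tuple[str, ...] = DEFAULT_ALPHABET

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.float64)
        self.atom_types = tuple(self.atom_types)
        self.charges = np.asarray(self.charges, dtype=np.int64)
        n = len(self.atom_types)
        if n < 1:
            raise ValueError("molecule must contain at least one atom")
        if self.positions.shape != (n, 3):
            raise ValueError(
                f"positions shape {self.positions.shape} != ({n}, 3)")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite coordinates")
        if self.charges.shape != (n,):
            raise ValueError("charges length mismatch")
        bad = [t for t in self.atom_types if t not in self.alphabet]
        if bad:
            raise ValueError(f"atom types {bad} not in alphabet {self.alphabet}")
        if np.any(np.abs(self.charges) > 2):
            raise ValueError("formal charges must satisfy |q| <= 2")

    @property
    def num_atoms(self) -> int:
        return len(self.atom_types)


def center_molecule(mol: MoleculeGraph) -> MoleculeGraph:
    """Subtract the unweighted centroid so column means are exactly zero."""
    pos = mol.positions - mol.positions.mean(axis=0, keepdims=True)
    return replace(mol, positions=pos)


def featurize(mol: MoleculeGraph) -> np.ndarray:
    """Per-atom scalar features: one-hot element block + charge column."""
    k = len(mol.alphabet)
    h = np.zeros((mol.num_atoms, k + 1))
    for i, t in enumerate(mol.atom_types):
        h[i, mol.alphabet.index(t)] = 1.0
    h[:, k] = mol.charges
    return h


def defeaturize(h: np.ndarray, alphabet: Sequence[str] = DEFAULT_ALPHABET
                ) -> tuple[tuple[str, ...], np.ndarray]:
    """Inverse of :func:`featurize` on (possibly soft) features.

    Element = argmax over the one-hot block (ties resolved in alphabet
    order, which is numpy argmax's first-match rule); charge = nearest
    integer of the last column.
    """
    h = np.asarray(h, dtype=np.float64)
    k = len(alphabet)
    types = tuple(alphabet[i] for i in np.argmax(h[:, :k], axis=1))
    charges = np.rint(h[:, k]).astype(np.int64)
    return types, charges


# ---------------------------------------------------------------------------
# RDKit conversion and file I/O
# ---------------------------------------------------------------------------

def to_rdkit(mol: MoleculeGraph,
             bonds: Iterable[tuple[int, int, int]] | None = None) -> Chem.Mol:
    """Build an RDKit molecule (unsanitized) from positions/types/charges."""
    rw = Chem.RWMol()
    for sym, q in zip(mol.atom_types, mol.charges):
        atom = Chem.Atom(sym)
        atom.SetFormalCharge(int(q))
        atom.SetNoImplicit(True)
        rw.AddAtom(atom)
    order_map = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE,
                 3: Chem.BondType.TRIPLE}
    for i, j, order in bonds or ():
        rw.AddBond(int(i), int(j), order_map[order])
    conf = Chem.Conformer(mol.num_atoms)
    for i, (x, y, z) in enumerate(mol.positions):
        conf.SetAtomPosition(i, Point3D(float(x), float(y), float(z)))
    m = rw.GetMol()
    m.AddConformer(conf)
    return m


def from_rdkit(rdmol: Chem.Mol, alphabet: Sequence[str] = DEFAULT_ALPHABET
               ) -> MoleculeGraph:
    conf = rdmol.GetConformer()
    n = rdmol.GetNumAtoms()
    pos = np.array([[conf.GetAtomPosition(i).x, conf.GetAtomPosition(i).y,
                     conf.GetAtomPosition(i).z] for i in range(n)])
    types = tuple(a.GetSymbol() for a in rdmol.GetAtoms())
    charges = np.array([a.GetFormalCharge() for a in rdmol.GetAtoms()])
    return MoleculeGraph(pos, types, charges, alphabet=tuple(alphabet))


def _split_xyz_records(text: str) -> list[tuple[int, str]]:
    """Split a (possibly multi-record) XYZ file into (line_no, block) pairs."""
    lines = text.splitlines()
    records = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError as exc:
            raise MoleculeParseError(
                f"line {i + 1}: expected atom count, got {lines[i]!r}") from exc
        block = lines[i:i + n + 2]
        if len(block) < n + 2:
            raise MoleculeParseError(
                f"line {i + 1}: truncated XYZ record (need {n} atoms)")
        records.append((i + 1, "\n".join(block) + "\n"))
        i += n + 2
    return records


def read_molecules(path: str | Path, format: str | None = None,
                   alphabet: Sequence[str] = DEFAULT_ALPHABET
                   ) -> list[MoleculeGraph]:
    """Read molecules from an XYZ or SDF (V2000) file.

    XYZ carries no charge information, so charges default to zero; SDF
    formal charges are preserved. Raises :class:`MoleculeParseError`
    naming the file, record index and (for XYZ) line on bad input.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    mols: list[MoleculeGraph] = []
    if fmt == "xyz":
        for rec_idx, (line_no, block) in enumerate(
                _split_xyz_records(path.read_text())):
            rd = Chem.MolFromXYZBlock(block)
            if rd is None or rd.GetNumAtoms() == 0:
                raise MoleculeParseError(
                    f"{path}: record {rec_idx} (line {line_no}): unparseable XYZ")
            try:
                mols.append(from_rdkit(rd, alphabet))
            except ValueError as exc:
                raise MoleculeParseError(
                    f"{path}: record {rec_idx} (line {line_no}): {exc}") from exc
    elif fmt == "sdf":
        if path.stat().st_size == 0:
            return []
        supplier = Chem.SDMolSupplier(str(path), sanitize=False, removeHs=False)
        for rec_idx, rd in enumerate(supplier):
            if rd is None:
                raise MoleculeParseError(
                    f"{path}: record {rec_idx}: unparseable SDF record")
            try:
                mols.append(from_rdkit(rd, alphabet))
            except ValueError as exc:
                raise MoleculeParseError(
                    f"{path}: record {rec_idx}: {exc}") from exc
    else:
        raise ValueError(f"unknown format {fmt!r} (expected 'xyz' or 'sdf')")
    return mols


def write_molecules(mols: Sequence[MoleculeGraph], path: str | Path,
                    format: str | None = None) -> None:
    """Write molecules to XYZ or SDF V2000. An empty sequence yields a
    valid empty file."""
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "xyz":
        parts = []
        for mol in mols:
            body = "\n".join(
                f"{t} {x:.6f} {y:.6f} {z:.6f}"
                for t, (x, y, z) in zip(mol.atom_types, mol.positions))
            parts.append(f"{mol.num_atoms}\n\n{body}\n")
        path.write_text("".join(parts))
    elif fmt == "sdf":
        writer = Chem.SDWriter(str(path))
        try:
            for mol in mols:
                writer.write(to_rdkit(mol))
        finally:
            writer.close()
    else:
        raise ValueError(f"unknown format {fmt!r} (expected 'xyz' or 'sdf')")


# ---------------------------------------------------------------------------
# Molecule-size distribution p(N)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AtomCountDistribution:
    """Empirical categorical distribution over molecule sizes, p(N)."""

    support: tuple[int, ...]
    probabilities: tuple[float, ...] = field(default=())

    def __post_init__(self):
        if len(self.support) != len(self.probabilities):
            raise ValueError("support/probabilities length mismatch")
        if any(s < 1 for s in self.support):
            raise ValueError("molecule sizes must be positive")
        if abs(sum(self.probabilities) - 1.0) > 1e-12:
            raise ValueError("probabilities must sum to 1")

    def to_dict(self) -> dict[int, float]:
        return dict(zip(self.support, self.probabilities))


def atom_count_distribution(mols: Sequence[MoleculeGraph]) -> AtomCountDistribution:
    """Traverse a dataset and tabulate the empirical p(N)."""
    if not mols:
        raise ValueError("cannot estimate p(N) from an empty dataset")
    sizes = np.array([m.num_atoms for m in mols])
    support, counts = np.unique(sizes, return_counts=True)
    probs = counts / counts.sum()
    return AtomCountDistribution(tuple(int(s) for s in support),
                                 tuple(float(p) for p in probs))


def sample_num_atoms(dist: AtomCountDistribution,
                     rng: np.random.Generator) -> int:
    return int(rng.choice(dist.support, p=dist.probabilities))


# ---------------------------------------------------------------------------
# Toy molecule templates (idealized geometries)
# ---------------------------------------------------------------------------

def _methyl_dirs(axis_phi: tuple[float, ...]) -> np.ndarray:
    """Unit vectors at the tetrahedral angle from -z, azimuths in degrees."""
    theta = math.radians(180.0 - 109.471)  # polar angle measured from +z
    return np.array([
        [math.sin(theta) * math.cos(math.radians(p)),
         math.sin(theta) * math.sin(math.radians(p)),
         math.cos(theta)] for p in axis_phi])


def _build_templates() -> dict[str, MoleculeGraph]:
    t: dict[str, MoleculeGraph] = {}

    def add(name, types, pos):
        t[name] = MoleculeGraph(np.asarray(pos, float), tuple(types),
                                np.zeros(len(types), int))

    # hydrogen fluoride: r(H-F) = 0.92
    add("hydrogen_fluoride", "HF", [[0, 0, 0], [0.92, 0, 0]])

    # water: r(O-H) = 0.96, angle H-O-H = 104.5 deg
    a = math.radians(104.5)
    add("water", "OHH", [[0, 0, 0], [0.96, 0, 0],
                         [0.96 * math.cos(a), 0.96 * math.sin(a), 0]])

    # ammonia: r(N-H) = 1.01, angle H-N-H = 107 deg
    cos_hnh = math.cos(math.radians(107.0))
    cos_th = math.sqrt((1.0 + 2.0 * cos_hnh) / 3.0)
    sin_th = math.sqrt(1.0 - cos_th ** 2)
    nh = [[1.01 * sin_th * math.cos(math.radians(p)),
           1.01 * sin_th * math.sin(math.radians(p)), 1.01 * cos_th]
          for p in (0.0, 120.0, 240.0)]
    add("ammonia", "NHHH", [[0, 0, 0]] + nh)

    # methane: tetrahedral, r(C-H) = 1.09
    tet = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]]) / math.sqrt(3)
    add("methane", "CHHHH", np.vstack([[0, 0, 0], 1.09 * tet]))

    # hydrogen cyanide: r(H-C) = 1.07, r(C#N) = 1.16 (linear)
    add("hydrogen_cyanide", "HCN", [[0, 0, 0], [1.07, 0, 0], [2.23, 0, 0]])

    # formaldehyde: r(C=O) = 1.20, r(C-H) = 1.09, angle H-C-O = 122 deg
    b = math.radians(122.0)
    add("formaldehyde", "COHH",
        [[0, 0, 0], [1.20, 0, 0],
         [1.09 * math.cos(b), 1.09 * math.sin(b), 0],
         [1.09 * math.cos(b), -1.09 * math.sin(b), 0]])

    # ethene: r(C=C) = 1.34, r(C-H) = 1.086, angle H-C-C = 121.3 deg (planar)
    c = math.radians(121.3)
    h = np.array([1.086 * math.cos(c), 1.086 * math.sin(c), 0.0])
    c1, c2 = np.array([-0.67, 0, 0]), np.array([0.67, 0, 0])
    add("ethene", "CCHHHH",
        [c1, c2, c1 + h, c1 + h * [1, -1, 1], c2 - h, c2 - h * [1, -1, 1]])

    # methanol: r(C-O) = 1.43, r(C-H) = 1.09, r(O-H) = 0.96,
    # angle C-O-H = 108.5 deg, methyl tetrahedral about the C-O axis
    o = np.array([0.0, 0.0, 1.43])
    d = math.radians(108.5)
    oh = o + 0.96 * np.array([math.sin(d), 0.0, -math.cos(d)])
    ch = 1.09 * _methyl_dirs((60.0, 180.0, 300.0))
    add("methanol", "COHHHH", np.vstack([[0, 0, 0], o, oh, ch]))

    # ethane: r(C-C) = 1.54, r(C-H) = 1.09, staggered
    c1, c2 = np.array([0, 0, 0.77]), np.array([0, 0, -0.77])
    h1 = c1 + 1.09 * _methyl_dirs((0.0, 120.0, 240.0))
    h2 = c2 - 1.09 * _methyl_dirs((60.0, 180.0, 300.0))
    add("ethane", "CCHHHHHH", np.vstack([c1, c2, h1, h2]))

    return t


TOY_TEMPLATES: dict[str, MoleculeGraph] = _build_templates()


def generate_toy_dataset(n: int, seed: int | np.random.Generator,
                         jitter_sd: float = 0.0,
                         translation_sd: float = 2.0) -> list[MoleculeGraph]:
    """Draw ``n`` idealized molecules, each under a random rigid motion.

    Each molecule is a uniformly chosen template, rotated by a uniform
    random rotation, translated by an isotropic Gaussian offset
    (sd ``translation_sd`` angstroms) and perturbed with i.i.d. Gaussian
    coordinate jitter of sd ``jitter_sd`` angstroms. Deterministic given
    the seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    names = sorted(TOY_TEMPLATES)
    out = []
    for _ in range(n):
        tpl = TOY_TEMPLATES[names[rng.integers(len(names))]]
        rot = Rotation.random(rng=rng).as_matrix()
        pos = tpl.positions @ rot.T
        pos = pos + rng.normal(scale=translation_sd, size=(1, 3))
        if jitter_sd > 0:
            pos = pos + rng.normal(scale=jitter_sd, size=pos.shape)
        out.append(replace(tpl, positions=pos))
    return out
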