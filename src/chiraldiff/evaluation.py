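"""Valence-based sample-quality metrics.

Generated molecules carry no bond information: bonds are inferred from
interatomic distances against a reference table of covalent bond lengths
(one window per element pair and bond order). An atom is *stable* when its
inferred bond orders sum to an allowed valence for its element and formal
charge; a molecule is stable when every atom is. *Validity* asks whether
the inferred connection table sanitizes under RDKit, and *uniqueness*
counts first occurrences of the canonical SMILES among the valid samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
from rdkit import Chem
from rdkit import RDLogger

from .molgraph import MoleculeGraph, to_rdkit

logger = logging.getLogger(__name__)
RDLogger.DisableLog("rdApp.*")

# Base valence per element; formal-charge adjustment in `allowed_valence`.
DEFAULT_VALENCES: dict[str, int] = {"H": 1, "C": 4, "N": 3, "O": 2, "F": 1}


@dataclass(frozen=True)
class BondTable:
    """Reference bond-length windows and allowed valences.

    ``windows`` maps ``(elem_a, elem_b, order)`` (elements sorted) to
    ``(length, margin)`` in angstroms: a pair at distance ``d`` is assigned
    the highest order with ``|d - length| <= margin``.
    """

    windows: dict[tuple[str, str, int], tuple[float, float]]
    valences: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_VALENCES))

    def __post_init__(self):
        for (a, b, order), (length, margin) in self.windows.items():
            if length <= 0 or margin < 0:
                raise ValueError(f"bad window for {a}-{b} order {order}")
        for (a, b, _), _ in self.windows.items():
            lengths = [self.windows[k][0] for k in self.windows
                       if k[:2] == (a, b)]
            orders = [k[2] for k in self.windows if k[:2] == (a, b)]
            by_order = sorted(zip(orders, lengths))
            for (o1, l1), (o2, l2) in zip(by_order, by_order[1:]):
                if l2 >= l1:
                    raise ValueError(
                        f"{a}-{b}: order {o2} length {l2} not shorter than "
                        f"order {o1} length {l1}")

    def lookup(self, elem_a: str, elem_b: str, order: int
               ) -> tuple[float, float] | None:
        key = (*sorted((elem_a, elem_b)), order)
        return self.windows.get(key)

    def allowed_valence(self, element: str, charge: int = 0) -> int | None:
        """Allowed bond-order sum for an element with a formal charge.

        Nitrogen and oxygen gain/lose a bond with charge (N+ binds 4,
        O- binds 1); for the remaining elements a charge removes a bond.
        """
        base = self.valences.get(element)
        if base is None:
            return None
        if element in ("N", "O"):
            return base + charge
        return base - abs(charge)


def load_bond_table(path: str | Path | None = None) -> BondTable:
    """Load the bond table from a TSV resource (default: bundled table)."""
    if path is None:
        text = (resources.files("chiraldiff.data") / "bond_table.tsv").read_text()
    else:
        text = Path(path).read_text()
    windows = {}
    for line_no, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 5:
            raise ValueError(f"bond table line {line_no}: expected 5 columns")
        a, b, order, length, margin = parts
        windows[(*sorted((a, b)), int(order))] = (float(length), float(margin))
    return BondTable(windows)


_warned_pairs: set[tuple[str, str]] = set()


def infer_bonds(mol: MoleculeGraph, table: BondTable
                ) -> list[tuple[int, int, int]]:
    """Assign bond orders from interatomic distances.

    Each unordered atom pair receives the highest order whose window
    contains the distance; pairs matching no window get no bond. Element
    pairs absent from the table are treated as never bonded (logged once).
    """
    bonds = []
    pos = mol.positions
    for i in range(mol.num_atoms):
        for j in range(i + 1, mol.num_atoms):
            ei, ej = mol.atom_types[i], mol.atom_types[j]
            if not any(table.lookup(ei, ej, o) for o in (1, 2, 3)):
                key = tuple(sorted((ei, ej)))
                if key not in _warned_pairs:
                    _warned_pairs.add(key)
                    logger.warning("element pair %s-%s absent from bond table; "
                                   "treated as never bonded", *key)
                continue
            d = float(np.linalg.norm(pos[i] - pos[j]))
            for order in (3, 2, 1):
                win = table.lookup(ei, ej, order)
                if win is not None and abs(d - win[0]) <= win[1]:
                    bonds.append((i, j, order))
                    break
    return bonds


def atom_stability(mol: MoleculeGraph, bonds: Sequence[tuple[int, int, int]],
                   table: BondTable) -> tuple[int, float, np.ndarray]:
    """Count atoms whose summed bond order equals an allowed valence.

    Returns (number stable, fraction, per-atom boolean mask).
    """
    order_sum = np.zeros(mol.num_atoms, dtype=np.int64)
    for i, j, order in bonds:
        order_sum[i] += order
        order_sum[j] += order
    stable = np.zeros(mol.num_atoms, dtype=bool)
    for i, (elem, q) in enumerate(zip(mol.atom_types, mol.charges)):
        allowed = table.allowed_valence(elem, int(q))
        stable[i] = allowed is not None and order_sum[i] == allowed
    n = int(stable.sum())
    return n, n / mol.num_atoms, stable


def molecule_stability(mols: Sequence[MoleculeGraph],
                       bonds_per_mol: Sequence[Sequence[tuple[int, int, int]]],
                       table: BondTable) -> float:
    """Fraction of molecules in which every atom is stable."""
    flags = [bool(atom_stability(m, b, table)[2].all())
             for m, b in zip(mols, bonds_per_mol)]
    return float(np.mean(flags))


def _canonical_smiles(mol: MoleculeGraph,
                      bonds: Sequence[tuple[int, int, int]]) -> str | None:
    """Canonical SMILES of the inferred bond graph, or None if sanitization
    fails (invalid molecule)."""
    try:
        rd = to_rdkit(mol, bonds=bonds)
        Chem.SanitizeMol(rd)
        return Chem.MolToSmiles(rd)
    except Exception:
        return None


def validity_uniqueness(mols: Sequence[MoleculeGraph],
                        bonds_per_mol: Sequence[Sequence[tuple[int, int, int]]],
                        ) -> tuple[float, float]:
    """Fractions of valid, and valid-and-unique, molecules.

    Valid = the inferred connection table sanitizes; unique = first
    occurrence of its canonical SMILES among the valid. Both fractions
    use the full sample count as denominator.
    """
    if not mols:
        raise ValueError("validity/uniqueness undefined for an empty sample set")
    smiles = [_canonical_smiles(m, b) for m, b in zip(mols, bonds_per_mol)]
    n = len(mols)
    n_valid = sum(s is not None for s in smiles)
    seen: set[str] = set()
    n_unique = 0
    for s in smiles:
        if s is not None and s not in seen:
            seen.add(s)
            n_unique += 1
    return n_valid / n, n_unique / n


@dataclass
class StabilityReport:
    """Aggregate sample-quality metrics, optionally mean +/- sd over
    repeated sample batches."""

    atom_stability: float
    molecule_stability: float
    validity: float
    valid_and_unique: float
    n_molecules: int
    n_atoms: int
    per_molecule_stable: list[bool]
    sd: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.valid_and_unique > self.validity + 1e-12:
            raise ValueError("valid_and_unique cannot exceed validity")

    def as_dict(self) -> dict[str, float]:
        out = {"atom_stability": self.atom_stability,
               "molecule_stability": self.molecule_stability,
               "validity": self.validity,
               "valid_and_unique": self.valid_and_unique}
        for k, v in self.sd.items():
            out[f"{k}_sd"] = v
        return out

    def to_text(self) -> str:
        lines = [f"molecules evaluated: {self.n_molecules}",
                 f"atoms evaluated:     {self.n_atoms}"]
        for k, v in self.as_dict().items():
            if not k.endswith("_sd"):
                sd = self.sd.get(k)
                tail = f" +/- {sd:.4f}" if sd is not None else ""
                lines.append(f"{k:20s} {v:.4f}{tail}")
        return "\n".join(lines)


def _evaluate_flat(mols: Sequence[MoleculeGraph], table: BondTable
                   ) -> tuple[float, float, float, float, list[bool]]:
    bonds_per_mol = [infer_bonds(m, table) for m in mols]
    stats = [atom_stability(m, b, table) for m, b in zip(mols, bonds_per_mol)]
    n_stable = sum(s[0] for s in stats)
    n_atoms = sum(m.num_atoms for m in mols)
    per_mol = [bool(s[2].all()) for s in stats]
    validity, unique = validity_uniqueness(mols, bonds_per_mol)
    return n_stable / n_atoms, float(np.mean(per_mol)), validity, unique, per_mol


def evaluate_samples(mols: Sequence[MoleculeGraph],
                     table: BondTable | None = None,
                     batches: int = 1) -> StabilityReport:
    """Compute all four metrics over a sample set.

    With ``batches > 1`` the set is split into equal consecutive batches
    and each metric is reported as the batch mean, with the batch standard
    deviation in ``report.sd`` (the convention for reporting repeated
    sampling runs).
    """
    if not mols:
        raise ValueError("cannot evaluate an empty sample set")
    table = table or load_bond_table()
    if batches <= 1:
        a, m, v, u, per_mol = _evaluate_flat(mols, table)
        sd = {}
    else:
        idx = np.array_split(np.arange(len(mols)), batches)
        rows = [_evaluate_flat([mols[i] for i in part], table)[:4]
                for part in idx if len(part)]
        arr = np.array(rows)
        a, m, v, u = arr.mean(axis=0)
        keys = ["atom_stability", "molecule_stability", "validity",
                "valid_and_unique"]
        sd = dict(zip(keys, arr.std(axis=0, ddof=1) if len(rows) > 1
                      else np.zeros(4)))
        per_mol = _evaluate_flat(mols, table)[4]
    return StabilityReport(float(a), float(m), float(v), float(u),
                           len(mols), sum(x.num_atoms for x in mols),
                           per_mol, sd)
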