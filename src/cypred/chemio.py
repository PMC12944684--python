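"""Structure I/O: standardization, canonicalization, SMILES enumeration, scaffolds.

Every molecule entering the pipeline passes through :func:`standardize_structure`
once; downstream modules key everything on the canonical SMILES it produces.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem.MolStandardize import rdMolStandardize
from rdkit.Chem.Scaffolds import MurckoScaffold

RDLogger.DisableLog("rdApp.*")

#: scaffold key used for molecules without any ring system
EMPTY_SCAFFOLD = ""


class StandardizationError(ValueError):
    """Raised when a structure cannot be standardized.

    Attributes
    ----------
    reason : str
        Machine-readable reason code (``unparseable`` | ``empty``).
    """

    def __init__(self, reason: str, detail: str = ""):
        self.reason = reason
        super().__init__(f"{reason}: {detail}" if detail else reason)


@dataclass(frozen=True)
class RawRecord:
    """One raw (structure, measurement) pair as ingested from a source table."""

    source_id: str
    structure: str
    value: Any
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.source_id:
            raise ValueError("source_id must be non-empty")
        if not self.structure:
            raise ValueError("structure must be non-empty")


@dataclass(frozen=True)
class StandardMolecule:
    """A desalted, charge-normalized molecule with its canonical SMILES."""

    canonical: str
    parent_only: bool
    graph_handle: Chem.Mol

    @property
    def num_atoms(self) -> int:
        return self.graph_handle.GetNumAtoms()


_NORMALIZER = rdMolStandardize.Normalizer()


def _largest_organic_fragment(mol: Chem.Mol) -> tuple[Chem.Mol, bool]:
    """Keep the fragment with the most heavy atoms; canonical-SMILES order
    breaks ties.  Returns (fragment, stripped_anything)."""
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=True)
    if len(frags) == 1:
        return frags[0], False
    keyed = [(f.GetNumHeavyAtoms(), Chem.MolToSmiles(f), f) for f in frags]
    # largest heavy-atom count wins; ties resolved by canonical-string order
    keyed.sort(key=lambda t: (-t[0], t[1]))
    return keyed[0][2], True


def standardize_structure(raw: str) -> StandardMolecule:
    """Desalt, normalize and canonicalize a SMILES string.

    The largest organic fragment is retained (ties broken by canonical-string
    order), functional-group charges are normalized with the toolkit's
    standard rules, and the canonical serialization is computed.  The result
    is invariant to the input atom ordering and idempotent: re-standardizing
    the canonical string returns the identical canonical string.

    Raises
    ------
    StandardizationError
        With reason code ``unparseable`` if the string is not valid SMILES,
        or ``empty`` for empty/whitespace input.
    """
    if raw is None or not str(raw).strip():
        raise StandardizationError("empty")
    mol = Chem.MolFromSmiles(str(raw))
    if mol is None:
        raise StandardizationError("unparseable", str(raw))
    if mol.GetNumAtoms() == 0:
        raise StandardizationError("empty", str(raw))
    parent, stripped = _largest_organic_fragment(mol)
    parent = _NORMALIZER.normalize(parent)
    Chem.SanitizeMol(parent)
    canonical = Chem.MolToSmiles(parent)
    # reparse so graph_handle corresponds exactly to the canonical string
    handle = Chem.MolFromSmiles(canonical)
    return StandardMolecule(canonical=canonical, parent_only=stripped, graph_handle=handle)


def enumerate_random_smiles(mol: StandardMolecule, n: int, seed: int) -> list[str]:
    """Return the canonical SMILES plus ``n`` randomized serializations.

    Randomized SMILES are produced by renumbering the atoms with a seeded
    permutation and serializing non-canonically, so every variant reparses to
    the same canonical structure.  Duplicates among the ``n`` variants are
    allowed.  Deterministic given (mol, n, seed).
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    import numpy as np

    out = [mol.canonical]
    rng = np.random.default_rng(seed)
    m = mol.graph_handle
    n_atoms = m.GetNumAtoms()
    for _ in range(n):
        perm = [int(i) for i in rng.permutation(n_atoms)]
        shuffled = Chem.RenumberAtoms(m, perm)
        out.append(Chem.MolToSmiles(shuffled, canonical=False))
    return out


def murcko_scaffold(mol: StandardMolecule) -> str:
    """Bemis–Murcko scaffold key: ring systems plus linkers, side chains
    removed, as canonical SMILES.  Acyclic molecules map to
    :data:`EMPTY_SCAFFOLD`."""
    scaf = MurckoScaffold.GetScaffoldForMol(mol.graph_handle)
    if scaf is None or scaf.GetNumAtoms() == 0:
        return EMPTY_SCAFFOLD
    return Chem.MolToSmiles(scaf)


# ---------------------------------------------------------------------------
# tabular I/O


def read_raw_csv(path) -> list[RawRecord]:
    """Read a raw measurement table: columns [id, smiles, value] (+ extras).

    Extra columns are carried along in ``meta``.
    """
    df = pd.read_csv(path, dtype={"id": str})
    required = {"id", "smiles", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"raw CSV missing columns: {sorted(missing)}")
    extras = [c for c in df.columns if c not in required]
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        records.append(
            RawRecord(
                source_id=str(d["id"]),
                structure=str(d["smiles"]),
                value=d["value"],
                meta={k: d[k] for k in extras},
            )
        )
    return records


def write_curated_csv(records, path) -> None:
    """Write curated records as CSV with the artifact's standard columns."""
    df = pd.DataFrame(
        [
            {
                "molecule_key": r.molecule_key,
                "canonical_smiles": r.molecule_key,
                "label": r.label,
                "n_replicates": r.n_replicates,
                "aggregation_branch": r.branch,
            }
            for r in records
        ]
    )
    df.to_csv(path, index=False)


def read_curated_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"molecule_key", "label"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"curated CSV missing columns: {sorted(missing)}")
    return df
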