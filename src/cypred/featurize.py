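"""Molecular representations for the tabular and graph blocks.

Four views of each molecule are produced:

* circular fingerprint bits (radius-4, 2048-bit, i.e. ECFP8-style),
* a pinned set of physicochemical descriptors,
* engineered features along four axes (lipophilicity/polarity, charge
  patches, structural motifs, drug-likeness),
* a dual graph: the atom/bond graph augmented with explicit ring tensors
  (ring atom sets, node-ring incidence, ring-ring adjacency).

All featurizers are pure functions of the canonical structure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Lipinski, QED, rdFingerprintGenerator, rdMolDescriptors
from sklearn.base import BaseEstimator, TransformerMixin

from .chemio import StandardMolecule, standardize_structure

DEFAULT_RADIUS = 4
DEFAULT_N_BITS = 2048

_HYBRID_CODE = {
    Chem.HybridizationType.S: 0,
    Chem.HybridizationType.SP: 1,
    Chem.HybridizationType.SP2: 2,
    Chem.HybridizationType.SP3: 3,
}

DESCRIPTOR_NAMES = [
    "MW",
    "SLogP",
    "TPSA",
    "HBD",
    "HBA",
    "RotatableBonds",
    "MolarRefractivity",
    "AromaticRings",
    "HeavyAtoms",
    "RingCount",
    "FractionCSP3",
    "Heteroatoms",
]


def fingerprint(mol: StandardMolecule, radius: int = DEFAULT_RADIUS, n_bits: int = DEFAULT_N_BITS) -> np.ndarray:
    """Circular substructure fingerprint as a 0/1 vector of length ``n_bits``."""
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    fp = gen.GetFingerprint(mol.graph_handle)
    arr = np.zeros(n_bits, dtype=np.uint8)
    for b in fp.GetOnBits():
        arr[b] = 1
    return arr


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    inter = int(np.sum((a > 0) & (b > 0)))
    union = int(np.sum((a > 0) | (b > 0)))
    return inter / union if union else 0.0


def mean_similarity(mol_fp: np.ndarray, references: list[np.ndarray]) -> float:
    """Mean Tanimoto similarity of one fingerprint to a reference set."""
    if not len(references):
        raise ValueError("references must be non-empty")
    return float(np.mean([tanimoto(mol_fp, r) for r in references]))


def descriptors(mol: StandardMolecule) -> dict[str, float]:
    """Pinned physicochemical descriptor set (ADME-oriented)."""
    m = mol.graph_handle
    return {
        "MW": Descriptors.MolWt(m),
        "SLogP": Crippen.MolLogP(m),
        "TPSA": rdMolDescriptors.CalcTPSA(m),
        "HBD": float(Lipinski.NumHDonors(m)),
        "HBA": float(Lipinski.NumHAcceptors(m)),
        "RotatableBonds": float(Lipinski.NumRotatableBonds(m)),
        "MolarRefractivity": Crippen.MolMR(m),
        "AromaticRings": float(rdMolDescriptors.CalcNumAromaticRings(m)),
        "HeavyAtoms": float(m.GetNumHeavyAtoms()),
        "RingCount": float(rdMolDescriptors.CalcNumRings(m)),
        "FractionCSP3": rdMolDescriptors.CalcFractionCSP3(m),
        "Heteroatoms": float(rdMolDescriptors.CalcNumHeteroatoms(m)),
    }


# ---------------------------------------------------------------------------
# motif catalog


@dataclass(frozen=True)
class MotifCatalog:
    """Named SMARTS patterns for SAR-relevant ring motifs."""

    patterns: dict[str, str]
    exemplars: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for name, smarts in self.patterns.items():
            if Chem.MolFromSmarts(smarts) is None:
                raise ValueError(f"invalid SMARTS for motif {name!r}")

    @property
    def names(self) -> list[str]:
        return list(self.patterns)

    def count(self, mol: StandardMolecule, name: str) -> int:
        patt = Chem.MolFromSmarts(self.patterns[name])
        return len(mol.graph_handle.GetSubstructMatches(patt))

    def counts(self, mol: StandardMolecule) -> dict[str, int]:
        return {name: self.count(mol, name) for name in self.patterns}

    @classmethod
    def default(cls) -> "MotifCatalog":
        raw = json.loads(resources.files("cypred.data").joinpath("motifs.json").read_text())
        return cls(
            patterns={k: v["smarts"] for k, v in raw["motifs"].items()},
            exemplars={k: v["exemplar"] for k, v in raw["motifs"].items()},
        )


#: ring-motif names (the SAR analysis set, excluding the atom-class patterns)
RING_MOTIFS = ["benzodioxole", "imidazole", "pyridine", "indole", "piperidine", "pyrazine"]


def log_solubility_estimate(mol: StandardMolecule) -> float:
    """Additive aqueous log-solubility estimate (mol/L).

    Linear model in LogP, molecular weight, rotatable bonds and aromatic
    proportion; intended as a monotone-plausible solubility proxy, not a
    calibrated solubility predictor.
    """
    m = mol.graph_handle
    logp = Crippen.MolLogP(m)
    mw = Descriptors.MolWt(m)
    rb = Lipinski.NumRotatableBonds(m)
    heavy = m.GetNumHeavyAtoms()
    arom = sum(1 for a in m.GetAtoms() if a.GetIsAromatic()) / heavy if heavy else 0.0
    return 0.16 - 0.63 * logp - 0.0062 * mw + 0.066 * rb - 0.74 * arom


def lipinski_violations(mol: StandardMolecule) -> int:
    """Rule-of-five breach count (0-4): MW>500, LogP>5, HBD>5, HBA>10."""
    m = mol.graph_handle
    return int(Descriptors.MolWt(m) > 500) + int(Crippen.MolLogP(m) > 5) + int(
        Lipinski.NumHDonors(m) > 5
    ) + int(Lipinski.NumHAcceptors(m) > 10)


def engineered_features(mol: StandardMolecule, catalog: MotifCatalog | None = None) -> dict[str, float]:
    """Engineered feature axes: polarity, charge patches, motifs, drug-likeness."""
    if catalog is None:
        catalog = MotifCatalog.default()
    m = mol.graph_handle
    heavy = m.GetNumHeavyAtoms()
    n_carbon = sum(1 for a in m.GetAtoms() if a.GetAtomicNum() == 6)
    n_arom_c = sum(1 for a in m.GetAtoms() if a.GetAtomicNum() == 6 and a.GetIsAromatic())
    n_coord = sum(1 for a in m.GetAtoms() if a.GetAtomicNum() in (7, 8, 16))
    asa = rdMolDescriptors.CalcLabuteASA(m)
    tpsa = rdMolDescriptors.CalcTPSA(m)
    feats = {
        "LogS": log_solubility_estimate(mol),
        "TPSA_eng": tpsa,
        "PositiveAtoms": float(sum(1 for a in m.GetAtoms() if a.GetFormalCharge() > 0)),
        "NegativeAtoms": float(sum(1 for a in m.GetAtoms() if a.GetFormalCharge() < 0)),
        "PolarSurfaceFraction": tpsa / asa if asa > 0 else 0.0,
        "CoordHeteroatomFraction": n_coord / heavy if heavy else 0.0,
        "AromaticCarbonRatio": n_arom_c / n_carbon if n_carbon else 0.0,
        "LipinskiViolations": float(lipinski_violations(mol)),
        "QED": QED.qed(m),
    }
    for name, c in catalog.counts(mol).items():
        feats[f"motif_{name}"] = float(c)
    return feats


# ---------------------------------------------------------------------------
# dual graph


@dataclass
class DualGraph:
    """Atom/bond graph with explicit ring tensors.

    ``rings`` holds the smallest set of smallest rings as atom-index tuples;
    ``node_ring_incidence`` lists (ring_index, atom_index) membership pairs;
    ``ring_ring_adjacency`` lists unordered ring pairs sharing at least one
    atom; ``node_mask`` marks atoms whose features are replaced by the mask
    token during augmentation or occlusion.
    """

    node_features: np.ndarray  # (n_atoms, 6): Z, charge, hybrid code, aromatic, in-ring, numHs
    edge_list: np.ndarray  # (n_edges, 2) undirected, i < j
    edge_features: np.ndarray  # (n_edges, 4): order, aromatic, conjugated, in-ring
    rings: list[tuple[int, ...]]
    node_ring_incidence: list[tuple[int, int]]
    ring_ring_adjacency: list[tuple[int, int]]
    ring_mask: np.ndarray  # (n_rings,) bool
    node_mask: np.ndarray | None = None  # (n_atoms,) bool

    def __post_init__(self):
        if self.node_mask is None:
            self.node_mask = np.zeros(self.num_atoms, dtype=bool)

    @property
    def num_atoms(self) -> int:
        return self.node_features.shape[0]

    @property
    def num_edges(self) -> int:
        return self.edge_list.shape[0]

    @property
    def num_rings(self) -> int:
        return len(self.rings)

    def validate(self) -> None:
        n = self.num_atoms
        if self.num_edges and (self.edge_list.min() < 0 or self.edge_list.max() >= n):
            raise ValueError("edge index out of range")
        for ring in self.rings:
            if any(a < 0 or a >= n for a in ring):
                raise ValueError("ring atom index out of range")
        inc = {(r, a) for r, ring in enumerate(self.rings) for a in ring}
        if inc != set(self.node_ring_incidence):
            raise ValueError("incidence inconsistent with rings")
        for i, j in self.ring_ring_adjacency:
            if i == j:
                raise ValueError("ring adjacency must be irreflexive")
            if not set(self.rings[i]) & set(self.rings[j]):
                raise ValueError("adjacent rings share no atom")
        if len(self.ring_mask) != self.num_rings:
            raise ValueError("ring_mask length mismatch")

    def copy(self) -> "DualGraph":
        return DualGraph(
            node_features=self.node_features.copy(),
            edge_list=self.edge_list.copy(),
            edge_features=self.edge_features.copy(),
            rings=[tuple(r) for r in self.rings],
            node_ring_incidence=list(self.node_ring_incidence),
            ring_ring_adjacency=list(self.ring_ring_adjacency),
            ring_mask=self.ring_mask.copy(),
            node_mask=self.node_mask.copy(),
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "nodes": self.node_features.tolist(),
                "edges": self.edge_list.tolist(),
                "edge_features": self.edge_features.tolist(),
                "rings": [list(r) for r in self.rings],
                "incidence": [list(p) for p in self.node_ring_incidence],
                "adjacency": [list(p) for p in self.ring_ring_adjacency],
                "ring_mask": self.ring_mask.astype(int).tolist(),
            }
        )

    @classmethod
    def from_json(cls, s: str) -> "DualGraph":
        d = json.loads(s)
        return cls(
            node_features=np.asarray(d["nodes"], dtype=float).reshape(-1, 6),
            edge_list=np.asarray(d["edges"], dtype=int).reshape(-1, 2),
            edge_features=np.asarray(d["edge_features"], dtype=float).reshape(-1, 4),
            rings=[tuple(r) for r in d["rings"]],
            node_ring_incidence=[tuple(p) for p in d["incidence"]],
            ring_ring_adjacency=[tuple(p) for p in d["adjacency"]],
            ring_mask=np.asarray(d["ring_mask"], dtype=bool),
        )


def build_dual_graph(mol: StandardMolecule) -> DualGraph:
    """Build the ring-augmented graph from a standardized molecule.

    Ring perception is the smallest set of smallest rings; two rings are
    neighbors when they share at least one atom (fused or spiro).
    """
    m = mol.graph_handle
    node_feats = np.array(
        [
            [
                a.GetAtomicNum(),
                a.GetFormalCharge(),
                _HYBRID_CODE.get(a.GetHybridization(), 4),
                int(a.GetIsAromatic()),
                int(a.IsInRing()),
                a.GetTotalNumHs(),
            ]
            for a in m.GetAtoms()
        ],
        dtype=float,
    ).reshape(-1, 6)
    edges, efeats = [], []
    for b in m.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        edges.append((min(i, j), max(i, j)))
        efeats.append(
            [b.GetBondTypeAsDouble(), int(b.GetIsAromatic()), int(b.GetIsConjugated()), int(b.IsInRing())]
        )
    rings = [tuple(r) for r in m.GetRingInfo().AtomRings()]
    incidence = [(ri, a) for ri, ring in enumerate(rings) for a in ring]
    adjacency = [
        (i, j)
        for i in range(len(rings))
        for j in range(i + 1, len(rings))
        if set(rings[i]) & set(rings[j])
    ]
    g = DualGraph(
        node_features=node_feats,
        edge_list=np.asarray(edges, dtype=int).reshape(-1, 2),
        edge_features=np.asarray(efeats, dtype=float).reshape(-1, 4),
        rings=rings,
        node_ring_incidence=incidence,
        ring_ring_adjacency=adjacency,
        ring_mask=np.ones(len(rings), dtype=bool),
    )
    g.validate()
    return g


# ---------------------------------------------------------------------------
# sklearn-style feature matrix transformer


class MoleculeFeaturizer(BaseEstimator, TransformerMixin):
    """Transform SMILES into the concatenated tabular feature matrix.

    Columns are fingerprint bits, then descriptors, then engineered features,
    then (optionally) the mean training-set similarity.  Feature names are
    stable for a fixed configuration and exposed via
    :meth:`get_feature_names_out`.
    """

    def __init__(self, radius: int = DEFAULT_RADIUS, n_bits: int = DEFAULT_N_BITS, include_similarity: bool = True):
        self.radius = radius
        self.n_bits = n_bits
        self.include_similarity = include_similarity

    def _mols(self, X) -> list[StandardMolecule]:
        return [x if isinstance(x, StandardMolecule) else standardize_structure(x) for x in X]

    def fit(self, X, y=None):
        mols = self._mols(X)
        self.catalog_ = MotifCatalog.default()
        self.reference_fps_ = np.vstack([fingerprint(m, self.radius, self.n_bits) for m in mols])
        desc = descriptors(mols[0])
        eng = engineered_features(mols[0], self.catalog_)
        names = [f"FP_{i}" for i in range(self.n_bits)] + list(desc) + list(eng)
        if self.include_similarity:
            names.append("MeanTrainSimilarity")
        names.append("AnyMissing")
        self.feature_names_ = names
        self.n_features_out_ = len(names)
        return self

    def _mean_similarities(self, fps: np.ndarray) -> np.ndarray:
        # vectorized mean Tanimoto of each row against the training references
        F = fps.astype(np.float32)
        R = self.reference_fps_.astype(np.float32)
        inter = F @ R.T
        union = F.sum(axis=1)[:, None] + R.sum(axis=1)[None, :] - inter
        with np.errstate(invalid="ignore", divide="ignore"):
            tan = np.where(union > 0, inter / union, 0.0)
        return tan.mean(axis=1)

    def transform(self, X) -> np.ndarray:
        mols = self._mols(X)
        fps = np.vstack([fingerprint(m, self.radius, self.n_bits) for m in mols])
        rows = []
        for m in mols:
            desc = descriptors(m)
            eng = engineered_features(m, self.catalog_)
            rows.append(np.array(list(desc.values()) + list(eng.values())))
        tail = np.vstack(rows)
        cols = [fps.astype(float), tail]
        if self.include_similarity:
            cols.append(self._mean_similarities(fps)[:, None])
        mat = np.concatenate(cols, axis=1)
        # undefined descriptor values become 0 with a companion missingness flag
        missing = ~np.isfinite(mat)
        mat = np.where(missing, 0.0, mat)
        return np.concatenate([mat, missing.any(axis=1)[:, None].astype(float)], axis=1)

    def get_feature_names_out(self, input_features=None):
        return np.asarray(self.feature_names_, dtype=object)
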