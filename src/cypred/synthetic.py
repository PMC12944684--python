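"""Synthetic molecule libraries with a planted structure-activity function.

Molecules are assembled from a fragment grammar: a neutral ring core plus
0-3 substituents drawn from a pool that includes the SAR-relevant ring
motifs (benzodioxole, imidazole, pyridine, indole, piperidine, pyrazine).
Labels follow an additive ground truth

    y = clip( intercept + sum_m beta_m * count_m
              + slope_logp * SLogP + slope_ar * aromatic_rings
              + Normal(0, noise_sd),  0, 100 )

so every pipeline stage — curation, featurization, regression, SAR
recovery — can be exercised against known effects without external data.
Attaching motifs as substituents keeps their presences quasi-independent,
which keeps marginal SAR estimates close to the planted effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import json

import numpy as np
from rdkit import Chem

from .chemio import RawRecord, StandardMolecule, standardize_structure
from .curate import curate_records
from .featurize import MotifCatalog

# neutral cores: no planted motif, varied ring chemistry
DEFAULT_CORES = [
    "c1ccccc1",      # benzene
    "C1CCCCC1",      # cyclohexane
    "c1ccoc1",       # furan
    "c1ccsc1",       # thiophene
    "C1CCOCC1",      # oxane
    "c1ccc2ccccc2c1",  # naphthalene
]

# substituent pool: motif rings plus neutral groups
MOTIF_SUBSTITUENTS = {
    "benzodioxole": "C1Oc2ccccc2O1",
    "imidazole": "c1c[nH]cn1",
    "pyridine": "c1ccncc1",
    "indole": "c1ccc2[nH]ccc2c1",
    "piperidine": "C1CCNCC1",
    "pyrazine": "c1cnccn1",
}
NEUTRAL_SUBSTITUENTS = ["C", "CC", "CCC", "O", "N", "F", "Cl", "OC", "C(F)(F)F", "C#N", "C(C)C"]

# planted effects in percentage points (directions/magnitudes echo the
# SAR analysis this generator is designed to exercise)
DEFAULT_BETAS = {
    "benzodioxole": 35.0,
    "indole": 16.0,
    "pyridine": 11.0,
    "imidazole": 9.0,
    "piperidine": -5.0,
    "pyrazine": -1.5,
}


@dataclass
class GeneratorConfig:
    n_molecules: int = 2000
    cores: list[str] = field(default_factory=lambda: list(DEFAULT_CORES))
    substituents: list[str] = field(
        default_factory=lambda: list(MOTIF_SUBSTITUENTS.values()) + list(NEUTRAL_SUBSTITUENTS)
    )
    betas: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BETAS))
    intercept: float = 20.0
    slope_logp: float = 2.0
    slope_aromatic_rings: float = 3.0
    noise_sd: float = 10.0
    replicates_k: int = 1
    outlier_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_molecules < 1:
            raise ValueError("n_molecules must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not self.cores or not self.substituents:
            raise ValueError("fragment grammar must be nonempty")


@dataclass
class GroundTruth:
    molecules: list[StandardMolecule]
    noiseless: np.ndarray  # pre-noise, pre-clip planted values
    labels: np.ndarray  # final clipped labels
    motif_counts: np.ndarray  # (n, n_motifs) design columns
    motif_names: list[str]
    design: np.ndarray  # full design matrix incl. slope columns and intercept


def _attachment_points(mol: Chem.Mol) -> list[int]:
    return [a.GetIdx() for a in mol.GetAtoms() if a.GetTotalNumHs() > 0 and a.GetAtomicNum() in (6, 7)]


def _attach(core: Chem.Mol, sub: Chem.Mol, rng: np.random.Generator) -> Chem.Mol | None:
    """Join a substituent to the core with a single bond at seeded positions."""
    core_sites = _attachment_points(core)
    sub_sites = _attachment_points(sub)
    if not core_sites or not sub_sites:
        return None
    ci = int(rng.choice(core_sites))
    si = int(rng.choice(sub_sites))
    combo = Chem.RWMol(Chem.CombineMols(core, sub))
    combo.AddBond(ci, core.GetNumAtoms() + si, Chem.BondType.SINGLE)
    try:
        m = combo.GetMol()
        Chem.SanitizeMol(m)
        return m
    except Exception:
        return None


def generate_molecules(config: GeneratorConfig) -> list[StandardMolecule]:
    """Assemble ``n_molecules`` distinct valid molecules from the grammar."""
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    seen: set[str] = set()
    out: list[StandardMolecule] = []
    attempts = 0
    max_attempts = 200 * config.n_molecules
    while len(out) < config.n_molecules and attempts < max_attempts:
        attempts += 1
        mol = Chem.MolFromSmiles(str(rng.choice(config.cores)))
        n_subs = int(rng.integers(0, 4))
        ok = True
        for _ in range(n_subs):
            sub = Chem.MolFromSmiles(str(rng.choice(config.substituents)))
            joined = _attach(mol, sub, rng)
            if joined is None:
                ok = False
                break
            mol = joined
        if not ok:
            continue
        try:
            std = standardize_structure(Chem.MolToSmiles(mol))
        except Exception:
            continue
        if std.canonical in seen:
            continue
        seen.add(std.canonical)
        out.append(std)
    if len(out) < config.n_molecules:
        raise RuntimeError("fragment grammar exhausted before reaching n_molecules")
    return out


def plant_labels(molecules: list[StandardMolecule], config: GeneratorConfig) -> GroundTruth:
    """Compute the planted additive labels for a molecule list."""
    from rdkit.Chem import Crippen, rdMolDescriptors

    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 1)))
    catalog = MotifCatalog.default()
    motif_names = [m for m in config.betas if m in catalog.patterns]
    n = len(molecules)
    counts = np.zeros((n, len(motif_names)))
    logp = np.zeros(n)
    arom = np.zeros(n)
    for i, mol in enumerate(molecules):
        for j, name in enumerate(motif_names):
            counts[i, j] = catalog.count(mol, name)
        logp[i] = Crippen.MolLogP(mol.graph_handle)
        arom[i] = rdMolDescriptors.CalcNumAromaticRings(mol.graph_handle)
    betas = np.array([config.betas[m] for m in motif_names])
    noiseless = config.intercept + counts @ betas + config.slope_logp * logp + config.slope_aromatic_rings * arom
    noise = rng.normal(0.0, config.noise_sd, size=n) if config.noise_sd > 0 else np.zeros(n)
    labels = np.clip(noiseless + noise, 0.0, 100.0)
    design = np.column_stack([np.ones(n), counts, logp, arom])
    return GroundTruth(
        molecules=molecules,
        noiseless=noiseless,
        labels=labels,
        motif_counts=counts,
        motif_names=motif_names,
        design=design,
    )


def make_replicates(truth: GroundTruth, config: GeneratorConfig) -> list[RawRecord]:
    """Emit k noisy replicate records per molecule (optionally with outliers).

    Replicate values are the final label plus Normal(0, noise_sd) noise,
    unclipped (curation handles clipping); with probability ``outlier_rate``
    one replicate of a molecule is displaced by +/-50 points.
    """
    if config.replicates_k < 1:
        raise ValueError("replicates_k must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 2)))
    records = []
    for i, mol in enumerate(truth.molecules):
        outlier_rep = int(rng.integers(config.replicates_k)) if rng.random() < config.outlier_rate else -1
        for k in range(config.replicates_k):
            v = truth.labels[i] + (rng.normal(0.0, config.noise_sd) if config.noise_sd > 0 else 0.0)
            if k == outlier_rep:
                v += 50.0 if rng.random() < 0.5 else -50.0
            records.append(RawRecord(source_id=f"SYN-{i:06d}-{k}", structure=mol.canonical, value=float(v)))
    return records


def make_benchmark(config: GeneratorConfig, out_dir: str | Path | None = None):
    """Full benchmark bundle: raw records, curated records, ground truth.

    When ``out_dir`` is given, writes raw.csv, curated.csv and truth.json.
    """
    import pandas as pd

    from .chemio import write_curated_csv

    molecules = generate_molecules(config)
    truth = plant_labels(molecules, config)
    raw = make_replicates(truth, config)
    curated, rejections = curate_records(raw)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            [{"id": r.source_id, "smiles": r.structure, "value": r.value} for r in raw]
        ).to_csv(out / "raw.csv", index=False)
        write_curated_csv(curated, out / "curated.csv")
        (out / "truth.json").write_text(
            json.dumps(
                {
                    "smiles": [m.canonical for m in truth.molecules],
                    "noiseless": truth.noiseless.tolist(),
                    "labels": truth.labels.tolist(),
                    "motif_names": truth.motif_names,
                    "motif_counts": truth.motif_counts.tolist(),
                    "config": {
                        "n_molecules": config.n_molecules,
                        "betas": config.betas,
                        "intercept": config.intercept,
                        "slope_logp": config.slope_logp,
                        "slope_aromatic_rings": config.slope_aromatic_rings,
                        "noise_sd": config.noise_sd,
                        "replicates_k": config.replicates_k,
                        "outlier_rate": config.outlier_rate,
                        "seed": config.seed,
                    },
                },
                indent=1,
            )
        )
    return raw, curated, truth
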