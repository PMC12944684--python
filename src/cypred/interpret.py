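"""Model interpretation and substructure SAR statistics.

Occlusion sensitivity masks atoms (or whole rings) and records the drop in
predicted inhibition; positive deltas mark units the model credits with
higher inhibition.  The SAR statistics quantify, per ring motif, the
association between motif presence and measured inhibition: point-biserial
correlation with a t-test p-value, Cohen's d, and a bootstrap CI on the mean
difference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .chemio import StandardMolecule, standardize_structure
from .featurize import DualGraph, MotifCatalog, build_dual_graph


@dataclass
class AttributionMap:
    unit_kind: str  # atom | ring
    deltas: np.ndarray  # base - occluded, percentage points


@dataclass
class SARResult:
    motif: str
    r_pb: float
    p_value: float
    cohens_d: float
    mean_diff: float
    ci95: tuple[float, float]
    n_with: int
    n_without: int
    stars: str


def occlude(predict_fn, graph: DualGraph | StandardMolecule | str, unit_kind: str = "atom") -> AttributionMap:
    """Occlusion-sensitivity attribution.

    ``predict_fn`` maps a :class:`DualGraph` to a scalar prediction.  For
    each atom (or each ring's atom set) the node features are replaced by the
    mask token and the model re-queried; delta = base - occluded.  Masking
    features rather than deleting atoms keeps the ring tensors and graph
    topology intact.
    """
    if unit_kind not in ("atom", "ring"):
        raise ValueError("unit_kind must be 'atom' or 'ring'")
    if not isinstance(graph, DualGraph):
        if not isinstance(graph, StandardMolecule):
            graph = standardize_structure(graph)
        graph = build_dual_graph(graph)
    base = float(predict_fn(graph))
    units = [(i,) for i in range(graph.num_atoms)] if unit_kind == "atom" else graph.rings
    deltas = np.zeros(len(units))
    for k, unit in enumerate(units):
        g = graph.copy()
        for a in unit:
            g.node_mask[a] = True
        deltas[k] = base - float(predict_fn(g))
    return AttributionMap(unit_kind=unit_kind, deltas=deltas)


def _split_groups(labels, presence):
    y = np.asarray(labels, dtype=float)
    p = np.asarray(presence).astype(bool)
    if y.shape != p.shape:
        raise ValueError("length mismatch")
    g1, g0 = y[p], y[~p]
    if len(g1) == 0 or len(g0) == 0:
        raise ValueError("one-class presence: both groups must be nonempty")
    return y, p, g1, g0


def point_biserial(labels, presence) -> tuple[float, float]:
    """Point-biserial correlation (continuous labels vs 0/1 presence).

    r = (M1 - M0) / s_y * sqrt(p*q) with the population SD of the labels;
    algebraically identical to the Pearson correlation of labels against the
    indicator.  The p-value uses the t transformation with n-2 df.
    """
    y, p, g1, g0 = _split_groups(labels, presence)
    s_y = float(np.std(y))  # population SD
    if s_y == 0:
        raise ValueError("constant labels")
    n = len(y)
    prop = len(g1) / n
    r = (g1.mean() - g0.mean()) / s_y * np.sqrt(prop * (1 - prop))
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1 - r * r))
    pval = float(2 * stats.t.sf(abs(t), df=n - 2))
    return r, pval


def cohens_d(labels, presence) -> float:
    """Standardized mean difference with pooled sample SD."""
    _, _, g1, g0 = _split_groups(labels, presence)
    n1, n0 = len(g1), len(g0)
    if n1 < 2 or n0 < 2:
        raise ValueError("both groups need size >= 2")
    s_pooled = np.sqrt(
        ((n1 - 1) * np.var(g1, ddof=1) + (n0 - 1) * np.var(g0, ddof=1)) / (n1 + n0 - 2)
    )
    if s_pooled == 0:
        raise ValueError("zero pooled SD")
    return float((g1.mean() - g0.mean()) / s_pooled)


def mean_difference_ci(labels, presence, n_boot: int = 2000, seed: int = 0) -> tuple[float, tuple[float, float]]:
    """Mean difference (with - without) and a percentile bootstrap 95% CI."""
    _, _, g1, g0 = _split_groups(labels, presence)
    rng = np.random.default_rng(seed)
    diff = float(g1.mean() - g0.mean())
    boots = np.empty(n_boot)
    for b in range(n_boot):
        boots[b] = rng.choice(g1, len(g1)).mean() - rng.choice(g0, len(g0)).mean()
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return diff, (float(lo), float(hi))


def spearman_matrix(columns: dict[str, np.ndarray]) -> tuple[list[str], np.ndarray]:
    """Pairwise Spearman rank correlations (average ranks on ties)."""
    names = list(columns)
    data = np.column_stack([np.asarray(columns[k], dtype=float) for k in names])
    if data.shape[0] < 3:
        raise ValueError("need at least 3 rows")
    rho = stats.spearmanr(data).statistic
    rho = np.atleast_2d(rho)
    if rho.shape == (1, 1):  # two columns: scipy returns a scalar
        r = float(rho[0, 0])
        rho = np.array([[1.0, r], [r, 1.0]])
    return names, rho


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def sar_report(
    smiles,
    labels,
    catalog: MotifCatalog | None = None,
    motifs: list[str] | None = None,
    n_boot: int = 2000,
    seed: int = 0,
    bh_correct: bool = False,
) -> list[SARResult]:
    """Per-motif SAR statistics over a labeled molecule set.

    Presence is a binary indicator (any match counts, regardless of
    multiplicity).  Motifs absent from the set, or present in every
    molecule, are skipped.  Benjamini-Hochberg adjustment of the p-values is
    available but off by default.
    """
    if catalog is None:
        catalog = MotifCatalog.default()
    from .featurize import RING_MOTIFS

    motif_names = motifs if motifs is not None else [m for m in RING_MOTIFS if m in catalog.patterns]
    y = np.asarray(labels, dtype=float)
    mols = [s if isinstance(s, StandardMolecule) else standardize_structure(s) for s in smiles]
    results = []
    for name in motif_names:
        presence = np.array([catalog.count(m, name) > 0 for m in mols])
        if presence.all() or not presence.any():
            continue
        r, p = point_biserial(y, presence)
        d = cohens_d(y, presence)
        diff, ci = mean_difference_ci(y, presence, n_boot=n_boot, seed=seed)
        results.append(
            SARResult(
                motif=name, r_pb=r, p_value=p, cohens_d=d, mean_diff=diff, ci95=ci,
                n_with=int(presence.sum()), n_without=int((~presence).sum()), stars=_stars(p),
            )
        )
    if bh_correct and results:
        # standard BH step-up
        m = len(results)
        ps = np.array([res.p_value for res in results])
        sorted_idx = np.argsort(ps)
        adj_p = np.empty(m)
        running = 1.0
        for k in range(m - 1, -1, -1):
            i = sorted_idx[k]
            running = min(running, ps[i] * m / (k + 1))
            adj_p[i] = running
        results = [
            SARResult(
                motif=res.motif, r_pb=res.r_pb, p_value=float(adj_p[i]), cohens_d=res.cohens_d,
                mean_diff=res.mean_diff, ci95=res.ci95, n_with=res.n_with,
                n_without=res.n_without, stars=_stars(float(adj_p[i])),
            )
            for i, res in enumerate(results)
        ]
    return results
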