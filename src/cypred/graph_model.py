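"""Ring-aware graph regression of percent inhibition.

The encoder treats rings as a third structural unit next to atoms and bonds.
Each layer updates, in order, (i) bond representations from their endpoint
atoms, (ii) atom representations from neighbor atoms, incident bonds and the
average representation of the rings containing the atom, and (iii) ring
representations from their member atoms.  Mean (or sum) readout over atoms
yields the graph embedding fed to a small prediction head.

Training supports InfoNCE contrastive pretraining over augmented graph views
(atom masking, bond deletion, subgraph removal) and fine-tuning with
similarity-weighted manifold mixup: within each mini-batch, pairs scored by a
convex combination of embedding cosine similarity and label proximity are
interpolated in embedding space (lambda ~ Beta(alpha, alpha)); the mixed
samples pass through the prediction head only and supplement the real samples
in the squared-error loss.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.model_selection import KFold

from . import _autograd as ag
from .chemio import StandardMolecule, standardize_structure
from .featurize import DualGraph, build_dual_graph

# encoded feature layout
_Z_LIST = [5, 6, 7, 8, 9, 14, 15, 16, 17, 35, 53]  # common heavy elements; rest -> "other"
_N_Z = len(_Z_LIST) + 1
_N_CHARGE = 3  # -, 0, +
_N_HYBRID = 5
NODE_DIM = _N_Z + _N_CHARGE + _N_HYBRID + 3 + 1  # + aromatic, in-ring, numHs, mask channel
EDGE_DIM = 4


# ---------------------------------------------------------------------------
# configs


@dataclass
class EncoderConfig:
    n_layers: int = 2
    hidden_dim: int = 32
    readout: str = "mean"  # mean | sum
    seed: int = 0

    def __post_init__(self):
        if self.n_layers < 0:
            raise ValueError("n_layers must be >= 0")
        if self.hidden_dim < 1:
            raise ValueError("hidden_dim must be >= 1")
        if self.readout not in ("mean", "sum"):
            raise ValueError("readout must be 'mean' or 'sum'")


@dataclass
class MixupConfig:
    alpha: float = 0.5
    w_g: float = 0.5
    w_y: float = 0.5
    top_k: int = 8
    n_mix_per_batch: int | None = None  # None -> batch size
    label_range: float = 100.0
    seed: int = 0

    def __post_init__(self):
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if not (0 <= self.w_g <= 1 and 0 <= self.w_y <= 1):
            raise ValueError("weights must lie in [0,1]")
        if abs(self.w_g + self.w_y - 1.0) > 1e-9:
            raise ValueError("w_g + w_y must equal 1")


@dataclass
class ContrastConfig:
    temperature: float = 0.1
    atom_mask_rate: float = 0.15
    bond_drop_rate: float = 0.10
    subgraph_drop_rate: float = 0.20
    epochs: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        for r in (self.atom_mask_rate, self.bond_drop_rate, self.subgraph_drop_rate):
            if not 0 <= r <= 1:
                raise ValueError("rates must be probabilities")


@dataclass
class MixedSample:
    h_tilde: np.ndarray
    y_tilde: float
    lam: float
    parents: tuple[int, int]


# ---------------------------------------------------------------------------
# graph encoding / batching


def encode_node_features(g: DualGraph) -> np.ndarray:
    """One-hot encode raw node features; masked atoms get the mask token."""
    n = g.num_atoms
    X = np.zeros((n, NODE_DIM), dtype=float)
    for i in range(n):
        if g.node_mask[i]:
            X[i, -1] = 1.0  # mask token: all-zero features plus mask channel
            continue
        z, charge, hyb, arom, inring, nh = g.node_features[i]
        zi = _Z_LIST.index(int(z)) if int(z) in _Z_LIST else len(_Z_LIST)
        X[i, zi] = 1.0
        X[i, _N_Z + int(np.sign(charge)) + 1] = 1.0
        X[i, _N_Z + _N_CHARGE + int(hyb)] = 1.0
        off = _N_Z + _N_CHARGE + _N_HYBRID
        X[i, off] = arom
        X[i, off + 1] = inring
        X[i, off + 2] = nh / 4.0
    return X


@dataclass
class GraphBatch:
    """A disjoint union of dual graphs with sparse aggregation operators."""

    X: np.ndarray
    E: np.ndarray
    u: np.ndarray
    v: np.ndarray
    A_nbr: sparse.csr_matrix  # atom <- neighbor atoms (sum)
    B_inc: sparse.csr_matrix  # atom <- incident bonds (sum)
    R_mean: sparse.csr_matrix  # ring <- member atoms (mean)
    R_atom: sparse.csr_matrix  # atom <- containing rings (mean)
    G_pool: sparse.csr_matrix  # graph <- atoms (mean or sum)
    n_graphs: int
    sizes: list[int] = field(default_factory=list)


def make_batch(graphs: list[DualGraph], readout: str = "mean") -> GraphBatch:
    Xs, Es, us, vs = [], [], [], []
    a_rows, a_cols = [], []
    b_rows, b_cols = [], []
    r_rows, r_cols, r_vals = [], [], []
    ra_rows, ra_cols, ra_vals = [], [], []
    g_rows, g_cols, g_vals = [], [], []
    n_off = e_off = r_off = 0
    for gi, g in enumerate(graphs):
        n, m = g.num_atoms, g.num_edges
        Xs.append(encode_node_features(g))
        Es.append(g.edge_features)
        for k in range(m):
            i, j = int(g.edge_list[k, 0]) + n_off, int(g.edge_list[k, 1]) + n_off
            us.append(i)
            vs.append(j)
            a_rows += [i, j]
            a_cols += [j, i]
            b_rows += [i, j]
            b_cols += [e_off + k, e_off + k]
        for ri, ring in enumerate(g.rings):
            w = 1.0 / len(ring)
            for a in ring:
                r_rows.append(r_off + ri)
                r_cols.append(n_off + a)
                r_vals.append(w)
        ring_count = np.zeros(n)
        for ri, ring in enumerate(g.rings):
            for a in ring:
                ring_count[a] += 1
        for ri, ring in enumerate(g.rings):
            for a in ring:
                ra_rows.append(n_off + a)
                ra_cols.append(r_off + ri)
                ra_vals.append(1.0 / ring_count[a])
        pool_w = 1.0 / n if readout == "mean" else 1.0
        for a in range(n):
            g_rows.append(gi)
            g_cols.append(n_off + a)
            g_vals.append(pool_w)
        n_off += n
        e_off += m
        r_off += g.num_rings
    N, M, R = n_off, e_off, r_off
    return GraphBatch(
        X=np.vstack(Xs),
        E=np.vstack(Es) if M else np.zeros((0, EDGE_DIM)),
        u=np.asarray(us, dtype=int),
        v=np.asarray(vs, dtype=int),
        A_nbr=sparse.csr_matrix((np.ones(len(a_rows)), (a_rows, a_cols)), shape=(N, N)),
        B_inc=sparse.csr_matrix((np.ones(len(b_rows)), (b_rows, b_cols)), shape=(N, M)),
        R_mean=sparse.csr_matrix((r_vals, (r_rows, r_cols)), shape=(R, N)),
        R_atom=sparse.csr_matrix((ra_vals, (ra_rows, ra_cols)), shape=(N, R)),
        G_pool=sparse.csr_matrix((g_vals, (g_rows, g_cols)), shape=(len(graphs), N)),
        n_graphs=len(graphs),
        sizes=[g.num_atoms for g in graphs],
    )


# ---------------------------------------------------------------------------
# encoder parameters and forward pass


def init_params(config: EncoderConfig) -> dict[str, ag.Parameter]:
    rng = np.random.default_rng(config.seed)
    d = config.hidden_dim

    def w(fan_in, fan_out):
        return ag.Parameter(rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out)))

    params = {
        "w_in": w(NODE_DIM, d),
        "b_in": ag.Parameter(np.zeros(d)),
        "w_ein": w(EDGE_DIM, d),
        "b_ein": ag.Parameter(np.zeros(d)),
        "w_h1": w(d, d),
        "b_h1": ag.Parameter(np.zeros(d)),
        "w_h2": w(d, 1),
        "b_h2": ag.Parameter(np.zeros(1)),
    }
    for layer in range(config.n_layers):
        params[f"we_{layer}"] = w(2 * d, d)
        params[f"be_{layer}"] = ag.Parameter(np.zeros(d))
        params[f"wa_{layer}"] = w(3 * d, d)
        params[f"ba_{layer}"] = ag.Parameter(np.zeros(d))
        params[f"wr_{layer}"] = w(2 * d, d)
        params[f"br_{layer}"] = ag.Parameter(np.zeros(d))
    return params


def encode_batch(batch: GraphBatch, params: dict, config: EncoderConfig) -> ag.Tensor:
    """Forward pass to graph embeddings (n_graphs x hidden_dim)."""
    h = ag.add(ag.matmul(ag.Tensor(batch.X), params["w_in"]), params["b_in"])
    e = ag.add(ag.matmul(ag.Tensor(batch.E), params["w_ein"]), params["b_ein"])
    r = ag.spmm(batch.R_mean, h)
    for layer in range(config.n_layers):
        # (i) bond update from endpoint atoms
        he = ag.add(ag.gather_rows(h, batch.u), ag.gather_rows(h, batch.v))
        e = ag.relu(ag.add(ag.matmul(ag.concat([e, he]), params[f"we_{layer}"]), params[f"be_{layer}"]))
        # (ii) atom update from neighbors, incident bonds and containing rings
        msg = ag.add(ag.spmm(batch.A_nbr, h), ag.spmm(batch.B_inc, e))
        ravg = ag.spmm(batch.R_atom, r)
        h = ag.relu(
            ag.add(ag.matmul(ag.concat([h, msg, ravg]), params[f"wa_{layer}"]), params[f"ba_{layer}"])
        )
        # (iii) ring update from member atoms
        rm = ag.spmm(batch.R_mean, h)
        r = ag.relu(ag.add(ag.matmul(ag.concat([r, rm]), params[f"wr_{layer}"]), params[f"br_{layer}"]))
    return ag.spmm(batch.G_pool, h)


def head_forward(g: ag.Tensor, params: dict) -> ag.Tensor:
    hid = ag.relu(ag.add(ag.matmul(g, params["w_h1"]), params["b_h1"]))
    return ag.add(ag.matmul(hid, params["w_h2"]), params["b_h2"])


def encode(graph: DualGraph, params: dict, config: EncoderConfig) -> np.ndarray:
    """Embed a single molecule graph."""
    return encode_batch(make_batch([graph], config.readout), params, config).detach()[0]


# ---------------------------------------------------------------------------
# view augmentation


def augment_view(graph: DualGraph, config: ContrastConfig, seed: int) -> DualGraph:
    """Stochastic structural view: subgraph removal, bond deletion, atom masking.

    The result is a valid dual graph: after atom removal the ring tensors are
    recomputed (rings losing any atom are dropped).  Rings are stored as atom
    sets, so bond deletion leaves the ring tensors unchanged.
    """
    rng = np.random.default_rng(seed)
    g = graph.copy()
    # subgraph removal: a random connected region of <= rate * |V| atoms
    k_max = int(config.subgraph_drop_rate * g.num_atoms)
    if k_max >= 1 and g.num_atoms > k_max:
        adj: dict[int, list[int]] = {i: [] for i in range(g.num_atoms)}
        for a, b in g.edge_list:
            adj[int(a)].append(int(b))
            adj[int(b)].append(int(a))
        start = int(rng.integers(g.num_atoms))
        removed, frontier = set(), [start]
        while frontier and len(removed) < k_max:
            cur = frontier.pop(0)
            if cur in removed:
                continue
            removed.add(cur)
            frontier.extend(n for n in adj[cur] if n not in removed)
        keep = [i for i in range(g.num_atoms) if i not in removed]
        remap = {old: new for new, old in enumerate(keep)}
        keep_edges = [
            k
            for k in range(g.num_edges)
            if int(g.edge_list[k, 0]) in remap and int(g.edge_list[k, 1]) in remap
        ]
        new_rings = [
            tuple(remap[a] for a in ring) for ring in g.rings if all(a in remap for a in ring)
        ]
        g = DualGraph(
            node_features=g.node_features[keep],
            edge_list=np.array(
                [[remap[int(g.edge_list[k, 0])], remap[int(g.edge_list[k, 1])]] for k in keep_edges],
                dtype=int,
            ).reshape(-1, 2),
            edge_features=g.edge_features[keep_edges],
            rings=new_rings,
            node_ring_incidence=[(ri, a) for ri, ring in enumerate(new_rings) for a in ring],
            ring_ring_adjacency=[
                (i, j)
                for i in range(len(new_rings))
                for j in range(i + 1, len(new_rings))
                if set(new_rings[i]) & set(new_rings[j])
            ],
            ring_mask=np.ones(len(new_rings), dtype=bool),
            node_mask=g.node_mask[keep],
        )
    # bond deletion
    if config.bond_drop_rate > 0 and g.num_edges:
        keep = rng.random(g.num_edges) >= config.bond_drop_rate
        g.edge_list = g.edge_list[keep]
        g.edge_features = g.edge_features[keep]
    # atom masking
    if config.atom_mask_rate > 0 and g.num_atoms:
        g.node_mask = g.node_mask | (rng.random(g.num_atoms) < config.atom_mask_rate)
    g.validate()
    return g


# ---------------------------------------------------------------------------
# contrastive loss


def info_nce_loss(view_embeddings: np.ndarray, temperature: float) -> float:
    """InfoNCE over 2B views where rows (2i, 2i+1) are positive pairs.

    Cosine-similarity softmax with temperature; for each anchor the candidate
    set is the other 2B-1 views.
    """
    Z = np.asarray(view_embeddings, dtype=float)
    n = Z.shape[0]
    if n < 4 or n % 2:
        raise ValueError("need 2B embeddings with B >= 2")
    norms = np.linalg.norm(Z, axis=1)
    if np.any(norms == 0):
        raise ValueError("zero-norm embedding")
    Zn = Z / norms[:, None]
    sim = Zn @ Zn.T / temperature
    losses = []
    for a in range(n):
        pos = a + 1 if a % 2 == 0 else a - 1
        cand = np.delete(np.arange(n), a)
        logits = sim[a, cand]
        losses.append(-(sim[a, pos] - (logits.max() + np.log(np.exp(logits - logits.max()).sum()))))
    return float(np.mean(losses))


# ---------------------------------------------------------------------------
# similarity-weighted mixup


def pair_score(h_i, h_j, y_i: float, y_j: float, label_range: float, w_g: float = 0.5, w_y: float = 0.5) -> float:
    """Composite pair similarity: w_g * cosine(h_i, h_j) + w_y * (1 - |dy| / R)."""
    h_i = np.asarray(h_i, dtype=float)
    h_j = np.asarray(h_j, dtype=float)
    ni, nj = np.linalg.norm(h_i), np.linalg.norm(h_j)
    if ni == 0 or nj == 0:
        raise ValueError("zero-norm embedding")
    if abs(y_i - y_j) > label_range:
        raise ValueError("label difference exceeds label range")
    s_g = float(h_i @ h_j / (ni * nj))
    s_y = 1.0 - abs(y_i - y_j) / label_range
    return w_g * s_g + w_y * s_y


def sample_mix_lambda(alpha: float, rng: np.random.Generator | int) -> float:
    """lambda ~ Beta(alpha, alpha), strictly inside (0, 1)."""
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    lam = float(rng.beta(alpha, alpha))
    eps = 1e-9
    return min(1.0 - eps, max(eps, lam))


def mix_pair(h_i, h_j, y_i: float, y_j: float, lam: float, parents: tuple[int, int] = (0, 1)) -> MixedSample:
    """Convex interpolation of embeddings and labels."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must lie in [0,1]")
    h_i = np.asarray(h_i, dtype=float)
    h_j = np.asarray(h_j, dtype=float)
    return MixedSample(
        h_tilde=lam * h_i + (1 - lam) * h_j,
        y_tilde=lam * y_i + (1 - lam) * y_j,
        lam=lam,
        parents=parents,
    )


def _score_matrix(H: np.ndarray, y: np.ndarray, config: MixupConfig) -> np.ndarray:
    norms = np.linalg.norm(H, axis=1)
    norms = np.maximum(norms, 1e-12)
    Hn = H / norms[:, None]
    s_g = Hn @ Hn.T
    s_y = 1.0 - np.abs(y[:, None] - y[None, :]) / config.label_range
    return config.w_g * s_g + config.w_y * s_y


def select_mix_pairs(
    H: np.ndarray, y: np.ndarray, config: MixupConfig, rng: np.random.Generator | int | None = None
) -> list[tuple[int, int, float]]:
    """Choose mixup partners by composite similarity.

    Each anchor's candidate pool is its ``top_k`` highest-scoring partners
    (self excluded); the partner is drawn with probability proportional to
    max(S, 0), falling back to uniform when no candidate scores positive.
    Anchors cycle through the batch until ``n_mix_per_batch`` pairs are drawn.
    """
    H = np.asarray(H, dtype=float)
    y = np.asarray(y, dtype=float)
    n = H.shape[0]
    if n < 2:
        raise ValueError("need a batch of at least 2")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    elif not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    n_mix = config.n_mix_per_batch if config.n_mix_per_batch is not None else n
    S = _score_matrix(H, y, config)
    pairs = []
    for t in range(n_mix):
        i = t % n
        others = np.delete(np.arange(n), i)
        scores = S[i, others]
        k = min(config.top_k, len(others))
        top = others[np.argsort(scores)[::-1][:k]]
        w = np.maximum(S[i, top], 0.0)
        if w.sum() <= 0:
            w = np.ones(len(top))
        j = int(rng.choice(top, p=w / w.sum()))
        pairs.append((i, j, float(S[i, j])))
    return pairs


# ---------------------------------------------------------------------------
# estimator


class RingGNNRegressor(BaseEstimator, RegressorMixin):
    """Ring-aware graph neural regressor for percent inhibition.

    Accepts SMILES strings, :class:`StandardMolecule` or :class:`DualGraph`
    inputs.  Optionally pretrains the encoder with InfoNCE over augmented
    views, then fine-tunes with squared-error loss over real plus
    similarity-weighted mixup samples.  Fully deterministic given ``seed``.

    Fitted attributes: ``params_`` (weights), ``loss_history_``,
    ``y_mean_`` / ``y_std_`` (label standardization).
    """

    def __init__(
        self,
        hidden_dim: int = 32,
        n_layers: int = 2,
        readout: str = "mean",
        epochs: int = 30,
        batch_size: int = 32,
        lr: float = 5e-3,
        mixup: bool = True,
        mixup_alpha: float = 0.5,
        w_g: float = 0.5,
        w_y: float = 0.5,
        top_k: int = 8,
        n_mix_per_batch: int | None = None,
        contrastive_epochs: int = 0,
        temperature: float = 0.1,
        atom_mask_rate: float = 0.15,
        bond_drop_rate: float = 0.10,
        subgraph_drop_rate: float = 0.20,
        label_range: float = 100.0,
        seed: int = 0,
    ):
        self.hidden_dim = hidden_dim
        self.n_layers = n_layers
        self.readout = readout
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.mixup = mixup
        self.mixup_alpha = mixup_alpha
        self.w_g = w_g
        self.w_y = w_y
        self.top_k = top_k
        self.n_mix_per_batch = n_mix_per_batch
        self.contrastive_epochs = contrastive_epochs
        self.temperature = temperature
        self.atom_mask_rate = atom_mask_rate
        self.bond_drop_rate = bond_drop_rate
        self.subgraph_drop_rate = subgraph_drop_rate
        self.label_range = label_range
        self.seed = seed

    # -- input handling -----------------------------------------------------

    @staticmethod
    def _graphs(X) -> list[DualGraph]:
        out = []
        for x in X:
            if isinstance(x, DualGraph):
                out.append(x)
            elif isinstance(x, StandardMolecule):
                out.append(build_dual_graph(x))
            else:
                out.append(build_dual_graph(standardize_structure(x)))
        return out

    def _encoder_config(self) -> EncoderConfig:
        return EncoderConfig(self.n_layers, self.hidden_dim, self.readout, self.seed)

    # -- training -----------------------------------------------------------

    def _pretrain(self, graphs: list[DualGraph], rng: np.random.Generator) -> None:
        cfg = ContrastConfig(
            temperature=self.temperature,
            atom_mask_rate=self.atom_mask_rate,
            bond_drop_rate=self.bond_drop_rate,
            subgraph_drop_rate=self.subgraph_drop_rate,
            epochs=self.contrastive_epochs,
            seed=self.seed,
        )
        enc_cfg = self._encoder_config()
        enc_params = {k: v for k, v in self.params_.items() if not k.startswith(("w_h", "b_h"))}
        opt = ag.Adam(enc_params, lr=self.lr)
        n = len(graphs)
        for _ in range(self.contrastive_epochs):
            order = rng.permutation(n)
            for lo in range(0, n, self.batch_size):
                idx = order[lo : lo + self.batch_size]
                if len(idx) < 2:
                    continue
                views = []
                for i in idx:
                    views.append(augment_view(graphs[i], cfg, int(rng.integers(2**31))))
                    views.append(augment_view(graphs[i], cfg, int(rng.integers(2**31))))
                batch = make_batch(views, self.readout)
                Z = ag.rownorm(encode_batch(batch, self.params_, enc_cfg))
                logits = ag.scale(ag.matmul_t(Z, Z), 1.0 / self.temperature)
                m = len(views)
                mask = ~np.eye(m, dtype=bool)
                targets = np.arange(m) ^ 1  # partner of each interleaved view
                loss = ag.cross_entropy_logits(logits, targets, mask)
                opt.zero_grad()
                loss.backward()
                opt.step()
                self.pretrain_loss_history_.append(float(loss.detach()))

    def fit(self, X, y):
        y = np.asarray(y, dtype=float)
        graphs = self._graphs(X)
        if len(graphs) != len(y):
            raise ValueError("X and y length mismatch")
        rng = np.random.default_rng(np.random.SeedSequence(self.seed))
        enc_cfg = self._encoder_config()
        self.params_ = init_params(enc_cfg)
        self.loss_history_: list[float] = []
        self.pretrain_loss_history_: list[float] = []
        self.y_mean_ = float(y.mean())
        self.y_std_ = float(y.std()) or 1.0
        if self.contrastive_epochs > 0:
            self._pretrain(graphs, rng)
        ys = (y - self.y_mean_) / self.y_std_
        mix_cfg = MixupConfig(
            alpha=self.mixup_alpha,
            w_g=self.w_g,
            w_y=self.w_y,
            top_k=self.top_k,
            n_mix_per_batch=self.n_mix_per_batch,
            label_range=self.label_range,
            seed=self.seed,
        )
        opt = ag.Adam(self.params_, lr=self.lr)
        n = len(graphs)
        for _ in range(self.epochs):
            order = rng.permutation(n)
            for lo in range(0, n, self.batch_size):
                idx = order[lo : lo + self.batch_size]
                batch = make_batch([graphs[i] for i in idx], self.readout)
                g_emb = encode_batch(batch, self.params_, enc_cfg)
                preds = head_forward(g_emb, self.params_)
                targets = ys[idx][:, None]
                n_mix = self.n_mix_per_batch if self.n_mix_per_batch is not None else len(idx)
                if self.mixup and len(idx) >= 2 and n_mix > 0:
                    y_batch = y[idx]  # pair scores use original label scale
                    pairs = select_mix_pairs(g_emb.detach(), y_batch, mix_cfg, rng)
                    lams = np.array([sample_mix_lambda(self.mixup_alpha, rng) for _ in pairs])
                    ii = [p[0] for p in pairs]
                    jj = [p[1] for p in pairs]
                    hi = ag.gather_rows(g_emb, ii)
                    hj = ag.gather_rows(g_emb, jj)
                    lam_col = lams[:, None]
                    h_mix = ag.add(ag.mul(hi, ag.Tensor(lam_col)), ag.mul(hj, ag.Tensor(1.0 - lam_col)))
                    y_mix = lams * ys[idx][ii] + (1 - lams) * ys[idx][jj]
                    preds = ag.concat([preds, head_forward(h_mix, self.params_)], axis=0)
                    targets = np.concatenate([targets, y_mix[:, None]], axis=0)
                loss = ag.mse_loss(preds, targets)
                opt.zero_grad()
                loss.backward()
                opt.step()
                self.loss_history_.append(float(loss.detach()))
        return self

    # -- inference ----------------------------------------------------------

    def encode_graphs(self, X) -> np.ndarray:
        """Graph embeddings for a list of molecules/graphs."""
        graphs = self._graphs(X)
        batch = make_batch(graphs, self.readout)
        return encode_batch(batch, self.params_, self._encoder_config()).detach()

    def predict(self, X, clip: bool = True) -> np.ndarray:
        graphs = self._graphs(X)
        batch = make_batch(graphs, self.readout)
        g_emb = encode_batch(batch, self.params_, self._encoder_config())
        raw = head_forward(g_emb, self.params_).detach()[:, 0] * self.y_std_ + self.y_mean_
        return np.clip(raw, 0.0, 100.0) if clip else raw


def train_regressor(
    graphs, labels, n_folds: int = 5, seed: int = 0, **estimator_kwargs
) -> tuple[list[RingGNNRegressor], np.ndarray]:
    """Cross-validated training: per-fold models plus out-of-fold predictions.

    Mixup and pretraining are confined to each training fold; every sample
    receives exactly one out-of-fold prediction.
    """
    y = np.asarray(labels, dtype=float)
    graphs = RingGNNRegressor._graphs(graphs)
    if len(graphs) < n_folds:
        raise ValueError("fewer samples than folds")
    oof = np.full(len(graphs), np.nan)
    models = []
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    for fold, (tr, va) in enumerate(kf.split(graphs)):
        est = RingGNNRegressor(seed=seed + fold, **estimator_kwargs)
        est.fit([graphs[i] for i in tr], y[tr])
        oof[va] = est.predict([graphs[i] for i in va])
        models.append(est)
    assert not np.isnan(oof).any()
    return models, oof
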