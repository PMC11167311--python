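"""Dual-branch graph convolutional model for pocket-ligand pairs.

Architecture: the pocket graph (residue nodes, 30-dim embedding
features) and the ligand graph (atom nodes, one-hot-style features) are
processed by separate stacks of graph-convolution layers
(symmetrically normalized adjacency with self-loops, ReLU), pooled to a
graph-level vector, concatenated and passed through fully connected
layers to a single output node.  The classification head applies a
sigmoid (score in (0, 1)); the regression head is linear (predicted
pKa).  Dropout (rate 0.2) is applied to the pooled pocket
representation, the pooled ligand representation and after the second
merge layer.

Training uses binary cross-entropy (classification) or mean squared
error (regression) with Adam, learning rate 0.0005 by default, and
checkpoints saved at a fixed epoch interval.

Implementation note: forward, backward and the optimizer are explicit
NumPy code.  Gradients are exact (verified against finite differences
in the test suite), and evaluation-mode inference is deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Literal, Sequence

import numpy as np
import scipy.sparse as sp


class TrainingDivergedError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# graph packing


@dataclass
class PackedGraphs:
    """A batch of graphs as one block-diagonal system."""

    x: np.ndarray               # (n_nodes_total, F)
    a_hat: sp.csr_matrix        # normalized adjacency with self-loops
    pool: sp.csr_matrix         # (n_graphs, n_nodes_total) mean-pool weights
    graph_index: np.ndarray     # node -> graph id
    n_graphs: int


def _normalized_adjacency(n: int, edges: np.ndarray) -> sp.csr_matrix:
    """D^-1/2 (A + I) D^-1/2 for an undirected edge list (both directions)."""
    if edges.size:
        rows = np.concatenate([edges[:, 0], np.arange(n)])
        cols = np.concatenate([edges[:, 1], np.arange(n)])
    else:
        rows = cols = np.arange(n)
    data = np.ones(len(rows))
    a = sp.coo_matrix((data, (rows, cols)), shape=(n, n)).tocsr()
    a.data[:] = 1.0  # collapse any duplicate edges
    deg = np.asarray(a.sum(axis=1)).ravel()
    d_inv_sqrt = 1.0 / np.sqrt(deg)
    return a.multiply(d_inv_sqrt[:, None]).multiply(d_inv_sqrt[None, :]).tocsr()


def pack_graphs(graphs: Sequence) -> PackedGraphs:
    """Concatenate graphs (objects with .node_features and .edge_array())
    into one block-diagonal batch."""
    if not graphs:
        raise ValueError("no graphs to pack")
    xs, blocks, gidx = [], [], []
    for gi, g in enumerate(graphs):
        x = np.asarray(g.node_features, dtype=np.float64)
        if x.ndim != 2 or x.shape[0] == 0:
            raise ValueError("graph with no nodes")
        if not np.all(np.isfinite(x)):
            raise ValueError("non-finite node features")
        xs.append(x)
        blocks.append(_normalized_adjacency(x.shape[0], g.edge_array()))
        gidx.append(np.full(x.shape[0], gi))
    x = np.vstack(xs)
    graph_index = np.concatenate(gidx)
    n_graphs = len(graphs)
    sizes = np.array([b.shape[0] for b in blocks])
    pool = sp.coo_matrix(
        (
            np.concatenate([np.full(s, 1.0 / s) for s in sizes]),
            (graph_index, np.arange(x.shape[0])),
        ),
        shape=(n_graphs, x.shape[0]),
    ).tocsr()
    return PackedGraphs(
        x=x,
        a_hat=sp.block_diag(blocks, format="csr"),
        pool=pool,
        graph_index=graph_index,
        n_graphs=n_graphs,
    )


# ---------------------------------------------------------------------------
# configuration


@dataclass
class ModelConfig:
    pocket_widths: tuple[int, ...] = (30, 60, 120)
    ligand_widths: tuple[int, ...] | None = None  # None -> (F, 2F, 4F)
    fc_widths: tuple[int, ...] = (256, 128)
    pooling: Literal["mean", "max"] = "mean"
    head: Literal["bc", "rg"] = "bc"
    dropout: float = 0.2

    def __post_init__(self):
        if not self.pocket_widths or not self.fc_widths:
            raise ValueError("width lists must be non-empty")
        if not (0 <= self.dropout < 1):
            raise ValueError("dropout must be in [0, 1)")


@dataclass
class TrainConfig:
    lr: float = 0.0005
    epochs: int = 2000
    checkpoint_interval: int = 100
    batch_size: int = 128
    seed: int = 0
    loss: Literal["bce", "mse"] | None = None  # None -> matched to head
    select: Literal["best", "last"] = "last"

    def __post_init__(self):
        if self.lr <= 0 or self.epochs < 1 or self.batch_size < 1:
            raise ValueError("invalid training configuration")


# ---------------------------------------------------------------------------
# model


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class GCNModel:
    """Seeded, explicitly differentiated dual-branch GCN."""

    def __init__(self, cfg: ModelConfig, pocket_dim: int, ligand_dim: int, seed: int = 0):
        self.cfg = cfg
        self.pocket_dim = pocket_dim
        self.ligand_dim = ligand_dim
        self.seed = seed
        if cfg.ligand_widths is None:
            lw = (ligand_dim, 2 * ligand_dim, 4 * ligand_dim)
        else:
            lw = tuple(cfg.ligand_widths)
        self.ligand_widths = lw
        rng = np.random.default_rng(seed)
        self.params: dict[str, np.ndarray] = {}
        self._init_branch(rng, "p", pocket_dim, cfg.pocket_widths)
        self._init_branch(rng, "l", ligand_dim, lw)
        merged = cfg.pocket_widths[-1] + lw[-1]
        dims = (merged, *cfg.fc_widths, 1)
        for k in range(len(dims) - 1):
            self.params[f"fc{k}_W"] = _glorot(rng, dims[k], dims[k + 1])
            self.params[f"fc{k}_b"] = np.zeros(dims[k + 1])
        self.n_fc = len(dims) - 1

    def _init_branch(self, rng, tag: str, in_dim: int, widths: tuple[int, ...]):
        dims = (in_dim, *widths)
        for k in range(len(widths)):
            self.params[f"{tag}{k}_W"] = _glorot(rng, dims[k], dims[k + 1])
            self.params[f"{tag}{k}_b"] = np.zeros(widths[k])

    # -- forward -----------------------------------------------------------

    def _branch_forward(self, tag: str, widths, batch: PackedGraphs):
        cache = []
        h = batch.x
        for k in range(len(widths)):
            m = h @ self.params[f"{tag}{k}_W"]
            z = batch.a_hat @ m + self.params[f"{tag}{k}_b"]
            h_new = np.maximum(z, 0.0)
            cache.append((h, z))
            h = h_new
        if self.cfg.pooling == "mean":
            pooled = batch.pool @ h
            pool_cache = None
        else:  # max
            pooled = np.full((batch.n_graphs, h.shape[1]), -np.inf)
            np.maximum.at(pooled, batch.graph_index, h)
            argmax = np.zeros((batch.n_graphs, h.shape[1]), dtype=np.int64)
            for col in range(h.shape[1]):
                # first node attaining the max in each graph
                hit = h[:, col] == pooled[batch.graph_index, col]
                idx = np.flatnonzero(hit)
                seen = np.zeros(batch.n_graphs, dtype=bool)
                for node in idx:
                    g = batch.graph_index[node]
                    if not seen[g]:
                        argmax[g, col] = node
                        seen[g] = True
            pool_cache = argmax
        return pooled, (cache, pool_cache, h.shape[0])

    def _branch_backward(self, tag: str, widths, batch: PackedGraphs,
                         branch_cache, d_pooled, grads):
        cache, argmax, n_nodes = branch_cache
        if self.cfg.pooling == "mean":
            dh = batch.pool.T @ d_pooled
        else:
            dh = np.zeros((n_nodes, d_pooled.shape[1]))
            rows = argmax
            cols = np.broadcast_to(np.arange(d_pooled.shape[1]), rows.shape)
            np.add.at(dh, (rows.ravel(), cols.ravel()), d_pooled.ravel())
        for k in reversed(range(len(widths))):
            h_in, z = cache[k]
            dz = dh * (z > 0)
            grads[f"{tag}{k}_b"] = dz.sum(axis=0)
            dm = batch.a_hat.T @ dz
            grads[f"{tag}{k}_W"] = h_in.T @ dm
            dh = dm @ self.params[f"{tag}{k}_W"].T

    def forward(
        self,
        pockets: PackedGraphs,
        ligands: PackedGraphs,
        train: bool = False,
        rng: np.random.Generator | None = None,
        return_cache: bool = False,
    ):
        """Scores for a packed batch; eval mode (train=False) is
        deterministic with dropout disabled."""
        if pockets.n_graphs != ligands.n_graphs:
            raise ValueError("pocket/ligand batch size mismatch")
        if pockets.x.shape[1] != self.pocket_dim or ligands.x.shape[1] != self.ligand_dim:
            raise ValueError("feature dimension mismatch with model configuration")
        pp, p_cache = self._branch_forward("p", self.cfg.pocket_widths, pockets)
        lp, l_cache = self._branch_forward("l", self.ligand_widths, ligands)

        def dropout_mask(shape):
            if not train or self.cfg.dropout == 0.0:
                return None
            if rng is None:
                raise ValueError("training-mode forward needs an RNG for dropout")
            return (rng.random(shape) >= self.cfg.dropout) / (1.0 - self.cfg.dropout)

        m_p, m_l = dropout_mask(pp.shape), dropout_mask(lp.shape)
        pp_d = pp if m_p is None else pp * m_p
        lp_d = lp if m_l is None else lp * m_l
        h = np.concatenate([pp_d, lp_d], axis=1)
        fc_cache = []
        m_fc = None
        for k in range(self.n_fc):
            z = h @ self.params[f"fc{k}_W"] + self.params[f"fc{k}_b"]
            last = k == self.n_fc - 1
            h_new = z if last else np.maximum(z, 0.0)
            if k == 1 and not last:  # after the second merge layer
                m_fc = dropout_mask(h_new.shape)
                if m_fc is not None:
                    h_new = h_new * m_fc
            fc_cache.append((h, z))
            h = h_new
        logits = h.ravel()
        if self.cfg.head == "bc":
            scores = 1.0 / (1.0 + np.exp(-logits))
        else:
            scores = logits
        if not return_cache:
            return scores
        cache = {
            "p": p_cache, "l": l_cache, "fc": fc_cache,
            "masks": (m_p, m_l, m_fc),
            "pp": pp, "lp": lp, "scores": scores, "logits": logits,
        }
        return scores, cache

    # -- backward ----------------------------------------------------------

    def backward(self, pockets, ligands, cache, d_logits) -> dict[str, np.ndarray]:
        """Gradients of the loss given d(loss)/d(logits)."""
        grads: dict[str, np.ndarray] = {}
        dh = d_logits.reshape(-1, 1)
        m_p, m_l, m_fc = cache["masks"]
        for k in reversed(range(self.n_fc)):
            h_in, z = cache["fc"][k]
            last = k == self.n_fc - 1
            if last:
                dz = dh
            else:
                if k == 1 and m_fc is not None:
                    dh = dh * m_fc
                dz = dh * (z > 0)
            grads[f"fc{k}_b"] = dz.sum(axis=0)
            grads[f"fc{k}_W"] = h_in.T @ dz
            dh = dz @ self.params[f"fc{k}_W"].T
        d_pp = dh[:, : self.cfg.pocket_widths[-1]]
        d_lp = dh[:, self.cfg.pocket_widths[-1]:]
        if m_p is not None:
            d_pp = d_pp * m_p
        if m_l is not None:
            d_lp = d_lp * m_l
        self._branch_backward("p", self.cfg.pocket_widths, pockets, cache["p"], d_pp, grads)
        self._branch_backward("l", self.ligand_widths, ligands, cache["l"], d_lp, grads)
        return grads

    # -- persistence -------------------------------------------------------

    def state_meta(self) -> dict:
        return {
            "cfg": asdict(self.cfg),
            "pocket_dim": self.pocket_dim,
            "ligand_dim": self.ligand_dim,
            "seed": self.seed,
        }

    def save(self, path, epoch: int | None = None, history: dict | None = None):
        meta = self.state_meta()
        meta["epoch"] = epoch
        meta["history"] = history or {}
        arrays = {f"param_{k}": v for k, v in self.params.items()}
        arrays["meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8).copy()
        np.savez_compressed(path, **arrays)

    @classmethod
    def load(cls, path) -> tuple["GCNModel", dict]:
        data = np.load(path)
        meta = json.loads(bytes(data["meta"]).decode())
        cfg_d = dict(meta["cfg"])
        for key in ("pocket_widths", "fc_widths"):
            cfg_d[key] = tuple(cfg_d[key])
        if cfg_d.get("ligand_widths") is not None:
            cfg_d["ligand_widths"] = tuple(cfg_d["ligand_widths"])
        cfg = ModelConfig(**cfg_d)
        model = cls(cfg, meta["pocket_dim"], meta["ligand_dim"], seed=meta["seed"])
        for k in model.params:
            model.params[k] = data[f"param_{k}"].copy()
        return model, meta


def build_model(cfg: ModelConfig, pocket_dim: int, ligand_dim: int, seed: int = 0) -> GCNModel:
    return GCNModel(cfg, pocket_dim, ligand_dim, seed=seed)


# ---------------------------------------------------------------------------
# losses


def bce_loss(scores: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy; returns (loss, d loss / d logits)."""
    eps = 1e-12
    p = np.clip(scores, eps, 1 - eps)
    loss = float(-np.mean(labels * np.log(p) + (1 - labels) * np.log(1 - p)))
    return loss, (scores - labels) / len(labels)


def mse_loss(pred: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    diff = pred - labels
    return float(np.mean(diff**2)), 2.0 * diff / len(labels)


# ---------------------------------------------------------------------------
# optimizer


class Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]):
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            params[k] -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)


# ---------------------------------------------------------------------------
# training


def collate(pairs: Sequence) -> tuple[PackedGraphs, PackedGraphs, np.ndarray]:
    """Pack a list of LabeledPair into pocket batch, ligand batch, labels."""
    pockets = pack_graphs([p.pocket for p in pairs])
    ligands = pack_graphs([p.ligand for p in pairs])
    labels = np.array([p.label for p in pairs], dtype=np.float64)
    return pockets, ligands, labels


def predict_batch(model: GCNModel, pairs: Sequence) -> np.ndarray:
    """Eval-mode scores, order-preserving; equal to per-pair forward
    within accumulation tolerance."""
    pockets, ligands, _ = collate(pairs)
    return model.forward(pockets, ligands, train=False)


def forward_pair(model: GCNModel, pocket, ligand) -> float:
    p = pack_graphs([pocket])
    l = pack_graphs([ligand])
    return float(model.forward(p, l, train=False)[0])


def _validation_metric(model: GCNModel, batch) -> dict[str, float]:
    from . import metrics as _metrics

    pockets, ligands, labels = batch
    scores = model.forward(pockets, ligands, train=False)
    if model.cfg.head == "bc":
        out = {"loss": bce_loss(scores, labels)[0]}
        if labels.min() != labels.max():
            out["auc"] = _metrics.classification_metrics(scores, labels)["auc"]
        return out
    mse = float(np.mean((scores - labels) ** 2))
    out = {"loss": mse, "rmse": float(np.sqrt(mse))}
    if np.ptp(scores) > 0 and np.ptp(labels) > 0:
        from scipy import stats

        out["pearson"] = float(stats.pearsonr(scores, labels).statistic)
    return out


def train(
    model: GCNModel,
    train_pairs: Sequence,
    val_pairs: Sequence,
    cfg: TrainConfig,
    checkpoint_dir=None,
) -> dict:
    """Minibatch Adam training with per-epoch validation metrics.

    Checkpoints are written every ``checkpoint_interval`` epochs when a
    directory is given; the returned history carries per-epoch training
    loss and validation metrics plus the checkpointed epochs.  The final
    model parameters are the last epoch's, or the best validation
    epoch's when ``select='best'`` (best = max AUC / min RMSE).
    """
    if not val_pairs:
        raise ValueError("validation set must be non-empty")
    loss_kind = cfg.loss or ("bce" if model.cfg.head == "bc" else "mse")
    if (loss_kind == "bce") != (model.cfg.head == "bc"):
        raise ValueError(f"loss {loss_kind!r} does not match head {model.cfg.head!r}")
    loss_fn = bce_loss if loss_kind == "bce" else mse_loss
    rng = np.random.default_rng(cfg.seed)
    order = rng.permutation(len(train_pairs))
    batches = [
        collate([train_pairs[i] for i in order[s: s + cfg.batch_size]])
        for s in range(0, len(train_pairs), cfg.batch_size)
    ]
    val_batch = collate(val_pairs)
    opt = Adam(model.params, lr=cfg.lr)
    history: dict = {"train_loss": [], "val": [], "checkpoints": []}
    select_key = "auc" if model.cfg.head == "bc" else "rmse"
    best = None
    for epoch in range(1, cfg.epochs + 1):
        epoch_loss = 0.0
        for bi in rng.permutation(len(batches)):
            pockets, ligands, labels = batches[bi]
            scores, cache = model.forward(
                pockets, ligands, train=True, rng=rng, return_cache=True
            )
            loss, d_scores = loss_fn(scores, labels)
            if not np.isfinite(loss):
                raise TrainingDivergedError(
                    f"non-finite training loss at epoch {epoch}"
                )
            if model.cfg.head == "bc":
                # d loss/d logits for sigmoid+BCE is (p - y)/n directly
                d_logits = (scores - labels) / len(labels)
            else:
                d_logits = d_scores
            grads = model.backward(pockets, ligands, cache, d_logits)
            opt.step(model.params, grads)
            epoch_loss += loss * labels.size
        history["train_loss"].append(epoch_loss / len(train_pairs))
        val = _validation_metric(model, val_batch)
        history["val"].append(val)
        if select_key in val:
            better = (
                best is None
                or (select_key == "auc" and val[select_key] > best[1])
                or (select_key == "rmse" and val[select_key] < best[1])
            )
            if better:
                best = (epoch, val[select_key], {k: v.copy() for k, v in model.params.items()})
        if epoch % cfg.checkpoint_interval == 0:
            history["checkpoints"].append(epoch)
            if checkpoint_dir is not None:
                model.save(
                    f"{checkpoint_dir}/checkpoint_epoch{epoch:05d}.npz",
                    epoch=epoch,
                    history={"train_loss": history["train_loss"][-1], "val": val},
                )
    if cfg.select == "best" and best is not None:
        history["best_epoch"] = best[0]
        model.params = best[2]
    return history
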