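"""The graph-convolutional function predictor.

Architecture, for a protein p_i with binary InterPro feature vector x_i:

  H(0)  = f(W(0) x + b(0))                       input fully connected layer
  H(l)  = f(Â H(l-1) W(l) + b(l)) + H(l-1)       residual GCN layer, l = 1..M
  ŷ_ij  = σ(w_j·h_i + b_j)                       per-term sigmoid output

with Â the symmetrically normalized adjacency (graph module), f = ReLU and
σ the logistic function. Training minimizes masked binary cross-entropy over
the labeled (training) proteins only — semi-supervised node classification —
with mini-batches whose M-hop neighborhoods are extracted from the top-k
pruned network. The model is trained once on the pooled proteins and networks
of all species (multispecies strategy).

Everything here is plain NumPy/SciPy: forward passes, hand-derived gradients
of the masked BCE loss, and an Adam optimizer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import sparse

from .features import SignatureMatrix
from .graph import NormalizedAdjacency, batch_neighborhood
from .homology import HomologyTable
from .scores import ScoreMatrix

EPS_CLIP = 1e-12  # score clipping inside the BCE loss


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


@dataclass
class TrainConfig:
    """Training hyperparameters.

    Defaults: batch size 40, 10 epochs, Adam with learning rate 1e-3, dropout
    0.5 after each GCN layer, k = 30 heaviest edges kept per node, M = 2 GCN
    layers, and a 3-model ensemble with distinct initialization seeds. The
    hidden width d = 512 is configuration-exposed.
    """

    batch_size: int = 40
    epochs: int = 10
    learning_rate: float = 1e-3
    dropout: float = 0.5
    k_edges: int = 30
    n_gcn_layers: int = 2
    hidden_dim: int = 512
    seeds: tuple = (0, 1, 2)
    #: initialize per-term output biases at the logit of the term's training
    #: prevalence, so early optimization is spent on signal rather than on
    #: learning base rates
    prior_bias_init: bool = True

    def __post_init__(self):
        if self.batch_size < 1 or self.hidden_dim < 1 or self.learning_rate <= 0:
            raise ValueError("batch size, hidden width and learning rate must be positive")
        if self.epochs < 0 or self.n_gcn_layers < 0:
            raise ValueError("epochs and layer count must be >= 0")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if len(self.seeds) < 1:
            raise ValueError("at least one ensemble seed required")


class GnnModel:
    """Parameter container: input layer, M residual GCN layers, per-term output.

    With ``extra_fc=True`` and M = 0 the model is the graph-free ablation
    (one additional dense hidden layer instead of graph convolutions).
    """

    def __init__(self, m: int, n_terms: int, terms: Sequence[str], config: TrainConfig,
                 seed: int = 0, extra_fc: bool = False):
        self.m = m
        self.n_terms = n_terms
        self.terms = list(terms)
        self.config = config
        self.extra_fc = extra_fc
        d = config.hidden_dim
        rng = np.random.default_rng(seed)

        def uniform(fan_in, shape):
            limit = 1.0 / np.sqrt(fan_in)
            return rng.uniform(-limit, limit, size=shape)

        self.params: dict[str, np.ndarray] = {
            "W0": uniform(m, (m, d)),
            "b0": np.zeros(d),
            "Wo": uniform(d, (n_terms, d)),
            "bo": np.zeros(n_terms),
        }
        for l in range(1, config.n_gcn_layers + 1):
            self.params[f"W{l}"] = uniform(d, (d, d))
            self.params[f"b{l}"] = np.zeros(d)
        if extra_fc:
            self.params["Wh"] = uniform(d, (d, d))
            self.params["bh"] = np.zeros(d)

    def copy_params(self) -> dict:
        return {k: v.copy() for k, v in self.params.items()}


# ---------------------------------------------------------------- forwards


def input_forward(x, model: GnnModel) -> np.ndarray:
    """H(0) = f(W(0) x + b(0)) row-wise; ``x`` is (S, m) sparse or dense."""
    if x.shape[1] != model.m:
        raise ValueError(f"feature width {x.shape[1]} != model m={model.m}")
    z = x @ model.params["W0"] + model.params["b0"]
    return relu(np.asarray(z))


def gcn_forward(h_prev: np.ndarray, adj, w: np.ndarray, b: np.ndarray, f=relu) -> np.ndarray:
    """One residual GCN layer: f(Â H W + b) + H.

    The residual is added outside the nonlinearity.
    """
    if not np.all(np.isfinite(h_prev)):
        raise ValueError("non-finite representation input")
    if adj.shape[0] != h_prev.shape[0]:
        raise ValueError("adjacency/representation dimension mismatch")
    return f(np.asarray(adj @ h_prev) @ w + b) + h_prev


def output_forward(h: np.ndarray, model: GnnModel) -> np.ndarray:
    """ŷ_ij = σ(w_j · h_i + b_j); scores strictly inside (0, 1)."""
    if h.shape[1] != model.params["Wo"].shape[1]:
        raise ValueError("representation width does not match output layer")
    return sigmoid(h @ model.params["Wo"].T + model.params["bo"])


def dnn_interpro_forward(x, model: GnnModel) -> np.ndarray:
    """Graph-free ablation forward: output(f(W_h·input(x) + b_h)). Consumes no
    network input, so predictions are invariant to any graph."""
    if not model.extra_fc:
        raise ValueError("model was not built with the extra hidden layer")
    h0 = input_forward(x, model)
    h1 = relu(h0 @ model.params["Wh"] + model.params["bh"])
    return output_forward(h1, model)


def gnn_scores(x, adj, model: GnnModel) -> np.ndarray:
    """Full composed forward on one (sub)graph."""
    h = input_forward(x, model)
    for l in range(1, model.config.n_gcn_layers + 1):
        h = gcn_forward(h, adj, model.params[f"W{l}"], model.params[f"b{l}"])
    return output_forward(h, model)


def bce_loss(scores: np.ndarray, truth: np.ndarray, labeled_mask: np.ndarray) -> float:
    """Masked binary cross-entropy, averaged over labeled proteins x all terms."""
    mask = np.asarray(labeled_mask, dtype=bool)
    if not mask.any():
        raise ValueError("labeled mask selects no proteins")
    y = np.asarray(truth, dtype=np.float64)[mask]
    p = np.clip(np.asarray(scores, dtype=np.float64)[mask], EPS_CLIP, 1.0 - EPS_CLIP)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


# ---------------------------------------------------------------- training


class _Adam:
    def __init__(self, params: dict, lr: float, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict):
        self.t += 1
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _gnn_batch_grads(model: GnnModel, x, adj, y: np.ndarray, seed_pos: np.ndarray,
                     rng: np.random.Generator | None):
    """Forward + backward on one mini-batch subgraph.

    Returns (loss, grads). ``rng`` enables inverted dropout after each GCN
    layer (training mode); None disables it.
    """
    p = model.params
    M = model.config.n_gcn_layers
    drop = model.config.dropout

    z0 = np.asarray(x @ p["W0"]) + p["b0"]
    h = relu(z0)
    cache = []
    for l in range(1, M + 1):
        ph = np.asarray(adj @ h)
        z = ph @ p[f"W{l}"] + p[f"b{l}"]
        h_new = relu(z) + h
        mask = None
        if rng is not None and drop > 0:
            mask = (rng.random(h_new.shape) >= drop) / (1.0 - drop)
            h_new = h_new * mask
        cache.append((ph, z, mask))
        h = h_new

    logits = h[seed_pos] @ p["Wo"].T + p["bo"]
    yhat = sigmoid(logits)
    n_seed, K = yhat.shape
    yc = np.clip(yhat, EPS_CLIP, 1.0 - EPS_CLIP)
    loss = float(-np.mean(y * np.log(yc) + (1 - y) * np.log(1 - yc)))

    g_logits = (yhat - y) / (n_seed * K)
    grads = {
        "Wo": g_logits.T @ h[seed_pos],
        "bo": g_logits.sum(axis=0),
    }
    dh = np.zeros_like(h)
    dh[seed_pos] = g_logits @ p["Wo"]
    for l in range(M, 0, -1):
        ph, z, mask = cache[l - 1]
        if mask is not None:
            dh = dh * mask
        dz = dh * (z > 0)
        grads[f"W{l}"] = ph.T @ dz
        grads[f"b{l}"] = dz.sum(axis=0)
        dh = dh + np.asarray(adj.T @ (dz @ p[f"W{l}"].T))
    dz0 = dh * (z0 > 0)
    grads["W0"] = np.asarray((x.T @ dz0))
    grads["b0"] = dz0.sum(axis=0)
    return loss, grads


def _dnn_batch_grads(model: GnnModel, x, y: np.ndarray):
    p = model.params
    z0 = np.asarray(x @ p["W0"]) + p["b0"]
    h0 = relu(z0)
    z1 = h0 @ p["Wh"] + p["bh"]
    h1 = relu(z1)
    logits = h1 @ p["Wo"].T + p["bo"]
    yhat = sigmoid(logits)
    n, K = yhat.shape
    yc = np.clip(yhat, EPS_CLIP, 1.0 - EPS_CLIP)
    loss = float(-np.mean(y * np.log(yc) + (1 - y) * np.log(1 - yc)))
    g = (yhat - y) / (n * K)
    dh1 = g @ p["Wo"]
    dz1 = dh1 * (z1 > 0)
    dh0 = dz1 @ p["Wh"].T
    dz0 = dh0 * (z0 > 0)
    grads = {
        "Wo": g.T @ h1,
        "bo": g.sum(axis=0),
        "Wh": h0.T @ dz1,
        "bh": dz1.sum(axis=0),
        "W0": np.asarray(x.T @ dz0),
        "b0": dz0.sum(axis=0),
    }
    return loss, grads


def train(features: SignatureMatrix, normalized: NormalizedAdjacency, train_table,
          valid_table=None, config: TrainConfig | None = None, seed: int = 0,
          extra_fc: bool = False) -> tuple[GnnModel, list]:
    """Train one model; returns (model, per-epoch mean losses).

    The training node set is the labeled proteins present in the graph. Each
    mini-batch extracts the M-hop neighborhood of its seed proteins and runs
    the forward/backward pass on that subgraph only. With ``extra_fc`` the
    graph is ignored and the graph-free ablation is trained instead.
    Deterministic given ``seed``.
    """
    config = config or TrainConfig()
    labeled = [p for p in train_table.proteins if extra_fc or p in normalized.index]
    if not labeled:
        raise ValueError("no labeled proteins available for training")
    y_by_protein = {p: i for i, p in enumerate(train_table.proteins)}
    y_dense = train_table.dense().astype(np.float64)

    model = GnnModel(features.m, train_table.n_terms, train_table.terms, config,
                     seed=seed, extra_fc=extra_fc)
    if config.prior_bias_init:
        prev = np.clip(y_dense[[y_by_protein[p] for p in labeled]].mean(axis=0),
                       1e-4, 1 - 1e-4)
        model.params["bo"] = np.log(prev / (1.0 - prev))
    if config.epochs == 0:
        return model, []
    opt = _Adam(model.params, config.learning_rate)
    rng = np.random.default_rng(seed + 1_000_003)
    history = []
    labeled = list(labeled)
    for epoch in range(config.epochs):
        order = rng.permutation(len(labeled))
        losses = []
        for start in range(0, len(labeled), config.batch_size):
            batch = [labeled[i] for i in order[start:start + config.batch_size]]
            y = y_dense[[y_by_protein[p] for p in batch]]
            if extra_fc:
                x = features.rows(batch)
                loss, grads = _dnn_batch_grads(model, x, y)
            else:
                sub = batch_neighborhood(normalized, batch, hops=config.n_gcn_layers)
                x = features.rows(sub.included)
                loss, grads = _gnn_batch_grads(model, x, sub.local_matrix, y,
                                               sub.seed_positions,
                                               rng if config.dropout > 0 else None)
            if not np.isfinite(loss):
                raise RuntimeError(f"training diverged at epoch {epoch}, batch {start // config.batch_size}")
            opt.step(model.params, grads)
            losses.append(loss)
        history.append(float(np.mean(losses)))
    return model, history


def train_ensemble(features: SignatureMatrix, normalized: NormalizedAdjacency,
                   train_table, valid_table=None, config: TrainConfig | None = None,
                   base_seed: int = 0) -> list:
    """Train one model per configured seed (different initial weights)."""
    config = config or TrainConfig()
    return [
        train(features, normalized, train_table, valid_table, config,
              seed=int(base_seed) + int(s))[0]
        for s in config.seeds
    ]


# ---------------------------------------------------------------- prediction


def predict(model: GnnModel, features: SignatureMatrix, normalized: NormalizedAdjacency | None,
            proteins: Sequence[str], homology: HomologyTable | None = None) -> ScoreMatrix:
    """Score the requested proteins.

    In-network proteins get forward-pass scores (stratum ``STRI``). A protein
    absent from the network copies the score row of its highest-bit-score
    in-network homolog (``HOMO``). With neither, the row is all zeros and the
    protein is flagged ``NONE`` — a documented outcome, not an error.
    """
    if model.extra_fc:
        values = dnn_interpro_forward(features.rows(proteins), model)
        return ScoreMatrix(proteins, model.terms, values,
                           {p: "STRI" for p in proteins})
    x = features.rows(normalized.nodes)
    full = gnn_scores(x, normalized.matrix, model)
    return _assemble_rows(full, normalized, proteins, model.terms, homology)


def predict_ensemble(models: Sequence[GnnModel], features: SignatureMatrix,
                     normalized: NormalizedAdjacency | None, proteins: Sequence[str],
                     homology: HomologyTable | None = None) -> ScoreMatrix:
    return ensemble_average([predict(m, features, normalized, proteins, homology) for m in models])


def _assemble_rows(full: np.ndarray, normalized: NormalizedAdjacency, proteins: Sequence[str],
                   terms: Sequence[str], homology: HomologyTable | None) -> ScoreMatrix:
    values = np.zeros((len(proteins), full.shape[1]))
    strata = {}
    in_graph = set(normalized.index)
    for i, p in enumerate(proteins):
        if p in normalized.index:
            values[i] = full[normalized.index[p]]
            strata[p] = "STRI"
            continue
        best = homology.best_homolog(p, in_graph) if homology is not None else None
        if best is not None:
            values[i] = full[normalized.index[best]]
            strata[p] = "HOMO"
        else:
            strata[p] = "NONE"
    return ScoreMatrix(proteins, terms, values, strata)


def ensemble_average(score_matrices: Sequence[ScoreMatrix]) -> ScoreMatrix:
    """Elementwise arithmetic mean of score matrices on identical axes."""
    first = score_matrices[0]
    for sm in score_matrices[1:]:
        if sm.proteins != first.proteins or sm.terms != first.terms:
            raise ValueError("score matrices have mismatched axes")
    mean = np.mean([sm.values for sm in score_matrices], axis=0)
    return ScoreMatrix(first.proteins, first.terms, mean, first.strata)


# ---------------------------------------------------------------- checkpoints


def save_model(model: GnnModel, path):
    """Write a self-describing .npz checkpoint (arrays + JSON metadata)."""
    meta = {
        "m": model.m,
        "n_terms": model.n_terms,
        "terms": model.terms,
        "extra_fc": model.extra_fc,
        "config": {
            "batch_size": model.config.batch_size,
            "epochs": model.config.epochs,
            "learning_rate": model.config.learning_rate,
            "dropout": model.config.dropout,
            "k_edges": model.config.k_edges,
            "n_gcn_layers": model.config.n_gcn_layers,
            "hidden_dim": model.config.hidden_dim,
            "seeds": list(model.config.seeds),
            "prior_bias_init": model.config.prior_bias_init,
        },
    }
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **model.params)


def load_model(path) -> GnnModel:
    data = np.load(path)
    meta = json.loads(bytes(data["__meta__"]).decode())
    cfg = meta["config"]
    cfg["seeds"] = tuple(cfg["seeds"])
    config = TrainConfig(**cfg)
    model = GnnModel(meta["m"], meta["n_terms"], meta["terms"], config,
                     extra_fc=meta["extra_fc"])
    for k in model.params:
        model.params[k] = data[k]
    return model
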