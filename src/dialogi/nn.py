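"""Minimal NumPy neural-network core for the document classifiers.

Architecture (baseline): trainable embedding (pretrained init, out-of-vocab
rows random) -> BiLSTM (one LSTM per direction, final states concatenated)
-> dense ReLU -> dense sigmoid.  The extended variant feeds an external
feature vector through a separate ReLU dense layer whose output is *added*
to the text branch's dense output before the shared sigmoid output layer.

Everything is explicit: forward, full backpropagation through time, Adam.
Training is single-threaded and fully deterministic given a seed, which the
gradient-check and reproducibility tests rely on.  Padding (index 0) is
masked: LSTM states carry through padded steps, so the final state equals
the state after the last real token.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

PAD, UNK = 0, 1


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


def _glorot(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    limit = np.sqrt(6.0 / (shape[0] + shape[1]))
    return rng.uniform(-limit, limit, size=shape)


def _orthogonal(rng: np.random.Generator, rows: int, cols: int) -> np.ndarray:
    a = rng.standard_normal((max(rows, cols), min(rows, cols)))
    q, r = np.linalg.qr(a)
    q = q * np.sign(np.diag(r))
    return q[:rows, :cols] if q.shape != (rows, cols) else q


def build_vocab(texts: list[list[str]]) -> dict[str, int]:
    """Word -> index map; 0 and 1 are reserved for padding and unknowns."""
    vocab: dict[str, int] = {}
    for text in texts:
        for w in text:
            if w not in vocab:
                vocab[w] = len(vocab) + 2
    return vocab


def texts_to_ids(texts: list[list[str]], vocab: dict[str, int],
                 max_len: int = 256) -> np.ndarray:
    x = np.zeros((len(texts), max_len), dtype=np.int32)
    for i, text in enumerate(texts):
        ids = [vocab.get(w, UNK) for w in text[:max_len]]
        x[i, : len(ids)] = ids
    return x


def _reverse_padded(x: np.ndarray) -> np.ndarray:
    """Reverse each row's non-pad prefix in place-order (padding stays at the end)."""
    out = np.zeros_like(x)
    lengths = (x != PAD).sum(axis=1)
    for i, L in enumerate(lengths):
        out[i, :L] = x[i, :L][::-1]
    return out


@dataclass
class LSTMWeights:
    w: np.ndarray   # (embed, 4u) gate order i, f, g, o
    u: np.ndarray   # (units, 4u)
    b: np.ndarray   # (4u,)


def _init_lstm(rng: np.random.Generator, embed_dim: int, units: int) -> LSTMWeights:
    w = _glorot(rng, (embed_dim, 4 * units))
    u = np.hstack([_orthogonal(rng, units, units) for _ in range(4)])
    b = np.zeros(4 * units)
    b[units: 2 * units] = 1.0  # forget-gate bias
    return LSTMWeights(w=w, u=u, b=b)


def _lstm_forward(emb: np.ndarray, mask: np.ndarray, p: LSTMWeights):
    """emb (B,T,e), mask (B,T) -> final hidden state (B,u) and BPTT caches."""
    B, T, _ = emb.shape
    units = p.u.shape[0]
    h = np.zeros((B, units))
    c = np.zeros((B, units))
    caches = []
    for t in range(T):
        x = emb[:, t]
        m = mask[:, t][:, None]
        z = x @ p.w + h @ p.u + p.b
        i = _sigmoid(z[:, :units])
        f = _sigmoid(z[:, units: 2 * units])
        g = np.tanh(z[:, 2 * units: 3 * units])
        o = _sigmoid(z[:, 3 * units:])
        c_new = f * c + i * g
        h_new = o * np.tanh(c_new)
        caches.append((x, h, c, i, f, g, o, c_new, m))
        h = m * h_new + (1 - m) * h
        c = m * c_new + (1 - m) * c
    return h, caches


def _lstm_backward(dh_final: np.ndarray, caches, p: LSTMWeights):
    """Returns (dW, dU, db, d_emb (B,T,e))."""
    B = dh_final.shape[0]
    units = p.u.shape[0]
    T = len(caches)
    dw = np.zeros_like(p.w)
    du = np.zeros_like(p.u)
    db = np.zeros_like(p.b)
    d_emb = np.zeros((B, T, p.w.shape[0]))
    dh = dh_final
    dc = np.zeros((B, units))
    for t in range(T - 1, -1, -1):
        x, h_prev, c_prev, i, f, g, o, c_new, m = caches[t]
        dh_new = dh * m
        dh_carry = dh * (1 - m)
        dc_masked = dc * m
        dc_carry = dc * (1 - m)
        tanh_c = np.tanh(c_new)
        do = dh_new * tanh_c
        dc_new = dc_masked + dh_new * o * (1 - tanh_c**2)
        di = dc_new * g
        dg = dc_new * i
        df = dc_new * c_prev
        dz = np.concatenate([di * i * (1 - i), df * f * (1 - f),
                             dg * (1 - g**2), do * o * (1 - o)], axis=1)
        dw += x.T @ dz
        du += h_prev.T @ dz
        db += dz.sum(axis=0)
        d_emb[:, t] = dz @ p.w.T
        dh = dz @ p.u.T + dh_carry
        dc = dc_new * f + dc_carry
    return dw, du, db, d_emb


@dataclass
class BiLSTMClassifier:
    """Baseline/extended classifier with explicit parameters.

    ``feature_dim > 0`` adds the external-feature branch (dense ReLU whose
    output is added to the text dense output before the shared output layer).
    """

    embed_dim: int
    lstm_units: int
    dense_units: int
    vocab: dict[str, int]
    feature_dim: int = 0
    seed: int = 0
    params: dict[str, np.ndarray] = field(default_factory=dict, repr=False)
    fwd: LSTMWeights | None = field(default=None, repr=False)
    bwd: LSTMWeights | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.params:
            return
        rng = np.random.default_rng(self.seed)
        v = len(self.vocab) + 2
        e, u_, d = self.embed_dim, self.lstm_units, self.dense_units
        self.params["E"] = rng.standard_normal((v, e)) / np.sqrt(e)
        self.params["E"][PAD] = 0.0
        self.fwd = _init_lstm(rng, e, u_)
        self.bwd = _init_lstm(rng, e, u_)
        self.params.update(fW=self.fwd.w, fU=self.fwd.u, fb=self.fwd.b,
                           bW=self.bwd.w, bU=self.bwd.u, bb=self.bwd.b)
        self.params["W1"] = _glorot(rng, (2 * u_, d))
        self.params["b1"] = np.zeros(d)
        self.params["W2"] = _glorot(rng, (d, 1))
        self.params["b2"] = np.zeros(1)
        if self.feature_dim > 0:
            self._init_extension(rng)

    def _init_extension(self, rng: np.random.Generator) -> None:
        self.params["Wf"] = _glorot(rng, (self.feature_dim, self.dense_units))
        self.params["bf"] = np.zeros(self.dense_units)

    def load_pretrained(self, word_vectors: dict[str, np.ndarray]) -> int:
        """Overwrite embedding rows for in-vocab words; returns the hit count."""
        hits = 0
        for word, idx in self.vocab.items():
            vec = word_vectors.get(word)
            if vec is not None:
                if len(vec) != self.embed_dim:
                    raise ValueError(f"pretrained dim {len(vec)} != embed_dim {self.embed_dim}")
                self.params["E"][idx] = vec
                hits += 1
        return hits

    def add_extension(self, feature_dim: int, seed: int | None = None) -> None:
        """Attach the external-feature branch to a trained baseline."""
        if feature_dim <= 0:
            raise ValueError(f"feature_dim must be positive, got {feature_dim}")
        self.feature_dim = feature_dim
        self._init_extension(np.random.default_rng(self.seed + 1 if seed is None else seed))

    # ---- persistence -----------------------------------------------------

    def save(self, path) -> None:
        """Persist parameters + vocab to an .npz archive."""
        import json

        meta = dict(embed_dim=self.embed_dim, lstm_units=self.lstm_units,
                    dense_units=self.dense_units, feature_dim=self.feature_dim,
                    seed=self.seed, vocab=self.vocab)
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **self.params)

    @classmethod
    def load(cls, path) -> "BiLSTMClassifier":
        import json

        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            params = {k: data[k] for k in data.files if k != "__meta__"}
        model = cls(embed_dim=meta["embed_dim"], lstm_units=meta["lstm_units"],
                    dense_units=meta["dense_units"], vocab=meta["vocab"],
                    feature_dim=meta["feature_dim"], seed=meta["seed"], params=params,
                    fwd=LSTMWeights(params["fW"], params["fU"], params["fb"]),
                    bwd=LSTMWeights(params["bW"], params["bU"], params["bb"]))
        return model

    # ---- forward ---------------------------------------------------------

    def text_dense_out(self, x: np.ndarray, batch: int = 512) -> np.ndarray:
        """ReLU dense output of the (frozen) text branch, batched."""
        outs = []
        for lo in range(0, len(x), batch):
            a1, _ = self._forward_text(x[lo: lo + batch])
            outs.append(a1)
        return np.concatenate(outs) if outs else np.zeros((0, self.dense_units))

    def _forward_text(self, x: np.ndarray):
        mask = (x != PAD).astype(np.float64)
        emb = self.params["E"][x]
        h_fwd, cache_f = _lstm_forward(emb, mask, self.fwd)
        x_rev = _reverse_padded(x)  # valid input has a contiguous non-pad prefix
        emb_rev = self.params["E"][x_rev]
        h_bwd, cache_b = _lstm_backward_input(emb_rev, (x_rev != PAD).astype(np.float64),
                                              self.bwd)
        h = np.concatenate([h_fwd, h_bwd], axis=1)
        z1 = h @ self.params["W1"] + self.params["b1"]
        a1 = np.maximum(z1, 0.0)
        cache = dict(x=x, x_rev=x_rev, mask=mask, cache_f=cache_f, cache_b=cache_b,
                     h=h, z1=z1)
        return a1, cache

    def _feature_act(self, feats: np.ndarray):
        zf = feats @ self.params["Wf"] + self.params["bf"]
        return np.maximum(zf, 0.0), zf

    def forward(self, x: np.ndarray, feats: np.ndarray | None = None):
        """Probabilities plus caches for backprop."""
        a1, cache = self._forward_text(x)
        a = a1
        if self.feature_dim > 0 and feats is not None:
            af, zf = self._feature_act(feats)
            a = a1 + af
            cache.update(feats=feats, zf=zf)
        logits = (a @ self.params["W2"] + self.params["b2"]).ravel()
        probs = _sigmoid(logits)
        cache.update(a1=a1, a=a, probs=probs)
        return probs, cache

    def predict_proba(self, x: np.ndarray, feats: np.ndarray | None = None,
                      batch: int = 512) -> np.ndarray:
        out = []
        for lo in range(0, len(x), batch):
            f = feats[lo: lo + batch] if feats is not None else None
            probs, _ = self.forward(x[lo: lo + batch], f)
            out.append(probs)
        return np.concatenate(out) if out else np.zeros(0)

    # ---- backward --------------------------------------------------------

    def backward(self, cache: dict, y: np.ndarray,
                 trainable: str = "all") -> dict[str, np.ndarray]:
        """Mean-BCE gradients; ``trainable`` is ``all`` or ``extension``."""
        probs = cache["probs"]
        B = len(y)
        dlogits = (probs - y) / B                              # (B,)
        grads: dict[str, np.ndarray] = {}
        da = dlogits[:, None] * self.params["W2"].T            # (B, d)
        if trainable == "extension":
            zf = cache["zf"]
            daf = da * (zf > 0)
            grads["Wf"] = cache["feats"].T @ daf
            grads["bf"] = daf.sum(axis=0)
            return grads
        grads["W2"] = cache["a"].T @ dlogits[:, None]
        grads["b2"] = np.array([dlogits.sum()])
        if "zf" in cache:
            daf = da * (cache["zf"] > 0)
            grads["Wf"] = cache["feats"].T @ daf
            grads["bf"] = daf.sum(axis=0)
        dz1 = da * (cache["z1"] > 0)
        grads["W1"] = cache["h"].T @ dz1
        grads["b1"] = dz1.sum(axis=0)
        dh = dz1 @ self.params["W1"].T
        u_ = self.lstm_units
        dwf_, duf_, dbf_, demb_f = _lstm_backward(dh[:, :u_], cache["cache_f"], self.fwd)
        dwb_, dub_, dbb_, demb_b = _lstm_backward(dh[:, u_:], cache["cache_b"], self.bwd)
        grads.update(fW=dwf_, fU=duf_, fb=dbf_, bW=dwb_, bU=dub_, bb=dbb_)
        de = np.zeros_like(self.params["E"])
        # demb_* are already zero at masked steps (BPTT propagates the mask)
        np.add.at(de, cache["x"], demb_f)
        np.add.at(de, cache["x_rev"], demb_b)
        de[PAD] = 0.0
        grads["E"] = de
        return grads


def _lstm_backward_input(emb_rev: np.ndarray, mask: np.ndarray, p: LSTMWeights):
    """Backward-direction LSTM = forward LSTM over the reversed sequence."""
    return _lstm_forward(emb_rev, mask, p)


class Adam:
    def __init__(self, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-7) -> None:
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for key, g in grads.items():
            if key not in self.m:
                self.m[key] = np.zeros_like(g)
                self.v[key] = np.zeros_like(g)
            self.m[key] = self.beta1 * self.m[key] + (1 - self.beta1) * g
            self.v[key] = self.beta2 * self.v[key] + (1 - self.beta2) * g**2
            params[key] -= self.lr * (self.m[key] / b1t) / (np.sqrt(self.v[key] / b2t) + self.eps)


def bce_loss(probs: np.ndarray, y: np.ndarray, eps: float = 1e-12) -> float:
    p = np.clip(probs, eps, 1 - eps)
    return float(-(y * np.log(p) + (1 - y) * np.log(1 - p)).mean())


def train_model(model: BiLSTMClassifier, x: np.ndarray, y: np.ndarray,
                feats: np.ndarray | None = None, lr: float = 1e-3, epochs: int = 1,
                batch_size: int = 32, seed: int = 0, trainable: str = "all") -> None:
    """Shuffled minibatch Adam training (in place)."""
    opt = Adam(lr=lr)
    rng = np.random.default_rng(seed)
    for _ in range(epochs):
        order = rng.permutation(len(x))
        for lo in range(0, len(x), batch_size):
            idx = order[lo: lo + batch_size]
            f = feats[idx] if feats is not None else None
            _, cache = model.forward(x[idx], f)
            grads = model.backward(cache, y[idx], trainable=trainable)
            opt.step(model.params, grads)
            model.params["E"][PAD] = 0.0


def train_extension_cached(model: BiLSTMClassifier, feats: np.ndarray,
                           a1_cached: np.ndarray, y: np.ndarray, lr: float = 1e-2,
                           epochs: int = 1, batch_size: int = 32, seed: int = 0) -> None:
    """Train only the feature branch against precomputed (frozen) text-branch
    activations — mathematically identical to running the full extended model
    with every base layer frozen, but without re-running the BiLSTM."""
    opt = Adam(lr=lr)
    rng = np.random.default_rng(seed)
    w2, b2 = model.params["W2"], model.params["b2"]
    for _ in range(epochs):
        order = rng.permutation(len(feats))
        for lo in range(0, len(feats), batch_size):
            idx = order[lo: lo + batch_size]
            af, zf = model._feature_act(feats[idx])
            logits = ((a1_cached[idx] + af) @ w2 + b2).ravel()
            probs = _sigmoid(logits)
            dlogits = (probs - y[idx]) / len(idx)
            da = dlogits[:, None] * w2.T
            daf = da * (zf > 0)
            grads = {"Wf": feats[idx].T @ daf, "bf": daf.sum(axis=0)}
            opt.step(model.params, grads)


def predict_extended_cached(model: BiLSTMClassifier, feats: np.ndarray,
                            a1_cached: np.ndarray) -> np.ndarray:
    af, _ = model._feature_act(feats)
    logits = ((a1_cached + af) @ model.params["W2"] + model.params["b2"]).ravel()
    return _sigmoid(logits)
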