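"""Attention-based feature-level fusion of the three modalities.

Each modality's feature vector is chunked into tokens and linearly
projected to a shared model width.  Per modality, multi-head scaled
dot-product self-attention reweights the tokens:

    Q = Wq x,  K = Wk x,  V = Wv x,      x' = softmax(Q K^T / s) V

and for every pair of modalities a two-path cross-attention lets each
modality select relevant structure from the other: queries and values
come from one modality, keys from the other, and symmetrically for the
reverse path.  Pooled self- and cross-attention outputs are concatenated
into the fused vector, which feeds a dense prediction head used to train
all attention parameters end-to-end (cross-entropy, Adam); the fused
vectors can then be re-extracted for an external classifier.

Everything is plain numpy with hand-derived gradients, so training is
exactly reproducible from the config seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "AttentionConfig",
    "FusionModel",
    "MODALITY_ORDER",
    "tokenize",
    "self_attention",
    "cross_attention",
    "train_fusion",
]

#: Canonical modality order; fused vectors always concatenate in this order.
MODALITY_ORDER = ("handwriting", "drawing", "clinical")


class DegenerateLabelsError(ValueError):
    """Training requires both classes to be present."""


@dataclass
class AttentionConfig:
    """Fusion architecture and training hyperparameters.

    ``model_dim`` is the shared projection width d (divisible by
    ``n_heads``); ``scale_mode`` selects the attention logit scale:
    ``"sqrt_d"`` divides by sqrt(head width) (standard scaled dot
    product), ``"d"`` divides by the full model width.
    """

    model_dim: int = 16
    n_heads: int = 2
    n_tokens: int = 4
    dropout_rate: float = 0.0
    scale_mode: str = "sqrt_d"
    seed: int = 0
    epochs: int = 150
    learning_rate: float = 0.01
    batch_size: int = 32

    def __post_init__(self) -> None:
        if self.model_dim % self.n_heads != 0:
            raise ValueError("model_dim must be divisible by n_heads")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.scale_mode not in ("sqrt_d", "d"):
            raise ValueError("scale_mode must be 'sqrt_d' or 'd'")

    @property
    def scale(self) -> float:
        if self.scale_mode == "sqrt_d":
            return float(np.sqrt(self.model_dim // self.n_heads))
        return float(self.model_dim)


# --------------------------------------------------------------------------
# attention primitives (forward + backward)
# --------------------------------------------------------------------------

def _split_heads(z: np.ndarray, h: int) -> np.ndarray:
    n, t, d = z.shape
    return z.reshape(n, t, h, d // h).transpose(0, 2, 1, 3)


def _merge_heads(z: np.ndarray) -> np.ndarray:
    n, h, t, dh = z.shape
    return z.transpose(0, 2, 1, 3).reshape(n, t, h * dh)


def _softmax(s: np.ndarray) -> np.ndarray:
    e = np.exp(s - s.max(axis=-1, keepdims=True))
    return e / e.sum(axis=-1, keepdims=True)


def _attention_forward(xq, xk, xv, wq, wk, wv, config: AttentionConfig):
    """Multi-head attention core.  Inputs are (N, T, d) token arrays; the
    query/value source and the key source may differ (cross-attention)."""
    h = config.n_heads
    q = _split_heads(xq @ wq, h)
    k = _split_heads(xk @ wk, h)
    v = _split_heads(xv @ wv, h)
    s = q @ k.transpose(0, 1, 3, 2) / config.scale
    a = _softmax(s)
    o = _merge_heads(a @ v)
    cache = (xq, xk, xv, wq, wk, wv, q, k, v, a, config)
    return o, cache


def _attention_backward(do: np.ndarray, cache):
    xq, xk, xv, wq, wk, wv, q, k, v, a, config = cache
    h = config.n_heads
    doh = _split_heads(do, h)
    dv = a.transpose(0, 1, 3, 2) @ doh
    da = doh @ v.transpose(0, 1, 3, 2)
    ds = a * (da - (da * a).sum(axis=-1, keepdims=True))
    ds = ds / config.scale
    dq = ds @ k
    dk = ds.transpose(0, 1, 3, 2) @ q
    dqf, dkf, dvf = (_merge_heads(z) for z in (dq, dk, dv))
    grads = {
        "wq": np.einsum("nti,ntj->ij", xq, dqf),
        "wk": np.einsum("nti,ntj->ij", xk, dkf),
        "wv": np.einsum("nti,ntj->ij", xv, dvf),
    }
    dxq = dqf @ wq.T
    dxk = dkf @ wk.T
    dxv = dvf @ wv.T
    return dxq, dxk, dxv, grads


def _as_batch(x: np.ndarray) -> tuple[np.ndarray, bool]:
    x = np.asarray(x, dtype=float)
    if x.ndim == 2:
        return x[None], True
    return x, False


def self_attention(x: np.ndarray, params: dict[str, np.ndarray],
                   config: AttentionConfig) -> np.ndarray:
    """Multi-head self-attention over one modality's tokens.

    ``x`` is ``(T, d)`` or ``(N, T, d)``; ``params`` holds ``wq, wk, wv``
    and the output projection ``wo`` (each ``(d, d)``).  The output has
    the input's token shape.
    """
    xb, squeeze = _as_batch(x)
    if xb.shape[-1] != params["wq"].shape[0]:
        raise ValueError("token dimension does not match projection shape")
    o, _ = _attention_forward(xb, xb, xb, params["wq"], params["wk"], params["wv"], config)
    out = o @ params["wo"]
    return out[0] if squeeze else out


def cross_attention(x_a: np.ndarray, x_b: np.ndarray,
                    params: dict[str, np.ndarray],
                    config: AttentionConfig) -> tuple[np.ndarray, np.ndarray]:
    """Two-path cross-attention between a pair of modalities.

    Path 1: queries and values from ``x_a``, keys from ``x_b``; path 2
    reverses the roles.  Returns the pair ``(x''_a, x''_b)``.

    Because values are drawn from the query modality while attention
    weights run over the other modality's keys, the construction is only
    defined when both modalities carry the same number of tokens (the
    fusion model guarantees this by tokenizing every modality to a shared
    token count).
    """
    xa, sq_a = _as_batch(x_a)
    xb, sq_b = _as_batch(x_b)
    if xa.shape[-2] != xb.shape[-2]:
        raise ValueError(
            "cross-attention requires equal token counts: values come from "
            "the query modality but weights run over the other modality's keys"
        )
    o1, _ = _attention_forward(xa, xb, xa, params["wq1"], params["wk1"],
                               params["wv1"], config)
    o2, _ = _attention_forward(xb, xa, xb, params["wq2"], params["wk2"],
                               params["wv2"], config)
    return (o1[0] if sq_a else o1), (o2[0] if sq_b else o2)


# --------------------------------------------------------------------------
# tokenization
# --------------------------------------------------------------------------

def tokenize(features: np.ndarray, n_tokens: int) -> np.ndarray:
    """Chunk a ``(N, F)`` feature matrix into ``(N, n_tokens, chunk)``.

    Features are split into ``n_tokens`` contiguous groups, zero-padded
    to a common chunk width; each group becomes one token.
    """
    x = np.atleast_2d(np.asarray(features, dtype=float))
    n, f = x.shape
    chunk = int(np.ceil(f / n_tokens))
    padded = np.zeros((n, n_tokens * chunk))
    padded[:, :f] = x
    return padded.reshape(n, n_tokens, chunk)


# --------------------------------------------------------------------------
# the model
# --------------------------------------------------------------------------

def _pairs(modalities: tuple[str, ...]) -> list[tuple[str, str]]:
    mods = [m for m in MODALITY_ORDER if m in modalities]
    return [(a, b) for i, a in enumerate(mods) for b in mods[i + 1:]]


@dataclass
class FusionModel:
    """Learned fusion parameters plus training metadata."""

    config: AttentionConfig
    modalities: tuple[str, ...]
    feature_dims: dict[str, int]
    params: dict[str, np.ndarray]
    training_log: list[float] = field(default_factory=list)

    @property
    def fused_dim(self) -> int:
        m = len(self.modalities)
        return (m + 2 * len(_pairs(self.modalities))) * self.config.model_dim

    # -------------------------------------------------------------- forward
    def _forward(self, features: dict[str, np.ndarray], labels=None,
                 dropout_rng: np.random.Generator | None = None):
        cfg = self.config
        p = self.params
        mods = self.modalities
        caches: dict = {}
        tokens: dict[str, np.ndarray] = {}
        pooled: list[np.ndarray] = []
        for m in mods:
            xc = tokenize(features[m], cfg.n_tokens)
            tokens[m] = xc @ p[f"embed_{m}"]
            caches[f"tok_{m}"] = xc
        for m in mods:
            o, cache = _attention_forward(
                tokens[m], tokens[m], tokens[m],
                p[f"self_{m}_wq"], p[f"self_{m}_wk"], p[f"self_{m}_wv"], cfg)
            proj = o @ p[f"self_{m}_wo"]
            caches[f"self_{m}"] = (cache, o)
            pooled.append(proj.mean(axis=1))
        for a, b in _pairs(mods):
            o1, c1 = _attention_forward(
                tokens[a], tokens[b], tokens[a],
                p[f"cross_{a}|{b}_wq1"], p[f"cross_{a}|{b}_wk1"],
                p[f"cross_{a}|{b}_wv1"], cfg)
            o2, c2 = _attention_forward(
                tokens[b], tokens[a], tokens[b],
                p[f"cross_{a}|{b}_wq2"], p[f"cross_{a}|{b}_wk2"],
                p[f"cross_{a}|{b}_wv2"], cfg)
            caches[f"cross_{a}|{b}"] = (c1, c2)
            pooled.append(o1.mean(axis=1))
            pooled.append(o2.mean(axis=1))
        fused = np.concatenate(pooled, axis=1)
        mask = None
        if dropout_rng is not None and cfg.dropout_rate > 0:
            keep = 1.0 - cfg.dropout_rate
            mask = (dropout_rng.random(fused.shape) < keep) / keep
            fused = fused * mask
        logits = fused @ p["head_w"] + p["head_b"]
        caches["fused"] = fused
        caches["mask"] = mask
        caches["tokens"] = tokens
        if labels is None:
            return fused, logits, caches
        probs = _softmax(logits)
        n = len(labels)
        loss = float(-np.log(probs[np.arange(n), labels] + 1e-300).mean())
        return fused, logits, caches, probs, loss

    def fuse(self, features: dict[str, np.ndarray]) -> np.ndarray:
        """Fused vectors (evaluation mode, no dropout): per-modality pooled
        self-attention outputs, then both pooled paths of every pair, in
        canonical modality order."""
        missing = [m for m in self.modalities if m not in features]
        if missing:
            raise ValueError(f"missing modalities: {missing}")
        fused, _, _ = self._forward(features)
        return fused

    def predict_proba(self, features: dict[str, np.ndarray]) -> np.ndarray:
        _, logits, _ = self._forward(features)
        return _softmax(logits)

    def predict(self, features: dict[str, np.ndarray]) -> np.ndarray:
        return self.predict_proba(features).argmax(axis=1)

    # ------------------------------------------------------------- backward
    def _backward(self, caches, probs, labels) -> dict[str, np.ndarray]:
        p = self.params
        cfg = self.config
        mods = self.modalities
        n = len(labels)
        grads: dict[str, np.ndarray] = {}
        dlogits = probs.copy()
        dlogits[np.arange(n), labels] -= 1.0
        dlogits /= n
        fused = caches["fused"]
        grads["head_w"] = fused.T @ dlogits
        grads["head_b"] = dlogits.sum(axis=0)
        dfused = dlogits @ p["head_w"].T
        if caches["mask"] is not None:
            dfused = dfused * caches["mask"]

        d = cfg.model_dim
        dtok = {m: np.zeros_like(caches["tokens"][m]) for m in mods}
        offset = 0

        def unpool(dpool: np.ndarray, t: int) -> np.ndarray:
            return np.repeat(dpool[:, None, :], t, axis=1) / t

        for m in mods:
            cache, o = caches[f"self_{m}"]
            t = o.shape[1]
            dproj = unpool(dfused[:, offset:offset + d], t)
            offset += d
            grads[f"self_{m}_wo"] = np.einsum("nti,ntj->ij", o, dproj)
            do = dproj @ p[f"self_{m}_wo"].T
            dxq, dxk, dxv, g = _attention_backward(do, cache)
            dtok[m] += dxq + dxk + dxv
            for k_, v_ in g.items():
                grads[f"self_{m}_{k_}"] = v_
        for a, b in _pairs(mods):
            c1, c2 = caches[f"cross_{a}|{b}"]
            ta = caches["tokens"][a].shape[1]
            tb = caches["tokens"][b].shape[1]
            do1 = unpool(dfused[:, offset:offset + d], ta)
            offset += d
            do2 = unpool(dfused[:, offset:offset + d], tb)
            offset += d
            dxq1, dxk1, dxv1, g1 = _attention_backward(do1, c1)
            dtok[a] += dxq1 + dxv1
            dtok[b] += dxk1
            dxq2, dxk2, dxv2, g2 = _attention_backward(do2, c2)
            dtok[b] += dxq2 + dxv2
            dtok[a] += dxk2
            for suffix, val in (("wq1", g1["wq"]), ("wk1", g1["wk"]), ("wv1", g1["wv"]),
                                ("wq2", g2["wq"]), ("wk2", g2["wk"]), ("wv2", g2["wv"])):
                grads[f"cross_{a}|{b}_{suffix}"] = val
        for m in mods:
            grads[f"embed_{m}"] = np.einsum(
                "ntc,ntd->cd", caches[f"tok_{m}"], dtok[m])
        return grads

    # ---------------------------------------------------------------- I/O
    def save(self, path: str | Path) -> None:
        meta = dict(dataclasses.asdict(self.config))
        np.savez(
            Path(path),
            __modalities=np.array(self.modalities),
            __training_log=np.array(self.training_log),
            __feature_dims=np.array([self.feature_dims[m] for m in self.modalities]),
            **{f"cfg_{k}": np.array(v) for k, v in meta.items()},
            **self.params,
        )

    @classmethod
    def load(cls, path: str | Path) -> "FusionModel":
        data = np.load(Path(path), allow_pickle=False)
        cfg_kwargs = {}
        for k in data.files:
            if k.startswith("cfg_"):
                v = data[k].item()
                cfg_kwargs[k[4:]] = v
        cfg_kwargs["scale_mode"] = str(cfg_kwargs["scale_mode"])
        config = AttentionConfig(**cfg_kwargs)
        modalities = tuple(str(m) for m in data["__modalities"])
        dims = {m: int(d) for m, d in zip(modalities, data["__feature_dims"])}
        params = {k: data[k] for k in data.files
                  if not k.startswith(("cfg_", "__"))}
        return cls(config, modalities, dims, params,
                   training_log=list(data["__training_log"]))


# --------------------------------------------------------------------------
# initialization and training
# --------------------------------------------------------------------------

def _init_model(feature_dims: dict[str, int], config: AttentionConfig) -> FusionModel:
    mods = tuple(m for m in MODALITY_ORDER if m in feature_dims)
    if not mods:
        raise ValueError("at least one modality is required")
    rng = np.random.default_rng(config.seed)
    d = config.model_dim
    params: dict[str, np.ndarray] = {}

    def mat(n_in: int, n_out: int) -> np.ndarray:
        return rng.normal(0.0, 1.0 / np.sqrt(n_in), (n_in, n_out))

    for m in mods:
        chunk = int(np.ceil(feature_dims[m] / config.n_tokens))
        params[f"embed_{m}"] = mat(chunk, d)
        for w in ("wq", "wk", "wv", "wo"):
            params[f"self_{m}_{w}"] = mat(d, d)
    for a, b in _pairs(mods):
        for w in ("wq1", "wk1", "wv1", "wq2", "wk2", "wv2"):
            params[f"cross_{a}|{b}_{w}"] = mat(d, d)
    fused_dim = (len(mods) + 2 * len(_pairs(mods))) * d
    # zero-init head: the untrained model predicts exactly chance, and the
    # attention stack starts receiving gradient once the head moves
    params["head_w"] = np.zeros((fused_dim, 2))
    params["head_b"] = np.zeros(2)
    return FusionModel(config, mods, dict(feature_dims), params)


def encode_labels(labels) -> np.ndarray:
    """Map PD/HC (or 0/1) labels to integer classes with PD = 1."""
    arr = np.asarray(labels)
    if arr.dtype.kind in "iub":
        return arr.astype(int)
    return np.array([1 if str(v).upper() == "PD" else 0 for v in arr])


def train_fusion(
    features: dict[str, np.ndarray],
    labels,
    config: AttentionConfig | None = None,
) -> FusionModel:
    """Train attention parameters and the dense head end-to-end.

    Mini-batch Adam on the softmax cross-entropy, fully seeded by
    ``config.seed`` (initialization, shuffling and dropout all derive
    from it).  The per-epoch mean training loss is recorded in
    ``model.training_log``.  ``epochs = 0`` returns the initialized,
    untrained model.
    """
    config = config or AttentionConfig()
    y = encode_labels(labels)
    if len(np.unique(y)) < 2:
        raise DegenerateLabelsError("training labels contain a single class")
    dims = {m: int(np.atleast_2d(x).shape[1]) for m, x in features.items()}
    model = _init_model(dims, config)
    feats = {m: np.asarray(features[m], dtype=float) for m in model.modalities}

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]).generate_state(1)[0])
    mom = {k: np.zeros_like(v) for k, v in model.params.items()}
    vel = {k: np.zeros_like(v) for k, v in model.params.items()}
    step = 0
    n = len(y)
    bs = min(config.batch_size, n)
    beta1, beta2, eps = 0.9, 0.999, 1e-8

    for _ in range(config.epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for lo in range(0, n, bs):
            idx = order[lo:lo + bs]
            batch = {m: feats[m][idx] for m in model.modalities}
            drop_rng = rng if config.dropout_rate > 0 else None
            _, _, caches, probs, loss = model._forward(batch, y[idx], dropout_rng=drop_rng)
            grads = model._backward(caches, probs, y[idx])
            step += 1
            for k, g in grads.items():
                mom[k] = beta1 * mom[k] + (1 - beta1) * g
                vel[k] = beta2 * vel[k] + (1 - beta2) * g * g
                mhat = mom[k] / (1 - beta1**step)
                vhat = vel[k] / (1 - beta2**step)
                model.params[k] -= config.learning_rate * mhat / (np.sqrt(vhat) + eps)
            epoch_losses.append(loss)
        model.training_log.append(float(np.mean(epoch_losses)))
    return model
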