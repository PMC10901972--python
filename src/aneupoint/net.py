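"""Hierarchical set-abstraction point-cloud classifier.

A from-scratch NumPy implementation of the PointNet++-style classification
architecture: stacked set-abstraction (SA) levels, each of which (1) samples
centroids by farthest-point sampling, (2) groups neighbors with a ball query
at one or more radii (multi-scale grouping, MSG), and (3) encodes each group
with a shared per-point MLP followed by max-pooling (a mini-PointNet);
scale features are concatenated.  A final group-all stage pools a global
feature which a fully connected head maps to two logits; the softmax
probability of the ruptured class is the rupture risk score.

Because the centroid choice and the grouping depend only on point
coordinates — never on weights — the grouping for each cloud is planned
once (:func:`build_plan`) and reused across every epoch, so training is a
sequence of dense matrix products.  Forward and backward passes are written
out explicitly; gradients are validated against finite differences in the
test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cloud import PointCloud, ball_query, fps


@dataclass(frozen=True)
class SALevelConfig:
    """One set-abstraction level: centroids plus per-scale grouping/MLP."""

    n_centroids: int
    radii: tuple                   # one radius per scale, strictly increasing
    max_k: tuple                   # neighbors per scale
    mlp_widths: tuple              # tuple of width-tuples, one per scale

    def __post_init__(self) -> None:
        if not (len(self.radii) == len(self.max_k) == len(self.mlp_widths) >= 1):
            raise ValueError("radii, max_k and mlp_widths must have equal, "
                             "non-zero length")
        if any(b <= a for a, b in zip(self.radii, self.radii[1:])):
            raise ValueError("radii must be strictly increasing across scales")
        if self.n_centroids < 1:
            raise ValueError("n_centroids must be >= 1")

    @property
    def out_channels(self) -> int:
        return sum(w[-1] for w in self.mlp_widths)


@dataclass(frozen=True)
class NetConfig:
    """Full network: SA levels, global pooling MLP and the FC head."""

    sa_levels: tuple
    global_mlp: tuple = (128,)
    head_widths: tuple = (64,)
    n_classes: int = 2
    dropout: float = 0.4
    seed: int = 0
    absolute_first: bool = True    # concat absolute centroid xyz at level 1

    def __post_init__(self) -> None:
        if self.n_classes != 2:
            raise ValueError("binary rupture classification requires "
                             "n_classes == 2")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")


def tiny_config(seed: int = 0) -> NetConfig:
    """Small CPU-friendly configuration for normalized 512-2048 point clouds."""
    return NetConfig(
        sa_levels=(
            SALevelConfig(n_centroids=64, radii=(0.15, 0.3),
                          max_k=(8, 16), mlp_widths=((16, 16), (16, 16))),
            SALevelConfig(n_centroids=16, radii=(0.3, 0.6),
                          max_k=(8, 16), mlp_widths=((32, 32), (32, 32))),
        ),
        global_mlp=(64,),
        head_widths=(32,),
        dropout=0.4,
        seed=seed,
    )


@dataclass
class Prediction:
    """Two logits and the softmax rupture-risk score (class-1 probability)."""

    logits: np.ndarray
    risk_score: float


# ---------------------------------------------------------------------------
# grouping plan (geometry only; computed once per cloud)


@dataclass
class GroupingPlan:
    """Weight-independent geometry of one cloud through all SA levels.

    Per level: centroid indices into the previous level's point set, and per
    scale the (C, K) neighbor index array plus the (C, K, 3) relative
    coordinates of the grouped points.
    """

    levels: list                    # list of dicts
    coords: np.ndarray              # original (N, 3), normalized


def build_plan(coords: np.ndarray, config: NetConfig,
               start_index: int | None = None) -> GroupingPlan:
    coords = np.asarray(coords, dtype=np.float64)
    pts = coords
    levels = []
    for lv in config.sa_levels:
        if lv.n_centroids > len(pts):
            raise ValueError(f"n_centroids={lv.n_centroids} exceeds the "
                             f"{len(pts)} points entering the level")
        if start_index is None:
            # permutation-safe geometric start: the point farthest from the
            # level centroid (ties broken by lowest index)
            start = int(np.argmax(
                np.linalg.norm(pts - pts.mean(axis=0), axis=1)))
        else:
            start = start_index
        cidx = fps(PointCloud(pts), lv.n_centroids, start_index=start)
        centroids = pts[cidx]
        scales = []
        for radius, kk in zip(lv.radii, lv.max_k):
            gi = ball_query(pts, cidx, radius, kk, order="distance")
            rel = pts[gi.neighbor_lists] - centroids[:, None, :]
            scales.append({"idx": gi.neighbor_lists, "rel": rel})
        levels.append({"cidx": cidx, "centroids": centroids,
                       "scales": scales})
        pts = centroids
    return GroupingPlan(levels=levels, coords=coords)


# ---------------------------------------------------------------------------
# the classifier


def _he_init(rng, fan_in, fan_out):
    return rng.standard_normal((fan_in, fan_out)) * np.sqrt(2.0 / fan_in)


class PointCloudClassifier:
    """Set-abstraction classifier with explicit NumPy backprop.

    Weights live in ``self.params`` (name -> array); ``forward`` consumes a
    list of :class:`GroupingPlan` (one per sample) and returns logits.
    """

    def __init__(self, config: NetConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.params: dict[str, np.ndarray] = {}
        in_ch = 3 + (3 if config.absolute_first else 0)
        for li, lv in enumerate(config.sa_levels):
            for si, widths in enumerate(lv.mlp_widths):
                ch = in_ch
                for wi, w in enumerate(widths):
                    self.params[f"sa{li}_s{si}_W{wi}"] = _he_init(rng, ch, w)
                    self.params[f"sa{li}_s{si}_b{wi}"] = np.zeros(w)
                    ch = w
            in_ch = lv.out_channels + 3     # +3 relative coords next level
        ch = config.sa_levels[-1].out_channels + 3
        for wi, w in enumerate(config.global_mlp):
            self.params[f"glob_W{wi}"] = _he_init(rng, ch, w)
            self.params[f"glob_b{wi}"] = np.zeros(w)
            ch = w
        for wi, w in enumerate(config.head_widths):
            self.params[f"head_W{wi}"] = _he_init(rng, ch, w)
            self.params[f"head_b{wi}"] = np.zeros(w)
            ch = w
        self.params["out_W"] = _he_init(rng, ch, config.n_classes)
        self.params["out_b"] = np.zeros(config.n_classes)

    # -- helpers ----------------------------------------------------------

    def _mlp_forward(self, x, prefix, n_layers, cache):
        for wi in range(n_layers):
            W, b = self.params[f"{prefix}_W{wi}"], self.params[f"{prefix}_b{wi}"]
            z = x @ W + b
            a = np.maximum(z, 0.0)
            cache.append((prefix, wi, x, z))
            x = a
        return x

    def _mlp_backward(self, grad, cache, grads):
        for prefix, wi, x, z in reversed(cache):
            grad = grad * (z > 0.0)
            W = self.params[f"{prefix}_W{wi}"]
            gw = x.reshape(-1, x.shape[-1]).T @ grad.reshape(-1, grad.shape[-1])
            grads[f"{prefix}_W{wi}"] = grads.get(f"{prefix}_W{wi}", 0) + gw
            gb = grad.reshape(-1, grad.shape[-1]).sum(axis=0)
            grads[f"{prefix}_b{wi}"] = grads.get(f"{prefix}_b{wi}", 0) + gb
            grad = grad @ W.T
        return grad

    # -- forward ----------------------------------------------------------

    def forward(self, plans, train: bool = False, rng=None):
        """Logits (B, 2) for a batch of grouping plans.

        In training mode, dropout is applied in the FC head using ``rng``.
        """
        cfg = self.config
        B = len(plans)
        caches = {"sa": [], "drop": []}
        feats = None                       # (B, N, F) or None at level 0
        for li, lv in enumerate(cfg.sa_levels):
            C = lv.n_centroids
            out_scales = []
            sa_cache = []
            for si, (radius, kk, widths) in enumerate(
                    zip(lv.radii, lv.max_k, lv.mlp_widths)):
                rel = np.stack([p.levels[li]["scales"][si]["rel"]
                                for p in plans])          # (B, C, K, 3)
                parts = [rel]
                if li == 0 and cfg.absolute_first:
                    cen = np.stack([p.levels[0]["centroids"] for p in plans])
                    parts.append(np.broadcast_to(cen[:, :, None, :],
                                                 rel.shape).copy())
                idx = None
                if feats is not None:
                    idx = np.stack([p.levels[li]["scales"][si]["idx"]
                                    for p in plans])      # (B, C, K)
                    gathered = np.take_along_axis(
                        feats[:, :, None, :],
                        idx[:, :, :, None].repeat(feats.shape[-1], axis=3),
                        axis=1)
                    parts.append(gathered)
                x = np.concatenate(parts, axis=-1)        # (B, C, K, ch)
                mlp_cache = []
                h = self._mlp_forward(x, f"sa{li}_s{si}", len(widths),
                                      mlp_cache)
                amax = np.argmax(h, axis=2)               # (B, C, ch)
                pooled = np.take_along_axis(h, amax[:, :, None, :],
                                            axis=2)[:, :, 0, :]
                out_scales.append(pooled)
                sa_cache.append({"mlp": mlp_cache, "amax": amax,
                                 "idx": idx, "h_shape": h.shape,
                                 "in_feat_dim": (feats.shape[-1]
                                                 if feats is not None else 0)})
            caches["sa"].append({"scales": sa_cache,
                                 "n_prev": (feats.shape[1]
                                            if feats is not None
                                            else len(plans[0].coords))})
            feats = np.concatenate(out_scales, axis=-1)   # (B, C, F)

        # group-all stage: concat centroid coords of the last level
        last_pts = np.stack([p.levels[-1]["centroids"] for p in plans])
        x = np.concatenate([last_pts, feats], axis=-1)    # (B, C, 3+F)
        glob_cache = []
        h = self._mlp_forward(x, "glob", len(cfg.global_mlp), glob_cache)
        gmax = np.argmax(h, axis=1)                       # (B, ch)
        g = np.take_along_axis(h, gmax[:, None, :], axis=1)[:, 0, :]
        caches["glob"] = (glob_cache, gmax, h.shape)

        head_cache = []
        y = g
        for wi in range(len(cfg.head_widths)):
            W, b = self.params[f"head_W{wi}"], self.params[f"head_b{wi}"]
            z = y @ W + b
            a = np.maximum(z, 0.0)
            head_cache.append((y, z))
            if train and cfg.dropout > 0:
                if rng is None:
                    raise ValueError("training-mode forward needs an rng "
                                     "for dropout")
                mask = (rng.random(a.shape) >= cfg.dropout) / (1 - cfg.dropout)
                caches["drop"].append(mask)
                a = a * mask
            else:
                caches["drop"].append(None)
            y = a
        caches["head"] = head_cache
        caches["pre_out"] = y
        logits = y @ self.params["out_W"] + self.params["out_b"]
        caches["feats_n_last"] = feats.shape
        self._cache = caches
        return logits

    # -- backward ---------------------------------------------------------

    def backward(self, plans, dlogits):
        """Parameter gradients for the last forward pass."""
        cfg = self.config
        caches = self._cache
        grads: dict[str, np.ndarray] = {}

        y = caches["pre_out"]
        grads["out_W"] = y.T @ dlogits
        grads["out_b"] = dlogits.sum(axis=0)
        grad = dlogits @ self.params["out_W"].T
        for wi in reversed(range(len(cfg.head_widths))):
            mask = caches["drop"][wi]
            if mask is not None:
                grad = grad * mask
            x, z = caches["head"][wi]
            grad = grad * (z > 0.0)
            grads[f"head_W{wi}"] = x.T @ grad
            grads[f"head_b{wi}"] = grad.sum(axis=0)
            grad = grad @ self.params[f"head_W{wi}"].T

        glob_cache, gmax, h_shape = caches["glob"]
        dh = np.zeros(h_shape)
        np.put_along_axis(dh, gmax[:, None, :], grad[:, None, :], axis=1)
        dx = self._mlp_backward(dh, glob_cache, grads)
        dfeats = dx[:, :, 3:]                   # coords carry no gradient

        for li in reversed(range(len(cfg.sa_levels))):
            lv = cfg.sa_levels[li]
            sa = caches["sa"][li]
            n_prev = sa["n_prev"]
            dprev = None
            offset = 0
            for si, widths in enumerate(lv.mlp_widths):
                ch = lv.mlp_widths[si][-1]
                dpool = dfeats[:, :, offset:offset + ch]
                offset += ch
                sc = sa["scales"][si]
                dh = np.zeros(sc["h_shape"])
                np.put_along_axis(dh, sc["amax"][:, :, None, :],
                                  dpool[:, :, None, :], axis=2)
                dxs = self._mlp_backward(dh, sc["mlp"], grads)
                fdim = sc["in_feat_dim"]
                if fdim:
                    dgath = dxs[..., -fdim:]    # (B, C, K, F_in)
                    if dprev is None:
                        dprev = np.zeros((dgath.shape[0], n_prev, fdim))
                    B, C, K, F = dgath.shape
                    idx = sc["idx"]
                    flat = (np.arange(B)[:, None, None] * n_prev + idx).ravel()
                    np.add.at(dprev.reshape(-1, F), flat,
                              dgath.reshape(-1, F))
            dfeats = dprev                       # None below level 1
            if dfeats is None:
                break
        return grads


# ---------------------------------------------------------------------------
# operations used directly by the training loop


def set_abstraction(points: np.ndarray, features, level: SALevelConfig,
                    weights: dict | None = None, seed: int = 0):
    """Single SA level on one cloud: (sub_points, sub_features).

    Convenience wrapper used for inspection and testing; training uses the
    batched classifier.  ``weights`` maps ``s{si}_W{wi}/b{wi}`` to arrays;
    when omitted, random weights seeded by ``seed`` are drawn with the same
    initializer as the classifier.
    """
    points = np.asarray(points, dtype=np.float64)
    if level.n_centroids > len(points):
        raise ValueError("n_centroids exceeds the number of points")
    rng = np.random.default_rng(seed)
    start = int(np.argmax(np.linalg.norm(points - points.mean(axis=0),
                                         axis=1)))
    cidx = fps(PointCloud(points), level.n_centroids, start_index=start)
    centroids = points[cidx]
    outs = []
    for si, (radius, kk, widths) in enumerate(
            zip(level.radii, level.max_k, level.mlp_widths)):
        gi = ball_query(points, cidx, radius, kk, order="distance")
        rel = points[gi.neighbor_lists] - centroids[:, None, :]
        parts = [rel]
        if features is not None:
            parts.append(np.asarray(features)[gi.neighbor_lists])
        x = np.concatenate(parts, axis=-1)
        ch = x.shape[-1]
        for wi, w in enumerate(widths):
            if weights is not None:
                W = weights[f"s{si}_W{wi}"]
                b = weights.get(f"s{si}_b{wi}", np.zeros(W.shape[1]))
            else:
                W = _he_init(rng, ch, w)
                b = np.zeros(w)
            x = np.maximum(x @ W + b, 0.0)
            ch = w
        outs.append(x.max(axis=1))
    return centroids, np.concatenate(outs, axis=-1)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def loss(logits: np.ndarray, labels) -> float:
    """Mean two-class softmax cross-entropy, -log p(true class)."""
    logits = np.atleast_2d(np.asarray(logits, dtype=np.float64))
    if not np.all(np.isfinite(logits)):
        raise ValueError("non-finite logits")
    labels = np.atleast_1d(np.asarray(labels, dtype=np.intp))
    p = softmax(logits)
    return float(-np.mean(np.log(p[np.arange(len(labels)), labels] + 1e-300)))


def loss_grad(logits: np.ndarray, labels) -> np.ndarray:
    """d(mean cross-entropy)/d(logits) = (softmax - onehot) / B."""
    logits = np.atleast_2d(np.asarray(logits, dtype=np.float64))
    labels = np.atleast_1d(np.asarray(labels, dtype=np.intp))
    g = softmax(logits)
    g[np.arange(len(labels)), labels] -= 1.0
    return g / len(labels)


def forward(cloud: PointCloud, config: NetConfig,
            classifier: PointCloudClassifier | None = None) -> Prediction:
    """Score one normalized cloud: logits plus softmax risk score."""
    clf = classifier if classifier is not None else PointCloudClassifier(config)
    plan = build_plan(cloud.coords, config)
    logits = clf.forward([plan])[0]
    return Prediction(logits=logits, risk_score=float(softmax(logits)[1]))


class Adam:
    """Adam with decoupled-free (classic L2) weight decay."""

    def __init__(self, params, lr=2e-5, weight_decay=1e-4,
                 beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr = lr
        self.wd = weight_decay
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params, grads, lr=None):
        self.t += 1
        lr = self.lr if lr is None else lr
        for k, p in params.items():
            g = grads.get(k)
            if g is None:
                continue
            g = g + self.wd * p
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            p -= lr * mhat / (np.sqrt(vhat) + self.eps)


def config_to_yaml(config: NetConfig, path) -> None:
    """Write a network configuration as a plain key-value YAML file."""
    import dataclasses

    import yaml

    d = dataclasses.asdict(config)
    d["sa_levels"] = [dataclasses.asdict(lv) for lv in config.sa_levels]
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


def config_from_yaml(path) -> NetConfig:
    import yaml

    with open(path) as fh:
        d = yaml.safe_load(fh)

    def tup(x):
        return tuple(tuple(i) if isinstance(i, list) else i for i in x)

    levels = tuple(SALevelConfig(
        n_centroids=lv["n_centroids"], radii=tuple(lv["radii"]),
        max_k=tuple(lv["max_k"]), mlp_widths=tup(lv["mlp_widths"]))
        for lv in d["sa_levels"])
    return NetConfig(sa_levels=levels, global_mlp=tuple(d["global_mlp"]),
                     head_widths=tuple(d["head_widths"]),
                     n_classes=d["n_classes"], dropout=d["dropout"],
                     seed=d["seed"], absolute_first=d["absolute_first"])


def save_checkpoint(path, classifier: PointCloudClassifier) -> None:
    """Single-file npz archive with a config hash for integrity."""
    import hashlib
    import json

    cfg = repr(classifier.config)
    h = hashlib.sha256(cfg.encode()).hexdigest()[:16]
    np.savez(path, __config_hash__=np.array(h),
             __config_repr__=np.array(cfg), **classifier.params)


def load_checkpoint(path, config: NetConfig) -> PointCloudClassifier:
    import hashlib

    data = np.load(path, allow_pickle=False)
    h = hashlib.sha256(repr(config).encode()).hexdigest()[:16]
    if str(data["__config_hash__"]) != h:
        raise ValueError("checkpoint was written for a different network "
                         "configuration")
    clf = PointCloudClassifier(config)
    for k in clf.params:
        clf.params[k] = data[k]
    return clf
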