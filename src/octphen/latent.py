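"""Latent phenotyping: autoencoder embeddings of thickness maps.

A conventional convolutional autoencoder (conv/pool encoder, dense bottleneck,
mirrored decoder, sigmoid output, MSE loss) compresses each subject's
thickness map to a k-dimensional embedding vector.  The module also provides
the bottleneck-size comparison, PCA of the embedding matrix, and rank-based
inverse-normal transformation of traits prior to association testing.

Maps are resampled to a square working resolution by area (block) averaging
and scaled to [0, 1] with a scale factor fitted on the training split only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from . import nn
from .thickness import ThicknessMap

__all__ = [
    "AutoencoderConfig",
    "EmbeddingMatrix",
    "Autoencoder",
    "resample_map",
    "train_autoencoder",
    "embed",
    "reconstruct",
    "embedding_pca",
    "inverse_rank_normalize",
    "normalize_traits",
]


@dataclass
class AutoencoderConfig:
    """Training configuration; defaults follow the study design (bottleneck 64,
    150 epochs, 2500/500 train/test split) at a desk-scale input resolution."""

    bottleneck: int = 64
    epochs: int = 150
    n_train: int = 2500
    n_test: int = 500
    input_shape: tuple[int, int] = (64, 64)
    n_down: int = 3  # conv/pool stages; input dims must divide by 2**n_down
    base_channels: int = 8
    lr: float = 1e-3
    batch_size: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.input_shape
        flat = h * w
        if self.bottleneck >= flat:
            raise ValueError("bottleneck must be smaller than the flattened input")
        if h % 2**self.n_down or w % 2**self.n_down:
            raise ValueError("input dims must be divisible by 2**n_down")


@dataclass
class EmbeddingMatrix:
    """Subjects x k latent features with training provenance."""

    values: np.ndarray  # (n_subjects, k)
    feature_ids: list[str]
    config: AutoencoderConfig
    reconstruction_mse_train: float
    reconstruction_mse_test: float
    subject_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values)):
            raise ValueError("embeddings must be finite")
        if self.values.shape[1] != self.config.bottleneck:
            raise ValueError("embedding width must equal the configured bottleneck")


def resample_map(m: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Area-average a map down to ``shape`` (exact block mean when divisible,
    linear interpolation of the block grid otherwise)."""
    h0, w0 = m.shape
    h1, w1 = shape
    if h0 % h1 == 0 and w0 % w1 == 0:
        return m.reshape(h1, h0 // h1, w1, w0 // w1).mean(axis=(1, 3))
    from scipy import ndimage

    return ndimage.zoom(m, (h1 / h0, w1 / w0), order=1, grid_mode=True, mode="nearest")


class Autoencoder:
    """Conv encoder -> dense bottleneck -> mirrored decoder, sigmoid output."""

    def __init__(self, config: AutoencoderConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        h, w = config.input_shape
        cb = config.base_channels
        self.enc_layers: list[nn.Layer] = []
        c_in = 1
        for d in range(config.n_down):
            c_out = cb * 2**d
            self.enc_layers += [nn.Conv2d(c_in, c_out, 3, rng), nn.ReLU(), nn.MaxPool2()]
            c_in = c_out
        hh, ww = h // 2**config.n_down, w // 2**config.n_down
        flat = c_in * hh * ww
        self.enc_layers += [nn.Flatten(), nn.Dense(flat, config.bottleneck, rng)]
        self.dec_layers: list[nn.Layer] = [
            nn.Dense(config.bottleneck, flat, rng),
            nn.ReLU(),
            nn.Reshape((c_in, hh, ww)),
        ]
        for d in reversed(range(config.n_down)):
            c_out = cb * 2 ** max(d - 1, 0)
            self.dec_layers += [nn.Upsample2(), nn.Conv2d(c_in, c_out, 3, rng), nn.ReLU()]
            c_in = c_out
        self.dec_layers += [nn.Conv2d(c_in, 1, 3, rng), nn.Sigmoid()]
        self.scale: float = 1.0  # map -> [0, 1] divisor, fitted on training split
        self.loss_history: list[float] = []
        self.test_loss_history: list[float] = []

    # forward/backward over (N, H, W) arrays already on the [0, 1] scale ----- #

    def _encode_arr(self, x01: np.ndarray) -> np.ndarray:
        h = x01[:, None, :, :].astype(np.float64)
        for lay in self.enc_layers:
            h = lay.forward(h)
        return h

    def _decode_arr(self, z: np.ndarray) -> np.ndarray:
        h = z
        for lay in self.dec_layers:
            h = lay.forward(h)
        return h[:, 0]

    def _backward(self, dout: np.ndarray) -> None:
        d = dout[:, None]
        for lay in reversed(self.dec_layers):
            d = lay.backward(d)
        for lay in reversed(self.enc_layers):
            d = lay.backward(d)

    def _layers(self):
        return self.enc_layers + self.dec_layers

    def prepare(self, maps: np.ndarray) -> np.ndarray:
        """Resample to the working resolution and scale to [0, 1]."""
        out = np.stack([resample_map(np.asarray(m, float), self.config.input_shape) for m in maps])
        return np.clip(out / self.scale, 0.0, 1.0)

    def encode(self, map_: np.ndarray) -> np.ndarray:
        """Latent vector for one thickness map (deterministic at inference)."""
        x = self.prepare(np.asarray(map_, float)[None])
        return self._encode_arr(x)[0]

    def reconstruct(self, map_: np.ndarray) -> tuple[np.ndarray, float]:
        """Reconstruction (on the [0, 1] scale) and its MSE against the input."""
        x = self.prepare(np.asarray(map_, float)[None])
        rec = self._decode_arr(self._encode_arr(x))
        return rec[0], float(np.mean((rec - x) ** 2))

    def mse(self, maps: np.ndarray) -> float:
        x = self.prepare(maps)
        rec = self._decode_arr(self._encode_arr(x))
        return float(np.mean((rec - x) ** 2))


def _as_array(maps) -> np.ndarray:
    arrs = [m.map if isinstance(m, ThicknessMap) else np.asarray(m, float) for m in maps]
    return np.stack(arrs)


def train_autoencoder(
    maps,
    config: AutoencoderConfig,
) -> tuple[Autoencoder, EmbeddingMatrix]:
    """Train on a seeded subject-level train/test split; embed every subject.

    ``maps``: sequence of :class:`~octphen.thickness.ThicknessMap` or 2-D
    arrays, one per subject (cohort order).  Embeddings are extracted with the
    final-epoch weights for all subjects, not only the training images.
    """
    arr = _as_array(maps)
    n = arr.shape[0]
    if config.n_train + config.n_test > n:
        raise ValueError("n_train + n_test exceeds the cohort size")
    rng = np.random.default_rng(config.seed)
    perm = rng.permutation(n)
    train_idx = perm[: config.n_train]
    test_idx = perm[config.n_train : config.n_train + config.n_test]

    model = Autoencoder(config)
    model.scale = float(arr[train_idx].max()) * 1.05 + 1e-12
    x_train = model.prepare(arr[train_idx])
    x_test = model.prepare(arr[test_idx])

    opt = nn.Adam(model._layers(), lr=config.lr)
    bs = config.batch_size
    for _ in range(config.epochs):
        order = rng.permutation(x_train.shape[0])
        total = 0.0
        for i in range(0, order.size, bs):
            idx = order[i : i + bs]
            xb = x_train[idx]
            rec = model._decode_arr(model._encode_arr(xb))
            loss, drec = nn.mse_loss(rec, xb)
            if not np.isfinite(loss):
                raise FloatingPointError("non-finite autoencoder loss")
            model._backward(drec)
            opt.step()
            total += loss * idx.size
        model.loss_history.append(total / order.size)
        rec_t = model._decode_arr(model._encode_arr(x_test))
        model.test_loss_history.append(float(np.mean((rec_t - x_test) ** 2)))

    mse_train = model.mse(arr[train_idx])
    mse_test = model.mse(arr[test_idx])
    values = np.concatenate(
        [model._encode_arr(model.prepare(arr[i : i + 256])) for i in range(0, n, 256)]
    )
    emb = EmbeddingMatrix(
        values=values,
        feature_ids=[f"e{i + 1}" for i in range(config.bottleneck)],
        config=config,
        reconstruction_mse_train=mse_train,
        reconstruction_mse_test=mse_test,
        subject_ids=[
            m.subject_id if isinstance(m, ThicknessMap) else str(i) for i, m in enumerate(maps)
        ],
    )
    return model, emb


def embed(model: Autoencoder, map_: np.ndarray | ThicknessMap) -> np.ndarray:
    """Latent vector of one map (length = bottleneck)."""
    m = map_.map if isinstance(map_, ThicknessMap) else map_
    return model.encode(m)


def reconstruct(model: Autoencoder, map_: np.ndarray | ThicknessMap) -> tuple[np.ndarray, float]:
    m = map_.map if isinstance(map_, ThicknessMap) else map_
    return model.reconstruct(m)


def embedding_pca(
    emb: EmbeddingMatrix | np.ndarray, n_components: int = 25
) -> tuple[np.ndarray, np.ndarray]:
    """PCA of the embedding matrix.

    Returns (scores: subjects x n_components, explained-variance fractions).
    Components are orthogonal; fractions are non-increasing.  Rank-deficient
    input is handled by truncating to the available rank (trailing fractions
    are 0 and the corresponding scores are zero columns).
    """
    from sklearn.decomposition import PCA

    x = emb.values if isinstance(emb, EmbeddingMatrix) else np.asarray(emb, float)
    if n_components > x.shape[1]:
        raise ValueError("n_components exceeds the embedding dimension")
    k = min(n_components, min(x.shape) - (1 if x.shape[0] <= x.shape[1] else 0))
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(x)
    frac = pca.explained_variance_ratio_
    if k < n_components:  # pad truncated rank with zeros
        scores = np.pad(scores, ((0, 0), (0, n_components - k)))
        frac = np.pad(frac, (0, n_components - k))
    return scores, frac


def inverse_rank_normalize(values: np.ndarray, offset: float = 3.0 / 8.0) -> np.ndarray:
    """Rank-based inverse-normal transform with the Blom offset.

    value -> Phi^{-1}((rank - 3/8) / (n + 1/4)); ties get average ranks;
    missing values stay missing.  Raises on all-constant input (ranks
    undefined) or fewer than 3 non-missing values.
    """
    x = np.asarray(values, float)
    out = np.full(x.shape, np.nan)
    ok = np.isfinite(x)
    n = int(ok.sum())
    if n < 3:
        raise ValueError("need at least 3 non-missing values")
    xv = x[ok]
    if np.all(xv == xv[0]):
        raise ValueError("all-constant column: ranks undefined")
    ranks = stats.rankdata(xv, method="average")
    out[ok] = stats.norm.ppf((ranks - offset) / (n - 2.0 * offset + 1.0))
    return out


def normalize_traits(values: np.ndarray) -> np.ndarray:
    """Column-wise inverse-rank normalization of a subjects x traits matrix."""
    x = np.asarray(values, float)
    return np.column_stack([inverse_rank_normalize(x[:, j]) for j in range(x.shape[1])])
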