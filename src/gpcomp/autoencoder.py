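"""Per-chunk symmetric autoencoders and the concatenated compressed matrix.

Architecture: input -> encoder hidden layers (ReLU) -> bottleneck
(sigmoid) -> mirrored decoder layers (all sigmoid) -> output at the
input dimension.  Training minimizes element-wise reconstruction MSE
with Adam on 60/20/20 row splits; everything is seeded and the per-chunk
seed derives from (global seed, chunk index) so results do not depend on
training order.

Implemented directly in NumPy: the stacks are small (a few thousand
weights per chunk) and a framework dependency would not survive an
offline install.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from gpcomp.encoding import ChunkSet, OneHotChunk
from gpcomp.errors import ConfigurationError, ConsistencyError, NumericalError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AutoencoderSpec:
    """Hyperparameters for one per-chunk autoencoder.

    ``encoder_layer_sizes`` lists the encoder widths; the last entry is
    the bottleneck.  The decoder mirrors these sizes in reverse, ending
    at the input dimension.
    """

    encoder_layer_sizes: tuple[int, ...] = (20, 16, 12, 5)
    batch_size: int = 32
    epochs: int = 200
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.encoder_layer_sizes:
            raise ConfigurationError("encoder_layer_sizes must be non-empty")
        if any(int(s) < 1 for s in self.encoder_layer_sizes):
            raise ConfigurationError("layer sizes must be positive")
        object.__setattr__(
            self, "encoder_layer_sizes", tuple(int(s) for s in self.encoder_layer_sizes)
        )
        if self.batch_size < 1 or self.epochs < 1 or self.learning_rate <= 0:
            raise ConfigurationError("batch_size, epochs >= 1; learning_rate > 0")

    @property
    def bottleneck(self) -> int:
        return self.encoder_layer_sizes[-1]

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


class AutoencoderModel:
    """Weights and forward pass for one symmetric autoencoder."""

    def __init__(self, input_dim: int, spec: AutoencoderSpec, rng: np.random.Generator):
        if spec.bottleneck > input_dim:
            raise ConfigurationError(
                f"bottleneck {spec.bottleneck} exceeds input dimension {input_dim}"
            )
        self.input_dim = input_dim
        self.spec = spec
        enc = list(spec.encoder_layer_sizes)
        widths = [input_dim] + enc + enc[-2::-1] + [input_dim]
        self.widths = widths
        self.n_encoder_layers = len(enc)
        # activations per layer: ReLU for encoder hiddens, sigmoid for the
        # bottleneck and every decoder layer (output included)
        self.activations = ["relu"] * (len(enc) - 1) + ["sigmoid"] * (
            len(widths) - len(enc)
        )
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for fan_in, fan_out in zip(widths[:-1], widths[1:]):
            limit = np.sqrt(6.0 / (fan_in + fan_out))  # Glorot uniform
            self.weights.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
            self.biases.append(np.zeros(fan_out))

    @staticmethod
    def _act(z: np.ndarray, kind: str) -> np.ndarray:
        if kind == "relu":
            return np.maximum(z, 0.0)
        return 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))

    def forward(self, x: np.ndarray) -> list[np.ndarray]:
        """Activations for every layer (input first, output last)."""
        acts = [np.asarray(x, dtype=float)]
        for w, b, kind in zip(self.weights, self.biases, self.activations):
            acts.append(self._act(acts[-1] @ w + b, kind))
        return acts

    def reconstruct(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)[-1]

    def encode(self, x: np.ndarray) -> np.ndarray:
        """Bottleneck activations (sigmoid, so values in (0, 1))."""
        acts = np.asarray(x, dtype=float)
        for layer in range(self.n_encoder_layers):
            acts = self._act(
                acts @ self.weights[layer] + self.biases[layer],
                self.activations[layer],
            )
        return acts


@dataclass
class TrainedChunkModel:
    chunk_index: int
    model: AutoencoderModel
    train_mse: float
    val_mse: float
    test_mse: float

    def __post_init__(self) -> None:
        for v in (self.train_mse, self.val_mse, self.test_mse):
            if not np.isfinite(v) or v < 0:
                raise NumericalError(f"invalid reported MSE {v}")

    @property
    def input_dim(self) -> int:
        return self.model.input_dim


@dataclass
class CompressedMatrix:
    """Concatenated bottleneck activations, one row per individual."""

    values: np.ndarray  # n x d, entries in (0, 1)
    individual_ids: list[str]
    spec: AutoencoderSpec
    n_chunks: int
    chunk_mses: list[float] = field(default_factory=list)

    @property
    def d(self) -> int:
        return self.values.shape[1]


def build_model(input_dim: int, spec: AutoencoderSpec) -> AutoencoderModel:
    """Untrained symmetric autoencoder with seeded Glorot initialization."""
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    return AutoencoderModel(input_dim, spec, rng)


def reconstruction_mse(x: np.ndarray, x_prime: np.ndarray) -> float:
    """Mean squared element-wise difference (mean over all entries)."""
    x = np.asarray(x, dtype=float)
    x_prime = np.asarray(x_prime, dtype=float)
    if x.shape != x_prime.shape:
        raise ConsistencyError(f"shape mismatch {x.shape} vs {x_prime.shape}")
    return float(np.mean((x - x_prime) ** 2))


def compression_ratio(p: int, d: int) -> float:
    """Percent reduction (1 - d/p) * 100, rounded to two decimals."""
    if p <= 0 or d <= 0:
        raise ConfigurationError("dimensions must be positive")
    if d > p:
        raise ConfigurationError(f"compressed dimension {d} exceeds original {p}")
    return round((1.0 - d / p) * 100.0, 2)


def split_indices(
    n: int, seed: int, fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Seeded 60/20/20 row split; the same indices are reused across chunks."""
    if n < 5:
        raise ConfigurationError("need at least 5 individuals for a 60/20/20 split")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xA11]))
    perm = rng.permutation(n)
    n_train = max(1, int(round(fractions[0] * n)))
    n_test = max(1, int(round(fractions[1] * n)))
    if n_train + n_test >= n:
        n_train = n - 2
        n_test = 1
    return perm[:n_train], perm[n_train : n_train + n_test], perm[n_train + n_test :]


def _adam_train(
    model: AutoencoderModel,
    x_train: np.ndarray,
    spec: AutoencoderSpec,
    rng: np.random.Generator,
) -> None:
    """In-place Adam minimization of reconstruction MSE."""
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    m_w = [np.zeros_like(w) for w in model.weights]
    v_w = [np.zeros_like(w) for w in model.weights]
    m_b = [np.zeros_like(b) for b in model.biases]
    v_b = [np.zeros_like(b) for b in model.biases]
    step = 0
    n = x_train.shape[0]
    for _ in range(spec.epochs):
        order = rng.permutation(n)
        for start in range(0, n, spec.batch_size):
            batch = x_train[order[start : start + spec.batch_size]]
            acts = model.forward(batch)
            out = acts[-1]
            # dL/d(out) for L = mean over all elements of (out - x)^2
            delta = 2.0 * (out - batch) / batch.size
            grads_w, grads_b = [], []
            for layer in range(len(model.weights) - 1, -1, -1):
                a_out = acts[layer + 1]
                if model.activations[layer] == "relu":
                    dz = delta * (a_out > 0)
                else:
                    dz = delta * a_out * (1.0 - a_out)
                grads_w.append(acts[layer].T @ dz)
                grads_b.append(dz.sum(axis=0))
                if layer > 0:
                    delta = dz @ model.weights[layer].T
            grads_w.reverse()
            grads_b.reverse()
            step += 1
            lr_t = spec.learning_rate * np.sqrt(1 - beta2**step) / (1 - beta1**step)
            for layer, (gw, gb) in enumerate(zip(grads_w, grads_b)):
                if not (np.isfinite(gw).all() and np.isfinite(gb).all()):
                    raise NumericalError(
                        f"non-finite gradient at step {step}, layer {layer}"
                    )
                m_w[layer] = beta1 * m_w[layer] + (1 - beta1) * gw
                v_w[layer] = beta2 * v_w[layer] + (1 - beta2) * gw**2
                m_b[layer] = beta1 * m_b[layer] + (1 - beta1) * gb
                v_b[layer] = beta2 * v_b[layer] + (1 - beta2) * gb**2
                model.weights[layer] -= lr_t * m_w[layer] / (np.sqrt(v_w[layer]) + eps)
                model.biases[layer] -= lr_t * m_b[layer] / (np.sqrt(v_b[layer]) + eps)


def train_chunk(
    chunk: OneHotChunk, spec: AutoencoderSpec, chunk_seed: int | None = None
) -> TrainedChunkModel:
    """Train one chunk's autoencoder on a seeded 60/20/20 row split."""
    x = np.asarray(chunk.data, dtype=float)
    n = x.shape[0]
    seed = spec.seed if chunk_seed is None else chunk_seed
    rng = np.random.default_rng(np.random.SeedSequence([seed, chunk.chunk_index]))
    model = AutoencoderModel(x.shape[1], spec, rng)
    idx_train, idx_test, idx_val = split_indices(n, spec.seed)
    _adam_train(model, x[idx_train], spec, rng)
    train_mse = reconstruction_mse(x[idx_train], model.reconstruct(x[idx_train]))
    test_mse = reconstruction_mse(x[idx_test], model.reconstruct(x[idx_test]))
    val_mse = reconstruction_mse(x[idx_val], model.reconstruct(x[idx_val]))
    if not np.isfinite(train_mse):
        raise NumericalError(f"training diverged on chunk {chunk.chunk_index}")
    return TrainedChunkModel(chunk.chunk_index, model, train_mse, val_mse, test_mse)


def compress_chunk(model: TrainedChunkModel, chunk: OneHotChunk) -> np.ndarray:
    """Bottleneck activations for all individuals of one chunk."""
    x = np.asarray(chunk.data, dtype=float)
    if x.shape[1] != model.input_dim:
        raise ConsistencyError(
            f"chunk width {x.shape[1]} does not match model input {model.input_dim}"
        )
    return model.model.encode(x)


def compress_all(
    cs: ChunkSet,
    spec: AutoencoderSpec,
    individual_ids: list[str] | None = None,
) -> CompressedMatrix:
    """Train every chunk independently and concatenate bottleneck blocks.

    Per-chunk seeds derive from (spec.seed, chunk index), so the result
    is independent of the order chunks are trained in.
    """
    n_rows = {c.data.shape[0] for c in cs.chunks}
    if len(n_rows) != 1:
        raise ConsistencyError("chunks disagree on individual count")
    blocks: list[np.ndarray] = []
    mses: list[float] = []
    for chunk in cs.chunks:
        try:
            trained = train_chunk(chunk, spec)
        except Exception as exc:
            raise NumericalError(
                f"compression failed on chunk {chunk.chunk_index}: {exc}"
            ) from exc
        blocks.append(compress_chunk(trained, chunk))
        mses.append(trained.val_mse)
    values = np.concatenate(blocks, axis=1)
    if individual_ids is None:
        individual_ids = [f"ind{i}" for i in range(values.shape[0])]
    assert values.shape[1] == spec.bottleneck * cs.n_chunks
    return CompressedMatrix(values, individual_ids, spec, cs.n_chunks, mses)


def random_search(
    cs: ChunkSet,
    search_space: Mapping[str, Sequence],
    n_trials: int,
    seed: int = 0,
    max_chunks: int = 3,
) -> tuple[AutoencoderSpec, list[dict]]:
    """Seeded random sampling of hyperparameters, scored by validation MSE.

    ``search_space`` maps AutoencoderSpec field names to candidate
    values; unlisted fields keep their defaults.  Candidates are scored
    on the mean validation reconstruction MSE over at most ``max_chunks``
    chunks.  Returns the best spec and the full trial log.
    """
    if n_trials < 1:
        raise ConfigurationError("n_trials must be >= 1")
    if not search_space or any(len(v) == 0 for v in search_space.values()):
        raise ConfigurationError("search space is empty")
    valid_fields = {f.name for f in dataclasses.fields(AutoencoderSpec)}
    unknown = set(search_space) - valid_fields
    if unknown:
        raise ConfigurationError(f"unknown hyperparameters: {sorted(unknown)}")

    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5EA7C4]))
    subset = cs.chunks[:max_chunks]
    trials: list[dict] = []
    best: tuple[float, AutoencoderSpec] | None = None
    for trial in range(n_trials):
        kwargs = {
            key: values[rng.integers(len(values))]
            for key, values in search_space.items()
        }
        kwargs.setdefault("seed", seed)
        candidate = AutoencoderSpec(**kwargs)
        try:
            score = float(
                np.mean([train_chunk(c, candidate).val_mse for c in subset])
            )
        except (ConfigurationError, NumericalError) as exc:
            logger.warning("trial %d failed: %s", trial, exc)
            trials.append({"trial": trial, "spec": candidate.to_dict(), "error": str(exc)})
            continue
        trials.append({"trial": trial, "spec": candidate.to_dict(), "val_mse": score})
        if best is None or score < best[0]:
            best = (score, candidate)
    if best is None:
        raise NumericalError("every random-search trial failed")
    return best[1], trials


# ---------------------------------------------------------------------------
# persistence


def write_compressed(cm: CompressedMatrix, path: str | Path, sep: str = "\t") -> None:
    import pandas as pd

    df = pd.DataFrame(
        cm.values, index=cm.individual_ids,
        columns=[f"f{j}" for j in range(cm.d)],
    )
    df.to_csv(path, sep=sep, index_label="id", float_format="%.10g")
    meta = {
        "spec": cm.spec.to_dict(),
        "n_chunks": cm.n_chunks,
        "d": cm.d,
        "chunk_val_mses": cm.chunk_mses,
    }
    Path(str(path) + ".json").write_text(json.dumps(meta, indent=2))


def read_compressed(path: str | Path, sep: str = "\t") -> CompressedMatrix:
    import pandas as pd

    df = pd.read_csv(path, sep=sep, index_col=0)
    meta_path = Path(str(path) + ".json")
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        spec = AutoencoderSpec(**{
            k: (tuple(v) if k == "encoder_layer_sizes" else v)
            for k, v in meta["spec"].items()
        })
        n_chunks = meta["n_chunks"]
        mses = meta.get("chunk_val_mses", [])
    else:
        spec, n_chunks, mses = AutoencoderSpec(), 1, []
    return CompressedMatrix(
        df.to_numpy(dtype=float), [str(i) for i in df.index], spec, n_chunks, mses
    )
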