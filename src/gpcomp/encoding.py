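"""One-hot encoding of dosages and column-wise chunking.

Each dosage maps to a triple: 0 -> [1,0,0], 1 -> [0,1,0], 2 -> [0,0,1].
Chunks are contiguous column blocks of floor(m/k) SNPs, the last chunk
absorbing any remainder, so concatenating chunks reproduces input order.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from gpcomp.errors import ConfigurationError, ConsistencyError, InputError
from gpcomp.genotype_io import MISSING, GenotypeMatrix


@dataclass
class OneHotChunk:
    """A contiguous block of one-hot-encoded markers for all individuals."""

    chunk_index: int
    snp_ids: list[str]
    data: np.ndarray  # n_individuals x (3 * len(snp_ids)), entries in {0,1}

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.shape[1] != 3 * len(self.snp_ids):
            raise ConsistencyError(
                f"chunk {self.chunk_index}: {self.data.shape[1]} columns "
                f"for {len(self.snp_ids)} SNPs (expected 3 per SNP)"
            )

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)


@dataclass
class ChunkSet:
    chunks: list[OneHotChunk]

    @property
    def n_chunks(self) -> int:
        return len(self.chunks)

    @property
    def total_snps(self) -> int:
        return sum(c.n_snps for c in self.chunks)

    @property
    def snp_ids(self) -> list[str]:
        return [s for c in self.chunks for s in c.snp_ids]


def one_hot_encode(g: GenotypeMatrix | np.ndarray) -> np.ndarray:
    """Expand an n x m dosage matrix to n x 3m binary columns.

    Missing entries are a hard error: the fixed input dimension of the
    downstream compression models requires a complete matrix (impute
    first, e.g. with :func:`gpcomp.genotype_io.impute_mean`).
    """
    if isinstance(g, GenotypeMatrix):
        values = g.values
        ind_ids, marker_ids = g.individual_ids, g.marker_ids
    else:
        values = np.asarray(g)
        ind_ids = marker_ids = None
    miss = values == MISSING
    if miss.any():
        i, j = np.argwhere(miss)[0]
        who = ind_ids[i] if ind_ids else f"row {i}"
        what = marker_ids[j] if marker_ids else f"column {j}"
        raise InputError(
            f"missing genotype for individual {who!r} at marker {what!r}; "
            "encoding requires a complete matrix"
        )
    if not np.isin(values, (0, 1, 2)).all():
        raise InputError("dosages must be 0, 1, or 2")
    n, m = values.shape
    out = np.zeros((n, 3 * m), dtype=np.uint8)
    cols = 3 * np.arange(m)
    for d in (0, 1, 2):
        rows, js = np.nonzero(values == d)
        out[rows, cols[js] + d] = 1
    return out


def decode_one_hot(encoded: np.ndarray) -> np.ndarray:
    """Dosages by argmax over each column triple.

    Accepts real-valued reconstructions.  An exact two-way tie resolves
    to the lower dosage (numpy argmax convention) with a warning.
    """
    encoded = np.asarray(encoded, dtype=float)
    if encoded.ndim != 2 or encoded.shape[1] % 3 != 0:
        raise ConsistencyError("encoded matrix width must be a multiple of 3")
    n, w = encoded.shape
    triples = encoded.reshape(n, w // 3, 3)
    top = triples.max(axis=2, keepdims=True)
    if ((triples == top).sum(axis=2) > 1).any():
        warnings.warn(
            "tied maxima in one-hot triples; decoded to the lower dosage",
            stacklevel=2,
        )
    return triples.argmax(axis=2).astype(np.int8)


def chunk_sizes(total_snps: int, n_chunks: int) -> list[int]:
    """floor(m/k) per chunk, remainder appended to the last chunk."""
    if n_chunks < 1:
        raise ConfigurationError("n_chunks must be >= 1")
    if n_chunks > total_snps:
        raise ConfigurationError(
            f"n_chunks={n_chunks} exceeds total SNPs ({total_snps})"
        )
    base = total_snps // n_chunks
    sizes = [base] * n_chunks
    sizes[-1] += total_snps - base * n_chunks
    return sizes


def divide_chunks(
    g: GenotypeMatrix | np.ndarray,
    n_chunks: int,
    snp_ids: list[str] | None = None,
) -> ChunkSet:
    """Encode (if needed) and split into contiguous column blocks.

    Accepts a :class:`GenotypeMatrix` (encoded here) or an already
    one-hot-encoded n x 3m matrix with ``snp_ids``.
    """
    if isinstance(g, GenotypeMatrix):
        snp_ids = g.marker_ids
        encoded = one_hot_encode(g)
    else:
        encoded = np.asarray(g)
        if snp_ids is None:
            if encoded.shape[1] % 3 != 0:
                raise ConsistencyError("width must be a multiple of 3")
            snp_ids = [f"snp{j}" for j in range(encoded.shape[1] // 3)]
    if encoded.shape[1] != 3 * len(snp_ids):
        raise ConsistencyError("snp_ids length does not match encoded width")

    sizes = chunk_sizes(len(snp_ids), n_chunks)
    chunks, start = [], 0
    for idx, size in enumerate(sizes):
        stop = start + size
        chunks.append(
            OneHotChunk(idx, snp_ids[start:stop], encoded[:, 3 * start : 3 * stop])
        )
        start = stop
    return ChunkSet(chunks)


def reassemble(cs: ChunkSet) -> np.ndarray:
    """Concatenate chunk data column-wise, checking order and row counts."""
    if not cs.chunks:
        raise ConsistencyError("empty chunk set")
    n_rows = {c.data.shape[0] for c in cs.chunks}
    if len(n_rows) != 1:
        raise ConsistencyError("chunks disagree on the number of individuals")
    indices = [c.chunk_index for c in cs.chunks]
    if indices != sorted(indices):
        raise ConsistencyError("chunks are out of order")
    return np.concatenate([c.data for c in cs.chunks], axis=1)


# ---------------------------------------------------------------------------
# chunk persistence: one delimited file per chunk plus a JSON manifest


def _chunk_checksum(chunk: OneHotChunk) -> str:
    h = hashlib.sha256()
    h.update(",".join(chunk.snp_ids).encode())
    h.update(np.ascontiguousarray(chunk.data, dtype=np.uint8).tobytes())
    return h.hexdigest()


def write_chunks(cs: ChunkSet, directory: str | Path, individual_ids: list[str]) -> Path:
    """Write each chunk as CSV plus a manifest; returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for chunk in cs.chunks:
        cols = [f"{s}_{d}" for s in chunk.snp_ids for d in (0, 1, 2)]
        fname = f"chunk_{chunk.chunk_index:05d}.csv"
        pd.DataFrame(chunk.data, index=individual_ids, columns=cols).to_csv(
            directory / fname, index_label="id"
        )
        entries.append(
            {
                "chunk_index": chunk.chunk_index,
                "file": fname,
                "snp_ids": chunk.snp_ids,
                "checksum": _chunk_checksum(chunk),
            }
        )
    manifest = {
        "n_chunks": cs.n_chunks,
        "total_snps": cs.total_snps,
        "individual_ids": individual_ids,
        "chunks": entries,
    }
    manifest_path = directory / "chunks_manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest_path


def read_chunks(manifest_path: str | Path) -> tuple[ChunkSet, list[str]]:
    """Load a chunk set written by :func:`write_chunks`, verifying checksums."""
    manifest_path = Path(manifest_path)
    manifest = json.loads(manifest_path.read_text())
    directory = manifest_path.parent
    chunks = []
    for entry in manifest["chunks"]:
        df = pd.read_csv(directory / entry["file"], index_col=0)
        chunk = OneHotChunk(
            entry["chunk_index"], entry["snp_ids"], df.to_numpy(dtype=np.uint8)
        )
        if _chunk_checksum(chunk) != entry["checksum"]:
            raise ConsistencyError(
                f"checksum mismatch for chunk {entry['chunk_index']}"
            )
        chunks.append(chunk)
    chunks.sort(key=lambda c: c.chunk_index)
    return ChunkSet(chunks), [str(i) for i in manifest["individual_ids"]]
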