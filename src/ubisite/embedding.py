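"""Per-lysine embedding extraction behind a pluggable encoder contract.

A protein-language-model encoder maps an amino-acid string to one feature
vector per residue; the row at a lysine's position is that site's feature
vector.  Real encoders (e.g. a 2560-dimensional ESM2-style model) plug in
through :class:`SequenceEncoder`; the deterministic :class:`MockEncoder`
satisfies the same contract without any model weights, so the entire
pipeline is exercisable offline.

Embeddings travel in an :class:`EmbeddingTable` and persist as a two-file
container: a TSV site table next to a raw little-endian float32 matrix with
a small self-describing header.
"""

from __future__ import annotations

import hashlib
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol, Sequence, runtime_checkable

import numpy as np

from .seqsites import (ProteinRecord, SiteRecord, extract_window,
                       read_site_table, window_center, write_site_table)

MAGIC = b"UBIEMB01"

FULL_SEQUENCE = "full_sequence"
WINDOW = "window"


@runtime_checkable
class SequenceEncoder(Protocol):
    """Contract every encoder backend must satisfy.

    ``embed_sequence`` returns a matrix of shape (sequence length, dim);
    output must be deterministic given the same sequence, and ``dim`` is
    fixed per encoder instance.  Adapters around real language models must
    document which hidden layer they expose (the convention here is the
    final per-residue representation before the output head).
    """

    name: str
    dim: int

    def embed_sequence(self, sequence: str) -> np.ndarray: ...


class EncoderContractError(RuntimeError):
    """An encoder violated its output-shape contract."""


class MockEncoder:
    """Deterministic stand-in encoder keyed by (residue letter, position).

    Each residue's vector is derived from a seeded hash of its letter and
    its 1-based position within the presented sequence, so identical inputs
    always embed identically while context (through position) still shifts
    the rows, mimicking how a window's coordinates shift under truncation.
    """

    def __init__(self, dim: int = 32, seed: int = 0,
                 name: str | None = None) -> None:
        if dim < 1:
            raise ValueError("dim must be >= 1")
        self.dim = int(dim)
        self.seed = int(seed)
        self.name = name or f"mock-d{dim}-s{seed}"

    def _residue_vector(self, letter: str, position: int) -> np.ndarray:
        key = f"{self.seed}:{letter}:{position}".encode()
        digest = hashlib.sha256(key).digest()
        root = int.from_bytes(digest[:8], "little")
        rng = np.random.Generator(np.random.PCG64(root))
        return rng.standard_normal(self.dim)

    def embed_sequence(self, sequence: str) -> np.ndarray:
        out = np.empty((len(sequence), self.dim), dtype=np.float64)
        for i, letter in enumerate(sequence):
            out[i] = self._residue_vector(letter, i + 1)
        return out


def mock_encoder(dim: int = 32, seed: int = 0) -> MockEncoder:
    return MockEncoder(dim=dim, seed=seed)


@dataclass
class EmbeddingTable:
    """Per-site feature matrix aligned row-for-row with its site list."""

    sites: list[SiteRecord]
    features: np.ndarray
    encoder_name: str = "unknown"
    mode: str = FULL_SEQUENCE
    window_n: int | None = None

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=np.float64)
        if self.features.ndim != 2:
            raise ValueError("features must be a 2-d matrix")
        if len(self.sites) != self.features.shape[0]:
            raise ValueError(
                f"{len(self.sites)} sites but {self.features.shape[0]} "
                "feature rows")
        if not np.all(np.isfinite(self.features)):
            raise ValueError("features contain non-finite values")

    @property
    def dim(self) -> int:
        return self.features.shape[1]

    def __len__(self) -> int:
        return len(self.sites)

    def labels(self) -> np.ndarray:
        """Label vector; raises if any site is unlabeled."""
        if any(s.label is None for s in self.sites):
            raise ValueError("table contains unlabeled sites")
        return np.array([s.label for s in self.sites], dtype=np.int64)

    def subset(self, indices: Sequence[int]) -> "EmbeddingTable":
        idx = list(indices)
        return EmbeddingTable(sites=[self.sites[i] for i in idx],
                              features=self.features[idx],
                              encoder_name=self.encoder_name,
                              mode=self.mode, window_n=self.window_n)


def _encode_checked(encoder: SequenceEncoder, sequence: str) -> np.ndarray:
    mat = np.asarray(encoder.embed_sequence(sequence), dtype=np.float64)
    if mat.shape != (len(sequence), encoder.dim):
        raise EncoderContractError(
            f"encoder {encoder.name!r} returned shape {mat.shape} for a "
            f"length-{len(sequence)} sequence (expected "
            f"({len(sequence)}, {encoder.dim}))")
    return mat


def embed_sites(encoder: SequenceEncoder, protein: ProteinRecord,
                sites: Sequence[SiteRecord], mode: str = FULL_SEQUENCE,
                window_n: int | None = None) -> EmbeddingTable:
    """Embed each lysine site of one protein.

    ``full_sequence`` mode runs the encoder once over the whole sequence
    and picks the row at each site's position; ``window`` mode embeds the
    truncated window around each site independently and picks the row at
    the lysine's (possibly shifted) position inside the window.
    """
    for s in sites:
        if s.protein_id != protein.id:
            raise ValueError(f"site {s.protein_id}:{s.position} does not "
                             f"belong to protein {protein.id}")
        if protein.sequence[s.position - 1] != "K":
            raise ValueError(f"position {s.position} of {protein.id} is not 'K'")
    if mode == FULL_SEQUENCE:
        rows = _encode_checked(encoder, protein.sequence)
        feats = np.array([rows[s.position - 1] for s in sites])
    elif mode == WINDOW:
        if window_n is None:
            raise ValueError("window mode requires window_n")
        feats_list = []
        for s in sites:
            sub = extract_window(protein.sequence, s.position, window_n)
            center = window_center(s.position, window_n)
            rows = _encode_checked(encoder, sub)
            feats_list.append(rows[center - 1])
        feats = (np.array(feats_list) if feats_list
                 else np.empty((0, encoder.dim)))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if feats.size == 0:
        feats = feats.reshape(0, encoder.dim)
    return EmbeddingTable(sites=list(sites), features=feats,
                          encoder_name=encoder.name, mode=mode,
                          window_n=window_n)


def embed_proteins(encoder: SequenceEncoder,
                   proteins: Sequence[ProteinRecord],
                   sites: Sequence[SiteRecord], mode: str = FULL_SEQUENCE,
                   window_n: int | None = None) -> EmbeddingTable:
    """Embed sites spanning several proteins; row order follows ``sites``."""
    by_protein = {p.id: p for p in proteins}
    tables = []
    # group contiguous runs per protein but restore the input site order
    order: list[int] = []
    for pid in dict.fromkeys(s.protein_id for s in sites):
        if pid not in by_protein:
            raise ValueError(f"no protein record for site protein {pid!r}")
        idx = [i for i, s in enumerate(sites) if s.protein_id == pid]
        order.extend(idx)
        tables.append(embed_sites(encoder, by_protein[pid],
                                  [sites[i] for i in idx], mode=mode,
                                  window_n=window_n))
    feats = (np.vstack([t.features for t in tables]) if tables
             else np.empty((0, encoder.dim)))
    all_sites = [s for t in tables for s in t.sites]
    inverse = np.argsort(order) if order else []
    return EmbeddingTable(
        sites=[all_sites[i] for i in inverse],
        features=feats[inverse] if len(order) else feats,
        encoder_name=encoder.name, mode=mode, window_n=window_n)


def batch_sites(table: EmbeddingTable, batch_size: int) -> list[list[int]]:
    """Group site indices into batches keeping same-protein sites together.

    Sites sharing a protein are contiguous within and across batches and a
    protein is split only when it alone exceeds ``batch_size`` (then in
    position order).  The concatenated batches are a permutation of all
    row indices.
    """
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    groups: dict[str, list[int]] = {}
    for i, s in enumerate(table.sites):
        groups.setdefault(s.protein_id, []).append(i)
    for idx in groups.values():
        idx.sort(key=lambda i: table.sites[i].position)
    batches: list[list[int]] = []
    current: list[int] = []
    for idx in groups.values():
        if len(idx) > batch_size:
            if current:
                batches.append(current)
                current = []
            for start in range(0, len(idx), batch_size):
                chunk = idx[start:start + batch_size]
                if len(chunk) == batch_size:
                    batches.append(chunk)
                else:
                    current = chunk
            continue
        if len(current) + len(idx) > batch_size:
            batches.append(current)
            current = []
        current.extend(idx)
    if current:
        batches.append(current)
    return batches


# ---------------------------------------------------------------------------
# on-disk container: <stem>.sites.tsv + <stem>.mat (float32, little-endian)

def _matrix_path(stem: Path) -> Path:
    return stem.with_suffix(".mat")


def _sites_path(stem: Path) -> Path:
    return stem.with_suffix(".sites.tsv")


def write_embeddings(table: EmbeddingTable, stem: str | Path) -> None:
    """Persist a table as TSV sites + raw float32 matrix.

    The matrix file starts with an 8-byte magic string, two little-endian
    uint64 fields (n_rows, dim), then row-major float32 data.  float32 is
    the contract: a write → read round trip is bit-exact at float32
    precision.
    """
    stem = Path(stem)
    write_site_table(table.sites, _sites_path(stem))
    mat = np.ascontiguousarray(table.features, dtype="<f4")
    with open(_matrix_path(stem), "wb") as fh:
        fh.write(MAGIC)
        fh.write(struct.pack("<QQ", mat.shape[0], mat.shape[1]))
        fh.write(f"{table.encoder_name}\t{table.mode}\t"
                 f"{table.window_n if table.window_n is not None else ''}\n"
                 .encode())
        fh.write(mat.tobytes())


def read_embeddings(stem: str | Path) -> EmbeddingTable:
    stem = Path(stem)
    sites = read_site_table(_sites_path(stem))
    with open(_matrix_path(stem), "rb") as fh:
        magic = fh.read(len(MAGIC))
        if magic != MAGIC:
            raise ValueError(f"{_matrix_path(stem)}: not an embedding matrix "
                             "(bad magic)")
        n_rows, dim = struct.unpack("<QQ", fh.read(16))
        meta = fh.readline().decode().rstrip("\n").split("\t")
        encoder_name, mode, window_raw = meta
        data = np.frombuffer(fh.read(), dtype="<f4")
    if data.size != n_rows * dim:
        raise ValueError(f"{_matrix_path(stem)}: expected {n_rows * dim} "
                         f"float32 values, found {data.size}")
    feats = data.reshape(n_rows, dim).astype(np.float64)
    return EmbeddingTable(sites=sites, features=feats,
                          encoder_name=encoder_name, mode=mode,
                          window_n=int(window_raw) if window_raw else None)
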