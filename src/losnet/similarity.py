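"""Patient-similarity search: blocked Jaccard k-nearest neighbors.

Two admissions are comparable only when they share sex and five-year age
group (the blocking predicate); within a block, similarity is the Jaccard
index of the diagnosis sets present at the point of admission.  For each
query admission the index returns its top-k most similar *training*
admissions — the neighbors whose observed LOS values later become features.

Two backends satisfy the same contract: ``exact`` scores a query against its
whole block with sparse matrix products (the true top-k), and ``minhash``
generates candidates by MinHash banding before exact re-scoring (approximate,
validated to ≥0.95 recall of the exact top-100 on test fixtures).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import sparse

from .records import AdmissionRecord, ChronicDiseaseCatalog, age_group

Backend = Literal["exact", "minhash"]

_MERSENNE = (1 << 61) - 1


def block_key(record: AdmissionRecord) -> tuple[str, str]:
    """(sex, age-group) blocking key; every elderly admission maps to one."""
    return record.sex, age_group(record.age)


def poa_set(record: AdmissionRecord,
            catalog: ChronicDiseaseCatalog | None = None) -> frozenset[str]:
    """Diagnosis codes flagged at admission, optionally catalog-restricted."""
    codes = record.poa_codes()
    if catalog is not None:
        codes &= catalog.codes
    return frozenset(codes)


def jaccard(d_i: Iterable[str], d_j: Iterable[str]) -> float:
    """|d_i ∩ d_j| / |d_i ∪ d_j|; undefined when both sets are empty."""
    a, b = set(d_i), set(d_j)
    union = a | b
    if not union:
        raise ValueError("Jaccard similarity of two empty sets is undefined")
    return len(a & b) / len(union)


@dataclass
class NeighborList:
    """Ordered top-k similar training admissions for one query admission."""

    query_id: str
    entries: list[tuple[str, float]] = field(default_factory=list)

    def ids(self) -> list[str]:
        return [i for i, _ in self.entries]

    def similarities(self) -> list[float]:
        return [s for _, s in self.entries]


@dataclass
class _Block:
    record_ids: list[str]
    patient_ids: list[str]
    matrix: sparse.csr_matrix       # binary admissions × vocabulary
    set_sizes: np.ndarray
    los: np.ndarray
    buckets: dict[tuple[int, int], dict[int, list[int]]] | None = None
    signatures: np.ndarray | None = None


@dataclass
class SimilarityIndex:
    """Per-block searchable collection of training admissions."""

    blocks: dict[tuple[str, str], _Block]
    vocab: dict[str, int]
    backend: Backend
    catalog: ChronicDiseaseCatalog | None
    minhash_perms: np.ndarray | None = None   # (2, num_perm) a,b coefficients
    band_rows: int = 1

    def __len__(self) -> int:
        return sum(len(b.record_ids) for b in self.blocks.values())

    def los_lookup(self) -> dict[str, int]:
        out = {}
        for b in self.blocks.values():
            out.update(zip(b.record_ids, b.los.tolist()))
        return out


def _vectorize(sets: Sequence[frozenset[str]], vocab: dict[str, int]
               ) -> sparse.csr_matrix:
    ri, ci = [], []
    for i, s in enumerate(sets):
        for c in s:
            if c in vocab:
                ri.append(i)
                ci.append(vocab[c])
    return sparse.csr_matrix(
        (np.ones(len(ri), dtype=np.int32), (ri, ci)),
        shape=(len(sets), max(len(vocab), 1)),
    )


def _minhash_signatures(m: sparse.csr_matrix, perms: np.ndarray) -> np.ndarray:
    """Column-index MinHash signatures, one column per admission row of m."""
    a, b = perms
    n_rows, num_perm = m.shape[0], a.shape[0]
    sig = np.full((num_perm, n_rows), np.iinfo(np.int64).max)
    indptr, indices = m.indptr, m.indices
    for i in range(n_rows):
        cols = indices[indptr[i]:indptr[i + 1]]
        if len(cols):
            h = (a[:, None] * (cols[None, :] + 1) + b[:, None]) % _MERSENNE
            sig[:, i] = h.min(axis=1)
    return sig


def build_index(
    train: Sequence[AdmissionRecord],
    backend: Backend = "exact",
    catalog: ChronicDiseaseCatalog | None = None,
    num_perm: int = 64,
    band_rows: int = 1,
    seed: int = 0,
) -> SimilarityIndex:
    """Index training admissions by block; deterministic given input order
    and seed."""
    if not train:
        raise ValueError("cannot index an empty training set")
    vocab_codes = sorted(set().union(*(poa_set(r, catalog) for r in train)))
    vocab = {c: k for k, c in enumerate(vocab_codes)}

    rng = np.random.default_rng(seed)
    perms = None
    if backend == "minhash":
        perms = np.stack([
            rng.integers(1, _MERSENNE, num_perm),
            rng.integers(0, _MERSENNE, num_perm),
        ])

    grouped: dict[tuple[str, str], list[AdmissionRecord]] = {}
    for r in train:
        grouped.setdefault(block_key(r), []).append(r)

    blocks = {}
    for key, recs in grouped.items():
        sets = [poa_set(r, catalog) for r in recs]
        m = _vectorize(sets, vocab)
        blk = _Block(
            record_ids=[r.record_id for r in recs],
            patient_ids=[r.patient_id for r in recs],
            matrix=m,
            set_sizes=np.asarray(m.sum(axis=1)).ravel(),
            los=np.array([r.los for r in recs]),
        )
        if backend == "minhash":
            blk.signatures = _minhash_signatures(m, perms)
            n_bands = num_perm // band_rows
            buckets: dict[tuple[int, int], dict[int, list[int]]] = {}
            for band in range(n_bands):
                rows = blk.signatures[band * band_rows:(band + 1) * band_rows]
                keys = np.apply_along_axis(
                    lambda col: hash(tuple(col)), 0, rows
                )
                per_band: dict[int, list[int]] = {}
                for i, hk in enumerate(keys):
                    per_band.setdefault(int(hk), []).append(i)
                buckets[(band, 0)] = per_band
            blk.buckets = buckets
        blocks[key] = blk
    return SimilarityIndex(blocks, vocab, backend, catalog, perms, band_rows)


def _candidates(index: SimilarityIndex, blk: _Block, q_vec: sparse.csr_matrix
                ) -> np.ndarray:
    """Row indices of candidate neighbors within the block."""
    if index.backend == "exact":
        return np.arange(len(blk.record_ids))
    sig = _minhash_signatures(q_vec, index.minhash_perms)[:, 0]
    num_perm = sig.shape[0]
    cand: set[int] = set()
    for band in range(num_perm // index.band_rows):
        rows = sig[band * index.band_rows:(band + 1) * index.band_rows]
        hk = hash(tuple(rows))
        cand.update(blk.buckets[(band, 0)].get(int(hk), ()))
    return np.fromiter(cand, dtype=np.int64) if cand else np.empty(0, np.int64)


def query_neighbors(
    index: SimilarityIndex,
    admission: AdmissionRecord,
    k: int = 100,
    exclude: set[str] | None = None,
    exclude_same_patient: bool = True,
) -> NeighborList:
    """Top-k training neighbors of ``admission`` within its block.

    The admission's own id is always removed; by default so are all training
    admissions of the same patient (guarding against label leakage through a
    patient's own past stays).  Zero-similarity entries are dropped even when
    k is not filled; ties break by ascending admission id.
    """
    key = block_key(admission)
    blk = index.blocks.get(key)
    if blk is None:
        return NeighborList(admission.record_id)

    q = poa_set(admission, index.catalog)
    q_vec = _vectorize([q], index.vocab)
    cand = _candidates(index, blk, q_vec)
    if len(cand) == 0 or len(q) == 0:
        return NeighborList(admission.record_id)

    sub = blk.matrix[cand]
    inter = np.asarray((sub @ q_vec.T).todense()).ravel()
    union = blk.set_sizes[cand] + len(q) - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sims = np.where(union > 0, inter / union, 0.0)

    excluded = set(exclude or ())
    excluded.add(admission.record_id)
    entries = []
    for pos, sim in zip(cand, sims):
        if sim <= 0.0:
            continue
        rid = blk.record_ids[pos]
        if rid in excluded:
            continue
        if exclude_same_patient and blk.patient_ids[pos] == admission.patient_id:
            continue
        entries.append((rid, float(sim)))
    entries.sort(key=lambda e: (-e[1], e[0]))
    return NeighborList(admission.record_id, entries[:k])


def neighbor_table(neighbors: Iterable[NeighborList]):
    """Flat export rows (query_id, rank, neighbor_id, similarity)."""
    import pandas as pd

    rows = [
        {"query_id": nl.query_id, "rank": rank, "neighbor_id": rid,
         "similarity": sim}
        for nl in neighbors
        for rank, (rid, sim) in enumerate(nl.entries, start=1)
    ]
    return pd.DataFrame(
        rows, columns=["query_id", "rank", "neighbor_id", "similarity"]
    )
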