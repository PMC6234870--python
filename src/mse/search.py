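"""Two-tier indexed top-k similarity search.

Tier one aggregates every sample's abundances to a chosen taxonomy rank
(default genus — fine enough to discriminate samples within one habitat,
still ~5x smaller than full profiles); the candidates with the smallest L1
key distance to the query are fetched. Tier two scores only those candidates with the exact
phylogenetic kernel and returns the top k. Exhaustive mode skips tier one
and guarantees exact results; the indexed tier is a high-recall heuristic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .database import ReferenceDatabase
from .errors import ValidationError
from .phylogeny import parse_lineage
from .similarity import KernelConfig, similarity_to_many

DEFAULT_LEVEL = "genus"


@dataclass
class IndexTable:
    """Per-sample index-key weight vectors at one taxonomy rank.

    ``weights`` is a samples x keys DataFrame; each row sums to <= 1 (to 1
    when every taxon resolves at the rank, counting the pooled
    "unclassified" key).
    """

    level: str
    weights: pd.DataFrame
    #: per-leaf column position into ``weights.columns`` (for fast queries)
    leaf_key_positions: np.ndarray = field(repr=False, default=None)

    @property
    def keys(self) -> list[str]:
        return list(self.weights.columns)


@dataclass
class HitList:
    """Ranked search result: (sample_id, similarity) descending, ties by id."""

    query_id: str
    hits: list[tuple[str, float]]
    k: int
    exhaustive: bool

    def ids(self) -> list[str]:
        return [sid for sid, _ in self.hits]


def build_index(db: ReferenceDatabase, level: str = DEFAULT_LEVEL) -> IndexTable:
    """Precompute index keys and weights for all database samples."""
    labels = db.phylogeny.rank_labels(level)
    keys = sorted(set(labels))
    key_pos = {g: j for j, g in enumerate(keys)}
    leaf_positions = np.array([key_pos[g] for g in labels], dtype=np.intp)
    matrix = db.matrix()
    weights = np.zeros((matrix.shape[0], len(keys)))
    np.add.at(weights.T, leaf_positions, matrix.T)
    table = IndexTable(
        level=level,
        weights=pd.DataFrame(weights, index=db.sample_ids, columns=keys),
        leaf_key_positions=leaf_positions,
    )
    return table


def query_key_vector(vector: np.ndarray, index: IndexTable) -> np.ndarray:
    """Aggregate a dense query vector onto the index keys."""
    out = np.zeros(len(index.keys))
    np.add.at(out, index.leaf_key_positions, vector)
    return out


def select_candidates(
    query_keys: np.ndarray, index: IndexTable, c: int, within: list[str] | None = None
) -> list[str]:
    """The `c` samples with smallest L1 distance on index-key vectors.

    Ties break by ascending sample id; if the (eligible) database is smaller
    than `c`, all samples are returned.
    """
    if c < 1:
        raise ValidationError(f"candidate pool size must be >= 1, got {c}")
    weights = index.weights if within is None else index.weights.loc[within]
    if weights.empty:
        raise ValidationError("cannot select candidates from an empty index")
    dist = np.abs(weights.to_numpy() - np.asarray(query_keys)[None, :]).sum(axis=1)
    ids = list(weights.index)
    order = sorted(range(len(ids)), key=lambda i: (dist[i], ids[i]))
    return [ids[i] for i in order[:c]]


def candidate_pool_size(k: int, n_db: int) -> int:
    """Default tier-one pool: max(15 k, 5% of the database)."""
    return max(15 * k, math.ceil(0.05 * n_db))


def _eligible_ids(
    db: ReferenceDatabase,
    exclude_studies: set[str],
    max_year: int | None,
    exclude_ids: set[str],
) -> list[str]:
    meta = db.metadata
    mask = ~meta["study_id"].isin(exclude_studies) if exclude_studies else pd.Series(
        True, index=meta.index
    )
    if max_year is not None:
        # samples without a timestamp cannot be proven eligible under a cutoff
        mask &= meta["year"].notna() & (meta["year"] <= max_year)
    if exclude_ids:
        mask &= ~meta.index.isin(exclude_ids)
    return list(meta.index[mask])


def search(
    query,
    db: ReferenceDatabase,
    k: int = 10,
    exhaustive: bool = False,
    exclude_studies: set[str] | None = None,
    max_year: int | None = None,
    exclude_ids: set[str] | None = None,
    candidates: int | None = None,
    level: str = DEFAULT_LEVEL,
    config: KernelConfig = KernelConfig(),
) -> HitList:
    """Top-k most similar database samples for one query profile.

    A query that happens to be in the database keeps its self-hit; pass
    ``exclude_ids`` to suppress it (the attention/novelty scorers do).
    Only candidate samples' store files are loaded in indexed mode.
    """
    if k < 1:
        raise ValidationError(f"k must be >= 1, got {k}")
    if isinstance(query, np.ndarray):
        qvec, query_id = query, "<query>"
    else:
        qvec = query.to_vector(db.phylogeny)
        query_id = query.sample_id
    if qvec.sum() <= 0:
        raise ValidationError(f"unmappable query {query_id!r}: no taxa on the reference tree")

    eligible = _eligible_ids(db, set(exclude_studies or ()), max_year, set(exclude_ids or ()))
    if not eligible:
        return HitList(query_id, [], k, exhaustive)

    if exhaustive:
        pool = eligible
    else:
        index = db._index_tables.get(level)
        if index is None:
            index = build_index(db, level)
            db._index_tables[level] = index
        c = candidates if candidates is not None else candidate_pool_size(k, db.n_samples)
        pool = select_candidates(query_key_vector(qvec, index), index, c, within=eligible)

    sims = similarity_to_many(qvec, db.matrix(pool), db.phylogeny, config, validate=False)
    order = sorted(range(len(pool)), key=lambda i: (-sims[i], pool[i]))
    hits = [(pool[i], float(sims[i])) for i in order[:k]]
    return HitList(query_id, hits, k, exhaustive)
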