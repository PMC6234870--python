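"""The time-stamped reference database and its on-disk sample store.

Each reference sample is re-encoded once against the build-time tree: its
taxa become (leaf-ordinal, abundance) pairs sorted by the canonical
post-order ordinal, and every sample lives in its own small text file. A
JSON manifest records the canonical leaf ordering (so stores are
self-describing) and maps sample ids to files. Searching then loads only the
candidate samples' files instead of the whole table — the property that lets
the engine scale to corpora far larger than RAM.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DuplicateSampleError, ValidationError
from .phylogeny import PhylogenyView
from .profiles import MicrobiomeProfile, align_to_phylogeny
from .similarity import KernelConfig, similarity_to_many

logger = logging.getLogger(__name__)

_MANIFEST = "manifest.json"
_META_COLUMNS = ["study_id", "habitat", "year", "date", "read_count", "mapping_rate"]


class SampleStore:
    """One re-encoded plain-text file per sample, plus a JSON manifest.

    Every ``load`` is appended to ``access_log`` so tests (and curious users)
    can verify that a search touched only its candidate files.
    """

    def __init__(self, directory, leaf_order: tuple[str, ...], samples: dict[str, str]):
        self.directory = Path(directory)
        self.leaf_order = tuple(leaf_order)
        self.samples = dict(samples)
        self.access_log: list[str] = []

    # -- construction ---------------------------------------------------
    @classmethod
    def create(cls, directory, leaf_order: tuple[str, ...]) -> "SampleStore":
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        store = cls(directory, leaf_order, {})
        store._write_manifest()
        return store

    @classmethod
    def open(cls, directory) -> "SampleStore":
        directory = Path(directory)
        with open(directory / _MANIFEST) as fh:
            manifest = json.load(fh)
        return cls(directory, tuple(manifest["leaf_order"]), manifest["samples"])

    def _write_manifest(self) -> None:
        manifest = {
            "format": "mse-sample-store/1",
            "encoding": "post-order leaf ordinal \\t relative abundance",
            "leaf_order": list(self.leaf_order),
            "samples": {sid: self.samples[sid] for sid in sorted(self.samples)},
        }
        with open(self.directory / _MANIFEST, "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
            fh.write("\n")

    # -- I/O -------------------------------------------------------------
    def write(self, sample_id: str, abundances: dict[str, float], flush: bool = True) -> None:
        """Re-encode one sample as sorted (ordinal, abundance) pairs.

        Bulk writers pass ``flush=False`` and call :meth:`flush` once at the
        end instead of rewriting the manifest per sample.
        """
        ordinal = {name: i for i, name in enumerate(self.leaf_order)}
        pairs = []
        for taxon, value in abundances.items():
            if taxon not in ordinal:
                raise ValidationError(
                    f"taxon {taxon!r} of sample {sample_id!r} is outside the canonical ordering"
                )
            pairs.append((ordinal[taxon], float(value)))
        pairs.sort()
        filename = f"{sample_id}.tsv"
        with open(self.directory / filename, "w") as fh:
            for k, v in pairs:
                fh.write(f"{k}\t{v!r}\n")
        self.samples[sample_id] = filename
        if flush:
            self._write_manifest()

    def flush(self) -> None:
        self._write_manifest()

    def load(self, sample_id: str) -> np.ndarray:
        """Load one sample's dense vector; the access is logged."""
        if sample_id not in self.samples:
            raise KeyError(sample_id)
        self.access_log.append(sample_id)
        vec = np.zeros(len(self.leaf_order))
        with open(self.directory / self.samples[sample_id]) as fh:
            for line in fh:
                k, v = line.split("\t")
                vec[int(k)] = float(v)
        return vec

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self.samples


def write_sample_store(db: "ReferenceDatabase", directory) -> dict:
    """Write every sample of `db` into a fresh store; returns the manifest."""
    store = SampleStore.create(directory, db.phylogeny.leaf_order)
    for sid in db.sample_ids:
        vec = db.vector(sid)
        abundances = {db.phylogeny.leaf_order[i]: float(v) for i, v in enumerate(vec) if v > 0}
        store.write(sid, abundances, flush=False)
    store.flush()
    db.store = store
    with open(store.directory / _MANIFEST) as fh:
        return json.load(fh)


class ReferenceDatabase:
    """Curated, deduplicated, time-stamped collection of profiles.

    Holds the phylogeny, per-sample metadata, taxonomy-level index tables
    (built lazily by :mod:`mse.search`) and either in-memory abundance
    vectors or a lazy on-disk :class:`SampleStore`.
    """

    def __init__(
        self,
        phylogeny: PhylogenyView,
        metadata: pd.DataFrame,
        vectors: dict[str, np.ndarray] | None = None,
        store: SampleStore | None = None,
        build_log: list[str] | None = None,
    ):
        self.phylogeny = phylogeny
        self.metadata = metadata
        self._vectors: dict[str, np.ndarray] = dict(vectors or {})
        self.store = store
        self.build_log: list[str] = list(build_log or [])
        self._index_tables: dict[str, object] = {}
        self._similarity_cache: dict[tuple, np.ndarray] = {}

    # -- construction ---------------------------------------------------
    @classmethod
    def build(
        cls,
        profiles: list[MicrobiomeProfile],
        phylogeny: PhylogenyView,
        storage_dir=None,
    ) -> "ReferenceDatabase":
        """Build from normalized profiles; taxa outside the tree are dropped."""
        ids = [p.sample_id for p in profiles]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise DuplicateSampleError(f"duplicate sample ids: {dupes}")
        rows = []
        vectors = {}
        for profile in profiles:
            aligned = align_to_phylogeny(profile, phylogeny)
            vectors[profile.sample_id] = aligned.to_vector(phylogeny)
            rows.append(
                {
                    "sample_id": profile.sample_id,
                    "study_id": profile.study_id,
                    "habitat": profile.habitat,
                    "year": profile.year,
                    "date": profile.date,
                    "read_count": profile.read_count,
                    "mapping_rate": profile.mapping_rate,
                }
            )
        metadata = pd.DataFrame(rows).set_index("sample_id")[_META_COLUMNS]
        db = cls(phylogeny, metadata, vectors)
        db.build_log.append(f"built from {len(profiles)} profiles")
        if storage_dir is not None:
            write_sample_store(db, storage_dir)
            db.build_log.append("sample store written")
        return db

    # -- basic accessors -------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.metadata.index)

    @property
    def n_samples(self) -> int:
        return len(self.metadata)

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self.metadata.index

    def vector(self, sample_id: str) -> np.ndarray:
        vec = self._vectors.get(sample_id)
        if vec is None:
            if self.store is None or sample_id not in self.store:
                raise KeyError(f"sample {sample_id!r} has no stored abundances")
            vec = self.store.load(sample_id)
            self._vectors[sample_id] = vec
        return vec

    def matrix(self, sample_ids: list[str] | None = None) -> np.ndarray:
        """Dense (n, n_leaves) abundance matrix; loads from the store as needed."""
        ids = self.sample_ids if sample_ids is None else list(sample_ids)
        return np.vstack([self.vector(sid) for sid in ids]) if ids else np.empty(
            (0, self.phylogeny.n_leaves)
        )

    def subset(self, sample_ids: list[str]) -> "ReferenceDatabase":
        """A database restricted to `sample_ids` (kept in the given order)."""
        ids = list(sample_ids)
        missing = [s for s in ids if s not in self.metadata.index]
        if missing:
            raise KeyError(f"samples not in database: {missing[:5]}")
        sub = ReferenceDatabase(
            self.phylogeny,
            self.metadata.loc[ids],
            {s: self._vectors[s] for s in ids if s in self._vectors},
            store=self.store,
            build_log=self.build_log + [f"subset of {len(ids)} samples"],
        )
        # cached similarity matrices restrict to the corresponding block
        pos = {sid: i for i, sid in enumerate(self.sample_ids)}
        take = np.array([pos[s] for s in ids], dtype=np.intp)
        for key, mat in self._similarity_cache.items():
            sub._similarity_cache[key] = mat[np.ix_(take, take)]
        return sub

    # -- similarity ------------------------------------------------------
    def similarity_matrix(self, config: KernelConfig = KernelConfig()) -> np.ndarray:
        """All-pairs similarity over the database, cached per kernel config."""
        key = (config.decay_rate, config.mode)
        if key not in self._similarity_cache:
            mat = self.matrix()
            n = mat.shape[0]
            out = np.empty((n, n))
            for i in range(n):
                out[i] = similarity_to_many(mat[i], mat, self.phylogeny, config, validate=False)
                out[i, i] = 1.0
            out = np.minimum(out, out.T)
            self._similarity_cache[key] = out
            logger.info("similarity matrix cached for %d samples (%s)", n, key)
        return self._similarity_cache[key]

    # -- persistence -----------------------------------------------------
    def save(self, directory) -> None:
        """Write the database (store, index, metadata, tree, lineages, log)."""
        from .search import DEFAULT_LEVEL, build_index  # deferred: avoids an import cycle

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        write_sample_store(self, directory / "samples")
        # precompute the default index so loaded databases can run tier-one
        # candidate selection without touching any sample file
        index = self._index_tables.get(DEFAULT_LEVEL) or build_index(self, DEFAULT_LEVEL)
        self._index_tables[DEFAULT_LEVEL] = index
        index.weights.rename_axis("sample_id").reset_index().to_csv(
            directory / f"index.{DEFAULT_LEVEL}.tsv", sep="\t", index=False
        )
        meta = self.metadata.reset_index()
        meta.to_csv(directory / "metadata.tsv", sep="\t", index=False)
        with open(directory / "tree.nwk", "w") as fh:
            fh.write(self.phylogeny.to_newick())
        with open(directory / "lineages.tsv", "w") as fh:
            fh.write("taxon_id\tlineage\n")
            for name in self.phylogeny.leaf_order:
                fh.write(f"{name}\t{self.phylogeny.lineages.get(name, '')}\n")
        with open(directory / "build_log.txt", "w") as fh:
            fh.write("\n".join(self.build_log) + "\n")

    @classmethod
    def load(cls, directory) -> "ReferenceDatabase":
        """Open a saved database; abundance vectors load lazily from the store."""
        directory = Path(directory)
        if not directory.is_dir():
            raise ValidationError(f"database directory does not exist: {directory}")
        lineages = {}
        with open(directory / "lineages.tsv") as fh:
            next(fh)
            for line in fh:
                taxon, _, lineage = line.rstrip("\n").partition("\t")
                lineages[taxon] = lineage
        phylo = PhylogenyView.from_newick(str(directory / "tree.nwk"), lineages)
        meta = pd.read_csv(
            directory / "metadata.tsv", sep="\t", dtype={"sample_id": str, "study_id": str}
        ).set_index("sample_id")
        store = SampleStore.open(directory / "samples")
        if tuple(store.leaf_order) != phylo.leaf_order:
            raise ValidationError("store manifest leaf order disagrees with the tree")
        log_path = directory / "build_log.txt"
        build_log = log_path.read_text().splitlines() if log_path.exists() else []
        db = cls(phylo, meta[_META_COLUMNS], store=store, build_log=build_log)
        for index_path in sorted(directory.glob("index.*.tsv")):
            from .search import IndexTable  # deferred: avoids an import cycle

            level = index_path.name.split(".")[1]
            weights = pd.read_csv(index_path, sep="\t", dtype={"sample_id": str}).set_index(
                "sample_id"
            )
            labels = phylo.rank_labels(level)
            key_pos = {g: j for j, g in enumerate(weights.columns)}
            db._index_tables[level] = IndexTable(
                level=level,
                weights=weights,
                leaf_key_positions=np.array([key_pos[g] for g in labels], dtype=np.intp),
            )
        return db

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<ReferenceDatabase: {self.n_samples} samples, {self.phylogeny.n_leaves} taxa>"
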