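"""Novelty (MNS), attention (MAS) and focus (MFI) scoring, plus curation.

MNS of a sample is one minus the rank-weighted mean of its top-n
similarities against all *earlier* samples: with descending similarities
S_1 >= ... >= S_n,

    MNS = 1 - sum_i S_i (n - i) / sum_i (n - i),

so with n = 10 the weights are (9, 8, ..., 1, 0)/45 and the 10th match
carries weight zero (implemented verbatim). A high MNS means the sample is
unlike anything previously deposited.

MAS of a sample m sums the similarities of other-study samples i that rank
m inside their own top-n with similarity >= theta_connect (0.85): attention
is attracted, not claimed. MFI = MNS x MAS combines novelty at birth with
attention accrued afterwards. Samples with MNS >= 0.15 at birth are novel;
MAS >= 14 marks high attention (the top-20% quantile of the original
corpus); both together mark a focus sample.

Near-duplicate curation drops the later-dated member of any pair whose
similarity reaches 0.9999, in a single chronological greedy pass.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .database import ReferenceDatabase
from .errors import ValidationError
from .search import search
from .similarity import KernelConfig

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScoreConfig:
    """Scoring thresholds and the kernel they are evaluated with.

    n_top:
        depth of the hit lists entering MNS and MAS (default 10).
    theta_novel:
        MNS at/above which a sample is novel (default 0.15).
    theta_mas:
        MAS at/above which a sample has high attention (default 14).
    theta_connect:
        minimum similarity for a connection to count toward MAS (0.85).
    theta_dedup:
        similarity at/above which two samples are duplicates (0.9999).
    exclude_same_study_from_pool:
        alternative reading of the same-study rule: besides same-study
        connections not counting toward MAS, same-study samples are removed
        from each observer's top-n pool. Default off.
    """

    n_top: int = 10
    theta_novel: float = 0.15
    theta_mas: float = 14.0
    theta_connect: float = 0.85
    theta_dedup: float = 0.9999
    kernel: KernelConfig = field(default_factory=KernelConfig)
    exclude_same_study_from_pool: bool = False

    def __post_init__(self) -> None:
        if self.n_top < 2:
            raise ValidationError(f"n_top must be >= 2, got {self.n_top}")
        for name in ("theta_novel", "theta_connect", "theta_dedup"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if self.theta_mas < 0:
            raise ValidationError(f"theta_mas must be >= 0, got {self.theta_mas}")


@dataclass
class ScorePanel:
    """Per-sample score record: MNS at birth, current MAS, and the flags."""

    sample_id: str
    mns: float
    mas: float
    mfi: float
    is_novel: bool
    is_high_attention: bool
    is_focus: bool


# ----------------------------------------------------------------------
# MNS
# ----------------------------------------------------------------------

def mns_from_similarities(similarities, n_top: int = 10) -> float:
    """Evaluate the novelty formula on a descending list of similarities.

    Fewer than ``n_top`` matches are padded with similarity 0 (an empty
    eligible database is maximally novel, MNS = 1).
    """
    if n_top < 2:
        raise ValidationError(f"n_top must be >= 2, got {n_top}")
    sims = sorted((float(s) for s in similarities), reverse=True)[:n_top]
    sims += [0.0] * (n_top - len(sims))
    weights = np.arange(n_top - 1, -1, -1, dtype=float)  # (n-1, ..., 1, 0)
    return float(1.0 - (np.asarray(sims) * weights).sum() / weights.sum())


def mns(
    query,
    db: ReferenceDatabase,
    config: ScoreConfig = ScoreConfig(),
    max_year: int | None = None,
    exhaustive: bool = True,
) -> float:
    """Novelty of one query against the (optionally year-restricted) database.

    ``max_year`` defaults to the query's birth year minus one — novelty is
    always judged against what existed before the sample.
    """
    if max_year is None and getattr(query, "year", None) is not None:
        max_year = query.year - 1
    exclude = {query.sample_id} if getattr(query, "sample_id", None) in db else set()
    hits = search(
        query,
        db,
        k=config.n_top,
        exhaustive=exhaustive,
        max_year=max_year,
        exclude_ids=exclude,
        config=config.kernel,
    )
    return mns_from_similarities([s for _, s in hits.hits], config.n_top)


# ----------------------------------------------------------------------
# MAS
# ----------------------------------------------------------------------

def _top_n_indices(row: np.ndarray, self_idx: int, n_top: int, id_rank: np.ndarray) -> np.ndarray:
    """Indices of the n_top largest entries of `row`, ties by ascending id."""
    scored = row.copy()
    scored[self_idx] = -np.inf
    order = np.lexsort((id_rank, -scored))
    return order[: min(n_top, len(order) - 1)]


def _mas_from_matrix(
    sims: np.ndarray,
    studies: list[str],
    ids: list[str],
    n_top: int,
    theta_connect: float,
    exclude_same_study_from_pool: bool = False,
) -> np.ndarray:
    """Accumulate MAS for every sample from an all-pairs similarity matrix."""
    n = len(ids)
    id_rank = np.argsort(np.argsort(np.array(ids, dtype=object)))
    studies_arr = np.array(studies, dtype=object)
    mas = np.zeros(n)
    for i in range(n):
        row = sims[i].copy()
        row[i] = -np.inf
        if exclude_same_study_from_pool:
            row[studies_arr == studies_arr[i]] = -np.inf
        top = np.lexsort((id_rank, -row))[:n_top]
        for j in top:
            s = row[j]
            if s >= theta_connect and studies_arr[j] != studies_arr[i]:
                mas[j] += s
    return mas


def mas_panel(
    db: ReferenceDatabase,
    config: ScoreConfig = ScoreConfig(),
    max_year: int | None = None,
    method: str = "exhaustive",
) -> pd.Series:
    """MAS for every sample of the (optionally year-restricted) database.

    ``method="exhaustive"`` ranks each observer's top-n from the all-pairs
    similarity matrix; ``"indexed"`` runs a two-tier search per observer and
    accumulates the same connectivity rule from those hit lists.
    """
    meta = db.metadata
    if max_year is not None:
        keep = list(meta.index[meta["year"].notna() & (meta["year"] <= max_year)])
    else:
        keep = list(meta.index)
    out = pd.Series(0.0, index=pd.Index(keep, name="sample_id"), name="mas")
    if len(keep) < 2:
        return out

    studies = [str(meta.at[s, "study_id"]) for s in keep]
    if method == "exhaustive":
        sub = db.subset(keep) if len(keep) < db.n_samples else db
        sims = sub.similarity_matrix(config.kernel)
        values = _mas_from_matrix(
            sims, studies, keep, config.n_top, config.theta_connect,
            config.exclude_same_study_from_pool,
        )
        out[:] = values
        return out
    if method != "indexed":
        raise ValidationError(f"unknown MAS method {method!r}")

    study_of = dict(zip(keep, studies))
    for sid in keep:
        exclude = (
            {s for s in keep if study_of[s] == study_of[sid]} - {sid}
            if config.exclude_same_study_from_pool
            else set()
        )
        hits = search(
            db.vector(sid),
            db,
            k=config.n_top,
            exhaustive=False,
            max_year=max_year,
            exclude_ids={sid} | exclude,
            config=config.kernel,
        )
        for other, s in hits.hits:
            if other in out.index and s >= config.theta_connect and study_of.get(other) != study_of[sid]:
                out[other] += s
    return out


def mas(
    sample_id: str,
    db: ReferenceDatabase,
    config: ScoreConfig = ScoreConfig(),
    max_year: int | None = None,
    method: str = "exhaustive",
) -> float:
    """MAS of one repository sample (defined only over the repository)."""
    if sample_id not in db:
        raise ValidationError(f"sample {sample_id!r} is not in the database; MAS is undefined")
    panel = mas_panel(db, config, max_year=max_year, method=method)
    return float(panel.get(sample_id, 0.0))


# ----------------------------------------------------------------------
# Panel and classification
# ----------------------------------------------------------------------

def score_panel(
    db: ReferenceDatabase,
    config: ScoreConfig = ScoreConfig(),
    method: str = "exhaustive",
) -> list[ScorePanel]:
    """MNS at birth, current MAS, MFI and flags for every sample.

    Samples without a year are scored against the whole database minus
    themselves (they cannot enter temporal analyses anyway).
    """
    meta = db.metadata
    ids = db.sample_ids
    mas_values = mas_panel(db, config, max_year=None, method=method)

    mns_values: dict[str, float] = {}
    if method == "exhaustive":
        sims = db.similarity_matrix(config.kernel)
        pos = {sid: i for i, sid in enumerate(ids)}
        years = meta["year"]
        for sid in ids:
            year = years.at[sid]
            if pd.isna(year):
                eligible = [s for s in ids if s != sid]
            else:
                eligible = list(meta.index[years.notna() & (years <= int(year) - 1)])
            row = sims[pos[sid]]
            top = sorted((float(row[pos[s]]) for s in eligible), reverse=True)[: config.n_top]
            mns_values[sid] = mns_from_similarities(top, config.n_top)
    else:
        for sid in ids:
            year = meta.at[sid, "year"]
            max_year = None if pd.isna(year) else int(year) - 1
            hits = search(
                db.vector(sid),
                db,
                k=config.n_top,
                exhaustive=False,
                max_year=max_year,
                exclude_ids={sid},
                config=config.kernel,
            )
            mns_values[sid] = mns_from_similarities([s for _, s in hits.hits], config.n_top)

    panels = []
    for sid in ids:
        m_n = mns_values[sid]
        m_a = float(mas_values.get(sid, 0.0))
        novel = m_n >= config.theta_novel
        attended = m_a >= config.theta_mas
        panels.append(
            ScorePanel(
                sample_id=sid,
                mns=m_n,
                mas=m_a,
                mfi=m_n * m_a,
                is_novel=novel,
                is_high_attention=attended,
                is_focus=novel and attended,
            )
        )
    return panels


def panel_frame(panels: list[ScorePanel], metadata: pd.DataFrame | None = None) -> pd.DataFrame:
    """Tabulate panels (optionally joined with sample metadata)."""
    frame = pd.DataFrame([vars(p) for p in panels]).set_index("sample_id")
    if metadata is not None:
        frame = frame.join(metadata)
    return frame


def mas_quantile_threshold(mas_values, q: float = 0.20) -> float:
    """The MAS value marking the top fraction `q` of most-attended samples.

    Uses the 'higher' interpolation so that at least a fraction q of samples
    sit at or above the returned threshold.
    """
    values = np.asarray(pd.Series(mas_values).to_numpy(), dtype=float)
    if values.size == 0:
        raise ValidationError("cannot take a quantile of an empty MAS distribution")
    if not (0.0 < q < 1.0):
        raise ValidationError(f"q must be in (0, 1), got {q}")
    return float(np.quantile(values, 1.0 - q, method="higher"))


# ----------------------------------------------------------------------
# Deduplication
# ----------------------------------------------------------------------

def deduplicate(
    db: ReferenceDatabase, config: ScoreConfig = ScoreConfig()
) -> tuple[list[str], list[tuple[str, str, float]]]:
    """Greedy chronological near-duplicate removal.

    Samples are visited oldest first (full date when present, else year;
    ties by ascending id). A newcomer whose best similarity against the
    already-kept set reaches ``theta_dedup`` is dropped — the later-dated
    member of every duplicate pair — and the pair is recorded as
    (kept_id, dropped_id, similarity).
    """
    meta = db.metadata

    def chrono_key(sid: str) -> tuple[str, str]:
        date = meta.at[sid, "date"]
        year = meta.at[sid, "year"]
        if not pd.isna(date):
            stamp = str(date)
        elif not pd.isna(year):
            stamp = f"{int(year):04d}-12-31"
        else:
            stamp = "9999-12-31"
        return (stamp, sid)

    order = sorted(db.sample_ids, key=chrono_key)
    sims = db.similarity_matrix(config.kernel)
    pos = {sid: i for i, sid in enumerate(db.sample_ids)}

    kept: list[str] = []
    kept_pos: list[int] = []
    dropped: list[tuple[str, str, float]] = []
    for sid in order:
        i = pos[sid]
        if kept_pos:
            against = sims[i, kept_pos]
            best = int(np.argmax(against))
            if against[best] >= config.theta_dedup:
                dropped.append((kept[best], sid, float(against[best])))
                continue
        kept.append(sid)
        kept_pos.append(i)
    kept_in_db_order = [sid for sid in db.sample_ids if sid in set(kept)]
    if dropped:
        logger.info("deduplicate: dropped %d of %d samples", len(dropped), db.n_samples)
    return kept_in_db_order, dropped
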