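"""Seeded, ground-truth-labelled synthetic microbiome corpora.

The generator emulates the structure of a public 16S repository at desk
scale: a reference phylogeny whose phyla are monophyletic clades,
habitat-structured communities drawn from Dirichlet archetypes, one study
per (habitat, year), timestamps spanning several years, planted
near-duplicates, and — the interesting part — an *emergent* habitat that is
novel when it first appears and is then resampled heavily ("followed") in
later years, next to an *orphan* habitat that appears once and is never
resampled. The emergent pioneers are the planted sleeping beauties; the
orphans are the never-followed novel controls.

Everything is driven by one :class:`numpy.random.Generator` seed and all
serialization uses shortest-round-trip float formatting, so outputs are
byte-identical across runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

from .errors import ValidationError
from .phylogeny import PhylogenyView
from .profiles import MicrobiomeProfile

_BRANCH_MEAN = 0.5  # exponential mean for simulated branch lengths


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic corpus.

    Defaults give ~840 samples over 8 years: 5 established habitats sampled
    20x/year, a 5-sample emergent pioneer cohort in 2016 hit by a tapering
    wave of follow-up studies afterwards, a 5-sample orphan cohort never
    resampled, 5 planted near-duplicates, and 2% of established samples
    failing sequencing QC.

    The emergent pioneers sit essentially at their archetype's centre
    (``pioneer_concentration_factor``) while their followers scatter around
    it (``follower_concentration_factor``), so every follower is closer to
    each pioneer than to any fellow follower and ranks all pioneers at the
    top of its hit list: the planted attention per pioneer is then the
    follower count times ~0.95, uniform across pioneers. The follow-up wave
    tapers geometrically (``follow_up_decay``), mirroring how organically
    accrued attention saturates after a discovery.
    """

    n_leaves: int = 200
    n_habitats: int = 5
    years: tuple[int, int] = (2010, 2017)
    samples_per_habitat_per_year: int = 20
    dirichlet_concentration: float = 50.0
    emergent_habitat_year: int = 2016
    emergent_cohort_size: int = 5
    follow_up_per_year: int = 13  # first-year wave size
    follow_up_decay: float = 2.0 / 13.0  # geometric taper of later waves
    pioneer_concentration_factor: float = 1000.0
    follower_concentration_factor: float = 4.0
    orphan_cohort_size: int = 5
    n_planted_duplicates: int = 5
    qc_fail_fraction: float = 0.02
    support_fraction: float = 0.30  # leaves per habitat archetype
    overlap_fraction: float = 0.10  # support shared between neighbour habitats
    rank_abundance_scale: float = 2.0  # e-folding of archetype rank abundances
    single_study_per_habitat: bool = False  # collapse a habitat into one study
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.years
        if hi < lo:
            raise ValidationError(f"invalid year range {self.years}")
        if not (lo <= self.emergent_habitat_year <= hi):
            raise ValidationError("emergent_habitat_year must fall inside the year range")
        for name in ("n_leaves", "n_habitats", "samples_per_habitat_per_year"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be positive")
        if self.dirichlet_concentration <= 0:
            raise ValidationError("dirichlet_concentration must be > 0")

    def follow_up_count(self, offset: int) -> int:
        """Followers arriving `offset` years after the emergent cohort."""
        return int(round(self.follow_up_per_year * self.follow_up_decay ** (offset - 1)))


@dataclass
class GroundTruth:
    """What the generator planted, for recovery tests.

    ``expected_focus`` are the emergent pioneers (followed afterwards);
    ``never_followed_novel`` the orphan cohort; both are expected novel.
    """

    habitat_of: dict[str, str]
    archetype_of: dict[str, str]
    expected_novel: list[str]
    expected_focus: list[str]
    never_followed_novel: list[str]
    duplicate_pairs: list[tuple[str, str]]
    qc_fail: list[str]

    def to_json(self) -> str:
        payload = asdict(self)
        payload["expected_novel"] = sorted(self.expected_novel)
        payload["expected_focus"] = sorted(self.expected_focus)
        payload["never_followed_novel"] = sorted(self.never_followed_novel)
        payload["duplicate_pairs"] = sorted(map(list, self.duplicate_pairs))
        payload["qc_fail"] = sorted(self.qc_fail)
        return json.dumps(payload, indent=1, sort_keys=True)


@dataclass
class SimulatedDataset:
    """A generated corpus: profiles + the inputs a database build consumes."""

    profiles: list[MicrobiomeProfile]
    phylogeny: PhylogenyView
    metadata: pd.DataFrame
    truth: GroundTruth
    config: SimulationConfig

    def table(self) -> pd.DataFrame:
        """Samples x taxa relative-abundance DataFrame (canonical leaf order)."""
        rows = {
            p.sample_id: [p.abundances.get(t, 0.0) for t in self.phylogeny.leaf_order]
            for p in self.profiles
        }
        frame = pd.DataFrame.from_dict(rows, orient="index", columns=self.phylogeny.leaf_order)
        frame.index.name = "sample_id"
        return frame

    def write(self, directory) -> None:
        """Write table.tsv, tree.nwk, lineages.tsv, metadata.tsv, truth.json."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        table = self.table()
        with open(directory / "table.tsv", "w") as fh:
            fh.write("sample_id\t" + "\t".join(table.columns) + "\n")
            for sid, row in zip(table.index, table.to_numpy()):
                fh.write(sid + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")
        with open(directory / "tree.nwk", "w") as fh:
            fh.write(self.phylogeny.to_newick())
        with open(directory / "lineages.tsv", "w") as fh:
            fh.write("taxon_id\tlineage\n")
            for name in self.phylogeny.leaf_order:
                fh.write(f"{name}\t{self.phylogeny.lineages[name]}\n")
        meta = self.metadata.reset_index()
        with open(directory / "metadata.tsv", "w") as fh:
            fh.write("\t".join(meta.columns) + "\n")
            for row in meta.itertuples(index=False):
                cells = []
                for v in row:
                    if isinstance(v, float) and not float(v).is_integer():
                        cells.append(repr(v))
                    elif pd.isna(v):
                        cells.append("")
                    else:
                        cells.append(str(int(v)) if isinstance(v, float) else str(v))
                fh.write("\t".join(cells) + "\n")
        with open(directory / "truth.json", "w") as fh:
            fh.write(self.truth.to_json())
            fh.write("\n")


# ----------------------------------------------------------------------
# Tree simulation
# ----------------------------------------------------------------------

def _pure_birth_topology(labels: list[str], rng: np.random.Generator) -> TreeNode:
    """Forward pure-birth (Yule) topology over the given tip labels."""
    tips = [TreeNode(name=labels[0])]
    for label in labels[1:]:
        victim = tips[int(rng.integers(len(tips)))]
        left = TreeNode(name=victim.name)
        right = TreeNode(name=label)
        victim.name = None
        victim.extend([left, right])
        tips.remove(victim)
        tips.extend([left, right])
    return tips[0].root()


def simulate_tree(
    n_leaves: int, seed: int, n_phyla: int = 8, genus_size: int = 5
) -> PhylogenyView:
    """A random reference phylogeny with clade-consistent lineages.

    Phyla are monophyletic blocks (a pure-birth subtree each, joined on a
    pure-birth backbone); genera are consecutive post-order blocks of up to
    `genus_size` leaves within a phylum. Branch lengths are exponential
    with mean 0.5.
    """
    if n_leaves < 2:
        raise ValidationError(f"n_leaves must be >= 2, got {n_leaves}")
    rng = np.random.default_rng(seed)
    n_phyla = max(1, min(n_phyla, n_leaves // 2 if n_leaves >= 4 else n_leaves))
    width = len(str(n_leaves))
    labels = [f"otu{i + 1:0{width}d}" for i in range(n_leaves)]
    sizes = [n_leaves // n_phyla] * n_phyla
    for i in range(n_leaves % n_phyla):
        sizes[i] += 1

    subtrees, lineages = [], {}
    start = 0
    for p, size in enumerate(sizes):
        block = labels[start : start + size]
        start += size
        phylum = f"P{p + 1:02d}"
        sub = (
            _pure_birth_topology(block, rng)
            if size > 1
            else TreeNode(name=block[0])
        )
        subtrees.append(sub)
        ordered = [t.name for t in sub.tips()] if size > 1 else block
        for g, chunk_start in enumerate(range(0, size, genus_size)):
            genus = f"{phylum}_G{g + 1:02d}"
            for leaf in ordered[chunk_start : chunk_start + genus_size]:
                lineages[leaf] = (
                    f"k__Bacteria;p__{phylum};c__{phylum}_c;o__{phylum}_o;"
                    f"f__{genus}_f;g__{genus}"
                )

    if len(subtrees) == 1:
        tree = subtrees[0]
    else:
        backbone = _pure_birth_topology([f"__phylum{i}" for i in range(n_phyla)], rng)
        anchor = {t.name: t for t in backbone.tips()}
        for i, sub in enumerate(subtrees):
            slot = anchor[f"__phylum{i}"]
            if sub.is_tip():
                slot.name = sub.name
            else:
                slot.name = None
                slot.extend(sub.children[:])
        tree = backbone

    for node in tree.postorder(include_self=True):
        node.length = None if node.is_root() else float(rng.exponential(_BRANCH_MEAN))
    return PhylogenyView(tree, lineages)


# ----------------------------------------------------------------------
# Corpus simulation
# ----------------------------------------------------------------------

def _archetype(
    n_leaves: int, start: int, width: int, scale: float
) -> np.ndarray:
    """Sparse archetype: exponential rank-abundance on a circular window."""
    weights = np.zeros(n_leaves)
    ranks = np.arange(width, dtype=float)
    profile = np.exp(-ranks / scale)
    for j in range(width):
        weights[(start + j) % n_leaves] += profile[j]
    return weights / weights.sum()


def _draw_sample(
    rng: np.random.Generator, archetype: np.ndarray, concentration: float
) -> np.ndarray:
    support = archetype > 0
    alpha = concentration * archetype[support]
    out = np.zeros_like(archetype)
    out[support] = rng.dirichlet(alpha)
    return out


def simulate_database(config: SimulationConfig = SimulationConfig()) -> SimulatedDataset:
    """Generate the full habitat-structured, time-stamped corpus."""
    rng = np.random.default_rng(config.seed)
    phylo = simulate_tree(config.n_leaves, seed=int(rng.integers(2**31)))
    L = config.n_leaves
    first_year, last_year = config.years

    width = max(1, round(config.support_fraction * L))
    overlap = round(config.overlap_fraction * width)
    step = max(1, width - overlap)

    archetypes: dict[str, np.ndarray] = {}
    for h in range(config.n_habitats):
        archetypes[f"habitat_{h + 1:02d}"] = _archetype(
            L, h * step, width, config.rank_abundance_scale
        )
    # emergent and orphan archetypes sit on windows offset half a step from
    # the established grid, so their dominant taxa are minor everywhere else
    archetypes["emergent"] = _archetype(
        L, config.n_habitats * step + step // 2, width, config.rank_abundance_scale
    )
    archetypes["orphan"] = _archetype(
        L, (config.n_habitats + 1) * step + step // 2, width, config.rank_abundance_scale
    )

    profiles: list[MicrobiomeProfile] = []
    habitat_of: dict[str, str] = {}
    archetype_of: dict[str, str] = {}
    qc_fail: list[str] = []
    counter = 0

    def new_id() -> str:
        nonlocal counter
        counter += 1
        return f"S{counter:05d}"

    def emit(
        habitat: str,
        archetype: str,
        year: int,
        study: str,
        fail_qc: bool = False,
        concentration: float | None = None,
    ) -> str:
        sid = new_id()
        vec = _draw_sample(
            rng,
            archetypes[archetype],
            config.dirichlet_concentration if concentration is None else concentration,
        )
        month = int(rng.integers(1, 13))
        day = int(rng.integers(1, 29))
        if fail_qc:
            flip_reads = bool(rng.integers(2))
            read_count = int(rng.integers(50, 500)) if flip_reads else int(rng.integers(5000, 50000))
            mapping_rate = (
                round(float(rng.uniform(0.85, 0.99)), 4)
                if flip_reads
                else round(float(rng.uniform(0.50, 0.79)), 4)
            )
            qc_fail.append(sid)
        else:
            read_count = int(rng.integers(5000, 50000))
            mapping_rate = round(float(rng.uniform(0.85, 0.99)), 4)
        profiles.append(
            MicrobiomeProfile(
                sample_id=sid,
                abundances={
                    phylo.leaf_order[i]: float(v) for i, v in enumerate(vec) if v > 0
                },
                study_id=study,
                habitat=habitat,
                year=year,
                date=f"{year}-{month:02d}-{day:02d}",
                read_count=read_count,
                mapping_rate=mapping_rate,
            )
        )
        habitat_of[sid] = habitat
        archetype_of[sid] = archetype
        return sid

    # established habitats, every year
    for year in range(first_year, last_year + 1):
        for h in range(config.n_habitats):
            habitat = f"habitat_{h + 1:02d}"
            study = (
                f"study_{habitat}" if config.single_study_per_habitat else f"study_{habitat}_{year}"
            )
            for _ in range(config.samples_per_habitat_per_year):
                fail = bool(rng.random() < config.qc_fail_fraction)
                emit(habitat, habitat, year, study, fail_qc=fail)

    # emergent habitat: tight pioneer cohort, then a tapering follow-up wave
    e_year = config.emergent_habitat_year
    conc = config.dirichlet_concentration
    pioneers = [
        emit(
            "emergent", "emergent", e_year, f"study_emergent_{e_year}",
            concentration=conc * config.pioneer_concentration_factor,
        )
        for _ in range(config.emergent_cohort_size)
    ]
    for year in range(e_year + 1, last_year + 1):
        for j in range(config.follow_up_count(year - e_year)):
            emit(
                "emergent", "emergent", year, f"study_follow_{year}_{j + 1:02d}",
                concentration=conc * config.follower_concentration_factor,
            )

    # orphan habitat: one cohort, never resampled
    orphans = [
        emit("orphan", "orphan", e_year, f"study_orphan_{e_year}")
        for _ in range(config.orphan_cohort_size)
    ]

    # planted near-duplicates: copy an earlier sample, perturb <= 1e-6, later date
    duplicate_pairs: list[tuple[str, str]] = []
    fail_set = set(qc_fail)
    eligible = [
        p
        for p in profiles
        if p.year is not None and p.year < last_year and p.sample_id not in fail_set
    ]
    n_dups = min(config.n_planted_duplicates, len(eligible))
    chosen = rng.choice(len(eligible), size=n_dups, replace=False) if n_dups else []
    for idx in sorted(int(i) for i in np.atleast_1d(chosen)):
        original = eligible[idx]
        vec = np.array([original.abundances.get(t, 0.0) for t in phylo.leaf_order])
        vec = vec * (1.0 + rng.uniform(-1e-7, 1e-7, size=vec.size))
        vec = vec / vec.sum()
        sid = new_id()
        year = original.year + 1
        profiles.append(
            MicrobiomeProfile(
                sample_id=sid,
                abundances={
                    phylo.leaf_order[i]: float(v) for i, v in enumerate(vec) if v > 0
                },
                study_id=f"study_dup_{sid}",
                habitat=original.habitat,
                year=year,
                date=f"{year}-06-15",
                read_count=int(rng.integers(5000, 50000)),
                mapping_rate=round(float(rng.uniform(0.85, 0.99)), 4),
            )
        )
        habitat_of[sid] = original.habitat
        archetype_of[sid] = archetype_of[original.sample_id]
        duplicate_pairs.append((original.sample_id, sid))

    metadata = pd.DataFrame(
        [
            {
                "sample_id": p.sample_id,
                "study_id": p.study_id,
                "habitat": p.habitat,
                "year": p.year,
                "date": p.date,
                "read_count": p.read_count,
                "mapping_rate": p.mapping_rate,
            }
            for p in profiles
        ]
    ).set_index("sample_id")

    truth = GroundTruth(
        habitat_of=habitat_of,
        archetype_of=archetype_of,
        expected_novel=pioneers + orphans,
        expected_focus=pioneers,
        never_followed_novel=orphans,
        duplicate_pairs=duplicate_pairs,
        qc_fail=qc_fail,
    )
    return SimulatedDataset(profiles, phylo, metadata, truth, config)


# ----------------------------------------------------------------------
# Hand-checkable worked example
# ----------------------------------------------------------------------

def worked_example_fixture() -> tuple[list[MicrobiomeProfile], PhylogenyView, dict]:
    """A tiny fixed database with exact, hand-computable similarities.

    Four leaves on a balanced tree with unit branch lengths; profiles cover
    the identity pair, the two-disjoint-leaves pair (phylogenetic similarity
    exp(-1) at decay rate 1), and a pair whose taxon-overlap similarity is
    exactly 0.85 (the attention-connectivity boundary).
    """
    newick = "((leafA:1.0,leafB:1.0)ab:1.0,(leafC:1.0,leafD:1.0)cd:1.0)root;"
    lineages = {
        "leafA": "k__Bacteria;p__P01;g__P01_G01",
        "leafB": "k__Bacteria;p__P01;g__P01_G01",
        "leafC": "k__Bacteria;p__P02;g__P02_G01",
        "leafD": "k__Bacteria;p__P02;g__P02_G01",
    }
    phylo = PhylogenyView.from_newick(newick, lineages)

    def prof(sid, abundances, year, study):
        return MicrobiomeProfile(
            sample_id=sid,
            abundances=abundances,
            study_id=study,
            habitat="toy",
            year=year,
            date=f"{year}-01-15",
            read_count=1000,
            mapping_rate=0.95,
        )

    profiles = [
        prof("ex01", {"leafA": 1.0}, 2010, "study_t1"),
        prof("ex02", {"leafB": 1.0}, 2010, "study_t2"),  # disjoint sibling leaves
        prof("ex03", {"leafA": 0.5, "leafC": 0.5}, 2011, "study_t3"),
        prof("ex04", {"leafA": 0.5, "leafC": 0.5}, 2012, "study_t4"),  # identical to ex03
        prof("ex05", {"leafA": 0.7, "leafC": 0.3}, 2011, "study_t5"),
        prof("ex06", {"leafA": 0.55, "leafC": 0.45}, 2012, "study_t6"),  # overlap(ex05, ex06)=0.85
    ]
    expected = {
        ("ex01", "ex02"): {"phylogenetic": float(np.exp(-1.0)), "taxon-overlap": 0.0},
        ("ex03", "ex04"): {"phylogenetic": 1.0, "taxon-overlap": 1.0},
        ("ex05", "ex06"): {"taxon-overlap": 0.85},
    }
    return profiles, phylo, expected
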