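"""Predicting future attention: trajectories, the hybrid model, beauties.

A novel sample's attention trajectory is its MAS recomputed against the
database as it stood 1, 2, 3 and 4 years after the sample's birth. Dividing
by the trajectory maximum gives per-offset attention ratios in [0, 1]. Two
components are fitted on historical cohorts:

* ``Reg_i`` — the expected maximum-MAS ratio at offset i, from an OLS
  regression of ratio on offset pooled over all training trajectories
  (floored at 0.05 so the estimator below cannot blow up, capped at 1);
* ``RF_i`` — normalized random-forest importances of the per-offset ratios
  in discriminating focus from nonfocus samples.

The maximum future MAS of a young sample with observed offsets 1..Y is then

    MAS_max = sum_i (MAS_i * RF_i / Reg_i) / sum_i RF_i ,

an importance-weighted average of per-offset extrapolations. "Sleeping
beauties" are novel samples still below the attention threshold whose
estimated maximum MAS reaches it.

The fitted component follows the Model/Results convention: build a
:class:`HybridAttentionModel` from trajectories and labels, call ``fit()``,
and read estimates and diagnostics off the returned
:class:`HybridAttentionResults` (or print ``summary()``).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, cross_val_score

from .database import ReferenceDatabase
from .errors import ValidationError
from .scores import ScoreConfig, ScorePanel, mas_panel, score_panel

logger = logging.getLogger(__name__)

DEFAULT_HORIZON = 4


@dataclass
class AttentionTrajectory:
    """Yearly MAS values of one sample after its birth.

    ``mas_by_offset[i]`` is the MAS computed with the database restricted to
    ``year <= birth_year + i``. Ratios divide by the trajectory maximum,
    with 0/0 defined as 0 (a never-followed sample has an all-zero
    trajectory and carries no regression information).
    """

    sample_id: str
    birth_year: int
    mas_by_offset: dict[int, float]

    @property
    def max_mas(self) -> float:
        return max(self.mas_by_offset.values()) if self.mas_by_offset else 0.0

    @property
    def ratios(self) -> dict[int, float]:
        top = self.max_mas
        if top <= 0:
            return {i: 0.0 for i in self.mas_by_offset}
        return {i: v / top for i, v in self.mas_by_offset.items()}

    def observed_offsets(self) -> list[int]:
        return sorted(self.mas_by_offset)


def trajectories(
    db: ReferenceDatabase,
    config: ScoreConfig = ScoreConfig(),
    horizon: int = DEFAULT_HORIZON,
    panels: list[ScorePanel] | None = None,
    birth_years: tuple[int, int] | None = None,
    max_db_year: int | None = None,
    method: str = "exhaustive",
) -> list[AttentionTrajectory]:
    """Attention trajectories for every sample that was novel at birth.

    ``birth_years`` restricts to a (first, last) cohort range. With
    ``max_db_year`` set, offsets whose cutoff lies beyond it are treated as
    not yet observable and omitted (the sleeping-beauty path); without it,
    every offset is computed and a cutoff past the newest sample simply
    covers the whole database (the training path).
    """
    if horizon < 1:
        raise ValidationError(f"horizon must be >= 1, got {horizon}")
    if panels is None:
        panels = score_panel(db, config, method=method)
    novel = {p.sample_id for p in panels if p.is_novel}
    meta = db.metadata
    tracked: list[tuple[str, int]] = []
    for sid in db.sample_ids:
        if sid not in novel or pd.isna(meta.at[sid, "year"]):
            continue
        year = int(meta.at[sid, "year"])
        if birth_years is not None and not (birth_years[0] <= year <= birth_years[1]):
            continue
        tracked.append((sid, year))
    if not tracked:
        return []

    cutoffs = sorted(
        {
            y + i
            for _, y in tracked
            for i in range(1, horizon + 1)
            if max_db_year is None or y + i <= max_db_year
        }
    )
    panel_by_cutoff = {c: mas_panel(db, config, max_year=c, method=method) for c in cutoffs}

    out = []
    for sid, year in tracked:
        series: dict[int, float] = {}
        for i in range(1, horizon + 1):
            cutoff = year + i
            if max_db_year is not None and cutoff > max_db_year:
                continue
            series[i] = float(panel_by_cutoff[cutoff].get(sid, 0.0))
        out.append(AttentionTrajectory(sample_id=sid, birth_year=year, mas_by_offset=series))
    return out


def awakening_year(traj: AttentionTrajectory, theta_mas: float) -> int | None:
    """First offset at which the trajectory reaches the attention threshold."""
    for i in traj.observed_offsets():
        if traj.mas_by_offset[i] >= theta_mas:
            return i
    return None


# ----------------------------------------------------------------------
# The hybrid regression / random-forest model
# ----------------------------------------------------------------------

@dataclass
class HybridAttentionResults:
    """Fitted hybrid model: regression curve, RF importances, diagnostics."""

    reg: dict[int, float]
    rf_importance: dict[int, float]
    rf_accuracy: float
    horizon: int
    theta_mas: float
    n_trajectories: int
    n_focus: int
    seed: int | None = None
    reg_coefficients: tuple[float, float] = (0.0, 0.0)  # (intercept, slope)

    # -- estimation ----------------------------------------------------
    def predict_max_mas(self, partial: AttentionTrajectory) -> float:
        """Estimated maximum future MAS from the observed offsets only."""
        observed = [i for i in partial.observed_offsets() if i in self.rf_importance]
        if not observed:
            raise ValidationError(
                f"trajectory of {partial.sample_id!r} has no observed offsets within the model horizon"
            )
        rf_sum = sum(self.rf_importance[i] for i in observed)
        if rf_sum <= 0:
            raise ValidationError("sum of RF importances over observed offsets is zero")
        total = sum(
            partial.mas_by_offset[i] * self.rf_importance[i] / self.reg[i] for i in observed
        )
        return float(total / rf_sum)

    def summary(self) -> str:
        lines = [
            "Hybrid attention model (OLS ratio curve x RF importances)",
            "=" * 58,
            f"training trajectories: {self.n_trajectories} ({self.n_focus} focus)",
            f"attention threshold (MAS): {self.theta_mas}",
            f"ratio curve: {self.reg_coefficients[0]:.4f} + {self.reg_coefficients[1]:.4f} * offset",
            f"cross-validated RF accuracy: {self.rf_accuracy:.4f}",
            "",
            "offset   Reg_i    RF_i",
        ]
        for i in sorted(self.reg):
            lines.append(f"{i:>6}   {self.reg[i]:.4f}   {self.rf_importance[i]:.4f}")
        return "\n".join(lines)

    # -- serialization ---------------------------------------------------
    def to_json(self) -> str:
        payload = {
            "reg": {str(k): v for k, v in self.reg.items()},
            "rf_importance": {str(k): v for k, v in self.rf_importance.items()},
            "rf_accuracy": self.rf_accuracy,
            "horizon": self.horizon,
            "theta_mas": self.theta_mas,
            "n_trajectories": self.n_trajectories,
            "n_focus": self.n_focus,
            "seed": self.seed,
            "reg_coefficients": list(self.reg_coefficients),
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "HybridAttentionResults":
        d = json.loads(text)
        return cls(
            reg={int(k): v for k, v in d["reg"].items()},
            rf_importance={int(k): v for k, v in d["rf_importance"].items()},
            rf_accuracy=d["rf_accuracy"],
            horizon=d["horizon"],
            theta_mas=d["theta_mas"],
            n_trajectories=d["n_trajectories"],
            n_focus=d["n_focus"],
            seed=d.get("seed"),
            reg_coefficients=tuple(d.get("reg_coefficients", (0.0, 0.0))),
        )


class HybridAttentionModel:
    """Unfitted hybrid model over training trajectories and focus labels.

    Parameters
    ----------
    trajectories:
        training :class:`AttentionTrajectory` list with full horizon
        coverage; all-zero trajectories are excluded from the regression
        (they carry no shape information) but kept for the classifier.
    labels:
        boolean focus labels, aligned with `trajectories`.
    use_ratios:
        train the classifier on max-normalized ratios (default) or raw MAS.
    """

    def __init__(
        self,
        trajectories: list[AttentionTrajectory],
        labels,
        horizon: int = DEFAULT_HORIZON,
        theta_mas: float = 14.0,
        use_ratios: bool = True,
    ):
        labels = [bool(x) for x in labels]
        if len(labels) != len(trajectories):
            raise ValidationError("labels and trajectories must align")
        complete = [
            (t, y)
            for t, y in zip(trajectories, labels)
            if set(range(1, horizon + 1)) <= set(t.mas_by_offset)
        ]
        if not complete:
            raise ValidationError("no trajectory has full horizon coverage")
        self.trajectories = [t for t, _ in complete]
        self.labels = np.array([y for _, y in complete], dtype=bool)
        if self.labels.all() or (~self.labels).all():
            raise ValidationError("need both focus and nonfocus samples to fit")
        self.horizon = horizon
        self.theta_mas = theta_mas
        self.use_ratios = use_ratios

    def _features(self) -> np.ndarray:
        rows = []
        for t in self.trajectories:
            src = t.ratios if self.use_ratios else t.mas_by_offset
            rows.append([src[i] for i in range(1, self.horizon + 1)])
        return np.array(rows)

    def fit(
        self,
        seed: int | None = 0,
        n_trees: int = 500,
        reg_floor: float = 0.05,
        cv_folds: int = 5,
    ) -> HybridAttentionResults:
        offsets = np.arange(1, self.horizon + 1)

        # regression component: pooled OLS of ratio on offset
        xs, ys = [], []
        for t in self.trajectories:
            if t.max_mas <= 0:
                continue
            for i in offsets:
                xs.append(i)
                ys.append(t.ratios[i])
        if not xs:
            raise ValidationError("all training trajectories are zero; cannot fit the ratio curve")
        slope, intercept = np.polyfit(xs, ys, 1)
        reg = {int(i): float(np.clip(intercept + slope * i, reg_floor, 1.0)) for i in offsets}

        # random-forest component on the per-offset features
        features = self._features()
        forest = RandomForestClassifier(n_estimators=n_trees, random_state=seed, n_jobs=1)
        class_sizes = [int(self.labels.sum()), int((~self.labels).sum())]
        folds = max(2, min(cv_folds, min(class_sizes)))
        cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        accuracy = float(cross_val_score(forest, features, self.labels, cv=cv).mean())
        forest.fit(features, self.labels)
        importances = forest.feature_importances_
        total = importances.sum()
        importances = importances / total if total > 0 else np.full(self.horizon, 1.0 / self.horizon)

        return HybridAttentionResults(
            reg=reg,
            rf_importance={int(i): float(w) for i, w in zip(offsets, importances)},
            rf_accuracy=accuracy,
            horizon=self.horizon,
            theta_mas=self.theta_mas,
            n_trajectories=len(self.trajectories),
            n_focus=int(self.labels.sum()),
            seed=seed,
            reg_coefficients=(float(intercept), float(slope)),
        )


def focus_labels(trajs: list[AttentionTrajectory], theta_mas: float = 14.0) -> list[bool]:
    """A trajectory is focus-labelled once its MAS ever reached the threshold."""
    return [t.max_mas >= theta_mas for t in trajs]


def fit_hybrid(
    trajs: list[AttentionTrajectory],
    labels,
    seed: int | None = 0,
    horizon: int = DEFAULT_HORIZON,
    theta_mas: float = 14.0,
    use_ratios: bool = True,
) -> HybridAttentionResults:
    """Convenience wrapper: construct the model and fit in one call."""
    return HybridAttentionModel(
        trajs, labels, horizon=horizon, theta_mas=theta_mas, use_ratios=use_ratios
    ).fit(seed=seed)


def predict_max_mas(model: HybridAttentionResults, partial: AttentionTrajectory) -> float:
    return model.predict_max_mas(partial)


def sleeping_beauties(
    db: ReferenceDatabase,
    model: HybridAttentionResults,
    config: ScoreConfig = ScoreConfig(),
    panels: list[ScorePanel] | None = None,
    birth_years: tuple[int, int] | None = None,
    method: str = "exhaustive",
) -> list[str]:
    """Novel samples still below the MAS threshold whose estimated maximum
    future MAS reaches it.

    ``birth_years`` selects the prediction cohorts (samples born after the
    model's training window); candidates need at least one observed offset.
    """
    if panels is None:
        panels = score_panel(db, config, method=method)
    panel_by_id = {p.sample_id: p for p in panels}
    meta = db.metadata
    years = meta["year"].dropna()
    max_db_year = int(years.max()) if len(years) else None
    trajs = trajectories(
        db,
        config,
        horizon=model.horizon,
        panels=panels,
        birth_years=birth_years,
        max_db_year=max_db_year,
        method=method,
    )
    beauties = []
    for traj in trajs:
        record = panel_by_id[traj.sample_id]
        if record.mas >= config.theta_mas:  # already awake
            continue
        observed = [i for i in traj.observed_offsets() if i in model.rf_importance]
        if not observed:
            continue
        if model.predict_max_mas(traj) >= config.theta_mas:
            beauties.append(traj.sample_id)
    return sorted(beauties)


@dataclass
class DiscriminationReport:
    """Cross-validated accuracy plus a 2-component PCA projection."""

    accuracy: float
    projection: np.ndarray = field(repr=False)
    explained_variance: tuple[float, float] = (0.0, 0.0)


def discrimination_report(
    trajs: list[AttentionTrajectory],
    labels,
    seed: int | None = 0,
    horizon: int = DEFAULT_HORIZON,
    use_ratios: bool = True,
) -> DiscriminationReport:
    """How separable are focus and nonfocus trajectories?

    Returns the stratified cross-validated random-forest accuracy and a
    2-component principal-component projection of the per-offset features
    for plotting.
    """
    model = HybridAttentionModel(trajs, labels, horizon=horizon, use_ratios=use_ratios)
    fitted = model.fit(seed=seed)
    features = model._features()
    pca = PCA(n_components=2, random_state=seed)
    projection = pca.fit_transform(features)
    return DiscriminationReport(
        accuracy=fitted.rf_accuracy,
        projection=projection,
        explained_variance=tuple(float(v) for v in pca.explained_variance_ratio_),
    )
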