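"""Weighted methylation indices, the epigenetic clock, and drug-use classification.

Each index is a weighted sum over selected cytosine sites,

    index score = sum_i beta_i * M_i,

where M_i is the methylation level at site i **in percent** and beta_i comes
from the per-site test that selected the site: the log fold change between
brain areas (BA index), the covariate-adjusted log odds ratio of drug use (DU
index), or the age slope in percent per year (Age index). The epigenetic
clock regresses chronological age on the Age-index score by ordinary least
squares; age acceleration is predicted minus chronological age. The drug-use
rule calls a sample positive when its DU score exceeds the control mean plus
1.96 control standard deviations (sample SD, n-1 denominator) — one-sided
97.5% specificity under a Gaussian null.

The three estimators (:class:`BrainAreaIndex`, :class:`MethylationClock`,
:class:`DrugUseClassifier`) follow scikit-learn conventions: parameters in
``__init__``, fitted attributes with trailing underscores, ``get_params`` /
``set_params``, and ``transform`` / ``predict`` / ``decision_function`` for
scoring new samples. The module-level functions are the thin procedural layer
they are built from.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, RegressorMixin
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from .core import MethylationMatrix
from .stats import (
    SiteTestResult,
    mann_whitney,
    select_sites,
    test_sites_age,
    test_sites_logistic,
    test_sites_paired_wilcoxon,
)

__all__ = [
    "IndexModel",
    "ClockModel",
    "ClassifierEval",
    "build_index",
    "score_samples",
    "fit_clock",
    "age_acceleration",
    "acceleration_contrast",
    "du_threshold",
    "evaluate_classifier",
    "roc_auc",
    "venn_overlap",
    "BrainAreaIndex",
    "MethylationClock",
    "DrugUseClassifier",
]

KIND_TO_TEST = {
    "BA": "log_fold_change",
    "DU": "log_odds_ratio",
    "Age": "age_slope",
}


@dataclass(frozen=True)
class IndexModel:
    """A set of selected cytosine sites with per-site weights.

    ``kind`` fixes the weight provenance: BA weights are log fold changes,
    DU weights log odds ratios, Age weights age slopes.
    """

    kind: str
    entries: tuple[tuple[tuple[int, str], float], ...]
    selection_alpha: float
    area: str | None = None

    def __post_init__(self):
        if self.kind not in KIND_TO_TEST:
            raise ValueError(f"kind must be one of {sorted(KIND_TO_TEST)}")
        seen = set()
        for site, weight in self.entries:
            if not np.isfinite(weight) or weight == 0:
                raise ValueError(f"weight at site {site} must be finite and nonzero")
            if site in seen:
                raise ValueError(f"duplicate site {site}")
            seen.add(site)

    @property
    def test_kind(self) -> str:
        return KIND_TO_TEST[self.kind]

    @property
    def sites(self) -> list[tuple[int, str]]:
        return [site for site, _ in self.entries]

    @property
    def weights(self) -> np.ndarray:
        return np.array([w for _, w in self.entries])

    def __len__(self) -> int:
        return len(self.entries)

    def to_json(self) -> str:
        return json.dumps(
            {
                "kind": self.kind,
                "selection_alpha": self.selection_alpha,
                "area": self.area,
                "entries": [[pos, strand, w] for (pos, strand), w in self.entries],
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "IndexModel":
        d = json.loads(text)
        return cls(
            kind=d["kind"],
            entries=tuple(((int(p), s), float(w)) for p, s, w in d["entries"]),
            selection_alpha=float(d["selection_alpha"]),
            area=d.get("area"),
        )


@dataclass(frozen=True)
class ClockModel:
    """Linear map from Age-index score to predicted age.

    ``predicted age = intercept + coefficient * score``; ``r_squared`` is the
    squared Pearson correlation of age and score on the training controls.
    """

    intercept: float
    coefficient: float
    r_squared: float
    p_value: float
    training_ids: tuple[str, ...] = ()

    def predict(self, scores) -> np.ndarray:
        return self.intercept + self.coefficient * np.asarray(scores, dtype=float)

    def to_json(self) -> str:
        return json.dumps(
            {
                "intercept": self.intercept,
                "coefficient": self.coefficient,
                "r_squared": self.r_squared,
                "p_value": self.p_value,
                "training_ids": list(self.training_ids),
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "ClockModel":
        d = json.loads(text)
        return cls(
            intercept=float(d["intercept"]),
            coefficient=float(d["coefficient"]),
            r_squared=float(d["r_squared"]),
            p_value=float(d["p_value"]),
            training_ids=tuple(d.get("training_ids", ())),
        )


@dataclass
class ClassifierEval:
    """Confusion-matrix summary and ROC of a thresholded score classifier.

    PPV/NPV are None when their denominator (positive or negative calls) is
    empty.
    """

    threshold: float
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    ppv: float | None
    npv: float | None
    roc_points: pd.DataFrame | None = None
    auc: float | None = None

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
            "auc": self.auc,
        }


def build_index(
    selected_results: Sequence[SiteTestResult],
    kind: str,
    selection_alpha: float = 0.05,
    area: str | None = None,
) -> IndexModel:
    """Assemble an index from selected per-site results, weights verbatim."""
    if kind not in KIND_TO_TEST:
        raise ValueError(f"kind must be one of {sorted(KIND_TO_TEST)}")
    if len(selected_results) == 0:
        raise ValueError(
            f"no sites selected for the {kind} index; consider a looser selection alpha"
        )
    expected = KIND_TO_TEST[kind]
    kinds = {r.test_kind for r in selected_results}
    if kinds != {expected}:
        raise ValueError(f"{kind} index needs test_kind {expected!r}, got {sorted(kinds)}")
    entries = tuple((r.site, float(r.effect)) for r in selected_results)
    return IndexModel(kind=kind, entries=entries, selection_alpha=selection_alpha, area=area)


def _levels_of(matrix) -> pd.DataFrame:
    return matrix.levels if isinstance(matrix, MethylationMatrix) else matrix


def score_samples(index: IndexModel, matrix) -> pd.Series:
    """Per-sample index scores: sum of weight x methylation level (percent)."""
    levels = _levels_of(matrix)
    missing = [s for s in index.sites if s not in levels.columns]
    if missing:
        raise KeyError(f"index sites missing from matrix: {missing[:10]}")
    grid = levels[index.sites].to_numpy(dtype=float)
    return pd.Series(grid @ index.weights, index=levels.index, name=f"{index.kind}_index")


def fit_clock(ages: Sequence[float], scores: Sequence[float], sample_ids=()) -> ClockModel:
    """Ordinary least squares of chronological age on the Age-index score."""
    ages = np.asarray(ages, dtype=float)
    scores_arr = np.asarray(scores, dtype=float)
    if ages.size != scores_arr.size:
        raise ValueError("ages and scores must be aligned")
    if ages.size < 8:
        raise ValueError("need at least 8 training samples")
    if np.ptp(scores_arr) == 0:
        raise ValueError("scores are constant; the clock is undefined")
    from scipy import stats as sps

    fit = sps.linregress(scores_arr, ages)
    return ClockModel(
        intercept=float(fit.intercept),
        coefficient=float(fit.slope),
        r_squared=float(fit.rvalue**2),
        p_value=float(fit.pvalue),
        training_ids=tuple(sample_ids),
    )


def age_acceleration(clock: ClockModel, scores: pd.Series, ages: Sequence[float]) -> pd.Series:
    """Predicted age minus chronological age, per sample."""
    predicted = clock.predict(scores.to_numpy(dtype=float))
    accel = predicted - np.asarray(ages, dtype=float)
    return pd.Series(accel, index=scores.index, name="age_acceleration")


def acceleration_contrast(
    acceleration: pd.Series,
    groups: pd.Series,
    heroin: pd.Series,
    drug_mask: pd.Series | None = None,
) -> dict:
    """Drug-vs-control contrast of age acceleration, heroin users excluded.

    Heroin has a reported rejuvenating rather than accelerating effect, so
    heroin-positive individuals are left out of the contrast. ``drug_mask``
    optionally restricts the drug side to a subgroup (e.g. ketamine only).
    Returns the median acceleration difference and the Mann-Whitney P.
    """
    keep = ~heroin.reindex(acceleration.index).astype(bool)
    accel = acceleration[keep]
    grp = groups.reindex(accel.index)
    control = accel[grp == "control"]
    drug = accel[grp == "drug"]
    if drug_mask is not None:
        drug = drug[drug_mask.reindex(drug.index).astype(bool)]
    if len(drug) == 0 or len(control) == 0:
        raise ValueError("both contrast groups must be non-empty")
    u, p = mann_whitney(drug.to_numpy(), control.to_numpy())
    return {
        "n_control": int(len(control)),
        "n_drug": int(len(drug)),
        "median_control": float(np.median(control)),
        "median_drug": float(np.median(drug)),
        "median_shift": float(np.median(drug) - np.median(control)),
        "mann_whitney_U": u,
        "p_value": p,
    }


def du_threshold(control_scores: Sequence[float], z: float = 1.96) -> float:
    """Decision threshold: control mean + z x control sample SD (n-1)."""
    scores_arr = np.asarray(control_scores, dtype=float)
    if scores_arr.size < 2:
        raise ValueError("need at least 2 control scores")
    return float(scores_arr.mean() + z * scores_arr.std(ddof=1))


def evaluate_classifier(
    scores: Sequence[float],
    labels: Sequence,
    threshold: float,
    positive_label="drug",
) -> ClassifierEval:
    """Confusion-matrix evaluation of the strict score > threshold rule.

    Ties at the threshold are negative calls, preserving the one-sided
    specificity interpretation of the 1.96-SD rule.
    """
    scores_arr = np.asarray(scores, dtype=float)
    y = np.asarray(labels) == positive_label
    if y.all() or not y.any():
        raise ValueError("both labels must be present")
    call = scores_arr > threshold
    tp = int(np.sum(call & y))
    fp = int(np.sum(call & ~y))
    tn = int(np.sum(~call & ~y))
    fn = int(np.sum(~call & y))
    return ClassifierEval(
        threshold=float(threshold),
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        sensitivity=tp / (tp + fn),
        specificity=tn / (tn + fp),
        ppv=tp / (tp + fp) if tp + fp else None,
        npv=tn / (tn + fn) if tn + fn else None,
    )


def roc_auc(
    scores: Sequence[float], labels: Sequence, positive_label="drug"
) -> tuple[pd.DataFrame, float]:
    """ROC over all distinct score thresholds and the trapezoidal AUC.

    Tied scores collapse to single ROC vertices, so the trapezoidal area
    equals the Mann-Whitney statistic U/(n1*n2) with ties counted one half.
    """
    y = (np.asarray(labels) == positive_label).astype(int)
    if y.min() == y.max():
        raise ValueError("both labels must be present")
    fpr, tpr, thresholds = _sk_roc_curve(y, np.asarray(scores, dtype=float))
    points = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thresholds})
    return points, float(_sk_auc(fpr, tpr))


def venn_overlap(models: Mapping[str, IndexModel]) -> dict:
    """Exclusive intersection-cell counts over the site sets of several indices.

    Returns a dict with one entry per non-empty combination of model names
    (keys are '&'-joined sorted name tuples) giving the number of sites that
    appear in exactly that set of models — the cells of a Venn diagram — plus
    ``shared_by_2_or_more``, the total count of sites in at least two models.
    """
    if len(models) < 2:
        raise ValueError("need at least 2 index models")
    site_sets = {name: set(m.sites) for name, m in models.items()}
    universe = set().union(*site_sets.values())
    cells: dict[str, int] = {}
    shared = 0
    for site in universe:
        members = tuple(sorted(name for name, s in site_sets.items() if site in s))
        key = "&".join(members)
        cells[key] = cells.get(key, 0) + 1
        if len(members) >= 2:
            shared += 1
    cells["shared_by_2_or_more"] = shared
    return cells


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

class BrainAreaIndex(BaseEstimator):
    """Brain-area methylation index (NAcc vs PFC contrast).

    Fits on paired level grids from the two areas (rows aligned by
    individual): each shared site is tested with the paired Wilcoxon
    signed-rank test, sites with P < ``alpha`` are selected, and their natural
    log fold change (area A mean over area B mean) becomes the site weight.
    ``transform`` scores any level grid with the frozen weights.

    Parameters
    ----------
    alpha : float
        Raw per-site selection threshold (no multiplicity adjustment).
    pseudocount : float
        Percent-scale pseudocount protecting the fold change at zero means.
    """

    def __init__(self, alpha: float = 0.05, pseudocount: float = 0.01):
        self.alpha = alpha
        self.pseudocount = pseudocount

    def fit(self, levels_a, levels_b) -> "BrainAreaIndex":
        levels_a = _levels_of(levels_a)
        levels_b = _levels_of(levels_b)
        self.results_ = test_sites_paired_wilcoxon(levels_a, levels_b, self.pseudocount)
        selected = select_sites(self.results_, self.alpha)
        self.index_ = build_index(selected, "BA", self.alpha, area="paired")
        self.n_sites_ = len(self.index_)
        return self

    def transform(self, levels) -> pd.Series:
        return score_samples(self.index_, levels)


class MethylationClock(BaseEstimator, RegressorMixin):
    """Epigenetic clock on an age-weighted methylation index.

    ``fit`` selects sites whose levels associate with chronological age
    (linear model with optional forensic covariates, P < ``alpha``), weights
    them by their age slope, scores the training samples, and regresses age on
    the score by OLS. ``predict`` returns predicted ages; ``acceleration`` is
    predicted minus chronological age. Train on controls only and score drug
    users with the frozen model.
    """

    def __init__(self, alpha: float = 0.05):
        self.alpha = alpha

    def fit(self, X, y, covariates: pd.DataFrame | None = None) -> "MethylationClock":
        levels = _levels_of(X)
        ages = np.asarray(y, dtype=float)
        self.results_ = test_sites_age(levels, ages, covariates)
        selected = select_sites(self.results_, self.alpha)
        self.index_ = build_index(selected, "Age", self.alpha)
        scores = score_samples(self.index_, levels)
        self.clock_ = fit_clock(ages, scores, sample_ids=levels.index)
        self.intercept_ = self.clock_.intercept
        self.coef_ = self.clock_.coefficient
        self.r_squared_ = self.clock_.r_squared
        self.n_sites_ = len(self.index_)
        return self

    def transform(self, X) -> pd.Series:
        return score_samples(self.index_, _levels_of(X))

    def predict(self, X) -> np.ndarray:
        return self.clock_.predict(self.transform(X).to_numpy())

    def acceleration(self, X, ages) -> pd.Series:
        return age_acceleration(self.clock_, self.transform(X), ages)


class DrugUseClassifier(BaseEstimator, ClassifierMixin):
    """Threshold classifier on the drug-use methylation index.

    ``fit`` runs a covariate-adjusted logistic regression of group on
    methylation at every site, selects sites with Wald P < ``alpha``, weights
    them by their log odds ratio, and sets the decision threshold at the
    control-score mean plus ``z`` control standard deviations. ``predict``
    applies the strict score > threshold rule; ``decision_function`` returns
    the score margin over the threshold so ROC analysis sees the full sweep.
    """

    def __init__(self, alpha: float = 0.05, z: float = 1.96, positive_label="drug"):
        self.alpha = alpha
        self.z = z
        self.positive_label = positive_label

    def fit(self, X, y, covariates: pd.DataFrame | None = None) -> "DrugUseClassifier":
        levels = _levels_of(X)
        y = np.asarray(y)
        self.results_ = test_sites_logistic(levels, y, covariates)
        selected = select_sites(self.results_, self.alpha)
        self.index_ = build_index(selected, "DU", self.alpha)
        scores = score_samples(self.index_, levels)
        control_scores = scores.to_numpy()[y != self.positive_label]
        self.threshold_ = du_threshold(control_scores, self.z)
        neg = np.unique(y[y != self.positive_label])
        self.classes_ = np.concatenate([neg[:1], [self.positive_label]])
        self.n_sites_ = len(self.index_)
        return self

    def transform(self, X) -> pd.Series:
        return score_samples(self.index_, _levels_of(X))

    def decision_function(self, X) -> np.ndarray:
        return self.transform(X).to_numpy() - self.threshold_

    def predict(self, X) -> np.ndarray:
        positive = self.decision_function(X) > 0
        return np.where(positive, self.classes_[1], self.classes_[0])

    def evaluate(self, X, y) -> ClassifierEval:
        """Confusion counts at the fitted threshold plus the full ROC/AUC."""
        scores = self.transform(X)
        ev = evaluate_classifier(scores, y, self.threshold_, self.positive_label)
        ev.roc_points, ev.auc = roc_auc(scores, y, self.positive_label)
        return ev
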