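"""Exhaustive (classifier family × gene subset) search under LOOCV.

This is the pipeline's engine.  Every candidate model is a pair of a
classifier family — logistic regression, Gaussian naive Bayes,
k-nearest neighbours, linear-margin SVM, or RBF-kernel SVM — and an
ordered gene subset.  Each pair is scored by leave-one-out
cross-validation: for every held-out sample the remaining samples are
balanced by synthetic minority oversampling, optionally standardized
(scaler fitted on the training fold only, so the held-out sample never
leaks into it), the classifier is fitted, and the held-out sample is
predicted once.  The n predictions aggregate into a single confusion
matrix per model, from which the full metric suite is derived.

Minority oversampling follows the classic SMOTE interpolation scheme:
each synthetic point is ``x + u * (x' - x)`` with ``u ~ Uniform(0, 1)``,
``x`` a minority-class training point and ``x'`` one of its 5 nearest
minority neighbours (Euclidean distance on the raw, unstandardized
features); the neighbour count drops to ``minority - 1`` when the
minority class is smaller than 6, and degenerates to duplication when
it has a single member.  Oversampling precedes standardization.

Randomness is confined to the oversampling: a single integer seed
drives a counter-based substream per LOOCV fold
(``default_rng([seed, fold_index])``), so serial and parallel fold
execution produce bit-identical results, and repeated runs that vary
only the seed isolate the oversampling variability — the quantity the
repeated-run stability summary measures.

Hyperparameters are fixed, not tuned: logistic regression with L2
penalty, C=1.0, intercept, 1000-iteration budget; Gaussian naive Bayes
with variance floor 1e-9 times the largest feature variance; KNN with
k=5, Euclidean, uniform votes; linear SVM with C=1.0; RBF SVM with
C=1.0 and gamma = 1 / (d * Var(training features)).  Features are
standardized for all families except naive Bayes, whose per-feature
variances already absorb scale.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .containers import ExpressionMatrix, SampleAnnotation, two_group_view
from .exceptions import ConfigError, DataError
from .metrics import METRIC_NAMES, ConfusionCounts, MetricSuite, compute_metrics

FAMILIES = (
    "logistic_regression",
    "naive_bayes",
    "knn",
    "linear_svm",
    "rbf_svm",
)

_FAMILY_DEFAULTS: dict[str, dict] = {
    "logistic_regression": {"C": 1.0, "max_iter": 1000},
    "naive_bayes": {"var_smoothing": 1e-9},
    "knn": {"n_neighbors": 5},
    "linear_svm": {"C": 1.0},
    "rbf_svm": {"C": 1.0, "gamma": "scale"},
}

#: Panel sizes above this need an explicit opt-in: the full enumeration
#: over five families grows as 5 * (2^p - p - 1) LOOCV evaluations.
DEFAULT_PANEL_CAP = 12
HARD_PANEL_CAP = 18


@dataclass(frozen=True)
class ModelSpec:
    """A (classifier family, gene subset) pair with fixed hyperparameters."""

    family: str
    genes: tuple[str, ...]
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ConfigError(f"unknown family {self.family!r}; expected one of {FAMILIES}")
        if len(self.genes) < 2:
            raise ConfigError("a model needs at least 2 genes")
        if len(set(self.genes)) != len(self.genes):
            raise ConfigError("duplicate genes in subset")

    @property
    def standardize(self) -> bool:
        # naive Bayes models per-feature variances directly; all margin-
        # and distance-based families need centred unit-variance features
        return self.family != "naive_bayes"

    def estimator(self):
        params = {**_FAMILY_DEFAULTS[self.family], **self.hyperparameters}
        if self.family == "logistic_regression":
            return LogisticRegression(**params)
        if self.family == "naive_bayes":
            return GaussianNB(**params)
        if self.family == "knn":
            return KNeighborsClassifier(**params)
        if self.family == "linear_svm":
            return SVC(kernel="linear", **params)
        return SVC(kernel="rbf", **params)


@dataclass(frozen=True)
class LeaderboardEntry:
    spec: ModelSpec
    counts: ConfusionCounts
    metrics: MetricSuite
    seed: int


def smote_balance(
    x: np.ndarray, y: np.ndarray, rng: np.random.Generator, k_neighbors: int = 5
) -> tuple[np.ndarray, np.ndarray]:
    """Oversample the minority class to parity by synthetic interpolation.

    Returns the augmented ``(x, y)``; already-balanced input is returned
    unchanged.  Interpolation happens on the raw feature scale.
    """
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise DataError("single-class training set")
    if n_pos == n_neg:
        return x, y
    minority = 1 if n_pos < n_neg else 0
    need = abs(n_neg - n_pos)
    xm = x[y == minority]
    m = xm.shape[0]
    if m == 1:
        synth = np.repeat(xm, need, axis=0)
    else:
        k = min(k_neighbors, m - 1)
        d = cdist(xm, xm)
        np.fill_diagonal(d, np.inf)
        nn = np.argsort(d, axis=1, kind="stable")[:, :k]  # per-point neighbours
        base = rng.integers(m, size=need)
        pick = rng.integers(k, size=need)
        u = rng.uniform(size=need)
        neigh = nn[base, pick]
        synth = xm[base] + u[:, None] * (xm[neigh] - xm[base])
    x_aug = np.vstack([x, synth])
    y_aug = np.concatenate([y, np.full(need, minority, dtype=y.dtype)])
    return x_aug, y_aug


def loocv_evaluate(
    matrix: ExpressionMatrix,
    ann: SampleAnnotation,
    spec: ModelSpec,
    seed: int = 0,
    fold_hook: Callable[[int, dict], None] | None = None,
) -> LeaderboardEntry:
    """Score one model by leave-one-out cross-validation.

    Aggregates the n single-sample predictions into one confusion
    matrix (positive class = disease/progression).  ``fold_hook``, when
    given, receives ``(fold_index, info)`` with the post-oversampling
    class counts and fitted scaler parameters — an instrumentation
    surface for leakage and class-parity checks.

    Fully reproducible given ``seed``; the seed feeds only the
    oversampling substreams.
    """
    sub, y = two_group_view(matrix.subset_genes(spec.genes), ann)
    x = sub.df.to_numpy().T  # samples x genes
    n = x.shape[0]

    tp = fp = tn = fn = 0
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        x_tr, y_tr = x[mask], y[mask]
        if y_tr.min(initial=1) == y_tr.max(initial=0):
            raise DataError("fold with single-class training set")
        rng = np.random.default_rng([seed, i])
        x_tr, y_tr = smote_balance(x_tr, y_tr, rng)

        x_test = x[i : i + 1]
        mean = sd = None
        if spec.standardize:
            mean = x_tr.mean(axis=0)
            sd = x_tr.std(axis=0)
            sd = np.where(sd == 0, 1.0, sd)
            x_tr = (x_tr - mean) / sd
            x_test = (x_test - mean) / sd

        clf = spec.estimator()
        clf.fit(x_tr, y_tr)
        pred = int(clf.predict(x_test)[0])

        if fold_hook is not None:
            fold_hook(
                i,
                {
                    "n_pos_train": int(y_tr.sum()),
                    "n_neg_train": int(y_tr.size - y_tr.sum()),
                    "scaler_mean": None if mean is None else mean.copy(),
                    "scaler_sd": None if sd is None else sd.copy(),
                    "prediction": pred,
                    "truth": int(y[i]),
                },
            )

        if y[i] == 1:
            tp += pred
            fn += 1 - pred
        else:
            fp += pred
            tn += 1 - pred

    counts = ConfusionCounts(tp, fp, tn, fn)
    return LeaderboardEntry(spec=spec, counts=counts, metrics=compute_metrics(counts), seed=seed)


def _subset_count(p: int, k_min: int, k_max: int) -> int:
    return sum(math.comb(p, k) for k in range(k_min, k_max + 1))


def enumerate_search(
    matrix: ExpressionMatrix,
    ann: SampleAnnotation,
    panel: Sequence[str],
    k_range: tuple[int, int] | None = None,
    families: Sequence[str] = FAMILIES,
    seed: int = 0,
    allow_large: bool = False,
) -> list[LeaderboardEntry]:
    """Evaluate every (family, subset) pair over the panel.

    Subsets run from ``k_range[0]`` (default 2) up to ``k_range[1]``
    (default the full panel).  Ordering is deterministic: families in
    the given order, then subsets by size and lexicographic position
    within the panel's order.  Panels above 12 genes require
    ``allow_large=True`` (the combination count is part of the error);
    panels above 18 are refused outright.
    """
    panel = list(panel)
    if len(set(panel)) != len(panel):
        raise ConfigError("duplicate genes in panel")
    unknown = [f for f in families if f not in FAMILIES]
    if unknown:
        raise ConfigError(f"unknown families {unknown}")
    k_min, k_max = k_range if k_range is not None else (2, len(panel))
    if not 2 <= k_min <= k_max <= len(panel):
        raise ConfigError(f"invalid k_range ({k_min}, {k_max}) for panel of {len(panel)}")
    if len(panel) > HARD_PANEL_CAP:
        raise ConfigError(f"panel of {len(panel)} exceeds the hard cap of {HARD_PANEL_CAP}")
    n_subsets = _subset_count(len(panel), k_min, k_max)
    if len(panel) > DEFAULT_PANEL_CAP and not allow_large:
        raise ConfigError(
            f"panel of {len(panel)} genes implies {n_subsets} subsets per family "
            f"({n_subsets * len(families)} LOOCV evaluations); pass allow_large=True "
            "to confirm"
        )

    entries: list[LeaderboardEntry] = []
    for family in families:
        for k in range(k_min, k_max + 1):
            for combo in itertools.combinations(panel, k):
                spec = ModelSpec(family=family, genes=combo)
                entries.append(loocv_evaluate(matrix, ann, spec, seed=seed))
    return entries


def best_by_metric(
    entries: Sequence[LeaderboardEntry], metric: str
) -> tuple[float, list[LeaderboardEntry], dict[str, int]]:
    """Maximum of one metric, the entries attaining it, per-family tallies."""
    if not entries:
        raise DataError("empty leaderboard")
    if metric not in METRIC_NAMES:
        raise DataError(f"unknown metric {metric!r}; expected one of {METRIC_NAMES}")
    values = [e.metrics[metric] for e in entries]
    finite = [v for v in values if not math.isnan(v)]
    if not finite:
        raise DataError(f"metric {metric!r} undefined for every entry")
    best = max(finite)
    winners = [e for e, v in zip(entries, values) if v == best]
    tally: dict[str, int] = {}
    for e in winners:
        tally[e.spec.family] = tally.get(e.spec.family, 0) + 1
    return best, winners, tally


@dataclass
class PanelReport:
    """Per-gene frequency among qualifying models, and the selected set."""

    frame: pd.DataFrame  # index: gene; columns: frequency, selected
    f1_min: float
    freq_cutoff: float
    n_qualifying: int

    @property
    def selected(self) -> list[str]:
        return list(self.frame.index[self.frame["selected"]])


def consensus_genes(
    entries: Sequence[LeaderboardEntry],
    f1_min: float = 0.96,
    freq_cutoff: float = 0.5,
) -> PanelReport:
    """Frequency-based gene consensus over high-F1 models.

    Restricts to entries with F1 > ``f1_min``, computes each gene's
    share of those models' subsets, and selects genes at or above
    ``freq_cutoff`` (default 50%).
    """
    qualifying = [
        e for e in entries if not math.isnan(e.metrics.f1) and e.metrics.f1 > f1_min
    ]
    if not qualifying:
        raise DataError(f"no leaderboard entry has F1 > {f1_min}")
    counts: dict[str, int] = {}
    for e in qualifying:
        for g in e.spec.genes:
            counts[g] = counts.get(g, 0) + 1
    freq = pd.Series(counts, dtype=float).sort_index() / len(qualifying)
    freq = freq.sort_values(ascending=False, kind="stable")
    frame = pd.DataFrame({"frequency": freq, "selected": freq >= freq_cutoff})
    frame.index.name = "gene_id"
    return PanelReport(
        frame=frame, f1_min=f1_min, freq_cutoff=freq_cutoff, n_qualifying=len(qualifying)
    )


@dataclass
class RepeatedRunSummary:
    """Across-run mean and SD per metric, plus the mean confusion matrix."""

    metric_mean: dict[str, float]
    metric_sd: dict[str, float]
    mean_counts: ConfusionCounts
    n_runs: int


def repeated_runs(
    matrix: ExpressionMatrix,
    ann: SampleAnnotation,
    spec: ModelSpec,
    n_runs: int = 100,
    base_seed: int = 0,
) -> RepeatedRunSummary:
    """Stability of one model across oversampling random states.

    Runs LOOCV with seeds ``base_seed .. base_seed + n_runs - 1`` (the
    seed varies only the oversampling) and reports per-metric mean and
    sample SD plus the mean confusion counts.
    """
    if n_runs < 2:
        raise ConfigError("n_runs must be >= 2")
    per_metric: dict[str, list[float]] = {m: [] for m in METRIC_NAMES}
    counts_acc = np.zeros(4)
    for r in range(n_runs):
        entry = loocv_evaluate(matrix, ann, spec, seed=base_seed + r)
        for m in METRIC_NAMES:
            per_metric[m].append(entry.metrics[m])
        counts_acc += [entry.counts.tp, entry.counts.fp, entry.counts.tn, entry.counts.fn]
    mean = {m: float(np.mean(v)) for m, v in per_metric.items()}
    sd = {m: float(np.std(v, ddof=1)) for m, v in per_metric.items()}
    counts_acc /= n_runs
    return RepeatedRunSummary(
        metric_mean=mean,
        metric_sd=sd,
        mean_counts=ConfusionCounts(*counts_acc),
        n_runs=n_runs,
    )


def decremental_ablation(
    matrix: ExpressionMatrix,
    ann: SampleAnnotation,
    family: str,
    panel: Sequence[str],
    seed: int = 0,
    subset_cap: int = 200,
) -> pd.DataFrame:
    """Median ± SD of every metric as the panel shrinks from full to 2.

    For each subset size k (descending) all C(|panel|, k) subsets are
    evaluated, or a seeded uniform sample of ``subset_cap`` of them when
    the count exceeds the cap.  Returns a table indexed by k with
    ``<metric>_median``, ``<metric>_sd`` and ``n_subsets`` columns.
    """
    panel = list(panel)
    if len(panel) < 3:
        raise ConfigError("ablation needs a panel of at least 3 genes")
    if subset_cap < 1:
        raise ConfigError("subset_cap must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for k in range(len(panel), 1, -1):
        combos = list(itertools.combinations(panel, k))
        if len(combos) > subset_cap:
            idx = rng.choice(len(combos), size=subset_cap, replace=False)
            combos = [combos[i] for i in sorted(idx)]
        values: dict[str, list[float]] = {m: [] for m in METRIC_NAMES}
        for combo in combos:
            entry = loocv_evaluate(
                matrix, ann, ModelSpec(family=family, genes=combo), seed=seed
            )
            for m in METRIC_NAMES:
                values[m].append(entry.metrics[m])
        row: dict[str, float] = {"k": k, "n_subsets": len(combos)}
        for m in METRIC_NAMES:
            row[f"{m}_median"] = float(np.median(values[m]))
            row[f"{m}_sd"] = float(np.std(values[m], ddof=1)) if len(combos) > 1 else 0.0
        rows.append(row)
    out = pd.DataFrame(rows).set_index("k")
    return out
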