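"""Noise-controlled variable-importance screening across ordered skill classes.

The screening question is whether a variable helps separate players from two
leagues.  Adjacent leagues overlap heavily, so each classification task pairs
leagues two steps apart (Bronze-Gold, Silver-Platinum, Gold-Diamond,
Platinum-Masters, Diamond-Professional), plus one contrastive extreme pair
(Bronze-Professional).  For each task the procedure repeats 25 times:

1. draw 70% of the task's rows without replacement;
2. append a fresh pseudo-variable of pure Uniform(0,1) noise (``control``);
3. fit a bagged forest of decision trees (1000 trees, 5 candidate features
   per split) and record out-of-bag accuracy;
4. record each variable's out-of-bag permutation importance.

The 95th percentile of the control variable's 25 importance values is the
critical value: a variable is flagged as relevant when its median importance
exceeds it.  Variables are ranked by descending median importance.  This
controls each variable's false-flag rate at roughly the 5% level but makes
no family-wise correction — it is a screening rule, not a confirmatory test.

The forest is a bagging ensemble of CART trees with per-tree out-of-bag
permutation importance (mean decrease in OOB accuracy).  The forest layer is
deliberately small and pluggable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import logging

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier

from .pac_features import FEATURE_NAMES
from .telemetry_io import LEAGUE_NAMES

__all__ = [
    "ScreeningConfig",
    "PairTask",
    "TaskResult",
    "ScreeningResult",
    "make_pair_tasks",
    "majority_baseline",
    "subsample_rows",
    "inject_control",
    "SubsampleForest",
    "fit_forest",
    "permutation_importance",
    "run_screening",
    "rank_matrix",
    "flag_matrix",
    "result_to_json",
]

logger = logging.getLogger(__name__)

CONTROL_NAME = "control"


@dataclass(frozen=True)
class ScreeningConfig:
    n_trees: int = 1000
    mtry: int = 5
    n_reps: int = 25
    subsample_frac: float = 0.70
    control_percentile: float = 95.0
    league_spacing: int = 2
    include_extreme_pair: bool = True
    balanced_n: int | None = None
    stratify: bool = False
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.subsample_frac <= 1:
            raise ValueError("subsample_frac must be in (0, 1]")
        if not 1 <= self.mtry <= len(FEATURE_NAMES) + 1:
            raise ValueError("mtry must be between 1 and n_features + 1")
        if self.n_trees < 1 or self.n_reps < 1 or self.league_spacing < 1:
            raise ValueError("n_trees, n_reps and league_spacing must be >= 1")


@dataclass(frozen=True)
class PairTask:
    league_lo: int
    league_hi: int

    @property
    def name(self) -> str:
        return f"{LEAGUE_NAMES[self.league_lo]}-{LEAGUE_NAMES[self.league_hi]}"


def make_pair_tasks(leagues_present, cfg: ScreeningConfig | None = None) -> list[PairTask]:
    """Enumerate the two-league classification tasks.

    Pairs every league with the one ``league_spacing`` above it (both must be
    present), ordered by the lower league, then appends the extreme
    (lowest, highest) contrastive pair if requested and not already present.
    """
    cfg = cfg or ScreeningConfig()
    present = sorted(set(int(v) for v in leagues_present))
    if any(not 1 <= v <= 7 for v in present):
        raise ValueError("leagues must lie in 1..7")
    tasks = [
        PairTask(lo, lo + cfg.league_spacing)
        for lo in present
        if lo + cfg.league_spacing in present
    ]
    if cfg.include_extreme_pair and len(present) >= 2:
        extreme = PairTask(present[0], present[-1])
        if extreme not in tasks:
            tasks.append(extreme)
    if not tasks:
        raise ValueError("no league pair can be formed from the leagues present")
    return tasks


def majority_baseline(n_lo: int, n_hi: int) -> float:
    """Accuracy of always guessing the more common class."""
    if n_lo + n_hi <= 0:
        raise ValueError("empty task")
    return max(n_lo, n_hi) / (n_lo + n_hi)


def subsample_rows(table: pd.DataFrame, frac: float, rng: np.random.Generator) -> pd.DataFrame:
    """Simple random sample of floor(frac * n) rows without replacement."""
    if len(table) == 0:
        raise ValueError("cannot subsample an empty table")
    if not 0 < frac <= 1:
        raise ValueError("frac must be in (0, 1]")
    m = int(np.floor(frac * len(table)))
    idx = rng.choice(len(table), size=m, replace=False)
    return table.iloc[np.sort(idx)].reset_index(drop=True)


def inject_control(table: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """Append one column of i.i.d. Uniform(0,1) noise named ``control``."""
    if CONTROL_NAME in table.columns:
        raise ValueError(f"column {CONTROL_NAME!r} already present")
    out = table.copy()
    out[CONTROL_NAME] = rng.random(len(table))
    return out


class SubsampleForest:
    """Bagged CART ensemble exposing out-of-bag predictions.

    Each tree is grown on a bootstrap sample of the rows with ``mtry``
    candidate features per split; rows left out of a tree's bootstrap are its
    out-of-bag (OOB) validation set.
    """

    def __init__(self, n_trees: int = 1000, mtry: int = 5, seed: int = 0):
        self.n_trees = n_trees
        self.mtry = mtry
        self.seed = seed
        self.trees_: list[DecisionTreeClassifier] = []
        self.oob_masks_: list[np.ndarray] = []
        self.classes_: np.ndarray | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "SubsampleForest":
        X = np.ascontiguousarray(X, dtype=np.float32)
        y = np.asarray(y)
        classes = np.unique(y)
        if len(classes) < 2:
            raise ValueError("forest requires at least two classes")
        if X.shape[1] < self.mtry:
            raise ValueError("mtry exceeds the number of features")
        self.classes_ = classes
        n = len(y)
        rng = np.random.default_rng(np.random.SeedSequence(self.seed))
        self.trees_ = []
        self.oob_masks_ = []
        for _ in range(self.n_trees):
            bag = rng.integers(0, n, size=n)
            oob = np.ones(n, dtype=bool)
            oob[bag] = False
            tree = DecisionTreeClassifier(
                max_features=self.mtry,
                random_state=int(rng.integers(0, 2**31 - 1)),
            )
            tree.fit(X[bag], y[bag])
            self.trees_.append(tree)
            self.oob_masks_.append(oob)
        self._X = X
        self._y = y
        return self

    def oob_votes(self) -> np.ndarray:
        """Per-row vote counts over classes from trees where the row is OOB."""
        n = len(self._y)
        votes = np.zeros((n, len(self.classes_)), dtype=np.int64)
        class_index = {c: i for i, c in enumerate(self.classes_)}
        for tree, oob in zip(self.trees_, self.oob_masks_):
            if not oob.any():
                continue
            pred = tree.predict(self._X[oob], check_input=False)
            rows = np.flatnonzero(oob)
            for c, i in class_index.items():
                votes[rows[pred == c], i] += 1
        return votes

    def oob_predictions(self) -> np.ndarray:
        """Majority-vote OOB prediction per row (ties to the first class)."""
        votes = self.oob_votes()
        pred = self.classes_[np.argmax(votes, axis=1)]
        return pred

    def oob_accuracy(self) -> float:
        votes = self.oob_votes()
        covered = votes.sum(axis=1) > 0
        if not covered.any():
            raise ValueError("no row has out-of-bag votes; too few trees")
        pred = self.classes_[np.argmax(votes[covered], axis=1)]
        return float(np.mean(pred == self._y[covered]))


def fit_forest(
    table: pd.DataFrame | np.ndarray,
    labels: Sequence,
    cfg: ScreeningConfig | None = None,
    seed: int | None = None,
) -> SubsampleForest:
    cfg = cfg or ScreeningConfig()
    X = table.to_numpy() if isinstance(table, pd.DataFrame) else np.asarray(table)
    forest = SubsampleForest(
        n_trees=cfg.n_trees,
        mtry=min(cfg.mtry, X.shape[1]),
        seed=cfg.seed if seed is None else seed,
    )
    return forest.fit(X, np.asarray(labels))


def permutation_importance(
    model: SubsampleForest,
    table: pd.DataFrame | np.ndarray,
    labels: Sequence,
    rng: np.random.Generator | int = 0,
    feature_names: Sequence[str] | None = None,
) -> dict[str, float]:
    """Out-of-bag permutation importance per variable.

    For each tree, each variable's OOB values are permuted and the drop in
    that tree's OOB accuracy recorded; the importance is the mean drop over
    trees.  Values can be negative for uninformative variables.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(np.random.SeedSequence(int(rng)))
    if isinstance(table, pd.DataFrame):
        names = list(table.columns) if feature_names is None else list(feature_names)
        X = table.to_numpy()
    else:
        X = np.asarray(table)
        names = (
            list(feature_names)
            if feature_names is not None
            else [f"x{i}" for i in range(X.shape[1])]
        )
    X = np.ascontiguousarray(X, dtype=np.float32)
    y = np.asarray(labels)
    p = X.shape[1]
    drop = np.zeros(p)
    used = 0
    for tree, oob in zip(model.trees_, model.oob_masks_):
        n_oob = int(oob.sum())
        if n_oob == 0:
            continue
        Xo = X[oob]
        yo = y[oob]
        base = float(np.mean(tree.predict(Xo, check_input=False) == yo))
        stacked = np.ascontiguousarray(np.tile(Xo, (p, 1)))
        for v in range(p):
            stacked[v * n_oob : (v + 1) * n_oob, v] = Xo[rng.permutation(n_oob), v]
        preds = tree.predict(stacked, check_input=False).reshape(p, n_oob)
        drop += base - np.mean(preds == yo, axis=1)
        used += 1
    if used == 0:
        raise ValueError("no tree had out-of-bag rows")
    drop /= used
    return dict(zip(names, drop))


@dataclass
class TaskResult:
    """Screening outcome for one two-league classification task."""

    task: PairTask
    importance: pd.DataFrame  # n_reps rows x (15 variables + control)
    median_importance: pd.Series
    critical_value: float
    control_max: float  # secondary diagnostic: max-of-control rule
    flagged: dict[str, bool]
    rank: dict[str, int]
    classification_rate: float
    oob_accuracies: list[float]
    majority_baseline: float
    n_lo: int
    n_hi: int
    n_dropped: int


@dataclass
class ScreeningResult:
    tasks: list[TaskResult]
    config: ScreeningConfig

    def task_by_name(self, name: str) -> TaskResult:
        for tr in self.tasks:
            if tr.task.name == name:
                return tr
        raise KeyError(name)


def _rank_variables(medians: pd.Series, means: pd.Series) -> dict[str, int]:
    order = sorted(
        medians.index, key=lambda v: (-medians[v], -means[v], v)
    )
    return {v: i + 1 for i, v in enumerate(order)}


def run_screening(table: pd.DataFrame, cfg: ScreeningConfig | None = None) -> ScreeningResult:
    """Run the full repeated-subsample screening over all league-pair tasks.

    ``table`` must carry a ``league`` column plus the 15 feature columns.
    Rows with missing feature values (players without PACs) are dropped per
    task with a logged count.  With ``balanced_n`` set, each class
    contributes exactly that many rows (drawn once per repetition) before the
    70% subsampling.
    """
    cfg = cfg or ScreeningConfig()
    if "league" not in table.columns:
        raise ValueError("feature table lacks a league column")
    missing = [v for v in FEATURE_NAMES if v not in table.columns]
    if missing:
        raise ValueError(f"feature table lacks columns {missing}")
    tasks = make_pair_tasks(table["league"].unique(), cfg)
    results = []
    for t_i, task in enumerate(tasks):
        sub = table[table["league"].isin([task.league_lo, task.league_hi])]
        complete = sub.dropna(subset=FEATURE_NAMES)
        n_dropped = len(sub) - len(complete)
        if n_dropped:
            logger.info("%s: dropped %d rows with missing PAC fields", task.name, n_dropped)
        n_lo = int((complete["league"] == task.league_lo).sum())
        n_hi = int((complete["league"] == task.league_hi).sum())
        min_needed = cfg.balanced_n if cfg.balanced_n is not None else 10
        for league, n in ((task.league_lo, n_lo), (task.league_hi, n_hi)):
            if n < min_needed:
                raise ValueError(
                    f"league {LEAGUE_NAMES[league]} has only {n} usable rows "
                    f"(need >= {min_needed})"
                )
        imp_rows = []
        accs = []
        for rep in range(cfg.n_reps):
            ss = np.random.SeedSequence(cfg.seed, spawn_key=(t_i, rep))
            s_bal, s_sub, s_forest, s_ctrl, s_perm = ss.spawn(5)
            rows = complete
            if cfg.balanced_n is not None:
                rng_bal = np.random.default_rng(s_bal)
                parts = []
                for league in (task.league_lo, task.league_hi):
                    grp = rows[rows["league"] == league]
                    take = rng_bal.choice(len(grp), size=cfg.balanced_n, replace=False)
                    parts.append(grp.iloc[np.sort(take)])
                rows = pd.concat(parts, ignore_index=True)
            rng_sub = np.random.default_rng(s_sub)
            if cfg.stratify:
                parts = [
                    subsample_rows(
                        rows[rows["league"] == lg].reset_index(drop=True),
                        cfg.subsample_frac,
                        rng_sub,
                    )
                    for lg in (task.league_lo, task.league_hi)
                ]
                drawn = pd.concat(parts, ignore_index=True)
            else:
                drawn = subsample_rows(
                    rows.reset_index(drop=True), cfg.subsample_frac, rng_sub
                )
            feats = inject_control(
                drawn[FEATURE_NAMES], np.random.default_rng(s_ctrl)
            )
            y = (drawn["league"].to_numpy() == task.league_hi).astype(np.int64)
            forest = fit_forest(
                feats, y, cfg, seed=int(s_forest.generate_state(1)[0] % (2**31 - 1))
            )
            accs.append(forest.oob_accuracy())
            imp = permutation_importance(
                forest, feats, y, np.random.default_rng(s_perm)
            )
            imp_rows.append(imp)
        importance = pd.DataFrame(imp_rows)
        medians = importance.median()
        means = importance.mean()
        critical = float(
            np.percentile(importance[CONTROL_NAME].to_numpy(), cfg.control_percentile)
        )
        flagged = {v: bool(medians[v] > critical) for v in importance.columns}
        rank = _rank_variables(medians, means)
        results.append(
            TaskResult(
                task=task,
                importance=importance,
                median_importance=medians,
                critical_value=critical,
                control_max=float(importance[CONTROL_NAME].max()),
                flagged=flagged,
                rank=rank,
                classification_rate=float(np.mean(accs)),
                oob_accuracies=[float(a) for a in accs],
                majority_baseline=majority_baseline(n_lo, n_hi)
                if cfg.balanced_n is None
                else 0.5,
                n_lo=n_lo if cfg.balanced_n is None else cfg.balanced_n,
                n_hi=n_hi if cfg.balanced_n is None else cfg.balanced_n,
                n_dropped=n_dropped,
            )
        )
    return ScreeningResult(tasks=results, config=cfg)


def rank_matrix(result: ScreeningResult) -> pd.DataFrame:
    """Variables x tasks matrix of importance ranks (1 = most important)."""
    cols = {tr.task.name: pd.Series(tr.rank) for tr in result.tasks}
    return pd.DataFrame(cols).loc[FEATURE_NAMES + [CONTROL_NAME]]


def flag_matrix(result: ScreeningResult) -> pd.DataFrame:
    """Boolean companion of :func:`rank_matrix`: beat-the-control flags."""
    cols = {tr.task.name: pd.Series(tr.flagged) for tr in result.tasks}
    return pd.DataFrame(cols).loc[FEATURE_NAMES + [CONTROL_NAME]]


def result_to_json(result: ScreeningResult) -> dict:
    """JSON-serializable report with one block per task."""
    blocks = {}
    for tr in result.tasks:
        blocks[tr.task.name] = {
            "league_lo": tr.task.league_lo,
            "league_hi": tr.task.league_hi,
            "importances": {
                v: [float(x) for x in tr.importance[v]] for v in tr.importance.columns
            },
            "medians": {v: float(tr.median_importance[v]) for v in tr.importance.columns},
            "critical_value": tr.critical_value,
            "control_max": tr.control_max,
            "flags": tr.flagged,
            "ranks": tr.rank,
            "classification_rate": tr.classification_rate,
            "oob_accuracies": tr.oob_accuracies,
            "majority_baseline": tr.majority_baseline,
            "n_lo": tr.n_lo,
            "n_hi": tr.n_hi,
            "n_dropped": tr.n_dropped,
        }
    cfgdict = {
        "n_trees": result.config.n_trees,
        "mtry": result.config.mtry,
        "n_reps": result.config.n_reps,
        "subsample_frac": result.config.subsample_frac,
        "control_percentile": result.config.control_percentile,
        "league_spacing": result.config.league_spacing,
        "include_extreme_pair": result.config.include_extreme_pair,
        "balanced_n": result.config.balanced_n,
        "stratify": result.config.stratify,
        "seed": result.config.seed,
    }
    return {"config": cfgdict, "tasks": blocks}
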