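"""Split strategies, regression/classification metrics, and Monte Carlo CV.

Four split strategies are supported for cell-drug pair tables:

* ``mix``  — pairs partitioned at random (the default 8:1:1 protocol);
* ``cell`` — cells partitioned, every pair follows its cell (unseen cells);
* ``drug`` — drugs partitioned symmetrically (unseen drugs);
* ``both`` — cells and drugs partitioned independently; a pair enters
  partition k only if both its cell and drug are assigned to k, and
  cross-partition pairs are discarded (their count is reported).

Partition sizes use largest-remainder rounding so they are deterministic.

Classification metrics use the quartile rule: the threshold is the 25th
percentile of the *observed* LN IC50 (linear-interpolation percentile); pairs
at or below it are "sensitive" (the positive class), the same threshold is
applied to predictions for F1, and AUROC ranks by the negated prediction so
that higher score means more sensitive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import f1_score, roc_auc_score

__all__ = [
    "SplitSpec",
    "SplitResult",
    "MetricReport",
    "split_pairs",
    "regression_metrics",
    "quartile_classification",
    "evaluate_predictions",
    "per_entity_metrics",
    "monte_carlo_cv",
]

Strategy = Literal["mix", "cell", "drug", "both"]


@dataclass(frozen=True)
class SplitSpec:
    strategy: Strategy = "mix"
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.strategy not in ("mix", "cell", "drug", "both"):
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if len(self.fractions) != 3 or any(f <= 0 for f in self.fractions):
            raise ValueError("fractions must be three positive numbers")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")


@dataclass
class SplitResult:
    train: pd.DataFrame
    val: pd.DataFrame
    test: pd.DataFrame
    n_discarded: int = 0  # cross-partition pairs under the 'both' strategy

    @property
    def partitions(self) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
        return self.train, self.val, self.test


@dataclass
class MetricReport:
    pcc: float
    rmse: float
    auroc: float = np.nan
    f1: float = np.nan
    n: int = 0

    def as_dict(self) -> dict[str, float]:
        return {"pcc": self.pcc, "rmse": self.rmse, "auroc": self.auroc,
                "f1": self.f1, "n": self.n}


def _allocate(n: int, fractions: Sequence[float]) -> list[int]:
    """Largest-remainder allocation of n items across the fractions."""
    exact = [f * n for f in fractions]
    base = [int(np.floor(e)) for e in exact]
    leftover = n - sum(base)
    remainders = sorted(
        range(len(fractions)), key=lambda i: (-(exact[i] - base[i]), i)
    )
    for i in remainders[:leftover]:
        base[i] += 1
    return base


def _partition_labels(
    items: np.ndarray, fractions: Sequence[float], rng: np.random.Generator
) -> dict:
    """Shuffle items and assign partition index 0/1/2 by largest remainder."""
    order = rng.permutation(len(items))
    counts = _allocate(len(items), fractions)
    labels = np.empty(len(items), dtype=int)
    start = 0
    for part, c in enumerate(counts):
        labels[order[start : start + c]] = part
        start += c
    return dict(zip(items.tolist(), labels.tolist()))


def split_pairs(pairs: pd.DataFrame, spec: SplitSpec) -> SplitResult:
    """Partition a pair table into train/val/test under the given strategy."""
    required = {"cell_id", "drug_id"}
    if not required.issubset(pairs.columns):
        raise ValueError(f"pair table must have columns {sorted(required)}")
    rng = np.random.default_rng(spec.seed)
    n = len(pairs)
    if n == 0:
        raise ValueError("empty pair table")

    if spec.strategy == "mix":
        order = rng.permutation(n)
        counts = _allocate(n, spec.fractions)
        idx = np.empty(n, dtype=int)
        start = 0
        for part, c in enumerate(counts):
            idx[order[start : start + c]] = part
            start += c
        parts = [pairs.loc[idx == k] for k in range(3)]
        discarded = 0
    elif spec.strategy in ("cell", "drug"):
        col = "cell_id" if spec.strategy == "cell" else "drug_id"
        entities = np.array(sorted(pairs[col].unique()), dtype=object)
        assign = _partition_labels(entities, spec.fractions, rng)
        labels = pairs[col].map(assign)
        parts = [pairs.loc[labels == k] for k in range(3)]
        discarded = 0
    else:  # both
        cells = np.array(sorted(pairs["cell_id"].unique()), dtype=object)
        drugs = np.array(sorted(pairs["drug_id"].unique()), dtype=object)
        cell_assign = pairs["cell_id"].map(_partition_labels(cells, spec.fractions, rng))
        drug_assign = pairs["drug_id"].map(_partition_labels(drugs, spec.fractions, rng))
        match = cell_assign == drug_assign
        parts = [pairs.loc[match & (cell_assign == k)] for k in range(3)]
        discarded = int((~match).sum())

    names = ("train", "val", "test")
    for name, part in zip(names, parts):
        if part.empty:
            raise ValueError(
                f"{name} partition is empty under strategy {spec.strategy!r}; "
                "use more data or different fractions"
            )
    return SplitResult(*[p.reset_index(drop=True) for p in parts], n_discarded=discarded)


def regression_metrics(pred: np.ndarray, obs: np.ndarray) -> tuple[float, float]:
    """(Pearson correlation, RMSE); PCC is NaN when obs is constant."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape or pred.ndim != 1:
        raise ValueError("pred and obs must be equal-length 1-D arrays")
    if len(pred) < 2:
        raise ValueError("need at least 2 observations")
    rmse = float(np.sqrt(np.mean((pred - obs) ** 2)))
    if np.all(obs == obs[0]) or np.all(pred == pred[0]):
        return np.nan, rmse
    pcc = float(np.corrcoef(pred, obs)[0, 1])
    return pcc, rmse


def quartile_classification(
    pred: np.ndarray, obs: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Sensitive/insensitive labels from the observed first-quartile threshold.

    Returns (labels_obs, labels_pred, auroc, f1) with sensitive (LN IC50 at or
    below the 25th percentile of obs) as the positive class.  AUROC scores by
    the negated prediction; F1 applies the observed threshold to predictions.
    """
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if len(obs) < 4:
        raise ValueError("need at least 4 observations for a quartile split")
    if np.all(obs == obs[0]):
        raise ValueError("all observations identical: quartile threshold undefined")
    tau = float(np.percentile(obs, 25))  # linear interpolation between order stats
    labels_obs = obs <= tau
    labels_pred = pred <= tau
    if labels_obs.all() or not labels_obs.any():
        raise ValueError("degenerate quartile labels (ties at the threshold)")
    auroc = float(roc_auc_score(labels_obs, -pred))
    f1 = float(f1_score(labels_obs, labels_pred, zero_division=0))
    return labels_obs, labels_pred, auroc, f1


def evaluate_predictions(pred: np.ndarray, obs: np.ndarray) -> MetricReport:
    """Full metric report (PCC, RMSE, AUROC, F1) for one prediction set."""
    pcc, rmse = regression_metrics(pred, obs)
    try:
        _, _, auroc, f1 = quartile_classification(pred, obs)
    except ValueError:
        auroc, f1 = np.nan, np.nan
    return MetricReport(pcc, rmse, auroc, f1, n=len(np.asarray(obs)))


def per_entity_metrics(
    pairs: pd.DataFrame,
    pred: np.ndarray,
    by: Literal["cell", "drug"] = "cell",
    min_pairs: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame, int]:
    """Metrics within each cell (across drugs) or each drug (across cells).

    Entities with fewer than ``min_pairs`` pairs or constant observations are
    skipped and counted.  Returns (per-entity table, mean/sd summary, n_skipped).
    """
    if by not in ("cell", "drug"):
        raise ValueError("by must be 'cell' or 'drug'")
    col = "cell_id" if by == "cell" else "drug_id"
    df = pairs.copy()
    df["_pred"] = np.asarray(pred, dtype=float)
    rows = []
    skipped = 0
    for entity, grp in df.groupby(col, sort=True):
        obs = grp["ln_ic50"].to_numpy()
        if len(grp) < min_pairs or np.all(obs == obs[0]):
            skipped += 1
            continue
        report = evaluate_predictions(grp["_pred"].to_numpy(), obs)
        rows.append({col: entity, **report.as_dict()})
    if not rows:
        raise ValueError("no entity retained (too few pairs or constant observations)")
    table = pd.DataFrame(rows)
    metrics = ["pcc", "rmse", "auroc", "f1"]
    summary = pd.DataFrame(
        {"mean": table[metrics].mean(), "sd": table[metrics].std(ddof=1)}
    )
    return table, summary, skipped


def monte_carlo_cv(
    pairs: pd.DataFrame,
    train_and_score: Callable[[SplitResult, int], MetricReport],
    n_iter: int = 10,
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> tuple[list[MetricReport], pd.DataFrame]:
    """Repeated random 8:1:1 resplits, each retrained and scored from scratch.

    ``train_and_score(split, iteration_seed)`` trains on ``split.train`` /
    ``split.val`` and returns the test-set report.  Fresh split seeds are
    spawned deterministically from the master ``seed``.  Returns all reports
    plus a mean/sd summary.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    child_seeds = [
        int(s.generate_state(1)[0] % (2**31))
        for s in np.random.SeedSequence(seed).spawn(n_iter)
    ]
    reports = []
    for i, child in enumerate(child_seeds):
        try:
            split = split_pairs(pairs, SplitSpec("mix", fractions, seed=child))
            reports.append(train_and_score(split, child))
        except Exception as exc:
            raise RuntimeError(f"Monte Carlo iteration {i} (seed {child}) failed") from exc
    table = pd.DataFrame([r.as_dict() for r in reports])
    summary = pd.DataFrame(
        {"mean": table[["pcc", "rmse", "auroc", "f1"]].mean(),
         "sd": table[["pcc", "rmse", "auroc", "f1"]].std(ddof=1)}
    )
    return reports, summary
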