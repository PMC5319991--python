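"""Cross-validation protocols and rank-based ROC/AUC evaluation.

Three leakage-safe protocols evaluate the predictor on a known association
matrix Y:

* **global LOOCV** — each known pair is removed in turn; kernels, network
  and scores are recomputed without it; the held-out pair is ranked against
  every unverified pair of the original matrix (one candidate set shared by
  all test rounds).
* **local LOOCV** — identical removal and recomputation, but the held-out
  pair is ranked only against its own disease's unconfirmed microbes.
* **repeated k-fold CV** — known pairs are randomly partitioned into k
  near-equal folds; each fold is removed together, scores recomputed once
  per fold, and each held-out pair ranked global-style; the AUC is averaged
  over repeats (mean ± sd).

Ranks use the mid-rank convention for ties, so the ROC construction below
reproduces the tie-corrected Mann-Whitney statistic.  Because local LOOCV
candidate sets differ per disease, every test round is reduced to its
*normalised exceedance* x = (rank - 1) / n_candidates in [0, 1]; the pooled
ROC sweeps thresholds over [0, 1] with TPR the empirical CDF of x and
FPR the threshold itself, and the trapezoidal area equals mean(1 - x)
exactly — which, for shared candidate sets, is the Mann-Whitney AUC.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import warnings
from typing import Any, Sequence

import numpy as np

from .association_data import AssociationMatrix
from .config import RunConfig
from .gip_similarity import DegenerateNetworkError
from .path_scoring import predict_all

__all__ = [
    "RankRecord",
    "CVReport",
    "roc_auc",
    "global_loocv",
    "local_loocv",
    "kfold_cv",
    "plot_roc",
]

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class RankRecord:
    """Outcome of one test round: where the held-out pair ranked."""

    microbe: str
    disease: str
    rank: float  # mid-rank among {candidates + the test pair}, in [1, n+1]
    n_candidates: int

    def __post_init__(self) -> None:
        if self.n_candidates < 0:
            raise ValueError("n_candidates must be >= 0")
        if not 1.0 <= self.rank <= self.n_candidates + 1:
            raise ValueError(
                f"rank {self.rank} outside [1, {self.n_candidates + 1}]"
            )

    @property
    def exceedance(self) -> float:
        """(rank - 1) / n_candidates: fraction of candidates beating the pair."""
        if self.n_candidates == 0:
            return 0.0
        return (self.rank - 1.0) / self.n_candidates


@dataclasses.dataclass(frozen=True)
class CVReport:
    """ROC curve, AUC and per-test rank records for one protocol run."""

    protocol: str
    auc: float
    auc_sd: float | None
    roc_points: np.ndarray  # (k, 2) array of (FPR, TPR), (0,0) .. (1,1)
    ranks: tuple[RankRecord, ...]
    config: dict[str, Any]
    seed: int | None = None
    n_failed: int = 0

    def __post_init__(self) -> None:
        pts = np.asarray(self.roc_points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("roc_points must be an (k, 2) array")
        if not (np.all(np.diff(pts[:, 0]) >= 0) and np.all(np.diff(pts[:, 1]) >= 0)):
            raise ValueError("ROC coordinates must be non-decreasing")
        if not (np.allclose(pts[0], (0, 0)) and np.allclose(pts[-1], (1, 1))):
            raise ValueError("ROC must run from (0, 0) to (1, 1)")
        if not 0.0 <= self.auc <= 1.0:
            raise ValueError(f"AUC {self.auc} outside [0, 1]")
        object.__setattr__(self, "roc_points", pts)
        object.__setattr__(self, "ranks", tuple(self.ranks))

    def to_json_dict(self) -> dict[str, Any]:
        return {
            "protocol": self.protocol,
            "auc": self.auc,
            "auc_sd": self.auc_sd,
            "n_test_samples": len(self.ranks),
            "n_failed": self.n_failed,
            "seed": self.seed,
            "config": self.config,
            "roc_points": [[float(f), float(t)] for f, t in self.roc_points],
            "ranks": [
                {
                    "microbe": r.microbe,
                    "disease": r.disease,
                    "rank": r.rank,
                    "n_candidates": r.n_candidates,
                }
                for r in self.ranks
            ],
        }

    def write_json(self, path: str | os.PathLike[str]) -> None:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            json.dump(self.to_json_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


# -- ROC / AUC -------------------------------------------------------------


def roc_auc(records: Sequence[RankRecord | tuple[float, int]]) -> tuple[float, np.ndarray]:
    """AUC and pooled ROC points from per-test (rank, candidate-set size).

    Accepts :class:`RankRecord` objects or bare ``(rank, n_candidates)``
    tuples.  The ROC is the staircase of the empirical CDF of the normalised
    exceedances against a uniform false-positive axis; its trapezoidal area
    equals ``mean(1 - exceedance)``, the tie-corrected Mann-Whitney AUC when
    all candidate sets coincide.
    """
    if len(records) == 0:
        raise ValueError("cannot build a ROC from zero test rounds")
    recs = [
        r if isinstance(r, RankRecord) else RankRecord("?", "?", float(r[0]), int(r[1]))
        for r in records
    ]
    # sorted so the mean is invariant to record order (k-fold shuffles it)
    x = np.sort(np.array([r.exceedance for r in recs]))
    auc = float(np.mean(1.0 - x))

    n = x.size
    points: list[tuple[float, float]] = [(0.0, 0.0)]
    cum = 0
    for v, c in zip(*np.unique(x, return_counts=True)):
        points.append((float(v), cum / n))
        cum += int(c)
        points.append((float(v), cum / n))
    points.append((1.0, 1.0))
    # drop consecutive duplicates (e.g. when some x equals 0 or 1)
    dedup = [points[0]]
    for p in points[1:]:
        if p != dedup[-1]:
            dedup.append(p)
    return auc, np.array(dedup)


def _midrank(candidate_scores: np.ndarray, test_score: float) -> float:
    """1-based mid-rank of the test score against the candidates."""
    better = int((candidate_scores > test_score).sum())
    tied = int((candidate_scores == test_score).sum())
    return better + 1 + tied / 2.0


# -- protocols -------------------------------------------------------------


def _rank_pairs_global(
    S: np.ndarray, candidate_mask: np.ndarray, pairs, Y: AssociationMatrix
) -> list[RankRecord]:
    cand = S[candidate_mask]
    out = []
    for i, j in pairs:
        out.append(
            RankRecord(
                microbe=Y.microbe_names[i],
                disease=Y.disease_names[j],
                rank=_midrank(cand, S[i, j]),
                n_candidates=cand.size,
            )
        )
    return out


def global_loocv(Y: AssociationMatrix, config: RunConfig | None = None) -> CVReport:
    """Leave each known pair out; rank it among all unverified pairs.

    The candidate set is fixed across rounds: every pair with Y=0 in the
    *original* matrix.  Kernels, network and scores are recomputed per round
    from the reduced matrix, so the held-out association never informs its
    own test (leakage safety).
    """
    cfg = config if config is not None else RunConfig()
    known = Y.known_pairs()
    if len(known) < 2:
        raise ValueError("global LOOCV needs at least 2 known associations")
    candidate_mask = Y.values == 0
    records: list[RankRecord] = []
    n_failed = 0
    for i, j in known:
        try:
            S = predict_all(Y.without([(i, j)]), cfg).values
        except DegenerateNetworkError:
            n_failed += 1
            warnings.warn(
                f"skipping LOOCV round for ({Y.microbe_names[i]}, "
                f"{Y.disease_names[j]}): network degenerate after removal",
                stacklevel=2,
            )
            continue
        records.extend(_rank_pairs_global(S, candidate_mask, [(i, j)], Y))
    auc, pts = roc_auc(records)
    return CVReport("global_loocv", auc, None, pts, records, cfg.to_dict(),
                    n_failed=n_failed)


def local_loocv(Y: AssociationMatrix, config: RunConfig | None = None) -> CVReport:
    """Leave each known pair out; rank it within its own disease.

    Candidates for test pair (m, d) are the microbes not known to associate
    with d in the original matrix.  A disease whose every microbe is a known
    associate leaves no candidates; the held-out pair is then trivially
    ranked first.
    """
    cfg = config if config is not None else RunConfig()
    known = Y.known_pairs()
    if len(known) < 2:
        raise ValueError("local LOOCV needs at least 2 known associations")
    records: list[RankRecord] = []
    n_failed = 0
    for i, j in known:
        try:
            S = predict_all(Y.without([(i, j)]), cfg).values
        except DegenerateNetworkError:
            n_failed += 1
            warnings.warn(
                f"skipping LOOCV round for ({Y.microbe_names[i]}, "
                f"{Y.disease_names[j]}): network degenerate after removal",
                stacklevel=2,
            )
            continue
        cand = S[Y.values[:, j] == 0, j]
        records.append(
            RankRecord(
                microbe=Y.microbe_names[i],
                disease=Y.disease_names[j],
                rank=_midrank(cand, S[i, j]),
                n_candidates=cand.size,
            )
        )
    auc, pts = roc_auc(records)
    return CVReport("local_loocv", auc, None, pts, records, cfg.to_dict(),
                    n_failed=n_failed)


def kfold_cv(
    Y: AssociationMatrix,
    k: int = 5,
    repeats: int = 100,
    seed: int = 0,
    config: RunConfig | None = None,
) -> CVReport:
    """Repeated k-fold CV over the known pairs, global-style candidate set.

    Per repeat, the known pairs are partitioned into k disjoint folds whose
    sizes differ by at most one; each fold is zeroed together and kernels /
    scores recomputed once per fold.  AUC is computed per repeat and
    reported as mean ± sample standard deviation; the pooled ROC aggregates
    every test round of every repeat.  Fully reproducible from ``seed``.
    """
    cfg = config if config is not None else RunConfig()
    if k < 2:
        raise ValueError("k must be >= 2")
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    known = Y.known_pairs()
    if len(known) < k:
        raise ValueError(f"need at least k={k} known associations, have {len(known)}")
    candidate_mask = Y.values == 0
    rng = np.random.default_rng(seed)
    per_repeat_auc: list[float] = []
    all_records: list[RankRecord] = []
    n_failed = 0
    for _ in range(repeats):
        order = rng.permutation(len(known))
        folds = np.array_split(order, k)
        repeat_records: list[RankRecord] = []
        for fold in folds:
            held = [known[t] for t in fold.tolist()]
            try:
                S = predict_all(Y.without(held), cfg).values
            except DegenerateNetworkError:
                n_failed += len(held)
                warnings.warn("skipping fold: network degenerate after removal",
                              stacklevel=2)
                continue
            repeat_records.extend(_rank_pairs_global(S, candidate_mask, held, Y))
        auc_r, _ = roc_auc(repeat_records)
        per_repeat_auc.append(auc_r)
        all_records.extend(repeat_records)
    mean_auc = float(np.mean(per_repeat_auc))
    sd = float(np.std(per_repeat_auc, ddof=1)) if repeats > 1 else 0.0
    _, pts = roc_auc(all_records)
    return CVReport("kfold", mean_auc, sd, pts, all_records, cfg.to_dict(),
                    seed=seed, n_failed=n_failed)


def plot_roc(report: CVReport, path: str | os.PathLike[str]) -> None:
    """Save the report's ROC curve as an image (PNG/SVG by extension)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.plot(report.roc_points[:, 0], report.roc_points[:, 1],
            label=f"{report.protocol} (AUC = {report.auc:.4f})")
    ax.plot([0, 1], [0, 1], linestyle="--", color="grey", linewidth=0.8)
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
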