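"""Replicate evaluation, AUC-weighted ensembling, and jackknife contributions.

Each candidate algorithm is scored by repeated stratified 80/20 holdout
(AUC and TSS per replicate). Algorithms whose mean holdout AUC reaches the
admission cutoff (0.85 by default) are refit on all data and combined per
cell with weights proportional to their mean AUC:

    W_i = r_i / sum_j r_j   over the h admitted models.

Variable importance uses a leave-one-covariate-out jackknife: the ensemble
prediction is rebuilt without each variable and scored by
1 - Pearson r against the full map, normalized to percentages.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import rankdata

from esdm.env_layers import EnvStack, Layer
from esdm.errors import ContractError, NoAdmissibleModelError
from esdm.occurrence import OccurrenceSet, extract_covariates
from esdm.sdm_core import ALGORITHMS, SDMFit, fit_sdm, predict_sdm

log = logging.getLogger(__name__)

DEFAULT_AUC_CUTOFF = 0.85
DEFAULT_N_REPLICATES = 20
DEFAULT_HOLDOUT = 0.2


# ---------------------------------------------------------------------------
# Metrics


def _check_labels(labels, scores) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ContractError("labels and scores must have equal length")
    if len(np.unique(labels)) < 2:
        raise ContractError("both classes must be present")
    return labels, scores


def auc_score(labels, scores) -> float:
    """Area under the ROC curve, Mann-Whitney formulation.

    Fraction of (positive, negative) pairs where the positive scores
    higher, ties counted as half.
    """
    labels, scores = _check_labels(labels, scores)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    ranks = rankdata(scores)  # average ranks handle ties as half-wins
    rank_sum_pos = ranks[labels == 1].sum()
    u = rank_sum_pos - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def tss_score(labels, scores) -> tuple[float, float]:
    """Max of sensitivity + specificity - 1 over candidate thresholds.

    Candidate thresholds are the unique score values; prediction is
    positive iff score >= threshold. Returns (tss, largest attaining
    threshold) — ties favour the more specific classification.
    """
    labels, scores = _check_labels(labels, scores)
    n_pos = labels.sum()
    n_neg = labels.size - n_pos
    thresholds = np.unique(scores)  # ascending
    pred = scores[None, :] >= thresholds[:, None]
    tp = (pred & (labels == 1)).sum(axis=1)
    fp = (pred & (labels == 0)).sum(axis=1)
    tss = tp / n_pos + (n_neg - fp) / n_neg - 1.0
    best = float(tss.max())
    threshold = float(thresholds[np.flatnonzero(np.isclose(tss, best))[-1]])
    return best, threshold


# ---------------------------------------------------------------------------
# Replicate evaluation


@dataclass
class EvaluationResult:
    algorithm: str
    replicate: int
    auc: float
    tss: float
    threshold: float


@dataclass
class ReplicateEvaluation:
    """Per-replicate metrics plus the holdout predictions that produced them.

    ``holdout_labels[rep]`` and ``holdout_scores[(algorithm, rep)]`` are
    aligned, so algorithm predictions can be re-weighted per replicate.
    """

    results: list[EvaluationResult] = field(default_factory=list)
    holdout_labels: dict[int, np.ndarray] = field(default_factory=dict)
    holdout_scores: dict[tuple[str, int], np.ndarray] = field(default_factory=dict)

    def mean_auc(self) -> dict[str, float]:
        by_algo: dict[str, list[float]] = {}
        for res in self.results:
            by_algo.setdefault(res.algorithm, []).append(res.auc)
        return {a: float(np.mean(v)) for a, v in by_algo.items()}

    def mean_tss(self) -> dict[str, float]:
        by_algo: dict[str, list[float]] = {}
        for res in self.results:
            by_algo.setdefault(res.algorithm, []).append(res.tss)
        return {a: float(np.mean(v)) for a, v in by_algo.items()}


def _stratified_split(y: np.ndarray, holdout: float, rng: np.random.Generator):
    """Indices (train, test) with ceil(holdout * n_c) test rows per class."""
    test_idx = []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        n_test = int(np.ceil(holdout * idx.size))
        perm = rng.permutation(idx)
        test_idx.append(perm[:n_test])
    test = np.sort(np.concatenate(test_idx))
    train = np.setdiff1d(np.arange(y.size), test)
    return train, test


def _replicate_seeds(seed: int, n: int) -> list[np.random.SeedSequence]:
    return np.random.SeedSequence(seed).spawn(n)


def evaluate_replicates(
    occ: OccurrenceSet,
    stack: EnvStack,
    algorithms: Sequence[str] = ALGORITHMS,
    n_rep: int = DEFAULT_N_REPLICATES,
    holdout: float = DEFAULT_HOLDOUT,
    seed: int = 0,
    hyperparams: Mapping[str, Mapping] | None = None,
) -> ReplicateEvaluation:
    """Repeated stratified holdout evaluation of each algorithm.

    Replicate seeds derive deterministically from the master seed; every
    algorithm sees the same split within a replicate.
    """
    if len(occ.presences) < 10 or len(occ.absences) < 10:
        raise ContractError("need at least 10 presences and 10 absences")
    hyperparams = hyperparams or {}
    cells, y = occ.labels()
    X = extract_covariates(cells, stack)
    ev = ReplicateEvaluation()
    for rep, ss in enumerate(_replicate_seeds(seed, n_rep)):
        split_seed, fit_seed = (int(s) for s in ss.generate_state(2))
        rng = np.random.default_rng(split_seed)
        train, test = _stratified_split(y, holdout, rng)
        ev.holdout_labels[rep] = y[test]
        for algo in algorithms:
            fit = fit_sdm(
                algo, X.iloc[train], y[train], hyperparams.get(algo), seed=fit_seed
            )
            scores = fit.predict(X.iloc[test])
            ev.holdout_scores[(algo, rep)] = scores
            auc = auc_score(y[test], scores)
            tss, thr = tss_score(y[test], scores)
            ev.results.append(EvaluationResult(algo, rep, auc, tss, thr))
    return ev


# ---------------------------------------------------------------------------
# Ensemble


def ensemble_weights(
    mean_auc_by_model: Mapping[str, float],
    cutoff: float = DEFAULT_AUC_CUTOFF,
    strict: bool = False,
) -> dict[str, float]:
    """AUC-proportional weights over models at or above the cutoff.

    ``strict`` demands AUC strictly above the cutoff; the default admits
    models printed exactly at it.
    """
    if strict:
        included = {a: r for a, r in mean_auc_by_model.items() if r > cutoff}
    else:
        included = {a: r for a, r in mean_auc_by_model.items() if r >= cutoff}
    if not included:
        raise NoAdmissibleModelError(
            f"no model reached the AUC cutoff {cutoff}: {dict(mean_auc_by_model)}"
        )
    total = sum(included.values())
    return {a: r / total for a, r in included.items()}


@dataclass
class EnsembleModel:
    fits: dict[str, SDMFit]
    weights: dict[str, float]
    cutoff: float
    mean_auc: dict[str, float]
    mean_tss: dict[str, float]
    auc: float
    tss: float
    evaluation: ReplicateEvaluation

    @property
    def h(self) -> int:
        return len(self.weights)

    def weighted_member_auc(self) -> float:
        """AUC-weighted average of member mean AUCs (alternative report)."""
        return float(sum(self.weights[a] * self.mean_auc[a] for a in self.weights))

    def weighted_member_tss(self) -> float:
        return float(sum(self.weights[a] * self.mean_tss[a] for a in self.weights))


def build_ensemble(
    occ: OccurrenceSet,
    stack: EnvStack,
    algorithms: Sequence[str] = ALGORITHMS,
    config: Mapping | None = None,
    seed: int = 0,
    evaluation: ReplicateEvaluation | None = None,
    weights: Mapping[str, float] | None = None,
) -> tuple[EnsembleModel, Layer]:
    """Fit the admitted models on all data and combine their maps.

    Ensemble AUC/TSS apply the weighted combination to each replicate's
    holdout predictions, then average across replicates. Passing
    ``evaluation`` (and optionally frozen ``weights``) skips re-evaluation.
    """
    config = dict(config or {})
    cutoff = config.get("auc_cutoff", DEFAULT_AUC_CUTOFF)
    n_rep = config.get("replicates", DEFAULT_N_REPLICATES)
    holdout = config.get("holdout", DEFAULT_HOLDOUT)
    hyperparams = config.get("hyperparams", {})
    strict = config.get("strict_cutoff", False)
    algorithms = config.get("algorithms", algorithms)

    if evaluation is None:
        evaluation = evaluate_replicates(
            occ, stack, algorithms, n_rep, holdout, seed, hyperparams
        )
    mean_auc = evaluation.mean_auc()
    mean_tss = evaluation.mean_tss()
    if weights is None:
        weights = ensemble_weights(mean_auc, cutoff, strict)
    weights = dict(weights)

    # ensemble-level metrics from re-weighted holdout predictions
    reps = sorted(evaluation.holdout_labels)
    rep_auc, rep_tss = [], []
    for rep in reps:
        combined = sum(
            w * evaluation.holdout_scores[(a, rep)] for a, w in weights.items()
        )
        labels = evaluation.holdout_labels[rep]
        rep_auc.append(auc_score(labels, combined))
        rep_tss.append(tss_score(labels, combined)[0])

    # refit admitted models on all occurrence data
    cells, y = occ.labels()
    X = extract_covariates(cells, stack)
    refit_seed = int(np.random.SeedSequence(seed).generate_state(1)[0])
    fits = {
        a: fit_sdm(a, X, y, hyperparams.get(a), seed=refit_seed) for a in weights
    }

    grid = stack.grid
    combined_map = np.zeros((grid.n_rows, grid.n_cols))
    for a, w in weights.items():
        combined_map = combined_map + w * predict_sdm(fits[a], stack).values
    combined_map = np.clip(combined_map, 0.0, 1.0)
    combined_map[~stack.valid_mask] = np.nan

    model = EnsembleModel(
        fits=fits,
        weights=weights,
        cutoff=cutoff,
        mean_auc=mean_auc,
        mean_tss=mean_tss,
        auc=float(np.mean(rep_auc)),
        tss=float(np.mean(rep_tss)),
        evaluation=evaluation,
    )
    ens_map = Layer(f"ensemble_{occ.species}", "continuous", combined_map, grid)
    return model, ens_map


# ---------------------------------------------------------------------------
# Jackknife variable contribution


def jackknife_contribution(
    occ: OccurrenceSet,
    stack: EnvStack,
    kept_variables: Sequence[str] | None = None,
    config: Mapping | None = None,
    seed: int = 0,
    full: tuple[EnsembleModel, Layer] | None = None,
) -> dict[str, float]:
    """Leave-one-covariate-out contributions in percent (sum to 100).

    For each variable the admitted models are refit (same seeds, same
    weights) on the reduced covariate set; the raw score is
    ``max(0, 1 - Pearson r(full map, reduced map))`` over valid cells.
    """
    names = list(kept_variables) if kept_variables is not None else stack.names
    if len(names) < 2:
        raise ContractError("jackknife needs at least two variables")
    work = stack.subset(names)
    if full is None:
        full = build_ensemble(occ, work, config=config, seed=seed)
    model, full_map = full
    mask = work.valid_mask
    full_vals = full_map.values[mask]

    raw: dict[str, float] = {}
    for v in names:
        reduced = work.subset([n for n in names if n != v])
        _, red_map = build_ensemble(
            occ,
            reduced,
            config=config,
            seed=seed,
            evaluation=model.evaluation,
            weights=model.weights,
        )
        red_vals = red_map.values[mask]
        if np.std(full_vals) == 0 or np.std(red_vals) == 0:
            warnings.warn(
                f"constant suitability map when removing {v!r}; contribution set to 0",
                stacklevel=2,
            )
            raw[v] = 0.0
            continue
        r = float(np.corrcoef(full_vals, red_vals)[0, 1])
        raw[v] = max(0.0, 1.0 - r)

    total = sum(raw.values())
    if total == 0:
        warnings.warn("all jackknife scores are zero; returning uniform shares", stacklevel=2)
        return {v: 100.0 / len(names) for v in names}
    return {v: 100.0 * s / total for v, s in raw.items()}
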