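"""Collinearity screening of continuous covariates.

Two screens run in sequence: a greedy pairwise Pearson filter (drop while
any kept pair has |r| >= r_max) followed by iterative variance-inflation
screening (drop the max-VIF variable while max VIF >= vif_max).
Categorical layers are exempt from both and always retained.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from esdm.env_layers import EnvStack
from esdm.errors import ContractError

DEFAULT_R_MAX = 0.7
DEFAULT_VIF_MAX = 10.0


@dataclass
class ScreeningReport:
    kept: list[str]
    dropped: list[dict] = field(default_factory=list)
    flagged: list[str] = field(default_factory=list)
    r_max: float = DEFAULT_R_MAX
    vif_max: float = DEFAULT_VIF_MAX

    def to_json(self) -> str:
        return json.dumps(
            {
                "kept": self.kept,
                "dropped": self.dropped,
                "flagged": self.flagged,
                "thresholds": {"r_max": self.r_max, "vif_max": self.vif_max},
            },
            indent=2,
        )

    def merge(self, other: "ScreeningReport") -> "ScreeningReport":
        return ScreeningReport(
            kept=other.kept,
            dropped=self.dropped + other.dropped,
            flagged=sorted(set(self.flagged) | set(other.flagged)),
            r_max=self.r_max,
            vif_max=other.vif_max,
        )


def _continuous_matrix(stack: EnvStack, names: Sequence[str]) -> np.ndarray:
    """Valid-mask cell values, one column per named continuous layer."""
    mask = stack.valid_mask
    cols = []
    for name in names:
        lyr = stack[name]
        if lyr.kind != "continuous":
            raise ContractError(f"layer {name!r} is not continuous")
        cols.append(lyr.values[mask])
    return np.column_stack(cols)


def pearson_matrix(stack: EnvStack, layer_subset: Sequence[str] | None = None):
    """Pairwise Pearson correlations over valid cells.

    Returns ``(matrix, names, flagged)`` where correlations involving a
    layer constant over valid cells are NaN and that layer is flagged.
    """
    names = list(layer_subset) if layer_subset is not None else [
        lyr.name for lyr in stack.layers if lyr.kind == "continuous"
    ]
    if len(names) < 2:
        raise ContractError("need at least two continuous layers")
    data = _continuous_matrix(stack, names)
    sd = data.std(axis=0)
    flagged = [names[j] for j in range(len(names)) if sd[j] == 0]
    with np.errstate(invalid="ignore", divide="ignore"):
        mat = np.corrcoef(data, rowvar=False)
    mat = np.asarray(mat, dtype=float)
    for j, name in enumerate(names):
        if name in flagged:
            mat[j, :] = np.nan
            mat[:, j] = np.nan
    np.fill_diagonal(mat, 1.0)
    return mat, names, flagged


def correlation_filter(stack: EnvStack, r_max: float = DEFAULT_R_MAX) -> ScreeningReport:
    """Greedy pairwise filter: while any kept pair has |r| >= r_max, drop
    the member of the worst (largest |r|) pair with the larger mean
    absolute correlation to the remaining variables; ties drop the later
    name in input order. Deterministic.
    """
    mat, names, flagged = pearson_matrix(stack)
    order = {n: i for i, n in enumerate(names)}
    kept = list(names)
    dropped: list[dict] = []

    def sub(names_now):
        idx = [order[n] for n in names_now]
        return mat[np.ix_(idx, idx)]

    while len(kept) >= 2:
        m = np.abs(sub(kept))
        np.fill_diagonal(m, 0.0)
        m_cmp = np.nan_to_num(m, nan=0.0)
        worst = np.unravel_index(np.argmax(m_cmp), m_cmp.shape)
        if m_cmp[worst] < r_max:
            break
        i, j = worst
        mean_i = np.nanmean(np.delete(m[i], i))
        mean_j = np.nanmean(np.delete(m[j], j))
        if mean_i > mean_j:
            drop, partner = i, j
        elif mean_j > mean_i:
            drop, partner = j, i
        else:  # tie: drop the later name in input order
            drop, partner = (i, j) if order[kept[i]] > order[kept[j]] else (j, i)
        dropped.append(
            {
                "name": kept[drop],
                "reason": "pearson",
                "statistic": float(m[i, j]),
                "partner": kept[partner],
            }
        )
        kept.pop(drop)

    return ScreeningReport(kept=kept, dropped=dropped, flagged=flagged, r_max=r_max)


def compute_vifs(stack: EnvStack, names: Sequence[str]) -> np.ndarray:
    """VIF_j = 1 / (1 - R^2_j) from OLS of variable j on the others.

    Variables are standardized over valid cells; the auxiliary regressions
    include an intercept. Perfect collinearity yields +inf.
    """
    data = _continuous_matrix(stack, names)
    sd = data.std(axis=0)
    sd[sd == 0] = 1.0
    z = (data - data.mean(axis=0)) / sd
    n, p = z.shape
    vifs = np.empty(p)
    for j in range(p):
        yj = z[:, j]
        design = np.column_stack([np.ones(n), np.delete(z, j, axis=1)])
        coef, _, _, _ = np.linalg.lstsq(design, yj, rcond=None)
        resid = yj - design @ coef
        sst = np.sum((yj - yj.mean()) ** 2)
        if sst == 0:
            vifs[j] = np.nan
            continue
        r2 = 1.0 - np.sum(resid**2) / sst
        vifs[j] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return vifs


def vif_filter(stack: EnvStack, vif_max: float = DEFAULT_VIF_MAX) -> ScreeningReport:
    """Iterative VIF screen: drop the max-VIF variable while the max VIF
    is >= vif_max (ties broken by input order). Run after the correlation
    filter. Layers constant over valid cells are exempt (VIF undefined).
    """
    names = [lyr.name for lyr in stack.layers if lyr.kind == "continuous"]
    kept = list(names)
    dropped: list[dict] = []
    while len(kept) >= 2:
        vifs = compute_vifs(stack, kept)
        vifs_cmp = np.nan_to_num(vifs, nan=0.0)
        worst = int(np.argmax(vifs_cmp))
        if not vifs_cmp[worst] >= vif_max:
            break
        dropped.append(
            {
                "name": kept[worst],
                "reason": "vif",
                "statistic": float(vifs[worst]),
                "partner": "",
            }
        )
        kept.pop(worst)
    return ScreeningReport(kept=kept, dropped=dropped, vif_max=vif_max)


def screen(
    stack: EnvStack,
    r_max: float = DEFAULT_R_MAX,
    vif_max: float = DEFAULT_VIF_MAX,
) -> ScreeningReport:
    """Full screen: Pearson filter, then VIF filter on the survivors.

    Categorical layers pass through untouched and are appended to ``kept``
    in their stack order.
    """
    continuous = [lyr.name for lyr in stack.layers if lyr.kind == "continuous"]
    categorical = [lyr.name for lyr in stack.layers if lyr.kind == "categorical"]
    if len(continuous) < 2:
        report = ScreeningReport(kept=continuous, r_max=r_max, vif_max=vif_max)
    else:
        rep1 = correlation_filter(stack, r_max)
        survivors = rep1.kept
        if len(survivors) >= 2:
            rep2 = vif_filter(stack.subset(survivors + categorical), vif_max)
            report = rep1.merge(rep2)
        else:
            report = rep1
    report.kept = report.kept + categorical
    return report
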