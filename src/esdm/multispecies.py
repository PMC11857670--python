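"""Conservation-value scoring and weighted multi-species habitat overlay.

Each species is scored on three ordinal scales — national protection
level, Red List status, and CITES appendix — averaged into a conservation
value I, normalized into weights P_i = I_i / sum_j I_j, and used for a
per-cell weighted superposition of single-species suitability maps.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from esdm.env_layers import Layer
from esdm.errors import ContractError, FormatError

GRADE_SCORES = {"I": 1.0, "II": 0.5, "III": 0.3, "non-protected": 0.1}
REDLIST_SCORES = {"CR": 1.0, "EN": 0.8, "VU": 0.6, "NT": 0.4, "LC": 0.2, "NE": 0.1}
CITES_SCORES = {"I": 1.0, "II": 0.6, "III": 0.3, "not-listed": 0.1}

# full-width Roman numerals as they appear in status tables
_ROMAN = {"Ⅰ": "I", "Ⅱ": "II", "Ⅲ": "III"}


def _normalize(value, blank: str) -> str:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return blank
    text = str(value).strip()
    if not text:
        return blank
    return _ROMAN.get(text, text)


@dataclass(frozen=True)
class SpeciesStatus:
    species: str
    national_level: str = "non-protected"
    redlist: str = "NE"
    cites: str = "not-listed"

    def __post_init__(self) -> None:
        if self.national_level not in GRADE_SCORES:
            raise ContractError(f"unknown national level {self.national_level!r}")
        if self.redlist not in REDLIST_SCORES:
            raise ContractError(f"unknown Red List status {self.redlist!r}")
        if self.cites not in CITES_SCORES:
            raise ContractError(f"unknown CITES appendix {self.cites!r}")


def score_status(status: SpeciesStatus) -> tuple[float, float, float]:
    """(I_grade, I_endangered, I_CITES) from the ordinal scales."""
    return (
        GRADE_SCORES[status.national_level],
        REDLIST_SCORES[status.redlist],
        CITES_SCORES[status.cites],
    )


def conservation_value(components: Sequence[float]) -> float:
    """Mean of the three component scores."""
    if len(components) != 3:
        raise ContractError("expected exactly three component scores")
    return float(sum(components)) / 3.0


def species_weights(values: Sequence[float]) -> list[float]:
    """Normalize conservation values into weights summing to 1."""
    values = [float(v) for v in values]
    if not values:
        raise ContractError("species set must be non-empty")
    if any(v <= 0 for v in values):
        raise ContractError("conservation values must be positive")
    total = sum(values)
    return [v / total for v in values]


def round_report(value: float, decimals: int = 3) -> float:
    """Half-up rounding used only at report time."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def load_status_table(path) -> list[SpeciesStatus]:
    """Read ``species,national_level,redlist,cites`` CSV; blanks score lowest."""
    try:
        df = pd.read_csv(path, dtype=str)
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"could not read status CSV {path}: {exc}") from exc
    required = {"species", "national_level", "redlist", "cites"}
    if not required.issubset(df.columns):
        raise FormatError(f"status CSV must have columns {sorted(required)}")
    out = []
    for _, row in df.iterrows():
        out.append(
            SpeciesStatus(
                species=str(row["species"]).strip(),
                national_level=_normalize(row["national_level"], "non-protected"),
                redlist=_normalize(row["redlist"], "NE"),
                cites=_normalize(row["cites"], "not-listed"),
            )
        )
    return out


def conservation_weights(statuses: Sequence[SpeciesStatus]) -> pd.DataFrame:
    """Score a species set: components, conservation value I, and weight P."""
    rows = []
    for st in statuses:
        g, e, c = score_status(st)
        rows.append(
            {
                "species": st.species,
                "I_grade": g,
                "I_endangered": e,
                "I_CITES": c,
                "I": conservation_value((g, e, c)),
            }
        )
    df = pd.DataFrame(rows)
    df["weight"] = species_weights(df["I"].tolist())
    return df


def stack_multispecies(maps: Sequence[Layer], weights: Sequence[float]) -> Layer:
    """Per-cell weighted sum of aligned suitability maps.

    A cell is valid iff valid in every map; weights should come from
    :func:`species_weights` so the output stays in [0, 1].
    """
    if len(maps) != len(weights):
        raise ContractError("one weight per map required")
    if not maps:
        raise ContractError("need at least one map")
    grid = maps[0].grid
    for m in maps[1:]:
        if not m.grid.aligned_with(grid):
            raise ContractError(f"map {m.name!r} is not aligned")
    valid = np.ones((grid.n_rows, grid.n_cols), dtype=bool)
    for m in maps:
        valid &= m.valid_mask
    combined = np.zeros((grid.n_rows, grid.n_cols))
    for m, w in zip(maps, weights):
        combined = combined + float(w) * np.nan_to_num(m.values, nan=0.0)
    combined[~valid] = np.nan
    return Layer("multispecies", "continuous", combined, grid)
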