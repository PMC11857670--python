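"""Presence points, pseudo-absence sampling, and covariate extraction.

Presence-only records are snapped to grid cells; class balance is obtained
by drawing as many pseudo-absences as retained presences, uniformly without
replacement from valid non-presence cells.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from esdm.env_layers import EnvStack, GridSpec
from esdm.errors import CapacityError, ContractError, FormatError

log = logging.getLogger(__name__)


@dataclass
class OccurrenceSet:
    species: str
    presences: list[tuple[float, float, int]] = field(default_factory=list)
    absences: list[int] = field(default_factory=list)
    seed: int | None = None
    n_dropped: int = 0

    @property
    def presence_cells(self) -> list[int]:
        return [cell for _, _, cell in self.presences]

    def labels(self) -> tuple[np.ndarray, np.ndarray]:
        """(cells, y) with presences labelled 1 and absences 0."""
        cells = np.array(self.presence_cells + list(self.absences), dtype=int)
        y = np.concatenate(
            [np.ones(len(self.presences), dtype=int), np.zeros(len(self.absences), dtype=int)]
        )
        return cells, y

    def to_json(self) -> str:
        return json.dumps(
            {
                "species": self.species,
                "presences": [[x, y, int(c)] for x, y, c in self.presences],
                "absences": [int(c) for c in self.absences],
                "seed": self.seed,
                "n_dropped": self.n_dropped,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "OccurrenceSet":
        d = json.loads(text)
        return cls(
            species=d["species"],
            presences=[(x, y, int(c)) for x, y, c in d["presences"]],
            absences=[int(c) for c in d["absences"]],
            seed=d.get("seed"),
            n_dropped=d.get("n_dropped", 0),
        )


def load_occurrences(
    path,
    grid: GridSpec,
    species: str | None = None,
    valid_mask: np.ndarray | None = None,
    dedupe: bool = True,
) -> dict[str, OccurrenceSet] | OccurrenceSet:
    """Read a ``species,x,y`` CSV and snap points to containing cells.

    Off-grid points and points on invalid cells are dropped (counted in
    ``n_dropped``). With ``dedupe`` at most one presence per cell survives
    (first record wins). Returns one OccurrenceSet per species, or a single
    set if ``species`` is given.
    """
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"could not read occurrence CSV {path}: {exc}") from exc
    required = {"species", "x", "y"}
    if not required.issubset(df.columns):
        raise FormatError(f"occurrence CSV must have columns {sorted(required)}")
    for col in ("x", "y"):
        if not pd.api.types.is_numeric_dtype(df[col]):
            raise FormatError(f"occurrence column {col!r} must be numeric")

    out: dict[str, OccurrenceSet] = {}
    for sp, sub in df.groupby("species", sort=True):
        occ = OccurrenceSet(species=str(sp))
        seen: set[int] = set()
        for x, y in zip(sub["x"].to_numpy(float), sub["y"].to_numpy(float)):
            r, c = grid.point_to_cell(x, y)
            r, c = int(r), int(c)
            if not (0 <= r < grid.n_rows and 0 <= c < grid.n_cols):
                occ.n_dropped += 1
                continue
            if valid_mask is not None and not valid_mask[r, c]:
                occ.n_dropped += 1
                continue
            cell = int(grid.flat_index(r, c))
            if dedupe and cell in seen:
                occ.n_dropped += 1
                continue
            seen.add(cell)
            occ.presences.append((float(x), float(y), cell))
        if occ.n_dropped:
            log.info("%s: dropped %d occurrence points", sp, occ.n_dropped)
        out[str(sp)] = occ
    if species is not None:
        if species not in out:
            raise FormatError(f"species {species!r} not present in {path}")
        return out[species]
    return out


def sample_pseudo_absences(
    grid: GridSpec,
    valid_mask: np.ndarray,
    presence_cells,
    n: int,
    seed: int,
) -> list[int]:
    """Draw ``n`` distinct cells uniformly from valid non-presence cells."""
    eligible = np.flatnonzero(valid_mask.ravel())
    eligible = np.setdiff1d(eligible, np.asarray(list(presence_cells), dtype=int))
    if n > eligible.size:
        raise CapacityError(
            f"requested {n} pseudo-absences but only {eligible.size} eligible cells"
        )
    rng = np.random.default_rng(seed)
    picked = rng.choice(eligible, size=n, replace=False)
    return [int(c) for c in picked]


def add_pseudo_absences(occ: OccurrenceSet, stack: EnvStack, seed: int) -> OccurrenceSet:
    """Complete an OccurrenceSet with as many absences as presences."""
    occ.absences = sample_pseudo_absences(
        stack.grid, stack.valid_mask, occ.presence_cells, len(occ.presences), seed
    )
    occ.seed = seed
    return occ


def categorical_codes(stack: EnvStack) -> dict[str, list[int]]:
    """Sorted category codes per categorical layer, over valid cells."""
    mask = stack.valid_mask
    return {
        lyr.name: sorted(int(v) for v in np.unique(lyr.values[mask]))
        for lyr in stack.layers
        if lyr.kind == "categorical"
    }


def extract_covariates(cells, stack: EnvStack) -> pd.DataFrame:
    """Design table for a list of flat cell indices.

    Continuous layers contribute one column each; categorical layers are
    one-hot expanded over the codes present in the full stack, columns
    named ``layer=code``. Column order follows stack order, codes sorted.
    """
    cells = np.asarray(list(cells), dtype=int)
    grid = stack.grid
    rows, cols = np.divmod(cells, grid.n_cols)
    mask = stack.valid_mask
    if not np.all(mask[rows, cols]):
        bad = cells[~mask[rows, cols]][:5]
        raise ContractError(f"cells on nodata requested (e.g. {bad.tolist()})")
    codes = categorical_codes(stack)
    data: dict[str, np.ndarray] = {}
    for lyr in stack.layers:
        vals = lyr.values[rows, cols]
        if lyr.kind == "continuous":
            data[lyr.name] = vals
        else:
            for code in codes[lyr.name]:
                data[f"{lyr.name}={code}"] = (vals == code).astype(float)
    return pd.DataFrame(data, index=cells)
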