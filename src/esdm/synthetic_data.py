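"""Synthetic landscapes and virtual species with known truth.

Gaussian random fields come from separable smoothing of white noise (then
standardized to mean 0, sd 1 over valid cells); correlated layer pairs mix
a source field with independent noise so the implied Pearson correlation
is ``mix / sqrt(mix^2 + (1 - mix)^2)``. A virtual species is a logistic
function of chosen layers, and presences are sampled with probability
proportional to true suitability.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage

from esdm.env_layers import EnvStack, GridSpec, Layer
from esdm.errors import ContractError
from esdm.occurrence import OccurrenceSet


@dataclass(frozen=True)
class LayerSpec:
    """One generated layer: gradient | gaussian_field | categorical | copy_of."""

    name: str
    generator: Literal["gradient", "gaussian_field", "categorical", "copy_of"]
    correlation_length: float = 5.0
    k: int = 3
    source: str = ""
    mix: float = 0.8


@dataclass
class LandscapeSpec:
    grid: GridSpec
    layers: list[LayerSpec] = field(default_factory=list)
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(
            {
                "grid": {
                    "n_rows": self.grid.n_rows,
                    "n_cols": self.grid.n_cols,
                    "cell_size": self.grid.cell_size,
                    "origin_x": self.grid.origin_x,
                    "origin_y": self.grid.origin_y,
                    "crs_tag": self.grid.crs_tag,
                    "nodata_value": self.grid.nodata_value,
                },
                "layers": [vars(ls) for ls in self.layers],
                "seed": self.seed,
            },
            indent=2,
        )


def mixture_correlation(mix: float) -> float:
    """Pearson r implied by mixing a unit field with independent noise."""
    return mix / np.sqrt(mix**2 + (1.0 - mix) ** 2)


def _standardize(values: np.ndarray) -> np.ndarray:
    sd = values.std()
    if sd == 0:
        return values - values.mean()
    return (values - values.mean()) / sd


def _gaussian_field(shape, correlation_length: float, rng: np.random.Generator):
    noise = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(noise, sigma=correlation_length, mode="reflect")
    return _standardize(smooth)


def generate_landscape(spec: LandscapeSpec) -> EnvStack:
    """Deterministic landscape from a :class:`LandscapeSpec`."""
    grid = spec.grid
    shape = (grid.n_rows, grid.n_cols)
    rng = np.random.default_rng(spec.seed)
    built: dict[str, Layer] = {}
    layers: list[Layer] = []
    for ls in spec.layers:
        if ls.generator == "gradient":
            cols = np.broadcast_to(
                np.arange(grid.n_cols, dtype=float), shape
            ).copy()
            values = _standardize(cols)
            kind = "continuous"
        elif ls.generator == "gaussian_field":
            values = _gaussian_field(shape, ls.correlation_length, rng)
            kind = "continuous"
        elif ls.generator == "categorical":
            base = _gaussian_field(shape, ls.correlation_length, rng)
            edges = np.quantile(base, np.linspace(0, 1, ls.k + 1)[1:-1])
            values = (np.digitize(base, edges) + 1).astype(float)
            kind = "categorical"
        elif ls.generator == "copy_of":
            if ls.source not in built:
                raise ContractError(
                    f"copy_of layer {ls.name!r} references unknown source {ls.source!r}"
                )
            if not 0.0 <= ls.mix <= 1.0:
                raise ContractError("mix coefficient must be in [0, 1]")
            src = _standardize(built[ls.source].values)
            noise = _standardize(rng.standard_normal(shape))
            values = _standardize(ls.mix * src + (1.0 - ls.mix) * noise)
            kind = "continuous"
        else:
            raise ContractError(f"unknown generator {ls.generator!r}")
        layer = Layer(ls.name, kind, values, grid)
        built[ls.name] = layer
        layers.append(layer)
    return EnvStack(layers)


@dataclass(frozen=True)
class Response:
    kind: Literal["linear", "gaussian"] = "linear"
    weight: float = 1.0
    center: float = 0.0
    width: float = 1.0


@dataclass
class VirtualSpecies:
    """Known truth: logistic(intercept + sum of per-layer responses)."""

    name: str
    responses: dict[str, Response]
    intercept: float = 0.0

    def __post_init__(self) -> None:
        if not any(r.weight != 0 for r in self.responses.values()):
            # constant 0.5 suitability everywhere: legal but usually a mistake
            import warnings

            warnings.warn(
                f"virtual species {self.name!r} has no nonzero response weight",
                stacklevel=3,
            )


def true_suitability(vs: VirtualSpecies, stack: EnvStack) -> Layer:
    """Ground-truth suitability raster in (0, 1) over valid cells."""
    grid = stack.grid
    eta = np.full((grid.n_rows, grid.n_cols), vs.intercept, dtype=float)
    for name, resp in vs.responses.items():
        if name not in stack:
            raise ContractError(f"virtual species references missing layer {name!r}")
        lyr = stack[name]
        if lyr.kind != "continuous":
            raise ContractError(
                f"virtual species response on categorical layer {name!r}"
            )
        v = lyr.values
        if resp.kind == "linear":
            eta = eta + resp.weight * v
        elif resp.kind == "gaussian":
            eta = eta + resp.weight * np.exp(-0.5 * ((v - resp.center) / resp.width) ** 2)
        else:
            raise ContractError(f"unknown response kind {resp.kind!r}")
    suit = 1.0 / (1.0 + np.exp(-eta))
    suit[~stack.valid_mask] = np.nan
    return Layer(f"truth_{vs.name}", "continuous", suit, grid)


def sample_virtual_occurrences(
    vs: VirtualSpecies,
    stack: EnvStack,
    n_presence: int,
    seed: int,
    mode: Literal["proportional", "bernoulli"] = "proportional",
) -> OccurrenceSet:
    """Presence cells drawn with probability proportional to suitability.

    ``proportional`` draws ``n_presence`` cells with replacement then
    deduplicates (so the retained count may be smaller); ``bernoulli``
    flips one coin per valid cell with p = suitability (``n_presence``
    ignored). Reproducible by seed.
    """
    if mode == "proportional" and n_presence < 1:
        raise ContractError("n_presence must be >= 1")
    truth = true_suitability(vs, stack)
    grid = stack.grid
    mask = stack.valid_mask
    valid_cells = np.flatnonzero(mask.ravel())
    p = truth.values.ravel()[valid_cells]
    if p.sum() <= 0:
        raise ContractError("zero suitability mass everywhere")
    rng = np.random.default_rng(seed)
    if mode == "proportional":
        draws = rng.choice(valid_cells, size=n_presence, replace=True, p=p / p.sum())
        cells = list(dict.fromkeys(int(c) for c in draws))  # dedupe, keep order
    elif mode == "bernoulli":
        hits = rng.random(valid_cells.size) < p
        cells = [int(c) for c in valid_cells[hits]]
    else:
        raise ContractError(f"unknown sampling mode {mode!r}")
    occ = OccurrenceSet(species=vs.name, seed=seed)
    for cell in cells:
        r, c = divmod(cell, grid.n_cols)
        x, y = grid.cell_center(r, c)
        occ.presences.append((float(x), float(y), cell))
    return occ


def default_fixture_spec(
    n_rows: int = 80, n_cols: int = 80, seed: int = 0
) -> LandscapeSpec:
    """A small landscape exercising every generator and the screens:
    a dominant field, independent noise fields, a near-duplicate pair
    (mix 0.9, implied r ~ 0.994), and a categorical land-class layer.

    The near-duplicate copies a *noise* layer so the correlation screen
    never removes a layer that a virtual species depends on.
    """
    grid = GridSpec(
        n_rows=n_rows,
        n_cols=n_cols,
        cell_size=30.0,
        origin_x=0.0,
        origin_y=n_rows * 30.0,
        crs_tag="local",
    )
    return LandscapeSpec(
        grid=grid,
        layers=[
            LayerSpec("elev", "gaussian_field", correlation_length=8.0),
            LayerSpec("moisture", "gaussian_field", correlation_length=5.0),
            LayerSpec("greenness", "gaussian_field", correlation_length=4.0),
            LayerSpec("green_twin", "copy_of", source="greenness", mix=0.9),
            LayerSpec("landclass", "categorical", correlation_length=6.0, k=3),
        ],
        seed=seed,
    )


def write_fixture(
    out_dir,
    spec: LandscapeSpec | None = None,
    species: Sequence[tuple[VirtualSpecies, dict]] | None = None,
    n_presence: int = 150,
    seed: int = 0,
) -> dict:
    """Emit a complete on-disk fixture: GeoTIFF stack + manifest,
    occurrence CSV, status CSV, truth GeoTIFFs, and the landscape spec.

    ``species`` pairs each VirtualSpecies with a status mapping
    (national_level / redlist / cites). Returns the path manifest.
    """
    from pathlib import Path

    from esdm.env_layers import write_raster

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = spec or default_fixture_spec(seed=seed)
    stack = generate_landscape(spec)
    if species is None:
        species = [
            (
                VirtualSpecies(
                    "virtual_a", {"elev": Response("linear", 5.0)}, intercept=-6.0
                ),
                {"national_level": "II", "redlist": "VU", "cites": "not-listed"},
            ),
            (
                VirtualSpecies(
                    "virtual_b",
                    {"moisture": Response("linear", 4.0), "elev": Response("linear", 1.0)},
                    intercept=-5.0,
                ),
                {"national_level": "non-protected", "redlist": "LC", "cites": "II"},
            ),
        ]

    manifest = {"layers": []}
    for lyr in stack.layers:
        path = out / f"layer_{lyr.name}.tif"
        write_raster(lyr, path)
        manifest["layers"].append({"path": path.name, "name": lyr.name, "kind": lyr.kind})
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    occ_lines = ["species,x,y"]
    status_lines = ["species,national_level,redlist,cites"]
    sample_seeds = np.random.SeedSequence(seed).spawn(len(species))
    for (vs, status), child in zip(species, sample_seeds):
        occ = sample_virtual_occurrences(
            vs, stack, n_presence, int(child.generate_state(1)[0])
        )
        for x, y, _ in occ.presences:
            occ_lines.append(f"{vs.name},{x},{y}")
        status_lines.append(
            f"{vs.name},{status.get('national_level', '')},"
            f"{status.get('redlist', '')},{status.get('cites', '')}"
        )
        write_raster(true_suitability(vs, stack), out / f"truth_{vs.name}.tif")
    (out / "occurrences.csv").write_text("\n".join(occ_lines) + "\n")
    (out / "status.csv").write_text("\n".join(status_lines) + "\n")
    (out / "landscape_spec.json").write_text(spec.to_json())
    return {
        "manifest": str(out / "manifest.json"),
        "occurrences": str(out / "occurrences.csv"),
        "status": str(out / "status.csv"),
    }
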