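"""End-to-end orchestration: screen, occurrences, ensembles, overlay.

A run is driven by one declarative config (YAML or dict) and writes, under
``output_dir``: per-species ensemble GeoTIFFs, metrics and contribution
JSON, the multi-species overlay GeoTIFF with its weight table, and a
machine-readable run report capturing every seed and threshold consumed.
Identical configs produce byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from esdm.ensemble_eval import (
    DEFAULT_AUC_CUTOFF,
    DEFAULT_HOLDOUT,
    DEFAULT_N_REPLICATES,
    build_ensemble,
    jackknife_contribution,
)
from esdm.env_layers import EnvStack, align_stack, read_raster, write_raster
from esdm.errors import EsdmError, FormatError, NoAdmissibleModelError
from esdm.multispecies import (
    conservation_weights,
    load_status_table,
    round_report,
    species_weights,
    stack_multispecies,
)
from esdm.occurrence import add_pseudo_absences, load_occurrences
from esdm.screening import DEFAULT_R_MAX, DEFAULT_VIF_MAX, screen
from esdm.sdm_core import ALGORITHMS

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    stack_manifest: str
    occurrences: str
    status: str
    output_dir: str
    r_max: float = DEFAULT_R_MAX
    vif_max: float = DEFAULT_VIF_MAX
    auc_cutoff: float = DEFAULT_AUC_CUTOFF
    replicates: int = DEFAULT_N_REPLICATES
    holdout: float = DEFAULT_HOLDOUT
    algorithms: list[str] = field(default_factory=lambda: list(ALGORITHMS))
    hyperparams: dict = field(default_factory=dict)
    seed: int = 0
    resample_method: str = "nearest"

    def __post_init__(self) -> None:
        if not 0 < self.holdout < 1:
            raise FormatError("holdout fraction must be in (0, 1)")
        if self.replicates < 1:
            raise FormatError("replicates must be >= 1")
        if not self.algorithms or not set(self.algorithms) <= set(ALGORITHMS):
            raise FormatError(
                f"algorithms must be a non-empty subset of {ALGORITHMS}"
            )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise FormatError(f"config {path} is not a mapping")
        base = Path(path).parent
        for key in ("stack_manifest", "occurrences", "status", "output_dir"):
            if key in raw and not Path(raw[key]).is_absolute():
                raw[key] = str(base / raw[key])
        return cls(**raw)

    def ensemble_config(self) -> dict:
        return {
            "auc_cutoff": self.auc_cutoff,
            "replicates": self.replicates,
            "holdout": self.holdout,
            "hyperparams": self.hyperparams,
            "algorithms": self.algorithms,
        }


def load_stack(manifest_path, method: str = "nearest") -> EnvStack:
    """Read a manifest (JSON list of raster paths) and align the layers.

    The first layer's grid is the alignment target. Relative paths resolve
    against the manifest's directory.
    """
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    entries = manifest["layers"] if isinstance(manifest, dict) else manifest
    layers = []
    for entry in entries:
        if isinstance(entry, str):
            entry = {"path": entry}
        p = Path(entry["path"])
        if not p.is_absolute():
            p = manifest_path.parent / p
        lyr = read_raster(p)
        if "name" in entry:
            lyr.name = entry["name"]
        if "kind" in entry:
            lyr.kind = entry["kind"]
        layers.append(lyr)
    if not layers:
        raise FormatError(f"empty stack manifest {manifest_path}")
    return align_stack(layers, layers[0].grid, method=method)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the run report (also written to disk)."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "seed": config.seed,
        "thresholds": {
            "r_max": config.r_max,
            "vif_max": config.vif_max,
            "auc_cutoff": config.auc_cutoff,
        },
        "replicates": config.replicates,
        "holdout": config.holdout,
        "algorithms": list(config.algorithms),
        "species": {},
    }

    stack = load_stack(config.stack_manifest, config.resample_method)
    screening = screen(stack, config.r_max, config.vif_max)
    (out / "screening.json").write_text(screening.to_json())
    report["screening"] = json.loads(screening.to_json())
    kept_stack = stack.subset(screening.kept)

    occ_by_species = load_occurrences(
        config.occurrences, stack.grid, valid_mask=kept_stack.valid_mask
    )
    statuses = {st.species: st for st in load_status_table(config.status)}

    species_names = sorted(occ_by_species)
    children = np.random.SeedSequence(config.seed).spawn(len(species_names))
    ens_cfg = config.ensemble_config()

    maps = {}
    for sp, child in zip(species_names, children):
        occ = occ_by_species[sp]
        absence_seed, model_seed = (int(s) for s in child.generate_state(2))
        sp_report: dict = {
            "n_presences": len(occ.presences),
            "n_dropped": occ.n_dropped,
            "absence_seed": absence_seed,
            "model_seed": model_seed,
        }
        report["species"][sp] = sp_report
        try:
            add_pseudo_absences(occ, kept_stack, absence_seed)
            model, ens_map = build_ensemble(
                occ, kept_stack, config=ens_cfg, seed=model_seed
            )
            contributions = jackknife_contribution(
                occ,
                kept_stack,
                config=ens_cfg,
                seed=model_seed,
                full=(model, ens_map),
            )
        except NoAdmissibleModelError as exc:
            log.warning("species %s excluded: %s", sp, exc)
            sp_report["status"] = "no_admissible_model"
            sp_report["mean_auc"] = {}
            continue
        except EsdmError as exc:
            raise EsdmError(f"[ensemble:{sp}] {exc}") from exc

        sp_report["status"] = "ok"
        sp_report["weights"] = model.weights
        sp_report["h"] = model.h
        sp_report["mean_auc"] = model.mean_auc
        sp_report["mean_tss"] = model.mean_tss
        sp_report["ensemble_auc"] = model.auc
        sp_report["ensemble_tss"] = model.tss
        sp_report["weighted_member_auc"] = model.weighted_member_auc()
        sp_report["weighted_member_tss"] = model.weighted_member_tss()
        maps[sp] = ens_map
        safe = sp.replace(" ", "_")
        write_raster(ens_map, out / f"ensemble_{safe}.tif")
        (out / f"metrics_{safe}.json").write_text(
            json.dumps(
                {
                    "weights": model.weights,
                    "h": model.h,
                    "cutoff": model.cutoff,
                    "mean_auc": model.mean_auc,
                    "mean_tss": model.mean_tss,
                    "ensemble_auc": model.auc,
                    "ensemble_tss": model.tss,
                    "replicates": [asdict(r) for r in model.evaluation.results],
                },
                indent=2,
            )
        )
        (out / f"contribution_{safe}.json").write_text(
            json.dumps(contributions, indent=2)
        )

    # multi-species overlay over modelled species, Eq-style renormalization
    modelled = [sp for sp in species_names if sp in maps]
    if modelled:
        missing_status = [sp for sp in modelled if sp not in statuses]
        if missing_status:
            raise FormatError(f"status table lacks species: {missing_status}")
        table = conservation_weights([statuses[sp] for sp in modelled])
        weights = species_weights(table["I"].tolist())
        overlay = stack_multispecies([maps[sp] for sp in modelled], weights)
        write_raster(overlay, out / "multispecies.tif")
        weight_rows = {
            row["species"]: {
                "I_grade": row["I_grade"],
                "I_endangered": row["I_endangered"],
                "I_CITES": row["I_CITES"],
                "I": row["I"],
                "weight": w,
                "weight_rounded": round_report(w),
            }
            for (_, row), w in zip(table.iterrows(), weights)
        }
        (out / "weights.json").write_text(json.dumps(weight_rows, indent=2))
        report["overlay"] = {"species": modelled, "weights": weight_rows}
    else:
        report["overlay"] = {"species": [], "weights": {}}

    (out / "run_report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
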