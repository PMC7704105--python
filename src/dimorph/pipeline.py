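"""End-to-end pipeline: simulate -> preprocess -> effects -> trait-level
meta-analysis -> condensing of correlated traits -> second-order aggregation.

Every stage writes a plain CSV into the output directory and the run is
summarised in ``manifest.json`` (seed, config hash, per-stage row counts,
exclusion tallies), so a run is fully reproducible and auditable. Re-running
with the same configuration produces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import preprocess as pp
from . import synthdata
from .effects import ES_TYPES, compute_effect_sizes
from .metamodel import fit_all_traits
from .rve import DEFAULT_RHO, condense_traits
from .secondorder import run_second_order

__all__ = ["PipelineConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failed; message carries the stage name and cause."""


_KNOWN_KEYS = {
    "records_path", "trait_map_path", "simulation", "es_types", "target_age_days",
    "min_age", "max_age", "min_per_sex", "min_institutions", "rho", "alpha",
    "outdir", "seed", "min_k",
}


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs; unknown YAML keys are rejected."""

    outdir: str = "dimorph_run"
    seed: int = 0
    records_path: str | None = None
    trait_map_path: str | None = None
    simulation: dict | None = None
    es_types: tuple[str, ...] = ES_TYPES
    target_age_days: float = 100.0
    min_age: float = 100.0
    max_age: float = 500.0
    min_per_sex: int = 6
    min_institutions: int = 2
    min_k: int = 2
    rho: float = DEFAULT_RHO
    alpha: float = 0.05

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "es_types" in raw:
            raw["es_types"] = tuple(raw["es_types"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["es_types"] = list(self.es_types)
        return d


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the manifest (also written to disk)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "config": config.to_dict(),
        "config_hash": _config_hash(config),
        "stages": {},
    }

    def stage(name, fn):
        try:
            return fn()
        except Exception as exc:  # noqa: BLE001 - rewrap with stage context
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    # --- input: simulate or load -------------------------------------------
    if config.records_path is not None:
        def _load():
            records = pp.read_records(config.records_path)
            if config.trait_map_path is None:
                raise ValueError("records_path requires trait_map_path")
            trait_map = pd.read_csv(config.trait_map_path, dtype=str).fillna({"subgroup_id": ""})
            return records, trait_map
        records, trait_map = stage("load", _load)
    else:
        sim_kwargs = dict(config.simulation or {})
        sim_kwargs.setdefault("seed", config.seed)
        sim = synthdata.SimulationConfig(**sim_kwargs)
        records, trait_map, truth = stage("simulate", lambda: synthdata.generate_dataset(sim))
        stage("simulate", lambda: synthdata.write_dataset(records, trait_map, truth, outdir))
    manifest["stages"]["input"] = {"n_records": len(records), "n_traits_mapped": len(trait_map)}

    # --- preprocess --------------------------------------------------------
    def _pre():
        summaries, exclusions = pp.preprocess(
            records,
            target_age_days=config.target_age_days,
            min_age=config.min_age,
            max_age=config.max_age,
            min_per_sex=config.min_per_sex,
            min_institutions=config.min_institutions,
        )
        return summaries, exclusions
    summaries, exclusions = stage("preprocess", _pre)
    summaries.to_csv(outdir / "population_summaries.csv", index=False)
    exclusions.to_csv(outdir / "exclusions.csv", index=False)
    manifest["stages"]["preprocess"] = {
        "n_populations": len(summaries),
        "n_traits": int(summaries["trait_id"].nunique()),
        "n_excluded_populations": len(exclusions),
        "exclusion_reasons": exclusions["reason"].value_counts().to_dict(),
    }
    if summaries.empty:
        raise PipelineError("stage 'preprocess' failed: no_traits_after_filters")

    # --- effect sizes ------------------------------------------------------
    effect_sizes = stage("effects", lambda: compute_effect_sizes(summaries, config.es_types))
    effect_sizes.to_csv(outdir / "effect_sizes.csv", index=False)
    manifest["stages"]["effects"] = {"n_effect_sizes": len(effect_sizes)}

    # --- trait-level multilevel meta-analysis ------------------------------
    meta = stage("metamodel", lambda: fit_all_traits(effect_sizes, min_k=config.min_k))
    meta.to_csv(outdir / "trait_meta_results.csv", index=False)
    converged = meta[meta["converged"]]
    manifest["stages"]["metamodel"] = {
        "n_fits": len(meta),
        "n_converged": len(converged),
        "n_excluded_nonconverged": int(len(meta) - len(converged)),
    }
    if converged.empty:
        raise PipelineError("stage 'metamodel' failed: no_traits_after_filters")

    # --- condense correlated traits ---------------------------------------
    condensed = stage(
        "rve", lambda: condense_traits(
            converged.merge(trait_map[["trait_id", "functional_group"]], on="trait_id"),
            trait_map, rho=config.rho,
        )
    )
    condensed.to_csv(outdir / "condensed_results.csv", index=False)
    clusters = trait_map[trait_map["subgroup_id"].astype(str) != ""]
    clusters.to_csv(outdir / "clusters.csv", index=False)
    manifest["stages"]["rve"] = {
        "n_trait_results": len(converged),
        "n_condensed_rows": len(condensed),
        "n_subgroups": int(clusters["subgroup_id"].nunique()) if len(clusters) else 0,
    }

    # --- second-order ------------------------------------------------------
    def _second():
        cond = condensed.copy()
        import numpy as np
        from scipy import stats as st
        z = st.norm.ppf(1 - config.alpha / 2)
        cond["ci_low"] = cond["mu_hat"] - z * cond["se"]
        cond["ci_high"] = cond["mu_hat"] + z * cond["se"]
        return run_second_order(cond, trait_map)
    second, sign_counts = stage("secondorder", _second)
    second.to_csv(outdir / "second_order_results.csv", index=False)
    sign_counts.to_csv(outdir / "sign_counts.csv", index=False)
    manifest["stages"]["secondorder"] = {
        "n_aggregates": len(second),
        "n_groups": int(sign_counts["group"].nunique()),
    }

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
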