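"""Synthetic consortium-style phenotyping data with known sex effects.

Emulates a multi-site wildtype-mouse phenotyping dataset: nine strains
partially crossed with eleven institutions, many strictly positive
continuous traits grouped into nine functional groups, clusters of
correlated traits, and configurable true sex effects on the mean (lnRR)
and on the relative variability (lnCVR), so that every downstream stage of
the pipeline can be validated against known ground truth.

Generative model (per trait, on the log scale):

    value = exp(m_sex + u_strain + u_institution + sigma_sex * z)

with trait-level baseline log-mean m, strain and institution shifts shared
by both sexes, and sex-specific residual log-SD sigma_sex. Values are
therefore lognormal: positivity is guaranteed and the raw-scale CV depends
only on sigma_log (CV = sqrt(exp(sigma_log^2) - 1)), which induces the
strong cross-trait coupling of log mean and log SD seen in real trait
panels.

Injecting the sex effects. The female residual log-SD sigma_f is drawn per
trait; the male one solves the target lnCVR exactly on the raw scale:

    sigma_m^2 = ln(1 + exp(2 lnCVR) (exp(sigma_f^2) - 1)),

and the male log-mean offset is lnRR - (sigma_m^2 - sigma_f^2)/2 so that
the raw-scale mean ratio equals exp(lnRR). The implied true lnVR is
lnCVR + lnRR.

Correlated clusters share, per animal, a latent standard-normal factor:
member traits use z = sqrt(r) a_animal + sqrt(1-r) e, giving between-trait
log-scale correlation r and hence correlated sampling errors downstream.

Seeding: one master seed; each trait consumes an independent child stream
(numpy SeedSequence spawn keys), so adding traits never perturbs the data
of existing ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["SimulationConfig", "generate_dataset", "write_dataset", "read_truth",
           "read_trait_map", "FUNCTIONAL_GROUPS"]

FUNCTIONAL_GROUPS = (
    "behaviour", "morphology", "metabolism", "physiology", "immunology",
    "hematology", "heart", "hearing", "eye",
)


class InfeasibleConfigError(ValueError):
    """Raised when a configuration cannot yield an analysable dataset."""


@dataclass
class SimulationConfig:
    """Study-design knobs for the synthetic dataset.

    Defaults mirror a large phenotyping consortium: 9 strains at 11
    institutions with partial crossing, per-population per-sex adult counts
    ~ Normal(400, 240) truncated at 6, ages spanning 65–550 days (so the
    adult filters have juveniles and aged animals to remove), and clusters
    of correlated traits covering roughly 40% of the trait panel in
    sub-groups of 2–5 (between-trait log-scale correlation 0.8).

    ``true_lnrr`` / ``true_lncvr`` may be a scalar (all traits), a sequence
    of per-trait values, or ``("normal", mu, sd)`` to draw per-trait truths.
    """

    n_strains: int = 9
    n_institutions: int = 11
    crossing_fraction: float = 0.2
    n_traits: int = 20
    n_groups: int = 9
    subgroup_spec: list[tuple[int, float]] | None = None
    n_mean: float = 400.0
    n_sd: float = 240.0
    n_min: int = 6
    true_lnrr: object = 0.0
    true_lncvr: object = 0.0
    sigma_strain: float = 0.1
    sigma_location: float = 0.1
    age_range: tuple[float, float] = (65.0, 550.0)
    adult_age_range: tuple[float, float] = (100.0, 500.0)
    juvenile_fraction: float = 0.15
    duplicate_prob: float = 0.2
    missing_rate: float = 0.02
    pops_per_trait: tuple[int, int] = (2, 18)
    base_logmean: tuple[float, float] = (2.0, 1.5)
    log_cv_location: float = -1.4
    log_cv_scale: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_strains, self.n_institutions, self.n_traits, self.n_groups) < 1:
            raise InfeasibleConfigError("all counts must be >= 1")
        if not (0 < self.crossing_fraction <= 1):
            raise InfeasibleConfigError("crossing_fraction must be in (0, 1]")
        if not (0 <= self.missing_rate < 1):
            raise InfeasibleConfigError("missing_rate must be in [0, 1)")
        if self.n_min < 2:
            raise InfeasibleConfigError("n_min must be >= 2")
        if self.n_groups > len(FUNCTIONAL_GROUPS):
            raise InfeasibleConfigError(f"at most {len(FUNCTIONAL_GROUPS)} functional groups")


def _per_trait(value, n_traits: int, rng: np.random.Generator, name: str) -> np.ndarray:
    """Expand a scalar / sequence / ("normal", mu, sd) spec to per-trait values."""
    if isinstance(value, tuple) and len(value) == 3 and value[0] == "normal":
        return rng.normal(value[1], value[2], size=n_traits)
    arr = np.asarray(value, float)
    if arr.ndim == 0:
        return np.full(n_traits, float(arr))
    if len(arr) != n_traits:
        raise InfeasibleConfigError(f"{name}: expected {n_traits} per-trait values")
    return arr


def _sigma_male(sigma_f: float, lncvr: float) -> float:
    """Male residual log-SD that realises the target raw-scale lnCVR."""
    return float(np.sqrt(np.log1p(np.exp(2.0 * lncvr) * np.expm1(sigma_f**2))))


def _default_subgroups(n_traits: int) -> list[tuple[int, float]]:
    """Clusters of sizes 2-5 covering ~40% of traits, correlation 0.8."""
    spec, used, size = [], 0, 2
    budget = int(0.4 * n_traits)
    while used + size <= budget:
        spec.append((size, 0.8))
        used += size
        size = size % 5 + 2  # cycle 2,3,4,5
    return spec


def generate_dataset(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (records, trait_map, truth) tables from a configuration.

    records: one row per animal x trait x measurement (animal_id, sex,
    strain, institution, age_days, trait_id, value). trait_map: trait_id,
    procedure, functional_group, subgroup_id. truth: per-trait true lnRR,
    lnVR, lnCVR and the generating parameters.
    """
    config.validate()
    master = np.random.SeedSequence(config.seed)
    rng0 = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(10**6,)))

    strains = [f"strain{i:02d}" for i in range(config.n_strains)]
    institutions = [f"inst{i:02d}" for i in range(config.n_institutions)]
    cells = [(s, l) for s in strains for l in institutions]
    n_cells = max(2, int(round(config.crossing_fraction * len(cells))))
    idx = rng0.choice(len(cells), size=n_cells, replace=False)
    realized = [cells[i] for i in idx]
    if len({l for _, l in realized}) < 2:
        raise InfeasibleConfigError(
            "crossing_fraction leaves fewer than 2 institutions; no trait can be eligible"
        )

    n_traits = config.n_traits
    trait_ids = [f"trait{i:03d}" for i in range(n_traits)]
    # contiguous blocks of traits per functional group
    groups = [FUNCTIONAL_GROUPS[(i * config.n_groups) // n_traits] for i in range(n_traits)]

    spec = config.subgroup_spec if config.subgroup_spec is not None else _default_subgroups(n_traits)
    subgroup_of: dict[int, tuple[str, float]] = {}
    cursor = 0
    for j, (size, corr) in enumerate(spec):
        if size < 2:
            raise InfeasibleConfigError("subgroup sizes must be >= 2")
        if cursor + size > n_traits:
            raise InfeasibleConfigError("subgroup_spec covers more traits than n_traits")
        for t in range(cursor, cursor + size):
            subgroup_of[t] = (f"sub{j:02d}", corr)
            groups[t] = groups[cursor]  # correlated traits share a functional group
        cursor += size

    lnrr = _per_trait(config.true_lnrr, n_traits, rng0, "true_lnrr")
    lncvr = _per_trait(config.true_lncvr, n_traits, rng0, "true_lncvr")

    # cluster members share the animal roster and population set so their
    # sampling errors can be correlated through a per-animal latent factor
    roster_cache: dict[str, dict] = {}

    def _build_roster(rng: np.random.Generator) -> dict:
        lo, hi = config.pops_per_trait
        n_pops = int(rng.integers(lo, min(hi, len(realized)) + 1))
        pop_idx = rng.choice(len(realized), size=n_pops, replace=False)
        pops = []
        for p in pop_idx:
            strain, inst = realized[p]
            entry = {"strain": strain, "institution": inst, "animals": {}}
            for sex in ("male", "female"):
                n_adult = max(
                    config.n_min,
                    int(round(rng.normal(config.n_mean, config.n_sd))),
                )
                n_juv = rng.binomial(n_adult, config.juvenile_fraction)
                ages_adult = rng.uniform(*config.adult_age_range, size=n_adult)
                lo_a, hi_a = config.age_range
                # juveniles below, aged animals above the adult window
                below = rng.uniform(lo_a, config.adult_age_range[0], size=(n_juv + 1) // 2)
                above = rng.uniform(config.adult_age_range[1], hi_a, size=n_juv // 2)
                ages = np.concatenate([ages_adult, below, above])
                ids = [f"{strain}_{inst}_{sex[0]}{i:04d}" for i in range(len(ages))]
                latent = rng.standard_normal(len(ages))
                entry["animals"][sex] = {"ids": ids, "ages": ages, "latent": latent,
                                         "n_adult": n_adult}
            pops.append(entry)
        return {"pops": pops}

    rec_frames = []
    trait_rows, truth_rows = [], []
    for t in range(n_traits):
        rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(t,)))
        sub = subgroup_of.get(t)
        if sub is not None:
            sub_id, corr = sub
            if sub_id not in roster_cache:
                sub_rng = np.random.default_rng(
                    np.random.SeedSequence(config.seed, spawn_key=(2 * 10**6, int(sub_id[3:])))
                )
                roster_cache[sub_id] = _build_roster(sub_rng)
            roster = roster_cache[sub_id]
        else:
            sub_id, corr = "", 0.0
            roster = _build_roster(rng)

        m0 = rng.normal(*config.base_logmean)
        sigma_f = float(np.exp(rng.normal(config.log_cv_location, config.log_cv_scale)))
        sigma_m = _sigma_male(sigma_f, lncvr[t])
        mf = m0
        mm = m0 + lnrr[t] - (sigma_m**2 - sigma_f**2) / 2.0
        sig = {"male": sigma_m, "female": sigma_f}
        mu = {"male": mm, "female": mf}

        u_strain = {s: rng.normal(0.0, config.sigma_strain) for s in strains}
        u_inst = {l: rng.normal(0.0, config.sigma_location) for l in institutions}

        rows = []
        for pop in roster["pops"]:
            shift = u_strain[pop["strain"]] + u_inst[pop["institution"]]
            for sex in ("male", "female"):
                animals = pop["animals"][sex]
                n_all = len(animals["ages"])
                z_unique = rng.standard_normal(n_all)
                z = (
                    np.sqrt(corr) * animals["latent"] + np.sqrt(1.0 - corr) * z_unique
                    if corr > 0 else z_unique
                )
                values = np.exp(mu[sex] + shift + sig[sex] * z)
                if config.missing_rate > 0:
                    miss = rng.random(n_all) < config.missing_rate
                    # the guaranteed adult minimum always has recorded values,
                    # so eligible populations never fall below n_min
                    miss[: config.n_min] = False
                    values = np.where(miss, np.nan, values)
                rows.append(pd.DataFrame({
                    "animal_id": animals["ids"],
                    "sex": sex,
                    "strain": pop["strain"],
                    "institution": pop["institution"],
                    "age_days": animals["ages"],
                    "trait_id": trait_ids[t],
                    "value": values,
                }))
                # duplicate measurements at another adult age, so the
                # closest-to-target selection has real work without breaking
                # the adult-count guarantee
                dup = rng.random(animals["n_adult"]) < config.duplicate_prob
                if dup.any():
                    ndup = int(dup.sum())
                    zd = rng.standard_normal(ndup)
                    rows.append(pd.DataFrame({
                        "animal_id": np.asarray(animals["ids"])[: animals["n_adult"]][dup],
                        "sex": sex,
                        "strain": pop["strain"],
                        "institution": pop["institution"],
                        "age_days": rng.uniform(*config.adult_age_range, size=ndup),
                        "trait_id": trait_ids[t],
                        "value": np.exp(mu[sex] + shift + sig[sex] * zd),
                    }))
        rec_frames.append(pd.concat(rows, ignore_index=True))

        trait_rows.append({
            "trait_id": trait_ids[t],
            "procedure": f"procedure_{groups[t]}",
            "functional_group": groups[t],
            "subgroup_id": sub_id,
        })
        truth_rows.append({
            "trait_id": trait_ids[t],
            "functional_group": groups[t],
            "subgroup_id": sub_id,
            "true_lnrr": float(lnrr[t]),
            "true_lncvr": float(lncvr[t]),
            "true_lnvr": float(lncvr[t] + lnrr[t]),
            "sigma_log_f": sigma_f,
            "sigma_log_m": sigma_m,
            "base_logmean": m0,
            "sigma_strain": config.sigma_strain,
            "sigma_location": config.sigma_location,
        })

    records = pd.concat(rec_frames, ignore_index=True)
    trait_map = pd.DataFrame(trait_rows)
    truth = pd.DataFrame(truth_rows)
    return records, trait_map, truth


def write_dataset(records: pd.DataFrame, trait_map: pd.DataFrame, truth: pd.DataFrame,
                  outdir) -> dict[str, Path]:
    """Write records.csv, trait_map.csv and truth.csv; returns the paths."""
    if records.empty or trait_map.empty:
        raise ValueError("refusing to write an empty dataset")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "records": outdir / "records.csv",
        "trait_map": outdir / "trait_map.csv",
        "truth": outdir / "truth.csv",
    }
    records.to_csv(paths["records"], index=False)
    trait_map.to_csv(paths["trait_map"], index=False)
    truth.to_csv(paths["truth"], index=False)
    return paths


def read_truth(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"trait_id": str, "subgroup_id": str})
    df["subgroup_id"] = df["subgroup_id"].fillna("")
    return df


def read_trait_map(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str)
    df["subgroup_id"] = df["subgroup_id"].fillna("")
    return df
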