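"""Data cleaning and reduction of individual records to population summaries.

The cleaning rules mirror standard consortium-phenotyping practice for
wildtype control data:

1. keep a single measurement per animal x trait — the one closest to 100
   days of age (ties: the earlier age, then stable input order);
2. keep adult, sexed animals with a recorded value (age in [100, 500] days,
   bounds inclusive);
3. summarise each trait x strain x institution ("population") per sex into
   n, mean and sample SD;
4. eligibility: at least 6 animals per sex in a population, populations for
   a trait spanning at least 2 institutions, no zero-variance ("fixed")
   trait, and positive means (ratio effect sizes are otherwise undefined).

Filter order is per-population first (minimum per-sex n), then per-trait
(institution span, fixed trait, non-positive mean). Every exclusion is
logged with a machine-readable reason; filters are idempotent.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "read_records",
    "select_closest_to_target_age",
    "filter_adults",
    "summarize_populations",
    "apply_eligibility_filters",
    "preprocess",
    "RECORD_COLUMNS",
]

RECORD_COLUMNS = ["animal_id", "sex", "strain", "institution", "age_days", "trait_id", "value"]


def read_records(path) -> pd.DataFrame:
    """Read an individual-records CSV (schema as written by synthdata)."""
    df = pd.read_csv(path, dtype={"animal_id": str, "strain": str, "institution": str,
                                  "trait_id": str, "sex": str})
    missing = set(RECORD_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"records file missing columns: {sorted(missing)}")
    return df


def select_closest_to_target_age(records: pd.DataFrame, target_age_days: float = 100.0) -> pd.DataFrame:
    """Keep one row per (animal, trait): the measurement closest to the target age.

    Ties on |age - target| are broken by the earlier age, then stable input
    order. Rows with missing age are never preferred over recorded ages.
    """
    if records.empty:
        return records.copy()
    df = records.copy()
    df["_dist"] = (df["age_days"] - target_age_days).abs()
    df["_order"] = range(len(df))
    df = df.sort_values(["_dist", "age_days", "_order"], kind="stable")
    df = df.drop_duplicates(subset=["animal_id", "trait_id"], keep="first")
    return (
        df.sort_values("_order", kind="stable")
        .drop(columns=["_dist", "_order"])
        .reset_index(drop=True)
    )


def filter_adults(
    records: pd.DataFrame, min_age: float = 100.0, max_age: float = 500.0
) -> pd.DataFrame:
    """Keep sexed adults with a recorded value; age bounds inclusive."""
    df = records
    keep = (
        df["age_days"].ge(min_age)
        & df["age_days"].le(max_age)
        & df["sex"].isin(["male", "female"])
        & df["value"].notna()
    )
    return df.loc[keep].reset_index(drop=True)


def summarize_populations(records: pd.DataFrame) -> pd.DataFrame:
    """Per-sex sufficient statistics for each trait x strain x institution.

    Returns one row per population with n_m/n_f, mean_m/mean_f, sd_m/sd_f
    (sample SD, denominator n-1). A population missing one sex gets n = 0
    for that sex; downstream eligibility filters remove it.
    """
    g = records.groupby(["trait_id", "strain", "institution", "sex"])["value"]
    stats = g.agg(n="count", mean="mean", sd="std").reset_index()
    wide = stats.pivot_table(
        index=["trait_id", "strain", "institution"],
        columns="sex",
        values=["n", "mean", "sd"],
        aggfunc="first",
    )
    wide.columns = [f"{a}_{'m' if b == 'male' else 'f'}" for a, b in wide.columns]
    wide = wide.reset_index()
    for col in ["n_m", "n_f", "mean_m", "mean_f", "sd_m", "sd_f"]:
        if col not in wide.columns:
            wide[col] = float("nan")
    wide["n_m"] = wide["n_m"].fillna(0).astype(int)
    wide["n_f"] = wide["n_f"].fillna(0).astype(int)
    wide["population_id"] = wide["strain"].astype(str) + ":" + wide["institution"].astype(str)
    return wide[
        ["trait_id", "strain", "institution", "population_id",
         "n_m", "mean_m", "sd_m", "n_f", "mean_f", "sd_f"]
    ]


def apply_eligibility_filters(
    summaries: pd.DataFrame, min_per_sex: int = 6, min_institutions: int = 2
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply population- then trait-level eligibility rules.

    Returns ``(kept, exclusions)``; the exclusion log has one row per
    dropped population with columns trait_id, population_id, reason in
    {min_per_sex, single_institution, fixed_trait, nonpositive_mean}, so
    kept rows + logged rows account for every input row.
    """
    df = summaries
    logs = []

    small = (df["n_m"] < min_per_sex) | (df["n_f"] < min_per_sex)
    logs.append(df.loc[small, ["trait_id", "population_id"]].assign(reason="min_per_sex"))
    df = df.loc[~small]

    def _drop_traits(df: pd.DataFrame, bad_traits, reason: str) -> pd.DataFrame:
        bad = df["trait_id"].isin(list(bad_traits))
        logs.append(df.loc[bad, ["trait_id", "population_id"]].assign(reason=reason))
        return df.loc[~bad]

    if not df.empty:
        span = df.groupby("trait_id")["institution"].nunique()
        df = _drop_traits(df, span.index[span < min_institutions], "single_institution")

    if not df.empty:
        bad_sd = (df["sd_m"] <= 0) | (df["sd_f"] <= 0) | df["sd_m"].isna() | df["sd_f"].isna()
        df = _drop_traits(df, df.loc[bad_sd, "trait_id"].unique(), "fixed_trait")

    if not df.empty:
        bad_mean = (df["mean_m"] <= 0) | (df["mean_f"] <= 0)
        df = _drop_traits(df, df.loc[bad_mean, "trait_id"].unique(), "nonpositive_mean")

    exclusions = pd.concat(logs, ignore_index=True) if logs else pd.DataFrame(
        columns=["trait_id", "population_id", "reason"]
    )
    return df.reset_index(drop=True), exclusions


def preprocess(
    records: pd.DataFrame,
    target_age_days: float = 100.0,
    min_age: float = 100.0,
    max_age: float = 500.0,
    min_per_sex: int = 6,
    min_institutions: int = 2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full cleaning chain: dedupe by age, adult filter, summarise, eligibility.

    Returns ``(population_summaries, exclusion_log)``.
    """
    step = select_closest_to_target_age(records, target_age_days)
    step = filter_adults(step, min_age=min_age, max_age=max_age)
    summaries = summarize_populations(step)
    return apply_eligibility_filters(summaries, min_per_sex, min_institutions)
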