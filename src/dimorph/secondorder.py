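"""Second-order meta-analysis: trait-level results as the unit of analysis.

Aggregates condensed trait-level meta-analytic means into functional-group
and overall estimates via classical random-effects models (purpose A),
tallies the direction of sex bias per group — male-biased means > 0,
female-biased < 0, exact zeros unclassified (the sign counts of which no
inferential test is made: vote-counting is avoided) — and, for traits whose
CI excludes zero, aggregates the male- and female-biased sides separately
to estimate overall bias magnitudes (purpose C).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .metamodel import fit_random_effects

__all__ = [
    "SecondOrderResult",
    "aggregate_group",
    "count_sign_bias",
    "aggregate_by_direction",
    "run_second_order",
]


@dataclass
class SecondOrderResult:
    """Functional-group (or overall) aggregate of trait-level results."""

    group: str
    es_type: str
    k_traits: int
    mean: float
    se: float
    ci_low: float
    ci_high: float
    tau2: float
    i2: float
    n_male_biased: int
    n_female_biased: int
    n_unclassified: int
    percent_male_biased: float
    percent_female_biased: float
    aggregable: bool = True


def count_sign_bias(estimates) -> dict[str, float]:
    """Count male-biased (> 0) and female-biased (< 0) trait-level means.

    Exact zeros are counted in neither direction and reported separately;
    percentages are over classified traits only.
    """
    est = np.asarray(estimates, float)
    n_male = int((est > 0).sum())
    n_female = int((est < 0).sum())
    n_zero = int((est == 0).sum())
    classified = n_male + n_female
    return {
        "n_male_biased": n_male,
        "n_female_biased": n_female,
        "n_unclassified": n_zero,
        "percent_male_biased": 100.0 * n_male / classified if classified else np.nan,
        "percent_female_biased": 100.0 * n_female / classified if classified else np.nan,
    }


def aggregate_group(
    results: pd.DataFrame, group: str = "All", es_type: str = "", method: str = "reml"
) -> SecondOrderResult:
    """Random-effects aggregate of one group's trait-level (mu_hat, se) rows."""
    if len(results) < 2:
        raise ValueError(f"group {group!r}: need at least 2 trait-level results")
    fit = fit_random_effects(
        results["mu_hat"].to_numpy(float), (results["se"].to_numpy(float)) ** 2,
        method=method,
    )
    signs = count_sign_bias(results["mu_hat"].to_numpy(float))
    return SecondOrderResult(
        group=group,
        es_type=es_type,
        k_traits=len(results),
        mean=fit.mean,
        se=fit.se,
        ci_low=fit.ci_low,
        ci_high=fit.ci_high,
        tau2=fit.tau2,
        i2=fit.i2,
        **signs,
    )


def _unaggregable(group, es_type, results) -> SecondOrderResult:
    signs = count_sign_bias(results["mu_hat"].to_numpy(float)) if len(results) else {
        "n_male_biased": 0, "n_female_biased": 0, "n_unclassified": 0,
        "percent_male_biased": np.nan, "percent_female_biased": np.nan,
    }
    return SecondOrderResult(
        group=group, es_type=es_type, k_traits=len(results),
        mean=np.nan, se=np.nan, ci_low=np.nan, ci_high=np.nan,
        tau2=np.nan, i2=np.nan, aggregable=False, **signs,
    )


def aggregate_by_direction(
    results: pd.DataFrame, group: str = "All", es_type: str = ""
) -> tuple[SecondOrderResult, SecondOrderResult]:
    """Aggregate significantly sex-biased traits separately by direction.

    A trait is significantly sex-biased when its 95% CI excludes zero.
    Returns (male_biased_side, female_biased_side); a side with fewer than
    2 traits is returned with ``aggregable = False``.
    """
    sig = results[(results["ci_low"] > 0) | (results["ci_high"] < 0)]
    male = sig[sig["mu_hat"] > 0]
    female = sig[sig["mu_hat"] < 0]
    out = []
    for side, label in ((male, "male_biased"), (female, "female_biased")):
        name = f"{group}:{label}"
        if len(side) >= 2:
            out.append(aggregate_group(side, group=name, es_type=es_type))
        else:
            out.append(_unaggregable(name, es_type, side))
    return out[0], out[1]


def run_second_order(
    condensed: pd.DataFrame, trait_map: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All second-order analyses over a condensed trait-level table.

    For each effect-size type: one aggregate per functional group plus one
    over all groups combined, and the per-group sign counts. ``condensed``
    needs columns trait_id, es_type, mu_hat, se, ci_low, ci_high and
    functional_group (joined from ``trait_map`` if absent).

    Returns ``(second_order_results, sign_counts)`` as flat tables.
    """
    df = condensed.copy()
    if "functional_group" not in df.columns:
        if trait_map is None:
            raise ValueError("need functional_group column or a trait_map")
        df = df.merge(trait_map[["trait_id", "functional_group"]], on="trait_id", how="left")
    if df["functional_group"].isna().any():
        bad = df.loc[df["functional_group"].isna(), "trait_id"].tolist()
        raise ValueError(f"traits without functional group: {bad[:5]}")

    results, counts = [], []
    for es, es_df in df.groupby("es_type", sort=True):
        blocks = [("All", es_df)] + [
            (g, sub) for g, sub in es_df.groupby("functional_group", sort=True)
        ]
        for label, sub in blocks:
            res = (
                aggregate_group(sub, group=label, es_type=es)
                if len(sub) >= 2
                else _unaggregable(label, es, sub)
            )
            results.append(res.__dict__)
            counts.append({
                "group": label, "es_type": es, "k_traits": len(sub),
                **count_sign_bias(sub["mu_hat"].to_numpy(float)),
            })
    return pd.DataFrame(results), pd.DataFrame(counts)
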