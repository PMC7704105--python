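"""Robust aggregation of correlated trait-level results.

Trait panels contain clusters of non-independent traits (overlapping or
hierarchically nested measurements, e.g. cell type A, B and A+B). Before
second-order aggregation, each such sub-group is collapsed into a single
result under the assumption that the members' sampling errors are
equicorrelated with rho (default 0.8, the conventional default of the
robust-variance meta-analysis literature).

Two layers:

* :func:`rve_fit` — a general correlated-effects robust-variance fit over
  many clusters (Hedges–Tipton–Johnson scheme): approximate inverse-variance
  weights built from each cluster's mean sampling variance, rho and a
  method-of-moments between-cluster tau2; sandwich (robust) standard error
  over clusters with a small-sample multiplier for few clusters. With
  rho = 0 and singleton clusters the tau2 moment estimator reduces exactly
  to DerSimonian–Laird, and the fit coincides with the classical
  random-effects model using that estimator.
* :func:`combine_correlated` — collapses one sub-group (a single correlated
  block). The point estimate uses the block's approximate equal weights;
  the robust SE is the sandwich taken over member traits, i.e. it comes
  from the members' empirical spread and remains valid when rho is
  misspecified. rho enters the moment tau2: member spread is compared with
  the spread expected from rho-correlated sampling errors,
  E[SS/(k-1)] = v_bar (1 - rho) + tau2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["CorrelatedCluster", "CombinedResult", "rve_fit", "combine_correlated",
           "condense_traits"]

DEFAULT_RHO = 0.8


@dataclass(frozen=True)
class CorrelatedCluster:
    """One sub-group of correlated traits: (estimate, variance) pairs."""

    subgroup_id: str
    estimates: tuple[float, ...]
    variances: tuple[float, ...]
    rho: float = DEFAULT_RHO

    def __post_init__(self) -> None:
        if len(self.estimates) != len(self.variances):
            raise ValueError("estimates and variances must have equal length")
        if len(self.estimates) < 1:
            raise ValueError("cluster needs at least one member")
        if not (0.0 <= self.rho <= 1.0):
            raise ValueError("rho must be in [0, 1]")
        if any(v <= 0 for v in self.variances):
            raise ValueError("member variances must be positive")


@dataclass
class CombinedResult:
    subgroup_id: str
    k_members: int
    estimate: float
    se: float
    tau2: float
    rho: float


def rve_fit(
    y, v, cluster_ids, rho: float = DEFAULT_RHO, small_sample: bool = True
) -> tuple[float, float, float]:
    """Correlated-effects robust-variance fit: returns (estimate, se, tau2).

    ``cluster_ids`` marks which effects share correlated sampling errors;
    clusters are independent of each other. Weights are
    ``1 / (k_j (vbar_j (1 + (k_j - 1) rho) / k_j + tau2))`` — the inverse
    variance of the cluster mean under the working model — shared by all
    members of cluster j. The SE is the between-cluster sandwich, with a
    ``m/(m-1)`` small-sample multiplier when there are at most 4 clusters.
    """
    y = np.asarray(y, float)
    v = np.asarray(v, float)
    ids = np.asarray(cluster_ids)
    if np.any(v <= 0):
        raise ValueError("variances must be positive")
    uniq, inv = np.unique(ids, return_inverse=True)
    m = len(uniq)
    if m < 2:
        raise ValueError("rve_fit needs at least 2 independent clusters")
    kj = np.bincount(inv)
    vbar = np.bincount(inv, weights=v) / kj

    # method-of-moments tau2 from Q with provisional weights w = 1/(k_j vbar_j)
    w0 = 1.0 / (kj[inv] * vbar[inv])
    W0 = w0.sum()
    b0 = (w0 * y).sum() / W0
    Q = (w0 * (y - b0) ** 2).sum()
    Wj = 1.0 / vbar  # per-cluster total provisional weight
    varmean_j = vbar * (1.0 + (kj - 1) * rho) / kj  # sampling var of cluster mean
    A = len(y) - (Wj**2 * varmean_j).sum() / W0
    B = W0 - (Wj**2).sum() / W0
    tau2 = max(0.0, (Q - A) / B) if B > 0 else 0.0

    w = 1.0 / (kj[inv] * (varmean_j[inv] + tau2))
    W = w.sum()
    b = float((w * y).sum() / W)
    e = y - b
    cluster_score = np.bincount(inv, weights=w * e)
    vr = float((cluster_score**2).sum() / W**2)
    if small_sample and m <= 4:
        vr *= m / (m - 1)
    return b, float(np.sqrt(vr)), float(tau2)


def combine_correlated(cluster: CorrelatedCluster, small_sample: bool = True) -> CombinedResult:
    """Collapse one correlated sub-group into a single (estimate, SE) pair.

    A singleton passes through unchanged. Otherwise the estimate is the
    approximate-weights mean (equal weights, since all members share the
    block-average variance), tau2 is the moment estimate of between-member
    heterogeneity in excess of rho-correlated sampling error, and the SE is
    the member-level sandwich sqrt(sum(w e)^2)/sum(w) with a k/(k-1)
    multiplier for blocks of at most 4 members — floored at the working-model
    variance of the mean, [vbar (1 + (k-1) rho) + tau2] / k. The floor
    matters when members agree closely: with 2-10 strongly correlated
    members the empirical sandwich can collapse towards zero, and a
    spuriously tiny SE would let one sub-group dominate the inverse-variance
    weights of every downstream second-order aggregate. Averaging k
    rho-correlated estimates cannot be more precise than the model variance,
    so the floor is a hard lower bound, not a tuning device.
    """
    y = np.asarray(cluster.estimates, float)
    v = np.asarray(cluster.variances, float)
    k = len(y)
    if k == 1:
        return CombinedResult(cluster.subgroup_id, 1, float(y[0]), float(np.sqrt(v[0])),
                              0.0, cluster.rho)
    vbar = float(v.mean())
    ybar = float(y.mean())
    ss = float(((y - ybar) ** 2).sum())
    tau2 = max(0.0, ss / (k - 1) - vbar * (1.0 - cluster.rho))
    vr = ss / k**2
    if small_sample and k <= 4:
        vr *= k / (k - 1)
    vr_model = (vbar * (1.0 + (k - 1) * cluster.rho) + tau2) / k
    vr = max(vr, vr_model)
    return CombinedResult(cluster.subgroup_id, k, ybar, float(np.sqrt(vr)), tau2, cluster.rho)


def condense_traits(
    results: pd.DataFrame, trait_map: pd.DataFrame, rho: float = DEFAULT_RHO
) -> pd.DataFrame:
    """Replace each correlated sub-group by one combined row.

    ``results`` is a trait-level table with columns trait_id, es_type,
    mu_hat, se (one es_type at a time or several; sub-groups are combined
    within es_type). Traits without a subgroup_id pass through. Output rows
    = independent traits + one per sub-group, with ``n_member_traits``
    recording how many traits each row absorbs.
    """
    if not set(results["trait_id"]).issubset(set(trait_map["trait_id"])):
        missing = sorted(set(results["trait_id"]) - set(trait_map["trait_id"]))
        raise ValueError(f"traits missing from trait_map: {missing[:5]}")
    sub_of = trait_map.set_index("trait_id")["subgroup_id"].fillna("").to_dict()
    df = results.copy()
    df["subgroup_id"] = df["trait_id"].map(sub_of).fillna("")

    # every member of a sub-group must carry the same set of effect-size
    # types, otherwise members would be combined across incompatible scales
    for sub_id, grp in df[df["subgroup_id"] != ""].groupby("subgroup_id"):
        es_sets = grp.groupby("trait_id")["es_type"].agg(frozenset)
        if es_sets.nunique() > 1:
            raise ValueError(f"sub-group {sub_id} mixes effect-size types across members")

    out = []
    independent = df[df["subgroup_id"] == ""].copy()
    independent["n_member_traits"] = 1
    out.append(independent.drop(columns=["subgroup_id"]))

    for (sub_id, es), grp in df[df["subgroup_id"] != ""].groupby(["subgroup_id", "es_type"]):
        combined = combine_correlated(
            CorrelatedCluster(
                subgroup_id=sub_id,
                estimates=tuple(grp["mu_hat"]),
                variances=tuple(grp["se"] ** 2),
                rho=rho,
            )
        )
        row = {c: np.nan for c in independent.columns if c != "subgroup_id"}
        row.update({
            "trait_id": f"subgroup:{sub_id}",
            "es_type": es,
            "mu_hat": combined.estimate,
            "se": combined.se,
            "k": int(grp["k"].sum()) if "k" in grp else np.nan,
            "n_member_traits": combined.k_members,
        })
        if "functional_group" in grp.columns:
            groups = grp["functional_group"].unique()
            row["functional_group"] = groups[0] if len(groups) == 1 else "mixed"
        if "converged" in row:
            row["converged"] = True
        out.append(pd.DataFrame([row]))

    return pd.concat(out, ignore_index=True)
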