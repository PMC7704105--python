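"""Ratio-based effect sizes comparing male and female trait distributions.

Three log-ratio effect sizes are computed from per-population, per-sex
summary statistics (n, mean, sample SD):

* ``lnRR``  — log response ratio, ``ln(mean_m / mean_f)``: sex difference in
  the mean.
* ``lnVR``  — log variability ratio, ``ln(sd_m / sd_f)`` with a small-sample
  bias correction: sex difference in absolute variability.
* ``lnCVR`` — log coefficient-of-variation ratio, ``ln(CV_m / CV_f)`` with
  the same correction: mean-adjusted (relative) variability difference.

Males are always in the numerator, so positive estimates are male-biased.
All three are unitless, which makes traits measured in different units
commensurable and cancels baseline shifts shared by the sexes.

The lnCVR sampling variance uses the independent-terms form (no mean–SD
correlation term): the full form requires the within-population correlation
between the log mean and log SD, which is not identifiable from summary
statistics alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "EffectSize",
    "ln_rr",
    "ln_vr",
    "ln_cvr",
    "percent_difference",
    "compute_effect_sizes",
    "ES_TYPES",
]

ES_TYPES = ("lnRR", "lnVR", "lnCVR")


class UndefinedEffectError(ValueError):
    """Raised when an effect size is undefined for the given summaries."""


@dataclass(frozen=True)
class EffectSize:
    """One effect size with its sampling variance for one trait x population."""

    trait_id: str
    population_id: str
    es_type: str
    estimate: float
    sampling_variance: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.estimate):
            raise UndefinedEffectError(f"non-finite estimate for {self.trait_id}")
        if not (self.sampling_variance > 0):
            raise UndefinedEffectError(
                f"sampling variance must be positive, got {self.sampling_variance}"
            )


def _check_counts(n_m, n_f) -> None:
    n_m = np.asarray(n_m)
    n_f = np.asarray(n_f)
    if np.any(n_m < 2) or np.any(n_f < 2):
        raise UndefinedEffectError("need at least 2 individuals per sex")


def ln_rr(n_m, mean_m, sd_m, n_f, mean_f, sd_f):
    """Log response ratio ln(mean_m/mean_f) and its sampling variance.

    Vectorised: scalar or array inputs; returns ``(estimate, variance)``.
    """
    _check_counts(n_m, n_f)
    mean_m, mean_f = np.asarray(mean_m, float), np.asarray(mean_f, float)
    if np.any(mean_m <= 0) or np.any(mean_f <= 0):
        raise UndefinedEffectError("lnRR requires positive means")
    sd_m, sd_f = np.asarray(sd_m, float), np.asarray(sd_f, float)
    n_m, n_f = np.asarray(n_m, float), np.asarray(n_f, float)
    est = np.log(mean_m / mean_f)
    var = sd_m**2 / (n_m * mean_m**2) + sd_f**2 / (n_f * mean_f**2)
    return est, var


def ln_vr(n_m, sd_m, n_f, sd_f):
    """Log SD ratio with small-sample bias correction, and its variance.

    estimate = ln(sd_m/sd_f) + 1/(2(n_m-1)) - 1/(2(n_f-1))
    variance = 1/(2(n_m-1)) + 1/(2(n_f-1))
    """
    _check_counts(n_m, n_f)
    sd_m, sd_f = np.asarray(sd_m, float), np.asarray(sd_f, float)
    if np.any(sd_m <= 0) or np.any(sd_f <= 0):
        raise UndefinedEffectError("lnVR requires positive SDs")
    n_m, n_f = np.asarray(n_m, float), np.asarray(n_f, float)
    cm, cf = 1.0 / (2.0 * (n_m - 1.0)), 1.0 / (2.0 * (n_f - 1.0))
    est = np.log(sd_m / sd_f) + cm - cf
    var = cm + cf
    return est, var


def ln_cvr(n_m, mean_m, sd_m, n_f, mean_f, sd_f):
    """Log CV ratio (mean-adjusted variability) and its sampling variance.

    With CV = sd/mean per sex:

    estimate = ln(CV_m/CV_f) + 1/(2(n_m-1)) - 1/(2(n_f-1))
    variance = sd_m^2/(n_m mean_m^2) + 1/(2(n_m-1))
             + sd_f^2/(n_f mean_f^2) + 1/(2(n_f-1))

    assuming independence of the mean and SD on the log scale.
    """
    _check_counts(n_m, n_f)
    mean_m, mean_f = np.asarray(mean_m, float), np.asarray(mean_f, float)
    sd_m, sd_f = np.asarray(sd_m, float), np.asarray(sd_f, float)
    if np.any(mean_m <= 0) or np.any(mean_f <= 0):
        raise UndefinedEffectError("lnCVR requires positive means")
    if np.any(sd_m <= 0) or np.any(sd_f <= 0):
        raise UndefinedEffectError("lnCVR requires positive SDs")
    n_m, n_f = np.asarray(n_m, float), np.asarray(n_f, float)
    cm, cf = 1.0 / (2.0 * (n_m - 1.0)), 1.0 / (2.0 * (n_f - 1.0))
    est = np.log((sd_m / mean_m) / (sd_f / mean_f)) + cm - cf
    var = sd_m**2 / (n_m * mean_m**2) + cm + sd_f**2 / (n_f * mean_f**2) + cf
    return est, var


def percent_difference(estimate) -> float:
    """Convert a log-ratio to the percent difference as reported in the field.

    For b >= 0 returns 100*(exp(b) - 1), the percent by which males exceed
    females; for b < 0 returns 100*(1 - exp(b)), the magnitude of the female
    bias. Both conventions return a non-negative percentage for the favoured
    sex.
    """
    b = np.asarray(estimate, float)
    out = np.where(b >= 0, 100.0 * (np.exp(b) - 1.0), 100.0 * (1.0 - np.exp(b)))
    return float(out) if out.ndim == 0 else out


_ES_FUNCS = {
    "lnRR": lambda s: ln_rr(s["n_m"], s["mean_m"], s["sd_m"], s["n_f"], s["mean_f"], s["sd_f"]),
    "lnVR": lambda s: ln_vr(s["n_m"], s["sd_m"], s["n_f"], s["sd_f"]),
    "lnCVR": lambda s: ln_cvr(s["n_m"], s["mean_m"], s["sd_m"], s["n_f"], s["mean_f"], s["sd_f"]),
}


def compute_effect_sizes(
    summaries: pd.DataFrame, es_types: tuple[str, ...] = ES_TYPES
) -> pd.DataFrame:
    """Compute effect sizes for every population summary row.

    Parameters
    ----------
    summaries
        Population summary table with columns trait_id, population_id,
        strain, institution, n_m, mean_m, sd_m, n_f, mean_f, sd_f.
    es_types
        Which of lnRR, lnVR, lnCVR to compute.

    Returns
    -------
    Long-format table: trait_id, population_id, strain, institution,
    es_type, estimate, sampling_variance, n_m, n_f.
    """
    frames = []
    for es in es_types:
        if es not in _ES_FUNCS:
            raise ValueError(f"unknown effect-size type {es!r}")
        est, var = _ES_FUNCS[es](summaries)
        frames.append(
            pd.DataFrame(
                {
                    "trait_id": summaries["trait_id"],
                    "population_id": summaries["population_id"],
                    "strain": summaries["strain"],
                    "institution": summaries["institution"],
                    "es_type": es,
                    "estimate": np.asarray(est, float),
                    "sampling_variance": np.asarray(var, float),
                    "n_m": summaries["n_m"].to_numpy(),
                    "n_f": summaries["n_f"].to_numpy(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
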