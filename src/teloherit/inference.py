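"""Derived statistics: variance partition, epigenetic fraction,
parent-offspring heritability, partner-age attenuation, cross-foster
recoding and coefficient comparison.

The central quantity is the split of the variance in offspring telomere
length (TL) explained by a parent's TL into a between-parent part (the
parent's mean TL across years — the putative additive-genetic path) and a
within-parent part (delta TL, the deviation from that mean — the epigenetic,
gamete-TL path).  The epigenetic fraction is the within share of their sum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lmm import MixedModelResults

__all__ = [
    "PartitionResult",
    "fixed_term_variance",
    "variance_partition",
    "epigenetic_fraction",
    "heritability_from_slopes",
    "predicted_partner_slope",
    "crossfoster_recode",
    "compare_coefficients",
]


def fixed_term_variance(fit: MixedModelResults, term: str) -> float:
    """Variance across rows of the centred fitted contribution of one fixed
    term, ``Var((x - x_bar) * beta_hat)`` in response units squared."""
    if not fit.converged:
        raise ValueError("fit did not converge")
    if term not in fit.params.index:
        raise KeyError(f"term {term!r} not in model")
    j = list(fit.params.index).index(term)
    x = fit.model.exog[:, j]
    beta = float(fit.params[term])
    return float(np.var(x * beta))


@dataclass
class PartitionResult:
    """Variance partition of a mixed-model fit.

    Percentages are each component's variance over the total modelled
    variance (combined fixed-effect variance + all random components +
    residual); ``r2`` is the conditional R^2 (all modelled variance over
    the total).  A random slope's contribution is its variance times the
    mean squared covariate.  All absolute values are in response units
    squared (bp^2 for TL); the epigenetic fraction is unit-free.
    """

    fixed_term_variance: dict[str, float]
    random_percent: dict[str, float]
    slope_percent: float
    r2: float
    total_variance: float
    epigenetic_fraction: float | None = None

    def summary(self) -> str:
        lines = ["Variance partition"]
        for t, v in self.fixed_term_variance.items():
            lines.append(f"  fixed   {t:<28s} {v:12.1f}")
        for t, pc in self.random_percent.items():
            lines.append(f"  random  {t:<28s} {pc:11.1f}%")
        lines.append(f"  random slopes combined            {self.slope_percent:11.1f}%")
        lines.append(f"  conditional R^2                   {self.r2:12.3f}")
        if self.epigenetic_fraction is not None:
            lines.append(
                f"  epigenetic fraction               {self.epigenetic_fraction:12.3f}")
        return "\n".join(lines)


def variance_partition(
    fit: MixedModelResults,
    mean_term: str | None = None,
    delta_term: str | None = None,
) -> PartitionResult:
    """Partition response variance over fixed terms and random components.

    When ``mean_term`` and ``delta_term`` name the between- and
    within-parent covariates of a parental-TL model, the epigenetic fraction
    ``Var(delta path) / (Var(mean path) + Var(delta path))`` is filled in.
    """
    if not fit.converged:
        raise ValueError("fit did not converge")
    names = list(fit.params.index)
    terms = [t for t in names if t != "(intercept)"]
    ftv = {t: fixed_term_variance(fit, t) for t in terms}

    # combined fixed-effect variance (covariances between terms included)
    fitted = fit.fittedvalues
    var_fixed = float(np.var(fitted))

    contrib: dict[str, float] = {}
    for name, Z in fit.model.re_design:
        v = fit.varcomps.get(name, 0.0)
        contrib[name] = v * float(np.mean(np.sum(Z * Z, axis=1)))
    resid = fit.varcomps["residual"]
    total = var_fixed + sum(contrib.values()) + resid

    random_percent = {name: 100.0 * c / total for name, c in contrib.items()}
    slope_percent = sum(pc for name, pc in random_percent.items() if "|" in name)
    r2 = (var_fixed + sum(contrib.values())) / total

    frac = None
    if mean_term is not None and delta_term is not None:
        frac = epigenetic_fraction(ftv[mean_term], ftv[delta_term])
    return PartitionResult(
        fixed_term_variance=ftv,
        random_percent=random_percent,
        slope_percent=slope_percent,
        r2=r2,
        total_variance=total,
        epigenetic_fraction=frac,
    )


def epigenetic_fraction(v_mean: float, v_delta: float) -> float:
    """Share of parental-TL-explained offspring-TL variance attributable to
    the within-parent (epigenetic) path: ``v_delta / (v_mean + v_delta)``."""
    if v_mean < 0 or v_delta < 0:
        raise ValueError("variances must be >= 0")
    if v_mean + v_delta == 0:
        raise ValueError("epigenetic fraction undefined when both variances are 0")
    return v_delta / (v_mean + v_delta)


def heritability_from_slopes(b_father: float, b_mother: float) -> float:
    """Narrow-sense heritability as the sum of the single-parent
    offspring-on-parent regression slopes (bp/bp scale).

    This is the simple parent-offspring regression estimator with no
    shared-environment correction; treat it as tentative.  Values outside
    [0, 1] are returned with a warning, never clamped.
    """
    h2 = b_father + b_mother
    if not 0.0 <= h2 <= 1.0:
        warnings.warn(f"heritability estimate {h2:.3f} outside [0, 1]",
                      stacklevel=2)
    return h2


def predicted_partner_slope(r_mate_age: float, b_partner: float) -> float:
    """Expected apparent own-age slope induced purely by the partner's age
    effect when mate ages correlate: ``r * b``."""
    if abs(r_mate_age) > 1:
        raise ValueError("|r_mate_age| must be <= 1")
    return r_mate_age * b_partner


def crossfoster_recode(table: pd.DataFrame) -> pd.DataFrame:
    """Add ``caring_father_age`` and ``father_age_diff`` columns.

    ``caring_father_age`` is the foster father's age (equal to the genetic
    father's when the clutch was not fostered); ``father_age_diff`` is
    genetic minus foster age, zero without fostering.  Row-wise the two add
    up exactly to the genetic father's age, so fitting both as covariates
    separates a conception-age effect (both coefficients equal) from a
    post-laying care effect (age-difference coefficient near zero).
    """
    out = table.copy()
    fostered = out["cross_fostered"].astype(bool)
    foster_age = pd.to_numeric(out["foster_father_age_y"], errors="coerce")
    if foster_age[fostered].isna().any():
        row = int(foster_age[fostered].isna().idxmax())
        raise ValueError(f"missing foster_father_age_y on fostered row {row}")
    genetic_age = pd.to_numeric(out["father_age_y"], errors="coerce")
    out["caring_father_age"] = foster_age.to_numpy()
    out["father_age_diff"] = (genetic_age - foster_age).to_numpy()
    return out


def compare_coefficients(
    fit: MixedModelResults, term_a: str, term_b: str
) -> tuple[float, float, float]:
    """Wald comparison of two fixed coefficients.

    Returns ``(difference, se_difference, z)`` with the SE from the fixed
    vcov (Var a + Var b - 2 Cov).  The scientific reading emphasises the
    similarity of the estimates; z is descriptive.
    """
    for t in (term_a, term_b):
        if t not in fit.params.index:
            raise KeyError(f"term {t!r} not in model")
    if fit.vcov_fixed is None:
        raise ValueError("fixed-effect vcov unavailable")
    diff = float(fit.params[term_a] - fit.params[term_b])
    va = float(fit.vcov_fixed.loc[term_a, term_a])
    vb = float(fit.vcov_fixed.loc[term_b, term_b])
    cab = float(fit.vcov_fixed.loc[term_a, term_b])
    se = float(np.sqrt(max(va + vb - 2 * cab, 0.0)))
    z = diff / se if se > 0 else 0.0
    return diff, se, z
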