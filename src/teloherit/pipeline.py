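"""Preset analysis battery and parameter-recovery harness.

``run_analysis`` executes the three-model battery on a breeding table:

* **parental age** (father and mother variants): offspring TL on offspring
  age plus the within-subject-centred parental age (mean + delta); random
  intercepts for parent ID, nest nested in parent, and gel; an independent
  random slope of delta age by parent.
* **cross-foster**: offspring TL on offspring age, the caring father's age
  and the genetic-minus-foster age difference (the two sum to the genetic
  father's age row-wise); random intercepts for genetic father, nest in
  father, gel and year.
* **parental TL** (father and mother variants): offspring TL on offspring
  age plus centred parental TL.  Parental TL covariates enter in kb so the
  coefficients read directly as bp-per-kb (divide by 1000 for the bp/bp
  slope); rows with missing parental TL are dropped listwise for this model
  only.

Derived statistics assembled from the battery: the mate-age correlation,
the within-parent TL attrition rate, the epigenetic fraction of the
parental-TL-explained variance, the slope-sum heritability, and the
partner-age attenuation prediction.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .centering import within_subject_center
from .inference import (
    compare_coefficients,
    crossfoster_recode,
    epigenetic_fraction,
    heritability_from_slopes,
    predicted_partner_slope,
    variance_partition,
)
from .lmm import MixedModel, ModelSpec
from .simulate import SimParams, simulate_population

__all__ = [
    "RunReport",
    "StudyReport",
    "run_analysis",
    "run_simulation_study",
    "mate_age_correlation",
    "parental_attrition",
    "PRESETS",
]


def mate_age_correlation(table: pd.DataFrame) -> tuple[float, int]:
    """Pearson correlation of father and mother age across nests."""
    nests = table.drop_duplicates("nest_id")
    r = float(np.corrcoef(nests["father_age_y"], nests["mother_age_y"])[0, 1])
    return r, len(nests)


def parental_attrition(table: pd.DataFrame, parent: str = "father") -> float:
    """Within-parent TL change (bp/yr) from the parents' own repeated
    measurements: OLS of parental TL on centred parental age over distinct
    parent-year records; the delta-age coefficient is the attrition rate."""
    cols = [f"{parent}_id", "year", f"{parent}_age_y", f"{parent}_tl_bp"]
    rec = table[cols].dropna().drop_duplicates([f"{parent}_id", "year"])
    rec = within_subject_center(rec, f"{parent}_age_y", f"{parent}_id",
                                level="year")
    X = np.column_stack([
        np.ones(len(rec)),
        rec[f"mean_{parent}_age_y"],
        rec[f"delta_{parent}_age_y"],
    ])
    beta, *_ = np.linalg.lstsq(X, rec[f"{parent}_tl_bp"].to_numpy(), rcond=None)
    return float(beta[2])


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

def _prep_parent_age(table: pd.DataFrame, parent: str) -> tuple[pd.DataFrame, ModelSpec]:
    mean_c, delta_c = f"mean_age_{parent}", f"delta_age_{parent}"
    data = within_subject_center(table, f"{parent}_age_y", f"{parent}_id",
                                 level="year", names=(mean_c, delta_c))
    spec = ModelSpec(
        response="offspring_tl_bp",
        fixed_terms=("offspring_age_d", mean_c, delta_c),
        random_intercepts=(f"{parent}_id/nest_id", "gel_id"),
        random_slopes=((delta_c, f"{parent}_id"),),
    )
    return data, spec


def _prep_crossfoster(table: pd.DataFrame, parent: str = "father"
                      ) -> tuple[pd.DataFrame, ModelSpec]:
    data = crossfoster_recode(table)
    spec = ModelSpec(
        response="offspring_tl_bp",
        fixed_terms=("offspring_age_d", "caring_father_age", "father_age_diff"),
        random_intercepts=("father_id/nest_id", "gel_id", "year"),
    )
    return data, spec


def _prep_parent_tl(table: pd.DataFrame, parent: str) -> tuple[pd.DataFrame, ModelSpec]:
    tl_col = f"{parent}_tl_bp"
    sub = table.dropna(subset=[tl_col]).copy()
    sub[f"{parent}_tl_kb"] = sub[tl_col] / 1000.0
    mean_c, delta_c = f"mean_tl_{parent}", f"delta_tl_{parent}"
    data = within_subject_center(sub, f"{parent}_tl_kb", f"{parent}_id",
                                 level="year", names=(mean_c, delta_c))
    spec = ModelSpec(
        response="offspring_tl_bp",
        fixed_terms=("offspring_age_d", mean_c, delta_c),
        random_intercepts=(f"{parent}_id/nest_id", "gel_id"),
        random_slopes=((delta_c, f"{parent}_id"),),
    )
    return data, spec


PRESETS = {
    "parental_age_father": lambda t: _prep_parent_age(t, "father"),
    "parental_age_mother": lambda t: _prep_parent_age(t, "mother"),
    "crossfoster": _prep_crossfoster,
    "parental_tl_father": lambda t: _prep_parent_tl(t, "father"),
    "parental_tl_mother": lambda t: _prep_parent_tl(t, "mother"),
}


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

@dataclass
class RunReport:
    """Machine-readable record of one analysis run.

    Every number is recomputable from the input table (or config + seed)
    alone.
    """

    models: dict = field(default_factory=dict)
    partitions: dict = field(default_factory=dict)
    derived: dict = field(default_factory=dict)
    config: dict = field(default_factory=dict)
    version: str = ""
    elapsed_s: float = 0.0

    def to_json(self, path=None) -> str:
        text = json.dumps(_jsonify(self.__dict__), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def summary(self) -> str:
        lines = [f"teloherit analysis report (v{self.version}, "
                 f"{self.elapsed_s:.1f} s)", ""]
        for name, m in self.models.items():
            lines.append(f"== {name} (n = {m['n']}, converged = {m['converged']}) ==")
            tab = pd.DataFrame(m["coefficients"]).T
            lines.append(tab.to_string(float_format=lambda v: f"{v:.3f}"))
            lines.append("random-effect variances: " + ", ".join(
                f"{k} {v:.0f}" for k, v in m["variance_components"].items()))
            lines.append("")
        if self.derived:
            lines.append("== derived statistics ==")
            for k, v in self.derived.items():
                lines.append(f"  {k}: {v:.4g}" if isinstance(v, float)
                             else f"  {k}: {v}")
        return "\n".join(lines)


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (pd.Series,)):
        return _jsonify(obj.to_dict())
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def _model_record(fit, extra=None) -> dict:
    rec = {
        "n": fit.nobs,
        "converged": fit.converged,
        "coefficients": {
            t: {
                "estimate": float(fit.params[t]),
                "s.e.": float(fit.bse[t]),
                "df": float(fit.df[t]),
                "t": float(fit.tvalues[t]),
                "p": float(fit.pvalues[t]),
            }
            for t in fit.params.index
        },
        "variance_components": {k: float(v) for k, v in fit.varcomps.items()},
        "boundary": sorted(fit.boundary),
        "reml_loglik": float(fit.reml_loglik),
    }
    if extra:
        rec.update(extra)
    return rec


def run_analysis(table: pd.DataFrame, config: dict | None = None,
                 presets: list[str] | None = None) -> RunReport:
    """Run the preset model battery on a breeding table.

    Per-model failures (non-convergence, inestimable terms) are recorded in
    the report and the run continues.
    """
    t0 = time.time()
    from . import __version__

    report = RunReport(config=dict(config or {}), version=__version__)
    names = presets or list(PRESETS)
    fits = {}
    for name in names:
        try:
            data, spec = PRESETS[name](table)
            fit = MixedModel.from_dataframe(data, spec).fit()
            fits[name] = fit
            report.models[name] = _model_record(fit)
        except Exception as exc:  # reported, run continues
            report.models[name] = {"error": f"{type(exc).__name__}: {exc}"}

    for name, fit in fits.items():
        if name.startswith("parental_"):
            parent = name.rsplit("_", 1)[-1]
            kind = "tl" if "tl" in name else "age"
            part = variance_partition(
                fit,
                mean_term=f"mean_{kind}_{parent}",
                delta_term=f"delta_{kind}_{parent}",
            )
            report.partitions[name] = {
                "fixed_term_variance": part.fixed_term_variance,
                "random_percent": part.random_percent,
                "slope_percent": part.slope_percent,
                "r2": part.r2,
                "total_variance": part.total_variance,
                "epigenetic_fraction": part.epigenetic_fraction,
            }

    derived: dict[str, float] = {}
    r, n_nests = mate_age_correlation(table)
    derived["mate_age_correlation"] = r
    derived["n_nests"] = n_nests
    derived["n_offspring"] = int(len(table))
    derived["n_crossfostered"] = int(table["cross_fostered"].sum())
    try:
        derived["father_attrition_bp_per_yr"] = parental_attrition(table, "father")
    except Exception:
        pass

    fa = fits.get("parental_age_father")
    if fa is not None and "delta_age_father" in fa.params:
        b_delta = float(fa.params["delta_age_father"])
        derived["delta_age_father_bp_per_yr"] = b_delta
        derived["predicted_delta_age_mother_bp_per_yr"] = predicted_partner_slope(
            r, b_delta)
    if "parental_age_mother" in fits:
        derived["delta_age_mother_bp_per_yr"] = float(
            fits["parental_age_mother"].params["delta_age_mother"])

    ftl = fits.get("parental_tl_father")
    mtl = fits.get("parental_tl_mother")
    if ftl is not None and mtl is not None:
        b_f = float(ftl.params["mean_tl_father"]) / 1000.0   # bp/kb -> bp/bp
        b_m = float(mtl.params["mean_tl_mother"]) / 1000.0
        derived["slope_father_mean_bp_per_bp"] = b_f
        derived["slope_mother_mean_bp_per_bp"] = b_m
        derived["heritability_slope_sum"] = heritability_from_slopes(b_f, b_m)
        part = report.partitions.get("parental_tl_father", {})
        if part.get("epigenetic_fraction") is not None:
            derived["epigenetic_fraction"] = part["epigenetic_fraction"]

    cf = fits.get("crossfoster")
    if cf is not None:
        diff, se, z = compare_coefficients(cf, "caring_father_age",
                                           "father_age_diff")
        derived["crossfoster_coef_difference"] = diff
        derived["crossfoster_coef_difference_se"] = se
        derived["crossfoster_coef_difference_z"] = z

    report.derived = derived
    report.elapsed_s = time.time() - t0
    return report


# ---------------------------------------------------------------------------
# simulation study
# ---------------------------------------------------------------------------

@dataclass
class StudyReport:
    """Parameter-recovery summary over simulation replicates."""

    n_replicates: int
    n_failed: int
    stats: dict  # name -> {truth, mean, bias, mc_se, sd, coverage}
    config: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        text = json.dumps(_jsonify(self.__dict__), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def summary(self) -> str:
        lines = [f"simulation study: {self.n_replicates} replicates "
                 f"({self.n_failed} failed)"]
        for name, s in self.stats.items():
            lines.append(
                f"  {name}: truth {s['truth']:.3f}, mean {s['mean']:.3f}, "
                f"bias {s['bias']:.3f} (MC se {s['mc_se']:.3f}), "
                f"coverage {s['coverage']:.3f}")
        return "\n".join(lines)


def run_simulation_study(params: SimParams, n_replicates: int = 100,
                         seed: int = 0, full: bool = False,
                         n_starts: int = 1) -> StudyReport:
    """Replicated simulate-and-refit study.

    Tracks the within-father age coefficient (truth ``beta_paternal_age +
    carry_over * adult_attrition + beta_care_age``) and, with ``full=True``,
    the attrition rate and the parent-offspring mean-TL slopes.  Coverage is
    the share of replicates whose 95% Wald interval contains the truth.
    ``n_starts=1`` speeds up the inner REML fits; the study's replication
    already protects against the occasional boundary trap.
    """
    rng = np.random.default_rng(seed)
    truth_delta = (params.beta_paternal_age
                   + params.carry_over * params.adult_attrition
                   + params.beta_care_age)
    est: dict[str, list[float]] = {"delta_age_father": []}
    cover: list[bool] = []
    if full:
        est["attrition"] = []
        est["h2_slope_sum"] = []
    n_failed = 0

    for _ in range(n_replicates):
        p = params.replace(seed=int(rng.integers(2**31 - 1)))
        try:
            table = simulate_population(p)
            data, spec = _prep_parent_age(table, "father")
            fit = MixedModel.from_dataframe(data, spec).fit(n_starts=n_starts)
            if not fit.converged:
                n_failed += 1
                continue
            b = float(fit.params["delta_age_father"])
            se = float(fit.bse["delta_age_father"])
            est["delta_age_father"].append(b)
            cover.append(abs(b - truth_delta) <= 1.96 * se)
            if full:
                est["attrition"].append(parental_attrition(table, "father"))
                d_f, s_f = _prep_parent_tl(table, "father")
                d_m, s_m = _prep_parent_tl(table, "mother")
                bf = float(MixedModel.from_dataframe(d_f, s_f)
                           .fit(n_starts=n_starts).params["mean_tl_father"])
                bm = float(MixedModel.from_dataframe(d_m, s_m)
                           .fit(n_starts=n_starts).params["mean_tl_mother"])
                est["h2_slope_sum"].append((bf + bm) / 1000.0)
        except Exception:
            n_failed += 1

    truths = {"delta_age_father": truth_delta,
              "attrition": params.adult_attrition,
              "h2_slope_sum": params.slope_father_mean + params.slope_mother_mean}
    stats = {}
    for name, vals in est.items():
        arr = np.asarray(vals, dtype=float)
        if len(arr) == 0:
            continue
        stats[name] = {
            "truth": truths[name],
            "mean": float(arr.mean()),
            "bias": float(arr.mean() - truths[name]),
            "mc_se": float(arr.std(ddof=1) / np.sqrt(len(arr))) if len(arr) > 1 else float("nan"),
            "sd": float(arr.std(ddof=1)) if len(arr) > 1 else float("nan"),
            "coverage": float(np.mean(cover)) if name == "delta_age_father" else float("nan"),
        }
    return StudyReport(
        n_replicates=n_replicates,
        n_failed=n_failed,
        stats=stats,
        config=params.to_dict(),
    )
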