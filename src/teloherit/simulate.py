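"""Synthetic longitudinal breeding data with a known inheritance structure.

Simulates a small colonial, socially monogamous bird population (persistent
pair bonds, annual broods, chicks blood-sampled at 2-4 days) and generates
offspring telomere length (TL, bp) from an explicit generative model::

    TL_i = mu
         + slope_father_mean * (G_f - mu)                  # additive path, father
         + slope_mother_mean * (G_m - mu)                  # additive path, mother
         + carry_over * (TL_f(t) - G_f - centred attrition)# gamete-TL carry-over
         + beta_paternal_age * age_f(t)                    # conception-age effect
         + beta_care_age     * age of caring father        # post-laying care effect
         + beta_offspring_age * age_d                      # nestling age at sampling
         + nest + gel + residual                           # noise layers

where ``G`` is an individual's genetic (recruitment) mean TL and
``TL_f(t) = G_f + adult_attrition * years since recruitment + noise`` is the
father's current TL.  The carry-over term is centred on the father's mean
breeding age so that, like the conception-age term, it is a pure
within-father effect.  With ``carry_over = 0`` the within-father offspring-TL
decline equals ``beta_paternal_age``; with ``beta_paternal_age = 0`` and
``carry_over > 0`` it equals ``carry_over * adult_attrition`` — the two
generative routes (transient vs carry-over gamete effect) that the
cross-sectional literature cannot distinguish.

Pair bonds persist across years with stochastic mortality and divorce, which
makes father and mother ages correlate strongly — the confound the
within-subject-centred analysis has to deal with.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .io import validate_table

__all__ = ["SimParams", "simulate_population", "apply_crossfoster"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SimParams:
    """Full parameterization of the generative model.

    Defaults emulate the study system: ~25 breeding pairs followed for 12
    seasons (~200 fathers, ~300 nests, ~700 sampled chicks), within-adult TL
    attrition of -87 bp/yr, a within-father conception-age effect of -56
    bp/yr on offspring TL, parent-offspring mean-TL slopes of 0.26 (father)
    and 0.46 (mother) bp/bp, a mate-age correlation near 0.75 from
    persistent pair bonds, and ~10% of nests cross-fostered.
    """

    n_pairs_start: int = 25
    n_years: int = 12
    adult_mortality: float = 0.35   # per year
    divorce_prob: float = 0.05      # per year, both pair members alive
    pairing_age_jitter: float = 0.7  # yr, SD of rank noise in assortative pairing
    recruit_age_mean: float = 1.7   # recruits enter at age 1 or 2
    chicks_per_nest_range: tuple[int, int] = (2, 3)
    offspring_sample_age_range: tuple[int, int] = (2, 4)  # days
    mu_tl0: float = 7500.0          # bp, population mean adult TL at recruitment
    sd_tl0_genetic: float = 550.0   # bp, between-individual additive SD
    sd_tl_adult_noise: float = 100.0  # bp, year-to-year fluctuation of adult TL
    adult_attrition: float = -87.0  # bp/yr within-adult TL change
    beta_paternal_age: float = -56.0  # bp per yr of father age at conception
    beta_offspring_age: float = -32.0  # bp per day of nestling age
    slope_father_mean: float = 0.26  # bp/bp
    slope_mother_mean: float = 0.46  # bp/bp
    carry_over: float = 0.0         # fraction of within-father TL deviation transmitted
    sd_nest: float = 250.0          # bp
    sd_gel: float = 300.0           # bp
    sd_resid: float = 350.0         # bp
    gel_capacity: int = 25          # lanes per gel
    crossfoster_fraction: float = 0.10  # proportion of nests
    beta_care_age: float = 0.0      # bp per yr of caring-father age
    max_age: int = 13               # years, oldest plausible breeder
    seed: int = 0

    def __post_init__(self):
        for name in ("sd_tl0_genetic", "sd_tl_adult_noise", "sd_nest", "sd_gel",
                     "sd_resid"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("adult_mortality", "divorce_prob", "carry_over",
                     "crossfoster_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        lo, hi = self.offspring_sample_age_range
        if not (2 <= lo <= hi <= 4):
            raise ValueError("offspring_sample_age_range must lie within [2, 4] days")
        lo, hi = self.chicks_per_nest_range
        if not (1 <= lo <= hi):
            raise ValueError("chicks_per_nest_range must be increasing and >= 1")
        if not 1.0 <= self.recruit_age_mean <= 2.0:
            raise ValueError("recruit_age_mean must be in [1, 2]")

    def replace(self, **kwargs) -> "SimParams":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["chicks_per_nest_range"] = list(d["chicks_per_nest_range"])
        d["offspring_sample_age_range"] = list(d["offspring_sample_age_range"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimParams":
        d = dict(d)
        for key in ("chicks_per_nest_range", "offspring_sample_age_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimParams":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class _Adult:
    """A breeding adult; TL state is latent truth."""

    id: str
    sex: str               # 'M' or 'F'
    age: int               # years
    recruit_age: int       # age in the year of recruitment
    g: float               # genetic (recruitment) mean TL, bp

    def tl_current(self, params: SimParams, noise: float) -> float:
        return self.g + params.adult_attrition * (self.age - self.recruit_age) + noise


def _recruit_age(params: SimParams, rng: np.random.Generator) -> int:
    # recruits enter at 1 or 2 years; P(age 2) set by recruit_age_mean
    return 1 + int(rng.random() < (params.recruit_age_mean - 1.0))


def _new_adult(params: SimParams, rng: np.random.Generator, sex: str,
               counter: list[int], age: int | None = None) -> _Adult:
    counter[0] += 1
    ra = _recruit_age(params, rng)
    if age is None:
        age = ra
    return _Adult(
        id=f"{sex}{counter[0]:04d}",
        sex=sex,
        age=age,
        recruit_age=min(ra, age),
        g=rng.normal(params.mu_tl0, params.sd_tl0_genetic),
    )


def simulate_population(params: SimParams) -> pd.DataFrame:
    """Simulate the colony and return a validated breeding table.

    Two passes: demography first (pairs, ages, nests, brood sizes), then
    offspring TL, so the carry-over term can be centred on each father's
    realised mean breeding age.  Non-positive simulated TLs are redrawn
    (fresh residual); if more than 1% of rows need a redraw a warning is
    emitted, signalling implausible parameters.
    """
    rng = np.random.default_rng(params.seed)
    counters = {"M": [0], "F": [0]}

    # initial standing population: ages from recruit age + geometric survival
    def initial_age(sex: str) -> int:
        extra = rng.geometric(max(params.adult_mortality, 1e-3)) - 1
        return min(_recruit_age(params, rng) + int(extra), params.max_age)

    init_m = [_new_adult(params, rng, "M", counters["M"], age=initial_age("M"))
              for _ in range(params.n_pairs_start)]
    init_f = [_new_adult(params, rng, "F", counters["F"], age=initial_age("F"))
              for _ in range(params.n_pairs_start)]
    # founding pairs are age-assortative, like all later re-pairing
    init_m.sort(key=lambda a: a.age + rng.normal(0.0, params.pairing_age_jitter))
    init_f.sort(key=lambda a: a.age + rng.normal(0.0, params.pairing_age_jitter))
    pairs: list[tuple[_Adult, _Adult]] = list(zip(init_m, init_f))

    nests = []       # (year, nest_id, father, mother, father_age, mother_age, brood)
    adult_noise: dict[tuple[str, int], float] = {}
    nest_counter = 0
    lo_b, hi_b = params.chicks_per_nest_range

    for year in range(params.n_years):
        for male, female in pairs:
            nest_counter += 1
            brood = int(rng.integers(lo_b, hi_b + 1))
            for ad in (male, female):
                adult_noise[(ad.id, year)] = rng.normal(0.0, params.sd_tl_adult_noise)
            nests.append({
                "year": year,
                "nest_id": f"N{nest_counter:04d}",
                "father": male,
                "mother": female,
                "father_age": male.age,
                "mother_age": female.age,
                "father_tl": male.tl_current(params, adult_noise[(male.id, year)]),
                "mother_tl": female.tl_current(params, adult_noise[(female.id, year)]),
                "brood": brood,
            })

        # end-of-season demography: mortality, divorce, re-pairing
        bonded: list[tuple[_Adult, _Adult]] = []
        free_m: list[_Adult] = []
        free_f: list[_Adult] = []
        for male, female in pairs:
            m_alive = (rng.random() >= params.adult_mortality
                       and male.age < params.max_age)
            f_alive = (rng.random() >= params.adult_mortality
                       and female.age < params.max_age)
            if m_alive:
                male.age += 1
            if f_alive:
                female.age += 1
            if m_alive and f_alive:
                if rng.random() >= params.divorce_prob:
                    bonded.append((male, female))
                else:
                    free_m.append(male)
                    free_f.append(female)
            elif m_alive:
                free_m.append(male)
            elif f_alive:
                free_f.append(female)
        n_new = params.n_pairs_start - len(bonded)
        while len(free_m) < n_new:
            free_m.append(_new_adult(params, rng, "M", counters["M"]))
        while len(free_f) < n_new:
            free_f.append(_new_adult(params, rng, "F", counters["F"]))
        # surplus free birds of one sex leave the breeding pool at random
        if len(free_m) > n_new:
            free_m = [free_m[i] for i in rng.permutation(len(free_m))[:n_new]]
        if len(free_f) > n_new:
            free_f = [free_f[i] for i in rng.permutation(len(free_f))[:n_new]]
        # age-assortative re-pairing: free birds (mostly new recruits, some
        # widowed/divorced older adults) pair by age rank with jitter.  Pure
        # random re-pairing cannot reproduce the strong mate-age correlation
        # observed in colonies with this much turnover.
        free_m.sort(key=lambda a: a.age + rng.normal(0.0, params.pairing_age_jitter))
        free_f.sort(key=lambda a: a.age + rng.normal(0.0, params.pairing_age_jitter))
        pairs = bonded + list(zip(free_m, free_f))

    # father mean breeding age over his distinct breeding years (centres carry-over)
    father_ages: dict[str, list[int]] = {}
    for nest in nests:
        father_ages.setdefault(nest["father"].id, []).append(nest["father_age"])
    abar = {fid: float(np.mean(ages)) for fid, ages in father_ages.items()}

    rows = []
    n_redrawn = 0
    lo_a, hi_a = params.offspring_sample_age_range
    chick = 0
    for nest in nests:
        father, mother = nest["father"], nest["mother"]
        nest_eff = rng.normal(0.0, params.sd_nest)
        carry_dev = nest["father_tl"] - father.g - params.adult_attrition * (
            abar[father.id] - father.recruit_age
        )
        for _ in range(nest["brood"]):
            chick += 1
            age_d = int(rng.integers(lo_a, hi_a + 1))
            mean_part = (
                params.mu_tl0
                + params.slope_father_mean * (father.g - params.mu_tl0)
                + params.slope_mother_mean * (mother.g - params.mu_tl0)
                + params.carry_over * carry_dev
                + params.beta_paternal_age * nest["father_age"]
                + params.beta_care_age * nest["father_age"]   # caring == genetic here
                + params.beta_offspring_age * age_d
                + nest_eff
            )
            tl = mean_part + rng.normal(0.0, params.sd_resid)
            tries = 0
            while tl <= 0 and tries < 100:
                tl = mean_part + rng.normal(0.0, params.sd_resid)
                n_redrawn += 1
                tries += 1
            if tl <= 0:
                raise RuntimeError("cannot draw a positive offspring TL; "
                                   "parameters are implausible")
            rows.append({
                "offspring_id": f"C{chick:05d}",
                "year": nest["year"],
                "nest_id": nest["nest_id"],
                "offspring_age_d": age_d,
                "offspring_tl_bp": tl,
                "father_id": father.id,
                "mother_id": mother.id,
                "foster_father_id": father.id,
                "foster_mother_id": mother.id,
                "father_age_y": float(nest["father_age"]),
                "mother_age_y": float(nest["mother_age"]),
                "foster_father_age_y": float(nest["father_age"]),
                "foster_mother_age_y": float(nest["mother_age"]),
                "father_tl_bp": nest["father_tl"],
                "mother_tl_bp": nest["mother_tl"],
                "cross_fostered": False,
            })

    if rows and n_redrawn > 0.01 * len(rows):
        warnings.warn(
            f"{n_redrawn} of {len(rows)} offspring TL draws were non-positive and "
            "redrawn (>1%): parameters look implausible", stacklevel=2)

    table = pd.DataFrame(rows)

    # gel assignment: chicks spread randomly over gels of fixed lane capacity
    order = rng.permutation(len(table))
    gel_of = np.empty(len(table), dtype=int)
    gel_of[order] = np.arange(len(table)) // params.gel_capacity
    gel_ids = np.array([f"G{g + 1:03d}" for g in gel_of])
    gel_eff = rng.normal(0.0, params.sd_gel, size=gel_of.max() + 1 if len(table) else 0)
    table["gel_id"] = gel_ids
    table["offspring_tl_bp"] = table["offspring_tl_bp"] + gel_eff[gel_of]

    if params.crossfoster_fraction > 0:
        table = apply_crossfoster(
            table,
            params.crossfoster_fraction,
            seed=int(rng.integers(2**31 - 1)),
            beta_care_age=params.beta_care_age,
        )
    return validate_table(table)


def apply_crossfoster(table: pd.DataFrame, fraction: float, seed: int,
                      beta_care_age: float = 0.0) -> pd.DataFrame:
    """Cross-foster whole clutches by pairwise swapping nests within a year.

    An even number of nests per year is selected (summing to ~``fraction`` of
    all nests) and swapped pairwise: foster parent IDs and ages are
    exchanged, genetic IDs stay.  When the generative model includes a
    post-laying care-age effect (``beta_care_age`` != 0), offspring TL is
    adjusted by ``beta_care_age * (foster father age - genetic father age)``,
    because the care term was generated against the genetic father.

    Years holding fewer than 2 nests cannot host a swap and are skipped with
    a log note.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    if table["cross_fostered"].any():
        raise ValueError("table already contains cross-fostered nests")
    out = table.copy().reset_index(drop=True)
    if fraction == 0 or not len(out):
        return out
    rng = np.random.default_rng(seed)

    nests = out[["nest_id", "year"]].drop_duplicates()
    total_target = int(round(fraction * len(nests) / 2.0)) * 2

    years = sorted(nests["year"].unique())
    per_year = {y: 0 for y in years}
    capacity = {y: (len(nests[nests["year"] == y]) // 2) * 2 for y in years}
    for y in years:
        if fraction > 0 and len(nests[nests["year"] == y]) < 2:
            logger.info("year %s has < 2 nests; cross-fostering skipped there", y)
    assigned = 0
    while assigned < total_target:
        open_years = [y for y in years if per_year[y] + 2 <= capacity[y]]
        if not open_years:
            break
        y = max(open_years, key=lambda yy: capacity[yy] - per_year[yy])
        per_year[y] += 2
        assigned += 2

    parent_cols = ["father_id", "mother_id", "father_age_y", "mother_age_y"]
    foster_cols = ["foster_father_id", "foster_mother_id",
                   "foster_father_age_y", "foster_mother_age_y"]
    for y in years:
        k = per_year[y]
        if k == 0:
            continue
        pool = nests.loc[nests["year"] == y, "nest_id"].to_numpy()
        chosen = rng.choice(pool, size=k, replace=False)
        rng.shuffle(chosen)
        for a, b in zip(chosen[0::2], chosen[1::2]):
            ia = out.index[out["nest_id"] == a]
            ib = out.index[out["nest_id"] == b]
            pa = out.loc[ia[0], parent_cols].to_numpy()
            pb = out.loc[ib[0], parent_cols].to_numpy()
            out.loc[ia, foster_cols] = pb
            out.loc[ib, foster_cols] = pa
            out.loc[list(ia) + list(ib), "cross_fostered"] = True

    if beta_care_age != 0.0:
        swapped = out["cross_fostered"]
        out.loc[swapped, "offspring_tl_bp"] = (
            out.loc[swapped, "offspring_tl_bp"]
            + beta_care_age
            * (out.loc[swapped, "foster_father_age_y"]
               - out.loc[swapped, "father_age_y"])
        )
    return out
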