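"""Within-subject centering of longitudinal parental covariates.

Splits a covariate ``x`` observed repeatedly per parent into a
between-individual component (the parent's mean over their sampled breeding
years) and a within-individual component (the deviation from that mean).  In
a regression the mean's coefficient estimates the cross-sectional
(between-parent) effect, the delta's coefficient the longitudinal
(within-parent) effect — the decomposition that lets a parental-age or
parental-TL effect be attributed to change within individuals rather than to
which individuals reproduce at which ages.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["within_subject_center"]


def within_subject_center(
    table: pd.DataFrame,
    covariate: str,
    group: str,
    level: str = "year",
    year: str = "year",
    names: tuple[str, str] | None = None,
) -> pd.DataFrame:
    """Add ``mean_<covariate>`` and ``delta_<covariate>`` columns.

    Parameters
    ----------
    table
        Breeding table (or any long-format frame).
    covariate
        Numeric column to centre (e.g. ``father_age_y``).
    group
        Grouping column identifying the subject (e.g. ``father_id``).
    level
        ``"year"`` (default): the per-subject mean is taken over the
        subject's *distinct* breeding years, each year counted once however
        many chicks it contributed.  ``"row"``: plain mean over rows, so
        larger broods weight the mean.
    year
        Year column used when ``level="year"``.
    names
        Optional explicit ``(mean_name, delta_name)`` output column names.

    Subjects observed in a single year get delta 0 for all their rows: they
    inform the between- but not the within-individual effect.

    Notes
    -----
    Row-wise, ``mean + delta`` reconstructs the covariate exactly, and within
    every subject the delta averages to zero over the subject's distinct
    years (``level="year"``) or rows (``level="row"``).  Centering a delta
    column again returns it unchanged (idempotence).
    """
    if covariate not in table.columns:
        raise KeyError(f"covariate column {covariate!r} not in table")
    if group not in table.columns:
        raise KeyError(f"group column {group!r} not in table")
    x = pd.to_numeric(table[covariate], errors="coerce")
    if x.isna().any():
        raise ValueError(
            f"covariate {covariate!r} is non-numeric or missing in scope")
    if level not in ("year", "row"):
        raise ValueError("level must be 'year' or 'row'")

    out = table.copy()
    work = pd.DataFrame({group: table[group], "_x": x.to_numpy()})
    if level == "year":
        if year not in table.columns:
            raise KeyError(f"year column {year!r} required for level='year'")
        work[year] = table[year]
        # one value per (subject, year), then average over years
        per_year = work.groupby([group, year], sort=False)["_x"].mean()
        means = per_year.groupby(level=0, sort=False).mean()
    else:
        means = work.groupby(group, sort=False)["_x"].mean()

    mean_name, delta_name = names or (f"mean_{covariate}", f"delta_{covariate}")
    mean_col = table[group].map(means).astype(float)
    out[mean_name] = mean_col.to_numpy()
    out[delta_name] = x.to_numpy() - mean_col.to_numpy()
    # guard against float fuzz breaking the exact reconstruction identity
    assert np.allclose(out[mean_name] + out[delta_name], x, atol=1e-9)
    return out
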