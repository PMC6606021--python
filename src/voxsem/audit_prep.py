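"""Scoring and two-part decomposition of AUDIT-style questionnaire data.

The AUDIT (Alcohol Use Disorders Identification Test) consists of ten
items scored 0-4; the sum score ranges 0-40 and is strongly zero
inflated in adolescent samples.  For growth modelling the score is split
into a binary any-use indicator (score > 0) and a continuous
score-given-use part in which structural zeros are treated as missing
under the usual MAR assumptions.
"""

from __future__ import annotations

import enum

import numpy as np
import pandas as pd

from .growth import TwoPartData

__all__ = [
    "SeverityCategory",
    "compute_sum_score",
    "categorize_severity",
    "severity_table",
    "decompose_two_part",
    "log_transform",
    "ITEM_COLUMNS",
]

ITEM_COLUMNS = [f"item_{k}" for k in range(1, 11)]


class SeverityCategory(enum.IntEnum):
    """WHO interpretation bands of the AUDIT sum score.

    0 = no use; 1-7 unproblematic use; 8-15 medium-level problems
    (simple advice warranted); 16-19 high-level problems (brief
    counselling warranted); 20+ indicates possible dependence (further
    diagnostics warranted).
    """

    no_use = 0
    unproblematic = 1
    medium_problems = 2
    high_problems = 3
    dependence_indicated = 4


_SEVERITY_LABELS = {
    SeverityCategory.no_use: "No use at all",
    SeverityCategory.unproblematic: "Unproblematic use",
    SeverityCategory.medium_problems: "Medium level of alcohol problems",
    SeverityCategory.high_problems: "High level of alcohol problems",
    SeverityCategory.dependence_indicated: "Indicating dependence",
}


def compute_sum_score(items: pd.DataFrame, mode: str = "strict") -> pd.DataFrame:
    """Total AUDIT score: the sum of the ten item scores.

    Parameters
    ----------
    items:
        Long-format table with ``subject_id``, ``occasion`` and
        ``item_1`` .. ``item_10`` columns (values 0-4 or missing).
    mode:
        ``"strict"`` (default): any missing item yields a missing sum.
        ``"prorate"``: scale the mean of the answered items up to ten
        items (rounded to the nearest integer); all-missing rows stay
        missing.

    Returns
    -------
    DataFrame with ``subject_id``, ``occasion`` and ``sum_score``.
    """
    if mode not in ("strict", "prorate"):
        raise ValueError("mode must be 'strict' or 'prorate'")
    missing_cols = [c for c in ITEM_COLUMNS if c not in items.columns]
    if missing_cols:
        raise ValueError(f"missing item columns: {missing_cols}")
    vals = items[ITEM_COLUMNS].to_numpy(dtype=float)
    finite = np.isfinite(vals)
    bad = finite & ((vals < 0) | (vals > 4) | (vals != np.round(vals)))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"item score out of range (0-4): subject "
            f"{items['subject_id'].iloc[i]!r}, occasion {items['occasion'].iloc[i]!r}, "
            f"{ITEM_COLUMNS[j]}={vals[i, j]}"
        )
    if mode == "strict":
        sums = np.where(finite.all(axis=1), np.nansum(vals, axis=1), np.nan)
    else:
        n_ans = finite.sum(axis=1)
        with np.errstate(invalid="ignore"):
            sums = np.where(n_ans > 0, np.round(np.nansum(vals, axis=1) * 10.0 / np.maximum(n_ans, 1)), np.nan)
    return pd.DataFrame(
        {
            "subject_id": items["subject_id"].to_numpy(),
            "occasion": items["occasion"].to_numpy(),
            "sum_score": sums,
        }
    )


def categorize_severity(score) -> "SeverityCategory | np.ndarray":
    """Map a sum score (0-40) onto the WHO severity bands.

    Accepts a scalar or an array; missing values map to missing.
    """
    arr = np.asarray(score, dtype=float)
    scalar = arr.ndim == 0
    arr = np.atleast_1d(arr)
    finite = np.isfinite(arr)
    if np.any(finite & ((arr < 0) | (arr > 40))):
        raise ValueError("sum score must lie in 0-40")
    out = np.full(arr.shape, np.nan)
    out[finite & (arr == 0)] = SeverityCategory.no_use
    out[finite & (arr >= 1) & (arr <= 7)] = SeverityCategory.unproblematic
    out[finite & (arr >= 8) & (arr <= 15)] = SeverityCategory.medium_problems
    out[finite & (arr >= 16) & (arr <= 19)] = SeverityCategory.high_problems
    out[finite & (arr >= 20)] = SeverityCategory.dependence_indicated
    if scalar:
        return SeverityCategory(int(out[0]))
    return out


def severity_table(sums: pd.DataFrame) -> pd.DataFrame:
    """Counts and percentages per severity band and occasion.

    Mirrors the usual cohort description layout: one row per band, one
    column pair (n, %) per occasion; percentages are relative to the
    non-missing scores at that occasion.
    """
    out = {}
    for occ, grp in sums.groupby("occasion"):
        s = grp["sum_score"].to_numpy(dtype=float)
        s = s[np.isfinite(s)]
        cats = categorize_severity(s) if s.size else np.zeros(0)
        n_tot = s.size
        counts = [int(np.sum(cats == c)) for c in SeverityCategory]
        out[f"n_occ{occ}"] = counts
        out[f"pct_occ{occ}"] = [100.0 * c / n_tot if n_tot else np.nan for c in counts]
    return pd.DataFrame(out, index=[_SEVERITY_LABELS[c] for c in SeverityCategory])


def decompose_two_part(
    sums: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    occasion_times=None,
) -> TwoPartData:
    """Split sum scores into the binary and continuous model parts.

    binary = 1 for any positive score, 0 for a zero score, missing where
    the score is missing; continuous carries the score where positive
    and is missing otherwise (zeros become structural missings of the
    continuous part).

    ``covariates`` is an optional per-subject frame indexed or ordered
    by ``subject_id``.
    """
    dup = sums.duplicated(subset=["subject_id", "occasion"])
    if dup.any():
        first = sums.loc[dup, ["subject_id", "occasion"]].iloc[0]
        raise ValueError(
            f"duplicate subject x occasion row: subject {first['subject_id']!r}, "
            f"occasion {first['occasion']!r}"
        )
    wide = sums.pivot(index="subject_id", columns="occasion", values="sum_score").sort_index(axis=1)
    scores = wide.to_numpy(dtype=float)
    # a zero score codes non-use; any other value codes use (instrument
    # scores are non-negative integers, so this is "score > 0" there, and
    # it stays consistent for model-scale synthetic scores)
    binary = np.where(np.isfinite(scores), (scores != 0).astype(float), np.nan)
    continuous = np.where(np.isfinite(scores) & (scores != 0), scores, np.nan)
    cov = None
    if covariates is not None:
        cov = covariates.set_index("subject_id") if "subject_id" in covariates.columns else covariates
        cov = cov.loc[wide.index]
    if occasion_times is None:
        occasion_times = np.arange(scores.shape[1], dtype=float)
    data = TwoPartData(
        binary,
        continuous,
        covariates=cov,
        occasion_times=np.asarray(occasion_times, dtype=float),
        subject_ids=wide.index.to_numpy(),
    )
    data.validate()
    return data


def log_transform(data: TwoPartData) -> TwoPartData:
    """Natural log of the positive scores; the binary part is untouched.

    Used as a robustness check against the skewness of score-given-use.
    Zeros never reach the continuous part, so no offset is needed; the
    missingness pattern is preserved exactly.
    """
    cont = data.continuous
    if np.any(np.isfinite(cont) & (cont <= 0)):
        raise ValueError("continuous part must be positive where observed")
    with np.errstate(invalid="ignore"):
        logged = np.where(np.isfinite(cont), np.log(cont), np.nan)
    return TwoPartData(
        data.binary.copy(), logged, data.covariates,
        data.occasion_times, data.subject_ids, data.voxel,
    )
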