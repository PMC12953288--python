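"""Steatosis grading rules and histology/MRI discordance constructs.

Two grading systems operate on the same 0-3 ordinal scale:

* **Histology** — pathologists estimate the percentage of hepatocytes that
  contain a large lipid droplet displacing the nucleus, and band it as
  S0 (< 5%), S1 (5-33%), S2 (34-66%), S3 (> 66%).  The printed bands live on
  integer percentages, leaving gaps on the real line (33 -> 34, 66 -> 67);
  inputs are therefore rounded half-up to an integer percent before banding,
  matching how pathologists report the estimate.
* **MRI-PDFF** — the proton density fat fraction (%) is banded with validated
  thresholds: S0 < 5.75, S1 >= 5.75, S2 >= 15.5, S3 >= 21.35, each threshold
  inclusive for the higher grade.

A pair of grades is *discordant* when they differ by at least one grade; the
direction records whether MRI over- or under-estimates relative to histology.
The scalar distance from a PDFF value to its closest grade threshold is a
candidate predictor of discordance: values far from every cutoff are robust
to measurement noise, values near a cutoff flip grades easily.

All graders accept scalars or numpy arrays; scalars in, scalars out.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

__all__ = [
    "PDFF_GRADE_THRESHOLDS",
    "Direction",
    "DiscordancePair",
    "grade_histology",
    "grade_pdff",
    "assess_discordance",
    "pdff_distance_to_threshold",
    "add_grading_columns",
]

#: PDFF cutoffs (%) for grades S1, S2, S3; each inclusive for the higher grade.
PDFF_GRADE_THRESHOLDS: tuple[float, float, float] = (5.75, 15.5, 21.35)


class Direction(str, Enum):
    """Direction of a histology/MRI grade disagreement."""

    CONCORDANT = "concordant"
    MRI_OVER = "mri_over"
    MRI_UNDER = "mri_under"


@dataclass(frozen=True)
class DiscordancePair:
    """One subject's histology grade vs MRI-PDFF grade comparison."""

    hist_grade: int
    pdff_grade: int
    discordant: bool
    magnitude: int
    direction: Direction


def _as_array(x, name: str):
    arr = np.asarray(x, dtype=float)
    if np.any(np.isnan(arr)):
        raise ValueError(f"{name} contains NaN")
    return arr


def grade_histology(pct_hepatocytes_large_ld):
    """Band the percentage of hepatocytes with large droplets into S0-S3.

    The input is rounded half-up to an integer percent, then banded:
    0-4 -> S0, 5-33 -> S1, 34-66 -> S2, 67-100 -> S3.

    Parameters
    ----------
    pct_hepatocytes_large_ld : float or array-like
        Percentage in [0, 100] of hepatocytes containing large (>= 100 um^2,
        nucleus-displacing) lipid droplets.

    Returns
    -------
    int or ndarray of int
        Steatosis grade(s) in {0, 1, 2, 3}.
    """
    arr = _as_array(pct_hepatocytes_large_ld, "pct_hepatocytes_large_ld")
    if np.any(arr < 0) or np.any(arr > 100):
        raise ValueError("hepatocyte percentage must lie in [0, 100]")
    pct = np.floor(arr + 0.5)  # round half-up: integer percent as reported
    grade = np.select([pct < 5, pct < 34, pct < 67], [0, 1, 2], default=3)
    return int(grade) if np.isscalar(pct_hepatocytes_large_ld) else grade.astype(int)


def grade_pdff(pdff_pct):
    """Band an MRI proton-density-fat-fraction (%) into PDFF-S0..S3.

    Thresholds 5.75 / 15.5 / 21.35 %, inclusive for the higher grade.
    """
    arr = _as_array(pdff_pct, "pdff_pct")
    if np.any(arr < 0):
        raise ValueError("PDFF must be non-negative")
    t1, t2, t3 = PDFF_GRADE_THRESHOLDS
    grade = np.select([arr < t1, arr < t2, arr < t3], [0, 1, 2], default=3)
    return int(grade) if np.isscalar(pdff_pct) else grade.astype(int)


def assess_discordance(hist_grade: int, pdff_grade: int) -> DiscordancePair:
    """Compare a histology grade with a PDFF grade.

    Discordance is a difference of >= 1 grade; ``magnitude`` is the absolute
    grade difference and ``direction`` records MRI over- vs under-estimation.
    """
    for name, g in (("hist_grade", hist_grade), ("pdff_grade", pdff_grade)):
        if g not in (0, 1, 2, 3):
            raise ValueError(f"{name} must be an integer in {{0,1,2,3}}, got {g!r}")
    diff = int(pdff_grade) - int(hist_grade)
    if diff > 0:
        direction = Direction.MRI_OVER
    elif diff < 0:
        direction = Direction.MRI_UNDER
    else:
        direction = Direction.CONCORDANT
    return DiscordancePair(
        hist_grade=int(hist_grade),
        pdff_grade=int(pdff_grade),
        discordant=diff != 0,
        magnitude=abs(diff),
        direction=direction,
    )


def pdff_distance_to_threshold(pdff_pct):
    """Scalar distance (%) from a PDFF value to its closest grade threshold.

    E.g. PDFF 3% and 18.25% both lie 2.75% from their nearest cutoffs
    (5.75% and 15.5%, respectively).  Only the three grade thresholds are
    considered; 0 and 100 are not cutoffs.
    """
    arr = _as_array(pdff_pct, "pdff_pct")
    if np.any(arr < 0):
        raise ValueError("PDFF must be non-negative")
    thresholds = np.asarray(PDFF_GRADE_THRESHOLDS)
    dist = np.min(np.abs(arr[..., None] - thresholds), axis=-1)
    return float(dist) if np.isscalar(pdff_pct) else dist


def add_grading_columns(cohort: pd.DataFrame) -> pd.DataFrame:
    """Append PDFF grading and discordance columns to a cohort table.

    Requires ``pdff_pct`` and ``hist_grade``; returns a copy with
    ``pdff_grade``, ``discordant`` (0/1), ``magnitude``, ``direction`` and
    ``pdff_distance`` appended.
    """
    for col in ("pdff_pct", "hist_grade"):
        if col not in cohort.columns:
            raise ValueError(f"cohort is missing required column {col!r}")
    out = cohort.copy()
    pdff = out["pdff_pct"].to_numpy(dtype=float)
    hist = out["hist_grade"].to_numpy()
    if not np.isin(hist, [0, 1, 2, 3]).all():
        raise ValueError("hist_grade values must lie in {0,1,2,3}")
    pg = grade_pdff(pdff)
    diff = pg - hist
    out["pdff_grade"] = pg
    out["discordant"] = (diff != 0).astype(int)
    out["magnitude"] = np.abs(diff).astype(int)
    out["direction"] = np.select(
        [diff > 0, diff < 0],
        [Direction.MRI_OVER.value, Direction.MRI_UNDER.value],
        default=Direction.CONCORDANT.value,
    )
    out["pdff_distance"] = pdff_distance_to_threshold(pdff)
    return out
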