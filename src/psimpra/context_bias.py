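"""Sequence-context bias analysis of the 729-reporter mixing experiment.

Each reporter carries a single modifiable U followed by one of the 3^6
hexamers over {A,C,G}.  Two analyses quantify how well psi-scores track
stoichiometry and how much the downstream context distorts them:

* per-reporter ordinary least squares of psi-score on psi fraction
  (linearity of the readout);
* a coefficient-of-variation ladder: reporters grouped by their first k
  downstream bases (k = 0..5, i.e. 1 group of 729 down to 243 groups of
  3), per-group CV = sd/mean with sample sd, averaged over groups.  The
  drop of mean CV with k measures how much proximal sequence context
  inflates apparent score variability.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

ALL_HEXAMERS = tuple("".join(p) for p in itertools.product("ACG", repeat=6))


@dataclass(frozen=True)
class MixSeries:
    """Psi-scores of one reporter across an increasing psi-fraction series."""

    hexamer: str
    ratios: tuple
    scores: tuple

    def __post_init__(self):
        r = tuple(float(x) for x in self.ratios)
        s = tuple(float(x) for x in self.scores)
        object.__setattr__(self, "ratios", r)
        object.__setattr__(self, "scores", s)
        if len(r) != len(s):
            raise ValueError("ratios and scores must align")
        if any(b <= a for a, b in zip(r, r[1:])):
            raise ValueError("ratios must be strictly increasing")
        if any(not 0 <= x <= 1 for x in r + s):
            raise ValueError("ratios and scores must lie in [0,1]")


@dataclass(frozen=True)
class CVReport:
    k: int
    n_groups: int
    group_size: int
    mean_cv: float
    per_group_cv: tuple
    n_zero_mean_groups: int = 0

    def __post_init__(self):
        if self.n_groups != 3 ** self.k or self.group_size != 3 ** (6 - self.k):
            raise ValueError("group arithmetic must satisfy 3^k x 3^(6-k) = 729")


def fit_linearity(series: MixSeries) -> tuple[float, float, float]:
    """OLS of score on psi fraction: (slope, intercept, R^2).

    Constant scores give slope 0 and, by convention, R^2 = 0 (no variance
    explained).  Fewer than three points or constant ratios are errors.
    """
    x = np.asarray(series.ratios)
    y = np.asarray(series.scores)
    if len(x) < 3:
        raise ValueError("linearity fit needs at least 3 points")
    if np.allclose(x, x[0]):
        raise ValueError("ratios are constant")
    if np.allclose(y, y[0]):
        return 0.0, float(y[0]), 0.0
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue ** 2)


def fit_linearity_table(scores: pd.DataFrame) -> pd.DataFrame:
    """Per-hexamer linearity fits from a long table (hexamer, ratio, score)."""
    rows = []
    for hexamer, grp in scores.groupby("hexamer", sort=True):
        grp = grp.sort_values("ratio")
        slope, intercept, r2 = fit_linearity(
            MixSeries(hexamer, tuple(grp["ratio"]), tuple(grp["score"]))
        )
        rows.append({"hexamer": hexamer, "slope": slope,
                     "intercept": intercept, "r2": r2})
    return pd.DataFrame(rows)


def _validate_hexamer_scores(scores_by_hexamer: Mapping[str, float]) -> np.ndarray:
    missing = [h for h in ALL_HEXAMERS if h not in scores_by_hexamer]
    if missing:
        head = ", ".join(missing[:5])
        raise ValueError(
            f"scores missing for {len(missing)} of 729 hexamers (e.g. {head})"
        )
    return np.array([float(scores_by_hexamer[h]) for h in ALL_HEXAMERS])


def cv_decomposition(scores_by_hexamer: Mapping[str, float], k: int) -> CVReport:
    """Mean per-group CV with the first k downstream bases fixed.

    Partitions the 729 hexamers by their first k characters (3^k groups of
    3^(6-k)); per-group CV = sample sd / mean; groups with mean 0 are
    excluded with a logged count; the report carries the unweighted mean
    over the remaining groups.
    """
    if not 0 <= k <= 5:
        raise ValueError("k must be in 0..5 (k=6 would give singleton groups)")
    values = _validate_hexamer_scores(scores_by_hexamer)
    group_size = 3 ** (6 - k)
    groups = values.reshape(3 ** k, group_size)  # lexicographic order blocks
    means = groups.mean(axis=1)
    sds = groups.std(axis=1, ddof=1)
    nonzero = means != 0
    n_zero = int((~nonzero).sum())
    if n_zero:
        logger.info("cv_decomposition k=%d: %d zero-mean groups excluded", k, n_zero)
    cvs = sds[nonzero] / means[nonzero]
    mean_cv = float(cvs.mean()) if len(cvs) else float("nan")
    return CVReport(k, 3 ** k, group_size, mean_cv, tuple(cvs), n_zero)


def max_cv(scores_by_hexamer: Mapping[str, float]) -> float:
    """Maximal variability: CV over all 729 scores as a single group."""
    return cv_decomposition(scores_by_hexamer, 0).mean_cv


def cv_ladder(scores_by_hexamer: Mapping[str, float],
              ks: Sequence[int] = range(6)) -> pd.DataFrame:
    """The (1;729) -> (243;3) CV ladder as one table."""
    rows = []
    for k in ks:
        rep = cv_decomposition(scores_by_hexamer, k)
        rows.append({
            "k": rep.k, "n_groups": rep.n_groups, "group_size": rep.group_size,
            "mean_cv": rep.mean_cv,
            "sd_of_group_cvs": float(np.std(rep.per_group_cv, ddof=1))
            if len(rep.per_group_cv) > 1 else float("nan"),
        })
    return pd.DataFrame(rows)
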