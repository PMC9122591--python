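"""RT-stop counting and psi-score calling from aligned fragments.

CMC forms a bulky adduct at pseudouridine that terminates reverse
transcription one base downstream (3') of the modified site, so truncated
cDNAs map with their 5'-most reference coordinate at psi+1.  The psi level
of a position is therefore read from the psi-score — reads beginning at a
position divided by reads covering it — computed at the position
immediately downstream.

Fragments are the union interval of a retained read pair, represented as
a pandas DataFrame with columns ref_id, start, end (0-based half-open),
mapq, proper_pair.  All references are plus-strand constructs; minus-strand
input is rejected.  SAM coordinates are converted at the I/O boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_MIN_MAPQ = 255
DEFAULT_MIN_COVERAGE = 100

FRAGMENT_COLUMNS = ["ref_id", "start", "end", "mapq", "proper_pair"]


@dataclass(frozen=True)
class AlignedFragment:
    ref_id: str
    start: int  # 0-based 5'-most reference coordinate of the pair
    end: int    # 0-based half-open
    mapq: int
    proper_pair: bool

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError(f"fragment [{self.start},{self.end}) is empty")
        if not 0 <= self.mapq <= 255:
            raise ValueError(f"mapq {self.mapq} outside [0,255]")


@dataclass
class ReadEndsProfile:
    """Per-position fragment-start and coverage vectors for one reference."""

    ref_id: str
    starts: np.ndarray
    coverage: np.ndarray

    def __post_init__(self):
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.coverage = np.asarray(self.coverage, dtype=np.int64)
        if self.starts.shape != self.coverage.shape:
            raise ValueError("starts and coverage must have equal length")
        if (self.starts < 0).any() or (self.coverage < 0).any():
            raise ValueError("negative counts")
        if (self.starts > self.coverage).any():
            raise ValueError("starts exceed coverage at some position")


@dataclass(frozen=True)
class PsiCall:
    ref_id: str
    position: int  # 0-based psi-site base; the score is read at position+1
    score: float   # NaN when masked
    se: float
    coverage_at_stop: int
    condition: str  # "CMC" or "INPUT"
    masked: bool


def as_fragment_frame(fragments) -> pd.DataFrame:
    """Coerce a list of AlignedFragment / tuples / DataFrame to the
    canonical fragment frame."""
    if isinstance(fragments, pd.DataFrame):
        missing = set(FRAGMENT_COLUMNS) - set(fragments.columns)
        if missing:
            raise ValueError(f"fragment frame missing columns {sorted(missing)}")
        return fragments
    return pd.DataFrame(
        [(f.ref_id, f.start, f.end, f.mapq, f.proper_pair) for f in fragments],
        columns=FRAGMENT_COLUMNS,
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def fragments_from_sam(path) -> pd.DataFrame:
    """Read pairs from SAM/BAM into fragment intervals.

    Uses the forward mate of each pair (positive template length): the
    fragment is [reference_start, reference_start + tlen).  Unpaired or
    minus-template records are ignored; unmapped records are skipped.
    """
    import pysam

    rows = []
    with pysam.AlignmentFile(str(path), check_sq=False) as af:
        for rec in af:
            if rec.is_unmapped or not rec.is_paired:
                continue
            tlen = rec.template_length
            if tlen <= 0:  # keep one record per pair
                continue
            rows.append((
                rec.reference_name,
                rec.reference_start,
                rec.reference_start + tlen,
                rec.mapping_quality,
                rec.is_proper_pair,
            ))
    return pd.DataFrame(rows, columns=FRAGMENT_COLUMNS)


def fragments_from_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return as_fragment_frame(df.rename(columns={"start0": "start", "end0": "end"}))


# ---------------------------------------------------------------------------
# Filtering and counting
# ---------------------------------------------------------------------------

def filter_fragments(
    fragments,
    insert_windows: Mapping[str, tuple[int, int]],
    min_mapq: int = DEFAULT_MIN_MAPQ,
) -> pd.DataFrame:
    """Retain proper pairs with mapq >= min_mapq falling inside the
    expected PCR-insert boundaries of their reference (inclusive)."""
    df = as_fragment_frame(fragments)
    unknown = sorted(set(df["ref_id"]) - set(insert_windows))
    if unknown:
        raise KeyError(f"fragments on references without an insert window: {unknown}")
    if len(df) == 0:
        return df
    lo = df["ref_id"].map(lambda r: insert_windows[r][0])
    hi = df["ref_id"].map(lambda r: insert_windows[r][1])
    keep = (
        df["proper_pair"].astype(bool)
        & (df["mapq"] >= min_mapq)
        & (df["start"] >= lo)
        & (df["end"] <= hi)
    )
    return df.loc[keep].reset_index(drop=True)


def count_read_ends(fragments, ref_length: int, ref_id: Optional[str] = None
                    ) -> ReadEndsProfile:
    """Per-position fragment-start counts and coverage on one reference.

    starts[i] = number of fragments with 5' boundary at i;
    coverage[i] = number of fragments with start <= i < end.
    """
    df = as_fragment_frame(fragments)
    if len(df) == 0:
        z = np.zeros(ref_length, dtype=np.int64)
        return ReadEndsProfile(ref_id or "", z, z.copy())
    refs = df["ref_id"].unique()
    if len(refs) > 1:
        raise ValueError(f"fragments span multiple references: {sorted(refs)}")
    if ref_id is None:
        ref_id = refs[0]
    start = df["start"].to_numpy()
    end = df["end"].to_numpy()
    if start.min() < 0 or end.max() > ref_length:
        raise ValueError("fragment outside reference bounds")
    starts = np.bincount(start, minlength=ref_length)
    # coverage from a difference array: +1 at start, -1 at end, prefix sum
    diff = np.zeros(ref_length + 1, dtype=np.int64)
    np.add.at(diff, start, 1)
    np.add.at(diff, end, -1)
    coverage = np.cumsum(diff[:-1])
    return ReadEndsProfile(ref_id, starts.astype(np.int64), coverage)


def binomial_se(S: int, C: int) -> float:
    """Standard error of a binomial proportion: ((S/C*(1-S/C))/C)^0.5."""
    if C <= 0:
        raise ValueError("coverage must be positive")
    if not 0 <= S <= C:
        raise ValueError("stop count must lie in [0, coverage]")
    p = S / C
    return math.sqrt(p * (1.0 - p) / C)


def psi_score_at(
    profile: ReadEndsProfile,
    psi_position: int,
    min_coverage: int = DEFAULT_MIN_COVERAGE,
    condition: str = "CMC",
) -> PsiCall:
    """Psi-score of a site, read one base downstream (plus strand).

    Sites whose stop position has coverage below ``min_coverage`` are
    emitted masked, with NaN score/SE rather than zeros.
    """
    stop_pos = psi_position + 1
    if not 0 <= stop_pos < len(profile.starts):
        raise IndexError(
            f"stop position {stop_pos} outside reference {profile.ref_id!r}"
        )
    S = int(profile.starts[stop_pos])
    C = int(profile.coverage[stop_pos])
    if C < max(min_coverage, 1):
        return PsiCall(profile.ref_id, psi_position, float("nan"), float("nan"),
                       C, condition, True)
    score = S / C
    return PsiCall(profile.ref_id, psi_position, score, binomial_se(S, C),
                   C, condition, False)


def calls_to_frame(calls: Sequence[PsiCall]) -> pd.DataFrame:
    return pd.DataFrame([{
        "ref_id": c.ref_id, "psi_pos0": c.position, "condition": c.condition,
        "score": c.score, "se": c.se, "coverage": c.coverage_at_stop,
        "masked": c.masked,
    } for c in calls])


def call_sites(
    fragments,
    ref_lengths: Mapping[str, int],
    psi_positions: Mapping[str, Optional[int]],
    min_coverage: int = DEFAULT_MIN_COVERAGE,
    condition: str = "CMC",
) -> pd.DataFrame:
    """Profile every reference and call its psi site in one pass.

    ``psi_positions`` maps ref_id -> 0-based psi position (None entries,
    e.g. U->G controls, are skipped).  Returns a calls frame.
    """
    df = as_fragment_frame(fragments)
    calls = []
    grouped = dict(iter(df.groupby("ref_id"))) if len(df) else {}
    for ref_id, psi in psi_positions.items():
        if psi is None:
            continue
        sub = grouped.get(ref_id, df.iloc[0:0])
        profile = count_read_ends(sub, ref_lengths[ref_id], ref_id)
        calls.append(psi_score_at(profile, psi, min_coverage, condition))
    return calls_to_frame(calls)


# ---------------------------------------------------------------------------
# Condition comparison
# ---------------------------------------------------------------------------

def compare_conditions(
    cmc_calls: Sequence[PsiCall] | pd.DataFrame,
    input_calls: Sequence[PsiCall] | pd.DataFrame,
) -> tuple[pd.DataFrame, dict]:
    """Per-site CMC - INPUT score deltas and a set-level paired t-test.

    Sites masked in either condition are excluded and counted.  Returns
    (per-site table, summary dict with t, p, n, n_excluded).
    """
    cmc = cmc_calls if isinstance(cmc_calls, pd.DataFrame) else calls_to_frame(cmc_calls)
    inp = (input_calls if isinstance(input_calls, pd.DataFrame)
           else calls_to_frame(input_calls))
    merged = cmc.merge(inp, on=["ref_id", "psi_pos0"], suffixes=("_cmc", "_input"))
    if len(merged) == 0:
        raise ValueError("no sites shared between the two conditions")
    excluded = merged["masked_cmc"] | merged["masked_input"]
    kept = merged.loc[~excluded].copy()
    if len(kept) == 0:
        raise ValueError("all shared sites are masked in at least one condition")
    kept["delta"] = kept["score_cmc"] - kept["score_input"]
    if len(kept) >= 2 and kept["delta"].nunique() > 1:
        t_stat, p_value = stats.ttest_rel(kept["score_cmc"], kept["score_input"])
    elif (kept["delta"] == 0).all():
        t_stat, p_value = 0.0, 1.0
    else:  # constant non-zero deltas: zero within-pair variance
        t_stat, p_value = float("inf"), 0.0
    summary = {
        "t": float(t_stat), "p": float(p_value),
        "n": int(len(kept)), "n_excluded": int(excluded.sum()),
    }
    cols = ["ref_id", "psi_pos0", "score_cmc", "score_input", "delta"]
    return kept[cols].reset_index(drop=True), summary
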