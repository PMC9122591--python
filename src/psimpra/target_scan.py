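"""Transcriptome scanning for uridines complementary to H/ACA pockets.

For each pocket an ideal 21-nt target pattern is materialized: the reverse
complement of the 3' guide element's terminal bases (pairing the 10 bases
5' of the psi site), the U itself, a wildcard at the unpaired +1 position,
and the reverse complement of the 5' guide element's bases pairing
positions +2..+10.  Guides shorter than the window pad the pattern with N
wildcards.  Every transcript uridine is then scored by the number of
non-wildcard flank positions (out of the 20 surrounding bases) matching
the pattern; uridines at >= min_matches (default 14) are emitted as hits.

Scanning is plus-strand only: transcript FASTA records are already
sense-stranded, and antisense complementarity is not a substrate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .library_design import PseudouridylationPocket
from .seqtools import normalize, revcomp

logger = logging.getLogger(__name__)

FLANK = 10          # bases considered on each side of the psi site
PATTERN_LEN = 2 * FLANK + 1
DEFAULT_MIN_MATCHES = 14
DEFAULT_SCAN_MIN_COVERAGE = 90  # hits kept at coverage > this, both conditions


@dataclass(frozen=True)
class ComplementarityHit:
    transcript_id: str
    u_position: int  # 0-based position of the U on the transcript
    pocket_id: str
    match_count: int
    match_mask: int  # 20 bits, bit 0 = farthest upstream flank position

    def __post_init__(self):
        if not 0 <= self.match_count <= 2 * FLANK:
            raise ValueError("match_count outside [0, 20]")
        if self.match_count != bin(self.match_mask).count("1"):
            raise ValueError("match_count disagrees with popcount(match_mask)")


@dataclass(frozen=True)
class BackgroundSet:
    """Seeded uniform sample of transcript uridines used as background."""

    positions: tuple  # of (transcript_id, u_position)
    seed: int


def ideal_target(pocket: PseudouridylationPocket) -> str:
    """The pocket's fully complementary 21-nt target, +1 wildcarded.

    Layout (5'->3' on the target): 10 upstream bases = revcomp of the 3'
    guide's psi-proximal (5'-terminal) bases, T, N at +1, then positions
    +2..+10 = revcomp of the 5' guide's psi-proximal (3'-terminal) bases.
    The duplex anchors at the psi-proximal guide ends, so short guides
    pad the pattern with N wildcards at the distal flank positions.
    """
    up = revcomp(pocket.guide3[:FLANK]).rjust(FLANK, "N")
    down = revcomp(pocket.guide5[-(FLANK - 1):]).ljust(FLANK - 1, "N")
    return up + "T" + "N" + down


def countable_positions(pattern: str) -> int:
    """Flank positions of a pattern that can contribute to match_count."""
    flank = pattern[:FLANK] + pattern[FLANK + 1 :]
    return sum(b != "N" for b in flank)


def scan_transcriptome(
    sequences: Mapping[str, str] | str,
    pockets: Sequence[PseudouridylationPocket],
    min_matches: int = DEFAULT_MIN_MATCHES,
    mode: str = "total",
) -> list[ComplementarityHit]:
    """Scan transcripts for uridines complementary to any pocket.

    ``sequences`` is a {transcript_id: sequence} mapping or a FASTA path.
    ``mode='total'`` counts matched flank positions; ``mode='contiguous'``
    scores the longest run of consecutive matches (the U and wildcard
    positions bridge runs).  Uridines closer than 10 nt to a transcript
    end, and windows containing non-ACGT characters, are skipped (the
    latter with a logged count).
    """
    if mode not in ("total", "contiguous"):
        raise ValueError(f"unknown scan mode {mode!r}")
    seqs = _load_sequences(sequences)
    patterns = [(p.pocket_id, ideal_target(p)) for p in pockets]
    hits: list[ComplementarityHit] = []
    n_skipped = 0
    for tid, seq in seqs.items():
        arr = np.frombuffer(seq.encode(), dtype="S1")
        u_positions = np.flatnonzero(arr == b"T")
        for u in u_positions:
            if u < FLANK or u + FLANK >= len(seq):
                continue
            window = seq[u - FLANK : u + FLANK + 1]
            if set(window) - set("ACGT"):
                n_skipped += 1
                continue
            for pocket_id, pattern in patterns:
                count, mask = _match_window(window, pattern, mode)
                if count >= min_matches:
                    total, _ = _match_window(window, pattern, "total")
                    hits.append(ComplementarityHit(
                        tid, int(u), pocket_id,
                        count if mode == "total" else total, mask,
                    ))
    if n_skipped:
        logger.info("scan: %d uridine windows skipped (non-nucleotide bases)",
                    n_skipped)
    return hits


def _match_window(window: str, pattern: str, mode: str) -> tuple[int, int]:
    """(score, 20-bit flank match mask) of a window against a pattern."""
    mask = 0
    bit = 0
    matches = []  # per pattern position: True/False/None (wildcard or U)
    for i, (w, p) in enumerate(zip(window, pattern)):
        if i == FLANK:          # the U itself never counts
            matches.append(None)
            continue
        if p == "N":
            matches.append(None)
        else:
            m = w == p
            matches.append(m)
            if m:
                mask |= 1 << bit
        bit += 1
    if mode == "total":
        return sum(bool(m) for m in matches if m is not None), mask
    # contiguous: longest run where wildcards/U bridge but do not add
    best = run = 0
    for m in matches:
        if m is False:
            run = 0
        elif m is True:
            run += 1
            best = max(best, run)
        # None: bridge — run continues without incrementing
    return best, mask


def hits_to_frame(hits: Sequence[ComplementarityHit]) -> pd.DataFrame:
    """BED-like hit table (0-based start, half-open end)."""
    return pd.DataFrame([{
        "transcript_id": h.transcript_id, "u_pos0": h.u_position,
        "u_end": h.u_position + 1, "pocket_id": h.pocket_id,
        "match_count": h.match_count, "match_mask": h.match_mask,
    } for h in hits])


def sample_background_uridines(
    sequences: Mapping[str, str] | str,
    n: int = 1000,
    seed: int = 0,
    eligible: Optional[set] = None,
) -> BackgroundSet:
    """Uniform seeded sample of n transcript uridines without replacement.

    ``eligible``, when given, restricts the pool (e.g. to sites with
    sufficient coverage in both conditions).
    """
    seqs = _load_sequences(sequences)
    pool = [
        (tid, int(u))
        for tid, seq in seqs.items()
        for u in np.flatnonzero(np.frombuffer(seq.encode(), dtype="S1") == b"T")
        if eligible is None or (tid, int(u)) in eligible
    ]
    if len(pool) < n:
        raise ValueError(f"only {len(pool)} eligible uridines, need {n}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pool), size=n, replace=False)
    return BackgroundSet(tuple(pool[i] for i in sorted(idx)), seed)


def bin_hits_and_score(
    hits: Sequence[ComplementarityHit] | pd.DataFrame,
    cmc_calls: pd.DataFrame,
    input_calls: pd.DataFrame,
    min_cov: int = DEFAULT_SCAN_MIN_COVERAGE,
    background: Optional[BackgroundSet] = None,
) -> pd.DataFrame:
    """CMC psi-score distributions of hits grouped by match count.

    Scores are taken only at sites with coverage strictly above
    ``min_cov`` in both conditions.  Bins with no surviving site are
    emitted with n = 0; a 'background' bin is added when a background
    uridine set is supplied.  Call frames are keyed (ref_id, psi_pos0).
    """
    hdf = hits if isinstance(hits, pd.DataFrame) else hits_to_frame(hits)
    cmc = cmc_calls.set_index(["ref_id", "psi_pos0"])
    inp = input_calls.set_index(["ref_id", "psi_pos0"])

    def site_score(tid, pos):
        key = (tid, pos)
        if key not in cmc.index or key not in inp.index:
            return None
        c, i = cmc.loc[key], inp.loc[key]
        if c["coverage"] <= min_cov or i["coverage"] <= min_cov:
            return None
        if bool(c["masked"]) or bool(i["masked"]):
            return None
        return float(c["score"])

    rows = []
    bins = sorted(hdf["match_count"].unique()) if len(hdf) else []
    for mc in bins:
        sub = hdf.loc[hdf["match_count"] == mc]
        scores = [s for s in (site_score(t, p) for t, p in
                              zip(sub["transcript_id"], sub["u_pos0"]))
                  if s is not None]
        rows.append({"bin": str(mc), "n": len(scores),
                     "mean_score": float(np.mean(scores)) if scores else float("nan"),
                     "scores": scores})
    if background is not None:
        scores = [s for s in (site_score(t, p) for t, p in background.positions)
                  if s is not None]
        rows.append({"bin": "background", "n": len(scores),
                     "mean_score": float(np.mean(scores)) if scores else float("nan"),
                     "scores": scores})
    return pd.DataFrame(rows)


def _load_sequences(sequences) -> dict[str, str]:
    if isinstance(sequences, Mapping):
        return {k: normalize(v) for k, v in sequences.items()}
    from pyfaidx import Fasta

    fa = Fasta(str(sequences))
    return {name: normalize(str(fa[name][:])) for name in fa.keys()}
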