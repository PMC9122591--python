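"""Synthetic inputs for every pipeline stage.

The fragment simulator emulates the statistical structure of a CMC/RT-stop
(psi-seq) library on a plus-strand construct: reverse transcription primes
at a fixed 3' position and walks toward the 5' end; on a CMC-treated,
pseudouridylated molecule it terminates one base downstream (3') of the
psi site with probability p_term (times an optional sequence-context
modifier), and at every base it may terminate with a background
probability p_bg (memoryless, i.e. geometric background stops — the
simplest model matching input-condition profiles).  Surviving molecules
run to a sampled full-length 5' boundary.  Fragments shorter than a
minimum are discarded as unsequenceable.  Paired-end detail is collapsed
to the fragment interval; an optional SAM writer fabricates two mates
covering the interval ends.

One global seed governs all draws through a documented splitting scheme:
every sampling site derives a child generator from
numpy.random.SeedSequence([seed, *subkeys]) where subkeys are small ints
and CRC32 hashes of reference names.
"""

from __future__ import annotations

import itertools
import zlib
from dataclasses import dataclass, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .library_design import (ContextReporter, PseudouridylationPocket,
                             TargetConstruct)
from .read_end_quant import FRAGMENT_COLUMNS
from .target_scan import FLANK, PATTERN_LEN, countable_positions, ideal_target

DEFAULT_MIN_FRAG_LEN = 20


def rng_for(seed: int, *subkeys) -> np.random.Generator:
    """Child generator for one sampling site of the global seed."""
    ints = [seed] + [
        k if isinstance(k, (int, np.integer)) else zlib.crc32(str(k).encode())
        for k in subkeys
    ]
    return np.random.default_rng(np.random.SeedSequence([int(i) for i in ints]))


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated sequencing run.

    stoichiometry: fraction of molecules pseudouridylated at the site.
    p_term: RT termination probability at the CMC adduct (one base 3' of
        the psi site); applied only under the CMC condition.
    p_bg: per-nucleotide background termination probability.
    coverage: molecules drawn per construct.
    frag_len: (mean, sd) of the full-length insert.
    context_effect: optional mapping from a downstream k-mer (the k bases
        immediately 3' of the psi site) to a multiplicative p_term
        modifier; k is inferred from the key length.
    """

    seed: int = 0
    stoichiometry: float = 0.5
    p_term: float = 0.3
    p_bg: float = 0.002
    coverage: int = 2000
    frag_len: tuple[float, float] = (130.0, 15.0)
    context_effect: Optional[Mapping[str, float]] = None
    condition: str = "CMC"
    min_frag_len: int = DEFAULT_MIN_FRAG_LEN
    primer_end: Optional[int] = None  # default: the reference 3' end

    def __post_init__(self):
        for name in ("stoichiometry", "p_term", "p_bg"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0,1]")
        if self.condition not in ("CMC", "INPUT"):
            raise ValueError("condition must be CMC or INPUT")


def context_modifier(downstream_seq: str,
                     context_effect: Optional[Mapping[str, float]]) -> float:
    """Resolve the p_term modifier for a site's downstream sequence."""
    if not context_effect:
        return 1.0
    k = len(next(iter(context_effect)))
    return float(context_effect.get(downstream_seq[:k], 1.0))


def default_context_effect(
    seed: int = 0,
    sigmas: Sequence[float] = (0.16, 0.08, 0.05, 0.03, 0.02, 0.01),
) -> dict[str, float]:
    """Per-hexamer termination modifiers with decaying positional impact.

    Each downstream position i contributes an independent lognormal
    factor per base (log-sd sigmas[i], mean-centered), so proximal bases
    dominate and the total score CV at 100% psi is on the 20% scale seen
    for pooled reporter sets.
    """
    rng = rng_for(seed, "context_effect")
    per_pos = []
    for sigma in sigmas:
        eff = np.exp(rng.normal(0.0, sigma, size=3))
        per_pos.append(dict(zip("ACG", eff / eff.mean())))
    return {
        "".join(h): float(np.prod([per_pos[i][b] for i, b in enumerate(h)]))
        for h in itertools.product("ACG", repeat=6)
    }


# ---------------------------------------------------------------------------
# Pocket fixtures
# ---------------------------------------------------------------------------

def simulate_pockets(
    n: int,
    guide_len_range: tuple[int, int] = (2, 11),
    seed: int = 0,
    n_snornas: Optional[int] = None,
) -> pd.DataFrame:
    """n random pseudouridylation pockets as a tidy table.

    With ``n_snornas`` given, the first ``n - n_snornas`` snoRNAs carry a
    second arm (so e.g. n=99, n_snornas=68 emulates a 68-snoRNA,
    99-targeting-arm panel); otherwise one arm per snoRNA.
    """
    if n < 1:
        raise ValueError("need n >= 1")
    lo, hi = guide_len_range
    if not 2 <= lo <= hi <= 11:
        raise ValueError("guide lengths must stay within [2, 11]")
    if n_snornas is not None and not n / 2 <= n_snornas <= n:
        raise ValueError("n_snornas must lie in [n/2, n]")
    rng = rng_for(seed, "pockets")
    bases = np.array(list("ACGT"))

    def guide():
        return "".join(bases[rng.integers(0, 4, size=rng.integers(lo, hi + 1))])

    rows = []
    if n_snornas is None:
        ids_arms = [(f"sno{i:03d}", 1) for i in range(n)]
    else:
        two_armed = n - n_snornas
        ids_arms = [(f"sno{i:03d}", 1) for i in range(n_snornas)]
        ids_arms += [(f"sno{i:03d}", 2) for i in range(two_armed)]
    for snorna_id, arm in ids_arms:
        rows.append({"snorna_id": snorna_id, "arm": arm,
                     "guide5": guide(), "guide3": guide()})
    return pd.DataFrame(rows)


def pockets_from_frame(df: pd.DataFrame) -> list[PseudouridylationPocket]:
    return [PseudouridylationPocket(r.snorna_id, int(r.arm), r.guide5, r.guide3)
            for r in df.itertuples()]


# ---------------------------------------------------------------------------
# Fragment simulation
# ---------------------------------------------------------------------------

def simulate_ref_fragments(
    ref_id: str,
    ref_len: int,
    psi_position: Optional[int],
    cfg: SimulationConfig,
    modifier: float = 1.0,
    n: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Simulate the RT walk on one reference (vectorized).

    For each molecule the background stop (geometric from the primer) and
    the psi stop (at psi_position+1, fired with probability
    stoichiometry x min(1, p_term x modifier) under CMC) are drawn
    independently; the realized 5' boundary is the first event the
    polymerase meets, i.e. the maximum of the candidate stop positions
    and the full-length boundary.
    """
    if rng is None:
        rng = rng_for(cfg.seed, "fragments", ref_id, cfg.condition)
    n = cfg.coverage if n is None else n
    primer_end = cfg.primer_end if cfg.primer_end is not None else ref_len
    if not 0 < primer_end <= ref_len:
        raise ValueError("primer_end outside the reference")
    mean, sd = cfg.frag_len
    lengths = np.maximum(np.rint(rng.normal(mean, sd, n)).astype(np.int64), 1)
    full_start = np.clip(primer_end - lengths, 0, primer_end - 1)

    neg = np.int64(-(10 ** 9))
    if cfg.p_bg > 0:
        bg_stop = primer_end - rng.geometric(cfg.p_bg, n).astype(np.int64)
    else:
        bg_stop = np.full(n, neg)
    bg_stop = np.where(bg_stop >= full_start, bg_stop, neg)

    psi_stop = np.full(n, neg)
    if (cfg.condition == "CMC" and psi_position is not None
            and cfg.stoichiometry > 0):
        stop_pos = psi_position + 1
        p_eff = min(1.0, cfg.p_term * modifier)
        fires = (rng.random(n) < cfg.stoichiometry) & (rng.random(n) < p_eff)
        reachable = (stop_pos <= primer_end - 1) & (stop_pos >= full_start)
        psi_stop = np.where(fires & reachable, stop_pos, neg)

    start = np.maximum(full_start, np.maximum(bg_stop, psi_stop))
    keep = (primer_end - start) >= cfg.min_frag_len
    start = start[keep]
    return pd.DataFrame({
        "ref_id": ref_id,
        "start": start,
        "end": np.full(len(start), primer_end, dtype=np.int64),
        "mapq": 255,
        "proper_pair": True,
    }, columns=FRAGMENT_COLUMNS)


def simulate_fragments(
    construct: TargetConstruct, cfg: SimulationConfig
) -> pd.DataFrame:
    """Simulate fragments for one designed construct (full sequence).

    The psi site is the construct's psi_index lifted to full-sequence
    coordinates; the context modifier is resolved from the sequence
    immediately downstream of the site.
    """
    seq = construct.full_seq or construct.variable_seq
    if construct.psi_index is None:
        psi = None
        modifier = 1.0
    else:
        offset = seq.index(construct.variable_seq)
        psi = offset + construct.psi_index
        modifier = context_modifier(seq[psi + 1 :], cfg.context_effect)
    return simulate_ref_fragments(construct.construct_id, len(seq), psi, cfg,
                                  modifier)


def simulate_library_fragments(
    constructs: Sequence[TargetConstruct], cfg: SimulationConfig
) -> tuple[pd.DataFrame, dict[str, int], dict[str, Optional[int]]]:
    """Fragments for a whole library.

    Returns (fragment frame, reference lengths, psi position per
    reference in full-sequence coordinates — None for controls).
    """
    frames, ref_lens, psi_pos = [], {}, {}
    for c in constructs:
        seq = c.full_seq or c.variable_seq
        ref_lens[c.construct_id] = len(seq)
        if c.psi_index is None:
            psi_pos[c.construct_id] = None
        else:
            psi_pos[c.construct_id] = seq.index(c.variable_seq) + c.psi_index
        frames.append(simulate_fragments(c, cfg))
    frags = (pd.concat(frames, ignore_index=True) if frames
             else pd.DataFrame(columns=FRAGMENT_COLUMNS))
    return frags, ref_lens, psi_pos


# ---------------------------------------------------------------------------
# Mixing pools (context reporters)
# ---------------------------------------------------------------------------

def simulate_mixing_pools(
    reporters: Sequence[ContextReporter],
    ratios: Sequence[float],
    cfg: SimulationConfig,
) -> dict[float, pd.DataFrame]:
    """Per-ratio fragment pools over the context-reporter set.

    The pool at ratio r draws each molecule's psi status with probability
    r (a psi-transcribed molecule behaves like stoichiometry 1); the
    context modifier is resolved from each reporter's hexamer.  Reference
    ids are ``ctx_<hexamer>``.
    """
    if any(not 0 <= r <= 1 for r in ratios):
        raise ValueError("ratios must lie in [0,1]")
    pools: dict[float, pd.DataFrame] = {}
    for r in ratios:
        frames = []
        for rep in reporters:
            psi = rep.full_seq.index("T")
            modifier = context_modifier(rep.hexamer, cfg.context_effect)
            ref_id = f"ctx_{rep.hexamer}"
            sub = replace(cfg, stoichiometry=float(r))
            rng = rng_for(cfg.seed, "mixing", ref_id, int(round(r * 1000)))
            frames.append(simulate_ref_fragments(
                ref_id, len(rep.full_seq), psi, sub, modifier, rng=rng))
        pools[float(r)] = pd.concat(frames, ignore_index=True)
    return pools


def expected_mixing_score(ratio: float, cfg: SimulationConfig,
                          modifier: float = 1.0) -> float:
    """Analytic expected psi-score at a reporter site (noise-free limit,
    negligible background): ratio x min(1, p_term x modifier)."""
    return float(ratio) * min(1.0, cfg.p_term * modifier)


# ---------------------------------------------------------------------------
# Transcriptomes with planted complementarity hits
# ---------------------------------------------------------------------------

def simulate_transcriptome_with_hits(
    n_transcripts: int,
    planted: Sequence[tuple[PseudouridylationPocket, int]],
    seed: int = 0,
    transcript_len: int = 2000,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Random transcripts with flanks of controlled complementarity.

    For each (pocket, match_count) a 21-nt window is written at a
    recorded position: the pocket's ideal target with exactly
    (countable_max - match_count) mismatches introduced at randomly
    chosen countable flank positions, wildcard positions filled with
    random bases.  Returns ({transcript_id: sequence}, truth table).
    """
    rng = rng_for(seed, "transcriptome")
    bases = np.array(list("ACGT"))
    seqs = {
        f"tx{i:03d}": "".join(bases[rng.integers(0, 4, transcript_len)])
        for i in range(n_transcripts)
    }
    arrs = {tid: list(s) for tid, s in seqs.items()}
    occupied: dict[str, list[tuple[int, int]]] = {tid: [] for tid in seqs}
    truth_rows = []
    tids = list(seqs)
    for j, (pocket, match_count) in enumerate(planted):
        pattern = ideal_target(pocket)
        cmax = countable_positions(pattern)
        if match_count > cmax:
            raise ValueError(
                f"{pocket.pocket_id}: requested {match_count} matches but only "
                f"{cmax} countable flank positions"
            )
        tid = tids[j % len(tids)]
        pos = _free_position(rng, occupied[tid], transcript_len)
        window = _window_with_matches(rng, pattern, match_count)
        u = pos + FLANK
        arrs[tid][pos : pos + len(window)] = window
        truth_rows.append({"transcript_id": tid, "u_pos0": u,
                           "pocket_id": pocket.pocket_id,
                           "match_count": match_count})
    seqs = {tid: "".join(a) for tid, a in arrs.items()}
    return seqs, pd.DataFrame(truth_rows)


def _free_position(rng, occupied: list, transcript_len: int,
                   margin: int = PATTERN_LEN) -> int:
    for _ in range(1000):
        pos = int(rng.integers(margin, transcript_len - 2 * margin))
        if all(abs(pos - o) >= 2 * margin for o, _ in occupied):
            occupied.append((pos, pos + margin))
            return pos
    raise RuntimeError("could not place a planted site without overlap")


def _window_with_matches(rng, pattern: str, match_count: int) -> list[str]:
    """Concretize a pattern with exactly match_count matching flank bases."""
    window = []
    countable_idx = []
    for i, p in enumerate(pattern):
        if i == FLANK:
            window.append("T")
        elif p == "N":
            window.append("ACG"[rng.integers(0, 3)])  # avoid incidental Us
        else:
            countable_idx.append(i)
            window.append(p)
    n_mismatch = len(countable_idx) - match_count
    for i in rng.choice(len(countable_idx), size=n_mismatch, replace=False):
        pos = countable_idx[int(i)]
        alternatives = [b for b in "ACGT" if b != pattern[pos]]
        window[pos] = alternatives[int(rng.integers(0, 3))]
    return window


# ---------------------------------------------------------------------------
# Writers (plain-text outputs only)
# ---------------------------------------------------------------------------

def write_fasta(seqs: Mapping[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n{seq}\n")


def write_fragments_tsv(fragments: pd.DataFrame, path) -> None:
    out = fragments.rename(columns={"start": "start0", "end": "end0"})
    out.to_csv(path, sep="\t", index=False)


def write_sam(
    fragments: pd.DataFrame,
    ref_lengths: Mapping[str, int],
    path,
    read_len: int = 50,
) -> None:
    """Fabricate a coordinate-sorted headered SAM with two mates covering
    each fragment's ends (the BAM-path round-trip format)."""
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": name, "LN": int(length)}
               for name, length in ref_lengths.items()],
    }
    ref_index = {name: i for i, name in enumerate(ref_lengths)}
    df = fragments.sort_values(
        ["ref_id", "start"], key=lambda s: s.map(ref_index) if s.name == "ref_id" else s
    ).reset_index(drop=True)
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for i, row in df.iterrows():
            frag_len = int(row["end"] - row["start"])
            rlen = min(read_len, frag_len)
            for first in (True, False):
                a = pysam.AlignedSegment(out.header)
                a.query_name = f"frag{i:08d}"
                a.reference_id = ref_index[row["ref_id"]]
                a.mapping_quality = int(row["mapq"])
                a.cigarstring = f"{rlen}M"
                a.query_sequence = "N" * rlen
                a.next_reference_id = a.reference_id
                if first:
                    a.reference_start = int(row["start"])
                    a.next_reference_start = int(row["end"]) - rlen
                    a.template_length = frag_len
                    a.flag = 0x1 | 0x2 | 0x20 | 0x40
                else:
                    a.reference_start = int(row["end"]) - rlen
                    a.next_reference_start = int(row["start"])
                    a.template_length = -frag_len
                    a.flag = 0x1 | 0x2 | 0x10 | 0x80
                if not row["proper_pair"]:
                    a.flag &= ~0x2
                out.write(a)
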