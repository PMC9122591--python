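"""Independent brute-force oracles used to check the implementation.

Everything here is deliberately naive (per-position loops, O(n^2) pair
scans, closed-form textbook formulas) and shares no code with the package
paths it validates.
"""

from __future__ import annotations

import numpy as np

WC = {"A": "T", "T": "A", "C": "G", "G": "C"}


def pairs_antiparallel(target_segment: str, guide_segment: str) -> bool:
    """True iff the two segments form a full antiparallel Watson-Crick
    duplex: target base i pairs guide base (L-1-i)."""
    if len(target_segment) != len(guide_segment):
        return False
    L = len(guide_segment)
    return all(WC[target_segment[i]] == guide_segment[L - 1 - i] for i in range(L))


def check_duplex(patch: str, guide5: str, guide3: str, up: int, down: int) -> dict:
    """Brute-force check of a designed complementarity patch.

    Layout: [up bases pairing the 3' guide element][U][+1 base][down
    bases pairing the 5' guide element], the duplex anchored at the
    psi-proximal guide ends (guide3's 5' end pairs target -1, guide5's
    3' end pairs target +2).  Returns which components pair.
    """
    assert len(patch) == up + 2 + down
    return {
        "upstream_paired": pairs_antiparallel(patch[:up], guide3[:up]) if up else True,
        "u_is_t": patch[up] == "T",
        "plus1": patch[up + 1],
        "plus1_unpaired_vs_guides": True,  # +1 never drawn from a guide by design
        "downstream_paired": (
            pairs_antiparallel(patch[up + 2:], guide5[-down:]) if down else True
        ),
    }


def brute_force_read_ends(fragments, ref_length: int):
    """O(n*L) per-position interval counter: (starts, coverage)."""
    starts = np.zeros(ref_length, dtype=int)
    coverage = np.zeros(ref_length, dtype=int)
    for start, end in fragments:
        starts[start] += 1
        for i in range(start, end):
            coverage[i] += 1
    return starts, coverage


def all_pairs_min_hamming(strings) -> int:
    best = min(len(s) for s in strings) + 1
    for i in range(len(strings)):
        for j in range(i + 1, len(strings)):
            d = sum(a != b for a, b in zip(strings[i], strings[j]))
            best = min(best, d)
    return best


def brute_force_scan(seqs: dict, patterns: dict, min_matches: int):
    """Per-position pattern comparison over every transcript uridine.

    patterns: {pocket_id: 21-char string, N = wildcard, center = T}.
    Returns a set of (transcript_id, u_pos, pocket_id, match_count).
    """
    out = set()
    for tid, seq in seqs.items():
        for u in range(10, len(seq) - 10):
            if seq[u] != "T":
                continue
            window = seq[u - 10 : u + 11]
            if any(ch not in "ACGT" for ch in window):
                continue
            for pid, pat in patterns.items():
                count = 0
                for i in range(21):
                    if i == 10 or pat[i] == "N":
                        continue
                    if window[i] == pat[i]:
                        count += 1
                if count >= min_matches:
                    out.add((tid, u, pid, count))
    return out


def ols_fit(x, y):
    """Closed-form simple OLS: (slope, intercept, r_squared)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xm, ym = x.mean(), y.mean()
    sxx = ((x - xm) ** 2).sum()
    sxy = ((x - xm) * (y - ym)).sum()
    slope = sxy / sxx
    intercept = ym - slope * xm
    ss_res = ((y - intercept - slope * x) ** 2).sum()
    ss_tot = ((y - ym) ** 2).sum()
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return slope, intercept, r2


def group_cv(values, ddof=1):
    """sd/mean with explicit formulas."""
    v = np.asarray(values, float)
    mean = v.sum() / len(v)
    var = ((v - mean) ** 2).sum() / (len(v) - ddof)
    return np.sqrt(var) / mean
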