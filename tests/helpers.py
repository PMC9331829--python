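"""Independent brute-force oracles used to validate the scanners.

These deliberately use direct shift/run enumeration rather than the suffix
array, seed-extend, or period-scan machinery they check.
"""

from __future__ import annotations

import numpy as np

from mitostruct import revcomp


def _true_runs(mask: np.ndarray, min_len: int):
    """Maximal True runs of length >= min_len as (start, end) inclusive."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [idx.size - 1]))
    for a, b in zip(starts, ends):
        if idx[b] - idx[a] + 1 >= min_len:
            yield int(idx[a]), int(idx[b])


def brute_dispersed(seq: str, min_len: int) -> set[tuple]:
    """All maximal exact repeat pairs in one linear sequence, by comparing
    the sequence against every shift of itself (direct) and of its reverse
    complement (palindromic).  Returns canonical tuples
    (kind, (s1, e1, st1), (s2, e2, st2)) with 1-based coordinates."""
    n = len(seq)
    a = np.frombuffer(seq.encode(), dtype=np.uint8)
    rc = np.frombuffer(revcomp(seq).encode(), dtype=np.uint8)
    pairs: set[tuple] = set()
    for d in range(1, n):  # direct pairs at occurrence distance d
        eq = a[d:] == a[:n - d]
        for s, e in _true_runs(eq, min_len):
            L = e - s + 1
            pairs.add(("direct", (s + 1, s + L, "+"),
                       (s + d + 1, s + d + L, "+")))
    # palindromic: a[k] vs rc[k + t]; rc position m is genomic n - 1 - m
    for t in range(-(n - 1), n):
        if t >= 0:
            eq = a[:n - t] == rc[t:]
            ks = 0
        else:
            eq = a[-t:] == rc[:n + t]
            ks = -t
        for s0, e0 in _true_runs(eq, min_len):
            s, e = s0 + ks, e0 + ks  # positions in a
            y1, y2 = n - 1 - (e + t), n - 1 - (s + t)
            occ_x = (s + 1, e + 1, "+")
            occ_y = (y1 + 1, y2 + 1, "-")
            if occ_x[:2] == occ_y[:2]:
                continue  # a locus matching its own reverse complement
            if occ_y[:2] < occ_x[:2]:
                occ_x, occ_y = (occ_y[0], occ_y[1], "+"), (occ_x[0], occ_x[1], "-")
            pairs.add(("palindromic", occ_x, occ_y))
    return pairs


def dispersed_as_set(repeats) -> set[tuple]:
    """Canonical tuple view of DispersedRepeat records on one molecule."""
    return {(r.kind, (r.occ1[1], r.occ1[2], r.occ1[3]),
             (r.occ2[1], r.occ2[2], r.occ2[3])) for r in repeats}


def brute_ssrs(seq: str, thresholds: dict[int, int]) -> set[tuple]:
    """MISA-style perfect SSR runs by direct per-position extension.

    Returns (start, end, unit_length, copies, canonical_motif) 1-based.
    """
    from mitostruct.repeat_scan import _canonical_rotation, _min_period

    n = len(seq)
    found: set[tuple] = set()
    for u in range(1, 7):
        i = 0
        while i + u <= n:
            if "N" in seq[i:i + u]:
                i += 1
                continue
            j = i + u
            while j < n and seq[j] == seq[j - u] and seq[j] != "N":
                j += 1
            run_len = j - i
            copies = run_len // u
            # keep only runs that are maximal on the left
            left_ext = i >= u and seq[i - 1] == seq[i - 1 + u] and "N" not in seq[i - 1]
            if copies >= thresholds[u] and not left_ext:
                motif = seq[i:i + u]
                if _min_period(motif) == u:
                    found.add((i + 1, i + u * copies, u, copies,
                               _canonical_rotation(motif)))
            i += 1
    return found


def brute_adjacent_match_pct(seq: str, start: int, end: int, p: int) -> float:
    """Percent of positions i in [start-1, end-1-p] with seq[i] == seq[i+p]
    (0-based internally; start/end 1-based inclusive)."""
    s = seq[start - 1:end]
    agree = sum(1 for i in range(len(s) - p) if s[i] == s[i + p])
    return 100.0 * agree / (len(s) - p)


def random_dna(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(np.array(list("ACGT"))[rng.choice(4, n, p=p)])
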