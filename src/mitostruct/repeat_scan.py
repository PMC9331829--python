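"""Repeat detection over multi-molecule genomes.

Three repeat classes are scanned:

* **SSRs** (microsatellites): maximal perfect runs of a 1–6 bp motif above a
  per-unit-length copy threshold (MISA-style defaults: mono 10, di 6, tri 5,
  tetra 5, penta 5, hexa 5).
* **Tandem repeats**: adjacent approximate copies of a unit, found by a
  period scan — for each candidate period ``p`` the positions where
  ``seq[i] == seq[i+p]`` form runs whose agreement fraction is the reported
  match percentage.
* **Dispersed repeats**: all maximal exact repeated pairs (direct or
  palindromic, within and across molecules) of length ≥ ``min_length``,
  enumerated via a suffix array + LCP over the concatenation of every
  forward and reverse-complement sequence with unique separators.

Circular molecules are virtually doubled so repeats crossing the origin are
found; their coordinates are re-mapped to wrapped intervals
(``end > length`` encodes the wrap) and shifted duplicates are discarded.
N runs act as hard breaks: no repeat spans an N.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .genome_io import Genome, Molecule, format_interval, revcomp

logger = logging.getLogger("mitostruct")

#: MISA web-server default minimum copy numbers per motif length.
DEFAULT_SSR_THRESHOLDS = {1: 10, 2: 6, 3: 5, 4: 5, 5: 5, 6: 5}


# ---------------------------------------------------------------------------
# Records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SSRRecord:
    molecule_id: str
    motif: str          # canonical (lexicographically minimal rotation)
    unit_length: int
    copies: int
    start: int          # 1-based inclusive
    end: int

    def __post_init__(self):
        assert self.end - self.start + 1 == self.unit_length * self.copies


@dataclass(frozen=True)
class TandemRepeat:
    molecule_id: str
    start: int
    end: int
    unit_length: int
    copy_number: float
    match_pct: float


@dataclass(frozen=True)
class DispersedRepeat:
    """A pair of exactly repeated occurrences.

    ``kind`` is ``"direct"`` (identical copies, same strand) or
    ``"palindromic"`` (reverse-complementary copies).  Occurrences are
    ``(molecule_id, start, end, strand)`` with 1-based inclusive coordinates;
    on a circular molecule ``end`` may exceed the molecule length to encode
    an origin-wrapping occurrence.  occ1 <= occ2 canonically and, for
    palindromic pairs, occ1 is always on the plus strand.
    """
    repeat_id: str
    kind: str
    length: int
    occ1: tuple[str, int, int, str]
    occ2: tuple[str, int, int, str]

    def occurrence_seqs(self, genome: Genome) -> tuple[str, str]:
        (m1, s1, e1, st1), (m2, s2, e2, st2) = self.occ1, self.occ2
        return genome[m1].fetch(s1, e1, st1), genome[m2].fetch(s2, e2, st2)

    def verify(self, genome: Genome) -> bool:
        """Occurrence sequences must be identical in repeat orientation."""
        a, b = self.occurrence_seqs(genome)
        return a == b


# ---------------------------------------------------------------------------
# SSRs
# ---------------------------------------------------------------------------

def _min_period(s: str) -> int:
    for p in range(1, len(s)):
        if len(s) % p == 0 and s == s[:p] * (len(s) // p):
            return p
    return len(s)


def _canonical_rotation(motif: str) -> str:
    return min(motif[i:] + motif[:i] for i in range(len(motif)))


def _n_free_segments(seq: str):
    """Yield (offset, subsequence) for maximal N-free stretches."""
    start = None
    for i, ch in enumerate(seq):
        if ch == "N":
            if start is not None:
                yield start, seq[start:i]
                start = None
        elif start is None:
            start = i
    if start is not None:
        yield start, seq[start:]


def find_ssrs(molecule: Molecule,
              thresholds: dict[int, int] | None = None) -> list[SSRRecord]:
    """MISA-style perfect microsatellite scan.

    Only maximal runs are reported, each at its smallest true unit length
    (a dinucleotide run is never additionally reported as a mononucleotide
    run, and vice versa: the motif's fundamental period must equal the
    scanned unit length).
    """
    thresholds = dict(DEFAULT_SSR_THRESHOLDS if thresholds is None else thresholds)
    missing = set(range(1, 7)) - set(thresholds)
    if missing:
        raise ValueError(f"thresholds must cover unit lengths 1-6; missing {missing}")
    out: list[SSRRecord] = []
    for offset, seg in _n_free_segments(molecule.seq):
        n = len(seg)
        if n < 2:
            continue
        arr = np.frombuffer(seg.encode(), dtype=np.uint8)
        for u in range(1, 7):
            if n < u * thresholds[u]:
                continue
            # m[k] marks seg[k+u] == seg[k]; a maximal True run [a, b]
            # is a maximal stretch of period u covering seg[a .. b+u]
            m = arr[u:] == arr[:-u]
            for a, b in _merged_true_runs(m, max_gap=0):
                run_len = b - a + 1 + u
                copies = run_len // u
                if copies < thresholds[u]:
                    continue
                motif = seg[a:a + u]
                if _min_period(motif) != u:
                    continue  # reported at its fundamental period instead
                start = offset + a + 1
                out.append(SSRRecord(molecule.id, _canonical_rotation(motif),
                                     u, copies, start, start + u * copies - 1))
    out.sort(key=lambda r: (r.start, r.unit_length))
    return out


# ---------------------------------------------------------------------------
# Tandem repeats
# ---------------------------------------------------------------------------

def find_tandem(molecule: Molecule, min_unit: int = 2, max_unit: int = 60,
                min_match_pct: float = 67.0) -> list[TandemRepeat]:
    """Period-scan tandem repeat detection.

    For each period ``p`` the boolean profile ``seq[i] == seq[i+p]`` is
    computed; runs of agreement (merged across mismatch gaps shorter than
    ``p``) whose span is at least two units and whose agreement fraction is
    at least ``min_match_pct`` are reported.  Reports contained in a
    better-scoring report at another period are collapsed (best match_pct,
    then smallest unit wins).
    """
    if not (1 <= min_unit <= max_unit):
        raise ValueError("need 1 <= min_unit <= max_unit")
    candidates: list[TandemRepeat] = []
    for offset, seg in _n_free_segments(molecule.seq):
        n = len(seg)
        if n < 2 * min_unit:
            continue
        arr = np.frombuffer(seg.encode(), dtype=np.uint8)
        for p in range(min_unit, min(max_unit, n // 2) + 1):
            m = arr[p:] == arr[:-p]
            if not m.any():
                continue
            for k0, k1, matches in _tandem_regions(m, p, min_match_pct / 100):
                total = k1 - k0 + 1
                span = total + p
                if span < 2 * p:
                    continue
                pct = 100.0 * matches / total
                if pct < min_match_pct:
                    continue
                candidates.append(TandemRepeat(
                    molecule.id, offset + k0 + 1, offset + k1 + p + 1,
                    p, round(span / p, 1), round(pct, 1)))
    return _collapse_tandem(candidates)


def _tandem_regions(m: np.ndarray, p: int, min_frac: float):
    """Greedy segmentation of the period-p match profile: a region grows to
    the next agreeing position only while the gap is shorter than one unit
    and the running agreement fraction stays above min_frac.  Yields
    (start, end, matches) over comparison indices (region ends on a match,
    so maximality at the boundaries is preserved)."""
    idx = np.flatnonzero(m).tolist()
    if not idx:
        return
    start = prev = idx[0]
    matches = 1
    for k in idx[1:]:
        gap = k - prev - 1
        if gap < p and (matches + 1) / (k - start + 1) >= min_frac:
            prev = k
            matches += 1
        else:
            yield start, prev, matches
            start = prev = k
            matches = 1
    yield start, prev, matches


def _merged_true_runs(m: np.ndarray, max_gap: int) -> list[tuple[int, int]]:
    """Maximal True runs in m, merging runs separated by <= max_gap Falses."""
    idx = np.flatnonzero(m)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > max_gap + 1)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [idx.size - 1]))
    return [(int(idx[a]), int(idx[b])) for a, b in zip(starts, ends)]


def _prefer(c: TandemRepeat, k: TandemRepeat) -> bool:
    """True when c should displace k for the same locus.

    Harmonically related periods (one divides the other) collapse to the
    fundamental period — a mismatch hits fewer comparisons at a doubled
    period, so raw match_pct alone would favour the harmonic.  Otherwise
    best match_pct wins, then the smaller unit, then the wider span.
    """
    pc, pk = c.unit_length, k.unit_length
    if pc != pk and (pc % pk == 0 or pk % pc == 0):
        return pc < pk
    return ((-c.match_pct, c.unit_length, c.start - c.end)
            < (-k.match_pct, k.unit_length, k.start - k.end))


def _collapse_tandem(cands: list[TandemRepeat]) -> list[TandemRepeat]:
    kept: list[TandemRepeat] = []
    for c in sorted(cands, key=lambda t: (t.start, t.unit_length)):
        matched = False
        for i, k in enumerate(kept):
            if k.molecule_id != c.molecule_id:
                continue
            nested = ((k.start <= c.start and c.end <= k.end)
                      or (c.start <= k.start and k.end <= c.end))
            if nested:
                if _prefer(c, k):
                    kept[i] = c
                matched = True
                break
        if not matched:
            kept.append(c)
    kept.sort(key=lambda t: (t.start, t.unit_length))
    return kept


# ---------------------------------------------------------------------------
# Dispersed (interspersed) repeats — suffix array / LCP
# ---------------------------------------------------------------------------

def _suffix_array(t: np.ndarray) -> np.ndarray:
    """Suffix array by prefix doubling (O(n log^2 n))."""
    n = len(t)
    rank = np.unique(t, return_inverse=True)[1].astype(np.int64)
    k = 1
    sa = np.argsort(rank, kind="stable")
    while True:
        key2 = np.full(n, -1, dtype=np.int64)
        if k < n:
            key2[:n - k] = rank[k:]
        sa = np.lexsort((key2, rank))
        r1, r2 = rank[sa], key2[sa]
        changed = np.ones(n, dtype=bool)
        changed[1:] = (r1[1:] != r1[:-1]) | (r2[1:] != r2[:-1])
        new = np.empty(n, dtype=np.int64)
        new[sa] = np.cumsum(changed) - 1
        rank = new
        if rank[sa[-1]] == n - 1:
            return sa
        k *= 2


def _lcp_array(t: np.ndarray, sa: np.ndarray) -> np.ndarray:
    """Kasai LCP: lcp[i] = common prefix of suffixes sa[i-1], sa[i]."""
    n = len(t)
    rank = np.empty(n, dtype=np.int64)
    rank[sa] = np.arange(n)
    lcp = np.zeros(n, dtype=np.int64)
    h = 0
    tl = t.tolist()
    sal = sa.tolist()
    rankl = rank.tolist()
    for i in range(n):
        r = rankl[i]
        if r > 0:
            j = sal[r - 1]
            while i + h < n and j + h < n and tl[i + h] == tl[j + h]:
                h += 1
            lcp[r] = h
            if h:
                h -= 1
        else:
            h = 0
    return lcp


def _maximal_pairs(t: np.ndarray, sa: np.ndarray, lcp: np.ndarray,
                   min_len: int):
    """All (pos1, pos2, length) maximal exact pairs with length >= min_len.

    A pair is maximal when the characters immediately left of both
    occurrences differ (left-maximality; unique sentinels make boundaries
    auto-maximal) and the match length is the exact LCP of the two suffixes
    (right-maximality).
    """
    n = len(sa)
    tl = t.tolist()
    sal = sa.tolist()
    lcpl = lcp.tolist()
    pairs = []
    i = 1
    while i < n:
        if lcpl[i] < min_len:
            i += 1
            continue
        j = i
        while j < n and lcpl[j] >= min_len:
            j += 1
        block = sal[i - 1:j]          # suffixes in the block
        blk_lcp = lcpl[i:j]           # lcp between consecutive block members
        for b in range(1, len(block)):
            m = blk_lcp[b - 1]
            q = block[b]
            cq = tl[q - 1] if q > 0 else -1
            for a in range(b - 1, -1, -1):
                if blk_lcp[a] < m:
                    m = blk_lcp[a]
                if m < min_len:
                    break
                p = block[a]
                cp = tl[p - 1] if p > 0 else -2
                if cp != cq:
                    pairs.append((p, q, m))
        i = j
    return pairs


class _Region:
    __slots__ = ("start", "end", "mol_idx", "strand", "seqlen", "mol_len")

    def __init__(self, start, end, mol_idx, strand, seqlen, mol_len):
        self.start, self.end = start, end
        self.mol_idx, self.strand = mol_idx, strand
        self.seqlen, self.mol_len = seqlen, mol_len


def _build_text(genome: Genome):
    """Concatenate forward and reverse-complement sequences (circular
    molecules doubled) with unique separators; N bases also become unique
    sentinels so no match crosses them."""
    base_map = {"A": 0, "C": 1, "G": 2, "T": 3}
    chunks: list[np.ndarray] = []
    regions: list[_Region] = []
    sentinel = -1
    pos = 0

    def encode(seq: str) -> np.ndarray:
        nonlocal sentinel
        arr = np.empty(len(seq), dtype=np.int64)
        for i, ch in enumerate(seq):
            v = base_map.get(ch)
            if v is None:
                v = sentinel
                sentinel -= 1
            arr[i] = v
        return arr

    def add(seq: str, mol_idx: int, strand: str, mol_len: int):
        nonlocal pos, sentinel
        arr = encode(seq)
        regions.append(_Region(pos, pos + len(arr), mol_idx, strand,
                               len(seq), mol_len))
        chunks.append(arr)
        chunks.append(np.array([sentinel], dtype=np.int64))
        sentinel -= 1
        pos += len(arr) + 1

    for mi, mol in enumerate(genome):
        s = mol.seq + mol.seq if mol.circular else mol.seq
        add(s, mi, "+", mol.length)
    for mi, mol in enumerate(genome):
        s = mol.seq + mol.seq if mol.circular else mol.seq
        add(revcomp(s), mi, "-", mol.length)
    return np.concatenate(chunks), regions


def find_dispersed(genome: Genome, min_length: int = 30) -> list[DispersedRepeat]:
    """All maximal exact dispersed repeat pairs of length >= min_length.

    Pairs are classified ``direct`` (both occurrences on the same strand)
    or ``palindromic`` (opposite strands).  Mirror duplicates from the
    reverse-complement half of the index and shift duplicates from circular
    doubling are removed; a locus matching its own reverse complement
    (a true DNA palindrome) is not a pair and is dropped.
    """
    if min_length < 8:
        raise ValueError("min_length < 8 refused (seed explosion)")
    text, regions = _build_text(genome)
    sa = _suffix_array(text)
    lcp = _lcp_array(text, sa)
    raw = _maximal_pairs(text, sa, lcp, min_length)

    starts = np.array([r.start for r in regions])

    def locate(p: int) -> tuple[_Region, int]:
        ri = int(np.searchsorted(starts, p, side="right")) - 1
        return regions[ri], p - regions[ri].start

    mol_ids = [m.id for m in genome]
    mol_order = {m.id: i for i, m in enumerate(genome)}
    seen: set[tuple] = set()
    results: list[tuple] = []
    for p, q, length in raw:
        occs = []
        skip = False
        for pos in (p, q):
            reg, off = locate(pos)
            L = reg.mol_len
            if length > L:
                skip = True
                break
            if reg.strand == "+":
                g0 = off
            else:  # map reverse-complement coordinates back to forward
                g0 = reg.seqlen - (off + length)
            start1 = g0 % L + 1
            end1 = start1 + length - 1  # may exceed L: wrapped occurrence
            occs.append((mol_ids[reg.mol_idx], start1, end1, reg.strand))
        if skip:
            continue
        o1, o2 = occs
        strands = (o1[3], o2[3])
        if strands == ("-", "-"):
            continue  # mirror of a direct pair found on the forward strands
        if (o1[0], o1[1], o1[2]) == (o2[0], o2[1], o2[2]):
            continue  # same locus (shift duplicate or self-palindrome)
        kind = "direct" if strands == ("+", "+") else "palindromic"
        key1 = (mol_order[o1[0]], o1[1], o1[2])
        key2 = (mol_order[o2[0]], o2[1], o2[2])
        if key2 < key1:
            o1, o2 = o2, o1
        if kind == "palindromic" and o1[3] == "-":
            # equivalent pair with both strands flipped; canonical occ1 is '+'
            o1 = (o1[0], o1[1], o1[2], "+")
            o2 = (o2[0], o2[1], o2[2], "-")
        dedup = (kind, o1, o2)
        if dedup in seen:
            continue
        seen.add(dedup)
        results.append((length, o1, o2, kind))

    results.sort(key=lambda r: (-r[0], mol_order[r[1][0]], r[1][1],
                                mol_order[r[2][0]], r[2][1], r[3]))
    return [DispersedRepeat(f"R{i + 1}", kind, length, o1, o2)
            for i, (length, o1, o2, kind) in enumerate(results)]


def longest_repeat(genome: Genome,
                   repeats: list[DispersedRepeat] | None = None
                   ) -> DispersedRepeat | None:
    """Longest dispersed pair; ties broken by (molecule, start). ``None``
    when the genome has no repeat above threshold."""
    if repeats is None:
        repeats = find_dispersed(genome)
    return repeats[0] if repeats else None


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

def ssr_table(records: list[SSRRecord]):
    import pandas as pd
    return pd.DataFrame([{"molecule": r.molecule_id, "start": r.start,
                          "end": r.end, "motif": r.motif,
                          "unit_length": r.unit_length, "copies": r.copies}
                         for r in records])


def tandem_table(records: list[TandemRepeat]):
    import pandas as pd
    return pd.DataFrame([{"molecule": r.molecule_id, "start": r.start,
                          "end": r.end, "unit_length": r.unit_length,
                          "copy_number": r.copy_number,
                          "match_pct": r.match_pct} for r in records])


def dispersed_table(repeats: list[DispersedRepeat], genome: Genome):
    import pandas as pd
    rows = []
    for r in repeats:
        (m1, s1, e1, st1), (m2, s2, e2, st2) = r.occ1, r.occ2
        rows.append({
            "repeat_id": r.repeat_id, "kind": r.kind, "length": r.length,
            "mol1": m1, "start1": s1, "end1": e1, "strand1": st1,
            "mol2": m2, "start2": s2, "end2": e2, "strand2": st2,
            "loc1": f"{m1}: {format_interval(s1, e1, genome[m1].length, st1)}",
            "loc2": f"{m2}: {format_interval(s2, e2, genome[m2].length, st2)}",
        })
    return pd.DataFrame(rows)
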