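"""Detection of plastid-derived fragments in a mitochondrial genome (MTPT).

Chloroplast sequence is recurrently transferred into plant mitogenomes.
This module finds cp↔mt homologous fragments by local alignment — exact
k-mer seeding, diagonal clustering, and banded X-drop extension with affine
gaps — and classifies chloroplast genes overlapping each fragment as
completely or partially transferred.

Scoring defaults are megablast-like: match +1, mismatch −2, gap open 2.5,
gap extend 0.5, 20-mer seeds.  The chloroplast genome is treated as
circular (virtually doubled for seeding and extension; coordinates are
normalised back and duplicates removed).  Fragments duplicated by the
chloroplast inverted repeat yield two hits, reported separately.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome_io import GeneFeature, Genome, revcomp

logger = logging.getLogger("mitostruct")

NEG_INF = -1e18


@dataclass(frozen=True)
class Scoring:
    match: float = 1.0
    mismatch: float = -2.0
    gap_open: float = 2.5    # cost of opening a gap (first gap base adds extend too)
    gap_extend: float = 0.5


DEFAULT_SCORING = Scoring()
DEFAULT_SEED_K = 20
DEFAULT_MIN_LENGTH = 28
DEFAULT_MIN_SCORE = 25.0


@dataclass
class HomologyHit:
    """One cp↔mt local alignment.

    Coordinates are 1-based inclusive.  ``cp_start <= cp_end`` always
    (``cp_end`` may exceed the cp length for an origin-wrapping hit on the
    circular chloroplast); a minus-strand fragment is encoded by descending
    mt coordinates (``mt_start > mt_end``).
    """
    aln_length: int          # alignment columns, gaps included
    identity_pct: float
    mismatches: int
    gap_openings: int
    cp_start: int
    cp_end: int
    mt_start: int
    mt_end: int
    score: float
    strand: str
    mt_molecule: str
    gap_columns: int = 0

    @property
    def mt_interval(self) -> tuple[int, int]:
        return (min(self.mt_start, self.mt_end), max(self.mt_start, self.mt_end))

    @property
    def cp_interval(self) -> tuple[int, int]:
        return (self.cp_start, self.cp_end)


@dataclass
class TransferAnnotation:
    hit: HomologyHit
    genes: list[tuple[str, str]]  # (gene_name, "complete"|"partial")


# ---------------------------------------------------------------------------
# Banded affine-gap X-drop extension with traceback
# ---------------------------------------------------------------------------

def _extend_xdrop(a: str, b: str, sc: Scoring, band: int, xdrop: float,
                  max_len: int = 30000):
    """Best-scoring alignment of a prefix of ``a`` with a prefix of ``b``.

    Returns ``(ai, bj, score, matches, mismatches, gap_openings, gap_cols)``
    where the alignment consumes ``a[:ai]`` and ``b[:bj]`` and ends in a
    match/mismatch column.  The DP runs in a band of half-width ``band``
    around the main diagonal and stops once every live cell falls more than
    ``xdrop`` below the best score seen (X-drop termination).
    """
    n, m = min(len(a), max_len), min(len(b), max_len)
    if n == 0 or m == 0:
        return 0, 0, 0.0, 0, 0, 0, 0
    w = band
    W = 2 * w + 1
    go = sc.gap_open + sc.gap_extend
    ge = sc.gap_extend
    av = np.frombuffer(a[:n].encode(), dtype=np.uint8)
    bv = np.frombuffer(b[:m].encode(), dtype=np.uint8)

    # band coordinate c in row i represents column j = i - w + c
    Ms, Es, Fs = [], [], []
    M = np.full(W, NEG_INF)
    E = np.full(W, NEG_INF)
    F = np.full(W, NEG_INF)
    M[w] = 0.0  # (0, 0)
    for c in range(w + 1, W):
        j = c - w
        if j > m:
            break
        E[c] = -(go + (j - 1) * ge)
    Ms.append(M); Es.append(E); Fs.append(F)

    best = (0.0, 0, w)  # (score, i, c) over M cells
    idx = np.arange(W, dtype=np.float64)
    for i in range(1, n + 1):
        prevM, prevE, prevF = Ms[-1], Es[-1], Fs[-1]
        j = idx + (i - w)          # column per band slot
        valid = (j >= 0) & (j <= m)
        jv = np.clip(j.astype(np.int64), 0, m)

        best_prev = np.maximum(np.maximum(prevM, prevE), prevF)
        subs = np.where(av[i - 1] == bv[np.clip(jv - 1, 0, m - 1)],
                        sc.match, sc.mismatch)
        M = np.where(valid & (jv >= 1), best_prev + subs, NEG_INF)
        M[M < NEG_INF / 2] = NEG_INF

        up_M = np.concatenate((prevM[1:], [NEG_INF]))
        up_F = np.concatenate((prevF[1:], [NEG_INF]))
        F = np.where(valid, np.maximum(up_M - go, up_F - ge), NEG_INF)
        if i <= w:                 # column 0 vertical gap
            c0 = w - i
            F[c0] = -(go + (i - 1) * ge)

        # E via in-row prefix max: E[c] = max_{d<c}(M[d] + d*ge) - go - (c-1)*ge
        t = np.where(M > NEG_INF / 2, M + idx * ge, NEG_INF)
        run = np.maximum.accumulate(t)
        E = np.full(W, NEG_INF)
        E[1:] = run[:-1] - go - (idx[1:] - 1) * ge
        E = np.where(valid & (jv >= 1) & (E > NEG_INF / 2), E, NEG_INF)

        Ms.append(M); Es.append(E); Fs.append(F)
        row_best = float(M.max())
        if row_best > best[0]:
            best = (row_best, i, int(M.argmax()))
        live = max(row_best, float(E.max()), float(F.max()))
        if live < best[0] - xdrop:
            break

    score, bi, bc = best
    # traceback from the best M cell to (0, 0)
    matches = mismatches = gap_open_count = gap_cols = 0
    i, c, state = bi, bc, "M"
    eps = 1e-6
    while True:
        j = i - w + c
        if i == 0 and j == 0:
            break
        if state == "M":
            if i == 0 or j == 0:
                break  # defensive: M is undefined on the borders
            if av[i - 1] == bv[j - 1]:
                matches += 1
                target = Ms[i][c] - sc.match
            else:
                mismatches += 1
                target = Ms[i][c] - sc.mismatch
            i -= 1
            if abs(Ms[i][c] - target) < eps:
                state = "M"
            elif abs(Es[i][c] - target) < eps:
                state = "E"
            else:
                state = "F"
        elif state == "F":  # vertical gap column: consumes a
            gap_cols += 1
            val = Fs[i][c]
            i -= 1
            c += 1
            if c < W and abs(Ms[i][c] - go - val) < eps:
                gap_open_count += 1
                state = "M"
            else:
                state = "F"
        else:               # E, horizontal gap column: consumes b
            gap_cols += 1
            val = Es[i][c]
            c -= 1
            if c >= 0 and abs(Ms[i][c] - go - val) < eps:
                gap_open_count += 1
                state = "M"
            else:
                state = "E"
    bj = bi - w + bc
    return bi, bj, score, matches, mismatches, gap_open_count, gap_cols


# ---------------------------------------------------------------------------
# Seeding and hit construction
# ---------------------------------------------------------------------------

def _kmer_index(seq: str, k: int) -> dict[str, list[int]]:
    idx: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i:i + k]
        if "N" in kmer:
            continue
        idx.setdefault(kmer, []).append(i)
    return idx


def _cluster_seeds(seeds: list[tuple[int, int]], band: int,
                   max_gap: int = 200) -> list[list[tuple[int, int]]]:
    """Group (mt_pos, cp_pos) seeds into collinear diagonal clusters."""
    seeds = sorted(seeds, key=lambda s: (s[0] - s[1], s[0]))
    clusters: list[list[tuple[int, int]]] = []
    for s in seeds:
        d = s[0] - s[1]
        placed = False
        for cl in reversed(clusters):
            d0 = cl[-1][0] - cl[-1][1]
            if abs(d - d0) <= band and 0 <= s[0] - cl[-1][0] <= max_gap:
                cl.append(s)
                placed = True
                break
            if d - d0 > band:
                break
        if not placed:
            clusters.append([s])
    return clusters


def _align_from_anchor(mt_seq: str, cp_seq: str, anchor: tuple[int, int],
                       k: int, sc: Scoring, band: int, xdrop: float):
    """Extend an exact k-mer anchor in both directions; return 0-based
    half-open spans on mt and cp plus alignment statistics."""
    mp, cp_ = anchor
    # rightwards from the end of the seed
    r = _extend_xdrop(mt_seq[mp + k:], cp_seq[cp_ + k:], sc, band, xdrop)
    # leftwards over the reversed prefixes ending at the seed start
    l = _extend_xdrop(mt_seq[:mp][::-1], cp_seq[:cp_][::-1], sc, band, xdrop)
    ai_r, bj_r, sc_r, mat_r, mis_r, go_r, gc_r = r
    ai_l, bj_l, sc_l, mat_l, mis_l, go_l, gc_l = l
    mt_s, mt_e = mp - ai_l, mp + k + ai_r
    cp_s, cp_e = cp_ - bj_l, cp_ + k + bj_r
    score = sc_l + sc_r + k * sc.match
    matches = mat_l + mat_r + k
    mism = mis_l + mis_r
    gopen = go_l + go_r
    gcols = gc_l + gc_r
    aln_len = matches + mism + gcols
    return (mt_s, mt_e, cp_s, cp_e, score, matches, mism, gopen, gcols, aln_len)


def find_homologous_fragments(mt: Genome, cp: Genome,
                              min_length: int = DEFAULT_MIN_LENGTH,
                              min_score: float = DEFAULT_MIN_SCORE,
                              scoring: Scoring = DEFAULT_SCORING,
                              seed_k: int = DEFAULT_SEED_K,
                              band: int = 50,
                              xdrop: float = 20.0) -> list[HomologyHit]:
    """Seed–extend local alignment of the chloroplast genome against every
    mitochondrial molecule, both strands.

    Hits wholly contained (on both genomes) in a higher-scoring hit are
    dropped; the remainder are reported with BLAST-style columns
    (alignment length, identity%, mismatches, gap openings, coordinates).
    """
    cp_mol = cp.molecules[0]
    Lcp = cp_mol.length
    cp_fwd = cp_mol.seq + cp_mol.seq if cp_mol.circular else cp_mol.seq
    hits: list[HomologyHit] = []
    for strand, cp_text in (("+", cp_fwd), ("-", revcomp(cp_fwd))):
        idx = _kmer_index(cp_text, seed_k)
        for mol in mt:
            seeds = []
            mseq = mol.seq
            for i in range(len(mseq) - seed_k + 1):
                for j in idx.get(mseq[i:i + seed_k], ()):
                    seeds.append((i, j))
            for cluster in _cluster_seeds(seeds, band):
                anchor = cluster[len(cluster) // 2]
                (mt_s, mt_e, cp_s, cp_e, score, matches, mism, gopen, gcols,
                 aln_len) = _align_from_anchor(mseq, cp_text, anchor, seed_k,
                                               scoring, band, xdrop)
                if aln_len < min_length or score < min_score:
                    continue
                identity = 100.0 * matches / aln_len
                # map cp text coordinates back to the (possibly doubled) genome
                cs, ce = cp_s + 1, cp_e  # 1-based inclusive on cp_text
                if strand == "-":
                    cs, ce = len(cp_text) - cp_e + 1, len(cp_text) - cp_s
                span = ce - cs + 1
                if span > Lcp:
                    continue
                cs_n = (cs - 1) % Lcp + 1
                ce_n = cs_n + span - 1   # may wrap (> Lcp) on circular cp
                if strand == "+":
                    h_mt_start, h_mt_end = mt_s + 1, mt_e
                else:
                    h_mt_start, h_mt_end = mt_e, mt_s + 1
                hits.append(HomologyHit(aln_len, round(identity, 3), mism,
                                        gopen, cs_n, ce_n, h_mt_start,
                                        h_mt_end, score, strand, mol.id,
                                        gcols))
    return _dedupe_hits(hits)


def _dedupe_hits(hits: list[HomologyHit]) -> list[HomologyHit]:
    hits = sorted(hits, key=lambda h: (-h.score, h.mt_molecule,
                                       h.mt_interval, h.cp_interval))
    kept: list[HomologyHit] = []
    for h in hits:
        contained = False
        for k in kept:
            if (k.mt_molecule == h.mt_molecule and k.strand == h.strand
                    and k.mt_interval[0] <= h.mt_interval[0]
                    and h.mt_interval[1] <= k.mt_interval[1]
                    and k.cp_interval[0] <= h.cp_interval[0]
                    and h.cp_interval[1] <= k.cp_interval[1]):
                contained = True
                break
        if not contained:
            kept.append(h)
    kept.sort(key=lambda h: (-h.aln_length, h.mt_molecule, h.mt_interval))
    return kept


# ---------------------------------------------------------------------------
# Transfer classification and summary
# ---------------------------------------------------------------------------

def _cp_intervals(hit: HomologyHit, cp_len: int) -> list[tuple[int, int]]:
    if hit.cp_end <= cp_len:
        return [(hit.cp_start, hit.cp_end)]
    return [(hit.cp_start, cp_len), (1, hit.cp_end - cp_len)]


def _covered(seg: tuple[int, int], intervals: list[tuple[int, int]]) -> str | None:
    """'complete' if seg fully inside the hit interval(s), 'partial' on
    overlap, None when disjoint."""
    s, e = seg
    overlap = any(not (e < a or s > b) for a, b in intervals)
    if not overlap:
        return None
    complete = any(a <= s and e <= b for a, b in intervals)
    return "complete" if complete else "partial"


def classify_transfers(hits: list[HomologyHit],
                       cp_features: list[GeneFeature],
                       cp_length: int | None = None) -> list[TransferAnnotation]:
    """Annotate each hit with the chloroplast genes it carries.

    A gene is *complete* when its full annotated span lies within the hit's
    chloroplast interval, *partial* when it merely overlaps.  Genes are
    deduplicated within a hit; a hit overlapping no gene is an intergenic
    transfer (empty list).
    """
    if cp_length is None:
        cp_length = max((h.cp_end for h in hits), default=0)
    out = []
    for hit in hits:
        ivals = _cp_intervals(hit, cp_length)
        genes: dict[str, str] = {}
        for f in cp_features:
            span = (min(s for _, s, _, _ in f.segments),
                    max(e for _, _, e, _ in f.segments))
            status = _covered(span, ivals)
            if status is None:
                continue
            # a gene seen both complete and partial keeps the stronger call
            if genes.get(f.gene_name) != "complete":
                genes[f.gene_name] = status
        out.append(TransferAnnotation(hit, sorted(genes.items())))
    return out


def transfer_summary(hits: list[HomologyHit],
                     mt_total_length: int) -> tuple[int, int, float]:
    """(fragment count, summed alignment length, percent of mitogenome).

    The total is the plain column sum over reported hits — overlapping or
    inverted-repeat-duplicated fragments are not deduplicated.
    """
    total = sum(h.aln_length for h in hits)
    pct = round(100.0 * total / mt_total_length, 2) if mt_total_length else 0.0
    return len(hits), total, pct


def mtpt_table(annotations: list[TransferAnnotation]) -> pd.DataFrame:
    rows = []
    for i, ann in enumerate(annotations, 1):
        h = ann.hit
        label = ", ".join(f"{status.capitalize()} ({gene})"
                          for gene, status in ann.genes) or "intergenic"
        rows.append({"fragment": i, "aln_length": h.aln_length,
                     "identity_pct": h.identity_pct, "mismatch": h.mismatches,
                     "gap_openings": h.gap_openings, "cp_start": h.cp_start,
                     "cp_end": h.cp_end, "mt_start": h.mt_start,
                     "mt_end": h.mt_end, "strand": h.strand,
                     "mt_molecule": h.mt_molecule, "annotation": label})
    return pd.DataFrame(rows)
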