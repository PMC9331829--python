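"""Repeat-mediated recombination detection from long reads.

A dispersed repeat pair offers two arrangements of its flanking sequence:
the *primary* conformation (the assembled genome) and the *alternative*
conformation produced by homologous recombination across the repeat, in
which the upstream/downstream flanks are exchanged between the two repeat
units.  For each candidate pair this module

1. extracts both repeat units with their flanking regions (default 1000 bp)
   as two primary references, and builds two flank-exchanged alternative
   references (``L1·U·R2`` and ``L2·U·R1``);
2. assigns each long read that *completely spans* a repeat unit — covering
   the unit plus at least ``anchor`` bp of flank on both sides — to the
   conformation whose reference it fits best;
3. counts per-conformation support and estimates the recombination
   frequency ``n_alt / (n_primary + n_alt)``.

Only reads spanning the unit carry conformation information: the repeat
unit itself is identical in all four references, so discrimination comes
entirely from the ``anchor`` flank bases on each side.  Read-to-reference
fit is scored by exact edit-distance infix alignment (edlib) of the
spanning window against the read; a read is ambiguous when its two best
conformation edit distances differ by less than 5% of the discriminating
window (``2 × anchor`` bases).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import edlib
import pandas as pd

from .genome_io import Genome, Molecule, format_interval, revcomp
from .repeat_scan import DispersedRepeat

logger = logging.getLogger("mitostruct")

DEFAULT_FLANK_LEN = 1000
DEFAULT_ANCHOR = 100
DEFAULT_MIN_IDENTITY = 0.75
DEFAULT_EVIDENCE_THRESHOLD = 2


@dataclass
class ConformationPair:
    """Primary and flank-exchanged alternative references for one repeat.

    Each reference is ``(sequence, unit_span)`` where ``unit_span`` is the
    1-based inclusive interval of the repeat unit on that reference.  The
    unit substring is identical across all four references.
    """
    repeat_id: str
    unit: str
    refs_primary: list[tuple[str, tuple[int, int]]]
    refs_alternative: list[tuple[str, tuple[int, int]]]
    flank_len: int
    inseparable: bool = False

    @property
    def unit_length(self) -> int:
        return len(self.unit)


@dataclass
class SpanningSupport:
    """Read support for the two conformations of one repeat pair."""
    repeat_id: str
    n_primary: int = 0
    n_alternative: int = 0
    n_ambiguous: int = 0
    n_nonspanning: int = 0
    flagged: bool = False

    @property
    def frequency(self) -> float | None:
        """Recombination frequency; ``None`` when no informative read."""
        denom = self.n_primary + self.n_alternative
        return None if denom == 0 else self.n_alternative / denom


# ---------------------------------------------------------------------------
# Conformation construction
# ---------------------------------------------------------------------------

def _genomic_flanks(mol: Molecule, start: int, end: int,
                    up_len: int, down_len: int) -> tuple[str, str]:
    """Upstream/downstream genomic flank sequences of [start, end],
    truncated at linear molecule ends, wrapped on circular molecules."""
    L = mol.length
    unit_len = end - start + 1
    if mol.circular:
        # flanks may wrap but must not run into the unit from the far side
        avail = L - unit_len
        up_len = min(up_len, avail // 2 if up_len + down_len > avail else up_len)
        down_len = min(down_len, avail - up_len)
    up = down = ""
    if up_len > 0:
        s = start - up_len
        if s < 1:
            if mol.circular:
                up = mol.fetch((s - 1) % L + 1, (s - 1) % L + up_len)
            else:
                up = mol.fetch(1, start - 1) if start > 1 else ""
        else:
            up = mol.fetch(s, start - 1)
    if down_len > 0:
        s = end + 1
        if mol.circular:
            s = (s - 1) % L + 1
            down = mol.fetch(s, s + down_len - 1)
        else:
            e = min(end + down_len, L)
            down = mol.fetch(s, e) if s <= e else ""
    return up, down


def _oriented_flanks(mol: Molecule, occ: tuple[str, int, int, str],
                     up_len: int, down_len: int) -> tuple[str, str]:
    """Flanks of an occurrence in repeat-unit orientation (minus-strand
    occurrences reverse-complement their flanks and swap sides)."""
    _, start, end, strand = occ
    if strand == "+":
        up, down = _genomic_flanks(mol, start, end, up_len, down_len)
        return up, down
    down_g, up_g = _genomic_flanks(mol, start, end, down_len, up_len)
    return revcomp(up_g), revcomp(down_g)


def build_conformations(genome: Genome, rep: DispersedRepeat,
                        flank_len: int = DEFAULT_FLANK_LEN) -> ConformationPair:
    """Build the four conformation references for a repeat pair.

    Primary references are the genome's own arrangements ``L1·U·R1`` and
    ``L2·U·R2``; the alternatives exchange downstream flanks: ``L1·U·R2``
    and ``L2·U·R1``.  All four are in the repeat unit's orientation
    (minus-strand occurrences reverse-complemented before assembly).
    Occurrences on the same molecule closer than ``flank_len`` are flagged
    inseparable and the facing flanks shrink to the gap.
    """
    u1, u2 = rep.occurrence_seqs(genome)
    if u1 != u2:
        raise ValueError(f"{rep.repeat_id}: occurrence sequences differ; "
                         "not an exact repeat pair")
    unit = u1
    o1, o2 = rep.occ1, rep.occ2
    lens = {0: [flank_len, flank_len], 1: [flank_len, flank_len]}  # [up, down] genomic
    inseparable = False
    if o1[0] == o2[0] and o1[2] <= genome[o1[0]].length and o2[2] <= genome[o1[0]].length:
        a, b = sorted((o1, o2), key=lambda o: o[1])
        gap = b[1] - a[2] - 1
        if gap < flank_len:
            inseparable = True
            lo = max(0, gap)
            logger.warning("%s: occurrences within flank distance (gap %d); "
                           "facing flanks shrunk", rep.repeat_id, gap)
            # facing sides: downstream of the left occ, upstream of the right
            left_is_1 = a == o1
            lens[0 if left_is_1 else 1][1] = lo
            lens[1 if left_is_1 else 0][0] = lo

    f1 = _oriented_flanks(genome[o1[0]], o1, *_orient_lens(o1, lens[0]))
    f2 = _oriented_flanks(genome[o2[0]], o2, *_orient_lens(o2, lens[1]))
    (l1, r1), (l2, r2) = f1, f2

    def ref(left: str, right: str) -> tuple[str, tuple[int, int]]:
        return left + unit + right, (len(left) + 1, len(left) + len(unit))

    return ConformationPair(rep.repeat_id, unit,
                            refs_primary=[ref(l1, r1), ref(l2, r2)],
                            refs_alternative=[ref(l1, r2), ref(l2, r1)],
                            flank_len=flank_len, inseparable=inseparable)


def _orient_lens(occ, updown: list[int]) -> tuple[int, int]:
    """Genomic [up, down] flank budgets -> (up, down) in unit orientation."""
    up, down = updown
    return (up, down) if occ[3] == "+" else (down, up)


# ---------------------------------------------------------------------------
# Read assignment
# ---------------------------------------------------------------------------

def _spanning_window(refseq: str, span: tuple[int, int],
                     anchor: int) -> tuple[str, int, int]:
    us, ue = span
    a1 = min(anchor, us - 1)
    a2 = min(anchor, len(refseq) - ue)
    return refseq[us - 1 - a1: ue + a2], a1, a2


_CIGAR_RE = re.compile(r"(\d+)([=XID])")


def _anchor_edits(cigar: str, a1: int, a2: int, wlen: int) -> tuple[int, int]:
    """Edit operations falling inside the left/right anchor regions of the
    window (edlib cigar: '='/'X'/'I' consume the window, 'D' the read)."""
    qpos = left = right = 0
    for ln, op in _CIGAR_RE.findall(cigar):
        n = int(ln)
        if op == "=":
            qpos += n
        elif op in "XI":
            s, e = qpos, qpos + n
            left += max(0, min(e, a1) - s)
            right += max(0, e - max(s, wlen - a2))
            qpos = e
        else:  # D: read bases inserted relative to the window
            if qpos < a1:
                left += n
            elif qpos >= wlen - a2:
                right += n
    return left, right


def _window_fit(window: str, a1: int, a2: int, read: str,
                read_rc: str) -> tuple[int, int, int]:
    """(total edits, left-anchor edits, right-anchor edits) for the better
    read orientation."""
    best = None
    for target in (read, read_rc):
        res = edlib.align(window, target, mode="HW", task="path")
        if best is None or res["editDistance"] < best["editDistance"]:
            best = res
    el, er = _anchor_edits(best["cigar"], a1, a2, len(window))
    return best["editDistance"], el, er


def assign_read(read: str, conf: ConformationPair,
                anchor: int = DEFAULT_ANCHOR,
                min_identity: float = DEFAULT_MIN_IDENTITY) -> str:
    """Label one read: ``primary`` | ``alternative`` | ``ambiguous`` |
    ``nonspanning``.

    A reference is spanned when its window (unit ± ``anchor`` bp of flank)
    aligns within the read at identity ≥ ``min_identity``.  The label is
    the conformation of the best-fitting spanned reference; when both
    conformations are spanned and their edit distances differ by less than
    5% of the ``2×anchor`` discriminating bases the read is ambiguous.
    """
    if anchor > conf.flank_len:
        raise ValueError("anchor must not exceed flank_len")
    read = read.upper()
    if len(read) < conf.unit_length + 2 * anchor:
        return "nonspanning"
    read_rc = revcomp(read)
    max_err = 1 - min_identity
    spanned_ed: dict[str, int] = {}  # conformation -> best spanned edit dist
    for label, refs in (("primary", conf.refs_primary),
                        ("alternative", conf.refs_alternative)):
        for refseq, span in refs:
            w, a1, a2 = _spanning_window(refseq, span, anchor)
            ed, el, er = _window_fit(w, a1, a2, read, read_rc)
            # spanned: whole window at min_identity AND each anchor region
            # individually covered at min_identity
            if (ed <= max_err * len(w) and el <= max_err * max(a1, 1)
                    and er <= max_err * max(a2, 1)):
                if label not in spanned_ed or ed < spanned_ed[label]:
                    spanned_ed[label] = ed
    if not spanned_ed:
        return "nonspanning"
    if len(spanned_ed) == 1:
        return next(iter(spanned_ed))
    margin = max(1, round(0.05 * 2 * anchor))
    ed_p, ed_a = spanned_ed["primary"], spanned_ed["alternative"]
    if abs(ed_p - ed_a) < margin:
        return "ambiguous"
    return "primary" if ed_p < ed_a else "alternative"


def count_support(reads, conf: ConformationPair,
                  anchor: int = DEFAULT_ANCHOR,
                  min_identity: float = DEFAULT_MIN_IDENTITY) -> SpanningSupport:
    """Aggregate :func:`assign_read` labels over a read set.

    ``reads`` is an iterable of sequences or ``(name, seq)`` pairs.
    Deterministic for fixed inputs; frequency is ``None`` when no read is
    conformation-informative.
    """
    sup = SpanningSupport(conf.repeat_id)
    for item in reads:
        seq = item[1] if isinstance(item, tuple) else item
        label = assign_read(seq, conf, anchor, min_identity)
        if label == "primary":
            sup.n_primary += 1
        elif label == "alternative":
            sup.n_alternative += 1
        elif label == "ambiguous":
            sup.n_ambiguous += 1
        else:
            sup.n_nonspanning += 1
    return sup


def recombination_screen(genome: Genome, reads,
                         repeats: list[DispersedRepeat],
                         min_repeat_len: int = 100,
                         flank_len: int = DEFAULT_FLANK_LEN,
                         anchor: int = DEFAULT_ANCHOR,
                         min_identity: float = DEFAULT_MIN_IDENTITY,
                         evidence_threshold: int = DEFAULT_EVIDENCE_THRESHOLD,
                         ) -> list[tuple[DispersedRepeat, SpanningSupport]]:
    """Test every repeat pair of length ≥ ``min_repeat_len`` for
    recombination support; pairs with ``n_alternative >= evidence_threshold``
    are flagged recombining."""
    reads = [(it[1] if isinstance(it, tuple) else it) for it in reads]
    results = []
    for rep in repeats:
        if rep.length < min_repeat_len:
            continue
        conf = build_conformations(genome, rep, flank_len)
        sup = count_support(reads, conf, anchor, min_identity)
        sup.flagged = sup.n_alternative >= evidence_threshold
        results.append((rep, sup))
    return results


def recomb_table(results: list[tuple[DispersedRepeat, SpanningSupport]],
                 genome: Genome) -> pd.DataFrame:
    rows = []
    for rep, sup in results:
        (m1, s1, e1, st1), (m2, s2, e2, st2) = rep.occ1, rep.occ2
        rows.append({
            "repeat_id": rep.repeat_id, "length_bp": rep.length,
            "loc1": f"{m1}: {format_interval(s1, e1, genome[m1].length, st1)}",
            "loc2": f"{m2}: {format_interval(s2, e2, genome[m2].length, st2)}",
            "reads_major": sup.n_primary,
            "reads_alternative": sup.n_alternative,
            "reads_ambiguous": sup.n_ambiguous,
            "frequency": (round(sup.frequency, 4)
                          if sup.frequency is not None else float("nan")),
            "flagged": sup.flagged,
        })
    return pd.DataFrame(rows)
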