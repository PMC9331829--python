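"""Codon counting and relative synonymous codon usage (RSCU).

RSCU for a codon *c* in a synonymous family of size *k* is the observed
count divided by the mean count over the family: ``RSCU(c) = x_c / mean(x)``.
A uniformly used family therefore has RSCU 1 for every member, and
single-codon families (Met/AUG, Trp/UGG) are 1 whenever observed.  Codons
with RSCU > 1 are "preferred".

Plant mitochondria translate with the standard genetic code; stop codons
are excluded from the table.  Counting is over the internal DNA alphabet,
with RNA spelling applied only at report time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product

import pandas as pd
from Bio.Data import CodonTable

logger = logging.getLogger("mitostruct")

_TABLE = CodonTable.unambiguous_dna_by_id[1]  # standard code
ALL_CODONS: tuple[str, ...] = tuple("".join(p) for p in product("TCAG", repeat=3))
STOP_CODONS = frozenset(_TABLE.stop_codons)
CODON_TO_AA: dict[str, str] = dict(_TABLE.forward_table)

#: amino acid -> tuple of synonymous (non-stop) codons
FAMILIES: dict[str, tuple[str, ...]] = {}
for _c, _aa in CODON_TO_AA.items():
    FAMILIES.setdefault(_aa, ())
FAMILIES = {aa: tuple(c for c in ALL_CODONS if CODON_TO_AA.get(c) == aa)
            for aa in FAMILIES}


@dataclass
class CodonCount:
    counts: dict[str, int]
    n_cds: int
    total_codons: int
    n_skipped: int = 0  # ambiguous-base codons

    def __post_init__(self):
        assert self.total_codons == sum(self.counts.values())


@dataclass
class RSCUTable:
    rscu: dict[str, float]
    counts: dict[str, int] = field(default_factory=dict)


def count_codons(cds_list: list[str] | list[tuple[str, str]]) -> CodonCount:
    """Tally frame-0 codons over coding sequences.

    Accepts plain sequences or ``(gene_name, seq)`` pairs.  Stop codons are
    excluded from the table; codons containing an ambiguous base are skipped
    with a logged total.  Sequence length is assumed a codon multiple
    (``extract_cds`` enforces it).
    """
    counts = {c: 0 for c in ALL_CODONS if c not in STOP_CODONS}
    skipped = 0
    n = 0
    for item in cds_list:
        seq = item[1] if isinstance(item, tuple) else item
        seq = seq.upper()
        n += 1
        for i in range(0, len(seq) - len(seq) % 3, 3):
            codon = seq[i:i + 3]
            if codon in STOP_CODONS:
                continue
            if codon in counts:
                counts[codon] += 1
            else:
                skipped += 1
    if skipped:
        logger.info("count_codons: %d ambiguous-base codon(s) skipped", skipped)
    return CodonCount(counts, n, sum(counts.values()), skipped)


def rscu(counts: CodonCount) -> RSCUTable:
    """RSCU per codon: observed count over the synonymous-family mean.

    A family with zero total observations reports RSCU 0 for all members
    (convention; the ratio is otherwise undefined).
    """
    values: dict[str, float] = {}
    for aa, fam in FAMILIES.items():
        total = sum(counts.counts[c] for c in fam)
        if total == 0:
            for c in fam:
                values[c] = 0.0
            continue
        mean = total / len(fam)
        for c in fam:
            values[c] = counts.counts[c] / mean
    return RSCUTable(values, dict(counts.counts))


def preferred_codons(table: RSCUTable) -> list[str]:
    """Codons used preferentially (RSCU > 1), sorted by descending RSCU,
    ties alphabetical."""
    return sorted((c for c, v in table.rscu.items() if v > 1.0),
                  key=lambda c: (-table.rscu[c], c))


def to_rna(codon: str) -> str:
    return codon.replace("T", "U")


def rscu_table(table: RSCUTable) -> pd.DataFrame:
    """Report table: codon (RNA spelling), amino acid, count, RSCU."""
    rows = [{"codon": to_rna(c), "amino_acid": CODON_TO_AA[c],
             "count": table.counts.get(c, 0), "rscu": round(table.rscu[c], 3)}
            for c in sorted(table.rscu, key=lambda c: (CODON_TO_AA[c], c))]
    return pd.DataFrame(rows)
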