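"""Genome input/output and basic sequence bookkeeping.

Plant mitochondrial genomes are frequently multi-molecule assemblies: a
mixture of linear and circular molecules that together constitute the
mitogenome.  This module defines the in-memory containers used throughout
the package (:class:`Molecule`, :class:`Genome`, :class:`GeneFeature`),
reads them from FASTA/GenBank, computes per-molecule and total statistics,
and extracts coding sequences while honouring multi-exon and trans-spliced
gene models.

Coordinate conventions
----------------------
All coordinates are 1-based and inclusive.  On circular molecules an
interval may wrap the origin; a wrapped interval is encoded with
``end > molecule.length`` (positions are taken modulo the length), and is
rendered for display as an ordered segment list such as
``34,939–36,490;1–127``.  A minus-strand interval carries ``strand='-'``
with ``start <= end`` after normalisation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger("mitostruct")

COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHVacgtnryswkmbdhv",
                           "TGCANYRSWMKVHDBtgcanyrswmkvhdb")
IUPAC_DNA = set("ACGTNRYSWKMBDHV")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC-aware)."""
    return seq.translate(COMPLEMENT)[::-1]


def gc_fraction(seq: str) -> float | None:
    """(G+C) / (A+C+G+T); ``None`` when no unambiguous base is present.

    N (and other ambiguity codes) are excluded from the denominator, so a
    run of N does not dilute the GC estimate.
    """
    g = seq.count("G") + seq.count("C")
    at = seq.count("A") + seq.count("T")
    denom = g + at
    if denom == 0:
        return None
    return g / denom


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class Molecule:
    """One sequence unit of a multi-molecule genome.

    Parameters
    ----------
    id : str
        Record identifier (unique within a genome).
    seq : str
        Upper-case DNA over the IUPAC alphabet.
    topology : str
        ``"linear"`` or ``"circular"``.
    """

    id: str
    seq: str
    topology: str = "linear"

    def __post_init__(self) -> None:
        if self.topology not in ("linear", "circular"):
            raise ValueError(f"molecule {self.id!r}: topology must be "
                             f"'linear' or 'circular', got {self.topology!r}")
        if not self.seq:
            raise ValueError(f"molecule {self.id!r}: empty sequence")

    @property
    def length(self) -> int:
        return len(self.seq)

    @property
    def circular(self) -> bool:
        return self.topology == "circular"

    def fetch(self, start: int, end: int, strand: str = "+") -> str:
        """Sequence of the 1-based inclusive interval [start, end].

        On circular molecules the interval may wrap: positions are taken
        modulo the molecule length (``end`` may exceed it).  Minus strand
        returns the reverse complement.
        """
        L = self.length
        if start < 1 or start > L:
            raise IndexError(f"start {start} outside molecule {self.id} (1..{L})")
        if end < start:
            raise IndexError(f"empty interval {start}..{end}")
        if end <= L:
            s = self.seq[start - 1:end]
        elif self.circular:
            if end - start + 1 > L:
                raise IndexError(f"interval {start}..{end} longer than circular "
                                 f"molecule {self.id} ({L} bp)")
            s = self.seq[start - 1:] + self.seq[:end - L]
        else:
            raise IndexError(f"interval {start}..{end} outside linear molecule "
                             f"{self.id} (1..{L})")
        return revcomp(s) if strand == "-" else s


@dataclass
class Genome:
    """Ordered collection of molecules with unique ids."""

    molecules: list[Molecule]

    def __post_init__(self) -> None:
        ids = [m.id for m in self.molecules]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate molecule ids: {ids}")

    def __iter__(self):
        return iter(self.molecules)

    def __len__(self) -> int:
        return len(self.molecules)

    def __getitem__(self, mol_id: str) -> Molecule:
        for m in self.molecules:
            if m.id == mol_id:
                return m
        raise KeyError(mol_id)

    @property
    def total_length(self) -> int:
        return sum(m.length for m in self.molecules)

    @property
    def gc_total(self) -> float | None:
        return gc_fraction("".join(m.seq for m in self.molecules))


@dataclass
class GeneFeature:
    """An annotated gene with one or more (possibly trans-spliced) segments.

    ``segments`` is a list of ``(molecule_id, start, end, strand)`` tuples in
    transcription order: concatenating each segment's sequence (reverse
    complemented when strand is ``'-'``) yields the mature coding sequence.
    """

    gene_name: str
    kind: str  # CDS | tRNA | rRNA
    segments: list[tuple[str, int, int, str]]
    trans_spliced: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("CDS", "tRNA", "rRNA"):
            raise ValueError(f"gene {self.gene_name!r}: bad kind {self.kind!r}")
        if not self.segments:
            raise ValueError(f"gene {self.gene_name!r}: no segments")
        for mol, start, end, strand in self.segments:
            if start > end:
                raise ValueError(f"gene {self.gene_name!r}: segment "
                                 f"{start}..{end} not normalised (start > end)")
            if strand not in ("+", "-"):
                raise ValueError(f"gene {self.gene_name!r}: bad strand {strand!r}")


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _validate_seq(record_id: str, seq: str) -> None:
    for off, ch in enumerate(seq):
        if ch not in IUPAC_DNA:
            raise ValueError(f"record {record_id!r}: non-IUPAC character "
                             f"{ch!r} at offset {off}")


def read_fasta(path: str | Path,
               topology: Mapping[str, str] | None = None) -> Genome:
    """Read a (multi-)FASTA into a :class:`Genome`.

    FASTA carries no topology, so it is supplied externally: either via the
    ``topology`` mapping (``id -> "linear"|"circular"``) or as a literal
    ``circular`` token in the record description.  Unspecified molecules
    default to linear.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: empty or not FASTA")
    topology = dict(topology or {})
    mols = []
    for rec in records:
        seq = str(rec.seq).upper()
        _validate_seq(rec.id, seq)
        topo = topology.get(rec.id)
        if topo is None:
            topo = "circular" if "circular" in rec.description.lower() else "linear"
        mols.append(Molecule(rec.id, seq, topo))
    return Genome(mols)


def write_fasta(genome: Genome, path: str | Path, width: int = 70) -> None:
    """Write a genome as FASTA, topology echoed in the description line."""
    with open(path, "w") as fh:
        for m in genome:
            fh.write(f">{m.id} {m.topology}\n")
            for i in range(0, m.length, width):
                fh.write(m.seq[i:i + width] + "\n")


def _feature_segments(feat, mol_id: str) -> list[tuple[str, int, int, str]]:
    """Convert a Biopython feature location to 1-based segments in
    transcription order."""
    parts = list(feat.location.parts)
    # Biopython lists parts of a complement(join(...)) in genomic order;
    # transcription order for a minus-strand multi-part feature is reversed.
    if len(parts) > 1 and all(p.strand == -1 for p in parts):
        if parts[0].start < parts[-1].start:
            parts = parts[::-1]
    segs = []
    for p in parts:
        strand = "-" if p.strand == -1 else "+"
        segs.append((mol_id, int(p.start) + 1, int(p.end), strand))
    return segs


_KIND_MAP = {"CDS": "CDS", "tRNA": "tRNA", "rRNA": "rRNA"}


def read_genbank(path: str | Path) -> tuple[Genome, list[GeneFeature]]:
    """Read a GenBank flat file: sequences plus CDS/tRNA/rRNA features.

    The LOCUS line's ``circular`` token sets molecule topology.  A gene
    split across molecules, or carrying a ``trans_splicing`` qualifier, is
    merged into a single :class:`GeneFeature` flagged ``trans_spliced``.
    Features without a ``gene`` qualifier are skipped with a warning.
    """
    records = list(SeqIO.parse(str(path), "genbank"))
    if not records:
        raise ValueError(f"{path}: empty or not GenBank")
    mols = []
    raw: list[tuple[str, str, list, bool]] = []  # (gene, kind, segments, ts_flag)
    for rec in records:
        topo = "circular" if rec.annotations.get("topology") == "circular" else "linear"
        seq = str(rec.seq).upper()
        _validate_seq(rec.id, seq)
        mols.append(Molecule(rec.id, seq, topo))
        for feat in rec.features:
            kind = _KIND_MAP.get(feat.type)
            if kind is None:
                continue
            gene = feat.qualifiers.get("gene", [None])[0]
            if gene is None:
                logger.warning("%s: %s feature without gene qualifier skipped "
                               "(%s)", path, feat.type, feat.location)
                continue
            ts = ("trans_splicing" in feat.qualifiers
                  or feat.qualifiers.get("exception", [""])[0] == "trans-splicing")
            raw.append((gene, kind, _feature_segments(feat, rec.id), ts))

    # Merge trans-spliced genes split over several features/records.
    features: list[GeneFeature] = []
    merged: dict[tuple[str, str], GeneFeature] = {}
    for gene, kind, segs, ts in raw:
        key = (gene, kind)
        if ts and key in merged:
            f = merged[key]
            f.segments.extend(segs)
            f.trans_spliced = True
            continue
        f = GeneFeature(gene, kind, segs, trans_spliced=ts)
        features.append(f)
        if ts:
            merged[key] = f
    # A gene whose segments span >1 molecule is trans-spliced by definition.
    for f in features:
        if len({s[0] for s in f.segments}) > 1:
            f.trans_spliced = True
    return Genome(mols), features


# ---------------------------------------------------------------------------
# Statistics and CDS extraction
# ---------------------------------------------------------------------------

def genome_stats(genome: Genome) -> pd.DataFrame:
    """Per-molecule and total length / GC% table.

    GC% excludes ambiguous bases from the denominator; a molecule of all-N
    reports NaN rather than 0.  The ``total`` row is length-weighted (it is
    the GC of the concatenated sequence).
    """
    if len(genome) == 0:
        raise ValueError("empty genome")
    rows = []
    for m in genome:
        gc = gc_fraction(m.seq)
        rows.append({"molecule": m.id, "topology": m.topology,
                     "length_bp": m.length,
                     "gc_pct": float("nan") if gc is None else 100 * gc})
    gc_tot = genome.gc_total
    rows.append({"molecule": "total", "topology": "-",
                 "length_bp": genome.total_length,
                 "gc_pct": float("nan") if gc_tot is None else 100 * gc_tot})
    return pd.DataFrame(rows)


def extract_cds(genome: Genome,
                features: Iterable[GeneFeature]) -> list[tuple[str, str]]:
    """Extract coding sequences, concatenating exons in annotation order.

    Minus-strand segments are reverse complemented individually; segments on
    different molecules (trans-splicing) concatenate the same way.  A CDS
    whose length is not a multiple of 3 is truncated to a whole number of
    codons with a warning.
    """
    out = []
    for f in features:
        if f.kind != "CDS":
            continue
        parts = []
        for mol_id, start, end, strand in f.segments:
            mol = genome[mol_id]
            if not mol.circular and end > mol.length:
                raise IndexError(f"gene {f.gene_name}: segment {start}..{end} "
                                 f"outside linear molecule {mol_id}")
            parts.append(mol.fetch(start, end, strand))
        cds = "".join(parts)
        if len(cds) % 3:
            logger.warning("CDS %s length %d not divisible by 3; trailing "
                           "%d base(s) dropped", f.gene_name, len(cds), len(cds) % 3)
            cds = cds[:len(cds) - len(cds) % 3]
        out.append((f.gene_name, cds))
    return out


def format_interval(start: int, end: int, length: int, strand: str = "+") -> str:
    """Render an interval in display style.

    Minus strand prints descending (``35,975–25,398``); an origin-wrapping
    interval on a circular molecule prints as segments
    (``34,939–36,490;1–127``).
    """
    def fmt(a: int, b: int) -> str:
        return f"{a:,}–{b:,}"

    if end > length:  # wraps the origin
        seg1, seg2 = (start, length), (1, end - length)
        if strand == "-":
            return f"{fmt(seg2[1], seg2[0])};{fmt(seg1[1], seg1[0])}"
        return f"{fmt(*seg1)};{fmt(*seg2)}"
    if strand == "-":
        return fmt(end, start)
    return fmt(start, end)
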