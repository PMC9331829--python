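"""Synthetic multi-molecule genomes, long reads, and chloroplast partners
with exact ground truth.

The generator emulates the data a plant-mitogenome structural analysis
consumes: a branched genome (one linear and two circular molecules by
default), planted microsatellites, tandem repeats and dispersed repeat
pairs (including a ≥1 kb "recombinationally active" pair), Nanopore-like
long reads drawn from a mixture of the primary and flank-exchanged
alternative conformations at a chosen proportion, and a circular
chloroplast genome sharing planted homologous fragments at stated
identities (optionally duplicated to mimic the chloroplast inverted
repeat).

Every planted element is recorded in a :class:`Truth` registry with exact
coordinates and, for reads, a per-read source label, so each detector can
be validated round-trip.  All outputs are pure functions of the
configuration: one seeded generator per operation, no global state.

Planted elements are *boundary-hardened*: the bases immediately flanking a
planted repeat occurrence or SSR run are forced to break the repeat, so
the element is maximal by construction and its truth coordinates are what
an exact scanner must report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np

from .genome_io import GeneFeature, Genome, Molecule, revcomp
from .recomb import build_conformations
from .repeat_scan import DispersedRepeat, _canonical_rotation, _min_period

logger = logging.getLogger("mitostruct")

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = {65: 0, 67: 1, 71: 2, 84: 3}


def _decode(arr: np.ndarray) -> str:
    return _BASES[arr].tobytes().decode()


def _encode(seq: str) -> np.ndarray:
    raw = np.frombuffer(seq.encode(), dtype=np.uint8)
    out = np.empty(len(raw), dtype=np.uint8)
    for byte, code in _CODE.items():
        out[raw == byte] = code
    return out


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class ReadModel:
    """Nanopore-like read model: gamma-distributed lengths (shape 2, mean
    anchored at the ~10 kb N50 scale of field data), i.i.d. per-base
    substitution and length-1-geometric indel errors."""
    n_reads: int = 500
    mean_length: float = 9816.0
    shape: float = 2.0
    min_length: int = 500
    sub_rate: float = 0.05
    ins_rate: float = 0.025
    del_rate: float = 0.025

    def __post_init__(self):
        for r in (self.sub_rate, self.ins_rate, self.del_rate):
            if not 0 <= r <= 0.2:
                raise ValueError(f"error rate {r} outside [0, 0.2]")


@dataclass
class PlantedSSR:
    motif: str
    copies: int
    molecule: int = 0       # index into cfg.molecules
    pos: int | None = None  # 0-based start; None = auto-place


@dataclass
class PlantedTandem:
    unit: str
    copies: int
    molecule: int = 0
    pos: int | None = None
    mismatches: int = 0


@dataclass
class PlantedRepeatPair:
    length: int
    kind: str = "direct"            # direct | palindromic
    molecule1: int = 0
    pos1: int | None = None
    molecule2: int = 0
    pos2: int | None = None
    recomb_freq: float = 0.0        # mixture proportion p of the alternative

    def __post_init__(self):
        if self.kind not in ("direct", "palindromic"):
            raise ValueError(f"bad repeat kind {self.kind!r}")
        if not 0 <= self.recomb_freq <= 1:
            raise ValueError("recomb_freq outside [0, 1]")


@dataclass
class PlantedTransfer:
    length: int
    identity: float = 1.0
    mt_molecule: int = 0
    mt_pos: int | None = None
    cp_pos: int | None = None
    ir_duplicate: bool = False      # also plant the reverse complement elsewhere


@dataclass
class SimConfig:
    seed: int = 0
    molecules: list[tuple[int, str]] = field(default_factory=lambda: [
        (60_000, "linear"), (40_000, "circular"), (15_000, "circular")])
    gc: float = 0.4572
    planted_ssrs: list[PlantedSSR] = field(default_factory=list)
    planted_tandems: list[PlantedTandem] = field(default_factory=list)
    planted_repeat_pairs: list[PlantedRepeatPair] = field(default_factory=list)
    read_model: ReadModel = field(default_factory=ReadModel)
    mtpt_plants: list[PlantedTransfer] = field(default_factory=list)
    plant_margin: int = 150         # clear space demanded around each plant


def default_config(seed: int = 0) -> SimConfig:
    """Study-scale default: a 115 kb three-molecule genome at mitogenome-like
    GC, with SSR/tandem tracks, one long recombinationally active repeat
    pair (p ≈ 0.45, the scale reported for active mitogenome repeats), one
    silent mid-size pair, one palindromic pair, and three chloroplast
    transfer fragments including an IR-duplicated one."""
    return SimConfig(
        seed=seed,
        planted_ssrs=[
            PlantedSSR("T", 12, molecule=0),
            PlantedSSR("AT", 8, molecule=0),
            PlantedSSR("TA", 7, molecule=1),
            PlantedSSR("AAG", 6, molecule=1),
            PlantedSSR("A", 11, molecule=2),
        ],
        planted_tandems=[
            PlantedTandem("ACGTGATTCGAAGCT", 4, molecule=0, mismatches=1),
            PlantedTandem("GATTACAGGCATCCAGT", 3, molecule=1),
        ],
        planted_repeat_pairs=[
            PlantedRepeatPair(1500, "direct", molecule1=0, molecule2=1,
                              recomb_freq=0.45),
            PlantedRepeatPair(300, "direct", molecule1=0, molecule2=0,
                              recomb_freq=0.0),
            PlantedRepeatPair(120, "palindromic", molecule1=1, molecule2=2),
        ],
        mtpt_plants=[
            PlantedTransfer(1200, identity=0.99, mt_molecule=0,
                            ir_duplicate=True),
            PlantedTransfer(300, identity=1.0, mt_molecule=1),
            PlantedTransfer(150, identity=0.92, mt_molecule=2),
        ],
    )


@dataclass
class Truth:
    """Registry of every planted element and per-read source label."""
    ssrs: list[dict] = field(default_factory=list)
    tandems: list[dict] = field(default_factory=list)
    repeat_pairs: list[DispersedRepeat] = field(default_factory=list)
    recomb_freqs: dict = field(default_factory=dict)
    reads: list[dict] = field(default_factory=list)
    transfers: list[dict] = field(default_factory=list)
    cp_gene_expect: list[dict] = field(default_factory=list)

    def n_reads_labeled(self, label: str) -> int:
        return sum(1 for r in self.reads if r["label"] == label)

    def to_json(self, path) -> None:
        payload = {
            "ssrs": self.ssrs, "tandems": self.tandems,
            "repeat_pairs": [asdict(r) for r in self.repeat_pairs],
            "recomb_freqs": self.recomb_freqs, "reads": self.reads,
            "transfers": self.transfers, "cp_gene_expect": self.cp_gene_expect,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


# ---------------------------------------------------------------------------
# Genome simulation
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=n, p=p).astype(np.uint8)


class _Placer:
    """Non-overlapping interval bookkeeping per molecule."""

    def __init__(self, lengths: list[int], margin: int):
        self.lengths = lengths
        self.margin = margin
        self.occupied: list[list[tuple[int, int]]] = [[] for _ in lengths]

    def _free(self, mol: int, start: int, length: int) -> bool:
        a, b = start - self.margin, start + length + self.margin
        if a < 0 or b > self.lengths[mol]:
            return False
        return all(e <= a or s >= b for s, e in self.occupied[mol])

    def place(self, rng, mol: int, length: int, pos: int | None) -> int:
        if pos is not None:
            if not self._free(mol, pos, length):
                raise ValueError(f"planted element at molecule {mol} pos {pos} "
                                 f"(len {length}) overlaps another plant or "
                                 "the molecule boundary")
            self.occupied[mol].append((pos, pos + length))
            return pos
        for _ in range(2000):
            cand = int(rng.integers(self.margin,
                                    self.lengths[mol] - length - self.margin))
            if self._free(mol, cand, length):
                self.occupied[mol].append((cand, cand + length))
                return cand
        raise ValueError(f"could not auto-place element of length {length} "
                         f"on molecule {mol}")


def _harden_boundary(seqs: list[np.ndarray], mol: int, pos: int, end: int,
                     forbidden_left: set[int], forbidden_right: set[int],
                     rng) -> None:
    """Force the bases just outside [pos, end) to avoid the given codes."""
    if pos - 1 >= 0:
        choices = [b for b in range(4) if b not in forbidden_left]
        seqs[mol][pos - 1] = choices[int(rng.integers(len(choices)))]
    if end < len(seqs[mol]):
        choices = [b for b in range(4) if b not in forbidden_right]
        seqs[mol][end] = choices[int(rng.integers(len(choices)))]


def simulate_genome(cfg: SimConfig) -> tuple[Genome, Truth]:
    """Generate a genome with all configured plants; reproducible per seed.

    Overlapping plants raise before emission.  Background composition
    follows ``cfg.gc``; planted elements sit verbatim at their registered
    coordinates (1-based in the Truth registry).
    """
    rng = np.random.default_rng(cfg.seed)
    lengths = [L for L, _ in cfg.molecules]
    seqs = [_random_seq(rng, L, cfg.gc) for L in lengths]
    mol_ids = [f"mol{i + 1}" for i in range(len(lengths))]
    placer = _Placer(lengths, cfg.plant_margin)
    truth = Truth()

    for p in cfg.planted_ssrs:
        u = len(p.motif)
        if not (1 <= u <= 6):
            raise ValueError(f"SSR motif {p.motif!r} outside 1-6 bp")
        if _min_period(p.motif) != u:
            raise ValueError(f"SSR motif {p.motif!r} is not primitive")
        length = u * p.copies
        pos = placer.place(rng, p.molecule, length, p.pos)
        planted = _encode(p.motif * p.copies)
        seqs[p.molecule][pos:pos + length] = planted
        # break period-u continuation on both sides
        _harden_boundary(seqs, p.molecule, pos, pos + length,
                         {int(planted[u - 1])}, {int(planted[length - u])}, rng)
        truth.ssrs.append({"molecule": mol_ids[p.molecule],
                           "motif": _canonical_rotation(p.motif),
                           "unit_length": u, "copies": p.copies,
                           "start": pos + 1, "end": pos + length})

    for t in cfg.planted_tandems:
        u = len(t.unit)
        length = u * t.copies
        pos = placer.place(rng, t.molecule, length, t.pos)
        arr = _encode(t.unit * t.copies)
        if t.mismatches:
            # substitutions placed in interior copies, deterministically
            sites = rng.choice(np.arange(u, length - u), size=t.mismatches,
                               replace=False)
            for s in sites:
                arr[s] = (arr[s] + 1 + rng.integers(3)) % 4
        seqs[t.molecule][pos:pos + length] = arr
        _harden_boundary(seqs, t.molecule, pos, pos + length,
                         {int(arr[u - 1])}, {int(arr[length - u])}, rng)
        truth.tandems.append({"molecule": mol_ids[t.molecule],
                              "unit_length": u, "copies": t.copies,
                              "start": pos + 1, "end": pos + length,
                              "mismatches": t.mismatches})

    for i, rp in enumerate(cfg.planted_repeat_pairs):
        unit = _random_seq(rng, rp.length, cfg.gc)
        pos1 = placer.place(rng, rp.molecule1, rp.length, rp.pos1)
        pos2 = placer.place(rng, rp.molecule2, rp.length, rp.pos2)
        seqs[rp.molecule1][pos1:pos1 + rp.length] = unit
        if rp.kind == "direct":
            copy2 = unit
        else:
            copy2 = _encode(revcomp(_decode(unit)))
        seqs[rp.molecule2][pos2:pos2 + rp.length] = copy2
        # maximality: flanking bases must differ between the two occurrences
        # (in repeat orientation).  Assign distinct bases explicitly.
        lef1, rig1 = int(rng.integers(4)), int(rng.integers(4))
        lef2, rig2 = (lef1 + 1 + int(rng.integers(3))) % 4, \
                     (rig1 + 1 + int(rng.integers(3))) % 4
        s1, s2 = seqs[rp.molecule1], seqs[rp.molecule2]
        if pos1 > 0:
            s1[pos1 - 1] = lef1
        if pos1 + rp.length < len(s1):
            s1[pos1 + rp.length] = rig1
        if rp.kind == "direct":
            if pos2 > 0:
                s2[pos2 - 1] = lef2
            if pos2 + rp.length < len(s2):
                s2[pos2 + rp.length] = rig2
        else:
            # oriented left flank of occ2 is the complement after its end
            if pos2 + rp.length < len(s2):
                s2[pos2 + rp.length] = 3 - lef2
            if pos2 > 0:
                s2[pos2 - 1] = 3 - rig2
        occ1 = (mol_ids[rp.molecule1], pos1 + 1, pos1 + rp.length, "+")
        st2 = "+" if rp.kind == "direct" else "-"
        occ2 = (mol_ids[rp.molecule2], pos2 + 1, pos2 + rp.length, st2)
        key1 = (rp.molecule1, pos1)
        key2 = (rp.molecule2, pos2)
        if key2 < key1:
            occ1, occ2 = (occ2[0], occ2[1], occ2[2], "+"), \
                         (occ1[0], occ1[1], occ1[2], st2)
        rep = DispersedRepeat(f"P{i + 1}", rp.kind, rp.length, occ1, occ2)
        truth.repeat_pairs.append(rep)
        truth.recomb_freqs[rep.repeat_id] = rp.recomb_freq

    genome = Genome([Molecule(mid, _decode(s), topo)
                     for mid, s, (_, topo) in zip(mol_ids, seqs, cfg.molecules)])
    for rep in truth.repeat_pairs:
        assert rep.verify(genome), f"planted pair {rep.repeat_id} corrupted"
    return genome, truth


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

def _apply_errors(arr: np.ndarray, rng: np.random.Generator,
                  model: ReadModel) -> np.ndarray:
    keep = rng.random(arr.size) >= model.del_rate
    bases = arr[keep].copy()
    n = bases.size
    if n == 0:
        return bases
    do_sub = rng.random(n) < model.sub_rate
    bases[do_sub] = (bases[do_sub] + rng.integers(1, 4, int(do_sub.sum()))) % 4
    if model.ins_rate > 0:
        nins = rng.geometric(1 - model.ins_rate, n) - 1
        total = int(nins.sum())
        if total:
            out = np.empty(n + total, dtype=np.uint8)
            out[:] = 0
            idx = np.arange(n) + np.concatenate(([0], np.cumsum(nins[:-1])))
            mask = np.ones(n + total, dtype=bool)
            mask[idx] = False
            out[idx] = bases
            out[mask] = rng.integers(0, 4, total, dtype=np.uint8)
            return out
    return bases


def _draw_length(rng, model: ReadModel) -> int:
    ln = int(rng.gamma(model.shape, model.mean_length / model.shape))
    return max(model.min_length, ln)


def simulate_reads(genome: Genome, rep: DispersedRepeat, p: float,
                   model: ReadModel | None = None, seed: int = 0,
                   spanning_only: bool = False,
                   flank_len: int | None = None,
                   span_margin: int = 150) -> tuple[list[tuple[str, str]], Truth]:
    """Draw long reads from a conformation mixture.

    Each read comes from the primary genome with probability ``1 − p`` and
    from the flank-exchanged alternative references otherwise.  With
    ``spanning_only=True`` both sources are the conformation references and
    start positions are restricted so every read covers the repeat unit
    plus ``span_margin`` bp of flank on both sides — the geometry is then
    symmetric across conformations and ``p`` is directly recoverable from
    spanning-read counts.  Read orientation is random; errors follow the
    model; truth labels are recorded per read.
    """
    if not 0 <= p <= 1:
        raise ValueError(f"p={p} outside [0, 1]")
    model = model or ReadModel()
    rng = np.random.default_rng(seed)
    if flank_len is None:
        flank_len = max(1000, int(model.mean_length))
    conf = build_conformations(genome, rep, flank_len)
    primary_refs = [(f"{rep.repeat_id}_primary{i + 1}", s, sp)
                    for i, (s, sp) in enumerate(conf.refs_primary)]
    alt_refs = [(f"{rep.repeat_id}_alt{i + 1}", s, sp)
                for i, (s, sp) in enumerate(conf.refs_alternative)]
    mol_lens = np.array([m.length for m in genome], dtype=float)
    mol_probs = mol_lens / mol_lens.sum()
    total_len = genome.total_length
    alt_len = sum(len(s) for _, s, _ in alt_refs)
    # genomic territory of the primary references: in a recombined genome
    # these neighbourhoods exist only in their exchanged arrangement
    primary_windows: dict[str, list[tuple[int, int]]] = {}
    for occ in (rep.occ1, rep.occ2):
        mol_id, s, e, _ = occ
        primary_windows.setdefault(mol_id, []).append(
            (max(1, s - flank_len), e + flank_len))

    def draw_from_genome(exclude_windows: bool) -> tuple[str, int, str]:
        for _ in range(100):
            mi = int(rng.choice(len(genome.molecules), p=mol_probs))
            mol = genome.molecules[mi]
            start = int(rng.integers(0, mol.length))
            if exclude_windows and any(
                    a - 1 <= start <= b for a, b in
                    primary_windows.get(mol.id, ())):
                continue
            return mol.id, start, mol.seq
        return mol.id, start, mol.seq  # windows cover the molecule: give up

    reads: list[tuple[str, str]] = []
    truth = Truth()
    truth.recomb_freqs[rep.repeat_id] = p
    for i in range(model.n_reads):
        alt = bool(rng.random() < p)
        label = "alternative" if alt else "primary"
        length = _draw_length(rng, model)
        in_refs = spanning_only or (alt and rng.random() < alt_len / total_len)
        if in_refs:
            name_src, refseq, (us, ue) = (alt_refs if alt else primary_refs)[
                int(rng.integers(2))]
            lo = max(0, us - 1 - span_margin)
            hi = ue + span_margin
            if spanning_only:
                need = hi - lo
                length = max(length, need + 100)
                a_min = max(0, hi - length)
                a_max = min(lo, len(refseq) - length)
                if a_max < a_min:
                    a_min, a_max = 0, max(0, len(refseq) - length)
                start = int(rng.integers(a_min, a_max + 1))
            else:
                start = int(rng.integers(0, max(1, len(refseq) - model.min_length)))
            src, spos = name_src, start
            frag = refseq[start:start + length]
        else:
            # a recombined genome is byte-identical to the primary one
            # outside the exchanged-flank neighbourhood, so off-target
            # alternative reads are drawn from the primary sequence
            # (excluding the primary-arrangement neighbourhood itself)
            src, spos, seq = draw_from_genome(exclude_windows=alt)
            mol = genome[src]
            end = spos + length
            if mol.circular:
                frag = (seq[spos:] + seq)[:length] if end > mol.length \
                    else seq[spos:end]
            else:
                frag = seq[spos:min(end, mol.length)]
        arr = _apply_errors(_encode(frag), rng, model)
        seq = _decode(arr)
        strand = "+"
        if rng.random() < 0.5:
            seq = revcomp(seq)
            strand = "-"
        name = f"read{i + 1:05d}"
        reads.append((name, seq))
        truth.reads.append({"name": name, "label": label, "source": src,
                            "start": spos, "strand": strand,
                            "length": len(seq)})
    return reads, truth


# ---------------------------------------------------------------------------
# Chloroplast partner with planted transfers
# ---------------------------------------------------------------------------

def simulate_cp_with_transfers(mt: Genome, plants: list[PlantedTransfer],
                               seed: int = 0, cp_length: int = 30_000,
                               gc: float = 0.37,
                               ) -> tuple[Genome, list[GeneFeature], Truth]:
    """Build a circular chloroplast genome carrying fragments copied from
    the mitogenome at stated identities.

    Identity is realised with substitutions placed deterministically from
    the seed.  ``ir_duplicate`` additionally plants the reverse complement
    of the fragment at a second locus, mimicking the chloroplast inverted
    repeat.  Synthetic gene features are emitted per fragment — one fully
    inside (expected complete) and one straddling its edge (expected
    partial) — so transfer classification is testable.
    """
    rng = np.random.default_rng(seed)
    cp_arr = _random_seq(rng, cp_length, gc)
    placer = _Placer([cp_length], margin=60)
    truth = Truth()
    features: list[GeneFeature] = []
    for i, pl in enumerate(plants):
        if pl.identity < 0.7:
            logger.warning("transfer %d identity %.2f below seeding "
                           "sensitivity", i + 1, pl.identity)
        mol = mt.molecules[pl.mt_molecule]
        if pl.mt_pos is None:
            mt_pos = int(rng.integers(0, mol.length - pl.length))
        else:
            mt_pos = pl.mt_pos
        frag = _encode(mol.seq[mt_pos:mt_pos + pl.length])
        n_sub = round((1 - pl.identity) * pl.length)
        if n_sub:
            sites = rng.choice(pl.length, size=n_sub, replace=False)
            frag = frag.copy()
            frag[sites] = (frag[sites] + rng.integers(1, 4, n_sub)) % 4
        loci = [(placer.place(rng, 0, pl.length, pl.cp_pos), False)]
        if pl.ir_duplicate:
            loci.append((placer.place(rng, 0, pl.length, None), True))
        for cp_pos, is_rc in loci:
            ins = _encode(revcomp(_decode(frag))) if is_rc else frag
            cp_arr[cp_pos:cp_pos + pl.length] = ins
            truth.transfers.append({
                "fragment": len(truth.transfers) + 1,
                "mt_molecule": mol.id, "mt_start": mt_pos + 1,
                "mt_end": mt_pos + pl.length, "cp_start": cp_pos + 1,
                "cp_end": cp_pos + pl.length, "length": pl.length,
                "identity": pl.identity, "strand": "-" if is_rc else "+",
            })
            gin_s = cp_pos + pl.length // 4 + 1
            gin_e = cp_pos + pl.length // 2
            features.append(GeneFeature(f"g{len(truth.transfers)}_in", "tRNA",
                                        [("cp", gin_s, gin_e, "+")]))
            truth.cp_gene_expect.append({"gene": f"g{len(truth.transfers)}_in",
                                         "fragment": len(truth.transfers),
                                         "expected": "complete"})
            gp_s = cp_pos + 3 * pl.length // 4 + 1
            gp_e = min(cp_pos + pl.length + 40, cp_length)
            features.append(GeneFeature(f"g{len(truth.transfers)}_part", "rRNA",
                                        [("cp", gp_s, gp_e, "+")]))
            truth.cp_gene_expect.append({"gene": f"g{len(truth.transfers)}_part",
                                         "fragment": len(truth.transfers),
                                         "expected": "partial"})
    # boundary hardening: force the first three bases outside each planted
    # locus to mismatch the corresponding mitochondrial continuation, so an
    # X-drop extension cannot profitably run past the planted fragment
    for tr in truth.transfers:
        mt_seq = mt[tr["mt_molecule"]].seq
        s0, e0 = tr["cp_start"] - 1, tr["cp_end"]
        ms, me = tr["mt_start"] - 1, tr["mt_end"]
        for off in range(3):
            if tr["strand"] == "+":
                if s0 - 1 - off >= 0 and ms - 1 - off >= 0:
                    cp_arr[s0 - 1 - off] = (_CODE[ord(mt_seq[ms - 1 - off])] + 1) % 4
                if e0 + off < cp_length and me + off < len(mt_seq):
                    cp_arr[e0 + off] = (_CODE[ord(mt_seq[me + off])] + 1) % 4
            else:
                if s0 - 1 - off >= 0 and me + off < len(mt_seq):
                    cp_arr[s0 - 1 - off] = (3 - _CODE[ord(mt_seq[me + off])] + 1) % 4
                if e0 + off < cp_length and ms - 1 - off >= 0:
                    cp_arr[e0 + off] = (3 - _CODE[ord(mt_seq[ms - 1 - off])] + 1) % 4
    cp = Genome([Molecule("cp", _decode(cp_arr), "circular")])
    return cp, features, truth


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_fastq(reads: list[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")
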