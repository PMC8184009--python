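"""Genome/annotation input and genome<->mRNA coordinate arithmetic.

All internal coordinates are 0-based, half-open. GTF input (1-based,
inclusive) is converted at the boundary. A splice junction is stored as
its intron interval ``[start, end)``: ``start`` is the first intronic
base and ``end`` is one past the last intronic base. "Donor" (5' splice
site) and "acceptor" (3' splice site) always refer to transcriptional
orientation, so on the minus strand the donor boundary is ``end`` and
the acceptor boundary is ``start``.
"""

from __future__ import annotations

import warnings
from bisect import bisect_right
from dataclasses import dataclass, field

from pyfaidx import Fasta

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID = set("ACGTN")
# IUPAC ambiguity codes other than N; mapped to N with a warning at load.
_AMBIG = set("RYSWKMBDHV")


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGTN string."""
    return seq.translate(COMPLEMENT)[::-1]


class GenomeSequence:
    """Indexed multi-record genome with strand-aware slicing.

    Wraps a pyfaidx index; sequences are uppercased and IUPAC ambiguity
    codes other than N are mapped to N (with one warning per load).
    """

    def __init__(self, fasta: Fasta):
        self._fasta = fasta
        self.chrom_names = list(fasta.keys())
        self._warned_ambiguous = False

    def chrom_length(self, chrom: str) -> int:
        return len(self._fasta[chrom])

    def fetch(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        """Sequence of ``[start, end)`` on ``chrom``; minus strand returns
        the reverse complement."""
        if chrom not in self._fasta:
            raise KeyError(f"unknown chromosome {chrom!r}")
        if start < 0 or end > self.chrom_length(chrom) or start > end:
            raise ValueError(
                f"slice [{start}, {end}) out of bounds for {chrom} "
                f"(length {self.chrom_length(chrom)})"
            )
        seq = str(self._fasta[chrom][start:end]).upper()
        if not set(seq) <= _VALID:
            bad = set(seq) - _VALID
            if not bad <= _AMBIG:
                raise ValueError(f"non-nucleotide symbols in {chrom}: {sorted(bad - _AMBIG)}")
            if not self._warned_ambiguous:
                warnings.warn(
                    f"IUPAC ambiguity codes {sorted(bad)} mapped to N", stacklevel=2
                )
                self._warned_ambiguous = True
            seq = "".join(c if c in _VALID else "N" for c in seq)
        return revcomp(seq) if strand == "-" else seq


def load_genome(path: str) -> GenomeSequence:
    """Open and index a (multi-)FASTA genome.

    Duplicate record names raise; lowercase sequence is uppercased on
    access.
    """
    fasta = Fasta(str(path), sequence_always_upper=True, duplicate_action="stop")
    return GenomeSequence(fasta)


@dataclass(frozen=True)
class TranscriptModel:
    """One transcript: ordered exons plus an optional CDS.

    ``exons`` are genomic 0-based half-open intervals sorted 5'->3' in
    transcript orientation (i.e. descending genomic coordinate on the
    minus strand). ``cds`` follows the same convention and must be
    contained in the exons.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds: tuple[tuple[int, int], ...] = ()

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript without exons")
        genomic = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(genomic, genomic[1:]):
            if e1 > s2:
                raise ValueError(f"{self.transcript_id}: overlapping exons")
        want = tuple(genomic) if self.strand == "+" else tuple(genomic[::-1])
        if self.exons != want:
            object.__setattr__(self, "exons", want)
        if self.cds:
            cds = tuple(sorted(self.cds)) if self.strand == "+" else tuple(sorted(self.cds)[::-1])
            object.__setattr__(self, "cds", cds)

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def exons_genomic(self) -> list[tuple[int, int]]:
        """Exons in ascending genomic order regardless of strand."""
        return sorted(self.exons)

    def introns(self) -> list[tuple[int, int]]:
        """Intron intervals in ascending genomic order."""
        g = self.exons_genomic
        return [(g[i][1], g[i + 1][0]) for i in range(len(g) - 1)]

    def junction_keys(self) -> list[tuple[str, str, int, int]]:
        """(chrom, strand, intron_start, intron_end) for each intron."""
        return [(self.chrom, self.strand, s, e) for s, e in self.introns()]


def transcript_sequence(t: TranscriptModel, g: GenomeSequence) -> str:
    """Mature mRNA sequence (sense orientation).

    Plus strand: concatenation of exon slices; minus strand: reverse
    complement of the concatenation, exon order reversed.
    """
    parts = [g.fetch(t.chrom, s, e, "+") for s, e in t.exons_genomic]
    seq = "".join(parts)
    return revcomp(seq) if t.strand == "-" else seq


class NotExonicError(ValueError):
    """A genomic position queried for an mRNA coordinate is not exonic."""


def _exon_offsets(t: TranscriptModel) -> list[int]:
    offs, acc = [], 0
    for s, e in t.exons:
        offs.append(acc)
        acc += e - s
    return offs


def genome_to_mrna(t: TranscriptModel, gpos: int) -> int:
    """mRNA coordinate (0-based) of exonic genomic position ``gpos``."""
    offs = _exon_offsets(t)
    for (s, e), off in zip(t.exons, offs):
        if s <= gpos < e:
            return off + (gpos - s) if t.strand == "+" else off + (e - 1 - gpos)
    raise NotExonicError(f"{t.transcript_id}: position {gpos} is not exonic")


def mrna_to_genome(t: TranscriptModel, mpos: int) -> int:
    """Genomic position of mRNA coordinate ``mpos`` (inverse of
    :func:`genome_to_mrna`)."""
    if not 0 <= mpos < t.length:
        raise NotExonicError(f"{t.transcript_id}: mRNA coordinate {mpos} out of range")
    acc = 0
    for s, e in t.exons:
        if mpos < acc + (e - s):
            k = mpos - acc
            return s + k if t.strand == "+" else e - 1 - k
        acc += e - s
    raise AssertionError("unreachable")


def extract_window(
    g: GenomeSequence, chrom: str, strand: str, anchor: int, up: int, down: int
) -> tuple[str, bool]:
    """Sense-orientation window around a boundary ``anchor``.

    ``up`` bases upstream (5' in transcript orientation) and ``down``
    bases downstream of the boundary coordinate. Returns
    ``(sequence, clipped)``; ``clipped`` is True when the window was
    shortened at a chromosome edge.
    """
    n = g.chrom_length(chrom)
    if not 0 <= anchor <= n:
        raise ValueError(f"anchor {anchor} outside {chrom}")
    if strand == "+":
        lo, hi = anchor - up, anchor + down
    else:
        lo, hi = anchor - down, anchor + up
    clo, chi = max(lo, 0), min(hi, n)
    return g.fetch(chrom, clo, chi, strand), (clo != lo or chi != hi)


@dataclass
class GenomeAnnotation:
    """Transcript collection with splice-site and interval indexes.

    ``annotated_donors`` / ``annotated_acceptors`` hold strand-aware
    boundary coordinates ``(chrom, strand, pos)``; ``annotated_junctions``
    holds intron intervals ``(chrom, strand, start, end)``.
    """

    transcripts: dict[str, TranscriptModel]
    annotated_donors: set[tuple[str, str, int]] = field(default_factory=set)
    annotated_acceptors: set[tuple[str, str, int]] = field(default_factory=set)
    annotated_junctions: set[tuple[str, str, int, int]] = field(default_factory=set)
    _exon_index: dict[tuple[str, str], tuple[list[int], list[int]]] = field(default_factory=dict)
    _intron_index: dict[tuple[str, str], tuple[list[int], list[int]]] = field(default_factory=dict)
    _donor_transcripts: dict[tuple[str, str, int], list[str]] = field(default_factory=dict)
    _acceptor_transcripts: dict[tuple[str, str, int], list[str]] = field(default_factory=dict)

    @classmethod
    def from_transcripts(cls, transcripts: list[TranscriptModel]) -> "GenomeAnnotation":
        ann = cls(transcripts={t.transcript_id: t for t in transcripts})
        exon_iv: dict[tuple[str, str], list[tuple[int, int]]] = {}
        intron_iv: dict[tuple[str, str], list[tuple[int, int]]] = {}
        for t in transcripts:
            for s, e in t.exons_genomic:
                exon_iv.setdefault((t.chrom, t.strand), []).append((s, e))
            for s, e in t.introns():
                intron_iv.setdefault((t.chrom, t.strand), []).append((s, e))
                key = (t.chrom, t.strand, s, e)
                ann.annotated_junctions.add(key)
                donor = e if t.strand == "-" else s
                acceptor = s if t.strand == "-" else e
                ann.annotated_donors.add((t.chrom, t.strand, donor))
                ann.annotated_acceptors.add((t.chrom, t.strand, acceptor))
                ann._donor_transcripts.setdefault(
                    (t.chrom, t.strand, donor), []).append(t.transcript_id)
                ann._acceptor_transcripts.setdefault(
                    (t.chrom, t.strand, acceptor), []).append(t.transcript_id)
        ann._exon_index = {k: _merge_index(v) for k, v in exon_iv.items()}
        ann._intron_index = {k: _merge_index(v) for k, v in intron_iv.items()}
        return ann

    # Point queries return the union over all transcripts.
    def is_exonic(self, chrom: str, strand: str, pos: int) -> bool:
        return _point_in(self._exon_index.get((chrom, strand)), pos)

    def is_intronic(self, chrom: str, strand: str, pos: int) -> bool:
        return _point_in(self._intron_index.get((chrom, strand)), pos)

    def transcripts_with_donor(self, chrom: str, strand: str, pos: int) -> list[str]:
        return self._donor_transcripts.get((chrom, strand, pos), [])

    def transcripts_with_acceptor(self, chrom: str, strand: str, pos: int) -> list[str]:
        return self._acceptor_transcripts.get((chrom, strand, pos), [])


def _merge_index(intervals: list[tuple[int, int]]) -> tuple[list[int], list[int]]:
    """Merge intervals; return parallel (starts, ends) for bisection."""
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [m[0] for m in merged], [m[1] for m in merged]


def _point_in(index: tuple[list[int], list[int]] | None, pos: int) -> bool:
    if index is None:
        return False
    starts, ends = index
    i = bisect_right(starts, pos) - 1
    return i >= 0 and pos < ends[i]


def _parse_gtf_attributes(attr: str) -> dict[str, str]:
    out = {}
    for part in attr.strip().rstrip(";").split(";"):
        part = part.strip()
        if not part:
            continue
        key, _, val = part.partition(" ")
        out[key] = val.strip().strip('"')
    return out


def load_annotation(path: str, genome: GenomeSequence | None = None) -> GenomeAnnotation:
    """Build a :class:`GenomeAnnotation` from an Ensembl-dialect GTF.

    Only ``exon`` and ``CDS`` feature lines are used; 1-based inclusive
    coordinates are converted to 0-based half-open. Transcripts on
    chromosomes absent from ``genome`` (when given) raise an error
    listing them; exons beyond chromosome bounds likewise.
    """
    exons: dict[str, list[tuple[int, int]]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str, str]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] not in ("exon", "CDS"):
                continue
            chrom, _, feat, start, end, _, strand = f[0], f[1], f[2], f[3], f[4], f[5], f[6]
            attrs = _parse_gtf_attributes(f[8])
            tid = attrs.get("transcript_id")
            gid = attrs.get("gene_id", tid)
            if tid is None:
                raise ValueError(f"GTF line lacks transcript_id: {line[:80]}")
            iv = (int(start) - 1, int(end))
            meta.setdefault(tid, (gid, chrom, strand))
            (exons if feat == "exon" else cds).setdefault(tid, []).append(iv)

    bad_chroms: dict[str, list[str]] = {}
    transcripts = []
    for tid, (gid, chrom, strand) in meta.items():
        if genome is not None:
            if chrom not in genome.chrom_names:
                bad_chroms.setdefault(chrom, []).append(tid)
                continue
            n = genome.chrom_length(chrom)
            for s, e in exons.get(tid, []):
                if s < 0 or e > n:
                    raise ValueError(f"{tid}: exon [{s},{e}) outside {chrom} bounds")
        transcripts.append(
            TranscriptModel(
                transcript_id=tid, gene_id=gid, chrom=chrom, strand=strand,
                exons=tuple(sorted(exons.get(tid, []))),
                cds=tuple(sorted(cds.get(tid, []))),
            )
        )
    if bad_chroms:
        raise ValueError(
            "transcripts on chromosomes absent from genome: "
            + "; ".join(f"{c}: {sorted(t)}" for c, t in sorted(bad_chroms.items()))
        )
    return GenomeAnnotation.from_transcripts(transcripts)
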