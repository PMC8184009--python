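"""Split-read junction extraction, depth normalization and PSI.

Counting rule: a read contributes one count to every junction spanned by
an N-operation in its CIGAR, provided the read is a primary, mapped,
non-duplicate alignment with NM <= ``max_mismatches`` and the shortest
aligned block immediately flanking the N-operation is at least
``min_overhang`` nt. Junction strand is taken from the aligner's XS
splice-strand tag when present, otherwise inferred from the
intron-terminal dinucleotides (GT..AG in plus orientation, CT..AC in
minus), otherwise stored unstranded ('.') for later resolution against
the annotation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pysam

from crypticsplice.annotation_io import GenomeAnnotation, GenomeSequence


@dataclass(frozen=True, order=True)
class Junction:
    """A genome-anchored intron candidate, stored as the intron interval
    ``[start, end)`` with transcriptional-orientation donor/acceptor."""

    chrom: str
    strand: str  # '+', '-' or '.' (unresolved)
    start: int   # first intronic base
    end: int     # one past last intronic base

    def __post_init__(self):
        if self.end - self.start < 1:
            raise ValueError(f"intron length < 1: {self}")

    @property
    def donor(self) -> int:
        """Donor (5' splice site) boundary coordinate."""
        return self.end if self.strand == "-" else self.start

    @property
    def acceptor(self) -> int:
        """Acceptor (3' splice site) boundary coordinate."""
        return self.start if self.strand == "-" else self.end

    @property
    def key(self) -> tuple[str, str, int, int]:
        return (self.chrom, self.strand, self.start, self.end)


def _infer_strand(g: GenomeSequence | None, chrom: str, start: int, end: int) -> str:
    if g is None:
        return "."
    first2 = g.fetch(chrom, start, min(start + 2, g.chrom_length(chrom)))
    last2 = g.fetch(chrom, max(end - 2, 0), end)
    if first2 == "GT" and last2 == "AG":
        return "+"
    if first2 == "CT" and last2 == "AC":
        return "-"
    return "."


def extract_split_reads(
    path: str,
    genome: GenomeSequence | None = None,
    min_overhang: int = 8,
    max_mismatches: int = 0,
) -> tuple[dict[Junction, int], int]:
    """Count junction-spanning split reads in a SAM/BAM file.

    Returns ``(counts, library_size)`` where ``library_size`` is the
    number of qualifying primary mapped reads (spliced or not). Reads
    lacking an NM tag are excluded and reported with a single warning.
    """
    counts: dict[Junction, int] = {}
    library_size = 0
    missing_nm = 0
    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
        for read in fh:
            if (read.is_unmapped or read.is_secondary or read.is_supplementary
                    or read.is_duplicate):
                continue
            try:
                nm = read.get_tag("NM")
            except KeyError:
                missing_nm += 1
                continue
            if nm > max_mismatches:
                continue
            library_size += 1
            cig = read.cigartuples
            if cig is None or not any(op == 3 for op, _ in cig):
                continue
            xs = read.get_tag("XS") if read.has_tag("XS") else None
            # Walk CIGAR tracking reference position and the aligned-block
            # length flanking each N operation.
            ref = read.reference_start
            # aligned (M/=/X) run lengths between N ops, in order
            blocks: list[int] = []
            introns: list[tuple[int, int]] = []
            cur = 0
            for op, ln in cig:
                if op in (0, 7, 8):  # M, =, X
                    cur += ln
                    ref += ln
                elif op == 2:  # D consumes reference, breaks nothing
                    ref += ln
                elif op == 3:  # N
                    blocks.append(cur)
                    cur = 0
                    introns.append((ref, ref + ln))
                    ref += ln
                # I, S, H, P do not consume reference
            blocks.append(cur)
            for i, (istart, iend) in enumerate(introns):
                if min(blocks[i], blocks[i + 1]) < min_overhang:
                    continue
                strand = xs if xs in ("+", "-") else _infer_strand(
                    genome, read.reference_name, istart, iend)
                j = Junction(read.reference_name, strand, istart, iend)
                counts[j] = counts.get(j, 0) + 1
    if missing_nm:
        warnings.warn(f"{path}: {missing_nm} reads lacked an NM tag and were excluded")
    return counts, library_size


def resolve_strand(j: Junction, ann: GenomeAnnotation) -> Junction:
    """Resolve an unstranded junction against the annotation.

    If exactly one strand assignment matches an annotated splice site or
    junction, adopt it; otherwise leave unstranded.
    """
    if j.strand != ".":
        return j
    hits = []
    for strand in "+-":
        cand = Junction(j.chrom, strand, j.start, j.end)
        if (cand.key in ann.annotated_junctions
                or (j.chrom, strand, cand.donor) in ann.annotated_donors
                or (j.chrom, strand, cand.acceptor) in ann.annotated_acceptors):
            hits.append(cand)
    return hits[0] if len(hits) == 1 else j


@dataclass
class JunctionCountMatrix:
    """Raw counts, CPM and PSI for a junction set across libraries.

    ``samples`` maps sample_id -> condition label; ``condition`` of the
    control is whatever the design says — this container is agnostic.
    """

    junctions: list[Junction]
    samples: dict[str, str]
    raw: pd.DataFrame            # junctions x samples, int
    library_sizes: pd.Series     # per sample
    normalized: pd.DataFrame | None = None  # CPM
    psi: pd.DataFrame | None = None         # [0,1] or NaN (undefined)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.samples)


def build_count_matrix(
    per_sample: dict[str, tuple[dict[Junction, int], int]],
    conditions: dict[str, str],
) -> JunctionCountMatrix:
    """Assemble per-sample count dicts into one matrix (union of junctions)."""
    all_j = sorted({j for counts, _ in per_sample.values() for j in counts})
    sample_ids = list(per_sample)
    raw = pd.DataFrame(0, index=range(len(all_j)), columns=sample_ids, dtype=np.int64)
    jindex = {j: i for i, j in enumerate(all_j)}
    for sid, (counts, _) in per_sample.items():
        for j, c in counts.items():
            raw.loc[jindex[j], sid] = c
    sizes = pd.Series({sid: size for sid, (_, size) in per_sample.items()})
    return JunctionCountMatrix(
        junctions=all_j,
        samples={sid: conditions[sid] for sid in sample_ids},
        raw=raw, library_sizes=sizes,
    )


def normalize_counts(m: JunctionCountMatrix) -> JunctionCountMatrix:
    """Fill ``normalized`` with counts-per-million; raw is preserved."""
    for sid in m.sample_ids:
        if m.library_sizes[sid] <= 0:
            raise ValueError(f"zero library size for sample {sid!r}")
    m.normalized = m.raw / m.library_sizes * 1e6
    return m


def _shared_site_groups(junctions: list[Junction]) -> list[np.ndarray]:
    """For each junction, indices of all junctions sharing its donor or
    acceptor boundary (itself included)."""
    donors: dict[tuple, list[int]] = {}
    acceptors: dict[tuple, list[int]] = {}
    for i, j in enumerate(junctions):
        donors.setdefault((j.chrom, j.strand, j.donor), []).append(i)
        acceptors.setdefault((j.chrom, j.strand, j.acceptor), []).append(i)
    groups = []
    for i, j in enumerate(junctions):
        members = set(donors[(j.chrom, j.strand, j.donor)])
        members |= set(acceptors[(j.chrom, j.strand, j.acceptor)])
        groups.append(np.fromiter(sorted(members), dtype=np.int64))
    return groups


def compute_psi(m: JunctionCountMatrix) -> JunctionCountMatrix:
    """Fill ``psi``: share of each junction among all junctions using
    either of its splice sites (a local-splice-variant proxy).

    PSI is NaN (undefined, not zero) where the local denominator is 0.
    """
    groups = _shared_site_groups(m.junctions)
    raw = m.raw.to_numpy(dtype=float)
    psi = np.full_like(raw, np.nan)
    for i, members in enumerate(groups):
        denom = raw[members].sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            psi[i] = np.where(denom > 0, raw[i] / denom, np.nan)
    m.psi = pd.DataFrame(psi, index=m.raw.index, columns=m.raw.columns)
    return m


def matrix_to_tsv(m: JunctionCountMatrix, path: str) -> None:
    """Write the documented junction count table (TSV)."""
    rows = {
        "chrom": [j.chrom for j in m.junctions],
        "strand": [j.strand for j in m.junctions],
        "donor": [j.donor for j in m.junctions],
        "acceptor": [j.acceptor for j in m.junctions],
        "intron_start": [j.start for j in m.junctions],
        "intron_end": [j.end for j in m.junctions],
    }
    df = pd.DataFrame(rows)
    for sid in m.sample_ids:
        df[f"raw_{sid}"] = m.raw[sid].to_numpy()
    if m.normalized is not None:
        for sid in m.sample_ids:
            df[f"cpm_{sid}"] = m.normalized[sid].to_numpy()
    if m.psi is not None:
        for sid in m.sample_ids:
            df[f"psi_{sid}"] = m.psi[sid].to_numpy()
    header = "#" + "\t".join(
        f"{sid}:{cond}:{int(m.library_sizes[sid])}" for sid, cond in m.samples.items()
    )
    with open(path, "w") as fh:
        fh.write(header + "\n")
        df.to_csv(fh, sep="\t", index=False)


def matrix_from_tsv(path: str) -> JunctionCountMatrix:
    """Read a junction count table written by :func:`matrix_to_tsv`."""
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise ValueError(f"{path}: missing sample header line")
        samples, sizes = {}, {}
        for tok in header[1:].strip().split("\t"):
            sid, cond, size = tok.rsplit(":", 2)
            samples[sid] = cond
            sizes[sid] = int(size)
        df = pd.read_csv(fh, sep="\t")
    junctions = [
        Junction(r.chrom, r.strand, int(r.intron_start), int(r.intron_end))
        for r in df.itertuples()
    ]
    m = JunctionCountMatrix(
        junctions=junctions,
        samples=samples,
        raw=df[[f"raw_{s}" for s in samples]].rename(
            columns={f"raw_{s}": s for s in samples}).astype(np.int64),
        library_sizes=pd.Series(sizes),
    )
    if f"cpm_{next(iter(samples))}" in df.columns:
        m.normalized = df[[f"cpm_{s}" for s in samples]].rename(
            columns={f"cpm_{s}": s for s in samples})
    if f"psi_{next(iter(samples))}" in df.columns:
        m.psi = df[[f"psi_{s}" for s in samples]].rename(
            columns={f"psi_{s}": s for s in samples})
    return m
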