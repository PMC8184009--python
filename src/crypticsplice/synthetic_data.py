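"""Synthetic genomes, annotations and condition-structured spliced
alignments with planted cryptic junctions and a truth manifest.

The generator emulates a 4-library core-EJC knockdown experiment (one
control, three knockdowns) over a toy genome: genes with canonical
GT..AG introns carrying an extended donor/acceptor consensus and a
planted branchpoint motif, plus cryptic junctions of all five
discovery classes planted at configured offsets, upregulated with a
configured fold change in a configured number of knockdown conditions.
Reads are single-end gapped SAM records (M/N CIGAR, NM:i:0, XS strand
tag) so the split-read filters are exercised literally; library depth
is padded exactly with ungapped filler reads.

All sequence design happens in "sense pre-mRNA space" (exon and intron
sequences in transcript orientation, concatenated); minus-strand genes
are reverse-complemented into the genome as a block, which keeps every
planted feature strand-correct by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from crypticsplice.annotation_io import GenomeAnnotation, TranscriptModel, revcomp
from crypticsplice.junction_quant import Junction, JunctionCountMatrix

DONOR_CONSENSUS = "GTAAGT"      # intron-initial
ACCEPTOR_CONSENSUS = "TTTCAG"   # intron-terminal
BRANCHPOINT_MOTIF = "CTAAC"
# sense codons without stops, used for CDS sequence
_STOPFREE = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
             if a + b + c not in ("TAA", "TAG", "TGA")]

CSS_PLANT_CLASSES = ("exonic_5ss", "exonic_3ss", "intronic_5ss",
                     "intronic_3ss", "novel_alternative")


@dataclass(frozen=True)
class PlantedSpec:
    """Plan entry for one cryptic junction to plant."""

    css_class: str
    fold_change: float = 8.0
    n_responsive_kd: int = 3
    offset_range: tuple[int, int] = (20, 60)

    def __post_init__(self):
        if self.css_class not in CSS_PLANT_CLASSES:
            raise ValueError(f"unknown class {self.css_class!r}")
        if self.n_responsive_kd >= 2 and self.fold_change <= 1:
            raise ValueError("responsive junctions need fold_change > 1")


def default_planted_plan() -> tuple[PlantedSpec, ...]:
    """Default plan: a mixture of all five classes, mostly responsive in
    >=2 of 3 knockdowns, plus non-responsive decoys."""
    plan: list[PlantedSpec] = []
    plan += [PlantedSpec("exonic_3ss", 8.0, 3)] * 8
    plan += [PlantedSpec("exonic_5ss", 8.0, 2)] * 8
    plan += [PlantedSpec("intronic_3ss", 8.0, 3, (10, 50))] * 4
    plan += [PlantedSpec("intronic_5ss", 8.0, 2, (10, 50))] * 4
    plan += [PlantedSpec("novel_alternative", 8.0, 2)] * 4
    plan += [PlantedSpec("exonic_3ss", 1.0, 0)] * 3
    plan += [PlantedSpec("exonic_5ss", 8.0, 1)] * 3
    plan += [PlantedSpec("intronic_3ss", 1.0, 0)] * 2
    return tuple(plan)


@dataclass(frozen=True)
class SimulationConfig:
    n_genes: int = 100
    exons_per_gene: tuple[int, int] = (3, 6)
    exon_length: tuple[int, int] = (80, 300)
    intron_length: tuple[int, int] = (70, 160)
    canonical_ss_fidelity: float = 0.9   # extended consensus positions
    planted_cryptic: tuple[PlantedSpec, ...] = field(default_factory=default_planted_plan)
    remnant_gt_fraction: float = 0.2     # junctions forced to begin GT downstream
    remnant_ag_fraction: float = 0.2     # junctions forced to end AG upstream
    control: str = "lacZ"
    knockdowns: tuple[str, ...] = ("eIF4AIII", "mago", "tsu")
    depth: int = 200_000
    read_length: int = 100
    min_overhang: int = 8
    noise: str = "none"                  # none | nb
    nb_dispersion: float = 0.1
    annotated_count_range: tuple[int, int] = (50, 150)
    cryptic_base_count: int = 10
    seed: int = 0

    def __post_init__(self):
        for lo, hi in (self.exons_per_gene, self.exon_length, self.intron_length):
            if lo > hi or lo <= 0:
                raise ValueError("empty or invalid range in config")
        if self.noise not in ("none", "nb"):
            raise ValueError(f"unknown noise mode {self.noise!r}")
        if self.exon_length[0] < 2 * self.min_overhang:
            raise ValueError("exons shorter than read overhang requirements")

    @property
    def conditions(self) -> dict[str, str]:
        out = {f"{self.control}_ctrl": self.control}
        for kd in self.knockdowns:
            out[f"{kd}_kd"] = kd
        return out


@dataclass
class GeneDesign:
    """One designed gene in sense pre-mRNA space."""

    gene_id: str
    chrom: str
    strand: str
    exon_seqs: list[str]
    intron_seqs: list[str]
    cds_mrna: tuple[int, int]
    gene_start: int = 0   # genomic offset, assigned at layout

    @property
    def exon_lens(self) -> list[int]:
        return [len(s) for s in self.exon_seqs]

    @property
    def length(self) -> int:
        return sum(map(len, self.exon_seqs)) + sum(map(len, self.intron_seqs))

    def sense_seq(self) -> str:
        parts = []
        for i, ex in enumerate(self.exon_seqs):
            parts.append(ex)
            if i < len(self.intron_seqs):
                parts.append(self.intron_seqs[i])
        return "".join(parts)

    def mrna(self) -> str:
        return "".join(self.exon_seqs)

    def sense_exon_bounds(self) -> list[tuple[int, int]]:
        """Exon intervals in sense pre-mRNA coordinates."""
        out, acc = [], 0
        for i, ex in enumerate(self.exon_seqs):
            out.append((acc, acc + len(ex)))
            acc += len(ex)
            if i < len(self.intron_seqs):
                acc += len(self.intron_seqs[i])
        return out

    def g(self, sense_boundary: int) -> int:
        """Map a sense pre-mRNA boundary to a genomic boundary."""
        if self.strand == "+":
            return self.gene_start + sense_boundary
        return self.gene_start + self.length - sense_boundary

    def genomic_exons(self) -> list[tuple[int, int]]:
        out = []
        for s, e in self.sense_exon_bounds():
            gs, ge = self.g(e), self.g(s)
            out.append((min(gs, ge), max(gs, ge)))
        return sorted(out)

    def transcript_model(self) -> TranscriptModel:
        lo, hi = self.cds_mrna
        cds_genomic = []
        acc = 0
        for (s, e) in self.sense_exon_bounds():
            ex_lo, ex_hi = acc, acc + (e - s)
            ov_lo, ov_hi = max(ex_lo, lo), min(ex_hi, hi)
            if ov_lo < ov_hi:
                b1 = self.g(s + (ov_lo - ex_lo))
                b2 = self.g(s + (ov_hi - ex_lo))
                cds_genomic.append((min(b1, b2), max(b1, b2)))
            acc = ex_hi
        return TranscriptModel(
            transcript_id=f"{self.gene_id}.t1", gene_id=self.gene_id,
            chrom=self.chrom, strand=self.strand,
            exons=tuple(self.genomic_exons()),
            cds=tuple(sorted(cds_genomic)),
        )


@dataclass
class PlantedJunction:
    """Truth record for one planted cryptic junction."""

    junction: Junction
    css_class: str
    gene_id: str
    fold_change: float
    responsive_conditions: tuple[str, ...]
    base_count: int
    offset: int
    left_run: int    # contiguous genomic bases left of the intron usable by reads
    right_run: int

    @property
    def responsive(self) -> bool:
        return len(self.responsive_conditions) >= 2


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    genes: list[GeneDesign]
    annotation: GenomeAnnotation
    chrom_seqs: dict[str, str]
    planted: list[PlantedJunction]
    annotated_counts: dict[Junction, int]
    samples: dict[str, str]               # sample id -> condition
    fasta: Path | None = None
    gtf: Path | None = None
    sams: dict[str, Path] = field(default_factory=dict)
    manifest: Path | None = None

    def truth_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.planted:
            rows.append({
                "chrom": p.junction.chrom, "strand": p.junction.strand,
                "intron_start": p.junction.start, "intron_end": p.junction.end,
                "donor": p.junction.donor, "acceptor": p.junction.acceptor,
                "css_class": p.css_class, "gene_id": p.gene_id,
                "fold_change": p.fold_change, "base_count": p.base_count,
                "offset": p.offset,
                "responsive_conditions": ",".join(p.responsive_conditions),
                "responsive": int(p.responsive),
            })
        return pd.DataFrame(rows)

    def remnant_frame(self) -> pd.DataFrame:
        """Regenerated-dinucleotide status of every annotated junction,
        read off the final mRNA sequences."""
        rows = []
        for gene in self.genes:
            mrna = gene.mrna()
            acc = 0
            for i, ex in enumerate(gene.exon_seqs[:-1]):
                acc += len(ex)
                rows.append({
                    "transcript_id": f"{gene.gene_id}.t1",
                    "junction_index": i, "mrna_position": acc,
                    "gt_downstream": int(mrna[acc:acc + 2] == "GT"),
                    "ag_upstream": int(mrna[acc - 2:acc] == "AG"),
                })
        return pd.DataFrame(rows)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def _with_consensus(seq: str, offset: int, consensus: str, invariant: str,
                    fidelity: float, rng: np.random.Generator) -> str:
    """Overwrite consensus positions; bases in ``invariant`` (by index
    flag string, '1' = always) are planted unconditionally, others with
    probability ``fidelity``."""
    out = list(seq)
    for k, base in enumerate(consensus):
        if invariant[k] == "1" or rng.random() < fidelity:
            out[offset + k] = base
    return "".join(out)


def _make_intron(rng: np.random.Generator, length: int, fidelity: float) -> str:
    seq = _random_seq(rng, length)
    seq = _with_consensus(seq, 0, DONOR_CONSENSUS, "110000", fidelity, rng)
    seq = _with_consensus(seq, length - 6, ACCEPTOR_CONSENSUS, "000011", fidelity, rng)
    if length >= 50:
        # branchpoint in the 15-45 nt window upstream of the 3' SS
        off = int(rng.integers(20, 39))  # motif end 20-38 nt upstream
        seq = _with_consensus(seq, length - off - len(BRANCHPOINT_MOTIF),
                              BRANCHPOINT_MOTIF, "0" * 5, fidelity, rng)
    return seq


def _make_gene(rng: np.random.Generator, cfg: SimulationConfig, gene_id: str,
               chrom: str, strand: str) -> GeneDesign:
    n_ex = int(rng.integers(cfg.exons_per_gene[0], cfg.exons_per_gene[1] + 1))
    exon_lens = [int(rng.integers(cfg.exon_length[0], cfg.exon_length[1] + 1))
                 for _ in range(n_ex)]
    intron_lens = [int(rng.integers(cfg.intron_length[0], cfg.intron_length[1] + 1))
                   for _ in range(n_ex - 1)]
    total = sum(exon_lens)
    cds_lo = 30
    cds_hi = total - 30
    cds_hi -= (cds_hi - cds_lo) % 3
    # mRNA: UTRs random, CDS from stop-free codons
    n_codons = (cds_hi - cds_lo) // 3
    codons = [_STOPFREE[i] for i in rng.integers(0, len(_STOPFREE), n_codons)]
    mrna = _random_seq(rng, cds_lo) + "".join(codons) + _random_seq(rng, total - cds_hi)
    exon_seqs, acc = [], 0
    for ln in exon_lens:
        exon_seqs.append(mrna[acc:acc + ln])
        acc += ln
    intron_seqs = [_make_intron(rng, ln, cfg.canonical_ss_fidelity) for ln in intron_lens]
    return GeneDesign(gene_id=gene_id, chrom=chrom, strand=strand,
                      exon_seqs=exon_seqs, intron_seqs=intron_seqs,
                      cds_mrna=(cds_lo, cds_hi))


def _edit_mrna(gene: GeneDesign, pos: int, bases: str) -> None:
    """Write ``bases`` into the mature mRNA at ``pos`` (edits the
    underlying exon sequences)."""
    acc = 0
    for i, ex in enumerate(gene.exon_seqs):
        if acc <= pos < acc + len(ex):
            k = pos - acc
            take = min(len(bases), len(ex) - k)
            gene.exon_seqs[i] = ex[:k] + bases[:take] + ex[k + take:]
            if take < len(bases):
                _edit_mrna(gene, pos + take, bases[take:])
            return
        acc += len(ex)
    raise ValueError(f"{gene.gene_id}: mRNA position {pos} out of range")


def _edit_intron(gene: GeneDesign, intron_idx: int, off: int, bases: str) -> None:
    s = gene.intron_seqs[intron_idx]
    gene.intron_seqs[intron_idx] = s[:off] + bases + s[off + len(bases):]


def _plant_cryptic(rng: np.random.Generator, cfg: SimulationConfig,
                   gene: GeneDesign, spec: PlantedSpec) -> PlantedJunction | None:
    """Try to plant one cryptic junction in ``gene``; None if infeasible."""
    n_introns = len(gene.intron_seqs)
    if n_introns < 1 or (spec.css_class == "novel_alternative" and n_introns < 2):
        return None
    margin = cfg.min_overhang + 2
    exon_lens = gene.exon_lens
    bounds = gene.sense_exon_bounds()
    mrna_len = sum(exon_lens)
    mrna_bounds = []
    acc = 0
    for ln in exon_lens:
        mrna_bounds.append((acc, acc + ln))
        acc += ln

    if spec.css_class == "novel_alternative":
        i = int(rng.integers(0, n_introns - 1))
        k = i + 1
        delta_don = bounds[i][1]       # sense donor boundary of intron i
        delta_acc = bounds[k + 1][0]   # sense acceptor boundary of intron k
        b1, b2 = gene.g(delta_don), gene.g(delta_acc)
        j = Junction(gene.chrom, gene.strand, min(b1, b2), max(b1, b2))
        u_run, d_run = exon_lens[i], exon_lens[k + 1]
        offset = 0
    else:
        i = int(rng.integers(0, n_introns))
        ilen = len(gene.intron_seqs[i])
        lo, hi = spec.offset_range
        if spec.css_class == "exonic_3ss":
            hi = min(hi, exon_lens[i + 1] - margin)
            if hi < lo:
                return None
            o = int(rng.integers(lo, hi + 1))
            beta = bounds[i + 1][0] + o            # sense acceptor boundary
            _edit_mrna(gene, mrna_bounds[i + 1][0] + o - 2, "AG")
            delta = bounds[i][1]                   # annotated donor boundary
            u_run, d_run = exon_lens[i], exon_lens[i + 1] - o
        elif spec.css_class == "exonic_5ss":
            hi = min(hi, exon_lens[i] - margin)
            if hi < lo:
                return None
            o = int(rng.integers(lo, hi + 1))
            beta = bounds[i][1] - o                # sense donor boundary
            _edit_mrna(gene, mrna_bounds[i][1] - o, "GT")
            delta = bounds[i + 1][0]               # annotated acceptor boundary
            u_run, d_run = exon_lens[i] - o, exon_lens[i + 1]
        elif spec.css_class == "intronic_3ss":
            hi = min(hi, ilen - 10)
            lo = max(lo, 10)
            if hi < lo:
                return None
            o = int(rng.integers(lo, hi + 1))
            beta = bounds[i][1] + o                # acceptor inside the intron
            _edit_intron(gene, i, o - 2, "AG")
            delta = bounds[i][1]
            u_run, d_run = exon_lens[i], (ilen - o) + exon_lens[i + 1]
        else:  # intronic_5ss
            hi = min(hi, ilen - 10)
            lo = max(lo, 10)
            if hi < lo:
                return None
            o = int(rng.integers(lo, hi + 1))
            beta = bounds[i + 1][0] - o            # donor inside the intron
            _edit_intron(gene, i, ilen - o, "GT")
            delta = bounds[i + 1][0]
            u_run, d_run = exon_lens[i] + (ilen - o), exon_lens[i + 1]
        b1, b2 = gene.g(beta), gene.g(delta)
        j = Junction(gene.chrom, gene.strand, min(b1, b2), max(b1, b2))
        offset = o
    if u_run < margin or d_run < margin:
        return None
    left_run, right_run = (u_run, d_run) if gene.strand == "+" else (d_run, u_run)
    n_resp = min(spec.n_responsive_kd, len(cfg.knockdowns))
    resp_idx = rng.choice(len(cfg.knockdowns), size=n_resp, replace=False)
    resp = tuple(sorted(cfg.knockdowns[int(x)] for x in resp_idx))
    return PlantedJunction(
        junction=j, css_class=spec.css_class, gene_id=gene.gene_id,
        fold_change=spec.fold_change, responsive_conditions=resp,
        base_count=cfg.cryptic_base_count, offset=offset,
        left_run=left_run, right_run=right_run,
    )


def _plant_remnants(rng: np.random.Generator, cfg: SimulationConfig,
                    genes: list[GeneDesign]) -> None:
    for gene in genes:
        acc = 0
        for i, ex in enumerate(gene.exon_seqs[:-1]):
            acc += len(ex)
            if rng.random() < cfg.remnant_ag_fraction:
                _edit_mrna(gene, acc - 2, "AG")
            if rng.random() < cfg.remnant_gt_fraction:
                _edit_mrna(gene, acc, "GT")


def design_dataset(cfg: SimulationConfig,
                   custom_genes: list[GeneDesign] | None = None,
                   custom_planted: list[dict] | None = None) -> SimulatedDataset:
    """Design genes, plant features and plan counts (no file output).

    ``custom_genes``/``custom_planted`` let fixture builders inject
    hand-designed genes alongside the random ones.
    """
    rng = np.random.default_rng(cfg.seed)
    genes = []
    for gi in range(cfg.n_genes):
        strand = "+" if gi % 2 == 0 else "-"
        genes.append(_make_gene(rng, cfg, f"g{gi:04d}", "chrS", strand))
    if custom_genes:
        genes = list(custom_genes) + genes
    _plant_remnants(rng, cfg, genes)

    # plant cryptic junctions: one per gene, genes drawn without replacement
    free = [g for g in genes if custom_genes is None or g not in custom_genes]
    order = list(rng.permutation(len(free)))
    planted: list[PlantedJunction] = []
    plan = list(cfg.planted_cryptic)
    # genome layout must be known before genomic coordinates exist, but
    # planting edits sequences; assign gene_start first using final
    # lengths (sequence edits never change lengths)
    gap = 100
    pos = gap
    for g_ in genes:
        g_.gene_start = pos
        pos += g_.length + gap
    chrom_len = pos
    gene_cursor = 0
    for spec in plan:
        pj = None
        while gene_cursor < len(order) and pj is None:
            gene = free[order[gene_cursor]]
            gene_cursor += 1
            pj = _plant_cryptic(rng, cfg, gene, spec)
        if pj is None:
            raise ValueError("infeasible config: ran out of genes eligible for planting")
        planted.append(pj)
    if custom_planted:
        planted = list(custom_planted) + planted

    # chromosome sequence: spacers + per-gene (possibly revcomp'd) blocks
    parts, cursor = [], 0
    for g_ in genes:
        parts.append(_random_seq(rng, g_.gene_start - cursor))
        block = g_.sense_seq()
        parts.append(revcomp(block) if g_.strand == "-" else block)
        cursor = g_.gene_start + g_.length
    parts.append(_random_seq(rng, chrom_len - cursor))
    chrom_seqs = {"chrS": "".join(parts)}

    ann = GenomeAnnotation.from_transcripts([g_.transcript_model() for g_ in genes])
    annotated_counts = {}
    for key in sorted(ann.annotated_junctions):
        annotated_counts[Junction(*key)] = int(
            rng.integers(cfg.annotated_count_range[0], cfg.annotated_count_range[1] + 1))
    samples = cfg.conditions
    return SimulatedDataset(
        config=cfg, genes=genes, annotation=ann, chrom_seqs=chrom_seqs,
        planted=planted, annotated_counts=annotated_counts, samples=samples,
    )


def _planned_count(pj: PlantedJunction, condition: str, control: str) -> int:
    if condition == control or condition not in pj.responsive_conditions:
        return pj.base_count
    return int(round(pj.base_count * pj.fold_change))


def _nb_sample(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    """Negative binomial via gamma-Poisson: var = mean + dispersion*mean^2."""
    if mean <= 0:
        return 0
    lam = rng.gamma(shape=1.0 / dispersion, scale=mean * dispersion)
    return int(rng.poisson(lam))


def _count_table(ds: SimulatedDataset, rng: np.random.Generator) -> tuple[list[Junction], np.ndarray]:
    """Per-(junction, sample) counts following the plan (NB noise if
    configured)."""
    cfg = ds.config
    annotated = list(ds.annotated_counts)
    junctions = annotated + [p.junction for p in ds.planted]
    sample_ids = list(ds.samples)
    counts = np.zeros((len(junctions), len(sample_ids)), dtype=np.int64)
    for si, sid in enumerate(sample_ids):
        cond = ds.samples[sid]
        for ji, j in enumerate(annotated):
            mean = ds.annotated_counts[j]
            counts[ji, si] = (mean if cfg.noise == "none"
                              else _nb_sample(rng, mean, cfg.nb_dispersion))
        for pi, p in enumerate(ds.planted):
            mean = _planned_count(p, cond, cfg.control)
            counts[len(annotated) + pi, si] = (
                mean if cfg.noise == "none" else _nb_sample(rng, mean, cfg.nb_dispersion))
    return junctions, counts


def generate_count_matrix(cfg: SimulationConfig,
                          ds: SimulatedDataset | None = None,
                          ) -> tuple[JunctionCountMatrix, SimulatedDataset]:
    """Count-level simulation: the planned (optionally NB-noised) count
    matrix with ``library_sizes = depth``, without writing alignments."""
    if ds is None:
        ds = design_dataset(cfg)
    rng = np.random.default_rng(cfg.seed + 1)
    junctions, counts = _count_table(ds, rng)
    raw = pd.DataFrame(counts, columns=list(ds.samples))
    m = JunctionCountMatrix(
        junctions=junctions, samples=dict(ds.samples), raw=raw,
        library_sizes=pd.Series({s: cfg.depth for s in ds.samples}),
    )
    return m, ds


# ---------------------------------------------------------------------------
# file output
# ---------------------------------------------------------------------------

def _annotated_runs(ds: SimulatedDataset) -> dict[Junction, tuple[int, int]]:
    runs = {}
    for gene in ds.genes:
        exon_lens = gene.exon_lens
        bounds = gene.sense_exon_bounds()
        for i in range(len(gene.intron_seqs)):
            b1, b2 = gene.g(bounds[i][1]), gene.g(bounds[i + 1][0])
            j = Junction(gene.chrom, gene.strand, min(b1, b2), max(b1, b2))
            u_run, d_run = exon_lens[i], exon_lens[i + 1]
            runs[j] = (u_run, d_run) if gene.strand == "+" else (d_run, u_run)
    return runs


def _write_junction_reads(fh, ds: SimulatedDataset, j: Junction, n: int,
                          left_run: int, right_run: int,
                          rng: np.random.Generator, name_prefix: str) -> int:
    cfg = ds.config
    chrom_seq = ds.chrom_seqs[j.chrom]
    total = min(cfg.read_length, left_run + right_run)
    lo = max(cfg.min_overhang, total - right_run)
    hi = min(total - cfg.min_overhang, left_run)
    if hi < lo or total < 2 * cfg.min_overhang:
        raise ValueError(f"infeasible read placement at {j}")
    written = 0
    gap = j.end - j.start
    for r in range(n):
        up = int(rng.integers(lo, hi + 1))
        down = total - up
        pos = j.start - up
        seq = chrom_seq[pos:j.start] + chrom_seq[j.end:j.end + down]
        flag = 16 if j.strand == "-" else 0
        fh.write(
            f"{name_prefix}.{r}\t{flag}\t{j.chrom}\t{pos + 1}\t60\t"
            f"{up}M{gap}N{down}M\t*\t0\t0\t{seq}\t*\tNM:i:0\tXS:A:{j.strand}\n"
        )
        written += 1
    return written


def generate(cfg: SimulationConfig, outdir: str | Path,
             ds: SimulatedDataset | None = None) -> SimulatedDataset:
    """Write FASTA, GTF, per-sample SAM and the truth manifest.

    Deterministic given ``cfg.seed``: the same config produces
    byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if ds is None:
        ds = design_dataset(cfg)

    fasta = outdir / "genome.fa"
    with open(fasta, "w") as fh:
        for chrom, seq in ds.chrom_seqs.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")
    # pyfaidx index must be rebuilt if stale
    fai = Path(str(fasta) + ".fai")
    if fai.exists():
        fai.unlink()

    gtf = outdir / "annotation.gtf"
    with open(gtf, "w") as fh:
        for gene in ds.genes:
            t = gene.transcript_model()
            for s, e in t.exons_genomic:
                fh.write(f"{t.chrom}\tsim\texon\t{s + 1}\t{e}\t.\t{t.strand}\t.\t"
                         f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";\n')
            for s, e in sorted(t.cds):
                fh.write(f"{t.chrom}\tsim\tCDS\t{s + 1}\t{e}\t.\t{t.strand}\t.\t"
                         f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";\n')

    rng = np.random.default_rng(cfg.seed + 1)
    junctions, counts = _count_table(ds, rng)
    ann_runs = _annotated_runs(ds)
    runs = {**ann_runs, **{p.junction: (p.left_run, p.right_run) for p in ds.planted}}

    read_rng = np.random.default_rng(cfg.seed + 2)
    chrom_names = list(ds.chrom_seqs)
    header_lines = ["@HD\tVN:1.6\tSO:unsorted"] + [
        f"@SQ\tSN:{c}\tLN:{len(ds.chrom_seqs[c])}" for c in chrom_names]
    for si, sid in enumerate(ds.samples):
        sam = outdir / f"{sid}.sam"
        with open(sam, "w") as fh:
            fh.write("\n".join(header_lines) + "\n")
            total_junction_reads = 0
            for ji, j in enumerate(junctions):
                n = int(counts[ji, si])
                if n == 0:
                    continue
                lr, rr = runs[j]
                total_junction_reads += _write_junction_reads(
                    fh, ds, j, n, lr, rr, read_rng, f"{sid}.j{ji}")
            n_filler = cfg.depth - total_junction_reads
            if n_filler < 0:
                raise ValueError("depth too small for planned junction reads")
            chrom = chrom_names[0]
            seq = ds.chrom_seqs[chrom]
            starts = read_rng.integers(0, len(seq) - cfg.read_length, size=n_filler)
            rl = cfg.read_length
            for r, pos in enumerate(starts):
                p = int(pos)
                fh.write(f"{sid}.f{r}\t0\t{chrom}\t{p + 1}\t60\t{rl}M\t*\t0\t0\t"
                         f"{seq[p:p + rl]}\t*\tNM:i:0\n")
        ds.sams[sid] = sam

    manifest = outdir / "truth.tsv"
    ds.truth_frame().to_csv(manifest, sep="\t", index=False)
    ds.remnant_frame().to_csv(outdir / "remnants.tsv", sep="\t", index=False)
    ds.fasta, ds.gtf, ds.manifest = fasta, gtf, manifest
    return ds


# ---------------------------------------------------------------------------
# hand-designed re-splicing fixture
# ---------------------------------------------------------------------------

def _fixture_gene(rng: np.random.Generator, cfg: SimulationConfig, gene_id: str,
                  exon_lens: list[int], edits: list[tuple[int, str]]) -> GeneDesign:
    """Gene with stop-free CDS [30, len-30) and explicit mRNA edits."""
    total = sum(exon_lens)
    cds_lo, cds_hi = 30, total - 30
    cds_hi -= (cds_hi - cds_lo) % 3
    n_codons = (cds_hi - cds_lo) // 3
    codons = [_STOPFREE[i] for i in rng.integers(0, len(_STOPFREE), n_codons)]
    mrna = _random_seq(rng, cds_lo) + "".join(codons) + _random_seq(rng, total - cds_hi)
    exon_seqs, acc = [], 0
    for ln in exon_lens:
        exon_seqs.append(mrna[acc:acc + ln])
        acc += ln
    introns = [_make_intron(rng, 80, 1.0) for _ in range(len(exon_lens) - 1)]
    g = GeneDesign(gene_id=gene_id, chrom="chrS", strand="+",
                   exon_seqs=exon_seqs, intron_seqs=introns,
                   cds_mrna=(cds_lo, cds_hi))
    for pos, bases in edits:
        _edit_mrna(g, pos, bases)
    return g


def plant_resplice_fixture(cfg: SimulationConfig | None = None,
                           outdir: str | Path | None = None,
                           mutate_remnants: bool = False) -> SimulatedDataset:
    """Dataset containing two hand-designed re-splicing genes.

    ``reA`` mimics the CkIIbeta topology: exon 3 begins GT (a
    regenerated 5' site at the exon2/3 junction) and a cryptic 3' splice
    site is planted 54 nt into exon 3, codon-aligned inside the CDS, so
    the predicted re-splicing deletes 54 nt / 18 amino acids in frame.

    ``reB`` mimics the CG31156 topology: exon 2 ends AG (a regenerated
    3' site at the exon2/3 junction) and a cryptic 5' splice site is
    planted 110 nt upstream of that junction, producing a 110 nt
    deletion and a frameshift.

    ``mutate_remnants=True`` destroys both regenerated dinucleotides
    (GT->GA, AG->AA), a negative control that must yield zero events.
    Background genes make the annotation large enough to train PWMs.
    """
    base = cfg or SimulationConfig()
    cfg = replace(base, n_genes=max(base.n_genes, 60), planted_cryptic=())
    rng = np.random.default_rng(cfg.seed + 7)

    # reA: exons 90,120,150,90 (mRNA junction 2/3 at 210; all %3==0)
    editsA = [(210, "GA" if mutate_remnants else "GT"), (261, "AAG")]
    geneA = _fixture_gene(rng, cfg, "reA", [90, 120, 150, 90], editsA)
    # reB: exons 90,150,120,90 (junction 2/3 at 240); cryptic GT at 130
    editsB = [(237, "AAA" if mutate_remnants else "AAG"), (129, "AGT")]
    geneB = _fixture_gene(rng, cfg, "reB", [90, 150, 120, 90], editsB)

    ds = design_dataset(cfg, custom_genes=[geneA, geneB])

    def add_planted(gene: GeneDesign, css: str, beta: int, partner_intron: int,
                    offset: int, u_run: int, d_run: int):
        bounds = gene.sense_exon_bounds()
        if css == "exonic_3ss":
            delta = bounds[partner_intron][1]
        else:
            delta = bounds[partner_intron + 1][0]
        b1, b2 = gene.g(beta), gene.g(delta)
        j = Junction(gene.chrom, gene.strand, min(b1, b2), max(b1, b2))
        ds.planted.append(PlantedJunction(
            junction=j, css_class=css, gene_id=gene.gene_id, fold_change=8.0,
            responsive_conditions=tuple(sorted(cfg.knockdowns)),
            base_count=cfg.cryptic_base_count, offset=offset,
            left_run=u_run, right_run=d_run,
        ))

    # reA cryptic acceptor: 54 nt into exon 3 (sense pre-mRNA boundary)
    boundsA = geneA.sense_exon_bounds()
    _edit_mrna(geneA, 210 + 54 - 2, "AG")  # intron-terminal AG, exonic context
    add_planted(geneA, "exonic_3ss", boundsA[2][0] + 54, 1, 54, 120, 150 - 54)
    # reB cryptic donor: 110 nt upstream of the exon2/3 junction
    boundsB = geneB.sense_exon_bounds()
    add_planted(geneB, "exonic_5ss", boundsB[1][1] - 110, 1, 110, 150 - 110, 120)

    # the cryptic-site edits above happened after design_dataset built
    # the chromosome sequence; splice the edited gene blocks back in
    seq = list(ds.chrom_seqs["chrS"])
    for g_ in (geneA, geneB):
        block = g_.sense_seq()
        block = revcomp(block) if g_.strand == "-" else block
        seq[g_.gene_start:g_.gene_start + g_.length] = block
    ds.chrom_seqs["chrS"] = "".join(seq)

    if outdir is not None:
        generate(cfg, outdir, ds=ds)
    return ds
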