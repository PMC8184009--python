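"""Cryptic-junction discovery: filter cascade, classification, metagene
distances and the set-overlap permutation test.

The filter cascade identifies unannotated junctions whose usage rises
upon knockdown of core EJC factors, in three ordered steps:

1. aggregate evidence: >= ``min_aggregate_reads`` split reads summed
   over all libraries;
2. count response: depth-normalized count fold change (with pseudocount)
   > ``count_fc_threshold`` versus control in at least
   ``min_concordant_kd`` knockdown conditions;
3. usage response: PSI fold change (with epsilon) > ``psi_fc_threshold``
   in at least ``min_concordant_kd`` knockdown conditions.

Each surviving junction is classified by where its novel end falls
relative to the annotation (exonic/intronic novel donor or acceptor, or
novel pairing of two annotated sites).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from crypticsplice.annotation_io import (
    GenomeAnnotation,
    GenomeSequence,
    genome_to_mrna,
    transcript_sequence,
)
from crypticsplice.junction_quant import Junction, JunctionCountMatrix, resolve_strand
from crypticsplice.splice_motifs import (
    PositionWeightMatrix,
    SpliceSiteScore,
    acceptor_window,
    donor_window,
    score_site,
)

CSS_CLASSES = (
    "exonic_5ss", "exonic_3ss", "intronic_5ss", "intronic_3ss",
    "novel_alternative", "unclassified",
)


@dataclass(frozen=True)
class ExperimentDesign:
    """Maps sample ids to one control condition and >=1 knockdowns."""

    control_samples: tuple[str, ...]
    kd_conditions: dict[str, tuple[str, ...]]  # condition -> sample ids

    def __post_init__(self):
        if not self.control_samples:
            raise ValueError("design needs at least one control sample")
        if not self.kd_conditions:
            raise ValueError("design needs at least one knockdown condition")

    @classmethod
    def from_conditions(cls, samples: dict[str, str], control: str) -> "ExperimentDesign":
        ctrl = tuple(s for s, c in samples.items() if c == control)
        kds: dict[str, list[str]] = {}
        for s, c in samples.items():
            if c != control:
                kds.setdefault(c, []).append(s)
        return cls(control_samples=ctrl,
                   kd_conditions={c: tuple(v) for c, v in kds.items()})


@dataclass(frozen=True)
class PipelineConfig:
    """Thresholds and geometry for the whole discovery pipeline."""

    min_aggregate_reads: int = 5
    count_fc_threshold: float = 2.0
    psi_fc_threshold: float = 2.0
    min_concordant_kd: int = 2
    count_pseudocount: float = 1.0   # CPM units
    psi_epsilon: float = 0.01
    strong_ss_threshold: float = 0.75
    metagene_window: int = 50
    ejc_offset: int = 24
    ejc_footprint_halfwidth: int = 10
    bp_window: tuple[int, int] = (15, 45)
    bp_match_min: float = 0.75
    min_overhang: int = 8
    max_mismatches: int = 0
    n_permutations: int = 100_000
    rng_seed: int = 0

    def __post_init__(self):
        if min(self.min_aggregate_reads, self.count_fc_threshold,
               self.psi_fc_threshold, self.min_concordant_kd) <= 0:
            raise ValueError("thresholds must be positive")
        if self.bp_window[0] >= self.bp_window[1]:
            raise ValueError("bp_window lower bound must be below upper")


@dataclass
class CrypticJunctionCall:
    """A novel junction that passed the filter cascade."""

    junction: Junction
    aggregate_reads: int
    count_fc: dict[str, float]      # per KD condition
    psi_fc: dict[str, float]
    host_gene: str | None = None
    host_transcript: str | None = None
    novel_end: str = "neither"      # donor | acceptor | both | neither
    css_class: str = "unclassified"
    boundary_distance: int | None = None
    within_ejc_footprint: bool = False
    ss_score: SpliceSiteScore | None = None
    bp_best_match: float | None = None


def identify_novel(junctions: list[Junction], ann: GenomeAnnotation) -> dict[Junction, bool]:
    """True for each junction whose (chrom, strand, donor, acceptor)
    quadruple is present in the annotation."""
    out = {}
    for j in junctions:
        jj = resolve_strand(j, ann)
        out[j] = jj.key in ann.annotated_junctions
    return out


def _condition_means(m: JunctionCountMatrix, sample_ids: tuple[str, ...], table) -> np.ndarray:
    vals = table[list(sample_ids)].to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows stay NaN
        return np.nanmean(vals, axis=1)


def filter_cryptic(
    m: JunctionCountMatrix,
    design: ExperimentDesign,
    ann: GenomeAnnotation,
    cfg: PipelineConfig = PipelineConfig(),
) -> tuple[list[CrypticJunctionCall], dict[str, int]]:
    """Apply the three-step filter cascade to the unannotated junctions.

    Returns the calls and a waterfall of counts after each step:
    ``novel`` -> ``aggregate_reads`` -> ``count_fc`` -> ``psi_fc``.
    Fold changes use condition-mean CPM and PSI; undefined PSI enters
    the ratio as ``psi_epsilon``.
    """
    if m.normalized is None or m.psi is None:
        raise ValueError("matrix must be normalized and PSI-filled first")

    novelty = identify_novel(m.junctions, ann)
    idx_novel = np.array([not novelty[j] for j in m.junctions])
    waterfall = {"candidates": len(m.junctions), "novel": int(idx_novel.sum())}

    agg = m.raw.to_numpy().sum(axis=1)
    pass1 = idx_novel & (agg >= cfg.min_aggregate_reads)
    waterfall["aggregate_reads"] = int(pass1.sum())

    ctrl_cpm = _condition_means(m, design.control_samples, m.normalized)
    ctrl_psi = _condition_means(m, design.control_samples, m.psi)
    p, eps = cfg.count_pseudocount, cfg.psi_epsilon

    count_fcs, psi_fcs = {}, {}
    for cond, sids in design.kd_conditions.items():
        kd_cpm = _condition_means(m, sids, m.normalized)
        kd_psi = _condition_means(m, sids, m.psi)
        count_fcs[cond] = (kd_cpm + p) / (ctrl_cpm + p)
        psi_fcs[cond] = (np.nan_to_num(kd_psi, nan=0.0) + eps) / \
            (np.nan_to_num(ctrl_psi, nan=0.0) + eps)

    count_hits = sum((fc > cfg.count_fc_threshold).astype(int) for fc in count_fcs.values())
    pass2 = pass1 & (count_hits >= cfg.min_concordant_kd)
    waterfall["count_fc"] = int(pass2.sum())

    psi_hits = sum((fc > cfg.psi_fc_threshold).astype(int) for fc in psi_fcs.values())
    pass3 = pass2 & (psi_hits >= cfg.min_concordant_kd)
    waterfall["psi_fc"] = int(pass3.sum())

    calls = []
    for i in np.flatnonzero(pass3):
        j = resolve_strand(m.junctions[i], ann)
        calls.append(CrypticJunctionCall(
            junction=j,
            aggregate_reads=int(agg[i]),
            count_fc={c: float(v[i]) for c, v in count_fcs.items()},
            psi_fc={c: float(v[i]) for c, v in psi_fcs.items()},
        ))
    return calls, waterfall


def _novel_site_query_pos(j: Junction, end: str) -> int:
    """Genomic base used to test whether a novel end is exonic/intronic:
    the first intron-side base of the cryptic intron at that end."""
    if end == "donor":
        return j.start if j.strand == "+" else j.end - 1
    return j.end - 1 if j.strand == "+" else j.start


def _pick_host(ann: GenomeAnnotation, tids: list[str]) -> tuple[str, str] | None:
    """Host (gene, transcript): longest transcript, then lexicographic
    gene id, then transcript id."""
    if not tids:
        return None
    ts = [ann.transcripts[t] for t in set(tids)]
    ts.sort(key=lambda t: (-t.length, t.gene_id, t.transcript_id))
    return ts[0].gene_id, ts[0].transcript_id


def classify(call: CrypticJunctionCall, ann: GenomeAnnotation) -> CrypticJunctionCall:
    """Assign css_class, novel_end and host gene/transcript (in place).

    A junction with both ends at annotated splice sites but an
    unannotated pairing is ``novel_alternative``; one annotated end plus
    a novel end in exonic (resp. intronic) sequence is
    ``exonic_5ss``/``exonic_3ss`` (resp. ``intronic_*``); anything else
    is ``unclassified``.
    """
    j = call.junction
    donor_known = (j.chrom, j.strand, j.donor) in ann.annotated_donors
    acceptor_known = (j.chrom, j.strand, j.acceptor) in ann.annotated_acceptors

    if donor_known and acceptor_known:
        call.novel_end = "neither"
        call.css_class = (
            "unclassified" if j.key in ann.annotated_junctions else "novel_alternative")
        host = _pick_host(ann, ann.transcripts_with_donor(j.chrom, j.strand, j.donor)
                          + ann.transcripts_with_acceptor(j.chrom, j.strand, j.acceptor))
    elif donor_known != acceptor_known:
        call.novel_end = "acceptor" if donor_known else "donor"
        qpos = _novel_site_query_pos(j, call.novel_end)
        if ann.is_exonic(j.chrom, j.strand, qpos):
            locality = "exonic"
        elif ann.is_intronic(j.chrom, j.strand, qpos):
            locality = "intronic"
        else:
            locality = None
        site = "5ss" if call.novel_end == "donor" else "3ss"
        call.css_class = f"{locality}_{site}" if locality else "unclassified"
        tids = (ann.transcripts_with_donor(j.chrom, j.strand, j.donor) if donor_known
                else ann.transcripts_with_acceptor(j.chrom, j.strand, j.acceptor))
        host = _pick_host(ann, tids)
    else:
        call.novel_end = "both"
        call.css_class = "unclassified"
        host = None
    if host:
        call.host_gene, call.host_transcript = host
    return call


def novel_site_mrna_position(call: CrypticJunctionCall, ann: GenomeAnnotation) -> int:
    """mRNA coordinate of the novel splice-site boundary on the host
    transcript (number of retained upstream bases for a donor; position
    of the first retained base for an acceptor)."""
    if call.host_transcript is None:
        raise ValueError("call has no host transcript")
    t = ann.transcripts[call.host_transcript]
    j = call.junction
    if call.novel_end == "donor":
        exon_side = j.donor - 1 if j.strand == "+" else j.donor
        return genome_to_mrna(t, exon_side) + 1
    if call.novel_end == "acceptor":
        first_exonic = j.acceptor if j.strand == "+" else j.acceptor - 1
        return genome_to_mrna(t, first_exonic)
    raise ValueError(f"novel_end={call.novel_end!r}: no single novel site")


def boundary_distance(
    call: CrypticJunctionCall, ann: GenomeAnnotation, cfg: PipelineConfig = PipelineConfig(),
) -> CrypticJunctionCall:
    """Signed mRNA-space distance from the novel site to the nearest
    annotated exon-exon junction of the host transcript (negative =
    upstream), plus the EJC-footprint flag (site within
    ``ejc_offset +/- ejc_footprint_halfwidth`` upstream of a junction).
    """
    from crypticsplice.resplice_scan import map_junctions_to_mrna

    t = ann.transcripts[call.host_transcript]
    spos = novel_site_mrna_position(call, ann)
    junctions = map_junctions_to_mrna(t)
    if not junctions:
        call.boundary_distance = None
        return call
    dists = [spos - jc for jc in junctions]
    call.boundary_distance = min(dists, key=lambda d: (abs(d), d))
    lo = -cfg.ejc_offset - cfg.ejc_footprint_halfwidth
    hi = -cfg.ejc_offset + cfg.ejc_footprint_halfwidth
    call.within_ejc_footprint = any(lo <= d <= hi for d in dists)
    return call


def attach_scores(
    calls: list[CrypticJunctionCall],
    ann: GenomeAnnotation,
    g: GenomeSequence,
    donor_pwm: PositionWeightMatrix,
    acceptor_pwm: PositionWeightMatrix,
) -> list[CrypticJunctionCall]:
    """Score each call's novel splice site on its mRNA context.

    The window is taken from the reconstructed mature mRNA of the host
    transcript when the site is exonic (so the cryptic intron side reads
    canonical-exon sequence, as seen by the splicing machinery on the
    mRNA); intronic or host-less sites fall back to genomic context.
    """
    mrna_cache: dict[str, str] = {}
    for call in calls:
        j = call.junction
        if call.novel_end not in ("donor", "acceptor"):
            continue
        pwm = donor_pwm if call.novel_end == "donor" else acceptor_pwm
        window = None
        if call.host_transcript and call.css_class.startswith("exonic"):
            t = ann.transcripts[call.host_transcript]
            seq = mrna_cache.setdefault(t.transcript_id, transcript_sequence(t, g))
            pos = novel_site_mrna_position(call, ann)
            if call.novel_end == "donor":
                lo, hi = pos - 3, pos + 6
            else:
                lo, hi = pos - 14, pos + 3
            if 0 <= lo and hi <= len(seq):
                window = seq[lo:hi]
        if window is None:
            boundary = j.donor if call.novel_end == "donor" else j.acceptor
            fn = donor_window if call.novel_end == "donor" else acceptor_window
            window, clipped = fn(g, j.chrom, j.strand, boundary)
            if clipped:
                call.ss_score = SpliceSiteScore.na()
                continue
        call.ss_score = score_site(pwm, window)
    return calls


def overlap_permutation_test(
    sets: list[set], universe: set, n_perm: int, seed: int = 0,
) -> tuple[float, int]:
    """Permutation test for the k-way overlap of junction sets.

    The null re-draws each set as a uniform random subset of the
    universe of the same size and records the intersection size.
    Sampling uses the exact sequential-hypergeometric equivalent of
    drawing the subsets literally (the intersection of a uniform random
    size-a subset with a fixed size-m set is hypergeometric, and given
    its size the running intersection is again a uniform subset), which
    makes very large ``n_perm`` tractable. Returns
    ``(p_value, observed_overlap)`` with the +1 Monte-Carlo correction.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    for i, s in enumerate(sets):
        if not s <= universe:
            raise ValueError(f"set {i} is not a subset of the universe")
    observed = len(set.intersection(*[set(s) for s in sets])) if sets else 0
    n = len(universe)
    rng = np.random.default_rng(seed)
    sizes = [len(s) for s in sets]
    inter = np.full(n_perm, sizes[0] if sizes else 0, dtype=np.int64)
    for size in sizes[1:]:
        # |running ∩ new| ~ Hypergeometric(ngood=running, nbad=n-running, k=size)
        inter = rng.hypergeometric(inter, n - inter, size)
    p = (1 + int((inter >= observed).sum())) / (1 + n_perm)
    return p, observed


def exact_two_set_overlap_pvalue(size_a: int, size_b: int, n: int, observed: int) -> float:
    """Closed-form hypergeometric upper tail P(|A∩B| >= observed) for two
    random subsets of a size-n universe (independent cross-check)."""
    return float(stats.hypergeom.sf(observed - 1, n, size_a, size_b))


def calls_to_tsv(calls: list[CrypticJunctionCall], path: str) -> None:
    """Write the cryptic-call catalogue (TSV, one row per call)."""
    import pandas as pd

    rows = []
    for c in calls:
        row = {
            "chrom": c.junction.chrom, "strand": c.junction.strand,
            "donor": c.junction.donor, "acceptor": c.junction.acceptor,
            "intron_start": c.junction.start, "intron_end": c.junction.end,
            "host_gene": c.host_gene or "", "host_transcript": c.host_transcript or "",
            "novel_end": c.novel_end, "css_class": c.css_class,
            "aggregate_reads": c.aggregate_reads,
            "boundary_distance": "" if c.boundary_distance is None else c.boundary_distance,
            "within_ejc_footprint": int(c.within_ejc_footprint),
            "ss_score": "" if c.ss_score is None or c.ss_score.missing
                        else f"{c.ss_score.normalized:.4f}",
            "bp_best_match": "" if c.bp_best_match is None else f"{c.bp_best_match:.4f}",
        }
        for cond, v in sorted(c.count_fc.items()):
            row[f"count_fc_{cond}"] = f"{v:.4f}"
        for cond, v in sorted(c.psi_fc.items()):
            row[f"psi_fc_{cond}"] = f"{v:.4f}"
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def calls_from_tsv(path: str) -> list[CrypticJunctionCall]:
    """Read a catalogue written by :func:`calls_to_tsv` (fold-change
    columns are restored from their per-condition columns)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    fc_conds = [c[len("count_fc_"):] for c in df.columns if c.startswith("count_fc_")]
    calls = []
    for r in df.itertuples():
        call = CrypticJunctionCall(
            junction=Junction(r.chrom, r.strand, int(r.intron_start), int(r.intron_end)),
            aggregate_reads=int(r.aggregate_reads),
            count_fc={c: float(getattr(r, f"count_fc_{c}")) for c in fc_conds},
            psi_fc={c: float(getattr(r, f"psi_fc_{c}")) for c in fc_conds},
            host_gene=r.host_gene or None,
            host_transcript=r.host_transcript or None,
            novel_end=r.novel_end, css_class=r.css_class,
            boundary_distance=None if r.boundary_distance == "" else int(r.boundary_distance),
            within_ejc_footprint=bool(int(r.within_ejc_footprint)),
        )
        if r.ss_score != "":
            call.ss_score = SpliceSiteScore(raw=float("nan"), normalized=float(r.ss_score))
        if r.bp_best_match != "":
            call.bp_best_match = float(r.bp_best_match)
        calls.append(call)
    return calls


def calls_to_bed(calls: list[CrypticJunctionCall], path: str) -> None:
    """BED6 of the novel splice-site positions (one line per call with a
    single novel end)."""
    with open(path, "w") as fh:
        for c in calls:
            if c.novel_end not in ("donor", "acceptor"):
                continue
            pos = _novel_site_query_pos(c.junction, c.novel_end)
            name = f"{c.css_class}|{c.host_gene or 'NA'}"
            fh.write(f"{c.junction.chrom}\t{pos}\t{pos + 1}\t{name}\t0\t{c.junction.strand}\n")
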