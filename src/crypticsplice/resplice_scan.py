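"""Re-splicing potential: regenerated splice sites at exon-exon
junctions and the coding consequences of predicted mRNA re-splicing.

Intron removal can regenerate a splice-site mimic at the resulting
exon-exon junction: an upstream exon ending ...AG regenerates a 3'
splice site, a downstream exon beginning GT... regenerates a 5' splice
site. When a cryptic exonic site is paired with such a regenerated
partner, a second splicing event on the already-mature mRNA (re-splicing)
would delete the intervening mRNA segment. Compatibility is decided on
the invariant dinucleotide alone; PWM scores are attached for reporting
but not thresholded, because validated functional regenerated sites can
score near the bottom of the scale.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq

from crypticsplice.annotation_io import (
    GenomeAnnotation,
    GenomeSequence,
    TranscriptModel,
    genome_to_mrna,
    transcript_sequence,
)
from crypticsplice.cryptic_discovery import CrypticJunctionCall, novel_site_mrna_position
from crypticsplice.splice_motifs import (
    ACCEPTOR_EXONIC,
    ACCEPTOR_INTRONIC,
    DONOR_EXONIC,
    DONOR_INTRONIC,
    PositionWeightMatrix,
    SpliceSiteScore,
    score_site,
)


@dataclass(frozen=True)
class RegeneratedSite:
    """A splice-site mimic at an mRNA exon-exon junction."""

    transcript_id: str
    junction_index: int          # 0-based along the mRNA
    mrna_position: int           # boundary coordinate on the mRNA
    site_type: str               # regenerated_5ss | regenerated_3ss
    dinucleotide_ok: bool
    score: SpliceSiteScore


@dataclass
class ResplicingEvent:
    """A cryptic site paired with a regenerated partner site, with the
    mRNA deletion it would produce."""

    cryptic_call: CrypticJunctionCall
    partner: RegeneratedSite
    deletion_span_mrna: tuple[int, int]
    deletion_length: int
    intermediate_junctions: tuple[int, ...] = ()
    frame_consequence: str | None = None
    aa_deleted: int | None = None


def map_junctions_to_mrna(t: TranscriptModel) -> list[int]:
    """mRNA coordinates of the transcript's exon-exon junctions
    (cumulative exon lengths; empty for single-exon transcripts)."""
    coords, acc = [], 0
    for s, e in t.exons[:-1]:
        acc += e - s
        coords.append(acc)
    return coords


def detect_regenerated_sites(
    t: TranscriptModel,
    g: GenomeSequence,
    donor_pwm: PositionWeightMatrix,
    acceptor_pwm: PositionWeightMatrix,
    mrna: str | None = None,
) -> list[RegeneratedSite]:
    """Survey every exon-exon junction of a transcript for regenerated
    donor (GT immediately downstream) and acceptor (AG immediately
    upstream) mimics, scoring each on the mRNA window spanning the
    junction. Windows clipped at transcript ends give missing scores."""
    seq = transcript_sequence(t, g) if mrna is None else mrna
    sites = []
    for idx, pos in enumerate(map_junctions_to_mrna(t)):
        gt_ok = seq[pos:pos + 2] == "GT"
        lo, hi = pos - DONOR_EXONIC, pos + DONOR_INTRONIC
        dscore = (score_site(donor_pwm, seq[lo:hi])
                  if lo >= 0 and hi <= len(seq) else SpliceSiteScore.na())
        sites.append(RegeneratedSite(t.transcript_id, idx, pos,
                                     "regenerated_5ss", gt_ok, dscore))
        ag_ok = seq[max(pos - 2, 0):pos] == "AG"
        lo, hi = pos - ACCEPTOR_INTRONIC, pos + ACCEPTOR_EXONIC
        ascore = (score_site(acceptor_pwm, seq[lo:hi])
                  if lo >= 0 and hi <= len(seq) else SpliceSiteScore.na())
        sites.append(RegeneratedSite(t.transcript_id, idx, pos,
                                     "regenerated_3ss", ag_ok, ascore))
    return sites


def _junction_index_for_intron(t: TranscriptModel, intron: tuple[int, int]) -> int | None:
    """Index (transcript order) of the mRNA junction formed by removing
    the given genomic intron, or None if the intron is not in t."""
    introns_genomic = t.introns()
    if intron not in introns_genomic:
        return None
    i = introns_genomic.index(intron)
    # introns() is in ascending genomic order; transcript order reverses
    # this on the minus strand.
    return i if t.strand == "+" else len(introns_genomic) - 1 - i


def resplicing_compatibility(
    call: CrypticJunctionCall,
    ann: GenomeAnnotation,
    g: GenomeSequence,
    donor_pwm: PositionWeightMatrix,
    acceptor_pwm: PositionWeightMatrix,
) -> list[ResplicingEvent]:
    """Pair an exonic cryptic call with its regenerated partner site.

    For a cryptic donor (exonic_5ss) joined to annotated acceptor A, the
    partner is the regenerated 3' site at the mRNA junction formed by
    removal of the intron ending at A; for a cryptic acceptor
    (exonic_3ss) joined to annotated donor D, the partner is the
    regenerated 5' site at the junction formed by removal of the intron
    starting at D. An event is emitted iff the partner's invariant
    dinucleotide is present. Events are computed per host transcript,
    de-duplicated by mRNA sequence context, and sorted by partner score
    descending; spans touching a transcript end are dropped.
    """
    if call.css_class not in ("exonic_5ss", "exonic_3ss"):
        return []
    j = call.junction
    if call.css_class == "exonic_5ss":
        anchored = ann.transcripts_with_acceptor(j.chrom, j.strand, j.acceptor)
        want_type = "regenerated_3ss"
    else:
        anchored = ann.transcripts_with_donor(j.chrom, j.strand, j.donor)
        want_type = "regenerated_5ss"
    if not anchored:
        raise ValueError(f"no host transcript carries the annotated end of {j}")

    events, seen_context = [], set()
    for tid in sorted(set(anchored)):
        t = ann.transcripts[tid]
        if j.strand == "+":
            # the annotated intron sharing the annotated end
            cands = [iv for iv in t.introns()
                     if (iv[1] == j.end if call.css_class == "exonic_5ss" else iv[0] == j.start)]
        else:
            cands = [iv for iv in t.introns()
                     if (iv[0] == j.start if call.css_class == "exonic_5ss" else iv[1] == j.end)]
        if not cands:
            continue
        jidx = _junction_index_for_intron(t, cands[0])
        if jidx is None:
            continue
        mrna = transcript_sequence(t, g)
        sites = [s for s in detect_regenerated_sites(t, g, donor_pwm, acceptor_pwm, mrna=mrna)
                 if s.junction_index == jidx and s.site_type == want_type]
        if not sites or not sites[0].dinucleotide_ok:
            continue
        partner = sites[0]
        tmp = CrypticJunctionCall(
            junction=j, aggregate_reads=call.aggregate_reads,
            count_fc=call.count_fc, psi_fc=call.psi_fc,
            host_transcript=tid, novel_end=call.novel_end,
            css_class=call.css_class,
        )
        try:
            cpos = novel_site_mrna_position(tmp, ann)
        except Exception:
            continue
        if call.css_class == "exonic_5ss":
            span = (cpos, partner.mrna_position)
        else:
            span = (partner.mrna_position, cpos)
        if span[1] <= span[0]:
            continue
        if span[0] <= 0 or span[1] >= t.length:
            continue  # span touches a transcript end
        context = mrna[max(span[0] - 20, 0):span[0]] + "|" + mrna[span[1]:span[1] + 20]
        if context in seen_context:
            continue
        seen_context.add(context)
        inter = tuple(i for i, p in enumerate(map_junctions_to_mrna(t))
                      if span[0] < p < span[1] and i != jidx)
        events.append(ResplicingEvent(
            cryptic_call=call, partner=partner,
            deletion_span_mrna=span, deletion_length=span[1] - span[0],
            intermediate_junctions=inter,
        ))
    events.sort(key=lambda e: (-(e.partner.score.normalized
                                 if not e.partner.score.missing else -1.0),
                               e.partner.transcript_id))
    return events


def _cds_mrna_range(t: TranscriptModel) -> tuple[int, int] | None:
    """CDS extent on the mRNA, [start, end), or None without CDS."""
    if not t.cds:
        return None
    positions = []
    for s, e in t.cds:
        positions.append(genome_to_mrna(t, s))
        positions.append(genome_to_mrna(t, e - 1))
    lo, hi = min(positions), max(positions) + 1
    return lo, hi


def consequence(event: ResplicingEvent, t: TranscriptModel, g: GenomeSequence) -> ResplicingEvent:
    """Annotate the reading-frame consequence of the predicted deletion.

    The deletion span is intersected with the CDS (in mRNA coordinates):
    no CDS or no overlap -> ``noncoding``; overlap that includes the
    start or stop codon -> ``spans_start_or_stop``; fully inside the CDS
    with length % 3 == 0 -> ``in_frame_deletion`` with ``aa_deleted``
    from translating the reference and deleted CDS and differencing the
    peptides (codon-phase aware); otherwise ``frameshift``.
    """
    s, e = event.deletion_span_mrna
    if not (0 <= s < e <= t.length):
        raise ValueError(f"deletion span {event.deletion_span_mrna} outside transcript")
    rng = _cds_mrna_range(t)
    if rng is None or e <= rng[0] or s >= rng[1]:
        event.frame_consequence = "noncoding"
        return event
    cds_lo, cds_hi = rng
    if s < cds_lo + 3 or e > cds_hi - 3:
        # removes (part of) the start or stop codon, or extends past it
        event.frame_consequence = "spans_start_or_stop"
        return event
    if (e - s) % 3 != 0:
        event.frame_consequence = "frameshift"
        return event
    mrna = transcript_sequence(t, g)
    ref_cds = mrna[cds_lo:cds_hi]
    alt_cds = mrna[cds_lo:s] + mrna[e:cds_hi]
    ref_aa = str(Seq(ref_cds[: len(ref_cds) - len(ref_cds) % 3]).translate(to_stop=True))
    alt_aa = str(Seq(alt_cds[: len(alt_cds) - len(alt_cds) % 3]).translate(to_stop=True))
    event.frame_consequence = "in_frame_deletion"
    # peptide-length difference; exceeds length/3 only if the new
    # junctional codon introduced a premature stop
    event.aa_deleted = len(ref_aa) - len(alt_aa)
    return event


def respliced_mrna(event: ResplicingEvent, t: TranscriptModel, g: GenomeSequence) -> str:
    """The predicted re-spliced mRNA product (deletion span removed)."""
    mrna = transcript_sequence(t, g)
    s, e = event.deletion_span_mrna
    return mrna[:s] + mrna[e:]


def events_to_tsv(events: list[ResplicingEvent], path: str) -> None:
    import pandas as pd

    rows = []
    for ev in events:
        rows.append({
            "transcript": ev.partner.transcript_id,
            "junction_index": ev.partner.junction_index,
            "site_type": ev.partner.site_type,
            "dinucleotide_ok": int(ev.partner.dinucleotide_ok),
            "partner_score": "" if ev.partner.score.missing
                             else f"{ev.partner.score.normalized:.4f}",
            "css_class": ev.cryptic_call.css_class,
            "deletion_start": ev.deletion_span_mrna[0],
            "deletion_end": ev.deletion_span_mrna[1],
            "deletion_length": ev.deletion_length,
            "intermediate_junctions": ",".join(map(str, ev.intermediate_junctions)),
            "frame_consequence": ev.frame_consequence or "",
            "aa_deleted": "" if ev.aa_deleted is None else ev.aa_deleted,
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
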