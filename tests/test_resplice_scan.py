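"""Regenerated splice sites, re-splicing compatibility and coding
consequences."""

import numpy as np
import pytest

from crypticsplice.annotation_io import (
    TranscriptModel,
    mrna_to_genome,
    transcript_sequence,
)
from crypticsplice.resplice_scan import (
    ResplicingEvent,
    RegeneratedSite,
    consequence,
    detect_regenerated_sites,
    map_junctions_to_mrna,
    respliced_mrna,
)
from crypticsplice.splice_motifs import train_pwm
from crypticsplice.synthetic_data import SimulationConfig, plant_resplice_fixture
from tests.conftest import write_genome

DONOR_PWM = train_pwm(["AGGGTAAGT"] * 20, kind="donor", exonic_up=3)
ACCEPTOR_PWM = train_pwm(["T" * 11 + "CAGGAA"] * 20, kind="acceptor", exonic_down=3)


def test_junction_positions_are_cumulative_exon_lengths():
    t = TranscriptModel("t", "g", "c", "+",
                        exons=((0, 100), (200, 250), (300, 325)))
    assert map_junctions_to_mrna(t) == [100, 150]
    single = TranscriptModel("t", "g", "c", "+", exons=((0, 50),))
    assert map_junctions_to_mrna(single) == []


def test_minus_strand_junctions_match_sequence_switch(tmp_path):
    rng = np.random.default_rng(9)
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 300)])
    g = write_genome(tmp_path, {"c1": seq})
    t = TranscriptModel("t", "g", "c1", "-", exons=((0, 40), (100, 160), (200, 260)))
    mrna = transcript_sequence(t, g)
    # rebuilding the mRNA exon by exon must switch source exactly at the
    # reported junction coordinates
    pieces = [g.fetch("c1", s, e, "-") for s, e in t.exons]
    cuts = map_junctions_to_mrna(t)
    assert mrna[:cuts[0]] == pieces[0]
    assert mrna[cuts[0]:cuts[1]] == pieces[1]
    assert mrna[cuts[1]:] == pieces[2]


def _transcript_with_junction_context(tmp_path, up_tail, down_head):
    """Two-exon plus-strand transcript whose exon 1 ends with
    ``up_tail`` and exon 2 begins with ``down_head``."""
    rng = np.random.default_rng(1)
    e1 = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 30 - len(up_tail))]) + up_tail
    e2 = down_head + "".join(np.array(list("ACGT"))[rng.integers(0, 4, 30 - len(down_head))])
    intron = "GT" + "A" * 40 + "AG"
    seq = e1 + intron + e2
    g = write_genome(tmp_path, {"c1": seq})
    t = TranscriptModel("t", "g", "c1", "+", exons=((0, 30), (74, 104)))
    return t, g


@pytest.mark.parametrize("up_tail,down_head,want", [
    ("TTAG", "CCCC", {"regenerated_3ss": True, "regenerated_5ss": False}),
    ("TTTT", "GTAAGT", {"regenerated_3ss": False, "regenerated_5ss": True}),
    ("TTTT", "AAAA", {"regenerated_3ss": False, "regenerated_5ss": False}),
])
def test_regenerated_dinucleotide_detection(tmp_path, up_tail, down_head, want):
    t, g = _transcript_with_junction_context(tmp_path, up_tail, down_head)
    sites = detect_regenerated_sites(t, g, DONOR_PWM, ACCEPTOR_PWM)
    flags = {s.site_type: s.dinucleotide_ok for s in sites}
    assert flags == want
    assert all(s.junction_index == 0 and s.mrna_position == 30 for s in sites)


def test_fixture_pipeline_emits_both_resplicing_topologies(resplice_run):
    events = resplice_run.events
    assert len(events) == 2
    by_tid = {e.partner.transcript_id: e for e in events}
    a = by_tid["reA.t1"]  # cryptic 3' SS + regenerated 5' SS, 54 nt
    assert a.partner.site_type == "regenerated_5ss"
    assert a.deletion_length == 54
    assert a.frame_consequence == "in_frame_deletion" and a.aa_deleted == 18
    b = by_tid["reB.t1"]  # cryptic 5' SS + regenerated 3' SS, 110 nt
    assert b.partner.site_type == "regenerated_3ss"
    assert b.deletion_length == 110
    assert b.frame_consequence == "frameshift"


def test_mutated_remnants_abolish_events(tmp_path_factory):
    from tests.conftest import PipelineRun

    out = tmp_path_factory.mktemp("simresplice_neg")
    ds = plant_resplice_fixture(SimulationConfig(seed=3), outdir=out,
                                mutate_remnants=True)
    run = PipelineRun(ds, out, seed=3)
    # the cryptic junctions are still called, but no regenerated partner
    assert {c.css_class for c in run.calls} == {"exonic_3ss", "exonic_5ss"}
    assert run.events == []


def _coding_transcript(tmp_path, n_codons=120):
    rng = np.random.default_rng(21)
    stopfree = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
                if a + b + c not in ("TAA", "TAG", "TGA")]
    cds = "".join(stopfree[i] for i in rng.integers(0, 61, n_codons))
    mrna = "AAAAAACCCCC" + "ATG" + cds + "TAAGGGGG"
    g = write_genome(tmp_path, {"c1": mrna})
    t = TranscriptModel("t", "g", "c1", "+", exons=((0, len(mrna)),),
                        cds=((11, 11 + 3 + len(cds) + 3),))
    return t, g


def _event(span):
    partner = RegeneratedSite("t", 0, span[0], "regenerated_5ss", True, None)
    return ResplicingEvent(cryptic_call=None, partner=partner,
                           deletion_span_mrna=span,
                           deletion_length=span[1] - span[0])


def test_inframe_deletion_reports_amino_acids_removed(tmp_path):
    t, g = _coding_transcript(tmp_path)
    start = 11 + 3 + 30  # codon-aligned, inside CDS
    ev = consequence(_event((start, start + 54)), t, g)
    assert ev.frame_consequence == "in_frame_deletion"
    assert ev.aa_deleted == 18


def test_frameshift_and_boundary_cases(tmp_path):
    t, g = _coding_transcript(tmp_path)
    start = 11 + 3 + 30
    ev = consequence(_event((start, start + 91)), t, g)
    assert ev.frame_consequence == "frameshift"
    # deletion overlapping the start codon
    ev = consequence(_event((5, 20)), t, g)
    assert ev.frame_consequence == "spans_start_or_stop"
    # deletion entirely in the 5' UTR has no coding consequence
    ev = consequence(_event((0, 6)), t, g)
    assert ev.frame_consequence == "noncoding"
    with pytest.raises(ValueError):
        consequence(_event((10, 10**6)), t, g)


def test_translation_oracle_agrees_with_frame_arithmetic(tmp_path):
    """Frame calls from span arithmetic match direct translation of the
    reference and deleted CDS over random in-CDS deletions."""
    from Bio.Seq import Seq

    t, g = _coding_transcript(tmp_path, n_codons=200)
    cds_lo, cds_hi = 11, 11 + 3 + 600 + 3
    mrna = transcript_sequence(t, g)
    rng = np.random.default_rng(77)
    for _ in range(300):
        s = int(rng.integers(cds_lo + 3, cds_hi - 40))
        ln = int(rng.integers(3, 36))
        e = min(s + ln, cds_hi - 3)
        ev = consequence(_event((s, e)), t, g)
        ref = str(Seq(mrna[cds_lo:cds_hi]).translate(to_stop=True))
        alt_cds = mrna[cds_lo:s] + mrna[e:cds_hi]
        alt = str(Seq(alt_cds[:len(alt_cds) - len(alt_cds) % 3]).translate(to_stop=True))
        if (e - s) % 3 != 0:
            assert ev.frame_consequence == "frameshift"
        else:
            assert ev.frame_consequence == "in_frame_deletion"
            assert ev.aa_deleted == len(ref) - len(alt)


def remap_deletion_to_genome(t: TranscriptModel, span) -> tuple[int, int]:
    """Independent oracle: genomic (donor, acceptor) boundaries of the
    junction created by deleting ``span`` from the mature mRNA."""
    s, e = span
    if t.strand == "+":
        return mrna_to_genome(t, s - 1) + 1, mrna_to_genome(t, e)
    return mrna_to_genome(t, s - 1), mrna_to_genome(t, e) + 1


@pytest.mark.parametrize("run_name", ["resplice_run", "noise_free_run"])
def test_resplicing_events_remap_to_cryptic_junction(request, run_name):
    run = request.getfixturevalue(run_name)
    assert run.events or run_name == "noise_free_run"
    for ev in run.events:
        t = run.ann.transcripts[ev.partner.transcript_id]
        donor_b, acceptor_b = remap_deletion_to_genome(t, ev.deletion_span_mrna)
        j = ev.cryptic_call.junction
        assert (donor_b, acceptor_b) == (j.donor, j.acceptor)
        # and the respliced product is the mRNA minus the span
        prod = respliced_mrna(ev, t, run.genome)
        assert len(prod) == t.length - ev.deletion_length
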