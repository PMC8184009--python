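"""Filter cascade, classification, metagene distances and the overlap
permutation test."""

import numpy as np
import pandas as pd
import pytest

from crypticsplice.annotation_io import GenomeAnnotation, TranscriptModel
from crypticsplice.cryptic_discovery import (
    CrypticJunctionCall,
    ExperimentDesign,
    PipelineConfig,
    boundary_distance,
    classify,
    exact_two_set_overlap_pvalue,
    filter_cryptic,
    identify_novel,
    overlap_permutation_test,
)
from crypticsplice.junction_quant import (
    Junction,
    JunctionCountMatrix,
    compute_psi,
    normalize_counts,
)
from crypticsplice.synthetic_data import (
    PlantedSpec,
    SimulationConfig,
    generate_count_matrix,
)
from tests.conftest import build_classification_toy

ANN, _ = build_classification_toy()
DESIGN = ExperimentDesign(control_samples=("ctrl",),
                          kd_conditions={"k1": ("k1",), "k2": ("k2",), "k3": ("k3",)})


def _matrix(rows, juncs, depth=10**6):
    samples = ["ctrl", "k1", "k2", "k3"]
    m = JunctionCountMatrix(
        junctions=juncs, samples={s: s for s in samples},
        raw=pd.DataFrame(rows, columns=samples),
        library_sizes=pd.Series({s: depth for s in samples}))
    normalize_counts(m)
    compute_psi(m)
    return m


def test_identify_novel_by_junction_quadruple():
    juncs = [
        Junction("chr1", "+", 100, 200),   # annotated pair
        Junction("chr1", "+", 100, 400),   # known ends, novel connectivity
        Junction("chr1", "+", 33, 44),     # both ends unannotated
    ]
    ann_flags = identify_novel(juncs, ANN)
    assert ann_flags[juncs[0]] is True
    assert ann_flags[juncs[1]] is False
    assert ann_flags[juncs[2]] is False


def test_aggregate_read_floor():
    # novel junction with 4 total reads: removed at step 1 even with
    # infinite fold change
    j = [Junction("chr1", "+", 50, 200)]
    m = _matrix([[0, 2, 2, 0]], j)
    calls, wf = filter_cryptic(m, DESIGN, ANN)
    assert calls == [] and wf["aggregate_reads"] == 0
    m = _matrix([[0, 3, 2, 0]], j)
    calls, wf = filter_cryptic(m, DESIGN, ANN)
    assert wf["aggregate_reads"] == 1 and len(calls) == 1


def test_count_fold_change_with_pseudocount():
    # ctrl CPM 0, KD CPMs (9,9,0), pseudocount 1 -> ratios (10,10,1):
    # passes in exactly 2/3 conditions
    j = [Junction("chr1", "+", 50, 200)]
    m = _matrix([[0, 9, 9, 0]], j)
    calls, wf = filter_cryptic(m, DESIGN, ANN)
    assert wf["count_fc"] == 1
    assert calls[0].count_fc == {"k1": pytest.approx(10.0),
                                 "k2": pytest.approx(10.0),
                                 "k3": pytest.approx(1.0)}


def test_psi_fold_change_blocks_small_usage_shifts():
    # counts give PSI ctrl 0.10, KDs (0.15, 0.12, 0.11): all PSI ratios
    # below 2 -> excluded at step 3 despite passing the count filter
    cr = Junction("chr1", "+", 50, 200)      # shares acceptor 200
    ref = Junction("chr1", "+", 100, 200)
    rows = [[10, 60, 48, 44], [90, 340, 352, 356]]
    m = _matrix(rows, [cr, ref])
    psi = m.psi.loc[0].tolist()
    assert psi == [pytest.approx(0.10), pytest.approx(0.15),
                   pytest.approx(0.12), pytest.approx(0.11)]
    calls, wf = filter_cryptic(m, DESIGN, ANN)
    assert wf["count_fc"] >= 1 and wf["psi_fc"] == 0 and calls == []


def test_filter_monotonicity_raising_thresholds_never_adds_calls():
    rng = np.random.default_rng(8)
    juncs = [Junction("chr1", "+", 3 * i, 800) for i in range(40)]
    rows = rng.integers(0, 40, size=(40, 4))
    m = _matrix(rows, juncs)
    base = PipelineConfig()
    baseline = {c.junction.key for c in filter_cryptic(m, DESIGN, ANN, base)[0]}
    for kw in ({"min_aggregate_reads": 20}, {"count_fc_threshold": 4.0},
               {"psi_fc_threshold": 4.0}, {"min_concordant_kd": 3}):
        cfg = PipelineConfig(**kw)
        stricter = {c.junction.key for c in filter_cryptic(m, DESIGN, ANN, cfg)[0]}
        assert stricter <= baseline


def test_classification_is_total_and_matches_construction():
    ann, labelled = build_classification_toy()
    for j, want_class, want_end in labelled:
        call = CrypticJunctionCall(junction=j, aggregate_reads=10,
                                   count_fc={}, psi_fc={})
        classify(call, ann)
        if want_class == "annotated":
            assert call.css_class == "unclassified" and call.novel_end == "neither"
        else:
            assert call.css_class == want_class, j
            assert call.novel_end == want_end, j
        # totality: a single valid label, always
        assert call.css_class in ("exonic_5ss", "exonic_3ss", "intronic_5ss",
                                  "intronic_3ss", "novel_alternative", "unclassified")


def test_host_gene_prefers_longest_transcript_then_gene_id():
    t_long = TranscriptModel("tL", "gB", "c", "+", exons=((0, 100), (200, 400)))
    t_short = TranscriptModel("tS", "gA", "c", "+", exons=((50, 100), (200, 300)))
    ann = GenomeAnnotation.from_transcripts([t_long, t_short])
    call = CrypticJunctionCall(junction=Junction("c", "+", 100, 250),
                               aggregate_reads=10, count_fc={}, psi_fc={})
    classify(call, ann)
    assert call.css_class == "exonic_3ss"
    assert (call.host_gene, call.host_transcript) == ("gB", "tL")


def test_boundary_distance_in_mrna_space():
    t = TranscriptModel("t", "g", "c", "+", exons=((0, 100), (200, 300), (400, 500)))
    ann = GenomeAnnotation.from_transcripts([t])
    # novel acceptor 30 nt before the second exon's end: mRNA position
    # 170, nearest junction at 200 -> -30
    call = CrypticJunctionCall(junction=Junction("c", "+", 100, 270),
                               aggregate_reads=9, count_fc={}, psi_fc={})
    classify(call, ann)
    boundary_distance(call, ann)
    assert call.boundary_distance == -30
    assert call.within_ejc_footprint  # -30 is within 24 +/- 10 upstream
    # novel donor exactly at a junction boundary -> 0
    call2 = CrypticJunctionCall(junction=Junction("c", "+", 300, 400),
                                aggregate_reads=9, count_fc={}, psi_fc={})
    call2.novel_end, call2.css_class, call2.host_transcript = "donor", "exonic_5ss", "t"
    boundary_distance(call2, ann)
    assert call2.boundary_distance == 0


def test_null_cascade_specificity_below_five_percent():
    """Junctions expressed at the normal annotated scale with no
    condition effect are almost never emitted."""
    plan = tuple(PlantedSpec(cls, 1.0, 0,
                             (10, 50) if "intronic" in cls else (20, 60))
                 for i in range(200)
                 for cls in [["exonic_3ss", "exonic_5ss",
                              "intronic_3ss", "intronic_5ss"][i % 4]])
    cfg = SimulationConfig(seed=17, n_genes=220, noise="nb", nb_dispersion=0.1,
                           planted_cryptic=plan, cryptic_base_count=80)
    m, ds = generate_count_matrix(cfg)
    normalize_counts(m)
    compute_psi(m)
    design = ExperimentDesign.from_conditions(dict(ds.samples), cfg.control)
    calls, _ = filter_cryptic(m, design, ds.annotation)
    assert len(calls) / 200 < 0.05


def test_permutation_trivial_cases():
    universe = set(range(30))
    p, obs = overlap_permutation_test([universe, universe], universe, 500, seed=0)
    assert p == pytest.approx(1.0) and obs == 30
    a, b = set(range(10)), set(range(20, 30))
    p, obs = overlap_permutation_test([a, b], universe, 500, seed=0)
    assert obs == 0 and p == pytest.approx(1.0)
    with pytest.raises(ValueError, match="subset"):
        overlap_permutation_test([{99}], universe, 10, seed=0)


def test_permutation_p_matches_hypergeometric_tail():
    rng = np.random.default_rng(4)
    universe = set(range(400))
    a = set(rng.choice(400, 100, replace=False))
    b = set(rng.choice(400, 80, replace=False))
    obs = len(a & b)
    n_perm = 20_000
    p, _ = overlap_permutation_test([a, b], universe, n_perm, seed=9)
    exact = exact_two_set_overlap_pvalue(100, 80, 400, obs)
    se = np.sqrt(exact * (1 - exact) / n_perm)
    assert abs(p - exact) <= 3 * se + 1 / (n_perm + 1)


def test_permutation_reproducible_given_seed():
    universe = set(range(100))
    a, b, c = set(range(40)), set(range(20, 70)), set(range(10, 60))
    r1 = overlap_permutation_test([a, b, c], universe, 5000, seed=123)
    r2 = overlap_permutation_test([a, b, c], universe, 5000, seed=123)
    assert r1 == r2
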