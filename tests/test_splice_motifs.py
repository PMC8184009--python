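"""PWM training/scoring, branchpoint EM discovery and logo matrices."""

import itertools

import numpy as np
import pytest

from crypticsplice.splice_motifs import (
    PositionWeightMatrix,
    derive_branchpoint_pwm,
    discover_motif,
    nucleotide_content,
    scan_branchpoint,
    score_site,
    train_pwm,
)
from tests.conftest import edit_distance


def _random_windows(rng, n, length):
    return ["".join(np.array(list("ACGT"))[rng.integers(0, 4, length)])
            for _ in range(n)]


def test_consensus_scores_one_anticonsensus_zero():
    pwm = train_pwm(["GTAAGT"] * 50)
    assert score_site(pwm, "GTAAGT").normalized == pytest.approx(1.0)
    anti = "".join("ACGT"[int(np.argmin(col))] for col in pwm.log_odds)
    assert score_site(pwm, anti).normalized == pytest.approx(0.0)
    with pytest.raises(ValueError, match="length"):
        score_site(pwm, "GTAA")


def test_too_few_usable_windows_rejected():
    with pytest.raises(ValueError, match="<10"):
        train_pwm(["ACGTA"] * 5)
    # N-containing windows are dropped before the count check
    with pytest.raises(ValueError):
        train_pwm(["ACGTA"] * 9 + ["ACGTN"] * 20)


def test_n_window_scores_missing():
    pwm = train_pwm(["GTAAGT"] * 20)
    s = score_site(pwm, "GTANGT")
    assert s.missing and np.isnan(s.normalized)


def test_ranking_matches_bruteforce_enumeration():
    rng = np.random.default_rng(6)
    pwm = train_pwm(_random_windows(rng, 60, 5))
    scored = []
    for combo in itertools.product("ACGT", repeat=5):
        w = "".join(combo)
        # independent brute-force: explicit per-position lookup and sum
        raw = sum(pwm.log_odds[k]["ACGT".index(c)] for k, c in enumerate(w))
        scored.append((w, raw, score_site(pwm, w).normalized))
    # normalized scores must be non-increasing along the brute-force
    # order (identical ranking modulo exact float ties)
    by_brute = sorted(scored, key=lambda x: -x[1])
    norms = [n for *_, n in by_brute]
    assert all(a >= b - 1e-12 for a, b in zip(norms, norms[1:]))
    # and strictly ordered pairs stay strictly ordered
    for (w1, b1, n1), (w2, b2, n2) in zip(by_brute, by_brute[1:]):
        if b1 - b2 > 1e-9:
            assert n1 > n2 - 1e-12


def test_normalized_score_invariant_to_columnwise_shift():
    rng = np.random.default_rng(7)
    pwm = train_pwm(_random_windows(rng, 40, 6))
    shifted = PositionWeightMatrix(
        kind=pwm.kind, log_odds=pwm.log_odds + np.array([[1.7]] * 6),
        background=pwm.background)
    for w in _random_windows(rng, 25, 6):
        a = score_site(pwm, w).normalized
        b = score_site(shifted, w).normalized
        assert a == pytest.approx(b, abs=1e-9)


def test_trained_splice_models_recover_planted_consensus(noise_free_run):
    donor, acceptor = noise_free_run.donor_pwm, noise_free_run.acceptor_pwm
    # windows: donor 3 exonic + 6 intronic, acceptor 14 intronic + 3 exonic
    assert donor.width == 9 and acceptor.width == 17
    assert donor.consensus()[3:9] == "GTAAGT"
    assert acceptor.consensus()[11:14] == "CAG"
    # invariant dinucleotide columns carry the most information on the
    # intron side (they are always planted; the extended consensus only
    # with probability ~0.9)
    ic_d = donor.information_content()
    assert min(ic_d[3], ic_d[4]) >= max(ic_d[k] for k in (5, 6, 7, 8))
    ic_a = acceptor.information_content()
    assert min(ic_a[12], ic_a[13]) >= max(ic_a[k] for k in range(11))


def test_annotated_donor_outscores_random_exonic_windows(noise_free_run):
    rng = np.random.default_rng(12)
    run = noise_free_run
    donors = sorted(run.ann.annotated_donors)
    genome = run.genome
    wins = []
    from crypticsplice.splice_motifs import donor_window
    for chrom, strand, pos in donors:
        w, clipped = donor_window(genome, chrom, strand, pos)
        if not clipped:
            wins.append(w)
    better = 0
    n = 1000
    chrom = genome.chrom_names[0]
    L = genome.chrom_length(chrom)
    for k in range(n):
        site = wins[rng.integers(len(wins))]
        start = int(rng.integers(0, L - 9))
        rand = genome.fetch(chrom, start, start + 9)
        s1 = score_site(run.donor_pwm, site)
        s2 = score_site(run.donor_pwm, rand)
        if not s1.missing and not s2.missing and s1.normalized > s2.normalized:
            better += 1
    assert better / n >= 0.95


def test_em_loglik_nondecreasing_and_planted_recovery():
    rng = np.random.default_rng(100)
    wins = []
    for _ in range(200):
        w = list("".join(np.array(list("ACGT"))[rng.integers(0, 4, 30)]))
        off = int(rng.integers(0, 26))
        w[off:off + 5] = "CTAAC"
        wins.append("".join(w))
    pwm, ll, trajs = discover_motif(wins, motif_width=5, seed=0,
                                    return_trajectories=True)
    assert edit_distance(pwm.consensus(), "CTAAC") <= 1
    for tr in trajs:
        assert all(b - a >= -1e-9 for a, b in zip(tr, tr[1:]))


def test_em_degenerate_identical_windows():
    pwm = discover_motif(["ACGTACGTAC"] * 30, motif_width=4, seed=1)
    # consensus must be one of the string's 4-mers
    assert pwm.consensus() in "ACGTACGTAC"
    assert pwm.frequencies.max(axis=1).min() > 0.9


def test_branchpoint_pwm_from_simulated_introns(noise_free_run):
    run = noise_free_run
    pwm = derive_branchpoint_pwm(run.ann, run.genome, motif_width=7, seed=5)
    cons = pwm.consensus()
    best = min(edit_distance(cons[i:i + 5], "CTAAC")
               for i in range(len(cons) - 4))
    assert best <= 1


def test_scan_reports_hits_and_best_match():
    pwm = train_pwm(["CTAAC"] * 25, kind="branchpoint")
    region = "GGGG" + "CTAAC" + "GGGGG"
    hits, best = scan_branchpoint(pwm, region, min_match=0.75)
    assert (4, pytest.approx(1.0)) in [(o, pytest.approx(m)) for o, m in hits]
    assert best[0] == 4 and best[1] == pytest.approx(1.0)
    # a region holding only the anti-consensus yields no hits at 0.75,
    # but the best (sub-threshold) match is still reported
    anti = "".join("ACGT"[int(np.argmin(col))] for col in pwm.log_odds)
    hits, best = scan_branchpoint(pwm, anti, min_match=0.75)
    assert hits == [] and best == (0, pytest.approx(0.0))
    with pytest.raises(ValueError, match="region"):
        scan_branchpoint(pwm, "CT", 0.5)


def test_scan_threshold_monotonicity():
    rng = np.random.default_rng(13)
    pwm = train_pwm(_random_windows(rng, 30, 6), kind="branchpoint")
    region = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 300)])
    hits_low, _ = scan_branchpoint(pwm, region, min_match=0.4)
    hits_high, _ = scan_branchpoint(pwm, region, min_match=0.6)
    assert set(hits_high) <= set(hits_low)


def test_nucleotide_content_examples_and_counting_oracle():
    m = nucleotide_content(["AAAA"] * 7)
    assert np.allclose(m[:, 0], 1.0)
    m = nucleotide_content(["AC", "AG"])
    assert m[0, 0] == pytest.approx(1.0)
    assert m[1, 1] == pytest.approx(0.5) and m[1, 2] == pytest.approx(0.5)
    # N excluded from the column denominator
    m = nucleotide_content(["AN", "AC"])
    assert m[1, 1] == pytest.approx(1.0)
    rng = np.random.default_rng(2)
    wins = _random_windows(rng, 50, 8)
    m = nucleotide_content(wins)
    for k in range(8):
        for b, base in enumerate("ACGT"):
            assert m[k, b] == pytest.approx(
                sum(w[k] == base for w in wins) / 50)
    with pytest.raises(ValueError):
        nucleotide_content([])


def test_pwm_tsv_roundtrip(tmp_path):
    rng = np.random.default_rng(3)
    pwm = train_pwm(_random_windows(rng, 30, 7), kind="donor", exonic_up=3)
    path = tmp_path / "pwm.tsv"
    pwm.to_tsv(path)
    back = PositionWeightMatrix.from_tsv(path)
    assert back.kind == "donor" and back.width == 7 and back.exonic_up == 3
    assert np.allclose(back.log_odds, pwm.log_odds, atol=1e-5)
    for w in _random_windows(rng, 10, 7):
        assert score_site(back, w).normalized == pytest.approx(
            score_site(pwm, w).normalized, abs=1e-4)
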