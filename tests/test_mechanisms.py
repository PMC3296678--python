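import numpy as np
import pytest
from scipy import stats

from intronevo.mechanisms import (adjacent_loss_test, detect_sliding,
                                  detect_tsd, find_direct_repeats,
                                  germline_enrichment, goodness_of_fit,
                                  ks_uniform, repeat_flanking_rate,
                                  scan_insertion_source, shuffle_null_p)
from intronevo.msa import ColumnClass, IntronColumnMap


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


# ---------------------------------------------------------------------------
# KS uniformity
# ---------------------------------------------------------------------------

def test_ks_point_mass_has_d_near_half():
    rep = ks_uniform([0.5] * 40)
    assert rep.statistic == pytest.approx(0.5, abs=0.03)
    assert rep.p_value < 1e-6


def test_ks_near_uniform_grid_not_rejected():
    n = 40
    rep = ks_uniform([(i + 1) / (n + 1) for i in range(n)])
    assert rep.statistic == pytest.approx(1 / (n + 1), abs=1e-9)
    assert rep.p_value > 0.99


def test_ks_matches_scipy_asymptotic(rng):
    for _ in range(25):
        x = rng.random(int(rng.integers(5, 60)))
        rep = ks_uniform(x)
        ref = stats.kstest(x, "uniform", mode="asymp")
        assert rep.statistic == pytest.approx(ref.statistic, rel=1e-10)
        assert rep.p_value == pytest.approx(ref.pvalue, rel=1e-8, abs=1e-12)


def test_ks_requires_five_positions():
    with pytest.raises(ValueError):
        ks_uniform([0.1, 0.2, 0.3, 0.9])


# ---------------------------------------------------------------------------
# chi-square machinery
# ---------------------------------------------------------------------------

def test_germline_chi2_matches_scipy_oracle(rng):
    for _ in range(100):
        a, b = rng.integers(1, 400, size=2)
        n1 = a + int(rng.integers(1, 400))
        n2 = b + int(rng.integers(1, 400))
        rep = germline_enrichment(int(a), n1, int(b), n2)
        table = np.array([[a, n1 - a], [b, n2 - b]])
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        assert rep.statistic == pytest.approx(chi2, rel=1e-10)
        assert rep.p_value == pytest.approx(p, rel=1e-10)


def test_equal_proportions_give_zero_statistic():
    rep = germline_enrichment(50, 100, 500, 1000)
    assert rep.statistic == pytest.approx(0.0, abs=1e-12)
    assert rep.p_value == pytest.approx(1.0)


def test_zero_margin_errors():
    with pytest.raises(ValueError):
        germline_enrichment(0, 10, 0, 20)


def test_adjacent_loss_forced_adjacency():
    # two losses in a two-intron gene are adjacent however they land
    rep = adjacent_loss_test({("g", "b"): [0, 1]}, {"g": 2}, n_perm=200, seed=1)
    assert rep.counts["observed"] == 1
    assert rep.counts["expected"] == pytest.approx(1.0)


def test_adjacent_loss_single_losses_never_adjacent():
    rep = adjacent_loss_test({("g1", "b"): [2], ("g2", "b"): [0]},
                             {"g1": 5, "g2": 4}, n_perm=100, seed=1)
    assert rep.counts["observed"] == 0


def test_goodness_of_fit_reproduces_printed_excess():
    rep = goodness_of_fit(9, 2.7)
    assert rep.statistic == pytest.approx(14.7, abs=1e-9)
    assert rep.p_value == pytest.approx(1.26e-4, rel=1e-2)


# ---------------------------------------------------------------------------
# direct repeats
# ---------------------------------------------------------------------------

def test_exact_repeat_at_5prime_junction_found():
    hits = find_direct_repeats("CCCCCCCCCCACGTA", "ACGTATTTTTTTTTT",
                               "GGGGGGGGGG")
    assert hits and hits[0].seq.startswith("ACGTA")


def test_no_shared_pentamer_empty():
    hits = find_direct_repeats("A" * 30, "G" * 20 + "C" * 20, "T" * 30)
    assert hits == []


def brute_repeats(a, b, min_len):
    found = set()
    for i in range(len(a)):
        for j in range(len(b)):
            k = 0
            while (i + k < len(a) and j + k < len(b) and a[i + k] == b[j + k]):
                k += 1
            if k >= min_len:
                found.add(a[i:i + k])
    return found


def test_repeats_match_brute_force_substring_scan(rng):
    for _ in range(200):
        left = random_seq(rng, 30)
        intron = random_seq(rng, 60)
        right = random_seq(rng, 30)
        hits = find_direct_repeats(left, intron, right, min_len=5, window=30)
        expected = set()
        for s in brute_repeats(left[-30:], intron[:30], 5):
            expected |= {s[i:i + 5] for i in range(len(s) - 4)}
        for s in brute_repeats(intron[-30:], right[:30], 5):
            expected |= {s[i:i + 5] for i in range(len(s) - 4)}
        got = set()
        for h in hits:
            got |= {h.seq[i:i + 5] for i in range(len(h.seq) - 4)}
        assert got == expected


def test_repeat_rate_planted_and_free(rng):
    planted = []
    free = []
    while len(free) < 30:
        left, intron, right = (random_seq(rng, 30), random_seq(rng, 60),
                               random_seq(rng, 30))
        if find_direct_repeats(left, intron, right):
            continue
        free.append((left, intron, right))
        planted.append((left, left[-6:] + intron[6:], right))
    assert repeat_flanking_rate(free) == 0.0
    assert repeat_flanking_rate(planted) == 1.0


def test_repeat_rate_tracks_planting_probability(rng):
    # chance-repeat-free junctions with repeats planted at p = 0.3
    p, n = 0.3, 400
    junctions = []
    n_planted = 0
    while len(junctions) < n:
        left, intron, right = (random_seq(rng, 30), random_seq(rng, 60),
                               random_seq(rng, 30))
        if find_direct_repeats(left, intron, right):
            continue
        if rng.random() < p:
            intron = left[-6:] + intron[6:]
            n_planted += 1
        junctions.append((left, intron, right))
    rate = repeat_flanking_rate(junctions)
    lo, hi = stats.binom.interval(0.99, n, p)
    assert lo / n <= rate <= hi / n


# ---------------------------------------------------------------------------
# TSD detection
# ---------------------------------------------------------------------------

def test_planted_tsd_recovered_exactly(rng):
    tsd = "GTACCGGT"
    element = random_seq(rng, 200)
    intron = tsd + element + tsd + "AG"
    found = detect_tsd("C" * 20, intron, random_seq(rng, 20))
    # a one-mismatch superstring ending in the acceptor may extend the call
    assert found is not None and found.startswith(tsd)


def test_tsd_absent_on_repeat_free_junctions(rng):
    for _ in range(20):
        intron = "GT" + random_seq(rng, 100) + "AG"
        down = random_seq(rng, 20)
        found = detect_tsd("C" * 20, intron, down)
        if found is not None:
            # only acceptable if a chance >=4-mer repeat truly exists
            assert len(found) >= 4


def test_tsd_with_one_mismatch_recovered(rng):
    tsd = "GTACCGGTA"
    mutated = tsd[:4] + ("C" if tsd[4] != "C" else "G") + tsd[5:]
    element = random_seq(rng, 150)
    intron = tsd + element + mutated + "AG"
    found = detect_tsd("C" * 20, intron, random_seq(rng, 20))
    assert found is not None and found.startswith(tsd[:8])


def test_tsd_copy_in_downstream_exon_found(rng):
    tsd = "GTCCAATG"
    element = random_seq(rng, 150)
    intron = tsd + element + "AG"
    down = random_seq(rng, 5) + tsd + random_seq(rng, 10)
    found = detect_tsd("C" * 20, intron, down)
    assert found is not None and found.startswith(tsd)


# ---------------------------------------------------------------------------
# insertion-source scan and shuffle null
# ---------------------------------------------------------------------------

def test_planted_library_slice_found_both_strands(rng):
    lib = {"m": random_seq(rng, 2000)}
    from intronevo.models import revcomp
    fwd = "GT" + lib["m"][300:450] + "AG"
    rev = "GT" + revcomp(lib["m"][600:780]) + "AG"
    for intron, strand in ((fwd, "+"), (rev, "-")):
        hits = scan_insertion_source(intron, lib, "mito_dsbr", "ev")
        assert hits and hits[0].strand == strand
        assert hits[0].coverage_pct >= 90
        assert hits[0].e_value <= 0.1


def test_random_intron_rarely_hits_unrelated_library(rng):
    lib = {f"t{i}": random_seq(rng, 600) for i in range(3)}
    n_hits = 0
    trials = 40
    for _ in range(trials):
        intron = "GT" + random_seq(rng, 200) + "AG"
        if scan_insertion_source(intron, lib, "transposon", "ev"):
            n_hits += 1
    assert n_hits / trials <= 0.05


def test_short_intron_rejected():
    with pytest.raises(ValueError):
        scan_insertion_source("GTAG", {"x": "ACGT" * 100}, "transposon")


def test_shuffle_p_small_for_planted_identity(rng):
    target = random_seq(rng, 400)
    query = target[100:180]
    p = shuffle_null_p(query, target, n_shuffles=199, seed=5)
    assert p == pytest.approx(1 / 200)


def test_shuffle_p_requires_shuffles():
    with pytest.raises(ValueError):
        shuffle_null_p("ACGTACGTACGTACGTACGTA", "ACGT" * 30, n_shuffles=0)


# ---------------------------------------------------------------------------
# sliding
# ---------------------------------------------------------------------------

def _colmap(shift, seq_a, seq_b):
    c1 = ColumnClass("k0", 100, (100, 129), [("spA", 0)])
    c2 = ColumnClass("k1", 100 + shift, (100 + shift, 129 + shift), [("spB", 0)])
    return (IntronColumnMap(columns=[c1, c2]),
            {("spA", 0): seq_a, ("spB", 0): seq_b})


def test_sliding_detected_for_conserved_shifted_intron(rng):
    seq = "GT" + random_seq(rng, 150) + "AG"
    cmap, seqs = _colmap(45, seq, seq)   # 45 cols - 30 marker = 15 nt shift
    hits = detect_sliding(cmap, seqs)
    assert len(hits) == 1
    assert hits[0].shift_cols == 15
    assert hits[0].e_value <= 0.1


def test_sliding_not_called_for_unrelated_introns(rng):
    a = "GT" + random_seq(rng, 150) + "AG"
    b = "GT" + random_seq(rng, 150) + "AG"
    cmap, seqs = _colmap(45, a, b)
    assert detect_sliding(cmap, seqs) == []


def test_small_shift_below_threshold_ignored(rng):
    seq = "GT" + random_seq(rng, 150) + "AG"
    cmap, seqs = _colmap(8, seq, seq)    # overlapping spans: raw shift 8
    assert detect_sliding(cmap, seqs) == []


def test_shared_species_pairs_ignored(rng):
    seq = "GT" + random_seq(rng, 150) + "AG"
    c1 = ColumnClass("k0", 100, (100, 129), [("spA", 0)])
    c2 = ColumnClass("k1", 145, (145, 174), [("spA", 1)])
    cmap = IntronColumnMap(columns=[c1, c2])
    assert detect_sliding(cmap, {("spA", 0): seq, ("spA", 1): seq}) == []
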