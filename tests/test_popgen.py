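"""Alignment- and genotype-based population-genetic statistics."""

import math
import warnings

import numpy as np
import pytest

from nlrdivers.alignment import Alignment, CodonAlignment
from nlrdivers.popgen import (DomainAnnotation, NoAnalyzableSitesError,
                              PopGenError, assign_codon_column_domains,
                              domain_subset, nucleotide_diversity,
                              segregating_sites, sliding_window_stats,
                              stats_from_genotypes, tajima_constants,
                              tajimas_d)
from conftest import random_nt_alignment


def _nt(seqs):
    return Alignment(records=tuple((f"s{i}", s) for i, s in enumerate(seqs)),
                     alphabet="nucleotide")


def brute_force_pair_stats(aln):
    """Oracle: enumerate all sequence pairs over gap-free columns."""
    cols = [j for j in range(aln.length)
            if all(seq[j] in "ACGT" for seq in aln.sequences)]
    n = aln.n_sequences
    diffs = []
    for i in range(n):
        for j in range(i + 1, n):
            a, b = aln.sequences[i], aln.sequences[j]
            diffs.append(sum(a[c] != b[c] for c in cols))
    S = sum(len({seq[c] for seq in aln.sequences}) > 1 for c in cols)
    pi_total = sum(diffs) / len(diffs)
    return len(cols), S, pi_total


def oracle_tajima_d(n, S, pi_total):
    """Independent constant-by-constant evaluation of the D formula."""
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return (pi_total - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


def test_segregating_sites_examples(toy_4x16):
    assert segregating_sites(_nt(["ACGT", "ACGT"])) == 0
    assert segregating_sites(_nt(["AAAA", "AAAT"])) == 1
    assert segregating_sites(toy_4x16) == 2


def test_nucleotide_diversity_examples(toy_4x16):
    two = _nt(["A" * 100, "A" * 97 + "TTT"])
    assert nucleotide_diversity(two) == pytest.approx(0.03)
    assert nucleotide_diversity(_nt(["ACGT"] * 3)) == 0.0
    assert nucleotide_diversity(toy_4x16) == pytest.approx(8 / 6 / 16)


def test_tajimas_d_toy_matches_constants_oracle(toy_4x16):
    res = tajimas_d(toy_4x16)
    assert res.S == 2
    assert res.pi_total == pytest.approx(8 / 6)
    assert res.tajima_d == pytest.approx(oracle_tajima_d(4, 2, 8 / 6),
                                         abs=1e-12)
    # retained constants match their definitions
    assert res.constants["a1"] == pytest.approx(1 + 1 / 2 + 1 / 3)
    assert res.constants["a2"] == pytest.approx(1 + 1 / 4 + 1 / 9)


def test_tajimas_d_undefined_cases():
    res = tajimas_d(_nt(["ACGT"] * 4))
    assert math.isnan(res.tajima_d)
    assert res.tajima_d_reason == "no segregating sites"
    res = tajimas_d(_nt(["AAAA", "AAAT"]))
    assert math.isnan(res.tajima_d)
    assert res.tajima_d_reason == "n_sequences < 3"


def test_complete_deletion_drops_gapped_and_ambiguous_columns():
    # col 1 has a gap, col 2 an N: both excluded from sites and S
    aln = _nt(["-NAT", "ACAT", "ACGT"])
    res = tajimas_d(aln)
    assert res.n_sites_analyzed == 2
    assert res.S == 1
    with pytest.raises(NoAnalyzableSitesError):
        segregating_sites(_nt(["A-", "-A"]))


def test_random_alignments_match_bruteforce_oracle(rng):
    for _ in range(25):
        n = int(rng.integers(2, 8))
        L = int(rng.integers(10, 50))
        aln = random_nt_alignment(rng, n, L, alphabet="ACG",
                                  gap_rate=0.05)
        try:
            res = tajimas_d(aln)
        except NoAnalyzableSitesError:
            continue
        sites, S, pi_total = brute_force_pair_stats(aln)
        assert res.n_sites_analyzed == sites
        assert res.S == S
        assert res.pi_total == pytest.approx(pi_total, abs=1e-12)


def test_estimators_match_tskit_on_simulated_data():
    """Cross-check against the independent tree-sequence statistics."""
    from nlrdivers.simulate import simulate_coalescent

    for seed in (1, 2, 3):
        sim = simulate_coalescent(n_samples=8, theta=6.0, length_bp=800,
                                  seed=seed)
        res = tajimas_d(sim.alignment)
        ts = sim.tree_sequence
        assert res.S == int(ts.segregating_sites(span_normalise=False))
        assert res.pi_total == pytest.approx(
            float(ts.diversity(span_normalise=False)), rel=1e-9)
        if res.S > 0:
            assert res.tajima_d == pytest.approx(float(ts.Tajimas_D()),
                                                 abs=1e-9)


# ---------------------------------------------------------------------------
# windows
# ---------------------------------------------------------------------------

def _random_codon_aln(rng, n, n_codons):
    mat = rng.choice(list("ACGT"), size=(n, 3 * n_codons))
    return CodonAlignment(records=tuple(
        (f"s{i}", "".join(mat[i])) for i in range(n)))


def test_sliding_window_count_and_coordinates(rng):
    aln = _random_codon_aln(rng, 4, 100)  # length 300
    wins = sliding_window_stats(aln, 300, 75)
    assert len(wins) == 1
    assert (wins[0].window_start, wins[0].window_end) == (1, 300)

    aln = _random_codon_aln(rng, 4, 150)  # length 450
    wins = sliding_window_stats(aln, 300, 75)
    assert [w.window_start for w in wins] == [1, 76, 151]
    assert all(w.window_end - w.window_start + 1 == 300 for w in wins)
    assert wins[0].midpoint == pytest.approx(150.5)


def test_sliding_window_too_short_warns_and_is_empty(rng):
    aln = _nt(["A" * 299, "C" * 299])
    with pytest.warns(UserWarning):
        assert sliding_window_stats(aln, 300, 75) == []


# ---------------------------------------------------------------------------
# domain subsets
# ---------------------------------------------------------------------------

def test_domain_majority_vote_and_tie():
    aln = CodonAlignment(records=(
        ("a", "AAACCC"), ("b", "AAACCC"), ("c", "AAACCC")))
    anns = [
        DomainAnnotation("a", "NBARC", 1, 1),
        DomainAnnotation("b", "NBARC", 1, 1),
        DomainAnnotation("c", "LRR", 1, 1),
    ]
    labels = assign_codon_column_domains(aln, anns)
    assert labels[0] == "NBARC"  # 2 of 3 strict majority
    assert labels[1] is None     # nobody annotates codon 2

    two = CodonAlignment(records=(("a", "AAA"), ("b", "AAA")))
    tie = [DomainAnnotation("a", "NBARC", 1, 1),
           DomainAnnotation("b", "LRR", 1, 1)]
    assert assign_codon_column_domains(two, tie) == [None]
    assert assign_codon_column_domains(two, []) == [None]


def test_domain_mapping_through_gaps():
    # sequence b is gapped at codon 1, so its residue 1 sits at codon 2
    aln = CodonAlignment(records=(
        ("a", "AAACCCGGG"), ("b", "---CCCGGG"), ("c", "AAACCCGGG")))
    anns = [
        DomainAnnotation("a", "CC", 2, 2),
        DomainAnnotation("b", "CC", 1, 1),
        DomainAnnotation("c", "CC", 2, 2),
    ]
    labels = assign_codon_column_domains(aln, anns)
    assert labels == [None, "CC", None]
    sub = domain_subset(aln, anns, "CC")
    assert sub.sequences == ("CCC", "CCC", "CCC")
    with pytest.warns(UserWarning):
        empty = domain_subset(aln, anns, "TIR")
    assert empty.length == 0


def test_domain_assignment_partitions_columns(rng):
    aln = _random_codon_aln(rng, 5, 30)
    anns = []
    for sid in aln.sequence_ids:
        anns.append(DomainAnnotation(sid, "NBARC", 1, 10))
        anns.append(DomainAnnotation(sid, "LRR", 11, 30))
    labels = assign_codon_column_domains(aln, anns)
    counts = {"NBARC": 0, "LRR": 0, None: 0}
    for lab in labels:
        counts[lab] += 1
    assert counts["NBARC"] == 10 and counts["LRR"] == 20
    assert sum(counts.values()) == aln.n_codons


# ---------------------------------------------------------------------------
# genotype matrices
# ---------------------------------------------------------------------------

def test_genotype_single_site_examples():
    res = stats_from_genotypes(np.array([[1, 0, 0, 0]]))
    assert res.pi == pytest.approx(0.5)
    assert res.S == 1
    mono = stats_from_genotypes(np.zeros((5, 6), dtype=int))
    assert mono.S == 0 and mono.pi == 0.0
    assert math.isnan(mono.tajima_d)


def test_genotype_matrix_matches_pairwise_bruteforce(rng):
    """pi from allele counts equals the mean over all 15 haplotype pairs of
    pairwise-complete per-site differences."""
    gt = rng.integers(0, 2, size=(20, 6))
    gt[rng.random(gt.shape) < 0.1] = -1
    res = stats_from_genotypes(gt)
    site_pis = []
    S = 0
    for row in gt:
        called = row[row >= 0]
        if called.size < 2:
            continue
        m = called.size
        diff_pairs = sum(
            1 for i in range(m) for j in range(i + 1, m)
            if called[i] != called[j])
        site_pis.append(diff_pairs / (m * (m - 1) / 2))
        if len(set(called.tolist())) > 1:
            S += 1
    assert res.S == S
    assert res.pi_total == pytest.approx(sum(site_pis), abs=1e-12)
    assert res.pi == pytest.approx(sum(site_pis) / len(site_pis), abs=1e-12)


def test_genotype_all_missing_sites_dropped():
    gt = np.array([[-1, -1, -1, -1], [0, 1, 0, 1]])
    res = stats_from_genotypes(gt)
    assert res.n_sites_analyzed == 1
    with pytest.raises(NoAnalyzableSitesError):
        stats_from_genotypes(np.full((3, 4), -1))


def test_tajima_constants_definitions():
    c = tajima_constants(10)
    assert c["a1"] == pytest.approx(sum(1 / i for i in range(1, 10)))
    with pytest.raises(PopGenError):
        tajima_constants(1)
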