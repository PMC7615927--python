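"""Alignment statistics against brute-force and R-implementation oracles."""

import numpy as np
import pytest

from macrodiv.seqstats import (
    AlignedSeqSet,
    diversity_estimate,
    nucleotide_diversity,
    parsimony_informative_sites,
    read_alignment,
    segregating_sites,
)

BASES = "ACGT"


def brute_pi(seqs, mode):
    """Independent double-loop oracle over pairs and sites."""
    n = len(seqs)
    valid = [[c in BASES for c in s] for s in seqs]
    if mode == "complete":
        keep = [j for j in range(len(seqs[0])) if all(v[j] for v in valid)]
        dists = []
        for i in range(n):
            for k in range(i + 1, n):
                d = sum(seqs[i][j] != seqs[k][j] for j in keep)
                dists.append(d / len(keep))
        return sum(dists) / len(dists)
    dists = []
    for i in range(n):
        for k in range(i + 1, n):
            sites = [j for j in range(len(seqs[0])) if valid[i][j] and valid[k][j]]
            d = sum(seqs[i][j] != seqs[k][j] for j in sites)
            dists.append(d / len(sites))
    return sum(dists) / len(dists)


def brute_S(seqs):
    cols = zip(*seqs)
    return sum(1 for col in cols if len({c for c in col if c in BASES}) >= 2)


def brute_PIS(seqs):
    count = 0
    for col in zip(*seqs):
        tall = {}
        for c in col:
            if c in BASES:
                tall[c] = tall.get(c, 0) + 1
        if sum(1 for v in tall.values() if v >= 2) >= 2:
            count += 1
    return count


@pytest.mark.parametrize(
    "seqs, pi, S, PIS",
    [
        (["AAAA", "AAAA", "AAAA"], 0.0, 0, 0),
        # pairwise diffs 1,2,1 over 3 pairs and 4 sites -> (4/3)/4 = 1/3
        (["AAAA", "AAAT", "AATT"], 1 / 3, 2, 0),
        # 4 differing pairs over 6 pairs and 3 sites -> (4/6)/3 = 2/9
        (["AAT", "AAT", "AAC", "AAC"], 2 / 9, 1, 1),
    ],
)
def test_hand_enumerated_statistics(seqs, pi, S, PIS):
    aln = AlignedSeqSet.from_strings(seqs)
    assert nucleotide_diversity(aln) == pytest.approx(pi, abs=1e-12)
    assert segregating_sites(aln) == S
    assert parsimony_informative_sites(aln) == PIS


def test_matches_r_reference_with_ambiguity():
    """Frozen values computed with the R ape/pegas routines (raw p-distance,
    both deletion modes) on an alignment containing an N."""
    aln = AlignedSeqSet.from_strings(
        ["ACGTACGTAA", "ACGTACGTAT", "ACCTACGAAT", "ACGTACGANT"]
    )
    assert nucleotide_diversity(aln, "pairwise") == pytest.approx(0.174074074074, abs=1e-10)
    assert nucleotide_diversity(aln, "complete") == pytest.approx(0.185185185185, abs=1e-10)
    assert segregating_sites(aln) == 3


def random_alignment(rng, with_missing=True):
    n = rng.integers(2, 7)
    L = rng.integers(8, 21)
    alphabet = "ACGT" + ("N-" if with_missing else "")
    probs = [0.23, 0.23, 0.23, 0.23, 0.04, 0.04] if with_missing else [0.25] * 4
    seqs = [
        "".join(rng.choice(list(alphabet), p=probs)) for _ in range(n * L)
    ]
    seqs = ["".join(seqs[i * L : (i + 1) * L]) for i in range(n)]
    return seqs


@pytest.mark.parametrize("mode", ["complete", "pairwise"])
def test_pi_equals_bruteforce_on_random_alignments(mode):
    """Exact agreement with the all-pairs/site-loop oracle (both deletion
    modes) on many random small alignments."""
    rng = np.random.default_rng(5)
    checked = 0
    while checked < 300:
        seqs = random_alignment(rng)
        aln = AlignedSeqSet.from_strings(seqs)
        try:
            expected = brute_pi(seqs, mode)
        except ZeroDivisionError:
            continue
        try:
            got = nucleotide_diversity(aln, mode)
        except ValueError:
            continue
        assert got == pytest.approx(expected, abs=1e-12)
        assert segregating_sites(aln, "pairwise") == brute_S(seqs)
        assert parsimony_informative_sites(aln, "pairwise") == brute_PIS(seqs)
        checked += 1


def test_statistics_invariant_to_sequence_order_and_duplicates(rng):
    seqs = random_alignment(rng, with_missing=False)
    aln = AlignedSeqSet.from_strings(seqs)
    perm = list(rng.permutation(len(seqs)))
    aln_p = AlignedSeqSet.from_strings([seqs[i] for i in perm])
    est, est_p = diversity_estimate(aln), diversity_estimate(aln_p)
    assert est.pi == est_p.pi and est.S == est_p.S and est.PIS == est_p.PIS
    # duplicating a sequence never creates new variable columns
    dup = AlignedSeqSet.from_strings(seqs + [seqs[0]])
    assert segregating_sites(dup) <= est.S + 0
    assert parsimony_informative_sites(dup) >= est.PIS  # duplicates can promote to PIS
    assert segregating_sites(dup) == est.S


def test_bounds_pis_le_s_le_l(rng):
    for _ in range(50):
        seqs = random_alignment(rng)
        aln = AlignedSeqSet.from_strings(seqs)
        est = diversity_estimate(aln, "pairwise")
        assert est.PIS <= est.S <= aln.length
        assert 0 <= est.pi <= 1


def test_read_alignment_contract(tmp_path):
    good = tmp_path / "sp.fasta"
    good.write_text(">a\nACGT\n>b\nACGA\n>c\nacga\n")
    aln = read_alignment(good)
    assert aln.n == 3 and aln.species_id == "sp"
    # lowercase record c coded identically to uppercase b
    assert (aln.matrix[1] == aln.matrix[2]).all()

    bad = tmp_path / "bad.fasta"
    bad.write_text(">ok\nACGTACGTAC\n>short\nACGTACGTA\n")
    with pytest.raises(ValueError, match="short"):
        read_alignment(bad)

    empty = tmp_path / "empty.fasta"
    empty.write_text("")
    with pytest.raises(ValueError, match="no FASTA"):
        read_alignment(empty)


def test_no_comparable_sites_error():
    aln = AlignedSeqSet.from_strings(["ANN", "N-N"])
    with pytest.raises(ValueError, match="no comparable sites"):
        nucleotide_diversity(aln, "complete")
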