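"""Diversity, divergence, and NG86 estimators."""

import itertools

import numpy as np
import pytest
from Bio.Data import CodonTable

from sweepkit._util import UNDEFINED, harmonic, is_undefined
from sweepkit.diversity import (
    KaKsResult,
    SaturationError,
    SiteFrequencySpectrum,
    codon_pair_diffs,
    divergence_jc,
    haplotype_statistics,
    jukes_cantor,
    ka_ks_ng86,
    mean_pairwise_differences,
    nucleotide_diversity,
    segregating_sites,
    theta_estimators,
    watterson_theta,
)
from sweepkit.regions import classify_sites, polarize_variants, variant_table
from conftest import coding_annotation, make_alignment


class TestPi:
    def test_two_sequences_one_difference(self):
        seqs = ["A" * 99 + "G", "A" * 100]
        aln = make_alignment(seqs)
        assert nucleotide_diversity(aln) == pytest.approx(0.01)

    def test_two_two_split_single_column(self):
        aln = make_alignment(["A", "A", "G", "G"])
        # 4 of the 6 pairs differ
        assert nucleotide_diversity(aln) == pytest.approx(4 / 6)

    def test_identical_sequences(self):
        aln = make_alignment(["ACGT"] * 5)
        assert nucleotide_diversity(aln) == 0.0

    def test_zero_sites_is_undefined_not_zero(self, small_region):
        from sweepkit.regions import classify_sites

        aln, ann = small_region.alignment, small_region.annotation
        cl = classify_sites(aln, ann)
        cl.counts["intronic"] = 0.0
        assert is_undefined(nucleotide_diversity(aln, cl, "intronic"))

    def test_two_route_equivalence_with_sfs(self, small_region):
        """pi from the unfolded SFS equals pi from pairwise differences."""
        aln, ann = small_region.alignment, small_region.annotation
        cl = classify_sites(aln, ann)
        t = polarize_variants(aln, cl)
        # restrict both routes to polarized biallelic sites
        pol = t.polarized()
        sfs = SiteFrequencySpectrum.from_table(t)
        n = aln.n
        pi_sfs = sfs.theta_pi_count()
        diffs = 0.0
        for _, row in pol.iterrows():
            k = int(row["derived_count"])
            diffs += k * (n - k)
        pi_pairs = diffs / (n * (n - 1) / 2)
        assert pi_sfs == pytest.approx(pi_pairs, rel=1e-12)


class TestSegregatingSites:
    def test_empty_table(self):
        aln = make_alignment(["ACGT"] * 4)
        t = variant_table(aln)
        assert segregating_sites(t) == (0, 0)

    def test_singleton_counting(self):
        cols = ["AAAAAAAAAG", "AAAAAAAAAC", "AAAAAGGGGG"]
        seqs = ["".join(c[i] for c in cols) for i in range(10)]
        aln = make_alignment(seqs)
        t = variant_table(aln)
        assert segregating_sites(t) == (3, 2)


class TestThetaEstimators:
    def test_watterson_n10(self):
        sfs = SiteFrequencySpectrum(10, [10, 0, 0, 0, 0, 0, 0, 0, 0])
        tw, _ = theta_estimators(sfs, 1000.0)
        assert tw == pytest.approx(10 / (2.828968 * 1000), rel=1e-5)
        assert watterson_theta(10, 10, 1000.0) == pytest.approx(tw)

    def test_all_singletons_theta_L(self):
        n, S = 8, 21
        xi = np.zeros(n - 1)
        xi[0] = S
        _, tl = theta_estimators(SiteFrequencySpectrum(n, xi), 500.0)
        assert tl == pytest.approx(S / ((n - 1) * 500.0))

    def test_no_variation(self):
        sfs = SiteFrequencySpectrum(10, np.zeros(9))
        assert theta_estimators(sfs, 100.0) == (0.0, 0.0)


class TestHaplotypes:
    def test_all_distinct(self):
        aln = make_alignment(["AAAA", "AAAT", "AATT", "ATTT"])
        assert haplotype_statistics(aln) == (4, pytest.approx(1.0))

    def test_one_duplicate_of_twelve(self):
        seqs = [f"{'A' * i}{'T' * (11 - i)}" for i in range(11)] + ["T" * 11]
        # last equals the i=0 haplotype -> counts 2,1x10
        assert len(set(seqs)) == 11
        aln = make_alignment(seqs)
        h, hd = haplotype_statistics(aln)
        assert h == 11
        assert hd == pytest.approx(12 / 11 * (1 - 14 / 144), abs=1e-9)

    def test_monomorphic(self):
        aln = make_alignment(["GGGG"] * 6)
        assert haplotype_statistics(aln) == (1, 0.0)


class TestJukesCantor:
    def test_zero(self):
        assert jukes_cantor(0.0) == 0.0

    def test_known_value(self):
        assert jukes_cantor(0.1) == pytest.approx(0.10732, abs=1e-5)

    def test_saturation(self):
        with pytest.raises(SaturationError):
            jukes_cantor(0.8)

    @pytest.mark.parametrize("p", np.linspace(0.01, 0.7, 12))
    def test_correction_exceeds_raw_and_monotone(self, p):
        assert jukes_cantor(p) >= p
        assert jukes_cantor(p + 0.01) > jukes_cantor(p)

    def test_divergence_averages_over_sample(self):
        seqs = ["AAAAAAAAAA", "AAAAAAAAAC"]
        aln = make_alignment(seqs, outgroup="GAAAAAAAAA")
        # per-sample p: 0.1 and 0.2 -> mean 0.15
        k = divergence_jc(aln)
        assert k == pytest.approx(jukes_cantor(0.15))


def _ng86_oracle(c1, c2):
    """Exhaustive pathway enumeration, independent of the implementation."""
    table = CodonTable.unambiguous_dna_by_id[1]
    aa = dict(table.forward_table)
    for s in table.stop_codons:
        aa[s] = "*"
    diffs = [i for i in range(3) if c1[i] != c2[i]]
    if not diffs:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diffs):
        cur, sd, nd, blocked = c1, 0, 0, False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if aa[nxt] == "*" and nxt != c2:
                blocked = True
            if aa[cur] == aa[nxt] and aa[cur] != "*":
                sd += 1
            else:
                nd += 1
            cur = nxt
        paths.append((sd, nd, blocked))
    ok = [(s, d) for s, d, b in paths if not b]
    if not ok:
        ok = [(s, d) for s, d, _ in paths]
    return (
        float(np.mean([s for s, _ in ok])),
        float(np.mean([d for _, d in ok])),
    )


class TestNG86:
    def test_identical_cds_omega_undefined(self):
        seq = "ATGAAATTTGGG"
        aln = make_alignment([seq, seq], outgroup=seq)
        cl = classify_sites(aln, coding_annotation(12))
        res = ka_ks_ng86(aln, cl)
        assert res.Ka == 0.0 and res.Ks == 0.0
        assert is_undefined(res.omega)

    def test_single_synonymous_codon_pair(self):
        assert codon_pair_diffs("TTT", "TTC") == (1.0, 0.0)

    def test_pathway_counts_match_exhaustive_oracle(self, rng):
        from sweepkit.synth import _nonstop_codons

        codons = _nonstop_codons()
        for _ in range(100):
            c1 = codons[int(rng.integers(len(codons)))]
            c2 = codons[int(rng.integers(len(codons)))]
            assert codon_pair_diffs(c1, c2) == pytest.approx(_ng86_oracle(c1, c2))

    def test_sd_nd_sum_to_nucleotide_differences(self, rng):
        from sweepkit.synth import _nonstop_codons

        codons = _nonstop_codons()
        for _ in range(50):
            c1 = codons[int(rng.integers(len(codons)))]
            c2 = codons[int(rng.integers(len(codons)))]
            sd, nd = codon_pair_diffs(c1, c2)
            ndiff = sum(a != b for a, b in zip(c1, c2))
            assert sd + nd == pytest.approx(ndiff)

    def test_region_level_against_per_codon_oracle(self, rng):
        """Whole-gene Sd/Nd equals summing the enumeration oracle per codon."""
        from sweepkit.synth import _nonstop_codons

        codons = _nonstop_codons()
        n_codons = 30
        anc = [codons[int(i)] for i in rng.integers(0, len(codons), n_codons)]
        out = []
        for c in anc:
            if rng.random() < 0.4:
                pos = int(rng.integers(3))
                b = "ACGT"[int(rng.integers(4))]
                cand = c[:pos] + b + c[pos + 1 :]
                out.append(cand if cand in codons else c)
            else:
                out.append(c)
        seq = "".join(anc)
        aln = make_alignment([seq, seq], outgroup="".join(out))
        cl = classify_sites(aln, coding_annotation(3 * n_codons))
        res = ka_ks_ng86(aln, cl)
        sd = sum(_ng86_oracle(a, o)[0] for a, o in zip(anc, out))
        nd = sum(_ng86_oracle(a, o)[1] for a, o in zip(anc, out))
        assert res.Sd == pytest.approx(sd)
        assert res.Nd == pytest.approx(nd)


def test_mean_pairwise_differences_matches_pi_numerator(small_region):
    aln, ann = small_region.alignment, small_region.annotation
    cl = classify_sites(aln, ann)
    t = variant_table(aln, cl)
    pi = nucleotide_diversity(aln, cl, None, table=t)
    mpd = mean_pairwise_differences(t)
    assert mpd / cl.counts["total"] == pytest.approx(pi, rel=1e-12)
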