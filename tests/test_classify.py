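import math

import numpy as np
import pytest
from scipy import stats

from collatmut import (
    Genome,
    MutationPair,
    MutationRecord,
    attribution_purity,
    categorize_pair,
    classify_primary,
    get_scheme,
    orientation_asymmetry,
    simulate_collateral_null,
    slippage_analysis,
)
from collatmut.classify import PairCategory


def rec(pos, ref, alt, sample="s1", chrom="chr1"):
    return MutationRecord(sample, chrom, pos, ref, alt)


@pytest.fixture(scope="module")
def cisplatin():
    return get_scheme("cisplatin_dt40")


class TestClassifyPrimary:
    def test_lower_strand_lesion(self, cisplatin):
        # observed A[C>A]C: N[C>A]Y matches; C>A means the damaged purine
        # is on the lower strand
        g = Genome.from_dict({"chr1": "TACCT"})
        c = classify_primary(rec(3, "C", "A"), cisplatin, g)
        assert (c.label, c.lesion_strand) == ("primary", "lower")

    def test_upper_strand_lesion(self, cisplatin):
        # observed G>T normalising to G[C>A]T
        g = Genome.from_dict({"chr1": "AAGCA"})
        c = classify_primary(rec(3, "G", "T"), cisplatin, g)
        assert (c.label, c.lesion_strand) == ("primary", "upper")
        assert c.context.pyr_class == "G[C>A]T"

    def test_uvc_non_primary(self):
        # observed A[C>G]A matches no UVC pattern
        g = Genome.from_dict({"chr1": "TACAT"})
        c = classify_primary(rec(3, "C", "G"), "uvc_dt40", g)
        assert c.label == "non_primary"

    def test_unusable_context_flagged(self, cisplatin):
        g = Genome.from_dict({"chr1": "TNCAT"})
        c = classify_primary(rec(3, "C", "A"), cisplatin, g)
        assert c.label == "non_primary" and c.unusable_context

    def test_strand_symmetry(self, cisplatin, toy_genome):
        from collatmut.genome import revcomp

        seq = toy_genome.sequence("chr1")
        rc_genome = Genome.from_dict({"chr1": revcomp(seq)})
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        n = len(seq)
        rng = np.random.default_rng(5)
        for pos in map(int, rng.integers(2, n - 1, size=40)):
            ref = seq[pos - 1]
            alt = comp[ref] if comp[ref] != ref else "A"
            fwd = classify_primary(rec(pos, ref, alt), cisplatin, toy_genome)
            rev = classify_primary(
                rec(n - pos + 1, comp[ref], comp[alt]), cisplatin, rc_genome
            )
            assert fwd.label == rev.label
            if fwd.label == "primary":
                # the same physical lesion flips strand with the representation
                assert {fwd.lesion_strand, rev.lesion_strand} == {"upper", "lower"}


class TestCategorizePair:
    def test_upper_lesion_collateral_5prime_consistent(self, cisplatin):
        # primary G>T (upper lesion) at 500, non-primary 5' at 492
        seq = list("A" * 520)
        seq[498:501] = list("AGC")  # G at 500 -> G[C>A]T class
        seq[490:492] = list("TC")  # non-primary C>G at 492
        g = Genome.from_dict({"chr1": "".join(seq)})
        p = MutationPair(rec(492, "C", "G"), rec(500, "G", "T"))
        cat = categorize_pair(p, cisplatin, g)
        assert cat.category == "proper"
        assert cat.orientation_consistent is True
        assert cat.primary_is_first is False

    def test_lower_lesion_collateral_3prime_consistent(self, cisplatin):
        # primary C>A (lower lesion) at 500, non-primary at 510
        seq = list("A" * 520)
        seq[498:501] = list("TCC")  # C at 500, down flank C -> N[C>A]Y
        seq[508:510] = list("TC")
        g = Genome.from_dict({"chr1": "".join(seq)})
        p = MutationPair(rec(500, "C", "A"), rec(510, "C", "G"))
        cat = categorize_pair(p, cisplatin, g)
        assert cat.category == "proper"
        assert cat.orientation_consistent is True
        assert cat.primary_is_first is True

    def test_both_primary_no_orientation(self, cisplatin):
        seq = list("A" * 520)
        seq[498:501] = list("TCC")
        seq[508:511] = list("TCC")
        g = Genome.from_dict({"chr1": "".join(seq)})
        p = MutationPair(rec(500, "C", "A"), rec(510, "C", "A"))
        cat = categorize_pair(p, cisplatin, g)
        assert cat.category == "both_primary"
        assert cat.orientation_consistent is None


class TestOrientationAsymmetry:
    def _pair(self, g, p1, p2):
        return MutationPair(p1, p2)

    def test_maximal_asymmetry_and_symmetric_table(self, cisplatin):
        # build pairs on a designed genome: upper-lesion primaries 3',
        # lower-lesion primaries 5'
        seq = list("A" * 10_000)
        pairs = []
        pos = 100
        for _ in range(8):
            seq[pos - 2 : pos + 1] = list("AGC")  # G>T primary at pos (upper)
            seq[pos - 12 : pos - 10] = list("TC")
            pairs.append(MutationPair(rec(pos - 10, "C", "G"), rec(pos, "G", "T")))
            pos += 300
        for _ in range(8):
            seq[pos - 2 : pos + 1] = list("TCC")  # C>A primary at pos (lower)
            seq[pos + 8 : pos + 10] = list("TC")  # positions pos+9, pos+10
            pairs.append(MutationPair(rec(pos, "C", "A"), rec(pos + 10, "C", "G")))
            pos += 300
        g = Genome.from_dict({"chr1": "".join(seq)})
        res = orientation_asymmetry(pairs, cisplatin, g)
        table = res["collapse_2x2"].to_numpy()
        # perfect segregation: upper-lesion all 3', lower-lesion all 5'
        assert table[0, 0] == 0 and table[1, 1] == 0
        assert res["fisher_p"] == pytest.approx(
            stats.fisher_exact(table)[1]
        )
        # symmetric table gives p = 1
        sym = np.array([[4, 4], [4, 4]])
        assert stats.fisher_exact(sym)[1] == 1.0

    def test_empty_input_errors(self, cisplatin, toy_genome):
        with pytest.raises(ValueError):
            orientation_asymmetry([], cisplatin, toy_genome)


class TestSlippage:
    def test_all_copy_fraction_one(self, cisplatin):
        # collateral alt equals its primary-side neighbour in every pair
        seq = list("A" * 1000)
        cats = []
        pos = 100
        for _ in range(6):
            seq[pos - 2 : pos + 1] = list("TCC")  # lower-lesion primary C>A at pos
            # collateral at pos+10, neighbour toward primary at pos+9
            seq[pos + 8] = "G"  # neighbour base (pos+9)
            seq[pos + 9] = "C"  # collateral ref (pos+10)
            pos += 150
        g = Genome.from_dict({"chr1": "".join(seq)})
        pos = 100
        for _ in range(6):
            pair = MutationPair(rec(pos, "C", "A"), rec(pos + 10, "C", "G"))
            cats.append(categorize_pair(pair, cisplatin, g))
            pos += 150
        assert all(c.category == "proper" for c in cats)
        res = slippage_analysis(cats, g)
        assert res["copy_fraction"] == 1.0 and res["n_copy"] == 6

    def test_fisher_equals_exact_hypergeometric_enumeration(self):
        # oracle: enumerate all 2x2 tables with fixed margins, sum
        # hypergeometric probabilities <= observed table's
        n_copy, n_noncopy = 20, 30
        n = n_copy + n_noncopy
        exp_copy = round(n / 3)
        row1, row2 = n, n
        col1 = n_copy + exp_copy
        total = row1 + row2

        def hyper_p(a):
            return (
                math.comb(row1, a)
                * math.comb(row2, col1 - a)
                / math.comb(total, col1)
            )

        p_obs = hyper_p(n_copy)
        p_exact = sum(
            hyper_p(a)
            for a in range(max(0, col1 - row2), min(row1, col1) + 1)
            if hyper_p(a) <= p_obs * (1 + 1e-9)
        )
        table = [[n_copy, n_noncopy], [exp_copy, n - exp_copy]]
        assert stats.fisher_exact(table)[1] == pytest.approx(p_exact, rel=1e-9)

    def test_parameter_recovery_from_generator(self):
        from collatmut import SyntheticConfig, simulate_clones, merge_dbs, close_mutation_ratio, categorize_pairs

        cfg = SyntheticConfig(
            genome_length=400_000,
            n_clones=6,
            n_lesions_per_clone=120,
            p_primary_error=0.6,
            p_collateral=0.4,
            p_slip=0.6,
            background_rate=2e-6,
            seed=11,
        )
        res = simulate_clones(cfg)
        merged, _ = merge_dbs([r for r in res.records if r.kind == "SBS"])
        pairs = close_mutation_ratio(merged)["pairs"]
        cats = categorize_pairs(pairs, "cisplatin_dt40", res.genome)
        slip = slippage_analysis([c for c in cats if c.category == "proper"], res.genome)
        n = slip["n_copy"] + slip["n_noncopy"]
        se = math.sqrt(0.6 * 0.4 / n)
        assert abs(slip["copy_fraction"] - 0.6) < 2.5 * se + 0.05


class TestSimulatedCollateralNull:
    def test_homopolymer_concentrated_distance(self, cisplatin):
        # distance distribution concentrated at one short distance on an
        # A-homopolymer background: neighbour base is A always, SD 0
        seq = list("A" * 3000)
        primaries = []
        pos = 500
        for _ in range(5):
            seq[pos - 2 : pos + 1] = list("TCT")  # T[C>A]T primary, lower lesion
            primaries.append(rec(pos, "C", "A"))
            pos += 400
        g = Genome.from_dict({"chr1": "".join(seq)})
        out = simulate_collateral_null(
            primaries, [3], cisplatin, g, set_size=20, n_runs=10, seed=3
        )
        freq = dict(zip(out["bases"], out["mean"]))
        assert freq["A"] == 1.0
        assert np.allclose(out["sd"], 0.0)

    def test_deterministic_under_seed(self, cisplatin, toy_genome):
        seq = toy_genome.sequence("chr1")
        primaries = []
        for i in range(2, len(seq) - 1):
            if seq[i - 1] == "C" and seq[i] in "CT" and len(primaries) < 30:
                primaries.append(rec(i, "C", "A"))
        a = simulate_collateral_null(primaries, [2, 3, 5, 8], cisplatin, toy_genome, 50, n_runs=5, seed=42)
        b = simulate_collateral_null(primaries, [2, 3, 5, 8], cisplatin, toy_genome, 50, n_runs=5, seed=42)
        assert np.array_equal(a["per_run"], b["per_run"])

    def test_matches_exhaustive_enumeration(self, cisplatin, toy_genome):
        """Neighbour-base frequencies approach the exhaustive average over
        all primaries x distances on the toy genome."""
        seq = toy_genome.sequence("chr1")
        primaries = []
        for i in range(200, len(seq) - 200):
            if seq[i - 1] == "C" and seq[i] in "CT":
                primaries.append(rec(i, "C", "A"))
        primaries = primaries[:200]
        distances = [2, 5]
        # exhaustive oracle: every (classifiable primary, distance) equally
        from collatmut import classify_primary

        counts = {b: 0 for b in "ACGT"}
        tot = 0
        for r in primaries:
            c = classify_primary(r, cisplatin, toy_genome)
            if c.label != "primary":
                continue
            for d in distances:
                if c.lesion_strand == "upper":
                    nb = seq[(r.pos - d + 1) - 1]
                else:
                    nb = seq[(r.pos + d - 1) - 1]
                counts[nb] += 1
                tot += 1
        expected = np.array([counts[b] / tot for b in "ACGT"])
        out = simulate_collateral_null(
            primaries, distances, cisplatin, toy_genome, set_size=400, n_runs=60, seed=9
        )
        se = out["sd"] / math.sqrt(60)
        assert np.all(np.abs(out["mean"] - expected) < 4 * se + 0.01)


class TestAttributionPurity:
    def test_zero_mock_full_purity(self):
        assert attribution_purity(100.0, 0.0) == 1.0

    def test_cisplatin_arithmetic(self):
        assert attribution_purity(219.6, 12.0) == pytest.approx(0.9454, abs=5e-4)

    def test_uvc_arithmetic(self):
        assert attribution_purity(1503.7, 8.0) == pytest.approx(0.9947, abs=5e-4)

    def test_zero_treated_undefined(self):
        with pytest.raises(ValueError):
            attribution_purity(0.0, 5.0)
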