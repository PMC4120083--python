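"""ML/MF statistics: tallying, non-conversion correction, fidelity, caller,
regional pooling, concordance, and sample comparison."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hairpinbs.methylation import (
    CallerConfig,
    add_dyad_stats,
    binomial_caller,
    compare_samples,
    cpg_concordance,
    depth_filter,
    dyad_methylation_level,
    estimate_nonconversion,
    methylation_fidelity,
    methylation_level,
    paired_noncpg_table,
    region_stats,
    strand_concordance,
    tally_calls,
    theoretical_min_mf,
)
from hairpinbs.recover import RecoveredMolecule
from hairpinbs.simulate import (
    ReferenceModel,
    simulate_dyad_tallies,
)


def _mol(seq, wcalls, ccalls, locus=("chrT", 0, "+"), read_id="m"):
    return RecoveredMolecule(read_id, seq, wcalls, ccalls, locus=locus)


class TestTallyCalls:
    REF = ReferenceModel("chrT", "AACGTTACGTTCAGT" + "A" * 1000)

    def test_single_molecule_dyad(self):
        mol = _mol("AACGT", "..M..", "...M.")
        sites, dyads = tally_calls([mol], self.REF)
        assert len(dyads) == 1
        row = dyads.iloc[0]
        assert (row.position, row.nMM, row.nMU, row.nUM, row.nUU) == (2, 1, 0, 0, 0)
        assert set(sites.context) == {"CpG"}

    def test_hemi_patterns_split_correctly(self):
        mols = [
            _mol("AACGT", "..M..", "...U."),  # Watson-only
            _mol("AACGT", "..U..", "...M."),  # Crick-only
            _mol("AACGT", "..U..", "...U."),
        ]
        _, dyads = tally_calls(mols, self.REF)
        row = dyads.iloc[0]
        assert (row.nMM, row.nMU, row.nUM, row.nUU) == (0, 1, 1, 1)

    def test_snp_masking_silences_mismatching_positions(self):
        """A recovered base disagreeing with the reference yields no call."""
        # reference position 2 is C; recovered says T there (call attached)
        mol = _mol("AATGT", "..U..", ".....")
        sites, dyads = tally_calls([mol], self.REF)
        assert len(sites) == 0 and len(dyads) == 0

    def test_context_assignment_from_reference(self):
        # chrT: ...TTCAGT -> C at 11 followed by A, then G at 13 -> CHG
        mol = _mol("TTCAGT", "..M...", "......", locus=("chrT", 9, "+"))
        sites, _ = tally_calls([mol], self.REF)
        assert sites.iloc[0].context == "CHG"

    def test_locus_outside_reference_is_an_error(self):
        mol = _mol("AACGT", ".....", ".....", locus=("chrT", 10**6, "+"))
        with pytest.raises(ValueError):
            tally_calls([mol], self.REF)

    def test_simulated_pure_hemi_round_trip(self):
        """10 Watson-only molecules tally as dyad (0, 10, 0, 0)."""
        mols = [_mol("AACGT", "..M..", "...U.", read_id=f"m{i}") for i in range(10)]
        _, dyads = tally_calls(mols, self.REF)
        row = dyads.iloc[0]
        assert (row.nMM, row.nMU, row.nUM, row.nUU) == (0, 10, 0, 0)


class TestNonconversionEstimate:
    def test_exact_fraction(self):
        sites = pd.DataFrame(
            {
                "reference": ["l"] * 2,
                "position": [1, 2],
                "strand": ["+", "+"],
                "context": ["CpG", "CpG"],
                "n_meth": [100, 3],
                "n_unmeth": [5000, 4897],
            }
        )
        r = estimate_nonconversion(sites)
        assert r["CpG"] == pytest.approx(103 / 10000)
        assert math.isnan(r["CHG"])  # no coverage -> flagged

    def test_zero_methylated_gives_zero(self):
        sites = pd.DataFrame(
            {
                "reference": ["l"],
                "position": [1],
                "strand": ["+"],
                "context": ["CHH"],
                "n_meth": [0],
                "n_unmeth": [500],
            }
        )
        assert estimate_nonconversion(sites)["CHH"] == 0.0


class TestMethylationLevel:
    def test_site_fraction(self):
        raw, corr = methylation_level(43, 57)
        assert raw == pytest.approx(0.43) and corr == pytest.approx(0.43)

    def test_correction_floor_at_rate(self):
        """ML equal to the non-conversion rate corrects to exactly zero."""
        _, corr = methylation_level(103, 9897, r=0.0103)
        assert corr == 0.0

    def test_dyad_strand_weighting(self):
        raw, _ = dyad_methylation_level(2, 1, 1, 6)
        assert raw == pytest.approx(6 / 20)

    def test_correction_identity_at_zero_rate(self):
        raw, corr = dyad_methylation_level(5, 3, 2, 10, r=0.0)
        assert corr == pytest.approx(raw)


class TestFidelity:
    @pytest.mark.parametrize(
        "counts,expected",
        [((4, 1, 1, 4), 0.8), ((0, 5, 5, 0), 0.0), ((5, 0, 0, 5), 1.0)],
    )
    def test_direct_formula(self, counts, expected):
        assert methylation_fidelity(*counts) == pytest.approx(expected)

    @pytest.mark.parametrize("ml,expected", [(0.5, 0.0), (0.0, 1.0), (1.0, 1.0), (0.75, 0.5)])
    def test_theoretical_minimum(self, ml, expected):
        assert theoretical_min_mf(ml) == pytest.approx(expected)

    def test_min_mf_matches_exhaustive_pairing(self):
        """For every tally of depth <= 6, |2ml-1| is a tight lower bound.

        Exhaustive check: enumerate all (nMM, nMU, nUM, nUU); group by
        (depth, methylated strand calls); the minimum MF in each group must
        equal the closed form, and every tally must sit at or above it.
        """
        best: dict[tuple[int, int], float] = {}
        tallies = []
        for n in range(1, 7):
            for a in range(n + 1):
                for b in range(n + 1 - a):
                    for c in range(n + 1 - a - b):
                        d = n - a - b - c
                        m = 2 * a + b + c
                        mf = (a + d) / n
                        tallies.append((n, m, mf))
                        key = (n, m)
                        best[key] = min(best.get(key, 1.0), mf)
        for n, m, mf in tallies:
            assert mf >= theoretical_min_mf(m / (2 * n)) - 1e-12
        for (n, m), mf_min in best.items():
            assert mf_min == pytest.approx(theoretical_min_mf(m / (2 * n)))

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.tuples(*[st.integers(0, 30)] * 4).filter(lambda t: sum(t) > 0))
    def test_identities(self, counts):
        """2*depth*ml_raw counts methylated strands exactly; MF=1 iff no
        hemi-methylated molecule; MF is bounded below by the theoretical
        minimum."""
        a, b, c, d = counts
        depth = a + b + c + d
        raw, _ = dyad_methylation_level(a, b, c, d)
        mf = methylation_fidelity(a, b, c, d)
        assert 2 * depth * raw == pytest.approx(2 * a + b + c)
        assert (mf == 1.0) == (b + c == 0)
        assert mf >= theoretical_min_mf(raw) - 1e-12


class TestDepthFilter:
    def test_pair_boundary(self):
        df = add_dyad_stats(
            pd.DataFrame(
                {
                    "reference": ["r"] * 3,
                    "position": [0, 2, 4],
                    "nMM": [5, 2, 0],
                    "nMU": [0, 2, 0],
                    "nUM": [0, 0, 2],
                    "nUU": [0, 0, 2],
                }
            )
        )
        kept = depth_filter(df, min_pairs=5)
        assert list(kept.position) == [0]  # depth 5 kept, 4 dropped

    def test_empty_passthrough(self):
        empty = pd.DataFrame(columns=["reference", "position", "nMM", "nMU", "nUM", "nUU"])
        assert len(depth_filter(empty)) == 0


class TestBinomialCaller:
    def _sites(self, n_meth, depth, context="CpG"):
        n_meth = np.atleast_1d(n_meth)
        return pd.DataFrame(
            {
                "reference": "r",
                "position": np.arange(len(n_meth)),
                "strand": "+",
                "context": context,
                "n_meth": n_meth,
                "n_unmeth": depth - n_meth,
            }
        )

    def test_exact_tail_probability(self):
        """depth 10, 5 methylated, p_null=0.01: exact binomial tail."""
        out = binomial_caller(self._sites([5], 10), CallerConfig(p_null=0.01))
        expected = sum(
            math.comb(10, k) * 0.01**k * 0.99 ** (10 - k) for k in range(5, 11)
        )
        assert out.pvalue.iloc[0] == pytest.approx(expected, rel=1e-9)
        assert expected == pytest.approx(2.4e-8, rel=0.05)

    def test_zero_methylated_never_significant(self):
        out = binomial_caller(self._sites([0, 0, 30], 30), CallerConfig(p_null=0.012))
        assert out.pvalue.iloc[0] == pytest.approx(1.0)
        assert not out.significant.iloc[0]

    def test_null_calibration_and_power(self):
        """On a pure null the flagged fraction stays within FDR noise; fully
        methylated sites at depth 30 are always caught."""
        rng = np.random.default_rng(42)
        null_meth = rng.binomial(30, 0.012, size=10_000)
        out = binomial_caller(self._sites(null_meth, 30), CallerConfig(p_null=0.012))
        frac = out.significant.mean()
        assert frac <= 0.01 + 3 * np.sqrt(0.01 * 0.99 / 10_000)
        mixed = np.concatenate([null_meth, np.full(1000, 30)])
        out2 = binomial_caller(self._sites(mixed, 30), CallerConfig(p_null=0.012))
        assert out2.significant.to_numpy()[10_000:].mean() >= 0.99

    def test_contexts_corrected_separately(self):
        sites = pd.concat(
            [self._sites([8], 10, "CpG"), self._sites([8], 10, "CHH")], ignore_index=True
        )
        out = binomial_caller(sites, CallerConfig(p_null={"CpG": 0.01, "CHG": 0.01, "CHH": 0.05}))
        assert out.pvalue.iloc[0] < out.pvalue.iloc[1]


class TestRegionStats:
    def _df(self, rows):
        return add_dyad_stats(
            pd.DataFrame(
                [
                    {"reference": "r", "position": p, "nMM": a, "nMU": b, "nUM": c, "nUU": d}
                    for p, (a, b, c, d) in rows
                ]
            )
        )

    def test_pooled_counts(self):
        df = self._df([(0, (10, 0, 0, 0)), (10, (0, 0, 0, 10))])
        ml, mf, n = region_stats(df, 0, 20)
        assert (ml, mf, n) == (0.5, 1.0, 2)

    def test_single_site_equals_site_value(self):
        df = self._df([(0, (4, 1, 1, 4))])
        ml, mf, _ = region_stats(df, 0, 5)
        assert ml == pytest.approx(0.5) and mf == pytest.approx(0.8)

    def test_pooling_differs_from_mean_of_sites(self):
        """Count weighting: a depth-50 dyad dominates a depth-2 dyad."""
        df = self._df([(0, (2, 0, 0, 0)), (10, (0, 0, 0, 50))])
        ml, _, _ = region_stats(df, 0, 20)
        mean_of_sites = np.mean([1.0, 0.0])
        assert ml == pytest.approx(2 / 52)
        assert abs(ml - mean_of_sites) > 0.4

    def test_uncovered_region_flagged(self):
        df = self._df([(0, (1, 0, 0, 0))])
        ml, mf, n = region_stats(df, 100, 200)
        assert n == 0 and math.isnan(ml) and math.isnan(mf)


class TestConcordance:
    def test_symmetric_mixture_is_perfectly_concordant(self):
        assert strand_concordance(50, 0, 0, 50) == pytest.approx(1.0)

    def test_pure_hemi_is_anticoncordant(self):
        assert strand_concordance(0, 50, 50, 0) == pytest.approx(-1.0)

    def test_independent_strands_near_zero(self):
        df = simulate_dyad_tallies((0.25, 0.25, 0.25, 0.25), n_dyads=100, n_pairs=20, seed=3)
        phi = cpg_concordance(df)
        assert abs(phi) < 3 / np.sqrt(100 * 20)

    def test_zero_variance_flagged(self):
        assert math.isnan(strand_concordance(10, 0, 10, 0))

    def test_chh_pairing_rejected(self):
        with pytest.raises(ValueError, match="CHG"):
            paired_noncpg_table([], {}, context="CHH")

    def test_chg_pairs_symmetric_sites(self):
        ref = ReferenceModel("chrT", "TTCAGTT" + "A" * 1000)
        mol = _mol("TTCAGTT", "..M....", "....M..", locus=("chrT", 0, "+"))
        table = paired_noncpg_table([mol], ref, context="CHG")
        assert table == (1, 0, 0, 0)


class TestCompareSamples:
    def _stats(self, ml, mf, n=10):
        return pd.DataFrame(
            {
                "reference": "r",
                "position": np.arange(n) * 2,
                "ml_corrected": ml,
                "mf": mf,
            }
        )

    def test_identical_samples_have_no_deltas(self):
        a = self._stats(0.5, 0.9)
        out = compare_samples(a, a.copy())
        assert out["frac_ml_up"] == out["frac_ml_down"] == 0.0
        assert out["frac_mf_up"] == out["frac_mf_down"] == 0.0

    def test_global_shift_detected(self):
        out = compare_samples(self._stats(0.5, 0.5), self._stats(0.8, 0.5))
        assert out["frac_ml_up"] == 1.0 and out["frac_ml_down"] == 0.0

    def test_partial_shift_fraction_recovered(self):
        """A known shift on 30% of dyads shows up as frac_ml_up ~ 0.30."""
        rng = np.random.default_rng(11)
        n = 1000
        shifted = rng.random(n) < 0.30
        ml_a = np.full(n, 0.2)
        ml_b = np.where(shifted, 0.9, 0.2)
        out = compare_samples(self._stats(ml_a, 0.9, n), self._stats(ml_b, 0.9, n))
        assert out["frac_ml_up"] == pytest.approx(shifted.mean())

    def test_empty_intersection_is_an_error(self):
        a = self._stats(0.5, 0.9)
        b = self._stats(0.5, 0.9).assign(position=lambda d: d.position + 10_000)
        with pytest.raises(ValueError):
            compare_samples(a, b)


def test_parameter_recovery_within_three_se():
    """Estimated (ML, MF) from 200 pairs/dyad match the mixture moments."""
    probs = (0.45, 0.05, 0.05, 0.45)
    df = add_dyad_stats(simulate_dyad_tallies(probs, n_dyads=100, n_pairs=200, seed=17))
    ml_expected = probs[0] + (probs[1] + probs[2]) / 2
    mf_expected = probs[0] + probs[3]
    n_obs = 100 * 200
    se_ml = np.sqrt(ml_expected * (1 - ml_expected) / (2 * n_obs))
    se_mf = np.sqrt(mf_expected * (1 - mf_expected) / n_obs)
    assert abs(df.ml_raw.mean() - ml_expected) < 3 * se_ml
    assert abs(df.mf.mean() - mf_expected) < 3 * se_mf
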