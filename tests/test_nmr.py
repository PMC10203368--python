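"""Methyl enumeration, normalization, pathway correlations and flagging."""

import numpy as np
import pandas as pd
import pytest

from hydrodr.nmr import (
    MethylTable,
    PathwayProfile,
    count_ailmtv_methyls,
    flag_responsive,
    load_lysozyme_sequence,
    normalize_intensities,
    pathway_correlation,
    pathway_profiles,
)


class TestCountMethyls:
    def test_lysozyme_has_61(self):
        _, total = count_ailmtv_methyls(load_lysozyme_sequence())
        assert total == 61

    def test_empty_sequence(self):
        counts, total = count_ailmtv_methyls("")
        assert counts == [] and total == 0

    def test_one_of_each_reporter(self):
        counts, total = count_ailmtv_methyls("AILMTV")
        assert counts == [1, 2, 2, 1, 1, 2]
        assert total == 9

    def test_unknown_letters_warn_and_count_zero(self):
        with pytest.warns(UserWarning, match="non-standard"):
            _, total = count_ailmtv_methyls("AXZ")
        assert total == 1


def small_table(intensities_by_sample, integrals_by_sample):
    peak_rows = []
    for (cond, tp), vals in intensities_by_sample.items():
        for i, v in enumerate(vals):
            peak_rows.append((i + 1, "L", "delta1", cond, tp, v))
    peaks = pd.DataFrame(
        peak_rows,
        columns=["residue_number", "residue_type", "methyl_id", "condition", "timepoint", "intensity"],
    )
    integrals = pd.DataFrame(
        [(c, t, v) for (c, t), v in integrals_by_sample.items()],
        columns=["condition", "timepoint", "oned_integral"],
    )
    return MethylTable(peaks, integrals)


class TestNormalize:
    def test_scale_invariance(self):
        base = np.array([1.0, 2.0, 3.0])
        t1 = small_table({("GC", "3h"): base}, {("GC", "3h"): 2.0})
        t2 = small_table({("GC", "3h"): 2 * base}, {("GC", "3h"): 4.0})
        n1, n2 = normalize_intensities(t1), normalize_intensities(t2)
        assert np.allclose(n1.peaks["intensity"], n2.peaks["intensity"])

    def test_unit_integral_is_identity(self):
        base = np.array([1.0, 2.0, 3.0])
        t = small_table({("GC", "3h"): base}, {("GC", "3h"): 1.0})
        assert np.allclose(normalize_intensities(t).peaks["intensity"], base)

    def test_concentration_difference_cancels(self):
        base = np.array([1.0, 2.0, 3.0])
        t = small_table(
            {("GC", "3h"): base, ("GC", "24h"): 2 * base},
            {("GC", "3h"): 1.0, ("GC", "24h"): 2.0},
        )
        profs = pathway_profiles(t)
        assert np.allclose(profs[("GC", "24h")].ratios, 1.0)

    def test_missing_integral_rejected(self):
        base = np.array([1.0, 2.0])
        t = small_table(
            {("GC", "3h"): base, ("THz", "3h"): base}, {("GC", "3h"): 1.0}
        )
        with pytest.raises(ValueError, match="integral"):
            normalize_intensities(t)


class TestPathways:
    def test_reference_profile_is_unity(self):
        base = np.array([1.0, 2.0, 3.0])
        t = small_table({("GC", "3h"): base}, {("GC", "3h"): 1.0})
        profs = pathway_profiles(t)
        assert np.allclose(profs[("GC", "3h")].ratios, 1.0)

    def test_per_methyl_gain_recovered(self):
        base = np.array([1.0, 2.0, 3.0])
        g = np.array([1.1, 0.9, 1.3])
        t = small_table(
            {("GC", "3h"): base, ("THz", "3h"): base * g},
            {("GC", "3h"): 1.0, ("THz", "3h"): 1.0},
        )
        profs = pathway_profiles(t)
        assert np.allclose(np.sort(profs[("THz", "3h")].ratios.to_numpy()), np.sort(g))

    def test_correlation_of_identical_and_reflected(self):
        idx = pd.MultiIndex.from_tuples([(i, "d") for i in range(5)])
        r = pd.Series([1.1, 0.8, 1.3, 0.95, 1.05], index=idx)
        a = PathwayProfile("THz", "3h", r)
        b = PathwayProfile("GC", "24h", 2.0 - r)
        assert pathway_correlation(a, a) == pytest.approx(1.0)
        assert pathway_correlation(a, b) == pytest.approx(-1.0)

    def test_planted_correlation_sign_recovery(self, rng):
        # planted rho = +/-0.6 at n = 57: the sign of the Pearson estimate
        # is recovered in at least 99% of 500 draws
        n, rho = 57, 0.6
        hits = 0
        draws = 500
        for _ in range(draws):
            x = rng.standard_normal(n)
            for sign in (1.0, -1.0):
                y = sign * (rho * x + np.sqrt(1 - rho**2) * rng.standard_normal(n))
                idx = pd.MultiIndex.from_tuples([(i, "d") for i in range(n)])
                a = PathwayProfile("A", "3h", pd.Series(1.0 + 0.1 * x, index=idx))
                b = PathwayProfile("B", "3h", pd.Series(1.0 + 0.1 * y, index=idx))
                hits += np.sign(pathway_correlation(a, b)) == sign
        assert hits >= 0.99 * 2 * draws


class TestFlagResponsive:
    def test_all_unity_flags_nothing(self):
        idx = pd.MultiIndex.from_tuples([(i, "d") for i in range(10)])
        p = PathwayProfile("GC", "24h", pd.Series(np.ones(10), index=idx))
        with pytest.raises(ValueError, match="degenerate"):
            flag_responsive(p)

    def test_single_outlier_flagged(self):
        n = 57
        ratios = np.ones(n)
        ratios[-1] = 1.5  # far beyond the SD of the ratio set
        idx = pd.MultiIndex.from_tuples([(i, "d") for i in range(n)])
        inc, dec, sd = flag_responsive(PathwayProfile("GC", "24h", pd.Series(ratios, index=idx)))
        assert inc == {(n - 1, "d")}
        assert dec == set()
        assert 0.5 > 3 * sd  # the outlier exceeds three SDs

    def test_reflection_swaps_flag_sets(self, rng):
        n = 57
        ratios = 1.0 + 0.05 * rng.standard_normal(n)
        idx = pd.MultiIndex.from_tuples([(i, "d") for i in range(n)])
        inc1, dec1, _ = flag_responsive(PathwayProfile("A", "3h", pd.Series(ratios, index=idx)))
        inc2, dec2, _ = flag_responsive(
            PathwayProfile("A", "3h", pd.Series(2.0 - ratios, index=idx))
        )
        assert inc1 == dec2 and dec1 == inc2

    def test_flags_invariant_to_global_rescaling(self, rng):
        n = 20
        base = np.exp(rng.normal(0, 0.3, n))
        factor = 1.0 + 0.2 * rng.standard_normal(n)
        t1 = small_table(
            {("GC", "3h"): base, ("GC", "24h"): base * factor},
            {("GC", "3h"): 1.0, ("GC", "24h"): 1.0},
        )
        t2 = small_table(
            {("GC", "3h"): 7 * base, ("GC", "24h"): 7 * base * factor},
            {("GC", "3h"): 7.0, ("GC", "24h"): 7.0},
        )
        f1 = flag_responsive(pathway_profiles(t1)[("GC", "24h")])
        f2 = flag_responsive(pathway_profiles(t2)[("GC", "24h")])
        assert f1[0] == f2[0] and f1[1] == f2[1]
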