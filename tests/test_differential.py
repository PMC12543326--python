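"""Summit windows, counting, TMM, dispersions, NB exact test, BH, DBR calls."""

import subprocess

import numpy as np
import pytest

from enhancerstate.differential import (
    CountMatrix,
    DiffRegion,
    bh_adjust,
    call_dbrs,
    count_fragments,
    estimate_dispersions,
    nb_exact_test,
    run_differential_binding,
    summit_windows,
    tmm_factors,
)
from enhancerstate.intervals import GenomicInterval, IntervalSet

from conftest import random_intervals
from oracles import bh_oracle, conditional_binomial_pvalue, midpoint_count_oracle

SAMPLES = [f"s{i}" for i in range(6)]
GROUPS = {f"s{i}": ("WT" if i < 3 else "KO") for i in range(6)}


def make_cm(counts, lib=None):
    counts = np.asarray(counts)
    n = counts.shape[0]
    regions = IntervalSet(
        GenomicInterval("chr1", i * 1000, i * 1000 + 500) for i in range(n)
    )
    samples = SAMPLES[: counts.shape[1]]
    groups = {s: GROUPS[s] for s in samples}
    if lib is None:
        lib = np.full(counts.shape[1], 1e6)
    return CountMatrix(regions, samples, counts, groups, lib)


class TestSummitWindows:
    def test_midpoint_window_spans_1000bp(self):
        s = IntervalSet([GenomicInterval("chr1", 1000, 2000)])
        (w,) = summit_windows(s, 500)
        assert (w.start, w.end) == (1000, 2000)

    def test_summit_offset_recentres_window(self):
        s = IntervalSet([GenomicInterval("chr1", 1000, 2000, summit_offset=300)])
        (w,) = summit_windows(s, 150)
        assert (w.start, w.end) == (1150, 1450)

    def test_clamped_at_chromosome_bounds(self):
        s = IntervalSet([GenomicInterval("chr1", 0, 200)], genome={"chr1": 450})
        (w,) = summit_windows(s, 500)  # summit 100
        assert (w.start, w.end) == (0, 450)
        with pytest.raises(ValueError):
            summit_windows(s, 0)

    def test_one_window_per_region(self, rng):
        s = random_intervals(rng, 50)
        assert len(summit_windows(s, 500)) == len(s)


class TestCountFragments:
    def test_no_fragments_gives_zero_matrix(self):
        windows = IntervalSet([GenomicInterval("chr1", 0, 100)])
        cm = count_fragments(windows, [IntervalSet(), IntervalSet()],
                             ["s0", "s3"], GROUPS)
        assert cm.counts.sum() == 0

    def test_single_midpoint_containment(self):
        windows = IntervalSet([GenomicInterval("chr1", 100, 200)])
        inside = IntervalSet([GenomicInterval("chr1", 50, 260)])  # midpoint 155
        outside = IntervalSet([GenomicInterval("chr1", 150, 460)])  # midpoint 305
        cm = count_fragments(windows, [inside, outside], ["s0", "s3"], GROUPS)
        assert cm.counts.tolist() == [[1, 0]]

    def test_matches_quadratic_oracle(self, rng):
        for _ in range(25):
            windows = random_intervals(rng, 30)
            frags = [random_intervals(rng, 200, max_len=250) for _ in range(2)]
            cm = count_fragments(windows, frags, ["s0", "s3"], GROUPS)
            for j, f in enumerate(frags):
                assert cm.counts[:, j].tolist() == midpoint_count_oracle(windows, f)


class TestTMM:
    def test_identical_columns_give_unit_factors(self, rng):
        col = rng.poisson(50, size=400)
        cm = make_cm(np.stack([col] * 4, axis=1))
        assert np.allclose(tmm_factors(cm), 1.0)

    def test_doubled_column_effective_sizes_ratio_two(self, rng):
        col = rng.poisson(100, size=500) + 1
        cm = make_cm(np.stack([col, 2 * col], axis=1)[:, :2],
                     lib=np.array([col.sum(), 2 * col.sum()], dtype=float))
        f = tmm_factors(cm)
        eff = cm.lib_sizes * f
        assert eff[1] / eff[0] == pytest.approx(2.0, rel=1e-6)
        assert np.allclose(f, 1.0, atol=1e-6)

    def test_geometric_mean_is_one(self, rng):
        counts = rng.negative_binomial(10, 0.1, size=(300, 6))
        cm = make_cm(counts, lib=counts.sum(0).astype(float))
        f = tmm_factors(cm)
        assert np.prod(f) ** (1 / len(f)) == pytest.approx(1.0, abs=1e-12)

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(ValueError):
            tmm_factors(make_cm(np.zeros((10, 4), dtype=int)))

    def test_agrees_with_edger_reference(self, rng, tmp_path):
        """Cross-check TMM factors against edgeR::calcNormFactors."""
        counts = rng.negative_binomial(5, 0.05, size=(400, 4))
        counts[rng.random(counts.shape) < 0.1] = 0
        lib = counts.sum(0).astype(float)
        cm = make_cm(counts, lib=lib)
        ours = tmm_factors(cm)
        cpath = tmp_path / "counts.tsv"
        np.savetxt(cpath, counts, fmt="%d", delimiter="\t")
        script = tmp_path / "tmm.R"
        script.write_text(
            "suppressMessages(library(edgeR))\n"
            f"x <- as.matrix(read.table('{cpath}', sep='\\t'))\n"
            "f <- calcNormFactors(x, method='TMM')\n"
            "cat(sprintf('%.12f', f), sep='\\n')\n"
        )
        res = subprocess.run(
            ["Rscript", "--vanilla", str(script)],
            capture_output=True, text=True, timeout=300,
        )
        assert res.returncode == 0, res.stderr
        theirs = np.array([float(x) for x in res.stdout.split()])
        assert np.allclose(ours, theirs, rtol=1e-6), (ours, theirs)


class TestDispersions:
    def test_poisson_counts_estimate_near_zero(self, rng):
        counts = rng.poisson(100, size=(2000, 6))
        disp = estimate_dispersions(make_cm(counts))
        assert np.median(disp) <= 0.05

    def test_nb_counts_recover_dispersion_scale(self, rng):
        size = 1 / 0.2
        counts = rng.negative_binomial(size, size / (size + 100), size=(2000, 6))
        disp = estimate_dispersions(make_cm(counts))
        assert 0.1 <= np.median(disp) <= 0.4

    def test_constant_region_clamped_to_floor(self):
        counts = np.vstack([np.full(6, 50), [10, 20, 30, 40, 50, 60]])
        disp = estimate_dispersions(make_cm(counts), n_prior=0.0)
        assert disp[0] == pytest.approx(1e-8)

    def test_single_replicate_group_rejected(self):
        counts = np.ones((5, 2), dtype=int)
        cm = CountMatrix(
            IntervalSet(GenomicInterval("chr1", i * 10, i * 10 + 5) for i in range(5)),
            ["s0", "s3"], counts, {"s0": "WT", "s3": "KO"}, np.array([1.0, 1.0]),
        )
        with pytest.raises(ValueError, match="fixed dispersion"):
            estimate_dispersions(cm)


class TestExactTest:
    def test_symmetric_counts_give_p_one_and_zero_lfc(self):
        counts = np.tile([[7, 3, 5, 7, 3, 5]], (4, 1))
        lfc, p = nb_exact_test(make_cm(counts), 0.1)
        assert np.allclose(p, 1.0)
        assert np.allclose(lfc, 0.0)

    def test_three_vs_seven_poisson_limit(self):
        counts = np.array([[1, 1, 1, 2, 2, 3]])
        lfc, p = nb_exact_test(make_cm(counts), 0.0)
        assert p[0] == pytest.approx(0.34375, abs=1e-12)
        assert lfc[0] > 0

    def test_exhaustive_binomial_limit(self):
        """phi -> 0 equals the exact conditional binomial for all totals <= 50."""
        rows, expected = [], []
        for t in range(1, 51):
            for s_ko in range(t + 1):
                s_wt = t - s_ko
                rows.append([s_wt, 0, 0, s_ko, 0, 0])
                expected.append(conditional_binomial_pvalue(s_ko, t, 3, 3))
        _, p = nb_exact_test(make_cm(np.array(rows)), 0.0)
        assert np.allclose(p, expected, atol=1e-12)
        # the NB route at tiny dispersion converges to the same values
        _, p_nb = nb_exact_test(make_cm(np.array(rows)), 1e-6)
        assert np.allclose(p_nb, expected, atol=1e-3)

    def test_group_label_swap_preserves_pvalues(self, rng):
        counts = rng.poisson(40, size=(50, 6))
        cm = make_cm(counts)
        _, p1 = nb_exact_test(cm, 0.1)
        swapped = CountMatrix(
            cm.regions, cm.samples, cm.counts,
            {s: ("KO" if g == "WT" else "WT") for s, g in cm.groups.items()},
            cm.lib_sizes,
        )
        _, p2 = nb_exact_test(swapped, 0.1)
        assert np.allclose(p1, p2)

    def test_type_one_error_calibrated(self, rng):
        """5000 null NB regions (phi=0.1, 3+3): rejection rate in [0.03, 0.07]."""
        size = 1 / 0.1
        counts = rng.negative_binomial(size, size / (size + 100), size=(5000, 6))
        _, p = nb_exact_test(make_cm(counts), 0.1)
        assert 0.03 <= (p < 0.05).mean() <= 0.07

    def test_negative_dispersion_rejected(self):
        with pytest.raises(ValueError):
            nb_exact_test(make_cm(np.ones((2, 6), dtype=int)), -0.1)


class TestBH:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.2]).tolist() == [0.2]

    def test_worked_example(self):
        q = bh_adjust([0.01, 0.02, 0.04])
        assert np.allclose(q, [0.03, 0.03, 0.04])

    def test_equal_pvalues_map_to_themselves(self):
        assert np.allclose(bh_adjust([0.07] * 9), 0.07)

    def test_matches_enumeration_and_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(50):
            p = rng.random(int(rng.integers(1, 40)))
            q = bh_adjust(p)
            assert np.allclose(q, bh_oracle(p.tolist()))
            assert np.allclose(q, multipletests(p, method="fdr_bh")[1])

    def test_monotone_and_dominates_p(self, rng):
        p = rng.random(200)
        q = bh_adjust(p)
        assert np.all(q >= p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])
        with pytest.raises(ValueError):
            bh_adjust([-0.1])


class TestCallDBRs:
    def region(self):
        return GenomicInterval("chr1", 0, 100)

    def test_threshold_and_sign_rules(self):
        results = [
            DiffRegion(self.region(), 1.2, 0.001, qvalue=0.049),
            DiffRegion(self.region(), 1.2, 0.001, qvalue=0.05),
            DiffRegion(self.region(), -0.3, 0.001, qvalue=0.01),
            DiffRegion(self.region(), 0.0, 0.001, qvalue=0.001),
        ]
        gained, lost = call_dbrs(results, alpha=0.05)
        assert [r.call for r in results] == ["gained", "ns", "lost", "ns"]
        assert len(gained) == 1 and len(lost) == 1

    def test_partition_of_tested_regions(self, rng):
        counts = rng.poisson(30, size=(100, 6))
        counts[:10, 3:] *= 8
        results = run_differential_binding(make_cm(counts), alpha=0.05)
        calls = {c: sum(r.call == c for r in results) for c in ("gained", "lost", "ns")}
        assert sum(calls.values()) == len(results)
        assert calls["gained"] >= 10 - 2  # planted eightfold increases found
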