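import numpy as np
import pandas as pd
import pytest

import mirdrift as md
from mirdrift.methylation import (
    define_promoters,
    fit_cpg_age_model,
    map_cpgs_to_promoters,
    summarize_promoter_methylation,
)

from conftest import brute_force_mapping


class TestFitCpgAgeModel:
    def test_noiseless_slope_exact(self):
        clin = md.generate_cohort(60, (50, 70), 60, seed=1)
        age_c = (clin["age_years"] - clin["age_years"].mean()).to_numpy()
        betas = pd.DataFrame(
            [0.3 + 0.001 * age_c], index=["cg1"], columns=clin["sample_id"]
        )
        res = fit_cpg_age_model(betas, clin)
        assert res.loc[0, "slope_per_year"] == pytest.approx(0.001, abs=1e-10)

    def test_zero_variance_probe_excluded_from_fdr(self):
        clin = md.generate_cohort(30, (50, 70), 60, seed=2)
        rng = np.random.default_rng(0)
        betas = pd.DataFrame(
            [np.full(30, 0.5), rng.uniform(0.2, 0.8, 30)],
            index=["flat", "ok"],
            columns=clin["sample_id"],
        )
        res = fit_cpg_age_model(betas, clin).set_index("probe_id")
        assert res.loc["flat", "slope_per_year"] == 0.0
        assert np.isnan(res.loc["flat", "p_value"])
        assert np.isnan(res.loc["flat", "fdr"])
        assert np.isfinite(res.loc["ok", "fdr"])

    def test_permuted_ages_give_near_nominal_rejection(self):
        """Permuting ages against a planted-effect matrix kills the signal.

        A single permutation leaves a small realized correlation with the
        true ages that is shared by every trend-carrying probe, so the
        per-permutation p-values are exchangeable but not independent;
        averaging the p<0.05 rate over permutations gives a stable check.
        """
        clin = md.generate_cohort(200, (43.5, 78.6), 61.6, seed=5)
        loci, probes = md.generate_annotation(100, (3, 5), seed=5)
        truth = md.plant_truth(loci, 20, 20, seed=5)
        betas = md.simulate_betas(clin, probes, truth, noise_sd=0.02, seed=5)
        rng = np.random.default_rng(99)
        rates = []
        for _ in range(5):
            permuted = clin.copy()
            permuted["age_years"] = rng.permutation(clin["age_years"].to_numpy())
            res = fit_cpg_age_model(betas, permuted)
            rates.append(float((res["p_value"] < 0.05).mean()))
        assert 0.02 <= np.mean(rates) <= 0.08


class TestDefinePromoters:
    def test_plus_strand_window(self):
        loci = pd.DataFrame(
            {"locus_id": ["mir1"], "chrom": ["chr1"], "start": [10_000],
             "end": [10_090], "strand": ["+"]}
        )
        w = define_promoters(loci).iloc[0]
        assert (w.tss, w.window_start, w.window_end) == (10_000, 8_000, 12_000)

    def test_minus_strand_window(self):
        loci = pd.DataFrame(
            {"locus_id": ["mir1"], "chrom": ["chr1"], "start": [5_000],
             "end": [6_000], "strand": ["-"]}
        )
        w = define_promoters(loci).iloc[0]
        assert (w.tss, w.window_start, w.window_end) == (6_000, 4_000, 8_000)

    def test_window_floored_at_chromosome_start(self):
        loci = pd.DataFrame(
            {"locus_id": ["mir1"], "chrom": ["chr1"], "start": [500],
             "end": [590], "strand": ["+"]}
        )
        w = define_promoters(loci).iloc[0]
        assert (w.window_start, w.window_end) == (1, 2_500)

    def test_missing_strand_rejected(self):
        loci = pd.DataFrame(
            {"locus_id": ["mir1"], "chrom": ["chr1"], "start": [500],
             "end": [590], "strand": [None]}
        )
        with pytest.raises(ValueError):
            define_promoters(loci)


class TestMapCpgs:
    def _window(self):
        return pd.DataFrame(
            {"base_id": ["mir1"], "chrom": ["chr1"], "window_start": [8_000],
             "window_end": [12_000], "tss": [10_000], "strand": ["+"]}
        )

    @pytest.mark.parametrize("pos, included", [(12_000, True), (12_001, False),
                                               (8_000, True), (7_999, False)])
    def test_closed_interval_boundaries(self, pos, included):
        probes = pd.DataFrame(
            {"probe_id": ["cg1"], "chrom": ["chr1"], "position": [pos]}
        )
        mapping = map_cpgs_to_promoters(probes, self._window())
        assert ("mir1" in mapping) == included

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            n_probes, n_windows = 200, 20
            probes = pd.DataFrame(
                {
                    "probe_id": [f"cg{i}" for i in range(n_probes)],
                    "chrom": rng.choice(["chr1", "chr2"], n_probes),
                    "position": rng.integers(1, 60_000, n_probes),
                }
            )
            starts = rng.integers(1, 56_000, n_windows)
            windows = pd.DataFrame(
                {
                    "base_id": [f"mir{i}" for i in range(n_windows)],
                    "chrom": rng.choice(["chr1", "chr2"], n_windows),
                    "window_start": starts,
                    "window_end": starts + 4_000,
                    "tss": starts + 2_000,
                    "strand": "+",
                }
            )
            assert map_cpgs_to_promoters(probes, windows) == brute_force_mapping(
                probes, windows
            )

    def test_chromosome_mismatch_warns(self):
        probes = pd.DataFrame(
            {"probe_id": ["cg1"], "chrom": ["1"], "position": [9_000]}
        )
        with pytest.warns(UserWarning, match="chromosome"):
            mapping = map_cpgs_to_promoters(probes, self._window())
        assert mapping == {}


class TestSummarize:
    def _fits(self, slopes, fdrs):
        return pd.DataFrame(
            {
                "probe_id": [f"cg{i}" for i in range(len(slopes))],
                "slope_per_year": slopes,
                "std_error": [0.001] * len(slopes),
                "p_value": [0.01] * len(slopes),
                "fdr": fdrs,
            }
        )

    def test_mean_of_two_slopes(self):
        out = summarize_promoter_methylation(
            {"mir1": {"cg0", "cg1"}}, self._fits([0.001, 0.003], [0.1, 0.2])
        ).iloc[0]
        assert out.mean_slope_per_year == pytest.approx(0.002)
        assert out.status == "Hyper"
        assert out.pct_per_year == pytest.approx(0.2)

    def test_single_cpg_passthrough(self):
        out = summarize_promoter_methylation(
            {"mir1": {"cg0"}}, self._fits([-0.004], [0.03])
        ).iloc[0]
        assert out.mean_slope_per_year == pytest.approx(-0.004)
        assert out.min_fdr == pytest.approx(0.03)
        assert out.n_cpgs == 1 and out.status == "Hypo"

    def test_hand_arithmetic_three_cpgs(self):
        out = summarize_promoter_methylation(
            {"mir1": {"cg0", "cg1", "cg2"}},
            self._fits([0.002, -0.001, 0.005], [0.2, 0.04, 0.5]),
        ).iloc[0]
        assert out.mean_slope_per_year == pytest.approx(0.002)
        assert out.min_fdr == pytest.approx(0.04)
        assert out.n_cpgs == 3

    def test_permutation_invariant_in_cpg_order(self):
        fits = self._fits([0.001, 0.002, 0.003], [0.3, 0.2, 0.1])
        a = summarize_promoter_methylation({"mir1": {"cg0", "cg1", "cg2"}}, fits)
        b = summarize_promoter_methylation(
            {"mir1": {"cg2", "cg0", "cg1"}}, fits.iloc[::-1]
        )
        pd.testing.assert_frame_equal(a, b)

    def test_uncovered_mirna_omitted(self):
        fits = self._fits([0.001], [0.5])
        fits.loc[0, "p_value"] = np.nan  # excluded probe
        out = summarize_promoter_methylation({"mir1": {"cg0"}}, fits)
        assert out.empty


def test_noiseless_drift_recovered_exactly_per_mirna():
    clin = md.generate_cohort(80, (50, 70), 60, seed=6)
    loci, probes = md.generate_annotation(10, (2, 3), seed=6)
    truth = md.plant_truth(loci, 3, 3, seed=6)
    betas = md.simulate_betas(clin, probes, truth, noise_sd=0.0, seed=6,
                              baseline_range=(0.4, 0.6))
    res = fit_cpg_age_model(betas, clin)
    mapping = map_cpgs_to_promoters(probes, md.define_promoters(loci))
    summaries = summarize_promoter_methylation(mapping, res).set_index("base_id")
    for row in truth.itertuples():
        if row.base_id in summaries.index:
            assert summaries.loc[row.base_id, "mean_slope_per_year"] == pytest.approx(
                row.beta_slope_per_year, abs=1e-9
            )
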