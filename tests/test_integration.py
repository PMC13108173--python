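import numpy as np
import pandas as pd
import pytest

import mirdrift as md
from mirdrift.integration import (
    classify_concordance,
    concordance_score,
    integrate,
    rank_candidates,
    sensitivity_reanalysis,
)


def _expr(base_ids, b=0.05, fdr=0.001, mirna_ids=None):
    b = np.broadcast_to(np.asarray(b, dtype=float), (len(base_ids),))
    fdr = np.broadcast_to(np.asarray(fdr, dtype=float), (len(base_ids),))
    return pd.DataFrame(
        {
            "mirna_id": mirna_ids or base_ids,
            "base_id": base_ids,
            "log2fc_per_year": b,
            "std_error": 0.01,
            "p_value": fdr / 2,
            "fdr": fdr,
            "pct_per_year": md.log2fc_to_pct_per_year(b),
            "direction": np.where(b > 0, "Up", "Down"),
        }
    )


def _meth(base_ids, slope=-0.002, min_fdr=0.01):
    slope = np.broadcast_to(np.asarray(slope, dtype=float), (len(base_ids),))
    return pd.DataFrame(
        {
            "base_id": base_ids,
            "mean_slope_per_year": slope,
            "min_fdr": min_fdr,
            "n_cpgs": 2,
            "pct_per_year": 100 * slope,
            "status": np.where(slope > 0, "Hyper", "Hypo"),
        }
    )


class TestClassify:
    @pytest.mark.parametrize(
        "direction, status, expected",
        [
            ("Down", "Hyper", "concordant"),
            ("Up", "Hypo", "concordant"),
            ("Up", "Hyper", "discordant"),
            ("Down", "Hypo", "discordant"),
        ],
    )
    def test_sign_rule(self, direction, status, expected):
        assert classify_concordance(direction, status) == expected

    def test_undefined_inputs_rejected(self):
        with pytest.raises(ValueError):
            classify_concordance("Sideways", "Hyper")
        with pytest.raises(ValueError):
            classify_concordance("Up", "NA")

    def test_symmetric_under_double_sign_flip(self):
        flip_d = {"Up": "Down", "Down": "Up"}
        flip_s = {"Hyper": "Hypo", "Hypo": "Hyper"}
        for d in ("Up", "Down"):
            for s in ("Hyper", "Hypo"):
                assert classify_concordance(d, s) == classify_concordance(
                    flip_d[d], flip_s[s]
                )

    def test_reference_pairs_all_concordant(self, reference_candidates):
        classes = [
            classify_concordance(d, s)
            for d, s in zip(
                reference_candidates["expr_direction"],
                reference_candidates["meth_status"],
            )
        ]
        assert classes.count("concordant") == 20


class TestIntegrate:
    def test_inner_join_intersection(self):
        joined = integrate(_expr(["a", "b", "c"]), _meth(["b", "c", "d"]))
        assert list(joined["base_id"]) == ["b", "c"]

    def test_arm_duplicates_resolved_to_single_record(self):
        expr = _expr(
            ["mir72", "mir72"],
            b=[0.05, 0.08],
            fdr=[0.01, 0.001],
            mirna_ids=["hsa-miR-7-2", "hsa-miR-7-2-3p"],
        )
        joined = integrate(expr, _meth(["mir72"]))
        assert len(joined) == 1
        # smallest adjusted p wins
        assert joined.loc[0, "expr_b"] == pytest.approx(0.08)

    def test_empty_side_gives_empty_output(self):
        joined = integrate(_expr([]), _meth(["a"]))
        assert joined.empty


class TestScore:
    def test_raw_product_of_reference_row(self):
        rec = integrate(_expr(["x", "y"], b=[0.01, -0.02]), _meth(["x", "y"]))
        rec.loc[0, ["expr_pct_per_year", "meth_pct_per_year"]] = [0.174, -0.122]
        scored = concordance_score(rec, mode="raw")
        assert scored.loc[0, "raw_score"] == pytest.approx(0.021228)

    def test_zero_coefficient_gives_zero_raw_score(self):
        rec = integrate(_expr(["x", "y"]), _meth(["x", "y"]))
        rec.loc[0, "expr_pct_per_year"] = 0.0
        assert concordance_score(rec, "raw").loc[0, "raw_score"] == 0.0

    def test_znorm_zero_for_mean_coefficient(self):
        rec = integrate(_expr(["a", "b", "c"], b=[0.02, 0.04, 0.06]),
                        _meth(["a", "b", "c"], slope=[-0.001, -0.002, -0.004]))
        # middle expression coefficient equals the set mean -> z_expr = 0
        rec["expr_pct_per_year"] = [1.0, 2.0, 3.0]
        scored = concordance_score(rec, mode="znorm")
        assert scored.loc[1, "z_score"] == pytest.approx(0.0, abs=1e-12)

    def test_znorm_rejects_degenerate_spread(self):
        rec = integrate(_expr(["a", "b"]), _meth(["a", "b"]))
        with pytest.raises(ValueError):
            concordance_score(rec, mode="znorm")
        with pytest.raises(ValueError):
            concordance_score(rec.iloc[:1], mode="znorm")
        with pytest.raises(ValueError):
            concordance_score(rec.iloc[:0], mode="raw")

    def test_scale_equivariance(self):
        rec = integrate(_expr(["a", "b", "c"], b=[0.02, -0.05, 0.09]),
                        _meth(["a", "b", "c"], slope=[-0.001, 0.003, -0.002]))
        base = concordance_score(rec, mode="znorm")
        scaled = rec.copy()
        scaled["expr_pct_per_year"] *= 3.0
        out = concordance_score(scaled, mode="znorm")
        np.testing.assert_allclose(out["raw_score"], 3.0 * base["raw_score"])
        np.testing.assert_allclose(out["z_score"], base["z_score"], atol=1e-12)


class TestRank:
    def _scored(self, scores, base_ids=None):
        n = len(scores)
        base_ids = base_ids or [f"m{i}" for i in range(n)]
        return pd.DataFrame(
            {
                "base_id": base_ids,
                "concordance_class": ["concordant"] * n,
                "score": scores,
            }
        )

    def test_highest_score_ranked_first(self):
        ranked = rank_candidates(self._scored([0.5, 0.2, 0.9]))
        assert ranked.loc[0, "score"] == 0.9 and ranked.loc[0, "rank"] == 1
        assert list(ranked["rank"]) == [1, 2, 3]

    def test_ties_broken_lexicographically(self):
        ranked = rank_candidates(self._scored([0.5, 0.5], ["zeta", "alpha"]))
        assert list(ranked["base_id"]) == ["alpha", "zeta"]

    def test_permutation_invariance(self):
        df = self._scored([0.1, 0.9, 0.4, 0.9, 0.2])
        shuffled = df.sample(frac=1, random_state=3).reset_index(drop=True)
        pd.testing.assert_frame_equal(rank_candidates(df), rank_candidates(shuffled))

    def test_discordant_records_excluded(self):
        df = self._scored([0.5, 0.7])
        df.loc[0, "concordance_class"] = "discordant"
        ranked = rank_candidates(df)
        assert len(ranked) == 1 and ranked.loc[0, "rank"] == 1


class TestSensitivity:
    def test_age_independent_covariates_keep_most_flags(self):
        study = md.simulate_study(
            seed=31, n_samples=250, n_mirna=60, n_concordant=10, n_discordant=10,
            expr_effect_range=(0.05, 0.2), meth_effect_range=(0.003, 0.005),
        )
        expr = md.fit_age_model(study.counts, study.clinical)
        _, final = md.select_age_associated(expr)
        cpg = md.fit_cpg_age_model(study.betas, study.clinical)
        mapping = md.map_cpgs_to_promoters(
            study.probes, md.define_promoters(study.loci)
        )
        meth = md.summarize_promoter_methylation(mapping, cpg)
        joined = md.integrate(final, meth)
        primary_conc = set(
            joined.loc[joined["concordance_class"] == "concordant", "base_id"]
        )
        robust = sensitivity_reanalysis(
            study.counts, study.betas, study.clinical, study.loci, study.probes,
            ["gleason", "t_stage"],
        )
        planted = set(
            study.truth.loc[
                study.truth["planted_class"] == "concordant", "base_id"
            ]
        )
        strong = primary_conc & planted
        assert len(strong) > 0
        assert len(strong & robust) / len(strong) >= 0.8

    def test_reference_table_robust_count(self, reference_candidates):
        assert int(reference_candidates["covariate_robust"].sum()) == 10
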