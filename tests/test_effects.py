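import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crispri_screen.effects import (
    atc_effect,
    atc_effects,
    classify_effects,
    combine_replicates,
    drug_effects,
    effect_magnitude,
    interaction_summary,
    median_center_effects,
)
from crispri_screen.fitness import guide_fitness
from crispri_screen.simulate import SimConfig, simulate_counts, simulate_library, simulate_locus


def _f(guide, mean, var, count=100):
    return {"guide_id": guide, "mean": mean, "variance": var, "count": count}


class TestAtcEffect:
    def test_identical_fitness_gives_zero(self):
        a = atc_effect(_f("g", -1.2, 0.05), _f("g", -1.2, 0.05))
        assert a["mean"] == 0.0

    def test_difference_of_independent_normals(self):
        a = atc_effect(_f("g", -2.0, 0.10), _f("g", -0.5, 0.05))
        assert a["mean"] == pytest.approx(-1.5)
        assert a["variance"] == pytest.approx(0.15)

    def test_low_uninduced_count_filters(self):
        a = atc_effect(_f("g", -2.0, 0.1), _f("g", -0.5, 0.05, count=29))
        assert a["filtered"] and np.isnan(a["mean"])

    def test_boundary_count_passes(self):
        a = atc_effect(_f("g", -2.0, 0.1), _f("g", -0.5, 0.05, count=30))
        assert not a["filtered"]

    def test_mismatched_guides_raise(self):
        with pytest.raises(ValueError):
            atc_effect(_f("g1", 0, 1), _f("g2", 0, 1))


class TestCombineReplicates:
    def test_equal_weight_average(self):
        mean, var, n = combine_replicates([-1, -3], [1, 1])
        assert (mean, var, n) == (-2.0, 0.5, 2)

    def test_single_replicate_unchanged(self):
        mean, var, n = combine_replicates([-1.7], [0.3])
        assert (mean, var) == (-1.7, 0.3)

    @given(st.integers(min_value=1, max_value=8), st.floats(0.01, 10.0))
    @settings(max_examples=25, deadline=None)
    def test_equal_variance_replicates_scale_as_one_over_r(self, r, v):
        _, var, _ = combine_replicates([0.0] * r, [v] * r)
        assert var == pytest.approx(v / r)

    def test_all_filtered_raises(self):
        with pytest.raises(ValueError):
            combine_replicates([np.nan], [np.nan])


class TestMedianCentering:
    def _effects(self, means):
        return pd.DataFrame(
            {
                "guide_id": [f"g{i}" for i in range(len(means))],
                "kind": "A",
                "pool": "p",
                "compound": "DMSO",
                "concentration": 1.0,
                "mean": means,
                "variance": 0.1,
                "n_replicates": 1,
                "filtered": False,
            }
        )

    def test_symmetric_effects_unchanged(self):
        eff = self._effects([-1.0, 0.0, 1.0])
        out = median_center_effects(eff)
        assert np.allclose(out["mean"], eff["mean"])

    def test_constant_shift_removed(self):
        base = self._effects([-1.0, 0.0, 1.0])
        shifted = self._effects([4.0, 5.0, 6.0])
        out = median_center_effects(shifted)
        assert np.allclose(out["mean"], base["mean"])
        assert np.allclose(out["variance"], shifted["variance"])

    def test_singleton_group_centers_to_zero(self):
        out = median_center_effects(self._effects([3.7]))
        assert out["mean"].iloc[0] == 0.0


class TestEffectMagnitude:
    @pytest.mark.parametrize("mean,mag", [(-3.2, 3.2), (0.7, 0.0), (0.0, 0.0)])
    def test_censored_absolute_value(self, mean, mag):
        assert effect_magnitude(mean) == mag

    def test_filtered_input_rejected(self):
        with pytest.raises(ValueError):
            effect_magnitude(np.nan)


class TestClassifyEffects:
    def _effects(self, means):
        return pd.DataFrame({"mean": means, "filtered": False})

    def test_thresholds_strict(self):
        labels = classify_effects(self._effects([-1.5, -1.9, -2.0, -2.1]))
        assert labels["growth_defect"].tolist() == [True, True, True, True]
        assert labels["effective"].tolist() == [False, False, False, True]

    def test_counts_monotone_in_threshold(self):
        rng = np.random.default_rng(0)
        eff = self._effects(rng.normal(-1, 1.5, 200))
        counts = [
            classify_effects(eff, {"t": t})["t"].sum() for t in (-0.5, -1.0, -1.5, -2.0)
        ]
        assert counts == sorted(counts, reverse=True)


class TestInteractionSummary:
    def _d(self, means, genes, filtered=None):
        n = len(means)
        return (
            pd.DataFrame(
                {
                    "guide_id": [f"g{i}" for i in range(n)],
                    "kind": "D",
                    "pool": "p",
                    "compound": "drug",
                    "concentration": 1.0,
                    "mean": means,
                    "variance": 0.1,
                    "n_replicates": 2,
                    "filtered": filtered if filtered is not None else [False] * n,
                }
            ),
            pd.DataFrame({"guide_id": [f"g{i}" for i in range(n)], "gene": genes}),
        )

    def test_mean_over_guide_set(self):
        d, lib = self._d([-2.0, -1.0, 0.0], ["x", "x", "x"])
        out = interaction_summary(d, lib)
        assert out["mean_D"].iloc[0] == pytest.approx(-1.0)
        assert not out["interaction"].iloc[0]  # strict > 1

    def test_fully_filtered_gene_is_missing_not_zero(self):
        d, lib = self._d([-2.0, np.nan], ["x", "y"], filtered=[False, True])
        out = interaction_summary(d, lib).set_index("gene")
        assert np.isnan(out.loc["y", "mean_D"])
        assert out.loc["y", "n_guides"] == 0


@pytest.fixture(scope="module")
def sim_effects():
    # one drug-sensitive gene in ten keeps the pool median pinned in the
    # unaffected bulk (median-centering drifts when a large fraction of
    # the pool is depleted)
    cfg = SimConfig(seed=9, n_genes=10, n_guides_per_gene=8, depth=200_000, replicates=2)
    genome, ann, (nuc, _) = simulate_locus(cfg)
    lib = simulate_library(cfg, genome, ann, nuc)
    matrix, truth = simulate_counts(cfg, lib)
    fit = guide_fitness(matrix, n_draws=300, seed=0)
    samples = matrix.samples.reset_index()
    return cfg, lib, truth, atc_effects(fit, samples), drug_effects(fit, samples)


class TestPipelineOnSimulation:
    def test_drug_effect_zero_when_drug_matches_control(self, sim_effects):
        # guides of non-targeted genes: D centers on zero in every drug
        cfg, lib, truth, _, d = sim_effects
        d = d.merge(lib[["guide_id", "gene"]], on="guide_id")
        null = d[(~d["filtered"])
                 & (d.apply(lambda r: truth.interactions.loc[r["gene"], r["compound"]] == 0, axis=1))]
        assert abs(null["mean"].mean()) < 0.15

    def test_essential_like_gene_has_negative_a_but_null_d(self):
        # a gene depleted on induction alone (fitness cost without drug)
        genes = [f"gene{i+1:02d}" for i in range(8)]
        inter = pd.DataFrame({"drugZ": [0.0] * 7 + [-0.2]}, index=genes)
        cfg = SimConfig(seed=21, n_genes=8, n_guides_per_gene=8, depth=200_000,
                        replicates=2, interaction_matrix=inter)
        # make gene01 costly in every induced condition (essential-like)
        cfg.interaction_matrix.insert(0, "DMSO", [0.0] * 8)
        cfg.interaction_matrix.loc["gene01", :] = -0.15
        genome, ann, (nuc, _) = simulate_locus(cfg)
        lib = simulate_library(cfg, genome, ann, nuc)
        matrix, truth = simulate_counts(cfg, lib)
        fit = guide_fitness(matrix, n_draws=300, seed=0)
        samples = matrix.samples.reset_index()
        a = atc_effects(fit, samples).merge(lib[["guide_id", "gene"]], on="guide_id")
        d = drug_effects(fit, samples).merge(lib[["guide_id", "gene"]], on="guide_id")
        g1a = a[(a["gene"] == "gene01") & (a["compound"] == "DMSO") & ~a["filtered"]]
        g1d = d[(d["gene"] == "gene01") & (d["compound"] == "drugZ") & ~d["filtered"]]
        assert g1a["mean"].mean() < -1.0          # strongly depleted on induction
        assert abs(g1d["mean"].mean()) < 0.3      # but no drug-specific effect

    def test_filtered_guides_propagate_as_missing(self, sim_effects):
        _, _, _, a, d = sim_effects
        for eff in (a, d):
            assert eff.loc[eff["filtered"], "mean"].isna().all()
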