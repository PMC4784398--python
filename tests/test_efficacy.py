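import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

from crispri_screen.core import ChromatinTrack
from crispri_screen.efficacy import (
    footprint_score,
    footprint_window,
    guide_context,
    occupancy_correlation,
    position_profile,
    relative_effects,
    sequence_context_test,
    tf_overlap_test,
)


def _guide(start=100, end=120, strand="+", chrom="chr1", gid="g"):
    return {"guide_id": gid, "chrom": chrom, "start": start, "end": end,
            "target_strand": strand}


class TestFootprint:
    def test_window_is_target_plus_three_each_side(self):
        # 20-nt protospacer occupying bases 100-119 -> footprint 97-122 (26 bp)
        s, e = footprint_window(_guide())
        assert (s, e) == (97, 123)
        assert e - s == 26

    @pytest.mark.parametrize(
        "kind,step,n", [("nucleosome_base", 1, 200), ("atac_insertion", 1, 200), ("array_log2", 4, 50)]
    )
    def test_constant_track_returns_constant(self, kind, step, n):
        t = ChromatinTrack("chr1", 0, np.full(n, 1.7), kind, step=step)
        assert footprint_score(_guide(), t) == pytest.approx(1.7)

    def test_array_probes_number_six_or_seven(self):
        t = ChromatinTrack("chr1", 0, np.arange(100.0), "array_log2", step=4)
        for start in range(60, 80):
            g = _guide(start=start, end=start + 20)
            s, e = footprint_window(g)
            n = len(t.probe_values(s, e))
            assert n in (6, 7)

    def test_outside_extent_raises(self):
        t = ChromatinTrack("chr1", 99, np.ones(30), "nucleosome_base")
        with pytest.raises(ValueError):
            footprint_score(_guide(), t)

    def test_translation_equivariance(self):
        rng = np.random.default_rng(0)
        vals = rng.random(400)
        t0 = ChromatinTrack("chr1", 0, vals, "nucleosome_base")
        t1 = ChromatinTrack("chr1", 50, vals, "nucleosome_base")
        g0 = _guide(start=150, end=170)
        g1 = _guide(start=200, end=220)
        assert footprint_score(g0, t0) == pytest.approx(footprint_score(g1, t1))

    def test_atac_smoothing_averages_51_base_window(self):
        vals = np.zeros(400)
        vals[200] = 51.0  # one insertion spike
        t = ChromatinTrack("chr1", 0, vals, "atac_insertion")
        g = _guide(start=190, end=210)  # footprint 187-213 contains the spike
        # smoothed signal is 1.0 at every base within 25 bp of the spike
        assert footprint_score(g, t) == pytest.approx(1.0)


class TestPositionProfile:
    def test_equal_magnitudes_give_flat_profile(self):
        prof = position_profile(np.linspace(-300, 300, 100), np.full(100, 2.5))
        assert (prof["median"] == 2.5).all()

    def test_window_centers_step_apart(self):
        prof = position_profile(np.linspace(-200, 200, 500), np.random.default_rng(0).random(500))
        assert np.allclose(np.diff(prof["center"]), 25.0)

    def test_invariant_to_input_order(self):
        rng = np.random.default_rng(1)
        pos, mag = rng.uniform(-400, 400, 200), rng.random(200)
        p1 = position_profile(pos, mag)
        order = rng.permutation(200)
        p2 = position_profile(pos[order], mag[order])
        pd.testing.assert_frame_equal(p1, p2)

    def test_peak_recovered_from_peaked_signal(self):
        rng = np.random.default_rng(2)
        pos = rng.uniform(-500, 500, 400)
        mag = np.exp(-0.5 * ((pos + 100) / 80) ** 2) * 3 + rng.random(400) * 0.3
        prof = position_profile(pos, mag)
        best = prof.loc[prof["median"].idxmax(), "center"]
        assert -200 <= best <= 0


class TestOccupancyCorrelation:
    def test_identical_vectors_give_rho_one(self):
        x = np.linspace(0, 1, 50)
        out = occupancy_correlation(x, x)
        assert out["rho"] == pytest.approx(1.0)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            occupancy_correlation(np.ones(50), np.linspace(0, 1, 50))

    def test_null_correlation_small_at_n_500(self):
        rng = np.random.default_rng(3)
        rhos = [
            occupancy_correlation(rng.random(500), rng.random(500))["rho"] for _ in range(20)
        ]
        assert np.quantile(np.abs(rhos), 0.95) < 0.15

    def test_signs_follow_simulated_chromatin_dependence(self):
        from crispri_screen.simulate import SimConfig, guide_potency, simulate_library, simulate_locus

        cfg = SimConfig(seed=8, n_genes=5, n_guides_per_gene=80)
        genome, ann, (nuc, atac) = simulate_locus(cfg)
        lib = simulate_library(cfg, genome, ann, nuc, window=(-500, 500))
        mags = 4.0 * guide_potency(cfg, lib).loc[lib["guide_id"]].to_numpy()
        occ = [footprint_score(g, nuc) for _, g in lib.iterrows()]
        ins = [footprint_score(g, atac) for _, g in lib.iterrows()]
        pos = lib["tss_offset"].to_numpy()
        assert occupancy_correlation(mags, occ, pos)["rho"] < 0
        assert occupancy_correlation(mags, ins, pos)["rho"] > 0

    def test_tss_window_restriction_applied(self):
        pos = np.concatenate([np.full(30, -100.0), np.full(30, 600.0)])
        mags = np.concatenate([np.linspace(0, 1, 30), np.full(30, 5.0)])
        scores = np.concatenate([np.linspace(0, 1, 30), np.full(30, 9.0)])
        out = occupancy_correlation(mags, scores, pos)
        assert out["n"] == 30


def _effects_frame(n, means, genes=None, lib_start=1000):
    eff = pd.DataFrame(
        {
            "guide_id": [f"g{i}" for i in range(n)],
            "mean": means,
            "variance": 0.05,
            "filtered": False,
        }
    )
    lib = pd.DataFrame(
        {
            "guide_id": [f"g{i}" for i in range(n)],
            "chrom": "chr1",
            "start": np.arange(n) * 40 + lib_start,
            "end": np.arange(n) * 40 + lib_start + 20,
            "target_strand": "+",
            "length": 20,
            "gene": genes if genes is not None else "x",
        }
    )
    return eff, lib


class TestRelativeEffects:
    def test_bounded_and_normalized(self):
        eff, _ = _effects_frame(5, [-6.5, -3.0, -1.0, 0.0, 2.0])
        rel = relative_effects(eff)
        assert ((rel >= 0) & (rel <= 1)).all()
        assert rel.iloc[0] == 1.0  # clamped at -6 over denominator -6

    def test_nonnegative_set_maps_to_zero(self):
        eff, _ = _effects_frame(3, [0.5, 1.0, 2.0])
        assert (relative_effects(eff) == 0).all()

    def test_denominator_is_per_set(self):
        eff, _ = _effects_frame(4, [-4.0, -2.0, -1.0, -0.5])
        eff["gene"] = ["a", "a", "b", "b"]
        rel = relative_effects(eff)
        assert rel.iloc[1] == pytest.approx(0.5)   # -2 / -4
        assert rel.iloc[3] == pytest.approx(0.5)   # -0.5 / -1


@pytest.fixture(scope="module")
def genome():
    rng = np.random.default_rng(0)
    return {"chr1": "".join(rng.choice(list("ACGT"), 6000))}


class TestSequenceContext:
    def test_context_has_63_sites_for_full_length_guide(self, genome):
        ctx = guide_context(_guide(start=1000, end=1020), genome)
        assert len(ctx) == 63

    def test_minus_strand_context_is_revcomp_layout(self, genome):
        from crispri_screen.core import revcomp

        g = _guide(start=1000, end=1020, strand="-")
        ctx = guide_context(g, genome)
        assert len(ctx) == 63
        # protospacer occupies sites 20..39 on the protospacer strand
        assert ctx[20:40] == revcomp(genome["chr1"][1000:1020])

    def test_identical_effects_give_p_one_everywhere(self, genome):
        eff, lib = _effects_frame(40, [-2.0] * 40)
        out = sequence_context_test(eff, lib, genome, n_perm=200, seed=0)
        covered = out.dropna(subset=["p"])
        assert (covered["p"] == 1.0).all()

    def test_all_63_sites_reported_with_bonferroni_252(self, genome):
        eff, lib = _effects_frame(40, np.linspace(-4, 0, 40))
        out = sequence_context_test(eff, lib, genome, n_perm=100, seed=0)
        assert set(out["site"]) == set(range(63))
        assert len(out) == 252
        covered = out.dropna(subset=["p"])
        assert (covered["p_bonferroni"] >= covered["p"] - 1e-12).all()
        assert (covered["p_bonferroni"] <= 1.0).all()

    def test_planted_base_signal_found(self):
        # guides whose protospacer starts with A are made strong; the test
        # should rank site 20 (first protospacer base) x A most significant
        rng = np.random.default_rng(4)
        n = 120
        seq = list(rng.choice(list("ACGT"), 40 * n + 200))
        starts = np.arange(n) * 40 + 100
        carrier = rng.random(n) < 0.5
        for s, c in zip(starts, carrier):
            seq[s] = "A" if c else rng.choice(list("CGT"))
        genome = {"chr1": "".join(seq)}
        means = np.where(carrier, -4.0, -0.5) + rng.normal(0, 0.3, n)
        eff, lib = _effects_frame(n, means, lib_start=100)
        lib["start"] = starts
        lib["end"] = starts + 20
        out = sequence_context_test(eff, lib, genome, n_perm=2000, seed=0)
        best = out.dropna(subset=["p"]).sort_values("p_bonferroni").iloc[0]
        assert (best["site"], best["base"]) == (20, "A")

    def test_permutation_p_uniform_under_null(self):
        # P at one fixed (site, base) over independent null simulations
        rng = np.random.default_rng(5)
        ps = []
        for rep in range(300):
            n = 40
            seq = "".join(rng.choice(list("ACGT"), 40 * n + 200))
            eff, lib = _effects_frame(n, rng.normal(-2, 1, n), lib_start=100)
            lib["start"] = np.arange(n) * 40 + 100
            lib["end"] = lib["start"] + 20
            out = sequence_context_test(eff, lib, {"chr1": seq}, n_perm=500,
                                        seed=rng.integers(2**31))
            row = out[(out["site"] == 25) & (out["base"] == "A")].iloc[0]
            if row["n"] > 0:
                ps.append(row["p"])
        assert kstest(ps, "uniform").pvalue > 0.01


class TestTfOverlap:
    def _sites(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "factor"])

    def test_malformed_interval_rejected(self):
        eff, lib = _effects_frame(12, np.linspace(-3, 0, 12))
        sites = self._sites([("chr1", 100, 100, "TF1")])
        with pytest.raises(ValueError, match="malformed"):
            tf_overlap_test(eff, lib, sites)

    def test_factor_below_ten_guides_excluded(self):
        eff, lib = _effects_frame(30, np.linspace(-3, 0, 30))
        # TF1 spans 9 guides only; TF2 spans all
        sites = self._sites(
            [("chr1", int(lib.start[0]), int(lib.end[8]), "TF1"),
             ("chr1", int(lib.start[0]), int(lib.end[29]), "TF2")]
        )
        out = tf_overlap_test(eff, lib, sites, n_perm=100, seed=0)
        assert "TF1" not in set(out["factor"])
        assert "TF2" in set(out["factor"])

    def test_center_level_requires_middle_base(self):
        eff, lib = _effects_frame(30, np.linspace(-3, 0, 30))
        g0 = lib.iloc[0]
        mid = g0["start"] + 9  # base ceil(20/2) = 10, 0-based index 9
        covers_mid = self._sites([("chr1", mid, mid + 1, "TFmid")])
        covers_first = self._sites([("chr1", g0["start"], g0["start"] + 1, "TFfirst")])
        out_mid = tf_overlap_test(eff, lib, covers_mid, n_perm=50, seed=0, min_guides=1,
                                  levels=("center",))
        out_first = tf_overlap_test(eff, lib, covers_first, n_perm=50, seed=0, min_guides=1,
                                    levels=("center",))
        assert out_mid["n"].iloc[0] == 1
        assert len(out_first) == 0

    def test_null_p_uniform(self):
        rng = np.random.default_rng(6)
        ps = []
        for rep in range(300):
            eff, lib = _effects_frame(60, rng.normal(-2, 1, 60))
            # random subset of 15 guides overlapped by one factor
            chosen = rng.choice(60, 15, replace=False)
            sites = self._sites(
                [("chr1", int(lib.start[i]), int(lib.end[i]), "TF") for i in chosen]
            )
            out = tf_overlap_test(eff, lib, sites, n_perm=500, seed=rng.integers(2**31),
                                  levels=("any",))
            ps.append(out["p"].iloc[0])
        assert kstest(ps, "uniform").pvalue > 0.01
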