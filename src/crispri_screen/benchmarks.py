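"""End-to-end validation benchmarks run on synthetic screens.

Each function regenerates its own synthetic data from a seed, runs the
relevant pipeline stages from scratch, and returns summary statistics:
exact count round-trips, estimator coverage against simulated truth,
resampling-variance calibration against the analytic Gamma log-variance,
chemical-genetic interaction specificity, permutation-test null
calibration, and enrichment of the guide-design ranking.  The test suite
asserts on these numbers; ``scripts/acceptance.py`` reports them.
"""

from __future__ import annotations

import tempfile
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import polygamma
from scipy.stats import kstest

from . import io
from .counting import DEFAULT_LAYOUT, count_guides
from .design import rank_guides
from .effects import atc_effects, drug_effects, interaction_summary, median_center_effects
from .efficacy import sequence_context_test, tf_overlap_test
from .fitness import guide_fitness, posterior_count_variance
from .simulate import (
    SimConfig,
    guide_potency,
    simulate_counts,
    simulate_library,
    simulate_locus,
    simulate_reads,
)

LN2_SQ = np.log(2) ** 2


def _child_seeds(seed: int, n: int) -> list[int]:
    """Deterministic sub-seeds below 2**31."""
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def roundtrip_check(seed: int, depth: int = 20_000) -> dict:
    """Simulate reads at error fraction 0 and recount them.

    Returns the number of (guide, sample) cells differing between the
    generating and the recovered count matrices (0 = exact round trip).
    """
    cfg = SimConfig(seed=seed, n_genes=4, n_guides_per_gene=8, depth=depth, replicates=1)
    genome, ann, (nuc, _) = simulate_locus(cfg)
    lib = simulate_library(cfg, genome, ann, nuc)
    matrix, _ = simulate_counts(cfg, lib)
    with tempfile.TemporaryDirectory() as d:
        path = Path(d) / "reads.fastq.gz"
        io.write_fastq(simulate_reads(matrix, lib, seed=seed), path)
        recovered = count_guides(path, DEFAULT_LAYOUT, lib, matrix.samples.reset_index())
    diff = (recovered.counts.loc[matrix.counts.index, matrix.counts.columns]
            != matrix.counts).to_numpy()
    return {
        "mismatched_cells": int(diff.sum()),
        "n_cells": int(diff.size),
        "rejected_reads": int(sum(recovered.rejections.values())),
    }


def recovery_coverage(seed: int, n_genes: int = 30, n_guides_per_gene: int = 10,
                      depth: int = 1_000_000, replicates: int = 2) -> dict:
    """Coverage of true effects by combined A estimates +/- 2 SD.

    300 guides (30 genes x 10), depth 1e6, T = 20 doublings; six genes are
    drug-sensitive with selection coefficients spanning -0.25..-0.1 per
    doubling.  Median-centered A estimates are compared with
    median-centered truth (the centering step the screen itself applies
    before interpreting A), and the fraction of unfiltered guides whose
    truth lies within estimate +/- 2 SD is returned.
    """
    genes = [f"gene{i + 1:02d}" for i in range(n_genes)]
    s = np.zeros(n_genes)
    s[: max(2, n_genes // 5)] = np.linspace(-0.25, -0.1, max(2, n_genes // 5))
    inter = pd.DataFrame({"drugX": s}, index=genes)
    cfg = SimConfig(seed=seed, n_genes=n_genes, n_guides_per_gene=n_guides_per_gene,
                    depth=depth, replicates=replicates, interaction_matrix=inter)
    genome, ann, (nuc, _) = simulate_locus(cfg)
    lib = simulate_library(cfg, genome, ann, nuc)
    matrix, truth = simulate_counts(cfg, lib)
    fit = guide_fitness(matrix, seed=seed)
    a = atc_effects(fit, matrix.samples.reset_index())
    a = median_center_effects(a[a["compound"] == "drugX"]).set_index("guide_id")
    expected = truth.expected_atc_effect("drugX_atc_r1", "drugX_noatc_r1")
    expected = expected - expected.median()
    ok = a.index[~a["filtered"]]
    z = (a.loc[ok, "mean"] - expected[ok]) / np.sqrt(a.loc[ok, "variance"])
    return {"coverage_pct": float(100 * (z.abs() <= 2).mean()), "n_guides": int(len(ok))}


def variance_calibration(seed: int, counts=(30, 100, 1000), total: int = 1_000_000,
                         n_guides: int = 500, n_draws: int = 1000) -> dict:
    """Worst relative error of the resampling variance vs the analytic
    Gamma log-variance trigamma(c + 0.5) / ln(2)^2 across count levels."""
    errs = {}
    for c, s in zip(counts, _child_seeds(seed, len(counts))):
        v = posterior_count_variance(c, total, n_guides, n_draws=n_draws, seed=s)
        analytic = polygamma(1, c + 0.5) / LN2_SQ
        errs[c] = abs(v - analytic) / analytic
    return {
        "max_rel_error_pct": float(100 * max(errs.values())),
        "per_count_rel_error_pct": {str(c): float(100 * e) for c, e in errs.items()},
        "n_draws": n_draws,
    }


def interaction_specificity(seed: int, n_seeds: int = 20, n_genes: int = 8,
                            n_guides_per_gene: int = 10, depth: int = 200_000) -> dict:
    """Interaction flags (|mean D| > 1) on a diagonal truth across seeds.

    Returns the fraction of diagonal (true) gene x compound cells flagged
    and the fraction of off-diagonal (null) cells flagged.
    """
    diag_hits, diag_total, off_hits, off_total = 0, 0, 0, 0
    for s in _child_seeds(seed, n_seeds):
        cfg = SimConfig(seed=s, n_genes=n_genes, n_guides_per_gene=n_guides_per_gene,
                        depth=depth, replicates=2)
        genome, ann, (nuc, _) = simulate_locus(cfg)
        lib = simulate_library(cfg, genome, ann, nuc)
        matrix, truth = simulate_counts(cfg, lib)
        fit = guide_fitness(matrix, seed=s)
        d = drug_effects(fit, matrix.samples.reset_index())
        summary = interaction_summary(d, lib)
        for _, row in summary.iterrows():
            is_diag = truth.interactions.loc[row["gene"], row["compound"]] != 0
            if is_diag:
                diag_total += 1
                diag_hits += bool(row["interaction"])
            else:
                off_total += 1
                off_hits += bool(row["interaction"])
    return {
        "diagonal_flag_rate_pct": float(100 * diag_hits / diag_total),
        "offdiagonal_flag_rate_pct": float(100 * off_hits / off_total),
        "n_cells": diag_total + off_total,
        "n_seeds": n_seeds,
    }


def _null_effect_frame(rng, n):
    eff = pd.DataFrame(
        {
            "guide_id": [f"g{i}" for i in range(n)],
            "mean": rng.normal(-2.0, 1.0, n),
            "variance": 0.05,
            "filtered": False,
        }
    )
    lib = pd.DataFrame(
        {
            "guide_id": eff["guide_id"],
            "chrom": "chr1",
            "start": np.arange(n) * 40 + 100,
            "end": np.arange(n) * 40 + 120,
            "target_strand": "+",
            "length": 20,
            "gene": "x",
        }
    )
    return eff, lib


def permutation_null_calibration(seed: int, reps: int = 500, n_perm: int = 1000,
                                 n_guides: int = 40) -> dict:
    """KS uniformity of permutation P values under a null simulation.

    For the sequence-context test, each replicate simulates independent
    effects and a random target region and records the P at one fixed
    (site, base); for the TF-overlap test, a random factor footprint is
    drawn each replicate.  Both P samples are tested against Uniform(0,1).
    """
    rng = np.random.default_rng(seed)
    ps_ctx, ps_tf = [], []
    for _ in range(reps):
        n = n_guides
        eff, lib = _null_effect_frame(rng, n)
        seq = "".join(rng.choice(list("ACGT"), 40 * n + 200))
        out = sequence_context_test(eff, lib, {"chr1": seq}, n_perm=n_perm,
                                    seed=int(rng.integers(2**31)))
        row = out[(out["site"] == 25) & (out["base"] == "A")].iloc[0]
        if row["n"] > 0:
            ps_ctx.append(row["p"])

        eff, lib = _null_effect_frame(rng, 60)
        chosen = rng.choice(60, 15, replace=False)
        sites = pd.DataFrame(
            [("chr1", int(lib.start[i]), int(lib.end[i]), "TF") for i in chosen],
            columns=["chrom", "start", "end", "factor"],
        )
        tf = tf_overlap_test(eff, lib, sites, n_perm=n_perm,
                             seed=int(rng.integers(2**31)), levels=("any",))
        ps_tf.append(tf["p"].iloc[0])
    return {
        "context_ks_p": float(kstest(ps_ctx, "uniform").pvalue),
        "tf_ks_p": float(kstest(ps_tf, "uniform").pvalue),
        "reps": reps,
        "n_perm": n_perm,
    }


def design_rule_enrichment(seed: int, n_seeds: int = 10, n_genes: int = 5,
                           n_guides_per_gene: int = 60) -> dict:
    """Mean simulated potency of tier-1 vs tier-4 ranked guides per seed."""
    wins, gaps = 0, []
    for s in _child_seeds(seed, n_seeds):
        cfg = SimConfig(seed=s, n_genes=n_genes, n_guides_per_gene=n_guides_per_gene)
        genome, ann, (nuc, _) = simulate_locus(cfg)
        lib = simulate_library(cfg, genome, ann, nuc, window=(-500, 500))
        potency = guide_potency(cfg, lib)
        ranked = rank_guides(lib, dict(zip(ann["gene"], ann["tss"])), nuc)
        ranked = ranked.merge(potency.rename("potency"), left_on="guide_id",
                              right_index=True)
        means = ranked.groupby("tier")["potency"].mean()
        gap = float(means.get(1, np.nan) - means.get(4, np.nan))
        gaps.append(gap)
        wins += gap > 0
    return {
        "tier1_wins": int(wins),
        "n_seeds": n_seeds,
        "mean_potency_gap": float(np.nanmean(gaps)),
    }


def effective_fractions(seed: int, n_genes: int = 10, n_guides_per_gene: int = 50,
                        depth: int = 500_000) -> dict:
    """Fractions of guides with effective repression (gRNA effect < -2).

    Computes the gRNA effect (A in the guide's partner compound) on a
    broad +/-500 bp tiling simulation and reports the effective fraction
    over all guides, and over guides both within 200 bp upstream of the
    TSS and in locally depleted chromatin (the design-rule tier).
    """
    cfg = SimConfig(seed=seed, n_genes=n_genes, n_guides_per_gene=n_guides_per_gene,
                    depth=depth, replicates=2)
    genome, ann, (nuc, _) = simulate_locus(cfg)
    lib = simulate_library(cfg, genome, ann, nuc, window=(-500, 500))
    matrix, truth = simulate_counts(cfg, lib)
    fit = guide_fitness(matrix, seed=seed)
    a = atc_effects(fit, matrix.samples.reset_index())
    # partner-compound gRNA effect for each gene's guides
    lib_idx = lib.set_index("guide_id")
    a = a[~a["filtered"]].copy()
    a["gene"] = lib_idx["gene"].reindex(a["guide_id"]).to_numpy()
    a = a[a["compound"] == "drug_" + a["gene"]]
    ranked = rank_guides(lib, dict(zip(ann["gene"], ann["tss"])), nuc)
    tier = ranked.set_index("guide_id")["tier"].reindex(a["guide_id"]).to_numpy()
    effective = (a["mean"] < -2.0).to_numpy()
    top = tier == 1
    return {
        "effective_pct_all": float(100 * effective.mean()),
        "effective_pct_tier1": float(100 * effective[top].mean()),
        "n_guides": int(len(effective)),
        "n_tier1": int(top.sum()),
    }
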