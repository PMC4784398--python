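"""Determinants of guide efficacy: position, chromatin, sequence, TF sites.

Guide effect magnitudes are relate to (i) protospacer midpoint position
relative to the TSS (windowed medians), (ii) chromatin state at the dCas9
footprint (nucleosome occupancy, smoothed ATAC insertion density, or
tiling-array log2 ratios), (iii) the identity of each base in the target
region (permutation test on median relative effect), and (iv) overlap with
transcription-factor binding sites (permutation test on mean magnitude).

The dCas9 footprint of a guide is its genomic target sequence plus three
bases on either end (26 bp for a 20-nt spacer), following exonuclease
footprinting of the bound complex.
"""

from __future__ import annotations

from collections.abc import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .core import ChromatinTrack, revcomp

FOOTPRINT_PAD = 3
ATAC_SMOOTH_WINDOW = 51
CONTEXT_FLANK = 20
PAM_LEN = 3


def footprint_window(guide: Mapping) -> tuple[int, int]:
    """Genomic interval predicted to be occupied by bound dCas9."""
    return int(guide["start"]) - FOOTPRINT_PAD, int(guide["end"]) + FOOTPRINT_PAD


def footprint_score(guide: Mapping, track: ChromatinTrack) -> float:
    """Average chromatin signal over a guide's dCas9 footprint.

    * ``nucleosome_base``: mean per-base occupancy over the footprint.
    * ``atac_insertion``: the per-base signal is first smoothed with a
      centered 51-base mean, then averaged over the footprint.
    * ``array_log2``: mean of the 4-bp tiling-array probes overlapping the
      footprint (6 or 7 probes for a 26-bp window).
    """
    s, e = footprint_window(guide)
    if track.kind == "array_log2":
        return float(np.nanmean(track.probe_values(s, e)))
    if track.kind == "nucleosome_base":
        return float(np.nanmean(track.slice(s, e)))
    # atac_insertion: centered moving average, then footprint mean
    if not track.covers(s, e):
        raise ValueError(f"footprint [{s}, {e}) outside track extent")
    half = ATAC_SMOOTH_WINDOW // 2
    lo = max(track.start, s - half)
    hi = min(track.end, e + half)
    vals = track.slice(lo, hi)
    kernel = np.ones(ATAC_SMOOTH_WINDOW) / ATAC_SMOOTH_WINDOW
    # normalize by actual coverage near track edges
    smooth = np.convolve(vals, kernel, mode="same") / np.convolve(
        np.ones_like(vals), kernel, mode="same"
    )
    return float(np.nanmean(smooth[s - lo : e - lo]))


def position_profile(
    positions,
    magnitudes,
    width: int = 50,
    step: int = 25,
) -> pd.DataFrame:
    """Median effect magnitude in sliding TSS-relative position windows.

    Windows of ``width`` bp advance by ``step`` bp (overlapping when
    ``step < width``); windows containing no guides are omitted.  Returns
    columns center, start, end, median, n.
    """
    positions = np.asarray(positions, dtype=float)
    magnitudes = np.asarray(magnitudes, dtype=float)
    if positions.size == 0:
        return pd.DataFrame(columns=["center", "start", "end", "median", "n"])
    first = int(np.floor(positions.min() / step) * step)
    last = int(np.ceil(positions.max() / step) * step)
    rows = []
    for start in range(first - width + step, last + step, step):
        end = start + width
        mask = (positions >= start) & (positions < end)
        if not mask.any():
            continue
        rows.append(
            {
                "center": start + width / 2.0,
                "start": start,
                "end": end,
                "median": float(np.median(magnitudes[mask])),
                "n": int(mask.sum()),
            }
        )
    return pd.DataFrame(rows)


def occupancy_correlation(
    magnitudes,
    scores,
    positions=None,
    tss_window: tuple[int, int] = (-400, 400),
    bin_width: float = 0.25,
    bin_step: float = 0.125,
) -> dict:
    """Spearman correlation of effect magnitude with a chromatin score.

    Restricts to guides whose TSS-relative position (if given) lies in
    ``tss_window``.  Also returns overlapping-bin medians with first and
    third quartiles along the score axis (bins of ``bin_width`` advancing
    by ``bin_step``).
    """
    magnitudes = np.asarray(magnitudes, dtype=float)
    scores = np.asarray(scores, dtype=float)
    if positions is not None:
        positions = np.asarray(positions, dtype=float)
        keep = (positions >= tss_window[0]) & (positions <= tss_window[1])
        magnitudes, scores = magnitudes[keep], scores[keep]
    ok = ~(np.isnan(magnitudes) | np.isnan(scores))
    magnitudes, scores = magnitudes[ok], scores[ok]
    if len(magnitudes) < 10:
        raise ValueError("need at least 10 paired observations")
    if np.ptp(scores) == 0 or np.ptp(magnitudes) == 0:
        raise ValueError("constant input vector")
    rho, p = stats.spearmanr(scores, magnitudes)
    bins = []
    lo = np.floor(scores.min() / bin_step) * bin_step
    hi = scores.max()
    start = lo
    while start < hi:
        mask = (scores >= start) & (scores < start + bin_width)
        if mask.any():
            q1, med, q3 = np.percentile(magnitudes[mask], [25, 50, 75])
            bins.append(
                {"score_center": start + bin_width / 2, "median": med,
                 "q1": q1, "q3": q3, "n": int(mask.sum())}
            )
        start += bin_step
    return {"rho": float(rho), "p": float(p), "n": len(magnitudes),
            "bins": pd.DataFrame(bins)}


# ---------------------------------------------------------------------------
# permutation machinery

def _null_statistics(values: np.ndarray, sizes, n_perm: int, rng, statistic) -> dict[int, np.ndarray]:
    """Sorted null distributions of ``statistic`` over random subsets.

    One null distribution is drawn per distinct subset size and shared by
    all tests of that size within a call; subsets are drawn without
    replacement from the full guide set, matching the observed-subset
    exchangeability under the global null.
    """
    nulls = {}
    n = len(values)
    for size in sorted(set(int(s) for s in sizes)):
        idx = np.argsort(rng.random((n_perm, n)), axis=1)[:, :size]
        nulls[size] = np.sort(statistic(values[idx], axis=1))
    return nulls


def _perm_p(null_sorted: np.ndarray, observed: float, plus_one: bool) -> float:
    """Fraction of null draws at least as large as the observed statistic."""
    n = len(null_sorted)
    r = n - np.searchsorted(null_sorted, observed, side="left")
    if plus_one:
        return float((r + 1) / (n + 1))
    return float(r / n)


def relative_effects(
    effects: pd.DataFrame,
    set_col: str = "gene",
    clamp: tuple[float, float] = (-6.0, 0.0),
) -> pd.Series:
    """Normalized guide potency within each drug/gene set.

    Each guide's effect is divided by the most negative effect in its set,
    both clamped to ``clamp`` = [-6, 0], yielding relative effects in
    [0, 1] (1 = as potent as the set's best guide, capped at -6).  Sets
    whose minimum effect is non-negative get relative effect 0.
    """
    lo, hi = clamp
    out = pd.Series(np.nan, index=effects.index, dtype=float)
    if set_col not in effects.columns:
        effects = effects.assign(**{set_col: "all"})
    for _, idx in effects.groupby(set_col).groups.items():
        sub = effects.loc[idx, "mean"]
        denom = float(np.clip(sub.min(), lo, hi))
        if denom >= 0:
            out.loc[idx] = 0.0
        else:
            out.loc[idx] = np.clip(sub, lo, hi) / denom
    return out


def guide_context(guide: Mapping, genome: Mapping[str, str] | str, flank: int = CONTEXT_FLANK) -> str:
    """Target-region sequence on the protospacer strand.

    Layout (5'->3' on the protospacer strand): ``flank`` bases upstream of
    the protospacer, the protospacer, the PAM, and ``flank`` bases
    downstream of the PAM; 63 sites for a 20-nt spacer with 20-bp flanks.
    """
    seq = genome if isinstance(genome, str) else genome[guide["chrom"]]
    s, e = int(guide["start"]), int(guide["end"])
    if guide["target_strand"] == "+":
        ctx = seq[s - flank : e + PAM_LEN + flank]
    else:
        ctx = revcomp(seq[s - PAM_LEN - flank : e + flank])
    expect = (e - s) + 2 * flank + PAM_LEN
    if len(ctx) != expect:
        raise ValueError(f"context for {guide.get('guide_id')} truncated by contig edge")
    return ctx


def sequence_context_test(
    effects: pd.DataFrame,
    library: pd.DataFrame,
    genome: Mapping[str, str] | str,
    n_perm: int = 10000,
    seed=None,
    set_col: str = "gene",
    flank: int = CONTEXT_FLANK,
    plus_one: bool = False,
) -> pd.DataFrame:
    """Per-(site, base) permutation test on median relative guide effect.

    For each site of the target region (20 bp upstream flank + 20-nt
    protospacer + PAM + 20 bp downstream flank = 63 sites) and each base,
    guides carrying that base at that site are collected; their median
    relative effect is compared with random same-size samples of all
    guides.  P is the fraction of ``n_perm`` samples with at least as
    large a median; Bonferroni correction multiplies by 4 x sites (252
    tests), capped at 1.  Sites carried by no guide are reported missing.
    """
    df = effects.merge(
        library[["guide_id", "chrom", "start", "end", "target_strand", "length", set_col]]
        .drop_duplicates("guide_id"),
        on="guide_id",
        suffixes=("", "_lib"),
    )
    if set_col not in df.columns and f"{set_col}_lib" in df.columns:
        df[set_col] = df[f"{set_col}_lib"]
    df = df[(~df["filtered"]) & (df["length"] == 20)].reset_index(drop=True)
    if df.empty:
        raise ValueError("no unfiltered 20-nt guides with effects")
    rel = relative_effects(df, set_col=set_col).to_numpy()
    contexts = np.array([list(guide_context(g, genome, flank)) for _, g in df.iterrows()])
    n_sites = contexts.shape[1]
    n_tests = 4 * n_sites
    rng = np.random.default_rng(seed)

    masks, meta = [], []
    for site in range(n_sites):
        for base in "ACGT":
            mask = contexts[:, site] == base
            meta.append((site, base, int(mask.sum())))
            masks.append(mask)
    nulls = _null_statistics(rel, [m for _, _, m in meta if m > 0], n_perm, rng, np.median)

    rows = []
    for (site, base, n), mask in zip(meta, masks):
        if n == 0:
            rows.append({"site": site, "base": base, "n": 0, "median_relative_effect": np.nan,
                         "p": np.nan, "p_bonferroni": np.nan})
            continue
        obs = float(np.median(rel[mask]))
        p = _perm_p(nulls[n], obs, plus_one)
        rows.append(
            {"site": site, "base": base, "n": n, "median_relative_effect": obs,
             "p": p, "p_bonferroni": min(1.0, p * n_tests)}
        )
    return pd.DataFrame(rows)


def _overlap_interval(guide: Mapping, level: str) -> tuple[int, int]:
    s, e = int(guide["start"]), int(guide["end"])
    L = e - s
    if level == "any":
        return s, e
    if level == "mid10":
        off = (L - 10) // 2
        return s + off, s + off + 10
    if level == "center":
        # the single middle base, position ceil(L/2) 1-based from the start
        mid = s + (L + 1) // 2 - 1
        return mid, mid + 1
    raise ValueError(f"unknown overlap level {level!r}")


def tf_overlap_test(
    effects: pd.DataFrame,
    library: pd.DataFrame,
    tf_sites: pd.DataFrame,
    n_perm: int = 10000,
    seed=None,
    min_guides: int = 10,
    levels: tuple[str, ...] = ("center", "mid10", "any"),
    plus_one: bool = False,
) -> pd.DataFrame:
    """Permutation test of TF-binding-site overlap against guide potency.

    ``tf_sites`` needs columns chrom, start, end, factor (0-based
    half-open).  For each factor and overlap level (site covering the
    middle base of the spacer, the middle 10 bases, or any part of it),
    the mean effect magnitude of overlapping guides is compared with
    ``n_perm`` random same-size guide samples; factors overlapping fewer
    than ``min_guides`` guides at a level are excluded.  Bonferroni
    correction is over the tests actually performed.
    """
    bad = tf_sites[tf_sites["end"] <= tf_sites["start"]]
    if len(bad):
        raise ValueError(f"malformed interval(s): end <= start at rows {list(bad.index[:5])}")
    df = effects.merge(
        library[["guide_id", "chrom", "start", "end"]].drop_duplicates("guide_id"),
        on="guide_id", suffixes=("", "_lib"),
    )
    df = df[~df["filtered"]].reset_index(drop=True)
    mags = df["mean"].clip(upper=0.0).abs().to_numpy()
    rng = np.random.default_rng(seed)

    tests = []
    for level in levels:
        ivals = np.array([_overlap_interval(g, level) for _, g in df.iterrows()])
        for factor, sites in tf_sites.groupby("factor"):
            mask = np.zeros(len(df), dtype=bool)
            for _, site in sites.iterrows():
                same = df["chrom"].to_numpy() == site["chrom"]
                mask |= same & (ivals[:, 0] < site["end"]) & (ivals[:, 1] > site["start"])
            if mask.sum() >= min_guides:
                tests.append((factor, level, mask))
    if not tests:
        return pd.DataFrame(columns=["factor", "level", "n", "mean_magnitude", "p", "p_bonferroni"])
    nulls = _null_statistics(mags, [m.sum() for _, _, m in tests], n_perm, rng, np.mean)
    rows = []
    for factor, level, mask in tests:
        n = int(mask.sum())
        obs = float(mags[mask].mean())
        p = _perm_p(nulls[n], obs, plus_one)
        rows.append({"factor": factor, "level": level, "n": n, "mean_magnitude": obs,
                     "p": p, "p_bonferroni": min(1.0, p * len(tests))})
    return pd.DataFrame(rows)
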