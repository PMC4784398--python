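"""Guide-level effect estimates and chemical-genetic interaction summaries.

Two contrasts are computed from per-sample fitness estimates:

* **A**, the ATc-induced fold change: fitness with minus fitness without
  induction of the guide RNA, ``A ~ Normal(l+ - l-, s2+ + s2-)``.  A's in
  replicate cultures are combined by inverse-variance weighting.  A guide's
  A in the presence of its partner reference compound is its "gRNA effect".
* **D**, the drug-specific effect: fitness in a compound versus the DMSO
  vehicle control, both induced, ``D ~ Normal(l_drug - l_ctrl, s2_drug +
  s2_ctrl)`` with the control distribution combined across its replicates.

Guides with fewer than 30 reads in the relevant control culture are
filtered: for A, the minus-ATc culture of that replicate; for D, the
induced no-drug control.  Filtered estimates propagate as missing values,
never as zero effects.
"""

from __future__ import annotations

from collections.abc import Mapping

import numpy as np
import pandas as pd

MIN_CONTROL_READS = 30

EFFECT_COLUMNS = [
    "guide_id", "kind", "pool", "compound", "concentration",
    "mean", "variance", "n_replicates", "filtered",
]


def atc_effect(f_plus: Mapping, f_minus: Mapping, min_control_reads: int = MIN_CONTROL_READS) -> dict:
    """A for one guide in one replicate: difference of +/-ATc fitness."""
    if f_plus["guide_id"] != f_minus["guide_id"]:
        raise ValueError("mismatched guide ids")
    if f_minus["count"] < min_control_reads:
        return {"guide_id": f_plus["guide_id"], "kind": "A", "mean": np.nan,
                "variance": np.nan, "filtered": True}
    return {
        "guide_id": f_plus["guide_id"],
        "kind": "A",
        "mean": f_plus["mean"] - f_minus["mean"],
        "variance": f_plus["variance"] + f_minus["variance"],
        "filtered": False,
    }


def combine_replicates(means, variances):
    """Inverse-variance-weighted combination of replicate estimates.

    var = 1 / (1/var_1 + ... + 1/var_R);  mean = var * sum(mean_r / var_r).
    """
    means = np.asarray(means, dtype=float)
    variances = np.asarray(variances, dtype=float)
    ok = ~(np.isnan(means) | np.isnan(variances))
    if not ok.any():
        raise ValueError("no unfiltered replicate estimates to combine")
    w = 1.0 / variances[ok]
    var = 1.0 / w.sum()
    return float(var * (means[ok] * w).sum()), float(var), int(ok.sum())


def _condition_frame(fitness: pd.DataFrame, samples: pd.DataFrame) -> pd.DataFrame:
    s = samples.copy()
    if "sample" in s.columns:
        s = s.set_index("sample")
    return fitness.merge(
        s[["atc", "compound", "concentration", "replicate"]],
        left_on="sample", right_index=True,
    )


def atc_effects(
    fitness: pd.DataFrame,
    samples: pd.DataFrame,
    min_control_reads: int = MIN_CONTROL_READS,
) -> pd.DataFrame:
    """Replicate-combined A per (guide, compound, concentration).

    Pairs each induced sample with the uninduced sample of the same
    (pool, compound, concentration, replicate); replicate-level A's with a
    minus-ATc count below ``min_control_reads`` are dropped, and guides
    with no surviving replicate are reported filtered (NaN mean/variance).
    """
    df = _condition_frame(fitness, samples)
    plus = df[df["atc"]]
    minus = df[~df["atc"]]
    pair_keys = ["guide_id", "pool", "compound", "concentration", "replicate"]
    merged = plus.merge(minus, on=pair_keys, suffixes=("_plus", "_minus"))
    merged["rep_mean"] = merged["mean_plus"] - merged["mean_minus"]
    merged["rep_var"] = merged["variance_plus"] + merged["variance_minus"]
    merged.loc[merged["count_minus"] < min_control_reads, ["rep_mean", "rep_var"]] = np.nan
    return _combine(merged, ["guide_id", "pool", "compound", "concentration"], "A")


def _combine(merged: pd.DataFrame, keys: list[str], kind: str) -> pd.DataFrame:
    rows = []
    for key, sub in merged.groupby(keys, dropna=False, sort=False):
        rec = dict(zip(keys, key))
        rec["kind"] = kind
        try:
            mean, var, n = combine_replicates(sub["rep_mean"], sub["rep_var"])
            rec.update(mean=mean, variance=var, n_replicates=n, filtered=False)
        except ValueError:
            rec.update(mean=np.nan, variance=np.nan, n_replicates=0, filtered=True)
        rows.append(rec)
    return pd.DataFrame(rows)[EFFECT_COLUMNS]


def combined_control_fitness(
    fitness: pd.DataFrame,
    samples: pd.DataFrame,
    control_compound: str = "DMSO",
) -> pd.DataFrame:
    """Induced vehicle-control fitness combined across its replicates."""
    df = _condition_frame(fitness, samples)
    ctrl = df[df["atc"] & (df["compound"] == control_compound)]
    if ctrl.empty:
        raise ValueError(f"control condition {control_compound!r} (+ATc) absent")
    rows = []
    for (guide, pool), sub in ctrl.groupby(["guide_id", "pool"], sort=False):
        mean, var, n = combine_replicates(sub["mean"], sub["variance"])
        rows.append(
            {"guide_id": guide, "pool": pool, "mean": mean, "variance": var,
             "n_replicates": n, "mean_count": float(sub["count"].mean())}
        )
    return pd.DataFrame(rows)


def drug_effects(
    fitness: pd.DataFrame,
    samples: pd.DataFrame,
    control_compound: str = "DMSO",
    min_control_reads: int = MIN_CONTROL_READS,
) -> pd.DataFrame:
    """Replicate-combined D per (guide, compound, concentration).

    Contrasts each induced drug sample with the replicate-combined induced
    vehicle control of the same pool.  Guides averaging fewer than
    ``min_control_reads`` reads across the induced no-drug control
    replicates are filtered.
    """
    ctrl = combined_control_fitness(fitness, samples, control_compound)
    ctrl = ctrl.set_index(["guide_id", "pool"])
    df = _condition_frame(fitness, samples)
    drug = df[df["atc"] & (df["compound"] != control_compound)].copy()
    idx = pd.MultiIndex.from_frame(drug[["guide_id", "pool"]])
    drug["ctrl_mean"] = ctrl["mean"].reindex(idx).to_numpy()
    drug["ctrl_var"] = ctrl["variance"].reindex(idx).to_numpy()
    drug["ctrl_count"] = ctrl["mean_count"].reindex(idx).to_numpy()
    drug["rep_mean"] = drug["mean"] - drug["ctrl_mean"]
    drug["rep_var"] = drug["variance"] + drug["ctrl_var"]
    drug.loc[drug["ctrl_count"] < min_control_reads, ["rep_mean", "rep_var"]] = np.nan
    return _combine(drug, ["guide_id", "pool", "compound", "concentration"], "D")


def median_center_effects(effects: pd.DataFrame, by: str | list[str] = "pool") -> pd.DataFrame:
    """Subtract the group median of unfiltered means; variances unchanged."""
    out = effects.copy()
    if isinstance(by, str):
        by = [by]
    group_keys = [k for k in by + ["kind", "compound", "concentration"] if k in out.columns]
    for _, idx in out.groupby(group_keys, dropna=False).groups.items():
        sub = out.loc[idx]
        med = sub.loc[~sub["filtered"], "mean"].median()
        if np.isnan(med):
            continue
        out.loc[idx, "mean"] = sub["mean"] - med
    return out


def effect_magnitude(mean: float) -> float:
    """|min(A, 0)|: apparent resistance in a repression-only contrast is
    treated as technical noise and censored to zero before taking the
    absolute value."""
    if np.isnan(mean):
        raise ValueError("filtered estimate has no magnitude")
    return abs(min(mean, 0.0))


def effect_magnitudes(effects: pd.DataFrame) -> pd.Series:
    """Vectorized censored magnitude over unfiltered rows."""
    ok = effects[~effects["filtered"]]
    return ok["mean"].clip(upper=0.0).abs()


DEFAULT_THRESHOLDS = {"growth_defect": -1.0, "effective": -2.0}


def classify_effects(
    effects: pd.DataFrame,
    thresholds: Mapping[str, float] = DEFAULT_THRESHOLDS,
    on: str = "mean",
) -> pd.DataFrame:
    """Boolean label per guide per threshold; strictly ``value < t``."""
    out = pd.DataFrame(index=effects.index)
    for name, t in thresholds.items():
        out[name] = effects[on] < t
        out.loc[effects["filtered"] | effects[on].isna(), name] = False
    return out


def grna_effects(
    effects_a: pd.DataFrame,
    library: pd.DataFrame,
    reference: pd.DataFrame,
) -> pd.DataFrame:
    """Select each guide's A in its partner reference compound.

    ``reference`` maps gene -> (compound, concentration); the returned
    frame is the subset of A estimates computed in that condition, merged
    with the guide annotations.
    """
    lib = library.merge(reference, on="gene", how="inner")
    keys = ["guide_id", "compound"]
    if "concentration" in reference.columns:
        keys.append("concentration")
    out = lib.merge(effects_a, on=keys, how="inner", suffixes=("", "_eff"))
    return out


def interaction_summary(
    effects_d: pd.DataFrame,
    library: pd.DataFrame,
    flag_threshold: float = 1.0,
) -> pd.DataFrame:
    """Gene x condition mean drug-specific effect and interaction flags.

    The mean D over a gene's unfiltered guides summarizes the
    chemical-genetic interaction (negative = drug sensitivity on
    repression, positive = resistance); cells with |mean| >
    ``flag_threshold`` are flagged.  Genes whose guides are all filtered in
    a condition are reported as missing (NaN mean), never as zero.
    """
    d = effects_d.merge(library[["guide_id", "gene"]], on="guide_id")
    genes = library["gene"].unique()
    conditions = d[["compound", "concentration"]].drop_duplicates()
    rows = []
    for _, cond in conditions.iterrows():
        sub = d[(d["compound"] == cond["compound"])
                & (d["concentration"].fillna(-1) == (cond["concentration"] if pd.notna(cond["concentration"]) else -1))]
        for gene in genes:
            vals = sub.loc[(sub["gene"] == gene) & ~sub["filtered"], "mean"]
            mean = float(vals.mean()) if len(vals) else np.nan
            rows.append(
                {
                    "gene": gene,
                    "compound": cond["compound"],
                    "concentration": cond["concentration"],
                    "mean_D": mean,
                    "n_guides": int(len(vals)),
                    "interaction": bool(abs(mean) > flag_threshold) if len(vals) else False,
                }
            )
    return pd.DataFrame(rows)
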