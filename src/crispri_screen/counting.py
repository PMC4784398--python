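"""Demultiplexing and perfect-match guide counting of amplicon reads.

A read is assigned to a sample by its dual barcodes and to a guide only
when the extracted spacer region matches a library spacer exactly; reads
with any spacer mismatch are rejected (and tallied), mirroring analysis
pipelines that keep only zero-edit-distance alignments.  Both 18- and
20-nt spacers are supported, the longer exact match taking priority.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import CountMatrix, validate_library
from .io import iter_fastq

SPACER_LENGTHS = (20, 18)


@dataclass(frozen=True)
class AmpliconLayout:
    """Structure of one sequencing read of the guide-expression amplicon.

    Read layout, 5' to 3': up-barcode, upstream constant (promoter-side
    scaffold), spacer (18 or 20 nt), downstream constant (gRNA scaffold),
    down-barcode.  Because the spacer length varies, the down-barcode is
    read from the end of the read.
    """

    upstream_const: str = "GCTCTAAAACTGGATCCAT"
    downstream_const: str = "GTTTTAGAGCTAGAAATAG"
    barcode_up_len: int = 6
    barcode_dn_len: int = 6

    @property
    def spacer_start(self) -> int:
        return self.barcode_up_len + len(self.upstream_const)

    def min_read_length(self) -> int:
        return self.spacer_start + 18 + len(self.downstream_const) + self.barcode_dn_len

    def assemble(self, bc_up: str, bc_dn: str, spacer: str) -> str:
        return bc_up + self.upstream_const + spacer + self.downstream_const + bc_dn

    def extract(self, read: str) -> tuple[str, str, str, str]:
        """(bc_up, bc_dn, candidate 20-mer, candidate 18-mer) from a read."""
        bc_up = read[: self.barcode_up_len]
        bc_dn = read[-self.barcode_dn_len :] if self.barcode_dn_len else ""
        s = self.spacer_start
        return bc_up, bc_dn, read[s : s + 20], read[s : s + 18]


DEFAULT_LAYOUT = AmpliconLayout()


def count_guides(
    fastq_paths,
    layout: AmpliconLayout,
    library: pd.DataFrame,
    samples: pd.DataFrame,
) -> CountMatrix:
    """Count perfect-match spacer reads per (guide, sample).

    Every read increments at most one cell; non-matching reads are tallied
    by rejection reason (``barcode_miss``, ``spacer_mismatch``,
    ``too_short``) on the returned matrix's ``rejections`` attribute, so
    that assigned + rejected equals total reads.
    """
    validate_library(library)
    s = samples.copy()
    if "sample" in s.columns:
        s = s.set_index("sample")
    by_barcode = {
        (row["barcode_up"], row["barcode_dn"]): (name, row["pool"])
        for name, row in s.iterrows()
    }
    if len(by_barcode) != len(s):
        raise ValueError("duplicate barcode pair in sample sheet")

    lut: dict[str, dict[str, str]] = {}
    for pool, sub in library.groupby("pool"):
        lut[pool] = {20: {}, 18: {}}
        for spacer, guide in zip(sub["spacer"], sub["guide_id"]):
            lut[pool][len(spacer)][spacer] = guide

    guides = library["guide_id"].to_numpy()
    guide_idx = {g: i for i, g in enumerate(guides)}
    sample_idx = {name: i for i, name in enumerate(s.index)}
    mat = np.zeros((len(guides), len(s)), dtype=np.int64)
    rejections: Counter = Counter()

    if isinstance(fastq_paths, (str, Path)):
        fastq_paths = [fastq_paths]
    min_len = layout.min_read_length()
    for path in fastq_paths:
        for _rid, seq, _qual in iter_fastq(path):
            if len(seq) < min_len:
                rejections["too_short"] += 1
                continue
            bc_up, bc_dn, cand20, cand18 = layout.extract(seq)
            hit = by_barcode.get((bc_up, bc_dn))
            if hit is None:
                rejections["barcode_miss"] += 1
                continue
            sample, pool = hit
            pool_lut = lut.get(pool)
            guide = pool_lut[20].get(cand20) if pool_lut else None
            if guide is None and pool_lut:
                guide = pool_lut[18].get(cand18)
            if guide is None:
                rejections["spacer_mismatch"] += 1
                continue
            mat[guide_idx[guide], sample_idx[sample]] += 1

    counts = pd.DataFrame(mat, index=pd.Index(guides, name="guide_id"), columns=s.index)
    pools = pd.Series(library["pool"].to_numpy(), index=guides)
    return CountMatrix(counts, samples, guide_pools=pools, rejections=dict(rejections))


def count_qc(matrix: CountMatrix, total_reads: int | None = None) -> dict:
    """Per-sample totals, detection rates and replicate concordance.

    Concordance is the Spearman correlation of log2(count + 0.5) between
    replicate samples of the same (pool, compound, concentration, ATc)
    condition; deep replicate libraries are expected to correlate above
    ~0.95.
    """
    from scipy.stats import spearmanr

    totals = matrix.counts.sum(axis=0)
    rejected = sum(matrix.rejections.values())
    assigned = int(totals.sum())
    if total_reads is None:
        total_reads = assigned + rejected
    detection = {}
    for pool in matrix.samples["pool"].unique():
        sub = matrix.counts.loc[matrix.guide_pools == pool,
                                matrix.samples.index[matrix.samples["pool"] == pool]]
        detection[pool] = float((sub.to_numpy() > 0).any(axis=1).mean()) if sub.size else 0.0
    pairs = []
    grouping = matrix.samples.groupby(["pool", "compound", "concentration", "atc"], dropna=False)
    for _, grp in grouping:
        names = list(grp.index)
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                a = np.log2(matrix.pool_counts(names[i]) + 0.5)
                b = np.log2(matrix.pool_counts(names[j]) + 0.5)
                if np.ptp(a) == 0 or np.ptp(b) == 0:
                    rho = 1.0 if a.equals(b) else np.nan
                else:
                    rho = float(spearmanr(a, b).statistic)
                pairs.append({"sample_a": names[i], "sample_b": names[j], "spearman": rho})
    return {
        "per_sample_totals": totals.to_dict(),
        "assigned": assigned,
        "rejected": dict(matrix.rejections),
        "fraction_assigned": assigned / total_reads if total_reads else 0.0,
        "detection_rate": detection,
        "replicate_concordance": pairs,
    }
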