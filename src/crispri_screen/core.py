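"""Core containers shared across the pipeline.

The screen quantifies guide RNA abundance by amplicon sequencing of pooled
competitive-growth cultures.  Counts live in a :class:`CountMatrix`
(guides x samples plus sample metadata); chromatin signal (nucleosome
occupancy, ATAC insertions, tiling-array log2 ratios) lives in a
:class:`ChromatinTrack`.  Guide libraries are plain pandas DataFrames with
the column schema in :data:`LIBRARY_COLUMNS`; helper validators keep the
modules honest about what they require.

Coordinate convention: 0-based, half-open everywhere in memory.  File
formats that are 1-based (wig, GFF) are converted at the I/O boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Columns of a guide library table.  `start`/`end` delimit the protospacer
#: (0-based half-open, genomic/plus-strand coordinates); `target_strand` is
#: the genomic strand carrying protospacer+PAM; `strand_class` says which
#: strand of the *gene* the gRNA base-pairs with (template / non_template);
#: `tss_offset` is the protospacer midpoint relative to the gene TSS,
#: negative upstream of the TSS.
LIBRARY_COLUMNS = [
    "guide_id",
    "spacer",
    "pam",
    "gene",
    "pool",
    "chrom",
    "start",
    "end",
    "target_strand",
    "strand_class",
    "tss_offset",
    "length",
    "tags",
    "mismatch",
]

#: Required columns of a sample sheet.  One row per sequencing sample;
#: (pool, atc, compound, concentration, replicate) identifies the culture.
SAMPLE_COLUMNS = ["sample", "pool", "atc", "compound", "concentration", "replicate"]

TRACK_KINDS = ("nucleosome_base", "atac_insertion", "array_log2")


class LibraryError(ValueError):
    """Malformed or internally inconsistent guide library."""


def validate_library(library: pd.DataFrame) -> pd.DataFrame:
    """Check a guide library table and report 18/20-mer ambiguities.

    Raises on duplicate spacers within a pool (they could not be told apart
    by sequencing) and on spacer lengths other than 18 or 20.  A 20-mer
    whose first 18 bases equal another guide's 18-mer spacer in the same
    pool is ambiguous under longest-match-first counting; such collisions
    are reported with a warning at load time.
    """
    if library.empty:
        raise LibraryError("empty guide library")
    missing = [c for c in ("guide_id", "spacer", "gene", "pool") if c not in library]
    if missing:
        raise LibraryError(f"library missing columns: {missing}")
    lengths = library["spacer"].str.len()
    bad = library.loc[~lengths.isin([18, 20]), "guide_id"]
    if len(bad):
        raise LibraryError(f"spacer length not in {{18, 20}}: {list(bad[:5])}")
    for pool, sub in library.groupby("pool"):
        dup = sub["spacer"][sub["spacer"].duplicated()]
        if len(dup):
            raise LibraryError(f"duplicate spacer(s) in pool {pool!r}: {sorted(set(dup))[:5]}")
        s18 = set(sub.loc[sub["spacer"].str.len() == 18, "spacer"])
        clash = sub.loc[
            (sub["spacer"].str.len() == 20) & sub["spacer"].str[:18].isin(s18), "guide_id"
        ]
        if len(clash):
            warnings.warn(
                f"pool {pool!r}: 20-nt spacer(s) whose 18-nt prefix collides with an "
                f"18-nt guide (longest match wins): {list(clash[:5])}",
                stacklevel=2,
            )
    return library


@dataclass
class ChromatinTrack:
    """A contiguous genomic signal track.

    Parameters
    ----------
    chrom : str
    start : int
        0-based genomic start of the first value.
    values : ndarray
        One value per ``step`` bases.
    kind : str
        ``nucleosome_base`` (per-base occupancy), ``atac_insertion``
        (per-base transposase insertion counts) or ``array_log2``
        (tiling-array log2 ratios, typically ``step=4``).
    step : int
        Base pairs per value (1 for per-base tracks).
    """

    chrom: str
    start: int
    values: np.ndarray
    kind: str
    step: int = 1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in TRACK_KINDS:
            raise ValueError(f"unknown track kind {self.kind!r}; expected one of {TRACK_KINDS}")
        if self.values.size == 0:
            raise ValueError("empty track")
        if self.step < 1:
            raise ValueError("step must be >= 1")

    @property
    def end(self) -> int:
        """0-based half-open genomic end of the covered interval."""
        return self.start + self.step * len(self.values)

    def covers(self, start: int, end: int) -> bool:
        return start >= self.start and end <= self.end

    def slice(self, start: int, end: int) -> np.ndarray:
        """Per-base values over [start, end) (only for step-1 tracks)."""
        if self.step != 1:
            raise ValueError("slice() requires a per-base (step=1) track")
        if not self.covers(start, end):
            raise ValueError(
                f"[{start}, {end}) outside track extent [{self.start}, {self.end})"
            )
        return self.values[start - self.start : end - self.start]

    def probe_values(self, start: int, end: int) -> np.ndarray:
        """Values of probes whose position falls in [start, end).

        Probes sit every ``step`` bases starting at ``start``; a 26-bp
        window on a 4-bp tiling therefore contains 6 or 7 probes.
        """
        if not self.covers(start, end):
            raise ValueError(
                f"[{start}, {end}) outside track extent [{self.start}, {self.end})"
            )
        first = -(-(start - self.start) // self.step)  # ceil division
        last = (end - 1 - self.start) // self.step
        return self.values[first : last + 1]


class CountMatrix:
    """Integer guide x sample count matrix with sample metadata.

    ``counts`` is indexed by guide id with one column per sample;
    ``samples`` is indexed by sample id and carries
    (pool, atc, compound, concentration, replicate).  ``guide_pools`` maps
    each guide to the pool it belongs to; guides are only expected to be
    observed in samples of their own pool.
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        samples: pd.DataFrame,
        guide_pools: pd.Series | None = None,
        rejections: dict[str, int] | None = None,
    ):
        samples = samples.copy()
        if "sample" in samples.columns:
            samples = samples.set_index("sample")
        missing = [c for c in SAMPLE_COLUMNS[1:] if c not in samples.columns]
        if missing:
            raise ValueError(f"sample sheet missing columns: {missing}")
        if set(counts.columns) != set(samples.index):
            raise ValueError("counts columns and sample sheet do not match")
        key = samples.reset_index()[["sample", "pool", "atc", "compound", "concentration", "replicate"]]
        if key.duplicated(subset=["pool", "atc", "compound", "concentration", "replicate"]).any():
            raise ValueError("sample sheet maps two samples to the same (pool, condition, replicate)")
        arr = counts.to_numpy()
        if (arr < 0).any():
            raise ValueError("negative counts")
        self.counts = counts.astype(np.int64)
        self.counts.index.name = "guide_id"
        self.samples = samples
        if guide_pools is None:
            pools = samples["pool"].unique()
            if len(pools) > 1:
                raise ValueError("guide_pools required when samples span multiple pools")
            guide_pools = pd.Series(pools[0], index=counts.index)
        self.guide_pools = guide_pools.reindex(counts.index)
        if self.guide_pools.isna().any():
            raise ValueError("guide_pools missing entries for some guides")
        self.rejections = dict(rejections or {})

    @property
    def guides(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def pool_counts(self, sample: str) -> pd.Series:
        """Counts of the guides belonging to the sample's pool."""
        pool = self.samples.loc[sample, "pool"]
        return self.counts.loc[self.guide_pools == pool, sample]

    def total_assigned(self) -> int:
        return int(self.counts.to_numpy().sum())

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"CountMatrix({len(self.guides)} guides x {len(self.sample_ids)} samples)"


@dataclass
class TssModel:
    """Transcription start site for one gene.

    ``source`` records whether the TSS came from transcript-isoform
    profiling (modal observed start) or the ATG-27 fallback used when no
    isoform data exist.
    """

    gene: str
    tss: int
    source: str = "isoform-profiling"  # or "ATG-27"


def revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTNacgtn", "TGCANtgcan"))[::-1]
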