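"""Synthetic pooled CRISPRi screen generator.

Emulates the full data-generating process the analysis assumes, so every
downstream stage is testable without external data:

* a synthetic yeast-like locus: genes on alternating strands, each with a
  nucleosome-depleted promoter region and phased downstream nucleosomes
  (cosine occupancy, ~165 bp period), plus an anti-correlated ATAC
  insertion track;
* a guide library (via :mod:`.design`) with per-guide repression potency
  from a logistic model in (TSS-relative position, footprint occupancy),
  calibrated so roughly 40 % of promoter-window guides are effective;
* pooled competitive growth: deterministic exponential abundance change
  over T pool doublings (default 20), ``2**(T * s * potency)`` fold when
  the guide is induced, where s is the gene x compound selection
  coefficient per doubling (negative = drug sensitivity on repression);
  stochasticity enters only through lognormal initial abundances and
  multinomial sequencing;
* amplicon reads with per-sample dual barcodes, optionally carrying 1-nt
  spacer errors to exercise perfect-match filtering.

A single seed fans out to per-stage child seeds, so any stage is
reproducible in isolation and identical seeds give bit-identical outputs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from . import design
from .core import ChromatinTrack, CountMatrix
from .counting import AmpliconLayout, DEFAULT_LAYOUT
from .efficacy import footprint_score

NUCLEOSOME_PERIOD = 165
NDR_INTERVAL = (-250, -10)  # TSS-relative, gene-oriented


@dataclass
class PotencyModel:
    """Logistic repression potency in (TSS-relative position, occupancy).

    ``potency = expit(steepness * (pw * pos + aw * (1 - occupancy) - offset)
    + eps)`` with ``pos`` a Gaussian bump centered ``position_center`` bp
    from the TSS and ``eps ~ Normal(0, logit_noise_sd)`` a guide-intrinsic
    term standing in for determinants the model does not track (sequence
    context, secondary structure).  Defaults are calibrated so that with
    the default locus model roughly 40 % of guides in a +/-500 bp TSS
    window are effective (potency above one half) while about three
    quarters of guides that are both within 200 bp upstream of the TSS and
    in depleted chromatin are.
    """

    position_center: float = -100.0
    position_scale: float = 150.0
    position_weight: float = 0.5
    accessibility_weight: float = 0.5
    offset: float = 0.62
    steepness: float = 4.0
    logit_noise_sd: float = 1.6

    def potency(self, tss_offset, occupancy, rng: np.random.Generator | None = None):
        pos = np.exp(-0.5 * ((np.asarray(tss_offset, dtype=float) - self.position_center)
                             / self.position_scale) ** 2)
        score = (self.position_weight * pos
                 + self.accessibility_weight * (1.0 - np.asarray(occupancy, dtype=float))
                 - self.offset)
        logit = self.steepness * score
        if rng is not None and self.logit_noise_sd > 0:
            logit = logit + rng.normal(0.0, self.logit_noise_sd, size=np.shape(score))
        return expit(logit)


def default_interactions(genes, s: float = -0.2) -> pd.DataFrame:
    """Diagonal reference-set interaction matrix: gene i x its partner
    compound, selection coefficient ``s`` per doubling (T*s = -4 at the
    default 20 doublings)."""
    mat = pd.DataFrame(0.0, index=list(genes), columns=[f"drug_{g}" for g in genes])
    for g in genes:
        mat.loc[g, f"drug_{g}"] = s
    return mat


@dataclass
class SimConfig:
    """Study conditions for the synthetic screen."""

    seed: int = 0
    n_genes: int = 8
    n_guides_per_gene: int = 10
    doublings: float = 20.0
    depth: int = 1_000_000
    interaction_matrix: pd.DataFrame | None = None
    potency_model: PotencyModel = field(default_factory=PotencyModel)
    replicates: int = 2
    abundance_dispersion: float = 0.5
    gene_spacing: int = 2000
    ndr_depth: float = 0.05
    track_noise: float = 0.05
    atac_scale: float = 10.0
    control_compound: str = "DMSO"
    chrom: str = "chrSim"

    def __post_init__(self):
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if self.depth < 0:
            raise ValueError("depth must be non-negative")
        if self.abundance_dispersion <= 0:
            raise ValueError("abundance_dispersion must be positive")
        if self.gene_spacing < 2000:
            raise ValueError("need >= 2 kb of genome per gene")
        if self.interaction_matrix is None:
            self.genes = [f"gene{i + 1:02d}" for i in range(self.n_genes)]
            self.interaction_matrix = default_interactions(self.genes)
        else:
            self.genes = list(self.interaction_matrix.index)

    def child_seeds(self) -> dict[str, np.random.SeedSequence]:
        names = ("locus", "potency", "counts", "reads", "mutants")
        return dict(zip(names, np.random.SeedSequence(self.seed).spawn(5)))


@dataclass
class SimTruth:
    """Ground truth backing one simulated count table."""

    potency: pd.Series                 # per guide, in [0, 1]
    abundance0: pd.Series              # per guide initial pool abundance
    f_true: pd.DataFrame               # guide x sample log2 growth effect T*s*potency
    interactions: pd.DataFrame         # gene x compound s per doubling

    def expected_fitness(self, sample: str) -> pd.Series:
        """Expected median-centered log2 abundance l for one sample."""
        x = np.log2(self.abundance0) + self.f_true[sample]
        return x - np.median(x)

    def expected_atc_effect(self, sample_plus: str, sample_minus: str) -> pd.Series:
        """Expected A between an induced and an uninduced sample."""
        return self.expected_fitness(sample_plus) - self.expected_fitness(sample_minus)


# ---------------------------------------------------------------------------
# locus


def simulate_locus(config: SimConfig):
    """Generate (genome, annotations, (nucleosome track, ATAC track)).

    Each gene block carries a nucleosome-depleted region (occupancy
    ``ndr_depth``) upstream of the TSS and cosine-phased nucleosomes with
    ~165 bp period elsewhere; the ATAC track is ``atac_scale * (1 -
    occupancy)`` plus noise.  PAM sites (NGG / CCN) are guaranteed on both
    strands in every 50-bp window of the gene blocks.
    """
    seeds = config.child_seeds()
    rng = np.random.default_rng(seeds["locus"])
    margin = 600
    length = config.n_genes * config.gene_spacing + 2 * margin
    seq = rng.choice(list("ACGT"), size=length, p=[0.31, 0.19, 0.19, 0.31])
    rows = []
    occ = np.full(length, 0.5)
    for i, gene in enumerate(config.genes):
        block_start = margin + i * config.gene_spacing
        strand = "+" if i % 2 == 0 else "-"
        tss = block_start + config.gene_spacing // 2
        orf_atg = tss + 27 if strand == "+" else tss - 27
        half = config.gene_spacing // 2
        # gene-oriented offsets d covering the block
        pos = np.arange(block_start, block_start + config.gene_spacing)
        d = (pos - tss) if strand == "+" else (tss - pos)
        prof = 0.5 + 0.5 * np.cos(2 * np.pi * (d - 80) / NUCLEOSOME_PERIOD)
        ndr = (d >= NDR_INTERVAL[0]) & (d < NDR_INTERVAL[1])
        prof[ndr] = config.ndr_depth
        far = d < NDR_INTERVAL[0]
        prof[far] = 0.5 + 0.45 * np.cos(2 * np.pi * (d[far] - NDR_INTERVAL[0]) / NUCLEOSOME_PERIOD)
        occ[pos] = prof
        if strand == "+":
            start, end = orf_atg, min(orf_atg + 900, block_start + config.gene_spacing)
        else:
            start, end = max(orf_atg - 899, block_start), orf_atg + 1
        rows.append({"gene": gene, "chrom": config.chrom, "strand": strand,
                     "start": start, "end": end, "orf_start": orf_atg, "tss": tss})
        _ensure_pams(seq, block_start, block_start + config.gene_spacing, rng)
    occ_clean = occ.copy()
    if config.track_noise > 0:
        occ = np.clip(occ + rng.normal(0, config.track_noise, size=length), 0, 1)
    atac = config.atac_scale * (1.0 - occ_clean)
    if config.track_noise > 0:
        atac = np.clip(
            atac + rng.normal(0, config.atac_scale * config.track_noise, size=length), 0, None
        )
    genome = {config.chrom: "".join(seq)}
    annotations = pd.DataFrame(rows)
    nuc = ChromatinTrack(config.chrom, 0, occ, "nucleosome_base")
    at = ChromatinTrack(config.chrom, 0, atac, "atac_insertion")
    return genome, annotations, (nuc, at)


def _ensure_pams(seq: np.ndarray, start: int, end: int, rng) -> None:
    """Plant GG / CC dinucleotides where a 50-bp window lacks them."""
    window = 50
    for w in range(start, end - window, window):
        block = "".join(seq[w : w + window])
        if "GG" not in block:
            seq[w + 10 : w + 12] = list("GG")
        if "CC" not in block:
            seq[w + 30 : w + 32] = list("CC")


# ---------------------------------------------------------------------------
# library + truth


def simulate_library(config: SimConfig, genome, annotations, nucleosome: ChromatinTrack,
                     window: tuple[int, int] = (-150, 50), lengths=(20,),
                     pool: str = "pool1") -> pd.DataFrame:
    """Tile every gene with guides and annotate footprint occupancy.

    Guides are subsampled evenly along the window to ``n_guides_per_gene``
    per gene (deterministically) when the window yields more.
    """
    libs = []
    for _, ann in annotations.iterrows():
        lib = design.enumerate_guides(genome, ann, int(ann["tss"]), window=window,
                                      lengths=lengths, pool=pool)
        if len(lib) > config.n_guides_per_gene:
            idx = np.linspace(0, len(lib) - 1, config.n_guides_per_gene).round().astype(int)
            lib = lib.iloc[np.unique(idx)]
        libs.append(lib)
    library = pd.concat(libs, ignore_index=True)
    library["occupancy"] = [footprint_score(g, nucleosome) for _, g in library.iterrows()]
    return library


def guide_potency(config: SimConfig, library: pd.DataFrame) -> pd.Series:
    """True repression potency per guide from the potency model.

    The guide-intrinsic logit noise is drawn from the ``potency`` child
    seed, so the same config yields the same potencies.
    """
    occ = library["occupancy"] if "occupancy" in library else pd.Series(0.5, index=library.index)
    rng = np.random.default_rng(config.child_seeds()["potency"])
    p = config.potency_model.potency(library["tss_offset"].to_numpy(), occ.to_numpy(), rng=rng)
    return pd.Series(p, index=library["guide_id"].to_numpy(), name="potency")


def make_sample_sheet(config: SimConfig, pool: str = "pool1") -> pd.DataFrame:
    """Samples: (control + every compound) x (+/- ATc) x replicates."""
    compounds = [config.control_compound] + [
        c for c in config.interaction_matrix.columns if c != config.control_compound
    ]
    bc = _barcodes(2 * len(compounds) * 2 * config.replicates)
    rows = []
    i = 0
    for compound, atc, rep in itertools.product(compounds, (False, True),
                                                range(1, config.replicates + 1)):
        rows.append(
            {
                "sample": f"{compound}_{'atc' if atc else 'noatc'}_r{rep}",
                "pool": pool,
                "atc": atc,
                "compound": compound,
                "concentration": 1.0,
                "replicate": rep,
                "barcode_up": bc[2 * i],
                "barcode_dn": bc[2 * i + 1],
            }
        )
        i += 1
    return pd.DataFrame(rows)


def _barcodes(n: int, k: int = 6) -> list[str]:
    # deterministic spread over the 4^k space so barcodes differ broadly
    space = 4 ** k
    step = max(1, space // (n + 1))
    out = []
    for i in range(n):
        x = (i + 1) * step % space
        out.append("".join("ACGT"[(x >> (2 * j)) & 3] for j in range(k)))
    assert len(set(out)) == n, "barcode collision in deterministic scheme"
    return out


def simulate_counts(
    config: SimConfig,
    library: pd.DataFrame,
    samples: pd.DataFrame | None = None,
    potency: pd.Series | None = None,
) -> tuple[CountMatrix, SimTruth]:
    """Simulate pooled growth and sequencing of the guide library.

    Initial abundances are lognormal with sigma ``abundance_dispersion``
    (one pool shared by all samples); induced samples multiply each
    guide's abundance by ``2**(T * s * potency)``; reads are multinomial
    at ``depth`` per sample.
    """
    missing = set(library["gene"]) - set(config.interaction_matrix.index)
    if missing:
        raise ValueError(f"guides target genes absent from the interaction matrix: {sorted(missing)}")
    if samples is None:
        samples = make_sample_sheet(config, pool=str(library["pool"].iloc[0]))
    if potency is None:
        potency = guide_potency(config, library)
    p = potency.to_numpy(dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("potency outside [0, 1]")
    seeds = config.child_seeds()
    rng = np.random.default_rng(seeds["counts"])
    guides = library["guide_id"].to_numpy()
    genes = library["gene"].to_numpy()
    a0 = rng.lognormal(mean=0.0, sigma=config.abundance_dispersion, size=len(guides))
    s_by_gene = config.interaction_matrix
    f_true = {}
    counts = {}
    for _, smp in samples.iterrows():
        compound = smp["compound"]
        if smp["atc"] and compound in s_by_gene.columns:
            s = s_by_gene[compound].reindex(genes).to_numpy()
        else:
            s = np.zeros(len(guides))
        f = config.doublings * s * p
        f_true[smp["sample"]] = f
        w = a0 * np.power(2.0, f)
        counts[smp["sample"]] = rng.multinomial(config.depth, w / w.sum())
    counts_df = pd.DataFrame(counts, index=guides)
    matrix = CountMatrix(counts_df, samples, guide_pools=pd.Series(
        library["pool"].to_numpy(), index=guides))
    truth = SimTruth(
        potency=pd.Series(p, index=guides),
        abundance0=pd.Series(a0, index=guides),
        f_true=pd.DataFrame(f_true, index=guides),
        interactions=config.interaction_matrix.copy(),
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# reads


def simulate_reads(
    counts: CountMatrix,
    library: pd.DataFrame,
    layout: AmpliconLayout = DEFAULT_LAYOUT,
    error_fraction: float = 0.0,
    seed=None,
):
    """Yield (read id, sequence, quality) amplicon reads for a count table.

    Each (guide, sample) cell emits exactly its count of reads: constant
    scaffold + the sample's dual barcodes + the guide spacer.  A
    ``error_fraction`` of reads carries one random spacer substitution,
    which perfect-match counting must reject.
    """
    if not 0 <= error_fraction <= 1:
        raise ValueError("error_fraction must be in [0, 1]")
    bcs = counts.samples[["barcode_up", "barcode_dn"]]
    if bcs.duplicated().any():
        raise ValueError("barcode collision between samples")
    spacers = library.set_index("guide_id")["spacer"]
    rng = np.random.default_rng(seed)
    rid = 0
    for sample in counts.sample_ids:
        up, dn = bcs.loc[sample, "barcode_up"], bcs.loc[sample, "barcode_dn"]
        col = counts.counts[sample]
        for guide_id, n in col[col > 0].items():
            spacer = spacers[guide_id]
            n_err = rng.binomial(n, error_fraction) if error_fraction > 0 else 0
            for j in range(n):
                sp = spacer
                if j < n_err:
                    k = rng.integers(len(sp))
                    alt = "ACGT"[(("ACGT".index(sp[k])) + rng.integers(1, 4)) % 4]
                    sp = sp[:k] + alt + sp[k + 1 :]
                seq = layout.assemble(up, dn, sp)
                rid += 1
                yield f"read{rid}", seq, "I" * len(seq)
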