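"""CRISPRi guide enumeration, mismatch series, and chromatin-aware ranking.

Effective CRISPRi in budding yeast needs the dCas9-repressor to sit in the
nucleosome-depleted promoter region just upstream of the TSS: guides whose
protospacer midpoint falls within 200 bp upstream of the TSS and in locally
depleted chromatin repress far more often than guides outside that window
or under a positioned nucleosome.  ``rank_guides`` encodes that rule as a
four-tier ranking; ``enumerate_guides`` produces every NGG-adjacent guide
(both strands, 18- and/or 20-nt spacers) in a TSS-relative window; and
``mutant_series`` builds the single-mismatch derivative set used to probe
seed-region specificity.
"""

from __future__ import annotations

from collections.abc import Mapping

import numpy as np
import pandas as pd

from .core import ChromatinTrack, TssModel, revcomp
from .efficacy import footprint_score, footprint_window

#: Spacer positions (1 = PAM-proximal) mutated in the mismatch series:
#: the whole seed region plus four PAM-distal probes.
MUTANT_POSITIONS = tuple(range(1, 11)) + (11, 12, 14, 16)

TSS_FALLBACK_OFFSET = 27


def infer_tss(annotation: Mapping, isoform_starts=None) -> TssModel:
    """Infer a gene's TSS from isoform data, else fall back to ATG-27.

    ``annotation`` needs keys ``gene``, ``strand`` and ``orf_start`` (the
    strand-aware genomic coordinate of the ATG).  With isoform data the TSS
    is the modal observed start; without, it is placed a fixed 27 bp
    upstream of the start codon on the coding strand.
    """
    strand = annotation["strand"]
    if strand not in "+-":
        raise ValueError(f"gene {annotation.get('gene')!r} missing strand")
    if isoform_starts is not None and len(isoform_starts) > 0:
        vals, counts = np.unique(np.asarray(isoform_starts), return_counts=True)
        # ties broken toward the most upstream start
        best = vals[counts == counts.max()]
        tss = int(best.min() if strand == "+" else best.max())
        return TssModel(annotation["gene"], tss, "isoform-profiling")
    orf_start = int(annotation["orf_start"])
    tss = orf_start - TSS_FALLBACK_OFFSET if strand == "+" else orf_start + TSS_FALLBACK_OFFSET
    return TssModel(annotation["gene"], tss, "ATG-27")


def _tss_offset(mid: float, tss: int, strand: str) -> float:
    return mid - tss if strand == "+" else tss - mid


def enumerate_guides(
    genome: Mapping[str, str] | str,
    annotation: Mapping,
    tss: TssModel | int,
    window: tuple[int, int] = (-150, 50),
    lengths: tuple[int, ...] = (20,),
    pool: str = "pool1",
    tags: str = "tiling",
) -> pd.DataFrame:
    """Enumerate all PAM-adjacent guides for one gene in a TSS window.

    Every NGG on either genomic strand whose protospacer midpoint lies
    within ``window`` (gene-oriented, relative to the TSS, negative =
    upstream) yields one guide per requested spacer length.  Guide ids are
    deterministic and unique:
    ``{gene}_{protospacer start}{target_strand}_{length}``.
    """
    if isinstance(genome, str):
        seq = genome
        chrom = annotation.get("chrom", "chr1") if hasattr(annotation, "get") else "chr1"
    else:
        chrom = annotation["chrom"]
        seq = genome[chrom]
    tss_pos = tss.tss if isinstance(tss, TssModel) else int(tss)
    gene = annotation["gene"]
    strand = annotation["strand"]
    lo, hi = window
    if strand == "+":
        g_lo, g_hi = tss_pos + lo, tss_pos + hi
    else:
        g_lo, g_hi = tss_pos - hi, tss_pos - lo
    if g_lo < 0 or g_hi > len(seq):
        raise ValueError(f"window [{g_lo}, {g_hi}) outside contig of length {len(seq)}")

    rows = []
    for L in sorted(lengths, reverse=True):
        # plus-strand protospacers: PAM = N G G at [p, p+3)
        for p in _find_all(seq, "GG"):
            pam_start = p - 1
            s, e = pam_start - L, pam_start
            if s < 0:
                continue
            _maybe_add(rows, seq, chrom, gene, strand, tss_pos, g_lo, g_hi, s, e, "+", L, pool, tags)
        # minus-strand protospacers appear as C C N at [q-?]: plus-strand "CC"
        for q in _find_all(seq, "CC"):
            s, e = q + 3, q + 3 + L
            if e > len(seq):
                continue
            _maybe_add(rows, seq, chrom, gene, strand, tss_pos, g_lo, g_hi, s, e, "-", L, pool, tags)
    lib = pd.DataFrame(
        rows,
        columns=[
            "guide_id", "spacer", "pam", "gene", "pool", "chrom", "start", "end",
            "target_strand", "strand_class", "tss_offset", "length", "tags", "mismatch",
        ],
    )
    return lib.sort_values(["tss_offset", "target_strand", "length"]).reset_index(drop=True)


def _find_all(seq: str, motif: str):
    i = seq.find(motif)
    while i != -1:
        yield i
        i = seq.find(motif, i + 1)


def _maybe_add(rows, seq, chrom, gene, g_strand, tss_pos, g_lo, g_hi, s, e, t_strand, L, pool, tags):
    mid = (s + e - 1) / 2.0
    if not (g_lo <= mid < g_hi):
        return
    if t_strand == "+":
        spacer = seq[s:e]
        pam = seq[e : e + 3]
    else:
        spacer = revcomp(seq[s:e])
        pam = revcomp(seq[s - 3 : s])
    if len(pam) < 3:
        return
    off = _tss_offset(mid, tss_pos, g_strand)
    # the gRNA base-pairs with the strand opposite the protospacer: a
    # protospacer on the gene's coding strand means the guide anneals to
    # the template strand.
    strand_class = "template" if t_strand == g_strand else "non_template"
    rows.append(
        {
            "guide_id": f"{gene}_{s}{t_strand}_{L}",
            "spacer": spacer,
            "pam": pam,
            "gene": gene,
            "pool": pool,
            "chrom": chrom,
            "start": s,
            "end": e,
            "target_strand": t_strand,
            "strand_class": strand_class,
            "tss_offset": off,
            "length": L,
            "tags": tags,
            "mismatch": "",
        }
    )


def mutant_series(guide: Mapping, seed=None) -> pd.DataFrame:
    """Single-mismatch derivatives of a functional 20-nt guide.

    One derivative per position in :data:`MUTANT_POSITIONS` (PAM-proximal
    numbering), with the substituted base drawn uniformly from the three
    alternatives, each emitted in 20-nt and 18-nt (two PAM-distal bases
    trimmed) versions: 14 positions x 2 lengths = 28 records.
    """
    spacer = guide["spacer"]
    if len(spacer) != 20:
        raise ValueError("mutant series is defined for 20-nt parent guides")
    rng = np.random.default_rng(seed)
    rows = []
    for pos in MUTANT_POSITIONS:
        idx = 20 - pos  # 0-based from the 5' (PAM-distal) end
        if not 0 <= idx < 20:
            raise ValueError(f"mismatch position {pos} outside spacer")
        alt = rng.choice([b for b in "ACGT" if b != spacer[idx]])
        mut20 = spacer[:idx] + alt + spacer[idx + 1 :]
        for L, sp in ((20, mut20), (18, mut20[2:])):
            rows.append(
                {
                    **{k: guide[k] for k in ("gene", "pool", "chrom", "start", "end",
                                             "target_strand", "strand_class", "tss_offset")},
                    "guide_id": f"{guide['guide_id']}_m{pos}{alt}_{L}",
                    "spacer": sp,
                    "pam": guide.get("pam", ""),
                    "length": L,
                    "tags": f"mutant{L}",
                    "mismatch": f"{pos}:{alt}",
                }
            )
    return pd.DataFrame(rows)


def rank_guides(
    library: pd.DataFrame,
    tss_by_gene: Mapping[str, int],
    nucleosome: ChromatinTrack,
    window: tuple[int, int] = (-200, 0),
    depleted_quantile: float = 0.5,
    local_halfwidth: int = 500,
) -> pd.DataFrame:
    """Rank guides by the promoter-window / nucleosome-depletion rule.

    Each guide is labeled ``in_window`` (protospacer midpoint within
    ``window`` of the TSS, default the 200 bp immediately upstream) and
    ``depleted`` (footprint occupancy below the ``depleted_quantile`` of
    occupancy over TSS +/- ``local_halfwidth``).  Tiers: 1 = both, 2 =
    in-window only, 3 = depleted only, 4 = neither; guides whose footprint
    the track does not cover are labeled unknown and ranked last (tier 5).
    Ties are broken by lower occupancy, then by distance to the TSS.
    """
    out = library.copy()
    in_window, depleted, occ = [], [], []
    for _, g in out.iterrows():
        off = g["tss_offset"]
        in_window.append(window[0] <= off <= window[1])
        tss = tss_by_gene[g["gene"]]
        lo = max(nucleosome.start, tss - local_halfwidth)
        hi = min(nucleosome.end, tss + local_halfwidth)
        s, e = footprint_window(g)
        if not nucleosome.covers(s, e) or hi <= lo:
            depleted.append(None)
            occ.append(np.nan)
            continue
        fp = footprint_score(g, nucleosome)
        thresh = np.nanquantile(nucleosome.slice(lo, hi), depleted_quantile)
        # tolerance so float averaging noise cannot cross the boundary
        depleted.append(bool(thresh - fp > 1e-9))
        occ.append(fp)
    out["in_window"] = in_window
    out["depleted"] = depleted
    out["footprint_occupancy"] = occ

    def tier(row):
        if row["depleted"] is None:
            return 5
        if row["in_window"] and row["depleted"]:
            return 1
        if row["in_window"]:
            return 2
        if row["depleted"]:
            return 3
        return 4

    out["tier"] = out.apply(tier, axis=1)
    out["depleted"] = out["depleted"].map(lambda v: v if v is None else bool(v))
    out = out.sort_values(
        by=["tier", "footprint_occupancy", "tss_offset"],
        key=lambda s: s.abs() if s.name == "tss_offset" else s,
        na_position="last",
    )
    return out.reset_index(drop=True)


def spacer_is_unique(genome: Mapping[str, str], spacer: str, pam_required: bool = True) -> bool:
    """Exact-match genome uniqueness check for spacer(+NGG) occurrences."""
    hits = 0
    for seq in genome.values():
        for target in (spacer, revcomp(spacer)):
            i = seq.find(target)
            while i != -1:
                if not pam_required:
                    hits += 1
                elif target == spacer:
                    if seq[i + len(spacer) + 1 : i + len(spacer) + 3] == "GG":
                        hits += 1
                else:
                    if seq[max(i - 3, 0) : i - 1] == "CC":
                        hits += 1
                i = seq.find(target, i + 1)
    return hits <= 1
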