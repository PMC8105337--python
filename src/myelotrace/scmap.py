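"""Per-cell somatic SNV mapping from barcode-tagged alignments.

Traces cell barcodes and UMIs through a tagged alignment file to count,
for each somatic SNV and each cell, the reads (and deduplicated UMIs)
supporting the reference and alternate alleles.  A cell's status at a
variant is "alt-detected" if at least one alt UMI is seen, "ref-only"
if only reference UMIs are seen, and "no-coverage" otherwise.  Group
summaries report a cell-level single-cell VAF (fraction of covered
cells with the variant detected); co-occurrence tables count cells in
which two variants are jointly covered and jointly detected.

Only SNVs are handled: indel support requires realignment logic outside
the scope of a deterministic counting tool.  Coordinates are 1-based in
VCF/SAM inputs and 0-based half-open internally.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pysam

from .syndata import DEFAULT_CELL_TAG, DEFAULT_UMI_TAG, Variant

__all__ = [
    "ExtractionLog",
    "load_snvs",
    "extract_observations",
    "collapse_umis",
    "group_summary",
    "cooccurrence",
]

_OBS_COLUMNS = ["variant_id", "cell_barcode", "umi", "allele", "read_id"]
_CALL_COLUMNS = ["variant_id", "cell_barcode", "ref_umis", "alt_umis",
                 "other_umis", "status"]


@dataclass
class ExtractionLog:
    """Counts of reads skipped during observation extraction."""

    n_reads: int = 0
    n_emitted: int = 0
    n_unmapped: int = 0
    n_secondary: int = 0
    n_duplicate: int = 0
    n_low_mapq: int = 0
    n_missing_tags: int = 0
    n_not_whitelisted: int = 0


def load_snvs(vcf_path: str) -> list[Variant]:
    """Read somatic SNVs from a VCF; non-SNV records are rejected."""
    variants = []
    with pysam.VariantFile(vcf_path) as vcf:
        for rec in vcf:
            for alt in rec.alts or ():
                if len(rec.ref) != 1 or len(alt) != 1 or \
                        rec.ref.upper() not in "ACGT" or alt.upper() not in "ACGT":
                    raise ValueError(
                        f"non-SNV variant at {rec.chrom}:{rec.pos} "
                        f"({rec.ref}>{alt}); only SNVs are supported"
                    )
                vid = rec.id or f"{rec.chrom}:{rec.pos}:{rec.ref}>{alt}"
                variants.append(
                    Variant(vid, rec.chrom, rec.pos, rec.ref.upper(),
                            alt.upper())
                )
    return variants


def extract_observations(
    alignments,
    variants: list[Variant],
    min_mapq: int = 10,
    barcode_whitelist: set[str] | None = None,
    cell_tag: str = DEFAULT_CELL_TAG,
    umi_tag: str = DEFAULT_UMI_TAG,
) -> tuple[pd.DataFrame, ExtractionLog]:
    """Emit one allele observation per read x covered variant.

    ``alignments`` is a :class:`pysam.AlignmentFile` (or any iterable of
    :class:`pysam.AlignedSegment`).  A read contributes an observation
    at a variant when its alignment places an aligned (non-gap,
    non-clipped) base at the variant position and its mapping quality is
    at least ``min_mapq``; the observed allele is "ref", "alt", or
    "other" by comparison with the variant alleles.  Unmapped,
    secondary/supplementary, duplicate-flagged, low-MAPQ and untagged
    reads are skipped and tallied in the returned log; a whitelist, if
    given, restricts cell barcodes.
    """
    for v in variants:
        if len(v.ref) != 1 or len(v.alt) != 1:
            raise ValueError(f"variant {v.id} is not an SNV")
    if isinstance(alignments, pysam.AlignmentFile):
        refs = set(alignments.references)
        missing = {v.chrom for v in variants} - refs
        if missing:
            raise ValueError(
                f"variant chromosome(s) {sorted(missing)} absent from "
                "alignment header"
            )
        records = alignments.fetch(until_eof=True)
    else:
        records = iter(alignments)

    # variant lookup keyed by (chrom, 0-based position)
    by_locus: dict[tuple[str, int], list[Variant]] = {}
    for v in variants:
        by_locus.setdefault((v.chrom, v.pos - 1), []).append(v)
    loci_by_chrom: dict[str, np.ndarray] = {}
    for (chrom, pos0) in by_locus:
        loci_by_chrom.setdefault(chrom, []).append(pos0)  # type: ignore[arg-type]
    loci_by_chrom = {c: np.sort(np.array(p)) for c, p in loci_by_chrom.items()}

    log = ExtractionLog()
    rows = []
    for read in records:
        log.n_reads += 1
        if read.is_unmapped:
            log.n_unmapped += 1
            continue
        if read.is_secondary or read.is_supplementary:
            log.n_secondary += 1
            continue
        if read.is_duplicate:
            log.n_duplicate += 1
            continue
        if read.mapping_quality < min_mapq:
            log.n_low_mapq += 1
            continue
        chrom = read.reference_name
        loci = loci_by_chrom.get(chrom)
        if loci is None:
            continue
        lo = np.searchsorted(loci, read.reference_start)
        hi = np.searchsorted(loci, read.reference_end)
        if lo == hi:
            continue
        if not (read.has_tag(cell_tag) and read.has_tag(umi_tag)):
            log.n_missing_tags += 1
            continue
        barcode = read.get_tag(cell_tag)
        if barcode_whitelist is not None and barcode not in barcode_whitelist:
            log.n_not_whitelisted += 1
            continue
        umi = read.get_tag(umi_tag)
        # walk the alignment: query offset for each covered locus
        aligned = {
            rpos: qpos
            for qpos, rpos in read.get_aligned_pairs(matches_only=False)
            if rpos is not None
        }
        seq = read.query_sequence
        emitted = False
        for pos0 in loci[lo:hi]:
            qpos = aligned.get(int(pos0))
            if qpos is None:  # deletion spanning the locus
                continue
            base = seq[qpos].upper()
            for v in by_locus[(chrom, int(pos0))]:
                allele = ("ref" if base == v.ref
                          else "alt" if base == v.alt else "other")
                rows.append((v.id, barcode, umi, allele, read.query_name))
                emitted = True
        if emitted:
            log.n_emitted += 1
    obs = pd.DataFrame(rows, columns=_OBS_COLUMNS)
    return obs, log


def collapse_umis(observations: pd.DataFrame) -> pd.DataFrame:
    """Collapse read-level observations to per-cell per-variant UMI counts.

    Within each (cell, variant, UMI) group the consensus allele is the
    majority over that UMI's reads; ties discard the UMI.  Output has
    one row per (variant, cell) with ref/alt/other UMI counts and the
    derived status.
    """
    if observations.empty:
        return pd.DataFrame(columns=_CALL_COLUMNS)
    rows = []
    grouped = observations.groupby(
        ["variant_id", "cell_barcode", "umi"], sort=True
    )["allele"]
    consensus = {}
    for (vid, cell, umi), alleles in grouped:
        counts = Counter(alleles)
        top = counts.most_common()
        if len(top) > 1 and top[0][1] == top[1][1]:
            continue  # tied UMI discarded
        consensus.setdefault((vid, cell), Counter())[top[0][0]] += 1
    for (vid, cell), c in sorted(consensus.items()):
        ref, alt, other = c.get("ref", 0), c.get("alt", 0), c.get("other", 0)
        if alt >= 1:
            status = "alt-detected"
        elif ref >= 1:
            status = "ref-only"
        else:
            status = "no-coverage"
        rows.append((vid, cell, ref, alt, other, status))
    return pd.DataFrame(rows, columns=_CALL_COLUMNS)


def group_summary(
    calls: pd.DataFrame, cell_annotations: pd.DataFrame,
    group_cols: list[str] = ("group",),
) -> tuple[pd.DataFrame, int]:
    """Per (variant, cell group) detection counts and single-cell VAF.

    ``cell_annotations`` maps ``cell_barcode`` to grouping columns (cell
    type and/or sample).  The group scVAF is the fraction of covered
    cells (alt-detected + ref-only) in which the variant was detected;
    groups with zero covered cells get NaN, not 0.  A UMI-level VAF
    (alt UMIs over ref+alt UMIs) is emitted as a secondary column.
    Unannotated barcodes are excluded; their count is returned.
    """
    group_cols = list(group_cols)
    ann = cell_annotations.set_index("cell_barcode")[group_cols]
    merged = calls.join(ann, on="cell_barcode", how="left")
    n_unannotated = int(merged[group_cols[0]].isna().sum())
    merged = merged.dropna(subset=group_cols)
    rows = []
    for (vid, *group), sub in merged.groupby(["variant_id"] + group_cols):
        n_alt = int((sub["status"] == "alt-detected").sum())
        n_ref = int((sub["status"] == "ref-only").sum())
        covered = n_alt + n_ref
        scvaf = n_alt / covered if covered else np.nan
        umi_alt = int(sub["alt_umis"].sum())
        umi_ref = int(sub["ref_umis"].sum())
        umi_vaf = umi_alt / (umi_alt + umi_ref) if umi_alt + umi_ref else np.nan
        rows.append((vid, *group, n_alt, n_ref, scvaf, umi_vaf))
    out = pd.DataFrame(
        rows,
        columns=["variant_id"] + group_cols
        + ["n_alt_cells", "n_ref_only_cells", "sc_vaf", "umi_vaf"],
    )
    return out, n_unannotated


def cooccurrence(calls: pd.DataFrame) -> pd.DataFrame:
    """Within-cell co-occurrence counts for every unordered variant pair.

    Counts are restricted to cells with coverage of both variants
    (status other than no-coverage at each): cells with both alts
    detected, with only one, and with neither.
    """
    covered = calls[calls["status"].isin(["alt-detected", "ref-only"])]
    status = {
        (r.variant_id, r.cell_barcode): r.status
        for r in covered.itertuples()
    }
    variants = sorted(covered["variant_id"].unique())
    cells_of = {
        v: set(covered.loc[covered["variant_id"] == v, "cell_barcode"])
        for v in variants
    }
    rows = []
    for va, vb in itertools.combinations(variants, 2):
        both_covered = cells_of[va] & cells_of[vb]
        n_both = n_a = n_b = n_neither = 0
        for cell in both_covered:
            a_alt = status[(va, cell)] == "alt-detected"
            b_alt = status[(vb, cell)] == "alt-detected"
            if a_alt and b_alt:
                n_both += 1
            elif a_alt:
                n_a += 1
            elif b_alt:
                n_b += 1
            else:
                n_neither += 1
        rows.append((va, vb, len(both_covered), n_both, n_a, n_b, n_neither))
    return pd.DataFrame(
        rows,
        columns=["variant_a", "variant_b", "n_covered_both", "n_both_alt",
                 "n_a_only", "n_b_only", "n_neither"],
    )
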