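"""Somatic call-set consensus, hard filters, and sample-identity checks.

The somatic SNV/INDEL strategy keeps variants reported by at least two
callers of the relevant trio (Mutect/VarScan/Strelka for SNVs;
VarScan/Strelka/Pindel for INDELs), then applies coverage cutoffs of
14X tumor / 8X normal and a high-pass tumor VAF of 0.05 with a low-pass
normal VAF of 0.02.  Structural variants with somatic score < 30 or
junction somatic score < 30 are removed.  Sample identity across
timepoints is checked by Pearson correlation of germline VAFs over a
small panel of germline loci (two dozen suffice).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "VariantCall",
    "SvCall",
    "SNV_TRIO",
    "INDEL_TRIO",
    "consensus_merge",
    "somatic_filter",
    "sv_filter",
    "identity_check",
]

SNV_TRIO = frozenset({"mutect", "varscan", "strelka"})
INDEL_TRIO = frozenset({"varscan", "strelka", "pindel"})


@dataclass(frozen=True)
class VariantCall:
    """A somatic small-variant call with its supporting evidence."""

    chrom: str
    pos: int
    ref: str
    alt: str
    variant_class: str  # "SNV" or "INDEL"
    callers: frozenset[str] = frozenset()
    tumor_depth: float = np.nan
    normal_depth: float = np.nan
    tumor_vaf: float = np.nan
    normal_vaf: float = np.nan

    def __post_init__(self) -> None:
        if self.ref.upper() == self.alt.upper():
            raise ValueError(f"ref == alt at {self.chrom}:{self.pos}")
        if self.variant_class not in ("SNV", "INDEL"):
            raise ValueError(f"unknown variant class {self.variant_class!r}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref.upper(), self.alt.upper())


@dataclass(frozen=True)
class SvCall:
    """A structural-variant call as a breakend pair plus scores."""

    chrom1: str
    pos1: int
    chrom2: str
    pos2: int
    sv_type: str
    somatic_score: float
    junction_somatic_score: float

    def __post_init__(self) -> None:
        if self.somatic_score < 0 or self.junction_somatic_score < 0:
            raise ValueError("SV scores must be >= 0")


def _nanmax(values):
    vals = [v for v in values if not (isinstance(v, float) and np.isnan(v))]
    return max(vals) if vals else np.nan


def consensus_merge(
    call_sets: dict[str, list[VariantCall]],
    snv_trio: frozenset[str] = SNV_TRIO,
    indel_trio: frozenset[str] = INDEL_TRIO,
    min_callers: int = 2,
) -> list[VariantCall]:
    """Two-of-three consensus merge across caller call sets.

    An SNV is retained iff reported by at least ``min_callers`` callers
    of the SNV trio; likewise for INDELs against the INDEL trio.  The
    merged record carries the union of caller ids and, for each numeric
    evidence field, the maximum across reporting callers.  Variants are
    keyed by (chrom, pos, ref, alt) with alleles upper-cased; a caller
    id outside both trios, or two callers disagreeing on the variant
    class at one key, is an error.
    """
    known = snv_trio | indel_trio
    unknown = set(call_sets) - known
    if unknown:
        raise ValueError(f"unknown caller id(s): {sorted(unknown)}")

    grouped: dict[tuple, list[tuple[str, VariantCall]]] = {}
    for caller, calls in call_sets.items():
        for call in calls:
            grouped.setdefault(call.key, []).append((caller, call))

    merged: list[VariantCall] = []
    for key in sorted(grouped):
        entries = grouped[key]
        classes = {c.variant_class for _, c in entries}
        if len(classes) > 1:
            raise ValueError(f"conflicting variant classes at {key}")
        vclass = classes.pop()
        trio = snv_trio if vclass == "SNV" else indel_trio
        supporting = {caller for caller, _ in entries if caller in trio}
        if len(supporting) < min_callers:
            continue
        calls = [c for _, c in entries]
        merged.append(
            replace(
                calls[0],
                callers=frozenset(caller for caller, _ in entries),
                tumor_depth=_nanmax(c.tumor_depth for c in calls),
                normal_depth=_nanmax(c.normal_depth for c in calls),
                tumor_vaf=_nanmax(c.tumor_vaf for c in calls),
                normal_vaf=_nanmax(c.normal_vaf for c in calls),
            )
        )
    return merged


def somatic_filter(
    calls: list[VariantCall],
    min_tumor_depth: float = 14,
    min_normal_depth: float = 8,
    min_tumor_vaf: float = 0.05,
    max_normal_vaf: float = 0.02,
) -> tuple[list[VariantCall], list[tuple[VariantCall, str]]]:
    """Coverage and VAF hard filter.

    Retains a call iff tumor depth >= 14, normal depth >= 8, tumor
    VAF >= 0.05 and normal VAF <= 0.02 (inclusive at the stated
    boundaries).  Returns ``(retained, rejected)`` where each rejected
    entry carries the first failing reason; records with a missing
    (NaN) field are rejected with reason ``"missing-field"``.
    """
    retained, rejected = [], []
    for call in calls:
        fields = (call.tumor_depth, call.normal_depth,
                  call.tumor_vaf, call.normal_vaf)
        if any(np.isnan(f) for f in fields):
            rejected.append((call, "missing-field"))
        elif call.tumor_depth < min_tumor_depth:
            rejected.append((call, "tumor-depth"))
        elif call.normal_depth < min_normal_depth:
            rejected.append((call, "normal-depth"))
        elif call.tumor_vaf < min_tumor_vaf:
            rejected.append((call, "tumor-vaf"))
        elif call.normal_vaf > max_normal_vaf:
            rejected.append((call, "normal-vaf"))
        else:
            retained.append(call)
    return retained, rejected


def sv_filter(svs: list[SvCall], min_score: float = 30) -> list[SvCall]:
    """Keep SVs with somatic score >= 30 AND junction somatic score >= 30."""
    return [
        sv for sv in svs
        if sv.somatic_score >= min_score
        and sv.junction_somatic_score >= min_score
    ]


def identity_check(
    vaf_table: pd.DataFrame,
    min_shared: int = 5,
    r_thresh: float = 0.8,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise germline-VAF concordance between samples.

    ``vaf_table`` is samples x loci of germline VAFs; NaN marks a locus
    without coverage in that sample.  For each sample pair the Pearson
    correlation is computed over loci covered in both; pairs sharing
    fewer than ``min_shared`` loci are left unresolved (NaN r).

    Returns ``(r_matrix, flags)`` where ``flags`` holds one row per
    unordered pair with columns sample_a/sample_b/n_shared/r/verdict and
    verdict in {"same-patient", "different", "unresolved"}.
    """
    samples = list(vaf_table.index)
    r = pd.DataFrame(np.eye(len(samples)), index=samples, columns=samples)
    rows = []
    for a, b in itertools.combinations(samples, 2):
        both = vaf_table.loc[a].notna() & vaf_table.loc[b].notna()
        n_shared = int(both.sum())
        if n_shared < min_shared:
            rab = np.nan
            verdict = "unresolved"
        else:
            x = vaf_table.loc[a, both].to_numpy(dtype=float)
            y = vaf_table.loc[b, both].to_numpy(dtype=float)
            if x.std() == 0 or y.std() == 0:
                rab = np.nan
                verdict = "unresolved"
            else:
                rab = float(np.corrcoef(x, y)[0, 1])
                verdict = "same-patient" if rab >= r_thresh else "different"
        r.loc[a, b] = r.loc[b, a] = rab
        rows.append(
            {"sample_a": a, "sample_b": b, "n_shared": n_shared,
             "r": rab, "verdict": verdict}
        )
    flags = pd.DataFrame(
        rows, columns=["sample_a", "sample_b", "n_shared", "r", "verdict"]
    )
    return r, flags
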