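"""Seeded synthetic-data generators with ground truth.

Every generator is a pure function of its parameters and a seed:
calling it twice with identical arguments produces byte-identical
output.  The generators emulate the data modalities consumed by the
rest of the pipeline —

* a clonal architecture (subclone tree with per-timepoint cancer-cell
  fractions, somatic variants, haplotype assignments and per-chromosome
  copy ratios),
* barcode/UMI-tagged single-cell alignments over somatic SNV loci,
* linked-read molecules spanning phased germline heterozygous sites and
  somatic sites,
* multi-population genotype panels under the Balding–Nichols model,
* per-cell log2 copy-ratio matrices with subclone structure, and
* clustered expression count matrices with planted gene programs —

each paired with a truth table mapping generated entities (cells,
molecules, samples, genes) back to the planted labels, so downstream
stages can be scored against known answers.

Reads are single-end, 100 bp, and perfectly aligned apart from the
variant base itself: the pipeline consumes alignments, not raw reads,
so realistic error profiles, mappability and doublets are out of scope.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

__all__ = [
    "Variant",
    "Subclone",
    "ClonalArchitecture",
    "PhasedBlock",
    "GenotypePanel",
    "ClusterSpec",
    "Program",
    "gen_architecture",
    "gen_tagged_reads",
    "gen_linked_reads",
    "gen_genotype_panel",
    "gen_cnv_matrix",
    "gen_expression",
    "default_gene_panel",
    "gen_tracking_scenario",
    "write_sam",
    "write_vcf",
    "write_gmt",
    "write_counts_mtx",
]

_BASES = "ACGT"
DEFAULT_CELL_TAG = "CB"
DEFAULT_UMI_TAG = "UB"
READ_LENGTH = 100


def _barcode(index: int, length: int = 16) -> str:
    """Collision-free barcode: base-4 encoding of ``index``."""
    out = []
    for _ in range(length):
        out.append(_BASES[index % 4])
        index //= 4
    return "".join(reversed(out))


# ---------------------------------------------------------------------------
# clonal architecture
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Variant:
    """A somatic SNV. ``pos`` is 1-based."""

    id: str
    chrom: str
    pos: int
    ref: str
    alt: str


@dataclass
class Subclone:
    """One node of the subclone tree.

    ``ccf`` holds the cancer-cell fraction at each timepoint; the root
    clone has CCF 1.0 throughout.  ``copy_ratio`` maps chromosome to the
    relative copy value on the linear scale where neutral = 1.0.
    ``haplotype`` maps each variant owned by this subclone to the
    germline haplotype (1 or 2) it arose on.
    """

    id: str
    parent: str | None
    ccf: np.ndarray
    variant_ids: list[str]
    copy_ratio: dict[str, float]
    haplotype: dict[str, int]


@dataclass
class ClonalArchitecture:
    """Subclone tree + somatic variants + per-timepoint tumor purity."""

    subclones: list[Subclone]
    variants: list[Variant]
    purity: np.ndarray

    def __post_init__(self) -> None:
        self._by_id = {s.id: s for s in self.subclones}
        self._var_by_id = {v.id: v for v in self.variants}

    @property
    def n_timepoints(self) -> int:
        return len(self.purity)

    @property
    def chromosomes(self) -> list[str]:
        return sorted({c for s in self.subclones for c in s.copy_ratio})

    def subclone(self, subclone_id: str) -> Subclone:
        return self._by_id[subclone_id]

    def variant(self, variant_id: str) -> Variant:
        return self._var_by_id[variant_id]

    def lineage(self, subclone_id: str) -> list[str]:
        """Subclone ids from root down to ``subclone_id`` (inclusive)."""
        chain = []
        node: str | None = subclone_id
        while node is not None:
            chain.append(node)
            node = self._by_id[node].parent
        return chain[::-1]

    def lineage_variants(self, subclone_id: str) -> set[str]:
        """Variant ids carried by cells of ``subclone_id`` (own + inherited)."""
        return {
            vid for sid in self.lineage(subclone_id)
            for vid in self._by_id[sid].variant_ids
        }

    def variant_haplotype(self, variant_id: str) -> int:
        for s in self.subclones:
            if variant_id in s.haplotype:
                return s.haplotype[variant_id]
        raise KeyError(variant_id)

    def occupancy(self, timepoint: int) -> dict[str, float]:
        """Fraction of tumor cells belonging to each subclone proper.

        A cell belongs to exactly one tree node; the occupancy of a node
        is its CCF minus the CCF of its children (children nest inside
        the parent's cell population).
        """
        if not 0 <= timepoint < self.n_timepoints:
            raise ValueError(
                f"timepoint {timepoint} outside architecture with "
                f"{self.n_timepoints} timepoints"
            )
        occ = {s.id: float(s.ccf[timepoint]) for s in self.subclones}
        for s in self.subclones:
            if s.parent is not None:
                occ[s.parent] -= float(s.ccf[timepoint])
        return occ

    def validate(self) -> None:
        """Raise ``ValueError`` on any violated structural invariant."""
        seen_vars: set[str] = set()
        for s in self.subclones:
            if s.parent is not None:
                parent = self._by_id[s.parent]
                if np.any(s.ccf > parent.ccf + 1e-12):
                    raise ValueError(
                        f"subclone {s.id} CCF exceeds parent {s.parent}"
                    )
            if any(r <= 0 for r in s.copy_ratio.values()):
                raise ValueError(f"non-positive copy ratio in {s.id}")
            for vid in s.variant_ids:
                if vid in seen_vars:
                    raise ValueError(f"variant {vid} assigned twice")
                if s.haplotype.get(vid) not in (1, 2):
                    raise ValueError(f"variant {vid} lacks haplotype in (1,2)")
                seen_vars.add(vid)
        if seen_vars != set(self._var_by_id):
            raise ValueError("variant assignment is not a bijection")
        by_chrom: dict[str, set[int]] = {}
        for v in self.variants:
            if v.pos in by_chrom.setdefault(v.chrom, set()):
                raise ValueError(f"duplicate position {v.chrom}:{v.pos}")
            by_chrom[v.chrom].add(v.pos)
        for t, occ in ((t, self.occupancy(t)) for t in range(self.n_timepoints)):
            if any(o < -1e-9 for o in occ.values()):
                raise ValueError(f"negative occupancy at timepoint {t}")
        if np.any(self.purity <= 0) or np.any(self.purity > 1):
            raise ValueError("purity must lie in (0, 1]")


def gen_architecture(
    seed: int,
    n_subclones: int = 3,
    n_timepoints: int = 2,
    n_variants: int = 12,
    chromosomes: tuple[str, ...] = ("chr1", "chr13", "chr16"),
    purity: np.ndarray | None = None,
) -> ClonalArchitecture:
    """Draw a random valid clonal architecture.

    The root clone has CCF 1.0 at every timepoint.  Each later subclone
    attaches to a random existing node and receives, per timepoint, a
    random share of its parent's *unallocated* CCF, which guarantees
    that sibling CCFs sum to at most the parent's and hence that tree
    occupancies are non-negative.  Every subclone owns at least one
    variant (requires ``n_variants >= n_subclones``); each non-root
    subclone additionally perturbs one chromosome's copy ratio so that
    subclones are distinguishable in copy-number space.
    """
    if n_subclones < 1:
        raise ValueError("n_subclones must be >= 1")
    if n_variants < n_subclones:
        raise ValueError("need n_variants >= n_subclones")
    if n_timepoints < 1:
        raise ValueError("n_timepoints must be >= 1")
    rng = np.random.default_rng(seed)

    if purity is None:
        purity = rng.uniform(0.6, 0.95, size=n_timepoints)
    purity = np.asarray(purity, dtype=float)
    if len(purity) != n_timepoints:
        raise ValueError("purity length must equal n_timepoints")

    parents: list[int | None] = [None]
    ccfs = [np.ones(n_timepoints)]
    unallocated = [np.ones(n_timepoints)]  # parent CCF not yet given to children
    for i in range(1, n_subclones):
        p = int(rng.integers(0, i))
        share = rng.uniform(0.3, 0.8, size=n_timepoints)
        ccf = unallocated[p] * share
        unallocated[p] = unallocated[p] - ccf
        parents.append(p)
        ccfs.append(ccf)
        unallocated.append(ccf.copy())

    # unique positions per chromosome
    var_chroms = [chromosomes[int(rng.integers(0, len(chromosomes)))]
                  for _ in range(n_variants)]
    positions: dict[str, set[int]] = {c: set() for c in chromosomes}
    variants: list[Variant] = []
    for i, chrom in enumerate(var_chroms):
        while True:
            pos = int(rng.integers(10_000, 5_000_000))
            if pos not in positions[chrom]:
                positions[chrom].add(pos)
                break
        ref = _BASES[int(rng.integers(0, 4))]
        alt = _BASES[(_BASES.index(ref) + int(rng.integers(1, 4))) % 4]
        variants.append(Variant(f"v{i}", chrom, pos, ref, alt))

    # each subclone gets one variant first, remainder assigned at random
    owner = list(range(n_subclones))
    owner += [int(rng.integers(0, n_subclones))
              for _ in range(n_variants - n_subclones)]

    ratio_choices = (0.5, 1.5, 2.0)
    subclones: list[Subclone] = []
    for i in range(n_subclones):
        if parents[i] is None:
            ratios = {c: 1.0 for c in chromosomes}
        else:
            ratios = dict(subclones[parents[i]].copy_ratio)
            ratios[chromosomes[(i - 1) % len(chromosomes)]] = ratio_choices[
                (i - 1) % len(ratio_choices)
            ]
        vids = [f"v{j}" for j, o in enumerate(owner) if o == i]
        haps = {vid: int(rng.integers(1, 3)) for vid in vids}
        subclones.append(
            Subclone(
                id=f"sc{i}",
                parent=None if parents[i] is None else f"sc{parents[i]}",
                ccf=ccfs[i],
                variant_ids=vids,
                copy_ratio=ratios,
                haplotype=haps,
            )
        )

    arch = ClonalArchitecture(subclones=subclones, variants=variants,
                              purity=purity)
    arch.validate()
    return arch


def _assign_cells(
    arch: ClonalArchitecture, timepoint: int, n_cells: int,
    rng: np.random.Generator,
) -> list[str]:
    """Draw a subclone id (or ``"normal"``) for each cell.

    Tumor with probability ``purity[timepoint]``; tumor cells land in a
    subclone proper with probability equal to its tree occupancy.
    """
    occ = arch.occupancy(timepoint)
    ids = list(occ)
    probs = np.clip(np.array([occ[i] for i in ids]), 0, None)
    probs = probs / probs.sum()
    purity = float(arch.purity[timepoint])
    labels = []
    for _ in range(n_cells):
        if rng.random() < purity:
            labels.append(ids[int(rng.choice(len(ids), p=probs))])
        else:
            labels.append("normal")
    return labels


# ---------------------------------------------------------------------------
# tagged single-cell alignments
# ---------------------------------------------------------------------------


def gen_tagged_reads(
    arch: ClonalArchitecture,
    timepoint: int,
    n_cells: int,
    mean_depth: float = 20.0,
    error_rate: float = 0.01,
    seed: int = 0,
    cell_tag: str = DEFAULT_CELL_TAG,
    umi_tag: str = DEFAULT_UMI_TAG,
) -> tuple[pysam.AlignmentHeader, list[pysam.AlignedSegment], pd.DataFrame]:
    """Simulate barcode/UMI-tagged alignments over the somatic loci.

    Cells are drawn from subclones in proportion to tree occupancy
    (scaled by purity); per cell and locus the read count is
    Poisson(``mean_depth``), each read on its own UMI.  A read carries
    the alternate base iff the cell's subclone lineage carries the
    variant, flipped with probability ``error_rate``.  Records are
    coordinate sorted and tagged with cell barcode and UMI.

    Returns ``(header, records, cell_truth)`` where ``cell_truth`` maps
    each cell barcode to its subclone (or ``"normal"``).
    """
    if not 0.0 <= error_rate < 0.5:
        raise ValueError("error_rate must be in [0, 0.5)")
    if mean_depth <= 0:
        raise ValueError("mean_depth must be > 0")
    rng = np.random.default_rng(seed)
    subclone_of = _assign_cells(arch, timepoint, n_cells, rng)
    barcodes = [_barcode(i) for i in range(n_cells)]

    max_pos: dict[str, int] = {}
    for v in arch.variants:
        max_pos[v.chrom] = max(max_pos.get(v.chrom, 0), v.pos)
    chroms = sorted(max_pos)
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": c, "LN": max_pos[c] + 10_000} for c in chroms],
        }
    )
    tid = {c: i for i, c in enumerate(chroms)}

    records: list[pysam.AlignedSegment] = []
    umi_counter = 0
    for ci, (bc, sc) in enumerate(zip(barcodes, subclone_of)):
        carried = set() if sc == "normal" else arch.lineage_variants(sc)
        for v in arch.variants:
            n_reads = int(rng.poisson(mean_depth))
            for _ in range(n_reads):
                offset = int(rng.integers(0, READ_LENGTH))
                start = max(1, v.pos - offset)
                offset = v.pos - start
                base = v.alt if v.id in carried else v.ref
                if rng.random() < error_rate:
                    base = v.ref if base == v.alt else v.alt
                seq = list("A" * READ_LENGTH)
                seq[offset] = base
                a = pysam.AlignedSegment(header)
                a.query_name = f"r{umi_counter}"
                a.query_sequence = "".join(seq)
                a.flag = 0
                a.reference_id = tid[v.chrom]
                a.reference_start = start - 1  # SAM text is 1-based
                a.mapping_quality = 60
                a.cigarstring = f"{READ_LENGTH}M"
                a.query_qualities = pysam.qualitystring_to_array(
                    "I" * READ_LENGTH
                )
                a.set_tag(cell_tag, bc)
                a.set_tag(umi_tag, _barcode(umi_counter, length=12))
                umi_counter += 1
                records.append(a)
    records.sort(key=lambda r: (r.reference_id, r.reference_start, r.query_name))
    truth = pd.DataFrame(
        {"cell_barcode": barcodes, "subclone": subclone_of}
    )
    return header, records, truth


def write_sam(path: str, header: pysam.AlignmentHeader,
              records: list[pysam.AlignedSegment]) -> None:
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for rec in records:
            out.write(rec)


# ---------------------------------------------------------------------------
# linked-read molecules
# ---------------------------------------------------------------------------


@dataclass
class PhasedBlock:
    """Phased germline heterozygous sites on one chromosome.

    ``hap1``/``hap2`` give the allele on each haplotype at every het;
    the two alleles differ at every position.
    """

    chrom: str
    positions: np.ndarray  # 1-based, sorted
    hap1: np.ndarray
    hap2: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.hap1 == self.hap2):
            raise ValueError("haplotype alleles must differ at every het")

    def allele(self, haplotype: int, pos: int) -> str:
        i = int(np.searchsorted(self.positions, pos))
        if i >= len(self.positions) or self.positions[i] != pos:
            raise KeyError(pos)
        return str(self.hap1[i] if haplotype == 1 else self.hap2[i])


def gen_linked_reads(
    arch: ClonalArchitecture,
    n_molecules: int = 500,
    molecule_len_bp: int = 50_000,
    het_spacing_bp: int = 2_000,
    error_rate: float = 0.01,
    seed: int = 0,
    timepoint: int = 0,
    chrom: str | None = None,
    variant_ids: list[str] | None = None,
) -> tuple[pd.DataFrame, PhasedBlock, pd.DataFrame]:
    """Simulate linked-read allele observations for barcoded molecules.

    Each molecule has a unique barcode, a haplotype drawn uniformly from
    {1, 2}, and a source subclone (or normal) drawn like a cell.  It
    reports the haplotype allele at every phased het it spans (flipped
    to the other haplotype's allele with probability ``error_rate``) and
    the somatic alternate allele at a spanned somatic site iff both its
    source lineage carries the variant and the variant's haplotype
    matches the molecule's.

    Returns ``(observations, phased_block, molecule_truth)``;
    observations have columns barcode/chrom/pos/allele.  Molecules that
    span no het are still emitted and marked uninformative in the truth
    table.
    """
    if molecule_len_bp <= het_spacing_bp:
        raise ValueError("molecule_len_bp must exceed het_spacing_bp")
    rng = np.random.default_rng(seed)
    if variant_ids is not None:
        somatic = [arch.variant(vid) for vid in variant_ids]
        chroms = {v.chrom for v in somatic}
        if len(chroms) != 1:
            raise ValueError("variant_ids must lie on one chromosome")
        chrom = chroms.pop()
    else:
        if chrom is None:
            chrom = arch.variants[0].chrom
        somatic = [v for v in arch.variants if v.chrom == chrom]
    if not somatic:
        raise ValueError(f"no somatic variants on {chrom}")
    pos_lo = min(v.pos for v in somatic) - molecule_len_bp
    pos_hi = max(v.pos for v in somatic) + molecule_len_bp
    pos_lo = max(1, pos_lo)

    som_pos = {v.pos for v in somatic}
    het_pos = np.array(
        [p for p in range(pos_lo, pos_hi, het_spacing_bp) if p not in som_pos]
    )
    hap1 = rng.choice(list(_BASES), size=len(het_pos))
    hap2 = np.array(
        [_BASES[(_BASES.index(a) + int(rng.integers(1, 4))) % 4] for a in hap1]
    )
    block = PhasedBlock(chrom=chrom, positions=het_pos, hap1=hap1, hap2=hap2)

    source = _assign_cells(arch, timepoint, n_molecules, rng)
    rows = []
    truth_rows = []
    for mi in range(n_molecules):
        bc = _barcode(mi)
        hap = int(rng.integers(1, 3))
        start = int(rng.integers(pos_lo, max(pos_lo + 1, pos_hi - molecule_len_bp)))
        end = start + molecule_len_bp
        carried = (set() if source[mi] == "normal"
                   else arch.lineage_variants(source[mi]))
        lo = np.searchsorted(het_pos, start)
        hi = np.searchsorted(het_pos, end, side="right")
        n_hets = int(hi - lo)
        for i in range(lo, hi):
            allele = hap1[i] if hap == 1 else hap2[i]
            if rng.random() < error_rate:
                allele = hap2[i] if hap == 1 else hap1[i]
            rows.append((bc, chrom, int(het_pos[i]), str(allele)))
        for v in somatic:
            if start <= v.pos < end:
                carries = (v.id in carried
                           and arch.variant_haplotype(v.id) == hap)
                allele = v.alt if carries else v.ref
                if rng.random() < error_rate:
                    allele = v.ref if allele == v.alt else v.alt
                rows.append((bc, chrom, v.pos, allele))
        truth_rows.append(
            {
                "barcode": bc,
                "haplotype": hap,
                "source": source[mi],
                "start": start,
                "end": end,
                "n_hets": n_hets,
                "informative": n_hets > 0,
            }
        )
    obs = pd.DataFrame(rows, columns=["barcode", "chrom", "pos", "allele"])
    truth = pd.DataFrame(truth_rows)
    return obs, block, truth


# ---------------------------------------------------------------------------
# genotype panel (Balding–Nichols)
# ---------------------------------------------------------------------------


@dataclass
class GenotypePanel:
    """Per-sample per-marker allele read counts with population truth."""

    ref: pd.DataFrame  # samples x markers, reference-allele read counts
    alt: pd.DataFrame
    populations: pd.Series  # sample -> population label
    pop_freqs: pd.DataFrame  # populations x markers, alt-allele frequency
    genotypes: pd.DataFrame  # samples x markers, dosage 0/1/2


def gen_genotype_panel(
    n_pops: int = 3,
    n_per_pop: int = 200,
    n_markers: int = 2_000,
    fst: float = 0.1,
    mean_depth: float = 30.0,
    missing_rate: float = 0.02,
    seed: int = 0,
) -> GenotypePanel:
    """Simulate a multi-population read-count panel.

    Ancestral allele frequencies are Uniform(0.05, 0.95); each
    population draws its own frequency from the Balding–Nichols beta
    distribution with divergence parameter ``fst`` (``fst = 0``
    collapses to identical frequencies, making populations
    exchangeable).  Diploid genotypes follow Hardy–Weinberg within each
    population; read depth is Poisson(``mean_depth``) and the alternate
    read count Binomial(depth, dosage/2).  A ``missing_rate`` fraction
    of (sample, marker) cells is zeroed out.
    """
    if not 0.0 <= fst < 1.0:
        raise ValueError("fst must be in [0, 1)")
    if not 0.0 <= missing_rate < 1.0:
        raise ValueError("missing_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    p_anc = rng.uniform(0.05, 0.95, size=n_markers)
    if fst == 0.0:
        pop_freq = np.tile(p_anc, (n_pops, 1))
    else:
        a = p_anc * (1 - fst) / fst
        b = (1 - p_anc) * (1 - fst) / fst
        pop_freq = rng.beta(a, b, size=(n_pops, n_markers))

    n_samples = n_pops * n_per_pop
    labels = np.repeat([f"POP{k}" for k in range(n_pops)], n_per_pop)
    samples = [f"{labels[i]}_S{i % n_per_pop}" for i in range(n_samples)]
    geno = np.vstack(
        [
            rng.binomial(2, pop_freq[k], size=(n_per_pop, n_markers))
            for k in range(n_pops)
        ]
    )
    depth = rng.poisson(mean_depth, size=geno.shape)
    alt = rng.binomial(depth, geno / 2.0)
    ref = depth - alt
    missing = rng.random(geno.shape) < missing_rate
    alt[missing] = 0
    ref[missing] = 0

    markers = [f"m{j}" for j in range(n_markers)]
    return GenotypePanel(
        ref=pd.DataFrame(ref, index=samples, columns=markers),
        alt=pd.DataFrame(alt, index=samples, columns=markers),
        populations=pd.Series(labels, index=samples, name="population"),
        pop_freqs=pd.DataFrame(
            pop_freq, index=[f"POP{k}" for k in range(n_pops)], columns=markers
        ),
        genotypes=pd.DataFrame(geno, index=samples, columns=markers),
    )


# ---------------------------------------------------------------------------
# CNV matrices
# ---------------------------------------------------------------------------


def default_gene_panel(
    arch: ClonalArchitecture, n_genes: int = 30
) -> pd.DataFrame:
    """A gene panel spread round-robin over the architecture's chromosomes."""
    chroms = arch.chromosomes
    return pd.DataFrame(
        {
            "gene": [f"g{i}" for i in range(n_genes)],
            "chrom": [chroms[i % len(chroms)] for i in range(n_genes)],
        }
    )


def gen_cnv_matrix(
    arch: ClonalArchitecture,
    timepoint: int,
    n_cells: int,
    noise_sd: float = 0.1,
    gene_panel: pd.DataFrame | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cell log2 copy-ratio matrix over a gene panel, with truth.

    Each cell's value at a gene is log2 of its subclone's copy ratio on
    the gene's chromosome plus Normal(0, ``noise_sd``) noise; normal
    (non-tumor) cells are copy neutral.
    """
    if gene_panel is None:
        gene_panel = default_gene_panel(arch)
    if len(gene_panel) == 0:
        raise ValueError("gene_panel must be non-empty")
    rng = np.random.default_rng(seed)
    subclone_of = _assign_cells(arch, timepoint, n_cells, rng)
    cells = [f"cell{i}" for i in range(n_cells)]
    base = np.zeros((n_cells, len(gene_panel)))
    for i, sc in enumerate(subclone_of):
        ratios = ({c: 1.0 for c in arch.chromosomes} if sc == "normal"
                  else arch.subclone(sc).copy_ratio)
        base[i] = [np.log2(ratios[c]) for c in gene_panel["chrom"]]
    values = base + rng.normal(0.0, noise_sd, size=base.shape)
    mat = pd.DataFrame(values, index=cells, columns=list(gene_panel["gene"]))
    truth = pd.DataFrame({"cell": cells, "subclone": subclone_of})
    return mat, truth


# ---------------------------------------------------------------------------
# expression counts with planted programs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ClusterSpec:
    """One expression cluster and its cell annotations."""

    name: str
    fraction: float
    sample: str = "S1"
    timepoint: int = 0
    cell_type: str = "Plasma"


@dataclass(frozen=True)
class Program:
    """A planted gene program: ``n_genes`` genes multiplied by ``fold``
    in the designated clusters."""

    name: str
    n_genes: int
    fold: float
    clusters: tuple[str, ...]


def gen_expression(
    cluster_spec: list[ClusterSpec],
    n_cells: int = 500,
    n_genes: int = 1_000,
    planted_programs: list[Program] = (),
    seed: int = 0,
    dispersion: float = 2.0,
    libsize_sd: float = 0.3,
):
    """Simulate a clustered count matrix with planted programs.

    Counts are negative binomial around lognormal per-gene means scaled
    by a lognormal per-cell library-size factor; genes belonging to a
    planted program are multiplied by the program's fold change in its
    designated clusters.  Returns an :class:`anndata.AnnData` whose
    ``obs`` carries sample, timepoint, cell type, cluster and the
    per-cell expressed-gene count, and whose ``var['program']`` is the
    gene-to-program truth map.
    """
    import anndata as ad

    known = {c.name for c in cluster_spec}
    for prog in planted_programs:
        unknown = set(prog.clusters) - known
        if unknown:
            raise ValueError(
                f"program {prog.name!r} references unknown clusters {unknown}"
            )
    rng = np.random.default_rng(seed)
    fracs = np.array([c.fraction for c in cluster_spec], dtype=float)
    fracs = fracs / fracs.sum()
    counts_per = np.floor(fracs * n_cells).astype(int)
    counts_per[0] += n_cells - counts_per.sum()
    cluster_of = np.repeat([c.name for c in cluster_spec], counts_per)

    gene_names = np.array([f"g{j:04d}" for j in range(n_genes)])
    program_of = np.array([""] * n_genes, dtype=object)
    pool = rng.permutation(n_genes)
    cursor = 0
    for prog in planted_programs:
        if cursor + prog.n_genes > n_genes:
            raise ValueError("planted programs exceed gene universe")
        program_of[pool[cursor:cursor + prog.n_genes]] = prog.name
        cursor += prog.n_genes

    base_mean = rng.lognormal(mean=0.0, sigma=1.0, size=n_genes)
    lib = rng.lognormal(mean=0.0, sigma=libsize_sd, size=n_cells)
    fold = np.ones((n_cells, n_genes))
    for prog in planted_programs:
        in_prog = program_of == prog.name
        in_clusters = np.isin(cluster_of, prog.clusters)
        fold[np.ix_(in_clusters, in_prog)] = prog.fold
    mu = lib[:, None] * base_mean[None, :] * fold
    r = dispersion
    counts = rng.negative_binomial(r, r / (r + mu))

    spec_of = {c.name: c for c in cluster_spec}
    obs = pd.DataFrame(
        {
            "cluster": cluster_of,
            "sample": [spec_of[c].sample for c in cluster_of],
            "timepoint": [spec_of[c].timepoint for c in cluster_of],
            "cell_type": [spec_of[c].cell_type for c in cluster_of],
        },
        index=[f"cell{i}" for i in range(n_cells)],
    )
    obs["n_genes"] = (counts > 0).sum(axis=1)
    var = pd.DataFrame({"program": program_of}, index=gene_names)
    adata = ad.AnnData(X=counts.astype(np.float64), obs=obs, var=var)
    adata.uns["programs"] = {
        p.name: {"fold": p.fold, "clusters": list(p.clusters),
                 "n_genes": p.n_genes}
        for p in planted_programs
    }
    return adata


def gen_tracking_scenario(
    seed: int,
    n_cells: int = 600,
    n_genes: int = 600,
    fold: float = 4.0,
    program_size: int = 40,
):
    """Two-timepoint subpopulation scenario with one planted loss/gain.

    Timepoint 0 (sample T1) holds subpopulations A and B; timepoint 1
    (sample T2) holds A and a novel C.  Each subpopulation expresses its
    own planted program (A's program is shared across timepoints) and
    carries a distinct per-chromosome copy-number category profile
    (ordered codes 0-4, neutral = 2): A has a chr13 loss, B is neutral,
    and the relapse-emergent C carries two alterations (chr13 deletion
    and chr16 gain), as newly dominant subclones typically differ from
    the pre-existing populations at multiple chromosomes.  The expected
    tracking outcome is exactly one stable pair (A), one loss (B) and
    one gain (C).

    Returns ``(adata, cnv_categories, expected_patterns)`` where
    ``cnv_categories`` maps cluster to its chromosome category dict and
    ``expected_patterns`` maps (timepoint key, profile id) to the
    planted pattern.
    """
    specs = [
        ClusterSpec("A1", 0.3, sample="T1", timepoint=0),
        ClusterSpec("B1", 0.2, sample="T1", timepoint=0),
        ClusterSpec("A2", 0.3, sample="T2", timepoint=1),
        ClusterSpec("C2", 0.2, sample="T2", timepoint=1),
    ]
    programs = [
        Program("PA", program_size, fold, ("A1", "A2")),
        Program("PB", program_size, fold, ("B1",)),
        Program("PC", program_size, fold, ("C2",)),
    ]
    adata = gen_expression(specs, n_cells, n_genes, programs, seed=seed)
    neutral = {"chr1": 2, "chr13": 2, "chr16": 2}
    cnv_categories = {
        "A1": {**neutral, "chr13": 1},
        "A2": {**neutral, "chr13": 1},
        "B1": dict(neutral),
        "C2": {**neutral, "chr13": 0, "chr16": 3},
    }
    expected = {
        ("t1", "T1/A1"): "stable",
        ("t1", "T1/B1"): "lost",
        ("t2", "T2/A2"): "stable",
        ("t2", "T2/C2"): "gained",
    }
    return adata, cnv_categories, expected


# ---------------------------------------------------------------------------
# writers for standard text formats
# ---------------------------------------------------------------------------

_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=CALLERS,Number=.,Type=String,Description="Callers reporting this variant">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
"""


def write_vcf(variants: list[Variant], path: str,
              contig_lengths: dict[str, int] | None = None) -> None:
    """Write a somatic SNV list as minimal VCF v4.2 (sites only)."""
    chroms: list[str] = []
    for v in variants:
        if v.chrom not in chroms:
            chroms.append(v.chrom)
    if contig_lengths is None:
        contig_lengths = {
            c: max(v.pos for v in variants if v.chrom == c) + 10_000
            for c in chroms
        }
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for c in chroms:
            fh.write(f"##contig=<ID={c},length={contig_lengths[c]}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in sorted(variants, key=lambda v: (chroms.index(v.chrom), v.pos)):
            fh.write(f"{v.chrom}\t{v.pos}\t{v.id}\t{v.ref}\t{v.alt}\t.\t.\t.\n")


def write_counts_mtx(adata, out_dir: str) -> None:
    """Write an expression AnnData as MTX + gene/barcode lists + obs TSV."""
    import os

    from scipy import io as spio
    from scipy import sparse

    os.makedirs(out_dir, exist_ok=True)
    spio.mmwrite(
        os.path.join(out_dir, "matrix.mtx"),
        sparse.csr_matrix(adata.X),
    )
    with open(os.path.join(out_dir, "genes.tsv"), "w") as fh:
        fh.write("\n".join(adata.var_names) + "\n")
    with open(os.path.join(out_dir, "barcodes.tsv"), "w") as fh:
        fh.write("\n".join(adata.obs_names) + "\n")
    adata.obs.to_csv(os.path.join(out_dir, "annotations.tsv"), sep="\t")


def write_gmt(pathways: dict[str, list[str]], path: str) -> None:
    """Write gene sets in GMT format (name, description, genes...)."""
    with open(path, "w") as fh:
        for name, genes in pathways.items():
            fh.write("\t".join([name, "synthetic"] + list(genes)) + "\n")
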