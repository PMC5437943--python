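"""Seeded synthetic somatic cohorts with planted truth.

Real cohort inputs for this kind of tooling are controlled-access tumor /
normal pairs; everything downstream of primary calling, however, only needs
the *shapes* of those data: per-caller somatic VCFs, a cohort MAF, per-sample
SEG files and a gene table.  This module generates all of them from a single
seeded :class:`CohortDesign` with known planted structure — driver genes
mutated at designed probabilities, molecular-subgroup marker mutations
consistent with planted ABC/GCB/U labels, recurrent copy-number regions with
designed penetrance, and per-caller detection at designed sensitivity with
false positives confined to intergenic space — so that every pipeline stage
can be checked against ground truth.

Randomness is hierarchical: the design's one seed is split per concern
(gene placement, per-patient mutations, per-caller detection, segment
noise) via ``numpy`` seed sequences, so regenerating one facet never
perturbs another.

What the generator does **not** emulate: read-level data (no FASTQ/BAM),
trinucleotide mutational signatures, subclonal structure, and caller-specific
error profiles beyond a flat sensitivity / uniform false-positive model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import DesignError
from .formats_io import (
    ChromTable,
    GeneRecord,
    MafRecord,
    SegRecord,
    VcfDocument,
    VcfSite,
)
from .aggregate import CNState
from .consensus import VariantKey, normalize_key

_BASES = ("A", "C", "G", "T")

#: Sampling weights for passenger consequence classes (drivers are drawn
#: from the non-silent subset only).
_CLASS_WEIGHTS = {
    "Missense_Mutation": 0.55,
    "Silent": 0.15,
    "Nonsense_Mutation": 0.08,
    "Splice_Site": 0.05,
    "Frame_Shift_Del": 0.05,
    "Frame_Shift_Ins": 0.04,
    "In_Frame_Del": 0.03,
    "In_Frame_Ins": 0.02,
    "3'UTR": 0.02,
    "Intron": 0.01,
}

_INDEL_CLASSES = {
    "Frame_Shift_Del": "DEL",
    "Frame_Shift_Ins": "INS",
    "In_Frame_Del": "DEL",
    "In_Frame_Ins": "INS",
}

#: Planted log2 ratio for each discrete copy state.
STATE_LOG2 = {
    CNState.DEEP_LOSS: -1.5,
    CNState.LOSS: -0.6,
    CNState.NEUTRAL: 0.0,
    CNState.GAIN: 0.6,
    CNState.AMP: 1.5,
}


@dataclass(frozen=True)
class CnvRegion:
    """A recurrent copy-number event planted at a designed penetrance."""

    chrom: str
    start: int  # 0-based half-open
    end: int
    state: CNState
    penetrance: float


@dataclass
class CohortDesign:
    """Full specification of a synthetic cohort.

    Defaults describe a desk-scale lymphoma-like study: 50 patients on a
    5-chromosome toy genome, six driver genes at 35–60% mutation
    probability, ~40 passenger mutations per patient (so a 50-patient cohort
    plants roughly 2000 variants), three ABC and three GCB subgroup marker
    genes with a 40/40/20 ABC/GCB/U split, four recurrent CNV regions, and
    three callers at 90% sensitivity with a handful of intergenic false
    positives each.
    """

    seed: int = 0
    n_patients: int = 50
    chrom_sizes: tuple[tuple[str, int], ...] = (
        ("chr1", 2_000_000),
        ("chr2", 1_600_000),
        ("chr3", 1_200_000),
        ("chr4", 900_000),
        ("chr5", 600_000),
    )
    n_passenger_genes: int = 40
    gene_length: int = 6_000
    gene_spacing: int = 30_000
    driver_genes: tuple[tuple[str, float], ...] = (
        ("DRV1", 0.60),
        ("DRV2", 0.50),
        ("DRV3", 0.45),
        ("DRV4", 0.40),
        ("DRV5", 0.35),
        ("DRV6", 0.35),
    )
    passenger_rate: float = 40.0
    abc_markers: tuple[str, ...] = ("ABCM1", "ABCM2", "ABCM3")
    gcb_markers: tuple[str, ...] = ("GCBM1", "GCBM2", "GCBM3")
    subgroup_fractions: tuple[float, float, float] = (0.4, 0.4, 0.2)
    cnv_regions: tuple[CnvRegion, ...] = (
        CnvRegion("chr1", 100_000, 500_000, CNState.AMP, 0.45),
        CnvRegion("chr2", 200_000, 700_000, CNState.GAIN, 0.40),
        CnvRegion("chr3", 100_000, 600_000, CNState.DEEP_LOSS, 0.35),
        CnvRegion("chr4", 150_000, 550_000, CNState.LOSS, 0.40),
    )
    caller_sensitivity: tuple[tuple[str, float], ...] = (
        ("strelka", 0.9),
        ("mutationseq", 0.9),
        ("somaticsniper", 0.9),
    )
    caller_fp_mean: float = 4.0

    def validate(self) -> None:
        for _, p in self.driver_genes:
            if not 0.0 <= p <= 1.0:
                raise DesignError(f"driver probability {p} outside [0, 1]")
        for _, s in self.caller_sensitivity:
            if not 0.0 <= s <= 1.0:
                raise DesignError(f"caller sensitivity {s} outside [0, 1]")
        for r in self.cnv_regions:
            if not 0.0 <= r.penetrance <= 1.0:
                raise DesignError(f"CNV penetrance {r.penetrance} outside [0, 1]")
        if abs(sum(self.subgroup_fractions) - 1.0) > 1e-9:
            raise DesignError("subgroup fractions must sum to 1")
        if set(self.abc_markers) & set(self.gcb_markers):
            raise DesignError("marker lists must be disjoint")

    @property
    def chrom_table(self) -> ChromTable:
        return ChromTable(self.chrom_sizes)

    def gene_names(self) -> list[str]:
        return (
            [g for g, _ in self.driver_genes]
            + list(self.abc_markers)
            + list(self.gcb_markers)
            + [f"PSG{i + 1}" for i in range(self.n_passenger_genes)]
        )


@dataclass(frozen=True)
class TruthVariant:
    """One planted somatic mutation."""

    patient: str
    gene: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    classification: str
    variant_type: str

    def key(self) -> VariantKey:
        return normalize_key(self.chrom, self.pos, self.ref, self.alt)


@dataclass
class CohortTruth:
    """Everything the generator planted, for later recovery checks."""

    design: CohortDesign
    chrom_table: ChromTable
    genes: list[GeneRecord]
    patients: list[str]
    variants: list[TruthVariant]
    cn_events: dict[str, list[CnvRegion]]  # patient -> regions carried
    labels: dict[str, str]  # patient -> ABC/GCB/U

    def variants_of(self, patient: str) -> list[TruthVariant]:
        return [v for v in self.variants if v.patient == patient]

    def key_index(self) -> dict[tuple[str, VariantKey], TruthVariant]:
        return {(v.patient, v.key()): v for v in self.variants}

    def annotate(
        self, patient: str, keys: Sequence[VariantKey]
    ) -> list[MafRecord]:
        """Map recovered variant keys back to annotated MAF records — the
        fixture-side stand-in for the annotation step a real pipeline runs
        on consensus VCFs."""
        idx = {v.key(): v for v in self.variants_of(patient)}
        out = []
        for k in keys:
            v = idx.get(k)
            if v is None:
                continue
            out.append(_truth_to_maf(v))
        return out


def _truth_to_maf(v: TruthVariant) -> MafRecord:
    end = v.pos + max(len(v.ref), 1) - 1
    return MafRecord(
        gene_symbol=v.gene,
        chrom=v.chrom,
        start=v.pos,
        end=end,
        ref_allele=v.ref,
        alt_allele=v.alt,
        variant_classification=v.classification,
        variant_type=v.variant_type,
        sample_id=v.patient,
    )


# ---------------------------------------------------------------------------
# Generation


def _place_genes(design: CohortDesign) -> list[GeneRecord]:
    """Lay genes down the genome left to right with fixed spacing.

    Placement is deterministic (no RNG): gene order is drivers, ABC markers,
    GCB markers, passengers; chromosomes fill in table order."""
    names = design.gene_names()
    genes: list[GeneRecord] = []
    chrom_iter = iter(design.chrom_sizes)
    chrom, size = next(chrom_iter)
    cursor = design.gene_spacing
    for name in names:
        while cursor + design.gene_length > size:
            nxt = next(chrom_iter, None)
            if nxt is None:
                raise DesignError(
                    "gene table does not fit in the designed genome; "
                    "enlarge chromosomes or reduce gene count/spacing"
                )
            chrom, size = nxt
            cursor = design.gene_spacing
        genes.append(
            GeneRecord(
                symbol=name, chrom=chrom, start=cursor,
                end=cursor + design.gene_length,
            )
        )
        cursor += design.gene_length + design.gene_spacing
    return genes


def _draw_snv(rng: np.random.Generator, gene: GeneRecord, used: set[int]):
    """A fresh 1-based position inside the gene plus a ref/alt base pair."""
    while True:
        pos = int(rng.integers(gene.start + 1, gene.end + 1))
        if pos not in used:
            used.add(pos)
            break
    ref = _BASES[rng.integers(0, 4)]
    alt = _BASES[rng.integers(0, 4)]
    while alt == ref:
        alt = _BASES[rng.integers(0, 4)]
    return pos, ref, alt


def _make_variant(
    rng: np.random.Generator,
    patient: str,
    gene: GeneRecord,
    used: set[int],
    classification: str,
) -> TruthVariant:
    pos, ref, alt = _draw_snv(rng, gene, used)
    vtype = _INDEL_CLASSES.get(classification, "SNP")
    if vtype == "DEL":
        extra = "".join(_BASES[i] for i in rng.integers(0, 4, size=2))
        ref, alt = ref + extra, ref
    elif vtype == "INS":
        extra = "".join(_BASES[i] for i in rng.integers(0, 4, size=2))
        ref, alt = ref, ref + extra
    return TruthVariant(
        patient=patient, gene=gene.symbol, chrom=gene.chrom, pos=pos,
        ref=ref, alt=alt, classification=classification, variant_type=vtype,
    )


def _sample_class(rng: np.random.Generator, *, non_silent: bool) -> str:
    classes = list(_CLASS_WEIGHTS)
    weights = np.array([_CLASS_WEIGHTS[c] for c in classes])
    if non_silent:
        keep = [c not in ("Silent", "3'UTR", "Intron") for c in classes]
        classes = [c for c, k in zip(classes, keep) if k]
        weights = weights[keep]
    weights = weights / weights.sum()
    return classes[rng.choice(len(classes), p=weights)]


def generate_cohort(design: CohortDesign) -> CohortTruth:
    """Build the full planted truth bundle for a design.

    Deterministic given ``design.seed``.  Subgroup labels are planted first
    and marker mutations made consistent with them: an ABC patient carries at
    least one ABC-unique marker mutation and no GCB-marker mutation (and
    symmetrically); U patients carry none.  Passenger mutations avoid marker
    genes so the planted labels stay exactly recoverable.
    """
    design.validate()
    chrom_table = design.chrom_table
    genes = _place_genes(design)
    by_name = {g.symbol: g for g in genes}
    patients = [f"P{i + 1:03d}" for i in range(design.n_patients)]

    root = np.random.SeedSequence(design.seed)
    ss_labels, ss_patients, ss_cn = root.spawn(3)
    label_rng = np.random.default_rng(ss_labels)
    patient_seeds = ss_patients.spawn(design.n_patients)
    cn_rng = np.random.default_rng(ss_cn)

    fracs = np.array(design.subgroup_fractions)
    labels = {
        p: ("ABC", "GCB", "U")[label_rng.choice(3, p=fracs)] for p in patients
    }

    variants: list[TruthVariant] = []
    passenger_pool = [
        g for g in genes
        if g.symbol not in design.abc_markers
        and g.symbol not in design.gcb_markers
    ]
    driver_prob = dict(design.driver_genes)

    for patient, ss in zip(patients, patient_seeds):
        rng = np.random.default_rng(ss)
        used: set[int] = set()

        for name, prob in design.driver_genes:
            if rng.random() < prob:
                cls = _sample_class(rng, non_silent=True)
                variants.append(
                    _make_variant(rng, patient, by_name[name], used, cls)
                )

        n_pass = int(rng.poisson(design.passenger_rate))
        for _ in range(n_pass):
            gene = passenger_pool[rng.integers(0, len(passenger_pool))]
            # drivers already handled above; avoid double-counting them
            if gene.symbol in driver_prob:
                continue
            cls = _sample_class(rng, non_silent=False)
            variants.append(_make_variant(rng, patient, gene, used, cls))

        lab = labels[patient]
        if lab in ("ABC", "GCB"):
            markers = design.abc_markers if lab == "ABC" else design.gcb_markers
            n_marked = 1 + int(rng.binomial(len(markers) - 1, 0.3))
            chosen = rng.choice(len(markers), size=n_marked, replace=False)
            for i in chosen:
                cls = _sample_class(rng, non_silent=True)
                variants.append(
                    _make_variant(rng, patient, by_name[markers[i]], used, cls)
                )

    cn_events: dict[str, list[CnvRegion]] = {p: [] for p in patients}
    for region in design.cnv_regions:
        for p in patients:
            if cn_rng.random() < region.penetrance:
                cn_events[p].append(region)

    return CohortTruth(
        design=design,
        chrom_table=chrom_table,
        genes=genes,
        patients=patients,
        variants=variants,
        cn_events=cn_events,
        labels=labels,
    )


# ---------------------------------------------------------------------------
# Emission


def emit_maf(truth: CohortTruth) -> list[MafRecord]:
    """The cohort's truth MAF (what perfect calling + annotation would give)."""
    return [_truth_to_maf(v) for v in truth.variants]


def emit_caller_vcfs(
    truth: CohortTruth, design: CohortDesign | None = None
) -> dict[str, dict[str, VcfDocument]]:
    """Per-patient, per-caller sites-only VCFs.

    Each truth variant appears in caller ``c``'s output with probability
    ``sensitivity_c``; on top, ``Poisson(caller_fp_mean)`` false positives
    are drawn uniformly from intergenic space (never inside a gene), so
    truth and FP calls are separable by construction.  Returns
    ``{patient: {caller: VcfDocument}}``.
    """
    design = design or truth.design
    root = np.random.SeedSequence(design.seed + 1_000_003)
    gene_spans = {
        chrom: [(g.start, g.end) for g in truth.genes if g.chrom == chrom]
        for chrom, _ in truth.chrom_table
    }
    out: dict[str, dict[str, VcfDocument]] = {}
    patient_seeds = root.spawn(len(truth.patients))
    for patient, ss in zip(truth.patients, patient_seeds):
        caller_seeds = ss.spawn(len(design.caller_sensitivity))
        per_caller: dict[str, VcfDocument] = {}
        truth_vars = truth.variants_of(patient)
        for (caller, sens), css in zip(design.caller_sensitivity, caller_seeds):
            rng = np.random.default_rng(css)
            sites = []
            for v in truth_vars:
                if rng.random() < sens:
                    sites.append(
                        VcfSite(chrom=v.chrom, pos=v.pos, ref=v.ref,
                                alt=v.alt, filter="PASS")
                    )
            n_fp = int(rng.poisson(design.caller_fp_mean))
            for _ in range(n_fp):
                sites.append(_intergenic_fp(rng, truth.chrom_table, gene_spans))
            sites.sort(
                key=lambda s: (truth.chrom_table.index(s.chrom), s.pos, s.alt)
            )
            header = ["##fileformat=VCFv4.2"] + [
                f"##contig=<ID={n},length={ln}>" for n, ln in truth.chrom_table
            ]
            per_caller[caller] = VcfDocument(header=header, sites=sites)
        out[patient] = per_caller
    return out


def _intergenic_fp(
    rng: np.random.Generator,
    chrom_table: ChromTable,
    gene_spans: Mapping[str, list[tuple[int, int]]],
) -> VcfSite:
    names = chrom_table.names
    while True:
        chrom = names[rng.integers(0, len(names))]
        pos0 = int(rng.integers(0, chrom_table.length(chrom)))
        if any(s <= pos0 < e for s, e in gene_spans[chrom]):
            continue
        ref = _BASES[rng.integers(0, 4)]
        alt = _BASES[rng.integers(0, 4)]
        while alt == ref:
            alt = _BASES[rng.integers(0, 4)]
        return VcfSite(chrom=chrom, pos=pos0 + 1, ref=ref, alt=alt, filter="PASS")


def emit_seg(truth: CohortTruth, noise_sd: float = 0.0) -> list[SegRecord]:
    """Per-sample segments tiling every chromosome.

    Each planted CNV region becomes one segment at its state's log2 level;
    the remaining genome is covered by neutral segments.  Gaussian noise of
    sd ``noise_sd`` is added to every segment mean (``0.0`` → thresholding
    recovers the planted states exactly).
    """
    rng = np.random.default_rng(
        np.random.SeedSequence(truth.design.seed + 2_000_029)
    )
    records: list[SegRecord] = []
    for patient in truth.patients:
        events = truth.cn_events[patient]
        for chrom, size in truth.chrom_table:
            cuts = sorted(
                {(r.start, r.end, r.state) for r in events if r.chrom == chrom},
                key=lambda t: t[0],
            )
            cursor = 0
            pieces: list[tuple[int, int, CNState]] = []
            for start, end, state in cuts:
                if start > cursor:
                    pieces.append((cursor, start, CNState.NEUTRAL))
                pieces.append((start, end, state))
                cursor = end
            if cursor < size:
                pieces.append((cursor, size, CNState.NEUTRAL))
            for s0, e0, state in pieces:
                lr = STATE_LOG2[state] + (
                    float(rng.normal(0.0, noise_sd)) if noise_sd > 0 else 0.0
                )
                records.append(
                    SegRecord(
                        sample_id=patient, chrom=chrom, start=s0 + 1, end=e0,
                        n_markers=max(1, (e0 - s0) // 1000), log2_ratio=lr,
                    )
                )
    return records


def truth_cn_states(truth: CohortTruth) -> dict[tuple[str, str], CNState]:
    """The planted per-(gene, patient) copy state (max-overlap semantics)."""
    out: dict[tuple[str, str], CNState] = {}
    for patient in truth.patients:
        for gene in truth.genes:
            best_ov, best_state = 0, CNState.NEUTRAL
            for r in truth.cn_events[patient]:
                if r.chrom != gene.chrom:
                    continue
                ov = min(r.end, gene.end) - max(r.start, gene.start)
                if ov > best_ov:
                    best_ov, best_state = ov, r.state
            if best_state != CNState.NEUTRAL:
                neutral_ov = (gene.end - gene.start) - best_ov
                if best_ov >= neutral_ov:
                    out[(gene.symbol, patient)] = best_state
                else:
                    pass  # neutral majority: planted state is NEUTRAL
    return out
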