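"""Gene×patient tabulation of cohort MAF and segmented copy-number data.

This is the tabulation layer feeding the circos and oncoprint layouts: it
turns per-mutation MAF rows into a gene×patient matrix of mutation-class
sets with a single "worst" consequence per cell, maps segmented log2 copy
ratios (or GISTIC integer calls) onto per-gene copy states, counts the six
pyrimidine-collapsed substitution classes per patient, and produces the
cohort summary tallies (per-class counts, per-patient burden, genecloud
weights).

Recurrence is counted in **distinct mutated patients**, not raw mutation
count — robust to hypermutated samples and identical to what an oncoprint
row displays.  Severity follows a fixed consequence ordering (inactivating
classes above missense above silent above noncoding); the table is
configurable for workflows that rank consequences differently.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import IntEnum
from typing import Iterable, Mapping, Sequence

from .errors import PreconditionError, ValidationError
from .formats_io import (
    ChromTable,
    GeneRecord,
    MafRecord,
    SegRecord,
    validate_segments,
)

# ---------------------------------------------------------------------------
# Severity

#: Consequence severity, most severe first.  Higher rank = more severe;
#: frameshifts and in-frame indels form documented tie groups.
SEVERITY_RANK: dict[str, int] = {
    "Nonsense_Mutation": 10,
    "Frame_Shift_Del": 9,
    "Frame_Shift_Ins": 9,
    "Splice_Site": 8,
    "Nonstop_Mutation": 7,
    "Translation_Start_Site": 6,
    "In_Frame_Del": 5,
    "In_Frame_Ins": 5,
    "Missense_Mutation": 4,
    "Silent": 2,
    "3'UTR": 1,
    "5'UTR": 1,
    "Intron": 1,
    "RNA": 1,
    "IGR": 1,
}

#: Classes that do not alter the protein; excluded from recurrence counting
#: unless ``include_silent`` is set.
NON_CODING_CLASSES = frozenset(
    {"Silent", "3'UTR", "5'UTR", "Intron", "RNA", "IGR"}
)


def worst_classification(
    classes: Iterable[str], severity: Mapping[str, int] = SEVERITY_RANK
) -> str:
    """Most severe classification; ties within a rank group broken by the
    canonical enum order (deterministic)."""
    order = {c: i for i, c in enumerate(severity)}
    return max(classes, key=lambda c: (severity[c], -order[c]))


# ---------------------------------------------------------------------------
# Copy-number states


class CNState(IntEnum):
    """Discrete per-gene copy-number state (GISTIC-style coding)."""

    DEEP_LOSS = -2
    LOSS = -1
    NEUTRAL = 0
    GAIN = 1
    AMP = 2


#: Default log2-ratio thresholds (t_deep, t_loss, t_gain, t_amp).
CN_THRESHOLDS = (-1.0, -0.25, 0.25, 1.0)


def log2_to_state(
    log2_ratio: float, thresholds: tuple[float, float, float, float] = CN_THRESHOLDS
) -> CNState:
    t_deep, t_loss, t_gain, t_amp = thresholds
    if not (t_deep < t_loss < 0 < t_gain < t_amp):
        raise PreconditionError(
            f"thresholds must satisfy t_deep < t_loss < 0 < t_gain < t_amp, got {thresholds}"
        )
    if log2_ratio <= t_deep:
        return CNState.DEEP_LOSS
    if log2_ratio <= t_loss:
        return CNState.LOSS
    if log2_ratio >= t_amp:
        return CNState.AMP
    if log2_ratio >= t_gain:
        return CNState.GAIN
    return CNState.NEUTRAL


# ---------------------------------------------------------------------------
# Cohort matrix


@dataclass
class SnvCell:
    """All classifications observed for one (gene, patient) pair."""

    classifications: tuple[str, ...]

    @property
    def worst(self) -> str:
        return worst_classification(self.classifications)

    @property
    def n_mutations(self) -> int:
        return len(self.classifications)


@dataclass
class CohortMatrix:
    """Gene×patient grid of mutation-class sets and copy-number states.

    ``snv_cells`` and ``cn_cells`` are sparse: absent keys mean "no mutation"
    and NEUTRAL respectively.  ``patient_count``/``mutation_count`` are the
    per-gene recurrence tallies under the matrix's ``include_silent`` policy.
    """

    genes: tuple[str, ...]
    patients: tuple[str, ...]
    snv_cells: dict[tuple[str, str], SnvCell] = field(default_factory=dict)
    cn_cells: dict[tuple[str, str], CNState] = field(default_factory=dict)
    patient_count: dict[str, int] = field(default_factory=dict)
    mutation_count: dict[str, int] = field(default_factory=dict)
    include_silent: bool = False

    def cn_state(self, gene: str, patient: str) -> CNState:
        return self.cn_cells.get((gene, patient), CNState.NEUTRAL)

    def total_cell_mutations(self) -> int:
        return sum(c.n_mutations for c in self.snv_cells.values())

    def merge_cn(self, cn: "CohortMatrix") -> "CohortMatrix":
        """Attach another matrix's copy-number side to this one.

        Genes and patients become the union (SNV-side order first); SNV
        tallies are unchanged."""
        genes = list(self.genes) + [g for g in cn.genes if g not in set(self.genes)]
        patients = list(self.patients) + [
            p for p in cn.patients if p not in set(self.patients)
        ]
        return CohortMatrix(
            genes=tuple(genes),
            patients=tuple(patients),
            snv_cells=dict(self.snv_cells),
            cn_cells=dict(cn.cn_cells),
            patient_count=dict(self.patient_count),
            mutation_count=dict(self.mutation_count),
            include_silent=self.include_silent,
        )


def build_mutation_matrix(
    records: Sequence[MafRecord],
    *,
    include_silent: bool = False,
    patients: Sequence[str] | None = None,
) -> CohortMatrix:
    """Tabulate MAF rows into a :class:`CohortMatrix` (SNV side).

    Every record lands in its cell regardless of class; ``include_silent``
    only controls whether silent/noncoding records count toward the per-gene
    recurrence tallies.  The patient universe defaults to the distinct sample
    ids observed; pass an explicit cohort roster to include mutation-free
    patients.
    """
    genes: list[str] = []
    seen_genes: set[str] = set()
    obs_patients: list[str] = []
    seen_patients: set[str] = set()
    cells: dict[tuple[str, str], list[str]] = {}
    counted: dict[str, set[str]] = {}
    mut_count: Counter[str] = Counter()

    for rec in records:
        if rec.gene_symbol not in seen_genes:
            seen_genes.add(rec.gene_symbol)
            genes.append(rec.gene_symbol)
        if rec.sample_id not in seen_patients:
            seen_patients.add(rec.sample_id)
            obs_patients.append(rec.sample_id)
        cells.setdefault((rec.gene_symbol, rec.sample_id), []).append(
            rec.variant_classification
        )
        if include_silent or rec.variant_classification not in NON_CODING_CLASSES:
            counted.setdefault(rec.gene_symbol, set()).add(rec.sample_id)
            mut_count[rec.gene_symbol] += 1

    if patients is not None:
        missing = seen_patients - set(patients)
        if missing:
            raise ValidationError(
                f"records for sample(s) outside the roster: {sorted(missing)}"
            )
        universe = tuple(patients)
    else:
        universe = tuple(obs_patients)

    return CohortMatrix(
        genes=tuple(genes),
        patients=universe,
        snv_cells={k: SnvCell(tuple(v)) for k, v in cells.items()},
        patient_count={g: len(s) for g, s in counted.items()},
        mutation_count=dict(mut_count),
        include_silent=include_silent,
    )


def gene_copy_states(
    segs: Sequence[SegRecord],
    genes: Sequence[GeneRecord],
    thresholds: tuple[float, float, float, float] = CN_THRESHOLDS,
    *,
    patients: Sequence[str] | None = None,
) -> CohortMatrix:
    """Assign one :class:`CNState` per (gene, patient) from segment data.

    The gene takes the log2 ratio of the single segment with the largest
    overlap against the gene body; ties go to the segment whose thresholded
    state is more extreme (then larger \\|log2\\|, then leftmost start).
    Genes with no overlapping segment are NEUTRAL.  Overlapping same-sample
    segments are a validation error.
    """
    log2_to_state(0.0, thresholds)  # validates threshold ordering
    validate_segments(segs)
    if patients is None:
        roster: list[str] = []
        seen: set[str] = set()
        for s in segs:
            if s.sample_id not in seen:
                seen.add(s.sample_id)
                roster.append(s.sample_id)
        patients = roster

    by_sample_chrom: dict[tuple[str, str], list[SegRecord]] = {}
    for s in segs:
        by_sample_chrom.setdefault((s.sample_id, s.chrom), []).append(s)

    cn_cells: dict[tuple[str, str], CNState] = {}
    for patient in patients:
        for gene in genes:
            candidates = by_sample_chrom.get((patient, gene.chrom), ())
            best: tuple[int, int, float, int] | None = None
            best_lr: float | None = None
            for seg in candidates:
                s0, e0 = seg.interval()
                ov = min(e0, gene.end) - max(s0, gene.start)
                if ov <= 0:
                    continue
                state = log2_to_state(seg.log2_ratio, thresholds)
                rank = (ov, abs(int(state)), abs(seg.log2_ratio), -seg.start)
                if best is None or rank > best:
                    best = rank
                    best_lr = seg.log2_ratio
            if best_lr is not None:
                state = log2_to_state(best_lr, thresholds)
                if state != CNState.NEUTRAL:
                    cn_cells[(gene.symbol, patient)] = state

    return CohortMatrix(
        genes=tuple(g.symbol for g in genes),
        patients=tuple(patients),
        cn_cells=cn_cells,
    )


def accept_gistic_states(
    table: Mapping[str, Mapping[str, int]]
) -> CohortMatrix:
    """Adopt externally computed integer gene states (−2..2) directly.

    ``table`` maps gene → patient → integer call; out-of-range values are
    rejected."""
    genes = tuple(table.keys())
    patients: list[str] = []
    seen: set[str] = set()
    cn_cells: dict[tuple[str, str], CNState] = {}
    for gene, row in table.items():
        for patient, call in row.items():
            if patient not in seen:
                seen.add(patient)
                patients.append(patient)
            if not -2 <= call <= 2:
                raise ValidationError(
                    f"gene {gene} patient {patient}: call {call} outside [-2, 2]"
                )
            if call != 0:
                cn_cells[(gene, patient)] = CNState(call)
    return CohortMatrix(genes=genes, patients=tuple(patients), cn_cells=cn_cells)


def apply_gene_filters(
    matrix: CohortMatrix,
    min_patients: int,
    blacklist: set[str] = frozenset(),
    *,
    gene_table: Sequence[GeneRecord] | None = None,
    chrom_order: ChromTable | None = None,
) -> list[str]:
    """Retain genes mutated in ≥ ``min_patients`` patients and not blacklisted.

    Retained genes are ordered genomically — by chromosome (canonical table
    order when ``chrom_order`` is given) then start — when ``gene_table``
    supplies coordinates; genes without coordinates sort last, alphabetically.
    """
    if min_patients < 1:
        raise PreconditionError("min_patients must be ≥ 1")
    kept = [
        g
        for g in matrix.genes
        if matrix.patient_count.get(g, 0) >= min_patients and g not in blacklist
    ]
    coords = {g.symbol: g for g in gene_table} if gene_table else {}

    # Chromosomes in the canonical table precede unknown ones; the index is
    # zero-padded so the composite key stays string-comparable.
    def safe_key(sym: str):
        g = coords.get(sym)
        if g is None:
            return (2, "", 0, sym)
        if chrom_order is not None and g.chrom in chrom_order.names:
            return (0, f"{chrom_order.index(g.chrom):09d}", g.start, sym)
        return (1, g.chrom, g.start, sym)

    kept.sort(key=safe_key)
    return kept


# ---------------------------------------------------------------------------
# Mutation spectrum

SPECTRUM_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class SpectrumCounts:
    """Per-patient counts over the six pyrimidine-collapsed SNV classes."""

    counts: dict[str, Counter]
    n_skipped: int = 0

    def patient(self, sample_id: str) -> dict[str, int]:
        c = self.counts.get(sample_id, Counter())
        return {cls: c.get(cls, 0) for cls in SPECTRUM_CLASSES}


def mutation_spectrum(records: Sequence[MafRecord]) -> SpectrumCounts:
    """Count each SNP into one of C>A, C>G, C>T, T>A, T>C, T>G per patient.

    Purine-reference substitutions are complemented onto the pyrimidine
    strand (G>A ≡ C>T).  Non-SNP records are ignored; SNPs with non-ACGT
    alleles are skipped and tallied in ``n_skipped``.
    """
    counts: dict[str, Counter] = {}
    skipped = 0
    for rec in records:
        if rec.variant_type != "SNP":
            continue
        ref, alt = rec.ref_allele.upper(), rec.alt_allele.upper()
        if ref not in _COMPLEMENT or alt not in _COMPLEMENT:
            skipped += 1
            continue
        if ref in ("G", "A"):
            ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
        counts.setdefault(rec.sample_id, Counter())[f"{ref}>{alt}"] += 1
    return SpectrumCounts(counts=counts, n_skipped=skipped)


# ---------------------------------------------------------------------------
# Cohort summary


@dataclass
class CohortSummary:
    """Exact tallies over a cohort MAF."""

    classification_counts: dict[str, int]
    variant_type_counts: dict[str, int]
    burden: dict[str, int]  # total records per patient
    top_genes: list[tuple[str, int]]  # (gene, mutated-patient count)
    genecloud_weights: dict[str, int]  # genes meeting the threshold


def summarize_cohort(
    records: Sequence[MafRecord],
    *,
    top_n: int = 10,
    genecloud_min_patients: int = 2,
) -> CohortSummary:
    """Descriptive cohort tallies: per-class and per-type counts, per-patient
    mutation burden, the ``top_n`` most recurrently mutated genes, and
    word-cloud weights (mutated-patient counts) for genes meeting the
    threshold."""
    cls_counts: Counter[str] = Counter()
    type_counts: Counter[str] = Counter()
    burden: Counter[str] = Counter()
    gene_patients: dict[str, set[str]] = {}
    for rec in records:
        cls_counts[rec.variant_classification] += 1
        type_counts[rec.variant_type] += 1
        burden[rec.sample_id] += 1
        if rec.variant_classification not in NON_CODING_CLASSES:
            gene_patients.setdefault(rec.gene_symbol, set()).add(rec.sample_id)
    recurrence = {g: len(p) for g, p in gene_patients.items()}
    top = sorted(recurrence.items(), key=lambda kv: (-kv[1], kv[0]))[:top_n]
    weights = {
        g: n for g, n in sorted(recurrence.items()) if n >= genecloud_min_patients
    }
    return CohortSummary(
        classification_counts=dict(cls_counts),
        variant_type_counts=dict(type_counts),
        burden=dict(burden),
        top_genes=top,
        genecloud_weights=weights,
    )
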