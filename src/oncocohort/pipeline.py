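"""End-to-end composition: per-patient consensus → cohort tables → layouts.

These helpers chain the module-level operations exactly the way the
module CLIs do, so the full scatter → vote → tabulate → layout path can be
exercised (and measured against planted truth) in one call.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .formats_io import ChromTable, MafRecord, VcfDocument
from .consensus import (
    ConsensusVariant,
    VariantKey,
    caller_result_from_sites,
    vote,
)
from .aggregate import (
    CohortMatrix,
    apply_gene_filters,
    build_mutation_matrix,
    gene_copy_states,
    summarize_cohort,
)
from .oncoprint import build_oncoprint, classify_subgroups, OncoprintTable
from .circos import CircosBundle, build_bundle
from .simulate import CohortTruth, emit_seg


def consensus_cohort(
    per_patient_vcfs: dict[str, dict[str, VcfDocument]],
    k: int,
    chrom_order: ChromTable,
    *,
    pass_only: bool = True,
) -> dict[str, list[ConsensusVariant]]:
    """Run k-of-n voting independently for every patient."""
    out = {}
    for patient, per_caller in per_patient_vcfs.items():
        results = [
            caller_result_from_sites(name, doc.sites, pass_only=pass_only)
            for name, doc in per_caller.items()
        ]
        out[patient] = vote(results, k, chrom_order=chrom_order)
    return out


def recovered_keys(
    consensus: dict[str, list[ConsensusVariant]]
) -> dict[str, set[VariantKey]]:
    return {p: {c.key for c in cons} for p, cons in consensus.items()}


@dataclass
class PipelineResult:
    """Everything the desk-scale pipeline produces from a synthetic cohort."""

    consensus: dict[str, list[ConsensusVariant]]
    maf: list[MafRecord]
    matrix: CohortMatrix
    retained_genes: list[str]
    subgroup_labels: dict[str, str]
    oncoprint: OncoprintTable
    circos: CircosBundle
    summary: object = field(default=None)


def run_pipeline(
    truth: CohortTruth,
    per_patient_vcfs: dict[str, dict[str, VcfDocument]],
    *,
    k: int = 2,
    min_patients: int = 5,
    blacklist: set[str] = frozenset(),
    seg_noise_sd: float = 0.0,
) -> PipelineResult:
    """Consensus-call, annotate via the truth index, tabulate, and lay out.

    Mirrors the real workflow: vote per patient, turn the surviving calls
    into an annotated cohort MAF (the truth bundle stands in for the
    annotation step), tabulate SNVs and copy number, filter genes, classify
    subgroups, and build both visual layouts.
    """
    chrom_order = truth.chrom_table
    cons = consensus_cohort(per_patient_vcfs, k, chrom_order)

    maf: list[MafRecord] = []
    for patient in truth.patients:
        keys = [c.key for c in cons.get(patient, [])]
        maf.extend(truth.annotate(patient, keys))

    matrix = build_mutation_matrix(maf, patients=truth.patients)
    segs = emit_seg(truth, noise_sd=seg_noise_sd)
    cn = gene_copy_states(segs, truth.genes, patients=truth.patients)
    full = matrix.merge_cn(cn)

    retained = apply_gene_filters(
        matrix,
        min_patients,
        blacklist,
        gene_table=truth.genes,
        chrom_order=chrom_order,
    )
    labels = classify_subgroups(
        matrix,
        set(truth.design.abc_markers),
        set(truth.design.gcb_markers),
    )
    summary = summarize_cohort(maf)
    oncop = build_oncoprint(
        full,
        burden=summary.burden,
        subgroups=labels,
        gene_subset=retained,
    )
    retained_records = [g for g in truth.genes if g.symbol in set(retained)]
    circos = build_bundle(
        matrix, cn, retained_records, chrom_order, min_patients
    )
    return PipelineResult(
        consensus=cons,
        maf=maf,
        matrix=matrix,
        retained_genes=retained,
        subgroup_labels=labels,
        oncoprint=oncop,
        circos=circos,
        summary=summary,
    )
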