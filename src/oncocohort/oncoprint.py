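"""Oncoprint construction: gene and sample ordering, covariates, subgroups.

An oncoprint is a gene×patient matrix in which each cell shows a patient's
worst mutation consequence in a gene, optionally combined with the gene's
copy-number state, with covariate tracks along the axes (per-patient
mutation burden and molecular subgroup; per-gene recurrence and externally
supplied significance values).

Sample ordering defaults to the classic mutual-exclusivity ("memo") sort:
patients are compared as binary mutation vectors over the gene ordering and
sorted lexicographically descending, which visually staircases mutually
exclusive events.  Ordering by molecular subgroup groups patients into
ABC / GCB / U blocks (memo-sorted within each block).

Subgroup classification follows a marker-vote rule: genes mutated
significantly more often in one subgroup serve as markers; a patient is
labelled by whichever marker set they carry more mutated genes from, and is
unclassifiable (U) on a tie — including the zero-evidence case.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .errors import PreconditionError, ValidationError
from .aggregate import (
    CNState,
    CohortMatrix,
    NON_CODING_CLASSES,
)

SUBGROUPS = ("ABC", "GCB", "U")


def classify_subgroups(
    matrix: CohortMatrix,
    abc_markers: set[str],
    gcb_markers: set[str],
    *,
    include_silent: bool = False,
) -> dict[str, str]:
    """Assign each patient an ABC / GCB / U label from marker-gene mutations.

    Genes present in both marker lists are not informative ("unique to
    either") and are dropped with a warning.  For each patient, ``a`` = the
    number of mutated ABC-unique markers and ``g`` = mutated GCB-unique
    markers; the label is ABC if ``a > g``, GCB if ``g > a``, else U.
    Silent/noncoding mutations do not count as marker evidence unless
    ``include_silent`` is set.
    """
    if not abc_markers or not gcb_markers:
        raise PreconditionError("both marker sets must be non-empty")
    shared = abc_markers & gcb_markers
    if shared:
        warnings.warn(
            f"marker gene(s) shared by both subgroups dropped: {sorted(shared)}",
            stacklevel=2,
        )
    abc = abc_markers - shared
    gcb = gcb_markers - shared
    if not abc or not gcb:
        raise PreconditionError("marker sets empty after removing shared genes")

    mutated: dict[str, set[str]] = {p: set() for p in matrix.patients}
    for (gene, patient), cell in matrix.snv_cells.items():
        counts = [
            c
            for c in cell.classifications
            if include_silent or c not in NON_CODING_CLASSES
        ]
        if counts:
            mutated.setdefault(patient, set()).add(gene)

    labels = {}
    for p in matrix.patients:
        a = len(mutated.get(p, set()) & abc)
        g = len(mutated.get(p, set()) & gcb)
        labels[p] = "ABC" if a > g else ("GCB" if g > a else "U")
    return labels


def order_genes(matrix: CohortMatrix) -> list[str]:
    """Genes by descending mutated-patient count, ties alphabetical."""
    return sorted(
        matrix.genes, key=lambda g: (-matrix.patient_count.get(g, 0), g)
    )


def _mutation_vector(
    matrix: CohortMatrix, patient: str, gene_order: Sequence[str]
) -> tuple[int, ...]:
    return tuple(
        1 if (g, patient) in matrix.snv_cells else 0 for g in gene_order
    )


def order_samples(
    matrix: CohortMatrix,
    method: str = "memo",
    *,
    gene_order: Sequence[str] | None = None,
    subgroups: Mapping[str, str] | None = None,
    given: Sequence[str] | None = None,
) -> list[str]:
    """Order patients for display.

    ``"memo"`` — lexicographic descending on the binary mutation vector over
    ``gene_order`` (default: :func:`order_genes`); ``"subgroup"`` — ABC, GCB
    then U blocks (labels from ``subgroups``), memo-sorted within each block;
    ``"given"`` — adopt ``given`` after checking it is a permutation of the
    patient set.
    """
    if method not in ("memo", "subgroup", "given"):
        raise PreconditionError(f"unknown ordering method {method!r}")
    if method == "given":
        if given is None or sorted(given) != sorted(matrix.patients):
            raise ValidationError(
                "given order is not a permutation of the patient set"
            )
        return list(given)
    if gene_order is None:
        gene_order = order_genes(matrix)
    vectors = {
        p: _mutation_vector(matrix, p, gene_order) for p in matrix.patients
    }
    # Stable sort: ties keep roster order.
    memo = sorted(matrix.patients, key=lambda p: tuple(-b for b in vectors[p]))
    if method == "memo":
        return memo
    if subgroups is None:
        raise PreconditionError("subgroup ordering requires subgroup labels")
    rank = {s: i for i, s in enumerate(SUBGROUPS)}
    return sorted(memo, key=lambda p: rank[subgroups[p]])


@dataclass
class OncoprintTable:
    """Fully ordered oncoprint with covariates, ready to emit."""

    genes: list[str]
    patients: list[str]
    matrix: CohortMatrix
    burden: dict[str, int] = field(default_factory=dict)
    subgroups: dict[str, str] = field(default_factory=dict)
    significance: dict[str, float] = field(default_factory=dict)

    def cell(self, gene: str, patient: str) -> str:
        """``"<classification>|<CNState>"``; ``"."`` for an empty cell."""
        snv = self.matrix.snv_cells.get((gene, patient))
        cn = self.matrix.cn_state(gene, patient)
        cls = snv.worst if snv is not None else ""
        cn_s = cn.name if cn != CNState.NEUTRAL else ""
        if not cls and not cn_s:
            return "."
        return f"{cls}|{cn_s}" if cn_s else cls


def build_oncoprint(
    matrix: CohortMatrix,
    *,
    burden: Mapping[str, int] | None = None,
    subgroups: Mapping[str, str] | None = None,
    significance: Mapping[str, float] | None = None,
    sample_method: str | None = None,
    given_order: Sequence[str] | None = None,
    gene_subset: Sequence[str] | None = None,
) -> OncoprintTable:
    """Assemble an ordered :class:`OncoprintTable` from a cohort matrix.

    ``sample_method`` defaults to ``"subgroup"`` when labels are supplied,
    else ``"memo"``.  ``gene_subset`` restricts and pre-filters the rows
    (e.g. the output of ``apply_gene_filters``); rows are then frequency-
    sorted.
    """
    genes = order_genes(matrix)
    if gene_subset is not None:
        keep = set(gene_subset)
        genes = [g for g in genes if g in keep]
    if sample_method is None:
        sample_method = "subgroup" if subgroups else "memo"
    patients = order_samples(
        matrix,
        sample_method,
        gene_order=genes,
        subgroups=subgroups,
        given=given_order,
    )
    return OncoprintTable(
        genes=genes,
        patients=patients,
        matrix=matrix,
        burden=dict(burden or {}),
        subgroups=dict(subgroups or {}),
        significance=dict(significance or {}),
    )


def emit_oncoprint(table: OncoprintTable, out_dir: str) -> list[str]:
    """Write the oncoprint as a deterministic TSV bundle.

    ``matrix.tsv`` (genes × patients, cells ``class|CNstate`` or ``.``),
    ``patient_covariates.tsv`` (burden, subgroup), ``gene_covariates.tsv``
    (recurrence, significance).  Returns the written file names.
    """
    os.makedirs(out_dir, exist_ok=True)
    written = []

    lines = ["gene\t" + "\t".join(table.patients)]
    for g in table.genes:
        lines.append(
            g + "\t" + "\t".join(table.cell(g, p) for p in table.patients)
        )
    _write(out_dir, "matrix.tsv", "\n".join(lines) + "\n", written)

    cov = ["sample\tburden\tsubgroup"]
    for p in table.patients:
        cov.append(
            f"{p}\t{table.burden.get(p, 0)}\t{table.subgroups.get(p, 'U')}"
        )
    _write(out_dir, "patient_covariates.tsv", "\n".join(cov) + "\n", written)

    gcov = ["gene\tpatient_count\tsignificance"]
    for g in table.genes:
        sig = table.significance.get(g)
        sig_s = f"{sig:.6g}" if sig is not None else "NA"
        gcov.append(f"{g}\t{table.matrix.patient_count.get(g, 0)}\t{sig_s}")
    _write(out_dir, "gene_covariates.tsv", "\n".join(gcov) + "\n", written)
    return written


def _write(out_dir: str, name: str, text: str, written: list[str]) -> None:
    with open(os.path.join(out_dir, name), "w") as fh:
        fh.write(text)
    written.append(name)


def read_significance(stream) -> dict[str, float]:
    """Two-column TSV ``gene<TAB>value`` of externally computed per-gene
    significance (e.g. driver-discovery Q-values); consumed, never computed."""
    text = stream if isinstance(stream, str) else stream.read()
    out = {}
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValidationError(f"significance line needs 2 columns: {line!r}")
        try:
            out[parts[0]] = float(parts[1])
        except ValueError:
            # tolerate a header row
            if parts[1].replace(".", "").isalpha():
                continue
            raise
    return out
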