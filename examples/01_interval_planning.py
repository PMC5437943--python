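"""Group chromosomes into capacity-bounded scatter intervals.

A whole-genome variant caller parallelized per chromosome is bounded below
by its longest chromosome, so smaller chromosomes can share a job as long
as their combined length stays under that bound.
"""

from oncocohort import ChromTable, plan_intervals, write_plan_beds

# Approximate human chromosome lengths (GRCh38, Mbp-rounded)
hg = ChromTable(tuple(
    (f"chr{name}", length * 1_000_000)
    for name, length in [
        (1, 249), (2, 242), (3, 198), (4, 190), (5, 182), (6, 171),
        (7, 159), (8, 145), (9, 138), (10, 134), (11, 135), (12, 133),
        (13, 114), (14, 107), (15, 102), (16, 90), (17, 83), (18, 80),
        (19, 59), (20, 64), (21, 47), (22, 51), ("X", 156), ("Y", 57),
    ]
))

plan = plan_intervals(hg, mode="grouped")
print(f"capacity (longest chromosome): {plan.capacity:,} bp")
print(f"{len(hg)} chromosomes packed into {len(plan.groups)} scatter jobs:")
for group, total in zip(plan.groups, plan.group_sums()):
    names = "+".join(c for c, _, _ in group)
    print(f"  {names:<22} {total:>12,} bp ({100 * total / plan.capacity:.0f}% of capacity)")

beds = write_plan_beds(plan)
print(f"\nfirst BED document:\n{beds[0]}", end="")
print("Each job's total never exceeds the longest chromosome, so the")
print("slowest scatter job is no slower than chr1 alone — with fewer jobs.")
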