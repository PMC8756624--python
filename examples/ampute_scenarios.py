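"""Create the 18 canonical missing-data scenarios and inspect allocations.

Missingness is confined to the hemorrhage-volume variable.  MCAR draws
masked cells blind to any variable; the MAR mechanisms hold the
failure:success missing-proportion ratio at 2:1 or 1:2 while preserving
the overall missing proportion exactly.
"""

from imputebench import (OUTCOME, allocate_missing_counts, ampute,
                         enumerate_scenarios, generate_cohort,
                         table2_profile)

scenarios = enumerate_scenarios(seed_base=1)
print(f"{len(scenarios)} scenarios (3 mechanisms x 6 proportions), e.g.:")
for s in scenarios[:3] + scenarios[-3:]:
    print(f"  {s.mechanism:8s} p={s.proportion:.2f} seed={s.seed}")

alloc = allocate_missing_counts(261, 1207, 0.30, "MAR_2_1")
print(f"\nMAR 2:1 at p=0.30: total {alloc.total} masked cells, "
      f"{alloc.m_failure} in the failure group, "
      f"{alloc.m_success} in the success group")
ratio = (alloc.m_failure / 261) / (alloc.m_success / 1207)
print(f"realised failure:success missing-proportion ratio = {ratio:.3f}")

cohort = generate_cohort(table2_profile(), mode="exact", seed=1)
for scenario in scenarios[:6]:
    inc = ampute(cohort, scenario)
    out = inc.records[OUTCOME].to_numpy()
    print(f"{scenario.label:16s} masked {int(inc.mask.sum()):4d} cells "
          f"({inc.mask[out == 1].sum()} failure / "
          f"{inc.mask[out == 0].sum()} success)")
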