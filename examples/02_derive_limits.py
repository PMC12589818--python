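"""Derive TG-218-style action and tolerance limits per disease site.

The action limit AL = 100 - dA/2 with dA = beta*sqrt(sd^2 + (mean-100)^2)
marks the lower bound of acceptable passing rates; the tolerance limit is
the individuals-chart lower control limit and warns earlier, when the
process merely leaves its historical behaviour.
"""

from psqakit import filter_records, generate_cohort, limits_by_stratum, showa2016_specs

records, _ = generate_cohort(showa2016_specs(), seed=1)
# per-site limits within one facility's own process history
reference = filter_records(records, facility="UniversityHospital")
limits = limits_by_stratum(reference, grouping="site", channel="3/3", beta=6)

print(f"{'site':28s} {'n':>4s} {'mean':>7s} {'sd':>6s} {'AL':>7s} {'TL':>7s}  flags")
for key, ls in limits.items():
    print(
        f"{key:28s} {ls.n_used:4d} {ls.mean:7.2f} {ls.sd:6.2f} "
        f"{ls.al:7.2f} {ls.tl:7.2f}  {';'.join(ls.flags)}"
    )
# Tight sites (CNS) earn action limits near 99%; wide sites (Pelvis) near
# 93-94%: each site is judged against its own achievable performance rather
# than a universal fixed threshold.
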