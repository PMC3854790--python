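"""Study-level summaries: mean ± s.d., Student's t test, count percentages.

Reproduces the statistics used to compare genotypes: group summaries with
95% confidence half-widths (1.96 x s.e.m.), a pooled-variance two-sample
t test, and the percentages derived from mating and in-vitro fertilization
counts.
"""

from spermbeat import (CountPair, group_summary, percent, pooled_rate,
                       students_t)

# VSL-like measurements (µm/s) for two groups of animals
wildtype = [60.1, 71.3, 69.6]
mutant = [29.8, 41.2, 34.0]
for name, values in [("wild-type", wildtype), ("mutant", mutant)]:
    s = group_summary(values)
    print(f"{name:>9}: mean {s.mean:5.1f} ± {s.sd:.1f} (s.d.), "
          f"95% CI ± {s.ci95_halfwidth:.1f}, n={s.n}")
r = students_t(wildtype, mutant)
print(f"Student's t test: t = {r.t:.2f}, df = {r.df:.0f}, p = {r.p:.4f}")
print()

# pregnancy rates per male genotype (pregnant females / matings)
for label, pair, dec in [("+/+", CountPair(26, 26), 0),
                         ("+/-", CountPair(14, 15), 1),
                         ("-/-", CountPair(13, 22), 1)]:
    print(f"pregnant females, {label} males: "
          f"{percent(pair, dec)}% ({pair.successes}/{pair.total})")

# in-vitro fertilization: 2-cell embryos / oocytes, pooled across sessions
print(f"IVF 2-cell rate, +/+ sperm: "
      f"{pooled_rate([CountPair(312, 655)], 0):.0f}%")
print(f"IVF 2-cell rate, -/- sperm: "
      f"{pooled_rate([CountPair(481, 793)], 0):.0f}%")
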