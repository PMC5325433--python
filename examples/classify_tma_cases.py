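"""Score a synthetic TMA and partition cases into the three marker subgroups.

Generates duplicate 0-10 cores per marker and site for 106 cases, sums them
to 0-20 IHC scores, bands CDH17/CLDN18 (++/+/-) and applies the joint-band
rules: Group 1 = CDH17(++)/CLDN18(+/-), Group 2 = CDH17(++)/CLDN18(++) or
CDH17(+)/CLDN18(+), Group 3 = CDH17(-)/any CLDN18.
"""

from gcmarkers import (
    TMAFixtureConfig,
    aggregate_core_table,
    classify_cases,
    generate_tma_fixture,
)

fx = generate_tma_fixture(TMAFixtureConfig(n_cases=106, seed=1))
ihc = aggregate_core_table(fx.cores)
groups = classify_cases(ihc)

sizes = groups["group"].value_counts().sort_index()
print("group sizes over 106 cases:")
for g, n in sizes.items():
    print(f"  {g:<13} {n}")

recovered = (
    groups.set_index("case_id")["group"].loc[fx.latent_groups.index]
    == fx.latent_groups
).mean()
print(f"\nlatent-group recovery: {recovered:.0%}")
print("(duplicate-core noise stays inside each group's score box, so the")
print(" band classifier reproduces the generating labels exactly)")

example = groups.iloc[0]
print(
    f"\nexample case {example['case_id']}: CDH17={example['cdh17']} "
    f"({example['cdh17_band']}), CLDN18={example['cldn18']} "
    f"({example['cldn18_band']}) -> {example['group']}"
)
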