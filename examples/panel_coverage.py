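"""Quantify how complementary markers jointly cover cases ("coupling").

From a synthetic TMA, primary-lesion IHC scores are binarized by band
(positive = band above negative) and the CDH17+CLDN18 panel's union coverage
and positivity patterns are counted; a greedy set-cover then ranks markers
by incremental coverage.
"""

from gcmarkers import (
    TMAFixtureConfig,
    aggregate_core_table,
    best_panel_greedy,
    calls_from_scores,
    coverage,
    generate_tma_fixture,
)
from gcmarkers.ihc import DEFAULT_BANDS

fx = generate_tma_fixture(TMAFixtureConfig(n_cases=106, seed=1))
ihc = aggregate_core_table(fx.cores)
scores = (
    ihc[ihc["site"] == "Pr"]
    .pivot(index="case_id", columns="marker", values="value")
    .astype("Float64")
)
calls = calls_from_scores(scores, DEFAULT_BANDS)

res = coverage(calls, ["CDH17", "CLDN18"])
print(
    f"CDH17 + CLDN18 covers {res.covered}/{res.total} cases "
    f"({res.percent()}%) — a case counts when either marker is non-negative"
)
print("\njoint positivity patterns (CDH17, CLDN18): count")
for pat, n in sorted(res.pattern_counts.items(), reverse=True):
    label = "/".join("+" if p else "-" for p in pat)
    print(f"  {label:<5} {n}")

panel, trace = best_panel_greedy(calls, max_size=3)
print("\ngreedy marker ranking (marker: newly covered -> cumulative):")
for _, row in trace.iterrows():
    print(
        f"  {row['marker']}: +{row['newly_covered']} -> "
        f"{row['cumulative_covered']}/{row['total']}"
    )
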