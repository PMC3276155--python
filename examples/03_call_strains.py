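"""Call depleted/enriched strains and compare the any-day vs sequential rules.

A strain is called when |standardized log2 value| >= 1 (a 2-fold change)
on at least 3 of the 6 sampled days -- any 3 days, or, in the stringent
variant, 3 consecutive sampled days.
"""

import poolfit as pf
from poolfit import benchmarks

truth, matrix, _ = benchmarks.run_reference_screen(seed=1, n_strains=800)
key = benchmarks._key_from_truth(truth)

any_calls = pf.classify_matrix(matrix, mode="any")
seq_calls = pf.classify_matrix(matrix, mode="sequential")

for name, calls in (("any 3 days", any_calls), ("3 sequential days", seq_calls)):
    dep = (calls["direction"] == "depleted").sum()
    enr = (calls["direction"] == "enriched").sum()
    print(f"{name:>18}: {dep} depleted, {enr} enriched of {len(calls)} strains")
# The sequential rule is strictly more stringent: every sequential call is
# also an any-day call.

any_calls.insert(1, "gene", key.set_index("strain_id")["gene"].reindex(any_calls["strain_id"]).to_numpy())
seq_calls.insert(1, "gene", key.set_index("strain_id")["gene"].reindex(seq_calls["strain_id"]).to_numpy())
shared = pf.overlap_calls(any_calls, seq_calls, "depleted")
print(f"\ndepleted under both rules: {len(shared)} genes")

print("\ncall summary by annotation class (any-day rule):")
print(pf.summarize_calls(any_calls, key).to_string(index=False))

t = truth.set_index("strain_id")
planted = set(t.index[(t["in_pool"]) & (t["fitness"] < 0)])
called = set(any_calls.loc[any_calls["direction"] == "depleted", "strain_id"])
tp = len(called & planted)
print(
    f"\nrecovery of the {len(planted)} planted depleted strains: "
    f"sensitivity {tp / len(planted):.2f}, precision {tp / len(called):.2f}"
)
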