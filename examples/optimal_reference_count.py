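"""How many reference genes does the normalization factor need?

Computes geNorm's pairwise variation V_n/n+1 between normalization factors
built from the top-n and top-(n+1) ranked genes.  V below 0.15 means the
(n+1)-th gene changes the normalization factor so little that including it
is unnecessary.
"""

from refstab import (
    genorm_ranking,
    optimal_reference_count,
    relative_quantities,
    simulate_ct,
    soybean_preset,
)

table, _ = simulate_ct(soybean_preset(seed=1))
q = relative_quantities(table)
ranking = genorm_ranking(q)
series = optimal_reference_count(q, ranking, cutoff=0.15)

print("geNorm ranking (most -> least stable):", " > ".join(ranking.ranking))
for n, v in series.v.items():
    marker = " <-- below 0.15 cutoff" if v < series.cutoff else ""
    print(f"V_{n}/{n + 1} = {v:.4f}{marker}")
print(f"\nOptimal number of reference genes: {series.optimal_n}")
# V_2/3 < 0.15 says the two most stable genes already give a reliable
# normalization factor; a third reference gene adds nothing.
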