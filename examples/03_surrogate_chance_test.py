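"""Is the observed coordination more than chance?

Simulates a handful of coupled dyads, builds shuffled pseudosynchrony
surrogates for each (bin-level permutation preserving every partner's
total speech seconds), and runs the paired t-test of real vs surrogate
lag-zero coordination across dyads.
"""

from dataclasses import replace

from speechcoord import DyadSimConfig, compare_to_chance, simulate_dyad, surrogate_distribution

results = []
for i in range(10):
    d = simulate_dyad(replace(DyadSimConfig(), seed=100 + i), dyad_id=f"d{i}")
    res = surrogate_distribution(d, n_surrogates=100, seed=i, measures=("rr_los",))
    results.append(res["rr_los"])
    if i < 3:
        r = res["rr_los"]
        print(f"dyad {i}: real RR_LOS = {r.real_value:.3f}, "
              f"surrogate mean = {r.surrogate_mean:.3f}")

c = compare_to_chance(results)
print(f"\npaired t-test across {c.n_dyads} dyads: t = {c.t_statistic:.2f}, p = {c.p_value:.2g}")
print(f"95% CI of the real RR_LOS mean: [{c.ci_low:.3f}, {c.ci_high:.3f}]")
print("A large positive t: lag-zero turn-taking coordination exceeds what the")
print("same speech budgets would produce by chance alignment.")
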