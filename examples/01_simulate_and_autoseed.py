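"""Simulate a SELEX experiment and discover its seed with Autoseed.

A binding model (consensus GGCGTG, 85% per-base match probability) is
planted into a 20 bp randomized library and enriched over 3 selection
cycles; gapped-pattern counting plus local-maxima search then recovers the
seed without being told what was planted.
"""

from selexmotif import (
    AutoseedConfig,
    GroundTruthModel,
    PatternBounds,
    SiteModel,
    count_patterns,
    find_local_maxima,
    pick_primary_and_secondary,
    pwm_from_consensus,
    simulate_experiment,
)

site = SiteModel(pwm_from_consensus("GGCGTG", 0.85), name="planted")
model = GroundTruthModel(components=[(1.0, site)], selection_strength=5.0,
                         cycles=3, reads_per_cycle=20_000, rng_seed=7)
cycles = simulate_experiment(model)
print(f"simulated {model.cycles} cycles of {model.reads_per_cycle} reads")

bounds = PatternBounds(min_defined=4, max_defined=7, max_gap=2)
table = count_patterns(cycles[-1].reads, bounds=bounds)
print(f"counted {len(table.counts)} gapped patterns in cycle {cycles[-1].cycle}")

maxima = find_local_maxima(table, AutoseedConfig(bounds=bounds, top=3))
for m in pick_primary_and_secondary(maxima):
    print(f"rank {m.rank}: {m.pattern.symbols}  count={m.count}  "
          f"role={m.role}  relation={m.relation_to_primary}")

# The rank-1 pattern is the strand-canonical form of the planted GGCGTG
# (CACGCC is its reverse complement); its count is the number of reads
# carrying the site on either strand.
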