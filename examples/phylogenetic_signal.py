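"""Phylogenetic-signal test for a binary infectivity trait.

Two synthetic datasets on 32-tip Yule trees:
(1) a strongly clade-structured trait (one state change on a long basal
    branch) — the jump-count HPD should sit far below every randomized null;
(2) the same trait permuted over the tips — the HPDs should overlap.
"""

import numpy as np

import halorange as hr
from halorange.trait_signal import randomize_traits

rng = np.random.default_rng(11)

tree, traits = hr.simulate_clade_structured_dataset(32, rng=rng)
for name, trait_vector in [
    ("clade-structured", traits),
    ("tip-permuted", randomize_traits(traits, rng)),
]:
    result = hr.signal_test(tree, trait_vector, n_map_samples=500, n_null=10, rng=rng)
    null_lo = min(h.lower for h in result.null_hpds)
    null_hi = max(h.upper for h in result.null_hpds)
    print(f"{name}:")
    print(f"  real Markov-jump 95% HPD : [{result.real_hpd.lower:.0f}, "
          f"{result.real_hpd.upper:.0f}]")
    print(f"  null HPDs span           : [{null_lo:.0f}, {null_hi:.0f}] "
          f"over {len(result.null_hpds)} randomized runs")
    print(f"  overlap with any null    : {any(result.overlap_flags)}")
    print(f"  decision                 : {result.decision}")
# "signal" = the real history needs far fewer state changes than any
# tip-randomized replicate, i.e. infectivity clusters on the tree.
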