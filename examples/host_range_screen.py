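"""Host-range matrix of the LR2-5 screen: counts, titers, and EOP.

Loads the packaged screening table (25 virus isolates titered on their own
isolation hosts and on Haloferax gibbonsii LR2-5), confirms interactions by
plaques only, and prints the efficiency of plating (EOP) of each LR2-5
infecting virus relative to its own host.
"""

import halorange as hr

matrix = hr.load_lr25_screen()

print(f"isolates screened:            {len(matrix.viruses)}")
print(f"plaque-positive on LR2-5:     {matrix.count_positive('LR2-5')}")
print(f"unique (identical genomes     {matrix.dedup_unique('LR2-5')}")
print("  collapsed):")
lo, hi = matrix.titer_summary("LR2-5")
print(f"titer range on LR2-5:         {lo:.1e} .. {hi:.1e} pfu/mL")
print()
print("EOP on LR2-5 (1 = plates as well as on the isolation host):")
for rec in matrix.eop_table("LR2-5"):
    if rec.defined:
        print(f"  {rec.virus_id:<10} {rec.formatted:>6}   (raw {rec.eop_raw:.2e})")
# An EOP around 1 (HSTV-2, HRTV-2, HFTV1) means LR2-5 is as good a host as
# the isolation host; values of 1e-3..1e-6 mean strongly reduced plating.
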