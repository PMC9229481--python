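"""Conserved-column scan of a protein alignment.

Builds a toy adhesin-like alignment in which one focal sequence carries a
single substitution inside an otherwise conserved block, and reports it with
both alignment-column and ungapped focal coordinates (the convention behind
substitution names like T380A).
"""

from halorange import conserved_column_scan

alignment = [
    ("virus1", "MNTLKQTAGW"),
    ("virus2", "MNTLKQTAGW"),
    ("virus3", "MNTLKQTAGW"),
    ("virus4", "MNSLKQTAGW"),   # one tolerated difference at column 3
    ("focal",  "MNTLKQAAGW"),   # T -> A at column 7
]

for report in conserved_column_scan(alignment, "focal", min_conservation=0.75):
    name = f"{report.consensus_residue}{report.focal_position}{report.focal_residue}"
    print(
        f"column {report.column_index}: consensus {report.consensus_residue} "
        f"({report.conservation:.0%} of non-focal residues), focal has "
        f"{report.focal_residue} -> substitution {name}"
    )
# Prints the single T7A-style report: only columns that are conserved among
# the other sequences AND differ in the focal sequence qualify.
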