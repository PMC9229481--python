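"""Motif counting, tetranucleotide avoidance statistics, and conserved-column scans.

Restriction-modification (RM) systems cleave unmethylated DNA at short, often
palindromic recognition sites; viral genomes under RM pressure accumulate fewer
of those sites than composition predicts. The avoidance statistic here is the
Karlin-style tetranucleotide relative abundance with a maximal-order
(trinucleotide) expectation,

    tau(abcd) = f(abcd) * f(bc) / (f(abc) * f(bcd)),

where f(w) is the overlapping occurrence frequency of the word w in the genome
symmetrized with its reverse complement. Under a third-order-consistent
composition tau ≈ 1; values below the conventional 0.78 cut-off flag
under-representation (site avoidance). Both the formula's symmetrization and
the threshold are configuration, not data.

Counting conventions: overlapping windows on a linear (non-circular) sequence;
any window containing a non-ACGT symbol is skipped and frequencies use the
number of valid windows as denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "GenomeRecord",
    "MotifCount",
    "TetramerSignature",
    "AlignmentColumnReport",
    "reverse_complement",
    "count_motif",
    "tetramer_tau",
    "signature_profile",
    "conserved_column_scan",
    "UNDERREPRESENTATION_THRESHOLD",
]

#: tau below this is called under-represented (Karlin convention)
UNDERREPRESENTATION_THRESHOLD = 0.78

_DNA = frozenset("ACGT")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomeRecord:
    """A linear nucleotide sequence; uppercase-normalized on construction."""

    id: str
    sequence: str
    topology: str = "linear"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"genome {self.id!r} has an empty sequence")
        object.__setattr__(self, "sequence", self.sequence.upper())

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MotifCount:
    genome_id: str
    motif: str
    count_forward: int
    count_both_strands: int
    density_fwd_per_kb: float
    density_both_per_kb: float


@dataclass(frozen=True)
class TetramerSignature:
    genome_id: str
    motif: str
    tau: float | None  # None when a component count is zero (not evaluable)
    underrepresented: bool | None
    threshold: float = UNDERREPRESENTATION_THRESHOLD

    @property
    def evaluable(self) -> bool:
        return self.tau is not None


def _check_motif(motif: str) -> str:
    motif = motif.upper()
    if len(motif) < 2 or not set(motif) <= _DNA:
        raise ValueError(f"motif must be length >= 2 over ACGT, got {motif!r}")
    return motif


def _count_overlapping(sequence: str, word: str) -> int:
    """Overlapping occurrences of ``word``; windows with non-ACGT are skipped.

    str.find with step 1 restarts one past each hit, which yields the
    overlapping count; a window containing an ambiguity code simply never
    equals ``word``, which implements the skip rule for counts.
    """
    count = 0
    start = sequence.find(word)
    while start != -1:
        count += 1
        start = sequence.find(word, start + 1)
    return count


def _valid_windows(sequence: str, k: int) -> int:
    """Number of length-k windows consisting only of A/C/G/T."""
    n = len(sequence)
    if n < k:
        return 0
    if set(sequence) <= _DNA:
        return n - k + 1
    bad = [i for i, ch in enumerate(sequence) if ch not in _DNA]
    windows = n - k + 1
    invalid = set()
    for i in bad:
        invalid.update(range(max(0, i - k + 1), min(windows, i + 1)))
    return windows - len(invalid)


def count_motif(genome: GenomeRecord, motif: str, both_strands: bool = False) -> MotifCount:
    """Overlapping occurrence count of ``motif`` in one genome.

    With ``both_strands``, occurrences of the reverse complement on the forward
    strand are added unless the motif is its own reverse complement (a
    palindrome in the biological sense), in which case both strands carry the
    same sites and the count is not doubled.
    """
    motif = _check_motif(motif)
    fwd = _count_overlapping(genome.sequence, motif)
    rc = reverse_complement(motif)
    if rc == motif:
        both = fwd
    else:
        both = fwd + _count_overlapping(genome.sequence, rc)
    kb = len(genome) / 1000.0
    return MotifCount(
        genome_id=genome.id,
        motif=motif,
        count_forward=fwd,
        count_both_strands=both,
        density_fwd_per_kb=fwd / kb,
        density_both_per_kb=both / kb,
    )


def _sym_frequency(genome: GenomeRecord, word: str) -> float | None:
    """Frequency of ``word`` over the genome plus its reverse complement.

    Counts and valid windows are accumulated over the two strands separately
    (no artificial junction windows). Returns None when no valid window exists.
    """
    seq = genome.sequence
    rc_seq = reverse_complement(seq)
    count = _count_overlapping(seq, word) + _count_overlapping(rc_seq, word)
    windows = _valid_windows(seq, len(word)) + _valid_windows(rc_seq, len(word))
    if windows == 0:
        return None
    return count / windows


def tetramer_tau(
    genome: GenomeRecord,
    motif: str,
    threshold: float = UNDERREPRESENTATION_THRESHOLD,
) -> TetramerSignature:
    """Maximal-order observed/expected ratio for a tetranucleotide.

    tau = f(abcd)·f(bc) / (f(abc)·f(bcd)) with reverse-complement-symmetrized
    frequencies, so the statistic is invariant under reverse complementation of
    the genome. A zero denominator (a component tri- or di-nucleotide absent)
    makes the signature not evaluable rather than infinite.
    """
    motif = _check_motif(motif)
    if len(motif) != 4:
        raise ValueError(f"tetramer statistic needs a length-4 motif, got {motif!r}")
    f4 = _sym_frequency(genome, motif)
    f3a = _sym_frequency(genome, motif[:3])
    f3b = _sym_frequency(genome, motif[1:])
    f2 = _sym_frequency(genome, motif[1:3])
    if None in (f4, f3a, f3b, f2) or f3a == 0 or f3b == 0 or f2 == 0:
        return TetramerSignature(genome.id, motif, None, None, threshold)
    tau = (f4 * f2) / (f3a * f3b)
    return TetramerSignature(genome.id, motif, tau, tau < threshold, threshold)


def signature_profile(
    genomes: Iterable[GenomeRecord],
    motifs: Sequence[str],
    threshold: float = UNDERREPRESENTATION_THRESHOLD,
) -> pd.DataFrame:
    """Per-genome, per-motif counts and (for tetramers) tau signatures.

    Length-4 motifs get the avoidance statistic; longer motifs — e.g. putative
    methyltransferase targets like GCGCTG — get counts and densities only.
    """
    genomes = list(genomes)
    if not genomes:
        raise ValueError("need at least one genome")
    rows = []
    for genome in genomes:
        for motif in motifs:
            mc = count_motif(genome, motif, both_strands=True)
            row = {
                "genome_id": genome.id,
                "motif": mc.motif,
                "count_fwd": mc.count_forward,
                "count_both": mc.count_both_strands,
                "density_per_kb": mc.density_both_per_kb,
                "tau": None,
                "underrepresented": None,
            }
            if len(mc.motif) == 4:
                sig = tetramer_tau(genome, mc.motif, threshold)
                row["tau"] = sig.tau
                row["underrepresented"] = sig.underrepresented
            rows.append(row)
    return pd.DataFrame(
        rows,
        columns=[
            "genome_id", "motif", "count_fwd", "count_both",
            "density_per_kb", "tau", "underrepresented",
        ],
    )


@dataclass(frozen=True)
class AlignmentColumnReport:
    """A conserved alignment column where the focal sequence carries a variant.

    Coordinates are 1-based; ``focal_position`` is the ungapped position in the
    focal sequence (the T380A-style coordinate), ``column_index`` the alignment
    column.
    """

    column_index: int
    focal_position: int
    consensus_residue: str
    focal_residue: str
    conservation: float


def conserved_column_scan(
    alignment: Sequence[tuple[str, str]],
    focal_id: str,
    min_conservation: float = 0.9,
) -> list[AlignmentColumnReport]:
    """Scan a protein alignment for conserved columns where one sequence differs.

    ``alignment`` is a list of ``(id, aligned_sequence)`` pairs with gaps as
    ``-``. A column is reported when, among the non-focal non-gap residues, a
    unique majority residue reaches ``min_conservation`` and the focal residue
    is present (not a gap) and differs. Ties for the majority residue mean no
    unique consensus, so the column is skipped. Output is independent of the
    order of the non-focal sequences.
    """
    if not 0.5 < min_conservation <= 1.0:
        raise ValueError("min_conservation must lie in (0.5, 1]")
    ids = [i for i, _ in alignment]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids in alignment")
    seqs = {i: s.upper() for i, s in alignment}
    if focal_id not in seqs:
        raise KeyError(f"focal sequence {focal_id!r} not in alignment")
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) != 1:
        raise ValueError("ragged alignment: sequences have unequal lengths")
    (ncol,) = lengths
    focal = seqs[focal_id]
    others = [s for i, s in seqs.items() if i != focal_id]

    reports: list[AlignmentColumnReport] = []
    focal_pos = 0
    for col in range(ncol):
        fres = focal[col]
        if fres != "-":
            focal_pos += 1
        residues = [s[col] for s in others if s[col] != "-"]
        if not residues or fres == "-":
            continue
        counts: dict[str, int] = {}
        for r in residues:
            counts[r] = counts.get(r, 0) + 1
        best = max(counts.values())
        top = [r for r, c in counts.items() if c == best]
        if len(top) != 1:
            continue  # tied consensus -> no unique majority residue
        consensus = top[0]
        conservation = best / len(residues)
        if conservation >= min_conservation and fres != consensus:
            reports.append(
                AlignmentColumnReport(
                    column_index=col + 1,
                    focal_position=focal_pos,
                    consensus_residue=consensus,
                    focal_residue=fres,
                    conservation=conservation,
                )
            )
    return reports
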