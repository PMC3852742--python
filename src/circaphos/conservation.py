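"""Alignment-column conservation profiles and mutagenic primer verification.

The conservation profile answers questions of the form "is this residue
invariant across the aligned kinase isoforms, and what ungapped position does
that alignment column correspond to in a given sequence?" — the analysis that
identifies the gain-of-function arginine of the CK1 tau allele in a new
species. The primer tools verify circular (whole-plasmid) mutagenesis
designs: the two primers must be mutually reverse-complementary, and the
intended substitution is read off by locating the primer footprint on the
template and translating the altered codon.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from Bio import AlignIO
from Bio.Seq import Seq

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP_CHARS = frozenset("-.")
DNA_ALPHABET = frozenset("ACGT")
MAX_INFO_BITS = math.log2(20)


def read_alignment(path: str | Path) -> list[tuple[str, str]]:
    aln = AlignIO.read(str(path), "fasta")
    return [(rec.id, str(rec.seq).upper()) for rec in aln]


@dataclass(frozen=True)
class AlignmentColumnProfile:
    column: int  # 1-based
    frequencies: dict  # amino acid -> fraction among non-gap rows
    gap_fraction: float
    consensus: Optional[str]
    consensus_tied: bool
    information_bits: float
    invariant: bool


def column_profiles(alignment: Sequence[tuple[str, str]] | str | Path) -> list[AlignmentColumnProfile]:
    """Per-column residue frequencies, consensus and Shannon information.

    Gaps are excluded from the frequencies and tracked as a separate gap
    fraction; information is log2(20) minus the entropy of the non-gap
    distribution. Consensus ties are broken alphabetically and flagged.
    """
    if isinstance(alignment, (str, Path)):
        alignment = read_alignment(alignment)
    rows = [seq for _, seq in alignment]
    if len(rows) < 2:
        raise ValueError("alignment needs at least 2 sequences")
    widths = {len(s) for s in rows}
    if len(widths) != 1:
        raise ValueError("ragged alignment: sequences differ in length")
    (width,) = widths

    profiles = []
    for j in range(width):
        col = [s[j] for s in rows]
        residues = [c for c in col if c not in GAP_CHARS]
        gap_fraction = 1.0 - len(residues) / len(col)
        if not residues:
            profiles.append(
                AlignmentColumnProfile(j + 1, {}, 1.0, None, False, 0.0, False)
            )
            continue
        freqs: dict[str, float] = {}
        for c in residues:
            freqs[c] = freqs.get(c, 0) + 1
        n = len(residues)
        freqs = {c: k / n for c, k in sorted(freqs.items())}
        top = max(freqs.values())
        winners = [c for c, f in freqs.items() if f == top]
        entropy = -sum(f * math.log2(f) for f in freqs.values())
        profiles.append(
            AlignmentColumnProfile(
                column=j + 1,
                frequencies=freqs,
                gap_fraction=gap_fraction,
                consensus=winners[0],
                consensus_tied=len(winners) > 1,
                information_bits=max(MAX_INFO_BITS - entropy, 0.0),
                invariant=(len(freqs) == 1 and gap_fraction == 0.0),
            )
        )
    return profiles


def invariant_columns(profiles: Sequence[AlignmentColumnProfile]) -> list[int]:
    return [p.column for p in profiles if p.invariant]


def profiles_to_frame(profiles: Sequence[AlignmentColumnProfile]) -> pd.DataFrame:
    """Logo-ready frequency matrix: one row per column, one column per residue."""
    mat = {aa: [p.frequencies.get(aa, 0.0) for p in profiles] for aa in AMINO_ACIDS}
    df = pd.DataFrame(mat, index=[p.column for p in profiles])
    df.index.name = "column"
    return df


def map_column_to_position(
    alignment: Sequence[tuple[str, str]] | str | Path,
    sequence_id: str,
    column: int,
) -> Optional[int]:
    """Map a 1-based alignment column to the 1-based ungapped position in one
    row; returns None when that row has a gap at the column."""
    if isinstance(alignment, (str, Path)):
        alignment = read_alignment(alignment)
    row = dict(alignment).get(sequence_id)
    if row is None:
        raise KeyError(f"sequence {sequence_id!r} not in alignment")
    if not 1 <= column <= len(row):
        raise ValueError(f"column {column} outside alignment width {len(row)}")
    if row[column - 1] in GAP_CHARS:
        return None
    return sum(1 for c in row[: column] if c not in GAP_CHARS)


def position_to_column(
    alignment: Sequence[tuple[str, str]] | str | Path,
    sequence_id: str,
    position: int,
) -> int:
    """Inverse of :func:`map_column_to_position` for non-gap cells."""
    if isinstance(alignment, (str, Path)):
        alignment = read_alignment(alignment)
    row = dict(alignment).get(sequence_id)
    if row is None:
        raise KeyError(f"sequence {sequence_id!r} not in alignment")
    count = 0
    for j, c in enumerate(row, start=1):
        if c not in GAP_CHARS:
            count += 1
            if count == position:
                return j
    raise ValueError(f"position {position} beyond ungapped length {count}")


def reverse_complement(seq: str) -> str:
    _validate_dna(seq)
    return str(Seq(seq.upper()).reverse_complement())


def _validate_dna(seq: str) -> None:
    bad = set(seq.upper()) - DNA_ALPHABET
    if bad:
        raise ValueError(f"non-ACGT characters in DNA sequence: {sorted(bad)}")


@dataclass(frozen=True)
class SubstitutionReport:
    primers_complementary: bool
    substitution_detected: bool
    codon_before: Optional[str]
    codon_after: Optional[str]
    aa_before: Optional[str]
    aa_after: Optional[str]
    protein_position: Optional[int]
    n_mismatches: int


def verify_mutagenic_primers(
    template: str,
    fwd_primer: str,
    rev_primer: str,
    frame: int = 0,
    first_codon_number: int = 1,
    max_mismatches: int = 3,
) -> SubstitutionReport:
    """Verify a circular-mutagenesis primer pair against a template CDS fragment.

    Checks that the primers are mutually reverse-complementary, locates the
    forward primer's footprint on the template (best ungapped placement by
    Hamming distance), and translates the codon(s) touched by the mismatch.
    ``frame`` is the 0-based offset of the first complete codon in the
    template fragment and ``first_codon_number`` its protein position, so the
    report can state the substitution in protein coordinates.
    Case-insensitive; mixed-case primers (lowercase flanks, uppercase
    mismatch) are accepted but case carries no meaning.
    """
    template = template.upper()
    fwd = fwd_primer.upper()
    rev = rev_primer.upper()
    for name, s in (("template", template), ("fwd", fwd), ("rev", rev)):
        _validate_dna(s)
    if min(len(fwd), len(rev)) < 15:
        raise ValueError("primers must be at least 15 nt")
    if len(fwd) > len(template):
        raise ValueError("template fragment shorter than the forward primer")

    complementary = reverse_complement(rev) == fwd

    # best ungapped placement of the forward primer on the template
    f = np.frombuffer(fwd.encode(), dtype=np.uint8)
    best_off, best_mm = -1, len(fwd) + 1
    for off in range(len(template) - len(fwd) + 1):
        w = np.frombuffer(template[off : off + len(fwd)].encode(), dtype=np.uint8)
        mm = int(np.sum(w != f))
        if mm < best_mm:
            best_off, best_mm = off, mm
    if best_mm > max_mismatches:
        raise ValueError(
            f"no primer footprint on template (best placement has {best_mm} mismatches)"
        )

    window = template[best_off : best_off + len(fwd)]
    mism = [i for i in range(len(fwd)) if window[i] != fwd[i]]
    if not mism:
        return SubstitutionReport(complementary, False, None, None, None, None, None, 0)

    codon_indices = {(best_off + i - frame) // 3 for i in mism}
    if len(codon_indices) > 1:
        raise ValueError("mismatches span more than one codon; not a single substitution")
    (ci,) = codon_indices
    start = frame + 3 * ci
    if start < 0 or start + 3 > len(template):
        raise ValueError("mutated codon is not fully contained in the template fragment")
    codon_before = template[start : start + 3]
    mutated = list(template)
    for i in mism:
        mutated[best_off + i] = fwd[i]
    codon_after = "".join(mutated[start : start + 3])
    return SubstitutionReport(
        primers_complementary=complementary,
        substitution_detected=True,
        codon_before=codon_before,
        codon_after=codon_after,
        aa_before=str(Seq(codon_before).translate()),
        aa_after=str(Seq(codon_after).translate()),
        protein_position=first_codon_number + ci,
        n_mismatches=len(mism),
    )
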