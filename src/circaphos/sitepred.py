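"""Peptide-to-proteome mapping and CK1 target-site prediction.

Prediction is deliberately transparent: an additive position-weight scorer
over a window centred on each candidate S/T, with a default weight table
encoding the canonical CK1 substrate preference for acidic (or
phospho-primed) residues immediately N-terminal of the acceptor (offsets
-3..-1), plus weaker contributions from the wider flanks. External
predictions (e.g. from a dedicated kinase-specificity tool) can be imported
from TSV instead and are interchangeable downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .quantio import ModSite, PHOSPHO_RESIDUES

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


def _default_weights() -> dict[tuple[int, str], float]:
    """Acidic-preference CK1 weight table.

    D/E at offsets -3..-1 score 1.0 each; D/E in the remaining window
    positions score 0.25. Every (offset, amino acid) pair in the window is
    defined; unlisted combinations default to 0 via ``dict.get``.
    """
    w: dict[tuple[int, str], float] = {}
    for off in range(-7, 8):
        for aa in AMINO_ACIDS:
            w[(off, aa)] = 0.0
    for off in (-3, -2, -1):
        w[(off, "D")] = 1.0
        w[(off, "E")] = 1.0
    for off in list(range(-7, -3)) + [1, 2]:
        w[(off, "D")] = 0.25
        w[(off, "E")] = 0.25
    return w


@dataclass
class Ck1MotifModel:
    """Additive position-weight model for CK1 acceptor sites.

    score(position) = sum of weights over the window (truncated at sequence
    ends, no padding); a site is called when score > score_threshold
    (strict). Only S/T are scanned unless ``scan_tyrosine`` is set.
    """

    window_halfwidth: int = 7
    weights: dict[tuple[int, str], float] = field(default_factory=_default_weights)
    score_threshold: float = 2.0
    scan_tyrosine: bool = False

    def acceptor_residues(self) -> frozenset[str]:
        return frozenset("STY") if self.scan_tyrosine else frozenset("ST")

    def score(self, sequence: str, position: int) -> float:
        """Score the 1-based ``position`` in ``sequence``."""
        total = 0.0
        for off in range(-self.window_halfwidth, self.window_halfwidth + 1):
            if off == 0:
                continue
            j = position - 1 + off
            if 0 <= j < len(sequence):
                total += self.weights.get((off, sequence[j]), 0.0)
        return total


@dataclass(frozen=True)
class PredictedSite:
    protein_id: str
    position: int
    residue: str
    kinase: str = "CK1epsilon"
    score: float = 0.0
    source: str = "builtin"

    def __post_init__(self) -> None:
        if self.residue not in PHOSPHO_RESIDUES:
            raise ValueError(f"predicted residue must be S/T/Y, got {self.residue!r}")
        if self.position < 1:
            raise ValueError("position is 1-based and must be >= 1")


def map_peptide_to_proteome(
    peptide: str,
    mods: Sequence[ModSite],
    proteome: Mapping[str, str],
) -> list[tuple[str, int, tuple[int, ...]]]:
    """Locate a stripped peptide in the proteome by exact substring match.

    Returns one entry per match: (protein_id, 0-based match offset, mapped
    1-based protein positions of all phospho positions). Protein position =
    offset + peptide position with 1-based peptide coordinates. Proteins are
    visited in sorted accession order and every occurrence within a protein
    is reported, so output order is deterministic. No match -> empty list.
    """
    peptide = peptide.upper()
    pep_positions: list[int] = []
    for site in mods:
        pep_positions.extend(site.positions)
    pep_positions = sorted(set(pep_positions))

    out: list[tuple[str, int, tuple[int, ...]]] = []
    for protein_id in sorted(proteome):
        seq = proteome[protein_id]
        start = seq.find(peptide)
        while start != -1:
            out.append(
                (protein_id, start, tuple(start + p for p in pep_positions))
            )
            start = seq.find(peptide, start + 1)
    return out


def predict_ck1_sites(
    protein_id: str,
    sequence: str,
    model: Ck1MotifModel | None = None,
) -> list[PredictedSite]:
    """Scan every acceptor residue of one protein with the motif model."""
    if not sequence:
        raise ValueError("protein sequence must be non-empty")
    model = model or Ck1MotifModel()
    sequence = sequence.upper()
    acceptors = model.acceptor_residues()
    sites = []
    for i, aa in enumerate(sequence, start=1):
        if aa not in acceptors:
            continue
        s = model.score(sequence, i)
        if s > model.score_threshold:
            sites.append(
                PredictedSite(protein_id, i, aa, score=s, source="builtin")
            )
    return sites


def predict_proteome(
    proteome: Mapping[str, str], model: Ck1MotifModel | None = None
) -> list[PredictedSite]:
    model = model or Ck1MotifModel()
    out: list[PredictedSite] = []
    for protein_id in sorted(proteome):
        out.extend(predict_ck1_sites(protein_id, proteome[protein_id], model))
    return out


@dataclass
class ImportReport:
    accepted: list[PredictedSite]
    rejected: list[tuple[int, str]]  # (1-based row, reason)


def import_predictions(
    path: str | Path, proteome: Mapping[str, str], kinase: str = "CK1epsilon"
) -> ImportReport:
    """Import an external prediction TSV (protein_id, position, residue, score).

    Every row is validated against the proteome: the protein must exist, the
    position must be inside it and the stated residue must match. Failing
    rows are rejected with a per-row reason, never silently dropped.
    """
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str, "residue": str})
    required = {"protein_id", "position", "residue", "score"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"prediction table missing column(s): {', '.join(sorted(missing))}")
    accepted: list[PredictedSite] = []
    rejected: list[tuple[int, str]] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        pid = str(row.protein_id)
        pos = int(row.position)
        res = str(row.residue).upper()
        if pid not in proteome:
            rejected.append((i, f"unknown protein {pid!r}"))
            continue
        seq = proteome[pid]
        if not 1 <= pos <= len(seq):
            rejected.append((i, f"position {pos} beyond protein length {len(seq)}"))
            continue
        if seq[pos - 1] != res:
            rejected.append(
                (i, f"residue mismatch: protein has {seq[pos - 1]!r} at {pos}, row says {res!r}")
            )
            continue
        accepted.append(
            PredictedSite(pid, pos, res, kinase=kinase, score=float(row.score), source="imported")
        )
    return ImportReport(accepted, rejected)


def export_predictions(sites: Iterable[PredictedSite], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "protein_id": s.protein_id,
                "position": s.position,
                "residue": s.residue,
                "score": s.score,
                "kinase": s.kinase,
            }
            for s in sites
        ]
    ).to_csv(path, sep="\t", index=False)


def predicted_position_set(sites: Iterable[PredictedSite]) -> set[tuple[str, int]]:
    return {(s.protein_id, s.position) for s in sites}


def flag_sites(
    site_keys: Iterable, predicted: set[tuple[str, int]]
) -> dict:
    """Map PhosphoSiteKey -> bool: any position of the key is a predicted site."""
    return {
        key: any((key.protein_id, p) in predicted for p in key.positions)
        for key in site_keys
    }
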