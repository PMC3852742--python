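"""Reading, validating and collating label-free phospho-peptide quantifications.

The central operation here is the collapse from redundant peptide-level
measurements (a phospho-site is typically observed across several charge
states, missed-cleavage variants and co-modified forms) to one row per unique
phospho-site, summing abundances within each (condition, replicate) cell.
Summation makes the collapse exactly conservative: the total abundance of the
site table equals the total abundance of the contributing peptide rows.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

PHOSPHO_RESIDUES = frozenset("STY")

_MOD_TOKEN = re.compile(
    r"^(?P<res>[STY])(?P<pos>\d+)"
    r"(?:\(amb:(?P<amb>[STY]\d+(?:,[STY]\d+)*)\))?$"
)

QUANT_COLUMNS = [
    "peptide",
    "mods",
    "protein",
    "charge",
    "missed_cleavages",
    "group",
    "replicate",
    "abundance",
]


class SchemaError(ValueError):
    """A quant table is missing a required column or is otherwise malformed."""


@dataclass(frozen=True)
class ModSite:
    """One phospho localization group on a peptide (1-based peptide positions).

    A confidently localized site has a single position; an ambiguous
    localization (e.g. ``T5(amb:T7)``) carries every candidate position.
    """

    positions: tuple[int, ...]
    residues: tuple[str, ...]

    @property
    def ambiguous(self) -> bool:
        return len(self.positions) > 1


def parse_mods(mods: str, peptide: str) -> list[ModSite]:
    """Parse a mods string like ``S3`` or ``S3;T5(amb:T7)``.

    Each ``;``-separated token is one localization group. Positions are
    validated against the peptide: they must fall inside the sequence and the
    named residue must match (phospho is only chemically possible on S/T/Y).
    """
    if not mods or not mods.strip():
        raise ValueError("empty mods string: at least one phospho-site required")
    sites: list[ModSite] = []
    for token in mods.strip().split(";"):
        m = _MOD_TOKEN.match(token.strip())
        if m is None:
            raise ValueError(f"cannot parse mod token {token!r}")
        pairs = [(m.group("res"), int(m.group("pos")))]
        if m.group("amb"):
            for alt in m.group("amb").split(","):
                pairs.append((alt[0], int(alt[1:])))
        positions, residues = [], []
        for res, pos in pairs:
            if not 1 <= pos <= len(peptide):
                raise ValueError(
                    f"mod position {pos} outside peptide of length {len(peptide)}"
                )
            if peptide[pos - 1] != res:
                raise ValueError(
                    f"mod {res}{pos}: peptide residue at position {pos} is "
                    f"{peptide[pos - 1]!r}, not {res!r}"
                )
            positions.append(pos)
            residues.append(res)
        order = np.argsort(positions)
        sites.append(
            ModSite(
                tuple(positions[i] for i in order),
                tuple(residues[i] for i in order),
            )
        )
    return sites


@dataclass(frozen=True)
class PeptideMeasurement:
    """One quantified phospho-peptide ion in one replicate of one condition."""

    peptide: str
    mods: tuple[ModSite, ...]
    protein_id: str
    charge: int
    missed_cleavages: int
    group: str
    replicate: int
    abundance: float

    def __post_init__(self) -> None:
        if self.abundance < 0:
            raise ValueError(f"negative abundance {self.abundance}")
        if self.charge < 1:
            raise ValueError(f"charge must be >= 1, got {self.charge}")
        if self.missed_cleavages < 0:
            raise ValueError("missed_cleavages must be >= 0")


@dataclass(frozen=True, order=True)
class PhosphoSiteKey:
    """Identity of a unique phospho-site: protein accession plus the ordered
    set of 1-based protein residue positions of its localization group(s).

    Equality and ordering use only ``(protein_id, positions)``; residue
    letters and the ambiguity flag are carried for display.
    """

    protein_id: str
    positions: tuple[int, ...]
    residues: tuple[str, ...] = field(default=(), compare=False)
    ambiguous: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        if not self.positions:
            raise ValueError("a site key needs at least one position")
        if tuple(sorted(set(self.positions))) != self.positions:
            raise ValueError("positions must be sorted and unique")

    @property
    def label(self) -> str:
        if self.residues and len(self.residues) == len(self.positions):
            parts = [f"{r}{p}" for r, p in zip(self.residues, self.positions)]
        else:
            parts = [str(p) for p in self.positions]
        return f"{self.protein_id}:{'/'.join(parts)}"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


@dataclass
class SkipRecord:
    """A measurement that could not be collated, with the reason."""

    measurement: PeptideMeasurement
    reason: str


@dataclass
class SiteQuantTable:
    """Unique phospho-sites x (group, replicate) summed abundances.

    ``data`` is indexed by :class:`PhosphoSiteKey` with a (group, replicate)
    column MultiIndex; missing cells stay NaN (never zero-filled).
    """

    data: pd.DataFrame
    n_source_peptides: pd.Series
    skipped: list[SkipRecord] = field(default_factory=list)
    ambiguous_matches: list[tuple[PeptideMeasurement, list[str]]] = field(
        default_factory=list
    )

    @property
    def sites(self) -> list[PhosphoSiteKey]:
        return list(self.data.index)

    @property
    def n_sites(self) -> int:
        return len(self.data)

    def total_abundance(self) -> float:
        if self.data.empty:
            return 0.0
        return float(np.nansum(self.data.to_numpy(dtype=float)))

    def group_values(self, site: PhosphoSiteKey, group: str) -> np.ndarray:
        """Observed (non-missing) abundances for one site in one condition."""
        row = self.data.loc[site, group]
        vals = row.to_numpy(dtype=float)
        return vals[~np.isnan(vals)]

    def to_tsv(self, path: str | Path) -> None:
        labels = {k: k.label.split(":", 1)[1] for k in self.data.index}
        rows = []
        for key in self.data.index:
            for (group, rep), val in self.data.loc[key].items():
                if pd.isna(val):
                    continue
                rows.append(
                    {
                        "protein_id": key.protein_id,
                        "positions": labels[key],
                        "group": group,
                        "replicate": rep,
                        "abundance": val,
                    }
                )
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_quant_table(path: str | Path, sep: str | None = None) -> list[PeptideMeasurement]:
    """Read a peptide-level quant CSV/TSV into validated measurements.

    Required columns: peptide, mods, protein, charge, missed_cleavages,
    group, replicate, abundance. Errors report the offending column or the
    1-based data row index.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep, dtype={"mods": str, "protein": str, "group": str})
    missing = [c for c in QUANT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"quant table missing column(s): {', '.join(missing)}")
    return measurements_from_frame(df)


def measurements_from_frame(df: pd.DataFrame) -> list[PeptideMeasurement]:
    out: list[PeptideMeasurement] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            peptide = str(row.peptide).strip().upper()
            abundance = float(row.abundance)
            if abundance < 0:
                raise ValueError(f"negative abundance {abundance}")
            mods = tuple(parse_mods(str(row.mods), peptide))
            out.append(
                PeptideMeasurement(
                    peptide=peptide,
                    mods=mods,
                    protein_id=str(row.protein),
                    charge=int(row.charge),
                    missed_cleavages=int(row.missed_cleavages),
                    group=str(row.group),
                    replicate=int(row.replicate),
                    abundance=abundance,
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"row {i}: {exc}") from exc
    return out


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a FASTA file as {accession: sequence}; accession is the
    description line split at the first whitespace."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        records[rec.id] = str(rec.seq).upper()
    return records


def site_key_for_measurement(
    m: PeptideMeasurement, protein_id: str, offset: int, proteome: Mapping[str, str]
) -> PhosphoSiteKey:
    """Build the site key for one peptide occurrence at 0-based ``offset``.

    All localization groups on the peptide are pooled into one key: a
    multiply phosphorylated peptide is a single quantified species, so
    splitting its abundance over the individual residues would double-count.
    """
    positions: list[int] = []
    ambiguous = any(s.ambiguous for s in m.mods)
    for site in m.mods:
        positions.extend(offset + p for p in site.positions)
    positions = sorted(set(positions))
    seq = proteome[protein_id]
    residues = tuple(seq[p - 1] for p in positions)
    return PhosphoSiteKey(protein_id, tuple(positions), residues, ambiguous)


def collate_sites(
    measurements: Sequence[PeptideMeasurement],
    proteome: Mapping[str, str],
) -> SiteQuantTable:
    """Collapse peptide measurements to unique phospho-sites.

    All charge states, missed-cleavage variants and repeated observations of
    the same site key are summed within each (group, replicate). Peptides
    with no exact proteome match go to the skip report rather than being
    silently dropped; peptides matching several proteins are assigned to the
    first accession in sort order and recorded as ambiguous.
    """
    from .sitepred import map_peptide_to_proteome

    cells: dict[PhosphoSiteKey, dict[tuple[str, int], float]] = {}
    n_src: dict[PhosphoSiteKey, int] = {}
    skipped: list[SkipRecord] = []
    ambiguous: list[tuple[PeptideMeasurement, list[str]]] = []

    for m in measurements:
        matches = map_peptide_to_proteome(m.peptide, m.mods, proteome)
        if not matches:
            skipped.append(SkipRecord(m, "peptide has no exact proteome match"))
            continue
        if len(matches) > 1:
            ambiguous.append((m, [prot for prot, _, _ in matches]))
        protein_id, offset, _ = matches[0]
        key = site_key_for_measurement(m, protein_id, offset, proteome)
        cell = (m.group, m.replicate)
        cells.setdefault(key, {})
        cells[key][cell] = cells[key].get(cell, 0.0) + m.abundance
        n_src[key] = n_src.get(key, 0) + 1

    if not cells:
        empty = pd.DataFrame(
            index=pd.Index([], dtype=object),
            columns=pd.MultiIndex.from_arrays([[], []], names=["group", "replicate"]),
        )
        return SiteQuantTable(empty, pd.Series(dtype=int), skipped, ambiguous)

    all_cells = sorted({c for d in cells.values() for c in d})
    columns = pd.MultiIndex.from_tuples(all_cells, names=["group", "replicate"])
    keys = sorted(cells)
    mat = np.full((len(keys), len(all_cells)), np.nan)
    col_ix = {c: j for j, c in enumerate(all_cells)}
    for i, key in enumerate(keys):
        for cell, val in cells[key].items():
            mat[i, col_ix[cell]] = val
    data = pd.DataFrame(mat, index=pd.Index(keys), columns=columns)
    counts = pd.Series([n_src[k] for k in keys], index=data.index, name="n_source_peptides")
    return SiteQuantTable(data, counts, skipped, ambiguous)
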