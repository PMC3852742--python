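"""Cross-dataset comparison of two differential phospho-site tables.

Supports the overlap bookkeeping between two overexpression experiments
(e.g. a mutant-allele line vs a wild-type-allele line), export of the overlap
as a chord-diagram flow matrix, construction of the stringent candidate table
(sites predicted as kinase targets and upregulated in one or both lines), and
summary counts over the packaged curated annotation fixture.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd

from .diffphos import DifferentialTable
from .quantio import PhosphoSiteKey

_PHOSPHO_GROUP = re.compile(r"\(p[^)]*\)")

CHORD_LABELS = ["A_up", "B_up", "A_down", "B_down"]


@dataclass(frozen=True)
class OverlapSummary:
    up_shared: int
    up_A_only: int
    up_B_only: int
    down_shared: int
    down_A_only: int
    down_B_only: int
    discordant_A_up_B_down: int = 0
    discordant_A_down_B_up: int = 0

    @property
    def discordant(self) -> int:
        return self.discordant_A_up_B_down + self.discordant_A_down_B_up

    @property
    def n_up_A(self) -> int:
        return self.up_shared + self.up_A_only

    @property
    def n_up_B(self) -> int:
        return self.up_shared + self.up_B_only

    @property
    def n_down_A(self) -> int:
        return self.down_shared + self.down_A_only

    @property
    def n_down_B(self) -> int:
        return self.down_shared + self.down_B_only


def compare_datasets(A: DifferentialTable, B: DifferentialTable) -> OverlapSummary:
    """Set algebra on the up/down site-key sets of two differential tables."""
    a_up, b_up = A.up_sites, B.up_sites
    a_dn, b_dn = A.down_sites, B.down_sites
    return OverlapSummary(
        up_shared=len(a_up & b_up),
        up_A_only=len(a_up - b_up),
        up_B_only=len(b_up - a_up),
        down_shared=len(a_dn & b_dn),
        down_A_only=len(a_dn - b_dn),
        down_B_only=len(b_dn - a_dn),
        discordant_A_up_B_down=len(a_up & b_dn),
        discordant_A_down_B_up=len(a_dn & b_up),
    )


def compare_site_sets(
    a_up: set, b_up: set, a_down: set, b_down: set
) -> OverlapSummary:
    """Overlap summary from raw site-key sets (for legacy/peptide-matched data)."""
    return OverlapSummary(
        len(a_up & b_up), len(a_up - b_up), len(b_up - a_up),
        len(a_down & b_down), len(a_down - b_down), len(b_down - a_down),
        len(a_up & b_down), len(a_down & b_up),
    )


def export_chord(summary: OverlapSummary) -> dict:
    """Symmetric chord-diagram flow matrix over [A_up, B_up, A_down, B_down].

    Shared sites are off-diagonal flows, exclusive sites are self-flows, and
    discordant sites flow between the up group of one dataset and the down
    group of the other; every row sums to that dataset's classified count.
    """
    m = [[0] * 4 for _ in range(4)]
    m[0][1] = m[1][0] = summary.up_shared
    m[2][3] = m[3][2] = summary.down_shared
    m[0][3] = m[3][0] = summary.discordant_A_up_B_down
    m[2][1] = m[1][2] = summary.discordant_A_down_B_up
    m[0][0] = summary.up_A_only - summary.discordant_A_up_B_down
    m[1][1] = summary.up_B_only - summary.discordant_A_down_B_up
    m[2][2] = summary.down_A_only - summary.discordant_A_down_B_up
    m[3][3] = summary.down_B_only - summary.discordant_A_up_B_down
    return {"labels": list(CHORD_LABELS), "matrix": m}


def chord_to_json(summary: OverlapSummary, path: str | Path | None = None) -> str:
    doc = json.dumps(export_chord(summary), indent=1)
    if path is not None:
        Path(path).write_text(doc)
    return doc


def chord_from_json(doc: str) -> dict:
    parsed = json.loads(doc)
    if set(parsed) != {"labels", "matrix"}:
        raise ValueError("not a chord document")
    return parsed


@dataclass(frozen=True)
class CandidateEntry:
    """One row of the stringent candidate table.

    ``site`` is a display label (gene/accession plus site notation);
    ``n_sites`` counts the phospho localization groups the display string
    carries (one per ``(p...)`` group), so a multiply phosphorylated peptide
    row contributes several sites to the summary counts.
    """

    site: str
    peptide_display: str
    category: str  # both / tau_only / wt_only / neither
    predicted_ck1: bool = True
    homolog: Optional[tuple[str, str, str]] = None  # (name, E-value, identity)
    alters_human_clock: str = "unknown"  # yes_period/yes_amplitude/yes_both/no/unknown
    rhythmic_mouse: str = "unknown"  # yes/no/unknown
    gene_id: str = ""

    @property
    def n_sites(self) -> int:
        return max(1, len(_PHOSPHO_GROUP.findall(self.peptide_display)))


_CATEGORIES = ("both", "tau_only", "wt_only", "neither")
_CLOCK_VALUES = ("yes_period", "yes_amplitude", "yes_both", "no", "unknown")


def categorize(site, up_A: set, up_B: set) -> str:
    if site in up_A and site in up_B:
        return "both"
    if site in up_A:
        return "tau_only"
    if site in up_B:
        return "wt_only"
    return "neither"


def build_candidate_table(
    A: DifferentialTable,
    B: DifferentialTable,
    predicted: Mapping[PhosphoSiteKey, bool],
    annotations: Mapping[PhosphoSiteKey, dict] | None = None,
) -> list[CandidateEntry]:
    """Stringent candidates: predicted kinase-target sites upregulated in at
    least one dataset, categorized by which up-sets contain them."""
    annotations = annotations or {}
    up_A, up_B = A.up_sites, B.up_sites
    entries = []
    for key in sorted(k for k, flag in predicted.items() if flag):
        cat = categorize(key, up_A, up_B)
        if cat == "neither":
            continue
        ann = annotations.get(key, {})
        entries.append(
            CandidateEntry(
                site=key.label,
                peptide_display=ann.get("peptide_display", key.label),
                category=cat,
                predicted_ck1=True,
                homolog=ann.get("homolog"),
                alters_human_clock=ann.get("alters_human_clock", "unknown"),
                rhythmic_mouse=ann.get("rhythmic_mouse", "unknown"),
                gene_id=key.protein_id,
            )
        )
    return entries


def load_candidate_fixture(path: str | Path | None = None) -> list[CandidateEntry]:
    """Load the packaged curated candidate annotation table.

    The fixture encodes, per predicted kinase-target peptide, the category
    (upregulated in both lines / one line / neither), the closest human
    relative with BLAST statistics, whether knockdown of that relative alters
    the human cellular clock, and whether the mouse homolog's transcript is
    clock-regulated.
    """
    if path is None:
        source = resources.files("circaphos.data").joinpath("curated_candidates.tsv")
        with resources.as_file(source) as p:
            df = pd.read_csv(p, sep="\t", dtype=str, keep_default_na=False)
    else:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    entries = []
    for row in df.itertuples(index=False):
        if row.category not in _CATEGORIES:
            raise ValueError(f"fixture entry {row.entry}: unknown category {row.category!r}")
        if row.alters_hs_clock not in _CLOCK_VALUES:
            raise ValueError(f"fixture entry {row.entry}: bad clock annotation")
        homolog = None
        if row.closest_human_relative not in (None, "", "N/A"):
            homolog = (row.closest_human_relative, row.e_value, row.identity)
        entries.append(
            CandidateEntry(
                site=f"{row.gene_id}:{row.site_sequence}",
                peptide_display=row.site_sequence,
                category=row.category,
                predicted_ck1=True,
                homolog=homolog,
                alters_human_clock=row.alters_hs_clock,
                rhythmic_mouse=row.rhythmic_mm,
                gene_id=row.gene_id,
            )
        )
    return entries


@dataclass(frozen=True)
class AnnotationSummary:
    n_entries: int
    n_with_homolog: int
    n_alter_clock: int
    n_rhythmic_mouse: int
    n_predicted_sites_by_category: dict
    n_proteins_by_category: dict


def summarize_candidate_annotations(entries: Iterable[CandidateEntry]) -> AnnotationSummary:
    """Annotation counts over a candidate list.

    The clock-effect numerator counts entries whose human relative alters
    period and/or amplitude; the denominator is the entries with a resolved
    homolog at all (unknown/no-similarity rows are excluded from both).
    """
    entries = list(entries)
    with_homolog = [e for e in entries if e.homolog is not None]
    n_alter = sum(1 for e in with_homolog if e.alters_human_clock.startswith("yes"))
    n_rhythmic = sum(1 for e in with_homolog if e.rhythmic_mouse == "yes")
    sites_by_cat: dict[str, int] = {}
    prots_by_cat: dict[str, set] = {}
    for e in entries:
        if not e.predicted_ck1:
            continue
        sites_by_cat[e.category] = sites_by_cat.get(e.category, 0) + e.n_sites
        prots_by_cat.setdefault(e.category, set()).add(e.gene_id or e.site)
    return AnnotationSummary(
        n_entries=len(entries),
        n_with_homolog=len(with_homolog),
        n_alter_clock=n_alter,
        n_rhythmic_mouse=n_rhythmic,
        n_predicted_sites_by_category=sites_by_cat,
        n_proteins_by_category={k: len(v) for k, v in prots_by_cat.items()},
    )


def candidates_to_tsv(entries: Iterable[CandidateEntry], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "site": e.site,
                "peptide": e.peptide_display,
                "category": e.category,
                "predicted_ck1": e.predicted_ck1,
                "homolog": e.homolog[0] if e.homolog else "N/A",
                "e_value": e.homolog[1] if e.homolog else "N/A",
                "identity": e.homolog[2] if e.homolog else "N/A",
                "alters_human_clock": e.alters_human_clock,
                "rhythmic_mouse": e.rhythmic_mouse,
            }
            for e in entries
        ]
    ).to_csv(path, sep="\t", index=False)
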