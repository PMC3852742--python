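"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators: (i) peptide-level label-free quant tables for a
two-condition (parent vs kinase-overexpressor), five-replicate design with a
configurable fraction of truly shifted phospho-sites and redundant peptide
variants per site; (ii) random proteomes with CK1-consensus motifs planted at
known positions; (iii) damped-cosinor luminescence plate traces.

Abundance model: per-site means are log-normal; replicate values multiply the
mean by log-normal noise with a given coefficient of variation; truly
regulated sites shift the overexpression group mean by a fold factor.
Redundant peptide variants split each site cell by a Dirichlet draw so that
collation by summation restores the site total exactly. Missing values are
dropped completely at random.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .quantio import PhosphoSiteKey

AA20 = "ACDEFGHIKLMNPQRSTVWY"
# residues drawn for random background; acidic letters appear at natural-ish
# frequency so chance motif matches exist but are rare
_BG = "AAACCDDEEFFGGGHIIKKLLLMNNPPQQRRSSSTTTVVWY"

MOTIF_WINDOW = 4  # planted consensus needs 3 upstream residues + acceptor


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


@dataclass
class PhosphoSimConfig:
    """Design of a synthetic two-condition phospho-LFQ experiment.

    Defaults mirror the study design this package targets: 156 unique sites
    quantified in 5 replicates per condition, with roughly 24% of sites
    up-shifted and 4% down-shifted in the overexpressor. Effect size and
    within-group CV are field-typical placeholders (the underlying abundance
    distribution of real LFQ data is not part of the design).
    """

    n_proteins: int = 40
    n_sites: int = 156
    replicates_per_group: int = 5
    frac_up: float = 0.24
    frac_down: float = 0.04
    effect_fold: float = 2.5
    abundance_log_mean: float = 11.0
    abundance_log_sd: float = 1.2
    cv_within: float = 0.2
    redundancy_max: int = 3
    missing_rate: float = 0.0
    seed: int = 0
    # independent stream for measurement noise; None reuses `seed`. Two
    # configs sharing `seed` but differing here model repeated measurement
    # of the same biological ground truth.
    noise_seed: int | None = None
    group_parent: str = "parent"
    group_ox: str = "CK1tau-OX"
    protein_length: int = 400

    def validate(self) -> None:
        _check(self.n_proteins >= 1, "n_proteins must be >= 1")
        _check(self.n_sites >= 1, "n_sites must be >= 1")
        _check(self.replicates_per_group >= 2, "replicates_per_group must be >= 2")
        _check(0 <= self.frac_up <= 1, "frac_up must be in [0, 1]")
        _check(0 <= self.frac_down <= 1, "frac_down must be in [0, 1]")
        _check(self.frac_up + self.frac_down <= 1, "frac_up + frac_down must be <= 1")
        _check(self.effect_fold > 1, "effect_fold must be > 1")
        _check(self.abundance_log_sd >= 0, "abundance_log_sd must be >= 0")
        _check(self.cv_within >= 0, "cv_within must be >= 0")
        _check(self.redundancy_max >= 1, "redundancy_max must be >= 1")
        _check(0 <= self.missing_rate < 1, "missing_rate must be in [0, 1)")
        _check(
            self.protein_length >= 40,
            "protein_length must leave room for peptide windows (>= 40)",
        )
        # each protein must be able to host its share of sites
        per = -(-self.n_sites // self.n_proteins)
        _check(
            per * 18 <= self.protein_length - 20,
            "n_sites too large for n_proteins x protein_length",
        )


@dataclass
class SimTruth:
    """Ground truth of a generated dataset, keyed by phospho-site."""

    site_class: dict[PhosphoSiteKey, str]
    true_fold: dict[PhosphoSiteKey, float]
    planted_motif_sites: set[tuple[str, int]]
    proteome: dict[str, str]

    def sites_of_class(self, cls: str) -> set[PhosphoSiteKey]:
        return {k for k, v in self.site_class.items() if v == cls}

    def to_json(self, path: str | Path) -> None:
        doc = {
            "sites": [
                {
                    "protein_id": k.protein_id,
                    "positions": list(k.positions),
                    "class": self.site_class[k],
                    "true_fold": self.true_fold[k],
                }
                for k in sorted(self.site_class)
            ],
            "planted_motif_sites": sorted(list(p) for p in self.planted_motif_sites),
        }
        Path(path).write_text(json.dumps(doc, indent=1))


def _random_protein(rng: np.random.Generator, length: int) -> list[str]:
    return list(rng.choice(list(_BG), size=length))


def generate_proteome(
    n_proteins: int,
    length: int,
    motif_density: float = 0.0,
    seed: int = 0,
) -> tuple[dict[str, str], set[tuple[str, int]]]:
    """Random proteome with CK1-consensus motifs planted at known positions.

    ``motif_density`` is the mean number of planted motifs per protein. A
    planted motif writes D-D-D immediately upstream of an S acceptor, which
    by construction scores 3.0 > 2.0 under the default
    :class:`~circaphos.sitepred.Ck1MotifModel`, so planted recall is 1.
    """
    _check(n_proteins >= 1, "n_proteins must be >= 1")
    _check(length >= MOTIF_WINDOW, "protein length must be >= the motif window")
    _check(motif_density >= 0, "motif_density must be >= 0")
    rng = np.random.default_rng(seed)
    proteome: dict[str, str] = {}
    planted: set[tuple[str, int]] = set()
    width = len(str(n_proteins))
    for i in range(n_proteins):
        pid = f"SP{i + 1:0{max(width, 3)}d}"
        seq = _random_protein(rng, length)
        n_mot = int(rng.poisson(motif_density))
        placed: list[int] = []
        for _ in range(n_mot):
            for _attempt in range(50):
                pos = int(rng.integers(MOTIF_WINDOW, length + 1))  # 1-based acceptor
                if all(abs(pos - q) >= 8 for q in placed):
                    break
            else:
                continue
            seq[pos - 4 : pos - 1] = ["D", "D", "D"]
            seq[pos - 1] = "S"
            placed.append(pos)
            planted.add((pid, pos))
        proteome[pid] = "".join(seq)
    return proteome, planted


def write_fasta(proteome: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for pid in proteome:
            fh.write(f">{pid}\n{proteome[pid]}\n")


def generate_phospho_dataset(
    cfg: PhosphoSimConfig,
) -> tuple[pd.DataFrame, SimTruth]:
    """Generate a peptide-level quant table plus its ground truth.

    The returned frame uses the quant-table schema of
    :func:`circaphos.quantio.read_quant_table`; ``SimTruth.proteome`` carries
    the matching protein sequences so the table can be collated.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    rng_noise = np.random.default_rng(cfg.seed if cfg.noise_seed is None else cfg.noise_seed)

    proteome, _ = generate_proteome(cfg.n_proteins, cfg.protein_length, 0.0, cfg.seed + 1)
    pids = sorted(proteome)

    # assign sites to proteins round-robin, at well-separated positions
    site_locs: list[tuple[str, int]] = []
    per_protein: dict[str, list[int]] = {p: [] for p in pids}
    margin = 15
    for s in range(cfg.n_sites):
        pid = pids[s % len(pids)]
        taken = per_protein[pid]
        lo = margin + 1
        hi = cfg.protein_length - margin
        for _ in range(200):
            pos = int(rng.integers(lo, hi + 1))
            if all(abs(pos - q) >= 18 for q in taken):
                break
        else:  # pragma: no cover - config validation prevents this
            raise RuntimeError("could not place all sites; increase protein_length")
        taken.append(pos)
        site_locs.append((pid, pos))

    # force the acceptor residue and make site keys
    seqs = {p: list(proteome[p]) for p in pids}
    keys: list[PhosphoSiteKey] = []
    for pid, pos in site_locs:
        res = "S" if rng.random() < 0.7 else "T"
        seqs[pid][pos - 1] = res
        keys.append(PhosphoSiteKey(pid, (pos,), (res,)))
    proteome = {p: "".join(seqs[p]) for p in pids}

    # planted classes
    n_up = int(round(cfg.frac_up * cfg.n_sites))
    n_down = int(round(cfg.frac_down * cfg.n_sites))
    classes = ["up"] * n_up + ["down"] * n_down + ["null"] * (cfg.n_sites - n_up - n_down)
    rng.shuffle(classes)

    site_class = dict(zip(keys, classes))
    true_fold = {
        k: (cfg.effect_fold if c == "up" else 1.0 / cfg.effect_fold if c == "down" else 1.0)
        for k, c in site_class.items()
    }

    sigma = float(np.sqrt(np.log1p(cfg.cv_within**2)))
    groups = [cfg.group_parent, cfg.group_ox]
    rows: list[dict] = []
    for key in keys:
        pid, pos = key.protein_id, key.positions[0]
        seq = proteome[pid]
        base_mean = float(np.exp(rng.normal(cfg.abundance_log_mean, cfg.abundance_log_sd)))
        # one peptide window per site; variants reuse it across charges/missed cuts
        left = int(rng.integers(4, 11))
        right = int(rng.integers(4, 11))
        start = max(0, pos - 1 - left)
        end = min(len(seq), pos + right)
        peptide = seq[start:end]
        pep_pos = pos - start  # 1-based within peptide
        mods = f"{key.residues[0]}{pep_pos}"
        n_var = int(rng.integers(1, cfg.redundancy_max + 1))
        for group in groups:
            fold = true_fold[key] if group == cfg.group_ox else 1.0
            for rep in range(1, cfg.replicates_per_group + 1):
                if cfg.missing_rate > 0 and rng_noise.random() < cfg.missing_rate:
                    continue
                noise = float(np.exp(rng_noise.normal(-0.5 * sigma**2, sigma)))
                cell = base_mean * fold * noise
                shares = rng_noise.dirichlet(np.ones(n_var)) if n_var > 1 else np.array([1.0])
                for v in range(n_var):
                    rows.append(
                        {
                            "peptide": peptide,
                            "mods": mods,
                            "protein": pid,
                            "charge": 2 + v % 3,
                            "missed_cleavages": v // 3,
                            "group": group,
                            "replicate": rep,
                            "abundance": float(cell * shares[v]),
                        }
                    )

    table = pd.DataFrame(rows, columns=[
        "peptide", "mods", "protein", "charge", "missed_cleavages",
        "group", "replicate", "abundance",
    ])
    truth = SimTruth(site_class, true_fold, set(), proteome)
    return table, truth


@dataclass
class TraceSimConfig:
    """Damped-cosinor luminescence trace model.

    y(t) = baseline + slope*t + amplitude * exp(-damping*t)
           * cos(2*pi*(t - phase)/period) + N(0, noise_sd).
    """

    period_h: float = 24.0
    amplitude: float = 100.0
    phase_h: float = 0.0
    damping_rate: float = 0.0
    baseline: float = 0.0
    baseline_slope: float = 0.0
    noise_sd: float = 0.0
    duration_h: float = 96.0
    sample_interval_h: float = 1.0
    n_wells: int = 1
    seed: int = 0

    def validate(self) -> None:
        _check(self.period_h > 0, "period_h must be positive")
        _check(self.sample_interval_h > 0, "sample_interval_h must be positive")
        _check(
            self.duration_h >= 2 * self.period_h,
            "duration_h must cover at least two full periods",
        )
        _check(self.damping_rate >= 0, "damping_rate must be >= 0")
        _check(self.noise_sd >= 0, "noise_sd must be >= 0")
        _check(self.n_wells >= 1, "n_wells must be >= 1")


def generate_traces(cfg: TraceSimConfig) -> tuple[pd.DataFrame, dict]:
    """Simulate a luminescence plate: column ``time_h`` plus one column per well.

    Returns the trace frame and a truth record echoing the generating
    parameters (notably the true period).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    t = np.arange(0.0, cfg.duration_h + 1e-9, cfg.sample_interval_h)
    clean = (
        cfg.baseline
        + cfg.baseline_slope * t
        + cfg.amplitude
        * np.exp(-cfg.damping_rate * t)
        * np.cos(2 * np.pi * (t - cfg.phase_h) / cfg.period_h)
    )
    data = {"time_h": t}
    for w in range(1, cfg.n_wells + 1):
        noise = rng.normal(0.0, cfg.noise_sd, size=t.shape) if cfg.noise_sd > 0 else 0.0
        data[f"well_{w:02d}"] = clean + noise
    truth = asdict(cfg)
    return pd.DataFrame(data), truth
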