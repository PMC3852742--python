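"""Structured pipeline configuration (YAML in, dataclasses out)."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import yaml

from .diffphos import DifferentialCriteria
from .synthdata import PhosphoSimConfig, TraceSimConfig


class ConfigurationError(ValueError):
    pass


@dataclass
class EnrichmentSettings:
    n_perm: int = 100_000
    seed: Optional[int] = None
    tail: str = "greater"


@dataclass
class RhythmSettings:
    window_low_h: float = 18.0
    window_high_h: float = 34.0
    n_harmonics: int = 1
    rae_threshold: float = 0.6


@dataclass
class PipelineConfig:
    """Everything one end-to-end run needs.

    Either ``quant_table`` + ``proteome_fasta`` point at real inputs, or
    ``synthetic`` drives the generator; prediction comes from the builtin
    scorer unless ``predictions_tsv`` is given.
    """

    output_dir: str = "circaphos_out"
    seed: Optional[int] = None
    quant_table: Optional[str] = None
    proteome_fasta: Optional[str] = None
    predictions_tsv: Optional[str] = None
    group_parent: str = "parent"
    group_ox: str = "CK1tau-OX"
    synthetic: Optional[PhosphoSimConfig] = None
    criteria: DifferentialCriteria = field(default_factory=DifferentialCriteria)
    enrichment: EnrichmentSettings = field(default_factory=EnrichmentSettings)
    rhythm: RhythmSettings = field(default_factory=RhythmSettings)

    def validate(self) -> None:
        synthetic = self.synthetic is not None
        if not synthetic:
            if self.quant_table is None:
                raise ConfigurationError(
                    "no input: provide quant_table or a synthetic block"
                )
            if not Path(self.quant_table).exists():
                raise ConfigurationError(f"quant_table not found: {self.quant_table}")
            if self.proteome_fasta is None:
                raise ConfigurationError(
                    "proteome_fasta is required to collate and predict on real input"
                )
            if not Path(self.proteome_fasta).exists():
                raise ConfigurationError(f"proteome_fasta not found: {self.proteome_fasta}")
        if self.predictions_tsv is not None and not Path(self.predictions_tsv).exists():
            raise ConfigurationError(f"predictions_tsv not found: {self.predictions_tsv}")
        seed = self.seed if self.seed is not None else self.enrichment.seed
        if seed is None:
            raise ConfigurationError(
                "a seed is mandatory: the enrichment stage is stochastic"
            )

    @property
    def effective_seed(self) -> int:
        return self.seed if self.seed is not None else self.enrichment.seed  # type: ignore[return-value]


def load_config(path: str | Path) -> PipelineConfig:
    doc = yaml.safe_load(Path(path).read_text()) or {}
    return config_from_dict(doc)


def config_from_dict(doc: dict) -> PipelineConfig:
    kwargs = dict(doc)
    if "synthetic" in kwargs and kwargs["synthetic"] is not None:
        kwargs["synthetic"] = PhosphoSimConfig(**kwargs["synthetic"])
    if "criteria" in kwargs and kwargs["criteria"] is not None:
        kwargs["criteria"] = DifferentialCriteria(**kwargs["criteria"])
    if "enrichment" in kwargs and kwargs["enrichment"] is not None:
        kwargs["enrichment"] = EnrichmentSettings(**kwargs["enrichment"])
    if "rhythm" in kwargs and kwargs["rhythm"] is not None:
        kwargs["rhythm"] = RhythmSettings(**kwargs["rhythm"])
    try:
        return PipelineConfig(**kwargs)
    except TypeError as exc:
        raise ConfigurationError(str(exc)) from exc


def dump_config(cfg: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(asdict(cfg), sort_keys=False))
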