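"""Pipeline orchestration: a reproducible run from one structured config.

A :class:`RunConfig` names exactly one input source (a directory of
FAERS-layout tables, or a synthetic-generator section), the drug lexicon,
the SMQ mapping, the analysis variants, and an output directory.  Every
analysis variant defaults to the choice that reproduces the published
carfilzomib analysis (corrected odds ratio, approximation IC interval,
age cutoff 65).  Identical config + seed yields byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import disproportionality as dp
from .descriptive import characteristics_table
from .ingest import clean, read_reports
from .reports import ReportSet
from .synthetic import (
    DrugSpec,
    EventSpec,
    GeneratorConfig,
    categories_from_config,
    example_config,
    simulate,
    write_faers_layout,
)
from .vocabulary import (
    CARFILZOMIB_LEXICON,
    DrugLexicon,
    SmqCategory,
    load_smq_table,
)

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid run configuration."""


@dataclass
class RunConfig:
    """Everything needed to reproduce a pipeline run."""

    output_dir: str
    input_dir: str | None = None
    synthetic: dict | None = None  # GeneratorConfig fields (catalogs as dicts)
    lexicon_path: str | None = None  # default: bundled carfilzomib lexicon
    smq_table_path: str | None = None  # required for directory input
    ror_variant: str = "odds-ratio"
    ic_interval: str = "approximation"
    age_cutoff: float = 65.0
    stratified: bool = True
    time_series: bool = True
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        if (self.input_dir is None) == (self.synthetic is None):
            raise ConfigError("exactly one of input_dir / synthetic must be set")
        if self.input_dir is not None:
            if not Path(self.input_dir).is_dir():
                raise ConfigError(f"input_dir {self.input_dir} does not exist")
            if self.smq_table_path is None:
                raise ConfigError("smq_table_path is required for directory input")
        for p in (self.lexicon_path, self.smq_table_path):
            if p is not None and not Path(p).exists():
                raise ConfigError(f"referenced path {p} does not exist")
        if self.ror_variant not in dp.ROR_VARIANTS:
            raise ConfigError(f"ror_variant must be one of {dp.ROR_VARIANTS}")
        if self.ic_interval not in dp.IC_INTERVAL_METHODS:
            raise ConfigError(f"ic_interval must be one of {dp.IC_INTERVAL_METHODS}")

    def generator_config(self) -> GeneratorConfig:
        if self.synthetic is None:
            raise ConfigError("no synthetic section in config")
        spec = dict(self.synthetic)
        spec.setdefault("seed", self.seed)
        if "drug_catalog" in spec:
            spec["drug_catalog"] = tuple(DrugSpec(**d) for d in spec["drug_catalog"])
        if "event_catalog" in spec:
            spec["event_catalog"] = tuple(
                EventSpec(e["pt"], e["prob"], tuple(e.get("categories", ())))
                for e in spec["event_catalog"]
            )
        if "association_multipliers" in spec:
            spec["association_multipliers"] = {
                (m["drug"], m["category"]): m["multiplier"]
                for m in spec["association_multipliers"]
            }
        if not spec.get("drug_catalog"):
            # minimal synthetic section: fall back to the demonstration config
            base = example_config(seed=spec.get("seed", 0))
            keep = {k: v for k, v in spec.items() if k != "drug_catalog"}
            spec = {**dataclasses.asdict(base), **keep}
            spec["drug_catalog"] = base.drug_catalog
            spec["event_catalog"] = base.event_catalog
            spec["association_multipliers"] = base.association_multipliers
        return GeneratorConfig(**spec)

    def config_hash(self) -> str:
        """Hash of the analysis-relevant fields (not output location/logging)."""
        fields = dataclasses.asdict(self)
        for k in ("output_dir", "log_level"):
            fields.pop(k, None)
        blob = json.dumps(fields, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _load_vocabulary(
    config: RunConfig, gen_config: GeneratorConfig | None
) -> tuple[DrugLexicon, list[SmqCategory]]:
    lexicon = (
        DrugLexicon.from_file(config.lexicon_path)
        if config.lexicon_path
        else CARFILZOMIB_LEXICON
    )
    if config.smq_table_path:
        categories = load_smq_table(config.smq_table_path)
    else:
        assert gen_config is not None
        categories = categories_from_config(gen_config)
    return lexicon, categories


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.6g")


def run_pipeline(config: RunConfig) -> dict:
    """Execute ingest -> clean -> map -> disproportionality -> descriptive.

    Writes all output tables plus a manifest (config hash, seed, per-stage
    row counts) into ``config.output_dir`` and returns the manifest.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
        "outputs": [],
    }

    gen_config = None
    if config.synthetic is not None:
        gen_config = config.generator_config()
        reports, ledger = simulate(gen_config)
        write_faers_layout(reports, out / "faers")
        ledger.to_json(out / "generation_ledger.json")
        manifest["outputs"].append("generation_ledger.json")
        reports = read_reports(out / "faers")  # exercise the full round trip
    else:
        reports = read_reports(config.input_dir)
    manifest["stages"]["input"] = len(reports)

    lexicon, categories = _load_vocabulary(config, gen_config)

    cleaned, cleaning = clean(reports, lexicon)
    cleaning.to_json(out / "cleaning_report.json")
    manifest["outputs"].append("cleaning_report.json")
    manifest["stages"]["duplicates_removed"] = cleaning.n_duplicates_removed
    manifest["stages"]["aberrant_removed"] = cleaning.n_aberrant_removed
    manifest["stages"]["retained"] = cleaning.n_retained

    from .vocabulary import category_membership, match_drug_mask

    hd = match_drug_mask(cleaned, lexicon)
    member = category_membership(cleaned, categories)
    manifest["stages"]["target_drug_reports"] = int(hd.sum())
    manifest["stages"]["cardiovascular_reports"] = int((member.any(axis=1) & hd).sum())

    variants = dict(ic_interval=config.ic_interval, ror_variant=config.ror_variant)
    signals = dp.run_category_analysis(cleaned, lexicon, categories, **variants)
    _write_csv(signals, out / "signals.csv")
    manifest["outputs"].append("signals.csv")

    if config.time_series:
        frames = []
        for cat in categories:
            ts = dp.ic_time_series(cleaned, lexicon, cat, **variants)
            ts.insert(0, "category", cat.name)
            frames.append(ts)
        _write_csv(pd.concat(frames, ignore_index=True), out / "ic_time_series.csv")
        manifest["outputs"].append("ic_time_series.csv")

    if config.stratified:
        strat = dp.stratified_analysis(
            cleaned, lexicon, categories, age_cutoff=config.age_cutoff, **variants
        )
        _write_csv(strat, out / "stratified.csv")
        manifest["outputs"].append("stratified.csv")

    chars = characteristics_table(cleaned, lexicon, categories)
    _write_csv(chars, out / "characteristics.csv")
    manifest["outputs"].append("characteristics.csv")

    tto = dp.tto_by_category(cleaned, lexicon, categories)
    tto_rows = []
    from .descriptive import tto_summary

    for name, values in tto.items():
        s = tto_summary(values)
        tto_rows.append({"category": name, **dataclasses.asdict(s)})
    _write_csv(pd.DataFrame(tto_rows), out / "time_to_onset.csv")
    manifest["outputs"].append("time_to_onset.csv")

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
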