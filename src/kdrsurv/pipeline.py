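"""End-to-end pipeline: simulate -> genotype -> intron -> summarize -> associate.

Every output table is plain TSV with a fixed column order and a one-line
provenance comment (version, seed, config hash), so re-running a stage on
identical inputs is byte-idempotent.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, genotype, intron, popstats, refcat, surveys, synth

log = logging.getLogger("kdrsurv")


@dataclass
class PipelineConfig:
    out_dir: Path
    seed: int = 0
    preset: str = "paperlike"  # simulate preset; "none" to genotype an input FASTA
    noise_rate: float = 0.0
    fasta: list[Path] = field(default_factory=list)  # input reads when preset == "none"
    refs_config: Path | None = None  # YAML from refcat.write_config; default built-ins
    district_table: Path | None = None  # default: bundled survey table
    identity_threshold: float = genotype.DEFAULT_IDENTITY_THRESHOLD
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        base = Path(path).parent
        kwargs: dict = {"out_dir": base / doc.get("out_dir", "out")}
        for key in ("seed", "preset", "noise_rate", "identity_threshold", "log_level"):
            if key in doc:
                kwargs[key] = doc[key]
        if doc.get("fasta"):
            kwargs["fasta"] = [base / p for p in doc["fasta"]]
        for key in ("refs_config", "district_table"):
            if doc.get(key):
                kwargs[key] = base / doc[key]
        return cls(**kwargs)

    def config_hash(self) -> str:
        # analytic parameters only: where the output lands must not change it
        skip = {"out_dir", "log_level"}
        payload = repr(
            sorted((k, str(v)) for k, v in self.__dict__.items() if k not in skip)
        ).encode()
        return hashlib.sha1(payload).hexdigest()[:12]


def _provenance(cfg: PipelineConfig) -> str:
    return f"# kdrsurv {__version__} seed={cfg.seed} config={cfg.config_hash()}"


def write_table(df: pd.DataFrame, path: Path, cfg: PipelineConfig, *, index: bool = False) -> Path:
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        fh.write(_provenance(cfg) + "\n")
        df.to_csv(fh, sep="\t", index=index)
    return path


def load_references(cfg: PipelineConfig):
    if cfg.refs_config is not None:
        return refcat.load_config(cfg.refs_config)
    cat = refcat.default_catalog()
    return refcat.default_references(cat), cat


def stage_simulate(cfg: PipelineConfig) -> list[Path]:
    """Simulate populations and write the FASTA + truth dataset."""
    refs, cat = load_references(cfg)
    if cfg.preset == "paperlike":
        configs = synth.paperlike_configs(cfg.seed, noise_rate=cfg.noise_rate)
    else:
        raise ValueError(f"unknown simulate preset {cfg.preset!r}")
    records: list[synth.TruthRecord] = []
    sequences: list[tuple[str, str]] = []
    for c in configs:
        r, s = synth.simulate_population(c, cat, refs)
        records.extend(r)
        sequences.extend(s)
    sim_dir = cfg.out_dir / "simulated"
    paths = synth.write_dataset(records, sequences, sim_dir, configs=configs, seed=cfg.seed)
    log.info("simulated %d individuals into %s", len(records), sim_dir)
    return [paths[f] for f in sorted(paths)]


def stage_genotype(cfg: PipelineConfig, fasta: list[Path]) -> Path:
    refs, cat = load_references(cfg)
    records = genotype.call_dataset(
        [Path(f) for f in fasta], refs, cat,
        identity_threshold=cfg.identity_threshold,
    )
    calls = genotype.records_to_frame(records)
    out = write_table(calls, cfg.out_dir / "calls.tsv", cfg)
    log.info("genotyped %d individuals -> %s", len(calls), out)
    return out


def read_table(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def stage_intron(cfg: PipelineConfig, calls_path: Path) -> Path:
    calls = read_table(calls_path)
    table, excluded = intron.intron_genotype_table_from_frame(calls)
    table.index.name = "intron"
    path = cfg.out_dir / "intron_genotype.tsv"
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        fh.write(_provenance(cfg) + "\n")
        fh.write(f"# excluded={excluded}\n")
        table.to_csv(fh, sep="\t", index=True)
    log.info("intron table written (%d individuals excluded)", excluded)
    return path


def stage_summarize(cfg: PipelineConfig, calls_path: Path) -> list[Path]:
    calls = read_table(calls_path)
    outs = [
        write_table(
            popstats.mutation_frequency(calls),
            cfg.out_dir / "mutation_frequency.tsv",
            cfg,
        )
    ]
    for site in popstats.SITES:
        outs.append(
            write_table(
                popstats.genotype_frequencies(calls, site),
                cfg.out_dir / f"genotype_frequencies_{site}.tsv",
                cfg,
            )
        )
        outs.append(
            write_table(
                popstats.allele_frequencies(calls, site),
                cfg.out_dir / f"allele_frequencies_{site}.tsv",
                cfg,
            )
        )
    patterns, wild_hom = popstats.combination_table(calls)
    outs.append(write_table(patterns, cfg.out_dir / "combinations.tsv", cfg))
    outs.append(
        write_table(
            wild_hom.reset_index(), cfg.out_dir / "wild_homozygotes.tsv", cfg
        )
    )
    return outs


def stage_associate(cfg: PipelineConfig, intron_table_path: Path) -> Path:
    """Chi-square of intron type vs 1534 mutation, plus usage-density correlations."""
    table = read_table(intron_table_path).set_index("intron")
    table = table.drop(index=[i for i in table.index if i == "Total"], errors="ignore")
    table = table.drop(columns=[c for c in table.columns if c == "Total"], errors="ignore")
    report: dict = {}
    try:
        two_by_two = popstats.intron_mutation_2x2(table)
        assoc = popstats.chi_square(two_by_two)
        report["intron_vs_1534"] = {
            "table": two_by_two.astype(int).tolist(),
            "chi_square": assoc.statistic,
            "df": assoc.df,
            "p_value": assoc.p_value,
            "low_expected": assoc.low_expected,
        }
    except ValueError as exc:
        report["intron_vs_1534"] = {"error": str(exc)}
    if cfg.district_table is not None:
        districts = pd.read_csv(cfg.district_table, sep="\t")
    else:
        districts = surveys.load_district_usage()
    dens = popstats.usage_density(districts)
    report["usage_density"] = {
        row["district"]: round(row["density_g_per_km2"], 2)
        for _, row in dens.iterrows()
    }
    for col, label in (
        ("kdr_frequency_pct", "density_vs_kdr_frequency"),
        ("f1534s_frequency_pct", "density_vs_f1534s_frequency"),
    ):
        if col in dens.columns:
            cor = popstats.pearson_correlation(dens["density_g_per_km2"], dens[col])
            report[label] = {"n": cor.n, "r": cor.r, "t": cor.t, "p_value": cor.p_value}
    out = cfg.out_dir / "association_report.yaml"
    out.write_text(
        _provenance(cfg) + "\n" + yaml.safe_dump(report, sort_keys=True)
    )
    return out


def run_pipeline(cfg: PipelineConfig) -> dict[str, Path]:
    """Execute every stage; raises with the failing stage named."""
    logging.basicConfig(level=cfg.log_level)
    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    stage = "simulate"
    try:
        if cfg.preset != "none":
            sim = stage_simulate(cfg)
            fasta = [p for p in sim if p.suffix == ".fasta"]
            outputs["simulated"] = cfg.out_dir / "simulated"
        else:
            fasta = cfg.fasta
        stage = "genotype"
        calls = stage_genotype(cfg, fasta)
        outputs["calls"] = calls
        stage = "intron"
        outputs["intron_genotype"] = stage_intron(cfg, calls)
        stage = "summarize"
        for p in stage_summarize(cfg, calls):
            outputs[p.stem] = p
        stage = "associate"
        outputs["association_report"] = stage_associate(
            cfg, outputs["intron_genotype"]
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return outputs
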