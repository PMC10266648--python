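"""Synthetic diploid populations with known kdr genotypes.

Stands in for field-collected mosquitoes: individuals are drawn under
Hardy-Weinberg equilibrium from per-codon allele frequencies (sites
independent — multi-site mutant combinations arise only by chance), each
chromosome's Domain III intron type is drawn conditional on the
individual's codon-1534 amino-acid genotype class, and every individual
is rendered as Sanger-style consensus amplicon sequences: heterozygous
positions become IUPAC ambiguity codes, and length-heterozygous intron
pairs are emitted as two per-haplotype records because a single
consensus string cannot represent a length polymorphism.

Truth tables accompany every dataset, so the whole calling pipeline can
be validated end-to-end at zero noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from ._iupac import merge
from .intron import INTRON_SEQUENCES, INTRON_LENGTHS
from .refcat import AlleleCatalog, ReferenceFragment
from . import surveys

_FREQ_TOL = 1e-9


class SimulationConfigError(ValueError):
    """Invalid simulation configuration (bad frequencies or alleles)."""


@dataclass
class PopulationSimConfig:
    """Study conditions for one simulated population."""

    population_code: str
    n_individuals: int
    allele_freqs: dict[int, dict[str, float]]
    intron_given_1534: dict[str, dict[str, float]] | None = None
    noise_rate: float = 0.0
    seed: int = 0

    def validate(self, cat: AlleleCatalog) -> None:
        if self.n_individuals < 0:
            raise SimulationConfigError("n_individuals must be >= 0")
        if not 0.0 <= self.noise_rate < 1.0:
            raise SimulationConfigError("noise_rate must be in [0, 1)")
        for site, freqs in self.allele_freqs.items():
            permitted = set(cat.alleles_at(site))
            for allele in freqs:
                if allele not in permitted:
                    raise SimulationConfigError(
                        f"allele {allele} not catalogued at codon {site}"
                    )
            total = sum(freqs.values())
            if abs(total - 1.0) > _FREQ_TOL:
                raise SimulationConfigError(
                    f"allele frequencies at {site} sum to {total!r}, not 1"
                )
        if self.intron_given_1534 is not None:
            for cls, dist in self.intron_given_1534.items():
                for t in dist:
                    if t not in INTRON_LENGTHS:
                        raise SimulationConfigError(f"unknown intron type {t!r}")
                total = sum(dist.values())
                if abs(total - 1.0) > _FREQ_TOL:
                    raise SimulationConfigError(
                        f"intron distribution for class {cls!r} sums to {total!r}, not 1"
                    )


@dataclass
class TruthRecord:
    """Ground truth for one simulated mosquito."""

    individual_id: str
    population_code: str
    genotypes: dict[int, tuple[str, str]]  # site -> unordered allele pair
    introns: tuple[str, str] | None = None  # one type label per chromosome
    mutant_carrier: bool = False


def _sorted_pair(site: int, pair: Sequence[str], cat: AlleleCatalog) -> tuple[str, str]:
    a, b = sorted(pair, key=lambda c: (cat.order_index(site, c), c))
    return a, b


def _aa_class(site: int, pair: tuple[str, str], cat: AlleleCatalog) -> str:
    return "/".join(cat.classify(site, c).amino_acid for c in pair)


def sample_population(
    cfg: PopulationSimConfig, cat: AlleleCatalog
) -> list[TruthRecord]:
    """Draw diploid individuals under Hardy-Weinberg from the configured
    per-site allele frequencies.  Deterministic given ``cfg.seed``."""
    cfg.validate(cat)
    rng = np.random.default_rng([cfg.seed, 0])
    records = []
    for i in range(cfg.n_individuals):
        genotypes = {}
        carrier = False
        for site, freqs in cfg.allele_freqs.items():
            alleles = list(freqs)
            probs = np.asarray(list(freqs.values()), dtype=float)
            probs = probs / probs.sum()  # guard rounding at the 1e-9 level
            pair = rng.choice(alleles, size=2, p=probs)
            genotypes[site] = _sorted_pair(site, pair, cat)
            carrier = carrier or any(cat.is_mutant(site, a) for a in pair)
        records.append(
            TruthRecord(
                individual_id=f"{cfg.population_code}{i + 1:04d}",
                population_code=cfg.population_code,
                genotypes=genotypes,
                mutant_carrier=carrier,
            )
        )
    return records


def default_intron_conditional() -> dict[str, dict[str, float]]:
    """Per-chromosome intron-type distribution given the 1534 genotype class.

    Estimated from the bundled survey's intron-by-genotype counts, pooled
    over codon-1532 classes and renormalised; the ``*`` row (overall
    marginal) covers classes the survey never observed.
    """
    counts = surveys.load_intron_genotype_counts()
    by_1534: dict[str, dict[str, float]] = {}
    for col in counts.columns:
        cls = col.split("+")[1]
        row = by_1534.setdefault(cls, {})
        for t, c in counts[col].items():
            row[t] = row.get(t, 0.0) + float(c)
    out: dict[str, dict[str, float]] = {}
    for cls, row in by_1534.items():
        total = sum(row.values())
        out[cls] = {t: c / total for t, c in row.items() if c > 0}
    marginal = counts.sum(axis=1)
    out["*"] = {t: float(c) / float(marginal.sum()) for t, c in marginal.items() if c > 0}
    return out


def assign_introns(
    records: list[TruthRecord],
    cfg: PopulationSimConfig,
    cat: AlleleCatalog,
) -> list[TruthRecord]:
    """Draw each chromosome's intron type conditional on the individual's
    1534 amino-acid genotype class.  Deterministic given ``cfg.seed``."""
    cond = cfg.intron_given_1534 or default_intron_conditional()
    for cls, dist in cond.items():
        total = sum(dist.values())
        if abs(total - 1.0) > _FREQ_TOL:
            raise SimulationConfigError(
                f"intron distribution for class {cls!r} sums to {total!r}, not 1"
            )
    rng = np.random.default_rng([cfg.seed, 1])
    for rec in records:
        pair = rec.genotypes.get(1534)
        cls = _aa_class(1534, pair, cat) if pair else "*"
        dist = cond.get(cls) or cond.get("*")
        if dist is None:
            raise SimulationConfigError(
                f"no intron distribution for 1534 class {cls!r} and no '*' fallback"
            )
        types = list(dist)
        probs = np.asarray(list(dist.values()), dtype=float)
        probs = probs / probs.sum()
        drawn = rng.choice(types, size=2, p=probs)
        rec.introns = tuple(sorted(drawn))  # type: ignore[assignment]
    return records


# ---------------------------------------------------------------------------
# sequence rendering

def _haplotype_sequence(
    frag: ReferenceFragment,
    alleles: Mapping[int, str],
    intron_seq: str | None,
) -> str:
    base = list(frag.sequence)
    for site, codon in alleles.items():
        start, _ = frag.codon_coords(site)
        base[start - 1 : start + 2] = list(codon)
    parts = []
    for seg in frag.segments:
        if seg.kind == "intron" and intron_seq is not None:
            parts.append(intron_seq)
        else:
            parts.append("".join(base[seg.start - 1 : seg.end]))
    return "".join(parts)


def _consensus(a: str, b: str) -> str:
    return "".join(merge(x, y) for x, y in zip(a, b))


def _apply_noise(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    chars = list(seq)
    hits = np.nonzero(rng.random(len(chars)) < rate)[0]
    for i in hits:
        pool = [b for b in "ACGT" if b != chars[i]]
        chars[i] = pool[rng.integers(len(pool))]
    return "".join(chars)


def render_sequences(
    records: list[TruthRecord],
    refs: Mapping[str, ReferenceFragment],
    cfg: PopulationSimConfig,
    cat: AlleleCatalog,
) -> list[tuple[str, str]]:
    """Render each individual as consensus amplicon FASTA entries.

    Per fragment the two haplotype sequences (reference with the
    individual's alleles substituted; Domain III with each chromosome's
    intron) are merged into one IUPAC consensus, except when the two
    haplotypes differ in length — then both haplotypes are emitted,
    flagged ``|hap1``/``|hap2`` in the header.  Substitution noise is
    applied after merging.  Deterministic given ``cfg.seed``.
    """
    rng = np.random.default_rng([cfg.seed, 2])
    out: list[tuple[str, str]] = []
    for rec in records:
        for fid, frag in refs.items():
            sites = [s for s in cat.sites_on(fid) if s in rec.genotypes]
            hap_alleles: list[dict[int, str]] = [{}, {}]
            for s in sites:
                pair = rec.genotypes[s]
                hap_alleles[0][s] = pair[0]
                hap_alleles[1][s] = pair[1]
            has_intron = any(seg.kind == "intron" for seg in frag.segments)
            intron_pair: tuple[str | None, str | None] = (None, None)
            if has_intron and rec.introns is not None:
                intron_pair = tuple(INTRON_SEQUENCES[t] for t in rec.introns)  # type: ignore[assignment]
            h1 = _haplotype_sequence(frag, hap_alleles[0], intron_pair[0])
            h2 = _haplotype_sequence(frag, hap_alleles[1], intron_pair[1])
            stem = f"{rec.population_code}|{rec.individual_id}|{fid}"
            if len(h1) == len(h2):
                seq = _apply_noise(_consensus(h1, h2), cfg.noise_rate, rng)
                out.append((stem, seq))
            else:
                out.append((f"{stem}|hap1", _apply_noise(h1, cfg.noise_rate, rng)))
                out.append((f"{stem}|hap2", _apply_noise(h2, cfg.noise_rate, rng)))
    return out


def simulate_population(
    cfg: PopulationSimConfig,
    cat: AlleleCatalog,
    refs: Mapping[str, ReferenceFragment],
) -> tuple[list[TruthRecord], list[tuple[str, str]]]:
    """Sample genotypes, assign introns and render sequences in one call."""
    records = sample_population(cfg, cat)
    assign_introns(records, cfg, cat)
    return records, render_sequences(records, refs, cfg, cat)


def truth_to_frame(records: list[TruthRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row: dict[str, object] = {
            "population": r.population_code,
            "individual": r.individual_id,
        }
        for site in sorted(r.genotypes):
            row[f"{site}_alleles"] = "/".join(r.genotypes[site])
        row["intron_types"] = "/".join(r.introns) if r.introns else ""
        row["mutant_carrier"] = bool(r.mutant_carrier)
        rows.append(row)
    return pd.DataFrame(rows)


def write_dataset(
    records: list[TruthRecord],
    sequences: list[tuple[str, str]],
    out_dir: str | Path,
    *,
    configs: Sequence[PopulationSimConfig] = (),
    seed: int | None = None,
) -> dict[str, Path]:
    """Write per-fragment FASTA files, the truth TSV and a config echo.

    Output is byte-deterministic for a given input (fixed column order,
    70-column FASTA wrap, sorted YAML keys).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    by_fragment: dict[str, list[tuple[str, str]]] = {}
    for header, seq in sequences:
        fid = header.split("|")[2]
        by_fragment.setdefault(fid, []).append((header, seq))
    paths: dict[str, Path] = {}
    for fid, entries in by_fragment.items():
        p = out_dir / f"{fid}.fasta"
        with p.open("w") as fh:
            for header, seq in entries:
                fh.write(f">{header}\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i : i + 70] + "\n")
        paths[fid] = p
    truth_path = out_dir / "truth.tsv"
    truth_to_frame(records).to_csv(truth_path, sep="\t", index=False)
    paths["truth"] = truth_path
    echo = {
        "seed": seed,
        "populations": [
            {
                "population_code": c.population_code,
                "n_individuals": c.n_individuals,
                "allele_freqs": {
                    int(s): {a: float(f) for a, f in fr.items()}
                    for s, fr in c.allele_freqs.items()
                },
                "intron_given_1534": c.intron_given_1534,
                "noise_rate": float(c.noise_rate),
                "seed": int(c.seed),
            }
            for c in configs
        ],
    }
    echo_path = out_dir / "config_echo.yaml"
    echo_path.write_text(yaml.safe_dump(echo, sort_keys=True))
    paths["config"] = echo_path
    return paths


# ---------------------------------------------------------------------------
# presets

def paperlike_configs(seed: int, *, noise_rate: float = 0.0) -> list[PopulationSimConfig]:
    """Sixteen populations parameterised from the bundled survey tables.

    Sample sizes follow the survey's per-population n (658 total); per-site
    allele frequencies follow the published allele columns (renormalised
    from rounded percentages); the intron conditional is the pooled
    survey estimate.  Per-population child seeds are spawned
    deterministically from ``seed``.
    """
    sizes = surveys.load_mutation_frequency()
    allele_tables = {s: surveys.load_codon_genotypes(s).set_index("code") for s in (1016, 1532, 1534)}
    cond = default_intron_conditional()
    child_seeds = np.random.SeedSequence(seed).generate_state(len(sizes)) % (2**31)
    configs = []
    for i, row in sizes.iterrows():
        code = row["code"]
        freqs: dict[int, dict[str, float]] = {}
        for site, table in allele_tables.items():
            cols = surveys.ALLELE_CLASSES[site]
            raw = table.loc[code, cols].astype(float)
            total = raw.sum()
            freqs[site] = {a: float(v) / total for a, v in raw.items() if v > 0}
        configs.append(
            PopulationSimConfig(
                population_code=code,
                n_individuals=int(row["n"]),
                allele_freqs=freqs,
                intron_given_1534=cond,
                noise_rate=noise_rate,
                seed=int(child_seeds[i]),
            )
        )
    return configs
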