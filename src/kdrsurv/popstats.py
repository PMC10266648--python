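"""Population-level kdr frequency tables and association statistics.

Counting conventions, fixed throughout:

* per-site denominators are the individuals with a unique-resolution call
  at that site (ambiguous/failed calls shrink N for that table only);
* allele frequency = (2 x homozygotes + heterozygotes carrying the
  allele) / 2N, computed exactly on counts;
* the kdr mutation frequency of a population is mutant carriers
  (wild/mutant heterozygotes + mutant genotypes) / N;
* pooled ("Total") rows pool counts over populations — never the mean of
  per-population percentages.

The chi-square here is Pearson's without continuity correction, and the
Pearson correlation p-value is the two-sided t test with n-2 degrees of
freedom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import surveys

SITES = (1016, 1532, 1534)

_MUTANT_ZYGOSITIES = {"het_wild_mut", "mut_hom", "mut_het"}


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (the convention of the printed tables)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def reconstruct_count(pct: float, n: int) -> int:
    """Invert a printed percentage back to the underlying count."""
    return int(round_half_up(pct * n / 100.0))


def _unique_site(calls: pd.DataFrame, site: int) -> pd.DataFrame:
    return calls[calls[f"{site}_resolution"] == "unique"]


def _class_order(site: int, observed: Sequence[str]) -> list[str]:
    known = surveys.GENOTYPE_CLASSES.get(site, [])
    extra = sorted(set(observed) - set(known))
    return [c for c in known if c in set(observed)] + extra


# ---------------------------------------------------------------------------
# frequency tables (operate on the calls table from genotype.records_to_frame)

def genotype_frequencies(calls: pd.DataFrame, site: int) -> pd.DataFrame:
    """Per-population and pooled genotype-class counts and frequencies.

    Long format: population, genotype, count, n, pct — with pooled
    ``Total`` rows computed on pooled counts.
    """
    sub = _unique_site(calls, site)
    col = f"{site}_aa"
    rows = []
    groups = list(sub.groupby("population", sort=True))
    groups.append(("Total", sub))
    for pop, g in groups:
        n = len(g)
        counts = g[col].value_counts()
        for cls in _class_order(site, counts.index):
            c = int(counts.get(cls, 0))
            rows.append(
                {
                    "population": pop,
                    "genotype": cls,
                    "count": c,
                    "n": n,
                    "pct": 100.0 * c / n if n else float("nan"),
                }
            )
    return pd.DataFrame(rows)


def allele_frequencies(calls: pd.DataFrame, site: int) -> pd.DataFrame:
    """Per-population and pooled codon-allele counts and frequencies.

    Alleles are counted directly from the called pairs, so the identity
    freq(a) = (2 hom + het) / 2N holds exactly on counts.
    """
    sub = _unique_site(calls, site)
    col = f"{site}_alleles"
    rows = []
    groups = list(sub.groupby("population", sort=True))
    groups.append(("Total", sub))
    for pop, g in groups:
        n = len(g)
        counts: dict[str, int] = {}
        for pair in g[col]:
            for allele in pair.split("/"):
                counts[allele] = counts.get(allele, 0) + 1
        known = surveys.ALLELE_CLASSES.get(site, [])
        order = [a for a in known if a in counts] + sorted(set(counts) - set(known))
        for allele in order:
            c = counts[allele]
            rows.append(
                {
                    "population": pop,
                    "allele": allele,
                    "count": c,
                    "n": n,
                    "pct": 100.0 * c / (2 * n) if n else float("nan"),
                }
            )
    return pd.DataFrame(rows)


def mutation_frequency(calls: pd.DataFrame) -> pd.DataFrame:
    """Mutant carriers / N per population, plus the pooled total.

    Individuals with no unique call at any site are excluded from N.
    """
    any_unique = np.zeros(len(calls), dtype=bool)
    for site in SITES:
        any_unique |= (calls[f"{site}_resolution"] == "unique").to_numpy()
    sub = calls[any_unique]
    rows = []
    groups = list(sub.groupby("population", sort=True))
    groups.append(("Total", sub))
    for pop, g in groups:
        n = len(g)
        carriers = int(g["mutant_carrier"].sum())
        rows.append(
            {
                "population": pop,
                "n": n,
                "carriers": carriers,
                "pct": 100.0 * carriers / n if n else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def combination_table(calls: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Multi-site mutant genotype patterns per population.

    Considers individuals with unique calls at all three sites.  Returns
    ``(patterns, wild_homozygotes)``: counts per (1016, 1532, 1534)
    genotype triple among individuals mutant at two or more sites, and the
    per-population count of individuals wild-homozygous at every site.
    """
    mask = np.ones(len(calls), dtype=bool)
    for site in SITES:
        mask &= (calls[f"{site}_resolution"] == "unique").to_numpy()
    sub = calls[mask]
    mutant_sites = sum(
        sub[f"{s}_zygosity"].isin(_MUTANT_ZYGOSITIES).astype(int) for s in SITES
    )
    wild_hom = (
        sub[(mutant_sites == 0)]
        .groupby("population", sort=True)
        .size()
        .rename("wild_homozygotes")
    )
    multi = sub[mutant_sites >= 2]
    if multi.empty:
        patterns = pd.DataFrame(
            columns=["population", "1016", "1532", "1534", "count"]
        )
    else:
        patterns = (
            multi.groupby(
                ["population", "1016_aa", "1532_aa", "1534_aa"], sort=True
            )
            .size()
            .rename("count")
            .reset_index()
            .rename(columns={f"{s}_aa": str(s) for s in SITES})
        )
    return patterns, wild_hom


# ---------------------------------------------------------------------------
# summary-level algebra (works directly on printed tables)

def allele_freq_from_genotype_classes(classes: Mapping[str, float]) -> dict[str, float]:
    """Allele frequencies from ``{"X/Y": weight}`` genotype classes.

    Each class contributes half its weight to each of its two allele
    labels; works identically on counts or percentages (homozygote "X/X"
    contributes its full weight to X).
    """
    out: dict[str, float] = {}
    for cls, w in classes.items():
        a, b = cls.split("/")
        out[a] = out.get(a, 0.0) + w / 2.0
        out[b] = out.get(b, 0.0) + w / 2.0
    return out


def pooled_rate(ns: Sequence[int], pcts: Sequence[float]) -> tuple[int, float]:
    """Pool printed per-population percentages back through their counts.

    Reconstructs each population's count as round_half_up(pct * n / 100),
    then returns ``(pooled_count, pooled_pct)`` over the pooled N.
    """
    if len(ns) != len(pcts):
        raise ValueError("ns and pcts must have equal length")
    carriers = sum(reconstruct_count(p, n) for n, p in zip(ns, pcts))
    total = int(sum(ns))
    return carriers, 100.0 * carriers / total


# ---------------------------------------------------------------------------
# association statistics

@dataclass
class AssociationResult:
    table: np.ndarray
    statistic: float
    df: int
    p_value: float
    test_name: str = "pearson-chi-square"
    low_expected: bool = False  # any expected cell count < 5


@dataclass
class CorrelationResult:
    n: int
    r: float
    t: float
    p_value: float


def chi_square(table) -> AssociationResult:
    """Pearson chi-square of independence, no continuity correction."""
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("need an r x c table with r, c >= 2")
    if (obs < 0).any():
        raise ValueError("counts must be nonnegative")
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ValueError("degenerate margins (empty row or column)")
    stat, p, df, expected = stats.chi2_contingency(obs, correction=False)
    return AssociationResult(
        table=obs,
        statistic=float(stat),
        df=int(df),
        p_value=float(p),
        low_expected=bool((expected < 5).any()),
    )


def pearson_correlation(x, y) -> CorrelationResult:
    """Product-moment correlation with the two-sided t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance")
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return CorrelationResult(n=n, r=r, t=math.inf, p_value=0.0)
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), n - 2)
    return CorrelationResult(n=n, r=r, t=t, p_value=float(p))


def usage_density(districts: pd.DataFrame) -> pd.DataFrame:
    """Pyrethroid grams per km^2 per district.

    Expects ``district``, ``area_km2`` and ``pyrethroid_g`` columns; rows
    without a positive area are dropped.  Extra columns pass through.
    """
    df = districts.copy()
    ok = df["area_km2"] > 0
    df = df[ok].reset_index(drop=True)
    df["density_g_per_km2"] = df["pyrethroid_g"] / df["area_km2"]
    return df


def intron_mutation_2x2(counts: pd.DataFrame) -> np.ndarray:
    """The intron A/B vs 1534 wild-hom/mutant-carrier table among 1532 I/I.

    Accepts either the bundled survey layout (string columns
    ``"I/I+F/F"``, ...) or the pipeline's intron-by-genotype table
    (MultiIndex columns).  Collapses 1534 classes into wild-homozygous
    (F/F) vs mutant-carrying, restricted to 1532 I/I individuals.
    """
    df = counts.copy()
    if isinstance(df.columns, pd.MultiIndex):
        df.columns = ["+".join(map(str, c)) for c in df.columns]
    df = df.loc[[i for i in df.index if i in ("A", "B")]]
    ii_cols = [c for c in df.columns if c.startswith("I/I+")]
    wild = [c for c in ii_cols if c.endswith("+F/F")]
    mut = [c for c in ii_cols if not c.endswith("+F/F")]
    out = np.column_stack(
        [df[wild].sum(axis=1).to_numpy(), df[mut].sum(axis=1).to_numpy()]
    ).astype(float)
    return out
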