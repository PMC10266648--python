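"""Reference fragments and the kdr allele catalog.

Genotype calls are anchored to three VGSC amplicons (Domain II, III, IV)
with explicit exon/intron layout and explicit codon-number anchors in the
house-fly numbering convention (V1016G on Domain II; I1532T and F1534S/C/I
on Domain III; Domain IV is surveyed but carries no catalogued resistance
allele).  Codon numbers are never derived from sequence — they are
anchored to fragment positions, because the numbering is a community
convention, not a property of the amplicon.

The shipped references are synthetic stand-ins with the same structure as
the susceptible-colony accession fragments a real survey would use; real
sequences can be loaded from a YAML config + FASTA via
:func:`load_references`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml
from Bio import SeqIO
from Bio.Seq import Seq

from .intron import INTRON_SEQUENCES

FRAGMENT_IDS = ("DomainII", "DomainIII", "DomainIV")

WILD = "wild"
WILD_SYNONYMOUS = "wild_synonymous"
MUTANT = "mutant"
UNCATALOGUED = "uncatalogued"

_WILD_CLASS = frozenset({WILD, WILD_SYNONYMOUS})


class InvalidCodonError(ValueError):
    """A codon string that is not three A/C/G/T letters."""


def translate_codon(codon: str) -> str:
    """Standard-genetic-code translation of a 3-letter A/C/G/T codon."""
    codon = codon.upper()
    if len(codon) != 3 or any(b not in "ACGT" for b in codon):
        raise InvalidCodonError(f"not an unambiguous codon: {codon!r}")
    return str(Seq(codon).translate())


@dataclass(frozen=True)
class Segment:
    kind: str  # "exon" | "intron"
    start: int  # 1-based inclusive
    end: int


@dataclass
class ReferenceFragment:
    """One annotated amplicon: sequence, exon/intron tiling, codon anchors."""

    fragment_id: str
    sequence: str
    segments: list[Segment]
    codon_anchor: dict[int, int]  # codon number -> fragment position of first base

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        self.validate()

    def validate(self) -> None:
        if self.fragment_id not in FRAGMENT_IDS:
            raise ValueError(f"unknown fragment id {self.fragment_id!r}")
        pos = 1
        for seg in self.segments:
            if seg.kind not in ("exon", "intron"):
                raise ValueError(f"segment kind {seg.kind!r}")
            if seg.start != pos:
                raise ValueError("segments must tile the fragment without gaps/overlap")
            pos = seg.end + 1
        if pos != len(self.sequence) + 1:
            raise ValueError("segments do not cover the full sequence")
        last = 0
        for codon in sorted(self.codon_anchor):
            start = self.codon_anchor[codon]
            if start <= last:
                raise ValueError("anchored codon positions must be strictly increasing")
            last = start
            if not any(
                s.kind == "exon" and s.start <= start and start + 2 <= s.end
                for s in self.segments
            ):
                raise ValueError(f"codon {codon} does not lie wholly within an exon")

    @property
    def exon_positions(self) -> list[int]:
        return [
            p
            for seg in self.segments
            if seg.kind == "exon"
            for p in range(seg.start, seg.end + 1)
        ]

    def codon_coords(self, codon_number: int) -> tuple[int, int]:
        if codon_number not in self.codon_anchor:
            raise KeyError(
                f"codon {codon_number} is not anchored on {self.fragment_id}"
            )
        start = self.codon_anchor[codon_number]
        return start, start + 2

    def codon_sequence(self, codon_number: int) -> str:
        start, end = self.codon_coords(codon_number)
        return self.sequence[start - 1 : end]


def codon_fragment_coords(frag: ReferenceFragment, codon_number: int) -> tuple[int, int]:
    """1-based inclusive fragment coordinates of an anchored codon."""
    return frag.codon_coords(codon_number)


@dataclass(frozen=True)
class AlleleEntry:
    codon_number: int
    codon: str
    amino_acid: str
    status: str  # wild | wild_synonymous | mutant | uncatalogued


@dataclass(frozen=True)
class CodonSite:
    codon_number: int
    fragment_id: str
    wild_alleles: frozenset[str]
    mutant_alleles: frozenset[str]

    def __post_init__(self) -> None:
        if self.wild_alleles & self.mutant_alleles:
            raise ValueError("wild and mutant allele sets must be disjoint")


class AlleleCatalog:
    """The permitted codon alleles per surveyed site.

    Entry order is meaningful: genotype labels (``F/S``, ``S/C``, ...) list
    alleles in catalog order, wild first — which is also the order the
    field reports them in.
    """

    def __init__(self, sites: dict[int, str], entries: list[AlleleEntry]):
        self.sites = dict(sites)  # codon number -> fragment id
        self._entries: dict[tuple[int, str], AlleleEntry] = {}
        self._order: dict[tuple[int, str], int] = {}
        for e in entries:
            if e.codon_number not in self.sites:
                raise ValueError(f"entry for unknown site {e.codon_number}")
            if translate_codon(e.codon) != e.amino_acid:
                raise ValueError(
                    f"{e.codon} does not translate to {e.amino_acid} at {e.codon_number}"
                )
            key = (e.codon_number, e.codon.upper())
            if key in self._entries:
                raise ValueError(f"duplicate catalog entry {key}")
            self._order[key] = len(self._order)
            self._entries[key] = e
        for codon_number in self.sites:
            self.site(codon_number)  # validates disjointness

    def entries(self) -> list[AlleleEntry]:
        return list(self._entries.values())

    def alleles_at(self, codon_number: int) -> list[str]:
        return [c for (n, c) in self._entries if n == codon_number]

    def site(self, codon_number: int) -> CodonSite:
        wild = frozenset(
            c
            for (n, c), e in self._entries.items()
            if n == codon_number and e.status in _WILD_CLASS
        )
        mut = frozenset(
            c
            for (n, c), e in self._entries.items()
            if n == codon_number and e.status == MUTANT
        )
        return CodonSite(codon_number, self.sites[codon_number], wild, mut)

    def sites_on(self, fragment_id: str) -> list[int]:
        return sorted(n for n, f in self.sites.items() if f == fragment_id)

    def classify(self, codon_number: int, codon: str) -> AlleleEntry:
        """Catalog entry for a codon, or an ``uncatalogued`` entry with the
        standard-genetic-code translation when absent."""
        codon = codon.upper()
        entry = self._entries.get((codon_number, codon))
        if entry is not None:
            return entry
        return AlleleEntry(codon_number, codon, translate_codon(codon), UNCATALOGUED)

    def order_index(self, codon_number: int, codon: str) -> int:
        """Sort key placing catalogued alleles in catalog order, uncatalogued last."""
        return self._order.get((codon_number, codon.upper()), 10_000)

    def is_mutant(self, codon_number: int, codon: str) -> bool:
        return self.classify(codon_number, codon).status == MUTANT


def classify_allele(cat: AlleleCatalog, codon_number: int, codon: str) -> AlleleEntry:
    """Functional wrapper around :meth:`AlleleCatalog.classify`."""
    return cat.classify(codon_number, codon)


def default_catalog() -> AlleleCatalog:
    """The kdr allele catalog for the three surveyed VGSC codons.

    1016: GTA/V wild, GGA/G mutant.  1532: ATC/I wild, ACC/T mutant.
    1534: TTC/F wild, TTT/F synonymous wild, TCC/S, TGC/C and ATC/I
    mutants.  Codon 1763 on Domain IV is anchored with only its wild
    allele, so any nonsynonymous variant there surfaces through the
    novel-allele channel.
    """
    sites = {1016: "DomainII", 1532: "DomainIII", 1534: "DomainIII", 1763: "DomainIV"}
    entries = [
        AlleleEntry(1016, "GTA", "V", WILD),
        AlleleEntry(1016, "GGA", "G", MUTANT),
        AlleleEntry(1532, "ATC", "I", WILD),
        AlleleEntry(1532, "ACC", "T", MUTANT),
        AlleleEntry(1534, "TTC", "F", WILD),
        AlleleEntry(1534, "TTT", "F", WILD_SYNONYMOUS),
        AlleleEntry(1534, "TCC", "S", MUTANT),
        AlleleEntry(1534, "TGC", "C", MUTANT),
        AlleleEntry(1534, "ATC", "I", MUTANT),
        AlleleEntry(1763, "GAC", "D", WILD),
    ]
    return AlleleCatalog(sites, entries)


def _random_exon(rng: np.random.Generator, length: int) -> list[str]:
    return list(rng.choice(list("ACGT"), size=length))


def default_references(cat: AlleleCatalog | None = None) -> dict[str, ReferenceFragment]:
    """Synthetic stand-in reference fragments.

    Deterministic sequences with the survey's amplicon structure: Domain II
    and IV are single exons; Domain III carries one 83 bp (type A) intron
    between two exon blocks, with codons 1532/1534 on the downstream exon.
    Each anchored codon carries the site's wild allele.
    """
    cat = cat or default_catalog()
    rng = np.random.default_rng(20200526)

    def plant(seq: list[str], pos: int, codon: str) -> None:
        seq[pos - 1 : pos + 2] = list(codon)

    # Domain II: 240 bp exon, codon 1016 at 100.
    s2 = _random_exon(rng, 240)
    plant(s2, 100, "GTA")
    d2 = ReferenceFragment(
        "DomainII", "".join(s2), [Segment("exon", 1, 240)], {1016: 100}
    )

    # Domain III: exon 120 bp + intron A (83 bp) + exon 120 bp; 1532 @ 240, 1534 @ 246.
    intron_a = INTRON_SEQUENCES["A"]
    e1 = _random_exon(rng, 120)
    e2 = _random_exon(rng, 120)
    s3 = e1 + list(intron_a) + e2
    plant(s3, 240, "ATC")
    plant(s3, 246, "TTC")
    d3 = ReferenceFragment(
        "DomainIII",
        "".join(s3),
        [Segment("exon", 1, 120), Segment("intron", 121, 203), Segment("exon", 204, 323)],
        {1532: 240, 1534: 246},
    )

    # Domain IV: 210 bp exon, codon 1763 at 90.
    s4 = _random_exon(rng, 210)
    plant(s4, 90, "GAC")
    d4 = ReferenceFragment(
        "DomainIV", "".join(s4), [Segment("exon", 1, 210)], {1763: 90}
    )
    return {f.fragment_id: f for f in (d2, d3, d4)}


# ---------------------------------------------------------------------------
# config round trip

def write_config(
    refs: dict[str, ReferenceFragment],
    cat: AlleleCatalog,
    out_dir: str | Path,
    *,
    stem: str = "references",
) -> Path:
    """Write references + catalog as a YAML config and companion FASTA."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fasta = out_dir / f"{stem}.fasta"
    with fasta.open("w") as fh:
        for frag in refs.values():
            fh.write(f">{frag.fragment_id}\n")
            for i in range(0, len(frag.sequence), 70):
                fh.write(frag.sequence[i : i + 70] + "\n")
    doc = {
        "fasta": fasta.name,
        "fragments": {
            f.fragment_id: {
                "segments": [[s.kind, s.start, s.end] for s in f.segments],
                "codons": {int(k): int(v) for k, v in f.codon_anchor.items()},
            }
            for f in refs.values()
        },
        "catalog": {
            "sites": {int(n): f for n, f in cat.sites.items()},
            "alleles": [
                {"codon_number": e.codon_number, "codon": e.codon,
                 "amino_acid": e.amino_acid, "status": e.status}
                for e in cat.entries()
            ],
        },
    }
    path = out_dir / f"{stem}.yaml"
    path.write_text(yaml.safe_dump(doc, sort_keys=True))
    return path


def load_config(path: str | Path) -> tuple[dict[str, ReferenceFragment], AlleleCatalog]:
    """Load references + catalog written by :func:`write_config`."""
    path = Path(path)
    doc = yaml.safe_load(path.read_text())
    seqs = {
        rec.id: str(rec.seq).upper()
        for rec in SeqIO.parse(path.parent / doc["fasta"], "fasta")
    }
    refs = {}
    for fid, spec in doc["fragments"].items():
        refs[fid] = ReferenceFragment(
            fid,
            seqs[fid],
            [Segment(k, s, e) for k, s, e in spec["segments"]],
            {int(c): int(p) for c, p in spec["codons"].items()},
        )
    cat = AlleleCatalog(
        {int(n): f for n, f in doc["catalog"]["sites"].items()},
        [
            AlleleEntry(a["codon_number"], a["codon"], a["amino_acid"], a["status"])
            for a in doc["catalog"]["alleles"]
        ],
    )
    return refs, cat
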