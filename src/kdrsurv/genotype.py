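"""Diploid codon genotype calling from VGSC amplicon sequences.

A Sanger consensus of a diploid PCR product shows heterozygous positions
as IUPAC ambiguity codes.  Calling a codon genotype therefore means:
align the read to the annotated reference fragment (IUPAC-aware,
semi-global), read off the three bases under the anchored codon, and
enumerate every unordered pair of plain codons whose per-position base
sets reproduce the observed window.  With two or more ambiguous positions
in one codon the phasing is not determined by the consensus alone; the
allele catalog restricts the candidates, and only a uniquely explained
window becomes a call — everything else is reported as ambiguous and
excluded from frequency tables rather than guessed.

Length-heterozygous Domain III individuals may be supplied as two
per-haplotype records (the in-silico analogue of TA cloning); the caller
then phases trivially.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

from . import intron as intron_mod
from ._iupac import ALPHABET, bases_of, compatible
from .refcat import MUTANT, UNCATALOGUED, AlleleCatalog, ReferenceFragment

_WILDISH = ("wild", "wild_synonymous")

#: Default alignment scoring (match/mismatch/gap open/gap extend).
DEFAULT_ALIGN_PARAMS = (2.0, -1.0, -5.0, -1.0)
DEFAULT_IDENTITY_THRESHOLD = 0.80


# ---------------------------------------------------------------------------
# alignment

@dataclass
class AlignmentResult:
    ok: bool
    identity: float
    score: float
    position_map: dict[int, int]  # 1-based reference pos -> 1-based read pos


@functools.lru_cache(maxsize=8)
def _aligner(params: tuple[float, float, float, float]) -> PairwiseAligner:
    match, mismatch, gap_open, gap_extend = params
    matrix = substitution_matrices.Array(alphabet=ALPHABET, dims=2)
    for a in ALPHABET:
        for b in ALPHABET:
            matrix[a, b] = match if compatible(a, b) else mismatch
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    # free end gaps: the read may start/stop anywhere on the fragment
    aligner.open_end_insertion_score = 0.0
    aligner.extend_end_insertion_score = 0.0
    aligner.open_end_deletion_score = 0.0
    aligner.extend_end_deletion_score = 0.0
    return aligner


def _sanitize(seq: str) -> str:
    seq = seq.upper()
    return "".join(c if c in ALPHABET else "N" for c in seq)


def align_to_reference(
    read: str,
    frag: ReferenceFragment,
    *,
    params: tuple[float, float, float, float] = DEFAULT_ALIGN_PARAMS,
    identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD,
) -> AlignmentResult:
    """Semi-global IUPAC-aware alignment of a read to a reference fragment.

    Ambiguity codes match any constituent base at full match score.  The
    acceptance gate is identity over the reference's *exon* positions
    (introns are length-polymorphic by design); below the threshold the
    result is flagged failed and the individual is excluded downstream.
    """
    if not read:
        raise ValueError("empty read")
    read = _sanitize(read)
    aln = _aligner(params).align(frag.sequence, read)[0]
    position_map: dict[int, int] = {}
    for (t0, t1), (q0, q1) in zip(*aln.aligned):
        for k in range(t1 - t0):
            position_map[t0 + k + 1] = q0 + k + 1
    exon = frag.exon_positions
    matches = 0
    for p in exon:
        q = position_map.get(p)
        if q is not None and compatible(frag.sequence[p - 1], read[q - 1]):
            matches += 1
    identity = matches / len(exon)
    return AlignmentResult(
        ok=identity >= identity_threshold,
        identity=identity,
        score=float(aln.score),
        position_map=position_map,
    )


def extract_codon_window(
    alignment: AlignmentResult,
    frag: ReferenceFragment,
    codon_number: int,
    read: str,
) -> str | None:
    """Read bases aligned under the codon's three reference positions.

    Returns ``None`` (failed call) when any position is deleted or not
    covered by the read.
    """
    start, end = frag.codon_coords(codon_number)
    read = _sanitize(read)
    bases = []
    for p in range(start, end + 1):
        q = alignment.position_map.get(p)
        if q is None:
            return None
        bases.append(read[q - 1])
    return "".join(bases)


# ---------------------------------------------------------------------------
# diploid codon decoding

@dataclass
class CodonGenotypeCall:
    """An unordered diploid pair of codon alleles at one surveyed site."""

    codon_number: int
    allele_pair: tuple[str, str] | None
    aa_genotype: str | None
    zygosity: str | None  # wild_hom | het_wild_mut | mut_hom | mut_het
    resolution: str  # unique | ambiguous | failed
    notes: list[str] = field(default_factory=list)
    candidates: list[tuple[str, str]] = field(default_factory=list)

    @property
    def has_mutant(self) -> bool:
        return self.zygosity in ("het_wild_mut", "mut_hom", "mut_het")


def enumerate_window_pairs(window: str) -> list[tuple[str, str]]:
    """All unordered plain-codon pairs whose per-position base sets equal
    the window's IUPAC base sets.  Raises on codes encoding >2 bases."""
    sets = [bases_of(b) for b in window]
    if any(len(s) > 2 for s in sets):
        raise ValueError("position encodes more than two bases")
    options = []
    for s in sets:
        bs = sorted(s)
        if len(bs) == 1:
            options.append([(bs[0], bs[0])])
        else:
            options.append([(bs[0], bs[1]), (bs[1], bs[0])])
    pairs = set()
    for combo in product(*options):
        x = "".join(c[0] for c in combo)
        y = "".join(c[1] for c in combo)
        pairs.add((x, y) if x <= y else (y, x))
    return sorted(pairs)


def _site_wild_aa(cat: AlleleCatalog, codon_number: int) -> str | None:
    for e in cat.entries():
        if e.codon_number == codon_number and e.status == "wild":
            return e.amino_acid
    return None


def call_from_pair(
    pair: tuple[str, str],
    cat: AlleleCatalog,
    codon_number: int,
    *,
    notes: Iterable[str] = (),
) -> CodonGenotypeCall:
    """Build a unique-resolution call from an explicit allele pair.

    Allele order in the label follows catalog order (wild allele first,
    mutants in their reported order); uncatalogued alleles sort last.
    """
    ordered = sorted(
        pair, key=lambda c: (cat.order_index(codon_number, c), c)
    )
    entries = [cat.classify(codon_number, c) for c in ordered]
    notes = list(notes)
    wild_aa = _site_wild_aa(cat, codon_number)

    def mutant_like(e) -> bool:
        if e.status == MUTANT:
            return True
        return e.status == UNCATALOGUED and e.amino_acid != wild_aa

    for e in entries:
        if e.status == "wild_synonymous":
            notes.append(f"synonymous wild allele {e.codon} present")
        if e.status == UNCATALOGUED:
            notes.append(f"uncatalogued allele {e.codon} ({e.amino_acid})")
    flags = [mutant_like(e) for e in entries]
    if not any(flags):
        zyg = "wild_hom"
    elif all(flags):
        zyg = "mut_hom" if ordered[0] == ordered[1] else "mut_het"
    else:
        zyg = "het_wild_mut"
    return CodonGenotypeCall(
        codon_number=codon_number,
        allele_pair=(ordered[0], ordered[1]),
        aa_genotype=f"{entries[0].amino_acid}/{entries[1].amino_acid}",
        zygosity=zyg,
        resolution="unique",
        notes=notes,
    )


def decode_diploid_codon(
    window: str, cat: AlleleCatalog, codon_number: int
) -> CodonGenotypeCall:
    """Decode a 3-letter IUPAC codon window into a diploid genotype call.

    Exactly one catalog-consistent pair -> unique call.  Several -> the
    phasing is genuinely ambiguous: candidates are listed and the call is
    excluded from counts.  No fully catalogued pair -> the window is
    explainable only with a novel allele, and becomes a unique flagged
    call only when a single such explanation exists.
    """
    try:
        pairs = enumerate_window_pairs(window)
    except ValueError as exc:
        return CodonGenotypeCall(
            codon_number, None, None, None, "failed", notes=[str(exc)]
        )
    catalogued = [
        p
        for p in pairs
        if cat.classify(codon_number, p[0]).status != UNCATALOGUED
        and cat.classify(codon_number, p[1]).status != UNCATALOGUED
    ]
    if len(catalogued) == 1:
        return call_from_pair(catalogued[0], cat, codon_number)
    if len(catalogued) > 1:
        return CodonGenotypeCall(
            codon_number,
            None,
            None,
            None,
            "ambiguous",
            notes=["multiple catalog-consistent phasings"],
            candidates=catalogued,
        )
    if len(pairs) == 1:  # only explanation involves an uncatalogued allele
        return call_from_pair(pairs[0], cat, codon_number)
    return CodonGenotypeCall(
        codon_number,
        None,
        None,
        None,
        "ambiguous",
        notes=["no catalog-consistent phasing; multiple novel-allele explanations"],
        candidates=pairs,
    )


# ---------------------------------------------------------------------------
# per-individual calling

@dataclass
class AmpliconRead:
    population: str
    individual: str
    fragment: str
    sequence: str
    haplotype: int | None = None  # 1/2 for per-haplotype records

    @classmethod
    def from_header(cls, header: str, sequence: str) -> "AmpliconRead":
        parts = header.split("|")
        if len(parts) not in (3, 4):
            raise ValueError(
                f"header {header!r}: expected population|individual|fragment[|hapN]"
            )
        hap = None
        if len(parts) == 4:
            if not parts[3].startswith("hap"):
                raise ValueError(f"header {header!r}: bad haplotype flag {parts[3]!r}")
            hap = int(parts[3][3:])
        return cls(parts[0], parts[1], parts[2], sequence, hap)


@dataclass
class IndividualRecord:
    """One mosquito: per-site calls, intron observations, carrier status."""

    individual_id: str
    population_code: str
    calls: dict[int, CodonGenotypeCall]
    intron_observations: list[intron_mod.IntronObservation] = field(default_factory=list)
    mutant_carrier: bool = False
    novel_alleles: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


def _failed(codon_number: int, why: str) -> CodonGenotypeCall:
    return CodonGenotypeCall(codon_number, None, None, None, "failed", notes=[why])


def call_individual(
    reads: Mapping[str, list[AmpliconRead]],
    refs: Mapping[str, ReferenceFragment],
    cat: AlleleCatalog,
    *,
    identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD,
    align_params: tuple[float, float, float, float] = DEFAULT_ALIGN_PARAMS,
) -> IndividualRecord:
    """Call all anchored codons (and the Domain III intron) for one individual.

    ``reads`` maps fragment id to either one consensus record or two
    per-haplotype records.  Missing fragments fail their sites; a failed
    alignment fails the fragment's sites and is logged on the record.
    """
    if not any(reads.values()):
        raise ValueError("at least one fragment read is required")
    first = next(r for rl in reads.values() for r in rl)
    rec = IndividualRecord(first.individual, first.population, {})

    for fid, frag in refs.items():
        sites = cat.sites_on(fid)
        rlist = list(reads.get(fid, []))
        if not rlist:
            for s in sites:
                rec.calls[s] = _failed(s, "fragment missing")
            continue
        haps = sorted(r.haplotype for r in rlist if r.haplotype is not None)
        if len(rlist) == 1 and rlist[0].haplotype is None:
            _call_consensus(rec, rlist[0], frag, sites, cat,
                            identity_threshold, align_params)
        elif len(rlist) == 2 and haps == [1, 2]:
            ordered = sorted(rlist, key=lambda r: r.haplotype)
            _call_haplotypes(rec, ordered, frag, sites, cat,
                             identity_threshold, align_params)
        else:
            raise ValueError(
                f"{rec.population_code}|{rec.individual_id}: duplicate {fid} records "
                "without hap1/hap2 flags"
            )

    rec.mutant_carrier = any(
        c.resolution == "unique"
        and c.allele_pair is not None
        and any(cat.is_mutant(c.codon_number, a) for a in c.allele_pair)
        for c in rec.calls.values()
    )
    for c in rec.calls.values():
        if c.resolution == "unique" and c.allele_pair:
            for a in c.allele_pair:
                e = cat.classify(c.codon_number, a)
                if e.status == UNCATALOGUED:
                    tag = f"{c.codon_number}:{a}({e.amino_acid})"
                    if tag not in rec.novel_alleles:
                        rec.novel_alleles.append(tag)
    return rec


def _call_consensus(rec, read, frag, sites, cat, thr, params) -> None:
    aln = align_to_reference(read.sequence, frag,
                             params=params, identity_threshold=thr)
    if not aln.ok:
        rec.warnings.append(
            f"{frag.fragment_id}: alignment failed (exon identity {aln.identity:.3f})"
        )
        for s in sites:
            rec.calls[s] = _failed(s, "alignment failed")
        return
    for s in sites:
        window = extract_codon_window(aln, frag, s, read.sequence)
        if window is None:
            rec.calls[s] = _failed(s, "codon not covered by read")
        else:
            rec.calls[s] = decode_diploid_codon(window, cat, s)
    if any(seg.kind == "intron" for seg in frag.segments):
        try:
            seq, warns = intron_mod.extract_intron(
                _sanitize(read.sequence), frag, aln.position_map
            )
        except intron_mod.IntronExtractionError as exc:
            rec.warnings.append(f"{frag.fragment_id}: intron extraction failed ({exc})")
        else:
            rec.intron_observations.append(
                intron_mod.classify_intron(
                    seq, individual_id=rec.individual_id, warnings=warns
                )
            )


def _call_haplotypes(rec, rlist, frag, sites, cat, thr, params) -> None:
    alns = []
    for r in rlist:
        aln = align_to_reference(r.sequence, frag,
                                 params=params, identity_threshold=thr)
        if not aln.ok:
            rec.warnings.append(
                f"{frag.fragment_id} hap{r.haplotype}: alignment failed "
                f"(exon identity {aln.identity:.3f})"
            )
        alns.append(aln)
    if not all(a.ok for a in alns):
        for s in sites:
            rec.calls[s] = _failed(s, "haplotype alignment failed")
        return
    for s in sites:
        codons = []
        for r, aln in zip(rlist, alns):
            w = extract_codon_window(aln, frag, s, r.sequence)
            if w is None:
                codons = None
                break
            if any(b not in "ACGT" for b in w):
                rec.warnings.append(
                    f"{frag.fragment_id} hap{r.haplotype}: ambiguity inside haplotype codon"
                )
                codons = None
                break
            codons.append(w)
        if codons is None:
            rec.calls[s] = _failed(s, "haplotype codon not recoverable")
        else:
            rec.calls[s] = call_from_pair(
                (codons[0], codons[1]), cat, s, notes=["haplotype-resolved"]
            )
    if any(seg.kind == "intron" for seg in frag.segments):
        for r, aln in zip(rlist, alns):
            try:
                seq, warns = intron_mod.extract_intron(
                    _sanitize(r.sequence), frag, aln.position_map
                )
            except intron_mod.IntronExtractionError as exc:
                rec.warnings.append(
                    f"{frag.fragment_id} hap{r.haplotype}: intron extraction failed ({exc})"
                )
            else:
                rec.intron_observations.append(
                    intron_mod.classify_intron(
                        seq,
                        individual_id=rec.individual_id,
                        haplotype_resolved=True,
                        warnings=warns,
                    )
                )


# ---------------------------------------------------------------------------
# dataset-level driver

def _iter_seq_records(fasta):
    if isinstance(fasta, (str, Path)):
        yield from SeqIO.parse(str(fasta), "fasta")
        return
    items = list(fasta)
    if items and isinstance(items[0], (str, Path)):
        for f in items:
            yield from SeqIO.parse(str(f), "fasta")
    else:
        yield from items


def read_amplicons(fasta: str | Path | Iterable) -> dict[tuple[str, str], dict[str, list[AmpliconRead]]]:
    """Group FASTA records by individual, preserving input order.

    ``fasta`` may be one path, several paths (e.g. one file per
    fragment), or an iterable of Bio.SeqRecord objects.  Headers follow
    ``population|individual|fragment[|hapN]``.
    """
    records = _iter_seq_records(fasta)
    grouped: dict[tuple[str, str], dict[str, list[AmpliconRead]]] = {}
    for rec in records:
        r = AmpliconRead.from_header(rec.id, str(rec.seq))
        grouped.setdefault((r.population, r.individual), {}).setdefault(
            r.fragment, []
        ).append(r)
    return grouped


def call_dataset(
    fasta: str | Path | Iterable,
    refs: Mapping[str, ReferenceFragment],
    cat: AlleleCatalog,
    **kwargs,
) -> list[IndividualRecord]:
    """Genotype every individual in a FASTA dataset."""
    return [
        call_individual(reads, refs, cat, **kwargs)
        for reads in read_amplicons(fasta).values()
    ]


SITE_COLUMNS = (1016, 1532, 1534)


def records_to_frame(records: Iterable[IndividualRecord]) -> pd.DataFrame:
    """Flatten individual records into the calls table (one row per mosquito)."""
    rows = []
    for rec in records:
        row: dict[str, object] = {
            "population": rec.population_code,
            "individual": rec.individual_id,
        }
        for s in SITE_COLUMNS:
            c = rec.calls.get(s) or _failed(s, "site not called")
            row[f"{s}_alleles"] = "/".join(c.allele_pair) if c.allele_pair else ""
            row[f"{s}_aa"] = c.aa_genotype or ""
            row[f"{s}_zygosity"] = c.zygosity or ""
            row[f"{s}_resolution"] = c.resolution
        pair = intron_mod.resolved_type_pair(rec.intron_observations)
        row["intron_types"] = "/".join(pair) if pair else ""
        row["intron_lengths"] = ";".join(
            str(o.length) for o in rec.intron_observations
        )
        row["intron_subtypes"] = ";".join(
            o.subtype for o in rec.intron_observations
        )
        row["mutant_carrier"] = bool(rec.mutant_carrier)
        row["novel_alleles"] = ";".join(rec.novel_alleles)
        row["warnings"] = ";".join(rec.warnings)
        rows.append(row)
    return pd.DataFrame(rows)
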