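"""Codon-level enumeration and scoring of spectrum-specific substitutions.

For every codon of a coding sequence, every directed single-nucleotide change
belonging to a mutational spectrum is applied at each of the three positions;
the resulting amino-acid substitutions are classified (synonymous, missense,
nonsense, stop-affected) and the missense ones are scored under a pairwise
amino-acid matrix.  Genome-level reports average over all spectrum-consistent
missense substitutions across all included codons (codon-occurrence-weighted)
and stratify by COG functional category.

The translation table is the bacterial code (NCBI table 11); start codons are
treated as ordinary codons, since disruption concerns the encoded residue,
not initiation.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable

from .matrices import ScoreMatrix
from .spectra import BASES, MutationalSpectrum

_TABLE11 = CodonTable.unambiguous_dna_by_id[11]
STOP_CODONS = frozenset(_TABLE11.stop_codons)

__all__ = [
    "CdsRecord",
    "Substitution",
    "SubstitutionSummary",
    "GenomeScoreReport",
    "AmbiguousCodonError",
    "translate_codon",
    "enumerate_substitutions",
    "score_substitutions",
    "score_genome",
    "gc_content",
    "compare_spectra",
    "read_cds_fasta",
    "read_cog_table",
    "load_genome",
]


class AmbiguousCodonError(ValueError):
    """Codon contains a base outside {A, C, G, T} (e.g. N, R, Y)."""


@dataclass
class CdsRecord:
    """One predicted coding sequence with its COG functional category."""

    id: str
    sequence: str
    cog: str | None = None

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()

    def codons(self) -> list[str]:
        seq = self.sequence
        usable = len(seq) - len(seq) % 3  # trailing partial codon dropped
        return [seq[i:i + 3] for i in range(0, usable, 3)]


class Substitution(NamedTuple):
    position: int          # 0-based position within the codon
    change: tuple[str, str]
    from_aa: str           # one-letter code, or '*' for stop
    to_aa: str
    kind: str              # synonymous | missense | nonsense | stop_affected


@dataclass
class SubstitutionSummary:
    mean_score: float | None
    n_missense: int
    n_synonymous: int
    n_nonsense: int
    n_stop_affected: int = 0


@dataclass
class GenomeScoreReport:
    """Average disruption of one spectrum on one genome under one matrix."""

    genome: str
    spectrum: str
    matrix: str
    gc_content: float
    mean_score: float | None
    n_missense: int
    n_synonymous: int
    n_nonsense: int
    n_stop_affected: int
    n_codons: int
    n_excluded_codons: int
    n_internal_stops: int
    n_cds: int
    higher_is_disruptive: bool
    cog_filter: str | None = None

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def translate_codon(codon: str) -> str:
    """Translate under the bacterial code; '*' for stop codons."""
    if codon in STOP_CODONS:
        return "*"
    try:
        return _TABLE11.forward_table[codon]
    except KeyError:
        raise AmbiguousCodonError(f"codon {codon!r} contains ambiguous bases") from None


def enumerate_substitutions(codon: str,
                            spectrum: MutationalSpectrum) -> list[Substitution]:
    """All single-nucleotide substitutions of ``codon`` accessible to ``spectrum``.

    Returns one entry per (position, applicable directed change), ordered by
    position then change.  Raises :class:`AmbiguousCodonError` on codons with
    non-ACGT symbols, which callers exclude from analysis.
    """
    codon = codon.upper()
    if len(codon) != 3 or any(b not in BASES for b in codon):
        raise AmbiguousCodonError(f"not an unambiguous codon: {codon!r}")
    from_aa = translate_codon(codon)
    out: list[Substitution] = []
    for pos in range(3):
        for change in spectrum.applicable(codon[pos]):
            mutant = codon[:pos] + change[1] + codon[pos + 1:]
            to_aa = translate_codon(mutant)
            if from_aa == "*":
                kind = "stop_affected"  # stop-loss (or stop->stop)
            elif to_aa == "*":
                kind = "nonsense"
            elif to_aa == from_aa:
                kind = "synonymous"
            else:
                kind = "missense"
            out.append(Substitution(pos, change, from_aa, to_aa, kind))
    return out


def score_substitutions(substitutions: Iterable[Substitution],
                        matrix: ScoreMatrix) -> SubstitutionSummary:
    """Score missense substitutions; count the rest without scoring them.

    Synonymous changes are excluded from the mean because a distance matrix
    has no meaningful diagonal; nonsense (stop-gain) and stop-affected
    changes are excluded because neither matrix defines stop scores.
    """
    total = 0.0
    n_mis = n_syn = n_non = n_stop = 0
    for sub in substitutions:
        if sub.kind == "missense":
            total += matrix.score(sub.from_aa, sub.to_aa)
            n_mis += 1
        elif sub.kind == "synonymous":
            n_syn += 1
        elif sub.kind == "nonsense":
            n_non += 1
        else:
            n_stop += 1
    return SubstitutionSummary(
        mean_score=total / n_mis if n_mis else None,
        n_missense=n_mis, n_synonymous=n_syn, n_nonsense=n_non,
        n_stop_affected=n_stop,
    )


@lru_cache(maxsize=512)
def _codon_table_for(spectrum: MutationalSpectrum, matrix: ScoreMatrix
                     ) -> dict[str, tuple[float, int, int, int, int]]:
    """Per-codon (score_sum, n_missense, n_syn, n_nonsense, n_stop) lookup.

    There are only 64 unambiguous codons, so genome scoring reduces to codon
    counting plus this table.
    """
    table = {}
    for b1 in BASES:
        for b2 in BASES:
            for b3 in BASES:
                codon = b1 + b2 + b3
                subs = enumerate_substitutions(codon, spectrum)
                s = sum(matrix.score(x.from_aa, x.to_aa)
                        for x in subs if x.kind == "missense")
                kinds = Counter(x.kind for x in subs)
                table[codon] = (s, kinds["missense"], kinds["synonymous"],
                                kinds["nonsense"], kinds["stop_affected"])
    return table


def gc_content(sequences: Iterable[str] | str) -> float:
    """Fraction of G+C over countable (ACGT) bases; ambiguous symbols excluded."""
    if isinstance(sequences, str):
        sequences = [sequences]
    gc = at = 0
    for seq in sequences:
        c = Counter(seq.upper())
        gc += c["G"] + c["C"]
        at += c["A"] + c["T"]
    if gc + at == 0:
        raise ValueError("no countable (ACGT) bases in input")
    return gc / (gc + at)


def score_genome(cds_set: Sequence[CdsRecord],
                 spectrum: MutationalSpectrum,
                 matrix: ScoreMatrix,
                 cog_filter: set[str] | None = None,
                 genome_id: str = "genome") -> GenomeScoreReport:
    """Aggregate spectrum-specific substitution scores over a CDS set.

    Terminal stop codons and codons with ambiguous bases are excluded;
    internal stop codons are counted as a data-quality warning and skipped.
    Mean score is over all missense substitutions across all included codons.
    """
    if not cds_set:
        raise ValueError("empty CDS set")
    if cog_filter is not None:
        kept = [r for r in cds_set if r.cog in cog_filter]
        if not kept:
            raise ValueError(
                f"COG filter {sorted(cog_filter)} removed all {len(cds_set)} CDSs"
            )
    else:
        kept = list(cds_set)

    codon_counts: Counter[str] = Counter()
    n_excluded = n_internal_stop = 0
    for rec in kept:
        codons = rec.codons()
        if codons and codons[-1] in STOP_CODONS:
            codons = codons[:-1]  # terminal stop never enumerated
        for i, codon in enumerate(codons):
            if any(b not in BASES for b in codon):
                n_excluded += 1
            elif codon in STOP_CODONS:
                n_internal_stop += 1
            else:
                codon_counts[codon] += 1

    table = _codon_table_for(spectrum, matrix)
    total = 0.0
    n_mis = n_syn = n_non = n_stop = 0
    for codon, count in codon_counts.items():
        s, mis, syn, non, stp = table[codon]
        total += count * s
        n_mis += count * mis
        n_syn += count * syn
        n_non += count * non
        n_stop += count * stp

    return GenomeScoreReport(
        genome=genome_id, spectrum=spectrum.name, matrix=matrix.name,
        gc_content=gc_content([r.sequence for r in kept]),
        mean_score=total / n_mis if n_mis else None,
        n_missense=n_mis, n_synonymous=n_syn, n_nonsense=n_non,
        n_stop_affected=n_stop,
        n_codons=sum(codon_counts.values()),
        n_excluded_codons=n_excluded, n_internal_stops=n_internal_stop,
        n_cds=len(kept), higher_is_disruptive=matrix.higher_is_disruptive,
        cog_filter="".join(sorted(cog_filter)) if cog_filter else None,
    )


def compare_spectra(genomes: Mapping[str, Sequence[CdsRecord]],
                    spectra: Sequence[MutationalSpectrum],
                    matrices: Sequence[ScoreMatrix],
                    cog_filter: set[str] | None = None) -> pd.DataFrame:
    """Long-format table: one row per (genome, spectrum, matrix).

    Columns include the genome GC content and the mean disruption score, so
    the table plots directly as score vs GC per spectrum.  Per-genome errors
    are re-raised with the genome id attached.
    """
    if not genomes:
        raise ValueError("need at least one genome")
    rows = []
    for gid, cds_set in genomes.items():
        for spectrum in spectra:
            for matrix in matrices:
                try:
                    rep = score_genome(cds_set, spectrum, matrix,
                                       cog_filter=cog_filter, genome_id=gid)
                except Exception as exc:
                    raise RuntimeError(f"scoring failed for genome {gid!r}: {exc}") from exc
                rows.append(rep.to_dict())
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# input readers
# ---------------------------------------------------------------------------

def read_cds_fasta(path: str | Path) -> list[CdsRecord]:
    """Read nucleotide CDS records from a (multi-)FASTA file."""
    return [CdsRecord(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def read_cog_table(path: str | Path) -> dict[str, str]:
    """Read a gene_id -> COG category mapping from a two-column TSV."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = [c for c in ("gene_id", "cog_category") if c in df.columns]
    if len(cols) != 2:
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["gene_id", "cog_category"], dtype=str)
    return dict(zip(df["gene_id"], df["cog_category"]))


def load_genome(fasta: str | Path, annot: str | Path | None = None) -> list[CdsRecord]:
    """Read CDS FASTA and, when given, attach COG categories from a TSV."""
    records = read_cds_fasta(fasta)
    if annot is not None:
        cogs = read_cog_table(annot)
        for rec in records:
            rec.cog = cogs.get(rec.id)
    return records
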