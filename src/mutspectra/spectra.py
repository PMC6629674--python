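"""Mutational spectra: directed single-nucleotide change sets of mutator classes.

Spectra are written as complementary-strand-symmetric pairs applied on the
coding strand: the mutY-deficient spectrum G:C -> T:A means both G->T and
C->A at coding-strand positions, and so on.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import FrozenSet, Iterable, Tuple

BASES = ("A", "C", "G", "T")

Change = Tuple[str, str]


@dataclass(frozen=True)
class MutationalSpectrum:
    """A named set of directed single-nucleotide changes on the coding strand."""

    name: str
    changes: FrozenSet[Change]

    def __post_init__(self) -> None:
        for frm, to in self.changes:
            if frm not in BASES or to not in BASES:
                raise ValueError(f"non-canonical base in change {frm}->{to}")
            if frm == to:
                raise ValueError(f"change {frm}->{to} maps a base to itself")

    def applicable(self, base: str) -> list[Change]:
        """Changes whose source base matches ``base``, in deterministic order."""
        return sorted(c for c in self.changes if c[0] == base)

    def __str__(self) -> str:  # pragma: no cover
        body = ", ".join(f"{a}>{b}" for a, b in sorted(self.changes))
        return f"{self.name}({body})"


def _spectrum(name: str, pairs: Iterable[str]) -> MutationalSpectrum:
    return MutationalSpectrum(name, frozenset((p[0], p[1]) for p in pairs))


ALL_CHANGES = frozenset((a, b) for a in BASES for b in BASES if a != b)

#: mutY-deficient mutators elevate G:C -> T:A transversions
MUTY = _spectrum("mutY", ["GT", "CA"])
#: mutT-deficient mutators elevate A:T -> C:G transversions
MUTT = _spectrum("mutT", ["AC", "TG"])
#: mismatch-repair-deficient mutators elevate both transitions
MMR = _spectrum("MMR", ["GA", "CT", "AG", "TC"])
#: all 12 directed changes, equally weighted
UNBIASED = MutationalSpectrum("unbiased", ALL_CHANGES)

BUILTIN_SPECTRA = {s.name: s for s in (MUTY, MUTT, MMR, UNBIASED)}

#: the six canonical point-mutation classes as complementary change pairs
CANONICAL_CLASSES = {
    "G:C>T:A": _spectrum("G:C>T:A", ["GT", "CA"]),
    "A:T>C:G": _spectrum("A:T>C:G", ["AC", "TG"]),
    "G:C>A:T": _spectrum("G:C>A:T", ["GA", "CT"]),
    "A:T>G:C": _spectrum("A:T>G:C", ["AG", "TC"]),
    "G:C>C:G": _spectrum("G:C>C:G", ["GC", "CG"]),
    "A:T>T:A": _spectrum("A:T>T:A", ["AT", "TA"]),
}


def get_spectrum(name: str) -> MutationalSpectrum:
    """Look up a built-in spectrum by name (case-sensitive)."""
    try:
        return BUILTIN_SPECTRA[name]
    except KeyError:
        raise KeyError(
            f"unknown spectrum {name!r}; built-ins: {sorted(BUILTIN_SPECTRA)}"
        ) from None
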