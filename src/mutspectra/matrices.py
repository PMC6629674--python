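"""Amino-acid substitution score matrices (Grantham distance, BLOSUM100).

Two dialects are supported: the AAindex-style lower-triangular entry used for
the Grantham physicochemical distance, and the NCBI whitespace-aligned square
format used for BLOSUM100.  Both loaders verify symmetry and completeness
over the 20 canonical amino acids.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping

AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"


@dataclass(frozen=True, eq=False)  # identity-hashed: ``scores`` is a dict
class ScoreMatrix:
    """Symmetric pairwise amino-acid scores.

    ``higher_is_disruptive`` is True for distance matrices (Grantham: larger
    distance = more disruptive substitution) and False for log-odds matrices
    (BLOSUM100: larger score = more conservative).
    """

    name: str
    kind: str  # "distance" | "log_odds"
    scores: Mapping[tuple[str, str], float]
    higher_is_disruptive: bool

    def __post_init__(self) -> None:
        need_diag = self.kind == "log_odds"
        for i, a in enumerate(AMINO_ACIDS):
            for b in AMINO_ACIDS[i + int(not need_diag):]:
                if (a, b) not in self.scores:
                    raise ValueError(f"{self.name}: missing pair ({a}, {b})")
        for (a, b), v in self.scores.items():
            if self.scores[(b, a)] != v:
                raise ValueError(f"{self.name}: asymmetric at ({a}, {b})")

    def score(self, a: str, b: str) -> float:
        try:
            return self.scores[(a, b)]
        except KeyError:
            raise KeyError(f"pair ({a}, {b}) not covered by matrix {self.name}") from None


def _data_path(filename: str) -> Path:
    return Path(str(resources.files("mutspectra") / "data" / filename))


def load_grantham(path: str | Path | None = None) -> ScoreMatrix:
    """Parse the Grantham distance matrix from an AAindex-style triangular entry.

    The entry's ``M rows = ..., cols = ...`` line fixes the amino-acid order;
    the following lines hold the lower triangle (diagonal included, zero).
    """
    path = _data_path("grantham.txt") if path is None else Path(path)
    order: str | None = None
    rows: list[list[float]] = []
    for line in path.read_text().splitlines():
        line = line.rstrip()
        if line.startswith("M ") and "rows" in line:
            order = line.split("rows =")[1].split(",")[0].strip()
            continue
        if order is None or not line or line.startswith(("H ", "D ", "A ", "T ", "J ", "//")):
            if line.startswith("//"):
                break
            continue
        rows.append([float(tok) for tok in line.split()])
    if order is None or len(rows) != len(order):
        raise ValueError(f"malformed AAindex-style entry in {path}")
    scores: dict[tuple[str, str], float] = {}
    for i, row in enumerate(rows):
        for j, v in enumerate(row):
            a, b = order[i], order[j]
            if a != b:
                scores[(a, b)] = scores[(b, a)] = v
            elif v != 0:
                raise ValueError("Grantham distance must be zero on the diagonal")
            else:
                scores[(a, a)] = 0.0
    if any(v < 0 for v in scores.values()):
        raise ValueError("Grantham distances must be non-negative")
    return ScoreMatrix("grantham", "distance", scores, higher_is_disruptive=True)


def load_blosum100(path: str | Path | None = None) -> ScoreMatrix:
    """Parse BLOSUM100 from the NCBI whitespace-aligned square text format.

    Ambiguity codes (B, Z, X) and the stop column (*) are ignored.
    """
    path = _data_path("blosum100.txt") if path is None else Path(path)
    header: list[str] | None = None
    scores: dict[tuple[str, str], float] = {}
    for line in path.read_text().splitlines():
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        toks = line.split()
        if header is None:
            header = toks
            continue
        row_aa, vals = toks[0], toks[1:]
        if row_aa not in AMINO_ACIDS:
            continue
        for col_aa, v in zip(header, vals):
            if col_aa in AMINO_ACIDS:
                scores[(row_aa, col_aa)] = float(v)
    mat = ScoreMatrix("blosum100", "log_odds", scores, higher_is_disruptive=False)
    return mat


BUILTIN_MATRICES = {"grantham": load_grantham, "blosum100": load_blosum100}


def get_matrix(name: str) -> ScoreMatrix:
    """Load a bundled matrix by name, or parse a user file by path."""
    key = str(name).lower()
    if key in BUILTIN_MATRICES:
        return BUILTIN_MATRICES[key]()
    p = Path(name)
    if p.exists():
        text = p.read_text()
        if "rows =" in text:
            return load_grantham(p)
        return load_blosum100(p)
    raise KeyError(f"unknown matrix {name!r}; built-ins: {sorted(BUILTIN_MATRICES)}")
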