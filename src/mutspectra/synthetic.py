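"""Synthetic CDS panels with a controllable genomic GC gradient.

Stands in for a panel of real bacterial genomes spanning genomic GC from
roughly 0.25 to 0.70.  Codon usage is the stationary outcome of two opposing
pressures, mirroring how real genomes conform to compositional bias:

* a GC-biased mutation pressure, acting much more strongly on synonymous
  third positions than on the constrained first/second positions (codon
  weight factor ``theta**(GC3 + gamma * GC12)``, gamma < 1, as in real
  bacteria where GC3 varies far more than GC12);
* purifying selection on the encoded residue: each site prefers an amino
  acid drawn from a typical bacterial proteome profile, and a codon encoding
  a different residue is penalised by a coarse biochemical exchange cost,
  with a rigidity surcharge for tryptophan, cysteine and glycine (classic
  low-exchangeability residues).

The second ingredient is what concentrates the residual G/C of AT-rich
genomes (and residual A/T of GC-rich genomes) in hard-to-replace residues --
the compositional signature that makes different mutator spectra differ in
their average protein-disruptive effect.  theta is solved numerically so the
expected CDS GC matches the requested target.

A plain neutral tilt (weight proportional to ``theta**GC(codon)``) is also
provided as :func:`calibrate_codon_weights`; it controls GC equally well but
produces no spectrum-by-GC interaction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from functools import lru_cache
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import brentq

from .scoring import CdsRecord, STOP_CODONS, gc_content, translate_codon

#: the 61 sense codons of the bacterial code, lexicographic order
SENSE_CODONS = tuple(
    b1 + b2 + b3
    for b1 in "ACGT" for b2 in "ACGT" for b3 in "ACGT"
    if b1 + b2 + b3 not in STOP_CODONS
)
_GC_COUNT = np.array([sum(b in "GC" for b in c) for c in SENSE_CODONS], dtype=float)
_GC12 = np.array([sum(b in "GC" for b in c[:2]) for c in SENSE_CODONS], dtype=float)
_GC3 = _GC_COUNT - _GC12
_AA_OF = tuple(translate_codon(c) for c in SENSE_CODONS)

#: expected GC fraction under uniform usage of the 61 sense codons
UNIFORM_GC = float(_GC_COUNT.mean() / 3.0)

#: typical bacterial proteome amino-acid frequencies (preferred-residue profile)
PROTEOME_PROFILE = {
    "A": 0.089, "R": 0.055, "N": 0.040, "D": 0.054, "C": 0.012,
    "Q": 0.039, "E": 0.061, "G": 0.074, "H": 0.022, "I": 0.060,
    "L": 0.102, "K": 0.059, "M": 0.024, "F": 0.041, "P": 0.044,
    "S": 0.063, "T": 0.054, "W": 0.013, "Y": 0.033, "V": 0.069,
}

#: coarse biochemical exchange classes used by the selection penalty
EXCHANGE_CLASSES = {
    **{a: "aliphatic" for a in "AVLIM"},
    **{a: "aromatic" for a in "FWY"},
    **{a: "polar" for a in "STNQP"},
    **{a: "positive" for a in "KRH"},
    **{a: "negative" for a in "DE"},
    **{a: "special" for a in "GC"},
}
#: residues whose replacement carries an extra cost (low exchangeability)
RIGID_RESIDUES = frozenset("WCG")

#: exchange costs (in units of the Boltzmann weight exponent)
SAME_CLASS_COST = 1.0
CROSS_CLASS_COST = 4.0
RIGIDITY_SURCHARGE = 6.0
#: relative strength of GC pressure on first/second vs third codon positions
POSITION_WEIGHT_GC12 = 0.25

DEFAULT_COG_PROPORTIONS = {"H": 0.10, "J": 0.15, "M": 0.10, "S": 0.65}
DEFAULT_PANEL_GC = (0.25, 0.35, 0.45, 0.55, 0.65, 0.70)


@dataclass(frozen=True)
class GenomeSpec:
    """Recipe for one synthetic genome."""

    gc_target: float
    n_genes: int = 500
    mean_len_codons: int = 300
    cog_proportions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COG_PROPORTIONS)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.2 <= self.gc_target <= 0.75:
            raise ValueError(f"gc_target {self.gc_target} outside [0.2, 0.75]")
        if self.n_genes < 0:
            raise ValueError("n_genes must be >= 0")
        total = sum(self.cog_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"cog_proportions must sum to 1, got {total}")
        if not {"H", "J", "M"} <= set(self.cog_proportions):
            raise ValueError("cog_proportions must include categories H, J and M")


# ---------------------------------------------------------------------------
# codon-weight calibration
# ---------------------------------------------------------------------------

def _expected_gc_plain(theta: float) -> float:
    w = theta ** _GC_COUNT
    return float((w @ _GC_COUNT) / (3.0 * w.sum()))


def calibrate_codon_weights(gc_target: float,
                            tol: float = 1e-6) -> tuple[np.ndarray, float]:
    """Neutral codon tilt: weights w_c proportional to theta**GC(c).

    theta is found by bracketed root finding on log(theta) so the weighted
    expected GC equals ``gc_target``; theta = 1 recovers uniform usage of
    the 61 sense codons.  Raises if the target lies outside what sense-codon
    composition can reach.
    """
    if not 0.2 < gc_target < 0.75:
        raise ValueError(f"gc_target {gc_target} outside supported range (0.2, 0.75)")
    f = lambda logt: _expected_gc_plain(np.exp(logt)) - gc_target
    lo, hi = -30.0, 30.0
    if f(lo) > 0 or f(hi) < 0:
        raise ValueError(f"gc_target {gc_target} unreachable by codon tilting")
    log_theta = brentq(f, lo, hi, xtol=tol)
    theta = float(np.exp(log_theta))
    w = theta ** _GC_COUNT
    return w / w.sum(), theta


@lru_cache(maxsize=1)
def _cost_matrix() -> np.ndarray:
    aas = sorted(PROTEOME_PROFILE)
    cost = np.zeros((len(aas), len(SENSE_CODONS)))
    for i, a0 in enumerate(aas):
        for j, b in enumerate(_AA_OF):
            if a0 == b:
                continue
            c = (SAME_CLASS_COST if EXCHANGE_CLASSES[a0] == EXCHANGE_CLASSES[b]
                 else CROSS_CLASS_COST)
            if a0 in RIGID_RESIDUES:
                c += RIGIDITY_SURCHARGE
            cost[i, j] = c
    return cost


def _selection_marginal(theta: float) -> np.ndarray:
    """Marginal codon distribution of the mutation-selection site model."""
    aas = sorted(PROTEOME_PROFILE)
    profile = np.array([PROTEOME_PROFILE[a] for a in aas])
    profile = profile / profile.sum()
    exponent = _GC3 + POSITION_WEIGHT_GC12 * _GC12
    w = (theta ** exponent)[None, :] * np.exp(-_cost_matrix())
    w /= w.sum(axis=1, keepdims=True)
    return profile @ w


def proteome_codon_weights(gc_target: float,
                           tol: float = 1e-9) -> tuple[np.ndarray, float]:
    """Selection-aware codon weights hitting ``gc_target`` in expectation.

    The generator's working model: GC pressure (third-position-weighted)
    opposed by residue-exchange costs; see the module docstring.
    """
    if not 0.2 <= gc_target <= 0.75:
        raise ValueError(f"gc_target {gc_target} outside supported range")
    f = lambda logt: float(_selection_marginal(np.exp(logt)) @ _GC_COUNT) / 3.0 - gc_target
    lo, hi = -40.0, 40.0
    if f(lo) > 0 or f(hi) < 0:
        raise ValueError(f"gc_target {gc_target} unreachable under the site model")
    log_theta = brentq(f, lo, hi, xtol=tol)
    theta = float(np.exp(log_theta))
    return _selection_marginal(theta), theta


# ---------------------------------------------------------------------------
# genome generation
# ---------------------------------------------------------------------------

def generate_genome(spec: GenomeSpec,
                    rng: np.random.Generator | None = None,
                    genome_id: str | None = None
                    ) -> tuple[list[CdsRecord], dict]:
    """Emit CDS records and a manifest for one synthetic genome.

    Each gene is ATG, then L-2 body codons drawn i.i.d. from the calibrated
    selection-aware weights, then a stop codon drawn uniformly from
    TAA/TAG/TGA; internal stops are impossible by construction.  Gene
    lengths are Poisson around ``mean_len_codons`` (floored at 10 codons).
    Fully reproducible from ``spec.seed`` when no generator is passed.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    gid = genome_id or f"synth_gc{int(round(spec.gc_target * 100)):02d}"
    records: list[CdsRecord] = []
    if spec.n_genes > 0:
        weights, _ = proteome_codon_weights(spec.gc_target)
        codon_arr = np.array(SENSE_CODONS)
        stops = sorted(STOP_CODONS)
        cog_letters = sorted(spec.cog_proportions)
        cog_p = np.array([spec.cog_proportions[c] for c in cog_letters])
        lengths = np.maximum(rng.poisson(spec.mean_len_codons, spec.n_genes), 10)
        cogs = rng.choice(cog_letters, size=spec.n_genes, p=cog_p)
        for i in range(spec.n_genes):
            body = rng.choice(codon_arr, size=int(lengths[i]) - 2, p=weights)
            stop = stops[rng.integers(len(stops))]
            seq = "ATG" + "".join(body) + stop
            records.append(CdsRecord(f"{gid}_g{i:05d}", seq, cog=str(cogs[i])))
    manifest = {
        "genome": gid,
        "gc_target": spec.gc_target,
        "realized_gc": gc_content([r.sequence for r in records]) if records else None,
        "n_genes": spec.n_genes,
        "mean_len_codons": spec.mean_len_codons,
        "seed": spec.seed,
        "n_codons": sum(len(r.sequence) // 3 for r in records),
    }
    return records, manifest


def generate_panel(gc_values: Sequence[float] = DEFAULT_PANEL_GC,
                   base_spec: GenomeSpec | None = None,
                   seed: int | None = None
                   ) -> dict[str, tuple[list[CdsRecord], dict]]:
    """One genome per GC value, sharing every other spec field.

    Per-genome RNG streams are derived from the base seed and the genome's
    index, so panels are reproducible and order-independent.
    """
    if len(set(gc_values)) < 2:
        raise ValueError("need at least 2 distinct GC values for a panel")
    base = base_spec or GenomeSpec(gc_target=gc_values[0])
    base_seed = base.seed if seed is None else seed
    panel: dict[str, tuple[list[CdsRecord], dict]] = {}
    for i, gc in enumerate(gc_values):
        spec = replace(base, gc_target=gc, seed=base_seed)
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=base_seed, spawn_key=(i,))
        )
        records, manifest = generate_genome(spec, rng=rng)
        panel[manifest["genome"]] = (records, manifest)
    return panel


# ---------------------------------------------------------------------------
# file output
# ---------------------------------------------------------------------------

def write_genome(records: Sequence[CdsRecord], manifest: dict,
                 prefix: str | Path) -> dict[str, Path]:
    """Write FASTA + COG TSV + JSON manifest under ``prefix``."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    fasta = prefix.with_suffix(".fasta")
    with open(fasta, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), 70):
                fh.write(rec.sequence[i:i + 70] + "\n")
    tsv = prefix.with_suffix(".cog.tsv")
    with open(tsv, "w") as fh:
        fh.write("gene_id\tcog_category\n")
        for rec in records:
            fh.write(f"{rec.id}\t{rec.cog or '-'}\n")
    man = prefix.with_suffix(".manifest.json")
    man.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return {"fasta": fasta, "annotation": tsv, "manifest": man}
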