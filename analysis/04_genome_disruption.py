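#!/usr/bin/env python
"""Protein-disruptive effects of mutator spectra across a GC gradient.

Generates the default synthetic panel (six genomes, CDS GC 0.25-0.70,
~150k codons each), scores every built-in mutational spectrum under the
Grantham distance and BLOSUM100, restricted to the essential-gene-enriched
COG categories H, J and M, and writes the tidy score table plus the
spectrum-ordering report under results/.

Finding: the transition-only mismatch-repair spectrum is the least
disruptive in every genome; the mutY (G:C->T:A) spectrum is most disruptive
in AT-rich genomes and the mutT (A:T->C:G) spectrum in GC-rich genomes,
the two swapping rank along the gradient.
"""

from pathlib import Path

from mutspectra import run_gc_panel

OUT = Path(__file__).resolve().parent.parent / "results" / "genome_disruption"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    tidy, ordering = run_gc_panel(panel_seed=404)
    tidy.to_csv(OUT / "spectrum_scores.tsv", sep="\t", index=False)
    ordering.to_csv(OUT / "spectrum_ordering.tsv", sep="\t", index=False)

    gr = tidy[tidy.matrix == "grantham"]
    wide = gr.pivot(index="gc_content", columns="spectrum", values="mean_score")
    print("mean Grantham score by genome GC (H/J/M genes):")
    print(wide.round(2).to_string())
    rho = (ordering[ordering.matrix == "grantham"]
           .drop_duplicates("spectrum")[["spectrum", "spearman_rho_vs_gc"]])
    print("\nSpearman rho of disruption vs GC (Grantham):")
    print(rho.to_string(index=False))
    print(f"\nwrote tables under {OUT}")


if __name__ == "__main__":
    main()
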