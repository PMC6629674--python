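"""Parameter-grid experiments: s_eff surfaces, fold-change curves, GC panels.

Runs the package's standard experimental designs at full size or at a scaled
preset (population sizes divided by 1e4, replicates by 4) that preserves the
qualitative behaviour while keeping runs tractable.  Each sweep cell is an
independent set of invasion replicates; per-replicate RNGs are derived from
(base_seed, cell index, replicate index), so results are identical whatever
the execution order or chunking.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .invasion import (
    SimulationParams,
    estimate_s_eff,
    run_invasion,
)
from .matrices import ScoreMatrix, load_blosum100, load_grantham
from .scoring import CdsRecord, compare_spectra
from .spectra import BUILTIN_SPECTRA, MutationalSpectrum
from .synthetic import DEFAULT_PANEL_GC, GenomeSpec, generate_panel

__all__ = [
    "SweepGrid",
    "run_sweep",
    "fold_change",
    "run_gc_panel",
    "PRESETS",
    "preset_grid",
]

#: standard parameter grids of the package's experimental designs
DEFAULT_M = (30, 100, 300, 1000)
DEFAULT_S_D = (0.064, 0.032, 0.016, 0.008, 0.004, 0.002, 0.001)
DEFAULT_KAPPA = (0.25, 0.5, 1.0, 2.0, 4.0)
DEFAULT_U_D = (0.5e-4, 1e-4, 2e-4, 4e-4, 8e-4, 16e-4)
DEFAULT_U_L = (0.2e-5, 0.4e-5, 0.8e-5, 1.6e-5, 3.2e-5, 6.4e-5)

#: scaled preset: populations / 1e4, replicates / 4
SCALED_N_BOTTLENECK = 1_000
SCALED_N_MAX = 100_000.0


@dataclass(frozen=True)
class SweepGrid:
    """A factorial grid of invasion conditions."""

    m_values: Sequence[float] = (300,)
    s_d_values: Sequence[float] = (0.064,)
    kappa_values: Sequence[float] = (1.0,)
    u_d_values: Sequence[float] = (2e-4,)
    u_l_values: Sequence[float] = (0.0,)
    kappa_target: str = "deleterious"
    replicates: int = 200
    base_seed: int = 0
    scale: Literal["full", "scaled"] = "full"
    n_bottleneck_values: Sequence[int] | None = None
    n_max_values: Sequence[float] | None = None

    def demography(self) -> tuple[Sequence[int], Sequence[float]]:
        if self.scale == "scaled":
            nb = self.n_bottleneck_values or (SCALED_N_BOTTLENECK,)
            nm = self.n_max_values or (SCALED_N_MAX,)
        else:
            nb = self.n_bottleneck_values or (10_000_000,)
            nm = self.n_max_values or (1_000_000_000.0,)
        return nb, nm

    def effective_replicates(self) -> int:
        return max(1, self.replicates // 4) if self.scale == "scaled" else self.replicates

    def cells(self) -> list[SimulationParams]:
        nb_vals, nm_vals = self.demography()
        out = []
        for m, s_d, kappa, u_d, u_l, nb, nm in itertools.product(
            self.m_values, self.s_d_values, self.kappa_values,
            self.u_d_values, self.u_l_values, nb_vals, nm_vals,
        ):
            out.append(SimulationParams(
                m=m, s_d=s_d, kappa=kappa, kappa_target=self.kappa_target,
                u_d=u_d, u_l=u_l, n_bottleneck=int(nb), n_max=float(nm),
            ))
        return out


def _run_cell(params: SimulationParams, replicates: int, base_seed: int,
              cell_index: int) -> dict:
    results = []
    for rep in range(replicates):
        ss = np.random.SeedSequence(entropy=base_seed, spawn_key=(cell_index, rep))
        results.append(run_invasion(params, np.random.default_rng(ss)))
    est = estimate_s_eff(results)
    return {
        "m": params.m, "s_d": params.s_d, "kappa": params.kappa,
        "u_d": params.u_d, "u_l": params.u_l,
        "kappa_target": params.kappa_target,
        "n_bottleneck": params.n_bottleneck, "n_max": params.n_max,
        "replicates": est.n_replicates,
        "n_qualifying": est.n_used,
        "mean_s_eff": est.mean,
        "se_s_eff": est.se,
        "fixation_fraction": est.fixation_fraction,
        "s_eff_defined": est.defined,
    }


def run_sweep(grid: SweepGrid, cell_indices: Sequence[int] | None = None) -> pd.DataFrame:
    """One summary row per grid cell; deterministic under the base seed.

    ``cell_indices`` restricts execution to a subset of cells without
    changing their seeds (the chunked-execution contract).  Cells whose
    s_eff is undefined are flagged via ``s_eff_defined``, never dropped.
    """
    cells = grid.cells()
    reps = grid.effective_replicates()
    picked = range(len(cells)) if cell_indices is None else cell_indices
    rows = [_run_cell(cells[i], reps, grid.base_seed, i) for i in picked]
    return pd.DataFrame(rows)


def fold_change(summary: pd.DataFrame, kappa_low: float = 0.25,
                kappa_high: float = 4.0) -> pd.DataFrame:
    """Per-condition ratio s_eff(kappa_high) / s_eff(kappa_low).

    The fold change quantifies how much the spectrum-bias factor kappa can
    modulate antimutator fitness within one (m, s_d, u_d, u_l) condition.
    Undefined (flagged NaN) when either endpoint mean is missing or <= 0.
    """
    keys = ["m", "s_d", "u_d", "u_l", "kappa_target"]
    rows = []
    for cond, sub in summary.groupby(keys):
        lo = sub.loc[np.isclose(sub["kappa"], kappa_low), "mean_s_eff"]
        hi = sub.loc[np.isclose(sub["kappa"], kappa_high), "mean_s_eff"]
        if len(lo) != 1 or len(hi) != 1:
            continue
        lo_v, hi_v = float(lo.iloc[0]), float(hi.iloc[0])
        ok = np.isfinite(lo_v) and np.isfinite(hi_v) and lo_v > 0 and hi_v > 0
        rows.append(dict(zip(keys, cond)) | {
            "kappa_low": kappa_low, "kappa_high": kappa_high,
            "s_eff_low": lo_v, "s_eff_high": hi_v,
            "fold_change": hi_v / lo_v if ok else np.nan,
            "defined": ok,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# standard experiment presets
# ---------------------------------------------------------------------------

PRESETS: dict[str, dict] = {
    # invasion speed vs m and s_d (trajectory-level design)
    "mutator-strength": dict(m_values=DEFAULT_M, s_d_values=(0.064,), kappa_values=(1.0,)),
    # kappa sweep across m and s_d
    "kappa-grid": dict(m_values=DEFAULT_M, s_d_values=DEFAULT_S_D, kappa_values=DEFAULT_KAPPA),
    # deleterious-rate modulation of the kappa effect
    "deleterious-rate": dict(m_values=(300,), s_d_values=(0.001,),
                     kappa_values=DEFAULT_KAPPA, u_d_values=DEFAULT_U_D),
    # lethal-rate modulation (kappa routed to u_l)
    "lethal-rate": dict(m_values=(300,), s_d_values=(0.001,),
                        kappa_values=DEFAULT_KAPPA, u_l_values=DEFAULT_U_L,
                        kappa_target="lethal"),
    # demographic sensitivity: bottleneck and maximum size axes
    "demography": dict(m_values=(300,), s_d_values=(0.008,),
                            kappa_values=(0.25, 1.0, 4.0),
                            n_bottleneck_values=(1_000, 10_000),
                            n_max_values=(100_000.0, 1_000_000.0)),
}


def preset_grid(name: str, scale: Literal["full", "scaled"] = "scaled",
                base_seed: int = 0, replicates: int = 200) -> SweepGrid:
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    return SweepGrid(base_seed=base_seed, scale=scale, replicates=replicates,
                     **PRESETS[name])


# ---------------------------------------------------------------------------
# genome-panel experiment
# ---------------------------------------------------------------------------

def run_gc_panel(genomes: Mapping[str, Sequence[CdsRecord]] | None = None,
                spectra: Sequence[MutationalSpectrum] | None = None,
                matrices: Sequence[ScoreMatrix] | None = None,
                cog_filter: set[str] | None = frozenset("HJM"),
                panel_seed: int = 0,
                panel_genes: int = 500) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Spectrum disruption scores across a GC-spanning genome panel.

    Returns the tidy per-(genome, spectrum, matrix) table and an ordering
    report: per-genome disruption ranks of the spectra (rank 1 = most
    disruptive) and each spectrum's Spearman rank correlation of disruption
    with genome GC.  Defaults score the synthetic panel under the built-in
    spectra, both matrices, and the essential-gene-enriched COG categories
    H, J, M.
    """
    if genomes is None:
        base = GenomeSpec(gc_target=DEFAULT_PANEL_GC[0], n_genes=panel_genes,
                          seed=panel_seed)
        panel = generate_panel(DEFAULT_PANEL_GC, base_spec=base, seed=panel_seed)
        genomes = {gid: recs for gid, (recs, _) in panel.items()}
    spectra = list(spectra or BUILTIN_SPECTRA.values())
    matrices = list(matrices or (load_grantham(), load_blosum100()))

    tidy = compare_spectra(genomes, spectra, matrices, cog_filter=cog_filter)

    rows = []
    for mat_name, sub in tidy.groupby("matrix"):
        higher_disruptive = bool(sub["higher_is_disruptive"].iloc[0])
        # disruption score: orient so larger = more disruptive
        sub = sub.assign(
            disruption=sub["mean_score"] * (1 if higher_disruptive else -1)
        )
        for genome, g in sub.groupby("genome"):
            ranks = g.set_index("spectrum")["disruption"].rank(ascending=False)
            for spec_name, rank in ranks.items():
                rows.append({
                    "matrix": mat_name, "genome": genome, "spectrum": spec_name,
                    "gc_content": float(g["gc_content"].iloc[0]),
                    "disruption_rank": float(rank),
                })
    ordering = pd.DataFrame(rows)

    corr_rows = []
    for (mat_name, spec_name), g in tidy.groupby(["matrix", "spectrum"]):
        sign = 1 if bool(g["higher_is_disruptive"].iloc[0]) else -1
        rho, p = stats.spearmanr(g["gc_content"], sign * g["mean_score"])
        corr_rows.append({"matrix": mat_name, "spectrum": spec_name,
                          "spearman_rho_vs_gc": float(rho), "p_value": float(p)})
    ordering = ordering.merge(pd.DataFrame(corr_rows), on=["matrix", "spectrum"])
    return tidy, ordering
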