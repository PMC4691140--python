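"""Assembly of analysis products as tables (and optional figures).

The analysis surface mirrors a typical elastic-network study of a
multi-domain protein: calibrate the spring constant against the
crystallographic B column, profile slow-mode mobility per residue and per
domain, map pairwise flexibility (MSFID), and summarize the unfolding
trajectory.  Everything numeric lives in pandas tables; figures are
optional artifacts so headless runs never need a display.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import gnm
from .gnm import GammaFit, ModeDecomposition
from .structure_io import CoarseGrainedStructure
from .unfolding import MeltingSummary, UnfoldingTrajectory

__all__ = [
    "AnalysisReport",
    "bfactor_comparison",
    "domain_statistics",
    "analyze_structure",
    "write_per_residue_table",
    "write_matrix",
    "write_trajectory",
    "write_melting_report",
    "plot_bfactor_overlay",
    "plot_msfid_heatmap",
    "plot_lnnc_curve",
]


@dataclass
class AnalysisReport:
    """Tabular summary of one structure's fluctuation analysis.

    The manifest records every convention the numbers depend on (cutoff,
    mode count, prefactors, tie-break rule) so each cell is recomputable
    from the stored inputs.
    """

    per_residue: pd.DataFrame
    gamma_fit: GammaFit | None
    domain_stats: pd.DataFrame | None
    manifest: dict = field(default_factory=dict)


def bfactor_comparison(
    structure: CoarseGrainedStructure,
    gamma_fit: GammaFit,
    decomp: ModeDecomposition | None = None,
    cutoff: float = gnm.DEFAULT_CUTOFF,
) -> tuple[pd.DataFrame, float]:
    """Aligned experimental/theoretical B-factor series and their Pearson r.

    The theoretical column is the Debye–Waller B-factor at the fitted γ
    over all non-zero modes.
    """
    exp = structure.experimental_bfactors
    if np.isnan(exp).any():
        raise ValueError("structure has no complete experimental B-factor column")
    if decomp is None:
        decomp = gnm.decompose(gnm.build_kirchhoff(structure, cutoff))
    theo = gnm.theoretical_bfactors(gnm.residue_msf(decomp, gamma=gamma_fit.gamma))
    table = pd.DataFrame({
        "index": np.arange(len(structure)),
        "chain": structure.chain_ids,
        "resnum": [s.residue_number for s in structure.sites],
        "experimental_b": exp,
        "theoretical_b": theo,
    })
    r = float(np.corrcoef(exp, theo)[0, 1])
    return table, r


def domain_statistics(
    report: gnm.FluctuationReport,
    domain_indices: Mapping[str, Sequence[int]],
    slow_msf: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-domain means of (slow-mode) MSF and of within-domain MSFID.

    `slow_msf` defaults to the report's own MSF; pass the six-slowest-mode
    profile to reproduce the collective-mobility comparison.  Empty domains
    are excluded with a warning.
    """
    import warnings

    msf = report.msf if slow_msf is None else np.asarray(slow_msf, float)
    rows = []
    for label, idx in domain_indices.items():
        idx = np.asarray(sorted(idx), dtype=int)
        if idx.size == 0:
            warnings.warn(f"domain {label!r} is empty; excluded", stacklevel=2)
            continue
        sub = report.msfid[np.ix_(idx, idx)]
        off = sub[np.triu_indices(idx.size, k=1)] if idx.size > 1 else np.array([np.nan])
        rows.append({
            "domain": label,
            "n_sites": int(idx.size),
            "mean_msf": float(msf[idx].mean()),
            "mean_msfid": float(off.mean()),
        })
    return pd.DataFrame(rows)


def analyze_structure(
    structure: CoarseGrainedStructure,
    domain_indices: Mapping[str, Sequence[int]] | None = None,
    cutoff: float = gnm.DEFAULT_CUTOFF,
    n_slow_modes: int = 6,
    fit_method: str = "mean",
) -> AnalysisReport:
    """One-stop fluctuation analysis of a structure.

    Builds the network, decomposes it, calibrates γ against the
    experimental B column when one is present (γ = 1 otherwise), and
    assembles the per-residue table (experimental and theoretical B,
    full-spectrum MSF, slow-mode MSF) plus per-domain statistics.
    """
    topo = gnm.build_kirchhoff(structure, cutoff)
    decomp = gnm.decompose(topo)
    msf1 = gnm.residue_msf(decomp)                       # γ = 1
    b1 = gnm.theoretical_bfactors(msf1)

    exp = structure.experimental_bfactors
    fit = None
    gamma = 1.0
    if not np.isnan(exp).any() and exp.mean() > 0:
        fit = gnm.fit_gamma(b1, exp, method=fit_method)
        gamma = fit.gamma

    slow = gnm.mode_subset_msf(decomp, gamma=gamma, k_slowest=min(
        n_slow_modes, decomp.nonzero_modes.size))
    report = gnm.fluctuation_report(decomp, gamma=gamma)

    per_residue = pd.DataFrame({
        "index": np.arange(len(structure)),
        "chain": structure.chain_ids,
        "resnum": [s.residue_number for s in structure.sites],
        "experimental_b": exp,
        "theoretical_b": report.bfactors,
        "msf": report.msf,
        f"msf_slow{n_slow_modes}": slow,
    })
    dstats = None
    if domain_indices:
        dstats = domain_statistics(report, domain_indices, slow_msf=slow)
    manifest = {
        "cutoff_rc": cutoff,
        "n_sites": len(structure),
        "n_contacts": topo.n_contacts,
        "n_slow_modes": n_slow_modes,
        "gamma": gamma,
        "fit_method": fit.method if fit else None,
        "pearson_r": fit.pearson_r if fit else None,
        "msfid_prefactor": gnm.MSFID_PREFACTOR,
        "tie_break": "lexicographic smallest pair",
        "source": structure.source_label,
    }
    return AnalysisReport(per_residue, fit, dstats, manifest)


# ---------------------------------------------------------------------------
# plain-text writers

def write_per_residue_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_matrix(matrix: np.ndarray, path: str | Path) -> None:
    """Dense tab-separated grid, suitable for external heatmap tools."""
    np.savetxt(path, matrix, delimiter="\t", fmt="%.6g")


def write_trajectory(trajectory: UnfoldingTrajectory,
                     structure: CoarseGrainedStructure,
                     path: str | Path) -> None:
    rows = []
    for e in trajectory.events:
        si, sj = structure.sites[e.pair[0]], structure.sites[e.pair[1]]
        rows.append((e.step, si.chain_id, si.residue_number,
                     sj.chain_id, sj.residue_number,
                     e.msfid, e.lnnc, e.t_over_t0))
    pd.DataFrame(rows, columns=[
        "step", "chain_i", "resnum_i", "chain_j", "resnum_j",
        "msfid", "lnnc", "t_over_t0",
    ]).to_csv(path, sep="\t", index=False, float_format="%.8g")


def write_melting_report(summary: MeltingSummary, path: str | Path) -> None:
    lines = [f"t0_kelvin\t{summary.t0_kelvin:g}"]
    lines.append("unfolding_order\t" + ",".join(summary.unfolding_order))
    for lab in summary.unfolding_order:
        lines.append(f"melt_kelvin[{lab}]\t{summary.melt_kelvin[lab]:.6g}")
    for lab in summary.excluded:
        lines.append(f"excluded\t{lab}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# optional figures (matplotlib Agg-safe; never required by the analysis)

def plot_bfactor_overlay(table: pd.DataFrame, path: str | Path) -> None:
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(9, 3))
    ax.plot(table["index"], table["experimental_b"], color="red", lw=1,
            label="experimental")
    ax.plot(table["index"], table["theoretical_b"], color="blue", lw=1,
            label="computed")
    ax.set_xlabel("residue index")
    ax.set_ylabel("B-factor (Å²)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_msfid_heatmap(msfid: np.ndarray, path: str | Path) -> None:
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4.2))
    im = ax.imshow(msfid, origin="lower", cmap="jet")
    fig.colorbar(im, ax=ax, label="MSFID (Å²)")
    ax.set_xlabel("residue index")
    ax.set_ylabel("residue index")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_lnnc_curve(trajectory: UnfoldingTrajectory, path: str | Path) -> None:
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.step([e.t_over_t0 for e in trajectory.events],
            [e.lnnc for e in trajectory.events], where="post")
    ax.set_xlabel("reduced temperature T/T0")
    ax.set_ylabel("LNNC")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
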