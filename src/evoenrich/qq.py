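"""Genomic-control-corrected stratified QQ analysis.

The enrichment readout of the analysis: p-values of an annotation's SNP
subset are compared, on the -log10 scale, with the uniform expectation and
with the full GWAS.  Both curves are corrected for genomic inflation with the
*global* λ_GC estimated from all GWAS SNPs — an upward (leftward) deflection
of the subset curve beyond the full-GWAS curve indicates that the annotation
captures true association signal, and crossing 5e-8 after correction marks
genome-wide significant enrichment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, Optional, Tuple

import numpy as np
from scipy.stats import chi2

from .model import GENOME_WIDE_SIG, GwasTable

logger = logging.getLogger(__name__)

#: median of the chi-square distribution with 1 df
CHI2_MEDIAN_1DF = float(chi2.ppf(0.5, 1))  # 0.45493642...

#: floor applied before the -log10 transform
P_FLOOR = 1e-300

#: expected -log10 quantiles at which curve deflection is reported
DEFLECTION_GRID = (1.0, 2.0, 3.0, 4.0, 5.0)


def lambda_gc(pvalues) -> float:
    """Genomic-control λ: median association χ² over the null median 0.45494."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("lambda_gc: empty p-value vector")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("lambda_gc: p-values must lie in (0, 1]")
    chisq = chi2.isf(p, 1)
    return float(np.median(chisq) / CHI2_MEDIAN_1DF)


def gc_correct(pvalues, lam: float) -> np.ndarray:
    """Deflate each p-value's χ² by λ and return the corrected upper-tail p."""
    if lam <= 0:
        raise ValueError("lambda must be positive")
    p = np.asarray(pvalues, dtype=float)
    if lam == 1.0:
        return p.copy()
    return chi2.sf(chi2.isf(p, 1) / lam, 1)


def gc_correct_table(gwas: GwasTable, lam: float) -> GwasTable:
    """A copy of the GWAS table with GC-corrected p-values."""
    corrected = np.clip(gc_correct(gwas.pvalues, lam), P_FLOOR, 1.0)
    return gwas.with_pvalues(corrected)


@dataclass
class QQCurve:
    """One QQ curve: best rank first, so both arrays are non-increasing."""

    n: int
    expected: np.ndarray    # -log10((i - 0.5) / n), i = 1..n
    observed: np.ndarray    # sorted -log10 of GC-corrected p
    lambda_gc: float        # the global λ used for correction
    subset_name: str

    def deflection(self, grid=DEFLECTION_GRID) -> np.ndarray:
        """observed - expected gap at reference expected quantiles.

        A machine-readable stand-in for visual leftward deflection; NaN where
        the curve does not reach the reference quantile.
        """
        exp_inc = self.expected[::-1]
        obs_inc = self.observed[::-1]
        out = np.interp(grid, exp_inc, obs_inc, left=np.nan, right=np.nan)
        return out - np.asarray(grid, dtype=float)


@dataclass
class EnrichmentSummary:
    crosses_gws: bool          # any corrected subset p < 5e-8
    deflection: np.ndarray     # observed-expected at DEFLECTION_GRID
    min_p_subset: float
    n_subset: int
    n_dropped: int = 0         # subset ids absent from the GWAS


def qq_curve(pvalues, subset_name: str, lam: float = 1.0) -> QQCurve:
    """Build a GC-corrected QQ curve with Hazen plotting positions."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError(f"qq_curve: empty p-value vector for {subset_name!r}")
    n = p.size
    corrected = np.clip(gc_correct(p, lam), P_FLOOR, 1.0)
    observed = -np.log10(np.sort(corrected))  # ascending p -> descending -log10
    expected = -np.log10((np.arange(1, n + 1) - 0.5) / n)
    return QQCurve(n=n, expected=expected, observed=observed,
                   lambda_gc=lam, subset_name=subset_name)


def stratified_qq(
    gwas: GwasTable,
    subset_ids: Iterable[str],
    subset_name: str = "subset",
    lam: Optional[float] = None,
) -> Tuple[QQCurve, QQCurve, EnrichmentSummary]:
    """QQ curves for the full GWAS and an annotation subset, sharing global λ.

    λ is estimated from all (already masked/filtered) GWAS p-values unless
    given; subset ids absent from the table are dropped with a count.
    """
    subset_ids = set(subset_ids)
    present = subset_ids & gwas.ids
    n_dropped = len(subset_ids) - len(present)
    if n_dropped:
        logger.warning("%s: %d subset ids not in the GWAS were dropped",
                       subset_name, n_dropped)
    if not present:
        raise ValueError(f"stratified_qq: empty subset for annotation {subset_name!r}")
    if lam is None:
        lam = lambda_gc(gwas.pvalues)
    full = qq_curve(gwas.pvalues, f"{gwas.trait_name}:all", lam)
    sub_p = gwas.subset(present).pvalues
    sub = qq_curve(sub_p, subset_name, lam)
    min_p = float(np.min(np.clip(gc_correct(sub_p, lam), P_FLOOR, 1.0)))
    summary = EnrichmentSummary(
        crosses_gws=bool(min_p < GENOME_WIDE_SIG),
        deflection=sub.deflection(),
        min_p_subset=min_p,
        n_subset=len(present),
        n_dropped=n_dropped,
    )
    return full, sub, summary


def plot_qq(curves: Dict[str, QQCurve], path, title: str = "Stratified QQ") -> None:
    """Write a stratified QQ plot (one line per curve plus the null diagonal)."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    lim = 0.0
    for name, c in curves.items():
        ax.plot(c.expected, c.observed, lw=1.2, label=f"{name} (n={c.n})")
        lim = max(lim, float(c.expected[0]), float(c.observed[0]))
    ax.plot([0, lim], [0, lim], color="grey", lw=0.8, ls="--", label="null")
    ax.axhline(-np.log10(GENOME_WIDE_SIG), color="black", lw=0.6, ls=":")
    ax.set_xlabel(r"expected $-\log_{10}(p)$")
    ax.set_ylabel(r"observed $-\log_{10}(p)$ (GC-corrected)")
    ax.set_title(title)
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
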