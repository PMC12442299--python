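"""Isoform-switch detection from single-cell expression matrices.

Counts are TPM-normalized (per transcript length and library size) and
log2(TPM+1)-transformed; for every gene with at least two modeled isoforms,
each isoform's expression is tested across cell types (Welch t-test for two
groups, one-way ANOVA otherwise) with Bonferroni correction over all
isoform×gene tests in the run. A gene is called a switch when at least two
of its isoforms are significant with distinct preferred cell types. Cell
types with fewer than 30 cells are excluded before testing. The cross-tissue
variant applies the identical machinery with tissue as the grouping factor
within one cell type.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ExpressionMatrix",
    "IsoformTest",
    "SwitchResult",
    "tpm_normalize",
    "log_transform",
    "aggregate_gene",
    "eligible_groups",
    "switch_test",
    "filter_switches",
    "detect_switches",
    "cross_tissue_switch",
]


@dataclass
class ExpressionMatrix:
    """Cells × transcripts counts with lengths, gene map and cell metadata."""

    counts: pd.DataFrame
    lengths: pd.Series
    tx2gene: pd.Series
    meta: pd.DataFrame  # indexed by cell, columns cell_type (and optional tissue)

    def __post_init__(self) -> None:
        missing = set(self.counts.columns) - set(self.lengths.index)
        if missing:
            raise ValueError(f"transcripts without lengths: {sorted(missing)[:5]}")
        if (self.lengths.loc[list(self.counts.columns)] <= 0).any():
            raise ValueError("transcript lengths must be positive")
        if not self.counts.index.equals(self.meta.index):
            raise ValueError("counts rows and cell metadata index differ")

    @property
    def genes(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for tx in self.counts.columns:
            out.setdefault(str(self.tx2gene[tx]), []).append(tx)
        return out


@dataclass
class IsoformTest:
    isoform_id: str
    p_raw: float
    p_corrected: float
    preferred: str
    fold_change: float
    significant: bool


@dataclass
class SwitchResult:
    gene_id: str
    tests: list[IsoformTest] = field(default_factory=list)

    @property
    def switch(self) -> bool:
        sig = [t for t in self.tests if t.significant]
        return len(sig) >= 2 and len({t.preferred for t in sig}) >= 2

    @property
    def max_fold_change(self) -> float:
        return max((t.fold_change for t in self.tests), default=0.0)


# ---------------------------------------------------------------------------

def tpm_normalize(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Transcripts per million: counts per length, rescaled to 1e6 per cell."""
    rates = counts / lengths.loc[counts.columns].to_numpy()[None, :]
    totals = rates.sum(axis=1)
    tpm = rates.mul(1e6).div(totals.replace(0, np.nan), axis=0)
    return tpm.fillna(0.0)


def log_transform(tpm: pd.DataFrame) -> pd.DataFrame:
    return np.log2(tpm + 1.0)


def aggregate_gene(matrix: pd.DataFrame, tx2gene: pd.Series) -> pd.DataFrame:
    """Cell × gene matrix by summing transcript columns per gene."""
    return matrix.T.groupby(tx2gene.loc[matrix.columns].to_numpy()).sum().T


def eligible_groups(labels: pd.Series, min_cells: int = 30) -> list[str]:
    """Group labels with at least ``min_cells`` members ('fewer than 30' excluded)."""
    counts = labels.value_counts()
    return sorted(counts.index[counts >= min_cells])


def switch_test(
    gene_id: str,
    isoform_ids: list[str],
    log_matrix: pd.DataFrame,
    tpm: pd.DataFrame,
    groups: pd.Series,
    bonferroni_m: int | None = None,
    alpha: float = 0.05,
) -> SwitchResult:
    """Test each isoform of one gene for group-specific expression.

    Welch t-test for two groups, one-way ANOVA otherwise, on log2(TPM+1).
    ``bonferroni_m`` is the size of the whole run's test family (defaults to
    the number of isoforms tested here). Preferred group = argmax of mean log
    expression; fold change = preferred-group mean TPM over the mean TPM of
    the remaining groups.
    """
    levels = sorted(groups.unique())
    if len(levels) < 2:
        raise ValueError(f"gene {gene_id}: a single eligible group; skipped")
    if len(isoform_ids) < 2:
        raise ValueError(f"gene {gene_id}: needs >= 2 modeled isoforms")
    m = bonferroni_m or len(isoform_ids)
    tests = []
    for iso in isoform_ids:
        values = log_matrix[iso]
        samples = [values[groups == lv].to_numpy() for lv in levels]
        if len(samples) == 2:
            _stat, p = stats.ttest_ind(samples[0], samples[1], equal_var=False)
        else:
            _stat, p = stats.f_oneway(*samples)
        p = float(p)
        p_corr = min(1.0, p * m)
        means = {lv: s.mean() for lv, s in zip(levels, samples)}
        preferred = max(levels, key=lambda lv: means[lv])
        tpm_vals = tpm[iso]
        pref_mean = float(tpm_vals[groups == preferred].mean())
        other_mean = float(tpm_vals[groups != preferred].mean())
        fc = pref_mean / other_mean if other_mean > 0 else np.inf
        tests.append(IsoformTest(iso, p, p_corr, preferred, fc, p_corr < alpha))
    return SwitchResult(gene_id=gene_id, tests=tests)


def filter_switches(results: list[SwitchResult]) -> list[SwitchResult]:
    """Keep genes whose switch flag is set, ranked by fold change (descending)."""
    flagged = [r for r in results if r.switch]
    return sorted(flagged, key=lambda r: -r.max_fold_change)


def detect_switches(
    em: ExpressionMatrix,
    min_cells: int = 30,
    alpha: float = 0.05,
    group_by: str = "cell_type",
    subset: pd.Series | None = None,
) -> list[SwitchResult]:
    """Run the switch test over every gene with >= 2 modeled isoforms.

    Cell groups with fewer than ``min_cells`` cells are dropped before
    testing; the Bonferroni family spans all isoform×gene tests in the run.
    """
    meta = em.meta if subset is None else em.meta[subset]
    labels = meta[group_by]
    keep_groups = eligible_groups(labels, min_cells)
    if len(keep_groups) < 2:
        return []
    cell_mask = labels.isin(keep_groups)
    cells = labels.index[cell_mask]
    groups = labels[cell_mask]

    tpm = tpm_normalize(em.counts.loc[cells], em.lengths)
    logm = log_transform(tpm)

    genes = {g: txs for g, txs in em.genes.items() if len(txs) >= 2}
    bonferroni_m = sum(len(txs) for txs in genes.values())
    results = []
    for gene_id, txs in genes.items():
        results.append(
            switch_test(gene_id, txs, logm, tpm, groups, bonferroni_m=bonferroni_m,
                        alpha=alpha)
        )
    return results


def cross_tissue_switch(
    em: ExpressionMatrix,
    cell_type: str,
    min_cells: int = 30,
    alpha: float = 0.05,
) -> list[SwitchResult]:
    """Switch detection across tissues within one cell type."""
    if "tissue" not in em.meta.columns:
        raise ValueError("cell metadata has no 'tissue' column")
    mask = em.meta["cell_type"] == cell_type
    return detect_switches(em, min_cells=min_cells, alpha=alpha, group_by="tissue",
                           subset=mask)
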