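"""Per-residue-effect regression of structural metric differences.

Each reference/isoform pair contributes one row: splicing-event length
features (residues) per event type plus the pLDDT difference; the outcome is
a standardized structural metric (difference). Signed mode splits ES and IR
by host transcript; absolute mode (forced for the TM-score outcome, which is
non-directional) uses absolute lengths with ES/IR unsplit. Coefficients are
interpreted as per-residue effects; p-values come from classical OLS t-tests
(matching R's ``lm``), with no multiple-testing correction across the grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .metrics import PairReport
from .splice import SpliceEventSet, event_length_features

__all__ = [
    "OUTCOME_METRICS",
    "RegressionDesign",
    "standardize",
    "build_design",
    "fit_ols",
    "effect_summary",
]

OUTCOME_METRICS = {
    "tm": "tm",
    "helix": "d_helix",
    "sheet": "d_sheet",
    "loop": "d_loop",
    "charge": "d_charge",
    "rg": "d_rg",
}


@dataclass
class RegressionDesign:
    """Feature matrix and standardized outcome for one metric."""

    X: pd.DataFrame
    y: np.ndarray
    outcome: str
    mode: str


def standardize(values) -> np.ndarray:
    """z-scores with sample standard deviation (ddof=1); idempotent."""
    v = np.asarray(values, dtype=float)
    sd = v.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("cannot standardize a constant (zero-variance) vector")
    return (v - v.mean()) / sd


def build_design(
    pair_reports: list[PairReport],
    event_sets: dict[str, SpliceEventSet],
    outcome_metric: str,
    mode: str | None = None,
) -> RegressionDesign:
    """Assemble the regression design for one outcome metric.

    ``pair_reports`` are matched to ``event_sets`` by isoform id. The
    TM-score outcome forces absolute mode. Pairs whose event lengths are not
    multiples of 3 (frame-ambiguous) are excluded with a warning.
    """
    if outcome_metric not in OUTCOME_METRICS:
        raise ValueError(
            f"unknown outcome {outcome_metric!r}; expected one of {sorted(OUTCOME_METRICS)}"
        )
    if outcome_metric == "tm":
        if mode == "signed":
            raise ValueError("the TM-score outcome is non-directional: absolute mode only")
        mode = "absolute"
    mode = mode or "signed"

    rows = []
    outcomes = []
    attr = OUTCOME_METRICS[outcome_metric]
    for pr in pair_reports:
        ev = event_sets.get(pr.iso_id)
        if ev is None:
            raise ValueError(f"pair {pr.iso_id}: no splice-event set provided")
        feats, ambiguous = event_length_features(ev, mode=mode, units="aa")
        if ambiguous:
            warnings.warn(f"pair {pr.iso_id}: frame-ambiguous event length, excluded")
            continue
        plddt = pr.d_plddt if mode == "signed" else abs(pr.d_plddt)
        feats = pd.concat([feats, pd.Series({"d_pLDDT" if mode == "signed" else "absd_pLDDT": plddt})])
        rows.append(feats)
        outcomes.append(getattr(pr, attr))
    if not rows:
        raise ValueError("no usable pairs for the regression design")
    X = pd.DataFrame(rows).reset_index(drop=True)
    y = standardize(outcomes)
    return RegressionDesign(X=X, y=y, outcome=outcome_metric, mode=mode)


def fit_ols(design: RegressionDesign) -> pd.DataFrame:
    """OLS with intercept; per-feature effect, standard error, t and p.

    Raises on rank deficiency, naming the collinear columns.
    """
    import statsmodels.api as sm

    X = design.X
    n, p = X.shape
    if n <= p + 1:
        raise ValueError(f"n_rows ({n}) must exceed n_features + intercept ({p + 1})")
    exog = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(exog.to_numpy())
    if rank < exog.shape[1]:
        bad = _collinear_columns(exog)
        raise ValueError(f"design is rank deficient; collinear columns: {bad}")
    fit = sm.OLS(design.y, exog).fit()
    out = pd.DataFrame({
        "feature": exog.columns,
        "effect": fit.params.to_numpy(),
        "se": fit.bse.to_numpy(),
        "t": fit.tvalues.to_numpy(),
        "p": fit.pvalues.to_numpy(),
    })
    return out[out["feature"] != "const"].reset_index(drop=True)


def _collinear_columns(exog: pd.DataFrame) -> list[str]:
    """Columns that do not increase the design rank when added left to right."""
    bad = []
    arr = exog.to_numpy()
    rank = 0
    kept: list[int] = []
    for j in range(arr.shape[1]):
        new_rank = np.linalg.matrix_rank(arr[:, kept + [j]])
        if new_rank > rank:
            kept.append(j)
            rank = new_rank
        else:
            bad.append(str(exog.columns[j]))
    return bad


def effect_summary(tables: dict[str, pd.DataFrame], alpha: float = 0.05) -> pd.DataFrame:
    """Tidy long table (outcome, feature, effect, p, significant) over outcomes."""
    frames = []
    for outcome, tab in tables.items():
        t = tab.copy()
        t.insert(0, "outcome", outcome)
        t["significant"] = t["p"] < alpha
        frames.append(t)
    return pd.concat(frames, ignore_index=True)
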