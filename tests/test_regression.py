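"""Per-residue-effect regression: recovery, calibration, design assembly."""

import numpy as np
import pytest

from isoformetrics.metrics import PairReport
from isoformetrics.regression import (
    RegressionDesign,
    build_design,
    effect_summary,
    fit_ols,
    standardize,
)
from isoformetrics.splice import SpliceEvent, SpliceEventSet
from isoformetrics.synth import make_regression_dataset


def _design(X, y, outcome="rg", mode="signed"):
    import pandas as pd

    return RegressionDesign(X=pd.DataFrame(X), y=np.asarray(y), outcome=outcome,
                            mode=mode)


def test_standardize_basics():
    np.testing.assert_allclose(standardize([1, 2, 3]), [-1, 0, 1])
    z = standardize([4.0, 8.0, 15.0, 16.0, 23.0, 42.0])
    assert z.mean() == pytest.approx(0.0, abs=1e-12)
    assert z.std(ddof=1) == pytest.approx(1.0)
    np.testing.assert_allclose(standardize(z), z, atol=1e-12)
    with pytest.raises(ValueError, match="constant"):
        standardize([5, 5, 5])


def test_noise_free_exact_recovery():
    X, y = make_regression_dataset([1.5, -2.0, 0.25], n=60, noise_sd=0.0, seed=1)
    # standardize the outcome the same way the design builder does
    scale = y.std(ddof=1)
    table = fit_ols(_design(X, standardize(y)))
    np.testing.assert_allclose(
        table["effect"].to_numpy(), np.array([1.5, -2.0, 0.25]) / scale, atol=1e-8
    )


def test_ols_matches_normal_equations():
    X, y = make_regression_dataset([0.7, -0.3], n=40, noise_sd=1.0, seed=2)
    table = fit_ols(_design(X, y))
    A = np.column_stack([np.ones(len(y)), X.to_numpy()])
    beta = np.linalg.solve(A.T @ A, A.T @ y)
    np.testing.assert_allclose(table["effect"].to_numpy(), beta[1:], atol=1e-10)


def test_estimates_within_three_se():
    """At n=500, sd=1, |beta_hat - beta| < 3 SE in >= 95% of seeded replicates."""
    beta = np.array([0.5, -1.0, 0.0, 2.0])
    covered = 0
    total = 0
    for seed in range(100):
        X, y = make_regression_dataset(beta, n=500, noise_sd=1.0, seed=seed)
        table = fit_ols(_design(X, y))
        within = np.abs(table["effect"].to_numpy() - beta) <= 3 * table["se"].to_numpy()
        covered += within.sum()
        total += len(beta)
    assert covered / total >= 0.95


def test_permutation_null_p_value_calibration():
    """Permuted outcomes give ~5% of p-values below 0.05."""
    rng = np.random.default_rng(123)
    hits = 0
    total = 0
    for seed in range(150):
        X, y = make_regression_dataset([1.0, 1.0, 1.0], n=80, noise_sd=1.0, seed=seed)
        y_perm = rng.permutation(y)
        table = fit_ols(_design(X, y_perm))
        hits += (table["p"] < 0.05).sum()
        total += len(table)
    rate = hits / total
    assert rate == pytest.approx(0.05, abs=0.02)


def test_rank_deficiency_names_collinear_column():
    import pandas as pd

    X = pd.DataFrame({"a": [1.0, 2, 3, 4, 5, 6], "b": [2.0, 4, 6, 8, 10, 12]})
    with pytest.raises(ValueError, match="b"):
        fit_ols(_design(X, [1.0, 2, 1, 2, 1, 2]))


def _pair(iso_id, d_rg, d_plddt, tm=0.8):
    return PairReport(ref_id=f"r-{iso_id}", iso_id=iso_id, tm=tm, d_helix=0.0,
                      d_sheet=0.0, d_loop=0.0, d_charge=0, d_rg=d_rg, d_idr=0.0,
                      d_plddt=d_plddt)


def _events(iso_id, *events):
    return SpliceEventSet(f"r-{iso_id}", iso_id, list(events))


def _ev(tp, delta_aa, host="both"):
    from isoformetrics.io import GenomicInterval

    # encode the signed delta via interval lengths (nt = 3 * aa)
    nt = abs(delta_aa) * 3
    iv = [GenomicInterval("c", 1, nt, "+")] if nt else []
    if delta_aa >= 0:
        return SpliceEvent(tp, [], iv, host=host)
    return SpliceEvent(tp, iv, [], host=host)


def test_build_design_hand_assembly():
    pairs = [_pair("i1", d_rg=1.0, d_plddt=2.0), _pair("i2", d_rg=-1.0, d_plddt=-2.0),
             _pair("i3", d_rg=0.5, d_plddt=0.0)]
    sets = {
        "i1": _events("i1", _ev("ES", -10, host="isoform")),
        "i2": _events("i2", _ev("ALE", 7)),
        "i3": _events("i3"),
    }
    design = build_design(pairs, sets, "rg", mode="signed")
    assert design.X.loc[0, "dL_ES(I)"] == -10
    assert design.X.loc[1, "dL_ALE"] == 7
    assert design.X.loc[2].eq(0).all()
    assert design.X.loc[0, "d_pLDDT"] == 2.0
    assert design.y.mean() == pytest.approx(0.0, abs=1e-12)


def test_tm_outcome_forces_absolute_mode():
    pairs = [_pair("i1", 0.0, 2.0, tm=0.9), _pair("i2", 0.0, -1.0, tm=0.4)]
    sets = {"i1": _events("i1", _ev("ES", -10, host="isoform")),
            "i2": _events("i2", _ev("IR", 5, host="reference"))}
    design = build_design(pairs, sets, "tm")
    assert design.mode == "absolute"
    assert "absdL_ES" in design.X.columns and "dL_ES(I)" not in design.X.columns
    assert design.X.loc[0, "absdL_ES"] == 10
    with pytest.raises(ValueError, match="non-directional"):
        build_design(pairs, sets, "tm", mode="signed")


def test_frame_ambiguous_pairs_excluded():
    pairs = [_pair("i1", 1.0, 0.0), _pair("i2", -1.0, 1.0), _pair("i3", 0.5, 2.0)]
    from isoformetrics.io import GenomicInterval

    odd = SpliceEvent("ES", [GenomicInterval("c", 1, 100, "+")], [], host="isoform")
    sets = {"i1": _events("i1", odd), "i2": _events("i2"), "i3": _events("i3")}
    with pytest.warns(UserWarning, match="frame-ambiguous"):
        design = build_design(pairs, sets, "rg")
    assert len(design.X) == 2


def test_effect_summary_flags():
    import pandas as pd

    t1 = pd.DataFrame({"feature": ["a", "b"], "effect": [1.0, 0.1],
                       "se": [0.1, 0.1], "t": [10.0, 1.0], "p": [0.001, 0.4]})
    t2 = pd.DataFrame({"feature": ["a"], "effect": [0.0], "se": [1.0],
                       "t": [0.0], "p": [0.99]})
    out = effect_summary({"rg": t1, "tm": t2})
    assert len(out) == 3
    assert out.loc[out["p"] < 0.05, "significant"].all()
    assert not out.loc[out["p"] >= 0.05, "significant"].any()
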