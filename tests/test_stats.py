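"""Partial Spearman screening, VIF, PCR and leave-one-out CV."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sst

from netlearn import (
    bonferroni,
    loocv,
    partial_spearman,
    pcr_fit,
    pcr_with_loocv,
    screen_nodes,
    vif,
)


def _controls(n_subjects, reps=2):
    subjects = np.repeat([f"s{i:02d}" for i in range(n_subjects)], reps)
    sessions = np.tile(["pre", "post"], n_subjects * reps // 2)
    return pd.DataFrame(
        {
            "session": pd.Categorical(sessions),
            "participant": pd.Categorical(subjects),
        }
    )


# ---------------------------------------------------------------------------
# Partial Spearman
# ---------------------------------------------------------------------------

def test_no_controls_reduces_to_spearman(rng):
    x = rng.standard_normal(30)
    y = 0.5 * x + rng.standard_normal(30)
    res = partial_spearman(x, y)
    rho, p = sst.spearmanr(x, y)
    assert res.rho == pytest.approx(rho, abs=1e-12)
    assert res.p == pytest.approx(p, rel=1e-6)
    assert res.ci95[0] <= res.rho <= res.ci95[1]


def test_monotone_transform_gives_rho_one(rng):
    x = rng.standard_normal(25)
    assert partial_spearman(x, x ** 3).rho == pytest.approx(1.0)
    assert partial_spearman(x, x ** 3).p == 0.0


def test_monotone_transform_invariance(rng):
    x = rng.standard_normal(40)
    y = rng.standard_normal(40)
    c = pd.DataFrame({"c": rng.standard_normal(40)})
    base = partial_spearman(x, y, controls=c).rho
    assert partial_spearman(np.exp(x), y, controls=c).rho == pytest.approx(base)
    assert partial_spearman(x, y ** 3 + 5 * y, controls=c).rho == pytest.approx(base)


def test_session_driven_outcome_partials_to_zero():
    """y carried entirely by the session dummy: the partial correlation
    with an unrelated x vanishes on average."""
    rhos = []
    for seed in range(100):
        r = np.random.default_rng(seed)
        controls = _controls(10)
        x = r.standard_normal(20)
        y = 2.0 * (controls["session"] == "post").to_numpy(float)
        y = y + 0.05 * r.standard_normal(20)
        rhos.append(partial_spearman(x, y, controls=controls).rho)
    assert abs(np.mean(rhos)) < 0.05


def test_matches_pingouin_partial_spearman(rng):
    pg = pytest.importorskip("pingouin")
    n = 40
    c = rng.standard_normal(n)
    x = 0.5 * c + rng.standard_normal(n)
    y = 0.4 * c + 0.3 * x + rng.standard_normal(n)
    # pingouin rank-transforms the covariate as well
    mine = partial_spearman(
        x, y, controls=pd.DataFrame({"c": sst.rankdata(c)})
    )
    ref = pg.partial_corr(
        data=pd.DataFrame({"x": x, "y": y, "c": c}),
        x="x", y="y", covar="c", method="spearman",
    )
    assert mine.rho == pytest.approx(float(ref["r"].iloc[0]), abs=1e-9)
    assert mine.p == pytest.approx(float(ref["p_val"].iloc[0]), rel=1e-6)


def test_partial_spearman_degenerate_inputs(rng):
    x = rng.standard_normal(6)
    with pytest.raises(ValueError, match="degrees of freedom"):
        partial_spearman(x, x, controls=_controls(3))
    dup = pd.DataFrame(
        {"a": ["u", "u", "v", "v", "w", "w"], "b": ["u", "u", "v", "v", "w", "w"]}
    )
    with pytest.raises(ValueError, match="rank-deficient"):
        partial_spearman(rng.standard_normal(6), rng.standard_normal(6),
                         controls=dup)


# ---------------------------------------------------------------------------
# Bonferroni
# ---------------------------------------------------------------------------

def test_bonferroni_arithmetic():
    p = [0.002] + [0.5] * 15
    flags = bonferroni(p, alpha=0.05)
    assert flags[0] and not flags[1:].any()  # 0.002 < 0.05/16
    p2 = [0.004] + [0.5] * 15
    assert not bonferroni(p2, alpha=0.05)[0]  # 0.004 > 0.003125
    assert bonferroni([0.04], alpha=0.05)[0]  # m=1 reduces to p < alpha
    with pytest.raises(ValueError):
        bonferroni([1.2])


# ---------------------------------------------------------------------------
# VIF
# ---------------------------------------------------------------------------

def _centered_orthonormal(rng, n, k):
    """Zero-mean columns with exactly zero pairwise sample correlation."""
    cols = []
    for _ in range(k):
        v = rng.standard_normal(n)
        v = v - v.mean()
        for u in cols:
            v = v - (v @ u) * u
        v = v - v.mean()
        cols.append(v / np.linalg.norm(v))
    return cols


def test_vif_orthogonal_features_are_one(rng):
    a, b, c = _centered_orthonormal(rng, 50, 3)
    out = vif(pd.DataFrame({"a": a, "b": b, "c": c}))
    assert np.allclose(out.to_numpy(), 1.0, atol=1e-8)


def test_vif_closed_form_for_correlated_pair(rng):
    # build two columns with exact sample correlation 0.9
    z1, z2 = _centered_orthonormal(rng, 200, 2)
    x1 = z1
    x2 = 0.9 * z1 + np.sqrt(1 - 0.81) * z2
    out = vif(pd.DataFrame({"x1": x1, "x2": x2}))
    assert out["x1"] == pytest.approx(1 / (1 - 0.81), abs=1e-6)  # 5.263...
    assert out["x2"] == pytest.approx(5.263157894736842, abs=1e-6)


def test_vif_duplicate_column_is_infinite(rng):
    x = rng.standard_normal(30)
    out = vif(pd.DataFrame({"a": x, "b": x, "c": rng.standard_normal(30)}))
    assert np.isinf(out["a"]) and np.isinf(out["b"])
    assert np.isfinite(out["c"])


# ---------------------------------------------------------------------------
# PCR
# ---------------------------------------------------------------------------

def test_pcr_perfect_fit(rng):
    x = rng.standard_normal(30)
    features = pd.DataFrame({"a": x, "b": 2 * x + 1})
    model = pcr_fit(features, y=3.0 * x)  # y linear in the (shared) component
    assert model.r2 == pytest.approx(1.0, abs=1e-10)
    assert model.explained_variance == pytest.approx(1.0, abs=1e-10)
    assert model.beta0 > 0  # sign convention: component tracks the outcome


def test_pcr_null_slope_centred(rng):
    b0s, r2s = [], []
    for seed in range(50):
        r = np.random.default_rng(seed)
        features = pd.DataFrame(r.standard_normal((40, 3)),
                                columns=["a", "b", "c"])
        y = r.standard_normal(40)
        m = pcr_fit(features, y)
        b0s.append(m.beta0)
        r2s.append(m.r2)
    # the sign convention makes beta0 >= 0; it stays small under the null
    assert np.mean(r2s) < 0.12
    assert np.mean(b0s) < 0.25


def test_pcr_slope_recovery_within_two_se(rng):
    """y' = 0.5 x' + noise: the fitted slope covers the truth at ~95%."""
    hits = 0
    for seed in range(100):
        r = np.random.default_rng(seed)
        x = r.standard_normal(40)
        features = pd.DataFrame({"a": x})  # single standardized feature
        scores = (x - x.mean()) / x.std(ddof=1)
        y = 0.5 * scores + 0.3 * r.standard_normal(40)
        m = pcr_fit(features, y)
        if abs(m.beta0 - 0.5) <= 2 * m.beta0_se:
            hits += 1
    assert hits >= 90


def test_pcr_with_controls_residualizes(rng):
    controls = _controls(10)
    sess = (controls["session"] == "post").to_numpy(float)
    x = rng.standard_normal(20)
    y = 5.0 * sess + 0.8 * (x - x.mean()) / x.std(ddof=1)
    m = pcr_fit(pd.DataFrame({"a": x}), y, controls=controls)
    # the big session effect is removed before the regression
    assert m.beta0 == pytest.approx(0.8, abs=0.05)


def test_pcr_degenerate_inputs(rng):
    with pytest.raises(ValueError, match="zero-variance"):
        pcr_fit(pd.DataFrame({"a": np.ones(10)}), rng.standard_normal(10))
    with pytest.raises(ValueError, match="at least one"):
        pcr_fit(pd.DataFrame(index=range(10)), rng.standard_normal(10))


# ---------------------------------------------------------------------------
# LOOCV
# ---------------------------------------------------------------------------

def test_loocv_noiseless_relationship(rng):
    x = rng.standard_normal(25)
    features = pd.DataFrame({"a": x, "b": -x})
    y = 2.0 * (x - x.mean()) / x.std(ddof=1)
    r2, rmse = loocv(features, y)
    assert r2 > 0.99
    assert rmse < 0.05


def test_loocv_pure_noise_r2_nonpositive_in_expectation(rng):
    r2s = []
    for seed in range(50):
        r = np.random.default_rng(seed)
        features = pd.DataFrame(r.standard_normal((20, 2)), columns=["a", "b"])
        r2s.append(loocv(features, r.standard_normal(20))[0])
    assert np.mean(r2s) <= 0.0


def test_loocv_rmse_at_least_in_sample_rmse(rng):
    wins = 0
    for seed in range(100):
        r = np.random.default_rng(seed)
        x = r.standard_normal(20)
        features = pd.DataFrame({"a": x + 0.1 * r.standard_normal(20),
                                 "b": x + 0.1 * r.standard_normal(20)})
        y = 0.5 * x + r.standard_normal(20)
        model = pcr_fit(features, y)
        _, rmse_cv = loocv(features, y)
        # in-sample rmse from the model fit
        from netlearn.stats import _ols_line, _pc_scores, control_design, _residualize
        s, _, _, _, _ = _pc_scores(features.to_numpy(float), y)
        Z = control_design(None, 20)
        xr, yr = _residualize(s, Z), _residualize(y, Z)
        resid = yr - (model.beta0 * xr + model.beta1)
        rmse_in = float(np.sqrt((resid ** 2).mean()))
        if rmse_cv >= rmse_in - 1e-12:
            wins += 1
    assert wins >= 95  # cross-validation is pessimistic vs in-sample fit


def test_loocv_refits_everything_per_fold(rng):
    """No leakage: per-fold standardization means must differ."""
    features = pd.DataFrame(rng.standard_normal((12, 3)),
                            columns=["a", "b", "c"])
    y = rng.standard_normal(12)
    _, _, details = loocv(features, y, return_details=True)
    means = np.stack(details["fold_means"])
    assert len(np.unique(means[:, 0])) > 1


def test_loocv_rescreen_mode_reports_fold_selections(rng):
    x = rng.standard_normal(24)
    features = pd.DataFrame(
        {
            "hit": x + 0.1 * rng.standard_normal(24),
            "miss1": rng.standard_normal(24),
            "miss2": rng.standard_normal(24),
        }
    )
    y = x + 0.1 * rng.standard_normal(24)
    r2, rmse, details = loocv(
        features, y, rescreen=True, return_details=True
    )
    assert r2 > 0.8
    assert all("hit" in nodes for nodes in details["fold_nodes"])


def test_loocv_needs_five_observations(rng):
    with pytest.raises(ValueError, match="at least 5"):
        loocv(pd.DataFrame({"a": np.arange(4.0)}), np.arange(4.0))


# ---------------------------------------------------------------------------
# The full screening chain
# ---------------------------------------------------------------------------

def test_chain_selects_superset_of_planted_nodes():
    """Nodes carrying a within-subject monotone association with the
    outcome survive screening in nearly every replicate."""
    planted = ["n03", "n07", "n11"]
    hits = 0
    n_rep = 20
    for seed in range(n_rep):
        r = np.random.default_rng(seed)
        controls = _controls(20)
        z = r.standard_normal(40)  # latent per subject x session
        y = (
            np.repeat(r.standard_normal(20), 2)  # subject effects
            + 0.3 * (controls["session"] == "post").to_numpy(float)
            + 1.0 * z
            + 0.1 * r.standard_normal(40)
        )
        cols = {}
        for i in range(16):
            name = f"n{i:02d}"
            if name in planted:
                cols[name] = 0.9 * z + 0.3 * r.standard_normal(40)
            else:
                cols[name] = r.standard_normal(40)
        table = screen_nodes(pd.DataFrame(cols), y, controls=controls)
        selected = set(table.loc[table["significant"], "node"])
        if set(planted) <= selected:
            hits += 1
    assert hits >= 0.9 * n_rep


def test_pcr_with_loocv_populates_cv_fields(rng):
    x = rng.standard_normal(20)
    features = pd.DataFrame({"a": x})
    y = 0.5 * x + 0.2 * rng.standard_normal(20)
    m = pcr_with_loocv(features, y)
    assert m.loocv_r2 is not None and m.loocv_rmse is not None
    assert m.loocv_rmse >= 0
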