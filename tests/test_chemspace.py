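import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glomtune.chemspace import (
    ChemSpace,
    distance_matrix,
    expected_random_performance,
    glomerulus_performance,
    pca_chemspace,
    performance_metric,
    smarts42_fingerprints,
    smarts42_patterns,
    zscore_features,
)

# --- SMARTS42 keyset ---------------------------------------------------------

KEY = {  # 1-based indices of selected keys, in shipped file order
    "acid": 1, "aldehyde": 2, "ester": 3, "ketone": 5, "alcohol": 6,
    "benzyl": 7, "thioether": 18, "thiol": 20, "alkene": 21, "sulfur": 22,
    "nitrogen": 23, "oxygen": 24, "ring": 25, "chain4": 26, "pyrazine": 16,
    "c6": 37,
}

# ten molecules with fully hand-derived 42-bit fingerprints (bits listed are
# the 1-based indices of the set keys; every other key is 0)
HAND_DERIVED = {
    "C": set(),                                        # methane
    "CCO": {6, 24},                                    # ethanol
    "CCCCCC=O": {2, 24, 26, 37},                       # hexanal
    "O=Cc1ccccc1": {2, 7, 24, 25},                     # benzaldehyde
    "CC(=O)c1ccccc1": {5, 7, 24, 25},                  # acetophenone
    "CCCCCC(=O)O": {1, 24, 26, 37},                    # hexanoic acid
    "CCOC(C)=O": {3, 24},                              # ethyl acetate
    "CCSCC": {18, 22},                                 # diethyl sulfide
    "CCS": {20, 22},                                   # ethanethiol
    "c1cnccn1": {16, 23, 25},                          # pyrazine
}


def test_patterns_parse_to_exactly_42():
    patterns = smarts42_patterns()
    assert len(patterns) == 42
    fp = smarts42_fingerprints(["CCCCCC=O"])
    assert fp.shape[1] == 42


def test_fingerprints_match_hand_derived_bits():
    smiles = list(HAND_DERIVED)
    fp = smarts42_fingerprints(smiles)
    for i, smi in enumerate(smiles):
        expected = np.zeros(42)
        for k in HAND_DERIVED[smi]:
            expected[k - 1] = 1.0
        np.testing.assert_array_equal(
            fp.iloc[i].to_numpy(), expected,
            err_msg=f"fingerprint mismatch for {smi}",
        )


def test_unparseable_smiles_flagged_absent(caplog):
    with caplog.at_level("WARNING"):
        fp = smarts42_fingerprints(["CCO", "C1CC"])
    assert fp.iloc[1].isna().all()
    assert not fp.iloc[0].isna().any()


def test_bad_pattern_file_raises(tmp_path):
    path = tmp_path / "keys.txt"
    path.write_text("CCO\tfine\nC1CC(\tbroken\n", encoding="utf-8")
    with pytest.raises(ValueError, match="pattern 2"):
        smarts42_patterns(path)


# --- feature processing ------------------------------------------------------

def test_zscore_drops_constant_columns():
    raw = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [7.0, 7.0, 7.0]})
    z = zscore_features(raw)
    assert list(z.columns) == ["a"]
    np.testing.assert_allclose(z["a"].mean(), 0.0, atol=1e-12)
    np.testing.assert_allclose(z["a"].std(ddof=0), 1.0)


def test_zscore_hand_computed():
    raw = pd.DataFrame({"a": [0.0, 2.0], "b": [1.0, 3.0]})
    z = zscore_features(raw)
    np.testing.assert_allclose(z.to_numpy(), [[-1.0, -1.0], [1.0, 1.0]])


def test_zscore_idempotent():
    rng = np.random.default_rng(0)
    raw = pd.DataFrame(rng.normal(size=(10, 4)))
    z = zscore_features(raw)
    zz = zscore_features(z)
    np.testing.assert_allclose(z.to_numpy(), zz.to_numpy(), atol=1e-12)


def test_zscore_all_constant_errors():
    with pytest.raises(ValueError):
        zscore_features(pd.DataFrame({"a": [1.0, 1.0]}))


def test_dice_distances():
    feats = pd.DataFrame(
        [[1, 1, 0], [1, 1, 0], [0, 0, 1], [1, 0, 1]],
        index=list("abcd"), dtype=float,
    )
    d = distance_matrix(feats, "one-minus-dice")
    assert d.loc["a", "b"] == 0.0               # identical rows
    assert d.loc["a", "c"] == 1.0               # disjoint rows
    assert d.loc["b", "d"] == pytest.approx(0.5)  # dice = 2*1/(2+2)
    assert np.allclose(d.to_numpy(), d.to_numpy().T)
    assert (np.diag(d.to_numpy()) == 0).all()
    # the ChemSpace container induces the same distance matrix on construction
    space = ChemSpace(features=feats, metric="one-minus-dice")
    np.testing.assert_allclose(space.distance.to_numpy(), d.to_numpy())


def test_cosine_zero_norm_flagged(caplog):
    feats = pd.DataFrame([[1.0, 0.0], [0.0, 0.0]], index=["a", "b"])
    with caplog.at_level("WARNING"):
        d = distance_matrix(feats, "cosine")
    assert np.isnan(d.loc["a", "b"])
    assert d.loc["a", "a"] == 0.0


def test_pca_chemspace_svd_oracle():
    rng = np.random.default_rng(1)
    lib = pd.DataFrame(rng.normal(size=(40, 8)),
                       index=[f"o{i}" for i in range(40)])
    scores, cumvar = pca_chemspace(lib, n_pcs=5)
    # independent SVD oracle on the z-scored matrix
    z = (lib - lib.mean()) / lib.std(ddof=0)
    s = np.linalg.svd(z.to_numpy(), compute_uv=False)
    np.testing.assert_allclose(
        cumvar.to_numpy(), np.cumsum(s**2) / (s**2).sum(), atol=1e-10
    )
    assert scores.shape == (40, 5)
    # distances are rotation-invariant: full-rank scores reproduce z distances
    full, _ = pca_chemspace(lib, n_pcs=8)
    from scipy.spatial.distance import pdist
    np.testing.assert_allclose(
        pdist(full.to_numpy()), pdist(z.to_numpy()), atol=1e-8
    )


def test_pca_chemspace_rank_two_library():
    base = np.random.default_rng(2).normal(size=(2, 6))
    coef = np.random.default_rng(3).normal(size=(30, 2))
    lib = pd.DataFrame(coef @ base)
    scores, cumvar = pca_chemspace(lib, n_pcs=2)
    assert cumvar.iloc[1] == pytest.approx(1.0)


# --- performance metric ------------------------------------------------------

def trapezoid_oracle(ordered: np.ndarray) -> float:
    """Brute-force cumulative-curve AUC: explicit trapezoid over the grid."""
    n = len(ordered)
    y = np.concatenate([[0.0], np.cumsum(ordered) / ordered.sum()])
    x = np.arange(n + 1) / n
    return sum((x[i + 1] - x[i]) * (y[i + 1] + y[i]) / 2 for i in range(n))


def panel_series(n, responders, query="q"):
    idx = [query] + [f"o{i}" for i in range(n - 1)]
    resp = pd.Series(0.0, index=idx)
    for r in responders:
        resp[f"o{r}"] = 1.0
    return resp


def test_perfect_ranking_scores_one():
    resp = panel_series(185, [0, 1, 2])
    dist = pd.Series(np.arange(185, dtype=float), index=resp.index)
    out = performance_metric(resp, dist, "q")
    assert out.P == pytest.approx(1.0)
    assert out.auc_model == out.auc_response


def test_worst_ranking_matches_trapezoid_oracle():
    # 5-odorant panel, 2 responders among the 4 non-query odorants, ranked last
    resp = panel_series(5, [2, 3])
    dist = pd.Series([0.0, 1.0, 2.0, 3.0, 4.0], index=resp.index)
    out = performance_metric(resp, dist, "q")
    worst = np.array([0.0, 0.0, 1.0, 1.0])
    best = np.array([1.0, 1.0, 0.0, 0.0])
    auc_model = trapezoid_oracle(worst)
    auc_response = trapezoid_oracle(best)
    assert out.auc_model == pytest.approx(auc_model)
    assert out.auc_response == pytest.approx(auc_response)
    assert out.P == pytest.approx(1 - 2 * (auc_response - auc_model) / auc_response)


def test_random_ranking_mean_matches_closed_form():
    rng = np.random.default_rng(4)
    resp = panel_series(185, [10, 20])
    base = np.arange(184, dtype=float)
    others = [o for o in resp.index if o != "q"]
    ps, aucs = [], []
    for _ in range(5000):
        dist = pd.Series(rng.permutation(base), index=others)
        out = performance_metric(resp, dist, "q")
        ps.append(out.P)
        aucs.append(out.auc_response)
    expected = expected_random_performance(aucs[0])
    # P has s.d. ~0.41 under random rankings: tolerance ~3.5 standard errors
    assert np.mean(ps) == pytest.approx(expected, abs=0.02)
    assert round(float(np.mean(ps)), 1) == 0.0


def test_metric_invariant_to_monotone_distance_transform():
    rng = np.random.default_rng(5)
    resp = pd.Series(rng.integers(0, 2, 30).astype(float),
                     index=[f"o{i}" for i in range(30)])
    resp.iloc[0] = 1.0
    dist = pd.Series(rng.random(30), index=resp.index)
    a = performance_metric(resp, dist, "o0").P
    b = performance_metric(resp, dist**3 + 2.0, "o0").P
    assert a == pytest.approx(b)


def test_no_responses_flagged(caplog):
    resp = panel_series(10, [])
    dist = pd.Series(np.arange(10, dtype=float), index=resp.index)
    with caplog.at_level("WARNING"):
        out = performance_metric(resp, dist, "q")
    assert np.isnan(out.P)


def test_constant_distances_degenerate_flagged(caplog):
    resp = panel_series(10, [3])
    dist = pd.Series(1.0, index=resp.index)
    with caplog.at_level("WARNING"):
        out = performance_metric(resp, dist, "q")
    assert any("degenerate" in rec.message for rec in caplog.records)
    assert np.isfinite(out.P)


def test_amplitude_mode_uses_summed_amplitudes():
    idx = ["q", "o0", "o1", "o2"]
    resp = pd.Series([0.0, 3.0, 1.0, 0.0], index=idx)
    dist = pd.Series([0.0, 1.0, 2.0, 3.0], index=idx)
    out = performance_metric(resp, dist, "q", mode="amplitude")
    # model curve accumulates amplitudes 3, 1, 0 -> exact trapezoid
    assert out.auc_model == pytest.approx(trapezoid_oracle(np.array([3.0, 1.0, 0.0])))
    assert out.P == pytest.approx(1.0)


def test_single_effective_odorant_glomeruli_excluded():
    matrix = pd.DataFrame(
        {"o0": [1.0, 1.0], "o1": [0.0, 0.5], "o2": [0.0, 0.0]},
        index=["narrow", "broad"],
    )
    feats = pd.DataFrame(np.eye(3), index=["o0", "o1", "o2"])
    dist = distance_matrix(feats, "one-minus-dice")
    out = glomerulus_performance(matrix, dist)
    assert "narrow" not in out.index
    assert "broad" in out.index


def test_class_aligned_space_beats_shuffled(noise_free_truth):
    """SMARTS42 distances on the class-structured synthetic panel predict
    co-tuning better than the same distances with shuffled odorant labels."""
    panel = noise_free_truth.panel
    smiles = pd.Series({o.id: o.smiles for o in panel})
    fp = smarts42_fingerprints(smiles)
    dist = distance_matrix(fp, "one-minus-dice")
    matrix = noise_free_truth.amplitudes
    aligned = glomerulus_performance(matrix, dist)
    rng = np.random.default_rng(6)
    perm = rng.permutation(dist.index.to_numpy())
    shuffled = pd.DataFrame(dist.to_numpy(), index=perm, columns=perm)
    shuffled = shuffled.loc[dist.index, dist.index]
    control = glomerulus_performance(matrix, shuffled)
    assert aligned.median() > control.median()
    assert aligned.median() > 0.2


@given(st.integers(2, 20), st.integers(0, 10_000))
@settings(max_examples=30, deadline=None)
def test_p_at_most_one_and_one_iff_perfect(n_resp, seed):
    rng = np.random.default_rng(seed)
    n = 50
    resp = pd.Series(0.0, index=[f"o{i}" for i in range(n)])
    responders = rng.choice(n - 1, size=min(n_resp, n - 2), replace=False) + 1
    resp.iloc[responders] = 1.0
    dist = pd.Series(rng.random(n), index=resp.index)
    out = performance_metric(resp, dist, "o0")
    assert out.P <= 1.0 + 1e-12
    order = np.argsort(dist.iloc[1:].to_numpy(), kind="stable")
    ranked = resp.iloc[1:].to_numpy()[order]
    perfect = (np.diff(ranked) <= 0).all()
    assert (abs(out.P - 1.0) < 1e-12) == perfect
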