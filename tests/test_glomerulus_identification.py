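import numpy as np
import pytest

from glomtune.containers import ResponseDataset
from glomtune.glomerulus_identification import (
    consensus_table,
    error_ratio,
    identify_glomeruli,
    median_ors_correlation,
    screen_diagnostic,
)

from conftest import make_dataset, make_ob

ODORANTS = [f"od{i}" for i in range(8)]


def ob_from_rows(rows: dict, ob_id: str, mouse_id: str):
    return make_ob(
        {g: dict(zip(ODORANTS, vals)) for g, vals in rows.items()}, ob_id, mouse_id
    )


def eight_identical_obs(rows: dict) -> ResponseDataset:
    return make_dataset(
        ob_from_rows(rows, f"m{m}{s}", f"m{m}")
        for m in range(1, 5) for s in ("L", "R")
    )


BASE_ROWS = {
    "gA": [5.0, 0, 0, 1.0, 0, 0, 0, 0],
    "gB": [0, 4.0, 0, 0, 2.0, 0, 0, 0],
    "gC": [0, 0, 3.0, 0, 0, 1.5, 0.5, 0],
}


def test_screen_excludes_silent_odorant():
    ds = eight_identical_obs(BASE_ROWS)
    passed = screen_diagnostic(ds)
    assert "od7" not in passed  # silent everywhere
    assert "od0" in passed


def test_screen_excludes_unreliable_odorant():
    rows_silent = {g: list(v) for g, v in BASE_ROWS.items()}
    for g in rows_silent:
        rows_silent[g][0] = 0.0  # od0 silent in 3 of 8 OBs
    obs = []
    for k, (m, s) in enumerate((m, s) for m in range(1, 5) for s in ("LR")):
        rows = rows_silent if k < 3 else BASE_ROWS
        obs.append(ob_from_rows(rows, f"m{m}{s}", f"m{m}"))
    ds = make_dataset(obs)
    assert "od0" not in screen_diagnostic(ds)


def test_screen_excludes_broad_activation():
    rows = {g: list(v) for g, v in BASE_ROWS.items()}
    # three glomeruli above 50% of the od0 max in one OB
    rows["gA"][0], rows["gB"][0], rows["gC"][0] = 5.0, 4.0, 3.0
    obs = [ob_from_rows(BASE_ROWS, f"m{m}{s}", f"m{m}")
           for m in range(1, 5) for s in ("L", "R")]
    obs[0] = ob_from_rows(rows, "m1L", "m1")
    assert "od0" not in screen_diagnostic(make_dataset(obs))


def test_error_ratio_identical_spectra_is_zero():
    ds = eight_identical_obs(BASE_ROWS)
    assert error_ratio(ds, "od0") == 0.0
    assert median_ors_correlation(ds, "od0") == pytest.approx(1.0)


# Rows for the shuffled-OB construction: gE is a near-copy of gA (but never
# maximally activated by od0) and gF is a near-copy of the shuffled spectrum,
# so in the shuffled OB the od0 winner's spectrum never best-correlates.
SHUFFLE_BASE = {
    "gA": [5.0, 0, 0, 1.0, 0, 0, 0, 0],
    "gB": [0, 4.0, 0, 0, 2.0, 0, 0, 0],
    "gC": [0, 0, 3.0, 0, 0, 1.5, 0.5, 0],
    "gE": [4.0, 0, 0, 0.9, 0, 0.1, 0, 0],
    "gF": [4.9, 0, 3.0, 0, 0, 0, 3.0, 0],
}
SHUFFLE_SWAPPED = dict(SHUFFLE_BASE, gA=[5.0, 0, 3.0, 0, 0, 0, 3.0, 0])


def test_error_ratio_shuffled_ob_enumeration_oracle():
    """With 4 OBs and the max-activated glomerulus of one OB carrying a
    spectrum that never best-correlates, 6 of the 12 ordered comparisons
    mismatch."""
    obs = [ob_from_rows(SHUFFLE_BASE, f"m{m}L", f"m{m}") for m in range(1, 5)]
    obs[3] = ob_from_rows(SHUFFLE_SWAPPED, "m4L", "m4")
    ds = make_dataset(obs)
    # enumeration oracle: all 3 ordered pairs into OB4 pick gE (a closer
    # spectral match than OB4's winner) and all 3 pairs out of OB4 pick gF;
    # the 6 base-base pairs match exactly
    assert error_ratio(ds, "od0", ordered=True) == pytest.approx(6 / 12)


def test_error_ratio_single_responsive_ob_undefined():
    rows_silent = {g: [0.0] + list(v)[1:] for g, v in BASE_ROWS.items()}
    obs = [ob_from_rows(rows_silent, f"m{m}{s}", f"m{m}")
           for m in range(1, 5) for s in ("L", "R")]
    obs[0] = ob_from_rows(BASE_ROWS, "m1L", "m1")
    assert np.isnan(error_ratio(make_dataset(obs), "od0"))


def test_median_ors_correlation_robust_to_one_outlier():
    obs = [ob_from_rows(BASE_ROWS, f"m{m}{s}", f"m{m}")
           for m in range(1, 5) for s in ("L", "R")]
    rows = {g: list(v) for g, v in BASE_ROWS.items()}
    rows["gA"] = [5.0, 3.0, 3.0, 0.0, 3.0, 3.0, 3.0, 3.0]  # decorrelated spectrum
    obs[7] = ob_from_rows(rows, "m4R", "m4")
    ds = make_dataset(obs)
    # 21 of 28 unordered pairs are still perfectly correlated
    assert median_ors_correlation(ds, "od0") == pytest.approx(1.0)


def test_identify_recovers_planted_diagnostics(noise_free_truth, noise_free_dataset):
    glomeruli = identify_glomeruli(noise_free_dataset)
    identified_odorants = {
        od for g in glomeruli for od in g.diagnostic_odorants
    }
    planted = set(
        noise_free_truth.primary_odorant[noise_free_truth.diagnostic_flags]
    )
    assert planted <= identified_odorants
    # the planted diagnostics map to exactly n_diagnostic distinct glomeruli,
    # each recovered with a perfect error ratio and ORS correlation
    planted_gloms = [
        g for g in glomeruli if set(g.diagnostic_odorants) & planted
    ]
    assert len(planted_gloms) == int(noise_free_truth.diagnostic_flags.sum())
    for g in planted_gloms:
        for od in set(g.diagnostic_odorants) & planted:
            err, med = g.odorant_stats[od]
            assert err == 0.0
            assert med == pytest.approx(1.0)


def test_identified_positions_match_planted_types(noise_free_truth, noise_free_dataset, noise_free_config):
    glomeruli = identify_glomeruli(noise_free_dataset)
    planted = set(noise_free_truth.primary_odorant[noise_free_truth.diagnostic_flags])
    primary_to_type = {
        od: t for t, od in noise_free_truth.primary_odorant.items()
    }
    for g in glomeruli:
        hits = set(g.diagnostic_odorants) & planted
        if not hits:
            continue
        tid = primary_to_type[next(iter(hits))]
        home = noise_free_truth.type_positions.loc[tid]
        # mean position within a few jitter s.d.s of the planted home
        jitter = noise_free_config.position_jitter_sd
        assert abs(g.position_mean[0] - home["ml_um"]) < 3 * jitter
        assert abs(g.position_mean[1] - home["ap_um"]) < 3 * jitter


def test_two_diagnostics_on_one_type_are_grouped():
    rows = {
        # gA responds singularly to both od0 and od3
        "gA": [5.0, 0, 0, 2.0, 0, 0, 0, 0],
        "gB": [0, 4.0, 0, 0, 2.0, 0, 0, 0],
        "gC": [0, 0, 3.0, 0, 0, 1.5, 0.5, 0],
    }
    ds = eight_identical_obs(rows)
    glomeruli = identify_glomeruli(ds)
    by_members = {tuple(g.diagnostic_odorants) for g in glomeruli}
    assert any({"od0", "od3"} <= set(m) for m in by_members)


def test_identify_invariant_to_ob_order(noise_free_dataset):
    forward = identify_glomeruli(noise_free_dataset)
    reversed_ds = ResponseDataset(list(reversed(noise_free_dataset.obs)))
    backward = identify_glomeruli(reversed_ds)
    key = lambda gs: sorted(tuple(g.diagnostic_odorants) for g in gs)
    assert key(forward) == key(backward)


def test_high_error_ratio_excluded():
    # half the OBs carry a decorrelated winner for od0: every cross-half
    # comparison mismatches (error ratio 32/56 > 0.2) so od0 is rejected
    obs = [ob_from_rows(SHUFFLE_BASE, f"m{m}{s}", f"m{m}")
           for m in range(1, 5) for s in ("L", "R")]
    for k in (1, 3, 5, 7):
        obs[k] = ob_from_rows(SHUFFLE_SWAPPED, obs[k].ob_id, obs[k].mouse_id)
    ds = make_dataset(obs)
    assert error_ratio(ds, "od0") > 0.2
    glomeruli = identify_glomeruli(ds)
    assert "od0" not in {od for g in glomeruli for od in g.diagnostic_odorants}


def test_lowering_r_min_never_removes(noise_free_dataset):
    strict = identify_glomeruli(noise_free_dataset, r_min=0.8)
    lax = identify_glomeruli(noise_free_dataset, r_min=0.5)
    strict_ods = {od for g in strict for od in g.diagnostic_odorants}
    lax_ods = {od for g in lax for od in g.diagnostic_odorants}
    assert strict_ods <= lax_ods


def test_consensus_table_layout(noise_free_dataset):
    glomeruli = identify_glomeruli(noise_free_dataset)
    table = consensus_table(glomeruli)
    assert set(table.columns) >= {
        "glomerulus", "odorant", "error_ratio", "median_ors_corr",
        "ml_um_mean", "ml_um_sd", "ap_um_mean", "ap_um_sd",
    }
    assert table["error_ratio"].between(0, 1).all()
    for g in glomeruli:
        assert g.consensus_spectrum.max() == pytest.approx(1.0)
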