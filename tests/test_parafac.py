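"""PARAFAC fitting, congruence, split-half and Fmax tests."""

from __future__ import annotations

import numpy as np
import pytest

from soilcnet import synth
from soilcnet.eem import EM_GRID, EX_GRID, EEMCube, correct_eems
from soilcnet.parafac import (
    PARAFACModel,
    _match_loadings,
    compute_fmax,
    default_library,
    fit_parafac,
    fmax_relative,
    library_from_csv,
    library_to_csv,
    match_components,
    split_half_validate,
    tucker_congruence,
)


# --------------------------------------------------------------- congruence


def test_tucker_congruence_of_identical_vectors_is_one(rng):
    v = rng.random(50)
    assert tucker_congruence(v, v) == pytest.approx(1.0, abs=1e-12)


def test_tucker_congruence_is_scale_invariant(rng):
    v = rng.random(50)
    assert tucker_congruence(v, 3.7 * v) == pytest.approx(1.0, abs=1e-12)


def test_tucker_congruence_of_orthogonal_vectors_is_zero():
    a = np.array([1.0, 0.0, 0.0])
    b = np.array([0.0, 1.0, 0.0])
    assert tucker_congruence(a, b) == pytest.approx(0.0, abs=1e-15)


def test_tucker_congruence_rejects_zero_vectors():
    with pytest.raises(ValueError, match="zero vector"):
        tucker_congruence(np.zeros(5), np.ones(5))


def test_tucker_congruence_rejects_length_mismatch():
    with pytest.raises(ValueError, match="equal length"):
        tucker_congruence(np.ones(5), np.ones(6))


# ----------------------------------------------------------------- fitting


def test_noiseless_cube_is_recovered_exactly(noiseless_setup):
    """Without noise the trilinear model is identifiable: fitted loadings
    match the generating spectra with TCC ~ 1 and explained variance ~ 1."""
    model, truth = noiseless_setup["model"], noiseless_setup["truth"]
    assert model.explained_variance > 0.9999
    ex_t = truth.true_ex_loadings.to_numpy()
    em_t = truth.true_em_loadings.to_numpy()
    # Components are ordered by ascending emission peak: C1(401) C2(443) C3(468).
    for r in range(3):
        assert tucker_congruence(model.ex_loadings[:, r], ex_t[:, r]) > 0.9999
        assert tucker_congruence(model.em_loadings[:, r], em_t[:, r]) > 0.9999


def test_noiseless_scores_are_proportional_to_truth(noiseless_setup):
    model, truth = noiseless_setup["model"], noiseless_setup["truth"]
    fitted = model.scores_frame()
    for c in ("C1", "C2", "C3"):
        ratio = fitted[c].to_numpy() / truth.true_scores[c].to_numpy()
        assert np.ptp(ratio) < 1e-3 * ratio.mean()


def test_fitted_components_are_ordered_by_emission_peak(fitted_model):
    peaks = fitted_model.em_peaks()
    assert (np.diff(peaks) > 0).all()
    # Default geometry: emission maxima near 401, 443, 468 nm.
    np.testing.assert_allclose(peaks, [401, 443, 468], atol=5)


def test_loadings_are_unit_norm_and_nonnegative(fitted_model):
    np.testing.assert_allclose(np.linalg.norm(fitted_model.ex_loadings, axis=0), 1.0, rtol=1e-9)
    np.testing.assert_allclose(np.linalg.norm(fitted_model.em_loadings, axis=0), 1.0, rtol=1e-9)
    assert fitted_model.ex_loadings.min() >= 0
    assert fitted_model.em_loadings.min() >= 0
    assert fitted_model.scores.min() >= 0


def test_fit_is_deterministic_for_a_fixed_seed(noiseless_setup):
    c = noiseless_setup["corrected"]
    a = fit_parafac(c, n_components=3, n_starts=2, seed=11)
    b = fit_parafac(c, n_components=3, n_starts=2, seed=11)
    np.testing.assert_array_equal(a.scores, b.scores)
    np.testing.assert_array_equal(a.ex_loadings, b.ex_loadings)
    np.testing.assert_array_equal(a.em_loadings, b.em_loadings)


def test_sample_order_does_not_change_the_spectra(noiseless_setup):
    """Permuting samples permutes scores but leaves loadings unchanged (up
    to floating-point summation order)."""
    c = noiseless_setup["corrected"]
    perm = np.random.default_rng(5).permutation(c.n_samples)
    shuffled = EEMCube(
        sample_ids=[c.sample_ids[i] for i in perm],
        ex_grid=c.ex_grid, em_grid=c.em_grid,
        intensities=c.intensities[perm], corrected=True,
    )
    a = fit_parafac(c, n_components=3, n_starts=2, seed=11)
    b = fit_parafac(shuffled, n_components=3, n_starts=2, seed=11)
    np.testing.assert_allclose(a.ex_loadings, b.ex_loadings, atol=1e-5)
    np.testing.assert_allclose(a.em_loadings, b.em_loadings, atol=1e-5)
    np.testing.assert_allclose(a.scores[perm], b.scores, rtol=1e-3)


def test_rank_one_cube_is_fit_by_a_single_component(rng):
    em = np.exp(-0.5 * ((EM_GRID - 430) / 30.0) ** 2)
    ex = np.exp(-0.5 * ((EX_GRID - 320) / 20.0) ** 2)
    scores = rng.random(8) + 0.5
    x = np.einsum("i,j,k->ijk", scores, em, ex)
    cube = EEMCube([f"s{i}" for i in range(8)], EX_GRID, EM_GRID, x, corrected=True)
    model = fit_parafac(cube, n_components=1, n_starts=2, seed=0)
    assert model.explained_variance > 0.999999
    ratio = model.scores[:, 0] / scores
    assert np.ptp(ratio) < 1e-6 * ratio.mean()


def test_fit_requires_corrected_input(eem_data):
    cube, _, _ = eem_data
    with pytest.raises(ValueError, match="corrected"):
        fit_parafac(cube, n_components=3)


def test_fit_requires_more_samples_than_components(noiseless_setup):
    c = noiseless_setup["corrected"]
    small = EEMCube(c.sample_ids[:2], c.ex_grid, c.em_grid,
                    c.intensities[:2], corrected=True)
    with pytest.raises(ValueError, match="samples"):
        fit_parafac(small, n_components=3)


def test_als_loss_stays_monotone_on_random_data(rng):
    """The monotone-loss invariant (asserted inside ALS) must hold on
    unstructured data with missing cells, not only on trilinear cubes."""
    x = np.abs(rng.normal(size=(8, 40, 20)))
    x[rng.random(x.shape) < 0.1] = np.nan
    cube = EEMCube(
        [f"s{i}" for i in range(8)],
        np.arange(20.0), np.arange(100.0, 140.0), x, corrected=True,
    )
    model = fit_parafac(cube, n_components=2, n_starts=3, seed=4, max_iter=80)
    assert 0.0 <= model.explained_variance <= 1.0


def test_model_serializes_to_csv_directory(tmp_path, fitted_model):
    fitted_model.to_dir(tmp_path / "model")
    assert (tmp_path / "model" / "ex_loadings.csv").exists()
    assert (tmp_path / "model" / "scores.csv").exists()
    assert (tmp_path / "model" / "model.json").exists()


# -------------------------------------------------------------- split-half


def test_refits_of_identical_data_match_with_unit_congruence(noiseless_setup):
    c = noiseless_setup["corrected"]
    a = fit_parafac(c, n_components=3, n_starts=2, seed=1)
    b = fit_parafac(c, n_components=3, n_starts=2, seed=2)
    for _, _, te, tm in _match_loadings(a, b):
        assert te > 0.9999
        assert tm > 0.9999


def test_split_half_passes_on_structured_data(corrected_cube):
    res = split_half_validate(
        corrected_cube, n_components=3, n_splits=1, seed=0, n_starts=2
    )
    assert res.passed
    for split in res.splits:
        for _, _, te, tm in split["pairs"]:
            assert te > 0.95 and tm > 0.95


def test_split_half_rejects_too_few_samples(noiseless_setup):
    c = noiseless_setup["corrected"]
    small = EEMCube(c.sample_ids[:6], c.ex_grid, c.em_grid,
                    c.intensities[:6], corrected=True)
    with pytest.raises(ValueError, match="too few samples"):
        split_half_validate(small, n_components=3)


# ------------------------------------------------------------------- Fmax


def _toy_model() -> PARAFACModel:
    ex = np.array([[0.3, 0.1], [0.1, 0.2]])
    em = np.array([[0.2, 0.4], [0.1, 0.1], [0.05, 0.2]])
    scores = np.array([[10.0, 0.0], [2.0, 5.0]])
    return PARAFACModel(
        n_components=2,
        ex_grid=np.array([300.0, 305.0]),
        em_grid=np.array([400.0, 401.0, 402.0]),
        ex_loadings=ex, em_loadings=em, scores=scores,
        sample_ids=["a", "b"], explained_variance=1.0,
    )


def test_fmax_is_score_times_loading_maxima():
    fmax = compute_fmax(_toy_model())
    assert fmax.loc["a", "C1"] == pytest.approx(10.0 * 0.3 * 0.2, abs=1e-12)
    assert fmax.loc["a", "C2"] == pytest.approx(0.0, abs=1e-12)
    assert fmax.loc["b", "C2"] == pytest.approx(5.0 * 0.2 * 0.4, abs=1e-12)


def test_relative_fmax_sums_to_one():
    rel = fmax_relative(compute_fmax(_toy_model()))
    np.testing.assert_allclose(rel.sum(axis=1), 1.0, rtol=1e-12)


def test_noiseless_fmax_matches_truth_proportions(noiseless_setup):
    """On exact trilinear data, relative Fmax must equal the truth-derived
    proportions (Fmax is scale-covariant; relative Fmax removes the overall
    Raman-unit scale)."""
    model, truth = noiseless_setup["model"], noiseless_setup["truth"]
    rel = fmax_relative(compute_fmax(model))
    t_fmax = (
        truth.true_scores
        * truth.true_ex_loadings.max(axis=0)
        * truth.true_em_loadings.max(axis=0)
    )
    t_rel = t_fmax.div(t_fmax.sum(axis=1), axis=0)
    np.testing.assert_allclose(rel.to_numpy(), t_rel.to_numpy(), atol=1e-6)


# ----------------------------------------------------------------- library


def test_components_match_their_generating_library_entries(fitted_model):
    matches = match_components(fitted_model, default_library())
    assert [m.component for m in matches] == ["C1", "C2", "C3"]
    for m in matches:
        assert m.matched
        assert min(m.tcc_ex, m.tcc_em) > 0.99
    assert "microbial" in matches[0].label.lower()
    assert "terrestrial" in matches[2].label.lower()


def test_dissimilar_library_entries_do_not_match(fitted_model):
    """Narrow spectra peaked far from every fitted component stay below the
    0.95 congruence threshold on at least one mode."""
    entries = default_library()
    for e in entries:
        e.ex_loading = np.exp(-0.5 * ((e.ex_wavelengths - 205.0) / 3.0) ** 2)
        e.em_loading = np.exp(-0.5 * ((e.em_wavelengths - 595.0) / 3.0) ** 2)
    matches = match_components(fitted_model, entries)
    assert not any(m.matched for m in matches)


def test_library_roundtrips_through_csv(tmp_path):
    lib = default_library()
    library_to_csv(lib, tmp_path / "lib.csv")
    back = library_from_csv(tmp_path / "lib.csv")
    assert [e.entry_id for e in back] == [e.entry_id for e in lib]
    np.testing.assert_allclose(back[0].em_loading, lib[0].em_loading, rtol=1e-12)


def test_empty_library_is_rejected(fitted_model):
    with pytest.raises(ValueError, match="empty"):
        match_components(fitted_model, [])
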