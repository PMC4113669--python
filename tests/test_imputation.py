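"""LD imputer, masking experiment and the accuracy-curve interpolation."""

import numpy as np
import pandas as pd
import pytest

from vigorclass import (
    accuracy_experiment,
    impute_missing,
    interpolate_accuracy,
    mask_genotypes,
    modal_imputer,
)
from vigorclass.genotype_io import MISSING
from vigorclass.imputation import ImputationError, ImputationResult, MaskingExperiment

from conftest import make_panel


# ---------------------------------------------------------------------------
# the imputer
# ---------------------------------------------------------------------------

def test_perfect_ld_neighbor_copies_genotype():
    # markers 0 and 1 duplicated on the same scaffold; one missing cell
    geno = np.array(
        [[0, 0], [1, 1], [2, 2], [0, 0], [1, 1], [2, 2], [0, 0], [2, MISSING]],
        dtype=np.int8,
    )
    panel = make_panel(geno, scaffolds=["sc1", "sc1"])
    result = impute_missing(panel)
    assert result.panel.genotypes[7, 1] == 2
    assert result.imputed_mask[7, 1]
    assert result.n_fallback == 0


def test_no_neighbor_falls_back_to_mode():
    geno = np.array([[0, 1], [0, 0], [0, 1], [2, 2], [MISSING, 1]], dtype=np.int8)
    panel = make_panel(geno, scaffolds=["a", "b"])  # marker 0 alone on scaffold a
    result = impute_missing(panel)
    assert result.panel.genotypes[4, 0] == 0  # modal genotype
    assert result.n_fallback == 1


def test_imputation_never_alters_called_cells(block_ld_dataset):
    from vigorclass import inject_missing

    panel = inject_missing(block_ld_dataset.panel, 0.05, seed=1)
    called = panel.genotypes != MISSING
    result = impute_missing(panel)
    assert result.panel.is_complete
    np.testing.assert_array_equal(
        result.panel.genotypes[called], panel.genotypes[called]
    )
    np.testing.assert_array_equal(result.imputed_mask, ~called)


def test_entirely_missing_marker_is_error():
    geno = np.array([[MISSING, 1], [MISSING, 0], [MISSING, 2]], dtype=np.int8)
    with pytest.raises(ImputationError, match="M0"):
        impute_missing(make_panel(geno))


def test_beats_modal_baseline_on_block_ld(block_ld_dataset):
    panel = block_ld_dataset.panel
    masked, mask = mask_genotypes(panel, 0.03, rng_seed=0)
    truth = panel.genotypes[mask[:, 0], mask[:, 1]]
    ld_acc = np.mean(impute_missing(masked).panel.genotypes[mask[:, 0], mask[:, 1]] == truth)
    mo_acc = np.mean(modal_imputer(masked).panel.genotypes[mask[:, 0], mask[:, 1]] == truth)
    assert ld_acc > mo_acc


def test_independent_markers_reduce_to_modal_baseline():
    """With no LD to exploit, the LD imputer defaults to the mode."""
    rng = np.random.default_rng(8)
    geno = rng.integers(0, 3, size=(60, 10)).astype(np.int8)
    panel = make_panel(geno, scaffolds=[f"s{j}" for j in range(10)])
    masked, mask = mask_genotypes(panel, 0.05, rng_seed=1)
    a = impute_missing(masked).panel.genotypes
    b = modal_imputer(masked).panel.genotypes
    np.testing.assert_array_equal(a, b)


# ---------------------------------------------------------------------------
# masking
# ---------------------------------------------------------------------------

def test_mask_exact_counts():
    rng = np.random.default_rng(0)
    panel = make_panel(rng.integers(0, 3, size=(10, 10)).astype(np.int8))
    masked, mask = mask_genotypes(panel, 0.2, rng_seed=5)
    assert len(mask) == 20
    assert (masked.genotypes == MISSING).sum() == 20


def test_mask_determinism():
    rng = np.random.default_rng(0)
    panel = make_panel(rng.integers(0, 3, size=(12, 8)).astype(np.int8))
    _, m1 = mask_genotypes(panel, 0.1, rng_seed=7)
    _, m2 = mask_genotypes(panel, 0.1, rng_seed=7)
    np.testing.assert_array_equal(m1, m2)


def test_mask_requires_complete_panel():
    panel = make_panel([[0, MISSING], [1, 2], [0, 1]])
    with pytest.raises(ImputationError):
        mask_genotypes(panel, 0.1, rng_seed=0)


def test_mask_single_cell():
    rng = np.random.default_rng(0)
    panel = make_panel(rng.integers(0, 3, size=(5, 4)).astype(np.int8))
    _, mask = mask_genotypes(panel, 0.05, rng_seed=0)  # round(0.05*20) = 1
    assert len(mask) == 1


# ---------------------------------------------------------------------------
# accuracy experiment
# ---------------------------------------------------------------------------

def test_oracle_imputer_scores_one(block_ld_dataset):
    panel = block_ld_dataset.panel

    def oracle(masked, **_):
        return ImputationResult(panel, masked.genotypes == MISSING, 0)

    exp = accuracy_experiment(panel, fractions=(0.02, 0.05), replicates=2,
                              rng_seed=0, imputer=oracle)
    assert exp.accuracies == [1.0, 1.0]


def test_frequency_imputer_matches_expected_accuracy(block_ld_dataset):
    """Random draws from genotype frequencies hit with prob sum_g f_g^2."""
    panel = block_ld_dataset.panel
    rng = np.random.default_rng(12)

    def freq_imputer(masked, **_):
        geno = masked.genotypes.copy()
        for j in range(masked.n_markers):
            obs = geno[:, j][geno[:, j] != MISSING]
            freqs = np.bincount(obs, minlength=3) / len(obs)
            rows = np.flatnonzero(geno[:, j] == MISSING)
            geno[rows, j] = rng.choice(3, size=len(rows), p=freqs)
        return ImputationResult(make_panel(geno), masked.genotypes == MISSING, 0)

    exp = accuracy_experiment(panel, fractions=(0.10,), replicates=5,
                              rng_seed=1, imputer=freq_imputer)
    freqs = np.stack(
        [np.bincount(panel.genotypes[:, j], minlength=3) / panel.n_samples
         for j in range(panel.n_markers)]
    )
    expected = float(np.mean((freqs**2).sum(axis=1)))
    assert exp.accuracies[0] == pytest.approx(expected, abs=0.04)


def test_accuracy_flat_then_drop(block_ld_dataset):
    exp = accuracy_experiment(block_ld_dataset.panel, replicates=3, rng_seed=2)
    acc = exp.accuracies
    assert acc[0] >= acc[-1]
    assert all(acc[i + 1] <= acc[i] + 0.02 for i in range(len(acc) - 1))


# ---------------------------------------------------------------------------
# interpolation
# ---------------------------------------------------------------------------

def _experiment(fractions, accuracies):
    return MaskingExperiment(
        missing_fractions=list(fractions), replicates_per_fraction=5,
        accuracies=list(accuracies), per_replicate=pd.DataFrame(), seed=0,
    )


def test_interpolation_at_measured_fraction_is_exact():
    exp = _experiment([0.01, 0.02], [1.0, 0.9])
    assert interpolate_accuracy(exp, 0.02) == 0.9


def test_interpolation_midpoint():
    exp = _experiment([0.01, 0.02], [1.0, 0.9])
    assert interpolate_accuracy(exp, 0.015) == pytest.approx(0.95)


def test_interpolation_of_reported_accuracy_curve():
    # querying a 0.8402 -> 0.8396 segment at 3.14% missing
    exp = _experiment(
        [0.01, 0.02, 0.03, 0.05, 0.10, 0.20],
        [0.8405, 0.8402, 0.8402, 0.8396, 0.8301, 0.8089],
    )
    assert round(interpolate_accuracy(exp, 0.0314), 5) == 0.84016
    assert round(interpolate_accuracy(exp, 0.0314), 3) == 0.840


def test_interpolation_refuses_extrapolation():
    exp = _experiment([0.01, 0.02], [1.0, 0.9])
    with pytest.raises(ValueError, match="extrapolate"):
        interpolate_accuracy(exp, 0.5)
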