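"""Repeated k-fold cross-validation of the liability-threshold classifier.

Per replicate (one test fold), the test error rate is

    ER = (1/n) * sum_i I(y_i != yhat_i)

and the cross-validation error is the plain average of ER over all
k x repeats replicates. Because folds can differ in size by one, this is not
identical to the pooled error (misclassified / total test observations);
both are reported.

The GRM is computed once on all samples and reused across folds: genomic
relationships are phenotype-free, so masking test phenotypes cannot leak
label information through G.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from .genotype_io import GenotypePanel, phenotype_vector
from .grm import GRM
from .threshold_model import classify, fit_threshold_model


def make_folds(n: int, k: int, rng_seed: int) -> list:
    """Random partition of range(n) into k folds with sizes differing <= 1."""
    if not 2 <= k <= n:
        raise ValueError(f"need 2 <= k <= n, got k={k}, n={n}")
    rng = np.random.default_rng(rng_seed)
    perm = rng.permutation(n)
    return [np.sort(part) for part in np.array_split(perm, k)]


def _stratified_folds(y: np.ndarray, k: int, rng_seed: int) -> list:
    rng = np.random.default_rng(rng_seed)
    folds = [[] for _ in range(k)]
    offset = 0
    for cls in np.unique(y):
        idx = rng.permutation(np.flatnonzero(y == cls))
        for pos, i in enumerate(idx):
            folds[(pos + offset) % k].append(i)
        offset += len(idx) % k
    return [np.sort(np.array(f, dtype=int)) for f in folds]


def test_error_rate(true, predicted) -> float:
    """Fraction of misclassified observations."""
    true = np.asarray(true)
    predicted = np.asarray(predicted)
    if true.shape != predicted.shape:
        raise ValueError("true and predicted must have equal length")
    if true.size == 0:
        raise ValueError("empty test set")
    return float(np.mean(true != predicted))


test_error_rate.__test__ = False  # name matches pytest's pattern; not a test


@dataclasses.dataclass
class CVResult:
    replicate_errors: list  # one ER per test fold, k x repeats total
    cv_error: float  # mean of replicate_errors
    n_test_total: int
    n_misclassified: int
    misclassified_ledger: list  # (replicate, sample_id, line_id, true, predicted)
    line_test_counts: dict  # line_id -> test appearances
    n_skipped: int  # folds skipped for single-class training sets
    seed: int
    k: int
    repeats: int

    @property
    def pooled_error(self) -> float:
        if self.n_test_total == 0:
            return float("nan")
        return self.n_misclassified / self.n_test_total

    def ledger_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.misclassified_ledger,
            columns=["replicate", "sample_id", "line_id", "true", "predicted"],
        )


def format_error_percent(n_misclassified: int, n_test_total: int, digits: int = 3) -> float:
    """Pooled error rate expressed as a percentage (e.g. 9/12326 -> 0.073)."""
    if n_test_total <= 0:
        raise ValueError("n_test_total must be positive")
    return round(100.0 * n_misclassified / n_test_total, digits)


def run_repeated_cv(
    panel: GenotypePanel,
    grm: GRM,
    k: int = 5,
    repeats: int = 100,
    mode: str = "estimate",
    h2_fixed: float | None = None,
    rng_seed: int = 0,
    reestimate_each_fold: bool = True,
    stratify: bool = False,
) -> CVResult:
    """Repeated k-fold cross-validation of the threshold-model classifier.

    Per repeat the samples are randomly partitioned into k folds; per fold,
    the test phenotypes are set to missing, the model refitted on the
    remainder (sigma_a^2 re-estimated unless ``mode='fixed_h2'`` or
    ``reestimate_each_fold=False``), and the held-out samples classified.
    Folds whose training portion contains a single class are skipped with a
    warning and counted in ``n_skipped``.
    """
    y = phenotype_vector(panel)
    if np.isnan(y).any():
        raise ValueError("repeated CV requires every sample to be phenotyped")
    n = panel.n_samples
    ids = panel.samples["sample_id"].tolist()
    lines = panel.samples["line_id"].tolist()

    eff_mode, eff_h2 = mode, h2_fixed
    if mode == "estimate" and not reestimate_each_fold:
        full = fit_threshold_model(y, grm, mode="estimate")
        eff_mode, eff_h2 = "fixed_h2", full.h2

    fold_seeds = np.random.SeedSequence(rng_seed).generate_state(repeats)
    replicate_errors = []
    ledger = []
    line_counts: dict = {}
    n_test_total = 0
    n_mis = 0
    n_skipped = 0
    replicate = 0
    for r in range(repeats):
        seed_r = int(fold_seeds[r])
        folds = (
            _stratified_folds(y, k, seed_r) if stratify else make_folds(n, k, seed_r)
        )
        for fold in folds:
            replicate += 1
            y_train = y.copy()
            y_train[fold] = np.nan
            train_classes = np.unique(y_train[~np.isnan(y_train)])
            if len(train_classes) < 2:
                warnings.warn(
                    f"replicate {replicate}: single-class training fold skipped",
                    RuntimeWarning,
                )
                n_skipped += 1
                continue
            fit = fit_threshold_model(y_train, grm, mode=eff_mode, h2_fixed=eff_h2)
            test_ids = [ids[i] for i in fold]
            probs = classify(fit, test_ids)
            pred = np.array([c.predicted_class for c in probs])
            truth = y[fold].astype(int)
            replicate_errors.append(test_error_rate(truth, pred))
            n_test_total += len(fold)
            for i, c, t in zip(fold, pred, truth):
                line_counts[lines[i]] = line_counts.get(lines[i], 0) + 1
                if c != t:
                    n_mis += 1
                    ledger.append((replicate, ids[i], lines[i], int(t), int(c)))

    cv_error = float(np.mean(replicate_errors)) if replicate_errors else float("nan")
    return CVResult(
        replicate_errors=replicate_errors,
        cv_error=cv_error,
        n_test_total=n_test_total,
        n_misclassified=n_mis,
        misclassified_ledger=ledger,
        line_test_counts=line_counts,
        n_skipped=n_skipped,
        seed=rng_seed,
        k=k,
        repeats=repeats,
    )


def per_line_error_summary(result: CVResult) -> pd.DataFrame:
    """Per-line test appearances, misclassification counts and rates."""
    rows = []
    errors_by_line: dict = {}
    for _, _, line_id, _, _ in result.misclassified_ledger:
        errors_by_line[line_id] = errors_by_line.get(line_id, 0) + 1
    for line_id, n_test in sorted(result.line_test_counts.items()):
        n_err = errors_by_line.get(line_id, 0)
        rows.append(
            {
                "line_id": line_id,
                "n_test": n_test,
                "n_misclassified": n_err,
                "error_rate": n_err / n_test if n_test else 0.0,
            }
        )
    return pd.DataFrame(rows, columns=["line_id", "n_test", "n_misclassified", "error_rate"])
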