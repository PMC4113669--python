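"""LD-based genotype imputation and the masking accuracy experiment.

Missing calls at a marker are predicted from the k most LD-correlated
markers on the same scaffold via local linear regression of dosage, with the
prediction rounded to the nearest valid genotype (ties toward the
heterozygote). Markers with no informative neighbor (r^2 below a floor, or
too little overlap) fall back to their modal genotype. Between-scaffold LD
is ignored by design: scaffold order along chromosomes is unknown, so only
within-scaffold structure is trusted.

The masking experiment injects known missingness into a complete panel at a
grid of fractions, imputes, and scores the exact-genotype accuracy over the
masked cells; the empirical accuracy curve can then be linearly interpolated
at an observed missing rate.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypePanel

DEFAULT_FRACTIONS = (0.01, 0.02, 0.03, 0.05, 0.10, 0.20)


class ImputationError(ValueError):
    pass


@dataclasses.dataclass
class ImputationResult:
    panel: GenotypePanel  # complete panel
    imputed_mask: np.ndarray  # True where a cell was filled in
    n_fallback: int  # cells imputed by the modal-genotype fallback


@dataclasses.dataclass
class MaskingExperiment:
    missing_fractions: list
    replicates_per_fraction: int
    accuracies: list  # per-fraction mean over replicates
    per_replicate: pd.DataFrame  # fraction, replicate, n_masked, accuracy
    seed: int


def _round_genotype(v: float) -> int:
    """Nearest genotype in {0,1,2}; ties (0.5, 1.5) toward the heterozygote."""
    if abs(v - 1.0) <= 0.5:
        return 1
    return 0 if v < 0.5 else 2


def _modal_genotype(col: np.ndarray) -> int:
    obs = col[col != MISSING]
    counts = np.bincount(obs, minlength=3)
    return int(np.argmax(counts))  # ties -> lowest dosage


def impute_missing(
    panel: GenotypePanel,
    k: int = 5,
    min_r2: float = 0.1,
    min_overlap: int = 5,
) -> ImputationResult:
    """Fill every missing cell using within-scaffold LD regression.

    Raises if any marker is entirely missing (no information at all).
    """
    if panel.n_samples < 2:
        raise ImputationError("need at least 2 samples")
    geno = panel.genotypes.copy()
    X = geno.astype(float)
    X[geno == MISSING] = np.nan
    n, m = geno.shape
    scaffolds = panel.markers["scaffold_id"].to_numpy()
    marker_ids = panel.markers["marker_id"].to_numpy()
    imputed = np.zeros((n, m), dtype=bool)
    n_fallback = 0

    by_scaffold: dict = {}
    for j, s in enumerate(scaffolds):
        by_scaffold.setdefault(s, []).append(j)

    for j in range(m):
        missing_rows = np.flatnonzero(geno[:, j] == MISSING)
        if missing_rows.size == 0:
            continue
        col = X[:, j]
        if np.isnan(col).all():
            raise ImputationError(f"marker {marker_ids[j]!r} is entirely missing")
        mode_j = _modal_genotype(geno[:, j])

        # rank same-scaffold neighbors by r^2 on jointly observed samples
        neighbors = []
        for c in by_scaffold[scaffolds[j]]:
            if c == j:
                continue
            both = ~np.isnan(col) & ~np.isnan(X[:, c])
            if both.sum() < min_overlap:
                continue
            a, b = col[both], X[both, c]
            if a.std() == 0 or b.std() == 0:
                continue
            r = np.corrcoef(a, b)[0, 1]
            if r * r >= min_r2:
                neighbors.append((r * r, c))
        neighbors.sort(reverse=True)
        ranked = [c for _, c in neighbors]

        for i in missing_rows:
            preds = [c for c in ranked if not np.isnan(X[i, c])][:k]
            value = None
            while preds:
                rows = ~np.isnan(col)
                for c in preds:
                    rows &= ~np.isnan(X[:, c])
                if rows.sum() >= min_overlap:
                    A = np.column_stack(
                        [np.ones(rows.sum()), X[np.ix_(np.flatnonzero(rows), preds)]]
                    )
                    coef, *_ = np.linalg.lstsq(A, col[rows], rcond=None)
                    value = float(coef[0] + X[i, preds] @ coef[1:])
                    break
                preds = preds[:-1]
            if value is None:
                value = float(mode_j)
                n_fallback += 1
            geno[i, j] = _round_genotype(value)
            imputed[i, j] = True

    out = GenotypePanel(geno, panel.markers.copy(), panel.samples.copy())
    return ImputationResult(panel=out, imputed_mask=imputed, n_fallback=n_fallback)


def mask_genotypes(panel: GenotypePanel, fraction: float, rng_seed: int):
    """Set round(fraction * n_cells) uniformly chosen cells to missing.

    The panel must be complete. Draws are rejected (up to 100 times) if they
    would blank an entire marker or sample. Returns
    ``(masked_panel, mask)`` with mask an array of (row, col) cell indices.
    """
    if not panel.is_complete:
        raise ImputationError("masking requires a complete panel")
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    n, m = panel.genotypes.shape
    n_cells = n * m
    n_mask = int(round(fraction * n_cells))
    if n_mask == 0:
        raise ValueError("fraction too small: no cell would be masked")
    rng = np.random.default_rng(rng_seed)
    for _ in range(100):
        flat = rng.choice(n_cells, size=n_mask, replace=False)
        rows, cols = np.unravel_index(flat, (n, m))
        row_counts = np.bincount(rows, minlength=n)
        col_counts = np.bincount(cols, minlength=m)
        if row_counts.max() < m and col_counts.max() < n:
            break
    else:
        raise ImputationError(
            "could not draw a mask leaving every marker and sample partially called"
        )
    geno = panel.genotypes.copy()
    geno[rows, cols] = MISSING
    masked = GenotypePanel(geno, panel.markers.copy(), panel.samples.copy())
    return masked, np.column_stack([rows, cols])


def accuracy_experiment(
    panel: GenotypePanel,
    fractions=DEFAULT_FRACTIONS,
    replicates: int = 5,
    rng_seed: int = 0,
    imputer=None,
    **imputer_kwargs,
) -> MaskingExperiment:
    """Mask / impute / score at each missing fraction.

    Accuracy is the proportion of masked cells imputed to the exact
    genotype (0/1/2). ``imputer`` defaults to :func:`impute_missing`; any
    callable with the same signature can be substituted (e.g. a baseline).
    """
    if not panel.is_complete:
        raise ImputationError("accuracy experiment requires a complete panel")
    if imputer is None:
        imputer = impute_missing
    fractions = sorted(fractions)
    seeds = np.random.SeedSequence(rng_seed).generate_state(len(fractions) * replicates)
    rows = []
    means = []
    s = 0
    for frac in fractions:
        accs = []
        for rep in range(replicates):
            try:
                masked, mask = mask_genotypes(panel, frac, int(seeds[s]))
                result = imputer(masked, **imputer_kwargs)
            except (ImputationError, ValueError) as e:
                raise ImputationError(f"at fraction {frac}: {e}") from e
            s += 1
            truth = panel.genotypes[mask[:, 0], mask[:, 1]]
            imput = result.panel.genotypes[mask[:, 0], mask[:, 1]]
            acc = float(np.mean(truth == imput))
            accs.append(acc)
            rows.append(
                {"fraction": frac, "replicate": rep, "n_masked": len(mask), "accuracy": acc}
            )
        means.append(float(np.mean(accs)))
    return MaskingExperiment(
        missing_fractions=list(fractions),
        replicates_per_fraction=replicates,
        accuracies=means,
        per_replicate=pd.DataFrame(rows),
        seed=rng_seed,
    )


def modal_imputer(panel: GenotypePanel, **_) -> ImputationResult:
    """Baseline: fill every missing cell with the marker's modal genotype."""
    geno = panel.genotypes.copy()
    imputed = np.zeros_like(geno, dtype=bool)
    for j in range(panel.n_markers):
        rows = np.flatnonzero(geno[:, j] == MISSING)
        if rows.size == 0:
            continue
        if (geno[:, j] == MISSING).all():
            raise ImputationError(
                f"marker {panel.markers['marker_id'].iloc[j]!r} is entirely missing"
            )
        geno[rows, j] = _modal_genotype(geno[:, j])
        imputed[rows, j] = True
    return ImputationResult(
        GenotypePanel(geno, panel.markers.copy(), panel.samples.copy()),
        imputed,
        int(imputed.sum()),
    )


def interpolate_accuracy(experiment: MaskingExperiment, at_fraction: float) -> float:
    """Linear interpolation of the empirical accuracy curve.

    Querying exactly at a measured fraction returns that fraction's mean;
    extrapolation outside the measured range is refused.
    """
    fr = np.asarray(experiment.missing_fractions, dtype=float)
    acc = np.asarray(experiment.accuracies, dtype=float)
    if not fr[0] <= at_fraction <= fr[-1]:
        raise ValueError(
            f"requested fraction {at_fraction} outside measured range "
            f"[{fr[0]}, {fr[-1]}]: refusing to extrapolate"
        )
    return float(np.interp(at_fraction, fr, acc))
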