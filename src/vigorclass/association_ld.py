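"""Single-SNP logistic association scan and pairwise LD (r^2) summaries.

The scan fits, per marker, logit(p_i) = mu + beta * dosage by Newton
maximum likelihood. LD is the squared Pearson correlation of dosage vectors
(composite genotypic r^2, the standard unphased estimator); it is invariant
to which allele is counted at either marker. Summaries average r^2 over all
distinct pairs, over pairs sharing a scaffold, and over a designated set of
large-effect markers. No multiple-testing correction is applied: the scan is
descriptive (effect magnitudes), not an inference procedure.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import linalg, special

from .genotype_io import MISSING, GenotypePanel

BETA_CAP = 10.0  # |beta| beyond this flags quasi-separation


@dataclasses.dataclass
class SnpEffect:
    marker_id: str
    beta: float  # log-odds per dosage unit
    se: float
    converged: bool
    separation_flag: bool
    monomorphic: bool = False


@dataclasses.dataclass
class LDMatrix:
    values: np.ndarray  # m x m r^2, NaN for monomorphic markers
    marker_ids: list
    scaffold_ids: list


@dataclasses.dataclass
class LDSummary:
    mean_total: float
    n_pairs_total: int
    mean_within_scaffold: float | None  # None when no scaffold has >= 2 markers
    n_pairs_within_scaffold: int
    mean_large_effect: float | None
    n_pairs_large_effect: int


def _logistic_fit_1d(x: np.ndarray, y: np.ndarray, max_iter: int = 50):
    """Newton ML fit of logit(p) = b0 + b1 x; returns (beta, se, converged, sep)."""
    X = np.column_stack([np.ones_like(x, dtype=float), x.astype(float)])
    beta = np.zeros(2)
    converged = False
    separated = False
    for _ in range(max_iter):
        eta = X @ beta
        p = special.expit(eta)
        w = np.clip(p * (1.0 - p), 1e-12, None)
        grad = X.T @ (y - p)
        if np.abs(grad).max() < 1e-10:
            converged = True
            break
        H = (X * w[:, None]).T @ X
        try:
            step = linalg.solve(H, grad, assume_a="pos")
        except linalg.LinAlgError:
            break
        # damped update for stability near separation
        if np.abs(step).max() > 5.0:
            step = step * (5.0 / np.abs(step).max())
        beta = beta + step
        if abs(beta[1]) > BETA_CAP:
            separated = True
            beta[1] = np.sign(beta[1]) * BETA_CAP
            break
    eta = X @ beta
    p = special.expit(eta)
    w = np.clip(p * (1.0 - p), 1e-12, None)
    H = (X * w[:, None]).T @ X
    try:
        cov = linalg.inv(H)
        se = float(np.sqrt(max(cov[1, 1], 0.0)))
    except linalg.LinAlgError:
        se = float("nan")
    return float(beta[1]), se, converged, separated


def single_snp_scan(panel: GenotypePanel, y: np.ndarray | None = None) -> list:
    """Per-marker logistic regression of the binary phenotype on dosage.

    Requires complete (imputed) genotypes and both classes present.
    Monomorphic markers are flagged and carry NaN effects.
    """
    if not panel.is_complete:
        raise ValueError("scan requires complete genotypes; impute first")
    if y is None:
        from .genotype_io import phenotype_vector

        y = phenotype_vector(panel)
    y = np.asarray(y, dtype=float)
    if np.isnan(y).any():
        raise ValueError("scan requires phenotypes for all samples")
    if len(np.unique(y)) < 2:
        raise ValueError("both phenotype classes must be present")
    effects = []
    for j in range(panel.n_markers):
        mid = str(panel.markers["marker_id"].iloc[j])
        x = panel.genotypes[:, j].astype(float)
        if np.all(x == x[0]):
            effects.append(
                SnpEffect(mid, float("nan"), float("nan"), False, False, True)
            )
            continue
        beta, se, conv, sep = _logistic_fit_1d(x, y)
        effects.append(SnpEffect(mid, beta, se, conv, sep))
    return effects


def effects_frame(effects: list) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(e) for e in effects])


def large_effect_markers(effects: list, top_q: float = 0.10) -> list:
    """Marker ids in the top-q quantile of |beta| (monomorphic excluded)."""
    usable = [e for e in effects if not e.monomorphic and np.isfinite(e.beta)]
    if not usable:
        return []
    mags = np.array([abs(e.beta) for e in usable])
    cut = np.quantile(mags, 1.0 - top_q)
    return [e.marker_id for e in usable if abs(e.beta) >= cut]


def ld_r2(panel: GenotypePanel, i: int, j: int) -> float:
    """Squared dosage correlation between markers i and j."""
    xi = panel.genotypes[:, i].astype(float)
    xj = panel.genotypes[:, j].astype(float)
    if (xi == MISSING).any() or (xj == MISSING).any():
        raise ValueError("ld_r2 requires complete genotypes")
    if np.std(xi) == 0 or np.std(xj) == 0:
        raise ValueError("zero-variance (monomorphic) marker")
    r = np.corrcoef(xi, xj)[0, 1]
    return float(r * r)


def ld_matrix(panel: GenotypePanel) -> LDMatrix:
    """All-pairs r^2; rows/columns of monomorphic markers are NaN."""
    if not panel.is_complete:
        raise ValueError("LD matrix requires complete genotypes")
    X = panel.genotypes.astype(float)
    sd = X.std(axis=0)
    poly = sd > 0
    m = panel.n_markers
    vals = np.full((m, m), np.nan)
    if poly.sum() >= 2:
        C = np.corrcoef(X[:, poly], rowvar=False)
        vals[np.ix_(poly, poly)] = C * C
    elif poly.sum() == 1:
        j = int(np.flatnonzero(poly)[0])
        vals[j, j] = 1.0
    np.fill_diagonal(vals, np.where(poly, 1.0, np.nan))
    return LDMatrix(
        values=vals,
        marker_ids=[str(s) for s in panel.markers["marker_id"]],
        scaffold_ids=[str(s) for s in panel.markers["scaffold_id"]],
    )


def ld_summaries(
    ld: LDMatrix, markers: pd.DataFrame | None = None, large_effect_ids=None
) -> LDSummary:
    """Mean r^2 over all pairs, within-scaffold pairs, and large-effect pairs."""
    m = ld.values.shape[0]
    scaffolds = np.asarray(ld.scaffold_ids)
    iu = np.triu_indices(m, k=1)
    vals = ld.values[iu]
    ok = np.isfinite(vals)
    mean_total = float(np.mean(vals[ok])) if ok.any() else float("nan")

    same = scaffolds[iu[0]] == scaffolds[iu[1]]
    within = vals[same & ok]
    mean_within = float(np.mean(within)) if within.size else None

    mean_large = None
    n_large = 0
    if large_effect_ids:
        idx = [ld.marker_ids.index(mid) for mid in large_effect_ids]
        if len(idx) >= 2:
            sub = ld.values[np.ix_(idx, idx)]
            iu2 = np.triu_indices(len(idx), k=1)
            lv = sub[iu2]
            lv = lv[np.isfinite(lv)]
            n_large = lv.size
            if lv.size:
                mean_large = float(np.mean(lv))
    return LDSummary(
        mean_total=mean_total,
        n_pairs_total=int(ok.sum()),
        mean_within_scaffold=mean_within,
        n_pairs_within_scaffold=int(within.size),
        mean_large_effect=mean_large,
        n_pairs_large_effect=n_large,
    )
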