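"""VanRaden genomic relationship matrix (GRM) and descriptive summaries.

The realized relationship between individuals a and b is

    G = Z Z' / (2 * sum_i p_i (1 - p_i))

where Z holds genotype dosages column-centered by twice the allele frequency
(z_ij = x_ij - 2 p_j). Monomorphic markers carry no information and are
excluded from both the numerator and the denominator sum.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypePanel


class GRMError(ValueError):
    pass


@dataclasses.dataclass
class GRM:
    """Symmetric realized-relationship matrix with its centering provenance."""

    values: np.ndarray
    sample_ids: list
    allele_freqs: np.ndarray  # p_i actually used (polymorphic markers)
    denom: float  # 2 * sum p_i (1 - p_i)
    n_markers_used: int

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def ridged(self, eps: float | None = None) -> np.ndarray:
        """G + eps*I for inversion; the stored G is never modified."""
        if eps is None:
            eps = 1e-6 * float(np.mean(np.diag(self.values)))
            eps = max(eps, 1e-12)
        return self.values + eps * np.eye(self.n)


def compute_grm(panel: GenotypePanel, missing_policy: str = "mean_impute") -> GRM:
    """Compute the VanRaden GRM from a genotype panel.

    missing_policy:
        ``"mean_impute"`` — a missing dosage contributes 0 after centering
        (equivalent to replacing it with 2 p_i);
        ``"require_complete"`` — raise if any cell is missing.
    """
    if panel.n_samples < 2:
        raise GRMError("need at least 2 samples")
    if missing_policy not in ("mean_impute", "require_complete"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    if missing_policy == "require_complete" and not panel.is_complete:
        raise GRMError(
            "panel has missing genotypes; impute first (see vigorclass.imputation)"
            " or use missing_policy='mean_impute'"
        )
    p = panel.allele_freqs()
    poly = (p > 0.0) & (p < 1.0) & np.isfinite(p)
    if not poly.any():
        raise GRMError("all markers monomorphic: GRM denominator is zero")
    dosage = panel.genotypes[:, poly].astype(float)
    pp = p[poly]
    Z = dosage - 2.0 * pp[None, :]
    Z[panel.genotypes[:, poly] == MISSING] = 0.0  # mean imputation after centering
    denom = float(2.0 * np.sum(pp * (1.0 - pp)))
    G = (Z @ Z.T) / denom
    G = 0.5 * (G + G.T)  # enforce exact symmetry
    return GRM(
        values=G,
        sample_ids=list(panel.samples["sample_id"]),
        allele_freqs=pp.copy(),
        denom=denom,
        n_markers_used=int(poly.sum()),
    )


@dataclasses.dataclass
class GRMSummary:
    mean_offdiag: float
    sd_offdiag: float
    cv_offdiag: float  # coefficient of variation, %; NaN if mean is 0
    mean_all: float
    mean_diag: float
    line_block_means: pd.DataFrame  # line x line mean relationship
    closest_pair: tuple  # (line_a, line_b, mean)
    farthest_pair: tuple

    def __str__(self) -> str:
        return (
            f"off-diagonal mean {self.mean_offdiag:.3f} "
            f"(SD {self.sd_offdiag:.3f}, CV {self.cv_offdiag:.1f}%); "
            f"closest lines {self.closest_pair[0]}/{self.closest_pair[1]} "
            f"({self.closest_pair[2]:.3f}); "
            f"farthest {self.farthest_pair[0]}/{self.farthest_pair[1]} "
            f"({self.farthest_pair[2]:.3f})"
        )


def grm_summary(grm: GRM, samples: pd.DataFrame) -> GRMSummary:
    """Overall and line-block means of the relationship matrix.

    ``samples`` must be aligned with ``grm.sample_ids`` and carry a
    ``line_id`` column. Both the off-diagonal-only and the all-entries mean
    are reported, since "average relationship" is ambiguous between the two.
    """
    if grm.n < 2:
        raise GRMError("no off-diagonal entries for a single sample")
    if list(samples["sample_id"]) != list(grm.sample_ids):
        raise GRMError("sample metadata not aligned with GRM ordering")
    G = grm.values
    off = G[~np.eye(grm.n, dtype=bool)]
    mean_off = float(off.mean())
    sd_off = float(off.std(ddof=0))
    if mean_off == 0.0:
        warnings.warn("off-diagonal mean is 0; CV undefined", RuntimeWarning)
        cv = float("nan")
    else:
        cv = 100.0 * sd_off / abs(mean_off)

    lines = samples["line_id"].to_numpy()
    line_levels = list(pd.unique(lines))
    block = pd.DataFrame(index=line_levels, columns=line_levels, dtype=float)
    for a in line_levels:
        ia = np.flatnonzero(lines == a)
        for b in line_levels:
            ib = np.flatnonzero(lines == b)
            sub = G[np.ix_(ia, ib)]
            if a == b:
                if len(ia) < 2:
                    block.loc[a, b] = float("nan")
                    continue
                mask = ~np.eye(len(ia), dtype=bool)
                block.loc[a, b] = float(sub[mask].mean())
            else:
                block.loc[a, b] = float(sub.mean())

    closest = farthest = None
    for i, a in enumerate(line_levels):
        for b in line_levels[i + 1 :]:
            v = block.loc[a, b]
            if closest is None or v > closest[2]:
                closest = (a, b, float(v))
            if farthest is None or v < farthest[2]:
                farthest = (a, b, float(v))
    if closest is None:  # single line: fall back to its own block
        a = line_levels[0]
        closest = farthest = (a, a, float(block.loc[a, a]))

    return GRMSummary(
        mean_offdiag=mean_off,
        sd_offdiag=sd_off,
        cv_offdiag=cv,
        mean_all=float(G.mean()),
        mean_diag=float(np.diag(G).mean()),
        line_block_means=block,
        closest_pair=closest,
        farthest_pair=farthest,
    )


def write_grm(grm: GRM, matrix_path, meta_path=None) -> None:
    df = pd.DataFrame(grm.values, index=grm.sample_ids, columns=grm.sample_ids)
    df.to_csv(matrix_path, sep="\t")
    if meta_path is not None:
        Path(meta_path).write_text(
            json.dumps(
                {"denom": grm.denom, "n_markers_used": grm.n_markers_used}, indent=1
            )
        )


def read_grm(matrix_path, meta_path=None) -> GRM:
    df = pd.read_csv(matrix_path, sep="\t", index_col=0)
    meta = {"denom": float("nan"), "n_markers_used": -1}
    if meta_path is not None:
        meta.update(json.loads(Path(meta_path).read_text()))
    return GRM(
        values=df.to_numpy(dtype=float),
        sample_ids=[str(s) for s in df.index],
        allele_freqs=np.array([]),
        denom=meta["denom"],
        n_markers_used=meta["n_markers_used"],
    )
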