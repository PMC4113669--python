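"""Genotype panel I/O, validation and quality-control filtering.

A :class:`GenotypePanel` couples an ``n_samples x n_markers`` dosage matrix
(0/1/2 copies of the counted allele, ``-1`` = missing) with a marker map
(chromosome, scaffold, physical position) and per-sample metadata (line
membership and the binary vigor class, 1 = high, 0 = low, -1 = unknown).

The QC pipeline mirrors standard SNP-array editing for small breeding panels:
exact-duplicate sample removal, a per-marker call-rate filter, then a minor
allele frequency (MAF) filter with MAF recomputed on the surviving samples.
All filters use "remove if <= threshold" semantics.

File dialects (all plain TSV):

* genotype table — first column ``sample_id``, header row of marker ids,
  cells in ``{0,1,2,NA}``;
* marker map — columns ``marker_id, chromosome, scaffold_id, position_bp``
  (chromosome 0 = unassigned to any of the 9 chromosomes, position -1 =
  unknown);
* sample table — columns ``sample_id, line_id, vigor_class`` with
  vigor_class in ``{0,1,NA}``;
* VCF v4.2 (biallelic SNPs, GT field only) via cyvcf2; dosage counts the
  ALT allele, so GT 0/0, 0/1, 1/1 load as 0, 1, 2.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

MISSING = -1
UNASSIGNED_CHROMOSOME = 0

MARKER_COLUMNS = ["marker_id", "chromosome", "scaffold_id", "position_bp"]
SAMPLE_COLUMNS = ["sample_id", "line_id", "vigor_class"]

_VALID_CODES = frozenset({-1, 0, 1, 2})


class GenotypeParseError(ValueError):
    """A genotype file could not be parsed (malformed cell / record)."""


class PanelValidationError(ValueError):
    """Panel metadata and genotype matrix are inconsistent."""


class EmptyPanelError(ValueError):
    """A filtering step removed every marker (or sample)."""


@dataclasses.dataclass
class GenotypePanel:
    """Samples x markers dosage matrix plus marker and sample metadata.

    ``genotypes[i, j]`` is the number of copies (0/1/2) of the counted allele
    carried by sample ``i`` at marker ``j``; ``-1`` marks a missing call.
    """

    genotypes: np.ndarray
    markers: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes)
        if self.genotypes.ndim != 2:
            raise PanelValidationError("genotypes must be a 2-d matrix")
        self.genotypes = self.genotypes.astype(np.int8, copy=False)
        self.markers = self.markers.reset_index(drop=True)
        self.samples = self.samples.reset_index(drop=True)
        self.validate()

    # -- structure ---------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.genotypes.shape[1]

    def validate(self) -> None:
        n, m = self.genotypes.shape
        if len(self.samples) != n:
            raise PanelValidationError(
                f"{len(self.samples)} sample records for {n} genotype rows"
            )
        if len(self.markers) != m:
            raise PanelValidationError(
                f"{len(self.markers)} marker records for {m} genotype columns"
            )
        bad = set(np.unique(self.genotypes)) - _VALID_CODES
        if bad:
            raise PanelValidationError(f"invalid genotype codes: {sorted(bad)}")
        for col in MARKER_COLUMNS:
            if col not in self.markers.columns:
                raise PanelValidationError(f"marker table lacks column {col!r}")
        for col in SAMPLE_COLUMNS:
            if col not in self.samples.columns:
                raise PanelValidationError(f"sample table lacks column {col!r}")
        if self.markers["marker_id"].duplicated().any():
            dup = self.markers["marker_id"][self.markers["marker_id"].duplicated()]
            raise PanelValidationError(f"duplicate marker ids: {sorted(set(dup))}")
        if self.samples["sample_id"].duplicated().any():
            dup = self.samples["sample_id"][self.samples["sample_id"].duplicated()]
            raise PanelValidationError(f"duplicate sample ids: {sorted(set(dup))}")

    # -- per-marker / per-sample statistics --------------------------------
    def missing_mask(self) -> np.ndarray:
        return self.genotypes == MISSING

    @property
    def n_missing(self) -> int:
        return int(self.missing_mask().sum())

    @property
    def is_complete(self) -> bool:
        return self.n_missing == 0

    def marker_call_rates(self) -> np.ndarray:
        """Fraction of samples with a called genotype, per marker."""
        return 1.0 - self.missing_mask().mean(axis=0)

    def sample_call_rates(self) -> np.ndarray:
        return 1.0 - self.missing_mask().mean(axis=1)

    def allele_freqs(self) -> np.ndarray:
        """Observed frequency of the counted allele, per marker.

        Markers with no called genotype get frequency NaN.
        """
        called = self.genotypes != MISSING
        dosage = np.where(called, self.genotypes, 0).astype(float)
        n_called = called.sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_called > 0, dosage.sum(axis=0) / (2.0 * n_called), np.nan)

    def maf(self) -> np.ndarray:
        p = self.allele_freqs()
        return np.minimum(p, 1.0 - p)

    # -- manipulation ------------------------------------------------------
    def subset(self, sample_idx=None, marker_idx=None) -> "GenotypePanel":
        sidx = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        midx = np.arange(self.n_markers) if marker_idx is None else np.asarray(marker_idx)
        return GenotypePanel(
            genotypes=self.genotypes[np.ix_(sidx, midx)].copy(),
            markers=self.markers.iloc[midx].reset_index(drop=True),
            samples=self.samples.iloc[sidx].reset_index(drop=True),
        )

    def copy(self) -> "GenotypePanel":
        return GenotypePanel(
            self.genotypes.copy(), self.markers.copy(), self.samples.copy()
        )


def phenotype_vector(panel: GenotypePanel) -> np.ndarray:
    """Binary phenotypes as float 0/1 with NaN for unknown class."""
    y = panel.samples["vigor_class"].to_numpy(dtype=float)
    y[y < 0] = np.nan
    return y


# ---------------------------------------------------------------------------
# Loading / writing
# ---------------------------------------------------------------------------

def load_genotypes(
    path,
    format: str = "table",
    marker_map=None,
    samples=None,
) -> GenotypePanel:
    """Load a genotype panel from a TSV table or a VCF.

    Parameters
    ----------
    path:
        Genotype table (TSV dialect above) or VCF file.
    format:
        ``"table"`` or ``"vcf"``.
    marker_map, samples:
        Optional paths to the marker-map and sample-table TSVs. For VCF input
        the marker map is taken from the VCF records themselves and
        ``marker_map`` is ignored.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "table":
        return _load_table(path, marker_map, samples)
    if format == "vcf":
        return _load_vcf(path, samples)
    raise ValueError(f"unknown format {format!r}")


def _parse_cell(value, sample_id, marker_id) -> int:
    s = str(value).strip()
    if s in ("NA", "", "nan", "<NA>"):
        return MISSING
    try:
        g = int(float(s))
    except ValueError:
        raise GenotypeParseError(
            f"malformed genotype {value!r} at sample {sample_id!r}, marker {marker_id!r}"
        ) from None
    if g not in (0, 1, 2):
        raise GenotypeParseError(
            f"genotype {value!r} outside {{0,1,2,NA}} at sample {sample_id!r},"
            f" marker {marker_id!r}"
        )
    return g


def _load_table(path: Path, marker_map, samples) -> GenotypePanel:
    table = pd.read_csv(path, sep="\t", dtype=str)
    if table.shape[1] < 2:
        raise GenotypeParseError(f"{path}: expected sample_id column plus markers")
    sample_ids = table.iloc[:, 0].astype(str).tolist()
    marker_ids = [str(c) for c in table.columns[1:]]
    geno = np.empty((len(sample_ids), len(marker_ids)), dtype=np.int8)
    for i, sid in enumerate(sample_ids):
        row = table.iloc[i, 1:]
        for j, mid in enumerate(marker_ids):
            geno[i, j] = _parse_cell(row.iloc[j], sid, mid)

    markers = _read_marker_map(marker_map, marker_ids)
    sample_df = _read_sample_table(samples, sample_ids)
    return GenotypePanel(geno, markers, sample_df)


def _read_marker_map(marker_map, marker_ids) -> pd.DataFrame:
    if marker_map is None:
        return pd.DataFrame(
            {
                "marker_id": marker_ids,
                "chromosome": UNASSIGNED_CHROMOSOME,
                "scaffold_id": marker_ids,  # each marker on its own scaffold
                "position_bp": -1,
            }
        )
    mm = pd.read_csv(marker_map, sep="\t", dtype={"marker_id": str, "scaffold_id": str})
    missing_cols = set(MARKER_COLUMNS) - set(mm.columns)
    if missing_cols:
        raise GenotypeParseError(f"marker map lacks columns {sorted(missing_cols)}")
    mm = mm.set_index("marker_id", drop=False)
    absent = [m for m in marker_ids if m not in mm.index]
    if absent:
        raise GenotypeParseError(f"markers absent from map: {absent[:5]}")
    mm = mm.loc[marker_ids].reset_index(drop=True)
    mm["chromosome"] = mm["chromosome"].astype(int)
    mm["position_bp"] = mm["position_bp"].fillna(-1).astype(np.int64)
    return mm[MARKER_COLUMNS]


def _read_sample_table(samples, sample_ids) -> pd.DataFrame:
    if samples is None:
        return pd.DataFrame(
            {"sample_id": sample_ids, "line_id": "unknown", "vigor_class": np.int8(-1)}
        )
    st = pd.read_csv(samples, sep="\t", dtype={"sample_id": str, "line_id": str})
    missing_cols = set(SAMPLE_COLUMNS) - set(st.columns)
    if missing_cols:
        raise GenotypeParseError(f"sample table lacks columns {sorted(missing_cols)}")
    st = st.set_index("sample_id", drop=False)
    absent = [s for s in sample_ids if s not in st.index]
    if absent:
        raise GenotypeParseError(f"samples absent from sample table: {absent[:5]}")
    st = st.loc[sample_ids].reset_index(drop=True)
    vc = pd.to_numeric(st["vigor_class"], errors="coerce")
    st["vigor_class"] = vc.fillna(-1).astype(np.int8)
    if not set(st["vigor_class"].unique()) <= {-1, 0, 1}:
        raise GenotypeParseError("vigor_class must be 0, 1 or NA")
    return st[SAMPLE_COLUMNS]


def _load_vcf(path: Path, samples) -> GenotypePanel:
    from cyvcf2 import VCF  # deferred: only needed for VCF input

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    marker_rows = []
    geno_cols = []
    for rec in vcf:
        if len(rec.ALT) != 1 or not rec.is_snp:
            raise GenotypeParseError(
                f"non-biallelic-SNP record at {rec.CHROM}:{rec.POS} in {path}"
            )
        col = np.empty(len(sample_ids), dtype=np.int8)
        for i, gt in enumerate(rec.genotypes):
            a0, a1 = gt[0], gt[1]
            col[i] = MISSING if (a0 < 0 or a1 < 0) else int(a0 > 0) + int(a1 > 0)
        geno_cols.append(col)
        chrom = str(rec.CHROM)
        try:
            chromosome = int(chrom)
            if not 1 <= chromosome <= 9:
                chromosome = UNASSIGNED_CHROMOSOME
        except ValueError:
            chromosome = UNASSIGNED_CHROMOSOME
        marker_rows.append(
            {
                "marker_id": rec.ID if rec.ID not in (None, ".") else f"{chrom}:{rec.POS}",
                "chromosome": chromosome,
                "scaffold_id": chrom,
                "position_bp": int(rec.POS),
            }
        )
    if not marker_rows:
        raise GenotypeParseError(f"no variant records in {path}")
    geno = np.column_stack(geno_cols)
    markers = pd.DataFrame(marker_rows)[MARKER_COLUMNS]
    sample_df = _read_sample_table(samples, sample_ids)
    return GenotypePanel(geno, markers, sample_df)


def write_panel(panel: GenotypePanel, genotypes, markers=None, samples=None) -> None:
    """Write a panel in the TSV dialect (inverse of :func:`load_genotypes`)."""
    geno = pd.DataFrame(
        panel.genotypes,
        index=pd.Index(panel.samples["sample_id"], name="sample_id"),
        columns=panel.markers["marker_id"],
    ).astype(object)
    geno[panel.genotypes == MISSING] = "NA"
    geno.to_csv(genotypes, sep="\t")
    if markers is not None:
        panel.markers[MARKER_COLUMNS].to_csv(markers, sep="\t", index=False)
    if samples is not None:
        st = panel.samples[SAMPLE_COLUMNS].copy()
        st["vigor_class"] = st["vigor_class"].astype(object)
        st.loc[st["vigor_class"] == -1, "vigor_class"] = "NA"
        st.to_csv(samples, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Quality control
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class QCReport:
    """Ledger of everything a :func:`qc_filter` run removed and why."""

    removed_samples: list = dataclasses.field(default_factory=list)  # (id, reason)
    removed_markers: list = dataclasses.field(default_factory=list)  # (id, reason)
    duplicate_groups: list = dataclasses.field(default_factory=list)
    n_samples_before: int = 0
    n_samples_after: int = 0
    n_markers_before: int = 0
    n_markers_after: int = 0
    n_missing_remaining: int = 0
    n_cells_remaining: int = 0

    @property
    def missing_percent(self) -> float:
        if self.n_cells_remaining == 0:
            return float("nan")
        return 100.0 * self.n_missing_remaining / self.n_cells_remaining

    def summary(self) -> str:
        lines = [
            f"samples: {self.n_samples_before} -> {self.n_samples_after}",
            f"markers: {self.n_markers_before} -> {self.n_markers_after}",
            (
                f"missing genotypes remaining: {self.n_missing_remaining} / "
                f"{self.n_cells_remaining} cells ({self.missing_percent:.2f}%)"
            ),
        ]
        for sid, reason in self.removed_samples:
            lines.append(f"removed sample {sid}: {reason}")
        for mid, reason in self.removed_markers:
            lines.append(f"removed marker {mid}: {reason}")
        return "\n".join(lines)


def find_duplicate_samples(genotypes: np.ndarray) -> list:
    """Groups of samples identical at 100% of jointly called genotypes.

    Missing cells are ignored; a pair with no jointly called marker is not
    considered duplicated. Returns groups of row indices (first index is the
    one input order keeps).
    """
    n = genotypes.shape[0]
    assigned = np.full(n, False)
    groups = []
    called = genotypes != MISSING
    for i in range(n):
        if assigned[i]:
            continue
        members = [i]
        for j in range(i + 1, n):
            if assigned[j]:
                continue
            both = called[i] & called[j]
            if both.any() and np.array_equal(genotypes[i][both], genotypes[j][both]):
                members.append(j)
                assigned[j] = True
        if len(members) > 1:
            groups.append(members)
    return groups


def qc_filter(
    panel: GenotypePanel,
    max_snp_missing: float = 0.15,
    min_maf: float = 0.025,
    drop_duplicates: bool = True,
):
    """Edit a panel: duplicates, then marker call rate, then MAF.

    Stage order is fixed: (1) remove all but the first member of each
    duplicate-sample group; (2) remove markers whose call rate (recomputed on
    the surviving samples) is <= ``1 - max_snp_missing``; (3) recompute MAF on
    surviving samples and remove markers with MAF <= ``min_maf``.

    Returns ``(filtered_panel, QCReport)``.
    """
    if not (0 <= max_snp_missing <= 1 and 0 <= min_maf <= 1):
        raise ValueError("thresholds must lie in [0, 1]")
    report = QCReport(
        n_samples_before=panel.n_samples, n_markers_before=panel.n_markers
    )
    current = panel

    if drop_duplicates:
        groups = find_duplicate_samples(current.genotypes)
        drop = set()
        ids = current.samples["sample_id"]
        for group in groups:
            report.duplicate_groups.append([ids.iloc[i] for i in group])
            keeper = ids.iloc[group[0]]
            for i in group[1:]:
                drop.add(i)
                report.removed_samples.append(
                    (ids.iloc[i], f"duplicate of {keeper} (100% matching genotypes)")
                )
        if drop:
            keep = [i for i in range(current.n_samples) if i not in drop]
            current = current.subset(sample_idx=keep)

    call = current.marker_call_rates()
    keep_call = call > 1.0 - max_snp_missing
    for j in np.flatnonzero(~keep_call):
        report.removed_markers.append(
            (
                current.markers["marker_id"].iloc[j],
                f"call rate {call[j]:.3f} <= {1.0 - max_snp_missing:.3f}",
            )
        )
    if not keep_call.any():
        raise EmptyPanelError("call-rate filter removed every marker")
    current = current.subset(marker_idx=np.flatnonzero(keep_call))

    maf = current.maf()
    keep_maf = maf > min_maf
    for j in np.flatnonzero(~keep_maf):
        report.removed_markers.append(
            (
                current.markers["marker_id"].iloc[j],
                f"MAF {maf[j]:.4f} <= {min_maf:.4f}",
            )
        )
    if not keep_maf.any():
        raise EmptyPanelError("MAF filter removed every marker")
    current = current.subset(marker_idx=np.flatnonzero(keep_maf))

    report.n_samples_after = current.n_samples
    report.n_markers_after = current.n_markers
    report.n_missing_remaining = current.n_missing
    report.n_cells_remaining = current.n_samples * current.n_markers
    return current, report
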