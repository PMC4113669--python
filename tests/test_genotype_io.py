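"""Panel loading, validation and the duplicate / call-rate / MAF editing."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from vigorclass.genotype_io import (
    MISSING,
    EmptyPanelError,
    GenotypeParseError,
    PanelValidationError,
    find_duplicate_samples,
    load_genotypes,
    phenotype_vector,
    qc_filter,
    write_panel,
)

from conftest import make_panel


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------

def test_table_round_trip(tmp_path, block_ld_dataset):
    panel = block_ld_dataset.masked_panel or block_ld_dataset.panel
    g, m, s = tmp_path / "g.tsv", tmp_path / "m.tsv", tmp_path / "s.tsv"
    write_panel(panel, g, m, s)
    back = load_genotypes(g, format="table", marker_map=m, samples=s)
    np.testing.assert_array_equal(back.genotypes, panel.genotypes)
    pd.testing.assert_frame_equal(
        back.markers, panel.markers.reset_index(drop=True), check_dtype=False
    )
    pd.testing.assert_frame_equal(
        back.samples, panel.samples.reset_index(drop=True), check_dtype=False
    )


def test_table_call_rates_and_missing(tmp_path):
    (tmp_path / "g.tsv").write_text(
        "sample_id\tM0\tM1\nA\t0\t1\nB\t1\tNA\nC\t2\t2\n"
    )
    panel = load_genotypes(tmp_path / "g.tsv")
    np.testing.assert_allclose(panel.marker_call_rates(), [1.0, 2 / 3])
    assert panel.n_missing == 1
    assert panel.genotypes[1, 1] == MISSING


def test_malformed_cell_names_location(tmp_path):
    (tmp_path / "g.tsv").write_text("sample_id\tM0\nA\t0\nB\tx\n")
    with pytest.raises(GenotypeParseError, match="'B'.*'M0'"):
        load_genotypes(tmp_path / "g.tsv")


def test_duplicate_sample_id_rejected(tmp_path):
    (tmp_path / "g.tsv").write_text("sample_id\tM0\nA\t0\nA\t1\n")
    with pytest.raises(PanelValidationError, match="duplicate sample ids"):
        load_genotypes(tmp_path / "g.tsv")


VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    "##contig=<ID=sc1>\n"
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tA\tB\tC\n"
)


def test_vcf_dosage_coding(tmp_path):
    vcf = tmp_path / "toy.vcf"
    vcf.write_text(
        VCF_HEADER + "sc1\t100\tsnp1\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\n"
        "sc1\t200\tsnp2\tC\tT\t.\tPASS\t.\tGT\t./.\t0/0\t0/1\n"
    )
    panel = load_genotypes(vcf, format="vcf")
    np.testing.assert_array_equal(panel.genotypes[:, 0], [0, 1, 2])
    np.testing.assert_array_equal(panel.genotypes[:, 1], [MISSING, 0, 1])
    assert list(panel.markers["marker_id"]) == ["snp1", "snp2"]
    assert list(panel.markers["scaffold_id"]) == ["sc1", "sc1"]


def test_vcf_non_biallelic_rejected(tmp_path):
    vcf = tmp_path / "bad.vcf"
    vcf.write_text(
        VCF_HEADER + "sc1\t100\tsnp1\tA\tG,T\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\n"
    )
    with pytest.raises(GenotypeParseError, match="sc1:100"):
        load_genotypes(vcf, format="vcf")


# ---------------------------------------------------------------------------
# statistics against brute-force oracles
# ---------------------------------------------------------------------------

def test_maf_matches_allele_count_oracle():
    rng = np.random.default_rng(4)
    geno = rng.integers(0, 3, size=(15, 12)).astype(np.int8)
    geno[rng.random(geno.shape) < 0.15] = MISSING
    panel = make_panel(geno)
    expected = []
    for j in range(12):
        alleles = []
        for i in range(15):
            g = geno[i, j]
            if g != MISSING:
                alleles += [1] * int(g) + [0] * (2 - int(g))
        p = np.mean(alleles)
        expected.append(min(p, 1 - p))
    np.testing.assert_allclose(panel.maf(), expected, atol=1e-12)


def test_phenotype_vector_missing_coding():
    panel = make_panel([[0], [1], [2]], vigor=[1, 0, -1])
    y = phenotype_vector(panel)
    assert y[0] == 1 and y[1] == 0 and np.isnan(y[2])


# ---------------------------------------------------------------------------
# QC filtering
# ---------------------------------------------------------------------------

def test_qc_clean_panel_is_identity():
    geno = [[0, 1, 2], [1, 1, 0], [2, 0, 1], [1, 2, 1]]
    panel = make_panel(geno)
    out, report = qc_filter(panel, max_snp_missing=0.15, min_maf=0.025)
    np.testing.assert_array_equal(out.genotypes, panel.genotypes)
    assert report.removed_samples == [] and report.removed_markers == []


def test_qc_removes_duplicate_keeps_first():
    geno = [[0, 1, 2, 1], [2, 1, 0, 1], [0, 1, 2, 1], [1, 0, 1, 2]]
    panel = make_panel(geno)
    out, report = qc_filter(panel)
    assert list(out.samples["sample_id"]) == ["S0", "S1", "S3"]
    assert report.removed_samples == [("S2", "duplicate of S0 (100% matching genotypes)")]


def test_duplicate_detection_ignores_missing_cells():
    # S0/S1 agree at every jointly called marker
    geno = [[0, MISSING, 2], [0, 1, MISSING], [1, 1, 1]]
    groups = find_duplicate_samples(np.array(geno, dtype=np.int8))
    assert groups == [[0, 1]]


def test_triplet_duplicates_keep_one():
    geno = [[0, 1], [0, 1], [0, 1], [2, 0]]
    panel = make_panel(geno)
    out, report = qc_filter(panel, min_maf=0.0)
    assert out.n_samples == 2
    assert report.duplicate_groups == [["S0", "S1", "S2"]]


def test_qc_call_rate_and_maf_boundaries():
    # marker 0: call rate exactly 0.85 is removed ("<=" rule);
    # marker 2: MAF exactly at min_maf is removed
    rng = np.random.default_rng(0)
    n = 20
    geno = rng.integers(0, 3, size=(n, 3)).astype(np.int8)
    geno[:3, 0] = MISSING  # call rate 17/20 = 0.85
    geno[:, 2] = 0
    geno[0, 2] = 2  # MAF 1/20 = 0.05
    panel = make_panel(geno)
    out, report = qc_filter(
        panel, max_snp_missing=0.15, min_maf=0.05, drop_duplicates=False
    )
    assert list(out.markers["marker_id"]) == ["M1"]
    reasons = dict(report.removed_markers)
    assert "call rate" in reasons["M0"] and "MAF" in reasons["M2"]


def test_qc_maf_recomputed_after_sample_removal():
    # After dropping the duplicate, M1's MAF falls to 1/6 <= 0.2 and must go
    geno = [[0, 1], [0, 1], [2, 0], [1, 0]]
    panel = make_panel(geno)
    out, _ = qc_filter(panel, min_maf=0.2)
    assert list(out.markers["marker_id"]) == ["M0"]


def test_qc_empty_panel_error():
    panel = make_panel([[0, 0], [0, 0], [0, 0]])
    with pytest.raises(EmptyPanelError):
        qc_filter(panel, min_maf=0.025)


def test_qc_idempotent(block_ld_dataset):
    panel = block_ld_dataset.masked_panel or block_ld_dataset.panel
    once, _ = qc_filter(panel)
    twice, report = qc_filter(once)
    np.testing.assert_array_equal(once.genotypes, twice.genotypes)
    assert report.removed_samples == [] and report.removed_markers == []


@given(st.integers(0, 2**31 - 1))
def test_qc_retained_maf_strictly_above_threshold(seed):
    rng = np.random.default_rng(seed)
    geno = rng.integers(0, 3, size=(12, 8)).astype(np.int8)
    geno[rng.random(geno.shape) < 0.1] = MISSING
    panel = make_panel(geno)
    try:
        out, _ = qc_filter(panel, min_maf=0.1)
    except EmptyPanelError:
        return
    assert (out.maf() > 0.1).all()
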