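"""Synthetic sugar-beet-like populations for exercising the pipeline.

The generator emulates the statistical structure of a small line-structured
breeding panel: a handful of inbred-ish lines (each line descends from a
founder haplotype pair per scaffold, so within-line relationships are
high), scaffold-blocked LD (Gaussian-copula AR(1) correlation within
scaffolds, independence between scaffolds), an oligogenic liability trait
(few large-effect loci clustered on a few scaffolds) with a chosen
liability-scale heritability, and controlled MCAR missingness plus optional
exact-duplicate samples.

The generative model for the phenotype mirrors the analysis model: liability
l = mu + g + e with e standard logistic, class = 1 iff l > 0. Lines are
labelled high-/low-vigor by ranking founder genetic merit at the QTL, so the
configured line counts — and, because sample counts are allocated to lines
by class, the configured class sizes — are met exactly. By default the
binary phenotype is assigned at the line level (all samples of a line share
the class, as observed in the real population); set
``line_level_phenotype=False`` for individual-level classes drawn from each
sample's own liability (used, e.g., for heritability-recovery simulations).
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_io import MISSING, GenotypePanel, find_duplicate_samples
from .threshold_model import LOGISTIC_VARIANCE, variance_from_h2


@dataclasses.dataclass
class SimConfig:
    """Full parameterization of a synthetic population."""

    n_lines_high: int = 15
    n_lines_low: int = 3
    samples_per_line: list | int | None = None  # None -> sugar-beet-like 100 + 24
    n_scaffolds: int = 99
    n_snps: int = 192
    within_scaffold_rho: float = 0.9
    maf_range: tuple = (0.05, 0.5)
    n_qtl: int = 10
    qtl_scaffolds: int = 3
    qtl_effect_size: float = 1.0
    qtl_effect_dist: str = "uniform"  # "uniform": |eff| ~ U(0.5,1.5)*size; "equal"
    target_h2: float = 0.78
    mu: float = 1.4
    missing_rate: float = 0.0
    n_duplicate_samples: int = 0
    line_noise: float = 0.01  # per-allele flip probability on inherited haplotypes
    line_level_phenotype: bool = True
    seed: int = 0

    def resolved_samples_per_line(self) -> list:
        n_lines = self.n_lines_high + self.n_lines_low
        if self.samples_per_line is None:
            # sugar-beet-like split: 100 samples over high lines, 24 over low lines
            high = _spread(100, self.n_lines_high)
            low = _spread(24, self.n_lines_low)
            return high + low
        if isinstance(self.samples_per_line, int):
            return [self.samples_per_line] * n_lines
        spl = list(self.samples_per_line)
        if len(spl) != n_lines:
            raise ValueError(
                f"samples_per_line has {len(spl)} entries for {n_lines} lines"
            )
        return spl

    def validate(self) -> None:
        if self.n_lines_high < 1 or self.n_lines_low < 0:
            raise ValueError("line counts must be positive")
        if not 0.0 <= self.target_h2 < 1.0:
            raise ValueError("target_h2 must lie in [0, 1)")
        if self.target_h2 > 0 and self.n_qtl == 0:
            raise ValueError("target_h2 > 0 is unattainable with n_qtl = 0")
        if not 0.0 <= self.within_scaffold_rho < 1.0:
            raise ValueError("within_scaffold_rho must lie in [0, 1)")
        lo, hi = self.maf_range
        if not 0.0 < lo <= hi <= 0.5:
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.n_snps < self.n_scaffolds:
            raise ValueError("need at least one SNP per scaffold")
        if min(self.resolved_samples_per_line()) < 1:
            raise ValueError("every line needs at least one sample")


def _spread(total: int, bins: int) -> list:
    base = total // bins
    extra = total % bins
    return [base + 1] * extra + [base] * (bins - extra)


@dataclasses.dataclass
class SimDataset:
    panel: GenotypePanel  # complete genotypes
    truth: dict  # g_true, qtl_ids, qtl_effects, realized_h2, liability, line_class
    masked_panel: GenotypePanel | None  # with injected missingness, if requested
    config: SimConfig


def _scaffold_sizes(rng, n_snps, n_scaffolds):
    """At least one SNP per scaffold, remainder multinomially spread."""
    sizes = np.ones(n_scaffolds, dtype=int)
    rest = n_snps - n_scaffolds
    if rest > 0:
        sizes += rng.multinomial(rest, np.full(n_scaffolds, 1.0 / n_scaffolds))
    return sizes


def _ar1_latent(rng, size, rho):
    z = np.empty(size)
    z[0] = rng.standard_normal()
    for t in range(1, size):
        z[t] = rho * z[t - 1] + math.sqrt(1.0 - rho * rho) * rng.standard_normal()
    return z


def simulate_dataset(config: SimConfig) -> SimDataset:
    """Generate a line-structured panel with an oligogenic liability trait."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    spl = config.resolved_samples_per_line()
    n_lines = config.n_lines_high + config.n_lines_low
    n_samples = sum(spl)
    m = config.n_snps

    sizes = _scaffold_sizes(rng, m, config.n_scaffolds)
    scaffold_of = np.repeat(np.arange(config.n_scaffolds), sizes)
    # scaffolds assigned to the 9 chromosomes plus a block of unassigned ones
    chrom_of_scaffold = np.concatenate(
        [
            rng.integers(1, 10, size=max(config.n_scaffolds - config.n_scaffolds // 10, 0)),
            np.zeros(config.n_scaffolds // 10, dtype=np.int64),
        ]
    )
    rng.shuffle(chrom_of_scaffold)

    p = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)
    thresh = stats.norm.ppf(p)  # latent < thresh -> allele 1, marginally freq p

    scaffold_slices = []
    start = 0
    for s in sizes:
        scaffold_slices.append(slice(start, start + s))
        start += s

    def draw_haplotype() -> np.ndarray:
        hap = np.empty(m, dtype=np.int8)
        for sl in scaffold_slices:
            z = _ar1_latent(rng, sl.stop - sl.start, config.within_scaffold_rho)
            hap[sl] = (z < thresh[sl]).astype(np.int8)
        return hap

    # two founder haplotypes per line
    founders = [(draw_haplotype(), draw_haplotype()) for _ in range(n_lines)]

    # oligogenic architecture: QTL clustered on the largest scaffolds.
    # Effects are drawn before sampling so lines can be ranked by founder
    # genetic merit, which decides which lines are high- vs low-vigor and
    # therefore which line receives which configured sample count.
    if config.n_qtl > 0 and config.target_h2 > 0:
        order_sc = np.argsort(sizes)[::-1]
        qtl_scaffold_ids = order_sc[: config.qtl_scaffolds]
        candidates = np.flatnonzero(np.isin(scaffold_of, qtl_scaffold_ids))
        if len(candidates) < config.n_qtl:
            candidates = np.arange(m)
        qtl_idx = np.sort(rng.choice(candidates, size=config.n_qtl, replace=False))
        signs = rng.choice([-1.0, 1.0], size=config.n_qtl)
        if config.qtl_effect_dist == "equal":
            mags = np.ones(config.n_qtl)
        elif config.qtl_effect_dist == "uniform":
            mags = rng.uniform(0.5, 1.5, config.n_qtl)
        else:
            raise ValueError(f"unknown qtl_effect_dist {config.qtl_effect_dist!r}")
        effects = signs * config.qtl_effect_size * mags
        founder_dosage = np.array(
            [founders[li][0][qtl_idx] + founders[li][1][qtl_idx] for li in range(n_lines)],
            dtype=float,
        )
        g_founder = (founder_dosage - founder_dosage.mean(axis=0)) @ effects
        line_rank = np.argsort(-g_founder, kind="stable")
    else:
        qtl_idx = np.array([], dtype=int)
        effects = np.array([])
        line_rank = rng.permutation(n_lines)
    line_class = np.zeros(n_lines, dtype=np.int8)
    line_class[line_rank[: config.n_lines_high]] = 1
    # configured sizes: first n_lines_high entries belong to the high-vigor
    # lines (in merit order), the remainder to the low-vigor lines
    size_of_line = np.empty(n_lines, dtype=int)
    for r, li in enumerate(line_rank):
        size_of_line[li] = spl[r]
    n_samples = int(size_of_line.sum())

    geno = np.empty((n_samples, m), dtype=np.int8)
    line_ids = []
    sample_ids = []
    line_of_sample = np.empty(n_samples, dtype=int)
    i = 0
    for li in range(n_lines):
        line_name = f"L{li + 1:02d}"
        for _ in range(size_of_line[li]):
            haps = []
            for _h in range(2):
                hap = np.empty(m, dtype=np.int8)
                for sl in scaffold_slices:
                    src = founders[li][rng.integers(2)]
                    hap[sl] = src[sl]
                if config.line_noise > 0:
                    flip = rng.random(m) < config.line_noise
                    hap = np.where(flip, 1 - hap, hap).astype(np.int8)
                haps.append(hap)
            geno[i] = haps[0] + haps[1]
            sample_ids.append(f"S{i + 1:03d}")
            line_ids.append(line_name)
            line_of_sample[i] = li
            i += 1

    if config.n_qtl > 0 and config.target_h2 > 0:
        D = geno[:, qtl_idx].astype(float)
        D -= D.mean(axis=0)
        g_raw = D @ effects
        var_raw = float(np.var(g_raw))
        if var_raw <= 0:
            raise ValueError(
                "QTL carry no genetic variance (monomorphic); re-seed or widen maf_range"
            )
        target_var = variance_from_h2(config.target_h2)
        scale = math.sqrt(target_var / var_raw)
        g_true = g_raw * scale
        effects_scaled = effects * scale
    else:
        effects_scaled = np.array([])
        g_true = np.zeros(n_samples)

    e = rng.logistic(0.0, 1.0, size=n_samples)
    liability = config.mu + g_true + e
    y_individual = (liability > 0).astype(np.int8)

    if config.line_level_phenotype:
        y = line_class[line_of_sample]
    else:
        y = y_individual

    var_g = float(np.var(g_true))
    realized_h2 = var_g / (var_g + LOGISTIC_VARIANCE) if var_g > 0 else 0.0

    markers = pd.DataFrame(
        {
            "marker_id": [f"SNP{j + 1:04d}" for j in range(m)],
            "chromosome": chrom_of_scaffold[scaffold_of],
            "scaffold_id": [f"scaffold{scaffold_of[j] + 1:05d}" for j in range(m)],
            "position_bp": _positions(rng, scaffold_of),
        }
    )
    samples = pd.DataFrame(
        {"sample_id": sample_ids, "line_id": line_ids, "vigor_class": y.astype(np.int8)}
    )
    truth = {
        "g_true": g_true,
        "qtl_ids": [markers["marker_id"].iloc[j] for j in qtl_idx],
        "qtl_indices": qtl_idx,
        "qtl_effects": effects_scaled,
        "realized_h2": realized_h2,
        "liability": liability,
        "y_individual": y_individual,
        "line_class": {f"L{li + 1:02d}": int(line_class[li]) for li in range(n_lines)},
    }

    # optional exact duplicates: overwrite the last sample(s) of the largest
    # lines with copies of a linemate, keeping the sample count unchanged
    if config.n_duplicate_samples > 0:
        high_lines = [li for li in range(n_lines) if line_class[li] == 1] or list(
            range(n_lines)
        )
        dup_lines = sorted(high_lines, key=lambda li: -spl[li])[
            : config.n_duplicate_samples
        ]
        for li in dup_lines:
            members = np.flatnonzero(line_of_sample == li)
            if len(members) < 2:
                continue
            src, dst = members[0], members[-1]
            geno[dst] = geno[src]
            y[dst] = y[src]
            samples.loc[dst, "vigor_class"] = samples.loc[src, "vigor_class"]

    panel = GenotypePanel(geno, markers, samples)

    masked = None
    if config.missing_rate > 0:
        masked = inject_missing(panel, config.missing_rate, config.seed + 1)

    return SimDataset(panel=panel, truth=truth, masked_panel=masked, config=config)


def _positions(rng, scaffold_of):
    pos = np.zeros(len(scaffold_of), dtype=np.int64)
    for s in np.unique(scaffold_of):
        idx = np.flatnonzero(scaffold_of == s)
        pos[idx] = np.sort(rng.integers(1, 2_000_000, size=len(idx)))
    return pos


def inject_missing(panel: GenotypePanel, rate: float, seed: int) -> GenotypePanel:
    """Missing-completely-at-random at exactly round(rate * n_cells) cells."""
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must lie in [0, 1)")
    if rate == 0.0:
        return panel.copy()
    n, m = panel.genotypes.shape
    n_cells = n * m
    n_miss = int(round(rate * n_cells))
    rng = np.random.default_rng(seed)
    flat = rng.choice(n_cells, size=n_miss, replace=False)
    rows, cols = np.unravel_index(flat, (n, m))
    geno = panel.genotypes.copy()
    geno[rows, cols] = MISSING
    return GenotypePanel(geno, panel.markers.copy(), panel.samples.copy())


# ---------------------------------------------------------------------------
# Constructed QC fixture
# ---------------------------------------------------------------------------

def beet_qc_fixture(seed: int = 0) -> GenotypePanel:
    """A 124 x 192 panel built to exercise every QC stage exactly once.

    By construction the panel contains exactly one duplicated sample, one
    marker with call rate 0.80, sixteen markers with MAF ~0.008, ~3% random
    missingness elsewhere, and no other sample or marker near a filter
    threshold — so qc_filter(max_snp_missing=0.15, min_maf=0.025) retains
    exactly 123 samples and 175 markers.
    """
    cfg = SimConfig(
        seed=seed,
        n_duplicate_samples=1,
        missing_rate=0.0,
        maf_range=(0.15, 0.5),
        target_h2=0.78,
    )
    ds = simulate_dataset(cfg)
    panel = ds.panel
    geno = panel.genotypes.copy()
    n, m = geno.shape
    rng = np.random.default_rng(seed + 10_000)

    groups = find_duplicate_samples(geno)
    if not groups:
        raise RuntimeError("fixture construction lost its duplicate pair")
    dup_pair = set(groups[0][:2])  # extras are broken up during repair
    free_samples = np.array([i for i in range(n) if i not in dup_pair])

    qtl_cols = set(int(j) for j in ds.truth["qtl_indices"])
    special = rng.choice(
        np.array([j for j in range(m) if j not in qtl_cols]), size=17, replace=False
    )
    low_maf_cols = special[:16]
    low_call_col = int(special[16])

    # 16 rare markers: two heterozygotes among non-duplicate samples
    for j in low_maf_cols:
        geno[:, j] = 0
        carriers = rng.choice(free_samples, size=2, replace=False)
        geno[carriers, j] = 1

    # one marker at call rate 99/124 ~ 0.80
    miss_rows = rng.choice(free_samples, size=25, replace=False)
    geno[miss_rows, low_call_col] = MISSING

    # ~3% background missingness on the remaining markers
    background = np.array(
        [j for j in range(m) if j not in set(low_maf_cols) and j != low_call_col]
    )
    n_bg = int(round(0.03 * n * len(background)))
    flat = rng.choice(n * len(background), size=n_bg, replace=False)
    rows, cols = np.unravel_index(flat, (n, len(background)))
    geno[rows, background[cols]] = MISSING

    _repair_fixture(geno, background, dup_pair, rng)

    return GenotypePanel(geno, panel.markers.copy(), panel.samples.copy())


def _repair_fixture(geno, background, dup_pair, rng, maf_floor=0.05, call_floor=0.90):
    """Nudge the background markers away from the QC thresholds.

    Keeps the designed removals (1 duplicate, 1 low-call marker, 16 rare
    markers) the only ones: raises any background marker that drifted to a
    low realized MAF, restores calls where random missingness cut a call
    rate too far, and breaks any accidental duplicate pair beyond the
    constructed one.
    """
    n = geno.shape[0]
    free = np.array([i for i in range(n) if i not in dup_pair])
    for j in background:
        col = geno[:, j]
        called = col != MISSING
        # call-rate head-room
        n_called = int(called.sum())
        if n_called / n <= call_floor:
            refill = [i for i in np.flatnonzero(~called) if i in set(free)]
            need = int(math.ceil(call_floor * n)) + 1 - n_called
            for i in refill[:need]:
                geno[i, j] = 0 if rng.random() < 0.5 else 1
        # MAF head-room (checked on called genotypes)
        col = geno[:, j]
        called = col != MISSING
        counts = col[called].astype(int)
        freq = counts.sum() / (2.0 * called.sum())
        maf = min(freq, 1.0 - freq)
        guard = 0
        while maf <= maf_floor and guard < 60:
            # flip a free sample's genotype toward the minor allele
            minor_is_counted = freq <= 0.5
            if minor_is_counted:
                cand = [i for i in free if geno[i, j] in (0, 1)]
                if not cand:
                    break
                i = cand[int(rng.integers(len(cand)))]
                geno[i, j] += 1
            else:
                cand = [i for i in free if geno[i, j] in (1, 2)]
                if not cand:
                    break
                i = cand[int(rng.integers(len(cand)))]
                geno[i, j] -= 1
            col = geno[:, j]
            called = col != MISSING
            freq = col[called].astype(int).sum() / (2.0 * called.sum())
            maf = min(freq, 1.0 - freq)
            guard += 1

    # break accidental duplicates (beyond the constructed pair)
    for _ in range(20):
        groups = find_duplicate_samples(geno)
        extra = [grp for grp in groups if set(grp) != dup_pair]
        if not extra:
            break
        for grp in extra:
            i = next(x for x in grp if x not in dup_pair)
            j = background[int(rng.integers(len(background)))]
            if geno[i, j] == MISSING:
                continue
            geno[i, j] = (geno[i, j] + 1) % 3
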