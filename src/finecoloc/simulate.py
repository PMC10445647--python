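"""Synthetic paired GWAS/QTL summary statistics and a cell-type expression atlas.

Everything downstream (fine-mapping, colocalization, annotation, enrichment)
is exercised against data generated here with known ground truth: an LD-
blocked haplotype panel, quantitative-trait association scans with planted
causal variants, and a genes x cell-types mean-expression atlas with planted
marker genes.

The haplotype panel is generated by blockwise copy-with-mutation chains:
within a block each variant's haplotype column is a copy of the previous
column in which every haplotype is independently resampled to
Bernoulli(maf) with probability ``1 - within_block_decay``.  This yields LD
that decays geometrically with index distance inside blocks, exact
independence across blocks, and a stationary allele frequency equal to the
block's target MAF.  Phenotypes are additive with Gaussian noise; effect
sizes are parameterized by the fraction of phenotypic variance each causal
variant explains, which keeps power knobs explicit and sample-size free.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .enrich import CellTypeData, specificity
from .finemap import LocusData, make_variant_ids

_BASES = np.array(["A", "C", "G", "T"])


@dataclass
class GenotypePanel:
    """Haplotype reference panel for one locus with blockwise LD."""

    allele_matrix: np.ndarray  # (hap_count, variant_count), entries in {0, 1}
    maf: np.ndarray
    positions: np.ndarray
    block_bounds: np.ndarray  # block boundaries: [0, b1, ..., variant_count]
    chrom: str
    ref: np.ndarray
    alt: np.ndarray
    ld: np.ndarray  # realized signed correlation between variants

    @property
    def hap_count(self) -> int:
        return self.allele_matrix.shape[0]

    @property
    def variant_count(self) -> int:
        return self.allele_matrix.shape[1]

    @property
    def variant_ids(self) -> np.ndarray:
        return make_variant_ids(self.chrom, self.positions, self.ref, self.alt)


@dataclass
class SimulationTruth:
    """Known causal configuration for a pair of studies at one locus.

    ``causal_indices``, ``variance_explained`` and ``effect_signs`` are
    2-tuples (study 1, study 2) of aligned arrays; each causal variant
    contributes its stated fraction of phenotypic variance with the given
    effect direction.
    """

    causal_indices: tuple
    variance_explained: tuple
    effect_signs: tuple

    def __post_init__(self):
        self.causal_indices = tuple(np.asarray(c, dtype=int) for c in self.causal_indices)
        self.variance_explained = tuple(
            np.asarray(v, dtype=float) for v in self.variance_explained
        )
        self.effect_signs = tuple(np.asarray(s, dtype=float) for s in self.effect_signs)
        if len(self.causal_indices) != 2:
            raise ValueError("truth must describe exactly two studies")
        for c, v, s in zip(self.causal_indices, self.variance_explained, self.effect_signs):
            if not (len(c) == len(v) == len(s)):
                raise ValueError("per-study truth arrays must be aligned")
            if len(c) > 5:
                raise ValueError("at most 5 causal variants per locus per study")
            if len(np.unique(c)) != len(c):
                raise ValueError("causal indices must be distinct")
            if v.sum() >= 1.0:
                raise ValueError("variance explained must sum to < 1")

    @property
    def shared_indices(self) -> np.ndarray:
        return np.intersect1d(self.causal_indices[0], self.causal_indices[1])

    @classmethod
    def from_dicts(cls, study1: dict, study2: dict) -> "SimulationTruth":
        """Build truth from {variant_index: (variance_explained, sign)} per study."""
        def unpack(d):
            idx = np.array(sorted(d), dtype=int)
            ve = np.array([d[i][0] for i in idx], dtype=float)
            sg = np.array([d[i][1] for i in idx], dtype=float)
            return idx, ve, sg

        i1, v1, s1 = unpack(study1)
        i2, v2, s2 = unpack(study2)
        return cls(causal_indices=(i1, i2), variance_explained=(v1, v2),
                   effect_signs=(s1, s2))

    def to_dict(self) -> dict:
        return {
            "causal_indices": [c.tolist() for c in self.causal_indices],
            "variance_explained": [v.tolist() for v in self.variance_explained],
            "effect_signs": [s.tolist() for s in self.effect_signs],
            "shared_indices": self.shared_indices.tolist(),
        }


def simulate_panel(variant_count: int, hap_count: int, block_size: int,
                   within_block_decay: float, maf_range=(0.05, 0.5),
                   seed: int = 0, chrom: str = "chr1",
                   position_start: int = 1_000_000) -> GenotypePanel:
    """Generate an LD-blocked haplotype panel.

    Parameters
    ----------
    variant_count, hap_count : int
        Panel dimensions; must be positive.
    block_size : int
        Number of consecutive variants per LD block (last block may be short).
        ``block_size=1`` gives fully independent variants.
    within_block_decay : float in (0, 1)
        Copy probability of the copy-with-mutation chain; adjacent-variant
        correlation is approximately this value.
    maf_range : (low, high] subset of (0, 0.5]
        One target MAF per block is drawn uniformly from this range.
    """
    if variant_count <= 0 or hap_count <= 0 or block_size <= 0:
        raise ValueError("variant_count, hap_count and block_size must be positive")
    if not (0 < within_block_decay < 1):
        raise ValueError("within_block_decay must be in (0, 1)")
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must lie within (0, 0.5]")
    rng = np.random.default_rng(seed)

    bounds = list(range(0, variant_count, block_size)) + [variant_count]
    H = np.empty((hap_count, variant_count), dtype=np.int8)
    maf = np.empty(variant_count)
    for s, e in zip(bounds[:-1], bounds[1:]):
        block_maf = rng.uniform(lo, hi)
        maf[s:e] = block_maf
        col = (rng.random(hap_count) < block_maf).astype(np.int8)
        H[:, s] = col
        for j in range(s + 1, e):
            mutate = rng.random(hap_count) < (1 - within_block_decay)
            fresh = (rng.random(hap_count) < block_maf).astype(np.int8)
            col = np.where(mutate, fresh, col)
            H[:, j] = col

    # monomorphic columns break correlation; nudge two haplotypes (rare)
    for j in range(variant_count):
        c = int(H[:, j].sum())
        if c == 0:
            H[: min(2, hap_count), j] = 1
        elif c == hap_count:
            H[: min(2, hap_count), j] = 0

    positions = position_start + np.cumsum(rng.integers(50, 500, size=variant_count))
    ref_idx = rng.integers(0, 4, size=variant_count)
    alt_idx = (ref_idx + rng.integers(1, 4, size=variant_count)) % 4
    ld = np.corrcoef(H.T) if variant_count > 1 else np.ones((1, 1))
    ld = np.clip((ld + ld.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(ld, 1.0)
    return GenotypePanel(
        allele_matrix=H, maf=maf, positions=positions.astype(np.int64),
        block_bounds=np.array(bounds), chrom=chrom,
        ref=_BASES[ref_idx].astype(object), alt=_BASES[alt_idx].astype(object),
        ld=ld,
    )


def draw_genotypes(panel: GenotypePanel, n_individuals: int,
                   rng: np.random.Generator) -> np.ndarray:
    """Diploid genotypes (n x m, dosage 0/1/2) by random haplotype pairing."""
    picks = rng.integers(0, panel.hap_count, size=(2, n_individuals))
    return (panel.allele_matrix[picks[0]] + panel.allele_matrix[picks[1]]).astype(float)


def simulate_study(panel: GenotypePanel, truth: SimulationTruth,
                   n_individuals: int, study_index: int, seed: int = 0) -> LocusData:
    """Simulate one study's per-variant marginal association scan at the locus.

    The phenotype is ``y = sum_j beta_j g_j + eps`` with each causal variant's
    beta scaled so it contributes its stated variance_explained in-sample and
    eps scaled so total variance is 1.  Marginal simple regressions yield
    (beta, se, z) per variant; the LD matrix is the signed genotype sample
    correlation.
    """
    if n_individuals < 50:
        raise ValueError("n_individuals must be >= 50")
    if study_index not in (1, 2):
        raise ValueError("study_index must be 1 or 2")
    cidx = truth.causal_indices[study_index - 1]
    ve = truth.variance_explained[study_index - 1]
    signs = truth.effect_signs[study_index - 1]
    if cidx.size and cidx.max() >= panel.variant_count:
        raise ValueError("causal index outside the panel")

    rng = np.random.default_rng(seed)
    G = draw_genotypes(panel, n_individuals, rng)
    n, m = G.shape
    y = rng.normal(0.0, np.sqrt(max(1.0 - ve.sum(), 1e-12)), size=n)
    for j, v, s in zip(cidx, ve, signs):
        g = G[:, j]
        sd = g.std()
        if sd == 0:
            continue
        y = y + s * np.sqrt(v) * (g - g.mean()) / sd

    Gc = G - G.mean(axis=0)
    yc = y - y.mean()
    sxx = (Gc**2).sum(axis=0)
    sxx = np.where(sxx == 0, np.nan, sxx)
    beta = (Gc.T @ yc) / sxx
    syy = float(yc @ yc)
    rss = np.maximum(syy - beta**2 * sxx, 1e-12)
    se = np.sqrt(rss / (n - 2) / sxx)
    beta = np.nan_to_num(beta)
    se = np.where(np.isfinite(se) & (se > 0), se, np.nan)

    with np.errstate(invalid="ignore"):
        ld = np.corrcoef(G.T) if m > 1 else np.ones((1, 1))
    ld = np.nan_to_num(ld)
    ld = np.clip((ld + ld.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(ld, 1.0)

    freq = G.mean(axis=0) / 2.0
    df = pd.DataFrame(
        {
            "variant_id": panel.variant_ids,
            "chrom": np.repeat(panel.chrom, m),
            "pos": panel.positions,
            "ref": panel.ref,
            "alt": panel.alt,
            "beta": beta,
            "se": se,
            "n": np.full(m, n),
            "maf": np.minimum(freq, 1 - freq),
        }
    )
    return LocusData.from_frame(df, ld)


@dataclass
class SyntheticAtlas:
    """A synthetic mean-expression atlas with planted cell-type markers."""

    ctd: CellTypeData
    markers: dict  # cell type -> list of planted marker gene IDs


def simulate_atlas(gene_count: int, cell_types, markers_per_type: int,
                   marker_fold: float, baseline_mean: float = 1.0,
                   seed: int = 0, noise_sd: float = 0.2,
                   expression_floor: float = 0.1) -> SyntheticAtlas:
    """Generate a genes x cell-types atlas with planted markers.

    Non-marker genes have equal expected mean expression in every cell type;
    each planted marker's expectation in its home type is
    ``marker_fold * baseline_mean``.  Multiplicative lognormal noise
    (sigma = ``noise_sd``) mimics normalized pseudobulk means.
    """
    cell_types = list(cell_types)
    if markers_per_type * len(cell_types) > gene_count:
        raise ValueError("markers_per_type * number of cell types exceeds gene_count")
    if marker_fold <= 1:
        raise ValueError("marker_fold must be > 1")
    rng = np.random.default_rng(seed)
    genes = [f"G{i:05d}" for i in range(gene_count)]
    expected = np.full((gene_count, len(cell_types)), baseline_mean)
    markers = {}
    g = 0
    for c, ct in enumerate(cell_types):
        markers[ct] = genes[g:g + markers_per_type]
        expected[g:g + markers_per_type, c] = marker_fold * baseline_mean
        g += markers_per_type
    noise = rng.lognormal(mean=0.0, sigma=noise_sd, size=expected.shape)
    mean_expr = pd.DataFrame(expected * noise, index=genes, columns=cell_types)
    ctd = specificity(mean_expr, floor=expression_floor)
    return SyntheticAtlas(ctd=ctd, markers=markers)
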