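"""Multi-causal Bayesian fine-mapping of a locus from summary statistics and LD.

The model follows the standard summary-statistic formulation: for a causal
configuration :math:`\\gamma` (a set of variant indices), the vector of
marginal z-scores is approximately

.. math::

    z \\mid \\gamma \\sim N(0,\\; R' + R'_\\gamma W R'_\\gamma^T)

under the alternative and :math:`z \\sim N(0, R')` under the null, where
:math:`R'` is the signed LD correlation matrix with a small ridge added to
the diagonal, :math:`R'_\\gamma` its columns at the configuration's indices,
and :math:`W` a diagonal prior variance with entries :math:`n_j w_0^2`
(``prior_effect_sd`` :math:`w_0` on the standardized-effect scale).  Because
:math:`R'_\\gamma = R' E_\\gamma`, the Bayes factor of a configuration reduces
by the matrix determinant lemma and Woodbury identity to a closed form in
the :math:`k \\times k` submatrix :math:`R'_{\\gamma\\gamma}` and the z-scores
at the configuration:

.. math::

    \\log BF(\\gamma) = -\\tfrac12 \\log\\det(I_k + R'_{\\gamma\\gamma} W)
                      + \\tfrac12 z_\\gamma^T (W^{-1} + R'_{\\gamma\\gamma})^{-1}
                        z_\\gamma .

For a single variant with no LD this is exactly the Wakefield approximate
Bayes factor.  Configurations up to size two are enumerated exhaustively;
larger configurations are explored by greedy expansion of the top-scoring
smaller configurations.  Per-variant posterior inclusion probabilities
(PIPs) are sums of normalized configuration posteriors, signals are
clustered greedily by LD with near-mutual-exclusivity in configurations,
and each signal yields a 95% credible set — the smallest PIP-descending
prefix whose within-signal normalized PIP mass reaches the coverage level.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import logsumexp

logger = logging.getLogger(__name__)

VARIANT_ID_BUILD = "b38"


class FineMapNumericalError(RuntimeError):
    """Raised when the configuration covariance is singular despite the ridge."""


def make_variant_ids(chrom, pos, ref, alt, build=VARIANT_ID_BUILD):
    """Build variant IDs in the ``chromosome_position_ref_alt_build`` convention."""
    chrom = np.atleast_1d(np.asarray(chrom, dtype=object))
    pos = np.atleast_1d(pos)
    ref = np.atleast_1d(ref)
    alt = np.atleast_1d(alt)
    if chrom.size == 1 and pos.size > 1:
        chrom = np.repeat(chrom, pos.size)
    return np.array(
        [f"{c}_{p}_{r}_{a}_{build}" for c, p, r, a in zip(chrom, pos, ref, alt)],
        dtype=object,
    )


def parse_variant_id(variant_id: str):
    """Split a ``chrom_pos_ref_alt_build`` ID into its components.

    Returns
    -------
    tuple of (chrom: str, pos: int, ref: str, alt: str, build: str)
    """
    parts = variant_id.rsplit("_", 4)
    if len(parts) != 5:
        raise ValueError(f"malformed variant ID: {variant_id!r}")
    chrom, pos, ref, alt, build = parts
    return chrom, int(pos), ref, alt, build


@dataclass
class LocusData:
    """Summary statistics and LD for one locus of one study.

    All arrays are aligned to the same variant order; ``ld`` is the square
    signed correlation matrix in that order.
    """

    variant_ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    beta: np.ndarray
    se: np.ndarray
    n: np.ndarray
    maf: np.ndarray
    ld: np.ndarray
    z: np.ndarray = None

    def __post_init__(self):
        self.variant_ids = np.asarray(self.variant_ids, dtype=object)
        m = len(self.variant_ids)
        for name in ("chrom", "ref", "alt"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=object))
        self.pos = np.asarray(self.pos, dtype=np.int64)
        for name in ("beta", "se", "maf"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.n = np.asarray(self.n, dtype=float)
        if self.z is None:
            self.z = self.beta / self.se
        self.z = np.asarray(self.z, dtype=float)
        self.ld = np.asarray(self.ld, dtype=float)
        for name in ("chrom", "pos", "ref", "alt", "beta", "se", "n", "maf", "z"):
            if len(getattr(self, name)) != m:
                raise ValueError(f"field {name!r} length != number of variants")
        if len(set(self.variant_ids)) != m:
            raise ValueError("variant_ids are not unique")
        if self.ld.shape != (m, m):
            raise ValueError("LD matrix shape does not match variant count")
        if not np.allclose(self.ld, self.ld.T, atol=1e-8):
            raise ValueError("LD matrix is not symmetric")
        if not np.allclose(np.diag(self.ld), 1.0, atol=1e-6):
            raise ValueError("LD matrix diagonal is not 1")
        if np.any(np.abs(self.ld) > 1 + 1e-8):
            raise ValueError("LD entries exceed |1|")

    @property
    def variant_count(self) -> int:
        return len(self.variant_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, ld: np.ndarray) -> "LocusData":
        """Build a locus from a summary-stat table, dropping unusable variants.

        Variants with missing or non-positive standard errors are dropped with
        a logged warning (sparse meta-analysis statistics are tolerated, not
        fatal); the LD matrix is subset to the retained variants.
        """
        se = pd.to_numeric(df["se"], errors="coerce").to_numpy()
        keep = np.isfinite(se) & (se > 0)
        if not keep.all():
            dropped = df["variant_id"].to_numpy()[~keep]
            logger.warning(
                "dropping %d variant(s) with missing/non-positive se: %s",
                len(dropped), ", ".join(map(str, dropped[:5])),
            )
        df = df.loc[keep].reset_index(drop=True)
        ld = np.asarray(ld, dtype=float)[np.ix_(keep, keep)]
        return cls(
            variant_ids=df["variant_id"].to_numpy(),
            chrom=df["chrom"].to_numpy(),
            pos=df["pos"].to_numpy(),
            ref=df["ref"].to_numpy(),
            alt=df["alt"].to_numpy(),
            beta=df["beta"].to_numpy(dtype=float),
            se=df["se"].to_numpy(dtype=float),
            n=df["n"].to_numpy(dtype=float),
            maf=df["maf"].to_numpy(dtype=float),
            ld=ld,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variant_id": self.variant_ids,
                "chrom": self.chrom,
                "pos": self.pos,
                "ref": self.ref,
                "alt": self.alt,
                "beta": self.beta,
                "se": self.se,
                "z": self.z,
                "n": self.n,
                "maf": self.maf,
            }
        )

    def subset(self, indices) -> "LocusData":
        indices = np.asarray(indices)
        return LocusData(
            variant_ids=self.variant_ids[indices],
            chrom=self.chrom[indices],
            pos=self.pos[indices],
            ref=self.ref[indices],
            alt=self.alt[indices],
            beta=self.beta[indices],
            se=self.se[indices],
            n=self.n[indices],
            maf=self.maf[indices],
            ld=self.ld[np.ix_(indices, indices)],
            z=self.z[indices],
        )


@dataclass
class FineMapConfig:
    """Tunable parameters of the fine-mapper.

    ``max_signals`` caps both the configuration size during enumeration and
    the number of signal clusters; ``prior_inclusion`` defaults to 1/m.
    """

    max_signals: int = 5
    prior_inclusion: float | np.ndarray | None = None
    prior_effect_sd: float = 0.2
    ld_ridge: float = 1e-3
    cluster_r2_min: float = 0.25
    coverage: float = 0.95
    cluster_pip_min: float = 0.01
    cooccur_posterior_max: float = 0.01
    beam_size: int = 10_000
    expand_parents: int = 100

    def __post_init__(self):
        if not (0 < self.coverage < 1):
            raise ValueError("coverage must be in (0, 1)")
        if self.max_signals < 1:
            raise ValueError("max_signals must be >= 1")


@dataclass(frozen=True)
class CausalConfig:
    """One enumerated causal configuration with its posterior weight."""

    indices: tuple
    log_bf: float
    log_prior: float
    posterior: float


@dataclass
class SignalCluster:
    """A group of variants carrying one (approximately) independent signal."""

    indices: np.ndarray
    pips: np.ndarray
    seed_index: int

    @property
    def signal_pip_total(self) -> float:
        return float(self.pips.sum())


@dataclass
class CredibleSet:
    """One fine-mapped signal reported at >= the requested coverage.

    ``pip`` holds the raw per-variant PIPs as emitted by fine-mapping
    (unnormalized); ``coverage_achieved`` is on the within-signal
    normalized scale.  Members are sorted by PIP descending, ties broken
    by variant ID.
    """

    cs_id: str
    member_ids: np.ndarray
    pip: np.ndarray
    signal_pip_total: float
    coverage_achieved: float
    lead_id: str

    def pip_map(self) -> dict:
        ids = list(self.member_ids)
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate variant IDs in credible set {self.cs_id}")
        return dict(zip(ids, self.pip))


def config_log_bf(locus: LocusData, indices, prior_effect_sd: float = 0.2,
                  ld_ridge: float = 1e-3) -> float:
    """Log Bayes factor of a causal configuration against the null.

    Parameters
    ----------
    locus : LocusData
    indices : sequence of int
        Distinct variant indices forming the configuration; empty -> 0.
    prior_effect_sd : float
        Prior SD of the standardized effect (W = n * prior_effect_sd**2).
    ld_ridge : float
        Diagonal regularization added to the LD matrix.
    """
    idx = np.asarray(sorted(indices), dtype=int)
    k = idx.size
    if k == 0:
        return 0.0
    if len(set(idx.tolist())) != k:
        raise ValueError("configuration indices must be distinct")
    if idx.min() < 0 or idx.max() >= locus.variant_count:
        raise ValueError("configuration index out of range")
    A = locus.ld[np.ix_(idx, idx)] + ld_ridge * np.eye(k)
    w = locus.n[idx] * prior_effect_sd**2
    zg = locus.z[idx]
    sign, logdet = np.linalg.slogdet(np.eye(k) + A * w[np.newaxis, :])
    if sign <= 0 or not np.isfinite(logdet):
        raise FineMapNumericalError(
            f"singular configuration covariance at indices {idx.tolist()} "
            f"(ridge={ld_ridge}); increase ld_ridge"
        )
    M = np.diag(1.0 / w) + A
    try:
        quad = float(zg @ np.linalg.solve(M, zg))
    except np.linalg.LinAlgError as err:  # pragma: no cover - ridge guards this
        raise FineMapNumericalError(str(err)) from err
    return float(-0.5 * logdet + 0.5 * quad)


def _log_prior_terms(m: int, prior_inclusion):
    p = np.full(m, 1.0 / m) if prior_inclusion is None else np.broadcast_to(
        np.asarray(prior_inclusion, dtype=float), (m,)
    ).copy()
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("prior inclusion probabilities must lie in (0, 1)")
    log_p = np.log(p)
    log_q = np.log1p(-p)
    return log_p, log_q, float(log_q.sum())


def _singleton_log_bfs(locus, ridge, w0):
    a = np.diag(locus.ld) + ridge
    w = locus.n * w0**2
    z = locus.z
    return -0.5 * np.log1p(a * w) + 0.5 * z**2 / (1.0 / w + a)


def _pair_log_bfs(locus, ridge, w0):
    m = locus.variant_count
    ii, jj = np.triu_indices(m, k=1)
    R = locus.ld
    a11 = R[ii, ii] + ridge
    a22 = R[jj, jj] + ridge
    a12 = R[ii, jj]
    w1 = locus.n[ii] * w0**2
    w2 = locus.n[jj] * w0**2
    z1, z2 = locus.z[ii], locus.z[jj]
    det_iaw = (1 + a11 * w1) * (1 + a22 * w2) - a12**2 * w1 * w2
    b11 = 1.0 / w1 + a11
    b22 = 1.0 / w2 + a22
    det_m = b11 * b22 - a12**2
    quad = (z1**2 * b22 - 2 * z1 * z2 * a12 + z2**2 * b11) / det_m
    bad = (det_iaw <= 0) | (det_m <= 0)
    if np.any(bad):
        raise FineMapNumericalError(
            f"{int(bad.sum())} size-2 configurations have a singular covariance "
            f"(ridge={ridge}); increase ld_ridge"
        )
    return ii, jj, -0.5 * np.log(det_iaw) + 0.5 * quad


def _batch_log_bfs(locus, idx_matrix: np.ndarray, ridge: float, w0: float) -> np.ndarray:
    """Log BFs for many equal-size configurations via stacked k x k linalg."""
    idx = np.asarray(idx_matrix, dtype=int)
    N, k = idx.shape
    A = locus.ld[idx[:, :, None], idx[:, None, :]] + ridge * np.eye(k)
    w = locus.n[idx] * w0**2
    z = locus.z[idx]
    sign, logdet = np.linalg.slogdet(np.eye(k) + A * w[:, None, :])
    if np.any(sign <= 0):
        raise FineMapNumericalError(
            f"singular configuration covariance among {int((sign <= 0).sum())} "
            f"size-{k} configurations (ridge={ridge}); increase ld_ridge"
        )
    M = A.copy()
    M[:, np.arange(k), np.arange(k)] += 1.0 / w
    x = np.linalg.solve(M, z[:, :, None])[:, :, 0]
    quad = (z * x).sum(axis=1)
    return -0.5 * logdet + 0.5 * quad


def enumerate_posterior(locus: LocusData, config: FineMapConfig | None = None):
    """Enumerate causal configurations and their normalized posteriors.

    Exhaustive over configurations of size <= 2 (the null included); sizes
    3..max_signals are explored by greedily expanding the top-scoring smaller
    configurations, keeping at most ``beam_size`` configurations overall.

    Returns
    -------
    list of CausalConfig, sorted by posterior descending.
    """
    config = config or FineMapConfig()
    m = locus.variant_count
    if m > 1000:
        raise ValueError("enumeration supports at most 1000 variants per locus")
    log_p, log_q, base = _log_prior_terms(m, config.prior_inclusion)
    delta = log_p - log_q  # per-variant log-prior increment over the null
    ridge, w0 = config.ld_ridge, config.prior_effect_sd

    entries: dict[tuple, float] = {(): 0.0}
    lbf1 = _singleton_log_bfs(locus, ridge, w0)
    for v in range(m):
        entries[(v,)] = float(lbf1[v])
    if config.max_signals >= 2 and m >= 2:
        ii, jj, lbf2 = _pair_log_bfs(locus, ridge, w0)
        for i, j, lb in zip(ii.tolist(), jj.tolist(), lbf2.tolist()):
            entries[(i, j)] = lb

    def score(item):
        idx, lbf = item
        return lbf + delta[list(idx)].sum()

    frontier = [it for it in entries.items() if len(it[0]) == min(2, config.max_signals)]
    for size in range(3, config.max_signals + 1):
        if not frontier:
            break
        frontier.sort(key=score, reverse=True)
        parents = frontier[: config.expand_parents]
        child_set = set()
        for idx, _ in parents:
            present = set(idx)
            for v in range(m):
                if v in present:
                    continue
                child = tuple(sorted(present | {v}))
                if child not in entries:
                    child_set.add(child)
        if not child_set:
            frontier = []
            continue
        child_list = sorted(child_set)
        lbfs = _batch_log_bfs(locus, np.array(child_list), ridge, w0)
        children = dict(zip(child_list, lbfs.tolist()))
        entries.update(children)
        frontier = list(children.items())

    items = list(entries.items())
    if len(items) > config.beam_size:
        items.sort(key=score, reverse=True)
        kept = items[: config.beam_size]
        if () not in dict(kept):
            kept.append(((), 0.0))
        items = kept

    idx_list = [it[0] for it in items]
    scores = np.array([score(it) for it in items]) + base
    posts = np.exp(scores - logsumexp(scores))
    log_priors = np.array([base + delta[list(idx)].sum() for idx in idx_list])
    configs = [
        CausalConfig(indices=idx, log_bf=float(lbf), log_prior=float(lp),
                     posterior=float(po))
        for (idx, lbf), lp, po in zip(items, log_priors, posts)
    ]
    configs.sort(key=lambda c: (-c.posterior, c.indices))
    return configs


def compute_pips(configs, variant_count: int) -> np.ndarray:
    """Per-variant PIPs: sum of posteriors of configurations containing each variant."""
    pips = np.zeros(variant_count)
    for c in configs:
        for v in c.indices:
            pips[v] += c.posterior
    return np.clip(pips, 0.0, 1.0)


def cluster_signals(configs, locus: LocusData, config: FineMapConfig | None = None):
    """Greedily cluster high-PIP variants into independent signals.

    The highest-PIP unassigned variant seeds each cluster; a variant joins if
    its squared LD correlation with the seed reaches ``cluster_r2_min`` and it
    never co-occurs with the seed in any *informative* configuration with
    posterior above ``cooccur_posterior_max``.  A configuration is informative
    about distinctness only when its joint fit beats its best single member
    (log BF above the members' best singleton log BF): redundant proxy pairs
    retain near-singleton Bayes factors and must not split a signal, whereas
    genuinely independent causals fit far better jointly.  Returns an empty
    list when no variant reaches ``cluster_pip_min`` — loci may legitimately
    yield no credible set.
    """
    config = config or FineMapConfig()
    pips = compute_pips(configs, locus.variant_count)
    candidates = [v for v in range(locus.variant_count) if pips[v] >= config.cluster_pip_min]
    # PIP descending, ties by variant ID for order-independence
    candidates.sort(key=lambda v: (-pips[v], str(locus.variant_ids[v])))

    lbf1 = _singleton_log_bfs(locus, config.ld_ridge, config.prior_effect_sd)
    heavy = [
        set(c.indices) for c in configs
        if c.posterior > config.cooccur_posterior_max and len(c.indices) >= 2
        and c.log_bf > max(lbf1[v] for v in c.indices)
    ]
    r2 = locus.ld**2

    clusters = []
    unassigned = list(candidates)
    while unassigned and len(clusters) < config.max_signals:
        seed = unassigned[0]
        members = []
        rest = []
        for v in unassigned:
            if v == seed:
                members.append(v)
                continue
            cooccurs = any(seed in s and v in s for s in heavy)
            if r2[seed, v] >= config.cluster_r2_min and not cooccurs:
                members.append(v)
            else:
                rest.append(v)
        clusters.append(
            SignalCluster(indices=np.array(members, dtype=int),
                          pips=pips[members], seed_index=seed)
        )
        unassigned = rest
    return clusters


def credible_set(cluster: SignalCluster, locus: LocusData, coverage: float = 0.95,
                 locus_id: str = "locus", signal_index: int = 1) -> CredibleSet:
    """Smallest PIP-descending member prefix reaching the coverage level.

    Coverage is computed on within-cluster normalized PIPs; reported ``pip``
    values stay on the raw emitted scale.  Ties in PIP are broken by lexical
    variant ID.
    """
    if cluster.indices.size == 0 or cluster.signal_pip_total <= 0:
        raise ValueError("credible_set requires a non-empty cluster with positive PIP mass")
    ids = locus.variant_ids[cluster.indices]
    order = sorted(range(len(ids)), key=lambda i: (-cluster.pips[i], str(ids[i])))
    pips = cluster.pips[order]
    ids = ids[order]
    frac = np.cumsum(pips) / cluster.signal_pip_total
    k = int(np.searchsorted(frac, coverage - 1e-12) + 1)
    k = min(k, len(ids))
    return CredibleSet(
        cs_id=f"{locus_id}:{signal_index}",
        member_ids=ids[:k],
        pip=pips[:k],
        signal_pip_total=cluster.signal_pip_total,
        coverage_achieved=float(frac[k - 1]),
        lead_id=str(ids[0]),
    )


@dataclass
class FineMapResult:
    """Full fine-mapping output for one locus."""

    locus_id: str
    configs: list
    pips: pd.Series
    credible_sets: list

    def pip_table(self) -> pd.DataFrame:
        return self.pips.rename("pip").rename_axis("variant_id").reset_index()


def finemap_locus(locus: LocusData, config: FineMapConfig | None = None,
                  locus_id: str = "locus") -> FineMapResult:
    """Run the full fine-mapping stage: enumerate, compute PIPs, cluster, report CS."""
    config = config or FineMapConfig()
    configs = enumerate_posterior(locus, config)
    pips = compute_pips(configs, locus.variant_count)
    clusters = cluster_signals(configs, locus, config)
    sets = [
        credible_set(cl, locus, config.coverage, locus_id, i + 1)
        for i, cl in enumerate(clusters)
    ]
    return FineMapResult(
        locus_id=locus_id,
        configs=configs,
        pips=pd.Series(pips, index=list(locus.variant_ids)),
        credible_sets=sets,
    )


def check_allele_alignment(a: LocusData, b: LocusData, flip: bool = False):
    """Flag ref/alt mismatches between two studies sharing variants by position.

    Variants are matched on (chrom, pos).  A variant whose ref/alt in ``b``
    are swapped relative to ``a`` is flagged; with ``flip=True`` a corrected
    copy of ``b`` is returned in which those variants' beta and z signs are
    flipped, alleles swapped, maf complemented and the LD rows/columns
    sign-flipped.

    Returns
    -------
    (b_out, flags) : (LocusData, pandas.DataFrame)
        flags has columns (chrom, pos, status) with status in
        {aligned, swapped, incompatible}.
    """
    key_a = {(c, p): (r, al) for c, p, r, al in zip(a.chrom, a.pos, a.ref, a.alt)}
    records = []
    to_flip = []
    for i, (c, p, r, al) in enumerate(zip(b.chrom, b.pos, b.ref, b.alt)):
        if (c, p) not in key_a:
            continue
        ra, aa = key_a[(c, p)]
        if (r, al) == (ra, aa):
            status = "aligned"
        elif (r, al) == (aa, ra):
            status = "swapped"
            to_flip.append(i)
        else:
            status = "incompatible"
        records.append({"chrom": c, "pos": p, "status": status})
    flags = pd.DataFrame(records, columns=["chrom", "pos", "status"])
    if not flip or not to_flip:
        return b, flags
    idx = np.array(to_flip, dtype=int)
    beta = b.beta.copy()
    z = b.z.copy()
    ld = b.ld.copy()
    ref = b.ref.copy()
    alt = b.alt.copy()
    maf = b.maf.copy()
    beta[idx] *= -1
    z[idx] *= -1
    ld[idx, :] *= -1
    ld[:, idx] *= -1
    ref[idx], alt[idx] = b.alt[idx], b.ref[idx]
    maf[idx] = 1.0 - maf[idx]
    ids = make_variant_ids(b.chrom, b.pos, ref, alt)
    b_out = LocusData(
        variant_ids=ids, chrom=b.chrom, pos=b.pos, ref=ref, alt=alt,
        beta=beta, se=b.se, n=b.n, maf=maf, ld=ld, z=z,
    )
    return b_out, flags
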