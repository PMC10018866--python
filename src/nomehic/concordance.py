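"""Single-molecule footprint concordance at loop anchors.

Each retained read pair comes from one DNA molecule whose two ends fall in
two loop anchors held in spatial proximity.  If chromatin accessibility is
coordinated across the loop, the per-read GCH methylation fractions of the
two ends should correlate across molecules.  The null of "anchors merely
share similar average accessibility" is built by permuting, within each
anchor pair, which end-2 goes with which end-1: every per-anchor mean is
preserved exactly while molecule identity is destroyed.  Observed and
shuffled Pearson correlations are compared with Fisher's (1925) z test for
two independent correlations; a short-range local control uses read pairs
confined to a single anchor.

Correlations are also reported after binarizing fractions at 0.5 (the phi
coefficient) and as the tetrachoric correlation — the latent bivariate
normal correlation implied by the dichotomized 2x2 table — since per-read
methylation fractions are close to binary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize, special, stats

from nomehic import bsreads, contexts
from nomehic.bsreads import AnchorPairSet, LinkedReadPair

DEFAULT_MIN_SITES = 3
DEFAULT_N_SHUFFLES = 100
DEFAULT_LOCAL_MAX_SEP = 1_000
DEFAULT_LOCAL_CAP = 100


class ConcordanceError(ValueError):
    """Degenerate or insufficient input to a concordance statistic."""


Points = np.ndarray  # (n, 2) array of per-read (fraction1, fraction2)


@dataclass
class ConcordanceResult:
    """Observed vs shuffle-null concordance for one pair population."""

    n_pairs: int
    r_observed: float
    phi_observed: Optional[float]
    tetrachoric_observed: Optional[float]
    r_shuffled_mean: float
    r_shuffled_per_rep: List[float]
    z_fisher: float
    p_fisher: float
    n_shuffles: int
    seed: int
    n_degenerate_replicates: int = 0

    def to_dict(self) -> Dict:
        d = self.__dict__.copy()
        d["r_shuffled_per_rep"] = list(map(float, self.r_shuffled_per_rep))
        return d


def pair_fractions(
    grouped_pairs: Dict[str, List[LinkedReadPair]],
    context: str = "GCH",
    min_sites: int = DEFAULT_MIN_SITES,
) -> Dict[str, List[Tuple[float, float]]]:
    """Per-read methylation fractions (end1, end2), grouped by anchor pair.

    A pair qualifies only if both ends carry at least ``min_sites`` calls in
    the requested context (GCH for accessibility, WCG for endogenous
    methylation).
    """
    labels = contexts.expand_labels([context])
    out: Dict[str, List[Tuple[float, float]]] = {}
    for gid, pairs in grouped_pairs.items():
        pts = []
        for p in pairs:
            m1, t1 = p.end1.summarize(labels)
            m2, t2 = p.end2.summarize(labels)
            if t1 >= min_sites and t2 >= min_sites:
                pts.append((m1 / t1, m2 / t2))
        if pts:
            out[gid] = pts
    return out


def _pool(groups: Dict[str, List[Tuple[float, float]]]) -> Points:
    pts = [pt for gid in sorted(groups) for pt in groups[gid]]
    return np.asarray(pts, dtype=float).reshape(-1, 2)


def pearson_r(points: Points) -> float:
    """Product-moment correlation of the two end fractions."""
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(pts) < 3:
        raise ConcordanceError(f"need >= 3 points, got {len(pts)}")
    x, y = pts[:, 0], pts[:, 1]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConcordanceError("zero variance on an axis: correlation undefined")
    return float(np.corrcoef(x, y)[0, 1])


def binarize_and_phi(
    points: Points, cutpoint: float = 0.5
) -> Tuple[float, np.ndarray]:
    """Binarize fractions (>= cutpoint -> 1) and return (phi, 2x2 table).

    The table is [[n11, n10], [n01, n00]]; phi is the Pearson correlation of
    the binarized pairs, equivalently the 2x2 determinant formula
    (n11*n00 - n10*n01) / sqrt of the product of the margins.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(pts) < 3:
        raise ConcordanceError(f"need >= 3 points, got {len(pts)}")
    x = (pts[:, 0] >= cutpoint).astype(int)
    y = (pts[:, 1] >= cutpoint).astype(int)
    n11 = int(np.sum((x == 1) & (y == 1)))
    n10 = int(np.sum((x == 1) & (y == 0)))
    n01 = int(np.sum((x == 0) & (y == 1)))
    n00 = int(np.sum((x == 0) & (y == 0)))
    table = np.array([[n11, n10], [n01, n00]])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConcordanceError("degenerate margin after binarization: phi undefined")
    phi = float(np.corrcoef(x, y)[0, 1])
    return phi, table


def tetrachoric_r(table: np.ndarray, method: str = "ml") -> float:
    """Tetrachoric correlation of a 2x2 table [[n11, n10], [n01, n00]].

    Models the binary margins as a dichotomized bivariate standard normal:
    thresholds are set from the margins, and rho is estimated by maximizing
    the multinomial likelihood of the four cells (``method='ml'``).  Any
    zero cell triggers a +0.5 continuity correction on all cells.
    ``method='cosine'`` uses the closed-form cos-pi approximation
    r = cos(pi / (1 + sqrt(ad/bc))).
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ConcordanceError("table must be 2x2 with nonnegative counts")
    if t.sum() < 1:
        raise ConcordanceError("empty table")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ConcordanceError("all-zero margin: tetrachoric undefined")
    if (t == 0).any():
        t = t + 0.5
    a, b = t[0]
    c, d = t[1]
    n = t.sum()
    if method == "cosine":
        return float(math.cos(math.pi / (1.0 + math.sqrt((a * d) / (b * c)))))
    if method != "ml":
        raise ConcordanceError(f"unknown method {method!r}")
    # thresholds from the margins: P(X=1)=row1, P(Y=1)=col1
    h = special.ndtri(1.0 - (a + b) / n)  # X > h with prob (a+b)/n
    k = special.ndtri(1.0 - (a + c) / n)
    obs = np.array([a, b, c, d])

    def negll(rho: float) -> float:
        p11 = stats.multivariate_normal.cdf(
            [-h, -k], mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]]
        )
        p1x = 1.0 - special.ndtr(h)
        px1 = 1.0 - special.ndtr(k)
        p10 = p1x - p11
        p01 = px1 - p11
        p00 = 1.0 - p1x - px1 + p11
        probs = np.clip([p11, p10, p01, p00], 1e-12, 1.0)
        return -float(np.dot(obs, np.log(probs)))

    res = optimize.minimize_scalar(
        negll, bounds=(-0.9999, 0.9999), method="bounded",
        options={"xatol": 1e-6},
    )
    return float(res.x)


def shuffle_null(
    groups: Dict[str, Sequence[Tuple[float, float]]],
    n_shuffles: int = DEFAULT_N_SHUFFLES,
    seed: int = 0,
) -> List[Points]:
    """Mean-preserving permutation null over molecule linkage.

    Within every anchor-pair group the end-2 fractions are permuted among
    the group's read pairs while end-1 stays fixed; singleton groups pass
    through unchanged.  Both per-anchor marginal means are therefore exact
    invariants of every replicate.  Returns one pooled (n, 2) point set per
    replicate; deterministic under ``seed``.
    """
    rng = np.random.default_rng(seed)
    gids = sorted(groups)
    arrays = {g: np.asarray(groups[g], dtype=float).reshape(-1, 2) for g in gids}
    replicates: List[Points] = []
    for _ in range(n_shuffles):
        pooled = []
        for g in gids:
            pts = arrays[g]
            if len(pts) > 1:
                perm = rng.permutation(len(pts))
                pts = np.column_stack([pts[:, 0], pts[perm, 1]])
            pooled.append(pts)
        replicates.append(np.vstack(pooled))
    return replicates


def fisher_z_compare(r1: float, n1: int, r2: float, n2: int) -> Tuple[float, float]:
    """Fisher's (1925) z test for two independent correlations.

    z = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3)), with a
    two-sided p from the standard normal.
    """
    if abs(r1) >= 1 or abs(r2) >= 1:
        raise ConcordanceError("|r| = 1: Fisher transform infinite")
    if n1 <= 3 or n2 <= 3:
        raise ConcordanceError("need n > 3 in both groups")
    z = (np.arctanh(r1) - np.arctanh(r2)) / math.sqrt(
        1.0 / (n1 - 3) + 1.0 / (n2 - 3)
    )
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def local_control_pairs(
    pairs: Iterable[LinkedReadPair],
    anchors: AnchorPairSet,
    max_separation: int = DEFAULT_LOCAL_MAX_SEP,
    sample_cap: int = DEFAULT_LOCAL_CAP,
    seed: int = 0,
) -> Dict[str, List[LinkedReadPair]]:
    """Short-range control: both ends inside one anchor, <= 1 kb apart.

    Within each anchor at most ``sample_cap`` qualifying pairs are sampled
    uniformly without replacement (seeded), keyed by anchor id.
    """
    rng = np.random.default_rng(seed)
    anchor_df = anchors.anchors()
    by_anchor: Dict[str, List[LinkedReadPair]] = {}
    for p in pairs:
        if p.separation is None or p.separation > max_separation:
            continue
        for _, a in anchor_df.iterrows():
            if (
                p.end1.chromosome == a.chrom
                and p.end1.start >= a.start
                and p.end1.end <= a.end
                and p.end2.start >= a.start
                and p.end2.end <= a.end
                and p.end2.chromosome == a.chrom
            ):
                by_anchor.setdefault(a.anchor_id, []).append(p)
                break
    sampled: Dict[str, List[LinkedReadPair]] = {}
    for aid in sorted(by_anchor):
        plist = by_anchor[aid]
        if len(plist) > sample_cap:
            idx = rng.choice(len(plist), size=sample_cap, replace=False)
            plist = [plist[i] for i in sorted(idx)]
        sampled[aid] = plist
    return sampled


def concordance_from_groups(
    groups: Dict[str, Sequence[Tuple[float, float]]],
    n_shuffles: int = DEFAULT_N_SHUFFLES,
    seed: int = 0,
    null_n_mode: str = "pooled",
) -> ConcordanceResult:
    """Observed r/phi/tetrachoric and shuffle-null comparison on grouped points.

    The Fisher z comparison uses r2 = mean of the per-replicate shuffled
    correlations.  Its effective sample size depends on ``null_n_mode``:
    ``"pooled"`` (default) sets n2 = n_pairs * n_shuffles, reflecting that a
    mean over ~independent replicates carries far less sampling noise than a
    single correlation — this keeps the null z approximately standard
    normal; ``"single"`` sets n2 = n_pairs, treating the null as one
    equally-sized sample, which is conservative.
    """
    pooled = _pool({g: list(v) for g, v in groups.items()})
    if len(pooled) < 3:
        raise ConcordanceError(
            f"insufficient data: {len(pooled)} qualifying pairs (< 3)"
        )
    r_obs = pearson_r(pooled)
    try:
        phi, table = binarize_and_phi(pooled)
        tet = tetrachoric_r(table)
    except ConcordanceError:
        phi, tet = None, None

    reps = shuffle_null(groups, n_shuffles=n_shuffles, seed=seed)
    r_reps: List[float] = []
    n_degenerate = 0
    for rep in reps:
        try:
            r_reps.append(pearson_r(rep))
        except ConcordanceError:
            n_degenerate += 1
    if not r_reps:
        raise ConcordanceError("all shuffle replicates degenerate")
    r_shuf = float(np.mean(r_reps))
    n = len(pooled)
    if null_n_mode == "pooled":
        n2 = n * max(1, len(r_reps))
    elif null_n_mode == "single":
        n2 = n
    else:
        raise ConcordanceError(f"unknown null_n_mode {null_n_mode!r}")
    z, p = fisher_z_compare(r_obs, n, r_shuf, n2)
    return ConcordanceResult(
        n_pairs=n,
        r_observed=r_obs,
        phi_observed=phi,
        tetrachoric_observed=tet,
        r_shuffled_mean=r_shuf,
        r_shuffled_per_rep=r_reps,
        z_fisher=z,
        p_fisher=p,
        n_shuffles=n_shuffles,
        seed=seed,
        n_degenerate_replicates=n_degenerate,
    )


def run_long_range_concordance(
    pairs: Sequence[LinkedReadPair],
    anchors: AnchorPairSet,
    context: str = "GCH",
    min_sites: int = DEFAULT_MIN_SITES,
    n_shuffles: int = DEFAULT_N_SHUFFLES,
    seed: int = 0,
    local_max_separation: int = DEFAULT_LOCAL_MAX_SEP,
    local_sample_cap: int = DEFAULT_LOCAL_CAP,
) -> Tuple[ConcordanceResult, Optional[ConcordanceResult]]:
    """Full long-range concordance analysis plus the local control.

    Long-range: CIS_LONG pairs assigned to anchor pairs, pooled per-read
    fraction points, observed statistics, 100x mean-preserving shuffle, and
    Fisher z of observed vs mean shuffled r (same n in both groups).
    Local control: short-range single-anchor pairs, same statistics; None
    when fewer than 3 qualify.
    """
    grouped = bsreads.assign_pairs_to_anchor_pairs(pairs, anchors)
    points = pair_fractions(grouped, context=context, min_sites=min_sites)
    long_range = concordance_from_groups(points, n_shuffles=n_shuffles, seed=seed)

    local_groups = local_control_pairs(
        pairs, anchors, local_max_separation, local_sample_cap, seed=seed
    )
    local_points = pair_fractions(local_groups, context=context, min_sites=min_sites)
    local_result: Optional[ConcordanceResult] = None
    try:
        local_result = concordance_from_groups(
            local_points, n_shuffles=n_shuffles, seed=seed + 1
        )
    except ConcordanceError:
        local_result = None
    return long_range, local_result
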