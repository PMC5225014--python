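"""Electrophoresis fingerprint processing and community comparison.

Traces are aligned to their internal size standard, baseline-corrected and
area-normalized; peaks (phylotypes) are called and summarized by alpha
diversity (Gini-Simpson, Shannon, richness, Pielou evenness); binarized
profiles are compared with the Jaccard index, tested by ANOSIM permutation,
and clustered agglomeratively.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
from scipy import signal
from scipy.cluster import hierarchy
from scipy.interpolate import PchipInterpolator
from scipy.ndimage import minimum_filter1d, uniform_filter1d
from scipy.spatial.distance import squareform

from .datatypes import AnosimResult, DistanceMatrix, DiversityIndices, FingerprintProfile, PeakSet

__all__ = [
    "preprocess_profile",
    "detect_peaks",
    "alpha_diversity",
    "bin_peaks",
    "binarize_and_jaccard",
    "anosim",
    "cluster_dendrogram",
    "linkage_to_newick",
]


def preprocess_profile(
    raw: FingerprintProfile,
    standard: list[float] | None = None,
    baseline_window_frac: float = 0.05,
) -> FingerprintProfile:
    """Align to the size standard, subtract baseline, normalize total area.

    Positions are remapped through a monotone (PCHIP) interpolation of the
    (observed, nominal) standard anchor pairs, extended linearly beyond the
    outermost anchors. The baseline is a rolling minimum over
    ``baseline_window_frac`` of the trace, smoothed by a moving average,
    subtracted and floored at zero; intensities are then scaled so the
    trapezoidal area is one.
    """
    anchors = raw.standard_peaks
    if standard is not None:
        anchors = [(obs, nom) for obs, nom in anchors if nom in set(standard)]
    if len(anchors) < 2:
        raise ValueError("need at least 2 size-standard peaks for alignment")
    if not np.any(raw.intensities > 0):
        raise ValueError("all-zero trace cannot be preprocessed")
    obs = np.array([a[0] for a in anchors], dtype=float)
    nom = np.array([a[1] for a in anchors], dtype=float)
    order = np.argsort(obs)
    obs, nom = obs[order], nom[order]
    if np.any(np.diff(obs) <= 0) or np.any(np.diff(nom) <= 0):
        raise ValueError("standard anchors must be strictly increasing")
    warp = PchipInterpolator(obs, nom, extrapolate=True)
    positions = np.asarray(warp(raw.positions), dtype=float)
    # PCHIP is monotone inside the anchors; linear extrapolation keeps it so
    intensities = raw.intensities.astype(float)
    window = max(3, int(round(baseline_window_frac * intensities.size)))
    baseline = uniform_filter1d(minimum_filter1d(intensities, size=window), size=window)
    corrected = np.clip(intensities - baseline, 0.0, None)
    area = np.trapezoid(corrected, positions)
    if area <= 0:
        raise ValueError("trace has no area after baseline subtraction")
    return FingerprintProfile(
        sample_id=raw.sample_id,
        positions=positions,
        intensities=corrected / area,
        standard_peaks=[(float(warp(o)), n) for o, n in zip(obs, nom)],
    )


def detect_peaks(profile: FingerprintProfile, min_rel_height: float = 0.05) -> PeakSet:
    """Call peaks as local maxima above ``min_rel_height`` x global maximum.

    Each peak's area is integrated between its flanking valleys (the lowest
    point between neighbouring retained peaks, trace ends outside); areas
    are renormalized to sum to one.
    """
    y = profile.intensities
    x = profile.positions
    if y.size == 0 or not np.any(y > 0):
        raise ValueError("empty profile")
    height = min_rel_height * float(y.max())
    idx, _ = signal.find_peaks(y, height=height if height > 0 else None)
    if idx.size == 0:
        # plateau-shaped or single-sample maxima: fall back to the global max
        idx = np.array([int(np.argmax(y))])
    # valley between consecutive peaks
    bounds = [0]
    for a, b in itertools.pairwise(idx):
        bounds.append(a + int(np.argmin(y[a:b + 1])))
    bounds.append(y.size - 1)
    areas = np.array([
        np.trapezoid(y[bounds[k]:bounds[k + 1] + 1], x[bounds[k]:bounds[k + 1] + 1])
        for k in range(len(idx))
    ])
    total = areas.sum()
    if total <= 0:
        raise ValueError("zero total peak area")
    return PeakSet(
        sample_id=profile.sample_id,
        positions=x[idx],
        areas=areas / total,
        heights=y[idx],
    )


def alpha_diversity(peaks: PeakSet) -> DiversityIndices:
    """Gini-Simpson, Shannon, richness and Pielou evenness from peak areas.

    With relative areas p_i: Simpson = 1 - sum p_i^2 (higher = more
    diverse), Shannon = -sum p_i ln p_i, richness = number of peaks,
    evenness = Shannon / ln(richness), defined as 1 for a single peak.
    """
    p = peaks.areas[peaks.areas > 0]
    if p.size == 0:
        raise ValueError("no peaks")
    p = p / p.sum()
    simpson = 1.0 - float(np.sum(p**2))
    shannon = float(-np.sum(p * np.log(p)))
    richness = int(peaks.n_peaks)
    evenness = 1.0 if richness == 1 else shannon / math.log(richness)
    return DiversityIndices(simpson=simpson, shannon=shannon, richness=richness, evenness=evenness)


def bin_peaks(peaksets: dict[str, PeakSet], match_tol: float = 0.5) -> pd.DataFrame:
    """Cluster peak positions across samples into phylotype bins.

    Single pass over all positions in ascending order: a peak joins the
    current bin while it lies within ``match_tol`` of the bin's first
    member, otherwise it opens a new bin (ties at exactly the tolerance go
    to the earlier bin). Returns a boolean samples x bins presence table.
    """
    events = sorted(
        (pos, sid)
        for sid, ps in peaksets.items()
        for pos in ps.positions
    )
    bins: list[float] = []
    presence: dict[str, set[int]] = {sid: set() for sid in peaksets}
    for pos, sid in events:
        if bins and pos - bins[-1] <= match_tol:
            b = len(bins) - 1
        else:
            bins.append(pos)
            b = len(bins) - 1
        presence[sid].add(b)
    mat = pd.DataFrame(
        False, index=list(peaksets), columns=[f"phy{b:04d}" for b in range(len(bins))]
    )
    for sid, bs in presence.items():
        for b in bs:
            mat.iloc[mat.index.get_loc(sid), b] = True
    return mat


def binarize_and_jaccard(
    peaksets: dict[str, PeakSet], match_tol: float = 0.5
) -> DistanceMatrix:
    """Presence/absence phylotype profiles compared by Jaccard distance.

    d(A, B) = 1 - |A n B| / |A u B|; a pair of two empty profiles is
    undefined and raises.
    """
    if len(peaksets) < 2:
        raise ValueError("need at least 2 samples")
    mat = bin_peaks(peaksets, match_tol=match_tol)
    empties = mat.index[~mat.any(axis=1)]
    if len(empties) >= 2:
        raise ValueError(f"Jaccard undefined for pair of empty profiles: {list(empties)}")
    vals = mat.values
    n = vals.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            inter = np.sum(vals[i] & vals[j])
            union = np.sum(vals[i] | vals[j])
            d[i, j] = d[j, i] = 1.0 - inter / union
    return DistanceMatrix(labels=list(mat.index), values=d)


def _anosim_r(dist: np.ndarray, groups: np.ndarray) -> float:
    """Clarke's R: rank-based contrast of between- vs within-group distances.

    R = (mean between-rank - mean within-rank) / (n(n-1)/4); ranks are
    midranks over the n(n-1)/2 distinct pairs.
    """
    n = dist.shape[0]
    iu = np.triu_indices(n, 1)
    from scipy.stats import rankdata

    ranks = rankdata(dist[iu])
    between = groups[iu[0]] != groups[iu[1]]
    r_b = ranks[between].mean()
    r_w = ranks[~between].mean()
    return float((r_b - r_w) / (n * (n - 1) / 4.0))


def anosim(
    dist: DistanceMatrix,
    groups,
    n_permutations: int = 999,
    seed: int | None = None,
    exact: bool = False,
) -> AnosimResult:
    """ANOSIM permutation test of group separation on a distance matrix.

    The statistic is Clarke's R in [-1, 1] (0 = random grouping, 1 = all
    between-group distances exceed all within-group ones). With sampled
    permutations, p = (1 + #{R_perm >= R_obs}) / (1 + n_permutations);
    with ``exact=True`` every distinct label assignment is enumerated and p
    is the exact upper-tail fraction (including the observed assignment).
    """
    g = pd.Series(list(groups), index=dist.labels) if not isinstance(groups, pd.Series) else groups
    g = g.loc[dist.labels]
    labels, counts = np.unique(g.values, return_counts=True)
    if len(labels) < 2:
        raise ValueError("ANOSIM needs at least 2 groups")
    if np.any(counts < 2):
        small = labels[counts < 2]
        raise ValueError(f"every group needs >= 2 members; too small: {list(small)}")
    gv = g.values
    d = dist.values
    r_obs = _anosim_r(d, gv)
    n = len(gv)
    if exact:
        count = 0
        total = 0
        for perm in _distinct_assignments(gv):
            total += 1
            if _anosim_r(d, perm) >= r_obs - 1e-12:
                count += 1
        return AnosimResult(R=r_obs, p_value=count / total, n_permutations=total)
    rng = np.random.default_rng(seed)
    hits = 0
    perm = gv.copy()
    for _ in range(n_permutations):
        rng.shuffle(perm)
        if _anosim_r(d, perm) >= r_obs - 1e-12:
            hits += 1
    p = (1 + hits) / (1 + n_permutations)
    return AnosimResult(R=r_obs, p_value=p, n_permutations=n_permutations)


def _distinct_assignments(groups: np.ndarray):
    """All distinct relabelings of a fixed group-size multiset."""
    n = len(groups)
    labels, counts = np.unique(groups, return_counts=True)
    # positions of the first label among n choose k, recursively
    def rec(avail: list[int], remaining: list[tuple[str, int]], current: np.ndarray):
        if not remaining:
            yield current.copy()
            return
        lab, k = remaining[0]
        if len(remaining) == 1:
            current[avail] = lab
            yield current.copy()
            return
        for subset in itertools.combinations(avail, k):
            current[list(subset)] = lab
            rest = [i for i in avail if i not in subset]
            yield from rec(rest, remaining[1:], current)

    template = np.empty(n, dtype=object)
    yield from rec(list(range(n)), list(zip(labels, counts)), template)


def cluster_dendrogram(dist: DistanceMatrix, method: str = "average") -> np.ndarray:
    """Agglomerative clustering of samples; returns the scipy linkage matrix.

    Default linkage is UPGMA (average); merge heights are non-decreasing.
    """
    condensed = squareform(dist.values, checks=True)
    return hierarchy.linkage(condensed, method=method)


def linkage_to_newick(link: np.ndarray, labels: list[str]) -> str:
    """Serialize a scipy linkage matrix as a Newick tree string."""
    tree = hierarchy.to_tree(link)

    def rec(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return f"({rec(tree.left, tree.dist)},{rec(tree.right, tree.dist)});"
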