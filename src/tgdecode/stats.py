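"""Group-level inference: cluster-mass permutation tests, the temporal
specificity index, vividness median splits and correlation tests.

The multiple-comparison problem over time (or time x time) is handled
nonparametrically: pointwise t statistics are thresholded at the two-tailed
p < ``cluster_alpha`` quantile, supra-threshold points are grouped into
connected clusters (1-D adjacency; 4-connectivity in 2-D), the t values are
summed within each cluster — separately for positive and negative clusters —
and each observed mass is ranked against the permutation distribution of the
largest cluster mass (by default the maximum over both tails, which controls
the two-tailed family-wise error at the nominal level) over sign-flip or
relabelling permutations. Monte-Carlo p values include the observed
statistic, so p is never 0.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy import stats as sp_stats

__all__ = [
    "ClusterResult",
    "SpecificityCurve",
    "cluster_permutation_vs_chance",
    "cluster_permutation_two_groups",
    "specificity_index",
    "median_split_compare",
    "correlation_test",
    "correlation_cluster_test",
]


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------

@dataclass
class ClusterResult:
    """Clusters of supra-threshold points with summed-t mass and permutation p."""

    clusters: list[np.ndarray]  # each (k, ndim) member indices
    mass: np.ndarray
    sign: list[str]  # "positive" | "negative"
    p_value: np.ndarray
    n_permutations: int
    cluster_alpha: float
    connectivity: str
    shape: tuple
    t_obs: np.ndarray = field(repr=False, default=None)
    alpha: float = 0.05

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def significant(self, alpha: float | None = None) -> list[int]:
        a = self.alpha if alpha is None else alpha
        return [i for i in range(self.n_clusters) if self.p_value[i] < a]

    def mask(self, alpha: float | None = None, sign: str | None = None) -> np.ndarray:
        """Boolean map of points belonging to significant clusters."""
        out = np.zeros(self.shape, dtype=bool)
        for i in self.significant(alpha):
            if sign is not None and self.sign[i] != sign:
                continue
            idx = tuple(self.clusters[i].T)
            out[idx] = True
        return out

    def to_json(self, path: str | Path) -> None:
        payload = {
            "shape": list(self.shape),
            "n_permutations": self.n_permutations,
            "cluster_alpha": self.cluster_alpha,
            "alpha": self.alpha,
            "connectivity": self.connectivity,
            "clusters": [
                {
                    "members": c.tolist(),
                    "mass": float(m),
                    "sign": s,
                    "p_value": float(p),
                }
                for c, m, s, p in zip(self.clusters, self.mass, self.sign, self.p_value)
            ],
        }
        Path(path).write_text(json.dumps(payload, sort_keys=True))

    def summary(self) -> str:
        lines = [
            f"Cluster permutation test  shape={self.shape}  "
            f"n_perm={self.n_permutations}  forming alpha={self.cluster_alpha}",
            f"  {self.n_clusters} cluster(s), {len(self.significant())} significant "
            f"at p < {self.alpha}",
        ]
        order = np.argsort(self.p_value)
        for i in order[:10]:
            lines.append(
                f"  {self.sign[i]:>8}  size={len(self.clusters[i]):4d}  "
                f"mass={self.mass[i]:10.2f}  p={self.p_value[i]:.4f}"
            )
        return "\n".join(lines)


@dataclass
class SpecificityCurve:
    """Per-time proportion of other training times decoding significantly worse."""

    times: np.ndarray
    proportion: np.ndarray  # nan outside the significant diagonal window
    window_mask: np.ndarray
    alpha: float

    def mean(self) -> float:
        """Mean specificity over the significant diagonal window."""
        if not self.window_mask.any():
            return float("nan")
        return float(np.nanmean(self.proportion[self.window_mask]))


# ---------------------------------------------------------------------------
# cluster machinery
# ---------------------------------------------------------------------------

def _label_clusters(t_map: np.ndarray, threshold: float):
    """(indices, mass) pairs for positive and negative supra-threshold clusters."""
    structure = ndimage.generate_binary_structure(t_map.ndim, 1)  # 4-connectivity in 2-D
    out = []
    for sign, mask in (("positive", t_map > threshold), ("negative", t_map < -threshold)):
        labels, n = ndimage.label(mask, structure=structure)
        for lab in range(1, n + 1):
            members = np.argwhere(labels == lab)
            mass = float(t_map[labels == lab].sum())
            out.append((members, mass, sign))
    return out


def _extreme_masses(t_map: np.ndarray, threshold: float) -> tuple[float, float]:
    """Largest positive and most negative cluster mass (0.0 when none)."""
    structure = ndimage.generate_binary_structure(t_map.ndim, 1)
    max_pos = 0.0
    min_neg = 0.0
    labels, n = ndimage.label(t_map > threshold, structure=structure)
    if n:
        max_pos = float(ndimage.sum_labels(t_map, labels, index=np.arange(1, n + 1)).max())
    labels, n = ndimage.label(t_map < -threshold, structure=structure)
    if n:
        min_neg = float(ndimage.sum_labels(t_map, labels, index=np.arange(1, n + 1)).min())
    return max_pos, min_neg


def _one_sample_t(x: np.ndarray) -> np.ndarray:
    """One-sample t over axis 0; 0 where the variance vanishes."""
    n = x.shape[0]
    mean = x.mean(axis=0)
    var = x.var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / np.sqrt(var / n)
    return np.nan_to_num(t, nan=0.0, posinf=0.0, neginf=0.0)


def _mc_p(observed: float, null: np.ndarray, tail: str) -> float:
    if tail == "greater":
        return (1 + int(np.sum(null >= observed))) / (null.size + 1)
    return (1 + int(np.sum(null <= observed))) / (null.size + 1)


def _build_result(t_obs, threshold, null_pos, null_neg, n_perm, cluster_alpha,
                  tail="two", tail_mode="joint") -> ClusterResult:
    clusters, masses, signs, pvals = [], [], [], []
    null_joint = np.maximum(null_pos, -null_neg)
    for members, mass, sign in _label_clusters(t_obs, threshold):
        if tail == "greater" and sign == "negative":
            continue
        clusters.append(members)
        masses.append(mass)
        signs.append(sign)
        if tail == "two" and tail_mode == "joint":
            # max-statistic over both tails: controls the two-tailed FWER
            pvals.append(_mc_p(abs(mass), null_joint, "greater"))
        elif sign == "positive":
            pvals.append(_mc_p(mass, null_pos, "greater"))
        else:
            pvals.append(_mc_p(mass, null_neg, "less"))
    return ClusterResult(
        clusters=clusters,
        mass=np.asarray(masses, dtype=float),
        sign=signs,
        p_value=np.asarray(pvals, dtype=float),
        n_permutations=n_perm,
        cluster_alpha=cluster_alpha,
        connectivity="1-D adjacency" if t_obs.ndim == 1 else "4-connectivity",
        shape=t_obs.shape,
        t_obs=t_obs,
    )


def _check_perm(n_perm: int, n_subjects: int, minimum: int = 2) -> None:
    if n_subjects < minimum:
        raise ValueError(f"need at least {minimum} subjects, got {n_subjects}")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} gives a coarse permutation distribution")


def cluster_permutation_vs_chance(maps, chance: float, n_perm: int = 1000,
                                  cluster_alpha: float = 0.05, seed: int = 0,
                                  tail: str = "two",
                                  tail_mode: str = "joint") -> ClusterResult:
    """One-sample cluster-mass permutation test of subject maps against chance.

    The permutation null is built by random sign-flips of the subject-level
    deviations (map - chance), recording per permutation the largest
    positive and most negative cluster mass. With ``tail_mode="joint"``
    (default) each observed cluster's |mass| is ranked against the
    per-permutation maximum over both tails, which controls the two-tailed
    family-wise error at the nominal level; ``"separate"`` ranks each sign
    against its own tail only (positive and negative clusters each at the
    full alpha).
    """
    maps = np.asarray(maps, dtype=float)
    diffs = maps - chance
    S = diffs.shape[0]
    _check_perm(n_perm, S)
    df = S - 1
    if tail == "two":
        threshold = sp_stats.t.ppf(1 - cluster_alpha / 2, df)
    else:
        threshold = sp_stats.t.ppf(1 - cluster_alpha, df)
    t_obs = _one_sample_t(diffs)

    flat = diffs.reshape(S, -1)
    ssq = np.einsum("sp,sp->p", flat, flat)
    rng = np.random.default_rng(seed)
    signs = rng.integers(0, 2, size=(n_perm, S)) * 2 - 1
    means = signs @ flat / S
    var = np.maximum(ssq[None, :] - S * means**2, 0.0) / (S - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_perm = means / np.sqrt(var / S)
    t_perm = np.nan_to_num(t_perm, nan=0.0, posinf=0.0, neginf=0.0)

    null_pos = np.empty(n_perm)
    null_neg = np.empty(n_perm)
    shape = t_obs.shape
    for i in range(n_perm):
        null_pos[i], null_neg[i] = _extreme_masses(t_perm[i].reshape(shape), threshold)
    return _build_result(t_obs, threshold, null_pos, null_neg, n_perm, cluster_alpha,
                         tail, tail_mode)


def _two_sample_t(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    na, nb = a.shape[0], b.shape[0]
    va = a.var(axis=0, ddof=1)
    vb = b.var(axis=0, ddof=1)
    sp = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (a.mean(axis=0) - b.mean(axis=0)) / np.sqrt(sp * (1 / na + 1 / nb))
    return np.nan_to_num(t, nan=0.0, posinf=0.0, neginf=0.0)


def cluster_permutation_two_groups(maps_a, maps_b, n_perm: int = 1000,
                                   cluster_alpha: float = 0.05, seed: int = 0,
                                   tail_mode: str = "joint") -> ClusterResult:
    """Independent-samples cluster-mass test (group A minus group B).

    Permutations randomly reassign subjects to groups, preserving sizes.
    """
    maps_a = np.asarray(maps_a, dtype=float)
    maps_b = np.asarray(maps_b, dtype=float)
    na, nb = maps_a.shape[0], maps_b.shape[0]
    _check_perm(n_perm, min(na, nb))
    df = na + nb - 2
    threshold = sp_stats.t.ppf(1 - cluster_alpha / 2, df)
    t_obs = _two_sample_t(maps_a, maps_b)

    pooled = np.concatenate([maps_a, maps_b], axis=0)
    rng = np.random.default_rng(seed)
    null_pos = np.empty(n_perm)
    null_neg = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(na + nb)
        t_p = _two_sample_t(pooled[perm[:na]], pooled[perm[na:]])
        null_pos[i], null_neg[i] = _extreme_masses(t_p, threshold)
    return _build_result(t_obs, threshold, null_pos, null_neg, n_perm, cluster_alpha,
                         tail_mode=tail_mode)


# ---------------------------------------------------------------------------
# temporal specificity
# ---------------------------------------------------------------------------

def _paired_lower_cluster(d: np.ndarray, domain: np.ndarray, threshold: float,
                          n_perm: int, rng: np.random.Generator,
                          alpha: float) -> np.ndarray:
    """1-D one-tailed paired cluster test of d > 0 restricted to ``domain``.

    ``d`` is subjects x times (diagonal minus off-diagonal accuracy);
    points outside ``domain`` are forced sub-threshold so adjacency breaks
    at window gaps. Returns the boolean map of significantly positive points.
    """
    S, T = d.shape
    t_obs = _one_sample_t(d)
    t_obs[~domain] = 0.0

    flat = d * domain[None, :]
    ssq = np.einsum("sp,sp->p", flat, flat)
    signs = rng.integers(0, 2, size=(n_perm, S)) * 2 - 1
    means = signs @ flat / S
    var = np.maximum(ssq[None, :] - S * means**2, 0.0) / (S - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_perm = np.nan_to_num(means / np.sqrt(var / S), nan=0.0, posinf=0.0, neginf=0.0)
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i], _ = _extreme_masses(t_perm[i], threshold)

    out = np.zeros(T, dtype=bool)
    for members, mass, sign in _label_clusters(t_obs, threshold):
        if sign != "positive":
            continue
        if _mc_p(mass, null, "greater") < alpha:
            out[members[:, 0]] = True
    return out


def specificity_index(tg_maps, diag_result: ClusterResult, alpha: float = 0.05,
                      n_perm: int = 1000, seed: int = 0,
                      method: str = "cluster", times: np.ndarray | None = None
                      ) -> SpecificityCurve:
    """Proportion of off-diagonal training times decoding significantly worse.

    For each time ``t`` inside the window where diagonal decoding is
    significantly above chance, the accuracies A(t', t) for all other
    training times ``t'`` in the window are compared with the matched-time
    accuracy A(t, t) across subjects (one-tailed, A(t', t) < A(t, t)); the
    curve reports the fraction of ``t'`` that are significantly lower.
    ``method`` selects cluster-corrected (default) or pointwise uncorrected
    comparisons. ``t' = t`` is never counted.
    """
    if hasattr(tg_maps[0], "accuracy"):
        if times is None:
            times = np.asarray(tg_maps[0].train_times)
        A = np.stack([m.accuracy for m in tg_maps])
    else:
        A = np.asarray(tg_maps, dtype=float)
        if times is None:
            times = np.arange(A.shape[1], dtype=float)
    S, T, T2 = A.shape
    if T != T2:
        raise ValueError("specificity needs square generalization matrices")

    window = np.zeros(T, dtype=bool)
    for i in diag_result.significant(alpha):
        if diag_result.sign[i] == "positive":
            window[diag_result.clusters[i][:, 0]] = True
    proportion = np.full(T, np.nan)
    if not window.any():
        warnings.warn("no significant diagonal window; specificity curve is empty")
        return SpecificityCurve(times=times, proportion=proportion,
                                window_mask=window, alpha=alpha)

    n_window = int(window.sum())
    rng = np.random.default_rng(seed)
    threshold = sp_stats.t.ppf(1 - alpha, S - 1)
    diag = A[:, np.arange(T), np.arange(T)]
    for t in np.flatnonzero(window):
        d = diag[:, t][:, None] - A[:, :, t]  # subjects x t'
        domain = window.copy()
        domain[t] = False  # own time never counted; gap breaks adjacency
        if not domain.any():
            proportion[t] = 0.0
            continue
        if method == "cluster":
            sig = _paired_lower_cluster(d, domain, threshold, n_perm, rng, alpha)
        elif method == "pointwise":
            t_stat = _one_sample_t(d)
            sig = (t_stat > threshold) & domain
        else:
            raise ValueError(f"unknown method {method!r}")
        proportion[t] = sig.sum() / n_window
    return SpecificityCurve(times=times, proportion=proportion,
                            window_mask=window, alpha=alpha)


# ---------------------------------------------------------------------------
# vividness analyses
# ---------------------------------------------------------------------------

def median_split_compare(subject_maps, vividness_per_subject, n_perm: int = 1000,
                         cluster_alpha: float = 0.05, seed: int = 0):
    """Median split on subject mean vividness, then a two-group cluster test.

    Returns ``(high_indices, low_indices, ClusterResult)`` where the test
    contrasts high minus low vividness. With an odd number of subjects the
    middle subject joins neither group. Ties straddling the median are
    broken deterministically by subject position (with a warning).
    """
    maps = np.asarray(subject_maps, dtype=float)
    S = maps.shape[0]
    if S < 4:
        raise ValueError("median split needs at least 4 subjects")
    means = np.array([np.mean(v) for v in vividness_per_subject], dtype=float)
    if means.shape[0] != S:
        raise ValueError("one vividness entry per subject required")
    order = np.argsort(means, kind="stable")
    half = S // 2
    low = order[:half]
    if S % 2:
        high = order[half + 1:]
    else:
        high = order[half:]
    boundary = means[order[half - 1]], means[order[half]]
    if boundary[0] == boundary[1]:
        warnings.warn(
            "vividness ties straddle the median; split resolved by subject order"
        )
    result = cluster_permutation_two_groups(
        maps[high], maps[low], n_perm=n_perm, cluster_alpha=cluster_alpha, seed=seed
    )
    return np.sort(high), np.sort(low), result


def correlation_test(x, y, n_perm: int = 1000, seed: int = 0) -> tuple[float, float]:
    """Pearson correlation with a permutation p value (two-tailed).

    The null distribution permutes the subject assignment of ``y``; the
    Monte-Carlo p includes the observed |r|.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 subjects")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in correlation input")
    r_obs = float(np.corrcoef(x, y)[0, 1])
    rng = np.random.default_rng(seed)
    xc = (x - x.mean()) / x.std()
    yc = (y - y.mean()) / y.std()
    count = 0
    for _ in range(n_perm):
        r_p = float(xc @ rng.permutation(yc)) / x.size
        if abs(r_p) >= abs(r_obs) - 1e-12:
            count += 1
    return r_obs, (1 + count) / (n_perm + 1)


def correlation_cluster_test(x, maps, n_perm: int = 1000, cluster_alpha: float = 0.05,
                             seed: int = 0, tail_mode: str = "joint") -> ClusterResult:
    """Cluster-corrected correlation of a subject scalar with subject maps.

    Pointwise correlation t statistics across subjects feed the cluster
    machinery; permutations shuffle the subject assignment of ``x``.
    """
    x = np.asarray(x, dtype=float)
    maps = np.asarray(maps, dtype=float)
    S = x.size
    _check_perm(n_perm, S, minimum=3)
    df = S - 2
    threshold = sp_stats.t.ppf(1 - cluster_alpha / 2, df)

    def corr_t(xv: np.ndarray) -> np.ndarray:
        xc = (xv - xv.mean())
        sx = np.sqrt((xc**2).sum())
        flat = maps.reshape(S, -1)
        mc = flat - flat.mean(axis=0, keepdims=True)
        sy = np.sqrt((mc**2).sum(axis=0))
        with np.errstate(divide="ignore", invalid="ignore"):
            r = (xc @ mc) / (sx * sy)
            r = np.clip(np.nan_to_num(r), -0.999999, 0.999999)
            t = r * np.sqrt(df / (1 - r**2))
        return t.reshape(maps.shape[1:])

    t_obs = corr_t(x)
    rng = np.random.default_rng(seed)
    null_pos = np.empty(n_perm)
    null_neg = np.empty(n_perm)
    for i in range(n_perm):
        t_p = corr_t(rng.permutation(x))
        null_pos[i], null_neg[i] = _extreme_masses(t_p, threshold)
    return _build_result(t_obs, threshold, null_pos, null_neg, n_perm, cluster_alpha,
                         tail_mode=tail_mode)
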