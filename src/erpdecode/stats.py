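"""Group-level inference for decoding time courses.

Decoding accuracy is compared with chance (1/4) at each post-onset time
point with one-sample t-tests (one-tailed: the classifier cannot produce
meaningfully below-chance decoding).  Multiple comparisons over time are
handled by cluster-based permutation: maximal runs of contiguously
significant points form clusters whose summed t scores ("t mass") are
compared with a permutation null of the largest mass.

The vs-chance null relabels the *stored test predictions* instead of
retraining: per permutation and participant, one uniformly drawn
permutation of the class codes is applied to the true labels, identically
at every time point in the epoch.  Holding the relabeling constant across
time respects the temporal autocorrelation of the data, which is exactly
what gives the cluster test its family-wise error control; relabeled
accuracy is re-smoothed with the same 5-point rule before t-testing.

Pairwise condition comparisons (e.g. identity vs expression decoding) use
two-tailed t-tests with a condition-swap null: per permutation, each
participant's pair of (already-smoothed) series is swapped with
probability 1/2 and the largest absolute cluster mass recorded.

Cluster p-values use the counting estimator p = #(null >= observed)/n_perm,
floored at 1/n_perm (with 1000 permutations the resolution is 1e-3, and a
mass above every null mass is reported as "< 0.001").

Also here: the behavioral one-sample/paired t-test and the default-prior
JZS Bayes factor (Cauchy prior with scale r on the standardized effect
size, marginal likelihood by numerical quadrature).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate
from scipy import stats as sps

from .core import ConfigError
from .preprocess import smooth_values

__all__ = ["Cluster", "ClusterSet", "NullDist", "pointwise_t", "form_clusters",
           "accuracy_matrix", "null_vs_chance", "null_condition_swap",
           "cluster_pvalues", "vs_chance_cluster_test",
           "condition_diff_cluster_test", "one_sample_t_test", "jzs_bf01"]

CHANCE = 0.25


@dataclass
class Cluster:
    start_ms: float
    end_ms: float
    start_idx: int
    end_idx: int  # inclusive
    mass: float
    p: float | None = None

    def to_dict(self) -> dict:
        d = {"start_ms": self.start_ms, "end_ms": self.end_ms, "mass": self.mass,
             "p": self.p}
        if self.p is not None:
            d["p_report"] = "<0.001" if self.p <= 1e-3 + 1e-12 else f"{self.p:.3f}"
        return d


@dataclass
class ClusterSet:
    """Maximal contiguous runs of significant time points, ordered by start."""

    clusters: list
    tail: str               # "one" (greater) or "two"
    point_alpha: float
    cluster_alpha: float
    df: int
    threshold: float

    def significant(self):
        return [c for c in self.clusters if c.p is not None and c.p < self.cluster_alpha]


@dataclass
class NullDist:
    """Largest cluster t mass per permutation (0 when a permutation yields
    no cluster); for two-tailed nulls the largest absolute mass."""

    masses: np.ndarray
    tail: str

    def __post_init__(self) -> None:
        self.masses = np.asarray(self.masses, dtype=float)

    @property
    def n_permutations(self) -> int:
        return self.masses.shape[0]


# ---------------------------------------------------------------------------
# point-wise tests and clusters


def pointwise_t(acc: np.ndarray, mu: float = CHANCE):
    """One-sample t per column of a (participants x time) matrix.

    Zero-variance columns give +/-inf with the sign of mean - mu (and 0 when
    the mean equals mu exactly); df = n - 1.
    """
    acc = np.asarray(acc, dtype=float)
    if acc.ndim != 2 or acc.shape[0] < 2:
        raise ConfigError("need a (participants x time) matrix with >= 2 participants")
    n = acc.shape[0]
    d = acc - mu
    m = d.mean(axis=0)
    s = d.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = m / (s / np.sqrt(n))
    # constant columns: detect exactly (ptp == 0) so that round-off in the
    # column mean cannot masquerade as a huge finite t
    zero_var = np.ptp(acc, axis=0) == 0.0
    m0 = acc[0] - mu
    with np.errstate(invalid="ignore"):  # sign 0 * inf -> overwritten below
        t[zero_var] = np.sign(m0[zero_var]) * np.inf
    t[zero_var & (m0 == 0.0)] = 0.0
    return t, n - 1


def _runs(mask: np.ndarray):
    """(start, stop_inclusive) index pairs of maximal True runs."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    stops = np.concatenate([idx[breaks], [idx[-1]]])
    return list(zip(starts, stops))


def _point_threshold(df: int, tail: str, point_alpha: float) -> float:
    if tail == "one":
        return float(sps.t.ppf(1.0 - point_alpha, df))
    if tail == "two":
        return float(sps.t.ppf(1.0 - point_alpha / 2.0, df))
    raise ConfigError(f"tail must be 'one' or 'two', got {tail!r}")


def form_clusters(t_series: np.ndarray, df: int, times: np.ndarray,
                  tail: str = "one", point_alpha: float = 0.05,
                  cluster_alpha: float = 0.05) -> ClusterSet:
    """Threshold the t series point-wise and form maximal contiguous runs.

    One-tailed: positive exceedances only.  Two-tailed: positive and
    negative exceedances form separate clusters; negative clusters carry
    signed (negative) mass.  Single-point clusters are permitted.
    """
    t_series = np.asarray(t_series, dtype=float)
    times = np.asarray(times, dtype=float)
    thr = _point_threshold(df, tail, point_alpha)
    clusters = []
    for sign in (1.0,) if tail == "one" else (1.0, -1.0):
        for a, b in _runs(sign * t_series > thr):
            clusters.append(Cluster(
                start_ms=float(times[a]), end_ms=float(times[b]),
                start_idx=int(a), end_idx=int(b),
                mass=float(t_series[a:b + 1].sum()),
            ))
    clusters.sort(key=lambda c: c.start_idx)
    return ClusterSet(clusters=clusters, tail=tail, point_alpha=point_alpha,
                      cluster_alpha=cluster_alpha, df=df, threshold=thr)


def _max_mass_one_tailed(t_series: np.ndarray, thr: float) -> float:
    mask = t_series > thr
    if not mask.any():
        return 0.0
    return max(t_series[a:b + 1].sum() for a, b in _runs(mask))


def _max_mass_two_tailed(t_series: np.ndarray, thr: float) -> float:
    best = 0.0
    for sign in (1.0, -1.0):
        mask = sign * t_series > thr
        for a, b in _runs(mask):
            best = max(best, abs(t_series[a:b + 1].sum()))
    return best


# ---------------------------------------------------------------------------
# permutation nulls


def accuracy_matrix(stores, smooth_points: int = 5) -> np.ndarray:
    """(participants x time) matrix of smoothed accuracy series recomputed
    from prediction stores."""
    return np.stack([smooth_values(s.accuracy(), smooth_points) for s in stores])


def null_vs_chance(stores, times: np.ndarray, n_perm: int = 1000, seed: int = 0,
                   smooth_points: int = 5, point_alpha: float = 0.05,
                   post_onset_only: bool = True) -> NullDist:
    """Null distribution of the largest cluster t mass under test-label
    relabeling.

    Per permutation: for each participant one uniform permutation of the
    class codes is applied to the stored true labels (the same relabeling at
    every time point); accuracy is recomputed from the stored predictions,
    smoothed, t-tested vs chance (one-tailed) over post-onset points and the
    largest cluster mass recorded (0 if none).
    """
    if n_perm < 1:
        raise ConfigError("n_perm must be >= 1")
    times = np.asarray(times, dtype=float)
    P = len(stores)
    if P < 2:
        raise ConfigError("need stores from >= 2 participants")
    C = stores[0].n_classes
    T = times.shape[0]
    # confusion counts per participant: accuracy under relabeling pi is
    # sum_c counts[c, pi(c), t] / attempts -- no retraining needed.
    counts = [s.counts().astype(np.float64) for s in stores]
    attempts = [s.n_attempts for s in stores]
    mask = times >= 0.0 if post_onset_only else np.ones(T, dtype=bool)
    df = P - 1
    thr = _point_threshold(df, "one", point_alpha)
    rng = np.random.default_rng(seed)
    cls = np.arange(C)

    masses = np.empty(n_perm)
    acc = np.empty((P, T))
    for b in range(n_perm):
        for p in range(P):
            pi = rng.permutation(C)
            acc[p] = counts[p][cls, pi, :].sum(axis=0) / attempts[p]
        # same smoothing arithmetic as the observed series, so the identity
        # relabeling reproduces the observed statistic bit-for-bit
        acc_s = smooth_values(acc, smooth_points)
        t, _ = pointwise_t(acc_s[:, mask], CHANCE)
        masses[b] = _max_mass_one_tailed(t, thr)
    return NullDist(masses=masses, tail="one")


def null_condition_swap(acc_a: np.ndarray, acc_b: np.ndarray, n_perm: int = 1000,
                        seed: int = 0, point_alpha: float = 0.05) -> NullDist:
    """Null distribution of the largest |cluster t mass| under random
    condition swaps of the two (already-smoothed) accuracy matrices."""
    acc_a = np.asarray(acc_a, dtype=float)
    acc_b = np.asarray(acc_b, dtype=float)
    if acc_a.shape != acc_b.shape:
        raise ConfigError("condition matrices must have identical shapes")
    if n_perm < 1:
        raise ConfigError("n_perm must be >= 1")
    P = acc_a.shape[0]
    diff = acc_a - acc_b
    df = P - 1
    thr = _point_threshold(df, "two", point_alpha)
    rng = np.random.default_rng(seed)
    masses = np.empty(n_perm)
    for b in range(n_perm):
        signs = rng.choice([-1.0, 1.0], size=P)
        t, _ = pointwise_t(diff * signs[:, None], 0.0)
        masses[b] = _max_mass_two_tailed(t, thr)
    return NullDist(masses=masses, tail="two")


def cluster_pvalues(clusters: ClusterSet, null: NullDist) -> ClusterSet:
    """p = #(null masses >= observed mass) / n_perm, floored at 1/n_perm.

    Two-tailed cluster sets compare |mass| against the null of largest
    absolute mass.  A cluster is significant when p < cluster_alpha (i.e.
    the observed mass exceeds the null's 1 - alpha quantile).
    """
    if null.n_permutations < 1:
        raise ConfigError("null distribution is empty")
    n = null.n_permutations
    for c in clusters.clusters:
        obs = abs(c.mass) if clusters.tail == "two" else c.mass
        exceed = int((null.masses >= obs).sum())
        c.p = max(exceed, 1) / n
    return clusters


def vs_chance_cluster_test(stores, times: np.ndarray, n_perm: int = 1000,
                           seed: int = 0, smooth_points: int = 5,
                           point_alpha: float = 0.05, cluster_alpha: float = 0.05,
                           post_onset_only: bool = True) -> dict:
    """Full vs-chance inference: observed clusters with permutation p-values.

    Returns a dict with the smoothed accuracy matrix, the observed
    ClusterSet (times restricted to post-onset when requested), and the
    NullDist.
    """
    times = np.asarray(times, dtype=float)
    acc = accuracy_matrix(stores, smooth_points)
    mask = times >= 0.0 if post_onset_only else np.ones_like(times, dtype=bool)
    t, df = pointwise_t(acc[:, mask], CHANCE)
    clusters = form_clusters(t, df, times[mask], tail="one",
                             point_alpha=point_alpha, cluster_alpha=cluster_alpha)
    null = null_vs_chance(stores, times, n_perm=n_perm, seed=seed,
                          smooth_points=smooth_points, point_alpha=point_alpha,
                          post_onset_only=post_onset_only)
    clusters = cluster_pvalues(clusters, null)
    return {"accuracy": acc, "clusters": clusters, "null": null,
            "times": times, "mask": mask}


def condition_diff_cluster_test(acc_a: np.ndarray, acc_b: np.ndarray,
                                times: np.ndarray, n_perm: int = 1000,
                                seed: int = 0, point_alpha: float = 0.05,
                                cluster_alpha: float = 0.05,
                                post_onset_only: bool = True) -> dict:
    """Paired two-tailed comparison of two decoding conditions with the
    condition-swap null.  Positive clusters: A > B."""
    times = np.asarray(times, dtype=float)
    acc_a = np.asarray(acc_a, dtype=float)
    acc_b = np.asarray(acc_b, dtype=float)
    mask = times >= 0.0 if post_onset_only else np.ones_like(times, dtype=bool)
    t, df = pointwise_t((acc_a - acc_b)[:, mask], 0.0)
    clusters = form_clusters(t, df, times[mask], tail="two",
                             point_alpha=point_alpha, cluster_alpha=cluster_alpha)
    null = null_condition_swap(acc_a[:, mask], acc_b[:, mask], n_perm=n_perm,
                               seed=seed, point_alpha=point_alpha)
    clusters = cluster_pvalues(clusters, null)
    return {"clusters": clusters, "null": null, "times": times, "mask": mask}


# ---------------------------------------------------------------------------
# behavioral tests


def one_sample_t_test(x: np.ndarray, mu: float = 0.0, tail: str = "two"):
    """One-sample Student t-test (paired designs reduce to this on the
    differences).  Returns (t, df, p)."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ConfigError("need at least 2 observations")
    n = x.size
    m = x.mean() - mu
    s = x.std(ddof=1)
    if np.ptp(x) == 0.0:  # constant sample: exact comparison with mu
        m0 = x[0] - mu
        t = 0.0 if m0 == 0.0 else np.sign(m0) * np.inf
    else:
        t = m / (s / np.sqrt(n))
    df = n - 1
    if tail == "two":
        p = 2.0 * sps.t.sf(abs(t), df)
    elif tail == "one":
        p = sps.t.sf(t, df)
    else:
        raise ConfigError(f"tail must be 'one' or 'two', got {tail!r}")
    return float(t), df, float(p)


def jzs_bf01(t: float, n: int, r: float = 0.707) -> float:
    """JZS Bayes factor favoring the null for a one-sample t statistic.

    The alternative places a Cauchy(0, r) prior on the standardized effect
    size, equivalent to g ~ InverseGamma(1/2, r^2/2) on the relative prior
    variance; the marginal likelihood is computed by adaptive quadrature:

        BF01 = (1 + t^2/nu)^(-(nu+1)/2)
               / Int_0^inf (1+ng)^(-1/2) (1 + t^2/((1+ng) nu))^(-(nu+1)/2)
                            InvGamma(g; 1/2, r^2/2) dg

    Strictly decreasing in |t| for fixed n.
    """
    if n < 2:
        raise ConfigError("n must be >= 2")
    if r <= 0:
        raise ConfigError("prior scale r must be positive")
    t = float(t)
    nu = n - 1

    def integrand(g):
        return ((1.0 + n * g) ** -0.5
                * (1.0 + t * t / ((1.0 + n * g) * nu)) ** (-(nu + 1) / 2.0)
                * sps.invgamma.pdf(g, 0.5, scale=r * r / 2.0))

    alt, err = integrate.quad(integrand, 0.0, np.inf, limit=200)
    if not np.isfinite(alt) or alt <= 0 or err > 1e-6 * max(alt, 1e-300):
        raise ArithmeticError(
            f"quadrature failed for t={t}, n={n}, r={r}: integral={alt}, abserr={err}")
    null_lik = (1.0 + t * t / nu) ** (-(nu + 1) / 2.0)
    return float(null_lik / alt)
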