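"""Time-on-task trend statistics.

Per-trial EEG measures (instantaneous alpha frequency, alpha power) are
correlated with trial order by Spearman rank correlation at every
(electrode, time bin); group-level one-sample t-maps of the rho values are
corrected for multiple comparisons with a spatio-temporal cluster-based
permutation test whose null flips the sign of whole subjects' rho maps.
The module also provides the two-line test of an inverted-U relationship
between two z-scored variables, and polynomial (degree 1-3) trend fits with
coefficient confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse, stats
from scipy.sparse.csgraph import connected_components

__all__ = [
    "Neighbourhood",
    "Cluster",
    "TrendResult",
    "TwoLineResult",
    "PolyTrendFit",
    "build_neighbourhood",
    "trial_order_rho",
    "cluster_permutation",
    "two_line_test",
    "poly_trend_fit",
    "zscore",
]


def zscore(x: np.ndarray) -> np.ndarray:
    """Z-transform over all (finite) elements of an array."""
    x = np.asarray(x, dtype=float)
    mu = np.nanmean(x)
    sd = np.nanstd(x, ddof=0)
    if sd == 0:
        raise ValueError("cannot z-score a constant array")
    return (x - mu) / sd


# ---------------------------------------------------------------------------
# spatial neighbourhood


@dataclass
class Neighbourhood:
    """Symmetric channel adjacency from a distance cutoff (no self-adjacency)."""

    adjacency: np.ndarray  # (n_channels, n_channels) bool
    cutoff_cm: float

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency, dtype=bool)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if a.diagonal().any():
            raise ValueError("no self-adjacency allowed")
        self.adjacency = a

    @property
    def n_neighbours(self) -> np.ndarray:
        return self.adjacency.sum(axis=1)


def build_neighbourhood(ch_pos: np.ndarray, cutoff_cm: float = 5.0) -> Neighbourhood:
    """Adjacency = Euclidean inter-electrode distance <= cutoff (default 5 cm)."""
    pos = np.asarray(ch_pos, dtype=float)
    if pos.ndim != 2:
        raise ValueError("ch_pos must be (n_channels, n_dims)")
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    adj = (d <= cutoff_cm) & ~np.eye(len(pos), dtype=bool)
    return Neighbourhood(adjacency=adj, cutoff_cm=cutoff_cm)


# ---------------------------------------------------------------------------
# Spearman trend maps


def trial_order_rho(measure: np.ndarray, trial_order: np.ndarray) -> np.ndarray:
    """Spearman rho between trial order and a measure, per remaining axis.

    ``measure`` has trials on the first axis (n_trials, ...); ties receive
    average ranks.  Constant series (rho undefined) are flagged NaN.
    """
    m = np.asarray(measure, dtype=float)
    order = np.asarray(trial_order, dtype=float)
    n = m.shape[0]
    if n < 3:
        raise ValueError("need >= 3 trials for a rank correlation")
    flat = m.reshape(n, -1)
    rm = stats.rankdata(flat, axis=0)
    ro = stats.rankdata(order)
    rm_c = rm - rm.mean(axis=0)
    ro_c = ro - ro.mean()
    denom = np.sqrt(np.sum(rm_c**2, axis=0) * np.sum(ro_c**2))
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (ro_c @ rm_c) / denom
    rho[np.sum(rm_c**2, axis=0) == 0] = np.nan
    return rho.reshape(m.shape[1:])


# ---------------------------------------------------------------------------
# cluster-based permutation test


@dataclass
class Cluster:
    cluster_id: int
    sign: int  # +1 / -1
    mass: float  # summed t-values
    p_value: float
    significant: bool
    members: np.ndarray  # (n_channels, n_times) bool


@dataclass
class TrendResult:
    rho: np.ndarray  # (n_subjects, n_channels, n_times)
    t_map: np.ndarray  # (n_channels, n_times)
    threshold: float
    cluster_labels: np.ndarray  # (n_channels, n_times) int, 0 = none
    clusters: list[Cluster] = field(default_factory=list)
    n_permutations: int = 0

    @property
    def significant_mask(self) -> np.ndarray:
        out = np.zeros(self.t_map.shape, dtype=bool)
        for c in self.clusters:
            if c.significant:
                out |= c.members
        return out


def _t_one_sample(x: np.ndarray) -> np.ndarray:
    """One-sample t against 0 along axis 0 (vectorised)."""
    n = x.shape[0]
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return mean / (sd / np.sqrt(n))


def _prune_mask(mask: np.ndarray, adjacency: np.ndarray) -> np.ndarray:
    """Keep samples with >=1 significant neighbour in space AND in time.

    Channels with no spatial neighbours at all are exempt from the spatial
    requirement (degenerate montages); a single-bin time axis is exempt from
    the temporal one.  Applied once, before connected-component labelling.
    """
    nc, nt = mask.shape
    spat = adjacency @ mask  # significant spatial neighbours per sample
    spat_ok = spat > 0
    no_nb = adjacency.sum(axis=1) == 0
    spat_ok[no_nb, :] = True
    temp_ok = np.zeros_like(mask)
    if nt > 1:
        temp_ok[:, 1:] |= mask[:, :-1]
        temp_ok[:, :-1] |= mask[:, 1:]
    else:
        temp_ok[:] = True
    return mask & spat_ok & temp_ok


def _grid_graph(n_channels: int, n_times: int, adjacency: np.ndarray) -> sparse.csr_matrix:
    """Sparse spatio-temporal adjacency over the flattened (channel, time) grid."""
    rows, cols = [], []
    ci, cj = np.nonzero(adjacency)
    for t in range(n_times):
        rows.append(ci * n_times + t)
        cols.append(cj * n_times + t)
    if n_times > 1:
        base = np.arange(n_channels)[:, None] * n_times + np.arange(n_times - 1)[None, :]
        base = base.ravel()
        rows.append(base)
        cols.append(base + 1)
        rows.append(base + 1)
        cols.append(base)
    r = np.concatenate(rows)
    c = np.concatenate(cols)
    n = n_channels * n_times
    return sparse.csr_matrix((np.ones(len(r), dtype=np.int8), (r, c)), shape=(n, n))


def _cluster_masses(
    t_map: np.ndarray,
    threshold: float,
    adjacency: np.ndarray,
    graph: sparse.csr_matrix,
    return_members: bool = False,
):
    """Signed suprathreshold clusters of a t-map.

    Returns (masses, sign, labels) where masses are summed t per cluster.
    """
    nc, nt = t_map.shape
    labels = np.zeros((nc, nt), dtype=int)
    masses: list[float] = []
    signs: list[int] = []
    members: list[np.ndarray] = []
    next_id = 1
    for sgn in (1, -1):
        mask = _prune_mask(sgn * t_map > threshold, adjacency)
        if not mask.any():
            continue
        keep = np.flatnonzero(mask.ravel())
        sub = graph[keep][:, keep]
        n_comp, lab = connected_components(sub, directed=False)
        for k in range(n_comp):
            nodes = keep[lab == k]
            mass = float(t_map.ravel()[nodes].sum())
            masses.append(mass)
            signs.append(sgn)
            labels.ravel()[nodes] = next_id
            if return_members:
                mem = np.zeros(nc * nt, dtype=bool)
                mem[nodes] = True
                members.append(mem.reshape(nc, nt))
            next_id += 1
    return np.array(masses), np.array(signs), labels, members


def cluster_permutation(
    rho: np.ndarray,
    neighbourhood: Neighbourhood,
    n_perm: int = 2000,
    cluster_alpha: float = 0.05,
    test_alpha: float = 0.05,
    rng: np.random.Generator | int | None = None,
) -> TrendResult:
    """Spatio-temporal cluster-based permutation test of group rho maps.

    ``rho`` is (n_subjects, n_channels, n_times).  Positive and negative
    samples are thresholded separately at a one-sided uncorrected
    ``cluster_alpha`` (t beyond the 1-alpha quantile for each sign) and
    clustered under the combined spatial+temporal adjacency; the cluster
    statistic is the summed t.  Thresholding per tail keeps cluster
    formation frequent enough under the null that the familywise error of
    the two-tailed decision calibrates at its nominal 5% level; with the
    stricter two-tailed sample threshold the null rarely forms clusters at
    all and the test becomes conservative.  The null flips the sign of
    entire subjects' maps; per iteration the most extreme positive and
    negative cluster masses are retained.  A cluster is significant when its
    mass exceeds the 1 - test_alpha/2 quantile of its tail's null (i.e.
    97.5% for the conventional 5% two-tailed level); p-values use the
    (b + 1) / (n_perm + 1) correction.
    """
    rho = np.asarray(rho, dtype=float)
    if rho.ndim != 3:
        raise ValueError("rho must be (n_subjects, n_channels, n_times)")
    n_sub, nc, nt = rho.shape
    if n_sub < 2:
        raise ValueError("group test undefined for a single subject")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if neighbourhood.adjacency.shape[0] != nc:
        raise ValueError("neighbourhood does not match the channel count")
    rng = np.random.default_rng(rng)

    threshold = float(stats.t.ppf(1.0 - cluster_alpha, df=n_sub - 1))
    t_obs = _t_one_sample(rho)
    graph = _grid_graph(nc, nt, neighbourhood.adjacency)
    masses, signs, labels, members = _cluster_masses(
        t_obs, threshold, neighbourhood.adjacency, graph, return_members=True
    )

    # permutation null: per iteration the most extreme cluster mass per tail
    flat = rho.reshape(n_sub, -1)
    ss = np.sum(flat**2, axis=0)
    null_pos = np.zeros(n_perm)
    null_neg = np.zeros(n_perm)
    chunk = max(1, min(n_perm, 512))
    done = 0
    while done < n_perm:
        k = min(chunk, n_perm - done)
        flips = rng.choice([-1.0, 1.0], size=(k, n_sub))
        means = (flips @ flat) / n_sub
        var = (ss[None, :] - n_sub * means**2) / (n_sub - 1)
        with np.errstate(invalid="ignore", divide="ignore"):
            t_perm = means / np.sqrt(var / n_sub)
        for j in range(k):
            m, s, _, _ = _cluster_masses(
                t_perm[j].reshape(nc, nt), threshold, neighbourhood.adjacency, graph
            )
            if len(m):
                pos = m[s > 0]
                neg = m[s < 0]
                if pos.size:
                    null_pos[done + j] = pos.max()
                if neg.size:
                    null_neg[done + j] = neg.min()
        done += k

    clusters = []
    for i, (mass, sgn) in enumerate(zip(masses, signs)):
        if sgn > 0:
            b = int(np.sum(null_pos >= mass))
        else:
            b = int(np.sum(null_neg <= mass))
        p = (b + 1) / (n_perm + 1)
        clusters.append(
            Cluster(
                cluster_id=i + 1,
                sign=int(sgn),
                mass=mass,
                p_value=p,
                significant=bool(p <= test_alpha / 2.0),
                members=members[i],
            )
        )
    return TrendResult(
        rho=rho,
        t_map=t_obs,
        threshold=threshold,
        cluster_labels=labels,
        clusters=clusters,
        n_permutations=n_perm,
    )


# ---------------------------------------------------------------------------
# two-line test of an inverted-U


@dataclass
class TwoLineResult:
    low_slopes: np.ndarray  # per-subject OLS slope for x < 0
    high_slopes: np.ndarray  # per-subject OLS slope for x > 0
    low_t: float
    low_p: float
    high_t: float
    high_p: float
    dof: int
    verdict: str  # inverted-U | monotonic-negative | monotonic-positive | inconclusive


def _ols_slope(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    return float(np.dot(xc, y - y.mean()) / np.dot(xc, xc))


def two_line_test(
    x_by_subject: list[np.ndarray],
    y_by_subject: list[np.ndarray],
    alpha: float = 0.05,
) -> TwoLineResult:
    """Two-line test: separate regressions of y on x for x < 0 and x > 0.

    x and y are z-scored within subject, so the split point is fixed at 0.
    An inverted-U verdict requires a significantly positive low-segment and
    significantly negative high-segment group slope; same-signed significant
    slopes yield a monotonic verdict; anything else is inconclusive.
    """
    lows, highs = [], []
    for x, y in zip(x_by_subject, y_by_subject):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        lo = x < 0
        hi = x > 0
        if lo.sum() < 2 or hi.sum() < 2:
            raise ValueError("a subject has no samples on one side of 0")
        lows.append(_ols_slope(x[lo], y[lo]))
        highs.append(_ols_slope(x[hi], y[hi]))
    lows = np.array(lows)
    highs = np.array(highs)
    lt, lp = stats.ttest_1samp(lows, 0.0)
    ht, hp = stats.ttest_1samp(highs, 0.0)
    low_sig = lp < alpha
    high_sig = hp < alpha
    if low_sig and high_sig and lt > 0 and ht < 0:
        verdict = "inverted-U"
    elif low_sig and high_sig and lt < 0 and ht < 0:
        verdict = "monotonic-negative"
    elif low_sig and high_sig and lt > 0 and ht > 0:
        verdict = "monotonic-positive"
    else:
        verdict = "inconclusive"
    return TwoLineResult(
        low_slopes=lows,
        high_slopes=highs,
        low_t=float(lt),
        low_p=float(lp),
        high_t=float(ht),
        high_p=float(hp),
        dof=len(lows) - 1,
        verdict=verdict,
    )


# ---------------------------------------------------------------------------
# polynomial trend fits


@dataclass
class PolyTrendFit:
    degrees: list[int]
    coefficients: list[np.ndarray]  # ascending powers, per degree
    conf_ints: list[np.ndarray]  # (n_coef, 2) 95% CI, per degree
    adj_r2: list[float]
    supported: list[bool]  # highest coefficient's CI excludes 0


def poly_trend_fit(
    values: np.ndarray,
    trial_numbers: np.ndarray,
    max_degree: int = 3,
) -> PolyTrendFit:
    """Least-squares polynomial fits of degree 1..max_degree with 95% CIs.

    A degree is "supported" iff the confidence interval of its
    highest-order coefficient excludes zero.  The predictor is centred and
    scaled before fitting (for conditioning); coefficients are reported on
    that standardised scale, which leaves support decisions and adjusted R²
    unchanged.
    """
    import statsmodels.api as sm

    y = np.asarray(values, dtype=float)
    x = np.asarray(trial_numbers, dtype=float)
    if y.shape != x.shape:
        raise ValueError("values and trial_numbers must match")
    if len(y) < max_degree + 2:
        raise ValueError("too few points for the requested degree")
    xs = (x - x.mean()) / x.std()
    degrees, coefs, cis, r2s, supported = [], [], [], [], []
    for deg in range(1, max_degree + 1):
        X = np.vander(xs, deg + 1, increasing=True)
        fit = sm.OLS(y, X).fit()
        ci = np.asarray(fit.conf_int(alpha=0.05))
        degrees.append(deg)
        coefs.append(np.asarray(fit.params))
        cis.append(ci)
        r2s.append(float(fit.rsquared_adj))
        lo, hi = ci[-1]
        # CI excluding 0 only counts if the coefficient is numerically nonzero
        # (a perfect lower-order fit leaves ~1e-16 coefficients with ~1e-16 CIs)
        tiny = 1e-10 * max(1.0, float(np.abs(y).max()))
        supported.append(bool((lo > 0 or hi < 0) and abs(fit.params[-1]) > tiny))
    return PolyTrendFit(
        degrees=degrees,
        coefficients=coefs,
        conf_ints=cis,
        adj_r2=r2s,
        supported=supported,
    )
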