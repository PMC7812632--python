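"""Permutation statistics for connectivity and PSD maps.

Two families of tests:

* :func:`perm_ttest_fdr` — per-cell one-sample t statistics against zero
  with sign-flip permutation p-values and Benjamini–Hochberg false
  discovery rate control (the "statsCond" style test on within-dyad
  condition differences).
* :func:`statscluster` — non-parametric cluster-based permutation test:
  cells exceeding a cluster-forming threshold are grouped into connected
  components under a space (and optionally space-frequency) adjacency
  structure; cluster mass is compared with the permutation null of the
  maximum cluster mass, controlling the familywise error rate.

:func:`con_matrix` builds the a-priori channel neighborhood from sensor
positions (Delaunay triangulation of the 2-D-projected montage) and its
expansion across adjacent frequency bins.  :func:`permute_dyads` provides
the dyad-level null schemes (time shuffling and "fake pairs").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sp_stats
from scipy.spatial import Delaunay, QhullError
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Adjacency
# ---------------------------------------------------------------------------


@dataclass
class AdjacencyStructure:
    """Boolean channel neighborhood, optionally expanded across frequency bins.

    ``ch_con`` is the N x N symmetric channel graph with a false diagonal.
    ``ch_con_freq`` indexes space-frequency cells channel-major (cell of
    channel c at bin k has index ``c * F + k``): two cells are adjacent iff
    they are spatial neighbors at the same bin, or the same channel at
    adjacent bins.
    """

    ch_con: np.ndarray
    ch_con_freq: np.ndarray
    freqs: np.ndarray
    method: str = "delaunay"
    params: dict = field(default_factory=dict)


def _project_azimuthal(positions: np.ndarray) -> np.ndarray:
    """Azimuthal equidistant projection of 3-D head positions to 2-D.

    The polar angle from the +z axis becomes the radius; points on the
    z-axis project to the origin.
    """
    p = np.asarray(positions, dtype=float)
    r = np.linalg.norm(p, axis=1)
    r = np.where(r < 1e-12, 1.0, r)
    theta = np.arccos(np.clip(p[:, 2] / r, -1, 1))
    rho = np.hypot(p[:, 0], p[:, 1])
    with np.errstate(invalid="ignore"):
        ux = np.where(rho > 1e-12, p[:, 0] / rho, 0.0)
        uy = np.where(rho > 1e-12, p[:, 1] / rho, 0.0)
    return np.column_stack([theta * ux, theta * uy])


def con_matrix(
    positions: np.ndarray,
    freqs: np.ndarray | list[float] | None = None,
    method: str = "delaunay",
    dist_threshold: float | None = None,
) -> AdjacencyStructure:
    """A-priori channel adjacency from sensor positions.

    ``method='delaunay'`` triangulates the 2-D azimuthal projection of the
    montage and connects channels sharing a triangle edge;
    ``method='distance'`` connects channels closer than ``dist_threshold``
    (meters, 3-D).  ``freqs`` expands the graph across adjacent frequency
    bins per the space-frequency rule.
    """
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    if n < 3:
        raise ValueError(f"need at least 3 positioned channels, got {n}")
    ch_con = np.zeros((n, n), dtype=bool)
    if method == "delaunay":
        pts2d = _project_azimuthal(positions)
        try:
            tri = Delaunay(pts2d)
        except QhullError as err:
            raise ValueError(f"degenerate sensor geometry: {err}") from err
        for simplex in tri.simplices:
            for i in range(3):
                a, b = simplex[i], simplex[(i + 1) % 3]
                ch_con[a, b] = ch_con[b, a] = True
    elif method == "distance":
        if dist_threshold is None:
            raise ValueError("distance method requires dist_threshold")
        d = np.linalg.norm(positions[:, None] - positions[None, :], axis=-1)
        ch_con = d < dist_threshold
        np.fill_diagonal(ch_con, False)
    else:
        raise ValueError(f"unknown adjacency method {method!r}")

    freqs = np.atleast_1d(np.asarray([] if freqs is None else freqs, dtype=float))
    n_f = max(len(freqs), 1)
    freq_adj = np.zeros((n_f, n_f), dtype=bool)
    idx = np.arange(n_f - 1)
    freq_adj[idx, idx + 1] = freq_adj[idx + 1, idx] = True
    ch_con_freq = np.kron(ch_con, np.eye(n_f, dtype=bool)) | np.kron(
        np.eye(n, dtype=bool), freq_adj
    )
    return AdjacencyStructure(
        ch_con=ch_con,
        ch_con_freq=ch_con_freq,
        freqs=freqs,
        method=method,
        params={"dist_threshold": dist_threshold},
    )


def interbrain_adjacency(ch_con: np.ndarray) -> np.ndarray:
    """Adjacency between inter-brain cells (i, j) of an N x N inter block.

    Two inter-brain links are neighbors when their ends are neighbors (or
    identical) on each respective head: cells (i, j) and (k, l) are
    adjacent iff (ch_con[i,k] or i==k) and (ch_con[j,l] or j==l), excluding
    the identical cell.
    """
    ch_con = np.asarray(ch_con, dtype=bool)
    n = len(ch_con)
    end1 = ch_con | np.eye(n, dtype=bool)
    adj = np.kron(end1, end1)
    np.fill_diagonal(adj, False)
    return adj


# ---------------------------------------------------------------------------
# One-sample permutation t-test with FDR
# ---------------------------------------------------------------------------


@dataclass
class FdrTestResult:
    """Per-cell t statistics, sign-flip permutation p-values, FDR mask."""

    T_obs: np.ndarray
    p_values: np.ndarray
    significant: np.ndarray
    T_obs_plot: np.ndarray
    alpha: float
    n_permutations: int
    exact: bool


def perm_ttest_fdr(
    data: np.ndarray,
    n_permutations: int = 5000,
    alpha: float = 0.05,
    tail: int = 0,
    seed: int | None = None,
) -> FdrTestResult:
    """One-sample t-test against 0 per cell, sign-flip permutations, BH-FDR.

    ``data`` is (n_subjects, ...cells): per-subject condition differences.
    When ``2**n_subjects <= n_permutations`` the sign-flip distribution is
    enumerated exactly; otherwise ``n_permutations`` random flips are drawn.
    Cells with zero variance are flagged undefined (NaN) and excluded from
    the FDR family.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim < 2:
        raise ValueError("data must be (n_subjects, ...cells)")
    n_subj = data.shape[0]
    if n_subj < 2:
        raise ValueError(f"need at least 2 subjects, got {n_subj}")
    if n_permutations < 100:
        raise ValueError("n_permutations must be >= 100")
    cell_shape = data.shape[1:]
    d = data.reshape(n_subj, -1)
    n_cells = d.shape[1]

    sd = d.std(axis=0, ddof=1)
    defined = sd > 0
    t_obs = np.full(n_cells, np.nan)
    t_obs[defined] = d.mean(axis=0)[defined] / (sd[defined] / np.sqrt(n_subj))

    exact = 2**n_subj <= n_permutations
    if exact:
        signs = np.array(
            [[1 if (m >> b) & 1 else -1 for b in range(n_subj)] for m in range(2**n_subj)],
            dtype=float,
        )
    else:
        rng = np.random.default_rng(seed)
        signs = rng.choice([-1.0, 1.0], size=(n_permutations, n_subj))
    m_perm = signs @ d / n_subj  # (n_perm, n_cells)
    ss = np.sum(d**2, axis=0)  # invariant under sign flips
    var_perm = (ss - n_subj * m_perm**2) / (n_subj - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_perm = m_perm / np.sqrt(var_perm / n_subj)

    p = np.full(n_cells, np.nan)
    if tail == 0:
        cmp = np.abs(t_perm) >= np.abs(t_obs)[None, :] - 1e-12
    elif tail == 1:
        cmp = t_perm >= t_obs[None, :] - 1e-12
    elif tail == -1:
        cmp = t_perm <= t_obs[None, :] + 1e-12
    else:
        raise ValueError(f"tail must be -1, 0 or 1, got {tail}")
    counts = np.nansum(cmp[:, defined], axis=0)
    n_eff = len(signs)
    if exact:
        p[defined] = counts / n_eff
    else:
        p[defined] = (1.0 + counts) / (1.0 + n_eff)

    significant = np.zeros(n_cells, dtype=bool)
    if defined.any():
        rej, _, _, _ = multipletests(p[defined], alpha=alpha, method="fdr_bh")
        significant[np.nonzero(defined)[0]] = rej
    t_plot = np.where(significant, np.nan_to_num(t_obs), 0.0)
    return FdrTestResult(
        T_obs=t_obs.reshape(cell_shape),
        p_values=p.reshape(cell_shape),
        significant=significant.reshape(cell_shape),
        T_obs_plot=t_plot.reshape(cell_shape),
        alpha=alpha,
        n_permutations=n_eff,
        exact=exact,
    )


# ---------------------------------------------------------------------------
# Cluster-based permutation test
# ---------------------------------------------------------------------------


@dataclass
class ClusterStatsResult:
    """Observed statistic map, clusters, masses and permutation p-values."""

    T_obs: np.ndarray
    clusters: list[np.ndarray]
    cluster_masses: np.ndarray
    cluster_p_values: np.ndarray
    significant_mask: np.ndarray
    threshold: float
    n_permutations: int
    test: str
    tail: int
    alpha: float


def _neighbor_lists(adjacency: np.ndarray | None, n_cells: int) -> list[np.ndarray] | None:
    if adjacency is None:
        return None
    adjacency = np.asarray(adjacency)
    if adjacency.shape != (n_cells, n_cells):
        raise ValueError(
            f"adjacency shape {adjacency.shape} does not match {n_cells} cells"
        )
    return [np.nonzero(adjacency[i])[0] for i in range(n_cells)]


def _clusters_from_mask(mask: np.ndarray, neighbors: list[np.ndarray] | None):
    """Connected components of suprathreshold cells (BFS on neighbor lists).

    Without adjacency every suprathreshold cell is its own cluster.
    """
    idx = np.nonzero(mask)[0]
    if neighbors is None:
        return [np.array([i]) for i in idx]
    seen = np.zeros(len(mask), dtype=bool)
    comps = []
    for start in idx:
        if seen[start]:
            continue
        stack = [start]
        seen[start] = True
        comp = []
        while stack:
            c = stack.pop()
            comp.append(c)
            for nb in neighbors[c]:
                if mask[nb] and not seen[nb]:
                    seen[nb] = True
                    stack.append(nb)
        comps.append(np.array(sorted(comp)))
    return comps


def _signed_clusters(stat: np.ndarray, threshold: float, tail: int, neighbors):
    """Clusters and masses; two-tailed splits positive and negative cells."""
    comps, masses = [], []
    sides = []
    if tail >= 0:
        sides.append(stat > threshold)
    if tail <= 0:
        sides.append(stat < -threshold)
    for mask in sides:
        for comp in _clusters_from_mask(mask, neighbors):
            comps.append(comp)
            masses.append(float(stat[comp].sum()))
    return comps, np.array(masses)


def _max_cluster_mass(stat: np.ndarray, threshold: float, tail: int, neighbors) -> float:
    _, masses = _signed_clusters(stat, threshold, tail, neighbors)
    return float(np.max(np.abs(masses))) if len(masses) else 0.0


def _ind_t_maps(d_all: np.ndarray, assign: np.ndarray, n1: int, n2: int) -> np.ndarray:
    """Pooled-variance two-sample t maps for many group-1 assignments.

    ``assign`` is (n_perm, n_total) boolean membership of group 1.
    """
    a = assign.astype(float)
    s1 = a @ d_all
    q1 = a @ d_all**2
    st = d_all.sum(axis=0)
    qt = (d_all**2).sum(axis=0)
    m1 = s1 / n1
    m2 = (st - s1) / n2
    ssq1 = q1 - n1 * m1**2
    ssq2 = (qt - q1) - n2 * m2**2
    sp2 = (ssq1 + ssq2) / (n1 + n2 - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    return np.nan_to_num(t)


def statscluster(
    groups: list[np.ndarray],
    test: str = "ind_ttest",
    adjacency: AdjacencyStructure | np.ndarray | None = None,
    tail: int = 0,
    n_permutations: int = 5000,
    alpha: float = 0.05,
    threshold: float | None = None,
    factor_level=None,
    seed: int | None = None,
) -> ClusterStatsResult:
    """Cluster-based permutation test between groups of per-subject maps.

    ``groups`` is a list of arrays (n_subjects_g, ...cells).  Cells whose
    statistic exceeds the cluster-forming threshold (by default the
    parametric critical value at ``alpha``) are grouped into connected
    components under ``adjacency``; cluster mass is the sum of statistics,
    and the null distribution is the maximum absolute cluster mass over
    label permutations (sign flips for the paired test).  Cluster p-values
    use the (1 + exceedances) / (1 + n_permutations) convention.
    """
    if factor_level is not None or test == "f_multipleway":
        raise NotImplementedError(
            "multiple-way ANOVA clustering is not implemented; use "
            "ind_ttest, rel_ttest or f_oneway"
        )
    if test not in ("ind_ttest", "rel_ttest", "f_oneway"):
        raise ValueError(f"test must be ind_ttest, rel_ttest or f_oneway, got {test!r}")
    if test in ("ind_ttest", "rel_ttest") and len(groups) != 2:
        raise ValueError(f"{test} requires exactly 2 groups, got {len(groups)}")
    groups = [np.asarray(g, dtype=float) for g in groups]
    cell_shape = groups[0].shape[1:]
    gs = [g.reshape(g.shape[0], -1) for g in groups]
    n_cells = gs[0].shape[1]
    if any(g.shape[1] != n_cells for g in gs):
        raise ValueError("inconsistent cell counts across groups")
    rng = np.random.default_rng(seed)

    if isinstance(adjacency, AdjacencyStructure):
        adj = adjacency.ch_con_freq if len(adjacency.ch_con_freq) == n_cells else adjacency.ch_con
    else:
        adj = adjacency
    neighbors = _neighbor_lists(adj, n_cells)

    is_f = test == "f_oneway"
    if is_f and tail != 1:
        tail = 1  # F statistics are one-sided by construction

    # observed statistic and permutation stat maps
    if test == "ind_ttest":
        n1, n2 = gs[0].shape[0], gs[1].shape[0]
        d_all = np.vstack(gs)
        n_tot = n1 + n2
        if threshold is None:
            threshold = float(sp_stats.t.ppf(1 - alpha / (2 if tail == 0 else 1), n_tot - 2))
        obs_assign = np.zeros((1, n_tot), dtype=bool)
        obs_assign[0, :n1] = True
        t_obs = _ind_t_maps(d_all, obs_assign, n1, n2)[0]
        assign = np.zeros((n_permutations, n_tot), dtype=bool)
        for i in range(n_permutations):
            assign[i, rng.permutation(n_tot)[:n1]] = True
        stat_perm = _ind_t_maps(d_all, assign, n1, n2)
    elif test == "rel_ttest":
        if gs[0].shape[0] != gs[1].shape[0]:
            raise ValueError("rel_ttest requires equal group sizes")
        d = gs[0] - gs[1]
        n = d.shape[0]
        if threshold is None:
            threshold = float(sp_stats.t.ppf(1 - alpha / (2 if tail == 0 else 1), n - 1))
        ss = np.sum(d**2, axis=0)
        signs = rng.choice([-1.0, 1.0], size=(n_permutations, n))
        m_perm = signs @ d / n
        var_perm = (ss - n * m_perm**2) / (n - 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            stat_perm = np.nan_to_num(m_perm / np.sqrt(var_perm / n))
        sd = d.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t_obs = np.nan_to_num(d.mean(axis=0) / (sd / np.sqrt(n)))
    else:  # f_oneway
        k = len(gs)
        sizes = [g.shape[0] for g in gs]
        n_tot = sum(sizes)
        if threshold is None:
            threshold = float(sp_stats.f.ppf(1 - alpha, k - 1, n_tot - k))
        d_all = np.vstack(gs)
        bounds = np.cumsum([0] + sizes)

        def f_map(dat: np.ndarray) -> np.ndarray:
            grand = dat.mean(axis=0)
            between = np.zeros(n_cells)
            within = np.zeros(n_cells)
            for gi in range(k):
                block = dat[bounds[gi] : bounds[gi + 1]]
                mg = block.mean(axis=0)
                between += sizes[gi] * (mg - grand) ** 2
                within += ((block - mg) ** 2).sum(axis=0)
            with np.errstate(divide="ignore", invalid="ignore"):
                f = (between / (k - 1)) / (within / (n_tot - k))
            return np.nan_to_num(f)

        t_obs = f_map(d_all)
        stat_perm = np.empty((n_permutations, n_cells))
        for i in range(n_permutations):
            stat_perm[i] = f_map(d_all[rng.permutation(n_tot)])

    comps, masses = _signed_clusters(t_obs, threshold, tail, neighbors)
    null_max = np.array(
        [_max_cluster_mass(stat_perm[i], threshold, tail, neighbors) for i in range(len(stat_perm))]
    )
    p_vals = np.array(
        [(1.0 + np.sum(null_max >= abs(m) - 1e-12)) / (1.0 + len(stat_perm)) for m in masses]
    )
    sig = np.zeros(n_cells, dtype=bool)
    for comp, p in zip(comps, p_vals):
        if p <= alpha:
            sig[comp] = True
    return ClusterStatsResult(
        T_obs=t_obs.reshape(cell_shape),
        clusters=comps,
        cluster_masses=masses,
        cluster_p_values=p_vals,
        significant_mask=sig.reshape(cell_shape),
        threshold=float(threshold),
        n_permutations=n_permutations,
        test=test,
        tail=tail,
        alpha=alpha,
    )


# ---------------------------------------------------------------------------
# Dyad-level permutation null schemes
# ---------------------------------------------------------------------------

SCHEMES = ("shuffle_time", "fake_pairs_within", "fake_pairs_between")


def _derangement(n: int, rng: np.random.Generator, max_tries: int = 10_000) -> np.ndarray:
    for _ in range(max_tries):
        perm = rng.permutation(n)
        if not np.any(perm == np.arange(n)):
            return perm
    raise RuntimeError("could not draw a derangement")  # pragma: no cover


def permute_dyads(
    dyads: list[tuple[str, str]],
    scheme: str,
    seed: int | None = None,
    groups: list | None = None,
    n_epochs: int | None = None,
    time_mode: str = "epochs",
    n_samples: int | None = None,
):
    """Surrogate pairings or epoch re-orderings for dyad-level nulls.

    ``dyads`` is the list of true pairs (participant A id, participant B
    id); ``groups`` optionally labels each dyad's condition/group.

    * ``shuffle_time``: independent epoch-index permutation per participant
      (requires ``n_epochs``); destroys inter-brain temporal coupling while
      keeping each participant's signal statistics.  With
      ``time_mode='circular'`` it instead returns one random circular
      sample shift per participant (requires ``n_samples``), preserving
      within-epoch autocorrelation exactly.
    * ``fake_pairs_within``: re-pairs A and B members inside each group by
      a derangement, so no surrogate pair equals a true pair (groups of a
      single dyad are infeasible).
    * ``fake_pairs_between``: pairs A members of one group with B members
      of the other (requires exactly two groups).
    """
    if scheme not in SCHEMES:
        raise ValueError(f"scheme must be one of {SCHEMES}, got {scheme!r}")
    rng = np.random.default_rng(seed)
    if groups is None:
        groups = [0] * len(dyads)
    if len(groups) != len(dyads):
        raise ValueError("groups must label every dyad")

    if scheme == "shuffle_time":
        if time_mode == "circular":
            if n_samples is None:
                raise ValueError("circular time_mode requires n_samples")
            return {
                p: int(rng.integers(1, n_samples))
                for a, b in dyads
                for p in (a, b)
            }
        if time_mode != "epochs":
            raise ValueError(f"time_mode must be 'epochs' or 'circular', got {time_mode!r}")
        if n_epochs is None:
            raise ValueError("shuffle_time requires n_epochs")
        out = {}
        for a, b in dyads:
            out[a] = rng.permutation(n_epochs)
            out[b] = rng.permutation(n_epochs)
        return out

    labels = sorted(set(groups), key=str)
    by_group = {g: [d for d, gg in zip(dyads, groups) if gg == g] for g in labels}

    if scheme == "fake_pairs_within":
        surrogates = []
        for g in labels:
            members = by_group[g]
            if len(members) < 2:
                raise ValueError(
                    f"group {g!r} has {len(members)} dyad(s); fake pairing needs >= 2"
                )
            perm = _derangement(len(members), rng)
            for i, j in enumerate(perm):
                surrogates.append((members[i][0], members[j][1]))
        return surrogates

    # fake_pairs_between
    if len(labels) != 2:
        raise ValueError(f"fake_pairs_between requires exactly 2 groups, got {len(labels)}")
    g1, g2 = by_group[labels[0]], by_group[labels[1]]
    if not g1 or not g2:
        raise ValueError("both groups need at least one dyad")
    surrogates = []
    perm2 = rng.permutation(len(g2))
    for i, d1 in enumerate(g1):
        surrogates.append((d1[0], g2[perm2[i % len(g2)]][1]))
    perm1 = rng.permutation(len(g1))
    for i, d2 in enumerate(g2):
        surrogates.append((d2[0], g1[perm1[i % len(g1)]][1]))
    return surrogates
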