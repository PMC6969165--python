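"""Consensus uncertainty-weighted NMF time-series pattern workflow.

The pipeline condenses the longitudinal panel into a small analyte x
(subgroup, visit) matrix of mean log2 expression D with a matching
standard-error matrix S, then factorizes D ~ A @ P under the
uncertainty-weighted objective

    chi^2 = sum_ij ((D_ij - (A @ P)_ij) / S_ij)^2

with non-negative amplitudes A (analyte x K) and patterns P (K x columns,
each pattern row a unit vector).  The factorization is stochastic — random
non-negative initialization per seed, multiplicative weighted updates —
so the workflow runs it many times and builds a consensus:

1. :func:`select_iterations` — pick the iteration count whose batch of runs
   attains the lowest mean chi^2;
2. :func:`merge_patterns` — pool all unit-norm patterns across runs and
   group them by root-mean-square distance (RMSD) within a tolerance
   expressed as a fraction of the pooled relative-strength range;
3. :func:`assign_markers` — per run, assign each analyte to the pattern
   whose indicator vector is nearest to the analyte's max-scaled amplitude
   row (the trajectory-distance marker statistic);
4. :func:`consensus_assignment` — keep analyte-pattern memberships whose
   occurrence frequency across runs strictly exceeds 50%.

Downstream, :func:`top_decliners` ranks a pattern's analytes by mean
log2 decline under treatment and :func:`responder_decline_test` compares
the aggregated decline rate between responders and non-responders by
Mann-Whitney U.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import AnalytePanel

__all__ = [
    "GroupedMeanMatrix",
    "PatternRun",
    "ConsensusPatternSet",
    "MarkerAssignment",
    "DeclineTest",
    "subgroups_by",
    "build_grouped_matrix",
    "weighted_chi2",
    "fit_weighted_nmf",
    "select_iterations",
    "merge_patterns",
    "assign_markers",
    "consensus_assignment",
    "top_decliners",
    "responder_decline_test",
]


@dataclass
class GroupedMeanMatrix:
    """Mean log2 expression and its standard error per (subgroup, visit)."""

    D: pd.DataFrame   # analytes x (subgroup, visit) columns
    S: pd.DataFrame   # same shape, strictly positive
    n: pd.Series      # subjects per column

    def __post_init__(self) -> None:
        if not self.D.columns.equals(self.S.columns) or not self.D.index.equals(self.S.index):
            raise ValueError("D and S must share index and columns")
        if (self.S.to_numpy() <= 0).any():
            raise ValueError("standard errors must be strictly positive")


@dataclass
class PatternRun:
    """One stochastic factorization: non-negative A, unit-norm P rows."""

    A: pd.DataFrame   # analytes x K, >= 0
    P: pd.DataFrame   # K x columns, rows unit Euclidean norm
    chi2: float
    seed: int
    n_iterations: int


@dataclass
class ConsensusPatternSet:
    centroids: pd.DataFrame       # merged pattern x columns, unit-norm rows
    members: dict                 # pattern id -> [(run index, k), ...]
    rmsd_tol: float               # absolute RMSD threshold used
    rel_strength_range: float     # pooled coordinate range the tolerance scaled
    frequencies: pd.DataFrame = None   # analyte x pattern occurrence frequency
    assignment: pd.Series = None       # analyte -> pattern id where freq > 0.5


@dataclass
class MarkerAssignment:
    assignment: pd.Series         # analyte -> pattern index (-1 = unassigned)
    distances: pd.DataFrame       # analyte x pattern trajectory distances
    ambiguous: list = field(default_factory=list)
    unassigned: list = field(default_factory=list)

    def ranked_markers(self, k: int) -> list:
        """Markers of pattern k by ascending trajectory distance."""
        hit = self.assignment[self.assignment == k].index
        return list(self.distances.loc[hit, k].sort_values().index)


@dataclass
class DeclineTest:
    group_declines: dict          # group -> per-subject mean log2 declines
    geometric_mean_fold: dict     # group -> 2 ** mean decline
    U: float
    p: float
    excluded_subjects: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# grouped matrix
# ---------------------------------------------------------------------------

def subgroups_by(meta: pd.DataFrame, columns, include=None) -> dict:
    """Build {label: subject ids} from metadata columns.

    ``columns`` e.g. ``("arm",)`` or ``("arm", "response")``; labels join the
    values with "/".  ``include`` optionally restricts to listed labels.
    """
    out = {}
    for key, grp in meta.groupby(list(columns)):
        if not isinstance(key, tuple):
            key = (key,)
        label = "/".join(str(k) for k in key)
        if include is not None and label not in include:
            continue
        out[label] = sorted(grp["subject"].unique())
    return out


def build_grouped_matrix(
    panel: AnalytePanel,
    meta: pd.DataFrame,
    subgroups: dict,
    visits=("week0", "week4", "week16"),
    se_floor: float = 1e-6,
) -> GroupedMeanMatrix:
    """Mean and SE of log2 expression per (subgroup, visit) cell.

    Columns are ordered subgroup-block by subgroup-block, visits in the
    given order within each block.  Cells with fewer than two subjects are
    an error; SE cells below ``se_floor`` are raised to the smallest
    positive SE observed (so chi-squared weights stay finite).
    """
    if panel.state != "normalized":
        raise ValueError("grouped matrix is built from the normalized panel")
    m = meta.loc[meta.index.intersection(panel.samples)]
    cols, means, ses, ns = [], [], [], []
    for label in subgroups:
        subjects = set(subgroups[label])
        for visit in visits:
            rows = m[(m["visit"] == visit) & m["subject"].isin(subjects)]
            if len(rows) < 2:
                raise ValueError(
                    f"cell ({label!r}, {visit!r}) has {len(rows)} subjects; "
                    "need >= 2 for a standard error"
                )
            block = panel.values.loc[rows.index]
            cols.append((label, visit))
            means.append(block.mean(axis=0))
            ses.append(block.std(axis=0, ddof=1) / np.sqrt(len(rows)))
            ns.append(len(rows))
    columns = pd.MultiIndex.from_tuples(cols, names=["subgroup", "visit"])
    D = pd.concat(means, axis=1)
    D.columns = columns
    S = pd.concat(ses, axis=1)
    S.columns = columns
    floor = S.to_numpy()[S.to_numpy() > se_floor]
    if floor.size == 0:
        raise ValueError("all standard errors at or below the floor")
    S = S.where(S > se_floor, floor.min())
    return GroupedMeanMatrix(D=D, S=S, n=pd.Series(ns, index=columns))


# ---------------------------------------------------------------------------
# weighted NMF
# ---------------------------------------------------------------------------

def weighted_chi2(D, S, A, P) -> float:
    """The uncertainty-weighted objective sum(((D - A@P)/S)^2)."""
    D, S = np.asarray(D, float), np.asarray(S, float)
    A, P = np.asarray(A, float), np.asarray(P, float)
    return float((((D - A @ P) / S) ** 2).sum())


def fit_weighted_nmf(
    gm: GroupedMeanMatrix,
    K: int,
    n_iterations: int = 5000,
    seed: int = 0,
) -> PatternRun:
    """One stochastic weighted factorization D ~ A @ P.

    Random non-negative initialization drawn from ``seed`` followed by
    multiplicative updates for the S-weighted least-squares objective
    (weights 1/S^2); the best state visited (by chi^2) is returned.
    Pattern rows are rescaled to unit Euclidean norm with the compensating
    scale absorbed into the amplitude columns, which leaves A @ P — and
    hence chi^2 — unchanged.  Identical seeds reproduce bit-identically.

    Interior optima of the weighted objective form a continuum (any
    invertible mixing of the factors that preserves non-negativity leaves
    chi^2 unchanged), so independent runs converge to different, equally
    good factor pairs; resolving that ambiguity is the job of the
    consensus stages, not of a single run.
    """
    D = gm.D.to_numpy(dtype=float)
    S = gm.S.to_numpy(dtype=float)
    n, m = D.shape
    if K > min(n, m):
        raise ValueError(f"K={K} exceeds min(matrix dims)={min(n, m)}")
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    if (D < 0).any():
        raise ValueError("weighted NMF requires a non-negative target matrix")
    if (S <= 0).any():
        raise ValueError("standard errors must be strictly positive")

    rng = np.random.default_rng(seed)
    scale = np.sqrt(max(D.mean(), np.finfo(float).tiny) / K)
    A = rng.uniform(0.5, 1.5, size=(n, K)) * scale
    P = rng.uniform(0.5, 1.5, size=(K, m)) * scale

    W = 1.0 / S**2
    WD = W * D
    eps = 1e-12
    best = (np.inf, A.copy(), P.copy())
    for _ in range(n_iterations):
        AP = A @ P
        A *= (WD @ P.T) / ((W * AP) @ P.T + eps)
        AP = A @ P
        P *= (A.T @ WD) / (A.T @ (W * AP) + eps)
        c = weighted_chi2(D, S, A, P)
        if c < best[0]:
            best = (c, A.copy(), P.copy())

    chi2_best, A, P = best
    norms = np.linalg.norm(P, axis=1)
    norms[norms == 0] = 1.0
    P = P / norms[:, None]
    A = A * norms[None, :]
    return PatternRun(
        A=pd.DataFrame(A, index=gm.D.index, columns=range(K)),
        P=pd.DataFrame(P, index=range(K), columns=gm.D.columns),
        chi2=float(chi2_best),
        seed=seed,
        n_iterations=n_iterations,
    )


def select_iterations(
    gm: GroupedMeanMatrix,
    K: int,
    candidates=(1000, 5000, 10000, 15000, 20000),
    n_runs: int = 10,
    seed: int = 0,
) -> tuple[int, pd.DataFrame]:
    """Choose the iteration count whose run batch attains the lowest mean chi^2.

    Each candidate gets ``n_runs`` independently seeded runs; ties go to the
    smallest candidate.
    """
    candidates = sorted(set(int(c) for c in candidates))
    if not candidates:
        raise ValueError("no iteration candidates given")
    ss = np.random.SeedSequence(seed)
    rows = []
    for cand, child in zip(candidates, ss.spawn(len(candidates))):
        seeds = [int(s.generate_state(1)[0] % 2**31) for s in child.spawn(n_runs)]
        chi2s = [fit_weighted_nmf(gm, K, cand, s).chi2 for s in seeds]
        rows.append({"n_iterations": cand,
                     "mean_chi2": float(np.mean(chi2s)),
                     "sd_chi2": float(np.std(chi2s, ddof=1)) if n_runs > 1 else 0.0,
                     "n_runs": n_runs})
    table = pd.DataFrame(rows).set_index("n_iterations")
    chosen = int(table["mean_chi2"].idxmin())  # idxmin takes the first (smallest)
    return chosen, table


# ---------------------------------------------------------------------------
# consensus across runs
# ---------------------------------------------------------------------------

def _rmsd(u: np.ndarray, v: np.ndarray) -> float:
    return float(np.sqrt(np.mean((u - v) ** 2)))


def merge_patterns(runs, tol: float = 0.05, range_mode: str = "unit",
                   linkage: str = "single") -> ConsensusPatternSet:
    """Pool unit-norm patterns across runs and group them by RMSD.

    The similarity criterion is RMSD within ``tol`` (default 5%) of the
    relative-strength range.  Patterns are unit vectors, so with the default
    ``range_mode="unit"`` the relative-strength scale is 1 and the threshold
    is ``tol`` itself; ``range_mode="observed"`` instead scales by
    (max - min) over all pooled pattern coordinates, which tightens the
    threshold when patterns are nearly flat (that tightening fragments the
    consensus precisely when runs agree, hence it is not the default).
    Grouping is greedy in (run, k) order: a pattern joins the nearest group
    within threshold — distance to the closest member (``linkage="single"``,
    default) or to the running centroid (``linkage="centroid"``, more
    compact, resists chaining) — subject to one-pattern-per-run per group;
    otherwise it opens a new group.  Final centroids are renormalized member
    means.
    """
    if len(runs) < 2:
        raise ValueError("need at least two runs to merge")
    cols = runs[0].P.columns
    K = runs[0].P.shape[0]
    for r in runs[1:]:
        if not r.P.columns.equals(cols):
            raise ValueError("runs have inconsistent column labels")
        if r.P.shape[0] != K:
            raise ValueError("runs have inconsistent K")

    pooled = [(ri, k, runs[ri].P.iloc[k].to_numpy(dtype=float))
              for ri in range(len(runs)) for k in range(K)]
    # a pattern whose row collapsed to zero carries no trajectory
    pooled = [(ri, k, v) for (ri, k, v) in pooled if np.linalg.norm(v) > 0]
    if not pooled:
        raise ValueError("all patterns are zero vectors")
    coords = np.concatenate([v for (_, _, v) in pooled])
    observed_range = float(coords.max() - coords.min())
    if range_mode == "unit":
        rel_range = 1.0
    elif range_mode == "observed":
        rel_range = observed_range
    else:
        raise ValueError(f"unknown range_mode {range_mode!r}")
    threshold = tol * rel_range

    if linkage not in ("single", "centroid"):
        raise ValueError(f"unknown linkage {linkage!r}")
    groups = []  # each: {"members": [(ri, k)], "vectors": [...], "runs": set, "centroid": vec}
    for ri, k, vec in pooled:
        best_g, best_d = None, np.inf
        for g in groups:
            if ri in g["runs"]:
                continue
            if linkage == "single":
                d = min(_rmsd(vec, w) for w in g["vectors"])
            else:
                d = _rmsd(vec, g["centroid"])
            if d <= threshold and d < best_d:
                best_g, best_d = g, d
        if best_g is None:
            groups.append({"members": [(ri, k)], "vectors": [vec],
                           "runs": {ri}, "centroid": vec})
        else:
            best_g["members"].append((ri, k))
            best_g["vectors"].append(vec)
            best_g["runs"].add(ri)
            c = np.mean(best_g["vectors"], axis=0)
            norm = np.linalg.norm(c)
            best_g["centroid"] = c / norm if norm > 0 else c

    # consolidation: greedy grouping can split one underlying pattern family
    # across groups when run-to-run wander sits near the threshold; fuse
    # groups whose centroids fall within the same threshold (closest pair
    # first) until none remain
    while len(groups) > 1:
        best = None
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                d = _rmsd(groups[i]["centroid"], groups[j]["centroid"])
                if d <= threshold and (best is None or d < best[0]):
                    best = (d, i, j)
        if best is None:
            break
        _, i, j = best
        groups[i]["members"] += groups[j]["members"]
        groups[i]["vectors"] += groups[j]["vectors"]
        groups[i]["runs"] |= groups[j]["runs"]
        c = np.mean(groups[i]["vectors"], axis=0)
        norm = np.linalg.norm(c)
        groups[i]["centroid"] = c / norm if norm > 0 else c
        del groups[j]

    # stable ordering: most-supported groups first, then first appearance
    order = sorted(range(len(groups)),
                   key=lambda i: (-len(groups[i]["members"]), i))
    centroids, members = [], {}
    for pid, gi in enumerate(order):
        g = groups[gi]
        c = np.mean(g["vectors"], axis=0)
        norm = np.linalg.norm(c)
        centroids.append(c / norm if norm > 0 else c)
        members[pid] = list(g["members"])
    centroid_df = pd.DataFrame(centroids, columns=cols)
    centroid_df.index.name = "pattern"
    return ConsensusPatternSet(
        centroids=centroid_df,
        members=members,
        rmsd_tol=threshold,
        rel_strength_range=rel_range,
    )


def assign_markers(run: PatternRun) -> MarkerAssignment:
    """Trajectory-distance marker assignment within one run.

    Each analyte's amplitude row is scaled to unit maximum; its distance to
    pattern k is the Euclidean distance to the k-th indicator vector, and the
    analyte is assigned to the argmin (ties to the lowest pattern index,
    flagged ambiguous).  All-zero amplitude rows are left unassigned.
    """
    A = run.A.to_numpy(dtype=float)
    n, K = A.shape
    rowmax = A.max(axis=1)
    zero = rowmax == 0
    scaled = np.divide(A, np.where(zero, 1.0, rowmax)[:, None])
    # ||scaled - e_k||^2 = sum(scaled^2) - 2*scaled_k + 1
    sq = (scaled**2).sum(axis=1)
    d2 = sq[:, None] - 2.0 * scaled + 1.0
    dist = np.sqrt(np.maximum(d2, 0.0))
    assign = dist.argmin(axis=1)
    ties = (dist == dist.min(axis=1, keepdims=True)).sum(axis=1) > 1
    assign_s = pd.Series(assign, index=run.A.index)
    assign_s[zero] = -1
    return MarkerAssignment(
        assignment=assign_s,
        distances=pd.DataFrame(dist, index=run.A.index, columns=range(K)),
        ambiguous=list(run.A.index[ties & ~zero]),
        unassigned=list(run.A.index[zero]),
    )


def consensus_assignment(
    runs,
    merged: ConsensusPatternSet,
    min_freq: float = 0.5,
) -> ConsensusPatternSet:
    """Map per-run marker assignments onto merged patterns and keep the
    memberships whose occurrence frequency strictly exceeds ``min_freq``.

    The frequency denominator is the total number of runs, so analytes a run
    left unassigned dilute their own frequencies.
    """
    n_runs = len(runs)
    to_merged = {}
    for pid, mem in merged.members.items():
        for ri, k in mem:
            to_merged[(ri, k)] = pid
    analytes = runs[0].A.index
    counts = pd.DataFrame(0.0, index=analytes, columns=sorted(merged.members))
    for ri, run in enumerate(runs):
        ma = assign_markers(run)
        for a, k in ma.assignment.items():
            if k < 0:
                continue
            pid = to_merged.get((ri, int(k)))
            if pid is not None:
                counts.loc[a, pid] += 1.0
    freq = counts / n_runs
    final = {}
    for a in analytes:
        row = freq.loc[a]
        pid = row.idxmax()
        if row[pid] > min_freq:
            final[a] = pid
    merged.frequencies = freq
    merged.assignment = pd.Series(final, dtype="object")
    return merged


# ---------------------------------------------------------------------------
# pharmacodynamic follow-up
# ---------------------------------------------------------------------------

def _subject_declines(analytes, panel, meta, subjects, visit_pair) -> tuple[pd.Series, list]:
    v0, v1 = visit_pair
    m = meta.loc[meta.index.intersection(panel.samples)]
    declines, excluded = {}, []
    for subject in subjects:
        grp = m[m["subject"] == subject]
        s0 = grp.index[grp["visit"] == v0]
        s1 = grp.index[grp["visit"] == v1]
        if len(s0) != 1 or len(s1) != 1:
            excluded.append(subject)
            continue
        declines[subject] = float(
            (panel.values.loc[s1[0], analytes].to_numpy()
             - panel.values.loc[s0[0], analytes].to_numpy()).mean()
        )
    return pd.Series(declines, dtype=float), excluded


def top_decliners(
    analytes,
    panel: AnalytePanel,
    meta: pd.DataFrame,
    arm: str = "apremilast",
    n_top: int = 4,
    visit_pair=("week4", "week16"),
) -> pd.DataFrame:
    """Rank a pattern's analytes by the magnitude of mean log2 decline
    between two visits in one treatment arm; return the top ``n_top``.

    Only analytes whose mean change is negative count as decliners; if fewer
    than ``n_top`` decline, all decliners are returned with a warning.
    """
    analytes = list(analytes)
    missing = [a for a in analytes if a not in panel.analytes]
    if missing:
        raise KeyError(f"analyte(s) not in panel: {missing}")
    m = meta.loc[meta.index.intersection(panel.samples)]
    subjects = sorted(m.loc[m["arm"] == arm, "subject"].unique())
    rows = []
    for a in analytes:
        decl, _ = _subject_declines([a], panel, meta, subjects, visit_pair)
        rows.append({"analyte": a, "mean_decline": float(decl.mean())})
    table = pd.DataFrame(rows).set_index("analyte")
    decliners = table[table["mean_decline"] < 0].copy()
    decliners = decliners.reindex(
        decliners["mean_decline"].abs().sort_values(ascending=False).index
    )
    if len(decliners) < n_top:
        warnings.warn(
            f"only {len(decliners)} of {len(analytes)} analytes decline; "
            f"returning all of them"
        )
        return decliners
    return decliners.head(n_top)


def responder_decline_test(
    analytes,
    panel: AnalytePanel,
    meta: pd.DataFrame,
    visit_pair=("week4", "week16"),
    arm: str = "apremilast",
    groups=("AR", "ANR"),
) -> DeclineTest:
    """Compare aggregated decline rates between responder groups.

    Per subject, the mean over ``analytes`` of the log2 change across
    ``visit_pair`` (the log of the geometric-mean fold change); the two
    response groups are compared by a two-sided Mann-Whitney U test.
    Subjects missing either visit are excluded and reported.
    """
    analytes = list(analytes)
    m = meta.loc[meta.index.intersection(panel.samples)]
    per_group, excluded = {}, []
    for g in groups:
        subjects = sorted(
            m.loc[(m["arm"] == arm) & (m["response"] == g), "subject"].unique()
        )
        decl, excl = _subject_declines(analytes, panel, meta, subjects, visit_pair)
        if len(decl) < 2:
            raise ValueError(f"response group {g!r} has {len(decl)} usable subjects")
        per_group[g] = decl
        excluded.extend(excl)
    a, b = (per_group[g].to_numpy() for g in groups)
    pooled = np.concatenate([a, b])
    method = ("exact" if len(a) <= 8 and len(b) <= 8
              and len(np.unique(pooled)) == len(pooled) else "asymptotic")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return DeclineTest(
        group_declines={g: per_group[g] for g in groups},
        geometric_mean_fold={g: float(2.0 ** per_group[g].mean()) for g in groups},
        U=float(res.statistic),
        p=float(res.pvalue),
        excluded_subjects=excluded,
    )
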