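"""Group-level statistics on behavioral flow.

The central test (BFA) compares two groups of recordings through the
Manhattan distance between their group-mean transition matrices::

    distance = sum_jk | mean_C(x_jk) - mean_T(x_jk) |

A permutation null is built by shuffling the group-assignment vector
(group sizes preserved); the observed distance is then located in that
null as a percentile (with an (N+1) denominator, so 1,000 permutations
cap it at 99.9), standardized into a z score, and converted into a
right-tailed parametric P value through the normal upper tail
(erf-based).

Per-animal behavioral-flow likeness (BFL) scores are log ratios of
Manhattan distances to the leave-one-out elementwise-median matrices of
the two groups; they drive Cohen's d effect sizes, power curves,
responder stratification and the in-silico sensitivity assay.  Per-unit
t-tests (clusters or individual transitions) use Benjamini–Yekutieli
correction, which controls FDR under arbitrary dependence between units.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats as sps
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.power import TTestIndPower

from bflow.flow import AlphabetError, TransitionMatrix

DEFAULT_N_GRID = (3, 4, 5, 6, 7, 12, 20, 30, 50, 60)


@dataclass
class GroupedTransitionSet:
    """Two groups of conformable transition matrices (control vs test)."""

    group_C: list[TransitionMatrix]
    group_T: list[TransitionMatrix]

    def __post_init__(self):
        mats = self.group_C + self.group_T
        if not self.group_C or not self.group_T:
            raise ValueError("both groups must be nonempty")
        alpha = mats[0].alphabet
        for m in mats[1:]:
            if not np.array_equal(m.alphabet, alpha):
                raise AlphabetError("transition-matrix alphabets differ")

    @property
    def alphabet(self) -> np.ndarray:
        return self.group_C[0].alphabet

    def stacked(self) -> tuple[np.ndarray, np.ndarray]:
        """All matrices flattened row-major, and a boolean control mask."""
        mats = [m.counts.ravel() for m in self.group_C + self.group_T]
        mask = np.zeros(len(mats), dtype=bool)
        mask[: len(self.group_C)] = True
        return np.asarray(mats, dtype=float), mask


@dataclass
class PermutationNull:
    distances: np.ndarray
    seed: int

    @property
    def n(self) -> int:
        return len(self.distances)


@dataclass
class BFAResult:
    """Permutation-test outcome: distance, percentile, z and P value."""

    distance: float
    percentile: float
    z: float
    p: float
    null: PermutationNull


@dataclass
class BFLScore:
    """Per-sample likeness: distances to both group medians and log ratio."""

    sample_id: str
    d_A: float
    d_B: float
    score: float
    degenerate: bool = False  # a zero distance made the score infinite


@dataclass
class PowerCurve:
    effect_size: float
    alpha: float
    n_grid: tuple
    power: np.ndarray


# ---------------------------------------------------------------------------
# Distances and the permutation test


def manhattan_group_distance(groups: GroupedTransitionSet) -> float:
    """Manhattan distance between the two group-mean matrices."""
    mean_C = np.mean([m.counts for m in groups.group_C], axis=0)
    mean_T = np.mean([m.counts for m in groups.group_T], axis=0)
    return float(np.abs(mean_C - mean_T).sum())


def erf_pvalue(z: float) -> float:
    """Right-tailed normal P value of a standardized distance.

    Equivalent to ``(1 - erf(z / sqrt(2))) / 2`` but evaluated through
    the complementary error function so relative precision survives for
    large z (where the naive form cancels to 0).
    """
    return float(0.5 * special.erfc(np.asarray(z, dtype=float) / math.sqrt(2.0)))


def bfa_permutation(groups: GroupedTransitionSet, n_perm: int = 1000,
                    seed: int = 0) -> BFAResult:
    """Behavioral flow analysis: permutation test on the group distance.

    The group-assignment vector is shuffled ``n_perm`` times (group sizes
    preserved) and the inter-group distance recomputed for each shuffle.
    Percentile uses the (N+1) denominator and a strict inequality (ties
    do not count as smaller), so its ceiling is 100·N/(N+1).  z is the
    observed distance standardized by the null's mean and SD, and the
    parametric P value comes from the normal upper tail.
    """
    X, mask = groups.stacked()
    n_c = int(mask.sum())
    n = X.shape[0]
    if n < 4:
        raise ValueError("need at least 4 recordings in total")
    observed = manhattan_group_distance(groups)

    rng = np.random.default_rng(seed)
    # weight vector w: +1/N_C on control slots, -1/N_T on test slots, so
    # the distance is sum |w . X| over cells; permutations permute w.
    w = np.where(mask, 1.0 / n_c, -1.0 / (n - n_c))
    perm_idx = np.argsort(rng.random((n_perm, n)), axis=1)
    W = w[perm_idx]  # (n_perm, n)
    null = np.abs(W @ X).sum(axis=1)

    percentile = 100.0 * float((null < observed).sum()) / (n_perm + 1)
    sd = float(null.std())
    if sd == 0:
        raise ValueError("degenerate permutation null (zero variance)")
    z = (observed - float(null.mean())) / sd
    return BFAResult(distance=observed, percentile=percentile, z=z,
                     p=erf_pvalue(z), null=PermutationNull(null, seed))


# ---------------------------------------------------------------------------
# Per-unit tests


def _by_adjust(pvals: np.ndarray) -> np.ndarray:
    return multipletests(pvals, method="fdr_by")[1]


def per_unit_tests(groups: GroupedTransitionSet | None = None,
                   units: str = "transitions",
                   values_C: np.ndarray | None = None,
                   values_T: np.ndarray | None = None,
                   unit_names: list | None = None,
                   equal_var: bool = False) -> pd.DataFrame:
    """Two-sample t-test per unit with Benjamini–Yekutieli correction.

    Units are either the observed transitions of a
    :class:`GroupedTransitionSet` (cells with a nonzero total count; the
    structurally zero diagonal is never tested) or arbitrary per-sample
    value matrices ``values_C`` / ``values_T`` (samples x units), e.g.
    cluster occurrences or classical readouts.  Welch's test by default.
    Units constant in both groups are skipped (no variance to test).
    """
    if groups is not None:
        if units != "transitions":
            raise ValueError("pass values_C/values_T for non-transition units")
        X, mask = groups.stacked()
        nc = len(groups.alphabet)
        observed = X.sum(axis=0) > 0
        offdiag = ~np.eye(nc, dtype=bool).ravel()
        keep = observed & offdiag
        values_C, values_T = X[mask][:, keep], X[~mask][:, keep]
        jj, kk = np.divmod(np.flatnonzero(keep), nc)
        unit_names = [f"{groups.alphabet[j]}->{groups.alphabet[k]}"
                      for j, k in zip(jj, kk)]
    values_C = np.asarray(values_C, dtype=float)
    values_T = np.asarray(values_T, dtype=float)
    if values_C.ndim == 1:
        values_C, values_T = values_C[:, None], values_T[:, None]
    if values_C.shape[0] < 2 or values_T.shape[0] < 2:
        raise ValueError("need >= 2 samples per group")
    if unit_names is None:
        unit_names = [f"unit{j}" for j in range(values_C.shape[1])]

    rows = []
    for j, name in enumerate(unit_names):
        a, b = values_C[:, j], values_T[:, j]
        if a.std() == 0 and b.std() == 0:
            if a.mean() == b.mean():
                continue  # constant and identical: nothing to test
            t, p = np.inf, 0.0
        else:
            t, p = sps.ttest_ind(a, b, equal_var=equal_var)
        rows.append({"unit": name, "mean_C": a.mean(), "mean_T": b.mean(),
                     "t": float(t), "p": float(p)})
    columns = ["unit", "mean_C", "mean_T", "t", "p"]
    table = pd.DataFrame(rows, columns=columns)
    if len(table):
        table["p_adj"] = _by_adjust(table["p"].to_numpy())
    else:
        table["p_adj"] = pd.Series(dtype=float)
    return table


# ---------------------------------------------------------------------------
# BFL


def bfl_scores(groups: GroupedTransitionSet) -> list[BFLScore]:
    """Behavioral-flow likeness score of every sample.

    For sample i, the elementwise median matrices M_A (over group A
    excluding i if i belongs to A) and M_B (likewise) are computed; d_A
    and d_B are the Manhattan distances of T_i to them, and the score is
    ``log(d_A / d_B)``.  A zero distance yields an infinite score flagged
    as degenerate.  Scores are invariant to a global rescaling of all
    matrices.
    """
    A, B = groups.group_C, groups.group_T
    if len(A) < 2 or len(B) < 2:
        raise ValueError("each group needs >= 2 samples for leave-one-out medians")
    out: list[BFLScore] = []
    stack_A = np.stack([m.counts for m in A]).astype(float)
    stack_B = np.stack([m.counts for m in B]).astype(float)
    for own, stack, other in ((A, stack_A, stack_B), (B, stack_B, stack_A)):
        for i, m in enumerate(own):
            M_own = np.median(np.delete(stack, i, axis=0), axis=0)
            M_other = np.median(other, axis=0)
            if own is A:
                M_A, M_B = M_own, M_other
            else:
                M_A, M_B = M_other, M_own
            d_A = float(np.abs(m.counts - M_A).sum())
            d_B = float(np.abs(m.counts - M_B).sum())
            degenerate = d_A == 0 or d_B == 0
            with np.errstate(divide="ignore"):
                score = float(np.log(d_A) - np.log(d_B)) if not degenerate \
                    else float(np.inf if d_B == 0 else -np.inf)
            out.append(BFLScore(sample_id=m.recording_id, d_A=d_A, d_B=d_B,
                                score=score, degenerate=degenerate))
    return out


def cohens_d_from_bfl(scores: list[BFLScore] | np.ndarray,
                      assignment: list | np.ndarray) -> float:
    """Absolute Cohen's d between two groups of BFL scores.

    Pooled standard deviation with (n-1) weights; infinite (degenerate)
    scores are excluded with a warning.
    """
    vals = np.asarray([s.score if isinstance(s, BFLScore) else s
                       for s in scores], dtype=float)
    assignment = np.asarray(assignment)
    finite = np.isfinite(vals)
    if not finite.all():
        warnings.warn(f"excluding {int((~finite).sum())} infinite scores",
                      stacklevel=2)
    vals, assignment = vals[finite], assignment[finite]
    labels = np.unique(assignment)
    if len(labels) != 2:
        raise ValueError("assignment must define exactly two groups")
    a = vals[assignment == labels[0]]
    b = vals[assignment == labels[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 finite scores per group")
    pooled = math.sqrt(((len(a) - 1) * a.var(ddof=1)
                        + (len(b) - 1) * b.var(ddof=1))
                       / (len(a) + len(b) - 2))
    if pooled == 0:
        return 0.0 if a.mean() == b.mean() else float(np.inf)
    return abs(a.mean() - b.mean()) / pooled


def power_curve(d: float, alpha: float = 0.05,
                n_grid: tuple = DEFAULT_N_GRID) -> PowerCurve:
    """Two-sided two-sample t-test power at each per-group size n.

    Uses the noncentral t distribution; at d = 0 the power equals the
    significance level exactly.
    """
    if not np.isfinite(d):
        raise ValueError("effect size must be finite")
    solver = TTestIndPower()
    power = np.array([
        solver.power(effect_size=abs(d), nobs1=n, alpha=alpha, ratio=1.0,
                     alternative="two-sided")
        for n in n_grid])
    return PowerCurve(effect_size=d, alpha=alpha, n_grid=tuple(n_grid),
                      power=power)


def stratify_responders(treated_scores, control_scores) -> np.ndarray:
    """Label treated animals as responders by their BFL score.

    Nonresponders are treated animals whose score lies within the closed
    full range of control scores; all others are responders.
    """
    t = np.asarray([s.score if isinstance(s, BFLScore) else s
                    for s in treated_scores], dtype=float)
    c = np.asarray([s.score if isinstance(s, BFLScore) else s
                    for s in control_scores], dtype=float)
    if len(c) == 0:
        raise ValueError("control scores must be nonempty")
    if not (np.isfinite(t).all() and np.isfinite(c).all()):
        raise ValueError("scores must be finite")
    inside = (t >= c.min()) & (t <= c.max())
    return np.where(inside, "nonresponder", "responder")


# ---------------------------------------------------------------------------
# Sensitivity assay and dose model


def sensitivity_assay(groups: GroupedTransitionSet,
                      sizes: tuple = (25, 20, 15, 10, 5), reps: int = 50,
                      n_perm: int = 1000, seed: int = 0) -> pd.DataFrame:
    """Detection sensitivity under stepwise group-size reduction.

    For each size, equally-sized random subsets of both groups are drawn
    ``reps`` times and the BFA run on each; P values are -log10
    transformed and summarized by mean and SD per size.  Sizes exceeding
    either group are skipped with a warning.
    """
    rng = np.random.default_rng(seed)
    n_c, n_t = len(groups.group_C), len(groups.group_T)
    rows = []
    for size in sizes:
        if size > min(n_c, n_t):
            warnings.warn(f"size {size} exceeds a group; skipped", stacklevel=2)
            continue
        neglog = np.empty(reps)
        for r in range(reps):
            sub = GroupedTransitionSet(
                group_C=[groups.group_C[i] for i in
                         rng.choice(n_c, size, replace=False)],
                group_T=[groups.group_T[i] for i in
                         rng.choice(n_t, size, replace=False)])
            res = bfa_permutation(sub, n_perm=n_perm,
                                  seed=int(rng.integers(2 ** 31)))
            neglog[r] = -math.log10(res.p)
        rows.append({"size": size, "mean_neglog10_p": neglog.mean(),
                     "sd_neglog10_p": neglog.std(ddof=1)})
    return pd.DataFrame(rows)


@dataclass
class DoseModelFit:
    slope: float
    intercept: float
    r_squared: float
    f_stat: float
    df: tuple
    p: float
    p_adj: float | None = None
    n_used: int = 0
    n_excluded: int = 0


def log_linear_dose_model(doses, counts) -> DoseModelFit:
    """OLS fit of log transition count on log dose.

    Both variables are natural-log transformed; zero (or negative)
    entries are excluded before the fit (their number is reported).  The
    algebraic identity R² = F / (F + df₂) holds for this single-predictor
    model.
    """
    doses = np.asarray(doses, dtype=float)
    counts = np.asarray(counts, dtype=float)
    ok = (doses > 0) & (counts > 0)
    if ok.sum() < 3:
        raise ValueError("need at least 3 strictly positive (dose, count) pairs")
    x, y = np.log(doses[ok]), np.log(counts[ok])
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return DoseModelFit(
        slope=float(model.params[1]), intercept=float(model.params[0]),
        r_squared=float(model.rsquared), f_stat=float(model.fvalue),
        df=(int(model.df_model), int(model.df_resid)),
        p=float(model.f_pvalue), n_used=int(ok.sum()),
        n_excluded=int((~ok).sum()))


def adjust_dose_model_pvalues(fits: list[DoseModelFit]) -> list[DoseModelFit]:
    """BY-adjust P values across a family of dose-model fits (in place)."""
    padj = _by_adjust(np.array([f.p for f in fits]))
    for f, p in zip(fits, padj):
        f.p_adj = float(p)
    return fits
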