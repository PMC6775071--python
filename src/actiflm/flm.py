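"""Functional linear modeling of 24-hour activity profiles.

Daily profiles are smoothed with penalized circular B-splines into
functional curves; two treatment groups of curves are then compared with a
point-wise permutation F-test: at every clock grid point a two-group
one-way ANOVA F statistic is computed on the curve evaluations, and its
null distribution is obtained by permuting condition labels (by default
swapping the two labels within each subject, respecting the crossover
pairing).  A point is significant where the observed F exceeds the
point-wise empirical (1-alpha) quantile of the permutation F values.

The p-curve uses the strict "greater than" counting rule: ``p(t)`` is the
proportion of permutation F values at ``t`` strictly larger than the
observed F; the conservative ``(1+b)/(1+n)`` convention is available via
``p_rule="add_one"``.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.interpolate import BSpline
from scipy.linalg import cho_factor, cho_solve

from .io import DailyProfile

MINUTES_PER_DAY = 1440

__all__ = [
    "BasisSpec",
    "FunctionalCurve",
    "ClockInterval",
    "FLMResult",
    "smooth_profile",
    "curve_matrix",
    "pointwise_F",
    "permute_labels",
    "pointwise_permutation_test",
    "extract_significant_intervals",
]

DEFAULT_LAMBDAS = tuple(np.logspace(-4.0, 6.0, 21))


@dataclass(frozen=True)
class BasisSpec:
    """Circular B-spline basis: ``n_basis`` functions of order ``order``
    (cubic by default) on evenly spaced knots over the 1440-minute clock."""

    n_basis: int = 24
    order: int = 4
    circular: bool = True

    def __post_init__(self) -> None:
        if self.order < 2:
            raise ValueError("order must be >= 2")
        if self.n_basis <= self.order:
            raise ValueError("n_basis must exceed the spline order")
        if not self.circular:
            raise ValueError("only the circular basis is implemented")


@dataclass
class FunctionalCurve:
    """A fitted periodic curve: basis spec plus coefficient vector."""

    basis: BasisSpec
    coefficients: np.ndarray
    gcv_lambda: float = np.nan
    transform: str = "none"

    def evaluate(self, minutes: np.ndarray) -> np.ndarray:
        """Evaluate the curve at arbitrary clock minutes."""
        X = _design_matrix(np.asarray(minutes, float), self.basis)
        return X @ self.coefficients

    def evaluate_grid(self, grid_size: int) -> np.ndarray:
        return self.evaluate(_grid_centers(grid_size))


def _grid_centers(grid_size: int) -> np.ndarray:
    step = MINUTES_PER_DAY / grid_size
    return (np.arange(grid_size) + 0.5) * step


# ----------------------------------------------------------------------
# Basis and penalty construction (cached: shapes are small and reused)
# ----------------------------------------------------------------------
_DESIGN_CACHE: dict[tuple, np.ndarray] = {}
_FIT_CACHE: dict[tuple, list] = {}


def _cardinal_bspline(order: int) -> BSpline:
    return BSpline.basis_element(np.arange(order + 1), extrapolate=False)


def _design_matrix(minutes: np.ndarray, basis: BasisSpec) -> np.ndarray:
    key = (minutes.tobytes(), basis.n_basis, basis.order)
    hit = _DESIGN_CACHE.get(key)
    if hit is not None:
        return hit
    B, k = basis.n_basis, basis.order
    delta = MINUTES_PER_DAY / B
    u = np.asarray(minutes, float) / delta
    # wrapped translates of the cardinal B-spline: partition of unity on the circle
    w = (u[:, None] - np.arange(B)[None, :]) % B
    M = _cardinal_bspline(k)
    X = M(w)
    X = np.nan_to_num(X, nan=0.0)
    if len(_DESIGN_CACHE) > 64:
        _DESIGN_CACHE.clear()
    _DESIGN_CACHE[key] = X
    return X


def _circular_penalty(n_basis: int, diff_order: int = 2) -> np.ndarray:
    """P = D'D for the cyclic difference operator of the given order."""
    D = np.eye(n_basis)
    for _ in range(diff_order):
        D = np.roll(D, -1, axis=1) - D
    return D.T @ D


def smooth_profile(
    profile: DailyProfile,
    basis: BasisSpec = BasisSpec(),
    transform: str = "log1p",
    lambdas: Sequence[float] = DEFAULT_LAMBDAS,
) -> FunctionalCurve:
    """Fit a penalized circular B-spline curve to a daily profile.

    The (optionally log1p-transformed) cell values are regressed on the
    circular basis with a cyclic second-difference roughness penalty; the
    penalty weight is chosen from ``lambdas`` by generalized
    cross-validation (GCV).  Missing cells are simply excluded from the
    fit.
    """
    if transform not in ("none", "log1p"):
        raise ValueError(f"unknown transform {transform!r}")
    y = profile.values.astype(float)
    obs = ~np.isnan(y)
    n_obs = int(obs.sum())
    if n_obs < basis.n_basis:
        raise ValueError(
            f"{profile.subject_id}/{profile.condition}: {n_obs} observed cells "
            f"< {basis.n_basis} basis functions"
        )
    y = y[obs]
    if transform == "log1p":
        y = np.log1p(y)
    t = _grid_centers(profile.grid_size)[obs]

    key = (t.tobytes(), basis.n_basis, basis.order, tuple(lambdas))
    fits = _FIT_CACHE.get(key)
    if fits is None:
        X = _design_matrix(t, basis)
        XtX = X.T @ X
        P = _circular_penalty(basis.n_basis)
        fits = []
        for lam in lambdas:
            c_and_lower = cho_factor(XtX + lam * P)
            edf = np.trace(cho_solve(c_and_lower, XtX))
            fits.append((lam, X, c_and_lower, XtX, edf))
        if len(_FIT_CACHE) > 64:
            _FIT_CACHE.clear()
        _FIT_CACHE[key] = fits

    yty = float(y @ y)
    best = None
    for lam, X, c_and_lower, XtX, edf in fits:
        Xty = X.T @ y
        coef = cho_solve(c_and_lower, Xty)
        rss = max(yty - 2.0 * float(coef @ Xty) + float(coef @ (XtX @ coef)), 0.0)
        denom = max(n_obs - edf, 1e-8)
        gcv = n_obs * rss / denom**2
        if best is None or gcv < best[0]:
            best = (gcv, lam, coef)
    _, lam, coef = best
    return FunctionalCurve(basis=basis, coefficients=coef, gcv_lambda=lam,
                           transform=transform)


def curve_matrix(
    profiles: Sequence[DailyProfile],
    grid_size: int,
    basis: BasisSpec = BasisSpec(),
    transform: str = "log1p",
) -> np.ndarray:
    """Smooth each profile and evaluate on a common clock grid (N x G)."""
    return np.vstack(
        [smooth_profile(p, basis, transform).evaluate_grid(grid_size) for p in profiles]
    )


# ----------------------------------------------------------------------
# Point-wise F statistic
# ----------------------------------------------------------------------
def pointwise_F(curves_a: np.ndarray, curves_b: np.ndarray) -> np.ndarray:
    """Two-group one-way ANOVA F at each grid point.

    ``F(t) = [between-group SS / (k-1)] / [within-group SS / (N-k)]`` with
    k=2 groups.  Points with zero within-group variance give ``inf`` when
    the groups differ and 0 when they do not.
    """
    A = np.atleast_2d(np.asarray(curves_a, float))
    B = np.atleast_2d(np.asarray(curves_b, float))
    if A.shape[1] != B.shape[1]:
        raise ValueError("groups must share the evaluation grid")
    na, nb = A.shape[0], B.shape[0]
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least 2 curves")
    ma = A.mean(axis=0)
    mb = B.mean(axis=0)
    grand = (na * ma + nb * mb) / (na + nb)
    ssb = na * (ma - grand) ** 2 + nb * (mb - grand) ** 2
    ssw = ((A - ma) ** 2).sum(axis=0) + ((B - mb) ** 2).sum(axis=0)
    df2 = na + nb - 2
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        F = ssb / (ssw / df2)
    F = np.where(ssw == 0.0, np.where(ssb > 0.0, np.inf, 0.0), F)
    return F


# ----------------------------------------------------------------------
# Permutations
# ----------------------------------------------------------------------
def _paired_structure(
    subjects: Sequence[str], labels: Sequence[str]
) -> tuple[list[str], np.ndarray]:
    """Validate one curve per condition per subject; return (subject order,
    index pairs array of shape (n_subjects, 2)) ordered (label_lo, label_hi)."""
    labels = np.asarray(labels)
    subjects = np.asarray(subjects)
    conds = sorted(set(labels))
    if len(conds) != 2:
        raise ValueError(f"need exactly 2 condition labels, got {conds}")
    order = []
    pairs = []
    for sid in dict.fromkeys(subjects):  # preserve first-seen order
        idx = np.flatnonzero(subjects == sid)
        labs = sorted(labels[idx])
        if len(idx) != 2 or labs != conds:
            raise ValueError(
                f"paired scheme requires one curve per condition per subject; "
                f"subject {sid!r} has labels {list(labels[idx])}"
            )
        lo = idx[labels[idx] == conds[0]][0]
        hi = idx[labels[idx] == conds[1]][0]
        order.append(str(sid))
        pairs.append((lo, hi))
    return order, np.asarray(pairs)


def permute_labels(
    labels: Sequence[str],
    subjects: Sequence[str],
    scheme: str = "paired",
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Return one permuted copy of the condition labels.

    ``paired`` independently swaps (or not) the two labels within each
    subject — the 2^n_subjects sign-flip group of the crossover.
    ``unpaired`` shuffles all labels, preserving group sizes.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    labels = np.asarray(labels, dtype=object)
    if scheme == "unpaired":
        return labels[rng.permutation(len(labels))]
    if scheme != "paired":
        raise ValueError(f"unknown scheme {scheme!r}")
    _, pairs = _paired_structure(subjects, labels)
    out = labels.copy()
    flips = rng.integers(0, 2, size=len(pairs)).astype(bool)
    for (lo, hi), flip in zip(pairs, flips):
        if flip:
            out[lo], out[hi] = out[hi], out[lo]
    return out


# ----------------------------------------------------------------------
# Results
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class ClockInterval:
    """Half-open clock-time interval [start, end) in minutes; ``end <=
    start`` denotes a wrap across midnight (end on the following day)."""

    start_minute: float
    end_minute: float
    direction: str = ""

    @property
    def length(self) -> float:
        if self.start_minute == 0.0 and self.end_minute == MINUTES_PER_DAY:
            return float(MINUTES_PER_DAY)
        return (self.end_minute - self.start_minute) % MINUTES_PER_DAY

    def to_mask(self, grid_size: int) -> np.ndarray:
        centers = _grid_centers(grid_size)
        if self.start_minute < self.end_minute:
            return (centers >= self.start_minute) & (centers < self.end_minute)
        return (centers >= self.start_minute) | (centers < self.end_minute)

    def __str__(self) -> str:
        def fmt(m: float) -> str:
            m = int(round(m)) % MINUTES_PER_DAY
            return f"{m // 60:02d}:{m % 60:02d}"

        tag = f" ({self.direction})" if self.direction else ""
        end = int(round(self.end_minute))
        end_s = "24:00" if end == MINUTES_PER_DAY else fmt(self.end_minute)
        return f"{fmt(self.start_minute)}-{end_s}{tag}"


@dataclass
class FLMResult:
    """Everything the point-wise permutation F-test produces."""

    grid: np.ndarray  # clock-minute centers, length G
    F_obs: np.ndarray
    F_perm: np.ndarray  # n_perm x G
    crit_curve: np.ndarray
    p_curve: np.ndarray
    alpha: float
    n_perm: int
    scheme: str
    seed: int | None
    conditions: tuple[str, str]
    mean_curves: dict  # condition -> mean smoothed curve on the grid
    significant_intervals: list = field(default_factory=list)
    transform: str = "log1p"

    @property
    def significant_mask(self) -> np.ndarray:
        return self.F_obs > self.crit_curve

    @property
    def fraction_significant(self) -> float:
        return float(np.mean(self.significant_mask))

    def to_dict(self) -> dict:
        return {
            "grid": self.grid.tolist(),
            "F_obs": self.F_obs.tolist(),
            "crit_curve": self.crit_curve.tolist(),
            "p_curve": self.p_curve.tolist(),
            "alpha": self.alpha,
            "n_perm": self.n_perm,
            "scheme": self.scheme,
            "seed": self.seed,
            "conditions": list(self.conditions),
            "mean_curves": {k: v.tolist() for k, v in self.mean_curves.items()},
            "transform": self.transform,
            "significant_intervals": [
                {
                    "start_minute": iv.start_minute,
                    "end_minute": iv.end_minute,
                    "direction": iv.direction,
                    "label": str(iv),
                }
                for iv in self.significant_intervals
            ],
        }


# ----------------------------------------------------------------------
# The test itself
# ----------------------------------------------------------------------
def pointwise_permutation_test(
    profiles: Sequence[DailyProfile],
    basis: BasisSpec = BasisSpec(),
    transform: str = "log1p",
    grid_size: int | None = None,
    n_perm: int = 500,
    alpha: float = 0.05,
    scheme: str = "paired",
    seed: int | None = None,
    p_rule: str = "greater",
    method: str = "sample",
    min_interval_minutes: float = 0.0,
) -> FLMResult:
    """Point-wise permutation F-test between two conditions of curves.

    Each profile is smoothed and evaluated on the clock grid; the observed
    F curve is referred, point by point, to the permutation distribution
    obtained by relabeling conditions (``scheme="paired"`` swaps labels
    within subjects; ``"unpaired"`` shuffles them freely).
    ``method="exhaustive"`` enumerates all 2^n paired relabelings instead
    of sampling ``n_perm`` of them.

    Returns a :class:`FLMResult` whose significant intervals are the
    maximal runs of grid points with ``F_obs > crit_curve``, merged across
    midnight and annotated with which condition's mean curve is higher.
    """
    if p_rule not in ("greater", "add_one"):
        raise ValueError(f"unknown p_rule {p_rule!r}")
    labels = np.asarray([p.condition for p in profiles], dtype=object)
    subjects = np.asarray([p.subject_id for p in profiles], dtype=object)
    conds = tuple(sorted(set(labels)))
    if len(conds) != 2:
        raise ValueError(f"need exactly two conditions, got {conds}")
    G = grid_size if grid_size is not None else profiles[0].grid_size
    if alpha > 0 and n_perm < 1.0 / alpha:
        warnings.warn(
            f"n_perm={n_perm} < 1/alpha={1 / alpha:.0f}: the critical quantile "
            "is unstable",
            stacklevel=2,
        )

    V = curve_matrix(profiles, G, basis, transform)
    in_a = labels == conds[0]
    F_obs = pointwise_F(V[in_a], V[~in_a])

    rng = np.random.default_rng(seed)
    if scheme == "paired":
        _paired_structure(subjects, labels)  # validate early
    if method == "exhaustive":
        if scheme != "paired":
            raise ValueError("exhaustive enumeration requires the paired scheme")
        _, pairs = _paired_structure(subjects, labels)
        if len(pairs) > 20:
            raise ValueError("exhaustive enumeration limited to <= 20 subjects")
        flip_sets = itertools.product((False, True), repeat=len(pairs))
        perm_masks = []
        for flips in flip_sets:
            m = in_a.copy()
            for (lo, hi), flip in zip(pairs, flips):
                if flip:
                    m[lo], m[hi] = m[hi], m[lo]
            perm_masks.append(m)
    elif method == "sample":
        perm_masks = [
            permute_labels(labels, subjects, scheme, rng) == conds[0]
            for _ in range(n_perm)
        ]
    else:
        raise ValueError(f"unknown method {method!r}")

    F_perm = np.vstack([pointwise_F(V[m], V[~m]) for m in perm_masks])
    n_used = F_perm.shape[0]

    if p_rule == "greater":
        p_curve = (F_perm > F_obs[None, :]).mean(axis=0)
    else:
        p_curve = (1.0 + (F_perm >= F_obs[None, :]).sum(axis=0)) / (1.0 + n_used)

    rank = int(np.ceil((1.0 - alpha) * n_used)) - 1  # nearest-rank quantile
    rank = min(max(rank, 0), n_used - 1)
    crit_curve = np.sort(F_perm, axis=0)[rank]

    mean_curves = {conds[0]: V[in_a].mean(axis=0), conds[1]: V[~in_a].mean(axis=0)}
    result = FLMResult(
        grid=_grid_centers(G),
        F_obs=F_obs,
        F_perm=F_perm,
        crit_curve=crit_curve,
        p_curve=p_curve,
        alpha=alpha,
        n_perm=n_used,
        scheme=scheme,
        seed=seed,
        conditions=conds,
        mean_curves=mean_curves,
        transform=transform,
    )
    result.significant_intervals = extract_significant_intervals(
        result, min_length=min_interval_minutes
    )
    return result


def extract_significant_intervals(
    result: FLMResult, min_length: float = 0.0
) -> list[ClockInterval]:
    """Maximal significant clock-time intervals, merged across midnight.

    Runs of consecutive significant grid points become half-open
    clock-time intervals; a run touching midnight on both sides is merged
    into a single wrapped interval.  Runs shorter than ``min_length``
    minutes are dropped.  Each interval is annotated with the condition
    whose mean curve is higher over it.
    """
    mask = result.significant_mask
    G = len(mask)
    cell = MINUTES_PER_DAY / G
    if not mask.any():
        return []
    if mask.all():
        return [_annotate(ClockInterval(0.0, float(MINUTES_PER_DAY)), result)]
    runs = []
    start = None
    for i in range(G):
        if mask[i] and start is None:
            start = i
        elif not mask[i] and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, G))
    if len(runs) > 1 and runs[0][0] == 0 and runs[-1][1] == G:
        first = runs.pop(0)
        last = runs.pop()
        runs.append((last[0], first[1]))  # wrapped interval
    out = []
    for s, e in runs:
        # e <= G for plain runs (e*cell = 1440 allowed as an exclusive end);
        # merged wrap runs carry e < s, i.e. the interval crosses midnight
        iv = ClockInterval(start_minute=s * cell, end_minute=e * cell)
        if iv.length >= min_length and iv.length > 0:
            out.append(_annotate(iv, result))
    # report in clock order of interval start
    out.sort(key=lambda iv: iv.start_minute)
    return out


def _annotate(iv: ClockInterval, result: FLMResult) -> ClockInterval:
    m = iv.to_mask(len(result.grid))
    a, b = result.conditions
    da = float(np.mean(result.mean_curves[a][m]))
    db = float(np.mean(result.mean_curves[b][m]))
    direction = f"{a}>{b}" if da > db else f"{b}>{a}"
    return ClockInterval(iv.start_minute, iv.end_minute, direction)
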