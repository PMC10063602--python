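"""Dichotomous Rasch estimation by conditional maximum likelihood.

The model gives the probability of a pass as

.. math:: P(X_{vi} = 1) = \\frac{e^{\\theta_v - \\delta_i}}{1 + e^{\\theta_v - \\delta_i}}

with person ability :math:`\\theta_v` and item difficulty :math:`\\delta_i`,
both in logits.  Because the raw score is a sufficient statistic for ability,
item difficulties can be estimated by maximising the likelihood conditional
on each person's raw score, which removes the person parameters entirely and
yields sample-free ("specifically objective") item estimates.  The
conditional likelihood is built from elementary symmetric functions (ESFs)
of the item easiness parameters; all ESF arithmetic here is done in log
space so banks of 57+ items do not overflow.

Missing data are handled exactly under ignorable missingness by conditioning
within each distinct administered-item pattern (one ESF table per pattern).

Person abilities are estimated by maximum likelihood given the calibrated
difficulties; extreme raw scores (0 or maximum), whose ML estimate is
unbounded, receive the conventional score adjustment by ``epsilon``
(default 0.3).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit

from .exceptions import ConvergenceError, LinkageError, ValidationError
from .io import Item, ItemBank, ResponseMatrix

__all__ = [
    "rasch_probability",
    "EsfTable",
    "esf",
    "cml_fit",
    "person_ml_estimate",
    "extreme_score_estimate",
    "PersonMeasure",
    "person_measures",
    "measures_frame",
    "ScoreToMeasureTable",
    "score_to_measure",
]


def rasch_probability(theta, delta):
    """Pass probability P = exp(theta-delta) / (1 + exp(theta-delta)).

    Accepts scalars or broadcastable arrays of logits.
    """
    return expit(np.asarray(theta, dtype=float) - np.asarray(delta, dtype=float))


# ---------------------------------------------------------------------------
# Elementary symmetric functions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EsfTable:
    """Elementary symmetric functions gamma_0..gamma_K of item easinesses."""

    log_gamma: np.ndarray
    item_ids: tuple[str, ...]

    @property
    def gamma(self) -> np.ndarray:
        return np.exp(self.log_gamma)

    def __len__(self) -> int:
        return len(self.log_gamma)


def _log_esf(log_eps: np.ndarray) -> np.ndarray:
    """log gamma_r for r = 0..K via the stable sum recursion in log space."""
    k = len(log_eps)
    lg = np.full(k + 1, -np.inf)
    lg[0] = 0.0
    for w in log_eps:
        lg[1:] = np.logaddexp(lg[1:], lg[:-1] + w)
    return lg


def esf(deltas: Sequence[float], item_ids: Sequence[str] | None = None) -> EsfTable:
    """ESF table for item difficulties ``deltas`` (easiness eps_i = exp(-delta_i)).

    gamma_r sums, over all response patterns with raw score r, the product of
    eps_i over the passed items.
    """
    d = np.asarray(deltas, dtype=float)
    if d.ndim != 1 or d.size < 1:
        raise ValidationError("esf requires a vector of at least one difficulty")
    if not np.isfinite(d).all():
        raise ValidationError("esf requires finite difficulties")
    ids = tuple(item_ids) if item_ids is not None else tuple(
        f"item{k + 1}" for k in range(d.size)
    )
    return EsfTable(log_gamma=_log_esf(-d), item_ids=ids)


# ---------------------------------------------------------------------------
# Conditional maximum likelihood calibration
# ---------------------------------------------------------------------------


@dataclass
class _Pattern:
    cols: np.ndarray        # item column indices administered in this pattern
    scores: np.ndarray      # distinct interior raw scores observed
    counts: np.ndarray      # person counts per score


def _collect_patterns(rm: ResponseMatrix):
    """Group persons by administered-item pattern; keep interior scores only."""
    obs = rm.observed()
    vals = rm.values
    groups: dict[tuple[int, ...], dict[int, int]] = {}
    s_obs = np.zeros(rm.n_items)
    for v in range(rm.n_persons):
        cols = tuple(np.flatnonzero(obs[v]))
        k = len(cols)
        if k < 2:
            continue
        r = int(vals[v, list(cols)].sum())
        if r == 0 or r == k:
            continue  # extreme persons carry no conditional information
        groups.setdefault(cols, {})
        groups[cols][r] = groups[cols].get(r, 0) + 1
        s_obs[list(cols)] += vals[v, list(cols)]
    patterns = []
    for cols, counts in sorted(groups.items()):
        scores = np.array(sorted(counts), dtype=int)
        patterns.append(
            _Pattern(
                cols=np.array(cols, dtype=int),
                scores=scores,
                counts=np.array([counts[r] for r in scores], dtype=float),
            )
        )
    return patterns, s_obs


def _check_linkage(patterns, n_items: int, anchored: np.ndarray) -> None:
    """Items must be linked by co-administration (or pinned by anchors)."""
    parent = list(range(n_items))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    used = np.zeros(n_items, dtype=bool)
    for pat in patterns:
        used[pat.cols] = True
        for c in pat.cols[1:]:
            union(int(pat.cols[0]), int(c))
    active = np.flatnonzero(used)
    if active.size == 0:
        raise LinkageError("no persons with interior scores; nothing to estimate")
    comps: dict[int, list[int]] = {}
    for j in active:
        comps.setdefault(find(int(j)), []).append(int(j))
    if anchored.any():
        for members in comps.values():
            if not anchored[members].any() and len(members) > 0:
                # a fully-free component is not identified relative to anchors
                if len(comps) > 1:
                    raise LinkageError(
                        "disconnected design: items never co-administered with "
                        "any anchored item"
                    )
    elif len(comps) > 1:
        raise LinkageError(
            "disconnected design: some items are never co-administered"
        )


def _pattern_terms(deltas: np.ndarray, pat: _Pattern):
    """Full and single-deleted log-ESF tables for one pattern."""
    log_eps = -deltas[pat.cols]
    lg = _log_esf(log_eps)
    kp = len(log_eps)
    lg_del = np.empty((kp, kp))  # row i: log gamma of the set without item i
    for i in range(kp):
        lg_del[i] = _log_esf(np.delete(log_eps, i))
    return log_eps, lg, lg_del


def _nll_and_grad(deltas: np.ndarray, patterns, s_obs: np.ndarray):
    nll = float(s_obs @ deltas)
    grad = s_obs.copy()
    for pat in patterns:
        log_eps, lg, lg_del = _pattern_terms(deltas, pat)
        nll += float(pat.counts @ lg[pat.scores])
        # E[x_i | r] = eps_i * gamma_{r-1}(without i) / gamma_r
        loge = (
            log_eps[:, None]
            + lg_del[:, pat.scores - 1]
            - lg[pat.scores][None, :]
        )
        grad[pat.cols] -= np.exp(loge) @ pat.counts
    return nll, grad


def _information_matrix(deltas: np.ndarray, patterns, n_items: int) -> np.ndarray:
    """Conditional information: sum over persons of Cov(x_i, x_j | r)."""
    H = np.zeros((n_items, n_items))
    for pat in patterns:
        log_eps, lg, lg_del = _pattern_terms(deltas, pat)
        kp = len(log_eps)
        E = np.exp(
            log_eps[:, None] + lg_del[:, pat.scores - 1] - lg[pat.scores][None, :]
        )  # kp x n_scores
        # diagonal: Var(x_i | r) = E_i (1 - E_i)
        var = E * (1.0 - E)
        Hp = np.zeros((kp, kp))
        Hp[np.arange(kp), np.arange(kp)] = var @ pat.counts
        # off-diagonal: E[x_i x_j | r] - E_i E_j
        for i in range(kp):
            base = np.delete(log_eps, i)
            for j in range(i + 1, kp):
                jj = j - 1  # index of item j inside 'base'
                lg_ij = _log_esf(np.delete(base, jj))
                eij = np.zeros(len(pat.scores))
                ge2 = pat.scores >= 2
                if ge2.any():
                    eij[ge2] = np.exp(
                        log_eps[i]
                        + log_eps[j]
                        + lg_ij[pat.scores[ge2] - 2]
                        - lg[pat.scores[ge2]]
                    )
                cov = eij - E[i] * E[j]
                val = float(cov @ pat.counts)
                Hp[i, j] = val
                Hp[j, i] = val
        H[np.ix_(pat.cols, pat.cols)] += Hp
    return H


def _suminv(H: np.ndarray) -> np.ndarray:
    """Inverse of the information matrix within the sum-to-zero gauge.

    The conditional information matrix is singular with null vector 1 (the
    likelihood is translation invariant); the covariance of the sum-zero
    constrained estimates is B (B' H B)^{-1} B' with B an orthonormal basis
    of the sum-zero subspace.
    """
    k = H.shape[0]
    ones = np.full((k, 1), 1.0 / math.sqrt(k))
    u, _, _ = np.linalg.svd(np.eye(k) - ones @ ones.T)
    b = u[:, : k - 1]  # orthonormal basis orthogonal to 1
    inner = b.T @ H @ b
    return b @ np.linalg.inv(inner) @ b.T


def cml_fit(
    rm: ResponseMatrix,
    anchors: ItemBank | Mapping[str, float] | None = None,
    *,
    max_iter: int = 50,
    tol: float = 1e-6,
    instruments: Mapping[str, str] | None = None,
    frame_id: str = "",
) -> ItemBank:
    """Calibrate item difficulties by conditional maximum likelihood.

    Parameters
    ----------
    rm:
        Screened response matrix (no extreme items; run
        :func:`nmm.io.extreme_screen` first).  Extreme persons are ignored
        automatically since they carry no conditional information.
    anchors:
        Optional fixed difficulties (an :class:`ItemBank` whose anchored
        items, or a mapping item_id -> logit).  Without anchors the free
        difficulties are constrained to sum to zero; with anchors the free
        items are scaled around them.
    max_iter, tol:
        Newton polish iterations and convergence tolerance on the maximum
        absolute score residual (observed minus expected item score).
    instruments:
        Optional item_id -> instrument labels for the returned bank.

    Returns
    -------
    ItemBank
        Difficulties with standard errors from the inverse conditional
        information matrix (Moore-Penrose inverse under the sum-to-zero
        gauge when no anchors are present).
    """
    n_items = rm.n_items
    anchor_map: dict[str, float] = {}
    if anchors is not None:
        if isinstance(anchors, ItemBank):
            anchor_map = {
                it.item_id: float(it.difficulty)
                for it in anchors.items
                if it.anchored and it.item_id in rm.items
            }
        else:
            anchor_map = {k: float(v) for k, v in anchors.items() if k in rm.items}
    anchored = np.array([i in anchor_map for i in rm.items])
    free = ~anchored

    if anchored.all():
        # nothing to estimate: the bank is fully specified by the anchors
        return ItemBank(
            [
                Item(
                    i,
                    (instruments or {}).get(i, "NA"),
                    anchor_map[i],
                    None,
                    anchored=True,
                )
                for i in rm.items
            ],
            frame_id=frame_id,
        )

    patterns, s_obs = _collect_patterns(rm)
    if not patterns:
        raise LinkageError("no persons with interior raw scores")
    _check_linkage(patterns, n_items, anchored)

    # check for extreme items among the persons that actually contribute
    n_resp = np.zeros(n_items)
    for pat in patterns:
        n_resp[pat.cols] += pat.counts.sum()
    for j in np.flatnonzero(free):
        if n_resp[j] == 0 or s_obs[j] == 0 or s_obs[j] == n_resp[j]:
            raise ValidationError(
                f"item {rm.items[j]!r} is extreme among contributing persons; "
                "run extreme_screen first"
            )

    # classical logit start values, centred / shifted into the anchor frame
    deltas = np.zeros(n_items)
    with np.errstate(divide="ignore"):
        start = np.log((n_resp[free] - s_obs[free]) / s_obs[free])
    start = np.clip(start, -5.0, 5.0)
    deltas[free] = start - start.mean()
    deltas[anchored] = [anchor_map[rm.items[j]] for j in np.flatnonzero(anchored)]

    n_free = int(free.sum())
    free_idx = np.flatnonzero(free)

    def pack(d: np.ndarray) -> np.ndarray:
        if anchored.any():
            return d[free_idx]
        return d[free_idx[:-1]]

    def unpack(x: np.ndarray) -> np.ndarray:
        d = deltas.copy()
        if anchored.any():
            d[free_idx] = x
        else:
            d[free_idx[:-1]] = x
            d[free_idx[-1]] = -x.sum()
        return d

    def objective(x: np.ndarray):
        d = unpack(x)
        nll, g = _nll_and_grad(d, patterns, s_obs)
        if anchored.any():
            gr = g[free_idx]
        else:
            gr = g[free_idx[:-1]] - g[free_idx[-1]]
        return nll, gr

    res = minimize(
        objective,
        pack(deltas),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": 500, "ftol": 1e-14, "gtol": 1e-9},
    )
    deltas = unpack(res.x)

    # Newton polish on the full parameterisation until the score residuals
    # (the gradient components) are below tolerance.
    nll, grad = _nll_and_grad(deltas, patterns, s_obs)
    H = None
    for _ in range(max_iter):
        resid = float(np.abs(grad[free_idx]).max())
        if resid < tol:
            break
        H = _information_matrix(deltas, patterns, n_items)
        if anchored.any():
            Hff = H[np.ix_(free_idx, free_idx)]
            step_f = np.linalg.solve(Hff, grad[free_idx])
            step = np.zeros(n_items)
            step[free_idx] = step_f
        else:
            step = np.linalg.pinv(H) @ grad
            step -= step.mean()  # stay in the sum-zero gauge
        scale = 1.0
        for _ in range(40):
            cand = deltas - scale * step
            nll_new, grad_new = _nll_and_grad(cand, patterns, s_obs)
            if nll_new <= nll + 1e-12:
                deltas, nll, grad = cand, nll_new, grad_new
                break
            scale *= 0.5
        else:
            break
    else:
        raise ConvergenceError(
            "CML estimation did not converge",
            gradient_norm=float(np.abs(grad[free_idx]).max()),
        )
    resid = float(np.abs(grad[free_idx]).max())
    if resid >= tol:
        raise ConvergenceError(
            f"CML estimation did not converge (max score residual {resid:.3g})",
            gradient_norm=resid,
        )

    H = _information_matrix(deltas, patterns, n_items)
    ses = np.full(n_items, np.nan)
    if anchored.any():
        Hff = H[np.ix_(free_idx, free_idx)]
        ses[free_idx] = np.sqrt(np.diag(np.linalg.inv(Hff)))
    else:
        ses = np.sqrt(np.clip(np.diag(_suminv(H)), 0.0, None))

    items = []
    for j, iid in enumerate(rm.items):
        items.append(
            Item(
                item_id=iid,
                instrument=(instruments or {}).get(iid, "NA"),
                difficulty=float(deltas[j]),
                se=None if anchored[j] else float(ses[j]),
                anchored=bool(anchored[j]),
            )
        )
    return ItemBank(items, frame_id=frame_id)


# ---------------------------------------------------------------------------
# Person ability estimation
# ---------------------------------------------------------------------------


def _solve_ability(target: float, deltas: np.ndarray, tol: float = 1e-8):
    """Solve sum_i P(theta, delta_i) = target by safeguarded Newton.

    Bisection fallback on a bracket (initially [-10, 10] logits, widened if
    needed); deterministic and bounded.
    """
    d = np.asarray(deltas, dtype=float)

    def f(t):
        return float(expit(t - d).sum()) - target

    lo, hi = -10.0, 10.0
    while f(lo) > 0 and lo > -50:
        lo -= 5.0
    while f(hi) < 0 and hi < 50:
        hi += 5.0
    theta = 0.5 * (lo + hi)
    for _ in range(200):
        p = expit(theta - d)
        fval = float(p.sum()) - target
        if fval > 0:
            hi = theta
        else:
            lo = theta
        info = float((p * (1.0 - p)).sum())
        step = fval / info if info > 0 else 0.0
        cand = theta - step
        if not (lo < cand < hi):
            cand = 0.5 * (lo + hi)
        if abs(cand - theta) < tol:
            theta = cand
            break
        theta = cand
    p = expit(theta - d)
    info = float((p * (1.0 - p)).sum())
    return theta, 1.0 / math.sqrt(info)


def person_ml_estimate(raw_score: int, deltas: Sequence[float]):
    """ML ability and SE for an interior raw score on the given items.

    ``theta`` solves sum_i P(theta, delta_i) = raw_score; the SE is
    1/sqrt(information) at the estimate.  By sufficiency the estimate depends
    on the responses only through the raw score.
    """
    d = np.asarray(deltas, dtype=float)
    k = d.size
    if not 0 < raw_score < k:
        raise ValidationError(
            f"raw score {raw_score} is not interior for {k} items; use "
            "extreme_score_estimate"
        )
    return _solve_ability(float(raw_score), d)


def extreme_score_estimate(
    raw_score: int, deltas: Sequence[float], epsilon: float = 0.3
):
    """Extrapolated ability for an extreme raw score (0 or maximum).

    The ML equation is solved for the adjusted score ``epsilon`` (score 0)
    or ``K - epsilon`` (score K); the SE comes from the information at that
    ability.
    """
    d = np.asarray(deltas, dtype=float)
    k = d.size
    if raw_score not in (0, k):
        raise ValidationError(f"raw score {raw_score} is not extreme for {k} items")
    if not 0 < epsilon < 1:
        raise ValidationError("epsilon must lie in (0, 1)")
    target = epsilon if raw_score == 0 else k - epsilon
    return _solve_ability(target, d)


@dataclass
class PersonMeasure:
    """Estimated ability for one person on their administered items."""

    person_id: str
    raw_score: int
    administered: tuple[str, ...]
    theta: float
    se: float
    extreme: bool


def person_measures(
    rm: ResponseMatrix, bank: ItemBank, epsilon: float = 0.3
) -> list[PersonMeasure]:
    """Ability estimates for every person with at least one administered item.

    Interior scores use :func:`person_ml_estimate`; extreme scores use
    :func:`extreme_score_estimate` and are flagged.  Estimates are cached per
    (administered pattern, raw score) since the raw score is sufficient.
    """
    obs = rm.observed()
    cache: dict[tuple, tuple[float, float, bool]] = {}
    out = []
    for v, person in enumerate(rm.persons):
        cols = np.flatnonzero(obs[v])
        if cols.size == 0:
            continue
        ids = tuple(rm.items[j] for j in cols)
        r = int(rm.values[v, cols].sum())
        key = (ids, r)
        if key not in cache:
            d = bank.difficulties(ids)
            if 0 < r < len(ids):
                theta, se = person_ml_estimate(r, d)
                cache[key] = (theta, se, False)
            else:
                theta, se = extreme_score_estimate(r, d, epsilon)
                cache[key] = (theta, se, True)
        theta, se, extreme = cache[key]
        out.append(PersonMeasure(person.person_id, r, ids, theta, se, extreme))
    return out


def measures_frame(measures: Sequence[PersonMeasure]) -> pd.DataFrame:
    """Tabular view of person measures, indexed by person_id."""
    return pd.DataFrame(
        {
            "person_id": [m.person_id for m in measures],
            "raw_score": [m.raw_score for m in measures],
            "n_administered": [len(m.administered) for m in measures],
            "theta": [m.theta for m in measures],
            "se": [m.se for m in measures],
            "extreme": [m.extreme for m in measures],
        }
    ).set_index("person_id")


# ---------------------------------------------------------------------------
# Score-to-measure tables
# ---------------------------------------------------------------------------


@dataclass
class ScoreToMeasureTable:
    """Raw score -> (ability, SE, 2SE [, 0-100 scaled]) lookup for an item set.

    The ``scaled`` and ``two_se_scaled`` columns are NaN until a scale
    transform is applied (see :mod:`nmm.crosswalk`).
    """

    frame: pd.DataFrame
    item_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        required = {"raw_score", "theta", "se", "two_se"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValidationError(f"score-to-measure table missing columns {missing}")
        for col in ("scaled", "two_se_scaled"):
            if col not in self.frame.columns:
                self.frame[col] = np.nan
        th = self.frame["theta"].to_numpy()
        if not (np.diff(th) > 0).all():
            raise ValidationError("theta must be strictly increasing in raw score")
        self.frame = self.frame.reset_index(drop=True)

    @property
    def max_score(self) -> int:
        return int(self.frame["raw_score"].max())

    def row(self, raw_score: int) -> pd.Series:
        sub = self.frame[self.frame["raw_score"] == raw_score]
        if sub.empty:
            raise KeyError(raw_score)
        return sub.iloc[0]

    def theta(self, raw_score: int) -> float:
        return float(self.row(raw_score)["theta"])

    def write_csv(self, path, comments: Sequence[str] = ()) -> None:
        from .io import _write_csv

        df = self.frame.copy()
        for col in ("theta", "se", "two_se", "scaled", "two_se_scaled"):
            df[col] = ["" if np.isnan(v) else "%.6f" % v for v in df[col]]
        df = df.rename(columns={"scaled": "scaled_0_100", "two_se_scaled": "two_se_0_100"})
        _write_csv(df, path, comments)

    @classmethod
    def read_csv(cls, path) -> "ScoreToMeasureTable":
        df = pd.read_csv(path, comment="#")
        df = df.rename(columns={"scaled_0_100": "scaled", "two_se_0_100": "two_se_scaled"})
        return cls(frame=df)


def score_to_measure(
    bank: ItemBank,
    item_subset: Sequence[str] | None = None,
    epsilon: float = 0.3,
) -> ScoreToMeasureTable:
    """Score-to-measure conversion table for an item set.

    One row per raw score 0..K; interior scores use the ML estimate, extreme
    scores the epsilon-adjusted extrapolation.
    """
    ids = list(item_subset) if item_subset is not None else bank.item_ids
    if not ids:
        raise ValidationError("empty item subset")
    d = bank.difficulties(ids)
    k = d.size
    rows = []
    for r in range(k + 1):
        if 0 < r < k:
            theta, se = person_ml_estimate(r, d)
        else:
            theta, se = extreme_score_estimate(r, d, epsilon)
        rows.append((r, theta, se, 2.0 * se))
    frame = pd.DataFrame(rows, columns=["raw_score", "theta", "se", "two_se"])
    return ScoreToMeasureTable(frame=frame, item_ids=tuple(ids))
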