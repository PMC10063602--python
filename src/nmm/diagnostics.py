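"""Measurement-property diagnostics for a calibrated dichotomous item bank.

Six complementary checks, mirroring standard Rasch quality assurance:

* targeting -- person vs item location distributions;
* item fit -- standardized (outfit-based) fit residuals with the
  conventional +/-2.5 bounds, and class-interval chi-square tests with
  Bonferroni-adjusted p-values;
* differential item functioning (DIF) -- two-way ANOVA of standardized
  residuals on subgroup x ability class interval (uniform DIF = main
  effect, non-uniform DIF = interaction);
* local dependency -- residual correlations against a relative cut-off
  (0.20 above the mean off-diagonal correlation);
* dimensionality -- Smith's method: split items by the sign of their
  loading on the first principal component of the residual correlation
  matrix, re-estimate each person on both subsets and count independent
  t-tests outside +/-1.96 (unidimensionality supported at <= 5%);
* reliability -- the person separation index (PSI), the proportion of
  true variance in the observed person-measure variance.

Extreme persons (raw score 0 or maximum) are excluded from residual-based
diagnostics: their residuals are degenerate.  They do enter the PSI when
requested, via their extrapolated measures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats
from statsmodels.stats.anova import anova_lm

from .exceptions import ValidationError
from .io import ItemBank, ResponseMatrix
from .rasch import (
    PersonMeasure,
    extreme_score_estimate,
    measures_frame,
    person_ml_estimate,
    rasch_probability,
)

FIT_RESIDUAL_BOUND = 2.5
T_CRITICAL = 1.96
LD_RELATIVE_CUTOFF = 0.20


def _interior_measures(measures: Sequence[PersonMeasure]) -> pd.DataFrame:
    mf = measures_frame(measures)
    return mf[~mf["extreme"]]


def expected_probabilities(
    rm: ResponseMatrix, bank: ItemBank, measures: Sequence[PersonMeasure]
) -> pd.DataFrame:
    """Model pass probabilities for non-extreme persons (NaN where missing)."""
    mf = _interior_measures(measures)
    idx = [rm.person_ids.index(pid) for pid in mf.index]
    theta = mf["theta"].to_numpy()
    delta = bank.difficulties(rm.items)
    p = rasch_probability(theta[:, None], delta[None, :])
    p = np.where(np.isnan(rm.values[idx]), np.nan, p)
    return pd.DataFrame(p, index=mf.index, columns=rm.items)


def standardized_residuals(
    rm: ResponseMatrix, bank: ItemBank, measures: Sequence[PersonMeasure]
) -> pd.DataFrame:
    """z_vi = (x_vi - P_vi) / sqrt(P_vi (1 - P_vi)) for administered responses.

    Rows are non-extreme persons; missing responses stay missing.
    """
    p = expected_probabilities(rm, bank, measures)
    idx = [rm.person_ids.index(pid) for pid in p.index]
    x = pd.DataFrame(rm.values[idx], index=p.index, columns=rm.items)
    return (x - p) / np.sqrt(p * (1.0 - p))


# ---------------------------------------------------------------------------
# Class intervals
# ---------------------------------------------------------------------------


@dataclass
class ClassIntervalAssignment:
    """Partition of persons into ability-ordered, equal-count classes."""

    assignment: pd.Series  # person_id -> class index 1..G
    boundaries: np.ndarray  # logit cut points between adjacent classes

    @property
    def n_classes(self) -> int:
        return int(self.assignment.max())


def class_intervals(
    measures: Sequence[PersonMeasure] | pd.DataFrame, n_classes: int = 5
) -> ClassIntervalAssignment:
    """Split non-extreme persons into ``n_classes`` equal-count ability classes."""
    mf = (
        measures
        if isinstance(measures, pd.DataFrame)
        else _interior_measures(measures)
    )
    if n_classes < 2:
        raise ValidationError("at least 2 class intervals are required")
    if len(mf) < n_classes:
        raise ValidationError(
            f"cannot form {n_classes} non-empty classes from {len(mf)} persons"
        )
    order = mf["theta"].sort_values(kind="mergesort")
    chunks = np.array_split(np.arange(len(order)), n_classes)
    assignment = pd.Series(index=mf.index, dtype=int, name="class")
    bounds = []
    for g, chunk in enumerate(chunks, start=1):
        ids = order.index[chunk]
        assignment.loc[ids] = g
        if g < n_classes:
            hi = order.iloc[chunk[-1]]
            lo_next = order.iloc[chunk[-1] + 1]
            bounds.append(0.5 * (hi + lo_next))
    return ClassIntervalAssignment(assignment=assignment, boundaries=np.array(bounds))


# ---------------------------------------------------------------------------
# Item fit
# ---------------------------------------------------------------------------


def item_fit_residuals(
    z: pd.DataFrame, p: pd.DataFrame, min_n: int = 10
) -> pd.DataFrame:
    """Standardized item fit residuals from outfit mean-squares.

    The outfit mean-square u_i = mean(z^2) over the item's responders is
    mapped to an approximate N(0,1) scale by the Wilson-Hilferty cube-root
    transform, with the variance of u_i taken from the model-implied
    kurtosis of z^2 under the Rasch model.  |value| > 2.5 flags misfit
    (positive: noisier than the model; negative: overly deterministic).
    Items with fewer than ``min_n`` responders get a low-n warning flag.
    """
    rows = []
    for item in z.columns:
        zi = z[item].dropna()
        n = len(zi)
        if n == 0:
            rows.append((item, np.nan, np.nan, 0, True, False))
            continue
        pi = p.loc[zi.index, item].to_numpy()
        u = float((zi**2).mean())
        # E[z^4] for a Bernoulli residual: (1-P)^2/P + P^2/(1-P)
        kurt = (1.0 - pi) ** 2 / pi + pi**2 / (1.0 - pi)
        var_u = float(np.sum(kurt - 1.0)) / n**2
        q = np.sqrt(max(var_u, 1e-12))
        fit = (u ** (1.0 / 3.0) - 1.0) * (3.0 / q) + q / 3.0
        rows.append((item, fit, u, n, n < min_n, abs(fit) > FIT_RESIDUAL_BOUND))
    return pd.DataFrame(
        rows,
        columns=["item_id", "fit_residual", "outfit_ms", "n", "low_n", "flagged"],
    ).set_index("item_id")


def item_chi_square(
    rm: ResponseMatrix,
    bank: ItemBank,
    measures: Sequence[PersonMeasure],
    n_classes: int = 5,
) -> pd.DataFrame:
    """Class-interval chi-square item fit tests.

    chi2_i = sum_g (O_g - E_g)^2 / V_g over ability classes, with O the
    observed class total, E the summed model probabilities and V the summed
    Bernoulli variances; df = (number of effective classes) - 1.  Classes
    whose variance is (numerically) zero are merged with a neighbour.  The
    Bonferroni factor is the number of items in the analysis.
    """
    z_index_mf = _interior_measures(measures)
    ci = class_intervals(z_index_mf, n_classes)
    p = expected_probabilities(rm, bank, measures)
    idx = [rm.person_ids.index(pid) for pid in p.index]
    x = pd.DataFrame(rm.values[idx], index=p.index, columns=rm.items)
    n_items = rm.n_items

    rows = []
    for item in rm.items:
        ok = x[item].notna()
        if ok.sum() == 0:
            rows.append((item, np.nan, 0, np.nan, np.nan))
            continue
        cls = ci.assignment[ok]
        o = x.loc[ok, item].groupby(cls).sum()
        e = p.loc[ok, item].groupby(cls).sum()
        var = (p.loc[ok, item] * (1 - p.loc[ok, item])).groupby(cls).sum()
        # merge (numerically) empty/degenerate classes into their neighbour
        o_l, e_l, v_l = [], [], []
        for g in o.index:
            if v_l and var[g] < 1e-10:
                o_l[-1] += o[g]
                e_l[-1] += e[g]
                v_l[-1] += var[g]
            else:
                o_l.append(o[g])
                e_l.append(e[g])
                v_l.append(var[g])
        # a degenerate leading class could not merge backwards; merge forwards
        while len(v_l) > 1 and v_l[0] < 1e-10:
            o_l[1] += o_l[0]
            e_l[1] += e_l[0]
            v_l[1] += v_l[0]
            o_l, e_l, v_l = o_l[1:], e_l[1:], v_l[1:]
        o_a, e_a, v_a = map(np.asarray, (o_l, e_l, v_l))
        valid = v_a > 1e-10
        if valid.sum() < 2:
            rows.append((item, np.nan, 0, np.nan, np.nan))
            continue
        chi2 = float(((o_a[valid] - e_a[valid]) ** 2 / v_a[valid]).sum())
        df = int(valid.sum()) - 1
        pval = float(stats.chi2.sf(chi2, df))
        rows.append((item, chi2, df, pval, min(1.0, pval * n_items)))
    return pd.DataFrame(
        rows, columns=["item_id", "chi_square", "chi_df", "chi_p", "chi_p_bonferroni"]
    ).set_index("item_id")


# ---------------------------------------------------------------------------
# Differential item functioning
# ---------------------------------------------------------------------------


def dif_anova(
    z: pd.DataFrame,
    groups: pd.Series,
    classes: ClassIntervalAssignment,
) -> pd.DataFrame:
    """Two-way ANOVA of standardized residuals on subgroup x class interval.

    Uniform DIF is the subgroup main effect; non-uniform DIF is the
    subgroup x class interaction.  Type-II sums of squares are used so
    unbalanced (or empty) subgroup x class cells are handled by the general
    linear model.  Bonferroni adjustment divides alpha by the item count.
    """
    common = z.index.intersection(groups.index)
    glab = groups.loc[common].astype(str)
    if glab[glab != "NA"].nunique() < 2:
        raise ValidationError("DIF analysis requires at least two subgroups")
    n_items = z.shape[1]
    rows = []
    for item in z.columns:
        d = pd.DataFrame(
            {
                "z": z.loc[common, item],
                "g": glab,
                "c": classes.assignment.reindex(common),
            }
        ).dropna()
        d = d[d["g"] != "NA"]
        if d["g"].nunique() < 2 or d["c"].nunique() < 2:
            rows.append((item, np.nan, np.nan, np.nan, np.nan))
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.ols("z ~ C(g) * C(c)", data=d).fit()
            tab = anova_lm(model, typ=2)
        gp = float(tab.loc["C(g)", "PR(>F)"])
        ip = float(tab.loc["C(g):C(c)", "PR(>F)"])
        rows.append((item, gp, ip, min(1.0, gp * n_items), min(1.0, ip * n_items)))
    return pd.DataFrame(
        rows,
        columns=[
            "item_id",
            "dif_group_p",
            "dif_interaction_p",
            "dif_group_p_bonferroni",
            "dif_interaction_p_bonferroni",
        ],
    ).set_index("item_id")


# ---------------------------------------------------------------------------
# Local dependency
# ---------------------------------------------------------------------------


@dataclass
class LocalDependencyResult:
    corr: pd.DataFrame
    mean_offdiag: float
    flagged_pairs: list[tuple[str, str]]


def local_dependency(
    z: pd.DataFrame,
    relative_cutoff: float = LD_RELATIVE_CUTOFF,
    min_overlap: int = 3,
) -> LocalDependencyResult:
    """Residual correlations against the relative cut-off.

    A pair is locally dependent when its pairwise-complete Pearson residual
    correlation exceeds the mean off-diagonal correlation by more than
    ``relative_cutoff`` (0.20 by default).
    """
    if z.shape[1] < 3:
        raise ValidationError("local dependency needs at least 3 items")
    constant = [c for c in z.columns if z[c].dropna().nunique() <= 1]
    if constant:
        warnings.warn(
            f"items with constant residuals skipped in LD: {constant}",
            stacklevel=2,
        )
    corr = z.corr(min_periods=min_overlap)
    k = corr.shape[0]
    off = corr.values[np.triu_indices(k, 1)]
    valid = off[~np.isnan(off)]
    qbar = float(valid.mean()) if valid.size else np.nan
    flagged = []
    for a in range(k):
        for b in range(a + 1, k):
            q = corr.iat[a, b]
            if not np.isnan(q) and q > qbar + relative_cutoff:
                flagged.append((corr.index[a], corr.columns[b]))
    return LocalDependencyResult(corr=corr, mean_offdiag=qbar, flagged_pairs=flagged)


# ---------------------------------------------------------------------------
# Dimensionality (Smith's method)
# ---------------------------------------------------------------------------


@dataclass
class DimensionalityResult:
    pct_t_outside: float
    positive_items: list[str]
    negative_items: list[str]
    n_tested: int
    status: str  # "ok" or "degenerate"


def smith_dimensionality(
    rm: ResponseMatrix,
    bank: ItemBank,
    z: pd.DataFrame,
    epsilon: float = 0.3,
    t_critical: float = T_CRITICAL,
) -> DimensionalityResult:
    """Smith's principal-component test of unidimensionality.

    The first principal component of the residual correlation matrix splits
    items into positively and negatively loading subsets.  Each person's
    ability is estimated separately from the two subsets (difficulties held
    at the calibrated bank values), and an independent t statistic
    t = (theta+ - theta-) / sqrt(se+^2 + se-^2) is computed.  The percentage
    of |t| > 1.96 should not exceed 5% under unidimensionality.
    """
    if z.shape[1] < 4:
        raise ValidationError("dimensionality assessment needs at least 4 items")
    if z.shape[0] < 30:
        raise ValidationError("dimensionality assessment needs at least 30 persons")
    corr = z.corr(min_periods=3).to_numpy()
    corr = np.where(np.isnan(corr), 0.0, corr)
    np.fill_diagonal(corr, 1.0)
    eigvals, eigvecs = np.linalg.eigh(corr)
    pc1 = eigvecs[:, -1]
    if pc1[np.argmax(np.abs(pc1))] < 0:
        pc1 = -pc1
    pos = [c for c, l in zip(z.columns, pc1) if l >= 0]
    neg = [c for c, l in zip(z.columns, pc1) if l < 0]
    if len(pos) < 2 or len(neg) < 2:
        return DimensionalityResult(np.nan, pos, neg, 0, "degenerate")

    def subset_theta(person_id: str, subset: list[str]):
        row = rm.values[rm.person_ids.index(person_id)]
        cols = [rm.items.index(i) for i in subset]
        x = row[cols]
        ok = ~np.isnan(x)
        if ok.sum() < 2:
            return None
        ids = [subset[j] for j in np.flatnonzero(ok)]
        d = bank.difficulties(ids)
        r = int(x[ok].sum())
        if 0 < r < len(ids):
            return person_ml_estimate(r, d)
        return extreme_score_estimate(r, d, epsilon)

    cache: dict[tuple, tuple[float, float] | None] = {}
    ts = []
    for pid in z.index:
        res_p = subset_theta(pid, pos)
        res_n = subset_theta(pid, neg)
        if res_p is None or res_n is None:
            continue
        tp, sp = res_p
        tn, sn = res_n
        ts.append((tp - tn) / np.sqrt(sp**2 + sn**2))
    ts = np.asarray(ts)
    pct = float(100.0 * np.mean(np.abs(ts) > t_critical)) if ts.size else np.nan
    return DimensionalityResult(pct, pos, neg, int(ts.size), "ok")


# ---------------------------------------------------------------------------
# Reliability and targeting
# ---------------------------------------------------------------------------


def psi(measures: Sequence[PersonMeasure], include_extremes: bool = True) -> float:
    """Person separation index: (V - M) / V.

    V is the sample variance of the person measures and M the mean squared
    standard error -- the proportion of true variance in the total variance.
    Returns NaN when V is zero (undefined).
    """
    mf = measures_frame(measures)
    if not include_extremes:
        mf = mf[~mf["extreme"]]
    if len(mf) < 2:
        raise ValidationError("PSI requires at least 2 persons")
    v = float(mf["theta"].var(ddof=1))
    if v <= 0:
        return float("nan")
    m = float((mf["se"] ** 2).mean())
    return (v - m) / v


@dataclass
class TargetingSummary:
    person_mean: float
    person_sd: float
    person_range: tuple[float, float]
    item_mean: float
    item_range: tuple[float, float]


def targeting_summary(
    measures: Sequence[PersonMeasure], bank: ItemBank
) -> TargetingSummary:
    """Person vs item location summary (the closer the means, the better)."""
    mf = measures_frame(measures)
    d = bank.difficulties()
    theta = mf["theta"].to_numpy()
    sd = float(np.std(theta, ddof=1)) if len(theta) > 1 else float("nan")
    return TargetingSummary(
        person_mean=float(theta.mean()),
        person_sd=sd,
        person_range=(float(theta.min()), float(theta.max())),
        item_mean=float(d.mean()),
        item_range=(float(d.min()), float(d.max())),
    )


# ---------------------------------------------------------------------------
# Assembled fit report
# ---------------------------------------------------------------------------


@dataclass
class FitReport:
    """Per-item diagnostics plus test-level summary for one analysis."""

    per_item: pd.DataFrame
    targeting: TargetingSummary
    ld: LocalDependencyResult
    dimensionality: DimensionalityResult
    psi_with_extremes: float
    psi_without_extremes: float

    def summary(self) -> dict:
        ld_total = self.ld.corr.shape[0] * (self.ld.corr.shape[0] - 1) / 2
        return {
            "n_items": int(self.per_item.shape[0]),
            "person_mean": self.targeting.person_mean,
            "person_sd": self.targeting.person_sd,
            "person_range": list(self.targeting.person_range),
            "item_mean": self.targeting.item_mean,
            "item_range": list(self.targeting.item_range),
            "n_fit_residuals_outside": int(self.per_item["flagged"].sum()),
            "n_significant_chi_square": int(
                (self.per_item["chi_p_bonferroni"] < 0.05).sum()
            ),
            "n_dif_diagnosis": int(
                (self.per_item.get("dif_diagnosis_p_bonferroni", pd.Series(dtype=float)) < 0.05).sum()
            ),
            "n_dif_gender": int(
                (self.per_item.get("dif_gender_p_bonferroni", pd.Series(dtype=float)) < 0.05).sum()
            ),
            "pct_ld_pairs": (
                100.0 * len(self.ld.flagged_pairs) / ld_total if ld_total else np.nan
            ),
            "pct_t_outside": self.dimensionality.pct_t_outside,
            "psi_with_extremes": self.psi_with_extremes,
            "psi_without_extremes": self.psi_without_extremes,
        }


def fit_report(
    rm: ResponseMatrix,
    bank: ItemBank,
    measures: Sequence[PersonMeasure] | None = None,
    n_classes: int = 5,
    epsilon: float = 0.3,
) -> FitReport:
    """Run the full diagnostic battery for one calibrated analysis."""
    from .rasch import person_measures as _pm

    measures = measures if measures is not None else _pm(rm, bank, epsilon)
    z = standardized_residuals(rm, bank, measures)
    p = expected_probabilities(rm, bank, measures)
    fitres = item_fit_residuals(z, p)
    chi = item_chi_square(rm, bank, measures, n_classes)
    per_item = fitres.join(chi)

    ci = class_intervals(measures, n_classes)
    pframe = rm.person_frame().set_index("person_id")
    for factor, col in (("diagnosis", "group"), ("gender", "gender")):
        labels = pframe[col]
        usable = labels[labels != "NA"]
        if usable.nunique() >= 2:
            dif = dif_anova(z, labels, ci)
            per_item = per_item.join(
                dif.rename(
                    columns={
                        "dif_group_p": f"dif_{factor}_p",
                        "dif_interaction_p": f"dif_{factor}_interaction_p",
                        "dif_group_p_bonferroni": f"dif_{factor}_p_bonferroni",
                        "dif_interaction_p_bonferroni": f"dif_{factor}_interaction_p_bonferroni",
                    }
                )
            )
    ld = local_dependency(z)
    dim = smith_dimensionality(rm, bank, z, epsilon)
    return FitReport(
        per_item=per_item,
        targeting=targeting_summary(measures, bank),
        ld=ld,
        dimensionality=dim,
        psi_with_extremes=psi(measures, include_extremes=True),
        psi_without_extremes=psi(measures, include_extremes=False),
    )
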