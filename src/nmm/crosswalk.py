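"""Anchored co-calibration, conversion tables and the 0-100 transform.

A crosswalk places raw scores from different instruments on one common
metric: legacy instruments are calibrated *around* anchored item
difficulties taken from the reference bank, score-to-measure tables are
built for each instrument, and every legacy raw score is matched to the
reference-table row with the nearest logit location.

The 0-100 transform is the linear map that sends 0 logits (the centre of a
sum-to-zero calibrated bank) to 50 and the zero-raw-score extrapolated
measure to 0; measurement uncertainties (2SE, coverage factor 2) propagate
with the same slope.  The maximum raw score is reported as 100 by
convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import LinkageError, ValidationError
from .io import ItemBank, ResponseMatrix, _write_csv
from .rasch import ScoreToMeasureTable, cml_fit

__all__ = [
    "anchored_calibration",
    "ScaleTransform",
    "build_scale_transform",
    "to_0_100",
    "apply_transform",
    "CrosswalkTable",
    "nearest_match",
    "export_crosswalk",
    "read_crosswalk",
    "crosswalk_to_markdown",
]


def anchored_calibration(
    rm_legacy: ResponseMatrix,
    reference_bank: ItemBank,
    *,
    instruments: Mapping[str, str] | None = None,
    **fit_kwargs,
) -> ItemBank:
    """Calibrate a legacy instrument into the reference frame via anchors.

    Items shared with ``reference_bank`` are fixed at their reference
    difficulties; the remaining items are estimated around them (no
    sum-to-zero constraint, so the output lives in the reference frame).
    """
    shared = [
        it.item_id
        for it in reference_bank.items
        if it.item_id in rm_legacy.items and it.difficulty is not None
    ]
    if not shared:
        raise LinkageError(
            "legacy matrix shares no calibrated items with the reference bank"
        )
    anchor_map = {i: float(reference_bank[i].difficulty) for i in shared}
    inst = dict(instruments or {})
    for i in shared:
        inst.setdefault(i, reference_bank[i].instrument)
    return cml_fit(rm_legacy, anchors=anchor_map, instruments=inst, **fit_kwargs)


# ---------------------------------------------------------------------------
# 0-100 transform
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScaleTransform:
    """Linear logit -> 0-100 map anchored at theta=0 -> 50 and theta_low -> 0."""

    slope: float        # (0-100 units) per logit
    theta_low: float    # zero-raw-score extrapolated measure (logits)

    @property
    def intercept(self) -> float:
        return 50.0

    def __call__(self, theta: float) -> float:
        return 50.0 + self.slope * float(theta)


def build_scale_transform(table: ScoreToMeasureTable) -> ScaleTransform:
    """Scale transform from a reference score-to-measure table.

    The slope is fixed by mapping the raw-score-0 extrapolated measure to 0
    while theta = 0 maps to 50: slope = 50 / |theta(0)|.
    """
    theta_low = table.theta(0)
    if theta_low >= 0:
        raise ValidationError(
            f"zero-score measure must be negative, got {theta_low:.3f}"
        )
    return ScaleTransform(slope=50.0 / abs(theta_low), theta_low=theta_low)


def to_0_100(
    theta: float,
    two_se: float,
    transform: ScaleTransform,
    is_max_score: bool = False,
):
    """Scaled (0-100) value and 2SE for a logit measure.

    Values are clamped to [0, 100]; the maximum raw score is reported as
    100.00 by convention.  The 2SE propagates linearly (slope x 2SE).
    """
    scaled_two_se = transform.slope * float(two_se)
    if is_max_score:
        return 100.0, scaled_two_se
    value = float(np.clip(transform(theta), 0.0, 100.0))
    return value, scaled_two_se


def apply_transform(
    table: ScoreToMeasureTable, transform: ScaleTransform
) -> ScoreToMeasureTable:
    """Fill the ``scaled``/``two_se_scaled`` columns of a table."""
    frame = table.frame.copy()
    kmax = table.max_score
    scaled, scaled_2se = [], []
    for _, row in frame.iterrows():
        v, s = to_0_100(
            row["theta"], row["two_se"], transform, row["raw_score"] == kmax
        )
        scaled.append(v)
        scaled_2se.append(s)
    frame["scaled"] = scaled
    frame["two_se_scaled"] = scaled_2se
    return ScoreToMeasureTable(frame=frame, item_ids=table.item_ids)


# ---------------------------------------------------------------------------
# Nearest-location matching
# ---------------------------------------------------------------------------


@dataclass
class CrosswalkTable:
    """Reference score-to-measure rows with legacy scores matched by logit.

    ``matches[name]`` is indexed by the legacy raw score and records the
    matched reference (``ref_score``) row together with the legacy measure.
    Each legacy raw score appears exactly once; matching is monotone.
    """

    reference: ScoreToMeasureTable
    matches: dict[str, pd.DataFrame] = field(default_factory=dict)

    def add(self, legacy_table: ScoreToMeasureTable, name: str) -> None:
        ref_scores = self.reference.frame["raw_score"].to_numpy()
        ref_theta = self.reference.frame["theta"].to_numpy()
        rows = []
        for _, row in legacy_table.frame.iterrows():
            dist = np.abs(ref_theta - row["theta"])
            j = int(np.argmin(dist))  # ties resolve to the lower score
            rows.append(
                (
                    int(row["raw_score"]),
                    row["theta"],
                    row["two_se"],
                    int(ref_scores[j]),
                    ref_theta[j],
                )
            )
        df = pd.DataFrame(
            rows,
            columns=["score", "theta", "two_se", "ref_score", "ref_theta"],
        ).set_index("score")
        if not df["ref_score"].is_monotonic_increasing:
            raise ValidationError("crosswalk matching must be monotone")
        self.matches[name] = df

    def matched_reference_score(self, name: str, legacy_score: int) -> int:
        return int(self.matches[name].loc[legacy_score, "ref_score"])


def nearest_match(
    legacy_table: ScoreToMeasureTable,
    reference_table: ScoreToMeasureTable,
    name: str = "legacy",
) -> CrosswalkTable:
    """Match every legacy raw score to the nearest reference logit location."""
    if legacy_table.frame.empty or reference_table.frame.empty:
        raise ValidationError("both tables must be non-empty")
    cw = CrosswalkTable(reference=reference_table)
    cw.add(legacy_table, name)
    return cw


# ---------------------------------------------------------------------------
# Export / import
# ---------------------------------------------------------------------------


def _fmt(v: float) -> str:
    return "" if v is None or (isinstance(v, float) and np.isnan(v)) else "%.6f" % v


def export_crosswalk(cw: CrosswalkTable, path, comments: Sequence[str] = ()) -> None:
    """Write a conversion-table CSV: one row per reference raw score.

    Reference columns first (measure, 2SE and, when present, the 0-100
    columns), then per instrument the matched raw score with its measure and
    2SE.  Reference rows without a matching legacy score render as empty
    cells.
    """
    ref = cw.reference.frame
    out = pd.DataFrame(
        {
            "raw_score": ref["raw_score"].astype(int),
            "theta": ref["theta"].map(_fmt),
            "two_se": ref["two_se"].map(_fmt),
            "scaled_0_100": ref["scaled"].map(_fmt),
            "two_se_0_100": ref["two_se_scaled"].map(_fmt),
        }
    )
    for name, df in cw.matches.items():
        sc = {int(r): [] for r in ref["raw_score"]}
        th = {int(r): [] for r in ref["raw_score"]}
        se = {int(r): [] for r in ref["raw_score"]}
        for score, row in df.iterrows():
            r = int(row["ref_score"])
            sc[r].append(str(int(score)))
            th[r].append(_fmt(row["theta"]))
            se[r].append(_fmt(row["two_se"]))
        out[f"{name}_score"] = [";".join(sc[int(r)]) for r in ref["raw_score"]]
        out[f"{name}_theta"] = [";".join(th[int(r)]) for r in ref["raw_score"]]
        out[f"{name}_two_se"] = [";".join(se[int(r)]) for r in ref["raw_score"]]
    _write_csv(out, path, comments)


def read_crosswalk(path) -> CrosswalkTable:
    """Read a conversion-table CSV written by :func:`export_crosswalk`."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False, comment="#")
    ref = pd.DataFrame(
        {
            "raw_score": df["raw_score"].astype(int),
            "theta": pd.to_numeric(df["theta"]),
            "se": pd.to_numeric(df["two_se"]) / 2.0,
            "two_se": pd.to_numeric(df["two_se"]),
            "scaled": pd.to_numeric(df["scaled_0_100"].replace("", np.nan)),
            "two_se_scaled": pd.to_numeric(df["two_se_0_100"].replace("", np.nan)),
        }
    )
    cw = CrosswalkTable(reference=ScoreToMeasureTable(frame=ref))
    names = sorted(
        {c[: -len("_score")] for c in df.columns if c.endswith("_score") and c != "raw_score"}
    )
    for name in names:
        rows = []
        for _, row in df.iterrows():
            if not row[f"{name}_score"]:
                continue
            scores = row[f"{name}_score"].split(";")
            thetas = row[f"{name}_theta"].split(";")
            two_ses = row[f"{name}_two_se"].split(";")
            for s, t, u in zip(scores, thetas, two_ses):
                rows.append(
                    (
                        int(s),
                        float(t),
                        float(u),
                        int(row["raw_score"]),
                        float(row["theta"]),
                    )
                )
        cw.matches[name] = (
            pd.DataFrame(
                rows, columns=["score", "theta", "two_se", "ref_score", "ref_theta"]
            )
            .sort_values("score")
            .set_index("score")
        )
    return cw


def crosswalk_to_markdown(cw: CrosswalkTable) -> str:
    """Render a conversion table as GitHub-flavoured markdown."""
    ref = cw.reference.frame
    names = list(cw.matches)
    header = ["score", "measure", "2SE", "0-100", "2SE 0-100"] + [
        f"{n} score" for n in names
    ]
    lines = ["| " + " | ".join(header) + " |", "|" + "---|" * len(header)]
    for _, row in ref.iterrows():
        r = int(row["raw_score"])
        cells = [
            str(r),
            f"{row['theta']:.2f}",
            f"{row['two_se']:.2f}",
            "" if np.isnan(row["scaled"]) else f"{row['scaled']:.2f}",
            "" if np.isnan(row["two_se_scaled"]) else f"{row['two_se_scaled']:.2f}",
        ]
        for n in names:
            hit = cw.matches[n][cw.matches[n]["ref_score"] == r]
            cells.append(";".join(str(int(s)) for s in hit.index))
        lines.append("| " + " | ".join(cells) + " |")
    return "\n".join(lines)
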