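"""Instruments, item banks, persons and dichotomous response matrices.

The data model mirrors how item-banking studies organise their raw material:

* an :class:`ItemBank` is an ordered set of items, each with an instrument
  label and (once calibrated) a difficulty in logits with a standard error;
* a :class:`ResponseMatrix` holds persons x items pass/fail responses with
  arbitrary missingness, plus person metadata (diagnostic group, gender, age).

CSV conventions: comma-separated, UTF-8, mandatory header row.  Missing
values are written as empty cells; both ``""`` and ``"NA"`` are accepted on
read.  Lines starting with ``#`` are treated as comments (the CLI uses them
to record the run configuration).  Logits are written with 6 decimals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ParseError, UnusableDataError, ValidationError

#: Person-metadata column names reserved in response CSVs; all other columns
#: are interpreted as items.
RESERVED_COLUMNS = ("person_id", "group", "gender", "age")

DIAGNOSTIC_GROUPS = ("HC", "SCD", "MCI", "AD", "NA")
GENDERS = ("M", "F", "NA")

#: Instrument labels used by the NeuroMET memory item bank.  User-defined
#: labels are also accepted everywhere.
KNOWN_INSTRUMENTS = ("CBT", "DST", "RAVLT", "WLL_CERAD", "MMSE_MEM", "MMSE_OTHER")

_LOGIT_FMT = "%.6f"


@dataclass
class Item:
    """A single dichotomous item.

    Parameters
    ----------
    item_id:
        Unique identifier within a bank.
    instrument:
        Instrument (legacy test) the item belongs to; free-form string.
    difficulty:
        Task difficulty location in logits, or ``None`` when uncalibrated.
    se:
        Standard error of the difficulty in logits, or ``None``.
    anchored:
        Whether the difficulty is fixed (an anchor) rather than estimated.
    """

    item_id: str
    instrument: str = "NA"
    difficulty: float | None = None
    se: float | None = None
    anchored: bool = False

    def __post_init__(self) -> None:
        if not self.item_id:
            raise ValidationError("item_id must be a non-empty string")
        if self.anchored and self.difficulty is None:
            raise ValidationError(
                f"item {self.item_id!r}: anchored items require a difficulty"
            )


@dataclass
class ItemBank:
    """An ordered collection of items sharing one frame of reference."""

    items: list[Item]
    frame_id: str = ""

    def __post_init__(self) -> None:
        ids = [it.item_id for it in self.items]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate item_ids in bank: {dup}")

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self):
        return iter(self.items)

    def __getitem__(self, item_id: str) -> Item:
        for it in self.items:
            if it.item_id == item_id:
                return it
        raise KeyError(item_id)

    def __contains__(self, item_id: str) -> bool:
        return any(it.item_id == item_id for it in self.items)

    @property
    def item_ids(self) -> list[str]:
        return [it.item_id for it in self.items]

    def difficulties(self, item_ids: Sequence[str] | None = None) -> np.ndarray:
        """Difficulties (logits) for ``item_ids`` (default: every item).

        Raises if any requested item is uncalibrated.
        """
        ids = list(item_ids) if item_ids is not None else self.item_ids
        out = np.empty(len(ids))
        for k, iid in enumerate(ids):
            it = self[iid]
            if it.difficulty is None:
                raise ValidationError(f"item {iid!r} has no difficulty")
            out[k] = it.difficulty
        return out

    def subset(self, item_ids: Iterable[str]) -> "ItemBank":
        return ItemBank([replace(self[i]) for i in item_ids], frame_id=self.frame_id)

    def anchored_items(self) -> "ItemBank":
        return ItemBank(
            [replace(it) for it in self.items if it.anchored], frame_id=self.frame_id
        )

    def is_centered(self, tol: float = 1e-6) -> bool:
        """True when the free (non-anchored) difficulties sum to zero.

        This is the identification constraint of a freely calibrated bank.
        """
        free = [it.difficulty for it in self.items if not it.anchored]
        if not free or any(d is None for d in free):
            return False
        return abs(sum(free)) <= tol

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "item_id": [it.item_id for it in self.items],
                "instrument": [it.instrument for it in self.items],
                "difficulty": [it.difficulty for it in self.items],
                "se": [it.se for it in self.items],
                "anchored": [it.anchored for it in self.items],
            }
        )


@dataclass
class Person:
    """Person metadata attached to one assessment."""

    person_id: str
    group: str = "NA"
    gender: str = "NA"
    age: float = math.nan

    def __post_init__(self) -> None:
        if not self.person_id:
            raise ValidationError("person_id must be a non-empty string")
        if self.group not in DIAGNOSTIC_GROUPS:
            raise ValidationError(
                f"person {self.person_id!r}: group {self.group!r} not one of "
                f"{DIAGNOSTIC_GROUPS}"
            )
        if self.gender not in GENDERS:
            raise ValidationError(
                f"person {self.person_id!r}: gender {self.gender!r} not one of "
                f"{GENDERS}"
            )


@dataclass
class ResponseMatrix:
    """Persons x items dichotomous responses; ``NaN`` encodes missing."""

    persons: list[Person]
    items: list[str]
    values: np.ndarray  # float array, entries in {0.0, 1.0, nan}

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.persons), len(self.items)):
            raise ValidationError(
                f"response array shape {self.values.shape} does not match "
                f"{len(self.persons)} persons x {len(self.items)} items"
            )
        pids = [p.person_id for p in self.persons]
        if len(set(pids)) != len(pids):
            dup = sorted({i for i in pids if pids.count(i) > 1})
            raise ValidationError(f"duplicate person_ids: {dup}")
        if len(set(self.items)) != len(self.items):
            dup = sorted({i for i in self.items if self.items.count(i) > 1})
            raise ValidationError(f"duplicate item columns: {dup}")
        obs = self.values[~np.isnan(self.values)]
        if obs.size and not np.isin(obs, (0.0, 1.0)).all():
            bad = obs[~np.isin(obs, (0.0, 1.0))][0]
            raise ValidationError(f"responses must be 0, 1 or missing; found {bad!r}")

    # -- basic views -------------------------------------------------------
    @property
    def n_persons(self) -> int:
        return len(self.persons)

    @property
    def n_items(self) -> int:
        return len(self.items)

    @property
    def person_ids(self) -> list[str]:
        return [p.person_id for p in self.persons]

    def observed(self) -> np.ndarray:
        """Boolean mask of administered (non-missing) responses."""
        return ~np.isnan(self.values)

    def raw_scores(self) -> np.ndarray:
        """Per-person count of passes over administered items."""
        return np.nansum(self.values, axis=1).astype(int)

    def administered_counts(self) -> np.ndarray:
        return self.observed().sum(axis=1)

    def person_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "person_id": [p.person_id for p in self.persons],
                "group": [p.group for p in self.persons],
                "gender": [p.gender for p in self.persons],
                "age": [p.age for p in self.persons],
            }
        )

    def to_frame(self) -> pd.DataFrame:
        df = self.person_frame()
        resp = pd.DataFrame(self.values, columns=self.items)
        return pd.concat([df, resp], axis=1)

    def subset_items(self, item_ids: Sequence[str]) -> "ResponseMatrix":
        idx = [self.items.index(i) for i in item_ids]
        return ResponseMatrix(
            persons=[replace(p) for p in self.persons],
            items=list(item_ids),
            values=self.values[:, idx].copy(),
        )

    def validate_coverage(self) -> None:
        """Require at least one administered response per person and item."""
        obs = self.observed()
        empty_p = [p.person_id for p, k in zip(self.persons, obs.sum(axis=1)) if k == 0]
        if empty_p:
            raise ValidationError(f"persons with no administered items: {empty_p}")
        empty_i = [i for i, k in zip(self.items, obs.sum(axis=0)) if k == 0]
        if empty_i:
            raise ValidationError(f"items with no responses: {empty_i}")


# ---------------------------------------------------------------------------
# CSV readers / writers
# ---------------------------------------------------------------------------


def _write_csv(df: pd.DataFrame, path, comments: Sequence[str] = ()) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for line in comments:
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)


def read_responses(path) -> ResponseMatrix:
    """Read a persons x items response CSV.

    The header row names the items; the reserved columns ``person_id``,
    ``group``, ``gender`` and ``age`` carry person metadata.  Cells must be
    ``0``, ``1`` or empty/``NA`` (missing).
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False, comment="#")
    if "person_id" not in df.columns:
        raise ParseError(f"{path}: missing required column 'person_id'")
    item_cols = [c for c in df.columns if c not in RESERVED_COLUMNS]
    if not item_cols:
        raise ParseError(f"{path}: no item columns found")

    persons = []
    for _, row in df.iterrows():
        age_raw = str(row.get("age", "")).strip()
        age = math.nan if age_raw in ("", "NA") else float(age_raw)
        grp = str(row.get("group", "NA")).strip() or "NA"
        gen = str(row.get("gender", "NA")).strip() or "NA"
        persons.append(Person(str(row["person_id"]), grp, gen, age))

    values = np.empty((len(df), len(item_cols)))
    for j, col in enumerate(item_cols):
        for i, cell in enumerate(df[col].astype(str)):
            c = cell.strip()
            if c in ("", "NA"):
                values[i, j] = np.nan
            elif c == "0":
                values[i, j] = 0.0
            elif c == "1":
                values[i, j] = 1.0
            else:
                raise ParseError(
                    f"{path}: invalid response {cell!r} for person "
                    f"{persons[i].person_id!r}, item {col!r} (expected 0, 1 or empty)"
                )
    rm = ResponseMatrix(persons=persons, items=item_cols, values=values)
    rm.validate_coverage()
    return rm


def write_responses(rm: ResponseMatrix, path, comments: Sequence[str] = ()) -> None:
    df = rm.person_frame()
    df["age"] = [("" if math.isnan(a) else repr(float(a))) for a in df["age"]]
    for j, col in enumerate(rm.items):
        df[col] = [
            "" if np.isnan(v) else str(int(v)) for v in rm.values[:, j]
        ]
    _write_csv(df, path, comments)


def _parse_float(cell: str, what: str) -> float | None:
    c = cell.strip()
    if c in ("", "NA"):
        return None
    try:
        return float(c)
    except ValueError as exc:
        raise ParseError(f"invalid {what}: {cell!r}") from exc


def read_item_bank(path) -> ItemBank:
    """Read an item-bank CSV (item_id, instrument, difficulty, se, anchored)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False, comment="#")
    if "item_id" not in df.columns:
        raise ParseError(f"{path}: missing required column 'item_id'")
    items = []
    for _, row in df.iterrows():
        anch_raw = str(row.get("anchored", "")).strip().lower()
        anchored = anch_raw in ("1", "true", "yes")
        items.append(
            Item(
                item_id=str(row["item_id"]),
                instrument=str(row.get("instrument", "NA")).strip() or "NA",
                difficulty=_parse_float(str(row.get("difficulty", "")), "difficulty"),
                se=_parse_float(str(row.get("se", "")), "se"),
                anchored=anchored,
            )
        )
    return ItemBank(items)


def write_item_bank(bank: ItemBank, path, comments: Sequence[str] = ()) -> None:
    df = bank.to_frame()
    for col in ("difficulty", "se"):
        df[col] = [
            "" if v is None or (isinstance(v, float) and math.isnan(v)) else _LOGIT_FMT % v
            for v in df[col]
        ]
    df["anchored"] = df["anchored"].map({True: "1", False: "0"})
    _write_csv(df, path, comments)


def read_anchors(path) -> ItemBank:
    """Read an anchor CSV (item_id, difficulty) as an all-anchored bank."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False, comment="#")
    for col in ("item_id", "difficulty"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    items = []
    for _, row in df.iterrows():
        d = _parse_float(str(row["difficulty"]), "difficulty")
        if d is None:
            raise ParseError(
                f"{path}: anchor {row['item_id']!r} has no difficulty"
            )
        inst = str(row.get("instrument", "NA")).strip() or "NA"
        items.append(Item(str(row["item_id"]), inst, d, None, anchored=True))
    return ItemBank(items)


def write_anchors(bank: ItemBank, path, comments: Sequence[str] = ()) -> None:
    rows = [(it.item_id, it.difficulty) for it in bank.items if it.anchored]
    df = pd.DataFrame(rows, columns=["item_id", "difficulty"])
    df["difficulty"] = [_LOGIT_FMT % d for d in df["difficulty"]]
    _write_csv(df, path, comments)


# ---------------------------------------------------------------------------
# Extreme screening
# ---------------------------------------------------------------------------


@dataclass
class ExtremeScreenResult:
    """Outcome of iterative extreme screening.

    ``matrix`` excludes extreme items (they cannot be calibrated) but keeps
    every person: extreme persons are flagged so they can later receive
    extrapolated measures rather than contribute to item estimation.
    """

    matrix: ResponseMatrix
    extreme_persons: list[str]
    extreme_items: list[str]


def extreme_screen(rm: ResponseMatrix) -> ExtremeScreenResult:
    """Flag extreme persons/items, iterating until stable.

    A person is extreme when they score 0 or maximum on their administered
    (non-extreme) items; an item is extreme when its observed responses among
    non-extreme persons are all 0 or all 1 (or it has none).  Removing an
    all-1 item can create a new all-0 person, so the two screens alternate
    until a fixed point.
    """
    obs = rm.observed()
    vals = rm.values
    person_ok = np.ones(rm.n_persons, dtype=bool)
    item_ok = np.ones(rm.n_items, dtype=bool)

    changed = True
    while changed:
        changed = False
        # items judged on responses of non-extreme persons
        for j in np.flatnonzero(item_ok):
            mask = obs[:, j] & person_ok
            n = int(mask.sum())
            s = int(vals[mask, j].sum()) if n else 0
            if n == 0 or s == 0 or s == n:
                item_ok[j] = False
                changed = True
        # persons judged on non-extreme items
        for i in np.flatnonzero(person_ok):
            mask = obs[i, :] & item_ok
            n = int(mask.sum())
            s = int(vals[i, mask].sum()) if n else 0
            if n == 0 or s == 0 or s == n:
                person_ok[i] = False
                changed = True

    if not item_ok.any():
        raise UnusableDataError("every item is extreme; no item can be calibrated")

    keep_items = [it for it, ok in zip(rm.items, item_ok) if ok]
    screened = rm.subset_items(keep_items)
    return ExtremeScreenResult(
        matrix=screened,
        extreme_persons=[p.person_id for p, ok in zip(rm.persons, person_ok) if not ok],
        extreme_items=[it for it, ok in zip(rm.items, item_ok) if not ok],
    )
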