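"""Synthetic cohorts with the structure of a multi-instrument memory study.

The generator emulates a 360-assessment cohort spanning the Alzheimer's
continuum: four diagnostic groups (healthy controls, subjective cognitive
decline, mild cognitive impairment, AD) with normal within-group ability
distributions, a 57-item bank drawn from five instruments whose difficulty
layouts differ (block/digit tasks wide with interior gaps, word-list items
compact around 0 logits), and whole-instrument missingness patterns
(alternate-version word-list administrations, a sub-study that skipped two
instruments).

Responses are Bernoulli draws from the dichotomous Rasch model, so the
generator doubles as the simulation oracle for parameter-recovery tests;
``inject_violation`` adds controlled violations (DIF, local dependency, a
second dimension, random misfit) as positive controls for the diagnostics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .io import Item, ItemBank, Person, ResponseMatrix
from .rasch import rasch_probability

__all__ = [
    "GroupSpec",
    "InstrumentLayout",
    "MissingnessRule",
    "CohortSpec",
    "default_neuromet_spec",
    "SimulationResult",
    "simulate",
    "inject_violation",
]


@dataclass(frozen=True)
class GroupSpec:
    """One diagnostic group: size and ability distribution (logits)."""

    name: str
    n: int
    mean: float
    sd: float

    def __post_init__(self):
        if self.n < 0:
            raise ValidationError("group sizes must be >= 0")
        if self.sd <= 0:
            raise ValidationError("group ability SDs must be > 0")


@dataclass(frozen=True)
class InstrumentLayout:
    """Difficulty layout of one instrument's items.

    Difficulties are drawn on a stratified grid over ``[lo, hi]`` with the
    ``gaps`` intervals removed, reproducing wide-with-gaps (block/digit) or
    compact (word-list) targeting structures.
    """

    name: str
    count: int
    lo: float
    hi: float
    gaps: tuple[tuple[float, float], ...] = ()


@dataclass(frozen=True)
class MissingnessRule:
    """``n`` assessments (optionally restricted to ``group``) miss whole instruments."""

    instruments: tuple[str, ...]
    n: int
    group: str | None = None


@dataclass
class CohortSpec:
    groups: tuple[GroupSpec, ...]
    instruments: tuple[InstrumentLayout, ...]
    missingness: tuple[MissingnessRule, ...] = ()
    seed: int = 0

    @property
    def n_persons(self) -> int:
        return sum(g.n for g in self.groups)

    @property
    def n_items(self) -> int:
        return sum(l.count for l in self.instruments)


#: Ability means/SDs per diagnostic group and per-instrument item counts of
#: the 57-item memory metric preset.
NEUROMET_GROUPS = (
    GroupSpec("HC", 87, 0.84, 0.95),
    GroupSpec("SCD", 167, 0.75, 0.85),
    GroupSpec("MCI", 52, 0.23, 0.84),
    GroupSpec("AD", 54, -0.33, 1.31),
)

NEUROMET_INSTRUMENTS = (
    InstrumentLayout("CBT", 14, -6.0, 7.1, ((-4.5, -2.5), (1.5, 3.5))),
    InstrumentLayout("DST", 12, -5.1, 5.4, ((-4.0, -2.0), (1.0, 3.0))),
    InstrumentLayout("RAVLT", 15, -1.65, 1.34),
    InstrumentLayout("WLL_CERAD", 10, -1.45, 1.76),
    InstrumentLayout("MMSE_MEM", 6, -3.9, 3.2),
)

NEUROMET_MISSINGNESS = (
    MissingnessRule(("RAVLT",), 41),
    MissingnessRule(("WLL_CERAD", "MMSE_MEM"), 88, "SCD"),
    MissingnessRule(("DST",), 2, "AD"),
)


def default_neuromet_spec(seed: int = 0) -> CohortSpec:
    """The 360-assessment, 57-item default cohort specification."""
    return CohortSpec(
        groups=NEUROMET_GROUPS,
        instruments=NEUROMET_INSTRUMENTS,
        missingness=NEUROMET_MISSINGNESS,
        seed=seed,
    )


def _stratified_draw(
    rng: np.random.Generator, layout: InstrumentLayout
) -> np.ndarray:
    """Draw ``count`` difficulties on a stratified grid over the gapped support."""
    segments = []
    lo = layout.lo
    for g_lo, g_hi in sorted(layout.gaps):
        if g_lo > lo:
            segments.append((lo, g_lo))
        lo = max(lo, g_hi)
    if layout.hi > lo:
        segments.append((lo, layout.hi))
    lengths = np.array([b - a for a, b in segments])
    total = lengths.sum()
    cum = np.concatenate([[0.0], np.cumsum(lengths)])

    def position(u: float) -> float:
        x = u * total
        k = int(np.searchsorted(cum, x, side="right")) - 1
        k = min(k, len(segments) - 1)
        return segments[k][0] + (x - cum[k])

    m = layout.count
    u = (np.arange(m) + rng.uniform(0.05, 0.95, size=m)) / m
    return np.array([position(v) for v in u])


@dataclass
class SimulationResult:
    """Simulated responses plus ground truth for recovery tests."""

    responses: ResponseMatrix
    bank: ItemBank                 # true difficulties
    abilities: pd.Series           # person_id -> true theta
    spec: CohortSpec


def simulate(spec: CohortSpec) -> SimulationResult:
    """Draw a cohort: abilities per group, Rasch responses, missingness.

    Identical seeds give identical output.
    """
    if spec.n_persons == 0:
        raise ValidationError("cohort has no persons")
    if spec.n_items == 0:
        raise ValidationError("cohort has no items")
    rng = np.random.default_rng(spec.seed)

    items: list[Item] = []
    for layout in spec.instruments:
        diffs = _stratified_draw(rng, layout)
        for k, d in enumerate(diffs, start=1):
            items.append(Item(f"{layout.name}_{k:02d}", layout.name, float(d)))
    bank = ItemBank(items, frame_id="truth")
    deltas = bank.difficulties()

    persons: list[Person] = []
    thetas = []
    width = len(str(spec.n_persons))
    pid = 0
    for grp in spec.groups:
        draws = rng.normal(grp.mean, grp.sd, size=grp.n)
        genders = rng.choice(["F", "M"], size=grp.n)
        ages = np.round(rng.normal(70.0, 7.0, size=grp.n)).clip(55, 90)
        for t, gen, age in zip(draws, genders, ages):
            pid += 1
            persons.append(Person(f"P{pid:0{width}d}", grp.name, str(gen), float(age)))
            thetas.append(float(t))
    thetas = np.asarray(thetas)

    prob = rasch_probability(thetas[:, None], deltas[None, :])
    values = (rng.random(prob.shape) < prob).astype(float)

    inst_cols = {
        layout.name: [j for j, it in enumerate(items) if it.instrument == layout.name]
        for layout in spec.instruments
    }
    group_idx = {
        grp.name: [i for i, p in enumerate(persons) if p.group == grp.name]
        for grp in spec.groups
    }
    for rule in spec.missingness:
        eligible = (
            np.arange(len(persons))
            if rule.group is None
            else np.array(group_idx.get(rule.group, []), dtype=int)
        )
        if rule.n > eligible.size:
            raise ValidationError(
                f"missingness rule {rule} exceeds the {eligible.size} eligible persons"
            )
        chosen = rng.choice(eligible, size=rule.n, replace=False)
        cols = [j for name in rule.instruments for j in inst_cols[name]]
        values[np.ix_(chosen, cols)] = np.nan

    if (~np.isnan(values)).sum(axis=1).min() == 0:
        raise ValidationError("missingness rules left a person with no items")

    rm = ResponseMatrix(persons=persons, items=bank.item_ids, values=values)
    return SimulationResult(
        responses=rm,
        bank=bank,
        abilities=pd.Series(thetas, index=rm.person_ids, name="theta"),
        spec=spec,
    )


def inject_violation(
    sim: SimulationResult, kind: str, params: dict
) -> SimulationResult:
    """Return a copy of the simulation with one controlled model violation.

    Supported kinds (params in brackets; ``seed`` defaults to 0):

    - ``dif`` (item_id, group, delta): re-draws the item's responses for one
      group with its difficulty shifted by ``delta`` logits;
    - ``local_dependency`` (item_id, source_item_id, p): the item copies the
      source item's response with probability ``p``;
    - ``second_dimension`` (item_ids, r): re-draws a cluster of items from a
      second ability correlated ``r`` with the first;
    - ``misfit`` (item_id): replaces the item's responses with fair coin
      flips, unrelated to ability.
    """
    rng = np.random.default_rng(params.get("seed", 0))
    rm = sim.responses
    values = rm.values.copy()
    theta = sim.abilities.to_numpy()

    def col(item_id: str) -> int:
        try:
            return rm.items.index(item_id)
        except ValueError:
            raise ValidationError(f"unknown item {item_id!r}") from None

    if kind == "dif":
        j = col(params["item_id"])
        delta = sim.bank[params["item_id"]].difficulty + params["delta"]
        mask = np.array([p.group == params["group"] for p in rm.persons])
        mask &= ~np.isnan(values[:, j])
        p = rasch_probability(theta[mask], delta)
        values[mask, j] = (rng.random(p.shape) < p).astype(float)
    elif kind == "local_dependency":
        j = col(params["item_id"])
        src = col(params["source_item_id"])
        copy = rng.random(len(theta)) < params["p"]
        ok = copy & ~np.isnan(values[:, j]) & ~np.isnan(values[:, src])
        values[ok, j] = values[ok, src]
    elif kind == "second_dimension":
        cols = [col(i) for i in params["item_ids"]]
        r = float(params["r"])
        sd = float(np.std(theta, ddof=1))
        theta2 = r * theta + math.sqrt(1.0 - r**2) * rng.normal(0.0, sd, len(theta))
        d = sim.bank.difficulties([rm.items[j] for j in cols])
        p = rasch_probability(theta2[:, None], d[None, :])
        draw = (rng.random(p.shape) < p).astype(float)
        sub = values[:, cols]
        values[:, cols] = np.where(np.isnan(sub), np.nan, draw)
    elif kind == "misfit":
        j = col(params["item_id"])
        ok = ~np.isnan(values[:, j])
        values[ok, j] = (rng.random(int(ok.sum())) < 0.5).astype(float)
    else:
        raise ValidationError(f"unknown violation kind {kind!r}")

    new_rm = ResponseMatrix(
        persons=[replace(p) for p in rm.persons], items=list(rm.items), values=values
    )
    return SimulationResult(
        responses=new_rm, bank=sim.bank, abilities=sim.abilities.copy(), spec=sim.spec
    )
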