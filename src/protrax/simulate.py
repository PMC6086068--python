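"""Continuous-time simulator of protracted-speciation genealogies.

The process tracks *population lineages*, the basic units of
diversification.  Each lineage is either a **good** species founder (it
has completed speciation) or an **incipient** lineage (a divergent
population that has not yet attained reproductive isolation).  Three
exponential-hazard event types act on every extant lineage:

splitting
    the lineage spawns a new incipient daughter;
conversion
    an incipient lineage completes speciation: it becomes good and
    founds a new species;
extirpation
    the lineage is lost (population death or merger back into the
    parental gene pool).

Good lineages carry no conversion hazard — a species founder has nothing
left to convert.  The simulation starts at the crown: one good founder
plus one incipient daughter, both present at time 0 and sharing the root
species until the daughter converts.  Time runs forward from 0 to
``duration`` (Myr); all stored times are absolute forward times.

Species identity follows the *nearest completed ancestor* rule: a
lineage belongs to the species founded by the genealogically closest
ancestor (itself included) that has completed speciation, the crown
founder counting as completed at time 0.  A conversion therefore claims
the converting lineage's entire not-yet-converted descendant subtree for
the new species, including daughters born before the conversion — all
descendants of a converting lineage are the new species unless a
conversion of their own intervenes.

The Gillespie scheme is exact: the waiting time to the next event is
exponential with the summed hazard over extant lineages, and the event
lineage is chosen proportionally to its own hazard.

Survival conditioning (configurable, default ``"both"``): an attempt is
discarded and re-run on the next RNG substream unless each of the two
crown lineages leaves at least one extant descendant, so that the
genealogy's crown age equals ``duration``; ``n_restarts`` counts
discarded attempts.  ``"any"`` only requires some lineage to survive;
``"none"`` disables conditioning.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "ProtractedParams",
    "LineageRecord",
    "Genealogy",
    "simulate_genealogy",
    "extant_richness",
    "sample_species_tree",
]

#: conditioning rules accepted by :func:`simulate_genealogy`
CONDITIONING_RULES = ("none", "any", "both")

#: hard cap on resimulation attempts before giving up (pathological
#: parameter sets only; the study's parameter ranges never approach it)
MAX_RESTARTS = 100_000


@dataclass(frozen=True)
class ProtractedParams:
    """Rates (per lineage per Myr) and duration (Myr) of one simulation.

    ``splitting`` and ``extirpation`` may differ between good and
    incipient lineages; conversion applies to incipient lineages only.
    """

    splitting_rate_good: float
    splitting_rate_incipient: float
    conversion_rate: float
    extirpation_rate_good: float
    extirpation_rate_incipient: float
    duration: float

    @classmethod
    def symmetric(
        cls, splitting_rate: float, conversion_rate: float, extirpation_rate: float, duration: float
    ) -> "ProtractedParams":
        """Same splitting/extirpation rates for good and incipient lineages."""
        return cls(
            splitting_rate_good=splitting_rate,
            splitting_rate_incipient=splitting_rate,
            conversion_rate=conversion_rate,
            extirpation_rate_good=extirpation_rate,
            extirpation_rate_incipient=extirpation_rate,
            duration=duration,
        )

    def __post_init__(self) -> None:
        rates = (
            self.splitting_rate_good,
            self.splitting_rate_incipient,
            self.conversion_rate,
            self.extirpation_rate_good,
            self.extirpation_rate_incipient,
        )
        if any(not math.isfinite(r) or r < 0 for r in rates):
            raise ValueError("all rates must be finite and non-negative")
        if not (math.isfinite(self.duration) and self.duration > 0):
            raise ValueError("duration must be positive and finite")


class LineageRecord:
    """Event history of a single population lineage.

    ``species_id`` is the identity the lineage holds at the end of the
    simulation under the nearest-completed-ancestor rule (see module
    docstring).  ``species_founder`` is True iff this lineage founded
    ``species_id`` (by converting, or as the crown root of the original
    species).
    """

    __slots__ = (
        "lineage_id",
        "parent_id",
        "origin_time",
        "end_time",
        "fate",
        "conversion_time",
        "species_id",
        "species_founder",
        "crown_side",
    )

    def __init__(
        self,
        lineage_id: int,
        parent_id: int | None,
        origin_time: float,
        species_id: int,
        species_founder: bool = False,
        crown_side: int = 0,
    ) -> None:
        self.lineage_id = lineage_id
        self.parent_id = parent_id
        self.origin_time = origin_time
        self.end_time = math.nan
        self.fate = ""  # "extant" | "extirpated"
        self.conversion_time: float | None = None
        self.species_id = species_id
        self.species_founder = species_founder
        self.crown_side = crown_side

    @property
    def is_extant(self) -> bool:
        return self.fate == "extant"

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"LineageRecord(id={self.lineage_id}, parent={self.parent_id}, "
            f"t=[{self.origin_time:.4g},{self.end_time:.4g}], {self.fate}, "
            f"sp={self.species_id}{'*' if self.species_founder else ''})"
        )


@dataclass
class Genealogy:
    """Complete lineage-level outcome of one protracted-speciation run."""

    params: ProtractedParams
    lineages: list[LineageRecord]
    seed: object
    n_restarts: int = 0
    conditioning: str = "both"
    _by_id: dict[int, LineageRecord] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._by_id:
            self._by_id = {lin.lineage_id: lin for lin in self.lineages}

    def lineage(self, lineage_id: int) -> LineageRecord:
        return self._by_id[lineage_id]

    def extant_lineages(self) -> list[LineageRecord]:
        return [lin for lin in self.lineages if lin.is_extant]


def extant_richness(g: Genealogy) -> int:
    """Number of distinct species among extant lineages."""
    return len({lin.species_id for lin in g.extant_lineages()})


def _as_seed_sequence(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


def simulate_genealogy(
    params: ProtractedParams,
    seed,
    conditioning: str = "both",
) -> Genealogy:
    """Simulate one protracted-speciation genealogy.

    Parameters
    ----------
    params : ProtractedParams
        Event rates and total duration.
    seed : int or numpy.random.SeedSequence
        Master seed for this replicate.  Rejected (fully extinct)
        attempts consume successive child substreams, so the result is
        reproducible and independent of how many restarts occurred
        before other replicates were run.
    conditioning : {"both", "any", "none"}
        Survival conditioning rule (see module docstring).

    Returns
    -------
    Genealogy
    """
    if conditioning not in CONDITIONING_RULES:
        raise ValueError(f"conditioning must be one of {CONDITIONING_RULES}")
    master = _as_seed_sequence(seed)
    n_restarts = 0
    while True:
        attempt_ss = master.spawn(1)[0]
        lineages = _run_once(params, np.random.default_rng(attempt_ss))
        if _accept(lineages, conditioning):
            return Genealogy(
                params=params,
                lineages=lineages,
                seed=seed,
                n_restarts=n_restarts,
                conditioning=conditioning,
            )
        n_restarts += 1
        if n_restarts >= MAX_RESTARTS:
            raise RuntimeError(
                f"survival conditioning not met after {MAX_RESTARTS} attempts"
            )


def _accept(lineages: list[LineageRecord], conditioning: str) -> bool:
    if conditioning == "none":
        return True
    sides = {lin.crown_side for lin in lineages if lin.is_extant}
    if conditioning == "any":
        return bool(sides)
    return sides == {0, 1}


def _run_once(params: ProtractedParams, rng: np.random.Generator) -> list[LineageRecord]:
    """One unconditioned Gillespie pass from crown to ``duration``."""
    lg, li = params.splitting_rate_good, params.splitting_rate_incipient
    chi = params.conversion_rate
    mg, mi = params.extirpation_rate_good, params.extirpation_rate_incipient
    T = params.duration
    hazard_good = lg + mg
    hazard_incip = li + chi + mi

    # crown start: good founder (species 0's founder) + incipient daughter
    root = LineageRecord(0, None, 0.0, species_id=0, species_founder=True, crown_side=0)
    daughter = LineageRecord(1, None, 0.0, species_id=0, crown_side=1)
    lineages = [root, daughter]
    good = [root]
    incip = [daughter]
    next_lineage = 2
    next_species = 1
    children: dict[int, list[LineageRecord]] = {0: [], 1: []}

    def reassign_subtree(lin: LineageRecord, species_id: int) -> None:
        """Claim not-yet-converted descendants for a newly founded species."""
        stack = list(children[lin.lineage_id])
        while stack:
            node = stack.pop()
            if node.conversion_time is None:  # a conversion of its own shields a subtree
                node.species_id = species_id
                stack.extend(children[node.lineage_id])

    t = 0.0
    while True:
        total = len(good) * hazard_good + len(incip) * hazard_incip
        if total <= 0.0:
            break
        t += rng.exponential(1.0 / total)
        if t >= T:
            break
        # one uniform draw locates class, lineage and event type
        x = rng.random() * total
        good_mass = len(good) * hazard_good
        if x < good_mass:
            idx = min(int(x / hazard_good), len(good) - 1)
            within = x - idx * hazard_good
            lin = good[idx]
            if within < lg:  # splitting
                child = LineageRecord(
                    next_lineage, lin.lineage_id, t, lin.species_id, crown_side=lin.crown_side
                )
                next_lineage += 1
                lineages.append(child)
                incip.append(child)
                children[lin.lineage_id].append(child)
                children[child.lineage_id] = []
            else:  # extirpation
                lin.end_time = t
                lin.fate = "extirpated"
                good[idx] = good[-1]
                good.pop()
        else:
            y = x - good_mass
            idx = min(int(y / hazard_incip), len(incip) - 1)
            within = y - idx * hazard_incip
            lin = incip[idx]
            if within < li:  # splitting
                child = LineageRecord(
                    next_lineage, lin.lineage_id, t, lin.species_id, crown_side=lin.crown_side
                )
                next_lineage += 1
                lineages.append(child)
                incip.append(child)
                children[lin.lineage_id].append(child)
                children[child.lineage_id] = []
            elif within < li + chi:  # conversion: founds a new species
                lin.conversion_time = t
                lin.species_id = next_species
                lin.species_founder = True
                next_species += 1
                incip[idx] = incip[-1]
                incip.pop()
                good.append(lin)
                reassign_subtree(lin, lin.species_id)
            else:  # extirpation
                lin.end_time = t
                lin.fate = "extirpated"
                incip[idx] = incip[-1]
                incip.pop()

    for lin in good:
        lin.end_time = T
        lin.fate = "extant"
    for lin in incip:
        lin.end_time = T
        lin.fate = "extant"
    return lineages


# ---------------------------------------------------------------------------
# species-tree sampling


def sample_species_tree(g: Genealogy, seed) -> dendropy.Tree:
    """Prune a genealogy to one random extant representative per species.

    For each extant species one extant population lineage is chosen
    uniformly at random; all other lineages are pruned.  The returned
    tree is the subtree of the full population genealogy induced by the
    representatives: internal nodes sit at the original splitting times,
    branch lengths are in Myr, tips are labelled ``S<species_id>`` and
    all lie at the present, so the tree is ultrametric with tip depth
    equal to the crown age of the induced tree.  A single-species
    genealogy yields a degenerate one-tip tree.
    """
    rng = np.random.default_rng(_as_seed_sequence(seed))
    by_species: dict[int, list[LineageRecord]] = {}
    for lin in g.lineages:
        if lin.is_extant:
            by_species.setdefault(lin.species_id, []).append(lin)
    if not by_species:
        raise ValueError("genealogy has no extant lineages")

    reps: dict[int, int] = {}  # lineage_id -> species_id
    for sp in sorted(by_species):
        members = sorted(by_species[sp], key=lambda lin: lin.lineage_id)
        chosen = members[rng.integers(len(members))]
        reps[chosen.lineage_id] = sp

    # how many representatives pass through each lineage's subtree
    reps_through: dict[int, int] = {}
    for rid in reps:
        node: LineageRecord | None = g.lineage(rid)
        while node is not None:
            reps_through[node.lineage_id] = reps_through.get(node.lineage_id, 0) + 1
            node = g.lineage(node.parent_id) if node.parent_id is not None else None

    children: dict[int, list[LineageRecord]] = {}
    for lin in g.lineages:
        if lin.parent_id is not None and reps_through.get(lin.lineage_id, 0) > 0:
            children.setdefault(lin.parent_id, []).append(lin)
    for kids in children.values():
        kids.sort(key=lambda lin: lin.origin_time)

    T = g.params.duration
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.is_rooted = True

    def attach(node: dendropy.Node, parent, parent_time: float | None):
        """Attach ``node`` under ``parent`` (or make it the root)."""
        if parent is None:
            tree.seed_node = node
            node.edge.length = None
        else:
            parent.add_child(node)
            node.edge.length = node.time - parent_time  # type: ignore[attr-defined]

    # iterative induced-subtree construction; each stack entry is the point
    # on lineage `lid`'s timeline at time `t0`, to be attached under `parent`
    crown = [lin for lin in g.lineages if lin.parent_id is None]
    start = [lin for lin in crown if reps_through.get(lin.lineage_id, 0) > 0]
    stack: list[tuple[int, float, object, float | None]]
    if len(start) == 2:
        root = dendropy.Node()
        root.time = 0.0
        attach(root, None, None)
        stack = [(lin.lineage_id, 0.0, root, 0.0) for lin in start]
    else:
        stack = [(start[0].lineage_id, 0.0, None, None)]

    while stack:
        lid, t0, parent, parent_time = stack.pop()
        while True:
            kids = [c for c in children.get(lid, ()) if c.origin_time > t0]
            self_rep = 1 if lid in reps else 0
            advanced = False
            for i, child in enumerate(kids):
                remaining = self_rep + sum(
                    reps_through[c.lineage_id] for c in kids[i + 1 :]
                )
                if remaining == 0:
                    # every remaining representative lies under this child:
                    # the path continues into it without a branching node
                    lid, t0 = child.lineage_id, child.origin_time
                    advanced = True
                    break
                node = dendropy.Node()
                node.time = child.origin_time
                attach(node, parent, parent_time)
                stack.append((child.lineage_id, child.origin_time, node, node.time))
                parent, parent_time = node, node.time
            if advanced:
                continue
            # no rep-bearing children left: the lineage itself is a representative
            assert self_rep == 1, f"lineage {lid} should carry a representative"
            leaf = dendropy.Node()
            leaf.time = T
            leaf.taxon = dendropy.Taxon(label=f"S{reps[lid]}")
            taxa.add_taxon(leaf.taxon)
            attach(leaf, parent, parent_time)
            break

    return tree
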