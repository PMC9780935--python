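"""Biotransformation rules and combinatorial enumeration of candidate metabolites.

A :class:`Transformation` is a net formula delta (atoms added minus atoms
removed) with a phase label (I = oxidative/reductive, II = conjugation).
:func:`enumerate_candidates` expands a parent compound into the bounded
multiset closure of phase I steps, each optionally extended by one phase II
conjugate whose chemical-handle predicate is satisfied — this is the
in-silico suspect library the annotator screens against.

The default rule set encodes the biotransformations observed for the
monoterpene limonene (carboxylation, hydroxylation, epoxidation/diol,
hydrogenation; glucuronide, sulfate, glycine and taurine conjugation).
Conjugation is gated: glucuronidation and sulfation need at least one
oxygen-adding phase I step on the scaffold, amino-acid conjugation needs the
carboxyl group.  An optional dehydrogenation (-H2) rule exists but is off by
default.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .chemcore import (
    M_H_NEG,
    M_H_POS,
    IonSpecies,
    MolecularFormula,
    FormulaError,
    ion_mz,
    monoisotopic_mass,
    parse_formula,
)

__all__ = [
    "Transformation",
    "RuleSet",
    "CandidateMetabolite",
    "default_ruleset",
    "apply_transformation",
    "enumerate_candidates",
    "canonical_label",
]

# handle predicates a conjugation step may require of the phase I multiset
REQUIRES_NONE = "none"
REQUIRES_OXYGEN = "oxygen_handle"
REQUIRES_CARBOXYL = "carboxyl_handle"


@dataclass(frozen=True)
class Transformation:
    """A biotransformation as a formula delta.

    ``added``/``removed`` are elemental deltas (either may be None);
    ``max_per_candidate`` bounds how often the rule may be applied to one
    candidate; ``requires`` gates phase II rules on a chemical handle
    created by phase I chemistry.
    """

    id: str
    phase: str  # "I" or "II"
    label_token: str
    added: Optional[MolecularFormula] = None
    removed: Optional[MolecularFormula] = None
    max_per_candidate: int = 1
    requires: str = REQUIRES_NONE
    adds_oxygen: bool = False
    adds_carboxyl: bool = False

    def __post_init__(self):
        if self.phase not in ("I", "II"):
            raise ValueError(f"phase must be I or II, got {self.phase!r}")
        if self.requires not in (REQUIRES_NONE, REQUIRES_OXYGEN, REQUIRES_CARBOXYL):
            raise ValueError(f"unknown requires predicate {self.requires!r}")
        if self.added is None and self.removed is None:
            raise ValueError("transformation must add or remove atoms")

    @property
    def mass_delta(self) -> float:
        d = 0.0
        if self.added is not None:
            d += monoisotopic_mass(self.added)
        if self.removed is not None:
            d -= monoisotopic_mass(self.removed)
        return d


@dataclass(frozen=True)
class RuleSet:
    transformations: Tuple[Transformation, ...]
    max_phase_I_steps: int = 4
    max_phase_II_conjugates: int = 1

    def __post_init__(self):
        ids = [t.id for t in self.transformations]
        if len(ids) != len(set(ids)):
            raise ValueError("transformation ids must be unique")

    @property
    def phase_I(self) -> List[Transformation]:
        return [t for t in self.transformations if t.phase == "I"]

    @property
    def phase_II(self) -> List[Transformation]:
        return [t for t in self.transformations if t.phase == "II"]


@dataclass(frozen=True)
class CandidateMetabolite:
    """A parent compound plus a multiset of transformations."""

    parent_id: str
    transformations: Tuple[Transformation, ...]  # applied multiset, canonical order
    formula: MolecularFormula  # neutral formula
    label: str

    @property
    def n_transformations(self) -> int:
        return len(self.transformations)

    def mz(self, ion: IonSpecies = M_H_NEG) -> float:
        return ion_mz(self.formula, ion)


def _t(
    id: str,
    phase: str,
    token: str,
    added: str = "",
    removed: str = "",
    max_n: int = 1,
    requires: str = REQUIRES_NONE,
    adds_oxygen: bool = False,
    adds_carboxyl: bool = False,
) -> Transformation:
    return Transformation(
        id=id,
        phase=phase,
        label_token=token,
        added=parse_formula(added) if added else None,
        removed=parse_formula(removed) if removed else None,
        max_per_candidate=max_n,
        requires=requires,
        adds_oxygen=adds_oxygen,
        adds_carboxyl=adds_carboxyl,
    )


def default_ruleset(include_dehydrogenation: bool = False) -> RuleSet:
    """Rule set for limonene-class monoterpene metabolism.

    Phase I: carboxylation (+O2-H2), hydroxylation (+O), diol formation
    (+O2H2, epoxidation followed by hydrolysis), hydrogenation (+H2, up to
    two).  Phase II (at most one per candidate): glucuronidation (+C6H8O6)
    and sulfation (+SO3) on any oxygenated scaffold, glycine (+C2H3NO) and
    taurine (+C2H5NO2S) conjugation on carboxylated scaffolds.
    ``include_dehydrogenation`` adds an optional -H2 rule, disabled by
    default because no observed metabolite requires it.
    """
    rules = [
        _t("carboxylation", "I", "+COOH", added="O2", removed="H2",
           adds_oxygen=True, adds_carboxyl=True),
        _t("hydroxylation", "I", "+OH", added="O", adds_oxygen=True),
        _t("diol", "I", "+OH+OH", added="O2H2", adds_oxygen=True),
        _t("hydrogenation", "I", "+H2", added="H2", max_n=2),
        _t("glucuronidation", "II", "glucuronide", added="C6H8O6",
           requires=REQUIRES_OXYGEN),
        _t("sulfation", "II", "sulfate", added="SO3", requires=REQUIRES_OXYGEN),
        _t("glycine", "II", "glycine", added="C2H3NO",
           requires=REQUIRES_CARBOXYL),
        _t("taurine", "II", "taurine", added="C2H5NO2S",
           requires=REQUIRES_CARBOXYL),
    ]
    if include_dehydrogenation:
        rules.insert(4, _t("dehydrogenation", "I", "-H2", removed="H2"))
    return RuleSet(tuple(rules))


#: canonical ordering of phase I label tokens in candidate labels
_PHASE_I_TOKEN_ORDER = ["+COOH", "+OH", "+OH+OH", "-H2", "+H2"]


def apply_transformation(
    f: MolecularFormula, t: Transformation
) -> MolecularFormula:
    """Apply one rule's formula delta; raises FormulaError when impossible."""
    out = f
    if t.added is not None:
        out = out + t.added
    if t.removed is not None:
        out = out - t.removed
    return out


def canonical_label(
    parent_id: str, transformations: Sequence[Transformation]
) -> str:
    """Deterministic label: parent, ordered phase I tokens, then conjugate."""
    phase1 = [t for t in transformations if t.phase == "I"]
    phase2 = [t for t in transformations if t.phase == "II"]

    def token_key(t: Transformation) -> int:
        try:
            return _PHASE_I_TOKEN_ORDER.index(t.label_token)
        except ValueError:
            return len(_PHASE_I_TOKEN_ORDER)

    parts = [parent_id]
    for t in sorted(phase1, key=token_key):
        parts.append(t.label_token)
    label = "".join(parts)
    for t in phase2:
        label += " " + t.label_token
    return label


def _phase_I_multisets(rules: RuleSet) -> List[Tuple[Transformation, ...]]:
    """All bounded multisets of phase I rules (cartesian product of counts)."""
    p1 = rules.phase_I
    ranges = [range(t.max_per_candidate + 1) for t in p1]
    out = []
    for counts in itertools.product(*ranges):
        if sum(counts) > rules.max_phase_I_steps:
            continue
        ms: List[Transformation] = []
        for t, c in zip(p1, counts):
            ms.extend([t] * c)
        out.append(tuple(ms))
    return out


def _handles(multiset: Sequence[Transformation]) -> Dict[str, bool]:
    return {
        REQUIRES_NONE: True,
        REQUIRES_OXYGEN: any(t.adds_oxygen for t in multiset),
        REQUIRES_CARBOXYL: any(t.adds_carboxyl for t in multiset),
    }


def enumerate_candidates(
    parent: MolecularFormula,
    parent_id: str,
    rules: RuleSet,
) -> List[CandidateMetabolite]:
    """Enumerate the candidate metabolite library for ``parent``.

    Every bounded phase I multiset is generated; each is optionally extended
    by up to ``max_phase_II_conjugates`` conjugates whose ``requires``
    predicate the multiset satisfies.  Chemically impossible applications
    (negative atom counts) are silently dropped.  The library is
    deduplicated on (neutral formula, label) and sorted by label.
    """
    seen = {}
    for p1 in _phase_I_multisets(rules):
        try:
            f1 = parent
            for t in p1:
                f1 = apply_transformation(f1, t)
        except FormulaError:
            continue
        handles = _handles(p1)
        conj_options: List[Tuple[Transformation, ...]] = [()]
        if rules.max_phase_II_conjugates >= 1:
            for t2 in rules.phase_II:
                if handles[t2.requires]:
                    conj_options.append((t2,))
        for conj in conj_options:
            try:
                f = f1
                for t in conj:
                    f = apply_transformation(f, t)
            except FormulaError:
                continue
            ms = tuple(p1) + conj
            label = canonical_label(parent_id, ms)
            key = (f, label)
            if key not in seen:
                seen[key] = CandidateMetabolite(
                    parent_id=parent_id,
                    transformations=ms,
                    formula=f,
                    label=label,
                )
    return sorted(seen.values(), key=lambda c: c.label)
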