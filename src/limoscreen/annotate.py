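"""Annotation of LC-MS features against a candidate metabolite library.

The screening logic is: (1) MS1 exact-mass match within a ppm tolerance
(default 10 ppm); (2) advisory isotope-pattern agreement; (3) MS/MS
corroboration through conjugate-class diagnostic fragments and the aglycone
complement left by the neutral loss of the conjugate; (4) exclusion of
features also present in non-supplemented control groups; (5) assignment of
an annotation confidence level on the Metabolomics Standards Initiative
scale (capped at level 2 — no authentic standards).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .chemcore import (
    M_H_NEG,
    IonSpecies,
    IsotopePattern,
    MolecularFormula,
    anion_mz,
    ion_mz,
    isotope_pattern,
    monoisotopic_mass,
    parse_formula,
    pattern_score,
    ppm_error,
)
from .rules import CandidateMetabolite

__all__ = [
    "Feature",
    "MS2Spectrum",
    "FragmentRule",
    "AnnotationHit",
    "default_fragment_rules",
    "match_features",
    "assign_fragments",
    "control_exclusion",
    "msi_level",
    "collapse_isomers",
    "assign_isomer_suffixes",
]


@dataclass(frozen=True)
class MS2Spectrum:
    """Product-ion spectrum: (m/z, relative abundance in % of base peak)."""

    fragments: Tuple[Tuple[float, float], ...]

    def __post_init__(self):
        if not self.fragments:
            raise ValueError("spectrum must contain at least one fragment")
        for mz, ab in self.fragments:
            if not (0 < ab <= 100):
                raise ValueError(f"relative abundance out of (0, 100]: {ab}")
            if mz <= 0:
                raise ValueError(f"non-positive fragment m/z: {mz}")

    @property
    def mzs(self) -> Tuple[float, ...]:
        return tuple(mz for mz, _ in self.fragments)


@dataclass(frozen=True)
class Feature:
    """One aligned LC-MS feature with per-sample intensities."""

    feature_id: str
    mz: float
    rt: float
    intensities: Tuple[Tuple[str, float], ...] = ()
    ms2: Optional[MS2Spectrum] = None

    def __post_init__(self):
        if self.mz <= 0:
            raise ValueError("feature m/z must be positive")
        if self.rt < 0:
            raise ValueError("retention time must be >= 0")
        if any(v < 0 for _, v in self.intensities):
            raise ValueError("intensities must be >= 0")

    def intensity_map(self) -> Dict[str, float]:
        return dict(self.intensities)


@dataclass(frozen=True)
class FragmentRule:
    """Diagnostic fragments and neutral losses for one conjugate class.

    ``diagnostics``: anion formulas of conjugate-specific fragments (their
    m/z is the ionic-formula mass plus one electron).  ``neutral_losses``:
    neutral formulas whose loss from the precursor leaves an
    aglycone-related complement fragment.
    """

    conjugate: str  # Transformation id of the phase II rule
    diagnostics: Tuple[MolecularFormula, ...]
    neutral_losses: Tuple[MolecularFormula, ...]

    def diagnostic_mzs(self) -> List[Tuple[str, float]]:
        return [(str(f), anion_mz(f)) for f in self.diagnostics]

    def loss_masses(self) -> List[Tuple[str, float]]:
        return [(str(f), monoisotopic_mass(f)) for f in self.neutral_losses]


def default_fragment_rules() -> Dict[str, FragmentRule]:
    """Negative-mode fragment rules for the four conjugate classes.

    Glucuronides shed the characteristic sugar-ring series (175.0248,
    113.0244, 99.0088, 85.0295, 75.0088, 59.0139) and lose the neutral
    C6H8O6 (176.0321) to expose the aglycone anion.  Sulfates give the SO3
    radical anion at 79.9574.  Taurine conjugates give the taurine anion
    (124.0074), its dehydrated sulfonate fragment (106.9808) and SO3; the
    amide bond can cleave either keeping the carbonyl with the aglycone
    (loss C2H5NO2S) or with the sulfonate side (loss C2H4O3S).  Glycine
    conjugates give the glycinate anion (74.0247) and lose CO2/HCOOH.
    """
    p = parse_formula
    return {
        "glucuronidation": FragmentRule(
            "glucuronidation",
            diagnostics=(p("C6H7O6"), p("C5H5O3"), p("C4H3O3"),
                         p("C4H5O2"), p("C2H3O3"), p("C2H3O2")),
            neutral_losses=(p("C6H8O6"),),
        ),
        "sulfation": FragmentRule(
            "sulfation",
            diagnostics=(p("SO3"),),
            neutral_losses=(p("SO3"),),
        ),
        "taurine": FragmentRule(
            "taurine",
            diagnostics=(p("C2H6NO3S"), p("C2H3O3S"), p("SO3")),
            neutral_losses=(p("C2H5NO2S"), p("C2H4O3S")),
        ),
        "glycine": FragmentRule(
            "glycine",
            diagnostics=(p("C2H4NO2"),),
            neutral_losses=(p("CO2"), p("CH2O2")),
        ),
    }


@dataclass(frozen=True)
class AnnotationHit:
    """A candidate <-> feature link with all gathered evidence."""

    feature_id: str
    feature_mz: float
    feature_rt: float
    candidate: CandidateMetabolite
    theoretical_mz: float
    ppm: float
    isotope_score: Optional[float] = None
    matched_diagnostics: Tuple[str, ...] = ()
    complement_matched: bool = False
    control_present: bool = False
    msi: Optional[str] = None

    @property
    def label(self) -> str:
        return self.candidate.label


def match_features(
    features: Sequence[Feature],
    library: Sequence[CandidateMetabolite],
    ion: IonSpecies = M_H_NEG,
    tol_ppm: float = 10.0,
) -> Tuple[List[AnnotationHit], List[Feature]]:
    """MS1 match: all (feature, candidate) pairs within ``tol_ppm``.

    Returns (hits, unmatched features).  Hits for one feature are ranked by
    absolute ppm error, ties broken by fewest transformations (the simpler
    candidate first).
    """
    if tol_ppm < 0:
        raise ValueError("tolerance must be >= 0")
    if not library:
        raise ValueError("empty candidate library")
    lib_mz = [(c, ion_mz(c.formula, ion)) for c in library]
    hits: List[AnnotationHit] = []
    unmatched: List[Feature] = []
    for feat in features:
        feat_hits = []
        for cand, theo in lib_mz:
            err = ppm_error(theo, feat.mz)
            if abs(err) <= tol_ppm:
                feat_hits.append(
                    AnnotationHit(
                        feature_id=feat.feature_id,
                        feature_mz=feat.mz,
                        feature_rt=feat.rt,
                        candidate=cand,
                        theoretical_mz=theo,
                        ppm=err,
                    )
                )
        if not feat_hits:
            unmatched.append(feat)
            continue
        feat_hits.sort(key=lambda h: (abs(h.ppm), h.candidate.n_transformations))
        hits.extend(feat_hits)
    return hits, unmatched


def score_isotopes(
    hit: AnnotationHit,
    observed: IsotopePattern,
    max_offset: int = 3,
) -> AnnotationHit:
    """Attach the advisory isotope-pattern agreement score to a hit."""
    theo = isotope_pattern(hit.candidate.formula, max_offset=max_offset)
    return replace(hit, isotope_score=pattern_score(observed, theo))


def assign_fragments(
    hit: AnnotationHit,
    spectrum: MS2Spectrum,
    rules: Dict[str, FragmentRule],
    frag_tol: float = 0.005,
) -> AnnotationHit:
    """Record conjugate diagnostic fragments and the aglycone complement.

    ``frag_tol`` is an absolute tolerance in Th (printed product ions
    deviate by a few mTh from theory, so ppm tolerances are too tight).
    Diagnostics above the precursor m/z are never matched.
    """
    conj = [t for t in hit.candidate.transformations if t.phase == "II"]
    if len(conj) > 1:
        raise ValueError("fragment rules defined for at most one conjugate")
    if not conj:
        return replace(hit, matched_diagnostics=(), complement_matched=False)
    rule = rules.get(conj[0].id)
    if rule is None:
        raise KeyError(f"no fragment rule for conjugate class {conj[0].id!r}")
    obs = np.asarray(spectrum.mzs)
    matched = []
    for name, dmz in rule.diagnostic_mzs():
        if dmz > hit.theoretical_mz:
            continue
        if np.any(np.abs(obs - dmz) <= frag_tol):
            matched.append(name)
    complement = False
    for _, loss in rule.loss_masses():
        target = hit.theoretical_mz - loss
        if target > 0 and np.any(np.abs(obs - target) <= frag_tol):
            complement = True
            break
    return replace(
        hit, matched_diagnostics=tuple(matched), complement_matched=complement
    )


def control_exclusion(
    hits: Sequence[AnnotationHit],
    intensities: Dict[str, Dict[str, float]],
    groups: Dict[str, str],
    control_groups: Sequence[str],
    presence_threshold: float = 0.05,
) -> List[AnnotationHit]:
    """Flag hits whose feature is present in non-supplemented control groups.

    ``intensities`` maps feature id -> {sample id -> intensity}; ``groups``
    maps sample id -> group name.  A hit is control-present when the mean
    intensity in any control group exceeds ``presence_threshold`` times the
    mean intensity over the supplemented (non-control) groups.
    """
    control_set = set(control_groups)
    if not control_set:
        raise ValueError("no control groups supplied")
    known_groups = set(groups.values())
    if not control_set & known_groups:
        raise ValueError("no sample belongs to any control group")
    out = []
    for hit in hits:
        inten = intensities.get(hit.feature_id, {})
        ctrl_means = []
        for g in sorted(control_set & known_groups):
            vals = [v for s, v in inten.items() if groups.get(s) == g]
            if vals:
                ctrl_means.append(float(np.mean(vals)))
        suppl = [v for s, v in inten.items()
                 if groups.get(s) is not None and groups[s] not in control_set]
        suppl_mean = float(np.mean(suppl)) if suppl else 0.0
        present = bool(
            ctrl_means
            and suppl_mean >= 0
            and max(ctrl_means) > presence_threshold * suppl_mean
        )
        out.append(replace(hit, control_present=present))
    return out


def msi_level(hit: AnnotationHit, isotope_floor: float = 0.5) -> AnnotationHit:
    """Assign the annotation confidence level.

    Level 2 (putative annotation) when at least one diagnostic fragment or
    the aglycone complement matched; level 3 (compound-class level) when the
    evidence is MS1-only; rejected when the isotope score falls below
    ``isotope_floor``.  Level 1 is never assigned (no authentic standards).
    """
    if hit.isotope_score is not None and hit.isotope_score < isotope_floor:
        return replace(hit, msi="rejected")
    if hit.matched_diagnostics or hit.complement_matched:
        return replace(hit, msi="2")
    return replace(hit, msi="3")


def collapse_isomers(labels: Sequence[str]) -> List[str]:
    """Distinct metabolite identities (positional isomers share a label)."""
    return sorted(set(labels))


def assign_isomer_suffixes(hits: Sequence[AnnotationHit]) -> Dict[str, str]:
    """Roman-numeral isomer suffixes per label, by ascending retention time.

    Returns feature id -> display label ("label I", "label II", ... when a
    label annotates several features; the bare label otherwise).
    """
    romans = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X"]
    by_label: Dict[str, List[AnnotationHit]] = {}
    for h in hits:
        by_label.setdefault(h.label, []).append(h)
    out: Dict[str, str] = {}
    for label, group in by_label.items():
        group = sorted(group, key=lambda h: (h.feature_rt, h.feature_id))
        if len(group) == 1:
            out[group[0].feature_id] = label
        else:
            for i, h in enumerate(group):
                suffix = romans[i] if i < len(romans) else str(i + 1)
                out[h.feature_id] = f"{label} {suffix}"
    return out
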