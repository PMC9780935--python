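"""End-to-end screening orchestration.

Thin glue over the library modules: MS1 match, per-feature best hit,
MS/MS evidence, optional control exclusion, confidence levels, isomer
suffixes and distinct-identity counting.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

from .annotate import (
    AnnotationHit,
    Feature,
    FragmentRule,
    MS2Spectrum,
    assign_fragments,
    assign_isomer_suffixes,
    collapse_isomers,
    control_exclusion,
    default_fragment_rules,
    match_features,
    msi_level,
)
from .chemcore import M_H_NEG, IonSpecies
from .rules import CandidateMetabolite

__all__ = ["screen", "distinct_metabolites", "ScreenResult"]


class ScreenResult:
    """Outcome of one screening run."""

    def __init__(self, hits: List[AnnotationHit], unmatched: List[Feature]):
        self.hits = hits
        self.unmatched = unmatched
        self.display_labels = assign_isomer_suffixes(hits)

    @property
    def identified(self) -> List[AnnotationHit]:
        return [h for h in self.hits
                if not h.control_present and h.msi != "rejected"]

    def distinct_labels(self) -> List[str]:
        return collapse_isomers([h.label for h in self.identified])


def screen(
    features: Sequence[Feature],
    library: Sequence[CandidateMetabolite],
    ion: IonSpecies = M_H_NEG,
    tol_ppm: float = 10.0,
    spectra: Optional[Dict[str, MS2Spectrum]] = None,
    fragment_rules: Optional[Dict[str, FragmentRule]] = None,
    frag_tol: float = 0.005,
    intensities: Optional[Dict[str, Dict[str, float]]] = None,
    groups: Optional[Dict[str, str]] = None,
    control_groups: Sequence[str] = (),
    presence_threshold: float = 0.05,
    isotope_floor: float = 0.5,
) -> ScreenResult:
    """Screen ``features`` against ``library``; one best hit per feature.

    The best hit is the smallest-|ppm| candidate (ties: fewest
    transformations).  If a spectrum is available for a feature (attached
    to the Feature or supplied via ``spectra``), diagnostic-fragment
    evidence is gathered; if group intensities and control groups are
    given, control exclusion is applied before confidence levels.
    """
    all_hits, unmatched = match_features(features, library, ion, tol_ppm)
    rules = fragment_rules or default_fragment_rules()
    spectra = spectra or {}
    feat_by_id = {f.feature_id: f for f in features}
    best: List[AnnotationHit] = []
    seen = set()
    for h in all_hits:  # hits are grouped per feature, best first
        if h.feature_id in seen:
            continue
        seen.add(h.feature_id)
        spec = spectra.get(h.feature_id) or feat_by_id[h.feature_id].ms2
        if spec is not None:
            h = assign_fragments(h, spec, rules, frag_tol)
        best.append(h)
    if control_groups and groups is not None:
        inten = intensities or {
            f.feature_id: f.intensity_map() for f in features
        }
        best = control_exclusion(best, inten, groups, control_groups,
                                 presence_threshold)
    best = [msi_level(h, isotope_floor) for h in best]
    return ScreenResult(best, unmatched)


def distinct_metabolites(result: ScreenResult) -> int:
    """Number of distinct metabolite identities after isomer collapsing."""
    return len(result.distinct_labels())
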