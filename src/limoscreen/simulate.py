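"""Seeded synthetic LC-MS cohorts with the statistical structure the
pipeline assumes, so every stage is testable without instrument data.

The generator plants metabolite features at their theoretical [M-H]- m/z
perturbed by Gaussian ppm jitter, draws per-animal intensities from a
log-normal with group-specific means (high between-animal variability is a
hallmark of xenobiotic metabolism), sets planted intensities to zero in
non-supplemented control groups, scatters decoy background features kept at
least an exclusion margin away from every library mass, draws urinary
creatinine per sample, and emits template-based conjugate MS2 spectra with
fragment dropout and abundance jitter.  Identical configs (including the
mandatory seed) give identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .annotate import FragmentRule, Feature, MS2Spectrum, default_fragment_rules
from .chemcore import M_H_NEG, ion_mz
from .doseprofile import SampleMeta
from .rules import CandidateMetabolite

__all__ = ["SimConfig", "GroundTruth", "simulate_cohort", "simulate_ms2",
           "demo_config"]

#: the four study dose groups: chow control, high-fat control, low and high dose
DEFAULT_GROUPS = ("NL", "HL", "HL0.1", "HL0.8")
DEFAULT_CONTROLS = ("NL", "HL")


@dataclass(frozen=True)
class SimConfig:
    """Cohort design and noise model.

    ``planted``: candidate label -> {group: mean intensity}; control groups
    absent from the inner mapping receive strict zeros.  ``cv`` is the
    between-animal coefficient of variation of the log-normal intensity
    model (sigma_log = sqrt(log(1 + cv^2))).  ``mz_sigma_ppm`` is the
    Gaussian m/z jitter.  Decoys are background features present in all
    groups, placed at least ``decoy_margin`` (Th) from every library mass.
    """

    seed: int
    planted: Dict[str, Dict[str, float]]
    groups: Tuple[str, ...] = DEFAULT_GROUPS
    control_groups: Tuple[str, ...] = DEFAULT_CONTROLS
    n_per_group: int = 8
    cv: float = 0.4
    mz_sigma_ppm: float = 2.0
    n_decoys: int = 50
    decoy_margin: float = 0.05
    decoy_mean_intensity: float = 5000.0
    mz_range: Tuple[float, float] = (100.0, 600.0)
    creatinine_mean: float = 1.0
    creatinine_cv: float = 0.3
    ms2_dropout: float = 0.1
    ms2_abundance_jitter: float = 0.2
    control_leakage: float = 0.0  # fraction of supplemented mean leaking into controls

    def __post_init__(self):
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if self.cv < 0 or self.mz_sigma_ppm < 0 or self.creatinine_cv < 0:
            raise ValueError("noise parameters must be >= 0")
        if not set(self.control_groups) <= set(self.groups):
            raise ValueError("control groups must be a subset of groups")


@dataclass(frozen=True)
class GroundTruth:
    """feature id -> planted label (or None for decoys) and true group means."""

    planted_label: Dict[str, Optional[str]]
    true_means: Dict[str, Dict[str, float]]

    def is_decoy(self, feature_id: str) -> bool:
        return self.planted_label[feature_id] is None


def _lognormal(rng: np.random.Generator, mean: float, cv: float,
               size: int) -> np.ndarray:
    if mean == 0:
        return np.zeros(size)
    if cv == 0:
        return np.full(size, mean)
    sigma = np.sqrt(np.log1p(cv ** 2))
    mu = np.log(mean) - sigma ** 2 / 2
    return rng.lognormal(mu, sigma, size)


def simulate_ms2(
    candidate: CandidateMetabolite,
    rules: Dict[str, FragmentRule],
    rng: np.random.Generator,
    dropout: float = 0.0,
    abundance_jitter: float = 0.0,
) -> Optional[MS2Spectrum]:
    """Template MS2 spectrum for a conjugated candidate.

    Diagnostics get a 40% template abundance, the aglycone complement 80%,
    plus a 100% precursor peak; each fragment is independently dropped with
    probability ``dropout`` and its abundance jittered by a factor
    ``1 + U(-j, j)``.  Returns None if every fragment is dropped.
    """
    conj = [t for t in candidate.transformations if t.phase == "II"]
    if not conj:
        raise ValueError(f"candidate {candidate.label} has no conjugate class")
    rule = rules.get(conj[0].id)
    if rule is None:
        raise KeyError(f"no fragment rule for conjugate class {conj[0].id!r}")
    precursor = candidate.mz(M_H_NEG)
    template: List[Tuple[float, float]] = [(precursor, 100.0)]
    for _, dmz in rule.diagnostic_mzs():
        if dmz < precursor:
            template.append((dmz, 40.0))
    loss_name, loss = rule.loss_masses()[0]
    if precursor - loss > 0:
        template.append((precursor - loss, 80.0))
    frags = []
    for mz, ab in template:
        if rng.random() < dropout:
            continue
        jitter = 1.0 + rng.uniform(-abundance_jitter, abundance_jitter)
        frags.append((mz, float(np.clip(ab * jitter, 0.1, 100.0))))
    if not frags:
        return None
    base = max(ab for _, ab in frags)
    frags = [(mz, ab / base * 100.0) for mz, ab in frags]
    return MS2Spectrum(tuple(sorted(frags)))


def simulate_cohort(
    config: SimConfig,
    library: Sequence[CandidateMetabolite],
) -> Tuple[List[Feature], Dict[str, MS2Spectrum], List[SampleMeta], GroundTruth]:
    """Generate one synthetic cohort.

    Returns (features, MS2 spectra keyed by feature id, sample metadata,
    ground truth).  Raises on planted labels missing from the library and
    on impossible decoy placement.
    """
    rng = np.random.default_rng(config.seed)
    by_label = {c.label: c for c in library}
    for label in config.planted:
        if label not in by_label:
            raise KeyError(f"planted label {label!r} not in library")

    samples = [f"{g}_{i + 1}" for g in config.groups
               for i in range(config.n_per_group)]
    sample_group = {s: s.rsplit("_", 1)[0] for s in samples}
    meta = [
        SampleMeta(
            s, sample_group[s], "urine",
            float(_lognormal(rng, config.creatinine_mean,
                             config.creatinine_cv, 1)[0]),
        )
        for s in samples
    ]

    lib_mz = np.array([ion_mz(c.formula, M_H_NEG) for c in library])
    frag_rules = default_fragment_rules()

    features: List[Feature] = []
    spectra: Dict[str, MS2Spectrum] = {}
    planted_label: Dict[str, Optional[str]] = {}
    true_means: Dict[str, Dict[str, float]] = {}

    for k, (label, means) in enumerate(sorted(config.planted.items())):
        cand = by_label[label]
        theo = cand.mz(M_H_NEG)
        eps = rng.normal(0.0, config.mz_sigma_ppm * 1e-6)
        fid = f"P{k + 1:03d}"
        inten = []
        full_means = {}
        for g in config.groups:
            if g in config.control_groups:
                suppl = [means.get(x, 0.0) for x in config.groups
                         if x not in config.control_groups]
                mean_g = config.control_leakage * float(np.mean(suppl))
            else:
                mean_g = means.get(g, 0.0)
            full_means[g] = mean_g
            draws = _lognormal(rng, mean_g, config.cv, config.n_per_group)
            for i, v in enumerate(draws):
                inten.append((f"{g}_{i + 1}", float(v)))
        features.append(Feature(fid, theo * (1.0 + eps), rt=float(1 + 0.2 * k),
                                intensities=tuple(inten)))
        planted_label[fid] = label
        true_means[fid] = full_means
        if any(t.phase == "II" for t in cand.transformations):
            spec = simulate_ms2(cand, frag_rules, rng,
                                config.ms2_dropout,
                                config.ms2_abundance_jitter)
            if spec is not None:
                spectra[fid] = spec

    lo, hi = config.mz_range
    for d in range(config.n_decoys):
        placed = False
        for _ in range(1000):
            mz = float(rng.uniform(lo, hi))
            if lib_mz.size == 0 or np.min(np.abs(lib_mz - mz)) > config.decoy_margin:
                placed = True
                break
        if not placed:
            raise RuntimeError("could not place decoy outside exclusion margin")
        fid = f"D{d + 1:03d}"
        mean = config.decoy_mean_intensity
        inten = []
        for g in config.groups:
            draws = _lognormal(rng, mean, config.cv, config.n_per_group)
            for i, v in enumerate(draws):
                inten.append((f"{g}_{i + 1}", float(v)))
        features.append(Feature(fid, mz, rt=float(rng.uniform(0.5, 6.0)),
                                intensities=tuple(inten)))
        planted_label[fid] = None
        true_means[fid] = {g: mean for g in config.groups}

    return features, spectra, meta, GroundTruth(planted_label, true_means)


def demo_config(library: Sequence[CandidateMetabolite], seed: int = 0,
                **overrides) -> SimConfig:
    """Cohort preset mirroring the observed urinary metabolite profile.

    Plants the 16 urinary metabolite identities with group mean intensities
    proportional to their published percent-of-total in the low- and
    high-dose groups (scaled to a 1e5 total), zero in both control groups.
    """
    from .io import load_fixture

    df = load_fixture("table2_features")
    by_label: Dict[str, Dict[str, float]] = {}
    for _, row in df.iterrows():
        label = row["label"]
        cur = by_label.setdefault(label, {"HL0.1": 0.0, "HL0.8": 0.0})
        cur["HL0.1"] += float(row["hl01_pct"]) * 1e3
        cur["HL0.8"] += float(row["hl08_pct"]) * 1e3
    labels = {c.label for c in library}
    missing = set(by_label) - labels
    if missing:
        raise KeyError(f"fixture labels missing from library: {missing}")
    return SimConfig(seed=seed, planted=by_label, **overrides)
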