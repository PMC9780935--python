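"""Readers and writers for all exchanged formats, plus packaged fixtures.

Formats: feature tables (delimited text: feature_id, mz, rt, then one column
per sample), MS/MS spectra (MGF via pyteomics, TITLE carries the feature
id), sample metadata (sample_id, group, tissue, creatinine), and TSV reports.
All writers emit UTF-8 tab-separated text with a header line; dot-decimal
regardless of locale.

Two fixtures ship with the package: ``table2_features`` (the 23 annotated
metabolite features, with retention times, observed [M-H]- m/z, printed
product-ion lists as "mz (rel%) ; ..." strings, tissue flags and group
percent columns) and ``table1_oil`` (the GC-MS composition of the
limonene-rich essential oil used as the supplement).
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import pandas as pd
from pyteomics import mgf as _mgf

from .annotate import AnnotationHit, Feature, MS2Spectrum
from .doseprofile import SampleMeta
from .rules import CandidateMetabolite
from .chemcore import M_H_NEG, M_H_POS, ion_mz

__all__ = [
    "read_features",
    "write_features",
    "read_mgf",
    "write_mgf",
    "read_metadata",
    "write_metadata",
    "write_report",
    "write_library",
    "parse_msms",
    "load_fixture",
    "table2_features",
]

_RESERVED = ("feature_id", "mz", "rt")


class FormatError(ValueError):
    """Malformed input file, reported with row/column context."""


def parse_msms(text: str) -> Optional[MS2Spectrum]:
    """Parse a product-ion list in the ``"mz (rel%); mz (rel%); ..."`` dialect.

    Returns None for empty text or the "n.d." (not detected) marker.
    """
    if text is None:
        return None
    text = str(text).strip()
    if not text or text.lower() in ("n.d.", "nd", "nan"):
        return None
    frags = []
    for i, chunk in enumerate(text.split(";")):
        chunk = chunk.strip()
        if not chunk:
            continue
        if "(" not in chunk or not chunk.endswith(")"):
            raise FormatError(f"bad MS/MS entry {chunk!r} (item {i})")
        mz_part, ab_part = chunk.split("(", 1)
        try:
            mz = float(mz_part.strip())
            ab = float(ab_part[:-1].strip())
        except ValueError as e:
            raise FormatError(f"non-numeric MS/MS entry {chunk!r} (item {i})") from e
        frags.append((mz, ab))
    if not frags:
        return None
    return MS2Spectrum(tuple(frags))


def format_msms(spectrum: Optional[MS2Spectrum]) -> str:
    if spectrum is None:
        return "n.d."
    return "; ".join(f"{mz:.4f} ({ab:g})" for mz, ab in spectrum.fragments)


def read_features(path) -> List[Feature]:
    """Read a delimited feature table (tab or comma sniffed from the header)."""
    df = _read_table(path)
    for col in _RESERVED:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    sample_cols = [c for c in df.columns if c not in _RESERVED]
    if len(set(df["feature_id"])) != len(df):
        raise FormatError(f"{path}: duplicate feature ids")
    feats = []
    for idx, row in df.iterrows():
        try:
            inten = tuple((c, float(row[c])) for c in sample_cols)
            feats.append(Feature(str(row["feature_id"]), float(row["mz"]),
                                 float(row["rt"]), inten))
        except (TypeError, ValueError) as e:
            raise FormatError(f"{path}: row {idx}: {e}") from e
    return feats


def write_features(features: Sequence[Feature], path) -> None:
    sample_ids: List[str] = []
    for f in features:
        for s, _ in f.intensities:
            if s not in sample_ids:
                sample_ids.append(s)
    rows = []
    for f in features:
        m = f.intensity_map()
        rows.append({"feature_id": f.feature_id, "mz": f.mz, "rt": f.rt,
                     **{s: m.get(s, 0.0) for s in sample_ids}})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_mgf(path) -> Dict[str, MS2Spectrum]:
    """Read MGF; TITLE identifies the feature each spectrum belongs to."""
    out: Dict[str, MS2Spectrum] = {}
    with _mgf.MGF(str(path)) as reader:
        for spec in reader:
            title = spec["params"].get("title")
            if title is None:
                raise FormatError(f"{path}: MGF spectrum without TITLE")
            mzs = spec["m/z array"]
            intens = spec["intensity array"]
            if len(mzs) == 0:
                continue
            base = float(max(intens))
            frags = tuple(
                (float(m), float(i) / base * 100.0) for m, i in zip(mzs, intens)
            )
            out[str(title)] = MS2Spectrum(frags)
    return out


def write_mgf(spectra: Dict[str, MS2Spectrum],
              precursors: Dict[str, float], path) -> None:
    entries = []
    for fid, spec in spectra.items():
        entries.append({
            "m/z array": [mz for mz, _ in spec.fragments],
            "intensity array": [ab for _, ab in spec.fragments],
            "params": {"title": fid, "pepmass": precursors.get(fid, 0.0),
                       "charge": "1-"},
        })
    _mgf.write(entries, str(path), file_mode="w")


def read_metadata(path) -> List[SampleMeta]:
    df = _read_table(path)
    for col in ("sample_id", "group", "tissue"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    if len(set(df["sample_id"])) != len(df):
        raise FormatError(f"{path}: duplicate sample ids")
    out = []
    for idx, row in df.iterrows():
        creat = row.get("creatinine")
        creat = None if pd.isna(creat) else float(creat)
        out.append(SampleMeta(str(row["sample_id"]), str(row["group"]),
                              str(row["tissue"]), creat))
    return out


def write_metadata(meta: Sequence[SampleMeta], path) -> None:
    pd.DataFrame(
        [{"sample_id": m.sample_id, "group": m.group, "tissue": m.tissue,
          "creatinine": m.creatinine} for m in meta]
    ).to_csv(path, sep="\t", index=False)


def write_report(hits: Sequence[AnnotationHit],
                 display_labels: Dict[str, str], path) -> None:
    """Annotation report TSV, one row per hit, mirroring the evidence model."""
    rows = []
    for h in hits:
        rows.append({
            "label": display_labels.get(h.feature_id, h.label),
            "feature_id": h.feature_id,
            "rt": h.feature_rt,
            "observed_mz": h.feature_mz,
            "theoretical_mz": round(h.theoretical_mz, 5),
            "ppm_error": round(h.ppm, 1),
            "isotope_score": ("" if h.isotope_score is None
                              else round(h.isotope_score, 3)),
            "matched_fragments": "; ".join(h.matched_diagnostics),
            "complement_matched": h.complement_matched,
            "control_present": h.control_present,
            "msi_level": h.msi or "",
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_library(library: Sequence[CandidateMetabolite], path) -> None:
    rows = []
    for c in library:
        rows.append({
            "label": c.label,
            "neutral_formula": str(c.formula),
            "mz_neg": round(ion_mz(c.formula, M_H_NEG), 5),
            "mz_pos": round(ion_mz(c.formula, M_H_POS), 5),
            "phase_I": "+".join(t.id for t in c.transformations if t.phase == "I"),
            "conjugate": "".join(t.id for t in c.transformations if t.phase == "II"),
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
    if not header.strip():
        raise FormatError(f"{path}: empty file")
    sep = "\t" if "\t" in header else ","
    return pd.read_csv(path, sep=sep)


def load_fixture(name: str) -> pd.DataFrame:
    """Load a packaged fixture table by name.

    ``"table2_features"``: the 23 annotated urinary/hepatic metabolite
    features.  ``"table1_oil"``: essential-oil composition (9 compounds).
    """
    fname = {"table2_features": "table2_features.tsv",
             "table1_oil": "table1_oil.tsv"}.get(name)
    if fname is None:
        raise KeyError(f"unknown fixture {name!r}")
    ref = importlib.resources.files("limoscreen").joinpath("data", fname)
    with importlib.resources.as_file(ref) as p:
        return pd.read_csv(p, sep="\t")


def table2_features(tissue: Optional[str] = None) -> List[Feature]:
    """The packaged metabolite features as Feature objects with MS2 attached.

    ``tissue="urine"`` returns all 23 features (every metabolite was seen in
    urine); ``tissue="liver"`` returns the 3 features also found in liver.
    """
    df = load_fixture("table2_features")
    if tissue == "liver":
        df = df[df["tissue"].str.contains("L")]
    elif tissue == "urine":
        df = df[df["tissue"].str.contains("U")]
    elif tissue is not None:
        raise ValueError(f"unknown tissue {tissue!r}")
    out = []
    for _, row in df.iterrows():
        out.append(Feature(
            feature_id=str(row["metabolite_id"]),
            mz=float(row["mz"]),
            rt=float(row["rt"]),
            intensities=(),
            ms2=parse_msms(row["msms"]),
        ))
    return out
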