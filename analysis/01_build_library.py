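#!/usr/bin/env python
"""Enumerate the candidate metabolite library for limonene.

Expands the parent monoterpene (C10H16) through the default phase I rules
(carboxylation, hydroxylation, diol formation, up to two hydrogenations)
and the predicate-gated phase II conjugations (glucuronide, sulfate,
glycine, taurine), and writes the library with theoretical [M-H]- and
[M+H]+ m/z to results/candidate_library.tsv.
"""

from pathlib import Path

from limoscreen import default_ruleset, enumerate_candidates, parse_formula
from limoscreen.io import write_library

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    library = enumerate_candidates(parse_formula("C10H16"), "limonene",
                                   default_ruleset())
    OUT.mkdir(exist_ok=True)
    write_library(library, OUT / "candidate_library.tsv")
    n_conj = sum(1 for c in library
                 if any(t.phase == "II" for t in c.transformations))
    print(f"candidate library: {len(library)} candidates "
          f"({len(library) - n_conj} phase I only, {n_conj} conjugated)")
    print(f"wrote {OUT / 'candidate_library.tsv'}")


if __name__ == "__main__":
    main()
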