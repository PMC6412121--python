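"""Physical constants and elemental building blocks for oligonucleotide mass math.

All monoisotopic atomic masses come from a single packaged table
(``data/atomic_masses.tsv``) so that every mass in the package is computed
from one authoritative source; ppm-level matching breaks down quickly when
two modules disagree in the fourth decimal.

``C`` always denotes the light isotope pool (12C); the heavy pool is the
separate element key ``C13``.  Compositions are plain ``dict[str, int]``
mappings element -> count.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def _load_atomic_masses() -> dict[str, float]:
    with resources.files("silnas.data").joinpath("atomic_masses.tsv").open() as fh:
        table = pd.read_csv(fh, sep="\t")
    return dict(zip(table["element"], table["monoisotopic_mass"]))


ATOMIC_MASS: dict[str, float] = _load_atomic_masses()

#: Mass of a proton, used for negative-mode charging (loss of z protons).
PROTON_MASS = 1.00727646

#: 13C - 12C mass difference; the per-atom heavy-label shift.
C13_SHIFT = ATOMIC_MASS["C13"] - ATOMIC_MASS["C"]

# Neutral nucleoside compositions (base + ribose, no phosphate).
NUCLEOSIDE_COMPOSITION: dict[str, dict[str, int]] = {
    "A": {"C": 10, "H": 13, "N": 5, "O": 4},  # adenosine
    "C": {"C": 9, "H": 13, "N": 3, "O": 5},   # cytidine
    "G": {"C": 10, "H": 13, "N": 5, "O": 5},  # guanosine
    "U": {"C": 9, "H": 12, "N": 2, "O": 6},   # uridine
}

#: Carbons per nucleoside (ribose 5 + base), the ceiling for 13C labelling.
NUCLEOSIDE_CARBONS = {b: c["C"] for b, c in NUCLEOSIDE_COMPOSITION.items()}

# Neutral nucleobase compositions, for a-B (base-loss) fragment ions.
NUCLEOBASE_COMPOSITION: dict[str, dict[str, int]] = {
    "A": {"C": 5, "H": 5, "N": 5},            # adenine
    "C": {"C": 4, "H": 5, "N": 3, "O": 1},    # cytosine
    "G": {"C": 5, "H": 5, "N": 5, "O": 1},    # guanine
    "U": {"C": 4, "H": 4, "N": 2, "O": 2},    # uracil
}

WATER: dict[str, int] = {"H": 2, "O": 1}
#: Condensed phosphate unit; one per internal phosphodiester linkage.
HPO3: dict[str, int] = {"H": 1, "P": 1, "O": 3}
#: Methyl substitution (CH2 replacing H), e.g. 2'-O-methylation.
METHYL: dict[str, int] = {"C": 1, "H": 2}

# 2,2,7-trimethylguanosine nucleoside (guanosine + 3 CH2), default cap base.
TMG_NUCLEOSIDE: dict[str, int] = {"C": 13, "H": 19, "N": 5, "O": 5}


def combine(*parts: dict[str, int], scale: int = 1) -> dict[str, int]:
    """Sum element-count dicts (each multiplied by ``scale``), dropping zeros."""
    out: dict[str, int] = {}
    for part in parts:
        for el, n in part.items():
            out[el] = out.get(el, 0) + n * scale
    return {el: n for el, n in out.items() if n != 0}


def subtract(a: dict[str, int], b: dict[str, int]) -> dict[str, int]:
    """Element-wise ``a - b``; negative intermediate results are allowed only
    if they cancel (the caller is doing bookkeeping, not chemistry)."""
    return combine(a, {el: -n for el, n in b.items()})
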