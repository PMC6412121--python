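"""Elemental composition, monoisotopic mass and ion m/z for oligonucleotides.

A chain of n nucleosides contains n-1 phosphodiester linkages, each adding
HPO3 and removing one water relative to the free nucleosides; end groups
(5'-OH / phosphates / TMG cap, 3'-OH / linear or 2',3'-cyclic phosphate)
are added on top, then per-site modification deltas.  The heavy channel of
an isotope-dilution experiment moves carbons from the 12C pool to the 13C
pool according to the label scheme (e.g. 13C10-guanosine for RNase T1
digests), leaving everything else untouched — so the heavy-light mass
difference is exactly (label count) x 1.0033548 Da, independent of any
modification.

MS2 product ions follow the dominant CID series of RNA. Conventions used
here (neutral-fragment masses, before deprotonation):

* ``c_i``  — 5' fragment of length i carrying the full 3'-phosphate,
* ``y_j``  — 3' fragment of length j with a 5'-hydroxyl,
* ``w_j``  — 3' fragment of length j with a 5'-phosphate,
* ``a-B_i``— c_i minus HPO3, minus water, minus the 3'-terminal nucleobase.

With these conventions ``mass(c_i) + mass(y_{n-i}) = precursor + water``
at every backbone position (ester hydrolysis adds one water).
"""

from __future__ import annotations

from dataclasses import dataclass

from .constants import (
    ATOMIC_MASS,
    HPO3,
    METHYL,
    NUCLEOBASE_COMPOSITION,
    NUCLEOSIDE_COMPOSITION,
    PROTON_MASS,
    TMG_NUCLEOSIDE,
    WATER,
    combine,
    subtract,
)
from .digestion import Fragment
from .rna import LabelScheme

#: Default acquisition window of the survey scan (m/z, negative mode).
DEFAULT_MZ_WINDOW = (480.0, 1980.0)
DEFAULT_MAX_CHARGE = 8

#: 5' end-group composition deltas relative to a bare 5'-OH chain.  The TMG
#: cap (2,2,7-trimethylguanosine joined by a 5'-5' triphosphate bridge) is a
#: package default and can be overridden per run via configuration, since
#: cap chemistry is a property of the sample, not of the algorithm.
FIVE_PRIME_DELTAS: dict[str, dict[str, int]] = {
    "hydroxyl": {},
    "monophosphate": dict(HPO3),
    "triphosphate": combine(HPO3, scale=3),
    "tmg-cap": combine(TMG_NUCLEOSIDE, combine(HPO3, scale=3), {"H": -2, "O": -1}),
}

THREE_PRIME_DELTAS: dict[str, dict[str, int]] = {
    "hydroxyl": {},
    "linear-phosphate": dict(HPO3),
    "cyclic-phosphate": subtract(HPO3, WATER),
}


def chain_composition(
    sequence: str,
    five_prime_end: str = "hydroxyl",
    three_prime_end: str = "hydroxyl",
    cap_override: dict | None = None,
) -> dict[str, int]:
    """Composition of an unmodified light chain with the given end groups."""
    parts = [NUCLEOSIDE_COMPOSITION[b] for b in sequence]
    n = len(sequence)
    linkages = combine(combine(HPO3, scale=n - 1), {"H": -2 * (n - 1), "O": -(n - 1)})
    five = (
        cap_override
        if (cap_override is not None and five_prime_end == "tmg-cap")
        else FIVE_PRIME_DELTAS[five_prime_end]
    )
    return combine(*parts, linkages, five, THREE_PRIME_DELTAS[three_prime_end])


def composition(
    fragment: Fragment,
    variant: tuple | list = (),
    channel: str = "light",
    scheme: LabelScheme | None = None,
    cap_override: dict | None = None,
) -> dict[str, int]:
    """Elemental composition of a fragment in a given modification variant
    and isotope channel.

    ``variant`` lists the modification sites actually present on the
    species (molecule coordinates; must lie inside the fragment).  In the
    heavy channel, ``scheme`` dictates how many carbons per nucleoside are
    13C; labels apply to the nucleoside carbons only, so modification
    methyl groups stay 12C.
    """
    for site in variant:
        if not fragment.start <= site.position <= fragment.end:
            raise ValueError(
                f"variant site {site.molecule_id}:{site.position} outside fragment "
                f"{fragment.start}..{fragment.end}"
            )
    counts = chain_composition(
        fragment.sequence, fragment.five_prime_end, fragment.three_prime_end, cap_override
    )
    for site in variant:
        counts = combine(counts, site.type.elemental_delta)
    if channel == "heavy":
        if scheme is None:
            raise ValueError("heavy channel requires a label scheme")
        n13 = scheme.label_count(fragment.sequence)
        counts = combine(counts, {"C": -n13, "C13": n13})
    elif channel != "light":
        raise ValueError(f"unknown channel {channel!r}")
    return counts


def monoisotopic_mass(counts: dict[str, int]) -> float:
    """Sum of count x monoisotopic atomic mass; 13C uses its own mass."""
    return sum(ATOMIC_MASS[el] * n for el, n in counts.items())


def mz_negative(mass: float, z: int) -> float:
    """m/z of the [M - zH]^z- ion."""
    if z < 1:
        raise ValueError("charge must be >= 1")
    return (mass - z * PROTON_MASS) / z


def observable_charges(
    mass: float,
    window: tuple[float, float] = DEFAULT_MZ_WINDOW,
    max_charge: int = DEFAULT_MAX_CHARGE,
) -> list[int]:
    """Charges whose [M - zH]^z- m/z falls inside the acquisition window."""
    lo, hi = window
    return [z for z in range(1, max_charge + 1) if lo <= mz_negative(mass, z) <= hi]


@dataclass(frozen=True)
class OligoSpecies:
    """A charged-neutral oligonucleotide species: fragment x variant x channel."""

    fragment: Fragment
    channel: str
    variant: tuple  # modification sites present
    composition: dict
    monoisotopic_mass: float

    @property
    def key(self) -> tuple:
        return (
            self.fragment.molecule_id,
            self.fragment.start,
            self.fragment.end,
            self.channel,
            tuple(sorted((s.position, s.mod_type) for s in self.variant)),
        )

    @property
    def label(self) -> str:
        from .rna import annotate_sequence

        seq = annotate_sequence(self.fragment.sequence, self.fragment.start, self.variant)
        prefix = "*" if self.channel == "heavy" else ""
        return f"{prefix}{seq}[{self.fragment.start}-{self.fragment.end}]"


def make_species(
    fragment: Fragment,
    variant: tuple | list = (),
    channel: str = "light",
    scheme: LabelScheme | None = None,
    cap_override: dict | None = None,
) -> OligoSpecies:
    counts = composition(fragment, variant, channel, scheme, cap_override)
    return OligoSpecies(
        fragment=fragment,
        channel=channel,
        variant=tuple(sorted(variant)),
        composition=counts,
        monoisotopic_mass=monoisotopic_mass(counts),
    )


@dataclass(frozen=True)
class IonSpecies:
    species: OligoSpecies
    charge: int
    mz: float


def ions_for(species: OligoSpecies, window=DEFAULT_MZ_WINDOW, max_charge=DEFAULT_MAX_CHARGE):
    return [
        IonSpecies(species, z, mz_negative(species.monoisotopic_mass, z))
        for z in observable_charges(species.monoisotopic_mass, window, max_charge)
    ]


@dataclass(frozen=True)
class Ms2Ion:
    series: str  # 'c' | 'y' | 'w' | 'a-B'
    index: int
    charge: int
    mz: float


def _base_composition(base: str, sites_at: dict, position: int) -> dict[str, int]:
    counts = dict(NUCLEOBASE_COMPOSITION[base])
    site = sites_at.get(position)
    # Base methylations leave with the base; ribose 2'-O-methyl stays behind.
    if site is not None and site.mod_type in ("base-methyl", "N6-methyl"):
        counts = combine(counts, METHYL)
    return counts


def ms2_ladders(species: OligoSpecies, max_charge: int = 2, scheme: LabelScheme | None = None):
    """Complete c / y / w / a-B product-ion series for a species.

    Fragment length must be >= 2.  Charges run from 1 to ``max_charge``.
    Heavy-channel precursors yield heavy product ions (labels partition with
    the sequence).
    """
    frag = species.fragment
    n = len(frag)
    if n < 2:
        raise ValueError("MS2 ladders need at least one backbone position")
    sites_at = {s.position: s for s in species.variant}
    heavy = species.channel == "heavy"

    def sub_mass(lo: int, hi: int, five: str, three: str) -> float:
        sub = Fragment(
            molecule_id=frag.molecule_id,
            start=frag.start + lo,
            end=frag.start + hi - 1,
            sequence=frag.sequence[lo:hi],
            sites=tuple(
                s for s in species.variant if frag.start + lo <= s.position <= frag.start + hi - 1
            ),
            five_prime_end=five,
            three_prime_end=three,
        )
        return monoisotopic_mass(
            composition(sub, sub.sites, "heavy" if heavy else "light", scheme)
        )

    water = monoisotopic_mass(WATER)
    hpo3 = monoisotopic_mass(dict(HPO3))
    ions = []
    for i in range(1, n):  # backbone position after residue i
        c_mass = sub_mass(0, i, frag.five_prime_end, "linear-phosphate")
        last_base = frag.sequence[i - 1]
        base_mass = monoisotopic_mass(
            _base_composition(last_base, sites_at, frag.start + i - 1)
        )
        if heavy and scheme is not None and last_base in scheme.substitutions:
            # base carbons are labelled; partition them between base and ribose
            base_c = NUCLEOBASE_COMPOSITION[last_base].get("C", 0)
            labelled = min(scheme.substitutions[last_base], base_c)
            base_mass += labelled * (ATOMIC_MASS["C13"] - ATOMIC_MASS["C"])
        ab_mass = c_mass - hpo3 - water - base_mass
        y_mass = sub_mass(i, n, "hydroxyl", frag.three_prime_end)
        w_mass = sub_mass(i, n, "monophosphate", frag.three_prime_end)
        for z in range(1, max_charge + 1):
            ions.append(Ms2Ion("c", i, z, mz_negative(c_mass, z)))
            ions.append(Ms2Ion("a-B", i, z, mz_negative(ab_mass, z)))
            ions.append(Ms2Ion("y", n - i, z, mz_negative(y_mass, z)))
            ions.append(Ms2Ion("w", n - i, z, mz_negative(w_mass, z)))
    return ions
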