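"""Modification-aware in-silico ribonuclease digestion.

RNase T1 cleaves 3' of guanosine and RNase A 3' of pyrimidines; both
mechanisms require the free 2'-OH of the residue 5' of the scissile bond,
so a 2'-O-methylated residue is never cleaved after (methylation extends
the product to the next cleavable residue, e.g. UUG -> UUGmG for Gm).
Products carry 5'-hydroxyl and 3'-phosphate ends.  RNase H, used with a
DNA guide for site-directed splitting, leaves 5'-phosphate / 3'-hydroxyl
ends instead and is exposed as :func:`rnase_h_split`.

Missed cleavages count *retained internal cuts*: a blocked (methylated)
position is not cleavable at all and therefore never counts as missed.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .rna import ModificationSite, RnaMolecule, annotate_sequence, shift_site


@dataclass(frozen=True)
class CleavageRule:
    enzyme: str
    cut_after_bases: frozenset
    product_5prime_end: str = "hydroxyl"
    product_3prime_end: str = "linear-phosphate"

    def with_cyclic_phosphate(self) -> "CleavageRule":
        """Variant leaving 2',3'-cyclic phosphate products (one water less)."""
        return CleavageRule(self.enzyme, self.cut_after_bases,
                            self.product_5prime_end, "cyclic-phosphate")


RNASE_T1 = CleavageRule("RNaseT1", frozenset("G"))
# Pseudouridine keeps base letter U and a free 2'-OH, so RNase A cleaves
# after it; no special casing needed beyond the U membership below.
RNASE_A = CleavageRule("RNaseA", frozenset("CU"))
CLEAVAGE_RULES = {"RNaseT1": RNASE_T1, "RNaseA": RNASE_A}


@dataclass(frozen=True)
class Fragment:
    """A digestion product with 1-based inclusive molecule coordinates."""

    molecule_id: str
    start: int
    end: int
    sequence: str
    sites: tuple = ()  # carried ModificationSites, molecule coordinates
    missed_cleavages: int = 0
    five_prime_end: str = "hydroxyl"
    three_prime_end: str = "linear-phosphate"
    provenance: tuple = ()

    def __post_init__(self):
        for site in self.sites:
            if not self.start <= site.position <= self.end:
                raise ValueError(
                    f"site {site.molecule_id}:{site.position} outside fragment "
                    f"{self.start}..{self.end}"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def annotated_sequence(self) -> str:
        return annotate_sequence(self.sequence, self.start, self.sites)


def cleavage_sites(
    molecule: RnaMolecule,
    rule: CleavageRule,
    sites: tuple | list = (),
) -> list[int]:
    """Positions i such that the enzyme cuts between i and i+1.

    A position is cleavable iff its base is in the rule's target set, it is
    not the 3'-terminal residue, and no 2'-OH-blocking modification sits on
    it.  RNase H does not belong here (use :func:`rnase_h_split`).
    """
    if rule.enzyme == "RNaseH":
        raise ValueError("RNase H is guide-directed; use rnase_h_split")
    blocked = {
        s.position for s in sites if s.type.blocks_3prime_cleavage
    }
    return [
        i
        for i in range(1, len(molecule))
        if molecule.base(i) in rule.cut_after_bases and i not in blocked
    ]


def digest(
    molecule: RnaMolecule,
    rule: CleavageRule,
    max_missed: int = 0,
    sites: tuple | list = (),
) -> list[Fragment]:
    """Complete digestion with up to ``max_missed`` retained internal cuts.

    ``sites`` is the modification variant of the molecule being digested
    (sites actually present on this molecule); blocking sites reshape the
    cut set, and carried sites are attached to the fragments that span them.
    Terminal fragments keep the molecule's original end chemistry on the
    uncut side.  At ``max_missed=0`` the fragments tile the molecule exactly.
    """
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    cuts = cleavage_sites(molecule, rule, sites)
    boundaries = [0] + cuts + [len(molecule)]
    site_list = sorted(sites)
    fragments = []
    for i, left in enumerate(boundaries[:-1]):
        for missed, right in enumerate(boundaries[i + 1 : i + 2 + max_missed]):
            start, end = left + 1, right
            fragments.append(
                Fragment(
                    molecule_id=molecule.id,
                    start=start,
                    end=end,
                    sequence=molecule.subsequence(start, end),
                    sites=tuple(s for s in site_list if start <= s.position <= end),
                    missed_cleavages=missed,
                    five_prime_end=(
                        molecule.five_prime_end if start == 1 else rule.product_5prime_end
                    ),
                    three_prime_end=(
                        molecule.three_prime_end
                        if end == len(molecule)
                        else rule.product_3prime_end
                    ),
                    provenance=(rule.enzyme,),
                )
            )
    return fragments


def rnase_h_split(
    molecule: RnaMolecule,
    cut_before: int,
    sites: tuple | list = (),
) -> tuple[tuple[RnaMolecule, tuple, int], tuple[RnaMolecule, tuple, int]]:
    """Guide-directed RNase H split of a molecule before ``cut_before``.

    Returns ``((upstream, upstream_sites, offset), (downstream,
    downstream_sites, offset))``.  The upstream product keeps the original
    5' end and gains a 3'-hydroxyl; the downstream product gains a
    5'-monophosphate (hence the "p" prefix of species like pUUGp) and keeps
    the original 3' end.  Site coordinates are re-indexed to each product;
    the returned offset converts back to parent coordinates
    (parent = product position + offset).
    """
    if not 1 < cut_before <= len(molecule):
        raise ValueError(
            f"cut_before {cut_before} outside 2..{len(molecule)} for {molecule.id}"
        )
    up = RnaMolecule(
        id=f"{molecule.id}[1-{cut_before - 1}]",
        sequence=molecule.subsequence(1, cut_before - 1),
        five_prime_end=molecule.five_prime_end,
        three_prime_end="hydroxyl",
    )
    down = RnaMolecule(
        id=f"{molecule.id}[{cut_before}-{len(molecule)}]",
        sequence=molecule.subsequence(cut_before, len(molecule)),
        five_prime_end="monophosphate",
        three_prime_end=molecule.three_prime_end,
    )
    up_sites = tuple(
        shift_site(s, 0, up.id) for s in sorted(sites) if s.position < cut_before
    )
    down_offset = cut_before - 1
    down_sites = tuple(
        shift_site(s, -down_offset, down.id)
        for s in sorted(sites)
        if s.position >= cut_before
    )
    return (up, up_sites, 0), (down, down_sites, down_offset)


def fragments_to_table(fragments: list[Fragment]) -> pd.DataFrame:
    """Export a fragment set as a tidy table (TSV-ready)."""
    return pd.DataFrame(
        [
            dict(
                molecule_id=f.molecule_id,
                start=f.start,
                end=f.end,
                sequence=f.annotated_sequence,
                five_prime_end=f.five_prime_end,
                three_prime_end=f.three_prime_end,
                missed_cleavages=f.missed_cleavages,
                enzymes="+".join(f.provenance),
            )
            for f in sorted(fragments, key=lambda f: (f.molecule_id, f.start, f.end))
        ]
    )
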