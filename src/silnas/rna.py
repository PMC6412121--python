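"""Core data model: RNA molecules, modification types and sites, label schemes.

Positions are 1-based and inclusive throughout the package, following the
convention used for snRNA modification maps ("70A in U1 snRNA"); conversion
to 0-based indexing happens only inside slicing expressions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import pandas as pd
from Bio import SeqIO

from .constants import METHYL

RNA_ALPHABET = frozenset("ACGU")

FIVE_PRIME_ENDS = frozenset({"hydroxyl", "monophosphate", "triphosphate", "tmg-cap"})
THREE_PRIME_ENDS = frozenset({"hydroxyl", "linear-phosphate", "cyclic-phosphate"})


@dataclass(frozen=True)
class ModificationType:
    """A post-transcriptional modification and its mass/cleavage behaviour.

    ``elemental_delta`` is the element-count difference against the
    unmodified residue.  ``blocks_3prime_cleavage`` marks ribose
    2'-O-methylations, which remove the free 2'-OH that RNase T1 and
    RNase A require and therefore suppress cleavage immediately 3' of the
    residue.  ``mass_silent`` marks pseudouridine, an isomer of uridine
    with zero mass change that is only separable chromatographically.
    ``rt_shift`` is the default retention-time offset (minutes) of the
    modified species relative to its unmodified counterpart; methylated
    oligonucleotides elute later on reversed phase, pseudouridylated ones
    earlier.
    """

    name: str
    elemental_delta: dict
    blocks_3prime_cleavage: bool = False
    mass_silent: bool = False
    allowed_bases: frozenset = RNA_ALPHABET
    rt_shift: float = 0.0

    def __post_init__(self):
        if self.mass_silent and self.elemental_delta:
            raise ValueError(f"{self.name}: mass-silent modification must have an empty delta")


MODIFICATION_TYPES: dict[str, ModificationType] = {
    m.name: m
    for m in [
        ModificationType(
            "2'-O-methyl", dict(METHYL), blocks_3prime_cleavage=True, rt_shift=0.5
        ),
        ModificationType(
            "pseudouridine", {}, mass_silent=True,
            allowed_bases=frozenset("U"), rt_shift=-0.7,
        ),
        ModificationType("base-methyl", dict(METHYL), rt_shift=0.3),
        ModificationType(
            "N6-methyl", dict(METHYL), allowed_bases=frozenset("A"), rt_shift=0.3
        ),
    ]
}

#: Short symbols as used in modification maps (Am, Gm, m6A, Ψ ...).
MODIFICATION_SYMBOLS = {
    "m": "2'-O-methyl",
    "Y": "pseudouridine",
    "psi": "pseudouridine",
    "Ψ": "pseudouridine",
    "m6": "N6-methyl",
}


@dataclass(frozen=True)
class RnaMolecule:
    """An RNA sequence with explicit 5'/3' end-group chemistry."""

    id: str
    sequence: str
    five_prime_end: str = "hydroxyl"
    three_prime_end: str = "linear-phosphate"

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"{self.id}: empty sequence")
        for i, ch in enumerate(self.sequence, start=1):
            if ch not in RNA_ALPHABET:
                raise ValueError(f"{self.id}: illegal character {ch!r} at position {i}")
        if self.five_prime_end not in FIVE_PRIME_ENDS:
            raise ValueError(f"{self.id}: unknown 5' end group {self.five_prime_end!r}")
        if self.three_prime_end not in THREE_PRIME_ENDS:
            raise ValueError(f"{self.id}: unknown 3' end group {self.three_prime_end!r}")

    def __len__(self) -> int:
        return len(self.sequence)

    def base(self, position: int) -> str:
        """Base at a 1-based position."""
        if not 1 <= position <= len(self.sequence):
            raise IndexError(f"{self.id}: position {position} outside 1..{len(self.sequence)}")
        return self.sequence[position - 1]

    def subsequence(self, start: int, end: int) -> str:
        """Subsequence between 1-based inclusive coordinates."""
        if not (1 <= start <= end <= len(self.sequence)):
            raise IndexError(f"{self.id}: range {start}..{end} outside 1..{len(self.sequence)}")
        return self.sequence[start - 1 : end]


@dataclass(frozen=True, order=True)
class ModificationSite:
    molecule_id: str
    position: int
    mod_type: str

    def __post_init__(self):
        if self.mod_type not in MODIFICATION_TYPES:
            raise ValueError(f"unknown modification type {self.mod_type!r}")

    @property
    def type(self) -> ModificationType:
        return MODIFICATION_TYPES[self.mod_type]


@dataclass
class ModificationProfile:
    """Per-site modification stoichiometry (fraction of molecules modified)."""

    stoichiometry: dict = field(default_factory=dict)  # ModificationSite -> float

    def __post_init__(self):
        seen: set[tuple[str, int]] = set()
        for site, frac in self.stoichiometry.items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"{site}: stoichiometry {frac} outside [0, 1]")
            key = (site.molecule_id, site.position)
            if key in seen:
                raise ValueError(f"duplicate stoichiometry entry for {key}")
            seen.add(key)

    def sites_for(self, molecule_id: str) -> list[ModificationSite]:
        return sorted(s for s in self.stoichiometry if s.molecule_id == molecule_id)

    def validate_against(self, molecules: list[RnaMolecule]) -> None:
        by_id = {m.id: m for m in molecules}
        for site in self.stoichiometry:
            mol = by_id.get(site.molecule_id)
            if mol is None:
                raise ValueError(f"{site.molecule_id}: unknown molecule")
            if not 1 <= site.position <= len(mol):
                raise ValueError(
                    f"{site.molecule_id}: position {site.position} outside 1..{len(mol)}"
                )
            base = mol.base(site.position)
            if base not in site.type.allowed_bases:
                raise ValueError(
                    f"{site.molecule_id}:{site.position} {site.mod_type} "
                    f"not compatible with base {base}"
                )


@dataclass(frozen=True)
class LabelScheme:
    """Per-nucleoside stable-isotope substitution of the heavy channel.

    The heavy internal standard is transcribed in vitro from
    13C-labelled NTPs; ``substitutions`` maps nucleoside -> number of
    carbons replaced by 13C.  The two schemes used with RNase T1 and
    RNase A digests are provided as :data:`T1_SCHEME` (13C10-guanosine)
    and :data:`A_SCHEME` (13C9-cytidine + 13C9-uridine).
    """

    name: str
    substitutions: dict  # base -> 13C count

    def __post_init__(self):
        from .constants import NUCLEOSIDE_CARBONS

        for base, n in self.substitutions.items():
            if base not in NUCLEOSIDE_CARBONS:
                raise ValueError(f"{self.name}: unknown nucleoside {base!r}")
            if not 0 <= n <= NUCLEOSIDE_CARBONS[base]:
                raise ValueError(
                    f"{self.name}: {n} 13C atoms exceed the {NUCLEOSIDE_CARBONS[base]} "
                    f"carbons of {base}"
                )

    def label_count(self, sequence: str) -> int:
        return sum(self.substitutions.get(b, 0) for b in sequence)


T1_SCHEME = LabelScheme("T1-scheme", {"G": 10})
A_SCHEME = LabelScheme("A-scheme", {"C": 9, "U": 9})
LABEL_SCHEMES = {s.name: s for s in (T1_SCHEME, A_SCHEME)}


def read_fasta(path) -> list[RnaMolecule]:
    """Read RNA (or DNA; T is mapped to U) molecules from a FASTA file.

    End-group chemistry defaults to 5'-hydroxyl / 3'-linear-phosphate and can
    be overridden per record with header tags, e.g.::

        >U2 five_prime_end=tmg-cap three_prime_end=hydroxyl
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    molecules = []
    for rec in records:
        tags = dict(
            item.split("=", 1) for item in rec.description.split()[1:] if "=" in item
        )
        seq = str(rec.seq).upper().replace("T", "U")
        for i, ch in enumerate(seq, start=1):
            if ch not in RNA_ALPHABET:
                raise ValueError(f"{path}: record {rec.id!r} illegal character {ch!r} at position {i}")
        molecules.append(
            RnaMolecule(
                id=rec.id,
                sequence=seq,
                five_prime_end=tags.get("five_prime_end", "hydroxyl"),
                three_prime_end=tags.get("three_prime_end", "linear-phosphate"),
            )
        )
    return molecules


MOD_TABLE_COLUMNS = ["molecule_id", "position", "mod_type", "stoichiometry"]


def read_modification_table(path, molecules: list[RnaMolecule]) -> ModificationProfile:
    """Read a per-site stoichiometry table (TSV) and validate it against
    the given molecules (bounds, base compatibility, duplicates)."""
    table = pd.read_csv(path, sep="\t")
    missing = set(MOD_TABLE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    stoich = {}
    for row in table.itertuples(index=False):
        site = ModificationSite(str(row.molecule_id), int(row.position), str(row.mod_type))
        if (site.molecule_id, site.position) in {(s.molecule_id, s.position) for s in stoich}:
            raise ValueError(f"{path}: duplicate row for {site.molecule_id}:{site.position}")
        frac = float(row.stoichiometry)
        if not 0.0 <= frac <= 1.0:
            raise ValueError(
                f"{path}: stoichiometry {frac} for {site.molecule_id}:{site.position} outside [0, 1]"
            )
        stoich[site] = frac
    profile = ModificationProfile(stoich)
    profile.validate_against(molecules)
    return profile


def write_modification_table(profile: ModificationProfile, path) -> None:
    rows = [
        (s.molecule_id, s.position, s.mod_type, f)
        for s, f in sorted(profile.stoichiometry.items())
    ]
    pd.DataFrame(rows, columns=MOD_TABLE_COLUMNS).to_csv(path, sep="\t", index=False)


def annotate_sequence(sequence: str, start: int, sites) -> str:
    """Render a fragment sequence with modification letters (CAmCUCCG style):
    'm' after a 2'-O-methylated base, 'Ψ' replacing pseudouridine, '(m6)'
    after a base-methylated residue."""
    by_pos = {s.position: s for s in sites}
    out = []
    for offset, base in enumerate(sequence):
        pos = start + offset
        site = by_pos.get(pos)
        if site is None:
            out.append(base)
        elif site.type.mass_silent:
            out.append("Ψ")
        elif site.mod_type == "2'-O-methyl":
            out.append(base + "m")
        else:
            out.append(base + "(m6)" if site.mod_type == "N6-methyl" else base + "(m)")
    return "".join(out)


def shift_site(site: ModificationSite, offset: int, new_molecule_id: str) -> ModificationSite:
    return replace(site, molecule_id=new_molecule_id, position=site.position + offset)
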