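"""Synthetic ground-truth scenarios and paired light/heavy LC-MS observations.

The generator emulates an isotope-dilution snRNA modification experiment:
a cellular ("light") RNA carrying partial modifications is mixed ~1:1 with
an unmodified in-vitro transcript ("heavy", 13C-labelled NTPs), digested
with RNase T1 and/or RNase A (optionally after a guide-directed RNase H
split), and measured in negative mode over a fixed m/z window.  For every
site the simulator emits the light-unmodified, light-modified and
heavy-reference species at their theoretical m/z (Gaussian ppm error),
with intensities proportional to (1-f), f and 1/mixing times lognormal
noise, as Gaussian chromatographic peaks; mass-silent pseudouridine
species appear at a shifted retention time instead of a shifted mass.

The default scenario uses SYNTHETIC 164-nt "U1-like" and 188-nt "U2-like"
sequences (the real snRNA sequences are not part of this package's inputs)
engineered so that the benchmark fragments sit at their reference
coordinates: CACUCCG at 69-75 with the 70Am site and its base-composition
isobar ACCCCUG at 85-91 in U1; UUGG at 17-20 (19Gm), AAGAU at 23-27
(25Gm), GGC at 11-13 (11/12Gm), UAG at 34-36 (34Psi) and so on in U2,
which is split before residue 17 by RNase H for the 19Gm readout.  Filler
regions are built from blocks with pairwise-distinct base multisets so
that filler fragments have unique m/z and serve as mixing-correction
pairs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .digestion import CLEAVAGE_RULES, Fragment, cleavage_sites, rnase_h_split
from .masses import DEFAULT_MZ_WINDOW, make_species, ms2_ladders, mz_negative, observable_charges
from .rna import LABEL_SCHEMES, ModificationSite, RnaMolecule

# --- synthetic benchmark sequences -------------------------------------------

_U1_SEQUENCE = (
    "AUACUUACCUG"                                                   # 1-11 cap fragment
    "AACGAUCGACCGAAUGAUUGCCUGCUUGAAAGCCCGAAACGAAAUGAACCGAAUUG"      # 12-67 filler
    "G"                                                             # 68
    "CACUCCG"                                                       # 69-75 (70Am)
    "AAUCCACUG"                                                     # 76-84
    "ACCCCUG"                                                       # 85-91 isobar of 69-75
    "ACCCGACCUGACUUGAUUUGCCCUGCCUUG"                                # 92-121 filler
    "AAACCGAAACUGAAAUUGAACCCGAACCUGAACUUG"                          # 122-157 filler
    "AAUUCCC"                                                       # 158-164 3' tail
)

_U2_SEQUENCE = (
    "AUC"            # 1-3   cap fragment (RNase A)
    "CACAAC"         # 4-9
    "U"              # 10
    "GGC"            # 11-13 (11Gm, 12Gm)
    "ACA"            # 14-16
    "UUGG"           # 17-20 (19Gm; RNase H cut before 17)
    "AC"             # 21-22
    "AAGAU"          # 23-27 (25Gm)
    "C"              # 28
    "AAGU"           # 29-32 (30Am)
    "G"              # 33
    "UAG"            # 34-36 (34 pseudouridine)
    "UAUCUG"         # 37-42 (40Cm)
    "UUCUUAUCAG"     # 43-52 (47Um)
    "UUUAAUAUCUG"    # 53-63 (61Cm)
    "CGACGAACGAAAACGAAAAACGAAAAAACGAAAAAAACGAAAAAAAACGAAAAAAAAACG"  # 64-124 filler
    "AAAAUGAAAAAUGAAAAAAUGAAAAAAAUGAAAAAAAAUG"                      # 125-164 filler
    "AAAAAAAAAACUGAAAAAAAAAUUG"                                     # 165-188 filler
)

U1_LIKE = RnaMolecule("U1", _U1_SEQUENCE, five_prime_end="tmg-cap", three_prime_end="hydroxyl")
U2_LIKE = RnaMolecule("U2", _U2_SEQUENCE, five_prime_end="tmg-cap", three_prime_end="hydroxyl")

#: 5' end chemistry of the in-vitro-transcribed heavy reference.
HEAVY_FIVE_PRIME_END = "triphosphate"

ENZYME_SCHEMES = {"RNaseT1": LABEL_SCHEMES["T1-scheme"], "RNaseA": LABEL_SCHEMES["A-scheme"]}


# --- scenario description -----------------------------------------------------

@dataclass(frozen=True)
class SiteGroup:
    """A co-regulated set of modification sites quantified as one table row.

    ``truth`` maps condition name to the ground-truth modified fraction.
    ``digest`` names the digest in which the group is quantified, and
    ``methods`` which estimators apply ('silnas', 'peak_area').
    """

    label: str
    sites: tuple  # ModificationSite, parent-molecule coordinates
    truth: dict
    digest: str
    methods: tuple = ("peak_area",)
    guide: str = ""

    @property
    def molecule_id(self) -> str:
        return self.sites[0].molecule_id

    @property
    def is_dependent(self) -> bool:
        values = list(self.truth.values())
        return max(values) - min(values) > 1e-12


@dataclass(frozen=True)
class DigestSpec:
    """One LC-MS run: a molecule digested with one enzyme, optionally after
    a guide-directed RNase H split before ``split_before``."""

    name: str
    molecule_id: str
    enzyme: str
    split_before: int | None = None
    split_piece: str = "downstream"


@dataclass
class SimulationScenario:
    molecules: list
    groups: list  # SiteGroup
    digests: list  # DigestSpec
    conditions: tuple = ("control", "knockdown-1", "knockdown-2")
    reference_condition: str = "control"
    n_replicates: int = 3
    mixing: float = 1.0          # true light:heavy molar ratio (nominal 1.0)
    intensity_cv: float = 0.05   # lognormal multiplicative noise per species
    mass_error_ppm: float = 2.0  # Gaussian m/z error, per scan
    stoichiometry_jitter_sd: float = 0.01  # biological replicate variation of f
    rt_jitter_sd: float = 0.02   # min
    peak_sigma: float = 0.05     # chromatographic Gaussian width, min
    rt_step: float = 0.02        # scan spacing, min
    base_intensity: float = 1.0e6
    region_intensity_sigma: float = 0.4  # lognormal spread of per-fragment response
    isomer_rt_step: float = 0.4  # extra shift per methyl position towards 3'
    n_correction_pairs: int = 10
    window: tuple = DEFAULT_MZ_WINDOW
    max_charge: int = 8
    emit_ms2: bool = True
    seed: int = 17

    def __post_init__(self):
        for name in ("intensity_cv", "mass_error_ppm", "rt_jitter_sd", "peak_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        known = {g.label for g in self.groups}
        if len(known) != len(self.groups):
            raise ValueError("duplicate group labels")
        digest_names = {d.name for d in self.digests}
        for g in self.groups:
            if g.digest not in digest_names:
                raise ValueError(f"group {g.label} references unknown digest {g.digest}")

    def truths_table(self) -> pd.DataFrame:
        rows = [
            (g.label, g.molecule_id, cond, g.truth[cond], g.is_dependent)
            for g in self.groups
            for cond in self.conditions
        ]
        return pd.DataFrame(
            rows, columns=["group", "molecule_id", "condition", "truth", "dependent"]
        )


def _m(mol_id: str, pos: int, mod: str = "2'-O-methyl") -> ModificationSite:
    return ModificationSite(mol_id, pos, mod)


def _truth(control, kd1=None, kd2=None):
    if kd1 is None:
        kd1 = kd2 = control  # structurally invariant site
    return {"control": control, "knockdown-1": kd1, "knockdown-2": kd2}


def default_scenario(**overrides) -> SimulationScenario:
    """The benchmark scenario: a U1-like and a U2-like molecule carrying the
    reference site set, a control and two independent knockdown conditions,
    3 replicates each.

    Control stoichiometries follow the reference control (ncRNA-treated) values
    and the knockdown values the two reference siRNA measurements for the
    TDP-43-dependent sites; structurally invariant sites (the caps, 11Gm,
    12Gm, 30Am and the 34 pseudouridine) keep their control value in every
    condition, so any apparent change there is noise by construction.
    """
    groups = [
        SiteGroup("U1-cap", (_m("U1", 1), _m("U1", 2)),
                  _truth(1.0), "U1-T1", ("peak_area",), "scaRNA16, 18"),
        SiteGroup("70Am", (_m("U1", 70),),
                  _truth(0.793, 0.242, 0.234), "U1-T1",
                  ("silnas", "peak_area"), "scaRNA7"),
        SiteGroup("U2-cap", (_m("U2", 1), _m("U2", 2)),
                  _truth(0.993), "U2-A", ("peak_area",)),
        SiteGroup("11Gm", (_m("U2", 11),),
                  _truth(0.953), "U2-A", ("peak_area",), "scaRNA2"),
        SiteGroup("12Gm", (_m("U2", 12),),
                  _truth(0.962), "U2-A", ("peak_area",)),
        SiteGroup("19Gm", (_m("U2", 19),),
                  _truth(0.765, 0.477, 0.539), "U2dn-T1", ("silnas",), "scaRNA9"),
        SiteGroup("25Gm", (_m("U2", 25),),
                  _truth(0.980, 0.339, 0.331), "U2-A",
                  ("silnas", "peak_area"), "scaRNA2"),
        SiteGroup("30Am", (_m("U2", 30),),
                  _truth(0.948), "U2-A", ("peak_area",), "scaRNA9"),
        SiteGroup("34Psi", (ModificationSite("U2", 34, "pseudouridine"),),
                  _truth(0.840), "U2-T1", ("silnas", "peak_area"), "scaRNA8"),
        SiteGroup("40Cm", (_m("U2", 40),),
                  _truth(0.951, 0.737, 0.636), "U2-T1", ("peak_area",)),
        SiteGroup("47Um", (_m("U2", 47),),
                  _truth(0.956, 0.271, 0.245), "U2-T1", ("peak_area",), "scaRNA28"),
        SiteGroup("61Cm", (_m("U2", 61),),
                  _truth(0.572, 0.206, 0.168), "U2-T1", ("peak_area",), "scaRNA2"),
    ]
    digests = [
        DigestSpec("U1-T1", "U1", "RNaseT1"),
        DigestSpec("U2-T1", "U2", "RNaseT1"),
        DigestSpec("U2dn-T1", "U2", "RNaseT1", split_before=17),
        DigestSpec("U2-A", "U2", "RNaseA"),
    ]
    scenario = SimulationScenario(
        molecules=[U1_LIKE, U2_LIKE], groups=groups, digests=digests, **overrides
    )
    return scenario


def recovery_scenario(
    truths: tuple = (0.05, 0.25, 0.50, 0.75, 0.95),
    mixing: float = 0.9,
    **overrides,
) -> SimulationScenario:
    """A parameter-recovery benchmark: one synthetic molecule with one
    2'-O-methyl site per target stoichiometry, each on its own RNase T1
    fragment with a unique base composition, plus twelve unmodified filler
    fragments that serve as mixing-correction pairs.  Defaults: 3
    replicates, 5% intensity CV, 2 ppm mass error, mixing 0.9.
    """
    site_bodies = ["ACC", "ACU", "AUU", "ACCC", "AUUU"]
    if len(truths) > len(site_bodies):
        raise ValueError(f"at most {len(site_bodies)} recovery sites supported")
    fillers = ["CC", "CU", "UU", "CCC", "CCU", "CUU", "UUU",
               "CCCC", "CCCU", "CCUU", "CUUU", "UUUU"]
    groups = []
    pos = 4
    sequence_parts = ["CCG"]
    for i, f in enumerate(truths):
        body = site_bodies[i]
        sequence_parts.append(body + "G")
        site_pos = pos  # the single A heads each site body
        groups.append(
            SiteGroup(
                label=f"site{i + 1}",
                sites=(ModificationSite("REC", site_pos, "2'-O-methyl"),),
                truth={"sample": float(f)},
                digest="REC-T1",
                methods=("silnas", "peak_area"),
            )
        )
        pos += len(body) + 1
    for body in fillers[1:]:
        sequence_parts.append(body + "G")
        pos += len(body) + 1
    molecule = RnaMolecule("REC", "".join(sequence_parts),
                           five_prime_end="hydroxyl", three_prime_end="hydroxyl")
    return SimulationScenario(
        molecules=[molecule],
        groups=groups,
        digests=[DigestSpec("REC-T1", "REC", "RNaseT1")],
        conditions=("sample",),
        reference_condition="sample",
        mixing=mixing,
        stoichiometry_jitter_sd=0.0,
        **overrides,
    )


# --- species enumeration (shared with the analysis pipeline) ------------------

@dataclass(frozen=True)
class SpeciesTemplate:
    """A (fragment, variant) species with the group-presence pattern that
    produces it; the abundance weight is the product over ``presence`` of
    f (present) or 1-f (absent)."""

    fragment: Fragment
    presence: tuple  # ((group_label, bool), ...)

    def weight(self, truths: dict) -> float:
        w = 1.0
        for label, present in self.presence:
            f = truths[label]
            w *= f if present else (1.0 - f)
        return w

    @property
    def variant_key(self) -> tuple:
        return tuple(sorted((s.position, s.mod_type) for s in self.fragment.sites))


def enumerate_digest_species(
    molecule: RnaMolecule, rule, groups: list
) -> list[SpeciesTemplate]:
    """All zero-missed-cleavage species of a partially modified digest.

    Blocking (2'-O-methyl) sites suppress their cut only in the molecules
    where the owning group is present, so fragment boundaries themselves
    depend on group presence; this enumerates every consistent
    (fragment, variant) combination with the exact presence pattern
    required to produce it.
    """
    site_owner: dict[int, str] = {}
    group_by_label = {}
    for g in groups:
        group_by_label[g.label] = g
        for s in g.sites:
            if s.position in site_owner:
                raise ValueError(f"position {s.position} claimed by two groups")
            site_owner[s.position] = g.label

    all_sites = [s for g in groups for s in g.sites]
    blocking = {
        s.position: site_owner[s.position]
        for s in all_sites
        if s.type.blocks_3prime_cleavage
        and s.position < len(molecule)
        and molecule.base(s.position) in rule.cut_after_bases
    }
    always_cuts = set(cleavage_sites(molecule, rule, all_sites))
    bounds = sorted({0, len(molecule)} | always_cuts | set(blocking))
    templates: list[SpeciesTemplate] = []
    for ia, a in enumerate(bounds[:-1]):
        for b in bounds[ia + 1 :]:
            inner = [p for p in bounds if a < p < b]
            if any(p in always_cuts for p in inner):
                break  # extending further also crosses this always-cut
            forced: dict[str, bool] = {}
            ok = True
            for p in inner:  # blocked positions retained inside => owner present
                if forced.setdefault(blocking[p], True) is not True:
                    ok = False
            for p in (a, b):  # active cut at a boundary => owner absent
                if p in blocking:
                    if forced.setdefault(blocking[p], False) is not False:
                        ok = False
            if not ok:
                continue
            frag_groups = sorted(
                {site_owner[pos] for pos in range(a + 1, b + 1) if pos in site_owner}
            )
            free = [g for g in frag_groups if g not in forced]
            for combo in itertools.product([False, True], repeat=len(free)):
                presence = dict(forced)
                presence.update(dict(zip(free, combo)))
                present_sites = tuple(
                    sorted(
                        s
                        for label, on in presence.items()
                        if on
                        for s in group_by_label[label].sites
                        if a + 1 <= s.position <= b
                    )
                )
                frag = Fragment(
                    molecule_id=molecule.id,
                    start=a + 1,
                    end=b,
                    sequence=molecule.subsequence(a + 1, b),
                    sites=present_sites,
                    missed_cleavages=0,
                    five_prime_end=(
                        molecule.five_prime_end if a == 0 else rule.product_5prime_end
                    ),
                    three_prime_end=(
                        molecule.three_prime_end
                        if b == len(molecule)
                        else rule.product_3prime_end
                    ),
                    provenance=(rule.enzyme,),
                )
                templates.append(
                    SpeciesTemplate(frag, tuple(sorted(presence.items())))
                )
    templates.sort(key=lambda t: (t.fragment.start, t.fragment.end, t.variant_key))
    return templates


def digest_context(scenario: SimulationScenario, spec: DigestSpec) -> dict:
    """Resolve a digest spec into light/heavy molecules, local site groups,
    cleavage rule and label scheme."""
    molecule = next(m for m in scenario.molecules if m.id == spec.molecule_id)
    groups = [g for g in scenario.groups if g.molecule_id == spec.molecule_id]
    heavy = replace(molecule, five_prime_end=HEAVY_FIVE_PRIME_END)
    if spec.split_before is not None:
        sites = [s for g in groups for s in g.sites]
        pieces_l = rnase_h_split(molecule, spec.split_before, sites)
        pieces_h = rnase_h_split(heavy, spec.split_before, ())
        idx = 1 if spec.split_piece == "downstream" else 0
        molecule, _, offset = pieces_l[idx]
        heavy = pieces_h[idx][0]
        local_groups = []
        for g in groups:
            shifted = _shifted(g, molecule, offset)
            if shifted and len(shifted) != len(g.sites):
                raise ValueError(f"group {g.label} straddles the RNase H cut")
            if shifted:
                local_groups.append(replace(g, sites=tuple(shifted)))
        groups = local_groups
    rule = CLEAVAGE_RULES[spec.enzyme]
    return dict(
        molecule=molecule,
        heavy_molecule=heavy,
        groups=groups,
        rule=rule,
        scheme=ENZYME_SCHEMES[spec.enzyme],
    )


def _shifted(group: SiteGroup, piece: RnaMolecule, offset: int) -> list:
    out = []
    for s in group.sites:
        local = s.position - offset
        if 1 <= local <= len(piece):
            out.append(ModificationSite(piece.id, local, s.mod_type))
    return out


# --- the simulator ------------------------------------------------------------

@dataclass
class SimulationResult:
    scenario: SimulationScenario
    peaklists: dict  # (condition, replicate, digest) -> DataFrame(mz, rt, intensity)
    spectra: dict    # (condition, replicate, digest) -> list of MS2 dicts
    ledger: pd.DataFrame
    truths: pd.DataFrame
    realized_truths: pd.DataFrame = field(default_factory=pd.DataFrame)


def _species_rt_offset(template: SpeciesTemplate, scenario: SimulationScenario) -> float:
    """RT shift of a variant species against its fragment's base RT: the
    per-modification shift plus a positional term separating methyl
    positional isomers (methyls nearer the 3' end elute later)."""
    offset = 0.0
    for s in template.fragment.sites:
        offset += s.type.rt_shift
        if s.mod_type == "2'-O-methyl":
            offset += scenario.isomer_rt_step * (s.position - template.fragment.start)
    return offset


def _build_species(ctx, scenario):
    """(template, channel, mz, charge) for every observable species."""
    light = enumerate_digest_species(ctx["molecule"], ctx["rule"], ctx["groups"])
    heavy = enumerate_digest_species(ctx["heavy_molecule"], ctx["rule"], [])
    out = []
    for template, channel in [(t, "light") for t in light] + [(t, "heavy") for t in heavy]:
        sp = make_species(
            template.fragment, template.fragment.sites, channel,
            ctx["scheme"] if channel == "heavy" else None,
        )
        charges = observable_charges(sp.monoisotopic_mass, scenario.window, scenario.max_charge)
        if not charges:
            continue
        z = charges[0]
        out.append(
            dict(
                template=template,
                channel=channel,
                species=sp,
                charge=z,
                mz=mz_negative(sp.monoisotopic_mass, z),
            )
        )
    return out


def _assign_rts(entries, scenario, rng) -> dict:
    """Base retention time per fragment (start, end, molecule), with same-m/z
    fragment families pushed apart so co-isolating species stay RT-resolved."""
    frag_keys = sorted({(e["template"].fragment.start, e["template"].fragment.end) for e in entries})
    slots = rng.uniform(8.0, 45.0, size=len(frag_keys))
    base_rt = dict(zip(frag_keys, slots))
    # respace families that share an m/z cluster
    order = sorted(entries, key=lambda e: e["mz"])
    i = 0
    min_gap = 3.0
    while i < len(order):
        j = i
        while (
            j + 1 < len(order)
            and (order[j + 1]["mz"] - order[i]["mz"]) / order[i]["mz"] * 1e6 <= 10.0
        ):
            j += 1
        if j > i:
            fams = sorted(
                {(e["template"].fragment.start, e["template"].fragment.end) for e in order[i : j + 1]},
                key=lambda k: base_rt[k],
            )
            for prev, cur in zip(fams, fams[1:]):
                gap = base_rt[cur] - base_rt[prev]
                if gap < min_gap:
                    base_rt[cur] += min_gap - gap
        i = j + 1
    return base_rt


def simulate(scenario: SimulationScenario) -> SimulationResult:
    """Generate MS1 peak lists (and optional MS2 spectra) for every
    condition x replicate x digest, plus a ground-truth ledger sufficient to
    recompute every expected estimate exactly.  Deterministic given the
    scenario seed."""
    for g in scenario.groups:
        if not any(m.id == g.molecule_id for m in scenario.molecules):
            raise ValueError(f"group {g.label} references unknown molecule {g.molecule_id}")
    root = np.random.SeedSequence(scenario.seed)
    n_noise = len(scenario.digests) * len(scenario.conditions) * scenario.n_replicates
    children = root.spawn(len(scenario.digests) + n_noise + 1)
    struct_rngs = [np.random.default_rng(c) for c in children[: len(scenario.digests)]]
    noise_iter = iter(children[len(scenario.digests) : -1])

    peaklists, spectra = {}, {}
    ledger_rows = []
    # Biological replicate-to-replicate variation of the true stoichiometry:
    # one realized fraction per (group, condition, replicate), shared by all
    # digests of the same sample.  Replicate effects are drawn sum-to-zero
    # within each condition (and rescaled to keep the per-replicate variance),
    # so condition-level means sit exactly at the prescribed truths and the
    # expected significance pattern is a structural property of the fixture,
    # not a per-seed accident.  Near the [0, 1] boundaries the effect scale
    # shrinks with the distance to the boundary so realized fractions stay
    # in range without clipping bias.
    bio_rng = np.random.default_rng(children[-1])
    sd = scenario.stoichiometry_jitter_sd
    n_rep = scenario.n_replicates
    realized: dict = {}
    for g in sorted(scenario.groups, key=lambda g: g.label):
        for condition in scenario.conditions:
            f0 = g.truth[condition]
            sd_eff = min(sd, f0 / 3.0, (1.0 - f0) / 3.0)
            if sd_eff > 0 and n_rep > 1:
                eff = bio_rng.normal(0.0, sd_eff, size=n_rep)
                eff = (eff - eff.mean()) * np.sqrt(n_rep / (n_rep - 1))
            else:
                eff = np.zeros(n_rep)
            for rep in range(1, n_rep + 1):
                realized[(g.label, condition, f"rep{rep}")] = float(
                    np.clip(f0 + eff[rep - 1], 0.0, 1.0)
                )

    per_digest = []
    for spec, srng in zip(scenario.digests, struct_rngs):
        ctx = digest_context(scenario, spec)
        entries = _build_species(ctx, scenario)
        base_rt = _assign_rts(entries, scenario, srng)
        # response factors are a property of the digestion locus, so they are
        # shared across the fragment family of one always-cut region: species
        # whose boundaries differ only through blocking methyls stay comparable
        all_sites = [s for g in ctx["groups"] for s in g.sites]
        region_bounds = [0] + cleavage_sites(ctx["molecule"], ctx["rule"], all_sites) + [
            len(ctx["molecule"])
        ]
        n_regions = len(region_bounds) - 1
        region_draw = np.exp(srng.normal(0.0, scenario.region_intensity_sigma, size=n_regions))
        region_scale = {}
        for key in sorted({(e["template"].fragment.start, e["template"].fragment.end) for e in entries}):
            idx = int(np.searchsorted(region_bounds, key[0] - 1, side="right")) - 1
            region_scale[key] = float(region_draw[min(idx, n_regions - 1)])
        per_digest.append((spec, ctx, entries, base_rt, region_scale))

    sigma_ln = float(np.sqrt(np.log1p(scenario.intensity_cv**2)))
    for spec, ctx, entries, base_rt, region_scale in per_digest:
        for condition in scenario.conditions:
            for rep in range(1, scenario.n_replicates + 1):
                rng = np.random.default_rng(next(noise_iter))
                key = (condition, f"rep{rep}", spec.name)
                rows, ms2_list = [], []
                for e in entries:
                    t = e["template"]
                    truths = {
                        label: realized[(label, condition, f"rep{rep}")]
                        for label, _ in t.presence
                    }
                    weight = t.weight(truths) if e["channel"] == "light" else 1.0
                    # one noise stream per species keeps replicates exchangeable
                    eps = float(np.exp(rng.normal(0.0, sigma_ln)))
                    drt = float(rng.normal(0.0, scenario.rt_jitter_sd))
                    if weight <= 0.0:
                        continue
                    fkey = (t.fragment.start, t.fragment.end)
                    amplitude = (
                        scenario.base_intensity
                        * region_scale[fkey]
                        * weight
                        * (scenario.mixing if e["channel"] == "light" else 1.0)
                        * eps
                    )
                    rt_obs = base_rt[fkey] + _species_rt_offset(t, scenario) + drt
                    k_lo = int(np.floor((rt_obs - 4 * scenario.peak_sigma) / scenario.rt_step))
                    k_hi = int(np.ceil((rt_obs + 4 * scenario.peak_sigma) / scenario.rt_step))
                    grid = np.arange(k_lo, k_hi + 1) * scenario.rt_step
                    profile = amplitude * np.exp(
                        -0.5 * ((grid - rt_obs) / scenario.peak_sigma) ** 2
                    )
                    # mass error is per scan, as on a real instrument; the
                    # feature-level m/z averages to well under the tolerance
                    mz_scans = e["mz"] * (
                        1.0 + rng.normal(0.0, scenario.mass_error_ppm, size=grid.size) * 1e-6
                    )
                    for mz_i, t_i, inten in zip(mz_scans, grid, profile):
                        rows.append((float(mz_i), float(t_i), float(inten)))
                    mz_obs = e["mz"]
                    if scenario.emit_ms2:
                        ladder = ms2_ladders(
                            e["species"], max_charge=2,
                            scheme=ctx["scheme"] if e["channel"] == "heavy" else None,
                        )
                        ms2_list.append(
                            dict(
                                precursor_mz=mz_obs,
                                rt=rt_obs,
                                peaks=pd.DataFrame(
                                    {
                                        "mz": [ion.mz for ion in ladder],
                                        "intensity": np.full(len(ladder), 100.0),
                                    }
                                ),
                            )
                        )
                    ledger_rows.append(
                        dict(
                            digest=spec.name,
                            condition=condition,
                            replicate=f"rep{rep}",
                            molecule_id=t.fragment.molecule_id,
                            start=t.fragment.start,
                            end=t.fragment.end,
                            channel=e["channel"],
                            variant=";".join(
                                f"{p}:{m}" for p, m in t.variant_key
                            ),
                            charge=e["charge"],
                            mz_theoretical=e["mz"],
                            mz_observed=mz_obs,
                            rt=rt_obs,
                            weight=weight,
                            amplitude=amplitude,
                        )
                    )
                frame = (
                    pd.DataFrame(rows, columns=["mz", "rt", "intensity"])
                    .sort_values(["rt", "mz"], kind="stable")
                    .reset_index(drop=True)
                )
                peaklists[key] = frame
                spectra[key] = ms2_list
    realized_table = pd.DataFrame(
        [
            dict(group=label, condition=condition, replicate=rep, truth=f)
            for (label, condition, rep), f in sorted(realized.items())
        ]
    )
    return SimulationResult(
        scenario=scenario,
        peaklists=peaklists,
        spectra=spectra,
        ledger=pd.DataFrame(ledger_rows),
        truths=scenario.truths_table(),
        realized_truths=realized_table,
    )


# --- fixture I/O --------------------------------------------------------------

def write_fixtures(result: SimulationResult, directory) -> list:
    """Write a simulation as plain-text fixtures: FASTA molecules, per-condition
    site tables, scenario config, TSV peak lists and MS2 tables, ledger.
    Everything round-trips through the package readers."""
    import pathlib

    import yaml

    directory = pathlib.Path(directory)
    if not directory.exists():
        raise FileNotFoundError(f"{directory} does not exist")
    written = []
    scenario = result.scenario

    fasta = directory / "molecules.fasta"
    with open(fasta, "w") as fh:
        for mol in scenario.molecules:
            fh.write(
                f">{mol.id} five_prime_end={mol.five_prime_end} "
                f"three_prime_end={mol.three_prime_end}\n{mol.sequence}\n"
            )
    written.append(fasta)

    for condition in scenario.conditions:
        path = directory / f"sites_{condition}.tsv"
        rows = [
            (s.molecule_id, s.position, s.mod_type, g.truth[condition])
            for g in scenario.groups
            for s in g.sites
        ]
        pd.DataFrame(
            rows, columns=["molecule_id", "position", "mod_type", "stoichiometry"]
        ).to_csv(path, sep="\t", index=False)
        written.append(path)

    config = dict(
        seed=scenario.seed,
        conditions=list(scenario.conditions),
        reference_condition=scenario.reference_condition,
        n_replicates=scenario.n_replicates,
        mixing=scenario.mixing,
        intensity_cv=scenario.intensity_cv,
        mass_error_ppm=scenario.mass_error_ppm,
        window=list(scenario.window),
        digests=[
            dict(name=d.name, molecule_id=d.molecule_id, enzyme=d.enzyme,
                 split_before=d.split_before)
            for d in scenario.digests
        ],
        groups=[
            dict(
                label=g.label,
                molecule_id=g.molecule_id,
                positions=[s.position for s in g.sites],
                mod_types=[s.mod_type for s in g.sites],
                digest=g.digest,
                methods=list(g.methods),
                guide=g.guide,
                truth={c: float(v) for c, v in g.truth.items()},
            )
            for g in scenario.groups
        ],
    )
    cfg_path = directory / "scenario.yaml"
    with open(cfg_path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
    written.append(cfg_path)

    for (condition, rep, digest), frame in result.peaklists.items():
        path = directory / f"peaks__{condition}__{rep}__{digest}.tsv"
        frame.to_csv(path, sep="\t", index=False)
        written.append(path)
    for (condition, rep, digest), specs in result.spectra.items():
        if not specs:
            continue
        parts = []
        for i, spec in enumerate(specs):
            part = spec["peaks"].copy()
            part.insert(0, "spectrum", i)
            part.insert(1, "precursor_mz", spec["precursor_mz"])
            part.insert(2, "precursor_rt", spec["rt"])
            parts.append(part)
        path = directory / f"ms2__{condition}__{rep}__{digest}.tsv"
        pd.concat(parts, ignore_index=True).to_csv(path, sep="\t", index=False)
        written.append(path)

    ledger_path = directory / "ledger.tsv"
    result.ledger.to_csv(ledger_path, sep="\t", index=False)
    written.append(ledger_path)
    if not result.realized_truths.empty:
        truth_path = directory / "realized_truths.tsv"
        result.realized_truths.to_csv(truth_path, sep="\t", index=False)
        written.append(truth_path)
    return written


def read_ms2_table(path) -> list[dict]:
    """Inverse of the MS2 table layout written by :func:`write_fixtures`."""
    table = pd.read_csv(path, sep="\t")
    out = []
    for _, sub in table.groupby("spectrum", sort=True):
        out.append(
            dict(
                precursor_mz=float(sub["precursor_mz"].iloc[0]),
                rt=float(sub["precursor_rt"].iloc[0]),
                peaks=sub[["mz", "intensity"]].reset_index(drop=True),
            )
        )
    return out
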