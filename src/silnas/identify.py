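"""Matching observed MS1 features (and optional MS2 spectra) against the
theoretical digest search space.

The search space enumerates, per molecule and enzyme, every fragment up to
the missed-cleavage cap, in the modification variants an RNA search engine
would consider: the unmodified form, each single variable methyl placement
(at most one variable methyl per fragment), and the fixed known-site
variant — known sites are exempt from the variable cap so that
multiply-methylated species such as GmGmC stay reachable.  Matching is by
m/z within a ppm tolerance (default +/-5 ppm at MS1, +/-20 ppm at MS2);
sequences with identical base composition collide exactly in m/z and are
reported as one ambiguity group, resolvable only by discriminating MS2
ions or chromatography.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .digestion import CLEAVAGE_RULES, digest
from .masses import (
    DEFAULT_MZ_WINDOW,
    IonSpecies,
    ions_for,
    make_species,
    ms2_ladders,
)
from .rna import LabelScheme, ModificationSite, RnaMolecule, LABEL_SCHEMES


@dataclass
class SearchSpace:
    """Deduplicated ion index over species x charges."""

    ions: list  # list[IonSpecies]
    window: tuple
    _mz: np.ndarray = field(init=False, repr=False)
    _order: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        mz = np.array([ion.mz for ion in self.ions], dtype=float)
        self._order = np.argsort(mz, kind="stable")
        self._mz = mz[self._order]

    def query(self, mz: float, tol_ppm: float) -> list:
        tol = mz * tol_ppm * 1e-6
        lo = np.searchsorted(self._mz, mz - tol, side="left")
        hi = np.searchsorted(self._mz, mz + tol, side="right")
        return [self.ions[self._order[i]] for i in range(lo, hi)]


def enumerate_variants(
    fragment, known_sites, variable_methyl: bool = True
) -> list[tuple]:
    """Modification variants of a fragment: unmodified, fixed known sites,
    and single variable 2'-O-methyl placements on any residue."""
    variants = [()]
    fixed = tuple(s for s in known_sites if fragment.start <= s.position <= fragment.end)
    if fixed and fixed not in variants:
        variants.append(fixed)
    if variable_methyl:
        for pos in range(fragment.start, fragment.end + 1):
            if any(s.position == pos for s in fixed):
                continue
            variants.append(
                (ModificationSite(fragment.molecule_id, pos, "2'-O-methyl"),)
            )
    # dedupe preserving order
    seen, unique = set(), []
    for v in variants:
        key = tuple(sorted((s.position, s.mod_type) for s in v))
        if key not in seen:
            seen.add(key)
            unique.append(tuple(sorted(v)))
    return unique


def build_search_space(
    molecules: list[RnaMolecule],
    enzymes: list[str] = ("RNaseT1",),
    max_missed: int = 1,
    window: tuple = DEFAULT_MZ_WINDOW,
    known_sites: dict | None = None,
    schemes: dict | None = None,
    variable_methyl: bool = True,
    include_heavy: bool = True,
    max_charge: int = 8,
) -> SearchSpace:
    """Theoretical ion index for the given molecules and enzymes.

    ``known_sites`` maps molecule_id -> list of fixed ModificationSites;
    fragments are enumerated both with blocking sites applied (the modified
    molecule population) and without (the unmodified population), since a
    partially modified sample contains both fragment sets.  ``schemes``
    maps enzyme -> LabelScheme for the heavy internal-standard channel
    (defaults: 13C10-G with RNase T1, 13C9-C/U with RNase A).
    """
    if not molecules:
        raise ValueError("at least one molecule required")
    known_sites = known_sites or {}
    if schemes is None:
        schemes = {"RNaseT1": LABEL_SCHEMES["T1-scheme"], "RNaseA": LABEL_SCHEMES["A-scheme"]}
    ions: list[IonSpecies] = []
    seen_species = set()
    for mol in molecules:
        fixed = tuple(sorted(known_sites.get(mol.id, ())))
        for enzyme in enzymes:
            rule = CLEAVAGE_RULES[enzyme]
            fragments = []
            for variant_sites in ({(), fixed} if fixed else {()}):
                fragments.extend(digest(mol, rule, max_missed, variant_sites))
            scheme = schemes.get(enzyme)
            for frag in fragments:
                for variant in enumerate_variants(frag, fixed, variable_methyl):
                    channels = ["light"] + (
                        ["heavy"] if include_heavy and not variant and scheme else []
                    )
                    for channel in channels:
                        sp = make_species(frag, variant, channel, scheme)
                        if sp.key in seen_species:
                            continue
                        seen_species.add(sp.key)
                        ions.extend(ions_for(sp, window, max_charge))
    ions.sort(key=lambda ion: (ion.mz, ion.species.key, ion.charge))
    return SearchSpace(ions=ions, window=window)


@dataclass(frozen=True)
class Identification:
    peak_index: int
    mz: float
    rt: float
    intensity: float
    ion: IonSpecies
    ppm_error: float
    ambiguous: bool = False
    isobaric_group: int | None = None
    ms2_score: tuple | None = None  # (matched count, intensity fraction)


def match_ms1(
    peaks: pd.DataFrame,
    space: SearchSpace,
    tol_ppm: float = 5.0,
) -> list[Identification]:
    """Match every peak (or feature) within +/- tol_ppm of a theoretical ion.

    All co-matching species are retained; peaks matching more than one
    distinct species are flagged ambiguous and share an isobaric group id.
    """
    if tol_ppm <= 0:
        raise ValueError("tolerance must be positive")
    out: list[Identification] = []
    group_ids: dict[tuple, int] = {}
    for idx, row in enumerate(peaks.itertuples(index=False)):
        hits = space.query(row.mz, tol_ppm)
        distinct = {h.species.key for h in hits}
        ambiguous = len(distinct) > 1
        group = None
        if ambiguous:
            gkey = tuple(sorted(distinct))
            group = group_ids.setdefault(gkey, len(group_ids))
        for hit in hits:
            out.append(
                Identification(
                    peak_index=idx,
                    mz=float(row.mz),
                    rt=float(getattr(row, "rt", np.nan)),
                    intensity=float(getattr(row, "intensity", np.nan)),
                    ion=hit,
                    ppm_error=(row.mz - hit.mz) / hit.mz * 1e6,
                    ambiguous=ambiguous,
                    isobaric_group=group,
                )
            )
    return out


def score_ms2(
    spectrum: pd.DataFrame,
    candidate: IonSpecies,
    tol_ppm: float = 20.0,
    max_charge: int = 2,
    scheme: LabelScheme | None = None,
) -> tuple[int, float]:
    """Score an MS2 spectrum against a candidate's theoretical ladders.

    Returns ``(matched ion count, fraction of spectrum intensity explained)``;
    an empty spectrum scores (0, 0.0).
    """
    if spectrum is None or len(spectrum) == 0:
        return (0, 0.0)
    if scheme is None and candidate.species.channel == "heavy":
        enzyme = candidate.species.fragment.provenance[0] if candidate.species.fragment.provenance else "RNaseT1"
        scheme = {"RNaseT1": LABEL_SCHEMES["T1-scheme"], "RNaseA": LABEL_SCHEMES["A-scheme"]}[enzyme]
    ladder = ms2_ladders(candidate.species, max_charge=max_charge, scheme=scheme)
    theo = np.sort(np.array([ion.mz for ion in ladder]))
    mz = spectrum["mz"].to_numpy(dtype=float)
    inten = (
        spectrum["intensity"].to_numpy(dtype=float)
        if "intensity" in spectrum
        else np.ones_like(mz)
    )
    tol = theo * tol_ppm * 1e-6
    matched_theo = 0
    for t, dt in zip(theo, tol):
        if np.any(np.abs(mz - t) <= dt):
            matched_theo += 1
    explained = np.zeros_like(mz, dtype=bool)
    for t, dt in zip(theo, tol):
        explained |= np.abs(mz - t) <= dt
    frac = float(inten[explained].sum() / inten.sum()) if inten.sum() > 0 else 0.0
    return (matched_theo, frac)


def resolve(
    identifications: list[Identification],
    spectra: list[dict] | None = None,
    ms2_tol_ppm: float = 20.0,
    rt_tolerance: float = 0.2,
) -> list[Identification]:
    """Final assignment policy for ambiguous matches.

    Per peak: (1) if an MS2 spectrum is available (matched by precursor m/z
    and RT), keep the candidate with the highest matched-ion count, breaking
    ties by explained-intensity fraction; (2) otherwise prefer the smallest
    |ppm error| when it genuinely discriminates; (3) otherwise all
    candidates are retained, still flagged ambiguous — isobaric groups
    without discriminating evidence are reported, never dropped.

    ``spectra`` entries are dicts with keys precursor_mz, rt and peaks
    (DataFrame mz/intensity).
    """
    spectra = spectra or []
    by_peak: dict[int, list[Identification]] = {}
    for ident in identifications:
        by_peak.setdefault(ident.peak_index, []).append(ident)
    resolved: list[Identification] = []
    for peak_index in sorted(by_peak):
        group = by_peak[peak_index]
        if len(group) == 1:
            resolved.extend(group)
            continue
        anchor = group[0]
        spectrum = _find_spectrum(spectra, anchor.mz, anchor.rt, ms2_tol_ppm, rt_tolerance)
        if spectrum is not None:
            scored = [
                replace(g, ms2_score=score_ms2(spectrum, g.ion, ms2_tol_ppm))
                for g in group
            ]
            best = max(s.ms2_score for s in scored)
            winners = [s for s in scored if s.ms2_score == best]
            if len(winners) == 1 and best[0] > 0:
                resolved.append(replace(winners[0], ambiguous=False))
                continue
            group = winners
        best_ppm = min(abs(g.ppm_error) for g in group)
        close = [g for g in group if abs(abs(g.ppm_error) - best_ppm) < 1e-9]
        if len(close) == 1:
            resolved.append(replace(close[0], ambiguous=False))
        else:
            resolved.extend(close)  # unresolved isobaric group, kept flagged
    return resolved


def _find_spectrum(spectra, precursor_mz, rt, tol_ppm, rt_tolerance):
    best, best_dist = None, None
    for spec in spectra:
        dmz = abs(spec["precursor_mz"] - precursor_mz) / precursor_mz * 1e6
        drt = abs(spec.get("rt", rt) - rt) if np.isfinite(rt) else 0.0
        if dmz <= tol_ppm and drt <= rt_tolerance:
            if best_dist is None or drt < best_dist:
                best, best_dist = spec, drt
    return best["peaks"] if best is not None else None


PEAKLIST_COLUMNS = ["mz", "rt", "intensity"]


def read_peaklist(path) -> pd.DataFrame:
    """Read an MS1 peak list from TSV (columns mz, rt, intensity[, scan])."""
    table = pd.read_csv(path, sep="\t")
    missing = set(PEAKLIST_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return table


def read_mzml_peaks(path, ms_level: int = 1) -> pd.DataFrame:
    """Convenience mzML ingestion producing the internal peak-list form.

    Supports the common subset of mzML: 32/64-bit float m/z and intensity
    arrays, uncompressed or zlib-compressed, with scan start times in
    minutes or seconds.
    """
    import base64
    import zlib

    from lxml import etree

    ns = {"mz": "http://psi.hupo.org/ms/mzml"}
    acc = {
        "ms_level": "MS:1000511",
        "rt": "MS:1000016",
        "f64": "MS:1000523",
        "f32": "MS:1000521",
        "zlib": "MS:1000574",
        "mz_array": "MS:1000514",
        "intensity_array": "MS:1000515",
    }
    tree = etree.parse(str(path))
    rows = []
    for spectrum in tree.iterfind(".//mz:spectrum", ns):
        params = {
            p.get("accession"): p.get("value", "")
            for p in spectrum.iterfind(".//mz:cvParam", ns)
        }
        if int(params.get(acc["ms_level"], 1)) != ms_level:
            continue
        rt = np.nan
        for p in spectrum.iterfind(".//mz:scanList//mz:cvParam", ns):
            if p.get("accession") == acc["rt"]:
                rt = float(p.get("value"))
                if p.get("unitName", "minute").startswith("second"):
                    rt /= 60.0
        arrays = {}
        for bda in spectrum.iterfind(".//mz:binaryDataArray", ns):
            cv = {p.get("accession") for p in bda.iterfind("mz:cvParam", ns)}
            binary = bda.findtext("mz:binary", default="", namespaces=ns)
            raw = base64.b64decode(binary)
            if acc["zlib"] in cv:
                raw = zlib.decompress(raw)
            dtype = "<f8" if acc["f64"] in cv else "<f4"
            data = np.frombuffer(raw, dtype=dtype)
            if acc["mz_array"] in cv:
                arrays["mz"] = data
            elif acc["intensity_array"] in cv:
                arrays["intensity"] = data
        for mz_val, inten in zip(arrays.get("mz", ()), arrays.get("intensity", ())):
            rows.append((float(mz_val), rt, float(inten)))
    return pd.DataFrame(rows, columns=PEAKLIST_COLUMNS)


def find_features(
    peaks: pd.DataFrame,
    tol_ppm: float = 5.0,
    min_separation: float = 0.2,
) -> pd.DataFrame:
    """Collapse a scan-level peak list into chromatographic features.

    m/z values are clustered greedily within the ppm tolerance; each
    cluster's XIC is split into RT-resolved peaks.  Returns a DataFrame with
    columns mz, rt, intensity (apex), area, cluster — the form expected by
    :func:`match_ms1` and the quantification stage.
    """
    from .quantify import pick_peaks

    if peaks.empty:
        return pd.DataFrame(columns=["mz", "rt", "intensity", "area", "cluster"])
    table = peaks.sort_values("mz", kind="stable").reset_index(drop=True)
    mz = table["mz"].to_numpy(dtype=float)
    # single-linkage in m/z: a gap larger than the tolerance starts a new
    # cluster (scans of one species are dense; distinct species are far)
    gaps = np.diff(mz) / mz[:-1] * 1e6
    cluster = np.concatenate([[0], np.cumsum(gaps > tol_ppm)])
    table["cluster"] = cluster
    rows = []
    for cid, sub in table.groupby("cluster"):
        chrom = sub.groupby("rt", as_index=False)["intensity"].sum().sort_values("rt")
        for peak in pick_peaks(chrom.reset_index(drop=True), min_separation=min_separation):
            members = sub[(sub["rt"] >= peak.rt_start) & (sub["rt"] <= peak.rt_end)]
            members = members[members["intensity"] > 0]
            if members.empty:
                continue
            rows.append(
                dict(
                    mz=float(np.average(members["mz"], weights=members["intensity"])),
                    rt=peak.rt_apex,
                    intensity=peak.apex_intensity,
                    area=peak.area,
                    cluster=cid,
                )
            )
    return pd.DataFrame(rows).sort_values(["mz", "rt"]).reset_index(drop=True)
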