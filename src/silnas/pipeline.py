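"""End-to-end analysis: features -> identification -> per-site stoichiometry.

The quantification stage mirrors the manual workflow it automates: for each
digest it enumerates the theoretical species implied by the known site
table (no ground-truth stoichiometries are used anywhere), finds
chromatographic features in the MS1 peak list, assigns features to species
— by m/z alone where the species is unique, by MS2 ladder scoring for
same-m/z candidates, and by the retention-order convention (methyls
towards the 3' end elute later; pseudouridylated species elute earlier and
the unmodified species co-elutes with its heavy standard) where MS2 cannot
discriminate — and then applies the two estimators from
:mod:`silnas.quantify`.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .identify import find_features, score_ms2
from .masses import make_species, mz_negative, observable_charges
from .quantify import (
    CorrectionFactor,
    PairedMeasurement,
    StoichiometryEstimate,
    aggregate_and_compare,
    correction_factor,
    peak_area_estimate,
    report_table,
    silnas_estimate,
)
from .simulate import (
    DigestSpec,
    SimulationScenario,
    digest_context,
    enumerate_digest_species,
    _species_rt_offset,
)

log = logging.getLogger("silnas")


@dataclass
class AnalysisConfig:
    ms1_tol_ppm: float = 5.0
    ms2_tol_ppm: float = 20.0
    k_policy: str = "mean"
    n_correction_pairs: int = 10
    min_pair_length: int = 2
    rt_match_tolerance: float = 0.3
    feature_min_separation: float = 0.15
    alpha: float = 0.05

    def __post_init__(self):
        if self.ms1_tol_ppm <= 0 or self.ms2_tol_ppm <= 0:
            raise ValueError("tolerances must be positive")


def _species_entries(ctx, scenario: SimulationScenario):
    entries = []
    light = enumerate_digest_species(ctx["molecule"], ctx["rule"], ctx["groups"])
    heavy = enumerate_digest_species(ctx["heavy_molecule"], ctx["rule"], [])
    for template, channel in [(t, "light") for t in light] + [(t, "heavy") for t in heavy]:
        sp = make_species(
            template.fragment, template.fragment.sites, channel,
            ctx["scheme"] if channel == "heavy" else None,
        )
        charges = observable_charges(sp.monoisotopic_mass, scenario.window, scenario.max_charge)
        if not charges:
            continue
        entries.append(
            dict(
                template=template,
                channel=channel,
                species=sp,
                charge=charges[0],
                mz=mz_negative(sp.monoisotopic_mass, charges[0]),
                key=(template.fragment.start, template.fragment.end,
                     template.variant_key, channel),
            )
        )
    entries.sort(key=lambda e: e["mz"])
    return entries


def _cluster_species(entries, tol_ppm):
    """Group theoretical species whose m/z are indistinguishable at the MS1
    tolerance — these share an XIC and need MS2 or RT order to separate."""
    clusters, current = [], []
    for e in entries:
        if current and (e["mz"] - current[0]["mz"]) / current[0]["mz"] * 1e6 > 2 * tol_ppm:
            clusters.append(current)
            current = []
        current.append(e)
    if current:
        clusters.append(current)
    return clusters


def assign_species(
    entries,
    features: pd.DataFrame,
    spectra,
    scenario: SimulationScenario,
    config: AnalysisConfig,
) -> dict:
    """Map species key -> (rt, apex intensity, area) from observed features.

    Same-m/z candidates are separated by MS2 ladder scoring when spectra
    are available and informative, otherwise by elution-order convention
    against the species' expected RT offsets (anchored on the heavy
    standard for mass-silent pairs).  Species without a feature (absent at
    the detection level) are simply not assigned.
    """
    assignments: dict = {}
    if features.empty:
        return assignments
    fmz = features["mz"].to_numpy(dtype=float)
    for cluster in _cluster_species(entries, config.ms1_tol_ppm):
        mz0 = cluster[0]["mz"]
        tol = mz0 * config.ms1_tol_ppm * 1e-6
        sel = features[(fmz >= mz0 - tol) & (fmz <= cluster[-1]["mz"] + tol)]
        if sel.empty:
            continue
        if len(cluster) == 1:
            row = sel.loc[sel["area"].idxmax()]
            assignments[cluster[0]["key"]] = (
                float(row["rt"]), float(row["intensity"]), float(row["area"])
            )
            continue
        # multi-species cluster: try MS2 scoring per feature
        rows = list(sel.itertuples(index=False))
        scored = {}
        for row in rows:
            spectrum = _nearest_spectrum(
                spectra, row.mz, row.rt, config.ms2_tol_ppm, config.rt_match_tolerance
            )
            if spectrum is None:
                continue
            scores = {
                e["key"]: score_ms2(spectrum, _ion_of(e), config.ms2_tol_ppm)
                for e in cluster
            }
            best = max(scores.values())
            winners = [k for k, v in scores.items() if v == best]
            if len(winners) == 1 and best[0] > 0:
                scored[(row.rt, row.intensity, row.area)] = winners[0]
        taken = set()
        for (rt, inten, area), key in scored.items():
            if key in taken:
                continue
            prev = assignments.get(key)
            if prev is None or area > prev[2]:
                assignments[key] = (float(rt), float(inten), float(area))
            taken.add(key)
        remaining = [e for e in cluster if e["key"] not in assignments]
        rem_rows = [
            r for r in rows
            if not any(
                np.isclose(r.rt, v[0]) and np.isclose(r.area, v[2])
                for v in assignments.values()
            )
        ]
        if remaining and rem_rows:
            # elution-order fallback: expected offsets vs observed RTs
            remaining.sort(key=lambda e: _species_rt_offset(e["template"], scenario))
            rem_rows.sort(key=lambda r: r.rt)
            if len(remaining) == len(rem_rows):
                for e, row in zip(remaining, rem_rows):
                    assignments[e["key"]] = (
                        float(row.rt), float(row.intensity), float(row.area)
                    )
            else:
                # anchor each remaining species at its nearest expected RT if a
                # co-cluster species was already placed; otherwise leave out
                placed = [
                    (assignments[e["key"]][0] - _species_rt_offset(e["template"], scenario))
                    for e in cluster
                    if e["key"] in assignments
                ]
                if placed:
                    anchor = float(np.median(placed))
                    for e in remaining:
                        expect = anchor + _species_rt_offset(e["template"], scenario)
                        dists = [abs(r.rt - expect) for r in rem_rows]
                        j = int(np.argmin(dists))
                        if dists[j] <= 1.0:
                            row = rem_rows[j]
                            assignments[e["key"]] = (
                                float(row.rt), float(row.intensity), float(row.area)
                            )
    return assignments


def _ion_of(entry):
    from .masses import IonSpecies

    return IonSpecies(entry["species"], entry["charge"], entry["mz"])


def _nearest_spectrum(spectra, precursor_mz, rt, tol_ppm, rt_tol):
    best, best_drt = None, None
    for spec in spectra or []:
        dmz = abs(spec["precursor_mz"] - precursor_mz) / precursor_mz * 1e6
        drt = abs(spec.get("rt", rt) - rt)
        if dmz <= tol_ppm and drt <= rt_tol:
            if best_drt is None or drt < best_drt:
                best, best_drt = spec, drt
    return None if best is None else best["peaks"]


def _correction_pairs(entries, assignments, groups, config):
    """(light, heavy) apex pairs from unmodified fragments whose species are
    the sole occupants of their m/z cluster, taken in coordinate order."""
    clusters = _cluster_species(entries, config.ms1_tol_ppm)
    solo = {c[0]["key"] for c in clusters if len(c) == 1}
    by_key = {e["key"]: e for e in entries}
    pairs = []
    for e in sorted(entries, key=lambda e: (e["template"].fragment.start, e["template"].fragment.end)):
        if e["channel"] != "light" or e["template"].presence or e["key"] not in solo:
            continue
        frag = e["template"].fragment
        if len(frag) < config.min_pair_length:
            continue
        hkey = (frag.start, frag.end, (), "heavy")
        if hkey not in by_key or hkey not in solo:
            continue
        la = assignments.get(e["key"])
        ha = assignments.get(hkey)
        if la is None or ha is None or la[1] <= 0 or ha[1] <= 0:
            continue
        pairs.append((la[1], ha[1]))
        if len(pairs) >= config.n_correction_pairs:
            break
    return pairs


def quantify_digest(
    scenario: SimulationScenario,
    spec: DigestSpec,
    peaks: pd.DataFrame,
    spectra,
    replicate: str,
    config: AnalysisConfig | None = None,
) -> tuple[list[StoichiometryEstimate], CorrectionFactor | None]:
    """Per-site estimates for one digest of one replicate.

    Only the site *positions and types* from the scenario are used — never
    the ground-truth stoichiometries; those exist solely inside the
    simulator.
    """
    config = config or AnalysisConfig()
    ctx = digest_context(scenario, spec)
    entries = _species_entries(ctx, scenario)
    features = find_features(
        peaks, config.ms1_tol_ppm, min_separation=config.feature_min_separation
    )
    assignments = assign_species(entries, features, spectra, scenario, config)
    pairs = _correction_pairs(entries, assignments, ctx["groups"], config)
    k = correction_factor(pairs, policy=config.k_policy) if len(pairs) >= 5 else None

    local_by_label = {g.label: g for g in ctx["groups"]}
    estimates: list[StoichiometryEstimate] = []
    for g in scenario.groups:
        if g.digest != spec.name or g.label not in local_by_label:
            continue
        local = local_by_label[g.label]
        anchor = min(s.position for s in local.sites)
        site_id = (g.molecule_id, min(s.position for s in g.sites),
                   local.sites[0].mod_type)
        mine = [
            e for e in entries
            if e["channel"] == "light"
            and e["template"].fragment.start <= anchor <= e["template"].fragment.end
        ]
        mod_side = [e for e in mine if dict(e["template"].presence).get(g.label)]
        unmod_side = [e for e in mine if not dict(e["template"].presence).get(g.label)]
        if "silnas" in g.methods and k is not None:
            est = _silnas_for_group(
                g, local, site_id, unmod_side, mod_side, entries, assignments, k, replicate
            )
            if est is not None:
                estimates.append(est)
        if "peak_area" in g.methods:
            areas_mod = {
                e["key"]: assignments[e["key"]][2]
                for e in mod_side
                if e["key"] in assignments
            }
            areas_unmod = {
                e["key"]: assignments[e["key"]][2]
                for e in unmod_side
                if e["key"] in assignments
            }
            if areas_mod or areas_unmod:
                estimates.append(
                    peak_area_estimate(areas_mod, areas_unmod, site=site_id, replicate=replicate)
                )
    return estimates, k


def _silnas_for_group(group, local, site_id, unmod_side, mod_side, entries,
                      assignments, k, replicate):
    pure = [
        e for e in unmod_side if not any(on for _, on in e["template"].presence)
    ]
    if not pure:
        return None
    pure.sort(key=lambda e: len(e["template"].fragment))
    target = pure[0]
    frag = target["template"].fragment
    hkey = (frag.start, frag.end, (), "heavy")
    ha = assignments.get(hkey)
    if ha is None or ha[1] <= 0:
        log.warning("no heavy standard feature for %s; silnas skipped", group.label)
        return None
    la = assignments.get(target["key"])
    light_apex = la[1] if la is not None else 0.0
    light_mod_apex = None
    mods = [e for e in mod_side if e["key"] in assignments]
    if mods:
        light_mod_apex = float(sum(assignments[e["key"]][1] for e in mods))
    m = PairedMeasurement(
        site=site_id,
        replicate=replicate,
        light_unmod=light_apex,
        heavy=ha[1],
        light_mod=light_mod_apex,
        signal_kind="apex",
    )
    return silnas_estimate(m, k)


def run_quantification(
    scenario: SimulationScenario,
    peaklists: dict,
    spectra: dict | None = None,
    config: AnalysisConfig | None = None,
    condition_of: dict | None = None,
):
    """Quantify every digest of every replicate and aggregate per site.

    ``peaklists`` maps (condition, replicate, digest_name) -> peak table,
    as produced by the simulator or read back from fixtures.  Returns
    (estimates table, site reports, summary table).
    """
    config = config or AnalysisConfig()
    spectra = spectra or {}
    digest_by_name = {d.name: d for d in scenario.digests}
    rows = []
    for (condition, replicate, digest_name), peaks in sorted(peaklists.items()):
        spec = digest_by_name[digest_name]
        ests, k = quantify_digest(
            scenario, spec, peaks, spectra.get((condition, replicate, digest_name)),
            replicate=f"{condition}/{replicate}", config=config,
        )
        log.info(
            "%s %s %s: %d estimates, k=%s", condition, replicate, digest_name,
            len(ests), f"{k.k:.4f}" if k else "n/a",
        )
        for e in ests:
            rows.append(
                dict(
                    site=e.site, method=e.method, condition=condition,
                    replicate=replicate, f_mod=e.f_mod, clamped=e.clamped,
                    diagnostic=e.diagnostic,
                )
            )
    table = pd.DataFrame(rows)
    guides = {}
    for g in scenario.groups:
        site_id = (g.molecule_id, min(s.position for s in g.sites), g.sites[0].mod_type)
        guides[site_id] = g.guide
    reports = aggregate_and_compare(
        table[["site", "method", "condition", "replicate", "f_mod"]],
        reference=scenario.reference_condition,
        alpha=config.alpha,
        guide_annotations=guides,
    )
    return table, reports, report_table(reports)


def provenance_header(config_obj, seed) -> str:
    blob = yaml.safe_dump(config_obj, sort_keys=True).encode()
    digest = hashlib.sha256(blob).hexdigest()[:16]
    return f"# silnas v{__version__} | config sha256:{digest} | seed {seed}\n"


def write_report(summary: pd.DataFrame, path, config_obj, seed) -> None:
    with open(path, "w") as fh:
        fh.write(provenance_header(config_obj, seed))
        summary.to_csv(fh, sep="\t", index=False)


def summary_json(summary: pd.DataFrame) -> str:
    return json.dumps(
        json.loads(summary.to_json(orient="records")), indent=2, sort_keys=True
    )
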