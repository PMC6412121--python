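"""Stoichiometry estimators for site-specific RNA modifications.

Two complementary readouts are implemented:

* **Isotope-dilution ratio** (:func:`silnas_estimate`): the light,
  unmodified fragment is read against its co-eluting heavy-labelled
  counterpart from the unmodified in-vitro transcript; the modified
  fraction is the depletion of the light unmodified species,
  ``f = 1 - L / (k * H)``, where ``k`` corrects the nominal 1:1 light/heavy
  mixing using ~10 pairs of unmodified fragments
  (:func:`correction_factor`).  Because this is a depletion readout it
  also quantifies mass-silent modifications (pseudouridine).

* **Peak areas** (:func:`peak_area_estimate`): extracted-ion-chromatogram
  areas of the modified and unmodified light species,
  ``f = sum(A_mod) / (sum(A_mod) + sum(A_unmod))``; isomeric modified
  species are summed, and mass-silent modifications are handled through
  retention-time-resolved species of identical m/z.

Both are ratio estimators: scaling every signal in a replicate by a
constant leaves them unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class CorrectionFactor:
    """Light/heavy mixing correction from unmodified fragment pairs."""

    k: float
    n_pairs: int
    ratios: tuple

    def __post_init__(self):
        if self.k <= 0:
            raise ValueError("correction factor must be positive")


@dataclass(frozen=True)
class PairedMeasurement:
    """Signals for one site in one replicate (apex intensity or area)."""

    site: tuple  # (molecule_id, position, mod_type)
    replicate: str
    light_unmod: float
    heavy: float
    light_mod: float | None = None
    signal_kind: str = "apex"  # 'apex' | 'area'

    def __post_init__(self):
        if self.light_unmod < 0 or (self.light_mod is not None and self.light_mod < 0):
            raise ValueError("signals must be non-negative")
        if self.heavy <= 0:
            raise ValueError("heavy (internal standard) signal must be positive")


@dataclass(frozen=True)
class StoichiometryEstimate:
    site: tuple
    f_mod: float
    method: str  # 'silnas' | 'peak_area'
    replicate: str
    clamped: bool = False
    diagnostic: float | None = None  # (L_unmod + L_mod)/(k*H), should be ~1


def correction_factor(
    pairs: list[tuple[float, float]],
    minimum_pairs: int = 5,
    policy: str = "mean",
) -> CorrectionFactor:
    """Mixing correction k from (light, heavy) signals of unmodified fragments.

    k is the average of per-pair light/heavy ratios (``policy='median'``
    for a robust variant).  Fewer than ~10 pairs triggers a warning, below
    ``minimum_pairs`` an error: the correction is only as good as its
    replicate support.
    """
    if len(pairs) < minimum_pairs:
        raise ValueError(f"need at least {minimum_pairs} correction pairs, got {len(pairs)}")
    if len(pairs) < 10:
        warnings.warn(
            f"only {len(pairs)} correction pairs; ~10 recommended", stacklevel=2
        )
    ratios = []
    for light, heavy in pairs:
        if heavy <= 0 or light <= 0:
            raise ValueError("correction pairs require positive light and heavy signals")
        ratios.append(light / heavy)
    if policy == "mean":
        k = float(np.mean(ratios))
    elif policy == "median":
        k = float(np.median(ratios))
    else:
        raise ValueError(f"unknown correction policy {policy!r}")
    return CorrectionFactor(k=k, n_pairs=len(ratios), ratios=tuple(ratios))


def _clamp(raw: float) -> tuple[float, bool]:
    if raw < 0.0:
        return 0.0, True
    if raw > 1.0:
        return 1.0, True
    return raw, False


def silnas_estimate(m: PairedMeasurement, k: CorrectionFactor) -> StoichiometryEstimate:
    """Depletion estimate f = 1 - light_unmod / (k * heavy), clamped to [0, 1].

    When the modified species was also measured, a consistency diagnostic
    ``(L_unmod + L_mod) / (k * H)`` is attached; it should sit near 1 if
    mixing, correction and responses are coherent.
    """
    denom = k.k * m.heavy
    raw = 1.0 - m.light_unmod / denom
    f_mod, clamped = _clamp(raw)
    diagnostic = None
    if m.light_mod is not None:
        diagnostic = (m.light_unmod + m.light_mod) / denom
    return StoichiometryEstimate(
        site=m.site, f_mod=f_mod, method="silnas", replicate=m.replicate,
        clamped=clamped, diagnostic=diagnostic,
    )


def extract_xic(
    peaks: pd.DataFrame,
    target_mz: float,
    tol_ppm: float = 5.0,
) -> pd.DataFrame:
    """Extracted-ion chromatogram: summed intensity vs RT within +/- tol_ppm.

    ``peaks`` needs columns mz, rt, intensity.  Returns a time-ordered
    DataFrame with columns rt, intensity (empty trace allowed).
    """
    if tol_ppm <= 0:
        raise ValueError("tolerance must be positive")
    tol = target_mz * tol_ppm * 1e-6
    sel = peaks[(peaks["mz"] >= target_mz - tol) & (peaks["mz"] <= target_mz + tol)]
    if sel.empty:
        return pd.DataFrame({"rt": [], "intensity": []})
    return (
        sel.groupby("rt", as_index=False)["intensity"].sum().sort_values("rt")
        .reset_index(drop=True)
    )


def warn_on_collisions(theoretical_mzs: dict, tol_ppm: float = 5.0) -> list[tuple]:
    """Report pairs of distinct species whose theoretical m/z are closer than
    the XIC tolerance — their traces merge and must be separated in RT."""
    items = sorted(theoretical_mzs.items(), key=lambda kv: kv[1])
    collisions = []
    for (ka, va), (kb, vb) in zip(items, items[1:]):
        if abs(vb - va) / va * 1e6 <= tol_ppm:
            collisions.append((ka, kb))
            warnings.warn(
                f"species {ka} and {kb} are within {tol_ppm} ppm; XIC traces merge",
                stacklevel=2,
            )
    return collisions


@dataclass(frozen=True)
class ChromPeak:
    rt_apex: float
    apex_intensity: float
    area: float
    rt_start: float
    rt_end: float
    flag: str = ""


def integrate_peak(
    chrom: pd.DataFrame,
    boundaries: tuple[float, float] | None = None,
    boundary_fraction: float = 0.01,
    noise_floor: float = 0.0,
    apex_rt: float | None = None,
) -> ChromPeak:
    """Trapezoidal area of one chromatographic peak.

    With explicit ``boundaries`` the trace is integrated between them
    (boundaries must overlap the trace).  In automatic mode the peak is the
    contiguous region around the apex (optionally the local apex nearest
    ``apex_rt``) where intensity stays above
    ``max(apex * boundary_fraction, noise_floor)`` — an automated stand-in
    for manual start/end selection.
    """
    if chrom.empty or float(chrom["intensity"].max()) <= 0:
        if boundaries is None:
            return ChromPeak(np.nan, 0.0, 0.0, np.nan, np.nan, flag="no peak")
        raise ValueError("explicit boundaries given but trace is empty")
    rt = chrom["rt"].to_numpy(dtype=float)
    inten = chrom["intensity"].to_numpy(dtype=float)
    if boundaries is not None:
        lo, hi = boundaries
        mask = (rt >= lo) & (rt <= hi)
        if not mask.any():
            raise ValueError(f"boundaries {boundaries} outside trace {rt[0]}..{rt[-1]}")
        sel_rt, sel_int = rt[mask], inten[mask]
    else:
        if apex_rt is None:
            apex_idx = int(np.argmax(inten))
        else:
            # local maxima, pick the one closest to the requested RT
            is_max = np.r_[True, inten[1:] >= inten[:-1]] & np.r_[inten[:-1] >= inten[1:], True]
            candidates = np.flatnonzero(is_max & (inten > 0))
            apex_idx = int(candidates[np.argmin(np.abs(rt[candidates] - apex_rt))])
        threshold = max(inten[apex_idx] * boundary_fraction, noise_floor)
        lo_idx = apex_idx
        while lo_idx > 0 and inten[lo_idx - 1] >= threshold:
            lo_idx -= 1
        hi_idx = apex_idx
        while hi_idx < len(inten) - 1 and inten[hi_idx + 1] >= threshold:
            hi_idx += 1
        sel_rt, sel_int = rt[lo_idx : hi_idx + 1], inten[lo_idx : hi_idx + 1]
    area = float(np.trapezoid(sel_int, sel_rt)) if len(sel_rt) > 1 else 0.0
    apex_pos = int(np.argmax(sel_int))
    return ChromPeak(
        rt_apex=float(sel_rt[apex_pos]),
        apex_intensity=float(sel_int[apex_pos]),
        area=area,
        rt_start=float(sel_rt[0]),
        rt_end=float(sel_rt[-1]),
    )


def pick_peaks(
    chrom: pd.DataFrame,
    min_separation: float = 0.2,
    rel_height: float = 0.05,
) -> list[ChromPeak]:
    """All resolved peaks of a trace, by local-maximum detection followed by
    valley-bounded trapezoidal integration.  Used to split RT-resolved
    species that share one m/z track (isobars, pseudouridine vs uridine)."""
    from scipy.signal import find_peaks

    if chrom.empty:
        return []
    rt = chrom["rt"].to_numpy(dtype=float)
    inten = chrom["intensity"].to_numpy(dtype=float)
    if len(inten) < 3:
        peak = integrate_peak(chrom)
        return [peak] if peak.area > 0 or peak.apex_intensity > 0 else []
    dt = np.median(np.diff(rt)) if len(rt) > 1 else min_separation
    distance = max(1, int(round(min_separation / max(dt, 1e-9))))
    idx, _ = find_peaks(inten, height=inten.max() * rel_height, distance=distance)
    if len(idx) == 0:
        idx = np.array([int(np.argmax(inten))])
    peaks = []
    # valley split: between consecutive apexes, cut at the minimum
    cut_points = [0]
    for a, b in zip(idx[:-1], idx[1:]):
        cut_points.append(int(a + np.argmin(inten[a:b + 1])))
    cut_points.append(len(inten) - 1)
    for j, apex in enumerate(idx):
        lo, hi = cut_points[j], cut_points[j + 1]
        seg = chrom.iloc[lo : hi + 1]
        peaks.append(integrate_peak(seg, apex_rt=float(rt[apex])))
    return peaks


def peak_area_estimate(
    modified_areas: dict | list,
    unmodified_areas: dict | list,
    site: tuple = ("", 0, ""),
    replicate: str = "",
) -> StoichiometryEstimate:
    """f = sum(modified areas) / (sum(modified) + sum(unmodified)).

    Area sets may be dicts (species label -> area) or plain lists; isomeric
    modified species are summed, matching composite rows like
    "GmGmC + GmGC" in site tables.
    """
    a_mod = float(sum(modified_areas.values() if isinstance(modified_areas, dict) else modified_areas))
    a_unmod = float(sum(unmodified_areas.values() if isinstance(unmodified_areas, dict) else unmodified_areas))
    if a_mod < 0 or a_unmod < 0:
        raise ValueError("areas must be non-negative")
    total = a_mod + a_unmod
    if total == 0:
        return StoichiometryEstimate(
            site=site, f_mod=float("nan"), method="peak_area", replicate=replicate,
            clamped=False,
        )
    f_mod, clamped = _clamp(a_mod / total)
    return StoichiometryEstimate(
        site=site, f_mod=f_mod, method="peak_area", replicate=replicate, clamped=clamped
    )


@dataclass
class SiteReport:
    """Per-site summary across conditions with pairwise tests vs reference."""

    site: tuple
    method: str
    per_condition: pd.DataFrame  # condition, mean, sem, n
    comparisons: pd.DataFrame    # condition, p_value, significant
    guide_annotation: str = ""


def aggregate_and_compare(
    estimates: list[StoichiometryEstimate] | pd.DataFrame,
    condition_of: dict | None = None,
    reference: str | None = None,
    alpha: float = 0.05,
    guide_annotations: dict | None = None,
) -> list[SiteReport]:
    """Aggregate replicate estimates into per-site, per-condition mean +/- SEM
    and compare each condition against the reference.

    Input is either a DataFrame with columns site (tuple), method, condition,
    replicate, f_mod, or a list of estimates plus a replicate->condition map.
    Two conditions: Welch t-test.  More: Tukey HSD across all conditions,
    reporting the pairs involving the reference.
    """
    if isinstance(estimates, pd.DataFrame):
        table = estimates.copy()
    else:
        if condition_of is None:
            raise ValueError("condition_of required with a list of estimates")
        table = pd.DataFrame(
            dict(
                site=[e.site for e in estimates],
                method=[e.method for e in estimates],
                condition=[condition_of[e.replicate] for e in estimates],
                replicate=[e.replicate for e in estimates],
                f_mod=[e.f_mod for e in estimates],
            )
        )
    reports = []
    conditions = list(dict.fromkeys(table["condition"]))
    if reference is None:
        reference = conditions[0]
    for (site, method), group in table.groupby(["site", "method"], sort=False):
        percond = (
            group.groupby("condition")["f_mod"]
            .agg(
                mean="mean",
                sem=lambda x: (x.std(ddof=1) / np.sqrt(len(x))) if len(x) > 1 else np.nan,
                n="count",
            )
            .reindex([c for c in conditions if c in set(group["condition"])])
            .reset_index()
        )
        others = [c for c in percond["condition"] if c != reference]
        rows = []
        if len(percond) > 2:
            from statsmodels.stats.multicomp import pairwise_tukeyhsd

            with warnings.catch_warnings():
                # all-identical groups (e.g. a fully modified cap) divide 0/0
                warnings.simplefilter("ignore", RuntimeWarning)
                res = pairwise_tukeyhsd(
                    group["f_mod"].to_numpy(), group["condition"].to_numpy(), alpha=alpha
                )
            frame = pd.DataFrame(
                res.summary().data[1:], columns=res.summary().data[0]
            )
            for cond in others:
                hit = frame[
                    ((frame["group1"] == reference) & (frame["group2"] == cond))
                    | ((frame["group1"] == cond) & (frame["group2"] == reference))
                ]
                p = float(hit["p-adj"].iloc[0]) if not hit.empty else np.nan
                rows.append((cond, p, bool(p < alpha)))
        else:
            for cond in others:
                a = group.loc[group["condition"] == reference, "f_mod"]
                b = group.loc[group["condition"] == cond, "f_mod"]
                if len(a) > 1 and len(b) > 1:
                    if np.allclose(a.var(ddof=1) + b.var(ddof=1), 0.0):
                        p = 1.0 if np.isclose(a.mean(), b.mean()) else 0.0
                    else:
                        p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
                else:
                    p = np.nan
                rows.append((cond, p, bool(p < alpha) if np.isfinite(p) else False))
        reports.append(
            SiteReport(
                site=site,
                method=method,
                per_condition=percond,
                comparisons=pd.DataFrame(rows, columns=["condition", "p_value", "significant"]),
                guide_annotation=(guide_annotations or {}).get(site, ""),
            )
        )
    return reports


def report_table(reports: list[SiteReport]) -> pd.DataFrame:
    """Flatten site reports into a table shaped like a publication summary:
    one row per site x method, one mean +/- SEM column pair per condition."""
    rows = []
    for rep in reports:
        row = {
            "molecule_id": rep.site[0],
            "position": rep.site[1],
            "mod_type": rep.site[2],
            "method": rep.method,
            "guide": rep.guide_annotation,
        }
        for rec in rep.per_condition.itertuples(index=False):
            row[f"{rec.condition}_mean_pct"] = 100.0 * rec.mean
            row[f"{rec.condition}_sem_pct"] = 100.0 * rec.sem if np.isfinite(rec.sem) else np.nan
            row[f"{rec.condition}_n"] = rec.n
        for rec in rep.comparisons.itertuples(index=False):
            row[f"{rec.condition}_p"] = rec.p_value
            row[f"{rec.condition}_signif"] = rec.significant
        rows.append(row)
    return pd.DataFrame(rows)
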