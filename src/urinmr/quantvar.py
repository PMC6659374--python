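"""Concentration post-processing and the three-layer variability statistics:
creatinine normalization, intra-assay / intra-individual / inter-individual
CV%, and below-detection accounting.

All CVs use the sample standard deviation (n-1 denominator); the day-to-day
and population layers operate on creatinine-normalized values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .signatures_io import CohortDesign, ConcentrationTable

__all__ = [
    "CvReport",
    "normalize_to_creatinine",
    "cv_percent",
    "intra_assay_cv",
    "intra_individual_cv",
    "inter_individual_cv",
    "absence_stats",
    "cv_report",
]


@dataclass
class CvReport:
    """Per-metabolite CV% at each design layer plus absence fractions."""

    table: pd.DataFrame  # metabolites x {intra_assay_cv, intra_individual_cv,
    #                       inter_individual_cv, n_*, absent_fraction}

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()


def normalize_to_creatinine(table: ConcentrationTable,
                            creatinine: str = "creatinine") -> ConcentrationTable:
    """Scale umol/L concentrations to umol per mmol of creatinine.

    The creatinine column itself is dropped. Samples whose creatinine is
    absent or non-positive are excluded (recorded in the returned table's
    index difference).
    """
    if table.units != "umol_per_L":
        raise ValueError(f"expected umol_per_L input, got {table.units}")
    if creatinine not in table.values.columns:
        raise ValueError("creatinine column missing")
    creat = table.values[creatinine].where(~table.absent_mask[creatinine])
    ok = creat.notna() & (creat > 0)
    if not ok.any():
        raise ValueError("no sample has usable creatinine")
    if (~ok).any():
        warnings.warn(f"{(~ok).sum()} sample(s) excluded: creatinine absent or <= 0")
    vals = table.values.loc[ok].drop(columns=[creatinine])
    mask = table.absent_mask.loc[ok].drop(columns=[creatinine])
    normed = vals.div(creat[ok] / 1000.0, axis=0)  # umol/L over mmol/L
    return ConcentrationTable(normed, units="umol_per_mmol_creatinine", absent_mask=mask)


def cv_percent(values) -> float:
    """``100 * sample SD / mean`` (n-1 denominator)."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if len(v) < 2:
        raise ValueError("cv_percent needs >= 2 values")
    mean = v.mean()
    if mean == 0:
        raise ValueError("cv_percent undefined for zero mean")
    return 100.0 * v.std(ddof=1) / mean


def _per_metabolite(table: ConcentrationTable, func) -> pd.Series:
    out = {}
    masked = table.values.mask(table.absent_mask)
    for met in masked.columns:
        out[met] = func(masked[met])
    return pd.Series(out)


def intra_assay_cv(table: ConcentrationTable, design: CohortDesign) -> pd.DataFrame:
    """Replicate-level CV% per metabolite, averaged over replicate groups."""
    groups = design.samples["replicate_group"].dropna()
    if groups.empty:
        raise ValueError("design has no replicate groups")
    masked = table.values.mask(table.absent_mask)
    per_group = []
    for _gid, members in groups.groupby(groups):
        ids = [s for s in members.index if s in masked.index]
        if len(ids) < 2:
            continue
        sub = masked.loc[ids]
        cvs = {}
        for met in sub.columns:
            col = sub[met].dropna()
            cvs[met] = cv_percent(col) if len(col) >= 2 and col.mean() != 0 else np.nan
        per_group.append(pd.Series(cvs))
    if not per_group:
        raise ValueError("no replicate group of size >= 2")
    cv = pd.concat(per_group, axis=1).mean(axis=1)
    n = pd.concat(per_group, axis=1).notna().sum(axis=1)
    return pd.DataFrame({"cv": cv, "n_groups": n})


def intra_individual_cv(table: ConcentrationTable, design: CohortDesign) -> pd.DataFrame:
    """Day-to-day CV% per metabolite: per-individual CV over collection days,
    then the unweighted mean across individuals."""
    samples = design.samples.loc[[s for s in design.samples.index if s in table.values.index]]
    masked = table.values.mask(table.absent_mask).loc[samples.index]
    per_ind = []
    for _ind, members in samples.groupby("individual"):
        days = members["collection_day"]
        if days.nunique() < 2:
            warnings.warn(f"individual {_ind}: fewer than 2 collection days; skipped")
            continue
        sub = masked.loc[members.index]
        cvs = {}
        for met in sub.columns:
            col = sub[met].dropna()
            cvs[met] = cv_percent(col) if len(col) >= 2 and col.mean() != 0 else np.nan
        per_ind.append(pd.Series(cvs))
    if not per_ind:
        raise ValueError("no individual with >= 2 collection days")
    stacked = pd.concat(per_ind, axis=1)
    return pd.DataFrame({"cv": stacked.mean(axis=1), "n_individuals": stacked.notna().sum(axis=1)})


def inter_individual_cv(table: ConcentrationTable, design: CohortDesign,
                        average_within_individual: bool = True) -> pd.DataFrame:
    """Population CV% per metabolite across individuals.

    Multi-sample individuals are first collapsed to their mean when
    ``average_within_individual`` (default); otherwise one sample per
    individual is required.
    """
    samples = design.samples.loc[[s for s in design.samples.index if s in table.values.index]]
    masked = table.values.mask(table.absent_mask).loc[samples.index]
    grouped = masked.groupby(samples["individual"])
    if not average_within_individual and (grouped.size() > 1).any():
        raise ValueError("multiple samples per individual; set average_within_individual")
    per_ind = grouped.mean()
    if len(per_ind) < 2:
        raise ValueError("need >= 2 individuals")
    cvs, ns = {}, {}
    for met in per_ind.columns:
        col = per_ind[met].dropna()
        cvs[met] = cv_percent(col) if len(col) >= 2 and col.mean() != 0 else np.nan
        ns[met] = len(col)
    return pd.DataFrame({"cv": pd.Series(cvs), "n_individuals": pd.Series(ns)})


def absence_stats(table: ConcentrationTable, noise_equivalent: dict | None = None,
                  lod_multiplier: float = 3.0) -> pd.Series:
    """Fraction of samples per metabolite below detection.

    A value is absent if flagged in the table's mask or, when a
    ``noise_equivalent`` area/concentration map is given, below
    ``lod_multiplier`` x its noise-equivalent level.
    """
    absent = table.absent_mask.copy()
    if noise_equivalent:
        for met, lod in noise_equivalent.items():
            if met in table.values.columns:
                absent[met] |= table.values[met] < lod_multiplier * lod
    return absent.mean(axis=0)


def cv_report(table: ConcentrationTable, design: CohortDesign) -> CvReport:
    """All applicable CV layers in one frame (NaN where a layer's design
    requirements are not met)."""
    mets = table.metabolites
    out = pd.DataFrame(index=mets)
    try:
        ia = intra_assay_cv(table, design)
        out["intra_assay_cv"] = ia["cv"]
        out["n_replicate_groups"] = ia["n_groups"]
    except ValueError:
        out["intra_assay_cv"] = np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            ii = intra_individual_cv(table, design)
            out["intra_individual_cv"] = ii["cv"]
            out["n_individuals_intra"] = ii["n_individuals"]
        except ValueError:
            out["intra_individual_cv"] = np.nan
    try:
        pop = inter_individual_cv(table, design)
        out["inter_individual_cv"] = pop["cv"]
        out["n_individuals"] = pop["n_individuals"]
    except ValueError:
        out["inter_individual_cv"] = np.nan
    out["absent_fraction"] = absence_stats(table)
    return CvReport(out)
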