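"""Cohort-level statistics: qPCR quantification, diarrhoea classification,
normality-gated group comparisons, Enterobacteriaceae/dry-matter
correlations, MUC13 genotyping and colostral immune-load arithmetic."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import QpcrRun, StandardCurve

__all__ = [
    "fit_standard_curve",
    "quantify_copies",
    "quantify_run",
    "classify_diarrhoea",
    "correlate_entero_dm",
    "group_compare",
    "paired_age_compare",
    "call_muc13",
    "muc13_genotype_and_test",
    "ingested_immune_load",
]

log = logging.getLogger(__name__)


def fit_standard_curve(standards: pd.DataFrame) -> StandardCurve:
    """Least-squares line of Cq on log10(copies) over the dilution series.

    Amplification efficiency follows from the slope as 10^(-1/slope) - 1
    (slope -3.32 at perfect doubling).
    """
    if len(standards) < 3:
        raise ValueError("need at least 3 dilution points")
    x = np.log10(standards["copies"].values.astype(float))
    y = standards["cq"].values.astype(float)
    if np.ptp(x) == 0:
        raise ValueError("standards have zero variance in copy number")
    res = stats.linregress(x, y)
    return StandardCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        cq_min=float(y.min()),
        cq_max=float(y.max()),
    )


def quantify_copies(
    curve: StandardCurve,
    cq: float,
    dna_mass_ug: float = 100.0,
    extrapolation_margin: float = 3.0,
) -> tuple[float, bool]:
    """Absolute copies per 100 ug DNA from a sample Cq.

    copies = 10^((Cq - intercept) / slope), rescaled by 100 / DNA input
    mass. Returns (copies, in_range); a Cq beyond the standards' range plus
    ``extrapolation_margin`` cycles is still quantified but flagged.
    """
    if curve.slope >= 0:
        raise ValueError("standard curve slope must be negative")
    in_range = (curve.cq_min - extrapolation_margin) <= cq <= (curve.cq_max + extrapolation_margin)
    if not in_range:
        log.warning("Cq %.2f outside standards range [%.2f, %.2f] +/- %.1f",
                    cq, curve.cq_min, curve.cq_max, extrapolation_margin)
    copies = 10.0 ** ((cq - curve.intercept) / curve.slope)
    return copies * 100.0 / dna_mass_ug, in_range


def quantify_run(run: QpcrRun, extrapolation_margin: float = 3.0) -> pd.DataFrame:
    """Quantify every unknown of a run against its own standard curve."""
    curve = fit_standard_curve(run.standards)
    rows = []
    for _, rec in run.samples.iterrows():
        copies, ok = quantify_copies(curve, rec["cq"], rec["dna_mass_ug"],
                                     extrapolation_margin)
        rows.append({"sample": rec["sample"], "target": rec["target"],
                     "copies_per_100ug": copies, "in_range": ok})
    return pd.DataFrame(rows)


def classify_diarrhoea(
    dm_series: pd.Series, dm_threshold: float = 20.0, min_consecutive: int = 2
) -> tuple[str, tuple | None]:
    """H/D call from a dry-matter time series.

    D iff dry matter is below ``dm_threshold`` on at least
    ``min_consecutive`` consecutive observed days (days must be adjacent:
    an observation gap breaks a run). Returns the label and the first
    qualifying (start_day, end_day) window, or None for H.
    """
    s = pd.Series(dm_series).dropna().sort_index()
    if s.empty:
        raise ValueError("empty dry-matter series")
    days = np.asarray(s.index, dtype=float)
    low = s.values < dm_threshold
    run_start = None
    run_len = 0
    prev_day = None
    for day, is_low in zip(days, low):
        contiguous = prev_day is not None and day - prev_day == 1
        if is_low:
            if run_len > 0 and contiguous:
                run_len += 1
            else:
                run_start, run_len = day, 1
            if run_len >= min_consecutive:
                return "D", (run_start, day)
        else:
            run_len = 0
        prev_day = day
    return "H", None


def correlate_entero_dm(
    copies: pd.Series, dm: pd.Series, dm_threshold: float = 20.0
) -> pd.DataFrame:
    """Pearson correlation of bacterial load vs dry matter, split at the
    liquid-feces threshold.

    Samples with DM below the threshold form the 'liquid' subgroup, the
    rest 'solid'; each subgroup needs >= 3 points and nonzero variance.
    Returns one row per subgroup: n, r, r_squared, p.
    """
    df = pd.DataFrame({"copies": copies, "dm": dm}).dropna()
    rows = []
    for name, sub in (("liquid", df[df["dm"] < dm_threshold]),
                      ("solid", df[df["dm"] >= dm_threshold])):
        if len(sub) < 3:
            raise ValueError(f"subgroup '{name}' has fewer than 3 points ({len(sub)})")
        if sub["copies"].std() == 0 or sub["dm"].std() == 0:
            rows.append({"subgroup": name, "n": len(sub), "r": np.nan,
                         "r_squared": np.nan, "p": np.nan, "degenerate": True})
            continue
        r, p = stats.pearsonr(sub["copies"], sub["dm"])
        rows.append({"subgroup": name, "n": len(sub), "r": float(r),
                     "r_squared": float(r**2), "p": float(p), "degenerate": False})
    return pd.DataFrame(rows)


@dataclass
class GroupCompareResult:
    test: str            # "t" or "mann-whitney"
    statistic: float
    p_value: float
    shapiro_p: dict
    branch_reason: str


def group_compare(values, groups, alpha_normality: float = 0.05) -> GroupCompareResult:
    """Two-group comparison gated by Shapiro-Wilk normality.

    Both groups normal at ``alpha_normality`` -> Student's t-test; either
    non-normal -> Mann-Whitney U. Groups smaller than 3 skip the gate and
    force the nonparametric branch (logged).
    """
    df = pd.DataFrame({"v": list(values), "g": list(groups)}).dropna()
    labs = sorted(df["g"].unique())
    if len(labs) != 2:
        raise ValueError(f"need exactly 2 groups, got {labs}")
    a = df.loc[df["g"] == labs[0], "v"].values.astype(float)
    b = df.loc[df["g"] == labs[1], "v"].values.astype(float)
    shapiro_p = {}
    if min(len(a), len(b)) < 3:
        log.warning("group below 3 samples; forcing Mann-Whitney")
        branch, reason = "mann-whitney", "group too small for normality gate"
    else:
        for lab, arr in ((labs[0], a), (labs[1], b)):
            if np.ptp(arr) == 0:
                shapiro_p[lab] = 0.0  # constant sample: not plausibly normal
            else:
                shapiro_p[lab] = float(stats.shapiro(arr).pvalue)
        normal = all(p_ >= alpha_normality for p_ in shapiro_p.values())
        branch = "t" if normal else "mann-whitney"
        reason = "both groups normal" if normal else "normality rejected"
    if branch == "t":
        res = stats.ttest_ind(a, b, equal_var=True)
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return GroupCompareResult(
        test=branch,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        shapiro_p=shapiro_p,
        branch_reason=reason,
    )


def paired_age_compare(values: pd.DataFrame) -> pd.DataFrame:
    """Within-group age effects: paired t-tests between consecutive ages.

    ``values``: rows = subjects, columns = ages (ascending). Returns one
    row per consecutive age pair with the paired-t statistic and p.
    """
    cols = sorted(values.columns)
    rows = []
    for a, b in zip(cols[:-1], cols[1:]):
        sub = values[[a, b]].dropna()
        if len(sub) < 2:
            raise ValueError(f"need >= 2 paired observations for ages {a}-{b}")
        res = stats.ttest_rel(sub[a], sub[b])
        rows.append({"age_from": a, "age_to": b, "t": float(res.statistic),
                     "p": float(res.pvalue), "n": len(sub)})
    return pd.DataFrame(rows)


def call_muc13(lengths, tol: float = 2.0) -> str:
    """Genotype from amplicon lengths: 151 bp -> A allele, 83 bp -> B.

    Lengths within ``tol`` bp of the nominal sizes are accepted; anything
    else yields an unassigned call ('--', with a warning).
    """
    alleles = []
    for ln in lengths:
        if ln is None or (isinstance(ln, float) and math.isnan(ln)):
            continue
        if abs(ln - 151.0) <= tol:
            alleles.append("A")
        elif abs(ln - 83.0) <= tol:
            alleles.append("B")
        else:
            log.warning("unrecognized MUC13 amplicon length %.1f bp", ln)
            alleles.append("-")
    if not alleles:
        return "--"
    if len(alleles) == 1:   # single band = homozygote
        alleles = alleles * 2
    return "".join(sorted(alleles[:2]))


def muc13_genotype_and_test(
    lengths_by_pig: dict[str, tuple], groups: dict[str, str],
    tol: float = 2.0, yates: bool = False,
) -> tuple[pd.DataFrame, float, float]:
    """Call genotypes and chi-square-test allele prevalence by group.

    Builds the 2x2 allele-count table (A/B x H/D) and applies Pearson's
    chi-squared test (no continuity correction unless ``yates``). Returns
    (genotype table, chi2, p).
    """
    rows = []
    counts = {("A", "H"): 0, ("A", "D"): 0, ("B", "H"): 0, ("B", "D"): 0}
    for pig, lens in lengths_by_pig.items():
        geno = call_muc13(lens, tol=tol)
        rows.append({"pig": pig, "genotype": geno, "group": groups.get(pig)})
        for allele in geno:
            if allele in "AB" and groups.get(pig) in ("H", "D"):
                counts[(allele, groups[pig])] += 1
    table = np.array([
        [counts[("A", "H")], counts[("A", "D")]],
        [counts[("B", "H")], counts[("B", "D")]],
    ])
    if table.sum() == 0 or (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
        chi2, p = np.nan, np.nan
    else:
        chi2, p, _, _ = stats.chi2_contingency(table, correction=yates)
    return pd.DataFrame(rows), float(chi2), float(p)


# minimal unit bookkeeping for concentration x volume products
_MASS = {"g": 1.0, "mg": 1e-3, "ug": 1e-6, "µg": 1e-6, "ng": 1e-9}
_VOL = {"l": 1.0, "ml": 1e-3, "mL": 1e-3}


def ingested_immune_load(
    concentrations: dict[str, tuple[float, str]], intake: tuple[float, str]
) -> dict[str, tuple[float, str]]:
    """Quantity of each colostral component ingested in the first day.

    Each concentration (value, 'mass/volume' unit) is multiplied by the
    colostrum intake (value, volume unit); the result carries the
    concentration's mass unit. A non-volume intake unit or mismatched
    denominators raise.
    """
    vol_value, vol_unit = intake
    if vol_value < 0:
        raise ValueError("intake must be non-negative")
    if vol_unit.lower() not in _VOL:
        raise ValueError(f"intake unit must be a volume, got '{vol_unit}'")
    out = {}
    for comp, (value, unit) in concentrations.items():
        if value < 0:
            raise ValueError(f"negative concentration for {comp}")
        try:
            num, denom = unit.split("/")
        except ValueError as exc:
            raise ValueError(f"concentration unit '{unit}' is not mass/volume") from exc
        if num.lower() not in _MASS or denom.lower() not in _VOL:
            raise ValueError(f"unsupported unit '{unit}' for {comp}")
        litres = vol_value * _VOL[vol_unit.lower()]
        per_litre = value / _VOL[denom.lower()]
        out[comp] = (per_litre * litres, num)
    return out
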