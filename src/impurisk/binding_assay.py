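"""Competition HLA-binding assay analysis: percent inhibition, IC50, bins.

In the competition format an unlabeled test peptide competes with a
labeled reference peptide for a soluble HLA DR molecule; the readout per
concentration is percent inhibition of the labeled signal.  Each
peptide-allele pair is titrated in triplicate over seven ascending
concentrations.  A four-parameter logistic (4PL) in log10 concentration is
fitted by least squares; the IC50 — the concentration inhibiting half of
the labeled competitor — is the curve's inflection point.  Dose dependence
is required for a binder call: a one-sided Spearman trend test of mean
inhibition against concentration (p < 0.05) plus an IC50 within 10x of the
tested range.  IC50s are binned: <=100 nM very-high, (100, 1e3] high,
(1e3, 1e4] moderate, (1e4, 1e5] low, (1e5, 1e6] negligible; anything above
1e6 nM or without dose-dependent inhibition is a non-binder.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

N_CONCENTRATIONS = 7
N_REPLICATES = 3

AFFINITY_BINS = (  # (upper bound nM, label)
    (100.0, "very-high"),
    (1_000.0, "high"),
    (10_000.0, "moderate"),
    (100_000.0, "low"),
    (1_000_000.0, "negligible"),
)

INHIBITION_CLIP = (-10.0, 110.0)


class AssayError(ValueError):
    pass


def percent_inhibition(
    signal: float, max_signal: float, background: float
) -> tuple[float, bool]:
    """Percent inhibition of the labeled competitor; (value, clipped flag)."""
    if max_signal <= background:
        raise AssayError("max_signal must exceed background")
    raw = 100.0 * (1.0 - (signal - background) / (max_signal - background))
    lo, hi = INHIBITION_CLIP
    return float(np.clip(raw, lo, hi)), not lo <= raw <= hi


@dataclass(frozen=True)
class InhibitionCurve:
    peptide: str
    allele: str
    concentrations_nM: tuple[float, ...]          # 7, strictly ascending
    inhibition: tuple[tuple[float, ...], ...]     # 7 x 3 percent values

    def __post_init__(self) -> None:
        if len(self.concentrations_nM) != N_CONCENTRATIONS:
            raise AssayError(f"expected {N_CONCENTRATIONS} concentrations")
        if any(c <= 0 for c in self.concentrations_nM):
            raise AssayError("concentrations must be positive")
        if any(b <= a for a, b in zip(self.concentrations_nM, self.concentrations_nM[1:])):
            raise AssayError("concentrations must be strictly ascending")
        if len(self.inhibition) != N_CONCENTRATIONS or any(
            len(reps) != N_REPLICATES for reps in self.inhibition
        ):
            raise AssayError(f"need {N_REPLICATES} replicates per concentration")
        if not np.isfinite(np.asarray(self.inhibition)).all():
            raise AssayError("non-finite inhibition values")


def four_pl(log_c: np.ndarray, bottom: float, top: float, log_ic50: float, hill: float):
    """4PL inhibition rising with concentration; inflection at log_ic50."""
    return bottom + (top - bottom) / (1.0 + 10 ** (hill * (log_ic50 - log_c)))


@dataclass
class IC50Result:
    peptide: str
    allele: str
    ic50_nM: Optional[float]
    dose_dependent: bool
    affinity_class: str
    top: Optional[float] = None
    bottom: Optional[float] = None
    hill: Optional[float] = None
    trend_p: Optional[float] = None
    diagnostics: dict = field(default_factory=dict)


def classify_affinity(ic50_nM: Optional[float], dose_dependent: bool) -> str:
    """The assay's qualitative bin for one IC50 (closed upper bounds)."""
    if not dose_dependent or ic50_nM is None:
        return "non-binder"
    if ic50_nM <= 0:
        raise AssayError("IC50 must be positive")
    for bound, label in AFFINITY_BINS:
        if ic50_nM <= bound:
            return label
    return "non-binder"


def fit_ic50(curve: InhibitionCurve, alpha: float = 0.05) -> IC50Result:
    """Least-squares 4PL fit plus the dose-dependence gate.

    Soft parameter bounds keep the asymptotes near the assay scale
    (bottom in [-10, 20], top in [60, 110], hill > 0).  A curve whose trend
    test fails, whose fitted IC50 falls more than 10x outside the tested
    range, or whose fit does not converge is reported as a non-binder.
    """
    conc = np.asarray(curve.concentrations_nM)
    y = np.asarray(curve.inhibition, dtype=float)          # 7 x 3
    log_c = np.log10(conc)
    means = y.mean(axis=1)

    if np.ptp(means) == 0:
        trend_p = 1.0  # flat response: no trend by construction
    else:
        _, trend_p = stats.spearmanr(conc, means, alternative="greater")
    x_all = np.repeat(log_c, N_REPLICATES)
    y_all = y.ravel()

    diagnostics: dict = {}
    try:
        p0 = [0.0, 100.0, float(np.median(log_c)), 1.0]
        bounds = ([-10.0, 60.0, log_c[0] - 3.0, 0.05], [20.0, 110.0, log_c[-1] + 3.0, 5.0])
        popt, _ = optimize.curve_fit(
            four_pl, x_all, y_all, p0=p0, bounds=bounds, maxfev=20000
        )
        bottom, top, log_ic50, hill = (float(v) for v in popt)
        ic50 = 10 ** log_ic50
        resid = y_all - four_pl(x_all, *popt)
        diagnostics["rmse"] = float(np.sqrt(np.mean(resid**2)))
        converged = True
    except RuntimeError as exc:
        bottom = top = hill = None
        ic50 = None
        converged = False
        diagnostics["fit_error"] = str(exc)

    in_range = (
        ic50 is not None
        and conc[0] / 10.0 <= ic50 <= conc[-1] * 10.0
    )
    dose_dependent = converged and trend_p < alpha and in_range
    result_ic50 = ic50 if dose_dependent else None
    return IC50Result(
        peptide=curve.peptide,
        allele=curve.allele,
        ic50_nM=result_ic50,
        dose_dependent=dose_dependent,
        affinity_class=classify_affinity(result_ic50, dose_dependent),
        top=top,
        bottom=bottom,
        hill=hill,
        trend_p=float(trend_p) if np.isfinite(trend_p) else None,
        diagnostics=diagnostics,
    )


# ---------------------------------------------------------------------------
# CSV interfaces

def read_curves_csv(path: Path) -> list[InhibitionCurve]:
    """Curves from CSV: peptide, allele, concentration_nM, replicate, percent_inhibition.

    A raw-signal dialect (columns signal, max_signal, background) is also
    accepted and converted to percent inhibition.
    """
    df = pd.read_csv(path)
    if "percent_inhibition" not in df.columns:
        df["percent_inhibition"] = [
            percent_inhibition(r.signal, r.max_signal, r.background)[0]
            for r in df.itertuples()
        ]
    curves = []
    for (pep, allele), grp in df.groupby(["peptide", "allele"], sort=False):
        concs = sorted(grp["concentration_nM"].unique())
        reps = tuple(
            tuple(grp.loc[grp["concentration_nM"] == c, "percent_inhibition"])
            for c in concs
        )
        curves.append(InhibitionCurve(pep, allele, tuple(concs), reps))
    return curves


def results_to_csv(results: Sequence[IC50Result], path: Path) -> None:
    pd.DataFrame(
        [
            {
                "peptide": r.peptide,
                "allele": r.allele,
                "ic50_nM": r.ic50_nM,
                "class": r.affinity_class,
                "dose_dependent": r.dose_dependent,
                "hill": r.hill,
                "top": r.top,
                "bottom": r.bottom,
                "trend_p": r.trend_p,
                "rmse": r.diagnostics.get("rmse"),
            }
            for r in results
        ]
    ).to_csv(path, index=False)
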