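"""FluoroSpot / naive T-cell assay analytics.

Donor PBMCs cultured with a test article are re-plated in triplicate on a
FluoroSpot plate (1.0e5 cells per well by default); cytokine-secreting
cells appear as spots.  Counts are normalised to spot-forming cells (SFC)
per 1e6 PBMCs.  A donor responds to a condition when all three criteria
hold: stimulation index SI >= 2 (test mean over medium mean), mean SFC per
million strictly above 50, and a two-sided two-sample Student's t-test of
the triplicates against medium with p < 0.05.  Donors enter the cohort
only when their controls behave (KLH, CEFT, PHA positive; HSA negative).
Cohort response rates, nonparametric API-versus-impurity comparisons
(Mann-Whitney and Wilcoxon signed-rank), spiked-product increments and a
carried-allele HLA coverage sum round out the module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_CELLS_PER_WELL = 1.0e5
SI_THRESHOLD = 2.0       # closed: SI >= 2
SFC_THRESHOLD = 50.0     # strict: SFC/1e6 > 50
P_THRESHOLD = 0.05

POSITIVE_CONTROLS = ("KLH", "CEFT", "PHA")
NEGATIVE_CONTROL = "HSA"
MEDIUM = "medium"


class TCellAssayError(ValueError):
    pass


@dataclass(frozen=True)
class FluoroSpotWell:
    donor: str
    condition: str
    spots: int
    cells_per_well: float = DEFAULT_CELLS_PER_WELL

    def __post_init__(self) -> None:
        if self.spots < 0:
            raise TCellAssayError("spot count must be >= 0")
        if self.cells_per_well <= 0:
            raise TCellAssayError("cells per well must be > 0")


@dataclass(frozen=True)
class DonorRecord:
    donor: str
    age: Optional[int] = None
    sex: Optional[str] = None
    drb1_alleles: tuple[str, ...] = ()
    qc_pass: Optional[bool] = None


@dataclass(frozen=True)
class PositivityCall:
    donor: str
    condition: str
    sfc_per_million: float
    si: float
    p_value: float
    si_ok: bool
    sfc_ok: bool
    stat_ok: bool
    background_floored: bool = False

    @property
    def positive(self) -> bool:
        return self.si_ok and self.sfc_ok and self.stat_ok


def sfc_per_million(count: float, cells_per_well: float = DEFAULT_CELLS_PER_WELL) -> float:
    """Spot-forming cells normalised per 1e6 PBMCs."""
    if cells_per_well <= 0:
        raise TCellAssayError("cells per well must be > 0")
    return count * (1.0e6 / cells_per_well)


def positivity(
    test_wells: Sequence[FluoroSpotWell],
    medium_wells: Sequence[FluoroSpotWell],
) -> PositivityCall:
    """Three-criterion response call for one donor-condition.

    SI uses the medium mean floored at one spot (flagged) so zero-background
    wells do not produce an undefined index.
    """
    if len(test_wells) < 2 or len(medium_wells) < 2:
        raise TCellAssayError("need at least 2 replicates per side")
    test = np.array([w.spots for w in test_wells], dtype=float)
    medium = np.array([w.spots for w in medium_wells], dtype=float)
    floored = medium.mean() < 1.0
    si = test.mean() / max(medium.mean(), 1.0)
    sfc = float(np.mean([sfc_per_million(w.spots, w.cells_per_well) for w in test_wells]))
    if np.ptp(test) == 0 and np.ptp(medium) == 0:
        p = 1.0 if test.mean() == medium.mean() else 0.0
    else:
        with warnings.catch_warnings():
            # near-identical replicates trigger a precision-loss warning;
            # the resulting large p is the correct call either way
            warnings.simplefilter("ignore", RuntimeWarning)
            p = float(stats.ttest_ind(test, medium, equal_var=True).pvalue)
    return PositivityCall(
        donor=test_wells[0].donor,
        condition=test_wells[0].condition,
        sfc_per_million=sfc,
        si=float(si),
        p_value=p,
        si_ok=si >= SI_THRESHOLD,
        sfc_ok=sfc > SFC_THRESHOLD,
        stat_ok=p < P_THRESHOLD,
        background_floored=floored,
    )


def donor_qc(calls: Mapping[str, PositivityCall]) -> bool:
    """Include a donor only when all controls behave as designed."""
    for ctrl in POSITIVE_CONTROLS + (NEGATIVE_CONTROL,):
        if ctrl not in calls:
            raise TCellAssayError(f"missing control condition {ctrl!r}")
    return (
        all(calls[c].positive for c in POSITIVE_CONTROLS)
        and not calls[NEGATIVE_CONTROL].positive
    )


def response_rate(calls: Iterable[PositivityCall]) -> tuple[int, int, int]:
    """(k positive, N donors, integer percent, half away from zero)."""
    calls = list(calls)
    n = len(calls)
    if n == 0:
        raise TCellAssayError("no donors")
    k = sum(c.positive for c in calls)
    percent = int(np.floor(100.0 * k / n + 0.5))
    return k, n, percent


@dataclass(frozen=True)
class ConditionComparison:
    mann_whitney_p: float
    wilcoxon_p: float
    degenerate_wilcoxon: bool = False


def compare_conditions(
    api_sfc: Sequence[float], imp_sfc: Sequence[float], paired: bool = True
) -> ConditionComparison:
    """Two-sided Mann-Whitney and Wilcoxon signed-rank p-values.

    Exact distributions for small samples (n <= 12, no ties), normal
    approximation with tie correction otherwise.  All-zero paired
    differences make the Wilcoxon statistic undefined; reported as p = 1
    with a flag.
    """
    a = np.asarray(api_sfc, dtype=float)
    b = np.asarray(imp_sfc, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise TCellAssayError("need at least 3 observations per group")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (max(len(a), len(b)) <= 12 and not has_ties) else "asymptotic"
    mw_p = float(stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)

    degenerate = False
    if paired:
        if len(a) != len(b):
            raise TCellAssayError("paired comparison requires equal lengths")
        diffs = a - b
        if np.all(diffs == 0):
            wx_p, degenerate = 1.0, True
        else:
            nz = diffs[diffs != 0]
            wx_method = "exact" if (len(nz) <= 12 and len(np.unique(np.abs(nz))) == len(nz)) else "approx"
            wx_p = float(
                stats.wilcoxon(a, b, alternative="two-sided", zero_method="wilcox",
                               method=wx_method).pvalue
            )
    else:
        wx_p, degenerate = float("nan"), True
    return ConditionComparison(mann_whitney_p=mw_p, wilcoxon_p=wx_p, degenerate_wilcoxon=degenerate)


@dataclass
class SpikedSummary:
    impurity: str
    incremental_responders: tuple[str, ...]   # positive to spiked, negative to RLD
    rld_rate: tuple[int, int, int]
    spiked_rate: tuple[int, int, int]
    rate_delta_pct: int
    spot_ratio_by_donor: dict[str, float]


def spiked_analysis(
    rld_calls: Mapping[str, PositivityCall],
    spiked_calls: Mapping[str, PositivityCall],
    impurity: str = "",
) -> SpikedSummary:
    """Incremental responders and per-donor spot ratios for a spiked product."""
    if set(rld_calls) != set(spiked_calls):
        raise TCellAssayError("RLD and spiked arms cover different donors")
    donors = sorted(rld_calls)
    incremental = tuple(
        d for d in donors if spiked_calls[d].positive and not rld_calls[d].positive
    )
    rld_rate = response_rate(rld_calls.values())
    spk_rate = response_rate(spiked_calls.values())
    ratios = {
        d: (
            spiked_calls[d].sfc_per_million / rld_calls[d].sfc_per_million
            if rld_calls[d].sfc_per_million > 0
            else float("inf")
        )
        for d in donors
    }
    return SpikedSummary(
        impurity=impurity,
        incremental_responders=incremental,
        rld_rate=rld_rate,
        spiked_rate=spk_rate,
        rate_delta_pct=spk_rate[2] - rld_rate[2],
        spot_ratio_by_donor=ratios,
    )


def spiked_concentration(api_ug_ml: float, abundance_pct: float) -> float:
    """Mass concentration of an impurity spiked at its observed abundance."""
    if api_ug_ml <= 0 or abundance_pct <= 0:
        raise TCellAssayError("concentration and abundance must be positive")
    return api_ug_ml * abundance_pct / 100.0


def hla_coverage(
    cohort: Iterable[DonorRecord], freq_table: Mapping[str, float]
) -> tuple[float, tuple[str, ...]]:
    """Percent of table frequency mass carried by >= 1 donor.

    Alleles absent from the table are flagged (returned) and excluded.
    """
    if sum(freq_table.values()) > 1.0 + 1e-9:
        raise TCellAssayError("frequency table sums to more than 1")
    carried: set[str] = set()
    unknown: set[str] = set()
    for donor in cohort:
        for allele in donor.drb1_alleles:
            if allele in freq_table:
                carried.add(allele)
            else:
                unknown.add(allele)
    pct = 100.0 * sum(freq_table[a] for a in carried)
    return pct, tuple(sorted(unknown))


# ---------------------------------------------------------------------------
# Cohort-level convenience over the CSV interface

def read_wells_csv(path: Path) -> list[FluoroSpotWell]:
    df = pd.read_csv(path)
    return [
        FluoroSpotWell(
            donor=str(r.donor),
            condition=str(r.condition),
            spots=int(r.spots),
            cells_per_well=float(getattr(r, "cells_per_well", DEFAULT_CELLS_PER_WELL)),
        )
        for r in df.itertuples()
    ]


def call_cohort(
    wells: Sequence[FluoroSpotWell],
    test_conditions: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Per-donor calls for every non-medium condition, with donor QC.

    Returns a tidy frame: donor, condition, sfc, si, p, positive, qc_pass.
    """
    by_donor: dict[str, dict[str, list[FluoroSpotWell]]] = {}
    for w in wells:
        by_donor.setdefault(w.donor, {}).setdefault(w.condition, []).append(w)
    rows = []
    for donor, conds in sorted(by_donor.items()):
        if MEDIUM not in conds:
            raise TCellAssayError(f"donor {donor} lacks medium wells")
        medium = conds[MEDIUM]
        calls = {
            c: positivity(ws, medium) for c, ws in conds.items() if c != MEDIUM
        }
        qc = donor_qc(calls)
        wanted = test_conditions or [
            c for c in conds if c not in POSITIVE_CONTROLS + (NEGATIVE_CONTROL, MEDIUM)
        ]
        for cond in wanted:
            call = calls[cond]
            rows.append(
                {
                    "donor": donor,
                    "condition": cond,
                    "sfc_per_million": call.sfc_per_million,
                    "si": call.si,
                    "p_value": call.p_value,
                    "positive": call.positive,
                    "qc_pass": qc,
                }
            )
    return pd.DataFrame(rows)


def cohort_rates(calls: pd.DataFrame) -> pd.DataFrame:
    """Response rate per condition over QC-passing donors."""
    ok = calls[calls["qc_pass"]]
    rows = []
    for cond, grp in ok.groupby("condition", sort=False):
        k = int(grp["positive"].sum())
        n = len(grp)
        pct = int(np.floor(100.0 * k / n + 0.5)) if n else 0
        rows.append({"condition": cond, "k": k, "N": n, "percent": pct})
    return pd.DataFrame(rows)
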