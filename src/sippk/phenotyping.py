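"""Enzyme reaction phenotyping in a human-liver-microsome donor bank.

Correlation analysis: across donors, the rate of a metabolic endpoint is
regressed against each CYP-specific marker activity; the enzyme with the
highest Pearson R is called the major contributor for that endpoint, and the
call is flagged "supported" above an R threshold of 0.7.

Genotyped-donor comparison: metabolite-formation rates from replicate
incubations of genotyped donors are summarised as fold-decrease versus wild
type with a two-sided Welch t-test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import WT, canonical_genotype

__all__ = [
    "DonorBank",
    "PhenotypingResult",
    "correlation_analysis",
    "genotype_rate_comparison",
    "SUPPORT_THRESHOLD_R",
]

SUPPORT_THRESHOLD_R = 0.7


class DonorBankError(ValueError):
    pass


@dataclass
class DonorBank:
    """Donor × enzyme marker activities and donor × endpoint response rates.

    ``activities`` and ``rates`` are indexed by donor id and must be aligned
    row-for-row.  ``ground_truth`` (when the bank is synthetic) travels with
    the data for closed-loop recovery tests.
    """

    activities: pd.DataFrame  # donor × enzyme
    rates: pd.DataFrame  # donor × endpoint
    genotype: Optional[pd.Series] = None
    ground_truth: Optional[dict] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.activities.index.equals(self.rates.index):
            raise DonorBankError("activities and rates must share the same donor index")
        if len(self.activities) < 3:
            raise DonorBankError("correlation analysis needs at least 3 donors")
        if (self.activities.values < 0).any():
            raise DonorBankError("marker activities must be non-negative")

    @property
    def n_donors(self) -> int:
        return len(self.activities)

    def to_csv(self, path) -> None:
        df = pd.concat(
            [self.activities.add_prefix("activity_"), self.rates.add_prefix("rate_")], axis=1
        )
        if self.genotype is not None:
            df.insert(0, "genotype", self.genotype)
        df.index.name = "donor"
        df.to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "DonorBank":
        df = pd.read_csv(path, index_col="donor")
        act = df.filter(like="activity_").rename(columns=lambda c: c[len("activity_"):])
        rates = df.filter(like="rate_").rename(columns=lambda c: c[len("rate_"):])
        genotype = df["genotype"] if "genotype" in df.columns else None
        return cls(activities=act, rates=rates, genotype=genotype)


@dataclass
class PhenotypingResult:
    correlations: pd.DataFrame  # endpoint × enzyme, Pearson R (NaN if undefined)
    ranking: Dict[str, pd.Series]  # per endpoint, enzymes sorted by R desc
    major_enzyme: pd.Series  # per endpoint
    supported: pd.Series  # per endpoint, R(major) > threshold
    threshold: float = SUPPORT_THRESHOLD_R

    def report(self) -> str:
        lines = ["endpoint: major enzyme (R, support)"]
        for endpoint in self.correlations.index:
            enz = self.major_enzyme[endpoint]
            r = self.correlations.loc[endpoint, enz]
            flag = "supported" if self.supported[endpoint] else "not supported"
            lines.append(f"{endpoint}: {enz} (R={r:.3f}, {flag})")
        return "\n".join(lines)


def correlation_analysis(
    bank: DonorBank, threshold: float = SUPPORT_THRESHOLD_R
) -> PhenotypingResult:
    """Pearson correlation of each endpoint rate with each marker activity.

    Enzymes whose activity column is constant across donors have no defined
    correlation; they are reported as NaN and excluded from the ranking.
    """
    enzymes = list(bank.activities.columns)
    endpoints = list(bank.rates.columns)
    r_matrix = pd.DataFrame(index=endpoints, columns=enzymes, dtype=float)
    for enzyme in enzymes:
        activity = bank.activities[enzyme].to_numpy(dtype=float)
        if np.ptp(activity) == 0.0:
            warnings.warn(
                f"marker activity for {enzyme} is constant across donors; "
                "correlation undefined",
                stacklevel=2,
            )
            r_matrix[enzyme] = np.nan
            continue
        for endpoint in endpoints:
            rate = bank.rates[endpoint].to_numpy(dtype=float)
            if np.ptp(rate) == 0.0:
                r_matrix.loc[endpoint, enzyme] = np.nan
            else:
                r_matrix.loc[endpoint, enzyme] = stats.pearsonr(activity, rate).statistic

    ranking: Dict[str, pd.Series] = {}
    major = {}
    supported = {}
    for endpoint in endpoints:
        row = r_matrix.loc[endpoint].dropna().sort_values(ascending=False)
        if row.empty:
            raise DonorBankError(f"no enzyme with defined correlation for {endpoint!r}")
        ranking[endpoint] = row
        major[endpoint] = row.index[0]
        supported[endpoint] = bool(row.iloc[0] > threshold)
    return PhenotypingResult(
        correlations=r_matrix,
        ranking=ranking,
        major_enzyme=pd.Series(major),
        supported=pd.Series(supported),
        threshold=threshold,
    )


def genotype_rate_comparison(
    rates: pd.DataFrame, reference: str = WT, rate_column: str = "rate"
) -> pd.DataFrame:
    """Fold-decrease versus the reference genotype plus Welch t-test p-values.

    ``rates`` holds one row per replicate incubation with columns
    ``genotype`` and ``rate``.  Returns one row per genotype with n, mean,
    SD, ``fold_decrease`` (= mean(reference)/mean(genotype)) and the
    two-sided Welch ``p_value`` against the reference (NaN for the reference
    itself when it has no comparator meaning; reported as 1.0 vs itself).
    """
    if "genotype" not in rates.columns or rate_column not in rates.columns:
        raise DonorBankError(f"rates table needs 'genotype' and '{rate_column}' columns")
    df = rates.copy()
    df["genotype"] = df["genotype"].map(canonical_genotype)
    reference = canonical_genotype(reference)
    groups = {g: sub[rate_column].to_numpy(dtype=float) for g, sub in df.groupby("genotype")}
    if reference not in groups:
        raise DonorBankError(f"reference genotype {reference} absent from the rate table")
    ref = groups[reference]
    if min(len(v) for v in groups.values()) < 2:
        raise DonorBankError("need at least 2 replicates per genotype group")

    rows = []
    for genotype, values in sorted(groups.items()):
        mean = float(values.mean())
        if mean == 0.0:
            warnings.warn(f"zero mean rate for {genotype}; fold-decrease infinite", stacklevel=2)
            fold = float("inf")
        else:
            fold = float(ref.mean() / mean)
        if np.array_equal(values, ref):
            p = 1.0  # identical samples (incl. the reference vs itself)
        else:
            t_res = stats.ttest_ind(ref, values, equal_var=False)
            p = float(t_res.pvalue)
            if not np.isfinite(p):  # zero variance in both groups, equal means
                p = 1.0 if mean == float(ref.mean()) else 0.0
        rows.append(
            {
                "genotype": genotype,
                "n": len(values),
                "mean_rate": mean,
                "sd_rate": float(values.std(ddof=1)),
                "fold_decrease": fold,
                "p_value": p,
            }
        )
    return pd.DataFrame(rows).set_index("genotype")
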