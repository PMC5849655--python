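"""Synthetic in-vitro fixtures with known ground truth.

Real microsome-bank data (a 16-donor kit with vendor-characterised marker
activities) and genotyped-donor incubations are not redistributable, so the
phenotyping workflows run on generated stand-ins: per-donor enzyme activities
drawn lognormally around 1 (inter-donor CV), endpoint rates as the
fm-weighted mixture of those activities under multiplicative replicate
noise, and duplicate genotyped incubations whose group means follow known
activity multipliers.  Every generator is a pure function of (truth, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .genotypes import WT
from .phenotyping import DonorBank
from .population import lognormal_sigma

__all__ = ["GroundTruth", "make_donor_bank", "make_genotyped_incubations", "DEFAULT_ENZYMES"]

DEFAULT_ENZYMES = (
    "CYP1A2",
    "CYP2B6",
    "CYP2C8",
    "CYP2C9",
    "CYP2C19",
    "CYP2D6",
    "CYP3A4",
)


@dataclass(frozen=True)
class GroundTruth:
    """Generator parameters: what the synthetic assays should embody.

    ``fm`` is the true enzyme mixture behind the metabolic endpoint(s);
    ``multipliers`` the true per-genotype activity ratios; the two CVs set
    the inter-donor activity spread and the incubation replicate noise.
    Defaults mirror the study conditions: a CYP2C9-dominant mixture, 30%
    inter-donor variability, 10% assay noise, and the measured homozygote
    activity ratios (1.0 / 0.345 / 0.089) with their interpolated
    heterozygotes.
    """

    fm: Mapping[str, float] = field(
        default_factory=lambda: {
            "CYP2B6": 0.0024,
            "CYP2C8": 0.0154,
            "CYP2C9": 0.8084,
            "CYP2C19": 0.0015,
            "CYP3A4": 0.1723,
        }
    )
    multipliers: Mapping[str, float] = field(
        default_factory=lambda: {"*1/*1": 1.0, "*2/*2": 0.345, "*3/*3": 0.089}
    )
    inter_donor_cv: float = 0.30
    replicate_cv: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.fm.values()) > 1.0 + 1e-9:
            raise ValueError("true fm fractions must sum to at most 1")
        if any(not (0.0 <= f <= 1.0) for f in self.fm.values()):
            raise ValueError("fm fractions must lie in [0, 1]")
        if any(not (0.0 <= m <= 1.0) for m in self.multipliers.values()):
            raise ValueError("genotype multipliers must lie in [0, 1]")
        if self.inter_donor_cv < 0 or self.replicate_cv < 0:
            raise ValueError("noise CVs must be non-negative")


def _lognoise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative lognormal noise with geometric mean 1."""
    if cv == 0.0:
        return np.ones(size)
    return np.exp(rng.normal(0.0, lognormal_sigma(cv), size))


def make_donor_bank(
    truth: GroundTruth,
    n_donors: int = 16,
    enzymes: Sequence[str] = DEFAULT_ENZYMES,
    endpoints: Optional[Mapping[str, Mapping[str, float]]] = None,
) -> DonorBank:
    """Generate a donor bank for correlation phenotyping.

    Activities are lognormal around 1 arbitrary unit per enzyme (so the
    wild-type total rate is ~1 and the analysis is ratio-based, as in
    practice).  Each endpoint's rate per donor is Σ fm_i·activity_i times
    replicate noise.  Endpoints default to a single total-metabolism
    readout driven by ``truth.fm``; pass a mapping endpoint -> fm to
    emulate several metabolite channels.
    """
    if n_donors < 3:
        raise ValueError("need at least 3 donors")
    missing = set(truth.fm) - set(enzymes)
    if missing:
        raise ValueError(f"truth fm names enzymes outside the marker panel: {sorted(missing)}")
    rng = np.random.default_rng(truth.seed)
    donors = [f"D{i + 1:02d}" for i in range(n_donors)]
    activities = pd.DataFrame(
        _lognoise(rng, truth.inter_donor_cv, (n_donors, len(enzymes))),
        index=pd.Index(donors, name="donor"),
        columns=list(enzymes),
    )
    endpoint_fm: Dict[str, Mapping[str, float]] = (
        dict(endpoints) if endpoints is not None else {"total_metabolites": dict(truth.fm)}
    )
    rates = {}
    for endpoint, fm in endpoint_fm.items():
        signal = sum(
            frac * activities[enzyme].to_numpy() for enzyme, frac in fm.items()
        )
        rates[endpoint] = signal * _lognoise(rng, truth.replicate_cv, n_donors)
    rates_df = pd.DataFrame(rates, index=activities.index)
    return DonorBank(
        activities=activities,
        rates=rates_df,
        ground_truth={"fm": dict(truth.fm), "seed": truth.seed,
                      "inter_donor_cv": truth.inter_donor_cv,
                      "replicate_cv": truth.replicate_cv},
        metadata={"generator": "make_donor_bank", "n_donors": n_donors},
    )


def make_genotyped_incubations(truth: GroundTruth, replicates: int = 2) -> pd.DataFrame:
    """Replicate incubation rates for genotyped single donors.

    The wild-type rate is 1 arbitrary unit; each genotype's rate is its
    activity multiplier times lognormal replicate noise.  Returns one row
    per genotype × replicate with columns genotype, replicate, rate, plus
    the true multiplier for closed-loop checks.
    """
    if replicates < 2:
        raise ValueError("need at least 2 replicates per genotype")
    if WT not in truth.multipliers:
        raise ValueError("ground truth must include the wild-type genotype")
    rng = np.random.default_rng(truth.seed)
    rows = []
    for genotype, mult in truth.multipliers.items():
        noise = _lognoise(rng, truth.replicate_cv, replicates)
        for rep in range(replicates):
            rows.append(
                {
                    "genotype": genotype,
                    "replicate": rep,
                    "rate": mult * noise[rep],
                    "true_multiplier": mult,
                }
            )
    return pd.DataFrame(rows)
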