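"""Univariate Cox screening, risk-score signature and stratified survival.

Each candidate gene is screened with a univariate Cox proportional-hazards
fit (Breslow tie handling); genes with Wald p below threshold form the
signature and each patient receives

    risk_score = sum_i beta_i * Exp_i

the linear combination of signature-gene expression weighted by the Cox
coefficients. The cohort is split at the median risk score and the two
arms compared with Kaplan-Meier curves and the log-rank test, overall and
within molecular subtypes (CIN, GS, EBV, MSI).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test

logger = logging.getLogger(__name__)

SUBTYPES = ("ALL", "CIN", "GS", "EBV", "MSI")

__all__ = [
    "SurvivalRecord",
    "RiskModel",
    "CoxResult",
    "SUBTYPES",
    "univariate_cox",
    "build_signature",
    "risk_score",
    "dichotomize",
    "km_estimate",
    "logrank",
    "subtype_markers",
]


@dataclass(frozen=True)
class SurvivalRecord:
    """One patient's follow-up, event flag, subtype and expression vector."""

    sample_id: str
    time: float
    event: int
    subtype: str = "ALL"
    expression: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise ValueError(f"{self.sample_id}: follow-up time must be positive")
        if self.event not in (0, 1):
            raise ValueError(f"{self.sample_id}: event must be 0 or 1")


@dataclass
class RiskModel:
    """An ordered gene signature with univariate Cox coefficients."""

    genes: list[str]
    beta: list[float]

    def __post_init__(self) -> None:
        if len(self.genes) != len(self.beta):
            raise ValueError("genes and beta must have equal length")

    @property
    def n(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class CoxResult:
    gene: str
    beta: float
    se: float
    wald_p: float
    lr_p: float
    ok: bool
    reason: str | None = None


def _records_frame(records: Sequence[SurvivalRecord], gene: str) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "time": [r.time for r in records],
            "event": [r.event for r in records],
            "x": [float(r.expression[gene]) for r in records],
        }
    )


def univariate_cox(records: Sequence[SurvivalRecord], gene: str) -> CoxResult:
    """Single-covariate Cox partial-likelihood fit (Breslow ties).

    Failures — no/too few events, zero expression variance,
    non-convergence — are returned as a flagged result, not raised, so
    screening loops can skip the gene.
    """
    fail = lambda why: CoxResult(gene, np.nan, np.nan, np.nan, np.nan, False, why)
    try:
        df = _records_frame(records, gene)
    except KeyError:
        return fail("gene missing from expression")
    if df["event"].sum() < 2:
        return fail("fewer than 2 events")
    if np.std(df["x"]) == 0:
        return fail("zero expression variance")
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="time", event_col="event")
    except Exception as exc:  # lifelines raises ConvergenceError and friends
        return fail(f"fit failed: {type(exc).__name__}")
    summary = cph.summary.loc["x"]
    return CoxResult(
        gene=gene,
        beta=float(cph.params_["x"]),
        se=float(cph.standard_errors_["x"]),
        wald_p=float(summary["p"]),
        lr_p=float(cph.log_likelihood_ratio_test().p_value),
        ok=True,
    )


def build_signature(
    records: Sequence[SurvivalRecord],
    candidate_genes: Sequence[str],
    p_threshold: float = 0.05,
) -> RiskModel:
    """Signature = candidates with Wald p below threshold, in input order."""
    if not candidate_genes:
        raise ValueError("candidate gene list is empty")
    genes, beta = [], []
    for gene in candidate_genes:
        res = univariate_cox(records, gene)
        if res.ok and res.wald_p < p_threshold:
            genes.append(gene)
            beta.append(res.beta)
    if not genes:
        logger.warning("build_signature: no gene passed p < %g", p_threshold)
    return RiskModel(genes=genes, beta=beta)


def risk_score(model: RiskModel, expression: Mapping[str, float]) -> float:
    """sum(beta_i * Exp_i) over the signature genes; 0 for an empty model."""
    total = 0.0
    for gene, b in zip(model.genes, model.beta):
        if gene not in expression:
            raise KeyError(f"signature gene {gene!r} missing from expression")
        total += b * float(expression[gene])
    return total


def dichotomize(records: Sequence[SurvivalRecord], model: RiskModel) -> dict:
    """Median split of risk scores; scores equal to the cutoff go low-risk."""
    if len(records) < 2:
        raise ValueError("need at least 2 records to dichotomize")
    scores = {r.sample_id: risk_score(model, r.expression) for r in records}
    vals = np.array(list(scores.values()))
    if np.all(vals == vals[0]):
        raise ValueError("non-informative score: all risk scores identical")
    cutoff = float(np.median(vals))
    high = sorted(s for s, v in scores.items() if v > cutoff)
    low = sorted(s for s, v in scores.items() if v <= cutoff)
    return {"high_risk": high, "low_risk": low, "cutoff": cutoff, "scores": scores}


def km_estimate(records: Sequence[SurvivalRecord]) -> pd.DataFrame:
    """Product-limit survival curve: columns time, survival.

    S(0) = 1; the curve steps only at event times; censoring shrinks the
    risk set without a step.
    """
    if not records:
        raise ValueError("no records")
    kmf = KaplanMeierFitter()
    kmf.fit(
        durations=[r.time for r in records],
        event_observed=[r.event for r in records],
    )
    sf = kmf.survival_function_
    return pd.DataFrame(
        {"time": sf.index.to_numpy(dtype=float), "survival": sf.iloc[:, 0].to_numpy()}
    )


def logrank(
    group_a: Sequence[SurvivalRecord], group_b: Sequence[SurvivalRecord]
) -> dict:
    """Two-group log-rank chi-square (1 df) over pooled event times."""
    if sum(r.event for r in group_a) + sum(r.event for r in group_b) == 0:
        raise ValueError("log-rank requires at least one event")
    res = logrank_test(
        [r.time for r in group_a],
        [r.time for r in group_b],
        event_observed_A=[r.event for r in group_a],
        event_observed_B=[r.event for r in group_b],
    )
    return {"statistic": float(res.test_statistic), "p": float(res.p_value)}


def subtype_markers(
    records: Sequence[SurvivalRecord],
    candidate_genes: Sequence[str],
    subtypes: Sequence[str] = SUBTYPES,
    p_threshold: float = 0.05,
    min_events: int = 2,
) -> pd.DataFrame:
    """Per-subtype univariate Cox screen; significant genes classed
    Risky (beta > 0: higher expression, worse survival) or Protective."""
    rows = []
    for subtype in subtypes:
        subset = (
            list(records)
            if subtype == "ALL"
            else [r for r in records if r.subtype == subtype]
        )
        if sum(r.event for r in subset) < min_events:
            logger.warning("subtype %s skipped: fewer than %d events", subtype, min_events)
            continue
        for gene in candidate_genes:
            res = univariate_cox(subset, gene)
            if res.ok and res.wald_p < p_threshold:
                rows.append(
                    {
                        "gene": gene,
                        "subtype": subtype,
                        "beta": res.beta,
                        "p": res.wald_p,
                        "class": "Risky" if res.beta > 0 else "Protective",
                    }
                )
    return pd.DataFrame(rows, columns=["gene", "subtype", "beta", "p", "class"])
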