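"""Concordance of RNA-based sex calls against DNA-based truth labels.

The RNA (XIST) pipeline is validated against the gel-based SRY/ZFX method:
agreement counts exact female/male matches; inconclusive and insufficient
calls count as disagreement but are itemized so the accounting of
"n inconclusive individuals" stays recoverable. Discordances are
characterized mechanistically:

* call female / DNA male — candidate XXY aneuploidy (XIST expressed and
  SRY present in the same individual);
* call male / DNA female with low RNA yield — suspected XIST dropout (the
  transcript present but below detection within the run's cycles);
* anything else on a low-yield sample — generic low-yield failure;
* otherwise — unexplained.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Mapping

import numpy as np
import pandas as pd

__all__ = ["ConcordanceReport", "concordance", "summarize_yields", "run_report"]

CALL_LEVELS = ("female", "male", "inconclusive", "insufficient")
TRUTH_LEVELS = ("female", "male")


@dataclass(frozen=True)
class ConcordanceReport:
    """Agreement summary between RNA-based calls and DNA-based labels."""

    n_compared: int
    n_agree: int
    agreement_percent: float  # 100 * n_agree / n_compared, 2 decimals
    confusion: pd.DataFrame  # truth {female,male} x call levels
    discordant: tuple[dict, ...]  # per-sample reason records
    excluded_unknown_truth: tuple[str, ...]
    cohort_yields: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        return {
            "n_compared": self.n_compared,
            "n_agree": self.n_agree,
            "agreement_percent": self.agreement_percent,
            "confusion": {
                truth: {call: int(self.confusion.loc[truth, call]) for call in CALL_LEVELS}
                for truth in TRUTH_LEVELS
            },
            "discordant": list(self.discordant),
            "excluded_unknown_truth": list(self.excluded_unknown_truth),
            "cohort_yields": (
                self.cohort_yields.to_dict(orient="index")
                if self.cohort_yields is not None
                else None
            ),
        }


def _discordance_reason(call: str, truth: str, low_yield: bool) -> str:
    if call == "female" and truth == "male":
        return "xxy_candidate"
    if call == "male" and truth == "female" and low_yield:
        return "xist_dropout_suspected"
    if low_yield:
        return "low_yield"
    return "unexplained"


def concordance(
    calls: pd.DataFrame, metadata: pd.DataFrame
) -> ConcordanceReport:
    """Compare per-sample sex calls with DNA-based truth labels.

    ``calls`` is the calls table from :func:`xistmelt.sex_caller.call_sample_sex`;
    ``metadata`` provides ``dna_sex`` truth (samples with unknown truth are
    excluded from the comparison and listed separately) and RNA yields for
    the per-cohort summaries.
    """
    merged = calls.merge(
        metadata[["sample_id", "dna_sex"]], on="sample_id", how="left", validate="1:1"
    )
    merged["dna_sex"] = merged["dna_sex"].fillna("unknown")
    unknown = tuple(merged.loc[~merged["dna_sex"].isin(TRUTH_LEVELS), "sample_id"])
    compared = merged[merged["dna_sex"].isin(TRUTH_LEVELS)]
    if compared.empty:
        raise ValueError("no samples with known DNA truth labels to compare")

    agree = compared["call"] == compared["dna_sex"]
    n_compared = int(len(compared))
    n_agree = int(agree.sum())

    confusion = pd.DataFrame(0, index=list(TRUTH_LEVELS), columns=list(CALL_LEVELS))
    for _, row in compared.iterrows():
        if row["call"] in CALL_LEVELS:
            confusion.loc[row["dna_sex"], row["call"]] += 1

    discordant = []
    for _, row in compared[~agree].iterrows():
        low = "low_yield" in str(row.get("flags", ""))
        discordant.append(
            {
                "sample_id": row["sample_id"],
                "call": row["call"],
                "dna_sex": row["dna_sex"],
                "reason": _discordance_reason(row["call"], row["dna_sex"], low),
            }
        )

    cohort_yields = None
    if "cohort" in metadata.columns and metadata["rna_yield"].notna().any():
        cohort_yields = summarize_yields(metadata)

    return ConcordanceReport(
        n_compared=n_compared,
        n_agree=n_agree,
        agreement_percent=round(100.0 * n_agree / n_compared, 2),
        confusion=confusion,
        discordant=tuple(discordant),
        excluded_unknown_truth=unknown,
        cohort_yields=cohort_yields,
    )


def summarize_yields(metadata: pd.DataFrame) -> pd.DataFrame:
    """Per-cohort RNA-yield statistics: n, mean, five-number summary."""
    with_yield = metadata[metadata["rna_yield"].notna()]
    if with_yield.empty:
        raise ValueError("no samples with recorded RNA yields")
    rows = {}
    for cohort, group in with_yield.groupby("cohort", sort=True):
        y = group["rna_yield"].to_numpy(float)
        rows[cohort] = {
            "n": int(y.size),
            "mean": float(np.mean(y)),
            "min": float(np.min(y)),
            "q1": float(np.percentile(y, 25)),
            "median": float(np.median(y)),
            "q3": float(np.percentile(y, 75)),
            "max": float(np.max(y)),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def run_report(
    *,
    params: Mapping[str, Any],
    seed: int | None,
    qc: Mapping[str, Any],
    cluster_result,
    calls: pd.DataFrame,
    concordance_report: ConcordanceReport | None = None,
    version: str = "unknown",
) -> dict:
    """Assemble the machine-readable end-of-run report.

    Deterministic for a given run (no timestamps); the concordance section
    is marked absent — not zero — when no truth labels were supplied.
    """
    qc_items = sorted(qc.items())
    reasons: dict[str, int] = {}
    for _, item in qc_items:
        if not item.passed:
            reasons[item.reason] = reasons.get(item.reason, 0) + 1
    clusters = [
        {
            "cluster": s.cluster_id,
            "size": s.size,
            "mean_tm": round(s.mean_tm, 3),
            "medoid_well": s.medoid_well_id,
            "outlier": s.is_outlier,
        }
        for s in sorted(cluster_result.summaries.values(), key=lambda s: s.cluster_id)
    ]
    return {
        "version": version,
        "seed": seed,
        "parameters": dict(params),
        "qc": {
            "n_wells": len(qc_items),
            "n_pass": sum(1 for _, v in qc_items if v.passed),
            "n_fail_by_reason": reasons,
        },
        "clusters": clusters,
        "calls": calls.sort_values("sample_id").to_dict(orient="records"),
        "concordance": concordance_report.to_dict() if concordance_report else None,
    }
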