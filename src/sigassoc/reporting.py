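"""Final association tables and secondary group comparisons.

``build_report`` assembles one row per significant association in the shape
of a publication table: direction of effect, percentage of mutated samples
in the cancer type, the driver's trinucleotide context, how much of the
associated signature falls in that context (its "amount"), and whether that
amount is high (> 5%) or low. ``group_comparison`` runs the driver-mutant vs
wild-type rank/location tests used for exposure and clinical follow-ups.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .association import mann_whitney_u, t_test_unpaired
from .drivers import DriverMutation
from .signatures import SignatureMatrix, channel_amount

__all__ = [
    "build_report",
    "summarize",
    "GroupComparison",
    "group_comparison",
]

REPORT_COLUMNS = [
    "signature",
    "aetiology",
    "gene",
    "coding_change",
    "protein_change",
    "direction",
    "cancer_type",
    "pct_mutated",
    "channel",
    "amount_pct",
    "rank",
    "p_value",
    "odds_ratio",
]


def build_report(
    significant: pd.DataFrame,
    sig_matrix: SignatureMatrix,
    drivers: list[DriverMutation],
    cancer_types: pd.Series,
    aetiology_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Annotate a post-exclusion significant set into the final table.

    ``significant`` needs columns ``cancer_type``, ``driver``, ``signature``,
    ``n_mutant``, ``p_value`` and ``odds_ratio``; ``cancer_types`` maps the
    analysis cohort's samples to types (for the mutated-sample percentage).
    Context amounts come from ``sig_matrix`` — conventionally the
    genome-form (as-published) matrix. Rows are sorted by signature, then by
    descending amount.
    """
    by_key = {d.key: d for d in drivers}
    type_sizes = cancer_types.value_counts()
    aetiology_map = aetiology_map or {}
    rows = []
    for _, assoc in significant.iterrows():
        driver = by_key.get(assoc["driver"])
        if driver is None:
            raise KeyError(f"unknown driver {assoc['driver']!r}")
        if not driver.channel:
            raise ValueError(f"driver {driver.key} has no channel assigned")
        amount, rank = channel_amount(sig_matrix, assoc["signature"], driver.channel)
        rows.append(
            {
                "signature": assoc["signature"],
                "aetiology": aetiology_map.get(assoc["signature"], ""),
                "gene": driver.gene,
                "coding_change": driver.coding_change,
                "protein_change": driver.protein_change,
                "direction": "greater_than_1"
                if assoc["odds_ratio"] > 1
                else "less_than_1",
                "cancer_type": assoc["cancer_type"],
                "pct_mutated": 100.0
                * assoc["n_mutant"]
                / type_sizes[assoc["cancer_type"]],
                "channel": driver.channel,
                "amount_pct": amount,
                "rank": rank,
                "p_value": assoc["p_value"],
                "odds_ratio": assoc["odds_ratio"],
            }
        )
    report = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    if len(report):
        order = {name: i for i, name in enumerate(sig_matrix.signature_names)}
        report = report.sort_values(
            ["signature", "amount_pct"],
            key=lambda col: col.map(order) if col.name == "signature" else -col,
        ).reset_index(drop=True)
    return report


def summarize(report: pd.DataFrame, tests: pd.DataFrame) -> dict[str, int]:
    """Headline counts for a finished analysis.

    ``tests`` is the full table of tested triples; ``report`` the
    post-exclusion significant table.
    """
    return {
        "n_tested": int(len(tests)),
        "n_significant": int(len(report)),
        "n_negative_retained": int((report["direction"] == "less_than_1").sum())
        if len(report)
        else 0,
        "n_cancer_types": int(report["cancer_type"].nunique()) if len(report) else 0,
        "n_signatures": int(report["signature"].nunique()) if len(report) else 0,
        "n_genes": int(report["gene"].nunique()) if len(report) else 0,
    }


@dataclass
class GroupComparison:
    """Driver-mutant vs wild-type comparison of a numeric per-sample value."""

    driver: str
    cancer_type: str
    test: str
    n_mutant: int
    n_wildtype: int
    mutant_median: float
    wildtype_median: float
    mutant_mean: float
    wildtype_mean: float
    statistic: float
    p_value: float


def group_comparison(
    values: pd.Series,
    call_matrix: pd.DataFrame,
    driver: str,
    cancer_type: str,
    cancer_types: pd.Series,
    test: str = "mann_whitney",
    sided: str = "two",
) -> GroupComparison:
    """Compare a per-sample quantity between driver-mutant and wild-type.

    ``values`` may be a signature's exposure proportions or a clinical
    variable (age, pack-years); samples with missing values are dropped.
    ``test`` is ``"mann_whitney"`` (rank-based, with ``sided``) or
    ``"t_test"`` (two-sided pooled-variance).
    """
    idx = cancer_types.index[cancer_types == cancer_type]
    idx = idx.intersection(values.dropna().index)
    calls = call_matrix.loc[idx, driver]
    mutant = values.loc[idx[calls == 1]].to_numpy(dtype=float)
    wildtype = values.loc[idx[calls == 0]].to_numpy(dtype=float)
    if len(mutant) == 0:
        raise ValueError(f"no mutant samples for {driver} in {cancer_type}")
    if len(wildtype) == 0:
        raise ValueError(f"no wild-type samples for {driver} in {cancer_type}")
    if test == "mann_whitney":
        stat, p = mann_whitney_u(mutant, wildtype, sided=sided)
    elif test == "t_test":
        stat, p = t_test_unpaired(mutant, wildtype)
    else:
        raise ValueError(f"unknown test {test!r}")
    return GroupComparison(
        driver=driver,
        cancer_type=cancer_type,
        test=test,
        n_mutant=len(mutant),
        n_wildtype=len(wildtype),
        mutant_median=float(np.median(mutant)),
        wildtype_median=float(np.median(wildtype)),
        mutant_mean=float(mutant.mean()),
        wildtype_mean=float(wildtype.mean()),
        statistic=float(stat),
        p_value=float(p),
    )
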