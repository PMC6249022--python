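"""Permutation-calibrated significance threshold for association testing.

The p-value cutoff for a target false-discovery rate is found by a
randomisation test: within each cancer type, driver presence labels are
shuffled across samples (preserving the mutated-sample count exactly), all
eligible regressions are refit, and the mean number of significant null
associations is compared with the observed number over a descending grid of
candidate thresholds. The selected threshold is the largest candidate whose
estimated FDR (mean null count / observed count) is below target.

Because signature exposures are compositional, a driver positively
associated with one signature tends to show mirror-image negative
associations with the others; those reciprocal negatives are excluded from
both the observed and the null significant counts before the FDR is formed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import child_rng
from .association import eligible_pairs, fit_logistic_batch, run_associations

__all__ = [
    "DEFAULT_THRESHOLDS",
    "FDRCalibration",
    "shuffle_driver",
    "exclude_reciprocal_negatives",
    "calibrate",
]

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = (0.05, 0.02, 0.01, 0.005, 0.004, 0.002, 0.001, 5e-4, 1e-4)


@dataclass
class FDRCalibration:
    """Threshold grid with observed vs permutation-null significant counts.

    ``grid`` has one row per candidate threshold: ``threshold``,
    ``observed_count``, ``null_mean_count`` and ``fdr_estimate`` (capped at
    1; NaN where the observed count is zero). ``selected_threshold`` is the
    largest candidate whose estimate is below ``target_fdr`` (NaN when none
    qualifies). ``null_counts`` keeps the per-iteration null significant
    counts for audit.
    """

    grid: pd.DataFrame
    selected_threshold: float
    n_iterations: int
    seed: int
    target_fdr: float
    observed: pd.DataFrame = field(repr=False)
    null_counts: pd.DataFrame = field(repr=False)

    @property
    def selected(self) -> bool:
        return not np.isnan(self.selected_threshold)

    def to_tsv(self, path) -> None:
        self.grid.to_csv(path, sep="\t", index=False)

    def summary(self) -> str:
        if self.selected:
            row = self.grid.set_index("threshold").loc[self.selected_threshold]
            return (
                f"selected P < {self.selected_threshold:g} "
                f"(observed {int(row['observed_count'])}, "
                f"null mean {row['null_mean_count']:.2f}, "
                f"FDR estimate {row['fdr_estimate']:.3f} "
                f"< target {self.target_fdr:g}; {self.n_iterations} iterations)"
            )
        return (
            f"no threshold reached FDR < {self.target_fdr:g} "
            f"over {self.n_iterations} iterations"
        )


def shuffle_driver(call_column: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Uniform random permutation of one driver column within a cancer type.

    The number of mutated samples is preserved exactly; exposures are never
    touched.
    """
    col = np.asarray(call_column)
    return col[rng.permutation(len(col))]


def exclude_reciprocal_negatives(significant: pd.DataFrame) -> pd.DataFrame:
    """Drop mirror-image negative associations from a significant set.

    An association with odds ratio < 1 is removed when the same
    (cancer type, driver) pair also has a significant association with odds
    ratio > 1 in the input set; negative associations without such a
    positive partner are kept (they are genuine findings, e.g. an
    age-related signature depleted among driver-mutant samples).
    """
    if len(significant) == 0:
        return significant
    pos = significant[significant["odds_ratio"] > 1]
    pos_pairs = set(zip(pos["cancer_type"], pos["driver"]))
    drop = significant.apply(
        lambda r: r["odds_ratio"] < 1
        and (r["cancer_type"], r["driver"]) in pos_pairs,
        axis=1,
    )
    return significant[~drop]


def _counts_after_exclusion(
    p: np.ndarray, b1: np.ndarray, ok: np.ndarray,
    group_ids: np.ndarray, n_groups: int, threshold: float,
) -> np.ndarray:
    """Vectorised significant-count after reciprocal-negative exclusion.

    ``p``, ``b1``, ``ok`` are (n_triples, B) arrays over B replicates;
    ``group_ids`` maps each triple to its (cancer type, driver) group.
    Returns a (B,) count vector.
    """
    sig = ok & (p < threshold)
    pos = sig & (b1 > 0)
    neg = sig & (b1 < 0)
    pos_any = np.zeros((n_groups, sig.shape[1]), dtype=bool)
    np.logical_or.at(pos_any, group_ids, pos)
    keep = sig & ~(neg & pos_any[group_ids])
    return keep.sum(axis=0)


def calibrate(
    call_matrix: pd.DataFrame,
    exposures: pd.DataFrame,
    cancer_types: pd.Series,
    thresholds=DEFAULT_THRESHOLDS,
    n_iter: int = 1000,
    target: float = 0.05,
    seed: int = 0,
    min_mut: int = 10,
    min_sig: int = 10,
    sig_prop: float = 0.20,
) -> FDRCalibration:
    """Run the full randomisation test and select the p-value threshold.

    Per iteration, every driver column is shuffled once within its cancer
    type (stream keyed by ``(seed, iteration, cancer type, driver)``) and
    that shuffle is reused across all signatures tested against the driver.
    Null and observed significant sets both pass through reciprocal-negative
    exclusion before counting; fits that did not converge cleanly are
    excluded from both sides symmetrically.

    Shuffling preserves per-type mutated-sample counts, so the eligible
    triple set is identical on real and null data (asserted).
    """
    thresholds = sorted(set(float(t) for t in thresholds), reverse=True)
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")

    observed = run_associations(
        call_matrix, exposures, cancer_types,
        min_mut=min_mut, min_sig=min_sig, sig_prop=sig_prop,
    )
    n_triples = len(observed)
    group_keys = list(
        dict.fromkeys(zip(observed["cancer_type"], observed["driver"]))
    )
    group_index = {k: g for g, k in enumerate(group_keys)}
    group_ids = np.array(
        [group_index[(c, d)] for c, d in zip(observed["cancer_type"], observed["driver"])],
        dtype=int,
    )

    null_p = np.ones((n_triples, n_iter))
    null_b1 = np.zeros((n_triples, n_iter))
    null_ok = np.zeros((n_triples, n_iter), dtype=bool)

    type_index = {
        ctype: cancer_types.index[cancer_types == ctype]
        for ctype in observed["cancer_type"].unique()
    }
    for ctype, driver in group_keys:
        idx = type_index[ctype]
        y = call_matrix.loc[idx, driver].to_numpy()
        n_t = len(y)
        y_null = np.empty((n_t, n_iter))
        for it in range(n_iter):
            rng = child_rng(seed, "fdr", it, ctype, driver)
            y_null[:, it] = shuffle_driver(y, rng)
        assert (y_null.sum(axis=0) == y.sum()).all(), "shuffle altered mutant count"
        rows = observed.index[
            (observed["cancer_type"] == ctype) & (observed["driver"] == driver)
        ]
        for row in rows:
            x = exposures.loc[idx, observed.loc[row, "signature"]].to_numpy()
            _, b1, _, pv, status = fit_logistic_batch(y_null, x)
            pos = observed.index.get_loc(row)
            null_p[pos] = pv
            null_b1[pos] = b1
            null_ok[pos] = status == "ok"

    # eligibility is a function of column sums and exposures only, both
    # preserved under shuffling — the null eligible set equals the observed
    null_triples = eligible_pairs(
        call_matrix, exposures, cancer_types,
        min_mut=min_mut, min_sig=min_sig, sig_prop=sig_prop,
    )
    assert len(null_triples) == n_triples

    obs_p = observed["p_value"].to_numpy()[:, None]
    obs_b1 = observed["beta1"].to_numpy()[:, None]
    obs_ok = (observed["fit_status"] == "ok").to_numpy()[:, None]

    grid_rows = []
    null_count_cols = {}
    for t in thresholds:
        obs_count = int(
            _counts_after_exclusion(
                obs_p, obs_b1, obs_ok, group_ids, len(group_keys), t
            )[0]
        )
        null_counts = _counts_after_exclusion(
            null_p, null_b1, null_ok, group_ids, len(group_keys), t
        )
        null_mean = float(null_counts.mean())
        fdr = min(null_mean / obs_count, 1.0) if obs_count > 0 else np.nan
        grid_rows.append(
            {
                "threshold": t,
                "observed_count": obs_count,
                "null_mean_count": null_mean,
                "fdr_estimate": fdr,
            }
        )
        null_count_cols[t] = null_counts

    grid = pd.DataFrame(grid_rows)
    qualifying = grid[grid["fdr_estimate"] < target]
    if len(qualifying):
        selected = float(qualifying["threshold"].max())
    else:
        selected = float("nan")
        logger.warning(
            "no candidate threshold achieves FDR < %g; report NA", target
        )
    null_df = pd.DataFrame(null_count_cols)
    null_df.index.name = "iteration"
    return FDRCalibration(
        grid=grid,
        selected_threshold=selected,
        n_iterations=n_iter,
        seed=seed,
        target_fdr=target,
        observed=observed,
        null_counts=null_df,
    )
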