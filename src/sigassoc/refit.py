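"""Refitting sample catalogs against a fixed signature matrix.

Given a sample's 96-channel counts ``n`` and a row-stochastic signature
matrix ``P`` (S × 96), the exposure vector ``e`` on the S-simplex is
estimated by maximising the multinomial log-likelihood

    L(e) = sum_c n_c * log( sum_s e_s * P_sc )

with an expectation–maximisation iteration. EM for this mixture model is
monotone (the log-likelihood never decreases) and, started from the uniform
vector, deterministic — so the fit is reproducible without MCMC. A
non-negative-least-squares backend on channel proportions is provided as an
independent second fitter for cross-backend checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .catalog import CatalogSet
from .signatures import SignatureMatrix

__all__ = [
    "ExposureVector",
    "fit_exposures",
    "fit_cohort_exposures",
    "nnls_exposures",
    "signature_presence",
]

#: exposures below this are reported as exactly 0 (vector renormalised)
ZERO_CLIP = 1e-6


@dataclass
class ExposureVector:
    """Fitted signature exposures for one sample.

    ``exposures`` lies on the simplex: non-negative, summing to 1.
    """

    sample_id: str
    signature_names: list[str]
    exposures: np.ndarray
    log_likelihood: float
    n_iterations: int
    converged: bool

    def __post_init__(self) -> None:
        self.exposures = np.asarray(self.exposures, dtype=float)
        if self.exposures.shape != (len(self.signature_names),):
            raise ValueError("one exposure per signature required")
        if (self.exposures < 0).any() or abs(self.exposures.sum() - 1) > 1e-8:
            raise ValueError("exposures must lie on the probability simplex")

    def __getitem__(self, signature: str) -> float:
        try:
            return float(self.exposures[self.signature_names.index(signature)])
        except ValueError:
            raise KeyError(f"unknown signature {signature!r}") from None


def _em(
    counts: np.ndarray, probs: np.ndarray, tol: float, max_iter: int
) -> tuple[np.ndarray, float, int, bool]:
    """EM ascent of the multinomial mixture likelihood from a uniform start."""
    n = counts.astype(float)
    total = n.sum()
    active = n > 0
    n_act = n[active]
    p_act = probs[:, active]  # S x C'
    if (p_act.sum(axis=0) == 0).any():
        bad = np.where(active)[0][p_act.sum(axis=0) == 0]
        raise ValueError(
            f"observed counts in channels unreachable by any signature: {bad.tolist()}"
        )
    S = probs.shape[0]
    e = np.full(S, 1.0 / S)
    ll_old = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        mix = e @ p_act  # C'
        ll = float(n_act @ np.log(mix))
        # responsibility-weighted counts, normalised by the total burden
        e = e * ((p_act / mix[None, :]) @ n_act) / total
        e /= e.sum()  # guard float drift off the simplex
        if ll - ll_old < tol and it > 1:
            converged = True
            ll_old = ll
            break
        ll_old = ll
    return e, ll_old, it, converged


def fit_exposures(
    counts,
    sig: SignatureMatrix,
    sample_id: str = "",
    tol: float = 1e-8,
    max_iter: int = 10_000,
) -> ExposureVector:
    """Maximum-likelihood signature exposures for one 96-channel catalog.

    Parameters
    ----------
    counts : array-like of 96 non-negative ints
        The sample's channel counts; the total must be at least 1.
    sig : SignatureMatrix
        Row-stochastic S × 96 matrix (typically exome-normalised).
    tol : float
        Convergence threshold on the per-iteration log-likelihood gain.

    Fitted exposures below ``1e-6`` are truncated to exactly 0 and the
    vector renormalised, so downstream presence thresholds are stable.
    """
    counts = np.asarray(counts)
    if counts.shape != (sig.probs.shape[1],):
        raise ValueError(f"expected 96 channel counts, got shape {counts.shape}")
    if (counts < 0).any():
        raise ValueError("channel counts must be non-negative")
    if counts.sum() < 1:
        raise ValueError("catalog has no SNVs; sample should have been filtered")
    e, ll, n_iter, converged = _em(counts, sig.probs, tol, max_iter)
    e = np.where(e < ZERO_CLIP, 0.0, e)
    e /= e.sum()
    return ExposureVector(
        sample_id=sample_id,
        signature_names=list(sig.signature_names),
        exposures=e,
        log_likelihood=ll,
        n_iterations=n_iter,
        converged=converged,
    )


def fit_cohort_exposures(
    catalogs: CatalogSet,
    sig: SignatureMatrix,
    tol: float = 1e-8,
    max_iter: int = 10_000,
) -> pd.DataFrame:
    """Exposure proportions for every sample in a catalog set.

    Returns a samples × signatures DataFrame of proportions (rows sum to 1),
    aligned with ``catalogs.meta``.
    """
    rows = np.empty((len(catalogs.sample_ids), sig.n_signatures))
    for i, sid in enumerate(catalogs.sample_ids):
        fit = fit_exposures(
            catalogs.counts.loc[sid].to_numpy(), sig, sample_id=sid,
            tol=tol, max_iter=max_iter,
        )
        rows[i] = fit.exposures
    return pd.DataFrame(
        rows, index=catalogs.sample_ids, columns=list(sig.signature_names)
    )


def nnls_exposures(counts, sig: SignatureMatrix) -> np.ndarray:
    """Second fitting backend: NNLS on channel proportions, renormalised.

    Independent of the EM route; used for cross-backend correlation checks.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.sum() < 1:
        raise ValueError("catalog has no SNVs")
    target = counts / counts.sum()
    coef, _ = nnls(sig.probs.T, target)
    if coef.sum() == 0:
        raise ValueError("NNLS returned the zero vector")
    return coef / coef.sum()


def signature_presence(
    exposures, signature: str, threshold: float, strict: bool = True
) -> bool:
    """Whether a signature's exposure clears a proportion threshold.

    Descriptive presence uses the strict rule (exposure > threshold, e.g.
    > 0.05 of the mutational load); eligibility counting for association
    testing uses the non-strict rule (exposure ≥ 0.20) via ``strict=False``.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    if isinstance(exposures, ExposureVector):
        value = exposures[signature]
    else:
        value = float(exposures[signature])
    return value > threshold if strict else value >= threshold
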