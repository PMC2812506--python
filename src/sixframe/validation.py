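"""Spectral validation by common-ion counting against synthetic-peptide
spectra, with an empirical resampling null and FDR thresholding.

If a candidate peptide assignment is correct, a synthetic peptide of the
same sequence fragmented under the same conditions should share most of its
ions with the experimental spectrum.  The score is the number of common
ions between the two peak lists after removing the low-mass region
(reporter/immonium/ammonium ions, m/z <= 160 by default).  Significance is
assessed against a null built from unrelated spectra drawn without
replacement and scored against the same synthetic references; the FDR at a
score threshold is the two-sample tail ratio (null tail fraction over real
tail fraction), made monotone by a cumulative minimum over ascending
scores.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from sixframe._matching import max_common_count
from sixframe.search import Spectrum

DEFAULT_MIN_MZ = 160.0
DEFAULT_TOL = 0.2


def common_ion_score(
    query: Spectrum,
    reference: Spectrum,
    min_mz: float = DEFAULT_MIN_MZ,
    tol: float = DEFAULT_TOL,
) -> int:
    """Number of common ions between two spectra.

    Both peak lists are filtered to m/z > ``min_mz`` and paired one-to-one
    within ``tol`` Th (maximum matching); the score is symmetric and
    intensity-free.
    """
    q = query.mz[query.mz > min_mz]
    r = reference.mz[reference.mz > min_mz]
    return max_common_count(q, r, tol)


@dataclass
class NullDistribution:
    """Scores of randomly drawn unrelated spectra against the references."""

    scores: np.ndarray
    n_reps: int
    set_size: int
    seed: int

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)


def build_null(
    pool: Sequence[Spectrum],
    references: Sequence[Spectrum],
    n_reps: int = 7000,
    set_size: int = 10,
    seed: int = 0,
    min_mz: float = DEFAULT_MIN_MZ,
    tol: float = DEFAULT_TOL,
) -> NullDistribution:
    """Score ``n_reps`` draws of ``set_size`` pool spectra (without
    replacement across all repetitions) against every reference spectrum.

    Deterministic given ``seed``; raises when the pool cannot supply
    ``n_reps * set_size`` distinct spectra.
    """
    needed = n_reps * set_size
    if needed > len(pool):
        raise ValueError(
            f"pool exhausted: {needed} spectra required for {n_reps} draws of "
            f"{set_size} without replacement, pool has {len(pool)}"
        )
    if not references:
        raise ValueError("references must be non-empty")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(pool), size=needed, replace=False)
    ref_filtered = [r.mz[r.mz > min_mz] for r in references]
    scores = np.empty(needed * len(references))
    k = 0
    for idx in chosen:
        q = pool[idx].mz[pool[idx].mz > min_mz]
        for r in ref_filtered:
            scores[k] = max_common_count(q, r, tol)
            k += 1
    return NullDistribution(scores=scores, n_reps=n_reps, set_size=set_size, seed=seed)


@dataclass
class FdrCurve:
    """Empirical FDR as a function of the common-ion score threshold."""

    scores: np.ndarray  # ascending unique candidate thresholds
    fdr_percent: np.ndarray  # monotone non-increasing, capped at 100

    def fdr_at(self, score: float) -> float:
        """FDR% at the largest tabulated threshold <= ``score``."""
        idx = np.searchsorted(self.scores, score, side="right") - 1
        if idx < 0:
            return 100.0
        return float(self.fdr_percent[idx])

    def threshold_at(self, target_fdr: float) -> float:
        """Smallest score whose FDR% is <= ``target_fdr``."""
        ok = np.nonzero(self.fdr_percent <= target_fdr)[0]
        if ok.size == 0:
            raise ValueError(
                f"target FDR {target_fdr}% unattainable; minimum achievable is "
                f"{float(self.fdr_percent.min()):.4g}%"
            )
        return float(self.scores[ok[0]])


def empirical_fdr(
    real_scores: Sequence[float], null: NullDistribution | Sequence[float]
) -> FdrCurve:
    """Two-sample tail-ratio FDR curve.

    At threshold s, FDR% = 100 * P(null >= s) / P(real >= s), capped at
    100, evaluated at every observed real score and smoothed by a
    cumulative minimum over ascending thresholds so the curve never rises
    with the score.
    """
    real = np.sort(np.asarray(real_scores, dtype=float))
    null_scores = np.sort(
        np.asarray(null.scores if isinstance(null, NullDistribution) else null, dtype=float)
    )
    if real.size == 0 or null_scores.size == 0:
        raise ValueError("both score sets must be non-empty")
    grid = np.unique(real)
    n_null = null_scores.size
    n_real = real.size
    null_tail = n_null - np.searchsorted(null_scores, grid, side="left")
    real_tail = n_real - np.searchsorted(real, grid, side="left")
    raw = np.minimum(100.0, 100.0 * (null_tail / n_null) / (real_tail / n_real))
    # running minimum over ascending thresholds (q-value style): raising the
    # threshold can never raise the reported FDR
    smooth = np.minimum.accumulate(raw)
    return FdrCurve(scores=grid, fdr_percent=smooth)
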