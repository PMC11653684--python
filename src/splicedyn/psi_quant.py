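"""PSI computation, missing-value imputation and the four-rule event filter.

PSI is the plain junction-count ratio L / (L + S); cells with no junction
support are missing.  Filtering keeps an event only if

  1. its average PSI lies within [0.05, 0.95] (on the imputed matrix),
  2. its average total junction support (L + S) is >= 10,
  3. fewer than 5 samples were missing before imputation, and
  4. its PSI range (max - min) exceeds 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import JunctionCountMatrix, SampleMetadata, SpliceEvent


@dataclass
class PsiMatrix:
    """PSI per event x sample with missingness mask and retained counts."""

    events: list[SpliceEvent]
    sample_ids: list[str]
    psi: np.ndarray  # float, NaN where missing (pre-imputation)
    missing_mask: np.ndarray  # bool; True where the input cell was missing
    L: np.ndarray | None = None
    S: np.ndarray | None = None
    metadata: list[SampleMetadata] | None = None

    def __post_init__(self) -> None:
        shape = (len(self.events), len(self.sample_ids))
        if self.psi.shape != shape or self.missing_mask.shape != shape:
            raise ValueError(f"psi/missing_mask must have shape {shape}")
        defined = ~np.isnan(self.psi)
        if np.any((self.psi[defined] < 0) | (self.psi[defined] > 1)):
            raise ValueError("PSI values must lie in [0, 1]")
        if self.metadata is not None:
            ids = [m.sample_id for m in self.metadata]
            if ids != list(self.sample_ids):
                raise ValueError("metadata sample order does not match matrix")

    @property
    def event_ids(self) -> list[str]:
        return [e.event_id for e in self.events]

    def take(self, indices: Sequence[int]) -> "PsiMatrix":
        idx = np.asarray(indices, dtype=int)
        return PsiMatrix(
            events=[self.events[i] for i in idx],
            sample_ids=list(self.sample_ids),
            psi=self.psi[idx].copy(),
            missing_mask=self.missing_mask[idx].copy(),
            L=None if self.L is None else self.L[idx].copy(),
            S=None if self.S is None else self.S[idx].copy(),
            metadata=self.metadata,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.psi, index=self.event_ids, columns=self.sample_ids)


@dataclass(frozen=True)
class FilterCriteria:
    """Default thresholds of the four-rule event filter."""

    psi_mean_low: float = 0.05
    psi_mean_high: float = 0.95
    min_mean_total: float = 10.0
    max_missing_samples: int = 5  # strict: missing count must be < this
    min_psi_range: float = 0.05

    def __post_init__(self) -> None:
        if not 0 <= self.psi_mean_low < self.psi_mean_high <= 1:
            raise ValueError("require 0 <= psi_mean_low < psi_mean_high <= 1")


def compute_psi(
    counts: JunctionCountMatrix,
    metadata: list[SampleMetadata] | None = None,
    normalize_lengths: bool = False,
) -> PsiMatrix:
    """PSI = L / (L + S); cells with L + S = 0 are missing.

    With ``normalize_lengths`` the counts are first divided by the
    effective form lengths carried by a jcec-dialect table.
    """
    L = counts.inclusion.astype(float)
    S = counts.skipping.astype(float)
    if normalize_lengths:
        if counts.inc_form_len is None or counts.skip_form_len is None:
            raise ValueError("length normalisation requested but no form lengths present")
        L = L / counts.inc_form_len[:, None]
        S = S / counts.skip_form_len[:, None]
    total = L + S
    missing = total == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        psi = np.where(missing, np.nan, L / np.where(missing, 1.0, total))
    return PsiMatrix(
        events=list(counts.events),
        sample_ids=list(counts.sample_ids),
        psi=psi,
        missing_mask=missing,
        L=counts.inclusion.copy(),
        S=counts.skipping.copy(),
        metadata=metadata,
    )


def impute_missing(
    psi_matrix: PsiMatrix,
    method: str = "knn",
    seed: int = 0,
    n_neighbors: int = 10,
) -> PsiMatrix:
    """Impute missing PSI cells; observed cells are preserved bit-exactly.

    ``knn`` (default) imputes each missing cell from the k nearest event
    rows (Euclidean over shared samples); ``iterative_forest`` runs a
    seeded iterative random-forest imputer in the spirit of missForest.
    """
    if method not in ("knn", "iterative_forest"):
        raise ValueError(f"unknown imputation method {method!r}")
    psi = psi_matrix.psi
    missing = np.isnan(psi)
    n_obs_per_event = (~missing).sum(axis=1)
    bad = n_obs_per_event < 2
    if bad.any():
        ids = [psi_matrix.event_ids[i] for i in np.flatnonzero(bad)]
        raise ValueError(f"events with fewer than 2 observed PSI values: {ids}")
    if not missing.any():
        return psi_matrix

    if method == "knn":
        from sklearn.impute import KNNImputer

        imputer = KNNImputer(n_neighbors=min(n_neighbors, max(len(psi_matrix.events) - 1, 1)))
        filled = imputer.fit_transform(psi)
    elif method == "iterative_forest":
        from sklearn.ensemble import ExtraTreesRegressor
        from sklearn.experimental import enable_iterative_imputer  # noqa: F401
        from sklearn.impute import IterativeImputer

        estimator = ExtraTreesRegressor(n_estimators=30, random_state=seed, n_jobs=1)
        imputer = IterativeImputer(
            estimator=estimator, random_state=seed, max_iter=5, sample_posterior=False
        )
        filled = imputer.fit_transform(psi)
    else:
        raise ValueError(f"unknown imputation method {method!r}")

    if filled.shape != psi.shape:  # a fully-missing sample column was dropped
        raise ValueError("imputer dropped columns; a sample has no observed values")
    filled = np.clip(filled, 0.0, 1.0)
    filled[~missing] = psi[~missing]  # observed cells bit-exact
    return replace(psi_matrix, psi=filled, missing_mask=psi_matrix.missing_mask.copy())


RULE_NAMES = ("mean_psi_band", "mean_total_count", "missing_samples", "psi_range")


def filter_events(
    psi_matrix: PsiMatrix,
    criteria: FilterCriteria = FilterCriteria(),
) -> tuple[PsiMatrix, pd.DataFrame]:
    """Apply the four event filters; imputation must already have run.

    Rules 1 and 4 are evaluated on the imputed PSI matrix, rule 2 on the
    retained raw counts, rule 3 on the pre-imputation missingness mask.
    Returns the surviving subset plus a per-event report naming the rule(s)
    each removed event failed.
    """
    psi = psi_matrix.psi
    if np.isnan(psi).any():
        raise ValueError("filter_events expects an imputed (complete) PSI matrix")
    if psi_matrix.L is None or psi_matrix.S is None:
        raise ValueError("mean-total-count filter requires retained junction counts")

    mean_psi = psi.mean(axis=1)
    pass_band = (mean_psi >= criteria.psi_mean_low) & (mean_psi <= criteria.psi_mean_high)
    mean_total = (psi_matrix.L + psi_matrix.S).mean(axis=1)
    pass_total = mean_total >= criteria.min_mean_total
    n_missing = psi_matrix.missing_mask.sum(axis=1)
    pass_missing = n_missing < criteria.max_missing_samples
    psi_range = psi.max(axis=1) - psi.min(axis=1)
    pass_range = psi_range > criteria.min_psi_range

    passed = pass_band & pass_total & pass_missing & pass_range
    failed_rules = []
    for i in range(len(psi_matrix.events)):
        failures = [
            name
            for name, ok in zip(
                RULE_NAMES, (pass_band[i], pass_total[i], pass_missing[i], pass_range[i])
            )
            if not ok
        ]
        failed_rules.append(",".join(failures))
    report = pd.DataFrame(
        {
            "event_id": psi_matrix.event_ids,
            "mean_psi": mean_psi,
            "mean_total": mean_total,
            "n_missing": n_missing,
            "psi_range": psi_range,
            "passed": passed,
            "failed_rules": failed_rules,
        }
    )
    surviving = psi_matrix.take(np.flatnonzero(passed))
    return surviving, report
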