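"""Two-group differential splicing calls and cross-species conservation.

The group comparison reuses the quasi-binomial GLM machinery: a single
group indicator versus an intercept-only null, quasi-likelihood F-test,
then |deltaPSI| > 0.1 and BH FDR < 0.05 to call events.  deltaPSI is
mean(group_b) - mean(group_a), i.e. DM minus GM with the defaults, so
"up" means more inclusion upon differentiation.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .developmental_dynamics import _evidence_weights, fit_quasibinomial_glm, quasi_f_test


def test_two_group(
    psi_matrix,
    group_labels: Sequence[str] | None = None,
    group_a: str = "GM",
    group_b: str = "DM",
) -> pd.DataFrame:
    """Per-event deltaPSI, quasi-likelihood F statistic and p-value."""
    if group_labels is None:
        if psi_matrix.metadata is None:
            raise ValueError("no group labels given and matrix carries no metadata")
        group_labels = [m.group for m in psi_matrix.metadata]
    labels = np.asarray(group_labels)
    if labels.size != len(psi_matrix.sample_ids):
        raise ValueError("group label vector length does not match sample count")
    in_a = labels == group_a
    in_b = labels == group_b
    if in_a.sum() < 2 or in_b.sum() < 2:
        raise ValueError(
            f"need >= 2 samples per group, got {int(in_a.sum())} {group_a!r} "
            f"and {int(in_b.sum())} {group_b!r}"
        )
    keep = in_a | in_b
    indicator = in_b[keep].astype(float)
    design_full = np.column_stack([np.ones(keep.sum()), indicator])
    design_null = np.ones((int(keep.sum()), 1))
    weights = _evidence_weights(psi_matrix)

    rows = []
    for i, event_id in enumerate(psi_matrix.event_ids):
        y = psi_matrix.psi[i][keep]
        w = weights[i][keep]
        delta = float(y[indicator == 1].mean() - y[indicator == 0].mean())
        if np.ptp(y) == 0.0:
            rows.append(dict(event_id=event_id, delta_psi=delta,
                             statistic=0.0, pvalue=1.0))
            continue
        null_fit = fit_quasibinomial_glm(y, design_null, w)
        full_fit = fit_quasibinomial_glm(y, design_full, w)
        if not (null_fit.converged and full_fit.converged):
            rows.append(dict(event_id=event_id, delta_psi=delta,
                             statistic=np.nan, pvalue=np.nan))
            continue
        f_stat, _, _, pvalue = quasi_f_test(null_fit, full_fit)
        rows.append(dict(event_id=event_id, delta_psi=delta,
                         statistic=f_stat, pvalue=pvalue))
    return pd.DataFrame(rows)


def benjamini_hochberg(pvalues) -> np.ndarray:
    """Step-up Benjamini-Hochberg adjusted p-values, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be a 1-d vector")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.empty(m)
    adjusted[order] = np.minimum(adjusted_sorted, 1.0)
    return adjusted


def call_dases(
    results: pd.DataFrame,
    delta_threshold: float = 0.1,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Apply |deltaPSI| > 0.1 and FDR < 0.05 (defaults) to the test output."""
    out = results.copy()
    if "fdr" not in out.columns:
        fdr = np.full(len(out), np.nan)
        tested = out["pvalue"].notna().to_numpy()
        if tested.any():
            fdr[tested] = benjamini_hochberg(out.loc[tested, "pvalue"].to_numpy())
        out["fdr"] = fdr
    out["is_dase"] = (
        out["fdr"].notna()
        & (out["fdr"] < fdr_threshold)
        & (out["delta_psi"].abs() > delta_threshold)
    )
    out["call"] = out["is_dase"]
    out["direction"] = np.where(
        ~out["is_dase"], "none", np.where(out["delta_psi"] > 0, "up", "down")
    )
    return out


@dataclass
class ConservedSummary:
    """Ortholog-exon keys called in at least ``min_species`` species."""

    conserved: set[str]
    per_combination: Counter

    @property
    def n_conserved(self) -> int:
        return len(self.conserved)


def count_conserved(
    dase_tables: Mapping[str, pd.DataFrame],
    min_species: int = 2,
    key_column: str = "ortholog_key",
    call_column: str = "is_dase",
) -> ConservedSummary:
    """Count ortholog-exon keys called differential in >= min_species tables.

    Each per-species table maps its events onto shared ortholog-exon keys
    (user-supplied mapping); duplicate keys within one species are an error.
    """
    called_in: dict[str, set[str]] = {}
    for species, table in dase_tables.items():
        keys = table[key_column]
        if keys.duplicated().any():
            dupes = keys[keys.duplicated()].tolist()
            raise ValueError(f"{species}: duplicate ortholog keys {dupes}")
        for key in table.loc[table[call_column].astype(bool), key_column]:
            called_in.setdefault(key, set()).add(species)
    conserved = {k for k, sp in called_in.items() if len(sp) >= min_species}
    combos = Counter(
        tuple(sorted(sp)) for k, sp in called_in.items() if k in conserved
    )
    return ConservedSummary(conserved=conserved, per_combination=combos)
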