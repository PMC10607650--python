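"""Condition contrasts: per-acid delta matrices, per-organism normalized
matrices, Welch significance tests from replicate summaries, and a
per-organism membrane-adaptation classification.

The central contrast is CO₂-enriched growth versus the same-temperature
control (``co2_10C`` vs ``control_10C``); the temperature contrast
(``control_25C`` vs ``control_10C``) is built the same way.  A fatty acid
that is undetected or below the reporting threshold in *both* conditions
carries no information about remodeling and is marked not-applicable; a
trace-to-quantified transition is a real change and stays applicable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .fa_core import MeltingPointTable, sort_key
from .profiles import (
    CensorPolicy,
    ProfileSet,
    ReplicateProfile,
    degree_of_unsaturation,
    wamt,
)

__all__ = [
    "DeltaMatrix",
    "AdaptationSummary",
    "delta_matrix",
    "normalize_deltas",
    "replicate_test",
    "adaptation_summary",
]

logger = logging.getLogger(__name__)


@dataclass
class DeltaMatrix:
    """Organisms × fatty-acids matrix of condition differences in
    percentage points (``NaN`` = not applicable), with its contrast
    ``(condition_a, condition_b)``; positive cells mean the acid is more
    abundant under ``condition_a``."""

    data: pd.DataFrame
    contrast: tuple[str, str]
    normalized: bool = False

    def to_csv(self, path) -> None:
        self.data.to_csv(path, na_rep="NA")

    def to_long(self) -> pd.DataFrame:
        long = self.data.reset_index(names="organism").melt(
            id_vars="organism", var_name="fatty_acid", value_name="delta"
        )
        long["applicable"] = long["delta"].notna()
        return long


def _applicable(cell_a, cell_b) -> bool:
    return cell_a.kind == "quantified" or cell_b.kind == "quantified"


def delta_matrix(
    profile_set: ProfileSet,
    contrast: tuple[str, str],
    censor_policy: CensorPolicy = "zero",
) -> DeltaMatrix:
    """Mean-percentage differences ``condition_a − condition_b`` per
    organism and fatty acid.

    Organisms missing either condition are dropped with a logged warning.
    Columns are ordered by chain length then double-bond count.  A cell is
    NaN (not applicable) when the acid is undetected or censored in both
    conditions.
    """
    cond_a, cond_b = contrast
    known = set(profile_set.conditions())
    for cond in contrast:
        if cond not in known:
            raise ValueError(
                f"unknown condition {cond!r}; available: {sorted(known)}"
            )
    acids = profile_set.fatty_acids()
    rows: dict[str, list[float]] = {}
    for organism in profile_set.organisms():
        if (organism, cond_a) not in profile_set or (
            organism,
            cond_b,
        ) not in profile_set:
            logger.warning(
                "dropping %s: missing one of contrast conditions %s", organism, contrast
            )
            continue
        prof_a = profile_set.get(organism, cond_a)
        prof_b = profile_set.get(organism, cond_b)
        row = []
        for acid in acids:
            cell_a = prof_a.components.get(acid)
            cell_b = prof_b.components.get(acid)
            if cell_a is None and cell_b is None:
                row.append(np.nan)
                continue
            from .profiles import not_detected

            cell_a = cell_a or not_detected()
            cell_b = cell_b or not_detected()
            if not _applicable(cell_a, cell_b):
                row.append(np.nan)
            else:
                row.append(
                    cell_a.resolved(censor_policy) - cell_b.resolved(censor_policy)
                )
        rows[organism] = row
    data = pd.DataFrame.from_dict(rows, orient="index", columns=acids)
    data.index.name = "organism"
    return DeltaMatrix(data=data, contrast=contrast, normalized=False)


def normalize_deltas(matrix: DeltaMatrix, method: str = "max-abs") -> DeltaMatrix:
    """Per-organism normalization so changes are displayed on a common
    scale row by row.

    ``"max-abs"`` (default) divides each row by its maximum absolute
    applicable delta, so every non-degenerate row spans [-1, 1] with at
    least one cell at ±1.  ``"zscore"`` centers and scales each row by its
    mean and standard deviation instead.  All-zero rows and NaN cells are
    left unchanged.  Idempotent for ``"max-abs"``.
    """
    if matrix.normalized and method == "max-abs":
        return DeltaMatrix(matrix.data.copy(), matrix.contrast, True)
    data = matrix.data.copy()
    for organism, row in data.iterrows():
        if method == "max-abs":
            scale = row.abs().max(skipna=True)
            if pd.notna(scale) and scale > 0:
                data.loc[organism] = row / scale
        elif method == "zscore":
            sd = row.std(skipna=True)
            if pd.notna(sd) and sd > 0:
                data.loc[organism] = (row - row.mean(skipna=True)) / sd
        else:
            raise ValueError(f"unknown normalization method {method!r}")
    return DeltaMatrix(data=data, contrast=matrix.contrast, normalized=True)


def replicate_test(
    cell_a: tuple[float, float, int], cell_b: tuple[float, float, int]
) -> float:
    """Two-sided Welch (unequal-variance) t-test from summary statistics.

    Parameters are ``(mean, sd, n)`` triples with ``n ≥ 2`` and at least
    one ``sd > 0``; the return value is the two-sided p-value in (0, 1].
    """
    mean_a, sd_a, n_a = cell_a
    mean_b, sd_b, n_b = cell_b
    if n_a < 2 or n_b < 2:
        raise ValueError(f"need n >= 2 per group, got n_a={n_a}, n_b={n_b}")
    if sd_a < 0 or sd_b < 0:
        raise ValueError("standard deviations must be >= 0")
    if sd_a == 0 and sd_b == 0:
        raise ValueError("degenerate groups: both standard deviations are zero")
    result = sps.ttest_ind_from_stats(
        mean_a, sd_a, n_a, mean_b, sd_b, n_b, equal_var=False
    )
    return float(result.pvalue)


@dataclass
class AdaptationSummary:
    """Per-organism classification of membrane remodeling under a contrast.

    ``table`` has one row per organism with the DU change, the WAMT change
    in °C and its direction label (``fluidization`` when WAMT drops by more
    than ``tolerance``, ``solidification`` when it rises by more, else
    ``unchanged``).  ``acid_pvalues`` lists per-acid Welch p-values for
    acids quantified in both conditions.
    """

    contrast: tuple[str, str]
    table: pd.DataFrame
    acid_pvalues: pd.DataFrame
    alpha: float = 0.05
    tolerance: float = 0.05

    def significant_acids(self, organism: str) -> list[tuple[str, float]]:
        sub = self.acid_pvalues
        sel = sub[(sub["organism"] == organism) & (sub["p_value"] < self.alpha)]
        return list(zip(sel["fatty_acid"], sel["p_value"]))


def _direction(delta_wamt: float, tolerance: float) -> str:
    if delta_wamt < -tolerance:
        return "fluidization"
    if delta_wamt > tolerance:
        return "solidification"
    return "unchanged"


def adaptation_summary(
    profile_set: ProfileSet,
    table: MeltingPointTable,
    contrast: tuple[str, str] = ("co2_10C", "control_10C"),
    censor_policy: CensorPolicy = "zero",
    alpha: float = 0.05,
    tolerance: float = 0.05,
    correction: str | None = None,
) -> AdaptationSummary:
    """DU/WAMT changes and per-acid significance for every organism with
    both contrast conditions.

    Per-acid p-values are uncorrected Welch tests by default, matching the
    per-acid significance reporting convention of FAME studies;
    ``correction="benjamini-hochberg"`` applies a per-organism BH
    adjustment instead.
    """
    cond_a, cond_b = contrast
    rows = []
    pvals = []
    for organism in profile_set.organisms():
        if (organism, cond_a) not in profile_set or (
            organism,
            cond_b,
        ) not in profile_set:
            continue
        prof_a = profile_set.get(organism, cond_a)
        prof_b = profile_set.get(organism, cond_b)
        du_a = degree_of_unsaturation(prof_a, censor_policy)
        du_b = degree_of_unsaturation(prof_b, censor_policy)
        wamt_a, _ = wamt(prof_a, table, censor_policy)
        wamt_b, _ = wamt(prof_b, table, censor_policy)
        delta_wamt = wamt_a - wamt_b
        rows.append(
            {
                "organism": organism,
                "delta_du": du_a - du_b,
                "delta_wamt": delta_wamt,
                "direction": _direction(delta_wamt, tolerance),
            }
        )
        org_pvals = []
        for acid in sorted(
            set(prof_a.components) & set(prof_b.components), key=sort_key
        ):
            cell_a = prof_a.components[acid]
            cell_b = prof_b.components[acid]
            if cell_a.kind != "quantified" or cell_b.kind != "quantified":
                continue
            if cell_a.sd is None or cell_b.sd is None:
                continue
            if cell_a.sd == 0 and cell_b.sd == 0:
                continue
            p = replicate_test(
                (cell_a.mean, cell_a.sd, prof_a.n_replicates),
                (cell_b.mean, cell_b.sd, prof_b.n_replicates),
            )
            org_pvals.append(
                {
                    "organism": organism,
                    "fatty_acid": acid,
                    "delta": cell_a.mean - cell_b.mean,
                    "p_value": p,
                }
            )
        if correction == "benjamini-hochberg" and org_pvals:
            raw = np.array([r["p_value"] for r in org_pvals])
            order = np.argsort(raw)
            m = len(raw)
            adj = np.empty(m)
            adj[order] = np.minimum.accumulate(
                (raw[order] * m / np.arange(1, m + 1))[::-1]
            )[::-1]
            for r, a in zip(org_pvals, np.minimum(adj, 1.0)):
                r["p_value"] = float(a)
        elif correction not in (None, "benjamini-hochberg"):
            raise ValueError(f"unknown correction {correction!r}")
        pvals.extend(org_pvals)
    summary = pd.DataFrame(
        rows, columns=["organism", "delta_du", "delta_wamt", "direction"]
    )
    pval_df = pd.DataFrame(
        pvals, columns=["organism", "fatty_acid", "delta", "p_value"]
    )
    summary["n_significant_acids"] = summary["organism"].map(
        pval_df[pval_df["p_value"] < alpha].groupby("organism").size()
    ).fillna(0).astype(int) if len(summary) else pd.Series(dtype=int)
    return AdaptationSummary(
        contrast=contrast,
        table=summary,
        acid_pvalues=pval_df,
        alpha=alpha,
        tolerance=tolerance,
    )


def heatmap(
    matrix: DeltaMatrix,
    path=None,
    ax=None,
    cmap: str = "RdYlGn",
):  # pragma: no cover - plotting convenience
    """Render a delta matrix as the conventional green-positive /
    red-negative heatmap with grey not-applicable cells."""
    import matplotlib

    if path is not None:
        matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = matrix.data
    if ax is None:
        _, ax = plt.subplots(
            figsize=(0.6 * len(data.columns) + 2, 0.35 * len(data) + 1.5)
        )
    vmax = np.nanmax(np.abs(data.to_numpy())) or 1.0
    cm = plt.get_cmap(cmap).copy()
    cm.set_bad(color="0.8")
    im = ax.imshow(data.to_numpy(), cmap=cm, vmin=-vmax, vmax=vmax, aspect="auto")
    ax.set_xticks(range(len(data.columns)), data.columns, rotation=90)
    ax.set_yticks(range(len(data.index)), data.index)
    label = "normalized change" if matrix.normalized else "change (percentage points)"
    ax.figure.colorbar(im, ax=ax, label=label)
    ax.set_title(f"{matrix.contrast[0]} vs {matrix.contrast[1]}")
    ax.figure.tight_layout()
    if path is not None:
        ax.figure.savefig(path, dpi=150)
        plt.close(ax.figure)
    return ax
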