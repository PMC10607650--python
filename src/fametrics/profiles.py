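"""Replicate fatty-acid composition profiles and their derived statistics.

A profile is one organism grown under one condition, described as the mean
percentage of total peak area (± standard deviation over biological
replicates) of each detected fatty acid.  GC reports routinely censor small
signals, so a cell can also be ``"<1"`` (detected below the 1% reporting
threshold) or ``"nd"`` (not detected); both resolve to configurable
percentages before any statistic is computed.

Two derived statistics summarize membrane physical state:

* **DU** — degree of unsaturation, the composition-weighted mean number of
  C=C double bonds per fatty acid::

      DU = 1·%monoenes/100 + 2·%dienes/100 + 3·%trienes/100 (+ k·%k-enes/100)

  Percentages enter as printed (% of total area); no renormalization.

* **WAMT** — weighted average melting temperature in °C, the
  composition-weighted mean of the pure-compound melting points of the
  acids, renormalized over the acids covered by the melting-point table.
  The fraction of quantified mass that was covered is reported as
  ``wamt_coverage``.  A lower WAMT indicates a more fluid membrane.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Literal

import numpy as np
import pandas as pd

from .fa_core import (
    FattyAcid,
    MeltingPointTable,
    canonicalize,
    parse_fatty_acid,
    sort_key,
    unsaturation_class,
)

__all__ = [
    "Cell",
    "quantified",
    "censored_below",
    "not_detected",
    "ReplicateProfile",
    "ProfileSet",
    "ProfileStats",
    "CensorPolicy",
    "degree_of_unsaturation",
    "wamt",
    "summarize",
    "CONDITIONS",
]

#: The condition vocabulary of the packaged study design: growth at 10 °C
#: under 20% CO₂ / 80% O₂ (modified atmosphere), and controls under normal
#: atmosphere at 10 °C and 25 °C.
CONDITIONS = ("co2_10C", "control_10C", "control_25C")

CensorPolicy = Literal["zero", "midpoint"]


@dataclass(frozen=True)
class Cell:
    """One fatty-acid entry of a profile: quantified mean ± sd, censored
    below a reporting threshold, or not detected."""

    kind: Literal["quantified", "censored_below", "not_detected"]
    mean: float | None = None
    sd: float | None = None
    threshold: float = 1.0
    sd_below: bool = False  # sd printed as "<x": sd holds the bound x

    def __post_init__(self) -> None:
        if self.kind == "quantified":
            if self.mean is None or not (0.0 < self.mean <= 100.0):
                raise ValueError(f"quantified mean must be in (0, 100]: {self.mean}")
            if self.sd is not None and self.sd < 0:
                raise ValueError(f"sd must be >= 0: {self.sd}")

    def resolved(self, policy: CensorPolicy = "zero") -> float:
        """Percentage used in computations under the given censoring policy.

        ``not_detected`` is always 0; ``censored_below`` is 0 under the
        default ``"zero"`` policy or half the threshold under ``"midpoint"``.
        """
        if self.kind == "quantified":
            return float(self.mean)
        if self.kind == "censored_below" and policy == "midpoint":
            return self.threshold / 2.0
        return 0.0


def quantified(mean: float, sd: float | None = None, sd_below: bool = False) -> Cell:
    return Cell("quantified", mean=mean, sd=sd, sd_below=sd_below)


def censored_below(threshold: float = 1.0) -> Cell:
    return Cell("censored_below", threshold=threshold)


def not_detected() -> Cell:
    return Cell("not_detected")


@dataclass
class ReplicateProfile:
    """Fatty-acid composition of one organism under one condition.

    ``components`` maps canonical fatty-acid labels to :class:`Cell`.
    ``replicates`` optionally carries the underlying replicate-level
    composition vectors (rows = replicates, columns = same labels); when
    present their mean/sd must agree with the summary cells.
    """

    organism: str
    condition: str
    components: dict[str, Cell]
    n_replicates: int = 3
    species: str = ""
    replicates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be positive")
        self.components = {
            canonicalize(label): cell for label, cell in self.components.items()
        }
        total = sum(
            c.mean for c in self.components.values() if c.kind == "quantified"
        )
        if self.components and not (90.0 <= total <= 102.0):
            raise ValueError(
                f"{self.organism}/{self.condition}: quantified means sum to "
                f"{total:.1f}%, outside the plausible [90, 102]% range"
            )
        if self.replicates is not None:
            self._check_replicates()

    def _check_replicates(self) -> None:
        reps = self.replicates
        if len(reps) != self.n_replicates:
            raise ValueError(
                f"{len(reps)} replicate rows but n_replicates={self.n_replicates}"
            )
        for label, cell in self.components.items():
            if cell.kind != "quantified" or label not in reps.columns:
                continue
            col = reps[label].to_numpy(float)
            if abs(col.mean() - cell.mean) > 0.05:
                raise ValueError(
                    f"{self.organism}/{self.condition}/{label}: replicate mean "
                    f"{col.mean():.3f} disagrees with summary {cell.mean:.3f}"
                )
            if cell.sd is not None and not cell.sd_below:
                if abs(col.std(ddof=1) - cell.sd) > 0.05:
                    raise ValueError(
                        f"{self.organism}/{self.condition}/{label}: replicate sd "
                        f"disagrees with summary"
                    )

    def resolved(self, policy: CensorPolicy = "zero") -> dict[str, float]:
        """Policy-resolved percentage per canonical label."""
        return {lab: cell.resolved(policy) for lab, cell in self.components.items()}

    def quantified_total(self) -> float:
        return sum(
            c.mean for c in self.components.values() if c.kind == "quantified"
        )


class ProfileSet:
    """Collection of profiles keyed by (organism, condition)."""

    def __init__(self, profiles: Iterable[ReplicateProfile] = ()) -> None:
        self._profiles: dict[tuple[str, str], ReplicateProfile] = {}
        for p in profiles:
            self.add(p)

    def add(self, profile: ReplicateProfile) -> None:
        key = (profile.organism, profile.condition)
        if key in self._profiles:
            raise ValueError(f"duplicate profile for {key}")
        self._profiles[key] = profile

    def get(self, organism: str, condition: str) -> ReplicateProfile:
        return self._profiles[(organism, condition)]

    def __contains__(self, key: tuple[str, str]) -> bool:
        return key in self._profiles

    def __len__(self) -> int:
        return len(self._profiles)

    def __iter__(self) -> Iterator[ReplicateProfile]:
        return iter(self._profiles.values())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ProfileSet):
            return NotImplemented
        if set(self._profiles) != set(other._profiles):
            return False
        for key, a in self._profiles.items():
            b = other._profiles[key]
            if (a.organism, a.condition, a.components, a.n_replicates, a.species) != (
                b.organism,
                b.condition,
                b.components,
                b.n_replicates,
                b.species,
            ):
                return False
            if (a.replicates is None) != (b.replicates is None):
                return False
            if a.replicates is not None and not a.replicates.equals(b.replicates):
                return False
        return True

    def organisms(self) -> list[str]:
        seen: dict[str, None] = {}
        for org, _ in self._profiles:
            seen.setdefault(org)
        return list(seen)

    def conditions(self) -> list[str]:
        seen: dict[str, None] = {}
        for _, cond in self._profiles:
            seen.setdefault(cond)
        return list(seen)

    def fatty_acids(self) -> list[str]:
        """Union of component labels across all profiles, in chain-length /
        bond-count order."""
        labels = {lab for p in self for lab in p.components}
        return sorted(labels, key=sort_key)


@dataclass(frozen=True)
class ProfileStats:
    du: float
    wamt: float
    wamt_coverage: float


def degree_of_unsaturation(
    profile: ReplicateProfile, censor_policy: CensorPolicy = "zero"
) -> float:
    """Degree of unsaturation of a profile.

    Each acid contributes its double-bond count times its policy-resolved
    percentage over 100.  Percentages are used as printed (% of total peak
    area); the small censored/undetected remainder is *not* redistributed.
    """
    if not profile.components:
        raise ValueError(
            f"{profile.organism}/{profile.condition}: empty profile"
        )
    du = 0.0
    for label, cell in profile.components.items():
        fa = parse_fatty_acid(label)
        du += fa.double_bond_count * cell.resolved(censor_policy) / 100.0
    return du


def wamt(
    profile: ReplicateProfile,
    table: MeltingPointTable,
    censor_policy: CensorPolicy = "zero",
) -> tuple[float, float]:
    """Weighted average melting temperature and table coverage.

    The weights are the policy-resolved percentages renormalized over the
    acids with a known melting point; ``coverage`` is the fraction of total
    resolved mass those acids account for.

    Raises
    ------
    ValueError
        If no acid with nonzero weight has a melting temperature
        ("no melting temperatures available").
    """
    weights = profile.resolved(censor_policy)
    total = sum(weights.values())
    covered_sum = 0.0
    weighted_temp = 0.0
    for label, w in weights.items():
        if w == 0.0:
            continue
        temp = table.get(label)
        if temp is not None:
            covered_sum += w
            weighted_temp += w * temp
    if covered_sum == 0.0:
        raise ValueError(
            f"{profile.organism}/{profile.condition}: "
            "no melting temperatures available"
        )
    coverage = covered_sum / total if total > 0 else 0.0
    return weighted_temp / covered_sum, coverage


def profile_stats(
    profile: ReplicateProfile,
    table: MeltingPointTable,
    censor_policy: CensorPolicy = "zero",
) -> ProfileStats:
    temp, cov = wamt(profile, table, censor_policy)
    return ProfileStats(
        du=degree_of_unsaturation(profile, censor_policy),
        wamt=temp,
        wamt_coverage=cov,
    )


def _condition_rank(cond: str) -> tuple[int, str]:
    try:
        return (CONDITIONS.index(cond), cond)
    except ValueError:
        return (len(CONDITIONS), cond)


def summarize(
    profile_set: ProfileSet,
    table: MeltingPointTable,
    censor_policy: CensorPolicy = "zero",
) -> pd.DataFrame:
    """Per-profile DU / WAMT / coverage table, ordered by organism then
    condition.  Errors in individual profiles are re-raised with the
    organism/condition context attached."""
    rows = []
    for profile in profile_set:
        try:
            stats = profile_stats(profile, table, censor_policy)
        except ValueError as err:
            raise ValueError(
                f"{profile.organism}/{profile.condition}: {err}"
            ) from err
        rows.append(
            {
                "organism": profile.organism,
                "condition": profile.condition,
                "du": stats.du,
                "wamt": stats.wamt,
                "wamt_coverage": stats.wamt_coverage,
            }
        )
    df = pd.DataFrame(
        rows, columns=["organism", "condition", "du", "wamt", "wamt_coverage"]
    )
    if len(df):
        df = df.sort_values(
            ["organism", "condition"],
            key=lambda s: (
                s if s.name == "organism" else s.map(lambda c: _condition_rank(c)[0])
            ),
            kind="stable",
        ).reset_index(drop=True)
    return df
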