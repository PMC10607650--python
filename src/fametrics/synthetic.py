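"""Synthetic replicate fatty-acid profiles with known condition effects.

The generator emulates the design of a modified-atmosphere growth study:
for each simulated organism, three conditions (CO₂-enriched at 10 °C and
controls at 10 °C / 25 °C), each observed as ``n_replicates`` compositional
vectors over a fixed panel of fatty acids.  Replicates are drawn by adding
independent per-acid Gaussian noise to the condition mean (baseline plus
the condition's signed effect vector), clipping negative draws to zero
(trace acids can vanish, as in real chromatograms) and re-closing the
vector to sum to 100%.

Because every effect sign is known by construction (:class:`GroundTruth`),
the generated sets support end-to-end sign-recovery and type-I-error
checks of the comparison pipeline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .fa_core import canonicalize, parse_fatty_acid
from .profiles import (
    Cell,
    ProfileSet,
    ReplicateProfile,
    not_detected,
    quantified,
)
from .stress_compare import replicate_test

__all__ = ["SyntheticSpec", "GroundTruth", "generate", "sign_recovery_rate"]

#: Fatty-acid panel routinely reported for food-spoilage fungi.
DEFAULT_ACIDS = (
    "C14:0",
    "C16:0",
    "C16:1 cis 9",
    "C18:0",
    "C18:1 cis 9",
    "C18:1 cis 11",
    "C18:2 cis 9, 12",
    "C18:3 cis 9, 12, 15",
    "C18:3 cis 6, 9, 12",
    "C18:0 3OH",
)

#: A typical yeast-like baseline composition (% of total), summing to 100.
DEFAULT_BASELINE = (1.0, 15.0, 5.0, 3.0, 40.0, 2.0, 22.0, 9.0, 1.0, 2.0)

#: CO₂ effect: mass moves from oleic and palmitic acid into the
#: polyunsaturated linoleic/linolenic pool (sums to zero).
DEFAULT_EFFECT_CO2 = (0.0, -3.0, 0.0, 0.0, -7.0, 0.0, 4.0, 6.0, 0.0, 0.0)

#: Warm-growth (25 °C) effect: the reverse movement, toward saturated and
#: monounsaturated acids (sums to zero).
DEFAULT_EFFECT_TEMP = (0.0, 3.0, 0.0, 1.0, 4.0, 0.0, -4.0, -4.0, 0.0, 0.0)

_CONDITION_EFFECTS = {
    "co2_10C": "effect_co2",
    "control_10C": None,
    "control_25C": "effect_temp",
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator parameters.

    ``noise_sd`` may be a scalar (shared by all acids) or a per-acid
    sequence; the default scales with abundance, clipped to the
    0.1–8 percentage-point range seen in replicate FAME tables.
    """

    organisms: int = 20
    acids: tuple[str, ...] = DEFAULT_ACIDS
    baseline_mean: tuple[float, ...] = DEFAULT_BASELINE
    effect_co2: tuple[float, ...] = DEFAULT_EFFECT_CO2
    effect_temp: tuple[float, ...] = DEFAULT_EFFECT_TEMP
    noise_sd: float | tuple[float, ...] | None = None
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "acids", tuple(canonicalize(a) for a in self.acids)
        )
        k = len(self.acids)
        for name in ("baseline_mean", "effect_co2", "effect_temp"):
            vec = tuple(float(x) for x in getattr(self, name))
            object.__setattr__(self, name, vec)
            if len(vec) != k:
                raise ValueError(f"{name} has {len(vec)} entries for {k} acids")
        if self.organisms < 1:
            raise ValueError("organisms must be >= 1")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if any(b < 0 for b in self.baseline_mean):
            raise ValueError("baseline_mean must be non-negative")
        if abs(sum(self.baseline_mean) - 100.0) > 1e-9:
            raise ValueError(
                f"baseline_mean sums to {sum(self.baseline_mean)}, not 100"
            )
        for name in ("effect_co2", "effect_temp"):
            eff = getattr(self, name)
            if abs(sum(eff)) > 1e-9:
                raise ValueError(f"{name} must sum to 0, sums to {sum(eff)}")
            shifted = [b + e for b, e in zip(self.baseline_mean, eff)]
            if any(s < 0 for s in shifted):
                raise ValueError(f"baseline + {name} goes negative: {shifted}")
        object.__setattr__(self, "noise_sd", self._resolve_noise(self.noise_sd))

    def _resolve_noise(self, noise) -> tuple[float, ...]:
        if noise is None:
            return tuple(
                min(8.0, max(0.1, 0.1 * b)) for b in self.baseline_mean
            )
        if np.isscalar(noise):
            if noise < 0:
                raise ValueError("noise_sd must be >= 0")
            return tuple(float(noise) for _ in self.acids)
        noise = tuple(float(x) for x in noise)
        if len(noise) != len(self.acids):
            raise ValueError("noise_sd length must match acids")
        if any(x < 0 for x in noise):
            raise ValueError("noise_sd must be >= 0")
        return noise

    def condition_mean(self, condition: str) -> np.ndarray:
        effect_name = _CONDITION_EFFECTS[condition]
        base = np.array(self.baseline_mean)
        if effect_name is None:
            return base
        return base + np.array(getattr(self, effect_name))

    # -- config I/O ----------------------------------------------------------

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticSpec":
        return cls(**{k: tuple(v) if isinstance(v, list) else v for k, v in d.items()})

    @classmethod
    def from_yaml(cls, path) -> "SyntheticSpec":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class GroundTruth:
    """True effect signs per (organism, acid) for each contrast, plus the
    analytic DU shift implied by each effect vector."""

    effect_signs: pd.DataFrame  # columns: organism, fatty_acid, contrast, sign
    delta_du: dict[str, float]  # contrast name -> analytic DU change

    def sign(self, organism: str, acid: str, contrast: str) -> int:
        df = self.effect_signs
        sel = df[
            (df["organism"] == organism)
            & (df["fatty_acid"] == acid)
            & (df["contrast"] == contrast)
        ]
        return int(sel["sign"].iloc[0])


def _analytic_delta_du(spec: SyntheticSpec, effect: tuple[float, ...]) -> float:
    return sum(
        parse_fatty_acid(a).double_bond_count * e / 100.0
        for a, e in zip(spec.acids, effect)
    )


def generate(spec: SyntheticSpec) -> tuple[ProfileSet, GroundTruth]:
    """Draw a replicate-level :class:`ProfileSet` and its ground truth.

    Deterministic for a fixed seed; each organism consumes an independent
    child stream of the master seed, so increasing ``organisms`` extends a
    set without reshuffling existing organisms.
    """
    master = np.random.SeedSequence(spec.seed)
    children = master.spawn(spec.organisms)
    profiles = []
    signs = []
    for i, child in enumerate(children):
        organism = f"SYN{i + 1:03d}"
        rng = np.random.default_rng(child)
        for condition in ("co2_10C", "control_10C", "control_25C"):
            mean = spec.condition_mean(condition)
            draws = rng.normal(
                loc=mean,
                scale=spec.noise_sd,
                size=(spec.n_replicates, len(spec.acids)),
            )
            draws = np.clip(draws, 0.0, None)
            totals = draws.sum(axis=1, keepdims=True)
            totals[totals == 0] = 1.0
            draws = draws / totals * 100.0
            reps = pd.DataFrame(draws, columns=list(spec.acids))
            components: dict[str, Cell] = {}
            for acid in spec.acids:
                col = reps[acid].to_numpy()
                m = float(col.mean())
                if m <= 0.0:
                    components[acid] = not_detected()
                else:
                    sd = float(col.std(ddof=1)) if spec.n_replicates > 1 else 0.0
                    components[acid] = quantified(m, sd)
            profiles.append(
                ReplicateProfile(
                    organism=organism,
                    condition=condition,
                    components=components,
                    n_replicates=spec.n_replicates,
                    replicates=reps,
                )
            )
        for contrast, effect in (
            ("co2_10C:control_10C", spec.effect_co2),
            ("control_25C:control_10C", spec.effect_temp),
        ):
            for acid, e in zip(spec.acids, effect):
                signs.append(
                    {
                        "organism": organism,
                        "fatty_acid": acid,
                        "contrast": contrast,
                        "sign": int(np.sign(e)),
                    }
                )
    truth = GroundTruth(
        effect_signs=pd.DataFrame(
            signs, columns=["organism", "fatty_acid", "contrast", "sign"]
        ),
        delta_du={
            "co2_10C:control_10C": _analytic_delta_du(spec, spec.effect_co2),
            "control_25C:control_10C": _analytic_delta_du(spec, spec.effect_temp),
        },
    )
    return ProfileSet(profiles), truth


def sign_recovery_rate(
    profile_set: ProfileSet,
    truth: GroundTruth,
    alpha: float = 0.05,
    contrast: tuple[str, str] = ("co2_10C", "control_10C"),
) -> float:
    """Fraction of truly shifted (organism, acid) cells whose Welch test is
    significant at ``alpha`` *and* whose observed delta has the true sign.

    With fewer than 3 replicates per group the Welch test has almost no
    power; a warning is emitted and the (typically tiny) rate is still
    returned.
    """
    cond_a, cond_b = contrast
    contrast_key = f"{cond_a}:{cond_b}"
    df = truth.effect_signs
    df = df[(df["contrast"] == contrast_key) & (df["sign"] != 0)]
    if df.empty:
        raise ValueError(f"ground truth has no nonzero effects for {contrast_key}")
    hits = 0
    total = 0
    low_n = False
    for _, row in df.iterrows():
        organism, acid, true_sign = row["organism"], row["fatty_acid"], row["sign"]
        if (organism, cond_a) not in profile_set or (
            organism,
            cond_b,
        ) not in profile_set:
            continue
        prof_a = profile_set.get(organism, cond_a)
        prof_b = profile_set.get(organism, cond_b)
        cell_a = prof_a.components.get(acid)
        cell_b = prof_b.components.get(acid)
        if (
            cell_a is None
            or cell_b is None
            or cell_a.kind != "quantified"
            or cell_b.kind != "quantified"
            or (cell_a.sd == 0 and cell_b.sd == 0)
        ):
            total += 1
            continue
        if prof_a.n_replicates < 3 or prof_b.n_replicates < 3:
            low_n = True
        p = replicate_test(
            (cell_a.mean, cell_a.sd, prof_a.n_replicates),
            (cell_b.mean, cell_b.sd, prof_b.n_replicates),
        )
        observed_sign = np.sign(cell_a.mean - cell_b.mean)
        total += 1
        if p < alpha and observed_sign == true_sign:
            hits += 1
    if low_n:
        warnings.warn(
            "fewer than 3 replicates per group: the Welch test is severely "
            "underpowered and the recovery rate will be low",
            stacklevel=2,
        )
    return hits / total


def false_positive_rate(
    profile_set: ProfileSet,
    truth: GroundTruth,
    alpha: float = 0.05,
    contrast: tuple[str, str] = ("co2_10C", "control_10C"),
) -> tuple[float, int]:
    """Rejection rate of the Welch test over cells with *zero* true effect,
    and the number of testable cells — the empirical type-I error under a
    null generator."""
    cond_a, cond_b = contrast
    contrast_key = f"{cond_a}:{cond_b}"
    df = truth.effect_signs
    df = df[(df["contrast"] == contrast_key) & (df["sign"] == 0)]
    rejections = 0
    total = 0
    for _, row in df.iterrows():
        organism, acid = row["organism"], row["fatty_acid"]
        prof_a = profile_set.get(organism, cond_a)
        prof_b = profile_set.get(organism, cond_b)
        cell_a = prof_a.components.get(acid)
        cell_b = prof_b.components.get(acid)
        if (
            cell_a is None
            or cell_b is None
            or cell_a.kind != "quantified"
            or cell_b.kind != "quantified"
            or (cell_a.sd == 0 and cell_b.sd == 0)
        ):
            continue
        p = replicate_test(
            (cell_a.mean, cell_a.sd, prof_a.n_replicates),
            (cell_b.mean, cell_b.sd, prof_b.n_replicates),
        )
        total += 1
        if p < alpha:
            rejections += 1
    if total == 0:
        raise ValueError("no testable null cells")
    return rejections / total, total
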