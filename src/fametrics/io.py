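"""File dialects, run configuration and the end-to-end pipeline.

Profile tables come in two dialects:

* **wide** — one row per (organism, condition); fatty-acid labels as
  columns; cells ``"mean±sd"`` (``±`` or ASCII ``+/-``), ``"nd"``, ``"<1"``
  or empty.  Optional ``species`` and ``n`` (replicate count) columns.
* **long** — tidy rows ``organism, condition, n, fatty_acid, status, mean,
  sd`` with status ``quantified`` / ``censored_below`` / ``not_detected``.

Both are TSV by default (fatty-acid labels contain commas); comma-separated
files are accepted when the filename ends in ``.csv``.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .fa_core import FattyAcidParseError, MeltingPointTable, default_melting_table, parse_fatty_acid
from .profiles import (
    Cell,
    CensorPolicy,
    ProfileSet,
    ReplicateProfile,
    censored_below,
    not_detected,
    quantified,
    summarize,
)
from .stress_compare import adaptation_summary, delta_matrix, normalize_deltas

__all__ = [
    "read_profiles",
    "write_profiles",
    "RunConfig",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

_PM_RE = re.compile(r"\s*(?:±|\+/-)\s*")
_META_COLUMNS = {"organism", "species", "condition", "n"}


def _parse_number(token: str, context: str) -> tuple[float, bool]:
    """Parse a numeric token, allowing a leading ``<`` (returns the bound
    and a below-flag).  Decimal commas are rejected explicitly."""
    token = token.strip()
    below = token.startswith("<")
    if below:
        token = token[1:].strip()
    if re.fullmatch(r"\d+,\d+", token):
        raise ValueError(
            f"{context}: {token!r} looks like a locale decimal comma; "
            "use '.' as the decimal separator"
        )
    try:
        return float(token), below
    except ValueError as err:
        raise ValueError(f"{context}: cannot parse number {token!r}") from err


def parse_cell(text: str, context: str = "cell") -> Cell:
    """Parse one wide-format cell: ``"10.4±0.5"``, ``"10.4"``, ``"nd"``,
    ``"<1"`` or empty (treated as not detected)."""
    text = ("" if text is None else str(text)).strip()
    if text in ("", "nd", "ND", "nan"):
        return not_detected()
    if text.startswith("<") and _PM_RE.search(text) is None:
        value, _ = _parse_number(text, context)
        return censored_below(value)
    parts = _PM_RE.split(text, maxsplit=1)
    mean, mean_below = _parse_number(parts[0], context)
    if mean_below:
        return censored_below(mean)
    if len(parts) == 1:
        return quantified(mean)
    sd, sd_below = _parse_number(parts[1], context)
    return quantified(mean, sd, sd_below=sd_below)


def format_cell(cell: Cell) -> str:
    if cell.kind == "not_detected":
        return "nd"
    if cell.kind == "censored_below":
        return f"<{cell.threshold:g}"
    out = f"{cell.mean:g}"
    if cell.sd is not None:
        out += f"±{'<' if cell.sd_below else ''}{cell.sd:g}"
    return out


def _sep_for(path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_profiles(path, dialect: str = "wide") -> ProfileSet:
    """Read a profile table into a :class:`ProfileSet`.

    Unknown fatty-acid columns raise with the offending label; duplicate
    (organism, condition) rows raise; an empty file yields an empty set
    with a warning.  Cells that cannot be parsed are reported together in
    the error message.
    """
    path = Path(path)
    if dialect == "long":
        return _read_long(path)
    if dialect != "wide":
        raise ValueError(f"unknown dialect {dialect!r}; use 'wide' or 'long'")
    df = pd.read_csv(path, sep=_sep_for(path), comment="#", dtype=str)
    if df.empty and not len(df.columns):
        warnings.warn(f"{path}: empty profile file", stacklevel=2)
        return ProfileSet()
    missing = {"organism", "condition"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    acid_columns = [c for c in df.columns if c not in _META_COLUMNS]
    for col in acid_columns:
        try:
            parse_fatty_acid(col)
        except FattyAcidParseError as err:
            raise ValueError(f"{path}: unknown fatty-acid column {col!r}: {err}")
    if df.empty:
        warnings.warn(f"{path}: no profile rows", stacklevel=2)
        return ProfileSet()
    profiles = ProfileSet()
    skipped: list[str] = []
    for _, row in df.iterrows():
        organism = str(row["organism"]).strip()
        condition = str(row["condition"]).strip()
        components: dict[str, Cell] = {}
        for col in acid_columns:
            context = f"{organism}/{condition}/{col}"
            try:
                components[col] = parse_cell(row[col], context)
            except ValueError as err:
                skipped.append(str(err))
        n = int(row["n"]) if "n" in df.columns and pd.notna(row["n"]) else 3
        species = (
            str(row["species"]).strip()
            if "species" in df.columns and pd.notna(row["species"])
            else ""
        )
        profile = ReplicateProfile(
            organism=organism,
            condition=condition,
            components=components,
            n_replicates=n,
            species=species,
        )
        try:
            profiles.add(profile)
        except ValueError as err:
            raise ValueError(f"{path}: {err}") from err
    if skipped:
        raise ValueError(
            f"{path}: {len(skipped)} unparseable cell(s):\n  " + "\n  ".join(skipped)
        )
    return profiles


def _read_long(path: Path) -> ProfileSet:
    df = pd.read_csv(path, sep=_sep_for(path), comment="#", dtype=str)
    if df.empty:
        warnings.warn(f"{path}: empty profile file", stacklevel=2)
        return ProfileSet()
    required = {"organism", "condition", "fatty_acid", "status"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    profiles: dict[tuple[str, str], dict] = {}
    for _, row in df.iterrows():
        key = (str(row["organism"]).strip(), str(row["condition"]).strip())
        entry = profiles.setdefault(
            key,
            {
                "components": {},
                "n": int(row["n"]) if "n" in df.columns and pd.notna(row["n"]) else 3,
                "species": (
                    str(row["species"]).strip()
                    if "species" in df.columns and pd.notna(row["species"])
                    else ""
                ),
            },
        )
        acid = str(row["fatty_acid"]).strip()
        status = str(row["status"]).strip()
        context = f"{key[0]}/{key[1]}/{acid}"
        if acid in entry["components"]:
            raise ValueError(f"{path}: duplicate entry for {context}")
        if status == "quantified":
            sd_text = str(row["sd"]) if "sd" in df.columns and pd.notna(row["sd"]) else ""
            sd, sd_below = (None, False) if not sd_text.strip() else _parse_number(
                sd_text, context
            )
            mean, _ = _parse_number(str(row["mean"]), context)
            entry["components"][acid] = quantified(mean, sd, sd_below=sd_below)
        elif status == "censored_below":
            threshold = (
                float(row["mean"]) if "mean" in df.columns and pd.notna(row["mean"]) else 1.0
            )
            entry["components"][acid] = censored_below(threshold)
        elif status == "not_detected":
            entry["components"][acid] = not_detected()
        else:
            raise ValueError(f"{path}: unknown status {status!r} at {context}")
    out = ProfileSet()
    for (organism, condition), entry in profiles.items():
        out.add(
            ReplicateProfile(
                organism=organism,
                condition=condition,
                components=entry["components"],
                n_replicates=entry["n"],
                species=entry["species"],
            )
        )
    return out


def write_profiles(profile_set: ProfileSet, path, dialect: str = "wide") -> None:
    """Write a :class:`ProfileSet` in the wide or long dialect, preserving
    censoring tokens so that read(write(s)) == s."""
    path = Path(path)
    sep = _sep_for(path)
    if dialect == "wide":
        acids = profile_set.fatty_acids()
        rows = []
        for p in profile_set:
            row = {"organism": p.organism, "species": p.species,
                   "condition": p.condition, "n": p.n_replicates}
            for acid in acids:
                cell = p.components.get(acid)
                row[acid] = format_cell(cell) if cell is not None else ""
            rows.append(row)
        df = pd.DataFrame(rows, columns=["organism", "species", "condition", "n", *acids])
    elif dialect == "long":
        rows = []
        for p in profile_set:
            for acid, cell in p.components.items():
                rows.append(
                    {
                        "organism": p.organism,
                        "species": p.species,
                        "condition": p.condition,
                        "n": p.n_replicates,
                        "fatty_acid": acid,
                        "status": cell.kind,
                        "mean": (
                            f"{cell.mean:g}"
                            if cell.kind == "quantified"
                            else (f"{cell.threshold:g}" if cell.kind == "censored_below" else "")
                        ),
                        "sd": (
                            f"{'<' if cell.sd_below else ''}{cell.sd:g}"
                            if cell.kind == "quantified" and cell.sd is not None
                            else ""
                        ),
                    }
                )
        df = pd.DataFrame(
            rows,
            columns=["organism", "species", "condition", "n", "fatty_acid", "status", "mean", "sd"],
        )
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    df.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# Run configuration and the end-to-end pipeline


@dataclass
class RunConfig:
    """Validated configuration for :func:`run_pipeline`."""

    profiles_path: str
    output_dir: str
    dialect: str = "wide"
    censor_policy: CensorPolicy = "zero"
    melting_table: str = "default"
    contrasts: tuple[tuple[str, str], ...] = (
        ("co2_10C", "control_10C"),
        ("control_25C", "control_10C"),
    )
    alpha: float = 0.05
    normalization: str = "max-abs"
    heatmaps: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha must be in (0, 1): {self.alpha}")
        if not Path(self.profiles_path).exists():
            raise ValueError(f"profiles file not found: {self.profiles_path}")
        if self.melting_table != "default" and not Path(self.melting_table).exists():
            raise ValueError(f"melting table not found: {self.melting_table}")
        self.contrasts = tuple(
            tuple(c.split(":")) if isinstance(c, str) else tuple(c)
            for c in self.contrasts
        )

    def load_melting_table(self) -> MeltingPointTable:
        if self.melting_table == "default":
            return default_melting_table()
        return MeltingPointTable.from_tsv(self.melting_table)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def digest(self) -> str:
        payload = json.dumps(
            {k: str(v) for k, v in vars(self).items()}, sort_keys=True
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _provenance_header(config: RunConfig) -> str:
    return f"# fametrics {__version__} config_hash={config.digest()}\n"


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run the full analysis: summary statistics, raw and normalized delta
    matrices per contrast, the adaptation summary for the first contrast,
    and a machine-readable run log.  Returns the paths written."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    table = config.load_melting_table()
    profile_set = read_profiles(config.profiles_path, config.dialect)
    written: dict[str, Path] = {}

    def _write(df: pd.DataFrame, name: str, index: bool = False) -> Path:
        dest = out / name
        with open(dest, "w", encoding="utf-8") as fh:
            fh.write(_provenance_header(config))
            df.to_csv(fh, index=index, na_rep="NA")
        return dest

    summary = summarize(profile_set, table, config.censor_policy)
    written["summary"] = _write(summary, "summary.csv")

    for cond_a, cond_b in config.contrasts:
        tag = f"{cond_a}_vs_{cond_b}"
        raw = delta_matrix(profile_set, (cond_a, cond_b), config.censor_policy)
        norm = normalize_deltas(raw, config.normalization)
        written[f"delta_{tag}"] = _write(raw.data, f"delta_{tag}.csv", index=True)
        written[f"delta_{tag}_normalized"] = _write(
            norm.data, f"delta_{tag}_normalized.csv", index=True
        )
        written[f"delta_{tag}_long"] = _write(raw.to_long(), f"delta_{tag}_long.csv")
        if config.heatmaps:  # pragma: no cover - optional plotting
            from .stress_compare import heatmap

            heatmap(norm, out / f"heatmap_{tag}.png")
            written[f"heatmap_{tag}"] = out / f"heatmap_{tag}.png"

    cond_a, cond_b = config.contrasts[0]
    adapt = adaptation_summary(
        profile_set, table, (cond_a, cond_b), config.censor_policy, config.alpha
    )
    written["adaptation"] = _write(adapt.table, "adaptation_summary.csv")
    written["acid_pvalues"] = _write(adapt.acid_pvalues, "acid_pvalues.csv")

    log = {
        "tool": "fametrics",
        "version": __version__,
        "config_hash": config.digest(),
        "seed": config.seed,
        "censor_policy": config.censor_policy,
        "normalization": config.normalization,
        "alpha": config.alpha,
        "n_profiles": len(profile_set),
        "contrasts": [":".join(c) for c in config.contrasts],
    }
    log_path = out / "run_log.json"
    log_path.write_text(json.dumps(log, indent=2))
    written["run_log"] = log_path
    return written
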