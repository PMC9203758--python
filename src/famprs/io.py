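"""Tab-separated trio tables, YAML configuration, and output metadata.

The on-disk exchange format is a TSV with one row per child: ``id``,
``prs``, parental columns (``mother_pheno``/``father_pheno`` z-scores for a
continuous trait, ``mother_status``/``father_status`` 0/1 indicators for a
disease), the child outcome (``pheno`` or ``status``), and named covariate
columns.  Missing values are written as ``NA``.  Every written table gets a
YAML sidecar recording the seed, parameters and a parameter hash so the
file can be regenerated.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "TrioTable",
    "TrioTableError",
    "ModelConfig",
    "ConfigError",
    "read_trio_table",
    "write_trio_table",
    "write_metadata",
    "read_metadata",
    "parameter_hash",
    "standardize_zscores",
]

_STATUS_COLUMNS = ("status", "mother_status", "father_status")
_RESERVED = {"id", "prs", "pheno", "status", "mother_pheno", "father_pheno",
             "mother_status", "father_status"}


class TrioTableError(ValueError):
    """A trio table violates the format contract."""


class ConfigError(ValueError):
    """A configuration file is malformed or inconsistent."""


@dataclass
class TrioTable:
    """A parsed trio table with per-row parental availability patterns."""

    data: pd.DataFrame
    kind: str  # "continuous" | "binary"
    pattern_counts: dict[str, int] = field(default_factory=dict)

    @property
    def covariate_columns(self) -> tuple[str, ...]:
        return tuple(c for c in self.data.columns if c not in _RESERVED)

    def patterns(self) -> pd.Series:
        return _patterns(self.data, self.kind)


def _patterns(df: pd.DataFrame, kind: str) -> pd.Series:
    suffix = "pheno" if kind == "continuous" else "status"
    has_m = df.get(f"mother_{suffix}")
    has_f = df.get(f"father_{suffix}")
    has_m = pd.Series(False, index=df.index) if has_m is None else has_m.notna()
    has_f = pd.Series(False, index=df.index) if has_f is None else has_f.notna()
    out = pd.Series("none", index=df.index)
    out[has_m & has_f] = "both"
    out[has_m & ~has_f] = "mother_only"
    out[~has_m & has_f] = "father_only"
    return out


def read_trio_table(path: str | Path) -> TrioTable:
    """Read and validate a TSV trio table.

    Raises :class:`TrioTableError` with the offending line number for
    non-numeric fields, duplicated ids, or status values outside
    ``{0, 1, NA}``.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path, sep="\t", dtype=str, na_values=["NA"],
                          keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise TrioTableError(f"{path}: empty file, header row required") from exc
    if "id" not in raw.columns or "prs" not in raw.columns:
        raise TrioTableError(f"{path}: header must include 'id' and 'prs'")
    if raw["id"].duplicated().any():
        dup = raw["id"][raw["id"].duplicated()].iloc[0]
        raise TrioTableError(f"{path}: duplicated id {dup!r}")
    has_pheno = "pheno" in raw.columns or "mother_pheno" in raw.columns
    has_status = "status" in raw.columns or "mother_status" in raw.columns
    if has_pheno and has_status:
        raise TrioTableError(f"{path}: mixes pheno and status columns")
    kind = "continuous" if has_pheno else "binary"

    df = pd.DataFrame({"id": raw["id"]})
    for col in raw.columns:
        if col == "id":
            continue
        try:
            # exact parse (pd.to_numeric's fast path is lossy at full precision)
            values = raw[col].astype(float)
        except (ValueError, TypeError):
            for i, v in raw[col].items():
                if pd.notna(v):
                    try:
                        float(v)
                    except ValueError:
                        # +1 header, +1 one-based
                        raise TrioTableError(
                            f"{path}:{int(i) + 2}: malformed value {v!r} "
                            f"in column {col!r}"
                        ) from None
            raise
        if col in _STATUS_COLUMNS:
            ok = values.isna() | values.isin([0.0, 1.0])
            if not ok.all():
                line = int((~ok).idxmax()) + 2
                raise TrioTableError(
                    f"{path}:{line}: status column {col!r} has value "
                    f"{values[(~ok).idxmax()]!r} outside {{0, 1, NA}}"
                )
        df[col] = values
    counts = _patterns(df, kind).value_counts().to_dict()
    return TrioTable(data=df, kind=kind, pattern_counts={k: int(v) for k, v in counts.items()})


def write_trio_table(
    df: pd.DataFrame,
    path: str | Path,
    metadata: dict | None = None,
    full_precision: bool = False,
) -> Path:
    """Write a trio table as TSV with ``NA`` missing values.

    Numeric output uses 6 significant digits unless ``full_precision``.
    When ``metadata`` is given it is written to ``<path>.meta.yaml`` with a
    parameter hash added.
    """
    path = Path(path)
    fmt = "%.17g" if full_precision else "%.6g"
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format=fmt)
    if metadata is not None:
        write_metadata(path.with_suffix(path.suffix + ".meta.yaml"), metadata)
    return path


def parameter_hash(payload: dict) -> str:
    """Short stable hash of a parameter dictionary (regeneration fingerprint)."""
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_metadata(path: str | Path, payload: dict) -> Path:
    path = Path(path)
    payload = dict(payload)
    payload.setdefault("parameter_hash", parameter_hash(payload))
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)
    return path


def read_metadata(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def standardize_zscores(
    values: np.ndarray | pd.Series,
    strata: np.ndarray | pd.Series | None = None,
) -> np.ndarray:
    """Z-score values, optionally within strata (e.g. sex-stratified).

    Mirrors the usual phenotype preprocessing where children's measures are
    standardized separately by sex while parents are standardized within
    their own (single-sex) populations.
    """
    values = np.asarray(values, dtype=float)
    out = np.full_like(values, np.nan)
    if strata is None:
        groups = [np.ones(values.shape, dtype=bool)]
    else:
        strata = np.asarray(strata)
        groups = [strata == s for s in pd.unique(strata[~pd.isna(strata)])]
    for mask in groups:
        mask = mask & ~np.isnan(values)
        if mask.sum() < 2:
            raise ValueError("each stratum needs at least 2 non-missing values")
        sd = values[mask].std(ddof=0)
        if sd == 0:
            raise ValueError("zero variance within a stratum")
        out[mask] = (values[mask] - values[mask].mean()) / sd
    return out


_CONFIG_DEFAULTS: dict = {
    "trait": None,  # "continuous" | "binary" (required)
    "summary": None,  # summary-statistic inputs
    "training_table": None,  # path to an individual-level TSV
    "covariates": [],
    "covariate_reference": {},
    "quadrature_nodes": 64,
    "L": 1_000_000,
    "beta_max": 5.0,
    "beta_tol": 1e-4,
    "seed": 0,
    "percentiles": [50, 80, 95, 99],
    "parent_covariate_policy": "reference",
    "simulate": None,  # block: n, alpha_sq/beta_sq or mu0/alpha/beta, keep_latent
    "full_precision": False,
}

_SIMULATE_KEYS = {
    "n", "alpha", "beta", "alpha_sq", "beta_sq", "mu0", "keep_latent",
    "use_covariates",
}


@dataclass
class ModelConfig:
    """Validated configuration for the command-line workflows.

    Every field has a documented default (see ``_CONFIG_DEFAULTS``);
    unknown keys are rejected so typos fail loudly.  ``summary`` and
    ``training_table`` are mutually exclusive routes to parameters.
    """

    values: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.values) - set(_CONFIG_DEFAULTS)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        merged = dict(_CONFIG_DEFAULTS)
        merged.update({k: v for k, v in self.values.items() if v is not None})
        self.values = merged
        if self.values["trait"] not in ("continuous", "binary", None):
            raise ConfigError(f"trait must be 'continuous' or 'binary', got {self.values['trait']!r}")
        if self.values["summary"] is not None and self.values["training_table"] is not None:
            raise ConfigError(
                "config supplies both summary statistics and a training table; "
                "choose one parameter source"
            )
        sim = self.values["simulate"]
        if sim is not None:
            unknown = set(sim) - _SIMULATE_KEYS
            if unknown:
                raise ConfigError(f"unknown simulate keys: {sorted(unknown)}")

    def __getitem__(self, key: str):
        return self.values[key]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ModelConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        return cls(values=raw)

    def with_overrides(self, **overrides) -> "ModelConfig":
        merged = dict(self.values)
        merged.update({k: v for k, v in overrides.items() if v is not None})
        return ModelConfig(values=merged)
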