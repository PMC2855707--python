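"""File formats and reports: phenotype CSV input, TSV/JSON output, configs.

The phenotype format is a tidy CSV with header columns ``generation``,
``id``, ``phenotype`` (extra columns are preserved but ignored).  Rows
sharing a (generation, id) pair are replicates of one genotype and are
collapsed to their line mean before generation summaries are computed, so a
replicated RIL population contributes one observation per line.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import __version__
from .joint import JointScalingFit, ModelSearchResult
from .scaling import EffectEstimate, GenerationMeans

__all__ = [
    "ConfigError",
    "DataError",
    "read_phenotypes",
    "read_means",
    "write_report",
    "load_config",
]


class ConfigError(ValueError):
    """Invalid configuration (CLI exit code 2)."""


class DataError(ValueError):
    """Invalid or unusable input data (CLI exit code 3)."""


def read_phenotypes(path, min_n: int = 2) -> GenerationMeans:
    """Read a per-individual phenotype CSV into generation summaries.

    Non-numeric phenotype cells raise a :class:`DataError` naming the
    offending row; empty phenotype cells are dropped with a warning;
    generations left with fewer than ``min_n`` observations are excluded
    with a warning.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except (pd.errors.EmptyDataError, FileNotFoundError) as exc:
        raise DataError(f"{path}: {exc}") from exc
    required = {"generation", "phenotype"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"{path}: missing required column(s) {sorted(missing)}")
    if len(df) == 0:
        raise DataError(f"{path}: no data rows")

    pheno = pd.to_numeric(df["phenotype"], errors="coerce")
    bad = pheno.isna() & df["phenotype"].notna()
    if bad.any():
        # +2: header line plus 1-based indexing
        lines = [int(i) + 2 for i in df.index[bad][:5]]
        raise DataError(f"{path}: non-numeric phenotype value(s) at "
                        f"line(s) {lines}")
    n_missing = int(pheno.isna().sum())
    if n_missing:
        warnings.warn(f"{path}: dropped {n_missing} row(s) with missing "
                      f"phenotype", stacklevel=2)
    df = df.assign(phenotype=pheno).dropna(subset=["phenotype"])
    if len(df) == 0:
        raise DataError(f"{path}: no usable phenotype values")

    gm = GenerationMeans.from_dataframe(df)
    keep = {}
    for g in gm.generations:
        if gm.n(g) < min_n:
            warnings.warn(f"{path}: generation {g} has n={gm.n(g)} < "
                          f"{min_n}; excluded", stacklevel=2)
        else:
            keep[g] = (gm.mean(g), gm.variance(g), gm.n(g))
    if not keep:
        raise DataError(f"{path}: no generation has n >= {min_n}")
    return GenerationMeans(keep)


def read_means(path) -> GenerationMeans:
    """Read a pre-summarised means CSV: generation, mean, variance, n."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except (pd.errors.EmptyDataError, FileNotFoundError) as exc:
        raise DataError(f"{path}: {exc}") from exc
    missing = {"generation", "mean", "variance", "n"} - set(df.columns)
    if missing:
        raise DataError(f"{path}: missing required column(s) {sorted(missing)}")
    try:
        return GenerationMeans({
            row["generation"]: (float(row["mean"]), float(row["variance"]),
                                int(row["n"]))
            for _, row in df.iterrows()})
    except (ValueError, TypeError) as exc:
        raise DataError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------


def _config_hash(config: Mapping[str, Any] | None) -> str | None:
    if config is None:
        return None
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _as_records(results) -> list[dict]:
    if isinstance(results, pd.DataFrame):
        return results.to_dict(orient="records")
    if isinstance(results, (JointScalingFit,)):
        return [results.to_dict()]
    if isinstance(results, ModelSearchResult):
        return [{"selected": results.selected.to_dict(),
                 "alpha": results.alpha, "adequate": results.adequate,
                 "path": results.path()}]
    if isinstance(results, EffectEstimate):
        return [results.to_dict()]
    if isinstance(results, (list, tuple)):
        out = []
        for r in results:
            if isinstance(r, EffectEstimate):
                out.append(r.to_dict())
            elif dataclasses.is_dataclass(r):
                out.append(dataclasses.asdict(r))
            elif isinstance(r, dict):
                out.append(dict(r))
            else:
                raise TypeError(f"cannot serialise result of type {type(r)}")
        return out
    if isinstance(results, dict):
        return [dict(results)]
    raise TypeError(f"cannot serialise results of type {type(results)}")


def write_report(results, path, format: str = "tsv",
                 config: Mapping[str, Any] | None = None,
                 timestamp: bool = False) -> Path:
    """Write an analysis report with stable field ordering.

    ``format`` is ``"tsv"`` or ``"json"``.  A version stamp and (when a
    config is supplied) a config hash are embedded.  Reports are
    byte-identical across runs unless ``timestamp=True``.
    """
    path = Path(path)
    records = _as_records(results)
    meta: dict[str, Any] = {"rilcross_version": __version__}
    h = _config_hash(config)
    if h:
        meta["config_hash"] = h
    if timestamp:
        meta["written_at"] = pd.Timestamp.now().isoformat()

    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "json":
        payload = {"meta": meta, "results": records}
        path.write_text(json.dumps(payload, indent=2, default=_json_default)
                        + "\n")
    elif format == "tsv":
        df = pd.DataFrame(records)
        header = "".join(f"# {k}: {v}\n" for k, v in meta.items())
        path.write_text(header + df.to_csv(sep="\t", index=False))
    else:
        raise ConfigError(f"unknown report format {format!r}")
    return path


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    if dataclasses.is_dataclass(o):
        return dataclasses.asdict(o)
    raise TypeError(f"not JSON serialisable: {type(o)}")


# ---------------------------------------------------------------------------
# Config files
# ---------------------------------------------------------------------------

_SIM_KEYS = {"effects", "n", "sigma_E", "variance_inflation", "t_selfing",
             "generations", "seed"}
_POWER_KEYS = {"effect_sizes", "n", "sigma2", "alpha", "method",
               "monte_carlo", "seed"}


def load_config(path, allowed_keys: set[str] | None = None) -> dict:
    """Load a JSON or YAML config file; reject unknown keys.

    ``allowed_keys=None`` skips the key check (caller validates).
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        import yaml
        try:
            cfg = yaml.safe_load(text)
        except yaml.YAMLError as exc:
            raise ConfigError(f"{path}: invalid YAML: {exc}") from exc
    else:
        try:
            cfg = json.loads(text)
        except json.JSONDecodeError as exc:
            raise ConfigError(f"{path}: invalid JSON: {exc}") from exc
    if not isinstance(cfg, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    if allowed_keys is not None:
        unknown = set(cfg) - allowed_keys
        if unknown:
            raise ConfigError(f"{path}: unknown config key(s) "
                              f"{sorted(unknown)}; allowed: "
                              f"{sorted(allowed_keys)}")
    return cfg
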