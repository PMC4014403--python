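"""Readers and writers for the package's tabular and config artifacts.

Every tabular artifact is TSV with a documented header, configs are YAML
and run manifests JSON — all diff-able, language-neutral formats.  Numeric
round-trips preserve 12 significant digits.  Writes are atomic (temp file
then rename) so a crashed run never leaves a half-written table.
"""

from __future__ import annotations

import json
import os
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model import (
    CDRC_FIELDS,
    RATIO_FIELDS,
    CDRCRanges,
    CDRCSet,
    MomentVector,
    ValidationError,
    default_ranges,
)
from .search import ACESConfig, SolutionEnsemble
from .simulate import CountDistribution, CountSample

__all__ = [
    "read_cdrc_tsv",
    "write_cdrc_tsv",
    "read_ranges",
    "write_moments_tsv",
    "write_sample_tsv",
    "read_histogram_tsv",
    "write_histogram_tsv",
    "write_ensemble_tsv",
    "read_ensemble_tsv",
    "write_manifest",
    "load_config",
    "config_to_aces",
    "atomic_write_text",
]

_FLOAT_FMT = "%.12g"


def atomic_write_text(path: str | Path, text: str) -> None:
    """Write text to ``path`` via a temp file + rename in the same directory."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=path.name + ".", suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _write_df(df: pd.DataFrame, path: str | Path) -> None:
    atomic_write_text(path, df.to_csv(sep="\t", index=False, float_format=_FLOAT_FMT))


def _read_tsv(path: str | Path, required: tuple[str, ...]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:  # noqa: BLE001 - surface file+reason
        raise ValidationError(f"cannot parse TSV {path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required columns {missing}")
    return df


def read_cdrc_tsv(path: str | Path) -> list[CDRCSet]:
    """Read rate sets from a TSV with columns k_on..g_p (one set per row)."""
    df = _read_tsv(path, CDRC_FIELDS)
    sets = []
    for i, row in df.iterrows():
        try:
            sets.append(CDRCSet(**{f: float(row[f]) for f in CDRC_FIELDS}))
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"{path}: line {i + 2}: {exc}") from exc
    return sets


def write_cdrc_tsv(sets: list[CDRCSet], path: str | Path, extra: dict | None = None) -> None:
    """Write rate sets (plus optional per-set annotation columns) as TSV."""
    data = {f: [getattr(s, f) for s in sets] for f in CDRC_FIELDS}
    if extra:
        data.update(extra)
    _write_df(pd.DataFrame(data), path)


def read_ranges(path: str | Path) -> CDRCRanges:
    """Read per-rate (min, max) ranges from TSV (*_min/*_max) or YAML."""
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        cfg = load_config(path)
        return cfg["ranges"]
    cols = tuple(f + suffix for f in CDRC_FIELDS for suffix in ("_min", "_max"))
    df = _read_tsv(path, cols)
    row = df.iloc[0]
    return CDRCRanges(
        **{f: (float(row[f + "_min"]), float(row[f + "_max"])) for f in CDRC_FIELDS}
    )


def write_moments_tsv(rows: list[dict], path: str | Path) -> None:
    """Per-set moment table: M, V, S, K, skewness, kurtosis, rna_mean, rna_fano."""
    _write_df(pd.DataFrame(rows), path)


def write_sample_tsv(sample: CountSample, path: str | Path) -> None:
    """Per-cell endpoint table (s, m, p)."""
    _write_df(pd.DataFrame({"s": sample.s, "m": sample.m, "p": sample.p}), path)


def write_histogram_tsv(dist: CountDistribution, path: str | Path) -> None:
    _write_df(
        pd.DataFrame({"count": dist.support, "probability": dist.probabilities}), path
    )


def read_histogram_tsv(path: str | Path) -> CountDistribution:
    df = _read_tsv(path, ("count", "probability"))
    probs = df["probability"].to_numpy(dtype=float)
    total = probs.sum()
    if not np.isclose(total, 1.0, atol=1e-6):
        raise ValidationError(f"{path}: probabilities sum to {total}, expected 1")
    return CountDistribution(
        support=df["count"].to_numpy(dtype=np.int64), probabilities=probs / total
    )


_ENSEMBLE_COLS = CDRC_FIELDS + ("M", "V", "S", "K") + RATIO_FIELDS


def write_ensemble_tsv(ensemble: SolutionEnsemble, path: str | Path) -> None:
    """One row per solution: six rates, four moments, eight ratios."""
    rows = []
    for s, mv, r in zip(ensemble.solutions, ensemble.moments, ensemble.ratios):
        row = {f: getattr(s, f) for f in CDRC_FIELDS}
        row.update(M=mv.M, V=mv.V, S=mv.S, K=mv.K)
        row.update(r.as_dict())
        rows.append(row)
    _write_df(pd.DataFrame(rows, columns=list(_ENSEMBLE_COLS)), path)


def read_ensemble_tsv(path: str | Path) -> list[CDRCSet]:
    """Re-read the rate sets of a written ensemble (moments/ratios rederivable)."""
    return read_cdrc_tsv(path)


def write_manifest(path: str | Path, payload: dict) -> None:
    """JSON run manifest: config echo, versions, seeds, counts, wall time."""
    atomic_write_text(path, json.dumps(payload, indent=2, sort_keys=True, default=str) + "\n")


def load_config(path: str | Path) -> dict:
    """Parse a YAML config: ranges, units, tolerances, resolution, order, seeds.

    Returns a dict with a ``ranges`` entry promoted to :class:`CDRCRanges`
    (defaults used for any rate not listed).
    """
    try:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    except yaml.YAMLError as exc:
        raise ValidationError(f"cannot parse YAML {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ValidationError(f"{path}: top level must be a mapping")
    out = dict(raw)
    base = default_ranges()
    if "ranges" in raw:
        spec = raw["ranges"]
        if not isinstance(spec, dict):
            raise ValidationError(f"{path}: 'ranges' must map rate names to [min, max]")
        updates = {}
        for name, pair in spec.items():
            if name not in CDRC_FIELDS:
                raise ValidationError(f"{path}: unknown rate {name!r} in ranges")
            if not (isinstance(pair, (list, tuple)) and len(pair) == 2):
                raise ValidationError(f"{path}: range for {name} must be [min, max]")
            updates[name] = (float(pair[0]), float(pair[1]))
        out["ranges"] = base.replace(**updates)
    else:
        out["ranges"] = base
    return out


def config_to_aces(cfg: dict, **overrides) -> ACESConfig:
    """Build an :class:`ACESConfig` from a parsed config dict plus overrides."""
    kwargs: dict = {"ranges": cfg["ranges"]}
    for key in ("resolution", "order", "reverse", "fixed", "tol", "moments", "grid_mode"):
        if key in cfg:
            kwargs[key] = tuple(cfg[key]) if key == "order" else cfg[key]
    kwargs.update(overrides)
    return ACESConfig(**kwargs)


def moment_vector_from_row(row: dict) -> MomentVector:
    return MomentVector(M=float(row["M"]), V=float(row["V"]), S=float(row["S"]), K=float(row["K"]))
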