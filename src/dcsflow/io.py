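"""File formats: curve files, manifests, run configuration and result tables.

The curve dialect is a plain-text stand-in for a correlator board's
native output: '#'-prefixed ``key: value`` header lines carrying the
acquisition metadata, followed by two tab-separated columns
``lag_s<TAB>g2``. Manifests and result tables are CSV; result tables are
prefixed with comment lines recording the master seed and the SHA-256 of
the run configuration so every output is traceable to its inputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import io as _io
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import CohortDesign, NoiseModel
from .errors import DataError, ParseError
from .forward import LagGrid, OpticalProperties
from .inversion import AutocorrCurve, CurveMeta, FitOptions

__all__ = [
    "read_curve",
    "write_curve",
    "read_manifest",
    "write_manifest",
    "RunConfig",
    "write_table",
    "read_table",
]

_REQUIRED_KEYS = (
    "mouse", "group", "week", "position", "separation_mm", "repeat",
    "integration_s", "wavelength_nm",
)
MANIFEST_COLUMNS = ["mouse", "group", "week", "position", "separation_mm", "repeat", "path"]


def write_curve(
    curve: AutocorrCurve,
    path: str | Path,
    integration_s: float = 2.0,
    wavelength_nm: float = 785.0,
) -> None:
    """Write one curve in the text dialect; full float precision (repr round-trip)."""
    m = curve.meta
    lines = [
        f"# mouse: {m.mouse}",
        f"# group: {m.group}",
        f"# week: {m.week}",
        f"# position: {m.position}",
        f"# separation_mm: {m.separation_mm!r}",
        f"# repeat: {m.repeat}",
        f"# integration_s: {integration_s!r}",
        f"# wavelength_nm: {wavelength_nm!r}",
    ]
    for lag, g2 in zip(curve.lags.lags_s, curve.g2):
        lines.append(f"{float(lag)!r}\t{float(g2)!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_curve(path: str | Path) -> AutocorrCurve:
    """Parse a curve file; raises :class:`ParseError` naming the offending line."""
    meta: dict[str, str] = {}
    lags: list[float] = []
    g2: list[float] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if ":" not in body:
                raise ParseError(f"malformed header {line!r}", line=lineno)
            key, _, value = body.partition(":")
            meta[key.strip()] = value.strip()
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ParseError(
                f"expected 2 tab-separated columns, got {len(parts)}", line=lineno
            )
        try:
            lags.append(float(parts[0]))
            g2.append(float(parts[1]))
        except ValueError as exc:
            raise ParseError(f"non-numeric data row: {exc}", line=lineno) from None

    missing = [k for k in _REQUIRED_KEYS if k not in meta]
    if missing:
        raise ParseError(f"missing metadata key(s): {', '.join(missing)}")
    if not lags:
        raise ParseError("no data rows")
    lag_arr = np.asarray(lags)
    if np.any(np.diff(lag_arr) <= 0):
        bad = int(np.argmax(np.diff(lag_arr) <= 0))
        raise ParseError("lag column is not strictly increasing",
                         line=len(meta) + bad + 2)
    try:
        cmeta = CurveMeta(
            mouse=meta["mouse"], group=meta["group"], week=int(meta["week"]),
            position=meta["position"], separation_mm=float(meta["separation_mm"]),
            repeat=int(meta["repeat"]),
        )
    except ValueError as exc:
        raise ParseError(f"invalid metadata: {exc}") from None
    return AutocorrCurve(lags=LagGrid(lag_arr), g2=np.asarray(g2), meta=cmeta)


def write_manifest(rows: pd.DataFrame, path: str | Path) -> None:
    rows[MANIFEST_COLUMNS].to_csv(path, index=False)


def read_manifest(path: str | Path, check_paths: bool = True) -> pd.DataFrame:
    """Read a manifest CSV; validates column set, key uniqueness and file existence."""
    df = pd.read_csv(path)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"manifest missing column(s): {', '.join(sorted(missing))}")
    key = ["mouse", "week", "position", "separation_mm", "repeat"]
    if df.duplicated(subset=key).any():
        raise DataError("manifest contains duplicate (mouse, week, position, separation, repeat) keys")
    if check_paths:
        root = Path(path).parent
        for p in df["path"]:
            full = root / p
            if not full.exists():
                raise DataError(f"manifest references missing curve file: {full}")
    return df


@dataclass(frozen=True)
class RunConfig:
    """Complete configuration of a simulate/fit/analyze run; YAML round-trippable."""

    optics: OpticalProperties = OpticalProperties()
    fit: FitOptions = FitOptions()
    design: CohortDesign = CohortDesign()
    noise: NoiseModel = NoiseModel()
    seed: int = 1
    outdir: str = "dcs_out"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["seed"] = int(self.seed)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        def build(klass, block):
            block = dict(block or {})
            for k, v in block.items():
                if isinstance(v, list):
                    block[k] = tuple(v)
            return klass(**block)

        return cls(
            optics=build(OpticalProperties, d.get("optics")),
            fit=build(FitOptions, d.get("fit")),
            design=build(CohortDesign, d.get("design")),
            noise=build(NoiseModel, d.get("noise")),
            seed=int(d.get("seed", 1)),
            outdir=str(d.get("outdir", "dcs_out")),
        )

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    @property
    def sha256(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()


def write_table(df: pd.DataFrame, path: str | Path, seed: int, config_hash: str) -> None:
    """Write a result CSV prefixed with seed and config-hash comment lines."""
    buf = _io.StringIO()
    buf.write(f"# seed: {seed}\n# config_sha256: {config_hash}\n")
    df.to_csv(buf, index=False)
    Path(path).write_text(buf.getvalue())


def read_table(path: str | Path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, comment="#")
    except pd.errors.EmptyDataError:
        return pd.DataFrame()
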