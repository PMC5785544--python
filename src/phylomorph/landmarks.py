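"""Landmark configurations, TPS-dialect file I/O, metadata and QC.

The atomic observation is a :class:`LandmarkConfiguration`: one specimen's
k x d matrix of landmark coordinates (d = 2 or 3) in physical length units
after the digitizer's pixel/voxel scale is applied.  Files follow the flat
TPS dialect emitted by the tpsDig family of tools: ``LM=`` (2D) or ``LM3=``
(3D) counts, one whitespace-separated landmark per line, ``ID=`` /
``IMAGE=`` specimen identifiers, and an optional ``SCALE=`` factor.

Missing landmarks are unsupported by design: configurations with absent
bones are excluded upstream rather than imputed, so any non-finite
coordinate or -999-style sentinel is a hard error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

ECOLOGY_CATEGORIES = ("aquatic", "terrestrial", "leaf_litter", "fossorial",
                      "arboreal")

__all__ = [
    "ECOLOGY_CATEGORIES",
    "LandmarkConfiguration",
    "SpecimenMetadata",
    "Dataset",
    "DatasetError",
    "TPSFormatError",
    "read_tps",
    "write_tps",
    "read_metadata",
    "qc_outliers",
]


class TPSFormatError(ValueError):
    pass


class DatasetError(ValueError):
    pass


@dataclass
class LandmarkConfiguration:
    """One specimen's landmark coordinates.

    ``coords`` are in physical units (after any scale factor has been
    applied); ``scale`` records the units-per-pixel/voxel factor used.
    ``stage`` is ``adult``, ``juvenile`` or ``embryo_stage_<S>``.
    """

    specimen_id: str
    species_id: str
    coords: np.ndarray
    scale: float = 1.0
    stage: str = "adult"

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] not in (2, 3):
            raise DatasetError(
                f"{self.specimen_id}: coords must be k x d with d in {{2,3}}")
        if not np.all(np.isfinite(self.coords)):
            raise DatasetError(
                f"{self.specimen_id}: non-finite coordinate (missing landmarks "
                "are unsupported)")
        if np.any(self.coords == -999.0):
            raise DatasetError(
                f"{self.specimen_id}: -999 sentinel coordinate (missing "
                "landmarks are unsupported)")
        if not self.scale > 0:
            raise DatasetError(f"{self.specimen_id}: scale must be positive")

    @property
    def k(self) -> int:
        return self.coords.shape[0]

    @property
    def d(self) -> int:
        return self.coords.shape[1]


@dataclass
class SpecimenMetadata:
    species_id: str
    ecology: str = "unknown"
    clade: str = ""
    stage: str = "adult"

    def __post_init__(self):
        if self.ecology not in ECOLOGY_CATEGORIES + ("unknown",):
            raise DatasetError(
                f"{self.species_id}: ecology {self.ecology!r} not one of "
                f"{ECOLOGY_CATEGORIES} or 'unknown'")


@dataclass
class Dataset:
    """Landmark configurations plus a species-keyed metadata table."""

    configurations: list
    metadata: pd.DataFrame = field(default=None)

    def validate(self) -> None:
        """Raise DatasetError naming the first violated invariant."""
        if len(self.configurations) < 3:
            raise DatasetError(
                f"dataset has {len(self.configurations)} configurations; "
                "at least 3 are needed for superimposition")
        k, d = self.configurations[0].k, self.configurations[0].d
        for cfg in self.configurations:
            if (cfg.k, cfg.d) != (k, d):
                raise DatasetError(
                    f"{cfg.specimen_id}: landmark layout {cfg.k}x{cfg.d} "
                    f"differs from dataset layout {k}x{d}")
        if self.metadata is not None:
            known = set(self.metadata["species_id"])
            for cfg in self.configurations:
                if cfg.species_id not in known:
                    raise DatasetError(
                        f"{cfg.specimen_id}: species {cfg.species_id!r} "
                        "absent from metadata")

    def coords_array(self) -> np.ndarray:
        self.validate()
        return np.stack([c.coords for c in self.configurations])

    @property
    def specimen_ids(self) -> list:
        return [c.specimen_id for c in self.configurations]

    @property
    def species_ids(self) -> list:
        return [c.species_id for c in self.configurations]


def _species_from_specimen(specimen_id: str) -> str:
    return specimen_id.split("__")[0]


def _stage_from_specimen(specimen_id: str) -> str:
    """The TPS dialect has no stage field; a ``__<stage>`` suffix on the
    specimen id (``sp12__embryo_stage_10``) carries it, defaulting to adult."""
    parts = specimen_id.split("__")
    if len(parts) > 1 and (parts[-1] in ("adult", "juvenile")
                           or parts[-1].startswith("embryo_stage_")):
        return parts[-1]
    return "adult"


def read_tps(path, scale_policy: str = "apply") -> list:
    """Read landmark configurations from a TPS flat file.

    ``scale_policy="apply"`` multiplies each record's coordinates by its
    SCALE factor; ``"ignore"`` keeps raw digitized units.  ``ID=`` is
    preferred over ``IMAGE=`` for the specimen identifier, falling back to
    the record's position in the file.
    """
    if scale_policy not in ("apply", "ignore"):
        raise ValueError("scale_policy must be 'apply' or 'ignore'")
    records = []
    current = None
    with open(path) as fh:
        lines = fh.readlines()
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        upper = line.upper()
        if upper.startswith("LM3=") or upper.startswith("LM="):
            if current is not None:
                records.append(current)
            ndim = 3 if upper.startswith("LM3=") else 2
            try:
                count = int(line.split("=", 1)[1])
            except ValueError:
                raise TPSFormatError(f"line {lineno}: bad landmark count") from None
            current = {"n": count, "d": ndim, "rows": [], "id": None,
                       "image": None, "scale": 1.0, "line": lineno}
        elif "=" in line and not line[0].isdigit() and not line[0] in "+-.":
            if current is None:
                raise TPSFormatError(f"line {lineno}: field outside a record")
            key, val = line.split("=", 1)
            key = key.strip().upper()
            if key == "ID":
                current["id"] = val.strip()
            elif key == "IMAGE":
                current["image"] = val.strip()
            elif key == "SCALE":
                try:
                    current["scale"] = float(val)
                except ValueError:
                    raise TPSFormatError(
                        f"line {lineno}: non-numeric SCALE") from None
            # other TPS fields (CURVES=, POINTS=, ...) are ignored
        else:
            if current is None:
                raise TPSFormatError(f"line {lineno}: coordinates outside a record")
            parts = line.split()
            try:
                row = [float(p) for p in parts]
            except ValueError:
                raise TPSFormatError(
                    f"line {lineno}: non-numeric coordinate {line!r}") from None
            if len(row) != current["d"]:
                raise TPSFormatError(
                    f"line {lineno}: expected {current['d']} coordinates, "
                    f"got {len(row)}")
            current["rows"].append(row)
    if current is not None:
        records.append(current)

    configs = []
    expected = None
    for i, rec in enumerate(records):
        name = rec["id"] or rec["image"] or f"record_{i}"
        if len(rec["rows"]) != rec["n"]:
            raise TPSFormatError(
                f"record {name!r} (line {rec['line']}): LM={rec['n']} but "
                f"{len(rec['rows'])} coordinate lines")
        if expected is None:
            expected = (rec["n"], rec["d"])
        elif (rec["n"], rec["d"]) != expected:
            raise TPSFormatError(
                f"record {name!r} (line {rec['line']}): landmark count "
                f"{rec['n']}x{rec['d']} inconsistent with {expected[0]}x"
                f"{expected[1]} earlier in file")
        coords = np.asarray(rec["rows"], dtype=float)
        scale = rec["scale"]
        if scale_policy == "apply":
            coords = coords * scale
        configs.append(LandmarkConfiguration(
            specimen_id=name, species_id=_species_from_specimen(name),
            coords=coords, scale=scale if scale_policy == "apply" else 1.0,
            stage=_stage_from_specimen(name)))
    log.info("read_tps: %s -> %d configurations", path, len(configs))
    return configs


def write_tps(configs: list, path) -> None:
    """Write configurations as TPS records.

    Coordinates are written in their stored physical units with SCALE=1, so
    ``read_tps(..., 'apply')`` after ``write_tps`` round-trips coordinates
    exactly.  An empty list yields an empty file.
    """
    if configs:
        k, d = configs[0].k, configs[0].d
        for cfg in configs:
            if (cfg.k, cfg.d) != (k, d):
                raise DatasetError(
                    f"{cfg.specimen_id}: heterogeneous landmark layout")
    with open(path, "w") as fh:
        for cfg in configs:
            tag = "LM3" if cfg.d == 3 else "LM"
            fh.write(f"{tag}={cfg.k}\n")
            for row in cfg.coords:
                fh.write(" ".join(f"{v:.17g}" for v in row) + "\n")
            fh.write(f"ID={cfg.specimen_id}\n")
            fh.write("SCALE=1\n")
    log.info("write_tps: wrote %d configurations to %s", len(configs), path)


def read_metadata(path) -> pd.DataFrame:
    """Read the species metadata CSV (species_id, ecology, clade, stage)."""
    df = pd.read_csv(path, dtype=str).fillna("unknown")
    if "species_id" not in df.columns:
        raise DatasetError("metadata CSV must have a species_id column")
    bad = set(df.get("ecology", pd.Series(dtype=str))) - set(
        ECOLOGY_CATEGORIES) - {"unknown"}
    if bad:
        raise DatasetError(f"unknown ecology categories: {sorted(bad)}")
    return df


def qc_outliers(alignment, threshold_sd: float) -> list:
    """Flag shape outliers after superimposition.

    Returns the specimen_ids whose Procrustes distance to the consensus
    exceeds mean + threshold_sd * SD of all such distances.  Data are only
    flagged, never removed.
    """
    if threshold_sd < 0:
        raise ValueError("threshold_sd must be non-negative")
    n = alignment.aligned.shape[0]
    if n < 3:
        raise DatasetError("outlier QC needs at least 3 specimens")
    dists = np.sqrt(((alignment.aligned - alignment.consensus) ** 2)
                    .sum(axis=(1, 2)))
    cut = dists.mean() + threshold_sd * dists.std(ddof=0)
    flagged = [alignment.specimen_ids[i] for i in np.flatnonzero(dists > cut)]
    log.info("qc_outliers: %d/%d specimens beyond mean + %.3g SD",
             len(flagged), n, threshold_sd)
    return flagged
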