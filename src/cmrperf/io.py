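"""File round-tripping: NIfTI image series and masks, CSV curves and
cohort tables, YAML configuration, JSON results.

CSV and JSON are the canonical exchange formats; NIfTI is used only for
image series and masks.  Every output embeds the tool version, a hash of
the generating configuration and the seed, so re-running a stage with
identical inputs is bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .exceptions import ConfigurationError, InputError
from .phantom import (
    AifParams,
    KineticParams,
    PhantomConfig,
    StateConfig,
    SubjectTruth,
)
from .segmentation import SegmentationMask, TimeIntensityCurve, partition_sectors

# Label codes in mask NIfTIs: 0 background, 1 cavity, 2 unsectored
# myocardium, 11..14 myocardial sectors in anatomical order.
CAVITY_CODE = 1
MYO_CODE = 2
SECTOR_BASE_CODE = 11


def config_hash(config) -> str:
    """Stable short hash of a configuration object or mapping."""
    if dataclasses.is_dataclass(config) and not isinstance(config, type):
        payload = dataclasses.asdict(config)
    else:
        payload = config
    text = json.dumps(payload, sort_keys=True, default=str)
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def _meta(config=None, seed: int | None = None) -> dict:
    meta = {"tool": "cmrperf", "version": __version__}
    if config is not None:
        meta["config_hash"] = config_hash(config)
    if seed is not None:
        meta["seed"] = int(seed)
    return meta


def _meta_comment(config=None, seed: int | None = None) -> str:
    parts = [f"{k}={v}" for k, v in _meta(config, seed).items()]
    return "# " + " ".join(parts)


# ---------------------------------------------------------------------------
# NIfTI

def write_series_nifti(series: np.ndarray, path: str | Path) -> None:
    """Write a dynamic series (n_frames, rows, cols) as an (x, y, frame) NIfTI."""
    vol = np.transpose(np.asarray(series, dtype=np.float64), (1, 2, 0))
    nib.save(nib.Nifti1Image(vol, np.eye(4)), str(path))


def read_series_nifti(path: str | Path) -> np.ndarray:
    vol = np.asarray(nib.load(str(path)).dataobj, dtype=np.float64)
    if vol.ndim != 3:
        raise InputError(f"{path}: expected a 3-D (x, y, frame) series")
    return np.transpose(vol, (2, 0, 1))


def write_mask_nifti(mask: SegmentationMask, path: str | Path) -> None:
    """Write an integer-coded labelmap (0/1/11..14) for a segmentation mask."""
    labels = np.zeros(mask.shape, dtype=np.int16)
    labels[mask.cavity] = CAVITY_CODE
    sel = mask.myocardium
    labels[sel] = SECTOR_BASE_CODE + mask.sector_index[sel]
    nib.save(nib.Nifti1Image(labels, np.eye(4)), str(path))


def read_mask_nifti(path: str | Path, reference_angle: float = 0.0) -> SegmentationMask:
    """Read a labelmap back into a :class:`SegmentationMask`.

    Sector codes 11..14 are honored; a plain myocardium code 2 (no sector
    information) is re-partitioned into 4 sectors about the cavity centroid.
    """
    labels = np.asarray(nib.load(str(path)).dataobj).astype(int)
    cavity = labels == CAVITY_CODE
    sectored = labels >= SECTOR_BASE_CODE
    plain = labels == MYO_CODE
    myocardium = sectored | plain
    if not cavity.any() or not myocardium.any():
        raise InputError(f"{path}: labelmap lacks cavity and/or myocardium")
    centroid = tuple(float(c.mean()) for c in np.nonzero(cavity))
    if plain.any() and not sectored.any():
        return partition_sectors(cavity, myocardium, centroid, reference_angle)
    sector_index = np.where(sectored, labels - SECTOR_BASE_CODE, -1)
    return SegmentationMask(
        cavity=cavity, myocardium=myocardium, sector_index=sector_index,
        center=centroid, reference_angle=reference_angle,
    )


# ---------------------------------------------------------------------------
# Curves CSV

def write_curves_csv(
    curves: list[TimeIntensityCurve], path: str | Path,
    config=None, seed: int | None = None,
) -> None:
    """Write curves as CSV rows (frame, value, region, state) with a meta header."""
    frames = []
    for c in curves:
        frames.append(pd.DataFrame({
            "frame": c.frames, "value": c.values,
            "region": c.region, "state": c.state if c.state is not None else "",
        }))
    df = pd.concat(frames, ignore_index=True)
    with open(path, "w") as fh:
        fh.write(_meta_comment(config, seed) + "\n")
        df.to_csv(fh, index=False, lineterminator="\n", float_format="%.12g")


def read_curves_csv(path: str | Path) -> dict[str, dict[str, TimeIntensityCurve]]:
    """Read a curves CSV into {state: {region: curve}}."""
    df = pd.read_csv(path, comment="#")
    required = {"frame", "value", "region", "state"}
    if not required.issubset(df.columns):
        raise InputError(f"{path}: curves CSV needs columns {sorted(required)}")
    out: dict[str, dict[str, TimeIntensityCurve]] = {}
    for (state, region), grp in df.groupby(["state", "region"], sort=False):
        grp = grp.sort_values("frame")
        state_key = "" if pd.isna(state) else str(state)
        out.setdefault(state_key, {})[str(region)] = TimeIntensityCurve(
            frames=grp["frame"].to_numpy(int), values=grp["value"].to_numpy(float),
            region=str(region), state=state_key or None,
        )
    return out


# ---------------------------------------------------------------------------
# YAML configuration

def config_to_dict(config: PhantomConfig) -> dict:
    return dataclasses.asdict(config)


def config_from_dict(d: dict) -> PhantomConfig:
    try:
        d = dict(d)
        if "aif" in d:
            d["aif"] = AifParams(**d["aif"])
        if "kinetics" in d:
            d["kinetics"] = KineticParams(**d["kinetics"])
        if "states" in d:
            d["states"] = tuple(StateConfig(**s) for s in d["states"])
        return PhantomConfig(**d)
    except TypeError as exc:
        raise ConfigurationError(f"bad phantom configuration: {exc}") from exc


def write_config_yaml(config: PhantomConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)


def read_config_yaml(path: str | Path) -> PhantomConfig:
    try:
        with open(path) as fh:
            data = yaml.safe_load(fh)
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        where = f" (line {mark.line + 1}, column {mark.column + 1})" if mark else ""
        raise ConfigurationError(f"malformed YAML in {path}{where}: {exc}") from exc
    if not isinstance(data, dict):
        raise ConfigurationError(f"{path}: expected a mapping at top level")
    return config_from_dict(data)


# ---------------------------------------------------------------------------
# JSON results

def write_json(payload: dict, path: str | Path, config=None, seed: int | None = None) -> None:
    doc = {"meta": _meta(config, seed), **payload}
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=False, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def read_json(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def truth_to_dict(truth: SubjectTruth) -> dict:
    return {
        "flows": dict(truth.flows),
        "true_mpr": truth.true_mpr,
        "recovery_to_rest": truth.recovery_to_rest,
        "delayed": truth.delayed,
    }


def write_cohort_csv(df: pd.DataFrame, path: str | Path,
                     config=None, seed: int | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_meta_comment(config, seed) + "\n")
        df.to_csv(fh, index=False, lineterminator="\n", float_format="%.12g")


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
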